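"""Generator contracts: determinism, stated rates, and forward-model truth."""

import numpy as np
import pandas as pd
import pytest

from duoqtl.simulate import (F1Line, Indel, PlantedQtl, SimConfig, TruthSet,
                             mechanism_phenotype, plant_indel_carriers,
                             simulate_allele_counts, simulate_bin_coverage,
                             simulate_experiment, simulate_f1,
                             simulate_marker_population, simulate_parents,
                             simulate_phenotypes)


class TestParents:
    def test_same_seed_identical(self):
        a = simulate_parents(n_chrom=2, chrom_len=300_000, seed=3)
        b = simulate_parents(n_chrom=2, chrom_len=300_000, seed=3)
        for chrom in ("Chr01", "Chr02"):
            pd.testing.assert_frame_equal(a[0].sites[chrom], b[0].sites[chrom])
            pd.testing.assert_frame_equal(a[1].sites[chrom], b[1].sites[chrom])

    def test_het_count_poisson_concentration(self):
        pd_g, pn_g = simulate_parents(n_chrom=1, chrom_len=1_000_000,
                                      het_density=1e-3, seed=4)
        for g in (pd_g, pn_g):
            assert abs(g.n_het_sites() - 1000) < 4 * np.sqrt(1000)

    def test_chromosome_count_configurable(self):
        pd_g, _ = simulate_parents(n_chrom=19, chrom_len=100_000,
                                   het_density=2e-4, seed=5)
        assert len(pd_g.chroms) == 19

    def test_het_alleles_distinct_and_positions_increasing(self, tiny_parents):
        for g in tiny_parents:
            for chrom, _ in g.chroms:
                het = g.het_sites(chrom)
                assert (het["a1"] != het["a2"]).all()
                pos = g.sites[chrom]["pos"].to_numpy()
                assert (np.diff(pos) > 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_parents(n_chrom=0)
        with pytest.raises(ValueError):
            simulate_parents(het_density=0)


class TestF1:
    def test_zero_indel_rate(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=20, indel_rate=0, seed=1,
                            indel_size_range=(100_000, 200_000))
        assert all(not l.indels for l in lines)

    def test_zero_recombination_single_block(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=10, recomb_per_chrom=0,
                            seed=2, indel_size_range=(100_000, 200_000))
        for l in lines:
            for chrom_intervals in l.pd_inheritance.values():
                assert len(chrom_intervals) == 1

    def test_deletion_fraction_matches_rate(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=4000, indel_rate=2.5,
                            p_deletion=0.665, seed=3,
                            indel_size_range=(100_000, 200_000))
        kinds = [i.kind for l in lines for i in l.indels]
        assert len(kinds) > 9000
        frac = np.mean([k == "deletion" for k in kinds])
        assert abs(frac - 0.665) < 0.02

    def test_inheritance_tiles_chromosome(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=30, seed=4,
                            indel_size_range=(100_000, 200_000))
        for l in lines:
            for chrom, length in tiny_parents[0].chroms:
                ivs = l.pn_inheritance[chrom]
                assert ivs[0][0] == 1 and ivs[-1][1] == length
                for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
                    assert s2 == e1 + 1

    def test_indels_never_overlap_within_line(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=300, indel_rate=4, seed=5,
                            indel_size_range=(100_000, 200_000))
        for l in lines:
            for i, a in enumerate(l.indels):
                assert not any(a.overlaps(b) for b in l.indels[i + 1:])

    def test_oversized_indel_range_rejected(self, tiny_parents):
        with pytest.raises(ValueError):
            simulate_f1(tiny_parents, n_lines=1,
                        indel_size_range=(10**9, 2 * 10**9))


class TestAlleleCounts:
    def test_error_free_reads_subset_of_true_alleles(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=3, indel_rate=0, seed=6,
                            indel_size_range=(100_000, 200_000))
        counts = simulate_allele_counts(tiny_parents, lines, mean_depth=20,
                                        error_rate=0.0, seed=7)
        pd_g, pn_g = tiny_parents
        for line in lines:
            df = counts[line.line_id]
            for chrom in ("Chr01",):
                sub = df[df["chrom"] == chrom]
                sites = pd_g.sites[chrom].set_index("pos")
                sites_n = pn_g.sites[chrom].set_index("pos")
                for _, row in sub.head(200).iterrows():
                    pos = row["pos"]
                    hap_d = line.hap_at("Pd", chrom, pos)
                    hap_n = line.hap_at("Pn", chrom, pos)
                    allowed = {sites.loc[pos, f"a{hap_d}"],
                               sites_n.loc[pos, f"a{hap_n}"]}
                    observed = {b for b in "ACGT" if row[b] > 0}
                    assert observed <= allowed

    def test_mean_depth_calibration(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=12, indel_rate=0, seed=8,
                            indel_size_range=(100_000, 200_000))
        counts = simulate_allele_counts(tiny_parents, lines, mean_depth=0.5,
                                        error_rate=0.0, seed=9)
        n_sites = sum(len(tiny_parents[0].sites[c])
                      for c, _ in tiny_parents[0].chroms)
        total = sum(df[list("ACGT")].to_numpy().sum()
                    for df in counts.values())
        mean_depth = total / (n_sites * len(lines))
        assert abs(mean_depth - 0.5) < 0.05

    def test_deletion_halves_depth(self, tiny_parents):
        chrom, length = tiny_parents[0].chroms[0]
        base = simulate_f1(tiny_parents, n_lines=1, indel_rate=0, seed=10,
                           indel_size_range=(100_000, 200_000))[0]
        deleted = F1Line("del", base.pd_inheritance, base.pn_inheritance,
                         [Indel(chrom, 1, length, "deletion")])
        counts = simulate_allele_counts(tiny_parents, [base, deleted],
                                        mean_depth=30, error_rate=0.0,
                                        seed=11)
        n_sites = len(tiny_parents[0].sites[chrom])
        d_base = counts[base.line_id]
        d_del = counts["del"]
        depth_base = d_base[d_base["chrom"] == chrom][list("ACGT")].sum().sum() / n_sites
        depth_del = d_del[d_del["chrom"] == chrom][list("ACGT")].sum().sum() / n_sites
        assert abs(depth_del / depth_base - 0.5) < 0.05


class TestBinCoverage:
    def test_copy_number_expectations(self, tiny_parents):
        chrom, length = tiny_parents[0].chroms[0]
        base = simulate_f1(tiny_parents, n_lines=1, indel_rate=0, seed=12,
                           indel_size_range=(100_000, 200_000))[0]
        # deletion spanning exactly bins 2..5, insertion spanning bins 7..8
        lines = [
            base,
            F1Line("del4", base.pd_inheritance, base.pn_inheritance,
                   [Indel(chrom, 50_001, 250_000, "deletion")]),
            F1Line("ins2", base.pd_inheritance, base.pn_inheritance,
                   [Indel(chrom, 300_001, 400_000, "insertion")]),
        ]
        bins, cov = simulate_bin_coverage(lines, tiny_parents[0].chroms,
                                          bin_size=50_000, mean_cov=2000,
                                          seed=13)
        sub = bins[bins["chrom"] == chrom].reset_index(drop=True)
        base_cov = cov.loc[sub["marker_id"], base.line_id].to_numpy()
        del_cov = cov.loc[sub["marker_id"], "del4"].to_numpy()
        ins_cov = cov.loc[sub["marker_id"], "ins2"].to_numpy()
        np.testing.assert_allclose(del_cov[1:5] / base_cov[1:5], 0.5,
                                   atol=0.12)
        np.testing.assert_allclose(del_cov[0] / base_cov[0], 1.0, atol=0.12)
        np.testing.assert_allclose(ins_cov[6:8] / base_cov[6:8], 1.5,
                                   atol=0.15)


class TestPhenotypes:
    def test_zero_effects_are_pure_noise(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=400, seed=14,
                            indel_size_range=(100_000, 200_000))
        truth = TruthSet(lines=lines, planted_qtls=[], noise_sd={"t": 1.0},
                         beta0={"t": 5.0}, parents=tiny_parents)
        ph = simulate_phenotypes(truth, seed=15)
        y = ph.values["t"]
        assert abs(y.mean() - 5.0) < 0.2 and abs(y.std() - 1.0) < 0.15

    def test_noise_free_dosage_effect_exact(self, tiny_parents):
        chrom, length = tiny_parents[0].chroms[0]
        base = simulate_f1(tiny_parents, n_lines=4, indel_rate=0, seed=16,
                           indel_size_range=(100_000, 200_000))
        deleted = F1Line("del", base[0].pd_inheritance,
                         base[0].pn_inheritance,
                         [Indel(chrom, 1, length, "deletion")])
        qtl = PlantedQtl("t", chrom, 100_000, 110_000, "dosage", 2.0)
        truth = TruthSet(lines=base + [deleted], planted_qtls=[qtl],
                         noise_sd={"t": 0.0}, parents=tiny_parents)
        ph = simulate_phenotypes(truth, seed=17)
        normal = ph.values.loc[base[0].line_id, "t"]
        assert ph.values.loc["del", "t"] == pytest.approx(normal - 2.0)

    def test_ols_recovers_planted_effect(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=343, seed=18,
                            indel_size_range=(100_000, 200_000))
        qtl = PlantedQtl("t", "Chr01", 200_000, 210_000, "Pd", 1.0)
        truth = TruthSet(lines=lines, planted_qtls=[qtl],
                         noise_sd={"t": 1.0}, parents=tiny_parents)
        ph = simulate_phenotypes(truth, seed=19)
        g = np.array([l.hap_at("Pd", "Chr01", qtl.midpoint) - 1
                      for l in lines], dtype=float)
        y = ph.values["t"].to_numpy()
        gc = g - g.mean()
        beta = float(gc @ (y - y.mean())) / float(gc @ gc)
        se = 1.0 / np.sqrt(float(gc @ gc))
        assert abs(beta - 1.0) < 3 * se

    def test_planted_qtl_outside_genome_rejected(self, tiny_parents):
        lines = simulate_f1(tiny_parents, n_lines=2, seed=20,
                            indel_size_range=(100_000, 200_000))
        qtl = PlantedQtl("t", "Chr09", 1, 10, "Pd", 1.0)
        truth = TruthSet(lines=lines, planted_qtls=[qtl],
                         noise_sd={"t": 1.0}, parents=tiny_parents)
        with pytest.raises(ValueError, match="outside"):
            simulate_phenotypes(truth, seed=21)


class TestExperimentDeterminism:
    def test_identical_seeds_identical_outputs(self):
        cfg = SimConfig(n_chrom=1, chrom_len=300_000, n_lines=10, deep_n=5)
        a = simulate_experiment(cfg, seed=42)
        b = simulate_experiment(cfg, seed=42)
        pd.testing.assert_frame_equal(a.phenotypes.values, b.phenotypes.values)
        pd.testing.assert_frame_equal(a.bin_coverage, b.bin_coverage)
        for lid in a.lowcov_counts:
            pd.testing.assert_frame_equal(a.lowcov_counts[lid],
                                          b.lowcov_counts[lid])


class TestMarkerPopulation:
    def test_determinism_and_shape(self):
        a = simulate_marker_population(n_lines=50, seed=9)
        b = simulate_marker_population(n_lines=50, seed=9)
        np.testing.assert_array_equal(a.dose, b.dose)
        np.testing.assert_array_equal(a.pd_code, b.pd_code)
        assert a.dose.shape == (100, 50)

    def test_planted_carriers_present(self):
        pop = simulate_marker_population(n_lines=200, seed=10)
        before = (pop.dose[30] == 0).sum()
        plant_indel_carriers(pop, 30, "deletion", n_carriers=20, seed=11)
        assert (pop.dose[30] == 0).sum() >= 20

    def test_mechanism_phenotype_effect_scaling(self):
        pop = simulate_marker_population(n_lines=343, seed=12)
        plant_indel_carriers(pop, 10, "deletion", n_carriers=20, seed=13)
        y, beta = mechanism_phenotype(pop, 10, "deletion", effect_std=0.5,
                                      seed=14)
        code = (pop.dose[10] == 0).astype(float)
        assert beta == pytest.approx(0.5 / code.std())
        carriers = y[code == 1].mean() - y[code == 0].mean()
        assert abs(carriers - beta) < 3 * (1 / np.sqrt((code == 1).sum()))
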