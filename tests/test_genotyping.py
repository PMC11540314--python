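"""Low-coverage genotyping: diagnostic reads, binning, line QC."""

import numpy as np
import pandas as pd
import pytest

from duoqtl.genotyping import (BinnedGenotypeMatrix, SnpHaplotypeObservations,
                               bin_genotypes, call_snp_haplotypes,
                               qc_select_lines)
from duoqtl.phasing import PhaseBlock, PhasedHaplotypes
from duoqtl.snp_select import InformativeSnpTable


def _setup_single_site():
    """One Pd site A/G phased as (hap1=A, hap2=G), Pn = A/A."""
    haps = PhasedHaplotypes("Pd", [PhaseBlock("Chr01", 0, pd.DataFrame(
        {"pos": [100], "hap1_allele": ["A"], "hap2_allele": ["G"]}))])
    snps = InformativeSnpTable("Pd", pd.DataFrame(
        {"chrom": ["Chr01"], "pos": [100], "focal_a1": ["A"],
         "focal_a2": ["G"], "other_alleles": ["A"]}))
    return haps, snps


def _count_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "A", "C", "G", "T"])


class TestCallSnpHaplotypes:
    def test_alternative_allele_read_records_haplotype(self):
        haps, snps = _setup_single_site()
        counts = {"L1": _count_df([("Chr01", 100, 0, 0, 1, 0)])}  # one G read
        obs = call_snp_haplotypes(counts, haps, snps)
        assert obs.codes.loc[0, "L1"] == 1  # hap2 carries G

    def test_shared_allele_read_is_uninformative(self):
        haps, snps = _setup_single_site()
        counts = {"L1": _count_df([("Chr01", 100, 1, 0, 0, 0)])}  # one A read
        obs = call_snp_haplotypes(counts, haps, snps)
        assert obs.codes.loc[0, "L1"] == -1

    def test_no_reads_no_record(self):
        haps, snps = _setup_single_site()
        counts = {"L1": _count_df([])}
        obs = call_snp_haplotypes(counts, haps, snps)
        assert obs.codes.loc[0, "L1"] == -1

    def test_error_read_matching_neither_parent_ignored(self):
        haps, snps = _setup_single_site()
        counts = {"L1": _count_df([("Chr01", 100, 0, 1, 0, 0)])}  # C read
        obs = call_snp_haplotypes(counts, haps, snps)
        assert obs.codes.loc[0, "L1"] == -1


def _obs(codes, positions=None, chrom="Chr01"):
    codes = np.asarray(codes, dtype=np.int8)
    n_sites = codes.shape[0]
    positions = positions or [100 * (i + 1) for i in range(n_sites)]
    sites = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "hap1_allele": "A", "hap2_allele": "G",
                          "block_id": 0})
    return SnpHaplotypeObservations(
        "Pd", sites, pd.DataFrame(codes, columns=[f"L{i}" for i in
                                                  range(codes.shape[1])]))


class TestBinGenotypes:
    def test_majority_tie_and_empty(self):
        col = [[0], [0], [0], [0], [0], [0], [0],          # 7x H1
               [0], [0], [0], [1], [1], [1], [-1],          # 3 vs 3 tie
               [-1], [-1], [-1], [-1], [-1], [-1], [-1],    # no observations
               [1]]                                          # short last bin
        obs = _obs(col)
        binned = bin_genotypes(obs, bin_size=7)
        assert list(binned.geno["L0"]) == ["H1", None, None, "H2"]
        assert list(binned.markers["snp_count"]) == [7, 7, 7, 1]

    def test_bin_intervals_span_member_snps(self):
        obs = _obs([[0]] * 5, positions=[10, 20, 30, 40, 55])
        binned = bin_genotypes(obs, bin_size=2)
        assert list(binned.markers["marker_id"]) == [
            "Chr01_10_20", "Chr01_30_40", "Chr01_55_55"]

    def test_majority_is_order_invariant(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([-1, 0, 1], size=(50, 8))
        a = bin_genotypes(_obs(codes), bin_size=50).geno
        b = bin_genotypes(_obs(codes[::-1]), bin_size=50).geno
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_bin_size_validated(self):
        with pytest.raises(ValueError):
            bin_genotypes(_obs([[0]]), bin_size=0)


class TestQcSelectLines:
    def _binned(self, geno_rows, lines):
        codes = np.asarray(geno_rows, dtype=object)
        markers = pd.DataFrame({
            "marker_id": [f"Chr01_{i * 10 + 1}_{i * 10 + 10}"
                          for i in range(codes.shape[0])],
            "chrom": "Chr01",
            "start": [i * 10 + 1 for i in range(codes.shape[0])],
            "end": [i * 10 + 10 for i in range(codes.shape[0])],
            "snp_count": 50})
        geno = pd.DataFrame(codes, columns=lines,
                            index=pd.Index(markers["marker_id"],
                                           name="marker_id"))
        return BinnedGenotypeMatrix("Pd", markers, geno)

    def test_clean_lines_all_retained(self):
        g = [["H1", "H1"], ["H1", "H2"], ["H2", "H2"], ["H2", "H2"]]
        genomic = self._binned(g, ["L1", "L2"])
        reference = self._binned(g, ["L1", "L2"])
        depths = pd.Series({"L1": 0.5, "L2": 0.3})
        selected, threshold, diag = qc_select_lines(genomic, reference,
                                                    depths, max_switches=2)
        assert set(selected) == {"L1", "L2"}
        assert threshold == 0.3

    def test_discordant_line_pushes_threshold(self):
        """A low-depth line whose genotypes disagree with the reference
        raises the depth cut so only cleaner lines survive."""
        good = ["H1"] * 5 + ["H2"] * 5
        bad_ref = ["H1", "H2"] * 5
        genomic = self._binned(np.array([good, good]).T, ["L1", "L2"])
        reference = self._binned(np.array([good, bad_ref]).T, ["L1", "L2"])
        depths = pd.Series({"L1": 0.5, "L2": 0.1})
        selected, threshold, _ = qc_select_lines(
            genomic, reference, depths, min_concordance=0.9, max_switches=3)
        assert selected == ["L1"] and threshold == 0.5

    def test_no_feasible_threshold_is_an_error(self):
        good = ["H1"] * 4
        bad = ["H1", "H2", "H1", "H2"]
        genomic = self._binned(np.array([bad]).T.reshape(4, 1), ["L1"])
        reference = self._binned(np.array([good]).T.reshape(4, 1), ["L1"])
        with pytest.raises(ValueError, match="diagnostics"):
            qc_select_lines(genomic, reference, pd.Series({"L1": 1.0}),
                            min_concordance=0.9, max_switches=1)


class TestRecoveryOnDefaultData:
    def test_bin_genotype_accuracy_and_na_rate(self, default_stages):
        """At 0.5x, >= 90% of non-NA bin genotypes match truth; the NA rate
        shrinks as depth grows."""
        cfg, exp, parents = default_stages
        res = parents["Pd"]
        geno = res.binned.geno
        markers = res.binned.markers
        truth_lines = {l.line_id: l for l in exp.lines}
        # per-block orientation: is the phased hap1 the truth's hap1?
        blocks = []
        for blk in res.haplotypes.blocks:
            truth = exp.parents[0].sites[blk.chrom].set_index("pos")
            t1 = truth.loc[blk.sites["pos"], "a1"].to_numpy()
            swapped = (blk.sites["hap1_allele"].to_numpy() != t1).mean() > 0.5
            blocks.append((blk.chrom, int(blk.sites["pos"].min()),
                           int(blk.sites["pos"].max()), swapped))

        def orientation(chrom, pos):
            for c, lo, hi, swapped in blocks:
                if c == chrom and lo <= pos <= hi:
                    return swapped
            return None

        match = 0
        total = 0
        for line_id in geno.columns:
            line = truth_lines[line_id]
            calls = geno[line_id]
            for mid, chrom, start, end in zip(
                    markers["marker_id"], markers["chrom"],
                    markers["start"], markers["end"]):
                call = calls[mid]
                if call is None or (isinstance(call, float) and np.isnan(call)):
                    continue
                swapped = orientation(chrom, start)
                if swapped is None:
                    continue
                true_hap = line.hap_at("Pd", chrom, (start + end) // 2)
                want = 3 - true_hap if swapped else true_hap
                total += 1
                match += int(call == f"H{want}")
        assert total > 1000
        assert match / total >= 0.90

    def test_na_rate_decreases_with_depth(self, tiny_parents):
        from duoqtl.phasing import PhaseBlock, PhasedHaplotypes
        from duoqtl.simulate import simulate_allele_counts, simulate_f1
        from duoqtl.snp_select import informative_snps_from_truth

        lines = simulate_f1(tiny_parents, n_lines=40, indel_rate=0, seed=61,
                            indel_size_range=(100_000, 200_000))
        snps = informative_snps_from_truth(tiny_parents, "Pd")
        blocks = []
        for chrom, _ in tiny_parents[0].chroms:
            sub = snps.rows[snps.rows["chrom"] == chrom]
            blocks.append(PhaseBlock(chrom, len(blocks), pd.DataFrame(
                {"pos": sub["pos"].to_numpy(),
                 "hap1_allele": sub["focal_a1"].to_numpy(),
                 "hap2_allele": sub["focal_a2"].to_numpy()})))
        haps = PhasedHaplotypes("Pd", blocks)
        na_rates = []
        for depth in (0.02, 0.1, 0.5):
            counts = simulate_allele_counts(tiny_parents, lines,
                                            mean_depth=depth, error_rate=0.0,
                                            seed=62)
            obs = call_snp_haplotypes(counts, haps, snps)
            binned = bin_genotypes(obs, bin_size=50)
            na_rates.append(float(binned.geno.isna().to_numpy().mean()))
        assert na_rates[0] > na_rates[1] > na_rates[2]
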