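"""End-to-end orchestration: simulate -> phase -> genotype -> QTL scans.

The pipeline mirrors the analysis order of the real study design: select
informative SNPs from parental calls, phase each parent with the
deep-coverage progeny subset, genotype every line from low-coverage
counts, call dosage from bin coverage, integrate the channels on a common
marker grid, then run the three single-channel scans and the combined
10-state model for every trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dosage as dosage_mod
from . import genotyping, integrate, phasing, qtl_combined, qtl_single, snp_select
from .config import PipelineConfig
from .io import PhenotypeTable
from .simulate import (SimConfig, SyntheticExperiment, TruthSet,
                       simulate_experiment)

log = logging.getLogger("duoqtl")


def sim_config(cfg: PipelineConfig) -> SimConfig:
    return SimConfig(
        n_chrom=cfg.n_chrom, chrom_len=cfg.chrom_len,
        het_density=cfg.het_density, n_lines=cfg.n_lines, deep_n=cfg.deep_n,
        recomb_per_chrom=cfg.recomb_per_chrom, indel_rate=cfg.indel_rate,
        indel_size_range=(cfg.indel_min_size, cfg.indel_max_size),
        p_deletion=cfg.p_deletion, low_depth=cfg.low_depth,
        deep_depth=cfg.deep_depth, error_rate=cfg.error_rate,
        cov_bin_size=cfg.cov_bin_size, mean_bin_cov=cfg.mean_bin_cov)


@dataclass
class GenotypingResult:
    """Phasing plus binned genotypes for one parent."""

    snps: snp_select.InformativeSnpTable
    haplotypes: phasing.PhasedHaplotypes
    binned: genotyping.BinnedGenotypeMatrix
    reference_binned: genotyping.BinnedGenotypeMatrix


@dataclass
class PipelineResult:
    config: PipelineConfig
    experiment: SyntheticExperiment
    parents: dict[str, GenotypingResult]
    selected_lines: list[str]
    depth_threshold: float
    dosage: dosage_mod.DosageMatrix
    common: integrate.CommonMarkerTable
    single_scans: dict[tuple[str, str], qtl_single.ScanResult]
    combined_scans: dict[str, qtl_combined.CombinedScanResult]
    qtls: pd.DataFrame
    report: pd.DataFrame = field(default_factory=pd.DataFrame)


def mean_depth_per_line(counts: dict[str, pd.DataFrame],
                        n_sites: int) -> pd.Series:
    """Mean read depth per line over the joint site list."""
    totals = {lid: df[list("ACGT")].to_numpy().sum()
              for lid, df in counts.items()}
    return pd.Series(totals, dtype=float) / n_sites


def genotype_parent(exp: SyntheticExperiment, focal: str,
                    cfg: PipelineConfig) -> GenotypingResult:
    """SNP selection, phasing and binned genotyping for one parent."""
    pd_calls = snp_select.call_genotypes(exp.parent_counts["Pd"])
    pn_calls = snp_select.call_genotypes(exp.parent_counts["Pn"])
    snps = snp_select.select_informative_snps(pd_calls, pn_calls, focal=focal)
    log.info("%s: %d informative SNPs (%s excluded)", focal, len(snps),
             snps.excluded)
    matrix = phasing.infer_inherited_alleles(exp.deep_counts, snps,
                                             depth_min=cfg.depth_min)
    haps = phasing.phase_parent(matrix, consistency=cfg.consistency)
    log.info("%s: %d phase blocks over %d sites", focal, len(haps.blocks),
             len(haps.site_table()))
    obs = genotyping.call_snp_haplotypes(exp.lowcov_counts, haps, snps)
    binned = genotyping.bin_genotypes(obs, bin_size=cfg.bin_size)
    ref_obs = genotyping.call_snp_haplotypes(exp.deep_counts, haps, snps)
    ref_binned = genotyping.bin_genotypes(ref_obs, bin_size=cfg.bin_size)
    return GenotypingResult(snps=snps, haplotypes=haps, binned=binned,
                            reference_binned=ref_binned)


def run_synthetic(cfg: PipelineConfig | None = None,
                  seed: int | None = None,
                  planted_qtls=None, noise_sd=None) -> PipelineResult:
    """Run the full pipeline on a synthetic experiment."""
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    exp = simulate_experiment(sim_config(cfg), seed=seed,
                              planted_qtls=planted_qtls, noise_sd=noise_sd)
    parents = {p: genotype_parent(exp, p, cfg) for p in ("Pd", "Pn")}

    n_sites = sum(len(exp.parents[0].sites[c]) for c, _ in exp.parents[0].chroms)
    depths = mean_depth_per_line(exp.lowcov_counts, n_sites)
    selected, threshold, _ = genotyping.qc_select_lines(
        parents["Pd"].binned, parents["Pd"].reference_binned, depths,
        min_concordance=cfg.min_concordance, max_switches=cfg.max_switches)
    log.info("line QC: %d of %d lines retained (depth >= %.3g)",
             len(selected), len(depths), threshold)

    for p in parents.values():
        p.binned.geno = p.binned.geno[selected]

    dose = dosage_mod.call_dosage_from_coverage(
        exp.bin_coverage[selected], exp.dosage_bins,
        low_cut=cfg.low_cut, high_cut=cfg.high_cut, min_run=cfg.min_run)
    common = integrate.build_common_markers(parents["Pd"].binned,
                                            parents["Pn"].binned, dose)
    states = qtl_combined.assign_states(common)

    single_scans: dict[tuple[str, str], qtl_single.ScanResult] = {}
    combined_scans: dict[str, qtl_combined.CombinedScanResult] = {}
    all_qtls = []
    rng = np.random.SeedSequence(seed).spawn(1)[0]
    scan_seed = int(rng.generate_state(1)[0] % (2**31))
    for t_i, trait in enumerate(exp.phenotypes.traits):
        y = exp.phenotypes.values[trait]
        for c_i, channel in enumerate(qtl_single.CHANNELS):
            res = qtl_single.scan_channel(
                y, common, channel, n_perm=cfg.n_perm,
                seed=scan_seed + 101 * t_i + c_i, min_n=cfg.min_n,
                min_minor=cfg.min_minor, trait=trait)
            single_scans[(trait, channel)] = res
            all_qtls.append(res.qtls)
        comb = qtl_combined.combined_scan(
            y, states, n_perm=cfg.n_perm, alpha=cfg.alpha,
            seed=scan_seed + 101 * t_i + 7, min_group=cfg.min_group,
            trait=trait)
        combined_scans[trait] = comb
        all_qtls.append(comb.qtls)
    nonempty = [q for q in all_qtls if len(q)]
    qtls = (pd.concat(nonempty, ignore_index=True)
            if nonempty else (all_qtls[0] if all_qtls else pd.DataFrame()))
    result = PipelineResult(
        config=cfg, experiment=exp, parents=parents,
        selected_lines=selected, depth_threshold=threshold, dosage=dose,
        common=common, single_scans=single_scans,
        combined_scans=combined_scans, qtls=qtls)
    result.report = build_report(result)
    return result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _interval_from_marker(marker_id: str) -> tuple[str, int, int]:
    chrom, start, end = marker_id.rsplit("_", 2)
    return chrom, int(start), int(end)


def qtl_interval(row: pd.Series) -> tuple[str, int, int]:
    chrom, start, _ = _interval_from_marker(row["start_marker"])
    _, _, end = _interval_from_marker(row["end_marker"])
    return chrom, start, end


def planted_recall(qtls: pd.DataFrame, truth: TruthSet) -> float:
    """Fraction of planted QTLs overlapped by any called QTL interval."""
    if not truth.planted_qtls:
        return float("nan")
    hits = 0
    intervals = [qtl_interval(row) for _, row in qtls.iterrows()]
    for q in truth.planted_qtls:
        for chrom, start, end in intervals:
            if chrom == q.chrom and start <= q.end and q.start <= end:
                hits += 1
                break
    return hits / len(truth.planted_qtls)


def build_report(result: PipelineResult) -> pd.DataFrame:
    """Per trait x channel/model: QTL count and variance explained.

    ``ve_single_mean``/``ve_single_sd`` summarize per-QTL adjusted R^2;
    ``ve_all`` is the joint adjusted R^2 of the trait on the peak markers
    of all the channel's QTLs.
    """
    rows = []
    traits = result.experiment.phenotypes.traits
    for trait in traits:
        y_full = result.experiment.phenotypes.values[trait]
        for channel in qtl_single.CHANNELS:
            scan = result.single_scans[(trait, channel)]
            q = scan.qtls
            if len(q):
                codes = qtl_single.encode_channel(result.common, channel)
                lines = [l for l in codes.columns if l in y_full.index]
                yv = y_full.loc[lines].to_numpy(dtype=float)
                G = codes.loc[q["peak_marker"], lines].to_numpy(dtype=float).T
                ve_all = qtl_single.variance_explained(yv, G)
                rows.append((trait, channel, len(q),
                             float(q["variance_explained"].mean()),
                             float(q["variance_explained"].std(ddof=0)),
                             ve_all))
            else:
                rows.append((trait, channel, 0, np.nan, np.nan, np.nan))
        comb = result.combined_scans[trait].qtls
        if len(comb):
            rows.append((trait, "combined", len(comb),
                         float(comb["variance_explained"].mean()),
                         float(comb["variance_explained"].std(ddof=0)),
                         np.nan))
        else:
            rows.append((trait, "combined", 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["trait", "channel", "n_qtl",
                                       "ve_single_mean", "ve_single_sd",
                                       "ve_all"])
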