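"""Truth-based evaluation of pipeline stages on synthetic experiments.

These helpers compare stage outputs against the simulator's ledger:
phase-link orientation, binned-genotype accuracy (up to the per-block
hap1/hap2 relabeling that phasing cannot resolve), dosage recovery, the
genome-wide type-I rate of the permutation threshold, and planted-QTL
detection/classification rates for the scans.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotyping import BinnedGenotypeMatrix
from .phasing import PhasedHaplotypes
from .qtl_combined import assign_states, combined_scan
from .qtl_single import prepare_design, scan_channel, _t_from_design
from .simulate import (F1Line, MarkerPopulation, ParentalGenome,
                       mechanism_phenotype, plant_indel_carriers,
                       simulate_marker_population)


# ---------------------------------------------------------------------------
# phasing / genotyping / dosage recovery
# ---------------------------------------------------------------------------


def phase_link_accuracy(haps: PhasedHaplotypes,
                        genome: ParentalGenome) -> float:
    """Fraction of accepted adjacent-SNP links oriented as in the truth."""
    stats = haps.link_stats
    stats = stats[stats["accepted"]]
    if stats.empty:
        return float("nan")
    correct = 0
    for chrom, sub in stats.groupby("chrom"):
        sites = genome.sites[chrom].set_index("pos")
        a1 = sites["a1"]
        a2 = sites["a2"]
        # alphabetical code of the allele truth-hap1 carries at each site
        code_l = (a1.loc[sub["pos_left"]].to_numpy()
                  > a2.loc[sub["pos_left"]].to_numpy()).astype(int)
        code_r = (a1.loc[sub["pos_right"]].to_numpy()
                  > a2.loc[sub["pos_right"]].to_numpy()).astype(int)
        truth_trans = (code_l != code_r).astype(int)
        correct += int((sub["orientation"].to_numpy() == truth_trans).sum())
    return correct / len(stats)


def _block_orientations(haps: PhasedHaplotypes, genome: ParentalGenome):
    out = []
    for blk in haps.blocks:
        truth = genome.sites[blk.chrom].set_index("pos")
        t1 = truth.loc[blk.sites["pos"], "a1"].to_numpy()
        swapped = (blk.sites["hap1_allele"].to_numpy() != t1).mean() > 0.5
        out.append((blk.chrom, int(blk.sites["pos"].min()),
                    int(blk.sites["pos"].max()), bool(swapped)))
    return out


def bin_genotype_accuracy(binned: BinnedGenotypeMatrix,
                          haps: PhasedHaplotypes,
                          genome: ParentalGenome,
                          lines: list[F1Line],
                          parent: str) -> tuple[float, float]:
    """(accuracy of non-NA bin calls, NA rate), up to per-block relabeling."""
    blocks = _block_orientations(haps, genome)

    def orientation(chrom, pos):
        for c, lo, hi, swapped in blocks:
            if c == chrom and lo <= pos <= hi:
                return swapped
        return None

    truth_lines = {l.line_id: l for l in lines}
    geno = binned.geno
    markers = binned.markers
    match = total = na = cells = 0
    for line_id in geno.columns:
        line = truth_lines[line_id]
        calls = geno[line_id]
        for mid, chrom, start, end in zip(markers["marker_id"],
                                          markers["chrom"],
                                          markers["start"], markers["end"]):
            cells += 1
            call = calls[mid]
            if call is None or (isinstance(call, float) and np.isnan(call)):
                na += 1
                continue
            swapped = orientation(chrom, start)
            if swapped is None:
                continue
            true_hap = line.hap_at(parent, chrom, (start + end) // 2)
            want = (3 - true_hap) if swapped else true_hap
            total += 1
            match += int(call == f"H{want}")
    return (match / total if total else float("nan"),
            na / cells if cells else float("nan"))


def dosage_confusion(dose: pd.DataFrame, bins: pd.DataFrame,
                     lines: list[F1Line]) -> tuple[float, float]:
    """(sensitivity on true indel bins, false-call rate on euploid bins)."""
    mids = ((bins["start"] + bins["end"]) // 2).to_numpy()
    truth = np.ones(dose.shape)
    for j, line in enumerate(lines):
        for ind in line.indels:
            mask = ((bins["chrom"] == ind.chrom).to_numpy()
                    & (mids >= ind.start) & (mids <= ind.end))
            truth[mask, j] = 0 if ind.kind == "deletion" else 2
    called = dose.to_numpy()
    indel_bins = truth != 1
    sensitivity = float((called[indel_bins] == truth[indel_bins]).mean())
    false_rate = float((called[~indel_bins] != 1).mean())
    return sensitivity, false_rate


# ---------------------------------------------------------------------------
# scan calibration and power
# ---------------------------------------------------------------------------


def null_scan_type_i(G: np.ndarray, n_traits: int = 200, n_perm: int = 200,
                     seed: int = 0, min_n: int = 20,
                     min_minor: int = 5) -> float:
    """Fraction of i.i.d.-noise traits with any marker above their own
    genome-wide 95% permutation threshold; ~5% by construction."""
    rng = np.random.default_rng(seed)
    design = prepare_design(G, min_n, min_minor)
    hits = 0
    n = G.shape[0]
    for t in range(n_traits):
        y = rng.normal(size=n)
        maxima = np.empty(n_perm)
        for b in range(n_perm):
            tt = np.abs(_t_from_design(design, rng.permutation(y)))
            maxima[b] = 0.0 if np.all(np.isnan(tt)) else np.nanmax(tt)
        t95 = np.percentile(maxima, 95)
        obs = np.abs(_t_from_design(design, y))
        hits += int(np.nanmax(obs) > t95 if not np.all(np.isnan(obs)) else 0)
    return hits / n_traits


def _overlaps_marker(qtls: pd.DataFrame, markers: pd.DataFrame,
                     marker_index: int, span: int) -> pd.DataFrame:
    planted = markers.iloc[marker_index]
    end = markers.iloc[min(marker_index + span - 1, len(markers) - 1)]
    lo, hi = planted["start"], end["end"]
    keep = []
    for _, q in qtls.iterrows():
        chrom_s, s, _ = q["start_marker"].rsplit("_", 2)
        _, _, e = q["end_marker"].rsplit("_", 2)
        if chrom_s == planted["chrom"] and int(s) <= hi and lo <= int(e):
            keep.append(q)
    return pd.DataFrame(keep, columns=qtls.columns)


def dosage_detection_rate(n_reps: int = 50, effect_std: float = 0.3,
                          n_perm: int = 200, seed: int = 0,
                          marker_index: int = 30, span: int = 3,
                          n_del: int = 24, n_ins: int = 12) -> float:
    """Power of the single-channel dosage scan for one planted QTL.

    Each replicate draws a fresh marker-level population, plants deletion
    and insertion carriers at the QTL (so the dosage code varies there),
    simulates the trait at the standardized effect, and counts a success
    when a called QTL interval overlaps the planted markers.
    """
    detected = 0
    for r in range(n_reps):
        pop = simulate_marker_population(seed=seed + 1000 + r)
        plant_indel_carriers(pop, marker_index, "deletion", n_del, span=span,
                             seed=seed + 2000 + r)
        plant_indel_carriers(pop, marker_index + span, "insertion", n_ins,
                             span=span, seed=seed + 3000 + r)
        y, _ = mechanism_phenotype(pop, marker_index, "dosage",
                                   effect_std=effect_std,
                                   seed=seed + 4000 + r)
        table = pop.to_common_marker_table()
        res = scan_channel(y, table, "dosage", n_perm=n_perm,
                           seed=seed + 5000 + r, trait="t")
        hits = _overlaps_marker(res.qtls, pop.markers, marker_index,
                                span + span)
        detected += int(len(hits) > 0)
    return detected / n_reps


MECHANISMS = ("deletion", "insertion", "Pd", "Pn", "Pd+Pn")


def mechanism_recovery(mechanism: str, n_reps: int = 15,
                       effect_std: float = 0.5, n_perm: int = 1000,
                       alpha: float = 0.05, seed: int = 0,
                       marker_index: int = 30, span: int = 3,
                       ) -> tuple[int, int]:
    """(detected, correctly classified) for one planted single mechanism.

    Dosage mechanisms get enough planted carriers at the QTL for their
    state groups to qualify (>= min_group per joint state); allelic
    mechanisms use the background population. A replicate counts as
    detected when a combined-model QTL overlaps the planted markers, and
    correct when that QTL's group equals the planted mechanism.
    """
    detected = correct = 0
    for r in range(n_reps):
        pop = simulate_marker_population(seed=seed + 100 + r)
        if mechanism == "deletion":
            plant_indel_carriers(pop, marker_index, "deletion", 14,
                                 span=span, seed=seed + 200 + r)
        elif mechanism == "insertion":
            plant_indel_carriers(pop, marker_index, "insertion", 24,
                                 span=span, seed=seed + 300 + r)
        y, _ = mechanism_phenotype(pop, marker_index, mechanism,
                                   effect_std=effect_std, seed=seed + 400 + r)
        states = assign_states(pop.to_common_marker_table())
        res = combined_scan(y, states, n_perm=n_perm, alpha=alpha,
                            seed=seed + 500 + r, trait="t")
        hits = _overlaps_marker(res.qtls, pop.markers, marker_index, span)
        if len(hits) == 0:
            continue
        detected += 1
        correct += int(mechanism in set(hits["channel_or_group"]))
    return detected, correct
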