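"""Genotyping all F1 lines from low-coverage counts with phased haplotypes.

At ~0.5x coverage most informative SNPs have zero or one read per line, so
a genotype is recorded at a SNP only when a read shows a haplotype-
diagnostic allele — one that, given the other parent's genotype, can only
have come from one of the focal parent's haplotypes. The sparse per-SNP
calls are then binned (50 SNPs per marker by default) and combined by
majority vote to make the calls robust; ties and empty bins are missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NUCLEOTIDES, marker_id
from .phasing import PhasedHaplotypes
from .snp_select import InformativeSnpTable

_BASE_COL = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass
class SnpHaplotypeObservations:
    """Sparse per-SNP haplotype observations for many lines.

    ``codes`` is sites x lines, int8: 0 = focal haplotype 1, 1 = haplotype
    2, -1 = no informative read. Rows align with ``sites`` (chrom, pos,
    hap1_allele, hap2_allele, block_id).
    """

    focal_parent: str
    sites: pd.DataFrame
    codes: pd.DataFrame


@dataclass
class BinnedGenotypeMatrix:
    """Majority-vote genotypes on bins of consecutive informative SNPs.

    ``geno`` is indexed by marker_id with one column per line and values
    "H1"/"H2"/NaN. Marker intervals span [first SNP pos, last SNP pos] of
    the bin, 1-based inclusive.
    """

    focal_parent: str
    markers: pd.DataFrame  # marker_id, chrom, start, end, snp_count
    geno: pd.DataFrame


def call_snp_haplotypes(counts: dict[str, pd.DataFrame],
                        haplotypes: PhasedHaplotypes,
                        snps: InformativeSnpTable,
                        ) -> SnpHaplotypeObservations:
    """Record the transmitted focal haplotype wherever a read is diagnostic.

    A focal allele is diagnostic iff the other parent does not carry it.
    A site yields a call when reads support exactly one diagnostic focal
    allele; reads showing only alleles shared with the other parent (or
    matching neither parent — sequencing error) yield no call.
    """
    sites = haplotypes.site_table()
    sites = sites.merge(snps.rows[["chrom", "pos", "other_alleles"]],
                        on=["chrom", "pos"], how="left")
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    h1_col = sites["hap1_allele"].map(_BASE_COL).to_numpy()
    h2_col = sites["hap2_allele"].map(_BASE_COL).to_numpy()
    other = sites["other_alleles"].fillna("").to_numpy()
    diag1 = np.array([a not in o for a, o in zip(sites["hap1_allele"], other)])
    diag2 = np.array([a not in o for a, o in zip(sites["hap2_allele"], other)])
    rows_idx = np.arange(len(sites))
    codes = {}
    for line_id, df in counts.items():
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        aligned = (df.set_index(idx)[list(NUCLEOTIDES)]
                   .reindex(key, fill_value=0).to_numpy())
        ev1 = (aligned[rows_idx, h1_col] > 0) & diag1
        ev2 = (aligned[rows_idx, h2_col] > 0) & diag2
        code = np.full(len(sites), -1, dtype=np.int8)
        code[ev1 & ~ev2] = 0
        code[ev2 & ~ev1] = 1
        codes[line_id] = code
    return SnpHaplotypeObservations(
        focal_parent=haplotypes.focal_parent,
        sites=sites.drop(columns=["other_alleles"]),
        codes=pd.DataFrame(codes))


def bin_genotypes(observations: SnpHaplotypeObservations,
                  bin_size: int = 50) -> BinnedGenotypeMatrix:
    """Aggregate per-SNP calls into consecutive bins of ``bin_size`` SNPs.

    Bins are consecutive runs of informative SNPs per chromosome (the last
    bin of a chromosome may be shorter); the bin genotype is the majority
    of the recorded haplotype observations, with ties and empty bins NA.
    """
    if bin_size < 1:
        raise ValueError("bin_size >= 1 required")
    sites = observations.sites
    C = observations.codes.to_numpy()
    marker_rows = []
    geno_rows = []
    for chrom in sites["chrom"].unique():
        idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        pos = sites["pos"].to_numpy()[idx]
        for lo in range(0, len(idx), bin_size):
            sel = idx[lo:lo + bin_size]
            start, end = int(pos[lo]), int(pos[min(lo + bin_size, len(idx)) - 1])
            marker_rows.append((marker_id(chrom, start, end), chrom, start,
                                end, len(sel)))
            sub = C[sel]
            c0 = (sub == 0).sum(axis=0)
            c1 = (sub == 1).sum(axis=0)
            call = np.where(c0 > c1, "H1", np.where(c1 > c0, "H2", None))
            geno_rows.append(call)
    markers = pd.DataFrame(marker_rows, columns=["marker_id", "chrom",
                                                 "start", "end", "snp_count"])
    geno = pd.DataFrame(geno_rows, columns=observations.codes.columns,
                        index=pd.Index(markers["marker_id"],
                                       name="marker_id"))
    return BinnedGenotypeMatrix(focal_parent=observations.focal_parent,
                                markers=markers, geno=geno)


def _line_switches(geno: pd.Series, markers: pd.DataFrame) -> float:
    """Mean number of genotype switches per chromosome for one line.

    Real recombination gives roughly the expected crossover count; noisy
    genotypes (e.g. shuffled bins) switch at every other marker, so the
    mean separates the two regimes while tolerating the occasional
    chromosome with a legitimately high crossover count.
    """
    counts = []
    for chrom in markers["chrom"].unique():
        ids = markers.loc[markers["chrom"] == chrom, "marker_id"]
        vals = geno.loc[ids].dropna().to_numpy()
        counts.append(int((vals[1:] != vals[:-1]).sum())
                      if len(vals) > 1 else 0)
    return float(np.mean(counts)) if counts else 0.0


def qc_line_diagnostics(genomic: BinnedGenotypeMatrix,
                        reference: BinnedGenotypeMatrix,
                        depth_per_line: pd.Series) -> pd.DataFrame:
    """Per-line depth, genomic-vs-reference concordance, and switch count."""
    overlap = [l for l in genomic.geno.columns if l in reference.geno.columns]
    common = genomic.geno.index.intersection(reference.geno.index)
    rows = []
    for line in overlap:
        g = genomic.geno.loc[common, line]
        r = reference.geno.loc[common, line]
        both = g.notna() & r.notna()
        conc = float((g[both] == r[both]).mean()) if both.any() else np.nan
        rows.append((line, float(depth_per_line.get(line, np.nan)),
                     conc, _line_switches(genomic.geno[line],
                                          genomic.markers)))
    return pd.DataFrame(rows, columns=["line_id", "depth", "concordance",
                                       "switches"])


def qc_select_lines(genomic: BinnedGenotypeMatrix,
                    reference: BinnedGenotypeMatrix,
                    depth_per_line: pd.Series,
                    min_concordance: float = 0.9,
                    max_switches: int = 5,
                    ) -> tuple[list[str], float, pd.DataFrame]:
    """Automated surrogate for the visual line-selection QC.

    Chooses the smallest per-line depth threshold at which every
    deep-subset line above it has genomic-vs-reference bin concordance
    >= ``min_concordance`` and at most ``max_switches`` haplotype switches
    per chromosome; retains all lines at or above that depth. Returns
    (selected line ids, threshold, per-line diagnostics).
    """
    diag = qc_line_diagnostics(genomic, reference, depth_per_line)
    if diag.empty:
        raise ValueError("no overlap lines between genomic and reference data")
    ok = (diag["concordance"].fillna(0) >= min_concordance) & \
         (diag["switches"] <= max_switches)
    threshold = None
    for d in sorted(diag["depth"].unique()):
        above = diag["depth"] >= d
        if above.any() and ok[above].all():
            threshold = float(d)
            break
    if threshold is None:
        raise ValueError(
            "no depth threshold satisfies the QC criteria; diagnostics:\n"
            + diag.to_string(index=False))
    selected = [l for l in genomic.geno.columns
                if depth_per_line.get(l, 0) >= threshold]
    return selected, threshold, diag
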