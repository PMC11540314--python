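"""Parental haplotype phasing from a deep-coverage subset of F1 progeny.

Each F1 inherits exactly one of the focal parent's two haplotypes at every
informative SNP, so co-inheritance across the deep subset reveals phase:
two adjacent SNPs are linked in cis (allele1-with-allele1) or in trans
according to the co-segregation pattern observed in the progeny. A link is
accepted when at least ``floor(consistency * N)`` of the N lines observed
at both sites agree with the majority orientation; accepted links chain
into phase blocks, and a rejected link starts a new block.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NUCLEOTIDES
from .snp_select import InformativeSnpTable

_BIT = {b: 1 << i for i, b in enumerate(NUCLEOTIDES)}


@dataclass
class InheritedAlleleMatrix:
    """Observed inherited focal allele per (deep line, informative SNP).

    ``codes`` is sites x lines, int8: 0 = focal_a1 inherited, 1 = focal_a2,
    -1 = missing (insufficient depth or inconsistent reads). Rows align
    with ``snps.rows``.
    """

    focal_parent: str
    snps: pd.DataFrame  # chrom, pos, focal_a1, focal_a2, other_alleles
    codes: pd.DataFrame  # index aligned to snps rows, columns line ids


@dataclass
class PhaseBlock:
    chrom: str
    block_id: int
    sites: pd.DataFrame  # pos, hap1_allele, hap2_allele


@dataclass
class PhasedHaplotypes:
    focal_parent: str
    blocks: list[PhaseBlock]
    link_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def site_table(self) -> pd.DataFrame:
        """All phased sites: chrom, pos, hap1_allele, hap2_allele, block_id."""
        frames = []
        for blk in self.blocks:
            df = blk.sites.copy()
            df.insert(0, "chrom", blk.chrom)
            df["block_id"] = blk.block_id
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "hap1_allele",
                                         "hap2_allele", "block_id"])
        return pd.concat(frames, ignore_index=True)


def consistency_threshold(n_lines: int, consistency: float = 0.9) -> int:
    """Minimum number of concordant lines to accept a phase link.

    floor(consistency * N): at the real design's N = 122 deep lines with
    the default 0.9 rule this is 109.
    """
    return math.floor(consistency * n_lines)


def infer_inherited_alleles(counts: dict[str, pd.DataFrame],
                            snps: InformativeSnpTable,
                            depth_min: int = 20,
                            noise_frac: float = 0.1,
                            min_noise_reads: int = 2,
                            ) -> InheritedAlleleMatrix:
    """Determine which focal allele each deep line inherited at each SNP.

    At a site with total depth >= ``depth_min``, an allele is "observed"
    when its count is at least ``min_noise_reads`` and ``noise_frac`` of
    the depth. A focal allele f is a consistent explanation when f is
    observed and every observed allele is attributable to f or to the other
    parent's genotype; the site is recorded only when exactly one focal
    allele is consistent, otherwise it is missing.
    """
    rows = snps.rows
    key = pd.MultiIndex.from_frame(rows[["chrom", "pos"]])
    f1_bits = rows["focal_a1"].map(_BIT).to_numpy()
    f2_bits = rows["focal_a2"].map(_BIT).to_numpy()
    other_bits = np.array([sum(_BIT[a] for a in s)
                           for s in rows["other_alleles"]])
    codes = {}
    for line_id, df in counts.items():
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        aligned = (df.set_index(idx)[list(NUCLEOTIDES)]
                   .reindex(key, fill_value=0).to_numpy())
        depth = aligned.sum(axis=1)
        thresh = np.maximum(min_noise_reads,
                            np.ceil(noise_frac * depth)).astype(int)
        observed = aligned >= thresh[:, None]
        obs_bits = (observed * np.array([1, 2, 4, 8])).sum(axis=1)
        full = 15
        valid1 = ((obs_bits & f1_bits) != 0) & \
                 ((obs_bits & (full ^ (f1_bits | other_bits))) == 0)
        valid2 = ((obs_bits & f2_bits) != 0) & \
                 ((obs_bits & (full ^ (f2_bits | other_bits))) == 0)
        code = np.full(len(rows), -1, dtype=np.int8)
        code[valid1 & ~valid2] = 0
        code[valid2 & ~valid1] = 1
        code[depth < depth_min] = -1
        codes[line_id] = code
    matrix = pd.DataFrame(codes, index=rows.index)
    return InheritedAlleleMatrix(focal_parent=snps.focal_parent,
                                 snps=rows, codes=matrix)


def phase_chromosome(matrix: InheritedAlleleMatrix, chrom: str,
                     consistency: float = 0.9,
                     min_lines: int = 10) -> tuple[list[PhaseBlock], pd.DataFrame]:
    """Chain adjacent informative SNPs of one chromosome into phase blocks.

    Returns (blocks, link_stats); hap1 of each block is anchored to the
    focal_a1 allele of the block's first SNP.
    """
    mask = matrix.snps["chrom"] == chrom
    rows = matrix.snps[mask].reset_index(drop=True)
    C = matrix.codes[mask.to_numpy()].to_numpy()
    n_sites = len(rows)
    if n_sites == 0:
        return [], pd.DataFrame()
    if n_sites < 2:
        warnings.warn(f"{chrom}: fewer than 2 informative SNPs; "
                      "emitting single-site blocks")
    left = C[:-1]
    right = C[1:]
    both = (left >= 0) & (right >= 0)
    n_obs = both.sum(axis=1)
    cis = ((left == right) & both).sum(axis=1)
    trans = n_obs - cis
    support = np.maximum(cis, trans)
    thresh = np.array([consistency_threshold(n, consistency) for n in n_obs])
    accepted = (n_obs >= min_lines) & (support >= thresh) & (cis != trans)
    orientation = (trans > cis).astype(int)  # 1 = trans link

    blocks: list[PhaseBlock] = []
    stats = pd.DataFrame({
        "chrom": chrom,
        "pos_left": rows["pos"].to_numpy()[:-1] if n_sites > 1 else [],
        "pos_right": rows["pos"].to_numpy()[1:] if n_sites > 1 else [],
        "n_lines": n_obs, "cis": cis, "trans": trans,
        "accepted": accepted, "orientation": orientation,
    }) if n_sites > 1 else pd.DataFrame()

    flip = 0
    cur: list[tuple[int, str, str]] = []

    def close_block() -> None:
        if cur:
            blocks.append(PhaseBlock(
                chrom=chrom, block_id=len(blocks),
                sites=pd.DataFrame(cur, columns=["pos", "hap1_allele",
                                                 "hap2_allele"])))

    for i in range(n_sites):
        a1, a2 = rows.loc[i, "focal_a1"], rows.loc[i, "focal_a2"]
        if i > 0:
            if accepted[i - 1]:
                flip ^= orientation[i - 1]
            else:
                close_block()
                cur = []
                flip = 0
        pair = (a1, a2) if flip == 0 else (a2, a1)
        cur.append((int(rows.loc[i, "pos"]), *pair))
    close_block()
    return blocks, stats


def phase_parent(matrix: InheritedAlleleMatrix,
                 consistency: float = 0.9,
                 min_lines: int = 10) -> PhasedHaplotypes:
    """Phase every chromosome of the focal parent."""
    all_blocks: list[PhaseBlock] = []
    stats = []
    for chrom in matrix.snps["chrom"].unique():
        blocks, st = phase_chromosome(matrix, chrom, consistency, min_lines)
        for blk in blocks:
            blk.block_id = len(all_blocks)
            all_blocks.append(blk)
        if len(st):
            stats.append(st)
    link_stats = (pd.concat(stats, ignore_index=True)
                  if stats else pd.DataFrame())
    return PhasedHaplotypes(focal_parent=matrix.focal_parent,
                            blocks=all_blocks, link_stats=link_stats)
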