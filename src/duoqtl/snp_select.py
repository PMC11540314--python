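"""Selection of haplotype-informative SNPs from parental genotype calls.

An informative SNP for a focal parent is a position where that parent is
heterozygous and the other parent is either homozygous or heterozygous with
a *different* unordered allele pair. Only these positions let a progeny read
reveal which focal haplotype was transmitted. Species-diagnostic SNPs
(fixed differences between the parents) carry no within-parent information
and are not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NUCLEOTIDES


@dataclass
class InformativeSnpTable:
    """Sites that distinguish the two haplotypes of ``focal_parent``.

    ``rows`` columns: chrom, pos, focal_a1, focal_a2 (the focal het pair),
    other_alleles (the other parent's unordered genotype as a sorted
    string, length 1 for homozygous, 2 for heterozygous). Sorted by
    (chrom, pos). ``excluded`` counts why candidate sites were dropped.
    """

    focal_parent: str
    rows: pd.DataFrame
    excluded: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)


def call_genotypes(counts: pd.DataFrame, min_frac: float = 0.2,
                   min_reads: int = 3) -> pd.DataFrame:
    """Call per-site diploid genotypes from high-coverage allele counts.

    An allele is considered present when it has at least ``min_reads`` reads
    and at least ``min_frac`` of the site's total. Returns chrom, pos,
    depth, and ``alleles`` — the sorted string of present alleles ("AG" for
    a het, "A" for a hom, "" when nothing passes, longer when messy).
    """
    mat = counts[list(NUCLEOTIDES)].to_numpy()
    depth = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = mat / depth[:, None]
    present = (mat >= min_reads) & (frac >= min_frac)
    alleles = ["".join(n for n, p in zip(NUCLEOTIDES, row) if p)
               for row in present]
    return pd.DataFrame({
        "chrom": counts["chrom"].to_numpy(),
        "pos": counts["pos"].to_numpy(),
        "depth": depth,
        "alleles": alleles,
    })


def select_informative_snps(pd_calls: pd.DataFrame, pn_calls: pd.DataFrame,
                            focal: str = "Pd",
                            min_depth: int = 10) -> InformativeSnpTable:
    """Retain sites where the focal parent's haplotypes are distinguishable.

    A site is kept iff both parents are genotyped at depth >= ``min_depth``,
    the focal parent is heterozygous, and the other parent is homozygous or
    heterozygous with a different unordered allele pair. Sites genotyped in
    only one parent are excluded and counted, not an error.
    """
    if focal not in ("Pd", "Pn"):
        raise ValueError(f"unknown focal parent {focal!r}")
    focal_calls, other_calls = ((pd_calls, pn_calls) if focal == "Pd"
                                else (pn_calls, pd_calls))
    merged = focal_calls.merge(other_calls, on=["chrom", "pos"], how="outer",
                               suffixes=("_f", "_o"), indicator=True)
    excluded = {"single_parent": int((merged["_merge"] != "both").sum()),
                "low_depth": 0, "focal_not_het": 0, "same_het_pair": 0}
    both = merged[merged["_merge"] == "both"]
    deep = (both["depth_f"] >= min_depth) & (both["depth_o"] >= min_depth)
    excluded["low_depth"] = int((~deep).sum())
    both = both[deep]
    focal_het = both["alleles_f"].str.len() == 2
    excluded["focal_not_het"] = int((~focal_het).sum())
    both = both[focal_het]
    other_ok = (both["alleles_o"].str.len().isin((1, 2))
                & (both["alleles_o"] != both["alleles_f"]))
    excluded["same_het_pair"] = int((~other_ok).sum())
    both = both[other_ok]
    rows = pd.DataFrame({
        "chrom": both["chrom"].to_numpy(),
        "pos": both["pos"].to_numpy(),
        "focal_a1": both["alleles_f"].str[0].to_numpy(),
        "focal_a2": both["alleles_f"].str[1].to_numpy(),
        "other_alleles": both["alleles_o"].to_numpy(),
    }).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return InformativeSnpTable(focal_parent=focal, rows=rows,
                               excluded=excluded)


def informative_snps_from_truth(parents, focal: str = "Pd") -> InformativeSnpTable:
    """Noise-free informative-SNP table straight from simulated parents."""
    pd_genome, pn_genome = parents
    focal_g, other_g = ((pd_genome, pn_genome) if focal == "Pd"
                        else (pn_genome, pd_genome))
    rows = []
    for chrom, _ in focal_g.chroms:
        f = focal_g.sites[chrom]
        o = other_g.sites[chrom]
        f_het = f["a1"] != f["a2"]
        f_pair = np.where(f["a1"] < f["a2"], f["a1"] + f["a2"],
                          f["a2"] + f["a1"])
        o_pair = np.where(o["a1"] == o["a2"], o["a1"],
                          np.where(o["a1"] < o["a2"], o["a1"] + o["a2"],
                                   o["a2"] + o["a1"]))
        keep = f_het & (f_pair != o_pair)
        sub = f[keep]
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "pos": sub["pos"].to_numpy(),
            "focal_a1": np.minimum(sub["a1"], sub["a2"]),
            "focal_a2": np.maximum(sub["a1"], sub["a2"]),
            "other_alleles": o_pair[keep.to_numpy()],
        }))
    table = pd.concat(rows, ignore_index=True).sort_values(
        ["chrom", "pos"]).reset_index(drop=True)
    return InformativeSnpTable(focal_parent=focal, rows=table)
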