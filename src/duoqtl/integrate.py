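"""Flanking-marker imputation and the unified common marker table.

The three genotype channels live on different native grids: *P. deltoides*
and *P. nigra* binned markers cover different SNP sets, and dosage bins
tile the genome. The common marker table puts all three on the Pd marker
grid: Pn genotypes are imputed at each Pd marker midpoint from the flanking
Pn markers (a gap between two equal-genotype flanks inherits that genotype;
unequal or missing flanks, and chromosome ends, are NA), and the dosage is
read from the bin containing the midpoint. A deleted region carries no Pn
haplotype, so dosage 0 forces the Pn channel to NA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import DosageMatrix
from .genotyping import BinnedGenotypeMatrix
from .io import NA, read_marker_table, write_marker_table

_HAP_LABELS = {"Pd": {"H1": "D1", "H2": "D2"},
               "Pn": {"H1": "N1", "H2": "N2"}}


@dataclass
class CommonMarkerTable:
    """Per line x marker triple (Pd haplotype, Pn haplotype, Pn dosage).

    ``pd_hap``/``pn_hap`` hold D1/D2 and N1/N2 labels (NaN for missing);
    ``dose`` holds 0/1/2 as floats with NaN. The invariant dose == 0 =>
    pn_hap is NA holds for every cell.
    """

    markers: pd.DataFrame  # marker_id, chrom, start, end [, snp_count]
    pd_hap: pd.DataFrame
    pn_hap: pd.DataFrame
    dose: pd.DataFrame

    @property
    def line_ids(self) -> list[str]:
        return list(self.pd_hap.columns)


class FlankImputer:
    """Position-queryable genotype lookup built from a binned matrix.

    Positions inside a marker interval return that marker's genotype;
    positions in a gap return the shared flanking genotype when both flanks
    agree and are observed, else NA; positions before the first or after
    the last marker of a chromosome are NA.
    """

    def __init__(self, binned: BinnedGenotypeMatrix):
        self.columns = binned.geno.columns
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in binned.markers["chrom"].unique():
            sub = binned.markers[binned.markers["chrom"] == chrom]
            geno = binned.geno.loc[sub["marker_id"]].to_numpy(dtype=object)
            self._per_chrom[chrom] = (sub["start"].to_numpy(),
                                      sub["end"].to_numpy(), geno)

    def at(self, chrom: str, pos: int) -> pd.Series:
        """Genotype of every line at one position (NaN where unknown)."""
        if chrom not in self._per_chrom:
            return pd.Series(np.nan, index=self.columns)
        starts, ends, geno = self._per_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos <= ends[i]:
            return pd.Series(geno[i], index=self.columns)
        # in a gap: flanks are markers i and i+1
        if i < 0 or i + 1 >= len(starts):
            return pd.Series(np.nan, index=self.columns)
        left, right = geno[i], geno[i + 1]
        equal = np.array([l == r and l is not None and not (
            isinstance(l, float) and np.isnan(l)) for l, r in zip(left, right)])
        out = np.where(equal, left, np.nan)
        return pd.Series(out, index=self.columns)


def impute_between_flanks(binned: BinnedGenotypeMatrix) -> FlankImputer:
    """Build the flanking-marker genotype imputer for one parent."""
    return FlankImputer(binned)


def build_common_markers(pd_binned: BinnedGenotypeMatrix,
                         pn_binned: BinnedGenotypeMatrix,
                         dosage: DosageMatrix) -> CommonMarkerTable:
    """Assemble the three channels on the Pd marker grid.

    The Pd binned markers are the reference; the Pn genotype at a marker is
    the flank-imputed value at the marker midpoint, and the dosage is that
    of the bin containing the midpoint. Dosage 0 forces Pn to NA.
    """
    pd_chroms = set(pd_binned.markers["chrom"])
    pn_chroms = set(pn_binned.markers["chrom"])
    dos_chroms = set(dosage.bins["chrom"])
    missing = pd_chroms - (pn_chroms & dos_chroms)
    if missing:
        raise ValueError(f"chromosome(s) {sorted(missing)} absent from an input")
    lines = [l for l in pd_binned.geno.columns if l in pn_binned.geno.columns
             and l in dosage.dose.columns]
    if not lines:
        raise ValueError("no shared lines across the three inputs")
    markers = pd_binned.markers.reset_index(drop=True)
    pd_vals = (pd_binned.geno[lines]
               .replace(_HAP_LABELS["Pd"])
               .set_axis(markers["marker_id"], axis=0))
    pd_vals = pd_vals.where(pd_vals.notna(), np.nan)  # None -> NaN
    imputer = impute_between_flanks(pn_binned)
    dose_by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(),
                dosage.dose.loc[sub["marker_id"], lines].to_numpy())
        for chrom, sub in dosage.bins.groupby("chrom")}
    pn_rows = []
    dose_rows = []
    for _, m in markers.iterrows():
        mid = (int(m["start"]) + int(m["end"])) // 2
        pn = imputer.at(m["chrom"], mid).reindex(lines).replace(
            _HAP_LABELS["Pn"])
        starts, ends, dvals = dose_by_chrom[m["chrom"]]
        i = np.searchsorted(starts, mid, side="right") - 1
        if i >= 0 and mid <= ends[i]:
            d = dvals[i].astype(float)
        else:
            d = np.full(len(lines), np.nan)
        pn = pn.mask(pd.Series(d, index=lines) == 0)
        pn_rows.append(pn.to_numpy())
        dose_rows.append(d)
    idx = pd.Index(markers["marker_id"], name="marker_id")
    return CommonMarkerTable(
        markers=markers,
        pd_hap=pd_vals,
        pn_hap=pd.DataFrame(pn_rows, index=idx, columns=lines),
        dose=pd.DataFrame(dose_rows, index=idx, columns=lines))


# ---------------------------------------------------------------------------
# serialization: one TSV with cells "Pd.Pn.dose", NA components spelled out
# ---------------------------------------------------------------------------


def write_common_markers(table: CommonMarkerTable, path,
                         metadata: dict | None = None) -> None:
    def fmt(pd_v, pn_v, d_v):
        p1 = NA if pd.isna(pd_v) else pd_v
        p2 = NA if pd.isna(pn_v) else pn_v
        p3 = NA if pd.isna(d_v) else str(int(d_v))
        return f"{p1}.{p2}.{p3}"

    cells = pd.DataFrame(
        np.vectorize(fmt)(table.pd_hap.to_numpy(), table.pn_hap.to_numpy(),
                          table.dose.to_numpy()),
        index=table.pd_hap.index, columns=table.pd_hap.columns)
    write_marker_table(table.markers, cells, path, metadata)


def read_common_markers(path) -> CommonMarkerTable:
    markers, cells = read_marker_table(path)
    pd_hap = cells.apply(lambda col: col.str.split(".").str[0])
    pn_hap = cells.apply(lambda col: col.str.split(".").str[1])
    dose = cells.apply(lambda col: col.str.split(".").str[2])
    pd_hap = pd_hap.mask(pd_hap == NA)
    pn_hap = pn_hap.mask(pn_hap == NA)
    dose = dose.mask(dose == NA).astype(float)
    return CommonMarkerTable(markers=markers, pd_hap=pd_hap, pn_hap=pn_hap,
                             dose=dose)
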