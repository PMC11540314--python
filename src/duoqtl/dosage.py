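"""Per-bin Pn-copy dosage genotypes from binned read coverage.

The F1s are diploid with one obligate *P. deltoides* copy, so the copy
number of the paternal (*P. nigra*) segment — the dosage — is 0 in a
deletion, 1 in the euploid state, and 2 in a duplication. It is read out
from per-bin coverage by double normalization: each line's bin coverage is
scaled by that line's genome-wide mean, then divided by the population
mean of the same quantity at that bin, so a euploid bin sits at ratio ~1,
a deletion at ~0.5 and a duplication at ~1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DosageMatrix:
    """Dosage genotype in {0, 1, 2} (or NA) per line per bin."""

    bins: pd.DataFrame  # marker_id, chrom, start, end
    dose: pd.DataFrame  # index marker_id, columns line ids, float with NaN


def normalize_coverage(bin_cov: pd.DataFrame,
                       leave_one_out: bool = True) -> pd.DataFrame:
    """Relative copy ratio per line per bin.

    ``bin_cov`` is indexed by bin id with one column per line. The ratio is
    (cov / line scale) / (population mean of that per-line-normalized value
    at the bin). The per-line scale is the median bin coverage — robust to
    the line's own indels while most of its genome is euploid, unlike the
    mean, which a large deletion drags down and thereby inflates every
    other bin. With ``leave_one_out`` the focal line is also excluded from
    the population mean so it cannot bias its own baseline. A line with
    zero coverage everywhere is returned as all-NaN.
    """
    if bin_cov.shape[1] < 2:
        raise ValueError("at least 2 lines required for population normalization")
    cov = bin_cov.to_numpy(dtype=float)
    line_mean = np.median(cov, axis=0)
    dead = line_mean == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = cov / line_mean[None, :]
    rel[:, dead] = np.nan
    n = (~dead).sum()
    total = np.nansum(rel, axis=1)
    if leave_one_out and n > 1:
        pop = (total[:, None] - np.where(dead, 0.0, rel)) / \
            np.where(dead, n, n - 1)
    else:
        pop = np.broadcast_to((total / n)[:, None], rel.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = rel / pop
    return pd.DataFrame(ratios, index=bin_cov.index, columns=bin_cov.columns)


def call_dosage(ratios: pd.DataFrame, bins: pd.DataFrame,
                low_cut: float = 0.75, high_cut: float = 1.25,
                min_run: int = 2) -> DosageMatrix:
    """Threshold copy ratios into dosage genotypes with run-length denoising.

    r < ``low_cut`` -> 0, r > ``high_cut`` -> 2, else 1 (capped at 2 however
    high the ratio). Within each chromosome, a run of consecutive non-1
    calls shorter than ``min_run`` bins is reset to 1: real indels span
    multiple bins at this resolution, isolated outlier bins do not.
    """
    if low_cut >= high_cut:
        raise ValueError("low_cut must be < high_cut")
    r = ratios.to_numpy(dtype=float)
    dose = np.where(np.isnan(r), np.nan,
                    np.where(r < low_cut, 0.0, np.where(r > high_cut, 2.0, 1.0)))
    chrom_arr = bins.set_index("marker_id").loc[ratios.index, "chrom"].to_numpy()
    for j in range(dose.shape[1]):
        col = dose[:, j]
        i = 0
        while i < len(col):
            if col[i] in (0.0, 2.0):
                k = i
                while (k < len(col) and col[k] == col[i]
                       and chrom_arr[k] == chrom_arr[i]):
                    k += 1
                if k - i < min_run:
                    col[i:k] = 1.0
                i = k
            else:
                i += 1
    return DosageMatrix(bins=bins.reset_index(drop=True),
                        dose=pd.DataFrame(dose, index=ratios.index,
                                          columns=ratios.columns))


def call_dosage_from_coverage(bin_cov: pd.DataFrame, bins: pd.DataFrame,
                              low_cut: float = 0.75, high_cut: float = 1.25,
                              min_run: int = 2,
                              leave_one_out: bool = True) -> DosageMatrix:
    """Convenience wrapper: normalize then threshold."""
    ratios = normalize_coverage(bin_cov, leave_one_out=leave_one_out)
    return call_dosage(ratios, bins, low_cut, high_cut, min_run)
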