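"""Single-marker QTL scans with genome-wide permutation thresholds.

For one trait and one genotype channel the model is the simple regression

    Y_i = beta0 + beta1 * gt_i + eps_i

fit by ordinary least squares at every marker. Genome-wide significance is
calibrated by permutation: the trait values are shuffled among lines, every
marker refit, and the maximum |t| recorded; the 95th and 99th percentiles
of the maxima over the permutations are the "significant" and "confirmed"
thresholds. Maximal runs of adjacent significant markers on one chromosome
are merged into QTLs, and the variance explained by a QTL is the adjusted
R-squared of a joint OLS fit on its member (or peak) markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .integrate import CommonMarkerTable

CHANNELS = ("Pd", "Pn", "dosage")

_PD_CODE = {"D1": 0.0, "D2": 1.0}
_PN_CODE = {"N1": 0.0, "N2": 1.0}


class MarkerSkipped(ValueError):
    """A marker cannot be fit; the message carries the reason."""


@dataclass
class ModelFit:
    """OLS fit of a trait on one marker's genotype codes."""

    beta0: float
    beta1: float
    t_value: float
    p_value: float
    n_used: int
    residual_sd: float


def encode_channel(table: CommonMarkerTable, channel: str) -> pd.DataFrame:
    """Numeric genotype codes per marker x line for one channel.

    Pd: D1 -> 0, D2 -> 1. Pn: N1 -> 0, N2 -> 1 (NA inside deletions).
    dosage: 0/1/2. Missing -> NaN everywhere.
    """
    if channel == "Pd":
        return table.pd_hap.apply(lambda c: c.map(_PD_CODE)).astype(float)
    if channel == "Pn":
        return table.pn_hap.apply(lambda c: c.map(_PN_CODE)).astype(float)
    if channel == "dosage":
        return table.dose.astype(float)
    raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


# ---------------------------------------------------------------------------
# vectorized per-marker OLS
# ---------------------------------------------------------------------------


@dataclass
class _MarkerDesign:
    """Sufficient statistics of a genotype matrix, reusable across
    permutations of the same trait vector."""

    X: np.ndarray          # n x m, NaN replaced by 0
    M: np.ndarray          # n x m validity mask
    n: np.ndarray          # per-marker complete observations
    sx: np.ndarray
    sxx_c: np.ndarray      # centered sum of squares of g
    valid: np.ndarray      # markers eligible for testing


def prepare_design(G: np.ndarray, min_n: int = 20,
                   min_minor: int = 5) -> _MarkerDesign:
    M = ~np.isnan(G)
    X = np.where(M, G, 0.0)
    n = M.sum(axis=0)
    sx = X.sum(axis=0)
    sxx = (X * X).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx * sx / n
    # minor-genotype count: observations not equal to the modal code
    levels = np.unique(G[~np.isnan(G)]) if np.any(M) else np.array([])
    counts = np.stack([((X == lv) & M).sum(axis=0) for lv in levels]) \
        if len(levels) else np.zeros((1, G.shape[1]))
    minor = n - counts.max(axis=0)
    valid = (n >= min_n) & (sxx_c > 0) & (minor >= min_minor)
    return _MarkerDesign(X=X, M=M, n=n, sx=sx, sxx_c=sxx_c, valid=valid)


def _t_from_design(d: _MarkerDesign, y: np.ndarray,
                   full: bool = False):
    """|t| per marker for one trait vector (NaN at invalid markers)."""
    sy = d.M.T @ y
    syy = d.M.T @ (y * y)
    sxy = d.X.T @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        sxy_c = sxy - d.sx * sy / d.n
        syy_c = syy - sy * sy / d.n
        beta1 = sxy_c / d.sxx_c
        sse = np.maximum(syy_c - beta1 * sxy_c, 0.0)
        df = d.n - 2
        sigma2 = sse / df
        se = np.sqrt(sigma2 / d.sxx_c)
        t = beta1 / se
    t = np.where(d.valid, t, np.nan)
    if not full:
        return t
    beta0 = (sy - beta1 * d.sx) / d.n
    p = 2 * sps.t.sf(np.abs(t), df)
    return t, beta0, beta1, np.sqrt(sigma2), p


def fit_single_marker(y: np.ndarray, g: np.ndarray,
                      min_n: int = 3) -> ModelFit:
    """OLS of one trait on one marker; raises :class:`MarkerSkipped` for
    monomorphic markers or insufficient complete pairs."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    n = len(y)
    if n < min_n:
        raise MarkerSkipped(f"insufficient data (n={n} < {min_n})")
    if np.ptp(g) == 0:
        raise MarkerSkipped("monomorphic")
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    beta1 = float(gc @ yc) / sxx
    beta0 = float(y.mean() - beta1 * g.mean())
    resid = yc - beta1 * gc
    sse = float(resid @ resid)
    df = n - 2
    sigma2 = sse / df if df > 0 else np.nan
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore"):
        t = beta1 / se if se > 0 else np.inf * np.sign(beta1)
    p = float(2 * sps.t.sf(abs(t), df)) if df > 0 else np.nan
    return ModelFit(beta0=beta0, beta1=beta1, t_value=float(t), p_value=p,
                    n_used=n, residual_sd=float(np.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------


def permutation_threshold(y: np.ndarray, G: np.ndarray,
                          n_perm: int = 1000, seed: int = 0,
                          min_n: int = 20, min_minor: int = 5,
                          design: _MarkerDesign | None = None,
                          ) -> tuple[float, float]:
    """Genome-wide max-|t| thresholds at the 5% and 1% levels.

    For each of ``n_perm`` permutations the trait vector is shuffled among
    lines, every marker refit, and the maximum |t| over markers recorded;
    returns the 95th and 99th percentiles of the maxima.
    """
    if n_perm < 1:
        raise ValueError("n_perm >= 1 required")
    rng = np.random.default_rng(seed)
    d = design if design is not None else prepare_design(G, min_n, min_minor)
    y = np.asarray(y, dtype=float)
    maxima = np.empty(n_perm)
    warned = False
    for b in range(n_perm):
        yp = rng.permutation(y)
        t = np.abs(_t_from_design(d, yp))
        if np.all(np.isnan(t)):
            if not warned:
                warnings.warn("all markers skipped in a permutation; "
                              "contributing max |t| = 0")
                warned = True
            maxima[b] = 0.0
        else:
            maxima[b] = np.nanmax(t)
    t95, t99 = np.percentile(maxima, [95, 99])
    return float(t95), float(t99)


# ---------------------------------------------------------------------------
# QTL calling and variance explained
# ---------------------------------------------------------------------------


def call_qtls(marker_stats: pd.DataFrame, t95: float, t99: float,
              ) -> list[dict]:
    """Merge maximal runs of adjacent significant markers into QTLs.

    ``marker_stats`` must be in common-marker order with columns marker_id,
    chrom, t. A QTL is a maximal run of consecutive same-chromosome markers
    with |t| > t95; it is "confirmed" when its peak |t| > t99.
    """
    qtls: list[dict] = []
    run: list[int] = []

    def close(run_idx: list[int]) -> None:
        if not run_idx:
            return
        sub = marker_stats.iloc[run_idx]
        peak = sub.loc[sub["t"].abs().idxmax()]
        qtls.append({
            "chrom": peak["chrom"],
            "start_marker": sub.iloc[0]["marker_id"],
            "end_marker": sub.iloc[-1]["marker_id"],
            "peak_marker": peak["marker_id"],
            "peak_stat": float(abs(peak["t"])),
            "member_markers": list(sub["marker_id"]),
            "significance": ("confirmed" if abs(peak["t"]) > t99
                             else "significant"),
        })

    prev_chrom = None
    for i, row in marker_stats.reset_index(drop=True).iterrows():
        sig = not pd.isna(row["t"]) and abs(row["t"]) > t95
        if sig and (not run or row["chrom"] == prev_chrom):
            run.append(i)
        else:
            close(run)
            run = [i] if sig else []
        prev_chrom = row["chrom"]
    close(run)
    return qtls


def variance_explained(y: np.ndarray, G: np.ndarray) -> float:
    """Adjusted R-squared of a joint OLS fit of the trait on a marker set.

    Complete-case rows only; collinear (redundant) columns do not inflate
    the predictor count — the rank of the design matrix is used.
    """
    y = np.asarray(y, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != len(y):
        G = G.T
    keep = ~np.isnan(y)
    keep &= ~np.isnan(G).any(axis=1)
    y, G = y[keep], G[keep]
    n = len(y)
    X = np.column_stack([np.ones(n), G])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    p = rank - 1  # independent predictors beyond the intercept
    if n < p + 2:
        raise ValueError("too few complete cases for the predictor count")
    resid = y - X @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    r2 = 1 - float((resid ** 2).sum()) / sst
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# whole-channel scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    trait: str
    channel: str
    marker_stats: pd.DataFrame
    t95: float
    t99: float
    qtls: pd.DataFrame  # io.QTL_COLUMNS layout


def scan_channel(y: pd.Series, table: CommonMarkerTable, channel: str,
                 n_perm: int = 1000, seed: int = 0, min_n: int = 20,
                 min_minor: int = 5, trait: str = "trait") -> ScanResult:
    """Complete single-channel scan for one trait.

    Lines with a missing phenotype are dropped before permutation so the
    shuffle stays exchangeable within observed lines; thresholds are
    computed per trait x channel.
    """
    codes = encode_channel(table, channel)
    lines = [l for l in codes.columns if l in y.index]
    yv = y.loc[lines].to_numpy(dtype=float)
    keep = ~np.isnan(yv)
    yv = yv[keep]
    G = codes[np.array(lines)[keep]].to_numpy(dtype=float).T  # lines x markers
    design = prepare_design(G, min_n, min_minor)
    t95, t99 = permutation_threshold(yv, G, n_perm=n_perm, seed=seed,
                                     design=design)
    t, beta0, beta1, resid_sd, p = _t_from_design(design, yv, full=True)
    marker_stats = pd.DataFrame({
        "marker_id": table.markers["marker_id"].to_numpy(),
        "chrom": table.markers["chrom"].to_numpy(),
        "t": t, "beta1": beta1, "p": p, "n_used": design.n,
    })
    raw = call_qtls(marker_stats, t95, t99)
    records = []
    code_by_marker = codes.T  # lines x markers frame
    for q in raw:
        Gq = code_by_marker.loc[lines, q["member_markers"]].to_numpy()[keep]
        ve = variance_explained(yv, Gq)
        records.append({
            "trait": trait, "channel_or_group": channel, "chrom": q["chrom"],
            "start_marker": q["start_marker"], "end_marker": q["end_marker"],
            "peak_marker": q["peak_marker"], "peak_stat": q["peak_stat"],
            "threshold": t95, "variance_explained": ve,
            "significance": q["significance"],
        })
    qtls = pd.DataFrame(records, columns=[
        "trait", "channel_or_group", "chrom", "start_marker", "end_marker",
        "peak_marker", "peak_stat", "threshold", "variance_explained",
        "significance"])
    return ScanResult(trait=trait, channel=channel,
                      marker_stats=marker_stats, t95=t95, t99=t99, qtls=qtls)
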