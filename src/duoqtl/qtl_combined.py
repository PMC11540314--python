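"""The combined-state QTL model: joint Pd/Pn/dosage genotype states.

Each line x marker is assigned a joint state label ``Pd.Pn.dose``. A
deletion removes the transmitted *P. nigra* copy (no Pn haplotype, dose
0) and an insertion duplicates it (the single inherited Pn haplotype at
dose 2), so the universe is {D1,D2} x ({NA}x{0} u {N1,N2}x{1,2}) — exactly
10 states, giving at most C(10,2) = 45 pairwise comparisons per marker.
Present state pairs are compared by two-group Monte-Carlo permutation
tests on the mean difference, p-values are Benjamini–Hochberg adjusted,
markers with any significant pair are merged by adjacency into QTLs, and
each QTL's origin is classified into one of six groups (deletion,
insertion, deletion+insertion, Pd, Pn, Pd+Pn) from which components differ
between its significant state pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .integrate import CommonMarkerTable
from .qtl_single import variance_explained

GROUPS = ("deletion", "insertion", "deletion+insertion", "Pd", "Pn", "Pd+Pn")


def enumerate_states() -> list[str]:
    """The canonical 10-state universe, in a fixed sort order."""
    states = []
    for pd_h in ("D1", "D2"):
        states.append(f"{pd_h}.NA.0")
        for pn_h in ("N1", "N2"):
            for dose in (1, 2):
                states.append(f"{pd_h}.{pn_h}.{dose}")
    return sorted(states)


_UNIVERSE = frozenset(enumerate_states())


@dataclass
class StateTable:
    """Joint genotype state per line x marker (NaN where incomplete)."""

    markers: pd.DataFrame
    states: pd.DataFrame  # index marker_id, columns line ids


def assign_states(table: CommonMarkerTable) -> StateTable:
    """Map each common-marker cell to its combined state label.

    A cell is missing when the Pd haplotype is NA, the dose is NA, or the
    Pn haplotype is NA at a non-zero dose. A dose of 0 with a recorded Pn
    haplotype violates the deletion invariant and is an error.
    """
    pd_h = table.pd_hap.to_numpy(dtype=object)
    pn_h = table.pn_hap.to_numpy(dtype=object)
    dose = table.dose.to_numpy(dtype=float)
    bad = (dose == 0) & ~pd.isna(pn_h)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "dose 0 with a non-NA Pn haplotype at marker "
            f"{table.pd_hap.index[i]!r}, line {table.pd_hap.columns[j]!r}")
    out = np.full(pd_h.shape, np.nan, dtype=object)
    complete = (~pd.isna(pd_h)) & (~np.isnan(dose)) & \
        (~pd.isna(pn_h) | (dose == 0))
    ii, jj = np.nonzero(complete)
    for i, j in zip(ii, jj):
        pn = "NA" if dose[i, j] == 0 else pn_h[i, j]
        out[i, j] = f"{pd_h[i, j]}.{pn}.{int(dose[i, j])}"
    states = pd.DataFrame(out, index=table.pd_hap.index,
                          columns=table.pd_hap.columns)
    return StateTable(markers=table.markers, states=states)


# ---------------------------------------------------------------------------
# pairwise permutation tests
# ---------------------------------------------------------------------------


def pairwise_state_tests(y: pd.Series, states: pd.Series,
                         n_perm: int = 1000, min_group: int = 5,
                         seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Two-group permutation tests for every qualifying state pair.

    The statistic is |mean difference|; the Monte-Carlo p-value uses the
    add-one estimator p = (1 + #{permuted >= observed}) / (1 + n_perm).
    States with fewer than ``min_group`` phenotyped lines are excluded.
    Raises ValueError when fewer than two states qualify.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    df = pd.DataFrame({"y": y, "state": states}).dropna()
    groups = {s: g["y"].to_numpy() for s, g in df.groupby("state")
              if len(g) >= min_group}
    if len(groups) < 2:
        raise ValueError("fewer than 2 states with enough lines at marker")
    for s in groups:
        if s not in _UNIVERSE:
            raise ValueError(f"state {s!r} outside the 10-state universe")
    rows = []
    for sa, sb in combinations(sorted(groups), 2):
        ya, yb = groups[sa], groups[sb]
        na, nb = len(ya), len(yb)
        obs = abs(ya.mean() - yb.mean())
        pool = np.concatenate([ya, yb])
        perm = np.tile(pool, (n_perm, 1))
        rng.permuted(perm, axis=1, out=perm)
        stat = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
        p_raw = (1 + int((stat >= obs - 1e-12).sum())) / (1 + n_perm)
        rows.append((sa, sb, float(ya.mean() - yb.mean()), p_raw, na, nb))
    return pd.DataFrame(rows, columns=["state_a", "state_b", "diff_means",
                                       "p_raw", "n_a", "n_b"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    p_adj(i) = min over j >= i (by ascending p) of p(j) * m / j, clipped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0, 1)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _parse(state: str) -> tuple[str, str, int]:
    pd_h, pn_h, dose = state.split(".")
    return pd_h, pn_h, int(dose)


def classify_pair(state_a: str, state_b: str) -> str | None:
    """Type the evidence a significant state pair carries.

    Pairs differing only in dose are dosage evidence: 0 vs 1 is deletion,
    1 vs 2 insertion, and 0 vs 2 — which an effect of either kind would
    separate — joint "deletion+insertion" evidence. Pairs at equal dose
    are allelic evidence (Pd, Pn, or the joint "Pd+Pn" when both
    haplotypes differ, since a pure effect of either parent separates that
    pair too). Pairs that differ in both dose and haplotype confound the
    mechanisms and are untyped (None).
    """
    pd_a, pn_a, d_a = _parse(state_a)
    pd_b, pn_b, d_b = _parse(state_b)
    if d_a != d_b:
        hap_equal = pd_a == pd_b and (pn_a == pn_b or "NA" in (pn_a, pn_b))
        if not hap_equal:
            return None
        doses = {d_a, d_b}
        if doses == {0, 1}:
            return "deletion"
        if doses == {1, 2}:
            return "insertion"
        return "deletion+insertion"  # 0 vs 2
    pd_diff = pd_a != pd_b
    pn_diff = pn_a != pn_b
    if pd_diff and pn_diff:
        return "Pd+Pn"
    if pd_diff:
        return "Pd"
    if pn_diff:
        return "Pn"
    return None


def _resolve(evidence: set, a: str, b: str, joint: str) -> str:
    """Combine single-mechanism and joint evidence kinds into one label.

    Joint evidence (a pair either mechanism would separate) only decides
    the label when no unambiguous single-mechanism pair points one way.
    """
    if a in evidence and b in evidence:
        return joint
    if a in evidence:
        return a
    if b in evidence:
        return b
    return joint


def classify_qtl(significant_pairs: pd.DataFrame) -> str:
    """Classify a QTL from its significant state pairs.

    Dosage evidence wins when present: deletion, insertion, or
    deletion+insertion; otherwise the allelic label (Pd, Pn, or Pd+Pn);
    only untyped pairs -> "ambiguous". Two identifiability rules temper
    the raw pair types:

    * joint pair types (0 vs 2 doses; both haplotypes differing) are
      compatible with either single mechanism and never override
      unambiguous pairs;
    * a deleted segment carries no Pn allele, so a deleted-vs-carrier pair
      also fires under a pure Pn allelic effect (the deleted lines mimic
      whichever haplotype is phenotypically null). Deletion evidence
      therefore counts only when deleted lines differ from carriers of
      *both* Pn haplotypes, or when no pure-Pn competitor pair is
      significant at the QTL.
    """
    if significant_pairs.empty:
        raise ValueError("classification needs at least one significant pair")
    evidence = set()
    del_haps = set()  # Pn haplotypes of the carrier side of deletion pairs
    for a, b in zip(significant_pairs["state_a"],
                    significant_pairs["state_b"]):
        kind = classify_pair(a, b)
        if kind is None:
            continue
        evidence.add(kind)
        if kind == "deletion":
            for state in (a, b):
                pn = _parse(state)[1]
                if pn != "NA":
                    del_haps.add(pn)
    pn_competitor = bool(evidence & {"Pn", "Pd+Pn"})
    deletion_ok = "deletion" in evidence and (
        len(del_haps) == 2 or not pn_competitor)
    insertion_ok = "insertion" in evidence
    cross_dose = "deletion+insertion" in evidence
    if deletion_ok and insertion_ok:
        return "deletion+insertion"
    if deletion_ok:
        return "deletion"
    if insertion_ok:
        return "insertion"
    if cross_dose and not pn_competitor:
        return "deletion+insertion"
    if evidence & {"Pd", "Pn", "Pd+Pn"}:
        return _resolve(evidence, "Pd", "Pn", "Pd+Pn")
    return "ambiguous"


# ---------------------------------------------------------------------------
# genome-wide combined scan
# ---------------------------------------------------------------------------


@dataclass
class CombinedScanResult:
    trait: str
    pair_tests: pd.DataFrame  # marker_id, state_a, state_b, ..., p_adj
    qtls: pd.DataFrame


def combined_scan(y: pd.Series, state_table: StateTable,
                  n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                  min_group: int = 5, trait: str = "trait",
                  bh_scope: str = "per_pair_across_markers",
                  ) -> CombinedScanResult:
    """Genome-wide combined-model scan for one trait.

    Pairwise permutation tests run at every marker with at least two
    qualifying states; BH adjustment is applied per comparison family
    (``per_pair_across_markers``, the default: one family per state pair
    across all markers) or ``per_marker_across_pairs``. Markers with any
    adjusted p < ``alpha`` merge by adjacency into QTLs; each QTL is
    classified from its significant pairs, and its variance explained is
    the adjusted R-squared of the trait on the peak marker's state
    dummies.
    """
    if bh_scope not in ("per_pair_across_markers", "per_marker_across_pairs"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    rng = np.random.default_rng(seed)
    all_tests = []
    for mid in state_table.markers["marker_id"]:
        st = state_table.states.loc[mid]
        try:
            res = pairwise_state_tests(y, st, n_perm=n_perm,
                                       min_group=min_group, seed=rng)
        except ValueError:
            continue
        res.insert(0, "marker_id", mid)
        all_tests.append(res)
    if all_tests:
        tests = pd.concat(all_tests, ignore_index=True)
        group_key = (["state_a", "state_b"]
                     if bh_scope == "per_pair_across_markers"
                     else ["marker_id"])
        tests["p_adj"] = (tests.groupby(group_key)["p_raw"]
                          .transform(lambda p: bh_adjust(p.to_numpy())))
    else:
        tests = pd.DataFrame(columns=["marker_id", "state_a", "state_b",
                                      "diff_means", "p_raw", "n_a", "n_b",
                                      "p_adj"])
    sig = tests[tests["p_adj"] < alpha]
    sig_markers = set(sig["marker_id"])
    markers = state_table.markers.reset_index(drop=True)
    qtl_rows = []
    run: list[int] = []

    def close(run_idx: list[int]) -> None:
        if not run_idx:
            return
        sub = markers.iloc[run_idx]
        member_ids = list(sub["marker_id"])
        pairs = sig[sig["marker_id"].isin(member_ids)]
        group = classify_qtl(pairs)
        peak_id = (pairs.groupby("marker_id")["p_adj"].min().idxmin())
        peak_p = float(pairs["p_adj"].min())
        st = state_table.states.loc[peak_id]
        df = pd.DataFrame({"y": y, "state": st}).dropna()
        dummies = pd.get_dummies(df["state"]).to_numpy(dtype=float)
        ve = variance_explained(df["y"].to_numpy(), dummies)
        qtl_rows.append({
            "trait": trait, "channel_or_group": group,
            "chrom": sub.iloc[0]["chrom"],
            "start_marker": member_ids[0], "end_marker": member_ids[-1],
            "peak_marker": peak_id, "peak_stat": peak_p,
            "threshold": alpha, "variance_explained": ve,
            "significance": "significant",
        })

    prev_chrom = None
    for i, row in markers.iterrows():
        is_sig = row["marker_id"] in sig_markers
        if is_sig and run and row["chrom"] == prev_chrom:
            run.append(i)
        else:
            close(run)
            run = [i] if is_sig else []
        prev_chrom = row["chrom"]
    close(run)
    qtls = pd.DataFrame(qtl_rows, columns=[
        "trait", "channel_or_group", "chrom", "start_marker", "end_marker",
        "peak_marker", "peak_stat", "threshold", "variance_explained",
        "significance"])
    return CombinedScanResult(trait=trait, pair_tests=tests, qtls=qtls)
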