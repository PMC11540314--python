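"""In-silico interspecific F1 hybrid experiment with a truth ledger.

The generator emulates the statistical structure of a *P. deltoides* x
*P. nigra* cross in which the pollen parent was irradiated: two outbred
parents with phased heterozygous SNPs, F1 lines produced by independent
meioses, large paternal-only indels (deletions and duplications of the
transmitted *P. nigra* segment), shallow whole-genome read counts, per-bin
coverage, and polygenic traits with planted allelic and dosage effects.

Every function is deterministic given its seed; identical parameters and
seeds reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import NUCLEOTIDES, PhenotypeTable

BASES = np.array(list(NUCLEOTIDES))
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ParentalGenome:
    """One outbred parent: chromosome lengths and per-site diploid alleles.

    ``sites[chrom]`` has columns pos, a1, a2 (a1 == a2 at homozygous sites);
    positions are 1-based, strictly increasing, and shared between the two
    parents of a cross (a joint site list, as a parsed-mpileup would hold).
    """

    parent_id: Literal["Pd", "Pn"]
    chroms: list[tuple[str, int]]
    sites: dict[str, pd.DataFrame]

    def het_sites(self, chrom: str) -> pd.DataFrame:
        df = self.sites[chrom]
        return df[df["a1"] != df["a2"]].reset_index(drop=True)

    def hom_sites(self, chrom: str) -> pd.DataFrame:
        df = self.sites[chrom]
        return df[df["a1"] == df["a2"]].reset_index(drop=True)

    def n_het_sites(self) -> int:
        return sum(len(self.het_sites(c)) for c, _ in self.chroms)


@dataclass(frozen=True)
class Indel:
    chrom: str
    start: int
    end: int  # inclusive
    kind: Literal["deletion", "insertion"]

    def overlaps(self, other: "Indel") -> bool:
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start)


@dataclass
class F1Line:
    """One F1 individual: inherited haplotype mosaic per parent plus indels.

    Inheritance is a list of (start, end, hap) intervals (1-based inclusive)
    tiling each chromosome; hap is 1 or 2 and names which parental haplotype
    was transmitted. Indels live only on the *P. nigra*-derived chromosome:
    a deletion removes the transmitted Pn copy, an insertion duplicates it.
    """

    line_id: str
    pd_inheritance: dict[str, list[tuple[int, int, int]]]
    pn_inheritance: dict[str, list[tuple[int, int, int]]]
    indels: list[Indel] = field(default_factory=list)

    def hap_at(self, parent: str, chrom: str, pos: int) -> int:
        intervals = (self.pd_inheritance if parent == "Pd"
                     else self.pn_inheritance)[chrom]
        for start, end, hap in intervals:
            if start <= pos <= end:
                return hap
        raise ValueError(f"position {chrom}:{pos} outside inheritance mosaic")

    def pn_dose(self, chrom: str, pos: int) -> int:
        """Copies of the transmitted Pn segment at a position: 0, 1 or 2."""
        for ind in self.indels:
            if ind.chrom == chrom and ind.start <= pos <= ind.end:
                return 0 if ind.kind == "deletion" else 2
        return 1

    def copy_number(self, chrom: str, pos: int) -> int:
        """Total copies (Pd contributes one, Pn contributes the dose)."""
        return 1 + self.pn_dose(chrom, pos)


@dataclass(frozen=True)
class PlantedQtl:
    """A planted trait effect.

    ``channel`` selects the genotype code the effect multiplies: "Pd"/"Pn"
    are the 0/1 haplotype codes, "dosage" the linear 0/1/2 Pn copy number,
    and "deletion"/"insertion" are indicator mechanisms (1 iff dose 0,
    resp. dose 2) for planting single-mechanism effects.
    """

    trait: str
    chrom: str
    start: int
    end: int
    channel: Literal["Pd", "Pn", "dosage", "deletion", "insertion"]
    effect: float  # trait units per genotype-code unit

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TruthSet:
    """Ground truth emitted by the simulator, for recovery testing."""

    lines: list[F1Line]
    planted_qtls: list[PlantedQtl]
    noise_sd: dict[str, float]
    beta0: dict[str, float] = field(default_factory=dict)
    parents: tuple[ParentalGenome, ParentalGenome] | None = None


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------


def simulate_parents(n_chrom: int = 5,
                     chrom_len: int = 2_000_000,
                     het_density: float = 5e-4,
                     seed: int = 0,
                     shared_het_frac: float = 0.15,
                     hom_match_prob: float = 0.8,
                     ) -> tuple[ParentalGenome, ParentalGenome]:
    """Simulate the two outbred parents of the cross.

    Heterozygous site counts per parent are Poisson at ``het_density`` sites
    per bp. A fraction ``shared_het_frac`` of each parent's het sites is
    heterozygous in both parents (half of those share the same unordered
    allele pair and are uninformative); at focal-het/other-hom sites the
    homozygous allele matches one of the focal alleles with probability
    ``hom_match_prob``, as expected for biallelic SNPs.
    """
    if n_chrom < 1 or chrom_len < 10**5 or het_density <= 0:
        raise ValueError("n_chrom >= 1, chrom_len >= 1e5, het_density > 0 required")
    rng = np.random.default_rng(seed)
    chroms = [(f"Chr{i + 1:02d}", int(chrom_len)) for i in range(n_chrom)]
    pd_sites: dict[str, pd.DataFrame] = {}
    pn_sites: dict[str, pd.DataFrame] = {}
    lam = het_density * chrom_len
    for chrom, length in chroms:
        n_shared = rng.poisson(shared_het_frac * lam)
        n_pd_only = rng.poisson((1 - shared_het_frac) * lam)
        n_pn_only = rng.poisson((1 - shared_het_frac) * lam)
        n_total = n_shared + n_pd_only + n_pn_only
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_total,
                                 replace=False))
        cls = rng.permutation(
            np.repeat([0, 1, 2], [n_shared, n_pd_only, n_pn_only]))
        pd_a1 = np.empty(n_total, dtype="<U1")
        pd_a2 = np.empty(n_total, dtype="<U1")
        pn_a1 = np.empty(n_total, dtype="<U1")
        pn_a2 = np.empty(n_total, dtype="<U1")
        for i in range(n_total):
            pair = rng.choice(4, size=2, replace=False)
            if cls[i] == 0:  # het in both
                pd_a1[i], pd_a2[i] = BASES[pair]
                if rng.random() < 0.5:  # same unordered pair: uninformative
                    pn_a1[i], pn_a2[i] = BASES[pair]
                else:
                    other = rng.choice(4, size=2, replace=False)
                    while set(other) == set(pair):
                        other = rng.choice(4, size=2, replace=False)
                    pn_a1[i], pn_a2[i] = BASES[other]
            elif cls[i] == 1:  # Pd het, Pn hom
                pd_a1[i], pd_a2[i] = BASES[pair]
                if rng.random() < hom_match_prob:
                    hom = BASES[pair[rng.integers(2)]]
                else:
                    hom = BASES[rng.integers(4)]
                pn_a1[i] = pn_a2[i] = hom
            else:  # Pn het, Pd hom
                pn_a1[i], pn_a2[i] = BASES[pair]
                if rng.random() < hom_match_prob:
                    hom = BASES[pair[rng.integers(2)]]
                else:
                    hom = BASES[rng.integers(4)]
                pd_a1[i] = pd_a2[i] = hom
        pd_sites[chrom] = pd.DataFrame(
            {"pos": pos, "a1": pd_a1, "a2": pd_a2})
        pn_sites[chrom] = pd.DataFrame(
            {"pos": pos, "a1": pn_a1, "a2": pn_a2})
    return (ParentalGenome("Pd", chroms, pd_sites),
            ParentalGenome("Pn", chroms, pn_sites))


# ---------------------------------------------------------------------------
# meiosis and indels
# ---------------------------------------------------------------------------


def _meiosis(rng: np.random.Generator, length: int,
             recomb_per_chrom: float) -> list[tuple[int, int, int]]:
    """One gamete: crossover count Poisson, breakpoints uniform, no
    interference; returns (start, end, hap) intervals tiling [1, length]."""
    n_xo = rng.poisson(recomb_per_chrom)
    breaks = np.sort(rng.integers(1, length, size=n_xo)) if n_xo else np.array([], int)
    hap = int(rng.integers(1, 3))
    intervals: list[tuple[int, int, int]] = []
    start = 1
    for b in breaks:
        if b >= start:
            intervals.append((start, int(b), hap))
            start = int(b) + 1
        hap = 3 - hap
    intervals.append((start, length, hap))
    # merge adjacent intervals left with the same haplotype (coincident breaks)
    merged: list[tuple[int, int, int]] = []
    for iv in intervals:
        if merged and merged[-1][2] == iv[2]:
            merged[-1] = (merged[-1][0], iv[1], iv[2])
        else:
            merged.append(iv)
    return merged


def simulate_f1(parents: tuple[ParentalGenome, ParentalGenome],
                n_lines: int = 343,
                recomb_per_chrom: float = 1.5,
                indel_rate: float = 2.5,
                indel_size_range: tuple[int, int] = (250_000, 750_000),
                p_deletion: float = 0.665,
                seed: int = 0) -> list[F1Line]:
    """Simulate F1 lines: independent meioses per parent plus Pn-only indels.

    Indel counts per line are Poisson(``indel_rate``); sizes are uniform in
    ``indel_size_range`` (capped at the chromosome length); each is a
    deletion with probability ``p_deletion``, else an insertion. Indels that
    would overlap within a line are re-drawn so the Pn dose stays in
    {0, 1, 2}.
    """
    if n_lines < 1:
        raise ValueError("n_lines >= 1 required")
    if not 0 <= p_deletion <= 1:
        raise ValueError("p_deletion must be in [0, 1]")
    pd_genome, pn_genome = parents
    chroms = pd_genome.chroms
    max_len = max(length for _, length in chroms)
    if indel_size_range[0] > max_len:
        raise ValueError("indel_size_range minimum exceeds chromosome length")
    rng = np.random.default_rng(seed)
    lines: list[F1Line] = []
    for i in range(n_lines):
        line_id = f"F1_{i + 1:04d}"
        pd_inh = {c: _meiosis(rng, L, recomb_per_chrom) for c, L in chroms}
        pn_inh = {c: _meiosis(rng, L, recomb_per_chrom) for c, L in chroms}
        n_indels = rng.poisson(indel_rate)
        indels: list[Indel] = []
        for _ in range(n_indels):
            for _attempt in range(100):
                ci = rng.integers(len(chroms))
                chrom, length = chroms[ci]
                size = int(rng.integers(indel_size_range[0],
                                        indel_size_range[1] + 1))
                size = min(size, length)
                start = int(rng.integers(1, length - size + 2))
                kind = "deletion" if rng.random() < p_deletion else "insertion"
                cand = Indel(chrom, start, start + size - 1, kind)
                if not any(cand.overlaps(x) for x in indels):
                    indels.append(cand)
                    break
        lines.append(F1Line(line_id, pd_inh, pn_inh, indels))
    return lines


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


def _haps_at_positions(intervals: list[tuple[int, int, int]],
                       pos: np.ndarray) -> np.ndarray:
    starts = np.array([iv[0] for iv in intervals])
    haps = np.array([iv[2] for iv in intervals])
    idx = np.searchsorted(starts, pos, side="right") - 1
    return haps[idx]


def _dose_at_positions(line: F1Line, chrom: str, pos: np.ndarray) -> np.ndarray:
    dose = np.ones(len(pos), dtype=int)
    for ind in line.indels:
        if ind.chrom != chrom:
            continue
        mask = (pos >= ind.start) & (pos <= ind.end)
        dose[mask] = 0 if ind.kind == "deletion" else 2
    return dose


def _scatter_errors(rng: np.random.Generator, counts: np.ndarray,
                    true_base: np.ndarray, n_true: np.ndarray,
                    error_rate: float) -> None:
    """Move a Binomial(error_rate) share of reads from each true base to a
    uniformly chosen other base, in place."""
    if error_rate <= 0:
        counts[np.arange(len(true_base)), true_base] += n_true
        return
    n_err = rng.binomial(n_true, error_rate)
    counts[np.arange(len(true_base)), true_base] += n_true - n_err
    # split errors uniformly over the three other bases
    e1 = rng.binomial(n_err, 1 / 3)
    e2 = rng.binomial(n_err - e1, 1 / 2)
    e3 = n_err - e1 - e2
    for k, e in enumerate((e1, e2, e3)):
        other = (true_base + 1 + k) % 4
        counts[np.arange(len(true_base)), other] += e

def _counts_frame(chrom: str, pos: np.ndarray, counts: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(counts, columns=list(NUCLEOTIDES))
    df.insert(0, "pos", pos)
    df.insert(0, "chrom", chrom)
    return df


def simulate_allele_counts(parents: tuple[ParentalGenome, ParentalGenome],
                           lines: Sequence[F1Line],
                           mean_depth: float = 0.5,
                           error_rate: float = 0.005,
                           seed: int = 0,
                           line_ids: Sequence[str] | None = None,
                           ) -> dict[str, pd.DataFrame]:
    """Per-line per-site nucleotide read counts at the joint parental sites.

    Depth at a site is Poisson(``mean_depth`` x copies/2) where copies is
    1 + Pn dose (deletions halve, duplications 1.5x the euploid rate); each
    read is drawn from the line's true alleles weighted by copy number, with
    a per-read substitution error to a uniformly chosen other base.
    Zero-depth sites are omitted, as in a parsed mpileup.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth > 0 required")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    pd_genome, pn_genome = parents
    rng = np.random.default_rng(seed)
    wanted = set(line_ids) if line_ids is not None else None
    out: dict[str, pd.DataFrame] = {}
    # per-chromosome site arrays, shared across lines
    site_arrays = {}
    for chrom, _ in pd_genome.chroms:
        sp = pd_genome.sites[chrom]
        sn = pn_genome.sites[chrom]
        site_arrays[chrom] = (
            sp["pos"].to_numpy(),
            sp["a1"].map(_BASE_INDEX).to_numpy(),
            sp["a2"].map(_BASE_INDEX).to_numpy(),
            sn["a1"].map(_BASE_INDEX).to_numpy(),
            sn["a2"].map(_BASE_INDEX).to_numpy(),
        )
    for line in lines:
        if wanted is not None and line.line_id not in wanted:
            continue
        frames = []
        for chrom, _ in pd_genome.chroms:
            pos, pd_a1, pd_a2, pn_a1, pn_a2 = site_arrays[chrom]
            hap_pd = _haps_at_positions(line.pd_inheritance[chrom], pos)
            hap_pn = _haps_at_positions(line.pn_inheritance[chrom], pos)
            pd_allele = np.where(hap_pd == 1, pd_a1, pd_a2)
            pn_allele = np.where(hap_pn == 1, pn_a1, pn_a2)
            dose = _dose_at_positions(line, chrom, pos)
            copies = 1 + dose
            depth = rng.poisson(mean_depth * copies / 2.0)
            with np.errstate(invalid="ignore"):
                w_pn = dose / copies
            n_pn = rng.binomial(depth, w_pn)
            n_pd = depth - n_pn
            counts = np.zeros((len(pos), 4), dtype=int)
            _scatter_errors(rng, counts, pd_allele, n_pd, error_rate)
            _scatter_errors(rng, counts, pn_allele, n_pn, error_rate)
            keep = depth > 0
            frames.append(_counts_frame(chrom, pos[keep], counts[keep]))
        df = pd.concat(frames, ignore_index=True)
        df.insert(0, "line_id", line.line_id)
        out[line.line_id] = df
    return out


def simulate_parent_counts(genome: ParentalGenome,
                           depth: float = 45.0,
                           error_rate: float = 0.005,
                           seed: int = 0) -> pd.DataFrame:
    """High-coverage read counts for one parental clone at the joint sites."""
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, _ in genome.chroms:
        df = genome.sites[chrom]
        pos = df["pos"].to_numpy()
        a1 = df["a1"].map(_BASE_INDEX).to_numpy()
        a2 = df["a2"].map(_BASE_INDEX).to_numpy()
        d = rng.poisson(depth, size=len(pos))
        n1 = rng.binomial(d, 0.5)
        n2 = d - n1
        counts = np.zeros((len(pos), 4), dtype=int)
        _scatter_errors(rng, counts, a1, n1, error_rate)
        _scatter_errors(rng, counts, a2, n2, error_rate)
        frames.append(_counts_frame(chrom, pos, counts))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "line_id", genome.parent_id)
    return out


# ---------------------------------------------------------------------------
# bin coverage
# ---------------------------------------------------------------------------


def tile_bins(chroms: list[tuple[str, int]], bin_size: int) -> pd.DataFrame:
    """Non-overlapping bins tiling each chromosome, 1-based inclusive."""
    if bin_size <= 0:
        raise ValueError("bin_size > 0 required")
    rows = []
    for chrom, length in chroms:
        start = 1
        while start <= length:
            end = min(start + bin_size - 1, length)
            rows.append((f"{chrom}_{start}_{end}", chrom, start, end))
            start = end + 1
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "start", "end"])


def simulate_bin_coverage(lines: Sequence[F1Line],
                          chroms: list[tuple[str, int]],
                          bin_size: int = 50_000,
                          mean_cov: float = 250.0,
                          seed: int = 0,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line per-bin read counts: Poisson(mean_cov x copy_number / 2).

    Copy number at a bin is taken at the bin midpoint from the line's
    indels (1 deletion, 2 euploid, 3 duplication). Returns (bins, coverage)
    with coverage indexed by bin marker_id, one column per line.
    """
    rng = np.random.default_rng(seed)
    bins = tile_bins(chroms, bin_size)
    mids = ((bins["start"] + bins["end"]) // 2).to_numpy()
    cov = {}
    for line in lines:
        cn = np.empty(len(bins), dtype=int)
        for chrom, _ in chroms:
            mask = (bins["chrom"] == chrom).to_numpy()
            dose = _dose_at_positions(line, chrom, mids[mask])
            cn[mask] = 1 + dose
        cov[line.line_id] = rng.poisson(mean_cov * cn / 2.0)
    coverage = pd.DataFrame(cov, index=pd.Index(bins["marker_id"],
                                                name="marker_id"))
    return bins, coverage


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _genotype_code(line: F1Line, qtl: PlantedQtl) -> float:
    pos = qtl.midpoint
    if qtl.channel == "Pd":
        return line.hap_at("Pd", qtl.chrom, pos) - 1
    dose = line.pn_dose(qtl.chrom, pos)
    if qtl.channel == "dosage":
        return dose
    if qtl.channel == "deletion":
        return 1.0 if dose == 0 else 0.0
    if qtl.channel == "insertion":
        return 1.0 if dose == 2 else 0.0
    # Pn allelic effect: absent segments contribute nothing
    if dose == 0:
        return 0.0
    return line.hap_at("Pn", qtl.chrom, pos) - 1


def simulate_phenotypes(truth: TruthSet, seed: int = 0) -> PhenotypeTable:
    """Forward model of the single-marker regression: for each trait,
    Y_i = beta0 + sum(effect x genotype code) + N(0, noise_sd^2).

    Genotype codes follow the scan's encoding: Pd haplotype 1/2 -> 0/1,
    Pn haplotype 1/2 -> 0/1 (0 when the segment is deleted), dosage 0/1/2.
    """
    chrom_bounds = {}
    if truth.parents is not None:
        chrom_bounds = dict(truth.parents[0].chroms)
    for qtl in truth.planted_qtls:
        if chrom_bounds:
            if qtl.chrom not in chrom_bounds or qtl.end > chrom_bounds[qtl.chrom]:
                raise ValueError(f"planted QTL {qtl} outside simulated genome")
    rng = np.random.default_rng(seed)
    traits = sorted(truth.noise_sd)
    values = {}
    for trait in traits:
        beta0 = truth.beta0.get(trait, 0.0)
        sd = truth.noise_sd[trait]
        qtls = [q for q in truth.planted_qtls if q.trait == trait]
        y = np.full(len(truth.lines), beta0, dtype=float)
        for qtl in qtls:
            y += qtl.effect * np.array(
                [_genotype_code(line, qtl) for line in truth.lines])
        y += rng.normal(0.0, sd, size=len(truth.lines))
        values[trait] = y
    df = pd.DataFrame(values, index=[l.line_id for l in truth.lines])
    return PhenotypeTable(values=df)


# ---------------------------------------------------------------------------
# whole experiment
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Desk-scale defaults for a full synthetic experiment.

    The population sizes mirror the real design (343 genotyped lines with a
    122-line deep-coverage subset at ~0.5x and >=20x respectively, ~2.5
    Pn-only indels per carrier at 66.5% deletions); the genome is scaled to
    5 chromosomes x 2 Mb so a full run stays desk-sized.
    """

    n_chrom: int = 5
    chrom_len: int = 2_000_000
    het_density: float = 5e-4
    n_lines: int = 343
    deep_n: int = 122
    recomb_per_chrom: float = 1.5
    indel_rate: float = 2.5
    indel_size_range: tuple[int, int] = (250_000, 750_000)
    p_deletion: float = 0.665
    low_depth: float = 0.5
    deep_depth: float = 30.0
    error_rate: float = 0.005
    cov_bin_size: int = 50_000
    mean_bin_cov: float = 250.0


@dataclass
class SyntheticExperiment:
    config: SimConfig
    seed: int
    parents: tuple[ParentalGenome, ParentalGenome]
    lines: list[F1Line]
    truth: TruthSet
    parent_counts: dict[str, pd.DataFrame]
    deep_counts: dict[str, pd.DataFrame]
    lowcov_counts: dict[str, pd.DataFrame]
    dosage_bins: pd.DataFrame
    bin_coverage: pd.DataFrame
    phenotypes: PhenotypeTable

    @property
    def deep_line_ids(self) -> list[str]:
        return list(self.deep_counts)


def default_planted_qtls(config: SimConfig) -> list[PlantedQtl]:
    """Demo trait set: one trait per channel plus an effect-free null trait.

    QTLs are placed on distinct chromosomes when available (wrapping around
    for very small genomes).
    """
    L = config.chrom_len
    n = config.n_chrom

    def chrom(i: int) -> str:
        return f"Chr{(i % n) + 1:02d}"

    return [
        PlantedQtl("trait_pd", chrom(0), L // 3, min(L // 3 + 100_000, L),
                   "Pd", 1.0),
        PlantedQtl("trait_pn", chrom(1), L // 2, min(L // 2 + 100_000, L),
                   "Pn", 1.0),
        PlantedQtl("trait_dosage", chrom(2), L // 4, min(L // 4 + 100_000, L),
                   "dosage", 1.5),
    ]


def simulate_experiment(config: SimConfig | None = None,
                        seed: int = 0,
                        planted_qtls: list[PlantedQtl] | None = None,
                        noise_sd: dict[str, float] | None = None,
                        ) -> SyntheticExperiment:
    """Run the whole generator with named substreams off one root seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    subs = {name: s for name, s in zip(
        ("parents", "f1", "parent_counts", "deep", "lowcov", "cov", "pheno"),
        ss.spawn(7))}

    def sub_seed(name: str) -> int:
        return int(subs[name].generate_state(1)[0] % (2**31))

    parents = simulate_parents(config.n_chrom, config.chrom_len,
                               config.het_density, seed=sub_seed("parents"))
    lines = simulate_f1(parents, config.n_lines, config.recomb_per_chrom,
                        config.indel_rate, config.indel_size_range,
                        config.p_deletion, seed=sub_seed("f1"))
    if planted_qtls is None:
        planted_qtls = default_planted_qtls(config)
    if noise_sd is None:
        noise_sd = {t: 1.0 for t in
                    sorted({q.trait for q in planted_qtls} | {"trait_null"})}
    truth = TruthSet(lines=lines, planted_qtls=planted_qtls,
                     noise_sd=noise_sd, parents=parents)
    parent_counts = {
        "Pd": simulate_parent_counts(parents[0], 45.0, config.error_rate,
                                     seed=sub_seed("parent_counts")),
        "Pn": simulate_parent_counts(parents[1], 65.0, config.error_rate,
                                     seed=sub_seed("parent_counts") + 1),
    }
    deep_ids = [l.line_id for l in lines[:config.deep_n]]
    deep_counts = simulate_allele_counts(
        parents, lines, config.deep_depth, config.error_rate,
        seed=sub_seed("deep"), line_ids=deep_ids)
    lowcov_counts = simulate_allele_counts(
        parents, lines, config.low_depth, config.error_rate,
        seed=sub_seed("lowcov"))
    dosage_bins, bin_coverage = simulate_bin_coverage(
        lines, parents[0].chroms, config.cov_bin_size, config.mean_bin_cov,
        seed=sub_seed("cov"))
    phenotypes = simulate_phenotypes(truth, seed=sub_seed("pheno"))
    return SyntheticExperiment(
        config=config, seed=seed, parents=parents, lines=lines, truth=truth,
        parent_counts=parent_counts, deep_counts=deep_counts,
        lowcov_counts=lowcov_counts, dosage_bins=dosage_bins,
        bin_coverage=bin_coverage, phenotypes=phenotypes)


# ---------------------------------------------------------------------------
# marker-level population generator
# ---------------------------------------------------------------------------
#
# For statistical power and calibration studies the read-level machinery is
# unnecessary: what the scans see is the common marker table. This generator
# draws that table directly — haplotype mosaics as a Markov chain over the
# marker grid and indels as marker-span events — emulating the study's
# sparse per-locus indel coverage (a handful of carrier lines per bin)
# independently of the dense desk-scale genome used for read-level recovery
# tests.


@dataclass
class MarkerPopulation:
    """Marker-grid truth for a simulated F1 population.

    ``pd_code``/``pn_code`` are markers x lines 0/1 haplotype codes;
    ``dose`` is the 0/1/2 Pn copy number. ``line_ids`` columns apply to all
    three matrices.
    """

    markers: pd.DataFrame
    line_ids: list[str]
    pd_code: np.ndarray
    pn_code: np.ndarray
    dose: np.ndarray

    def to_common_marker_table(self):
        from .integrate import CommonMarkerTable

        idx = pd.Index(self.markers["marker_id"], name="marker_id")
        pd_hap = pd.DataFrame(
            np.where(self.pd_code == 0, "D1", "D2"), index=idx,
            columns=self.line_ids)
        pn_hap = pd.DataFrame(
            np.where(self.pn_code == 0, "N1", "N2"), index=idx,
            columns=self.line_ids).where(self.dose != 0)
        dose = pd.DataFrame(self.dose.astype(float), index=idx,
                            columns=self.line_ids)
        return CommonMarkerTable(markers=self.markers, pd_hap=pd_hap,
                                 pn_hap=pn_hap, dose=dose)


def _mosaic_codes(rng: np.random.Generator, n_lines: int, n_markers: int,
                  switch_prob: float) -> np.ndarray:
    start = rng.integers(0, 2, size=n_lines)
    flips = rng.random((n_markers - 1, n_lines)) < switch_prob
    codes = np.empty((n_markers, n_lines), dtype=np.int8)
    codes[0] = start
    codes[1:] = flips
    return np.cumsum(codes, axis=0) % 2


def simulate_marker_population(n_lines: int = 343, n_chrom: int = 5,
                               markers_per_chrom: int = 20,
                               marker_len: int = 100_000,
                               recomb_per_chrom: float = 1.5,
                               indel_rate: float = 0.78,
                               indel_span: tuple[int, int] = (3, 6),
                               p_deletion: float = 0.665,
                               seed: int = 0) -> MarkerPopulation:
    """Simulate haplotype and dosage genotypes directly on a marker grid.

    Haplotype codes follow a two-state Markov chain with switch probability
    ``recomb_per_chrom / markers_per_chrom`` between adjacent markers;
    indel counts per line are Poisson(``indel_rate``) — calibrated so
    roughly half the lines carry at least one indel — each spanning a
    uniform ``indel_span`` run of markers, deletions with probability
    ``p_deletion``. Overlapping indels within a line are re-drawn.
    """
    rng = np.random.default_rng(seed)
    line_ids = [f"F1_{i + 1:04d}" for i in range(n_lines)]
    switch = recomb_per_chrom / markers_per_chrom
    rows = []
    pd_parts, pn_parts, dose_parts = [], [], []
    for c in range(n_chrom):
        chrom = f"Chr{c + 1:02d}"
        for m in range(markers_per_chrom):
            start = m * marker_len + 1
            end = (m + 1) * marker_len
            rows.append((f"{chrom}_{start}_{end}", chrom, start, end))
        pd_parts.append(_mosaic_codes(rng, n_lines, markers_per_chrom, switch))
        pn_parts.append(_mosaic_codes(rng, n_lines, markers_per_chrom, switch))
        dose_parts.append(np.ones((markers_per_chrom, n_lines), dtype=np.int8))
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "start", "end"])
    dose = np.concatenate(dose_parts)
    n_markers_total = len(markers)
    for j in range(n_lines):
        n_ind = rng.poisson(indel_rate)
        taken: list[tuple[int, int]] = []
        for _ in range(n_ind):
            for _attempt in range(100):
                c = int(rng.integers(n_chrom))
                span = int(rng.integers(indel_span[0], indel_span[1] + 1))
                span = min(span, markers_per_chrom)
                lo = c * markers_per_chrom + int(
                    rng.integers(0, markers_per_chrom - span + 1))
                hi = lo + span
                if all(hi <= a or b <= lo for a, b in taken):
                    taken.append((lo, hi))
                    dose[lo:hi, j] = 0 if rng.random() < p_deletion else 2
                    break
    return MarkerPopulation(markers=markers, line_ids=line_ids,
                            pd_code=np.concatenate(pd_parts),
                            pn_code=np.concatenate(pn_parts), dose=dose)


def plant_indel_carriers(pop: MarkerPopulation, marker_index: int,
                         kind: str, n_carriers: int, span: int = 3,
                         seed: int = 0) -> None:
    """Force ``n_carriers`` random lines to carry an indel over a marker run.

    Used to give a planted QTL a controlled carrier count (the study's
    dosage power depends directly on how many lines carry an indel at the
    locus). The run starts at ``marker_index`` and stays on one chromosome.
    """
    rng = np.random.default_rng(seed)
    chrom = pop.markers.iloc[marker_index]["chrom"]
    same = pop.markers["chrom"] == chrom
    hi = min(marker_index + span, int(np.flatnonzero(same.to_numpy()).max()) + 1)
    value = 0 if kind == "deletion" else 2
    carriers = rng.choice(len(pop.line_ids), size=n_carriers, replace=False)
    pop.dose[marker_index:hi, carriers] = value


def mechanism_phenotype(pop: MarkerPopulation, marker_index: int,
                        mechanism: str, effect_std: float = 0.5,
                        noise_sd: float = 1.0, seed: int = 0,
                        ) -> tuple[pd.Series, float]:
    """Trait with a single-mechanism planted effect at one marker.

    ``effect_std`` is the standardized effect: the raw coefficient is
    ``effect_std * noise_sd / sd(genotype code)``, so the expected scan t
    is about effect_std * sqrt(n) regardless of carrier counts. Mechanism
    codes: deletion/insertion indicators of dose 0 / dose 2, Pd/Pn the
    haplotype codes (Pn 0 where deleted), dosage the linear 0/1/2 code,
    Pd+Pn both haplotype codes with equal coefficients.
    """
    rng = np.random.default_rng(seed)
    d = pop.dose[marker_index].astype(float)
    codes: list[np.ndarray] = []
    if mechanism == "deletion":
        codes = [(d == 0).astype(float)]
    elif mechanism == "insertion":
        codes = [(d == 2).astype(float)]
    elif mechanism == "dosage":
        codes = [d]
    elif mechanism == "Pd":
        codes = [pop.pd_code[marker_index].astype(float)]
    elif mechanism == "Pn":
        codes = [np.where(d == 0, 0.0, pop.pn_code[marker_index]).astype(float)]
    elif mechanism == "Pd+Pn":
        codes = [pop.pd_code[marker_index].astype(float),
                 np.where(d == 0, 0.0, pop.pn_code[marker_index]).astype(float)]
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    y = rng.normal(0.0, noise_sd, size=len(pop.line_ids))
    beta = np.nan
    for code in codes:
        sd = code.std()
        if sd == 0:
            raise ValueError("planted mechanism has zero genotype variance")
        beta = effect_std * noise_sd / sd
        y = y + beta * code
    return pd.Series(y, index=pop.line_ids), float(beta)
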