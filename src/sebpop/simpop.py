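"""Synthetic admixed-cohort generator.

Produces genotype datasets that emulate the statistical structure of a
multi-way admixed, geographically structured cohort such as the South African
South-Eastern Bantu-speaking (SEB) groups: K ancestral components (by default
Bantu-related, Khoe-San-related and Eurasian-related), group-specific
admixture proportions and drift, per-haplotype local-ancestry tracts, an X
chromosome with sex-biased ancestry contributions, three sampling sites with
mixed group composition, and self/parent/grandparent ethnicity metadata.

The allele-frequency model is a two-layer Balding-Nichols construction:

* each ancestry k draws its frequency ``f_k`` from a Beta distribution around
  a shared base frequency ``p`` with differentiation parameter ``F_anc[k]``;
* each group adds its own drift ``F_g`` as a second Balding-Nichols layer
  around the ancestry frequencies, giving controllable between-group F_ST
  independent of admixture differences.

Local-ancestry tracts follow a Poisson switch process of rate ``g`` (the
number of generations since admixture) per Morgan; at every switch point the
ancestry is redrawn i.i.d. from the haplotype's admixture proportions, so
"silent" same-ancestry switches are allowed and the observed switch rate is
``g * (1 - sum_k q_k^2)`` per Morgan.

X-chromosome haplotypes use the single-pulse equilibrium expectation
``H_X = (2 s_f + s_m) / 3`` where ``s_f`` and ``s_m`` are the female and male
per-ancestry contribution fractions; autosomes use ``H_A = (s_f + s_m) / 2``.
Males carry a single X haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    MetadataError,
    ParameterError,
    RangeError,
)

__all__ = [
    "Chromosome",
    "GroupSpec",
    "SimConfig",
    "VariantMap",
    "AncestralFrequencies",
    "GenotypeDataset",
    "LocalAncestryMatrix",
    "TrueAncestry",
    "MISSING",
    "build_variant_map",
    "draw_ancestral_frequencies",
    "sample_ancestry_tracts",
    "simulate_local_ancestry",
    "simulate_genotypes",
    "spike_enrichment",
    "generate_pedigree_ethnicities",
    "ec_concordance",
    "ec_mask",
    "simulate_geographic_cline",
    "simulate_hierarchical_groups",
    "default_groups",
    "default_chromosomes",
    "default_config",
    "ANCESTRY_NAMES",
]

MISSING = -1  # genotype / ancestry sentinel
ANCESTRY_NAMES = ("BS", "KS", "EUR")

# Clipping bounds keep loci polymorphic so downstream estimators stay defined.
_FREQ_LO, _FREQ_HI = 0.001, 0.999

REL_COLUMNS = ["rel1", "rel2", "rel3", "rel4", "rel5", "rel6"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_simplex(v, name: str, tol: float = 1e-9) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or np.any(v < -tol) or abs(v.sum() - 1.0) > max(tol, 1e-9):
        raise ParameterError(f"{name} must be a probability simplex, got {v!r}")
    return np.clip(v, 0.0, 1.0)


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class Chromosome:
    """One simulated chromosome: physical and genetic length plus annotation.

    ``centromere`` is a (start_bp, end_bp) interval used by scan exclusions;
    the default sits in the middle of the chromosome.
    """

    name: str
    length_bp: int
    length_morgans: float
    is_x: bool = False
    centromere: tuple[int, int] | None = None

    def __post_init__(self):
        if self.length_bp <= 0 or self.length_morgans <= 0:
            raise ParameterError("chromosome lengths must be positive")
        if self.centromere is None:
            mid = self.length_bp // 2
            object.__setattr__(self, "centromere", (mid - 500_000, mid + 500_000))


@dataclass
class GroupSpec:
    """One simulated population group.

    ``q`` are autosomal admixture proportions (length-K simplex); ``s_f`` and
    ``s_m`` are the female/male per-ancestry contribution fractions with
    ``(s_f + s_m) / 2 == q``.  ``drift`` is the group's Balding-Nichols drift
    around its ancestry frequencies, ``g`` the generations since admixture and
    ``geo`` the (lat, lon) of the group's language-majority-area median.
    """

    name: str
    n: int
    q: Sequence[float]
    s_f: Sequence[float] | None = None
    s_m: Sequence[float] | None = None
    drift: float = 0.0
    g: int = 30
    geo: tuple[float, float] | None = None
    site_fractions: Sequence[float] | None = None

    def __post_init__(self):
        if self.n < 0:
            raise ParameterError(f"group {self.name}: n must be >= 0")
        self.q = _check_simplex(self.q, f"group {self.name} q")
        if (self.s_f is None) != (self.s_m is None):
            raise ParameterError(
                f"group {self.name}: s_f and s_m must be given together"
            )
        if self.s_f is None:
            self.s_f = self.q.copy()
            self.s_m = self.q.copy()
        self.s_f = _check_simplex(self.s_f, f"group {self.name} s_f")
        self.s_m = _check_simplex(self.s_m, f"group {self.name} s_m")
        if np.max(np.abs((self.s_f + self.s_m) / 2.0 - self.q)) > 1e-9:
            raise ParameterError(
                f"group {self.name}: (s_f + s_m)/2 must equal q"
            )
        if self.drift < 0:
            raise ParameterError(f"group {self.name}: drift must be >= 0")
        if self.g < 1:
            raise ParameterError(f"group {self.name}: g must be >= 1")

    @property
    def h_x(self) -> np.ndarray:
        """X-chromosome ancestry expectation (2 s_f + s_m) / 3."""
        return (2.0 * self.s_f + self.s_m) / 3.0


@dataclass
class SimConfig:
    """Full simulator configuration; every stochastic choice flows from ``seed``."""

    groups: list[GroupSpec]
    chroms: list[Chromosome]
    L: int
    F_anc: Sequence[float]
    ancestries: Sequence[str] = ANCESTRY_NAMES
    sites: Sequence[str] = ("Agincourt", "Dikgale", "Soweto")
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    mismatch_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        K = len(self.ancestries)
        self.F_anc = np.asarray(self.F_anc, dtype=float)
        if self.F_anc.shape != (K,):
            raise ConfigurationError("F_anc must have one entry per ancestry")
        if np.any(self.F_anc <= 0) or np.any(self.F_anc >= 1):
            raise ParameterError("F_anc entries must lie in (0, 1)")
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        lo, hi = self.base_freq_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("base_freq_range must satisfy 0 < lo < hi < 1")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not (0 <= self.mismatch_rate <= 1):
            raise ConfigurationError("mismatch_rate must lie in [0, 1]")
        n_sites = len(self.sites)
        for grp in self.groups:
            if len(grp.q) != K:
                raise ConfigurationError(
                    f"group {grp.name}: q has {len(grp.q)} entries, expected {K}"
                )
            if grp.site_fractions is None:
                grp.site_fractions = np.full(n_sites, 1.0 / n_sites)
            grp.site_fractions = np.asarray(grp.site_fractions, dtype=float)
            if grp.site_fractions.shape != (n_sites,):
                raise ConfigurationError(
                    f"group {grp.name}: site_fractions must match the site list"
                )
            if np.any(grp.site_fractions < 0) or abs(grp.site_fractions.sum() - 1) > 1e-9:
                raise ConfigurationError(
                    f"group {grp.name}: site fractions must be >= 0 and sum to 1"
                )

    @property
    def K(self) -> int:
        return len(self.ancestries)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class VariantMap:
    """Per-variant coordinates: chromosome, bp (1-based), cM, ploidy flag."""

    chrom: np.ndarray  # str per variant
    pos: np.ndarray  # int, 1-based inclusive
    cm: np.ndarray  # genetic position within chromosome
    is_x: np.ndarray  # bool per variant
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    chromosomes: list[Chromosome] | None = None

    def __post_init__(self):
        L = len(self.pos)
        if self.ref is None:
            self.ref = np.full(L, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(L, "G", dtype=object)
        for name in pd.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if np.any(np.diff(p) <= 0):
                raise ParameterError(
                    f"variant positions must be strictly increasing on {name}"
                )

    def __len__(self) -> int:
        return len(self.pos)

    def region_index(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Column indices of variants within [start_bp, end_bp] (1-based inclusive)."""
        sel = (self.chrom == chrom) & (self.pos >= start_bp) & (self.pos <= end_bp)
        idx = np.flatnonzero(sel)
        if not np.any(self.chrom == chrom):
            raise RangeError(f"chromosome {chrom!r} not in variant map")
        return idx


@dataclass
class AncestralFrequencies:
    """K x L alternate-allele frequencies, one row per ancestral population."""

    freq: np.ndarray
    variants: VariantMap | None = None
    base: np.ndarray | None = None
    ancestries: Sequence[str] | None = None

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2:
            raise ParameterError("freq must be a K x L matrix")
        if np.any(self.freq < _FREQ_LO - 1e-12) or np.any(self.freq > _FREQ_HI + 1e-12):
            raise ParameterError("ancestral frequencies must lie in [0.001, 0.999]")

    @property
    def K(self) -> int:
        return self.freq.shape[0]


@dataclass
class GenotypeDataset:
    """Sample x variant dosage matrix with variant map and sample metadata.

    ``G`` holds dosages in {0, 1, 2} for diploid calls, {0, 1} for hemizygous
    male X calls, and -1 for missing.  ``samples`` carries id, group, site,
    sex, self_ethnicity and the six parent/grandparent ethnicity labels.
    """

    G: np.ndarray
    variants: VariantMap
    samples: pd.DataFrame

    def __post_init__(self):
        if self.G.shape != (len(self.samples), len(self.variants)):
            raise ParameterError("G shape must be (n samples, L variants)")
        if self.samples["id"].duplicated().any():
            raise MetadataError("sample ids must be unique")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def L(self) -> int:
        return self.G.shape[1]

    def subset_samples(self, mask_or_index) -> "GenotypeDataset":
        samples = self.samples.loc[mask_or_index] if isinstance(
            mask_or_index, pd.Series
        ) else self.samples.iloc[mask_or_index]
        idx = samples.index.to_numpy()
        return GenotypeDataset(
            G=self.G[idx], variants=self.variants, samples=samples.reset_index(drop=True)
        )


@dataclass
class LocalAncestryMatrix:
    """Per-haplotype, per-variant ancestry labels with posterior scores.

    Rows 2i and 2i+1 belong to sample i.  For male samples the second X
    haplotype does not exist: those cells hold -1 with posterior 0.
    """

    A: np.ndarray  # (2n, L) int8; -1 marks absent haplotype cells
    P: np.ndarray  # (2n, L) float, posteriors in [0, 1]
    K: int
    variants: VariantMap | None = None

    def __post_init__(self):
        if self.A.shape != self.P.shape:
            raise ParameterError("A and P must have identical shapes")
        if np.any((self.P < 0) | (self.P > 1)):
            raise ParameterError("posteriors must lie in [0, 1]")

    def dosage(self, ancestry_index: int, posterior_min: float = -1.0) -> np.ndarray:
        """Per-variant mean dosage of one ancestry over valid haplotype cells."""
        valid = (self.A >= 0) & (self.P > posterior_min)
        hits = valid & (self.A == ancestry_index)
        denom = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, hits.sum(axis=0) / denom, np.nan)


@dataclass
class TrueAncestry:
    """Realized per-sample ancestry dosages, autosomes and X separately."""

    Q_auto: np.ndarray  # (n, K)
    Q_X: np.ndarray  # (n, K); nan when no X loci simulated
    ancestries: Sequence[str]


# ---------------------------------------------------------------------------
# variant map construction


def build_variant_map(chroms: Sequence[Chromosome], L: int) -> VariantMap:
    """Spread ``L`` evenly spaced variants over ``chroms`` proportionally to bp."""
    bp = np.array([c.length_bp for c in chroms], dtype=float)
    counts = np.floor(L * bp / bp.sum()).astype(int)
    # largest-remainder top-up
    rem = L * bp / bp.sum() - counts
    for i in np.argsort(-rem)[: L - counts.sum()]:
        counts[i] += 1
    chrom_names, pos, cm, is_x = [], [], [], []
    for c, k in zip(chroms, counts):
        if k == 0:
            continue
        p = np.round((np.arange(k) + 0.5) * c.length_bp / k).astype(np.int64)
        p = np.maximum.accumulate(np.maximum(p, 1))
        p += np.concatenate([[0], np.cumsum(np.diff(p) == 0)])  # force strict increase
        chrom_names.append(np.full(k, c.name, dtype=object))
        pos.append(p)
        cm.append(p * (100.0 * c.length_morgans / c.length_bp))
        is_x.append(np.full(k, c.is_x))
    return VariantMap(
        chrom=np.concatenate(chrom_names),
        pos=np.concatenate(pos),
        cm=np.concatenate(cm),
        is_x=np.concatenate(is_x),
        chromosomes=list(chroms),
    )


# ---------------------------------------------------------------------------
# core draws


def draw_ancestral_frequencies(
    K: int,
    L: int,
    F_anc,
    base_freq_range: tuple[float, float] = (0.05, 0.95),
    variant_map: VariantMap | None = None,
    seed=None,
) -> AncestralFrequencies:
    """Draw per-ancestry allele frequencies under the Balding-Nichols model.

    A base frequency p ~ Uniform(base_freq_range) is drawn per locus; each
    ancestry then draws f_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F) so that
    E[f_k] = p and Var[f_k] = F p (1-p).  Frequencies are clipped to
    [0.001, 0.999].
    """
    if K < 1 or L < 1:
        raise ParameterError("K and L must be >= 1")
    F = np.broadcast_to(np.asarray(F_anc, dtype=float), (K,)).copy()
    if np.any(F <= 0) or np.any(F >= 1):
        raise ParameterError("F_anc must lie in (0, 1)")
    rng = _rng(seed)
    lo, hi = base_freq_range
    p = rng.uniform(lo, hi, size=L)
    ratio = (1.0 - F[:, None]) / F[:, None]
    f = rng.beta(p[None, :] * ratio, (1.0 - p[None, :]) * ratio)
    f = np.clip(f, _FREQ_LO, _FREQ_HI)
    return AncestralFrequencies(freq=f, variants=variant_map, base=p)


def _drift_frequencies(freq: np.ndarray, F_g: float, rng) -> np.ndarray:
    """Second Balding-Nichols layer: group-level drift around ancestry freqs."""
    if F_g <= 0:
        return freq.copy()
    ratio = (1.0 - F_g) / F_g
    out = rng.beta(freq * ratio, (1.0 - freq) * ratio)
    return np.clip(out, _FREQ_LO, _FREQ_HI)


def sample_ancestry_tracts(
    q, g: int, morgans: float, n_haplotypes: int, seed=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample ancestry tracts for ``n_haplotypes`` haploid chromosomes.

    Switch points form a Poisson process of rate ``g`` per Morgan; segment
    ancestries are i.i.d. draws from ``q`` (same-ancestry switches allowed).
    Returns a (breakpoints_in_morgans, segment_states) pair per haplotype;
    segment i covers [breaks[i-1], breaks[i]) with breaks implicitly anchored
    at 0 and ``morgans``.
    """
    q = _check_simplex(q, "q")
    if g < 1:
        raise ParameterError("g must be >= 1")
    rng = _rng(seed)
    cum_q = np.cumsum(q)
    cum_q[-1] = 1.0
    out = []
    n_switch = rng.poisson(g * morgans, size=n_haplotypes)
    for ns in n_switch:
        breaks = np.sort(rng.uniform(0.0, morgans, size=ns))
        states = np.searchsorted(cum_q, rng.random(ns + 1), side="right")
        out.append((breaks, states.astype(np.int8)))
    return out


def _tract_labels_batch(A, rows, cols, cm_morgans, morgans, q, g, rng):
    """Fill ancestry labels for many haplotypes on one chromosome."""
    q = np.asarray(q, dtype=float)
    cum_q = np.cumsum(q)
    cum_q[-1] = 1.0
    n_switch = rng.poisson(g * morgans, size=len(rows))
    for r, ns in zip(rows, n_switch):
        if ns == 0:
            A[r, cols] = np.searchsorted(cum_q, rng.random(), side="right")
            continue
        breaks = np.sort(rng.uniform(0.0, morgans, size=ns))
        states = np.searchsorted(cum_q, rng.random(ns + 1), side="right").astype(np.int8)
        A[r, cols] = states[np.searchsorted(breaks, cm_morgans, side="right")]


def simulate_local_ancestry(
    q,
    g: int,
    variants: VariantMap,
    n_haplotypes: int,
    seed=None,
    posterior_noise: float = 0.0,
) -> LocalAncestryMatrix:
    """Simulate truth local-ancestry labels for every variant of ``variants``.

    Posteriors are 1.0 (truth tracts); ``posterior_noise`` > 0 degrades them
    by subtracting Uniform(0, posterior_noise) per cell, emulating the
    uncertainty profile of inferred local ancestry.
    """
    q = _check_simplex(q, "q")
    rng = _rng(seed)
    L = len(variants)
    A = np.empty((n_haplotypes, L), dtype=np.int8)
    for name in pd.unique(variants.chrom):
        cols = np.flatnonzero(variants.chrom == name)
        cm = variants.cm[cols]
        morgans = _chrom_morgans(variants, name)
        tracts = sample_ancestry_tracts(q, g, morgans, n_haplotypes, rng)
        for h, (breaks, states) in enumerate(tracts):
            A[h, cols] = states[np.searchsorted(breaks, cm / 100.0, side="right")]
    P = np.ones_like(A, dtype=np.float32)
    if posterior_noise > 0:
        P -= rng.uniform(0.0, posterior_noise, size=P.shape).astype(np.float32)
    K = len(q)
    return LocalAncestryMatrix(A=A, P=P, K=K, variants=variants)


def _chrom_morgans(variants: VariantMap, name: str) -> float:
    if variants.chromosomes is not None:
        for c in variants.chromosomes:
            if c.name == name:
                return c.length_morgans
    cm = variants.cm[variants.chrom == name]
    return float(cm.max()) / 100.0 if len(cm) else 0.0


# ---------------------------------------------------------------------------
# full cohort simulation


def simulate_genotypes(
    config: SimConfig,
) -> tuple[GenotypeDataset, LocalAncestryMatrix, TrueAncestry]:
    """Simulate the full cohort described by ``config``.

    Returns the genotype dataset (with metadata), truth local-ancestry tracts
    and the realized per-sample ancestry dosages (autosomes and X separately).
    """
    K = config.K
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_tracts, rng_geno, rng_meta, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    variants = build_variant_map(config.chroms, config.L)
    anc = draw_ancestral_frequencies(
        K,
        len(variants),
        config.F_anc,
        config.base_freq_range,
        variant_map=variants,
        seed=rng_freq,
    )
    auto_cols = np.flatnonzero(~variants.is_x)
    x_cols = np.flatnonzero(variants.is_x)

    n_total = sum(g.n for g in config.groups)
    L = len(variants)
    G = np.empty((n_total, L), dtype=np.int8)
    A = np.full((2 * n_total, L), MISSING, dtype=np.int8)
    Q_auto = np.zeros((n_total, K))
    Q_X = np.full((n_total, K), np.nan)
    meta_rows = []

    chrom_infos = []
    for c in config.chroms:
        cols = np.flatnonzero(variants.chrom == c.name)
        if len(cols):
            chrom_infos.append(
                (c.is_x, cols, variants.cm[cols] / 100.0, c.length_morgans)
            )

    row = 0
    for grp in config.groups:
        if grp.n == 0:
            continue
        f_grp = _drift_frequencies(anc.freq, grp.drift, rng_freq)
        sexes = np.where(rng_meta.random(grp.n) < 0.5, "F", "M")
        sites = _assign_sites(config.sites, grp.site_fractions, grp.n, rng_meta)
        h_x = grp.h_x
        hap_rows = np.arange(2 * row, 2 * (row + grp.n))
        # X rows: first haplotype for everyone, second only for females
        x_rows = np.concatenate(
            [hap_rows[0::2], hap_rows[1::2][sexes == "F"]]
        )
        for is_x, cols, cmM, morgans in chrom_infos:
            if is_x:
                _tract_labels_batch(A, x_rows, cols, cmM, morgans, h_x, grp.g, rng_tracts)
            else:
                _tract_labels_batch(
                    A, hap_rows, cols, cmM, morgans, grp.q, grp.g, rng_tracts
                )
        for i in range(grp.n):
            meta_rows.append(
                {
                    "id": f"{grp.name}_{i:04d}",
                    "group": grp.name,
                    "site": sites[i],
                    "sex": sexes[i],
                    "self_ethnicity": grp.name,
                }
            )
        # allele draws for the whole group at once, chunked over haplotypes
        rows = np.arange(2 * row, 2 * (row + grp.n))
        _draw_alleles_into(G, A, f_grp, rows, row, grp.n, rng_geno)
        # realized dosages
        if len(auto_cols):
            blockA = A[rows][:, auto_cols]
            for k in range(K):
                Q_auto[row : row + grp.n, k] = (
                    (blockA == k).reshape(grp.n, 2, -1).mean(axis=(1, 2))
                )
        else:
            Q_auto[row : row + grp.n] = np.nan
        if len(x_cols):
            blockX = A[rows][:, x_cols]
            valid = blockX >= 0
            for k in range(K):
                hits = (blockX == k) & valid
                Q_X[row : row + grp.n, k] = (
                    hits.reshape(grp.n, 2, -1).sum(axis=(1, 2))
                    / valid.reshape(grp.n, 2, -1).sum(axis=(1, 2))
                )
        row += grp.n

    samples = pd.DataFrame(
        meta_rows,
        columns=["id", "group", "site", "sex", "self_ethnicity"],
    )
    pool = [g.name for g in config.groups]
    mismatch = config.mismatch_rate if len(pool) > 1 else 0.0
    if n_total:
        rels = generate_pedigree_ethnicities(
            samples["group"].to_numpy(), mismatch, pool, seed=rng_meta
        )
    else:
        rels = np.empty((0, 6), dtype=object)
    for j, col in enumerate(REL_COLUMNS):
        samples[col] = rels[:, j] if n_total else pd.Series(dtype=object)

    if config.missing_rate > 0 and n_total:
        mask = rng_miss.random(G.shape) < config.missing_rate
        G[mask] = MISSING

    P = np.where(A >= 0, 1.0, 0.0).astype(np.float32)
    dataset = GenotypeDataset(G=G, variants=variants, samples=samples)
    la = LocalAncestryMatrix(A=A, P=P, K=K, variants=variants)
    truth = TrueAncestry(Q_auto=Q_auto, Q_X=Q_X, ancestries=list(config.ancestries))
    return dataset, la, truth


def _assign_sites(sites, fractions, n, rng) -> np.ndarray:
    counts = np.floor(np.asarray(fractions) * n).astype(int)
    rem = np.asarray(fractions) * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    if counts.sum() != n or np.any(counts < 0):
        raise ConfigurationError("site fractions incompatible with group size")
    out = np.repeat(np.asarray(sites, dtype=object), counts)
    rng.shuffle(out)
    return out


def _draw_alleles_into(G, A, f_grp, hap_rows, sample_row0, n, rng, chunk=512):
    """Draw alleles Bernoulli(f_grp[ancestry, locus]) and sum into genotypes."""
    f32 = f_grp.astype(np.float32)
    K = f32.shape[0]
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        rows = hap_rows[2 * start : 2 * stop]
        block = A[rows]  # (2m, L)
        # mask-accumulated gather of f[ancestry, locus]; absent cells get 0
        pmat = np.zeros(block.shape, dtype=np.float32)
        for k in range(K):
            np.add(pmat, (block == k) * f32[k][None, :], out=pmat)
        alleles = (rng.random(block.shape, dtype=np.float32) < pmat).astype(np.int8)
        geno = alleles[0::2] + alleles[1::2]
        G[sample_row0 + start : sample_row0 + stop] = geno


# ---------------------------------------------------------------------------
# fixtures and metadata


def spike_enrichment(
    la: LocalAncestryMatrix,
    regions: Iterable[tuple[str, int, int]],
    ancestry_index: int,
    target_dosage: float,
    seed=None,
) -> LocalAncestryMatrix:
    """Resample haplotypes inside ``regions`` to a target ancestry dosage.

    Within each (chrom, start_bp, end_bp) region, exactly round(target * H)
    of the H valid haplotypes carry ``ancestry_index`` across the whole
    region; the rest are reassigned uniformly among the other ancestries.
    Cells outside the regions are untouched.
    """
    if not (0.0 <= target_dosage <= 1.0):
        raise ParameterError("target_dosage must lie in [0, 1]")
    if la.variants is None:
        raise ParameterError("LocalAncestryMatrix carries no variant map")
    rng = _rng(seed)
    A = la.A.copy()
    P = la.P.copy()
    for chrom, start, end in regions:
        cols = la.variants.region_index(chrom, start, end)
        if len(cols) == 0:
            raise RangeError(f"region {chrom}:{start}-{end} matches no variants")
        valid = np.flatnonzero(np.all(A[:, cols] >= 0, axis=1))
        H = len(valid)
        m = int(round(target_dosage * H))
        carriers = rng.choice(valid, size=m, replace=False)
        others = np.setdiff1d(valid, carriers)
        A[np.ix_(carriers, cols)] = ancestry_index
        if la.K > 1 and len(others):
            block = A[np.ix_(others, cols)]
            hits = block == ancestry_index
            if hits.any():
                alt = rng.integers(0, la.K - 1, size=int(hits.sum()))
                alt = np.where(alt >= ancestry_index, alt + 1, alt)
                block[hits] = alt.astype(np.int8)
                A[np.ix_(others, cols)] = block
        P[np.ix_(valid, cols)] = 1.0
    return LocalAncestryMatrix(A=A, P=P, K=la.K, variants=la.variants)


def generate_pedigree_ethnicities(
    sample_groups: Sequence[str],
    mismatch_rate: float,
    group_pool: Sequence[str],
    seed=None,
) -> np.ndarray:
    """Draw the 6 parent/grandparent ethnicity labels per sample.

    Each label independently equals the sample's own group with probability
    1 - mismatch_rate, otherwise a uniform draw from the other groups.
    """
    if not (0.0 <= mismatch_rate <= 1.0):
        raise ParameterError("mismatch_rate must lie in [0, 1]")
    groups = np.asarray(sample_groups, dtype=object)
    n = len(groups)
    pool = list(dict.fromkeys(group_pool))
    if mismatch_rate > 0 and len(pool) < 2:
        raise ConfigurationError(
            "mismatch_rate > 0 requires at least two groups in the pool"
        )
    rng = _rng(seed)
    out = np.tile(groups[:, None], (1, 6)).astype(object)
    flip = rng.random((n, 6)) < mismatch_rate
    for i, j in zip(*np.nonzero(flip)):
        alternatives = [p for p in pool if p != groups[i]]
        out[i, j] = alternatives[rng.integers(len(alternatives))]
    return out


def ec_concordance(sample: Mapping) -> bool:
    """Ethno-linguistic concordance: >= 5 of the 6 relative labels match self."""
    try:
        self_eth = sample["self_ethnicity"]
        rels = [sample[c] for c in REL_COLUMNS]
    except KeyError as exc:
        raise MetadataError(f"missing metadata field: {exc}") from exc
    if any(pd.isna(r) for r in rels):
        raise MetadataError("all six relative ethnicity labels must be present")
    return sum(r == self_eth for r in rels) >= 5


def ec_mask(samples: pd.DataFrame) -> np.ndarray:
    """Vectorized EC filter over a sample metadata frame."""
    matches = np.zeros(len(samples), dtype=int)
    for c in REL_COLUMNS:
        if c not in samples:
            raise MetadataError(f"missing metadata column: {c}")
        if samples[c].isna().any():
            raise MetadataError("all six relative ethnicity labels must be present")
        matches += (samples[c] == samples["self_ethnicity"]).to_numpy()
    return matches >= 5


# ---------------------------------------------------------------------------
# stylized geography-linked generator (structure-geography properties)


def simulate_geographic_cline(
    points: Sequence[tuple[float, float]],
    n_per_group: int,
    L: int,
    gradient: float = 0.2,
    base_freq_range: tuple[float, float] = (0.2, 0.8),
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes whose allele frequencies follow a linear geographic cline.

    Each locus gets random loadings (u, v) on standardized (lat, lon); group
    frequencies are base + gradient * (lat~ * u + lon~ * v), clipped away from
    fixation.  Returns (G, group_index) with one block of ``n_per_group``
    diploid samples per point.  Used to test that PCA coordinates recover the
    planted geography (Procrustes r^2 -> 1 as the gradient dominates noise).
    """
    rng = _rng(seed)
    pts = np.asarray(points, dtype=float)
    z = (pts - pts.mean(axis=0)) / (pts.std(axis=0) + 1e-12)
    lo, hi = base_freq_range
    p = rng.uniform(lo, hi, size=L)
    u = rng.standard_normal((2, L))
    f = p[None, :] + gradient * (z @ u)
    f = np.clip(f, 0.01, 0.99)
    G = np.concatenate(
        [rng.binomial(2, f[i], size=(n_per_group, L)).astype(np.int8) for i in range(len(pts))]
    )
    labels = np.repeat(np.arange(len(pts)), n_per_group)
    return G, labels


def simulate_hierarchical_groups(
    clusters: Sequence[Sequence[str]],
    n_per_group: int,
    L: int,
    F_between: float = 0.01,
    F_within: float = 0.003,
    base_freq_range: tuple[float, float] = (0.1, 0.9),
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-level drifted groups: clusters diverge by ``F_between`` from a
    shared base, groups within a cluster add ``F_within`` around their
    cluster frequency.  Emulates linguistic-cluster structure (e.g. the
    Nguni / Sotho-Tswana / Tsonga three-way split).  Returns (G, labels).
    """
    rng = _rng(seed)
    lo, hi = base_freq_range
    p = rng.uniform(lo, hi, size=L)

    def bn(freq, F):
        ratio = (1.0 - F) / F
        return np.clip(rng.beta(freq * ratio, (1.0 - freq) * ratio), _FREQ_LO, _FREQ_HI)

    blocks, labels = [], []
    for cluster in clusters:
        fc = bn(p, F_between)
        for name in cluster:
            fg = bn(fc, F_within)
            blocks.append(rng.binomial(2, fg, size=(n_per_group, L)).astype(np.int8))
            labels.extend([name] * n_per_group)
    return np.concatenate(blocks), np.asarray(labels, dtype=object)


# ---------------------------------------------------------------------------
# defaults anchored to the published cohort design


# (name, n_EC, BS%, KS%, EUR%, generations since admixture, (lat, lon) of the
# language-majority-area median).  Ancestry percentages follow the published
# K=3 unsupervised clustering means; sizes follow the EC sample counts.
_GROUP_TABLE = [
    ("Pedi", 851, 88.28, 10.61, 1.12, 33, (-24.5, 29.5)),
    ("Sotho", 46, 84.17, 14.65, 1.18, 26, (-29.0, 27.0)),
    ("Tswana", 73, 78.19, 20.49, 1.32, 24, (-26.0, 25.5)),
    ("Swazi", 30, 90.43, 8.69, 0.87, 28, (-26.0, 31.0)),
    ("Xhosa", 63, 80.24, 17.62, 2.14, 24, (-32.0, 27.5)),
    ("Zulu", 177, 84.64, 13.58, 1.78, 30, (-28.5, 31.0)),
    ("Tsonga", 1438, 97.80, 1.56, 0.65, 45, (-23.5, 31.0)),
    ("Venda", 24, 91.31, 6.45, 2.24, 45, (-22.9, 30.5)),
]

# Qualitative sampling-site composition (Agincourt, Dikgale, Soweto): Tsonga
# dominates Agincourt, Pedi dominates Dikgale, the remaining groups are
# recruited mostly in urban Soweto.
_SITE_FRACTIONS = {
    "Pedi": (0.10, 0.75, 0.15),
    "Sotho": (0.10, 0.10, 0.80),
    "Tswana": (0.05, 0.15, 0.80),
    "Swazi": (0.55, 0.05, 0.40),
    "Xhosa": (0.05, 0.05, 0.90),
    "Zulu": (0.10, 0.02, 0.88),
    "Tsonga": (0.88, 0.05, 0.07),
    "Venda": (0.30, 0.30, 0.40),
}

# Sex-biased contributions: Khoe-San gene flow is female-biased, Eurasian
# gene flow male-biased; the Bantu-related component absorbs the remainder so
# that s_f and s_m stay on the simplex with (s_f + s_m)/2 = q.
_KS_FEMALE_FACTOR = 1.4
_EUR_FEMALE_FACTOR = 0.6

# Per-ancestry Balding-Nichols differentiation from the shared base frequency
# (Bantu-related close to the base; Khoe-San and Eurasian more diverged, so
# pairwise ancestral F_ST ~ 0.10 (BS-KS) and ~ 0.15 (BS-EUR)).
DEFAULT_F_ANC = (0.02, 0.08, 0.13)


def _sex_split(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s_f = q.copy()
    s_f[1] = _KS_FEMALE_FACTOR * q[1]
    s_f[2] = _EUR_FEMALE_FACTOR * q[2]
    s_f[0] = 1.0 - s_f[1] - s_f[2]
    s_m = 2.0 * q - s_f
    return s_f, s_m


def default_groups(n_scale: float = 1.0, drift: float = 0.003) -> list[GroupSpec]:
    """The eight-group cohort preset at ``n_scale`` times the EC sample sizes."""
    groups = []
    for name, n, bs, ks, eur, g, geo in _GROUP_TABLE:
        q = np.array([bs, ks, eur], dtype=float)
        q /= q.sum()
        s_f, s_m = _sex_split(q)
        groups.append(
            GroupSpec(
                name=name,
                n=max(2, int(round(n * n_scale))),
                q=q,
                s_f=s_f,
                s_m=s_m,
                drift=drift,
                g=g,
                geo=geo,
                site_fractions=np.array(_SITE_FRACTIONS[name]),
            )
        )
    return groups


def default_chromosomes(
    n_autosomes: int = 4,
    autosome_bp: int = 100_000_000,
    include_x: bool = True,
    x_bp: int = 150_000_000,
) -> list[Chromosome]:
    """A compact genome: equal autosomes at 1 cM/Mb plus an X chromosome."""
    chroms = [
        Chromosome(str(i + 1), autosome_bp, autosome_bp / 1e8)
        for i in range(n_autosomes)
    ]
    if include_x:
        chroms.append(Chromosome("X", x_bp, x_bp / 1e8, is_x=True))
    return chroms


def default_config(
    n_scale: float = 0.05, L: int = 5000, seed: int = 0, **overrides
) -> SimConfig:
    """Cohort-preset configuration at a desk-friendly scale."""
    cfg = dict(
        groups=default_groups(n_scale=n_scale),
        chroms=default_chromosomes(),
        L=L,
        F_anc=DEFAULT_F_ANC,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
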