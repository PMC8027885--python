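"""Ancestry proportions and ancestry-based statistics.

Covers supervised ancestry-proportion estimation (binomial admixture
likelihood, per-individual EM on the simplex), the X-vs-autosome admixture
difference ratio (delta-admix) with its bootstrap, inversion of sex-specific
contribution fractions, the population branch statistic (PBS), the
local-ancestry enrichment scan, and group allele-frequency fold-change
scanning.

Sign convention for delta-admix: the X chromosome spends two thirds of its
history in females, so an ancestry contributed preferentially by women is
over-represented on X relative to the autosomes.  delta_admix_k =
(mean Q_X,k - mean Q_A,k) / mean Q_A,k is therefore positive for
female-biased contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ModelViolationError, ParameterError
from .simpop import MISSING, AncestralFrequencies, LocalAncestryMatrix

__all__ = [
    "AdmixtureProportions",
    "DeltaAdmixResult",
    "EnrichmentRegion",
    "PBSResult",
    "estimate_ancestry_supervised",
    "delta_admix",
    "bootstrap_delta_admix",
    "wilcoxon_rank_sum",
    "compare_ancestry_by_site",
    "invert_sex_contributions",
    "pbs_scores",
    "khoesan_enrichment_scan",
    "allele_frequency_scan",
    "regions_to_bed",
]


@dataclass
class AdmixtureProportions:
    """Per-sample ancestry proportions (rows on the simplex)."""

    Q: np.ndarray  # n x K
    scope: str  # "autosomal" | "X"
    ancestries: Sequence[str] | None = None
    converged: np.ndarray | None = None  # per-sample flag from the estimator

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2:
            raise ParameterError("Q must be an n x K matrix")
        if np.any(self.Q < -1e-9) or np.any(np.abs(self.Q.sum(axis=1) - 1) > 1e-6):
            raise ParameterError("rows of Q must lie on the simplex")
        if self.scope not in ("autosomal", "X"):
            raise ParameterError("scope must be 'autosomal' or 'X'")


@dataclass
class DeltaAdmixResult:
    ancestries: list[str]
    point: np.ndarray  # per-ancestry point estimate (NaN where undefined)
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    subsample: int


@dataclass
class EnrichmentRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    mean_dosage: float
    z: float


@dataclass
class PBSResult:
    """Per-variant branch lengths T = -log(1 - F_ST) and PBS for population A."""

    fst_ab: np.ndarray
    fst_ac: np.ndarray
    fst_bc: np.ndarray
    t_ab: np.ndarray
    t_ac: np.ndarray
    t_bc: np.ndarray
    pbs: np.ndarray
    valid: np.ndarray  # False where any F_ST = 1 made T infinite


# ---------------------------------------------------------------------------
# supervised ancestry estimation


def estimate_ancestry_supervised(
    G: np.ndarray,
    anc: AncestralFrequencies,
    ploidy: int | np.ndarray = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    scope: str = "autosomal",
) -> AdmixtureProportions:
    """Per-individual maximum-likelihood ancestry proportions by EM.

    Model: dosage g_l ~ Binomial(ploidy, x_l) with x_l = sum_k q_k f_kl and
    known ancestral frequencies f.  The EM update multiplies q_k by the
    average posterior responsibility of ancestry k over allele draws; the
    log-likelihood is non-decreasing in every iteration.  Missing genotypes
    are ignored.  Non-converged samples keep their last iterate and are
    flagged.
    """
    G = np.asarray(G)
    n, L = G.shape
    F = anc.freq
    K = F.shape[0]
    if F.shape[1] != L:
        raise DataError("frequency matrix does not match the genotype matrix")
    if np.any(F <= 0) or np.any(F >= 1):
        raise ParameterError("ancestral frequencies must lie strictly in (0, 1)")
    pl = np.broadcast_to(np.asarray(ploidy, dtype=float), (n,)).copy()
    if K == 1:
        return AdmixtureProportions(
            Q=np.ones((n, 1)),
            scope=scope,
            ancestries=list(anc.ancestries) if anc.ancestries else None,
            converged=np.ones(n, dtype=bool),
        )
    w = (G != MISSING).astype(float)
    g = np.where(G == MISSING, 0, G).astype(float)
    wg = w * g  # alt-allele counts among called draws
    wgc = pl[:, None] * w - g  # reference-allele counts among called draws
    denom = pl * w.sum(axis=1)
    if np.any(denom == 0):
        raise DataError("every sample needs at least one called genotype")
    FT = np.ascontiguousarray(F.T)
    FcT = np.ascontiguousarray((1.0 - F).T)

    def em_step(Q, wg, wgc, denom):
        x = Q @ F
        np.clip(x, 1e-12, 1 - 1e-12, out=x)
        A = (wg / x) @ FT
        B = (wgc / (1.0 - x)) @ FcT
        Qn = Q * (A + B) / denom[:, None]
        Qn /= Qn.sum(axis=1, keepdims=True)
        return Qn

    def loglik(Q, wg, wgc):
        x = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        return (wg * np.log(x)).sum(axis=1) + (wgc * np.log1p(-x)).sum(axis=1)

    # SQUAREM-accelerated EM: each cycle takes three EM steps, forms the
    # extrapolated iterate, and falls back to the plain EM result whenever
    # the extrapolation would decrease the log-likelihood — so the
    # monotonicity guarantee of EM is preserved.  Convergence is judged on
    # the plain EM-step change, matching the un-accelerated definition.
    Q_full = np.full((n, K), 1.0 / K)
    converged_full = np.zeros(n, dtype=bool)
    active = np.arange(n)
    Q = Q_full.copy()
    steps = 0
    while steps < max_iter and len(active):
        Q1 = em_step(Q, wg, wgc, denom[active])
        delta = np.abs(Q1 - Q).max(axis=1)
        done = delta < tol
        Q2 = em_step(Q1, wg, wgc, denom[active])
        steps += 3
        r = Q1 - Q
        v = (Q2 - Q1) - r
        vnorm = np.sqrt((v * v).sum(axis=1))
        alpha = np.where(
            vnorm > 0, -np.sqrt((r * r).sum(axis=1)) / np.where(vnorm > 0, vnorm, 1), -1.0
        )
        alpha = np.minimum(alpha, -1.0)
        Qs = Q - 2 * alpha[:, None] * r + (alpha**2)[:, None] * v
        np.clip(Qs, 1e-9, None, out=Qs)
        Qs /= Qs.sum(axis=1, keepdims=True)
        Qs = em_step(Qs, wg, wgc, denom[active])  # stabilizing EM step
        worse = loglik(Qs, wg, wgc) < loglik(Q2, wg, wgc) - 1e-9
        Qs[worse] = Q2[worse]
        Q = Qs
        if done.any():
            idx = active[done]
            Q_full[idx] = Q[done]
            converged_full[idx] = True
            keep = ~done
            active = active[keep]
            Q = Q[keep]
            wg = wg[keep]
            wgc = wgc[keep]
    if len(active):
        Q_full[active] = Q
    Q, converged = Q_full, converged_full
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} samples did not converge within "
            f"{max_iter} EM iterations",
            stacklevel=2,
        )
    return AdmixtureProportions(
        Q=Q,
        scope=scope,
        ancestries=list(anc.ancestries) if anc.ancestries else None,
        converged=converged,
    )


def admixture_loglik(Q, F, G, ploidy=2) -> np.ndarray:
    """Binomial admixture log-likelihood per sample (without the binomial
    coefficient, which does not depend on Q)."""
    G = np.asarray(G)
    n = G.shape[0]
    pl = np.broadcast_to(np.asarray(ploidy, dtype=float), (n,))
    w = (G != MISSING).astype(float)
    g = np.where(G == MISSING, 0, G).astype(float)
    x = np.clip(np.asarray(Q) @ F, 1e-12, 1 - 1e-12)
    return (w * (g * np.log(x) + (pl[:, None] * w - g) * np.log1p(-x))).sum(axis=1)


# ---------------------------------------------------------------------------
# delta-admix


def delta_admix(
    Q_auto: AdmixtureProportions,
    Q_X: AdmixtureProportions,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-ancestry admixture-difference ratio (X - autosome) / autosome.

    Uses group means over ``subset`` (all samples when None).  Positive
    values indicate female-biased contribution of that ancestry; an ancestry
    with zero autosomal mean is reported as NaN.
    """
    QA, QX = Q_auto.Q, Q_X.Q
    if QA.shape != QX.shape:
        raise DataError("autosomal and X proportion matrices must align")
    if subset is not None:
        QA, QX = QA[subset], QX[subset]
    if QA.shape[0] == 0:
        raise DataError("empty sample subset")
    mA = QA.mean(axis=0)
    mX = QX.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (mX - mA) / mA
    return np.where(mA > 0, out, np.nan)


def bootstrap_delta_admix(
    Q_auto: AdmixtureProportions,
    Q_X: AdmixtureProportions,
    group_index: np.ndarray,
    n_boot: int = 50,
    subsample: int = 20,
    seed: int | None = None,
) -> DeltaAdmixResult:
    """Delta-admix with bootstrap SE from without-replacement subsamples.

    Defaults mirror the published design: 50 bootstrap iterations of 20
    samples each; the SE is the standard deviation of the resampled
    estimates and the CI the 2.5/97.5 percentile interval.
    """
    idx = np.asarray(group_index)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if subsample > len(idx):
        raise ParameterError("subsample exceeds the group size")
    point = delta_admix(Q_auto, Q_X, idx)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, Q_auto.Q.shape[1]))
    for b in range(n_boot):
        sub = rng.choice(idx, size=subsample, replace=False)
        reps[b] = delta_admix(Q_auto, Q_X, sub)
    ancestries = list(Q_auto.ancestries) if Q_auto.ancestries else [
        f"anc{k}" for k in range(Q_auto.Q.shape[1])
    ]
    return DeltaAdmixResult(
        ancestries=ancestries,
        point=point,
        se=np.nanstd(reps, axis=0, ddof=1),
        ci_low=np.nanpercentile(reps, 2.5, axis=0),
        ci_high=np.nanpercentile(reps, 97.5, axis=0),
        n_boot=n_boot,
        subsample=subsample,
    )


def invert_sex_contributions(H_A: float, H_X: float) -> tuple[float, float]:
    """Solve the single-pulse system for (s_f, s_m).

    H_A = (s_f + s_m)/2 and H_X = (2 s_f + s_m)/3 give s_f = 3 H_X - 2 H_A
    and s_m = 4 H_A - 3 H_X.  Solutions outside [-0.02, 1.02] indicate the
    observations are incompatible with the single-pulse model; values inside
    are clipped to [0, 1].
    """
    if not (0.0 <= H_A <= 1.0 and 0.0 <= H_X <= 1.0):
        raise ParameterError("H_A and H_X must lie in [0, 1]")
    s_f = 3.0 * H_X - 2.0 * H_A
    s_m = 4.0 * H_A - 3.0 * H_X
    for name, val in (("s_f", s_f), ("s_m", s_m)):
        if not (-0.02 <= val <= 1.02):
            raise ModelViolationError(
                f"{name} = {val:.4f} outside [-0.02, 1.02]; observed (H_A, H_X) "
                "are incompatible with a single admixture pulse"
            )
    return float(np.clip(s_f, 0.0, 1.0)), float(np.clip(s_m, 0.0, 1.0))


# ---------------------------------------------------------------------------
# rank and location tests


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (midranks, tie-corrected normal
    approximation with continuity correction).

    Returns (W, p) where W is the rank sum of the first sample.  When every
    value in both samples is identical the test carries no information and
    p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both samples must be non-empty")
    n = len(x)
    W = float(stats.rankdata(np.concatenate([x, y]))[:n].sum())
    if np.all(np.concatenate([x, y]) == x[0]):
        return W, 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return W, float(res.pvalue)


def compare_ancestry_by_site(
    Q: AdmixtureProportions,
    metadata: pd.DataFrame,
    group: str,
    ancestry_index: int = 1,
    min_per_site: int = 2,
) -> pd.DataFrame:
    """Welch t-tests of one ancestry proportion between site pairs of a group.

    Returns a frame with site_a, site_b, n_a, n_b, t, df, p; site pairs where
    either site has fewer than ``min_per_site`` samples of the group are
    skipped.
    """
    sel = metadata["group"] == group
    if not sel.any():
        raise DataError(f"group {group!r} not present")
    q = Q.Q[np.asarray(sel), ancestry_index]
    sites = metadata.loc[sel, "site"].to_numpy()
    rows = []
    names = sorted(pd.unique(sites))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            qa = q[sites == names[i]]
            qb = q[sites == names[j]]
            if len(qa) < min_per_site or len(qb) < min_per_site:
                continue
            t, p = stats.ttest_ind(qa, qb, equal_var=False)
            va, vb = qa.var(ddof=1), qb.var(ddof=1)
            if va + vb == 0:
                df = float(len(qa) + len(qb) - 2)
            else:
                df = (va / len(qa) + vb / len(qb)) ** 2 / (
                    (va / len(qa)) ** 2 / (len(qa) - 1)
                    + (vb / len(qb)) ** 2 / (len(qb) - 1)
                )
            rows.append(
                {
                    "site_a": names[i],
                    "site_b": names[j],
                    "n_a": len(qa),
                    "n_b": len(qb),
                    "t": float(t),
                    "df": float(df),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows, columns=["site_a", "site_b", "n_a", "n_b", "t", "df", "p"])


# ---------------------------------------------------------------------------
# PBS


def pbs_scores(fst_ab, fst_ac, fst_bc) -> PBSResult:
    """Population branch statistic for focal population A.

    T_xy = -log(1 - max(F_xy, 0)); PBS_A = (T_AB + T_AC - T_BC) / 2.
    Negative F_ST estimates are floored at 0 before the log; F_ST = 1 gives
    an infinite branch and the variant is flagged invalid (excluded from
    ranking, PBS reported as NaN).
    """
    ab = np.atleast_1d(np.asarray(fst_ab, dtype=float))
    ac = np.atleast_1d(np.asarray(fst_ac, dtype=float))
    bc = np.atleast_1d(np.asarray(fst_bc, dtype=float))
    if not (ab.shape == ac.shape == bc.shape):
        raise DataError("the three F_ST vectors must align")

    def branch(f):
        f = np.maximum(f, 0.0)
        with np.errstate(divide="ignore"):
            return -np.log1p(-f)

    t_ab, t_ac, t_bc = branch(ab), branch(ac), branch(bc)
    valid = np.isfinite(t_ab) & np.isfinite(t_ac) & np.isfinite(t_bc)
    pbs = np.where(valid, (t_ab + t_ac - t_bc) / 2.0, np.nan)
    return PBSResult(
        fst_ab=ab, fst_ac=ac, fst_bc=bc,
        t_ab=t_ab, t_ac=t_ac, t_bc=t_bc, pbs=pbs, valid=valid,
    )


# ---------------------------------------------------------------------------
# local-ancestry enrichment scan


def khoesan_enrichment_scan(
    la: LocalAncestryMatrix,
    ancestry_index: int,
    posterior_min: float = 0.8,
    sd_mult: float = 3.0,
    min_snps: int = 3,
    excl_bp: int = 2_000_000,
    tail: str = "high",
) -> list[EnrichmentRegion]:
    """Scan for regions of unusually high (or low) local-ancestry dosage.

    Haplotype-variant calls with posterior <= ``posterior_min`` are dropped;
    variants within ``excl_bp`` of a chromosome end or the centromere are
    excluded; per-variant mean dosage of ``ancestry_index`` is compared to
    the genome-wide mean and SD; runs of >= ``min_snps`` consecutive
    variants beyond mean + sd_mult*SD (``tail="high"``, the default
    candidate definition) or beyond either bound (``tail="both"``) are
    merged into candidate regions.
    """
    if la.variants is None or la.variants.chromosomes is None:
        raise DataError("local-ancestry matrix needs an annotated variant map")
    if tail not in ("high", "both"):
        raise ParameterError("tail must be 'high' or 'both'")
    v = la.variants
    keep = np.ones(len(v), dtype=bool)
    for c in v.chromosomes:
        sel = v.chrom == c.name
        pos = v.pos
        near_telomere = (pos <= excl_bp) | (pos >= c.length_bp - excl_bp)
        cen_lo, cen_hi = c.centromere
        near_centromere = (pos >= cen_lo - excl_bp) & (pos <= cen_hi + excl_bp)
        keep &= ~(sel & (near_telomere | near_centromere))
    dosage = la.dosage(ancestry_index, posterior_min=posterior_min)
    keep &= np.isfinite(dosage)
    if not keep.any():
        raise DataError("no variants retained after posterior/region filters")
    mu = float(dosage[keep].mean())
    sd = float(dosage[keep].std(ddof=0))
    hi = dosage > mu + sd_mult * sd
    lo = dosage < mu - sd_mult * sd
    flag = keep & (hi | lo if tail == "both" else hi)
    regions: list[EnrichmentRegion] = []
    idx = np.flatnonzero(flag)
    if len(idx) == 0:
        return regions
    # merge runs of consecutive retained flagged variants per chromosome
    kept_idx = np.flatnonzero(keep)
    rank = {j: r for r, j in enumerate(kept_idx)}
    run: list[int] = []
    for j in idx:
        if run and (v.chrom[j] != v.chrom[run[-1]] or rank[j] != rank[run[-1]] + 1):
            _flush_run(run, v, dosage, mu, sd, min_snps, regions)
            run = []
        run.append(int(j))
    _flush_run(run, v, dosage, mu, sd, min_snps, regions)
    return regions


def _flush_run(run, v, dosage, mu, sd, min_snps, regions):
    if len(run) >= min_snps:
        mean_d = float(np.mean(dosage[run]))
        regions.append(
            EnrichmentRegion(
                chrom=str(v.chrom[run[0]]),
                start_bp=int(v.pos[run[0]]),
                end_bp=int(v.pos[run[-1]]),
                n_snps=len(run),
                mean_dosage=mean_d,
                z=float((mean_d - mu) / sd) if sd > 0 else np.inf,
            )
        )


def regions_to_bed(regions: list[EnrichmentRegion]) -> str:
    """BED (0-based half-open) text for a list of enrichment regions."""
    lines = [
        f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
        f"n_snps={r.n_snps};mean={r.mean_dosage:.4f};z={r.z:.2f}"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# allele-frequency fold-change scan


def allele_frequency_scan(
    G: np.ndarray,
    labels: np.ndarray,
    fold_min: float = 3.0,
    n_boot: int = 50,
    subsample: int = 30,
    seed: int | None = None,
    variants=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank variants by between-group alternate-allele frequency fold change.

    For every variant and group pair, fold = max(f_i/f_j, f_j/f_i).  Variants
    where either frequency is exactly 0 cannot be ranked by a finite fold and
    are reported separately.  Bootstrap SEs of each frequency come from
    ``n_boot`` without-replacement subsamples of ``subsample`` individuals
    (the published 50 x 30 design).  Groups smaller than ``subsample`` are
    dropped with a warning.  Returns (ranked_table, unbounded_table).
    """
    G = np.asarray(G)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    groups = [g for g in dict.fromkeys(labels.tolist())]
    kept_groups = []
    for g in groups:
        if (labels == g).sum() >= subsample:
            kept_groups.append(g)
        else:
            warnings.warn(
                f"group {g!r} smaller than the bootstrap subsample; dropped",
                stacklevel=2,
            )
    if len(kept_groups) < 2:
        raise DataError("need at least two groups of sufficient size")
    freqs, ses = {}, {}
    for g in kept_groups:
        rows = np.flatnonzero(labels == g)
        freqs[g] = _alt_freq(G[rows])
        boots = np.empty((n_boot, G.shape[1]))
        for b in range(n_boot):
            sub = rng.choice(rows, size=subsample, replace=False)
            boots[b] = _alt_freq(G[sub])
        ses[g] = boots.std(axis=0, ddof=1)
    ranked, unbounded = [], []
    for i in range(len(kept_groups)):
        for j in range(i + 1, len(kept_groups)):
            ga, gb = kept_groups[i], kept_groups[j]
            fa, fb = freqs[ga], freqs[gb]
            zero = (fa == 0) | (fb == 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = np.maximum(fa / fb, fb / fa)
            for l in np.flatnonzero(zero & (fa != fb)):
                unbounded.append(_scan_row(l, ga, gb, fa, fb, ses, np.inf, variants))
            sel = (~zero) & (fold >= fold_min)
            for l in np.flatnonzero(sel):
                ranked.append(_scan_row(l, ga, gb, fa, fb, ses, float(fold[l]), variants))
    cols = [
        "variant", "chrom", "pos", "group_a", "group_b",
        "freq_a", "freq_b", "se_a", "se_b", "fold",
    ]
    ranked_df = pd.DataFrame(ranked, columns=cols)
    if len(ranked_df):
        ranked_df = ranked_df.sort_values("fold", ascending=False).reset_index(drop=True)
    return ranked_df, pd.DataFrame(unbounded, columns=cols)


def _alt_freq(G_rows: np.ndarray) -> np.ndarray:
    obs = G_rows != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(
            obs.sum(0) > 0,
            np.where(obs, G_rows, 0).sum(0) / (2.0 * obs.sum(0)),
            np.nan,
        )


def _scan_row(l, ga, gb, fa, fb, ses, fold, variants):
    return {
        "variant": int(l),
        "chrom": str(variants.chrom[l]) if variants is not None else ".",
        "pos": int(variants.pos[l]) if variants is not None else -1,
        "group_a": ga,
        "group_b": gb,
        "freq_a": float(fa[l]),
        "freq_b": float(fb[l]),
        "se_a": float(ses[ga][l]),
        "se_b": float(ses[gb][l]),
        "fold": fold,
    }
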