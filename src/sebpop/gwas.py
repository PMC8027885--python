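"""Simulated-trait case-control GWAS framework.

The point of this module is to quantify how fine-scale population structure
inflates association statistics when case-control labels are confounded with
sampling site or ethno-linguistic group.  It provides variant QC, the four
label-assignment schemes (site-vs-site, mixed-site cases, within-site group
exclusion, and fully random labels), allelic chi-square and logistic
association tests, the genomic inflation factor lambda, genomic-control and
PC-covariate correction, significance tallies and a multi-iteration driver.

The logistic solver is a variant-batched iteratively reweighted least
squares (IRLS) Newton fit with a Wald test on the genotype coefficient.
Variants whose plain ML fit does not converge — which happens for *every*
variant when the PC covariates separate cases from controls completely, as
clean two-group simulations produce — fall back to Firth bias-reduced
logistic regression, whose penalized estimates always exist; this mirrors
the Firth fallback of contemporary GWAS tools.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .simpop import MISSING, GenotypeDataset
from .structure import genotype_pca, ld_prune

__all__ = [
    "TraitAssignment",
    "AssocTable",
    "InflationReport",
    "GWAS_SIGNIFICANCE",
    "SUGGESTIVE_METHODS",
    "SUGGESTIVE_RESULTS",
    "qc_filter",
    "hwe_test",
    "assign_trait_labels",
    "assoc_test",
    "genomic_inflation",
    "gc_correct",
    "pc_corrected_assoc",
    "tally_significant",
    "run_gwas_suite",
    "qq_data",
]

GWAS_SIGNIFICANCE = 5e-8
SUGGESTIVE_METHODS = 1e-5  # threshold named in the study's methods
SUGGESTIVE_RESULTS = 5e-5  # threshold named in the study's results text

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class TraitAssignment:
    case_ids: np.ndarray
    control_ids: np.ndarray
    scheme: str
    params: dict
    seed: int | None

    def __post_init__(self):
        overlap = np.intersect1d(self.case_ids, self.control_ids)
        if len(overlap):
            raise DataError("case and control sets must be disjoint")


@dataclass
class AssocTable:
    """Per-variant association results.

    ``stat`` is the 1-df chi-square (allelic) or squared Wald z (logistic);
    ``beta`` the log-odds effect (NaN for the allelic test); ``valid`` is
    False where the fit failed or the statistic is undefined.
    """

    chrom: np.ndarray
    pos: np.ndarray
    stat: np.ndarray
    df: int
    p: np.ndarray
    beta: np.ndarray
    valid: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "CHR": self.chrom,
                "POS": self.pos,
                "STAT": self.stat,
                "DF": self.df,
                "P": self.p,
                "BETA": self.beta,
                "VALID": self.valid,
            }
        )


@dataclass
class InflationReport:
    scenario: str
    iteration: int
    seed: int
    lambda_raw: float
    lambda_gc: float
    lambda_pc: float
    counts_raw: dict
    counts_gc: dict
    counts_pc: dict


# ---------------------------------------------------------------------------
# QC


def hwe_test(G: np.ndarray) -> np.ndarray:
    """Per-variant Hardy-Weinberg chi-square (1 df) p-value on genotype counts."""
    G = np.asarray(G)
    n0 = (G == 0).sum(axis=0).astype(float)
    n1 = (G == 1).sum(axis=0).astype(float)
    n2 = (G == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = np.zeros_like(n)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
            chi2 += term
    pval = stats.chi2.sf(chi2, 1)
    return np.where((n > 0) & (p > 0) & (q > 0), pval, 1.0)


def qc_filter(
    G: np.ndarray,
    miss_max: float = 0.05,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
) -> np.ndarray:
    """Variant mask after missingness, MAF and HWE filters (QC defaults)."""
    G = np.asarray(G)
    n = G.shape[0]
    obs = G != MISSING
    missingness = 1.0 - obs.sum(axis=0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(obs.sum(0) > 0, np.where(obs, G, 0).sum(0) / (2.0 * obs.sum(0)), 0.0)
    maf = np.minimum(f, 1 - f)
    keep = (missingness <= miss_max) & (maf >= maf_min) & (hwe_test(G) >= hwe_p_min)
    if not keep.any():
        raise DataError("all variants removed by QC")
    return keep


# ---------------------------------------------------------------------------
# trait assignment


def assign_trait_labels(
    metadata: pd.DataFrame, scheme: str, params: dict, seed: int | None = None
) -> TraitAssignment:
    """Assign artificial case/control labels under one of four schemes.

    category1: cases from one site, controls from another (site-confounded).
    category2: cases a stated mixture of two sites, controls from one site.
    category3: cases and controls from one site, one group absent in cases.
    category4: random labels within one site (null design).
    """
    rng = np.random.default_rng(seed)
    ids = metadata["id"].to_numpy()
    site = metadata["site"].to_numpy()
    group = metadata["group"].to_numpy()

    def draw(pool, k):
        if len(pool) < k:
            raise DataError(
                f"scheme {scheme}: requested {k} samples, only {len(pool)} eligible"
            )
        return rng.choice(pool, size=k, replace=False)

    if scheme == "category1":
        n = params.get("n", 800)
        cases = draw(ids[site == params["site_case"]], n)
        controls = draw(ids[site == params["site_control"]], n)
    elif scheme == "category2":
        n = params.get("n", 800)
        frac = params["mix_fraction"]  # fraction of cases from the second site
        site_main, site_mix = params["site_control"], params["site_mix"]
        n_mix = int(round(frac * n))
        cases_mix = draw(ids[site == site_mix], n_mix)
        main_pool = ids[site == site_main]
        cases_main = draw(main_pool, n - n_mix)
        remaining = np.setdiff1d(main_pool, cases_main)
        controls = draw(remaining, n)
        cases = np.concatenate([cases_mix, cases_main])
    elif scheme == "category3":
        n = params.get("n", 500)
        s = params["site"]
        excluded = params["excluded_group"]
        case_pool = ids[(site == s) & (group != excluded)]
        cases = draw(case_pool, n)
        control_pool = np.setdiff1d(ids[site == s], cases)
        controls = draw(control_pool, n)
    elif scheme == "category4":
        s = params["site"]
        n_case = params.get("n_case", 400)
        n_control = params.get("n_control", 400)
        pool = ids[site == s]
        both = draw(pool, n_case + n_control)
        cases, controls = both[:n_case], both[n_case:]
    else:
        raise ParameterError(f"unknown scheme {scheme!r}")
    return TraitAssignment(
        case_ids=np.sort(cases),
        control_ids=np.sort(controls),
        scheme=scheme,
        params=dict(params),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# association tests


def _subset(dataset: GenotypeDataset, assignment: TraitAssignment):
    index = pd.Index(dataset.samples["id"])
    rows = index.get_indexer(np.concatenate([assignment.case_ids, assignment.control_ids]))
    if np.any(rows < 0):
        raise DataError("assignment references samples absent from the dataset")
    y = np.zeros(len(rows))
    y[: len(assignment.case_ids)] = 1.0
    return rows, y


def allelic_chi2(G: np.ndarray, y: np.ndarray):
    """2x2 allele-count chi-square (1 df) per variant, missing excluded."""
    G = np.asarray(G)
    obs = G != MISSING
    gv = np.where(obs, G, 0).astype(float)
    case = y == 1
    a_alt = gv[case].sum(axis=0)  # alt alleles in cases
    a_tot = 2.0 * obs[case].sum(axis=0)
    b_alt = gv[~case].sum(axis=0)
    b_tot = 2.0 * obs[~case].sum(axis=0)
    a_ref, b_ref = a_tot - a_alt, b_tot - b_alt
    N = a_tot + b_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        det = a_alt * b_ref - a_ref * b_alt
        denom = a_tot * b_tot * (a_alt + b_alt) * (a_ref + b_ref)
        chi2 = np.where(denom > 0, N * det**2 / np.where(denom > 0, denom, 1), np.nan)
    valid = denom > 0
    return chi2, valid


def _sigmoid(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -40.0, 40.0)))


def _batched_irls(C, g, y, max_iter=25, tol=1e-8):
    """Plain Newton/IRLS logistic over many variants sharing covariates C.

    Model per variant l: logit P(y=1) = C @ beta_c[l] + g[:, l] * beta_g[l].
    Returns (beta_g, se_g, converged).
    """
    n, pc = C.shape
    L = g.shape[1]
    p = pc + 1
    beta = np.zeros((L, p))
    converged = np.zeros(L, dtype=bool)
    active = np.ones(L, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        b = beta[idx]
        ga = g[:, idx]
        eta = C @ b[:, :pc].T + ga * b[:, pc]
        mu = _sigmoid(eta)
        W = mu * (1.0 - mu)
        resid = y[:, None] - mu
        score = np.empty((len(idx), p))
        score[:, :pc] = resid.T @ C
        score[:, pc] = (resid * ga).sum(axis=0)
        H = _hessian_blocks(C, ga, W)
        try:
            step = np.linalg.solve(H, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            jitter = H + 1e-8 * np.eye(p)[None]
            step = np.linalg.solve(jitter, score[..., None])[..., 0]
        b_new = b + step
        done = np.abs(step).max(axis=1) < tol
        beta[idx] = b_new
        converged[idx[done]] = True
        active[idx[done]] = False
        # treat exploding coefficients as non-convergence and stop updating
        blown = np.abs(b_new).max(axis=1) > 80
        active[idx[blown]] = False
    se = _wald_se(C, g, y, beta)
    return beta[:, -1], se, converged


def _hessian_blocks(C, ga, W):
    """Per-variant (p x p) Hessians X^T W X with shared covariate block."""
    n, pc = C.shape
    L = ga.shape[1]
    p = pc + 1
    H = np.empty((L, p, p))
    H[:, :pc, :pc] = np.einsum("ni,nl,nj->lij", C, W, C, optimize=True)
    cross = np.einsum("ni,nl->li", C, W * ga, optimize=True)
    H[:, :pc, pc] = cross
    H[:, pc, :pc] = cross
    H[:, pc, pc] = (W * ga * ga).sum(axis=0)
    return H


def _wald_se(C, g, y, beta):
    n, pc = C.shape
    p = pc + 1
    eta = C @ beta[:, :pc].T + g * beta[:, pc]
    mu = _sigmoid(eta)
    W = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = _hessian_blocks(C, g, W)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(H + 1e-8 * np.eye(p)[None])
    return np.sqrt(np.maximum(cov[:, p - 1, p - 1], 0.0))


def _batched_firth(C, g, y, max_iter=60, tol=1e-6):
    """Firth bias-reduced logistic over many variants sharing covariates.

    The penalized score adds h_i (1/2 - mu_i) to each observation, where h
    is the leverage of the weighted design; penalized estimates exist even
    under complete separation.
    """
    n, pc = C.shape
    L = g.shape[1]
    p = pc + 1
    beta = np.zeros((L, p))
    converged = np.zeros(L, dtype=bool)
    for _ in range(max_iter):
        eta = C @ beta[:, :pc].T + g * beta[:, pc]
        mu = _sigmoid(eta)
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = _hessian_blocks(C, g, W)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.inv(H + 1e-8 * np.eye(p)[None])
        # leverages h[n, l] = W * x_i' Hinv x_i with x_i = [C_i, g_il]
        t_cc = np.einsum("ni,lij,nj->nl", C, Hinv[:, :pc, :pc], C, optimize=True)
        t_cg = C @ Hinv[:, :pc, pc].T  # (n, L)
        t_gg = Hinv[:, pc, pc][None, :]
        h = W * (t_cc + 2.0 * g * t_cg + g * g * t_gg)
        adj = y[:, None] - mu + h * (0.5 - mu)
        score = np.empty((L, p))
        score[:, :pc] = adj.T @ C
        score[:, pc] = (adj * g).sum(axis=0)
        step = np.einsum("lij,lj->li", Hinv, score)
        np.clip(step, -5.0, 5.0, out=step)
        beta += step
        done = np.abs(step).max(axis=1) < tol
        if done.all():
            converged[:] = True
            break
    else:
        converged = np.abs(step).max(axis=1) < tol
    se = _wald_se(C, g, y, beta)
    return beta[:, -1], se, converged


def assoc_test(
    dataset: GenotypeDataset,
    assignment: TraitAssignment,
    covariates: np.ndarray | None = None,
    method: str = "allelic",
    maf_min: float = 0.05,
    firth_fallback: bool = True,
) -> AssocTable:
    """Case-control association test per variant.

    ``method="allelic"``: 2x2 allele-count chi-square (1 df) — the basic
    association test.  ``method="logistic"``: additive genotype coding,
    batched IRLS with optional covariates and a Wald chi-square on the
    genotype coefficient; variants whose ML fit fails fall back to Firth
    regression when ``firth_fallback`` is set, otherwise they are flagged
    invalid.  Variants below ``maf_min`` in the analysis samples are flagged
    invalid (the simulation suite restricts itself to common variants).
    """
    rows, y = _subset(dataset, assignment)
    G = dataset.G[rows]
    v = dataset.variants
    obs = G != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(obs.sum(0) > 0, np.where(obs, G, 0).sum(0) / (2.0 * obs.sum(0)), 0.0)
    maf_ok = np.minimum(f, 1 - f) >= maf_min
    beta = np.full(dataset.L, np.nan)
    stat = np.full(dataset.L, np.nan)
    if method == "allelic":
        chi2, valid = allelic_chi2(G, y)
        stat = chi2
        valid = valid & maf_ok
    elif method == "logistic":
        C = np.ones((len(rows), 1))
        if covariates is not None:
            C = np.column_stack([C, covariates])
        use = np.flatnonzero(maf_ok)
        bg = np.empty(len(use))
        se = np.empty(len(use))
        conv = np.zeros(len(use), dtype=bool)
        block_size = 2048  # bounds the (n x block) temporaries of the solver
        for lo in range(0, len(use), block_size):
            blk = use[lo : lo + block_size]
            gmat = np.where(obs[:, blk], G[:, blk], 0).astype(float)
            # mean-impute missing dosages so every variant keeps all samples
            if (~obs[:, blk]).any():
                means = gmat.sum(0) / obs[:, blk].sum(0)
                gmat = np.where(obs[:, blk], gmat, means[None, :])
            b_b, se_b, conv_b = _batched_irls(C, gmat, y)
            if firth_fallback and not conv_b.all():
                bad = np.flatnonzero(~conv_b)
                b_f, se_f, conv_f = _batched_firth(C, gmat[:, bad], y)
                b_b[bad], se_b[bad] = b_f, se_f
                conv_b[bad] = conv_f
            sl = slice(lo, lo + len(blk))
            bg[sl], se[sl], conv[sl] = b_b, se_b, conv_b
        ok = conv & (se > 0) & np.isfinite(se)
        z2 = np.full(len(use), np.nan)
        z2[ok] = (bg[ok] / se[ok]) ** 2
        stat[use] = z2
        beta[use] = np.where(ok, bg, np.nan)
        valid = np.zeros(dataset.L, dtype=bool)
        valid[use[ok]] = True
    else:
        raise ParameterError(f"unknown method {method!r}")
    p = np.full(dataset.L, np.nan)
    good = valid & np.isfinite(stat)
    p[good] = stats.chi2.sf(stat[good], 1)
    return AssocTable(
        chrom=v.chrom.copy(),
        pos=v.pos.copy(),
        stat=stat,
        df=1,
        p=p,
        beta=beta,
        valid=good,
        method=method,
    )


# ---------------------------------------------------------------------------
# inflation, correction, tallies


def genomic_inflation(table: AssocTable) -> float:
    """Genomic inflation factor: median 1-df chi-square over its null median."""
    p = table.p[table.valid]
    if len(p) == 0:
        raise DataError("no valid variants")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def gc_correct(table: AssocTable, lam: float | None = None) -> AssocTable:
    """Genomic-control correction: divide chi-squares by lambda when > 1."""
    if lam is None:
        lam = genomic_inflation(table)
    if lam <= 1.0:
        return table
    stat = table.stat / lam
    p = np.full_like(table.p, np.nan)
    p[table.valid] = stats.chi2.sf(stat[table.valid], 1)
    return replace(table, stat=stat, p=p)


def pc_corrected_assoc(
    dataset: GenotypeDataset,
    assignment: TraitAssignment,
    n_pcs: int = 3,
    seed: int | None = None,
    maf_min: float = 0.05,
    ld_kwargs: dict | None = None,
) -> AssocTable:
    """Logistic association with the leading PCs of the analysis samples.

    PCs are computed per analysis (cases + controls only) on the LD-pruned
    variant subset, then used as covariates; ``n_pcs=0`` degenerates to the
    plain logistic test.
    """
    if n_pcs == 0:
        return assoc_test(dataset, assignment, method="logistic", maf_min=maf_min)
    rows, y = _subset(dataset, assignment)
    G = dataset.G[rows]
    kw = dict(r2_threshold=0.5, window=50, step=5)
    if ld_kwargs:
        kw.update(ld_kwargs)
    kept = ld_prune(G, chrom=dataset.variants.chrom, **kw)
    pca = genotype_pca(G[:, kept], n_pcs=n_pcs)
    return assoc_test(
        dataset, assignment, covariates=pca.coords, method="logistic", maf_min=maf_min
    )


def tally_significant(
    table: AssocTable, thresholds: Sequence[float] = (GWAS_SIGNIFICANCE, SUGGESTIVE_METHODS)
) -> dict:
    """Count valid variants below each p-value threshold."""
    p = table.p[table.valid]
    return {float(t): int((p < t).sum()) for t in thresholds}


def qq_data(table: AssocTable) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(table.p[table.valid])
    m = len(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(np.clip(p, 1e-300, 1))}
    )


# ---------------------------------------------------------------------------
# multi-iteration driver


def run_gwas_suite(
    dataset: GenotypeDataset,
    scenarios: Sequence[dict],
    n_iter: int = 50,
    seed: int = 0,
    n_pcs: int = 3,
    maf_min: float = 0.05,
    thresholds: Sequence[float] = (GWAS_SIGNIFICANCE, SUGGESTIVE_METHODS),
    collect_qq: bool = False,
) -> tuple[list[InflationReport], pd.DataFrame, dict]:
    """Run the simulated-trait GWAS suite.

    For every scenario (dict with ``name``, ``scheme``, ``params``) and
    iteration: assign labels, run the raw allelic test on common variants,
    apply genomic control, run the PC-corrected logistic test, and record
    the lambda triple plus significance tallies.  Returns (reports, summary
    frame with per-scenario medians, qq curves keyed by scenario when
    requested).
    """
    ss = np.random.SeedSequence(seed)
    reports: list[InflationReport] = []
    qq: dict[str, pd.DataFrame] = {}
    for scen in scenarios:
        name = scen.get("name", scen["scheme"])
        child = np.random.SeedSequence((seed, zlib.crc32(name.encode()) & 0x7FFFFFFF))
        iter_seeds = child.generate_state(n_iter)
        for it in range(n_iter):
            it_seed = int(iter_seeds[it] & 0x7FFFFFFF)
            try:
                assignment = assign_trait_labels(
                    dataset.samples, scen["scheme"], scen["params"], seed=it_seed
                )
            except DataError as exc:
                reports.append(
                    InflationReport(
                        scenario=name, iteration=it, seed=it_seed,
                        lambda_raw=np.nan, lambda_gc=np.nan, lambda_pc=np.nan,
                        counts_raw={}, counts_gc={}, counts_pc={"skipped": str(exc)},
                    )
                )
                continue
            raw = assoc_test(dataset, assignment, method="allelic", maf_min=maf_min)
            lam_raw = genomic_inflation(raw)
            corrected = gc_correct(raw, lam_raw)
            lam_gc = genomic_inflation(corrected)
            pc_table = pc_corrected_assoc(
                dataset, assignment, n_pcs=n_pcs, maf_min=maf_min
            )
            lam_pc = genomic_inflation(pc_table)
            reports.append(
                InflationReport(
                    scenario=name,
                    iteration=it,
                    seed=it_seed,
                    lambda_raw=lam_raw,
                    lambda_gc=lam_gc,
                    lambda_pc=lam_pc,
                    counts_raw=tally_significant(raw, thresholds),
                    counts_gc=tally_significant(corrected, thresholds),
                    counts_pc=tally_significant(pc_table, thresholds),
                )
            )
            if collect_qq and it == 0:
                qq[name] = pd.concat(
                    {
                        "raw": qq_data(raw),
                        "gc": qq_data(corrected),
                        "pc": qq_data(pc_table),
                    },
                    names=["correction"],
                )
    frame = pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "lambda_raw": r.lambda_raw,
                "lambda_gc": r.lambda_gc,
                "lambda_pc": r.lambda_pc,
                **{
                    f"raw_p<{t:g}": c
                    for t, c in r.counts_raw.items()
                    if isinstance(t, float)
                },
                **{
                    f"pc_p<{t:g}": c
                    for t, c in r.counts_pc.items()
                    if isinstance(t, float)
                },
            }
            for r in reports
        ]
    )
    summary = (
        frame.groupby("scenario").median(numeric_only=True).reset_index()
        if len(frame)
        else frame
    )
    return reports, summary, qq
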