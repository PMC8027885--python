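"""Population-structure statistics and structure-vs-geography tests.

Implements the statistics used to characterize fine-scale structure in an
admixed cohort and its correlation with geography: window-based LD pruning,
genotype PCA, Weir & Cockerham (1984) F_ST variance components, UPGMA trees
on pairwise F_ST, Weiszfeld geometric medians, great-circle distances, and
Mantel / Procrustes permutation tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, ParameterError
from .simpop import MISSING

__all__ = [
    "GeoPoint",
    "DistanceMatrix",
    "PCAResult",
    "TreeNode",
    "MantelResult",
    "ProcrustesResult",
    "ld_prune",
    "genotype_pca",
    "weir_cockerham_fst",
    "pairwise_fst_matrix",
    "upgma_tree",
    "geometric_median",
    "great_circle_distance",
    "mantel_test",
    "procrustes_test",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A point on the globe in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ParameterError(f"invalid coordinates ({self.lat}, {self.lon})")


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal.

    F_ST entries may be negative (the estimator is unbiased, not bounded);
    the raw values are stored and :meth:`floored` clamps at zero for use as a
    distance.
    """

    labels: list[str]
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise DataError("distance matrix shape must match the label list")
        if np.nanmax(np.abs(self.D - self.D.T)) > 1e-12:
            raise DataError("distance matrix must be symmetric")
        np.fill_diagonal(self.D, 0.0)

    def floored(self) -> "DistanceMatrix":
        return DistanceMatrix(labels=list(self.labels), D=np.maximum(self.D, 0.0))

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.D[iu]


@dataclass
class PCAResult:
    coords: np.ndarray  # n x m principal-component coordinates
    eigenvalues: np.ndarray  # length m, non-increasing
    variant_index: np.ndarray  # variants actually used (monomorphic excluded)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None = None


@dataclass
class ProcrustesResult:
    m2: float
    r: float
    r2: float
    p: float
    n_perm: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# LD pruning


def _imputed_standardized(G: np.ndarray) -> np.ndarray:
    X = np.asarray(G, dtype=float)
    X[np.asarray(G) == MISSING] = np.nan
    means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    inds = np.where(np.isnan(X))
    X[inds] = means[inds[1]]
    return X


def ld_prune(
    G: np.ndarray,
    r2_threshold: float = 0.5,
    window: int = 50,
    step: int = 5,
    chrom: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained variants.

    Within each window of ``window`` variants (advancing by ``step``), for
    every ordered pair with squared Pearson genotype correlation above the
    threshold the later variant is dropped.  Missing genotypes are
    mean-imputed for the correlation.  Windows never span chromosomes.
    """
    if window < 2 or window < step:
        raise ParameterError("need window >= 2 and window >= step")
    G = np.asarray(G)
    L = G.shape[1]
    keep = np.ones(L, dtype=bool)
    X = _imputed_standardized(G)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    norms[norms == 0] = np.nan  # constant columns: correlation undefined -> 0
    Xn = Xc / norms
    if chrom is None:
        blocks = [np.arange(L)]
    else:
        chrom = np.asarray(chrom)
        blocks = [np.flatnonzero(chrom == c) for c in dict.fromkeys(chrom)]
    for block in blocks:
        m = len(block)
        if m < 2:
            continue
        Xb = np.ascontiguousarray(Xn[:, block].T)  # (m, n), row-contiguous
        # r^2 for all pairs within `window` indices, as a distance band
        high_pairs = []
        for d in range(1, min(window, m)):
            r = np.nan_to_num(np.einsum("ij,ij->i", Xb[:-d], Xb[d:]))
            for a in np.flatnonzero(r * r > r2_threshold):
                high_pairs.append((a, a + d))
        if not high_pairs:
            continue
        high_pairs.sort()
        # replay the window sweep over the (few) high-LD pairs only
        for ws in range(0, m, step):
            for a, b in high_pairs:
                if ws <= a and b < ws + window and keep[block[a]] and keep[block[b]]:
                    keep[block[b]] = False
            if ws + window >= m:
                break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# PCA


def genotype_pca(G: np.ndarray, n_pcs: int = 10) -> PCAResult:
    """PCA of a dosage matrix with the standard GWAS standardization.

    Missing dosages are mean-imputed per variant; columns are centered by
    2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)); monomorphic variants are
    excluded.  Coordinates are eigenvector projections of the sample
    covariance (deterministic up to column sign).
    """
    G = np.asarray(G)
    n, L = G.shape
    if n < 2:
        raise ParameterError("need at least 2 samples")
    obs = G != MISSING
    Gf = np.where(obs, G, 0).astype(float)
    counts = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(counts > 0, Gf.sum(axis=0) / (2.0 * counts), 0.0)
    poly = (p_hat > 0) & (p_hat < 1) & (counts > 0)
    if n_pcs > min(n - 1, int(poly.sum())):
        raise ParameterError("n_pcs exceeds the available rank")
    idx = np.flatnonzero(poly)
    X = np.where(obs[:, idx], G[:, idx], 2.0 * p_hat[idx]).astype(float)
    X -= 2.0 * p_hat[idx]
    X /= np.sqrt(2.0 * p_hat[idx] * (1.0 - p_hat[idx]))
    # eigendecomposition of the sample covariance via the n x n Gram matrix
    gram = (X @ X.T) / (len(idx))
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:n_pcs]
    eigenvalues = vals[order]
    coords = vecs[:, order] * np.sqrt(np.maximum(eigenvalues, 0.0) * len(idx))
    return PCAResult(coords=coords, eigenvalues=eigenvalues, variant_index=idx)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST


def _wc_components(G, labels, popA, popB):
    """Per-locus Weir & Cockerham (1984) variance components a, b, c."""
    G = np.asarray(G)
    labels = np.asarray(labels)
    pops = (popA, popB)
    r = 2
    masks = [labels == p for p in pops]
    if not all(m.any() for m in masks):
        raise DataError("both populations must be present in labels")
    sub = [G[m] for m in masks]
    called = [s != MISSING for s in sub]
    n_i = np.vstack([c.sum(axis=0) for c in called]).astype(float)  # (2, L)
    ok = np.all(n_i >= 2, axis=0)
    if not ok.any():
        raise DataError("each population needs >= 2 called genotypes at some locus")
    p_i = np.vstack(
        [
            np.where(c.sum(0) > 0, np.where(c, s, 0).sum(0), np.nan)
            for s, c in zip(sub, called)
        ]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = p_i / (2.0 * n_i)
        h_i = np.vstack(
            [((s == 1) & c).sum(0) / np.maximum(c.sum(0), 1) for s, c in zip(sub, called)]
        )
    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    defined = ok & (nbar > 1) & (nc > 0)
    return a, b, c, defined


def weir_cockerham_fst(G, labels, popA, popB):
    """Weir & Cockerham theta-hat between two populations.

    Returns (a, b, c, theta) where a, b, c are per-locus variance components
    (NaN where undefined) and theta is the ratio-of-averages estimate
    sum(a) / sum(a + b + c) over loci with a defined denominator.
    """
    a, b, c, defined = _wc_components(G, labels, popA, popB)
    tot = a + b + c
    use = defined & np.isfinite(tot) & (np.abs(tot) > 0)
    if not use.any():
        raise DataError("no locus with a defined F_ST denominator")
    theta = float(a[use].sum() / tot[use].sum())
    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    c = np.where(defined, c, np.nan)
    return a, b, c, theta


def pairwise_fst_matrix(G, labels, group_names: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Weir-Cockerham theta-hat between all groups in ``labels``."""
    labels = np.asarray(labels)
    if group_names is None:
        group_names = list(dict.fromkeys(labels.tolist()))
    if len(group_names) < 2:
        raise ParameterError("need at least two groups")
    k = len(group_names)
    D = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        *_, theta = weir_cockerham_fst(G, labels, group_names[i], group_names[j])
        D[i, j] = D[j, i] = theta
    return DistanceMatrix(labels=[str(g) for g in group_names], D=D)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    """Rooted binary tree with branch lengths; UPGMA output is ultrametric."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0
    height: float = 0.0

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        return [n for ch in self.children for n in ch.leaf_names()]

    def newick(self) -> str:
        if self.is_leaf():
            return f"{self.name};"
        inner = ",".join(ch._newick_inner() for ch in self.children)
        return f"({inner});"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{_fmt(self.branch_length)}"
        inner = ",".join(ch._newick_inner() for ch in self.children)
        return f"({inner}):{_fmt(self.branch_length)}"

    def root_to_leaf_depths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: TreeNode, depth: float):
            d = depth + node.branch_length
            if node.is_leaf():
                out[node.name] = d
            for ch in node.children:
                walk(ch, d)

        walk(self, -self.branch_length)  # root's own length does not count
        return out

    def clades(self) -> list[frozenset[str]]:
        out = []

        def walk(node: TreeNode):
            out.append(frozenset(node.leaf_names()))
            for ch in node.children:
                walk(ch)

        walk(self)
        return out


def _fmt(x: float) -> str:
    s = f"{x:.10f}".rstrip("0").rstrip(".")
    return s if s else "0"


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration of a labelled distance matrix.

    At every step the pair at minimal average distance is merged at height
    d/2 (so branch lengths are half the merge-height deltas); ties are broken
    by the lexicographically smallest label pair.  The result is ultrametric.
    """
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ParameterError("need at least two labels")
    D = {
        frozenset((a, b)): dm.D[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    nodes = {name: TreeNode(name=name, height=0.0) for name in labels}
    sizes = {name: 1 for name in labels}
    active = sorted(labels)
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(active, 2):
            key = tuple(sorted((a, b)))
            d = D[frozenset(key)]
            if best is None or d < best[0] - 1e-15 or (
                abs(d - best[0]) <= 1e-15 and key < best[1]
            ):
                best = (d, key)
        d, (a, b) = best
        h = d / 2.0
        na, nb = nodes.pop(a), nodes.pop(b)
        na.branch_length = h - na.height
        nb.branch_length = h - nb.height
        merged_name = f"({a}|{b})"
        merged = TreeNode(children=[na, nb], height=h)
        for other in active:
            if other in (a, b):
                continue
            dnew = (
                sizes[a] * D[frozenset((a, other))] + sizes[b] * D[frozenset((b, other))]
            ) / (sizes[a] + sizes[b])
            D[frozenset((merged_name, other))] = dnew
        sizes[merged_name] = sizes[a] + sizes[b]
        nodes[merged_name] = merged
        active = sorted([x for x in active if x not in (a, b)] + [merged_name])
    (root,) = nodes.values()
    root.branch_length = 0.0
    return root


# ---------------------------------------------------------------------------
# geography


def great_circle_distance(p1: GeoPoint, p2: GeoPoint) -> float:
    """Haversine distance in kilometres (Earth radius 6371.0 km)."""
    phi1, phi2 = math.radians(p1.lat), math.radians(p2.lat)
    dphi = phi2 - phi1
    dlam = math.radians(p2.lon - p1.lon)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geometric_median(
    points: Sequence[GeoPoint],
    weights: Sequence[float] | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> GeoPoint:
    """Weighted geometric median by Weiszfeld iteration.

    Points are projected to a local equirectangular plane about the weighted
    centroid; iterations stop when the update moves less than ``tol`` degrees.
    A current iterate coinciding with a data point follows the standard
    optimality test (stay if the residual pull is below that point's weight,
    else step away).
    """
    pts = np.array([[p.lat, p.lon] for p in points], dtype=float)
    if len(pts) == 0:
        raise ParameterError("need at least one point")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ParameterError("weights must be >= 0 and not all zero")
    lat0 = float((w @ pts[:, 0]) / w.sum())
    coslat = math.cos(math.radians(lat0))
    xy = np.column_stack([pts[:, 1] * coslat, pts[:, 0]])  # degree-scaled plane
    y = (w @ xy) / w.sum()
    for _ in range(max_iter):
        d = np.linalg.norm(xy - y, axis=1)
        at = d < 1e-12
        if at.any():
            j = int(np.argmax(at))
            rest = ~at
            if not rest.any():
                break
            R = ((w[rest, None] * (xy[rest] - y)) / d[rest, None]).sum(axis=0)
            if np.linalg.norm(R) <= w[at].sum():
                break  # the data point is the median
            y = y + (np.linalg.norm(R) - w[at].sum()) / np.linalg.norm(R) * R / (
                (w[rest] / d[rest]).sum()
            )
            continue
        wd = w / d
        y_new = (wd @ xy) / wd.sum()
        move = np.linalg.norm(y_new - y)
        y = y_new
        if move < tol:
            break
    return GeoPoint(lat=float(y[1]), lon=float(y[0] / coslat))


# ---------------------------------------------------------------------------
# Mantel and Procrustes permutation tests


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt((x @ x) * (y @ y))
    return float(x @ y / denom) if denom > 0 else 0.0


def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """One-sided Mantel test of matrix correlation.

    r is the Pearson correlation over the strict upper triangles; the null is
    built by jointly permuting rows/columns of D2.  With random permutations
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1); with ``exhaustive=True`` all
    n! label permutations (identity included) are enumerated and
    p = #{r_perm >= r_obs} / n!.
    """
    if D1.labels != D2.labels:
        raise DataError("matrices must share the same label order")
    n = len(D1.labels)
    if n < 3:
        raise DataError("need at least 3 labels")
    x = D1.condensed()
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson(x, D2.condensed())
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            P = D2.D[np.ix_(perm, perm)]
            if _pearson(x, P[iu]) >= r_obs - 1e-12:
                count += 1
            total += 1
        return MantelResult(r=r_obs, p=count / total, n_perm=total, seed=seed)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        P = D2.D[np.ix_(perm, perm)]
        if _pearson(x, P[iu]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs, p=(1 + count) / (n_perm + 1), n_perm=n_perm, seed=seed
    )


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual m^2 after optimal translation, scaling and rotation/reflection."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.linalg.norm(Xc)
    ny = np.linalg.norm(Yc)
    if nx == 0 or ny == 0:
        raise DataError("degenerate configuration (zero spread)")
    Xc /= nx
    Yc /= ny
    s = np.linalg.svd(Xc.T @ Yc, compute_uv=False)
    return float(1.0 - s.sum() ** 2)


def procrustes_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Procrustes superposition of two point configurations with permutation p.

    Both configurations are centered and scaled to unit sum of squares; the
    optimal orthogonal map (rotation, reflection allowed) and scaling
    minimize the residual m^2.  The statistic r = sqrt(1 - m^2); the p-value
    permutes rows of Y (one-sided, add-one corrected).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0] or X.shape[0] < 3:
        raise DataError("need matching configurations with >= 3 rows")
    m2 = _procrustes_m2(X, Y)
    r = math.sqrt(max(0.0, 1.0 - m2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        if math.sqrt(max(0.0, 1.0 - _procrustes_m2(X, Y[perm]))) >= r - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ProcrustesResult(m2=m2, r=r, r2=r * r, p=p, n_perm=n_perm, seed=seed)
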