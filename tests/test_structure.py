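"""Structure statistics against closed forms and independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import squareform

from sebpop import simpop, structure
from sebpop.errors import DataError, ParameterError
from sebpop.structure import DistanceMatrix, GeoPoint


# ---------------------------------------------------------------------------
# LD pruning


def _brute_force_prune(G, r2_threshold=0.5, window=50, step=5):
    """Naive windowed scan: the documented algorithm, coded plainly."""
    X = np.asarray(G, dtype=float)
    L = X.shape[1]
    keep = np.ones(L, dtype=bool)
    col_mean = X.mean(axis=0)
    for ws in range(0, L, step):
        idx = list(range(ws, min(ws + window, L)))
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1 :]:
                if not (keep[a] and keep[b]):
                    continue
                xa, xb = X[:, a], X[:, b]
                if xa.std() == 0 or xb.std() == 0:
                    continue
                r = np.corrcoef(xa, xb)[0, 1]
                if r * r > r2_threshold:
                    keep[b] = False
        if ws + window >= L:
            break
    return np.flatnonzero(keep)


class TestLdPrune:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        G[:, 4] = G[:, 3]
        kept = structure.ld_prune(G, window=10, step=2)
        assert 3 in kept and 4 not in kept

    def test_independent_variants_retained(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, 0.4, size=(200, 60)).astype(np.int8)
        kept = structure.ld_prune(G)
        assert len(kept) == 60

    def test_matches_brute_force_on_correlated_panel(self):
        # build a panel with genuine LD blocks so pruning has work to do
        rng = np.random.default_rng(2)
        blocks = []
        for _ in range(40):
            base = rng.binomial(2, rng.uniform(0.2, 0.8), size=120)
            for _ in range(5):
                noisy = base.copy()
                flip = rng.random(120) < 0.1
                noisy[flip] = rng.integers(0, 3, size=flip.sum())
                blocks.append(noisy)
        G = np.array(blocks).T.astype(np.int8)
        kept = structure.ld_prune(G)
        oracle = _brute_force_prune(G)
        assert np.array_equal(kept, oracle)

    def test_bad_window_rejected(self):
        with pytest.raises(ParameterError):
            structure.ld_prune(np.zeros((4, 4)), window=1)


# ---------------------------------------------------------------------------
# PCA


class TestGenotypePCA:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.2, size=100)
        b = rng.binomial(2, 0.8, size=100)
        G = np.vstack([np.tile(a, (10, 1)), np.tile(b, (10, 1))]).astype(np.int8)
        res = structure.genotype_pca(G, n_pcs=2)
        pc1 = res.coords[:, 0]
        assert max(pc1[:10].max(), -pc1[:10].min()) > 0
        assert (pc1[:10] > 0).all() != (pc1[10:] > 0).all()  # clean split
        assert pc1[:10].max() < pc1[10:].min() or pc1[10:].max() < pc1[:10].min()

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(4)
        G = rng.binomial(2, rng.uniform(0.1, 0.9, size=80), size=(30, 80)).astype(np.int8)
        res = structure.genotype_pca(G, n_pcs=5)
        # independent standardization + SVD
        p = G.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        X = (G[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        evals = s**2 / keep.sum()
        coords = U * s
        assert np.allclose(res.eigenvalues, evals[:5], atol=1e-8)
        for j in range(5):
            assert np.allclose(res.coords[:, j], coords[:, j], atol=1e-6) or np.allclose(
                res.coords[:, j], -coords[:, j], atol=1e-6
            )

    def test_monomorphic_excluded_without_effect(self):
        rng = np.random.default_rng(5)
        G = rng.binomial(2, 0.5, size=(20, 30)).astype(np.int8)
        G_mono = np.column_stack([G, np.zeros((20, 3), dtype=np.int8)])
        r1 = structure.genotype_pca(G, n_pcs=3)
        r2 = structure.genotype_pca(G_mono, n_pcs=3)
        assert np.allclose(r1.eigenvalues, r2.eigenvalues)
        assert np.allclose(np.abs(r1.coords), np.abs(r2.coords))

    def test_npcs_bound(self):
        with pytest.raises(ParameterError):
            structure.genotype_pca(np.array([[0, 1], [1, 0], [2, 1]]), n_pcs=3)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST


class TestWeirCockerham:
    def test_complete_differentiation(self):
        G = np.array([[2] * 20] * 5 + [[0] * 20] * 5, dtype=np.int8)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        *_, theta = structure.weir_cockerham_fst(G, labels, "A", "B")
        assert theta == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(6)
        block = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(40, 300)).astype(np.int8)
        G = np.vstack([block, block])
        labels = np.array(["A"] * 40 + ["B"] * 40)
        *_, theta = structure.weir_cockerham_fst(G, labels, "A", "B")
        assert theta <= 0.01

    def test_hand_evaluated_components(self):
        # 5 + 5 individuals at one locus:
        # popA = [0,0,1,1,2] (p=0.4, het=0.4), popB = [1,2,2,2,1] (p=0.8, het=0.4)
        # n_bar=5, n_c=5, p_bar=0.6, s2=0.08, h_bar=0.4
        # a = 0.08 - (1/4)(0.24 - 0.04 - 0.1)        = 0.055
        # b = (5/4)(0.24 - 0.04 - (9/20)*0.4)        = 0.025
        # c = 0.4/2                                  = 0.2
        # theta = 0.055 / 0.28                       = 0.19642857...
        G = np.array([[0], [0], [1], [1], [2], [1], [2], [2], [2], [1]], dtype=np.int8)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        a, b, c, theta = structure.weir_cockerham_fst(G, labels, "A", "B")
        assert a[0] == pytest.approx(0.055, abs=1e-12)
        assert b[0] == pytest.approx(0.025, abs=1e-12)
        assert c[0] == pytest.approx(0.2, abs=1e-12)
        assert theta == pytest.approx(0.055 / 0.28, abs=1e-12)

    def test_pairwise_matrix_consistency(self, two_group_sim):
        ds, _, _ = two_group_sim
        labels = ds.samples["group"].to_numpy()
        dm = structure.pairwise_fst_matrix(ds.G, labels)
        assert dm.D[0, 1] == dm.D[1, 0]
        assert dm.D[0, 0] == 0
        *_, theta = structure.weir_cockerham_fst(ds.G, labels, dm.labels[0], dm.labels[1])
        assert dm.D[0, 1] == pytest.approx(theta)

    def test_three_drifted_groups_recover_parameter(self):
        cfg = simpop.SimConfig(
            groups=[
                simpop.GroupSpec(name=n, n=100, q=[1.0], drift=0.05, g=5)
                for n in ["A", "B", "C"]
            ],
            chroms=simpop.default_chromosomes(2, include_x=False),
            L=5000,
            F_anc=[0.1],
            ancestries=["a"],
            seed=7,
        )
        ds, _, _ = simpop.simulate_genotypes(cfg)
        dm = structure.pairwise_fst_matrix(ds.G, ds.samples["group"].to_numpy())
        off = dm.condensed()
        assert ((off > 0.03) & (off < 0.07)).all()

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            structure.pairwise_fst_matrix(np.zeros((4, 3)), np.array(["A"] * 4))


# ---------------------------------------------------------------------------
# UPGMA


def _brute_force_upgma(labels, D):
    """Independent agglomeration tracking heights and clades."""
    clusters = {frozenset([l]): 0.0 for l in labels}
    dist = {
        frozenset([a, b]): D[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    merges = []
    items = [frozenset([l]) for l in labels]

    def avg(c1, c2):
        return np.mean([dist[frozenset([a, b])] for a in c1 for b in c2])

    while len(items) > 1:
        best = min(
            (
                (avg(c1, c2), tuple(sorted([min(c1), min(c2)])), c1, c2)
                for c1, c2 in itertools.combinations(items, 2)
            ),
            key=lambda t: (t[0], t[1]),
        )
        d, _, c1, c2 = best
        merged = c1 | c2
        merges.append((merged, d / 2.0))
        items = [c for c in items if c not in (c1, c2)] + [merged]
    return merges


class TestUpgma:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            D=np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = structure.upgma_tree(dm)
        assert tree.newick() == "((A:0.5,B:0.5):1.5,C:2);"
        depths = tree.root_to_leaf_depths()
        assert all(abs(d - 2.0) < 1e-12 for d in depths.values())

    def test_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = 7
            M = rng.random((n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            tree = structure.upgma_tree(DistanceMatrix(labels=[f"t{i}" for i in range(n)], D=D))
            depths = list(tree.root_to_leaf_depths().values())
            assert max(depths) - min(depths) < 1e-9

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(9)
        labels = list("ABCDEF")
        M = rng.random((6, 6)) * 10
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        tree = structure.upgma_tree(DistanceMatrix(labels=labels, D=D))
        clades = set(map(frozenset, tree.clades()))
        merges = _brute_force_upgma(labels, D)
        for clade, height in merges:
            assert frozenset(clade) in clades
        # scipy average linkage agrees on merge heights
        Z = hierarchy.average(squareform(D, checks=False))
        scipy_heights = sorted(Z[:, 2] / 2.0)
        ours = sorted(h for _, h in merges)
        assert np.allclose(sorted({round(h, 12) for h in ours}), sorted({round(h, 12) for h in scipy_heights}))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(DataError):
            DistanceMatrix(labels=["A", "B"], D=np.array([[0, 1], [2, 0]], float))


# ---------------------------------------------------------------------------
# geography


class TestGeometry:
    def test_identical_points(self):
        p = GeoPoint(-25.0, 28.0)
        assert structure.geometric_median([p, p, p]).lat == pytest.approx(-25.0)
        assert structure.great_circle_distance(p, p) == 0.0

    def test_equilateral_symmetry(self):
        pts = [GeoPoint(0, 0), GeoPoint(1, 0), GeoPoint(0.5, math.sqrt(3) / 2)]
        med = structure.geometric_median(pts)
        assert med.lat == pytest.approx(0.5, abs=1e-6)
        assert med.lon == pytest.approx(math.sqrt(3) / 6, abs=1e-3)

    def test_weighted_median_matches_grid_search(self):
        pts = [
            GeoPoint(-24.0, 29.0),
            GeoPoint(-26.5, 27.5),
            GeoPoint(-23.0, 31.0),
            GeoPoint(-28.0, 30.0),
        ]
        w = [3.0, 1.0, 2.0, 0.5]
        med = structure.geometric_median(pts, weights=w)
        # grid search over the same planar objective at 1e-3 degree resolution
        lat0 = sum(wi * p.lat for wi, p in zip(w, pts)) / sum(w)
        coslat = math.cos(math.radians(lat0))

        def objective(lat, lon):
            return sum(
                wi * math.hypot((lon - p.lon) * coslat, lat - p.lat)
                for wi, p in zip(w, pts)
            )

        lats = np.arange(-28.0, -23.0, 1e-3)
        lons = np.arange(27.5, 31.0, 1e-3)
        LA, LO = np.meshgrid(lats, lons, indexing="ij")
        dists = np.zeros_like(LA)
        for wi, p in zip(w, pts):
            dists += wi * np.hypot((LO - p.lon) * coslat, LA - p.lat)
        i, j = np.unravel_index(np.argmin(dists), dists.shape)
        assert med.lat == pytest.approx(LA[i, j], abs=2e-3)
        assert med.lon == pytest.approx(LO[i, j], abs=2e-3)
        assert objective(med.lat, med.lon) <= dists[i, j] + 1e-6

    def test_zero_weights_rejected(self):
        with pytest.raises(ParameterError):
            structure.geometric_median([GeoPoint(0, 0)], weights=[0.0])

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ((0, 0), (0, 180), 20015.086796),
            ((0, 0), (0, 90), 10007.543398),
            ((90, 0), (-90, 0), 20015.086796),
        ],
    )
    def test_great_circle_reference_values(self, p1, p2, expected):
        d = structure.great_circle_distance(GeoPoint(*p1), GeoPoint(*p2))
        assert d == pytest.approx(expected, abs=0.1)


# ---------------------------------------------------------------------------
# Mantel


def _mantel_exhaustive_oracle(D1, D2):
    """Plain enumeration over all label permutations."""
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(A, B):
        a, b = A[iu], B[iu]
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    r_obs = corr(D1, D2)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        P = D2[np.ix_(perm, perm)]
        if corr(D1, P) >= r_obs - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


class TestMantel:
    def test_affine_invariance(self):
        rng = np.random.default_rng(10)
        M = rng.random((5, 5))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        off = (D > 0).astype(float)
        d1 = DistanceMatrix(labels=list("abcde"), D=D)
        d2 = DistanceMatrix(labels=list("abcde"), D=2 * D + 3 * off)
        res = structure.mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_matches_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            M1, M2 = rng.random((4, 4)), rng.random((4, 4))
            D1, D2 = (M1 + M1.T) / 2, (M2 + M2.T) / 2
            np.fill_diagonal(D1, 0)
            np.fill_diagonal(D2, 0)
            labels = list("wxyz")
            res = structure.mantel_test(
                DistanceMatrix(labels=labels, D=D1),
                DistanceMatrix(labels=labels, D=D2),
                exhaustive=True,
            )
            r_oracle, p_oracle = _mantel_exhaustive_oracle(D1, D2)
            assert res.r == pytest.approx(r_oracle, abs=1e-12)
            assert res.p == pytest.approx(p_oracle, abs=1e-12)
            assert res.n_perm == 24

    def test_p_lower_bound(self):
        rng = np.random.default_rng(12)
        M = rng.random((6, 6))
        D1 = (M + M.T) / 2
        np.fill_diagonal(D1, 0)
        d1 = DistanceMatrix(labels=list("abcdef"), D=D1)
        d2 = DistanceMatrix(labels=list("abcdef"), D=D1 * 1.5)
        res = structure.mantel_test(d1, d2, n_perm=199, seed=1)
        assert res.p >= 1.0 / 200

    def test_label_mismatch_rejected(self):
        d1 = DistanceMatrix(labels=["a", "b", "c"], D=np.zeros((3, 3)))
        d2 = DistanceMatrix(labels=["a", "c", "b"], D=np.zeros((3, 3)))
        with pytest.raises(DataError):
            structure.mantel_test(d1, d2)


# ---------------------------------------------------------------------------
# Procrustes


class TestProcrustes:
    def test_exact_superposition(self):
        rng = np.random.default_rng(13)
        X = rng.random((6, 2))
        th = 1.1
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        Y = X @ R * 3.0 + np.array([5.0, -2.0])
        res = structure.procrustes_test(X, Y, n_perm=99, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 100)

    def test_rotation_invariance_of_statistic(self):
        rng = np.random.default_rng(14)
        X = rng.random((8, 2))
        Y = rng.random((8, 2))
        base = structure.procrustes_test(X, Y, n_perm=9, seed=0).m2
        for th in (0.3, 2.0):
            R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
            rot = structure.procrustes_test(X @ R, Y, n_perm=9, seed=0).m2
            assert rot == pytest.approx(base, abs=1e-12)

    def test_matches_rotation_grid_oracle_and_scipy(self):
        rng = np.random.default_rng(15)
        X = rng.random((5, 2))
        Y = rng.random((5, 2))
        res = structure.procrustes_test(X, Y, n_perm=9, seed=0)
        # brute-force search over rotation angle (and reflection) at 1e-4 rad
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        Xc /= np.linalg.norm(Xc)
        Yc /= np.linalg.norm(Yc)
        best = np.inf
        for reflect in (1.0, -1.0):
            Yr = Yc.copy()
            Yr[:, 1] *= reflect
            for th in np.arange(0, 2 * math.pi, 1e-4):
                R = np.array(
                    [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
                )
                Z = Yr @ R
                scale = np.sum(Xc * Z)  # optimal scaling given rotation
                best = min(best, 1 - scale**2 if scale > 0 else 1.0)
        assert res.m2 == pytest.approx(best, abs=1e-6)
        _, _, disparity = scipy_procrustes(X, Y)
        assert res.m2 == pytest.approx(disparity, abs=1e-9)

    def test_rank_deficient_rejected(self):
        X = np.zeros((4, 2))
        Y = np.random.default_rng(16).random((4, 2))
        with pytest.raises(DataError):
            structure.procrustes_test(X, Y, n_perm=9)


# ---------------------------------------------------------------------------
# module-level invariants on simulated data


class TestStructureInvariants:
    def test_fst_recovers_drift_parameter(self):
        thetas = []
        for seed in range(5):
            cfg = simpop.SimConfig(
                groups=[
                    simpop.GroupSpec(name=n, n=100, q=[1.0], drift=0.05, g=5)
                    for n in ["A", "B"]
                ],
                chroms=simpop.default_chromosomes(2, include_x=False),
                L=5000,
                F_anc=[0.1],
                ancestries=["a"],
                seed=seed,
            )
            ds, _, _ = simpop.simulate_genotypes(cfg)
            *_, theta = structure.weir_cockerham_fst(
                ds.G, ds.samples["group"].to_numpy(), "A", "B"
            )
            thetas.append(theta)
        assert 0.045 < np.mean(thetas) < 0.055

    def test_mantel_p_uniform_under_null(self):
        # independent random matrices: permutation p should be uniform
        rng = np.random.default_rng(18)
        ps = []
        labels = list("abcdef")
        for i in range(1000):
            M1, M2 = rng.random((6, 6)), rng.random((6, 6))
            D1, D2 = (M1 + M1.T) / 2, (M2 + M2.T) / 2
            np.fill_diagonal(D1, 0)
            np.fill_diagonal(D2, 0)
            res = structure.mantel_test(
                DistanceMatrix(labels=labels, D=D1),
                DistanceMatrix(labels=labels, D=D2),
                n_perm=999,
                seed=i,
            )
            ps.append(res.p)
        from scipy import stats as sps

        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01, ks

    def test_procrustes_recovers_geography_as_noise_vanishes(self):
        pts = [(-24.0, 29.0), (-26.0, 26.0), (-28.0, 31.0), (-23.0, 31.5), (-29.0, 27.0)]
        r2s = []
        for gradient in (0.02, 0.08, 0.3):
            G, labels = simpop.simulate_geographic_cline(
                pts, n_per_group=30, L=1500, gradient=gradient, seed=17
            )
            pca = structure.genotype_pca(G, n_pcs=2)
            means = np.vstack(
                [pca.coords[labels == i].mean(axis=0) for i in range(len(pts))]
            )
            geo = np.array([[lon, lat] for lat, lon in pts])
            r2s.append(structure.procrustes_test(geo, means, n_perm=9, seed=0).r2)
        assert r2s[0] < r2s[-1]
        assert r2s[-1] > 0.9
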