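"""Interaction matrix normalization, SOM gridding, correlations, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clearclip.dynamics import (
    hcluster,
    normalize_matrix,
    som_fit,
    stage_correlation,
    topographic_ok,
    zscore_rows,
)

TPS = ["t1", "t2", "t3", "t4", "t5"]


def _heights(rows):
    return pd.DataFrame(
        rows, columns=["interaction_id", "transcript_id", "timepoint", "height"]
    )


def _expr(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "timepoint", "abundance"])


def archetype_matrix(n=400, seed=13, noise=0.15, k=4):
    """Rows drawn from k stage-peaked archetype profiles + Gaussian noise."""
    rng = np.random.Generator(np.random.PCG64(seed))
    T = len(TPS)
    centers = np.linspace(0, T - 1, k)
    arch = np.exp(-0.5 * ((np.arange(T)[None, :] - centers[:, None]) / 0.7) ** 2)
    labels = rng.integers(0, k, size=n)
    X = arch[labels] + rng.normal(0, noise, size=(n, T))
    mat = pd.DataFrame(X, index=[f"i{j:04d}" for j in range(n)], columns=TPS)
    return mat, labels


class TestNormalize:
    def test_simple_ratio(self):
        h = _heights([("i1", "tx", "t1", 10.0)])
        e = _expr([("tx", tp, 5.0) for tp in TPS])
        mat, dropped = normalize_matrix(h, e, TPS)
        assert mat.loc["i1", "t1"] == pytest.approx(2.0)
        assert (mat.loc["i1", TPS[1:]] == 0).all()
        assert not dropped

    def test_doubling_abundance_halves_cells(self):
        h = _heights([("i1", "tx", tp, 10.0) for tp in TPS])
        e1 = _expr([("tx", tp, 5.0) for tp in TPS])
        e2 = _expr([("tx", tp, 10.0) for tp in TPS])
        m1, _ = normalize_matrix(h, e1, TPS)
        m2, _ = normalize_matrix(h, e2, TPS)
        assert np.allclose(m1.to_numpy(), 2 * m2.to_numpy())

    def test_missing_expression_drops_interaction(self):
        h = _heights([("i1", "tx_missing", "t1", 10.0), ("i2", "tx", "t1", 4.0)])
        e = _expr([("tx", tp, 2.0) for tp in TPS])
        mat, dropped = normalize_matrix(h, e, TPS)
        assert dropped == ["i1"]
        assert list(mat.index) == ["i2"]

    def test_floor_prevents_blowups(self):
        h = _heights([("i1", "tx", "t1", 1.0)])
        e = _expr([("tx", "t1", 1e-9)] + [("tx", tp, 1.0) for tp in TPS[1:]])
        mat, _ = normalize_matrix(h, e, TPS, floor=0.1)
        assert mat.loc["i1", "t1"] == pytest.approx(10.0)

    def test_never_negative_or_nan(self):
        mat, _ = archetype_matrix(50)
        h = _heights(
            [(f"i{j}", "tx", tp, abs(v)) for j, row in enumerate(mat.to_numpy())
             for tp, v in zip(TPS, row)]
        )
        e = _expr([("tx", tp, 1.0) for tp in TPS])
        out, _ = normalize_matrix(h, e, TPS)
        assert np.isfinite(out.to_numpy()).all()
        assert (out.to_numpy() >= 0).all()


class TestZscore:
    def test_linear_row(self):
        m = pd.DataFrame([[1, 2, 3, 4, 5]], columns=TPS)
        z = zscore_rows(m)
        assert z.to_numpy().mean() == pytest.approx(0.0, abs=1e-12)
        assert z.to_numpy().std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_row_becomes_zero(self):
        z = zscore_rows(pd.DataFrame([[3, 3, 3, 3, 3]], columns=TPS))
        assert (z.to_numpy() == 0).all()

    def test_idempotent(self):
        m, _ = archetype_matrix(30)
        z1 = zscore_rows(m)
        z2 = zscore_rows(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


class TestSOM:
    def test_identical_rows_share_tile(self):
        m, _ = archetype_matrix(40)
        m.iloc[1] = m.iloc[0]
        som = som_fit(m, grid=(6, 6), rng_seed=0)
        assert som.tile_of.iloc[0] == som.tile_of.iloc[1]

    def test_deterministic_under_seed(self):
        m, _ = archetype_matrix(60)
        a = som_fit(m, grid=(6, 6), rng_seed=5)
        b = som_fit(m, grid=(6, 6), rng_seed=5)
        assert (a.tile_of == b.tile_of).all()

    def test_archetype_pairs_land_on_nearby_tiles(self):
        m, labels = archetype_matrix(400, seed=13)
        som = som_fit(zscore_rows(m), grid=(8, 8), rng_seed=13)
        coords = np.array([som.tile_coords(t) for t in som.tile_of])
        rng = np.random.Generator(np.random.PCG64(1))
        same = 0
        close = 0
        for _ in range(4000):
            i, j = rng.integers(0, len(labels), 2)
            if labels[i] != labels[j] or i == j:
                continue
            same += 1
            cheb = np.abs(coords[i] - coords[j]).max()
            close += cheb <= 2
        assert same > 400
        assert close / same >= 0.90

    def test_topographic_property(self):
        m, _ = archetype_matrix(300)
        som = som_fit(zscore_rows(m), grid=(8, 8), rng_seed=3)
        adjacent, random_pairs = topographic_ok(som)
        assert adjacent < random_pairs

    def test_archetype_recovery_by_tile_clustering(self):
        """k-means over tile mean profiles recovers the planted temporal
        programs (adjusted Rand index vs planted labels)."""
        from sklearn.cluster import KMeans

        m, labels = archetype_matrix(400, seed=13)
        som = som_fit(zscore_rows(m), grid=(8, 8), rng_seed=13)
        km = KMeans(n_clusters=4, n_init=10, random_state=0).fit(som.tile_mean)
        pred = km.labels_[som.tile_of.to_numpy()]
        assert adjusted_rand_score(labels, pred) >= 0.8


class TestStageCorrelation:
    def test_duplicated_column_r1(self):
        m, _ = archetype_matrix(50)
        m["t2"] = m["t1"]
        c = stage_correlation(m)
        assert c.loc["t1", "t2"] == pytest.approx(1.0)
        assert np.allclose(np.diag(c), 1.0)

    def test_negated_column_r_minus_1(self):
        m, _ = archetype_matrix(50)
        m["t2"] = -m["t1"]
        assert stage_correlation(m).loc["t1", "t2"] == pytest.approx(-1.0)

    def test_shared_archetypes_make_adjacent_stages_more_similar(self):
        rng = np.random.Generator(np.random.PCG64(4))
        n = 300
        base = rng.uniform(0.5, 2.0, n)
        m = pd.DataFrame(
            {
                "t1": base + rng.normal(0, 0.2, n),
                "t2": base + rng.normal(0, 0.2, n),
                "t4": rng.uniform(0.5, 2.0, n),
            }
        )
        c = stage_correlation(m)
        assert c.loc["t1", "t2"] > c.loc["t1", "t4"]

    def test_zero_variance_column_gives_nan(self):
        m = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [5.0, 5.0, 5.0]})
        assert np.isnan(stage_correlation(m).loc["t1", "t2"])


class TestHcluster:
    def test_identical_rows_merge_first_at_zero(self):
        m, _ = archetype_matrix(10)
        m.iloc[1] = m.iloc[0]
        ids, Z, newick = hcluster(m)
        assert Z[0][2] == pytest.approx(0.0)
        merged = {int(Z[0][0]), int(Z[0][1])}
        assert merged == {0, 1}

    def test_two_separated_archetypes_split_at_top(self):
        rng = np.random.Generator(np.random.PCG64(5))
        a = np.array([1.0, 0.0, 0.0, 0.0, 1.0])
        b = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        rows = [a + rng.normal(0, 0.05, 5) for _ in range(6)]
        rows += [b + rng.normal(0, 0.05, 5) for _ in range(6)]
        m = pd.DataFrame(rows, index=[f"i{j:02d}" for j in range(12)], columns=TPS)
        ids, Z, _ = hcluster(m)
        first_six = {f"i{j:02d}" for j in range(6)}
        top_left = set(ids[:6])
        assert top_left in (first_six, {f"i{j:02d}" for j in range(6, 12)})

    def test_permutation_invariant_merge_heights(self):
        m, _ = archetype_matrix(20)
        _, Z1, n1 = hcluster(m)
        _, Z2, n2 = hcluster(m.sample(frac=1.0, random_state=2))
        assert np.allclose(Z1[:, 2], Z2[:, 2])
        assert n1 == n2

    def test_single_row_trivial_tree(self):
        m, _ = archetype_matrix(1)
        ids, Z, newick = hcluster(m)
        assert ids == ["i0000"] and len(Z) == 0
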