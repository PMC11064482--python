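"""Bray-Curtis, PCoA, PERMANOVA and PERMDISP against independent oracles."""

from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import f_oneway

import microclade as mc
from microclade.stats import DistanceMatrix, _gower


def frame(rows, prefix="s"):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(len(arr))])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = mc.bray_curtis(frame([[0.2, 0.8], [0.2, 0.8]]))
        assert dm.data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = mc.bray_curtis(frame([[1.0, 0.0], [0.0, 1.0]]))
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        dm = mc.bray_curtis(frame([[0.6, 0.4], [0.2, 0.8]]))
        assert dm.data[0, 1] == pytest.approx(0.4)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            mc.bray_curtis(frame([[0.0, 0.0], [0.0, 0.0]]))

    @given(st.integers(0, 10_000))
    def test_matches_scipy_and_invariants(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((5, 4))
        dm = mc.bray_curtis(frame(x))
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)
        assert dm.data.min() >= 0 and dm.data.max() <= 1
        for i in range(5):
            for j in range(i):
                assert dm.data[i, j] == pytest.approx(scipy_braycurtis(x[i], x[j]))


class TestPcoa:
    def test_three_equidistant_points(self):
        d = 0.6
        dm = DistanceMatrix(("a", "b", "c"), d * (1 - np.eye(3)))
        res = mc.pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_embedding_round_trip(self):
        """Distances of an exactly embeddable configuration are reproduced."""
        points = np.array([[0.0], [1.0], [2.5], [4.0]])
        d = np.abs(points - points.T)
        res = mc.pcoa(DistanceMatrix(tuple("abcd"), d))
        coords = res.coordinates.to_numpy()
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(recon, d, atol=1e-9)

    def test_duplicate_samples_identical_coordinates(self):
        table = frame([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1], [0.2, 0.8]])
        res = mc.pcoa(mc.bray_curtis(table))
        assert np.allclose(
            res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[1].to_numpy()
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            mc.pcoa(DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        table = frame(rng.dirichlet(np.ones(6), size=9))
        dm = mc.bray_curtis(table)
        mine = mc.pcoa(dm)
        theirs = sk_pcoa(skbio.DistanceMatrix(dm.data, ids=list(dm.ids)))
        k = mine.coordinates.shape[1]
        assert np.allclose(mine.eigenvalues[:k], np.asarray(theirs.eigvals)[:k], atol=1e-8)
        # coordinates agree up to per-axis sign
        a, b = mine.coordinates.to_numpy(), theirs.samples.to_numpy()[:, :k]
        for j in range(k):
            assert np.allclose(a[:, j], b[:, j], atol=1e-6) or np.allclose(
                a[:, j], -b[:, j], atol=1e-6
            )


def brute_force_permanova_f(d, labels):
    """Independent single-factor pseudo-F: explicit group SS on distances."""
    n = len(labels)
    total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    within = 0.0
    levels = sorted(set(labels))
    for lev in levels:
        idx = [i for i, g in enumerate(labels) if g == lev]
        sub = d[np.ix_(idx, idx)]
        within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    between = total - within
    df_b, df_w = len(levels) - 1, n - len(levels)
    return (between / df_b) / (within / df_w)


class TestPermanova:
    def test_full_factorial_dfs(self, full_design):
        params = mc.ScenarioParams(scenario="climate", reads_per_sample=80, seed=2)
        counts = mc.simulate_clade_counts(full_design, params)
        md = full_design.metadata("T3")
        tr = md.index[md["type"] == "transplant"]
        ab = mc.relative_abundance(counts.loc[tr])
        res = mc.permanova(mc.bray_curtis(ab), md, n_permutations=29, seed=1)
        assert [t.df for t in res.terms] == [4, 4, 16]
        assert res.residual_df == len(tr) - 25

    def test_equals_classical_anova_f_univariate(self, rng):
        y = np.concatenate([rng.normal(0, 1, 7), rng.normal(2, 1, 7)])
        table = pd.DataFrame({"y": y}, index=[f"s{i:02d}" for i in range(14)])
        md = pd.DataFrame({"g": ["a"] * 7 + ["b"] * 7}, index=table.index)
        res = mc.permanova(mc.euclidean(table), md, terms=("g",), n_permutations=9)
        assert res.terms[0].f == pytest.approx(f_oneway(y[:7], y[7:]).statistic)

    def test_agrees_with_brute_force_partitioning(self, rng):
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        table = frame(rng.dirichlet(np.ones(5), size=12))
        md = pd.DataFrame({"g": labels}, index=table.index)
        dm = mc.bray_curtis(table)
        res = mc.permanova(dm, md, terms=("g",), n_permutations=9)
        assert res.terms[0].f == pytest.approx(
            brute_force_permanova_f(dm.data, labels)
        )

    def test_exact_p_matches_enumeration_oracle(self, rng):
        """Exhaustive permutation p on 6 samples equals a from-scratch tally."""
        labels = ["a", "a", "a", "b", "b", "b"]
        table = frame(rng.random((6, 3)))
        md = pd.DataFrame({"g": labels}, index=table.index)
        dm = mc.bray_curtis(table)
        res = mc.permanova(dm, md, terms=("g",), method="exact")
        f_obs = res.terms[0].f
        count = 0
        total = 0
        for perm in iter_permutations(range(6)):
            permuted = [labels[i] for i in perm]
            f = brute_force_permanova_f(dm.data, permuted)
            count += f >= f_obs - 1e-12
            total += 1
        assert res.n_permutations == 720
        assert res.terms[0].p == pytest.approx(count / total)

    @given(st.integers(0, 10_000))
    def test_ss_decomposition_exact(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b, reps = 2, 2, 2
        labels = [(f"a{i}", f"b{j}") for i in range(n_a) for j in range(n_b)
                  for _ in range(reps)]
        table = frame(rng.dirichlet(np.ones(4), size=len(labels)))
        md = pd.DataFrame(labels, columns=["fa", "fb"], index=table.index)
        res = mc.permanova(
            mc.bray_curtis(table), md, terms=("fa", "fb", "fa:fb"), n_permutations=9
        )
        ss_sum = sum(t.ss for t in res.terms) + res.residual_ss
        assert ss_sum == pytest.approx(res.total_ss, abs=1e-9)
        r2_sum = sum(t.r2 for t in res.terms) + res.residual_r2
        assert r2_sum == pytest.approx(1.0, abs=1e-9)

    def test_p_invariant_to_sample_order(self, rng):
        table = frame(rng.dirichlet(np.ones(4), size=10))
        md = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5}, index=table.index)
        dm = mc.bray_curtis(table)
        shuffled = table.sample(frac=1.0, random_state=3)
        dm2 = mc.bray_curtis(shuffled)
        r1 = mc.permanova(dm, md, terms=("g",), n_permutations=199, seed=5)
        r2 = mc.permanova(dm2, md, terms=("g",), n_permutations=199, seed=5)
        assert r1.terms[0].p == r2.terms[0].p
        assert r1.terms[0].f == pytest.approx(r2.terms[0].f)

    def test_confounded_term_rejected(self):
        table = frame(np.random.default_rng(0).random((6, 3)))
        md = pd.DataFrame(
            {"a": ["x", "x", "x", "y", "y", "y"], "b": ["u", "u", "u", "v", "v", "v"]},
            index=table.index,
        )
        with pytest.raises(ValueError, match="'b'"):
            mc.permanova(mc.bray_curtis(table), md, terms=("a", "b"), n_permutations=9)

    def test_matches_skbio_single_factor_f(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        table = frame(rng.dirichlet(np.ones(5), size=12))
        labels = ["a"] * 6 + ["b"] * 6
        md = pd.DataFrame({"g": labels}, index=table.index)
        dm = mc.bray_curtis(table)
        mine = mc.permanova(dm, md, terms=("g",), n_permutations=99)
        theirs = sk_permanova(
            skbio.DistanceMatrix(dm.data, ids=list(dm.ids)), labels, permutations=99
        )
        assert mine.terms[0].f == pytest.approx(theirs["test statistic"])


class TestPermdisp:
    def test_translated_copies_equal_dispersion(self):
        rng = np.random.default_rng(1)
        cloud = rng.random((6, 3))
        table = frame(np.vstack([cloud, cloud + 5.0]))
        md = pd.Series(["a"] * 6 + ["b"] * 6, index=table.index)
        res = mc.permdisp(mc.euclidean(table), md, n_permutations=99, seed=1)
        assert res.f == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.5

    def test_zero_spread_group_zero_distances(self):
        rows = np.vstack([np.tile([0.3, 0.7], (4, 1)), np.random.default_rng(2).random((4, 2))])
        table = frame(rows)
        md = pd.Series(["dup"] * 4 + ["spread"] * 4, index=table.index)
        res = mc.permdisp(mc.euclidean(table), md, n_permutations=49, seed=1)
        assert np.allclose(res.distances.loc[[f"s{i}" for i in range(4)]], 0.0, atol=1e-9)

    def test_planar_geometric_oracle(self):
        """Euclidean input: distances to centroid match direct 2-D geometry."""
        pts = np.array(
            [[0.0, 0.0], [2.0, 0.0], [1.0, 2.0], [5.0, 5.0], [7.0, 5.0], [6.0, 8.0]]
        )
        table = frame(pts)
        md = pd.Series(["g1"] * 3 + ["g2"] * 3, index=table.index)
        res = mc.permdisp(mc.euclidean(table), md, n_permutations=9, seed=1)
        for gidx, members in enumerate([range(3), range(3, 6)]):
            centroid = pts[list(members)].mean(axis=0)
            for i in members:
                expected = np.linalg.norm(pts[i] - centroid)
                assert res.distances.loc[f"s{i}"] == pytest.approx(expected, abs=1e-9)

    def test_reports_df_groups_minus_one(self, rng):
        table = frame(rng.random((9, 3)))
        md = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=table.index)
        res = mc.permdisp(mc.euclidean(table), md, n_permutations=9, seed=1)
        assert res.df == 2

    def test_singleton_group_rejected(self, rng):
        table = frame(rng.random((5, 3)))
        md = pd.Series(["a"] * 4 + ["b"], index=table.index)
        with pytest.raises(ValueError, match="singleton"):
            mc.permdisp(mc.euclidean(table), md)


class TestGower:
    @given(st.integers(0, 10_000))
    def test_trace_is_total_ss(self, seed):
        """tr(G) equals sum of squared distances / n (McArdle-Anderson)."""
        rng = np.random.default_rng(seed)
        x = rng.random((7, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        g = _gower(d)
        n = len(x)
        expected = (d[np.triu_indices(n, 1)] ** 2).sum() / n
        assert np.trace(g) == pytest.approx(expected, abs=1e-9)
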