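"""Morisita-Horn, NMDS recovery, envfit, Mantel, and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from trophicweb import (
    AnalysisConfig,
    DistanceMatrix,
    InputError,
    envfit,
    mantel,
    morisita_horn,
    morisita_horn_matrix,
    nmds,
    permanova,
)
from trophicweb.ordination import procrustes_error

abund = st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8)


class TestMorisitaHorn:
    def test_hand_value(self):
        assert morisita_horn([1, 1], [1, 3]) == pytest.approx(1.0 - 8.0 / 9.0, abs=1e-12)

    def test_identical_and_disjoint(self):
        assert morisita_horn([2, 3, 0], [2, 3, 0]) == pytest.approx(0.0, abs=1e-12)
        assert morisita_horn([2, 0], [0, 5]) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            morisita_horn([0, 0], [1, 2])

    @given(x=abund, y=abund, c=st.integers(min_value=1, max_value=9))
    def test_symmetry_bounds_and_scale_invariance(self, x, y, c):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if x.sum() == 0 or y.sum() == 0:
            return
        d = morisita_horn(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(morisita_horn(y, x), abs=1e-12)
        assert d == pytest.approx(morisita_horn(c * x, y), abs=1e-10)


class TestNMDS:
    def test_recovers_exact_two_dimensional_configuration(self, fast_config):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 2))
        d = DistanceMatrix([f"p{i}" for i in range(15)], squareform(pdist(x)))
        res = nmds(d, fast_config)
        assert res.stress < 1e-3
        assert procrustes_error(x, res.scores) < 1e-2

    def test_scores_centered_and_pc_rotated(self, fast_config):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 2)) * [3.0, 1.0]
        d = DistanceMatrix([f"p{i}" for i in range(12)], squareform(pdist(x)))
        res = nmds(d, fast_config)
        s = res.scores
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-8)
        cov = s.T @ s
        assert abs(cov[0, 1]) < 1e-6 * cov[0, 0]  # axes uncorrelated
        assert cov[0, 0] >= cov[1, 1]  # axis 1 carries the larger variance

    def test_all_equal_dissimilarities_flagged_degenerate(self, fast_config):
        n = 5
        d = np.full((n, n), 0.6)
        np.fill_diagonal(d, 0.0)
        res = nmds(DistanceMatrix([f"p{i}" for i in range(n)], d), fast_config)
        assert res.degenerate
        assert res.stress == pytest.approx(0.0)

    def test_reproducible_given_seed(self, fast_config):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 3))
        d = DistanceMatrix([f"p{i}" for i in range(10)], squareform(pdist(x)))
        a = nmds(d, fast_config)
        b = nmds(d, fast_config)
        assert np.array_equal(a.scores, b.scores)
        assert a.stress == b.stress

    def test_too_few_items_rejected(self, fast_config):
        d = DistanceMatrix(["a", "b", "c"], squareform(pdist(np.eye(3))))
        with pytest.raises(InputError):
            nmds(d, fast_config)


class TestEnvfit:
    @pytest.fixture()
    def ordination(self, fast_config):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 2))
        d = DistanceMatrix([f"p{i}" for i in range(20)], squareform(pdist(x)))
        return nmds(d, fast_config)

    def test_variable_equal_to_axis_one(self, ordination, fast_config):
        v = pd.DataFrame({"v": ordination.scores[:, 0]}, index=ordination.plot_ids)
        f = envfit(ordination, v, fast_config)[0]
        assert f.r_squared == pytest.approx(1.0, abs=1e-9)
        assert abs(f.direction[0]) == pytest.approx(1.0, abs=1e-6)
        assert f.p_value == pytest.approx(1.0 / (fast_config.n_perm_ordination + 1))

    def test_variable_negative_axis_two(self, ordination, fast_config):
        v = pd.DataFrame({"v": -ordination.scores[:, 1]}, index=ordination.plot_ids)
        f = envfit(ordination, v, fast_config)[0]
        assert f.r_squared == pytest.approx(1.0, abs=1e-9)
        assert abs(f.direction[1]) == pytest.approx(1.0, abs=1e-6)

    def test_r_squared_invariant_to_affine_rescaling(self, ordination, fast_config):
        rng = np.random.default_rng(7)
        raw = rng.normal(size=20)
        a = envfit(ordination, pd.DataFrame({"v": raw}), fast_config)[0]
        b = envfit(ordination, pd.DataFrame({"v": 5.0 * raw - 3.0}), fast_config)[0]
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)
        assert a.p_value == b.p_value

    def test_zero_variance_variable_named_in_error(self, ordination, fast_config):
        with pytest.raises(InputError, match="flatvar"):
            envfit(ordination, pd.DataFrame({"flatvar": np.ones(20)}), fast_config)


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(8)
        d = DistanceMatrix([f"p{i}" for i in range(10)], squareform(pdist(rng.normal(size=(10, 3)))))
        r, p = mantel(d, d, n_perm=199, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1.0 / 200.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        base = squareform(pdist(rng.normal(size=(10, 3))))
        d1 = DistanceMatrix([f"p{i}" for i in range(10)], base)
        d2 = DistanceMatrix([f"p{i}" for i in range(10)], 2.5 * base + (1 - np.eye(10)) * 0.3)
        r, _ = mantel(d1, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(10)
        a = squareform(pdist(rng.normal(size=(12, 3))))
        b = squareform(pdist(rng.normal(size=(12, 3))))
        labels = [f"p{i}" for i in range(12)]
        r, _ = mantel(DistanceMatrix(labels, a), DistanceMatrix(labels, b), n_perm=9, seed=0)
        r_ref, _, _ = sk_mantel(a, b, permutations=0)
        assert r == pytest.approx(float(r_ref), abs=1e-10)

    def test_constant_distances_rejected(self):
        flat = (1 - np.eye(6)) * 0.4
        d = DistanceMatrix([f"p{i}" for i in range(6)], flat)
        with pytest.raises(InputError):
            mantel(d, d, n_perm=9, seed=0)


class TestPermanova:
    def test_one_way_statistic_matches_reference(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(11)
        y = rng.normal(size=(18, 3))
        y[9:] += 1.0
        d = squareform(pdist(y))
        labels = [f"p{i}" for i in range(18)]
        grouping = ["a"] * 9 + ["b"] * 9
        ours = permanova(
            DistanceMatrix(labels, d),
            pd.DataFrame({"g": grouping}, index=labels),
            n_perm=9,
            seed=0,
        )
        ref = sk_permanova(SkDM(d, ids=labels), grouping=grouping, permutations=9)
        assert ours.loc["g", "pseudo_F"] == pytest.approx(float(ref["test statistic"]), abs=1e-8)

    def test_strong_separation_reaches_p_floor(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(20, 3))
        y[10:] += 6.0
        d = squareform(pdist(y))
        labels = [f"p{i}" for i in range(20)]
        res = permanova(
            DistanceMatrix(labels, d),
            pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10}, index=labels),
            n_perm=199,
            seed=1,
        )
        assert res.loc["g", "p_value"] == pytest.approx(1.0 / 200.0)

    def test_aliased_term_rejected(self):
        rng = np.random.default_rng(13)
        d = squareform(pdist(rng.normal(size=(10, 3))))
        labels = [f"p{i}" for i in range(10)]
        x = rng.normal(size=10)
        design = pd.DataFrame({"x": x, "y": 2.0 * x}, index=labels)
        with pytest.raises(InputError, match="aliased"):
            permanova(DistanceMatrix(labels, d), design, n_perm=9, seed=0)

    def test_marginal_two_term_sums_of_squares_partition(self):
        rng = np.random.default_rng(14)
        d = squareform(pdist(rng.normal(size=(16, 3))))
        labels = [f"p{i}" for i in range(16)]
        design = pd.DataFrame(
            {"x": rng.normal(size=16), "g": ["a", "b"] * 8}, index=labels
        )
        res = permanova(DistanceMatrix(labels, d), design, n_perm=19, seed=0)
        assert set(res.index) == {"x", "g", "residual"}
        assert (res["df"] > 0).all()


class TestMorisitaHornMatrix:
    def test_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(
            rng.integers(0, 10, size=(5, 7)) + (rng.random((5, 7)) < 0.3),
            index=[f"p{i}" for i in range(5)],
        )
        table.iloc[:, 0] += 1
        m = morisita_horn_matrix(table)
        v = table.to_numpy(float)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else morisita_horn(v[i], v[j])
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)
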