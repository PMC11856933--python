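"""Quantitative network indices against literal-formula and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from trophicweb import (
    InputError,
    InteractionMatrix,
    all_indices,
    generality,
    interaction_evenness,
    linkage_density,
    robustness_exact,
    robustness_higher,
    shannon_bits,
    vulnerability,
)

from conftest import random_interaction_matrix


def _literal_indices(counts: np.ndarray) -> dict[str, float]:
    """Independent literal-formula reference (plain loops, no shortcuts)."""
    counts = np.asarray(counts, dtype=float)
    i_dim, j_dim = counts.shape
    m = counts.sum()

    def h_bits(vec):
        tot = sum(vec)
        return -sum((v / tot) * math.log2(v / tot) for v in vec if v > 0)

    g = sum(
        (counts[:, j].sum() / m) * 2 ** h_bits(counts[:, j])
        for j in range(j_dim)
        if counts[:, j].sum() > 0
    )
    v = sum(
        (counts[i, :].sum() / m) * 2 ** h_bits(counts[i, :])
        for i in range(i_dim)
        if counts[i, :].sum() > 0
    )
    ent = -sum(
        (c / m) * math.log(c / m) for c in counts.ravel() if c > 0
    )
    return {
        "generality": g,
        "vulnerability": v,
        "linkage_density": 0.5 * (g + v),
        "interaction_evenness": (
            ent / math.log(i_dim * j_dim) if i_dim * j_dim >= 2 else None
        ),
    }


def _robustness_enumeration(counts: np.ndarray) -> float:
    """Literal average over all removal orders of the trapezoid area."""
    b = np.asarray(counts) > 0
    b = b[:, b.any(axis=0)]
    n_hosts, n_para = b.shape
    areas = []
    for order in itertools.permutations(range(n_hosts)):
        removed = set()
        ys = [1.0]
        for h in order:
            removed.add(h)
            alive = sum(
                1 for j in range(n_para) if any(b[i, j] and i not in removed for i in range(n_hosts))
            )
            ys.append(alive / n_para)
        ys[-1] = 0.0
        area = sum((ys[k] + ys[k + 1]) / 2.0 for k in range(n_hosts)) / n_hosts
        areas.append(area)
    return float(np.mean(areas))


class TestShannon:
    @pytest.mark.parametrize(
        "weights,expected",
        [((1, 1), 1.0), ((5, 0, 0), 0.0), ((2, 1), 0.9182958340544896)],
    )
    def test_known_values(self, weights, expected):
        assert shannon_bits(weights) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            shannon_bits([0, 0])


class TestHandValues:
    def test_worked_example(self, example_matrix):
        assert generality(example_matrix) == pytest.approx(
            (3 / 4) * 2**0.9182958340544896 + (1 / 4), abs=1e-10
        )
        assert vulnerability(example_matrix) == pytest.approx(1.5, abs=1e-12)
        assert linkage_density(example_matrix) == pytest.approx(
            0.5 * (generality(example_matrix) + 1.5), abs=1e-12
        )
        assert interaction_evenness(example_matrix) == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("n", range(1, 7))
    def test_uniform_matrix_effective_numbers_equal_richness(self, n):
        m = InteractionMatrix(
            "u", [f"h{i}" for i in range(n)], [f"q{j}" for j in range(n)], np.ones((n, n), int)
        )
        assert generality(m) == pytest.approx(n, abs=1e-10)
        assert vulnerability(m) == pytest.approx(n, abs=1e-10)
        assert linkage_density(m) == pytest.approx(n, abs=1e-10)
        if n >= 2:
            assert interaction_evenness(m) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 3, 17])
    def test_single_link_matrix(self, k):
        m = InteractionMatrix("s", ["h"], ["q"], [[k]])
        assert generality(m) == pytest.approx(1.0)
        assert vulnerability(m) == pytest.approx(1.0)
        assert linkage_density(m) == pytest.approx(1.0)

    def test_single_realized_link_evenness_zero(self):
        m = InteractionMatrix("s", ["h1", "h2"], ["q1", "q2"], [[5, 0], [0, 0]])
        assert interaction_evenness(m) == pytest.approx(0.0, abs=1e-12)

    def test_evenness_undefined_for_1x1(self):
        with pytest.raises(InputError, match="evenness"):
            interaction_evenness(InteractionMatrix("s", ["h"], ["q"], [[3]]))

    def test_empty_matrix_errors(self):
        m = InteractionMatrix("e", ["h"], ["q"], [[0]])
        with pytest.raises(InputError, match="empty network"):
            generality(m)


class TestFormulaOracle:
    def test_200_random_matrices_match_literal_formulas(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = random_interaction_matrix(rng)
            ref = _literal_indices(m.counts)
            assert generality(m) == pytest.approx(ref["generality"], abs=1e-10)
            assert vulnerability(m) == pytest.approx(ref["vulnerability"], abs=1e-10)
            assert linkage_density(m) == pytest.approx(ref["linkage_density"], abs=1e-10)
            if m.n_hosts * m.n_parasitoids >= 2:
                assert interaction_evenness(m) == pytest.approx(
                    ref["interaction_evenness"], abs=1e-10
                )


class TestInvariances:
    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_interaction_matrix(rng, max_dim=5)
            m3 = InteractionMatrix(m.plot_id, m.host_labels, m.parasitoid_labels, m.counts * 3)
            for fn in (generality, vulnerability, linkage_density):
                assert fn(m) == pytest.approx(fn(m3), abs=1e-12)
            if m.n_hosts * m.n_parasitoids >= 2:
                assert interaction_evenness(m) == pytest.approx(
                    interaction_evenness(m3), abs=1e-12
                )
            assert robustness_exact(m) == pytest.approx(robustness_exact(m3), abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = random_interaction_matrix(rng, max_dim=5)
            pr = rng.permutation(m.n_hosts)
            pc = rng.permutation(m.n_parasitoids)
            mp = InteractionMatrix(
                m.plot_id,
                [m.host_labels[i] for i in pr],
                [m.parasitoid_labels[j] for j in pc],
                m.counts[np.ix_(pr, pc)],
            )
            for fn in (generality, vulnerability, linkage_density, robustness_exact):
                assert fn(m) == pytest.approx(fn(mp), abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_uniform_k_host_parasitoids_have_generality_k(self, k):
        # every parasitoid attacks exactly k hosts uniformly
        rng = np.random.default_rng(7)
        i_dim, j_dim = 6, 5
        counts = np.zeros((i_dim, j_dim), int)
        for j in range(j_dim):
            counts[rng.choice(i_dim, k, replace=False), j] = 1
        m = InteractionMatrix("k", [f"h{i}" for i in range(i_dim)], [f"q{j}" for j in range(j_dim)], counts)
        assert generality(m) == pytest.approx(k, abs=1e-10)

    def test_linkage_density_is_mean_of_g_and_v(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            m = random_interaction_matrix(rng)
            assert linkage_density(m) == pytest.approx(
                0.5 * (generality(m) + vulnerability(m)), abs=1e-12
            )


class TestRobustness:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([[3, 0], [0, 2]], 0.5),  # each parasitoid on its own host
            ([[1, 1], [1, 1]], 0.75),  # both survive until the last host
            ([[2, 3]], 0.5),  # single host
        ],
    )
    def test_enumeration_hand_values(self, counts, expected):
        counts = np.asarray(counts)
        m = InteractionMatrix(
            "r",
            [f"h{i}" for i in range(counts.shape[0])],
            [f"q{j}" for j in range(counts.shape[1])],
            counts,
        )
        assert robustness_higher(m, method="enumerate") == pytest.approx(expected, abs=1e-12)
        assert robustness_exact(m) == pytest.approx(expected, abs=1e-12)

    def test_closed_form_equals_enumeration_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            m = random_interaction_matrix(rng, max_dim=5, max_count=4)
            if not (m.counts.sum(axis=0) > 0).any():
                continue
            assert robustness_exact(m) == pytest.approx(
                _robustness_enumeration(m.counts), abs=1e-10
            )

    def test_monte_carlo_converges_to_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            m = random_interaction_matrix(rng, max_dim=3, max_count=5)
            exact = _robustness_enumeration(m.counts)
            mc = robustness_higher(m, n_orders=2000, seed=1, method="sample")
            assert abs(mc - exact) < 0.02

    def test_bundle_deterministic_and_consistent(self, example_matrix, fast_config):
        a = all_indices(example_matrix, fast_config)
        b = all_indices(example_matrix, fast_config)
        assert a == b
        assert a.linkage_density == pytest.approx(
            0.5 * (a.generality_qw + a.vulnerability_qw), abs=1e-12
        )
        assert 0.0 <= a.interaction_evenness <= 1.0
        assert 0.0 <= a.robustness_higher <= 1.0
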