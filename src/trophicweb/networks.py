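"""Community-level quantitative indices of bipartite host-parasitoid networks.

For an I x J count matrix with entries n_ij (rows hosts, columns
parasitoids), column sums A_j, row sums A_i and total m:

* generality        G  = sum_j (A_j / m) * 2**H_j   (effective hosts per parasitoid)
* vulnerability     V  = sum_i (A_i / m) * 2**H_i   (effective parasitoids per host)
* linkage density   Lq = 0.5 * (G + V)
* interaction evenness E = -sum_ij p_ij ln p_ij / ln(I*J), p_ij = n_ij / m
* robustness (higher level) R = area under the secondary-extinction curve of
  parasitoid persistence as hosts are removed in random order.

H_j (H_i) is the Shannon entropy, in bits, of column j (row i); the
effective-number base 2**H matches the bit-based entropy, while evenness
uses natural logs (the base cancels in the ratio).  Zero cells are skipped
everywhere (0 * log 0 = 0).

The private ``*_counts`` functions operate on raw count arrays; the null
stage calls them directly on hundreds of thousands of randomized tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Callable

import numpy as np
from scipy.special import gammaln

from .core import AnalysisConfig, InputError, InteractionMatrix

__all__ = [
    "NetworkIndices",
    "shannon_bits",
    "generality",
    "vulnerability",
    "linkage_density",
    "interaction_evenness",
    "robustness_higher",
    "robustness_exact",
    "all_indices",
    "INDEX_NAMES",
]

INDEX_NAMES = (
    "generality",
    "vulnerability",
    "linkage_density",
    "interaction_evenness",
    "robustness",
)


@dataclass(frozen=True)
class NetworkIndices:
    """Bundle of the five community-level indices for one plot."""

    generality_qw: float
    vulnerability_qw: float
    linkage_density: float
    interaction_evenness: float
    robustness_higher: float

    def as_dict(self) -> dict[str, float]:
        return {
            "generality": self.generality_qw,
            "vulnerability": self.vulnerability_qw,
            "linkage_density": self.linkage_density,
            "interaction_evenness": self.interaction_evenness,
            "robustness": self.robustness_higher,
        }


def shannon_bits(weights) -> float:
    """Shannon entropy, in bits, of a nonnegative weight vector."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise InputError("negative weight in entropy")
    total = w.sum()
    if total <= 0:
        raise InputError("all-zero weight vector has no entropy")
    p = w[w > 0] / total
    return float(-(p * np.log2(p)).sum())


def _as_counts(matrix: InteractionMatrix) -> np.ndarray:
    if matrix.m < 1:
        raise InputError(f"empty network (m=0) in plot {matrix.plot_id!r}")
    return matrix.counts.astype(float)


def _effective_partners_counts(c: np.ndarray, axis: int) -> float:
    """sum over lines of (A/m) * 2**H(line); axis=0 columns, axis=1 rows."""
    lines = c if axis == 1 else c.T  # (n_lines, line_length)
    m = c.sum()
    totals = lines.sum(axis=1)
    p = lines / np.where(totals > 0, totals, 1.0)[:, None]
    h = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=1)
    return float(np.sum(np.where(totals > 0, (totals / m) * 2.0**h, 0.0)))


def _generality_counts(c: np.ndarray) -> float:
    return _effective_partners_counts(c, axis=0)


def _vulnerability_counts(c: np.ndarray) -> float:
    return _effective_partners_counts(c, axis=1)


def _linkage_density_counts(c: np.ndarray) -> float:
    return 0.5 * (_generality_counts(c) + _vulnerability_counts(c))


def _evenness_counts(c: np.ndarray) -> float:
    i, j = c.shape
    if i * j < 2:
        raise InputError("evenness undefined for a 1x1 network")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum() / math.log(i * j))


def _robustness_exact_counts(c: np.ndarray) -> float:
    b = c > 0
    b = b[:, b.any(axis=0)]
    n_hosts, n_para = b.shape
    if n_para == 0:
        raise InputError("no parasitoid with a realized link")
    d = b.sum(axis=0).astype(np.int64)  # hosts used by each parasitoid
    k = np.arange(n_hosts + 1)
    lc_total = gammaln(n_hosts + 1) - gammaln(k + 1) - gammaln(n_hosts - k + 1)
    kd = k[None, :] - d[:, None]  # (J, I+1)
    nd = n_hosts - d[:, None]
    with np.errstate(invalid="ignore"):
        lc_part = gammaln(nd + 1) - gammaln(kd + 1) - gammaln(nd - kd + 1)
    p_ext = np.where(kd >= 0, np.exp(lc_part - lc_total[None, :]), 0.0)
    y = 1.0 - p_ext.mean(axis=0)
    y[0] = 1.0
    y[-1] = 0.0
    return float(np.trapezoid(y, dx=1.0 / n_hosts))


COUNT_INDEX_FNS: dict[str, Callable[[np.ndarray], float]] = {
    "generality": _generality_counts,
    "vulnerability": _vulnerability_counts,
    "linkage_density": _linkage_density_counts,
    "interaction_evenness": _evenness_counts,
    "robustness": _robustness_exact_counts,
}


def generality(matrix: InteractionMatrix) -> float:
    """Weighted mean effective number of host species per parasitoid species."""
    return _generality_counts(_as_counts(matrix))


def vulnerability(matrix: InteractionMatrix) -> float:
    """Weighted mean effective number of parasitoid species per host species."""
    return _vulnerability_counts(_as_counts(matrix))


def linkage_density(matrix: InteractionMatrix) -> float:
    """Quantitative linkage density Lq = (generality + vulnerability) / 2."""
    return _linkage_density_counts(_as_counts(matrix))


def interaction_evenness(matrix: InteractionMatrix) -> float:
    """Shannon evenness of the interaction distribution, normalized by ln(I*J)."""
    return _evenness_counts(_as_counts(matrix))


def robustness_exact(matrix: InteractionMatrix) -> float:
    """Exact expected robustness of the higher level under random host removal.

    The expected extinction curve has a closed form: a parasitoid using d
    of the I hosts is extinct after k uniformly random removals with
    hypergeometric probability C(I-d, k-d) / C(I, k).  The trapezoidal area
    (endpoints (0,1) and (1,0) included) is linear in the expected curve,
    so this equals the average over all I! removal orders exactly.
    """
    return _robustness_exact_counts(_as_counts(matrix))


def _areas_for_orders(b: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Trapezoidal areas for host-removal orders given 1-based removal positions.

    ``positions`` is (n_orders, I): positions[o, h] = step at which host h
    is removed in order o.  A parasitoid is extinct once all of its hosts
    are removed, i.e. after step max over its hosts' positions.
    """
    n_orders, n_hosts = positions.shape
    ext = np.max(positions[:, :, None] * b[None, :, :], axis=1)  # (orders, J)
    k = np.arange(n_hosts + 1)
    y = (ext[:, None, :] > k[None, :, None]).mean(axis=2).astype(float)
    y[:, 0] = 1.0
    y[:, -1] = 0.0
    return np.trapezoid(y, dx=1.0 / n_hosts, axis=1)


def robustness_higher(
    matrix: InteractionMatrix,
    n_orders: int = 500,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Robustness of the higher level under random host-removal orders.

    ``method="auto"`` enumerates all I! <= 40,320 removal orders when
    I <= 8 hosts (exact, seed-independent); ``"sample"`` forces Monte-Carlo
    averaging over ``n_orders`` uniformly random orders; ``"enumerate"``
    forces full enumeration.
    """
    if n_orders < 1:
        raise InputError("n_orders must be >= 1")
    if method not in ("auto", "sample", "enumerate"):
        raise InputError(f"unknown robustness method {method!r}")
    c = _as_counts(matrix)
    b = c > 0
    b = b[:, b.any(axis=0)]
    n_hosts = b.shape[0]
    if b.shape[1] == 0:
        raise InputError("no parasitoid with a realized link")
    enumerate_all = method == "enumerate" or (method == "auto" and n_hosts <= 8)
    if enumerate_all:
        if n_hosts > 8:
            raise InputError("full enumeration supported only for <= 8 hosts")
        orders = np.array(list(permutations(range(n_hosts))), dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        orders = np.argsort(rng.random((n_orders, n_hosts)), axis=1)
    positions = np.argsort(orders, axis=1) + 1
    chunk = max(1, int(2_000_000 / max(1, n_hosts * b.shape[1])))
    areas = [
        _areas_for_orders(b, positions[s : s + chunk])
        for s in range(0, positions.shape[0], chunk)
    ]
    return float(np.concatenate(areas).mean())


def all_indices(
    matrix: InteractionMatrix, config: AnalysisConfig | None = None
) -> NetworkIndices:
    """The five indices of one plot's network.

    Robustness uses the exact closed-form expectation (see
    :func:`robustness_exact`), so the bundle is fully deterministic.
    """
    c = _as_counts(matrix)
    g = _generality_counts(c)
    v = _vulnerability_counts(c)
    return NetworkIndices(
        generality_qw=g,
        vulnerability_qw=v,
        linkage_density=0.5 * (g + v),
        interaction_evenness=_evenness_counts(c),
        robustness_higher=_robustness_exact_counts(c),
    )
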