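"""Patefield fixed-margin null models for interaction matrices.

A Patefield draw is a random contingency table with exactly the observed
row and column totals, distributed as the multivariate (Fisher-Yates)
hypergeometric — the null of independent reassortment of interactions.
Sampling is by sequential row-wise multivariate-hypergeometric draws,
which samples that distribution exactly (no swap chains, hence no burn-in
or mixing decisions).

Significance of an observed index is summarized by a two-sided permutation
p-value (double the smaller tail, add-one rule, capped at 1) and a z-score
against the null mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from . import networks
from .core import AnalysisConfig, InputError, InteractionMatrix

__all__ = ["NullDistribution", "patefield_sample", "null_test", "null_test_all"]

_INDEX_FNS: dict[str, Callable[[np.ndarray], float]] = networks.COUNT_INDEX_FNS


@dataclass(frozen=True)
class NullDistribution:
    """Observed index, its Patefield null distribution, and the test summary.

    ``z_score`` is NaN (and ``degenerate`` True) when the null SD is zero;
    the p-value is still defined by the tie rule and equals 1 in that case.
    """

    index_name: str
    observed: float
    null_values: np.ndarray
    p_value: float
    z_score: float
    n_resampled: int = 0

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.z_score)

    @property
    def n_null(self) -> int:
        return len(self.null_values)


def patefield_sample(
    row_margins, col_margins, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """One random count matrix with the given row and column totals.

    Rows are filled in order; row i is a multivariate-hypergeometric draw
    of its total from the remaining column capacities, which yields exactly
    the fixed-margin hypergeometric table distribution.
    """
    r = np.asarray(row_margins, dtype=np.int64)
    c = np.asarray(col_margins, dtype=np.int64)
    if np.any(r < 0) or np.any(c < 0):
        raise InputError("margins must be nonnegative")
    if r.sum() != c.sum():
        raise InputError(f"margin sums differ: {r.sum()} != {c.sum()}")
    if r.sum() < 1:
        raise InputError("margin total must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    remaining = c.copy()
    out = np.zeros((len(r), len(c)), dtype=np.int64)
    for i, ri in enumerate(r):
        if ri > 0:
            row = rng.multivariate_hypergeometric(remaining, int(ri))
            out[i] = row
            remaining -= row
    return out


def _summary(index_name: str, observed: float, null_values: np.ndarray, n_resampled: int):
    null_values = np.asarray(null_values, dtype=float)
    n = len(null_values)
    tol = 1e-12 * max(1.0, abs(observed))
    p_low = (np.sum(null_values <= observed + tol) + 1) / (n + 1)
    p_high = (np.sum(null_values >= observed - tol) + 1) / (n + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    sd = null_values.std(ddof=1) if n > 1 else 0.0
    z = (observed - null_values.mean()) / sd if sd > 0 else np.nan
    return NullDistribution(index_name, float(observed), null_values, float(p), float(z), n_resampled)


def null_test_all(
    matrix: InteractionMatrix,
    config: AnalysisConfig | None = None,
    index_names: Iterable[str] = networks.INDEX_NAMES,
    n_null: int | None = None,
    max_resample: int = 100,
) -> dict[str, NullDistribution]:
    """Patefield null test of several indices sharing one set of draws.

    A draw on which an index is undefined (e.g. evenness on a degenerate
    table) is resampled for all indices, with the resample count recorded.
    """
    config = config or AnalysisConfig()
    index_names = list(index_names)
    unknown = [k for k in index_names if k not in _INDEX_FNS]
    if unknown:
        raise InputError(f"unknown index name(s): {unknown}")
    n_null = config.n_null if n_null is None else int(n_null)
    fns = {k: _INDEX_FNS[k] for k in index_names}
    counts = matrix.counts.astype(float)
    if counts.sum() < 1:
        raise InputError(f"empty network (m=0) in plot {matrix.plot_id!r}")
    observed = {k: fn(counts) for k, fn in fns.items()}

    rng = config.rng("nulls", matrix.plot_id)
    r = matrix.host_totals
    c = matrix.parasitoid_totals
    nulls = {k: np.empty(n_null) for k in index_names}
    n_resampled = 0
    for d in range(n_null):
        for _attempt in range(max_resample):
            table = patefield_sample(r, c, rng).astype(float)
            try:
                vals = {k: fn(table) for k, fn in fns.items()}
            except InputError:
                n_resampled += 1
                continue
            break
        else:
            raise InputError(
                f"could not draw a valid null table in {max_resample} attempts"
            )
        for k, v in vals.items():
            nulls[k][d] = v
    return {
        k: _summary(k, observed[k], nulls[k], n_resampled) for k in index_names
    }


def null_test(
    matrix: InteractionMatrix,
    index_name: str,
    config: AnalysisConfig | None = None,
    n_null: int | None = None,
) -> NullDistribution:
    """Patefield null test of a single named index."""
    return null_test_all(matrix, config, [index_name], n_null)[index_name]
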