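"""ParaFit: permutation test of host-parasitoid cophylogenetic congruence.

Given patristic distance matrices for hosts and parasitoids and the binary
association matrix A (parasitoids x hosts) of realized links, the global
statistic is built from principal coordinates of the two distance matrices:
B = host coordinates, C = parasitoid coordinates, D = C' A B (the
fourth-corner matrix), ParaFitGlobal = sum(D^2).  The null of random host
use is simulated by independently permuting each parasitoid's host
assignments; the p-value is one-sided (permuted >= observed) with the
add-one rule.

Negative principal-coordinate eigenvalues (possible for non-additive
distances) are handled with the Lingoes correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, DistanceMatrix, InputError

__all__ = ["ParafitResult", "pcoa_coords", "parafit_global"]


@dataclass(frozen=True)
class ParafitResult:
    global_stat: float
    p_value: float
    n_perm: int
    per_link_stats: np.ndarray | None = None
    degenerate: bool = False  # statistic invariant under the permutation null


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    return a - a.mean(0, keepdims=True) - a.mean(1, keepdims=True) + a.mean()


def pcoa_coords(dist: DistanceMatrix, eig_tol: float = 1e-8) -> np.ndarray:
    """Principal-coordinate axes (columns) for the positive eigenvalues.

    If the smallest eigenvalue of the Gower-centered matrix is below
    ``-eig_tol`` the Lingoes correction (add -2*lambda_min to every squared
    off-diagonal distance) is applied before decomposition.
    """
    d = dist.values
    vals, vecs = np.linalg.eigh(_gower_center(d))
    scale = max(1.0, float(np.abs(vals).max()))
    if vals.min() < -eig_tol * scale:
        c = -vals.min()
        d2 = d**2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        vals, vecs = np.linalg.eigh(_gower_center(np.sqrt(d2)))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > eig_tol * scale
    if not keep.any():
        # all-identical items: a single zero coordinate
        return np.zeros((d.shape[0], 1))
    return vecs[:, keep] * np.sqrt(vals[keep])


def parafit_global(
    host_dist: DistanceMatrix,
    para_dist: DistanceMatrix,
    links: np.ndarray,
    config: AnalysisConfig | None = None,
    n_perm: int | None = None,
    per_link: bool = False,
) -> ParafitResult:
    """ParaFitGlobal test of nonrandom association between two phylogenies.

    ``links`` is the parasitoid x host association matrix in the order of
    ``para_dist.labels`` x ``host_dist.labels``; counts are accepted and
    binarized.  Species without any link must be excluded beforehand.
    """
    config = config or AnalysisConfig()
    n_perm = config.n_perm_parafit if n_perm is None else int(n_perm)
    a = np.asarray(links)
    if a.ndim != 2 or a.shape != (para_dist.n, host_dist.n):
        raise InputError(
            f"links shape {a.shape} must be (n_parasitoids={para_dist.n}, "
            f"n_hosts={host_dist.n})"
        )
    if np.any(a.astype(float) < 0):
        raise InputError("negative entry in association matrix")
    a = (a.astype(float) > 0).astype(float)
    if a.sum() == 0:
        raise InputError("empty association matrix")
    if np.any(a.sum(axis=1) == 0) or np.any(a.sum(axis=0) == 0):
        raise InputError(
            "species without links present; exclude unlinked species first"
        )

    b = pcoa_coords(host_dist)  # hosts x axes
    c = pcoa_coords(para_dist)  # parasitoids x axes

    def stat(assoc: np.ndarray) -> float:
        d = c.T @ assoc @ b
        return float((d**2).sum())

    obs = stat(a)

    n_para, n_host = a.shape
    if n_host < 2 or n_para < 2:
        # permuting host assignments cannot change anything
        return ParafitResult(obs, 1.0, n_perm, None, degenerate=True)

    rng = config.rng("parafit")
    count = 0
    for _ in range(n_perm):
        perm_rows = np.argsort(rng.random((n_para, n_host)), axis=1)
        a_perm = np.take_along_axis(a, perm_rows, axis=1)
        if stat(a_perm) >= obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)

    per_link_stats = None
    if per_link:
        # leave-one-link-out contribution of each realized link
        stats = []
        for i, j in np.argwhere(a > 0):
            a_drop = a.copy()
            a_drop[i, j] = 0.0
            stats.append(obs - stat(a_drop))
        per_link_stats = np.asarray(stats)
    return ParafitResult(obs, float(p), n_perm, per_link_stats)
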