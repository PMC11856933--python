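"""Phylogenetic and functional community metrics.

All metrics are abundance-weighted (here typically by wood volume for
trees).  With normalized weights p_i and pairwise distances d_ij:

* MPD   = sum_{i != j} p_i p_j d_ij / sum_{i != j} p_i p_j
* MNTD  = sum_i p_i min_{j != i} d_ij
* Rao's Q = sum_{i,j} p_i p_j d_ij   (quadratic entropy; i = j terms are 0
  and there is no denominator — Rao's Q and MPD are deliberately kept as
  distinct quantities even though they are verbally conflated in parts of
  the ecological literature)
* between-community MPD = sum_{i,k} p_i q_k d_ik for communities p and q,
  the building block of plot x plot phylogenetic dissimilarity matrices.

Functional (trait) distances are Euclidean on per-trait z-scores, divided
by sqrt(n_traits) so that one full standard deviation in a single trait
contributes 1/sqrt(n_traits).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DistanceMatrix, InputError, normalize_name

__all__ = [
    "mpd",
    "mntd",
    "rao_q",
    "trait_distances",
    "between_community_mpd",
    "between_community_mpd_matrix",
    "community_weights",
]


def community_weights(labels: Sequence[str], weights) -> tuple[list[str], np.ndarray]:
    """Validate and normalize a (labels, weights) community description."""
    labels = [normalize_name(x) for x in labels]
    w = np.asarray(weights, dtype=float)
    if len(labels) != len(w):
        raise InputError("labels and weights differ in length")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise InputError("weights must be finite and nonnegative")
    keep = w > 0
    if not keep.any():
        raise InputError("community has no species with positive weight")
    labels = [lab for lab, k in zip(labels, keep) if k]
    w = w[keep]
    return labels, w / w.sum()


def _pairwise(labels, weights, dist: DistanceMatrix):
    labels, p = community_weights(labels, weights)
    d = dist.submatrix(labels).values
    return p, d


def mpd(labels: Sequence[str], weights, dist: DistanceMatrix) -> float:
    """Abundance-weighted mean pairwise distance of one community."""
    p, d = _pairwise(labels, weights, dist)
    if len(p) < 2:
        raise InputError("MPD undefined for a single-species community")
    w = np.outer(p, p)
    np.fill_diagonal(w, 0.0)
    return float((w * d).sum() / w.sum())


def mntd(labels: Sequence[str], weights, dist: DistanceMatrix) -> float:
    """Abundance-weighted mean nearest-taxon distance of one community."""
    p, d = _pairwise(labels, weights, dist)
    if len(p) < 2:
        raise InputError("MNTD undefined for a single-species community")
    d = d.copy()
    np.fill_diagonal(d, np.inf)
    return float((p * d.min(axis=1)).sum())


def rao_q(labels: Sequence[str], weights, trait_dist: DistanceMatrix) -> float:
    """Rao's quadratic entropy sum_ij p_i p_j d_ij (0 for one species)."""
    p, d = _pairwise(labels, weights, trait_dist)
    return float(p @ d @ p)


def between_community_mpd(
    labels_x: Sequence[str],
    weights_x,
    labels_y: Sequence[str],
    weights_y,
    dist: DistanceMatrix,
) -> float:
    """Inter-community mean pairwise distance sum_{i,k} p_i q_k d_ik."""
    lx, p = community_weights(labels_x, weights_x)
    ly, q = community_weights(labels_y, weights_y)
    union = list(dict.fromkeys(lx + ly))  # communities may share species
    sub = dist.submatrix(union)
    ix = [sub.labels.index(lab) for lab in lx]
    iy = [sub.labels.index(lab) for lab in ly]
    d = sub.values[np.ix_(ix, iy)]
    return float(p @ d @ q)


def between_community_mpd_matrix(
    table: pd.DataFrame, dist: DistanceMatrix, zero_diagonal: bool = True
) -> DistanceMatrix:
    """Plot x plot inter-community MPD matrix from an abundance frame.

    Equivalent to calling :func:`between_community_mpd` on every plot pair
    (computed as W d W' with row-normalized weights W).  The diagonal —
    a plot's within-community MPD, not a self-dissimilarity — is zeroed so
    the result can feed rank-based ordination.
    """
    ids = [normalize_name(i) for i in table.index]
    cols = [normalize_name(c) for c in table.columns]
    w = table.to_numpy(dtype=float)
    if np.any(w < 0):
        raise InputError("negative abundance")
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        bad = [p for p, t in zip(ids, totals) if t <= 0]
        raise InputError(f"empty communities: {bad}")
    w = w / totals[:, None]
    d = dist.submatrix(cols).values
    m = w @ d @ w.T
    m = (m + m.T) / 2.0
    if zero_diagonal:
        np.fill_diagonal(m, 0.0)
    return DistanceMatrix(ids, m)


def trait_distances(trait_table: pd.DataFrame) -> DistanceMatrix:
    """Species x species Euclidean distance on z-scored traits / sqrt(n_traits).

    Rows are species, columns traits; missing values are not allowed.
    Zero-variance traits carry no information and are dropped with a
    warning.
    """
    df = trait_table.copy()
    df.index = [normalize_name(x) for x in df.index]
    if df.isna().any().any():
        raise InputError("trait table contains missing values")
    sd = df.std(ddof=1)
    dead = list(sd.index[(sd == 0) | sd.isna()])
    if dead:
        warnings.warn(f"dropping zero-variance trait(s): {dead}", stacklevel=2)
        df = df.drop(columns=dead)
    if df.shape[1] == 0:
        # all species identical: zero functional distance everywhere
        return DistanceMatrix(list(df.index), np.zeros((len(df), len(df))))
    z = (df - df.mean()) / df.std(ddof=1)
    x = z.to_numpy(dtype=float)
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    return DistanceMatrix(list(df.index), np.sqrt(sq / x.shape[1]))
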