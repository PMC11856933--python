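"""Shared domain containers and run configuration.

Every stage of the pipeline exchanges data through the small set of
validated containers defined here: per-plot host x parasitoid interaction
matrices, plot x species abundance tables, symmetric distance matrices,
plot covariate records, and the analysis configuration that owns the master
random seed.

Randomness: a single master seed in :class:`AnalysisConfig` is split into
independent per-stage streams with :func:`stream_rng`, which hashes a path
of string/int keys into a ``numpy.random.SeedSequence`` spawn key.  Any
stage can therefore be rerun in isolation and reproduce exactly the draws
it saw inside a full run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "InteractionMatrix",
    "AbundanceTable",
    "DistanceMatrix",
    "PlotCovariates",
    "AnalysisConfig",
    "normalize_name",
    "stream_rng",
    "stream_seed",
]


class InputError(ValueError):
    """Raised when an input file or container violates its contract."""


def normalize_name(name: object) -> str:
    """Normalize a species/plot label: trim, collapse whitespace, unify '_' and ' '.

    Matching is exact after this normalization; there is deliberately no
    fuzzy matching (a silent mismatch between a tree tip and a community
    column is worse than a loud error).
    """
    return " ".join(str(name).strip().replace("_", " ").split())


def _path_key(path: Sequence[object]) -> tuple[int, ...]:
    return tuple(zlib.crc32(repr(p).encode("utf8")) for p in path)


def stream_rng(master_seed: int, *path: object) -> np.random.Generator:
    """Independent generator for stage ``path`` under one master seed.

    The path (e.g. ``("nulls", plot_id, draw)``) is hashed (CRC-32 per
    element) into a SeedSequence spawn key, so streams for distinct paths
    are statistically independent and stable across runs and platforms.
    """
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=_path_key(path))
    )


def stream_seed(master_seed: int, *path: object) -> int:
    """A derived 31-bit integer seed for the stream at ``path``."""
    return int(stream_rng(master_seed, *path).integers(0, 2**31 - 1))


def _check_unique(labels: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise InputError(f"duplicate {axis} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class InteractionMatrix:
    """Per-plot host x parasitoid matrix of parasitized-brood-cell counts.

    Rows are hosts (lower trophic level), columns parasitoids (higher
    level); every downstream formula assumes this orientation.  ``counts``
    holds nonnegative integers; row sums ``A_i`` and column sums ``A_j``
    and the grand total ``m`` are derived on demand, never stored.
    """

    plot_id: str
    host_labels: tuple[str, ...]
    parasitoid_labels: tuple[str, ...]
    counts: np.ndarray

    def __init__(self, plot_id, host_labels, parasitoid_labels, counts):
        object.__setattr__(self, "plot_id", str(plot_id))
        object.__setattr__(
            self, "host_labels", tuple(normalize_name(h) for h in host_labels)
        )
        object.__setattr__(
            self,
            "parasitoid_labels",
            tuple(normalize_name(p) for p in parasitoid_labels),
        )
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise InputError("interaction counts must be a 2-D array")
        if arr.shape != (len(self.host_labels), len(self.parasitoid_labels)):
            raise InputError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.host_labels)} hosts x "
                f"{len(self.parasitoid_labels)} parasitoids"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InputError("interaction matrix needs at least one row and column")
        if not np.all(np.isfinite(arr.astype(float))):
            raise InputError("non-finite interaction count")
        if np.any(arr.astype(float) < 0):
            i, j = np.argwhere(arr.astype(float) < 0)[0]
            raise InputError(
                f"negative count at host {self.host_labels[i]!r} / "
                f"parasitoid {self.parasitoid_labels[j]!r}"
            )
        if not np.allclose(arr.astype(float), np.round(arr.astype(float))):
            i, j = np.argwhere(
                ~np.isclose(arr.astype(float), np.round(arr.astype(float)))
            )[0]
            raise InputError(
                f"non-integer count at host {self.host_labels[i]!r} / "
                f"parasitoid {self.parasitoid_labels[j]!r}"
            )
        _check_unique(self.host_labels, "host")
        _check_unique(self.parasitoid_labels, "parasitoid")
        arr = np.round(arr.astype(float)).astype(np.int64)
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)

    @property
    def n_hosts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_parasitoids(self) -> int:
        return self.counts.shape[1]

    @property
    def m(self) -> int:
        """Total number of interactions (parasitized brood cells)."""
        return int(self.counts.sum())

    @property
    def host_totals(self) -> np.ndarray:
        """Row sums A_i."""
        return self.counts.sum(axis=1)

    @property
    def parasitoid_totals(self) -> np.ndarray:
        """Column sums A_j."""
        return self.counts.sum(axis=0)

    @property
    def proportions(self) -> np.ndarray:
        """p_ij = counts / m."""
        m = self.m
        if m == 0:
            raise InputError(f"empty network (m=0) in plot {self.plot_id!r}")
        return self.counts / m

    def drop_empty(self) -> "InteractionMatrix":
        """Matrix restricted to rows/columns with at least one interaction."""
        r = self.host_totals > 0
        c = self.parasitoid_totals > 0
        if not r.any() or not c.any():
            raise InputError(f"empty network (m=0) in plot {self.plot_id!r}")
        return InteractionMatrix(
            self.plot_id,
            [h for h, k in zip(self.host_labels, r) if k],
            [p for p, k in zip(self.parasitoid_labels, c) if k],
            self.counts[np.ix_(r, c)],
        )


@dataclass(frozen=True)
class AbundanceTable:
    """Plot x species table of counts (or nonnegative weights, e.g. wood volume)."""

    plot_ids: tuple[str, ...]
    species_labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, plot_ids, species_labels, values):
        object.__setattr__(self, "plot_ids", tuple(normalize_name(p) for p in plot_ids))
        object.__setattr__(
            self, "species_labels", tuple(normalize_name(s) for s in species_labels)
        )
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(self.plot_ids), len(self.species_labels)):
            raise InputError("abundance table shape does not match labels")
        if not np.all(np.isfinite(arr)):
            raise InputError("non-finite abundance value")
        if np.any(arr < 0):
            raise InputError("negative abundance value")
        _check_unique(self.plot_ids, "plot")
        _check_unique(self.species_labels, "species")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def empty_plots(self) -> tuple[str, ...]:
        """Plots whose row is all zero (flagged; dropped by the pipeline)."""
        z = self.values.sum(axis=1) == 0
        return tuple(p for p, k in zip(self.plot_ids, z) if k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.plot_ids), columns=list(self.species_labels)
        )

    def row(self, plot_id: str) -> np.ndarray:
        return self.values[self.plot_ids.index(normalize_name(plot_id))]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over labelled items.

    One shared representation for patristic, trait and Morisita-Horn
    distances.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, labels, values, _tol: float = 1e-9):
        object.__setattr__(self, "labels", tuple(normalize_name(x) for x in labels))
        arr = np.asarray(values, dtype=float)
        n = len(self.labels)
        if arr.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(arr)):
            raise InputError("non-finite distance")
        if np.any(arr < -_tol):
            raise InputError("negative distance")
        if not np.allclose(arr, arr.T, atol=_tol):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=_tol):
            raise InputError("distance matrix diagonal is not zero")
        _check_unique(self.labels, "distance")
        arr = np.clip((arr + arr.T) / 2.0, 0.0, None)
        np.fill_diagonal(arr, 0.0)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        want = [normalize_name(x) for x in labels]
        idx = []
        for lab in want:
            if lab not in self.labels:
                raise InputError(f"label {lab!r} not in distance matrix")
            idx.append(self.labels.index(lab))
        idx = np.asarray(idx, dtype=int)
        return DistanceMatrix(want, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class PlotCovariates:
    """Per-plot design and environment record."""

    plot_id: str
    site: str
    tree_species_richness: int
    canopy_cover: float
    elevation: float
    slope: float
    eastness: float
    northness: float
    tree_mpd: float = np.nan
    tree_mntd: float = np.nan
    tree_raoq: float = np.nan

    def __post_init__(self):
        if self.tree_species_richness < 1:
            raise InputError("tree species richness must be >= 1")
        if not 0.0 <= self.canopy_cover <= 1.0:
            raise InputError("canopy cover must lie in [0, 1]")
        for v, name in ((self.eastness, "eastness"), (self.northness, "northness")):
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise InputError(f"{name} must lie in [-1, 1]")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of every stochastic stage of the analysis.

    Defaults follow the study protocol: 10,000 Patefield null draws per
    plot, 999 permutations for ordination-based tests, 9,999 for the
    cophylogenetic test, and 2-D NMDS.
    """

    random_seed: int = 0
    n_null: int = 10_000
    n_perm_ordination: int = 999
    n_perm_parafit: int = 9_999
    n_extinction_orders: int = 500
    nmds_dimensions: int = 2
    nmds_restarts: int = 20

    def __post_init__(self):
        for name in (
            "n_null",
            "n_perm_ordination",
            "n_perm_parafit",
            "n_extinction_orders",
            "nmds_dimensions",
            "nmds_restarts",
        ):
            if int(getattr(self, name)) < 1:
                raise InputError(f"{name} must be >= 1")

    def rng(self, *path: object) -> np.random.Generator:
        return stream_rng(self.random_seed, *path)

    def seed_for(self, *path: object) -> int:
        return stream_seed(self.random_seed, *path)
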