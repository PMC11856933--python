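"""Readers and writers for the pipeline's file formats.

Tables are plain comma-separated UTF-8 files with '.' decimals, first row
and first column carrying labels.  Trees are single-tree Newick strings
with branch lengths.  Parsing is strict: duplicate labels, negative counts
or branch lengths, and missing internal branch lengths are errors, never
silently repaired.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import (
    AbundanceTable,
    DistanceMatrix,
    InputError,
    InteractionMatrix,
    PlotCovariates,
    normalize_name,
)

__all__ = [
    "PhyloTree",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_abundance_table",
    "write_abundance_table",
    "read_covariates",
    "write_covariates",
    "read_newick",
    "newick_from_string",
    "write_newick",
    "patristic_distances",
]


class PhyloTree:
    """Rooted tree with branch lengths; tip labels are normalized strings.

    Branch-length units (substitutions/site, Myr, ...) are opaque — every
    consumer uses them only relatively.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [normalize_name(leaf.taxon.label) for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise InputError(f"duplicate tip label(s): {dup}")
        self.tip_labels: tuple[str, ...] = tuple(labels)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                where = (
                    f"tip {normalize_name(node.taxon.label)!r}"
                    if node.is_leaf() and node.taxon is not None
                    else "an internal edge"
                )
                raise InputError(f"missing branch length on {where}")
            if node.edge.length < 0:
                raise InputError("negative branch length")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def newick_from_string(newick: str) -> PhyloTree:
    """Parse a single-tree Newick string."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        if "Duplicate taxon" in str(exc) or "duplicate" in str(exc).lower():
            raise InputError(f"duplicate tip label: {exc}") from exc
        raise InputError(f"unparseable Newick string: {exc}") from exc
    return PhyloTree(tree)


def read_newick(path: str | Path) -> PhyloTree:
    return newick_from_string(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Symmetric matrix of tip-to-tip path lengths (sums of branch lengths)."""
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = {normalize_name(t.label): t for t in pdm.taxon_iter()}
    labels = list(tree.tip_labels)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)


def _read_label_frame(path: str | Path, normalize_columns: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = [normalize_name(x) for x in df.index]
    if normalize_columns:  # columns are species labels, not field names
        df.columns = [normalize_name(x) for x in df.columns]
    return df


def read_interaction_matrix(path: str | Path, plot_id: str) -> InteractionMatrix:
    """Read a host x parasitoid count matrix.

    Header row holds parasitoid labels, first column host labels, cells are
    nonnegative integer counts of parasitized brood cells.
    """
    df = _read_label_frame(path)
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise InputError(f"non-numeric cell in {path}")
    return InteractionMatrix(plot_id, list(df.index), list(df.columns), values)


def write_interaction_matrix(matrix: InteractionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.counts,
        index=list(matrix.host_labels),
        columns=list(matrix.parasitoid_labels),
    ).to_csv(path)


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a plot x species abundance (or wood-volume weight) table."""
    df = _read_label_frame(path)
    return AbundanceTable(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path)


_COVARIATE_COLUMNS = [
    "site",
    "tree_species_richness",
    "canopy_cover",
    "elevation",
    "slope",
    "eastness",
    "northness",
]


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the plot covariate table (index = plot id).

    Required columns: site, tree_species_richness, canopy_cover, elevation,
    slope, eastness, northness.  Tree diversity columns (tree_mpd,
    tree_mntd, tree_raoq) are optional — the pipeline computes them.
    """
    df = _read_label_frame(path, normalize_columns=False)
    missing = [c for c in _COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"covariate table missing column(s): {missing}")
    for plot, row in df.iterrows():  # row-level validation via the domain type
        try:
            PlotCovariates(
                plot_id=str(plot),
                site=str(row["site"]),
                tree_species_richness=int(row["tree_species_richness"]),
                canopy_cover=float(row["canopy_cover"]),
                elevation=float(row["elevation"]),
                slope=float(row["slope"]),
                eastness=float(row["eastness"]),
                northness=float(row["northness"]),
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"invalid covariates for plot {plot!r}: {exc}") from exc
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    dist.to_frame().to_csv(path)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = _read_label_frame(path)
    if list(df.index) != list(df.columns):
        raise InputError("distance matrix rows and columns disagree")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))
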