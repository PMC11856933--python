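"""Synthetic study-design generator.

Generates complete datasets shaped like a two-site tree-diversity
experiment with trap-nest sampling of cavity-nesting hosts (bees/wasps)
and their parasitoids:

* 88 plots over two sites on a species-richness gradient {1,2,4,8,16,24}
  (site A: 8 plots of each of 1,2,4,8 plus 6x16 and 2x24; site B the same
  plus 8 extra monocultures), of which 3 monocultures are marked as having
  no living trees and are excluded — 85 analysis plots;
* a 40-species tree pool (16 per site, non-overlapping, plus 8 shared
  species that complete the 24-species mixtures), a pure-birth phylogeny,
  7 leaf traits evolved by Brownian motion, and lognormal wood volumes;
* pools of ~56 host and ~50 parasitoid species with their own pure-birth
  phylogenies;
* per-plot host abundances (plot totals around 400 brood cells) and
  host x parasitoid interaction matrices whose totals are around 14
  parasitized cells per plot, mirroring the sparse networks such trap-nest
  studies yield;
* plot covariates (canopy cover increasing with richness, elevation,
  slope, aspect-derived eastness/northness).

Links are phylogenetically structured through a latent trait-matching
kernel: one Brownian trait per pool evolves on each phylogeny and a
parasitoid's propensity for a host is logistic in the negative squared
trait difference, mixed with a flat background at weight
(1 - phylo_signal_links).  Known, signed covariate effects (richness on
host abundance and on linkage, canopy on interaction evenness) make
sign-recovery experiments possible.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import expit

from .core import AbundanceTable, AnalysisConfig, InputError, InteractionMatrix, stream_rng
from .io import (
    PhyloTree,
    patristic_distances,
    write_abundance_table,
    write_covariates,
    write_interaction_matrix,
    write_newick,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the field design."""

    seed: int = 0
    richness_levels: tuple[int, ...] = (1, 2, 4, 8, 16, 24)
    n_tree_pool: int = 40
    n_host_species: int = 56
    n_parasitoid_species: int = 50
    n_excluded_plots: int = 3
    host_mean_abundance: float = 400.0
    # expected parasitized brood cells per plot in the pooled (multi-season)
    # matrix; per-season parasitoid catches of ~14 accumulate across the
    # five sampled seasons
    parasitoid_mean_cells: float = 70.0
    parasitoid_pool_base: float = 12.0
    # signed effect sizes (log-linear on the standardized predictor)
    beta_richness_host_abundance: float = 0.2
    beta_richness_linkage: float = 0.45
    beta_canopy_evenness: float = -0.4
    beta_canopy_richness: float = 0.025  # canopy slope per log2 richness step
    phylo_signal_links: float = 0.7  # lambda in [0, 1]
    overdispersion: float = 0.3  # lognormal sigma on plot totals
    trait_sigma: float = 1.0  # Brownian rate of the 7 leaf traits
    trait_phylo_signal: float = 0.5  # variance share of the Brownian component
    matched_trees: bool = False  # parasitoid tree mirrors the host tree

    def __post_init__(self):
        if not 0.0 <= self.phylo_signal_links <= 1.0:
            raise InputError("phylo_signal_links must lie in [0, 1]")
        if self.overdispersion < 0:
            raise InputError("overdispersion must be >= 0")


@dataclass
class SyntheticDataset:
    """One complete synthetic dataset, ready for every pipeline stage."""

    config: SimulationConfig
    plots: pd.DataFrame  # all 88 designed plots incl. the excluded flag
    covariates: pd.DataFrame  # analysis plots only
    tree_phylogeny: PhyloTree
    tree_traits: pd.DataFrame
    tree_communities: AbundanceTable  # wood volumes, analysis plots
    host_tree: PhyloTree
    parasitoid_tree: PhyloTree
    host_abundance: AbundanceTable
    parasitoid_abundance: AbundanceTable
    interactions: dict[str, InteractionMatrix] = field(default_factory=dict)

    @property
    def plot_ids(self) -> list[str]:
        return list(self.covariates.index)


_TRAIT_NAMES = ["sla", "toughness", "ldmc", "leaf_c", "leaf_cn", "leaf_mg", "leaf_ca"]


def _yule_tree(n_tips: int, prefix: str, seed: int) -> PhyloTree:
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_pyrandom.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"{prefix}{i + 1:02d}"
    return PhyloTree(tree)


def _brownian_traits(tree: PhyloTree, n_traits: int, sigma: float, rng) -> pd.DataFrame:
    """Traits evolved by Brownian motion along the tree's branches."""
    values: dict[int, np.ndarray] = {}
    dtree = tree.dendropy_tree
    rows = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(n_traits)
        else:
            step = rng.normal(0.0, sigma * np.sqrt(max(node.edge.length, 0.0)), n_traits)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            rows[node.taxon.label.replace("_", " ")] = values[id(node)]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.loc[list(tree.tip_labels)]
    df.columns = [f"trait_{k + 1}" for k in range(n_traits)]
    return df


def _plot_design(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    per_site = {1: 8, 2: 8, 4: 8, 8: 8, 16: 6, 24: 2}
    for site in ("A", "B"):
        counts = dict(per_site)
        if site == "B":
            counts[1] += 8  # extra monocultures
        for richness in config.richness_levels:
            for _ in range(counts.get(richness, 0)):
                rows.append({"site": site, "tree_species_richness": richness})
    df = pd.DataFrame(rows)
    # hyphenated ids survive label normalization (underscores become spaces)
    df.index = [f"plot-{i + 1:03d}" for i in range(len(df))]
    # plots lost to complete tree mortality; monocultures are the ones at risk
    mono = df.index[df["tree_species_richness"] == 1]
    dead = rng.choice(mono, size=config.n_excluded_plots, replace=False)
    df["excluded"] = df.index.isin(dead)
    return df


def simulate_trees_and_traits(
    config: SimulationConfig,
) -> tuple[PhyloTree, pd.DataFrame, AbundanceTable, pd.DataFrame]:
    """Tree phylogeny, leaf traits, per-plot wood-volume communities, design.

    The pool is split 16/16 between the sites with 8 shared species that
    only occur in the 24-species mixtures.
    """
    rng = stream_rng(config.seed, "trees")
    design = _plot_design(config, stream_rng(config.seed, "design"))
    tree = _yule_tree(config.n_tree_pool, "T", stream_rng(config.seed, "tree_topology").integers(2**31 - 1))
    trng = stream_rng(config.seed, "tree_traits")
    traits = _brownian_traits(tree, len(_TRAIT_NAMES), config.trait_sigma, trng)
    # leaf traits are only partly phylogenetically conserved: mix the
    # Brownian component with species-specific variation
    w = float(np.clip(config.trait_phylo_signal, 0.0, 1.0))
    z = (traits - traits.mean()) / traits.std(ddof=1).replace(0.0, 1.0)
    noise = pd.DataFrame(
        trng.normal(size=traits.shape), index=traits.index, columns=traits.columns
    )
    traits = np.sqrt(w) * z + np.sqrt(1.0 - w) * noise
    traits.columns = _TRAIT_NAMES

    labels = list(tree.tip_labels)
    site_pool = {"A": labels[:16], "B": labels[16:32]}
    shared = labels[32:40]
    pdist = patristic_distances(tree)
    dbar = pdist.values[np.triu_indices(len(labels), 1)].mean()

    analysis = design[~design["excluded"]]
    volumes = np.zeros((len(analysis), len(labels)))
    for r, (plot, row) in enumerate(analysis.iterrows()):
        richness = int(row["tree_species_richness"])
        pool = list(site_pool[row["site"]])
        if richness >= len(pool):  # the 24-mixtures add the shared species
            chosen = pool + list(shared[: richness - len(pool)])
        else:
            # low-richness compositions are phylogenetically clustered around
            # a focal species (clustering relaxes as richness grows), which
            # yields the strong positive richness-MPD association a nested
            # diversity design exhibits
            focal = pool[int(rng.integers(len(pool)))]
            d_focal = pdist.submatrix(pool).values[pool.index(focal)]
            tau = 0.1 * dbar * richness
            w = np.exp(-d_focal / tau)
            w[pool.index(focal)] = 0.0
            others = rng.choice(
                pool, size=richness - 1, replace=False, p=w / w.sum()
            ) if richness > 1 else []
            chosen = [focal] + list(others)
        idx = [labels.index(s) for s in chosen]
        volumes[r, idx] = rng.lognormal(mean=0.0, sigma=0.6, size=len(idx))
    communities = AbundanceTable(list(analysis.index), labels, volumes)
    return tree, traits, communities, design


def simulate_covariates(config: SimulationConfig, design: pd.DataFrame) -> pd.DataFrame:
    """Plot covariates for the analysis plots (canopy rises with richness)."""
    rng = stream_rng(config.seed, "covariates")
    analysis = design[~design["excluded"]]
    n = len(analysis)
    log2_r = np.log2(analysis["tree_species_richness"].astype(float).to_numpy())
    canopy = np.clip(
        0.30 + config.beta_canopy_richness * log2_r + rng.normal(0.0, 0.08, n),
        0.02,
        0.98,
    )
    elevation = np.where(
        analysis["site"].to_numpy() == "A",
        rng.normal(210.0, 40.0, n),
        rng.normal(260.0, 40.0, n),
    )
    slope = rng.uniform(5.0, 40.0, n)
    aspect = rng.uniform(0.0, 2.0 * np.pi, n)
    return pd.DataFrame(
        {
            "site": analysis["site"].to_numpy(),
            "tree_species_richness": analysis["tree_species_richness"].to_numpy(),
            "canopy_cover": canopy,
            "elevation": elevation,
            "slope": slope,
            "eastness": np.sin(aspect),
            "northness": np.cos(aspect),
        },
        index=analysis.index,
    )


def _matching_kernel(host_vals: np.ndarray, para_vals: np.ndarray, lam: float) -> np.ndarray:
    """Parasitoid x host link propensities from latent trait matching.

    Logistic in the negative squared latent-trait difference, thresholded
    and scaled per parasitoid so each accepts roughly its two
    best-matching hosts and rejects hosts beyond its fifth — the strong
    specialization that makes trap-nest networks depart from fixed-margin
    nulls in nearly every plot.  Mixed with a flat background at weight
    (1 - lam); lam = 0 gives completely unstructured host use.
    """
    d2 = (para_vals[:, None] - host_vals[None, :]) ** 2
    srt = np.sort(d2, axis=1)
    k2 = min(1, d2.shape[1] - 1)
    k5 = min(4, d2.shape[1] - 1)
    t0 = srt[:, [k2]]
    scale = np.maximum((srt[:, [k5]] - srt[:, [k2]]) / 4.0, 1e-9)
    kernel = expit((t0 - d2) / scale)
    return lam * kernel + (1.0 - lam) * max(kernel.mean(), 1e-3)


def simulate_host_parasitoid_webs(
    config: SimulationConfig, covariates: pd.DataFrame
) -> tuple[PhyloTree, PhyloTree, AbundanceTable, AbundanceTable, dict[str, InteractionMatrix]]:
    """Host/parasitoid phylogenies, abundance tables and per-plot networks."""
    rng = stream_rng(config.seed, "webs")
    host_tree = _yule_tree(
        config.n_host_species, "H", stream_rng(config.seed, "host_topology").integers(2**31 - 1)
    )
    bm = stream_rng(config.seed, "latent_traits")
    th = _brownian_traits(host_tree, 1, 1.0, bm).to_numpy()[:, 0]
    th = (th - th.mean()) / (th.std() + 1e-12)
    if config.matched_trees:
        # cospeciation scenario: the parasitoid tree is the host tree pruned
        # to n_parasitoid_species tips and parasitoids inherit their host
        # counterpart's latent trait value
        t2 = dendropy.Tree.get(
            data=host_tree.as_newick(), schema="newick", preserve_underscores=True
        )
        host_order = list(host_tree.tip_labels)
        keep = host_order[: config.n_parasitoid_species]
        t2.retain_taxa_with_labels([lab.replace(" ", "_") for lab in keep] + keep)
        kept_sources = []
        for i, leaf in enumerate(t2.leaf_node_iter()):
            kept_sources.append(leaf.taxon.label.replace("_", " "))
            leaf.taxon.label = f"P{i + 1:02d}"
        parasitoid_tree = PhyloTree(t2)
        tp = np.array([th[host_order.index(lab)] for lab in kept_sources])
        tp = tp + bm.normal(0.0, 0.05, len(tp))
    else:
        parasitoid_tree = _yule_tree(
            config.n_parasitoid_species,
            "P",
            stream_rng(config.seed, "para_topology").integers(2**31 - 1),
        )
        tp = _brownian_traits(parasitoid_tree, 1, 1.0, bm).to_numpy()[:, 0]
        tp = (tp - tp.mean()) / (tp.std() + 1e-12)
    kernel = _matching_kernel(th, tp, config.phylo_signal_links)

    hosts = list(host_tree.tip_labels)
    paras = list(parasitoid_tree.tip_labels)
    n_h, n_p = len(hosts), len(paras)

    # species-level base abundances and environmental loadings (hosts
    # respond to canopy and elevation, phylogenetically structured)
    host_base = rng.lognormal(0.0, 0.8, n_h)
    host_canopy_load = _brownian_traits(host_tree, 1, 0.4, bm).to_numpy()[:, 0]
    host_elev_load = _brownian_traits(host_tree, 1, 0.4, bm).to_numpy()[:, 0]
    para_base = rng.lognormal(0.0, 0.8, n_p)

    z_rich = covariates["tree_species_richness"].astype(float).apply(np.log2)
    z_rich = ((z_rich - z_rich.mean()) / z_rich.std(ddof=1)).to_numpy()
    z_can = covariates["canopy_cover"].astype(float)
    z_can = ((z_can - z_can.mean()) / z_can.std(ddof=1)).to_numpy()
    z_elev = covariates["elevation"].astype(float)
    z_elev = ((z_elev - z_elev.mean()) / z_elev.std(ddof=1)).to_numpy()

    host_counts = np.zeros((len(covariates), n_h), dtype=np.int64)
    para_counts = np.zeros((len(covariates), n_p), dtype=np.int64)
    interactions: dict[str, InteractionMatrix] = {}
    for r, plot in enumerate(covariates.index):
        mu_total = config.host_mean_abundance * np.exp(
            config.beta_richness_host_abundance * z_rich[r]
        )
        sigma = config.overdispersion
        total = int(
            np.round(rng.lognormal(np.log(mu_total) - sigma**2 / 2.0, sigma))
        )
        total = max(total, 20)
        w = host_base * np.exp(
            0.5 * host_canopy_load * z_can[r] + 0.5 * host_elev_load * z_elev[r]
        )
        host_row = rng.multinomial(total, w / w.sum())
        host_counts[r] = host_row

        # parasitoid species active in this plot (more with higher richness)
        s_p = int(
            np.clip(
                np.round(
                    config.parasitoid_pool_base
                    * np.exp(config.beta_richness_linkage * z_rich[r])
                    * rng.lognormal(0.0, 0.2)
                ),
                3,
                n_p,
            )
        )
        active = rng.choice(n_p, size=s_p, replace=False, p=para_base / para_base.sum())

        mu_cells = config.parasitoid_mean_cells * np.exp(
            config.beta_richness_linkage * z_rich[r]
        )
        m_plot = int(rng.poisson(mu_cells))
        if m_plot < 1 or host_row.sum() == 0:
            continue  # plot without parasitized cells; dropped downstream

        probs = host_row[:, None] * kernel.T[:, active] * para_base[None, active]
        if probs.sum() <= 0:
            continue
        probs = probs / probs.sum()
        # closed canopies concentrate interactions on the preferred host-
        # parasitoid pairs: sharpening the cell distribution lowers the
        # measured interaction evenness (the canopy -> evenness effect)
        exponent = np.exp(-config.beta_canopy_evenness * z_can[r])
        probs = probs**exponent
        probs = probs / probs.sum()
        cells = rng.multinomial(m_plot, probs.ravel()).reshape(probs.shape)
        para_counts[r, active] += cells.sum(axis=0)
        keep_h = cells.sum(axis=1) > 0
        keep_p = cells.sum(axis=0) > 0
        interactions[plot] = InteractionMatrix(
            plot,
            [hosts[i] for i in np.flatnonzero(keep_h)],
            [paras[j] for j in active[keep_p]],
            cells[np.ix_(keep_h, keep_p)],
        )

    host_table = AbundanceTable(list(covariates.index), hosts, host_counts)
    para_table = AbundanceTable(list(covariates.index), paras, para_counts)
    return host_tree, parasitoid_tree, host_table, para_table, interactions


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """One complete synthetic dataset under the configured study conditions."""
    config = config or SimulationConfig()
    tree, traits, communities, design = simulate_trees_and_traits(config)
    covariates = simulate_covariates(config, design)
    host_tree, para_tree, host_ab, para_ab, inter = simulate_host_parasitoid_webs(
        config, covariates
    )
    return SyntheticDataset(
        config=config,
        plots=design,
        covariates=covariates,
        tree_phylogeny=tree,
        tree_traits=traits,
        tree_communities=communities,
        host_tree=host_tree,
        parasitoid_tree=para_tree,
        host_abundance=host_ab,
        parasitoid_abundance=para_ab,
        interactions=inter,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write every input file the pipeline stages read (CSV + Newick)."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    write_newick(dataset.tree_phylogeny, out / "tree_phylogeny.nwk")
    write_newick(dataset.host_tree, out / "host_phylogeny.nwk")
    write_newick(dataset.parasitoid_tree, out / "parasitoid_phylogeny.nwk")
    dataset.tree_traits.to_csv(out / "tree_traits.csv")
    write_abundance_table(dataset.tree_communities, out / "tree_communities.csv")
    write_abundance_table(dataset.host_abundance, out / "host_abundance.csv")
    write_abundance_table(dataset.parasitoid_abundance, out / "parasitoid_abundance.csv")
    write_covariates(dataset.covariates, out / "plot_covariates.csv")
    dataset.plots.to_csv(out / "plot_design.csv")
    for plot, matrix in dataset.interactions.items():
        write_interaction_matrix(matrix, out / "matrices" / f"{plot}.csv")
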