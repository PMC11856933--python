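"""End-to-end orchestration of the plot-level analysis.

Stages (each independently runnable from cached upstream outputs):

1. tree community metrics — wood-volume-weighted MPD and MNTD on the tree
   phylogeny, Rao's Q on leaf-trait distances (monocultures yield NaN and
   are flagged);
2. network metrics — the five quantitative indices per plot;
3. Patefield null tests per plot and index, with the per-index count of
   plots whose observed value departs from the fixed-margin null;
4. composition — Morisita-Horn NMDS for trees, hosts and parasitoids plus
   phylogenetic-composition NMDS (between-community MPD) for hosts and
   parasitoids, each with fitted environmental vectors; Mantel tests and
   PERMANOVA between/on the dissimilarity matrices;
5. ParaFit cophylogenetic test on the pooled host-parasitoid links;
6. standardized linear models of each index (primary: tree species
   richness; alternative: tree MPD) with AICc backward simplification.

``run_all`` executes everything, writes CSV/JSON outputs, and returns a
manifest recording configuration, seeds, exclusions and per-stage shapes.
Plots whose pooled host community or interaction matrix is empty are
dropped from network/evenness analyses with a logged count; tree-only
metrics keep every analysis plot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import AnalysisConfig, DistanceMatrix, InputError
from .cophylogeny import ParafitResult, parafit_global
from .io import (
    PhyloTree,
    patristic_distances,
    read_abundance_table,
    read_covariates,
    read_interaction_matrix,
    read_newick,
)
from .networks import INDEX_NAMES, all_indices
from .nulls import null_test_all
from .ordination import envfit, mantel, morisita_horn_matrix, nmds, permanova
from .phylo import (
    between_community_mpd_matrix,
    mntd,
    mpd,
    rao_q,
    trait_distances,
)
from .regression import (
    ALT_MODEL_TERMS,
    FULL_MODEL_TERMS,
    ModelFit,
    simplify_by_aicc,
    standardize_predictors,
)
from .simulate import SyntheticDataset, simulate_dataset

log = logging.getLogger("trophicweb")

__all__ = [
    "load_dataset",
    "tree_community_metrics",
    "network_metrics_table",
    "null_summary",
    "composition_analysis",
    "pooled_links",
    "regression_models",
    "run_all",
]


def load_dataset(data_dir: str | Path) -> SyntheticDataset:
    """Load a dataset directory written by :func:`trophicweb.simulate.write_dataset`."""
    d = Path(data_dir)
    required = [
        "tree_phylogeny.nwk",
        "host_phylogeny.nwk",
        "parasitoid_phylogeny.nwk",
        "tree_traits.csv",
        "tree_communities.csv",
        "host_abundance.csv",
        "parasitoid_abundance.csv",
        "plot_covariates.csv",
    ]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise InputError(f"data directory {d} is missing: {missing}")
    covariates = read_covariates(d / "plot_covariates.csv")
    interactions = {}
    for path in sorted((d / "matrices").glob("*.csv")):
        plot = path.stem
        interactions[plot] = read_interaction_matrix(path, plot)
    plots_path = d / "plot_design.csv"
    plots = pd.read_csv(plots_path, index_col=0) if plots_path.exists() else covariates
    return SyntheticDataset(
        config=None,
        plots=plots,
        covariates=covariates,
        tree_phylogeny=read_newick(d / "tree_phylogeny.nwk"),
        tree_traits=pd.read_csv(d / "tree_traits.csv", index_col=0),
        tree_communities=read_abundance_table(d / "tree_communities.csv"),
        host_tree=read_newick(d / "host_phylogeny.nwk"),
        parasitoid_tree=read_newick(d / "parasitoid_phylogeny.nwk"),
        host_abundance=read_abundance_table(d / "host_abundance.csv"),
        parasitoid_abundance=read_abundance_table(d / "parasitoid_abundance.csv"),
        interactions=interactions,
    )


def tree_community_metrics(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-plot wood-volume-weighted tree MPD, MNTD and Rao's Q."""
    pdist_tree = patristic_distances(dataset.tree_phylogeny)
    tdist = trait_distances(dataset.tree_traits)
    comm = dataset.tree_communities.to_frame()
    rows = {}
    for plot, row in comm.iterrows():
        present = row[row > 0]
        labels, weights = list(present.index), present.to_numpy()
        if len(labels) < 2:
            # monoculture: pairwise diversity undefined
            rows[plot] = {"tree_mpd": np.nan, "tree_mntd": np.nan, "tree_raoq": 0.0}
            continue
        rows[plot] = {
            "tree_mpd": mpd(labels, weights, pdist_tree),
            "tree_mntd": mntd(labels, weights, pdist_tree),
            "tree_raoq": rao_q(labels, weights, tdist),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def network_metrics_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """The five indices per plot; NaN rows for plots without a usable network."""
    rows = {}
    for plot in dataset.covariates.index:
        matrix = dataset.interactions.get(plot)
        if matrix is None or matrix.m < 1:
            rows[plot] = {k: np.nan for k in INDEX_NAMES}
            continue
        matrix = matrix.drop_empty()
        try:
            rows[plot] = all_indices(matrix).as_dict()
        except InputError:
            # 1x1 networks: evenness undefined, other indices still valid
            vals = {k: np.nan for k in INDEX_NAMES}
            from .networks import COUNT_INDEX_FNS

            for k in INDEX_NAMES:
                try:
                    vals[k] = COUNT_INDEX_FNS[k](matrix.counts.astype(float))
                except InputError:
                    pass
            rows[plot] = vals
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(dataset.covariates.index)
    n_missing = int(df["linkage_density"].isna().sum())
    if n_missing:
        log.info("dropped %d plot(s) without a usable network", n_missing)
    return df


def null_summary(
    dataset: SyntheticDataset,
    config: AnalysisConfig,
    n_null: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Patefield null tests for every plot and index.

    Returns the long per-plot table (observed, null mean/sd, z, p) and the
    per-index count of plots with p < alpha — the "x out of n plots depart
    from the null" summary.
    """
    rows = []
    for plot in dataset.covariates.index:
        matrix = dataset.interactions.get(plot)
        if matrix is None or matrix.m < 1:
            continue
        matrix = matrix.drop_empty()
        names = [
            k
            for k in INDEX_NAMES
            if not (k == "interaction_evenness" and matrix.n_hosts * matrix.n_parasitoids < 2)
        ]
        res = null_test_all(matrix, config, names, n_null)
        for k, nd in res.items():
            rows.append(
                {
                    "plot": plot,
                    "index": k,
                    "observed": nd.observed,
                    "null_mean": float(np.mean(nd.null_values)),
                    "null_sd": float(np.std(nd.null_values, ddof=1)),
                    "z": nd.z_score,
                    "p": nd.p_value,
                }
            )
    table = pd.DataFrame(rows)
    counts = (
        table[table["p"] < alpha].groupby("index")["plot"].count().reindex(INDEX_NAMES).fillna(0).astype(int)
    )
    return table, counts


def _phylo_composition_matrix(
    table: pd.DataFrame, tree: PhyloTree
) -> DistanceMatrix:
    dist = patristic_distances(tree)
    return between_community_mpd_matrix(table, dist)


def composition_analysis(
    dataset: SyntheticDataset, config: AnalysisConfig
) -> dict[str, dict]:
    """NMDS + envfit for each community, plus Mantel tests and PERMANOVA.

    Communities ordinated: tree, host and parasitoid species composition
    (Morisita-Horn) and host/parasitoid phylogenetic composition
    (between-community MPD).  Only plots with nonempty host and parasitoid
    communities enter, so all five matrices share one plot set.
    """
    hosts = dataset.host_abundance.to_frame()
    paras = dataset.parasitoid_abundance.to_frame()
    trees = dataset.tree_communities.to_frame()
    ok = (hosts.sum(axis=1) > 0) & (paras.sum(axis=1) > 0) & (trees.sum(axis=1) > 0)
    keep = list(hosts.index[ok])
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("composition: dropped %d plot(s) with empty communities", n_dropped)
    hosts, paras, trees = hosts.loc[keep], paras.loc[keep], trees.loc[keep]

    dissim = {
        "tree_species": morisita_horn_matrix(trees),
        "host_species": morisita_horn_matrix(hosts),
        "parasitoid_species": morisita_horn_matrix(paras),
        "host_phylo": _phylo_composition_matrix(hosts, dataset.host_tree),
        "parasitoid_phylo": _phylo_composition_matrix(paras, dataset.parasitoid_tree),
    }

    metrics = tree_community_metrics(dataset).loc[keep]
    cov = dataset.covariates.loc[keep]
    env = pd.DataFrame(
        {
            "log2_richness": np.log2(cov["tree_species_richness"].astype(float)),
            "tree_raoq": metrics["tree_raoq"],
            "tree_mpd": metrics["tree_mpd"].fillna(0.0),
            "canopy_cover": cov["canopy_cover"],
            "elevation": cov["elevation"],
            "eastness": cov["eastness"],
            "northness": cov["northness"],
            "slope": cov["slope"],
        },
        index=keep,
    )

    out: dict[str, dict] = {"n_plots": len(keep), "n_dropped": n_dropped}
    for name, dmat in dissim.items():
        ordination = nmds(dmat, config)
        fits = envfit(ordination, env, config)
        out[name] = {
            "ordination": ordination,
            "stress": ordination.stress,
            "envfit": pd.DataFrame(
                {
                    "variable": [f.variable for f in fits],
                    "r_squared": [f.r_squared for f in fits],
                    "p": [f.p_value for f in fits],
                    "nmds1": [f.direction[0] for f in fits],
                    "nmds2": [f.direction[1] for f in fits],
                }
            ).set_index("variable"),
        }

    pairs = [
        ("tree_species", "host_species"),
        ("tree_species", "parasitoid_species"),
        ("host_species", "parasitoid_species"),
        ("host_phylo", "parasitoid_phylo"),
    ]
    mantel_rows = []
    for a, b in pairs:
        r, p = mantel(
            dissim[a], dissim[b], config.n_perm_ordination, config.seed_for("mantel", a, b)
        )
        mantel_rows.append({"pair": f"{a}~{b}", "r": r, "p": p})
    out["mantel"] = pd.DataFrame(mantel_rows).set_index("pair")

    perm_design = env[["log2_richness", "canopy_cover", "elevation", "eastness"]]
    out["permanova"] = {
        name: permanova(
            dissim[name],
            perm_design,
            n_perm=config.n_perm_ordination,
            seed=config.seed_for("permanova", name),
        )
        for name in ("host_species", "parasitoid_species")
    }
    out["dissimilarity"] = dissim
    return out


def pooled_links(dataset: SyntheticDataset) -> tuple[np.ndarray, list[str], list[str]]:
    """Binary parasitoid x host association pooled over all plots.

    Species without any realized link are excluded (as are species absent
    from the corresponding phylogeny).
    """
    hosts = list(dataset.host_tree.tip_labels)
    paras = list(dataset.parasitoid_tree.tip_labels)
    a = np.zeros((len(paras), len(hosts)))
    for matrix in dataset.interactions.values():
        for i, h in enumerate(matrix.host_labels):
            if h not in hosts:
                continue
            hi = hosts.index(h)
            for j, p in enumerate(matrix.parasitoid_labels):
                if p not in paras:
                    continue
                if matrix.counts[i, j] > 0:
                    a[paras.index(p), hi] = 1.0
    keep_p = a.sum(axis=1) > 0
    keep_h = a.sum(axis=0) > 0
    return (
        a[np.ix_(keep_p, keep_h)],
        [h for h, k in zip(hosts, keep_h) if k],
        [p for p, k in zip(paras, keep_p) if k],
    )


def parafit_analysis(dataset: SyntheticDataset, config: AnalysisConfig) -> ParafitResult:
    """ParaFit test of the pooled host-parasitoid association."""
    links, host_labels, para_labels = pooled_links(dataset)
    host_d = patristic_distances(dataset.host_tree).submatrix(host_labels)
    para_d = patristic_distances(dataset.parasitoid_tree).submatrix(para_labels)
    return parafit_global(host_d, para_d, links, config)


def regression_models(
    dataset: SyntheticDataset,
    indices: pd.DataFrame,
    tree_metrics: pd.DataFrame,
    simplify: bool = True,
) -> dict[str, dict[str, ModelFit]]:
    """Primary (richness) and alternative (tree MPD) models per index."""
    cov = dataset.covariates.join(tree_metrics)
    design = standardize_predictors(cov)
    out: dict[str, dict[str, ModelFit]] = {}
    for index_name in indices.columns:
        y = indices[index_name]
        fits = {}
        for label, terms in (("primary", FULL_MODEL_TERMS), ("alternative", ALT_MODEL_TERMS)):
            terms = [
                t
                for t in terms
                if all(p in list(design.columns) + ["site"] for p in t.split(":"))
            ]
            used = sorted({p for t in terms for p in t.split(":")})
            keep = ~(y.isna() | design[used].isna().any(axis=1))
            if keep.sum() <= len(terms) + 3:
                continue
            if simplify:
                fits[label] = simplify_by_aicc(
                    y[keep], design[keep], terms, name=index_name
                )
            else:
                from .regression import fit_index_model

                fits[label] = fit_index_model(
                    y[keep], design[keep], terms, name=index_name
                )
        out[index_name] = fits
    return out


def run_all(
    config: AnalysisConfig,
    data: SyntheticDataset | str | Path | None = None,
    out_dir: str | Path | None = None,
    n_null: int | None = None,
) -> dict:
    """Execute every stage and return (and optionally write) the manifest."""
    if data is None:
        from .simulate import SimulationConfig

        data = simulate_dataset(SimulationConfig(seed=config.random_seed))
    elif not isinstance(data, SyntheticDataset):
        data = load_dataset(data)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    tree_metrics = tree_community_metrics(data)
    indices = network_metrics_table(data)
    null_table, null_counts = null_summary(data, config, n_null)
    comp = composition_analysis(data, config)
    pfit = parafit_analysis(data, config)
    models = regression_models(data, indices, tree_metrics)

    manifest["stages"]["tree_metrics"] = {"n_plots": len(tree_metrics)}
    manifest["stages"]["network_metrics"] = {
        "n_plots": int(indices["linkage_density"].notna().sum())
    }
    manifest["stages"]["nulls"] = {
        "n_null": int(n_null or config.n_null),
        "significant_counts": {k: int(v) for k, v in null_counts.items()},
        "n_networks": int(null_table["plot"].nunique()) if len(null_table) else 0,
    }
    manifest["stages"]["composition"] = {
        "n_plots": comp["n_plots"],
        "stress": {
            k: comp[k]["stress"]
            for k in (
                "tree_species",
                "host_species",
                "parasitoid_species",
                "host_phylo",
                "parasitoid_phylo",
            )
        },
    }
    manifest["stages"]["parafit"] = {
        "global_stat": pfit.global_stat,
        "p_value": pfit.p_value,
        "n_perm": pfit.n_perm,
    }
    manifest["stages"]["models"] = {
        idx: {
            label: {"terms": list(fit.terms), "aicc": fit.aicc, "r2": fit.r_squared}
            for label, fit in fits.items()
        }
        for idx, fits in models.items()
    }

    if out is not None:
        tree_metrics.to_csv(out / "tree_metrics.csv")
        indices.to_csv(out / "network_indices.csv")
        null_table.to_csv(out / "null_tests.csv", index=False)
        null_counts.to_frame("n_significant").to_csv(out / "null_counts.csv")
        for name in ("host_species", "parasitoid_species", "tree_species", "host_phylo", "parasitoid_phylo"):
            comp[name]["ordination"].scores_frame().to_csv(out / f"nmds_{name}.csv")
            comp[name]["envfit"].to_csv(out / f"envfit_{name}.csv")
        comp["mantel"].to_csv(out / "mantel.csv")
        for name, table in comp["permanova"].items():
            table.to_csv(out / f"permanova_{name}.csv")
        coef_rows = []
        for idx, fits in models.items():
            for label, fit in fits.items():
                block = fit.coefficients.copy()
                block.insert(0, "model", label)
                block.insert(0, "response", idx)
                coef_rows.append(block.reset_index(names="term"))
        if coef_rows:
            pd.concat(coef_rows).to_csv(out / "model_coefficients.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    manifest["_objects"] = {
        "tree_metrics": tree_metrics,
        "indices": indices,
        "null_table": null_table,
        "null_counts": null_counts,
        "composition": comp,
        "parafit": pfit,
        "models": models,
    }
    return manifest
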