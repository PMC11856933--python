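"""Compositional dissimilarity, NMDS ordination, and permutation tests.

The compositional workflow mirrors the standard community-ecology recipe:
abundance-based Morisita-Horn dissimilarities between plots, 2-D non-metric
multidimensional scaling (Kruskal stress-1, primary tie treatment, best of
several restarts plus a metric PCoA start, final scores centered and
principal-components rotated), then permutation-based inference — fitting
environmental vectors to the axis scores (envfit), Mantel correlation
between two distance matrices, and PERMANOVA with marginal term tests.

All permutation p-values use the add-one rule (count + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .core import AnalysisConfig, DistanceMatrix, InputError, normalize_name

__all__ = [
    "OrdinationResult",
    "EnvFitResult",
    "morisita_horn",
    "morisita_horn_matrix",
    "nmds",
    "envfit",
    "mantel",
    "permanova",
    "procrustes_error",
]


# ---------------------------------------------------------------------------
# Morisita-Horn


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity between two abundance vectors in [0, 1].

    1 - 2 sum(x_i y_i) / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y), with
    X = sum(x), Y = sum(y); insensitive to rescaling either community.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("abundance vectors differ in length")
    if np.any(x < 0) or np.any(y < 0):
        raise InputError("negative abundance")
    bx, by = x.sum(), y.sum()
    if bx <= 0 or by <= 0:
        raise InputError("all-zero abundance vector")
    sim = 2.0 * (x * y).sum() / (((x**2).sum() / bx**2 + (y**2).sum() / by**2) * bx * by)
    return float(min(1.0, max(0.0, 1.0 - sim)))


def morisita_horn_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Plot x plot Morisita-Horn dissimilarity matrix from an abundance frame."""
    ids = [normalize_name(i) for i in table.index]
    v = table.to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = morisita_horn(v[i], v[j])
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# NMDS


@dataclass(frozen=True)
class OrdinationResult:
    """Best-restart NMDS configuration with Kruskal stress-1."""

    plot_ids: tuple[str, ...]
    scores: np.ndarray  # (n_plots, k), centered, PC-rotated
    stress: float
    converged: bool
    n_restarts_used: int
    degenerate: bool = False
    stress_trace: tuple[float, ...] = ()  # accepted stresses of the best start

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.plot_ids), columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    return a - a.mean(0, keepdims=True) - a.mean(1, keepdims=True) + a.mean()


def _pcoa_start(d: np.ndarray, k: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(_gower_center(d))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order][:k], vecs[:, order][:, :k]
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _fit_disparities(d: np.ndarray, order: np.ndarray, iso: IsotonicRegression) -> np.ndarray:
    """Monotone (primary-ties) least-squares fit of configuration distances."""
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
    return dhat


def _nmds_single(
    delta: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    """Minimize stress-1 from one start; accepted iterations never increase it."""
    n = x0.shape[0]
    iso = IsotonicRegression(increasing=True)
    x = x0.copy()
    d = pdist(x)
    # primary tie treatment: within blocks of equal dissimilarity the fit
    # may follow the configuration distances, so sort ties by d as well
    order = np.lexsort((d, delta))
    dhat = _fit_disparities(d, order, iso)
    stress = _stress1(d, dhat)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        # Guttman transform toward the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / np.where(d > 0, d, 1.0), 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x_new = b @ x / n
        d_new = pdist(x_new)
        order = np.lexsort((d_new, delta))
        dhat_new = _fit_disparities(d_new, order, iso)
        stress_new = _stress1(d_new, dhat_new)
        if stress_new >= stress - tol:
            converged = stress_new >= stress or stress - stress_new < tol
            if stress_new < stress:  # tiny improvement still accepted
                x, d, dhat, stress = x_new, d_new, dhat_new, stress_new
                trace.append(stress)
            break
        x, d, dhat, stress = x_new, d_new, dhat_new, stress_new
        trace.append(stress)
    return x, stress, converged, trace


def _pc_rotate(x: np.ndarray) -> np.ndarray:
    """Center and rotate scores so axis 1 carries maximal variance.

    Sign convention: each axis is flipped so its largest-|value| score is
    positive, making results reproducible across runs.
    """
    x = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for k in range(x.shape[1]):
        if x[np.argmax(np.abs(x[:, k])), k] < 0:
            x[:, k] = -x[:, k]
    return x


def nmds(
    dissim: DistanceMatrix,
    config: AnalysisConfig | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix (Kruskal stress-1).

    Runs a metric PCoA start plus ``config.nmds_restarts`` random starts
    and keeps the configuration with lowest stress.  Scores are centered
    and PC-rotated.  All-equal dissimilarities are a degenerate (rank-free)
    case: the PCoA configuration is returned, flagged, with stress 0.
    """
    config = config or AnalysisConfig()
    d = dissim.values
    n = d.shape[0]
    if n < 4:
        raise InputError("NMDS needs at least 4 items")
    if not np.all(np.isfinite(d)):
        raise InputError("non-finite dissimilarity")
    k = config.nmds_dimensions
    delta = squareform(d, checks=False)
    rng = config.rng("nmds", dissim.labels)
    if np.allclose(delta, delta[0]):
        x = _pc_rotate(_pcoa_start(d, k))
        return OrdinationResult(dissim.labels, x, 0.0, True, 0, degenerate=True)
    starts = [_pcoa_start(d, k)]
    scale = max(delta.max(), 1e-12)
    for _ in range(config.nmds_restarts):
        starts.append(rng.normal(scale=scale, size=(n, k)))
    best_x, best_stress, best_conv, best_trace = None, np.inf, False, []
    for x0 in starts:
        x, stress, conv, trace = _nmds_single(delta, x0, max_iter, tol)
        if stress < best_stress:
            best_x, best_stress, best_conv, best_trace = x, stress, conv, trace
    return OrdinationResult(
        dissim.labels,
        _pc_rotate(best_x),
        best_stress,
        best_conv,
        len(starts),
        stress_trace=tuple(best_trace),
    )


def procrustes_error(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual between two configurations in [0, 1].

    Both are centered and unit-scaled, y is optimally rotated/reflected
    onto x; returns sqrt(1 - (sum singular values)^2), the standard
    Procrustes statistic m12 squared-root.
    """
    x = x - x.mean(0)
    y = y - y.mean(0)
    x = x / np.linalg.norm(x)
    y = y / np.linalg.norm(y)
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(np.sqrt(max(0.0, 1.0 - s.sum() ** 2)))


# ---------------------------------------------------------------------------
# envfit


@dataclass(frozen=True)
class EnvFitResult:
    """Fit of one (standardized) environmental variable to NMDS scores."""

    variable: str
    direction: np.ndarray  # unit 2-vector of regression coefficients
    r_squared: float
    p_value: float
    n_perm: int


def envfit(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    config: AnalysisConfig | None = None,
    n_perm: int | None = None,
) -> list[EnvFitResult]:
    """Regress each variable on the axis scores; permutation significance.

    Variables are z-scored before fitting.  The direction is the normalized
    coefficient vector (the arrow), R^2 the coefficient of determination of
    the two-axis regression, and p the add-one permutation p-value of R^2
    under row permutation of the variable (999 permutations by default).
    """
    config = config or AnalysisConfig()
    n_perm = config.n_perm_ordination if n_perm is None else int(n_perm)
    scores = ordination.scores
    n = scores.shape[0]
    if len(variables) != n:
        raise InputError("variables and ordination have different plot counts")
    x = np.column_stack([np.ones(n), scores])
    q, _ = np.linalg.qr(x)
    results = []
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise InputError(f"non-finite values in variable {name!r}")
        sd = v.std(ddof=1)
        if sd == 0:
            raise InputError(f"zero-variance variable {name!r}")
        v = (v - v.mean()) / sd
        rng = config.rng("envfit", name)

        coef, *_ = np.linalg.lstsq(x, v, rcond=None)
        direction = coef[1:]
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else direction

        def r2(vec: np.ndarray) -> float:
            fitted = q @ (q.T @ vec)
            tss = ((vec - vec.mean()) ** 2).sum()
            rss = ((vec - fitted) ** 2).sum()
            return 1.0 - rss / tss

        obs = r2(v)
        perms = np.array([r2(rng.permutation(v)) for _ in range(n_perm)])
        p = (np.sum(perms >= obs - 1e-12) + 1) / (n_perm + 1)
        results.append(EnvFitResult(name, direction, float(obs), float(p), n_perm))
    return results


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same items.

    Pearson r of the upper triangles; one-sided p (r_perm >= r_obs) by
    permuting the items of the second matrix, add-one rule.
    """
    if set(d1.labels) != set(d2.labels):
        raise InputError("distance matrices have different labels")
    d2 = d2.submatrix(d1.labels)
    n = d1.n
    if n < 4:
        raise InputError("Mantel test needs at least 4 items")
    iu = np.triu_indices(n, 1)
    a = d1.values[iu]
    b = d2.values[iu]
    if np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0):
        raise InputError("constant off-diagonal distances; r undefined")
    az = (a - a.mean()) / a.std()
    r_obs = float((az * (b - b.mean())).mean() / b.std())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        bp = d2.values[np.ix_(idx, idx)][iu]
        r_p = (az * (bp - bp.mean())).mean() / bp.std()
        if r_p >= r_obs - 1e-12:
            count += 1
    return r_obs, float((count + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# PERMANOVA


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Columns (n x q) encoding one term; 'a:b' is an interaction product."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        part = part.strip()
        if part not in design.columns:
            raise InputError(f"unknown design column {part!r}")
        col = design[part]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
    out = blocks[0]
    for nxt in blocks[1:]:
        out = np.concatenate(
            [out[:, [i]] * nxt for i in range(out.shape[1])], axis=1
        )
    return out


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank] if rank < q.shape[1] else q
    return q @ q.T, rank


def permanova(
    dissim: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA with marginal (Type-II-like) tests.

    The Gower-centered inner-product matrix G of the squared dissimilarities
    partitions total sum of squares trace(G).  Each term's marginal SS is
    trace(H_full G) - trace(H_reduced G) with the reduced hat matrix
    dropping that term; pseudo-F = (SS_term/df_term) / (SS_resid/df_resid).
    p-values come from raw row permutations of G (add-one rule), a choice
    that is practically indistinguishable from residual permutation at
    these sample sizes.
    """
    if terms is None:
        terms = [str(c) for c in design.columns]
    if len(design) != dissim.n:
        raise InputError("design and dissimilarity have different sizes")
    n = dissim.n
    g = _gower_center(dissim.values)
    blocks = {t: _term_columns(design, t) for t in terms}
    ones = np.ones((n, 1))
    x_full = np.concatenate([ones] + [blocks[t] for t in terms], axis=1)
    h_full, rank_full = _hat(x_full)
    df_resid = n - rank_full
    if df_resid < 1:
        raise InputError("design leaves no residual degrees of freedom")

    dfs, reduced_hats = {}, {}
    for t in terms:
        x_red = np.concatenate(
            [ones] + [blocks[u] for u in terms if u != t], axis=1
        )
        h_red, rank_red = _hat(x_red)
        df_t = rank_full - rank_red
        if df_t < 1:
            raise InputError(f"term {t!r} is aliased with the other terms")
        dfs[t] = df_t
        reduced_hats[t] = h_red

    def stats(gmat: np.ndarray) -> dict[str, tuple[float, float]]:
        ss_model_full = float((h_full * gmat).sum())  # trace(H G)
        ss_resid = float(np.trace(gmat)) - ss_model_full
        out = {}
        for t in terms:
            ss_t = ss_model_full - float((reduced_hats[t] * gmat).sum())
            f = (ss_t / dfs[t]) / (ss_resid / df_resid)
            out[t] = (ss_t, f)
        return out

    obs = stats(g)
    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    for _ in range(n_perm):
        idx = rng.permutation(n)
        perm = stats(g[np.ix_(idx, idx)])
        for t in terms:
            if perm[t][1] >= obs[t][1] - 1e-12:
                exceed[t] += 1
    rows = []
    for t in terms:
        ss_t, f = obs[t]
        rows.append(
            {
                "term": t,
                "df": dfs[t],
                "ss": ss_t,
                "pseudo_F": f,
                "p_value": (exceed[t] + 1) / (n_perm + 1),
            }
        )
    rows.append(
        {
            "term": "residual",
            "df": df_resid,
            "ss": float(np.trace(g)) - float((h_full * g).sum()),
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")
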