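"""Standardized linear models of network indices on plot predictors.

Each index is modeled by ordinary least squares on standardized
predictors: continuous predictors are z-scored (tree species richness is
log2-transformed first, matching the log-scale richness gradient), site is
a categorical contrast, and site x diversity interactions are available.
Models are simplified backwards: at each step the nonsignificant
(p > 0.05) term whose removal most lowers AICc is dropped, respecting
marginality (a main effect is never dropped while its interaction
remains), until no removal lowers AICc.  Both conditions are required for
a drop, so terms that are nonsignificant but carry AICc weight are
retained — the final model can keep terms with p somewhat above 0.05.

Because tree species richness and tree phylogenetic MPD are strongly
collinear in diversity experiments, they are never offered to the same
model; the alternative-model protocol swaps one for the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import InputError

__all__ = [
    "ModelFit",
    "standardize_predictors",
    "build_design",
    "fit_index_model",
    "simplify_by_aicc",
    "vif",
    "FULL_MODEL_TERMS",
    "ALT_MODEL_TERMS",
]

# Full models offered to simplification, per the stated protocol: diversity
# terms with site interactions plus environmental covariates.  The primary
# model uses richness, the alternative model replaces it with tree MPD.
FULL_MODEL_TERMS = [
    "site",
    "log2_richness",
    "tree_raoq",
    "canopy_cover",
    "elevation",
    "eastness",
    "northness",
    "slope",
    "site:log2_richness",
    "site:tree_raoq",
]
ALT_MODEL_TERMS = [t.replace("log2_richness", "tree_mpd") for t in FULL_MODEL_TERMS]

_CONTINUOUS = [
    "canopy_cover",
    "elevation",
    "slope",
    "eastness",
    "northness",
    "tree_mpd",
    "tree_mntd",
    "tree_raoq",
]


@dataclass(frozen=True)
class ModelFit:
    """OLS fit summary: per-term estimates, AICc, fit statistics, VIFs."""

    response: str
    terms: tuple[str, ...]
    coefficients: pd.DataFrame  # estimate, se, t, p per design column
    aicc: float
    n: int
    r_squared: float
    vifs: dict[str, float]
    term_columns: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def term_estimate(self, column: str) -> float:
        return float(self.coefficients.loc[column, "estimate"])

    def term_min_p(self, term: str) -> float:
        """Smallest coefficient p-value of a (possibly multi-column) term."""
        cols = self.term_columns.get(term, (term,))
        ps = [self.coefficients.loc[c, "p"] for c in cols if c in self.coefficients.index]
        return float(min(ps)) if ps else 1.0


def standardize_predictors(covariates: pd.DataFrame) -> pd.DataFrame:
    """Standardized design table from raw plot covariates.

    tree_species_richness becomes z-scored ``log2_richness``; continuous
    covariates are z-scored; ``site`` stays categorical.  Zero-variance
    predictors are dropped with a warning.  Already-standardized columns
    pass through unchanged (z-scoring is idempotent).
    """
    import warnings

    out = pd.DataFrame(index=covariates.index)
    if "site" in covariates:
        out["site"] = covariates["site"].astype(str)
    if "tree_species_richness" in covariates:
        lr = np.log2(covariates["tree_species_richness"].astype(float))
        sd = lr.std(ddof=1)
        if sd == 0:
            warnings.warn("dropping zero-variance predictor 'tree_species_richness'", stacklevel=2)
        else:
            out["log2_richness"] = (lr - lr.mean()) / sd
    for col in _CONTINUOUS:
        if col not in covariates:
            continue
        v = covariates[col].astype(float)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance predictor {col!r}", stacklevel=2)
            continue
        out[col] = (v - v.mean()) / sd
    return out


def _term_matrix(design: pd.DataFrame, term: str) -> pd.DataFrame:
    parts = [p.strip() for p in term.split(":")]
    cols: pd.DataFrame | None = None
    for part in parts:
        if part not in design.columns:
            raise InputError(f"unknown predictor {part!r}")
        col = design[part]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            block = pd.get_dummies(col, prefix=part, drop_first=True).astype(float)
        else:
            block = col.to_frame(part).astype(float)
        if cols is None:
            cols = block
        else:
            new = {}
            for a in cols.columns:
                for b in block.columns:
                    new[f"{a}:{b}"] = cols[a] * block[b]
            cols = pd.DataFrame(new, index=design.index)
    assert cols is not None
    return cols


def build_design(design: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric model matrix (without intercept) for a list of terms.

    The richness/MPD exclusivity rule is enforced structurally: a model may
    include ``log2_richness`` or ``tree_mpd``, never both.
    """
    flat = {p for t in terms for p in t.split(":")}
    if "log2_richness" in flat and "tree_mpd" in flat:
        raise InputError(
            "tree MPD and tree species richness are collinear and may not "
            "enter the same model"
        )
    blocks = [_term_matrix(design, t) for t in terms]
    if not blocks:
        return pd.DataFrame(index=design.index)
    x = pd.concat(blocks, axis=1)
    if x.columns.duplicated().any():
        raise InputError("duplicate model columns")
    return x


def _aicc(result, n: int) -> float:
    # k counts all estimated parameters including the residual variance
    k = int(result.df_model) + 2
    if n - k - 1 <= 0:
        return np.inf
    return float(result.aic + 2.0 * k * (k + 1) / (n - k - 1))


def fit_index_model(
    response: pd.Series, design: pd.DataFrame, terms: list[str], name: str | None = None
) -> ModelFit:
    """OLS of one network index on the given terms of a standardized design."""
    y = response.astype(float)
    if y.isna().any():
        keep = ~y.isna()
        y = y[keep]
        design = design.loc[keep]
    x = build_design(design, terms)
    n = len(y)
    if n <= x.shape[1] + 1:
        raise InputError("more coefficients than observations")
    term_columns = {
        t: tuple(_term_matrix(design, t).columns) for t in terms
    }
    xc = sm.add_constant(x.to_numpy(dtype=float)) if x.shape[1] else np.ones((n, 1))
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        raise InputError(f"rank-deficient design for terms {terms}")
    res = sm.OLS(y.to_numpy(dtype=float), xc).fit()
    names = ["intercept"] + list(x.columns)
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=names,
    )
    vifs = vif(x) if x.shape[1] >= 2 else {c: 1.0 for c in x.columns}
    return ModelFit(
        response=name or (response.name or "index"),
        terms=tuple(terms),
        coefficients=coef,
        aicc=_aicc(res, n),
        n=n,
        r_squared=float(res.rsquared),
        vifs=vifs,
        term_columns=term_columns,
    )


def _removable(terms: list[str]) -> list[str]:
    """Terms not protected by marginality (no interaction involves them)."""
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
            continue
        if any(":" in u and t in u.split(":") for u in terms if u != t):
            continue
        out.append(t)
    return out


def simplify_by_aicc(
    response: pd.Series,
    design: pd.DataFrame,
    terms: list[str],
    alpha: float = 0.05,
    name: str | None = None,
) -> ModelFit:
    """Backward simplification of a full model (see module docstring).

    A term may be dropped only if it is nonsignificant (every coefficient
    p > alpha) and dropping it lowers AICc; among droppable terms the one
    lowering AICc most goes first.  The intercept-only model is a valid
    endpoint.  The returned model has the lowest AICc encountered.
    """
    current_terms = list(terms)
    fit = fit_index_model(response, design, current_terms, name)
    while current_terms:
        candidates = []
        for t in _removable(current_terms):
            if fit.term_min_p(t) <= alpha:  # some coefficient is significant
                continue
            reduced = [u for u in current_terms if u != t]
            try:
                fit_red = fit_index_model(response, design, reduced, name)
            except InputError:
                continue
            if fit_red.aicc < fit.aicc:
                candidates.append((fit_red.aicc, t, fit_red))
        if not candidates:
            break
        _, dropped, fit = min(candidates, key=lambda c: c[0])
        current_terms = [u for u in current_terms if u != dropped]
    return fit


def vif(x: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor 1 / (1 - R^2_k) per design column.

    Perfect collinearity yields ``inf``.  Columns are augmented with an
    intercept when regressing each on the others.
    """
    if x.shape[1] < 2:
        raise InputError("VIF needs at least 2 predictors")
    arr = x.to_numpy(dtype=float)
    n = arr.shape[0]
    out = {}
    for k, col in enumerate(x.columns):
        others = np.column_stack(
            [np.ones(n), np.delete(arr, k, axis=1)]
        )
        yk = arr[:, k]
        beta, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ beta
        tss = ((yk - yk.mean()) ** 2).sum()
        rss = (resid**2).sum()
        if tss == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - rss / tss
        out[col] = float(np.inf) if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out
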