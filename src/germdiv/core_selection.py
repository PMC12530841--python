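"""Core DUS trait selection: correlation-matrix PCA, eigenvalue-weighted
composite score F, trait-F correlation screen, and forward stepwise regression.

The composite score mirrors the standard germplasm-evaluation recipe: run PCA
on the trait correlation matrix, retain components with eigenvalue > 1
(Kaiser rule), weight each retained component's standardized score by its
share of the retained eigenvalue mass, and sum.  Traits that track F well are
then screened by Pearson correlation and a stepwise OLS of F on the traits
picks a parsimonious core set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .traits import TraitTable

__all__ = [
    "PCAResult",
    "CompositeScore",
    "CoreTraitSet",
    "standardize_traits",
    "pca",
    "composite_score",
    "trait_f_correlation",
    "stepwise_select",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray            # descending
    loadings: pd.DataFrame             # trait x component
    scores: pd.DataFrame               # accession x component, unit variance
    contribution: np.ndarray           # lambda_i / p
    cumulative_contribution: np.ndarray
    retained: int                      # number of components with lambda > 1


@dataclass
class CompositeScore:
    weights: np.ndarray                # per retained component, sums to 1
    f_values: pd.Series                # per accession


@dataclass
class CoreTraitSet:
    selected_traits: list[str]
    coefficients: pd.Series            # intercept + per-trait OLS coefficients
    r_squared: float
    correlation_table: pd.DataFrame
    path: list[dict] = field(default_factory=list)


def standardize_traits(table: TraitTable, exclude_invariant: bool = True):
    """Center and scale trait codes; drop zero-variance traits.

    Missing codes are mean-imputed (i.e. zero after centering) so that PCA
    operates on a complete matrix.  Returns (standardized DataFrame, list of
    dropped trait ids).
    """
    if len(table.accessions) < 2:
        raise ValueError("need >= 2 accessions")
    df = table.codes.copy()
    dropped: list[str] = []
    if exclude_invariant:
        dropped = [t for t in df.columns if df[t].dropna().nunique() <= 1]
        df = df.drop(columns=dropped)
    if df.shape[1] == 0:
        raise ValueError("all traits invariant: nothing to standardize")
    means = df.mean()
    sds = df.std(ddof=1)
    z = (df - means) / sds
    return z.fillna(0.0), dropped


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Eigen-decomposition of the trait correlation matrix.

    Components are ordered by descending eigenvalue.  Sign convention: the
    largest-magnitude entry of each loading vector is positive, which makes
    scores reproducible across eigensolvers.  Scores are standardized to unit
    variance (the "regression"-style factor scores).
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need >= 2 accessions and >= 2 traits")
    corr = np.corrcoef(x, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(p):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    # z-scored data (ddof=1 to match the correlation matrix)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    raw_scores = z @ evecs                      # variance lambda_j
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(evals > 1e-12, raw_scores / np.sqrt(np.maximum(evals, 1e-300)), 0.0)
    retained = max(1, int(np.sum(evals > 1.0)))
    comp_names = [f"PC{j + 1}" for j in range(p)]
    contribution = evals / p
    return PCAResult(
        eigenvalues=evals,
        loadings=pd.DataFrame(evecs, index=matrix.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        contribution=contribution,
        cumulative_contribution=np.cumsum(contribution),
        retained=retained,
    )


def composite_score(pca_result: PCAResult) -> CompositeScore:
    """F = sum_i w_i P_i with w_i = lambda_i / sum of retained eigenvalues."""
    r = pca_result.retained
    lam = pca_result.eigenvalues[:r]
    weights = lam / lam.sum()
    f = pca_result.scores.iloc[:, :r].to_numpy() @ weights
    return CompositeScore(weights=weights,
                          f_values=pd.Series(f, index=pca_result.scores.index, name="F"))


def trait_f_correlation(matrix: pd.DataFrame, score: CompositeScore,
                        alpha_levels: tuple[float, float] = (0.05, 0.01)) -> pd.DataFrame:
    """Pearson r of each trait with F, starred at the two significance levels."""
    f = score.f_values.loc[matrix.index].to_numpy()
    rows = []
    for tid in matrix.columns:
        x = matrix[tid].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"{tid}: zero variance, F-correlation undefined")
            rows.append({"trait_id": tid, "r": np.nan, "p": np.nan, "stars": ""})
            continue
        r, p = sps.pearsonr(x, f)
        stars = "**" if p <= min(alpha_levels) else ("*" if p <= max(alpha_levels) else "")
        rows.append({"trait_id": tid, "r": r, "p": p, "stars": stars})
    return pd.DataFrame(rows).set_index("trait_id")


def _fit_ols(f: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(f, sm.add_constant(X, has_constant="add")).fit()
    return model


def stepwise_select(matrix: pd.DataFrame, score: CompositeScore,
                    p_enter: float = 0.05, p_remove: float = 0.10) -> CoreTraitSet:
    """Forward stepwise OLS of F on traits with entry/removal tests.

    Candidates are the traits significantly correlated with F (at the entry
    level).  At each step the candidate with the smallest coefficient p-value
    enters if p < p_enter (ties broken by larger |r| with F, then trait id);
    included traits with p > p_remove are dropped.  Returns the final model
    and the selection path.
    """
    if not p_enter < p_remove:
        raise ValueError("require p_enter < p_remove (prevents cycling)")
    f = score.f_values.loc[matrix.index].to_numpy()
    corr = trait_f_correlation(matrix, score)
    candidates = [t for t in matrix.columns
                  if np.isfinite(corr.loc[t, "p"]) and corr.loc[t, "p"] <= p_enter]
    selected: list[str] = []
    path: list[dict] = []
    if not candidates:
        warnings.warn("no trait passes the entry threshold; empty core set")
        return CoreTraitSet([], pd.Series(dtype=float), 0.0, corr, [])

    id_rank = {t: i for i, t in enumerate(matrix.columns)}
    while True:
        changed = False
        # forward step
        best = None
        for t in candidates:
            if t in selected:
                continue
            model = _fit_ols(f, matrix[selected + [t]])
            p_t = float(model.pvalues.iloc[-1])
            key = (p_t, -abs(corr.loc[t, "r"]), id_rank[t])
            if np.isfinite(p_t) and p_t < p_enter and (best is None or key < best[0]):
                best = (key, t)
        if best is not None:
            selected.append(best[1])
            model = _fit_ols(f, matrix[selected])
            path.append({"action": "add", "trait": best[1],
                         "r_squared": float(model.rsquared)})
            changed = True
        # backward step
        if len(selected) > 1:
            model = _fit_ols(f, matrix[selected])
            pvals = model.pvalues.iloc[1:].dropna()  # skip intercept
            if not pvals.empty and float(pvals.max()) > p_remove:
                worst = pvals.idxmax()
                selected.remove(worst)
                model = _fit_ols(f, matrix[selected])
                path.append({"action": "remove", "trait": worst,
                             "r_squared": float(model.rsquared)})
                changed = True
        if not changed:
            break

    model = _fit_ols(f, matrix[selected])
    coeffs = model.params.rename(index={"const": "intercept"})
    return CoreTraitSet(selected_traits=selected, coefficients=coeffs,
                        r_squared=float(model.rsquared),
                        correlation_table=corr, path=path)
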