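"""Per-gene lasso regression and its transformation into a regulatory network.

Each gene j is modelled as Y_j ~ X A_j, where X holds the TF expression
profiles. The objective is the standard scaled lasso

    (1 / (2m)) * ||Y_j - X A_j||^2 + lambda * sum_i |a_ij|

with a free intercept; the response is centered implicitly by the intercept
and TF features are used as-is (an opt-in flag standardizes them). When gene
j is itself a TF its own feature column is zeroed before fitting, so a_jj = 0
exactly. The fitted coefficient matrix A is thresholded at |a_ij| >= alpha to
produce the network; coefficient signs are preserved (positive weight =
up-regulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold

from .datamodel import (
    CoefficientMatrix,
    ExpressionMatrix,
    RegulatoryNetwork,
    TrnkitError,
    warn,
)

_LASSO_KW = dict(fit_intercept=True, max_iter=10_000, tol=1e-6)


@dataclass
class FitReport:
    """Cross-validation summary for the lambda-tuning step."""

    lambda_star: float
    per_gene_r2: pd.Series  # mean out-of-fold R^2 per gene at lambda_star
    fold_seed: int
    per_lambda: pd.DataFrame  # one row per candidate lambda: mean/median/q25/q75 of gene R^2

    @property
    def mean_r2(self) -> float:
        return float(self.per_gene_r2.mean())


def _design(expr: ExpressionMatrix, standardize: bool = False) -> np.ndarray:
    X = expr.tf_design()
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


def _fit_matrix(
    X: np.ndarray,
    Y: np.ndarray,
    tf_ids: list[str],
    gene_ids: list[str],
    lam: float,
) -> np.ndarray:
    """Fit all genes at once; returns (n_tf, n_genes) coefficients.

    Non-TF genes share one multi-output lasso call; each TF gene is refit with
    its own feature column zeroed (self-masking), giving a_jj = 0 exactly.
    """
    tf_pos = {t: i for i, t in enumerate(tf_ids)}
    coef = np.zeros((len(tf_ids), len(gene_ids)))
    plain_cols = [c for c, g in enumerate(gene_ids) if g not in tf_pos]
    if lam > 0:
        model = Lasso(alpha=lam, **_LASSO_KW)
    else:
        model = LinearRegression()
    if plain_cols:
        model.fit(X, Y[:, plain_cols])
        c = model.coef_
        coef[:, plain_cols] = c.T if c.ndim == 2 else c[:, None]
    for c, g in enumerate(gene_ids):
        i = tf_pos.get(g)
        if i is None:
            continue
        Xm = X.copy()
        Xm[:, i] = 0.0
        model.fit(Xm, Y[:, c])
        coef[:, c] = model.coef_
        coef[i, c] = 0.0
    return coef


def fit_gene_model(
    expr: ExpressionMatrix,
    gene: str,
    lam: float,
    *,
    standardize: bool = False,
) -> pd.Series:
    """Lasso coefficient vector over TFs for one gene."""
    if lam < 0:
        raise TrnkitError("lambda must be nonnegative")
    if gene not in expr.values.index:
        raise TrnkitError(f"gene {gene} not found")
    X = _design(expr, standardize)
    y = expr.gene_response(gene)
    coef = _fit_matrix(X, y[:, None], expr.tf_ids, [gene], lam)[:, 0]
    return pd.Series(coef, index=expr.tf_ids, name=gene)


def fit_coefficients(
    expr: ExpressionMatrix,
    lam: float,
    genes: list[str] | None = None,
    *,
    standardize: bool = False,
    r2: pd.Series | None = None,
) -> CoefficientMatrix:
    """Fit the full TF x gene coefficient matrix A at one lambda."""
    if lam < 0:
        raise TrnkitError("lambda must be nonnegative")
    gene_ids = list(genes) if genes is not None else expr.gene_ids
    X = _design(expr, standardize)
    Y = expr.values.loc[gene_ids].to_numpy().T
    coef = _fit_matrix(X, Y, expr.tf_ids, gene_ids, lam)
    values = pd.DataFrame(coef, index=expr.tf_ids, columns=gene_ids)
    return CoefficientMatrix(values, lambda_used=lam, r2=r2)


def _fold_indices(m: int, folds: int, seed: int, contiguous: bool) -> list[np.ndarray]:
    if contiguous:
        return [np.asarray(idx) for idx in np.array_split(np.arange(m), folds)]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(m))]


def cv_r2(
    expr: ExpressionMatrix,
    lam: float,
    folds: int = 10,
    seed: int = 0,
    *,
    contiguous: bool = False,
    standardize: bool = False,
) -> pd.Series:
    """Mean out-of-fold R^2 per gene under k-fold cross-validation."""
    m = expr.m
    if m < folds:
        raise TrnkitError(f"m={m} samples < {folds} folds")
    X = _design(expr, standardize)
    Y = expr.values.to_numpy().T  # m x n
    gene_ids = expr.gene_ids
    scores = np.zeros((folds, len(gene_ids)))
    for f, test in enumerate(_fold_indices(m, folds, seed, contiguous)):
        train = np.setdiff1d(np.arange(m), test)
        coef = _fit_matrix(X[train], Y[train], expr.tf_ids, gene_ids, lam)
        intercepts = Y[train].mean(axis=0) - X[train].mean(axis=0) @ coef
        pred = X[test] @ coef + intercepts
        resid = ((Y[test] - pred) ** 2).sum(axis=0)
        total = ((Y[test] - Y[test].mean(axis=0)) ** 2).sum(axis=0)
        total[total == 0] = np.finfo(float).tiny
        scores[f] = 1.0 - resid / total
    return pd.Series(scores.mean(axis=0), index=gene_ids)


def tune_lambda(
    expr: ExpressionMatrix,
    grid: list[float],
    folds: int = 10,
    seed: int = 0,
    *,
    contiguous: bool = False,
    standardize: bool = False,
) -> tuple[float, FitReport]:
    """Pick the lambda maximizing the mean (over genes) of mean CV R^2."""
    if not grid:
        raise TrnkitError("empty lambda grid")
    if any(l < 0 for l in grid):
        raise TrnkitError("lambda values must be nonnegative")
    if expr.m < folds:
        raise TrnkitError(f"m={expr.m} samples < {folds} folds")
    rows, per_gene = [], {}
    for lam in grid:
        r2 = cv_r2(expr, lam, folds=folds, seed=seed, contiguous=contiguous, standardize=standardize)
        per_gene[lam] = r2
        rows.append(
            {
                "lambda": lam,
                "mean_r2": r2.mean(),
                "median_r2": r2.median(),
                "q25_r2": r2.quantile(0.25),
                "q75_r2": r2.quantile(0.75),
            }
        )
    per_lambda = pd.DataFrame(rows)
    best = per_lambda.loc[per_lambda["mean_r2"].idxmax(), "lambda"]
    report = FitReport(
        lambda_star=float(best),
        per_gene_r2=per_gene[best],
        fold_seed=seed,
        per_lambda=per_lambda,
    )
    return float(best), report


def default_lambda_grid() -> list[float]:
    """Geometric grid 5^-6 .. 5^1 (half-integer exponents)."""
    return [float(5.0**e) for e in np.arange(-6, 1.5, 0.5)]


def filter_by_r2(report: FitReport, percentile: float = 25) -> tuple[list[str], float]:
    """Drop genes whose mean CV R^2 falls strictly below the given percentile.

    The cutoff uses the linear-interpolation percentile convention; genes
    exactly at the cutoff are retained.
    """
    if not (0 <= percentile < 100):
        raise TrnkitError("percentile must be in [0, 100)")
    r2 = report.per_gene_r2
    cutoff = float(np.percentile(r2.to_numpy(), percentile))
    retained = r2.index[r2.to_numpy() >= cutoff].tolist()
    return retained, cutoff


def threshold_network(A: CoefficientMatrix, alpha: float) -> RegulatoryNetwork:
    """Apply the cutoff |a_ij| >= alpha and build the network G.

    Boundary values are kept; singleton nodes never enter the node set.
    """
    if alpha < 0:
        raise TrnkitError("alpha must be nonnegative")
    net = RegulatoryNetwork(
        (tf, g, w) for tf, g, w in A.nonzero_edges() if abs(w) >= alpha
    )
    if net.n_edges == 0:
        warn(f"alpha={alpha} removed every edge: empty network")
    return net


def match_density_alpha(A: CoefficientMatrix, target_edge_count: int) -> float:
    """Smallest alpha whose thresholded network has <= target_edge_count edges.

    Edge count is a right-continuous step function of alpha over the distinct
    |a_ij| values, so the answer is exact.
    """
    if target_edge_count < 1:
        raise TrnkitError("target_edge_count must be >= 1")
    mags = np.abs(A.values.to_numpy())
    mags = np.sort(mags[mags > 0])[::-1]
    if target_edge_count >= mags.size:
        if target_edge_count > mags.size:
            warn(
                f"target edge count {target_edge_count} exceeds {mags.size} nonzero "
                "coefficients; returning alpha=0"
            )
        return 0.0
    # distinct magnitudes descending; count at alpha=v is #(|a| >= v).
    # If ties at the maximum already exceed the target, only an alpha just
    # above the largest magnitude satisfies the bound.
    alpha = float(np.nextafter(mags[0], np.inf))
    for v in np.unique(mags)[::-1]:
        if int((mags >= v).sum()) <= target_edge_count:
            alpha = v
        else:
            break
    return float(alpha)


def infer_treatment_networks(
    expr: ExpressionMatrix,
    lam: float,
    reference_density: int,
    *,
    min_samples: int = 2,
    standardize: bool = False,
) -> dict[str, RegulatoryNetwork]:
    """Refit per treatment category and threshold to a common density.

    Each category's model is fit on that category's samples only; its alpha is
    chosen with :func:`match_density_alpha` so every treatment network has (at
    most) ``reference_density`` edges, easing cross-condition comparison.
    """
    if expr.sample_category is None:
        raise TrnkitError("expression matrix has no sample categories")
    by_cat: dict[str, list[str]] = {}
    for s in expr.sample_ids:
        cat = expr.sample_category.get(s)
        if cat is not None:
            by_cat.setdefault(cat, []).append(s)
    nets: dict[str, RegulatoryNetwork] = {}
    for cat, samples in by_cat.items():
        if len(samples) < min_samples:
            warn(f"category {cat!r} has {len(samples)} samples (<{min_samples}); skipped")
            continue
        sub = expr.subset_samples(samples)
        A = fit_coefficients(sub, lam, standardize=standardize)
        alpha = match_density_alpha(A, reference_density)
        nets[cat] = threshold_network(A, alpha)
    return nets
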