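"""Elastic Net age models with disease-state covariates.

The clock predicts chronological age from per-CpG methylation levels:

    Y_hat = beta0 + sum_i beta_i * x_i  (+ sum_j gamma_j * D_j)

fit by minimizing the penalized least-squares objective

    (1/2n) * sum_i (y_i - Y_hat_i)^2 + lam1 * sum|beta_i| + lam2 * sum beta_i^2

where the L1/L2 penalties act ONLY on the site coefficients ``beta_i``;
the intercept and the binary disease covariates ``D_j`` are never
penalized, which keeps the covariate coefficients interpretable as
age shifts in years.  Site columns are standardized to zero mean / unit
variance on the training samples and the scaling parameters are stored
with the model, so predictions are invariant to affine rescaling of any
input column.

The site block is solved with scikit-learn's coordinate descent
(``ElasticNet``); when covariates are present the model alternates between
the penalized site block and an exact least-squares solve of the
intercept+covariate block until the joint (convex) objective converges.

A note on the covariate sign: the model is trained against chronological
age, so if a disease makes methylation look ``delta`` years older, the
fitted coefficient gamma converges to ``-delta`` (given old-looking
methylation, chronological age is younger).  The disease's effect on
epigenetic age — the quantity aging studies care about — is therefore
``-gamma``; :func:`covariate_ci` reports both.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold, LeaveOneOut

__all__ = [
    "ClockModel",
    "LoocvRun",
    "encode_covariates",
    "fit_elastic_net",
    "penalized_objective",
    "default_grid",
    "tune_penalties",
    "loocv_predict",
    "covariate_ci",
    "predict_ages",
    "feature_overlap",
    "lambda_to_sklearn",
]

logger = logging.getLogger(__name__)

REFERENCE_DISEASE = "normal"


def child_seed(master: int, *keys) -> int:
    """Deterministic sub-seed below 2**31, stable under reordering of work.

    String keys are hashed with crc32 so a sample keeps its seed when the
    cohort is permuted.
    """
    ints = [int(master)]
    for k in keys:
        ints.append(zlib.crc32(k.encode()) if isinstance(k, str) else int(k))
    return int(np.random.SeedSequence(ints).generate_state(1)[0] >> 1)


def lambda_to_sklearn(lam1: float, lam2: float) -> tuple[float, float]:
    """Map the (lam1, lam2) penalty pair to sklearn's (alpha, l1_ratio).

    sklearn minimizes (1/2n)||y - Xw||^2 + alpha*l1_ratio*||w||_1
    + 0.5*alpha*(1-l1_ratio)*||w||^2, so alpha = lam1 + 2*lam2 and
    l1_ratio = lam1 / alpha.
    """
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be non-negative")
    alpha = lam1 + 2.0 * lam2
    if alpha == 0.0:
        return 0.0, 1.0
    return alpha, lam1 / alpha


def encode_covariates(
    sample_table: pd.DataFrame,
    vocabulary: Optional[Sequence[str]] = None,
    reference: str = REFERENCE_DISEASE,
) -> pd.DataFrame:
    """One-hot disease design matrix with the reference level dropped.

    Columns are the non-reference vocabulary levels in declared order;
    reference samples get all-zero rows.  An observed label outside the
    vocabulary is an error listing the known levels.
    """
    labels = sample_table["disease"].astype(str)
    if vocabulary is None:
        vocabulary = [reference] + sorted(set(labels) - {reference})
    vocabulary = list(vocabulary)
    if reference not in vocabulary:
        raise ValueError(f"reference level {reference!r} missing from vocabulary")
    unseen = set(labels) - set(vocabulary)
    if unseen:
        raise ValueError(
            f"unknown disease label(s) {sorted(unseen)}; known levels: {vocabulary}"
        )
    levels = [v for v in vocabulary if v != reference]
    data = {lv: (labels == lv).astype(float).to_numpy() for lv in levels}
    return pd.DataFrame(data, index=sample_table.index, columns=levels)


@dataclass
class ClockModel:
    """A fitted methylation clock.

    Site coefficients are on the standardized scale; ``feature_means`` and
    ``feature_scales`` map raw betas onto it.  ``covariate_levels`` is the
    full disease vocabulary (reference first).
    """

    intercept: float
    coef: pd.Series                       # index: site keys
    feature_means: pd.Series
    feature_scales: pd.Series
    lam1: float
    lam2: float
    include_covariates: bool = False
    covariate_coef: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    covariate_levels: list[str] = field(default_factory=lambda: [REFERENCE_DISEASE])
    version: str = "bsclock-model-1"

    def __post_init__(self) -> None:
        if not (len(self.coef) == len(self.feature_means) == len(self.feature_scales)):
            raise ValueError("coefficient and scaling lengths disagree")
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("penalties must be non-negative")

    @property
    def sites(self) -> list[str]:
        return list(self.coef.index)

    @property
    def selected_sites(self) -> list[str]:
        """Sites with a nonzero coefficient."""
        return list(self.coef.index[self.coef.to_numpy() != 0.0])

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "intercept": self.intercept,
            "lam1": self.lam1,
            "lam2": self.lam2,
            "include_covariates": self.include_covariates,
            "covariate_levels": self.covariate_levels,
            "sites": self.sites,
            "coef": self.coef.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "covariate_coef": {k: float(v) for k, v in self.covariate_coef.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClockModel":
        with open(path) as fh:
            d = json.load(fh)
        sites = d["sites"]
        return cls(
            intercept=float(d["intercept"]),
            coef=pd.Series(d["coef"], index=sites, dtype=float),
            feature_means=pd.Series(d["feature_means"], index=sites, dtype=float),
            feature_scales=pd.Series(d["feature_scales"], index=sites, dtype=float),
            lam1=float(d["lam1"]),
            lam2=float(d["lam2"]),
            include_covariates=bool(d["include_covariates"]),
            covariate_coef=pd.Series(d["covariate_coef"], dtype=float),
            covariate_levels=list(d["covariate_levels"]),
            version=d.get("version", "bsclock-model-1"),
        )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales == 0.0, 1.0, scales)
    return (X - means) / scales, means, scales


def penalized_objective(
    Xs: np.ndarray,
    y: np.ndarray,
    D: Optional[np.ndarray],
    intercept: float,
    beta: np.ndarray,
    gamma: Optional[np.ndarray],
    lam1: float,
    lam2: float,
) -> float:
    """Value of the penalized objective on standardized features."""
    pred = intercept + Xs @ beta
    if D is not None and D.size:
        pred = pred + D @ gamma
    n = len(y)
    return float(
        0.5 / n * np.sum((y - pred) ** 2)
        + lam1 * np.sum(np.abs(beta))
        + lam2 * np.sum(beta**2)
    )


def _solve_site_block(
    Xs: np.ndarray, r: np.ndarray, lam1: float, lam2: float
) -> np.ndarray:
    """Penalized site coefficients for centered target r (no intercept)."""
    if lam1 == 0.0 and lam2 > 0.0:
        # ridge closed form: (X'X/n + 2*lam2*I) b = X'r/n
        n, p = Xs.shape
        A = Xs.T @ Xs / n + 2.0 * lam2 * np.eye(p)
        return np.linalg.solve(A, Xs.T @ r / n)
    alpha, l1_ratio = lambda_to_sklearn(lam1, lam2)
    en = ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False, max_iter=100000, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        en.fit(Xs, r)
    return en.coef_


def fit_elastic_net(
    X,
    y,
    lam1: float,
    lam2: float,
    D: Optional[pd.DataFrame] = None,
    include_covariates: bool = True,
    covariate_levels: Optional[list[str]] = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> ClockModel:
    """Fit the clock objective; penalties act on site coefficients only.

    Parameters
    ----------
    X : DataFrame or array, n x p
        Methylation betas at the selected sites (no missing values).
    y : array, n
        Chronological ages in years.
    lam1, lam2
        L1 and L2 penalty weights (>= 0).
    D : DataFrame or None
        Binary disease design matrix (reference level dropped).  Ignored
        when ``include_covariates`` is False.
    include_covariates
        With False (or an empty D) this is the covariate-free model, which
        is exactly the covariate model with q = 0.

    With ``lam1 = lam2 = 0`` the problem must be overdetermined
    (n > p + q + 1) and is solved by ordinary least squares.
    """
    Xf = _as_frame(X)
    Xv = Xf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(Xv).all():
        raise ValueError("X contains non-finite values; filter or impute first")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    n, p = Xv.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")

    use_D = include_covariates and D is not None and D.shape[1] > 0
    if use_D:
        Dv = np.asarray(D, dtype=float)
        levels = list(D.columns) if isinstance(D, pd.DataFrame) else [
            f"d{j}" for j in range(Dv.shape[1])
        ]
    else:
        Dv = np.zeros((n, 0))
        levels = []
    q = Dv.shape[1]

    Xs, means, scales = _standardize(Xv)
    Z = np.column_stack([np.ones(n), Dv])  # unpenalized block

    if lam1 == 0.0 and lam2 == 0.0:
        if p + q + 1 > n:
            raise ValueError(
                f"unpenalized fit is underdetermined (n={n} <= p+q+1={p + q + 1}); "
                "set lam1/lam2 > 0"
            )
        M = np.column_stack([Z, Xs])
        sol, *_ = np.linalg.lstsq(M, y, rcond=None)
        intercept, gamma, beta = sol[0], sol[1 : 1 + q], sol[1 + q :]
    else:
        beta = np.zeros(p)
        intercept = float(np.mean(y))
        gamma = np.zeros(q)
        ZtZinvZt = np.linalg.pinv(Z)
        for _ in range(max_iter):
            # exact solve of the unpenalized intercept+covariate block
            sol = ZtZinvZt @ (y - Xs @ beta)
            new_intercept, new_gamma = sol[0], sol[1:]
            new_beta = _solve_site_block(Xs, y - new_intercept - Dv @ new_gamma, lam1, lam2)
            delta = max(
                abs(new_intercept - intercept),
                np.max(np.abs(new_beta - beta), initial=0.0),
                np.max(np.abs(new_gamma - gamma), initial=0.0),
            )
            intercept, gamma, beta = float(new_intercept), new_gamma, new_beta
            if delta < tol:
                break
            if q == 0:
                # no coupling beyond the intercept: one more exact pass suffices
                sol = ZtZinvZt @ (y - Xs @ beta)
                intercept = float(sol[0])
                break

    if covariate_levels is None:
        covariate_levels = [REFERENCE_DISEASE] + levels
    return ClockModel(
        intercept=float(intercept),
        coef=pd.Series(beta, index=Xf.columns, dtype=float),
        feature_means=pd.Series(means, index=Xf.columns, dtype=float),
        feature_scales=pd.Series(scales, index=Xf.columns, dtype=float),
        lam1=float(lam1),
        lam2=float(lam2),
        include_covariates=bool(use_D),
        covariate_coef=pd.Series(gamma, index=levels, dtype=float),
        covariate_levels=covariate_levels,
    )


def default_grid(
    X,
    y,
    n_alphas: int = 20,
    l1_ratios: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
    alpha_min_ratio: float = 1e-3,
) -> list[tuple[float, float]]:
    """Penalty grid: per mixing value, a log-spaced path of total penalties.

    The largest total penalty on each path is the smallest value that
    zeroes every site coefficient (``max|X_s'(y - ybar)| / (n * l1_ratio)``).
    Returned as (lam1, lam2) pairs.
    """
    Xv = _as_frame(X).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, _, _ = _standardize(Xv)
    n = len(y)
    base = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)
    if base == 0.0:
        base = 1.0
    grid: list[tuple[float, float]] = []
    for m in l1_ratios:
        if m <= 0:
            raise ValueError("l1_ratios must be positive")
        amax = base / m
        for alpha in np.geomspace(alpha_min_ratio * amax, amax, n_alphas):
            grid.append((alpha * m, alpha * (1.0 - m) / 2.0))
    return grid


def _fold_errors_fast(
    Xv: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    grid: list[tuple[float, float]],
    tol: float,
) -> np.ndarray:
    """Summed squared test errors per grid pair for one CV fold
    (covariate-free).  Pairs sharing a mixing ratio are solved as one
    warm-started coordinate-descent path, largest penalty first."""
    Xs, means, scales = _standardize(Xv[train])
    Xte = (Xv[test] - means) / scales
    ytr = y[train]
    r = ytr - ytr.mean()
    errs = np.zeros(len(grid))
    by_ratio: dict[float, list[int]] = {}
    for g, (lam1, lam2) in enumerate(grid):
        alpha, ratio = lambda_to_sklearn(lam1, lam2)
        by_ratio.setdefault(round(ratio, 12), []).append(g)
    for ratio, idxs in by_ratio.items():
        alphas = {g: grid[g][0] + 2.0 * grid[g][1] for g in idxs}
        order = sorted(idxs, key=lambda g: -alphas[g])
        en = None
        for g in order:
            alpha = alphas[g]
            if alpha == 0.0:
                raise ValueError("unpenalized pairs are not valid in a CV grid")
            if ratio == 0.0:  # pure ridge: closed form, no path needed
                coef = _solve_site_block(Xs, r, 0.0, alpha / 2.0)
            else:
                if en is None:
                    en = ElasticNet(
                        alpha=alpha, l1_ratio=ratio, fit_intercept=False,
                        warm_start=True, max_iter=20000, tol=tol,
                    )
                en.set_params(alpha=alpha)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    en.fit(Xs, r)
                coef = en.coef_
            pred = ytr.mean() + Xte @ coef
            errs[g] = np.sum((pred - y[test]) ** 2)
    return errs


def tune_penalties(
    X,
    y,
    grid: Sequence[tuple[float, float]],
    k: int = 10,
    seed: int = 0,
    D: Optional[pd.DataFrame] = None,
    include_covariates: bool = False,
    tol: float = 1e-5,
) -> tuple[float, float]:
    """Pick the (lam1, lam2) pair minimizing mean k-fold CV squared error.

    Ties on CV error are broken toward stronger regularization (largest
    total penalty lam1 + 2*lam2), then toward the lexicographically
    smallest pair.  Deterministic given the seed.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(f"n={n} < k={k}; use a smaller number of folds")
    grid = list(grid)
    if not grid:
        raise ValueError("empty penalty grid")
    if len(grid) == 1:
        return grid[0]
    use_D = include_covariates and D is not None and D.shape[1] > 0
    mse = np.zeros(len(grid))
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    Xv = Xf.to_numpy(dtype=float)
    for train, test in kf.split(Xf):
        if not use_D:
            mse += _fold_errors_fast(Xv, y, train, test, grid, tol)
            continue
        Xtr, Xte = Xf.iloc[train], Xf.iloc[test]
        Dtr, Dte = D.iloc[train], D.iloc[test]
        for g, (lam1, lam2) in enumerate(grid):
            model = fit_elastic_net(
                Xtr, y[train], lam1, lam2, D=Dtr, include_covariates=True
            )
            pred = _predict_frame(model, Xte, Dte)
            mse[g] += np.sum((pred - y[test]) ** 2)
    mse /= n
    best = mse.min()
    ties = [grid[i] for i in np.flatnonzero(mse == best)]
    strength = max(l1 + 2 * l2 for l1, l2 in ties)
    ties = [g for g in ties if g[0] + 2 * g[1] == strength]
    return min(ties)


def _predict_frame(
    model: ClockModel, X: pd.DataFrame, D: Optional[pd.DataFrame]
) -> np.ndarray:
    Xs = (X.to_numpy(dtype=float) - model.feature_means.to_numpy()) / (
        model.feature_scales.to_numpy()
    )
    pred = model.intercept + Xs @ model.coef.to_numpy()
    if model.include_covariates and len(model.covariate_coef):
        if D is None:
            Dv = np.zeros((len(X), len(model.covariate_coef)))
        else:
            Dv = D[list(model.covariate_coef.index)].to_numpy(dtype=float)
        pred = pred + Dv @ model.covariate_coef.to_numpy()
    return pred


@dataclass
class LoocvRun:
    """Leave-one-out predictions plus the per-fold model summaries."""

    table: pd.DataFrame            # sample, age, predicted, lam1, lam2
    covariate_coefs: pd.DataFrame  # n x q, one row per held-out fold
    include_covariates: bool
    covariate_levels: list[str]
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def loocv_predict(
    X,
    sample_table: pd.DataFrame,
    include_covariates: bool = True,
    inner_k: int = 5,
    grid: Optional[Sequence[tuple[float, float]]] = None,
    seed: int = 0,
    vocabulary: Optional[Sequence[str]] = None,
) -> LoocvRun:
    """Leave-one-out protocol: per fold, tune penalties by inner k-fold CV
    on the n-1 training samples, refit, and predict the held-out sample.

    ``X`` is the n x p beta frame restricted to the clock's feature sites,
    row-aligned with ``sample_table``.  A 1-point ``grid`` skips the inner
    CV (the pair is used as-is).  ``grid=None`` builds the default grid on
    each training fold.  Samples are processed in a canonical order
    (sorted by id) and each fold's inner seed derives from (master seed,
    sample id), so results are invariant to the input row order.  The
    held-out sample's age is never seen during tuning or fitting.
    """
    Xf = _as_frame(X)
    if not Xf.index.equals(sample_table.index):
        raise ValueError("X rows must align with the sample table")
    n = len(Xf)
    if n < inner_k + 1:
        raise ValueError(f"n={n} too small for LOOCV with inner_k={inner_k}")
    order = sorted(range(n), key=lambda i: str(Xf.index[i]))
    Xc = Xf.iloc[order]
    meta = sample_table.iloc[order]
    y = meta["age"].to_numpy(dtype=float)
    D_all = encode_covariates(meta, vocabulary=vocabulary) if include_covariates else None
    levels = (
        [REFERENCE_DISEASE] + list(D_all.columns)
        if D_all is not None
        else [REFERENCE_DISEASE]
    )

    rows = []
    cov_rows = []
    for train, test in LeaveOneOut().split(Xc):
        i = int(test[0])
        sid = str(Xc.index[i])
        Xtr = Xc.iloc[train]
        ytr = y[train]
        Dtr = D_all.iloc[train] if D_all is not None else None
        fold_grid = list(grid) if grid is not None else default_grid(Xtr, ytr)
        if len(fold_grid) > 1:
            lam1, lam2 = tune_penalties(
                Xtr,
                ytr,
                fold_grid,
                k=inner_k,
                seed=child_seed(seed, sid),
                D=Dtr,
                include_covariates=include_covariates,
            )
        else:
            lam1, lam2 = fold_grid[0]
        model = fit_elastic_net(
            Xtr, ytr, lam1, lam2, D=Dtr, include_covariates=include_covariates
        )
        pred = _predict_frame(
            model, Xc.iloc[[i]], D_all.iloc[[i]] if D_all is not None else None
        )[0]
        rows.append(
            {"sample": sid, "age": y[i], "predicted": pred, "lam1": lam1, "lam2": lam2}
        )
        cov_rows.append(model.covariate_coef)

    table = pd.DataFrame(rows)
    cov = pd.DataFrame(cov_rows, index=table["sample"])
    return LoocvRun(
        table=table,
        covariate_coefs=cov,
        include_covariates=include_covariates,
        covariate_levels=levels,
        seed=seed,
    )


def covariate_ci(
    run: LoocvRun, level: float = 0.95, method: str = "percentile"
) -> pd.DataFrame:
    """Disease-covariate point estimates and confidence intervals.

    The point estimate is the mean of the coefficient across the LOOCV
    folds; ``percentile`` bounds are the empirical (1-level)/2 and
    1-(1-level)/2 percentiles (linear interpolation), ``normal`` bounds
    use mean +/- z * sd.  ``age_effect`` columns report the negated
    coefficient — the disease's shift in epigenetic age (positive =
    accelerated aging) — with correspondingly flipped bounds.
    """
    if not run.include_covariates or run.covariate_coefs.shape[1] == 0:
        warnings.warn("run has no covariates; empty covariate CI")
        return pd.DataFrame(
            columns=["coefficient", "lower", "upper",
                     "age_effect", "age_effect_lower", "age_effect_upper"]
        )
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    out = {}
    for name, col in run.covariate_coefs.items():
        vals = col.to_numpy(dtype=float)
        est = float(np.mean(vals))
        if method == "percentile":
            lo, hi = np.percentile(vals, [tail, 100.0 - tail])
        elif method == "normal":
            from scipy.stats import norm

            z = norm.ppf(1.0 - (1.0 - level) / 2.0)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            lo, hi = est - z * sd, est + z * sd
        else:
            raise ValueError(f"unknown CI method {method!r}")
        out[name] = {
            "coefficient": est,
            "lower": float(lo),
            "upper": float(hi),
            "age_effect": -est,
            "age_effect_lower": -float(hi),
            "age_effect_upper": -float(lo),
        }
    return pd.DataFrame(out).T


class PredictionDetails(NamedTuple):
    predictions: pd.Series
    n_imputed_sites: int
    n_imputed_cells: int


def predict_ages(
    model: ClockModel,
    matrix,
    sample_table: Optional[pd.DataFrame] = None,
    max_missing: float = 0.5,
    return_details: bool = False,
):
    """Apply a fitted clock to a (possibly cross-tissue) methylation matrix.

    Model sites absent from the matrix — and individual missing cells —
    are imputed with the training-mean beta (i.e. a standardized value of
    0); the counts are logged.  If more than ``max_missing`` of the
    model's sites are absent entirely the prediction is refused.  Without
    a sample table, covariates are taken as the reference class (all
    zeros) with a warning.
    """
    from .io_formats import MethylationMatrix

    beta = matrix.beta if isinstance(matrix, MethylationMatrix) else _as_frame(matrix)
    sites = model.sites
    present = [s for s in sites if s in beta.columns]
    n_absent = len(sites) - len(present)
    if len(sites) and n_absent / len(sites) > max_missing:
        raise ValueError(
            f"{n_absent}/{len(sites)} model sites missing from the matrix "
            f"(cap {max_missing:.0%}); refusing to predict"
        )
    X = pd.DataFrame(
        np.tile(model.feature_means.to_numpy(), (len(beta), 1)),
        index=beta.index,
        columns=sites,
    )
    n_cells = 0
    if present:
        vals = beta[present].to_numpy(dtype=float)
        nan_mask = np.isnan(vals)
        n_cells = int(nan_mask.sum())
        if n_cells:
            vals = np.where(nan_mask, np.tile(model.feature_means[present].to_numpy(), (len(beta), 1)), vals)
        X[present] = vals
    if n_absent or n_cells:
        logger.info(
            "imputed %d absent model sites and %d missing cells with training means",
            n_absent,
            n_cells,
        )

    D = None
    if model.include_covariates and len(model.covariate_coef):
        if sample_table is None:
            warnings.warn(
                "model has disease covariates but no sample table given; "
                "assuming the reference class for all samples"
            )
        else:
            D = encode_covariates(sample_table, vocabulary=model.covariate_levels)
    pred = pd.Series(_predict_frame(model, X, D), index=beta.index, name="predicted")
    if return_details:
        return PredictionDetails(pred, n_absent, n_cells)
    return pred


def feature_overlap(models: dict[str, ClockModel] | Sequence[ClockModel]):
    """Pairwise overlap counts of selected sites, plus per-model unique counts.

    Returns (overlap, unique): ``overlap`` is a symmetric DataFrame whose
    diagonal holds each model's selected-site count, ``unique`` a Series of
    sites selected by that model and no other.
    """
    if not isinstance(models, dict):
        models = {f"model{i}": m for i, m in enumerate(models)}
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    sets = {name: set(m.selected_sites) for name, m in models.items()}
    names = list(sets)
    overlap = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
        dtype=int,
    )
    unique = pd.Series(
        {
            a: len(sets[a] - set().union(*(sets[b] for b in names if b != a)))
            for a in names
        },
        dtype=int,
        name="unique_sites",
    )
    return overlap, unique
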