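"""Genome-wide site filtering and bootstrap stability selection.

The clock's feature set is built in three stages:

1. coverage filter — keep sites with sufficient read depth in every
   sample (default 50 reads, the depth at which predictive accuracy and
   site count balance on deep cohorts);
2. age-correlation filter — keep sites whose methylation correlates with
   chronological age (|rho| > 0.2 by default, Spearman);
3. stability selection — bootstrap the cohort B times (default 500), fit
   an Elastic Net at globally tuned penalties on each resample, and keep
   sites whose coefficient is nonzero in more than a fraction f (default
   one half) of the resamples.

Both filters are monotone: a stricter threshold always yields a subset of
the looser threshold's sites.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .clock_model import child_seed, default_grid, fit_elastic_net, tune_penalties
from .io_formats import MethylationMatrix

__all__ = [
    "FilterConfig",
    "StabilityResult",
    "filter_by_coverage",
    "correlate_with_age",
    "filter_by_correlation",
    "rank_and_truncate",
    "tune_hyperparameters_global",
    "stability_select",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds and bootstrap settings for feature selection."""

    min_coverage: int = 50
    min_abs_correlation: float = 0.2
    correlation_method: str = "spearman"
    n_bootstrap: int = 500
    frequency_threshold: float = 0.5
    seed: int = 0
    coverage_inclusive: bool = True  # True: keep coverage >= threshold

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 <= self.min_abs_correlation <= 1.0:
            raise ValueError("min_abs_correlation must be in [0, 1]")
        if self.correlation_method not in {"spearman", "pearson"}:
            raise ValueError("correlation method must be spearman or pearson")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 <= self.frequency_threshold < 1.0:
            raise ValueError("frequency_threshold must be in [0, 1)")


def filter_by_coverage(
    matrix: MethylationMatrix, min_coverage: int, inclusive: bool = True
) -> list[str]:
    """Sites covered by at least ``min_coverage`` reads in EVERY sample.

    ``inclusive=False`` switches to a strictly-greater rule.  Column order
    is preserved.  An empty result is permitted (with a warning).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    cov = matrix.coverage.to_numpy()
    ok = (cov >= min_coverage).all(axis=0) if inclusive else (cov > min_coverage).all(axis=0)
    sites = [s for s, keep in zip(matrix.sites, ok) if keep]
    if not sites:
        warnings.warn(f"no sites pass the coverage filter at {min_coverage}")
    return sites


def correlate_with_age(
    matrix: MethylationMatrix | pd.DataFrame,
    ages: Sequence[float],
    method: str = "spearman",
) -> pd.Series:
    """Per-site correlation between methylation level and chronological age.

    Spearman (average-rank ties) by default; Pearson by request.  Sites
    with zero beta variance across samples get correlation 0.  Requires
    at least 3 samples and no missing betas among the included samples.
    """
    beta = matrix.beta if isinstance(matrix, MethylationMatrix) else matrix
    ages = np.asarray(ages, dtype=float)
    n = beta.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 samples to correlate with age, got {n}")
    if len(ages) != n:
        raise ValueError("ages length must match sample count")
    vals = beta.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(
            "missing betas among included samples; apply the coverage filter first"
        )
    if method == "spearman":
        vals = rankdata(vals, axis=0)
        ages = rankdata(ages)
    elif method != "pearson":
        raise ValueError("method must be spearman or pearson")
    xc = vals - vals.mean(axis=0)
    yc = ages - ages.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.Series(corr, index=beta.columns, name=f"{method}_corr")


def filter_by_correlation(profile: pd.Series, min_abs_correlation: float) -> list[str]:
    """Sites with |correlation| strictly above the threshold (order kept)."""
    if not 0.0 <= min_abs_correlation <= 1.0:
        raise ValueError("min_abs_correlation must be in [0, 1]")
    mask = profile.abs().to_numpy() > min_abs_correlation
    return [s for s, keep in zip(profile.index, mask) if keep]


def rank_and_truncate(profile: pd.Series, m: int) -> list[str]:
    """The m sites with largest |correlation|, ties broken by site key."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > len(profile):
        warnings.warn(
            f"requested top {m} sites but only {len(profile)} available; returning all"
        )
        m = len(profile)
    order = sorted(profile.index, key=lambda s: (-abs(profile[s]), str(s)))
    return order[:m]


def tune_hyperparameters_global(
    X,
    y,
    k: int = 10,
    grid: Optional[Sequence[tuple[float, float]]] = None,
    seed: int = 0,
) -> tuple[float, float]:
    """10-fold CV over the penalty grid on the whole (filtered) dataset.

    Returns the (lam1, lam2) pair with minimum mean CV squared error;
    ties go to the strongest total penalty, then the lexicographically
    smallest pair.  See :func:`bsclock.clock_model.default_grid` for the
    default grid.
    """
    if grid is None:
        grid = default_grid(X, y)
    return tune_penalties(X, y, grid, k=k, seed=seed)


@dataclass
class StabilityResult:
    """Bootstrap selection frequencies and the final feature set."""

    frequencies: pd.Series      # per site, fraction of resamples with nonzero coef
    n_bootstrap: int
    frequency_threshold: float
    lam1: float
    lam2: float
    seed: int
    n_redrawn: int = 0

    @property
    def selected(self) -> list[str]:
        """Sites selected in more than the threshold fraction of resamples."""
        thr = self.frequency_threshold
        return [s for s, f in self.frequencies.items() if f > thr]

    def to_dir(self, outdir, config: Optional[dict] = None) -> None:
        os.makedirs(outdir, exist_ok=True)
        table = pd.DataFrame(
            {
                "site": self.frequencies.index,
                "frequency": self.frequencies.to_numpy(),
                "selected": [s in set(self.selected) for s in self.frequencies.index],
            }
        )
        table.to_csv(os.path.join(outdir, "stability.tsv"), sep="\t", index=False)
        manifest = {
            "n_bootstrap": self.n_bootstrap,
            "frequency_threshold": self.frequency_threshold,
            "lam1": self.lam1,
            "lam2": self.lam2,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "n_selected": len(self.selected),
        }
        if config:
            manifest["config"] = config
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)


def stability_select(
    X,
    y,
    lam1: float,
    lam2: float,
    n_bootstrap: int = 500,
    frequency_threshold: float = 0.5,
    seed: int = 0,
) -> StabilityResult:
    """Bootstrap stability selection at fixed penalties.

    Each of the B replicates draws n samples with replacement (replicate
    b is seeded from (master seed, b), so results do not depend on
    execution order), fits the Elastic Net, and records which site
    coefficients are nonzero.  A degenerate resample with zero age
    variance is redrawn (and logged) so B stays fixed.  The selected set
    is {sites with frequency > threshold} — strictly greater.
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    nonzero = np.zeros(p)
    n_redrawn = 0
    for b in range(n_bootstrap):
        attempt = 0
        while True:
            rng = np.random.default_rng(child_seed(seed, b, attempt))
            idx = rng.integers(0, n, size=n)
            if np.ptp(y[idx]) > 0:
                break
            attempt += 1
            n_redrawn += 1
            logger.info("bootstrap %d: constant-age resample redrawn", b)
        model = fit_elastic_net(
            X.iloc[idx], y[idx], lam1, lam2, include_covariates=False
        )
        nonzero += (model.coef.to_numpy() != 0.0).astype(float)
        if n_bootstrap >= 100 and (b + 1) % max(1, n_bootstrap // 10) == 0:
            logger.info("bootstrap %d/%d", b + 1, n_bootstrap)
    freqs = pd.Series(nonzero / n_bootstrap, index=X.columns, name="frequency")
    return StabilityResult(
        frequencies=freqs,
        n_bootstrap=n_bootstrap,
        frequency_threshold=frequency_threshold,
        lam1=lam1,
        lam2=lam2,
        seed=seed,
        n_redrawn=n_redrawn,
    )
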