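"""Accuracy metrics and aging-rate analytics.

Cohort accuracy is summarized by the Pearson correlation r between
predicted and chronological ages and by the mean absolute error in years.
Per sample, the aging rate is predicted/chronological age (>1 means
accelerated aging) and the age discrepancy is predicted - chronological;
the two satisfy discrepancy = chronological * (rate - 1) exactly.

Group contrasts (disease vs healthy, male vs female, optionally within
ten-year age bins) use the two-sided Mann-Whitney U test: aging rates are
ratios with skewed distributions, so a rank test is the safer default
(Welch's t is available by flag).  For small pooled samples the p-value
is computed exactly by enumerating group assignments, which handles ties;
larger samples use the normal approximation with tie correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionReport",
    "GroupComparison",
    "correlation_metric",
    "mae_metric",
    "aging_rates",
    "age_discrepancy",
    "prediction_report",
    "mann_whitney_u",
    "compare_groups",
    "accuracy_vs_feature_count",
]

EXACT_MW_MAX_POOLED = 18  # enumerate C(n, n1) group assignments up to this pooled n


def _aligned(pred, chron) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    chron = np.asarray(chron, dtype=float)
    if pred.shape != chron.shape:
        raise ValueError(
            f"predicted and chronological ages differ in length "
            f"({pred.shape} vs {chron.shape})"
        )
    return pred, chron


def correlation_metric(pred, chron) -> float:
    """Pearson product-moment correlation of predicted vs chronological age.

    Returns NaN (with a warning) if either vector has zero variance.
    """
    pred, chron = _aligned(pred, chron)
    if len(pred) < 3:
        raise ValueError("need >= 3 samples for a correlation")
    if not (np.isfinite(pred).all() and np.isfinite(chron).all()):
        raise ValueError("non-finite ages")
    if np.ptp(pred) == 0 or np.ptp(chron) == 0:
        warnings.warn("zero variance; correlation undefined (NA)")
        return float("nan")
    return float(np.corrcoef(pred, chron)[0, 1])


def mae_metric(pred, chron) -> float:
    """Mean absolute error between predicted and chronological age (years)."""
    pred, chron = _aligned(pred, chron)
    if len(pred) < 1:
        raise ValueError("need >= 1 sample")
    return float(np.mean(np.abs(pred - chron)))


def aging_rates(pred, chron) -> np.ndarray:
    """Per-sample aging rate: predicted / chronological age."""
    pred, chron = _aligned(pred, chron)
    bad = np.flatnonzero(chron <= 0)
    if len(bad):
        raise ValueError(
            f"chronological age must be > 0 for an aging rate (sample index {bad[0]})"
        )
    return pred / chron


def age_discrepancy(pred, chron) -> np.ndarray:
    """Per-sample age discrepancy: predicted - chronological age (years)."""
    pred, chron = _aligned(pred, chron)
    return pred - chron


@dataclass
class PredictionReport:
    """Per-sample predictions with rates and cohort-level r / MAE."""

    per_sample: pd.DataFrame  # sample, age, predicted, aging_rate, age_discrepancy
    r: float
    mae: float
    n: int

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


def prediction_report(samples, pred, chron) -> PredictionReport:
    pred, chron = _aligned(pred, chron)
    table = pd.DataFrame(
        {
            "sample": list(samples),
            "age": chron,
            "predicted": pred,
            "aging_rate": aging_rates(pred, chron),
            "age_discrepancy": age_discrepancy(pred, chron),
        }
    )
    return PredictionReport(
        per_sample=table,
        r=correlation_metric(pred, chron),
        mae=mae_metric(pred, chron),
        n=len(pred),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (ties count one half)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(x, y, exact_max_pooled: int = EXACT_MW_MAX_POOLED) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first group, p).

    For pooled n up to ``exact_max_pooled`` the null distribution of U is
    enumerated over all C(n, n1) group assignments of the pooled values
    (correct under ties); otherwise the normal approximation with tie
    correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    if n1 + n2 <= exact_max_pooled:
        pooled = np.concatenate([x, y])
        total = math.comb(n1 + n2, n1)
        # two-sided: fold the (symmetric) null distribution about n1*n2/2
        dev = abs(u - n1 * n2 / 2.0)
        hits = 0
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(comb)] = True
            u_b = _u_statistic(pooled[sel], pooled[~sel])
            if abs(u_b - n1 * n2 / 2.0) >= dev - 1e-12:
                hits += 1
        return u, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def _age_bin(age: float, width: float = 10.0) -> str:
    lo = math.floor(age / width) * width
    return f"[{lo:g},{lo + width:g})"


@dataclass
class GroupComparison:
    """Pairwise group contrasts of aging rates, optionally per age bin."""

    table: pd.DataFrame  # stratum, group_a, group_b, n_a, n_b, median_a, median_b, U, p

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compare_groups(
    rates,
    labels,
    ages: Optional[Sequence[float]] = None,
    stratify_bins: bool = False,
    bin_width: float = 10.0,
    test: str = "mannwhitney",
    bh_correct: bool = False,
) -> GroupComparison:
    """Compare aging-rate distributions between groups.

    Two-sided Mann-Whitney U (or Welch's t with ``test="welch"``) for
    every pair of labels, optionally within left-closed ten-year age bins
    [a, a+10) anchored at age 0.  A stratum in which a group is empty is
    reported with NA statistics.  ``bh_correct`` applies a
    Benjamini-Hochberg adjustment across all reported p-values (off by
    default; raw p-values are the primary output).
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if len(rates) != len(labels):
        raise ValueError("rates and labels length mismatch")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct group labels")
    if test not in {"mannwhitney", "welch"}:
        raise ValueError("test must be 'mannwhitney' or 'welch'")
    if stratify_bins:
        if ages is None:
            raise ValueError("stratify_bins requires ages")
        ages = np.asarray(ages, dtype=float)
        strata = [_age_bin(a, bin_width) for a in ages]
    else:
        strata = ["all"] * len(rates)
    strata = np.asarray(strata)

    rows = []
    for stratum in sorted(set(strata)):
        in_s = strata == stratum
        for a, b in itertools.combinations(uniq, 2):
            ga = rates[in_s & (labels == a)]
            gb = rates[in_s & (labels == b)]
            row = {
                "stratum": stratum,
                "group_a": a,
                "group_b": b,
                "n_a": len(ga),
                "n_b": len(gb),
                "median_a": float(np.median(ga)) if len(ga) else np.nan,
                "median_b": float(np.median(gb)) if len(gb) else np.nan,
            }
            if len(ga) == 0 or len(gb) == 0:
                row["U"] = np.nan
                row["p"] = np.nan
            elif test == "mannwhitney":
                row["U"], row["p"] = mann_whitney_u(ga, gb)
            else:
                t = stats.ttest_ind(ga, gb, equal_var=False)
                row["U"], row["p"] = float(t.statistic), float(t.pvalue)
            rows.append(row)
    table = pd.DataFrame(rows)
    if bh_correct:
        mask = table["p"].notna()
        p = table.loc[mask, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        table.loc[mask, "p_adjusted"] = adj
    return GroupComparison(table)


def accuracy_vs_feature_count(
    matrix,
    sample_table: pd.DataFrame,
    m_values: Sequence[int],
    seed: int = 0,
    include_covariates: bool = False,
    grid=None,
    inner_k: int = 5,
    correlation_method: str = "spearman",
) -> pd.DataFrame:
    """Prediction accuracy as a function of the number of top-ranked sites.

    Sites are ranked by |correlation with age| on the full cohort; for
    each m the top-m sites are fed through the LOOCV protocol and the
    resulting Pearson r and MAE recorded.  Returns a (m, r, mae) table.
    """
    from .clock_model import loocv_predict
    from .feature_selection import correlate_with_age, rank_and_truncate
    from .io_formats import MethylationMatrix

    beta = matrix.beta if isinstance(matrix, MethylationMatrix) else matrix
    m_values = list(m_values)
    if any(m < 1 for m in m_values):
        raise ValueError("m values must be >= 1")
    if m_values != sorted(m_values):
        raise ValueError("m_values must be sorted ascending")
    ages = sample_table["age"].to_numpy(dtype=float)
    profile = correlate_with_age(beta, ages, method=correlation_method)
    rows = []
    for m in m_values:
        sites = rank_and_truncate(profile, m)
        run = loocv_predict(
            beta[sites],
            sample_table,
            include_covariates=include_covariates,
            inner_k=inner_k,
            grid=grid,
            seed=seed,
        )
        rows.append(
            {
                "m": m,
                "r": correlation_metric(run.table["predicted"], run.table["age"]),
                "mae": mae_metric(run.table["predicted"], run.table["age"]),
            }
        )
    return pd.DataFrame(rows)
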