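"""Seeded synthetic cohorts with the statistical structure the clock assumes.

The generator emulates how per-CpG betas arise in bisulfite sequencing:

* each sample has a latent epigenetic age ``A = age + disease offset +
  Normal(0, noise_sd)`` (disease shifts epigenetic age by a stated number
  of years — this gives covariate recovery a known target);
* a causal site s tracks it linearly, ``mu_s(A) = clip(b_s + slope_s *
  A/100, 0.01, 0.99)`` with the slope in beta-units per 100 years;
  non-causal sites have an age-independent mean;
* read depth is drawn per (sample, site) as ``C = 1 + Poisson(m_s)`` with
  a per-site Gamma mean — marginally a shifted negative binomial — so the
  coverage filter has genuine work to do;
* the observed beta is ``Binomial(C, mu) / C``: binomial counting noise,
  not Gaussian noise on the beta, which is what makes coverage thresholds
  meaningful.

Everything is deterministic given the config seed.  Causal baselines are
drawn so the mean methylation track stays within [0.05, 0.95] across the
whole age range; otherwise clipping would silently flatten the stated
slope at the extremes.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clock_model import child_seed
from .io_formats import MethylationMatrix, site_key, validate_sample_table, write_matrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_multi_tissue",
    "write_cohort",
]

MU_FLOOR, MU_CEIL = 0.01, 0.99  # hard clip on per-read methylation probability
BASE_FLOOR, BASE_CEIL = 0.05, 0.95  # causal tracks stay inside this band by design


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    Defaults describe the reference cohort used throughout the test
    suite: 200 samples aged 1-85, 2000 sites of which 100 drift with age
    at 0.3-0.6 beta-units per century, mean read depth 60, and 3 years of
    biological noise on the latent epigenetic age.
    """

    n_samples: int = 200
    n_sites: int = 2000
    n_causal: int = 100
    slope_range: tuple[float, float] = (0.3, 0.6)  # |slope|, beta-units / 100 yr
    baseline_beta_range: tuple[float, float] = (0.1, 0.9)
    age_range: tuple[float, float] = (1.0, 85.0)
    mean_coverage: float = 60.0
    coverage_dispersion: float = 16.0  # Gamma shape of per-site mean depth
    disease_offsets: dict[str, float] = field(default_factory=dict)  # level -> years
    disease_prevalence: dict[str, float] = field(default_factory=dict)
    sex_ratio: float = 0.5  # fraction female
    noise_sd: float = 3.0  # years, on latent epigenetic age
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_sites:
            raise ValueError("n_causal must be <= n_sites")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0 < self.slope_range[0] <= self.slope_range[1]:
            raise ValueError("slope_range must be 0 < lo <= hi")
        if not 0 < self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing and positive")
        if self.mean_coverage < 1:
            raise ValueError("mean_coverage must be >= 1")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        extra = set(self.disease_offsets) - set(self.disease_prevalence)
        if extra:
            raise ValueError(f"offsets for diseases without prevalence: {sorted(extra)}")
        total = sum(self.disease_prevalence.values())
        if any(p < 0 for p in self.disease_prevalence.values()) or total > 1:
            raise ValueError("prevalences must be >= 0 and sum to <= 1")
        if "normal" in self.disease_prevalence:
            raise ValueError("'normal' is the implicit remainder, not a disease level")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    causal_sites: list[str]
    slopes: pd.Series      # signed, beta-units per 100 years, causal sites only
    baselines: pd.Series   # all sites
    latent_age: pd.Series  # per sample, years
    disease_offsets: dict[str, float]


@dataclass
class SyntheticCohort:
    matrix: MethylationMatrix
    samples: pd.DataFrame
    truth: GroundTruth


def _site_keys(n_sites: int) -> list[str]:
    return [site_key("chr1", 1000 + 100 * i) for i in range(n_sites)]


def _draw_roster(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    n = config.n_samples
    ids = [f"S{i:04d}" for i in range(n)]
    ages = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.uniform(size=n) < config.sex_ratio, "female", "male")
    levels = list(config.disease_prevalence)
    probs = [config.disease_prevalence[lv] for lv in levels]
    levels.append("normal")
    probs.append(1.0 - sum(probs))
    disease = rng.choice(levels, size=n, p=probs)
    return validate_sample_table(
        pd.DataFrame({"sample": ids, "age": ages, "sex": sex, "disease": disease})
    )


def _draw_causal_slopes(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    mags = rng.uniform(*config.slope_range, size=config.n_causal)
    signs = rng.choice([-1.0, 1.0], size=config.n_causal)
    return mags * signs


def _draw_baselines(
    rng: np.random.Generator,
    config: SimulationConfig,
    causal_idx: np.ndarray,
    slopes: np.ndarray,
) -> np.ndarray:
    lo_cfg, hi_cfg = config.baseline_beta_range
    base = rng.uniform(lo_cfg, hi_cfg, size=config.n_sites)
    a0, a1 = config.age_range
    for j, s in zip(causal_idx, slopes):
        # feasible baseline so b + s*A/100 stays in the safe band over the age range
        if s >= 0:
            lo, hi = BASE_FLOOR - s * a0 / 100.0, BASE_CEIL - s * a1 / 100.0
        else:
            lo, hi = BASE_FLOOR - s * a1 / 100.0, BASE_CEIL - s * a0 / 100.0
        lo2, hi2 = max(lo, lo_cfg), min(hi, hi_cfg)
        if lo2 >= hi2:  # configured range incompatible with the slope; use feasible band
            lo2, hi2 = lo, hi
        base[j] = rng.uniform(lo2, hi2)
    return base


def _draw_betas(
    rng: np.random.Generator,
    config: SimulationConfig,
    latent_age: np.ndarray,
    baselines: np.ndarray,
    causal_idx: np.ndarray,
    slopes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n, p = config.n_samples, config.n_sites
    mu = np.tile(baselines, (n, 1))
    mu[:, causal_idx] = baselines[causal_idx] + np.outer(latent_age / 100.0, slopes)
    mu = np.clip(mu, MU_FLOOR, MU_CEIL)
    site_depth = rng.gamma(
        config.coverage_dispersion,
        (config.mean_coverage - 1.0) / config.coverage_dispersion,
        size=p,
    )
    coverage = 1 + rng.poisson(np.broadcast_to(site_depth, (n, p)))
    beta = rng.binomial(coverage, mu) / coverage
    return beta, coverage


def simulate_cohort(config: Optional[SimulationConfig] = None, **overrides) -> SyntheticCohort:
    """Generate one cohort; deterministic given ``config.seed``.

    Keyword overrides are applied on top of the given (or default) config.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    samples = _draw_roster(rng, config)
    offsets = np.array(
        [config.disease_offsets.get(d, 0.0) for d in samples["disease"]], dtype=float
    )
    latent = (
        samples["age"].to_numpy()
        + offsets
        + rng.normal(0.0, config.noise_sd, size=config.n_samples)
    )
    causal_idx = np.sort(rng.choice(config.n_sites, size=config.n_causal, replace=False))
    slopes = _draw_causal_slopes(rng, config)
    baselines = _draw_baselines(rng, config, causal_idx, slopes)
    beta, coverage = _draw_betas(rng, config, latent, baselines, causal_idx, slopes)

    keys = _site_keys(config.n_sites)
    ids = list(samples.index)
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=ids, columns=keys),
        pd.DataFrame(coverage, index=ids, columns=keys, dtype=np.int64),
    )
    truth = GroundTruth(
        causal_sites=[keys[j] for j in causal_idx],
        slopes=pd.Series(slopes, index=[keys[j] for j in causal_idx]),
        baselines=pd.Series(baselines, index=keys),
        latent_age=pd.Series(latent, index=ids),
        disease_offsets=dict(config.disease_offsets),
    )
    return SyntheticCohort(matrix=matrix, samples=samples, truth=truth)


def simulate_multi_tissue(
    configs: Sequence[SimulationConfig], shared_causal_fraction: float
) -> list[SyntheticCohort]:
    """Cohorts for several tissues measured on one shared sample roster.

    All tissues share the stated fraction of causal sites (identical
    sites and slopes); each tissue's remaining causal sites are drawn
    from disjoint pools, so the ground-truth pairwise causal overlap is
    exactly the shared set.  Ages, sex and disease come from the first
    config's roster; latent epigenetic age and betas are drawn per tissue
    (tissue-specific biological noise and read sampling).
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 tissue configs")
    if not 0.0 <= shared_causal_fraction <= 1.0:
        raise ValueError("shared_causal_fraction must be in [0, 1]")
    n_sites = configs[0].n_sites
    n_samples = configs[0].n_samples
    for c in configs:
        if c.n_sites != n_sites or c.n_samples != n_samples:
            raise ValueError("tissue configs must share n_sites and n_samples")

    n_shared = round(shared_causal_fraction * min(c.n_causal for c in configs))
    own_counts = [c.n_causal - n_shared for c in configs]
    if n_shared + sum(own_counts) > n_sites:
        raise ValueError("not enough sites for disjoint tissue-specific causal sets")

    rng0 = np.random.default_rng(configs[0].seed)
    samples = _draw_roster(rng0, configs[0])
    pool = rng0.permutation(n_sites)
    shared_idx = np.sort(pool[:n_shared])
    shared_slopes = (
        rng0.uniform(*configs[0].slope_range, size=n_shared)
        * rng0.choice([-1.0, 1.0], size=n_shared)
    )
    cursor = n_shared
    keys = _site_keys(n_sites)

    cohorts = []
    for t, config in enumerate(configs):
        rng = np.random.default_rng(child_seed(config.seed, "tissue", t))
        own_idx = np.sort(pool[cursor : cursor + own_counts[t]])
        cursor += own_counts[t]
        causal_idx = np.sort(np.concatenate([shared_idx, own_idx]).astype(int))
        slope_by_idx = dict(zip(shared_idx, shared_slopes))
        own_slopes = (
            rng.uniform(*config.slope_range, size=own_counts[t])
            * rng.choice([-1.0, 1.0], size=own_counts[t])
        )
        slope_by_idx.update(zip(own_idx, own_slopes))
        slopes = np.array([slope_by_idx[j] for j in causal_idx])

        offsets = np.array(
            [config.disease_offsets.get(d, 0.0) for d in samples["disease"]]
        )
        latent = (
            samples["age"].to_numpy()
            + offsets
            + rng.normal(0.0, config.noise_sd, size=n_samples)
        )
        baselines = _draw_baselines(rng, config, causal_idx, slopes)
        beta, coverage = _draw_betas(rng, config, latent, baselines, causal_idx, slopes)
        ids = list(samples.index)
        matrix = MethylationMatrix(
            pd.DataFrame(beta, index=ids, columns=keys),
            pd.DataFrame(coverage, index=ids, columns=keys, dtype=np.int64),
        )
        truth = GroundTruth(
            causal_sites=[keys[j] for j in causal_idx],
            slopes=pd.Series(slopes, index=[keys[j] for j in causal_idx]),
            baselines=pd.Series(baselines, index=keys),
            latent_age=pd.Series(latent, index=ids),
            disease_offsets=dict(config.disease_offsets),
        )
        cohorts.append(SyntheticCohort(matrix=matrix, samples=samples.copy(), truth=truth))
    return cohorts


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the matrix bundle plus a ground-truth JSON."""
    write_matrix(cohort.matrix, cohort.samples, outdir)
    truth = {
        "causal_sites": cohort.truth.causal_sites,
        "slopes": {k: float(v) for k, v in cohort.truth.slopes.items()},
        "latent_age": {k: float(v) for k, v in cohort.truth.latent_age.items()},
        "disease_offsets": cohort.truth.disease_offsets,
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
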