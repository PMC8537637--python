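"""Synthetic study cohort and virtual trial population.

The original 204-patient clinical covariate table is not public, so a
synthetic source cohort stands in for it (all distributions here are
synthetic emulations, not patient data).  Defaults emulate the simulation
study's conditions: 194 source patients with baseline Mayo endoscopic
subscore 2 or 3 (49%:51%), adult body weights (log-normal, mean 72.3 kg --
the mean weight implied by a 1084 mg mean cumulative dose at 3 x 5 mg/kg),
fat-free mass from weight/height/sex via the Janmahasatian body-composition
formula, and 50% prevalences of corticosteroid use and extensive colitis.
Each source patient is expanded by Monte Carlo sampling of interindividual
(and interoccasion) variability -- 200 samples per patient, 38,800 virtual
patients in total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .exposure_response import ERParams, category_probabilities
from .pk_model import PopPKParams

COHORT_COLUMNS = ["patient_id", "body_weight_kg", "height_cm", "sex", "ffm_kg",
                  "baseline_mayo", "steroid_use", "extensive_colitis"]


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic source cohort.

    Weights are log-normal with arithmetic mean ``weight_mean_kg`` and
    coefficient of variation ``weight_cv``; heights are normal within sex.
    """

    n_source: int = 194
    n_expand: int = 200
    mayo3_fraction: float = 0.51
    weight_mean_kg: float = 72.3
    weight_cv: float = 0.20
    height_mean_male_cm: float = 176.0
    height_sd_male_cm: float = 7.0
    height_mean_female_cm: float = 163.0
    height_sd_female_cm: float = 6.5
    male_fraction: float = 0.5
    steroid_prevalence: float = 0.5
    extensive_prevalence: float = 0.5
    seed: int = 20211006

    def __post_init__(self) -> None:
        if not (self.n_source > 0 and self.n_expand > 0):
            raise ValueError("n_source and n_expand must be positive integers")
        for name in ("mayo3_fraction", "male_fraction", "steroid_prevalence",
                     "extensive_prevalence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not (self.weight_mean_kg > 0 and self.weight_cv > 0):
            raise ValueError("weight distribution parameters must be positive")
        if min(self.height_mean_male_cm, self.height_sd_male_cm,
               self.height_mean_female_cm, self.height_sd_female_cm) <= 0:
            raise ValueError("height distribution parameters must be positive")

    def replace(self, **changes) -> "CohortConfig":
        return dataclasses.replace(self, **changes)


def janmahasatian_ffm(weight_kg, height_cm, is_male):
    """Fat-free mass (kg) from weight, height and sex (Janmahasatian)."""
    wt = np.asarray(weight_kg, dtype=float)
    ht = np.asarray(height_cm, dtype=float)
    if np.any(wt <= 0) or np.any(ht <= 0):
        raise ValueError("weight and height must be strictly positive")
    bmi = wt / (ht / 100.0) ** 2
    male = np.asarray(is_male, dtype=bool)
    ffm = np.where(male,
                   9.27e3 * wt / (6.68e3 + 216.0 * bmi),
                   9.27e3 * wt / (8.78e3 + 244.0 * bmi))
    return ffm


def _largest_remainder_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1.0
    return counts


def generate_source_cohort(config: CohortConfig,
                           seed: int | None = None) -> pd.DataFrame:
    """Draw the synthetic source cohort; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_source

    male = rng.random(n) < config.male_fraction
    sigma = np.sqrt(np.log1p(config.weight_cv ** 2))
    mu = np.log(config.weight_mean_kg) - 0.5 * sigma ** 2

    def draw_anthropometry(m: np.ndarray):
        k = len(m)
        h = np.where(
            m,
            rng.normal(config.height_mean_male_cm, config.height_sd_male_cm, k),
            rng.normal(config.height_mean_female_cm, config.height_sd_female_cm, k))
        h = np.clip(h, 140.0, 210.0)
        w = rng.lognormal(mu, sigma, k)
        return h, w

    height, weight = draw_anthropometry(male)
    # reject implausible tall-and-light tail combinations (BMI so low that the
    # body-composition formula would give fat-free mass >= weight)
    for _ in range(100):
        ffm = janmahasatian_ffm(weight, height, male)
        bad = ~((ffm > 0) & (ffm < 0.95 * weight))
        if not bad.any():
            break
        height[bad], weight[bad] = draw_anthropometry(male[bad])
    else:
        raise ValueError("degenerate cohort: fat-free mass outside (0, weight)")

    n2, n3 = _largest_remainder_counts(
        n, np.array([1.0 - config.mayo3_fraction, config.mayo3_fraction]))
    mayo = rng.permutation(np.repeat([2, 3], [n2, n3]))

    steroid = rng.random(n) < config.steroid_prevalence
    extensive = rng.random(n) < config.extensive_prevalence

    return pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "body_weight_kg": weight,
        "height_cm": height,
        "sex": np.where(male, "M", "F"),
        "ffm_kg": ffm,
        "baseline_mayo": mayo,
        "steroid_use": steroid,
        "extensive_colitis": extensive,
    })


def expand_virtual(cohort: pd.DataFrame, params: PopPKParams,
                   n_expand: int = 200, seed: int | None = None,
                   n_occasions: int = 3) -> pd.DataFrame:
    """Expand the cohort by Monte Carlo sampling of random effects.

    Each source patient receives ``n_expand`` independent draws of the
    interindividual deviations (eta_ke, eta_v) and of one interoccasion
    deviation per dosing occasion (kappa_1..kappa_K).  The returned frame
    has one row per virtual patient (|cohort| x n_expand) and carries the
    truth random effects used by every dosing scenario.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if n_expand <= 0:
        raise ValueError("n_expand must be positive")
    rng = np.random.default_rng(seed)
    n = len(cohort) * n_expand
    pop = cohort.loc[cohort.index.repeat(n_expand)].reset_index(drop=True)
    pop["replicate"] = np.tile(np.arange(1, n_expand + 1), len(cohort))
    pop["eta_ke"] = rng.normal(0.0, params.omega_ke, n)
    pop["eta_v"] = rng.normal(0.0, params.omega_v, n)
    kappa = rng.normal(0.0, params.omega_iov_ke, (n, n_occasions))
    for k in range(n_occasions):
        pop[f"kappa{k + 1}"] = kappa[:, k]
    return pop


def log_uniform_exposure_sampler(low: float = 1e2,
                                 high: float = 2e4) -> Callable:
    """AUC sampler spanning the rise, midpoint and plateau of the ER curves."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.uniform(np.log(low), np.log(high), n))

    return sample


def generate_er_dataset(n: int, er_truth: ERParams,
                        exposure_sampler: Callable | None = None,
                        seed: int | None = None,
                        mayo3_fraction: float = 0.5) -> pd.DataFrame:
    """Simulate (AUC, baseline, ordinal outcome) records from known truth.

    Outcomes are drawn from the sequential-model category probabilities at
    the sampled exposures; used for profiling and recovery tests.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    sampler = exposure_sampler or log_uniform_exposure_sampler()
    auc = np.asarray(sampler(n, rng), dtype=float)
    mayo = np.where(rng.random(n) < mayo3_fraction, 3, 2)
    probs = category_probabilities(auc, mayo, er_truth)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=-1)
    outcome = 1 + (u[:, None] > cum).sum(axis=-1)
    outcome = np.minimum(outcome, 3)
    return pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "auc_d84": auc,
        "baseline_mayo": mayo,
        "outcome_mayo_d84": outcome,
    })
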