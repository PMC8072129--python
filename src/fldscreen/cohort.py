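"""Seeded synthetic physical-examination cohorts.

The generator emulates the statistical structure a routine-exam screening
dataset hands to the downstream pipeline: a ~23% fatty-liver prevalence,
age- and sex-dependent analyte distributions, class separation on the
liver-panel analytes, a nonlinear dependence of risk on feature
combinations (so symbolic feature search has something to find), and
column-wise missingness including near-empty columns.

Generative model
----------------
* ``sex ~ Bernoulli(male_fraction)``; ``age`` from a three-component
  truncated-normal mixture over ``age_range``, rounded to whole years.
* Six core analytes — TG, ALT, AST, GGT, UA, GLU — are log-normal with
  sex- and age-dependent log-locations and a fixed latent correlation
  structure (AST tracks ALT; UA and GLU track TG weakly).
* Latent risk score
  ``eta = b0 + b_TG*TG + b_logALT*log(ALT) + b_GGT*GGT + b_GLU*GLU + b_age*age_z``
  with ``age_z = (age - 47)/16``; the label is ``Bernoulli(logistic(eta))``.
  The intercept ``b0`` is calibrated by root search so the expected
  prevalence matches ``prevalence_target``.
* Noise features are log-normal draws independent of everything else.
* Missingness is injected per column, completely at random, with
  ``n_sparse_columns`` columns pushed to a near-empty rate.

Everything is driven by named substreams of a single seed, so the same
config always yields a bit-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .exceptions import CalibrationError, ConfigurationError
from .tables import AGE, LABEL, SEX, feature_columns

#: Core analytes; the first six informative columns, always generated.
CORE_ANALYTES = ("TG", "ALT", "AST", "GGT", "UA", "GLU")

# Per-analyte log-scale parameters: (log-location, age slope on age_z,
# sex contrast on sex-0.5, residual log-SD). Units: TG, GLU mmol/L;
# ALT, AST, GGT U/L; UA umol/L.
_ANALYTE_PARAMS = {
    "TG": (math.log(1.30), 0.10, 0.18, 0.45),
    "ALT": (math.log(24.0), 0.05, 0.25, 0.50),
    "AST": (math.log(23.0), 0.06, 0.12, 0.35),
    "GGT": (math.log(28.0), 0.10, 0.35, 0.55),
    "UA": (math.log(330.0), 0.02, 0.21, 0.22),
    "GLU": (math.log(5.2), 0.10, 0.02, 0.13),
}

# Age mixture: (weight, mean years, SD years), truncated to age_range.
_AGE_MIXTURE = ((0.25, 30.0, 9.0), (0.45, 46.0, 11.0), (0.30, 65.0, 9.0))

#: Default latent-risk coefficients. Scaled so the Bayes score separates
#: cases from controls with AUC ~ 0.92 at the default prevalence.
DEFAULT_EFFECT_SIZES: Mapping[str, float] = {
    "TG": 1.8,        # per mmol/L
    "log_ALT": 2.5,   # per log U/L
    "GGT": 0.026,     # per U/L
    "GLU": 0.74,      # per mmol/L
    "age": 0.74,      # per standardised age unit
}

_AGE_CENTER, _AGE_SCALE = 47.0, 16.0
_CALIBRATION_N = 50_000
_NOISE_PARAM_SEED = 20210412  # fixes noise-column locations/scales across runs

# named rng substreams
_S_DEMOGRAPHICS, _S_LABEL, _S_NOISE, _S_UNLABELLED, _S_MISSING, _S_CALIB = (
    0, 1, 2, 3, 4, 101)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``missing_rates`` is either one rate applied to every feature column or
    a mapping from column name to rate (unlisted columns get 0). The last
    ``n_sparse_columns`` feature columns are additionally forced to at
    least ``sparse_missing_rate`` missing, emulating items most patients
    never had measured. ``unlabeled_fraction`` of rows get no ultrasound
    label (``fld`` missing).
    """

    n_samples: int = 10_000
    prevalence_target: float = 0.23
    male_fraction: float = 0.55
    age_range: tuple[float, float] = (18.0, 95.0)
    n_informative: int = 6
    n_noise: int = 24
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    missing_rates: float | Mapping[str, float] = 0.12
    n_sparse_columns: int = 2
    sparse_missing_rate: float = 0.95
    unlabeled_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ConfigurationError("prevalence_target must lie in (0, 1)")
        if not 0.0 < self.male_fraction < 1.0:
            raise ConfigurationError("male_fraction must lie in (0, 1)")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy min < max")
        if lo < 0:
            raise ConfigurationError("age_range must be non-negative")
        if self.n_informative < len(CORE_ANALYTES):
            raise ConfigurationError(
                f"n_informative must be >= {len(CORE_ANALYTES)}: the core "
                f"analytes {CORE_ANALYTES} carry the planted signal")
        if self.n_noise < 0 or self.n_sparse_columns < 0:
            raise ConfigurationError("feature counts must be non-negative")
        if self.n_sparse_columns > self.n_informative + self.n_noise:
            raise ConfigurationError("more sparse columns than feature columns")
        for key, value in self.effect_sizes.items():
            if not np.isfinite(value):
                raise ConfigurationError(f"effect size {key!r} is not finite")
        unknown = set(self.effect_sizes) - set(DEFAULT_EFFECT_SIZES)
        if unknown:
            raise ConfigurationError(f"unknown effect-size terms: {sorted(unknown)}")
        for rate in self._rate_items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("missing rates must lie in [0, 1]")
        if not 0.9 <= self.sparse_missing_rate <= 1.0:
            raise ConfigurationError("sparse_missing_rate must lie in [0.9, 1]")
        if not 0.0 <= self.unlabeled_fraction < 1.0:
            raise ConfigurationError("unlabeled_fraction must lie in [0, 1)")

    def _rate_items(self):
        if isinstance(self.missing_rates, Mapping):
            return list(self.missing_rates.values())
        return [float(self.missing_rates)]

    def rate_for(self, column: str) -> float:
        if isinstance(self.missing_rates, Mapping):
            return float(self.missing_rates.get(column, 0.0))
        return float(self.missing_rates)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _sample_demographics(config: CohortConfig, n: int, rng: np.random.Generator):
    lo, hi = config.age_range
    weights = np.array([w for w, _, _ in _AGE_MIXTURE])
    comps = rng.choice(len(_AGE_MIXTURE), size=n, p=weights / weights.sum())
    mu = np.array([m for _, m, _ in _AGE_MIXTURE])[comps]
    sd = np.array([s for _, _, s in _AGE_MIXTURE])[comps]
    a, b = (lo - mu) / sd, (hi - mu) / sd
    age = truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    age = np.clip(np.rint(age), math.ceil(lo), math.floor(hi))
    sex = (rng.random(n) < config.male_fraction).astype(int)
    return age, sex


def _sample_analytes(config: CohortConfig, age, sex, rng):
    """Core analytes plus extra informative columns; returns dict of arrays."""
    n = len(age)
    age_z = (age - _AGE_CENTER) / _AGE_SCALE
    sex_c = sex - 0.5
    e = {name: rng.standard_normal(n) for name in CORE_ANALYTES}
    g = {
        "TG": e["TG"],
        "ALT": e["ALT"],
        "AST": 0.75 * e["ALT"] + math.sqrt(1 - 0.75**2) * e["AST"],
        "GGT": 0.35 * e["ALT"] + math.sqrt(1 - 0.35**2) * e["GGT"],
        "UA": 0.50 * e["TG"] + math.sqrt(1 - 0.50**2) * e["UA"],
        "GLU": 0.25 * e["TG"] + math.sqrt(1 - 0.25**2) * e["GLU"],
    }
    values = {}
    for name in CORE_ANALYTES:
        loc, a_slope, s_slope, sigma = _ANALYTE_PARAMS[name]
        values[name] = np.exp(loc + a_slope * age_z + s_slope * sex_c
                              + sigma * g[name])
    # extra informative columns: weakly coupled to the TG latent
    for j in range(len(CORE_ANALYTES), config.n_informative):
        eps = rng.standard_normal(n)
        latent = 0.4 * e["TG"] + math.sqrt(1 - 0.16) * eps
        values[f"INF{j + 1:02d}"] = np.exp(
            math.log(50.0) + 0.05 * age_z + 0.10 * sex_c + 0.4 * latent)
    return values, age_z


def _latent_slope(config: CohortConfig, analytes, age_z) -> np.ndarray:
    b = {**DEFAULT_EFFECT_SIZES, **dict(config.effect_sizes)}
    return (b["TG"] * analytes["TG"]
            + b["log_ALT"] * np.log(analytes["ALT"])
            + b["GGT"] * analytes["GGT"]
            + b["GLU"] * analytes["GLU"]
            + b["age"] * age_z)


def calibrate_intercept(config: CohortConfig) -> float:
    """Intercept ``b0`` matching the target prevalence.

    Draws a fixed calibration sample of the latent slope and solves
    ``mean(logistic(b0 + slope)) = prevalence_target`` by bracketed root
    search; the mean is strictly increasing in ``b0``, so the root is
    unique. With all slopes zero this returns the exact logit of the
    target (up to solver tolerance).
    """
    config.validate()
    rng = _rng(config, _S_CALIB)
    age, sex = _sample_demographics(config, _CALIBRATION_N, rng)
    analytes, age_z = _sample_analytes(config, age, sex, rng)
    slope = _latent_slope(config, analytes, age_z)
    if not np.all(np.isfinite(slope)):
        raise CalibrationError("latent score is degenerate (non-finite)")

    def excess(b0: float) -> float:
        return float(expit(b0 + slope).mean() - config.prevalence_target)

    lo, hi = -60.0, 60.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise CalibrationError("target prevalence unreachable for this score")
    return float(brentq(excess, lo, hi, xtol=1e-12))


def _noise_columns(config: CohortConfig, n: int, rng) -> dict[str, np.ndarray]:
    param_rng = np.random.default_rng(_NOISE_PARAM_SEED)
    out = {}
    for j in range(config.n_noise):
        loc = param_rng.uniform(0.0, 4.6)       # exp -> roughly 1..100
        sigma = param_rng.uniform(0.2, 0.6)
        out[f"noise{j + 1:02d}"] = np.exp(loc + sigma * rng.standard_normal(n))
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a complete (no missing exam values) synthetic cohort.

    Columns: ``sex``, ``age``, ``fld`` (NaN for the unlabelled fraction),
    the core analytes, extra informative columns, then noise columns.
    Missingness in the exam features is injected separately by
    :func:`inject_missingness`.
    """
    config.validate()
    n = config.n_samples
    b0 = calibrate_intercept(config)
    rng = _rng(config, _S_DEMOGRAPHICS)
    age, sex = _sample_demographics(config, n, rng)
    analytes, age_z = _sample_analytes(config, age, sex, rng)
    eta = b0 + _latent_slope(config, analytes, age_z)
    label = (_rng(config, _S_LABEL).random(n) < expit(eta)).astype(float)
    if config.unlabeled_fraction > 0:
        drop = _rng(config, _S_UNLABELLED).random(n) < config.unlabeled_fraction
        label[drop] = np.nan
    noise = _noise_columns(config, n, _rng(config, _S_NOISE))
    data = {SEX: sex, AGE: age, LABEL: label}
    data.update(analytes)
    data.update(noise)
    return pd.DataFrame(data)


def inject_missingness(table: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Mask exam-feature cells completely at random at per-column rates.

    The last ``n_sparse_columns`` feature columns are masked at
    ``max(rate, sparse_missing_rate)``; ``sex``, ``age`` and ``fld`` are
    never masked. Returns a new table.
    """
    config.validate()
    out = table.copy()
    rng = _rng(config, _S_MISSING)
    features = feature_columns(table)
    sparse = set(features[len(features) - config.n_sparse_columns:]) \
        if config.n_sparse_columns else set()
    for col in features:
        rate = config.rate_for(col)
        if col in sparse:
            rate = max(rate, config.sparse_missing_rate)
        if rate <= 0.0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort and inject its configured missingness."""
    return inject_missingness(generate_cohort(config), config)
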