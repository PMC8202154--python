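"""Synthetic survival cohorts with a latent biological-age offset.

The generator produces per-participant tables with the statistical skeleton
that the biological-age pipeline assumes about a middle-aged population
cohort: chronological age (CA) uniform over the recruitment window, a latent
Gaussian offset ``delta`` so that the true biological age is
``BA_true = CA + delta``, biomarkers that track ``BA_true`` approximately
linearly with block-correlated residuals (adiposity, lung function, blood
pressure and lipid panels move together), two right-censored outcomes whose
hazards depend on ``BA_true`` only, and baseline eligibility fields whose
failure probabilities increase with ``delta`` (the biologically older are
likelier to be on medication, report worse health, walk slowly or smoke).

Everything is driven by a single :class:`SimulationConfig`; a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "EligibilityParams",
    "generate_cohort",
    "generate_biomarkers",
    "generate_outcomes",
    "generate_eligibility",
    "DEFAULT_PANEL",
]

# Default biomarker panel: (name, block, slope_male, slope_female, intercept,
# residual_sd).  Slopes are per year of biological age, in raw biomarker
# units; blocks give the correlated adiposity / lung / blood-pressure / lipid
# groups; block=None is a free-standing biomarker.  Slope signs and rough
# magnitudes follow the usual clinical picture (lung function, IGF-1, grip
# strength and albumin fall with age; blood pressure, cystatin C, reaction
# time and HbA1c rise; lipid trends are steeper in women).
DEFAULT_PANEL: tuple[tuple[str, str | None, float, float, float, float], ...] = (
    ("bmi", "adiposity", 0.050, 0.050, 26.0, 4.0),
    ("waist_hip_ratio", "adiposity", 0.0012, 0.0012, 0.90, 0.06),
    ("body_fat_pct", "adiposity", 0.10, 0.10, 25.0, 7.0),
    ("fev1", "lung", -0.032, -0.028, 4.6, 0.45),
    ("fvc", "lung", -0.038, -0.033, 5.8, 0.60),
    ("peak_flow", "lung", -2.2, -1.8, 520.0, 85.0),
    ("sbp", "bp", 0.45, 0.55, 112.0, 13.0),
    ("dbp", "bp", 0.10, 0.12, 78.0, 9.0),
    ("pulse_rate", "bp", 0.0, 0.0, 68.0, 10.0),
    ("ldl_c", "lipids", 0.004, 0.030, 3.5, 0.80),
    ("apob", "lipids", 0.001, 0.008, 1.00, 0.22),
    ("total_chol", "lipids", 0.006, 0.040, 5.4, 1.00),
    ("cystatin_c", None, 0.0075, 0.0065, 0.55, 0.11),
    ("reaction_time", None, 3.0, 2.8, 380.0, 70.0),
    ("igf1", None, -0.16, -0.20, 30.0, 5.0),
    ("grip_strength", None, -0.30, -0.20, 55.0, 8.0),
    ("hba1c", None, 0.13, 0.14, 29.0, 3.5),
    ("albumin", None, -0.055, -0.050, 48.0, 2.3),
)

_ELIGIBILITY_RULES = (
    "medication",
    "poor_health",
    "slow_walk",
    "current_smoker",
    "prior_disease",
    "prior_admission",
)

# Alcohol-frequency categories with population-scale frequencies.
_ALCOHOL_CATEGORIES = (
    ("never", 0.080),
    ("special_occasions", 0.115),
    ("one_to_three_monthly", 0.111),
    ("once_twice_weekly", 0.258),
    ("three_four_weekly", 0.231),
    ("daily", 0.205),
)


@dataclass
class EligibilityParams:
    """Parameters linking baseline health flags to the latent offset ``delta``.

    Each eligibility rule fails with probability
    ``expit(logit(base_fail[rule]) + delta_slope * delta)`` so that
    biologically older participants (larger ``delta``) are likelier to fail
    the healthy-at-baseline screen.  ``base_fail`` of 0 or 1 short-circuits
    to never/always failing regardless of ``delta``.
    """

    base_fail: dict[str, float] = field(
        default_factory=lambda: {
            "medication": 0.30,
            "poor_health": 0.12,
            "slow_walk": 0.08,
            "current_smoker": 0.11,
            "prior_disease": 0.10,
            "prior_admission": 0.12,
        }
    )
    delta_slope: float = 0.08  # logit units per year of delta
    episodes_mean: float = 0.9  # Poisson mean of prior care episodes at delta=0
    episodes_delta_slope: float = 0.04  # log-mean increase per year of delta
    n_centers: int = 10

    def validate(self) -> None:
        for rule in _ELIGIBILITY_RULES:
            if rule not in self.base_fail:
                raise ConfigurationError(f"eligibility_params.base_fail missing rule {rule!r}")
            p = self.base_fail[rule]
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"eligibility_params.base_fail[{rule!r}]={p} outside [0, 1]"
                )
        if self.episodes_mean < 0:
            raise ConfigurationError("eligibility_params.episodes_mean must be >= 0")
        if self.n_centers < 1:
            raise ConfigurationError("eligibility_params.n_centers must be >= 1")


def _default(col: int):
    return field(default_factory=lambda: tuple(row[col] for row in DEFAULT_PANEL))


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    n_participants
        Cohort size.
    sex_ratio
        Fraction of male participants.
    age_range
        Recruitment window in years; CA ~ Uniform(age_range).
    sigma_delta
        SD in years of the latent offset delta = BA_true - CA.
    biomarkers, blocks, slopes, slopes_female, intercepts, residual_sds
        Per-biomarker panel definition.  ``slopes`` are used for men and,
        when ``slopes_female`` is None, for women too.  ``residual_sds`` is
        the *total* residual SD around the age trend; a fraction
        ``block_correlation`` of that residual variance is shared within
        each named block.
    block_correlation
        Within-block residual correlation, in [0, 1).
    baseline_hazards, hazard_log_hr_per_year
        Per-outcome exponential baseline hazard (1/year) and log hazard
        ratio per year of (centred) true biological age.
    followup_range
        Administrative censoring drawn uniformly over this window (years).
    eligibility_params
        See :class:`EligibilityParams`.
    seed
        Seed for the single random stream; fixes the output byte-for-byte.
    """

    n_participants: int = 10_000
    sex_ratio: float = 0.5
    age_range: tuple[float, float] = (40.0, 70.0)
    sigma_delta: float = 8.0
    biomarkers: tuple[str, ...] = _default(0)
    blocks: tuple[str | None, ...] = _default(1)
    slopes: tuple[float, ...] = _default(2)
    slopes_female: tuple[float, ...] | None = _default(3)
    intercepts: tuple[float, ...] = _default(4)
    residual_sds: tuple[float, ...] = _default(5)
    block_correlation: float = 0.5
    baseline_hazards: dict[str, float] = field(
        default_factory=lambda: {"mortality": 0.002, "admission": 0.022}
    )
    hazard_log_hr_per_year: dict[str, float] = field(
        default_factory=lambda: {"mortality": 0.09, "admission": 0.05}
    )
    followup_range: tuple[float, float] = (6.0, 12.0)
    eligibility_params: EligibilityParams = field(default_factory=EligibilityParams)
    seed: int = 0

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.baseline_hazards)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError(f"n_participants={self.n_participants} must be positive")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ConfigurationError(f"sex_ratio={self.sex_ratio} outside [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"age_range={self.age_range} must satisfy low < high")
        if self.sigma_delta < 0:
            raise ConfigurationError(f"sigma_delta={self.sigma_delta} must be >= 0")
        p = len(self.biomarkers)
        for name in ("blocks", "slopes", "intercepts", "residual_sds"):
            vals = getattr(self, name)
            if len(vals) != p:
                raise ConfigurationError(
                    f"{name} has {len(vals)} entries for {p} biomarkers"
                )
        if self.slopes_female is not None and len(self.slopes_female) != p:
            raise ConfigurationError(
                f"slopes_female has {len(self.slopes_female)} entries for {p} biomarkers"
            )
        if any(s < 0 for s in self.residual_sds):
            raise ConfigurationError("residual_sds must be >= 0")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ConfigurationError(
                f"block_correlation={self.block_correlation} outside [0, 1)"
            )
        if set(self.baseline_hazards) != set(self.hazard_log_hr_per_year):
            raise ConfigurationError(
                "baseline_hazards and hazard_log_hr_per_year must name the same outcomes"
            )
        for name, lam in self.baseline_hazards.items():
            if lam < 0:
                raise ConfigurationError(f"baseline_hazards[{name!r}]={lam} must be >= 0")
        f0, f1 = self.followup_range
        if f0 < 0 or f1 < f0:
            raise ConfigurationError(f"followup_range={self.followup_range} invalid")
        self.eligibility_params.validate()


def _sex_slopes(config: SimulationConfig, sex: np.ndarray) -> np.ndarray:
    """Per-participant slope matrix (n x p), female overrides applied."""
    k_m = np.asarray(config.slopes, dtype=float)
    k_f = k_m if config.slopes_female is None else np.asarray(config.slopes_female, float)
    return np.where((sex == "M")[:, None], k_m[None, :], k_f[None, :])


def generate_biomarkers(
    ba_true: np.ndarray,
    config: SimulationConfig,
    *,
    sex: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the biomarker panel given each participant's true biological age.

    Each biomarker j follows ``x_j = q_j + k_j * BA_true + u_j`` where the
    residual ``u_j`` has total SD ``s_j`` and is split between a shared
    within-block factor and an independent part so that two biomarkers in the
    same block have residual correlation ``block_correlation``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ba_true = np.asarray(ba_true, dtype=float)
    n = ba_true.shape[0]
    if sex is None:
        sex = np.full(n, "M")
    slopes = _sex_slopes(config, np.asarray(sex))
    q = np.asarray(config.intercepts, float)
    s = np.asarray(config.residual_sds, float)
    rho = config.block_correlation

    block_names = [b for b in dict.fromkeys(config.blocks) if b is not None]
    eta = rng.standard_normal((n, len(block_names)))
    eps = rng.standard_normal((n, len(config.biomarkers)))

    x = q[None, :] + slopes * ba_true[:, None]
    for j, block in enumerate(config.blocks):
        if block is None:
            x[:, j] += s[j] * eps[:, j]
        else:
            g = block_names.index(block)
            x[:, j] += s[j] * (np.sqrt(rho) * eta[:, g] + np.sqrt(1.0 - rho) * eps[:, j])
    return pd.DataFrame(x, columns=list(config.biomarkers))


def generate_outcomes(
    ba_true: np.ndarray,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw (event, time) pairs for each configured outcome.

    Event times are exponential with rate ``lambda0 * exp(beta * (BA_true -
    mean BA_true))``; censoring is uniform over ``followup_range`` and
    independent of everything else.  Outcomes are conditionally independent
    given ``BA_true``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ba_true = np.asarray(ba_true, dtype=float)
    n = ba_true.shape[0]
    centred = ba_true - ba_true.mean()
    out: dict[str, np.ndarray] = {}
    for name in config.outcomes:
        lam0 = config.baseline_hazards[name]
        beta = config.hazard_log_hr_per_year[name]
        rate = lam0 * np.exp(beta * centred)
        raw = rng.exponential(1.0, n)
        with np.errstate(divide="ignore"):
            t_event = np.where(rate > 0, raw / np.where(rate > 0, rate, 1.0), np.inf)
        censor = rng.uniform(config.followup_range[0], config.followup_range[1], n)
        out[f"{name}_event"] = (t_event <= censor).astype(int)
        out[f"{name}_time"] = np.minimum(t_event, censor)
    return pd.DataFrame(out)


def _fail_probability(base: float, delta: np.ndarray, slope: float) -> np.ndarray:
    if base <= 0.0:
        return np.zeros_like(delta)
    if base >= 1.0:
        return np.ones_like(delta)
    return expit(logit(base) + slope * delta)


def generate_eligibility(
    delta: np.ndarray,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw eligibility fields and sociodemographic covariates.

    Every failure probability is monotone increasing in the latent offset
    ``delta`` (for positive ``delta_slope``), so the healthy-at-baseline
    screen preferentially removes the biologically old.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    ep = config.eligibility_params
    fail = {
        rule: rng.random(n) < _fail_probability(ep.base_fail[rule], delta, ep.delta_slope)
        for rule in _ELIGIBILITY_RULES
    }

    health_split = rng.random(n)
    walk_split = rng.random(n)
    smoke_split = rng.random(n)
    df = pd.DataFrame(
        {
            "on_medication": fail["medication"].astype(int),
            "self_rated_health": np.where(
                fail["poor_health"],
                np.where(health_split < 0.5, "fair", "poor"),
                np.where(health_split < 0.6, "good", "excellent"),
            ),
            "walk_pace": np.where(
                fail["slow_walk"], "slow", np.where(walk_split < 0.5, "steady", "brisk")
            ),
            "smoking": np.where(
                fail["current_smoker"],
                "current",
                np.where(smoke_split < 2.0 / 3.0, "never", "previous"),
            ),
            "prior_episodes": rng.poisson(
                ep.episodes_mean * np.exp(ep.episodes_delta_slope * delta)
            ),
            "prior_disease": fail["prior_disease"].astype(int),
            "prior_admission": fail["prior_admission"].astype(int),
            "imd_quintile": rng.integers(1, 6, n),
            "alcohol": rng.choice(
                [c for c, _ in _ALCOHOL_CATEGORIES],
                size=n,
                p=np.array([w for _, w in _ALCOHOL_CATEGORIES])
                / sum(w for _, w in _ALCOHOL_CATEGORIES),
            ),
            "center": rng.integers(0, ep.n_centers, n),
        }
    )
    return df


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a complete synthetic cohort table.

    Returns a DataFrame with one row per participant: id, sex, chronological
    age ``ca``, the latent ``ba_true`` (kept for validation; unavailable in
    real data), the biomarker panel, eligibility fields, covariates, and one
    (event, time) pair per configured outcome.  Fixing ``config.seed`` makes
    the output byte-identical across runs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    sex = np.where(rng.random(n) < config.sex_ratio, "M", "F")
    ca = rng.uniform(config.age_range[0], config.age_range[1], n)
    delta = (
        rng.normal(0.0, config.sigma_delta, n) if config.sigma_delta > 0 else np.zeros(n)
    )
    ba_true = ca + delta

    biomarkers = generate_biomarkers(ba_true, config, sex=sex, rng=rng)
    outcomes = generate_outcomes(ba_true, config, rng=rng)
    eligibility = generate_eligibility(delta, config, rng=rng)

    head = pd.DataFrame({"id": np.arange(n), "sex": sex, "ca": ca, "ba_true": ba_true})
    return pd.concat([head, biomarkers, eligibility, outcomes], axis=1)
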