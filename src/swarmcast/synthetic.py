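"""Synthetic stratified incidence panels.

Generates annual age/sex-stratified rate panels with a monotone age
gradient, a male/female rate ratio, smooth logistic rise-and-plateau
trends with stratum-specific midpoints, an optional late-age rolloff,
and multiplicative lognormal noise. Intended as a statistically
realistic stand-in for registry-style exports so the whole pipeline is
testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from swarmcast.errors import ConfigError
from swarmcast.panel import AsirPanel, canonical_stratum_order

DEFAULT_AGE_GROUPS: tuple[str, ...] = (
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
    "70-74", "75-79", "80-84", "85-89", "90-94", "95+",
)


@dataclass(frozen=True)
class TrendConfig:
    """Logistic rise-and-plateau in time, per stratum.

    Each stratum's expected rate moves from ``start_frac`` of its plateau
    level up to the full level along a logistic curve; midpoints are spread
    across strata (as fractions of the panel span) so different time steps
    carry information for different strata.
    """

    start_frac: float = 0.5
    steepness_years: float = 4.0
    midpoint_frac_lo: float = 0.25
    midpoint_frac_hi: float = 0.70


@dataclass(frozen=True)
class SyntheticConfig:
    n_years: int = 32
    start_year: int = 1990
    age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    sexes: tuple[str, ...] = ("male", "female")
    base_rate_40: float = 5.0
    age_log_slope: float = 0.47
    sex_ratio: float = 2.2
    trend: TrendConfig = field(default_factory=TrendConfig)
    late_age_rolloff: float = 0.45  # multiplier on the last age group; 1.0 disables
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 16:
            raise ConfigError(f"n_years must be >= 16, got {self.n_years}")
        if self.base_rate_40 <= 0:
            raise ConfigError("base_rate_40 must be positive")
        if self.sex_ratio <= 0:
            raise ConfigError("sex_ratio must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.late_age_rolloff <= 0:
            raise ConfigError("late_age_rolloff must be positive")
        if not self.age_groups or not self.sexes:
            raise ConfigError("age_groups and sexes must be non-empty")

    @property
    def strata(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            canonical_stratum_order(
                [(s, a) for s in self.sexes for a in self.age_groups]
            )
        )


def _stratum_level(config: SyntheticConfig, sex: str, age_index: int) -> float:
    """Plateau rate for one stratum: exponential age gradient, sex ratio,
    late-age rolloff on the final group."""
    level = config.base_rate_40 * np.exp(config.age_log_slope * age_index)
    if age_index == len(config.age_groups) - 1 and len(config.age_groups) > 1:
        level *= config.late_age_rolloff
    if sex == config.sexes[0] and len(config.sexes) > 1:
        level *= config.sex_ratio
    return level


def _surface_at(config: SyntheticConfig, years: np.ndarray) -> np.ndarray:
    """Evaluate the expectation surface at arbitrary calendar years.

    Logistic midpoints are anchored to the configured panel span in absolute
    years, so evaluating past the panel end continues the same curves.
    """
    strata = config.strata
    values = np.empty((len(years), len(strata)))
    n_ages = len(config.age_groups)
    tr = config.trend
    for j, (sex, age) in enumerate(strata):
        a = config.age_groups.index(age)
        level = _stratum_level(config, sex, a)
        mid_frac = tr.midpoint_frac_lo + (tr.midpoint_frac_hi - tr.midpoint_frac_lo) * (
            a / max(n_ages - 1, 1)
        )
        mid_year = config.start_year + mid_frac * (config.n_years - 1)
        z = (years - mid_year) / tr.steepness_years
        rise = 1.0 / (1.0 + np.exp(-z))
        values[:, j] = level * (tr.start_frac + (1.0 - tr.start_frac) * rise)
    return values


def expected_surface(config: SyntheticConfig) -> AsirPanel:
    """Noiseless expectation surface; the oracle for parameter-recovery tests."""
    years = np.arange(config.start_year, config.start_year + config.n_years)
    return AsirPanel(
        years=tuple(int(y) for y in years),
        strata=config.strata,
        values=_surface_at(config, years),
    )


def generate_panel(config: SyntheticConfig) -> AsirPanel:
    """Expectation surface times multiplicative lognormal noise (mean 1,
    coefficient of variation ``noise_cv``). ``noise_cv=0`` returns the
    surface exactly and never touches the RNG; identical seeds give
    bitwise-identical panels.
    """
    surface = expected_surface(config)
    if config.noise_cv == 0:
        return surface
    rng = np.random.default_rng(config.seed)
    s2 = np.log1p(config.noise_cv**2)
    noise = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=surface.values.shape)
    return AsirPanel(
        years=surface.years, strata=surface.strata, values=surface.values * noise
    )


def extend_surface(config: SyntheticConfig, extra_years: int) -> AsirPanel:
    """Expectation surface continued ``extra_years`` past the panel end.

    Evaluates the same absolute-year trend curves beyond the configured span;
    the ground truth for scoring out-of-sample forecasts on noiseless panels.
    """
    end = config.start_year + config.n_years
    years = np.arange(end, end + extra_years)
    return AsirPanel(
        years=tuple(int(y) for y in years),
        strata=config.strata,
        values=_surface_at(config, years),
    )
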