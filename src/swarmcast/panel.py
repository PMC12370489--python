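"""Stratified incidence panels: long-CSV I/O, validation, z-normalization.

A panel is a T x S matrix of annual rates (per 100,000 person-years) with
year row labels and (sex, age_group) column labels. The long CSV dialect is
one row per (year, sex, age_group) cell with configurable column names; the
defaults match the GBD results-tool export (``year, sex, age_name, val``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from swarmcast.errors import (
    DuplicateRecordError,
    IncompletePanelError,
    PanelValidationError,
    StratumMismatchError,
    ZeroVarianceError,
)

#: Default long-CSV column names (GBD results-tool dialect).
DEFAULT_SCHEMA: Mapping[str, str] = {
    "year": "year",
    "sex": "sex",
    "age_group": "age_name",
    "value": "val",
}

_SEX_ORDER = {"male": 0, "female": 1}


def _age_sort_key(age_group: str) -> tuple[int, str]:
    """Sort age-group labels by their leading number; open-ended last."""
    digits = ""
    for ch in str(age_group):
        if ch.isdigit():
            digits += ch
        elif digits:
            break
    return (int(digits) if digits else 10**6, str(age_group))


def canonical_stratum_order(strata: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Sex-major (male before female), age ascending — stable across runs."""
    return sorted(
        strata,
        key=lambda st: (_SEX_ORDER.get(st[0], 2), st[0], _age_sort_key(st[1])),
    )


@dataclass(frozen=True)
class AsirPanel:
    """Annual incidence rates for S (sex, age-group) strata over T years.

    Attributes
    ----------
    years : tuple of int
        Consecutive calendar years, strictly increasing with step 1.
    strata : tuple of (sex, age_group) pairs
        Unique column labels in canonical order.
    values : ndarray of shape (T, S)
        Non-negative rates; z-scored panels (``zscored=True``) may be negative.
    zscored : bool
        True when the values are in z-units rather than rate units.
    """

    years: tuple[int, ...]
    strata: tuple[tuple[str, str], ...]
    values: np.ndarray
    zscored: bool = False

    def __post_init__(self):
        years = tuple(int(y) for y in self.years)
        strata = tuple((str(s), str(a)) for s, a in self.strata)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "strata", strata)
        object.__setattr__(self, "values", values)
        if len(years) == 0:
            raise PanelValidationError("panel has no years")
        diffs = np.diff(years)
        if len(diffs) and not np.all(diffs == 1):
            raise PanelValidationError(
                f"years must be consecutive and strictly increasing, got {years}"
            )
        if len(set(strata)) != len(strata):
            raise PanelValidationError("duplicate (sex, age_group) strata")
        if values.shape != (len(years), len(strata)):
            raise PanelValidationError(
                f"values shape {values.shape} != (T={len(years)}, S={len(strata)})"
            )
        if not np.all(np.isfinite(values)):
            raise PanelValidationError("panel contains non-finite values")
        if not self.zscored and np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise PanelValidationError(
                f"negative rate at year {years[bad[0]]}, stratum {strata[bad[1]]}"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def stratum_index(self, sex: str, age_group: str) -> int:
        return self.strata.index((sex, age_group))

    def to_frame(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Unpivot to the long-CSV dialect (one row per cell)."""
        sch = dict(DEFAULT_SCHEMA, **(schema or {}))
        T, S = self.shape
        return pd.DataFrame(
            {
                sch["year"]: np.repeat(self.years, S),
                sch["sex"]: [st[0] for _ in range(T) for st in self.strata],
                sch["age_group"]: [st[1] for _ in range(T) for st in self.strata],
                sch["value"]: self.values.ravel(),
            }
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Per-stratum mean/std fitted over ``fit_years`` (population std)."""

    strata: tuple[tuple[str, str], ...]
    mean: np.ndarray
    std: np.ndarray
    fit_years: tuple[int, int]

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        if self.mean.shape != (len(self.strata),) or self.std.shape != (len(self.strata),):
            raise PanelValidationError("params length does not match strata")
        if np.any(self.std <= 0):
            raise ZeroVarianceError("sigma must be positive for every stratum")


def read_panel(path: str | Path, schema: Mapping[str, str] | None = None) -> AsirPanel:
    """Read a long-format CSV into a validated :class:`AsirPanel`.

    Parameters
    ----------
    path : path to a UTF-8 CSV with a header row.
    schema : optional map overriding the default column names
        (keys ``year, sex, age_group, value``).

    Raises
    ------
    IncompletePanelError
        if any (year, stratum) cell is absent.
    DuplicateRecordError
        if a cell appears more than once.
    PanelValidationError
        on negative values or non-consecutive years.
    """
    sch = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in sch.values() if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"CSV missing columns {missing_cols}; present: {list(df.columns)}")
    df = df[[sch["year"], sch["sex"], sch["age_group"], sch["value"]]].copy()
    df.columns = ["year", "sex", "age_group", "value"]
    df["year"] = df["year"].astype(int)
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    df["age_group"] = df["age_group"].astype(str).str.strip()

    dup = df.duplicated(subset=["year", "sex", "age_group"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DuplicateRecordError(
            f"duplicate record for year {row.year}, sex {row.sex}, age {row.age_group}"
        )

    years = sorted(df["year"].unique())
    strata = canonical_stratum_order(
        {(s, a) for s, a in zip(df["sex"], df["age_group"])}
    )
    expected = {(y, s, a) for y in years for s, a in strata}
    present = set(zip(df["year"], df["sex"], df["age_group"]))
    gaps = sorted(expected - present)
    if gaps:
        raise IncompletePanelError(gaps)

    wide = df.pivot_table(
        index="year", columns=["sex", "age_group"], values="value", aggfunc="first"
    )
    wide = wide.loc[years, [tuple(st) for st in strata]]
    return AsirPanel(years=tuple(years), strata=tuple(strata), values=wide.to_numpy())


def write_panel(
    panel: AsirPanel, path: str | Path, schema: Mapping[str, str] | None = None
) -> None:
    """Write a panel as long-format CSV in the same dialect ``read_panel`` reads."""
    panel.to_frame(schema).to_csv(path, index=False)


def _resolve_fit_years(panel: AsirPanel, fit_years) -> tuple[int, int]:
    if fit_years is None:
        return (panel.years[0], panel.years[-1])
    lo, hi = int(min(fit_years)), int(max(fit_years))
    if lo < panel.years[0] or hi > panel.years[-1]:
        raise PanelValidationError(
            f"fit_years {lo}-{hi} outside panel span {panel.years[0]}-{panel.years[-1]}"
        )
    return (lo, hi)


def normalize(
    panel: AsirPanel, fit_years=None
) -> tuple[AsirPanel, NormalizationParams]:
    """Z-score each stratum using mean/std computed over ``fit_years`` only.

    ``fit_years`` is any iterable of years (or None = all years); statistics
    never read values outside it, so fitting on a training prefix cannot leak
    validation-era information. Population (ddof=0) standard deviation.
    """
    lo, hi = _resolve_fit_years(panel, fit_years)
    rows = [i for i, y in enumerate(panel.years) if lo <= y <= hi]
    fit_block = panel.values[rows]
    mu = fit_block.mean(axis=0)
    sigma = fit_block.std(axis=0, ddof=0)
    flat = np.flatnonzero(sigma <= 0)
    if flat.size:
        names = [panel.strata[j] for j in flat]
        raise ZeroVarianceError(f"constant stratum over fit years {lo}-{hi}: {names}")
    params = NormalizationParams(
        strata=panel.strata, mean=mu, std=sigma, fit_years=(lo, hi)
    )
    z = (panel.values - mu) / sigma
    zpanel = AsirPanel(years=panel.years, strata=panel.strata, values=z, zscored=True)
    return zpanel, params


def denormalize(panel_z: AsirPanel, params: NormalizationParams) -> AsirPanel:
    """Invert :func:`normalize`: x = z * sigma + mu per stratum."""
    if tuple(params.strata) != tuple(panel_z.strata):
        raise StratumMismatchError(
            "normalization params strata do not match panel strata"
        )
    x = panel_z.values * params.std + params.mean
    # tiny negative dust from float round-trip is clipped, real negatives are not
    x = np.where((x < 0) & (x > -1e-9), 0.0, x)
    return AsirPanel(years=panel_z.years, strata=panel_z.strata, values=x)
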