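"""Synthetic one-year daily meteorological driver, recycled every model year.

The production model needs daily photosynthetically active radiation (PAR),
daytime mean air temperature, vapour-pressure deficit and daylength for a
temperate grassland.  Site weather for the study system is not available, so
this module generates a deterministic sinusoidal annual cycle (peaking at
midsummer, day 172) whose daily PAR is normalised so the annual incident PAR
(IPAR) hits a prescribed total exactly.  Determinism matters: the model is
deterministic and equilibrium detection compares successive recycled years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "AnnualForcing",
    "generate_forcing",
    "annual_ipar",
    "default_forcing",
    "read_forcing_csv",
    "write_forcing_csv",
    "DAYS_PER_YEAR",
    "MIDSUMMER_DAY",
]

DAYS_PER_YEAR = 365
MIDSUMMER_DAY = 172  # seasonal cycles peak here (northern midsummer)

#: Relative seasonal amplitude of daily PAR around its mean (dimensionless).
PAR_REL_AMPLITUDE = 0.6
#: Daylength cycle: mean and amplitude in hours.
DAYLENGTH_MEAN_H = 12.0
DAYLENGTH_AMPLITUDE_H = 4.0

_IPAR_RTOL = 1e-9


class DailyWeather(NamedTuple):
    day_of_year: int
    par: float  # MJ m-2 day-1
    tair: float  # degC, daytime mean
    vpd: float  # kPa, daytime mean
    daylength: float  # hours


@dataclass(frozen=True)
class AnnualForcing:
    """365 daily weather records plus the annual incident PAR total.

    Stored column-wise as arrays for fast model evaluation; ``days`` iterates
    row-wise records.  The stored ``ipar`` must equal the daily sum.
    """

    par: np.ndarray  # (365,) MJ m-2 day-1
    tair: np.ndarray  # (365,) degC
    vpd: np.ndarray  # (365,) kPa
    daylength: np.ndarray  # (365,) hours
    ipar: float  # MJ m-2 yr-1
    day_of_year: np.ndarray = field(
        default_factory=lambda: np.arange(1, DAYS_PER_YEAR + 1)
    )

    def __post_init__(self) -> None:
        for name in ("par", "tair", "vpd", "daylength"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (DAYS_PER_YEAR,):
                raise ValueError(f"{name} must have shape ({DAYS_PER_YEAR},)")
        if np.any(self.par < 0.0):
            raise ValueError("daily PAR must be nonnegative")
        if np.any(self.vpd <= 0.0):
            raise ValueError("daily VPD must be strictly positive")
        if np.any((self.daylength <= 0.0) | (self.daylength > 24.0)):
            raise ValueError("daylength must lie in (0, 24] hours")
        total = float(self.par.sum())
        if not np.isclose(total, self.ipar, rtol=_IPAR_RTOL, atol=0.0):
            raise ValueError(
                f"stored ipar ({self.ipar}) inconsistent with daily sum ({total})"
            )

    @property
    def days(self) -> Iterator[DailyWeather]:
        for i in range(DAYS_PER_YEAR):
            yield DailyWeather(
                int(self.day_of_year[i]),
                float(self.par[i]),
                float(self.tair[i]),
                float(self.vpd[i]),
                float(self.daylength[i]),
            )


def _seasonal(mean: float, amplitude: float, days: np.ndarray) -> np.ndarray:
    """Sinusoid peaking at midsummer: mean + amplitude*cos(2pi (d - peak)/365)."""
    return mean + amplitude * np.cos(2.0 * np.pi * (days - MIDSUMMER_DAY) / DAYS_PER_YEAR)


def generate_forcing(
    annual_ipar_target: float = 2500.0,
    mean_temp: float = 12.0,
    temp_amplitude: float = 14.0,
    mean_vpd: float = 1.0,
    vpd_amplitude: float = 0.5,
) -> AnnualForcing:
    """Build the deterministic sinusoidal annual forcing.

    Parameters
    ----------
    annual_ipar_target : annual incident PAR, MJ m-2 yr-1 (> 0); daily PAR is
        rescaled so the annual sum equals this exactly.
    mean_temp, temp_amplitude : degC; daily tair = mean + amp*cos(...).
    mean_vpd, vpd_amplitude : kPa; the VPD cycle must stay strictly positive.
    """
    if not annual_ipar_target > 0.0:
        raise ValueError("annual_ipar_target must be positive")
    if vpd_amplitude >= mean_vpd:
        raise ValueError("vpd cycle would cross zero (amplitude >= mean)")
    if vpd_amplitude < 0.0 or temp_amplitude < 0.0:
        raise ValueError("amplitudes must be nonnegative")
    days = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    par_shape = _seasonal(1.0, PAR_REL_AMPLITUDE, days)
    par = par_shape * (annual_ipar_target / par_shape.sum())
    tair = _seasonal(mean_temp, temp_amplitude, days)
    vpd = _seasonal(mean_vpd, vpd_amplitude, days)
    daylength = _seasonal(DAYLENGTH_MEAN_H, DAYLENGTH_AMPLITUDE_H, days)
    return AnnualForcing(
        par=par, tair=tair, vpd=vpd, daylength=daylength,
        ipar=float(par.sum()),
    )


def default_forcing() -> AnnualForcing:
    """The study's default forcing (IPAR 2500 MJ m-2 yr-1, temperate cycle)."""
    return generate_forcing()


def annual_ipar(f: AnnualForcing) -> float:
    """Annual incident PAR total, consistency-checked against the daily sum."""
    total = float(np.sum(f.par))
    if not np.isclose(total, f.ipar, rtol=_IPAR_RTOL, atol=0.0):
        raise ValueError(
            f"stored ipar ({f.ipar}) inconsistent with daily sum ({total})"
        )
    return f.ipar


# ---------------------------------------------------------------------------
# CSV interface

def write_forcing_csv(f: AnnualForcing, path) -> None:
    pd.DataFrame(
        {
            "day_of_year": f.day_of_year,
            "par": f.par,
            "tair": f.tair,
            "vpd": f.vpd,
            "daylength": f.daylength,
        }
    ).to_csv(path, index=False)


def read_forcing_csv(path) -> AnnualForcing:
    frame = pd.read_csv(path)
    par = frame["par"].to_numpy(dtype=float)
    return AnnualForcing(
        par=par,
        tair=frame["tair"].to_numpy(dtype=float),
        vpd=frame["vpd"].to_numpy(dtype=float),
        daylength=frame["daylength"].to_numpy(dtype=float),
        ipar=float(par.sum()),
        day_of_year=frame["day_of_year"].to_numpy(dtype=int),
    )
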