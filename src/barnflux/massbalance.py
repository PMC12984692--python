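"""CO2 mass-balance estimation of ventilation and gas emission rates.

The indirect CO2 balance method infers the air exchange rate of a naturally
ventilated barn from the indoor-outdoor CO2 gradient and the herd's metabolic
CO2 excretion, then converts NH3/CH4 concentration gradients into emission
rates:

    qt    = 5.6 * m**0.75 + 1.6e-5 * p**3 + 22 * y        [W per cow]
    CF    = 4e-5 * (20 - Ti)**3 + 1                        [-]
    qcor  = qt * CF                                        [W per cow]
    P_CO2 = 0.299 * qcor                                   [g cow-1 h-1]
    Q     = P_CO2 * N / (C_CO2,in - C_CO2,out)             [m3 h-1]
    Et    = Q * (C_in - C_out)                             [g h-1]
    E     = Et * 500 / (N * m)                             [g LU-1 h-1]

where m is the mean animal mass (kg), p days after insemination, y milk yield
(kg d-1), Ti the indoor air temperature (degC), N the herd size and one
livestock unit (LU) is 500 kg of animal mass.  All concentrations entering the
balance are mass concentrations (g m-3); ppm readings are converted assuming
ideal-gas behaviour at the indoor temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "HerdState",
    "EmissionFlag",
    "EmissionEstimate",
    "MassBalanceModel",
    "MassBalanceResults",
    "heat_production",
    "temperature_correction",
    "co2_excretion_rate",
    "ventilation_rate",
    "emission_rate",
    "emission_per_lu",
    "ppm_to_mass_concentration",
    "mass_concentration_to_ppm",
    "estimate_emissions_series",
]

#: Mass of one livestock unit (kg).
LU_MASS_KG = 500.0

#: Ratio of CO2 excretion (g cow-1 h-1) to corrected heat production (W).
CO2_PER_WATT = 0.299

#: Molar masses (g mol-1) of the gases handled by the balance.
MOLAR_MASS = {"NH3": 17.031, "CH4": 16.043, "CO2": 44.010}

#: Ideal gas constant, J mol-1 K-1.
_R = 8.314462618

#: Default minimum CO2 gradient (g m-3) below which Q is undefined.
DEFAULT_MIN_GRADIENT = 1e-6


@dataclass(frozen=True)
class HerdState:
    """Herd descriptors entering the heat-production model.

    Parameters
    ----------
    n_cows : int
        Number of cows housed in the barn (N >= 1).
    mass_kg : float
        Average animal mass m (kg cow-1).
    days_after_insemination : float
        Days after insemination p (d).
    milk_yield_kg_day : float
        Milk yield y (kg d-1).
    """

    n_cows: int
    mass_kg: float
    days_after_insemination: float
    milk_yield_kg_day: float

    def __post_init__(self) -> None:
        if self.n_cows < 1:
            raise ValueError(f"herd size must be >= 1, got {self.n_cows}")
        if not (self.mass_kg > 0 and math.isfinite(self.mass_kg)):
            raise ValueError(f"animal mass must be positive, got {self.mass_kg}")
        if self.days_after_insemination < 0:
            raise ValueError("days after insemination must be >= 0")
        if self.milk_yield_kg_day < 0:
            raise ValueError("milk yield must be >= 0")


class EmissionFlag(str, Enum):
    OK = "ok"
    INVALID_GRADIENT = "invalid_gradient"
    NEGATIVE_EMISSION = "negative_emission"


@dataclass
class EmissionEstimate:
    """One hour's mass-balance result.

    Attributes mirror the balance quantities: ventilation rate ``Q``
    (m3 h-1), emission rate ``Et`` (g h-1), per-livestock-unit emission ``E``
    (g LU-1 h-1), total and corrected heat production ``qt``/``qcor`` (W),
    temperature correction ``CF`` and per-cow CO2 excretion ``P_CO2``
    (g cow-1 h-1).  ``flag`` records hours where the balance is undefined
    (non-positive CO2 gradient) or the gas gradient is negative.
    """

    Q: float
    Et: float
    E: float
    qt: float
    CF: float
    qcor: float
    P_CO2: float
    flag: EmissionFlag = EmissionFlag.OK


def heat_production(herd: HerdState) -> float:
    """Total heat production qt (W) of one cow.

    qt = 5.6 m^0.75 + 1.6e-5 p^3 + 22 y; strictly increasing in mass,
    pregnancy stage and milk yield.
    """
    qt = (
        5.6 * herd.mass_kg**0.75
        + 1.6e-5 * herd.days_after_insemination**3
        + 22.0 * herd.milk_yield_kg_day
    )
    if not math.isfinite(qt):
        raise ValueError("non-finite heat production from inputs")
    return qt


def temperature_correction(indoor_temp_c: float) -> float:
    """Temperature correction factor CF = 4e-5 (20 - Ti)^3 + 1.

    Equals 1 at the 20 degC reference and decreases with indoor temperature.
    """
    if not np.all(np.isfinite(indoor_temp_c)):
        raise ValueError("indoor temperature must be finite")
    return 4e-5 * (20.0 - np.asarray(indoor_temp_c)) ** 3 + 1.0


def co2_excretion_rate(herd: HerdState, indoor_temp_c: float) -> tuple[float, float]:
    """Corrected heat production qcor (W) and CO2 excretion P_CO2 (g cow-1 h-1).

    qcor = qt * CF and P_CO2 = 0.299 * qcor.
    """
    qcor = heat_production(herd) * temperature_correction(indoor_temp_c)
    return qcor, CO2_PER_WATT * qcor


def ventilation_rate(
    p_co2: float,
    n_cows: int,
    c_co2_in: float,
    c_co2_out: float,
    min_gradient: float = DEFAULT_MIN_GRADIENT,
) -> tuple[float, EmissionFlag]:
    """Ventilation rate Q = P_CO2 N / (C_CO2,in - C_CO2,out), m3 h-1.

    Concentrations are mass concentrations in g m-3.  When the indoor-outdoor
    gradient is below ``min_gradient`` the balance is undefined; the hour is
    flagged ``invalid_gradient`` (Q returned as NaN) rather than raising, so
    that series processing continues.
    """
    gradient = c_co2_in - c_co2_out
    if gradient <= min_gradient:
        return float("nan"), EmissionFlag.INVALID_GRADIENT
    return p_co2 * n_cows / gradient, EmissionFlag.OK


def emission_rate(q: float, c_in: float, c_out: float) -> float:
    """Gas emission rate Et = Q (C_in - C_out), g h-1 (concentrations g m-3)."""
    return q * (c_in - c_out)


def emission_per_lu(et: float, herd: HerdState) -> float:
    """Emission per livestock unit E = Et * 500 / (N m), g LU-1 h-1."""
    return et * LU_MASS_KG / (herd.n_cows * herd.mass_kg)


def _molar_volume_m3(temp_c: float, pressure_kpa: float) -> float:
    return _R * (temp_c + 273.15) / (pressure_kpa * 1000.0)


def ppm_to_mass_concentration(
    c_ppm, gas: str, temp_c: float = 20.0, pressure_kpa: float = 101.325
):
    """Convert a volumetric mixing ratio (ppm) to mass concentration (g m-3).

    Ideal gas: c [g m-3] = ppm * 1e-6 * M / Vm with Vm = R T / P the molar
    volume.  Exact inverse of :func:`mass_concentration_to_ppm`.
    """
    if gas not in MOLAR_MASS:
        raise ValueError(f"unknown gas {gas!r}; expected one of {sorted(MOLAR_MASS)}")
    if np.any(np.asarray(temp_c) <= -273.15):
        raise ValueError("temperature below absolute zero")
    vm = _molar_volume_m3(np.asarray(temp_c, dtype=float), pressure_kpa)
    return np.asarray(c_ppm) * 1e-6 * MOLAR_MASS[gas] / vm


def mass_concentration_to_ppm(
    c_g_m3, gas: str, temp_c: float = 20.0, pressure_kpa: float = 101.325
):
    """Inverse of :func:`ppm_to_mass_concentration`."""
    if gas not in MOLAR_MASS:
        raise ValueError(f"unknown gas {gas!r}; expected one of {sorted(MOLAR_MASS)}")
    vm = _molar_volume_m3(temp_c, pressure_kpa)
    return np.asarray(c_g_m3) * vm * 1e6 / MOLAR_MASS[gas]


NegativePolicy = Literal["keep", "zero", "drop"]


class MassBalanceModel:
    """CO2 mass-balance model over a table of hourly barn records.

    Built from a DataFrame carrying indoor/outdoor CO2 and target-gas
    concentrations plus indoor temperature; :meth:`estimate` applies the
    balance hour by hour and returns :class:`MassBalanceResults`.

    Parameters
    ----------
    records : pandas.DataFrame
        Hourly records.  Required columns: ``T_in`` plus the CO2 and
        target-gas concentration columns (see ``concentration_unit``).
        Indoor concentrations may be supplied as several sampling-point
        columns (``<name>_in_1`` ...); all present indoor points are averaged.
    herd : HerdState
    gas : {"NH3", "CH4"}
        Target gas.
    concentration_unit : {"ppm", "g_m3"}
        Unit of the concentration columns.  ppm values are converted at the
        hour's indoor temperature and 101.325 kPa.
    negative_policy : {"keep", "zero", "drop"}
        What to do with hours whose gas gradient is negative: keep and flag
        (default), clamp Et/E to zero, or drop the hour from the output.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        herd: HerdState,
        gas: str = "NH3",
        concentration_unit: str = "ppm",
        negative_policy: NegativePolicy = "keep",
        min_gradient: float = DEFAULT_MIN_GRADIENT,
        pressure_kpa: float = 101.325,
    ) -> None:
        if gas not in ("NH3", "CH4"):
            raise ValueError(f"target gas must be NH3 or CH4, got {gas!r}")
        if concentration_unit not in ("ppm", "g_m3"):
            raise ValueError("concentration_unit must be 'ppm' or 'g_m3'")
        if negative_policy not in ("keep", "zero", "drop"):
            raise ValueError("negative_policy must be keep, zero or drop")
        self.records = records
        self.herd = herd
        self.gas = gas
        self.concentration_unit = concentration_unit
        self.negative_policy = negative_policy
        self.min_gradient = min_gradient
        self.pressure_kpa = pressure_kpa
        self._check_columns()

    def _indoor_columns(self, name: str) -> list[str]:
        cols = [c for c in self.records.columns if c == f"{name}_in"]
        cols += sorted(
            c for c in self.records.columns
            if c.startswith(f"{name}_in_") and c[len(name) + 4:].isdigit()
        )
        return cols

    def _check_columns(self) -> None:
        missing = []
        if "T_in" not in self.records.columns:
            missing.append("T_in")
        for name in ("C_CO2", f"C_{self.gas}"):
            if not self._indoor_columns(name):
                missing.append(f"{name}_in")
            if f"{name}_out" not in self.records.columns:
                missing.append(f"{name}_out")
        if missing:
            raise KeyError(f"records missing required columns: {missing}")

    def estimate(self) -> "MassBalanceResults":
        df = self.records
        t_in = df["T_in"].to_numpy(dtype=float)
        n = len(df)

        def conc(name: str, outdoor: bool) -> np.ndarray:
            if outdoor:
                vals = df[f"{name}_out"].to_numpy(dtype=float)
            else:
                vals = df[self._indoor_columns(name)].to_numpy(dtype=float).mean(axis=1)
            if self.concentration_unit == "ppm":
                gas_key = name.replace("C_", "")
                vals = np.asarray(
                    ppm_to_mass_concentration(vals, gas_key, t_in, self.pressure_kpa)
                )
            return vals

        co2_in = conc("C_CO2", outdoor=False)
        co2_out = conc("C_CO2", outdoor=True)
        gas_in = conc(f"C_{self.gas}", outdoor=False)
        gas_out = conc(f"C_{self.gas}", outdoor=True)

        qt = heat_production(self.herd)
        cf = np.asarray(temperature_correction(t_in), dtype=float)
        qcor = qt * cf
        p_co2 = CO2_PER_WATT * qcor

        gradient = co2_in - co2_out
        valid = gradient > self.min_gradient
        q = np.full(n, np.nan)
        q[valid] = p_co2[valid] * self.herd.n_cows / gradient[valid]

        et = q * (gas_in - gas_out)
        e = et * LU_MASS_KG / (self.herd.n_cows * self.herd.mass_kg)

        flags = np.where(valid, EmissionFlag.OK.value, EmissionFlag.INVALID_GRADIENT.value)
        negative = valid & (et < 0)
        flags = np.where(negative, EmissionFlag.NEGATIVE_EMISSION.value, flags)
        if self.negative_policy == "zero":
            et = np.where(negative, 0.0, et)
            e = np.where(negative, 0.0, e)

        out = pd.DataFrame(
            {
                "Q": q,
                "Et": et,
                "E": e,
                "qt": qt,
                "CF": cf,
                "qcor": qcor,
                "P_CO2": p_co2,
                "flag": flags,
            },
            index=df.index,
        )
        if self.negative_policy == "drop":
            out = out[~negative]
        return MassBalanceResults(self, out)


@dataclass
class MassBalanceResults:
    """Hourly emission estimates produced by :class:`MassBalanceModel`.

    ``table`` has one row per retained hour with columns Q, Et, E, qt, CF,
    qcor, P_CO2 and flag.
    """

    model: MassBalanceModel
    table: pd.DataFrame

    @property
    def estimates(self) -> list[EmissionEstimate]:
        return [
            EmissionEstimate(
                Q=row.Q, Et=row.Et, E=row.E, qt=row.qt, CF=row.CF,
                qcor=row.qcor, P_CO2=row.P_CO2, flag=EmissionFlag(row.flag),
            )
            for row in self.table.itertuples()
        ]

    def summary(self) -> str:
        t = self.table
        ok = t["flag"] == EmissionFlag.OK.value
        lines = [
            f"CO2 mass-balance emission estimates - gas {self.model.gas}",
            f"hours: {len(t)}  ok: {int(ok.sum())}  "
            f"invalid_gradient: {int((t['flag'] == 'invalid_gradient').sum())}  "
            f"negative_emission: {int((t['flag'] == 'negative_emission').sum())}",
        ]
        if ok.any():
            lines += [
                f"Q  (m3 h-1):    mean {t.loc[ok, 'Q'].mean():12.1f}",
                f"Et (g h-1):     mean {t.loc[ok, 'Et'].mean():12.3f}",
                f"E  (g LU-1 h-1): mean {t.loc[ok, 'E'].mean():11.4f}",
            ]
        return "\n".join(lines)


def estimate_emissions_series(
    records: pd.DataFrame,
    herd: HerdState,
    gas: str = "NH3",
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper: apply the CO2 balance to a table of hourly records.

    Returns the per-hour table of :class:`MassBalanceResults`.  See
    :class:`MassBalanceModel` for options.
    """
    return MassBalanceModel(records, herd, gas=gas, **kwargs).estimate().table
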