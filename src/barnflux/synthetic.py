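"""Seeded synthetic barn campaigns for exercising the emission pipeline.

The generator emulates one month of hourly records from a naturally
ventilated Mediterranean dairy barn: diurnal climate cycles with AR(1)
weather noise, 15-minute behavioural scan counts, the printed step-wise diet
schedule, and indoor gas concentrations built so that the CO2 mass-balance
relation holds by construction:

    C_CO2,in = C_CO2,out + P_CO2 * N / Q_true
    C_gas,in = C_gas,out + E_gas,true / Q_true

with a known (latent) ventilation rate Q_true driven by wind speed, a known
NH3 emission driven by indoor temperature, herd activity and time since
cleaning, and a known CH4 emission driven by ration mass and feeding
activity.  Because truth is stored alongside the records, every downstream
stage (mass balance, feature assembly, network training) is testable without
any measurement campaign.

Concentration columns are in ppm (the unit the gas analyser reports);
conversion to mass concentration uses the hour's indoor temperature at
101.325 kPa, matching the estimator's convention, so with the noise turned
off the estimator inverts the generator exactly.  Measurement noise is
additive Gaussian on the indoor ppm channels with variance set from the
signal-to-noise ratio ``snr`` = var(signal)/var(noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bhv
from . import massbalance as mb

__all__ = ["GeneratorConfig", "SyntheticStudy", "gen_climate", "gen_activity_scans",
           "gen_diet_schedule", "gen_concentrations", "gen_study", "load_diet_table"]

#: Instrument detection limits, ppm.
DETECTION_LIMIT_PPM = {"NH3": 0.2, "CH4": 0.4, "CO2": 1.5}

DIET_COLUMNS = [
    "alfalfa_hay", "hay", "grass_hay", "beet", "urea", "milk_performer_170a1",
    "citrus_pulp", "fat", "yeast", "flaked_maize_soybean", "cottonseed",
    "salt", "bicarbonate",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic campaign.

    Defaults reproduce the emulated campaign: a 30-day November month of 720
    hours minus two maintenance hours (718 records) for a 56-cow Friesian
    herd.  Herd covariates (mass 620 kg, 120 d after insemination, 28 kg/d
    milk) are plausible mid-lactation values and fully configurable.
    """

    n_records: int = 718
    seed: int = 42
    herd_size: int = 56
    mean_mass: float = 620.0          # kg per cow
    days_after_insemination: float = 120.0
    milk_yield: float = 28.0          # kg per day
    snr: float = 3.0                  # var(signal)/var(noise) on concentrations
    cleaning_hour: int = 7
    feeding_hour: int = 12            # feed delivered once daily, at noon
    milking_hours: tuple[int, int] = (6, 18)
    outdoor_co2_baseline: float = 0.78      # g m-3 (~420 ppm)
    outdoor_nh3_baseline: float = 1.8e-4    # g m-3 (~0.25 ppm)
    outdoor_ch4_baseline: float = 1.4e-3    # g m-3 (~2 ppm)
    mean_outdoor_temp: float = 14.0   # degC, November Mediterranean
    diurnal_amplitude: float = 6.0    # degC, daily max - min
    indoor_offset: float = 2.5        # degC added indoors by the herd
    climate_noise: float = 1.0        # scale on AR(1) weather noise (0 = exact cycle)
    base_ventilation: float = 15000.0 # m3 h-1 at zero wind
    wind_ventilation_gain: float = 0.05  # per m s-1
    dropped_hours: tuple[int, ...] | None = None  # maintenance gaps in the hour grid
    n_sampling_points: int = 1        # >1 expands indoor gas columns with jitter
    start: str = "2021-11-01 00:00"

    def __post_init__(self) -> None:
        if self.n_records < 24:
            raise ValueError("n_records must be >= 24")
        if self.herd_size < 1:
            raise ValueError("herd_size must be >= 1")
        if self.mean_mass <= 0:
            raise ValueError("mean_mass must be > 0")
        if self.milk_yield < 0 or self.days_after_insemination < 0:
            raise ValueError("milk_yield and days_after_insemination must be >= 0")
        if not self.snr > 0:
            raise ValueError("snr must be > 0 (may be inf)")
        if self.dropped_hours is None:
            # default month: 720 h minus two maintenance hours -> 718 records;
            # other campaign lengths drop nothing unless positions are given
            object.__setattr__(
                self, "dropped_hours", (311, 502) if self.n_records == 718 else ()
            )
        total = self.n_records + len(self.dropped_hours)
        if any(not 0 <= h < total for h in self.dropped_hours):
            raise ValueError("dropped_hours must index the generated hour grid")
        if len(set(self.dropped_hours)) != len(self.dropped_hours):
            raise ValueError("dropped_hours must be unique")
        if self.n_sampling_points < 1:
            raise ValueError("n_sampling_points must be >= 1")

    @property
    def herd(self) -> mb.HerdState:
        return mb.HerdState(
            n_cows=self.herd_size,
            mass_kg=self.mean_mass,
            days_after_insemination=self.days_after_insemination,
            milk_yield_kg_day=self.milk_yield,
        )


def _timeline(config: GeneratorConfig) -> tuple[pd.DatetimeIndex, pd.DatetimeIndex]:
    """Full hourly grid and the grid with maintenance hours removed."""
    total = config.n_records + len(config.dropped_hours)
    full = pd.date_range(config.start, periods=total, freq="h")
    keep = np.ones(total, dtype=bool)
    keep[list(config.dropped_hours)] = False
    return full, full[keep]


def _diurnal_phase(hour_frac: np.ndarray, t_min: float = 5.0, t_max: float = 14.0) -> np.ndarray:
    """Phase of a time-warped daily cosine: maximum at t_max, minimum at t_min."""
    h = np.asarray(hour_frac) % 24.0
    rise_len = (t_max - t_min) % 24.0           # 9 h warming half
    fall_len = 24.0 - rise_len                  # 15 h cooling half
    theta = np.empty_like(h, dtype=float)
    rising = (h >= t_min) & (h < t_max)
    theta[rising] = np.pi + np.pi * (h[rising] - t_min) / rise_len
    x = (h[~rising] - t_max) % 24.0
    theta[~rising] = np.pi * x / fall_len
    return theta


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary first-order autoregressive noise."""
    eps = rng.normal(0.0, 1.0, size=n)
    out = np.empty(n)
    out[0] = eps[0] / math.sqrt(max(1.0 - phi * phi, 1e-12))
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return sigma * out


def gen_climate(config: GeneratorConfig) -> pd.DataFrame:
    """Per-hour indoor/outdoor climate over the full generated hour grid.

    Outdoor temperature follows a warped daily cosine (minimum near 05:00,
    maximum near 14:00, range ``diurnal_amplitude``) plus AR(1) noise; the
    barn interior sits ``indoor_offset`` degC warmer.  Humidity is inversely
    coupled to temperature and clipped to [0, 100]; wind direction wraps to
    [0, 360); wind speeds are floored at a small positive value so the
    wind-driven ventilation stays defined.
    """
    full, _ = _timeline(config)
    rng = np.random.default_rng([config.seed, 0x11])
    n = len(full)
    hh = full.hour.to_numpy() + full.minute.to_numpy() / 60.0
    theta = _diurnal_phase(hh)
    cyc = np.cos(theta)

    cn = config.climate_noise
    t_out = config.mean_outdoor_temp + 0.5 * config.diurnal_amplitude * cyc
    t_out = t_out + _ar1(rng, n, 0.75, 0.6 * cn)
    t_in = t_out + config.indoor_offset + _ar1(rng, n, 0.75, 0.3 * cn)

    rh_out = 80.0 - 2.5 * (t_out - config.mean_outdoor_temp) + _ar1(rng, n, 0.7, 3.0 * cn)
    rh_in = 75.0 - 2.5 * (t_in - config.mean_outdoor_temp - config.indoor_offset) \
        + _ar1(rng, n, 0.7, 3.0 * cn)
    rh_out = np.clip(rh_out, 0.0, 100.0)
    rh_in = np.clip(rh_in, 0.0, 100.0)

    ws_out = 2.0 + 0.8 * cyc + _ar1(rng, n, 0.7, 0.5 * cn)
    ws_out = np.maximum(ws_out, 0.05)
    ws_in = np.maximum(0.3 * ws_out + _ar1(rng, n, 0.6, 0.1 * cn), 0.0)

    wd_out = np.mod(310.0 + _ar1(rng, n, 0.8, 25.0 * cn), 360.0)
    wd_in = np.mod(wd_out + _ar1(rng, n, 0.5, 10.0 * cn), 360.0)
    wd_out[wd_out >= 360.0] = 0.0
    wd_in[wd_in >= 360.0] = 0.0

    return pd.DataFrame(
        {
            "T_out": t_out, "T_in": t_in,
            "RH_out": rh_out, "RH_in": rh_in,
            "WS_out": ws_out, "WS_in": ws_in,
            "WD_out": wd_out, "WD_in": wd_in,
        },
        index=full,
    )


def _behaviour_probs(hour_frac: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Time-varying (lying, standing, walking, feeding) probabilities."""
    h = np.asarray(hour_frac, dtype=float) % 24.0
    p_lie = 0.50 + 0.28 * np.cos(2 * np.pi * (h - 2.0) / 24.0)
    x = (h - config.feeding_hour) % 24.0
    p_feed = 0.06 + 0.38 * np.exp(-(((x - 1.0) / 1.8) ** 2))
    milk = sum(np.exp(-(((h - mh) / 1.0) ** 2)) for mh in config.milking_hours)
    rest = np.maximum(1.0 - p_lie - p_feed, 0.02)
    p_stand = rest * 0.75 + 0.10 * milk
    p_walk = rest * 0.25
    probs = np.stack([p_lie, p_stand, p_walk, p_feed], axis=1)
    return probs / probs.sum(axis=1, keepdims=True)


def gen_activity_scans(config: GeneratorConfig) -> pd.DataFrame:
    """15-minute behavioural scan counts, four per retained hour.

    Counts are multinomial draws of the whole herd from smooth diurnal
    probabilities: lying peaks at night, feeding peaks in the hours after
    feed delivery, standing gets bumps around milking.  Each scan partitions
    the herd, so lying + standing + walking + feeding = herd size.
    """
    _, kept = _timeline(config)
    rng = np.random.default_rng([config.seed, 0x22])
    stamps = kept.repeat(4) + pd.to_timedelta(np.tile([0, 15, 30, 45], len(kept)), unit="m")
    hh = stamps.hour.to_numpy() + stamps.minute.to_numpy() / 60.0
    probs = _behaviour_probs(hh, config)
    counts = np.vstack([rng.multinomial(config.herd_size, p) for p in probs])
    return pd.DataFrame(
        {
            "timestamp": stamps,
            "n_lying": counts[:, 0],
            "n_standing": counts[:, 1],
            "n_walking": counts[:, 2],
            "n_feeding": counts[:, 3],
        }
    )


def load_diet_table() -> pd.DataFrame:
    """The printed dietary schedule: per-ingredient kg on each change day."""
    with resources.files("barnflux.data").joinpath("diet_schedule.csv").open() as fh:
        return pd.read_csv(fh)


def gen_diet_schedule(config: GeneratorConfig) -> pd.DataFrame:
    """Per-day ration table (13 ingredient masses, kg) over the campaign.

    The ration changes on the printed change days (1, 11, 18, 20, 22, 26,
    30) and is held constant in between; campaigns longer than the printed
    schedule keep the last ration.
    """
    table = load_diet_table().set_index("day")
    total_hours = config.n_records + len(config.dropped_hours)
    n_days = math.ceil(total_hours / 24)
    days = pd.RangeIndex(1, n_days + 1, name="day")
    out = table.reindex(range(1, n_days + 1)).ffill()
    out.index = days
    return out[DIET_COLUMNS]


def _hourly_diet(config: GeneratorConfig, index: pd.DatetimeIndex) -> pd.DataFrame:
    daily = gen_diet_schedule(config)
    start = pd.Timestamp(config.start).normalize()
    day_no = ((index.normalize() - start).days + 1).astype(int)
    day_no = np.clip(day_no, 1, daily.index.max())
    out = daily.loc[day_no].reset_index(drop=True)
    out.index = index
    return out


def _nh3_emission(config: GeneratorConfig, t_in, cai, hours_since_cleaning):
    """True NH3 emission (g h-1): smooth in temperature, activity, cleaning age."""
    return (
        4.0
        * (1.0 + 0.15 * (np.asarray(t_in) - 10.0))
        * (1.0 + 0.10 * np.asarray(cai))
        * (1.0 + 0.005 * np.asarray(hours_since_cleaning))
    )


def _ch4_emission(config: GeneratorConfig, diet_total, hour_frac, cai):
    """True CH4 emission (g h-1): ration-mass driven with a post-feeding peak."""
    x = (np.asarray(hour_frac) - config.feeding_hour) % 24.0
    peak = np.exp(-(((x - 2.0) / 2.5) ** 2))
    return (
        800.0
        * (np.asarray(diet_total) / 50.0)
        * (1.0 + 0.25 * peak)
        * (1.0 + 0.10 * np.asarray(cai))
    )


def gen_concentrations(
    config: GeneratorConfig,
    climate: pd.DataFrame,
    hourly_behaviour: pd.DataFrame,
    diet: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Indoor/outdoor CO2, NH3, CH4 concentrations (ppm) plus latent truth.

    The latent ventilation rate is an affine function of outdoor wind speed;
    per-cow CO2 excretion comes from the mass-balance module's own heat
    production model, so the balance is invertible by construction.  Gaussian
    noise with variance var(signal)/snr is added to the indoor channels, then
    all channels are floored at the instrument detection limits.
    """
    if not (len(climate) == len(hourly_behaviour) == len(diet)):
        raise ValueError(
            "climate, behaviour and diet inputs must be index-aligned: "
            f"lengths {len(climate)}, {len(hourly_behaviour)}, {len(diet)}"
        )
    index = climate.index
    rng = np.random.default_rng([config.seed, 0x33])
    t_in = climate["T_in"].to_numpy()
    hh = index.hour.to_numpy().astype(float)

    q_true = config.base_ventilation * (1.0 + config.wind_ventilation_gain * climate["WS_out"].to_numpy())

    herd = config.herd
    qt = mb.heat_production(herd)
    p_co2 = mb.CO2_PER_WATT * qt * np.asarray(mb.temperature_correction(t_in))

    cai = hourly_behaviour["CAI"].to_numpy()
    hsc = (hh - config.cleaning_hour) % 24.0
    diet_total = diet[DIET_COLUMNS].sum(axis=1).to_numpy()

    e_nh3 = _nh3_emission(config, t_in, cai, hsc)
    e_ch4 = _ch4_emission(config, diet_total, hh, cai)

    out_g = {
        "CO2": np.full(len(index), config.outdoor_co2_baseline),
        "NH3": np.full(len(index), config.outdoor_nh3_baseline),
        "CH4": np.full(len(index), config.outdoor_ch4_baseline),
    }
    excess_g = {
        "CO2": p_co2 * herd.n_cows / q_true,
        "NH3": e_nh3 / q_true,
        "CH4": e_ch4 / q_true,
    }

    conc = pd.DataFrame(index=index)
    truth = pd.DataFrame(
        {"Q_true": q_true, "E_NH3_true": e_nh3, "E_CH4_true": e_ch4}, index=index
    )
    for gas in ("CO2", "NH3", "CH4"):
        in_ppm_clean = np.asarray(
            mb.mass_concentration_to_ppm(out_g[gas] + excess_g[gas], gas, t_in)
        )
        out_ppm = np.asarray(mb.mass_concentration_to_ppm(out_g[gas], gas, t_in))
        sd_signal = float(np.std(in_ppm_clean))
        noise_sd = 0.0 if math.isinf(config.snr) else sd_signal / math.sqrt(config.snr)
        floor = DETECTION_LIMIT_PPM[gas]
        truth[f"C_{gas}_in_clean"] = in_ppm_clean
        if config.n_sampling_points > 1 and gas != "CO2":
            for k in range(1, config.n_sampling_points + 1):
                noisy = in_ppm_clean + rng.normal(0.0, noise_sd, len(index))
                conc[f"C_{gas}_in_{k}"] = np.maximum(noisy, floor)
        else:
            noisy = in_ppm_clean + rng.normal(0.0, noise_sd, len(index))
            conc[f"C_{gas}_in"] = np.maximum(noisy, floor)
        conc[f"C_{gas}_out"] = np.maximum(out_ppm, floor)
    return conc, truth


@dataclass
class SyntheticStudy:
    """One generated campaign: hourly records, 15-min scans and latent truth."""

    config: GeneratorConfig
    records: pd.DataFrame
    scans: pd.DataFrame
    truth: pd.DataFrame

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write records/scans/truth as round-trippable CSV files."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": d / "hourly_records.csv",
            "scans": d / "scans.csv",
            "truth": d / "truth.csv",
        }
        self.records.to_csv(paths["records"], index=False)
        self.scans.to_csv(paths["scans"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths

    def split(self):
        """The study's canonical 70:15:15 partition.

        The split is part of the dataset definition (seeded by the study
        seed) so that repeated trainings and ablation rows share one test
        partition and stay comparable.
        """
        from .dataset import split_70_15_15

        return split_70_15_15(len(self.records), self.config.seed)

    @classmethod
    def read(cls, directory: str | Path, config: GeneratorConfig | None = None) -> "SyntheticStudy":
        d = Path(directory)
        records = pd.read_csv(d / "hourly_records.csv", parse_dates=["timestamp"])
        scans = pd.read_csv(d / "scans.csv", parse_dates=["timestamp"])
        truth = pd.read_csv(d / "truth.csv", parse_dates=["timestamp"])
        return cls(config=config or GeneratorConfig(), records=records, scans=scans, truth=truth)


def gen_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Assemble a full synthetic campaign of exactly ``n_records`` hours.

    Climate, hourly behaviour indices (from the 15-min scans), the diet
    schedule and the constructed concentrations are merged into one hourly
    record table; the aligned truth table carries Q_true, the true emission
    rates and the noiseless indoor concentration signals.
    """
    config = config or GeneratorConfig()
    full, kept = _timeline(config)

    climate = gen_climate(config).loc[kept]
    scans = gen_activity_scans(config)
    hourly = bhv.hourly_behaviour(bhv.scans_from_frame(scans)).reindex(kept)
    diet = _hourly_diet(config, kept)
    conc, truth = gen_concentrations(config, climate, hourly, diet)

    records = pd.concat(
        [
            pd.DataFrame(
                {"timestamp": kept, "hour": kept.hour.to_numpy().astype("int64")},
                index=kept,
            ),
            climate,
            hourly,
            diet,
            conc,
        ],
        axis=1,
    ).reset_index(drop=True)
    truth = truth.reset_index(names="timestamp")
    scans = scans.reset_index(drop=True)
    assert len(records) == config.n_records
    return SyntheticStudy(config=config, records=records, scans=scans, truth=truth)
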