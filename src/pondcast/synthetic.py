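"""Synthetic pond water-quality time series with injected sensor faults.

Generates the kind of data a wireless aquaculture monitoring station records:
meteorological covariates (water temperature, solar radiation, wind speed,
rainfall, air humidity) sampled at a fixed interval, a latent "true" dissolved
oxygen (DO) trace with a diel cycle, and several DO sensors that observe the
truth through noise plus three realistic fault modes:

* **zero faults** — the sensor reports an exact 0.00 mg/L reading,
* **spike faults** — the reading jumps far above its neighbours,
* **persistent bias** — one sensor reads systematically low (or high).

The true DO follows

    DO(t) = m + a * sin(2*pi*(h(t) - phi)/24) + b*(T(t) - T_mean) + e(t)

with ``h(t)`` the hour of day, ``T(t)`` the water temperature and ``e(t)`` an
AR(1) residual — a diel sinusoid phase-locked to the solar cycle (DO peaks in
late afternoon, after photosynthesis has run all day) plus a weak temperature
coupling. This is a statistical emulation of pond dynamics, not a
biogeochemical model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SensorFrame",
    "generate_truth",
    "corrupt_sensors",
    "simulate",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ["water_temp", "solar_rad", "wind_speed", "rainfall", "humidity"]

#: Start of the simulated record; only the time of day matters to the model.
_EPOCH = pd.Timestamp("2015-06-21 00:00:00")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic pond generator.

    Fault rates are i.i.d. per reading. ``biased_sensor_index`` is 0-based
    (default 3, i.e. the fourth sensor, which reads low by ``bias_offset``).
    The truth-process coefficients (``do_mean``, ``do_amplitude``,
    ``temp_coupling``, ``ar_rho``, ``ar_sd``) control the diel DO model
    documented in the module docstring.
    """

    n_samples: int = 720
    interval_minutes: float = 20.0
    n_sensors: int = 4
    noise_sd: float = 0.2
    zero_fault_rate: float = 0.02
    spike_fault_rate: float = 0.01
    spike_magnitude: float = 3.0
    biased_sensor_index: Optional[int] = 3
    bias_offset: float = -0.8
    seed: int = 0
    # truth process: DO(t) = m + a*sin(2*pi*(h - phi)/24) + b*(T - T_mean) + AR(1)
    do_mean: float = 6.0
    do_amplitude: float = 2.0
    do_phase_hour: float = 10.0  # sinusoid peaks at phi + 6 h = 16:00
    temp_coupling: float = 0.1
    ar_rho: float = 0.9
    ar_sd: float = 0.15
    # covariate processes
    temp_mean: float = 26.0
    temp_amplitude: float = 3.0
    temp_noise_sd: float = 0.3
    solar_max: float = 800.0
    solar_noise_sd: float = 20.0
    wind_mean: float = 2.0
    wind_noise_sd: float = 0.6
    rain_event_rate: float = 0.01
    rain_event_mm: float = 2.0
    humidity_mean: float = 75.0
    humidity_amplitude: float = 10.0
    humidity_noise_sd: float = 2.0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.interval_minutes <= 0:
            raise ValueError("interval_minutes must be positive")
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")
        if self.noise_sd < 0 or self.ar_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for name in ("zero_fault_rate", "spike_fault_rate", "rain_event_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if not -1.0 < self.ar_rho < 1.0:
            raise ValueError("ar_rho must lie in (-1, 1) for a stationary residual")
        if self.biased_sensor_index is not None and not (
            0 <= self.biased_sensor_index < self.n_sensors
        ):
            raise ValueError("biased_sensor_index out of range")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SensorFrame:
    """Aligned multi-sensor + covariate time series; the package's I/O object.

    ``sensor_do`` is an ``(n, S)`` array of DO readings, ``truth_do`` the
    latent true DO (synthetic data only) and ``valid_mask`` an ``(n, S)``
    boolean array that is ``False`` where a fault was injected. The mask
    exists for evaluation only — the fusion stage never sees it.
    """

    timestamps: pd.DatetimeIndex
    covariates: pd.DataFrame
    sensor_do: Optional[np.ndarray] = None
    truth_do: Optional[np.ndarray] = None
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if len(self.covariates) != n:
            raise ValueError("covariates and timestamps have different lengths")
        if list(self.covariates.columns) != COVARIATE_COLUMNS:
            raise ValueError(f"covariate columns must be {COVARIATE_COLUMNS}")
        if n >= 2:
            deltas = np.diff(self.timestamps.asi8)
            if not (deltas > 0).all() or not (deltas == deltas[0]).all():
                raise ValueError("timestamps must be strictly increasing at a fixed interval")
        for name in ("sensor_do", "truth_do", "valid_mask"):
            arr = getattr(self, name)
            if arr is not None and arr.shape[0] != n:
                raise ValueError(f"{name} length does not match timestamps")
        if self.sensor_do is not None and (self.sensor_do < 0).any():
            raise ValueError("DO readings must be non-negative")
        if self.truth_do is not None and (self.truth_do < 0).any():
            raise ValueError("true DO must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_sensors(self) -> int:
        return 0 if self.sensor_do is None else self.sensor_do.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Flat table in the package CSV dialect (timestamp + covariates +
        ``do_s1..do_sS`` + optional ``do_truth``)."""
        df = self.covariates.copy()
        df.insert(0, "timestamp", self.timestamps)
        if self.sensor_do is not None:
            for j in range(self.sensor_do.shape[1]):
                df[f"do_s{j + 1}"] = self.sensor_do[:, j]
        if self.truth_do is not None:
            df["do_truth"] = self.truth_do
        return df.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SensorFrame":
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        cov = df[COVARIATE_COLUMNS].copy()
        cov.index = range(len(df))
        sensor_cols = sorted(
            (c for c in df.columns if c.startswith("do_s") and c[4:].isdigit()),
            key=lambda c: int(c[4:]),
        )
        sensor_do = df[sensor_cols].to_numpy(float) if sensor_cols else None
        truth = df["do_truth"].to_numpy(float) if "do_truth" in df.columns else None
        return cls(timestamps=ts, covariates=cov, sensor_do=sensor_do, truth_do=truth)

    @classmethod
    def from_csv(cls, path) -> "SensorFrame":
        return cls.from_dataframe(pd.read_csv(path))


def _hours_of_day(timestamps: pd.DatetimeIndex) -> np.ndarray:
    return (
        timestamps.hour.to_numpy(float)
        + timestamps.minute.to_numpy(float) / 60.0
        + timestamps.second.to_numpy(float) / 3600.0
    )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with innovation standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho**2))
    innov = rng.normal(0.0, sd, size=n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov[t - 1]
    return e


def generate_truth(config: SyntheticConfig) -> SensorFrame:
    """Generate covariates and the latent true DO trace (no sensors yet).

    Deterministic in ``config.seed``; with all noise terms zero the truth is
    the closed-form diel sinusoid plus temperature coupling.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_samples
    ts = pd.DatetimeIndex(
        _EPOCH + pd.to_timedelta(np.arange(n) * config.interval_minutes, unit="m")
    )
    h = _hours_of_day(ts)

    # Covariates: diel structure, peaks mid-day / mid-afternoon.
    temp = (
        config.temp_mean
        + config.temp_amplitude * np.sin(2 * np.pi * (h - 9.0) / 24.0)
        + _ar1(rng, n, 0.9, config.temp_noise_sd)
    )
    solar = np.clip(
        config.solar_max * np.sin(np.pi * (h - 6.0) / 12.0)
        + rng.normal(0.0, config.solar_noise_sd, size=n) * (config.solar_noise_sd > 0),
        0.0,
        None,
    )
    wind = np.clip(config.wind_mean + _ar1(rng, n, 0.8, config.wind_noise_sd), 0.0, None)
    rain = np.where(
        rng.random(n) < config.rain_event_rate,
        rng.exponential(config.rain_event_mm, size=n),
        0.0,
    )
    humidity = np.clip(
        config.humidity_mean
        - config.humidity_amplitude * np.sin(2 * np.pi * (h - 9.0) / 24.0)
        + rng.normal(0.0, config.humidity_noise_sd, size=n) * (config.humidity_noise_sd > 0),
        10.0,
        100.0,
    )
    cov = pd.DataFrame(
        {
            "water_temp": temp,
            "solar_rad": solar,
            "wind_speed": wind,
            "rainfall": rain,
            "humidity": humidity,
        },
        index=range(n),
    )

    truth = (
        config.do_mean
        + config.do_amplitude * np.sin(2 * np.pi * (h - config.do_phase_hour) / 24.0)
        + config.temp_coupling * (temp - config.temp_mean)
        + _ar1(rng, n, config.ar_rho, config.ar_sd)
    )
    truth = np.maximum(truth, 0.05)  # physical floor; inactive at defaults
    return SensorFrame(timestamps=ts, covariates=cov, truth_do=truth)


def corrupt_sensors(frame: SensorFrame, config: SyntheticConfig) -> SensorFrame:
    """Observe the true DO through ``n_sensors`` faulty sensors.

    Each reading is truth plus Gaussian noise; with probability
    ``zero_fault_rate`` it is replaced by an exact 0.00 (masked invalid), with
    probability ``spike_fault_rate`` it gains ``spike_magnitude`` (masked
    invalid); the biased sensor has ``bias_offset`` added throughout; readings
    are clipped at 0 mg/L.
    """
    config.validate()
    if frame.truth_do is None:
        raise ValueError("frame has no truth_do; generate_truth must run first")
    rng = np.random.default_rng([config.seed, 1])
    n, s = len(frame), config.n_sensors
    truth = frame.truth_do[:, None]

    readings = truth + rng.normal(0.0, config.noise_sd, size=(n, s))
    if config.biased_sensor_index is not None:
        readings[:, config.biased_sensor_index] += config.bias_offset
    spikes = rng.random((n, s)) < config.spike_fault_rate
    readings = readings + spikes * config.spike_magnitude
    zeros = rng.random((n, s)) < config.zero_fault_rate
    readings = np.where(zeros, 0.0, readings)
    readings = np.clip(readings, 0.0, None)

    valid = ~(zeros | spikes)
    return SensorFrame(
        timestamps=frame.timestamps,
        covariates=frame.covariates,
        sensor_do=readings,
        truth_do=frame.truth_do,
        valid_mask=valid,
    )


def simulate(config: SyntheticConfig) -> SensorFrame:
    """Convenience: ``corrupt_sensors(generate_truth(config), config)``."""
    return corrupt_sensors(generate_truth(config), config)
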