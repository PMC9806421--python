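"""Voltage-clamp protocol engine.

Renders the standard protocol families (conditioning-pulse availability,
slow-inactivation development, double-pulse repriming, diary plots during
drug application) into synthetic sweep families by driving the Markov
channel model of :mod:`statekin.channel` through piecewise-constant command
voltages.

Conventions
-----------
* Availability of a sweep is the occupancy of the unbound resting state R at
  the onset of the epoch tagged ``test``; the peak-current proxy is
  availability times a fixed maximal amplitude (activation kinetics are not
  rendered into current waveforms).  Currents are treated as magnitudes.
* Each sweep starts from the stationary distribution at the holding
  potential under the inhibitor concentration in force at t = 0, i.e.
  protocols describe fully equilibrated (control or drug-equilibrated)
  conditions; the time-varying drug-application experiment is
  :func:`simulate_inhibition_diary`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .channel import (
    ALL_STATES,
    ChannelModel,
    ConfigurationError,
    InhibitorSchedule,
    StateDistribution,
    ZERO_SCHEDULE,
    propagate,
    steady_state,
)

__all__ = [
    "Epoch",
    "ProtocolSpec",
    "SweepRecord",
    "SweepFamily",
    "DiarySeries",
    "run_protocol",
    "simulate_inhibition_diary",
    "fast_inactivation_protocol",
    "slow_inactivation_protocol",
    "development_protocol",
    "repriming_protocol",
]


@dataclass(frozen=True)
class Epoch:
    """One command-voltage epoch: ``duration`` s at ``voltage`` mV."""

    duration: float
    voltage: float
    tag: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError(f"epoch duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class ProtocolSpec:
    """A swept voltage-clamp protocol.

    ``sweep_param`` ("voltage" or "duration") of the epoch tagged
    ``sweep_tag`` is replaced by each value of ``sweep_values`` in turn; the
    epoch tagged ``test`` defines where availability is read.
    """

    epochs: tuple[Epoch, ...]
    sweep_param: str
    sweep_tag: str
    sweep_values: tuple[float, ...]
    holding: float = -80.0
    inter_sweep_interval: float = 2.0
    normalization: str = "none"

    def __post_init__(self) -> None:
        tags = [e.tag for e in self.epochs if e.tag]
        if len(tags) != len(set(tags)):
            raise ConfigurationError("tagged epochs must be unique")
        if self.sweep_param not in ("voltage", "duration"):
            raise ConfigurationError(f"unknown sweep parameter {self.sweep_param!r}")
        if self.sweep_tag not in tags:
            raise ConfigurationError(f"sweep tag {self.sweep_tag!r} not found")
        if "test" not in tags:
            raise ConfigurationError("protocol has no epoch tagged 'test'")
        vals = np.asarray(self.sweep_values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("sweep values must be finite")
        if not np.all(np.diff(vals) >= 0):
            raise ConfigurationError("sweep values must be sorted")
        if self.normalization not in ("none", "first", "holding"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")

    def sweep_epochs(self, value: float) -> tuple[Epoch, ...]:
        out = []
        for e in self.epochs:
            if e.tag == self.sweep_tag:
                e = replace(e, **{self.sweep_param: float(value)})
            out.append(e)
        return tuple(out)


@dataclass(frozen=True)
class SweepRecord:
    axis_value: float
    availability: float
    peak: float
    peak_norm: float
    times: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    occupancy: np.ndarray = field(repr=False, default_factory=lambda: np.empty((0, 0)))
    voltages: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class SweepFamily:
    """Per-sweep availability / normalized-peak records plus trajectories."""

    records: tuple[SweepRecord, ...]
    normalization: str
    holding: float
    reference_peak: float

    @property
    def axis_values(self) -> np.ndarray:
        return np.array([r.axis_value for r in self.records])

    @property
    def availability(self) -> np.ndarray:
        return np.array([r.availability for r in self.records])

    @property
    def peaks_norm(self) -> np.ndarray:
        return np.array([r.peak_norm for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis_value": self.axis_values,
                "availability": self.availability,
                "peak": [r.peak for r in self.records],
                "peak_norm": self.peaks_norm,
            }
        )

    def trajectory_frame(self) -> pd.DataFrame:
        """Tidy long-format occupancy trajectories (one row per time point)."""
        rows = []
        for i, r in enumerate(self.records):
            if r.times.size == 0:
                continue
            df = pd.DataFrame(r.occupancy, columns=list(ALL_STATES))
            df.insert(0, "sweep_id", i)
            df.insert(1, "axis_value", r.axis_value)
            df.insert(2, "time_s", r.times)
            df.insert(3, "voltage_mV", r.voltages)
            df["availability"] = r.availability
            df["peak_norm"] = r.peak_norm
            rows.append(df)
        if not rows:
            return pd.DataFrame()
        return pd.concat(rows, ignore_index=True)


def run_protocol(
    model: ChannelModel,
    protocol: ProtocolSpec,
    schedule: InhibitorSchedule = ZERO_SCHEDULE,
    noise_sd: float = 0.0,
    seed: int | None = None,
    i_max: float = 1.0,
    dt: float = 1e-3,
    stride: int = 0,
) -> SweepFamily:
    """Run every sweep of a protocol and return the sweep family.

    ``stride`` > 0 records the occupancy trajectory every ``stride``
    propagation steps; 0 records endpoints only (cheapest).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x0 = float(schedule.concentration(0.0))
    start = steady_state(model, protocol.holding, x0)

    records: list[SweepRecord] = []
    for value in protocol.sweep_values:
        p = start
        t = 0.0
        availability = None
        traj_t, traj_p, traj_v = [], [], []
        for epoch in protocol.sweep_epochs(value):
            if epoch.tag == "test":
                availability = p.availability
            times, dists = propagate(
                model, p, epoch.voltage, schedule, epoch.duration,
                dt=dt, t0=t, stride=stride if stride > 0 else 0,
            )
            if stride > 0:
                traj_t.append(times)
                traj_p.append(np.array([d.vector() for d in dists]))
                traj_v.append(np.full(len(times), epoch.voltage))
            p = dists[-1]
            t = float(times[-1])
            if epoch.tag == "test":
                break
        assert availability is not None  # ProtocolSpec guarantees a test epoch
        peak = availability * i_max
        if noise_sd > 0:
            peak = peak + rng.normal(0.0, noise_sd * i_max)
        records.append(
            SweepRecord(
                axis_value=float(value),
                availability=float(availability),
                peak=float(peak),
                peak_norm=float(peak),  # filled below
                times=np.concatenate(traj_t) if traj_t else np.empty(0),
                occupancy=np.concatenate(traj_p) if traj_p else np.empty((0, 0)),
                voltages=np.concatenate(traj_v) if traj_v else np.empty(0),
            )
        )

    if protocol.normalization == "first":
        ref = records[0].peak
    elif protocol.normalization == "holding":
        # pre-drug reference: current elicited from the holding potential in
        # the drug-free stationary state
        ref = steady_state(model, protocol.holding, 0.0).availability * i_max
    else:
        ref = 1.0
    if ref <= 0:
        raise ValueError("normalization reference peak is not positive")
    records = [replace(r, peak_norm=r.peak / ref) for r in records]
    return SweepFamily(
        records=tuple(records),
        normalization=protocol.normalization,
        holding=protocol.holding,
        reference_peak=float(ref),
    )


@dataclass(frozen=True)
class DiarySeries:
    """Normalized peak current versus time during drug application.

    Times are relative to drug onset (onset = 0); peaks are normalized to
    the mean of the pre-onset baseline pulses.
    """

    times: np.ndarray
    peaks_norm: np.ndarray
    baseline_mean: float
    V_h: float

    def onset_series(self) -> tuple[np.ndarray, np.ndarray]:
        """The post-onset part of the diary (t >= 0)."""
        m = self.times >= 0
        return self.times[m], self.peaks_norm[m]


def simulate_inhibition_diary(
    model: ChannelModel,
    V_h: float,
    schedule: InhibitorSchedule,
    test_interval: float = 2.0,
    n_pulses: int = 100,
    seed: int | None = None,
    noise_sd: float = 0.0,
    n_baseline: int = 5,
    dt: float = 0.05,
) -> DiarySeries:
    """Diary plot of normalized peak current under repeated test pulses.

    Test pulses are delivered every ``test_interval`` s (default 2 s, i.e.
    0.5 Hz); ``n_baseline`` pulses precede drug onset.  The brief test
    depolarizations themselves are not propagated (repriming at the holding
    potentials is complete within a few ms, leaving no measurable
    accumulation at 0.5 Hz); availability is read at each pulse time.
    """
    if test_interval <= 0:
        raise ValueError("test_interval must be > 0 (default 2 s)")
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    rng = np.random.default_rng(seed)

    t_first = -n_baseline * test_interval
    pulse_times = t_first + test_interval * np.arange(n_baseline + n_pulses)
    if schedule.shape != "zero" and schedule.onset_time > pulse_times[-1]:
        warnings.warn(
            "inhibitor onset falls after the last test pulse; diary is control-only",
            stacklevel=2,
        )

    p = steady_state(model, V_h, 0.0)
    peaks = np.empty(len(pulse_times))
    peaks[0] = p.availability
    for i in range(1, len(pulse_times)):
        _, dists = propagate(
            model, p, V_h, schedule, test_interval,
            dt=dt, t0=pulse_times[i - 1], stride=0,
        )
        p = dists[-1]
        peaks[i] = p.availability
    if noise_sd > 0:
        peaks = peaks + rng.normal(0.0, noise_sd * peaks[: n_baseline + 1].mean(),
                                   size=peaks.shape)

    baseline = peaks[pulse_times <= 0]
    baseline_mean = float(baseline.mean()) if baseline.size else float(peaks[0])
    return DiarySeries(
        times=pulse_times,
        peaks_norm=peaks / baseline_mean,
        baseline_mean=baseline_mean,
        V_h=V_h,
    )


# ---------------------------------------------------------------------------
# Canonical protocol builders
# ---------------------------------------------------------------------------

def _voltage_grid(start: float = -140.0, stop: float = 20.0, step: float = 10.0):
    return tuple(np.arange(start, stop + step / 2, step))


def fast_inactivation_protocol(
    voltages: Sequence[float] | None = None,
    holding: float = -80.0,
    prepulse_s: float = 0.100,
    test_voltage: float = -20.0,
) -> ProtocolSpec:
    """100 ms conditioning pulses (-140..+20 mV) followed directly by a test
    pulse; isolates the voltage dependence of fast inactivation."""
    return ProtocolSpec(
        epochs=(
            Epoch(prepulse_s, -80.0, "prepulse"),
            Epoch(0.010, test_voltage, "test"),
        ),
        sweep_param="voltage",
        sweep_tag="prepulse",
        sweep_values=tuple(voltages) if voltages is not None else _voltage_grid(),
        holding=holding,
        normalization="none",
    )


def slow_inactivation_protocol(
    voltages: Sequence[float] | None = None,
    holding: float = -80.0,
    prepulse_s: float = 5.0,
    recovery_s: float = 0.100,
    recovery_voltage: float = -120.0,
    test_voltage: float = -20.0,
) -> ProtocolSpec:
    """5 s conditioning pulses, then 100 ms at -120 mV to clear fast
    inactivation, then the test pulse; isolates slow inactivation."""
    return ProtocolSpec(
        epochs=(
            Epoch(prepulse_s, -80.0, "prepulse"),
            Epoch(recovery_s, recovery_voltage, "recovery"),
            Epoch(0.010, test_voltage, "test"),
        ),
        sweep_param="voltage",
        sweep_tag="prepulse",
        sweep_values=tuple(voltages) if voltages is not None else _voltage_grid(),
        holding=holding,
        normalization="none",
    )


def development_protocol(
    conditioning_voltage: float,
    durations: Sequence[float],
    holding: float = -80.0,
    recovery_s: float = 0.050,
    recovery_voltage: float = -120.0,
    test_voltage: float = -20.0,
) -> ProtocolSpec:
    """Variable-length conditioning step to one voltage, 50 ms recovery at
    -120 mV, then the test pulse; tracks the development of slow
    inactivation (or of inhibition, under drug)."""
    return ProtocolSpec(
        epochs=(
            Epoch(1.0, conditioning_voltage, "prepulse"),
            Epoch(recovery_s, recovery_voltage, "recovery"),
            Epoch(0.010, test_voltage, "test"),
        ),
        sweep_param="duration",
        sweep_tag="prepulse",
        sweep_values=tuple(sorted(float(d) for d in durations)),
        holding=holding,
        normalization="first",
    )


def repriming_protocol(
    V_h: float,
    recovery_times: Sequence[float],
    s1_s: float = 0.010,
    test_voltage: float = -20.0,
    recovery_voltage: float = -120.0,
) -> ProtocolSpec:
    """Double-pulse repriming: S1 (10 ms at -20 mV), a variable-length
    recovery period at -120 mV, then S2; peaks are normalized to the
    pre-drug current from the holding potential (I2/I1con)."""
    return ProtocolSpec(
        epochs=(
            Epoch(s1_s, test_voltage, "s1"),
            Epoch(1.0, recovery_voltage, "recovery"),
            Epoch(s1_s, test_voltage, "test"),
        ),
        sweep_param="duration",
        sweep_tag="recovery",
        sweep_values=tuple(sorted(float(t) for t in recovery_times)),
        holding=V_h,
        normalization="holding",
    )
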