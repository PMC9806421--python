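"""Current-clamp spike-feature extraction.

Definitions follow standard whole-cell practice for cortical neurons:

* threshold -- the membrane potential at which dV/dt first reaches
  20 mV/ms on the rising phase of a spike;
* amplitude -- the voltage difference between threshold and peak;
* half-width -- the interval between the rising and falling phases at the
  level halfway between the peak and the *holding* potential (note: the
  holding potential, not the threshold, is the reference);
* input resistance -- steady-state voltage deflection divided by the
  injected current (70 pA standard step).

A stylized spike-train generator (:func:`synth_ap_train`) produces traces
whose features are recoverable by construction, for round-trip testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoltageTrace",
    "SpikeWindow",
    "APFeatureSet",
    "detect_spikes",
    "ap_features",
    "fractional_inhibition",
    "input_resistance",
    "synth_ap_train",
]


@dataclass(frozen=True)
class VoltageTrace:
    """A uniformly sampled membrane-potential trace."""

    time: np.ndarray      # s
    voltage: np.ndarray   # mV
    injected_pA: float = 0.0
    holding: float = -80.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ValueError("time and voltage must be equal-length arrays (n >= 2)")
        dts = np.diff(t)
        if np.any(dts <= 0) or np.ptp(dts) > 1e-9 * dts[0] + 1e-12:
            raise ValueError("trace must be uniformly sampled with dt > 0")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def dvdt(self) -> np.ndarray:
        """Central two-point derivative in mV/ms (no smoothing)."""
        v = np.asarray(self.voltage, dtype=float)
        d = np.gradient(v, self.time)  # mV per s
        return d / 1000.0


@dataclass(frozen=True)
class SpikeWindow:
    start: int       # index of the threshold (dV/dt crossing) sample
    peak_index: int
    end: int


@dataclass(frozen=True)
class APFeatureSet:
    threshold: float          # mV
    amplitude: float          # mV (peak - threshold)
    half_width: float | None  # ms; None when a flank never crosses half-level
    peak_time: float          # s
    peak_voltage: float       # mV
    missing: tuple[str, ...] = ()


def detect_spikes(
    trace: VoltageTrace,
    dvdt_threshold: float = 20.0,
    min_peak: float = 0.0,
    merge_ms: float = 2.0,
) -> list[SpikeWindow]:
    """Detect spikes as upward dV/dt crossings followed by a local maximum.

    A window opens at the first sample where dV/dt >= ``dvdt_threshold``
    (mV/ms), runs to the subsequent local maximum and on until the voltage
    falls back below the threshold voltage (or the next crossing).  Windows
    whose threshold crossings are closer than ``merge_ms`` are merged
    (refractory handling).  Spikes whose peak is below ``min_peak`` mV are
    discarded.
    """
    v = np.asarray(trace.voltage, dtype=float)
    d = trace.dvdt()
    above = d >= dvdt_threshold
    crossings = np.where(above[1:] & ~above[:-1])[0] + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)

    merge_n = max(int(round(merge_ms * 1e-3 / trace.dt)), 1)
    windows: list[SpikeWindow] = []
    for c in crossings:
        if windows and c - windows[-1].start < merge_n:
            continue
        # find the next local maximum at/after the crossing
        i = c
        while i + 1 < v.size and v[i + 1] >= v[i]:
            i += 1
        peak = i
        if v[peak] < min_peak:
            continue
        # window ends when V falls back to the crossing-sample voltage,
        # or at the trace end
        j = peak
        while j + 1 < v.size and v[j + 1] < v[j] and v[j + 1] > v[c]:
            j += 1
        if windows and peak == windows[-1].peak_index:
            continue
        windows.append(SpikeWindow(start=int(c), peak_index=int(peak), end=int(j)))
    return windows


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def ap_features(trace: VoltageTrace, window: SpikeWindow,
                holding: float | None = None) -> APFeatureSet:
    """Extract threshold, amplitude and half-width for one spike window.

    The half-width level is (peak + holding)/2, with linear interpolation
    between samples on each flank; if either flank never crosses the level
    the half-width is reported missing rather than fabricated.
    """
    if holding is None:
        holding = trace.holding
    t = np.asarray(trace.time, dtype=float)
    v = np.asarray(trace.voltage, dtype=float)
    thr_v = float(v[window.start])
    pk = window.peak_index
    peak_v = float(v[pk])
    amplitude = peak_v - thr_v
    half = (peak_v + holding) / 2.0

    missing: list[str] = []
    half_width: float | None = None
    if peak_v <= half:
        missing.append("half_width")
    else:
        # rising crossing: search back from the peak
        i = pk
        while i > 0 and v[i - 1] > half:
            i -= 1
        if v[i - 1 if i > 0 else 0] > half and i == 0:
            missing.append("half_width")
        else:
            t_rise = _interp_crossing(t[i - 1], t[i], v[i - 1], v[i], half) \
                if i > 0 else t[0]
            # falling crossing: search forward from the peak
            j = pk
            while j + 1 < v.size and v[j + 1] > half:
                j += 1
            if j + 1 >= v.size:
                missing.append("half_width")
            else:
                t_fall = _interp_crossing(t[j], t[j + 1], v[j], v[j + 1], half)
                half_width = (t_fall - t_rise) * 1000.0  # ms
    return APFeatureSet(
        threshold=thr_v,
        amplitude=amplitude,
        half_width=half_width,
        peak_time=float(t[pk]),
        peak_voltage=peak_v,
        missing=tuple(missing),
    )


def fractional_inhibition(count_control: int, count_drug: int) -> float | None:
    """(control - drug) / control spike counts; None when control = 0."""
    if count_control < 0 or count_drug < 0:
        raise ValueError("spike counts must be >= 0")
    if count_control == 0:
        return None
    return (count_control - count_drug) / count_control


def input_resistance(delta_V_ss: float, I_inj: float = 70.0) -> float:
    """Input resistance in MOhm from a steady-state deflection.

    delta_V_ss in mV, I_inj in pA; mV/pA = GOhm, so R = 1000 * dV/I MOhm.
    """
    if I_inj == 0:
        raise ValueError("injected current must be non-zero")
    return 1000.0 * delta_V_ss / I_inj


def synth_ap_train(
    n_spikes: int,
    threshold: float = -47.6,
    peak: float = 20.0,
    half_width_ms: float = 1.4,
    holding: float = -80.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 5e-5,
    duration: float = 1.0,
    pre_slope: float = 10.0,
    min_upstroke: float = 60.0,
) -> VoltageTrace:
    """Generate a stylized spike train with analytically known features.

    Each spike is piecewise linear: a slow approach ramp from holding to
    threshold at ``pre_slope`` mV/ms (below the 20 mV/ms detection
    criterion), then a symmetric triangular spike whose flank slope is set
    by the requested half-width at the level (peak+holding)/2 (but at least
    ``min_upstroke`` mV/ms).  Deterministic given ``seed``.
    """
    if peak <= threshold:
        raise ValueError(f"infeasible geometry: peak {peak} <= threshold {threshold}")
    if not (-100.0 <= holding <= -40.0 and -70.0 <= threshold <= -20.0
            and peak <= 60.0 and 0.1 <= half_width_ms <= 20.0):
        raise ValueError("spike parameters outside physiological ranges")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    v = np.full(n, float(holding))
    if n_spikes > 0:
        dt_ms = dt * 1000.0
        half = (peak + holding) / 2.0
        # the requested half-width sets the flank slopes: symmetric when the
        # implied upstroke is fast enough to detect, otherwise the rise is
        # floored at min_upstroke and the fall flank absorbs the remainder;
        # rise and fall durations are snapped to whole samples so that the
        # threshold kink and the apex fall exactly on the grid, keeping the
        # generated features recoverable to within one sample
        sym_slope = 2.0 * (peak - half) / half_width_ms
        s_rise = max(sym_slope, min_upstroke)
        inv_fall = half_width_ms / (peak - half) - 1.0 / s_rise
        s_fall = 1.0 / inv_fall if inv_fall > 0 else s_rise
        n_rise = max(int(round((peak - threshold) / s_rise / dt_ms)), 1)
        rise_slope = (peak - threshold) / (n_rise * dt_ms)
        n_fall = max(int(round((peak - holding) / s_fall / dt_ms)), 2)
        n_ramp = max(int(round((threshold - holding) / pre_slope / dt_ms)), 1)
        spike_samples = n_ramp + n_rise + n_fall
        period = n // n_spikes
        if spike_samples + 2 > period:
            raise ValueError("spikes do not fit: reduce n_spikes or half-width")
        for k in range(n_spikes):
            i0 = k * period + (period - spike_samples) // 2
            i_thr = i0 + n_ramp
            i_pk = i_thr + n_rise
            i_end = i_pk + n_fall
            v[i0:i_thr + 1] = np.linspace(holding, threshold, n_ramp + 1)
            v[i_thr:i_pk + 1] = threshold + rise_slope * dt_ms * np.arange(
                n_rise + 1)
            v[i_pk:i_end + 1] = np.linspace(peak, holding, n_fall + 1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return VoltageTrace(time=t, voltage=v, holding=holding)
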