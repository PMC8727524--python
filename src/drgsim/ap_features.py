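"""Action-potential detection and excitability measures.

Operational definitions (applied identically to simulated and imported
sweeps):

* an AP is a voltage peak above −10 mV with ≥ 20 mV prominence and ≥ 1 ms
  separation from its neighbours;
* the voltage threshold of an AP is the membrane potential at the last
  upward crossing of dV/dt = 5 mV/ms on the upstroke (searching backward
  from the peak to the preceding local minimum), linearly interpolated;
* latency (step protocols) runs from stimulus onset to the first AP's
  threshold point;
* ramp rheobase is the injected current (above the 0 pA baseline) at the
  first AP's threshold time; the capacitance-normalized variant divides by
  the cell's membrane capacitance;
* rheobase charge transfer integrates the injected current from stimulus
  onset (steps) or from the ramp's 0 pA crossing (ramps) to the threshold
  point;
* step-evoked APs are all counted; ramp-evoked APs only within the first
  2 s from the start of the rising ramp segment;
* the first inter-AP interval is the time between the peaks of the first
  two APs;
* AP waveform measures (peak potential, amplitude above threshold, 10–90%
  rise and 90–10% fall times, maximal rising speed, duration at the
  +15 mV level) are taken from the first AP.

Threshold, latency, rheobase and charge transfer always derive from the
first AP of a sweep, so that cumulative Na-channel inactivation during
later spikes cannot bias them. Undefined features (e.g. no AP, or fewer
than two APs for the first interval) are reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .sweeps import Sweep

__all__ = [
    "DetectionSettings",
    "APFeatures",
    "SweepFeatures",
    "ThresholdNotFound",
    "detect_aps",
    "ap_threshold",
    "ap_waveform_measures",
    "count_aps",
    "latency",
    "rheobase_ramp",
    "charge_transfer",
    "first_isi",
    "sweep_features",
    "features_table",
    "phase_plot",
]

#: dV/dt level (mV/ms) defining the voltage threshold
THRESHOLD_DVDT = 5.0
#: membrane-potential level (mV) at which AP duration is measured
DURATION_LEVEL = 15.0
#: ramp AP-counting window (ms) measured from the start of the rising ramp
RAMP_COUNT_WINDOW = 2000.0


@dataclass(frozen=True)
class DetectionSettings:
    """Peak-detection constants (config-exposed)."""

    min_peak_mV: float = -10.0
    min_prominence_mV: float = 20.0
    min_separation_ms: float = 1.0
    #: half-width (points) of an optional smoothing window for the dV/dt
    #: estimate; 0 disables smoothing (simulated traces are noise-free)
    smooth_halfwidth: int = 0


DEFAULT_DETECTION = DetectionSettings()


class ThresholdNotFound(ValueError):
    """The upstroke never reaches the threshold dV/dt level."""


@dataclass
class APFeatures:
    peak_time: float
    peak_potential: float
    threshold: float
    threshold_time: float
    amplitude: float
    rise_time_10_90: float
    fall_time_90_10: float
    rising_speed: float
    duration_at_plus15: float


@dataclass
class SweepFeatures:
    n_aps: int
    latency: float = math.nan
    first_isi: float = math.nan
    threshold: float = math.nan
    rheobase: float = math.nan
    rheobase_norm: float = math.nan
    charge_transfer: float = math.nan
    per_ap: list[APFeatures] = field(default_factory=list)


def _dvdt(sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION) -> np.ndarray:
    """Central-difference voltage derivative (mV/ms) on the recorded grid."""
    v = sweep.v
    if settings.smooth_halfwidth > 0:
        w = 2 * settings.smooth_halfwidth + 1
        v = np.convolve(v, np.ones(w) / w, mode="same")
    return np.gradient(v, sweep.t)


def detect_aps(
    sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION
) -> np.ndarray:
    """Indices of AP peaks, in time order (empty array when none)."""
    distance = max(1, int(round(settings.min_separation_ms / sweep.dt)))
    peaks, _ = find_peaks(
        sweep.v,
        height=settings.min_peak_mV,
        prominence=settings.min_prominence_mV,
        distance=distance,
    )
    return peaks


def ap_threshold(
    sweep: Sweep,
    peak_index: int,
    settings: DetectionSettings = DEFAULT_DETECTION,
) -> tuple[float, float]:
    """(threshold mV, threshold time ms) for the AP peaking at ``peak_index``.

    The upstroke is scanned backward from the peak to the preceding local
    minimum for the last upward crossing of dV/dt = 5 mV/ms; voltage and
    time are linearly interpolated at the crossing.
    """
    v, t = sweep.v, sweep.t
    dv = _dvdt(sweep, settings)
    # preceding local minimum of the voltage trace
    j = int(peak_index)
    while j > 0 and v[j - 1] <= v[j]:
        j -= 1
    if j == peak_index:
        raise ThresholdNotFound("peak has no rising flank")
    seg = np.arange(j, peak_index)
    crossings = seg[(dv[seg] < THRESHOLD_DVDT) & (dv[seg + 1] >= THRESHOLD_DVDT)]
    if crossings.size == 0:
        if dv[seg[0]] >= THRESHOLD_DVDT:
            # upstroke already above 5 mV/ms at the local minimum: the
            # crossing happened at/before the minimum; use the minimum
            return float(v[j]), float(t[j])
        raise ThresholdNotFound(
            f"dV/dt never reaches {THRESHOLD_DVDT} mV/ms on the upstroke "
            f"before t={t[peak_index]:.3f} ms"
        )
    k = int(crossings[-1])
    frac = (THRESHOLD_DVDT - dv[k]) / (dv[k + 1] - dv[k])
    return (
        float(v[k] + frac * (v[k + 1] - v[k])),
        float(t[k] + frac * (t[k + 1] - t[k])),
    )


def _cross_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """First interpolated time at which y crosses ``level`` in the given
    direction; NaN when it never does."""
    if rising:
        hits = np.flatnonzero((y[:-1] < level) & (y[1:] >= level))
    else:
        hits = np.flatnonzero((y[:-1] >= level) & (y[1:] < level))
    if hits.size == 0:
        return math.nan
    k = hits[0]
    frac = (level - y[k]) / (y[k + 1] - y[k])
    return float(t[k] + frac * (t[k + 1] - t[k]))


def ap_waveform_measures(
    sweep: Sweep,
    peak_index: int,
    settings: DetectionSettings = DEFAULT_DETECTION,
) -> APFeatures:
    """All per-AP waveform measures for one detected AP."""
    v, t = sweep.v, sweep.t
    thr, thr_t = ap_threshold(sweep, peak_index, settings)
    peak_v = float(v[peak_index])
    peak_t = float(t[peak_index])
    amplitude = peak_v - thr
    lo = thr + 0.1 * amplitude
    hi = thr + 0.9 * amplitude
    dv = _dvdt(sweep, settings)

    # rising flank: from threshold sample to peak
    i0 = int(np.searchsorted(t, thr_t))
    rise = slice(max(i0 - 1, 0), peak_index + 1)
    t10 = _cross_time(t[rise], v[rise], lo, rising=True)
    t90 = _cross_time(t[rise], v[rise], hi, rising=True)
    rise_time = t90 - t10

    # falling flank: from the peak to the next local minimum
    j = int(peak_index)
    nmax = v.size - 1
    while j < nmax and v[j + 1] <= v[j]:
        j += 1
    fall = slice(peak_index, j + 1)
    f90 = _cross_time(t[fall], v[fall], hi, rising=False)
    f10 = _cross_time(t[fall], v[fall], lo, rising=False)
    fall_time = f10 - f90

    rising_speed = float(np.max(dv[rise]))

    if peak_v <= DURATION_LEVEL:
        duration = math.nan
    else:
        up = _cross_time(t[rise], v[rise], DURATION_LEVEL, rising=True)
        down = _cross_time(t[fall], v[fall], DURATION_LEVEL, rising=False)
        duration = down - up

    return APFeatures(
        peak_time=peak_t,
        peak_potential=peak_v,
        threshold=thr,
        threshold_time=thr_t,
        amplitude=amplitude,
        rise_time_10_90=rise_time,
        fall_time_90_10=fall_time,
        rising_speed=rising_speed,
        duration_at_plus15=duration,
    )


def _stim_window(sweep: Sweep) -> tuple[float, float]:
    onset = float(sweep.meta["onset_ms"])
    end = float(sweep.meta.get("stim_end_ms", sweep.t[-1]))
    return onset, end


def count_aps(
    sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION
) -> int:
    """AP count per the protocol's rule: all APs during a step; ramp APs
    only within the first 2 s from the start of the rising ramp."""
    peaks = detect_aps(sweep, settings)
    if peaks.size == 0:
        return 0
    tp = sweep.t[peaks]
    if sweep.meta.get("protocol") == "ramp":
        start = float(sweep.meta["ramp_start_ms"])
        return int(np.sum((tp >= start) & (tp <= start + RAMP_COUNT_WINDOW)))
    onset, end = _stim_window(sweep)
    return int(np.sum((tp >= onset) & (tp <= end)))


def latency(
    sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION
) -> float:
    """Stimulus onset to first-AP threshold point (ms); NaN without APs."""
    peaks = detect_aps(sweep, settings)
    if peaks.size == 0:
        return math.nan
    _, thr_t = ap_threshold(sweep, int(peaks[0]), settings)
    return thr_t - float(sweep.meta["onset_ms"])


def rheobase_ramp(
    sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION
) -> float:
    """Injected current above baseline at the first AP's threshold time (pA)."""
    if sweep.meta.get("protocol") != "ramp":
        raise ValueError("rheobase is defined on ramp sweeps")
    peaks = detect_aps(sweep, settings)
    if peaks.size == 0:
        return math.nan
    _, thr_t = ap_threshold(sweep, int(peaks[0]), settings)
    i_at = float(np.interp(thr_t, sweep.t, sweep.i))
    return i_at - 0.0  # baseline is the 0 pA pre-stimulus level


def charge_transfer(
    sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION
) -> float:
    """Trapezoidal ∫I dt (pC) from stimulus onset (step) or the ramp's 0 pA
    crossing (ramp) to the first AP's threshold time."""
    peaks = detect_aps(sweep, settings)
    if peaks.size == 0:
        return math.nan
    _, thr_t = ap_threshold(sweep, int(peaks[0]), settings)
    if sweep.meta.get("protocol") == "ramp":
        t0 = float(sweep.meta["baseline_cross_ms"])
    else:
        t0 = float(sweep.meta["onset_ms"])
    if thr_t <= t0:
        return 0.0
    # integrate on the recorded grid, with interpolated partial end intervals
    n = 200  # resample inside [t0, thr_t] for exact partial-interval handling
    grid = np.linspace(t0, thr_t, max(n, 2))
    cur = np.interp(grid, sweep.t, sweep.i)
    return float(np.trapezoid(cur, grid)) / 1000.0


def first_isi(
    sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION
) -> float:
    """Peak-to-peak time between the first two APs (ms); NaN if < 2 APs."""
    peaks = detect_aps(sweep, settings)
    if peaks.size < 2:
        return math.nan
    return float(sweep.t[peaks[1]] - sweep.t[peaks[0]])


def phase_plot(
    sweep: Sweep,
    window: tuple[float, float] | None = None,
    settings: DetectionSettings = DEFAULT_DETECTION,
) -> tuple[np.ndarray, np.ndarray]:
    """(V, dV/dt) trajectory, optionally restricted to a time window (ms)."""
    dv = _dvdt(sweep, settings)
    if window is None:
        return sweep.v.copy(), dv
    lo, hi = window
    m = (sweep.t >= lo) & (sweep.t <= hi)
    return sweep.v[m], dv[m]


def sweep_features(
    sweep: Sweep, settings: DetectionSettings = DEFAULT_DETECTION
) -> SweepFeatures:
    """All per-sweep measures, with the first-AP-only policy applied."""
    peaks = detect_aps(sweep, settings)
    out = SweepFeatures(n_aps=count_aps(sweep, settings))
    if peaks.size == 0:
        return out
    try:
        first = ap_waveform_measures(sweep, int(peaks[0]), settings)
    except ThresholdNotFound:
        return out
    out.per_ap = [first]
    out.threshold = first.threshold
    out.latency = first.threshold_time - float(sweep.meta["onset_ms"])
    out.charge_transfer = charge_transfer(sweep, settings)
    if sweep.meta.get("protocol") == "ramp":
        out.rheobase = rheobase_ramp(sweep, settings)
        cm = sweep.meta.get("cm_pF")
        if cm:
            out.rheobase_norm = out.rheobase / float(cm)
    if peaks.size >= 2:
        out.first_isi = first_isi(sweep, settings)
    return out


_TABLE_COLUMNS = [
    "cell_id", "genotype", "drug", "protocol", "amplitude_pA",
    "n_aps", "latency", "first_isi", "threshold", "rheobase",
    "rheobase_norm", "charge_transfer", "peak_potential", "amplitude",
    "rise_time_10_90", "fall_time_90_10", "rising_speed", "duration_at_plus15",
]


def features_table(
    sweeps: list[Sweep], settings: DetectionSettings = DEFAULT_DETECTION
) -> pd.DataFrame:
    """One row per sweep with every AP/excitability measure (NaN = undefined)."""
    rows = []
    for sw in sweeps:
        f = sweep_features(sw, settings)
        ap = f.per_ap[0] if f.per_ap else None
        rows.append({
            "cell_id": sw.meta.get("cell_id", ""),
            "genotype": sw.meta.get("genotype", ""),
            "drug": sw.meta.get("drug", "none"),
            "protocol": sw.meta.get("protocol", ""),
            "amplitude_pA": sw.meta.get("amplitude_pA", math.nan),
            "n_aps": f.n_aps,
            "latency": f.latency,
            "first_isi": f.first_isi,
            "threshold": f.threshold,
            "rheobase": f.rheobase,
            "rheobase_norm": f.rheobase_norm,
            "charge_transfer": f.charge_transfer,
            "peak_potential": ap.peak_potential if ap else math.nan,
            "amplitude": ap.amplitude if ap else math.nan,
            "rise_time_10_90": ap.rise_time_10_90 if ap else math.nan,
            "fall_time_90_10": ap.fall_time_90_10 if ap else math.nan,
            "rising_speed": ap.rising_speed if ap else math.nan,
            "duration_at_plus15": ap.duration_at_plus15 if ap else math.nan,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
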