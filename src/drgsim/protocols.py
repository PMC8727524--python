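"""Current-clamp stimulus protocols.

Four standard waveform families used to characterize DRG neuron
excitability:

* ``step_family`` — depolarizing steps, 25–150 pA in 25 pA increments, 600 ms;
* ``ramp`` — a slow depolarizing ramp (0.1 pA/ms) preceded by a
  hyperpolarizing onset plateau;
* ``sag_family`` — hyperpolarizing steps, −50…−100 pA in −10 pA increments,
  600 ms, for HCN-mediated voltage sag;
* ``rin_pulse`` — a −50 pA, 500 ms pulse for input resistance.

Waveforms are piecewise linear, represented exactly by segments, so charge
and current values have closed forms. Every sweep starts and ends at the
0 pA baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: default pre-stimulus baseline (ms); feature extractors use its tail as the
#: baseline window
DEFAULT_PRE_MS = 200.0
#: default post-stimulus tail (ms)
DEFAULT_POST_MS = 100.0


@dataclass(frozen=True)
class Segment:
    """One linear piece of a current waveform: ``dur`` ms from ``i0`` to ``i1`` pA."""

    dur: float
    i0: float
    i1: float

    @property
    def charge_pC(self) -> float:
        return self.dur * (self.i0 + self.i1) / 2.0 / 1000.0


@dataclass(frozen=True)
class StimSweep:
    """A piecewise-linear injected-current waveform, right-continuous at
    segment boundaries (steps switch instantaneously)."""

    segments: tuple[Segment, ...]
    meta: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def duration(self) -> float:
        return float(sum(s.dur for s in self.segments))

    def _nodes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        starts = np.cumsum([0.0] + [s.dur for s in self.segments])[:-1]
        i0 = np.array([s.i0 for s in self.segments])
        slope = np.array(
            [(s.i1 - s.i0) / s.dur if s.dur > 0 else 0.0 for s in self.segments]
        )
        return starts, i0, slope

    def current(self, t: np.ndarray | float) -> np.ndarray:
        """Evaluate I(t) in pA; 0 outside the sweep."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts, i0, slope = self._nodes()
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(i0) - 1)
        out = i0[idx] + slope[idx] * (t - starts[idx])
        out[(t < 0) | (t > self.duration)] = 0.0
        return out

    def charge_pC(self) -> float:
        """Closed-form total charge of the waveform (pC)."""
        return float(sum(s.charge_pC for s in self.segments))


@dataclass(frozen=True)
class StimulusProtocol:
    name: str
    sweeps: tuple[StimSweep, ...]
    pre_ms: float
    post_ms: float

    def __post_init__(self) -> None:
        for k, sw in enumerate(self.sweeps):
            first, last = sw.segments[0], sw.segments[-1]
            if first.i0 != 0.0 or last.i1 != 0.0:
                raise ValueError(f"sweep {k} of {self.name} must start/end at 0 pA")
            if last.dur < 100.0:
                raise ValueError(f"sweep {k} of {self.name} needs a >=100 ms tail")


def _make_sweep(pre: float, stim: list[Segment], post: float, meta: dict) -> StimSweep:
    segs = [Segment(pre, 0.0, 0.0), *stim, Segment(post, 0.0, 0.0)]
    m = dict(meta)
    m.setdefault("onset_ms", pre)
    m["stim_end_ms"] = pre + sum(s.dur for s in stim)
    return StimSweep(tuple(segs), m)


def step_family(
    amplitudes_pA: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0, 125.0, 150.0),
    duration_ms: float = 600.0,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
) -> StimulusProtocol:
    """Depolarizing step family: 25–150 pA, 600 ms, 25 pA increments."""
    sweeps = tuple(
        _make_sweep(
            pre_ms,
            [Segment(duration_ms, a, a)],
            post_ms,
            {"protocol": "step_family", "amplitude_pA": a},
        )
        for a in amplitudes_pA
    )
    return StimulusProtocol("step_family", sweeps, pre_ms, post_ms)


def ramp(
    onset_pA: float = -50.0,
    onset_ms: float = 500.0,
    slope_pA_per_ms: float = 0.1,
    ramp_ms: float = 3000.0,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
) -> StimulusProtocol:
    """Ramp protocol: hyperpolarizing onset plateau, then a linear ramp.

    The ramp rises from the onset level at ``slope_pA_per_ms`` (default
    0.1 pA/ms) and, with the defaults, ends 300 pA above the onset (250 pA
    above baseline). The time at which the ramp current crosses 0 pA is
    recorded in the sweep metadata (``baseline_cross_ms``), as is the ramp
    start time (``ramp_start_ms``) used for the 2-s AP-counting window.
    """
    if slope_pA_per_ms <= 0:
        raise ValueError("ramp slope must be positive")
    end_pA = onset_pA + slope_pA_per_ms * ramp_ms
    if end_pA < 250.0:
        raise ValueError("ramp must exceed 250 pA above baseline")
    ramp_start = pre_ms + onset_ms
    meta = {
        "protocol": "ramp",
        "ramp_start_ms": ramp_start,
        "ramp_slope_pA_per_ms": slope_pA_per_ms,
        # time at which the rising ramp passes 0 pA (only meaningful for a
        # hyperpolarizing onset; equals ramp start otherwise)
        "baseline_cross_ms": ramp_start + max(0.0, -onset_pA) / slope_pA_per_ms,
    }
    stim = [
        Segment(onset_ms, onset_pA, onset_pA),
        Segment(ramp_ms, onset_pA, end_pA),
    ]
    # current drops back to baseline instantaneously at ramp end (tail segment)
    sw = _make_sweep(pre_ms, stim, post_ms, meta)
    return StimulusProtocol("ramp", (sw,), pre_ms, post_ms)


def sag_family(
    amplitudes_pA: tuple[float, ...] = (-50.0, -60.0, -70.0, -80.0, -90.0, -100.0),
    duration_ms: float = 600.0,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
) -> StimulusProtocol:
    """Hyperpolarizing step family for voltage sag: −50…−100 pA, 600 ms."""
    if any(a >= 0 for a in amplitudes_pA):
        raise ValueError("sag family amplitudes must be hyperpolarizing (< 0)")
    sweeps = tuple(
        _make_sweep(
            pre_ms,
            [Segment(duration_ms, a, a)],
            post_ms,
            {"protocol": "sag_family", "amplitude_pA": a},
        )
        for a in amplitudes_pA
    )
    return StimulusProtocol("sag_family", sweeps, pre_ms, post_ms)


def rin_pulse(
    amplitude_pA: float = -50.0,
    duration_ms: float = 500.0,
    repeats: int = 1,
    period_ms: float = 5000.0,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
) -> StimulusProtocol:
    """Input-resistance pulse: −50 pA for 500 ms (repeatable every 5 s)."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    stim: list[Segment] = []
    for r in range(repeats):
        stim.append(Segment(duration_ms, amplitude_pA, amplitude_pA))
        if r < repeats - 1:
            stim.append(Segment(period_ms - duration_ms, 0.0, 0.0))
    sw = _make_sweep(
        pre_ms,
        stim,
        post_ms,
        {"protocol": "rin_pulse", "amplitude_pA": amplitude_pA},
    )
    return StimulusProtocol("rin_pulse", (sw,), pre_ms, post_ms)


ALL_PROTOCOLS = {
    "step_family": step_family,
    "ramp": ramp,
    "sag_family": sag_family,
    "rin_pulse": rin_pulse,
}


def write_protocol(protocol: StimulusProtocol, directory: str | Path, dt_ms: float = 0.025) -> list[Path]:
    """Serialize each sweep's sampled current waveform as delimited text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, sw in enumerate(protocol.sweeps):
        t = np.arange(0.0, sw.duration + dt_ms / 2, dt_ms)
        df = pd.DataFrame({"time_ms": t, "i_pA": sw.current(t)})
        p = directory / f"{protocol.name}_sweep{k:02d}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths.append(p)
    return paths
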