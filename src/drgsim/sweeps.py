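"""Recorded current-clamp sweeps and their on-disk text format.

A :class:`Sweep` is one sampled (time, voltage, current) trace together with
the metadata needed by the feature extractors: which protocol produced it,
when the stimulus starts, and its amplitude (steps) or ramp geometry (ramps).

Units are fixed package-wide: time in ms, voltage in mV, current in pA,
conductance in nS, capacitance in pF (so pA/pF = mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: metadata keys serialized to the sidecar file (all optional except protocol)
_META_FLOAT_KEYS = {
    "onset_ms",
    "stim_end_ms",
    "amplitude_pA",
    "ramp_start_ms",
    "ramp_slope_pA_per_ms",
    "baseline_cross_ms",
    "dt_ms",
    "cm_pF",
    "seed",
}


@dataclass
class Sweep:
    """One current-clamp trace: uniform time base, voltage and injected current."""

    t: np.ndarray  # ms, uniform, strictly increasing
    v: np.ndarray  # mV
    i: np.ndarray  # pA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if not (self.t.shape == self.v.shape == self.i.shape):
            raise ValueError("t, v, i must have equal lengths")
        if self.t.size < 2:
            raise ValueError("sweep needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("t must be uniformly sampled")
        for name, arr in (("t", self.t), ("v", self.v), ("i", self.i)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return float(self.t[1] - self.t[0])

    @property
    def onset_ms(self) -> float:
        return float(self.meta["onset_ms"])

    def __len__(self) -> int:
        return self.t.size


def write_sweep(sweep: Sweep, path: str | Path) -> None:
    """Write a sweep as delimited text plus a ``<path>.meta`` sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_ms": sweep.t, "v_mV": sweep.v, "i_pA": sweep.i})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    lines = [f"{k}\t{v}" for k, v in sorted(sweep.meta.items())]
    Path(str(path) + ".meta").write_text("\n".join(lines) + "\n")


def read_sweep(path: str | Path) -> Sweep:
    """Read a sweep written by :func:`write_sweep` (or any file with the
    same three columns; metadata sidecar is optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta: dict = {}
    side = Path(str(path) + ".meta")
    if side.exists():
        for line in side.read_text().splitlines():
            if not line.strip():
                continue
            k, _, v = line.partition("\t")
            if k in _META_FLOAT_KEYS:
                meta[k] = float(v)
            else:
                meta[k] = v
    return Sweep(
        t=df["time_ms"].to_numpy(),
        v=df["v_mV"].to_numpy(),
        i=df["i_pA"].to_numpy(),
        meta=meta,
    )
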