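"""Passive membrane properties: RMP, input resistance, voltage sag and a
capacitance estimate.

Definitions:

* RMP — mean voltage over the zero-current baseline window (last 100 ms of
  the pre-stimulus segment);
* input resistance — (V_baseline − V_steady) / |I| from the −50 pA pulse,
  with V_steady averaged over the last 50 ms of the pulse; reported in MΩ;
* sag amplitude — V_steady − V_min during a hyperpolarizing step, where
  V_steady is the mean of the last 50 ms of the step and V_min the lowest
  voltage (excluding the first 2 ms after onset, to avoid resampling
  artifacts at the capacitive transient);
* sag ratio — 100 × sag amplitude / (V_baseline − V_min);
* capacitance estimate — a single-exponential fit to the first 40 ms of
  the pulse response; cm = τ_fit / Rin. The amplifier-based measurement the
  definition replaces is not reproducible offline, so this fit is the
  package's own estimator; HCN activation contaminates it slightly (the
  fit tolerance is documented in the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .sweeps import Sweep

__all__ = [
    "PassiveFeatures",
    "rmp",
    "input_resistance",
    "sag_metrics",
    "estimate_capacitance",
    "passive_table",
]

BASELINE_WINDOW_MS = 100.0
STEADY_WINDOW_MS = 50.0
SAG_BLANK_MS = 2.0
CM_FIT_WINDOW_MS = 40.0


@dataclass
class PassiveFeatures:
    rmp: float
    rin: float
    cm_est: float
    sag_amplitude: dict[float, float]  # keyed by step amplitude (pA)
    sag_ratio: dict[float, float]


def _baseline(sweep: Sweep) -> float:
    onset = sweep.onset_ms
    if onset < BASELINE_WINDOW_MS:
        raise ValueError(
            f"need a zero-current baseline of >= {BASELINE_WINDOW_MS} ms"
        )
    m = (sweep.t >= onset - BASELINE_WINDOW_MS) & (sweep.t < onset)
    return float(sweep.v[m].mean())


def rmp(sweep: Sweep) -> float:
    """Resting membrane potential: mean voltage of the baseline window (mV)."""
    return _baseline(sweep)


def input_resistance(sweep: Sweep) -> float:
    """Steady-state input resistance (MΩ) from a hyperpolarizing pulse."""
    onset = sweep.onset_ms
    end = float(sweep.meta["stim_end_ms"])
    amp = float(sweep.meta["amplitude_pA"])
    if amp >= 0:
        raise ValueError("input resistance uses a hyperpolarizing pulse")
    if end - onset < 2 * STEADY_WINDOW_MS:
        raise ValueError("pulse too short for a steady-state window")
    v_base = _baseline(sweep)
    m = (sweep.t >= end - STEADY_WINDOW_MS) & (sweep.t < end)
    v_steady = float(sweep.v[m].mean())
    return (v_base - v_steady) / abs(amp) * 1000.0  # mV/pA -> MΩ


def sag_metrics(sweep: Sweep) -> tuple[float, float]:
    """(sag amplitude mV, sag ratio %) of a hyperpolarizing step sweep."""
    onset = sweep.onset_ms
    end = float(sweep.meta["stim_end_ms"])
    amp = float(sweep.meta.get("amplitude_pA", 0.0))
    if amp >= 0:
        raise ValueError("sag is defined on hyperpolarizing sweeps")
    v_base = _baseline(sweep)
    m_min = (sweep.t >= onset + SAG_BLANK_MS) & (sweep.t < end)
    v_min = float(sweep.v[m_min].min())
    m_st = (sweep.t >= end - STEADY_WINDOW_MS) & (sweep.t < end)
    v_steady = float(sweep.v[m_st].mean())
    sag_amp = v_steady - v_min
    denom = v_base - v_min
    sag_ratio = 100.0 * sag_amp / denom if denom != 0 else math.nan
    return sag_amp, sag_ratio


def estimate_capacitance(sweep: Sweep, rin: float) -> float:
    """Capacitance (pF) from a monoexponential fit of the early pulse response.

    Fits ``V(t) = v_inf + (v0 - v_inf) * exp(-t/τ)`` over the first
    ``CM_FIT_WINDOW_MS`` of the pulse and returns ``cm = 1000 τ / Rin``
    (τ in ms, Rin in MΩ). The window is kept short so that slow HCN
    activation does not inflate the fitted time constant.
    Returns NaN when the fit does not converge.
    """
    onset = sweep.onset_ms
    m = (sweep.t >= onset) & (sweep.t <= onset + CM_FIT_WINDOW_MS)
    t = sweep.t[m] - onset
    v = sweep.v[m]

    def model(tt, v_inf, dv, tau):
        return v_inf + dv * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            t,
            v,
            p0=(float(v[-1]), float(v[0] - v[-1]), 10.0),
            maxfev=10000,
        )
    except RuntimeError:
        return math.nan
    v_inf, dv, tau = popt
    tau = abs(tau)
    # Pair τ with the resistance of the *fast* charging phase, taken from
    # the fit's own asymptote. The steady-state Rin of a sagging cell
    # includes slow HCN activation and would overestimate cm; for a purely
    # passive cell the two resistances coincide and cm = 1000 τ / Rin.
    amp = float(sweep.meta.get("amplitude_pA", 0.0))
    v_base = _baseline(sweep)
    r_early = (v_base - v_inf) / abs(amp) * 1000.0 if amp != 0 else rin
    if not math.isfinite(r_early) or r_early <= 0:
        r_early = rin
    return 1000.0 * tau / r_early


def passive_table(
    rin_sweeps: list[Sweep], sag_sweeps: list[Sweep]
) -> "pd.DataFrame":
    """Per-cell passive-feature table.

    ``rin_sweeps`` holds one rin-pulse sweep per cell; ``sag_sweeps`` all
    sag-family sweeps (grouped by ``cell_id``). Sag columns are suffixed by
    the absolute step amplitude: ``sag_amp_50`` … ``sag_ratio_100``. The
    per-sweep baseline is reported alongside (``sag_base_50`` …) so that
    sag comparisons can be checked against resting-potential offsets.
    """
    import pandas as pd

    by_cell: dict[str, dict] = {}
    for sw in rin_sweeps:
        cid = sw.meta.get("cell_id", "")
        rin = input_resistance(sw)
        by_cell[cid] = {
            "cell_id": cid,
            "genotype": sw.meta.get("genotype", ""),
            "drug": sw.meta.get("drug", "none"),
            "rmp": rmp(sw),
            "rin": rin,
            "cm_est": estimate_capacitance(sw, rin),
        }
    for sw in sag_sweeps:
        cid = sw.meta.get("cell_id", "")
        row = by_cell.setdefault(
            cid,
            {
                "cell_id": cid,
                "genotype": sw.meta.get("genotype", ""),
                "drug": sw.meta.get("drug", "none"),
                "rmp": math.nan,
                "rin": math.nan,
                "cm_est": math.nan,
            },
        )
        amp = abs(float(sw.meta["amplitude_pA"]))
        sag_amp, sag_ratio = sag_metrics(sw)
        key = f"{amp:.0f}"
        row[f"sag_amp_{key}"] = sag_amp
        row[f"sag_ratio_{key}"] = sag_ratio
        row[f"sag_base_{key}"] = _baseline(sw)
    return pd.DataFrame(list(by_cell.values()))
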