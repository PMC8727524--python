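"""Single-compartment conductance-based model of a small/medium DRG neuron.

The membrane equation is

    cm * dV/dt = -sum_c gbar_c * prod_g x_g^p_g * (V - E_c) + I_inj

with Hodgkin-Huxley-style gating variables relaxing as
``dx/dt = (x_inf(V) - x) / tau_x(V)``. The default cell carries five
conductances:

* passive leak,
* transient Na (m^3 h) supporting the action-potential upstroke,
* delayed-rectifier K (n^4) supporting repolarization and tonic firing,
* HCN (slow activation gate y times a fast inward-rectification gate r) —
  the hyperpolarization-activated cation conductance responsible for
  voltage sag and a major determinant of input resistance near rest,
* M-type K (Kv7; single slow gate p), a small sub-threshold brake.

The Fmr1-KO preset differs from wild type *only* in the HCN maximal
conductance (default 40% of WT), encoding the hypothesis that reduced HCN
function raises input resistance and thereby produces hyperexcitability.
Bath application of the channel blockers is emulated by zeroing the
targeted conductance: ZD7288 -> HCN, XE991 -> M current.

Integration is fixed-step: exponential Euler both for the gating variables
(Rush-Larsen update) and for the voltage (relaxation toward the
instantaneous steady state), which is unconditionally stable. The inner
loop is compiled with numba; gate steady states and update factors are
tabulated on a 0.05 mV grid over [-150, 80] mV and linearly interpolated.

Units: mV, ms, pA, nS, pF throughout (pA/pF = mV/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .protocols import StimulusProtocol
from .sweeps import Sweep

__all__ = [
    "Gate",
    "ChannelSpec",
    "NeuronParams",
    "SimConfig",
    "IntegrationError",
    "default_params",
    "make_genotype",
    "apply_drug",
    "simulate",
    "simulate_cohort",
    "resting_state",
    "DEFAULT_MODEL",
]

# voltage grid for rate tabulation
_V_LO, _V_HI, _V_STEP = -150.0, 80.0, 0.05

GENOTYPES = ("WT", "KO")
DRUGS = ("none", "ZD7288", "XE991")


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gate:
    """One gating variable: steady state, time constant (ms) and exponent."""

    name: str
    inf: Callable[[np.ndarray], np.ndarray]
    tau: Callable[[np.ndarray], np.ndarray]
    power: int = 1


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance: maximal value (nS), reversal (mV) and gating scheme."""

    name: str
    gbar: float
    erev: float
    gates: tuple[Gate, ...] = ()

    def validate(self) -> None:
        if self.gbar < 0:
            raise ValueError(f"{self.name}: gbar must be >= 0")
        v = np.arange(-120.0, 60.0, 0.5)
        for g in self.gates:
            inf = np.asarray(g.inf(v), dtype=float)
            tau = np.asarray(g.tau(v), dtype=float)
            if np.any(inf < 0) or np.any(inf > 1):
                raise ValueError(f"{self.name}.{g.name}: steady state outside [0, 1]")
            if np.any(tau <= 0):
                raise ValueError(f"{self.name}.{g.name}: non-positive time constant")
            if g.power < 1:
                raise ValueError(f"{self.name}.{g.name}: power must be >= 1")


@dataclass(frozen=True)
class NeuronParams:
    """Full description of one virtual cell."""

    cm: float
    channels: tuple[ChannelSpec, ...]
    label: str = "WT"
    drug: str = "none"

    def validate(self) -> None:
        if self.cm <= 0:
            raise ValueError("cm must be > 0")
        names = [c.name for c in self.channels]
        if names.count("leak") != 1:
            raise ValueError("exactly one leak channel required")
        if names.count("hcn") != 1:
            raise ValueError("exactly one HCN channel required")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.drug == "ZD7288" and self.channel("hcn").gbar != 0.0:
            raise ValueError("ZD7288 condition requires HCN gbar = 0")
        if self.drug == "XE991" and "km" in names and self.channel("km").gbar != 0.0:
            raise ValueError("XE991 condition requires KM gbar = 0")
        for c in self.channels:
            c.validate()

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_gbar(self, name: str, gbar: float) -> "NeuronParams":
        chans = tuple(
            replace(c, gbar=float(gbar)) if c.name == name else c
            for c in self.channels
        )
        return replace(self, channels=chans)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings."""

    dt: float = 0.025          # ms
    record_dt: float = 0.025   # ms, must be an integer multiple of dt
    v_init: float = -60.0      # mV
    settle_time: float = 1500.0  # ms of zero-current equilibration
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        ratio = self.record_dt / self.dt
        if self.record_dt < self.dt or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("record_dt must be an integer multiple of dt")
        if self.settle_time < 500.0:
            raise ValueError("settle_time must be >= 500 ms (HCN gating is slow)")

    @property
    def stride(self) -> int:
        return int(round(self.record_dt / self.dt))


# ---------------------------------------------------------------------------
# default kinetics
# ---------------------------------------------------------------------------

def _sig(v, vhalf, k):
    """Rising sigmoid for k > 0, falling for k < 0."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vhalf) / k))


def _bell(v, base, amp, vmid, width):
    """Bell-shaped time constant: base + amp / cosh((v - vmid)/width)."""
    return base + amp / np.cosh((np.asarray(v, dtype=float) - vmid) / width)


#: All tunable constants of the default cell. Conductances in nS, voltages
#: in mV, times in ms. ``ko_hcn_fraction`` scales HCN gbar in the KO preset.
#: ``e_leak = None`` balances the leak reversal so that the cell's resting
#: potential sits exactly at ``e_hcn``: at that voltage the HCN current is
#: zero for any gbar, so the genotypes share one resting potential by
#: construction and the HCN contrast acts purely through the shunting
#: (input-resistance) effect.
DEFAULT_MODEL: dict[str, float | None] = {
    "cm": 25.0,
    "g_leak": 0.56,
    "e_leak": None,
    "g_na": 400.0,
    "e_na": 60.0,
    "g_kdr": 200.0,
    "e_k": -90.0,
    "g_hcn_wt": 5.5,
    "e_hcn": -60.0,
    "g_km": 1.5,
    "ko_hcn_fraction": 0.4,
    # Na activation
    "na_m_vhalf": -26.5, "na_m_k": 6.0,
    # Na inactivation
    "na_h_vhalf": -42.0, "na_h_k": 6.0,
    "na_h_tau_base": 1.0, "na_h_tau_amp": 100.0, "na_h_tau_width": 15.0,
    # Kdr activation
    "kdr_n_vhalf": -27.0, "kdr_n_k": 10.0,
    "kdr_tau_base": 1.0, "kdr_tau_amp": 16.0,
    "kdr_tau_vmid": -50.0, "kdr_tau_width": 25.0,
    # HCN activation: weighted sum of a steep hyperpolarized component
    # (HCN4-like, carries the voltage sag and saturates by ~-85 mV) and a
    # shallow depolarized tail (HCN1-like, sub-threshold shunt up to ~-40 mV)
    "hcn_y1_vhalf": -68.0, "hcn_y1_k": 4.0,
    "hcn_y2_vhalf": -50.0, "hcn_y2_k": 10.0,
    "hcn_y2_frac": 0.4,
    # HCN time constant (bell)
    "hcn_tau_base": 60.0, "hcn_tau_amp": 350.0,
    "hcn_tau_vmid": -85.0, "hcn_tau_width": 20.0,
    # HCN instantaneous inward rectification: the open-channel current
    # vanishes at strongly depolarized potentials, so Ih shapes the
    # sub-threshold trajectory but not the spike itself
    "hcn_r_vhalf": -15.0, "hcn_r_k": 5.0, "hcn_r_tau": 0.2,
    # KM activation
    "km_p_vhalf": -35.0, "km_p_k": 10.0,
    "km_tau": 150.0,
}


def _hcn_inf(p: dict, v):
    """Composite HCN activation curve (mixed fast/slow subunit population)."""
    f = p["hcn_y2_frac"]
    return (1.0 - f) * _sig(v, p["hcn_y1_vhalf"], -p["hcn_y1_k"]) + f * _sig(
        v, p["hcn_y2_vhalf"], -p["hcn_y2_k"]
    )


def _steady_current_no_leak(p: dict, g_hcn: float, v: float) -> float:
    """Summed steady-state current (pA) of all gated channels at voltage v."""
    m = float(_sig(v, p["na_m_vhalf"], p["na_m_k"]))
    h = float(_sig(v, p["na_h_vhalf"], -p["na_h_k"]))
    n = float(_sig(v, p["kdr_n_vhalf"], p["kdr_n_k"]))
    y = float(_hcn_inf(p, v)) * float(_sig(v, p["hcn_r_vhalf"], -p["hcn_r_k"]))
    pm = float(_sig(v, p["km_p_vhalf"], p["km_p_k"]))
    return (
        p["g_na"] * m**3 * h * (v - p["e_na"])
        + p["g_kdr"] * n**4 * (v - p["e_k"])
        + g_hcn * y * (v - p["e_hcn"])
        + p["g_km"] * pm * (v - p["e_k"])
    )


def _balanced_e_leak(p: dict) -> float:
    """Leak reversal that places the gated-channel fixed point at e_hcn."""
    v = p["e_hcn"]
    # I_hcn(e_hcn) = 0, so gbar does not matter here
    return v + _steady_current_no_leak(p, 0.0, v) / p["g_leak"]


def _build_channels(p: dict, g_hcn: float) -> tuple[ChannelSpec, ...]:
    """Cached so that identical parameter values yield identical channel
    (and gate-function) objects; parameter sets then compare by == and the
    WT/KO presets share every gate. Only the HCN gbar is swapped in."""
    base = _build_channels_cached(tuple(sorted(p.items())))
    return tuple(
        replace(c, gbar=float(g_hcn)) if c.name == "hcn" else c for c in base
    )


@lru_cache(maxsize=128)
def _build_channels_cached(items: tuple) -> tuple[ChannelSpec, ...]:
    p = dict(items)
    g_hcn = p["g_hcn_wt"]
    na_m = Gate(
        "m",
        lambda v: _sig(v, p["na_m_vhalf"], p["na_m_k"]),
        lambda v: _bell(v, 0.05, 0.30, p["na_m_vhalf"], 15.0),
        power=3,
    )
    na_h = Gate(
        "h",
        lambda v: _sig(v, p["na_h_vhalf"], -p["na_h_k"]),
        lambda v: _bell(
            v, p["na_h_tau_base"], p["na_h_tau_amp"],
            p["na_h_vhalf"], p["na_h_tau_width"],
        ),
    )
    kdr_n = Gate(
        "n",
        lambda v: _sig(v, p["kdr_n_vhalf"], p["kdr_n_k"]),
        lambda v: _bell(
            v, p["kdr_tau_base"], p["kdr_tau_amp"],
            p["kdr_tau_vmid"], p["kdr_tau_width"],
        ),
        power=4,
    )
    hcn_y = Gate(
        "y",
        lambda v: _hcn_inf(p, v),
        lambda v: _bell(
            v, p["hcn_tau_base"], p["hcn_tau_amp"],
            p["hcn_tau_vmid"], p["hcn_tau_width"],
        ),
    )
    hcn_r = Gate(
        "r",
        lambda v: _sig(v, p["hcn_r_vhalf"], -p["hcn_r_k"]),
        lambda v: np.full_like(np.asarray(v, dtype=float), p["hcn_r_tau"]),
    )
    km_p = Gate(
        "p",
        lambda v: _sig(v, p["km_p_vhalf"], p["km_p_k"]),
        lambda v: np.full_like(np.asarray(v, dtype=float), p["km_tau"]),
    )
    e_leak = p["e_leak"] if p["e_leak"] is not None else _balanced_e_leak(p)
    return (
        ChannelSpec("leak", p["g_leak"], e_leak),
        ChannelSpec("na", p["g_na"], p["e_na"], (na_m, na_h)),
        ChannelSpec("kdr", p["g_kdr"], p["e_k"], (kdr_n,)),
        ChannelSpec("hcn", g_hcn, p["e_hcn"], (hcn_y, hcn_r)),
        ChannelSpec("km", p["g_km"], p["e_k"], (km_p,)),
    )


def default_params(genotype: str = "WT", overrides: dict | None = None) -> NeuronParams:
    """The deterministic (zero-variability) parameter set for a genotype."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    p = dict(DEFAULT_MODEL)
    if overrides:
        unknown = set(overrides) - set(p)
        if unknown:
            raise ValueError(f"unknown model overrides: {sorted(unknown)}")
        p.update(overrides)
    g_hcn = p["g_hcn_wt"] * (p["ko_hcn_fraction"] if genotype == "KO" else 1.0)
    params = NeuronParams(cm=p["cm"], channels=_build_channels(p, g_hcn), label=genotype)
    params.validate()
    return params


def make_genotype(
    genotype: str,
    variability_cv: float = 0.0,
    seed: int = 0,
    overrides: dict | None = None,
) -> NeuronParams:
    """Draw one virtual cell of a genotype.

    Cell-to-cell variability multiplies every maximal conductance and the
    membrane capacitance by independent lognormal factors with unit mean
    and the given coefficient of variation (cells vary in both channel
    density and size). Deterministic for a fixed seed.
    """
    if variability_cv < 0:
        raise ValueError("variability_cv must be >= 0")
    params = default_params(genotype, overrides)
    if variability_cv == 0:
        return params
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + variability_cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    factors = rng.lognormal(mean=mu, sigma=sigma, size=len(params.channels) + 1)
    chans = tuple(
        replace(c, gbar=c.gbar * f) for c, f in zip(params.channels, factors)
    )
    out = replace(params, channels=chans, cm=params.cm * factors[-1])
    out.validate()
    return out


_DRUG_TARGET = {"ZD7288": "hcn", "XE991": "km"}


def apply_drug(params: NeuronParams, drug: str) -> NeuronParams:
    """Emulate bath application of a blocker by zeroing its target conductance."""
    if drug == "none":
        return replace(params, drug="none")
    if drug not in _DRUG_TARGET:
        raise ValueError(f"unknown drug {drug!r}")
    out = replace(params.with_gbar(_DRUG_TARGET[drug], 0.0), drug=drug)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kernel(v, x, gbar, erev, gate_ptr, powers, xinf, edt, v0, inv_dv,
            istim, sweep_of, cm, dt, nt, stride, rec):  # pragma: no cover
    B = v.shape[0]
    nch = erev.shape[0]
    ngrid = xinf.shape[1]
    fmax = ngrid - 1.000001
    for k in range(nt):
        if k % stride == 0:
            j = k // stride
            for b in range(B):
                rec[b, j] = v[b]
        for b in range(B):
            vb = v[b]
            f = (vb - v0) * inv_dv
            if f < 0.0:
                f = 0.0
            elif f > fmax:
                f = fmax
            i0 = int(f)
            w = f - i0
            gtot = 0.0
            ge = 0.0
            for c in range(nch):
                geff = gbar[b, c]
                for gg in range(gate_ptr[c], gate_ptr[c + 1]):
                    xi = xinf[gg, i0] * (1.0 - w) + xinf[gg, i0 + 1] * w
                    ed = edt[gg, i0] * (1.0 - w) + edt[gg, i0 + 1] * w
                    xn = xi + (x[b, gg] - xi) * ed
                    x[b, gg] = xn
                    for _ in range(powers[gg]):
                        geff *= xn
                gtot += geff
                ge += geff * erev[c]
            iin = istim[sweep_of[b], k]
            if gtot > 1e-12:
                vt = (ge + iin) / gtot
                v[b] = vt + (vb - vt) * math.exp(-dt * gtot / cm[b])
            else:
                v[b] = vb + dt * iin / cm[b]
        if k % 200 == 199:
            for b in range(B):
                if not math.isfinite(v[b]):
                    return k, b
    j = nt // stride
    if j * stride == nt:
        for b in range(B):
            rec[b, j] = v[b]
    return -1, -1


class _CompiledModel:
    """Tables and index arrays for a family of cells sharing one channel
    skeleton (identical kinetics; per-cell gbar)."""

    def __init__(self, cells: Sequence[NeuronParams]):
        ref = cells[0]
        for c in cells:
            c.validate()
            if [ch.name for ch in c.channels] != [ch.name for ch in ref.channels]:
                raise ValueError("cohort cells must share the channel skeleton")
        self.cm = np.array([c.cm for c in cells])
        self.erev = np.array([c.erev for c in ref.channels])
        gates: list[Gate] = []
        ptr = [0]
        for ch in ref.channels:
            gates.extend(ch.gates)
            ptr.append(len(gates))
        self.gate_ptr = np.array(ptr, dtype=np.int64)
        self.powers = np.array([g.power for g in gates], dtype=np.int64)
        self.gates = gates
        self.grid = np.arange(_V_LO, _V_HI + _V_STEP / 2, _V_STEP)
        self.xinf = np.vstack([np.asarray(g.inf(self.grid), dtype=float) for g in gates]) \
            if gates else np.zeros((0, self.grid.size))
        self.taus = np.vstack([np.asarray(g.tau(self.grid), dtype=float) for g in gates]) \
            if gates else np.zeros((0, self.grid.size))
        self.gbar = np.array([[ch.gbar for ch in c.channels] for c in cells])

    def edt(self, dt: float) -> np.ndarray:
        return np.exp(-dt / self.taus) if self.taus.size else self.taus

    def steady_gates(self, v: float) -> np.ndarray:
        return np.array([float(g.inf(np.array([v]))[0]) for g in self.gates])

    def dvdt(self, v: np.ndarray, x: np.ndarray, iin: float = 0.0) -> np.ndarray:
        """Instantaneous dV/dt (mV/ms) for state arrays (B,), (B, n_gates)."""
        gtot = np.zeros_like(v)
        ge = np.zeros_like(v)
        for c in range(self.erev.size):
            geff = self.gbar[:, c].copy()
            for gg in range(self.gate_ptr[c], self.gate_ptr[c + 1]):
                geff = geff * x[:, gg] ** self.powers[gg]
            gtot += geff
            ge += geff * self.erev[c]
        return (ge - gtot * v + iin) / self.cm


def _settle(model: _CompiledModel, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrate all cells at zero current; returns (v, gates) state.

    The exponential-Euler fixed point coincides with the continuous-time
    fixed point for any dt, so settling may use a coarser step than the
    recording integration without changing the resting state.
    """
    B = model.gbar.shape[0]
    v = np.full(B, config.v_init)
    x = np.tile(model.steady_gates(config.v_init), (B, 1))
    dt_settle = 0.2
    nt = int(round(config.settle_time / dt_settle))
    istim = np.zeros((1, nt))
    sweep_of = np.zeros(B, dtype=np.int64)
    rec = np.empty((B, 1))
    bad_k, bad_b = _kernel(
        v, x, model.gbar, model.erev, model.gate_ptr, model.powers,
        model.xinf, model.edt(dt_settle), _V_LO, 1.0 / _V_STEP,
        istim, sweep_of, model.cm, dt_settle, nt, nt + 1, rec,
    )
    if bad_k >= 0:
        raise IntegrationError(
            f"non-finite state during settling at t={bad_k * dt_settle:.2f} ms (cell {bad_b})"
        )
    return v, x


def resting_state(params: NeuronParams, config: SimConfig | None = None) -> tuple[float, float]:
    """Settled resting potential (mV) and the residual |dV/dt| (mV/ms)."""
    config = config or SimConfig()
    config.validate()
    model = _CompiledModel([params])
    v, x = _settle(model, config)
    return float(v[0]), float(abs(model.dvdt(v, x)[0]))


def simulate_cohort(
    cells: Sequence[NeuronParams],
    stimulus: StimulusProtocol,
    config: SimConfig | None = None,
    cell_ids: Sequence[str] | None = None,
) -> list[list[Sweep]]:
    """Integrate every cell through every sweep of a protocol.

    Returns one list of :class:`Sweep` per cell, in sweep order. All cells
    are settled at zero current first, then all (cell, sweep) jobs are
    advanced in one compiled batch.
    """
    config = config or SimConfig()
    config.validate()
    model = _CompiledModel(cells)
    n_cells = len(cells)
    n_sweeps = len(stimulus.sweeps)
    if cell_ids is None:
        cell_ids = [f"cell{j:03d}" for j in range(n_cells)]

    v_rest, x_rest = _settle(model, config)

    durations = {sw.duration for sw in stimulus.sweeps}
    if len(durations) != 1:
        raise ValueError("all sweeps of a protocol must share a duration")
    dur = durations.pop()
    dt, stride = config.dt, config.stride
    nt = int(round(dur / dt))
    t_steps = np.arange(nt) * dt
    istim = np.vstack([sw.current(t_steps) for sw in stimulus.sweeps])
    if not np.all(np.isfinite(istim)):
        raise ValueError("stimulus contains non-finite currents")

    # batch layout: job index = cell * n_sweeps + sweep
    B = n_cells * n_sweeps
    v = np.repeat(v_rest, n_sweeps).copy()
    x = np.repeat(x_rest, n_sweeps, axis=0).copy()
    gbar = np.repeat(model.gbar, n_sweeps, axis=0)
    cm_arr = np.repeat(model.cm, n_sweeps)
    sweep_of = np.tile(np.arange(n_sweeps, dtype=np.int64), n_cells)
    n_rec = nt // stride + 1
    rec = np.empty((B, n_rec))
    bad_k, bad_b = _kernel(
        v, x, gbar, model.erev, model.gate_ptr, model.powers,
        model.xinf, model.edt(dt), _V_LO, 1.0 / _V_STEP,
        istim, sweep_of, cm_arr, dt, nt, stride, rec,
    )
    if bad_k >= 0:
        raise IntegrationError(
            f"non-finite state in sweep {bad_b % n_sweeps} of cell "
            f"{cell_ids[bad_b // n_sweeps]} near t={bad_k * dt:.2f} ms"
        )

    t_rec = np.arange(n_rec) * config.record_dt
    out: list[list[Sweep]] = []
    for j, cell in enumerate(cells):
        sweeps_j = []
        for s, stim_sweep in enumerate(stimulus.sweeps):
            meta = dict(stim_sweep.meta)
            meta.update(
                cell_id=cell_ids[j],
                genotype=cell.label,
                drug=cell.drug,
                dt_ms=config.record_dt,
                cm_pF=cell.cm,
                seed=config.seed,
            )
            sweeps_j.append(
                Sweep(
                    t=t_rec,
                    v=rec[j * n_sweeps + s],
                    i=stim_sweep.current(t_rec),
                    meta=meta,
                )
            )
        out.append(sweeps_j)
    return out


def simulate(
    params: NeuronParams,
    stimulus: StimulusProtocol,
    config: SimConfig | None = None,
    cell_id: str = "cell000",
) -> list[Sweep]:
    """Integrate a single cell through a protocol; one Sweep per stimulus sweep."""
    return simulate_cohort([params], stimulus, config, cell_ids=[cell_id])[0]
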