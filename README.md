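# drgsim

Virtual current-clamp electrophysiology of small/medium dorsal-root-ganglion
(DRG) sensory neurons, built to study one mechanism: **how a loss of HCN
("h-current") conductance raises input resistance and makes nociceptive
neurons hyperexcitable**, as observed in *Fmr1* knockout (KO) mice, a model
of Fragile X syndrome.

The package is aimed at cellular electrophysiologists and computational
neuroscientists who want a tested, reproducible pipeline for:

* a **conductance-based single-compartment DRG neuron** with leak,
  transient Na (m³h), delayed-rectifier K (n⁴), HCN (slow gate *y* with
  inward rectification) and M-type K (Kv7) currents, with WT and *Fmr1*-KO
  presets that differ **only** in the HCN maximal conductance
  (KO = 40 % of WT by default);
* the four standard **stimulus protocols**: depolarizing steps
  (25–150 pA, 600 ms, 25 pA increments), a slow ramp (0.1 pA/ms with a
  hyperpolarizing onset), hyperpolarizing sag steps (−50…−100 pA) and a
  −50 pA/500 ms input-resistance pulse;
* operational **AP feature extraction**: spike threshold at the
  dV/dt = 5 mV/ms crossing, latency, ramp rheobase (also
  capacitance-normalized), rheobase charge transfer, first inter-AP
  interval, per-step AP counts (2-s window on ramps), and spike-waveform
  measures (peak, amplitude, 10–90 % rise / 90–10 % fall time, maximal
  rising speed, duration at +15 mV);
* **passive properties**: RMP, steady-state input resistance, sag
  amplitude and sag ratio
  (100 % × sag amplitude ÷ (baseline − minimum)), and a capacitance
  estimate from an exponential fit;
* **2^−ΔΔCt qPCR quantification** of *Hcn1–4* relative to *Rpl13a*
  (technical replicates averaged per sample, group referencing to WT,
  t-test on ΔCt), plus a seeded synthetic Ct-table generator;
* **cohort statistics**: seeded virtual cohorts per genotype × drug
  condition, per-feature Student's t-tests (mean ± SEM, α = 0.05), and
  in-silico pharmacology — ZD7288 (HCN block) and XE991 (Kv7 block)
  emulated by zeroing the target conductance.

The membrane equation is

```
cm dV/dt = −Σ_c ḡ_c · Πx_g^p · (V − E_c) + I_inj,   dx/dt = (x_∞(V) − x)/τ_x(V)
```

in units mV / ms / pA / nS / pF, integrated with fixed-step exponential
Euler (40 kHz sampling by default; a numba kernel makes full cohorts run
in seconds). A deliberate design feature: the HCN reversal sits at the
resting potential, with the leak reversal balanced so that both genotypes
rest at exactly the same voltage — the genotype contrast is then a *pure
shunting* effect of the h-conductance, which is the mechanism the
experimental pharmacology isolates (the RMP itself is insensitive to HCN
block).

## Worked example

```python
import drgsim as d

for genotype in ("WT", "KO"):
    cell = d.make_genotype(genotype)          # deterministic preset (cv = 0)
    rin = d.input_resistance(d.simulate(cell, d.rin_pulse())[0])
    sag = d.sag_metrics(d.simulate(cell, d.sag_family())[0])
    ramp = d.sweep_features(d.simulate(cell, d.ramp())[0])
    print(f"{genotype}: Rin = {rin:.0f} MOhm, sag ratio(-50 pA) = {sag[1]:.1f} %, "
          f"ramp rheobase = {ramp.rheobase:.1f} pA, APs in 2 s = {ramp.n_aps}")
```

prints

```
WT: Rin = 218 MOhm, sag ratio(-50 pA) = 37.8 %, ramp rheobase = 45.7 pA, APs in 2 s = 35
KO: Rin = 412 MOhm, sag ratio(-50 pA) = 34.7 %, ramp rheobase = 32.7 pA, APs in 2 s = 40
```

— the KO preset has roughly double the input resistance, a smaller
voltage sag, a ~13 pA lower ramp rheobase and fires more ramp-evoked APs,
purely because its HCN conductance is reduced to 40 % of the WT value.
The qPCR side:

```python
from drgsim import qpcr

table = qpcr.generate_ct_table(noise_sd=0.15, seed=1)   # 3 bio x 3 tech
for gene, r in sorted(qpcr.fold_change(qpcr.delta_ct(table)).items()):
    print(f"{gene}: KO fold = {r.group_mean['KO']:.2f} +/- {r.group_sem['KO']:.2f}, "
          f"p = {r.p_value:.2g}")
```

```
Hcn1: KO fold = 0.43 +/- 0.01, p = 3.1e-05
Hcn2: KO fold = 1.05 +/- 0.05, p = 0.6
Hcn3: KO fold = 1.08 +/- 0.05, p = 0.26
Hcn4: KO fold = 0.32 +/- 0.01, p = 0.00011
```

recovering the generator's true folds (0.4, 1.0, 1.0, 0.35) from noisy
cycle thresholds. The full virtual experiment — cohorts of 20 cells per
genotype, all four protocols, per-feature t-tests and a text report — is
one call (or `drgsim run-all --out results/`):

```python
from drgsim import ExperimentConfig, run_experiment, comparison_report
res = run_experiment(ExperimentConfig(n_cells=20, seed=42))
print(comparison_report(res.comparisons))
```

The command-line interface (`drgsim simulate / extract / qpcr / report /
run-all`) reads and writes plain TSV sweeps (`time_ms`, `v_mV`, `i_pA`
plus a key-value metadata sidecar), so traces from other sources can be
fed through the same feature extractors.

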