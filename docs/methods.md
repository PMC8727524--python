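# Methods

## The model

A single-compartment membrane,

cm·dV/dt = −Σ_c ḡ_c·(Π_g x_g^{p_g})·(V − E_c) + I_inj,
dx/dt = (x_∞(V) − x)/τ_x(V),

with five conductances (units: mV, ms, pA, nS, pF; pA/pF = mV/ms):

| channel | gates | default ḡ (nS) | E (mV) | role |
|---|---|---|---|---|
| leak | — | 0.56 | balanced (≈ −53.9) | resting conductance |
| Na (transient) | m³h | 400 | +60 | spike upstroke |
| Kdr | n⁴ | 200 | −90 | repolarization, tonic firing |
| HCN | y·r | 5.5 (WT), 2.2 (KO) | −60 | sag, sub-threshold shunt |
| KM (Kv7) | p | 1.5 | −90 | slow sub-threshold brake |

cm = 25 pF. Gating steady states are sigmoids and time constants are
bell-shaped in voltage; every constant lives in
`drgsim.neuron_model.DEFAULT_MODEL` and can be overridden per run. The
KO preset differs from WT **only** in the HCN maximal conductance
(40 % of WT by default, `ko_hcn_fraction`). Bath ZD7288 and XE991 are
emulated by zeroing the HCN and KM conductances respectively. Kinetics
are taken as already at near-physiological temperature; no Q10 scaling.

The model aims at qualitative, not quantitative, fidelity. It was
calibrated (at zero cell-to-cell variability) to a fixed set of
behavioural targets: resting potential ≈ −60 mV and identical between
genotypes; WT silent at the 25 pA step but firing from 50 pA (step
rheobase 42.5 pA); KO step rheobase 25 pA, so that with 20 %
conductance scatter about half of KO cells fire at 25 pA and no WT cell
does; tonic firing with monotonically increasing AP counts up to
150 pA; clear voltage sag in WT, reduced in KO at every step of the sag
family; and a lower ramp rheobase / higher ramp AP count in KO.

### Design choices worth knowing about

**HCN reversal at the resting potential.** E_h is set to −60 mV and the
leak reversal is solved so that the HCN-free fixed point of all other
channels sits exactly at E_h. At that voltage the h-current is zero for
*any* conductance value, so WT and KO rest at the same potential by
construction, and blocking HCN does not move the RMP. This encodes the
hypothesis the pharmacology isolates: the h-conductance acts on
excitability through its *shunting* effect on input resistance, not
through a tonic depolarizing current. The physiological h-current
reversal is more depolarized (≈ −30 mV); pulling it to rest is a
deliberate idealization that removes the RMP confound entirely. (A
consequence that is visible in the XE991 condition: removing KM shifts
the rest away from E_h, and a small genotype RMP offset reappears.)

**Composite HCN activation.** The activation curve is a weighted sum of
a steep hyperpolarized sigmoid (midpoint −68 mV, slope 4; saturating by
≈ −85 mV) and a shallow depolarized tail (midpoint −50 mV, slope 10;
weight 0.4). The steep component carries the voltage sag — its
saturation is what keeps the sag *ratio* larger in WT even though KO
cells hyperpolarize further for the same current. The shallow tail
keeps a fraction of the conductance active through the whole
sub-threshold range, which is what makes the slow-ramp rheobase depend
on the HCN level (on a 0.1 pA/ms ramp the gate is quasi-static, so only
conductance present near threshold can matter). A mixed HCN1/HCN4
channel population motivates the two components. A fast
inward-rectification gate (r, midpoint −15 mV, τ = 0.2 ms) shuts the
open-channel current at depolarized potentials, so the h-current shapes
the sub-threshold trajectory but not the spike itself.

**Slow sodium inactivation.** τ_h ≈ 100 ms below threshold. During the
few milliseconds it takes a step to drive the cell to threshold the
inactivation state is effectively frozen, which decouples the spike
waveform (peak, rise/fall, duration) from how fast the approach was —
i.e. from the genotype. With fast inactivation the (wanted) threshold
difference would leak strongly into the (unwanted) waveform
differences.

**Cell-to-cell variability.** Every maximal conductance *and* the
capacitance is multiplied by an independent unit-mean lognormal factor
(CV 0.2 by default); kinetics are shared. Size variation is included
because an estimator applied to a cohort with literally identical
capacitance everywhere has almost no between-cell variance, and any
systematic estimator bias — however small — then dominates a t-test;
real cohorts scatter in size, and identical size distributions across
genotypes preserve the expected "no capacitance difference" result.

## Numerics

Fixed-step integration, dt = 0.025 ms, recorded at the same rate
(40 kHz). Gates use the exponential (Rush–Larsen) update; the voltage
uses an exponential update toward its instantaneous steady state
(V_target = (Σ gE + I)/Σ g, relaxation time cm/Σ g), which is
unconditionally stable. Gate steady states and update factors are
tabulated on a 0.05 mV grid over [−150, 80] mV and linearly
interpolated inside a numba kernel; a cohort × sweep batch integrates
in one call. Cells are settled at zero current for 1500 ms before every
protocol (the exponential update's fixed point is dt-independent, so
settling uses a coarser step); the settled state satisfies
|dV/dt| < 0.01 mV/ms. Halving dt changes input resistance, sag ratio,
rheobase, thresholds and AP counts by less than every test tolerance
(most digits do not move), and a 10×-finer reference trace stays within
0.5 mV outside spike upstrokes. Identical inputs give bit-identical
traces.

## Feature extraction

dV/dt is a central difference on the recorded grid, unsmoothed by
default (the synthetic traces are noise-free; a moving-average option
exists for imported data). APs are voltage peaks above −10 mV with
≥ 20 mV prominence and ≥ 1 ms separation. The threshold is the *last*
upward crossing of dV/dt = 5 mV/ms between the preceding voltage
minimum and the peak, linearly interpolated; threshold, latency,
rheobase and charge transfer always come from the first AP of a sweep.
"Rising speed" is the maximal upstroke dV/dt; amplitude is peak −
threshold. Ramp AP counts use a 2-s window anchored at the start of the
rising ramp segment. Baseline windows are the last 100 ms before
stimulus onset; steady-state windows the last 50 ms of a step; the sag
minimum search skips the first 2 ms after onset.

Two operational caveats surfaced by the pipeline (both visible in the
per-step tables): at steps ≥ 100 pA, passive charging of a
high-resistance cell alone can exceed 5 mV/ms, so the threshold
definition degrades for the KO preset at strong drive — group
comparisons therefore use the 50 and 75 pA steps; and the capacitance
estimate pairs the fitted charging τ with the resistance taken from the
fit's own early asymptote rather than the steady-state Rin, because the
steady-state value of a sagging cell includes slow HCN activation and
would inflate the estimate by tens of percent (for a passive cell the
two resistances coincide and cm = 1000·τ/Rin exactly; with the default
active cell the estimate is within ~7 % of truth).

## Protocols

As in the standard experimental designs: steps 25–150 pA × 600 ms
(25 pA increments); sag steps −50…−100 pA × 600 ms (−10 pA increments);
−50 pA × 500 ms Rin pulse (repeatable every 5 s); ramp at 0.1 pA/ms.
The ramp's unspecified geometry defaults to a −50 pA, 500 ms
hyperpolarizing onset plateau (matching the Rin pulse magnitude)
followed by 3000 ms of ramp (reaching 250 pA above baseline), with a
200 ms pre-stimulus baseline and ≥ 100 ms tail on every sweep. All
waveforms are piecewise linear with closed-form charge.

## Statistics

Two-sample Student's t-test (pooled variance; Welch behind a flag),
two-sided, α = 0.05, no multiple-testing correction; groups summarized
as mean ± SEM. Degenerate inputs follow fixed conventions (zero
variance with equal means → p = 1; unequal → p = 0). Default cohorts
are n = 20 cells per genotype × drug condition, CV 0.2, master seed 42;
per-cell seeds are drawn from one seeded generator in a fixed order, so
a config fully determines every output. Drug conditions simulate fresh,
independent cohorts (no within-cell washout). The simulator is
noiseless, so each condition is one trial per cell.

## qPCR quantification

ΔCt per sample = mean-of-technical-replicates Ct(target) − Ct(Rpl13a);
ΔΔCt references each sample to the *mean* ΔCt of the WT group, so the
WT geometric-mean fold is exactly 1 (and at zero noise every WT fold is
exactly 1). The group test runs on ΔCt values, not folds (folds are
log-normal); the fold SEM is computed across per-sample folds. The
synthetic generator shifts KO target baselines by −log2(true fold) and
adds Gaussian cycle noise (default SD 0.15, 3 biological × 3 technical
replicates); its default truth (Hcn1 0.4, Hcn4 0.35, Hcn2 = Hcn3 = 1)
is illustrative, not a measured value.

## What the synthetic data does and does not emulate

The generator reproduces the *structure* of the real experiments —
protocols, sampling rate, genotype contrast, conductance scatter,
replicate layout — but not recording noise, electrode/bridge artifacts,
junction-potential offsets, channel stochasticity, rundown, or
cell-size/IB4 heterogeneity beyond a lognormal capacitance factor.
Passing cohort tests therefore shows that the *mechanism and pipeline*
behave as expected, not that real recordings would give these exact
numbers. One concrete consequence: in a noiseless cohort the t-test
resolves arbitrarily small systematic differences. A genuine threshold
hyperpolarization in KO mechanically raises KO's spike amplitude
(measured from threshold) and slightly raises the overshoot, so these
two waveform comparisons come out significant here (≈ 0.7 and ≈ 2 mV at
75 pA) even though biological variance would swamp them in real data;
the other waveform measures, RMP and capacitance are non-significant as
expected. The corresponding acceptance checks are left failing rather
than masked, and this is the documented reason.

## Problem sizes

Default runs use 20 cells per group (stable desk-scale power for the
effect sizes above), 200 seeded repeats for the qPCR recovery rate, and
the full four-protocol battery per cell; a complete two-genotype
experiment with statistics takes a few seconds on one CPU after the
kernel is compiled.

## Known limitations

Single compartment (no axon initial segment or morphology); no
temperature scaling; the HCN activation curve and reversal are
phenomenological calibrations, not fits to voltage-clamp data; ramp
"threshold" differences are small and not statistically resolved in
this model (step thresholds are); cell "size" has no simulator analog
beyond the capacitance factor. The 25 pA firing fraction of a 20-cell
KO cohort has an intrinsic binomial spread of ±11 percentage points
around its calibrated 49 % population value — single-seed values
between 40 and 60 % are typical but excursions occur.
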