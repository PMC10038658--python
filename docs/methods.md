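# Methods

## Gating model

The channel is a reversible six-state birth–death chain
C1–C2–C3–C4–C5–O6 with one conducting state. Each directed edge carries a
rate law k(V, P) = k0·exp(kv·V + kp·P), with V the membrane potential
(mV), P the pipette pressure (mmHg; suction is negative). Default
parameters:

| quantity | value | units | role |
|---|---|---|---|
| k0,activation | 800 | s⁻¹ | per-subunit forward rate, C1..C5 |
| k0,deactivation | 0.1 | s⁻¹ | per-subunit backward rate |
| k0,opening | 70 | s⁻¹ | C5→O6 |
| k0,closing | 55 | s⁻¹ | O6→C5 |
| kv,activation | +0.055 | mV⁻¹ | voltage sensitivity, forward |
| kv,deactivation | −0.055 | mV⁻¹ | voltage sensitivity, backward |
| kp (forward / backward) | −0.05 / −0.005 | mmHg⁻¹ | pressure sensitivity |

Activation multiplicities are the standard four-identical-subunit
aggregation: 4:3:2:1 on the forward steps, 1:2:3:4 on the backward steps.
The pore step is voltage-insensitive in both variants; this is what caps
the saturating open probability at k0,opening/(k0,opening+k0,closing) =
70/125 = 0.56 instead of letting it approach 1. The voltage sensitivities
are interpreted per millivolt: per-volt values would make voltage
dependence negligible over the −100..−20 mV working range, whereas per-mV
values put the per-subunit activation midpoint near −82 mV and the
overall activation midpoint in the −60 mV region, consistent with the
macroscopic and single-channel behaviour the model is meant to emulate.

The **MSA** variant places kp on all eight activation/deactivation edges;
the **MSO** variant places it only on the pore edge. At P = 0 the two are
identical. Their separating signatures, both machine-checked: MSA shifts
the activation midpoint under suction but leaves the maximum Po invariant
(spread < 1e−6 across 0..−50 mmHg); MSO raises and steepens the curve,
with Po_max(P) following the two-state closed form
kO·e^(kpO·P) / (kO·e^(kpO·P) + kC·e^(kpC·P)) to < 1e−4.

Numerics: stationary occupancies use the exact birth–death product
formula evaluated in log space (detailed balance holds by construction;
πQ = 0 is asserted in tests); transient occupancies use per-segment
matrix exponentials (scipy's scaling-and-squaring) with conditions
switching instantaneously at segment boundaries; rate-law exponents are
capped at 700 so extreme inputs saturate to a large finite rate instead
of overflowing (with a logged warning).

## Resting-potential scatter

Cell-attached recordings cannot measure the cell's resting potential, so
the true membrane potential differs from the commanded one by a
cell-specific offset. The offset is modeled as Gaussian across cells,
default mean +20 mV, sd 12 mV, acting as a hyperpolarizing shift:
V_true = V_command − offset. The apparent Po-vs-command curve is then
the Gaussian-weighted average Po(Vcmd) = ∫ Po(Vcmd − v)·N(v) dv, computed
by 64-point Gauss–Hermite quadrature (refined automatically if a 96-point
rule disagrees by more than 1e−6). A positive mean shifts the apparent
curve toward positive command voltages and the sd makes it shallower —
the observed relationship between single-channel Po curves and whole-cell
activation. Both parameters are configuration keys, fitted from
zero-pressure data by `fit_resting_potential` when a measured cohort is
analyzed.

## Simulator

State trajectories are sampled exactly (Gillespie) with
piecewise-constant rates; at segment boundaries the exponential clock
restarts, which is exact by memorylessness. Initial states are drawn from
the stationary distribution at the holding conditions. Rendering maps
trajectories to currents with a linear ohmic unitary current, γ = 6.7 pS
and E_rev = +55 mV by default — chosen jointly to reproduce single-channel
amplitudes of ≈1 pA at −80 mV, 0.77 pA at −60 mV and ≈0.5 pA at −20 mV.
Samples are box-car integrals over each tick (sub-sample dwells weight
the amplitude), white Gaussian noise is pre-scaled so its post-filter sd
equals the configured value (0.25 pA default), and signal plus noise pass
through a causal 4-pole Bessel low-pass (bilinear transform; Bessel being
the electrophysiology standard), 5 kHz at acquisition. Analysis refilters
to 0.5 kHz. The driving force uses the commanded voltage (matching how
amplitudes are reported in cell-attached work); the resting offset acts
on gating only. Capacitance transients, leak, pressure-clamp settling and
multi-channel patches are not modeled.

## Idealization and Po estimation

Two cross-checked estimators operate on magnitude-inverted traces (open
level positive). Half-amplitude thresholding classifies a sample open iff
it exceeds half the open amplitude (ties keep the previous level) and
collapses runs into dwells. The all-point histogram (0.2 pA bins for
single sweeps, 0.05 pA for pooled data; areas normalized to 1) is fitted
with a sum of two Gaussians plus a constant baseline by unweighted least
squares on bin heights; Po is the open component's relative weight
A2/(A1+A2). The open mean is parametrized as closed mean + Δ with Δ
bounded away from zero — and, when an expected amplitude is supplied
(from the two-Gaussian fit of richer data or from γ·(V−E_rev)), bounded
to 0.4–2.5× that amplitude with the closed mean anchored near its
initialization and the fit grid padded with empty bins over the
admissible open range. These constraints keep the fit well-posed on
one-level (all-closed) data, where the open weight must pin near zero. A
raw-sample EM backend provides an independent second route (agreement
within 0.02 Po in tests). Paired pressure responses are the difference of
per-half open fractions within the same sweep, with 2/cutoff after each
segment boundary excluded as filter settle time.

Note one model behaviour that matters when reading paired ΔPo values: on
the standard 400 ms ladder the channel is still activating between the
two 200 ms halves, so ΔPo contains a positive activation-drift component
in addition to the pressure effect. The drift is physical (episodes start
from the −120 mV holding distribution) and is retained in the default
study; analyses that need near-stationary halves (e.g. comparing a
background channel with a weakly mechanosensitive pore mutant) use the
4 s-step ladder timing, where the drift fraction is negligible.

## Dwell analysis and missed-event correction

At saturating voltages deactivation is negligible and gating reduces to
the two-state C5↔O6 flicker; only −20 mV fits are interpreted as pore
rates. The first and last dwell of every trace are discarded (truncated
by the window); traces with fewer than three dwells contribute nothing
and are counted, since this selection enriches high-Po traces and biases
rates slightly upward — the bookkeeping is reported with every fit.

Band-limited recordings miss events shorter than the dead time td,
default 0.3/cutoff (0.6 ms at 0.5 kHz) — half the filter's 10–90% rise
time, the conventional detectable-event limit; td is a configuration knob
recorded in every output. Dead-time imposition merges any dwell shorter
than td into its flanking opposite-class dwells, greedily left-to-right
(deterministic; short dwells at sequence edges are dropped and counted).
The estimator maximizes a shifted-exponential likelihood whose means obey

    E[apparent open]   = e^(kO·td)·(td + 1/kC) + (e^(kO·td) − 1)/kO − td
    E[apparent closed] = e^(kC·td)·(td + 1/kO) + (e^(kC·td) − 1)/kC − td

which is first-order-correct in td for both missed-gap concatenation and
the absorption of short measured-class dwells, and was validated against
a brute-force oracle (simulate exponential dwells, impose td, compare).
At td = 0 it reduces to the plain exponential MLE. Standard errors come
from the numerically observed information in log-rate space. Constraints:
`fixed_ratio` pins kO/(kO+kC) to an independently measured Po;
`fit_pressure_series` fits k(P) = k(0)·e^(kp·P) jointly across pressure
conditions, optionally pinning the total |kp_open|+|kp_close|.

## Macroscopic analysis

Peak currents are step-window extrema (first two samples skipped as the
unmodeled capacitive instant), reported in pA and pA/pF. The activation
fit uses I(V) = (V−E_rev)·G_max / (1 + exp((V_half−V)/δV)) — the sign
convention in which positive tabulated slopes describe a conductance that
rises with depolarization; the literal printed-order convention is also
selectable. Availability uses 1/(1 + exp((V_half−V)/δV)), in which the
conventional negative tabulated slope describes availability falling with
depolarization; fits with a positive slope (rising data) are flagged.
Kinetics fits are single- or bi-exponential with amplitudes initialized
by linear least squares over a small tau grid (robust to sign patterns);
constant traces are flagged unidentifiable. Whole-cell synthetic currents
are N independent channels (default 500) × unitary current × the
deterministic open-occupancy time course; fluid shear has no printed
tension calibration and is mapped to an effective pressure (default
−10 mmHg equivalent). The step-1 duration of the two-pulse protocol is
not specified by the emulated experiments; 500 ms was chosen, long
relative to the ≈8–19 ms activation time constants.

## Model discrimination

`compare()` consumes a Po table keyed by (cell, V, P). The
resting-potential model is fitted once on the zero-pressure rows and
shared by both variants, so the comparison is not confounded by it. Each
variant's pressure sensitivity is then refitted by least squares.
Stationary Po depends only on the per-edge difference kp_forward −
kp_backward, so by default kp_forward is freed with kp_backward held at
its default; freeing both is possible but only their difference is
identified. Variants are ranked by total residual sum of squares with
equal weight per (V, P) cell; a per-voltage paired two-tailed t-test on
within-cell ΔPo (implemented directly from the mean and sd of paired
differences) is included as reporting plumbing. Single-pressure data are
flagged non-discriminable.

## Synthetic studies: scale and scope

The default study is 12 cells × 150 ladder sweeps per cell at −10 mmHg —
the scale at which the paired t-test at −60 mV is reliably powered, in
line with cohorts of roughly 7–21 cells in comparable experiments. The
dwell-recovery study uses 20 patches × 120 sweeps of 500 ms at −20 mV;
the discrimination study uses 40 cohorts of 8 cells × 100 sweeps
(generated as exact state-path occupancies, without the rendering chain,
whose unbiasedness the idealization tests establish separately). Studies
are fully reproducible: every random draw derives from the master seed,
and `generate_study` writes a manifest from which the TSV traces
regenerate byte-identically.

What passing tests on these studies do and do not show: the generator
realizes the model's own assumptions (one channel per patch, exponential
dwells, stationary Gaussian noise, instantaneous pressure steps, no
inactivation, drift-free baseline). Success on synthetic data therefore
validates the estimators and the discrimination logic under those
assumptions; it does not certify performance against rig artifacts absent
from the model — seal drift, pressure-clamp settling, residual
inactivation, endogenous channel contamination — and two-Gaussian Po
estimates remain intrinsically fragile on data containing a single level.

## Known limitations

* The missed-event correction is first order; chained double-short merges
  are second-order effects it ignores (no exact Hawkes–Jalali–Colquhoun
  likelihood), matching the scope of the correction it models.
* The six-state dwell likelihood is not implemented — only the truncated
  two-state model is fitted, valid at saturating voltages.
* Edge-dwell discarding biases dwell means low and fitted rates a few
  percent high in finite sweeps; this is inherent to the procedure and
  reported, not corrected.
* Mixed MSA+MSO models and Bayesian or information-criterion model
  selection are out of scope; discrimination is RSS ranking.
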