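# Methods

`hergsim` has two stages: a voltage-clamp stage that synthesizes and
analyses whole-cell Kv11.1 (hERG) recordings, and a ventricular-myocyte
stage that propagates the measured channel defect into human cellular
electrophysiology. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data can and
cannot show.

## Channel model

The Kv11.1 current is modelled as a two-gate Hodgkin–Huxley system,

I(V, t) = g_max · a(t) · h(t) · (V − E_K),

with an activation gate `a` and an availability gate `h` (1 −
inactivation), each relaxing mono-exponentially toward a Boltzmann
steady state:

a∞(V) = 1 / (1 + exp(−(V − V₁/₂,act)/k_act)),
h∞(V) = 1 / (1 + exp(+(V − V₁/₂,inact)/k_inact)).

This structure was chosen because the experiments characterize exactly
four kinetic processes, each with a single exponential: activation,
deactivation (the a-gate moving in either direction), and inactivation,
recovery from inactivation (the h-gate). No Markov scheme is attempted;
inward rectification is emergent from the fast, voltage-dependent
h-gate rather than from an instantaneous rectification factor. The
time constant at a given voltage is direction-aware: the a-gate uses
the activation τ-curve when a∞(V) > a and the deactivation curve
otherwise, analogously τ_inact/τ_rec for the h-gate. This mirrors how
the four processes are measured (each protocol isolates one direction)
at the cost of a small non-physicality (a single ODE would have one τ
per voltage).

Under a piecewise-constant command voltage each gate has the closed
form g(t+Δ) = g∞ − (g∞ − g)·e^(−Δ/τ), so sweeps are synthesized
exactly, with no solver error; tests verify agreement with a 1-µs
Euler integration and an independent stiff ODE solution to < 0.1%.

**Parameters.** Each variant (WT, S1021Qfs*98, A228V, and the
compound S1021Qfs*98/A228V) carries the measured medians: V₁/₂ and k
of both Boltzmann curves, and one anchored time constant per process
(τ_act at +30 mV, τ_deact at −90 mV, τ_inact at 0 mV, τ_rec at −80
and −20 mV). Full τ(V) curves are monotone shape-preserving (PCHIP in
log τ) interpolants through anchor sets that extend the measured
anchors with the canonical hERG voltage dependence (activation
accelerates and inactivation accelerates with depolarization;
deactivation slows; recovery slows toward less negative voltages),
clamped outside the anchor range. τ_rec at −120 mV is set fast enough
(0.25 ms in WT) that the 2-ms conditioning step at −120 mV achieves
full recovery — the design rationale of the protocol itself. Variant
curves are the WT shape rescaled through the variant's measured
anchors. These anchor sets are package choices constrained by single
printed values; only the anchored voltages are quantitative claims.

`E_K` defaults to the Nernst potential of the recording solutions
(4.8 mM bath / ~125 mM pipette K⁺ at 37 °C), −87.1 mV. Command
voltages are used as printed; no junction-potential correction
(~15 mV) is applied, since whether the reported voltages were
corrected is not stated. `g_max` per group is calibrated in one
division (the model is linear in conductance) so the simulated
activation-protocol tail at the anchored voltage equals the measured
median tail current.

**Compound heterozygote.** A literal 1:1 conductance mixture of the
two parent channels would give a mean tail of ~217 pA, whereas the
measured compound tail is 111.8 pA — the frameshift subunit is
dominant-negative, which no linear mixture can produce. The compound
group therefore uses its own measured parameter column; the 1:1
mixture model (trace = weighted sum of independently gating
populations) is available in `simulate_sweep_mixture` and is exact by
linearity.

## Protocols

Five protocols over four schedules, holding at −80 mV:

* **activation**: 2-s steps −50…+50 mV (10-mV), 2-s tail at −50 mV, 0.2 Hz;
* **deactivation**: 2-s prepulse +50 mV, 6-s steps 0…−120 mV, 0.25 Hz;
* **inactivation (τ)**: 500-ms prepulse +50 mV, 2 ms at −120 mV
  (full recovery without deactivation), 500-ms test +60…−60 mV, 0.2 Hz;
* **steady-state inactivation** and **recovery** share one schedule:
  500→480-ms prepulse +50 mV, an interpulse −120…+60 mV growing from
  2 ms in 2-ms steps (gating slows at less negative voltages), 500-ms
  test at +50 mV, 0.2 Hz.

The printed deactivation timing (8-s sweeps at 0.25 Hz) cannot fit its
own period; when a sweep overruns the nominal period the protocol
class inserts a minimum 2-s holding interval at −80 mV instead.

## Analysis pipeline

Tail currents are the signed extremum within 100 ms of the
repolarizing-step onset. Boltzmann fits are free in all four
parameters (A1, A2, V₁/₂, k > 0) unless normalized mode pins the
plateaus. Exponential fits exclude one settling sample after a step;
decays riding on a much slower drift (the inactivating test pulse,
where the a-gate deactivates over hundreds of ms) are refined to a
window of ~10 fitted time constants.

Two analyses compensate a structural bias with measured quantities
from the same cell: during the brief interpulse the current is the
product of the fast-recovering h-gate and the slowly deactivating
a-gate, so a raw single-exponential fit returns a rate near
1/τ_rec + 1/τ_deact (4–9% fast here). `recovery_tau` multiplies the
interpulse trace by exp(+t/τ_deact(V)) using the deactivation
protocol's fitted τ, which restores a pure exponential in τ_rec; the
steady-state-availability points are likewise divided by the predicted
surviving activation exp(−d/τ_deact(V)). With this, a noiseless cell
returns every generating parameter to within 1% through the full
protocol pipeline (the residual being genuine finite-protocol
distortion, e.g. incomplete equilibration at ±extreme voltages).
Without compensation, τ_rec(−80) reads ~9% low. Exact (1e-6) recovery
is only possible for fits applied to data generated directly from the
fitted functional form, and is tested there.

Group statistics mirror the experimental analysis: median (Q1, Q3)
with type-7 quartiles, Kruskal–Wallis with tie correction, Dunn's
pairwise z-tests with Bonferroni adjustment over all pairs (the
multiplicity flavour of "Dunn's post-test" is not stated; classical
Dunn–Bonferroni is used). Currents are reported as amplitudes, never
densities.

## Synthetic cohorts

Each virtual cell perturbs the group medians: log-normal multipliers
for positive parameters (time constants, slope factors, conductance,
C_m, R_a) and additive Gaussian shifts for the signed half-activation
voltages. Spreads are derived from the measured interquartile ranges
(σ = ln(Q3/Q1)/1.349 multiplicative, sd = (Q3−Q1)/1.349 additive), so
the cohorts reproduce the printed IQRs by construction. Parameters
are drawn independently per cell (no covariance structure is
reported). Recording noise is additive white Gaussian (default 5 pA
RMS — a typical whole-cell noise floor; the study does not print one),
added after simulation. Not emulated: capacitive transients, series-
resistance error, leak currents, rundown, cell-to-cell parameter
correlations. Passing tests therefore show pipeline correctness and
statistical power at the measured spreads, not robustness to those
artefacts.

Default sampling: 1 ms for the slow protocols (activation,
deactivation), 0.05 ms for the fast ones (inactivation, recovery),
balancing fidelity (τ down to ~0.25 ms) against volume.

## Ventricular myocyte stage

The human ventricular action-potential model is the published
41-variable dynamic formulation (O'Hara–Rudy), midmyocardial
parameter set, reimplemented in full with three config-isolated
modifications:

* `p_ca_scale` = 0.8 baseline (the 20% L-type Ca²⁺-permeability
  reduction that calibrates midmyocardial APD₉₀ to the experimental
  range);
* `g_kr_scale` = 0.31 for the variant cell (the measured ~69% current
  loss, applied as a pure conductance scale since gating was
  unchanged);
* a β-adrenergic (1 µM isoproterenol) effect set.

Validation: with the baseline calibration the model reproduces the
study's own steady-state values — APD₉₀ 324.5 ms control vs printed
324 ms, 554.9 ms vs printed 555 ms at g_Kr×0.31 (71.0% prolongation) —
and the published resting state (−87.8 mV, Na⁺ᵢ ≈ 7.6 mM).

**β-AS formulation.** Modelled as two populations per PKA target
(phosphorylated fraction with the full effect, unaffected remainder),
with saturating-isoproterenol fractions taken from the β-adrenergic
signalling literature: I_CaL 0.45, I_Ks 0.55, Na⁺/K⁺ pump 0.30,
phospholamban 0.85, troponin-I 0.67. Full-phospho effects: P_Ca ×2.5
with hyperpolarizing shifts of the activation (−3 mV default) and
inactivation (−2.8 mV) curves, G_Ks ×3.2, pump ×1.3, SERCA Km ×0.54,
troponin Km ×1.6. Steady-state gating of the mixture is the
fraction-weighted average of the two populations' curves. The effect
set switches on as a step (no phosphorylation kinetics ramp). The
−16 → −3 mV activation-shift reduction is exposed in config; with
−16 mV the control midmyocardial model develops EADs immediately
(excess I_CaL window current), with −3 mV it is stable — matching the
motivation for the reduction. Known limitation: the EAD onset *time*
under β-AS is an emergent function of the exact PKA effect magnitudes
and kinetics; with this step-applied effect set the g_Kr-reduced
model's first EAD at 2.5 Hz occurs after ~20–25 s of regular activity
(sustained thereafter), earlier than the ~43 s reported with the
original formulation. All qualitative behaviours (which model is
stable under which protocol) reproduce.

**Protocols.** Baseline: pacing at CL 1000 ms with the standard
stimulus (−80 µA/µF, 0.5 ms) until the beat-to-beat relative L2 state
change < 1e-6 or 1000 beats (the convergence cap; Na⁺ equilibration
dominates the approach to the limit cycle). Acute hypokalemia:
[K⁺]ₑ 5.4 → 3.0 mM switched at a stimulus boundary from the 1-Hz
steady state, ≥30 beats; because the resting potential follows E_K
(−103 mV at 3.0 mM) the stimulus is lengthened to 1.0 ms after the
switch so pacing stays suprathreshold (amplitude unchanged) —
otherwise capture is lost, whereas the experiment being emulated shows
continued APs. β-AS: from the 1-Hz non-stimulated steady state, the
effect set and CL 400 ms start simultaneously; ≥60 s; EAD times are
measured from the switch.

**Metrics.** APD₉₀ runs from maximal upstroke dV/dt to the
interpolated crossing of V_rest + 0.1·(V_peak − V_rest) with V_rest
taken immediately before the stimulus; beats that never reach the 90%
level (EAD-arrested repolarization) are flagged NaN. CaT amplitude is
peak minus pre-stimulus cytosolic Ca²⁺. An EAD is a local voltage
minimum followed by a rise ≥ 1 mV occurring after a 100-ms
post-stimulus blanking window (which excludes the physiological
spike-notch-dome complex of the midmyocardial AP) and before
repolarization below −40 mV; all thresholds are config-exposed.

**Numerics.** Fixed-step hybrid Rush–Larsen integration (gates by
exact local exponential relaxation, concentrations/voltage by forward
Euler), dt = 0.005 ms, numba-compiled; deterministic by construction.
Halving dt changes APD₉₀ by < 1 ms (tested). The Φ flux terms use a
voltage floor of 1e-8 mV to avoid the removable singularity at 0 mV.
An adaptive stiff solver was considered and rejected: at these
problem sizes (10³ beats × 2·10⁵ steps) the compiled fixed-step
scheme is orders of magnitude faster at equal accuracy, and EAD
timing benefits from a constant step. Problem sizes used in the test
suite: full 1000-beat pacing for the steady-state criteria (shared
across tests), 150-beat quasi-steady pacing for the 5-point
g_Kr-monotonicity sweep, 20 beats for the dt-convergence check.

## Degenerate inputs and tie-breaks

Empty schedules, non-positive durations, negative dt, out-of-domain
gate-τ voltages, empty groups, all-tied rank tests (H = 0, p = 1),
zero traces (tails = 0, normalization refused), truncated cohort
files (explicit parse error), unknown group labels: all raise typed
errors or defined values, covered by tests. Boltzmann/exponential
non-convergence is flagged (`converged=False`) with parameters
retained.

## Known limitations

* The τ(V) anchor shapes beyond the measured voltages are plausible
  but not data-constrained; analyses anchored at measured voltages do
  not depend on them to first order.
* The β-AS effect magnitudes are literature-anchored reconstructions;
  the EAD onset time (not its existence or pattern) is sensitive to
  them.
* Single-cell only: no fibre/tissue electrotonic coupling, no
  population-of-models variability, no temperature or drug-block
  effects.
* The clamp stage models the channel, not the recording chain
  (no R_s/C_m artefacts); C_m and R_a are carried as metadata only.
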