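# Methods

## HCN gating model

I_h is modeled as a single Hodgkin-Huxley activation gate with exponential
voltage dependence of the opening and closing rates,
`α = A·e^{−(V−V½)/Vα}`, `β = A·e^{+(V−V½)/Vβ}`.  The steady state
`m∞ = α/(α+β)` is algebraically identical to a falling Boltzmann with slope
factor `k = (1/Vα+1/Vβ)⁻¹`, and `τ = 1/(α+β)` peaks near `V½`.  Two frozen
parameter sets represent the cAMP conditions:

| condition | A | V½ (mV) | Vα (mV) | Vβ (mV) | k (mV) | τ(V½) |
|---|---|---|---|---|---|---|
| 0 mM cAMP | 6.907 s⁻¹ | −102.1 | 18.71 | 21.73 | 10.05 | 72.4 ms |
| 1 mM cAMP | 7.570 s⁻¹ | −87.31 | 31.46 | 10.84 | 8.06 | 66.1 ms |

cAMP enters only through these two discrete sets; no explicit
cAMP-dependent (Markov) gating is modeled.

**Units of A.**  `A` is interpreted as per-second.  Read as per-millisecond
it would give τ(V½) ≈ 0.07 ms, three orders of magnitude faster than the
measured tens-of-milliseconds I_h kinetics the model is fitted to, so the
per-second reading is the only self-consistent one.  A `rate_unit` switch
on `RateParams` exposes the alternative; `time_constant` always returns ms.

**Gate integration** uses the exact solution of the linear gate ODE at
fixed voltage (`m′ = m∞ + (m−m∞)e^{−dt/τ}`), unconditionally stable and
bounded in [0, 1] for any step size.

**The global HH fit** minimizes the weighted sum of squared residuals of
three datasets simultaneously — the steady-state activation curve and the
activation and deactivation time constants — each weighted by the inverse
square of its maximum value, so datasets with different units contribute on
comparable scales.  Optimization is trust-region least squares with 10
randomized restarts around data-driven initial guesses (midpoint from the
activation curve's half-crossing, `A` from 1/(2·max τ)); convergence
tolerances 1e−14 (objective) and 1e−12 (parameters).  68% confidence
half-widths are the square roots of the diagonal of the inverse Hessian of
the weighted SSE (Gauss-Newton approximation `2JᵀWJ`), the convention the
printed parameter uncertainties follow.  These unscaled intervals are *not*
calibrated to the data's noise level; `ci68_scaled` multiplies the
covariance by the reduced weighted SSE and does have nominal coverage.  In
simulation the scaled intervals cover the generating voltage parameters at
66–74%; the interval for the rate amplitude `A` under-covers (~50%) because
its likelihood is strongly curved — a known limitation of first-order
intervals, left as is.

## Tail-current activation analysis

Activation curves are measured from blocker-subtracted step families
(holding −70 mV, conditioning −70…−150 mV, tail at −70 mV).  Because the
subtracted trace's zero current is the channel-free level, the tail
amplitude is referenced to zero (default), making it proportional to the
absolute open fraction reached during the conditioning step; referencing to
the pre-step holding current (the raw-recording convention) is available
but under-reports activation whenever the holding potential itself
activates the channel — a ~2 mV midpoint bias for the 1 mM cAMP condition.
The amplitude is the mean over a 2 ms window starting 0.5 ms after the
step (skipping capacitive settling); the window-mean decay factor is
common to all sweeps and cancels in the normalization to the most
activated step.  Points are fitted with a free-amplitude-less Boltzmann;
the residual bias from the <1 plateau at −150 mV and the window decay is
under 0.3 mV, an order of magnitude below the 0.8 mV population SEM.

## Dose-response and endogenous cAMP

Midpoint shifts versus intracellular cAMP are fitted with a Hill function
(EC₅₀, maximal shift s_max, coefficient h; h free by default, pinnable to
1).  EC₅₀ is fitted on a log scale and its covariance mapped back by the
delta method.  s_max is anchored so the 1 mM (1000 µM) shift equals the
measured 17 mV (s_max ≈ 17.69 mV for h = 1, EC₅₀ = 40.4 µM), since neither
s_max nor h is reported directly.  The endogenous concentration estimate
inverts the mean Hill curve at the perforated-patch shift (4.8 ± 1.2 mV;
the figure-legend value, which differs from the 4.9 in the text by a
rounding step) and bounds it by the overlap of the fit's 68%
first-order confidence band (400 log-spaced points over 10⁻¹–10⁵ µM) with
shift ± SEM.  Because s_max and h are anchored rather than measured, the
endogenous estimate is reproducible in order of magnitude (~10–40 µM for
typical seeds), not as an exact value.

## Cable model

Geometry: 31 sections in a chain — a 150 µm × 1.2 µm white-matter cylinder,
then 15 repeats of internode (35 × 0.8 µm) + bouton (8 × 8 µm); default
discretization 11/7/3 segments respectively (a convergence test shows the
resting potential is discretization-independent to <0.05 mV).  Cylinder
lateral areas only (no end caps).  Specific capacitance 0.9 µF/cm², axial
resistivity 120 Ω·cm.  Internodes (and, by default, the white-matter
cylinder, switchable — the original description is silent on its
myelination) have capacitance and all leak conductances divided by 10.
Reversal potentials: Na⁺ +55, K⁺ −97, HCN −23.3 mV (the Methods value; the
Results section prints −23.4).  Densities (pS/µm², bouton / axon): NaV
2000 / 0, KV 1000 / 0, Na-leak 0.0138 / ÷10, K-leak 0.18 / ÷10, HCN
0.3 / 0.03.  Five variants: `control`, `no_hcn` (ZD7288), `camp_1mM`,
`vm_model` (HCN removed, e_K −90 mV: depolarization only) and `rm_model`
(e_HCN −85.5 mV, densities 1 / 0.1: conductance increase only).

**Na/K split of the HCN conductance.**  For energy accounting the HCN
conductance is split as `ratio_K/Na = (e_Na + e_HCN)/(e_Na − e_K)` = 0.2086,
`g_Na = (1−ratio)·g`, the published attribution.  This formula does not
make the two-conductance mixture reverse at e_HCN (the sign of e_HCN in the
numerator would have to flip; the physically consistent ratio is 0.515), so
membrane dynamics always use the single conductance with reversal −23.3 mV,
and the split only attributes Na⁺ flux, computed with the Na driving force
`g_Na·m·(V−e_Na)`.  A `thermodynamic` convention is provided; it is also
the automatic fallback where the printed formula leaves [0, 1] (the
`rm_model` reversal).

**NaV/KV kinetics** are not published for this axon and are authored here:
Boltzmann steady states and bell-shaped time constants,
m³h sodium (activation midpoint −38 mV/7 mV, τ_m 0.01–0.05 ms;
inactivation midpoint −60 mV/6 mV, τ_h 0.1–0.6 ms) and n⁴ potassium
(midpoint −50 mV/9 mV, τ_n 0.1–0.4 ms; n¹ selectable).  They are calibrated
to three anchors: (1) AP half-duration ~0.17 ms at a bouton, the ultrafast
class these terminals show; (2) the KV midpoint low enough that
repolarization proceeds to the resting potential rather than parking the
wake depolarized (midpoints ≥ −40 mV leave a 10 mV standing depolarization
for tens of ms after each spike); (3) negligible NaV/KV window conductance
at rest, so the HCN-free resting potential matches the leak-mixture value
(−86.2 mV) analytically.  With these choices the conduction-velocity
ordering (1 mM cAMP > control > no-HCN), the velocity-vs-rest peak at
−65 mV, and the input-resistance ratio all emerge without further tuning.
The steady-state NaV availability at −65 mV is then 0.70 (it reaches 50% at
−60 mV): a steeper or more negative inactivation curve restores the 50%
anchor but moves the velocity peak below −65 mV, and both could not be met
simultaneously in this mechanism set; the velocity-peak anchor was given
priority.  All quantities that depend on NaV/KV details are treated as
ordering/ratio predictions, not absolute targets.

**Integration** is backward Euler on the spatially discretized cable
equation (tridiagonal solve per step — the chain topology has no branches),
with all gates advanced first by their exact exponential update at the
start-of-step voltage.  Default dt 0.0125 ms for AP work (an upper bound of
0.2 ms is enforced).  Equilibration: 1 s coarse pre-run at dt 5 ms followed
by damped fixed-point refinement to |dV/dt| < 10⁻⁶ mV/ms.  Verified
properties: zero drift at rest (<10⁻⁹ mV over 100 ms), charge conservation
through an AP (<0.01%), subthreshold dt-halving changes <0.03 mV, and
agreement with an independent explicit-Euler reference on an isolated
bouton to <0.2 mV through an AP at dt = 5×10⁻⁵ ms.  Pointwise dt-halving
comparisons *during the AP upstroke* are dominated by O(dt) phase error of
any first-order scheme (a 5×10⁻⁵ ms timing shift already moves a sample by
0.1 mV at ~2000 mV/ms), so convergence contracts are stated for
subthreshold responses and for peak-derived quantities (velocities change
<0.5% on dt halving), not for samples on the upstroke.

## Protocols

Input resistance follows the bench protocol: −10 pA for 300 ms at a central
bouton, R_in from the steady-state deflection, τ_m from a mono-exponential
fit of the relaxation.  Sag ratio is steady-state deflection ÷ peak
deflection (≈0.5 means the voltage relaxed halfway back; the complement
convention is a flag).  Conduction velocity divides the bouton 5→12 path
distance (301 µm) by the AP peak-time difference, peaks refined by 3-point
quadratic interpolation; the stimulus is a 0.2 ms current pulse at the
white-matter end, emulating white-matter stimulation.  Trains deliver
20 pulses at 100–1666 Hz; APs are detected globally (prominence-based) and
matched to stimuli by latency, since the conduction delay can exceed the
stimulus period; peaks at or below −40 mV are failures.  The
velocity-vs-rest curve sets each resting potential by uniformly shifting
the K-leak reversal (bisection), so every point compares true steady
states; NaV availability is h∞(rest).

## Energy accounting

At rest, pathway Na⁺ currents are evaluated analytically from the
equilibrated state (1 pA sustained = 1 pC/s); per-AP cost integrates Na⁺
influx from stimulus onset to 10 ms after the last bouton's peak minus the
resting influx over the same window (Na tails are negligible afterwards at
these kinetics).  Costs are normalized per mm of the 15-unit
bouton+internode chain (645 µm), excluding the white-matter cylinder by
default (switchable) since the repeat unit is the fiber's characteristic
structure.  The HCN share of the budget at firing rate f is
`(rest_with − rest_without)/(rest_without + f·ap_cost)`.

## CAP analysis

Compound-AP sweeps are smoothed with a cubic smoothing spline (penalty 0 =
interpolation, None = generalized cross-validation; a fixed penalty can be
set for determinism — unsmoothed peak picking on noisy sweeps biases
delay-derived velocities, which smoothing removes).  The first 0.3 ms after
the stimulus marker are excluded from peak search.  Delay is the
quadratic-refined peak-time difference between electrodes; velocity is
separation/delay.  Time-courses are normalized to the −5–0 min baseline
window; standard effect windows are 10–15 min and 1–6 min (fast effects).

## Synthetic data

Generators emit a manifest (parameters, seed, ground truth) sufficient for
bit-exact regeneration.  Defaults encode the recorded study conditions:
per-cell midpoint SD 4.8 mV (0.8 mV SEM × √36 for the 0 mM condition;
1.2 mV × √16 for 1 mM), sweep noise 2% of the family's largest I_h
amplitude at 10 kHz sampling, dose-response SEM 1.2 mV at
{30, 100, 300, 1000, 3000, 10000} µM, CAP waveforms as a
difference-of-Gaussians (the shape is irrelevant to delay-based analyses by
construction).  For the 0→1 mM shift the two condition pipelines share the
random seed (common random numbers), the synthetic analogue of a paired
design: cell-scatter draws cancel in the difference without changing its
expectation.  The generators emulate amplitude statistics and timing, not
electrode artifacts, series-resistance errors, drift or temperature — so
passing recovery tests demonstrates correctness of the analysis chain under
the stated noise model, not robustness to every artifact of real
recordings.

## Known limitations

- The maximal failure-free train frequency is the same for the control and
  HCN-free models (both ~1.1 kHz here), whereas experiments show a factor
  ~2.  In this mechanism set the post-AP wake potential is set by where KV
  closes — a fixed voltage — which erases the resting-potential difference
  between variants within one inter-stimulus interval (the membrane time
  constants, 13/46 ms, are far longer than the intervals).  Reproducing the
  experimental separation plausibly requires activity-dependent mechanisms
  (ion accumulation, pump electrogenicity, slow NaV inactivation) that are
  deliberately outside this model.  For the same reason the sign pattern of
  delay changes during 200 Hz trains (experimentally: slowing without HCN,
  slight speed-up with) is not reproduced.
- The sag ratio of the model at a −150 mV peak is ~0.7 versus the measured
  ~0.5: the model's HCN density (0.18 channels/µm², two orders of magnitude
  below the immunogold estimate) and its fast activation at strongly
  hyperpolarized potentials limit how far the transient peak can overshoot
  the steady state.
- Endogenous-cAMP estimates inherit the anchored s_max/h (see above).
- No temperature dependence, stochastic gating, K⁺/Ca²⁺ homeostasis or
  mitochondrial energetics.
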