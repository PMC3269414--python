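# Methods

This note records the models, estimators and numerical choices behind
`sporepulse`, and what the synthetic data do and do not establish.

## Synthetic microcolony model

The generator emulates already-segmented single-cell traces from a
time-lapse movie of a microcolony under nutrient limitation.

**Growth and division.** Cells are rods of constant width, so length is
the size coordinate. Within a cycle, length grows exponentially and the
cell divides symmetrically when it has doubled; each daughter receives
half the final length and the mother's concentrations (mean
fluorescence is concentration-like and continuous across division in
the noise-free ideal). Cycle durations are lognormal around
`mean_cycle_min` (default 240 min, CV 0.10) and are realized as whole
frames on a global 10-min grid, with the growth rate set so length
doubles exactly over the realized cycle. The 240-min default reflects
multi-hour cycles under nutrient limitation while giving 24 frames per
cycle — enough for the window-7 smoother and curvature-based widths to
operate well inside each cycle.

**Pulses and feedback.** Each cycle carries one promoter-activity pulse
in the reporter channel: a raised cosine (smooth, compactly supported,
analytically integrable) centered at phase 0.6 of the cycle with full
width 0.6 of the cycle. Amplitudes follow the pulse-to-pulse map
p′ = g(p)·η with saturating g(p) = a₀ + v·p/(K + p) (defaults a₀ = 1,
v = 12, K = 3, Hill exponent 1) and lognormal unit-mean noise η
(CV 0.2). The defaults were set so that (i) the first pulse is the
basal one (a₀ = p₀ = 1: the first pulse arises with no feedback
history), (ii) the map visibly saturates within the sampled amplitude
range (g′(p*) ≈ 0.2, so top amplitudes become nearly independent of
their predecessors), and (iii) the noise-free staircase 1, 4, 7.9, 9.7,
10.2 crosses the sporulation threshold Θ = 10 in its fifth cycle. A
cell whose amplitude reaches Θ sporulates (phase-bright flag at its end
frame) instead of dividing. The feedback-bypass variant replaces the
map by relaxation to a constitutive level c with the dilution
timescale, p′ = c + (p − c)e^(−ln2), times the same noise.

**Observables and noise.** Mean fluorescence obeys
dM/dt = ρ(t) − (μ + γ)M within each cycle (γ is extra
maturation/photobleaching loss, default 0 because dilution dominates),
integrated with fixed-step RK4 at 4 substeps per frame. The
constitutive channel uses a constant ρ. Measurement noise is
multiplicative lognormal, independent per frame and channel (default
CV 0.05, the scale appropriate to a pixel-averaged mean fluorescence of
a segmented cell); lengths are reported noise-free. Runs are
bit-reproducible from the seed; lineage ids encode the path from the
founder ("1", then append 0/1 per division).

**Because Θ lies in the saturating approach to the fixed point
p\* ≈ 10.3** — unavoidable when the threshold must be reached only
after ~5 cycles of a saturating staircase — noisy crossing is a
threshold-waiting process: survivors are selected for low amplitudes,
the deferral distribution acquires a tail (mean ≈ 7 cycles vs the
noise-free 5), and the per-cycle hazard rises to a plateau near 0.5
rather than to 1. These are exactly the qualitative features of the
experimental deferral data, so they are treated as the study
conditions, not artifacts.

**What the generator does not emulate:** image formation and
segmentation errors, spatial crowding and mechanics, extracellular
signalling, growth-rate slowdown over the movie, asymmetric division,
pulse-shape variability, and correlated (non-white) measurement noise.
Passing tests therefore certify the estimators against idealized
segmented traces, not against raw microscopy.

## Promoter-activity estimators

ρ = μM + dM/dt (+ γ_extra·M) is the production rate per unit length,
an approximation to the rate per chromosomal equivalent; the constant
width factor is dropped throughout (all activities in arbitrary
units). Derivatives are central differences in the interior and
one-sided at the ends; each cell's series is differentiated
independently — never across a division, where continuity of M holds
only in the noise-free ideal. Negative ρ from noise is retained
(clipping would bias pulse areas). The total-fluorescence Euler
estimator P = ΔF/Δt + γF is also provided; note its γ convention
differs (total fluorescence is not diluted by growth), and its forward
difference estimates the derivative at the interval midpoint — the
equivalence test aligns it accordingly. On noise-free colonies the
recovered peak amplitudes match injected ones to ~2.3% RMS, dominated
by the O(Δt²) curvature bias of central differences on 10-min frames.

## Pulse detection

The trimmed-window smoother (window 7; edge windows shrink
symmetrically, with the two boundary points falling back to the median
of the three nearest) rejects single-frame outliers entirely and
introduces no phase shift on symmetric pulses (cross-correlation peaks
at lag 0; a symmetric bump may acquire a 3-point plateau, resolved
leftmost). Peaks must dominate a 5-frame sliding boxcar that fits
entirely inside the trace — boundary extrema are not local maxima; this
single rule removed essentially all false positives at trace edges.
Width is the contiguous negative-curvature run around the peak
(flagged, not dropped, when clipped by the trace boundary); area is
height × width by default (trapezoidal optional); the default minimum
pulse size is 10% of the colony-wide 95th-percentile candidate area, a
relative rule that transfers across arbitrary-unit datasets. At the
wild-type conditions (amplitude CV 0.2, measurement CV 0.05) recall and
precision are ≈ 0.94. Detection degrades sharply if per-frame
measurement noise reaches CV ≈ 0.2, because ρ is a derivative of an
accumulated concentration ~50–100× the pulse amplitude — a physical
limit of derivative-based activity estimates, not of the smoother.

## Return maps and the feedback fit

Each cycle is represented by its largest pulse; every parent→child link
contributes one (mother, daughter) amplitude pair, so both daughters
reuse the mother's amplitude — a documented accounting choice that
matches lineage-tree data volume. Diagonal counts use a 1e-9 relative
tolerance for ties (ties arise only synthetically) and an exact
two-sided binomial test against 0.5.

`FeedbackMapModel` fits g by least squares on log amplitudes by default
(the maximum-likelihood scale for multiplicative lognormal pulse
noise; linear scale available), with the Hill exponent bounded to
[0.5, 6] and multiple starts. The identifiable quantity is the **fixed
point p\*** (stable diagonal intersection, recovered to ~3% across seed
families at 250 pairs, CV 0.2). The raw parameters are sloppy: because
amplitudes are generated by the map itself, they never sample far below
the first pulse nor deep into the plateau, leaving a₀–h and v–K ridges;
a Fisher-information analysis of this design puts per-parameter
standard-deviation floors near or above 100% for a₀, v and h. Users
should interpret the fitted curve and p\*, not individual parameters.

## Deferral statistics

T₅₀ scans spore-formation frames for the earliest moment spores are
≥50% of objects (spores persist; divided cells are replaced by their
daughters; censored cells count through their last frame) and returns
log₂ of the object count then. Per-lineage deferral of a cell at depth
k is k + 1 completed cycles. The hazard at depth k is the sporulating
fraction of the non-censored depth-k cohort, with binomial standard
errors; censored branches are excluded from numerator and denominator.
The survival-product reconstruction of the deferral histogram accounts
for cohort doubling (2^k weighting) and matches the direct histogram
exactly on complete trees. The Hill fit weights points by their known
binomial errors (`absolute_sigma`), which is what makes the covariance
95% CI calibrated (coverage ≈ 95% in simulation); a cohort bootstrap CI
is available because published CIs of such fits come from varied,
often unstated, procedures.

## Circuit models

Time is measured in cell cycles; dilution λ = ln 2 per cycle. The
phosphorelay is reduced to direct kinase→Spo0A transfer (relay
intermediates do not change the qualitative conclusions) with constant
phosphatase activity k_E. Autophosphorylation is gated on during the
first f_pulse = 0.3 of every cycle, giving one Spo0A~P pulse per
cycle. Total Spo0A is held at A_tot by constitutive expression
balancing dilution, so A_P + A_u is a conserved check (≤1e-8 drift).
Kinase production is β_K (open loop), β_K·g(A_P) (instantaneous), or
β_K·g(A_P(t−τ)) with τ = 0.5 (polyphasic) — the delay places fed-back
production after the pulse that caused it, so kinase accumulates
between pulses. g is saturating (basal 0.05, half-saturation 0.25·A_tot,
Hill 2); the threshold is Θ = 0.5·A_tot; defaults k_t = 10, k_E = 2.

Integration is explicit fixed-step RK4 (step 1/500 cycle; the
discontinuous gate argues against adaptive steps), with a dense
linearly interpolated history for the delay; halving the step moves
T_D by <1e-3 cycles. T_D is the first up-crossing of Θ, linearly
interpolated between steps. Because crossings cluster near pulse
peaks, T_D is a near-staircase function of β_K; tuning and the
sensitivity derivative therefore act on a continuous surrogate — the
per-cycle A_P-maximum envelope's interpolated crossing cycle, offset by
the pulse window — which agrees with the first crossing to a fraction
of a cycle. Sensitivity S = |Δln T_D/Δln β_K| uses a central
difference with δ = 0.01, shrinking δ (÷4, floor 1e-5) when a
perturbation loses the crossing, as happens near the open-loop
reachability boundary at long deferrals.

The one-dimensional analogs make the architecture comparison exact:
open loop dX/dt = b − X (threshold reachable only for b > 100);
instantaneous dX/dt = (b−1)X (b > 1); polyphasic per-cycle map
X′ = (1+b)X e^(−1) (pulse-proportional production delivered after the
pulse, then a cycle of dilution; ln(1+b) > 1, i.e. b > e−1). The
polyphasic map is a reconstruction constrained by those thresholds and
the delayed-production logic, not a transcription of any published
equation set. Closed forms and direct integration agree to <0.1%, and
the sensitivity ordering S_open > S_inst > S_poly holds at every
matched deferral time in {2..8} for both families, with the polyphasic
time constant exponentially less sensitive to feedback strength.

## Problem sizes

Defaults used by the tests and the acceptance script: colonies of
~100–300 cells (one founder, ≤240 frames), 2 colonies for recovery and
detection metrics (≥100 traces), 250 pairs × 20 seeds for the feedback
fit, 50 colonies for the T₅₀ bound, 20 resamples for Hill coverage,
and the T_D grid {2..8} for the sensitivity curves. These sizes give
stable statistics in well under a minute each on one CPU.

## Known limitations

- Hill-parameter point estimates of the feedback map are not
  individually reliable at realistic sample sizes (see above); p\* is.
- The hazard is exactly monotone only in expectation; finite cohorts
  fluctuate around the plateau.
- The two-component model is deterministic; stochastic kinetics,
  relay intermediates, and mechanistic pulse generation are out of
  scope, as is fitting circuit parameters to trace data.
- γ conventions differ between the concentration-based and
  total-fluorescence estimators; both are exposed and documented
  rather than reconciled.
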