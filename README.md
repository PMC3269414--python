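# sporepulse

Tools for studying how *Bacillus subtilis* defers sporulation for
multiple cell cycles through a **pulsed positive feedback loop** on
sporulation kinase expression.

Under nutrient limitation, the master regulator Spo0A is phosphorylated
in discrete pulses, typically one per cell cycle. Each Spo0A~P pulse
up-regulates kinase expression, which raises the amplitude of the next
pulse — a saturating, once-per-cycle ratchet. Sporulation initiates only
when Spo0A~P crosses a threshold, so the ratchet's slow climb sets a
deferral time of several cell cycles. `sporepulse` implements the full
single-cell analysis chain behind this picture, plus the circuit models
that explain why the pulsed ("polyphasic") architecture makes the
deferral time robust to parameter variation:

- **`sporepulse.colony`** — synthetic microcolony generator: lineage
  trees of exponentially growing, symmetrically dividing cells carrying
  a pulsed Spo0A-reporter channel and a constitutive channel, with
  lognormal cycle-length, pulse-amplitude and measurement noise, and
  threshold-triggered sporulation. Stands in for time-lapse microscopy
  movies so every downstream stage is testable without data downloads.
- **`sporepulse.activity`** — promoter-activity inference from traces:
  μ(t) = L̇/L and ρ(t) = μM + Ṁ (+ γ·M), the production rate per unit
  cell length estimated from mean fluorescence M and length L; also the
  explicit-Euler total-fluorescence estimator P(t) = ΔF/Δt + γF.
- **`sporepulse.pulses`** — pulse detection exactly in the
  trimmed-window tradition: each point replaced by its window mean after
  rejecting the window's max and min (window 7), local maxima by a
  sliding boxcar, width = contiguous frames of negative second
  derivative, area = height × width, with a minimum pulse size.
- **`sporepulse.returnmap`** — return maps of successive pulse
  amplitudes (p_N, p_N+1) along lineages, above/below-diagonal counts
  with exact binomial tests, and `FeedbackMapModel` — a least-squares
  fit of the saturating map p_N+1 = a₀ + v·p_N^h/(K^h + p_N^h) whose
  results object carries parameters, covariance and the fixed point p*.
- **`sporepulse.deferral`** — T₅₀ (log₂ of the colony size at the
  moment half its objects are spores), per-lineage deferral
  distributions, the per-cycle sporulation hazard, and
  `HillSporulationModel` for the sporulated-fraction vs induction Hill
  fit with covariance and bootstrap confidence intervals.
- **`sporepulse.circuits` / `sporepulse.onedim`** — deterministic
  models of the sporulation initiation circuit in three architectures
  (open loop, instantaneous feedback, polyphasic i.e. delayed pulsed
  feedback), deferral times T_D, promoter-strength tuning, and the
  sensitivity S = |∂ln T_D/∂ln β_K|; plus the analytically solvable
  one-dimensional analogs with thresholds b₀ = 100, 1 and e−1.

## Worked example

Simulate a wild-type-like microcolony, run the pipeline, and fit the
feedback map — all from the shell (the same functions are importable):

```sh
sporepulse simulate --seed 7 --out colony7
sporepulse activity --traces colony7 --out act7.csv
sporepulse pulses   --traces colony7 --activity act7.csv --out pulses7.csv
sporepulse returnmap --traces colony7 --pulses pulses7.csv \
    --out map7.csv --fit fit7.json
sporepulse defer    --traces colony7 --out defer7.json
```

prints

```
wrote 179 cells to colony7
wrote activity for 175 cells to act7.csv
detected 164 pulses, wrote pulses7.csv
146 pairs: 96 above / 50 below the diagonal (binomial p = 0.000175)
...
fixed point p*: 8.2412
T_50 = 5.882643049361842, mean deferral = 7.98 cycles
```

Read: pulse amplitudes grow along lineages (96 of 146 successive-pulse
pairs lie above the diagonal, far from the 50:50 expected without
feedback), the fitted saturating map intersects the diagonal at
p* ≈ 8.2 (where pulse growth stops), and the colony's T₅₀ of 5.9 cell
cycles underestimates the mean per-lineage deferral of 8.0 cycles, as
it must. Detected-amplitude fits sit below the generator's ground-truth
map because smoothing shrinks peak heights; the diagonal statistics and
fixed-point location are the robust readouts.

On the modeling side:

```sh
sporepulse model tune --mode instantaneous --target-td 5
sporepulse model tune --mode polyphasic    --target-td 5
```

```
beta_K = 0.949856   S = 1.3107
beta_K = 1.01089    S = 1.0786
```

Both circuits are tuned to defer five cell cycles, but a 1% change in
kinase promoter strength moves the polyphasic circuit's deferral time
by only ~1.08%, less than the instantaneous feedback's 1.31% — and far
less than the open loop's (S ≈ 7 at the same deferral). The closed-form
one-dimensional analogs give S = b/(b−1) ≈ 2.086 (instantaneous) and
b/((1+b)(ln(1+b)−1)) ≈ 0.927 (polyphasic) at the same five-cycle
tuning.

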