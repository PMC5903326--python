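# Methods

## Signal model of the synthetic generator

Each session holds `2 × n_trials_per_class` trials (default 120) of 8 s
(3 s rest + 5 s MI) at 256 Hz on the 11-electrode montage C3, C4, Cz, T3,
T4, F3, F4, Fz, P3, P4, Pz. Per channel the signal is the sum of

* **1/f background** — Gaussian noise spectrally shaped to PSD ∝ 1/f
  (exponent configurable), RMS 4 µV. This reproduces the broadband roll-off
  of scalp EEG without committing to a source model.
* **Sensorimotor oscillation** — band-limited Gaussian noise in the ERD band
  (default 8–12 Hz), RMS 8 µV on every channel (a resting mu rhythm is not
  confined to the motor strip). RMS is fixed exactly per trial and channel
  before modulation, so the spectral contract below has low Monte-Carlo
  variance.
* **Power-line interference** — a 60 Hz sinusoid, 2 µV amplitude, random
  phase per trial and channel, so the notch stage is exercised.

The ERD multiplies the oscillation on the target channels (default C3, C4)
by √(1 − depth) from `onset_latency` (0.5 s) after the MI cue onward, so the
band power drops by the factor (1 − depth). The contract, verified with an
independent Welch periodogram: post-onset MI band power / rest band power
= 1 − depth (±0.1 over ≥ 100 trials); non-target channels and bands are
stationary. The amplitude RMS values are not calibrated to any cohort — no
quantitative ERD magnitude was available to calibrate against — they are
chosen so the oscillation dominates its band (background leakage into
8–12 Hz is < 10 % of oscillator power), making the depth parameter an
honest effect-size dial.

What the generator deliberately omits: ocular/muscular artefacts, volume
conduction (channels are independent, so CSP faces no correlated
background), inter-trial non-stationarity, and subject idiosyncrasies.
Passing tests therefore demonstrate correctness and calibration of the
*processing chain*, not expected accuracy on human EEG.

## Windows and filter bank

REST windows span 1.5–2.5 s, MI windows 3.5–4.5 s (half-open in samples,
0-based seconds). The six subbands 8–12 … 28–32 Hz are contiguous; the
prose source of this design also mentions 1 Hz overlap, which contradicts
the listed edges — the explicit list is the default and the band list is a
config key for anyone wanting overlap.

"30th-order FIR" fixes 31 symmetric taps and a 15-sample group delay, but
not the design method. A windowed (Hamming) design at this length leaves a
10 Hz tone at gain 0.165 through the 20–24 Hz band, which would defeat the
point of a filter bank. We use a linear-phase least-squares design
(`scipy.signal.firls`) with 8 Hz transition bands, normalised to unit gain
at the band centre; cross-band leakage of a 10 Hz tone into band 4 is then
≈ 0.012. The 60 Hz notch is a 31-tap least-squares band-stop of the same
transition width (gain ≈ 10⁻⁴ at 60 Hz); a naive 59–61 Hz band-stop at 31
taps is numerically a no-op (gain 0.87).

Filtering is **causal** (`lfilter`, no forward–backward pass): the online
stage classifies each window the moment it has elapsed and cannot look
ahead, and the offline path must be sample-identical to it. The first 31
samples of each filtered window contain the transient and are kept —
variance features are robust to this, and trimming would desynchronise the
offline and online paths.

## CSP and features

Per-window spatial covariances are `X Xᵀ` (no mean removal — inputs are
bandpassed) normalised by their trace, then averaged within class. The
filters solve `S1 w = λ (S1 + S2) w` via `scipy.linalg.eigh`; eigenvalues
are clipped to [0, 1] and sorted descending, and a ridge of
1e−8 × mean-diagonal is added only if cond(S1+S2) > 1e10 (logged). Features
are log normalised variances over all 11 filters per band, 66 columns
band-major. The log transform is the default (`log_var_ratio`); raw ratios
are available (`log_transform=False`). The single-band baseline uses the
classic convention instead: first/last m = 2 filters, variances normalised
over those 2m projections.

## Swarm selection

Positions live in [0,1]⁶⁶, velocities are clamped to |v| ≤ 1 ("minimum
speed 0" in the source prose cannot mean signed velocity ≥ 0, which would
break the update), and inertia descends linearly 1 → 0 (the prose's
"descends from 0 to 1" is self-contradictory; both endpoints are config
fields). r1, r2 are drawn per particle **and** per dimension. Thresholding
at 0.5 decodes a mask; an empty mask is repaired by forcing the dimension
with the highest position value on; pair closure (j ↔ 12 − j within each
band; filter 6 is self-paired) is applied last and is idempotent. Personal
and global bests update only on strict improvement, so the best fitness is
non-increasing and ties keep the first-found solution.

Fitness `2·err + nselec/66` uses resubstitution error by default, which is
what the stop criterion ("0 % classification error or 50 generations")
implies; an internal stratified holdout is available (`eval_mode =
"holdout"`) for anyone worried about selection overfitting. Note a
consequence of the stop rule: on separable training data the swarm halts at
the *first* zero-error mask, so the feature count is not minimised further
in that case.

`select_features` runs fitness through a cached evaluator that precomputes
per-class feature sums and scatter matrices once and solves each masked LDA
subproblem by slicing — numerically equivalent to the plain
fit-predict route (unit-tested) but fast enough for 50 × 50 swarms inside
10 × 10 cross-validation.

## LDA

Closed form with pooled covariance and equal priors (classes are balanced
by construction): `w = Σ⁻¹(μ_MI − μ_REST)`, bias at the midpoint of
projected means. A relative ridge of 1e−6 is engaged only when the pooled
covariance is numerically singular (logged). A decision score of exactly 0
resolves to REST — conservative for orthosis activation.

## Cross-validation

10 repetitions × 10 folds. The fold unit is the **trial**, so a trial's
REST and MI windows always stay on the same side of the split (sibling
windows of one trial in both partitions would leak slow-varying trial
state). Because each trial contributes one window per class, trial folds are
exactly stratified at the window level. Repetition r shuffles with seed
`base + r`; the proposed method and the baseline consume identical
partitions (paired comparison); each fold's PSO seed is derived
deterministically from (repetition, fold). CSP filters, mask and LDA are
refit per fold from training windows only; the deployment model for the
online stage is refit once on all offline data.

## Online stage

Six consecutive [k, k+1) s windows per trial: 3 REST then 3 MI — the MI
windows occupy the first three seconds of the 5-s MI interval, contiguous
with the rest windows. The trigger fires iff ≥ 2 of the 3 MI windows are
classified MI; REST windows never influence the trigger. %CA counts all six
windows; %CT counts triggered trials. Per-run (20 trials) feedback is a
5-level band of %CT (≥ 90, ≥ 80, ≥ 70, ≥ 60, below). Processing time per
window is recorded but never asserted against. Classifier weights stay
frozen across sessions.

## Chance level and statistics

Practical level of chance: `p̃ = (k+2)/(n+4)`,
`100·[p̃ + z_{1−α/2}·√(p̃(1−p̃)/(n+4))]`, k = n/2 by default, z from the
normal inverse CDF (any α works). For n = 240 decisions at α = 0.05 this is
56.27 % — which truncates to the conventionally quoted 56.2 %. The "n"
entering the bound is the number of evaluated decisions (both classes
pooled: 120 trials per class → n = 240). Method comparison uses a
two-sided Mann–Whitney U test; normality checks use the
Lilliefors-corrected KS test (statsmodels); offline-vs-online comparisons a
paired t-test; the %CA↔%CT relation Pearson r with an OLS r².

## Problem sizes and tolerances in the test suite

Full-scale checks (120-trial sessions, complete 10 × 10 CV with 50 × 50
swarms) run in the acceptance tests: a depth-0.7 ERD must exceed the 56.2 %
chance line, and 10 null (depth-0) sessions must fall below it in ≥ 9 of 10
seeded runs. Unit and property tests use 30-trial sessions and reduced
schemes; Monte-Carlo tolerances follow the quantity's sampling error (band
power ratios ±0.1 over ≥ 100 trials; eigen-residuals < 1e−8; duality of
eigenvalues and projected variances ±0.05). All stochastic components
(generator, swarm, folds) are seeded; identical seeds give bit-identical
outputs.

## Known limitations

* The generator's channel independence makes the spatial problem easier
  than real EEG; CSP's advantage over single-channel band power is
  understated on such data.
* Resubstitution error inside the fitness overfits when the training window
  count is small relative to 66 features; the holdout mode mitigates but
  was not made the default because the stop criterion is defined on
  training error.
* EDF output is 16-bit and clips at the recorded absolute maximum; the
  writer targets interchange, not archival fidelity beyond quantisation.
* The orthosis, amplifier drivers and cue GUI are out of scope; the trigger
  is an event in the session log plus an optional callback.
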