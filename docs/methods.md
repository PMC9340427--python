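# Methods

## Signal path

Raw NIRS channels ([O₂Hb], [tHb], arbitrary units, nominally 50 Hz) are
converted to the tissue saturation index sample-wise,
`TSI = 100·[O₂Hb]/[tHb]`, *before* averaging; the 1 Hz working series is
the arithmetic mean of each half-open 1 s bin `[t, t+1)`, time-stamped at
the bin's left edge, with a trailing partial bin discarded (partial bins
would have unequal variance). Computing TSI before averaging is a
convention choice — the alternative (average channels, then divide) gives
slightly different values when the channels co-vary within a second — and
is recorded in each trace's provenance metadata. TSI values outside
[0, 100] (possible when instrument noise makes [O₂Hb] exceed [tHb]) are
flagged in metadata and passed through unclipped so the filter sees the
raw signal.

Time is in seconds, 0-based at session start; all segmentation arithmetic
uses half-open windows on the 1 Hz grid.

## Smoothing

A second-order Butterworth low-pass with 0.1 Hz cutoff, applied
forward-backward (`filtfilt`, odd signal extension, pad length
3·(order+1)). Zero-phase filtering is the default because TD and τ are
phase-sensitive: a causal pass would delay every onset by the group delay
(~2 s at low frequency for this design) and bias TD systematically
upward. A single causal pass remains available (`zero_phase=False`). The
double pass squares the magnitude response, so the design cutoff is the
half-amplitude point of the cascade (|H(f_c)|² = 1/2), not its −3 dB
point; the tests verify the measured attenuation against the designed
filter's frequency response.

The filter is a noise-suppression stage and is *optional*
(`cutoff=None`). It is not distortion-free: zero-phase low-passing a
signal with slope discontinuities (the sprint-onset corner, the TD kink)
smears them over ~±(1/2πf_c) s. On the synthetic piecewise signal this
adds a systematic onset-slope bias of roughly +0.25 %·s⁻¹ (toward zero,
worst when the post-window easing is sharp) while leaving TD/τ/MRT
recovery good (median errors ≈ 0.4/1.1/0.8 s at 1 % noise). Validation
therefore checks slope recovery on the unsmoothed series and delay/time
constant recovery both ways; noise-free self-consistency is checked with
smoothing off, since there is no noise to remove. For real, smoother
physiological onsets the bias is smaller, but users comparing absolute
slopes across processing pipelines should hold the filter setting fixed.

## Deoxygenation fit

Ordinary least squares of TSI on t over exactly the first 10 samples of
the sprint (t = 0…9 s, i.e. a 9 s span). The closed-form normal-equation
solution is used directly; the property suite checks it to 1e-10 against
an independent implementation. A constant window (SS_tot = 0) returns
slope 0, intercept at the value and an explicit "R² undefined" flag
rather than propagating NaN silently. Other window lengths require an
explicit override (`expected_points=None`).

## Reoxygenation fit

The delayed mono-exponential is written with a negative exponent,
`TSIb + A(1 − e^{−(t−TD)/τ})`: the only sign that saturates (and the one
consistent with the A′ = A(1 − e^{−(Tend−TD)/τ}) end-of-window formula).
For t ≤ TD the model value is pinned at TSIb, and by default **all**
samples in [0, Tend) enter the residual — TD must be identified from the
pre-rise floor. `fit_span="post_delay"` restricts the residual to
t ≥ TD for sensitivity analyses.

Minimisation is trust-region nonlinear least squares (analytic Jacobian;
bounds A > 0, TD ∈ [0, Tend), τ > 0; TSIb free) from multiple
deterministic starts: a heuristic start (TSIb ← min of the first 10 s;
A ← range; TD ← first 10 %-of-range crossing; τ ← time to 63 % minus TD),
four jittered copies of it (fixed seed), and the best node of a coarse
profiled grid (TD every 5 s up to 60 s × τ every 5 s up to 120 s, with
TSIb and A solved linearly at each node). The grid start makes the
optimiser provably at least as good as a coarse exhaustive search, since
trust-region polishing never increases the RSS. Convergence: relative RSS
tolerance 1e-10, at most 2000 residual evaluations; among equal-RSS
solutions the smallest TD wins. A segment whose range (or fitted
amplitude) is below 0.5 %TSI is flagged as a failed fit (amplitude
indistinguishable from zero) instead of returning meaningless parameters.

R² and adjR² are computed on the sub-span from the exponential onset
(t ≥ TD) to Tend, with n the sample count of that sub-span. The model as
fitted has four free parameters, but adjR² uses k = 3 by convention
(counting the kinetic parameters, baseline treated as given); `k_dof` is
configurable, and `fix_baseline=True` pins TSIb to the observed onset
value so exactly three parameters are free. Inclusion in group summaries
is strict: R² > 0.80.

## Performance metrics

Total work is the trapezoidal integral of sampled power over the closed
30 s window (the closing sample is required so a constant 600 W sprint
integrates to exactly 18.0 kJ); mean power is work divided by the window
span, and peak power the maximum sample. When only per-sprint summaries
are available, work = mean power × duration. The power-decrease
percentage uses the printed formula and is scale-invariant and bounded in
(−100, 0].

## Synthetic sessions

The generator emulates one 5-sprint session per condition at 1 Hz (30 s
lead-in plateau; sprints every 270 s). Per sprint the noiseless TSI is:
plateau at TSI₀ → exactly linear decline at rate a for the first 10 s →
slope-continuous exponential easing to the sprint floor (set equal to the
recovery baseline TSIb, so the recovery joins continuously) → the delayed
mono-exponential recovery itself. Only the first 10 s of the sprint must
be linear, since that is all the linear model ever sees; the easing time
constant follows from slope continuity, (TSI(10 s) − TSIb)/|a|.

Noise model: i.i.d. Gaussian noise (default sd 1.0 %TSI) plus a
random-walk drift whose sd accumulates to 0.5 %TSI per 100 s. These
defaults make the noise-free limit exact while producing fitted R² values
bracketing the 0.95–0.98 range typical of well-behaved recordings. All
randomness flows from a single integer seed through one `numpy`
generator; identical (spec, seed) pairs are bit-identical.

Per-condition parameter means are centred on published group statistics:
baseline saturation TSI₀ {BFR 80.0, G-BFR 72.4, HYP 77.6, NOR 79.2} %,
deoxygenation rate −2.6 (BFR) to −2.4 (NOR) %·s⁻¹, and recovery
(A, TD, τ) per condition — delay longest under cuff restriction, time
constant longest under gravity-induced restriction — with the asymptotic
amplitude back-computed from the published end-of-window amplitude A′.
TSIb is not published; its means (BFR 49, G-BFR 39, HYP 46, NOR 49 %)
were chosen so the sprint floor sits below the 10 s linear extrapolation
and recovery ends slightly below the pre-sprint baseline, preserving the
published TSIb ordering (highest under BFR). Draws violating structural
constraints (floor above the linear extrapolation, recovery exceeding
100 %, non-physiological delays) are redrawn up to a cap, then clamped
with a logged warning. Power traces decay exponentially within each
sprint, scaled to the drawn mean power, with a ~6.5 % per-sprint fatigue
factor yielding power-decrease percentages near −13 %.

What the generator does **not** emulate: heterogeneous optode coupling,
movement artefacts, cardiac/respiratory oscillations, blood-volume
([tHb]) dynamics decoupled from saturation, or any forward O₂-transport
physiology. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated signal-plus-noise model, not
robustness to every artefact of field recordings.

## Validation sizes and known limitations

The acceptance script and test suite use: 4 noise-free sessions (one per
condition) for exact self-consistency (every parameter recovered to
≤ 1e-3); 100 noisy replicate sessions (500 sprints) for recovery error
medians; 50 noisy recoveries for the grid-oracle dominance check; and
2000-sample sinusoids for the filter response. These sizes give stable
medians while keeping a full run in well under a minute.

Known limitations: TD and τ trade off strongly when TD is large relative
to τ (flat floors), inflating individual errors even when medians are
small; the per-condition printed SDs are used as between-sprint draws,
which overstates within-subject variability; group summaries deliberately
stop at mean ± sample SD (n−1), exporting tidy long-format tables for
inferential statistics in external tools.
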