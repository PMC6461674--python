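# Methods

This note documents the models, estimators and numerical choices behind
`trifret`, in the order data flows through the package.

## Experiment being modelled

A nucleosome carries three dyes: Cy3 (donor) and Cy5 (acceptor) flanking the
exit side, and Alexa750 (second acceptor) positioned so that Cy5→Alexa750
FRET reports on entry-side DNA. Excitation alternates between 532 nm
(probing Cy3 and, through the cascade Cy3→Cy5→Alexa750, everything
downstream) and 638 nm (probing the Cy5→Alexa750 pair directly). On
remodeller + ATP addition, entry-side FRET changes non-monotonically (DNA is
pulled on, then propagated past the dyad) while exit-side FRET decreases
monotonically; the lag `t_lag` between the two onsets is the central
statistic. Cy3→Alexa750 FRET is taken as zero throughout (large distance,
small Förster radius), so no three-way de-mixing is attempted.

## Synthetic data generator

`sample_kinetics` draws, per molecule,

* `t_entry_onset ~ Exp(1/k_init)` — waiting time to remodeller engagement
  (default `k_init = 0.2 s⁻¹`);
* `t_lag ~ Exp(τ)` with `1/τ = k_max·S/(K_app + S)` at ATP concentration
  `S`. The hyperbolic (Michaelis–Menten) form is the minimal model for a
  single rate-limiting step involving ATP binding. Defaults: `K_app = 60 µM`
  (the ATPase's known half-saturation range is 50–60 µM) and
  `k_max = 0.2286 s⁻¹`, chosen so that the mean lag at 500 µM is 4.9 s —
  the measured original-orientation condition. `KineticConfig.for_mean_lag`
  retargets the hyperbola to any condition (e.g. 21.0 s for the flipped
  601 orientation).

FRET trajectories are piecewise linear: exit-side `E1` steps from 0.75 to
0.25 over `d_exit = 2 s` starting at `t_exit = t_entry + t_lag`; entry-side
`E2` rises 0.15 → 0.75 over `d_rise = 2 s`, then falls to 0.45 over
`d_fall = 3 s`. Real transitions are gradual multi-bp movements without a
published parametric form; linear ramps with configurable durations are the
simplest shape with a well-defined onset. The FRET levels are plausible
high/low values for the labelling geometry, not measured constants.

`render_traces` converts trajectories to per-frame photons. Under 532 nm the
budget `N` (default 500 photons/frame) splits `(1−E1) : E1(1−E2) : E1·E2`
across Cy3/Cy5/A750; a fraction `d_cy5_532 = 0.05` of the budget is
direct-excited Cy5 (re-transferred to A750 with `E2`). Under 638 nm, Cy5
splits `(1−E2) : E2` plus direct-excited A750 (`d_a750_638 = 0.05`).
Channel signals scale with detection factors `g_cy3 = 1.25`, `g_cy5 ≡ 1`,
`g_a750 = 0.8`; bleedthrough mixes 10% of Cy3 emission into the Cy5 channel
and 10% of Cy5 emission into the A750 channel. Poisson shot noise, Gaussian
read noise (SD 5) and a constant background (10 counts/channel) follow, in
that order. Each dye bleaches in a single step, exponentially in cumulative
exposure to the laser(s) that excite it (Cy3 sees only the 532 nm
half-cycle); emission is zeroed at frame granularity from the bleach frame
on, and a bleached acceptor returns its transfer share to the donor. The
photophysics defaults are conventions of a plausible TIRF setup, recorded in
every manifest, not published values.

What the generator does **not** emulate: dye blinking and triplet states,
partial-frame bleaching, slow baseline drift, spatial/optical effects, and
any coupling between remodelling state and photophysics. Passing tests on
synthetic data therefore demonstrate correctness of the analysis chain under
the stated noise model, not robustness to every artefact of real recordings.

## Frame pairing and corrections

Alternating-excitation blocks are paired nearest-in-time (the i-th 532 block
with the i-th 638 block); each aligned record keeps the midpoint timestamp
plus both block times, and each FRET value is attributed to its own
excitation frame's time so that onsets are not biased by half an ALEX cycle
(0.1 s at the default 0.1 s frame interval).

Corrections are applied in the order **bleedthrough → direct excitation →
scaling**, which inverts the forward model exactly: the Cy5 emission that
bleeds into the A750 channel includes the direct-excited Cy5 contribution,
so bleedthrough must be removed first. The direct-excitation step subtracts
`d_cy5_532·I638_Cy5` from the 532 Cy5 channel, the direct-excited-Cy5→A750
re-transfer (`d_cy5_532 ×` the corrected 638 A750 signal) from the 532 A750
channel, and the direct A750 term from the 638 A750 channel using the
per-record Cy5-equivalent total. On noiseless data the round trip
render → correct → FRET equations reproduces the ground-truth efficiencies
to better than 1e-9 (during entry-side ramps the per-channel identities hold
only up to the within-cycle E2 change, but the residuals cancel exactly in
both FRET ratios). Records whose denominator falls below a floor (default
`3 × read-noise SD × √3 ≈ 26` counts) are flagged invalid rather than
clipped; valid FRET outside [−0.2, 1.2] raises, since genuine noise cannot
get there under any sane correction parameters.

`estimate_corrections` reconstructs all six parameters from segments where a
subset of dyes has photobleached: bleedthroughs from acceptor-dark segments,
`d_cy5_532` from donor-dark segments, backgrounds from dye-dark segments,
and the two scale factors plus `d_a750_638` from intensity changes across
bleach steps (donor recovery vs acceptor loss). The last three are coupled
and solved by fixed-point iteration; each equation is exact given the
others, so the iteration converges to the exact values on noiseless data.
The estimator assumes FRET is locally constant within the ±10 s windows
around a bleach step — in practice calibration uses molecules that are
static or have finished remodelling. Parameters without qualifying segments
keep their defaults and are flagged.

## Event detection

Onsets are fit with a two-phase model — constant baseline `µ`, then a linear
ramp `µ + s·(t − t₀)` continuous at the breakpoint — by exhaustive scan of
the breakpoint over sample positions (prefix-sum algebra, O(n)) followed by
bounded continuous minimisation of the profile RSS over the two adjacent
sampling intervals. An event is called only if the fitted change from onset
to window end exceeds `onset_threshold` (default 0.1 FRET) in the required
direction. Because the model has no plateau phase, the fit window is first
trimmed where the smoothed series (moving average over `baseline_window =
10` cycles) completes 80% of its total excursion; this keeps the model
well-specified for the rise-then-fall entry trace (trimmed at the rise) and
the decrease-then-plateau exit trace, and is exact on noiseless data. Exit
onsets are searched only at times ≥ the entry onset, encoding the observed
ordering; the unconstrained exit onset is also computed and the fraction of
molecules where it would precede entry is reported as a diagnostic, so the
prior cannot silently hide contrary data. `min_segment = 2` points are
required on each side of a breakpoint; with noise SD 0.05 and the
generator's 2–3 s ramps the onset error is ~1 frame (median), 95th
percentile ~3 frames.

Photobleach steps are found per dye on FRET-insensitive channel
combinations (Cy3: its 532 channel; Cy5: summed 638 emission; A750: its
638 channel, bleed-corrected when parameters are known) by recursive
two-segment mean-shift fits with a robust noise scale
(`1.4826·median|Δy|/√2`). A candidate step must exceed `penalty = 6` noise
SEs and pass a sharpness test — the drop across a 3-sample window must be at
least 70% of the drop across a 9-sample window — which separates
single-frame bleach steps from gradual FRET ramps. Steps smaller than 20% of
the channel's initial level are treated as crosstalk echoes of another dye's
bleach. Molecules with more than one step per dye are flagged
`multi_step_bleach` (double labelling) and excluded; molecules whose Cy5
bleaches before an exit onset are censored at the bleach time.

## Lag-time and ATP-dependence fits

The primary lag estimator is the closed-form exponential MLE (sample mean),
bin-free and unbiased. The censored variant uses
`mean = (Σ lags + Σ censoring times) / n_uncensored`, the exact MLE under
exponential right-censoring; censored molecules are excluded from the
default fit (event counts refer to completed transitions) but exported for
the censored option. A binned least-squares mode (Freedman–Diaconis bins)
reproduces the conventional histogram fit for comparison. Uncertainty is a
seeded nonparametric bootstrap (1000 resamples); goodness of fit is a KS
statistic against the fitted exponential, reported per condition without
multiplicity correction (descriptive, not a screen). The ATP dependence is
fit by weighted nonlinear least squares of `1/mean_lag` on
`k_max·S/(K_app+S)` in log-parameters with a multi-start grid over decades,
weights `1/SD²` with `SD(1/τ) = SEM(τ)/τ²`; confidence intervals come from
the Jacobian at the optimum. Population FRET histograms aggregate
per-molecule mean FRET before the entry onset or after the exit onset into
fixed 0.02-wide bins over [−0.1, 1.1].

## Twist-defect buffering model

Two buffering stages sit between the ATPase injection point and the exit:
entry-SHL2→dyad (capacity 2 bp) and dyad→exit (capacity 3 bp), plus an
initial 1 bp defect formed on binding. The capacities are calibrated to
reproduce the observed gap-limited probe shifts 9/7/4 nt at `m = 8` and are
consistent with the 1–3 bp absorption bounds inferred from the experiments;
the two-buffer layout is a minimal choice, not a structural assignment.

*Deterministic mode:* a gap `m` bp beyond the stall site allows exactly `m`
injections; buffers fill in order of passage up to capacity, so
`entry = m + defect`, `dyad = entry − min(2, entry)`,
`exit = dyad − min(3, dyad)`. Outputs are non-decreasing in `m`, and
`entry = exit + absorbed` always (conservation). The known stronger-barrier
behaviour of the `m = 5` construct is out of model scope; the
`barrier_attenuation` flag exists but raises if enabled.

*Stochastic mode:* a continuous-time Markov chain with injections at
`k_inj` (stopped at `m`; cascading to the exit when all buffers are full,
unless disabled) and per-bp downstream relaxation at `k_relax`. The first
entry movement is the initial defect (t = 0) or else the first injection;
the lag to the first exit movement is the model's `t_lag`. The two
mechanistic extremes map to rate ratios, not code paths: with `k_inj ≫
k_relax` defects accumulate and the state at injection completion equals the
deterministic shifts (the transient gap-limited pattern, which then decays
as defects resolve — as the cross-linking time courses show); with
`k_relax ≫ k_inj` each bp traverses the stages sequentially and the lag is
Erlang with one stage per buffer. A single buffering stage with fast
injection gives an exponential lag — the single rate-limiting step regime
that matches the measured lag distributions. Note the buffers drain as
`t → ∞` under free relaxation, so the asymptotic stochastic shifts equal the
deterministic ones only in the zero-capacity limit; the deterministic
arithmetic describes the stalled transient, not the equilibrium.

## Problem sizes and numerical conventions

Recovery checks run the full pipeline at the measured event counts (185 and
190 molecules) with 120–200 s traces at the default 0.1 s frame interval
and 0.2 s ALEX cycle; the ATP-dependence check uses 100 molecules at each of
five concentrations (20–500 µM). Frames are 0-based, times in seconds, all
intervals half-open; a single RNG stream per dataset with the seed recorded
in the manifest makes every dataset bit-reproducible. Statistical acceptance
bands (2 bootstrap SEM for lag means, 10% for hyperbola parameters) are
inherently probabilistic per seed: with 100–200 events the sample mean
itself carries most of the band, and the `K_app` estimator's information
bound under the five-concentration design is ~20% relative SD, so
single-seed checks of that parameter can fail without any implementation
error.

## Known limitations

* Onset definition is the breakpoint of a baseline+ramp fit; if the "onset"
  of the original by-eye assignments corresponds to mid-transition instead,
  absolute onsets shift by half a ramp, though lags shift much less.
* The correction estimator needs bleach-ordered segments of several seconds;
  datasets without suitable bleaching events fall back to defaults.
* Censoring by trace end is treated like bleach censoring; very long lags
  relative to the recording length bias the uncensored mean low (negligible
  at the default trace lengths).
* The buffering model ignores sequence-dependent energetics (TA-rich vs
  TA-poor asymmetry enters only through distinct lag means) and
  multi-remodeller coordination.
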