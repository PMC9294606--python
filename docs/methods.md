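# Methods

## The depletion model

Transmission is modeled as a single homogeneous pool of `N` releasable
vesicles. At stimulus `k` the synapse releases `release_k = Pr · n_k`
vesicles (deterministic mode) or `release_k ~ Binomial(round(n_k), Pr)`
(stochastic mode; the draw is clipped so release never exceeds the
fractional pool), and the postsynaptic current is `release_k · Q` pA.
Between stimuli the pool refills at a constant rate (vesicles/s)
integrated over the inter-stimulus interval; whether the source
replenishes continuously or once per interval is indistinguishable under
this integration, which is why only the product `rate · ISI` matters.
The pool may optionally be capped at `n0`: off by default during trains
(the linear-replenishment reading of the model), on by default for
recovery simulations so that recovery ratios saturate at 1.

For the uncapped deterministic case with regular ISI the normalized
amplitudes obey

    a_k = r/p + (1 − r/p)(1 − p)^(k−1),   r = rate·ISI/n0,

an exact closed form (`closed_form_train`) used as the oracle for the
simulator and for both estimators. Facilitation, calcium dynamics and
multi-pool kinetics are deliberately out of scope.

## Estimators

Both estimators first normalize amplitudes to the first IPSC, which
removes the unknown number of stimulated axons and makes them invariant
to uniform scaling (tested as such).

*Train method.* Cumulative normalized amplitude vs stimulus number is
essentially linear late in a 40 × 100 Hz train; an ordinary
least-squares line over stimuli 33–40 (eight points — the configurable
default resolves an internal inconsistency in the usual "last 7 points,
stimuli 33–40" phrasing) yields y-intercept = relative RRP,
1/intercept = `Pr`, slope = relative replenishment per stimulus. The
method assumes `(1 − p)^33 ≈ 0`; the residual biases `Pr` upward by
`~(1 − p)^33`-sized terms — about 0.3% relative at `p = 0.2`, 13% at
`p = 0.1`. Tests assert near-exactness only where the assumption holds.

*EQ method.* Each normalized IPSC is plotted against the cumulative
amplitude of the *preceding* IPSCs (exclusive convention; the x-intercept
is provably identical under the inclusive one, and a test demonstrates
it). For a geometric train `IPSC_k = 1 − p · cum_{k−1}` exactly, so the
OLS line through the first 5 points has x-intercept `1/p` exactly:
x-intercept = relative RRP, first IPSC / x-intercept = `Pr`. Release
probability is computed as the reciprocal of the x-intercept (the
transposed phrasing sometimes seen — x-intercept divided by the first
IPSC — is dimensionally backwards). Replenishment inflates the early
cumulative axis and biases `Pr` downward by roughly `1.25·r`; the
estimator is only exact at `r = 0`.

Degenerate inputs (non-depressing trains: intercept ≤ 0 or slope ≥ 0)
set `valid=False` on the result instead of raising.

## Amplitude measurement under summation

With `tau_slow` comparable to or larger than the 10 ms ISI, each response
rides on the decaying tails of its predecessors. The measurement locates
the response latency once, on the first (largest) response, as the
extremum of the deviation from a linear pre-stimulus baseline within
0.5–8 ms post-stimulus; every amplitude is then the deviation at that
fixed latency from a local baseline fit. The default baseline is a
quadratic fit over the 5 ms pre-stimulus window (clamped below the ISI)
extrapolated under the response — the curvature term is what removes the
biexponential tail, keeping noiseless errors ≤ ~2% even with
`tau_slow = 5 × ISI`, where a constant baseline errs by ~20%. A constant
(pre-stimulus mean) mode is retained for comparison. Evaluating at a
single fixed latency rather than a window extremum keeps the measurement
unbiased in noise.

## Synthetic recordings

All generators are pure functions of (parameters, seed), sampled at
50 kHz by default, and return a `GroundTruth` record with the exact event
times (sample-aligned), amplitudes and construction features.

*Minis.* Homogeneous Poisson event times; log-normal amplitudes with the
requested mean and CV (strictly positive and right-skewed, as real mini
distributions are; only the mean is constrained by data). The trace is
the linear sum of peak-normalized kernels
`(1 − e^{−t/τ_rise})(w e^{−t/τ_fast} + (1 − w) e^{−t/τ_slow})` plus white
Gaussian noise; the default `noise_sd = amp_mean/5` defines SNR 5.
Wild-type-like defaults: 78.1 Hz, 57.4 pA, `τ_fast = 6.25` ms,
`τ_slow = 13.4` ms, `w = 0.6`; `τ_rise = 1.3` ms is a compromise choice
because one rise constant cannot match a 1.54 ms 10–90 rise and a 2.4 ms
time-to-peak simultaneously (it gives 1.39 / 2.56 ms). No stimulus
artifact is rendered, and all events form one population.

*Evoked trains.* Per sweep, an amplitude series is drawn from the
depletion model and convolved with the kernel; summation is linear.

*Action potentials.* Templates are piecewise waveforms constructed so
that the measured features equal the requested ones: a quadratic foot
whose dV/dt ramps linearly to 20 mV/ms exactly at the threshold voltage
(and exactly on a sample, so the sample-resolution threshold readout is
exact); two-slope upstroke and downstroke whose fast limbs realize the
requested maximal slopes and whose slow limbs, which contain the
half-amplitude crossings, are scaled to realize the requested half-width
(`r₂ = c·max_rise`, `f₂ = c·max_fall` with
`c = (A/2)(1/max_rise + 1/max_fall)/HW ≤ 1`; `c > 1` means the half-width
is infeasible for those slopes and is rejected); a flat trough at
threshold − AHP; and an exponential recovery. Peak and trough land
exactly on samples (the fast/slow split is adjusted to snap segment
durations to the grid), so amplitude and AHP are exact and the half-width
crossings sit inside linear segments where interpolation is exact.
Conductance-based dynamics are out of scope by design: the point of the
generator is exact feature ground truth.

Step-evoked sweeps use a leaky integrator (τ_m 20 ms, R_m 350 MΩ by
default) charging from the baseline toward `V₀ + I·R_m`; the closed-form
first-spike latency is `−τ_m ln(1 − V_range/(I·R_m))`, and the template
peak is placed at that threshold-crossing time so the measured
peak-latency equals the analytic value within one sample. Spontaneous
sweeps place spikes on a regular schedule.

## Mini detection

At every lag the kernel template (truncated to 1.5 ms — long enough to
cover the rising edge, short enough that near-coincident events rarely
share a window) is fit to the data by optimal scale and offset via
rolling FFT sums. The detection criterion is the fitted scale divided by
its standard error (the regression t-statistic). Criterion maxima above
3.5 (prominence ≥ 1.75, 1 ms refractory) mark events; detected kernels
are subtracted and detection repeats (3 passes), recovering events masked
by larger neighbours. Fitted amplitudes below 2.5× a robust noise-SD
estimate (median absolute first difference / (0.6745·√2)) are rejected —
this floor, not the criterion, sets the amplitude detection limit, and it
is exposed as `min_amplitude`. The normalization by SE(scale) rather than
by the residual SD matters at high rates: the residual-SD criterion
equals amplitude/noise-SD, which at SNR 5 with 30% amplitude CV leaves
~14% of events below threshold 3.5.

At 78 Hz, events closer than the 1 ms refractory (≈7.5% of Poisson gaps)
are indistinguishable in principle, so detected frequency runs ~5–7%
below the true rate with precision ≈ 1; passing tests bound recall and
precision at 0.9 and the mean frequency within 10% of the generator rate.

Decay kinetics are fit from the peak onward to
`A(w e^{−t/τf} + (1 − w) e^{−t/τs})` by bounded least squares,
initialized from the time to half decay (`τf₀ = t₁/₂/ln 2`, `τs₀ = 3τf₀`,
`w₀ = 0.7`); labels are swapped post hoc if needed so `τf ≤ τs`, and the
slow component is flagged unidentifiable when `w ≥ 0.99` or
`τs/τf < 1.2`. Recovery is exact on noiseless step-rise biexponentials;
on kernels with a slow rise the post-peak rise term biases the fit, so
kinetic ground-truth tests use step-rise inputs.

## AP features

Threshold is the membrane potential at the last upward 20 mV/ms dV/dt
crossing before the peak, read at sample resolution (central differences,
no smoothing); amplitude is peak − threshold; half-width is measured at
threshold + amplitude/2 with linear interpolation; maximal rates are the
dV/dt extrema between threshold and the AHP trough, the repolarization
rate reported as a positive magnitude; AHP is threshold minus the voltage
minimum within 10 ms post-peak (threshold-referenced, not
baseline-referenced — the choice is configurable and recorded in
reports). Evoked rate is spike count / step duration (robust at low
counts); input resistance is the OLS slope of ΔV vs ΔI through the
origin-inclusive point set, in MΩ.

## Statistics and pipeline

Group comparison is the unpaired two-tailed Student's t-test with pooled
variance (Welch variant by flag); no multiple-testing correction. The
pipeline runs a two-group synthetic study — control vs reduced
replenishment — with per-cell seeds derived arithmetically from one root
seed, so outputs are byte-reproducible. Fixture conditions: pool 300
vesicles, `Pr = 0.2`, `Q = 57.4` pA (one vesicle = one quantum, giving
~3.4 nA first IPSCs), replenishment 240 vs 96 vesicles/s, 10 sweeps of
5 pA noise per cell. Every analysis default left open by convention
(detection criterion, fit windows, AHP reference, slope threshold) is
written to `params_log.yaml`.

## Problem sizes and limitations

Tests and the acceptance script use 40-stimulus trains, 10–60 s mini
traces, 10-sweep averages and 50-seed recovery suites; everything runs in
minutes on one CPU. The generators emulate linear summation, stationary
Poisson minis, white noise and template-identical spikes; they do not
emulate electrode artifacts, baseline drift, receptor desensitization or
saturation, amplitude correlations, or spike-shape adaptation — so
passing tests validate the estimators and measurement code under the
model's assumptions, not the biology of any particular recording. The
EQ estimator is biased downward by replenishment and the Train estimator
upward at small `Pr`; both biases are documented above and visible in the
parameter-recovery suite.
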