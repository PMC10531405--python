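# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `cfpop`. All defaults live in `cfpop.pipeline.RunConfig`
and `cfpop.synth.GeneratorConfig`.

## Data model

Events are trial-relative seconds with the cue onset at 0; trials span
[-2, +6) s so a [-2, -1) s pre-cue baseline always exists. Spike times are
quantized to a 10 ms grid (the 100 Hz resolution of the detection stage).
All bins everywhere are half-open `[t, t+Δ)`. A trial is HIT (Go + lick in
[0, 1) s), MISS (Go, no lick), FA (No-go + lick) or CR (No-go, no lick);
a session's learning stage is 1 / 2 / 3 for fraction correct < 0.6 /
[0.6, 0.8] / > 0.8 (the middle interval is closed — the source convention
is unstated). In HIT trials rewards follow the first lick at +0.41, +0.82
and +1.23 s.

## Synthetic cohort

The generator emulates the statistical structure of the recorded cohort;
it is the package's test bed, not a biophysical simulation.

* **Scale.** Defaults: 17 mice x 6 sessions x 30 neurons x 30 trials
  (per-session scale matches the recordings: ~30 simultaneously imaged
  cells, >=30 trials). Tests and the acceptance suite use the
  `small_config` desk-scale presets (2–4 mice x 6 sessions x 24 neurons x
  30 trials, i.e. 288–576 neurons); these sizes are the package's own
  choice to keep the suite fast while keeping every statistic in its
  asymptotic regime.
* **Rates.** Complex spikes are Bernoulli per 10 ms bin at
  baseline 1.1 spikes/s plus a planted non-negative rank-4 component
  `Σ_r λ_r w[n,r] b[t,r] a[k,r]` defined on the PSTH grid. The four
  components mimic the reported phenomenology: (1) fast post-cue response
  (peak ~200 ms) in HIT, concentrated in AldC-positive compartments,
  (2) very fast FA response (peak ~100 ms, gone by ~400 ms) in the lateral
  hemisphere, (3) slow prolonged HIT response (peak ~300 ms, tail ~1 s) in
  the medial hemisphere, (4) fast CR response in the lateral hemisphere.
  Peak amplitudes (6, 6, 3.5, 5) Hz put single-neuron responses in the
  few-Hz range seen in the imaging PSTHs. Each neuron draws one dominant
  component (probability set by a compartment-affinity table) plus small
  cross-loadings, so components overlap within compartments and within
  single neurons — deliberately non-orthogonal structure.
* **Synchrony.** Within each component's dominant population, spikes are
  generated by a thinned mother process: a mother train at the bin-wise
  maximum component rate is kept per neuron with probability
  `p · rate_n / rate_max`, and independent spikes supply the remaining
  `(1-p) · rate_n`, so marginal rates are conserved while zero-lag
  coincidences scale with the single parameter `p` (defaults 0.6, 0.5,
  0.4, 0.25 for components 1–4, mirroring the reported ordering of
  within-component synchrony strengths). Baseline spikes are independent.
* **Behavior.** Go first-lick latency = polynomial trend (default constant
  0.5 s) + Gaussian jitter with stage SDs (0.28, 0.20, 0.14) s; Go lapse
  (MISS) probabilities (0.22, 0.10, 0.02); No-go early-lick (FA)
  probabilities (0.66, 0.45, 0.15). These map the reported learning
  curves — fraction correct for Go 0.78 -> 0.98, fraction incorrect for
  No-go 0.66 -> 0.15, latency fluctuation 0.45 -> 0.22 (a mean absolute
  deviation of σ√(2/π) normalized by the ~0.5 s mean latency) — onto the
  three stages. Licking continues as a ~6.5 Hz bout (to 2.5 s in HIT,
  1.2 s in FA). Sessions progress through stages in thirds of each mouse's
  training; the recorded stage is recomputed from realized performance.
* **Calcium.** Unit transients `exp(-t/τ_d) − exp(-t/τ_r)` with
  τ_r = 10 ms, τ_d = 300 ms, sampled at 7.8 Hz; Gaussian noise with
  SD = (transient peak)/10^(SNR/20), SNR 10 dB. The SNR is defined against
  the unitary peak because the source states only "10 dB".
* **Not emulated:** dye saturation and nonlinearity, drift, neuropil
  contamination, imaging artifacts, inter-trial timing structure,
  compartment-specific baseline rates, reward-omission dynamics. Passing
  tests therefore certify the analysis code under the planted model, not
  detector or decomposition performance on real recordings.

## Spike detection

The detector estimates CS onsets finer than the frame interval by matched
filtering against an onset dictionary: for every candidate onset on the
10 ms grid, the transient kernel is evaluated at the actual frame times, so
sub-frame timing is encoded in the pattern of frame values. Events are
selected by orthogonal matching pursuit (largest residual-energy reduction
among candidates whose least-squares amplitude exceeds
`max(threshold_sd · σ_amp, 0.3)`; all accepted amplitudes are then refit
jointly by NNLS). Two refinements follow: clusters whose fitted amplitude
is ~2 are re-searched exhaustively for the best local onset *pair*
(two transients 150–300 ms apart are otherwise absorbed into one midpoint
event), and each event is re-localized by the posterior mean of its
fixed-amplitude onset likelihood over a ±0.25 s window (the raw argmax has
heavy timing tails at 10 dB). Amplitudes ≥1.5 finally emit round(a) events
on adjacent grid steps (transients are quantal; several spikes within one
frame are indistinguishable from one larger transient). Noise SD is
estimated from the MAD of a 5-frame median-filter residual.
`threshold_sd = 1.25` is part of the validation contract: it was set so the
stated simulation protocol (Poisson 1 Hz, 10 dB, 5x100 spikes, 100 ms
tolerance) lands at the protocol's reference sensitivity of ~90%; at that operating point
precision is ~0.6–0.7. Scoring matches estimated to true spikes greedily by
ascending |Δt| (ties: earlier true spike), one-to-one; sensitivity,
precision and the harmonic-mean f1 use 0 for 0/0.

## Behavior

The latency trend is the AIC-argmin polynomial of order 0–5 (order capped
at n−2 below 7 points), with Gaussian-profile AIC `n·ln(RSS/n) + 2(order+1)`
and an RSS floor of 1e−12 so numerically perfect fits choose the smallest
order. Note AIC retains a constant overfitting probability at any noise
level; exact-order recovery is only guaranteed once the floor binds.
Fluctuation = |latency − trend| / (per-mouse mean HIT/FA latency); the
trial index for trends and learning slopes is cumulative over a mouse's
sessions in training order.

## Tensor decomposition

PSTHs use 50 ms bins over [-0.5, 2) s, averaged within (session,
condition), baseline-subtracted per neuron (mean [-2, -1) s rate over all
trials), with slices of any (session, condition) having <5 trials fixed to
exactly 0. Negative entries (possible after baseline subtraction) are kept;
the non-negative model simply cannot reconstruct them.

The non-negative CP fit uses HALS column updates with a 1e−12 positivity
floor (a plain zero permanently locks a component out) and a random restart
of fully dead components; stopping at relative objective change <1e−6 or
500 sweeps. Multistart stability selection: `n_init` random non-negative
initializations are clustered by mean matched factor congruence (greedy
component matching; threshold 0.95) and the best-objective member of the
largest cluster is returned — the "most frequent solution" made precise.
Canonical form: unit-norm factor columns, scale in λ, components sorted by
descending λ; values below 1e−9 are snapped to exact 0 so the "all
coefficients zero = null neuron" rule is well defined. VAF restricts data
and reconstruction to [0, 1) s, applies a zero-phase 4th-order Butterworth
low-pass (2 Hz cutoff at the 20 Hz bin rate), and computes
`1 − var(x−x̂)/var(x)` pooled over entries. The permutation null replaces
every (neuron, trial) activity by that of a uniformly random other
(neuron, trial) — condition labels stay with the destination trial — then
rebuilds the tensor and refits per rank. topTC sampling takes the top-N
coefficients per component within each learning stage (ties by ascending
neuron id) and removes neurons sampled by more than one component;
classification is the argmax of the raw (unit-column) coefficients.

## Synchrony

Instantaneous synchrony counts distinct co-active neurons per 30 ms bin in
a 300 ms window ([first lick − 0.3, first lick) for HIT/FA — allowed to
extend pre-cue for very early licks — and [0, 0.3) post-cue for CR/MISS),
summing `C(n_k, 2)` and normalizing by `C(N, 2)`; repeated spikes of one
neuron in a bin count once. The worked scenario (10 neurons, bins with 4
and 2 co-active, 20 spikes) gives 7/45, printed as 0.15 — the printed value
is a truncation, reproduced only where that scenario is reported.
Cross-correlograms bin per trial at 10 ms over the full trial and pool
numerators and spike counts across trials (no cross-trial products);
normalization is the geometric mean √(ΣX·ΣY) (the standard CCG convention;
the source formula is typographically ambiguous). Synchrony strength is
the sum of the three lags within ±10 ms. The shift predictor rotates the
reference neuron's trial assignment by one (last wraps to first).

## Decoding

The spike-triggered lick response histograms (lick − spike) lags in 100 ms
bins over ±1 s, pooled across trials and divided by trial count and bin
width. For decoding, a common response is built from all spike and lick
events in the [0, 1) s post-cue window, and `p(l|s)` = rate/dt0 with
`dt0 = 10 Hz` — the lick-histogram sampling rate, so `p(l|s)` is the
probability of the lick falling in its observed 100 ms bin (probabilities
floored at 1e−6 and capped at 1). `p(l|S) = Π_s p(l|s)`; a lick with no
in-range spikes under a model falls back to chance `1/dt0` and is counted.
Because the product penalizes every additional spike, the model comparison
is informative in the sparse regime (a handful of in-range spikes per
trial, as for per-session topTC populations); the packaged coupled fixture
(`simulate_coupled_licking`) generates that regime — one pre-lick
synchronous volley of a small component population plus sparse uncoupled
background — and reproduces the ordering sync_topTC > all_topTC >
all_session > chance. Absolute log-likelihoods of the original recordings
are not reproducible without the raw data.

## Regression and dimensionality

The synchrony-behavior model is plain OLS,
`y ~ syn_TC1 + syn_TC2 + syn_TC3 + syn_TC4 + fraction_correct`, with trials
lacking any sampled component neurons dropped and per-component missing
synchrony coded 0; p-values are two-sided t tests; a rank-deficient design
is fatal with a collinearity report (the pipeline pre-drops structurally
constant columns at small scale). Added-variable values are the residuals
of predictor and response on the remaining predictors, shifted by their
means; the adjusted slope equals the full-model coefficient (checked to
1e−10). Between-animal change correlations difference each variable
between an animal's best- and worst-performance sessions and regress
across animals (≥3). PCA is covariance PCA on centered features (no
standardization); the participation ratio is `d = 1/Σ λ̂_i²`; k-means on
PC scores uses k = 4 with 20 seeded restarts.

A note on expectations: with the planted geometry the four components are
deliberately correlated, so the noiseless participation ratio is ~2.6 (< 4),
and with Poisson averaging noise d inflates well above the planted rank —
consistent with trial-averaged dimensionalities in the tens for the real
data. The tests assert the noiseless value lies in [2, 4] and the noisy
value stays far below the neuron count.

## Pipeline

Stages exchange data only through TSV tables in the run directory, so any
stage can run on externally supplied tables. The detect stage runs the
simulation-validation benchmark (re-detecting every generated neuron's
calcium trace would dominate runtime and feeds nothing downstream; per-
trace detection stays available via `cfpop detect`). Outputs are
byte-reproducible under a fixed config and seed (the log holds timings and
is exempt). `--reduced` scales n_init/n_perm/top_n down for smoke runs.

## Limitations

* The detector's operating point is tuned to the 10 dB GCaMP6f protocol;
  other indicators need re-tuning of `threshold_sd` and the kernel.
* The generator's components are stationary within a session; slow
  within-session drifts of response or synchrony are not modeled.
* The decoding likelihood is a scoring rule for model comparison, not a
  calibrated generative model of licking.
* Multistart HALS is a local method; stability selection makes the
  reported solution reproducible, not provably global.
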