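# Methods

This note documents the models, parameter choices and numerical conventions
behind `semgkit`, and what the synthetic experiments do and do not show.

## Signal model and conditioning

Trials are `channels × time` matrices in arbitrary units at a fixed sampling
rate (1926 Hz by default, matching common wireless sEMG hardware). Amplitude
is left unitless throughout: the analog amplification factor of the
acquisition chain is metadata, and nothing downstream depends on absolute
volts.

Conditioning is a 4th-order Butterworth band-pass, 10–500 Hz. Filtering is
zero-phase (forward–backward, `sosfiltfilt`) by default because all analysis
here is offline; a `causal=True` switch applies a single forward pass for
real-time emulation. Note that zero-phase filtering squares the magnitude
response, so attenuation at the cutoffs is 6 dB rather than 3 dB. A
Butterworth response is flat only well inside its band: noise occupying the
10–500 Hz skirts loses a few percent RMS per extra pass, which is expected
behaviour, not a defect; flatness assertions in the tests therefore probe
30–300 Hz content.

Windowing defaults — 250 ms windows, 50 % overlap, 0.5 s trimmed from each
trial end — are deliberate engineering choices, not reconstructions:
250 ms/50 % is standard for myoelectric-control latency budgets, and the
trim isolates steady-state contraction from posture-transition ramps. Window
length in samples is `round(length_ms·fs/1000)`; the hop is
`floor(N·(1 − overlap))`, at least 1; a trailing partial window is dropped.

## Time-domain features and threshold calibration

MAV and WL follow the textbook definitions. The two thresholded counts use
these conventions:

- **ZC** counts adjacent pairs with strictly opposite signs
  (`x_i · x_{i+1} < 0`) whose step magnitude `|x_i − x_{i+1}|` reaches the
  threshold. The magnitude gate uses an absolute value so the count is
  direction-independent.
- **SSC** applies the indicator to the product
  `(x_i − x_{i−1})(x_i − x_{i+1}) ≥ θ` exactly as defined; exact zeros
  (flat samples) count when θ = 0 because of the `≥` comparison.

The threshold is θ_c = R × RMS of channel *c* during a rest-calibration
trial, with one shared R for ZC and SSC (a per-feature override exists).
R is selected from the 21-value grid 0.0:0.5:10.0 by
`optimize_R`, which holds out the last training session, trains the
Hudgins pipeline at every grid value, and returns the R with the highest
validation accuracy, breaking ties toward smaller R (less aggressive
gating is more robust when accuracies are equal). Features are z-scored per
column before classification using training-fold statistics only; the
statistics are stored with the model.

## Classifier and cross-testing

The classifier is a single-hidden-layer (64-unit) multilayer perceptron
with early stopping on an automatically partitioned 15 % validation split,
trained with Adam for at most 200 epochs (scikit-learn's `MLPClassifier`).
The architecture is configurable and recorded in every result; no
architecture search is performed because the pipeline, not the network, is
the object of study.

Cross-testing treats recording *sessions* as the unit of generalization: at
level TRNk, fold *f* (of 10) trains on the k consecutive sessions starting
at *f* (mod 10) and tests on the remaining 10 − k. The contiguous rotation
is deterministic and covers every session as test data exactly 10 − k
times. Per-fold threshold calibration and normalization use only that
fold's training sessions, so no information leaks from test sessions;
this is verified bit-for-bit in the tests. Classification is per-window;
a trial-majority-vote aggregation exists (`--vote`-style analyses can be
built on `TrainedModel.predict_proba`) but per-window numbers are the ones
reported, with fold confusions pooled as counts before row-normalizing.

## Silhouette statistic

Points are per-window MAV vectors (dimension = channel count), clustered by
posture. With distance d(i, j):

- a(i): mean distance to the other members of i's cluster (divisor
  |C| − 1),
- b(i): minimum over other clusters of the mean distance to that cluster,
- s(i) = (b − a)/max(a, b), with s(i) = 0 for singleton clusters,
- š(J): mean s over cluster J, and **SC = max_J š(J)**.

SC as a max-over-clusters is unusual — the wider literature averages over
all points — so the conventional mean silhouette is always reported
alongside. The max is dominated by the best-separated posture and is
therefore less sensitive to training effects than the mean; both rise
monotonically under the simulated training schedule.

Distances default to Mahalanobis with a single covariance pooled over all
points and shrunk toward scaled identity,
Σ̂ = (1 − γ)·S + γ·(tr S/d)·I with γ = 0.1. Pooling plus shrinkage keeps
the estimate positive-definite even with small or degenerate clusters;
per-cluster covariances were rejected as singular-prone. γ = 0 on
zero-variance data raises rather than silently regularizing. The silhouette
engine is vectorized but kept deliberately simple (full n × n distance
matrix); it is verified against a naive O(n²) double loop and, for the
Euclidean case, against scikit-learn's `silhouette_samples`.

t-SNE (scikit-learn, PCA initialization, fixed `random_state`) provides the
2-D cluster visualization; it plays no quantitative role.

## Synthetic data model

Channel *c* of a posture-*p* trial is band-limited Gaussian noise —
the standard interference-pattern model of sEMG — normalized to exact unit
RMS and scaled by

a = A[p, c] · exp(ε),  ε ~ Normal(0, σ_day²),

where A is the 12 × 9 posture × channel amplitude matrix and σ_day is the
per-day trial-to-trial dispersion. The spectral carrier is 4th-order
band-pass noise centred at a posture × channel centroid with relative
bandwidth 0.6 (wide enough for realistic ZC/SSC statistics, narrow enough
that centroids are distinguishable). Channels are then mixed by a
row-stochastic crosstalk matrix with 1 − λ on the diagonal and λ/(C − 1)
off-diagonal (λ = 0.1 by default). Each session contains one 5 s trial per
posture in a seeded random order plus one rest trial (amplitude 0.05) for
threshold calibration; 10 sessions per day.

Design choices worth making explicit:

- **The training effect is amplitude-dispersion shrinkage only.** The
  default schedule σ = (0.5, 0.25, 0.1) across 3 days models an untrained
  user converging to consistent contractions under feedback. No within-day
  adaptation, fatigue, or electrode-shift dynamics are modeled.
- **The amplitude matrix has deliberate hard pairs.** Cylindrical vs
  spherical grasp and palmar vs tip pinch differ by only a few percent in
  amplitude, so amplitude-only (MAV) classification confuses them; their
  spectral centroids are pulled apart (±10 %) so the frequency-bearing
  Hudgins features can resolve them. This reproduces the qualitative
  confusion structure of grasp/pinch postures, not any subject's numbers.
- **Unbiasedness.** Band-limited noise is normalized to exact unit RMS
  before scaling, so realized trial RMS equals the drawn target exactly at
  λ = 0; crosstalk then attenuates per-channel RMS by a known, documented
  factor (≈ 1 − λ for uncorrelated channels).
- **The residual-limb fixture is illustrative.** `amputee_8ch` swaps the
  montage (BR, FCR, ECR, ED, ECU, FDP, FDS, FCU), derives FDP as a
  deep-flexor profile correlated with FDS, and uses a longer, higher
  dispersion schedule (0.7 … 0.1 over 5 days). It is a plausible scenario
  for studying information loss — `amputee_mode` removes channels and
  renormalizes, making postures that differed only on lost channels
  statistically confusable — not a reconstruction of any patient.
- Generation is bit-reproducible: every trial's RNG is seeded from
  (config seed, day, session, slot), so datasets regenerate identically and
  subsets of days can be generated independently.

**What passing tests show, and do not show.** The simulator produces
Gaussian, stationary, independently drawn trials with exactly the structure
the pipeline assumes. Success on it validates the *implementation*
(feature semantics, fold hygiene, statistic correctness) and the *direction*
of the studied effects (less dispersion → tighter clusters → higher
accuracy; spectral features > amplitude features when amplitude is
ambiguous). It does not certify performance on real sEMG, which is
non-Gaussian, non-stationary, fatigue- and electrode-placement-dependent,
and in which the printed accuracy levels depend on the subject population.

## Numerical conventions and degenerate inputs

- Dataset files are delimited text written with 17 significant digits, so
  save → load round-trips float64 samples bit-exactly.
- Confusion matrices with an empty true class keep a zero row and flag the
  row index rather than dividing by zero.
- An all-zero live activation vector scores 0 against any radar target with
  a `no_activation` flag; all-zero *target* patterns are flagged at
  construction and refused by the scorer.
- Ties in `optimize_R` resolve to the smaller R; ties in the silhouette
  max (exactly equal cluster means) resolve to the first cluster in label
  order, which cannot change the SC value.
- Problem sizes in the test-suite and the acceptance script are the shipped
  study scale (12 postures × 10 sessions × 3 days, 5 s trials at 1926 Hz)
  for the end-to-end checks, and reduced scenarios (2–5 postures, 1.5–2 s
  trials) for unit-level checks, chosen so the whole suite completes in a
  few minutes on one CPU.
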