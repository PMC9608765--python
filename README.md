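# semgkit

Surface-EMG (sEMG) hand-posture recognition for myoelectric control, with a
focus on how *user training* — not just better classifiers — improves
recognition. The package implements the full offline pipeline used to study
radar-plot visual-feedback training of 12 hand postures from multichannel
forearm sEMG, plus a synthetic sEMG simulator so that every stage runs and is
testable without human recordings.

**Who it is for:** researchers in myoelectric prosthesis control and
biomedical signal processing who want a reproducible, end-to-end reference
pipeline (conditioning → features → classification → cluster-variability
analysis → biofeedback targets) with exact, oracle-tested feature semantics.

## The pipeline

1. **Conditioning** — 4th-order Butterworth band-pass, 10–500 Hz, applied
   zero-phase per channel (`signal_io.bandpass_filter`); trials are sliced
   into 250 ms windows with 50 % overlap after trimming 0.5 s transition
   ramps from each end.
2. **Time-domain features** (`features`) — per window and channel, either
   MAV only or the Hudgins set:

   - MAV = (1/N) Σᵢ |xᵢ|
   - WL = Σᵢ |xᵢ₊₁ − xᵢ|
   - ZC = #{i : xᵢ·xᵢ₊₁ < 0 and |xᵢ − xᵢ₊₁| ≥ θ}
   - SSC = #{i : (xᵢ − xᵢ₋₁)(xᵢ − xᵢ₊₁) ≥ θ}

   with the noise-rejection threshold θ calibrated per channel as
   θ = R × RMS(rest signal), R swept over the grid 0.0, 0.5, …, 10.0
   (`calibrate_threshold`, `optimize_R`).
3. **Classification** (`classify`) — a multilayer perceptron (one 64-unit
   hidden layer, early stopping) evaluated by session-wise ten-fold
   cross-testing: at training level TRNk, fold *f* trains on *k* consecutive
   sessions of a 10-session day and tests on the other 10 − k, rotated over
   all 10 start positions. Reported as mean ± SD fold accuracy and a
   row-normalized 12 × 12 confusion matrix.
4. **Variability analysis** (`variability`) — per-window MAV vectors
   (one dimension per channel) clustered by posture. For point *i*:
   a(i) = mean within-cluster distance, b(i) = smallest mean distance to
   another cluster, s(i) = (b − a)/max(a, b) (0 for singletons), and the
   summary statistic SC = max over clusters of the mean silhouette š(J).
   Distances are Mahalanobis with a shrinkage-regularized pooled covariance;
   a t-SNE 2-D embedding is provided for visualization.
5. **Feedback targets** (`feedback`) — per-posture radar patterns (mean
   channel MAV scaled by the peak channel) with a cosine match score, the
   computational core of radar-plot biofeedback training.

The simulator (`synthetic_data`) generates interference-pattern sEMG as
amplitude-modulated band-limited Gaussian noise with posture × channel
amplitude and spectral-centroid profiles, trial-to-trial log-normal amplitude
dispersion that *shrinks over training days* (the modeled training effect),
inter-electrode crosstalk, and per-session rest trials for threshold
calibration. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import semgkit as sk
from semgkit.features import FeatureConfig, HUDGINS, MAV_ONLY

cfg = sk.load_fixture_config("healthy_9ch")      # 12 postures, 9 channels,
recs, truth = sk.generate_dataset(cfg)           # 3 days x 10 sessions

day1 = [r for r in recs if r.day_id == 1]
res = sk.cross_test(day1, k=9, feature_config=FeatureConfig(HUDGINS, 0.5), seed=1)
print(f"TRN9 Hudgins day 1: {res.mean_accuracy:.1f} +/- {res.sd_accuracy:.1f} %")

windows = sk.segment_dataset([sk.bandpass_filter(r) for r in day1], filter_spec=None)
fm = sk.extract_features(windows, FeatureConfig(MAV_ONLY, 0.0))
sc, rep = sk.silhouette_coefficient(sk.mav_pointset(fm))
print(f"day 1 SC = {sc:.4f} (mean silhouette {rep.mean_silhouette:.4f})")
```

prints (seed 1):

```
TRN9 Hudgins day 1: 58.8 +/- 8.7 %
day 1 SC = 0.8820 (mean silhouette 0.0685)
```

Day 1 simulates an untrained user (amplitude dispersion σ = 0.5): nine
training sessions recognize the 12 postures at ~59 %. Rerunning on day 3
(σ = 0.1, the trained state) yields 98.3 %, and the mean silhouette of the
MAV clusters rises from 0.07 to 0.23 — the computational signature of
feedback training: less trial-to-trial variability, tighter posture
clusters, higher accuracy.

The same experiment is available from the shell:

```bash
semgkit simulate --out data/ --seed 1
semgkit crosstest --data data/ --trn 9 --set HUDGINS --r 0.5 --day 1 \
    --seed 1 --out result.json
semgkit run --out results/ --seed 1          # full multi-day report
```

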