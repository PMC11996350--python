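# Methods

This note documents the models, algorithms, priors, parameter defaults
and numerical choices implemented in `hepkit`, and what the synthetic
cohorts do and do not emulate.

## Synthetic recordings

Each simulated session mimics a wakeful-rest experience-sampling
protocol: 5 runs × 10 thought probes (50 trials), probes separated by
integer intervals drawn uniformly from 15–45 s, recorded at 250 Hz on
31 scalp channels (extended 10/20 positions from MNE's template montage)
plus one ECG channel.

**Cardiac signal.** The ECG is a train of PQRST complexes — five
Gaussian bumps with fixed latencies/widths/amplitudes relative to the R
peak (R: 900 µV, σ = 10 ms) — on an R–R process with i.i.d. Gaussian
inter-beat intervals (default mean heart rate 70 bpm, IBI SD 60 ms,
floored at 300 ms), plus 5 µV white noise. R times are recorded as
ground truth; with `ibi_sd = 0` the train is an exact metronome, which
pins down detector alignment to the sample.

**Scalp signal.** Every EEG channel carries 1/f noise (spectrally
shaped Gaussian noise, exponent 1, RMS 10 µV). The cardiac template
leaks into each channel as a cardiac-field artifact (CFA) with a gain
that decays with distance from a source below Oz — the ECG electrode
sits on the back, so posterior channels are most contaminated — spanning
0.2–1 % of the cardiac amplitude (≈2–9 µV at the R peak), jittered per
participant. Posterior channels (O1, O2, Oz, P3, P4, P7, P8, Pz) carry
amplitude-modulated 10 Hz alpha (default 5 µV, slowly varying envelope).

**Arousal and the HEP.** A latent trial-level arousal state follows an
AR(1) across trials (autocorrelation 0.6, stationary unit variance)
plus a participant-level mean (SD 0.3). The observed 0–100 rating is
`round(50 + 15·latent)` clipped to [0, 100]; at these scales fewer than
10 % of ratings clip. Frontal channels (Fp1, Fp2, F3, F4, Fz, FC1, FC2)
receive a heartbeat-locked Gaussian bump (latency 348 ms, σ = 12 ms)
whose amplitude for beats inside trial *k*'s pre-probe window is

    a_k = hep_base_amp + slope_i · latent_k,

with base amplitude 1 µV and participant slope

    slope_i = hep_arousal_slope + sign(hep_arousal_slope)·anxiety_moderation·z_i
              + heterogeneity·ε_i,

default −0.75 µV per arousal z-unit, moderation 0.3 µV/z per
anxiety z-score, heterogeneity SD 0.25. Beats outside pre-probe windows
receive the base amplitude. Trait anxiety z_i maps to a GAD-7-like
composite `clip(round(8 + 4 z_i), 0, 21)` and a correlated STAI-S-like
composite. Defaults give a detectably negative group-level coupling —
the direction the pipeline is designed to recover — moderated by
anxiety.

`drift_component` optionally injects a probe-locked but **not**
heartbeat-locked confound: a sinusoid (1.3 Hz, random phase per trial)
spanning each 10 s pre-probe window at frontal channels with amplitude
proportional to the trial latent. It is the positive control for the
surrogate analysis's specificity: a real arousal-coupled signal that
should *not* survive the surrogate test.

**Determinism.** Per-participant seeds derive from the master seed via
`SeedSequence([master, index])`, so any participant regenerates
identically in isolation. `draw_cohort_profiles` returns
participant-level ground truth (anxiety, slopes) without synthesizing
signals, for large calibration studies.

**What the generator does not emulate:** eye blinks and myogenic
artifacts, ICA mixing, electrode impedance drift, heart-rate reactivity
to arousal, ectopic beats, realistic rating distributions. Passing
recovery tests therefore demonstrates correctness of the analysis
machinery under the stated signal model, not robustness to every
artifact class in human data. The R–R statistics are a plausibility
choice (not taken from any dataset); the 700 ms exclusion dropout is
consequently far lower here (<1 %) than in real recordings, where
physiological HRV and detector noise dominate that number.

## Preprocessing and epoching

Recordings are resampled to 250 Hz if needed, band-passed 1–55 Hz
(zero-phase FIR via MNE), and the 31 scalp channels are re-referenced to
their common average; the ECG channel is filtered but never enters the
reference. No baseline correction is applied anywhere: heartbeat-locked
designs have no true baseline, since pre-R activity mixes the previous
beat's response with preparation for the next.

The pre-probe window is exactly [onset − 10 s, onset). R peaks are
detected by a Pan–Tompkins-style detector (5–35 Hz band-pass, squared
derivative, 150 ms integration, adaptive threshold at 20 % of the 99.5th
percentile, 250 ms refractory period, raw-maximum refinement within
±50 ms); on synthetic ECG it recovers every beat to the sample, and at
SNR 10 its sensitivity and positive predictive value both exceed 0.99.

The 700 ms exclusion is a greedy forward scan: a beat is dropped when it
follows the last *retained* beat by less than 700 ms. The rule is
idempotent. It applies to HEP epoching only; heart rate and RMSSD use
the unfiltered series. Epochs run from −100 ms to +650 ms on the grid
t = −0.100 + i/f<sub>s</sub> (188 samples at 250 Hz, last sample
+648 ms); an epoch is kept whenever it lies inside the recording, even
if it extends past the window end (the window gates R-peak selection
only). Artifact rejection is a deliberate, fully deterministic
stand-in for learned procedures: epochs whose maximum peak-to-peak
amplitude across channels exceeds 150 µV (configurable) are dropped.

Statistical analysis is restricted to 250–450 ms post-R (boundary
samples included; on the 250 Hz grid this is 252–448 ms): earlier
samples overlap the CFA, later ones exceed the window where scalp HEP
effects are reported. Regressions use the raw 0–100 rating as predictor
(slopes in µV per rating point); the downstream one-sample *t* on slopes
is invariant to predictor scaling, so this choice only affects units.
The median split assigns rating-ties to the low half — one of the two
defensible conventions; it is configurable in no way because the paired
test is insensitive to which half absorbs the tie mass given trial
averaging.

## Cluster permutation inference

Pointwise statistic: one-sample *t* across participants (df = n−1),
thresholded at the two-tailed p = .01 quantile. Points with zero
variance across participants get t = 0 (with a warning) rather than ±∞.
Clusters are connected components of same-sign suprathreshold points,
where (c, t) touches (c, t±1) and (c′, t) for neighboring channels c′.
Adjacency comes from 3D template positions with a 6.2 cm cutoff, giving
≈5 neighbors per channel on the 31-channel montage.

The cluster statistic is the mass Σt. The permutation scheme flips the
sign of whole participant maps (for the paired test, condition swapping
equals sign-flipping the difference maps, and the implementation reduces
it to exactly that); each permutation contributes the maximum |Σt| over
its clusters, or 0 if none forms — the max-mass null controls the
family-wise error rate. Monte-Carlo p-values use (1 + m)/(1 + N);
when `n_perm="all"` (or N ≥ 2ⁿ) the test enumerates all 2ⁿ sign
patterns and reports the exact m/2ⁿ. Sign-flip t maps are vectorized:
flipping signs leaves per-point sums of squares unchanged, so only the
mean is recomputed per permutation.

## Surrogate-heartbeat control

The observed statistic is the signed Σt of the cluster with the largest
|Σt| from the median-split paired cluster test on real heartbeats. Each
null iteration draws, per pre-probe window, k distinct surrogate sample
indices uniformly in the window (k = the number of true heartbeats in
that window, counted before the 700 ms exclusion; collisions with true
R-peak samples are excluded; no minimum gap between surrogates), then
reruns the *identical* epoching → rejection → trial-average →
median-split → paired-cluster code path, recording the signed max-|Σt|
mass (0 if no cluster). After 100 iterations (default) the decision is
two-tailed at 5 %: significant iff the observed statistic exceeds the
97.5th or falls below the 2.5th percentile of the null. Fewer than 40
iterations trigger a resolution warning.

## Hierarchical Bayesian arousal models

For each physiological measure x (heart rate, RMSSD, time-on-task =
trial order number, log alpha power), with y = arousal z-scored within
participant:

    y_ij = (β₀ + b₀ᵢ) + (β₁ + b₁ᵢ) x_ij + ε_ij,
    ε_ij ~ N(0, σ²),  (b₀ᵢ, b₁ᵢ) ~ N(0, Σ_b).

Priors are conjugate and weakly informative, scaled to the data:
β ~ N(0, diag(10·sd(y), 10·sd(y)/sd(x))²), σ² ~ Inv-Gamma(2, var(y)),
Σ_b ~ Inv-Wishart(ν₀ = 4, S₀ = diag(0.5·sd(y)², 0.5·(sd(y)/sd(x))²)).
Sampling is by Gibbs with the fixed effects drawn from their
*collapsed* conditional (random effects marginalized per participant via
2×2 Woodbury blocks) — plain alternation of β and bᵢ mixes poorly when
they are strongly coupled; the collapsed step brings split-R̂ to ≈1.000
on all parameters. Four chains of 5000 draws (2500 warm-up) by default;
split-R̂ (chains halved, no rank normalization) must be ≤ 1.01 on every
tracked parameter or summaries are withheld. The group slope is reported
as posterior mean with the 95% credible interval; an interval excluding
zero counts as evidence of a nonzero relationship. In recovery
simulations the 95% interval covers the true slope at its nominal rate.

## Bayes factors

One-sample/paired JZS Bayes factor: Cauchy(0, r) prior on the
standardized effect (default r = √2⁄2), written as the scale mixture
δ|g ~ N(0, g), g ~ Inv-Gamma(½, r²/2), and integrated over log g by
adaptive quadrature with max-shift stabilization (accurate to <1 %
against dense-grid integration; overflow-safe at extreme t or n).
Regression Bayes factor: Zellner–Siow setup for one predictor,
g ~ Inv-Gamma(½, n·r²/2), BF₁₀ as the standard one-dimensional integral
in n and R². Labels follow the canonical thresholds: <3 anecdotal,
3–10 substantial, 10–31.6 strong, 31.6–100 very strong, >100 decisive.

The ECG confound check pools trials across participants (no participant
term) when regressing peak/mean ECG amplitude in the cluster window on
arousal, reporting BF₀₁.

## Spectral features

Morlet decomposition uses 50 logarithmically spaced frequencies from 2
to 30 Hz with n_cycles = freq/2 (constant temporal SD 1/4π s, spectral
SD 2 Hz), unit-energy plain Morlet wavelets (no zero-mean correction:
its DC term skews peak localization at low f·σ_t, and the 1 Hz
high-pass already removes DC). Power is in µV²; samples inside the
wavelet half-support (5σ_t) are flagged as edge-contaminated. Alpha
power is the mean over the 8–12 Hz bins (the decomposition range is
fixed; the band bounds are a configurable convention) and the eight
parieto-occipital channels, log-transformed before modeling.

## Pipeline, seeds, problem sizes

A single master seed determines everything: per-participant simulation
seeds, permutation draws, surrogate iterations, Gibbs chains — each via
named sub-seeds. Identical configuration + seed gives byte-identical
reports (timestamps aside). Heavy stages cache on disk keyed by the
configuration's content hash.

Simulation studies in the test suite and the acceptance script run at
desk scale: cohorts of 6–12 participants, 10–50 trials, 200–1000
permutations, 40–50 surrogate iterations, 2000–3000 Gibbs draws. These
sizes were chosen so the complete validation runs on one CPU in minutes;
the statistical criteria (coverage rates, error calibration, recovery
probabilities) are evaluated at their nominal levels regardless of
scale, with planted effect sizes scaled up where trial counts are
scaled down so that power is comparable to a full-size study.

## Known limitations

* The artifact-rejection stand-in is amplitude-only; it will not catch
  low-amplitude structured artifacts that learned methods address.
* The surrogate null and cluster permutation assume exchangeability
  that the simulator satisfies by construction; real data can violate
  it (e.g., nonstationary noise across runs).
* The Gibbs sampler covers the Gaussian random-slope model only; no
  frequentist mixed-model p-values are produced.
* EDF input/output is not implemented; recordings use the float32 +
  JSON-sidecar dialect (lossless round-trip at float32 precision).
* Bundles are held in memory per participant (~100 MB at full session
  length); very long recordings would need chunked processing.
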