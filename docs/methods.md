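# Methods

This note documents the models, numerical choices, and open design
decisions behind `adaptivenf`. It is the package's account of its own
science; every empirical statement here is something the test suite or the
acceptance script computes.

## Task designs

Training runs are a 2 (attention: face/word) × 2 (word valence:
trauma/neutral) factorial of twelve 30-trial blocks (1 s per trial), three
blocks per cell, separated by 8 s of rest, with a rest block after every
task block including the last (whether a trailing rest existed in the
original paradigm is not specified; a uniform rule keeps the TR grid
regular). At the default TR of 2 s this gives 12 × 15 + 12 × 4 = 228 TRs.
Feedback runs prepend 20 resting TRs (40 s) and use six attend-face plus
six attend-word blocks, all with trauma-dominant words: 248 TRs.

Within a block, category counts are exact integer allocations (90% → 27 of
30 trials are go, dominant-valence, and female-face trials respectively)
rather than Bernoulli draws, so the proportions hold in every block. No two
no-go trials are adjacent — a standard go/no-go constraint that prevents
degenerate inhibition sequences. When the minority count of the attended
category equals the no-go count, the rare attended stimuli are placed on
the no-go trials, so "no" responses correspond to rare-category
identifications.

Sensitivity defaults to no-go accuracy (the proportion of no-go trials with
a withheld response), which is the measure the group analyses plot; d′ with
the log-linear correction, z((hits+0.5)/(n_go+1)) − z((FA+0.5)/(n_nogo+1)),
is available as an alternative.

## Generative subject model

The simulator is intentionally minimal: it encodes exactly the statistical
structure the analysis chain is designed to detect, and nothing more.

**Spatial patterns.** Each subject has a base activation map p₀ and a
difference map d — smoothed (σ = 1.5 voxels) unit-RMS Gaussian random
fields restricted to an ellipsoidal "gray matter" mask (~670 voxels of a
12×12×12 grid; large enough for cluster tests, small enough for
second-scale tests). The two attentional states activate
pattern_face = p₀ + ½·s·d and pattern_word = p₀ − ½·s·d, where s is the
`separability` parameter; at s = 0 the conditions are indistinguishable by
construction.

**Latent attention state.** A per-TR state s_t ∈ [0, 1] relaxes toward an
engagement level each TR:

    level_t = 0.5 + compliance · attenuation_t · (s_instructed − 0.5)
    s_t = clip(s_{t−1} + (level_t − s_{t−1}) + feedback_t + N(0, σ_s))

with s_instructed = 1 (attend-face), 0 (attend-word) or 0.5 (rest), and
attenuation_t = `valence_attenuation` during trauma-word blocks for PTSD
subjects, 1 otherwise. Compliance therefore sets the *sustained depth* of
engagement rather than the approach rate: a half-compliant subject settles
halfway between neutral and the instructed state. This choice matters —
scaling only the approach rate produces transient group differences that
vanish within a few TRs and leaves nothing for the regulation GLMs or the
decoder to detect. In closed-loop mode,
feedback_t = responsiveness · (target_opacity − 0.5) · (s_instructed − s_t):
high opacity (positive feedback) pulls the state further toward the
instructed pole, low opacity pushes it away, emulating the
task-difficulty contingency.

**BOLD signal.** The noiseless signal is the causal convolution of the
canonical double-gamma HRF with the stimulus-gated pattern mixture
s_t·pattern_face + (1−s_t)·pattern_word (zero during rest), on a baseline
of 100 a.u. The generation HRF is identical to the analysis HRF, so the
noiseless limit (compliance 1, σ_s = 0) is exactly the convolution of known
boxcars — a property the tests exploit. Noise is per-voxel AR(1) Gaussian
(φ = 0.3, stationary SD = `noise_sd` = 1) plus slow sinusoidal drift
(amplitude 0.5, periods 100–300 s). Head motion is a sum of slow sinusoids
(0.01–0.05 mm/deg) plus transient spikes of 0.5–1.5 mm on a random
translation axis at rate 0.02/TR, guaranteeing FD > 0.4 mm events for the
censoring tests.

**Behavior.** P(correct no-go) = logistic(−3.3 + 1.5·opacity +
5.0·compliance) and P(correct go) = logistic(0 + same terms); the paradigm
provides no generative behavioral model, so the constants were chosen to
give realistic accuracies (controls ≈ 0.8, PTSD ≈ 0.7 no-go accuracy at
balanced opacity) with a compliance effect detectable at cohort size
10 + 9. Behavior is monotone in both opacity and compliance by
construction.

**Cohorts.** `generate_cohort` draws 10 PTSD + 9 control subjects by
default. Compliance ~ N(0.78, 0.12) for controls and N(0.62, 0.12) for
PTSD, clipped to [0.35, 0.98] (the clip keeps subjects off the accuracy and
behavior ceilings, where all between-subject variance would be crushed);
PTSD valence_attenuation ~ U(0.25, 0.95), controls fixed at 1; separability
~ N(0.25, 0.02); noise SD ~ N(1.0, 0.05); age ~ U(22, 55) and education ~
U(10, 20) as covariates. The default separability of 0.25 places
cross-validated decoding accuracy near 0.85 — clearly above chance, clearly
below ceiling — with realistic between-subject spread. These distributions
plant the two qualitative group effects the analyses should recover:
poorer brain-state regulation in PTSD (via lower compliance and trauma
attenuation) and a weaker accuracy→sensitivity coupling in PTSD during
trauma blocks (attenuation varies independently of compliance, decoupling
trauma-block decodability from behavior only in that group).

## Preprocessing

FD is the sum of absolute temporal differences of the six rigid-body
parameters, with rotations converted to arc length on a 50 mm sphere (the
field-standard convention). Because the measure can also be read as a raw
parameter-difference sum, `rotation_radius_mm=None` disables the
conversion. Censoring: FD > 0.4 mm censors the TR and its successor; a kept
TR whose preceding and following TRs are both censored is censored as
isolated (a boundary TR has no such pair and is never isolated); a run
losing ≥ 50% of TRs is censored entirely. The Volterra nuisance set is
[R R² R_{t−1} R²_{t−1}] (lag zero-padded at row 1) plus CSF and WM means —
26 columns. The 128 s "bandpass" is implemented as a high-pass via
discrete-cosine drift regression: a single stated cutoff defines drift
removal, not a band. Normalization modes (percent signal change, z-score,
detrend, high-pass) all compute their statistics over uncensored TRs only
but transform every row, preserving alignment. Processing order is
detrend → high-pass → nuisance → scaling by default and configurable, since
the upstream toolchain's internal order is not fully reconstructible.

## Decoding

The classifier is an SVC (libsvm) with RBF kernel, C = 1, bandwidth
γ = 1/(n_features·var) (the common "scale" heuristic; only kernel and cost
are prescribed), solver tolerance 1e−8 so that label-flip antisymmetry of
the decision values holds to ~1e−6. Cross-validation holds out one
attend-word and one attend-face block jointly per fold (the j-th of each in
block-index order; the pairing rule is otherwise unconstrained), retrains,
and averages per-fold accuracy until every block has served as test data;
accuracy is computed separately for trauma- and neutral-word blocks.
Fold-wise z-scoring uses training-fold statistics by default
(leakage-free); a literal mode that standardizes before splitting exists
for comparison. Accuracy saturates near 0.93 even for arbitrarily strong
signal because block-transition TRs carry the HRF-lagged previous state —
a genuine property of block-design decoding with unshifted labels, not a
bug.

Backward weights from the RBF machine use the pre-image approximation
w = Σᵢ αᵢyᵢxᵢ over support vectors; a spatial map of a nonlinear machine is
not uniquely defined, and a linear-kernel mode gives the exact primal
correspondence. The forward encoding transform A = Cov(X)·w / var(Xw)
(normalized to unit maximum absolute value) converts the decoder into an
activation pattern; on suppressor constructions the forward map
down-weights noise-only voxels that the decoder must use, which the tests
verify against the generative pattern difference.

## Real-time loop

Incremental normalization keeps per-voxel running sums (n, Σt, Σt², Σy,
Σty, Σy²), fits the linear trend from the sums, and standardizes the
current residual by the running residual SD — O(voxels) per TR, exactly
equal to batch recomputation (verified to 1e−9). The first 20 volumes are
warmup: ingested into the statistics but producing no prediction, so the
first HD appears at TR 21. The opacity chain is sigmoid (slope 1.0 by
default — the slope only rescales HD units and is configurable), affine
scaling to [0.17, 0.83], three-value temporal smoothing of the raw scaled
values starting at the fourth value of each block, and
round-half-away-from-zero quantization to the 0–255 alpha pair (face and
word alphas move oppositely; pre-quantization opacities sum to 1 exactly).
Smoothing history resets at block starts because each block begins at
balanced opacity; carrying history across the rest gap would contradict
that. In attend-word blocks the HD is negated before the sigmoid — the
unique monotone implementation of "moving away from the desired state
masks the target". The opacity computed at TR t is shown on the two trials
of TR t+1; the first TR of each block shows 0.5/0.5.

Two ambiguities are resolved by documented defaults: smoothing operates on
raw (not recursively smoothed) values, and warmup rest TRs remain in the
detrend fit after task onset.

## Statistics

The canonical HRF is gammaPDF(t; 6, 1) − gammaPDF(t; 16, 1)/6, sampled at
the TR, truncated at 32 s, peak-normalized (peak ≈ 5 s). Design matrices
contain an intercept and two HRF-convolved block boxcars; when a feedback
opacity trace is supplied, two parametric modulators (instruction × target
opacity) are mean-centered within their instruction blocks before
convolution to decorrelate them from the block main effect (centering is
switchable). Regulation betas are OLS of the HD trace on this design with
censored/invalid TRs dropped; because the boxcars are 0/1, good regulation
appears as a positive attend-face beta and a negative attend-word beta, so
the instruction-consistent score multiplies each beta by its instruction
label. Voxelwise GLMs add the nuisance columns and share a common df per
map (censoring is equal across voxels of a run). Group models are REML
linear mixed models (statsmodels MixedLM) with by-subject random
intercepts and slopes for within-subject factors; when the full random
structure fails at desk-scale n the structure is simplified stepwise
(slopes → intercept-only) and flagged. Contrast codes are PTSD +1 /
control −1, attend-face +1 / attend-word −1, trauma +1 / neutral −1.
Constant covariates are dropped so the fit equals the covariate-free
model. No multiplicity adjustment is applied across the several mixed
models. Cluster-extent thresholding applies the two-sided |t| threshold at
uncorrected p < 0.001 and keeps face-connected components of ≥ 13 voxels;
the extent is applied as a fixed constant — its derivation from noise
autocorrelation simulation is out of scope.

## What the tests do and do not show

Passing tests demonstrate that every printed pipeline constant is
implemented exactly, that the fast implementations equal brute-force
oracles, and that the full closed loop recovers planted effects of the
expected sign at the study's sample size (30 replicate cohorts of 10 + 9,
one feedback run per subject, two training runs — sizes chosen to keep the
whole suite at desk scale). They do not show that the pipeline recovers
effects from real BOLD data: the generator has iid-across-voxel AR(1)
noise, no physiological or spatially correlated noise, no anatomy, no
registration error, and a one-dimensional attention state. Reported group
t-statistics from real participants are therefore not reproduction targets
anywhere in the package.
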