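# Methods

`dementnet` implements a confound-masked, multi-input classification
framework for heterogeneous 3D brain images, together with the synthetic
phantom cohorts used to exercise and validate it end to end on a single
CPU. This note records the model, the study conditions the generator
encodes, the numerical choices, and the limitations we know about.

## The model

**Per-image encoder.** Each volume is center-cropped/padded to a fixed
grid (default 32³), z-normalized within a brain mask (voxels above the
70th intensity percentile — the phantom brain occupies the bright
minority of the field of view), cut into non-overlapping cubic patches
(default 8³), and encoded by a small 3D vision transformer: linear patch
embedding, learned positional embeddings, a prepended summary token, and
pre-norm transformer blocks. Two linear maps read the summary token into
the mean and log-variance of a diagonal-Gaussian latent (default
d = 128). At inference the latent is the mean, deterministically; during
training a reparameterized sample feeds the classifier, and a
KL(q ‖ N(0, I)) term keeps the latent distribution Gaussian, which
stabilizes the Mahalanobis confidence measure below.

**Token stack.** A patient contributes 1–14 images plus sex and
ethnicity. Image latents fill slots 0–13 with a sinusoidal positional
encoding of the age at scan (years as the position index) added
per-image; slots 14–15 hold sex and ethnicity tokens — deterministic
unit-norm pseudo-random vectors obtained by hashing the category string
(SHA-256 seeded), with a dedicated token for missing ethnicity rather
than imputation. Empty slots are zero vectors, excluded from attention
and from pooling, so outputs depend only on occupied slots (this is
tested bit-for-bit). A second transformer runs over the 16 tokens;
numeric age (mean age at scan / 100) is concatenated to the masked
mean-pooled representation before independent per-task sigmoid heads.
Age therefore enters twice — as a per-image positional encoding and as a
numeric feature at the head — so the model has no incentive to extract
age from the image content itself.

**Confound masking.** Per-image confounds are modality, angle, slice
thickness bin (≤1.5 / 1.5–3 / >3 mm), sequence tag, site, sex, and
10-year age bin. Training alternates GAN-style:

1. *Discriminator step*: one linear head per confound category is
   trained by cross-entropy to predict the **true** confound value from
   the detached image latents. Gradients never reach the encoder
   (asserted in tests by parameter partition).
2. *Encoder step*: the encoder/classifier minimize task cross-entropy
   plus (i) the adversarial term — the same heads, now frozen, driven
   toward the **modal** (most frequent) value of each category, so CT
   latents are pushed to look like the majority MR latents and so on;
   (ii) a latent cluster/de-cluster term; (iii) the KL term.

The cluster/de-cluster loss for a latent I with label l and confound c is

    ‖I − μ_{L=l}‖ − ‖I − μ_{L≠l}‖ + ‖I − μ_{C≠c}‖ − ‖I − μ_{C=c}‖

with batch-mean group centers (μ over other groups is the unweighted
mean of their means): same-label points are pulled together while each
point is pulled toward the *other* confound groups' means, merging
confound clusters. Three engineering choices matter and were validated
on the synthetic benchmark:

- the adversarial and de-cluster terms act on the deterministic **mean**
  latents — the representation probes and the confidence measure see at
  test time — while label clustering acts on the sampled latents, whose
  reparameterization noise prevents the representation from collapsing
  onto per-label points;
- confound de-clustering is computed **within each label group**.
  Confounds are correlated with the label by construction, so merging
  unconditional confound means fights the task separation; conditioning
  removes that tug-of-war, which we found otherwise destabilizes the
  adversarial game and leaves residual probe-recoverable confound
  signal;
- de-clustering is averaged over all confound categories each step
  rather than cycling one category at a time.

Loss weights default to classification 1.0, adversarial 1.0, cluster
0.1, KL 0.001, with the confound de-cluster component scaled ×8
(effective 0.8); heavier adversarial weights overshoot — the game
oscillates and re-injects confound structure — and lighter de-clustering
leaves leaks on some initializations. An optional task-only warmup
(`adversarial_warmup_steps`) delays the game; 50 warmup steps make
optimization reliable when the planted signal is small and focal.
Ablations (`adversarial=False`) disable both the adversarial
cross-entropy and the confound de-cluster half; label clustering and KL
remain.

**Age-matched resampling.** Each step draws an equal case/control batch
for one task; controls are resampled (with replacement) from the same
10-year age bins as the drawn cases, falling back to the nearest
occupied bin. No patient is ever excluded — atypically aged patients are
simply rarer in batches. With a planted 20-year population age gap the
mean batch gap is below one year.

**Mahalanobis confidence.** After training, the latent bank stores, per
task and label value, the mean μ and ridge-regularized covariance
S + εI (ε = 10⁻³·trace(S)/d; ×10 harder when fewer than d/4 images) of
the training images' latent means. A test image's confidence is
(I − μ)ᵀ S⁻¹ (I − μ) against its predicted label's bank entry; the
thresholded quantity is the per-dimension mean (raw / d), making the
default cutoff 1.2 independent of the latent width. Images above the
cutoff are flagged out-of-distribution and can be excluded from
evaluation.

**Attention parcellation.** The summary token's attention over patches —
either the raw final layer averaged over heads, or attention rollout
(residual-corrected head-averaged matrices multiplied through the
layers) — is upsampled to voxels by nearest-patch assignment and
z-scored within the brain mask. Per disease, at least 20 such volumes
are averaged per parcel of the aligned parcellation; parcels with mean
z ≥ 1 (one SD above average, the 68th percentile) are flagged. We
z-score per image first and then average, and we found rollout markedly
more stable across initializations than the raw last layer (below).

**Evaluation machinery.** AUC is the Mann–Whitney probability that a
random case outscores a random control (ties ½), with per-site,
confidence-stratified, modality-combination (pairs plus singleton
diagonal; image-count buckets 1 / 2–5 / 6–10 / 11–14) and first-visit
variants. The metadata baseline is a 200-tree random forest on age, sex,
ethnicity, modality, angle, slice thickness and sequence — never any
image-derived quantity — and the additive value of imaging is the
imaging AUC minus this baseline's. The comorbidity scan scores each
patient by 1 − |Y − Y′|, and per ICD code reports the signed performance
effect, Kruskal–Wallis H/p of score against code presence, chi-squared
dependence (no continuity correction) of code on label,
Benjamini–Hochberg adjusted p-values, and the residual from a
least-squares regression of effect on chi-squared across codes
(standouts above the line).

## The synthetic cohorts

Phantoms are 32³ volumes: a brain ellipsoid with a cortex shell and four
interior ellipsoid analogs (ventricle, hippocampus, caudate, brainstem),
each with a base intensity. The generator plants, with one seed driving
everything:

- **disease effects** — per task, per parcel radius scales and intensity
  shifts (default dementia: hippocampus ×0.8, ventricle ×1.3);
- **demographics** — cases N(72, 8²) years vs controls N(52, 14²) (a
  20-year gap), balanced sex with a ±3% global size effect, ethnicity
  missing at 37% and 8.6% Hispanic among the answered;
- **acquisition confounds** — per-modality intensity transfer curves
  y = gain·x^γ + offset plus Gaussian noise (T1 is the identity; the
  second modality is a FLAIR-like contrast curve (0.7, 2.6, 0.1), a
  *nonlinear* change chosen because per-image normalization removes
  affine intensity differences exactly); smooth per-site multiplicative
  polynomial bias fields (amplitude 0.10); a modality–label contingency
  (default: the modality agrees with the label 60% of the time);
- **comorbidities** — codes with control prevalence and an odds
  multiplier given the disease label (e.g. hypertension I10: 0.20, ×3);
- 1–14 images per patient (truncated geometric, mean ≈ 2.2); aligned
  ground-truth parcellations; age/ventricle trends of 1%/3% per decade.

Out-of-distribution images reuse the same phantom family under a stated
shift: bias-field amplitude ×k, noise ×k, or an unseen modality tag with
its own transfer curve.

What the phantoms do **not** emulate: anatomy (no folding, no
registration), scanner-specific artifacts beyond smooth bias and
Gaussian noise, longitudinal change within a patient, label noise, and
code/medication errors. Passing tests therefore demonstrate that the
machinery behaves as designed under controlled signal and confounding —
not that the model reaches any particular performance on clinical data.

## Preset experiments and their conditions

The `experiments` module fixes the desk-scale study conditions (latent
width 32, ViT width 32, 300–500 steps, batch 8, n = 120–500 patients;
each training run is under two minutes on one CPU):

- **Confound masking** — n = 200, the default biomarker plus the
  FLAIR-like modality signature at 60% label agreement. Linear probes on
  frozen per-image latents measure disease AUC and modality accuracy on
  a held-out quarter. Note the information floor: with a strong
  biomarker in the latents, a modality probe can reach ~0.60 accuracy
  purely through the label–modality contingency, so "masked" means
  accuracy near that floor, not near 0.5. The ablation arm runs on a
  confound-separable variant (95% agreement), the shortcut-learning
  regime in which a no-adversary model demonstrably *keeps* modality in
  its latents (probe ≥ 0.9).
- **OOD detection** — bias amplitude ×5 images against held-out
  in-distribution images, scored by normalized Mahalanobis distance
  against the better-matching label bank.
- **Null controls** — a null-effect cohort (no disease, age, sex,
  modality or site signal): held-out imaging AUC and, on a larger
  2 000-patient metadata-only cohort (volumes unrendered), the random
  forest baseline; both sit at chance.
- **Attention recovery** — the disease signal is confined to the
  hippocampus analog as a space-occupying hyperintense change (radius
  ×1.6, intensity +0.45), ages equalized so nothing else correlates with
  the label; training uses the 50-step warmup; aggregation uses rollout.
- **Age matching** — 50 batches of 64 from a 400-patient cohort.

### A finding about attention polarity

Desk-scale experiments with atrophy-style signals (shrunken and/or
darkened hippocampus analog) consistently produced **negative** case-image
attention z on the signal parcel while control images showed strongly
positive z (+4 to +6): the summary token attends a distinctive structure
where it is *present*, and when disease is the absence or fading of the
structure, disease-image attention moves elsewhere even as the parcel
remains perfectly localized (|z| large) and classification is perfect.
Attention marks salience, not evidence. The attention-recovery
experiment therefore plants a signal that is present in cases, and uses
rollout, which integrates the information path across layers and proved
far more stable across initializations than raw last-layer attention.
This is a real limitation of raw-attention interpretability at small
scale and should temper per-disease readings of such maps generally.

## Numerical choices

- All computation is float64 numpy; the autodiff engine is tape-based
  reverse mode with explicit broadcasting-aware backward rules, checked
  against central finite differences in the test suite.
- Optimizers: Adam (β = 0.9/0.999, ε = 1e-8), learning rate 1e-3 for
  both parameter sets, 1:1 discriminator:encoder steps.
- Probability clamping at 1e-7 before log in cross-entropies; norm
  terms carry +1e-12 inside the square root, so "zero" distances are
  accurate to ~1e-6.
- Modal-value ties break lexicographically; vocabulary building is
  order-independent.
- Covariance ridge as above; Mahalanobis uses a linear solve, not an
  explicit inverse; a singular (unregularized) covariance raises with
  instructions rather than silently pseudo-inverting.
- Degenerate inputs: single-label batches drop the label cluster terms;
  single-valued metadata features are dropped with a warning; AUC over
  a single class is reported as undefined, never 0.5; empty
  modality-combination cells are reported with a note.
- Training aborts on a non-finite loss and returns the last good
  parameters with the step recorded in the log attrs.

## Known limitations

- The adversarial game equilibrium is approximate: a fresh probe can
  recover weak residual confound signal on some initializations; the
  experiments quantify rather than eliminate this.
- Raw attention maps are unstable at this scale (see above); rollout is
  the supported default for parcel reports.
- The latent bank assumes roughly Gaussian latents; the KL term
  encourages but does not enforce this, and banks built from few images
  (< d/4) are heavily shrunk and correspondingly blunt.
- Checkpoints store flat parameter arrays positionally with a config
  hash; they are not portable across architecture changes.
- The phantom generator's realism limits are listed above; in
  particular CT/PET-specific physics are reduced to transfer curves.
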