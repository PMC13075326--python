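# Methods

## Problem and pipeline

Atrial high-rate episodes (AHREs) are device-detected runs of fast atrial
sensing transmitted by remotely monitored pacemakers and ICDs. Most are
either true atrial tachycardia / atrial fibrillation (AT/AF), which carries
stroke risk, or false positives from electrical noise or far-field
oversensing (FFO) of the ventricular R-wave on the atrial lead. The package
implements an automatic triage pipeline:

1. standardize each episode to the last 10 s of two-channel intracardiac
   EGM at 128 Hz (1280 samples per channel);
2. train a 1D residual network per fold of a center-level fourfold
   cross-validation, with sinus-vs-AT/AF pretraining and transfer;
3. combine the four models by soft voting (probability averaging);
4. auto-accept only predictions whose top ensemble probability clears a
   threshold (0.90 / 0.95), leaving the rest for human review;
5. quantify uncertainty with a patient-level bootstrap and explain
   predictions with Grad-CAM++ saliency.

Real AHRE archives are proprietary, so a seeded synthetic cohort generator
stands in for them end to end.

## Preprocessing

Signals longer than 10 s keep their last 1280 samples; shorter ones are
zero-padded at the *beginning* so recent activity stays right-aligned.
Episodes without a transmitted ventricular channel carry a zero vector and
`has_ventricular=False`. Each channel is independently max-abs scaled into
[-1, 1] after padding (padding cannot change the max-abs, so the order is
immaterial); all-zero channels pass through, making normalization
idempotent. Device markers are binarized onto the same grid at
`round(t * 128)`, with the exact `t = 10 s` edge clipped onto the final
sample and markers before the retained window dropped. Markers are stored
(with their type: AS, TA, Vs, Vp) but are *not* a classifier input; the
network sees the two EGM channels only.

## Synthetic cohort generator

The generator emulates the statistical structure reported for the real
multi-center archives, not cardiac biophysics:

* **Class mechanisms.** All deflections are first-derivative-of-Gaussian
  kernels (width 8–20 ms), which visually match biphasic EGM spikes.
  SINUS: regular atrial activations at 50–90 bpm, each conducted after a
  120–200 ms AV delay. AT/AF: atrial rate 180–350 bpm; the AF mode draws
  i.i.d. uniform cycle lengths and low-amplitude (0.3–0.8) fibrillatory
  deflections, and the ventricular response is a thinned (20–40%
  conduction), jittered subsample with a 350 ms refractory floor — the
  simplest mechanism that is "irregularly irregular". NOISE: a sinus base
  plus 1–3 bursts (0.5–3 s) of band-limited 30–60 Hz noise on the atrial
  channel with spurious high-rate markers inside bursts. FFO: a sinus base
  plus an attenuated (20–60%), wider far-field deflection on the atrial
  channel 0–80 ms after every ventricular activation, double-counting
  atrial markers.
* **Burdens.** Per-patient episode counts are shifted negative binomial,
  `1 + NB(r=2, p)`, with `p` calibrated so the median AT/AF and FFO burden
  is 6 episodes and the noise burden 5, matching the reported medians;
  `r=2` was chosen over a geometric tail because it places the median CDF
  point farther from 0.5, so finite-sample medians are stable, while still
  producing 1–25+ tails. Noise and FFO are patient-level minorities
  (prevalence 0.45 and 0.15), making AT/AF the modal class (~65/25/10) in
  every center.
* **Center bias.** Each center draws once: a spike-width scale (0.8–1.25),
  a dominant noise frequency (35–55 Hz), and a relative-amplitude scale
  applied to secondary components. A *global* amplitude scale would be
  erased by max-abs normalization, so center bias is expressed through
  relative amplitudes, widths, and frequencies instead.
* **Reproducibility.** One root seed fans out hierarchically
  (center/patient/episode) through `SeedSequence` spawn keys, so cohorts
  are bit-reproducible and stable under appending centers.
* **Sinus episodes** (pretraining only, ~0.5 per AHRE) belong to dedicated
  sinus-only patients per center, which structurally guarantees the
  no-overlap constraint between pretraining patients and validation/test
  patients; the protocol still filters defensively.
* A `hard_mode` flag narrows the burst- and far-field-amplitude gaps for
  stress-testing; the default ("easy") world is deliberately separable.

What a green end-to-end test establishes: the full protocol — splitting,
pretraining, transfer, augmentation, training, voting, thresholding — is
wired correctly and can learn cleanly separable class mechanisms. It does
*not* establish clinical-grade performance: real EGM morphology variation,
device-specific sensing artifacts, and label noise are all absent, which is
why the published headline numbers are not reproduction targets.

## Classifier

The 1D-ResNet10 (defaults): stem conv(k=7, stride 2, F=32) + batch norm +
ReLU + max-pool(3, stride 2) bringing 1280 samples to a 320-point feature
map; two residual stages of two blocks each (F, then 2F channels; the
second stage downsamples x2 via a strided conv with a 1x1 projection
shortcut, giving 160 feature positions); global average pooling; a hidden
dense layer (H=64, ReLU); a softmax output (2 classes for pretraining,
3 for triage). Ten weight layers lie on the main path (stem + 8 block
convs + output dense). The published text fixes the stem compression
(320 points) and the 2x2 block layout but not filter counts or kernel
sizes; the defaults here fill those gaps and are all exposed in
`ModelSpec`.

Because no deep-learning framework is available in the target environment,
layers and backpropagation are implemented directly in NumPy (channels-last
float32, im2col convolutions over BLAS). The full-network analytic gradient
is tested against float64 central differences; conv biases feeding a batch
norm have exactly zero gradient in training mode (the batch mean absorbs
them), which that test also confirms.

Training: categorical focal loss `FL = -sum_c alpha_c (1-p_c)^gamma y_c
log p_c` with gamma=2 and uniform alpha (exactly cross-entropy at gamma=0;
probabilities clipped at 1e-7), Adam at lr 0.001 (eps 1e-7), batch 64,
early stopping after 5 stagnant epochs, 50 max. The saved checkpoint is
the epoch with the highest class-weighted F2 on validation, where the
per-class F2 = 5PR/(4P+R) is weighted by validation class supports —
"class-weighted" is not defined in the source text and support weighting is
the standard reading; a fixed AT/AF-heavy weighting can be substituted via
configuration. Ties keep the earliest epoch. Pretraining uses sinus +
training-split AT/AF episodes only (no augmentation); every layer except
the final dense layer transfers to the 3-class model.

## Augmentation

Five channel-coherent operators: blank a random 2 s (256-sample) window
(same window on both channels), per-channel amplitude scale ~ U[0.4, 1.2],
inversion, temporal shift of 0.4–1.5 s in a random direction with zero
fill, and exchange of the two 5 s halves. Every noise/FFO training episode
yields one copy per technique (5x enlargement); disjoint random 4% slices
(floor) of AT/AF training episodes yield one copy per technique (20%
total). Copies supplement originals, carry provenance (source episode,
technique), keep their marker train unchanged, and never enter
pretraining, validation, or test pools.

## Protocol

Center groups mirror the published fold table: the largest center (by AHRE
count) splits into two patient-stratified halves, the two smallest merge,
and — for more than four centers — the smallest groups keep merging until
four remain. Splits are greedy over patients sorted by episode burden
(seeded shuffle for ties), each patient going to the side furthest below
its per-class target; patients are atomic, so 80/20 and 50/50 targets are
best-effort (tested at ±10 percentage points for class balance and
[0.75, 0.85] for the train fraction). "Class rectification" in the source
is read as this same class stratification. A class carried by a single
patient is pinned to the training side with a warning. Patient leakage
between any training pool (pretraining and augmentation sources included)
and a fold's validation/test sets raises before training starts.

## Triage and evaluation

Soft voting averages probability rows across the four fold models; the
prediction is the argmax with ties resolved in the order AT/AF, noise, FFO
(mirroring the labeling rule that prioritized true AT/AF, and clinically
conservative). An episode is retained at threshold tau iff its top
probability is >= tau; the source alternates between "> 95%" and "at least
95%", and `>=` is adopted (measure-zero difference for continuous
probabilities). Metrics are standard one-vs-rest precision, recall,
specificity, and F2 in percent — the source's printed precision/recall
equations swap TP+FN and TP+FP relative to universal definitions and are
treated as a typographical slip (a unit test documents the standard
definitions). Zero-denominator ratios are reported as NaN / "-", never as
a silent 0. Coverage = retained/total; error rate = incorrect/retained.

The patient-level bootstrap resamples patients with replacement (B=1000)
and draws one episode per class each drawn patient possesses, which keeps
heavy-burden patients from dominating and guarantees minority-class
representation. Point estimate = mean over iterations (the plug-in
estimate is also reported); CI = 2.5/97.5 percentiles. Specificity is
computed one-vs-rest on each resampled episode set.

## Saliency

Grad-CAM++ targets the output of the last residual block of the second
stage (160 positions at the default spec). The network is piecewise linear
between that activation and the logit, so with the exponentiated-score
form the second- and third-order terms reduce to powers of the first-order
gradient and one backward pass suffices:
`alpha = g^2 / (2 g^2 + sum_t A g^3)` (zero where the denominator
vanishes), `w_k = sum_t alpha ReLU(g)`, `map = ReLU(sum_k w_k A_k)`,
linearly interpolated to 1280 samples. One temporal map is shared by both
channels (channel-specific attribution is not defined by this
construction). Ensemble maps min-max normalize each member first —
constant maps normalize to zero by convention — then average. Note that
global average pooling makes the gradient position-uniform, so the spatial
structure of a map comes entirely from the feature activations; the
localization test exploits this by planting a cue in an otherwise
featureless background.

## Numerical and design choices

* Probability clipping 1e-7 in losses; BN eps 1e-5, momentum 0.9.
* He-normal initialization (glorot-scale for the output layer), seeded;
  training histories are bit-reproducible at fixed seed and thread count.
* Argmax ties in `triage_classify` prefer AT/AF, then noise, then FFO.
* The marker edge case `t = 10 s` rounds to index 1280 and is clipped to
  1279; any earlier out-of-window marker is dropped.
* The 4% AT/AF augmentation slices use floor rounding (minimum 0), drawn
  without replacement and disjoint across techniques, so totals are exact.
* Fold, training, and bootstrap randomness derive from named substreams of
  the root seed so stages can rerun independently.

## Known limitations

* The synthetic world is separable by construction; performance numbers on
  it say nothing about clinical accuracy.
* The NumPy network trains at roughly 5 GMAC/s on one CPU; the shipped
  end-to-end tests therefore run at reduced epochs (the separable cohort
  converges in 2–3 epochs). Full 50-epoch training works but is slow.
* Exact filter counts and kernel sizes of the original model are unknown;
  the defaults are a faithful reading of the stated constraints, not a
  reproduction.
* Bootstrap specificity on resampled one-episode-per-class sets is one
  reasonable reading of an under-specified procedure.
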