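# Methods

## The model

`mosaicvae` fits a deep generative model to *mosaic* trimodal single-cell
data: a collection of batches in which each batch measured an arbitrary
subset of chromatin accessibility (ATAC, binarized fragment counts), gene
expression (RNA, UMI counts) and surface protein (ADT, tag counts), over
feature sets that overlap but need not coincide.

Each cell carries two latent variables with standard-normal priors: a
biological state **c** (cellular identity and heterogeneity) and a technical
noise **u** (batch-driven unwanted variation). The batch ID *s* is generated
from **u** alone through a categorical batch decoder; each measured modality
*x^m* is generated from (**c**, **u**) through a modality decoder —
Bernoulli means in (0, 1) for ATAC, Poisson means for RNA and ADT. Modality
decoders share their front layers and modality encoders share their tail
layers.

Inference is a product of diagonal-Gaussian experts: one expert per measured
modality plus one for the batch ID, multiplied with the prior. Precisions
add, so any of the 2^3 − 1 modality combinations is handled by the same
(M + 1) encoders:

    nu = (1 + sum_i 1/nu_i)^-1,    mu = nu * sum_i mu_i / nu_i

Training minimizes, per cell,

    L = L_ELBO + L_align + L_IB

* **L_ELBO** = −[γ·log p(s|u) + Σ_m log p(x^m|c,u)] + KL[q(c,u|x,s) ‖ N(0,I)],
  with the reconstruction term restricted to each batch's *measured*
  features (the padded, mask-0 columns contribute nothing). γ ≥ 1 pushes
  batch information into **u**.
* **L_align** = α Σ_m ‖z^m − z̄‖² — the dispersion of reparameterized samples
  drawn from each *single-modality* posterior q(z|x^m, s) (a product of
  prior, batch expert and that modality's expert, reusing cached expert
  parameters). This self-supervised pretext task pulls the modalities onto a
  shared latent geometry, which is what makes cross-modal imputation and
  diagonal integration possible.
* **L_IB** — an information-bottleneck pair applied to the joint posterior
  and to every unimodal posterior: +β^s E[log p_η(s|c)] penalizes batch
  information in **c** (adversarially, via batch classifiers r, r^m),
  +β^x KL[q(u)‖N(0,I)] limits the information capacity of **u**, and
  −β^x E[log p_θ(s|u)] keeps the batch signal in **u**.

Training alternates K classifier updates (encoders frozen: the classifiers
see detached latent samples) with one joint encoder/decoder update
(classifier parameters held fixed), using AdamW throughout. Early stopping
watches a batch-stratified validation split.

## Design choices where the design was open

* **The batch expert covers only u.** The batch-ID encoder parameterizes the
  **u** block of z; its **c** block is flat (mean 0, variance 10^4, i.e. an
  uninformative expert). Letting the batch expert parameterize all of z
  gives it a direct, loss-free channel from the batch one-hot into the
  biological embedding — in our experiments the expert's c-variances
  collapse to ~0.01 and a linear probe reads the batch off mu_c with
  accuracy 1.0 even when the adversarial classifier is at chance. Since *s*
  carries no biological information by assumption, a flat c-block enforces
  exactly the independence the information bottleneck only approximates.
* **Encoder input transform.** RNA/ADT counts enter the encoders as
  log1p(counts); ATAC enters binary. Raw counts are used in the likelihoods.
* **Masked inputs are hard-zeroed.** Encoder inputs are multiplied by the
  feature mask, so values in unmeasured columns can never influence any
  loss (this is tested as an invariance).
* **Variance heads** output log-variance, exponentiated and clamped to
  [10^-4, 10^4]; this keeps the product of experts away from degenerate
  precisions.
* **Poisson rate parameterization.** By default the decoder produces a
  normalized rate (softmax over features, restricted to measured features
  inside the likelihood) scaled by the cell's observed library size, which
  removes sequencing depth from **c**. Absolute softplus rates are a config
  switch (`Architecture.scaled_rates=False`). For cells missing a modality,
  imputation uses the modality's median observed library; batch-corrected
  counts use the median library of the reference batch.
* **One Monte-Carlo sample** per expectation (standard stochastic
  variational practice).
* **Early stopping**: patience 10 epochs on the total validation loss,
  min-delta 0.
* **ATAC layer splitting**: when peak names parse as `chrom:start-end`, the
  ATAC input layer is split into independent per-chromosome linear blocks
  (width allocated proportionally); otherwise features are cut into a
  configurable number of contiguous blocks.
* **Batch correction tie-break**: the reference batch b* minimizing
  ‖ū_b − ū‖₂ resolves ties to the lowest batch ID; ū averages batch means
  with equal weight per batch.
* **Reciprocal mapping mechanics**: the combined model keeps the reference
  rows of the batch encoder's one-hot layer and the reference columns of the
  batch decoder head, appending freshly initialized entries for query
  batches; classifiers are reinitialized outright. Each fine-tuning
  minibatch draws `replay_fraction` (default 0.5) of its cells uniformly
  from the reference.
* **Novel-type detection**: the two-component 1-D Gaussian mixture on the
  "query"-class probabilities is initialized at the extreme probabilities
  with tight initial variances (a quarter of the observed range); with the
  default wide initialization EM can merge the intermediate and
  high-probability cells into one component and over-call novel types.
  Consequence of the kNN construction: a genuinely novel query cluster is
  only detectable when its size is at least about k (otherwise its
  neighborhoods necessarily contain reference cells).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| d_c / d_u | 32 / 2 | latent sizes (biological / technical) |
| enc_hidden / dec_hidden | 1024→128 / 128→1024 | shared hidden widths |
| dropout | 0.2 | all hidden layers |
| α | 50 | modality-alignment weight |
| β^s / β^x | 30 / 4 | technical / biological bottleneck weights |
| γ | 1000 | batch-ID likelihood weight |
| K | 3 | classifier updates per joint update |
| lr / minibatch | 10^-4 / 256 | AdamW learning rate / minibatch size |
| max epochs / patience | 2000 / 10 | training budget / early stopping |
| train:val | 95:5 | batch-stratified split |

The bundled benchmark and the test suite run a scaled-down configuration
(d_c = 8, hidden 128→32, classifier 64→64, 150 epochs at lr 10^-3,
1,500 cells with 200/120/40 features) so a full study fits in minutes on one
CPU core; the loss weights above are unchanged.

## The synthetic benchmark

The generator draws **c** from a Gaussian mixture over cell types (default:
4 types, centroids scaled so k-means on the *true* latents reaches ARI
≈ 0.99 — clearly separated types, as for major immune lineages), **u** as a
per-batch offset (scale 1.0) plus within-batch noise at a tenth of that
scale, and maps [c; u] through fixed random *linear* decoders: sigmoid link
for ATAC Bernoulli probabilities (logit offset −1.5, mean accessibility
≈ 0.26), softplus times a library scale for RNA (≈1 count/feature, sparse)
and ADT (≈20 counts/feature, dense). Mosaic structure is imposed afterwards
by deleting whole (batch, modality) blocks and/or masking a fraction of
features per block.

The linear ground truth makes recovery identifiable at desk scale and gives
every downstream head a measurable target (true rates λ, true labels, true
batch offsets). It deliberately omits nonlinear gene programs, chromatin
co-accessibility, doublets and ambient contamination — passing tests show
the machinery recovers the model's own generative structure from mosaic
observations, not that it resolves real tissues.

## Evaluation suite

Batch metrics (graph iLISI, graph connectivity, kBET), modality-alignment
metrics (modality ASW, FOSCTTM, label-transfer F1, cross-modal ATAC
AUROC / RNA / ADT Pearson r) and biological-conservation metrics (NMI, ARI
against a resolution-swept Leiden clustering maximizing NMI, isolated-label
F1, cLISI), each scaled to [0, 1], higher is better. Overall scores:
0.4·batch + 0.6·bio per space; 0.3·batch + 0.3·modality + 0.4·bio across
embedding and feature space. LISI values are rescaled as (LISI − 1)/(L − 1)
with L the number of labels (cLISI flipped to reward separation); kBET uses
neighborhood size k = 15 graphs, tests 10% of cells per label at level 0.05;
the Leiden sweep covers resolutions 0.1–2.0 in steps of 0.1. Feature-space
graphs standardize each modality, project to 32 principal components and
concatenate — an intentional simplification of weighted-nearest-neighbor
fusion, which we do not re-implement.

Two printed-formula edge cases worth noting: the cross-modal match score
divides by N and never counts the true match itself, so its floor on
completely misaligned data is 1/N (0.5 for two cells), and the silhouette
of perfectly overlapping modality clouds is slightly below zero under the
standard estimator, so "identical embeddings" score just under 1.

## Known limitations

* Training runs on a single CPU via the package's own vectorized autodiff
  tape; there is no GPU path and no negative-binomial likelihood.
* The feature-space evaluation graph replaces WNN with concatenated
  per-modality PCA.
* Model transfer requires feature-name overlap with the pretrained unions;
  novel query features are dropped, not learned.
* Architecture surgery (adding modalities to a pretrained model) is out of
  scope.
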