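# mosaicvae

Mosaic integration of trimodal single-cell data (ATAC + RNA + ADT) with a
modular product-of-experts variational autoencoder.

## The problem

Single-cell multi-omics experiments rarely measure the same modalities in
every sample: one batch may profile chromatin accessibility and expression,
another expression and surface proteins, a third only one modality, and the
feature sets (peaks, genes, antibodies) only partially overlap. *Mosaic
integration* is the joint analysis of such collections — producing one
batch-corrected cell embedding, filling in the missing modalities and
features, and transferring annotations between datasets. `mosaicvae` is for
computational biologists who need those operations on trimodal mosaic count
data and a benchmark suite to score the result.

## The model

Each cell has a biological-state latent **c** and a technical-noise latent
**u**, both with N(0, I) priors. The batch ID s is generated from **u**
(categorical decoder); each measured modality x^m is generated from
(**c**, **u**) — Bernoulli for binarized ATAC, Poisson for RNA/ADT counts.
The posterior over z = (c, u) is a product of diagonal-Gaussian experts, one
per available input plus the prior:

    nu_n = (1 + 1/nu_s + Σ_m 1/nu_m)^-1,   mu_n = nu_n ⊙ (mu_s/nu_s + Σ_m mu_m/nu_m)

so the same (M + 1) encoders serve every modality combination. Training
minimizes the negative ELBO (reconstruction restricted to measured
features, γ-weighted batch likelihood) plus a self-supervised modality
alignment penalty α Σ_m ‖z^m − z̄‖² over single-modality posterior samples,
plus an adversarial information-bottleneck pair (β^s against batch signal in
**c**, β^x against data signal in **u**) with batch classifiers updated K
times per joint update. See `docs/methods.md` for the full account.

Everything runs on plain numpy via the package's own vectorized
reverse-mode autodiff tape — no deep-learning framework required.

## Worked example

```python
import mosaicvae as mv

# a trimodal benchmark with known ground truth: 3 batches x 500 cells, 4 types
cfg = mv.SimulationConfig(seed=1, type_separation=6.0)
dataset, truth = mv.simulate_dataset(cfg)

# drop a different modality from each batch -> pairwise mosaic
mosaic = mv.apply_mosaic_pattern(dataset, {1: ("ATAC", "RNA"),
                                           2: ("RNA", "ADT"),
                                           3: ("ATAC", "ADT")})

arch = mv.Architecture(d_c=8, d_u=2, enc_hidden=(128, 32), dec_hidden=(32, 128),
                       clf_hidden=(64, 64), dropout=0.2)
results = mv.MosaicVAE(mosaic, arch, mv.LossWeights()).fit(
    epochs=150, lr=1e-3, batch_size=256, patience=150, seed=0)
print(results.summary())

latent = results.infer_latent()          # mu_c: the integrated embedding
imputed = results.impute(latent)         # means for ALL modalities, full unions
corrected = results.batch_correct(latent)

from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
ari = adjusted_rand_score(truth.type_labels,
                          KMeans(4, n_init=10, random_state=0).fit_predict(latent.mu_c))
print(f"clustering ARI vs true types: {ari:.3f}")
```

Output of the `fit`/ARI part of this script on one CPU core (~2.5 min):

```
Mosaic product-of-experts VAE
==============================================
cells: 1500   batches: 3   modalities: ATAC, RNA, ADT
latents: d_c=8  d_u=2   hidden: enc (128, 32) / dec (32, 128)
weights: alpha=50.0 beta_s=30.0 beta_x=4.0 gamma=1000.0 K=3
epochs run: 150   final train loss: 284.3773   final val loss: 257.4709
classifier/joint updates: 2700/900
clustering ARI vs true types: 0.942
```

ARI 0.94 against the generating cell types — from data in which every batch
is missing a different modality. On the same run, imputed ADT means for the
batch that never measured ADT correlate with the generating Poisson rates
at r ≈ 0.80 per feature, versus ≈ 0 for a shuffled-latent baseline.

A command-line interface mirrors the library:
`mosaicvae simulate | train | embed | impute | correct | transfer | map |
annotate | evaluate` (see `mosaicvae --help`); every run writes a
`run_manifest.yaml` from which it can be replayed.

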