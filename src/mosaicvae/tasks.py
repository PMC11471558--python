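"""Post-training task heads: latent integration, imputation, batch correction.

All heads consume a fitted :class:`~mosaicvae.model.MosaicVAEResults`; the
cell embedding is the posterior mean of the biological state ``c`` (the MAP
estimate of a Gaussian posterior), obtained deterministically with dropout
disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ATAC, MosaicDataset
from .model import MosaicVAEResults, _GroupData, _poe_t, modality_means

__all__ = ["LatentTable", "infer_latent", "infer_unimodal_latent", "impute",
           "impute_from_combination", "batch_correct", "reference_noise"]


@dataclass
class LatentTable:
    """Per-cell joint-posterior moments, split into biological and technical parts."""

    mu_c: np.ndarray
    nu_c: np.ndarray
    mu_u: np.ndarray
    nu_u: np.ndarray
    batch_ids: np.ndarray
    cell_ids: list[str]

    def __post_init__(self):
        n = len(self.cell_ids)
        for name in ("mu_c", "nu_c", "mu_u", "nu_u"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} row count does not match cell count")
        if (self.nu_c <= 0).any() or (self.nu_u <= 0).any():
            raise ValueError("posterior variances must be positive")


def _groups(results: MosaicVAEResults, dataset: MosaicDataset):
    unknown = set(dataset.modalities) - set(results.networks.feature_sizes)
    if unknown:
        raise ValueError(f"dataset modalities unknown to the model: {sorted(unknown)}")
    arch = results.model.architecture
    return [_GroupData(b, dataset.feature_spaces, results.networks.n_batches, arch)
            for b in dataset.batches]


def infer_latent(results: MosaicVAEResults, dataset: MosaicDataset) -> LatentTable:
    """Joint product-of-experts posterior for every cell (deterministic)."""
    nets = results.networks
    d_c = results.model.architecture.d_c
    mus, nus = [], []
    for g in _groups(results, dataset):
        experts = [nets.encode_batch(g.s_onehot)]
        experts += [nets.encode_modality(m, g.x_enc[m]) for m in g.modalities]
        mu, nu = _poe_t(experts)
        mus.append(mu.data)
        nus.append(nu.data)
    mu = np.vstack(mus)
    nu = np.vstack(nus)
    return LatentTable(mu[:, :d_c], nu[:, :d_c], mu[:, d_c:], nu[:, d_c:],
                       dataset.batch_labels(), dataset.cell_ids())


def infer_unimodal_latent(results: MosaicVAEResults,
                          dataset: MosaicDataset) -> dict[str, dict[str, np.ndarray]]:
    """Posterior means per single measured modality (prior + batch + one expert).

    Returns ``{modality: {"mu_c": ..., "mu_u": ..., "rows": global row indices}}``
    covering exactly the cells that measured each modality.
    """
    nets = results.networks
    d_c = results.model.architecture.d_c
    out: dict[str, dict[str, list]] = {}
    offset = 0
    for g in _groups(results, dataset):
        batch_expert = nets.encode_batch(g.s_onehot)
        for m in g.modalities:
            mu, _ = _poe_t([batch_expert, nets.encode_modality(m, g.x_enc[m])])
            rec = out.setdefault(m, {"mu_c": [], "mu_u": [], "rows": []})
            rec["mu_c"].append(mu.data[:, :d_c])
            rec["mu_u"].append(mu.data[:, d_c:])
            rec["rows"].append(np.arange(offset, offset + g.n))
        offset += g.n
    return {m: {k: np.concatenate(v) if k == "rows" else np.vstack(v)
                for k, v in rec.items()} for m, rec in out.items()}


def impute_from_combination(results: MosaicVAEResults, dataset: MosaicDataset,
                            combination: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Impute all modalities using only `combination` as observed input.

    Cells are embedded with the batch expert plus the experts of the listed
    modalities (where measured), then decoded in mean mode over full unions.
    Used by the cross-modal feature-space evaluation, where e.g. ATAC is
    predicted from {RNA}, {ADT} and {RNA, ADT}.
    """
    restricted = MosaicDataset(
        dataset.feature_spaces,
        [type(b)(b.batch_id,
                 {m: X for m, X in b.counts.items() if m in combination},
                 {m: v for m, v in b.feature_mask.items() if m in combination},
                 b.cell_ids)
         for b in dataset.batches])
    latent = infer_latent(results, restricted)
    return impute(results, latent, mode="mean", dataset=dataset)


def _median_libraries(results: MosaicVAEResults, dataset: MosaicDataset) -> dict[str, float]:
    libs: dict[str, list[np.ndarray]] = {}
    for g in _groups(results, dataset):
        for m in g.modalities:
            libs.setdefault(m, []).append(g.lib[m].ravel())
    return {m: float(np.median(np.concatenate(v))) for m, v in libs.items()}


def _decode_all(results: MosaicVAEResults, c: np.ndarray, u: np.ndarray,
                libraries: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    from ._autograd import Tensor
    nets = results.networks
    logits = nets.decode(Tensor(c), Tensor(u))
    return modality_means(nets, logits, libraries)


def impute(results: MosaicVAEResults, latent: LatentTable, mode: str = "mean",
           seed: int = 0, dataset: MosaicDataset | None = None) -> dict[str, np.ndarray]:
    """Decode every cell's MAP latents into padded means for all modalities.

    ``mode="mean"`` returns the modality means; ``mode="sample"`` draws
    Bernoulli (ATAC) / Poisson (RNA, ADT) counts from them with a seeded RNG.
    """
    if mode not in ("mean", "sample"):
        raise ValueError("mode must be 'mean' or 'sample'")
    ds = dataset or results.model.dataset
    med = _median_libraries(results, ds)
    n = latent.mu_c.shape[0]
    # per-cell library: observed total when the modality was measured,
    # the modality's median observed library otherwise
    libraries = {m: np.full(n, med.get(m, 1.0)) for m in results.networks.feature_sizes}
    offset = 0
    for g in _groups(results, ds):
        for m in g.modalities:
            libraries[m][offset:offset + g.n] = g.lib[m].ravel()
        offset += g.n
    means = _decode_all(results, latent.mu_c, latent.mu_u, libraries)
    if mode == "mean":
        return means
    rng = np.random.default_rng(seed)
    out = {}
    for m, lam in means.items():
        if m == ATAC:
            out[m] = (rng.random(lam.shape) < lam).astype(np.int64)
        else:
            out[m] = rng.poisson(lam).astype(np.int64)
    return out


def reference_noise(latent: LatentTable) -> tuple[int, np.ndarray]:
    """Pick the 'standard' technical noise: the batch whose mean u is closest
    (Euclidean) to the grand mean of batch means; ties break to the lowest ID."""
    batch_ids = np.unique(latent.batch_ids)
    means = np.vstack([latent.mu_u[latent.batch_ids == b].mean(axis=0)
                       for b in batch_ids])
    grand = means.mean(axis=0)
    dist = np.linalg.norm(means - grand, axis=1)
    k = int(np.argmin(dist))  # argmin returns the first (lowest-ID) minimum
    return int(batch_ids[k]), means[k]


def batch_correct(results: MosaicVAEResults, latent: LatentTable,
                  dataset: MosaicDataset | None = None) -> dict:
    """Decode every cell with its own c and the reference batch's mean u.

    Returns the corrected mean-mode counts per modality plus the chosen
    reference batch.  The library size applied to the Poisson modalities is
    the median observed library of the reference batch.
    """
    ds = dataset or results.model.dataset
    b_star, u_star = reference_noise(latent)
    n = latent.mu_c.shape[0]
    ref_lib: dict[str, float] = {}
    for g in _groups(results, ds):
        if g.batch_id == b_star:
            for m in g.modalities:
                ref_lib[m] = float(np.median(g.lib[m]))
    med = _median_libraries(results, ds)
    libraries = {m: np.full(n, ref_lib.get(m, med.get(m, 1.0)))
                 for m in results.networks.feature_sizes}
    u = np.tile(u_star, (n, 1))
    corrected = _decode_all(results, latent.mu_c, u, libraries)
    return {"counts": corrected, "reference_batch": b_star, "u_star": u_star}
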