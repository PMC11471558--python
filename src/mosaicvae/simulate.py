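"""Synthetic trimodal mosaic datasets with known ground truth.

The generator mirrors the model's own generative assumptions so that every
downstream stage has a recoverable target: a biological state ``c`` drawn
from a Gaussian mixture over cell types, a technical noise ``u`` dominated
by a per-batch offset, linear decoders mapping ``[c; u]`` to modality means
(sigmoid link for binary ATAC, softplus times a library scale for RNA/ADT
counts), and Bernoulli / Poisson sampling.  Mosaic structure (whole missing
modalities per batch, partially unmeasured features) is applied afterwards.

Linear ground-truth decoders are a deliberate simplification: they make the
latent structure identifiable at small problem sizes, which is what tests
need; they do not emulate the nonlinear feature programs of real cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .data import (ADT, ATAC, MODALITIES, RNA, BatchRecord, FeatureSpace,
                   MosaicDataset, infer_chrom_blocks)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset",
           "apply_mosaic_pattern", "write_ground_truth", "read_ground_truth"]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe the standard desk-scale benchmark used throughout the
    test suite: three batches of 500 cells, four cell types, trimodal.
    """

    n_cells_per_batch: tuple[int, ...] = (500, 500, 500)
    n_types: int = 4
    type_proportions: tuple[float, ...] | None = None  # None -> uniform
    n_features: dict = field(default_factory=lambda: {ATAC: 200, RNA: 120, ADT: 40})
    d_c: int = 8
    d_u: int = 2
    batch_shift_scale: float = 1.0
    type_separation: float = 4.0
    library_scale: dict = field(default_factory=lambda: {RNA: 1.0, ADT: 20.0})
    atac_logit_offset: float = -1.5   # shifts mean accessibility below 0.5
    mosaic_pattern: dict | None = None       # batch_id -> retained modalities
    feature_dropout: dict | None = None      # (batch_id, modality) -> fraction
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.type_proportions is not None:
            p = np.asarray(self.type_proportions, dtype=float)
            if len(p) != self.n_types or not np.isclose(p.sum(), 1.0) or (p < 0).any():
                raise ValueError("type_proportions must be a simplex vector of length n_types")
        if self.d_c < 2 or self.d_u < 1:
            raise ValueError("latent sizes too small: need d_c >= 2, d_u >= 1")
        if min(self.n_cells_per_batch) < 1:
            raise ValueError("every batch needs at least one cell")
        if self.mosaic_pattern is not None:
            kept = set()
            for b, mods in self.mosaic_pattern.items():
                if not mods:
                    raise ValueError(f"batch {b} would retain no modality")
                kept.update(mods)
            untouched = set(range(1, len(self.n_cells_per_batch) + 1)) - set(self.mosaic_pattern)
            if untouched:
                kept.update(MODALITIES)
            if not set(MODALITIES) <= kept and not kept <= set(MODALITIES):
                raise ValueError(f"unknown modalities in pattern: {kept - set(MODALITIES)}")
        return self


@dataclass
class GroundTruth:
    c_true: np.ndarray               # N x d_c
    u_true: np.ndarray               # N x d_u
    type_labels: np.ndarray          # N
    lambda_true: dict[str, np.ndarray]   # modality -> N x D^m expected values
    decoder_weights: dict[str, tuple[np.ndarray, np.ndarray]]  # (W, b) per modality
    type_centroids: np.ndarray       # K x d_c
    batch_offsets: np.ndarray        # B x d_u


def _feature_names(modality: str, D: int) -> list[str]:
    if modality == ATAC:
        # spread peaks over a handful of synthetic chromosomes
        n_chrom = min(4, D)
        return [f"chr{1 + i * n_chrom // D}:{1000 * i + 1}-{1000 * i + 500}"
                for i in range(D)]
    prefix = "gene" if modality == RNA else "adt"
    return [f"{prefix}{i + 1}" for i in range(D)]


def simulate_dataset(config: SimulationConfig) -> tuple[MosaicDataset, GroundTruth]:
    """Draw a mosaic dataset and its generating ground truth from `config`."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    B = len(config.n_cells_per_batch)
    N = sum(config.n_cells_per_batch)
    K, d_c, d_u = config.n_types, config.d_c, config.d_u
    d_z = d_c + d_u

    props = (np.full(K, 1.0 / K) if config.type_proportions is None
             else np.asarray(config.type_proportions, dtype=float))
    centroids = config.type_separation * rng.standard_normal((K, d_c)) / np.sqrt(d_c)
    offsets = config.batch_shift_scale * rng.standard_normal((B, d_u))

    batch_ids = np.concatenate([np.full(n, b + 1) for b, n in
                                enumerate(config.n_cells_per_batch)])
    type_labels = rng.choice(K, size=N, p=props)
    if len(np.unique(type_labels)) < K:
        raise ValueError("degenerate configuration: a cell type drew zero cells")

    c_true = centroids[type_labels] + rng.standard_normal((N, d_c))
    u_noise = 0.1 * config.batch_shift_scale * rng.standard_normal((N, d_u))
    u_true = offsets[batch_ids - 1] + u_noise
    z = np.hstack([c_true, u_true])

    lambda_true, weights, counts_full = {}, {}, {}
    for m in MODALITIES:
        D = config.n_features[m]
        W = rng.standard_normal((d_z, D)) / np.sqrt(d_z)
        if m == ATAC:
            b = np.full(D, config.atac_logit_offset)
            lam = 1.0 / (1.0 + np.exp(-(z @ W + b)))
            counts_full[m] = (rng.random((N, D)) < lam).astype(np.int64)
        else:
            b = np.zeros(D)
            lam = config.library_scale[m] * np.logaddexp(0.0, z @ W + b)
            counts_full[m] = rng.poisson(lam).astype(np.int64)
        lambda_true[m], weights[m] = lam, (W, b)

    spaces = {m: FeatureSpace(m, _feature_names(m, config.n_features[m]),
                              infer_chrom_blocks(_feature_names(m, config.n_features[m]))
                              if m == ATAC else None)
              for m in MODALITIES}

    batches, offset = [], 0
    for b in range(B):
        n = config.n_cells_per_batch[b]
        rows = slice(offset, offset + n)
        counts = {m: sp.csr_matrix(counts_full[m][rows]) for m in MODALITIES}
        masks = {m: np.ones(config.n_features[m], dtype=np.uint8) for m in MODALITIES}
        if config.feature_dropout:
            for m in MODALITIES:
                frac = config.feature_dropout.get((b + 1, m), 0.0)
                if frac > 0.0:
                    drop = rng.choice(config.n_features[m],
                                      size=int(frac * config.n_features[m]),
                                      replace=False)
                    masks[m][drop] = 0
                    keep = sp.diags(masks[m].astype(np.int64))
                    counts[m] = (counts[m] @ keep).tocsr()
        cell_ids = [f"batch{b + 1}_cell{i + 1}" for i in range(n)]
        batches.append(BatchRecord(b + 1, counts, masks, cell_ids))
        offset += n

    dataset = MosaicDataset(spaces, batches)
    if config.mosaic_pattern:
        dataset = apply_mosaic_pattern(dataset, config.mosaic_pattern)
    dataset.validate()
    truth = GroundTruth(c_true, u_true, type_labels, lambda_true, weights,
                        centroids, offsets)
    return dataset, truth


def apply_mosaic_pattern(dataset: MosaicDataset, pattern: dict) -> MosaicDataset:
    """Drop whole (batch, modality) blocks; untouched blocks are shared, not copied.

    `pattern` maps batch_id -> modalities to retain; batches absent from the
    mapping keep everything.
    """
    unknown = set(pattern) - {b.batch_id for b in dataset.batches}
    if unknown:
        raise ValueError(f"pattern references unknown batches: {sorted(unknown)}")
    new_batches = []
    for b in dataset.batches:
        if b.batch_id not in pattern:
            new_batches.append(b)
            continue
        keep = set(pattern[b.batch_id])
        if not keep & set(b.measured_modalities):
            raise ValueError(f"batch {b.batch_id} would retain no modality")
        counts = {m: X for m, X in b.counts.items() if m in keep}
        masks = {m: v for m, v in b.feature_mask.items() if m in keep}
        new_batches.append(BatchRecord(b.batch_id, counts, masks, b.cell_ids))
    return MosaicDataset(dataset.feature_spaces, new_batches)


# ------------------------------------------------------- ground-truth archive

def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "c_true.tsv", truth.c_true, delimiter="\t")
    np.savetxt(out / "u_true.tsv", truth.u_true, delimiter="\t")
    np.savetxt(out / "type_labels.tsv", truth.type_labels, fmt="%d")
    for m, lam in truth.lambda_true.items():
        np.savetxt(out / f"lambda_{m}.tsv", lam, delimiter="\t")


def read_ground_truth(in_dir) -> dict:
    src = Path(in_dir)
    out = {
        "c_true": np.loadtxt(src / "c_true.tsv", delimiter="\t", ndmin=2),
        "u_true": np.loadtxt(src / "u_true.tsv", delimiter="\t", ndmin=2),
        "type_labels": np.loadtxt(src / "type_labels.tsv", dtype=int, ndmin=1),
    }
    for m in MODALITIES:
        path = src / f"lambda_{m}.tsv"
        if path.exists():
            out[f"lambda_{m}"] = np.loadtxt(path, delimiter="\t", ndmin=2)
    return out
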