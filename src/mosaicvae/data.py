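"""Mosaic multimodal count data: feature unions, padding/masking, I/O.

A *mosaic* dataset is a collection of experimental batches in which each
batch measured an arbitrary subset of the three modalities (ATAC peaks, RNA
genes, ADT proteins), over feature sets that overlap but need not coincide.
Counts are aligned to the per-modality feature union: each batch carries a
cells x D^m matrix padded with zero columns for the features it did not
measure, together with a binary mask marking the measured columns.  Matrices
are kept sparse; the padded layout costs nothing for the zero columns.

On disk a dataset is a directory of CellRanger-style MTX/TSV triplets, one
per (batch, modality), tied together by a YAML manifest.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml

ATAC, RNA, ADT = "ATAC", "RNA", "ADT"
MODALITIES = (ATAC, RNA, ADT)

_COORD_RE = re.compile(r"^(?P<chrom>[^:]+)[:\-](?P<start>\d+)-(?P<end>\d+)$")


@dataclass
class FeatureSpace:
    """Ordered feature union of one modality across all batches."""

    modality: str
    names: list[str]
    atac_chrom_blocks: np.ndarray | None = None  # block index per feature

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.atac_chrom_blocks is not None:
            self.atac_chrom_blocks = np.asarray(self.atac_chrom_blocks, dtype=int)
            if len(self.atac_chrom_blocks) != len(self.names):
                raise ValueError("chromosome blocks must cover exactly the features")

    @property
    def size(self) -> int:
        return len(self.names)

    def index_of(self, names: list[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"features not in the {self.modality} union: {missing[:5]}")
        return np.array([lookup[n] for n in names], dtype=int)


def infer_chrom_blocks(names: list[str], n_fallback_blocks: int = 22) -> np.ndarray:
    """Partition ATAC peaks into chromosome groups.

    Peak names parsing as ``chrom:start-end`` (or ``chrom-start-end``) are
    grouped by chromosome in first-seen order; otherwise the features are cut
    into `n_fallback_blocks` equal contiguous blocks.
    """
    chroms = []
    for n in names:
        m = _COORD_RE.match(n)
        if m is None:
            # fallback: equal contiguous blocks
            k = min(n_fallback_blocks, max(1, len(names)))
            return np.minimum(np.arange(len(names)) * k // max(1, len(names)), k - 1)
        chroms.append(m.group("chrom"))
    order: dict[str, int] = {}
    for c in chroms:
        order.setdefault(c, len(order))
    return np.array([order[c] for c in chroms], dtype=int)


@dataclass
class BatchRecord:
    """One experimental batch: padded sparse counts + masks for its measured modalities."""

    batch_id: int
    counts: dict[str, sp.csr_matrix]
    feature_mask: dict[str, np.ndarray]
    cell_ids: list[str]

    @property
    def measured_modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if m in self.counts)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def validate(self, feature_spaces: dict[str, FeatureSpace]) -> None:
        for m, X in self.counts.items():
            space = feature_spaces[m]
            if X.shape != (self.n_cells, space.size):
                raise ValueError(
                    f"batch {self.batch_id} {m}: shape {X.shape} != "
                    f"({self.n_cells}, {space.size})")
            if X.nnz and X.data.min() < 0:
                raise ValueError(f"batch {self.batch_id} {m}: negative counts")
            mask = self.feature_mask[m]
            if mask.shape != (space.size,) or not np.isin(mask, (0, 1)).all():
                raise ValueError(f"batch {self.batch_id} {m}: invalid feature mask")
            unmeasured = np.flatnonzero(mask == 0)
            if unmeasured.size and X[:, unmeasured].nnz:
                raise ValueError(
                    f"batch {self.batch_id} {m}: nonzero counts in masked-out columns")
            if m == ATAC and X.nnz and X.data.max() > 1:
                raise ValueError(f"batch {self.batch_id}: ATAC counts must be binarized")


@dataclass
class MosaicDataset:
    feature_spaces: dict[str, FeatureSpace]
    batches: list[BatchRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [b.batch_id for b in self.batches]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"batch_ids must be 1..B without gaps, got {ids}")

    @property
    def B(self) -> int:
        return len(self.batches)

    @property
    def N(self) -> int:
        return sum(b.n_cells for b in self.batches)

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if m in self.feature_spaces)

    def validate(self) -> "MosaicDataset":
        for b in self.batches:
            b.validate(self.feature_spaces)
        return self

    def batch_labels(self) -> np.ndarray:
        """Per-cell batch ID, concatenated over batches in ID order."""
        return np.concatenate([np.full(b.n_cells, b.batch_id) for b in self.batches])

    def cell_ids(self) -> list[str]:
        return [cid for b in self.batches for cid in b.cell_ids]


# --------------------------------------------------------------------- ops

def build_feature_union(per_batch_features: dict[str, list[list[str]]],
                        atac_fallback_blocks: int = 22) -> dict[str, FeatureSpace]:
    """Ordered per-modality union of batch feature lists.

    Order is deterministic: first seen across batches in batch-ID order, then
    within-batch order.  Duplicates within one batch's list are rejected.
    """
    spaces = {}
    for modality, lists in per_batch_features.items():
        union: list[str] = []
        seen: set[str] = set()
        for i, names in enumerate(lists):
            dups = [n for n, c in _count(names).items() if c > 1]
            if dups:
                raise ValueError(
                    f"duplicate {modality} features in batch list {i + 1}: {dups[:5]}")
            for n in names:
                if n not in seen:
                    seen.add(n)
                    union.append(n)
        blocks = infer_chrom_blocks(union, atac_fallback_blocks) if modality == ATAC else None
        spaces[modality] = FeatureSpace(modality, union, blocks)
    return spaces


def _count(items):
    c: dict[str, int] = {}
    for x in items:
        c[x] = c.get(x, 0) + 1
    return c


def pad_counts(raw_counts, raw_features: list[str],
               space: FeatureSpace) -> tuple[sp.csr_matrix, np.ndarray]:
    """Place raw columns at their union positions; zero-fill the rest.

    Returns the padded cells x D^m sparse matrix and the binary feature mask
    (1 exactly on the observed columns).
    """
    raw = sp.csr_matrix(raw_counts)
    if raw.shape[1] != len(raw_features):
        raise ValueError(f"raw matrix has {raw.shape[1]} columns "
                         f"but {len(raw_features)} feature names")
    idx = space.index_of(raw_features)
    cols = np.zeros(space.size, dtype=bool)
    cols[idx] = True
    proj = sp.csr_matrix(
        (np.ones(len(idx)), (np.arange(len(idx)), idx)),
        shape=(len(idx), space.size))
    padded = (raw @ proj).tocsr()
    return padded, cols.astype(np.uint8)


def mask_features(padded_vector: np.ndarray, feature_mask: np.ndarray) -> np.ndarray:
    """Drop padded positions, keeping observed entries in order (inverse of padding)."""
    padded_vector = np.asarray(padded_vector)
    feature_mask = np.asarray(feature_mask)
    if padded_vector.shape[-1] != feature_mask.shape[0]:
        raise ValueError("vector / mask length mismatch")
    if not np.isin(feature_mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    return padded_vector[..., feature_mask.astype(bool)]


def binarize_atac(counts):
    """Set every positive fragment count to 1."""
    X = sp.csr_matrix(counts)
    if X.nnz and X.data.min() < 0:
        raise ValueError("negative counts cannot be binarized")
    X = X.copy()
    X.data = (X.data > 0).astype(X.data.dtype)
    X.eliminate_zeros()
    return X


def split_train_val(dataset: MosaicDataset, ratio: float = 0.95,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Batch-stratified train/validation split over global cell indices."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    offset = 0
    for b in dataset.batches:
        idx = offset + rng.permutation(b.n_cells)
        if b.n_cells < 2:
            warnings.warn(f"batch {b.batch_id} has <2 cells; all placed in train")
            train.append(idx)
        else:
            n_train = int(round(ratio * b.n_cells))
            n_train = min(max(n_train, 1), b.n_cells - 1)
            train.append(idx[:n_train])
            val.append(idx[n_train:])
        offset += b.n_cells
    empty = np.array([], dtype=int)
    return (np.sort(np.concatenate(train)) if train else empty,
            np.sort(np.concatenate(val)) if val else empty)


# ---------------------------------------------------------------------- I/O

def write_mosaic(dataset: MosaicDataset, out_dir) -> Path:
    """Write MTX/TSV triplets per (batch, modality) plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"modalities": {}, "batches": []}
    for m in dataset.modalities:
        space = dataset.feature_spaces[m]
        feat_path = out / f"features_{m}.tsv"
        feat_path.write_text("\n".join(space.names) + "\n")
        manifest["modalities"][m] = {"features": feat_path.name}
    for b in dataset.batches:
        entry: dict = {"batch_id": b.batch_id, "modalities": {}}
        bc_path = out / f"barcodes_batch{b.batch_id}.tsv"
        bc_path.write_text("\n".join(b.cell_ids) + "\n")
        entry["barcodes"] = bc_path.name
        for m in b.measured_modalities:
            stem = f"batch{b.batch_id}_{m}"
            mtx = out / f"{stem}.mtx"
            scipy.io.mmwrite(str(mtx), b.counts[m].astype(np.int64).T.tocoo())
            mask_path = out / f"{stem}_mask.tsv"
            np.savetxt(mask_path, b.feature_mask[m][None, :], fmt="%d", delimiter="\t")
            entry["modalities"][m] = {"matrix": mtx.name, "mask": mask_path.name}
        manifest["batches"].append(entry)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out / "manifest.yaml"


def read_mosaic(manifest_path) -> MosaicDataset:
    """Load a dataset written by :func:`write_mosaic` (exact round trip)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    spaces: dict[str, FeatureSpace] = {}
    for m, info in manifest["modalities"].items():
        names = _read_lines(root / info["features"])
        blocks = infer_chrom_blocks(names) if m == ATAC else None
        spaces[m] = FeatureSpace(m, names, blocks)
    batches = []
    for entry in manifest["batches"]:
        cell_ids = _read_lines(root / entry["barcodes"])
        counts, masks = {}, {}
        for m, files in entry["modalities"].items():
            path = root / files["matrix"]
            try:
                X = sp.csr_matrix(scipy.io.mmread(str(path)).T)
            except Exception as exc:  # corrupt header / body
                raise ValueError(f"cannot read MTX file {path.name}: {exc}") from exc
            if X.shape != (len(cell_ids), spaces[m].size):
                raise ValueError(
                    f"{path.name}: dimensions {X.shape} do not match barcodes/features "
                    f"({len(cell_ids)}, {spaces[m].size})")
            if X.nnz and not np.allclose(X.data, np.round(X.data)):
                raise ValueError(f"{path.name}: non-integer values")
            counts[m] = X.astype(np.int64)
            masks[m] = np.loadtxt(root / files["mask"], delimiter="\t",
                                  dtype=np.uint8, ndmin=1).reshape(-1)
        batches.append(BatchRecord(entry["batch_id"], counts, masks, cell_ids))
    return MosaicDataset(spaces, batches).validate()


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing file: {path.name}")
    return path.read_text().splitlines()
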