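"""Knowledge transfer: fine-tuning on query data, reciprocal reference
mapping with replay, and kNN label transfer with novel-type detection.

Model transfer reuses a pretrained model's modality encoders/decoders on a
new (query) dataset whose batches differ: the batch-ID modules and the
adversarial batch classifiers are reinitialized for the query's batches
while the modality networks are fine-tuned.  Reciprocal mapping additionally
mixes replayed reference cells into every fine-tuning minibatch so that one
model embeds reference and query into a single aligned space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import KNeighborsClassifier

from .data import BatchRecord, MosaicDataset
from .model import MosaicVAE, MosaicVAEResults, Networks
from .tasks import LatentTable, infer_latent

__all__ = ["TransferPlan", "AnnotationResult", "harmonize_dataset",
           "model_transfer", "reciprocal_map", "transfer_labels"]


@dataclass
class TransferPlan:
    """How to fine-tune a pretrained model on query data."""

    epochs: int = 50
    lr: float = 1e-4
    batch_size: int = 256
    replay_fraction: float = 0.5   # reference share of each minibatch (reciprocal)
    val_ratio: float = 0.05
    patience: int = 10
    seed: int = 0

    def validate(self) -> "TransferPlan":
        if not 0.0 <= self.replay_fraction < 1.0:
            raise ValueError("replay_fraction must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        return self


@dataclass
class AnnotationResult:
    labels: list[str]
    query_class_prob: np.ndarray | None = None
    threshold_means: tuple[float, float] | None = None


def harmonize_dataset(query: MosaicDataset, reference_spaces: dict) -> MosaicDataset:
    """Map a query dataset onto the reference feature spaces by name intersection.

    Query features absent from the reference union are dropped with a
    warning; reference features the query lacks stay masked out.  Modalities
    unknown to the reference are dropped entirely.
    """
    keep_mods = [m for m in query.modalities if m in reference_spaces]
    dropped_mods = set(query.modalities) - set(keep_mods)
    if dropped_mods:
        warnings.warn(f"query modalities unknown to the model dropped: {sorted(dropped_mods)}")
    any_overlap = False
    # per modality: query-union column -> reference-union column (or -1)
    col_map = {}
    for m in keep_mods:
        ref_pos = {n: i for i, n in enumerate(reference_spaces[m].names)}
        qnames = query.feature_spaces[m].names
        col_map[m] = np.array([ref_pos.get(n, -1) for n in qnames])
        n_lost = int((col_map[m] < 0).sum())
        if n_lost:
            warnings.warn(f"{m}: {n_lost} query features not in the reference union; dropped")
        if (col_map[m] >= 0).any():
            any_overlap = True
    if not any_overlap:
        raise ValueError("no overlapping features with the reference in any modality")

    batches = []
    for b in query.batches:
        counts, masks = {}, {}
        for m in b.measured_modalities:
            if m not in keep_mods:
                continue
            cmap = col_map[m]
            D_ref = reference_spaces[m].size
            src = np.flatnonzero((cmap >= 0) & (b.feature_mask[m] == 1))
            proj = sp.csr_matrix(
                (np.ones(len(src)), (src, cmap[src])),
                shape=(len(cmap), D_ref))
            counts[m] = (b.counts[m] @ proj).tocsr()
            mask = np.zeros(D_ref, dtype=np.uint8)
            mask[cmap[src]] = 1
            masks[m] = mask
        if counts:
            batches.append(BatchRecord(b.batch_id, counts, masks, b.cell_ids))
    ds = MosaicDataset({m: reference_spaces[m] for m in keep_mods}, batches)
    return ds.validate()


def _reinit_batch_modules(networks: Networks, n_batches: int,
                          rng: np.random.Generator,
                          copy_reference_rows: int = 0) -> Networks:
    """Rebuild batch-ID modules and classifiers for `n_batches` batches.

    Modality encoder/decoder weights are carried over from `networks`.  With
    `copy_reference_rows` = B_ref > 0, the first B_ref one-hot rows of the
    batch encoder and output columns of the batch decoder are copied from
    the pretrained model (reciprocal mapping keeps the reference batches).
    """
    old = networks
    fresh = Networks(old.arch, old.feature_sizes, n_batches, rng,
                     atac_blocks=_atac_blocks(old))
    # carry over modality parameters
    for src, dst in zip(old.modality_params(), fresh.modality_params()):
        dst.data = src.data.copy()
    if copy_reference_rows:
        B_ref = copy_reference_rows
        # batch encoder: first linear has shape (B, h) — copy reference rows
        src_lin, dst_lin = old.enc_batch.blocks[0].lin, fresh.enc_batch.blocks[0].lin
        dst_lin.W.data[:B_ref] = src_lin.W.data[:B_ref].copy()
        dst_lin.b.data = src_lin.b.data.copy()
        for s_blk, d_blk in zip(old.enc_batch.blocks, fresh.enc_batch.blocks):
            d_blk.norm.g.data = s_blk.norm.g.data.copy()
            d_blk.norm.b.data = s_blk.norm.b.data.copy()
        for s, d in zip(old.enc_batch.blocks[1:], fresh.enc_batch.blocks[1:]):
            d.lin.W.data = s.lin.W.data.copy()
            d.lin.b.data = s.lin.b.data.copy()
        dst_head, src_head = fresh.enc_batch.head, old.enc_batch.head
        dst_head.W.data = src_head.W.data.copy()
        dst_head.b.data = src_head.b.data.copy()
        # batch decoder: hidden copied; head columns for reference batches copied
        for s_blk, d_blk in zip(old.dec_batch.blocks, fresh.dec_batch.blocks):
            d_blk.lin.W.data = s_blk.lin.W.data.copy()
            d_blk.lin.b.data = s_blk.lin.b.data.copy()
            d_blk.norm.g.data = s_blk.norm.g.data.copy()
            d_blk.norm.b.data = s_blk.norm.b.data.copy()
        fresh.dec_batch.head.W.data[:, :B_ref] = old.dec_batch.head.W.data[:, :B_ref].copy()
        fresh.dec_batch.head.b.data[:B_ref] = old.dec_batch.head.b.data[:B_ref].copy()
    return fresh


def _atac_blocks(networks: Networks):
    from .data import ATAC
    from .model import _SplitLinear
    if ATAC in networks.enc_in and isinstance(networks.enc_in[ATAC].lin, _SplitLinear):
        return networks.enc_in[ATAC].lin.block_idx
    return None


def model_transfer(pretrained: MosaicVAEResults, query: MosaicDataset,
                   plan: TransferPlan | None = None) -> MosaicVAEResults:
    """Fine-tune a pretrained model on a query dataset (pure function).

    The pretrained results object is never mutated: modality networks are
    copied and fine-tuned, batch-ID modules and classifiers are freshly
    initialized for the query's batches.
    """
    plan = (plan or TransferPlan()).validate()
    ref_spaces = pretrained.model.dataset.feature_spaces
    query_h = harmonize_dataset(query, ref_spaces)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 1]))
    networks = _reinit_batch_modules(pretrained.networks, query_h.B, rng)
    model = MosaicVAE(query_h, pretrained.model.architecture,
                      pretrained.model.loss_weights)
    if plan.epochs == 0:
        return MosaicVAEResults(model, networks, [])
    return model.fit(epochs=plan.epochs, lr=plan.lr, batch_size=plan.batch_size,
                     val_ratio=plan.val_ratio, patience=plan.patience,
                     seed=plan.seed, networks=networks)


def _concat_datasets(reference: MosaicDataset, query: MosaicDataset) -> MosaicDataset:
    """Stack reference and query batches; query batch IDs are shifted by B_ref."""
    spaces = dict(reference.feature_spaces)
    batches = list(reference.batches)
    B_ref = reference.B
    for b in query.batches:
        batches.append(BatchRecord(B_ref + b.batch_id, dict(b.counts),
                                   dict(b.feature_mask),
                                   [f"query:{c}" for c in b.cell_ids]))
    return MosaicDataset(spaces, batches).validate()


def reciprocal_map(pretrained: MosaicVAEResults, reference: MosaicDataset,
                   query: MosaicDataset, plan: TransferPlan | None = None,
                   ) -> tuple[MosaicVAEResults, LatentTable]:
    """Fine-tune on query with reference replay; embed both with one model.

    Each fine-tuning minibatch mixes ``replay_fraction`` reference cells with
    query cells; the reference batch-ID parameters are kept and new rows are
    appended for the query batches.  Returns the fine-tuned results and the
    joint latent table over reference followed by query cells.
    """
    plan = (plan or TransferPlan()).validate()
    ref_spaces = pretrained.model.dataset.feature_spaces
    if plan.replay_fraction > 0 and reference is None:
        raise ValueError("replay requested but no reference dataset given")
    query_h = harmonize_dataset(query, ref_spaces)
    combined = _concat_datasets(reference, query_h)
    B_ref = reference.B
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 2]))
    networks = _reinit_batch_modules(pretrained.networks, combined.B, rng,
                                     copy_reference_rows=B_ref)
    model = MosaicVAE(combined, pretrained.model.architecture,
                      pretrained.model.loss_weights)

    from .data import split_train_val
    train_idx, _ = split_train_val(combined, 1.0 - plan.val_ratio, seed=plan.seed)
    n_ref = reference.N
    ref_pool = train_idx[train_idx < n_ref]
    query_pool = train_idx[train_idx >= n_ref]

    f = plan.replay_fraction
    n_q = max(1, int(round(plan.batch_size * (1.0 - f))))
    n_r = plan.batch_size - n_q if f > 0 else 0

    def sampler(rng_s, batch_size):
        order = rng_s.permutation(query_pool)
        out = []
        for i in range(0, len(order), n_q):
            mb = order[i:i + n_q]
            if n_r and len(ref_pool):
                mb = np.concatenate([mb, rng_s.choice(ref_pool, size=n_r,
                                                      replace=len(ref_pool) < n_r)])
            out.append(mb)
        return out

    if plan.epochs == 0:
        results = MosaicVAEResults(model, networks, [])
    else:
        results = model.fit(epochs=plan.epochs, lr=plan.lr,
                            batch_size=plan.batch_size, val_ratio=plan.val_ratio,
                            patience=plan.patience, seed=plan.seed,
                            networks=networks, sampler=sampler)
    latent = infer_latent(results, combined)
    return results, latent


def transfer_labels(reference_embeddings: np.ndarray, reference_labels,
                    query_embeddings: np.ndarray, mode: str = "same_tissue",
                    k: int = 100, gmm_tol: float = 1e-4,
                    seed: int = 0) -> AnnotationResult:
    """kNN label transfer; in cross-tissue mode novel types become "unknown".

    Same tissue: a k-nearest-neighbour classifier (uniform weights) fitted
    on the reference embeddings labels each query cell.  Cross tissue: the
    classifier is fitted on reference plus query (query labeled "query");
    a two-component 1-D Gaussian mixture on the predicted "query"-class
    probabilities separates cells resembling the reference (lower mean;
    labeled by the best non-query class) from genuinely novel ones (higher
    mean; labeled "unknown").
    """
    ref = np.asarray(reference_embeddings, dtype=float)
    qry = np.asarray(query_embeddings, dtype=float)
    labels = np.asarray([str(x) for x in reference_labels])
    if len(labels) == 0:
        raise ValueError("empty reference")
    if ref.shape[1] != qry.shape[1]:
        raise ValueError("embedding dimensions differ")

    if mode == "same_tissue":
        kk = min(k, len(ref))
        if kk < k:
            warnings.warn(f"k shrunk to reference size {kk}")
        clf = KNeighborsClassifier(n_neighbors=kk, weights="uniform")
        clf.fit(ref, labels)
        return AnnotationResult(list(clf.predict(qry)))

    if mode != "cross_tissue":
        raise ValueError(f"unknown mode {mode!r}")

    X = np.vstack([ref, qry])
    y = np.concatenate([labels, np.full(len(qry), "query")])
    kk = min(k, len(X))
    if kk < k:
        warnings.warn(f"k shrunk to training size {kk}")
    clf = KNeighborsClassifier(n_neighbors=kk, weights="uniform")
    clf.fit(X, y)
    probs = clf.predict_proba(qry)
    classes = list(clf.classes_)
    qi = classes.index("query")
    q_prob = probs[:, qi]
    # init at the extreme probabilities with tight variances, otherwise EM can
    # merge the intermediate and high-probability cells into one component
    var0 = max((0.25 * (q_prob.max() - q_prob.min())) ** 2, 1e-4)
    gmm = GaussianMixture(n_components=2, tol=gmm_tol, random_state=seed,
                          means_init=[[q_prob.min()], [q_prob.max()]],
                          precisions_init=[[[1.0 / var0]], [[1.0 / var0]]])
    comp = gmm.fit_predict(q_prob[:, None])
    means = gmm.means_.ravel()
    novel = comp == int(np.argmax(means))
    non_query = [i for i in range(len(classes)) if i != qi]
    best = np.asarray(classes)[non_query][probs[:, non_query].argmax(axis=1)]
    out = np.where(novel, "unknown", best)
    return AnnotationResult(list(out), q_prob,
                            (float(means.min()), float(means.max())))
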