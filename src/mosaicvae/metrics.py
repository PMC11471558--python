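"""Integration benchmarking metrics on embedding and feature space.

Three metric families are computed on kNN graphs or embeddings:

* batch correction — graph iLISI, graph connectivity, kBET;
* modality alignment — modality ASW, FOSCTTM, label-transfer F1, and
  cross-modal feature-space scores (ATAC AUROC, RNA/ADT Pearson r);
* biological conservation — NMI, ARI (against a resolution-swept community
  clustering), isolated-label F1, graph cLISI.

All scores live in [0, 1] with higher = better.  Overall scores combine the
families with fixed weights: 0.4 batch / 0.6 bio for the per-space score and
0.3 batch / 0.3 modality / 0.4 bio for the dual-space mosaic score.

Feature-space graphs use per-modality standardization + PCA concatenation,
a deliberate simplification of weighted-nearest-neighbour fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import (adjusted_rand_score, f1_score,
                             normalized_mutual_info_score, roc_auc_score,
                             silhouette_samples)
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborGraph", "MetricsReport", "build_knn_graph", "graph_ilisi",
    "graph_clisi", "graph_connectivity", "kbet", "modality_asw", "foscttm",
    "label_transfer_f1", "cross_modal_feature_scores", "bio_conservation",
    "overall_scores", "modality_contribution", "feature_space_graph",
]


@dataclass
class NeighborGraph:
    indices: np.ndarray    # N x k
    distances: np.ndarray  # N x k, non-decreasing per row
    space_tag: str = "embedding"

    @property
    def n(self) -> int:
        return self.indices.shape[0]

    @property
    def k(self) -> int:
        return self.indices.shape[1]


@dataclass
class MetricsReport:
    batch: dict = field(default_factory=dict)     # space -> {iLISI, gc, kBET}
    modality: dict = field(default_factory=dict)  # {ASW, FOSCTTM, ltF1, AUROC, RNAr, ADTr}
    bio: dict = field(default_factory=dict)       # space -> {NMI, ARI, ilF1, cLISI}
    overall: dict = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, float]]:
        rows = []
        for space, d in self.batch.items():
            rows += [(f"batch/{space}/{k}", v) for k, v in d.items()]
        rows += [(f"modality/{k}", v) for k, v in self.modality.items()]
        for space, d in self.bio.items():
            rows += [(f"bio/{space}/{k}", v) for k, v in d.items()]
        rows += [(f"overall/{k}", v) for k, v in self.overall.items()]
        return rows


def build_knn_graph(points: np.ndarray, k: int = 15,
                    space_tag: str = "embedding") -> NeighborGraph:
    """Exact Euclidean kNN excluding self."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    # drop self (first column unless duplicates displaced it)
    keep_idx = np.empty((n, k), dtype=int)
    keep_dist = np.empty((n, k))
    for i in range(n):
        cols = np.flatnonzero(idx[i] != i)[:k]
        if len(cols) < k:                      # self not in list (duplicates)
            cols = np.arange(1, k + 1)
        keep_idx[i] = idx[i, cols]
        keep_dist[i] = dist[i, cols]
    return NeighborGraph(keep_idx, keep_dist, space_tag)


# ------------------------------------------------------------------- LISI

def _lisi(graph: NeighborGraph, labels: np.ndarray) -> np.ndarray:
    """Per-cell inverse Simpson index of distance-weighted neighbor labels."""
    labels = np.asarray(labels)
    uniq, enc = np.unique(labels, return_inverse=True)
    L = len(uniq)
    out = np.empty(graph.n)
    for i in range(graph.n):
        d = graph.distances[i]
        scale = d.max() if d.max() > 0 else 1.0
        w = np.exp(-d / scale)
        w = w / w.sum()
        p = np.bincount(enc[graph.indices[i]], weights=w, minlength=L)
        out[i] = 1.0 / np.sum(p ** 2)
    return out


def graph_ilisi(graph: NeighborGraph, batch_labels: np.ndarray) -> float:
    """Batch-mixing LISI rescaled to [0, 1]; 1 = perfect mixing."""
    L = len(np.unique(batch_labels))
    if L < 2:
        warnings.warn("single batch present; iLISI undefined, returning 1")
        return 1.0
    lisi = _lisi(graph, batch_labels)
    return float(np.clip((lisi.mean() - 1.0) / (L - 1.0), 0.0, 1.0))


def graph_clisi(graph: NeighborGraph, type_labels: np.ndarray) -> float:
    """Cell-type LISI rescaled so 1 = perfect separation."""
    L = len(np.unique(type_labels))
    if L < 2:
        return 1.0
    lisi = _lisi(graph, type_labels)
    return float(np.clip(1.0 - (lisi.mean() - 1.0) / (L - 1.0), 0.0, 1.0))


def graph_connectivity(graph: NeighborGraph, type_labels: np.ndarray) -> float:
    """Average largest-connected-component fraction of per-type subgraphs."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    labels = np.asarray(type_labels)
    scores = []
    for lab in np.unique(labels):
        cells = np.flatnonzero(labels == lab)
        pos = -np.ones(graph.n, dtype=int)
        pos[cells] = np.arange(len(cells))
        rows, cols = [], []
        for local, i in enumerate(cells):
            nb = graph.indices[i]
            inside = pos[nb[labels[nb] == lab]]
            rows += [local] * len(inside)
            cols += list(inside)
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(len(cells), len(cells)))
        n_comp, comp = connected_components(adj, directed=False)
        largest = np.bincount(comp).max() if len(cells) else 0
        scores.append(largest / max(len(cells), 1))
    return float(np.mean(scores))


def kbet(graph: NeighborGraph, batch_labels: np.ndarray,
         type_labels: np.ndarray | None = None, test_fraction: float = 0.1,
         alpha: float = 0.05, seed: int = 0) -> float:
    """1 - chi-square rejection rate of local vs global batch composition.

    Computed within each type label then averaged (labels present in a
    single batch are skipped with a warning).
    """
    batch_labels = np.asarray(batch_labels)
    if len(np.unique(batch_labels)) < 2:
        raise ValueError("kBET needs at least two batches")
    types = (np.zeros(len(batch_labels), dtype=int) if type_labels is None
             else np.asarray(type_labels))
    rng = np.random.default_rng(seed)
    uniq_b = np.unique(batch_labels)
    scores = []
    for lab in np.unique(types):
        cells = np.flatnonzero(types == lab)
        global_freq = np.array([(batch_labels[cells] == b).mean() for b in uniq_b])
        if (global_freq > 0).sum() < 2:
            warnings.warn(f"label {lab!r} present in a single batch; skipped by kBET")
            continue
        n_test = max(1, int(test_fraction * len(cells)))
        tested = rng.choice(cells, size=n_test, replace=False)
        rejected = 0
        for i in tested:
            nb = graph.indices[i]
            obs = np.array([(batch_labels[nb] == b).sum() for b in uniq_b])
            exp = global_freq * len(nb)
            ok = exp > 0
            chi2 = ((obs[ok] - exp[ok]) ** 2 / exp[ok]).sum()
            pval = stats.chi2.sf(chi2, df=ok.sum() - 1)
            rejected += pval < alpha
        scores.append(1.0 - rejected / n_test)
    if not scores:
        raise ValueError("no label usable for kBET")
    return float(np.mean(scores))


# -------------------------------------------------------- modality alignment

def modality_asw(embeddings: dict[str, np.ndarray], type_labels: np.ndarray) -> float:
    """Silhouette-based modality mixing (1 = perfectly aligned modalities).

    Embeddings of each modality are stacked with a modality tag playing the
    role of the batch label in the batch-ASW convention: per type label,
    average 1 - |silhouette|, then average across labels.
    """
    mods = sorted(embeddings)
    X = np.vstack([embeddings[m] for m in mods])
    mod_tag = np.concatenate([np.full(len(embeddings[m]), i) for i, m in enumerate(mods)])
    types = np.concatenate([np.asarray(type_labels) for _ in mods])
    scores = []
    for lab in np.unique(types):
        sel = types == lab
        if sel.sum() < 2 or len(np.unique(mod_tag[sel])) < 2:
            continue
        s = silhouette_samples(X[sel], mod_tag[sel])
        scores.append(float(np.mean(1.0 - np.abs(s))))
    if not scores:
        raise ValueError("no type label with >=2 cells in >=2 modalities")
    return float(np.mean(scores))


def foscttm(e1: np.ndarray, e2: np.ndarray) -> float:
    """1 - fraction of samples closer than the true match, both directions.

    Rows of `e1`/`e2` are embeddings of the same cells in two modalities;
    1 means every cell's true match is its nearest cross-modal point.
    """
    e1, e2 = np.asarray(e1, dtype=float), np.asarray(e2, dtype=float)
    n = e1.shape[0]
    if n < 2 or e1.shape != e2.shape:
        raise ValueError("need >= 2 matched rows of equal dimension")
    d = np.linalg.norm(e1[:, None, :] - e2[None, :, :], axis=2)
    true = np.diag(d)
    frac1 = (d < true[:, None]).sum(axis=1) / n   # cells in m2 closer to e1_i
    frac2 = (d < true[None, :]).sum(axis=0) / n   # cells in m1 closer to e2_i
    return float(1.0 - 0.5 * (frac1.mean() + frac2.mean()))


def label_transfer_f1(embeddings: dict[str, np.ndarray],
                      type_labels: np.ndarray) -> float:
    """1-NN cross-modal label transfer, micro-F1 averaged over ordered pairs."""
    mods = sorted(embeddings)
    if len(mods) < 2:
        raise ValueError("need at least two modality embeddings")
    labels = np.asarray(type_labels)
    scores = []
    for src in mods:
        for dst in mods:
            if src == dst:
                continue
            nn = NearestNeighbors(n_neighbors=1).fit(embeddings[src])
            idx = nn.kneighbors(embeddings[dst], return_distance=False)[:, 0]
            scores.append(f1_score(labels, labels[idx], average="micro"))
    return float(np.mean(scores))


def cross_modal_feature_scores(impute_fn, dataset, true_counts: dict[str, np.ndarray],
                               modalities: tuple[str, ...] = ("ATAC", "RNA", "ADT"),
                               ) -> dict[str, float]:
    """Impute each target modality from every combination of the others.

    `impute_fn(combination)` must return imputed means over the full unions
    for all modalities when only `combination` is observed.  ATAC is scored
    by AUROC against the true binary counts; RNA/ADT by flattened Pearson r.
    Constant predictions score 0 with a warning.
    """
    from itertools import combinations
    out = {}
    for target in modalities:
        others = [m for m in modalities if m != target]
        combos = [c for r in range(1, len(others) + 1)
                  for c in combinations(others, r)]
        scores = []
        for combo in combos:
            lam = impute_fn(combo)[target]
            truth = np.asarray(true_counts[target], dtype=float)
            if target == "ATAC":
                scores.append(roc_auc_score(truth.ravel() > 0, lam.ravel()))
            else:
                if np.std(lam) == 0 or np.std(truth) == 0:
                    warnings.warn(f"constant {target} prediction; Pearson set to 0")
                    scores.append(0.0)
                else:
                    scores.append(float(np.corrcoef(lam.ravel(), truth.ravel())[0, 1]))
        key = {"ATAC": "ATAC_AUROC", "RNA": "RNA_pearson", "ADT": "ADT_pearson"}[target]
        out[key] = float(np.clip(np.mean(scores), 0.0, 1.0))
    return out


# ----------------------------------------------------- biological conservation

def _leiden_sweep(graph: NeighborGraph, type_labels: np.ndarray,
                  resolutions=None, seed: int = 0) -> np.ndarray:
    """Community clustering swept over resolutions, keeping the max-NMI one."""
    import igraph
    import leidenalg
    if resolutions is None:
        resolutions = np.arange(0.1, 2.01, 0.1)
    edges = [(i, j) for i in range(graph.n) for j in graph.indices[i]]
    g = igraph.Graph(n=graph.n, edges=edges, directed=False)
    g.simplify()
    best, best_nmi = None, -1.0
    for res in resolutions:
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(res), seed=seed, n_iterations=2)
        pred = np.asarray(part.membership)
        nmi = normalized_mutual_info_score(type_labels, pred)
        if nmi > best_nmi:
            best, best_nmi = pred, nmi
    return best


def _isolated_f1(pred: np.ndarray, type_labels: np.ndarray,
                 batch_labels: np.ndarray | None) -> float:
    """F1 for the labels shared by the fewest batches, best over clusters."""
    labels = np.asarray(type_labels)
    if batch_labels is None:
        counts = {lab: 1 for lab in np.unique(labels)}
    else:
        counts = {lab: len(np.unique(np.asarray(batch_labels)[labels == lab]))
                  for lab in np.unique(labels)}
    fewest = min(counts.values())
    isolated = [lab for lab, c in counts.items() if c == fewest]
    scores = []
    for lab in isolated:
        truth = labels == lab
        best = 0.0
        for cl in np.unique(pred):
            best = max(best, f1_score(truth, pred == cl))
        scores.append(best)
    return float(np.mean(scores))


def bio_conservation(graph: NeighborGraph, type_labels: np.ndarray,
                     batch_labels: np.ndarray | None = None,
                     seed: int = 0) -> dict[str, float]:
    """NMI, ARI (vs optimized community clustering), isolated-label F1, cLISI."""
    pred = _leiden_sweep(graph, type_labels, seed=seed)
    return {
        "NMI": float(normalized_mutual_info_score(type_labels, pred)),
        "ARI": float(np.clip(adjusted_rand_score(type_labels, pred), 0.0, 1.0)),
        "isolated_F1": _isolated_f1(pred, type_labels, batch_labels),
        "cLISI": graph_clisi(graph, type_labels),
    }


# ------------------------------------------------------------- overall scores

def overall_scores(batch: dict[str, dict[str, float]],
                   modality: dict[str, float],
                   bio: dict[str, dict[str, float]]) -> dict[str, float]:
    """Weighted overall scores: 0.4/0.6 per space; 0.3/0.3/0.4 across spaces."""
    out = {}
    for space in batch:
        if space not in bio:
            raise ValueError(f"missing bio metrics for space {space!r}")
        b, o = batch[space], bio[space]
        _require(b, ("iLISI", "graph_connectivity", "kBET"), f"batch[{space}]")
        _require(o, ("NMI", "ARI", "isolated_F1", "cLISI"), f"bio[{space}]")
        out[f"scib_{space}"] = (0.4 * np.mean([b["iLISI"], b["graph_connectivity"],
                                               b["kBET"]])
                                + 0.6 * np.mean([o["NMI"], o["ARI"],
                                                 o["isolated_F1"], o["cLISI"]]))
    if set(batch) == {"embedding", "feature"} and modality:
        _require(modality, ("ASW", "FOSCTTM", "label_transfer_F1",
                            "ATAC_AUROC", "RNA_pearson", "ADT_pearson"), "modality")
        b6 = [batch[s][k] for s in ("embedding", "feature")
              for k in ("iLISI", "graph_connectivity", "kBET")]
        m6 = [modality[k] for k in ("ASW", "FOSCTTM", "label_transfer_F1",
                                    "ATAC_AUROC", "RNA_pearson", "ADT_pearson")]
        o8 = [bio[s][k] for s in ("embedding", "feature")
              for k in ("NMI", "ARI", "isolated_F1", "cLISI")]
        out["mosaic_overall"] = 0.3 * np.mean(b6) + 0.3 * np.mean(m6) + 0.4 * np.mean(o8)
    return {k: float(v) for k, v in out.items()}


def _require(d: dict, keys, where: str) -> None:
    missing = [k for k in keys if k not in d]
    if missing:
        raise ValueError(f"missing {where} components: {missing}")


def modality_contribution(modality_graphs: dict[str, NeighborGraph],
                          joint_graph: NeighborGraph) -> dict[str, np.ndarray]:
    """Per-cell neighbor-overlap with the joint graph, normalized across modalities."""
    raw = {}
    for m, g in modality_graphs.items():
        if g.n != joint_graph.n or g.k != joint_graph.k:
            raise ValueError("graphs must share N and k")
        raw[m] = np.array([
            len(set(g.indices[i]) & set(joint_graph.indices[i])) / joint_graph.k
            for i in range(g.n)])
    total = sum(raw.values())
    total = np.where(total == 0, 1.0, total)
    return {m: v / total for m, v in raw.items()}


def feature_space_graph(counts: dict[str, np.ndarray], k: int = 15,
                        n_components: int = 32, seed: int = 0) -> NeighborGraph:
    """Standardize each modality, project to PCs, concatenate, build kNN."""
    parts = []
    for m in sorted(counts):
        X = np.asarray(counts[m], dtype=float)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
        nc = min(n_components, min(Xs.shape) - 1)
        if nc < n_components:
            warnings.warn(f"{m}: shrinking PCA components to {nc}")
        parts.append(PCA(n_components=nc, random_state=seed).fit_transform(Xs))
    return build_knn_graph(np.hstack(parts), k=k, space_tag="feature")
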