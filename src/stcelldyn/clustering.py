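"""Reference-based clustering with supervised label propagation.

The opioid-naive wild-type group (AA_SAL) is clustered first: scaled
expression -> PCA (top 100 components) -> removal of components correlated
with a technical bias vector (log2 total counts per cell) -> shared
nearest-neighbor graph -> Louvain community detection with a
modularity-maximizing resolution scan.  All remaining cells are projected
into the reference component space and labeled by a random forest trained
on the reference partition.  A per-cluster downsampled t-SNE provides the
2-D embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors


@dataclass
class EmbeddingSet:
    """PCA scores with the bias-filtered component set."""

    scores: np.ndarray  # cells x retained components
    retained_component_ids: np.ndarray
    bias_correlations: np.ndarray  # all fitted components
    mean_: np.ndarray = None
    scale_: np.ndarray = None
    components_: np.ndarray = None  # all fitted loadings (for projection)
    clip: float = 10.0

    @property
    def n_retained(self) -> int:
        return len(self.retained_component_ids)

    def project(self, X) -> np.ndarray:
        """Project new cells with the reference scaling and loadings."""
        Z = _scale_clip(X, self.mean_, self.scale_, self.clip)
        return (Z @ self.components_.T)[:, self.retained_component_ids]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # int cluster per cell
    provenance: np.ndarray  # 'reference-louvain' | 'rf-predicted'
    rf_confidence: np.ndarray = None  # vote fraction; nan for reference cells
    resolution: float = None
    modularity: float = None
    extras: dict = field(default_factory=dict)


def _scale_clip(X, mean, scale, clip):
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
    Z = (X - mean) / scale
    np.clip(Z, -clip, clip, out=Z)
    return Z


def corrected_pca(X, bias=None, n_components: int = 100,
                  bias_r_max: float = 0.7, clip: float = 10.0,
                  seed: int = 0) -> EmbeddingSet:
    """PCA on scaled expression with technical-bias component removal.

    Genes are standardized (zero mean, unit variance, values clipped at
    ±``clip``); the top ``n_components`` components are fitted and any
    component whose score vector has \\|Pearson r\\| > ``bias_r_max``
    against the bias vector (default: log2 total expression per cell) is
    excluded.  The absolute correlation is used because anti-correlated
    components are equally technical.
    """
    Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
    n_cells, n_genes = Xd.shape
    if bias is None:
        bias = np.log2(Xd.sum(axis=1) + 1.0)
    bias = np.asarray(bias, float)
    mean = Xd.mean(axis=0)
    scale = Xd.std(axis=0)
    scale[scale == 0] = 1.0
    Z = _scale_clip(Xd, mean, scale, clip)
    k = min(n_components, n_cells - 1, n_genes)
    if k < n_components:
        warnings.warn(f"n_components reduced to {k}")
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(Z)
    r = np.zeros(k)
    if bias.std() > 0:
        for j in range(k):
            sj = scores[:, j]
            r[j] = 0.0 if sj.std() == 0 else np.corrcoef(sj, bias)[0, 1]
    retained = np.flatnonzero(np.abs(r) <= bias_r_max)
    return EmbeddingSet(scores=scores[:, retained],
                        retained_component_ids=retained,
                        bias_correlations=r, mean_=mean, scale_=scale,
                        components_=pca.components_, clip=clip)


def snn_graph(scores: np.ndarray, k: int = 50) -> ig.Graph:
    """Exact kNN -> shared-nearest-neighbor Jaccard graph (Seurat-like);
    edges with Jaccard weight <= 1/15 are pruned."""
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    _, idx = nn.kneighbors(scores)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    shared = adj @ adj.T
    shared = sp.triu(shared.tocoo(), k=1)
    union = 2 * k - shared.data
    jac = shared.data / union
    keep = jac > 1.0 / 15.0
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def louvain_reference(E: EmbeddingSet, k: int = 50,
                      resolution: str | float = "auto",
                      resolution_grid=None, seed: int = 0) -> ClusterAssignment:
    """Louvain clustering of the reference cells on the SNN graph.

    ``resolution='auto'`` scans ``resolution_grid`` (default 0.4–2.0 step
    0.2) and keeps the partition with maximal modularity.
    """
    g = snn_graph(E.scores, k=k)
    w = g.es["weight"]
    if resolution == "auto":
        grid = (np.arange(0.4, 2.01, 0.2) if resolution_grid is None
                else np.asarray(resolution_grid, float))
    else:
        grid = [float(resolution)]
    best = None
    import random as _random
    for res in grid:
        ig.set_random_number_generator(_random.Random(seed))
        part = g.community_multilevel(weights=w, resolution=res)
        q = g.modularity(part.membership, weights=w)
        if best is None or q > best[0]:
            best = (q, res, np.asarray(part.membership))
    q, res, labels = best
    n = len(labels)
    return ClusterAssignment(labels=labels,
                             provenance=np.full(n, "reference-louvain"),
                             rf_confidence=np.full(n, np.nan),
                             resolution=float(res), modularity=float(q))


def propagate_labels(E_ref: np.ndarray, labels_ref: np.ndarray,
                     E_query: np.ndarray, n_trees: int = 200,
                     seed: int = 0) -> ClusterAssignment:
    """Random-forest label propagation from the reference partition to
    query cells; returns predicted labels with class-vote confidence."""
    labels_ref = np.asarray(labels_ref)
    if E_query.shape[0] == 0:
        return ClusterAssignment(labels=np.array([], dtype=labels_ref.dtype),
                                 provenance=np.array([], dtype=object),
                                 rf_confidence=np.array([]))
    if len(np.unique(labels_ref)) == 1:
        warnings.warn("single reference class: constant prediction")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(E_ref, labels_ref)
    proba = rf.predict_proba(E_query)
    pred = rf.classes_[np.argmax(proba, axis=1)]
    conf = proba.max(axis=1)
    return ClusterAssignment(labels=pred,
                             provenance=np.full(len(pred), "rf-predicted"),
                             rf_confidence=conf)


def cluster_all(X, cells, reference_group: str = "AA_SAL", k: int = 50,
                n_components: int = 100, n_trees: int = 200,
                resolution: str | float = "auto",
                seed: int = 0) -> tuple[EmbeddingSet, ClusterAssignment]:
    """Full workflow: corrected PCA on the reference group, Louvain there,
    random-forest propagation to all other cells."""
    group = cells["sample"].to_numpy()
    ref = group == reference_group
    if not ref.any():
        raise ValueError(f"reference group {reference_group} absent")
    Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
    E = corrected_pca(Xd[ref], n_components=n_components, seed=seed)
    ref_assign = louvain_reference(E, k=min(k, int(ref.sum()) - 1),
                                   resolution=resolution, seed=seed)
    E_query = E.project(Xd[~ref])
    q_assign = propagate_labels(E.scores, ref_assign.labels, E_query,
                                n_trees=n_trees, seed=seed)
    labels = np.empty(Xd.shape[0], dtype=int)
    prov = np.empty(Xd.shape[0], dtype=object)
    conf = np.full(Xd.shape[0], np.nan)
    labels[ref] = ref_assign.labels
    prov[ref] = "reference-louvain"
    labels[~ref] = q_assign.labels
    prov[~ref] = "rf-predicted"
    conf[~ref] = q_assign.rf_confidence
    full_scores = np.empty((Xd.shape[0], E.n_retained))
    full_scores[ref] = E.scores
    full_scores[~ref] = E_query
    out = ClusterAssignment(labels=labels, provenance=prov, rf_confidence=conf,
                            resolution=ref_assign.resolution,
                            modularity=ref_assign.modularity,
                            extras={"scores": full_scores, "embedding": E})
    return E, out


def embed_tsne(scores: np.ndarray, labels: np.ndarray,
               max_per_cluster: int = 1000, seed: int = 0,
               perplexity: float = 30.0):
    """Per-cluster downsampled t-SNE.  Returns (coordinates, kept indices)."""
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size > max_per_cluster:
            idx = rng.choice(idx, size=max_per_cluster, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    perp = min(perplexity, max((keep.size - 1) / 3.0, 2.0))
    ts = TSNE(n_components=2, random_state=seed, perplexity=perp, init="pca")
    coords = ts.fit_transform(scores[keep])
    return coords, keep
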