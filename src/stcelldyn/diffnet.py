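"""Differential co-expression networks and mutual-information hub
analysis.

For a module's genes, region × region Pearson networks are built
separately under saline and morphine; the MOR − SAL difference matrix,
normalized by its maximum absolute entry, captures treatment-induced
rewiring (top edges retained).  Gene-level hubs are scored on
ARACNe-style mutual-information networks (equal-frequency discretization,
plug-in estimator, data-processing-inequality pruning, permutation edge
threshold) inferred per condition; Δhub = degree_MOR − degree_SAL.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# differential correlation networks
# ---------------------------------------------------------------------------

@dataclass
class DifferentialNetwork:
    module: str
    genotype: str
    edges: pd.DataFrame  # region_a, region_b, r_SAL, r_MOR, delta, normalized_delta
    max_abs_delta: float


def differential_network(module_genes, M_sal: pd.DataFrame,
                         M_mor: pd.DataFrame, max_edges: int = 200,
                         module: str = "", genotype: str = "") -> DifferentialNetwork:
    """Region-pair correlation difference (MOR − SAL) over module genes.

    Regions are inner-joined across conditions; delta is normalized by the
    maximum |delta| (computed before truncation); the top ``max_edges``
    edges by |normalized_delta| are kept, ties broken lexicographically by
    (region_a, region_b).
    """
    genes = [g for g in module_genes if g in M_sal.columns and g in M_mor.columns]
    if len(genes) < 2:
        raise ValueError("need >= 2 module genes present in both matrices")
    regions = sorted(set(M_sal.index) & set(M_mor.index))
    dropped = (set(M_sal.index) | set(M_mor.index)) - set(regions)
    if dropped:
        warnings.warn(f"regions absent in one condition dropped: {sorted(dropped)}")
    if len(regions) < 3:
        raise ValueError("need >= 3 shared regions")
    R_sal = np.corrcoef(M_sal.loc[regions, genes].to_numpy())
    R_mor = np.corrcoef(M_mor.loc[regions, genes].to_numpy())
    delta = R_mor - R_sal
    rows = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            rows.append({"region_a": regions[i], "region_b": regions[j],
                         "r_SAL": float(R_sal[i, j]),
                         "r_MOR": float(R_mor[i, j]),
                         "delta": float(delta[i, j])})
    tab = pd.DataFrame(rows)
    mx = float(tab["delta"].abs().max())
    tab["normalized_delta"] = tab["delta"] / mx if mx > 0 else 0.0
    tab["_abs"] = tab["normalized_delta"].abs()
    tab = tab.sort_values(["_abs", "region_a", "region_b"],
                          ascending=[False, True, True]).drop(columns="_abs")
    tab = tab.head(max_edges).reset_index(drop=True)
    return DifferentialNetwork(module=module, genotype=genotype, edges=tab,
                               max_abs_delta=mx)


# ---------------------------------------------------------------------------
# ARACNe-style mutual information networks
# ---------------------------------------------------------------------------

def discretize_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning into ``n_bins`` bins."""
    order = np.argsort(x, kind="stable")
    bins = np.empty(x.size, dtype=int)
    bins[order] = (np.arange(x.size) * n_bins) // x.size
    return bins


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int | None = None) -> float:
    """Plug-in MI (nats) on equal-frequency-discretized data
    (default ceil(sqrt(n)) bins)."""
    n = x.size
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n)))
    bx = discretize_equal_frequency(np.asarray(x, float), n_bins)
    by = discretize_equal_frequency(np.asarray(y, float), n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())


def dpi_prune(MI: np.ndarray, tolerance: float = 0.0) -> np.ndarray:
    """Data-processing-inequality pruning: in every triangle, the weakest
    edge is removed if weaker than both others by more than
    ``tolerance``.  Returns a pruned copy (removed edges set to 0)."""
    A = np.asarray(MI, dtype=float).copy()
    n = A.shape[0]
    remove = np.zeros_like(A, dtype=bool)
    for i, j, k in itertools.combinations(range(n), 3):
        eij, eik, ejk = A[i, j], A[i, k], A[j, k]
        if min(eij, eik, ejk) == 0:
            continue
        if eij < eik - tolerance and eij < ejk - tolerance:
            remove[i, j] = remove[j, i] = True
        elif eik < eij - tolerance and eik < ejk - tolerance:
            remove[i, k] = remove[k, i] = True
        elif ejk < eij - tolerance and ejk < eik - tolerance:
            remove[j, k] = remove[k, j] = True
    A[remove] = 0.0
    return A


def aracne_network(M: pd.DataFrame, tolerance: float = 0.0,
                   n_perm: int = 100, alpha: float = 0.05,
                   seed: int = 0, apply_dpi: bool = True) -> pd.DataFrame:
    """ARACNe-style MI adjacency over genes (columns) across region
    samples (rows).

    Pairwise plug-in MI on ceil(sqrt(n))-bin equal-frequency data; edges
    below a permutation significance threshold (1−alpha quantile of MI
    between independently permuted gene pairs, ``n_perm`` draws) are
    zeroed; DPI pruning removes the weakest edge of each remaining
    triangle.  Constant genes get zero rows.
    """
    if M.shape[0] < 4:
        raise ValueError("need >= 4 samples")
    if M.shape[1] < 3:
        raise ValueError("need >= 3 genes")
    X = M.to_numpy(dtype=float)
    n, m = X.shape
    genes = list(M.columns)
    MI = np.zeros((m, m))
    const = X.std(axis=0) == 0
    for i in range(m):
        for j in range(i + 1, m):
            if const[i] or const[j]:
                continue
            MI[i, j] = MI[j, i] = mutual_information(X[:, i], X[:, j])
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = []
        for _ in range(n_perm):
            i, j = rng.integers(m), rng.integers(m)
            if const[i] or const[j]:
                continue
            null.append(mutual_information(rng.permutation(X[:, i]), X[:, j]))
        if null:
            thr = float(np.quantile(null, 1 - alpha))
            MI[MI < thr] = 0.0
    if apply_dpi:
        MI = dpi_prune(MI, tolerance=tolerance)
    return pd.DataFrame(MI, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# hub analysis and region-specific modules
# ---------------------------------------------------------------------------

@dataclass
class HubResult:
    module: str
    genotype: str
    table: pd.DataFrame  # gene, degree_SAL, degree_MOR, delta_hub
    top_hubs: list = field(default_factory=list)
    subnetwork_nodes: list = field(default_factory=list)
    subnetwork_edges: pd.DataFrame | None = None


def delta_hub(net_sal: pd.DataFrame, net_mor: pd.DataFrame, top_k: int = 3,
              max_nodes: int = 25, module: str = "",
              genotype: str = "") -> HubResult:
    """Change in network degree between conditions.

    degree = number of retained (post-threshold, post-DPI) edges; Δhub =
    degree_MOR − degree_SAL; the top ``top_k`` genes by |Δhub| (ties:
    higher degree_MOR, then lexicographic) seed a subnetwork of their
    MOR-network neighbors ranked by MI, truncated to ``max_nodes``.
    """
    genes = list(net_sal.columns)
    if list(net_mor.columns) != genes:
        raise ValueError("networks must share the gene set")
    d_sal = (net_sal.to_numpy() > 0).sum(axis=1)
    d_mor = (net_mor.to_numpy() > 0).sum(axis=1)
    tab = pd.DataFrame({"gene": genes, "degree_SAL": d_sal,
                        "degree_MOR": d_mor,
                        "delta_hub": d_mor - d_sal})
    if tab["degree_SAL"].sum() == 0 and tab["degree_MOR"].sum() == 0:
        warnings.warn("both networks empty")
        return HubResult(module=module, genotype=genotype, table=tab)
    ranked = sorted(tab.itertuples(index=False),
                    key=lambda r: (-abs(r.delta_hub), -r.degree_MOR, r.gene))
    hubs = [r.gene for r in ranked[:top_k]]
    # subnetwork: hubs + MOR neighbors by descending MI weight
    nodes = list(hubs)
    cand = []
    for h in hubs:
        w = net_mor[h]
        for g in w.index[w > 0]:
            if g not in nodes:
                cand.append((float(w[g]), g, h))
    for _, g, _ in sorted(cand, key=lambda t: (-t[0], t[1])):
        if len(nodes) >= max_nodes:
            break
        if g not in nodes:
            nodes.append(g)
    sub = net_mor.loc[nodes, nodes]
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if sub.loc[a, b] > 0:
                edges.append({"gene_a": a, "gene_b": b,
                              "mi": float(sub.loc[a, b])})
    return HubResult(module=module, genotype=genotype, table=tab,
                     top_hubs=hubs, subnetwork_nodes=nodes,
                     subnetwork_edges=pd.DataFrame(edges))


def region_specific_modules(eigengenes_by_region: pd.DataFrame,
                            z_crit: float = 1.5) -> pd.DataFrame:
    """Flag modules whose eigengene, z-scored across regions, exceeds
    |z| > ``z_crit``; 'single_region' marks modules where exactly one
    region exceeds.  Input: regions × modules mean-eigengene matrix."""
    if eigengenes_by_region.shape[0] < 3:
        raise ValueError("need >= 3 regions")
    E = eigengenes_by_region
    rows = []
    for mod in E.columns:
        v = E[mod].to_numpy(dtype=float)
        sd = v.std()
        z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
        n_exceed = int((np.abs(z) > z_crit).sum())
        for region, zi in zip(E.index, z):
            rows.append({"module": mod, "region": region, "z": float(zi),
                         "region_specific": bool(abs(zi) > z_crit),
                         "single_region": n_exceed == 1 and abs(zi) > z_crit})
    return pd.DataFrame(rows)
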