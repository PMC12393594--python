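"""Rule-based neurotransmitter/glial identity calling and hierarchical
annotation.

An identity rule is a conjunction of gene groups; a cell passes the
identity iff every group contains at least one "high" gene, where high
means log2(CPM + 1) > 3 on the raw counts.  A two-component Gaussian
mixture fitted to each rule gene's log2CPM distribution is reported as a
bimodality diagnostic but does not change the call.  A cluster receives
every identity passed by more than 30% of its cells; the primary identity
is the one with the largest passing fraction (ties broken
lexicographically).  Marker-based cluster QC requires >= 8 high-confidence
markers (adjusted P < 0.01, q_diff >= 0.7) and a cumulative DE score
(sum of -log10 adjusted P over those markers) >= 150.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.mixture import GaussianMixture

from .differential import de_test


def load_rules(path=None) -> dict:
    """Load the identity rule table (JSON: kind -> identity -> list of
    alternative-gene groups).  Default: the curated mouse-brain rules
    shipped with the package."""
    if path is None:
        with resources.files("stcelldyn.data").joinpath("rules.json").open() as fh:
            return json.load(fh)
    with open(path) as fh:
        return json.load(fh)


def log2cpm(counts) -> np.ndarray:
    """log2(CPM + 1) per entry on raw counts (dense)."""
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    cpm = counts.multiply(1e6 / totals[:, None]).tocsr()
    return np.log2(np.asarray(cpm.todense()) + 1.0)


def call_high_expression(counts, gene_names, gene: str,
                         threshold_log2cpm: float = 3.0, seed: int = 0):
    """High-expression call for one gene: log2(CPM+1) > threshold.

    Returns (boolean per cell, diagnostics dict with the two GMM component
    means and their posterior crossover point when a 2-component fit is
    possible).  An absent gene yields all-False with a warning.
    """
    gene_names = list(gene_names)
    if gene not in gene_names:
        warnings.warn(f"gene {gene!r} absent; all cells low")
        n = sp.csr_matrix(counts).shape[0]
        return np.zeros(n, dtype=bool), {"present": False}
    j = gene_names.index(gene)
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    vals = np.log2(np.asarray(counts[:, j].todense()).ravel() * 1e6 / totals + 1.0)
    high = vals > threshold_log2cpm
    diag = {"present": True, "gmm_means": None, "crossover": None}
    if np.unique(vals).size >= 2 and vals.size >= 10:
        gm = GaussianMixture(n_components=2, random_state=seed).fit(vals[:, None])
        means = np.sort(gm.means_.ravel())
        grid = np.linspace(means[0], means[1], 512)
        post = gm.predict_proba(grid[:, None])
        hi = int(np.argmax(gm.means_.ravel()))
        cross = grid[np.argmin(np.abs(post[:, hi] - 0.5))]
        diag["gmm_means"] = means.tolist()
        diag["crossover"] = float(cross)
    return high, diag


def classify_cells(counts, gene_names, rules: dict | None = None,
                   threshold_log2cpm: float = 3.0) -> pd.DataFrame:
    """Per-cell identity flags: a cell passes an identity iff every
    required group has >= 1 high gene.  Cells may pass several identities;
    all are recorded (boolean DataFrame, cells × identities)."""
    rules = load_rules() if rules is None else rules
    gene_names = list(gene_names)
    name_to_col = {g: i for i, g in enumerate(gene_names)}
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    n = counts.shape[0]
    flags = {}
    for kind, idents in rules.items():
        for ident, groups in idents.items():
            ok = np.ones(n, dtype=bool)
            for group in groups:
                any_high = np.zeros(n, dtype=bool)
                for g in group:
                    j = name_to_col.get(g)
                    if j is None:
                        continue
                    vals = np.log2(
                        np.asarray(counts[:, j].todense()).ravel() * 1e6 / totals + 1.0)
                    any_high |= vals > threshold_log2cpm
                ok &= any_high
            flags[ident] = ok
    return pd.DataFrame(flags)


@dataclass
class AnnotationRecord:
    cluster: int
    nt_identity: str | None = None
    glial_identity: str | None = None
    primary_identity: str | None = None
    passing_fraction: dict = field(default_factory=dict)
    qc: str = "retained"
    hierarchy: dict = field(default_factory=dict)
    markers: pd.DataFrame | None = None
    overlap_best_match: list | None = None
    overlap_score: float | None = None


def assign_cluster_identity(flags: pd.DataFrame, labels: np.ndarray,
                            rules: dict | None = None,
                            min_fraction: float = 0.30) -> dict[int, AnnotationRecord]:
    """Aggregate per-cell identity flags to clusters.

    Each identity with passing fraction strictly > ``min_fraction`` is
    assigned; the primary identity is the highest fraction (ties resolved
    lexicographically).  Clusters passing nothing are labeled "Other".
    """
    rules = load_rules() if rules is None else rules
    nt_set = set(rules.get("neurotransmitter", {}))
    glial_set = set(rules.get("glial", {}))
    labels = np.asarray(labels)
    out = {}
    for c in np.unique(labels):
        m = labels == c
        frac = flags.iloc[np.flatnonzero(m)].mean(axis=0).to_dict()
        passing = {k: v for k, v in frac.items() if v > min_fraction}
        rec = AnnotationRecord(cluster=int(c), passing_fraction=frac)
        if passing:
            best = sorted(passing.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            rec.primary_identity = best
            nts = sorted((k for k in passing if k in nt_set),
                         key=lambda k: (-passing[k], k))
            gls = sorted((k for k in passing if k in glial_set),
                         key=lambda k: (-passing[k], k))
            rec.nt_identity = nts[0] if nts else None
            rec.glial_identity = gls[0] if gls else None
        else:
            rec.primary_identity = "Other"
        out[int(c)] = rec
    return out


def marker_qc(cluster: int, X, labels: np.ndarray, gene_names,
              min_cells: int = 50, p_adj_max: float = 0.01,
              q_diff_min: float = 0.7, min_markers: int = 8,
              de_score_min: float = 150.0, neglogp_cap: float = 300.0):
    """Marker-based cluster retention.

    One-vs-rest Wilcoxon markers; high-confidence markers require adjusted
    P < ``p_adj_max`` and q_diff >= ``q_diff_min``; the DE score is the sum
    of -log10(P_adj) over those markers (per-gene contribution capped at
    ``neglogp_cap``).  Verdict "retained" iff >= ``min_markers`` markers
    and DE score >= ``de_score_min``.
    """
    labels = np.asarray(labels)
    in_mask = labels == cluster
    n_in = int(in_mask.sum())
    if n_in < min_cells:
        return {"verdict": "too_small", "n_cells": n_in,
                "n_markers": 0, "de_score": 0.0, "markers": None}
    Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
    if Xd[in_mask].sum() == 0:
        return {"verdict": "other", "n_cells": n_in,
                "n_markers": 0, "de_score": 0.0, "markers": None}
    tab = de_test(Xd[in_mask], Xd[~in_mask], gene_names,
                  min_pct=0.0, logfc_min=0.0, upregulated_only=False)
    hi = tab[(tab["p_adj"] < p_adj_max) & (tab["q_diff"] >= q_diff_min)]
    contrib = np.minimum(-np.log10(np.maximum(hi["p_adj"].to_numpy(), 1e-300)),
                         neglogp_cap)
    score = float(contrib.sum())
    verdict = ("retained" if len(hi) >= min_markers and score >= de_score_min
               else "other")
    return {"verdict": verdict, "n_cells": n_in, "n_markers": int(len(hi)),
            "de_score": score, "markers": hi, "cap": neglogp_cap}


def overlap_score(markers, reference_sets: dict):
    """Proportion of cluster markers found in each reference gene set.

    Returns (best_match list — all argmax ties, best score, per-set score
    dict).  An empty marker set has no defined score.
    """
    markers = set(markers)
    if not markers:
        return None, None, {}
    scores = {name: len(markers & set(genes)) / len(markers)
              for name, genes in reference_sets.items()}
    if not scores:
        return None, None, {}
    best = max(scores.values())
    best_match = sorted(k for k, v in scores.items() if v == best)
    return best_match, best, scores


def read_gmt(path) -> dict:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def build_hierarchy(records: dict[int, AnnotationRecord],
                    region_profiles: dict[int, pd.Series],
                    rules: dict | None = None) -> dict[int, dict]:
    """Four-level labels per cluster.

    level1: neuronal iff any neurotransmitter identity, else non-neuronal;
    level2: primary identity; level3: identity × dominant depth-3
    meso-structure; level4: the cluster id.  "Other" clusters propagate
    "Other" at levels 2-3.
    """
    rules = load_rules() if rules is None else rules
    nt_set = set(rules.get("neurotransmitter", {}))
    out = {}
    for c, rec in records.items():
        ident = rec.primary_identity or "Other"
        neuronal = rec.nt_identity is not None and ident in nt_set
        if ident == "Other":
            h = {"level1": "non-neuronal", "level2": "Other",
                 "level3": "Other", "level4": f"cluster_{c}"}
        else:
            prof = region_profiles.get(c)
            meso = (prof.idxmax() if prof is not None and len(prof)
                    else "unknown")
            h = {"level1": "neuronal" if neuronal else "non-neuronal",
                 "level2": ident, "level3": f"{ident}-{meso}",
                 "level4": f"cluster_{c}"}
        rec.hierarchy = h
        out[c] = h
    return out


def annotate_clusters(counts, gene_names, labels, cells: pd.DataFrame,
                      rules: dict | None = None,
                      min_fraction: float = 0.30) -> dict[int, AnnotationRecord]:
    """Convenience wrapper: per-cell flags -> cluster identities ->
    hierarchy from the depth-3 region distribution."""
    rules = load_rules() if rules is None else rules
    flags = classify_cells(counts, gene_names, rules=rules)
    recs = assign_cluster_identity(flags, labels, rules=rules,
                                   min_fraction=min_fraction)
    labels = np.asarray(labels)
    profiles = {int(c): cells["region_d3"][labels == c].value_counts(normalize=True)
                for c in np.unique(labels)}
    build_hierarchy(recs, profiles, rules=rules)
    return recs
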