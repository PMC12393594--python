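"""End-to-end orchestration of the analysis stages.

Stages communicate through files in the output directory; every stochastic
stage consumes a seed derived from the root seed and the stage name, and a
manifest recording seeds, per-stage wall time and output hashes is written
next to the outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, clustering, coexpression, differential, diffnet, \
    preprocess, synthetic

STAGES = ["simulate", "qc", "cluster", "annotate", "deg", "dispro",
          "composition", "network", "modules", "diffnet"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (root_seed + zlib.crc32(stage.encode())) % (2 ** 31)


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def default_config(seed: int = 0, out_dir: str = "out") -> dict:
    return {
        "seed": seed,
        "out_dir": out_dir,
        "stages": list(STAGES),
        "sim": {},
        "qc": {"fov_scale": 0.1},
        "cluster": {"k": 50, "n_trees": 200, "reference_group": "AA_SAL"},
        "deg": {"min_pct": 0.25, "logfc_min": 0.1},
        "modules": {"power": 8, "min_size": 20, "deep_split": 3,
                    "merge_cut": 0.10, "min_cells": 100},
        "network": {"r_min": 0.95},
    }


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config, indent=1, default=str))
    manifest = {"seed": config["seed"], "stages": {}, "files": {}}
    enabled = config.get("stages", STAGES)
    state: dict = {}
    for stage in STAGES:
        if stage not in enabled:
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, state, out)
        except Exception as exc:  # halt with stage name, keep partials
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": stage_seed(config["seed"], stage),
            "seconds": round(time.time() - t0, 3)}
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _hash(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_stage(stage: str, config: dict, state: dict, out: Path) -> None:
    seed = stage_seed(config["seed"], stage)
    if stage == "simulate":
        cfg = synthetic.SimConfig(seed=seed, **config.get("sim", {}))
        state["ds"] = synthetic.generate_dataset(cfg)
        synthetic.write_fixture(state["ds"], out / "fixture")
    elif stage == "qc":
        ds = state["ds"]
        X, gkeep, ckeep, report = preprocess.run_qc(
            ds.counts, ds.genes, ds.cells,
            fov_scale=config.get("qc", {}).get("fov_scale", 1.0))
        state.update(X=X, gene_names=list(ds.genes.index[gkeep]),
                     cells=ds.cells.iloc[ckeep].copy(), ckeep=ckeep,
                     truth_types=ds.truth.cell_type_of_cell[ckeep])
        (out / "qc_report.json").write_text(json.dumps({
            "pass_rate": report.pass_rate, "removed": report.removed,
            "retained_fovs": report.retained_fovs}, indent=1))
    elif stage == "cluster":
        c = config.get("cluster", {})
        E, assign = clustering.cluster_all(
            state["X"], state["cells"], k=c.get("k", 50),
            n_trees=c.get("n_trees", 200),
            reference_group=c.get("reference_group", "AA_SAL"), seed=seed)
        state["assign"] = assign
        pd.DataFrame({"cell": state["cells"].index,
                      "cluster": assign.labels,
                      "provenance": assign.provenance,
                      "confidence": assign.rf_confidence}) \
            .to_csv(out / "clusters.tsv", sep="\t", index=False)
    elif stage == "annotate":
        # raw counts restricted to retained cells/genes for CPM calls
        ds = state["ds"]
        gidx = [list(ds.genes.index).index(g) for g in state["gene_names"]]
        raw = ds.counts[state["ckeep"]][:, gidx]
        state["recs"] = annotation.annotate_clusters(
            raw, state["gene_names"], state["assign"].labels, state["cells"])
        rows = [{"cluster": c, "primary": r.primary_identity,
                 **r.hierarchy} for c, r in state["recs"].items()]
        pd.DataFrame(rows).to_csv(out / "annotation.tsv", sep="\t", index=False)
    elif stage == "deg":
        X, cells = state["X"], state["cells"]
        tabs = []
        for geno in ("AA", "GG"):
            a = ((cells["genotype"] == geno)
                 & (cells["treatment"] == "MOR")).to_numpy()
            b = ((cells["genotype"] == geno)
                 & (cells["treatment"] == "SAL")).to_numpy()
            import numpy as _np
            Xd = X.toarray() if hasattr(X, "toarray") else X
            tab = differential.de_test(
                Xd[a], Xd[b], state["gene_names"],
                upregulated_only=False,
                comparison=f"{geno}:MOR_vs_SAL", **{
                    k: v for k, v in config.get("deg", {}).items()
                    if k in ("min_pct", "logfc_min")})
            tabs.append(tab)
        state["deg"] = pd.concat(tabs, ignore_index=True)
        state["deg"].to_csv(out / "deg.tsv", sep="\t", index=False)
    elif stage == "dispro":
        deg_aa = state["deg"][state["deg"]["comparison"] == "AA:MOR_vs_SAL"]
        sig = deg_aa[deg_aa["p_adj"] < 0.05]
        if len(sig) >= 3:
            res = differential.disproportionality(
                state["X"], state["assign"].labels, state["gene_names"], sig)
            pd.DataFrame([r.__dict__ for r in res]) \
                .to_csv(out / "disproportionality.tsv", sep="\t", index=False)
    elif stage == "composition":
        dyn = differential.composition_dynamics(
            state["cells"], state["assign"].labels, min_n=20)
        dyn.table.to_csv(out / "composition.csv", index=False)
    elif stage == "network":
        M, _ = coexpression.region_mean_matrix(
            state["X"], state["cells"], min_cells=20, seed=seed,
            gene_names=state["gene_names"])
        edges, cent, _ = coexpression.interregion_network(
            M, r_min=config.get("network", {}).get("r_min", 0.95))
        edges.to_csv(out / "interregion_edges.tsv", sep="\t", index=False)
        state["region_matrix"] = M
    elif stage == "modules":
        c = config.get("modules", {})
        rows = {}
        ncounts = {}
        for grp in synthetic.GROUPS:
            M, nc = coexpression.region_mean_matrix(
                state["X"], state["cells"], group=grp,
                min_cells=c.get("min_cells", 100), seed=seed,
                gene_names=state["gene_names"])
            for r in M.index:
                rows[f"{r}_{grp}"] = M.loc[r]
        pooled = pd.DataFrame(rows).T
        state["pooled_matrix"] = pooled
        mods = coexpression.detect_modules(
            pooled, power=c.get("power", 8), min_size=c.get("min_size", 20),
            deep_split=c.get("deep_split", 3),
            merge_cut=c.get("merge_cut", 0.10))
        state["modules"] = mods
        mods.assignment.rename("module").to_csv(out / "modules.tsv", sep="\t")
        mods.eigengenes.to_csv(out / "eigengenes.csv")
    elif stage == "diffnet":
        mods = state["modules"]
        cells, X = state["cells"], state["X"]
        nets = []
        for geno in ("AA", "GG"):
            mats = {}
            for trt in ("SAL", "MOR"):
                M, _ = coexpression.region_mean_matrix(
                    X, cells, group=f"{geno}_{trt}", min_cells=20, seed=seed,
                    gene_names=state["gene_names"])
                mats[trt] = M
            for mod in mods.modules:
                genes = mods.genes_of(mod)
                if len(genes) < 2:
                    continue
                dn = diffnet.differential_network(
                    genes, mats["SAL"], mats["MOR"], module=mod,
                    genotype=geno)
                e = dn.edges.copy()
                e.insert(0, "module", mod)
                e.insert(1, "genotype", geno)
                nets.append(e)
        if nets:
            pd.concat(nets, ignore_index=True).to_csv(
                out / "differential_networks.tsv", sep="\t", index=False)
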