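"""End-to-end pipeline: preprocessing -> clustering -> reporting -> relatedness.

``run_pipeline`` drives the four stages from a single config mapping
and writes a self-describing results bundle: merged expression TSV,
per-method embedding and label TSVs, median/abundance tables, figures,
augmented FCS files and a JSON manifest capturing versions, seeds,
parameters and input hashes. Identical config + seed reproduces the
label and table files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusterx import ClusterXParams, clusterx
from .densvm import densvm
from .dimred import METHODS, reduce
from .fcs import read_fcs, select_markers, write_augmented_fcs
from .phenograph import phenograph
from .preprocess import (
    MergeSpec,
    TransformSpec,
    merge_samples,
    transform_auto_logicle,
    transform_cytof_asinh,
)
from .progression import cluster_medians, downsample_equal, marker_trend
from .report import (
    abundance_table,
    median_expression_table,
    render_heatmap,
    render_scatter,
)

log = logging.getLogger("cytopipe")

CLUSTER_METHODS = ("ClusterX", "PhenoGraph", "DensVM")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_config(config: dict) -> dict:
    """Fill defaults and fail fast on an unusable config."""
    cfg = dict(config)
    if not cfg.get("fcs_files"):
        raise ValueError("config must name at least one FCS file (fcs_files)")
    if not cfg.get("markers"):
        raise ValueError("config must provide a marker selection list (markers)")
    cfg.setdefault("transform", "cytofAsinh")
    cfg.setdefault("cofactor", 5.0)
    cfg.setdefault("merge", "ceil")
    cfg.setdefault("ncells", 10000)
    cfg.setdefault("dimred", ["tsne"])
    cfg.setdefault("cluster", ["ClusterX"])
    cfg.setdefault("progression", None)
    cfg.setdefault("path", None)
    cfg.setdefault("trend_markers", [])
    cfg.setdefault("alpha", 0.001)
    cfg.setdefault("k", 30)
    cfg.setdefault("perplexity", 30.0)
    cfg.setdefault("seed", 42)
    if isinstance(cfg["dimred"], str):
        cfg["dimred"] = [cfg["dimred"]]
    if isinstance(cfg["cluster"], str):
        cfg["cluster"] = [cfg["cluster"]]
    for m in cfg["dimred"]:
        if m not in METHODS:
            raise ValueError(f"unknown dimred method {m!r}; choose from {METHODS}")
    for m in cfg["cluster"]:
        if m not in CLUSTER_METHODS:
            raise ValueError(f"unknown cluster method {m!r}; choose from {CLUSTER_METHODS}")
    if cfg["progression"] not in (None, "isomap", "diffusionmap"):
        raise ValueError("progression must be isomap or diffusionmap")
    TransformSpec(method=cfg["transform"], cofactor=cfg["cofactor"])  # validates
    MergeSpec(method=cfg["merge"], fixed_num=cfg["ncells"])
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _transform_block(matrix: np.ndarray, cfg: dict) -> np.ndarray:
    if cfg["transform"] == "none":
        return matrix
    out = np.empty_like(matrix, dtype=np.float64)
    for j in range(matrix.shape[1]):
        if cfg["transform"] == "cytofAsinh":
            out[:, j] = transform_cytof_asinh(
                matrix[:, j], cofactor=cfg["cofactor"], seed=cfg["seed"] + j
            )
        else:
            out[:, j] = transform_auto_logicle(matrix[:, j])
    return out


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the full pipeline and return the results-bundle directory."""
    cfg = validate_config(config)
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    log.addHandler(handler)
    stage = "setup"
    artifacts: list[str] = []
    try:
        # ---- stage 1: pre-processing -----------------------------------
        stage = "preprocess"
        log.info("reading %d FCS file(s)", len(cfg["fcs_files"]))
        samples = [read_fcs(p) for p in cfg["fcs_files"]]
        blocks = []
        for s in samples:
            block = select_markers(s, cfg["markers"])
            blocks.append((_transform_block(block, cfg), s.path))
        merge_spec = MergeSpec(
            method=cfg["merge"], fixed_num=cfg["ncells"], seed=cfg["seed"]
        )
        expr = merge_samples(
            blocks,
            cfg["markers"],
            merge_spec,
            transform=TransformSpec(method=cfg["transform"], cofactor=cfg["cofactor"]),
        )
        frame = pd.DataFrame(expr.values, columns=expr.marker_names)
        frame.insert(0, "cell_id", [c.id for c in expr.cell_ids])
        frame.to_csv(out / "expression.tsv", sep="\t", index=False)
        artifacts.append("expression.tsv")

        # ---- stage 2/3: embedding + clustering -------------------------
        stage = "dimred"
        embeddings = {}
        need_tsne = any(m in cfg["cluster"] for m in ("ClusterX", "DensVM"))
        methods = list(cfg["dimred"])
        if need_tsne and "tsne" not in methods:
            methods.append("tsne")
        for method in methods:
            log.info("embedding with %s", method)
            params = {"perplexity": cfg["perplexity"]} if method == "tsne" else {}
            emb = reduce(expr, method, d=2, params=params, seed=cfg["seed"])
            embeddings[method] = emb
            emb.to_frame(expr.cell_ids).to_csv(
                out / f"embedding_{method}.tsv", sep="\t", index=False
            )
            artifacts.append(f"embedding_{method}.tsv")

        stage = "cluster"
        results = {}
        for method in cfg["cluster"]:
            log.info("clustering with %s", method)
            if method == "ClusterX":
                res = clusterx(embeddings["tsne"], ClusterXParams(alpha=cfg["alpha"]))
            elif method == "PhenoGraph":
                res = phenograph(expr, k=cfg["k"], seed=cfg["seed"])
            else:
                res = densvm(expr, embeddings["tsne"])
            results[method] = res
            pd.DataFrame(
                {"cell_id": [c.id for c in expr.cell_ids], "label": res.labels}
            ).to_csv(out / f"labels_{method}.tsv", sep="\t", index=False)
            artifacts.append(f"labels_{method}.tsv")

        # ---- stage 3: interpretation tables + figures ------------------
        stage = "report"
        plot_embedding = embeddings[methods[0]]
        for method, res in results.items():
            med = median_expression_table(expr, res)
            med.to_csv(out / f"median_expression_{method}.tsv", sep="\t")
            abund = abundance_table(res, expr.cell_ids)
            abund.to_csv(out / f"abundance_{method}.tsv", sep="\t")
            render_heatmap(
                med, out / f"heatmap_median_{method}.png", title=f"{method} medians"
            )
            render_scatter(
                plot_embedding,
                out / f"scatter_{method}.png",
                color_by="cluster",
                labels=res,
            )
            artifacts += [
                f"median_expression_{method}.tsv",
                f"abundance_{method}.tsv",
                f"heatmap_median_{method}.png",
                f"scatter_{method}.png",
            ]
        if len(samples) > 1:
            render_scatter(
                plot_embedding,
                out / "scatter_sample.png",
                color_by="sample",
                cell_ids=expr.cell_ids,
            )
            artifacts.append("scatter_sample.png")

        # ---- stage 4: inter-subset relatedness -------------------------
        if cfg["progression"]:
            stage = "progression"
            first = cfg["cluster"][0]
            res = results[first]
            idx = downsample_equal(res, target=500, seed=cfg["seed"])
            sub_expr = expr.values[idx]
            emb = reduce(sub_expr, cfg["progression"], d=2, seed=cfg["seed"])
            med = cluster_medians(emb, res.labels[idx])
            med.to_csv(out / "progression_cluster_medians.tsv", sep="\t")
            artifacts.append("progression_cluster_medians.tsv")
            if cfg["path"] and cfg["trend_markers"]:
                from .preprocess import ExpressionMatrix

                sub = ExpressionMatrix(
                    values=sub_expr,
                    cell_ids=[expr.cell_ids[i] for i in idx],
                    marker_names=expr.marker_names,
                )
                rows = []
                for marker in cfg["trend_markers"]:
                    fit, _ = marker_trend(
                        sub, emb, res.labels[idx], cfg["path"], marker, component=2
                    )
                    rows.append(
                        {
                            "marker": marker,
                            "path": "+".join(map(str, cfg["path"])),
                            "beta0": fit.beta0,
                            "beta1": fit.beta1,
                            "sigma": fit.scale,
                            "loglik": fit.loglik,
                            "n": int(np.isin(res.labels[idx], cfg["path"]).sum()),
                            "n_censored": fit.n_censored,
                        }
                    )
                pd.DataFrame(rows).to_csv(out / "marker_trends.tsv", sep="\t", index=False)
                artifacts.append("marker_trends.tsv")

        # ---- augmented FCS back-export ---------------------------------
        stage = "fcs_export"
        for s in samples:
            per_file = np.array([c.source_file == s.path for c in expr.cell_ids])
            new_params: dict[str, np.ndarray] = {}
            for method, emb in embeddings.items():
                for dim in range(2):
                    vec = np.zeros(s.n_events, dtype=np.float32)
                    for row, cid in zip(emb.coords[per_file], np.array(expr.cell_ids)[per_file]):
                        vec[cid.index_in_file - 1] = row[dim]
                    new_params[f"{method}_{dim + 1}"] = vec
            for method, res in results.items():
                vec = np.zeros(s.n_events, dtype=np.float32)
                for lab, cid in zip(res.labels[per_file], np.array(expr.cell_ids)[per_file]):
                    vec[cid.index_in_file - 1] = lab
                new_params[method] = vec
            dest = out / (Path(s.path).stem + "_analyzed.fcs")
            write_augmented_fcs(s, new_params, dest)
            artifacts.append(dest.name)

        # ---- manifest --------------------------------------------------
        stage = "manifest"
        manifest = {
            "cytopipe_version": __version__,
            "config": {k: v for k, v in cfg.items()},
            "inputs": {
                str(p): _sha256(Path(p)) for p in cfg["fcs_files"]
            },
            "n_cells": expr.n_cells,
            "n_markers": len(expr.marker_names),
            "clusters": {m: int(r.n_clusters) for m, r in results.items()},
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return out
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for name in artifacts:
                (out / name).unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
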