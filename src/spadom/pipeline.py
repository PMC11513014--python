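"""End-to-end pipeline: load/simulate -> preprocess -> graph -> train ->
cluster -> SVG detection, driven by a plain config dictionary (the CLI
feeds it from YAML)."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import clustering, datasets, graph, model, simulate, svg

log = logging.getLogger("spadom")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "spadom_out",
    "data": {"synthetic": None, "paths": None, "format": None},
    "preprocess": {"n_hvg": 3000, "normalize": True, "log1p": True},
    "graph": {"k": 6},
    "model": {},  # ModelConfig field overrides
    "clustering": {"n_domains": None, "method": "gmm", "smooth_iterations": 0},
    "svg": {"target_mean_neighbors": 10, "fc_threshold": 1.5, "alpha_fdr": 0.05, "portion": 1.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_input(config: dict):
    """Return (dataset, truth_svgs-or-None) from the config's data section."""
    data = config["data"]
    if data.get("synthetic") is not None:
        spec_kwargs = dict(data["synthetic"] or {})
        spec_kwargs.setdefault("seed", config["seed"])
        spec = simulate.SyntheticSpec(**spec_kwargs)
        log.info("simulating synthetic slide: %s", spec)
        return simulate.generate(spec)
    if data.get("paths"):
        ds = datasets.read_dataset(data["paths"], format=data.get("format"))
        log.info("loaded dataset: %d spots x %d genes", ds.n_spots, ds.n_genes)
        return ds, None
    raise ValueError("config.data must provide either 'synthetic' or 'paths'")


def run_pipeline(config: dict) -> dict:
    """Execute every stage and write artifacts to config['output_dir'].

    Returns a dict with the in-memory results (dataset, train state,
    assignment, SVG report, metrics).
    """
    config = _merge(DEFAULT_CONFIG, config)
    outdir = config["output_dir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(config["seed"])

    stage = "load"
    try:
        ds, truth_svgs = load_input(config)

        stage = "preprocess"
        ds = datasets.preprocess(ds, **config["preprocess"])
        log.info("preprocessed: %d genes retained", ds.n_genes)
        if ds.image_feats is None:
            raise datasets.CapabilityError(
                "dataset has no image features; provide an image_feats input "
                "or use synthetic data with surrogate features"
            )

        stage = "graph"
        g = graph.build_knn_graph(ds.coords, k=int(config["graph"]["k"]))

        stage = "train"
        cfg = model.ModelConfig(**{"seed": seed, **config["model"]})
        state = model.train(ds, g, cfg)
        state.save(os.path.join(outdir, "model"))
        log.info("trained %d epochs; final loss %.4f", cfg.epochs,
                 state.loss_trace[-1, 3] if cfg.epochs else float("nan"))

        stage = "cluster"
        cl = config["clustering"]
        K = cl["n_domains"]
        if K is None:
            if ds.labels is None:
                raise ValueError("clustering.n_domains not set and no labels to infer it from")
            K = len(np.unique(ds.labels))
        assignment = clustering.cluster_embedding(
            state.Zfusion, int(K), method=cl["method"], seed=seed
        )
        labels = assignment.labels
        if cl.get("smooth_iterations", 0):
            labels = clustering.smooth_labels(labels, g, int(cl["smooth_iterations"]))
        pd.DataFrame({"spot_id": ds.spot_ids, "domain": labels}).to_csv(
            os.path.join(outdir, "domains.csv"), index=False
        )

        metrics: dict = {"seed": seed, "n_spots": ds.n_spots, "n_genes": ds.n_genes, "K": int(K)}
        if ds.labels is not None:
            metrics.update(clustering.score_agreement(labels, ds.labels))
            log.info("agreement with reference labels: ARI=%.3f NMI=%.3f",
                     metrics["ari"], metrics["nmi"])

        stage = "svg"
        report = svg.detect_svgs(ds, labels, svg.MGLParams(**config["svg"]))
        report.table.to_csv(os.path.join(outdir, "svg_report.csv"), index=False)
        with open(os.path.join(outdir, "svg_summary.json"), "w") as fh:
            json.dump(report.summary(), fh, indent=2)
        final_genes = sorted(set().union(*report.final_sets.values()))
        if final_genes:
            name_to_col = {str(nm): j for j, nm in enumerate(ds.gene_names)}
            mi = [svg.morans_i(ds.expr[:, name_to_col[str(gname)]], g) for gname in final_genes]
            metrics["median_morans_i"] = float(np.median(mi))
            metrics["n_final_svgs"] = len(final_genes)
        if truth_svgs is not None:
            scores = simulate.score_svg_recovery(
                report.final_sets, truth_svgs, labels, ds.labels
            )
            metrics["svg_recall_mean"] = float(np.mean([s["recall"] for s in scores.values()]))
            metrics["svg_precision_mean"] = float(np.mean([s["precision"] for s in scores.values()]))

        with open(os.path.join(outdir, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=2)
        with open(os.path.join(outdir, "config_used.json"), "w") as fh:
            json.dump(_jsonable(config), fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "dataset": ds,
        "train_state": state,
        "assignment": assignment,
        "labels": labels,
        "svg_report": report,
        "metrics": metrics,
        "graph": g,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
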