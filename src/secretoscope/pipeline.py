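"""End-to-end pipeline: read/simulate → impute → decompose → report.

A run is driven by a plain-YAML (or dict) configuration and writes every
intermediate artifact plus a ``manifest.json`` recording input checksums,
the seed, package versions and all parameters.  The manifest contains no
timestamps, so two runs from one configuration are byte-identical in every
numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .association import (
    amplitude_infiltrate_correlation,
    cluster_order,
    compare_all_treatments,
    pca_scores,
    pearson_matrix,
)
from .datamodel import ValidationError
from .io import (
    align_tables,
    aggregate_by_animal,
    read_edges,
    read_infiltrates,
    read_metadata,
    read_secretome,
    write_infiltrates,
    write_metadata,
    write_secretome,
)
from .network import build_subnetwork, edges_frame, write_graphml
from .surprisal import (
    count_significant_processes,
    decompose,
    estimate_noise_sd_replicates,
    impute_missing_svd,
    log_transform,
    process_activity,
    process_membership,
)
from .synthetic import simulate_study

__all__ = ["run_pipeline", "load_config"]

log = logging.getLogger("secretoscope")

_FLOAT_FMT = "%.12g"

_DEFAULTS = {
    "seed": 0,
    "inputs": {},
    "simulate": None,
    "impute": {"rank": None, "tol": 1e-9, "max_iter": 1000},
    "significance": {"noise_sd": "auto", "n_boot": 100},
    "membership": {"fold": 20.0, "quantile": 0.20},
    "activity": {"threshold": "auto"},
    "association": {
        "aggregate": "mean",
        "distance": "chebyshev",
        "linkage": "average",
        "pca_components": 2,
    },
    "network": {"min_score": None},
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _merged(config: dict) -> dict:
    out = {}
    for key, default in _DEFAULTS.items():
        val = config.get(key, default)
        if isinstance(default, dict) and isinstance(val, dict):
            out[key] = {**default, **val}
        else:
            out[key] = val
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, na_rep="NA", float_format=_FLOAT_FMT, index=index)


def _stage(name: str, t0: float, **shapes) -> None:
    info = ", ".join(f"{k}={v}" for k, v in shapes.items())
    log.info("%s: %s (%.2fs)", name, info, time.perf_counter() - t0)


def run_pipeline(config: dict | str | Path, outdir, log_level: str = "INFO") -> Path:
    """Execute the full analysis described by ``config`` into ``outdir``.

    ``config`` is a dict or a path to a YAML file.  Either
    ``inputs.secretome`` (with optional infiltrates / metadata / edges
    paths and ``detection_floor``) or a ``simulate`` block must be given.
    Returns the run directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))

    manifest: dict = {
        "package": "secretoscope",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": cfg,
        "inputs": {},
        "stages": [],
    }
    seed = int(cfg["seed"])

    # ---- stage: load or simulate -------------------------------------
    t0 = time.perf_counter()
    inputs = cfg["inputs"] or {}
    infiltrates = metadata = edges = None
    truth = None
    if cfg["simulate"] is not None:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)
        secretome, infiltrates, metadata, truth = simulate_study(**sim)
        write_secretome(secretome, outdir / "secretome.csv")
        write_infiltrates(infiltrates, outdir / "infiltrates.csv")
        write_metadata(metadata, outdir / "metadata.csv")
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "seed": truth.seed,
                    "n_cytokines": truth.n_cytokines,
                    "n_samples": truth.n_samples,
                    "K_true": truth.K_true,
                    "noise_sd": truth.noise_sd,
                    "missing_fraction": truth.missing_fraction,
                    "infiltrate_link": {
                        str(k): list(v) for k, v in truth.infiltrate_link.items()
                    },
                    "baseline_log_levels": truth.baseline_log_levels.tolist(),
                    "planted_G": truth.planted_G.tolist(),
                    "planted_lambda": truth.planted_lambda.tolist(),
                },
                indent=1,
            )
        )
        _stage("simulate", t0, secretome=secretome.values.shape)
    elif inputs.get("secretome"):
        floor = float(inputs.get("detection_floor", 1.0))
        secretome = read_secretome(inputs["secretome"], detection_floor=floor)
        manifest["inputs"]["secretome"] = _sha256(inputs["secretome"])
        if inputs.get("infiltrates"):
            infiltrates = read_infiltrates(inputs["infiltrates"])
            manifest["inputs"]["infiltrates"] = _sha256(inputs["infiltrates"])
        if inputs.get("metadata"):
            metadata = read_metadata(inputs["metadata"])
            manifest["inputs"]["metadata"] = _sha256(inputs["metadata"])
        if inputs.get("edges"):
            edges = read_edges(inputs["edges"])
            manifest["inputs"]["edges"] = _sha256(inputs["edges"])
        _stage("read", t0, secretome=secretome.values.shape)
    else:
        raise ValidationError(
            "config must provide either 'inputs.secretome' or a 'simulate' block"
        )
    if cfg["simulate"] is not None and inputs.get("edges"):
        edges = read_edges(inputs["edges"])
        manifest["inputs"]["edges"] = _sha256(inputs["edges"])

    # ---- stage: log transform + imputation ---------------------------
    t0 = time.perf_counter()
    ln = log_transform(secretome)
    imp_cfg = cfg["impute"]
    imputed = impute_missing_svd(
        ln,
        rank=imp_cfg["rank"],
        tol=float(imp_cfg["tol"]),
        max_iter=int(imp_cfg["max_iter"]),
    )
    _stage("impute", t0, missing=secretome.n_missing,
           iterations=imputed.n_iter, converged=imputed.converged)

    # ---- stage: decomposition + significance -------------------------
    t0 = time.perf_counter()
    result = decompose(imputed.values)
    sig = cfg["significance"]
    noise_sd = sig["noise_sd"]
    if noise_sd == "auto":
        # prefer the replicate-pooled estimate when metadata allows it
        if metadata is not None:
            try:
                noise_sd = estimate_noise_sd_replicates(secretome, metadata)
            except ValueError:
                noise_sd = "estimate"
        else:
            noise_sd = "estimate"
    k = count_significant_processes(
        result, noise_sd=noise_sd, n_boot=int(sig["n_boot"]), seed=seed
    )
    _stage("decompose", t0, components=result.n_components, K_significant=k)

    (outdir / "decomposition.json").write_text(
        json.dumps(
            {
                "cytokine_ids": result.cytokine_ids,
                "sample_ids": result.sample_ids,
                "G": result.G.to_numpy().tolist(),
                "lambda": result.lam.to_numpy().tolist(),
                "singular_values": result.singular_values.tolist(),
                "K_significant": result.K_significant,
                "noise_sd_est": result.noise_sd_est,
                "null_threshold_95": result.null_threshold,
                "null_method": (
                    "Monte-Carlo pure-noise 95th percentile "
                    "(stand-in for replicate-based error limits)"
                ),
            },
            indent=1,
        )
    )

    # ---- stage: membership, activity, networks -----------------------
    t0 = time.perf_counter()
    mem_cfg, act_cfg, net_cfg = cfg["membership"], cfg["activity"], cfg["network"]
    proc_rows, act_rows = [], []
    net_dir = outdir / "networks"
    for alpha in range(1, k + 1):
        proc = process_membership(
            result, alpha, fold=float(mem_cfg["fold"]),
            quantile=float(mem_cfg["quantile"]),
        )
        proc = process_activity(
            result, alpha, threshold=act_cfg["threshold"], process=proc
        )
        members = set(proc.member_ids)
        for cyt in result.cytokine_ids:
            proc_rows.append({
                "alpha": alpha,
                "cytokine": cyt,
                "G": result.G.iloc[:, alpha][cyt],
                "member": cyt in members,
            })
        for s in result.sample_ids:
            act_rows.append({
                "alpha": alpha,
                "sample": s,
                "lambda": result.lam.iloc[alpha][s],
                "call": proc.activity_calls[s],
            })
        if edges is not None:
            net_dir.mkdir(exist_ok=True)
            net = build_subnetwork(proc, edges, min_score=net_cfg["min_score"])
            write_graphml(net, net_dir / f"process_{alpha}.graphml")
            _write_csv(edges_frame(net), net_dir / f"process_{alpha}_edges.csv",
                       index=False)
    _write_csv(pd.DataFrame(proc_rows,
                            columns=["alpha", "cytokine", "G", "member"]),
               outdir / "processes.csv", index=False)
    _write_csv(pd.DataFrame(act_rows,
                            columns=["alpha", "sample", "lambda", "call"]),
               outdir / "activity.csv", index=False)
    _stage("processes", t0, K=k, networks=edges is not None)

    # ---- stage: associations -----------------------------------------
    t0 = time.perf_counter()
    asc = cfg["association"]
    if infiltrates is not None and metadata is not None:
        aligned = align_tables(secretome, infiltrates, metadata)
        per_tumor = aggregate_by_animal(secretome, metadata, agg=asc["aggregate"])
        # rename aggregated columns to the matched infiltrate record ids
        groups = aligned.groups()
        animal_for = {
            inf: metadata.animal_of(exps[0]) for inf, exps in groups.items()
        }
        cols = {a: inf for inf, a in animal_for.items()}
        sec_cols = per_tumor.values.rename(columns=cols)
        shared = [c for c in sec_cols.columns if c in set(infiltrates.sample_ids)]
        report = pearson_matrix(sec_cols.loc[:, shared],
                                infiltrates.values.loc[:, shared])
        cluster_order(report, distance=asc["distance"],
                      linkage_method=asc["linkage"])
        tidy = report.r.stack(future_stack=True).rename("r").reset_index()
        tidy.columns = ["row", "col", "r"]
        tidy["n"] = report.n_pairs.stack(future_stack=True).to_numpy()
        _write_csv(tidy, outdir / "correlation.csv", index=False)
        (outdir / "orders.json").write_text(json.dumps({
            "row_order": report.row_order,
            "col_order": report.col_order,
            "row_ids": report.row_ids,
            "col_ids": report.col_ids,
            "linkage_params": report.linkage_params,
        }, indent=1))
        if k >= 1:
            amp_report = amplitude_infiltrate_correlation(
                result, infiltrates, aligned
            )
            amp_tidy = amp_report.r.stack(future_stack=True).rename("r").reset_index()
            amp_tidy.columns = ["process", "population", "r"]
            _write_csv(amp_tidy, outdir / "amplitude_correlation.csv", index=False)
    scores, frac = pca_scores(imputed.values,
                              n_components=int(asc["pca_components"]))
    pca_out = scores.copy()
    pca_out.index.name = "sample"
    _write_csv(pca_out, outdir / "pca_scores.csv")
    (outdir / "pca_variance.json").write_text(
        json.dumps({"explained_fraction": frac.tolist()}, indent=1)
    )
    if metadata is not None:
        tstats = compare_all_treatments(secretome, metadata)
        _write_csv(tstats, outdir / "treatment_stats.csv", index=False)
    _stage("associations", t0, pca_components=int(asc["pca_components"]))

    manifest["seed"] = seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir
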