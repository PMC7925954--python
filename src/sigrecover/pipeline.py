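"""End-to-end pipeline: simulate/load -> preprocess -> gene sets -> score -> report.

Driven by a YAML config; every stage writes plain TSV/YAML outputs into the
output directory, and a manifest records the seed, config hash and package
version so a rerun with the same config and seed reproduces every table
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineError
from .gene_sets import (
    cross_reference,
    merge_sets,
    overlap_report,
    read_gene_list,
    read_ortholog_map,
)
from .metrics import Thresholds, gene_metrics, summarize_transcriptome, summary_table
from .preprocess import Roles, load_study, preprocess_study
from .report import HeatmapSpec, MarkerPanel, build_marker_panel, render_heatmap
from .simulate import SimConfig, simulate_study, write_study

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

_FLOAT_FORMAT = "%.10g"

DEFAULT_CONFIG: dict = {
    "simulate": {},  # populated from SimConfig defaults when the section is present
    "roles": {"naive": "naive", "reference": "no_scs", "treatments": ["dtmp", "hrp", "lrp"]},
    "filter": {"min_cpm": 0.5, "min_samples": 4},
    "prior_count": 2.0,
    "mean_scale": "geometric",
    "thresholds": {
        "change_min": 0.10,
        "near_naive_max": 0.15,
        "rf_cut": 1.0,
        "rf_rule": "le_one",
        "alpha": 0.05,
    },
    "report": {"heatmaps": True, "order": "by_naive_fc", "blue_up": True, "clip": None},
}

_KNOWN_KEYS: dict[str, set | None] = {
    "simulate": None,  # validated by SimConfig.from_dict
    "inputs": {"counts", "design", "signatures", "ortholog_map"},
    "composites": None,  # free-form: name -> [set names]
    "roles": {"naive", "reference", "treatments"},
    "filter": {"min_cpm", "min_samples"},
    "prior_count": set(),
    "mean_scale": set(),
    "thresholds": {"change_min", "near_naive_max", "rf_cut", "rf_rule", "alpha"},
    "report": {"heatmaps", "order", "blue_up", "clip", "markers", "marker_threshold"},
}


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - set(_KNOWN_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key, allowed in _KNOWN_KEYS.items():
        if key in cfg and isinstance(allowed, set) and allowed and isinstance(cfg[key], dict):
            extra = set(cfg[key]) - allowed
            if extra:
                raise ConfigurationError(f"unknown keys under {key!r}: {sorted(extra)}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigurationError("config needs either a 'simulate' or an 'inputs' section")


def load_config(path) -> dict:
    """Read and validate a pipeline config; defaults fill unset sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a YAML mapping")
    _validate_config(cfg)
    return cfg


def _merged(cfg: dict, key: str) -> dict:
    out = dict(DEFAULT_CONFIG.get(key, {}))
    out.update(cfg.get(key) or {})
    return out


def _config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None) -> dict:
    """Run every stage and write all outputs under ``out_dir``.

    ``config`` is a validated dict or a path to a YAML file. ``seed``
    overrides the simulate section's seed. Returns the manifest dict.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _save(df: pd.DataFrame, name: str, index_label=None) -> None:
        p = out / name
        df.to_csv(p, sep="\t", float_format=_FLOAT_FORMAT, index_label=index_label)
        written.append(name)

    roles_cfg = _merged(config, "roles")
    roles = Roles(
        naive=roles_cfg["naive"],
        reference=roles_cfg["reference"],
        treatments=tuple(roles_cfg["treatments"]),
    )

    # --- stage: obtain the study -----------------------------------------
    stage = "simulate/load"
    try:
        signature_files: dict[str, Path] = {}
        if "simulate" in config:
            sim_dict = dict(config.get("simulate") or {})
            if seed is not None:
                sim_dict["seed"] = seed
            sim_cfg = SimConfig.from_dict(sim_dict)
            roles = sim_cfg.roles
            study, truth = simulate_study(sim_cfg)
            sim_dir = out / "simulated"
            write_study(study, truth, sim_dir)
            written.append("simulated/")
            for name in truth.signature_symbols:
                signature_files[name] = sim_dir / f"signature_{name}.txt"
            used_seed = sim_cfg.seed
        else:
            inputs = config["inputs"]
            study = load_study(inputs["counts"], inputs["design"], roles)
            for p in inputs.get("signatures", []):
                p = Path(p)
                signature_files[p.stem.removeprefix("signature_")] = p
            used_seed = seed

        stage = "preprocess"
        filt = _merged(config, "filter")
        prep = preprocess_study(
            study,
            min_cpm=filt["min_cpm"],
            min_samples=int(filt["min_samples"]),
            prior_count=config.get("prior_count", DEFAULT_CONFIG["prior_count"]),
            mean_scale=config.get("mean_scale", DEFAULT_CONFIG["mean_scale"]),
        )
        _save(prep.factors.to_frame(), "factors.tsv", index_label="sample_id")
        _save(prep.logcpm, "logcpm.tsv", index_label="gene_id")
        _save(prep.group_expression.values, "group_expression.tsv", index_label="gene_id")
        _save(prep.fold_changes, "fold_changes.tsv", index_label="gene_id")

        stage = "gene_sets"
        ortho = None
        if "inputs" in config and config["inputs"].get("ortholog_map"):
            ortho = read_ortholog_map(config["inputs"]["ortholog_map"])
        sets = {
            name: read_gene_list(p, name=name, ortholog_map=ortho)
            for name, p in sorted(signature_files.items())
        }
        composites = []
        comp_cfg = config.get("composites") or {name: [name] for name in sets}
        for comp_name, members in comp_cfg.items():
            missing = [m for m in members if m not in sets]
            if missing:
                raise ConfigurationError(
                    f"composites[{comp_name!r}] references unknown sets {missing}"
                )
            ct = merge_sets([sets[m] for m in members], comp_name)
            composites.append(cross_reference(ct, prep.retained_genes))
        _save(overlap_report(composites), "overlap_report.tsv")

        stage = "score"
        thr = Thresholds(**_merged(config, "thresholds"))
        summaries = []
        metrics_frames = []
        for ct in composites:
            # pass the full union so symbols outside the measured universe are
            # counted as excluded in the summary's bookkeeping
            summ = summarize_transcriptome(
                prep.group_expression,
                ct.union_symbols,
                thresholds=thr,
                name=ct.name,
                fc=prep.fold_changes,
            )
            summaries.append(summ)
            gm = gene_metrics(prep.group_expression, ct.overlapped_symbols, thr)
            gm.insert(0, "transcriptome", ct.name)
            metrics_frames.append(gm)
        _save(summary_table(summaries), "recovery_summary.tsv")
        _save(
            pd.concat(metrics_frames).rename_axis("gene_id"),
            "gene_metrics.tsv",
            index_label="gene_id",
        )

        stage = "report"
        rep = _merged(config, "report")
        if rep.get("heatmaps", True):
            spec = HeatmapSpec(
                order=rep.get("order", "by_naive_fc"),
                blue_up=rep.get("blue_up", True),
                clip=rep.get("clip"),
            )
            for ct, summ in zip(composites, summaries):
                gm = gene_metrics(prep.group_expression, ct.overlapped_symbols, thr)
                changed = gm.index[gm["changed"]]
                if len(changed):
                    name = f"heatmap_{ct.name}.png"
                    render_heatmap(
                        prep.fold_changes, changed, out / name, spec=spec, title=ct.name
                    )
                    written.append(name)
        if rep.get("markers"):
            panel = MarkerPanel(
                groups={k: tuple(v) for k, v in rep["markers"].items()},
                threshold=rep.get("marker_threshold", 0.15),
            )
            table = build_marker_panel(
                prep.group_expression,
                panel,
                fc=prep.fold_changes,
                out_path=out / "heatmap_markers.png",
            )
            _save(table, "marker_panel.tsv")
    except Exception as exc:
        logger.error("pipeline failed in stage %s: %s", stage, exc)
        if isinstance(exc, (ConfigurationError,)):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": used_seed,
        "config_hash": _config_hash(config),
        "outputs": written,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
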