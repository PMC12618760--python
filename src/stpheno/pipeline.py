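"""End-to-end pipeline: normalize → map → rank → PDI → render.

Driven by a YAML/JSON config naming the bulk table (and its scale), the
atlas, the feature gene list, the sample annotation table and the
(case, control) pairs. All numeric outputs are written as TSV with fixed
float formatting, so a rerun with an identical config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .iomodel import (
    StphenoError,
    load_feature_set,
    read_atlas,
    read_expression_table,
    read_gene_lengths,
    read_sample_annotations,
)
from .normalize import gene_lengths_from_gtf, harmonize
from .pdi import classify_pdi, compute_pdi, write_pdi_map
from .projection import DEFAULT_MIN_OVERLAP, map_samples, rank_positions, write_pcc_map
from .render import render_spatial_map

logger = logging.getLogger("stpheno")


class PipelineError(StphenoError):
    """An error in a pipeline stage, tagged with the stage name."""


def setup_logging(log_file: Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr, and additionally to a run-log file when given."""
    root = logging.getLogger("stpheno")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file, mode="w")
        fh.setFormatter(fmt)
        root.addHandler(fh)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path.name} is not a mapping")
    return cfg


def _require(cfg: dict, key: str) -> object:
    if key not in cfg:
        raise PipelineError(f"config: missing required key {key!r}")
    return cfg[key]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StphenoError as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full projection pipeline from a config.

    Config keys: ``bulk`` {path, scale}, optional ``gene_lengths`` or
    ``gtf``, ``atlas`` {expression, metadata}, ``features`` (path),
    ``groups`` (path, optional when the bulk table needs none), ``pairs``
    (list of [case, control]), optional ``min_overlap``, ``aggregation``,
    ``epsilon``, ``top_k``, ``plots`` (bool), ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    # validate required config before any computation
    bulk_cfg = _require(config, "bulk")
    atlas_cfg = _require(config, "atlas")
    features_path = _require(config, "features")
    pairs = [tuple(p) for p in config.get("pairs", [])]

    out_dir = Path(out_dir or config.get("out_dir", "stpheno_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(out_dir / "run.log")
    logger.info("stpheno %s pipeline start", __version__)

    # --- load -------------------------------------------------------------
    features = _stage("load")(load_feature_set)(features_path)
    atlas = _stage("load")(read_atlas)(
        _require(atlas_cfg, "expression"), _require(atlas_cfg, "metadata")
    )
    annotations = None
    if config.get("groups"):
        annotations = _stage("load")(read_sample_annotations)(config["groups"])
    bulk = _stage("load")(read_expression_table)(
        _require(bulk_cfg, "path"), _require(bulk_cfg, "scale"), annotations
    )

    # --- normalize ----------------------------------------------------------
    lengths = None
    if bulk.scale == "counts":
        if config.get("gene_lengths"):
            lengths = _stage("normalize")(read_gene_lengths)(config["gene_lengths"])
        elif config.get("gtf"):
            lengths = _stage("normalize")(gene_lengths_from_gtf)(config["gtf"])
    bulk = _stage("normalize")(harmonize)(bulk, lengths)

    # --- map ----------------------------------------------------------------
    min_overlap = int(config.get("min_overlap", DEFAULT_MIN_OVERLAP))
    pcc = _stage("map")(map_samples)(bulk, atlas, features, min_overlap)
    write_pcc_map(pcc, out_dir / "pcc.tsv", out_dir / "pcc.meta.json")

    top_k = int(config.get("top_k", 3))
    ranks = _stage("map")(rank_positions)(pcc, top_k)
    rank_rows = [
        {"sample_id": sid, "rank": i + 1, "position_id": pid, "pcc": v}
        for sid, lst in ranks.items()
        for i, (pid, v) in enumerate(lst)
    ]
    pd.DataFrame(rank_rows).to_csv(
        out_dir / "rankings.tsv", sep="\t", index=False, float_format="%.10g"
    )

    # --- pdi ----------------------------------------------------------------
    pdimap = None
    if pairs:
        aggregation = config.get("aggregation", "mean_pcc")
        pdimap = _stage("pdi")(compute_pdi)(
            pcc,
            annotations,
            pairs,
            aggregation,
            bulk=bulk,
            atlas=atlas,
            features=features,
            min_overlap=min_overlap,
        )
        write_pdi_map(pdimap, out_dir / "pdi.tsv")
        labels = classify_pdi(pdimap, float(config.get("epsilon", 0.0)))
        labels.index.name = "position_id"
        labels.to_csv(out_dir / "pdi_classes.tsv", sep="\t")

    # --- render -------------------------------------------------------------
    if config.get("plots", True):
        plot_dir = out_dir / "plots"
        plot_dir.mkdir(exist_ok=True)
        for sid in pcc.sample_ids:
            _stage("render")(render_spatial_map)(
                pcc.values.loc[sid], atlas, plot_dir / f"pcc_{sid}.svg",
                mode="pcc", title=str(sid),
            )
        if pdimap is not None:
            for label in pdimap.labels:
                _stage("render")(render_spatial_map)(
                    pdimap.values[label], atlas, plot_dir / f"pdi_{label}.svg",
                    mode="pdi", title=str(label),
                )

    # --- run log ------------------------------------------------------------
    run_meta = {
        "stpheno_version": __version__,
        "python_version": sys.version.split()[0],
        "n_genes_used": pcc.n_genes_used,
        "min_overlap": min_overlap,
        "feature_provenance": features.provenance,
        "n_samples": int(bulk.n_samples),
        "n_positions": int(len(atlas.position_ids)),
        "pairs": [list(p) for p in pairs],
        "aggregation": config.get("aggregation", "mean_pcc"),
        "bulk_scale_declared": bulk_cfg.get("scale"),
        "seed": config.get("seed"),
    }
    (out_dir / "run_meta.json").write_text(
        json.dumps(run_meta, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: %s", out_dir)
    return out_dir
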