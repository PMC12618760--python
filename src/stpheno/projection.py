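"""Spatial projection core: Pearson-correlation mapping of bulk samples onto
the reference atlas.

Each bulk sample is correlated with every atlas position over a single
common gene universe (feature set ∩ bulk genes ∩ atlas genes), giving a
samples × positions PCC map; a sample's inferred embryonic location is the
position (or tied positions) with the highest PCC. Using one universe for
all pairs keeps PCC values comparable across positions, which the PDI
subtraction downstream assumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .iomodel import AtlasReference, ExpressionMatrix, FeatureGeneSet, StphenoError

logger = logging.getLogger("stpheno")

#: Default minimum size of the common gene universe.
DEFAULT_MIN_OVERLAP = 100


class UndefinedCorrelationError(StphenoError):
    """A correlation is undefined because an input vector has zero variance."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient Cov(X, Y) / (σX · σY).

    Raises :class:`UndefinedCorrelationError` when either vector has zero
    standard deviation; an undefined correlation is never coerced to a
    number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("pearson requires vectors of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero-variance vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class PCCMap:
    """Samples × positions matrix of Pearson correlations.

    ``values`` holds NaN at undefined cells (zero-variance vectors); the
    boolean ``undefined`` mask marks them explicitly. ``n_genes_used`` is the
    size of the common gene universe, identical for every cell of a run.
    """

    values: pd.DataFrame  # samples x positions, NaN where undefined
    undefined: pd.DataFrame  # boolean mask, same shape
    n_genes_used: int
    feature_provenance: str = ""
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        defined = ~self.undefined.to_numpy(dtype=bool)
        if np.isnan(arr[defined]).any():
            raise StphenoError("NaN in a cell not marked undefined")
        finite = arr[defined]
        if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
            raise StphenoError("PCC outside [-1, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def position_ids(self) -> pd.Index:
        return self.values.columns


def common_gene_universe(
    bulk: ExpressionMatrix, atlas: AtlasReference, features: FeatureGeneSet
) -> list[str]:
    """Sorted intersection features ∩ bulk genes ∩ atlas genes."""
    return sorted(
        features.genes
        & set(bulk.gene_ids)
        & set(atlas.expression.gene_ids)
    )


def map_samples(
    bulk: ExpressionMatrix,
    atlas: AtlasReference,
    features: FeatureGeneSet,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PCCMap:
    """Correlate every bulk sample with every atlas position.

    Both matrices must be on the log2(TPM+1) scale. The correlation is
    computed over the single common gene universe for all (sample, position)
    pairs; zero-variance vectors yield undefined cells (NaN + mask), logged
    as warnings.
    """
    if bulk.scale != "log2TPM1":
        raise StphenoError(
            f"bulk scale must be log2TPM1 for mapping, got {bulk.scale!r}"
        )
    universe = common_gene_universe(bulk, atlas, features)
    if len(universe) < min_overlap:
        raise StphenoError(
            f"common gene universe too small: |features|={len(features)}, "
            f"|bulk∩features|={len(features.genes & set(bulk.gene_ids))}, "
            f"|atlas∩features|={len(features.genes & set(atlas.expression.gene_ids))}, "
            f"intersection={len(universe)} < min_overlap={min_overlap}"
        )
    B = bulk.values.loc[universe].to_numpy(dtype=float)  # genes x samples
    A = atlas.expression.values.loc[universe].to_numpy(dtype=float)  # genes x positions

    Bc = B - B.mean(axis=0, keepdims=True)
    Ac = A - A.mean(axis=0, keepdims=True)
    bnorm = np.sqrt((Bc**2).sum(axis=0))
    anorm = np.sqrt((Ac**2).sum(axis=0))
    zero_b = bnorm == 0.0
    zero_a = anorm == 0.0
    if zero_b.any():
        logger.warning(
            "zero-variance bulk samples (undefined PCC): %s",
            bulk.sample_ids[zero_b].tolist(),
        )
    if zero_a.any():
        logger.warning(
            "zero-variance atlas positions (undefined PCC): %s",
            atlas.position_ids[zero_a].tolist(),
        )
    denom = np.outer(np.where(zero_b, np.nan, bnorm), np.where(zero_a, np.nan, anorm))
    with np.errstate(invalid="ignore"):
        pcc = np.clip((Bc.T @ Ac) / denom, -1.0, 1.0)
    undefined = np.isnan(pcc)
    values = pd.DataFrame(pcc, index=bulk.sample_ids, columns=atlas.position_ids)
    mask = pd.DataFrame(undefined, index=bulk.sample_ids, columns=atlas.position_ids)
    return PCCMap(
        values=values,
        undefined=mask,
        n_genes_used=len(universe),
        feature_provenance=features.provenance,
        min_overlap=min_overlap,
    )


def rank_positions(
    pcc: PCCMap, k: int = 1
) -> dict[str, list[tuple[str, float]]]:
    """Per-sample positions ranked by PCC (descending).

    Exact ties are broken lexicographically by position id, and every member
    of a tie straddling the k-th place is reported even if that exceeds k.
    Undefined cells are excluded; a sample with no defined cell is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[tuple[str, float]]] = {}
    for sample in pcc.sample_ids:
        row = pcc.values.loc[sample].dropna()
        if row.empty:
            raise StphenoError(f"sample {sample!r}: all PCC cells undefined")
        ordered = sorted(row.items(), key=lambda it: (-it[1], it[0]))
        cut = min(k, len(ordered))
        while cut < len(ordered) and ordered[cut][1] == ordered[cut - 1][1]:
            cut += 1
        out[sample] = [(pid, float(v)) for pid, v in ordered[:cut]]
    return out


def write_pcc_map(pcc: PCCMap, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Serialize a PCC map as TSV plus a JSON sidecar of run metadata."""
    path = Path(path)
    out = pcc.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")
    if meta_path is None:
        meta_path = path.with_suffix(".meta.json")
    meta = {
        "n_genes_used": pcc.n_genes_used,
        "feature_provenance": pcc.feature_provenance,
        "min_overlap": pcc.min_overlap,
        "n_undefined_cells": int(pcc.undefined.to_numpy().sum()),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_pcc_map(path: str | Path, meta_path: str | Path | None = None) -> PCCMap:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    if meta_path is None:
        meta_path = path.with_suffix(".meta.json")
    meta = json.loads(Path(meta_path).read_text())
    return PCCMap(
        values=values,
        undefined=values.isna(),
        n_genes_used=int(meta["n_genes_used"]),
        feature_provenance=meta.get("feature_provenance", ""),
        min_overlap=int(meta.get("min_overlap", DEFAULT_MIN_OVERLAP)),
    )
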