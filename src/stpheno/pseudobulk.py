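"""Single-cell-reference comparison via pseudo-bulk profiles.

When the reference is a single-cell dataset rather than a spatial atlas,
member cells of each annotated cell type are summed into one pseudo-bulk
column, scaled to counts per million and log2(CPM+1)-transformed (no gene
lengths for UMI-style counts). The feature set is the union of each cell
type's top-ranked marker genes (top 50 by default), and bulk samples are
compared to the pseudo-bulk reference with Spearman's rank correlation
(average ranks for ties).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.stats import rankdata

from .iomodel import ExpressionMatrix, FeatureGeneSet, StphenoError, ValidationError, canonicalize_gene_id

logger = logging.getLogger("stpheno")

DEFAULT_TOP_MARKERS = 50


def pseudobulk_by_celltype(
    sc_counts: ExpressionMatrix, labels: pd.Series
) -> ExpressionMatrix:
    """Sum single-cell counts per cell type, then CPM and log2(CPM+1).

    ``labels`` maps cell id → cell-type label and must cover every column of
    ``sc_counts``.
    """
    if sc_counts.scale != "counts":
        raise ValidationError(f"expected scale 'counts', got {sc_counts.scale!r}")
    if sc_counts.n_samples == 0 or sc_counts.n_genes == 0:
        raise ValidationError("empty single-cell matrix")
    labels = labels.astype(str)
    unlabeled = sc_counts.sample_ids.difference(labels.index)
    if len(unlabeled):
        raise ValidationError(
            f"cells without a cell-type label: {unlabeled.tolist()[:10]}"
        )
    lab = labels.reindex(sc_counts.sample_ids)
    summed = sc_counts.values.T.groupby(lab).sum().T  # genes x cell types
    summed = summed[sorted(summed.columns)]
    totals = summed.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValidationError(f"cell types with all-zero counts: {bad}")
    cpm = summed / totals * 1e6
    out = np.log2(cpm + 1.0)
    out.columns.name = None
    return ExpressionMatrix(out, "logCPM1")


def merge_top_markers(
    markers: pd.DataFrame, n: int = DEFAULT_TOP_MARKERS
) -> FeatureGeneSet:
    """Union of each cell type's ``n`` top-ranked marker genes.

    ``markers`` needs columns ``cell_type``, ``gene_id`` and ``rank``
    (1 = best). A type with fewer than ``n`` markers contributes all it has,
    with a warning.
    """
    required = {"cell_type", "gene_id", "rank"}
    if not required <= set(markers.columns):
        raise ValidationError(f"marker table needs columns {sorted(required)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if (markers["rank"] < 1).any():
        raise ValidationError("marker ranks must be >= 1")
    genes: set[str] = set()
    for ctype, sub in markers.groupby("cell_type"):
        if len(sub) < n:
            logger.warning(
                "cell type %r has only %d markers (< %d); using all",
                ctype, len(sub), n,
            )
        top = sub.nsmallest(n, "rank")["gene_id"]
        genes.update(canonicalize_gene_id(g) for g in top)
    return FeatureGeneSet(frozenset(genes), provenance=f"top{n}_markers")


def spearman_correlate(
    bulk: ExpressionMatrix,
    reference: ExpressionMatrix,
    features: FeatureGeneSet,
) -> pd.DataFrame:
    """Spearman rank correlation of bulk samples vs reference columns.

    Computed over the common gene universe (features ∩ both matrices),
    average ranks for ties. Constant-after-ranking vectors yield NaN cells
    with a warning, never a numeric placeholder.
    """
    universe = sorted(
        features.genes & set(bulk.gene_ids) & set(reference.gene_ids)
    )
    if len(universe) < 3:
        raise StphenoError(
            f"common gene universe too small for Spearman: {len(universe)} < 3"
        )
    B = bulk.values.loc[universe].to_numpy(dtype=float)
    R = reference.values.loc[universe].to_numpy(dtype=float)
    Brank = rankdata(B, method="average", axis=0)
    Rrank = rankdata(R, method="average", axis=0)

    Bc = Brank - Brank.mean(axis=0, keepdims=True)
    Rc = Rrank - Rrank.mean(axis=0, keepdims=True)
    bnorm = np.sqrt((Bc**2).sum(axis=0))
    rnorm = np.sqrt((Rc**2).sum(axis=0))
    for ids, norms, kind in (
        (bulk.sample_ids, bnorm, "bulk samples"),
        (reference.sample_ids, rnorm, "reference columns"),
    ):
        if (norms == 0.0).any():
            logger.warning(
                "constant-rank %s (undefined Spearman): %s",
                kind, ids[norms == 0.0].tolist(),
            )
    denom = np.outer(
        np.where(bnorm == 0.0, np.nan, bnorm),
        np.where(rnorm == 0.0, np.nan, rnorm),
    )
    with np.errstate(invalid="ignore"):
        rho = np.clip((Bc.T @ Rc) / denom, -1.0, 1.0)
    return pd.DataFrame(rho, index=bulk.sample_ids, columns=reference.sample_ids)


def read_mtx_expression(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> ExpressionMatrix:
    """Read an MTX sparse count matrix with gene/cell id sidecar tables.

    Gene and cell files are one id per line (first column if tab-separated).
    Rows of the MTX are genes, columns are cells.
    """

    def _ids(path: str | Path) -> list[str]:
        out = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    out.append(line.split("\t")[0])
        return out

    mat = mmread(str(mtx_path)).toarray().astype(float)
    genes = [canonicalize_gene_id(g) for g in _ids(genes_path)]
    cells = _ids(cells_path)
    if mat.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(cells)} cells"
        )
    df = pd.DataFrame(mat, index=genes, columns=cells)
    return ExpressionMatrix(df, "counts")


def read_cell_labels(path: str | Path) -> pd.Series:
    """Read a (cell_id, cell_type) TSV into a cell → type Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "cell_type"} <= set(df.columns):
        raise ValidationError("label table needs columns cell_id, cell_type")
    if df["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell ids in label table")
    return df.set_index("cell_id")["cell_type"]


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a ranked marker TSV (cell_type, gene_id, rank)."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene_id", "rank"} <= set(df.columns):
        raise ValidationError("marker table needs columns cell_type, gene_id, rank")
    df["rank"] = df["rank"].astype(int)
    return df
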