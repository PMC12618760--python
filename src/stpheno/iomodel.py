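"""Data model and file I/O for expression matrices, atlas metadata and gene sets.

The working objects of the framework:

* :class:`ExpressionMatrix` — a genes × samples table that always knows what
  scale its values are on (raw counts, TPM, log2(TPM+1) or log2(CPM+1)).
* :class:`AtlasReference` — a spatially resolved reference: an expression
  matrix on the log2(TPM+1) scale whose columns are embryo positions, plus a
  position table (stage, section along the proximal→distal axis, anatomical
  domain code, and grid coordinates for corn-plot rendering).
* :class:`FeatureGeneSet` — the restricted, spatially informative gene list
  over which all correlations are computed.
* :class:`GeneLengthTable` — per-gene effective lengths (bp) for TPM.

Gene identifiers are matched across bulk / atlas / feature set purely by
canonicalized id string (Ensembl version suffixes stripped, whitespace
trimmed); no symbol↔accession translation is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("stpheno")

#: Valid value scales for an ExpressionMatrix.
SCALES = ("counts", "TPM", "log2TPM1", "logCPM1")

#: Anatomical domain vocabulary of the E7.5 mouse gastrula corn plot:
#: anterior / posterior / lateral epiblast-ectoderm (A, P, L1, R1, L2, R2),
#: anterior / posterior endoderm (EA, EP) and mesoderm (MA, MP).
E75_DOMAIN_CODES = frozenset(
    {"A", "P", "L1", "R1", "L2", "R2", "EA", "EP", "MA", "MP"}
)

#: Column sum every TPM sample must satisfy.
TPM_TOTAL = 1e6
#: Relative tolerance on the TPM column-sum invariant.
TPM_RTOL = 1e-6

_ENSEMBL_VERSION = re.compile(r"^(ENS[A-Za-z0-9]+)\.\d+$")

#: Metadata columns required in an atlas position table.
ATLAS_META_COLUMNS = (
    "position_id",
    "stage",
    "section_index",
    "domain_code",
    "layout_row",
    "layout_col",
)


class StphenoError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(StphenoError):
    """An input violated a documented precondition or invariant."""


def canonicalize_gene_id(gene_id: str) -> str:
    """Canonical form of a gene identifier.

    Strips surrounding whitespace and, for Ensembl-style accessions
    (``ENS...``), the trailing version suffix ``.N``. Idempotent.
    """
    g = str(gene_id).strip()
    m = _ENSEMBL_VERSION.match(g)
    return m.group(1) if m else g


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric table with a declared value scale.

    Parameters
    ----------
    values
        DataFrame with canonicalized gene ids as index and sample ids as
        columns. No missing values.
    scale
        One of ``counts``, ``TPM``, ``log2TPM1``, ``logCPM1``.
    sample_annotations
        Optional table indexed by sample id with at least ``condition``,
        ``timepoint`` and ``replicate`` columns for grouped analyses.
    """

    values: pd.DataFrame
    scale: str
    sample_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(
                f"unknown scale {self.scale!r}; expected one of {SCALES}"
            )
        vals = self.values
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:10]}")
        if vals.columns.has_duplicates:
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        if vals.isna().any().any():
            gi, si = np.argwhere(vals.isna().to_numpy())[0]
            raise ValidationError(
                f"missing value at gene {vals.index[gi]!r}, "
                f"sample {vals.columns[si]!r}"
            )
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if self.scale in ("counts", "TPM") and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value on scale {self.scale!r} at gene "
                f"{vals.index[gi]!r}, sample {vals.columns[si]!r}"
            )
        if self.scale == "TPM":
            sums = arr.sum(axis=0)
            bad = ~np.isclose(sums, TPM_TOTAL, rtol=TPM_RTOL, atol=0.0)
            if bad.any():
                s = vals.columns[np.argwhere(bad)[0, 0]]
                raise ValidationError(
                    f"TPM column {s!r} does not sum to 1e6 "
                    f"(got {sums[bad][0]:.6g})"
                )
        if self.sample_annotations is not None:
            ann = self.sample_annotations
            missing = vals.columns.difference(ann.index)
            if len(missing):
                raise ValidationError(
                    f"samples without annotation: {missing.tolist()[:10]}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        """New matrix with the same annotations but different values/scale."""
        return ExpressionMatrix(values, scale, self.sample_annotations)


@dataclass(frozen=True)
class FeatureGeneSet:
    """The spatially informative gene set used for correlations."""

    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("feature gene set is empty")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_ids(cls, ids: Iterable[str], provenance: str = "") -> "FeatureGeneSet":
        return cls(frozenset(canonicalize_gene_id(g) for g in ids), provenance)


@dataclass(frozen=True)
class GeneLengthTable:
    """Per-gene effective length in base pairs (merged exon union)."""

    lengths: pd.Series  # gene_id -> int bp

    def __post_init__(self) -> None:
        s = self.lengths
        if s.index.has_duplicates:
            raise ValidationError("duplicate gene ids in length table")
        if (s < 1).any():
            bad = s.index[s < 1].tolist()
            raise ValidationError(f"non-positive gene lengths: {bad[:10]}")

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class AtlasReference:
    """Spatial reference atlas: expression bound to position metadata.

    ``positions`` is indexed by position_id with columns ``stage``,
    ``section_index``, ``domain_code``, ``layout_row``, ``layout_col``.
    Position ids are exactly the expression sample ids, each stage's layout
    cells are unique, and domain codes are checked against
    ``domain_vocab[stage]`` when a vocabulary is declared.
    """

    expression: ExpressionMatrix
    positions: pd.DataFrame
    domain_vocab: Mapping[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.expression.scale != "log2TPM1":
            raise ValidationError(
                f"atlas expression must be on log2TPM1 scale, "
                f"got {self.expression.scale!r}"
            )
        pos = self.positions
        missing_cols = [c for c in ATLAS_META_COLUMNS[1:] if c not in pos.columns]
        if missing_cols:
            raise ValidationError(f"atlas metadata lacks columns: {missing_cols}")
        if pos.index.has_duplicates:
            dups = pos.index[pos.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate position ids: {dups[:10]}")
        expr_ids = set(self.expression.sample_ids)
        meta_ids = set(pos.index)
        only_meta = sorted(meta_ids - expr_ids)
        only_expr = sorted(expr_ids - meta_ids)
        if only_meta or only_expr:
            raise ValidationError(
                "position ids do not match expression columns; "
                f"metadata-only: {only_meta[:10]}, expression-only: {only_expr[:10]}"
            )
        cells = pos[["stage", "layout_row", "layout_col"]]
        dup = cells.duplicated(keep=False)
        if dup.any():
            clash = pos.index[dup].tolist()
            raise ValidationError(
                f"positions share a layout cell within a stage: {clash[:10]}"
            )
        if self.domain_vocab is not None:
            for pid, row in pos.iterrows():
                vocab = self.domain_vocab.get(str(row["stage"]))
                if vocab is not None and row["domain_code"] not in vocab:
                    raise ValidationError(
                        f"position {pid!r}: domain code {row['domain_code']!r} "
                        f"not in the vocabulary of stage {row['stage']!r}"
                    )
        # order positions like the expression columns
        self.positions = pos.loc[self.expression.sample_ids]

    @property
    def position_ids(self) -> pd.Index:
        return self.positions.index

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.positions["stage"].astype(str)))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path,
    scale: str,
    annotations: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a delimited genes × samples table.

    First column = gene identifiers, header row = sample identifiers. TSV by
    default; ``.csv`` files are comma-separated. Gene ids are canonicalized;
    duplicate gene rows collapse by summation when ``scale='counts'`` and are
    rejected otherwise.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = [h.strip() for h in header[1:]]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValidationError(f"duplicate sample id in header: {s!r}")
        seen.add(s)

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.columns = sample_ids
    df.index = [canonicalize_gene_id(g) for g in df.index]
    df.index.name = "gene_id"

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raw = df.iat[gi, si]
        what = "missing" if (pd.isna(raw) or str(raw).strip() == "") else f"non-numeric ({raw!r})"
        raise ValidationError(
            f"{what} value at gene {df.index[gi]!r}, sample {df.columns[si]!r} "
            f"in {path.name}"
        )

    if numeric.index.has_duplicates:
        if scale == "counts":
            n_before = len(numeric)
            numeric = numeric.groupby(level=0, sort=False).sum()
            logger.info(
                "collapsed %d duplicate gene rows by summation",
                n_before - len(numeric),
            )
        else:
            dups = numeric.index[numeric.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate gene ids on non-count scale {scale!r}: {dups[:10]}"
            )
    return ExpressionMatrix(numeric.astype(float), scale, annotations)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes × samples table (inverse of :func:`read_expression_table`)."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, condition, timepoint, replicate)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path.name}: missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate sample ids")
    for col in ("condition", "timepoint"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing {col!r} column")
    return df.set_index("sample_id")


def read_atlas(
    expr_path: str | Path,
    meta_path: str | Path,
    domain_vocab: Mapping[str, frozenset[str]] | None = None,
) -> AtlasReference:
    """Read a spatial reference atlas (expression on log2TPM1 + metadata).

    The metadata table must carry the columns ``position_id``, ``stage``,
    ``section_index``, ``domain_code``, ``layout_row``, ``layout_col``.
    """
    expr = read_expression_table(expr_path, scale="log2TPM1")
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path))
    missing = [c for c in ATLAS_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"{meta_path.name}: missing columns {missing}")
    meta = meta.set_index("position_id")
    meta.index = meta.index.astype(str).str.strip()
    for col in ("section_index", "layout_row", "layout_col"):
        meta[col] = meta[col].astype(int)
    return AtlasReference(expr, meta, domain_vocab)


def write_atlas(atlas: AtlasReference, expr_path: str | Path, meta_path: str | Path) -> None:
    """Write an atlas back to its two-file representation."""
    write_expression_table(atlas.expression, expr_path)
    meta_path = Path(meta_path)
    out = atlas.positions.copy()
    out.index.name = "position_id"
    out.to_csv(meta_path, sep=_sep_for(meta_path))


def load_feature_set(path: str | Path) -> FeatureGeneSet:
    """Load a plain-text gene list (one id per line, ``#`` comments ignored)."""
    path = Path(path)
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(canonicalize_gene_id(line))
    if not ids:
        raise ValidationError(f"{path.name}: no gene ids after parsing")
    return FeatureGeneSet(frozenset(ids), provenance=path.name)


def write_feature_set(features: FeatureGeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(features.genes):
            fh.write(g + "\n")


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    """Read a two-column gene-length TSV (gene_id, length_bp)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"gene_id", "length_bp"} <= set(df.columns):
        raise ValidationError(f"{path.name}: need columns gene_id, length_bp")
    s = df.set_index("gene_id")["length_bp"].astype(int)
    s.index = [canonicalize_gene_id(g) for g in s.index]
    return GeneLengthTable(s)


def write_gene_lengths(table: GeneLengthTable, path: str | Path) -> None:
    out = table.lengths.rename("length_bp").to_frame()
    out.index.name = "gene_id"
    out.to_csv(path, sep=_sep_for(Path(path)))
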