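"""Expression-scale harmonization: counts → TPM → log2(TPM+1).

Bulk samples arrive as raw read counts and are length-normalized to
transcripts per million, then log-transformed, so they live on the same
log2(TPM+1) scale as the reference atlas. Effective gene length is the
merged union of a gene's exon intervals (strand-agnostic), derivable from a
GENCODE-style GTF.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .iomodel import (
    ExpressionMatrix,
    GeneLengthTable,
    TPM_TOTAL,
    ValidationError,
    canonicalize_gene_id,
)

logger = logging.getLogger("stpheno")


def counts_to_tpm(counts: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Length-normalize raw counts to transcripts per million.

    Per sample: ``rate_g = count_g / length_g(kb)`` then
    ``TPM_g = rate_g / Σ_g rate_g * 1e6``, so every column sums to 1e6.
    """
    if counts.scale != "counts":
        raise ValidationError(f"expected scale 'counts', got {counts.scale!r}")
    missing = counts.gene_ids.difference(lengths.lengths.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} genes lack a length, e.g. {missing.tolist()[:10]}"
        )
    len_kb = lengths.lengths.reindex(counts.gene_ids).to_numpy(dtype=float) / 1e3
    rates = counts.values.to_numpy(dtype=float) / len_kb[:, None]
    totals = rates.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        sample = counts.sample_ids[np.argwhere(zero)[0, 0]]
        raise ValidationError(f"sample {sample!r} has all-zero counts")
    tpm = rates / totals * TPM_TOTAL
    out = pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids)
    return counts.with_values(out, "TPM")


def log_transform(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    if tpm.scale != "TPM":
        raise ValidationError(f"expected scale 'TPM', got {tpm.scale!r}")
    arr = tpm.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative values cannot be log-transformed")
    out = pd.DataFrame(np.log2(arr + 1.0), index=tpm.gene_ids, columns=tpm.sample_ids)
    return tpm.with_values(out, "log2TPM1")


def harmonize(
    bulk: ExpressionMatrix, lengths: GeneLengthTable | None = None
) -> ExpressionMatrix:
    """Bring a bulk matrix onto the log2(TPM+1) working scale.

    Counts require a length table; matrices already declared as TPM skip the
    length normalization; log2TPM1 input passes through unchanged.
    """
    if bulk.scale == "log2TPM1":
        return bulk
    if bulk.scale == "counts":
        if lengths is None:
            raise ValidationError("count input requires gene lengths (GTF or table)")
        bulk = counts_to_tpm(bulk, lengths)
    if bulk.scale != "TPM":
        raise ValidationError(f"cannot harmonize scale {bulk.scale!r} to log2TPM1")
    return log_transform(bulk)


def _validate_gtf_lines(gtf_path: Path) -> None:
    # light structural check so malformed lines fail with a line number
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(
                    f"{gtf_path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValidationError(
                    f"{gtf_path.name}:{lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise ValidationError(
                    f"{gtf_path.name}:{lineno}: invalid interval [{start}, {end}]"
                )


def gene_lengths_from_gtf(gtf_path: str | Path) -> GeneLengthTable:
    """Effective gene lengths from a GENCODE-dialect GTF.

    Length = total bases covered by the union of a gene's exon intervals
    (overlaps merged, strand-agnostic; GTF coordinates are 1-based
    inclusive). Genes annotated without exon features are omitted with a
    warning.
    """
    import pyranges as pr

    gtf_path = Path(gtf_path)
    _validate_gtf_lines(gtf_path)
    gr = pr.read_gtf(str(gtf_path))
    df = gr.df
    if "Feature" not in df.columns or "gene_id" not in df.columns:
        raise ValidationError(f"{gtf_path.name}: not a GTF with gene_id attributes")
    exons = df[df["Feature"] == "exon"]
    no_exon = set(df["gene_id"].dropna()) - set(exons["gene_id"])
    if no_exon:
        logger.warning(
            "omitting %d genes without exon features: %s",
            len(no_exon),
            sorted(no_exon)[:10],
        )
    if exons.empty:
        raise ValidationError(f"{gtf_path.name}: no exon features")
    merged = pr.PyRanges(
        exons[["Chromosome", "Start", "End", "gene_id"]]
    ).merge(by="gene_id", strand=False)
    mdf = merged.df
    lengths = (
        (mdf["End"] - mdf["Start"]).groupby(mdf["gene_id"]).sum().astype(int)
    )
    lengths.index = [canonicalize_gene_id(g) for g in lengths.index]
    lengths = lengths.groupby(level=0).max()  # version-collapsed ids keep longest
    return GeneLengthTable(lengths)
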