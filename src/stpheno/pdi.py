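"""Phenotypic difference index (PDI): group-wise PCC differences per position.

For each spatial position the PDI is the case group's PCC minus the control
group's PCC (e.g. knockout minus wild type). With PCC in [-1, 1] the PDI
lies in [-2, 2]: 0 means no change in association strength with that
position, positive values an enhanced, negative values an attenuated
transcriptional concordance of the case relative to the control.

Comparisons are matched within timepoint labels (case D3 vs control D3,
...), one comparison column per (condition pair, timepoint).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .iomodel import AtlasReference, ExpressionMatrix, FeatureGeneSet, StphenoError
from .projection import DEFAULT_MIN_OVERLAP, PCCMap, map_samples

logger = logging.getLogger("stpheno")

AGGREGATIONS = ("mean_pcc", "pooled_profile")


@dataclass
class PDIMap:
    """Positions × comparison-labels matrix of PDI values in [-2, 2].

    ``comparisons`` records, per column label, the case condition, control
    condition, timepoint and group sizes. Swapping a comparison's case and
    control roles negates its column exactly.
    """

    values: pd.DataFrame  # positions x comparison labels
    comparisons: pd.DataFrame  # index = label; case, control, timepoint, n_case, n_control
    aggregation: str = "mean_pcc"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and (np.abs(finite) > 2.0 + 1e-12).any():
            raise StphenoError("PDI outside [-2, 2]")

    @property
    def position_ids(self) -> pd.Index:
        return self.values.index

    @property
    def labels(self) -> pd.Index:
        return self.values.columns


def comparison_label(case: str, control: str, timepoint: str) -> str:
    return f"{case}_{timepoint}_vs_{control}_{timepoint}"


def _group_samples(groups: pd.DataFrame, condition: str, timepoint: str) -> list[str]:
    sel = (groups["condition"].astype(str) == condition) & (
        groups["timepoint"].astype(str) == timepoint
    )
    return groups.index[sel].tolist()


def _resolve_groups(
    pcc: PCCMap, groups: pd.DataFrame | None, bulk: ExpressionMatrix | None
) -> pd.DataFrame:
    if groups is None:
        if bulk is None or bulk.sample_annotations is None:
            raise StphenoError("no sample→(condition, timepoint) table available")
        groups = bulk.sample_annotations
    missing = pcc.sample_ids.difference(groups.index)
    if len(missing):
        raise StphenoError(
            f"samples without condition/timepoint assignment: {missing.tolist()[:10]}"
        )
    return groups.loc[pcc.sample_ids]


def compute_pdi(
    pcc: PCCMap,
    groups: pd.DataFrame | None,
    pairs: Sequence[tuple[str, str]],
    aggregation: str = "mean_pcc",
    *,
    bulk: ExpressionMatrix | None = None,
    atlas: AtlasReference | None = None,
    features: FeatureGeneSet | None = None,
    min_overlap: int | None = None,
) -> PDIMap:
    """PDI per position for each (case, control) pair, within matched timepoints.

    ``aggregation='mean_pcc'`` (default): per position, mean of the case
    replicates' PCCs minus the mean of the control replicates' PCCs;
    undefined PCC cells are excluded from the means with the exclusion count
    logged. ``aggregation='pooled_profile'``: average the groups' log2(TPM+1)
    profiles first, correlate each pooled profile with the atlas once, then
    subtract — this requires ``bulk``, ``atlas`` and ``features``.

    A timepoint present in only one of the two conditions is skipped with a
    warning; a pair with no shared timepoint at all is an error.
    """
    if aggregation not in AGGREGATIONS:
        raise StphenoError(
            f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}"
        )
    groups = _resolve_groups(pcc, groups, bulk)
    cond = groups["condition"].astype(str)
    tp = groups["timepoint"].astype(str)

    columns: dict[str, pd.Series] = {}
    meta_rows: list[dict] = []
    for case, control in pairs:
        for c in (case, control):
            if not (cond == c).any():
                raise StphenoError(f"condition {c!r} has no samples")
        case_tps = set(tp[cond == case])
        ctrl_tps = set(tp[cond == control])
        shared = sorted(case_tps & ctrl_tps)
        for only, owner in ((case_tps - ctrl_tps, case), (ctrl_tps - case_tps, control)):
            for t in sorted(only):
                logger.warning(
                    "timepoint %r present only in condition %r; "
                    "comparison %s vs %s skipped there",
                    t, owner, case, control,
                )
        if not shared:
            raise StphenoError(
                f"pair ({case!r}, {control!r}) shares no timepoint"
            )
        for t in shared:
            case_ids = _group_samples(groups, case, t)
            ctrl_ids = _group_samples(groups, control, t)
            label = comparison_label(case, control, t)
            if aggregation == "mean_pcc":
                case_rows = pcc.values.loc[case_ids]
                ctrl_rows = pcc.values.loc[ctrl_ids]
                n_excl = int(case_rows.isna().sum().sum() + ctrl_rows.isna().sum().sum())
                if n_excl:
                    logger.warning(
                        "comparison %s: %d undefined PCC cells excluded from means",
                        label, n_excl,
                    )
                col = case_rows.mean(axis=0) - ctrl_rows.mean(axis=0)
            else:
                col = _pooled_profile_pdi(
                    case_ids, ctrl_ids, bulk, atlas, features, min_overlap
                )
            columns[label] = col
            meta_rows.append(
                {
                    "label": label,
                    "case": case,
                    "control": control,
                    "timepoint": t,
                    "n_case": len(case_ids),
                    "n_control": len(ctrl_ids),
                }
            )
    values = pd.DataFrame(columns)
    values.index.name = "position_id"
    comparisons = pd.DataFrame(meta_rows).set_index("label")
    return PDIMap(values=values, comparisons=comparisons, aggregation=aggregation)


def _pooled_profile_pdi(
    case_ids: list[str],
    ctrl_ids: list[str],
    bulk: ExpressionMatrix | None,
    atlas: AtlasReference | None,
    features: FeatureGeneSet | None,
    min_overlap: int | None,
) -> pd.Series:
    if bulk is None or atlas is None or features is None:
        raise StphenoError(
            "pooled_profile aggregation needs bulk, atlas and features"
        )
    pooled = pd.DataFrame(
        {
            "case": bulk.values[case_ids].mean(axis=1),
            "control": bulk.values[ctrl_ids].mean(axis=1),
        }
    )
    pooled_em = ExpressionMatrix(pooled, "log2TPM1")
    sub = map_samples(
        pooled_em, atlas, features,
        min_overlap=min_overlap if min_overlap is not None else DEFAULT_MIN_OVERLAP,
    )
    return sub.values.loc["case"] - sub.values.loc["control"]


def classify_pdi(pdimap: PDIMap, epsilon: float = 0.0) -> pd.DataFrame:
    """Label each cell enhanced (PDI > ε), attenuated (PDI < −ε) or unchanged.

    The default ε = 0 puts the boundary at no change in association
    strength; NaN cells classify as NA.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    arr = pdimap.values.to_numpy(dtype=float)
    labels = np.full(arr.shape, "unchanged", dtype=object)
    labels[arr > epsilon] = "enhanced"
    labels[arr < -epsilon] = "attenuated"
    labels[np.isnan(arr)] = "NA"
    return pd.DataFrame(labels, index=pdimap.values.index, columns=pdimap.values.columns)


def write_pdi_map(pdimap: PDIMap, path: str | Path) -> None:
    path = Path(path)
    out = pdimap.values.copy()
    out.index.name = "position_id"
    out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")
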