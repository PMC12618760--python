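"""Ground-truthed synthetic atlases and bulk time courses.

The generator emulates the structure the projection framework relies on: a
staged corn-plot layout of positions, each with a disjoint block of marker
genes elevated above a shared baseline (all on the log2(TPM+1) working
scale), bulk replicates drawn from a position's signature with Gaussian
noise, and a knockout-style fate shift modeled as a convex mixture of the
origin signature and an alternative target position's signature. Every
stochastic call is threaded through one seed, so outputs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iomodel import AtlasReference, ExpressionMatrix, FeatureGeneSet, StphenoError
from .pdi import PDIMap
from .projection import PCCMap, rank_positions

#: Study-condition defaults for the synthetic scenario.
DEFAULT_POSITIONS = 10
DEFAULT_GENES = 2000
DEFAULT_MARKERS = 50
DEFAULT_EFFECT = 2.0
DEFAULT_BASELINE_SD = 1.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_REPLICATES = 3
DEFAULT_MIX_WEIGHT = 0.5
#: Mean baseline abundance on the log2(TPM+1) scale.
BASELINE_MEAN = 4.0


@dataclass(frozen=True)
class BulkDesign:
    """One group of synthetic bulk replicates."""

    origin: str
    condition: str
    timepoint: str
    n_reps: int = DEFAULT_REPLICATES
    perturb_target: str | None = None
    w: float = 0.0


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated bulk experiment.

    ``table`` is indexed by sample id with columns ``origin``, ``target``
    (NaN when unperturbed) and ``w`` (mixing weight toward the target).
    """

    table: pd.DataFrame
    seed: int
    noise_sd: float

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise StphenoError("duplicate sample ids in truth table")


@dataclass
class SimulatedAtlas:
    """A simulated atlas plus its generating signatures and marker map."""

    atlas: AtlasReference
    signatures: pd.DataFrame  # genes x positions, noise-free
    markers: dict[str, list[str]]  # position_id -> marker gene ids

    @property
    def feature_set(self) -> FeatureGeneSet:
        genes: set[str] = set()
        for block in self.markers.values():
            genes.update(block)
        return FeatureGeneSet(frozenset(genes), provenance="synthetic_markers")


def simulate_atlas(
    n_stages: int = 1,
    positions_per_stage: int = DEFAULT_POSITIONS,
    n_genes: int = DEFAULT_GENES,
    markers_per_position: int = DEFAULT_MARKERS,
    effect_size: float = DEFAULT_EFFECT,
    baseline_sd: float = DEFAULT_BASELINE_SD,
    seed: int = 0,
) -> SimulatedAtlas:
    """Simulate a staged spatial reference atlas.

    Each position's signature is a shared nonnegative baseline (log2(TPM+1)
    scale) with its own disjoint block of ``markers_per_position`` genes
    elevated by ``effect_size`` log2-units. Positions are laid out on a
    per-stage grid (sections as rows, domains as columns).
    """
    if effect_size <= 0:
        raise StphenoError("effect_size must be > 0")
    n_positions = n_stages * positions_per_stage
    if markers_per_position * n_positions > n_genes:
        raise StphenoError(
            f"marker budget {markers_per_position} x {n_positions} positions "
            f"exceeds {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    baseline = np.clip(rng.normal(BASELINE_MEAN, baseline_sd, n_genes), 0.0, None)
    order = rng.permutation(n_genes)  # marker blocks scattered over the genome

    n_cols = max(1, math.ceil(math.sqrt(positions_per_stage)))
    position_ids: list[str] = []
    meta_rows: list[dict] = []
    for s in range(n_stages):
        stage = f"stage{s + 1}"
        for p in range(positions_per_stage):
            pid = f"{stage}_pos{p + 1:02d}"
            position_ids.append(pid)
            meta_rows.append(
                {
                    "position_id": pid,
                    "stage": stage,
                    "section_index": p // n_cols,
                    "domain_code": f"D{p % n_cols + 1}",
                    "layout_row": p // n_cols,
                    "layout_col": p % n_cols,
                }
            )

    sig = np.tile(baseline[:, None], (1, n_positions))
    markers: dict[str, list[str]] = {}
    for j, pid in enumerate(position_ids):
        block = order[j * markers_per_position : (j + 1) * markers_per_position]
        sig[block, j] += effect_size
        markers[pid] = sorted(gene_ids[i] for i in block)

    signatures = pd.DataFrame(sig, index=gene_ids, columns=position_ids)
    expr = ExpressionMatrix(signatures.copy(), "log2TPM1")
    positions = pd.DataFrame(meta_rows).set_index("position_id")
    vocab = {
        f"stage{s + 1}": frozenset(f"D{c + 1}" for c in range(n_cols))
        for s in range(n_stages)
    }
    atlas = AtlasReference(expr, positions, domain_vocab=vocab)
    return SimulatedAtlas(atlas=atlas, signatures=signatures, markers=markers)


def simulate_bulk(
    signatures: pd.DataFrame,
    design: Sequence[BulkDesign | tuple],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate bulk replicates from position signatures.

    Each replicate of a design group is
    ``(1 - w) * signature(origin) + w * signature(perturb_target)`` plus
    Gaussian noise of standard deviation ``noise_sd``, clipped at 0 (the
    working scale is log2(TPM+1), which is nonnegative).
    """
    design = [d if isinstance(d, BulkDesign) else BulkDesign(*d) for d in design]
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []
    for d in design:
        if d.origin not in signatures.columns:
            raise StphenoError(f"unknown origin position {d.origin!r}")
        if d.perturb_target is not None and d.perturb_target not in signatures.columns:
            raise StphenoError(f"unknown perturbation target {d.perturb_target!r}")
        if not 0.0 <= d.w <= 1.0:
            raise StphenoError(f"mixing weight w={d.w} outside [0, 1]")
        if d.n_reps < 1:
            raise StphenoError("n_reps must be >= 1")
        base = signatures[d.origin].to_numpy(dtype=float)
        if d.perturb_target is not None and d.w > 0:
            target = signatures[d.perturb_target].to_numpy(dtype=float)
            mean = (1.0 - d.w) * base + d.w * target
        else:
            mean = base
        for r in range(d.n_reps):
            sid = f"{d.condition}_{d.timepoint}_{d.origin}_rep{r + 1}"
            if sid in cols:
                raise StphenoError(f"duplicate sample id {sid!r} in design")
            noise = rng.normal(0.0, noise_sd, len(mean)) if noise_sd > 0 else 0.0
            cols[sid] = np.clip(mean + noise, 0.0, None)
            ann_rows.append(
                {
                    "sample_id": sid,
                    "condition": d.condition,
                    "timepoint": d.timepoint,
                    "replicate": f"rep{r + 1}",
                }
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "origin": d.origin,
                    "target": d.perturb_target if d.w > 0 else None,
                    "w": d.w,
                    "condition": d.condition,
                    "timepoint": d.timepoint,
                }
            )
    values = pd.DataFrame(cols, index=signatures.index)
    annotations = pd.DataFrame(ann_rows).set_index("sample_id")
    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows).set_index("sample_id"),
        seed=seed,
        noise_sd=noise_sd,
    )
    bulk = ExpressionMatrix(values, "log2TPM1", annotations)
    return bulk, truth


def fate_shift_design(
    position_ids: Sequence[str],
    n_reps: int = DEFAULT_REPLICATES,
    w: float = DEFAULT_MIX_WEIGHT,
    case: str = "KO",
    control: str = "WT",
) -> list[BulkDesign]:
    """The canonical knockout fate-shift scenario.

    For every position, one control group of replicates drawn from that
    origin, and one case group whose signature is shifted with weight ``w``
    toward the cyclically next position. Each origin gets its own timepoint
    label, so each case/control comparison is matched per origin.
    """
    design: list[BulkDesign] = []
    ids = list(position_ids)
    for i, origin in enumerate(ids):
        tp = f"D{i + 1}"
        target = ids[(i + 1) % len(ids)]
        design.append(BulkDesign(origin, control, tp, n_reps))
        design.append(BulkDesign(origin, case, tp, n_reps, target, w))
    return design


def recovery_report(
    result: PCCMap | PDIMap,
    truth: SyntheticTruth,
    include_perturbed: bool = False,
) -> dict:
    """Score a mapping or PDI result against the generator's ground truth.

    For a PCC map: the origin-recovery rate, the fraction of samples whose
    top-ranked position is their true origin. By default only unperturbed
    samples (w = 0) count — a half-mixed sample is equidistant from origin
    and target by construction, so its top-1 label is uninformative; pass
    ``include_perturbed=True`` for the unrestricted rate.

    For a PDI map: the sign-agreement rate, the fraction of perturbed
    comparisons whose PDI at the perturbation target is positive.
    """
    if isinstance(result, PCCMap):
        missing = result.sample_ids.difference(truth.table.index)
        if len(missing):
            raise StphenoError(
                f"samples absent from truth table: {missing.tolist()[:10]}"
            )
        ranks = rank_positions(result, k=1)
        sub = truth.table.loc[result.sample_ids]
        if not include_perturbed:
            sub = sub[sub["w"] == 0.0]
        if sub.empty:
            raise StphenoError("no samples to score for origin recovery")
        correct = sum(
            1 for sid, row in sub.iterrows() if ranks[sid][0][0] == row["origin"]
        )
        return {
            "origin_recovery": correct / len(sub),
            "n_samples": int(len(sub)),
        }
    if isinstance(result, PDIMap):
        checks: list[bool] = []
        for label, comp in result.comparisons.iterrows():
            sub = truth.table[
                (truth.table["w"] > 0)
                & truth.table["target"].notna()
                & (truth.table["condition"] == comp["case"])
                & (truth.table["timepoint"] == comp["timepoint"])
            ]
            for target in sorted(set(sub["target"])):
                if target not in result.values.index:
                    raise StphenoError(
                        f"perturbation target {target!r} absent from PDI map"
                    )
                checks.append(bool(result.values.loc[target, label] > 0))
        if not checks:
            raise StphenoError("no perturbed comparisons to score")
        return {
            "pdi_sign_agreement": sum(checks) / len(checks),
            "n_targets": len(checks),
        }
    raise TypeError(f"cannot score a {type(result).__name__}")
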