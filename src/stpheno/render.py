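"""Corn-plot-style rendering of PCC and PDI spatial maps.

One panel per stage; each position is drawn as a grid cell at its
(layout_row, layout_col). PDI columns use a diverging palette centered at 0
with symmetric limits ±max(|PDI|); PCC columns use a sequential palette on
[min, max]. Undefined cells are hatched. By default higher section indices
are drawn lower on the panel (distal at the bottom), matching
proximal→distal embryo depictions.

SVG output is deterministic for fixed input (fixed hash salt, no embedded
timestamps), so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .iomodel import AtlasReference, StphenoError

PCC_CMAP = "viridis"
PDI_CMAP = "RdBu_r"


def render_spatial_map(
    values: pd.Series,
    atlas: AtlasReference,
    out_path: str | Path,
    mode: str = "pdi",
    title: str | None = None,
    flip: bool = False,
) -> Path:
    """Render one PCC or PDI column as a per-stage corn-plot grid.

    ``values`` is indexed by position id (NaN = undefined, drawn hatched).
    ``flip=True`` puts low section indices at the bottom instead.
    """
    if mode not in ("pcc", "pdi"):
        raise StphenoError(f"mode must be 'pcc' or 'pdi', got {mode!r}")
    pos = atlas.positions
    missing = pos.index.difference(values.index)
    if len(missing):
        raise StphenoError(f"values lack positions: {missing.tolist()[:10]}")
    vals = values.reindex(pos.index).astype(float)

    finite = vals.dropna()
    if mode == "pdi":
        m = float(np.abs(finite).max()) if len(finite) else 0.0
        if m == 0.0:
            m = 1.0  # all-zero column still renders at the palette midpoint
        vmin, vmax, cmap = -m, m, PDI_CMAP
    else:
        if len(finite):
            vmin, vmax = float(finite.min()), float(finite.max())
            if vmin == vmax:
                vmin, vmax = vmin - 0.5, vmax + 0.5
        else:
            vmin, vmax = -1.0, 1.0
        cmap = PCC_CMAP

    stages = atlas.stages
    with plt.rc_context({"svg.hashsalt": "stpheno"}):
        fig, axes = plt.subplots(
            1, len(stages), figsize=(3.2 * len(stages) + 1.2, 3.4), squeeze=False
        )
        for ax, stage in zip(axes[0], stages):
            sub = pos[pos["stage"].astype(str) == stage]
            rows = np.sort(sub["layout_row"].unique())
            cols = np.sort(sub["layout_col"].unique())
            rmap = {r: i for i, r in enumerate(rows)}
            cmap_idx = {c: i for i, c in enumerate(cols)}
            grid = np.full((len(rows), len(cols)), np.nan)
            for pid, row in sub.iterrows():
                grid[rmap[row["layout_row"]], cmap_idx[row["layout_col"]]] = vals[pid]
            masked = np.ma.masked_invalid(grid)
            origin = "lower" if flip else "upper"
            im = ax.imshow(
                masked, cmap=cmap, vmin=vmin, vmax=vmax, origin=origin, aspect="equal"
            )
            # hatch undefined cells
            for (ri, ci), bad in np.ndenumerate(masked.mask if masked.mask.shape else np.zeros_like(grid, bool)):
                if bad:
                    ax.add_patch(
                        plt.Rectangle(
                            (ci - 0.5, ri - 0.5), 1, 1,
                            fill=False, hatch="///", edgecolor="grey", linewidth=0.5,
                        )
                    )
            # column labels: domain codes; row labels: section indices
            col_domains = (
                sub.sort_values("layout_col")
                .drop_duplicates("layout_col")
                .set_index("layout_col")["domain_code"]
            )
            ax.set_xticks(range(len(cols)))
            ax.set_xticklabels([str(col_domains.get(c, "")) for c in cols], fontsize=7)
            row_sections = (
                sub.sort_values("layout_row")
                .drop_duplicates("layout_row")
                .set_index("layout_row")["section_index"]
            )
            ax.set_yticks(range(len(rows)))
            ax.set_yticklabels([str(row_sections.get(r, "")) for r in rows], fontsize=7)
            ax.set_title(str(stage), fontsize=9)
        fig.colorbar(im, ax=axes[0].tolist(), shrink=0.85, label=mode.upper())
        if title:
            fig.suptitle(title, fontsize=10)
        out_path = Path(out_path)
        fig.savefig(out_path, metadata=_deterministic_metadata(out_path))
        plt.close(fig)
    return out_path


def _deterministic_metadata(path: Path) -> dict | None:
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    if path.suffix.lower() == ".png":
        return {"Software": None}
    return None
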