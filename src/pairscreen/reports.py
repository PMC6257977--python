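"""Result writers and checkerboard visualisations.

Heatmaps use a purple→yellow diverging scale clamped to [−100%, +100%];
patches excluded by the replicate-SD rule are white with an "X".  Growth
curve grids show treated curves (red) over the median untreated curve
(black) with the display range [−50%, 120%].  CSV/TXT outputs are
deterministic (sorted keys, fixed float format) and carry the run
configuration as comment headers — display clamping never applies to them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .confluence import ConfluenceCurve
from .dtem import DetectionTable
from .optimize import OptimizationResult
from .qc import QCReport
from .viability import SurvivalMatrix, SynergyResult

__all__ = [
    "render_checkerboard",
    "render_curve_grid",
    "render_qc_scatter",
    "render_detection_curves",
    "write_matrix_csv",
    "write_detection_txt",
    "write_confluence_csv",
    "write_nd_csv",
    "write_synergy_tables",
]

HEATMAP_CLAMP = (-100.0, 100.0)
CURVE_DISPLAY_RANGE = (-50.0, 120.0)  # percent change in confluence
FIGURE_FORMATS = ("pdf", "png")


def _metadata_header(metadata: Mapping | None) -> str:
    lines = []
    for k in sorted(metadata or {}):
        lines.append(f"# {k}: {metadata[k]}")
    return "\n".join(lines) + ("\n" if lines else "")


def _save(fig, path_base: Path, formats: Sequence[str] = FIGURE_FORMATS) -> list[Path]:
    paths = []
    for ext in formats:
        p = path_base.with_suffix(f".{ext}")
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def render_checkerboard(
    values: np.ndarray,
    conc1: Sequence[float],
    conc2: Sequence[float],
    path_base: str | Path,
    excluded: np.ndarray | None = None,
    title: str = "",
    clamp: tuple[float, float] = HEATMAP_CLAMP,
    formats: Sequence[str] = FIGURE_FORMATS,
) -> list[Path]:
    """Heatmap of one drug pair's index matrix (percent scale)."""
    values = np.asarray(values, dtype=float)
    shown = np.clip(values, *clamp)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(conc2), 1.0 + 0.6 * len(conc1)))
    masked = np.ma.masked_invalid(shown)
    cmap = plt.get_cmap("viridis").copy()  # purple → yellow
    cmap.set_bad("white")
    im = ax.imshow(masked, cmap=cmap, vmin=clamp[0], vmax=clamp[1], origin="lower")
    if excluded is not None:
        for i, j in zip(*np.nonzero(np.asarray(excluded, dtype=bool))):
            ax.text(j, i, "X", ha="center", va="center", color="black")
    ax.set_xticks(range(len(conc2)), [f"{c:g}" for c in conc2])
    ax.set_yticks(range(len(conc1)), [f"{c:g}" for c in conc1])
    ax.set_xlabel("drug 2 concentration")
    ax.set_ylabel("drug 1 concentration")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="%")
    return _save(fig, Path(path_base), formats)


def render_curve_grid(
    curves: Mapping[str, ConfluenceCurve],
    layout_wells: Mapping[tuple[int, int], Sequence[str]],
    median_control: np.ndarray,
    conc1: Sequence[float],
    conc2: Sequence[float],
    path_base: str | Path,
    title: str = "",
    formats: Sequence[str] = FIGURE_FORMATS,
) -> list[Path]:
    """Checkerboard grid of relative growth curves for one drug pair.

    ``layout_wells`` maps (dose-grid row, column) → the wells of that patch.
    Treated curves in red, the plate-wide median untreated curve in black;
    y-range fixed to the display window.
    """
    n1, n2 = len(conc1), len(conc2)
    fig, axes = plt.subplots(
        n1, n2, figsize=(1.6 * n2, 1.3 * n1), sharex=True, sharey=True, squeeze=False
    )
    for i in range(n1):
        for j in range(n2):
            ax = axes[n1 - 1 - i][j]  # doses increase upwards
            ax.plot(100.0 * median_control, color="black", lw=1)
            for w in layout_wells.get((i, j), []):
                curve = curves.get(w)
                if curve is not None and curve.relative is not None:
                    ax.plot(100.0 * curve.relative, color="red", lw=1)
            ax.set_ylim(*CURVE_DISPLAY_RANGE)
            ax.tick_params(labelsize=6)
            if i == 0:
                ax.set_xlabel(f"{conc2[j]:g}", fontsize=7)
            if j == 0:
                ax.set_ylabel(f"{conc1[i]:g}", fontsize=7)
    if title:
        fig.suptitle(title)
    return _save(fig, Path(path_base), formats)


def render_qc_scatter(
    report: QCReport, path_base: str | Path, formats: Sequence[str] = FIGURE_FORMATS
) -> list[Path]:
    """Per-well deviation norms with the outlier threshold line."""
    fig, ax = plt.subplots(figsize=(6, 3))
    wells = report.wells
    values = [report.l1_norms[w] for w in wells]
    colors = ["red" if w in report.flagged else "tab:blue" for w in wells]
    ax.scatter(range(len(wells)), values, c=colors, s=12)
    ax.axhline(report.threshold, color="red", ls=":", label="threshold")
    ax.set_xlabel("well index")
    ax.set_ylabel(r"$\|e_w\|_1$")
    ax.legend()
    return _save(fig, Path(path_base), formats)


def render_detection_curves(
    result: OptimizationResult,
    path_base: str | Path,
    hours_per_frame: float = 6.0,
    formats: Sequence[str] = FIGURE_FORMATS,
) -> list[Path]:
    """Detection count vs window start, one line per (r, b) grid pair."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    x = [hours_per_frame * k for k, _ in result.intervals]
    for gi, (r, b) in enumerate(result.grid):
        ax.plot(x, result.n_detections[gi], marker="o", label=f"r={r:g}, b={b:g}")
    ax.set_xlabel("first time point of interval (h)")
    ax.set_ylabel("number of detections")
    ax.legend(fontsize=8)
    return _save(fig, Path(path_base), formats)


# ---------------------------------------------------------------------------
# tabular outputs


def write_matrix_csv(
    path: str | Path,
    values: np.ndarray,
    conc1: Sequence[float],
    conc2: Sequence[float],
    excluded: np.ndarray | None = None,
    metadata: Mapping | None = None,
) -> None:
    """One index matrix as CSV (rows = drug-1 doses); raw, unclamped values."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(conc1), columns=list(conc2))
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        df.to_csv(fh, float_format="%.6g")
        if excluded is not None:
            fh.write("# excluded mask (1 = excluded by the replicate-SD rule)\n")
            pd.DataFrame(
                np.asarray(excluded, dtype=int), index=list(conc1), columns=list(conc2)
            ).to_csv(fh)


def write_detection_txt(
    path: str | Path, table: DetectionTable, metadata: Mapping | None = None
) -> None:
    """Raw per-well DTEM results: well, role, l1, τ, d̃, detected."""
    meta = dict(metadata or {})
    meta.update(table.metadata)
    meta["tau"] = table.pool.tau
    meta["null_percentile"] = table.pool.percentile
    meta["n_detections"] = table.n_detections
    meta["detection_strength"] = table.strength
    meta["degenerate_null"] = table.degenerate_null
    rows = [
        {
            "well": r.well,
            "role": r.role,
            "l1": r.l1,
            "tau": table.pool.tau,
            "d_tilde": r.d_tilde,
            "detected": int(r.detected),
        }
        for r in sorted(table.records, key=lambda r: r.well)
    ]
    with open(path, "w") as fh:
        fh.write(_metadata_header(meta))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.8g")


def write_confluence_csv(
    path: str | Path,
    curves: Mapping[str, ConfluenceCurve],
    metadata: Mapping | None = None,
) -> None:
    """Raw and relative confluence, one row per well per time point."""
    rows = []
    for w in sorted(curves):
        c = curves[w]
        for t, v in enumerate(c.confluence):
            rows.append(
                {
                    "well": w,
                    "time_index": t,
                    "confluence": v,
                    "relative_confluence": (
                        c.relative[t] if c.relative is not None else np.nan
                    ),
                    "valid": int(c.valid),
                }
            )
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.8g")


def write_nd_csv(
    path: str | Path, result: OptimizationResult, metadata: Mapping | None = None
) -> None:
    """Detection-count matrix: rows = (r, b) pairs, columns = intervals."""
    cols = [f"t{k + 1}..t{last + 1}" for k, last in result.intervals]
    idx = [f"r={r:g},b={b:g}" for r, b in result.grid]
    with open(path, "w") as fh:
        fh.write(_metadata_header(metadata))
        pd.DataFrame(result.n_detections, index=idx, columns=cols).to_csv(fh)
        fh.write("# detection strength (sum of positive relative differences)\n")
        pd.DataFrame(result.strengths, index=idx, columns=cols).to_csv(
            fh, float_format="%.6g"
        )


def write_synergy_tables(
    out_dir: str | Path, result: SynergyResult, metadata: Mapping | None = None
) -> list[Path]:
    """One CSV per index type per drug pair; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta.update(result.metadata)
    written = []
    groups: list[tuple[str, Mapping, bool]] = [
        ("survival", result.survival, True),
        ("bliss", result.bliss, False),
        ("bliss_scaled", result.bliss_scaled, False),
        ("therapeutic", result.therapeutic, False),
        ("therapeutic_refined", result.therapeutic_rw, False),
    ]
    for name, matrices, is_survival in groups:
        for pair, mat in matrices.items():
            surv = result.survival[pair]
            tag = f"{pair[0]}_{pair[1]}"
            path = out / f"{name}_{tag}.csv"
            values = mat.values if isinstance(mat, SurvivalMatrix) else mat
            write_matrix_csv(
                path,
                values,
                surv.conc1,
                surv.conc2,
                excluded=surv.excluded if is_survival else np.isnan(np.asarray(values, dtype=float)),
                metadata={**meta, "index": name, "pair": f"{pair[0]}+{pair[1]}"},
            )
            written.append(path)
    return written
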