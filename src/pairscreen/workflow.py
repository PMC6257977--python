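"""End-to-end orchestration of the imaging workflows.

Both imaging analyses share the same front end: quality control over the
untreated frames flags outlier wells, those wells are dropped from
everything downstream, and the global background interval is estimated from
the surviving wells' untreated frames.  The morphology workflow then sweeps
the (r, b) parameter grid over decreasing time windows; the confluence
workflow segments every post-treatment frame and builds relative growth
curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .confluence import ConfluenceCurve, median_control_curve, run_confluence
from .dtem import DEFAULT_NULL_PERCENTILE
from .optimize import DEFAULT_GRID, OptimizationResult, optimize
from .qc import QCReport, detect_outliers, qc_extract
from .segmentation import DEFAULT_DEVIATION, BackgroundModel, estimate_background

__all__ = ["MorphologyRun", "run_morphology", "ConfluenceRun", "run_confluence_workflow"]


def _qc_and_background(
    datastore: Mapping[str, Sequence[np.ndarray]],
    n_untreated_frames: int,
    deviation: float,
    workers: int,
    value_range: tuple[float, float] | None,
) -> tuple[QCReport, dict, BackgroundModel]:
    qc_tems = qc_extract(datastore, n_untreated_frames, workers=workers, value_range=value_range)
    report = detect_outliers(qc_tems)
    kept = {w: datastore[w] for w in report.kept()}
    # background re-estimated without flagged wells
    model = estimate_background(kept, n_untreated_frames, deviation)
    return report, kept, model


@dataclass
class MorphologyRun:
    qc: QCReport
    model: BackgroundModel
    optimization: OptimizationResult


def run_morphology(
    datastore: Mapping[str, Sequence[np.ndarray]],
    roles: Mapping[str, str],
    n_untreated_frames: int,
    deviation: float = DEFAULT_DEVIATION,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    percentile: float = DEFAULT_NULL_PERCENTILE,
    workers: int = 1,
    value_range: tuple[float, float] | None = None,
) -> MorphologyRun:
    """QC → background model → parameter-optimised deviation analysis."""
    report, kept, model = _qc_and_background(
        datastore, n_untreated_frames, deviation, workers, value_range
    )
    result = optimize(
        kept,
        model,
        roles,
        n_untreated_frames,
        grid=grid,
        percentile=percentile,
        workers=workers,
        value_range=value_range,
    )
    return MorphologyRun(qc=report, model=model, optimization=result)


@dataclass
class ConfluenceRun:
    qc: QCReport
    model: BackgroundModel
    curves: dict[str, ConfluenceCurve]
    median_control: np.ndarray


def run_confluence_workflow(
    datastore: Mapping[str, Sequence[np.ndarray]],
    roles: Mapping[str, str],
    n_untreated_frames: int,
    deviation: float = DEFAULT_DEVIATION,
    workers: int = 1,
    value_range: tuple[float, float] | None = None,
) -> ConfluenceRun:
    """QC → background model → per-well relative growth curves."""
    report, kept, model = _qc_and_background(
        datastore, n_untreated_frames, deviation, workers, value_range
    )
    curves = run_confluence(kept, model, n_untreated_frames, workers=workers)
    controls = [
        w for w in kept if roles.get(w) in ("growth_control", "control")
    ]
    median = median_control_curve(curves, controls)
    return ConfluenceRun(qc=report, model=model, curves=curves, median_control=median)
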