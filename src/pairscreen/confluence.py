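"""Confluence growth curves from foreground segmentation.

Confluence at a time point is simply the fraction of frame pixels outside
the global background interval, c(t) = (foreground count)/N.  To compare
wells with different seeding densities, curves are re-expressed relative to
the first post-treatment time point:

    c̃(t_i) = c(t_i)/c(t_1) − 1

so every well starts at 0 and later values are fractional increases or
decreases in confluence.  Extraction follows the same map/reduce contract as
the feature pipeline: per-frame segmentation and counting is the map step,
per-well curve assembly the reduce step, and results are identical for any
worker count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .segmentation import BackgroundModel, segment

__all__ = [
    "frame_confluence",
    "relative_curve",
    "ConfluenceCurve",
    "run_confluence",
    "median_control_curve",
]


def frame_confluence(mask: np.ndarray) -> float:
    """Fraction of foreground pixels in a binary mask."""
    mask = np.asarray(mask)
    return float(mask.sum() / mask.size)


def relative_curve(confluence: Sequence[float]) -> np.ndarray:
    """Curve relative to its first value: c(t)/c(t1) − 1."""
    c = np.asarray(confluence, dtype=float)
    if c.size == 0:
        raise ValueError("empty confluence series")
    if c[0] <= 0:
        raise ValueError("relative confluence undefined: c(t1) = 0")
    return c / c[0] - 1.0


@dataclass
class ConfluenceCurve:
    """Per-well confluence trajectory over the post-treatment frames."""

    well: str
    confluence: np.ndarray  # fractions per time point
    relative: np.ndarray | None  # None when c(t1) = 0
    n_pixels: int

    @property
    def valid(self) -> bool:
        return self.relative is not None


def _frame_conf(frame: np.ndarray, model: BackgroundModel) -> float:
    return frame_confluence(segment(frame, model))


def run_confluence(
    datastore: Mapping[str, Sequence[np.ndarray]],
    model: BackgroundModel,
    n_untreated_frames: int = 0,
    workers: int = 1,
) -> dict[str, ConfluenceCurve]:
    """Confluence and relative-confluence curves for every well.

    The first ``n_untreated_frames`` frames of each movie are skipped — they
    serve background estimation and QC only; the relative curve is anchored
    at the first post-treatment frame.  Wells with zero confluence at that
    anchor get ``relative=None`` and are reported invalid instead of
    dividing by zero.
    """
    wells = sorted(datastore)
    if not wells:
        raise ValueError("empty datastore")
    tasks = [
        (w, t)
        for w in wells
        for t in range(n_untreated_frames, len(datastore[w]))
    ]
    if not tasks:
        raise ValueError("no post-treatment frames")
    if workers == 1:
        values = [_frame_conf(datastore[w][t], model) for w, t in tasks]
    else:
        values = Parallel(n_jobs=workers)(
            delayed(_frame_conf)(datastore[w][t], model) for w, t in tasks
        )
    series: dict[str, list[float]] = {w: [] for w in wells}
    for (w, _t), v in zip(tasks, values):
        series[w].append(v)
    curves = {}
    for w in wells:
        c = np.asarray(series[w])
        rel = relative_curve(c) if c[0] > 0 else None
        curves[w] = ConfluenceCurve(
            well=w,
            confluence=c,
            relative=rel,
            n_pixels=int(np.asarray(datastore[w][0]).size),
        )
    return curves


def median_control_curve(
    curves: Mapping[str, ConfluenceCurve], control_wells: Sequence[str]
) -> np.ndarray:
    """Pointwise median relative curve over the (QC-surviving) control wells."""
    rels = [
        curves[w].relative
        for w in control_wells
        if w in curves and curves[w].relative is not None
    ]
    if not rels:
        raise ValueError("no valid control curves")
    return np.median(np.stack(rels), axis=0)
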