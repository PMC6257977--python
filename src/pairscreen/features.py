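"""Hierarchical pixel-histogram features and time-evolving morphology matrices.

The morphology of a well at one time point is summarised by pixel histograms
extracted at a hierarchy of consecutively reduced resolutions.  Level 1 is
the original frame; level j is the frame downscaled by r^(j−1) per dimension
(exact area-weighted averaging).  The bin count shrinks by the factor b per
level and the hierarchy stops before it would drop below 2.  Concatenating
the per-level histograms gives the frame's feature vector h_w(t); stacking
the vectors of all time points column-wise gives the per-well feature matrix
H_w (the time-evolving morphologies, TEM).

Two masking modes exist:

* ``all_pixels`` — raw counts over every pixel (used by image quality
  control, where confluence differences are themselves informative);
* ``foreground_normalized`` — only pixels outside the background interval τ
  are counted (τ re-applied to each downscaled image) and each level's
  histogram is normalised to unit sum, so the features depend on cell
  morphology but not on confluence.

Extraction follows a map/reduce contract: per-frame feature extraction (the
map step) is independent and may run on any number of workers; per-well
assembly (the reduce step) collects columns by (well, time) key.  The result
is bit-identical regardless of worker count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import floor
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .segmentation import BackgroundModel

__all__ = [
    "HierarchySchedule",
    "build_schedule",
    "downscale_mean",
    "frame_features",
    "TEMMatrix",
    "extract_tem",
    "extract_plate_tem",
    "DEFAULT_ANALYSIS_BINS",
]

#: bins at the original resolution for the morphology analysis
DEFAULT_ANALYSIS_BINS = 16

MASK_MODES = ("all_pixels", "foreground_normalized")


@dataclass(frozen=True)
class HierarchySchedule:
    """Resolution/bin schedule of the histogram hierarchy.

    ``bins_per_level[j]`` histograms the image downscaled by ``r**j`` per
    dimension (j = 0 is the original resolution).
    """

    b0: int
    r: float
    b: float
    bins_per_level: tuple[int, ...]

    @property
    def levels(self) -> int:
        return len(self.bins_per_level)

    @property
    def n_features(self) -> int:
        return int(sum(self.bins_per_level))

    def scale(self, level: int) -> float:
        return self.r**level


def build_schedule(b0: int = DEFAULT_ANALYSIS_BINS, r: float = 0.5, b: float = 0.5) -> HierarchySchedule:
    """Generate hierarchy levels until the next bin count would drop below 2.

    Fractional intermediate bin counts are floored (e.g. 10 → 5 → 2).
    """
    if b0 < 2:
        raise ValueError("initial bin count must be at least 2")
    if not 0 < r <= 1 or not 0 < b <= 1:
        raise ValueError("scale factors r and b must lie in (0, 1]")
    bins = [int(b0)]
    if b < 1:
        while True:
            nxt = bins[-1] * b
            if nxt < 2:
                break
            bins.append(floor(nxt))
    return HierarchySchedule(b0=int(b0), r=float(r), b=float(b), bins_per_level=tuple(bins))


# ---------------------------------------------------------------------------
# exact area-weighted downscaling


@lru_cache(maxsize=256)
def _axis_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out × n_in) matrix averaging an axis of length n_in down to n_out.

    Output cell i covers the input interval [i·f, (i+1)·f) with f = n_in/n_out;
    each input pixel contributes proportionally to its overlap, so rows sum
    to 1 and integer factors reduce to plain block means.
    """
    edges = np.linspace(0.0, n_in, n_out + 1)
    k = np.arange(n_in)
    lo = np.maximum.outer(edges[:-1], k.astype(float))
    hi = np.minimum.outer(edges[1:], (k + 1).astype(float))
    w = np.clip(hi - lo, 0.0, None)
    w /= n_in / n_out
    return w


def downscale_mean(image: np.ndarray, scale: float) -> np.ndarray:
    """Downscale by ``scale`` per dimension with exact area averaging."""
    img = np.asarray(image, dtype=np.float64)
    if scale == 1.0:
        return img
    if not 0 < scale < 1:
        raise ValueError("scale must lie in (0, 1]")
    h, w = img.shape
    h_out = max(1, floor(h * scale))
    w_out = max(1, floor(w * scale))
    wr = _axis_weights(h, h_out)
    wc = _axis_weights(w, w_out)
    return wr @ img @ wc.T


# ---------------------------------------------------------------------------
# per-frame features


def _value_range(frame: np.ndarray, value_range: tuple[float, float] | None):
    if value_range is not None:
        return value_range
    dtype = np.asarray(frame).dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return (float(info.min), float(info.max))
    raise ValueError(
        "value_range must be given explicitly for non-integer frames"
    )


def frame_features(
    frame: np.ndarray,
    schedule: HierarchySchedule,
    mask_mode: str = "foreground_normalized",
    model: BackgroundModel | None = None,
    value_range: tuple[float, float] | None = None,
    well: str | None = None,
) -> np.ndarray:
    """Concatenated hierarchical histogram vector of one frame.

    Bin edges are uniform over the intensity range of the frame's dtype
    (rightmost bin closed), fixed across frames and wells so features are
    comparable.  In foreground mode the background interval is re-applied to
    every downscaled image; a level with empty foreground contributes a zero
    block (a warning is emitted so pathological wells are visible).
    """
    if mask_mode not in MASK_MODES:
        raise ValueError(f"mask_mode must be one of {MASK_MODES}")
    if mask_mode == "foreground_normalized" and model is None:
        raise ValueError("foreground mode requires a background model")
    rng = _value_range(frame, value_range)
    img0 = np.asarray(frame, dtype=np.float64)
    if img0.ndim != 2:
        raise ValueError("frames must be 2-D grayscale images")
    blocks: list[np.ndarray] = []
    for level, nbins in enumerate(schedule.bins_per_level):
        img = downscale_mean(img0, schedule.scale(level))
        if mask_mode == "foreground_normalized":
            lo, hi = model.tau
            values = img[(img < lo) | (img > hi)]
            hist, _ = np.histogram(values, bins=nbins, range=rng)
            total = hist.sum()
            if total > 0:
                blocks.append(hist / total)
            else:
                warnings.warn(
                    f"empty foreground at hierarchy level {level + 1}"
                    + (f" (well {well})" if well else ""),
                    RuntimeWarning,
                    stacklevel=2,
                )
                blocks.append(np.zeros(nbins))
        else:
            hist, _ = np.histogram(img, bins=nbins, range=rng)
            blocks.append(hist.astype(np.float64))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# per-well and per-plate extraction (map/reduce)


@dataclass
class TEMMatrix:
    """Per-well feature matrix: one histogram-hierarchy column per time point."""

    well: str
    values: np.ndarray  # (n_features × n_timepoints)
    schedule: HierarchySchedule
    mask_mode: str
    times: tuple[int, ...]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def window(self, start: int, stop: int | None = None) -> "TEMMatrix":
        """Sub-matrix restricted to time indices [start, stop) of the columns."""
        stop = self.values.shape[1] if stop is None else stop
        return TEMMatrix(
            well=self.well,
            values=self.values[:, start:stop],
            schedule=self.schedule,
            mask_mode=self.mask_mode,
            times=self.times[start:stop],
        )


def extract_tem(
    movie: Sequence[np.ndarray],
    schedule: HierarchySchedule,
    mask_mode: str = "foreground_normalized",
    model: BackgroundModel | None = None,
    frame_range: tuple[int, int] | None = None,
    well: str = "",
    workers: int = 1,
    value_range: tuple[float, float] | None = None,
) -> TEMMatrix:
    """TEM matrix of one movie; columns follow frame order within ``frame_range``."""
    start, stop = frame_range if frame_range is not None else (0, len(movie))
    if not 0 <= start < stop <= len(movie):
        raise ValueError(f"frame range [{start}, {stop}) outside movie of length {len(movie)}")
    frames = list(movie[start:stop])
    if workers == 1:
        cols = [
            frame_features(f, schedule, mask_mode, model, value_range, well)
            for f in frames
        ]
    else:
        cols = Parallel(n_jobs=workers)(
            delayed(frame_features)(f, schedule, mask_mode, model, value_range, well)
            for f in frames
        )
    return TEMMatrix(
        well=well,
        values=np.column_stack(cols),
        schedule=schedule,
        mask_mode=mask_mode,
        times=tuple(range(start, stop)),
    )


def extract_plate_tem(
    datastore: Mapping[str, Sequence[np.ndarray]],
    schedule: HierarchySchedule,
    mask_mode: str = "foreground_normalized",
    model: BackgroundModel | None = None,
    frame_range: tuple[int, int] | None = None,
    workers: int = 1,
    value_range: tuple[float, float] | None = None,
) -> dict[str, TEMMatrix]:
    """TEM matrices for every well of a datastore.

    Map step: hierarchical histograms of single frames, flattened over all
    (well, time) pairs and distributed over ``workers`` jobs.  Reduce step:
    columns regrouped per well in time order.  Missing frames inside the
    requested range raise an error naming every (well, time) hole.
    """
    wells = sorted(datastore)
    if not wells:
        raise ValueError("empty datastore")
    n_frames = {w: len(datastore[w]) for w in wells}
    start, stop = frame_range if frame_range is not None else (0, min(n_frames.values()))
    missing = [(w, t) for w in wells for t in range(start, stop) if t >= n_frames[w]]
    if missing:
        raise ValueError(f"missing frames in requested range: {missing}")

    tasks = [(w, t) for w in wells for t in range(start, stop)]
    if workers == 1:
        results = [
            frame_features(datastore[w][t], schedule, mask_mode, model, value_range, w)
            for w, t in tasks
        ]
    else:
        results = Parallel(n_jobs=workers)(
            delayed(frame_features)(
                datastore[w][t], schedule, mask_mode, model, value_range, w
            )
            for w, t in tasks
        )
    by_well: dict[str, list[np.ndarray]] = {w: [] for w in wells}
    for (w, _t), col in zip(tasks, results):
        by_well[w].append(col)
    return {
        w: TEMMatrix(
            well=w,
            values=np.column_stack(by_well[w]),
            schedule=schedule,
            mask_mode=mask_mode,
            times=tuple(range(start, stop)),
        )
        for w in wells
    }
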