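"""Image quality control: flag outlier wells before treatment effects exist.

During the untreated acquisition interval all wells should look alike, so a
well whose pixel statistics deviate strongly from the plate average is an
imaging artefact (condensation, debris, focus failure) rather than biology.
TEM matrices are extracted over the untreated frames only, in all-pixels
mode with the fixed QC hierarchy (128 bins at the original resolution,
resolution factor 1/4, bin factor 1/8 → bin counts [128, 16, 2]).  Per well
the matrix rows are averaged over the untreated columns (h̄_w), the global
average h̄ is the mean over wells, and the L1 norm of e_w = h̄_w − h̄ enters a
pool P_e.  Wells with ‖e_w‖₁ ≥ 1.5 × (95th percentile of P_e) are flagged
and excluded from all downstream image analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .features import TEMMatrix, build_schedule, extract_plate_tem

__all__ = [
    "QC_BINS",
    "QC_RESOLUTION_FACTOR",
    "QC_BIN_FACTOR",
    "QC_THRESHOLD_MULTIPLIER",
    "QC_PERCENTILE",
    "qc_schedule",
    "qc_extract",
    "QCReport",
    "detect_outliers",
]

QC_BINS = 128
QC_RESOLUTION_FACTOR = 0.25
QC_BIN_FACTOR = 0.125
QC_THRESHOLD_MULTIPLIER = 1.5
QC_PERCENTILE = 95.0


def qc_schedule():
    """The fixed QC hierarchy: bins [128, 16, 2]."""
    return build_schedule(QC_BINS, QC_RESOLUTION_FACTOR, QC_BIN_FACTOR)


def qc_extract(
    datastore: Mapping[str, Sequence[np.ndarray]],
    n_untreated_frames: int,
    workers: int = 1,
    value_range: tuple[float, float] | None = None,
) -> dict[str, TEMMatrix]:
    """All-pixels TEM over the untreated frames with the fixed QC settings."""
    if n_untreated_frames < 1:
        raise ValueError("need at least one untreated frame for QC")
    short = [w for w, frames in datastore.items() if len(frames) < n_untreated_frames]
    if short:
        raise ValueError(f"wells without enough untreated frames: {sorted(short)}")
    return extract_plate_tem(
        datastore,
        schedule=qc_schedule(),
        mask_mode="all_pixels",
        frame_range=(0, n_untreated_frames),
        workers=workers,
        value_range=value_range,
    )


@dataclass
class QCReport:
    """Per-well deviation norms, the outlier threshold and the flag set."""

    wells: list[str]
    l1_norms: dict[str, float]
    percentile_value: float
    threshold: float
    flagged: set[str]

    def kept(self) -> list[str]:
        return [w for w in self.wells if w not in self.flagged]


def detect_outliers(
    tems: Mapping[str, TEMMatrix],
    multiplier: float = QC_THRESHOLD_MULTIPLIER,
    percentile: float = QC_PERCENTILE,
) -> QCReport:
    """Flag wells whose untreated-feature deviation is extreme.

    The percentile of the L1 pool uses linear interpolation between order
    statistics.  When the percentile is exactly 0 (all wells identical)
    nothing is flagged — otherwise the ≥ comparison would flag every well.
    The global average h̄ includes eventual outliers, which are unknown at
    this point.
    """
    wells = sorted(tems)
    if len(wells) < 2:
        raise ValueError("outlier detection needs at least two wells")
    hbar_w = np.stack([tems[w].values.mean(axis=1) for w in wells])
    hbar = hbar_w.mean(axis=0)
    l1 = np.abs(hbar_w - hbar).sum(axis=1)
    p = float(np.percentile(l1, percentile))
    threshold = multiplier * p
    if p == 0:
        flagged: set[str] = set()
    else:
        flagged = {w for w, v in zip(wells, l1) if v >= threshold}
    return QCReport(
        wells=wells,
        l1_norms={w: float(v) for w, v in zip(wells, l1)},
        percentile_value=p,
        threshold=threshold,
        flagged=flagged,
    )
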