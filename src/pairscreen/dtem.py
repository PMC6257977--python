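"""Deviations of treated morphology trajectories from untreated controls.

The deviation of a well's time-evolving morphologies (TEM) from the control
behaviour (DTEM) is the element-wise difference of its feature matrix from
the average control matrix.  Controls themselves are evaluated leave-one-out
(each control compared against the mean of the other N_c − 1), so their L1
magnitudes form an empirical null distribution Δ_c of morphological change
observed without treatment.  The null threshold τ is a percentile of Δ_c
(default the 95th, fixing the false-alarm probability at 5%); the relative
difference

    d̃(w) = ‖ΔH(w)‖₁ / τ − 1

is zero at the threshold, and wells with d̃ > 0 are detections.  N_D counts
them; the sum of positive d̃ values is exported separately as a detection
strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .features import TEMMatrix

__all__ = [
    "DTEMRecord",
    "NullPool",
    "DetectionTable",
    "control_dtem",
    "treated_dtem",
    "null_threshold",
    "relative_difference",
    "count_detections",
    "detection_strength",
    "dtem_table",
    "DEFAULT_NULL_PERCENTILE",
]

DEFAULT_NULL_PERCENTILE = 95.0


@dataclass
class DTEMRecord:
    """Deviation matrix of one well and its scalar summaries."""

    well: str
    role: str  # control | treated
    delta: np.ndarray  # K × T
    l1: float
    d_tilde: float | None = None

    @property
    def detected(self) -> bool:
        return self.d_tilde is not None and self.d_tilde > 0


def _control_matrix(controls: Mapping[str, TEMMatrix]) -> tuple[list[str], np.ndarray]:
    wells = sorted(controls)
    mats = np.stack([controls[w].values for w in wells])
    return wells, mats


def control_dtem(controls: Mapping[str, TEMMatrix]) -> list[DTEMRecord]:
    """Leave-one-out deviations of every control from the other controls.

    ΔH(c) = H(c) − mean of the remaining N_c − 1 control matrices.  By
    construction the records sum to the zero matrix.
    """
    wells, mats = _control_matrix(controls)
    n = len(wells)
    if n < 2:
        raise ValueError("leave-one-out control deviations need at least 2 controls")
    total = mats.sum(axis=0)
    records = []
    for i, w in enumerate(wells):
        others_mean = (total - mats[i]) / (n - 1)
        delta = mats[i] - others_mean
        records.append(
            DTEMRecord(well=w, role="control", delta=delta, l1=float(np.abs(delta).sum()))
        )
    return records


def treated_dtem(treated: TEMMatrix, controls: Mapping[str, TEMMatrix]) -> DTEMRecord:
    """Deviation of a treated well from the mean of *all* controls."""
    if not controls:
        raise ValueError("no control wells available")
    _, mats = _control_matrix(controls)
    delta = treated.values - mats.mean(axis=0)
    return DTEMRecord(
        well=treated.well, role="treated", delta=delta, l1=float(np.abs(delta).sum())
    )


@dataclass(frozen=True)
class NullPool:
    """Control L1 magnitudes and the percentile threshold derived from them."""

    magnitudes: tuple[float, ...]
    percentile: float
    tau: float


def null_threshold(
    magnitudes: Iterable[float], percentile: float = DEFAULT_NULL_PERCENTILE
) -> NullPool:
    """Percentile (linear interpolation) of the control magnitude pool."""
    mags = tuple(float(m) for m in magnitudes)
    if not mags:
        raise ValueError("empty null pool")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    tau = float(np.percentile(mags, percentile))
    return NullPool(magnitudes=mags, percentile=percentile, tau=tau)


def relative_difference(l1: float, tau: float) -> float:
    """Relative distance of a magnitude from the null threshold: l1/τ − 1."""
    if tau <= 0:
        raise ValueError("degenerate null threshold (τ ≤ 0)")
    return l1 / tau - 1.0


def count_detections(d_tildes: Iterable[float]) -> int:
    """Number of wells with strictly positive relative difference."""
    return int(sum(1 for d in d_tildes if d > 0))


def detection_strength(d_tildes: Iterable[float]) -> float:
    """Sum of the positive relative differences (a graded companion to N_D)."""
    return float(sum(d for d in d_tildes if d > 0))


@dataclass
class DetectionTable:
    """All DTEM records of one plate/run with the shared null threshold."""

    records: list[DTEMRecord]
    pool: NullPool
    degenerate_null: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_detections(self) -> int:
        return count_detections(
            r.d_tilde for r in self.records if r.role == "treated" and r.d_tilde is not None
        )

    @property
    def strength(self) -> float:
        return detection_strength(
            r.d_tilde for r in self.records if r.role == "treated" and r.d_tilde is not None
        )

    def control_false_alarm_fraction(self) -> float:
        ctl = [r for r in self.records if r.role == "control"]
        if not ctl:
            return float("nan")
        return count_detections(r.d_tilde for r in ctl) / len(ctl)

    def by_well(self) -> dict[str, DTEMRecord]:
        return {r.well: r for r in self.records}


def dtem_table(
    tems: Mapping[str, TEMMatrix],
    roles: Mapping[str, str],
    percentile: float = DEFAULT_NULL_PERCENTILE,
) -> DetectionTable:
    """Full DTEM analysis of one plate (one parameter setting, one window).

    ``roles`` maps well → role; wells with role ``growth_control`` (or
    ``control``) build the null pool, every other well present in ``tems``
    is scored as treated.  With a degenerate null (τ = 0, all controls
    identical) treated wells with positive magnitude get d̃ = +inf rather
    than aborting; the table is flagged ``degenerate_null``.
    """
    controls = {
        w: t for w, t in tems.items() if roles.get(w) in ("growth_control", "control")
    }
    records = control_dtem(controls)
    for w in sorted(tems):
        if w in controls:
            continue
        records.append(treated_dtem(tems[w], controls))
    pool = null_threshold((r.l1 for r in records if r.role == "control"), percentile)
    degenerate = pool.tau <= 0
    for r in records:
        if degenerate:
            r.d_tilde = float("inf") if r.l1 > 0 else 0.0
        else:
            r.d_tilde = relative_difference(r.l1, pool.tau)
    return DetectionTable(records=records, pool=pool, degenerate_null=degenerate)
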