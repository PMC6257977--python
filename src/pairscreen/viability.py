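"""End-point viability and synergy analysis of checkerboard plates.

From a plate-reader fluorescence file (fluorometric cytotoxicity assay) the
survival index of each treated well is computed relative to the medians of
the blank and growth-control wells:

    S(c1, c2) = (f(c1, c2) − f̃_blank) / (f̃_control − f̃_blank)

Replicate patches are merged under the standard-deviation exclusion rule,
then pairwise combination effects are scored per patch:

* Bliss index              B    = 100·(s1·s2 − s12)   (positive = synergy)
* scaled Bliss index       B_S  = B·(1 − s12)
* therapeutic index        T    = 100·(s_ref − s_target)
* refined therapeutic      T_RW = T·s_ref

where s1, s2 are the single-drug survivals at the patch's doses and s12 the
combination survival.  The therapeutic indices need a second (reference /
toxicity) cell-model plate sharing the layout; a positive T means the
reference cells survive the combination better than the target cells.  The
refinement weights are configurable and recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .plate import DEFAULT_SD_THRESHOLD, LayoutError, PlateLayout, merge_replicates

__all__ = [
    "survival_index",
    "bliss_index",
    "therapeutic_index",
    "refine_index",
    "survival_table",
    "SurvivalMatrix",
    "SynergyResult",
    "run_viability",
]


def survival_index(f: float, blank_median: float, control_median: float) -> float:
    """Survival fraction of one well relative to blank/control medians."""
    denom = control_median - blank_median
    if denom == 0:
        raise ValueError(
            "degenerate assay: control and blank medians coincide"
        )
    return (f - blank_median) / denom


def bliss_index(s1: float, s2: float, s12: float) -> float:
    """Bliss-independence deviation in percent.

    Positive when the observed combination survival ``s12`` is below the
    independent expectation ``s1*s2`` (more killing than independence,
    i.e. synergy); negative for antagonism.
    """
    return 100.0 * (s1 * s2 - s12)


def therapeutic_index(s_target: float, s_reference: float) -> float:
    """Therapeutic window in percent: reference minus target survival."""
    return 100.0 * (s_reference - s_target)


def refine_index(index: float, weight: float) -> float:
    """Down-weight an index for ranking; ``weight`` must be in [0, 1]."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"refinement weight {weight} outside [0, 1]")
    return index * weight


# default refinement weights; both take the merged survival fractions
def _bliss_weight(s1: float, s2: float, s12: float) -> float:
    return float(np.clip(1.0 - s12, 0.0, 1.0))


def _therapeutic_weight(s_target: float, s_reference: float) -> float:
    return float(np.clip(s_reference, 0.0, 1.0))


@dataclass
class SurvivalMatrix:
    """Merged survival fractions of one drug pair on the full dose grid.

    Rows follow drug-1 concentrations, columns drug-2 concentrations, both
    ascending and including the zero dose, so ``values[0, 0]`` is the
    untreated control survival.  ``excluded`` marks patches removed by the
    replicate-SD rule (or never measured); their values are NaN.  ``sd``
    holds the replicate standard deviations in percentage points.
    """

    pair: tuple[str, str]
    conc1: list[float]
    conc2: list[float]
    values: np.ndarray  # fractions, NaN where excluded/missing
    sd: np.ndarray
    excluded: np.ndarray  # bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.conc1, columns=self.conc2)


@dataclass
class SynergyResult:
    """All per-pair survival and synergy matrices of one analysis run."""

    survival: dict[tuple[str, str], SurvivalMatrix]
    bliss: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    bliss_scaled: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    therapeutic: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    therapeutic_rw: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    reference_survival: dict[tuple[str, str], SurvivalMatrix] | None = None
    metadata: dict = field(default_factory=dict)


def survival_table(
    fluorescence: Mapping[str, float],
    layout: PlateLayout,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> dict[tuple[str, str], SurvivalMatrix]:
    """Survival matrices for every drug pair of one reader plate.

    Replicates are merged per concentration patch; the SD filter operates in
    percentage points of survival index.  The (0, 0) corner is the merged
    survival of the growth-control wells (≈1 by construction).
    """
    layout.require_controls(blanks=True)
    blanks = [fluorescence[w] for w in layout.blank_wells if w in fluorescence]
    controls = [fluorescence[w] for w in layout.control_wells if w in fluorescence]
    if not blanks or not controls:
        raise LayoutError("reader plate missing blank or control measurements")
    f_blank = float(np.median(blanks))
    f_control = float(np.median(controls))

    def _s(well: str) -> float:
        return survival_index(fluorescence[well], f_blank, f_control)

    # merge per patch, working in percent for the SD rule
    merged: dict[tuple, tuple[float | None, float, bool]] = {}
    for patch, wells in layout.replicate_groups().items():
        vals = [100.0 * _s(w) for w in wells if w in fluorescence]
        if not vals:
            continue
        res = merge_replicates(vals, threshold=sd_threshold)
        merged[patch] = (
            None if res.merged_value is None else res.merged_value / 100.0,
            res.sd,
            res.excluded,
        )
    ctrl = merge_replicates([100.0 * _s(w) for w in layout.control_wells], sd_threshold)
    ctrl_entry = (
        None if ctrl.merged_value is None else ctrl.merged_value / 100.0,
        ctrl.sd,
        ctrl.excluded,
    )

    out: dict[tuple[str, str], SurvivalMatrix] = {}
    for pair in layout.drug_pairs:
        c1, c2 = layout.conc_grid(pair)
        n1, n2 = len(c1), len(c2)
        values = np.full((n1, n2), np.nan)
        sd = np.full((n1, n2), np.nan)
        excl = np.ones((n1, n2), dtype=bool)
        for i, a in enumerate(c1):
            for j, b in enumerate(c2):
                if i == 0 and j == 0:
                    entry = ctrl_entry
                else:
                    entry = merged.get((pair, a, b))
                if entry is None:
                    continue
                value, s_dev, ex = entry
                sd[i, j] = s_dev
                excl[i, j] = ex
                if not ex:
                    values[i, j] = value
        out[pair] = SurvivalMatrix(
            pair=pair, conc1=c1, conc2=c2, values=values, sd=sd, excluded=excl
        )
    return out


def _synergy_grids(
    surv: SurvivalMatrix,
    bliss_weight: Callable[[float, float, float], float],
) -> tuple[np.ndarray, np.ndarray]:
    """Bliss and scaled-Bliss grids; NaN where any needed patch is excluded."""
    v = surv.values
    n1, n2 = v.shape
    b = np.full((n1, n2), np.nan)
    bs = np.full((n1, n2), np.nan)
    for i in range(n1):
        for j in range(n2):
            s1, s2, s12 = v[i, 0], v[0, j], v[i, j]
            if np.isnan(s1) or np.isnan(s2) or np.isnan(s12):
                continue
            b[i, j] = bliss_index(s1, s2, s12)
            bs[i, j] = refine_index(b[i, j], bliss_weight(s1, s2, s12))
    return b, bs


def run_viability(
    fluorescence: Mapping[str, float],
    layout: PlateLayout,
    reference_fluorescence: Mapping[str, float] | None = None,
    reference_layout: PlateLayout | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    bliss_weight: Callable[[float, float, float], float] = _bliss_weight,
    therapeutic_weight: Callable[[float, float], float] = _therapeutic_weight,
) -> SynergyResult:
    """Full viability/synergy analysis of one target plate.

    Bliss indices are always computed; therapeutic indices only when a
    reference (toxicity) plate is supplied.  The reference plate must share
    the target plate's layout (same pairs and dose grids).
    """
    survival = survival_table(fluorescence, layout, sd_threshold)
    result = SynergyResult(
        survival=survival,
        metadata={
            "sd_threshold_percent": sd_threshold,
            "bliss_scaled_weight": "1 - s12",
            "therapeutic_refined_weight": "s_reference",
        },
    )
    for pair, surv in survival.items():
        b, bs = _synergy_grids(surv, bliss_weight)
        result.bliss[pair] = b
        result.bliss_scaled[pair] = bs

    if reference_fluorescence is not None:
        ref_layout = reference_layout or layout
        ref = survival_table(reference_fluorescence, ref_layout, sd_threshold)
        result.reference_survival = ref
        for pair, surv in survival.items():
            if pair not in ref:
                raise LayoutError(f"reference plate lacks drug pair {pair}")
            rsurv = ref[pair]
            if rsurv.conc1 != surv.conc1 or rsurv.conc2 != surv.conc2:
                raise LayoutError(
                    f"reference concentration grid differs for pair {pair}"
                )
            t = np.full_like(surv.values, np.nan)
            trw = np.full_like(surv.values, np.nan)
            ok = ~np.isnan(surv.values) & ~np.isnan(rsurv.values)
            for i, j in zip(*np.nonzero(ok)):
                t[i, j] = therapeutic_index(surv.values[i, j], rsurv.values[i, j])
                trw[i, j] = refine_index(
                    t[i, j],
                    therapeutic_weight(surv.values[i, j], rsurv.values[i, j]),
                )
            result.therapeutic[pair] = t
            result.therapeutic_rw[pair] = trw
    return result
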