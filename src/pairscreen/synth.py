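"""Synthetic image datastores, reader plates and layouts with known truth.

The generator emulates the statistics the pipeline actually measures in
label-free phase-contrast movies of microtiter wells:

* a near-constant background band: intensity μ plus small clipped Gaussian
  noise, guaranteed to stay inside the background interval τ so truth masks
  are exact;
* elliptical cell-like blobs whose *count trajectory* sets confluence and
  growth/death dynamics, and whose *pixel-intensity distribution* sets
  morphology — a two-mode mixture whose mixing weight is the morphology
  parameter, so a treatment-induced morphology shift is a change in exactly
  the quantity the histogram features measure, at constant confluence;
* optional planted pathologies: a pure-noise outlier well (for QC) and a
  runaway-growth "contamination" well.

Everything is driven by a single integer seed; per-well generators are
spawned from (seed, well index) so output is byte-identical for a given
seed regardless of generation order.  Ground-truth masks and area fractions
are recorded alongside the frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .plate import PLATE_GEOMETRIES, PlateLayout, WellAddress, WellEntry, write_specification

__all__ = [
    "SynthSpec",
    "WellRecipe",
    "SynthPlate",
    "synth_movie",
    "synth_plate",
    "write_plate",
    "demo_layout",
    "synth_reader_plate",
]


@dataclass(frozen=True)
class SynthSpec:
    """Global generation parameters shared by all wells of a plate.

    Defaults mirror the acquisition they emulate — 15 frames per well of
    which the first 2 are untreated — at desk-scale frame size.  Background
    noise is clipped to ±4 around μ = 100, well inside the default ±5%
    interval [95, 105]; blob intensities are clipped to [118, 250], well
    outside it.
    """

    shape: tuple[int, int] = (64, 80)
    n_frames: int = 15
    n_untreated: int = 2
    background: float = 100.0
    noise_sd: float = 1.5
    noise_clip: float = 4.0
    low_mode: float = 160.0
    high_mode: float = 220.0
    blob_sd: float = 8.0
    blob_intensity_clip: tuple[float, float] = (118.0, 250.0)
    blob_radius: tuple[int, int] = (3, 7)
    seed: int = 0

    def validate(self, tau: tuple[float, float] | None = None) -> None:
        tau = tau or (0.95 * self.background, 1.05 * self.background)
        lo, hi = self.blob_intensity_clip
        if tau[0] <= lo <= tau[1] or tau[0] <= hi <= tau[1]:
            raise ValueError(
                "blob intensity range overlaps the background interval; "
                "segmentation would be untestable"
            )
        if self.background - self.noise_clip < tau[0] or self.background + self.noise_clip > tau[1]:
            raise ValueError("background noise exceeds the background interval")


@dataclass(frozen=True)
class WellRecipe:
    """Per-well ground truth: growth dynamics and morphology.

    ``blob_count`` is the count at the first frame; counts at frame i are
    ``round(blob_count · growth**i)`` (growth > 1 grows, < 1 dies).
    ``morphology`` in [0, 1] is the mixture weight of the high intensity
    mode; shifting it changes the foreground histogram at constant blob
    count.  ``morphology_onset`` delays the shift: frames before that index
    use ``baseline_morphology`` (late-acting treatments).  ``outlier``
    replaces the movie by pure uniform noise.
    """

    blob_count: int = 12
    growth: float = 1.0
    morphology: float = 0.25
    baseline_morphology: float = 0.25
    morphology_onset: int = 0
    outlier: bool = False

    def morphology_at(self, frame_index: int) -> float:
        return self.morphology if frame_index >= self.morphology_onset else self.baseline_morphology


def _blob_params(spec: SynthSpec, rng: np.random.Generator, n: int):
    h, w = spec.shape
    cy = rng.uniform(0, h, size=n)
    cx = rng.uniform(0, w, size=n)
    ry = rng.integers(spec.blob_radius[0], spec.blob_radius[1] + 1, size=n)
    rx = rng.integers(spec.blob_radius[0], spec.blob_radius[1] + 1, size=n)
    return cy, cx, ry, rx


def synth_movie(
    spec: SynthSpec, recipe: WellRecipe, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray], list[float]]:
    """One well's movie: (frames uint8, truth masks, truth area fractions).

    Blobs persist across frames (frame i shows the first count(i) blobs of a
    per-well pool), so growth adds blobs and death removes the most recent
    ones.
    """
    spec.validate()
    h, w = spec.shape
    counts = [
        max(0, round(recipe.blob_count * recipe.growth**i))
        for i in range(spec.n_frames)
    ]
    max_count = max(counts) if counts else 0
    cy, cx, ry, rx = _blob_params(spec, rng, max_count)
    yy, xx = np.mgrid[0:h, 0:w]

    frames, masks, fractions = [], [], []
    for i in range(spec.n_frames):
        noise = np.clip(
            rng.normal(0.0, spec.noise_sd, size=(h, w)),
            -spec.noise_clip,
            spec.noise_clip,
        )
        frame = spec.background + noise
        mask = np.zeros((h, w), dtype=bool)
        for j in range(counts[i]):
            blob = ((yy - cy[j]) / ry[j]) ** 2 + ((xx - cx[j]) / rx[j]) ** 2 <= 1.0
            mask |= blob
        n_fg = int(mask.sum())
        if n_fg:
            high = rng.random(n_fg) < recipe.morphology_at(i)
            modes = np.where(high, spec.high_mode, spec.low_mode)
            vals = rng.normal(modes, spec.blob_sd)
            frame[mask] = np.clip(vals, *spec.blob_intensity_clip)
        if recipe.outlier:
            frame = rng.integers(0, 256, size=(h, w)).astype(float)
        frames.append(np.clip(np.round(frame), 0, 255).astype(np.uint8))
        masks.append(mask)
        fractions.append(n_fg / (h * w))
    return frames, masks, fractions


@dataclass
class SynthPlate:
    """In-memory synthetic plate: frames plus recorded ground truth."""

    spec: SynthSpec
    datastore: dict[str, list[np.ndarray]]
    truth_masks: dict[str, list[np.ndarray]] = field(repr=False, default_factory=dict)
    truth_fractions: dict[str, list[float]] = field(default_factory=dict)
    recipes: dict[str, WellRecipe] = field(default_factory=dict)
    layout: PlateLayout | None = None


def synth_plate(
    spec: SynthSpec,
    recipes: Mapping[str, WellRecipe],
    layout: PlateLayout | None = None,
) -> SynthPlate:
    """Generate a full plate from per-well recipes (keyed by well id)."""
    plate = SynthPlate(spec=spec, datastore={}, layout=layout)
    for idx, well in enumerate(sorted(recipes)):
        rng = np.random.default_rng([spec.seed, idx])
        frames, masks, fractions = synth_movie(spec, recipes[well], rng)
        plate.datastore[well] = frames
        plate.truth_masks[well] = masks
        plate.truth_fractions[well] = fractions
        plate.recipes[well] = recipes[well]
    return plate


def write_plate(plate: SynthPlate, out_dir: str | Path) -> None:
    """Write a plate to disk: <WELL>_<T>.tif frames, truth JSON, spec CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for well, frames in plate.datastore.items():
        for t, frame in enumerate(frames):
            tifffile.imwrite(out / f"{well}_{t:02d}.tif", frame)
    truth = {
        "seed": plate.spec.seed,
        "n_untreated": plate.spec.n_untreated,
        "fractions": plate.truth_fractions,
        "recipes": {
            w: {
                "blob_count": r.blob_count,
                "growth": r.growth,
                "morphology": r.morphology,
                "outlier": r.outlier,
            }
            for w, r in plate.recipes.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    if plate.layout is not None:
        write_specification(plate.layout, out / "plate_spec.csv")


# ---------------------------------------------------------------------------
# layouts and reader plates


def demo_layout(
    n_pairs: int = 8,
    n_conc: int = 6,
    n_replicates: int = 1,
    plate_format: int = 384,
    n_blanks: int = 8,
    n_extra_controls: int = 4,
) -> PlateLayout:
    """A checkerboard layout: every pair gets an n×n dose grid (zero doses
    included); the (0, 0) patch of each pair is a growth-control well, and
    ``n_extra_controls`` additional growth controls follow the pair blocks
    (leave-one-out null estimation needs several controls).

    Wells are assigned row-major.  Concentrations are a doubling series
    starting at 0.125 (arbitrary units).
    """
    n_rows, n_cols = PLATE_GEOMETRIES[plate_format]
    all_wells = [
        WellAddress(row=r, column=c + 1).id for r in range(n_rows) for c in range(n_cols)
    ]
    concs = [0.0] + [0.125 * 2**i for i in range(n_conc - 1)]
    entries: dict[str, WellEntry] = {}
    cursor = 0

    def take() -> str:
        nonlocal cursor
        if cursor >= len(all_wells):
            raise ValueError("layout does not fit the plate format")
        w = all_wells[cursor]
        cursor += 1
        return w

    for p in range(n_pairs):
        d1, d2 = f"drugA{p + 1}", f"drugB{p + 1}"
        for c1 in concs:
            for c2 in concs:
                for rep in range(n_replicates):
                    w = take()
                    if c1 == 0.0 and c2 == 0.0:
                        entries[w] = WellEntry(
                            well=w, role="growth_control", replicate=f"ctrl-{p + 1}-{rep + 1}"
                        )
                    else:
                        entries[w] = WellEntry(
                            well=w,
                            role="treated",
                            drug1=d1,
                            conc1=c1,
                            drug2=d2,
                            conc2=c2,
                            replicate=f"{d1}-{d2}-{c1}-{c2}",
                        )
    for k in range(n_extra_controls):
        w = take()
        entries[w] = WellEntry(well=w, role="growth_control", replicate=f"ctrl-extra-{k + 1}")
    for _ in range(n_blanks):
        w = take()
        entries[w] = WellEntry(well=w, role="blank")
    return PlateLayout(plate_format=plate_format, wells=entries)


def synth_reader_plate(
    layout: PlateLayout,
    truth_s: Mapping[tuple[str, str], np.ndarray],
    blank_signal: float = 200.0,
    control_signal: float = 20000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Fluorescence values implementing a known survival surface.

    ``truth_s`` gives, per drug pair, the survival fractions on the pair's
    sorted (zero-inclusive) dose grid; the signal of a treated well is
    ``blank + S·(control − blank)`` plus optional Gaussian noise, so with
    zero noise the viability analysis recovers the surface exactly.
    """
    rng = rng or np.random.default_rng(0)
    span = control_signal - blank_signal
    fluor: dict[str, float] = {}
    grids = {pair: layout.conc_grid(pair) for pair in layout.drug_pairs}
    for well, entry in layout.wells.items():
        if entry.role == "blank":
            f = blank_signal
        elif entry.role == "growth_control":
            f = control_signal
        else:
            pair = entry.pair
            c1, c2 = grids[pair]
            i = c1.index(float(entry.conc1 or 0.0))
            j = c2.index(float(entry.conc2 or 0.0))
            f = blank_signal + float(truth_s[pair][i, j]) * span
        if noise_sd > 0:
            f += rng.normal(0.0, noise_sd)
        fluor[well] = float(f)
    return fluor


def shifted_recipe(base: WellRecipe, morphology_shift: float) -> WellRecipe:
    """A treated-well recipe whose morphology mixture is shifted by a delta."""
    return replace(base, morphology=float(np.clip(base.morphology + morphology_shift, 0.0, 1.0)))
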