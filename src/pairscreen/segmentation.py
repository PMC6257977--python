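"""Global background-interval estimation and foreground segmentation.

Label-free phase-contrast frames of sparsely seeded wells are dominated by a
near-constant background.  The background intensity is estimated from the
first (untreated) frames of every well: the per-well median pixel μ_w forms
a pool P_b whose median μ_b is the global background level.  A multiplicative
deviation δ (default 0.05) turns it into the interval

    τ = [τ_l, τ_h] = [(1 − δ)·μ_b, (1 + δ)·μ_b]

and a pixel is foreground iff its value falls outside τ (boundary values
count as background).  The interval is global — a single threshold pair for
the whole image library — which keeps segmentation trivially deterministic
and scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["BackgroundModel", "estimate_background", "segment", "DEFAULT_DEVIATION"]

DEFAULT_DEVIATION = 0.05


@dataclass(frozen=True)
class BackgroundModel:
    """Global background intensity interval shared by all wells."""

    pool: tuple[float, ...]  # per-well median intensities μ_w
    mu_b: float
    deviation: float

    @property
    def tau(self) -> tuple[float, float]:
        return ((1.0 - self.deviation) * self.mu_b, (1.0 + self.deviation) * self.mu_b)

    @property
    def tau_low(self) -> float:
        return self.tau[0]

    @property
    def tau_high(self) -> float:
        return self.tau[1]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mu_b": self.mu_b,
                    "deviation": self.deviation,
                    "tau": list(self.tau),
                    "pool": list(self.pool),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(pool=tuple(doc["pool"]), mu_b=doc["mu_b"], deviation=doc["deviation"])


def estimate_background(
    datastore: Mapping[str, Sequence[np.ndarray]],
    n_untreated_frames: int = 2,
    deviation: float = DEFAULT_DEVIATION,
) -> BackgroundModel:
    """Estimate the background interval from the untreated frames.

    ``datastore`` maps well id → time-ordered frames.  All pixels of the
    first ``n_untreated_frames`` frames of each well are pooled and their
    median is that well's μ_w; μ_b is the median over wells.

    δ = 0 is accepted as the limit case where only exact-μ_b pixels are
    background.
    """
    if not datastore:
        raise ValueError("empty datastore")
    if deviation < 0:
        raise ValueError("deviation must be non-negative")
    if n_untreated_frames < 1:
        raise ValueError("need at least one untreated frame")
    pool = []
    for well in sorted(datastore):
        frames = datastore[well]
        if len(frames) < n_untreated_frames:
            raise ValueError(
                f"well {well} has {len(frames)} frames, "
                f"fewer than the {n_untreated_frames} untreated frames"
            )
        pixels = np.concatenate(
            [np.asarray(f).ravel() for f in frames[:n_untreated_frames]]
        )
        pool.append(float(np.median(pixels)))
    mu_b = float(np.median(pool))
    return BackgroundModel(pool=tuple(pool), mu_b=mu_b, deviation=deviation)


def segment(frame: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Binary foreground mask: 1 where the pixel value lies outside τ."""
    frame = np.asarray(frame)
    lo, hi = model.tau
    return (frame < lo) | (frame > hi)
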