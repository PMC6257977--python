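"""Image datastore reading: well/time-indexed grayscale frame files."""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["DEFAULT_PATTERN", "read_datastore", "read_reader_csv"]

#: default filename convention <WELL>_<T>.tif (or .png), e.g. "B07_03.tif"
DEFAULT_PATTERN = r"^(?P<well>[A-Za-z]+\d{2})_(?P<time>\d+)\.(?P<ext>tiff?|png)$"


def _load(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            frame = tifffile.imread(path)
        else:
            frame = iio.imread(path)
    except Exception as exc:  # pragma: no cover - IO failure path
        raise IOError(f"unreadable image {path}: {exc}") from exc
    frame = np.asarray(frame)
    if frame.ndim == 3 and frame.shape[2] == 1:
        frame = frame[:, :, 0]
    if frame.ndim != 2:
        raise IOError(f"{path} is not a grayscale image (shape {frame.shape})")
    return frame


def read_datastore(
    root: str | Path, pattern: str = DEFAULT_PATTERN
) -> dict[str, list[np.ndarray]]:
    """Read a directory of per-well frames into well → time-ordered movies.

    Files not matching the pattern are skipped with a warning.  Each well's
    time indices must form a contiguous series starting at its minimum, and
    all wells must have the same frame count; a ragged datastore raises with
    the offending (well, time) positions.
    """
    root = Path(root)
    rx = re.compile(pattern)
    found: dict[str, dict[int, Path]] = {}
    for path in sorted(root.iterdir()):
        if not path.is_file():
            continue
        m = rx.match(path.name)
        if m is None:
            if path.suffix.lower() in (".tif", ".tiff", ".png"):
                warnings.warn(f"skipping unrecognised file {path.name}", stacklevel=2)
            continue
        well = m.group("well").upper()
        found.setdefault(well, {})[int(m.group("time"))] = path
    if not found:
        raise ValueError(f"no frames matching pattern in {root}")

    counts = {w: len(ts) for w, ts in found.items()}
    n = max(counts.values())
    missing = []
    for well, ts in found.items():
        t0 = min(ts)
        for k in range(n):
            if t0 + k not in ts:
                missing.append((well, t0 + k))
    if missing:
        raise ValueError(f"ragged datastore, missing frames: {sorted(missing)}")

    return {
        well: [_load(ts[t]) for t in sorted(ts)] for well, ts in sorted(found.items())
    }


def read_reader_csv(path: str | Path) -> dict[str, float]:
    """Read a plate-reader file: long-format CSV with columns well,value."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "well" not in cols or "value" not in cols:
        raise ValueError("reader CSV needs columns 'well' and 'value'")
    return {
        str(w).upper(): float(v)
        for w, v in zip(df[cols["well"]], df[cols["value"]])
    }
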