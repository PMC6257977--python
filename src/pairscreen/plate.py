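"""Checkerboard plate layouts, specification parsing and replicate merging.

A checkerboard experiment combines two drugs at all pairwise concentrations
(including the zero doses, i.e. the single-drug margins) on a microtiter
plate.  Wells are addressed ``<row letter><2-digit column>`` ("B07").  Each
well carries a role: ``treated`` (a concentration patch of some drug pair,
possibly with one or both doses zero), ``growth_control`` (untreated cells)
or ``blank`` (no cells).  Replicate wells of the same patch form a replicate
group whose survival values are merged unless their spread exceeds a
standard-deviation cut-off.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellAddress",
    "WellEntry",
    "PlateLayout",
    "ReplicateMergeResult",
    "LayoutError",
    "parse_specification",
    "merge_replicates",
    "PLATE_GEOMETRIES",
    "DEFAULT_SD_THRESHOLD",
]

#: rows × columns for the supported standard plate formats; other formats can
#: be registered by adding entries here.
PLATE_GEOMETRIES: dict[int, tuple[int, int]] = {
    6: (2, 3),
    12: (3, 4),
    24: (4, 6),
    48: (6, 8),
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
}

#: default replicate standard-deviation cut-off, in percentage points of
#: survival index: replicate groups with SD at or above this are excluded.
DEFAULT_SD_THRESHOLD = 30.0

_ROW_LETTERS = string.ascii_uppercase + "".join(
    a + b for a in "A" for b in string.ascii_uppercase
)  # A..Z, AA..AZ — covers 1536-well (32 rows)


class LayoutError(ValueError):
    """Raised when a plate specification is inconsistent or incomplete."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A plate position: 0-based row, 1-based column."""

    row: int
    column: int

    @property
    def id(self) -> str:
        return f"{_ROW_LETTERS[self.row]}{self.column:02d}"

    @classmethod
    def parse(cls, well_id: str) -> "WellAddress":
        well_id = well_id.strip().upper()
        i = 0
        while i < len(well_id) and well_id[i].isalpha():
            i += 1
        if i == 0 or i >= len(well_id) or not well_id[i:].isdigit():
            raise LayoutError(f"malformed well id {well_id!r}")
        row_part, col_part = well_id[:i], well_id[i:]
        try:
            row = _ROW_LETTERS.index(row_part)
        except ValueError:
            raise LayoutError(f"malformed well id {well_id!r}") from None
        return cls(row=row, column=int(col_part))

    def in_bounds(self, plate_format: int) -> bool:
        n_rows, n_cols = PLATE_GEOMETRIES[plate_format]
        return 0 <= self.row < n_rows and 1 <= self.column <= n_cols

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


@dataclass(frozen=True)
class WellEntry:
    """One well of a parsed specification."""

    well: str
    role: str  # treated | growth_control | blank
    drug1: str | None = None
    conc1: float | None = None
    drug2: str | None = None
    conc2: float | None = None
    replicate: str | None = None

    @property
    def pair(self) -> tuple[str, str] | None:
        if self.role != "treated":
            return None
        return (self.drug1 or "", self.drug2 or "")

    @property
    def patch(self) -> tuple[tuple[str, str], float, float] | None:
        """(drug pair, c1, c2) identifying the concentration patch."""
        if self.role != "treated":
            return None
        return (self.pair, float(self.conc1 or 0.0), float(self.conc2 or 0.0))


_ROLES = {"treated", "growth_control", "blank"}


@dataclass
class PlateLayout:
    """A validated checkerboard layout of one plate."""

    plate_format: int
    wells: dict[str, WellEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ---------------------------------------------------
    @property
    def drug_pairs(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        for e in self.wells.values():
            if e.pair is not None and e.pair not in seen:
                seen.append(e.pair)
        return seen

    @property
    def role_map(self) -> dict[str, str]:
        return {w: e.role for w, e in self.wells.items()}

    @property
    def replicate_map(self) -> dict[str, str | None]:
        return {w: e.replicate for w, e in self.wells.items()}

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, e in self.wells.items() if e.role == role)

    @property
    def treated_wells(self) -> list[str]:
        return self.wells_with_role("treated")

    @property
    def control_wells(self) -> list[str]:
        return self.wells_with_role("growth_control")

    @property
    def blank_wells(self) -> list[str]:
        return self.wells_with_role("blank")

    def conc_grid(self, pair: tuple[str, str]) -> tuple[list[float], list[float]]:
        """Sorted drug-1 / drug-2 concentrations of a pair, zero doses included."""
        c1 = {0.0}
        c2 = {0.0}
        for e in self.wells.values():
            if e.pair == tuple(pair):
                c1.add(float(e.conc1 or 0.0))
                c2.add(float(e.conc2 or 0.0))
        return sorted(c1), sorted(c2)

    def replicate_groups(self) -> dict[tuple, list[str]]:
        """Treated wells grouped by concentration patch (pair, c1, c2)."""
        groups: dict[tuple, list[str]] = {}
        for w in self.treated_wells:
            key = self.wells[w].patch
            groups.setdefault(key, []).append(w)
        return groups

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.plate_format not in PLATE_GEOMETRIES:
            raise LayoutError(
                f"unsupported plate format {self.plate_format}; "
                f"known formats: {sorted(PLATE_GEOMETRIES)}"
            )
        for w, e in self.wells.items():
            addr = WellAddress.parse(w)
            if addr.id != w:
                raise LayoutError(f"well id {w!r} is not canonical ({addr.id})")
            if not addr.in_bounds(self.plate_format):
                raise LayoutError(
                    f"well {w} outside the {self.plate_format}-well plate"
                )
            if e.role not in _ROLES:
                raise LayoutError(f"well {w}: unknown role {e.role!r}")
            if e.role == "treated" and (e.drug1 is None or e.drug2 is None):
                raise LayoutError(f"treated well {w} missing drug pair")
        # replicate groups must be homogeneous in (pair, c1, c2)
        by_rep: dict[tuple, set] = {}
        for w in self.treated_wells:
            e = self.wells[w]
            if e.replicate is not None:
                by_rep.setdefault((e.pair, e.replicate), set()).add(e.patch)
        for (pair, rep), patches in by_rep.items():
            if len(patches) > 1:
                raise LayoutError(
                    f"replicate group {rep!r} of pair {pair} mixes patches {patches}"
                )

    def require_controls(self, blanks: bool = True) -> None:
        """Raise unless growth controls (and optionally blanks) exist."""
        if not self.control_wells:
            raise LayoutError("layout has no growth-control wells")
        if blanks and not self.blank_wells:
            raise LayoutError("layout has no blank wells")


# ---------------------------------------------------------------------------
# specification parsing

_CSV_COLUMNS = ["well", "drug1", "conc1", "drug2", "conc2", "role", "replicate"]


def _entries_from_records(records: Iterable[Mapping]) -> dict[str, WellEntry]:
    wells: dict[str, WellEntry] = {}
    for rec in records:
        well = WellAddress.parse(str(rec["well"])).id
        if well in wells:
            raise LayoutError(f"well {well} assigned more than once")

        def _get(key):
            v = rec.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return v

        role = str(_get("role") or "treated")
        entry = WellEntry(
            well=well,
            role=role,
            drug1=(str(_get("drug1")) if _get("drug1") is not None else None),
            conc1=(float(_get("conc1")) if _get("conc1") is not None else None),
            drug2=(str(_get("drug2")) if _get("drug2") is not None else None),
            conc2=(float(_get("conc2")) if _get("conc2") is not None else None),
            replicate=(str(_get("replicate")) if _get("replicate") is not None else None),
        )
        wells[well] = entry
    return wells


def parse_specification(path: str | Path, fmt: str | None = None) -> PlateLayout:
    """Parse a plate specification file (CSV or JSON) into a :class:`PlateLayout`.

    CSV dialect: columns ``well,drug1,conc1,drug2,conc2,role,replicate`` plus an
    optional ``# plate_format: N`` comment header (default 384).  JSON dialect:
    ``{"plate_format": N, "wells": [{...}, ...]}`` with the same keys.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        plate_format = int(doc.get("plate_format", 384))
        wells = _entries_from_records(doc["wells"])
    elif fmt == "csv":
        plate_format = 384
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "plate_format" in line:
                        plate_format = int(line.split(":", 1)[1])
                else:
                    break
        df = pd.read_csv(path, comment="#")
        missing = set(_CSV_COLUMNS[:1]) - set(df.columns)
        if missing:
            raise LayoutError(f"specification missing columns: {sorted(missing)}")
        wells = _entries_from_records(df.to_dict("records"))
    else:
        raise ValueError(f"unknown specification format {fmt!r}")
    return PlateLayout(plate_format=plate_format, wells=wells)


def write_specification(layout: PlateLayout, path: str | Path) -> None:
    """Write a layout back to the canonical CSV dialect."""
    rows = []
    for w in sorted(layout.wells):
        e = layout.wells[w]
        rows.append(
            {
                "well": w,
                "drug1": e.drug1 or "",
                "conc1": "" if e.conc1 is None else e.conc1,
                "drug2": e.drug2 or "",
                "conc2": "" if e.conc2 is None else e.conc2,
                "role": e.role,
                "replicate": e.replicate or "",
            }
        )
    with open(path, "w") as fh:
        fh.write(f"# plate_format: {layout.plate_format}\n")
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# replicate merging


@dataclass(frozen=True)
class ReplicateMergeResult:
    """Outcome of merging intra-plate replicate values.

    ``sd`` is the sample standard deviation (n−1 denominator) in the units of
    the input values; ``merged_value`` is defined only when not excluded.
    """

    merged_value: float | None
    sd: float
    excluded: bool
    n: int


def merge_replicates(
    values: Sequence[float], threshold: float = DEFAULT_SD_THRESHOLD
) -> ReplicateMergeResult:
    """Merge replicate measurements, excluding over-dispersed groups.

    Values whose sample standard deviation is *smaller than* ``threshold``
    (same units as the values; percentage points of survival index in the
    viability workflow) are kept and averaged; groups at or above the
    threshold are excluded.  Singletons have SD 0 and are always kept.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot merge an empty replicate group")
    if threshold <= 0:
        raise ValueError("SD threshold must be positive")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    excluded = sd >= threshold
    merged = None if excluded else float(np.mean(vals))
    return ReplicateMergeResult(merged_value=merged, sd=sd, excluded=excluded, n=vals.size)
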