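"""Data model and I/O for 384-well screening plates.

The canonical on-disk form is long format: one row per well per read, with
columns ``plate_id, read, well, role, compound_id, rlu, viability``.  Role
vocabulary on disk is ``M0, M1_DMSO, M1_TSA, COMPOUND, EMPTY``; well
addresses are row letter + column number (``A1`` .. ``P24``), accepted
case-insensitively and canonicalized to upper case.  Numeric cells may carry
thousands-separator commas (``12,432.0``); the decimal separator is the dot.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
import re
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: default plate geometry (384-well): rows A..P, columns 1..24
N_ROWS = 16
N_COLS = 24

_ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_WELL_RE = re.compile(r"^([A-Za-z]+)0*([0-9]+)$")


class WellRole(enum.Enum):
    """Role of a well on a screening plate.

    M0 wells are non-polarized background controls, M1_SOLVENT wells are the
    stimulated vehicle (DMSO) baseline that defines hit thresholds, M1_TSA
    wells are the stimulated positive control, COMPOUND wells carry one test
    compound each.
    """

    M0_CONTROL = "M0"
    M1_SOLVENT = "M1_DMSO"
    M1_TSA = "M1_TSA"
    COMPOUND = "COMPOUND"
    EMPTY = "EMPTY"

    @classmethod
    def from_label(cls, label: str) -> "WellRole":
        try:
            return cls(str(label).strip().upper())
        except ValueError:
            raise FormatError(
                f"unknown well role {label!r}; expected one of "
                f"{[r.value for r in cls]}"
            ) from None


@dataclasses.dataclass(frozen=True, order=True)
class WellAddress:
    """A well position on a rectangular plate, e.g. ``A1`` or ``P24``."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if len(self.row) != 1 or self.row not in _ROW_LETTERS:
            raise ValueError(f"invalid well row {self.row!r}")
        if self.column < 1:
            raise ValueError(f"invalid well column {self.column}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(str(text).strip())
        if not m or len(m.group(1)) != 1:
            raise ValueError(f"unparseable well address {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def in_bounds(self, n_rows: int = N_ROWS, n_cols: int = N_COLS) -> bool:
        return _ROW_LETTERS.index(self.row) < n_rows and 1 <= self.column <= n_cols

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclasses.dataclass
class PlateLayout:
    """Mapping of wells to roles and (for COMPOUND wells) compound ids."""

    plate_id: str
    wells: dict[WellAddress, tuple[WellRole, str | None]]

    def wells_of_role(self, role: WellRole) -> list[WellAddress]:
        return sorted(a for a, (r, _) in self.wells.items() if r is role)

    def compound_wells(self) -> dict[WellAddress, str]:
        return {
            a: cid
            for a, (r, cid) in sorted(self.wells.items())
            if r is WellRole.COMPOUND and cid is not None
        }


@dataclasses.dataclass
class PlateRead:
    """All well-level signals for one plate in one read.

    ``medium_tag`` records the read's measurement condition (the screen's two
    reads used phenol-red and phenol-red-free medium, which shifts the
    baseline scale); ``viability`` holds the parallel ATP-luminescence
    counterscreen where measured (read 2 in the screen design).
    """

    plate_id: str
    read_index: int
    signal: dict[WellAddress, float]
    viability: dict[WellAddress, float] | None = None
    medium_tag: str = ""

    def __post_init__(self) -> None:
        if self.read_index < 1:
            raise ValueError("read_index must be a positive integer")


@dataclasses.dataclass
class ScreenDataset:
    """An assembled screen: layouts, reads, and the compound-library registry.

    The registry is a DataFrame with one row per library entry and columns
    ``compound_id, library, plate_id, well``; entries are unique on
    ``(library, compound_id)`` so overlapping drug space between libraries is
    kept distinct.
    """

    layouts: dict[str, PlateLayout]
    reads: dict[tuple[str, int], PlateRead]
    library_registry: pd.DataFrame

    def read_indices(self) -> list[int]:
        return sorted({idx for (_, idx) in self.reads})

    def library_of(self, compound_id: str) -> str:
        hits = self.library_registry.loc[
            self.library_registry["compound_id"] == compound_id, "library"
        ]
        return str(hits.iloc[0]) if len(hits) else ""

    @property
    def n_compounds(self) -> int:
        return len(self.library_registry)


# ---------------------------------------------------------------------------
# parsing helpers

_PLATE_COLUMNS = ["plate_id", "read", "well", "role", "compound_id", "rlu"]
_MANIFEST_COLUMNS = ["compound_id", "library", "plate_id", "well"]


def parse_rlu(cell: object) -> float:
    """Parse a signal cell, accepting thousands-separator commas.

    >>> parse_rlu("12,432.0")
    12432.0
    """
    if isinstance(cell, (int, float)):
        value = float(cell)
    else:
        text = str(cell).strip().strip('"').replace(",", "")
        if not text:
            raise ValueError("empty signal cell")
        value = float(text)
    if not math.isfinite(value):
        raise ValueError(f"non-finite signal {cell!r}")
    return value


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: Path, mandatory: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return df


def load_screen(
    plate_files: Iterable[str | Path],
    manifest_files: Iterable[str | Path],
    n_rows: int = N_ROWS,
    n_cols: int = N_COLS,
) -> ScreenDataset:
    """Read long-format plate files and library manifests into a dataset.

    Rows whose signal cannot be parsed are rejected with a logged diagnostic
    naming the file and line; a duplicate ``(plate, read, well)`` row is an
    integrity error, as is a compound well whose compound does not resolve in
    any manifest.
    """
    manifest_files = [Path(p) for p in manifest_files]
    plate_files = [Path(p) for p in plate_files]
    if not manifest_files:
        raise IntegrityError("no libraries registered: empty manifest list")

    manifests = []
    for path in manifest_files:
        mdf = _read_table(path, _MANIFEST_COLUMNS)[_MANIFEST_COLUMNS].copy()
        dup = mdf.duplicated(subset=["library", "compound_id"])
        if dup.any():
            first = mdf.loc[dup].iloc[0]
            raise IntegrityError(
                f"{path}: duplicate compound {first['compound_id']!r} within "
                f"library {first['library']!r}"
            )
        manifests.append(mdf)
    registry = pd.concat(manifests, ignore_index=True)
    dup = registry.duplicated(subset=["library", "compound_id"])
    if dup.any():
        first = registry.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate compound {first['compound_id']!r} in library "
            f"{first['library']!r} across manifests"
        )
    registry["well"] = [str(WellAddress.parse(w)) for w in registry["well"]]
    registry = registry.sort_values(
        ["library", "plate_id", "well", "compound_id"]
    ).reset_index(drop=True)

    layouts: dict[str, PlateLayout] = {}
    signals: dict[tuple[str, int], dict[WellAddress, float]] = {}
    viability: dict[tuple[str, int], dict[WellAddress, float]] = {}
    seen: set[tuple[str, int, WellAddress]] = set()

    medium_tags: dict[tuple[str, int], str] = {}
    for path in plate_files:
        df = _read_table(path, _PLATE_COLUMNS)
        has_viab = "viability" in df.columns
        for i, row in enumerate(df.itertuples(index=False), start=2):
            rec = row._asdict()
            role_raw = str(rec["role"]).strip().upper()
            try:
                well = WellAddress.parse(rec["well"])
                # EMPTY wells may legitimately carry no measurement
                rlu = (
                    None
                    if role_raw == "EMPTY" and not str(rec["rlu"]).strip()
                    else parse_rlu(rec["rlu"])
                )
            except ValueError as exc:
                logger.warning("%s line %d: rejected row (%s)", path, i, exc)
                continue
            plate = str(rec["plate_id"]).strip()
            try:
                read_idx = int(str(rec["read"]).strip())
            except ValueError:
                logger.warning("%s line %d: rejected row (bad read index)", path, i)
                continue
            role = WellRole.from_label(rec["role"])
            cid = str(rec["compound_id"]).strip() or None
            if role is not WellRole.COMPOUND:
                cid = None

            key = (plate, read_idx, well)
            if key in seen:
                raise IntegrityError(
                    f"{path} line {i}: duplicate row for plate {plate!r} "
                    f"read {read_idx} well {well}"
                )
            seen.add(key)

            layout = layouts.setdefault(plate, PlateLayout(plate, {}))
            if well in layout.wells and layout.wells[well] != (role, cid):
                raise IntegrityError(
                    f"{path} line {i}: well {well} on plate {plate!r} has "
                    f"conflicting role/compound assignments across reads"
                )
            layout.wells[well] = (role, cid)
            if rlu is not None:
                signals.setdefault((plate, read_idx), {})[well] = rlu
            else:
                signals.setdefault((plate, read_idx), {})
            if "medium_tag" in df.columns:
                tag = str(rec.get("medium_tag", "")).strip()
                if tag:
                    medium_tags[(plate, read_idx)] = tag
            if has_viab:
                raw = str(rec.get("viability", "")).strip()
                if raw:
                    try:
                        viability.setdefault((plate, read_idx), {})[well] = parse_rlu(raw)
                    except ValueError as exc:
                        logger.warning(
                            "%s line %d: viability ignored (%s)", path, i, exc
                        )

    known = set(zip(registry["compound_id"], registry["plate_id"]))
    for plate, layout in layouts.items():
        for well, cid in layout.compound_wells().items():
            if (cid, plate) not in known and cid not in set(registry["compound_id"]):
                raise IntegrityError(
                    f"compound {cid!r} (plate {plate!r} well {well}) not found "
                    f"in any registered library"
                )

    reads = {
        key: PlateRead(
            key[0], key[1], sig, viability.get(key) or None,
            medium_tag=medium_tags.get(key, ""),
        )
        for key, sig in signals.items()
    }
    return ScreenDataset(layouts=layouts, reads=reads, library_registry=registry)


def write_screen(dataset: ScreenDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset back to the canonical long-format files.

    Returns the paths written (``plates.tsv`` and ``manifest.tsv``).  Numeric
    values are serialized with full repr precision so a load/write/load
    round-trip is bit-exact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (plate, read_idx), pr in sorted(dataset.reads.items()):
        layout = dataset.layouts[plate]
        wells = sorted(set(layout.wells) | set(pr.signal))
        for well in wells:
            role, cid = layout.wells.get(well, (WellRole.EMPTY, None))
            sig = pr.signal.get(well)
            viab = (pr.viability or {}).get(well)
            rows.append(
                {
                    "plate_id": plate,
                    "read": read_idx,
                    "well": str(well),
                    "role": role.value,
                    "compound_id": cid or "",
                    "rlu": "" if sig is None else repr(float(sig)),
                    "viability": "" if viab is None else repr(float(viab)),
                    "medium_tag": pr.medium_tag,
                }
            )
    plates_path = out_dir / "plates.tsv"
    pd.DataFrame(rows).to_csv(plates_path, sep="\t", index=False)
    manifest_path = out_dir / "manifest.tsv"
    dataset.library_registry.to_csv(manifest_path, sep="\t", index=False)
    return {"plates": plates_path, "manifest": manifest_path}


@dataclasses.dataclass
class LayoutIssue:
    severity: str  # "error" | "warning"
    well: str
    message: str


def validate_layout(
    layout: PlateLayout, n_rows: int = N_ROWS, n_cols: int = N_COLS
) -> list[LayoutIssue]:
    """Check a layout against the plate-geometry and role invariants.

    An empty list means the layout is usable for hit calling; in particular a
    layout without M1 solvent-control wells is an error because the per-plate
    hit thresholds would be undefined.
    """
    issues: list[LayoutIssue] = []
    seen_compounds: dict[str, WellAddress] = {}
    n_solvent = 0
    for well, (role, cid) in sorted(layout.wells.items()):
        if not well.in_bounds(n_rows, n_cols):
            bound = f"row out of range A–{_ROW_LETTERS[n_rows - 1]}"
            if _ROW_LETTERS.index(well.row) < n_rows:
                bound = f"column out of range 1–{n_cols}"
            issues.append(LayoutIssue("error", str(well), bound))
        if role is WellRole.COMPOUND:
            if cid is None:
                issues.append(
                    LayoutIssue("error", str(well), "compound well without compound_id")
                )
            elif cid in seen_compounds:
                issues.append(
                    LayoutIssue(
                        "error",
                        str(well),
                        f"compound {cid!r} already placed at {seen_compounds[cid]}",
                    )
                )
            else:
                seen_compounds[cid] = well
        elif cid is not None:
            issues.append(
                LayoutIssue("error", str(well), f"{role.name} well carries a compound_id")
            )
        if role is WellRole.M1_SOLVENT:
            n_solvent += 1
    if n_solvent == 0:
        issues.append(LayoutIssue("error", "", "no solvent control wells"))
    return issues


def dataset_to_json(dataset: ScreenDataset) -> str:
    """Serialize a dataset to canonical JSON (sorted keys, repr floats)."""
    obj = {
        "layouts": {
            plate: {
                str(w): {"role": role.value, "compound_id": cid}
                for w, (role, cid) in sorted(layout.wells.items())
            }
            for plate, layout in sorted(dataset.layouts.items())
        },
        "reads": {
            f"{plate}/{idx}": {
                "signal": {str(w): pr.signal[w] for w in sorted(pr.signal)},
                "viability": (
                    {str(w): pr.viability[w] for w in sorted(pr.viability)}
                    if pr.viability
                    else None
                ),
                "medium_tag": pr.medium_tag,
            }
            for (plate, idx), pr in sorted(dataset.reads.items())
        },
        "library_registry": dataset.library_registry.to_dict(orient="records"),
    }
    return json.dumps(obj, sort_keys=True, indent=1)
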