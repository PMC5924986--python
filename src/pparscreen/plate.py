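"""Multiwell plate data model and CSV I/O.

Plates are the unit of work for reporter-gene screening: each well carries a
firefly (reporter) and a Renilla (transfection control) luminescence read, a
role (negative control, positive control, sample, or empty), and the derived
firefly/Renilla ratio used by all downstream statistics.  Also included is the
bookkeeping for reformatting 384-well library plates into 96-well assay plates
with dedicated control columns.

CSV dialects
------------
Plate reads (long format): header ``well,firefly,renilla``, one row per well.
Layout: header ``well,role,sample_id`` with role in ``neg|pos|sample|empty``.
Both UTF-8, comma-delimited, ``.`` decimal.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Role",
    "WellAddress",
    "WellRecord",
    "ScreeningPlate",
    "parse_layout",
    "default_screen_layout",
    "load_plate_reads",
    "write_plate",
    "plan_reformat",
    "Transfer",
]

#: rows/columns per supported plate format
PLATE_DIMS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24)}

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"
_ADDR_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class Role(str, Enum):
    """Function of a well on a screening plate."""

    negative_control = "negative_control"
    positive_control = "positive_control"
    sample = "sample"
    empty = "empty"


_ROLE_ALIASES: dict[str, Role] = {
    "neg": Role.negative_control,
    "negative": Role.negative_control,
    "negative_control": Role.negative_control,
    "pos": Role.positive_control,
    "positive": Role.positive_control,
    "positive_control": Role.positive_control,
    "sample": Role.sample,
    "empty": Role.empty,
}


@dataclass(frozen=True, order=True)
class WellAddress:
    """Plate coordinate: row letter + 1-based column, canonical form ``A1``."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in _ROW_LETTERS:
            raise ValueError(f"invalid row letter {self.row!r}")
        if self.column < 1:
            raise ValueError(f"column must be >= 1, got {self.column}")

    @classmethod
    def parse(cls, text: str, plate_format: int | None = None) -> "WellAddress":
        m = _ADDR_RE.match(str(text).strip())
        if not m:
            raise ValueError(f"cannot parse well address {text!r}")
        addr = cls(m.group(1).upper(), int(m.group(2)))
        if plate_format is not None:
            addr.validate(plate_format)
        return addr

    def validate(self, plate_format: int) -> "WellAddress":
        n_rows, n_cols = PLATE_DIMS[plate_format]
        if _ROW_LETTERS.index(self.row) >= n_rows or self.column > n_cols:
            raise ValueError(
                f"address {self} out of bounds for {plate_format}-well format"
            )
        return self

    @property
    def row_index(self) -> int:
        return _ROW_LETTERS.index(self.row)

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclass
class WellRecord:
    """One well: reads, role, and the derived firefly/Renilla ratio."""

    address: WellAddress
    role: Role = Role.empty
    sample_id: str | None = None
    firefly: float | None = None
    renilla: float | None = None

    @property
    def ratio(self) -> float | None:
        """Vector-normalized signal; ``None`` when Renilla is missing or 0."""
        if self.firefly is None or self.renilla is None or self.renilla <= 0:
            return None
        return self.firefly / self.renilla

    @property
    def usable(self) -> bool:
        return self.ratio is not None


class ScreeningPlate:
    """A plate of :class:`WellRecord` keyed by canonical address string."""

    def __init__(self, plate_id: str, plate_format: int = 96):
        if plate_format not in PLATE_DIMS:
            raise ValueError(f"unsupported plate format {plate_format}")
        self.plate_id = plate_id
        self.plate_format = plate_format
        self.wells: dict[str, WellRecord] = {}

    def add(self, record: WellRecord) -> None:
        key = str(record.address)
        if key in self.wells:
            raise ValueError(f"duplicate well {key} on plate {self.plate_id}")
        record.address.validate(self.plate_format)
        self.wells[key] = record

    def __getitem__(self, addr: str) -> WellRecord:
        return self.wells[str(WellAddress.parse(addr))]

    def __iter__(self):
        return iter(sorted(self.wells.values(), key=lambda w: w.address))

    def __len__(self) -> int:
        return len(self.wells)

    def by_role(self, *roles: Role) -> list[WellRecord]:
        wanted = set(roles)
        return [w for w in self if w.role in wanted]

    def controls(self) -> list[WellRecord]:
        return self.by_role(Role.negative_control, Role.positive_control)

    def samples(self) -> list[WellRecord]:
        return self.by_role(Role.sample)

    def require_controls(self) -> None:
        """QC and hit calling need at least one well of each control role."""
        if not self.by_role(Role.negative_control) or not self.by_role(
            Role.positive_control
        ):
            raise ValueError(
                f"plate {self.plate_id} lacks negative and/or positive controls"
            )


# ---------------------------------------------------------------------------
# layouts


def parse_layout(
    layout_table: pd.DataFrame, plate_format: int = 96
) -> dict[str, tuple[Role, str | None]]:
    """Parse a well→(role, sample_id) map; unlisted wells default to empty.

    Rejects duplicate addresses (naming both table rows) and addresses out of
    bounds for the declared format.
    """
    required = {"well", "role"}
    missing = required - set(layout_table.columns)
    if missing:
        raise ValueError(f"layout table missing columns: {sorted(missing)}")
    mapping: dict[str, tuple[Role, str | None]] = {}
    first_row: dict[str, int] = {}
    for i, row in layout_table.reset_index(drop=True).iterrows():
        addr = WellAddress.parse(row["well"], plate_format)
        key = str(addr)
        if key in mapping:
            raise ValueError(
                f"duplicate address {key} in layout (rows {first_row[key]} and {i})"
            )
        role_txt = str(row["role"]).strip().lower()
        if role_txt not in _ROLE_ALIASES:
            raise ValueError(f"unknown role {row['role']!r} at layout row {i}")
        sample_id = row.get("sample_id")
        if sample_id is not None and (
            pd.isna(sample_id) or str(sample_id) == ""
        ):
            sample_id = None
        mapping[key] = (_ROLE_ALIASES[role_txt], sample_id)
        first_row[key] = i
    # fill unlisted wells as empty
    n_rows, n_cols = PLATE_DIMS[plate_format]
    for r in _ROW_LETTERS[:n_rows]:
        for c in range(1, n_cols + 1):
            mapping.setdefault(f"{r}{c}", (Role.empty, None))
    return mapping


def default_screen_layout(
    plate_format: int = 96, sample_ids: Sequence[str] | None = None
) -> dict[str, tuple[Role, str | None]]:
    """Standard screen layout: column 1 negative controls (vehicle), column 12
    positive controls (reference agonist), columns 2–11 samples, row-major."""
    if plate_format != 96:
        raise ValueError("default screen layout is defined for 96-well plates")
    mapping: dict[str, tuple[Role, str | None]] = {}
    sample_wells = sample_positions(96)
    ids = list(sample_ids) if sample_ids is not None else None
    if ids is not None and len(ids) > len(sample_wells):
        raise ValueError(f"at most {len(sample_wells)} samples per plate")
    k = 0
    n_rows, n_cols = PLATE_DIMS[96]
    for r in _ROW_LETTERS[:n_rows]:
        for c in range(1, n_cols + 1):
            key = f"{r}{c}"
            if c == 1:
                mapping[key] = (Role.negative_control, None)
            elif c == n_cols:
                mapping[key] = (Role.positive_control, None)
            else:
                mapping[key] = (Role.sample, None)
    if ids is not None:
        for key in sample_wells:
            if k < len(ids):
                mapping[key] = (Role.sample, ids[k])
                k += 1
            else:
                mapping[key] = (Role.empty, None)
    return mapping


def sample_positions(plate_format: int = 96) -> list[str]:
    """Row-major sample well order for the default screen layout (A2..A11, B2..)."""
    n_rows, n_cols = PLATE_DIMS[plate_format]
    return [
        f"{r}{c}"
        for r in _ROW_LETTERS[:n_rows]
        for c in range(2, n_cols)
    ]


# ---------------------------------------------------------------------------
# reads I/O


def load_plate_reads(
    reads_table: pd.DataFrame,
    layout: Mapping[str, tuple[Role, str | None]],
    plate_id: str = "plate",
    plate_format: int = 96,
) -> ScreeningPlate:
    """Build a :class:`ScreeningPlate` from a long-format reads table.

    The table must have columns ``well, firefly, renilla``.  Ratios are derived
    where Renilla > 0; wells with Renilla = 0 are kept but unusable.  Reads on
    wells the layout marks empty trigger a warning, negative luminescence or
    non-numeric cells are rejected with their position.
    """
    required = {"well", "firefly", "renilla"}
    missing = required - set(reads_table.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    plate = ScreeningPlate(plate_id, plate_format)
    for i, row in reads_table.reset_index(drop=True).iterrows():
        addr = WellAddress.parse(row["well"], plate_format)
        values = {}
        for channel in ("firefly", "renilla"):
            try:
                v = float(row[channel])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric {channel} value {row[channel]!r} at row {i}, well {addr}"
                ) from None
            if not math.isfinite(v):
                raise ValueError(f"non-finite {channel} at row {i}, well {addr}")
            if v < 0:
                raise ValueError(
                    f"negative {channel} luminescence ({v}) at row {i}, well {addr}"
                )
            values[channel] = v
        role, sample_id = layout.get(str(addr), (Role.empty, None))
        if role is Role.empty:
            warnings.warn(
                f"well {addr} has reads but layout marks it empty", stacklevel=2
            )
        plate.add(
            WellRecord(
                address=addr,
                role=role,
                sample_id=sample_id,
                firefly=values["firefly"],
                renilla=values["renilla"],
            )
        )
    return plate


def write_plate(plate: ScreeningPlate) -> pd.DataFrame:
    """Long-format reads table (inverse of :func:`load_plate_reads`)."""
    rows = [
        {"well": str(w.address), "firefly": w.firefly, "renilla": w.renilla}
        for w in plate
        if w.firefly is not None or w.renilla is not None
    ]
    return pd.DataFrame(rows, columns=["well", "firefly", "renilla"])


# ---------------------------------------------------------------------------
# 384 -> 96 reformatting


#: library plate columns kept empty for control placement downstream
RESERVED_384_COLUMNS = (1, 2, 23, 24)


@dataclass(frozen=True)
class Transfer:
    """One liquid-handling move from a library well to an assay plate well."""

    source_plate: str
    source_well: str
    target_plate: int  # 1-based assay plate number
    target_well: str
    sample_id: str | None = None


def plan_reformat(
    source_plates: Iterable[ScreeningPlate],
    target_format: int = 96,
) -> list[Transfer]:
    """Map non-empty 384-well library wells onto 96-well assay plates.

    Sources are walked row-major, plate by plate; targets fill the sample wells
    (columns 2–11) row-major, ``ceil(n/80)`` plates in total.  Columns 1, 2, 23
    and 24 of each source must be empty (they are reserved), and target control
    columns never receive a sample.
    """
    if target_format != 96:
        raise ValueError("reformat targets 96-well assay plates")
    sources: list[tuple[str, WellRecord]] = []
    for plate in source_plates:
        if plate.plate_format != 384:
            raise ValueError(f"source plate {plate.plate_id} is not 384-well")
        for w in plate:
            if w.role is Role.empty:
                continue
            if w.address.column in RESERVED_384_COLUMNS:
                raise ValueError(
                    f"sample in reserved column: {plate.plate_id} {w.address}"
                )
            sources.append((plate.plate_id, w))
    targets = sample_positions(96)
    per_plate = len(targets)  # 80
    transfers = []
    for idx, (src_plate, w) in enumerate(sources):
        transfers.append(
            Transfer(
                source_plate=src_plate,
                source_well=str(w.address),
                target_plate=idx // per_plate + 1,
                target_well=targets[idx % per_plate],
                sample_id=w.sample_id,
            )
        )
    return transfers
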