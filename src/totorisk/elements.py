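"""Domain types for trace-element measurements and the element constant table.

Concentrations are carried in µg/g dry weight throughout ingest; any
dry-to-fresh conversion is applied downstream in the exposure stage, never
here. A measurement below the instrument's detection limit (LOD) is stored
as a censored record with no value; detected values falling between the LOD
and the quantification limit (LOQ) are kept but flagged ``below_loq``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import SchemaError

TISSUES = frozenset({"liver", "muscle"})
HABITATS = frozenset({"estuarine", "rocky", "continental"})
SEASONS = frozenset({"winter", "spring", "autumn"})
GROUPS = frozenset({"MF", "MM", "IF", "IM", "UN"})
ELEMENTS = ("Cu", "Cd", "Zn", "Fe", "Pb")

#: tokens that mean "no measured value" in the value column of a record file
MISSING_TOKENS = frozenset({"", "NA", "<LOD"})

RECORD_HEADER = (
    "fish_id",
    "tissue",
    "habitat",
    "season",
    "group",
    "element",
    "value_ug_g_dw",
    "status",
)

ELEMENT_TABLE_HEADER = ("symbol", "rfd_mg_kg_day", "rdi_mg_day", "lod_ug_g", "loq_ug_g")


@dataclass(frozen=True)
class ElementSpec:
    """Per-element regulatory and analytical constants.

    Parameters
    ----------
    symbol : str
        Element identifier (Cu, Cd, Zn, Fe or Pb).
    rfd : float, optional
        EPA oral reference dose, mg per kg body weight per day. ``None``
        where no RfD is established (Pb).
    rdi : float, optional
        Recommended daily intake for essential elements, mg per day per
        person. ``None`` for non-essential elements (Cd, Pb).
    lod, loq : float
        Instrument detection and quantification limits, µg/g dry weight.
    """

    symbol: str
    rfd: Optional[float]
    rdi: Optional[float]
    lod: float
    loq: float

    def __post_init__(self) -> None:
        if self.rfd is not None and self.rfd <= 0:
            raise ValueError(f"{self.symbol}: rfd must be positive, got {self.rfd}")
        if self.rdi is not None and self.rdi <= 0:
            raise ValueError(f"{self.symbol}: rdi must be positive, got {self.rdi}")
        if not (0 < self.lod <= self.loq):
            raise ValueError(
                f"{self.symbol}: need 0 < lod <= loq, got lod={self.lod}, loq={self.loq}"
            )


@dataclass(frozen=True)
class ConcentrationRecord:
    """One fish x tissue x element measurement, possibly left-censored at the LOD."""

    fish_id: str
    tissue: str
    habitat: str
    season: str
    group: str
    element: str
    value: Optional[float]  # µg/g dry weight; None when censored
    censored: bool
    below_loq: bool = False  # detected but between LOD and LOQ

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise SchemaError(f"unknown tissue {self.tissue!r}")
        if self.habitat not in HABITATS:
            raise SchemaError(f"unknown habitat {self.habitat!r}")
        if self.season not in SEASONS:
            raise SchemaError(f"unknown season {self.season!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"unknown sex/maturity group {self.group!r}")
        if self.element not in ELEMENTS:
            raise SchemaError(f"unknown element {self.element!r}")
        if self.censored:
            if self.value is not None:
                raise ValueError("censored record must not carry a value")
        else:
            if self.value is None:
                raise ValueError("detected record must carry a value")
            if self.value <= 0:
                raise ValueError(f"concentration must be positive, got {self.value}")

    @property
    def stratum(self) -> tuple:
        return (self.tissue, self.habitat, self.season, self.group, self.element)


@dataclass(frozen=True)
class StudyDesign:
    """Which strata exist and their sample sizes: (tissue, habitat, season, group, element, n)."""

    cells: tuple

    def __post_init__(self) -> None:
        seen = set()
        for cell in self.cells:
            *key, n = cell
            key = tuple(key)
            if n < 1:
                raise ValueError(f"cell {key}: n must be >= 1, got {n}")
            if key in seen:
                raise ValueError(f"duplicate cell {key}")
            seen.add(key)


def default_element_table() -> dict:
    """The five study elements with EPA RfDs, RDIs and instrument LOD/LOQs.

    RfDs in mg/kg/day, RDIs in mg/day/person, LOD/LOQ in µg/g dry weight.
    Pb has no established RfD; Cd and Pb, being non-essential, have no RDI.
    """
    specs = [
        ElementSpec("Cu", rfd=0.40, rdi=0.9, lod=0.017, loq=0.020),
        ElementSpec("Cd", rfd=0.001, rdi=None, lod=0.01, loq=0.02),
        ElementSpec("Zn", rfd=0.30, rdi=11.0, lod=0.021, loq=0.060),
        ElementSpec("Fe", rfd=0.7, rdi=8.0, lod=0.65, loq=1.35),
        ElementSpec("Pb", rfd=None, rdi=None, lod=0.07, loq=0.10),
    ]
    return {s.symbol: s for s in specs}


def _parse_value(token: str, status: str, row_no: int) -> tuple:
    """Map the (value, status) cell pair to (value, censored)."""
    token = token.strip()
    if status not in {"detected", "censored"}:
        raise SchemaError(f"row {row_no}: unknown status {status!r}")
    if status == "censored":
        if token not in MISSING_TOKENS:
            raise SchemaError(
                f"row {row_no}: censored row carries value {token!r}; expected one of {sorted(MISSING_TOKENS)}"
            )
        return None, True
    if token in MISSING_TOKENS:
        raise SchemaError(f"row {row_no}: detected row has no value")
    try:
        value = float(token)
    except ValueError as exc:
        raise SchemaError(f"row {row_no}: non-numeric value {token!r}") from exc
    if value <= 0:
        raise ValueError(f"row {row_no}: concentration must be positive, got {value}")
    return value, False


def read_records(
    path, element_table: Optional[dict] = None
) -> list:
    """Read a long-format concentration CSV into validated records.

    The file must carry the header ``fish_id,tissue,habitat,season,group,
    element,value_ug_g_dw,status`` (an optional trailing ``below_loq`` column
    is honoured). Censored rows are those with status ``censored`` and an
    empty/``NA``/``<LOD`` value cell. When an element table is supplied (the
    default table otherwise), detected values below the element's LOQ are
    flagged ``below_loq``.
    """
    table = element_table if element_table is not None else default_element_table()
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if tuple(header[: len(RECORD_HEADER)]) != RECORD_HEADER:
            raise SchemaError(
                f"{path}: header mismatch; expected {','.join(RECORD_HEADER)}"
            )
        has_loq_col = len(header) > len(RECORD_HEADER) and header[8] == "below_loq"
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < len(RECORD_HEADER):
                raise SchemaError(f"{path}: row {row_no}: expected >=8 fields, got {len(row)}")
            fish_id, tissue, habitat, season, group, element, raw_value, status = (
                c.strip() for c in row[:8]
            )
            value, censored = _parse_value(raw_value, status, row_no)
            try:
                rec = ConcentrationRecord(
                    fish_id, tissue, habitat, season, group, element, value, censored
                )
            except SchemaError as exc:
                raise SchemaError(f"{path}: row {row_no}: {exc}") from None
            if rec.element not in table:
                raise SchemaError(
                    f"{path}: row {row_no}: element {rec.element!r} not in element table"
                )
            if has_loq_col and len(row) > 8 and row[8].strip():
                rec = replace(rec, below_loq=row[8].strip().lower() == "true")
            elif not censored and value is not None and value < table[rec.element].loq:
                rec = replace(rec, below_loq=True)
            records.append(rec)
    return records


def write_records(records: Iterable[ConcentrationRecord], path) -> None:
    """Write records to the standard CSV schema (round-trips with :func:`read_records`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_HEADER + ("below_loq",))
        for rec in records:
            writer.writerow(
                [
                    rec.fish_id,
                    rec.tissue,
                    rec.habitat,
                    rec.season,
                    rec.group,
                    rec.element,
                    "" if rec.value is None else repr(rec.value),
                    "censored" if rec.censored else "detected",
                    "true" if rec.below_loq else "false",
                ]
            )


def read_element_table(path) -> dict:
    """Read an element constant table (CSV columns symbol,rfd_mg_kg_day,rdi_mg_day,lod_ug_g,loq_ug_g)."""
    path = Path(path)
    table = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != ELEMENT_TABLE_HEADER:
            raise SchemaError(
                f"{path}: header mismatch; expected {','.join(ELEMENT_TABLE_HEADER)}"
            )
        for row in reader:
            def opt(key: str) -> Optional[float]:
                tok = (row[key] or "").strip()
                return None if tok in MISSING_TOKENS else float(tok)

            spec = ElementSpec(
                symbol=row["symbol"].strip(),
                rfd=opt("rfd_mg_kg_day"),
                rdi=opt("rdi_mg_day"),
                lod=float(row["lod_ug_g"]),
                loq=float(row["loq_ug_g"]),
            )
            table[spec.symbol] = spec
    return table


def write_element_table(table: dict, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ELEMENT_TABLE_HEADER)
        for spec in table.values():
            writer.writerow(
                [
                    spec.symbol,
                    "" if spec.rfd is None else repr(spec.rfd),
                    "" if spec.rdi is None else repr(spec.rdi),
                    repr(spec.lod),
                    repr(spec.loq),
                ]
            )


def validate_elements(records: Sequence[ConcentrationRecord], table: dict) -> None:
    """Reject records whose element is absent from the element table."""
    for rec in records:
        if rec.element not in table:
            raise SchemaError(f"record {rec.fish_id}: element {rec.element!r} not in table")
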