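"""Electronic-structure summary records.

A :class:`QCRecord` is the per-structure substrate of every analysis stage:
frontier orbital energies with occupancies, total energy, dipole vector and
harmonic frequencies, optionally augmented with per-orbital population
weights over named atom groups (the input to a projected density of states).

Records are serialized as JSON with a canonical field order and
shortest-round-trip float formatting, so that ``parse ∘ write`` is the
identity on the data model and repeated writes are byte-identical.

Canonical units: orbital energies in eV, total energies in hartree, dipole
components in Debye, frequencies in cm⁻¹ (a negative wavenumber encodes an
imaginary mode). Unit conversions are explicit operations elsewhere in the
package, never implicit here.
"""

from __future__ import annotations

import json
import warnings
from typing import Iterator, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "QCRecord",
    "RecordSet",
    "ValidationRecordError",
    "parse_record",
    "write_record",
    "homo_lumo",
    "load_record",
    "save_record",
    "load_record_set",
    "save_record_set",
]

#: canonical JSON key order for a serialized record
_FIELD_ORDER = (
    "label",
    "method",
    "basis",
    "total_energy",
    "orbital_energies",
    "occupancies",
    "dipole",
    "frequencies",
    "group_names",
    "population_weights",
)

_WEIGHT_ROW_TOL = 1e-6


class ValidationRecordError(ValueError):
    """A record violates one of the structural invariants."""


class QCRecord(BaseModel):
    """One structure's electronic-structure summary.

    Parameters
    ----------
    label
        Non-empty structure identifier, e.g. ``"Cellulose-GO"``.
    method, basis
        Free-text computation family and basis-set tags, e.g.
        ``"B3LYP"`` / ``"3-21g"``.
    total_energy
        Total electronic energy in hartree; optional because a record may
        be a truncated frontier-region summary.
    orbital_energies
        Orbital energies in eV, sorted ascending.
    occupancies
        Per-orbital occupied flag (True = occupied).  Stored explicitly
        rather than inferred from an electron count, because records may
        contain only a frontier window of the spectrum.
    dipole
        Dipole moment, either a 3-vector ``[x, y, z]`` or a scalar
        magnitude, in Debye.
    frequencies
        Harmonic frequencies in cm⁻¹; negative values encode imaginary
        modes and are carried with a warning at validation time.
    group_names / population_weights
        Optional Mulliken-style partition: for each orbital a row of
        fractions over the named atom groups, each row summing to 1.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    method: str = ""
    basis: str = ""
    total_energy: Optional[float] = None
    orbital_energies: tuple[float, ...] = ()
    occupancies: tuple[bool, ...] = ()
    dipole: Optional[tuple[float, ...]] = None
    frequencies: tuple[float, ...] = ()
    group_names: Optional[tuple[str, ...]] = None
    population_weights: Optional[tuple[tuple[float, ...], ...]] = None

    @field_validator("label")
    @classmethod
    def _label_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("label must be non-empty")
        return v

    @field_validator("dipole")
    @classmethod
    def _dipole_shape(cls, v):
        if v is not None and len(v) not in (1, 3):
            raise ValueError("dipole must be a 3-vector or a scalar magnitude")
        return v

    @model_validator(mode="after")
    def _check_invariants(self) -> "QCRecord":
        e = self.orbital_energies
        occ = self.occupancies
        if len(e) != len(occ):
            raise ValueError(
                f"{len(e)} orbital energies but {len(occ)} occupancies"
            )
        if any(b > a for a, b in zip(e[1:], e)):
            raise ValueError("orbital_energies must be sorted ascending")
        occupied = [x for x, o in zip(e, occ) if o]
        virtual = [x for x, o in zip(e, occ) if not o]
        if occupied and virtual and max(occupied) >= min(virtual):
            raise ValueError(
                f"occupied orbital at {max(occupied)} eV is not below the "
                f"lowest virtual orbital at {min(virtual)} eV"
            )
        if self.population_weights is not None:
            if self.group_names is None:
                raise ValueError("population_weights given without group_names")
            ng = len(self.group_names)
            if len(self.population_weights) != len(e):
                raise ValueError("one population_weights row required per orbital")
            for i, row in enumerate(self.population_weights):
                if len(row) != ng:
                    raise ValueError(
                        f"weight row {i} has {len(row)} entries for {ng} groups"
                    )
                s = sum(row)
                if abs(s - 1.0) > _WEIGHT_ROW_TOL:
                    raise ValueError(
                        f"weight row {i} sums to {s!r}, expected 1 within "
                        f"{_WEIGHT_ROW_TOL}"
                    )
        if any(f < 0 for f in self.frequencies):
            warnings.warn(
                f"record {self.label!r} carries imaginary mode(s) "
                "(negative wavenumbers)",
                stacklevel=2,
            )
        return self

    # -- convenience views ------------------------------------------------

    @property
    def occupied_energies(self) -> list[float]:
        return [e for e, o in zip(self.orbital_energies, self.occupancies) if o]

    @property
    def virtual_energies(self) -> list[float]:
        return [e for e, o in zip(self.orbital_energies, self.occupancies) if not o]

    @property
    def has_imaginary_modes(self) -> bool:
        return any(f < 0 for f in self.frequencies)


def homo_lumo(record: QCRecord) -> tuple[float, float]:
    """Frontier orbital energies ``(E_HOMO, E_LUMO)`` in eV.

    The HOMO is the highest occupied orbital energy, the LUMO the lowest
    virtual one.  Raises :class:`ValidationRecordError` if the record lacks
    either an occupied or a virtual orbital.
    """
    occ = record.occupied_energies
    virt = record.virtual_energies
    if not occ or not virt:
        raise ValidationRecordError(
            f"record {record.label!r} needs at least one occupied and one "
            "virtual orbital to define a HOMO/LUMO pair"
        )
    return max(occ), min(virt)


class RecordSet:
    """A label-keyed collection of :class:`QCRecord` with unique labels."""

    def __init__(self, records: Sequence[QCRecord] = (), provenance: str = ""):
        self._records: dict[str, QCRecord] = {}
        self.provenance = provenance
        for r in records:
            self.add(r)

    def add(self, record: QCRecord) -> None:
        if record.label in self._records:
            raise ValidationRecordError(f"duplicate label {record.label!r}")
        self._records[record.label] = record

    def __getitem__(self, label: str) -> QCRecord:
        return self._records[label]

    def __iter__(self) -> Iterator[QCRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, label: str) -> bool:
        return label in self._records

    @property
    def labels(self) -> list[str]:
        return list(self._records)


# -- canonical (de)serialization ------------------------------------------


def _record_to_obj(record: QCRecord) -> dict:
    raw = record.model_dump()
    obj = {}
    for key in _FIELD_ORDER:
        val = raw.get(key)
        if val is None or (key not in ("label",) and val == ()):
            continue  # optional / empty fields are omitted
        obj[key] = val
    return obj


def write_record(record: QCRecord) -> str:
    """Serialize a record to canonical JSON text.

    Keys appear in a fixed order, floats use the shortest representation
    that round-trips, optional fields are omitted, and the output ends
    with a newline — two calls on the same record yield identical bytes.
    """
    return json.dumps(_record_to_obj(record), indent=2) + "\n"


def parse_record(source: str | bytes | dict) -> QCRecord:
    """Parse one serialized record (JSON text or an already-decoded dict).

    Raises :class:`ValidationRecordError` naming the offending field on a
    schema violation, including an occupied orbital lying at or above a
    virtual one.
    """
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    if isinstance(source, str):
        try:
            obj = json.loads(source)
        except json.JSONDecodeError as exc:
            raise ValidationRecordError(f"record is not valid JSON: {exc}") from exc
    else:
        obj = source
    if not isinstance(obj, dict):
        raise ValidationRecordError("record must be a JSON object")
    try:
        return QCRecord(**obj)
    except Exception as exc:  # pydantic ValidationError carries field names
        raise ValidationRecordError(str(exc)) from exc


def load_record(path) -> QCRecord:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_record(fh.read())


def save_record(record: QCRecord, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(write_record(record))


def save_record_set(rs: RecordSet, path) -> None:
    obj = {
        "provenance": rs.provenance,
        "records": [_record_to_obj(r) for r in rs],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(json.dumps(obj, indent=2) + "\n")


def load_record_set(path) -> RecordSet:
    with open(path, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    if isinstance(obj, list):
        records = [parse_record(o) for o in obj]
        return RecordSet(records)
    if "records" not in obj:
        # a single bare record file
        return RecordSet([parse_record(obj)])
    return RecordSet(
        [parse_record(o) for o in obj["records"]],
        provenance=obj.get("provenance", ""),
    )
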