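"""Mapping from electronic-structure parser output to the record schema.

qcpost does not parse raw program log files itself — mature parser
ecosystems (cclib and friends) already do that.  This module documents
the attribute mapping those parsers expose and converts their in-memory
result into a :class:`~qcpost.records.QCRecord`:

==================  ===========================================
parser attribute    record field
==================  ===========================================
moenergies[0]       orbital_energies (eV, ascending)
homos[0]            occupancies (indices <= homo are occupied)
scfenergies[-1]     total_energy (converted eV -> hartree)
moments[1]          dipole (Debye 3-vector)
vibfreqs            frequencies (cm^-1, negatives = imaginary)
==================  ===========================================

Population weight rows (for PDOS) are not a standard parser attribute at
the group level; pass them explicitly if a population analysis has been
aggregated over atom groups.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .binding import HARTREE_TO_EV
from .records import QCRecord

__all__ = ["record_from_parsed"]


def record_from_parsed(
    attrs: Mapping,
    label: str,
    method: str = "",
    basis: str = "",
    group_names: Optional[Sequence[str]] = None,
    population_weights: Optional[Sequence[Sequence[float]]] = None,
) -> QCRecord:
    """Build a record from a cclib-style attribute mapping.

    Only the restricted (single-spin-channel) case is handled: the first
    row of ``moenergies``/``homos`` is used.  Orbital energies are sorted
    ascending with their occupancies carried along.
    """
    if "moenergies" not in attrs or "homos" not in attrs:
        raise ValueError("parsed attributes need 'moenergies' and 'homos'")
    energies = [float(e) for e in attrs["moenergies"][0]]
    homo_idx = int(attrs["homos"][0])
    flags = [i <= homo_idx for i in range(len(energies))]
    order = sorted(range(len(energies)), key=lambda i: energies[i])
    energies = [energies[i] for i in order]
    flags = [flags[i] for i in order]

    total = None
    if attrs.get("scfenergies") is not None:
        total = float(attrs["scfenergies"][-1]) / HARTREE_TO_EV

    dipole = None
    moments = attrs.get("moments")
    if moments is not None and len(moments) > 1:
        dipole = tuple(float(x) for x in moments[1])

    return QCRecord(
        label=label,
        method=method,
        basis=basis,
        total_energy=total,
        orbital_energies=tuple(energies),
        occupancies=tuple(flags),
        dipole=dipole,
        frequencies=tuple(float(f) for f in attrs.get("vibfreqs", ())),
        group_names=tuple(group_names) if group_names else None,
        population_weights=(
            tuple(tuple(float(w) for w in row) for row in population_weights)
            if population_weights
            else None
        ),
    )
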