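"""Fragment binding energies and hartree/eV conversion.

The binding energy of a complex against its isolated fragments is the raw
total-energy difference

    BE = TE(complex) − Σ_i TE(fragment_i)     (hartree)

with the convention that a *negative* BE marks a favorable association.
The difference is reported as computed; the sign is never flipped to match
an external table.  Site ranking orders candidate functionalization sites
from most to least favorable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite
from typing import Sequence

__all__ = [
    "HARTREE_TO_EV",
    "FragmentSet",
    "BindingResult",
    "hartree_to_ev",
    "binding_energy",
    "rank_sites",
]

#: eV per hartree used for reported conversions.  The 6-digit literature
#: value; pass ``constant=`` explicitly for the full CODATA figure
#: (27.211386245981).
HARTREE_TO_EV = 27.2114


def hartree_to_ev(x: float, constant: float = HARTREE_TO_EV) -> float:
    """Convert an energy from hartree to eV (linear, exact)."""
    return x * constant


@dataclass(frozen=True)
class FragmentSet:
    """A complex and the isolated fragments it dissociates into."""

    complex_label: str
    complex_te: float  # hartree
    fragments: tuple[tuple[str, float], ...]  # (label, TE in hartree)
    site_tag: str = ""

    def __post_init__(self):
        if not self.fragments:
            raise ValueError(
                f"{self.complex_label!r}: at least one fragment required"
            )
        tes = [self.complex_te, *(te for _, te in self.fragments)]
        if not all(isfinite(t) for t in tes):
            raise ValueError(f"{self.complex_label!r}: non-finite total energy")


@dataclass(frozen=True)
class BindingResult:
    """Binding energy of one complex, in hartree and eV."""

    label: str
    be_au: float
    be_ev: float = field(default=None)  # type: ignore[assignment]
    site_tag: str = ""

    def __post_init__(self):
        if self.be_ev is None:
            object.__setattr__(self, "be_ev", hartree_to_ev(self.be_au))


def binding_energy(fs: FragmentSet) -> BindingResult:
    """BE = TE(complex) − Σ TE(fragments); negative = favorable.

    Invariant under permutation of the fragment list; a complex measured
    against itself as sole fragment gives exactly zero.
    """
    be_au = fs.complex_te - sum(te for _, te in fs.fragments)
    return BindingResult(
        label=fs.complex_label,
        be_au=be_au,
        be_ev=hartree_to_ev(be_au),
        site_tag=fs.site_tag,
    )


def rank_sites(results: Sequence[BindingResult]) -> list[BindingResult]:
    """Order sites by stability: ascending BE (most negative first).

    Ties are broken by ``site_tag`` lexicographically, so the ranking is
    total and reproducible.
    """
    if not results:
        raise ValueError("rank_sites requires at least one result")
    return sorted(results, key=lambda r: (r.be_au, r.site_tag))
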