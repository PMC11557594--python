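"""Seeded synthetic electronic-structure summaries for testing the pipeline.

The generator emulates the statistical shape of the records the analysis
consumes — two normal clusters of orbital energies separated by a
controlled HOMO–LUMO gap, Dirichlet population-weight rows over named
atom groups, a normal dipole vector, and calculated/experimental
frequency pairs related by a known scale factor plus additive noise —
without pretending to reproduce real quantum-chemistry level spacings.

Every draw goes through one :class:`numpy.random.Generator` constructed
from the spec's seed; there is no global random state, so identical specs
yield byte-identical serialized records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .records import QCRecord, RecordSet

__all__ = [
    "SyntheticSpec",
    "gen_qc_record",
    "gen_freq_pair",
    "gen_record_set",
    "specs_for_gaps",
]

#: minimal HOMO–LUMO separation enforced when the requested gap is zero,
#: so generated records always satisfy the strict occupied < virtual rule
_MIN_SEPARATION = 1e-9

_FREQ_RANGE = (400.0, 3800.0)  # cm⁻¹, the mid-IR window the tables span


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic record.

    Defaults describe a cellulose-like insulator: a wide 7.944 eV gap,
    three atom groups (C, H, O), 30 frequencies in the mid-IR window and
    an effective harmonic scale factor of 0.9614 with 5 cm⁻¹ of additive
    experimental noise.
    """

    seed: int = 0
    label: str = "synthetic"
    n_occupied: int = 30
    n_virtual: int = 30
    gap: float = 7.944  # eV
    occupied_spread: float = 3.0  # eV
    virtual_spread: float = 3.0  # eV
    n_groups: int = 3
    dirichlet_concentration: float = 1.0
    n_freqs: int = 30
    true_scale: float = 0.9614
    freq_noise_sd: float = 5.0  # cm⁻¹
    dipole_scale: float = 2.0  # Debye

    def __post_init__(self):
        if self.n_occupied < 1 or self.n_virtual < 1:
            raise ValueError("need at least one occupied and one virtual orbital")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.occupied_spread <= 0 or self.virtual_spread <= 0:
            raise ValueError("spreads must be positive")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.n_freqs < 0:
            raise ValueError("n_freqs must be non-negative")
        if self.true_scale <= 0:
            raise ValueError("true_scale must be positive")
        if self.freq_noise_sd < 0:
            raise ValueError("freq_noise_sd must be non-negative")


def _group_names(n: int) -> tuple[str, ...]:
    base = ("C", "H", "O", "N", "S")
    if n <= len(base):
        return base[:n]
    return base + tuple(f"G{i}" for i in range(len(base), n))


def gen_qc_record(spec: SyntheticSpec) -> QCRecord:
    """Draw one record: clustered orbitals with a preserved gap, Dirichlet
    population weights, a normal dipole and uniform frequencies.

    Occupied energies are drawn from a normal cluster centred one spread
    below −gap/2 and clipped to lie at or below −gap/2 (virtual ones
    mirrored above +gap/2), so the emitted record always satisfies
    ``lumo − homo ≥ gap``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    half = spec.gap / 2.0
    occ = rng.normal(-half - spec.occupied_spread, spec.occupied_spread,
                     spec.n_occupied)
    occ = np.minimum(occ, -half - _MIN_SEPARATION / 2)
    virt = rng.normal(half + spec.virtual_spread, spec.virtual_spread,
                      spec.n_virtual)
    virt = np.maximum(virt, half + _MIN_SEPARATION / 2)
    energies = np.concatenate([np.sort(occ), np.sort(virt)])
    occupancies = (True,) * spec.n_occupied + (False,) * spec.n_virtual

    names = _group_names(spec.n_groups)
    weights = rng.dirichlet(
        np.full(spec.n_groups, spec.dirichlet_concentration), size=energies.size
    )
    # exact renormalization so serialized rows always pass the 1e-6 check
    weights = weights / weights.sum(axis=1, keepdims=True)

    dipole = rng.normal(0.0, spec.dipole_scale, 3)
    freqs = np.sort(rng.uniform(*_FREQ_RANGE, spec.n_freqs))
    total_energy = float(-40.0 * spec.n_occupied + rng.normal(0.0, 1.0))

    return QCRecord(
        label=spec.label,
        method="synthetic",
        basis="synthetic",
        total_energy=total_energy,
        orbital_energies=tuple(float(e) for e in energies),
        occupancies=occupancies,
        dipole=tuple(float(x) for x in dipole),
        frequencies=tuple(float(f) for f in freqs),
        group_names=names,
        population_weights=tuple(tuple(float(w) for w in row) for row in weights),
    )


def gen_freq_pair(spec: SyntheticSpec) -> tuple[list[float], list[float]]:
    """Paired (calculated, experimental) frequency lists.

    ``calc`` is uniform over the mid-IR window and sorted;
    ``exp = true_scale · calc + N(0, freq_noise_sd)``, so
    :func:`~qcpost.vibrational.estimate_scale` applied to the pair is an
    unbiased estimator of ``true_scale``.
    """
    rng = np.random.default_rng(spec.seed)
    calc = np.sort(rng.uniform(*_FREQ_RANGE, spec.n_freqs))
    exp = spec.true_scale * calc + rng.normal(0.0, spec.freq_noise_sd,
                                              spec.n_freqs)
    return [float(x) for x in calc], [float(x) for x in exp]


def gen_record_set(specs: Sequence[SyntheticSpec]) -> RecordSet:
    """Generate a labelled collection of records (labels must be unique)."""
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    return RecordSet(
        [gen_qc_record(s) for s in specs],
        provenance="synthetic: clustered-orbital generator",
    )


def specs_for_gaps(
    gaps: Sequence[float], seed: int = 0, **overrides
) -> list[SyntheticSpec]:
    """Convenience: one spec per requested gap, labelled and sub-seeded."""
    return [
        replace(
            SyntheticSpec(seed=seed * 10_000 + i, label=f"structure-{i:02d}",
                          gap=float(g)),
            **overrides,
        )
        for i, g in enumerate(gaps)
    ]
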