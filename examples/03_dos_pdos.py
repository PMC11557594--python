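"""DOS and projected DOS of a synthetic cellulose-like record.

Generates a seeded record with a 7.944 eV gap and three atom groups,
broadens the orbital spectrum with 0.3 eV Gaussians referenced to the
midgap Fermi level, and verifies the projected curves partition the total.
"""

import numpy as np

from qcpost import (
    BroadeningSpec,
    dos_curve,
    fermi_reference,
    homo_lumo,
    pdos_curves,
)
from qcpost.synthetic import SyntheticSpec, gen_qc_record

rec = gen_qc_record(SyntheticSpec(seed=7, label="cellulose-like"))
homo, lumo = homo_lumo(rec)
shift = -fermi_reference(homo, lumo, "midgap")
spec = BroadeningSpec()  # fwhm 0.3 eV, step 0.01 eV, 4-fwhm padding

total = dos_curve(rec.orbital_energies, spec, shift=shift)
groups = pdos_curves(rec.orbital_energies, rec.population_weights,
                     rec.group_names, spec, shift=shift)

n = len(rec.orbital_energies)
print(f"record: {n} orbitals, HOMO {homo:.3f} eV, LUMO {lumo:.3f} eV, "
      f"gap {lumo - homo:.3f} eV")
print(f"DOS integral: {total.integral():.4f} (orbital count {n})")
stack = np.sum([c.intensity for c in groups], axis=0)
print(f"max |sum of PDOS - DOS|: {np.max(np.abs(stack - total.intensity)):.2e}")
for c in groups:
    print(f"  group {c.label}: integral {c.integral():.3f} states")
# With the midgap reference at 0 eV, occupied states sit below zero and
# virtual states above; each group's integral is the number of states the
# population analysis attributes to it.
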