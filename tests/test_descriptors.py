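"""Reactivity descriptor cascade: formulas, identities, table reproduction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcpost import (
    ReferenceMetal,
    compare_tables,
    compute_descriptors,
    descriptor_table,
    dipole_magnitude,
    electron_affinity,
    electron_transfer_fraction,
    electronegativity_and_potential,
    electrophilicity,
    gap,
    hardness,
    ionization_potential,
    rounded_cascade,
    rounded_descriptor_table,
    softness,
)
from qcpost.descriptors import round_to_printed
from qcpost.records import QCRecord, RecordSet
from qcpost.datasets import (
    EXPECTED_DESCRIPTOR_DISCREPANCIES,
    FRONTIER_ORBITALS,
    PUBLISHED_DESCRIPTORS,
    published_descriptor_frame,
)
from qcpost.synthetic import SyntheticSpec, gen_qc_record

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestElementaryOps:
    @pytest.mark.parametrize(
        "homo, lumo, expected",
        [(-6.502, 1.442, 7.944), (-4.244, -4.076, 0.168), (-1.0, 1.0, 2.0)],
    )
    def test_gap(self, homo, lumo, expected):
        assert gap(homo, lumo) == pytest.approx(expected, abs=1e-12)

    def test_gap_rejects_inverted_pair(self):
        with pytest.raises(ValueError):
            gap(1.0, -1.0)

    def test_koopmans_negation(self):
        assert ionization_potential(-6.502) == 6.502
        assert electron_affinity(1.442) == -1.442
        assert ionization_potential(0.0) == 0.0

    @pytest.mark.parametrize(
        "I, A, chi, mu",
        [(6.502, -1.442, 2.530, -2.530), (6.492, 0.524, 3.508, -3.508)],
    )
    def test_electronegativity_and_potential(self, I, A, chi, mu):
        c, m = electronegativity_and_potential(I, A)
        assert c == pytest.approx(chi, abs=1e-12)
        assert m == pytest.approx(mu, abs=1e-12)
        assert m == -c  # exact identity

    def test_symmetric_I_A_gives_zero_potential(self):
        _, mu = electronegativity_and_potential(1.7, -1.7)
        assert mu == 0.0

    @pytest.mark.parametrize(
        "I, A, eta",
        [(6.502, -1.442, 3.972), (4.244, 4.076, 0.084), (2.0, 2.0, 0.0)],
    )
    def test_hardness(self, I, A, eta):
        assert hardness(I, A) == pytest.approx(eta, abs=1e-12)

    def test_hardness_warns_for_unbound_ordering(self):
        with pytest.warns(UserWarning, match="negative"):
            assert hardness(1.0, 2.0) == -0.5

    def test_softness(self):
        assert softness(3.972) == pytest.approx(0.2517623, abs=1e-6)
        assert round_to_printed(softness(3.972)) == 0.252
        assert softness(1.0) == 1.0
        with pytest.raises(ZeroDivisionError, match="Cellulose-X"):
            softness(0.0, label="Cellulose-X")

    def test_electrophilicity(self):
        assert electrophilicity(-2.530, 3.972) == pytest.approx(
            0.805752, abs=1e-6
        )
        assert electrophilicity(0.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            electrophilicity(-1.0, 0.0)

    @pytest.mark.parametrize(
        "v, expected", [((3, 4, 0), 5.0), ((0, 0, 0), 0.0),
                        ((1, 1, 1), math.sqrt(3)), ((63.975,), 63.975)]
    )
    def test_dipole_magnitude(self, v, expected):
        assert dipole_magnitude(v) == pytest.approx(expected, abs=1e-9)


class TestElectronTransfer:
    def test_zero_numerator(self):
        ref = ReferenceMetal(chi=2.5, eta=7.0)
        assert electron_transfer_fraction(2.5, 1.0, ref) == 0.0

    def test_literal_rule_cellulose(self):
        # hand derivation: (0 - 2.530) / (2 * (7 - 3.972)) = -2.530/6.056
        dn = electron_transfer_fraction(2.530, 3.972)
        assert dn == pytest.approx(-0.4177675, abs=1e-6)

    def test_literal_rule_go(self):
        # hand derivation: (0 - 4.160) / (2 * (7 - 0.084)) = -4.160/13.832
        dn = electron_transfer_fraction(4.160, 0.084)
        assert dn == pytest.approx(-0.3007519, abs=1e-6)

    def test_conventional_rule_uses_sum_denominator(self):
        ref = ReferenceMetal.conventional()
        dn = electron_transfer_fraction(2.530, 3.972, ref)
        assert dn == pytest.approx((7 - 2.530) / (2 * 3.972), abs=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            electron_transfer_fraction(1.0, 7.0, ReferenceMetal(eta=7.0))


class TestAlgebraicIdentities:
    """Structural identities asserted over synthetic records."""

    @pytest.mark.parametrize("seed", range(10))
    def test_gap_equals_twice_hardness_and_softness_inverts(self, seed):
        rec = gen_qc_record(SyntheticSpec(seed=seed, label="s",
                                          gap=0.5 + 0.9 * seed))
        d = compute_descriptors(rec)
        assert d.gap == pytest.approx(2.0 * d.hardness, abs=0.0)
        assert d.softness * d.hardness == pytest.approx(1.0, abs=1e-12)
        assert d.chemical_potential == -d.electronegativity

    @given(mu=finite, eta=st.floats(min_value=0.01, max_value=50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_electrophilicity_even_in_mu(self, mu, eta):
        assert electrophilicity(mu, eta) == electrophilicity(-mu, eta)


class TestTableReproduction:
    def test_rounded_cascade_matches_consistent_published_cells(self):
        """Every published cell not on the documented discrepancy list is
        reproduced exactly at 3 decimals from the printed HOMO/LUMO."""
        flagged = {(lab, q) for lab, q, _, _ in EXPECTED_DESCRIPTOR_DISCREPANCIES}
        for label, (homo, lumo) in FRONTIER_ORBITALS.items():
            got = rounded_cascade(homo, lumo)
            I, A, mu, eta, sigma, omega = PUBLISHED_DESCRIPTORS[label]
            published = {"I": I, "A": A, "mu": mu, "eta": eta,
                         "sigma": sigma, "omega": omega}
            for q, val in published.items():
                if (label, q) in flagged:
                    assert got[q] != val, (label, q)
                else:
                    assert got[q] == pytest.approx(val, abs=1e-12), (label, q)

    def test_all_ionization_and_affinity_cells_match(self):
        for label, (homo, lumo) in FRONTIER_ORBITALS.items():
            got = rounded_cascade(homo, lumo)
            I, A = PUBLISHED_DESCRIPTORS[label][:2]
            assert got["I"] == I and got["A"] == A, label

    def test_discrepancy_report_flags_exactly_the_documented_cells(self):
        rounded = rounded_descriptor_table(dict(FRONTIER_ORBITALS.items()))
        report = compare_tables(rounded, published_descriptor_frame())
        found = {(r.label, r.quantity) for r in report.itertuples()}
        expected = {
            (lab, q)
            for lab, q, _, _ in EXPECTED_DESCRIPTOR_DISCREPANCIES
            if q != "gap"  # gap cells are checked against the ΔE table
        }
        assert found == expected

    def test_recomputed_values_in_discrepancy_list_are_correct(self):
        for lab, q, _published, recomputed in EXPECTED_DESCRIPTOR_DISCREPANCIES:
            if q == "gap":
                homo, lumo = FRONTIER_ORBITALS[lab]
                assert round_to_printed(gap(homo, lumo)) == recomputed, (lab, q)
            else:
                homo, lumo = FRONTIER_ORBITALS[lab]
                assert rounded_cascade(homo, lumo)[q] == recomputed, (lab, q)


class TestDescriptorTable:
    def test_empty_set_gives_empty_table(self):
        df = descriptor_table(RecordSet())
        assert len(df) == 0

    def test_cellulose_gap_matches_dipole_table(self, frontier_records):
        df = descriptor_table(frontier_records)
        assert round_to_printed(df.loc["Cellulose", "gap"]) == 7.944

    def test_bad_structure_does_not_abort_table(self, frontier_records):
        bad = QCRecord(label="no-virtual", orbital_energies=(-2.0, -1.0),
                       occupancies=(True, True))
        records = RecordSet(list(frontier_records) + [bad])
        df = descriptor_table(records)
        assert len(df) == 10
        assert df.loc["no-virtual", "error"] != ""
        assert math.isnan(df.loc["no-virtual", "gap"])
        assert df.loc["Cellulose", "error"] == ""

    def test_dipole_and_transfer_columns_populated(self, frontier_records):
        df = descriptor_table(frontier_records)
        assert df.loc["Cellulose-GO", "tdm"] == pytest.approx(63.975)
        assert df.loc["Cellulose", "dN"] == pytest.approx(-0.41776, abs=1e-4)


def test_round_to_printed_ties_go_toward_positive_infinity():
    assert round_to_printed(3.3325) == 3.333
    assert round_to_printed(-3.2775) == -3.277
    assert round_to_printed(-2.3985) == -2.398
    assert round_to_printed(4.0365) == 4.037
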