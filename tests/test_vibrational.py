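"""Vibrational analysis: scaling, monotone matching, model selection, diffing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcpost import (
    Band,
    BandList,
    apply_scale,
    assign_bands,
    band_residual,
    bands_from_frame,
    bands_to_frame,
    diff_bands,
    estimate_scale,
    model_error,
    rank_models,
)
from qcpost.datasets import (
    IR_MODEL_TAGS,
    cellulose_exp_bands,
    composite_bands,
    ir_model_bands,
)
from qcpost.synthetic import SyntheticSpec, gen_freq_pair


def single_bands(*values, source=""):
    return BandList(tuple(Band(lo=float(v)) for v in values), source=source)


class TestApplyScale:
    def test_elementwise(self):
        assert apply_scale([1000.0, 2000.0], 0.96) == [960.0, 1920.0]

    def test_identity_factor(self):
        assert apply_scale([500.0, 700.0], 1.0) == [500.0, 700.0]

    def test_imaginary_modes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="imaginary"):
            assert apply_scale([-50.0, 1000.0], 0.96) == [960.0]

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            apply_scale([1000.0], 0.0)


class TestBandResidual:
    def test_point_distance(self):
        assert band_residual(Band(637), Band(615)) == 22.0

    def test_overlapping_intervals_have_zero_residual(self):
        assert band_residual(Band(1022, 1117), Band(1030, 1160)) == 0.0

    def test_disjoint_interval_uses_nearest_endpoints(self):
        assert band_residual(Band(1138, 1263), Band(1030, 1100)) == 38.0

    def test_symmetry(self):
        a, b = Band(895), Band(872)
        assert band_residual(a, b) == band_residual(b, a) == 23.0


class TestAssignBands:
    def test_identical_lists_all_zero(self):
        bl = single_bands(615, 895, 1280)
        ar = assign_bands(bl, bl, tol=100)
        assert [r for _, _, r in ar.pairs] == [0.0, 0.0, 0.0]
        assert not ar.unmatched_model and not ar.unmatched_exp

    def test_single_pair_residual(self):
        ar = assign_bands(single_bands(637), single_bands(615), tol=100)
        assert ar.pairs[0][2] == 22.0

    def test_residual_beyond_tolerance_dissolves_pair(self):
        ar = assign_bands(single_bands(500), single_bands(700), tol=100)
        assert not ar.pairs
        assert len(ar.unmatched_model) == len(ar.unmatched_exp) == 1

    def test_matching_is_monotone(self):
        """Bands pair in wavenumber order, without crossings."""
        ar = assign_bands(single_bands(600, 610), single_bands(605, 615),
                          tol=100)
        assert [(m.lo, e.lo) for m, e, _ in ar.pairs] == [(600, 605), (610, 615)]

    def test_absent_bands_never_match(self):
        model = BandList((Band(1640, present=False), Band(1650)))
        ar = assign_bands(model, single_bands(1640), tol=100)
        assert ar.pairs[0][0].lo == 1650

    def test_residuals_symmetric_for_single_valued_lists(self):
        a, b = single_bands(600, 900, 1200), single_bands(620, 880, 1260)
        fw = assign_bands(a, b, tol=100)
        bw = assign_bands(b, a, tol=100)
        assert [r for *_, r in fw.pairs] == [r for *_, r in bw.pairs]


class TestModelError:
    def test_all_zero_residuals(self):
        bl = single_bands(1, 2, source="m")
        score = model_error(assign_bands(bl, bl, tol=10))
        assert score.mad == score.rmsd == 0.0

    def test_b3lyp_321g_mad_is_131_over_7(self):
        """Hand-summed residuals over the seven shared single bands:
        22+5+2+4+12+43+43 = 131."""
        ar = assign_bands(ir_model_bands("B3LYP/3-21g"), cellulose_exp_bands(),
                          tol=math.inf)
        score = model_error(ar)
        assert score.n_matched == 7
        assert score.mad == pytest.approx(131 / 7, abs=1e-12)

    def test_hf_321g_mad_is_142_over_7(self):
        """Hand-summed residuals: 18+23+4+4+0+90+3 = 142."""
        ar = assign_bands(ir_model_bands("HF/3-21g"), cellulose_exp_bands(),
                          tol=math.inf)
        score = model_error(ar)
        assert score.n_matched == 7
        assert score.mad == pytest.approx(142 / 7, abs=1e-12)

    def test_mad_zero_iff_all_residuals_zero(self):
        ar = assign_bands(single_bands(600, 900), single_bands(600, 905),
                          tol=100)
        assert model_error(ar).mad > 0

    def test_interval_pairs_excluded_by_default(self):
        model = BandList((Band(1022, 1117), Band(2943)), source="m")
        exp = BandList((Band(1030, 1160), Band(2900)), source="e")
        default = model_error(assign_bands(model, exp, tol=math.inf))
        assert default.n_matched == 1
        opted_in = model_error(assign_bands(model, exp, tol=math.inf),
                               include_intervals=True)
        assert opted_in.n_matched == 2

    def test_no_matches_is_an_error(self):
        ar = assign_bands(single_bands(500), single_bands(5000), tol=10)
        with pytest.raises(ValueError):
            model_error(ar)


class TestRankModels:
    def test_full_table_ranking_puts_b3lyp_321g_first(self):
        exp = cellulose_exp_bands()
        scores = [
            model_error(assign_bands(ir_model_bands(tag), exp, tol=math.inf))
            for tag in IR_MODEL_TAGS
        ]
        ranked = rank_models(scores)
        assert ranked[0].model == "B3LYP/3-21g"
        assert ranked[1].model == "HF/3-21g"
        assert ranked[0].mad < ranked[1].mad

    def test_single_model(self):
        from qcpost import ModelScore

        s = ModelScore("only", 1.0, 2.0, 3)
        assert rank_models([s]) == [s]

    def test_tie_broken_by_rmsd_then_tag(self):
        from qcpost import ModelScore

        a = ModelScore("b-model", 1.0, 5.0, 3)
        b = ModelScore("a-model", 1.0, 4.0, 3)
        c = ModelScore("c-model", 1.0, 4.0, 3)
        assert [s.model for s in rank_models([a, b, c])] == [
            "a-model", "c-model", "b-model"
        ]


class TestEstimateScale:
    def test_noiseless_recovery(self):
        calc = [500.0, 1200.0, 3000.0]
        assert estimate_scale(calc, [0.96 * c for c in calc]) == pytest.approx(
            0.96, abs=1e-12
        )

    def test_identical_lists_give_unity(self):
        assert estimate_scale([400.0, 800.0], [400.0, 800.0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            estimate_scale([1.0, 2.0], [1.0])

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_seeded_recovery_within_half_percent(self, seed):
        calc, exp = gen_freq_pair(SyntheticSpec(seed=seed))
        assert estimate_scale(calc, exp) == pytest.approx(0.9614, abs=0.005)

    @given(c=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_scale_equivariance(self, c):
        calc = np.array([500.0, 1200.0, 2100.0, 3300.0])
        exp = 0.93 * calc + np.array([2.0, -3.0, 1.0, 4.0])
        base = estimate_scale(calc, exp)
        assert estimate_scale(c * calc, exp) == pytest.approx(base / c, rel=1e-9)


class TestDiffBands:
    def test_identical_lists(self):
        bl = cellulose_exp_bands()
        d = diff_bands(bl, bl, tol=50)
        assert not d.new and not d.lost
        assert all(s == 0 for *_, s in d.shifted)

    def test_composite_gains_exactly_the_carboxyl_band(self):
        d = diff_bands(cellulose_exp_bands(), composite_bands(), tol=50)
        assert [b.lo for b in d.new] == [1710.0]
        assert d.new[0].assignment == "COOH of GO"
        assert not d.lost

    def test_composite_shifts_are_all_downward_or_zero(self):
        d = diff_bands(cellulose_exp_bands(), composite_bands(), tol=50)
        singles = [
            (a.lo, s) for a, b, s in d.shifted
            if not a.is_interval and not b.is_interval
        ]
        assert singles, "expected matched single-valued pairs"
        assert all(s <= 0 for _, s in singles)
        # every pair shifts strictly down except the unchanged 1280 C-CO band
        assert all(s < 0 for lo, s in singles if lo != 1280.0)
        shifts = dict(singles)
        assert shifts[3345.0] == -20.0 and shifts[2900.0] == -20.0


class TestCsvInterchange:
    def test_frame_roundtrip(self):
        bl = composite_bands()
        again = bands_from_frame(bands_to_frame(bl), source=bl.source)
        assert again == bl

    def test_missing_optional_columns(self):
        import pandas as pd

        df = pd.DataFrame({"lo": [600.0, 1700.0]})
        bl = bands_from_frame(df)
        assert all(not b.is_interval and b.present for b in bl)
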