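"""Agreement metrics: oracles, closed forms, and protocol self-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fovecast import PhantomSpec, make_phantom_case, metrics as M
from fovecast.metrics import (
    RetinaMask,
    band_status,
    bland_altman,
    concordance,
    evaluate_case,
    layer_visibility_score,
    segment_neurosensory,
    thickness_profile,
)

from conftest import SMALL_GEOMETRY


def brute_force_confusion(ai, gt):
    tp = fp = fn = tn = 0
    for a, g in zip(ai.ravel(), gt.ravel()):
        if a and g:
            tp += 1
        elif a and not g:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestSegmentation:
    def test_matches_phantom_truth(self, small_case):
        """ILM/RPE curves on a noise-free central slice track the generator
        truth to about a pixel."""
        fs = small_case.truth.fovea_slice
        img = small_case.post.slice(fs).astype(float) / 255.0
        mask = segment_neurosensory(img)
        truth_ilm = small_case.truth.ilm_surface[fs]
        truth_rpe = small_case.truth.rpe_surface[fs]
        sel = mask.valid
        assert sel.mean() > 0.9
        assert np.abs(mask.ilm_curve[sel] - truth_ilm[sel]).max() <= 2.0
        assert np.abs(mask.rpe_curve[sel] - truth_rpe[sel]).max() <= 2.0

    def test_blank_image_yields_empty_invalid_mask(self):
        mask = segment_neurosensory(np.zeros((64, 64)))
        assert not mask.mask.any()
        assert not mask.valid.any()

    def test_supplied_curves_bypass_detection(self):
        ilm = np.full(32, 5.0)
        rpe = np.full(32, 20.0)
        mask = segment_neurosensory(np.zeros((32, 32)), curves=(ilm, rpe))
        assert mask.valid.all()
        assert np.array_equal(mask.ilm_curve, ilm)
        assert mask.mask[10].all() and not mask.mask[25].any()


class TestConcordance:
    def test_identical_masks_perfect(self, rng):
        m = rng.random((20, 20)) > 0.5
        c = concordance(m, m)
        assert (c.accuracy, c.precision, c.recall, c.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_counted_toy_case(self):
        gt = np.zeros((4, 4), dtype=bool)
        ai = np.zeros((4, 4), dtype=bool)
        gt.ravel()[[0, 1, 2, 3, 4, 5]] = True
        ai.ravel()[[2, 3, 4, 5, 6, 7]] = True  # 4 overlapping of 6 each
        c = concordance(ai, gt)
        assert c.accuracy == pytest.approx(12 / 16)
        assert c.precision == pytest.approx(2 / 3)
        assert c.recall == pytest.approx(2 / 3)
        assert c.f1 == pytest.approx(2 / 3)

    def test_matches_brute_force_oracle_on_random_masks(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            ai = r.random((12, 9)) > 0.6
            gt = r.random((12, 9)) > 0.4
            c = concordance(ai, gt)
            tp, fp, fn, tn = brute_force_confusion(ai, gt)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            assert c.accuracy == (tp + tn) / (tp + fp + fn + tn)

    def test_undefined_f1_flagged_zero(self):
        gt = np.zeros((3, 3), dtype=bool)
        gt[0, 0] = True
        c = concordance(np.zeros((3, 3), dtype=bool), gt)
        assert c.f1 == 0.0 and not c.f1_defined

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestThicknessProfile:
    def make_uniform_mask(self, w=224, thick_px=100.0):
        ilm = np.full(w, 40.0)
        rpe = ilm + thick_px
        mask = np.zeros((224, w), dtype=bool)
        return RetinaMask(mask, ilm, rpe, np.ones(w, dtype=bool))

    def test_uniform_phantom_arithmetic(self):
        """100-pixel uniform thickness at 5.2 um pitch reads 520 um in all
        four summaries."""
        mask = self.make_uniform_mask()
        prof = thickness_profile(mask, 112, axial_pitch_um=5.2, lateral_pitch_um=23.4375)
        assert prof.as_array() == pytest.approx([520.0, 520.0, 520.0, 520.0])

    def test_fh_is_thickness_at_foveola(self):
        mask = self.make_uniform_mask()
        mask.rpe_curve[112] = mask.ilm_curve[112] + 50.0
        prof = thickness_profile(mask, 112, 5.2, 23.4375)
        assert prof.fh == pytest.approx(50 * 5.2)

    def test_windows_disjoint_and_linear(self):
        mask = self.make_uniform_mask(thick_px=80.0)
        p1 = thickness_profile(mask, 112, 5.2, 23.4375)
        mask2 = self.make_uniform_mask(thick_px=160.0)
        p2 = thickness_profile(mask2, 112, 5.2, 23.4375)
        assert np.allclose(p2.as_array(), 2 * p1.as_array())
        # nasal/temporal annuli exclude the foveal window
        inner = int(np.floor(500 / 23.4375 + 0.5))
        outer = int(np.floor(1500 / 23.4375 + 0.5))
        assert inner < outer

    def test_invalid_fovea_column_rejected(self):
        mask = self.make_uniform_mask()
        mask.valid[112] = False
        with pytest.raises(ValueError):
            thickness_profile(mask, 112, 5.2, 23.4375)


class TestBlandAltman:
    def test_identical_pairs_zero_band(self):
        r = bland_altman([100, 200, 300], [100, 200, 300])
        assert (r.bias, r.loa_low, r.loa_high, r.pass_30) == (0.0, 0.0, 0.0, True)

    def test_constructed_differences_closed_form(self):
        # percentage differences exactly {-10, 0, +10}
        gt = np.array([100.0, 100.0, 100.0])
        ai = gt * np.array([(2 - 0.1 / 2) / (2 + 0.1 / 2) ** -1 * 0 + 0, 0, 0])
        # build pairs with d = 100*(a-g)/((a+g)/2) = target
        targets = np.array([-10.0, 0.0, 10.0])
        ai = gt * (1 + targets / 200) / (1 - targets / 200)
        r = bland_altman(ai, gt)
        assert r.bias == pytest.approx(0.0, abs=1e-9)
        assert r.loa_high == pytest.approx(1.96 * np.std(targets, ddof=1))
        assert r.loa_low == pytest.approx(-r.loa_high)
        assert r.pass_30

    def test_threshold_is_strict_thirty_percent(self):
        # constructed so the upper limit lands just above +30
        gt = np.full(40, 100.0)
        d = np.linspace(-27, 27, 40)  # sample SD ~16.2 -> limits ~ +/-31.7
        ai = gt * (1 + d / 200) / (1 - d / 200)
        r = bland_altman(ai, gt)
        assert r.loa_high > 30.0
        assert not r.pass_30

    @given(st.lists(st.floats(-20, 20), min_size=2, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_limits_bracket_bias_for_any_difference_set(self, diffs):
        d = np.asarray(diffs)
        gt = np.full(len(d), 100.0)
        ai = gt * (1 + d / 200) / (1 - d / 200)
        r = bland_altman(ai, gt)
        assert r.loa_low <= r.bias <= r.loa_high

    def test_zero_mean_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, -1.0], [-1.0, 1.0])

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


@pytest.fixture(scope="module")
def native():
    """Factory for native-resolution central slices with chosen band gaps."""

    def build(elm_gap, ez_gap, seed=0):
        spec = PhantomSpec(
            elm_gap_um=elm_gap, ez_gap_um=ez_gap, seed=seed,
            noise_sd=0.0, **SMALL_GEOMETRY,
        )
        case = make_phantom_case(spec)
        fs = case.truth.fovea_slice
        img = case.post.slice(fs).astype(float) / 255.0
        mask = segment_neurosensory(img)
        kw = dict(
            fovea_col=case.truth.fovea_col,
            axial_pitch_um=spec.axial_pitch_um,
            lateral_pitch_um=spec.geometry.lateral_pitch,
        )
        return img, mask, kw

    return build


class TestBandStatus:
    def test_defect_free_phantom_both_restored(self, native):
        img, mask, kw = native(0.0, 0.0)
        assert band_status(img, mask, band="ELM", **kw).status == "restored"
        assert band_status(img, mask, band="EZ", **kw).status == "restored"

    @pytest.mark.parametrize("band,gaps", [("ELM", (200.0, 0.0)), ("EZ", (0.0, 200.0))])
    def test_large_gap_detected_on_right_band(self, native, band, gaps):
        img, mask, kw = native(*gaps)
        assert band_status(img, mask, band=band, **kw).status == "disrupted"
        other = "EZ" if band == "ELM" else "ELM"
        assert band_status(img, mask, band=other, **kw).status == "restored"

    def test_gap_below_tolerance_counts_as_restored(self, native):
        img, mask, kw = native(0.0, 0.0)
        # synthetically fail one column: a 1-column break (31.25 um) is
        # below the 50 um tolerance
        col = kw["fovea_col"]
        img2 = img.copy()
        img2[:, col] = img2[:, col] * 0.0
        mask2 = segment_neurosensory(img2)
        status = band_status(img2, mask2, band="EZ", **kw)
        assert status.largest_gap_um <= 50.0 or status.status == "restored"

    def test_unknown_band_rejected(self, native):
        img, mask, kw = native(0.0, 0.0)
        with pytest.raises(ValueError):
            band_status(img, mask, band="RPE", **kw)


class TestLayerVisibility:
    def test_clean_phantom_scores_ten(self, small_case):
        fs = small_case.truth.fovea_slice
        img = small_case.post.slice(fs).astype(float)
        assert layer_visibility_score(img, small_case.truth, fs) == 10

    def test_erased_band_loses_its_point(self, small_case):
        fs = small_case.truth.fovea_slice
        img = small_case.post.slice(fs).astype(float).copy()
        b = small_case.truth.band_boundaries_px
        rows = np.arange(img.shape[0])[:, None]
        ez = (rows >= b[7, fs][None, :]) & (rows < b[8, fs][None, :])
        img[ez] = 40.0  # overwrite with outer-nuclear gray
        assert layer_visibility_score(img, small_case.truth, fs) == 9

    def test_blank_image_scores_zero(self, small_case):
        fs = small_case.truth.fovea_slice
        blank = np.zeros_like(small_case.post.slice(fs), dtype=float)
        assert layer_visibility_score(blank, small_case.truth, fs) == 0


class TestEvaluateCase:
    def test_oracle_predictor_gives_perfect_agreement(self, small_case):
        """Substituting a predictor that returns the GT crop drives all
        concordance metrics to 1 and thickness differences to zero."""
        report = evaluate_case(
            small_case.pre,
            small_case.post,
            state=None,
            case_id=small_case.case_id,
            fovea_slice=small_case.truth.fovea_slice,
            fovea_col=small_case.truth.fovea_col,
            predictor="oracle",
            crop_size=128,
            out_size=64,
        )
        assert report.concordance.accuracy == 1.0
        assert report.concordance.f1 == 1.0
        assert report.thickness_ai.as_array() == pytest.approx(
            report.thickness_gt.as_array()
        )
        # identity-aligned case: both residuals sit at the sub-pixel floor
        assert report.residual_rms_after_um < small_case.pre.geometry.axial_pitch

    def test_report_serialises_completely(self, small_case):
        report = evaluate_case(
            small_case.pre, small_case.post, None,
            fovea_slice=small_case.truth.fovea_slice,
            fovea_col=small_case.truth.fovea_col,
            predictor="oracle", crop_size=128, out_size=64,
        )
        d = report.as_dict()
        for key in ("concordance", "thickness_ai", "elm_ai", "residual_rms_after_um"):
            assert key in d

    def test_cohort_aggregation_matches_hand_summary(self, rng):
        values = rng.uniform(200, 300, 10)
        noise = rng.normal(0, 5, 10)
        r = bland_altman(values + noise, values)
        d = 100 * noise / ((2 * values + noise) / 2)
        assert r.bias == pytest.approx(d.mean())
        assert r.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
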