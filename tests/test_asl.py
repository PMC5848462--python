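import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cafasim import (
    ASLParams,
    cbf_per_delay,
    classify_misery_perfusion,
    final_cbf,
    kinetic_decay_factor,
    load_case_regional,
    lr_percent_difference,
    quantify,
    regional_summary,
    simulate_asl_signals,
    wd_forward,
    wd_to_att,
    weighted_delay,
)

PARAMS = ASLParams()


class TestKineticDecayFactor:
    def test_plateau_below_pld(self):
        # delta <= w_i: label fully arrived, factor independent of delta
        b1 = kinetic_decay_factor(0.3, 1, PARAMS)
        b2 = kinetic_decay_factor(2.0, 1, PARAMS)
        assert b1 == pytest.approx(b2)
        assert b1 == pytest.approx(
            np.exp(-0.61 * 2.0) - np.exp(-0.61 * (1.5 + 2.0))
        )

    def test_zero_when_bolus_fully_passed(self):
        assert kinetic_decay_factor(PARAMS.tau + PARAMS.w[0], 0, PARAMS) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # delta = 1.2, w = 1.0, tau = 1.5, R1a = 0.61
        b = kinetic_decay_factor(1.2, 0, PARAMS)
        assert b == pytest.approx(np.exp(-0.732) - np.exp(-1.525), rel=1e-12)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            kinetic_decay_factor(-0.1, 0, PARAMS)


class TestWeightedDelay:
    @pytest.mark.parametrize(
        "dM, expected",
        [((1.0, 1.0, 1.0), 2.0), ((1.0, 0.0, 0.0), 1.0), ((2.0, 1.0, 1.0), 1.75)],
    )
    def test_hand_computed_values(self, dM, expected):
        assert weighted_delay(np.array(dM), PARAMS) == pytest.approx(expected)

    def test_zero_total_signal_masked(self):
        assert np.isnan(weighted_delay(np.zeros(3), PARAMS))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 100.0), min_size=3, max_size=3).filter(lambda v: sum(v) > 0))
    def test_wd_bounded_by_pld_range(self, dM):
        wd = weighted_delay(np.array(dM), PARAMS)
        assert PARAMS.w[0] - 1e-9 <= wd <= PARAMS.w[-1] + 1e-9


class TestWdToAtt:
    def test_forward_inverse_round_trip(self):
        wd = wd_forward(1.4, PARAMS)
        att, lo, hi = wd_to_att(wd, PARAMS)
        assert att == pytest.approx(1.4, abs=1e-6)
        assert not lo and not hi

    def test_plateau_censored_low(self):
        wd_plateau = wd_forward(PARAMS.w[0], PARAMS)
        att, lo, hi = wd_to_att(wd_plateau - 1e-6, PARAMS)
        assert lo and not hi
        assert att == pytest.approx(PARAMS.w[0])

    def test_above_max_censored_high(self):
        att, lo, hi = wd_to_att(PARAMS.w[-1] + 0.5, PARAMS)
        assert hi and not lo

    def test_forward_map_monotone_on_grid(self):
        grid = np.linspace(PARAMS.w[0], PARAMS.w[-1] + PARAMS.tau - 1e-3, 100)
        vals = np.array([wd_forward(d, PARAMS) for d in grid])
        assert np.all(np.diff(vals) >= -1e-12)


class TestCbfChain:
    def test_noiseless_recovery_at_every_pld(self):
        acq = simulate_asl_signals(
            np.array([[50.0]]), np.array([[1.2]]), np.array([[1000.0]])
        )
        maps = quantify(acq)
        assert maps.att[0, 0] == pytest.approx(1.2, abs=1e-6)
        np.testing.assert_allclose(maps.cbf_i[:, 0, 0], 50.0, rtol=1e-6)
        assert maps.cbf_final[0, 0] == pytest.approx(50.0, rel=1e-6)

    def test_zero_signal_gives_zero_cbf(self):
        assert cbf_per_delay(0.0, 1000.0, 1.5, 0, PARAMS) == pytest.approx(0.0)

    def test_doubling_m0_halves_cbf(self):
        f1 = cbf_per_delay(3.0, 1000.0, 1.5, 1, PARAMS)
        f2 = cbf_per_delay(3.0, 2000.0, 1.5, 1, PARAMS)
        assert f2 == pytest.approx(f1 / 2)

    def test_noisy_recovery_many_voxels(self):
        # 2% signal noise, 1000 voxels, fixed seed: recovery stays accurate
        rng = np.random.default_rng(0)
        cbf_t = rng.uniform(20.0, 70.0, size=1000)
        att_t = rng.uniform(1.1, 2.5, size=1000)
        M0 = np.full(1000, 1000.0)
        acq = simulate_asl_signals(cbf_t, att_t, M0, noise_sd=0.02, seed=1)
        maps = quantify(acq)
        cbf_err = np.abs(maps.cbf_final - cbf_t) / cbf_t
        att_err = np.abs(maps.att - att_t)
        assert np.median(cbf_err) < 0.05
        assert np.median(att_err) < 0.1


class TestFinalCbf:
    @pytest.mark.parametrize(
        "vals, expected",
        [
            ((51.76, 50.61, 52.38), 51.58),
            ((32.54, 49.55, 54.76), 45.62),
            ((40.0, 40.0, 40.0), 40.0),
        ],
    )
    def test_mean_of_per_delay_estimates(self, vals, expected):
        assert round(float(final_cbf(vals)), 2) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            final_cbf([])

    def test_commutes_with_region_averaging(self):
        rng = np.random.default_rng(5)
        cbf_i = rng.uniform(30, 60, size=(3, 50))
        assert np.mean(final_cbf(cbf_i)) == pytest.approx(
            float(final_cbf(cbf_i.mean(axis=1)))
        )


class TestLrPercentDifference:
    @pytest.mark.parametrize(
        "left, right, expected",
        [(51.76, 52.93, -2.21), (1.23, 1.13, 8.85), (5.0, 5.0, 0.0)],
    )
    def test_hand_values(self, left, right, expected):
        assert round(lr_percent_difference(left, right), 2) == pytest.approx(expected)

    def test_zero_right_undefined(self):
        with pytest.raises(ZeroDivisionError):
            lr_percent_difference(1.0, 0.0)


class TestMiseryClassifier:
    def test_healthy_territory_unflagged(self):
        flags = classify_misery_perfusion(51.58, 1.23, 2.69)
        assert not flags.overall

    def test_low_cbf_flagged(self):
        assert classify_misery_perfusion(34.9, 1.0, 0.0).flag_cbf

    def test_prolonged_att_flagged(self):
        assert classify_misery_perfusion(50.0, 8.0, 0.0).flag_att

    def test_asymmetry_flagged(self):
        assert classify_misery_perfusion(50.0, 1.0, -11.0).flag_asym


class TestRegionalSummary:
    def test_reproduces_case_table(self):
        report = regional_summary(load_case_regional())
        finals = report[report.metric == "Final CBF"].set_index("region")
        assert finals.loc["fronto-temporal", "left"] == 51.58
        assert finals.loc["fronto-temporal", "right"] == 50.23
        assert finals.loc["fronto-temporal", "delta_pct"] == 2.69
        assert finals.loc["fronto-parietal", "left"] == 45.62
        assert finals.loc["fronto-parietal", "right"] == 46.60
        assert finals.loc["fronto-parietal", "delta_pct"] == -2.10
        att = report[report.metric == "ATT"].set_index("region")
        assert att.loc["fronto-temporal", "delta_pct"] == 8.85
        assert att.loc["fronto-parietal", "delta_pct"] == 6.87

    def test_symmetric_inputs_have_zero_differences(self):
        df = pd.DataFrame(
            {
                "region": ["a", "a"],
                "side": ["left", "right"],
                "cbf_pld1": [50.0, 50.0],
                "cbf_pld2": [50.0, 50.0],
                "cbf_pld3": [50.0, 50.0],
                "att": [1.2, 1.2],
            }
        )
        report = regional_summary(df)
        assert (report.delta_pct == 0).all()
        assert not report[report.metric == "Final CBF"].flag_any.any()

    def test_missing_side_rejected(self):
        df = load_case_regional()
        with pytest.raises(ValueError):
            regional_summary(df[df.side == "left"])

    def test_absolute_value_option(self):
        report = regional_summary(load_case_regional(), signed=False)
        assert (report.delta_pct >= 0).all()


def test_nifti_map_round_trip(tmp_path):
    from cafasim.asl import read_acquisition_nifti, write_maps_nifti
    import nibabel as nib

    cbf = np.full((4, 4, 2), 48.0)
    att = np.full((4, 4, 2), 1.6)
    M0 = np.full((4, 4, 2), 1000.0)
    acq = simulate_asl_signals(cbf, att, M0)
    maps = quantify(acq)
    prefix = str(tmp_path / "case")
    write_maps_nifti(maps, prefix)
    nib.save(
        nib.Nifti1Image(np.moveaxis(acq.dM, 0, -1), np.eye(4)),
        str(tmp_path / "dm.nii.gz"),
    )
    nib.save(nib.Nifti1Image(M0, np.eye(4)), str(tmp_path / "m0.nii.gz"))
    back = read_acquisition_nifti(str(tmp_path / "dm.nii.gz"), str(tmp_path / "m0.nii.gz"))
    np.testing.assert_allclose(back.dM, acq.dM, rtol=1e-12)
    loaded_cbf = np.asarray(nib.load(prefix + "_cbf.nii.gz").dataobj)
    np.testing.assert_allclose(loaded_cbf, 48.0, rtol=1e-6)
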