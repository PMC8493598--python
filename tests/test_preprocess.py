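import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import braingraph as bg
from braingraph.errors import InputError, ParameterError, SubjectExclusionError
from braingraph.preprocess import friston24, gross_motion_exceeded


def make_motion(t=50):
    return np.zeros((t, 6))


class TestDiscard:
    def test_200_minus_10_leaves_190(self, rng):
        ts = rng.standard_normal((200, 8))
        mot = rng.standard_normal((200, 6))
        ts2, mot2 = bg.discard_initial_volumes(ts, mot, 10)
        assert ts2.shape == (190, 8)
        assert mot2.shape == (190, 6)
        np.testing.assert_array_equal(ts2, ts[10:])

    def test_zero_discard_is_identity(self, rng):
        ts = rng.standard_normal((20, 4))
        mot = rng.standard_normal((20, 6))
        ts2, mot2 = bg.discard_initial_volumes(ts, mot, 0)
        np.testing.assert_array_equal(ts2, ts)
        np.testing.assert_array_equal(mot2, mot)

    def test_discarding_more_than_length_errors(self, rng):
        with pytest.raises(InputError):
            bg.discard_initial_volumes(
                rng.standard_normal((5, 3)), rng.standard_normal((5, 6)), 10
            )


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        mot = np.ones((30, 6)) * 0.3
        assert np.all(bg.framewise_displacement(mot) == 0)

    def test_translation_jump(self):
        mot = make_motion()
        mot[10:, 0] = 0.3  # sustained 0.3 mm shift on one axis
        fd = bg.framewise_displacement(mot)
        assert fd[10] == pytest.approx(0.3)
        assert fd[11] == 0

    def test_rotation_jump_converts_at_50mm(self):
        mot = make_motion()
        mot[7:, 4] = 0.004  # radians
        fd = bg.framewise_displacement(mot)
        assert fd[7] == pytest.approx(0.2)

    def test_first_volume_is_zero(self, rng):
        fd = bg.framewise_displacement(rng.standard_normal((20, 6)))
        assert fd[0] == 0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(offset=st.floats(-5, 5, allow_nan=False))
    def test_translation_invariance(self, offset):
        rng = np.random.default_rng(0)
        mot = rng.normal(0, 0.1, size=(40, 6))
        fd0 = bg.framewise_displacement(mot)
        fd1 = bg.framewise_displacement(mot + offset)
        np.testing.assert_allclose(fd0, fd1, atol=1e-10)


class TestScrubMask:
    def test_neighbor_rule_hand_case(self):
        # one bad volume at index 1 flags itself, 1 before and 2 after
        fd = np.array([0.0, 0.25, 0.1, 0.1, 0.1])
        mask = bg.scrub_mask(fd, 0.2, n_before=1, n_after=2)
        np.testing.assert_array_equal(mask, [True, True, True, True, False])

    def test_all_below_threshold_empty(self):
        assert not bg.scrub_mask(np.full(20, 0.05)).any()

    def test_window_clipped_at_boundaries(self):
        fd = np.zeros(5)
        fd[0] = 0.5
        mask = bg.scrub_mask(fd)
        np.testing.assert_array_equal(mask, [True, True, True, False, False])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 1000))
    def test_lowering_threshold_never_unflags(self, seed):
        fd = np.random.default_rng(seed).uniform(0, 0.5, size=60)
        hi = bg.scrub_mask(fd, 0.3)
        lo = bg.scrub_mask(fd, 0.15)
        assert np.all(lo[hi])  # every volume flagged at 0.3 is flagged at 0.15


class TestNuisanceDesign:
    def test_spike_columns_match_flags(self, rng):
        mot = rng.normal(0, 0.05, size=(50, 6))
        mask = np.zeros(50, bool)
        mask[[4, 17, 33]] = True
        design = bg.build_nuisance_design(mot, mask)
        spike_cols = [c for c in design.columns if c.startswith("spike")]
        assert len(spike_cols) == 3
        col = design["spike_t0017"].to_numpy()
        assert col[17] == 1 and col.sum() == 1

    def test_degenerate_motion_collapses(self):
        design = bg.build_nuisance_design(make_motion(), np.zeros(50, bool))
        # zero motion: all 24 expansion columns are constant/zero and drop
        assert set(design.columns) == {"intercept", "trend"}

    def test_friston24_has_24_columns(self, rng):
        f24 = friston24(rng.standard_normal((30, 6)))
        assert f24.shape == (30, 24)
        # lag column shifts by one volume
        np.testing.assert_array_equal(
            f24["mot1_lag"].to_numpy()[1:], f24["mot1"].to_numpy()[:-1]
        )

    def test_wm_csf_included(self, rng):
        design = bg.build_nuisance_design(
            rng.normal(0, 0.05, (40, 6)), np.zeros(40, bool),
            rng.standard_normal(40), rng.standard_normal(40),
        )
        assert {"wm", "csf"} <= set(design.columns)


class TestRegression:
    def test_design_column_fits_perfectly(self, rng):
        mot = rng.normal(0, 0.05, size=(60, 6))
        design = bg.build_nuisance_design(mot, np.zeros(60, bool))
        ts = design[["trend"]].to_numpy() * 3.2
        resid = bg.regress_nuisance(ts, design)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_spike_volume_residual_is_zero(self, rng):
        mot = rng.normal(0, 0.05, size=(60, 6))
        mask = np.zeros(60, bool)
        mask[20] = True
        design = bg.build_nuisance_design(mot, mask)
        ts = rng.standard_normal((60, 5))
        resid = bg.regress_nuisance(ts, design)
        np.testing.assert_allclose(resid[20], 0, atol=1e-8)

    def test_residuals_match_normal_equations_oracle(self, rng):
        x = rng.standard_normal((20, 3))
        y = rng.standard_normal((20, 4))
        import pandas as pd
        resid = bg.regress_nuisance(y, pd.DataFrame(x), min_dof=10)
        beta = np.linalg.solve(x.T @ x, x.T @ y)  # independent normal equations
        np.testing.assert_allclose(resid, y - x @ beta, atol=1e-8)
        # orthogonality, scaled by norms
        inner = np.abs(x.T @ resid)
        scale = np.linalg.norm(x, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert np.all(inner <= 1e-8 * scale)

    def test_too_few_dof_signals_exclusion(self, rng):
        # every volume flagged: one spike column per volume leaves no dof
        mot = rng.normal(0, 0.05, size=(30, 6))
        mask = np.ones(30, bool)
        design = bg.build_nuisance_design(mot, mask)
        with pytest.raises(SubjectExclusionError):
            bg.regress_nuisance(rng.standard_normal((30, 3)), design)


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.04 * t)[:, None]  # on-bin at T=200, TR=2
        out = bg.bandpass_filter(sig, 0.01, 0.08, 2.0)
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.01)
        np.testing.assert_allclose(out[:, 0], sig[:, 0], atol=0.01)

    def test_stopband_sinusoid_removed(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)[:, None]
        out = bg.bandpass_filter(sig, 0.01, 0.08, 2.0)
        assert np.abs(out).max() < 0.01 * np.abs(sig).max()

    def test_constant_series_zeroed(self):
        out = bg.bandpass_filter(np.full((100, 3), 7.0))
        np.testing.assert_allclose(out, 0, atol=1e-10)

    def test_band_outside_nyquist_rejected(self, rng):
        with pytest.raises(ParameterError):
            bg.bandpass_filter(rng.standard_normal((50, 2)), 0.01, 0.3, 2.0)


class TestSubjectPipeline:
    def test_shapes_and_qc(self, rng):
        ts = rng.standard_normal((200, 10))
        mot = bg.simulate_motion(200, spike_rate=0.05, rng=rng)
        res = bg.preprocess_subject(ts, mot)
        assert res.timeseries.shape == (190, 10)
        assert res.fd.shape == (190,)
        assert res.mean_fd == pytest.approx(res.fd.mean())
        assert not res.excluded

    def test_gross_motion_flagged(self):
        mot = make_motion(200)
        mot[100:, 2] = 2.0  # 2 mm sustained shift
        assert gross_motion_exceeded(mot)
        ts = np.random.default_rng(0).standard_normal((200, 5))
        res = bg.preprocess_subject(ts, mot)
        assert res.excluded
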