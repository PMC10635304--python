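"""Feature selection, MLP training/prediction, APT reconstruction, loss."""

import numpy as np
import pytest

from synthcest.ml import (
    APTRegressor,
    apt_loss,
    feature_matrix,
    select_features,
)
from synthcest.params import AcquisitionParams, ZSpectrum, default_offset_grid
from synthcest.signal_model import lorentzian_line


class TestSelectFeatures:
    def test_window_boundaries_are_inclusive(self):
        off = np.array([-5.0, -0.5, 0.5, 2.5, -5.01, 0.51, 2.49])
        sel_off, _ = select_features(off, np.zeros_like(off))
        for boundary in (-5.0, -0.5, 0.5, 2.5):
            assert boundary in sel_off
        assert -5.01 in sel_off          # inside [-10, -5]
        assert 0.51 not in sel_off       # excluded band
        assert 2.49 not in sel_off       # excluded band

    def test_default_grid_keeps_37_points(self):
        off = default_offset_grid()
        sel_off, sel_val = select_features(off, np.arange(off.size, dtype=float))
        assert sel_off.size == 37  # 4 + 9 + 24 on the 87-point grid

    def test_selection_is_order_invariant(self):
        off = default_offset_grid()
        val = np.random.default_rng(0).uniform(0, 1, off.size)
        perm = np.random.default_rng(1).permutation(off.size)
        a = select_features(off, val)
        b = select_features(off[perm], val[perm])
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_missing_window_rejected(self):
        off = np.linspace(-10, 0, 30)  # nothing in [2.5, 10]
        with pytest.raises(ValueError, match="window"):
            select_features(off, np.zeros_like(off))


class TestAptLoss:
    off = default_offset_grid()

    def test_identical_spectra_have_zero_loss(self):
        s = lorentzian_line(0.05, 1.0, 3.5, self.off)
        assert apt_loss(s, s, self.off) == 0.0

    def test_constant_shift_gives_the_shift(self):
        s = lorentzian_line(0.05, 1.0, 3.5, self.off)
        assert apt_loss(s + 0.003, s, self.off) == pytest.approx(0.003)

    def test_loss_only_sees_2_to_5_ppm(self):
        s = np.zeros_like(self.off)
        outside = (self.off < 2.0) | (self.off > 5.0)
        t = np.where(outside, 10.0, 0.0)
        assert apt_loss(s, t, self.off) == 0.0

    def test_uncovered_window_rejected(self):
        off = np.linspace(-10, 0, 20)
        with pytest.raises(ValueError):
            apt_loss(np.zeros(20), np.zeros(20), off)


def _toy_dataset(n=400, seed=0, noise=0.0):
    """Features with a planted linear structure and (A, W) targets."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.0, 0.1, n)
    W = rng.uniform(0.5, 2.0, n)
    X = np.column_stack([A, W, A + W]) + rng.normal(0, noise, (n, 3))
    return X, np.column_stack([A, W])


class TestAPTRegressor:
    def test_constant_targets_are_learned(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (500, 5))
        y = np.tile([0.04, 1.5], (500, 1))
        m = APTRegressor(epochs=500, random_state=0).fit(X, y)
        pred = m.predict(X[:50])
        assert pred[:, 0].mean() == pytest.approx(0.04, abs=2e-3)
        assert pred[:, 1].mean() == pytest.approx(1.5, abs=0.02)
        np.testing.assert_allclose(pred[:, 0], 0.04, atol=0.02)
        np.testing.assert_allclose(pred[:, 1], 1.5, atol=0.2)

    def test_identical_seed_gives_identical_weights(self):
        X, y = _toy_dataset()
        m1 = APTRegressor(epochs=50, random_state=3).fit(X, y)
        m2 = APTRegressor(epochs=50, random_state=3).fit(X, y)
        for w1, w2 in zip(m1.weights_, m2.weights_):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(m1.predict(X[:10]), m2.predict(X[:10]))

    def test_different_seed_changes_weights(self):
        X, y = _toy_dataset()
        m1 = APTRegressor(epochs=30, random_state=3).fit(X, y)
        m2 = APTRegressor(epochs=30, random_state=4).fit(X, y)
        assert any(
            not np.array_equal(w1, w2)
            for w1, w2 in zip(m1.weights_, m2.weights_))

    def test_standardization_constants_stored_and_applied(self):
        X, y = _toy_dataset()
        m = APTRegressor(epochs=50, random_state=0).fit(X, y)
        assert m.x_mean_.shape == (3,)
        # manual forward pass through stored weights equals predict()
        xs = (X[:5] - m.x_mean_) / m.x_scale_
        a = np.maximum(xs @ m.weights_[0] + m.biases_[0], 0)
        a = np.maximum(a @ m.weights_[1] + m.biases_[1], 0)
        out = a @ m.weights_[2] + m.biases_[2]
        np.testing.assert_allclose(out, m.predict(X[:5]), rtol=1e-12)

    def test_feature_mismatch_rejected(self):
        X, y = _toy_dataset()
        m = APTRegressor(epochs=20, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="feature"):
            m.predict(np.zeros((2, 7)))

    def test_nonfinite_training_data_rejected(self):
        X, y = _toy_dataset()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            APTRegressor().fit(X, y)


class TestPredictApt:
    @pytest.fixture(scope="class")
    def model_and_grid(self):
        acq = AcquisitionParams()
        off = acq.offsets_ppm
        rng = np.random.default_rng(0)
        # spectra whose amide dip encodes (A, W) directly
        records_X, records_y, zs = [], [], []
        from synthcest.ml import select_features as sf
        for _ in range(600):
            a = rng.uniform(0.01, 0.08)
            w = rng.uniform(0.8, 2.0)
            z = 1 - lorentzian_line(0.7, 2.0, 0.0, off) - lorentzian_line(a, w, 3.5, off)
            sel_off, sel_val = sf(off, z)
            records_X.append(sel_val)
            records_y.append((a, w))
        m = APTRegressor(epochs=400, random_state=0).fit(
            np.array(records_X), np.array(records_y), feature_offsets=sel_off)
        return m, off

    def test_reconstruction_identities(self, model_and_grid):
        m, off = model_and_grid
        z = ZSpectrum(off, 1 - lorentzian_line(0.7, 2.0, 0.0, off)
                      - lorentzian_line(0.05, 1.2, 3.5, off))
        pred = m.predict_apt(z)
        i35 = np.argmin(np.abs(off - 3.5))
        assert pred.spectrum[i35] == pytest.approx(pred.A, rel=1e-12)
        # half maximum at center ± W/2 (evaluate analytically off-grid)
        half = lorentzian_line(pred.A, pred.W, 3.5,
                               np.array([3.5 + pred.W / 2]))[0]
        assert half == pytest.approx(pred.A / 2, rel=1e-12)

    def test_batch_prediction_over_voxel_stack_shape(self, model_and_grid):
        m, off = model_and_grid
        preds = []
        for i in range(16):
            z = ZSpectrum(off, 1 - lorentzian_line(0.7, 2.0, 0.0, off)
                          - lorentzian_line(0.02 + 0.002 * i, 1.5, 3.5, off))
            preds.append(m.predict_apt(z))
        assert len(preds) == 16
        assert all(p.spectrum.shape == off.shape for p in preds)

    def test_negative_amplitude_clamped_with_counter(self, model_and_grid):
        m, off = model_and_grid
        before = m.n_clamped_
        # spectrum with an amide *peak* (not dip) pushes A negative
        z = ZSpectrum(off, np.clip(
            1 - lorentzian_line(0.7, 2.0, 0.0, off)
            + lorentzian_line(0.04, 1.2, 3.5, off), 0, 1.05))
        pred = m.predict_apt(z)
        if pred.clamped:
            assert pred.A == 0.0
            assert m.n_clamped_ == before + 1
        else:  # regression can still return a small positive value
            assert pred.A >= 0.0


def test_feature_matrix_stacks_records(acq):
    from synthcest.synth_data import TrainingRecord
    off = acq.offsets_ppm
    recs = [
        TrainingRecord(
            offsets=off, features=np.full(off.size, 0.5),
            target_A=0.01 * (i + 1), target_W=1.0,
            truth_offsets=off, truth_spectrum=np.zeros(off.size))
        for i in range(3)
    ]
    X, y, sel = feature_matrix(recs)
    assert X.shape == (3, 37) and y.shape == (3, 2)
    assert sel.size == 37
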