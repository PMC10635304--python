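"""Neural-network prediction of the amide CESTR peak.

The regressor maps a reduced Z-spectrum to the amplitude A and width W
of the amide CESTR peak; the APT spectrum is then reconstructed as a
Lorentzian centred at the amide offset.  Input features are the spectrum
samples inside three windows — [−10, −5], [−0.5, 0.5] and [2.5, 10] ppm
— the intermediate offsets being excluded because their influence on the
3.5 ppm signal is negligible.  The network is a multilayer perceptron
with two hidden layers of 100 ReLU units and a two-node linear output,
trained with Adam on a mean-squared-error loss with per-feature input
standardization and early stopping on a held-out validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .params import ZSpectrum
from .signal_model import lorentzian_line

__all__ = [
    "FEATURE_WINDOWS",
    "LOSS_WINDOW",
    "select_features",
    "feature_matrix",
    "APTPrediction",
    "APTRegressor",
    "apt_loss",
]

#: closed feature-selection intervals in ppm
FEATURE_WINDOWS = ((-10.0, -5.0), (-0.5, 0.5), (2.5, 10.0))

#: evaluation window of the APT-spectrum loss, ppm
LOSS_WINDOW = (2.0, 5.0)

AMIDE_PPM = 3.5


def _window_mask(offsets):
    offsets = np.asarray(offsets, dtype=float)
    mask = np.zeros(offsets.shape, dtype=bool)
    for lo, hi in FEATURE_WINDOWS:
        mask |= (offsets >= lo) & (offsets <= hi)
    return mask


def select_features(z, values=None):
    """Restrict a Z-spectrum to the feature windows.

    Accepts a :class:`ZSpectrum` or an ``(offsets, values)`` pair and
    returns ``(offsets_sel, values_sel)`` sorted by offset.  Raises if
    the grid contributes no point inside one of the windows.
    """
    if isinstance(z, ZSpectrum):
        offsets, values = z.offsets, z.values
    else:
        offsets = np.asarray(z, dtype=float)
        values = np.asarray(values, dtype=float)
    order = np.argsort(offsets, kind="stable")
    offsets, values = offsets[order], values[order]
    mask = _window_mask(offsets)
    for lo, hi in FEATURE_WINDOWS:
        if not np.any((offsets >= lo) & (offsets <= hi)):
            raise ValueError(f"grid has no samples inside the window [{lo}, {hi}] ppm")
    return offsets[mask], values[mask]


def feature_matrix(records):
    """Stack training records into (X, y) feature/target matrices."""
    X, y = [], []
    sel_offsets = None
    for rec in records:
        off, val = select_features(rec.offsets, rec.features)
        if sel_offsets is None:
            sel_offsets = off
        X.append(val)
        y.append((rec.target_A, rec.target_W))
    return np.asarray(X), np.asarray(y), sel_offsets


@dataclass
class APTPrediction:
    """Predicted amide peak (A, W) and its Lorentzian reconstruction."""

    A: float
    W: float
    offsets: np.ndarray
    spectrum: np.ndarray
    clamped: bool = False


class APTRegressor(BaseEstimator, RegressorMixin):
    """MLP regressor of the amide CESTR peak amplitude and width.

    Parameters
    ----------
    hidden_layer_sizes : tuple
        Hidden layer widths (default two layers of 100).
    epochs : int
        Maximum number of Adam epochs; training normally ends earlier
        when the validation loss stops improving.
    learning_rate, batch_size : float, int
        Adam step size and minibatch size.
    validation_fraction : float
        Held-out fraction used by early stopping.
    patience : int
        Epochs without validation improvement before stopping (best
        weights are restored).
    random_state : int
        Seeds the weight initialization, shuffling and validation split;
        identical data + parameters + seed give identical weights.

    Attributes
    ----------
    weights_, biases_ : list of ndarray — fitted layer parameters
    x_mean_, x_scale_ : ndarray — feature standardization constants
    feature_offsets_ : ndarray — ppm grid of the selected features
    loss_curve_, validation_scores_ : training history
    """

    def __init__(self, hidden_layer_sizes=(100, 100), epochs=4000,
                 learning_rate=1e-3, batch_size=64, validation_fraction=0.1,
                 patience=50, tol=0.0, random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y, feature_offsets=None):
        """Fit on a feature matrix (n, d) and targets (n, 2) = (A, W)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("X must be 2-D with one target row per sample")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in the training data")
        self.x_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.x_scale_ = np.where(scale > 0, scale, 1.0)
        Xs = (X - self.x_mean_) / self.x_scale_

        # early stopping scores a validation split; with (near-)constant
        # targets that score is undefined, so train for the full budget
        use_early_stop = bool(np.any(y.std(axis=0) > 1e-12))
        mlp = MLPRegressor(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=self.batch_size,
            max_iter=self.epochs,
            early_stopping=use_early_stop,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.patience,
            tol=self.tol,
            shuffle=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            # hitting the epoch cap is an accepted outcome, not a failure
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            mlp.fit(Xs, y)
        if not np.all(np.isfinite(mlp.loss_curve_)):
            raise RuntimeError("training diverged: non-finite loss")
        self.weights_ = [w.copy() for w in mlp.coefs_]
        self.biases_ = [b.copy() for b in mlp.intercepts_]
        self.loss_curve_ = list(mlp.loss_curve_)
        self.validation_scores_ = (
            list(mlp.validation_scores_) if use_early_stop else [])
        self.n_epochs_ = mlp.n_iter_
        self.n_features_in_ = X.shape[1]
        self.feature_offsets_ = (
            None if feature_offsets is None else np.asarray(feature_offsets, float)
        )
        self.n_clamped_ = 0
        return self

    def _forward(self, Xs):
        a = Xs
        last = len(self.weights_) - 1
        for i, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            a = a @ w + b
            if i < last:
                a = np.maximum(a, 0.0)
        return a

    def predict(self, X):
        """Predict (A, W) rows for a feature matrix."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("fit the model before predicting")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: model expects {self.n_features_in_} "
                f"features, got {X.shape[1]}"
            )
        return self._forward((X - self.x_mean_) / self.x_scale_)

    def predict_apt(self, z, offsets=None) -> APTPrediction:
        """Predict the APT spectrum of one Z-spectrum.

        Returns the predicted (A, W) and the Lorentzian reconstruction
        centred at the amide offset on the requested (default: full
        input) grid.  Negative predicted amplitudes are clamped to zero
        and counted in ``n_clamped_``.
        """
        if isinstance(z, ZSpectrum):
            grid = z.offsets if offsets is None else np.asarray(offsets, float)
            sel_off, x = select_features(z)
        else:
            raise TypeError("predict_apt expects a ZSpectrum")
        if self.feature_offsets_ is not None and not np.array_equal(
            sel_off, self.feature_offsets_
        ):
            raise ValueError("spectrum grid does not match the model's feature grid")
        a, w = self.predict(x[None, :])[0]
        clamped = a < 0
        if clamped:
            self.n_clamped_ += 1
            a = 0.0
        w = max(w, 1e-6)
        spec = lorentzian_line(a, w, AMIDE_PPM, grid)
        return APTPrediction(float(a), float(w), grid, spec, clamped=bool(clamped))


def apt_loss(pred, truth, offsets) -> float:
    """Mean absolute difference of two APT spectra over the 2–5 ppm window."""
    offsets = np.asarray(offsets, dtype=float)
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != offsets.shape or truth.shape != offsets.shape:
        raise ValueError("spectra and offsets must share one grid")
    lo, hi = LOSS_WINDOW
    mask = (offsets >= lo) & (offsets <= hi)
    if not np.any(mask):
        raise ValueError("grid does not cover the 2-5 ppm loss window")
    return float(np.mean(np.abs(pred[mask] - truth[mask])))
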