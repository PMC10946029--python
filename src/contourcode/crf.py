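"""Classical receptive field model: 2-D Gaussian fit and 2-SD extent test.

The CRF of a neuron is estimated from its mean responses to small grating
patches shown on a position grid (5 x 5 by default).  The response surface
is approximated by an axis-aligned 2-D Gaussian

    r(x, y) = baseline + amplitude * exp(-((x-cx)^2 / (2 sx^2)
                                           + (y-cy)^2 / (2 sy^2)))

and the CRF extent is the open 2-SD ellipse:  a point is inside iff
((x-cx)/sx)^2 + ((y-cy)/sy)^2 < 4  (strict inequality).  All local feature
computations downstream are gated by this test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator


class DegenerateGridError(ValueError):
    """The response grid carries no spatial signal (all responses equal)."""


@dataclass(frozen=True)
class CRFModel:
    """Fitted classical receptive field (axis-aligned 2-D Gaussian)."""

    center: tuple[float, float]
    sd: tuple[float, float]
    amplitude: float = 1.0
    baseline: float = 0.0
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        if self.sd[0] <= 0 or self.sd[1] <= 0:
            raise ValueError("CRF SDs must be positive")

    def in_extent(self, points: np.ndarray) -> np.ndarray:
        """True for points strictly inside the 2-SD ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = (((pts[:, 0] - self.center[0]) / self.sd[0]) ** 2
             + ((pts[:, 1] - self.center[1]) / self.sd[1]) ** 2)
        out = q < 4.0
        return out if np.asarray(points).ndim > 1 else bool(out[0])

    def predict(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = ((pts[:, 0] - self.center[0]) ** 2 / (2 * self.sd[0] ** 2)
             + (pts[:, 1] - self.center[1]) ** 2 / (2 * self.sd[1] ** 2))
        return self.baseline + self.amplitude * np.exp(-z)


@dataclass(frozen=True)
class RFGrid:
    """Mean responses of one neuron to grating patches on a position grid."""

    positions: np.ndarray  # (n, 2) grid positions
    responses: np.ndarray  # (n,) mean responses

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) != len(resp):
            raise ValueError("positions must be (n, 2) matching responses")
        if len(np.unique(pos, axis=0)) < 4:
            raise ValueError("need at least 4 distinct grid positions")
        if np.any(resp < 0):
            raise ValueError("grid responses must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "responses", resp)


def _gauss2d(xy, cx, cy, sx, sy, amp, base):
    x, y = xy
    return base + amp * np.exp(-((x - cx) ** 2 / (2 * sx**2)
                                 + (y - cy) ** 2 / (2 * sy**2)))


class GaussianReceptiveField(BaseEstimator):
    """Sklearn-style estimator for the 2-D Gaussian receptive field.

    Parameters
    ----------
    clip_negative_baseline : bool
        Clip a negative fitted baseline to zero (robustness on noisy grids).

    Attributes
    ----------
    center_, sd_, amplitude_, baseline_ : fitted Gaussian parameters.
    residual_norm_ : float
        Euclidean norm of the fit residuals (diagnostic).
    model_ : CRFModel
        Immutable snapshot of the fitted parameters.
    """

    def __init__(self, clip_negative_baseline: bool = True):
        self.clip_negative_baseline = clip_negative_baseline

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise DegenerateGridError("all grid responses are equal; "
                                      "receptive field unfittable")
        base0 = float(np.min(y))
        amp0 = float(np.ptp(y))
        w = np.clip(y - base0, 0, None)
        w = w / w.sum()
        cx0, cy0 = (w @ X[:, 0], w @ X[:, 1])
        # grid pitch lower-bounds the initial SD guess
        ux = np.unique(X[:, 0])
        pitch = float(np.min(np.diff(ux))) if len(ux) > 1 else 1.0
        sx0 = max(np.sqrt(w @ (X[:, 0] - cx0) ** 2), pitch / 2)
        sy0 = max(np.sqrt(w @ (X[:, 1] - cy0) ** 2), pitch / 2)

        span_x = np.ptp(X[:, 0]) or pitch
        span_y = np.ptp(X[:, 1]) or pitch
        lo = [X[:, 0].min() - span_x, X[:, 1].min() - span_y,
              pitch * 1e-3, pitch * 1e-3, 0.0, -np.inf]
        hi = [X[:, 0].max() + span_x, X[:, 1].max() + span_y,
              4 * span_x, 4 * span_y, np.inf, np.inf]
        p0 = np.clip([cx0, cy0, sx0, sy0, amp0, base0], lo, hi)
        params, _ = curve_fit(
            _gauss2d, (X[:, 0], X[:, 1]), y, p0=p0, bounds=(lo, hi),
            maxfev=20000,
        )
        cx, cy, sx, sy, amp, base = params
        if self.clip_negative_baseline and base < 0:
            base = 0.0
        resid = y - _gauss2d((X[:, 0], X[:, 1]), cx, cy, sx, sy, amp, base)
        self.center_ = (float(cx), float(cy))
        self.sd_ = (float(sx), float(sy))
        self.amplitude_ = float(amp)
        self.baseline_ = float(base)
        self.residual_norm_ = float(np.linalg.norm(resid))
        self.model_ = CRFModel(self.center_, self.sd_, self.amplitude_,
                               self.baseline_, self.residual_norm_)
        return self

    def predict(self, X):
        return self.model_.predict(X)


def fit_crf(grid: RFGrid, clip_negative_baseline: bool = True) -> CRFModel:
    """Fit the 2-D Gaussian CRF model to a grating response grid.

    Raises :class:`DegenerateGridError` when the grid carries no signal;
    callers should exclude such neurons downstream.
    """
    est = GaussianReceptiveField(clip_negative_baseline=clip_negative_baseline)
    est.fit(grid.positions, grid.responses)
    return est.model_


def in_extent(crf: CRFModel, point) -> bool | np.ndarray:
    """Strict 2-SD ellipse membership test (thin wrapper)."""
    return crf.in_extent(point)
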