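"""Constant-velocity Kalman filter over the box state
(cx, cy, a, h) + velocities — the standard SORT-family motion model.

The state is 8-dimensional: box centre, aspect ratio ``a = w/h``,
height, and their per-frame velocities.  Process and measurement noise
scale with the box height, so uncertainty grows with apparent object
size; the scale weights follow the SORT convention (1/20 for position,
1/160 for velocity).
"""

from __future__ import annotations

import numpy as np

from .geometry import BoundingBox

__all__ = ["KalmanBoxFilter", "box_to_state", "state_to_box"]

STD_WEIGHT_POSITION = 1.0 / 20.0
STD_WEIGHT_VELOCITY = 1.0 / 160.0


def box_to_state(box: BoundingBox) -> np.ndarray:
    """(cx, cy, a, h) measurement vector for a box."""
    return np.array(
        [box.x + box.w / 2.0, box.y + box.h / 2.0, box.w / box.h, box.h]
    )


def state_to_box(mean: np.ndarray) -> BoundingBox:
    """Box from the first four state components; degenerate states are
    clamped to a 1-px minimum size."""
    cx, cy, a, h = mean[:4]
    h = max(float(h), 1.0)
    w = max(float(a) * h, 1.0)
    return BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)


class KalmanBoxFilter:
    """Linear-Gaussian recursive estimator for one track."""

    def __init__(self) -> None:
        ndim, dt = 4, 1.0
        self._F = np.eye(2 * ndim)
        for i in range(ndim):
            self._F[i, ndim + i] = dt
        self._H = np.eye(ndim, 2 * ndim)

    def initiate(self, measurement: np.ndarray):
        """Prior from a first detection: zero velocity, height-scaled
        covariance."""
        mean = np.concatenate([measurement, np.zeros(4)])
        h = measurement[3]
        std = [
            2 * STD_WEIGHT_POSITION * h,
            2 * STD_WEIGHT_POSITION * h,
            1e-2,
            2 * STD_WEIGHT_POSITION * h,
            10 * STD_WEIGHT_VELOCITY * h,
            10 * STD_WEIGHT_VELOCITY * h,
            1e-5,
            10 * STD_WEIGHT_VELOCITY * h,
        ]
        return mean, np.diag(np.square(std))

    def predict(self, mean: np.ndarray, cov: np.ndarray):
        h = mean[3]
        std = [
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_POSITION * h,
            1e-2,
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_VELOCITY * h,
            STD_WEIGHT_VELOCITY * h,
            1e-5,
            STD_WEIGHT_VELOCITY * h,
        ]
        q = np.diag(np.square(std))
        mean = self._F @ mean
        cov = self._F @ cov @ self._F.T + q
        return mean, cov

    def update(self, mean: np.ndarray, cov: np.ndarray,
               measurement: np.ndarray):
        h = mean[3]
        std = [
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_POSITION * h,
            1e-1,
            STD_WEIGHT_POSITION * h,
        ]
        r = np.diag(np.square(std))
        s = self._H @ cov @ self._H.T + r
        k = cov @ self._H.T @ np.linalg.solve(s, np.eye(4)).T
        innovation = measurement - self._H @ mean
        new_mean = mean + k @ innovation
        new_cov = cov - k @ s @ k.T
        return new_mean, new_cov
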