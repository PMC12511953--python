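"""Constant-velocity Kalman filter over (cx, cy, a, h) box states.

The state vector is (cx, cy, a, h, v_cx, v_cy, v_a, v_h): box center, aspect
ratio a = width/height, height, and their per-frame velocities (dt = 1
frame).  Using the aspect ratio directly in the state means the tracker and
the movement-amplitude analysis share a single definition of the
aspect-ratio coefficient.

Prediction follows the standard linear system

    x_k = F x_{k-1} + B u_k        (B u fixed at zero: no control input)
    P_k = F P_{k-1} F' + Q_k

and the correction step is the standard Kalman update in Joseph form.
Default noise covariances follow the SORT/ByteTrack convention of scaling
position standard deviations with the box height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import InvalidArgumentError, NumericalError
from .geometry import Box

__all__ = [
    "KalmanState",
    "transition_matrix",
    "initiate",
    "default_process_noise",
    "default_measurement_noise",
    "kalman_predict",
    "kalman_update",
]

#: std of position/size noise, as a fraction of box height (SORT convention)
STD_WEIGHT_POSITION = 1.0 / 20
#: std of velocity noise, as a fraction of box height
STD_WEIGHT_VELOCITY = 1.0 / 160

_H = np.hstack([np.eye(4), np.zeros((4, 4))])  # measurement matrix


@dataclass
class KalmanState:
    """Gaussian belief over the 8-D box state: mean vector and covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(8)
        self.cov = np.asarray(self.cov, dtype=float).reshape(8, 8)
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise InvalidArgumentError("covariance must be symmetric within 1e-9")

    def box(self) -> Box:
        cx, cy, a, h = self.mean[:4]
        h = max(h, 0.0)
        return Box.from_xyah(cx, cy, max(a, 0.0), h)


def transition_matrix() -> np.ndarray:
    """8x8 constant-velocity transition for dt = 1 frame."""
    f = np.eye(8)
    f[:4, 4:] = np.eye(4)
    return f


def initiate(box: Box) -> KalmanState:
    """Belief for a newly observed box: measured position, zero velocity,
    height-scaled uncertainty (velocities weakly constrained)."""
    cx, cy, a, h = box.to_xyah()
    mean = np.array([cx, cy, a, h, 0.0, 0.0, 0.0, 0.0])
    std = np.array(
        [
            2 * STD_WEIGHT_POSITION * h,
            2 * STD_WEIGHT_POSITION * h,
            1e-2,
            2 * STD_WEIGHT_POSITION * h,
            10 * STD_WEIGHT_VELOCITY * h,
            10 * STD_WEIGHT_VELOCITY * h,
            1e-5,
            10 * STD_WEIGHT_VELOCITY * h,
        ]
    )
    return KalmanState(mean, np.diag(std**2))


def default_process_noise(h: float) -> np.ndarray:
    std = np.array(
        [
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_POSITION * h,
            1e-2,
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_VELOCITY * h,
            STD_WEIGHT_VELOCITY * h,
            1e-5,
            STD_WEIGHT_VELOCITY * h,
        ]
    )
    return np.diag(std**2)


def default_measurement_noise(h: float) -> np.ndarray:
    std = np.array(
        [
            STD_WEIGHT_POSITION * h,
            STD_WEIGHT_POSITION * h,
            1e-1,
            STD_WEIGHT_POSITION * h,
        ]
    )
    return np.diag(std**2)


def _check_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (8, 8) and m.shape != (4, 4):
        raise InvalidArgumentError(f"{name} must be square 4x4 or 8x8, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-9):
        raise InvalidArgumentError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(m).min() < -1e-8:
        raise InvalidArgumentError(f"{name} must be positive semidefinite")
    return m


def kalman_predict(s: KalmanState, F=None, Q=None) -> KalmanState:
    """A-priori state: mean <- F mean, cov <- F cov F' + Q.

    ``F`` defaults to the constant-velocity transition, ``Q`` to the
    height-scaled diagonal process noise.  ``Q`` must be PSD; the covariance
    trace can only grow (or stay equal for Q = 0).
    """
    F = transition_matrix() if F is None else np.asarray(F, dtype=float)
    if F.shape != (8, 8):
        raise InvalidArgumentError(f"F must be 8x8, got {F.shape}")
    Q = default_process_noise(s.mean[3]) if Q is None else _check_psd(Q, "Q")
    mean = F @ s.mean
    cov = F @ s.cov @ F.T + Q
    return KalmanState(mean, 0.5 * (cov + cov.T))


def kalman_update(s: KalmanState, z, R=None) -> KalmanState:
    """Posterior state after measuring z = (cx, cy, a, h).

    ``R`` (positive definite) defaults to the height-scaled diagonal
    measurement noise.  Uses the Joseph-form covariance update; a singular
    innovation covariance raises :class:`NumericalError`.
    """
    z = np.asarray(z, dtype=float).reshape(4)
    if R is None:
        R = default_measurement_noise(s.mean[3])
    else:
        R = np.asarray(R, dtype=float)
        if R.shape != (4, 4):
            raise InvalidArgumentError(f"R must be 4x4, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-9):
            raise InvalidArgumentError("R must be symmetric")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise InvalidArgumentError("R must be positive definite")
    innovation_cov = _H @ s.cov @ _H.T + R
    try:
        chol = linalg.cho_factor(innovation_cov, lower=True)
        gain = linalg.cho_solve(chol, _H @ s.cov).T  # (8, 4)
    except linalg.LinAlgError as exc:
        raise NumericalError(f"singular innovation covariance: {exc}") from exc
    innovation = z - _H @ s.mean
    mean = s.mean + gain @ innovation
    ikh = np.eye(8) - gain @ _H
    cov = ikh @ s.cov @ ikh.T + gain @ R @ gain.T
    return KalmanState(mean, 0.5 * (cov + cov.T))
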