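"""Constant-velocity Kalman filter over box geometry.

State is the 8-vector (cx, cy, a, h, vcx, vcy, va, vh) where a = width /
height; the measurement is (cx, cy, a, h).  Process and measurement noise
scale with the box height h so the filter is equally tolerant for small and
large fish.  The Mahalanobis distance of a measurement under the predicted
innovation covariance feeds the cascade's Motion stage; the conventional
gate is the chi-square 95th percentile at 4 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import chi2

from .boxes import BoundingBox

#: chi-square 0.95 quantile, 4 dof — the default Motion-stage gate.
CHI2_GATE_95_4DOF: float = float(chi2.ppf(0.95, df=4))


class NumericalError(RuntimeError):
    """Covariance lost positive definiteness (collapsed/degenerate state)."""


@dataclass(frozen=True)
class TrackState:
    """Kalman mean and covariance; immutable snapshot of one track."""

    mean: np.ndarray  # shape (8,)
    covariance: np.ndarray  # shape (8, 8)

    def predicted_box(self) -> BoundingBox:
        cx, cy, a, h = self.mean[:4]
        return BoundingBox.from_cah(cx, cy, max(a, 1e-6), max(h, 1e-6))


def linear_update(
    mean: np.ndarray,
    cov: np.ndarray,
    measurement: np.ndarray,
    H: np.ndarray,
    R: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic linear Kalman correction (Joseph-free, Cholesky gain).

    Exposed separately so the scalar closed forms (gain 1/2 for unit prior
    and measurement variance, etc.) can be checked directly.
    """
    S = H @ cov @ H.T + R
    try:
        chol = scipy.linalg.cho_factor(S, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"innovation covariance not positive definite: {exc}") from exc
    K = scipy.linalg.cho_solve(chol, (cov @ H.T).T, check_finite=False).T
    innovation = measurement - H @ mean
    new_mean = mean + K @ innovation
    new_cov = cov - K @ S @ K.T
    new_cov = (new_cov + new_cov.T) / 2.0  # keep symmetric under roundoff
    return new_mean, new_cov


class KalmanBoxFilter:
    """Shared filter object; per-track state lives in :class:`TrackState`.

    Noise weights follow the tracking-by-detection convention: position /
    height standard deviations proportional to h (1/20 by default), velocity
    standard deviations proportional to h (1/160), aspect noise constant.
    """

    ndim = 4

    def __init__(
        self,
        std_pos_weight: float = 1.0 / 20,
        std_vel_weight: float = 1.0 / 160,
        std_aspect_proc: float = 1e-2,
        std_aspect_vel_proc: float = 1e-5,
        std_aspect_meas: float = 1.0,
        std_height_meas_weight: float = 1.0 / 2,
    ) -> None:
        self.std_pos_weight = std_pos_weight
        self.std_vel_weight = std_vel_weight
        self.std_aspect_proc = std_aspect_proc
        self.std_aspect_vel_proc = std_aspect_vel_proc
        # shape measurements are far noisier than centroids for non-rigid
        # swimmers: tail beats and turns change a and h by tens of percent
        # per frame, so gating must not evict a pair over deformation alone
        self.std_aspect_meas = std_aspect_meas
        self.std_height_meas_weight = std_height_meas_weight
        self._F = np.eye(8)
        self._F[:4, 4:] = np.eye(4)  # unit time step: one frame
        self._H = np.zeros((4, 8))
        self._H[:4, :4] = np.eye(4)

    # -- noise models -------------------------------------------------

    def _process_noise(self, h: float) -> np.ndarray:
        std = np.array(
            [
                self.std_pos_weight * h,
                self.std_pos_weight * h,
                self.std_aspect_proc,
                self.std_pos_weight * h,
                self.std_vel_weight * h,
                self.std_vel_weight * h,
                self.std_aspect_vel_proc,
                self.std_vel_weight * h,
            ]
        )
        return np.diag(std**2)

    def _measurement_noise(self, h: float) -> np.ndarray:
        std = np.array(
            [
                self.std_pos_weight * h,
                self.std_pos_weight * h,
                self.std_aspect_meas,
                self.std_height_meas_weight * h,
            ]
        )
        return np.diag(std**2)

    # -- filter steps -------------------------------------------------

    def init_state(self, box: BoundingBox) -> TrackState:
        """Start a track at a detection: zero velocity, h-scaled spread."""
        mean = np.zeros(8)
        mean[:4] = box.to_cah()
        h = box.height
        std = np.array(
            [
                2 * self.std_pos_weight * h,
                2 * self.std_pos_weight * h,
                max(2 * self.std_aspect_proc, 1e-2),
                2 * self.std_pos_weight * h,
                10 * self.std_vel_weight * h,
                10 * self.std_vel_weight * h,
                max(10 * self.std_aspect_vel_proc, 1e-5),
                10 * self.std_vel_weight * h,
            ]
        )
        std = np.maximum(std, 1e-6)  # positive diagonal even at zero weights
        return TrackState(mean, np.diag(std**2))

    def predict(self, state: TrackState) -> TrackState:
        mean = self._F @ state.mean
        cov = self._F @ state.covariance @ self._F.T + self._process_noise(mean[3])
        cov = (cov + cov.T) / 2.0
        return TrackState(mean, cov)

    def update(self, state: TrackState, box: BoundingBox) -> TrackState:
        z = np.asarray(box.to_cah())
        R = self._measurement_noise(state.mean[3])
        mean, cov = linear_update(state.mean, state.covariance, z, self._H, R)
        return TrackState(mean, cov)

    def gating_distance(self, state: TrackState, box: BoundingBox) -> float:
        """Squared Mahalanobis distance of the measurement from the
        predicted measurement under the innovation covariance."""
        return float(self.gating_distances(state, [box])[0])

    def gating_distances(self, state: TrackState, boxes: list[BoundingBox]) -> np.ndarray:
        S = (
            self._H @ state.covariance @ self._H.T
            + self._measurement_noise(state.mean[3])
        )
        try:
            chol = scipy.linalg.cho_factor(S, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular innovation covariance (degenerate state): {exc}"
            ) from exc
        z = np.array([b.to_cah() for b in boxes])
        d = z - self._H @ state.mean
        solved = scipy.linalg.cho_solve(chol, d.T, check_finite=False)
        return np.einsum("ij,ji->i", d, solved)
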