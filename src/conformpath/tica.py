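"""Time-lagged independent component analysis (slow linear modes of a trajectory)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .featurize import FeatureTrajectory

__all__ = ["TICAModel", "fit_tica", "transform"]


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray            # symmetrized time-lagged covariance
    eigenvalues: np.ndarray     # descending
    components: np.ndarray      # (d, n_components), C0-orthonormal columns
    epsilon: float
    labels: list[str] = None


def _traj_list(features) -> list[FeatureTrajectory]:
    return [features] if isinstance(features, FeatureTrajectory) else list(features)


def fit_tica(
    features: FeatureTrajectory | Sequence[FeatureTrajectory],
    lag: int,
    n_components: int | None = None,
    epsilon: float | None = None,
) -> TICAModel:
    """Solve the symmetrized generalized eigenproblem C_tau v = lambda (C_0 + eps I) v.

    Data are mean-free; C_tau is symmetrized as (C_tau + C_tau^T)/2 so the
    spectrum is real. ``epsilon`` defaults to 1e-6 * trace(C_0)/d; pass 0 to
    disable regularization (rank-deficient C_0 then raises).
    """
    trajs = _traj_list(features)
    d = trajs[0].n_features
    labels = trajs[0].labels
    if any(t.n_features != d for t in trajs):
        raise ValueError("feature dimension mismatch across trajectories")
    if all(len(t) <= lag for t in trajs):
        raise ValueError("need at least one trajectory longer than the lag")
    if n_components is None:
        n_components = d
    if n_components > d:
        raise ValueError("cannot request more components than features")

    x_all = np.vstack([t.values for t in trajs])
    mean = x_all.mean(axis=0)

    c0 = np.zeros((d, d))
    ctau = np.zeros((d, d))
    n0 = ntau = 0
    for t in trajs:
        x = t.values - mean
        c0 += x.T @ x
        n0 += len(x)
        if len(x) > lag:
            x0, xt = x[:-lag], x[lag:]
            ctau += x0.T @ xt
            ntau += len(x0)
    c0 /= n0
    ctau /= ntau
    ctau = 0.5 * (ctau + ctau.T)

    if epsilon is None:
        epsilon = 1e-6 * np.trace(c0) / d
    if epsilon == 0.0:
        eigvals_c0 = np.linalg.eigvalsh(c0)
        if eigvals_c0.min() < 1e-12 * max(eigvals_c0.max(), 1e-300):
            raise ValueError(
                "instantaneous covariance is rank deficient; pass epsilon > 0 to regularize"
            )
    reg = c0 + epsilon * np.eye(d)
    eigenvalues, vectors = scipy.linalg.eigh(ctau, reg)
    order = np.argsort(-eigenvalues)
    eigenvalues = eigenvalues[order][:n_components]
    components = vectors[:, order][:, :n_components]
    return TICAModel(
        lag=lag, mean=mean, c0=c0, ctau=ctau,
        eigenvalues=eigenvalues, components=components,
        epsilon=float(epsilon), labels=list(labels),
    )


def transform(
    model: TICAModel,
    features: FeatureTrajectory,
    n_components: int | None = None,
) -> FeatureTrajectory:
    """Project a trajectory onto the leading tICA components."""
    if features.labels != model.labels:
        raise ValueError("feature labels do not match the trained model")
    comps = model.components if n_components is None else model.components[:, :n_components]
    y = (features.values - model.mean) @ comps
    labels = [f"tic{i + 1}" for i in range(y.shape[1])]
    return FeatureTrajectory(y, labels=labels, dt=features.dt)
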