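"""2-D free-energy landscapes from feature trajectories, with structure projection.

F = -kT ln(p / p_max), shifted so the most populated bin sits at 0 kcal/mol.
Empty bins carry an infinite sentinel rather than a fake 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import KT_300K
from .featurize import FeatureTrajectory, order_params
from .structure_io import BWMap, Structure

__all__ = [
    "FreeEnergyLandscape",
    "estimate_landscape",
    "project_structures",
    "landscape_convergence",
    "DEFAULT_RANGE",
]

DEFAULT_RANGE = ((15.0, 25.0), (30.0, 80.0))


@dataclass
class FreeEnergyLandscape:
    edges: tuple[np.ndarray, np.ndarray]
    prob: np.ndarray
    free_energy: np.ndarray
    kT: float

    @property
    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ex, ey = self.edges
        return 0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:])

    def locate(self, point: Sequence[float]) -> tuple[int, int] | None:
        """Bin index of a point, or None when out of range."""
        x, y = point
        ex, ey = self.edges
        if not (ex[0] <= x <= ex[-1] and ey[0] <= y <= ey[-1]):
            return None
        i = min(int(np.searchsorted(ex, x, side="right")) - 1, len(ex) - 2)
        j = min(int(np.searchsorted(ey, y, side="right")) - 1, len(ey) - 2)
        return max(i, 0), max(j, 0)

    def to_csv(self, path) -> None:
        cx, cy = self.bin_centers
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        df = pd.DataFrame(
            {
                "center_x": gx.ravel(),
                "center_y": gy.ravel(),
                "p": self.prob.ravel(),
                "F": self.free_energy.ravel(),
            }
        )
        df.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "kT": self.kT,
            "bins": [len(self.edges[0]) - 1, len(self.edges[1]) - 1],
            "range": [
                [float(self.edges[0][0]), float(self.edges[0][-1])],
                [float(self.edges[1][0]), float(self.edges[1][-1])],
            ],
        }


def estimate_landscape(
    features: FeatureTrajectory,
    bins: int | Sequence[int] = 100,
    kT: float = KT_300K,
    value_range: Sequence = None,
    columns: Sequence[int] = (0, 1),
    smooth_sigma: float = 0.0,
) -> FreeEnergyLandscape:
    """Histogram-based free-energy estimate over two feature columns.

    Optional Gaussian bin smoothing is off by default (``smooth_sigma`` in bins).
    """
    if len(features) == 0:
        raise ValueError("empty trajectory")
    data = features.values[:, list(columns)]
    if data.shape[1] != 2:
        raise ValueError("two feature columns required")
    bins = np.broadcast_to(np.asarray(bins, dtype=int), (2,))
    if np.any(bins < 10):
        raise ValueError("need at least 10 bins per dimension")
    if value_range is None:
        value_range = [
            (data[:, 0].min(), data[:, 0].max()),
            (data[:, 1].min(), data[:, 1].max()),
        ]
    counts, ex, ey = np.histogram2d(
        data[:, 0], data[:, 1], bins=tuple(int(b) for b in bins), range=value_range
    )
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        counts = gaussian_filter(counts, sigma=smooth_sigma)
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples fall inside the landscape range")
    prob = counts / total
    with np.errstate(divide="ignore"):
        free_energy = np.where(
            prob > 0, -kT * np.log(prob / prob.max()), np.inf
        )
    return FreeEnergyLandscape(edges=(ex, ey), prob=prob, free_energy=free_energy, kT=kT)


def project_structures(
    structures: Iterable[Structure],
    bw_maps: BWMap | Sequence[BWMap],
    landscape: FreeEnergyLandscape,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Order parameters of external structures located on the landscape.

    Out-of-range points are flagged (``in_range = False``), not dropped.
    """
    structures = list(structures)
    if isinstance(bw_maps, dict):
        bw_maps = [bw_maps] * len(structures)
    rows = []
    for idx, (s, bw) in enumerate(zip(structures, bw_maps)):
        op = order_params(s, bw)
        loc = landscape.locate((op.distance, op.angle))
        rows.append(
            {
                "name": names[idx] if names else f"structure_{idx}",
                "distance": op.distance,
                "angle": op.angle,
                "bin_x": loc[0] if loc else -1,
                "bin_y": loc[1] if loc else -1,
                "F": float(landscape.free_energy[loc]) if loc else np.nan,
                "in_range": loc is not None,
            }
        )
    return pd.DataFrame(rows)


def landscape_convergence(
    features: FeatureTrajectory | Sequence[FeatureTrajectory],
    n_splits: int = 2,
    bins: int | Sequence[int] = 50,
    kT: float = KT_300K,
    value_range: Sequence = None,
    f_cap: float = 5.0,
) -> float:
    """RMS free-energy difference between data splits, over shared low-F bins.

    A single trajectory is split by time into ``n_splits`` blocks; a sequence of
    trajectories is treated as by-round splits. Only bins occupied in every
    split with F <= ``f_cap`` in every split enter the RMS. For more than two
    splits the mean over pairwise RMS values is returned.
    """
    if isinstance(features, FeatureTrajectory):
        if n_splits < 2:
            raise ValueError("need at least 2 splits")
        blocks = np.array_split(features.values, n_splits)
        splits = [FeatureTrajectory(b, labels=features.labels, dt=features.dt) for b in blocks]
    else:
        splits = list(features)
        if len(splits) < 2:
            raise ValueError("need at least 2 splits")
    if value_range is None:
        allv = np.vstack([s.values[:, :2] for s in splits])
        value_range = [
            (allv[:, 0].min(), allv[:, 0].max()),
            (allv[:, 1].min(), allv[:, 1].max()),
        ]
    landscapes = [
        estimate_landscape(s, bins=bins, kT=kT, value_range=value_range) for s in splits
    ]
    fs = np.stack([l.free_energy for l in landscapes])
    mask = np.all(np.isfinite(fs), axis=0) & np.all(fs <= f_cap, axis=0)
    if not mask.any():
        raise ValueError("no common occupied bins below the free-energy cap")
    diffs = []
    for a in range(len(fs)):
        for b in range(a + 1, len(fs)):
            diffs.append(float(np.sqrt(np.mean((fs[a][mask] - fs[b][mask]) ** 2))))
    return float(np.mean(diffs))
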