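"""Activation order parameters and backbone-dihedral features.

The two order parameters monitoring the activation state are the Cα–Cα
distance between BW positions 5.55 and 7.46 and the three-point Cα angle with
vertex at 6.47 and arms to 6.34 and 2.41 (degrees).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure_io import BWMap, MissingAtomError, Structure

__all__ = [
    "OrderParams",
    "FeatureTrajectory",
    "order_params",
    "order_params_series",
    "backbone_dihedrals",
    "three_point_angle",
]

logger = logging.getLogger(__name__)

DISTANCE_PAIR = ("5.55", "7.46")
ANGLE_TRIPLE = ("6.34", "6.47", "2.41")  # vertex is the middle entry


@dataclass(frozen=True)
class OrderParams:
    """Distance (Å) and angle (degrees) activation order parameters."""

    distance: float
    angle: float

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError(f"distance must be positive, got {self.distance}")
        if not 0.0 <= self.angle <= 180.0:
            raise ValueError(f"angle must be in [0, 180] degrees, got {self.angle}")

    def as_array(self) -> np.ndarray:
        return np.array([self.distance, self.angle], dtype=float)


@dataclass
class FeatureTrajectory:
    """Time-ordered T×d matrix of feature values with a frame spacing."""

    values: np.ndarray
    labels: list[str] = None
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("feature values must be a T×d matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature trajectory contains non-finite values")
        if self.labels is None:
            self.labels = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count does not match feature dimension")
        if not self.dt > 0:
            raise ValueError("frame spacing must be positive")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "frame", np.arange(len(self)))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt: float = 1.0) -> "FeatureTrajectory":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "frame"]
        return cls(df[cols].to_numpy(dtype=float), labels=list(cols), dt=dt)


def three_point_angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle (degrees) at ``vertex`` between arms to ``a`` and ``b``."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate angle: arm coincides with vertex")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def order_params(structure: Structure, bw: BWMap) -> OrderParams:
    """Compute the (distance, angle) activation order parameters of one structure."""
    def _ca(pos: str) -> np.ndarray:
        try:
            chain, res_seq = bw[pos]
        except KeyError:
            raise MissingAtomError(f"BW position {pos!r} missing from table") from None
        return structure.ca_coord(chain, res_seq)

    p1, p2 = (_ca(pos) for pos in DISTANCE_PAIR)
    distance = float(np.linalg.norm(p1 - p2))
    arm_a, vertex, arm_b = (_ca(pos) for pos in ANGLE_TRIPLE)
    angle = three_point_angle(arm_a, vertex, arm_b)
    return OrderParams(distance=distance, angle=angle)


def order_params_series(
    frames: Iterable[Structure], bw: BWMap, dt: float = 1.0
) -> FeatureTrajectory:
    """Order parameters per frame; errors name the offending frame index."""
    rows = []
    for i, frame in enumerate(frames):
        try:
            op = order_params(frame, bw)
        except (MissingAtomError, ValueError) as exc:
            raise type(exc)(f"frame {i}: {exc}") from None
        rows.append([op.distance, op.angle])
    if not rows:
        raise ValueError("no frames supplied")
    return FeatureTrajectory(np.array(rows), labels=["distance", "angle"], dt=dt)


# --------------------------------------------------------------------------
# Backbone dihedrals
# --------------------------------------------------------------------------

def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


_PEPTIDE_BOND_MAX = 2.0  # Å; C–N beyond this is a chain break


def _dihedral_spec(structure: Structure) -> list[tuple[str, str, int, int]]:
    """Enumerate computable (kind, chain, res, partner_res) dihedrals of a structure.

    Dihedrals spanning a chain break (missing atom or stretched C–N bond) are
    dropped and logged.
    """
    spec: list[tuple[str, str, int, int]] = []
    for chain in structure.chains():
        residues = [r for r, _ in structure.residues(chain)]
        for prev, cur in zip(residues[:-1], residues[1:]):
            try:
                c_prev = structure.atom(chain, prev, "C").coord
                n_cur = structure.atom(chain, cur, "N").coord
            except MissingAtomError:
                logger.warning("chain %s %d-%d: missing backbone atom, dihedrals dropped", chain, prev, cur)
                continue
            if np.linalg.norm(n_cur - c_prev) > _PEPTIDE_BOND_MAX:
                logger.warning("chain %s %d-%d: chain break, dihedrals dropped", chain, prev, cur)
                continue
            spec.append(("phi", chain, cur, prev))
            spec.append(("psi", chain, prev, cur))
    return spec


def _eval_dihedral(structure: Structure, kind: str, chain: str, res: int, partner: int) -> float:
    if kind == "phi":
        return dihedral_deg(
            structure.atom(chain, partner, "C").coord,
            structure.atom(chain, res, "N").coord,
            structure.atom(chain, res, "CA").coord,
            structure.atom(chain, res, "C").coord,
        )
    return dihedral_deg(
        structure.atom(chain, res, "N").coord,
        structure.atom(chain, res, "CA").coord,
        structure.atom(chain, res, "C").coord,
        structure.atom(chain, partner, "N").coord,
    )


def backbone_dihedrals(
    frames: Sequence[Structure], expand: bool = True, dt: float = 1.0
) -> FeatureTrajectory:
    """φ/ψ backbone dihedrals per frame, sin/cos-expanded by default.

    The set of computable dihedrals is fixed by the first frame; subsequent
    frames must provide the same atoms.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames supplied")
    spec = _dihedral_spec(frames[0])
    if not spec:
        raise ValueError("no computable backbone dihedrals (need N/CA/C per residue)")
    rows = []
    for i, frame in enumerate(frames):
        try:
            rows.append([_eval_dihedral(frame, *entry) for entry in spec])
        except MissingAtomError as exc:
            raise MissingAtomError(f"frame {i}: {exc}") from None
    degs = np.array(rows)
    base_labels = [f"{kind}_{chain}{res}" for kind, chain, res, _ in spec]
    if not expand:
        return FeatureTrajectory(degs, labels=base_labels, dt=dt)
    rad = np.radians(degs)
    values = np.empty((degs.shape[0], 2 * degs.shape[1]))
    values[:, 0::2] = np.sin(rad)
    values[:, 1::2] = np.cos(rad)
    labels: list[str] = []
    for lab in base_labels:
        labels.extend([f"{lab}_sin", f"{lab}_cos"])
    return FeatureTrajectory(values, labels=labels, dt=dt)
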