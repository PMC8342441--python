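"""Nudged-elastic-band minimum-energy paths with a simulated-annealing optimizer.

The band force decomposition keeps the potential force perpendicular to the
path tangent and the spring force parallel to it, so the replicas relax onto
the minimum energy path without sliding into the end basins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import kabsch_superpose
from .synthetic_data import PotentialSurface

__all__ = [
    "Band",
    "NEBForces",
    "AnnealPhase",
    "init_band",
    "neb_tangent",
    "neb_forces",
    "anneal_band",
    "select_replicas",
    "default_schedule",
    "NEBConvergenceWarning",
]


class NEBConvergenceWarning(UserWarning):
    pass


@dataclass
class Band:
    """Ordered replicas R_0..R_N with a spring constant; endpoints optionally fixed."""

    replicas: np.ndarray
    spring_k: float = 10.0
    fixed_ends: bool = True

    def __post_init__(self) -> None:
        self.replicas = np.asarray(self.replicas, dtype=float)
        if self.replicas.ndim != 2:
            raise ValueError("replicas must be an (N+1, d) array")
        if self.replicas.shape[0] < 3:
            raise ValueError("a band needs at least 3 replicas (N >= 2)")
        if not self.spring_k > 0:
            raise ValueError("spring constant must be positive")

    @property
    def n_replicas(self) -> int:
        return self.replicas.shape[0]

    @property
    def ndim(self) -> int:
        return self.replicas.shape[1]

    def energies(self, surface: PotentialSurface) -> np.ndarray:
        return np.asarray(surface.energy(self.replicas), dtype=float)

    def to_csv(self, path, surface: PotentialSurface | None = None) -> None:
        df = pd.DataFrame(self.replicas, columns=[f"x{i}" for i in range(self.ndim)])
        df.insert(0, "replica", np.arange(self.n_replicas))
        if surface is not None:
            df["energy"] = self.energies(surface)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spring_k: float = 10.0) -> "Band":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("x")]
        return cls(df[cols].to_numpy(dtype=float), spring_k=spring_k)


@dataclass
class NEBForces:
    """Per-replica tangents and force components (zero rows at fixed endpoints)."""

    tangents: np.ndarray
    f_perp: np.ndarray
    f_par: np.ndarray
    f_total: np.ndarray

    def max_perp(self) -> float:
        return float(np.abs(self.f_perp).max())

    def max_total(self) -> float:
        return float(np.abs(self.f_total).max())


def init_band(
    start: Sequence[float],
    end: Sequence[float],
    n_replicas: int,
    superpose: bool = False,
    spring_k: float = 10.0,
) -> Band:
    """Linearly interpolate ``n_replicas`` interior replicas between two endpoints.

    With ``superpose`` the rigid-body difference between the endpoints is
    removed first (coordinates are interpreted as flattened (n_atoms, 3) sets).
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if start.shape != end.shape or start.ndim != 1:
        raise ValueError("start and end must be 1-D vectors of equal dimension")
    if n_replicas < 3:
        raise ValueError("need at least 3 interior replicas")
    if superpose:
        if start.size % 3:
            raise ValueError("superpose requires coordinates divisible by 3")
        pts_end = end.reshape(-1, 3)
        pts_start = start.reshape(-1, 3)
        rot, trans, _ = kabsch_superpose(pts_end, pts_start)
        end = (pts_end @ rot.T + trans).ravel()
    t = np.linspace(0.0, 1.0, n_replicas + 2)[:, None]
    replicas = (1.0 - t) * start + t * end
    return Band(replicas, spring_k=spring_k)


def neb_tangent(band: Band, i: int, energies: np.ndarray) -> np.ndarray:
    """Unit tangent at interior replica ``i`` from the energy-dependent four-case rule.

    Monotone segments use the uphill difference vector; local extrema blend the
    two difference vectors with the max/min absolute energy differences, the
    larger weight going to the side of the higher-energy neighbour.
    """
    n = band.n_replicas
    if not 1 <= i <= n - 2:
        raise IndexError("tangent undefined at fixed endpoint replicas")
    r = band.replicas
    v_prev, v_i, v_next = energies[i - 1], energies[i], energies[i + 1]
    fwd = r[i + 1] - r[i]
    bwd = r[i] - r[i - 1]
    if v_next > v_i > v_prev:
        tau = fwd
    elif v_next < v_i < v_prev:
        tau = bwd
    else:
        dv_max = max(abs(v_next - v_i), abs(v_prev - v_i))
        dv_min = min(abs(v_next - v_i), abs(v_prev - v_i))
        if v_next >= v_prev:
            tau = fwd * dv_max + bwd * dv_min
        else:
            tau = fwd * dv_min + bwd * dv_max
    norm = np.linalg.norm(tau)
    if norm == 0.0:
        # degenerate (coincident replicas); fall back to the chord
        chord = r[i + 1] - r[i - 1]
        cn = np.linalg.norm(chord)
        return chord / cn if cn > 0 else np.zeros_like(chord)
    return tau / norm


def _unit_tangents(r: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Vectorized four-case tangents for all interior replicas (zeros at ends).

    Cross-checked against the per-replica reference :func:`neb_tangent` in the
    test suite.
    """
    n, d = r.shape
    fwd = r[1:] - r[:-1]                       # segment i -> i+1
    v_prev, v_i, v_next = e[:-2], e[1:-1], e[2:]
    up = (v_next > v_i) & (v_i > v_prev)
    down = (v_next < v_i) & (v_i < v_prev)
    dv_f = np.abs(v_next - v_i)
    dv_b = np.abs(v_prev - v_i)
    dv_max = np.maximum(dv_f, dv_b)
    dv_min = np.minimum(dv_f, dv_b)
    w_f = np.where(v_next >= v_prev, dv_max, dv_min)
    w_b = np.where(v_next >= v_prev, dv_min, dv_max)
    blend = w_f[:, None] * fwd[1:] + w_b[:, None] * fwd[:-1]
    tau = np.where(up[:, None], fwd[1:], np.where(down[:, None], fwd[:-1], blend))
    norms = np.linalg.norm(tau, axis=1)
    degenerate = norms == 0.0
    if degenerate.any():
        chord = r[2:] - r[:-2]
        cn = np.linalg.norm(chord, axis=1)
        safe = cn > 0
        tau[degenerate & safe] = chord[degenerate & safe]
        norms = np.linalg.norm(tau, axis=1)
    out = np.zeros((n, d))
    nonzero = norms > 0
    out[1:-1][nonzero] = tau[nonzero] / norms[nonzero][:, None]
    return out


def neb_forces(band: Band, surface: PotentialSurface) -> NEBForces:
    """NEB force decomposition: F⊥ from the potential, F∥ from the springs."""
    n, d = band.replicas.shape
    r = band.replicas
    energies = band.energies(surface)
    grads = np.asarray(surface.gradient(r), dtype=float)
    if not np.all(np.isfinite(grads)):
        raise ValueError("non-finite gradient on band")
    tangents = _unit_tangents(r, energies)
    proj = np.sum(grads * tangents, axis=1, keepdims=True)
    f_perp = -grads + proj * tangents
    seg = np.linalg.norm(r[1:] - r[:-1], axis=1)
    spring_mag = np.zeros(n)
    spring_mag[1:-1] = band.spring_k * (seg[1:] - seg[:-1])
    f_par = spring_mag[:, None] * tangents
    f_perp[0] = f_perp[-1] = 0.0
    f_par[0] = f_par[-1] = 0.0
    return NEBForces(tangents, f_perp, f_par, f_perp + f_par)


@dataclass(frozen=True)
class AnnealPhase:
    """One phase of the annealing protocol: kT ramps kT_start -> kT_end."""

    kT_start: float
    kT_end: float
    n_steps: int
    spring_k: float


def default_schedule(energy_scale: float = 2.0) -> list[AnnealPhase]:
    """Heat / equilibrate / anneal-to-zero / cool protocol scaled to a toy surface.

    ``energy_scale`` plays the role of the barrier height. Temperatures are a
    small fraction of it: hot enough to shake replicas off a bad initial
    interpolation, cold enough that spacing fluctuations stay well below the
    inter-replica distance (which would tangle the band).
    """
    hot = 0.02 * energy_scale
    warm = 0.01 * energy_scale
    return [
        AnnealPhase(0.0, hot, 300, 10.0),     # heating
        AnnealPhase(warm, warm, 400, 50.0),   # equilibration
        AnnealPhase(hot, 0.0, 800, 50.0),     # simulated annealing
        AnnealPhase(0.0, 0.0, 300, 50.0),     # cooling
    ]


def anneal_band(
    band: Band,
    surface: PotentialSurface,
    schedule: Sequence[AnnealPhase] | None = None,
    seed: int = 0,
    dt: float = 2e-3,
    tol: float = 1e-3,
    max_descent_steps: int = 200_000,
) -> Band:
    """Langevin dynamics on the replicas driven by the total NEB force.

    Thermal noise is injected perpendicular to the band tangent only, so the
    annealing explores path variations without scrambling replica order along
    the band. After the temperature schedule, a zero-temperature descent with
    adaptive step size runs until ``max |F⊥| < tol`` (or a warning is raised).
    Endpoints stay immutable throughout.
    """
    if schedule is None:
        energies = band.energies(surface)
        schedule = default_schedule(max(float(np.ptp(energies)), 1.0))
    rng = np.random.default_rng(seed)
    replicas = band.replicas.copy()
    work = Band(replicas, spring_k=band.spring_k, fixed_ends=band.fixed_ends)
    ends = (replicas[0].copy(), replicas[-1].copy())

    for phase in schedule:
        work.spring_k = phase.spring_k
        kts = np.linspace(phase.kT_start, phase.kT_end, phase.n_steps)
        for kt in kts:
            forces = neb_forces(work, surface)
            noise = np.sqrt(2.0 * max(kt, 0.0) * dt) * rng.standard_normal(replicas.shape)
            # project noise off the tangent: anneal the path shape, not the spacing
            noise -= np.sum(noise * forces.tangents, axis=1, keepdims=True) * forces.tangents
            noise[0] = noise[-1] = 0.0
            replicas += forces.f_total * dt + noise
            np.clip(replicas, surface.bounds[:, 0], surface.bounds[:, 1], out=replicas)
            replicas[0], replicas[-1] = ends

    # zero-temperature relaxation with adaptive step; the residual tracks the
    # total force so both the path (F_perp) and the spacing (F_par) converge
    step = dt
    forces = neb_forces(work, surface)
    residual = forces.max_total()
    resets = 0
    for _ in range(max_descent_steps):
        if residual < tol:
            break
        trial = replicas + forces.f_total * step
        trial[0], trial[-1] = ends
        trial_band = Band(trial, spring_k=work.spring_k, fixed_ends=True)
        trial_forces = neb_forces(trial_band, surface)
        trial_residual = trial_forces.max_total()
        if trial_residual <= residual * 1.2:
            replicas, forces, residual = trial, trial_forces, trial_residual
            work.replicas = replicas
            step = min(step * 1.1, 50 * dt)
        else:
            step *= 0.5
            if step < 1e-13:
                # tangent-case switching chatter: restart the step size a few
                # times before giving up
                resets += 1
                if resets > 25:
                    break
                step = dt
    if forces.max_perp() >= tol:
        warnings.warn(
            f"NEB did not converge: max |F_perp| = {forces.max_perp():.3e} (tol {tol:.1e})",
            NEBConvergenceWarning,
        )
    return Band(replicas, spring_k=work.spring_k, fixed_ends=band.fixed_ends)


def select_replicas(band: Band, n_select: int) -> Band:
    """Greedy sub-selection of the most mutually different replicas.

    Repeatedly removes the interior replica with the smallest sum of distances
    to its current neighbours until ``n_select`` remain; endpoints are always
    kept.
    """
    if n_select < 2:
        raise ValueError("must keep at least the two endpoints")
    if n_select > band.n_replicas:
        raise ValueError("cannot select more replicas than the band holds")
    kept = list(range(band.n_replicas))
    r = band.replicas
    while len(kept) > n_select:
        scores = []
        for pos in range(1, len(kept) - 1):
            prev_r, cur_r, next_r = r[kept[pos - 1]], r[kept[pos]], r[kept[pos + 1]]
            scores.append(
                np.linalg.norm(cur_r - prev_r) + np.linalg.norm(cur_r - next_r)
            )
        drop = 1 + int(np.argmin(scores))
        kept.pop(drop)
    return Band(r[kept], spring_k=band.spring_k, fixed_ends=band.fixed_ends)
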