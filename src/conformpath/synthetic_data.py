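"""Synthetic inputs with the statistical structure the analysis pipeline assumes.

Dynamics are overdamped Langevin directly in the 2-D order-parameter space
(distance Å, angle °): the downstream landscape/MSM/TPT/tICA machinery is
exercised faithfully without atomistic simulation. The default three-basin
surface places its minima at the inactive / intermediate / active regions of
the order-parameter landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import KT_300K
from .featurize import FeatureTrajectory

__all__ = [
    "PotentialSurface",
    "LangevinConfig",
    "DoseResponseTruth",
    "Basin",
    "make_three_basin_potential",
    "make_double_well",
    "simulate_langevin",
    "boltzmann_populations",
    "match_basins_to_centers",
    "generate_dose_response",
    "DEFAULT_BASIN_CENTERS",
    "DEFAULT_BASIN_DEPTHS",
    "DEFAULT_BASIN_WIDTHS",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

# Inactive / intermediate / active basin centers in (distance Å, angle °).
DEFAULT_BASIN_CENTERS = ((21.3, 38.0), (18.0, 48.5), (17.4, 69.4))
# kcal/mol well depths; deepest = inactive, then active, then intermediate,
# mirroring the qualitative population ordering of the three-state system.
DEFAULT_BASIN_DEPTHS = (2.6, 2.0, 2.3)
# Per-basin (distance, angle) Gaussian widths.
DEFAULT_BASIN_WIDTHS = ((0.8, 4.0), (0.8, 4.0), (0.8, 3.2))
DEFAULT_BOUNDS = ((15.0, 25.0), (30.0, 80.0))


@dataclass
class PotentialSurface:
    """Smooth d-dimensional potential with analytic gradient and domain bounds.

    ``energy`` maps ``(..., d)`` points to scalar kcal/mol values; ``gradient``
    maps them to ``(..., d)`` kcal/mol-per-unit-coordinate vectors.
    """

    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    bounds: np.ndarray

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.ndim != 2 or self.bounds.shape[1] != 2:
            raise ValueError("bounds must be a (d, 2) array")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("each bound must satisfy lower < upper")

    @property
    def ndim(self) -> int:
        return self.bounds.shape[0]


def _gaussian_mixture_surface(
    centers: np.ndarray,
    depths: np.ndarray,
    widths: np.ndarray,
    bounds: np.ndarray,
    confinement: float,
) -> PotentialSurface:
    mid = bounds.mean(axis=1)
    half = 0.5 * (bounds[:, 1] - bounds[:, 0])

    def energy(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None, :] - centers) / widths  # (..., k, d)
        wells = -(depths * np.exp(-0.5 * np.sum(z * z, axis=-1))).sum(axis=-1)
        conf = confinement * np.sum(((x - mid) / half) ** 4, axis=-1)
        return wells + conf

    def gradient(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        diff = x[..., None, :] - centers  # (..., k, d)
        z = diff / widths
        g = np.exp(-0.5 * np.sum(z * z, axis=-1))  # (..., k)
        wells = np.sum((depths * g)[..., None] * diff / widths**2, axis=-2)
        conf = confinement * 4.0 * ((x - mid) / half) ** 3 / half
        return wells + conf

    return PotentialSurface(energy=energy, gradient=gradient, bounds=bounds)


def make_three_basin_potential(
    basin_centers: Sequence[Sequence[float]] = DEFAULT_BASIN_CENTERS,
    basin_depths: Sequence[float] = DEFAULT_BASIN_DEPTHS,
    widths: Sequence = DEFAULT_BASIN_WIDTHS,
    bounds: Sequence = DEFAULT_BOUNDS,
    confinement: float = 0.35,
) -> PotentialSurface:
    """Sum of three inverted Gaussians plus a confining quartic wall.

    Default centers sit at the inactive, intermediate, and active regions of
    the (distance, angle) landscape; the construction places one local
    minimum at (approximately) each requested center.
    """
    centers = np.asarray(basin_centers, dtype=float)
    if centers.shape[0] != 3:
        raise ValueError("exactly three basin centers required")
    if len({tuple(c) for c in centers.tolist()}) != 3:
        raise ValueError("basin centers must be distinct")
    depths = np.broadcast_to(np.asarray(basin_depths, dtype=float), (3,)).copy()
    if np.any(depths <= 0):
        raise ValueError("basin depths must be positive")
    widths = np.asarray(widths, dtype=float)
    widths = np.broadcast_to(widths, centers.shape).copy()
    if np.any(widths <= 0):
        raise ValueError("basin widths must be positive")
    return _gaussian_mixture_surface(
        centers, depths, widths, np.asarray(bounds, dtype=float), confinement
    )


def make_double_well(
    barrier: float = 2.0,
    separation: float = 1.0,
    transverse: float = 1.0,
    offset: float = 0.0,
    bounds: Sequence = ((-2.5, 2.5), (-2.5, 2.5)),
) -> PotentialSurface:
    """Polynomial double well with an analytic saddle.

    ``V(x, y) = barrier * ((x/separation)^2 - 1)^2 + transverse * y^2 + offset * x``.
    For ``offset = 0`` the minima are at (±separation, 0) with V = 0 and the
    saddle at the origin with V = ``barrier``.
    """

    def energy(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        u = (x / separation) ** 2 - 1.0
        return barrier * u**2 + transverse * y**2 + offset * x

    def gradient(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        u = (x / separation) ** 2 - 1.0
        gx = barrier * 4.0 * u * x / separation**2 + offset
        gy = 2.0 * transverse * y
        return np.stack([gx, gy], axis=-1)

    return PotentialSurface(energy=energy, gradient=gradient, bounds=np.asarray(bounds, float))


# --------------------------------------------------------------------------
# Overdamped Langevin sampler
# --------------------------------------------------------------------------

@dataclass
class LangevinConfig:
    """Parameters of the overdamped Langevin integrator (dimensionless time units)."""

    dt: float
    diffusion: Sequence[float] | float
    kT: float
    n_steps: int
    x0: Sequence[float]
    seed: int
    scheme: str = "lm"

    def __post_init__(self) -> None:
        if self.scheme not in ("lm", "euler"):
            raise ValueError("scheme must be 'lm' or 'euler'")
        if not self.dt > 0:
            raise ValueError("time step must be positive")
        if not self.kT > 0:
            raise ValueError("kT must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        self.x0 = np.asarray(self.x0, dtype=float)
        self.diffusion = np.broadcast_to(
            np.asarray(self.diffusion, dtype=float), self.x0.shape
        ).copy()
        if np.any(self.diffusion < 0):
            raise ValueError("diffusion coefficients must be non-negative")


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, int]:
    """Reflect coordinates into [lo, hi]; returns (reflected x, reflection count)."""
    n = 0
    span = hi - lo
    for _ in range(64):  # a step never overshoots by more than a few spans
        below = x < lo
        above = x > hi
        if not (below.any() or above.any()):
            break
        n += int(below.sum() + above.sum())
        x = np.where(below, 2 * lo - x, x)
        x = np.where(above, 2 * hi - x, x)
    else:
        raise RuntimeError("reflection failed to terminate; step size too large")
    return x, n


def simulate_langevin(surface: PotentialSurface, config: LangevinConfig) -> FeatureTrajectory:
    """Overdamped update ``x <- x - grad(V) * dt * D / kT + sqrt(2 D dt) * xi``.

    The default ``scheme='lm'`` (Leimkuhler–Matthews) averages consecutive
    noise increments, ``xi -> (xi_t + xi_{t+1}) / 2``, which reduces the
    finite-timestep sampling bias of the plain Euler–Maruyama rule from
    O(dt) to O(dt^2) at identical cost; ``scheme='euler'`` uses the literal
    rule above.

    Trajectories escaping the domain are reflected at the boundary; the
    reflection count is logged and attached as ``traj.n_reflections``. A fixed
    seed yields a byte-identical trajectory. Dimensions with ``diffusion = 0``
    run noise-free pure gradient descent at unit mobility.
    """
    d = surface.ndim
    if config.x0.shape != (d,):
        raise ValueError(f"initial point must have dimension {d}")
    lo, hi = surface.bounds[:, 0], surface.bounds[:, 1]
    if np.any(config.x0 < lo) or np.any(config.x0 > hi):
        raise ValueError("initial point outside domain bounds")
    rng = np.random.default_rng(config.seed)
    mobility = np.where(
        config.diffusion > 0, config.diffusion / config.kT, 1.0
    ) * config.dt
    noise_scale = np.sqrt(2.0 * config.diffusion * config.dt)
    out = np.empty((config.n_steps + 1, d))
    out[0] = x = config.x0.copy()
    n_reflections = 0
    chunk = 65536
    grad = surface.gradient
    lm = config.scheme == "lm"
    xi_prev = rng.standard_normal(d) if lm else None
    step = 0
    while step < config.n_steps:
        m = min(chunk, config.n_steps - step)
        xi = rng.standard_normal((m, d))
        for i in range(m):
            if lm:
                kick = 0.5 * (xi_prev + xi[i])
                xi_prev = xi[i]
            else:
                kick = xi[i]
            x = x - grad(x) * mobility + noise_scale * kick
            x, nr = _reflect(x, lo, hi)
            n_reflections += nr
            out[step + 1 + i] = x
        step += m
    if n_reflections:
        logger.info("simulate_langevin: %d boundary reflections", n_reflections)
    labels = ["distance", "angle"] if d == 2 else [f"x{i}" for i in range(d)]
    traj = FeatureTrajectory(out, labels=labels, dt=config.dt)
    traj.n_reflections = n_reflections
    return traj


# --------------------------------------------------------------------------
# Boltzmann basin populations (oracle for MSM stationary recovery)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Basin:
    minimum: tuple
    min_energy: float
    probability: float


def boltzmann_populations(
    surface: PotentialSurface, kT: float, grid_resolution: int | Sequence[int] = 500
) -> list[Basin]:
    """Per-basin Boltzmann probabilities by dense grid integration.

    Grid cells are assigned to basins by discrete steepest descent (each cell
    points at its lowest-energy 8-neighbour); cell weights ``exp(-V/kT)`` are
    accumulated per terminal minimum. Probabilities sum to 1.
    """
    if surface.ndim != 2:
        raise ValueError("grid watershed implemented for 2-D surfaces")
    res = np.broadcast_to(np.asarray(grid_resolution, dtype=int), (2,))
    nx, ny = int(res[0]), int(res[1])
    (x_lo, x_hi), (y_lo, y_hi) = surface.bounds
    xs = x_lo + (np.arange(nx) + 0.5) * (x_hi - x_lo) / nx
    ys = y_lo + (np.arange(ny) + 0.5) * (y_hi - y_lo) / ny
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    v = surface.energy(grid)
    if not np.all(np.isfinite(v)):
        raise ValueError("energy not finite on the domain grid")

    # lowest-energy neighbour pointer (8-neighbourhood, self included)
    padded = np.full((nx + 2, ny + 2), np.inf)
    padded[1:-1, 1:-1] = v
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    stacked = np.stack(
        [padded[1 + di : 1 + di + nx, 1 + dj : 1 + dj + ny] for di, dj in shifts]
    )
    best = np.argmin(stacked, axis=0)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    di = np.array([s[0] for s in shifts])[best]
    dj = np.array([s[1] for s in shifts])[best]
    pointer = ((ii + di) * ny + (jj + dj)).ravel()

    # path doubling to the terminal minimum of every cell
    for _ in range(64):
        nxt = pointer[pointer]
        if np.array_equal(nxt, pointer):
            break
        pointer = nxt

    weights = np.exp(-(v - v.min()) / kT).ravel()
    sums = np.bincount(pointer, weights=weights, minlength=nx * ny)
    minima = np.flatnonzero(np.arange(nx * ny) == pointer)
    total = weights.sum()

    basins = []
    for m in minima:
        mi, mj = divmod(int(m), ny)
        basins.append(
            Basin(
                minimum=(float(xs[mi]), float(ys[mj])),
                min_energy=float(v[mi, mj]),
                probability=float(sums[m] / total),
            )
        )
    basins.sort(key=lambda b: -b.probability)
    return basins


def match_basins_to_centers(
    basins: Sequence[Basin], centers: Sequence[Sequence[float]]
) -> np.ndarray:
    """Probabilities ordered by requested centers (nearest-basin matching).

    When the watershed produced more basins than centers (spurious shallow
    minima), each basin's mass is attributed to its nearest center.
    """
    centers = np.asarray(centers, dtype=float)
    probs = np.zeros(len(centers))
    for b in basins:
        idx = int(np.argmin(np.linalg.norm(centers - np.asarray(b.minimum), axis=1)))
        probs[idx] += b.probability
    return probs


# --------------------------------------------------------------------------
# Dose-response generation
# --------------------------------------------------------------------------

@dataclass
class DoseResponseTruth:
    """Known operational-model parameters for simulated dose-response data."""

    basal: float
    emax: float
    n: float
    log_ka: float
    log_r: float
    concentrations: Sequence[float]
    noise_sd: float
    n_replicates: int
    seed: int
    receptor: str = "WT"
    pathway: str = "Gq"
    role: str = "test"

    def __post_init__(self) -> None:
        if self.emax < self.basal:
            raise ValueError("Emax must be >= basal")
        if not self.n > 0:
            raise ValueError("slope n must be positive")
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def generate_dose_response(truth: DoseResponseTruth):
    """Simulate replicate dose-response curves: forward-model mean + Gaussian noise."""
    from .pharm import DoseResponseCurve, OperationalParams, operational_forward

    params = OperationalParams(
        basal=truth.basal,
        emax=truth.emax,
        n=truth.n,
        log_ka=truth.log_ka,
        log_r=truth.log_r,
    )
    x = np.log10(truth.concentrations)
    mean = operational_forward(params, x, role=truth.role)
    rng = np.random.default_rng(truth.seed)
    responses = mean[None, :] + truth.noise_sd * rng.standard_normal(
        (truth.n_replicates, len(x))
    )
    return DoseResponseCurve(
        concentrations=np.asarray(truth.concentrations, dtype=float),
        responses=responses,
        receptor=truth.receptor,
        pathway=truth.pathway,
        role=truth.role,
    )
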