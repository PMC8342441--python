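"""Markov state models: microstate clustering, transition-matrix estimation,
implied timescales, PCCA+ coarse-graining, Chapman–Kolmogorov validation, and
similarity-score representative-conformation selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .featurize import FeatureTrajectory
from .structure_io import kabsch_superpose

__all__ = [
    "MicrostateModel",
    "TransitionMatrix",
    "MacrostateModel",
    "SimilarityMatrix",
    "cluster_microstates",
    "count_transitions",
    "estimate_T",
    "implied_timescales",
    "timescales_from_T",
    "pcca",
    "ck_test",
    "CKTestResult",
    "similarity_matrix",
    "representative_conformation",
    "label_macrostates",
    "UNDEFINED_TIMESCALE",
]

logger = logging.getLogger(__name__)

#: sentinel for eigenvalues outside (0, 1) where a relaxation time is undefined
UNDEFINED_TIMESCALE = -1.0


def _as_dtraj_list(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        return [np.asarray(dtrajs, dtype=int)]
    return [np.asarray(d, dtype=int) for d in dtrajs]


# --------------------------------------------------------------------------
# Microstate clustering
# --------------------------------------------------------------------------

@dataclass
class MicrostateModel:
    centers: np.ndarray  # (k, d), original feature units
    dtrajs: list[np.ndarray]
    k: int
    seed: int
    inertia: float
    standardized: bool
    scale_mean: np.ndarray = None
    scale_std: np.ndarray = None

    def assign(self, features: FeatureTrajectory) -> np.ndarray:
        x = features.values
        if self.standardized:
            x = (x - self.scale_mean) / self.scale_std
            centers = (self.centers - self.scale_mean) / self.scale_std
        else:
            centers = self.centers
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def cluster_microstates(
    features: FeatureTrajectory | Sequence[FeatureTrajectory],
    k: int,
    max_iter: int = 200,
    seed: int = 42,
    standardize: bool = True,
) -> MicrostateModel:
    """k-means microstates (k-means++ seeding, fixed seed, per-axis z-scoring).

    The k-means objective is non-increasing per Lloyd iteration; determinism
    follows from the fixed ``random_state``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    trajs = [features] if isinstance(features, FeatureTrajectory) else list(features)
    x = np.vstack([t.values for t in trajs])
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct frames")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    xs = (x - mean) / std if standardize else x
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence chatter
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
            random_state=seed,
        ).fit(xs)
    centers = km.cluster_centers_ * std + mean if standardize else km.cluster_centers_
    labels = km.labels_
    dtrajs, offset = [], 0
    for t in trajs:
        dtrajs.append(labels[offset : offset + len(t)].astype(int))
        offset += len(t)
    return MicrostateModel(
        centers=centers, dtrajs=dtrajs, k=k, seed=seed, inertia=float(km.inertia_),
        standardized=standardize, scale_mean=mean, scale_std=std,
    )


# --------------------------------------------------------------------------
# Transition counting and estimation
# --------------------------------------------------------------------------

def count_transitions(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts C_ij = #{t: s_t = i, s_{t+lag} = j}.

    Trajectories are counted independently (no cross-trajectory transitions).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    dtrajs = _as_dtraj_list(dtrajs)
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs if d.size)) + 1
    counts = np.zeros((n_states, n_states), dtype=float)
    any_pairs = False
    for d in dtrajs:
        if len(d) <= lag:
            continue
        any_pairs = True
        np.add.at(counts, (d[:-lag], d[lag:]), 1.0)
    if not any_pairs:
        warnings.warn("lag >= trajectory length: zero count matrix", UserWarning)
    return counts


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix on the largest strongly connected component."""

    T: np.ndarray
    lag: int                      # frames
    lag_time: float               # physical units
    counts: np.ndarray            # restricted to the active set
    reversible: bool
    pi: np.ndarray
    active_set: np.ndarray        # original state indices of the rows

    def __post_init__(self) -> None:
        rows = self.T.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.allclose(self.pi @ self.T, self.pi, atol=1e-8):
            raise ValueError("pi is not stationary for T")
        if self.reversible:
            flux = self.pi[:, None] * self.T
            if not np.allclose(flux, flux.T, atol=1e-8):
                raise ValueError("detailed balance violated for reversible matrix")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self, n: int | None = None) -> np.ndarray:
        ev = np.linalg.eigvals(self.T)
        order = np.argsort(-np.abs(ev))
        ev = ev[order]
        return ev if n is None else ev[:n]


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    adj = csr_matrix((counts > 0).astype(int))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp == 0:
        raise ValueError("empty count matrix")
    # pick the component with the largest total counts
    best, best_weight = 0, -1.0
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        w = counts[np.ix_(idx, idx)].sum()
        if w > best_weight:
            best, best_weight = c, w
    active = np.flatnonzero(labels == best)
    if best_weight <= 0:
        raise ValueError("no connected component with transitions")
    dropped = counts.shape[0] - active.size
    if dropped:
        logger.info("estimate_T: dropped %d states outside the largest SCC", dropped)
    return active


def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    ev, vec = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(ev - 1.0)))
    pi = np.real(vec[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _reversible_mle(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000):
    """Self-consistent maximum-likelihood estimator under detailed balance."""
    c_sym = counts + counts.T
    c_row = counts.sum(axis=1)
    x = c_sym.copy()
    x /= x.sum()
    T_prev = None
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        x = x_new
        x_row = x.sum(axis=1)
        T = x / x_row[:, None]
        if T_prev is not None and np.abs(T - T_prev).max() < tol:
            break
        T_prev = T
    pi = x.sum(axis=1)
    return T, pi / pi.sum()


def estimate_T(
    counts: np.ndarray,
    mode: str = "nonreversible",
    lag: int = 1,
    frame_time: float = 1.0,
) -> TransitionMatrix:
    """Estimate a row-stochastic transition matrix on the largest strong component.

    ``nonreversible``: plain row normalization; ``reversible``: iterative
    detailed-balance maximum likelihood (converged at max |ΔT| < 1e-10).
    """
    counts = np.asarray(counts, dtype=float)
    if mode not in ("nonreversible", "reversible"):
        raise ValueError("mode must be 'nonreversible' or 'reversible'")
    active = _largest_scc(counts)
    c = counts[np.ix_(active, active)]
    if mode == "nonreversible":
        T = c / c.sum(axis=1, keepdims=True)
        pi = _stationary_distribution(T)
    else:
        T, pi = _reversible_mle(c)
    return TransitionMatrix(
        T=T, lag=lag, lag_time=lag * frame_time, counts=c,
        reversible=(mode == "reversible"), pi=pi, active_set=active,
    )


# --------------------------------------------------------------------------
# Implied timescales
# --------------------------------------------------------------------------

def timescales_from_T(T_or_tm, lag_time: float, n_its: int = 3) -> np.ndarray:
    """t_i = -lag / ln lambda_i for the dominant nontrivial eigenvalues.

    Eigenvalues outside (0, 1) yield :data:`UNDEFINED_TIMESCALE`.
    """
    T = T_or_tm.T if isinstance(T_or_tm, TransitionMatrix) else np.asarray(T_or_tm)
    ev = np.linalg.eigvals(T)
    ev = ev[np.argsort(-np.abs(ev))]
    out = np.full(n_its, UNDEFINED_TIMESCALE)
    for i, lam in enumerate(ev[1 : n_its + 1]):
        lam_r = float(np.real(lam))
        if 0.0 < lam_r < 1.0 and abs(np.imag(lam)) < 1e-8:
            out[i] = -lag_time / np.log(lam_r)
    return out


def implied_timescales(
    dtrajs,
    lags: Sequence[int],
    n_its: int = 3,
    mode: str = "nonreversible",
    frame_time: float = 1.0,
) -> np.ndarray:
    """Implied-timescale curves t_i(τ) for ascending lags; shape (n_lags, n_its)."""
    lags = list(lags)
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ValueError("lags must be ascending")
    dtrajs = _as_dtraj_list(dtrajs)
    n_states = int(max(d.max() for d in dtrajs)) + 1
    curves = np.full((len(lags), n_its), UNDEFINED_TIMESCALE)
    for row, lag in enumerate(lags):
        counts = count_transitions(dtrajs, lag, n_states=n_states)
        tm = estimate_T(counts, mode=mode, lag=lag, frame_time=frame_time)
        curves[row] = timescales_from_T(tm, tm.lag_time, n_its=n_its)
    return curves


# --------------------------------------------------------------------------
# PCCA+ coarse-graining
# --------------------------------------------------------------------------

@dataclass
class MacrostateModel:
    memberships: np.ndarray      # chi, (k, m), rows sum to 1
    crisp: np.ndarray            # (k,) argmax assignment
    probabilities: np.ndarray    # (m,) stationary macrostate probabilities
    labels: list[str] = None

    def macro_dtrajs(self, dtrajs, active_set: np.ndarray) -> list[np.ndarray]:
        """Map microstate trajectories to crisp macrostate trajectories.

        Frames visiting states outside the active set are mapped to the
        macrostate of the nearest active state index (rare, logged).
        """
        lookup = np.full(int(active_set.max()) + 1, -1, dtype=int)
        lookup[active_set] = self.crisp
        out = []
        for d in _as_dtraj_list(dtrajs):
            d = np.asarray(d)
            mapped = np.full(len(d), -1, dtype=int)
            in_range = d < len(lookup)
            mapped[in_range] = lookup[d[in_range]]
            if np.any(mapped < 0):
                n_bad = int(np.sum(mapped < 0))
                logger.warning("macro_dtrajs: %d frames outside active set dropped", n_bad)
                # keep array alignment by forward-filling from the previous frame
                for i in np.flatnonzero(mapped < 0):
                    mapped[i] = mapped[i - 1] if i else 0
            out.append(mapped)
        return out


def pcca(tm: TransitionMatrix, m: int) -> MacrostateModel:
    """PCCA+ fuzzy coarse-graining into ``m`` metastable macrostates.

    Inner-simplex vertex search on the ``m`` dominant right eigenvectors of T;
    memberships are the simplex coordinates, clipped to [0, 1] and
    row-normalized. Macrostate probabilities are π-weighted membership sums.
    """
    T = tm.T
    k = T.shape[0]
    if not 2 <= m <= k:
        raise ValueError("need 2 <= m <= number of microstates")
    ev, vec = np.linalg.eig(T)
    order = np.argsort(-np.real(ev))
    ev, vec = ev[order], vec[:, order]
    if m < k and abs(np.real(ev[m - 1]) - np.real(ev[m])) < 1e-10:
        raise ValueError(
            f"degenerate eigenvalue gap at m={m}; choose a different number of macrostates"
        )
    if np.abs(np.imag(ev[:m])).max() > 1e-8:
        raise ValueError("dominant eigenvalues are complex; estimate a reversible matrix")
    X = np.real(vec[:, :m])
    X[:, 0] = 1.0  # the Perron eigenvector is constant; fix its scale
    # π-weighted normalization of the remaining eigenvectors
    for j in range(1, m):
        norm = np.sqrt(np.sum(tm.pi * X[:, j] ** 2))
        if norm > 0:
            X[:, j] /= norm

    # inner-simplex vertex search (ISA): find m rows spanning the simplex
    ortho = X.copy()
    idx = np.zeros(m, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[idx[0]]
    for j in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        pivot = ortho[idx[j]] / norms[idx[j]]
        ortho = ortho - np.outer(ortho @ pivot, pivot)
    A = np.linalg.inv(X[idx])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    probabilities = chi.T @ tm.pi
    probabilities = probabilities / probabilities.sum()
    return MacrostateModel(memberships=chi, crisp=crisp, probabilities=probabilities)


def label_macrostates(
    macro: MacrostateModel,
    micro_centers: np.ndarray,
    tm: TransitionMatrix,
    reference_centers: dict,
) -> MacrostateModel:
    """Name macrostates by nearest reference basin center of their mean features."""
    centers = micro_centers[tm.active_set] if micro_centers.shape[0] > tm.n_states else micro_centers
    m = macro.memberships.shape[1]
    names = list(reference_centers)
    ref = np.asarray([reference_centers[n] for n in names], dtype=float)
    labels = []
    for j in range(m):
        w = macro.memberships[:, j] * tm.pi
        mean = (w[:, None] * centers).sum(axis=0) / w.sum()
        labels.append(names[int(np.argmin(np.linalg.norm(ref - mean, axis=1)))])
    macro.labels = labels
    return macro


# --------------------------------------------------------------------------
# Chapman–Kolmogorov test
# --------------------------------------------------------------------------

@dataclass
class CKTestResult:
    factors: list[int]
    predicted: np.ndarray          # (n_factors, m) self-transition probabilities
    estimated: np.ndarray          # (n_factors, m)
    errors: np.ndarray             # (n_factors, m) error bars on estimated
    predicted_errors: np.ndarray   # (n_factors, m) error bars on predicted

    def passes(self, n_sigma: float = 2.0, slack: float = 0.01) -> bool:
        combined = np.hypot(self.errors, self.predicted_errors)
        return bool(
            np.all(np.abs(self.predicted - self.estimated) <= n_sigma * combined + slack)
        )


def _macro_T(macro_dtrajs, lag: int, m: int):
    counts = count_transitions(macro_dtrajs, lag, n_states=m)
    row = counts.sum(axis=1, keepdims=True)
    T = np.divide(counts, row, out=np.full_like(counts, np.nan), where=row > 0)
    return T, counts


def ck_test(
    dtrajs,
    lag: int,
    macro: MacrostateModel,
    active_set: np.ndarray,
    factors: Sequence[int] = (2, 3, 4, 5),
    n_boot: int = 200,
    seed: int = 0,
) -> CKTestResult:
    """Chapman–Kolmogorov test on the coarse-grained model.

    Compares the f-step propagation of the macrostate transition matrix
    estimated at ``lag`` against matrices re-estimated at ``f * lag``.

    Error bars use *effective* transition counts (sliding-window pairs overlap
    ``lag``-fold, so raw counts overstate the information content by that
    factor): multinomial errors on the re-estimated side, and posterior
    (Dirichlet) sampling of the base matrix propagated through the matrix
    power on the predicted side.
    """
    factors = sorted(set(int(f) for f in factors))
    if any(f < 1 for f in factors):
        raise ValueError("factors must be positive integers")
    m = macro.memberships.shape[1]
    mdtrajs = macro.macro_dtrajs(dtrajs, active_set)
    T_base, counts_base = _macro_T(mdtrajs, lag, m)
    if np.isnan(T_base).any():
        raise ValueError("macrostate not visited at the base lag")
    rng = np.random.default_rng(seed)
    eff_base = counts_base / lag
    boot = np.stack(
        [
            np.vstack([rng.dirichlet(eff_base[i] + 0.5) for i in range(m)])
            for _ in range(n_boot)
        ]
    )
    predicted = np.empty((len(factors), m))
    estimated = np.empty((len(factors), m))
    errors = np.empty((len(factors), m))
    predicted_errors = np.empty((len(factors), m))
    for row, f in enumerate(factors):
        predicted[row] = np.diag(np.linalg.matrix_power(T_base, f))
        boot_diags = np.stack(
            [np.diag(np.linalg.matrix_power(b, f)) for b in boot]
        )
        predicted_errors[row] = boot_diags.std(axis=0)
        T_f, counts_f = _macro_T(mdtrajs, f * lag, m)
        diag = np.diag(T_f)
        n_eff = counts_f.sum(axis=1) / (f * lag)
        estimated[row] = diag
        with np.errstate(invalid="ignore", divide="ignore"):
            errors[row] = np.sqrt(
                np.clip(diag * (1 - diag), 0, None) / np.maximum(n_eff, 1.0)
            )
    return CKTestResult(
        factors=factors, predicted=predicted, estimated=estimated,
        errors=errors, predicted_errors=predicted_errors,
    )


# --------------------------------------------------------------------------
# Representative conformation (similarity score)
# --------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    distances: np.ndarray
    d_scale: float
    scores: np.ndarray  # S_ij = exp(-d_ij / d_scale)


def similarity_matrix(distances: np.ndarray) -> SimilarityMatrix:
    """S_ij = exp(-d_ij / d_scale); d_scale is the std of the pairwise distances."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    off = d[np.triu_indices_from(d, k=1)]
    d_scale = float(np.std(off))
    if d_scale == 0.0:
        scores = np.ones_like(d)
    else:
        scores = np.exp(-d / d_scale)
    return SimilarityMatrix(distances=d, d_scale=d_scale, scores=scores)


def _pairwise_rmsd(frames: np.ndarray) -> np.ndarray:
    """Pairwise Kabsch-aligned RMSD of (n_frames, n_atoms, 3) coordinate sets."""
    n = frames.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(frames[i], frames[j])
            d[i, j] = d[j, i] = rmsd
    return d


def representative_conformation(pool) -> tuple[int, SimilarityMatrix]:
    """Most representative frame of a candidate pool by mean similarity score.

    ``pool`` is either a precomputed symmetric distance matrix or an
    (n_frames, n_atoms, 3) coordinate stack (pairwise aligned RMSD is used).
    Ties resolve to the lowest frame index.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim == 3:
        distances = _pairwise_rmsd(pool)
    elif pool.ndim == 2 and pool.shape[0] == pool.shape[1]:
        distances = pool
    else:
        raise ValueError("pool must be a distance matrix or an (n, n_atoms, 3) stack")
    if distances.shape[0] < 2:
        raise ValueError("need at least 2 candidate frames")
    sim = similarity_matrix(distances)
    scores = sim.scores.mean(axis=1)
    return int(np.argmax(scores)), sim
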