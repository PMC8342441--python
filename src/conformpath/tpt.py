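"""Transition-path-theory kinetics: committors and mean first passage times."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .msm import TransitionMatrix, _stationary_distribution

__all__ = ["TPTResult", "committor", "mfpt", "mfpt_matrix", "net_flux"]


@dataclass
class TPTResult:
    source: np.ndarray
    target: np.ndarray
    committor: np.ndarray
    mfpt: float
    flux: np.ndarray = None


def _unwrap(T) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(T, TransitionMatrix):
        return T.T, T.pi
    return np.asarray(T, dtype=float), None


def _validate_sets(n: int, A, B) -> tuple[np.ndarray, np.ndarray]:
    A = np.unique(np.asarray(list(A), dtype=int))
    B = np.unique(np.asarray(list(B), dtype=int))
    if A.size == 0 or B.size == 0:
        raise ValueError("state sets must be nonempty")
    if np.intersect1d(A, B).size:
        raise ValueError("state sets must be disjoint")
    if A.max() >= n or B.max() >= n or A.min() < 0 or B.min() < 0:
        raise ValueError("state index out of range")
    return A, B


def committor(T, A: Sequence[int], B: Sequence[int]) -> np.ndarray:
    """Forward committor q+ (probability of reaching B before A).

    Solves ``(I - T_CC) q_C = T_CB 1`` on the intermediate states C; q+ is 0 on
    A and 1 on B.
    """
    T, _ = _unwrap(T)
    n = T.shape[0]
    A, B = _validate_sets(n, A, B)
    q = np.zeros(n)
    q[B] = 1.0
    C = np.setdiff1d(np.arange(n), np.union1d(A, B))
    if C.size == 0:
        warnings.warn("A and B cover all states; committor is trivial", UserWarning)
        return q
    M = np.eye(C.size) - T[np.ix_(C, C)]
    rhs = T[np.ix_(C, B)].sum(axis=1)
    q[C] = np.linalg.solve(M, rhs)
    return q


def _reachable(T: np.ndarray, source: np.ndarray, target: np.ndarray) -> bool:
    dist = shortest_path(csr_matrix((T > 0).astype(float)), indices=source)
    return bool(np.isfinite(dist[:, target]).any(axis=1).all())


def mfpt(
    T,
    source: Sequence[int],
    target: Sequence[int],
    lag_physical: float = 1.0,
    pi: np.ndarray | None = None,
) -> float:
    """Mean first passage time from ``source`` to ``target`` in physical units.

    Per-state times solve ``(I - T_notT) t = lag * 1``; the set-level MFPT is
    the stationary-weighted average over the source states (π restricted and
    renormalized to the source). Unreachable targets yield ``inf`` + warning.
    """
    T, pi_tm = _unwrap(T)
    n = T.shape[0]
    source = np.unique(np.asarray(list(source), dtype=int))
    target = np.unique(np.asarray(list(target), dtype=int))
    if source.size == 0 or target.size == 0:
        raise ValueError("state sets must be nonempty")
    if np.intersect1d(source, target).size == source.size:
        return 0.0
    if not _reachable(T, np.setdiff1d(source, target), target):
        warnings.warn("target unreachable from source; MFPT is infinite", UserWarning)
        return float("inf")
    others = np.setdiff1d(np.arange(n), target)
    M = np.eye(others.size) - T[np.ix_(others, others)]
    t_others = np.linalg.solve(M, lag_physical * np.ones(others.size))
    t = np.zeros(n)
    t[others] = t_others
    if pi is None:
        pi = pi_tm if pi_tm is not None else _stationary_distribution(T)
    w = pi[source]
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    return float(np.dot(w, t[source]))


def mfpt_matrix(
    T, macrostate_sets: Sequence[Sequence[int]], lag_physical: float = 1.0
) -> np.ndarray:
    """m×m table of set-level MFPTs between macrostate microstate-sets."""
    m = len(macrostate_sets)
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            out[a, b] = mfpt(T, macrostate_sets[a], macrostate_sets[b], lag_physical)
    return out


def net_flux(T, A: Sequence[int], B: Sequence[int], pi: np.ndarray | None = None) -> np.ndarray:
    """Net reactive flux matrix f+_ij = max(f_ij - f_ji, 0) for the A→B transition."""
    Tm, pi_tm = _unwrap(T)
    if pi is None:
        pi = pi_tm if pi_tm is not None else _stationary_distribution(Tm)
    qp = committor(Tm, A, B)
    qm = 1.0 - qp  # backward committor for reversible chains
    flux = pi[:, None] * qm[:, None] * Tm * qp[None, :]
    np.fill_diagonal(flux, 0.0)
    return np.clip(flux - flux.T, 0.0, None)
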