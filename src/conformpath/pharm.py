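"""Operational-model pharmacology: dose-response fitting, transduction
coefficients log(τ/K_A), Δlog(τ/K_A) relative activities with SEM propagation,
and the mutant × pathway bias heat map.

The forward model implements both printed branches of the fitting template:
the reference branch (Y1, ``operate1``) drops the dissociation constant, the
full branch (Y2, ``operate2``) carries LogKA. A per-curve ``role`` flag selects
the branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "OperationalParams",
    "OperationalFit",
    "DoseResponseCurve",
    "BiasEntry",
    "operational_forward",
    "fit_operational",
    "delta_log_tau_ka",
    "bias_heatmap",
    "UnidentifiableFitError",
]


class UnidentifiableFitError(RuntimeError):
    """Raised when a curve carries no dose-dependent signal to fit."""


@dataclass
class OperationalParams:
    basal: float
    emax: float
    n: float
    log_ka: float       # log10 M
    log_r: float        # log10(tau / K_A)

    def validate(self) -> None:
        if self.emax < self.basal:
            raise ValueError("Emax must be >= basal")
        if not self.n > 0:
            raise ValueError("transducer slope n must be positive")


@dataclass
class OperationalFit(OperationalParams):
    sem: dict = field(default_factory=dict)
    converged: bool = True
    identifiable: bool = True
    residual: float = np.nan
    role: str = "test"
    receptor: str = ""
    pathway: str = ""

    @property
    def log_tau_ka(self) -> float:
        return self.log_r


@dataclass
class DoseResponseCurve:
    """Replicate dose-response data on a shared concentration grid (molar)."""

    concentrations: np.ndarray
    responses: np.ndarray           # (n_replicates, n_concentrations)
    receptor: str = ""
    pathway: str = ""
    role: str = "test"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.responses.shape[1] != self.concentrations.shape[0]:
            raise ValueError("replicates must align to the concentration grid")

    @property
    def x(self) -> np.ndarray:
        """X = log10 concentration."""
        return np.log10(self.concentrations)


def operational_forward(
    params: OperationalParams, X: np.ndarray, role: str = "test"
) -> np.ndarray:
    """Mean response of the operational model at log10 concentrations ``X``.

    ``role='reference'`` uses operate1 = ((1 + A) / (10^LogR * A))^n;
    ``role='test'`` uses operate2 = ((1 + A/10^LogKA) / (10^LogR * A))^n;
    Y = basal + (Emax - basal) / (1 + operate).
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("log-concentrations must be finite (A > 0)")
    A = np.power(10.0, X)
    r = np.power(10.0, params.log_r)
    if role == "reference":
        operate = ((1.0 + A) / (r * A)) ** params.n
    elif role == "test":
        ka = np.power(10.0, params.log_ka)
        operate = ((1.0 + A / ka) / (r * A)) ** params.n
    else:
        raise ValueError("role must be 'reference' or 'test'")
    return params.basal + (params.emax - params.basal) / (1.0 + operate)


def fit_operational(
    curve: DoseResponseCurve,
    role: str | None = None,
    log_r_grid: Sequence[float] = (-2.0, 1.0, 4.0, 7.0, 10.0),
    max_nfev: int = 400,
    fix_emax: float | None = None,
    fix_basal: float | None = None,
) -> OperationalFit:
    """Nonlinear least-squares operational-model fit with multi-start guesses.

    Initial basal/Emax come from the curve extremes, n starts at 1, LogKA at
    the mid concentration, and LogR scans a grid. SEMs come from the
    Gauss–Newton covariance of the best fit.

    ``fix_emax`` / ``fix_basal`` pin the system constants of the transducer
    model. With every parameter free the model carries an exact ridge at
    n = 1 (Emax·R and R + 1/K_A enter the mean response only as products and
    sums), so log(τ/K_A) is identified from a single curve only once the
    system maximum is constrained — in practice the response scale of the
    normalized reference pathway.
    """
    role = role or curve.role
    if curve.concentrations.size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    x = np.repeat(curve.x[None, :], curve.responses.shape[0], axis=0).ravel()
    y = curve.responses.ravel()

    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * scale:
        raise UnidentifiableFitError(
            "flat dose-response curve: LogR is unbounded below and cannot be fitted"
        )

    basal0 = fix_basal if fix_basal is not None else float(y.min())
    emax0 = fix_emax if fix_emax is not None else float(y.max())
    # LogKA is weakly identified: scan several starts across the dose range
    log_ka_starts = (
        [0.0]
        if role == "reference"
        else [float(np.quantile(curve.x, q)) for q in (0.4, 0.85)]
    )

    all_names = (
        ["basal", "emax", "n", "log_r"]
        if role == "reference"
        else ["basal", "emax", "n", "log_ka", "log_r"]
    )
    fixed = {}
    if fix_basal is not None:
        fixed["basal"] = float(fix_basal)
    if fix_emax is not None:
        fixed["emax"] = float(fix_emax)
    free = [nm for nm in all_names if nm not in fixed]
    bound_table = {
        "basal": (-np.inf, np.inf), "emax": (-np.inf, np.inf), "n": (1e-3, 10.0),
        "log_ka": (-15.0, 5.0), "log_r": (-15.0, 20.0),
    }
    lower = [bound_table[nm][0] for nm in free]
    upper = [bound_table[nm][1] for nm in free]

    def _full(theta: np.ndarray) -> OperationalParams:
        values = dict(zip(free, theta))
        values.update(fixed)
        return OperationalParams(
            basal=values["basal"], emax=values["emax"], n=values["n"],
            log_ka=values.get("log_ka", 0.0), log_r=values["log_r"],
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _full(theta)
        try:
            p.validate()
        except ValueError:
            return np.full_like(y, 1e6)
        return operational_forward(p, x, role=role) - y

    best = None
    for log_r0 in log_r_grid:
        for log_ka0 in log_ka_starts:
            start = {
                "basal": basal0, "emax": emax0, "n": 1.0,
                "log_ka": log_ka0, "log_r": float(log_r0),
            }
            theta0 = np.array([start[nm] for nm in free])
            try:
                res = least_squares(
                    residuals, theta0, bounds=(lower, upper),
                    max_nfev=max_nfev, xtol=1e-10, ftol=1e-10,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("operational-model fit failed from every start")
    # polish the winning start with tight tolerances
    scout_ok = bool(best.success)
    best = least_squares(
        residuals, best.x, bounds=(lower, upper),
        max_nfev=4 * max_nfev, xtol=1e-12, ftol=1e-12,
    )

    params = _full(best.x)
    dof = max(y.size - len(free), 1)
    sigma2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    identifiable = True
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        sems = {nm: float(np.sqrt(max(c, 0.0))) for nm, c in zip(free, np.diag(cov))}
    except np.linalg.LinAlgError:
        identifiable = False
        sems = {nm: float("inf") for nm in free}
    for nm in fixed:
        sems[nm] = 0.0
    fit = OperationalFit(
        basal=params.basal, emax=params.emax, n=params.n,
        log_ka=params.log_ka, log_r=params.log_r,
        sem=sems, converged=bool(best.success) or scout_ok, identifiable=identifiable,
        residual=float(np.sqrt(2.0 * best.cost / y.size)),
        role=role, receptor=curve.receptor, pathway=curve.pathway,
    )
    if not fit.converged:
        warnings.warn(
            f"fit did not report convergence (residual {fit.residual:.3g})", UserWarning
        )
    return fit


@dataclass(frozen=True)
class BiasEntry:
    receptor: str
    pathway: str
    delta: float
    sem: float


def delta_log_tau_ka(fit_mut: OperationalFit, fit_wt: OperationalFit) -> BiasEntry:
    """Relative activity Δlog(τ/K_A) = log(τ/K_A)_mutant − log(τ/K_A)_WT.

    The SEM propagates in quadrature: sqrt(SEM_mut² + SEM_WT²).
    """
    if fit_mut.pathway != fit_wt.pathway:
        raise ValueError(
            f"pathway mismatch: {fit_mut.pathway!r} vs {fit_wt.pathway!r}"
        )
    if not (fit_mut.converged and fit_wt.converged):
        raise ValueError("both fits must have converged")
    delta = fit_mut.log_r - fit_wt.log_r
    sem = float(np.hypot(fit_mut.sem.get("log_r", np.nan), fit_wt.sem.get("log_r", np.nan)))
    return BiasEntry(receptor=fit_mut.receptor, pathway=fit_mut.pathway, delta=delta, sem=sem)


def bias_heatmap(
    entries: Sequence[BiasEntry], allow_missing: bool = False
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Mutant × pathway Δlog(τ/K_A) matrix with symmetric color bounds ±max|Δ|."""
    if not entries:
        raise ValueError("no bias entries supplied")
    receptors = list(dict.fromkeys(e.receptor for e in entries))
    pathways = list(dict.fromkeys(e.pathway for e in entries))
    matrix = pd.DataFrame(np.nan, index=receptors, columns=pathways)
    for e in entries:
        matrix.loc[e.receptor, e.pathway] = e.delta
    if matrix.isna().any().any() and not allow_missing:
        raise ValueError("incomplete mutant × pathway grid; pass allow_missing=True")
    vmax = float(np.nanmax(np.abs(matrix.to_numpy())))
    return matrix, (-vmax, vmax)
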