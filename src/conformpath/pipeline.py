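"""End-to-end orchestration: simulate -> landscape -> MSM -> TPT / tICA -> report.

Every stage writes plain CSV/JSON artifacts so any stage can be rerun
standalone; the summary JSON is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import KT_300K, __version__
from .featurize import FeatureTrajectory
from .landscape import estimate_landscape
from .msm import (
    cluster_microstates,
    count_transitions,
    estimate_T,
    implied_timescales,
    label_macrostates,
    pcca,
    representative_conformation,
)
from .synthetic_data import (
    DEFAULT_BASIN_CENTERS,
    LangevinConfig,
    make_three_basin_potential,
    simulate_langevin,
)
from .tica import fit_tica, transform
from .tpt import mfpt_matrix

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_STATE_NAMES = ("inactive", "intermediate", "active")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated stage parameters for a full synthetic-pipeline run."""

    seed: int = 1
    out_dir: str = "run"
    # simulate
    n_steps: int = 200_000
    dt: float = 0.05
    kT: float = KT_300K
    diffusion: tuple = (0.6, 15.0)
    x0: tuple = (21.3, 38.0)
    frame_time: float = 1.0
    # landscape
    bins: int = 60
    # msm
    k: int = 100
    lag: int = 50
    n_macrostates: int = 3
    max_iter: int = 200
    mode: str = "nonreversible"
    its_lags: tuple = (10, 25, 50, 100)
    # tica
    tica_lag: int = 50
    tica_k: int = 50
    tica_macrostates: int = 3
    # representative selection
    pool_size: int = 20

    def validate(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.k > self.n_steps + 1:
            raise ValueError(f"k={self.k} exceeds the {self.n_steps + 1} frames to be simulated")
        if self.tica_k > self.n_steps + 1:
            raise ValueError("tica_k exceeds the frames to be simulated")
        if self.lag < 1 or self.tica_lag < 1:
            raise ValueError("lags must be >= 1")
        if self.n_macrostates < 2 or self.tica_macrostates < 2:
            raise ValueError("need at least 2 macrostates")
        if self.bins < 10:
            raise ValueError("need at least 10 landscape bins")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg


def _representative_frames(features, micro, macro, tm, pool_size: int) -> dict:
    """Per-macrostate representative frame index via the similarity score.

    The candidate pool holds the frames nearest to the microstate centers of
    each macrostate; the pairwise distance is feature-space Euclidean.
    """
    x = np.vstack([t.values for t in (features if isinstance(features, list) else [features])])
    out = {}
    m = macro.memberships.shape[1]
    dtraj = np.concatenate(micro.dtrajs)
    for j in range(m):
        micro_states = tm.active_set[np.flatnonzero(macro.crisp == j)]
        pool_idx = []
        for s in micro_states:
            frames_in_state = np.flatnonzero(dtraj == s)
            if frames_in_state.size == 0:
                continue
            center = micro.centers[s]
            d = np.linalg.norm(x[frames_in_state] - center, axis=1)
            pool_idx.append(frames_in_state[int(np.argmin(d))])
        pool_idx = np.array(sorted(set(int(i) for i in pool_idx)))[:pool_size]
        if pool_idx.size < 2:
            out[j] = int(pool_idx[0]) if pool_idx.size else -1
            continue
        coords = x[pool_idx]
        dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        winner, _ = representative_conformation(dmat)
        out[j] = int(pool_idx[winner])
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable summary (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("simulate")
        surface = make_three_basin_potential()
        traj = simulate_langevin(
            surface,
            LangevinConfig(
                dt=config.dt, diffusion=config.diffusion, kT=config.kT,
                n_steps=config.n_steps, x0=config.x0, seed=config.seed,
            ),
        )
        traj.to_csv(out_dir / "traj.csv")
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    try:
        _stage("landscape")
        ls = estimate_landscape(traj, bins=config.bins, kT=config.kT)
        ls.to_csv(out_dir / "landscape.csv")
        (out_dir / "landscape.json").write_text(json.dumps(ls.metadata(), sort_keys=True))
    except Exception as exc:
        raise PipelineError("landscape", str(exc)) from exc

    try:
        _stage("msm")
        micro = cluster_microstates(traj, k=config.k, max_iter=config.max_iter, seed=config.seed)
        np.savetxt(out_dir / "dtrajs.csv", micro.dtrajs[0], fmt="%d")
        its = implied_timescales(micro.dtrajs, list(config.its_lags), mode=config.mode,
                                 frame_time=config.frame_time)
        counts = count_transitions(micro.dtrajs, config.lag)
        tm = estimate_T(counts, mode=config.mode, lag=config.lag, frame_time=config.frame_time)
        np.savetxt(out_dir / "transition_matrix.csv", tm.T, delimiter=",")
        macro = pcca(tm, config.n_macrostates)
        ref = {name: center for name, center in zip(_STATE_NAMES, DEFAULT_BASIN_CENTERS)}
        macro = label_macrostates(macro, micro.centers, tm, ref)
    except Exception as exc:
        raise PipelineError("msm", str(exc)) from exc

    try:
        _stage("tpt")
        sets = [
            tm.active_set[np.flatnonzero(macro.crisp == j)].tolist()
            for j in range(config.n_macrostates)
        ]
        # mfpt_matrix works on active-set-internal indices
        internal_sets = [np.flatnonzero(macro.crisp == j) for j in range(config.n_macrostates)]
        mfpts = mfpt_matrix(tm, internal_sets, lag_physical=tm.lag_time)
        np.savetxt(out_dir / "mfpt.csv", mfpts, delimiter=",")
    except Exception as exc:
        raise PipelineError("tpt", str(exc)) from exc

    try:
        _stage("tica")
        tica_model = fit_tica(traj, lag=config.tica_lag)
        proj = transform(tica_model, traj)
        tmicro = cluster_microstates(proj, k=config.tica_k, seed=config.seed)
        tcounts = count_transitions(tmicro.dtrajs, config.lag)
        ttm = estimate_T(tcounts, mode=config.mode, lag=config.lag, frame_time=config.frame_time)
        tmacro = pcca(ttm, config.tica_macrostates)
    except Exception as exc:
        raise PipelineError("tica", str(exc)) from exc

    try:
        _stage("report")
        reps = _representative_frames(traj, micro, macro, tm, config.pool_size)
        summary = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "landscape_path": str(out_dir / "landscape.csv"),
            "n_macrostates": config.n_macrostates,
            "macrostate_labels": macro.labels,
            "macrostate_populations": [round(float(p), 12) for p in macro.probabilities],
            "mfpt_table": [[round(float(v), 9) for v in row] for row in mfpts],
            "implied_timescales": [[round(float(v), 9) for v in row] for row in its],
            "tica_macrostate_count": int(tmacro.memberships.shape[1]),
            "tica_eigenvalues": [round(float(v), 12) for v in tica_model.eigenvalues],
            "representative_frames": {str(k): v for k, v in sorted(reps.items())},
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    return summary
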