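"""Parameter estimation for the release/replenishment model.

The canonical experiment constrains the model with normalized EPSC amplitudes
from regular trains at several frequencies plus a post-train recovery curve:
the trains pin the release probability ``pv`` and the fast replenishment time
constant ``tau_h``, while the recovery curve (probes out to tens of seconds)
pins the background time constant ``tau_b`` and the relaxation time constant
``tau_d``.

Fitting is bounded nonlinear least squares (scipy ``least_squares``, trf)
from multiple seeded random starts; time constants are optimized in log10
space since plausible values span several decades.  A two-parameter "delta"
fit re-estimates only ``pv`` and ``tau_h`` with the slow time constants held
at reference (wild-type) values — the comparison used to interpret a
genotype difference as a change in release probability and activity-dependent
replenishment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .model import ReleaseModelParams, StimulusProtocol, _simulate_amps_exact

__all__ = [
    "TrainSet",
    "RecoverySet",
    "FitDataset",
    "FitConfig",
    "FitResult",
    "objective_rss",
    "fit_model",
    "fit_ko_delta",
    "DEFAULT_BOUNDS",
]

PARAM_ORDER = ("pv", "tau_b", "tau_h", "tau_d")

# Bounds bracket the plausible physiological range and the 30 s recovery horizon.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "pv": (0.01, 0.9),
    "tau_h": (1.0, 1000.0),
    "tau_b": (100.0, 60000.0),
    "tau_d": (10.0, 30000.0),
}


@dataclass
class TrainSet:
    """One train protocol with its mean normalized amplitudes (and SEMs)."""

    protocol: StimulusProtocol
    amps: np.ndarray
    sem: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.amps = np.asarray(self.amps, dtype=float)
        if self.amps.size != len(self.protocol):
            raise ValueError(
                f"{self.amps.size} amplitudes for {len(self.protocol)} spikes "
                f"in {self.protocol.label!r}"
            )
        if np.any(self.amps < 0.0):
            raise ValueError("normalized amplitudes must be non-negative")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.size != self.amps.size:
                raise ValueError("SEM length must match amplitudes")


@dataclass
class RecoverySet:
    """Conditioning train + recovery probes with probe amplitudes.

    ``mode="sequential"`` treats all probes as one sweep (each probe releases
    and perturbs later probes, as in a single-trace protocol);
    ``mode="independent"`` treats each probe as a fresh sweep from the
    post-train state.
    """

    protocol: StimulusProtocol
    probe_intervals_s: np.ndarray
    amps: np.ndarray
    sem: Optional[np.ndarray] = None
    mode: str = "sequential"

    def __post_init__(self) -> None:
        self.probe_intervals_s = np.asarray(self.probe_intervals_s, dtype=float)
        self.amps = np.asarray(self.amps, dtype=float)
        n_probes = int(self.protocol.probe_mask.sum())
        if n_probes == 0:
            raise ValueError("recovery protocol has no tagged probes")
        if self.amps.size != n_probes or self.probe_intervals_s.size != n_probes:
            raise ValueError("probe amplitudes/intervals must match tagged probes")
        if self.mode not in ("sequential", "independent"):
            raise ValueError(f"unknown recovery mode {self.mode!r}")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)


@dataclass
class FitDataset:
    """Everything one condition contributes to the objective."""

    train_sets: List[TrainSet]
    recovery_set: Optional[RecoverySet] = None
    condition_label: str = ""

    def n_points(self) -> int:
        n = sum(ts.amps.size for ts in self.train_sets)
        if self.recovery_set is not None:
            n += self.recovery_set.amps.size
        return n


@dataclass
class FitConfig:
    """Optimizer settings for the multi-start bounded least-squares fit."""

    free_params: Tuple[str, ...] = PARAM_ORDER
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    n_starts: int = 20
    seed: int = 0
    tolerance: float = 1e-12
    fixed_values: Dict[str, float] = field(default_factory=dict)
    weights: str = "uniform"

    def __post_init__(self) -> None:
        for p in self.free_params:
            if p not in PARAM_ORDER:
                raise ValueError(f"unknown parameter {p!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        lo, hi = self.bounds.get("pv", DEFAULT_BOUNDS["pv"])
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("pv bounds must satisfy 0 < low < high <= 1")
        for p in ("tau_b", "tau_h", "tau_d"):
            lo, hi = self.bounds.get(p, DEFAULT_BOUNDS[p])
            if not (0.0 < lo < hi):
                raise ValueError(f"{p} bounds must be positive and ordered")
        if self.weights not in ("uniform", "inverse-sem"):
            raise ValueError(f"unknown weights mode {self.weights!r}")


@dataclass
class FitResult:
    params: ReleaseModelParams
    rss: float
    residuals: Dict[str, np.ndarray]
    converged: bool
    start_count: int
    best_start_seed: int
    warnings: List[str] = field(default_factory=list)
    start_rss: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rss": self.rss,
            "converged": self.converged,
            "start_count": self.start_count,
            "best_start_seed": self.best_start_seed,
            "warnings": list(self.warnings),
            "residual_rms": {
                k: float(np.sqrt(np.mean(v**2))) for k, v in self.residuals.items()
            },
        }


def predict_dataset(
    params: ReleaseModelParams, dataset: FitDataset
) -> Dict[str, np.ndarray]:
    """Model-predicted normalized amplitudes for every set in the dataset."""
    out: Dict[str, np.ndarray] = {}
    for ts in dataset.train_sets:
        amps = _simulate_amps_exact(
            ts.protocol.spike_times,
            params.pv,
            params.tau_b,
            params.tau_h,
            params.tau_d,
            params.n0,
            params.tau_r_start,
        )
        out[ts.protocol.label] = amps / amps[0]
    rs = dataset.recovery_set
    if rs is not None:
        out[rs.protocol.label] = _predict_recovery(params, rs)
    return out


def _predict_recovery(params: ReleaseModelParams, rs: RecoverySet) -> np.ndarray:
    mask = rs.protocol.probe_mask
    if rs.mode == "sequential":
        amps = _simulate_amps_exact(
            rs.protocol.spike_times,
            params.pv,
            params.tau_b,
            params.tau_h,
            params.tau_d,
            params.n0,
            params.tau_r_start,
        )
        return (amps / amps[0])[mask]
    # independent mode: each probe is its own sweep from the post-train state
    train_times = tuple(
        t for t, m in zip(rs.protocol.spike_times, mask) if not m
    )
    probe_times = [t for t, m in zip(rs.protocol.spike_times, mask) if m]
    out = np.empty(len(probe_times))
    for i, tp in enumerate(probe_times):
        amps = _simulate_amps_exact(
            train_times + (tp,),
            params.pv,
            params.tau_b,
            params.tau_h,
            params.tau_d,
            params.n0,
            params.tau_r_start,
        )
        out[i] = amps[-1] / amps[0]
    return out


def _residual_vector(
    params: ReleaseModelParams, dataset: FitDataset, weights: str
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    preds = predict_dataset(params, dataset)
    pieces = []
    per_set: Dict[str, np.ndarray] = {}
    sets: List[Tuple[str, np.ndarray, Optional[np.ndarray]]] = [
        (ts.protocol.label, ts.amps, ts.sem) for ts in dataset.train_sets
    ]
    if dataset.recovery_set is not None:
        rs = dataset.recovery_set
        sets.append((rs.protocol.label, rs.amps, rs.sem))
    for label, obs, sem in sets:
        r = preds[label] - obs
        per_set[label] = r
        if weights == "inverse-sem" and sem is not None:
            w = 1.0 / np.clip(sem, np.nanmax(sem) * 1e-3 + 1e-12, None)
            r = r * w / w.mean()
        pieces.append(r)
    return np.concatenate(pieces), per_set


def objective_rss(
    params: ReleaseModelParams, dataset: FitDataset, weights: str = "uniform"
) -> float:
    """Sum of squared residuals between model and data on normalized amplitudes."""
    r, _ = _residual_vector(params, dataset, weights)
    return float(np.dot(r, r))


def _encode(values: Dict[str, float], free: Sequence[str]) -> np.ndarray:
    x = []
    for p in free:
        v = values[p]
        x.append(v if p == "pv" else math.log10(v))
    return np.asarray(x)


def _decode(x: np.ndarray, free: Sequence[str], fixed: Dict[str, float]) -> dict:
    values = dict(fixed)
    for p, xi in zip(free, x):
        values[p] = xi if p == "pv" else 10.0**xi
    return values


def _identifiability_warnings(dataset: FitDataset, free: Sequence[str]) -> List[str]:
    warns = []
    slow_free = {"tau_b", "tau_d"} & set(free)
    if slow_free and dataset.recovery_set is None:
        warns.append(
            f"{sorted(slow_free)} free without recovery data: "
            "slow replenishment time constants are poorly identified"
        )
    if len(dataset.train_sets) < 2 and ({"pv", "tau_h"} & set(free)):
        warns.append(
            "fewer than 2 train frequencies: pv/tau_h may be poorly identified"
        )
    return warns


def fit_model(dataset: FitDataset, config: Optional[FitConfig] = None) -> FitResult:
    """Multi-start bounded least-squares estimate of the free model parameters.

    Initial points are drawn uniformly within bounds (log-uniform for time
    constants) from a generator seeded by ``config.seed``; the reference
    parameter midpoint is always included as the first start.  Deterministic
    given the seed.
    """
    config = config or FitConfig()
    free = tuple(p for p in PARAM_ORDER if p in config.free_params)
    fixed = dict(config.fixed_values)
    missing = [p for p in PARAM_ORDER if p not in free and p not in fixed]
    if missing:
        raise ValueError(f"parameters neither free nor fixed: {missing}")
    if not dataset.train_sets and dataset.recovery_set is None:
        raise ValueError("empty dataset")

    warns = _identifiability_warnings(dataset, free)
    for w in warns:
        warnings.warn(w, stacklevel=2)

    bounds = {p: config.bounds.get(p, DEFAULT_BOUNDS[p]) for p in PARAM_ORDER}
    lo = _encode({p: bounds[p][0] for p in free}, free)
    hi = _encode({p: bounds[p][1] for p in free}, free)

    def residual(x: np.ndarray) -> np.ndarray:
        values = _decode(x, free, fixed)
        params = ReleaseModelParams(**values)
        r, _ = _residual_vector(params, dataset, config.weights)
        return r

    rng = np.random.default_rng(config.seed)
    starts = [(lo + hi) / 2.0]
    for _ in range(config.n_starts - 1):
        starts.append(rng.uniform(lo, hi))

    best = None
    best_i = -1
    start_rss: List[float] = []
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
                max_nfev=400 * (len(free) + 1),
            )
        except Exception:
            start_rss.append(math.inf)
            continue
        rss = float(2.0 * sol.cost)
        start_rss.append(rss)
        if best is None or rss < best_rss:
            best, best_rss, best_i = sol, rss, i

    if best is None:
        raise RuntimeError("all optimizer starts failed")

    values = _decode(best.x, free, fixed)
    params = ReleaseModelParams(**values)
    _, per_set = _residual_vector(params, dataset, config.weights)
    converged = bool(best.status > 0) and math.isfinite(best_rss)
    return FitResult(
        params=params,
        rss=best_rss,
        residuals=per_set,
        converged=converged,
        start_count=len(starts),
        best_start_seed=best_i,
        warnings=warns,
        start_rss=start_rss,
    )


def fit_ko_delta(
    dataset: FitDataset,
    wt_params: ReleaseModelParams,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Two-parameter delta fit: only pv and tau_h free, slow constants at WT.

    Used to ask whether a condition difference is explained by release
    probability and activity-dependent replenishment alone, with the
    background replenishment (tau_b) and its relaxation (tau_d) inherited
    from the reference fit.
    """
    config = config or FitConfig()
    delta_config = FitConfig(
        free_params=("pv", "tau_h"),
        bounds=dict(config.bounds),
        n_starts=config.n_starts,
        seed=config.seed,
        tolerance=config.tolerance,
        fixed_values={"tau_b": wt_params.tau_b, "tau_d": wt_params.tau_d},
        weights=config.weights,
    )
    return fit_model(dataset, delta_config)
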