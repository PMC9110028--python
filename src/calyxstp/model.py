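"""Vesicle-pool model of transmitter release with activity-dependent replenishment.

The readily releasable pool (RRP) has normalized occupancy ``n`` (0..1).  Each
presynaptic action potential at time ``s`` releases a fraction ``Pv`` of the
pool, producing an EPSC proportional to ``n(s)·Pv``, and instantaneously resets
the replenishment time constant ``tau_r`` to the fast, activity-dependent value
``tau_h``.  Between spikes the pool refills from an infinite reserve,

    dn/dt     = (1 - n) / tau_r(t)
    dtau_r/dt = (tau_b - tau_r) / tau_d

so ``tau_r`` relaxes back to the slow background value ``tau_b`` with time
constant ``tau_d``.

The spike-free dynamics admit a closed-form solution, used by the exact
event-driven engine; a forward-Euler integrator is retained as the reference
method.  All times are milliseconds; amplitudes are positive magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReleaseModelParams",
    "StimulusProtocol",
    "SimulationTrace",
    "interval_update",
    "apply_spike",
    "simulate",
    "steady_state_norm_amplitude",
]


@dataclass(frozen=True)
class ReleaseModelParams:
    """Parameters of the release/replenishment model.

    Attributes
    ----------
    pv : float
        Vesicle release probability per action potential, dimensionless,
        0 < pv <= 1.
    tau_b : float
        Background (resting) replenishment time constant, ms.
    tau_h : float
        Post-spike (activity-dependent) replenishment time constant, ms;
        typically faster (smaller) than ``tau_b``.
    tau_d : float
        Relaxation time constant of the replenishment rate back to
        background, ms.
    n0 : float
        Initial normalized pool occupancy (default 1: full pool at rest).
    tau_r_init : float or None
        Replenishment time constant at protocol start; ``None`` means the
        resting value ``tau_b``.
    """

    pv: float
    tau_b: float
    tau_h: float
    tau_d: float
    n0: float = 1.0
    tau_r_init: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pv <= 1.0):
            raise ValueError(f"pv must be in (0, 1], got {self.pv}")
        for name in ("tau_b", "tau_h", "tau_d"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0.0 <= self.n0 <= 1.0):
            raise ValueError(f"n0 must be in [0, 1], got {self.n0}")
        if self.tau_r_init is not None:
            lo = min(self.tau_b, self.tau_h)
            hi = max(self.tau_b, self.tau_h)
            if not (lo <= self.tau_r_init <= hi):
                raise ValueError(
                    f"tau_r_init={self.tau_r_init} outside [{lo}, {hi}]"
                )

    @property
    def tau_r_start(self) -> float:
        """Effective initial replenishment time constant."""
        return self.tau_b if self.tau_r_init is None else self.tau_r_init

    def with_updates(self, **kwargs) -> "ReleaseModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "pv": self.pv,
            "tau_b": self.tau_b,
            "tau_h": self.tau_h,
            "tau_d": self.tau_d,
            "n0": self.n0,
            "tau_r_init": self.tau_r_init,
        }


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered presynaptic spike-time sequence (ms), optionally tagged.

    ``segment_tags`` marks each spike as part of the conditioning ``"train"``
    or as a ``"recovery_probe"``; untagged protocols are plain trains.
    """

    spike_times: tuple = ()
    label: str = ""
    segment_tags: Optional[tuple] = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.spike_times)
        object.__setattr__(self, "spike_times", times)
        if len(times) == 0:
            raise ValueError("protocol must contain at least one spike")
        arr = np.asarray(times)
        if arr[0] < 0.0 or np.any(np.diff(arr) <= 0.0):
            raise ValueError("spike_times must be non-negative and strictly increasing")
        if self.segment_tags is not None:
            tags = tuple(self.segment_tags)
            if len(tags) != len(times):
                raise ValueError("segment_tags length must match spike_times")
            bad = set(tags) - {"train", "recovery_probe"}
            if bad:
                raise ValueError(f"unknown segment tags: {sorted(bad)}")
            object.__setattr__(self, "segment_tags", tags)

    def __len__(self) -> int:
        return len(self.spike_times)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.spike_times, dtype=float)

    @property
    def probe_mask(self) -> np.ndarray:
        """Boolean mask of recovery-probe spikes (all False when untagged)."""
        if self.segment_tags is None:
            return np.zeros(len(self), dtype=bool)
        return np.array([t == "recovery_probe" for t in self.segment_tags])

    @classmethod
    def regular_train(
        cls, frequency_hz: float, duration_ms: float, label: str = ""
    ) -> "StimulusProtocol":
        """Regular train: floor(f·D/1000) spikes at interval 1000/f ms, from t=0."""
        if frequency_hz <= 0 or duration_ms <= 0:
            raise ValueError("frequency and duration must be positive")
        n_spikes = int(math.floor(frequency_hz * duration_ms / 1000.0))
        if n_spikes < 1:
            raise ValueError("protocol would contain no spikes")
        isi = 1000.0 / frequency_hz
        times = tuple(i * isi for i in range(n_spikes))
        return cls(
            spike_times=times,
            label=label or f"train_{frequency_hz:g}hz",
            segment_tags=("train",) * n_spikes,
        )

    @classmethod
    def train_with_recovery(
        cls,
        frequency_hz: float,
        duration_ms: float,
        probe_intervals_ms: Sequence[float],
        label: str = "",
    ) -> "StimulusProtocol":
        """Conditioning train plus recovery probes at the given intervals.

        Probe times are measured from the last conditioning stimulus (the
        recovery time origin).
        """
        train = cls.regular_train(frequency_hz, duration_ms)
        t_end = train.spike_times[-1]
        probes = tuple(sorted(float(d) for d in probe_intervals_ms))
        if any(d <= 0 for d in probes):
            raise ValueError("probe intervals must be positive")
        times = train.spike_times + tuple(t_end + d for d in probes)
        tags = ("train",) * len(train) + ("recovery_probe",) * len(probes)
        return cls(
            spike_times=times,
            label=label or f"recovery_{frequency_hz:g}hz",
            segment_tags=tags,
        )


@dataclass
class SimulationTrace:
    """Per-spike record of a simulated protocol.

    ``epsc_raw`` is ``n_pre·pv`` (read from the pre-spike occupancy);
    ``epsc_norm`` is normalized to the first spike of the protocol.  ``dense``
    optionally holds a regularly sampled (time, n, tau_r) trajectory.
    """

    spike_times: np.ndarray
    n_pre: np.ndarray
    n_post: np.ndarray
    tau_r_pre: np.ndarray
    epsc_raw: np.ndarray
    epsc_norm: np.ndarray
    params: ReleaseModelParams
    protocol: StimulusProtocol
    method: str = "exact"
    dense: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tabular trace: spike_index (1-based), time_ms, pool states, EPSCs."""
        return pd.DataFrame(
            {
                "spike_index": np.arange(1, len(self.spike_times) + 1),
                "time_ms": self.spike_times,
                "n_pre": self.n_pre,
                "n_post": self.n_post,
                "tau_r_pre_ms": self.tau_r_pre,
                "epsc_raw": self.epsc_raw,
                "epsc_norm": self.epsc_norm,
            }
        )


def interval_update(
    n: float, tau_r: float, delta: float, params: ReleaseModelParams
) -> tuple:
    """Exact spike-free update of (n, tau_r) over an interval of ``delta`` ms.

    With c = tau_r - tau_b at interval start, the replenishment time constant
    relaxes as tau_r(Δ) = tau_b + c·e^(-Δ/tau_d), and the depletion deficit
    decays as 1 - n(Δ) = (1 - n)·e^(-I) with

        I = Δ/tau_b + (tau_d/tau_b)·ln[(tau_b + c·e^(-Δ/tau_d)) / (tau_b + c)]

    (the integral of dt/tau_r(t) in closed form; I = Δ/tau_b when c = 0).
    """
    if tau_r <= 0.0:
        raise ValueError(f"tau_r must be positive, got {tau_r}")
    if delta < 0.0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    if not (0.0 <= n <= 1.0):
        raise ValueError(f"n must be in [0, 1], got {n}")
    if delta == 0.0:
        return n, tau_r
    tau_b, tau_d = params.tau_b, params.tau_d
    c = tau_r - tau_b
    decay = math.exp(-delta / tau_d)
    tau_r_new = tau_b + c * decay
    if c == 0.0:
        integral = delta / tau_b
    else:
        integral = delta / tau_b + (tau_d / tau_b) * math.log(tau_r_new / tau_r)
    n_new = 1.0 - (1.0 - n) * math.exp(-integral)
    return n_new, tau_r_new


def apply_spike(n: float, params: ReleaseModelParams) -> tuple:
    """Release at a spike: EPSC from the pre-spike pool, then deplete and reset.

    Returns ``(epsc_raw, n_after, tau_r_after)`` with ``epsc_raw = n·pv``,
    ``n_after = n·(1 - pv)`` and ``tau_r_after = tau_h`` (the post-spike reset
    applies to every spike, including the first).
    """
    if not (0.0 <= n <= 1.0):
        raise ValueError(f"n must be in [0, 1], got {n}")
    epsc = n * params.pv
    return epsc, n * (1.0 - params.pv), params.tau_h


def _simulate_amps_exact(
    spike_times: Sequence[float],
    pv: float,
    tau_b: float,
    tau_h: float,
    tau_d: float,
    n0: float,
    tau_r0: float,
) -> np.ndarray:
    """Fast inner loop: raw EPSC amplitudes only, exact event-driven updates.

    Inlined closed-form interval update; used by the fitting objective where
    this loop dominates runtime.
    """
    exp = math.exp
    log = math.log
    n = n0
    tau_r = tau_r0
    amps = np.empty(len(spike_times))
    t_prev = spike_times[0]
    for i, t in enumerate(spike_times):
        delta = t - t_prev
        if delta > 0.0:
            c = tau_r - tau_b
            tau_r_new = tau_b + c * exp(-delta / tau_d)
            if c == 0.0:
                integral = delta / tau_b
            else:
                integral = delta / tau_b + (tau_d / tau_b) * log(tau_r_new / tau_r)
            n = 1.0 - (1.0 - n) * exp(-integral)
            tau_r = tau_r_new
        amps[i] = n * pv
        n *= 1.0 - pv
        tau_r = tau_h
        t_prev = t
    return amps


def _simulate_euler(
    protocol: StimulusProtocol, params: ReleaseModelParams, dt: float
) -> tuple:
    """Forward-Euler reference integrator; spike events applied as in exact mode.

    Each inter-spike interval is integrated with uniform sub-steps of size
    <= dt, so spike times fall exactly on step boundaries.
    """
    times = protocol.times
    isis = np.diff(times)
    if len(isis) and dt >= isis.min():
        raise ValueError(
            f"Euler dt={dt} must be smaller than the smallest inter-spike "
            f"interval ({isis.min():g} ms)"
        )
    tau_b, tau_d = params.tau_b, params.tau_d
    n = params.n0
    tau_r = params.tau_r_start
    n_pre = np.empty(len(times))
    tau_r_pre = np.empty(len(times))
    n_post = np.empty(len(times))
    t_prev = times[0]
    for i, t in enumerate(times):
        delta = t - t_prev
        if delta > 0.0:
            steps = max(1, int(math.ceil(delta / dt - 1e-12)))
            h = delta / steps
            for _ in range(steps):
                n += h * (1.0 - n) / tau_r
                tau_r += h * (tau_b - tau_r) / tau_d
            n = min(n, 1.0)
        n_pre[i] = n
        tau_r_pre[i] = tau_r
        n *= 1.0 - params.pv
        n_post[i] = n
        tau_r = params.tau_h
        t_prev = t
    return n_pre, n_post, tau_r_pre


def simulate(
    protocol: StimulusProtocol,
    params: ReleaseModelParams,
    method: str = "exact",
    dt: float = 0.01,
    dense_dt: Optional[float] = None,
) -> SimulationTrace:
    """Simulate a stimulus protocol and return the per-spike trace.

    Parameters
    ----------
    method : {"exact", "euler"}
        "exact" iterates the closed-form interval update between spikes;
        "euler" integrates the differential equations with explicit forward
        Euler at step ``dt`` (ms), applying identical spike events.
    dense_dt : float, optional
        If given (exact mode only), additionally sample the continuous
        (n, tau_r) trajectory every ``dense_dt`` ms into ``trace.dense``.
    """
    times = protocol.times
    if method == "exact":
        n = params.n0
        tau_r = params.tau_r_start
        n_pre = np.empty(len(times))
        n_post = np.empty(len(times))
        tau_r_pre = np.empty(len(times))
        dense_rows = [] if dense_dt is not None else None
        t_prev = times[0]
        for i, t in enumerate(times):
            delta = t - t_prev
            if delta > 0.0:
                if dense_rows is not None:
                    for ts in np.arange(t_prev + dense_dt, t, dense_dt):
                        nd, trd = interval_update(n, tau_r, ts - t_prev, params)
                        dense_rows.append((ts, nd, trd))
                n, tau_r = interval_update(n, tau_r, delta, params)
            n_pre[i] = n
            tau_r_pre[i] = tau_r
            _, n, tau_r = apply_spike(n, params)
            n_post[i] = n
            t_prev = t
        dense = (
            pd.DataFrame(dense_rows, columns=["time_ms", "n", "tau_r_ms"])
            if dense_rows is not None
            else None
        )
    elif method == "euler":
        if dt <= 0.0:
            raise ValueError("dt must be positive for method='euler'")
        n_pre, n_post, tau_r_pre = _simulate_euler(protocol, params, dt)
        dense = None
    else:
        raise ValueError(f"unknown method {method!r}")

    epsc_raw = n_pre * params.pv
    epsc_norm = epsc_raw / epsc_raw[0]
    return SimulationTrace(
        spike_times=times,
        n_pre=n_pre,
        n_post=n_post,
        tau_r_pre=tau_r_pre,
        epsc_raw=epsc_raw,
        epsc_norm=epsc_norm,
        params=params,
        protocol=protocol,
        method=method,
        dense=dense,
    )


def steady_state_norm_amplitude(
    frequency_hz: float,
    params: ReleaseModelParams,
    constant_tau: bool = False,
    tol: float = 1e-12,
    max_spikes: int = 20000,
) -> float:
    """Steady-state normalized EPSC amplitude during a regular train.

    With ``constant_tau`` (tau_r pinned at tau_h throughout), the fixed point
    is available in closed form:

        n* = (1 - E) / (1 - (1 - pv)·E),   E = e^(-Δ/tau_h),  Δ = 1000/f ms

    and the normalized amplitude equals n*/n0.  Otherwise the full model is
    iterated until the per-spike amplitude converges.
    """
    if frequency_hz <= 0.0:
        raise ValueError("frequency must be positive")
    if constant_tau:
        delta = 1000.0 / frequency_hz
        E = math.exp(-delta / params.tau_h)
        n_star = (1.0 - E) / (1.0 - (1.0 - params.pv) * E)
        first = params.n0 if params.n0 > 0 else 1.0
        return n_star / first
    delta = 1000.0 / frequency_hz
    n = params.n0
    tau_r = params.tau_r_start
    first = None
    prev = None
    for i in range(max_spikes):
        if i > 0:
            n, tau_r = interval_update(n, tau_r, delta, params)
        amp = n * params.pv
        if first is None:
            first = amp
        if prev is not None and abs(amp - prev) <= tol * max(first, 1e-300):
            return amp / first
        prev = amp
        n *= 1.0 - params.pv
        tau_r = params.tau_h
    return prev / first
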