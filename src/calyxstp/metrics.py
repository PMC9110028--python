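"""Short-term depression and recovery summary statistics.

Implements the standard analyses applied to normalized EPSC amplitude
sequences at this synapse: paired-pulse ratio, late/early amplitude ratios,
a single-exponential fit to the depression time course within a train, and a
double-exponential fit to the post-train recovery curve.  Fits use lmfit
(Levenberg-Marquardt with bounds) and return flagged results rather than
raising on degenerate data, so batch pipelines keep going.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "TrainMetrics",
    "RecoveryMetrics",
    "paired_pulse_ratio",
    "ratio_k",
    "fit_std_exponential",
    "fit_recovery_double_exponential",
    "train_metrics",
]


@dataclass
class TrainMetrics:
    """Within-train depression summary.

    ppr2: EPSC_2/EPSC_1.  ratio80: EPSC_80/EPSC_1 (NaN when the train is
    shorter than 80 stimuli).  std_tau: depression decay time constant, ms.
    ss_amp: fitted steady-state normalized amplitude.
    """

    ppr2: float
    ratio80: float
    std_tau: float
    ss_amp: float
    converged: bool = True
    message: str = ""


@dataclass
class RecoveryMetrics:
    """Post-train recovery summary from a double-exponential fit.

    depth: depression at train end, D = 1 - A_end.  fast_fraction: weight f
    of the fast component of the recovery deficit.  tau_fast / tau_slow in
    seconds, ordered tau_fast < tau_slow.
    """

    depth: float
    fast_fraction: float
    tau_fast: float
    tau_slow: float
    converged: bool = True
    message: str = ""


def paired_pulse_ratio(amps: Sequence[float]) -> float:
    """EPSC_2/EPSC_1 for an ordered amplitude sequence."""
    amps = np.asarray(amps, dtype=float)
    if amps.size < 2:
        raise ValueError("paired-pulse ratio needs at least two amplitudes")
    if amps[0] == 0.0:
        raise ValueError("first amplitude is zero; ratio undefined")
    return float(amps[1] / amps[0])


def ratio_k(amps: Sequence[float], k: int = 80) -> float:
    """EPSC_k/EPSC_1 (1-based index; default the 80th response)."""
    amps = np.asarray(amps, dtype=float)
    if k < 1 or k > amps.size:
        raise ValueError(f"k={k} out of range for {amps.size} amplitudes")
    if amps[0] == 0.0:
        raise ValueError("first amplitude is zero; ratio undefined")
    return float(amps[k - 1] / amps[0])


def _single_exp_residual(pars, t, y):
    ss = pars["ss"].value
    a0 = pars["a0"].value
    tau = pars["tau"].value
    return ss + (a0 - ss) * np.exp(-t / tau) - y


def fit_std_exponential(
    times_ms: Sequence[float],
    norm_amps: Sequence[float],
    n_starts: int = 5,
    seed: int = 0,
) -> tuple:
    """Fit A(t) = ss + (A0 - ss)·e^(-t/tau) to within-train amplitudes.

    ``times_ms`` start at the first stimulus (origin 0).  A0, ss and tau are
    all free; the initial amplitude is not pinned to 1, which keeps the fit
    robust to noisy first responses.  Returns
    ``(std_tau_ms, ss_amp, converged, message)``; flat or otherwise
    tau-unidentifiable input yields ``converged=False`` with tau = NaN.
    """
    t = np.asarray(times_ms, dtype=float)
    y = np.asarray(norm_amps, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points for the exponential fit")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("times must be strictly increasing")
    span = t[-1] - t[0]
    if np.ptp(y) < 1e-12:
        return math.nan, float(y.mean()), False, "flat amplitudes: tau unidentifiable"

    rng = np.random.default_rng(seed)
    tau_guesses = [span / 5.0] + list(
        10 ** rng.uniform(math.log10(span / 200.0), math.log10(2.0 * span), n_starts - 1)
    )
    best = None
    for tau0 in tau_guesses:
        pars = Parameters()
        pars.add("ss", value=float(y[-5:].mean()), min=-1.0, max=2.0)
        pars.add("a0", value=float(y[0]), min=-1.0, max=3.0)
        pars.add("tau", value=float(tau0), min=span * 1e-4, max=span * 100.0)
        try:
            out = minimize(_single_exp_residual, pars, args=(t, y))
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        return math.nan, math.nan, False, "exponential fit failed to converge"
    tau = float(best.params["tau"].value)
    ss = float(best.params["ss"].value)
    # tau pushed to its bounds means the decay is not resolved by the data
    if tau >= span * 99.0 or tau <= span * 1.1e-4:
        return tau, ss, False, "tau at fit bound: poorly identified"
    return tau, ss, True, ""


def _double_exp_residual(pars, t, y, depth):
    f = pars["f"].value
    tf = pars["tau_fast"].value
    ts = pars["tau_slow"].value
    model = 1.0 - depth * (f * np.exp(-t / tf) + (1.0 - f) * np.exp(-t / ts))
    return model - y


def fit_recovery_double_exponential(
    intervals_s: Sequence[float],
    norm_amps: Sequence[float],
    a_end: float,
    n_starts: int = 8,
    seed: int = 0,
) -> RecoveryMetrics:
    """Fit the post-train recovery curve with a bi-exponential approach to 1.

        A(t) = 1 - D·[f·e^(-t/tau_f) + (1 - f)·e^(-t/tau_s)]

    The depth D is fixed at 1 - a_end (measured end-of-train amplitude);
    f, tau_f, tau_s are free, with the fast/slow ordering enforced by
    sorting after the fit.  Intervals are in seconds from the last
    conditioning stimulus.
    """
    t = np.asarray(intervals_s, dtype=float)
    y = np.asarray(norm_amps, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 recovery probes")
    if np.any(t <= 0.0) or np.any(np.diff(t) <= 0.0):
        raise ValueError("intervals must be positive and strictly increasing")
    depth = 1.0 - float(a_end)
    if not (0.0 <= depth <= 1.0):
        raise ValueError(f"end-of-train amplitude {a_end} outside [0, 1]")
    if depth < 1e-9:
        return RecoveryMetrics(
            depth=0.0,
            fast_fraction=math.nan,
            tau_fast=math.nan,
            tau_slow=math.nan,
            converged=False,
            message="no depression: recovery time constants unidentifiable",
        )

    rng = np.random.default_rng(seed)
    t_lo, t_hi = t[0], t[-1]
    starts = [(0.5, t_lo * 2.0, t_hi / 3.0)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                rng.uniform(0.1, 0.9),
                10 ** rng.uniform(math.log10(t_lo / 5.0), math.log10(t_hi)),
                10 ** rng.uniform(math.log10(t_lo), math.log10(t_hi * 5.0)),
            )
        )
    best = None
    for f0, tf0, ts0 in starts:
        pars = Parameters()
        pars.add("f", value=f0, min=0.0, max=1.0)
        pars.add("tau_fast", value=tf0, min=t_lo * 1e-3, max=t_hi * 100.0)
        pars.add("tau_slow", value=ts0, min=t_lo * 1e-3, max=t_hi * 100.0)
        try:
            out = minimize(_double_exp_residual, pars, args=(t, y, depth))
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        return RecoveryMetrics(
            depth=depth,
            fast_fraction=math.nan,
            tau_fast=math.nan,
            tau_slow=math.nan,
            converged=False,
            message="recovery fit failed to converge",
        )
    f = float(best.params["f"].value)
    tf = float(best.params["tau_fast"].value)
    ts = float(best.params["tau_slow"].value)
    if tf > ts:  # enforce tau_fast < tau_slow by relabelling
        tf, ts = ts, tf
        f = 1.0 - f
    return RecoveryMetrics(
        depth=depth, fast_fraction=f, tau_fast=tf, tau_slow=ts, converged=True
    )


def train_metrics(
    times_ms: Sequence[float], norm_amps: Sequence[float]
) -> TrainMetrics:
    """All within-train metrics for one normalized amplitude sequence."""
    amps = np.asarray(norm_amps, dtype=float)
    ppr = paired_pulse_ratio(amps)
    r80 = ratio_k(amps, 80) if amps.size >= 80 else math.nan
    tau, ss, ok, msg = fit_std_exponential(times_ms, amps)
    return TrainMetrics(
        ppr2=ppr, ratio80=r80, std_tau=tau, ss_amp=ss, converged=ok, message=msg
    )
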