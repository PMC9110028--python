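"""Synthetic EPSC-train datasets emulating the study's stimulation protocols.

Generates the conditions the analysis assumes: 800 ms regular trains at
100/200/400/600 Hz and a 100 Hz conditioning train followed by recovery
probes at 50 ms - 30 s, with per-cell lognormal parameter variability and
multiplicative Gaussian amplitude noise, repeats per cell, per-sweep
renormalization to the first EPSC, and averaging across repeats and cells
into a fit-ready dataset with SEMs.  Fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import FitDataset, RecoverySet, TrainSet
from .model import ReleaseModelParams, StimulusProtocol, simulate

__all__ = [
    "NoiseSpec",
    "TRAIN_FREQUENCIES_HZ",
    "RECOVERY_INTERVALS_S",
    "make_paper_protocols",
    "generate_dataset",
]

TRAIN_FREQUENCIES_HZ = (100.0, 200.0, 400.0, 600.0)
TRAIN_DURATION_MS = 800.0
RECOVERY_INTERVALS_S = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0)
RECOVERY_CONDITIONING_HZ = 100.0


@dataclass(frozen=True)
class NoiseSpec:
    """Statistical structure of the emulated experiment.

    amp_cv: multiplicative Gaussian CV on each amplitude.  cell_param_cv:
    lognormal CV of per-cell jitter applied to each model parameter.
    n_cells / n_repeats: cells and sweeps per protocol per cell.
    """

    amp_cv: float = 0.1
    cell_param_cv: float = 0.1
    n_cells: int = 10
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amp_cv < 0 or self.cell_param_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.n_cells < 1 or self.n_repeats < 1:
            raise ValueError("n_cells and n_repeats must be >= 1")


def make_paper_protocols(
    frequencies_hz: Sequence[float] = TRAIN_FREQUENCIES_HZ,
    duration_ms: float = TRAIN_DURATION_MS,
    recovery_intervals_s: Sequence[float] = RECOVERY_INTERVALS_S,
    recovery_conditioning_hz: float = RECOVERY_CONDITIONING_HZ,
) -> List[StimulusProtocol]:
    """Study protocols: the four trains plus the tagged recovery protocol."""
    protocols = [
        StimulusProtocol.regular_train(f, duration_ms) for f in frequencies_hz
    ]
    protocols.append(
        StimulusProtocol.train_with_recovery(
            recovery_conditioning_hz,
            duration_ms,
            [1000.0 * d for d in recovery_intervals_s],
        )
    )
    return protocols


def _jitter_params(
    params: ReleaseModelParams, cv: float, rng: np.random.Generator
) -> ReleaseModelParams:
    """Lognormal per-cell jitter with the given CV on each model parameter."""
    if cv == 0.0:
        return params
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = -0.5 * sigma * sigma  # unit-mean lognormal
    factors = np.exp(rng.normal(mu, sigma, size=4))
    return params.with_updates(
        pv=min(float(params.pv * factors[0]), 0.99),
        tau_b=float(params.tau_b * factors[1]),
        tau_h=float(params.tau_h * factors[2]),
        tau_d=float(params.tau_d * factors[3]),
    )


def generate_dataset(
    params: ReleaseModelParams,
    protocols: Optional[Sequence[StimulusProtocol]] = None,
    noise: Optional[NoiseSpec] = None,
    recovery_mode: str = "sequential",
) -> Tuple[FitDataset, pd.DataFrame]:
    """Simulate every protocol per cell/repeat and average into a FitDataset.

    Per sweep each amplitude is multiplied by (1 + eps), eps ~ N(0, amp_cv),
    truncated at zero (truncations counted in the ``n_truncated`` attribute of
    the returned table), then renormalized to the sweep's first EPSC.  Repeats
    are averaged within cells; the FitDataset carries cell means and
    across-cell SEMs.  Returns the dataset and the per-cell sweep table
    (columns: dataset_id, condition, cell, repeat, frequency_hz,
    stimulus_index, time_ms, segment, interval_ms, amplitude, amplitude_norm).
    """
    noise = noise or NoiseSpec()
    protocols = list(protocols) if protocols is not None else make_paper_protocols()
    rng = np.random.default_rng(noise.seed)
    cell_rngs = [np.random.default_rng(s) for s in rng.integers(0, 2**31, noise.n_cells)]

    rows: List[dict] = []
    n_truncated = 0
    # per protocol: cell-mean normalized amplitude arrays
    cell_means: Dict[str, List[np.ndarray]] = {p.label: [] for p in protocols}

    for ci, crng in enumerate(cell_rngs):
        cell_params = _jitter_params(params, noise.cell_param_cv, crng)
        for proto in protocols:
            trace = simulate(proto, cell_params)
            sweep_norms = []
            for rep in range(noise.n_repeats):
                eps = crng.normal(0.0, noise.amp_cv, size=len(proto)) if noise.amp_cv else 0.0
                noisy = trace.epsc_raw * (1.0 + eps)
                n_truncated += int(np.sum(noisy < 0.0))
                noisy = np.maximum(noisy, 0.0)
                if noisy[0] <= 0.0:
                    # degenerate sweep: first EPSC wiped out by noise; skip it
                    continue
                norm = noisy / noisy[0]
                sweep_norms.append(norm)
                tags = proto.segment_tags or ("train",) * len(proto)
                t_last_train = max(
                    t for t, g in zip(proto.spike_times, tags) if g == "train"
                )
                for k, (t, g) in enumerate(zip(proto.spike_times, tags)):
                    rows.append(
                        {
                            "dataset_id": proto.label,
                            "condition": "",
                            "cell": ci,
                            "repeat": rep,
                            "frequency_hz": _protocol_frequency(proto),
                            "stimulus_index": k + 1,
                            "time_ms": t,
                            "segment": g,
                            "interval_ms": (
                                t - t_last_train if g == "recovery_probe" else np.nan
                            ),
                            "amplitude": noisy[k],
                            "amplitude_norm": norm[k],
                        }
                    )
            if sweep_norms:
                cell_means[proto.label].append(np.mean(sweep_norms, axis=0))

    train_sets = []
    recovery_set = None
    for proto in protocols:
        means = np.asarray(cell_means[proto.label])
        grand = means.mean(axis=0)
        sem = (
            means.std(axis=0, ddof=1) / np.sqrt(means.shape[0])
            if means.shape[0] > 1
            else None
        )
        mask = proto.probe_mask
        if mask.any():
            t_last = max(
                t
                for t, g in zip(proto.spike_times, proto.segment_tags)
                if g == "train"
            )
            intervals_s = (np.asarray(proto.spike_times)[mask] - t_last) / 1000.0
            recovery_set = RecoverySet(
                protocol=proto,
                probe_intervals_s=intervals_s,
                amps=grand[mask],
                sem=sem[mask] if sem is not None else None,
                mode=recovery_mode,
            )
        else:
            train_sets.append(TrainSet(protocol=proto, amps=grand, sem=sem))

    table = pd.DataFrame(rows)
    table.attrs["n_truncated"] = n_truncated
    table.attrs["seed"] = noise.seed
    dataset = FitDataset(
        train_sets=train_sets, recovery_set=recovery_set, condition_label=""
    )
    return dataset, table


def _protocol_frequency(proto: StimulusProtocol) -> float:
    """Nominal frequency from the first inter-spike interval."""
    if len(proto) < 2:
        return np.nan
    return 1000.0 / (proto.spike_times[1] - proto.spike_times[0])
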