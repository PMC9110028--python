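"""CSV/JSON schema shared by all pipeline stages.

The tabular schema (one row per stimulus) is:

    dataset_id, condition, frequency_hz, stimulus_index, time_ms,
    amplitude, amplitude_norm

with two optional columns: ``segment`` (train | recovery_probe) and
``interval_ms`` (recovery rows only: probe delay from the last conditioning
stimulus).  Files written by the pipeline start with a ``#`` provenance
comment line carrying the config hash and seed; readers here skip it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .fitting import FitDataset, RecoverySet, TrainSet
from .model import StimulusProtocol

REQUIRED_COLUMNS = (
    "dataset_id",
    "condition",
    "frequency_hz",
    "stimulus_index",
    "time_ms",
    "amplitude",
    "amplitude_norm",
)


class SchemaError(ValueError):
    """Input table does not conform to the amplitude CSV schema."""


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (order-independent)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    """Write a schema table with a leading provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a schema table, validating required columns."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file; missing columns "
                          f"{list(REQUIRED_COLUMNS)}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    bad = df[df["amplitude_norm"] < 0]
    if len(bad):
        raise SchemaError(
            f"{path}: negative normalized amplitudes at rows "
            f"{bad.index.tolist()[:10]}"
        )
    return df


def dataset_from_table(
    df: pd.DataFrame, condition: Optional[str] = None, recovery_mode: str = "sequential"
) -> FitDataset:
    """Assemble a FitDataset from a schema table.

    Rows are grouped by ``dataset_id``; within each group, cell/repeat rows
    (if present) are averaged per stimulus_index.  A group containing
    ``recovery_probe`` segment rows becomes the recovery set; the others
    become train sets.
    """
    if condition is not None:
        df = df[df["condition"].fillna("").astype(str) == condition]
        if len(df) == 0:
            raise SchemaError(f"no rows for condition {condition!r}")
    has_segment = "segment" in df.columns

    train_sets = []
    recovery_set = None
    for ds_id, g in df.groupby("dataset_id", sort=True):
        agg = (
            g.groupby("stimulus_index", sort=True)
            .agg(
                time_ms=("time_ms", "mean"),
                amplitude_norm=("amplitude_norm", "mean"),
                sem=("amplitude_norm", "sem"),
                segment=("segment", "first") if has_segment else ("time_ms", "size"),
            )
            .reset_index()
        )
        times = tuple(agg["time_ms"].to_numpy())
        amps = agg["amplitude_norm"].to_numpy()
        sem = agg["sem"].to_numpy()
        sem = None if np.all(~np.isfinite(sem)) else np.nan_to_num(sem)
        if has_segment and (agg["segment"] == "recovery_probe").any():
            tags = tuple(agg["segment"])
            proto = StimulusProtocol(
                spike_times=times, label=str(ds_id), segment_tags=tags
            )
            mask = proto.probe_mask
            t_last = max(t for t, m in zip(times, mask) if not m)
            intervals_s = (np.asarray(times)[mask] - t_last) / 1000.0
            recovery_set = RecoverySet(
                protocol=proto,
                probe_intervals_s=intervals_s,
                amps=amps[mask],
                sem=sem[mask] if sem is not None else None,
                mode=recovery_mode,
            )
        else:
            proto = StimulusProtocol(spike_times=times, label=str(ds_id))
            train_sets.append(TrainSet(protocol=proto, amps=amps, sem=sem))
    label = condition or ""
    return FitDataset(
        train_sets=train_sets, recovery_set=recovery_set, condition_label=label
    )


def write_json(obj: Dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
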