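"""Reading, writing and validation of spike-timestamp tables and feature tables.

The canonical on-disk format is a delimited long table with one row per spike::

    cell_id,mouse_id,group_label,time_s

Comma- and tab-delimited files are both accepted on input; output is always
comma-delimited. Timestamps are stored in seconds (microsecond resolution or
better); interspike intervals elsewhere in the package are reported in
milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIGNATURES",
    "FEATURE_NAMES",
    "SpikeTrain",
    "CohortTable",
    "FeatureVector",
    "SpikeDataError",
    "SchemaError",
    "load_spike_trains",
    "write_spike_trains",
    "validate_train",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

#: Closed set of signature labels, in fixed canonical order.
SIGNATURES = ("control", "ataxia", "dystonia", "tremor")

#: The 12 spike-train parameters, in canonical column order.
FEATURE_NAMES = (
    "firing_rate",
    "mean_ifr",
    "median_ifr",
    "cv",
    "cv2",
    "skewness",
    "isi25",
    "isi100",
    "interburst_pause",
    "mode_fraction",
    "rhythmicity_index",
    "oscillation_peaks",
)

#: Recording length (s) required for featurization unless explicitly overridden.
STANDARD_DURATION_S = 30.0


class SpikeDataError(ValueError):
    """Malformed or invalid spike data."""


class SchemaError(SpikeDataError):
    """A table is missing required columns."""


@dataclass
class SpikeTrain:
    """One cell's spike timestamps from a single awake recording.

    Timestamps are in seconds, strictly increasing, within [0, duration].
    """

    cell_id: str
    timestamps: np.ndarray
    duration: float = STANDARD_DURATION_S
    mouse_id: str = ""
    group_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)


@dataclass
class CohortTable:
    """A set of spike trains with unique cell ids."""

    trains: list[SpikeTrain]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.trains]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SpikeDataError(f"duplicate cell_id in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self):
        return iter(self.trains)


@dataclass
class FeatureVector:
    """The 12 spike-train parameters for one cell."""

    cell_id: str
    group_label: str
    firing_rate: float
    mean_ifr: float
    median_ifr: float
    cv: float
    cv2: float
    skewness: float
    isi25: float
    isi100: float
    interburst_pause: float
    mode_fraction: float
    rhythmicity_index: float
    oscillation_peaks: float

    def values(self) -> np.ndarray:
        """Feature values as an array in canonical :data:`FEATURE_NAMES` order."""
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> pd.DataFrame:
    import csv as _csv

    # sep=None sniffs comma vs tab; engine="python" is required for sniffing.
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         skip_blank_lines=True)
    except (pd.errors.EmptyDataError, _csv.Error):
        raise SpikeDataError(f"no records in {path}") from None
    if df.empty:
        raise SpikeDataError(f"no records in {path}")
    return df


def load_spike_trains(
    path: str | Path,
    format: str = "long_table",
    duration: float = STANDARD_DURATION_S,
    provenance: str = "",
) -> CohortTable:
    """Read spike timestamps into a :class:`CohortTable`.

    Parameters
    ----------
    path
        A delimited file (``long_table``) or a directory of per-cell files
        (``per_cell_files``), each holding one ``time_s`` column.
    format
        ``"long_table"`` (canonical) or ``"per_cell_files"``.
    duration
        Recording length in seconds attached to every train (the tables store
        timestamps only).

    Duplicate timestamps within a cell are rejected; timestamps are sorted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long_table":
        df = _read_delimited(path)
        required = {"cell_id", "time_s"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing column(s) {sorted(missing)} in {path}")
        bad = pd.to_numeric(df["time_s"], errors="coerce").isna()
        if bad.any():
            # +2: header line plus 1-based numbering.
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SpikeDataError(f"malformed row at line {line} of {path}: "
                                 f"non-numeric time_s {df['time_s'][bad].iloc[0]!r}")
        df["time_s"] = df["time_s"].astype(float)
        trains = []
        for cell_id, sub in df.groupby("cell_id", sort=False):
            ts = np.sort(sub["time_s"].to_numpy())
            if np.any(np.diff(ts) <= 0):
                raise SpikeDataError(f"duplicate timestamp in cell {cell_id!r}")
            mouse = str(sub["mouse_id"].iloc[0]) if "mouse_id" in sub else ""
            group = str(sub["group_label"].iloc[0]) if "group_label" in sub else ""
            trains.append(SpikeTrain(str(cell_id), ts, duration=duration,
                                     mouse_id=mouse, group_label=group))
        return CohortTable(trains, provenance=provenance or str(path))
    elif format == "per_cell_files":
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise SpikeDataError(f"no records in {path}")
        trains = []
        for f in files:
            df = _read_delimited(f)
            col = "time_s" if "time_s" in df.columns else df.columns[0]
            ts = np.sort(pd.to_numeric(df[col], errors="raise").to_numpy(float))
            if np.any(np.diff(ts) <= 0):
                raise SpikeDataError(f"duplicate timestamp in cell {f.stem!r}")
            trains.append(SpikeTrain(f.stem, ts, duration=duration))
        return CohortTable(trains, provenance=provenance or str(path))
    raise ValueError(f"unknown format {format!r}")


def write_spike_trains(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as the canonical comma-delimited long table."""
    rows = []
    for t in cohort:
        for ts in t.timestamps:
            rows.append((t.cell_id, t.mouse_id, t.group_label, ts))
    df = pd.DataFrame(rows, columns=["cell_id", "mouse_id", "group_label", "time_s"])
    df.to_csv(path, index=False, float_format="%.9f")


def validate_train(train: SpikeTrain, require_30s: bool = True) -> list[str]:
    """Return a list of invariant violations (empty means the train is valid)."""
    v: list[str] = []
    ts = train.timestamps
    if require_30s and train.duration != STANDARD_DURATION_S:
        v.append("duration != 30 s")
    if train.duration <= 0:
        v.append("non-positive duration")
    if ts.size:
        d = np.diff(ts)
        if np.any(d == 0):
            v.append("duplicate timestamp")
        if np.any(d < 0):
            v.append("timestamps not sorted")
        if ts[0] < 0 or ts[-1] > train.duration:
            v.append("timestamp outside [0, duration]")
    if ts.size < 2:
        v.append("fewer than 2 spikes")
    return v


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_FEATURE_HEADER = ("cell_id", "group_label") + FEATURE_NAMES


def write_feature_table(features: Sequence[FeatureVector], path: str | Path,
                        header_comment: str = "") -> None:
    """Write feature vectors as comma-delimited text, 12 significant digits."""
    df = pd.DataFrame(
        [(f.cell_id, f.group_label) + tuple(f.values()) for f in features],
        columns=list(_FEATURE_HEADER),
    )
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    """Read a feature table written by :func:`write_feature_table`."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError:
        raise SpikeDataError(f"no records in {path}") from None
    missing = set(_FEATURE_HEADER) - set(df.columns)
    if missing:
        raise SchemaError(f"feature table missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(FeatureVector(
            cell_id=str(row["cell_id"]),
            group_label="" if pd.isna(row["group_label"]) else str(row["group_label"]),
            **{n: float(row[n]) for n in FEATURE_NAMES},
        ))
    return out


# ---------------------------------------------------------------------------
# Model files
# ---------------------------------------------------------------------------

def save_model(tree, path: str | Path) -> None:
    """Serialize a fitted :class:`~spikesig.classifier.SignatureTree` to JSON."""
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2)


def load_model(path: str | Path):
    from .classifier import SignatureTree

    with open(path) as fh:
        return SignatureTree.from_dict(json.load(fh))
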