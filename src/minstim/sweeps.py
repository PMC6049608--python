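"""Sweep-set and event-table containers and their on-disk layouts.

A :class:`SweepSet` is a stack of equal-length traces recorded from one cell
(or one field electrode) under one condition — the unit on which event
detection operates.  An :class:`EventTable` holds the per-sweep measurements
(baseline, peak, charge, failure flag) that the quantal estimators consume.

Two file dialects carry the same logical schema and are selected by
extension:

* ``.h5`` / ``.hdf5`` — an HDF5 container: dataset ``data`` (sweeps x
  samples) with the scalar acquisition attributes attached, plus per-sweep
  ``order_index`` and ``timestamp_s`` datasets.
* ``.csv`` — a text dialect: a header block of ``# key = value`` lines
  followed by one row per sweep (``sweep_index, order_index, timestamp_s,
  s0 .. sN``).

Currents are stored as recorded (inward negative).  Time origin is the first
sample; ``stim_time_ms`` is measured from sweep start; all post-stimulus
windows used downstream are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SweepSet",
    "EventTable",
    "SweepFormatError",
    "read_sweepset",
    "write_sweepset",
    "read_event_table",
    "write_event_table",
    "EVENT_TABLE_COLUMNS",
]


class SweepFormatError(ValueError):
    """A sweep or event file does not conform to the documented layout."""


#: Stable column order of the event-table dialect.  Append-only.
EVENT_TABLE_COLUMNS = [
    "sweep_index",
    "order_index",
    "timestamp_s",
    "holding_potential_mv",
    "baseline_pa",
    "noise_context",
    "peak_pa",
    "peak_latency_ms",
    "amplitude_pa",
    "charge_pc",
    "is_failure",
    "qc_excluded",
    "qc_reason",
]

_SCALAR_ATTRS = ("sampling_rate_hz", "stim_time_ms")
_META_ATTRS = ("experiment_id", "cell_id", "animal_id", "genotype", "age_label")


@dataclass
class SweepSet:
    """Equal-length traces from one recording, with acquisition metadata.

    Parameters
    ----------
    data
        2-D array, sweeps x samples.  pA for voltage clamp, mV for field
        recordings.
    sampling_rate_hz
        Digitization rate (the recordings this models were digitized at
        5 kHz).
    stim_time_ms
        Stimulus onset, ms from sweep start.
    holding_potential_mv
        -60 or +40 for voltage clamp; ``None`` for field recordings.
    order_index, timestamp_s
        Per-sweep acquisition order and wall-clock time.
    """

    data: np.ndarray
    sampling_rate_hz: float
    stim_time_ms: float
    holding_potential_mv: float | None = None
    experiment_id: str = ""
    cell_id: str = ""
    animal_id: str = ""
    genotype: str = ""
    age_label: str = ""
    order_index: np.ndarray | None = None
    timestamp_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SweepFormatError(
                f"sweep data must be 2-D (sweeps x samples), got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 1:
            raise SweepFormatError("a SweepSet requires at least one sweep")
        if self.sampling_rate_hz <= 0:
            raise SweepFormatError("sampling_rate_hz must be positive")
        if not 0 <= self.stim_time_ms < self.duration_ms:
            raise SweepFormatError(
                f"stim_time_ms={self.stim_time_ms} outside sweep [0, {self.duration_ms}) ms"
            )
        if self.order_index is None:
            self.order_index = np.arange(self.n_sweeps)
        else:
            self.order_index = np.asarray(self.order_index)
            if self.order_index.shape != (self.n_sweeps,):
                raise SweepFormatError("order_index length must equal sweep count")
        if self.timestamp_s is None:
            self.timestamp_s = np.zeros(self.n_sweeps)
        else:
            self.timestamp_s = np.asarray(self.timestamp_s, dtype=float)
            if self.timestamp_s.shape != (self.n_sweeps,):
                raise SweepFormatError("timestamp_s length must equal sweep count")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt_ms(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.sampling_rate_hz

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        """Sample times in ms from sweep start."""
        return np.arange(self.n_samples) * self.dt_ms

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample at (or immediately after) ``t_ms``."""
        return int(np.ceil(round(t_ms / self.dt_ms, 9)))

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Slice of samples in the half-open window ``[start_ms, end_ms)``."""
        i0 = self.sample_index(start_ms)
        i1 = self.sample_index(end_ms)
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError(
                f"window [{start_ms}, {end_ms}) ms outside sweep "
                f"[0, {self.duration_ms}) ms"
            )
        return slice(i0, i1)

    def subset(self, mask: np.ndarray) -> "SweepSet":
        """A new SweepSet restricted to the sweeps selected by ``mask``."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            order_index=np.asarray(self.order_index)[mask],
            timestamp_s=np.asarray(self.timestamp_s)[mask],
        )


@dataclass
class EventTable:
    """Per-sweep measurements for one SweepSet, one row per sweep.

    Wraps a :class:`pandas.DataFrame` with the fixed column set
    :data:`EVENT_TABLE_COLUMNS`.  ``amplitude_pa`` is the measurement the
    potency estimators consume: the post-template-subtraction peak at
    -60 mV, the 25-ms read at +40 mV.
    """

    frame: pd.DataFrame
    experiment_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SweepFormatError(f"event table missing columns: {missing}")
        self.frame = self.frame[EVENT_TABLE_COLUMNS].reset_index(drop=True)
        if len(self.frame) == 0:
            raise SweepFormatError("event table must have at least one row")
        charges = self.frame["charge_pc"].to_numpy(dtype=float)
        if not np.all(np.isfinite(charges)):
            raise SweepFormatError("charge_pc must be finite for every sweep")
        bad = (~self.frame["qc_excluded"].astype(bool)) & self.frame[
            "is_failure"
        ].isna()
        if bad.any():
            raise SweepFormatError(
                "is_failure must be defined for every non-excluded sweep"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def included(self) -> pd.DataFrame:
        """Rows not excluded by QC."""
        return self.frame[~self.frame["qc_excluded"].astype(bool)]

    @property
    def n_failures(self) -> int:
        return int(self.included["is_failure"].astype(bool).sum())

    @property
    def n_events(self) -> int:
        return int(len(self.included))


# ---------------------------------------------------------------------------
# SweepSet I/O


def write_sweepset(sweeps: SweepSet, path: str | Path, overwrite: bool = False) -> Path:
    """Write a SweepSet to ``path`` (.h5/.hdf5 or .csv, by extension).

    Refuses to overwrite an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    ext = path.suffix.lower()
    if ext in (".h5", ".hdf5"):
        _write_h5(sweeps, path)
    elif ext == ".csv":
        _write_csv(sweeps, path)
    else:
        raise SweepFormatError(f"unsupported sweep-file extension: {ext!r}")
    return path


def read_sweepset(path: str | Path) -> SweepSet:
    """Read a SweepSet written by :func:`write_sweepset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext in (".h5", ".hdf5"):
        return _read_h5(path)
    if ext == ".csv":
        return _read_csv(path)
    raise SweepFormatError(f"unsupported sweep-file extension: {ext!r}")


def _write_h5(sweeps: SweepSet, path: Path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=sweeps.data)
        for key in _SCALAR_ATTRS:
            dset.attrs[key] = getattr(sweeps, key)
        if sweeps.holding_potential_mv is not None:
            dset.attrs["holding_potential_mv"] = sweeps.holding_potential_mv
        for key in _META_ATTRS:
            dset.attrs[key] = getattr(sweeps, key)
        f.create_dataset("order_index", data=np.asarray(sweeps.order_index))
        f.create_dataset("timestamp_s", data=np.asarray(sweeps.timestamp_s))


def _read_h5(path: Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise SweepFormatError(f"{path}: missing 'data' dataset")
        dset = f["data"]
        attrs = dict(dset.attrs)
        for key in _SCALAR_ATTRS:
            if key not in attrs:
                raise SweepFormatError(f"{path}: missing required attribute {key!r}")
        kwargs = {key: float(attrs[key]) for key in _SCALAR_ATTRS}
        if "holding_potential_mv" in attrs:
            kwargs["holding_potential_mv"] = float(attrs["holding_potential_mv"])
        for key in _META_ATTRS:
            val = attrs.get(key, "")
            kwargs[key] = val.decode() if isinstance(val, bytes) else str(val)
        return SweepSet(
            data=dset[()],
            order_index=f["order_index"][()] if "order_index" in f else None,
            timestamp_s=f["timestamp_s"][()] if "timestamp_s" in f else None,
            **kwargs,
        )


def _write_csv(sweeps: SweepSet, path: Path) -> None:
    lines = []
    for key in _SCALAR_ATTRS:
        lines.append(f"# {key} = {getattr(sweeps, key)!r}")
    if sweeps.holding_potential_mv is not None:
        lines.append(f"# holding_potential_mv = {sweeps.holding_potential_mv!r}")
    for key in _META_ATTRS:
        lines.append(f"# {key} = {getattr(sweeps, key)!r}")
    cols = ["sweep_index", "order_index", "timestamp_s"] + [
        f"s{i}" for i in range(sweeps.n_samples)
    ]
    lines.append(",".join(cols))
    for i in range(sweeps.n_sweeps):
        row = [str(i), str(int(sweeps.order_index[i])), repr(float(sweeps.timestamp_s[i]))]
        row += [repr(float(v)) for v in sweeps.data[i]]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_csv(path: Path) -> SweepSet:
    header: dict[str, str] = {}
    body_start = 0
    with open(path) as f:
        raw = f.readlines()
    for i, line in enumerate(raw):
        if line.startswith("#"):
            if "=" not in line:
                raise SweepFormatError(f"{path}: malformed header line {line!r}")
            key, _, val = line[1:].partition("=")
            header[key.strip()] = val.strip().strip("'\"")
        else:
            body_start = i
            break
    for key in _SCALAR_ATTRS:
        if key not in header:
            raise SweepFormatError(f"{path}: missing required header field {key!r}")
    from io import StringIO

    table = pd.read_csv(
        StringIO("".join(raw[body_start:])), float_precision="round_trip"
    )
    sample_cols = [c for c in table.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    if not sample_cols:
        raise SweepFormatError(f"{path}: no sample columns found")
    kwargs: dict = {key: float(header[key]) for key in _SCALAR_ATTRS}
    if "holding_potential_mv" in header:
        kwargs["holding_potential_mv"] = float(header["holding_potential_mv"])
    for key in _META_ATTRS:
        kwargs[key] = header.get(key, "")
    return SweepSet(
        data=table[sample_cols].to_numpy(dtype=float),
        order_index=table["order_index"].to_numpy()
        if "order_index" in table
        else None,
        timestamp_s=table["timestamp_s"].to_numpy(dtype=float)
        if "timestamp_s" in table
        else None,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# EventTable I/O


def write_event_table(
    events: EventTable, path: str | Path, overwrite: bool = False
) -> Path:
    """Write an event table as CSV with the stable column order."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    frame = events.frame[EVENT_TABLE_COLUMNS]
    with open(path, "w") as f:
        f.write(f"# experiment_id = {events.experiment_id!r}\n")
        frame.to_csv(f, index=False)
    return path


def read_event_table(path: str | Path) -> EventTable:
    """Read an event table written by :func:`write_event_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    experiment_id = ""
    with open(path) as f:
        first = f.readline()
        if first.startswith("#"):
            _, _, val = first[1:].partition("=")
            experiment_id = val.strip().strip("'\"")
            frame = pd.read_csv(f)
        else:
            from io import StringIO

            frame = pd.read_csv(StringIO(first + f.read()))
    missing = [c for c in EVENT_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SweepFormatError(f"{path}: event table missing columns {missing}")
    frame["qc_reason"] = frame["qc_reason"].fillna("")
    return EventTable(frame=frame, experiment_id=experiment_id)
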