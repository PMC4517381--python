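"""Data types and on-disk formats for every pipeline stage.

The native format is deliberately plain: each recording is a TSV body
(one timestamp column plus one column per channel) with a JSON sidecar
carrying the instrument metadata, so every artifact is inspectable and
diffable.  Matrices are labeled TSV with a one-line ``# key: value``
header comment; metrics reports are JSON (machine use) or TSV (an
index-table layout for humans).  All writers emit floats with 17
significant digits so that write -> read is an exact round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FormatError",
    "Recording",
    "ROISeries",
    "ConnectionMatrix",
    "AdjacencyMatrix",
    "MetricsReport",
    "SYMMETRIC_MEASURES",
    "read_recording",
    "write_recording",
    "read_roi_series",
    "write_roi_series",
    "read_connection_matrix",
    "write_connection_matrix",
    "read_adjacency_matrix",
    "write_adjacency_matrix",
    "read_metrics_report",
    "write_metrics_report",
]

#: measures whose pairwise value is order-invariant, hence whose
#: connection matrices must be exactly symmetric
SYMMETRIC_MEASURES = frozenset({"pearson", "coherence", "mutual_information"})

_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file violated the documented format or a type invariant."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """One participant's multi-channel HbO time series plus instrument metadata.

    ``timestamps`` are seconds on the instrument's local clock;
    ``clock_offset`` maps local time to the session clock
    (session time = timestamp + clock_offset).
    """

    participant_id: str
    instrument_id: str
    sampling_rate: float
    clock_offset: float
    timestamps: np.ndarray
    channels: list[str]
    roi_map: dict[str, str]
    hbo: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise FormatError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )
        if self.timestamps.ndim != 1:
            raise FormatError("timestamps must be a 1-D vector")
        diffs = np.diff(self.timestamps)
        if len(diffs) and not np.all(diffs > 0):
            bad = int(np.argmin(diffs > 0)) + 1
            raise FormatError(
                f"timestamps not strictly increasing (sample index {bad})"
            )
        if self.hbo.shape[0] != self.timestamps.shape[0]:
            raise FormatError(
                f"hbo has {self.hbo.shape[0]} rows but there are "
                f"{self.timestamps.shape[0]} timestamps"
            )
        if self.hbo.shape[1] != len(self.channels):
            raise FormatError(
                f"hbo has {self.hbo.shape[1]} columns but there are "
                f"{len(self.channels)} channel labels"
            )
        unknown = set(self.roi_map) - set(self.channels)
        if unknown:
            raise FormatError(
                f"roi_map refers to unknown channels: {sorted(unknown)}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def rois(self) -> list[str]:
        """ROI labels present in the channel map, in sorted order."""
        return sorted(set(self.roi_map.values()))

    def roi_channels(self, roi: str) -> list[str]:
        return [c for c in self.channels if self.roi_map.get(c) == roi]

    def channel_data(self, channel: str) -> np.ndarray:
        return self.hbo[:, self.channels.index(channel)]

    def replace(self, **kwargs) -> "Recording":
        data = {
            "participant_id": self.participant_id,
            "instrument_id": self.instrument_id,
            "sampling_rate": self.sampling_rate,
            "clock_offset": self.clock_offset,
            "timestamps": self.timestamps,
            "channels": list(self.channels),
            "roi_map": dict(self.roi_map),
            "hbo": self.hbo,
            "events": list(self.events),
        }
        data.update(kwargs)
        return Recording(**data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.instrument_id == other.instrument_id
            and self.sampling_rate == other.sampling_rate
            and self.clock_offset == other.clock_offset
            and np.array_equal(self.timestamps, other.timestamps)
            and self.channels == other.channels
            and self.roi_map == other.roi_map
            and np.array_equal(self.hbo, other.hbo)
            and [(float(t), str(m)) for t, m in self.events]
            == [(float(t), str(m)) for t, m in other.events]
        )


@dataclass
class ROISeries:
    """One participant x ROI averaged series on the common clock."""

    participant_id: str
    roi: str
    sampling_rate: float
    start_time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("ROISeries values must be 1-D")
        if self.values.shape[0] < 2:
            raise FormatError("ROISeries needs at least 2 samples")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


def _check_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) < 2:
        raise FormatError("at least two nodes required")
    if len(set(labels)) != len(labels):
        raise FormatError("node labels must be unique")
    return labels


@dataclass
class ConnectionMatrix:
    """Pairwise inter-brain synchronization values before thresholding."""

    labels: list[str]
    values: np.ndarray
    measure: str
    window_start: float | None = None

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise FormatError(
                f"values must be {k}x{k}, got {self.values.shape}"
            )
        if self.measure in SYMMETRIC_MEASURES and not np.array_equal(
            self.values, self.values.T
        ):
            raise FormatError(
                f"matrix for symmetric measure '{self.measure}' is asymmetric"
            )
        if self.measure == "pearson":
            if np.any(np.abs(self.values) > 1 + 1e-12):
                raise FormatError("pearson values must lie in [-1, 1]")
            if not np.allclose(np.diag(self.values), 1.0):
                raise FormatError("pearson matrix must have unit diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class AdjacencyMatrix:
    """Binary, symmetric, zero-diagonal multi-brain network."""

    labels: list[str]
    values: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise FormatError(
                f"values must be {k}x{k}, got {self.values.shape}"
            )
        vals = self.values.astype(float)
        if not np.all((vals == 0) | (vals == 1)):
            raise FormatError("adjacency entries must be 0 or 1")
        if not np.array_equal(vals, vals.T):
            raise FormatError("adjacency matrix must be symmetric")
        if np.any(np.diag(vals) != 0):
            raise FormatError("adjacency diagonal must be zero")
        self.values = vals.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2

    def edges(self) -> list[tuple[str, str]]:
        k = self.n_nodes
        return [
            (self.labels[i], self.labels[j])
            for i in range(k)
            for j in range(i + 1, k)
            if self.values[i, j]
        ]


_NODAL_FIELDS = (
    "degree",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "clustering_coefficient",
)
_NETWORK_FIELDS = (
    "global_efficiency",
    "local_efficiency",
    "characteristic_path_length",
    "assortativity",
)


@dataclass
class MetricsReport:
    """Per-node and network-level topological indices of one MBN."""

    labels: list[str]
    nodal: dict[str, np.ndarray]
    network: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        for key in _NODAL_FIELDS:
            if key not in self.nodal:
                raise FormatError(f"missing nodal metric '{key}'")
            arr = np.asarray(self.nodal[key], dtype=float)
            if arr.shape != (len(self.labels),):
                raise FormatError(f"nodal metric '{key}' has wrong length")
            self.nodal[key] = arr
        for key in _NETWORK_FIELDS:
            if key not in self.network:
                raise FormatError(f"missing network metric '{key}'")
            self.network[key] = float(self.network[key])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetricsReport):
            return NotImplemented
        return (
            self.labels == other.labels
            and all(
                np.array_equal(self.nodal[k], other.nodal[k], equal_nan=True)
                for k in _NODAL_FIELDS
            )
            and all(
                (
                    np.isnan(self.network[k]) and np.isnan(other.network[k])
                )
                or self.network[k] == other.network[k]
                for k in _NETWORK_FIELDS
            )
            and self.flags == other.flags
        )


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

_SIDE_FIELDS = (
    "participant_id",
    "instrument_id",
    "sampling_rate",
    "clock_offset",
    "channels",
    "roi_map",
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(path: str | Path) -> Recording:
    """Read a Recording from ``<path>`` (TSV body) + ``<path stem>.json`` sidecar.

    Raises :class:`FormatError` with the offending line number for malformed
    bodies and a named-field message for incomplete sidecars.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side}")
    meta = json.loads(side.read_text())
    for fld in _SIDE_FIELDS:
        if fld not in meta:
            raise FormatError(f"missing header field '{fld}' in {side}")

    times: list[float] = []
    rows: list[list[float]] = []
    n_chan = len(meta["channels"])
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != n_chan + 1:
            raise FormatError(
                f"line 1: header has {len(header)} columns, expected {n_chan + 1}"
            )
        if header[1:] != list(meta["channels"]):
            raise FormatError("line 1: header channels disagree with sidecar")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_chan + 1:
                raise FormatError(
                    f"line {lineno}: expected {n_chan + 1} columns, "
                    f"got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if times and vals[0] <= times[-1]:
                raise FormatError(
                    f"line {lineno}: timestamps not strictly increasing"
                )
            times.append(vals[0])
            rows.append(vals[1:])

    events = [(float(t), str(m)) for t, m in meta.get("events", [])]
    return Recording(
        participant_id=str(meta["participant_id"]),
        instrument_id=str(meta["instrument_id"]),
        sampling_rate=float(meta["sampling_rate"]),
        clock_offset=float(meta["clock_offset"]),
        timestamps=np.array(times),
        channels=[str(c) for c in meta["channels"]],
        roi_map={str(k): str(v) for k, v in meta["roi_map"].items()},
        hbo=np.array(rows).reshape(len(times), n_chan),
        events=events,
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "participant_id": rec.participant_id,
        "instrument_id": rec.instrument_id,
        "sampling_rate": rec.sampling_rate,
        "clock_offset": rec.clock_offset,
        "channels": rec.channels,
        "roi_map": rec.roi_map,
        "events": [[t, m] for t, m in rec.events],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(rec.channels) + "\n")
        for i in range(rec.n_samples):
            row = [_fmt(rec.timestamps[i])] + [
                _fmt(v) for v in rec.hbo[i]
            ]
            fh.write("\t".join(row) + "\n")
    return path


def write_roi_series(series: ROISeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "participant_id": series.participant_id,
        "roi": series.roi,
        "sampling_rate": series.sampling_rate,
        "start_time": series.start_time,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    with open(path, "w") as fh:
        fh.write("time\tvalue\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{_fmt(t)}\t{_fmt(v)}\n")
    return path


def read_roi_series(path: str | Path) -> ROISeries:
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side}")
    meta = json.loads(side.read_text())
    for fld in ("participant_id", "roi", "sampling_rate", "start_time"):
        if fld not in meta:
            raise FormatError(f"missing header field '{fld}' in {side}")
    body = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return ROISeries(
        participant_id=str(meta["participant_id"]),
        roi=str(meta["roi"]),
        sampling_rate=float(meta["sampling_rate"]),
        start_time=float(meta["start_time"]),
        values=body[:, 1],
    )


# ---------------------------------------------------------------------------
# matrix I/O  (labeled TSV with a one-line '# key: value' comment header)
# ---------------------------------------------------------------------------


def _write_labeled_matrix(
    labels: Sequence[str], values: np.ndarray, header: str, path: Path,
    fmt=_fmt,
) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, values):
            fh.write(lab + "\t" + "\t".join(fmt(v) for v in row) + "\n")
    return path


def _read_labeled_matrix(path: Path) -> tuple[dict[str, str], list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    while lines and lines[0].startswith("#"):
        key, _, val = lines.pop(0).lstrip("# ").partition(":")
        meta[key.strip()] = val.strip()
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    labels = lines[0].split("\t")[1:]
    if len(labels) < 2:
        raise FormatError("at least two nodes required")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        rows.append([float(v) for v in parts[1:]])
        if parts[0] != labels[len(rows) - 1]:
            raise FormatError(
                f"{path}: row label '{parts[0]}' does not match header order"
            )
    values = np.array(rows)
    if values.shape != (len(labels), len(labels)):
        raise FormatError(f"{path}: matrix is not square")
    return meta, labels, values


def write_connection_matrix(cm: ConnectionMatrix, path: str | Path) -> Path:
    extra = "" if cm.window_start is None else f"\n# window_start: {_fmt(cm.window_start)}"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# measure: {cm.measure}{extra}\n")
        fh.write("\t" + "\t".join(cm.labels) + "\n")
        for lab, row in zip(cm.labels, cm.values):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    return path


def read_connection_matrix(path: str | Path) -> ConnectionMatrix:
    meta, labels, values = _read_labeled_matrix(Path(path))
    if "measure" not in meta:
        raise FormatError(f"{path}: missing '# measure:' header")
    ws = meta.get("window_start")
    return ConnectionMatrix(
        labels=labels,
        values=values,
        measure=meta["measure"],
        window_start=None if ws is None else float(ws),
    )


def write_adjacency_matrix(am: AdjacencyMatrix, path: str | Path) -> Path:
    thr = "nan" if am.threshold is None else _fmt(am.threshold)
    return _write_labeled_matrix(
        am.labels, am.values, f"threshold: {thr}", Path(path),
        fmt=lambda v: str(int(v)),
    )


def read_adjacency_matrix(path: str | Path) -> AdjacencyMatrix:
    meta, labels, values = _read_labeled_matrix(Path(path))
    if "threshold" not in meta:
        raise FormatError(f"{path}: missing '# threshold:' header")
    thr = float(meta["threshold"])
    return AdjacencyMatrix(
        labels=labels,
        values=values,
        threshold=None if np.isnan(thr) else thr,
    )


# ---------------------------------------------------------------------------
# metrics report I/O
# ---------------------------------------------------------------------------


def write_metrics_report(mr: MetricsReport, path: str | Path) -> Path:
    """Write a metrics report; ``.json`` gives the exact machine format,
    anything else an index-table TSV (metrics as rows, one column per
    node plus a network column)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        doc = {
            "labels": mr.labels,
            "nodal": {k: [float(v) for v in mr.nodal[k]] for k in _NODAL_FIELDS},
            "network": {k: mr.network[k] for k in _NETWORK_FIELDS},
            "flags": mr.flags,
        }
        path.write_text(json.dumps(doc, indent=1, allow_nan=True))
        return path
    with open(path, "w") as fh:
        fh.write("metric\t" + "\t".join(mr.labels) + "\tnetwork\n")
        net_of = {
            "global_efficiency": "global_efficiency",
            "local_efficiency": "local_efficiency",
        }
        for key in _NODAL_FIELDS:
            net = net_of.get(key)
            netval = "" if net is None else _fmt(mr.network[net])
            fh.write(
                key + "\t" + "\t".join(_fmt(v) for v in mr.nodal[key])
                + "\t" + netval + "\n"
            )
        for key in ("characteristic_path_length", "assortativity"):
            fh.write(key + "\t" * (len(mr.labels) + 1) + _fmt(mr.network[key]) + "\n")
    return path


def read_metrics_report(path: str | Path) -> MetricsReport:
    path = Path(path)
    if path.suffix != ".json":
        raise FormatError("metrics reports are read back from the JSON form")
    doc = json.loads(path.read_text())
    return MetricsReport(
        labels=doc["labels"],
        nodal={k: np.array(v, dtype=float) for k, v in doc["nodal"].items()},
        network={k: float(v) for k, v in doc["network"].items()},
        flags=list(doc.get("flags", [])),
    )
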