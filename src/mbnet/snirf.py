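"""Read-only SNIRF (HDF5) adapter.

Maps the first data block of a SNIRF file onto :class:`Recording`.
SNIRF carries no ROI concept, so the channel -> ROI map is supplied by
the caller (channels without an entry are kept unmapped).  Channels are
labeled ``S{source}D{detector}`` with the data-type label appended when
several types share a source-detector pair; by default only
HbO-labeled (or raw-wavelength, if no concentration data exists)
channels are selected.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .io_formats import FormatError, Recording

__all__ = ["read_snirf"]


def _as_str(x) -> str:
    if isinstance(x, bytes):
        return x.decode()
    if isinstance(x, np.ndarray):
        return _as_str(x.item() if x.shape == () else x[0])
    return str(x)


def _scalar(group, name, default=None):
    if name not in group:
        return default
    val = group[name][()]
    if isinstance(val, np.ndarray):
        val = val.item() if val.shape == () else val[0]
    return val


def read_snirf(
    path: str | Path,
    roi_map: dict[str, str] | None = None,
    participant_id: str | None = None,
    clock_offset: float = 0.0,
    data_type_label: str = "HbO",
) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs_keys = sorted(k for k in f if k.startswith("nirs"))
        if not nirs_keys:
            raise FormatError(f"{path}: no /nirs group")
        nirs = f[nirs_keys[0]]
        data_keys = sorted(k for k in nirs if k.startswith("data"))
        if not data_keys:
            raise FormatError(f"{path}: no data block")
        data = nirs[data_keys[0]]
        ts = np.asarray(data["time"][()], dtype=float).ravel()
        series = np.atleast_2d(np.asarray(data["dataTimeSeries"][()], dtype=float))
        if series.shape[0] != ts.shape[0]:
            series = series.T

        ml_keys = sorted(
            (k for k in data if k.startswith("measurementList")),
            key=lambda k: int(k.replace("measurementList", "") or 0),
        )
        labels: list[str] = []
        keep: list[int] = []
        for idx, key in enumerate(ml_keys):
            ml = data[key]
            s = int(_scalar(ml, "sourceIndex", 0))
            d = int(_scalar(ml, "detectorIndex", 0))
            lab = _scalar(ml, "dataTypeLabel")
            lab = _as_str(lab) if lab is not None else ""
            if lab and lab != data_type_label:
                continue
            keep.append(idx)
            labels.append(f"S{s}D{d}" if lab in ("", data_type_label) else f"S{s}D{d}_{lab}")
        if not keep:
            raise FormatError(
                f"{path}: no channels with dataTypeLabel '{data_type_label}'"
            )
        # disambiguate duplicated source-detector pairs
        seen: dict[str, int] = {}
        uniq = []
        for lab in labels:
            seen[lab] = seen.get(lab, 0) + 1
            uniq.append(lab if seen[lab] == 1 else f"{lab}_{seen[lab]}")
        labels = uniq

        meta = nirs.get("metaDataTags")
        pid = participant_id
        if pid is None and meta is not None and "SubjectID" in meta:
            pid = _as_str(meta["SubjectID"][()])
        if pid is None:
            pid = path.stem
        instrument = "snirf"
        if meta is not None:
            for tag in ("ManufacturerName", "Model"):
                if tag in meta:
                    instrument = _as_str(meta[tag][()])
                    break

        if len(ts) < 2:
            raise FormatError(f"{path}: time vector too short")
        rate = 1.0 / float(np.median(np.diff(ts)))
        roi_map = roi_map or {}
        roi_map = {k: v for k, v in roi_map.items() if k in labels}
        events: list[tuple[float, str]] = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[key]
            name = _as_str(stim["name"][()]) if "name" in stim else key
            if "data" in stim:
                arr = np.atleast_2d(np.asarray(stim["data"][()], dtype=float))
                for row in arr:
                    events.append((float(row[0]), name))
        return Recording(
            participant_id=pid,
            instrument_id=instrument,
            sampling_rate=rate,
            clock_offset=clock_offset,
            timestamps=ts,
            channels=labels,
            roi_map=roi_map,
            hbo=series[:, keep],
            events=sorted(events),
        )
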