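"""Preprocessing chain for heterogeneous-instrument group recordings.

The chain mirrors the standard multi-instrument fNIRS workflow: express
all recordings on one session clock using their clock offsets and trim to
the common overlap window; down-sample the fast instrument onto the slow
instrument's rate (anti-alias filter, then spline evaluation on the
uniform target grid -- the 55.5 -> 10 Hz ratio is not an integer, so
plain decimation does not apply); zero-phase low-pass to remove
high-frequency instrumental noise; and average each region of interest's
channels into one series per participant.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .io_formats import Recording, ROISeries

__all__ = [
    "align_to_common_clock",
    "resample",
    "lowpass",
    "roi_average",
    "preprocess_group",
]


def _check_uniform(rec: Recording) -> float:
    """Return the sample interval; reject visibly non-uniform grids."""
    dt = np.diff(rec.timestamps)
    if len(dt) == 0:
        raise ValueError("recording has fewer than 2 samples")
    mean = float(dt.mean())
    if np.max(np.abs(dt - mean)) > 0.01 * mean:
        raise ValueError(
            f"recording '{rec.participant_id}' is not uniformly sampled"
        )
    return mean


def align_to_common_clock(recordings: list[Recording]) -> list[Recording]:
    """Express all recordings on one session clock and trim to their overlap.

    Session time for a sample is ``timestamp + clock_offset``; session zero
    is the earliest such time across the group.  Every output recording has
    ``clock_offset == 0`` and covers exactly the window
    ``[max of starts, min of ends]``.  Raises ``ValueError`` naming a
    disjoint pair when the recordings share no time window.
    """
    if len(recordings) < 2:
        raise ValueError("alignment needs at least two recordings")
    starts = [r.timestamps[0] + r.clock_offset for r in recordings]
    ends = [r.timestamps[-1] + r.clock_offset for r in recordings]
    zero = min(starts)
    lo = max(starts)
    hi = min(ends)
    if lo > hi:
        a = recordings[int(np.argmax(starts))]
        b = recordings[int(np.argmin(ends))]
        raise ValueError(
            "no temporal overlap between recordings "
            f"'{b.participant_id}' and '{a.participant_id}'"
        )
    out = []
    for rec in recordings:
        t = rec.timestamps + rec.clock_offset - zero
        keep = (t >= lo - zero - 1e-12) & (t <= hi - zero + 1e-12)
        if keep.sum() < 2:
            raise ValueError(
                f"recording '{rec.participant_id}' has fewer than 2 samples "
                "in the overlap window"
            )
        out.append(
            rec.replace(
                timestamps=t[keep],
                hbo=rec.hbo[keep],
                clock_offset=0.0,
                events=[(t0 + rec.clock_offset - zero, m) for t0, m in rec.events],
            )
        )
    return out


def resample(
    rec: Recording,
    target_rate: float,
    grid_start: float | None = None,
    grid_end: float | None = None,
) -> Recording:
    """Down-sample onto a uniform grid at ``target_rate``.

    An order-8 Butterworth anti-alias filter (zero-phase, cutoff at 80% of
    the target Nyquist) is applied before the signal is evaluated on the
    target grid with a cubic spline.  ``grid_start``/``grid_end`` let a
    group share one grid; they default to the recording's own span.
    Upsampling is not supported.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate > rec.sampling_rate * (1 + 1e-9):
        raise ValueError(
            f"upsampling unsupported: target {target_rate} Hz exceeds "
            f"recording rate {rec.sampling_rate} Hz"
        )
    _check_uniform(rec)
    same_rate = abs(target_rate - rec.sampling_rate) <= 1e-9 * rec.sampling_rate
    if same_rate and grid_start is None and grid_end is None:
        return rec.replace()

    if grid_start is None:
        grid_start = float(rec.timestamps[0])
    if grid_end is None:
        grid_end = float(rec.timestamps[-1])
    if grid_start < rec.timestamps[0] - 1e-9 or grid_end > rec.timestamps[-1] + 1e-9:
        raise ValueError("requested grid extends beyond the recording")
    n = int(np.floor((grid_end - grid_start) * target_rate + 1e-9)) + 1
    grid = grid_start + np.arange(n) / target_rate

    data = rec.hbo
    if not same_rate:
        sos = signal.butter(
            8, 0.8 * target_rate / 2, btype="low", fs=rec.sampling_rate,
            output="sos",
        )
        data = signal.sosfiltfilt(sos, data, axis=0)
    interp = CubicSpline(rec.timestamps, data, axis=0)
    return rec.replace(
        timestamps=grid, hbo=interp(grid), sampling_rate=target_rate
    )


def lowpass(rec: Recording, cutoff: float) -> Recording:
    """Zero-phase order-4 Butterworth low-pass (applied forward-backward,
    so no group delay and squared magnitude response)."""
    nyq = rec.sampling_rate / 2
    if not 0 < cutoff < nyq:
        raise ValueError(
            f"cutoff at/above Nyquist: need 0 < cutoff < {nyq} Hz, "
            f"got {cutoff} Hz"
        )
    _check_uniform(rec)
    sos = signal.butter(4, cutoff, btype="low", fs=rec.sampling_rate, output="sos")
    return rec.replace(hbo=signal.sosfiltfilt(sos, rec.hbo, axis=0))


def roi_average(rec: Recording, roi: str) -> ROISeries:
    """Unweighted per-timepoint mean of the ROI's channels."""
    chans = rec.roi_channels(roi)
    if not chans:
        raise ValueError(
            f"unknown ROI '{roi}'; available ROIs: {rec.rois}"
        )
    idx = [rec.channels.index(c) for c in chans]
    return ROISeries(
        participant_id=rec.participant_id,
        roi=roi,
        sampling_rate=rec.sampling_rate,
        start_time=float(rec.timestamps[0]),
        values=rec.hbo[:, idx].mean(axis=1),
    )


def preprocess_group(
    recordings: list[Recording],
    target_rate: float = 10.0,
    lowpass_cutoff: float = 2.5,
    roi: str = "prefrontal",
) -> list[ROISeries]:
    """Full chain: align -> resample onto one shared grid -> low-pass ->
    ROI-average.  Output series share start time, rate and length, ready
    for pairwise synchrony."""
    aligned = align_to_common_clock(recordings)
    gstart = max(float(r.timestamps[0]) for r in aligned)
    gend = min(float(r.timestamps[-1]) for r in aligned)
    out = []
    for rec in aligned:
        rec = resample(rec, target_rate, grid_start=gstart, grid_end=gend)
        rec = lowpass(rec, lowpass_cutoff)
        out.append(roi_average(rec, roi))
    return out
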