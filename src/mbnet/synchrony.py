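"""Inter-brain synchrony: pairwise edge weights and MBN thresholding.

Edges of a multi-brain network are pairwise synchronization values
between participants' ROI-averaged series.  Pearson correlation is the
default (and the measure used for the worked nine-person example);
band-averaged magnitude-squared coherence, plug-in mutual information and
a log-ratio Granger statistic are available alternatives.  A real-valued
connection matrix is thresholded (strict ``>``) into the binary adjacency
matrix of the MBN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .io_formats import (
    SYMMETRIC_MEASURES,
    AdjacencyMatrix,
    ConnectionMatrix,
    ROISeries,
)

__all__ = [
    "SynchronyParams",
    "pearson_pair",
    "coherence_band_pair",
    "mutual_information_pair",
    "granger_pair",
    "connection_matrix",
    "threshold_adjacency",
    "symmetrize_directed",
    "windowed_connection_matrices",
]

MEASURES = ("pearson", "coherence", "mutual_information", "granger")


@dataclass
class SynchronyParams:
    """Parameters of the pairwise synchrony measure.

    band
        frequency band (Hz) over which coherence is averaged; the default
        covers the slow hemodynamic range.
    n_bins
        equal-width histogram bins per axis for mutual information.
    max_lag
        autoregressive model order for the Granger statistic.
    n_segments
        Welch segments (50% overlap, Hann window) for coherence.
    window
        optional ``(length_s, step_s)`` for a sliding-window (dynamic) MBN.
    """

    measure: str = "pearson"
    band: tuple[float, float] = (0.01, 0.5)
    n_bins: int = 8
    max_lag: int = 1
    n_segments: int = 8
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(
                f"unknown measure '{self.measure}'; choose from {MEASURES}"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")


def _values(x) -> np.ndarray:
    if isinstance(x, ROISeries):
        return x.values
    return np.asarray(x, dtype=float)


def _rate(x) -> float | None:
    return x.sampling_rate if isinstance(x, ROISeries) else None


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv, yv = _values(x), _values(y)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if xv.shape[0] < 3:
        raise ValueError("series must have length >= 3")
    rx, ry = _rate(x), _rate(y)
    if rx is not None and ry is not None and abs(rx - ry) > 1e-9:
        raise ValueError(f"sampling rates differ: {rx} vs {ry} Hz")
    return xv, yv


def pearson_pair(x, y) -> float:
    """Product-moment correlation of two equal-rate series."""
    xv, yv = _check_pair(x, y)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance input")
    xd = xv - xv.mean()
    yd = yv - yv.mean()
    r = float(xd @ yd / np.sqrt((xd @ xd) * (yd @ yd)))
    return min(1.0, max(-1.0, r))


def coherence_band_pair(
    x, y, band: tuple[float, float], n_segments: int = 8, fs: float | None = None
) -> float:
    """Magnitude-squared coherence averaged over ``band``.

    Welch estimate with Hann window and 50% overlap; ``n_segments`` sets
    the segment count (at least 2; segment averaging is what keeps the
    estimate below 1 for unrelated signals, with a known small-sample
    bias of about ``1/n_segments``).
    """
    xv, yv = _check_pair(x, y)
    if fs is None:
        fs = _rate(x) or _rate(y)
    if fs is None:
        raise ValueError("sampling rate required (pass fs= or ROISeries)")
    if n_segments < 2:
        raise ValueError("insufficient segments: n_segments must be >= 2")
    nyq = fs / 2
    lo, hi = band
    if not 0 < lo < hi < nyq:
        raise ValueError(
            f"band must lie within (0, {nyq}) Hz, got {band}"
        )
    nperseg = (2 * len(xv)) // (n_segments + 1)
    if nperseg < 8:
        raise ValueError(
            "insufficient segments: series too short for "
            f"{n_segments} Welch segments"
        )
    f, cxy = _sig.coherence(
        xv, yv, fs=fs, nperseg=nperseg, noverlap=nperseg // 2
    )
    sel = (f >= lo) & (f <= hi)
    if not sel.any():
        raise ValueError("no Welch frequencies fall inside the band")
    return float(cxy[sel].mean())


def mutual_information_pair(x, y, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) from the joint equal-width
    ``n_bins x n_bins`` histogram."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    xv, yv = _check_pair(x, y)
    joint, _, _ = np.histogram2d(xv, yv, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _ols_rss(design: np.ndarray, target: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("degenerate regression: singular design matrix")
    resid = target - design @ coef
    return float(resid @ resid)


def granger_pair(x, y, max_lag: int = 1) -> tuple[float, float]:
    """Directed log-ratio Granger statistics ``(F_xy, F_yx)``.

    ``F_xy = ln(RSS_restricted / RSS_full)`` for predicting ``y`` from its
    own ``max_lag`` past values (restricted) vs additionally ``x``'s past
    values (full); ``F_yx`` is the reverse direction.  Both are >= 0 up to
    numerical noise; unrelated series give values near 0.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    xv, yv = _check_pair(x, y)
    n = len(xv)
    if n <= 10 * max_lag:
        raise ValueError(
            f"series length {n} too short for max_lag={max_lag} "
            "(need length > 10 * max_lag)"
        )

    def lagmat(v: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [v[max_lag - k - 1 : n - k - 1] for k in range(max_lag)]
        )

    ones = np.ones((n - max_lag, 1))
    lx, ly = lagmat(xv), lagmat(yv)

    def one_direction(src_l, dst_l, dst):
        rss_r = _ols_rss(np.hstack([ones, dst_l]), dst)
        rss_f = _ols_rss(np.hstack([ones, dst_l, src_l]), dst)
        if rss_f <= 0 or rss_r <= 0:
            raise ValueError("degenerate regression: zero residual variance")
        return max(0.0, float(np.log(rss_r / rss_f)))

    f_xy = one_direction(lx, ly, yv[max_lag:])
    f_yx = one_direction(ly, lx, xv[max_lag:])
    return f_xy, f_yx


def _pair_value(xv, yv, params: SynchronyParams, fs: float | None):
    m = params.measure
    if m == "pearson":
        return pearson_pair(xv, yv)
    if m == "coherence":
        return coherence_band_pair(
            xv, yv, params.band, n_segments=params.n_segments, fs=fs
        )
    if m == "mutual_information":
        return mutual_information_pair(xv, yv, n_bins=params.n_bins)
    raise AssertionError(m)


def _series_labels(series: list[ROISeries]) -> list[str]:
    pids = [s.participant_id for s in series]
    if len(set(pids)) == len(pids):
        return pids
    return [f"{s.participant_id}:{s.roi}" for s in series]


def connection_matrix(
    series: list[ROISeries], params: SynchronyParams | None = None
) -> ConnectionMatrix:
    """K x K matrix of the chosen pairwise measure over all node pairs.

    Symmetric measures are computed once per unordered pair and mirrored,
    so the matrix is exactly symmetric.  For ``granger`` the entry (i, j)
    is the directed statistic i -> j and the matrix is generally
    asymmetric; symmetrize explicitly before thresholding.
    """
    params = params or SynchronyParams()
    if len(series) < 2:
        raise ValueError("need at least two series")
    n0 = series[0].n_samples
    r0 = series[0].sampling_rate
    for s in series[1:]:
        if s.n_samples != n0:
            raise ValueError("series lengths differ; preprocess onto one grid")
        if abs(s.sampling_rate - r0) > 1e-9:
            raise ValueError("series sampling rates differ")
    labels = _series_labels(series)
    k = len(series)
    vals = np.zeros((k, k))
    if params.measure == "granger":
        for i in range(k):
            for j in range(i + 1, k):
                f_ij, f_ji = granger_pair(
                    series[i], series[j], max_lag=params.max_lag
                )
                vals[i, j] = f_ij
                vals[j, i] = f_ji
    else:
        for i in range(k):
            for j in range(i + 1, k):
                v = _pair_value(series[i], series[j], params, r0)
                vals[i, j] = vals[j, i] = v
        if params.measure in ("pearson", "coherence"):
            np.fill_diagonal(vals, 1.0)
        else:  # mutual information of a series with itself = its entropy
            for i in range(k):
                vals[i, i] = mutual_information_pair(
                    series[i], series[i], n_bins=params.n_bins
                )
    return ConnectionMatrix(labels=labels, values=vals, measure=params.measure)


def threshold_adjacency(
    cm: ConnectionMatrix, tau: float, absolute: bool = False
) -> AdjacencyMatrix:
    """Binary MBN: edge (i, j) iff value > ``tau`` (strict), i != j.

    With the default ``absolute=False`` the signed value is compared, so
    negative correlations never form edges at a positive threshold.
    """
    vals = cm.values
    if not np.array_equal(vals, vals.T):
        raise ValueError(
            "asymmetric connection matrix; symmetrize explicitly first "
            "(see symmetrize_directed)"
        )
    if absolute:
        vals = np.abs(vals)
    adj = (vals > tau).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return AdjacencyMatrix(labels=list(cm.labels), values=adj, threshold=tau)


def symmetrize_directed(cm: ConnectionMatrix, how: str = "max") -> ConnectionMatrix:
    """Collapse a directed (e.g. Granger) matrix to an undirected one."""
    ops = {"max": np.maximum, "min": np.minimum}
    if how == "mean":
        vals = (cm.values + cm.values.T) / 2
    elif how in ops:
        vals = ops[how](cm.values, cm.values.T)
    else:
        raise ValueError(f"unknown symmetrization '{how}'")
    return ConnectionMatrix(
        labels=list(cm.labels),
        values=vals,
        measure=cm.measure,
        window_start=cm.window_start,
    )


def windowed_connection_matrices(
    series: list[ROISeries], params: SynchronyParams
) -> list[ConnectionMatrix]:
    """Sliding-window connection matrices for a dynamic MBN.

    Windows start at the series start and advance by the step for as long
    as a full window fits; each output matrix is tagged with its window
    start time on the common clock.
    """
    if params.window is None:
        raise ValueError("params.window must be set (length_s, step_s)")
    length_s, step_s = params.window
    if step_s <= 0:
        raise ValueError("step must be positive")
    fs = series[0].sampling_rate
    wlen = int(round(length_s * fs))
    step = int(round(step_s * fs))
    if wlen < 10:
        raise ValueError("window must cover at least 10 samples")
    if step < 1:
        raise ValueError("step shorter than one sample")
    n = series[0].n_samples
    if wlen > n:
        raise ValueError("window longer than series")
    out = []
    for start in range(0, n - wlen + 1, step):
        chunk = [
            ROISeries(
                participant_id=s.participant_id,
                roi=s.roi,
                sampling_rate=s.sampling_rate,
                start_time=s.start_time + start / fs,
                values=s.values[start : start + wlen],
            )
            for s in series
        ]
        cm = connection_matrix(chunk, params)
        cm.window_start = series[0].start_time + start / fs
        out.append(cm)
    return out
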