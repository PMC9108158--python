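"""Sliding-window dynamic functional connectivity.

A subject's ROI time series (T volumes x R regions) is segmented into
overlapping rectangular windows of ``window_len`` volumes advanced by ``step``
volumes.  Within each window the R x R Pearson correlation matrix is computed,
variance-stabilised by the Fisher z transform (z = atanh r), and its strict
upper triangle flattened into an edge vector of length E = R(R-1)/2.  The
result is a W x E matrix of windowed connectivity features — the sample
matrix consumed by state clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "RoiTimeSeries",
    "WindowParams",
    "WindowedFc",
    "count_windows",
    "window_correlation",
    "fisher_z",
    "vectorize_upper",
    "reconstruct_matrix",
    "compute_dynamic_fc",
    "n_edges",
]

#: Correlations are clamped to this magnitude before atanh so degenerate
#: windows (duplicated signals) yield a large finite z instead of infinity.
R_CLAMP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """One subject's ROI signal matrix (T volumes x R regions)."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0
    roi_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be 2-D (volumes x ROIs)")
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite values in time series of {self.subject_id}")
        if self.roi_ids is not None and len(self.roi_ids) != self.data.shape[1]:
            raise ValueError("roi_ids length does not match column count")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowParams:
    """Sliding-window geometry: 15 volumes (30 s at TR = 2 s), step 1."""

    window_len_volumes: int = 15
    step_volumes: int = 1

    def __post_init__(self) -> None:
        if self.step_volumes < 1:
            raise ValueError("step must be >= 1")
        if self.window_len_volumes < self.step_volumes:
            raise ValueError("window length must be >= step")

    def validate_for(self, n_volumes: int, tr_seconds: float) -> None:
        if self.window_len_volumes > n_volumes:
            raise ValueError(
                f"window length {self.window_len_volumes} exceeds series "
                f"length {n_volumes}"
            )
        if self.window_len_volumes * tr_seconds < 30.0:
            warnings.warn(
                "window shorter than 30 s; windowed correlations may be "
                "unreliable at low frequencies",
                stacklevel=2,
            )


@dataclass
class WindowedFc:
    """W x E matrix of Fisher-z edge vectors plus window start indices."""

    subject_id: str
    data: np.ndarray
    window_starts: np.ndarray
    n_rois: int

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]


def n_edges(n_rois: int) -> int:
    """Number of distinct ROI pairs: R(R-1)/2 (12,720 for R = 160)."""
    return n_rois * (n_rois - 1) // 2


def count_windows(n_volumes: int, window_len: int, step: int = 1) -> int:
    """Number of sliding windows: floor((T - L)/step) + 1.

    229 volumes with a 15-volume window and unit step give 215 windows.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_len > n_volumes:
        raise ValueError(
            f"window length {window_len} exceeds series length {n_volumes}"
        )
    return (n_volumes - window_len) // step + 1


def window_correlation(window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of one window (L volumes x R ROIs)."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 3:
        raise ValueError("window must be 2-D with at least 3 volumes")
    sd = window.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance signal in window for ROI index(es) {dead.tolist()}"
        )
    r = np.corrcoef(window, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z transform, z = atanh(r), with |r| clamped to 1 - 1e-7.

    The clamp keeps z finite (~8.1) when a window contains perfectly
    correlated signals.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -R_CLAMP, R_CLAMP))
    return float(z) if np.isscalar(r) else z


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle in row-major order.

    Edge order is (0,1), (0,2), ..., (0,R-1), (1,2), ... — the on-disk
    contract for all edge vectors in this package.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju]


def reconstruct_matrix(vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric matrix, unit diagonal."""
    vector = np.asarray(vector, dtype=float)
    expected = n_edges(n_rois)
    if vector.shape != (expected,):
        raise ValueError(
            f"edge vector length {vector.shape} does not match R={n_rois} "
            f"(expected {expected})"
        )
    out = np.eye(n_rois)
    iu, ju = np.triu_indices(n_rois, k=1)
    out[iu, ju] = vector
    out[ju, iu] = vector
    return out


def _windowed_pearson(data: np.ndarray, window_len: int, step: int) -> np.ndarray:
    """All windowed correlation matrices at once, shape (W, R, R)."""
    views = sliding_window_view(data, window_len, axis=0)[::step]  # W x R x L
    centred = views - views.mean(axis=2, keepdims=True)
    sd = centred.std(axis=2)
    if np.any(sd == 0):
        w, roi = np.argwhere(sd == 0)[0]
        raise ValueError(
            f"zero-variance signal for ROI index {roi} in window {w}"
        )
    normed = centred / (sd[:, :, None] * np.sqrt(window_len))
    corr = np.einsum("wrl,wsl->wrs", normed, normed)
    return np.clip(corr, -1.0, 1.0)


def compute_dynamic_fc(ts: RoiTimeSeries, params: WindowParams | None = None) -> WindowedFc:
    """Full sliding-window pipeline: correlate, Fisher-z, vectorise.

    Returns a W x E matrix whose row w is
    ``fisher_z(vectorize_upper(window_correlation(window_w)))``.
    """
    if params is None:
        params = WindowParams()
    params.validate_for(ts.n_volumes, ts.tr_seconds)
    L, step = params.window_len_volumes, params.step_volumes
    w = count_windows(ts.n_volumes, L, step)
    corr = _windowed_pearson(ts.data, L, step)
    iu, ju = np.triu_indices(ts.n_rois, k=1)
    edges = fisher_z(corr[:, iu, ju])
    starts = np.arange(w) * step
    return WindowedFc(
        subject_id=ts.subject_id, data=edges, window_starts=starts, n_rois=ts.n_rois
    )
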