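"""Functional-connectivity construction from ROI time series.

Turns regional BOLD time series into Fisher-z connectivity matrices and
edge vectors under one fixed edge-index convention: 0-based, row-major
over the strict upper triangle, so a symmetric ``N x N`` matrix maps to
``N*(N-1)/2`` features (6670 for the 116-region AAL parcellation).

Cleaning follows the conventional resting-state order: linear detrend,
zero-phase Butterworth bandpass (0.01-0.08 Hz by default), then nuisance
regression against confounds that were themselves detrended and filtered
identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "EdgeVector",
    "edge_index",
    "n_edges",
    "clean_timeseries",
    "correlation_matrix",
    "vectorize",
    "devectorize",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_edge_vector_tsv",
]

#: |r| values are clipped to 1 - _R_CLIP before atanh to keep z finite.
_R_CLIP = 1e-7
#: symmetry tolerance for matrices entering vectorize()
_SYM_TOL = 1e-10


def n_edges(n_regions: int) -> int:
    """Number of unordered region pairs (upper-triangle edges)."""
    return n_regions * (n_regions - 1) // 2


def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, row-major.

    Edge ``e`` connects regions ``(iu[e], ju[e])`` with ``iu[e] < ju[e]``;
    the ordering is lexicographic, i.e. (0,1), (0,2), ..., (N-2,N-1).
    """
    return np.triu_indices(n_regions, k=1)


@dataclass
class RoiTimeSeries:
    """T x N matrix of regional time series in arbitrary BOLD units."""

    values: np.ndarray
    sampling_interval: float = 2.0  # seconds (TR)
    region_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T x N matrix")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.region_ids is None:
            self.region_ids = [f"roi_{i}" for i in range(self.values.shape[1])]
        if len(self.region_ids) != self.values.shape[1]:
            raise ValueError("region_ids length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    z: np.ndarray
    region_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("z must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite values")
        if self.region_ids is None:
            self.region_ids = [f"roi_{i}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValueError("region_ids length must match matrix order")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class EdgeVector:
    """Upper-triangle flattening of a connectivity matrix.

    ``values[e]`` is the Fisher-z weight of the edge joining
    ``edge_index[0][e]`` and ``edge_index[1][e]`` (0-based, i < j,
    row-major over the strict upper triangle).
    """

    values: np.ndarray
    n_regions: int
    region_ids: list[str] | None = None
    edge_index: tuple[np.ndarray, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n_edges(self.n_regions),):
            raise ValueError(
                f"expected {n_edges(self.n_regions)} edges for "
                f"{self.n_regions} regions, got {self.values.shape}"
            )
        self.edge_index = edge_index(self.n_regions)


def _bandpass_sos(band: tuple[float, float], fs: float):
    low, high = band
    nyquist = fs / 2.0
    if not 0.0 < low < high:
        raise ValueError(f"invalid band {band}: need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"band upper edge {high} Hz must be below the Nyquist "
            f"frequency {nyquist} Hz (sampling interval {1.0 / fs} s)"
        )
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _detrend_filter(x: np.ndarray, sos) -> np.ndarray:
    x = signal.detrend(x, axis=0, type="linear")
    return signal.sosfiltfilt(sos, x, axis=0)


def clean_timeseries(
    ts: RoiTimeSeries,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.08),
) -> RoiTimeSeries:
    """Detrend, bandpass and regress confounds out of ROI time series.

    Order of operations is fixed: linear detrend, zero-phase 4th-order
    Butterworth bandpass, then OLS residualisation against the confound
    columns (detrended and filtered identically, plus an intercept).

    Parameters
    ----------
    ts
        Input series, T timepoints by N regions.
    confounds
        Optional T x K nuisance matrix (e.g. WM/CSF means, motion
        parameters). Rank-deficient confounds are reduced to a full-rank
        column subset with a warning.
    band
        Passband in Hz; the upper edge must lie below Nyquist.
    """
    fs = 1.0 / ts.sampling_interval
    sos = _bandpass_sos(band, fs)
    cleaned = _detrend_filter(ts.values, sos)

    if confounds is not None and np.size(confounds) > 0:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != ts.n_timepoints:
            raise ValueError("confounds must have one row per timepoint")
        conf = _detrend_filter(confounds, sos)
        design = np.column_stack([np.ones(len(conf)), conf])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # keep a full-rank pivot subset (QR with column pivoting)
            _, _, piv = sla.qr(design, mode="economic", pivoting=True)
            keep = np.sort(piv[:rank])
            warnings.warn(
                f"confound matrix is rank-deficient; keeping columns {keep.tolist()} "
                "of the intercept-augmented design",
                stacklevel=2,
            )
            design = design[:, keep]
        beta, *_ = np.linalg.lstsq(design, cleaned, rcond=None)
        cleaned = cleaned - design @ beta

    return RoiTimeSeries(cleaned, ts.sampling_interval, list(ts.region_ids))


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlations between all region pairs, Fisher-z transformed.

    ``z[i, j] = atanh(r_ij)`` off the diagonal; the diagonal is set to 0.
    Perfect correlations are clipped to ``1 - 1e-7`` in magnitude (with a
    warning) so the transform stays finite on degenerate input.
    """
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.region_ids[i] for i in bad]
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= 1.0 - _R_CLIP):
        warnings.warn(
            "perfectly correlated region pair(s); clipping |r| before atanh",
            stacklevel=2,
        )
        r = np.clip(r, -(1.0 - _R_CLIP), 1.0 - _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against FP asymmetry
    return ConnectivityMatrix(z, list(ts.region_ids))


def vectorize(m: ConnectivityMatrix) -> EdgeVector:
    """Flatten the strict upper triangle to a length N*(N-1)/2 vector."""
    asym = np.max(np.abs(m.z - m.z.T))
    if asym > _SYM_TOL:
        raise ValueError(f"matrix asymmetric beyond tolerance: max |z - z.T| = {asym:g}")
    iu, ju = edge_index(m.n_regions)
    return EdgeVector(m.z[iu, ju], m.n_regions, list(m.region_ids))


def devectorize(v: EdgeVector) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize`."""
    n = v.n_regions
    z = np.zeros((n, n))
    iu, ju = v.edge_index
    z[iu, ju] = v.values
    z = z + z.T
    return ConnectivityMatrix(z, list(v.region_ids) if v.region_ids else None)


# ---------------------------------------------------------------------------
# plain-text readers/writers

def read_timeseries_tsv(path, sampling_interval: float = 2.0) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(df.to_numpy(float), sampling_interval, list(df.columns))


def write_timeseries_tsv(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=ts.region_ids).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(float), list(df.columns))


def write_matrix_tsv(m: ConnectivityMatrix, path) -> None:
    pd.DataFrame(m.z, index=m.region_ids, columns=m.region_ids).to_csv(path, sep="\t")


def write_edge_vector_tsv(v: EdgeVector, path) -> None:
    iu, ju = v.edge_index
    ids = v.region_ids or [f"roi_{i}" for i in range(v.n_regions)]
    pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "region_i": [ids[i] for i in iu],
            "region_j": [ids[j] for j in ju],
            "z": v.values,
        }
    ).to_csv(path, sep="\t", index=False)
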