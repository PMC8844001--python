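"""Multiplication of temporal derivatives (MTD) windowed coupling.

The MTD estimator scores moment-to-moment coupling between two regions
as the product of their normalised first differences:

    raw(t, i, j) = dx_i(t) * dx_j(t) / (sigma_i * sigma_j)

where dx is the backward difference of the BOLD signal and sigma the
run-level (population) standard deviation of dx per region.  The raw
product series is then smoothed with a simple moving average of
``w`` TRs, yielding one symmetric coupling matrix per retained window.

Edge convention: the first ``w`` positions of the difference series are
dropped, so a run of T volumes yields exactly T - 1 - w windows
(292 for T = 300, w = 7).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import RoiTimeSeries

__all__ = [
    "DerivativeSeries",
    "CouplingWindowSeries",
    "temporal_derivatives",
    "mtd_coupling",
    "smooth_windows",
    "vectorize_upper",
    "devectorize_upper",
    "coupling_windows",
    "coupling_vectors",
    "n_windows",
]

DEFAULT_WINDOW_TR = 7


def n_windows(n_volumes: int, w: int = DEFAULT_WINDOW_TR) -> int:
    """Number of coupling windows retained from a run of ``n_volumes``."""
    return n_volumes - 1 - w


@dataclass
class DerivativeSeries:
    """Backward differences of a run with per-ROI derivative scale."""

    dx: np.ndarray       # (T-1, n_roi)
    sigma: np.ndarray    # (n_roi,) population std of dx over the run

    @property
    def n_roi(self) -> int:
        return self.dx.shape[1]


@dataclass
class CouplingWindowSeries:
    """Ordered smoothed coupling matrices for one run."""

    matrices: np.ndarray  # (W, n_roi, n_roi)
    window_size: int
    run_id: str | None = None
    subject_id: str | None = None

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_roi(self) -> int:
        return self.matrices.shape[1]

    def vectors(self) -> np.ndarray:
        """(W, n_roi*(n_roi-1)/2) upper-triangle coupling vectors."""
        iu = np.triu_indices(self.n_roi, k=1)
        return self.matrices[:, iu[0], iu[1]]


def temporal_derivatives(ts: RoiTimeSeries) -> DerivativeSeries:
    """First differences of the BOLD series and their run-level scale.

    sigma uses the population convention (ddof = 0) over all T - 1
    differences of each ROI.
    """
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes to form derivative statistics")
    dx = np.diff(ts.values, axis=0)
    sigma = dx.std(axis=0, ddof=0)
    return DerivativeSeries(dx=dx, sigma=sigma)


def mtd_coupling(deriv: DerivativeSeries) -> np.ndarray:
    """Raw coupling tensor of shape (T-1, n_roi, n_roi).

    ROIs with zero derivative variability (flat signal) get zero
    coupling everywhere, with a warning, so downstream clustering input
    stays finite.
    """
    sigma = deriv.sigma.copy()
    flat = sigma == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} ROI(s) have flat signal (sigma = 0); "
            "their couplings are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma[flat] = 1.0
    dxn = deriv.dx / sigma
    dxn[:, flat] = 0.0
    return np.einsum("ti,tj->tij", dxn, dxn)


def smooth_windows(
    raw: np.ndarray,
    w: int = DEFAULT_WINDOW_TR,
    run_id: str | None = None,
    subject_id: str | None = None,
) -> CouplingWindowSeries:
    """Moving-average smoothing of the raw coupling tensor.

    Window m (0-based) is the unweighted mean of raw positions
    m+1 ... m+w, i.e. the leading ``w`` positions are dropped and
    (T - 1) - w windows are retained.
    """
    raw = np.asarray(raw, dtype=float)
    n_raw = raw.shape[0]
    if w < 1:
        raise ValueError("window size must be >= 1")
    if w >= n_raw:
        raise ValueError(f"window w={w} too large for {n_raw} raw coupling samples")
    csum = np.cumsum(raw, axis=0)
    # window m = mean over raw[m+1 : m+1+w] = (csum[m+w] - csum[m]) / w
    smoothed = (csum[w:] - csum[: n_raw - w]) / w
    return CouplingWindowSeries(
        matrices=smoothed, window_size=w, run_id=run_id, subject_id=subject_id
    )


def vectorize_upper(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Row-major upper-triangle (diagonal excluded) flattening.

    A 114 x 114 coupling matrix yields the 6441 unique coupling values.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(matrix, matrix.T, atol=atol, rtol=0.0):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def devectorize_upper(vector: np.ndarray, n_roi: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; diagonal is set to 0."""
    vector = np.asarray(vector, dtype=float)
    expected = n_roi * (n_roi - 1) // 2
    if vector.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got {vector.shape}")
    out = np.zeros((n_roi, n_roi))
    iu = np.triu_indices(n_roi, k=1)
    out[iu] = vector
    return out + out.T


def coupling_windows(ts: RoiTimeSeries, w: int = DEFAULT_WINDOW_TR) -> CouplingWindowSeries:
    """Full MTD stage for one run: derivatives -> raw products -> windows."""
    deriv = temporal_derivatives(ts)
    raw = mtd_coupling(deriv)
    return smooth_windows(raw, w=w, run_id=ts.run_id, subject_id=ts.subject_id)


def coupling_vectors(ts: RoiTimeSeries, w: int = DEFAULT_WINDOW_TR) -> np.ndarray:
    """(W, n_roi*(n_roi-1)/2) coupling vectors without materialising the
    full (T-1, n, n) tensor — the memory-lean path used when
    concatenating many runs for clustering."""
    deriv = temporal_derivatives(ts)
    sigma = deriv.sigma.copy()
    flat = sigma == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} ROI(s) have flat signal (sigma = 0); "
            "their couplings are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma[flat] = 1.0
    dxn = deriv.dx / sigma
    dxn[:, flat] = 0.0
    iu, ju = np.triu_indices(ts.n_roi, k=1)
    raw_vec = dxn[:, iu] * dxn[:, ju]
    return smooth_windows(raw_vec, w=w).matrices
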