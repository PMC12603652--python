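"""Containers and basic signal operations for ROI-level fMRI time series.

Everything downstream builds on the primitives here: validated containers
for single series and multi-voxel region-of-interest (ROI) matrices,
discrete-cosine high-pass filter bases (SPM convention), projection-based
confound removal, and SPM-style first-eigenvariate extraction.

All operations accept either the typed containers or bare NumPy arrays and
return a result of matching kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError

#: Largest absolute entry below which a matrix is treated as identically zero.
ZERO_TOL = 1e-12


@dataclass(eq=False)
class TimeSeries:
    """A single regularly sampled signal.

    Parameters
    ----------
    values : array-like, shape (T,)
        Signal samples in arbitrary units.
    tr : float
        Sampling interval (repetition time), seconds.
    """

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2 and 1 in v.shape:
            v = v.ravel()
        if v.ndim != 1:
            raise InvalidArgumentError("TimeSeries values must be one-dimensional")
        if v.size < 8:
            raise InvalidArgumentError(
                f"a TimeSeries needs at least 8 samples, got {v.size}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("TimeSeries values must all be finite")
        if not float(self.tr) > 0:
            raise InvalidArgumentError("tr must be positive")
        self.values = v
        self.tr = float(self.tr)

    @property
    def n_scans(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size


@dataclass(eq=False)
class RoiMatrix:
    """Multi-voxel ROI data: T timepoints by V voxels.

    Rows are timepoints, columns are voxels; the spatial layout of the ROI
    is irrelevant here (the matrix arrives already extracted).
    """

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise InvalidArgumentError("RoiMatrix values must be two-dimensional")
        if v.shape[1] < 1:
            raise InvalidArgumentError("RoiMatrix needs at least one voxel column")
        if v.shape[0] < 8:
            raise InvalidArgumentError(
                f"RoiMatrix needs at least 8 timepoints, got {v.shape[0]}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("RoiMatrix values must all be finite")
        if not float(self.tr) > 0:
            raise InvalidArgumentError("tr must be positive")
        self.values = v
        self.tr = float(self.tr)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass(eq=False)
class BasisSet:
    """A T-by-K matrix of nuisance/filter regressors with column labels."""

    columns: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.columns, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.ndim != 2:
            raise InvalidArgumentError("BasisSet columns must be two-dimensional")
        if not np.all(np.isfinite(c)):
            raise InvalidArgumentError("BasisSet columns must all be finite")
        self.columns = c
        if not self.labels:
            self.labels = [f"nuisance_{k}" for k in range(c.shape[1])]
        if len(self.labels) != c.shape[1]:
            raise InvalidArgumentError("number of labels must match column count")

    @classmethod
    def empty(cls, n_scans: int) -> "BasisSet":
        return cls(np.empty((n_scans, 0)), [])

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def concat_bases(*bases: BasisSet | None) -> BasisSet:
    """Horizontally stack basis sets, skipping ``None`` and empty entries."""
    keep = [b for b in bases if b is not None and b.n_columns > 0]
    if not keep:
        n = next(
            (b.columns.shape[0] for b in bases if b is not None), 0
        )
        return BasisSet.empty(n)
    cols = np.hstack([b.columns for b in keep])
    labels: list[str] = []
    for b in keep:
        labels.extend(b.labels)
    return BasisSet(cols, labels)


def _data(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def _like(x, values: np.ndarray):
    if isinstance(x, TimeSeries):
        return TimeSeries(values, x.tr)
    if isinstance(x, RoiMatrix):
        return RoiMatrix(values, x.tr)
    return values


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float) -> BasisSet:
    """Discrete-cosine high-pass filter basis, SPM convention.

    Returns the non-constant cosine regressors with period at least
    ``cutoff`` seconds.  The retained column count is
    ``floor(2 * n_scans * tr / cutoff + 1) - 1`` (the constant term is
    excluded; an intercept is modeled separately in any GLM).  Columns are
    mutually orthonormal and have zero sample mean.

    Parameters
    ----------
    n_scans : int
        Number of timepoints T.
    tr : float
        Sampling interval, seconds.
    cutoff : float
        High-pass cutoff period, seconds.  ``inf`` disables filtering
        (zero columns).
    """
    if n_scans <= 0 or tr <= 0 or cutoff <= 0:
        raise InvalidArgumentError("n_scans, tr and cutoff must be positive")
    if not cutoff > 2 * tr:
        raise InvalidArgumentError("cutoff must exceed twice the sampling interval")
    order = int(np.floor(2.0 * n_scans * tr / cutoff + 1.0))
    n_cols = max(0, order - 1)
    t = np.arange(n_scans)
    cols = np.empty((n_scans, n_cols))
    for j in range(n_cols):
        k = j + 1
        cols[:, j] = np.sqrt(2.0 / n_scans) * np.cos(
            np.pi * (2 * t + 1) * k / (2.0 * n_scans)
        )
    labels = [f"dct_{j + 1}" for j in range(n_cols)]
    return BasisSet(cols, labels)


def residualize(data, nuisance: BasisSet):
    """Project out the column space of ``nuisance`` from ``data``.

    Computes ``(I - P) @ data`` with P the orthogonal projector onto the
    nuisance columns.  Rank-deficient bases are handled by least squares
    (pseudoinverse), so repeated or collinear regressors are harmless and
    the operation is idempotent.
    """
    x = _data(data)
    basis = nuisance.columns
    if basis.shape[1] == 0:
        return data
    if basis.shape[0] != x.shape[0]:
        raise InvalidArgumentError(
            f"nuisance has {basis.shape[0]} rows but data has {x.shape[0]}"
        )
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return _like(data, x - basis @ coef)


def first_eigenvariate(roi: RoiMatrix | np.ndarray, tr: float | None = None) -> TimeSeries:
    """First eigenvariate of a T-by-V ROI matrix, SPM scaling and sign.

    Returns ``u1 * sqrt(s1 / V)`` where ``u1`` is the leading left singular
    vector and ``s1`` the leading eigenvalue of the data Gram matrix, with
    the sign chosen so the sum of voxel weights is positive.  For V
    identical columns this reproduces the common column exactly.
    """
    y = _data(roi)
    if y.ndim == 1:
        y = y[:, None]
    if tr is None:
        tr = roi.tr if isinstance(roi, RoiMatrix) else 1.0
    if np.max(np.abs(y)) < ZERO_TOL:
        raise DegenerateInputError("ROI matrix is numerically all-zero")
    n_vox = y.shape[1]
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    u1 = u[:, 0]
    v1 = vt[0]
    s1 = s[0] ** 2  # leading eigenvalue of Y'Y
    sign = 1.0 if v1.sum() >= 0 else -1.0
    return TimeSeries(sign * u1 * np.sqrt(s1 / n_vox), tr)
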