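"""AR(1) noise modeling, prewhitening, and whitening inversion.

The whitening matrix **W** for a stationary AR(1) process with lag-1
coefficient rho is banded lower triangular:

    W[0, 0]   = sqrt(1 - rho^2)
    W[t, t]   = 1,      t >= 1
    W[t, t-1] = -rho,   t >= 1

so that for x with AR(1) covariance Sigma(rho), ``W @ Sigma @ W.T`` is a
multiple of the identity.  Because W is triangular with positive diagonal
it is exactly invertible; "whitening inversion" — multiplying an
already-whitened series by W^-1 to restore its original temporal
structure — is a banded triangular solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .core_timeseries import _data, _like
from .errors import DegenerateInputError, InvalidArgumentError

logger = logging.getLogger(__name__)

#: rho is clipped to this magnitude to keep W invertible and well scaled.
RHO_CLIP = 0.99


@dataclass(frozen=True)
class ArModel:
    """First-order autoregressive noise model.

    Attributes
    ----------
    rho : float
        Lag-1 autoregressive coefficient, clipped to [-0.99, 0.99].
    innovation_sd : float
        Standard deviation of the AR innovations, in signal units.
    """

    rho: float
    innovation_sd: float

    def __post_init__(self) -> None:
        if abs(self.rho) > RHO_CLIP:
            raise InvalidArgumentError(f"|rho| must be <= {RHO_CLIP}, got {self.rho}")
        if self.innovation_sd < 0:
            raise InvalidArgumentError("innovation_sd must be non-negative")


@dataclass(eq=False)
class WhiteningMatrix:
    """Banded lower-triangular T-by-T whitening operator and its source rho."""

    entries: np.ndarray
    source_rho: float

    def __post_init__(self) -> None:
        w = np.asarray(self.entries, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidArgumentError("whitening matrix must be square")
        if np.any(np.diag(w) <= 0):
            raise InvalidArgumentError("whitening matrix diagonal must be positive")
        self.entries = w

    @property
    def n_scans(self) -> int:
        return self.entries.shape[0]


def estimate_ar1(residuals, demean: bool = False) -> ArModel:
    """Yule-Walker lag-1 AR coefficient and innovation scale.

    ``rho = sum_t e_t e_{t-1} / sum_t e_t^2``, clipped to [-0.99, 0.99].
    Two-dimensional input (T by V) pools numerator and denominator across
    columns, which reduces to the single-series estimate at V = 1.

    Parameters
    ----------
    residuals : array-like or TimeSeries
        Residual series; should be (near) zero-mean, e.g. from a model
        that included an intercept.  Set ``demean=True`` to subtract the
        column mean first.
    """
    e = _data(residuals)
    if e.ndim == 1:
        e = e[:, None]
    if np.max(np.abs(e)) < 1e-12:
        raise DegenerateInputError("residuals are numerically all-zero")
    if demean:
        e = e - e.mean(axis=0, keepdims=True)
        if np.max(np.abs(e)) < 1e-12:
            raise DegenerateInputError("residuals are constant (zero after demeaning)")
    num = float(np.sum(e[1:] * e[:-1]))
    den = float(np.sum(e * e))
    rho = num / den
    if abs(rho) > RHO_CLIP:
        logger.warning("AR(1) estimate %.4f clipped to +/-%.2f", rho, RHO_CLIP)
        rho = float(np.clip(rho, -RHO_CLIP, RHO_CLIP))
    innov = e[1:] - rho * e[:-1]
    innovation_sd = float(np.sqrt(np.mean(innov**2)))
    return ArModel(rho=rho, innovation_sd=innovation_sd)


def build_whitening_matrix(ar: ArModel | float, n_scans: int) -> WhiteningMatrix:
    """Construct the banded AR(1) whitening matrix for ``n_scans`` timepoints.

    Accepts an :class:`ArModel` or a bare rho.  The first row uses the
    stationary initialization ``sqrt(1 - rho^2)`` so that the full series
    length is preserved and ``W @ Sigma(rho) @ W.T`` equals the innovation
    variance times the identity exactly.
    """
    rho = ar.rho if isinstance(ar, ArModel) else float(ar)
    if not abs(rho) < 1.0:
        raise InvalidArgumentError(f"|rho| must be < 1, got {rho}")
    if n_scans < 1:
        raise InvalidArgumentError("n_scans must be positive")
    w = np.eye(n_scans)
    w[0, 0] = np.sqrt(1.0 - rho**2)
    idx = np.arange(1, n_scans)
    w[idx, idx - 1] = -rho
    return WhiteningMatrix(entries=w, source_rho=rho)


def apply_whitening(w: WhiteningMatrix, x):
    """Return ``W @ x`` for a series or matrix (columns whitened jointly).

    Uses the banded structure directly (O(T) per column) rather than a
    dense product.
    """
    v = _data(x)
    rho = w.source_rho
    if v.shape[0] != w.n_scans:
        raise InvalidArgumentError(
            f"series has {v.shape[0]} rows but W is {w.n_scans}x{w.n_scans}"
        )
    out = np.empty_like(v, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * v[0]
    out[1:] = v[1:] - rho * v[:-1]
    return _like(x, out)


def invert_whitening(w: WhiteningMatrix, y):
    """Solve ``W @ x = y`` by forward substitution (banded triangular solve).

    This is the whitening-inversion correction: applied to a prewhitened
    extracted series it restores the original temporal structure, so
    ``invert_whitening(W, apply_whitening(W, x)) == x`` to rounding error.
    """
    v = _data(y)
    if v.shape[0] != w.n_scans:
        raise InvalidArgumentError(
            f"series has {v.shape[0]} rows but W is {w.n_scans}x{w.n_scans}"
        )
    out = solve_triangular(w.entries, v, lower=True)
    return _like(y, out)
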