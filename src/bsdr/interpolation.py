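"""Discrete relaxation of band indices via piecewise-linear interpolation.

A band index ``I`` in ``1..L`` is relaxed to a normalized index ``q`` in
``[0, 1]``.  The denormalization map is ``d(q) = floor(q * (L - 1)) + 1``;
reflectance at a fractional position is the linear interpolation between the
two bracketing bands,

    B(q) = v[d(q)] + (v[d(q) + 1] - v[d(q)]) * (q * (L - 1) - floor(q * (L - 1)))

(with the ``d(q) + 1`` access clamped to band ``L`` when ``d(q) = L``, where
the fractional multiplier is exactly zero).  ``B`` is continuous on [0, 1],
exact at grid points, and differentiable between them with slope
``(v[d(q) + 1] - v[d(q)]) * (L - 1)`` — which is what lets a gradient flow
through the band-selection parameters.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DataValidationError, DomainError


def _check_unit_interval(q: np.ndarray | float) -> None:
    arr = np.asarray(q, dtype=np.float64)
    if not np.isfinite(arr).all() or (arr < 0).any() or (arr > 1).any():
        raise DomainError("normalized band indices must lie in [0, 1]")


def denormalize_index(q, n_bands: int):
    """Map a normalized index ``q`` in [0, 1] to the 1-based band index.

    ``d(q) = floor(q * (L - 1)) + 1`` — monotone non-decreasing in ``q`` and
    surjective onto ``1..L`` as ``q`` sweeps the unit interval.  Accepts
    scalars or arrays.
    """
    if n_bands < 2:
        raise DataValidationError(f"need at least 2 bands, got {n_bands}")
    _check_unit_interval(q)
    idx = np.floor(np.asarray(q, dtype=np.float64) * (n_bands - 1)).astype(np.int64) + 1
    if np.isscalar(q) or np.ndim(q) == 0:
        return int(idx)
    return idx


def interpolate_reflectance(v: np.ndarray, q: float) -> float:
    """Reflectance of one spectrum ``v`` at the normalized index ``q``.

    Exact at grid points ``q = (j - 1)/(L - 1)``; linear between them.  The
    result always lies between the two bracketing band values.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.shape[0] < 2:
        raise DataValidationError("v must be a 1-D reflectance vector with at least 2 bands")
    _check_unit_interval(q)
    L = v.shape[0]
    pos = q * (L - 1)
    left = int(np.floor(pos))          # 0-based image of d(q) - 1
    frac = pos - left
    right = min(left + 1, L - 1)       # clamp: at q=1 the multiplier frac is 0
    return float(v[left] + (v[right] - v[left]) * frac)


def interpolate_batch(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Evaluate every sample's interpolator at each of ``t`` normalized indices.

    Entry ``(i, p)`` equals ``interpolate_reflectance(X[i], r[p])``.  The map
    is differentiable with respect to ``r`` (see ``interpolate_batch_with_slopes``).
    """
    values, _ = interpolate_batch_with_slopes(X, r)
    return values


def interpolate_batch_with_slopes(X: np.ndarray, r: np.ndarray):
    """Batched interpolation plus the analytic derivative w.r.t. each index.

    Returns
    -------
    values : ndarray of shape (N, t)
        ``values[i, p] = B_i(r[p])``.
    slopes : ndarray of shape (N, t)
        ``d values[i, p] / d r[p]`` — the bracketing segment's slope scaled by
        ``L - 1``.  At an interior grid point the right-hand segment's slope
        is used (left-hand at ``q = 1``); both are valid subgradients.
    """
    X = np.asarray(X, dtype=np.float64)
    r = np.atleast_1d(np.asarray(r, dtype=np.float64))
    if X.ndim != 2 or X.shape[1] < 2:
        raise DataValidationError("X must be an N x L matrix with L >= 2")
    _check_unit_interval(r)
    L = X.shape[1]
    pos = r * (L - 1)
    # clamping the left bracket to L-2 reproduces the q=1 boundary rule:
    # frac becomes 1 and the value is exactly v[L]
    left = np.minimum(np.floor(pos).astype(np.int64), L - 2)
    frac = pos - left
    lo = X[:, left]
    hi = X[:, left + 1]
    values = lo + (hi - lo) * frac
    slopes = (hi - lo) * (L - 1)
    return values, slopes
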