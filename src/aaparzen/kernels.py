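"""Aitchison-Aitken kernel on binary feature vectors.

The AA kernel is the discrete analogue of an isotropic Gaussian on the
hypercube {0,1}^L::

    K(x, y; lambda) = lambda^L * ((1 - lambda) / lambda)^d(x, y)

where ``d`` is the Hamming distance and the smoothing parameter ``lambda``
lies in the open interval (0.5, 1).  Writing ``alpha = ln(lambda/(1-lambda))``
(positive on that interval) the kernel factorizes as::

    K(x, y) = lambda^L * exp(-alpha x.x) * exp(2 alpha x.y) * exp(-alpha y.y)

and the cross term ``exp(2 alpha x.y)`` expands as a power series with
coefficients ``gamma_r = (2 alpha)^r / r!``.  The compressed estimator sums
the ``r >= 2`` terms of that series in closed form via :func:`tail_factor`.

All scalar functions here are pure; everything else in the package builds on
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "as_bit_vector",
    "hamming_distance",
    "aa_kernel",
    "log_aa_kernel",
    "factorized_kernel",
    "series_coefficient",
    "tail_factor",
    "log_tail_factor",
]


@dataclass(frozen=True)
class KernelParams:
    """Smoothing parameter and feature dimension of the AA kernel.

    Parameters
    ----------
    lam
        Smoothing parameter, strictly between 0.5 and 1.  ``lam = 0.5``
        (uniform kernel, ``alpha = 0``) and ``lam = 1`` (delta kernel,
        ``alpha`` infinite) are rejected: the log-odds transform degenerates
        at both ends.
    L
        Feature dimension (number of bits), at least 1.
    """

    lam: float
    L: int

    def __post_init__(self) -> None:
        if not (0.5 < self.lam < 1.0):
            raise ValueError(
                f"smoothing parameter lam must lie in the open interval "
                f"(0.5, 1); got {self.lam!r}"
            )
        if int(self.L) != self.L or self.L < 1:
            raise ValueError(f"feature dimension L must be a positive integer; got {self.L!r}")
        object.__setattr__(self, "L", int(self.L))

    @property
    def alpha(self) -> float:
        """Log-odds of the smoothing parameter, ``ln(lam / (1 - lam)) > 0``."""
        return math.log(self.lam / (1.0 - self.lam))

    @property
    def log_lam(self) -> float:
        return math.log(self.lam)


def as_bit_vector(x, L: int | None = None) -> np.ndarray:
    """Validate and return ``x`` as a 1-D int64 array with entries in {0, 1}."""
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D bit vector, got array of ndim {arr.ndim}")
    if arr.dtype == bool:
        arr = arr.astype(np.int64)
    if not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))][0]
        raise ValueError(f"bit vector contains a non-binary entry: {bad!r}")
    arr = arr.astype(np.int64)
    if L is not None and arr.shape[0] != L:
        raise ValueError(f"bit vector has length {arr.shape[0]}, expected {L}")
    return arr


def hamming_distance(x, y) -> int:
    """Number of positions at which two equal-length bit vectors disagree.

    Equals ``x.x - 2 x.y + y.y`` for binary vectors.
    """
    xv = as_bit_vector(x)
    yv = as_bit_vector(y, L=xv.shape[0])
    return int(np.count_nonzero(xv != yv))


def log_aa_kernel(x, y, params: KernelParams) -> float:
    """Natural log of :func:`aa_kernel`; safe for large ``L``."""
    d = hamming_distance(as_bit_vector(x, params.L), as_bit_vector(y, params.L))
    return params.L * params.log_lam - params.alpha * d


def aa_kernel(x, y, params: KernelParams) -> float:
    """AA kernel mass ``lam^L ((1-lam)/lam)^d(x,y)``.

    Maximal (``lam^L``) iff ``x == y``; strictly positive; sums to 1 over
    all ``2^L`` query vectors ``x`` for any fixed ``y``.
    """
    return math.exp(log_aa_kernel(x, y, params))


def factorized_kernel(x, y, params: KernelParams) -> float:
    """The exponential factorization of the AA kernel.

    Computes ``lam^L exp(-alpha x.x) exp(2 alpha x.y) exp(-alpha y.y)``,
    algebraically identical to :func:`aa_kernel`.
    """
    xv = as_bit_vector(x, params.L)
    yv = as_bit_vector(y, params.L)
    a = params.alpha
    xx = int(xv @ xv)
    yy = int(yv @ yv)
    xy = int(xv @ yv)
    return math.exp(params.L * params.log_lam - a * xx + 2.0 * a * xy - a * yy)


def series_coefficient(r: int, alpha: float) -> float:
    """Power-series coefficient ``gamma_r = (2 alpha)^r / r!`` of ``exp(2 alpha t)``."""
    if int(r) != r or r < 0:
        raise ValueError(f"series order r must be a non-negative integer; got {r!r}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive; got {alpha!r}")
    r = int(r)
    return (2.0 * alpha) ** r / math.factorial(r)


# tail_factor regime boundaries.  Below _MU_SMALL the closed form
# 4a^2(e^mu - mu - 1)/mu^2 cancels catastrophically and a 3-term Taylor
# series (truncation error ~ mu^3/60, < 1e-13 relative) is used instead;
# above _MU_LOG the exponential overflows double precision and only the
# log-scale value is representable.
_MU_SMALL = 1e-4
_MU_LOG = 700.0
# Above this, (mu + 1) e^-mu < 2e-16 and log(e^mu - mu - 1) == mu in double
# precision.
_MU_ASYMPTOTIC = 40.0


def tail_factor(mu: float, alpha: float) -> float:
    """Closed-form sum of the series tail: ``sum_{r>=2} gamma_r t^{r-2}`` at ``mu = 2 alpha t``.

    Returns ``4 alpha^2 (e^mu - mu - 1) / mu^2`` for ``mu > 0`` and the
    analytic limit ``2 alpha^2`` at ``mu = 0``.  Continuous and strictly
    increasing in ``mu``.  Overflows to ``inf`` for ``mu`` beyond roughly
    700; use :func:`log_tail_factor` there.
    """
    if mu < 0:
        raise ValueError(f"mu must be non-negative; got {mu!r}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive; got {alpha!r}")
    if mu < _MU_SMALL:
        # Taylor: 4a^2 (e^mu - mu - 1)/mu^2 = 2a^2 (1 + mu/3 + mu^2/12 + ...)
        return 2.0 * alpha * alpha * (1.0 + mu / 3.0 + mu * mu / 12.0)
    if mu > _MU_LOG:
        return math.inf
    return 4.0 * alpha * alpha * (math.expm1(mu) - mu) / (mu * mu)


def log_tail_factor(mu: float, alpha: float) -> float:
    """Natural log of :func:`tail_factor`; finite for arbitrarily large ``mu``.

    For large ``mu`` the exponential dominates and
    ``log g = log(4 alpha^2) + mu - 2 log mu`` exactly to double precision.
    """
    if mu < 0:
        raise ValueError(f"mu must be non-negative; got {mu!r}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive; got {alpha!r}")
    if mu < _MU_ASYMPTOTIC:
        return math.log(tail_factor(mu, alpha))
    return math.log(4.0 * alpha * alpha) + mu - 2.0 * math.log(mu)
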