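"""Non-extensive (Tsallis) statistics primitives.

This module holds the mathematical core of the package: the
Boltzmann–Gibbs and Tsallis entropy functionals, and the two interval
probability models fitted elsewhere in the package —

* the *q-exponential* density ``a x^c (1 + (q-1) b x^h)^(-1/(q-1))``,
  whose entropic index ``q > 1`` quantifies non-extensivity (long-range
  correlation, i.e. "complexity") of the underlying dynamics, and
* its ``q -> 1`` limit, the stretched/weighted Boltzmann–Gibbs
  exponential ``a x^c exp(-b x^h)``, the null model for purely chaotic
  (uncorrelated) dynamics.

Both densities are supported on ``x >= 0`` and the normalization
constant ``a`` is always determined analytically (incomplete-beta /
gamma closed forms, see :func:`normalize_qexp` and
:func:`normalize_bg`), never fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "EntropyResult",
    "QExpParams",
    "BGExpParams",
    "entropy_bg",
    "entropy_q",
    "qexp_pdf",
    "qexp_cdf",
    "qexp_ppf",
    "bg_pdf",
    "bg_cdf",
    "bg_ppf",
    "normalize_qexp",
    "normalize_bg",
    "q_upper_bound",
]


class ParameterError(ValueError):
    """Raised when distribution or entropy parameters are invalid."""


def _validate_probabilities(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ParameterError("probability vector must be 1-D with at least one state")
    if np.any(p < 0):
        raise ParameterError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"probabilities must sum to 1 (got {total!r})")
    return p


@dataclass(frozen=True)
class EntropyResult:
    """Value of an entropy functional.

    Attributes
    ----------
    value : float
        Entropy in units of ``k``.
    k : float
        Scale constant (Boltzmann constant analogue; default 1).
    q : float
        Entropic index used; ``q = 1`` denotes the Boltzmann–Gibbs
        functional.
    """

    value: float
    k: float = 1.0
    q: float = 1.0


def entropy_bg(p, k: float = 1.0) -> EntropyResult:
    """Boltzmann–Gibbs entropy ``S = -k sum p_i ln p_i``.

    Zero probabilities contribute nothing (the ``0 ln 0 -> 0`` limit
    convention).  For an equiprobable vector over ``W`` states the value
    is ``k ln W``.
    """
    p = _validate_probabilities(p)
    nz = p[p > 0]
    return EntropyResult(value=float(-k * np.sum(nz * np.log(nz))), k=k, q=1.0)


def entropy_q(p, q: float, k: float = 1.0) -> EntropyResult:
    """Tsallis entropy ``S_q = k/(q-1) (1 - sum p_i^q)``.

    ``q = 1`` is routed to :func:`entropy_bg` (the analytic limit), so a
    division by zero can never occur.  ``0^q`` contributes 0.
    """
    if q == 1.0:
        return entropy_bg(p, k=k)
    p = _validate_probabilities(p)
    nz = p[p > 0]
    value = k / (q - 1.0) * (1.0 - float(np.sum(nz**q)))
    return EntropyResult(value=value, k=k, q=q)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


def q_upper_bound(c: float, h: float) -> float:
    """Largest entropic index for which the q-exponential is normalizable.

    Normalizability on ``[0, inf)`` requires ``1/(q-1) > (c+1)/h``,
    i.e. ``q < 1 + h/(c+1)``.
    """
    return 1.0 + h / (c + 1.0)


def _check_shape(b: float, c: float, h: float) -> None:
    if not b > 0:
        raise ParameterError(f"scale b must be > 0 (got {b})")
    if not h > 0:
        raise ParameterError(f"stretching exponent h must be > 0 (got {h})")
    if not c > -1:
        raise ParameterError(f"power-law exponent c must be > -1 (got {c})")


@dataclass(frozen=True)
class QExpParams:
    """Parameters of the q-exponential interval density.

    ``a`` is derived analytically from ``(b, c, h, q)`` on construction
    and is never an independent degree of freedom.
    """

    b: float
    c: float
    h: float
    q: float
    a: float = field(init=False)

    def __post_init__(self):
        _check_shape(self.b, self.c, self.h)
        if not self.q > 1:
            raise ParameterError(f"entropic index q must be > 1 (got {self.q})")
        qmax = q_upper_bound(self.c, self.h)
        if not self.q < qmax:
            raise ParameterError(
                "normalizability violated: need 1/(q-1) > (c+1)/h, "
                f"i.e. q < {qmax:.6g} (got q = {self.q})"
            )
        object.__setattr__(self, "a", normalize_qexp(self.b, self.c, self.h, self.q))

    @property
    def alpha(self) -> float:
        """Incomplete-beta shape ``(c+1)/h``."""
        return (self.c + 1.0) / self.h

    @property
    def beta(self) -> float:
        """Incomplete-beta shape ``1/(q-1) - (c+1)/h``; > 0 by construction."""
        return 1.0 / (self.q - 1.0) - self.alpha


@dataclass(frozen=True)
class BGExpParams:
    """Parameters of the Boltzmann–Gibbs (stretched exponential) null model."""

    b: float
    c: float
    h: float
    a: float = field(init=False)

    def __post_init__(self):
        _check_shape(self.b, self.c, self.h)
        object.__setattr__(self, "a", normalize_bg(self.b, self.c, self.h))

    @property
    def alpha(self) -> float:
        return (self.c + 1.0) / self.h


# ---------------------------------------------------------------------------
# Normalization constants
# ---------------------------------------------------------------------------


def normalize_qexp(b: float, c: float, h: float, q: float) -> float:
    """Analytic normalization of the q-exponential density.

    With ``alpha = (c+1)/h`` and ``beta = 1/(q-1) - alpha``::

        a = h ((q-1) b)^alpha / B(alpha, beta)

    which makes ``a x^c (1 + (q-1) b x^h)^(-1/(q-1))`` integrate to 1 on
    ``[0, inf)`` (substitute ``y = (q-1) b x^h`` and reduce to a Beta
    integral).  Raises :class:`ParameterError` when the normalizability
    condition ``1/(q-1) > (c+1)/h`` fails.
    """
    _check_shape(b, c, h)
    if not q > 1:
        raise ParameterError(f"entropic index q must be > 1 (got {q})")
    alpha = (c + 1.0) / h
    beta = 1.0 / (q - 1.0) - alpha
    if beta <= 0:
        raise ParameterError(
            f"normalizability violated: 1/(q-1) = {1/(q-1):.6g} must exceed "
            f"(c+1)/h = {alpha:.6g}"
        )
    return h * ((q - 1.0) * b) ** alpha / special.beta(alpha, beta)


def normalize_bg(b: float, c: float, h: float) -> float:
    """Normalization ``a = h b^((c+1)/h) / Gamma((c+1)/h)`` of the BG model.

    This is the ``q -> 1`` limit of :func:`normalize_qexp`.
    """
    _check_shape(b, c, h)
    alpha = (c + 1.0) / h
    return h * b**alpha / special.gamma(alpha)


# ---------------------------------------------------------------------------
# Densities, distribution functions, quantiles
# ---------------------------------------------------------------------------


def _as_qexp(params) -> QExpParams:
    if isinstance(params, QExpParams):
        return params
    raise ParameterError("expected QExpParams")


def qexp_pdf(x, params: QExpParams):
    """q-exponential density ``a x^c (1 + (q-1) b x^h)^(-1/(q-1))`` on x >= 0.

    The decaying-tail convention (negative exponent) is used throughout:
    it is the only sign for which the expression is a probability
    density, and it reduces exactly to :func:`bg_pdf` as ``q -> 1``.
    """
    p = _as_qexp(params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("intervals must be >= 0")
    # exp(-log1p(.)/(q-1)) form stays accurate as q -> 1, where the
    # direct power (1 + eps*u)^(-1/eps) loses the exponential limit.
    y = (p.q - 1.0) * p.b * x**p.h
    with np.errstate(divide="ignore"):
        out = p.a * x**p.c * np.exp(-np.log1p(y) / (p.q - 1.0))
    return out if out.ndim else float(out)


def qexp_cdf(x, params: QExpParams):
    """Distribution function; regularized incomplete beta in closed form."""
    p = _as_qexp(params)
    x = np.asarray(x, dtype=float)
    y = (p.q - 1.0) * p.b * np.maximum(x, 0.0) ** p.h
    out = special.betainc(p.alpha, p.beta, y / (1.0 + y))
    return out if out.ndim else float(out)


def qexp_ppf(u, params: QExpParams):
    """Quantile function (exact inverse of :func:`qexp_cdf`)."""
    p = _as_qexp(params)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ParameterError("probabilities must lie in [0, 1]")
    z = special.betaincinv(p.alpha, p.beta, u)
    with np.errstate(divide="ignore"):  # u = 1 maps to +inf
        y = z / (1.0 - z)
    out = (y / ((p.q - 1.0) * p.b)) ** (1.0 / p.h)
    return out if out.ndim else float(out)


def bg_pdf(x, params: BGExpParams):
    """Boltzmann–Gibbs density ``a x^c exp(-b x^h)`` on x >= 0."""
    if not isinstance(params, BGExpParams):
        raise ParameterError("expected BGExpParams")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("intervals must be >= 0")
    out = params.a * x**params.c * np.exp(-params.b * x**params.h)
    return out if out.ndim else float(out)


def bg_cdf(x, params: BGExpParams):
    """Distribution function; regularized lower incomplete gamma."""
    if not isinstance(params, BGExpParams):
        raise ParameterError("expected BGExpParams")
    x = np.asarray(x, dtype=float)
    out = special.gammainc(params.alpha, params.b * np.maximum(x, 0.0) ** params.h)
    return out if out.ndim else float(out)


def bg_ppf(u, params: BGExpParams):
    """Quantile function of the BG model."""
    if not isinstance(params, BGExpParams):
        raise ParameterError("expected BGExpParams")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ParameterError("probabilities must lie in [0, 1]")
    out = (special.gammaincinv(params.alpha, u) / params.b) ** (1.0 / params.h)
    return out if out.ndim else float(out)
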