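"""Functional-response curves for prey-depletion feeding trials.

In a fixed-duration trial without prey replacement, the number of prey a
predator kills depends on the initial density ``N0``, the attack rate ``a``
(searching efficiency per unit trial time), the handling time ``h`` (trial-time
units spent per prey killed) and the trial duration ``T``.  The Type II
expectation is Rogers' random-predator equation, the implicit relation

    Ne = N0 * (1 - exp(a * (Ne * h - T)))

whose explicit solution uses the principal branch of the Lambert W function:

    Ne = N0 - W0(a * h * N0 * exp(-a * (T - h * N0))) / (a * h)

Two alternatives share the same depletion machinery: the linear (Type I)
response is the ``h -> 0`` limit ``N0 * (1 - exp(-a*T))``, and the sigmoid
(Type III) response replaces the constant attack rate by the density-dependent
form ``a(N) = b*N / (1 + c*N)``, so that attack efficiency collapses at low
prey density (the low-density refuge).

All expectations are deterministic; stochastic trial outcomes live in
:mod:`frmodules.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw as _scipy_lambertw

__all__ = [
    "FRParams",
    "lambert_w0",
    "rogers_expected_eaten",
    "alt_response_expected",
    "expected_eaten",
]

#: branch point of the principal Lambert W branch
_BRANCH_POINT = -1.0 / np.e
#: tolerated numerical undershoot below the branch point (clamped, not an error)
_DOMAIN_TOL = 1e-12
#: below this product a*h the Rogers solution is evaluated in its h->0 limit
_AH_UNDERFLOW = 1e-12
#: largest exponent safe for np.exp in double precision
_EXP_MAX = 700.0


def _w0_real(z_clamped):
    """W0 for z already clamped to [-1/e, inf); handles the branch point.

    The library routine loses accuracy (returns NaN) within float rounding of
    the branch point, where the series w = -1 + p - p^2/3 + O(p^3) with
    p = sqrt(2 (e z + 1)) is exact enough.
    """
    z_arr = np.asarray(z_clamped, dtype=float)
    near = z_arr < _BRANCH_POINT + 1e-10
    w = np.empty_like(z_arr)
    if np.any(near):
        p = np.sqrt(np.maximum(2.0 * (np.e * z_arr[near] + 1.0), 0.0))
        w[near] = -1.0 + p - p**2 / 3.0
    if np.any(~near):
        w[~near] = np.real(_scipy_lambertw(z_arr[~near], k=0))
    return w


def lambert_w0(z):
    """Principal branch W0 of the Lambert W function on the real axis.

    Solves ``w * exp(w) = z`` for ``z >= -1/e``.  Values within ``1e-12``
    below the branch point are clamped to it; anything lower raises a
    ``ValueError``.  Accepts scalars or arrays.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < _BRANCH_POINT - _DOMAIN_TOL):
        bad = float(np.min(z_arr))
        raise ValueError(
            f"lambert_w0 is undefined for z={bad!r}: the principal branch "
            f"requires z >= -1/e ({_BRANCH_POINT!r})"
        )
    w = _w0_real(np.maximum(z_arr, _BRANCH_POINT))
    if np.ndim(z) == 0:
        return float(w)
    return w


def _lambert_w0_from_log(log_z):
    """W0(exp(log_z)) for large log_z, solving w + log(w) = log_z by Newton.

    Used where z itself would overflow double precision (log_z > ~700).
    For such z, W0(z) ~ log_z - log(log_z), an excellent starting point.
    """
    log_z = np.asarray(log_z, dtype=float)
    w = log_z - np.log(log_z)
    for _ in range(6):
        f = w + np.log(w) - log_z
        w = w - f / (1.0 + 1.0 / w)
    return w


def _rogers_core(a, h, n0, t):
    """Vectorised Rogers Type II expectation; inputs broadcast as float arrays.

    No argument validation: callers (public wrappers, the fit machinery) are
    responsible for sign checks.  Degenerate ``a*h`` falls back to the h=0
    closed form; huge Lambert arguments are handled in log space.
    """
    a, h, n0, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a, h, n0, t))
    )
    ah = a * h
    # h -> 0 (or a -> 0) closed form: N0 * (1 - exp(-a*T))
    closed = n0 * (-np.expm1(-a * t))
    degenerate = ah < _AH_UNDERFLOW

    out = np.where(degenerate, closed, 0.0)
    if not np.all(degenerate):
        mask = ~degenerate
        a_m, h_m, n0_m, t_m = a[mask], h[mask], n0[mask], t[mask]
        ah_m = ah[mask]
        with np.errstate(divide="ignore"):
            log_z = np.log(ah_m * n0_m) - a_m * (t_m - h_m * n0_m)
        w = np.empty_like(log_z)
        big = log_z > _EXP_MAX
        if np.any(big):
            w[big] = _lambert_w0_from_log(log_z[big])
        small = ~big
        if np.any(small):
            z = np.exp(log_z[small])
            w[small] = _w0_real(np.maximum(z, _BRANCH_POINT))
        ne = n0_m - w / ah_m
        out[mask] = ne
    # numerical safety: the exact solution lies in [0, N0]
    return np.clip(out, 0.0, n0)


def _check_args(a, h, n0, t):
    if a < 0:
        raise ValueError(f"attack rate must be >= 0, got a={a}")
    if h < 0:
        raise ValueError(f"handling time must be >= 0, got h={h}")
    if n0 < 0:
        raise ValueError(f"initial prey density must be >= 0, got N0={n0}")
    if not t > 0:
        raise ValueError(f"trial duration must be > 0, got T={t}")


def rogers_expected_eaten(a, h, n0, t=1.0):
    """Expected prey killed under the Type II random-predator equation.

    Parameters
    ----------
    a : float
        Attack rate, per unit trial duration (>= 0).
    h : float
        Handling time, trial-duration units per prey (>= 0).
    n0 : float
        Initial prey density (>= 0).
    t : float
        Trial duration (> 0); defaults to 1 trial-duration unit.

    Returns
    -------
    float
        Expected kills ``Ne`` in ``[0, n0]`` satisfying the implicit
        depletion relation ``Ne = N0 (1 - exp(a (Ne h - T)))``.
    """
    _check_args(a, h, n0, t)
    if n0 == 0 or a == 0:
        return 0.0
    return float(_rogers_core(a, h, n0, t))


@dataclass
class FRParams:
    """Parameters of one functional-response curve.

    ``a``/``h`` parameterise the Type I and II variants; ``b``/``c`` give the
    Type III density-dependent attack rate ``a(N) = b*N / (1 + c*N)`` (with
    ``c = 0`` this is the two-parameter Hassell form).  ``t`` is the trial
    duration; a 40-h trial is mapped to ``t = 1`` by convention, so ``a`` and
    ``h`` are expressed per trial.
    """

    a: float = 0.0
    h: float = 0.0
    t: float = 1.0
    variant: str = "II"
    b: float = 0.0
    c: float = 0.0

    def __post_init__(self):
        if self.variant not in ("I", "II", "III"):
            raise ValueError(f"unknown response variant {self.variant!r}")
        if not self.t > 0:
            raise ValueError(f"trial duration must be > 0, got T={self.t}")


def alt_response_expected(params: FRParams, n0, t=None):
    """Expected kills under the Type I (linear) or Type III (sigmoid) variant.

    Type I is the depletion-consistent ``h = 0`` limit ``N0 (1 - exp(-a T))``
    (not Holling's rectilinear form), so that all variants share one binomial
    likelihood.  Type III substitutes ``a(N0) = b*N0 / (1 + c*N0)`` into the
    Rogers solution.
    """
    t = params.t if t is None else t
    if params.variant == "I":
        _check_args(params.a, 0.0, n0, t)
        return float(n0 * -np.expm1(-params.a * t))
    if params.variant == "III":
        if params.b < 0 or params.c < 0:
            raise ValueError(
                f"Type III coefficients must be >= 0, got b={params.b}, c={params.c}"
            )
        _check_args(0.0, params.h, n0, t)
        if n0 == 0 or params.b == 0:
            return 0.0
        a_eff = params.b * n0 / (1.0 + params.c * n0)
        return float(_rogers_core(a_eff, params.h, n0, t))
    raise ValueError(
        f"alt_response_expected handles variants I and III, got {params.variant!r}"
    )


def expected_eaten(params: FRParams, n0, t=None):
    """Dispatch to the Type I/II/III expectation for ``params.variant``."""
    t = params.t if t is None else t
    if params.variant == "II":
        _check_args(params.a, params.h, n0, t)
        if n0 == 0 or params.a == 0:
            return 0.0
        return float(_rogers_core(params.a, params.h, n0, t))
    return alt_response_expected(params, n0, t)
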