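"""Closed-form quantities of the active/inactive traveling-wave ODE system.

In the comoving variable ``z = x - c t`` a traveling wave ``(a(z), i(z))`` of
the growth model

.. math::

    A_t = A_{xx} + A - A(A+I), \\qquad I_t = A(A+I) + r A,

solves the first-order system

.. math::

    a' = b, \\qquad
    b' = a(a+i) - a - c b, \\qquad
    i' = -\\tfrac{1}{c}\\, a (a+i+r),

with wave speed ``c > 0`` and inactive-production rate ``r >= 0``.  Every point
``(0, 0, K)`` is a fixed point: the model has a continuum of steady states and
the Jacobian there is degenerate (one zero eigenvalue along the continuum).
This module collects the vector field, its Jacobian, the eigensystem at the
fixed points, and the algebraic identities that tie the limits and the turning
point of a wave orbit to its initial data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "PhaseState",
    "EigenSystem",
    "LimitPair",
    "vector_field",
    "jacobian",
    "fixed_point_eigensystem",
    "critical_density",
    "decay_rate",
    "unstable_direction",
    "limit_map",
    "alpha_threshold",
    "a_star",
    "turning_point_active",
]

#: absolute tolerance for algebraic comparisons ("= i_c", "= 0", degeneracy)
ALG_TOL = 1e-10


@dataclass(frozen=True)
class ModelParams:
    """Wave-frame parameters: speed ``c > 0`` and production rate ``r >= 0``."""

    c: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c) and np.isfinite(self.r)):
            raise ValueError("model parameters must be finite")
        if self.c <= 0:
            raise ValueError(f"wave speed must be positive, got c={self.c}")
        if self.r < 0:
            raise ValueError(f"production rate must be nonnegative, got r={self.r}")


@dataclass(frozen=True)
class PhaseState:
    """A point ``(a, b, i)`` in phase space, with ``b = a'``."""

    a: float
    b: float
    i: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.a, self.b, self.i)):
            raise ValueError("phase state components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.i], dtype=float)


@dataclass(frozen=True)
class EigenSystem:
    """Eigenvalues/eigenvectors of the Jacobian at a fixed point ``(0,0,K)``.

    ``lambda0 = 0`` always (direction along the continuum of fixed points);
    the nonzero pair is ``-c/2 +- sqrt(c^2/4 + K - 1)``.  When the discriminant
    ``c^2/4 + K - 1`` vanishes the pair degenerates to a single eigen-direction
    (``degenerate`` flag); when it is negative the pair is complex conjugate
    (``is_complex`` flag, real/imaginary parts stored separately).
    """

    lambda0: float
    lambda_plus: complex
    lambda_minus: complex
    discriminant: float
    vectors: np.ndarray  # rows e0, e+, e- (e- duplicated if degenerate)
    is_complex: bool
    degenerate: bool


@dataclass(frozen=True)
class LimitPair:
    """Limiting inactive densities ``i(-inf)`` and ``i(+inf)`` of a wave."""

    i_minus_inf: float
    i_plus_inf: float

    @property
    def total(self) -> float:
        return self.i_minus_inf + self.i_plus_inf


def _check_state(s) -> np.ndarray:
    arr = s.as_array() if isinstance(s, PhaseState) else np.asarray(s, dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise ValueError("state must be a finite 3-vector (a, b, i)")
    return arr


def vector_field(params: ModelParams, s) -> np.ndarray:
    """Right-hand side ``(a', b', i')`` of the wave ODE system."""
    a, b, i = _check_state(s)
    c, r = params.c, params.r
    return np.array([b, a * (a + i) - a - c * b, -(a * (a + i + r)) / c])


def jacobian(params: ModelParams, s) -> np.ndarray:
    """Jacobian of :func:`vector_field` at a state ``(a, b, i)``."""
    a, _, i = _check_state(s)
    c, r = params.c, params.r
    return np.array(
        [
            [0.0, 1.0, 0.0],
            [2 * a + i - 1, -c, a],
            [-(2 * a + i + r) / c, 0.0, -a / c],
        ]
    )


def critical_density(c: float) -> float:
    """Minimal admissible right-limit inactive density ``i_c = max{0, 1 - c^2/4}``.

    A wave converging to ``(0,0,i_{+inf})`` can only stay nonnegative if the
    linearization there does not spiral, i.e. ``c^2/4 + i_{+inf} - 1 >= 0``.
    """
    if not np.isfinite(c) or c <= 0:
        raise ValueError(f"wave speed must be positive, got c={c}")
    return max(0.0, 1.0 - c * c / 4.0)


def fixed_point_eigensystem(params: ModelParams, K: float) -> EigenSystem:
    """Eigensystem of the Jacobian at the fixed point ``(0, 0, K)``.

    Eigenvalues are ``0`` and ``-c/2 +- sqrt(c^2/4 + K - 1)``.  The zero
    eigenvector is ``(0, 0, 1)`` (the continuum direction).  For a simple
    nonzero eigenvalue ``lam`` the eigenvector solves the linear system at
    ``(0,0,K)``; for the unstable case it is returned exactly in the printed
    normalization of :func:`unstable_direction`.
    """
    if not np.isfinite(K):
        raise ValueError("K must be finite")
    c, r = params.c, params.r
    disc = c * c / 4.0 + K - 1.0
    e0 = np.array([0.0, 0.0, 1.0])
    degenerate = abs(disc) <= ALG_TOL
    is_complex = disc < -ALG_TOL

    if is_complex:
        root = complex(0.0, math.sqrt(-disc))
        lam_p = -c / 2.0 + root
        lam_m = -c / 2.0 - root
        # complex eigenvectors of the (a, b) block, lifted with the i-row
        vecs = np.zeros((3, 3), dtype=complex)
        vecs[0] = e0
        for row, lam in ((1, lam_p), (2, lam_m)):
            vecs[row] = _lifted_eigenvector(c, r, K, lam)
        return EigenSystem(0.0, lam_p, lam_m, disc, vecs, True, False)

    root = math.sqrt(max(disc, 0.0))
    lam_p = -c / 2.0 + root
    lam_m = -c / 2.0 - root
    vecs = np.zeros((3, 3))
    vecs[0] = e0
    if degenerate:
        # single eigen-direction for the repeated eigenvalue -c/2
        vecs[1] = vecs[2] = _lifted_eigenvector(c, r, K, -c / 2.0).real
        return EigenSystem(0.0, lam_p, lam_m, disc, vecs, False, True)
    if K > 1.0:
        # unstable case: keep the printed normalization e+ = (-lam_-, K-1, ...)
        vecs[1] = unstable_direction(params, K)
    else:
        vecs[1] = _lifted_eigenvector(c, r, K, lam_p).real
    vecs[2] = _lifted_eigenvector(c, r, K, lam_m).real
    return EigenSystem(0.0, lam_p, lam_m, disc, vecs, False, False)


def _lifted_eigenvector(c: float, r: float, K: float, lam) -> np.ndarray:
    """Eigenvector of the Jacobian at ``(0,0,K)`` for eigenvalue ``lam != 0``.

    The (a, b) block gives ``(1, lam)``; the i-row reads
    ``i' = -(K + r)/c * a`` so the i-component is ``-(K + r)/(c lam)``.
    At ``lam = 0`` (K = 1: lambda_+ merges with the continuum eigenvalue) the
    only eigen-direction is the continuum one ``(0, 0, 1)``.
    """
    if abs(lam) <= ALG_TOL:
        return np.array([0.0, 0.0, 1.0], dtype=complex)
    return np.array([1.0, lam, -(K + r) / (c * lam)], dtype=complex)


def decay_rate(params: ModelParams, i_limit: float):
    """Asymptotic rate ``mu = -c/2 + sqrt(c^2/4 + i_limit - 1)`` of Eq. (1.6).

    Returns ``(mu, flag)`` where flag is ``"exponential"``,
    ``"sub-exponential"`` (zero discriminant: decay of order ``z e^{-cz/2}``)
    or ``"spiraling"`` (negative discriminant: no admissible nonnegative wave;
    ``mu`` is then the complex value).
    """
    c = params.c
    disc = c * c / 4.0 + i_limit - 1.0
    if disc < -ALG_TOL:
        return complex(-c / 2.0, math.sqrt(-disc)), "spiraling"
    if abs(disc) <= ALG_TOL:
        return -c / 2.0, "sub-exponential"
    return -c / 2.0 + math.sqrt(disc), "exponential"


def unstable_direction(params: ModelParams, i_minus_inf: float) -> np.ndarray:
    """Unstable eigenvector ``e+`` at ``(0, 0, i_{-inf})`` for ``i_{-inf} > 1``.

    Printed normalization (kept for sign traceability):

    .. math::

        e_+ = \\bigl(-\\lambda_-, \\; i_{-\\infty} - 1, \\;
                \\tfrac{1}{c} (r + i_{-\\infty}) \\lambda_- / \\lambda_+\\bigr).

    Its a- and b-components are positive, its i-component negative: the wave
    leaves the unstable state gaining active mass while depleting the slack of
    inactive particles.
    """
    if i_minus_inf <= 1.0:
        raise ValueError("unstable manifold requires i_minus_inf > 1")
    c, r = params.c, params.r
    disc = c * c / 4.0 + i_minus_inf - 1.0  # > c^2/4 > 0 here
    root = math.sqrt(disc)
    lam_p = -c / 2.0 + root
    lam_m = -c / 2.0 - root
    return np.array(
        [-lam_m, i_minus_inf - 1.0, (r + i_minus_inf) * lam_m / (lam_p * c)]
    )


def unit_unstable_direction(params: ModelParams, i_minus_inf: float) -> np.ndarray:
    """Unit-normalized :func:`unstable_direction`, oriented with positive a."""
    e = unstable_direction(params, i_minus_inf)
    e = e / np.linalg.norm(e)
    return e if e[0] > 0 else -e


def limit_map(a0: float, i0: float, params: ModelParams) -> float:
    """Limit ``i(+inf)`` of the orbit started at ``(a0, 0, i0)``, Eq. (6.16).

    .. math::

        i_{+\\infty}(a_0, i_0) = 1 - \\sqrt{(i_0 + a_0 - 1)^2
            + \\tfrac{1+r}{c^2}\\,(a_0^2 + 2 c^2 a_0)}.

    Valid whenever the trajectory stays nonnegative and converges; decreasing
    in ``a0`` on ``[0, 1 - i0]`` with ``limit_map(0, i0) = i0``.
    """
    if a0 < 0:
        raise ValueError("a0 must be nonnegative")
    c, r = params.c, params.r
    rad = (i0 + a0 - 1.0) ** 2 + (1.0 + r) / c**2 * (a0**2 + 2.0 * c**2 * a0)
    return 1.0 - math.sqrt(rad)


def alpha_threshold(i0: float, params: ModelParams) -> float:
    """The ``a0`` with ``limit_map(a0, i0) = i_c``, Eq. (6.13).

    .. math::

        \\alpha(i_0) = \\frac{c^2}{1 + c^2 + r}\\Bigl\\{ -(i_0 + r)
            + \\sqrt{(i_0+r)^2 + \\tfrac{c^2+1+r}{c^2}
              \\bigl((1-i_c)^2 - (1-i_0)^2\\bigr)} \\Bigr\\}.
    """
    c, r = params.c, params.r
    ic = critical_density(c)
    if not (ic - ALG_TOL <= i0 < 1.0):
        raise ValueError(f"i0 must lie in [i_c, 1) = [{ic}, 1), got {i0}")
    q = (c * c + 1.0 + r) / (c * c)
    rad = (i0 + r) ** 2 + q * ((1.0 - ic) ** 2 - (1.0 - i0) ** 2)
    return c * c / (1.0 + c * c + r) * (-(i0 + r) + math.sqrt(max(rad, 0.0)))


def a_star(i0: float, params: ModelParams) -> float:
    """Sharp upper bound ``a*(i0) = min{alpha(i0), 1 - i0}`` for attractor starts."""
    return min(alpha_threshold(i0, params), 1.0 - i0)


def turning_point_active(
    i_z0: float, i_minus_inf: float, params: ModelParams
) -> float:
    """Active density at the turning point of a shooting orbit, Eq. (7.13).

    At the first phase-time ``z0`` with ``b(z0) = 0`` the orbit from
    ``(0,0,i_{-inf})`` satisfies

    .. math::

        a_{z_0} = \\frac{c^2}{c^2+1+r}\\Bigl\\{ -(i_{z_0} + r)
            + \\sqrt{(i_{z_0}+r)^2 + \\tfrac{c^2+1+r}{c^2}
              \\bigl((i_{-\\infty}-1)^2 - (1-i_{z_0})^2\\bigr)} \\Bigr\\}.

    Requires ``(i_{-inf}-1)^2 >= (1-i_{z0})^2`` (strict for a positive value).
    """
    c, r = params.c, params.r
    gap = (i_minus_inf - 1.0) ** 2 - (1.0 - i_z0) ** 2
    if gap < -ALG_TOL:
        raise ValueError(
            "inadmissible turning point: (i_minus_inf - 1)^2 < (1 - i_z0)^2"
        )
    q = (c * c + 1.0 + r) / (c * c)
    rad = (i_z0 + r) ** 2 + q * max(gap, 0.0)
    return c * c / (c * c + 1.0 + r) * (-(i_z0 + r) + math.sqrt(rad))
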