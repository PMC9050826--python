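"""Trapping triangle of the reduced (a, b) subsystem.

Freezing the inactive density at a constant value ``i`` reduces the wave
system to the planar flow

.. math::

    \\bar a' = \\bar b, \\qquad \\bar b' = \\bar a(\\bar a + i - 1) - c \\bar b,

with fixed points ``(0, 0)`` and ``(1 - i, 0)``.  For ``i in [i_c, 1)`` the
triangle ``T_c(i)`` — convex hull of the two fixed points and the apex where
the half-line below the stable eigenvector at the origin meets the half-line
below the unstable eigenvector at ``(1-i, 0)`` — is forward invariant, and the
family is nested: it grows as ``i`` decreases.  Within it ``a >= 0`` and
``b <= 0``, which is what pins the full wave orbit to nonnegative densities
once it has turned.  This module builds the triangle and certifies invariance
and nestedness numerically by boundary flux scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ALG_TOL, critical_density

__all__ = [
    "ReducedEigenData",
    "Triangle",
    "reduced_eigendata",
    "reduced_vector_field",
    "build_triangle",
    "contains",
    "invariance_scan",
    "nestedness_scan",
]


@dataclass(frozen=True)
class ReducedEigenData:
    """Eigenvalues/vectors of the planar flow at its two fixed points.

    At the origin: ``lambda_pm(i) = -c/2 +- sqrt(c^2/4 + i - 1)`` with
    eigenvectors ``l_pm = (lambda_mp, 1 - i)``; at ``(1-i, 0)``:
    ``beta_pm(i) = -c/2 +- sqrt(c^2/4 + 1 - i)`` with ``r_pm = (-beta_mp, 1-i)``.
    """

    lambda_plus: float
    lambda_minus: float
    l_plus: np.ndarray
    l_minus: np.ndarray
    beta_plus: float
    beta_minus: float
    r_plus: np.ndarray
    r_minus: np.ndarray
    degenerate: bool  # lambda_+ == lambda_- (i == i_c with i_c > 0, or c=2, i=0)


@dataclass(frozen=True)
class Triangle:
    """The trapping region ``T_c(i)``: vertices and internal angles."""

    c: float
    i: float
    p0: np.ndarray  # (0, 0)
    p1: np.ndarray  # (1 - i, 0)
    apex: np.ndarray  # C(i), below the a-axis
    gamma_l: float  # internal angle at p0, radians
    gamma_r: float  # internal angle at p1, radians
    degenerate: bool

    @property
    def vertices_ccw(self) -> np.ndarray:
        """Vertices in counterclockwise order (interior left of each edge)."""
        return np.array([self.p0, self.apex, self.p1])


def reduced_vector_field(c: float, i: float, p) -> np.ndarray:
    """Planar flow ``(b, a(a + i - 1) - c b)`` at ``p = (a, b)``."""
    if c <= 0:
        raise ValueError("c must be positive")
    a, b = np.asarray(p, dtype=float)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("state must be finite")
    return np.array([b, a * (a + i - 1.0) - c * b])


def reduced_eigendata(c: float, i: float) -> ReducedEigenData:
    disc_l = c * c / 4.0 + i - 1.0
    disc_r = c * c / 4.0 + 1.0 - i
    if disc_l < -ALG_TOL:
        raise ValueError("spiraling case (i < i_c): no real eigendata at origin")
    root_l = math.sqrt(max(disc_l, 0.0))
    root_r = math.sqrt(disc_r)
    lam_p, lam_m = -c / 2.0 + root_l, -c / 2.0 - root_l
    beta_p, beta_m = -c / 2.0 + root_r, -c / 2.0 - root_r
    one_mi = 1.0 - i
    return ReducedEigenData(
        lambda_plus=lam_p,
        lambda_minus=lam_m,
        l_plus=np.array([lam_m, one_mi]),
        l_minus=np.array([lam_p, one_mi]),
        beta_plus=beta_p,
        beta_minus=beta_m,
        r_plus=np.array([-beta_m, one_mi]),
        r_minus=np.array([-beta_p, one_mi]),
        degenerate=abs(disc_l) <= ALG_TOL,
    )


def build_triangle(c: float, i: float) -> Triangle:
    """Construct ``T_c(i)`` for ``i in [i_c, 1)``.

    The apex solves the 2x2 linear system ``-p l_+(i) = (1-i, 0) - q r_+(i)``
    with ``p, q >= 0``.  In the degenerate case (repeated eigenvalue at the
    origin) the left half-line direction is the single eigenvector and the
    triangle is flagged; invariance is then settled by continuity, not by the
    scan.
    """
    ic = critical_density(c)
    if not (ic - ALG_TOL <= i < 1.0):
        raise ValueError(f"i must lie in [i_c, 1) = [{ic}, 1), got {i}")
    eig = reduced_eigendata(c, i)
    p0 = np.zeros(2)
    p1 = np.array([1.0 - i, 0.0])
    # -p*l_plus = p1 - q*r_plus  =>  [l_plus, -r_plus] @ (-p, q)... solve directly:
    # apex = -p*l_plus; apex = p1 - q*r_plus
    A = np.column_stack([-eig.l_plus, eig.r_plus])
    pq = np.linalg.solve(A, p1)
    p_coef, q_coef = pq
    apex = -p_coef * eig.l_plus
    # internal angles from vertex geometry
    gamma_l = _angle_between(p1 - p0, apex - p0)
    gamma_r = _angle_between(p0 - p1, apex - p1)
    return Triangle(c, i, p0, p1, apex, gamma_l, gamma_r, eig.degenerate)


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(float(np.clip(cosang, -1.0, 1.0)))


def contains(t: Triangle, p, tol: float = 1e-12) -> bool:
    """Closed-hull membership test for a point in ``T_c(i)``.

    Uses signed areas against the counterclockwise vertex ordering; ``tol``
    is an absolute slack so shared vertices and edge points count as inside.
    """
    p = np.asarray(p, dtype=float)
    verts = t.vertices_ccw
    for k in range(3):
        v0, v1 = verts[k], verts[(k + 1) % 3]
        edge = v1 - v0
        cross = edge[0] * (p[1] - v0[1]) - edge[1] * (p[0] - v0[0])
        if cross < -tol:
            return False
    return True


def invariance_scan(c: float, i: float, n_samples: int = 200) -> dict:
    """Certify invariance of ``T_c(i)`` by sampling the boundary flux.

    Samples each edge uniformly (excluding a 1e-6 edge-length neighborhood of
    the two fixed-point vertices, where the flux legitimately vanishes) and
    reports the minimum inner product of the flow with the inward normal.
    A pass requires the minimum to be nonnegative.
    """
    tri = build_triangle(c, i)
    if tri.degenerate:
        return {"status": "degenerate", "min_flux": None, "pass": None}
    eps = 1e-6
    verts = tri.vertices_ccw  # p0, apex, p1
    fixed = {0, 2}  # indices of p0 and p1 in ccw order
    min_flux = np.inf
    argmin = None
    for k in range(3):
        v0, v1 = verts[k], verts[(k + 1) % 3]
        k1 = (k + 1) % 3
        lo = eps if k in fixed else 0.0
        hi = 1.0 - eps if k1 in fixed else 1.0
        ts = np.linspace(lo, hi, n_samples)
        edge = v1 - v0
        # ccw ordering: interior is to the left, inward normal = (-dy, dx)
        normal = np.array([-edge[1], edge[0]])
        normal = normal / np.linalg.norm(normal)
        for s in ts:
            pt = v0 + s * edge
            flux = reduced_vector_field(c, i, pt) @ normal
            if flux < min_flux:
                min_flux = flux
                argmin = pt
    return {
        "status": "ok",
        "min_flux": float(min_flux),
        "argmin": argmin,
        "pass": bool(min_flux >= -ALG_TOL),
    }


def nestedness_scan(c: float, i1: float, i2: float) -> bool:
    """Check ``T_c(i2) \\subseteq T_c(i1)`` vertexwise for ``i1 <= i2``.

    The triangles shrink as ``i`` grows; because both are triangles with two
    vertices on the a-axis and convex, vertex containment implies set
    containment.  Also asserts containment in the outermost region
    ``T_c(i_c)`` whenever that one is nondegenerate.
    """
    if not (i1 <= i2 + ALG_TOL):
        raise ValueError("require i1 <= i2")
    outer = build_triangle(c, i1)
    inner = build_triangle(c, i2)
    tol = 1e-9
    ok = all(contains(outer, v, tol=tol) for v in inner.vertices_ccw)
    ic = critical_density(c)
    outermost = build_triangle(c, ic)
    if not outermost.degenerate:
        ok = ok and all(contains(outermost, v, tol=tol) for v in inner.vertices_ccw)
    return ok
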