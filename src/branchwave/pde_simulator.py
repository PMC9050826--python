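"""Method-of-lines solver for the active/inactive growth PDE.

.. math::

    A_t = A_{xx} + A - A(A+I), \\qquad I_t = A(A+I) + r A.

Active particles diffuse, branch at rate 1 and become inactive on collision;
inactive particles neither move nor decay (``I_t >= 0`` pointwise).  Starting
from a compact heap of active particles on a zero-inactive background the
system self-organizes into a pulled front: a pulse of ``A`` invading at the
linear-spreading speed, leaving a plateau of inactive particles behind.

Spatial discretization is a second-order central stencil for ``A_xx`` with
no-flux (reflecting) boundaries; ``I`` carries no spatial operator.  Time
stepping is classical RK4 at the diffusive stability cap ``dt = 0.4 dx^2``.
Front tracking interpolates the rightmost level crossing of ``A`` and fits
the slow pulled-front approach of the speed with a ``c - k/t`` correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams
from .wave_constructor import WaveOrbit

__all__ = [
    "Grid1D",
    "PDERun",
    "initial_condition_gaussian",
    "run_simulation",
    "track_front",
    "plateau_density",
    "comoving_profile_compare",
]


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid on ``[x_min, x_max]`` with ``n`` nodes."""

    x_min: float
    x_max: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 nodes")
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n)


@dataclass
class PDERun:
    """Space-time output: sampled fields plus front-tracking summaries."""

    grid: Grid1D
    times: np.ndarray
    A: np.ndarray  # shape (n_times, n_nodes)
    I: np.ndarray
    params: ModelParams
    front_positions: np.ndarray | None = None
    speed_estimate: float | None = None
    plateau_estimate: float | None = None


def initial_condition_gaussian(
    grid: Grid1D, amplitude: float = 0.5, width: float = 1.0, center: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian heap ``A(x, 0) = amplitude * exp(-((x-center)/width)^2)``, ``I = 0``.

    The reference case is ``amplitude = 1/2, width = 1, center = 0``, i.e.
    ``A(x,0) = exp(-x^2)/2`` on a zero-inactive background.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    x = grid.x
    A = amplitude * np.exp(-(((x - center) / width) ** 2))
    return A, np.zeros_like(A)


def _rhs(A: np.ndarray, I: np.ndarray, r: float, inv_dx2: float):
    """Reaction + diffusion right-hand side with reflecting boundaries."""
    lap = np.empty_like(A)
    lap[1:-1] = A[:-2] - 2.0 * A[1:-1] + A[2:]
    # no-flux: ghost node mirrors the first interior node
    lap[0] = 2.0 * (A[1] - A[0])
    lap[-1] = 2.0 * (A[-2] - A[-1])
    collision = A * (A + I)
    dA = lap * inv_dx2 + A - collision
    dI = collision + r * A
    return dA, dI


def run_simulation(
    fields: tuple[np.ndarray, np.ndarray],
    params: ModelParams,
    grid: Grid1D,
    t_end: float,
    n_outputs: int = 76,
    dt_factor: float = 0.4,
) -> PDERun:
    """Advance the fields to ``t_end`` with fixed-step RK4, storing snapshots.

    The step is ``dt = dt_factor * dx^2`` (diffusive stability cap), rounded
    so output times are hit exactly.  Raises on instability (max |A| > 10);
    negative values are never clipped, so a scheme error surfaces as a
    negativity failure in the stored fields rather than being masked.
    """
    A, I = (np.array(f, dtype=float, copy=True) for f in fields)
    if A.shape != (grid.n,) or I.shape != (grid.n,):
        raise ValueError("fields must match the grid")
    r = params.r
    inv_dx2 = 1.0 / grid.dx**2
    out_times = np.linspace(0.0, t_end, n_outputs)
    dt_cap = dt_factor * grid.dx**2
    As = [A.copy()]
    Is = [I.copy()]
    t = 0.0
    for t_next in out_times[1:]:
        n_steps = max(1, int(math.ceil((t_next - t) / dt_cap)))
        dt = (t_next - t) / n_steps
        for _ in range(n_steps):
            k1A, k1I = _rhs(A, I, r, inv_dx2)
            k2A, k2I = _rhs(A + 0.5 * dt * k1A, I + 0.5 * dt * k1I, r, inv_dx2)
            k3A, k3I = _rhs(A + 0.5 * dt * k2A, I + 0.5 * dt * k2I, r, inv_dx2)
            k4A, k4I = _rhs(A + dt * k3A, I + dt * k3I, r, inv_dx2)
            A = A + dt / 6.0 * (k1A + 2.0 * k2A + 2.0 * k3A + k4A)
            I = I + dt / 6.0 * (k1I + 2.0 * k2I + 2.0 * k3I + k4I)
        t = t_next
        if np.max(np.abs(A)) > 10.0 or not np.all(np.isfinite(A)):
            raise RuntimeError(f"instability detected at t={t:.3f}: max|A| > 10")
        As.append(A.copy())
        Is.append(I.copy())
    return PDERun(
        grid=grid, times=out_times, A=np.array(As), I=np.array(Is), params=params
    )


def track_front(
    run: PDERun, level: float = 0.01, fit_bramson: bool = True
) -> tuple[np.ndarray, float | None]:
    """Rightmost level crossings of ``A`` per output time, and the speed.

    The crossing is linearly interpolated between grid nodes.  The asymptotic
    speed comes from least squares over the last half of the time window; a
    pulled front approaches its speed only like ``c - k/t``, so the default
    fit is ``x_f(t) = x0 + c t - k ln t``, whose slope ``c`` is the
    extrapolated asymptotic speed.  Stores results on the run and returns
    ``(front_positions, speed_estimate)``.
    """
    x = run.grid.x
    fronts = np.full(len(run.times), np.nan)
    for j, A in enumerate(run.A):
        above = np.flatnonzero(A >= level)
        if above.size == 0:
            continue
        k = above[-1]
        if k == len(x) - 1:
            fronts[j] = x[-1]  # front at the boundary: truncated value
            continue
        # interpolate between node k (>= level) and k+1 (< level)
        A0, A1 = A[k], A[k + 1]
        frac = (A0 - level) / (A0 - A1) if A0 != A1 else 0.0
        fronts[j] = x[k] + frac * run.grid.dx
    run.front_positions = fronts
    valid = np.isfinite(fronts) & (run.times > 0)
    if int(valid.sum()) < 4:
        run.speed_estimate = None
        return fronts, None
    t_v, f_v = run.times[valid], fronts[valid]
    half = t_v >= 0.5 * t_v[-1]
    t_fit, f_fit = t_v[half], f_v[half]
    if fit_bramson:
        M = np.column_stack([t_fit, np.log(t_fit), np.ones_like(t_fit)])
    else:
        M = np.column_stack([t_fit, np.ones_like(t_fit)])
    coef, *_ = np.linalg.lstsq(M, f_fit, rcond=None)
    run.speed_estimate = float(coef[0])
    return fronts, run.speed_estimate


def plateau_density(run: PDERun, margin: float = 30.0) -> float:
    """Limiting inactive density behind the front at the final time.

    Averages the final ``I`` over ``[front - 2*margin, front - margin]``
    restricted to nodes where ``A < 1e-6`` (the front has fully passed).
    Raises if the window is empty (front not yet separated).
    """
    if run.front_positions is None:
        track_front(run)
    front = run.front_positions[-1]
    if not np.isfinite(front) or front < 2.0 * margin + run.grid.x_min:
        raise RuntimeError("not-yet-separated: front too close to the origin")
    x = run.grid.x
    mask = (x >= front - 2.0 * margin) & (x <= front - margin) & (run.A[-1] < 1e-6)
    if not mask.any():
        raise RuntimeError("not-yet-separated: no active-free window behind front")
    est = float(run.I[-1][mask].mean())
    run.plateau_estimate = est
    return est


def comoving_profile_compare(run: PDERun, orbit: WaveOrbit) -> dict:
    """Sup-norm discrepancy between the late-time PDE front and a wave orbit.

    Aligns the profiles so the maxima of ``A`` and of the orbit's ``a``
    coincide, then reports sup-norm differences of both components over a
    window around the front.  Parameters of run and orbit must match.
    """
    if (run.params.c, run.params.r) != (orbit.params.c, orbit.params.r):
        raise ValueError("run and orbit parameters must match")
    x = run.grid.x
    A, I = run.A[-1], run.I[-1]
    jmax = int(np.argmax(A))
    zmax = orbit.z[int(np.argmax(orbit.a))]
    # window: orbit span mapped around the PDE front
    z_rel = orbit.z - zmax
    lo = max(x[0] - x[jmax], z_rel[0])
    hi = min(x[-1] - x[jmax], z_rel[-1])
    sel = (z_rel >= lo) & (z_rel <= hi)
    xs = x[jmax] + z_rel[sel]
    A_interp = np.interp(xs, x, A)
    I_interp = np.interp(xs, x, I)
    return {
        "sup_A": float(np.max(np.abs(A_interp - orbit.a[sel]))),
        "sup_I": float(np.max(np.abs(I_interp - orbit.i[sel]))),
        "window": (float(lo), float(hi)),
    }
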