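"""Construction of traveling-wave orbits by unstable-manifold shooting.

A heteroclinic wave orbit with left limit ``i_{-inf} in (1, 2 - i_c]`` is the
unique trajectory leaving ``(0, 0, i_{-inf})`` along the unstable eigenvector
with positive active density.  We realize it by offsetting the initial state a
distance ``epsilon`` along that eigenvector, integrating the wave ODE system
with a high-order adaptive scheme, detecting the turning point (first downward
zero of ``b = a'``, the unique maximum of the active pulse) by event
root-finding, and declaring convergence once ``max(|a|, |b|)`` drops below a
threshold.  The measured right limit is refined through the closed-form limit
map applied at the final small-amplitude state, which removes the
finite-truncation bias.

The same integrator drives attractor orbits started at ``(a0, 0, i0)`` with
``a0 <= a*(i0)``, and the module evaluates every orbit diagnostic: the
integral (mass-transfer) identities, shape (monotone ``i``, single maximum of
``a``), exponential tail rates, and consistency of the turning point with its
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import model_core as mc
from .model_core import ModelParams, PhaseState

__all__ = [
    "ShootingConfig",
    "WaveOrbit",
    "init_on_unstable_manifold",
    "integrate_orbit",
    "shoot_wave",
    "attractor_orbit",
    "integral_identities",
    "verify_shape",
    "tail_rate_fit",
    "turning_point_consistency",
]

#: state-norm cap beyond which an orbit is declared diverged
BLOWUP_CAP = 1e3


@dataclass(frozen=True)
class ShootingConfig:
    """Numerical knobs for orbit integration.

    epsilon
        Offset along the unit unstable eigenvector; the linearization error of
        the manifold is O(epsilon^2).
    rel_tol, abs_tol
        Integrator tolerances (DOP853).
    z_max
        Phase-time horizon; reaching it without converging flags the orbit.
    conv_tol
        Convergence threshold on max(|a|, |b|).
    n_output
        Number of uniformly spaced samples drawn from the dense output.
    tail_fit_window
        Fraction of the span used for exponential tail-rate fitting.
    """

    epsilon: float = 1e-7
    rel_tol: float = 1e-10
    abs_tol: float = 1e-12
    z_max: float = 150.0
    conv_tol: float = 1e-10
    n_output: int = 4000
    tail_fit_window: float = 0.15

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.conv_tol <= 0 or not np.isfinite(self.z_max):
            raise ValueError("epsilon, conv_tol must be positive and z_max finite")


#: relaxed settings for the critical wave (i_plus_inf = i_c with zero
#: discriminant), whose tail decays only like z * exp(-c z / 2)
CRITICAL_CONFIG = ShootingConfig(conv_tol=1e-8, z_max=400.0, n_output=8000)


@dataclass
class WaveOrbit:
    """A sampled orbit ``(z, a, b, i)`` with limits and diagnostics."""

    z: np.ndarray
    a: np.ndarray
    b: np.ndarray
    i: np.ndarray
    params: ModelParams
    i_minus_inf: float  # prescribed left limit (or i0 for attractor orbits)
    i_plus_inf_observed: float
    z0: float | None  # phase-time of first downward b = 0 crossing
    a_z0: float | None
    i_z0: float | None
    converged: bool
    nonneg: bool
    status: str = "ok"

    def state_at_end(self) -> np.ndarray:
        return np.array([self.a[-1], self.b[-1], self.i[-1]])


def init_on_unstable_manifold(
    params: ModelParams, i_minus_inf: float, cfg: ShootingConfig = ShootingConfig()
) -> PhaseState:
    """Start state ``(0, 0, i_{-inf}) + epsilon * e_hat_+`` on the manifold.

    Admissible left limits are ``i_{-inf} in (1, 2 - i_c]``; beyond that range
    the mirrored right limit would fall below the critical density and the
    orbit spirals negative.
    """
    ic = mc.critical_density(params.c)
    if not (1.0 < i_minus_inf <= 2.0 - ic + mc.ALG_TOL):
        raise ValueError(
            f"i_minus_inf must lie in (1, 2 - i_c] = (1, {2.0 - ic}], got {i_minus_inf}"
        )
    e_hat = mc.unit_unstable_direction(params, i_minus_inf)
    s = np.array([0.0, 0.0, i_minus_inf]) + cfg.epsilon * e_hat
    return PhaseState(*s)


def _integrate(
    s0: np.ndarray, params: ModelParams, cfg: ShootingConfig, detect_turning: bool
) -> tuple:
    """Run the adaptive integrator with convergence/turning/blow-up events."""

    def rhs(_z, y):
        a, b, i = y
        c, r = params.c, params.r
        return (b, a * (a + i) - a - c * b, -(a * (a + i + r)) / c)

    def ev_converged(_z, y):
        return max(abs(y[0]), abs(y[1])) - cfg.conv_tol

    ev_converged.terminal = True
    ev_converged.direction = -1

    def ev_turning(_z, y):
        return y[1]

    ev_turning.terminal = False
    ev_turning.direction = -1  # first downward crossing of b = 0 only

    def ev_blowup(_z, y):
        return BLOWUP_CAP - max(abs(y[0]), abs(y[1]), abs(y[2]))

    ev_blowup.terminal = True
    ev_blowup.direction = -1

    events = [ev_converged, ev_blowup] + ([ev_turning] if detect_turning else [])
    sol = solve_ivp(
        rhs,
        (0.0, cfg.z_max),
        s0,
        method="DOP853",
        rtol=cfg.rel_tol,
        atol=cfg.abs_tol,
        events=events,
        dense_output=True,
    )
    return sol


def integrate_orbit(
    s0: PhaseState,
    params: ModelParams,
    cfg: ShootingConfig = ShootingConfig(),
    i_minus_inf: float | None = None,
) -> WaveOrbit:
    """Integrate from ``s0`` until convergence, blow-up, or the horizon.

    The first downward ``b = 0`` crossing is recorded as the turning point
    ``(z0, a_z0, i_z0)``.  On convergence the right limit is refined by one
    application of the closed-form limit map at the final state (valid because
    ``|b|`` is below the convergence threshold there); otherwise the raw final
    ``i`` is reported.
    """
    y0 = s0.as_array() if isinstance(s0, PhaseState) else np.asarray(s0, float)
    sol = _integrate(y0, params, cfg, detect_turning=True)

    z_end = sol.t[-1]
    zs = np.linspace(sol.t[0], z_end, cfg.n_output)
    samples = sol.sol(zs)
    a, b, i = samples

    converged = len(sol.t_events[0]) > 0
    blown_up = len(sol.t_events[1]) > 0
    status = "converged" if converged else ("diverged" if blown_up else "horizon")

    z0 = a_z0 = i_z0 = None
    if len(sol.t_events[2]) > 0:
        z0 = float(sol.t_events[2][0])
        a_z0, _, i_z0 = (float(v) for v in sol.y_events[2][0])

    nonneg = bool(a.min() >= -10.0 * cfg.abs_tol and i.min() >= -10.0 * cfg.abs_tol)

    if converged:
        a_end, b_end, i_end = samples[:, -1]
        if abs(b_end) < 10.0 * cfg.conv_tol and a_end >= 0.0:
            i_plus = mc.limit_map(float(a_end), float(i_end), params)
        else:
            i_plus = float(i_end)
    else:
        i_plus = float(i[-1])

    return WaveOrbit(
        z=zs,
        a=a,
        b=b,
        i=i,
        params=params,
        i_minus_inf=float(i_minus_inf) if i_minus_inf is not None else float(y0[2]),
        i_plus_inf_observed=i_plus,
        z0=z0,
        a_z0=a_z0,
        i_z0=i_z0,
        converged=converged,
        nonneg=nonneg,
        status=status,
    )


def shoot_wave(
    params: ModelParams, i_minus_inf: float, cfg: ShootingConfig | None = None
) -> WaveOrbit:
    """Construct the heteroclinic wave orbit with prescribed left limit.

    Chooses the relaxed critical configuration automatically when the mirrored
    right limit sits exactly at the critical density with zero discriminant
    (sub-exponential tail).
    """
    if cfg is None:
        i_plus_expected = 2.0 - i_minus_inf
        disc = params.c**2 / 4.0 + i_plus_expected - 1.0
        cfg = CRITICAL_CONFIG if abs(disc) <= 1e-8 else ShootingConfig()
        # scale the horizon with the analytic rates: escape from the unstable
        # state at lambda_+ and decay into the stable one at |mu_{+inf}|
        lam_p = -params.c / 2.0 + math.sqrt(params.c**2 / 4.0 + i_minus_inf - 1.0)
        z_escape = (math.log(1.0 / cfg.epsilon) + 5.0) / lam_p
        if disc > 1e-8:
            mu = -params.c / 2.0 + math.sqrt(disc)
            z_decay = (math.log(1.0 / cfg.conv_tol) + 5.0) / abs(mu)
        else:
            z_decay = 2.0 / params.c * (math.log(1.0 / cfg.conv_tol) + 10.0)
        z_need = 1.5 * (z_escape + z_decay)
        if z_need > cfg.z_max:
            cfg = ShootingConfig(
                epsilon=cfg.epsilon,
                rel_tol=cfg.rel_tol,
                abs_tol=cfg.abs_tol,
                z_max=z_need,
                conv_tol=cfg.conv_tol,
                n_output=cfg.n_output,
                tail_fit_window=cfg.tail_fit_window,
            )
    s0 = init_on_unstable_manifold(params, i_minus_inf, cfg)
    return integrate_orbit(s0, params, cfg, i_minus_inf=i_minus_inf)


def attractor_orbit(
    a0: float,
    i0: float,
    params: ModelParams,
    cfg: ShootingConfig = ShootingConfig(),
) -> WaveOrbit:
    """Orbit from ``(a0, 0, i0)``; flagged when outside the proven attractor.

    For ``i0 in [i_c, 1)`` and ``a0 in [0, a*(i0)]`` the orbit keeps ``i``
    non-increasing and ``b <= 0`` and converges to ``(0, 0, limit_map(a0, i0))``.
    Out-of-attractor starts are integrated anyway for boundary exploration.
    """
    ic = mc.critical_density(params.c)
    in_attractor = False
    if ic - mc.ALG_TOL <= i0 < 1.0:
        in_attractor = 0.0 <= a0 <= mc.a_star(i0, params) + mc.ALG_TOL
    if a0 == 0.0:
        # fixed point: constant orbit
        zs = np.linspace(0.0, 1.0, 11)
        return WaveOrbit(
            z=zs,
            a=np.zeros_like(zs),
            b=np.zeros_like(zs),
            i=np.full_like(zs, i0),
            params=params,
            i_minus_inf=i0,
            i_plus_inf_observed=i0,
            z0=None,
            a_z0=None,
            i_z0=None,
            converged=True,
            nonneg=True,
            status="constant",
        )
    if in_attractor:
        # widen the horizon when the predicted limit decays slowly
        i_limit = mc.limit_map(a0, i0, params)
        disc = params.c**2 / 4.0 + i_limit - 1.0
        if disc > 1e-8:
            mu = -params.c / 2.0 + math.sqrt(disc)
            z_need = 2.0 * (math.log(1.0 / cfg.conv_tol) + 5.0) / abs(mu)
        else:
            z_need = 3.0 / params.c * (math.log(1.0 / cfg.conv_tol) + 10.0)
        if z_need > cfg.z_max:
            cfg = ShootingConfig(
                epsilon=cfg.epsilon,
                rel_tol=cfg.rel_tol,
                abs_tol=cfg.abs_tol,
                z_max=z_need,
                conv_tol=cfg.conv_tol,
                n_output=cfg.n_output,
                tail_fit_window=cfg.tail_fit_window,
            )
    orbit = integrate_orbit(PhaseState(a0, 0.0, i0), params, cfg, i_minus_inf=i0)
    if not in_attractor:
        orbit.status = orbit.status + ";out-of-attractor"
    return orbit


def integral_identities(
    orbit: WaveOrbit, z1: float | None = None, z2: float | None = None
) -> np.ndarray:
    """Residuals of the three mass-transfer identities between two turning points.

    For any span ``[z1, z2]`` of the orbit with ``b(z1) = b(z2) = 0`` (up to
    tolerance), with ``A(t) = int_{z1}^t a dz`` computed by quadrature on the
    samples:

    1. ``int a (a + i) dz  =  A(z2) + c [a(z2) - a(z1)]``
    2. ``i(z1) - i(z2)     =  (1+r)/c * A(z2) + a(z2) - a(z1)``
    3. ``int a (a + i) dz  =  [i(z2) + a(z2)] A(z2) + (1+r)/(2c) A(z2)^2
       + [a(z1)^2 - a(z2)^2]/(2c)``

    The ``a(z2) - a(z1)`` term in the second identity drops out whenever the
    active density vanishes at both endpoints (e.g. over the full line, which
    yields the limit correspondence ``i(-inf) + i(+inf) = 2``), but it is
    required on partial spans such as tail-to-turning-point.

    Returns the triple of absolute residuals.
    """
    z, a, b, i = orbit.z, orbit.a, orbit.b, orbit.i
    if z1 is None:
        z1 = z[0]
    if z2 is None:
        z2 = z[-1]
    if z2 > z1:
        m = max(int(np.sum((z >= z1) & (z <= z2))), 100)
        zz = np.linspace(z1, z2, m)
        aa = np.interp(zz, z, a)
        bb = np.interp(zz, z, b)
        ii = np.interp(zz, z, i)
    else:
        zz, aa, bb, ii = z[:1], a[:1], b[:1], i[:1]
    if abs(bb[0]) > 1e-4 or abs(bb[-1]) > 1e-4:
        raise ValueError("integral identities require b = 0 at both endpoints")
    c, r = orbit.params.c, orbit.params.r
    A2 = float(np.trapezoid(aa, zz))
    lhs = float(np.trapezoid(aa * (aa + ii), zz))
    a1, a2 = float(aa[0]), float(aa[-1])
    i1, i2 = float(ii[0]), float(ii[-1])
    res1 = abs(lhs - (A2 + c * (a2 - a1)))
    res2 = abs((i1 - i2) - ((1.0 + r) / c * A2 + a2 - a1))
    res3 = abs(
        lhs - ((i2 + a2) * A2 + (1.0 + r) / (2.0 * c) * A2**2 + (a1**2 - a2**2) / (2.0 * c))
    )
    return np.array([res1, res2, res3])


def verify_shape(orbit: WaveOrbit, tol: float = 1e-9) -> dict:
    """Monotonicity of ``i`` and uniqueness of the maximum of ``a``.

    Interior local maxima of ``a`` are counted on the samples; for a wave
    orbit there is exactly one (at the turning point, since ``a' = b``), for a
    constant orbit none.  Monotonicity violations of ``i`` beyond ``tol`` are
    counted pairwise.
    """
    a, i = orbit.a, orbit.i
    di = np.diff(i)
    mono_violations = int(np.sum(di > tol))
    interior = (a[1:-1] > a[:-2] + tol) & (a[1:-1] >= a[2:] - tol)
    # collapse plateaus: count runs of flagged samples as single maxima
    flags = np.flatnonzero(interior)
    n_max = 0 if flags.size == 0 else int(1 + np.sum(np.diff(flags) > 1))
    ok = (
        mono_violations == 0
        and n_max <= 1
        and float(a.min()) >= -tol
        and float(i.min()) >= -tol
    )
    return {
        "monotonicity_violations": mono_violations,
        "n_local_maxima": n_max,
        "min_a": float(a.min()),
        "min_i": float(i.min()),
        "pass": bool(ok),
    }


def tail_rate_fit(orbit: WaveOrbit, side: str = "right") -> dict:
    """Fit the exponential rate of the active-density tail.

    Right side: linear fit of ``log a`` against ``z`` over the trailing
    window, compared against ``mu_{+inf} = -c/2 + sqrt(c^2/4 + i_{+inf} - 1)``.
    In the critical (zero-discriminant) case the decay is ``z e^{-cz/2}`` and
    the corrected fit of ``log(a/z)`` is compared against ``-c/2``.
    Left side: fit over the leading window, compared against the growth rate
    ``mu_{-inf} = -c/2 + sqrt(c^2/4 + i_{-inf} - 1) > 0``.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    z, a = orbit.z, orbit.a
    n = len(z)
    win = max(int(round(n * 0.15)), 30)
    if side == "right":
        zz, aa = z[-win:], a[-win:]
        i_limit = orbit.i_plus_inf_observed
    else:
        zz, aa = z[:win], a[:win]
        i_limit = orbit.i_minus_inf
    pos = aa > 0
    if int(pos.sum()) < 30:
        return {"status": "insufficient-data"}
    zz, aa = zz[pos], aa[pos]
    mu, kind = mc.decay_rate(orbit.params, i_limit)
    sub_exponential = side == "right" and kind == "sub-exponential"
    if sub_exponential:
        # the prefactor grows linearly from the wave center, so measure the
        # abscissa from the turning point (falling back to the span start)
        z_ref = orbit.z0 if orbit.z0 is not None else z[0]
        zs = zz - z_ref + 1.0
        slope = np.polyfit(zz, np.log(aa / zs), 1)[0]
        expected = -orbit.params.c / 2.0
    else:
        slope = np.polyfit(zz, np.log(aa), 1)[0]
        expected = mu
    return {
        "status": "ok",
        "rate": float(slope),
        "expected": float(np.real(expected)),
        "sub_exponential": sub_exponential,
        "rel_err": float(abs(slope - np.real(expected)) / max(abs(np.real(expected)), 1e-30)),
    }


def turning_point_consistency(orbit: WaveOrbit) -> dict:
    """Residual of the measured turning point against its closed form.

    Compares ``a_z0`` with the algebraic value from ``(i_z0, i_{-inf})`` and
    checks the bounds ``a_z0 <= a*(i_z0)``, ``a_z0 + i_z0 <= 1`` and
    ``i_z0 > 2 - i_{-inf}``.
    """
    if orbit.z0 is None:
        raise ValueError("orbit has no detected turning point")
    params = orbit.params
    predicted = mc.turning_point_active(orbit.i_z0, orbit.i_minus_inf, params)
    residual = abs(orbit.a_z0 - predicted)
    tol = 1e-9
    ic = mc.critical_density(params.c)
    checks = {
        "a_z0_le_a_star": orbit.a_z0 <= mc.a_star(orbit.i_z0, params) + 1e-6,
        "sum_le_one": orbit.a_z0 + orbit.i_z0 <= 1.0 + tol,
        "i_z0_above_mirror": orbit.i_z0 > 2.0 - orbit.i_minus_inf - tol,
        "i_z0_in_range": ic < orbit.i_z0 < 1.0,
    }
    return {"residual": float(residual), "predicted": float(predicted), **checks}
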