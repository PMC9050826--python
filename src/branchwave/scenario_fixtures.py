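"""Synthetic input scenarios for every stage of the analysis.

The model needs no external data: every study condition is a parameterized
synthetic state.  This module generates the input families the analysis
assumes — the compact Gaussian heap of active particles on a zero-inactive
background that triggers self-organization, attractor starts ``(a0, 0, i0)``
on the ``b = 0`` plane, localized perturbations of computed wave profiles,
and parameter sweeps over the admissible wave family — plus lossless CSV/JSON
round-trip I/O so runs are reproducible from plain-text artifacts.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import model_core as mc
from .model_core import ModelParams, PhaseState
from .pde_simulator import Grid1D, initial_condition_gaussian
from .wave_constructor import WaveOrbit

__all__ = [
    "Scenario",
    "make_bump",
    "make_attractor_start",
    "make_perturbed_wave",
    "parameter_grid",
    "resample_orbit",
    "save_scenario",
    "load_scenario",
]


@dataclass(frozen=True)
class Scenario:
    """A named, seeded synthetic input with its generated payload."""

    name: str
    params: ModelParams
    kind: str  # gaussian-bump | plane-state | perturbed-wave | attractor-start | parameter-grid
    seed: int
    payload: dict


def make_bump(
    grid: Grid1D,
    amplitude: float = 0.5,
    center: float = 0.0,
    width: float = 1.0,
    params: ModelParams = ModelParams(c=2.0, r=0.0),
    mirror: bool = False,
) -> Scenario:
    """Gaussian heap of active particles on a zero-inactive background.

    Defaults reproduce the reference case ``A(x,0) = exp(-x^2)/2``, ``I = 0``.
    With ``mirror=True`` a second identical bump is superposed at ``-center``,
    producing two outgoing fronts.
    """
    A, I = initial_condition_gaussian(grid, amplitude, width, center)
    if mirror and center != 0.0:
        A2, _ = initial_condition_gaussian(grid, amplitude, width, -center)
        A = A + A2
    return Scenario(
        name="gaussian-bump",
        params=params,
        kind="gaussian-bump",
        seed=0,
        payload={"x": grid.x, "A": A, "I": I},
    )


@dataclass(frozen=True)
class AttractorStart:
    """A start state on the ``b = 0`` plane with its admissibility flag."""

    state: PhaseState
    in_attractor: bool


def make_attractor_start(
    i0: float, fraction: float, params: ModelParams
) -> AttractorStart:
    """State ``(fraction * a*(i0), 0, i0)``; ``fraction > 1`` leaves the attractor.

    ``fraction = 0`` is the fixed point, ``fraction = 1`` the boundary of the
    proven attractor; larger fractions are flagged for must-fail exploration.
    """
    ic = mc.critical_density(params.c)
    if not (ic - mc.ALG_TOL <= i0 < 1.0) or fraction < 0:
        raise ValueError("require i0 in [i_c, 1) and fraction >= 0")
    a0 = fraction * mc.a_star(i0, params)
    return AttractorStart(
        state=PhaseState(a0, 0.0, i0), in_attractor=bool(fraction <= 1.0)
    )


def resample_orbit(
    orbit: WaveOrbit, z_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``(a, i)`` of a converged orbit onto new abscissae.

    Monotone cubic interpolation inside the computed span; beyond it the tails
    are extended with the analytic rates: ``a`` decays/grows exponentially at
    ``mu_{+-inf}`` and ``i`` approaches its limit at the same rate, which
    avoids kinks at the truncation points.
    """
    z, a, i = orbit.z, orbit.a, orbit.i
    a_int = PchipInterpolator(z, a, extrapolate=False)
    i_int = PchipInterpolator(z, i, extrapolate=False)
    a_new = a_int(z_new)
    i_new = i_int(z_new)
    mu_m, _ = mc.decay_rate(orbit.params, orbit.i_minus_inf)
    mu_p, _ = mc.decay_rate(orbit.params, orbit.i_plus_inf_observed)
    mu_m, mu_p = float(np.real(mu_m)), float(np.real(mu_p))
    left = z_new < z[0]
    right = z_new > z[-1]
    if left.any():
        dz = z_new[left] - z[0]
        a_new[left] = a[0] * np.exp(mu_m * dz)
        i_new[left] = orbit.i_minus_inf + (i[0] - orbit.i_minus_inf) * np.exp(mu_m * dz)
    if right.any():
        dz = z_new[right] - z[-1]
        a_new[right] = a[-1] * np.exp(mu_p * dz)
        i_lim = orbit.i_plus_inf_observed
        i_new[right] = i_lim + (i[-1] - i_lim) * np.exp(mu_p * dz)
    return a_new, i_new


def make_perturbed_wave(
    orbit: WaveOrbit,
    grid: Grid1D,
    amplitude: float = 0.01,
    decay: float = 1.0,
    support: tuple[float, float] | None = None,
    seed: int = 0,
    front_at: float | None = None,
) -> Scenario:
    """Wave profile on a PDE grid plus a seeded, localized random perturbation.

    The orbit is resampled onto the grid (front maximum placed at
    ``front_at``, default mid-domain), then a smooth random bump combination —
    compactly supported on ``support`` and damped by ``exp(-decay * |x -
    x_front|)`` — is added to ``A``, scaled to the requested sup-norm
    amplitude.  Rejected if the perturbation would push ``A`` negative.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if not orbit.converged:
        raise ValueError("need a converged orbit")
    x = grid.x
    if front_at is None:
        front_at = 0.5 * (grid.x_min + grid.x_max)
    zmax = orbit.z[int(np.argmax(orbit.a))]
    a, i = resample_orbit(orbit, x - front_at + zmax)
    pert = np.zeros_like(x)
    if amplitude > 0:
        rng = np.random.default_rng(seed)
        lo, hi = support if support is not None else (
            front_at - 10.0, front_at + 10.0,
        )
        centers = rng.uniform(lo, hi, size=8)
        widths = rng.uniform(0.5, 2.0, size=8)
        signs = rng.choice([-1.0, 1.0], size=8)
        for ctr, w, s in zip(centers, widths, signs):
            pert += s * np.exp(-(((x - ctr) / w) ** 2))
        pert *= np.exp(-decay * np.abs(x - front_at))
        pert[(x < lo) | (x > hi)] = 0.0
        sup = np.max(np.abs(pert))
        if sup > 0:
            pert *= amplitude / sup
    A = a + pert
    if A.min() < 0:
        raise ValueError("perturbation amplitude makes A negative")
    return Scenario(
        name=f"perturbed-wave-seed{seed}",
        params=orbit.params,
        kind="perturbed-wave",
        seed=seed,
        payload={"x": x, "A": A, "I": i, "A_wave": a},
    )


def parameter_grid(
    c_values, r_values, i_minus_inf_values
) -> tuple[list[Scenario], list[Scenario]]:
    """Cartesian sweep over the wave family, split into admissible/must-fail.

    A combination is admissible iff ``c > 0``, ``r >= 0`` and
    ``i_{-inf} in (1, 2 - i_c(c)]``; the rest are returned separately as
    must-fail cases (their orbits spiral negative).
    """
    admissible: list[Scenario] = []
    inadmissible: list[Scenario] = []
    for c in c_values:
        for r in r_values:
            for im in i_minus_inf_values:
                if c <= 0 or r < 0:
                    continue
                params = ModelParams(c=c, r=r)
                ok = 1.0 < im <= 2.0 - mc.critical_density(c) + mc.ALG_TOL
                sc = Scenario(
                    name=f"wave-c{c}-r{r}-im{im}",
                    params=params,
                    kind="parameter-grid",
                    seed=0,
                    payload={"i_minus_inf": im, "admissible": ok},
                )
                (admissible if ok else inadmissible).append(sc)
    return admissible, inadmissible


def save_scenario(sc: Scenario, directory) -> Path:
    """Write a scenario to ``<dir>/<name>.json`` (+ ``.csv`` for array payloads)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {k: v for k, v in sc.payload.items() if isinstance(v, np.ndarray)}
    scalars = {k: v for k, v in sc.payload.items() if not isinstance(v, np.ndarray)}
    meta = {
        "name": sc.name,
        "kind": sc.kind,
        "seed": sc.seed,
        "c": sc.params.c,
        "r": sc.params.r,
        "scalars": scalars,
        "has_arrays": bool(arrays),
    }
    path = directory / f"{sc.name}.json"
    path.write_text(json.dumps(meta, indent=1))
    if arrays:
        df = pd.DataFrame(arrays)
        df.to_csv(directory / f"{sc.name}.csv", index=False, float_format="%.17g")
    return path


def load_scenario(path) -> Scenario:
    """Read a scenario written by :func:`save_scenario` (lossless to 1e-15 rel)."""
    path = Path(path)
    meta = json.loads(path.read_text())
    payload: dict = dict(meta["scalars"])
    if meta["has_arrays"]:
        df = pd.read_csv(path.with_suffix(".csv"), float_precision="round_trip")
        payload.update({k: df[k].to_numpy() for k in df.columns})
    return Scenario(
        name=meta["name"],
        params=ModelParams(c=meta["c"], r=meta["r"]),
        kind=meta["kind"],
        seed=meta["seed"],
        payload=payload,
    )
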