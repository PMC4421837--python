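"""Coarse-grained nucleation-conversion-polymerization (NCP) kinetics.

The model tracks three populations of an aggregating protein (tau K18 and
variants) in a well-mixed solution:

* ``m`` — free monomer concentration (μM),
* ``x`` — number concentration of small oligomers (μM),
* ``f`` — number concentration of fibrils (μM),

with oligomers of fixed average length ``x_a`` and fibrils of fixed average
length ``f_a`` (monomer units).  Four microscopic processes connect them:

* nucleation, rate ``k_n·m^n_c`` — monomers assemble into oligomers
  (heparin catalysis is subsumed into ``k_n``);
* oligomer dissociation, rate ``k_n_rev·x`` — complete disassembly of an
  oligomer back to monomers;
* conversion, rate ``k_plus·m·x`` — an oligomer converts into a
  growth-competent fibril in a reaction first order in monomer;
* reversion, rate ``k_off·f`` — a fibril reverts to a small oligomer,
  releasing free monomer.

The governing equations are::

    dx/dt = k_n·m^n_c − k_n_rev·x − k_plus·m·x + k_off·f
    df/dt = k_plus·m·x − k_off·f
    dm/dt = −x_a·(k_n·m^n_c − k_n_rev·x) − (f_a − x_a)·(k_plus·m·x − k_off·f)

The monomer equation is the unique first-order closure with constant average
lengths that conserves total monomer mass ``m + x_a·x + f_a·f`` exactly:
creating one oligomer sequesters ``x_a`` monomers, and converting one
oligomer into one fibril sequesters a further ``f_a − x_a``.

Units are μM and hours throughout; ``k_n`` carries units μM^(1−n_c)·h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the last good time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class RateConstants:
    """The four microscopic rate constants of the NCP model.

    Parameters
    ----------
    k_n
        Nucleation rate constant, μM^(1−n_c)·h⁻¹.
    k_n_rev
        Oligomer dissociation rate constant, h⁻¹.
    k_plus
        Monomer-dependent oligomer→fibril conversion rate constant, μM⁻¹·h⁻¹.
    k_off
        Fibril→oligomer reversion rate constant, h⁻¹.
    n_c
        Reaction order of nucleation in monomer (critical nucleus size),
        integer ≥ 2.
    """

    k_n: float
    k_n_rev: float
    k_plus: float
    k_off: float
    n_c: int = 2

    def __post_init__(self) -> None:
        for name in ("k_n", "k_n_rev", "k_plus", "k_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if int(self.n_c) != self.n_c or self.n_c < 2:
            raise ValueError(f"n_c must be an integer >= 2, got {self.n_c!r}")

    def scaled(self, factor: float) -> "RateConstants":
        """All four rate constants multiplied by ``factor`` (time rescaling)."""
        return replace(
            self,
            k_n=self.k_n * factor,
            k_n_rev=self.k_n_rev * factor,
            k_plus=self.k_plus * factor,
            k_off=self.k_off * factor,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Fixed average lengths and initial monomer concentration.

    ``x_a`` and ``f_a`` are held constant over a simulation — a requirement
    of the mass-conserving closure.  Defaults: ``f_a = 2000`` monomer units
    (a ~1 μm fibril with one molecule per β-strand) and ``m0 = 10`` μM, the
    standard in-vitro aggregation condition.
    """

    x_a: float = 3.0
    f_a: float = 2000.0
    m0: float = 10.0
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if not (1 < self.x_a < self.f_a):
            raise ValueError(
                f"require 1 < x_a < f_a, got x_a={self.x_a}, f_a={self.f_a}"
            )
        if self.m0 <= 0:
            raise ValueError(f"m0 must be > 0, got {self.m0}")


@dataclass(frozen=True)
class KineticState:
    """Concentrations (μM) of monomer, oligomer and fibril at time ``t`` (h)."""

    m: float
    x: float
    f: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 0 or self.x < 0 or self.f < 0:
            raise ValueError(
                f"concentrations must be >= 0, got m={self.m}, x={self.x}, f={self.f}"
            )

    def total_mass(self, config: ModelConfig) -> float:
        """Total monomer mass m + x_a·x + f_a·f (μM)."""
        return self.m + config.x_a * self.x + config.f_a * self.f


@dataclass
class Trajectory:
    """Integrated time course of the NCP model on a strictly increasing grid."""

    times: np.ndarray
    m: np.ndarray
    x: np.ndarray
    f: np.ndarray
    config: ModelConfig
    params: RateConstants

    @property
    def fibril_mass(self) -> np.ndarray:
        """Fibril residue concentration f_a·f(t), μM."""
        return self.config.f_a * self.f

    @property
    def total_mass(self) -> np.ndarray:
        return self.m + self.config.x_a * self.x + self.config.f_a * self.f

    def state(self, i: int) -> KineticState:
        return KineticState(m=self.m[i], x=self.x[i], f=self.f[i], t=self.times[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "m_uM": self.m,
                "x_uM": self.x,
                "f_uM": self.f,
                "fibril_mass_uM": self.fibril_mass,
            }
        )


def derivatives(
    state: KineticState, params: RateConstants, config: ModelConfig
) -> tuple[float, float, float]:
    """Rates of change (dm/dt, dx/dt, df/dt) in μM·h⁻¹.

    Satisfies the mass-conservation identity
    ``dm/dt + x_a·dx/dt + f_a·df/dt = 0`` analytically.
    """
    if state.m < 0 or state.x < 0 or state.f < 0:
        raise ValueError("negative concentrations are outside the model domain")
    nucleation = params.k_n * state.m**params.n_c - params.k_n_rev * state.x
    conversion = params.k_plus * state.m * state.x - params.k_off * state.f
    dx = nucleation - conversion
    df = conversion
    dm = -config.x_a * nucleation - (config.f_a - config.x_a) * conversion
    return dm, dx, df


def _rhs_reduced(params: RateConstants, config: ModelConfig, total_mass: float):
    """RHS advancing (x, f) only; m is eliminated through mass conservation."""
    x_a, f_a, n_c = config.x_a, config.f_a, params.n_c

    def rhs(t, y):
        x, f = y
        m = total_mass - x_a * x - f_a * f
        if m < 0.0:
            m = 0.0
        nucleation = params.k_n * m**n_c - params.k_n_rev * x
        conversion = params.k_plus * m * x - params.k_off * f
        return (nucleation - conversion, conversion)

    return rhs


_NEG_TOL = 1e-12  # μM; magnitudes below this are integrator noise, clipped


def integrate(
    params: RateConstants,
    config: ModelConfig,
    times: Sequence[float] | np.ndarray,
    initial: KineticState | None = None,
    method: str = "LSODA",
    dense: bool = False,
):
    """Integrate the NCP equations over a strictly increasing time grid.

    Mass conservation is enforced by construction: the solver advances
    (x, f) and recovers ``m`` algebraically from the conserved total mass,
    so ``m + x_a·x + f_a·f`` is exact at every grid point.

    Parameters
    ----------
    params, config
        Model parameters; ``config.rtol``/``config.atol`` control accuracy.
    times
        Strictly increasing grid starting at the initial time.
    initial
        Starting state; defaults to (m0, 0, 0) at t = times[0].
    dense
        If True, return ``(Trajectory, sol)`` where ``sol`` is the solver
        object with a dense interpolant.

    Raises
    ------
    IntegrationError
        If the solver fails; the exception carries the last good time.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    if initial is None:
        initial = KineticState(m=config.m0, x=0.0, f=0.0, t=times[0])
    total_mass = initial.total_mass(config)
    rhs = _rhs_reduced(params, config, total_mass)
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        (initial.x, initial.f),
        t_eval=times,
        method=method,
        rtol=config.rtol,
        atol=config.atol,
        dense_output=dense,
    )
    if not sol.success or sol.t.shape != times.shape:
        last = float(sol.t[-1]) if len(sol.t) else None
        raise IntegrationError(f"integrator failed: {sol.message}", last_time=last)
    x, f = sol.y
    # the algebraic m carries O(rtol*mass) roundoff; only warn beyond that
    m_tol = max(_NEG_TOL, 100.0 * config.rtol * total_mass)
    x = _clip_small_negatives(x)
    f = _clip_small_negatives(f)
    m = _clip_small_negatives(
        total_mass - config.x_a * x - config.f_a * f, tol=m_tol
    )
    traj = Trajectory(times=times, m=m, x=x, f=f, config=config, params=params)
    return (traj, sol) if dense else traj


def _clip_small_negatives(arr: np.ndarray, tol: float = _NEG_TOL) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    bad = arr < -tol
    if np.any(bad):
        import warnings

        warnings.warn(
            f"concentration dipped to {arr[bad].min():.3e} μM; clipping at 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.clip(arr, 0.0, None)


def plateau_fibril_mass(
    params: RateConstants,
    config: ModelConfig,
    initial: KineticState | None = None,
    rel_flux: float = 1e-6,
    horizon_factor: float = 100.0,
    max_doublings: int = 12,
) -> tuple[float, float, Trajectory]:
    """Find the plateau W = f_a·f(∞) of the fibril residue concentration.

    Integrates until the relative flux |d(f_a·f)/dt| / W drops below
    ``rel_flux`` (default 1e-6 h⁻¹ relative), starting from a horizon of
    ``horizon_factor / (k_plus·m0)`` and doubling as needed.

    Returns ``(W, t_plateau, trajectory)``.
    """
    if params.k_plus <= 0:
        raise ValueError("k_plus must be > 0 for fibrils to form")
    if initial is None:
        initial = KineticState(m=config.m0, x=0.0, f=0.0)
    horizon = horizon_factor / (params.k_plus * config.m0)
    for _ in range(max_doublings):
        times = np.concatenate(
            [[0.0], np.geomspace(horizon * 1e-6, horizon, 400)]
        )
        traj = integrate(params, config, times, initial=initial)
        W = traj.fibril_mass[-1]
        if W <= 0:
            horizon *= 2
            continue
        dm, dx, df = derivatives(traj.state(len(times) - 1), params, config)
        if abs(config.f_a * df) / W < rel_flux:
            return float(W), float(horizon), traj
        horizon *= 2
    raise IntegrationError(
        f"no fibril-mass plateau within horizon {horizon / 2:.3g} h "
        f"(relative flux criterion {rel_flux:g})"
    )


def half_time(
    params: RateConstants,
    config: ModelConfig,
    initial: KineticState | None = None,
    W: float | None = None,
    rel_flux: float = 1e-6,
    horizon_factor: float = 100.0,
) -> float:
    """First time t_W/2 at which the fibril residue concentration reaches W/2.

    ``W`` defaults to the plateau of the reaction started from ``initial``;
    for seeded comparisons pass the unseeded plateau explicitly so both
    half-times are measured against the same target.

    The crossing is bracketed on a dense trajectory and refined with the
    solver's interpolant via Brent's method.
    """
    from scipy.optimize import brentq

    if initial is None:
        initial = KineticState(m=config.m0, x=0.0, f=0.0)
    if W is None:
        W, t_plateau, _ = plateau_fibril_mass(
            params, config, initial=initial, rel_flux=rel_flux,
            horizon_factor=horizon_factor,
        )
    if W <= 0:
        raise ValueError("no fibril formation: plateau W is zero")
    target = 0.5 * W

    horizon = horizon_factor / (params.k_plus * config.m0)
    for _ in range(12):
        times = np.concatenate([[0.0], np.geomspace(horizon * 1e-6, horizon, 400)])
        traj, sol = integrate(params, config, times, initial=initial, dense=True)
        above = traj.fibril_mass >= target
        if above.any():
            i = int(np.argmax(above))
            if i == 0:
                return 0.0
            lo, hi = times[i - 1], times[i]

            def g(t):
                x, f = sol.sol(t)
                return config.f_a * f - target

            return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-12))
        horizon *= 2
    raise IntegrationError(f"fibril mass never reached W/2 = {target:.3g} μM")


def write_trajectory(traj: Trajectory, path, sidecar: bool = True) -> None:
    """Write a trajectory as delimited text plus a JSON parameter sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    if sidecar:
        meta = {
            "params": {
                "k_n": traj.params.k_n,
                "k_n_rev": traj.params.k_n_rev,
                "k_plus": traj.params.k_plus,
                "k_off": traj.params.k_off,
                "n_c": traj.params.n_c,
            },
            "config": {
                "x_a": traj.config.x_a,
                "f_a": traj.config.f_a,
                "m0": traj.config.m0,
            },
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2)
        )
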