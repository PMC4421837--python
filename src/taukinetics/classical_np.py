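"""Classical nucleated-polymerization theory and its bound analysis.

In the classical picture there is a single aggregate type: oligomers are
just small fibrils.  Fibrils of length j (monomer units, j ≥ n_c) nucleate
at rate k_n·m^n_c, elongate by monomer addition at 2·k_plus·m per fibril
(the factor of 2 counts the two free ends) and shed monomers at 2·k_off.

The master equation for the length distribution f_j(t) reads::

    df_j/dt = 2·k_plus·m·(f_{j−1} − f_j) + 2·k_off·(f_{j+1} − f_j)
              + k_n·m^n_c·δ_{j,n_c}          (f_j ≡ 0 for j < n_c)

Summing over j (neglecting loss of aggregates through complete
depolymerization) gives the zeroth moment — the total aggregate number
concentration::

    dP/dt = k_n·m(t)^n_c    ⇒    P(t) = ∫₀ᵗ k_n·m(τ)^n_c dτ

Given an observed monomer time course m(t), P(t) is a lower bound on the
aggregate number whenever the nucleation rate is chosen minimally, and
μ(t) = (m(0) − m(t)) / P(t) is then an upper bound on the mean aggregate
length.  These bounds are the quantitative argument that a single-species
model cannot simultaneously account for the observed oligomer numbers and
for micrometre-long fibrils (~2000 monomer units): matching the oligomer
numbers caps μ(t) far below the observed fibril length, while assuming the
observed length caps the aggregate number far below the observed oligomer
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class LengthDistribution:
    """Length-resolved fibril populations at one time point.

    ``f_j[i]`` is the concentration (μM) of fibrils of length
    ``j = j_min + i`` for ``j_min = n_c ≤ j ≤ j_max``.
    """

    j_min: int
    j_max: int
    f_j: np.ndarray
    m: float
    t: float

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.j_min, self.j_max + 1)

    @property
    def number(self) -> float:
        """Total aggregate number concentration P = Σ f_j (μM)."""
        return float(self.f_j.sum())

    @property
    def mass(self) -> float:
        """Aggregated monomer mass Σ j·f_j (μM)."""
        return float((self.lengths * self.f_j).sum())


@dataclass
class MomentSeries:
    """Aggregate number P(t) and mean length μ(t) over time."""

    times: np.ndarray
    P: np.ndarray
    mu: np.ndarray | None = None


class TruncationError(RuntimeError):
    pass


def integrate_master(
    k_n: float,
    k_plus: float,
    k_off: float,
    n_c: int,
    m0: float,
    times,
    j_max: int,
    rtol: float = 1e-8,
    atol: float = 1e-14,
    leakage_tol: float = 1e-6,
) -> list[LengthDistribution]:
    """Integrate the nucleated-polymerization master equation.

    Dissociation out of a length-n_c fibril removes it from the distribution
    and returns its n_c monomers to solution, so total monomer mass
    m + Σ j·f_j is conserved exactly.

    Raises
    ------
    TruncationError
        If the population at j_max exceeds ``leakage_tol`` × Σ f_j at any
        reported time (choose a larger j_max).
    """
    if j_max < n_c + 10:
        raise ValueError(f"j_max must be >= n_c + 10, got {j_max}")
    if m0 <= 0:
        raise ValueError("m0 must be > 0")
    times = np.asarray(times, dtype=float)
    n = j_max - n_c + 1  # lengths n_c .. j_max

    def rhs(t, y):
        m, f = y[0], y[1:]
        m = max(m, 0.0)
        grow = 2.0 * k_plus * m
        shrink = 2.0 * k_off
        df = np.empty_like(f)
        # elongation: j-1 -> j ; no influx into n_c from below; the top bin
        # is reflecting (nothing grows past j_max) so mass stays conserved
        df[0] = -grow * f[0]
        df[1:] = grow * (f[:-1] - f[1:])
        df[-1] += grow * f[-1]
        # dissociation: j+1 -> j ; length n_c disassembles completely
        df[:-1] += shrink * (f[1:] - f[:-1])
        df[-1] += -shrink * f[-1]
        nucl = k_n * m**n_c
        df[0] += nucl
        # monomer balance: nucleation consumes n_c; each elongation 1;
        # each dissociation releases 1, except full disassembly releases n_c
        dm = (
            -n_c * nucl
            - grow * (f.sum() - f[-1])
            + shrink * (f[1:].sum() + n_c * f[0])
        )
        return np.concatenate([[dm], df])

    y0 = np.zeros(n + 1)
    y0[0] = m0
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, t_eval=times, method="BDF",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    out = []
    for i, t in enumerate(times):
        f = np.clip(sol.y[1:, i], 0.0, None)
        total = f.sum()
        if total > 0 and f[-1] > leakage_tol * total:
            raise TruncationError(
                f"truncation leakage f_jmax/P = {f[-1] / total:.2e} at t={t:g} h; "
                f"increase j_max (currently {j_max})"
            )
        out.append(
            LengthDistribution(
                j_min=n_c, j_max=j_max, f_j=f, m=float(max(sol.y[0, i], 0.0)), t=t
            )
        )
    return out


def integrate_master_adaptive(
    k_n, k_plus, k_off, n_c, m0, times, j_max0: int | None = None, **kw
) -> list[LengthDistribution]:
    """``integrate_master`` with j_max doubled until leakage is acceptable."""
    j_max = j_max0 or max(4 * n_c, n_c + 20)
    for _ in range(12):
        try:
            return integrate_master(k_n, k_plus, k_off, n_c, m0, times, j_max, **kw)
        except TruncationError:
            j_max *= 2
    raise TruncationError(f"leakage criterion not met even at j_max={j_max}")


class MonomerSeries:
    """Linearly interpolated monomer time course m(τ) on [t0, t_end].

    Extrapolation outside the observed support is forbidden.
    """

    def __init__(self, times, m):
        self.times = np.asarray(times, dtype=float)
        self.m = np.asarray(m, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.m < 0):
            raise ValueError("monomer concentrations must be >= 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("t outside the support of the monomer series")
        return np.interp(t, self.times, self.m)

    def power_integral(self, t: float, n_c: int) -> float:
        """∫_{t0}^{t} m(τ)^n_c dτ, exact for the piecewise-linear interpolant.

        On a segment where m is linear from a to b over Δτ the integral is
        (b^{n_c+1} − a^{n_c+1}) / ((n_c+1)(b − a)) · Δτ, with the constant
        limit a^{n_c}·Δτ when a = b.
        """
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError("t outside the support of the monomer series")
        ts = self.times
        total = 0.0
        for i in range(len(ts) - 1):
            t1, t2 = ts[i], ts[i + 1]
            if t1 >= t:
                break
            t2 = min(t2, t)
            a = float(self(t1))
            b = float(self(t2))
            dt = t2 - t1
            if np.isclose(a, b):
                total += a**n_c * dt
            else:
                total += (b ** (n_c + 1) - a ** (n_c + 1)) / ((n_c + 1) * (b - a)) * dt
        return total


def aggregate_number(m_series: MonomerSeries, k_n: float, n_c: int, times) -> MomentSeries:
    """Zeroth moment P(t) = ∫₀ᵗ k_n·m(τ)^n_c dτ over the given times."""
    times = np.asarray(times, dtype=float)
    P = np.array([k_n * m_series.power_integral(t, n_c) for t in times])
    return MomentSeries(times=times, P=P)


def minimal_nucleation_rate(
    m_series: MonomerSeries, oligomer_series, obs_times, n_c: int
) -> float:
    """Smallest k_n such that P(t) ≥ observed oligomer numbers at all times.

    Since P is proportional to k_n, the minimum is
    max_t [ x_obs(t) / ∫₀ᵗ m^n_c dτ ] over times with x_obs > 0.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    x_obs = np.asarray(oligomer_series, dtype=float)
    if np.all(x_obs <= 0):
        raise ValueError("oligomer observations are zero everywhere; k_n unbounded")
    k_min = 0.0
    for t, x in zip(obs_times, x_obs):
        if x <= 0:
            continue
        integral = m_series.power_integral(t, n_c)
        if integral <= 0:
            raise ValueError(f"monomer power integral vanishes at t={t:g} h")
        k_min = max(k_min, x / integral)
    return k_min


def mean_length_bound(
    m_series: MonomerSeries, oligomer_series, obs_times, n_c: int, times=None
) -> tuple[MomentSeries, float]:
    """Upper bound μ(t) = (m(0) − m(t)) / P(t) on the mean aggregate length.

    ``k_n`` is set to the smallest value for which P(t) accounts for the
    observed oligomer numbers, making P a lower bound and μ an upper bound.
    Returns the moment series (with ``mu`` populated; NaN where P = 0) and
    the minimizing k_n.
    """
    if times is None:
        times = np.asarray(obs_times, dtype=float)
    k_n = minimal_nucleation_rate(m_series, oligomer_series, obs_times, n_c)
    ms = aggregate_number(m_series, k_n, n_c, times)
    m0 = float(m_series(m_series.times[0]))
    aggregated = m0 - m_series(times)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(ms.P > 0, aggregated / ms.P, np.nan)
    ms.mu = mu
    return ms, k_n


def oligomer_bound_fixed_length(m_series: MonomerSeries, times, L: float = 2000.0) -> MomentSeries:
    """Upper bound on the oligomer number assuming all aggregates have length L.

    P(t) = (m(0) − m(t)) / L.  With L the observed fibril length (~2000
    monomer units) this is a strong upper bound on x(t) under the classical
    single-species model.
    """
    if L <= 0:
        raise ValueError("assumed length L must be > 0")
    times = np.asarray(times, dtype=float)
    m0 = float(m_series(m_series.times[0]))
    P = (m0 - m_series(times)) / L
    return MomentSeries(times=times, P=np.clip(P, 0.0, None))


def nc_scan(
    m_series: MonomerSeries, oligomer_series, obs_times, nc_values=range(2, 11)
) -> dict[int, tuple[MomentSeries, float]]:
    """Apply the mean-length bound for a range of critical nucleus sizes."""
    return {
        int(n_c): mean_length_bound(m_series, oligomer_series, obs_times, n_c)
        for n_c in nc_values
    }
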