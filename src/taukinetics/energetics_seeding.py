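"""Activation free energies and seeding/compartmentalization predictions.

Transition-state theory relates a rate constant to an activation free
energy, k = Γ·exp(−ΔG‡/RT).  For the same process in two constructs the
unknown prefactor Γ cancels, and the mutation-induced change in activation
free energy (in RT units) is::

    ΔΔG‡ = −ln(k_mut / k_wt)

so a process that is *faster* in the mutant has a *negative* ΔΔG‡ (its
barrier is lowered).  Applying this to the four rate constants of the
conversion model quantifies how a disease mutation reshapes the
aggregation energy landscape.

Seeding is modelled by starting the conversion model with a non-zero
oligomer concentration x(0).  With W the fibril-residue plateau of the
*unseeded* reaction, the half-times t_W/2 (unseeded) and ˢt_W/2 (seeded)
are the times at which each reaction reaches W/2; using the unseeded W for
both matters because seeding can raise the final fibril mass.  The seed
concentration that doubles the rate of fibril formation is the x(0) at
which ˢt_W/2 / t_W/2 = 1/2.  Converting concentrations to molecule copy
numbers in a neuronal cell volume (~6,000 μm³) turns these into predictions
for prion-like cell-to-cell spreading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .conversion_model import (
    KineticState,
    ModelConfig,
    RateConstants,
    half_time,
    plateau_fibril_mass,
)

AVOGADRO = 6.02214076e23  # mol^-1

PROCESS_NAMES = ("k_n", "k_n_rev", "k_plus", "k_off")


def ddg(k_wt: float, k_mut: float) -> float:
    """ΔΔG‡ = −ln(k_mut/k_wt) in RT units; negative means faster mutant."""
    if k_wt <= 0 or k_mut <= 0:
        raise ValueError("rate constants must be > 0")
    return -math.log(k_mut / k_wt)


def ddg_error(k_wt: float, sd_wt: float, k_mut: float, sd_mut: float) -> float:
    """First-order (delta-method) standard error of ΔΔG‡ in RT units."""
    if sd_wt < 0 or sd_mut < 0:
        raise ValueError("standard errors must be >= 0")
    return math.sqrt((sd_wt / k_wt) ** 2 + (sd_mut / k_mut) ** 2)


@dataclass
class DdgEntry:
    value: float | None  # None => not determined
    stderr: float | None = None

    @property
    def determined(self) -> bool:
        return self.value is not None


@dataclass
class DdgTable:
    """Per-process ΔΔG‡ (RT units) between a reference and a mutant construct."""

    entries: dict[str, DdgEntry] = field(default_factory=dict)
    label_wt: str = "wt"
    label_mut: str = "mutant"

    def __getitem__(self, process: str) -> DdgEntry:
        return self.entries[process]

    def to_dict(self) -> dict:
        return {
            name: {
                "ddg_RT": e.value,
                "stderr_RT": e.stderr,
                "determined": e.determined,
            }
            for name, e in self.entries.items()
        }


def ddg_table(fit_wt, fit_mut, label_wt: str = "wt", label_mut: str = "mutant") -> DdgTable:
    """ΔΔG‡ table from two fitted parameter sets.

    Accepts FitResult objects (``params`` + ``stderr`` dict + ``identifiable``
    dict) or bare RateConstants.  Unidentifiable or missing parameters
    propagate as not-determined entries rather than failures.
    """
    table = DdgTable(label_wt=label_wt, label_mut=label_mut)
    for name in PROCESS_NAMES:
        k_wt, sd_wt, ok_wt = _extract(fit_wt, name)
        k_mut, sd_mut, ok_mut = _extract(fit_mut, name)
        if not (ok_wt and ok_mut) or k_wt is None or k_mut is None or k_wt <= 0 or k_mut <= 0:
            table.entries[name] = DdgEntry(value=None)
            continue
        value = ddg(k_wt, k_mut)
        stderr = (
            ddg_error(k_wt, sd_wt, k_mut, sd_mut)
            if sd_wt is not None and sd_mut is not None
            else None
        )
        table.entries[name] = DdgEntry(value=value, stderr=stderr)
    return table


def _extract(fit, name: str):
    """(value, stderr, identifiable) for one rate constant from fit or params."""
    if isinstance(fit, RateConstants):
        return getattr(fit, name), None, True
    params = getattr(fit, "params")
    value = getattr(params, name, None) if params is not None else None
    stderr = getattr(fit, "stderr", {}) or {}
    ident = getattr(fit, "identifiable", {}) or {}
    return value, stderr.get(name), bool(ident.get(name, True))


@dataclass(frozen=True)
class SeedingScenario:
    """Initial conditions and parameters for a seeded aggregation reaction.

    Seed oligomers are assigned the average oligomer length x_a in the mass
    balance, so x(0) = x0 adds x_a·x0 μM of monomer-equivalent mass.
    """

    params: RateConstants
    config: ModelConfig
    x0: float = 0.0
    f0: float = 0.0
    volume_L: float = 6e-12  # 6,000 μm^3 neuronal cell

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.f0 < 0:
            raise ValueError("seed concentrations must be >= 0")
        if self.volume_L <= 0:
            raise ValueError("volume must be > 0")

    def initial_state(self) -> KineticState:
        return KineticState(m=self.config.m0, x=self.x0, f=self.f0, t=0.0)


@dataclass
class SeededHalfTime:
    unseeded_h: float
    seeded_h: float
    W_uM: float

    @property
    def ratio(self) -> float:
        return self.seeded_h / self.unseeded_h


def seeded_half_time(scenario: SeedingScenario, unseeded: tuple[float, float] | None = None) -> SeededHalfTime:
    """Half-times of the unseeded and seeded reactions against the same W.

    ``unseeded`` may carry a precomputed ``(t_half, W)`` pair to avoid
    re-integrating the unseeded reaction inside root searches.
    """
    params, config = scenario.params, scenario.config
    if unseeded is None:
        W, _, _ = plateau_fibril_mass(params, config)
        t_unseeded = half_time(params, config, W=W)
    else:
        t_unseeded, W = unseeded
    seeded_state = scenario.initial_state()
    t_seeded = half_time(params, config, initial=seeded_state, W=W)
    return SeededHalfTime(unseeded_h=t_unseeded, seeded_h=t_seeded, W_uM=W)


def seeds_to_halve(
    params: RateConstants,
    config: ModelConfig,
    f0: float = 0.0,
    target_ratio: float = 0.5,
    rel_tol: float = 0.01,
    x0_max: float | None = None,
) -> float:
    """Oligomer seed concentration x0* (μM) at which ˢt_W/2/t_W/2 = target.

    The root is located by Brent's method on log10(x0) after automatic
    bracket expansion; relative tolerance 1% by default.  Raises if the
    target ratio is unreachable below ``x0_max`` (default m0/x_a, i.e. all
    protein supplied as seeds).
    """
    if not (0 < target_ratio < 1):
        raise ValueError("target_ratio must be in (0, 1)")
    if x0_max is None:
        x0_max = config.m0 / config.x_a
    W, _, _ = plateau_fibril_mass(params, config)
    t_unseeded = half_time(params, config, W=W)

    def ratio(log10_x0: float) -> float:
        sc = SeedingScenario(params=params, config=config, x0=10.0**log10_x0, f0=f0)
        return seeded_half_time(sc, unseeded=(t_unseeded, W)).ratio - target_ratio

    lo = math.log10(x0_max) - 8.0  # start searching far below full seeding
    hi = math.log10(x0_max)
    r_hi = ratio(hi)
    if r_hi > 0:
        raise ValueError(
            f"target ratio {target_ratio} unreachable even at x0={x0_max:g} μM"
        )
    r_lo = ratio(lo)
    expansions = 0
    while r_lo < 0 and expansions < 6:
        lo -= 4.0
        r_lo = ratio(lo)
        expansions += 1
    if r_lo < 0:
        raise ValueError("ratio below target even for vanishing seeds")
    log_root = brentq(ratio, lo, hi, xtol=math.log10(1.0 + rel_tol) / 2)
    return float(10.0**log_root)


def copies_to_concentration(n_copies: float, volume_L: float) -> float:
    """Concentration (μM) of ``n_copies`` molecules in ``volume_L`` litres."""
    if n_copies < 0 or volume_L <= 0:
        raise ValueError("copies must be >= 0 and volume > 0")
    return n_copies / (AVOGADRO * volume_L) * 1e6


def concentration_to_copies(conc_uM: float, volume_L: float) -> int:
    """Molecule copy count (nearest integer) of a μM concentration in a volume."""
    if conc_uM < 0 or volume_L <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    return int(round(conc_uM * 1e-6 * AVOGADRO * volume_L))
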