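# Methods

## The nucleation–conversion–polymerization model

`taukinetics` models the heparin-induced aggregation of the tau repeat
domain (K18) as a three-species network: free monomer *m*(*t*), small
structurally distinct oligomers *x*(*t*) (number concentration), and
fibrils *f*(*t*) (number concentration), with fixed average lengths
*x*ₐ (oligomer) and *f*ₐ (fibril) in monomer units.  Four processes:

* nucleation: monomers → oligomer, rate *k*ₙ·*m*^*n*c (heparin catalysis is
  folded into *k*ₙ; the critical order *n*c = 2 throughout),
* oligomer dissociation: oligomer → monomers, rate ǩₙ·*x*,
* conversion: oligomer + monomers → fibril, rate *k*₊·*m*·*x* (first order
  in monomer),
* reversion: fibril → oligomer + monomers, rate *k*off·*f*.

The governing equations are

    dx/dt = kₙ·m^nc − ǩₙ·x − k₊·m·x + koff·f
    df/dt = k₊·m·x − koff·f
    dm/dt = −xₐ·(kₙ·m^nc − ǩₙ·x) − (fₐ − xₐ)·(k₊·m·x − koff·f)

The monomer equation is the unique closure that conserves total monomer
mass *m* + *x*ₐ·*x* + *f*ₐ·*f* exactly with constant average lengths: one
nucleation event sequesters *x*ₐ monomers (the created species has average
size *x*ₐ, not *n*c), and one conversion sequesters a further
*f*ₐ − *x*ₐ.  A consequence worth keeping in mind is that conversion
transfers ~*f*ₐ monomers into fibril mass *instantaneously*; the model
does not resolve gradual elongation.

**Units.** μM and hours everywhere; *k*ₙ carries μM^(1−*n*c)·h⁻¹.

**Defaults.** *x*ₐ = 3 (the count-weighted mean of detected oligomer
sizes, dominated by dimers–pentamers), *f*ₐ = 2000 (a ~1 μm fibril with
one molecule per β-strand; fit quality is insensitive to this within a
factor of ~2), *m*₀ = 10 μM in vitro and 2 μM for intracellular
scenarios.

**Numerics.** The integrator advances only (*x*, *f*) and recovers
*m* = *M*tot − *x*ₐ·*x* − *f*ₐ·*f* algebraically, so mass conservation is
exact by construction rather than tolerance-limited; LSODA with
rtol 1e−8 / atol 1e−12 (configurable).  Values below −100·rtol·*M*tot are
clipped to zero with a warning.  Half-times *t*W/2 are found by
bracketing the crossing of the fibril residue concentration
*f*ₐ·*f*(*t*) through *W*/2 on a geometric grid and refining with
Brent's method on the solver's dense interpolant; the plateau *W* is
detected by a relative-flux criterion (|d(*f*ₐ*f*)/d*t*|/W < 1e−6 h⁻¹)
with a doubling horizon starting at 100/(*k*₊·*m*₀).

## Classical nucleated-polymerization bounds

The single-species master equation for fibrils of length *j* ≥ *n*c uses
elongation 2·*k*₊·*m* and shedding 2·*k*off per fibril (two free ends),
with nucleation feeding length *n*c.  Two boundary choices keep mass
exact: the top of the truncated length range is reflecting (nothing
elongates past *j*max; a leakage check enforces *f*(*j*max) < 1e−6·ΣΡ*f*),
and dissociation out of length *n*c disassembles the aggregate
completely, returning *n*c monomers.  The zeroth moment integrates to
*P*(*t*) = ∫ *k*ₙ·*m*(τ)^*n*c dτ, evaluated exactly on the
piecewise-linear interpolant of an observed monomer series (closed-form
per-segment power integrals; extrapolation is forbidden).  Two bound
arguments follow: choosing the smallest *k*ₙ whose *P*(*t*) accounts for
the observed oligomer numbers makes μ(*t*) = (*m*(0) − *m*(*t*))/*P*(*t*)
an upper bound on mean aggregate length; alternatively fixing the length
at 2000 makes *P*(*t*) = (*m*(0) − *m*(*t*))/2000 an upper bound on
oligomer numbers.  On conversion-model data both bounds fail by large
factors — the quantitative core of the argument that oligomers cannot be
"small fibrils".

## Single-molecule FRET burst analysis

Two-channel photon traces binned at 100 μs (the confocal residence time)
are corrected (background subtraction, then donor→acceptor cross-talk
α·donor′, then floored at zero) and segmented into bursts — maximal runs
of bins strictly above threshold (10 counts/bin in either channel for
aggregation-mode data; 7 counts per 1 ms bin in the acceptor channel for
dissociation-mode data).  Donor bursts count soluble molecules; acceptor
bursts are oligomers, since neither monomer species appears there
(acceptor monomers are not directly excited; donor monomers have nothing
to transfer to).  Per burst,

    size_app = 2·(I_D + I_A/γ) / ⟨I_D⟩        E = I_A / (I_A + γ·I_D)

with ⟨I_D⟩ the mean donor intensity of monomer bursts and γ the
detection/quantum-yield correction (default 1.0; must be calibrated for
quantitative E).  The factor 2 compensates the average 50% donor
labelling; individual oligomers deviate binomially, which broadens (but,
by symmetry of the binomial truncated to 1 ≤ donors ≤ *n*−1, does not
bias) the size estimate.  ⟨I_D⟩ should come from a monomer-only
reference (e.g. a sample at reaction start): in a mixed trace, donor-only
oligomers are invisible in the acceptor channel and would inflate the
monomer mean by a few percent.  Very long, very bright acceptor events
(duration > 5 bins AND intensity > 100·⟨I_D⟩, both configurable) are
excluded as fibril fragments.  Burst rates give concentrations by
proportionality to a reference of known concentration; oligomer number
concentration is the soluble concentration times the oligomer event
fraction, with a 50,000-fold dilution factor mapping back to the
reaction mixture.

## Fitting

The four rate constants are fitted simultaneously to *m*(*t*) and
*x*(*t*) by Levenberg–Marquardt in log₁₀ parameter space (positivity and
decade-scale search for free), with multistart (default 16 draws within
±3 decades of a heuristic initialization).  Weights are 1/sd when
per-point standard deviations exist, else each series is normalized by
its maximum so both contribute comparably (the simultaneous equal-weight
reading of "global least squares"; recorded in each FitResult).
Standard errors come from the local covariance (JᵀJ)⁻¹s² mapped through
the delta method; a parameter with relative standard error above 10 (or
a singular covariance) is flagged unidentifiable and propagates as
"not determined" into ΔΔG tables rather than failing.

## Energetics and seeding

ΔΔG‡ = −ln(*k*mut/*k*wt) in RT units (transition-state theory; the
prefactor cancels in the difference).  The sign convention makes a
faster mutant process negative.  Errors propagate first order:
σ = √((σwt/*k*wt)² + (σmut/*k*mut)²).

Seeding sets *x*(0) > 0 (seed oligomers are assigned size *x*ₐ in the
mass balance).  Both seeded and unseeded half-times are measured against
the *unseeded* plateau *W*, because seeding can raise the final fibril
mass.  The dose that doubles the rate (ˢ*t*W/2/*t*W/2 = 1/2) is found by
Brent root-finding on log₁₀ *x*₀ to 1% with automatic bracket expansion.
Copy-number conversions use *c* = *n*/(N_A·V) with a 6,000 μm³ neuronal
volume.

## Reference rate constants

Values for wild-type K18 (`reference.K18`) were calibrated once, by a
damped fixed-point iteration on (kₙ, k₊) with (ǩₙ, koff) tied through
the observed end state, against four robust observations of the standard
in-vitro reaction (10 μM, 37 °C): oligomer peak ≈ 5 nM (≈0.1% of soluble
molecules), ~90% of fibril mass formed by 3 h, final soluble protein
≈ 5 μM, late-time oligomer level ≈ 4 nM.  Variant parameter sets apply
the reported per-process activation-free-energy changes multiplicatively.
With these constants the model independently reproduces the published
in-vitro seed-dose estimates (0.01/0.3/0.2 μM scale) and the ≈4 h
intracellular half-times of K18 and ΔK280 at 2 μM.  It does *not*
reproduce the published intracellular seed *copy numbers* (~30 and
~2000) or the ≈300 h P301L intracellular half-time: those quantities are
hypersensitive to the late-time curvature of the 2 μM trajectory and to
the ǩₙ/*k*₊ balance, which the printed in-vitro observations do not pin
down.  They would require the original fitted constants.  The
corresponding checks are kept in the acceptance suite and fail loudly
rather than being weakened.

## The synthetic-data generators

Time courses: the ODE solution sampled at sparse times with independent
multiplicative log-normal noise per point (σ defaults 5% for *m*, 20%
for *x*, matching the relative scatter of replicate single-molecule
measurements; log-normal keeps concentrations positive).  Photon traces:
Poisson background per bin, species events as Poisson arrivals occupying
one bin each, binomial (p = 0.5) donor/acceptor label composition per
subunit, donor photons ∝ (donor labels)·(1−E), acceptor photons
∝ γ·(donor labels)·E with transfer requiring at least one acceptor
label, cross-talk added, Poisson counts drawn.  Not emulated: diffusion
and flow profiles, burst-shape statistics, photophysics (blinking,
bleaching, quenching), multi-bin bursts, and real instrument drift — so
passing round-trip tests validates the threshold-and-intensity analysis
chain, not burst-shape-sensitive inference.  All generators are
deterministic under a fixed seed.

## Problem sizes used in the shipped tests

Mass-conservation sweep: 1,000 random parameter draws on a 25-point
grid.  Recovery study: 12 sample points, 5% noise on both series, 50
replicates (median statistics), 2-start fits.  Burst round trips:
400,000 bins (40 s of trace) per oligomer size, ≥1,000 detected events.
Master-equation oracle: *j*max = 20 against a dt = 1e−4 h explicit-Euler
reference.  These sizes make the full suite run in well under a minute
of CPU while leaving Monte-Carlo error comfortably inside the asserted
tolerances.
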