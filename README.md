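# taukinetics

Mechanistic kinetics of tau (K18) amyloid aggregation: single-molecule
FRET burst analysis for oligomer detection and sizing, a
nucleation–conversion–polymerization (NCP) kinetic model with global
rate-constant fitting, classical nucleated-polymerization bound analysis,
and activation-free-energy / seeding predictions — all exercisable on
synthetic data.

## Who this is for

People studying protein-aggregation kinetics — in particular the early,
oligomer-dominated phase that bulk assays (ThT fluorescence, light
scattering) barely see.  The package takes two kinds of input: kinetic
time courses of soluble monomer *m*(*t*) and oligomer number
concentration *x*(*t*), and time-binned two-channel photon traces from
single-molecule confocal measurements.  From the traces it extracts
oligomer counts, apparent sizes and FRET efficiencies; from the time
courses it extracts microscopic rate constants; and from those it derives
how disease mutations reshape the aggregation energy landscape and how
effective oligomer seeding would be, including inside a cell.

## The model

Monomers *m*, structurally distinct oligomers *x* (average length *x*ₐ),
and fibrils *f* (average length *f*ₐ), connected by nucleation (*k*ₙ,
order *n*꜀ = 2 in monomer), oligomer dissociation (ǩₙ), monomer-dependent
oligomer→fibril conversion (*k*₊), and fibril reversion (*k*off):

    dx/dt = kₙ·m^nc − ǩₙ·x − k₊·m·x + koff·f
    df/dt = k₊·m·x − koff·f
    dm/dt = −xₐ·(kₙ·m^nc − ǩₙ·x) − (fₐ − xₐ)·(k₊·m·x − koff·f)

Total monomer mass *m* + *x*ₐ·*x* + *f*ₐ·*f* is conserved exactly.  The
conversion step is the point: a classical single-species
nucleated-polymerization model provably cannot reproduce nanomolar
oligomer numbers and micrometre-long fibrils at the same time (the
`classical_np` module implements those bound arguments), while the NCP
model fits both.  Burst-derived quantities follow standard two-channel
conventions: apparent size 2·(I_D + I_A/γ)/⟨I_D⟩ and FRET efficiency
I_A/(I_A + γ·I_D).  Mutation effects are summarized per process as
ΔΔG‡ = −ln(*k*mut/*k*wt) in RT units.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

Simulate wild-type K18 at the standard in-vitro condition (10 μM, the
calibrated reference constants), estimate the oligomer seed dose that
doubles the fibril-formation rate, and compare the ΔK280 variant:

```python
import numpy as np
from taukinetics import integrate, seeds_to_halve, ddg_table
from taukinetics import reference

traj = integrate(reference.K18, reference.IN_VITRO, np.linspace(0, 8, 17))
for i in (0, 2, 6, 16):
    print(f"{traj.times[i]:4.1f}  {traj.m[i]:5.2f}  "
          f"{traj.x[i]*1e3:5.2f}  {traj.fibril_mass[i]:5.2f}")

x0 = seeds_to_halve(reference.K18, reference.IN_VITRO)
print(f"seed dose doubling the K18 fibril-formation rate: {x0*1e3:.1f} nM")

table = ddg_table(reference.K18, reference.K18_DK280)
for name, e in table.entries.items():
    print(f"ddG({name}) = {e.value:+.2f} RT")
```

prints

```
 0.0  10.00   0.00   0.00
 1.0   8.38   4.22   1.61
 3.0   5.49   4.80   4.50
 8.0   4.96   4.01   5.03
seed dose doubling the K18 fibril-formation rate: 5.4 nM
ddG(k_n) = -4.90 RT
ddG(k_n_rev) = -1.50 RT
ddG(k_plus) = +2.50 RT
ddG(k_off) = +1.70 RT
```

Columns are time (h), soluble monomer (μM), oligomer number
concentration (nM) and fibril residue concentration (μM): half the
protein fibrillizes within ~3 h while oligomers stay near 5 nM — about
0.1% of soluble molecules.  A few-nanomolar oligomer spike is enough to
double the rate of fibril formation, because nucleation is the
bottleneck.  The ΔΔG table says the ΔK280 deletion strongly accelerates
nucleation (−4.9 RT) while slowing the oligomer→fibril conversion.

A `taukin` command-line tool wraps the same functionality
(`taukin simulate`, `taukin bursts`, `taukin fit`, `taukin ddg`,
`taukin seed`, `taukin classical-bound`, `taukin synth ...`); run
`taukin --help`.

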