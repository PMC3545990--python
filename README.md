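# tightbind

Analysis tools for **slow, tight-binding inhibition of serine proteases by
Kunitz/BPTI-type inhibitors**, with a companion suite of **structural
measurements for protease–inhibitor interfaces**.

The package is aimed at enzymologists and structural biologists studying
protein protease inhibitors such as aprotinin (BPTI) and textilinin-1 (a
Kunitz inhibitor from *Pseudonaja textilis* venom) acting on plasmin, plasma
kallikrein and trypsin — a regime where the inhibitor concentration is
comparable to the enzyme concentration, equilibration is slow on the assay
timescale, and progress curves must therefore be analysed by numerical
integration rather than classical steady-state rate laws.

## What it computes

**Kinetics.** Continuous chromogenic assays are modelled as competitive
binding with Michaelis–Menten turnover under the quasi-steady-state
approximation:

    E + I  <=>[k_on][k_off]  EI            (one-step scheme)
    E + I  <=>  EI  <=>[k_f][k_r]  EI*     (two-step isomerization scheme)
    E + I  ->[k_on]  EI                    (irreversible scheme, k_off = 0)

    dP/dt  = k_cat · E_free · S / (K_m + S)
    dEI/dt = k_on · E_free · I_free / (1 + S/K_m) − k_off · EI  (± isomerization)

Free-species concentrations follow from exact conservation of the enzyme,
inhibitor and substrate totals. The engine provides

- stiff ODE simulation of progress-curve families (`simulate_progress`),
  with the Morrison–Walsh closed form
  `P(t) = vs·t + (v0 − vs)(1 − e^(−kobs·t))/kobs` and
  `kobs = k_off + k_on·[I]/(1 + S/K_m)` as analytic limits,
- a seeded synthetic-data generator reproducing the standard three assay
  designs (plasmin 0.5 nM, kallikrein 1.0 nM, trypsin 0.5 nM with their
  inhibitor ladders),
- simultaneous (global) nonlinear regression of whole families with shared
  `k_on`, `k_off` (Levenberg–Marquardt on log-rates, multi-start),
- model discrimination by AICc Akaike weights plus the variance-ratio
  (F) test, with an automatic irreversible refit when `k_off` comes out
  undetermined, and
- derived constants: `Ki = k_off/k_on` with
  `cv(Ki) = sqrt(cv(k_on)² + cv(k_off)²)`,
  `t½(on) = ln2/(k_on·[I])` at a 1 µM reference, `t½(off) = ln2/k_off`,
  and selectivity fold-ratios.

**Structure.** Coordinate files (PDB/mmCIF via gemmi) feed a measurement
suite: Kabsch least-squares superposition and Cα RMSD; the *docking angle*
(rigid rotation relating two copies of an inhibitor after superimposing
their protease partners); IUPAC χ1 dihedrals (catalytic-histidine rotamers);
distance-classified contacts (hydrogen bond ≤ 3.2 Å, ionic ≤ 4.0 Å, van der
Waals, sub-van-der-Waals close approach); bond angles at a central atom
(tetrahedral-intermediate geometry at the P1 carbonyl carbon); and
solvent-accessible surface area by the Lee–Richards z-slice algorithm with
Chothia-style united-atom radii, from which buried interface areas are
computed as `SASA(A) + SASA(B) − SASA(AB)`.

## Worked example

```python
from tightbind import (RateParameters, SchemeId, builtin_designs,
                       generate_family, NoiseModel, analyze_family)
from tightbind.datasets import KINETIC_CONSTANTS
from tightbind.progress_fit import curve_r

rates = KINETIC_CONSTANTS[("textilinin-1", "plasmin")]
truth = RateParameters(k_on=rates.k_on.value, k_off=rates.k_off.value)
family = generate_family(builtin_designs()["plasmin"], "one_step", truth,
                         NoiseModel(seed=1))
fits, comparison, summary = analyze_family(
    family, ["one_step", "two_step"],
    fixed={"k_cat": 10.0, "K_m": 200e-6}, inhibitor="textilinin-1")

fit = fits[SchemeId.ONE_STEP]
print(fit.estimates["k_on"], fit.estimates["k_off"])
print(summary.K_i.value * 1e9, summary.t_half_off)
```

prints (seed 1):

```
k_on  = 1.720e+06 ± 4.6e+02 M^-1 s^-1
k_off = 7.500e-04 ± 5.1e-07 s^-1
Ki    = 0.4360 ± 0.0003 nM
t_half_on(1 µM) = 0.40 s, t_half_off = 15.4 min
Akaike weight (one-step) = 0.864, F-test p = 0.856 -> one_step selected
minimum per-curve correlation r = 0.9968
```

i.e. the global fit recovers the generating association/dissociation rates
(true values 1.72×10⁶ M⁻¹s⁻¹ and 7.50×10⁻⁴ s⁻¹), the dissociation constant
of ~0.436 nM follows as `k_off/k_on`, and model discrimination prefers the
simpler one-step scheme, as it should for data generated by it.

A command-line interface mirrors the library:
`tightbind simulate|fixtures|fit|report|run-all` for kinetics and
`tightbind geom distance|chi1|superpose|docking-angle|contacts|angles|sasa|buried|fetch`
for structures (selectors are `chain:resnum[:atom]`).

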