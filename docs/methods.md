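# Methods

## Kinetic model

The assays being modelled are continuous chromogenic protease assays:
enzyme is added to a 1 mL mixture of substrate plus inhibitor and
p-nitroaniline release is followed in time. Two regimes make the classical
steady-state treatment invalid here. *Tight binding*: inhibitor
concentrations (0–50 nM) are comparable to the enzyme concentration
(0.5–1 nM), so formation of the EI complex measurably depletes the free
inhibitor pool. *Slow binding*: equilibration takes seconds to minutes, so
the progress curves are biphasic. Both demand numerical integration of the
species balance.

The dynamics are competitive binding with quasi-steady-state (QSSA)
Michaelis–Menten turnover. Writing `E_free` for enzyme not bound by
inhibitor:

    dP/dt   = k_cat · E_free · S / (K_m + S)
    dS/dt   = −dP/dt
    dEI/dt  = k_on · E_free · I_free / (1 + S/K_m) − k_off · EI
              − k_f · EI + k_r · EI*          (isomerization terms, two-step only)
    dEI*/dt = k_f · EI − k_r · EI*

The factor `1/(1 + S/K_m)` is substrate protection: under the QSSA only the
substrate-free fraction `K_m/(K_m + S)` of uninhibited enzyme is available
for association. It is required for internal consistency — without it the
simulated approach rate would be `k_off + k_on·I` while the closed-form
limit used as an oracle (`kobs = k_off + k_on·I/(1 + S/K_m)`) and the
standard competitive slow-binding analysis both carry the protection
factor; with it, simulation and the Morrison–Walsh curve agree to <1% in
the excess-inhibitor limit.

The integrated state is the reduced vector `(EI, EI*, P)`; free species are
reconstructed from the conservation laws, so the enzyme, inhibitor and
substrate totals are conserved to machine precision by construction. When
`k_f = 0` the EI* equation is dropped entirely, which makes the one-step
scheme and the degenerate two-step scheme agree bit-for-bit — the nesting
property that scheme discrimination relies on. Integration uses LSODA with
rtol 1e-8 and atol 1e-12 M (nanomolar species with second-order terms make
the system stiff); output product is clamped to be non-decreasing at the
float level.

### Parameters

| parameter | units | default | role |
|---|---|---|---|
| `k_on` | M⁻¹ s⁻¹ | fitted | association rate constant |
| `k_off` | s⁻¹ | fitted | dissociation rate constant (0 = irreversible) |
| `k_isom_f`, `k_isom_r` | s⁻¹ | fitted (two-step) | isomerization of EI to a tightened EI* |
| `k_cat` | s⁻¹ | 10 | turnover number of the chromogenic substrate |
| `K_m` | M | 200e-6 | Michaelis constant |
| `S_0` | M | 500e-6 | substrate concentration |

The substrate constants for the chromogenic substrates used with these
enzymes are not published, so they are documented configuration rather than
measurements. All derived-constant results are insensitive to them in the
excess-substrate designs: the uninhibited control curve anchors the
turnover scale, and `k_cat·E_total` can alternatively be freed as one
shared nuisance scale (`fit_turnover=True`).

## Synthetic data generator

`synthetic_assay` emulates the three standard family designs — plasmin
0.5 nM against 0, 2, 5, 10, 15, 20, 40, 50 nM inhibitor; plasma kallikrein
1.0 nM against 0, 3, 6, 12, 24 nM; trypsin 0.5 nM against 0, 2, 3, 4, 6,
11, 19, 21 nM — over 1800 s sampled at 1 s (association half-lives at these
ladders are seconds-to-minutes and dissociation half-lives minutes, so both
phases are covered). Noise is additive, homoscedastic, Gaussian on the
signal, seeded. The default sd (5e-9 signal units, i.e. 5 nM product) was set so that every curve of every design — including the
nearly flat most-inhibited plasmin curve — keeps an observed-vs-fitted
correlation above 0.99, matching how such fits are reported; at that level
the kallikrein design yields rate-constant CVs of ~15–35% (weak inhibition
at 0–24 nM against a ~1.9 µM dissociation constant leaves the rates barely
identifiable) while the plasmin and trypsin designs are far cleaner.

What the generator does **not** emulate: photometric drift, heteroscedastic
or correlated noise, outliers, pre-incubation protocols, enzyme autolysis,
product inhibition. Passing recovery tests therefore demonstrate
correctness of the estimator under the stated noise model, not robustness
to real-world instrument artifacts.

## Global fitting and inference

All curves of a family are fitted simultaneously with `k_on`, `k_off`
(plus isomerization rates for the two-step scheme) shared across curves.
The objective is unweighted least squares on the signal, minimized by
Levenberg–Marquardt on log10-transformed rates — positivity is enforced by
the parameterization and the tight-binding objective is better conditioned
in logs. Starting values come from a classical two-stage analysis (per-curve
Morrison–Walsh fits, then a linear regression of `kobs` on the
protection-corrected inhibitor concentration); a small multi-start
(3 decade-shifted starts by default) guards against bad basins. In the
scheme-comparison driver, richer schemes are warm-started from the simpler
scheme's optimum and a single start, which is both faster and more stable.

Standard errors are Gauss–Newton: `(JᵀJ)⁻¹ · rss/(n−p)` on the log scale,
propagated to the natural scale. A singular covariance flags the fit
non-identifiable rather than silently reporting zeros. Seed-sweep
calibration checks (20 seeds) verify median relative bias below 5% and
empirical estimate scatter within a factor 2 of the mean reported SE.

Scheme discrimination uses AICc (`n·ln(rss/n) + 2p + 2p(p+1)/(n−p−1)`) and
Akaike weights together with the extra-sum-of-squares F test. AICc rather
than AIC is deliberate: it converges to AIC as n grows and protects the
small-family case. The selection rule is parsimony-first — a more complex
scheme is accepted only when its Akaike weight exceeds 0.5 *and* the F test
rejects the simpler scheme at α = 0.05. When a selected reversible fit
leaves `k_off` with a CV above 100%, the family is automatically refit
under the irreversible scheme (`k_off = 0`) and the comparison redone; this
is the standard rescue for apparently irreversible inhibitors, where the
reversible `k_off` estimate is meaningless.

Derived constants: `Ki = k_off/k_on` exactly; its error propagates as
`cv(Ki) = sqrt(cv(k_on)² + cv(k_off)²)` (first-order, treating the two rate
estimates as uncorrelated — the same convention as the source analyses,
slightly conservative when the covariance term is negative).
`t½(on) = ln2/(k_on·[I])` is reported at a 1 µM reference inhibitor
concentration; `t½(off) = ln2/k_off` in minutes. For irreversible pairs the
dissociation half-life is absent and a literature equilibrium constant may
be carried through instead.

## Structural measurements

Coordinates are read verbatim (plasminogen numbering for microplasmin,
chymotrypsinogen numbering for trypsin); one conformer per atom is kept
(highest occupancy, ties to altloc A). Superposition is least-squares
(Kabsch, via an SVD-based rotation fit) over Cα atoms paired by residue
number with unpaired residues dropped. The docking angle between two
copies of a complex superposes the protease partners, applies that
transform to the first inhibitor copy, and reports the axis–angle magnitude
of the residual best-fit rotation onto the second copy; it is symmetric in
the argument order to numerical precision.

χ1 is the signed IUPAC dihedral N–CA–CB–γ (γ = OG/OG1/SG/CG1/CG by residue
type); an eclipsed arrangement reads 0°. Rotamer differences are reported
signed in this convention (a stated rotation "by −157°" is convention
dependent; the signed IUPAC difference plus its magnitude are both
available). Contacts are heavy-atom distance classifications — no hydrogens
exist at these resolutions — with priority ionic (opposite formal-charge
groups ≤ 4.0 Å) > hydrogen bond (donor/acceptor pair ≤ 3.2 Å) >
sub-van-der-Waals close approach (< 3.4 Å) > van der Waals (≤ 4.0 Å);
donor/acceptor and charged-group membership come from fixed per-residue
tables (backbone N excluded for proline).

SASA is Lee–Richards: each atom sphere, expanded by the 1.4 Å probe, is cut
by planes normal to z at 0.1 Å spacing (0.05 Å or finer in the oracle
tests); on each plane the arc of the atom's circle not inside any
neighbouring expanded sphere is merged-interval integrated, and each slab
contributes `accessible_arc · R · slab_height`. The planes lie on an
absolute grid and the outermost slabs absorb the polar caps, so an isolated
sphere is exact and areas of disjoint subsets add exactly — which makes
`buried = SASA(A) + SASA(B) − SASA(AB)` free of grid jitter and exactly
zero for separated parts. Because the slicing direction is fixed in space,
rigid rotation of the input changes the discretization slightly; the error
is below ~0.5% at 0.02 Å spacing and is the stated tolerance in the
invariance tests. Radii are Chothia-style united heavy-atom values
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.90 Å); hydrogens are ignored, unknown
elements are an error, and waters are excluded unless requested. The
independent cross-checks are the analytic sphere, a brute-force spherical
quadrature oracle, and a Shrake–Rupley implementation from another library
run with the same radii.

## Problem sizes and determinism

The default test and acceptance computations use the full three assay
designs at 1800 s / 1 s sampling for single fits; seed-sweep calibrations
subsample to 5 s so that twenty replicate fits stay inexpensive, a choice
that only widens per-fit SEs and does not bias estimates. All randomness
(noise, multi-start jitter, quadrature oracles) flows from explicit integer
seeds; reruns with the same configuration produce byte-identical JSON.

## Known limitations

- The kinetic engine does not model pre-incubation, enzyme autolysis,
  product inhibition, absorbance-path optics, or heteroscedastic noise.
- Substrate constants (`k_cat`, `K_m`, `S_0`) are assumed, not measured;
  only excess-substrate conclusions are robust to that assumption.
- The kallikrein design barely inhibits at its printed ladder given a
  ~1.9 µM dissociation constant, so rate CVs there are intrinsically large
  (tens of percent); this mirrors the published uncertainty for that pair.
- Crystallographic symmetry mates are not generated; packing analyses are
  limited to the deposited asymmetric-unit contents.
- SASA carries the orientation-dependent discretization inherent to
  z-slicing (below ~0.5% at fine spacing).
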