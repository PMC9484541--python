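# Methods

## The survival model

Cell survival after a train of electroporation pulses is modelled with a
Fermi (logistic) dose-response in the electric field strength *E* (V/cm):

    S(E, N) = 1 / (1 + exp((E − Ec(N)) / Ac(N)))
    Ec(N) = E0 · exp(−k1 · N)
    Ac(N) = A0 · exp(−k2 · N)

*Ec(N)* is the field at which half of the population dies after *N* pulses
and serves downstream as the irreversible-electroporation threshold;
*Ac(N)* sets the width of the transition. The four cell-specific
coefficients (E0, k1, A0, k2) capture the whole dose-response surface at a
fixed pulse duration; pulse frequency is not a model input, so the model
should not be extrapolated to high-frequency bursts.

The coefficients are estimated in two steps:

1. **Stage 1** — for each pulse number, a two-parameter logistic fit of
   mean replicate viability (fraction) against field strength. At least
   three distinct field levels are required. Initialisation: *Ec* at the
   field whose mean viability is nearest 0.5, *Ac* at a quarter of the
   field span; up to six perturbed restarts; bounds (0, 10⁵] on both.
2. **Stage 2** — two independent exponential fits of the stage-1 *Ec* and
   *Ac* series against pulse number, each reporting its own R².
   Initialised by log-linear regression, with a fallback start grid of
   decay rates in [−0.02, 0.05]. Decay rates are bounded to [−0.1, 0.1]:
   small *negative* rates occur in the published database (*Ac* can grow
   with pulse number), so the fits must not force positivity.

Viability is stored as a percentage and divided by 100 for fitting. Values
above 100% (low-field proliferation) are retained; the logistic simply
fits such points poorly, which shows up as a low stage-1 R² exactly as in
the published tables. Duplicated field levels are averaged before fitting.
Stage-1 fits use replicate means rather than individual wells; with
homoscedastic replicate noise the two choices give identical least-squares
estimates, and means are what dose-response tables report.

Two fallback models are provided for data a single exponential cannot
represent: a double-exponential decay law for *Ec(N)* and *Ac(N)* (four
parameters per curve, requiring at least five pulse numbers; the two terms
are exchangeable, so only predictions are identified), and a power law
E = a·(tp/t0)^b linking a characteristic lethal field to pulse duration
(t0 = 1 ms), fitted exactly in log-log coordinates. The power law is fitted
by default to the Ec(100) threshold versus duration, since that is the
summary quantity the database tabulates per duration. Neither fallback is
invoked automatically unless the single-exponential stage-2 fit fails.

R² is reported as computed, including negative values (a fit worse than
the mean), again matching the published database. Degenerate inputs —
constant viability across all fields, all-dead plates — raise explicit
fit-failure errors rather than returning garbage coefficients.

## The bundled databases

`data/cell_coefficients.csv` holds the published coefficient sets for 20
digestive-system cell lines (esophagus, stomach, colon, bile duct, liver,
pancreas) at pulse durations of 25, 50, 75 and 100 μs — 80 entries, one of
which (PANC-1 at 25 μs) required the double-exponential fallback and has no
published single-exponential coefficients (stored as NA). The tabulated
Ec(100) column is reproduced by E0·exp(−100·k1) to better than 0.001 V/cm
for every complete row, which the test suite verifies. The stomach line is
named GES-1; the spelling "GSE-1" found in some sources is accepted as an
input alias.

`data/tissue_properties.csv` holds per-organ electrical conductivity,
density, heat capacity, thermal conductivity, blood perfusion and
metabolic heat generation used by the simulator.

## The synthetic-data generator

Raw replicate-level viability data are not redistributable, so the
generator emulates the assay around a known coefficient set: nine field
levels (250–3000 V/cm), nine pulse numbers (10–90), durations from
{25, 50, 75, 100} μs, ten replicates per condition. Replicate noise is
additive Gaussian on the viability fraction, truncated at zero, with
default SD 0.03 — a modelling choice on the scale of typical colorimetric
assay scatter, not a published value. An optional stimulation term
`boost · exp(−E/cutoff)` reproduces the qualitative low-field
proliferation effect (viability above 100% below ~500 V/cm) and vanishes
at ablative fields. The generator does not emulate plate-layout artefacts,
heteroscedastic noise, cuvette electrochemistry or inter-passage
variability, so parameter-recovery results bound estimation error under
idealised noise only, not assay systematics.

Parameter-recovery checks use five bundled 100 μs coefficient sets
(KYSE-150, MKN-45, SW-480, L-02, HuCCT-1) chosen so that the half-lethal
field at the smallest pulse number lies inside the emulated field range —
sets whose Ec(10) exceeds 3000 V/cm (e.g. MGC-823) force stage 1 to
extrapolate and are intrinsically harder to recover; this is a property of
the assay design, not of the fitting code.

## The injury simulator

A homogeneous 2D tissue slab (default 40 × 40 mm, 0.25 mm grid) with two
needle electrodes (1 mm diameter, 10 mm apart, one at the pulse voltage
and one grounded) — an explicit stand-in geometry, configurable in
`DomainSpec`. Physics:

* **Potential**: ∇·(σ∇V) = 0 with Dirichlet electrodes and zero-flux outer
  boundaries, 5-point finite differences, direct sparse solve. For
  homogeneous σ the conductivity cancels. Verified against the
  parallel-plate solution (exact) and the analytic two-wire potential
  (≤ 5% of the applied voltage at default resolution away from electrode
  surfaces, ≤ 2% at half spacing; the residual error is dominated by the
  staircase rasterisation of the circular electrodes).
* **Bioheat**: Pennes' equation with the Joule source averaged over the
  pulse duty cycle (10⁻⁴ at 100 μs / 1 Hz); 0.1 s backward-Euler steps
  with a factorised sparse operator (unconditionally stable), or an
  explicit stepper with a stability guard for verification work. The outer
  boundary is held at 37 °C; the electrode interiors deposit no Joule heat
  (perfect conductors) but are not otherwise thermally distinguished.
  Per-pulse microsecond transients are not resolved: at 1 Hz the tissue
  integrates the deposited energy, so N pulses are N seconds of averaged
  heating. Perfusion (ml·min⁻¹·kg⁻¹) is converted to a volumetric sink
  with blood density 1050 kg/m³, blood heat capacity 3617 J/(kg·°C),
  arterial temperature 37 °C.
* **Damage**: electrical-injury probability 1 − S(|E|, N) where |E| ≥
  Ec(N) and 0 below the threshold (reversible electroporation); thermal
  injury from the Arrhenius integral Ω with P = 1 − exp(−Ω), accumulated
  by trapezoidal quadrature over the temperature history (exact for
  constant temperature, additive over partitions). Default kinetics
  ζ = 7.39 × 10³⁹ s⁻¹, Ea = 2.577 × 10⁵ J/mol — widely used soft-tissue
  coagulation values adopted as an external assumption (no organ-specific
  kinetics are bundled); configurable per run. At body temperature these
  kinetics accumulate Ω ≈ 0.06 over 200 s, safely below the 0.5
  injury-probability threshold.
* **Area ratios**: injured area (probability strictly above 0.5) divided
  by tissue area by node counting, electrode interiors excluded from
  numerator and denominator.

Temperatures are stored in °C and converted to K only inside the Arrhenius
exponent. The field is solved once per run: conductivity changes during
electroporation (electro-thermal coupling) are out of scope.

## Numerical and design notes

* Survival S(E, N) is *not* globally monotone in N: below the crossing
  field, a shrinking Ac(N) raises survival slightly with more pulses.
  This is the model pathology the explicit Ec(N) threshold removes; the
  monotonicity tests therefore run over the assay's design range
  (≥ 250 V/cm), and the injured *area* is exactly monotone in N whenever
  k1 ≥ 0 because it depends on the threshold alone.
* The injured area is **not** always monotone in pulse duration: several
  published coefficient pairs have Ec(N) curves that cross at high N
  (e.g. the 75 vs 100 μs sets of KYSE-410), so their longer-duration
  ablation areas are smaller near N = 100. One qualitative-structure test
  asserts strict duration monotonicity and fails on exactly those pairs;
  it is kept as an honest record that the duration trend is a tendency of
  most, not all, coefficient sets.
* All stochastic routines take explicit seeds (generator default
  20220905). Problem sizes in the test suite are chosen to keep the full
  run around two minutes: the six-organ 200 s thermal sweep runs at the
  default 0.25 mm resolution (~45 s), and recovery studies use 20 seeds
  per truth set.
* A spacing of at least four grid cells across an electrode diameter is
  enforced; coarser grids misrepresent the electrode boundary badly enough
  to distort the near field.
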