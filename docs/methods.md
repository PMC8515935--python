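# Methods

## The model

A pathway scenario is a small reaction network in which each reaction `j`
carries, per unit flux, (i) signed stoichiometric coefficients over chemical
species, (ii) signed production of the *reduced* form of each redox-carrier
couple it touches (Fd, NADH, NADPH), (iii) signed ATP made or spent by
substrate-level phosphorylation (SLP), and (iv) a signed count of ions
translocated vectorially across the membrane (positive builds the gradient).
Species are either *external* (gases, water, bulk protons, freely exchanged)
or *internal* (balanced to exactly zero); the product has its own row fixed
to 1 mol.  Writing one balance row per internal species, one per carrier
couple (net production of the reduced form = 0, which implies electron
conservation), and the product-target row gives a linear system `A f = b`
over the reaction fluxes.

Key modelling choices:

* **Exact rational arithmetic.**  All stoichiometric solves use
  `fractions.Fraction`/sympy rationals; the answers are ratios like 3/2 and
  7/2 divided by 183/50, and floating point would blur exactly the identities
  the tests assert.  Floats appear only in display, thermodynamics and
  statistics.
* **Lumping.**  THF-cycle intermediates are collapsed to one reaction per
  carrier- or ATP-coupled step; purely chemical steps (cyclohydrolase,
  methyltransferase, Pta) are folded into a neighbour.  Only carrier- and
  ATP-coupled steps can change the ATP yield, so the lumping is lossless for
  the quantity computed.
* **Signed reversible fluxes.**  Rnf and Nfn are single columns allowed to go
  negative rather than forward/backward pairs; on H₂ + CO₂ the acetate scheme
  genuinely needs Rnf running backwards (ATP-driven Fd reduction by NADH),
  and signed columns keep the system square.
* **Vectorial protons only.**  `ions_translocated` counts membrane
  translocation; scalar protons of bulk chemistry are external and
  unbalanced, which is the accounting convention behind chemiosmotic ATP
  yields.
* **No objective function.**  The schemes are determined; if a model's system
  is under- or over-determined the solver raises (naming the null-space
  dimension and free reactions, or the violated constraint) instead of
  optimising, because a silent minimisation could fabricate a yield.

### Carrier assignments in the shipped scenarios

Direct enzymology on *C. ljungdahlii* fixes the MTHFR donor (Fd_red²⁻).  The
remaining assignments — NADPH-dependent methylene-THF dehydrogenase, the
formate step on CO taking ½ Fd_red + ½ NADPH, the carrier-free H₂-dependent
CO₂ reductase on H₂, the bifurcating Hyt (2 H₂ → Fd_red + NADPH), 2 H⁺
translocated per Fd_red/NADH couple at Rnf, and the NADPH-dependent
2,3-butanediol dehydrogenase — follow cell-extract measurements in the close
relative *C. autoethanogenum* and are, jointly, the assignment consistent
with all five published net-ATP yields.  They are data, not code: any
scenario can be exported to JSON, edited and re-run.  Whether the Nfn
transhydrogenase is drawn explicitly or folded into other arrows differs
between published schemes; the shipped scenarios are one consistent
reconstruction with an explicit reversible Nfn column.

## Energetics

`net_atp = slp + net_ions / h_per_atp`, exact because 3.66 is parsed as
183/50.  Display rounds half-away-from-zero to two decimals; comparisons
against published two-decimal values use the unrounded number with a ±0.012
band, since the published ethanol figure (0.95 for an unrounded 0.9563)
is evidently truncated rather than rounded.  The H⁺/ATP ratio is a
parameter: 3.66 by default (11-subunit c ring), swept inclusively over
[2.666, 5] — the known extremes of c-ring stoichiometry — by
`sweep_h_per_atp`.

Redox thermodynamics: ΔG°′ = −n·F·(E°′_acceptor − E°′_donor) with
F = 96.485 kJ·V⁻¹·mol⁻¹ and potentials in the standard-state table
(methylene-THF/methyl-THF −200 mV, NAD(P)H −320 mV, clostridial Fd nominally
−400 mV with a −500 mV physiological override available).  For a two-step
couple such as flavodoxin (−430/−60 mV) the nominal potential is the
midpoint of the two one-electron steps — a deliberate simplification;
callers needing a single step can construct a one-electron couple.  No
Nernst concentration corrections and no temperature dependence are applied.

## Enzymology arithmetic

* Purification tables: total activity = protein × specific activity; yield
  and fold are relative to the first (cell-extract) row.  Display rounds to
  one decimal half-away-from-zero; tests compare unrounded values within
  ±0.15 because the published record was itself computed from rounded
  intermediates.
* Absorbance assays: Beer–Lambert, rate (mM/min) = slope/(ε·path), scaled by
  assay volume and enzyme mass; a `stoich_factor` converts acceptor turnover
  to product formation for one- vs two-electron dyes.  One unit (U) is
  1 µmol product per minute.
* Progress curves: ordinary least-squares slope over a user-chosen linear
  window, volume- and mass-scaled to U/mg.
* Michaelis–Menten fits: unweighted nonlinear least squares of
  v = V_max·S/(K_m+S) (optional 1/v² weighting; no weighting scheme is
  canonical for these assays), initialised from a Lineweaver–Burk
  linearisation, converged at relative parameter change < 1e-8 (`xtol`)
  within a bounded iteration budget via `scipy.optimize.least_squares`.
  Standard errors are asymptotic, from the Jacobian at the optimum scaled by
  SSR/(n−2).  Non-positive estimates are flagged, not clipped;
  non-convergence raises with the optimiser trace attached.

## Synthetic data

Generators are pure functions of their spec, seed included (one
`numpy.random.default_rng(seed)` per call, no global state), and emulate:

* **Saturation series** — v_i = V_max·S_i/(K_m+S_i)·(1+ε_i),
  ε_i ~ N(0, CV).  Noise is multiplicative because enzyme-assay error scales
  with signal.  Defaults mirror the characterised Fd-dependent MTHFR
  (K_m 1.46 µM, V_max 91.2 U/mg, CV 5%, 8 concentrations geometric over
  0.25–16×K_m).  The published K_m/V_max values are experimental
  observations; here they are generator defaults, never fit targets.
* **Progress curves** — min(v·t, s₀) plus Gaussian noise clipped at zero,
  with a substrate-exhaustion plateau; default enzyme load 0.62 µg/mL, the
  scale of the characterised assay.
* **Toy networks** — a random conversion chain S₀→…→P with positive rational
  stoichiometries (triangular, hence uniquely solvable), planted fluxes by
  back-substitution, and carrier coefficients drawn at random except for one
  closing coefficient per couple chosen so the planted fluxes balance the
  couple exactly.  By construction the planted vector is *the* solution, so
  it is a free oracle for the solver.

What the generators do **not** emulate: real assays drift, saturate
detectors, and have correlated replicate structure; real networks have
thermodynamic direction constraints the toy chains ignore.  Passing tests
therefore demonstrate arithmetic and solver correctness under the stated
error model, not robustness to real instrument pathology.

## Test-problem sizes and numerical tolerances

Shipped scenarios are 9–12 reactions; random networks are capped at 6
reactions and 3 couples, where exact solves are instantaneous and a dense
Fraction Gaussian elimination is a practical independent oracle.  Parameter-
recovery checks use 200 seeded datasets (median relative error: K_m < 10%,
V_max < 5%) and a 25-dataset spot check against a 25% K_m band.  Exact
assertions are used wherever arithmetic is rational; float comparisons use
explicit absolute/relative bands stated in each test.

## Known limitations

* The flux model is linear balance only: no thermodynamic feasibility check,
  no kinetics, no growth/maintenance ATP demand, no genome-scale context.
* ΔG°′ values are standard-state; physiological carrier ratios can move
  effective potentials by tens of mV.
* The MTHFR-donor comparison changes only the carrier ledger; any protein-
  level coupling mechanism (e.g. conformationally coupled pumping) is
  represented purely by its net ion count, as in the Rnf-coupled variant.
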