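# Methods

## The model

`c1flux` computes theoretical carbon yields for methanol-to-PHB conversion
by flux balance analysis on a small, curated network rather than a
genome-scale reconstruction. The network is assembled from modules:

* **core** — EMP glycolysis with kinase (Pfk) and phosphatase (Fbp) steps
  kept separate so flux can run both F6P→pyruvate and, gluconeogenically,
  G3P→F6P; the non-oxidative pentose phosphate rearrangements (Rpi, Rpe,
  two transketolase reactions, transaldolase), pyruvate dehydrogenase,
  the acetyl-phosphate node (Pta, AckA), and cofactor closure (below).
  Lower glycolysis (G3P→pyruvate) is lumped into one reaction producing
  2 ATP and 1 NADH per triose; the lumping is irrelevant to carbon optima.
* **c1** — Mdh (methanol + NAD⁺ → formaldehyde + NADH), Hps
  (formaldehyde + Ru5P → H6P), Phi (H6P → F6P): the RuMP entry.
* **nog** — phosphoketolase on F6P and on Xu5P, each splitting a sugar
  phosphate into acetyl-phosphate and a shorter sugar with no carbon loss.
* **phb** — PhaA (2 acetyl-CoA → acetoacetyl-CoA + CoA), PhaB (NADPH
  reduction), PhaC in monomer-releasing form (3HB-CoA → 3HB + CoA), and the
  3HB sink that serves as the FBA objective: PHB is a polymer, so its C4
  monomer is the flux proxy.
* **xump** — Das (formaldehyde + Xu5P → DHA + G3P) and Dak (DHA + ATP →
  DHAP + ADP), sharing Mdh with the c1 module.
* **frma** — the endogenous formaldehyde→formate drain (lumped
  GSH-dependent dehydrogenase) with a formate exchange. FBA optima never
  route flux through it, so adding or knocking it out leaves every optimum
  unchanged; it exists to make knockout scenarios faithful (with the drain
  present, severing Hps gives a feasible zero-production state instead of
  an infeasible one).

Everything lives in one cytosolic compartment; exchanges are single-species
boundary reactions. The analysis is yield-level — transport, gene-protein
rules, enzyme capacities and thermodynamic feasibility are out of scope.

## Carbon accounting

Coefficients are exact rationals (`fractions.Fraction`) end to end;
floating point appears only when the LP is assembled. Every internal
reaction in every shipped module has carbon imbalance exactly zero, which
is asserted as a library invariant. Acyl-CoA thioesters count only their
acyl carbons (acetyl-CoA = 2, acetoacetyl- and 3HB-CoA = 4); the CoA
carrier is catalytic and carbon-free in the bookkeeping. This is the
convention under which 3 CH₂O → pyruvate → acetyl-CoA + CO₂ yields 2/3,
and it is what makes the 67% / 100% ceiling arithmetic come out as
integers of small denominators.

## Cofactor closure and maintenance

With non-growth maintenance (NGAM) at its default of 0, all optima here are
carbon-limited, not energy-limited. Cofactors are therefore closed by
lumped pseudo-reactions instead of a respiratory chain: an irreversible
NADH→NAD⁺ "respiration" sink, a lumped oxidative phosphorylation reaction
producing `atp_per_nadh` ATP per NADH (default 2; the optima are provably
insensitive to this P/O-like ratio, and a test asserts equality at ratios
1 and 2), a reversible transhydrogenase coupling NADPH to NADH, and a free
ATP hydrolysis drain whose lower bound is the NGAM value. These lumped
reactions are intentionally not H/O balanced; the model's claims are carbon
claims, and only carbon balance is enforced for them.

No biomass reaction is included: production optima describe resting-cell
biocatalysis. NGAM and the ATP:NADH ratio are exposed as `core_module`
parameters for sensitivity runs.

## The linear program

`solve_fba` maximizes one reaction's flux subject to `S v = 0` and box
bounds, via scipy's HiGHS dual simplex at 1e-9 feasibility/optimality
tolerances. Substrate uptake follows a fixed-flux convention (both bounds
set to the stated rate); an upper-bound mode exists and gives identical
optima on these substrate-limited networks, which is tested. Reported
fluxes are rounded to 1e-9 to suppress alternate-optima jitter; when a flux
*distribution* is reported, a parsimonious second stage (minimize Σ|v| at
the fixed optimum) makes it deterministic. Acceptance-level claims
constrain only objective values and boundary fluxes — alternate interior
optima are legal. Infeasibility and unboundedness are returned as explicit
statuses, never as silent zeros.

The independent oracle `vertex_oracle` enumerates basic feasible solutions
by brute force (every rank-sized basis × every at-bound assignment of the
non-basic variables) and is guarded to ≤ 12 active reactions with finite
bounds; it exists only to check the solver and is never the production
path. A second independent route builds the same LP in cobrapy (GLPK) in a
test and compares optima.

## Yield reports

A yield report carries substrate and product fluxes, their carbon counts,
the C-mol yield as float and as an exact rational (LP floats are snapped to
rationals with denominators ≤ 10⁶ — far finer than any stoichiometric ratio
in these networks), and the CO₂ export flux. Pathway comparison is done on
the rationals so the headline "+50%" is exact rather than 49.3% from
pre-rounded decimals; the two-decimal form (0.67) is a display convention.
The acetyl-CoA ceiling operation attaches a temporary acetyl-CoA sink as
objective plus a carbon-free CoA supply exchange (the drained thioester
would otherwise strand its carrier), fixes the uptake, and reports the
percent carbon yield on acetyl carbons.

## Assay arithmetic

The assay chain mirrors a plate-reader kinetic protocol: an OLS standard
curve (free intercept, r² reported, warning below 0.98), absorbance→
concentration inversion, and an initial rate fitted over the first 5 points
with an automatic fallback to the longest prefix with r² ≥ 0.98 — an
operationalization of "read until steady state"; both window and threshold
are configurable, and a blank-subtraction pre-step is available. The curve
path is the default deliberately; an extinction-coefficient shortcut is not
provided.

The unit definition is concentration-based: 1 U = 1 mM substrate converted
per minute in the reaction mix, so total units equal the rate and specific
activity is 1000 × rate / protein_mg (mU/mg). This is taken literally from
the protocol being reproduced even though the conventional unit is
amount-based; `units="umol"` provides the conventional 1 µmol/min
interpretation using the 200 µL reaction volume (0.01 mM/min with 0.2 mg
protein: 50 mU/mg concentration-based, 10 mU/mg amount-based). The in-vivo
variant of the protocol states its unit in mmol/min, which conflicts
dimensionally with the mM/min definition; both are treated as
concentration-rate definitions here, and neither convention is asserted
against wet-lab activity tables — those are measurements, not computable
quantities. Whole-cell protein is estimated as OD₆₀₀ × volume × 125 mg
(0.250 g dry biomass per OD-liter, half protein), and PHB content is the
percent ratio of PHB to cell dry weight per liter of broth, with
PHB > biomass rejected as inconsistent input.

## Synthetic data

`make_known_optimum_network` emulates the small flux-consistent networks
the LP tests need: a unit-stoichiometry production chain whose substrate
bound is the unique binding constraint (interior capacities are drawn in
[1.5, 3]× the substrate bound), decorated with decoy branches that are
certificates, not beliefs — each decoy either ends in a dead-end metabolite
(steady state forces zero flux) or is zero-bounded. All metabolites in one
network share a carbon count, so decoys are carbon-balanced too.
`make_trace` emulates the plate-reader measurement: A(t) = intercept +
slope × rate × t + Gaussian(0, σ) at 1-minute reads, defaults 10 points,
rate 0.01 mM/min, curve slope 0.62 AU/mM — magnitudes typical of an NADH
assay at 340 nm. Both generators are pure functions of their seed (one
local `numpy` generator per call).

What the synthetic fixtures do *not* emulate: genome-scale network
statistics, enzyme saturation or lag phases in traces, heteroscedastic or
drifting baselines, and replicate-to-replicate protein variation. Passing
the recovery tests therefore shows the estimators are correct and unbiased
under the stated noise model, not that real traces are this well-behaved.

## Problem sizes and determinism

The pathway networks have ~30 reactions, so every LP solves in
milliseconds; property suites use 100 seeded oracle networks (≤ 12
reactions each, the enumeration guard) and 200 seeded traces per noise
level — sizes chosen so the full suite runs in seconds while the
statistical assertions (bias ≤ 2%, ±2 SE coverage ≈ 95%) are stable.
All randomness flows through explicit seeds; the FBA pipeline itself is
deterministic.

## Known limitations

* Yield-level abstraction only: no kinetics, no enzyme capacity, no ΔG
  filtering — the 100% MCC ceiling is a stoichiometric statement, not a
  prediction of achievable titer.
* The serine assimilation cycle is not shipped: its published yield figure
  depends on energy assumptions not restated in the source being
  reproduced, so a module could not be validated rather than guessed at.
* SBML import/export is not implemented; the JSON dialect is the
  serialization format, and the independent-solver cross-check is done
  in-memory via cobrapy.
* Wet-lab quantities (measured activities, fermentation PHB contents) are
  inputs to the calculation machinery here, never reproduced numbers.
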