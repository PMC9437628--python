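# Methods

## The model

`sphingosim` centers on a deterministic mass-action model of TNF-α–driven
sphingomyelin signaling in neurons.  The network has 73 species and 51
irreversible reactions organized in two arms that converge on two
non-consumed outcome accumulators, `CellSurvival` and `CellDeath`:

* **TNFR1 arm.**  TNF-α binds TNFR1; the ligated receptor recruits the
  adaptors TRADD, RAIDD and (directly at the receptor) FAN.  TRADD nucleates
  FADD, TRAF2 and RIP recruitment.  RIP together with RAIDD activates
  caspase-2 (→ death); FADD activates caspase-8; TRAF2 routes through
  NIK → IKK → NF-κB, whose transcriptional output cIAP2 neutralizes active
  caspase-8 (an anti-apoptotic, survival-credited reaction).
* **Sphingolipid arm.**  The TRADD/FADD adaptors activate acid
  sphingomyelinase and FAN drives neutral sphingomyelinase translocation;
  active SMase hydrolyzes sphingomyelin to ceramide (the enzyme enters the
  rate as a read arc and is not consumed).  Ceramide activates cathepsin D
  → BID → cytochrome-C release → caspase-3/9 → death; activates CAPK →
  Raf → MEK → ERK with both survival and death outputs; activates CAPP,
  which dephosphorylates active AKT; and is deacylated to sphingosine,
  whose phosphorylation yields S1P → S1P receptor → Gi-coupled receptor →
  PI3K → PIP3 → AKT survival signaling, with Ras/GAP cycling feeding Raf.
  SMS converts ceramide back to sphingomyelin.

All rates follow the law of mass action: for a reaction with rate constant
`kf`, `rate = kf · Π [Xi]^ci` over reactants *and* modifiers.  Modifiers
(read arcs) multiply into the rate with exponent 1 but have net
stoichiometry 0 — this represents catalysis without consumption.
Inhibitory interactions are ordinary mass-action consumption reactions
(e.g., an inhibitor sequestering its target), keeping the engine to a
single rate-law family.  Amounts are dimensionless relative concentrations
("RC"); time is in relative time units ("RTU").

A handful of modeling choices deserve comment:

* `cIAP2 + actCASP8 → cIAP2 + CellSurvival`: the NF-κB arm's anti-apoptotic
  effect is realized by crediting each neutralized caspase-8 to the survival
  accumulator.  This both captures the biology (blocked apoptosis is
  survival) and gives cIAP2 its observed place among the closeness-1 hub
  species.
* Cytochrome-C release consumes an intact-mitochondria pool species that is
  returned when the apoptosome forms, so the organelle pool cycles rather
  than depletes.
* Sphingosine inhibits PKC through a catalytic consumption reaction
  (sphingosine unconsumed), and carries a direct pro-apoptotic output.

## Initial conditions and kinetics

The 39 input species take their initial amounts from the bundled
average-gene-expression table (`data/table3_expression.csv`); derived
species and the accumulators start at 0.  Three inputs without expression
data (sphingomyelin, CAPK, the mitochondrial pool) are fixed at 8.0.

Rate constants are "adjusted" values in [0, 0.1].  Twelve are pinned by the
analysis itself (0.1 for reactions 1, 2, 8, 9, 12, 15, 27, 31, 38; 0.01 for
7, 49, 51).  The remaining 39 are calibrated once, inside [0, 0.1], so that
the model reproduces the study's qualitative outcomes — the homeostatic
survival/death balance at healthy input levels, the scan crossing points at
the adjusted values, the TNF-α dose behavior, and the caspase-inhibitor
response — and are frozen in `data/kinetics_adjusted.json`.  A second
scheme (`literature-where-known`) overrides the reactions with published
mass-action constants (0.185 μM⁻¹s⁻¹ for the TNFR-complex binding steps)
while keeping the calibrated values elsewhere.

## Simulation

`simulate` integrates the compiled ODE system with LSODA (stiff-capable,
adaptive) at `rel_tol 1e-6`, `abs_tol 1e-9`, sampling 1001 evenly spaced
points over [0, 100] RTU by default.  The analytic state Jacobian assembled
from the mass-action structure is supplied to the solver.  Peaks are read
off the dense output grid (the reported peaks are only resolved to ~2
significant figures, so grid resolution suffices; ties resolve to the
earliest time).  The balance gap is the signed terminal difference
`CellSurvival − CellDeath`; the model is "balanced" when |gap| is below 5%
of terminal survival — the operational definition adopted here, since no
numeric criterion accompanies the published balanced-state figure.

## Scans

Parameter scans clone the model with one rate constant swapped (21-point
grid over [0, 0.2] by default); entity scans swap one initial amount
(26 points over [0, 50]).  Terminal survival/death are recorded per grid
point; the crossing point interpolates the first sign change of their
difference linearly between grid neighbours (multiple crossings warn and
report the first).  "N-fold relative difference" is operationalized as the
terminal max/min ratio with an epsilon-guarded denominator — the near-equal
baseline makes the ratio the only self-consistent reading of fold language.

## Sensitivity analysis

Local sensitivities are computed by the forward variational system
`dS/dt = J_x S + ∂f/∂p` integrated alongside the state (inputs: all 51 rate
constants, or all 73 initial amounts, for which `S(0) = I`).  Sensitivities
are unnormalized and aggregated as `∫|S_ij(t)| dt` over the horizon
(trapezoid rule on the output grid); `max-abs` and `terminal-abs`
aggregations are available.  A repeated central-finite-difference estimator
(±1% relative perturbation) serves as an independent cross-check and agrees
within 2% on all entries above 1% of the column maximum.  Because the
aggregation integrates over the horizon, parameters acting early and on
persistent pools acquire large aggregates; rankings are therefore reported,
not absolute magnitudes.

## Network centrality

The reaction network maps to graphs in two modes: the drawn bipartite form
(species + interaction nodes; reactant → interaction, interaction →
product, read arcs in both directions) and the directed species projection
(each reaction contributes edges from every species it reads to every
species it produces).  Degree audits use the drawn-network convention — a
read arc counts as both incoming and outgoing.  Betweenness is
endpoint-excluded shortest-path betweenness (Brandes, via networkx),
normalized by (n−1)(n−2) on directed graphs; closeness is the reachable-set
convention `|R(x)| / Σ_{y∈R(x)} d(x, y)` over outgoing unit-weight paths
(0 when nothing is reachable) — the plain inverse-distance-sum would score
0 for most nodes of a weakly connected digraph.  Reported species
centralities for the flagship model use the directed species projection,
the mode whose values line up with the published ones (ceramide's
betweenness 0.085 vs 0.078 reported; cytochrome C closeness exactly
0.75; hub caspases/regulators exactly 1).

## Drug dosing

Drugs enter as species with irreversible mass-action sequestration
reactions, one per target (`drug + target → inert complex`), so delivered
drug mass is conserved between free and complexed forms.  Bundled drugs:
Etanercept (targets TNF-α), Nivocasan (pro-caspase-8 and pro-caspase-9) and
Scyphostatin (neutral SMase).  The default sequestration constant is 0.1
(the standard adjusted kinetic); Nivocasan's per-target constants are
calibrated (0.005 for caspase-8, 0.1 for caspase-9) to reproduce the
reported preferential caspase-9 blockade and the ≈2.5-fold survival/death
ratio at a sustained amount of 10 — the published table gives IC50s but no
in-model binding kinetics, so these constants are reconstruction parameters
like the uncited rate constants.  Repeat-dose schedules expand each row
into `repeat_count` boluses spaced by `interval`; dosed simulation
integrates piecewise, bumping the drug amount at each event with unchanged
tolerances.  Boluses are instantaneous even though the schedule rows carry
a rate field (amount/rate ≤ 0.8 RTU, far below the 5-RTU interval, so an
infusion would be indistinguishable at reported resolution); the field is
parsed and retained.

## Synthetic data

`synthetic_expression_table` draws input-species values from a normal
distribution truncated at 0.5 with mean 8.8 and spread 1.4 — the sample
mean and standard deviation of the bundled 39-entry table (the real values
are roughly symmetric with no heavy tail, so a truncated normal, not a
lognormal).  `random_mass_action_model` emits connected uni/bimolecular
networks with rate constants in (0, 0.1] and no synthesis-from-nothing, so
moiety conservation stays testable; a seeded spanning chain guarantees
connectivity.  All generators are byte-deterministic under their seed.
What these generators do *not* emulate: microarray noise structure (probe
effects, normalization artifacts), correlated expression across genes, and
any topological resemblance to real signaling networks beyond valid
mass-action structure — property tests passing on them certify the
*engines*, not biological fidelity.

## Numerical choices and degenerate inputs

* Stiffness: the cascades mix ~1-RTU binding transients with ~100-RTU
  accumulation, mildly stiff; LSODA switches method automatically.
* Nonnegativity is intrinsic to mass action from nonnegative initials;
  solver excursions are bounded by `abs_tol` (trajectories are asserted
  above −1e−8, not clipped).
* Zero states are exact fixed points; models with empty species lists are
  refused at export; validation reports all violations rather than the
  first.
* Scan grids must be strictly increasing and nonnegative; a fold ratio at a
  zero denominator is guarded at 1e−12.
* All test problem sizes (scan grids, 100-seed oracle sweeps, ≤12-node
  brute-force graphs) were chosen so exhaustive enumeration stays exact.

## Known limitations

* The complete 51-reaction table and most rate constants are reconstructed,
  not transcribed: the published narrative pins the topology's arms, eight
  degree audits, and a dozen constants, and the rest is calibrated to the
  reported outcomes.  Quantities that depend on the unpublished remainder
  (exact peak magnitudes, exact sensitivity magnitudes, near-tied
  centrality orderings) are reproduced approximately, and the shipped
  tests distinguish hard structural claims from calibrated ones.
* Sensitivity-rank comparisons depend on the (unpublished) aggregation the
  original analysis used; this package states its aggregation explicitly.
* No stochastic simulation, no Michaelis–Menten/Hill kinetics, no
  compartments, no PK absorption/clearance — all out of scope by design.
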