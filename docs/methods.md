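# Methods

This note records the models implemented in `methyloflux`, the
assumptions behind them, the parameters that matter, and the design
choices made where several defensible options existed.

## Constraint-based simulation

The feasible flux space is {v : S·v = 0, α ≤ v ≤ β} over the
compartment-tagged network.  The objective is the biomass
pseudo-reaction flux (units 1/hr) unless another reaction is named.
Numerical choices:

- **Solver.** All LPs and MIPs are solved with HiGHS through SciPy
  (`linprog` / `milp`), primal feasibility tolerance 1e-9, MIP relative
  gap 0.  HiGHS is deterministic, so repeated solves reproduce
  identical flux vectors bit-for-bit.
- **Infinities.** Unbounded fluxes are capped at ±1000 mmol/gDCW-hr
  when handed to the solver — the same big-M value used in the
  activity MIP — so "unbounded" outcomes cannot arise silently.
- **Alternate optima.** FBA optima are degenerate; a second stage
  minimizes Σ|v| with the stage-1 objective pinned (auxiliary
  variables t ≥ |v|).  Every derived statistic (P/O, CER, OUR, RQ,
  flux-sums) is computed from this parsimonious representative, which
  makes reports reproducible.  The choice of representative does not
  affect the objective value and, in the bundled network, not the
  reported gas exchange either (the proton and redox cycles leave no
  slack at the optimum).
- **Conditions.** Measured uptakes are equalities (a chemostat at
  steady state consumes what it consumes), while *availability* is
  expressed as a lower-bound-only `max_uptakes` entry.  The scan and
  the biotransformation analyses use `max_uptakes`, because clamping an
  internal reaction below the consumption a fixed supply would force
  must not be mistaken for biological infeasibility.
- **NGAM vs GAM.** Non-growth-associated maintenance is an equality on
  the dedicated `ATPM` reaction (subsystem "ATP maintenance");
  growth-associated ATP stays inside the biomass equation.  The two are
  never mixed.
- **Degenerate inputs.** An infeasible problem returns a
  `FluxSolution` with `status="infeasible"` and an empty flux map;
  downstream statistics refuse non-optimal solutions rather than
  propagating NaNs.

## P/O ratio

P/O is reported operationally as 0.5·v_ATPS3m/v_CYOOm with the oxidase
written per mol O₂ (two O atoms per turnover).  Retuning multiplies
the proton-translocation coefficient of the oxidase so that, when the
proton-motive cycle is the only link between respiration and ATP
synthesis, the reported ratio equals the target: with n_h protons per
synthase turnover the required pumping is 2·n_h·target per O₂.  In the
toy network all proton pumping is assigned to the oxidase and the
synthase uses 3 protons/ATP, giving P/O = pumped/6 in closed form;
this is a deliberate lumping — complex I/III pumping is folded into
the oxidase coefficient — chosen because it makes the tunable knob
exactly the coefficient the retuning operation adjusts.

## Maintenance estimation

The Pirt construction: q_s = D/Y_max + m_s fitted by unweighted OLS
(scipy.stats.linregress) over ≥ 2 distinct dilution rates.  The
substrate-to-ATP conversion runs through the model: Y_ATP is the LP
maximum of the ATP-maintenance flux at unit substrate uptake and zero
growth.  Both m_s and NGAM = m_s·Y_ATP are reported because the
conversion route (model-based vs literature yields) is itself an
assumption; a marginally negative noisy intercept is clamped to zero
on the ATP scale.  For the toy network on glucose, Y_ATP = 21.76
mmol ATP/mmol (2 glycolytic + 2 substrate-level + 12 NADH at P/O
1.48), which the test suite verifies against this hand computation.

## Flux-sum

Φ_i = ½ Σ_j |S_ij·v_j|.  Per-compartment pools are reported as-is; an
aggregate per base id uses each reaction's *net* base stoichiometry so
inter-compartment transport cancels instead of double-counting.  Both
are exposed because compartment-free turnover figures (e.g. "ATP
flux-sum") are conventional in the literature while the
compartmentalized values are the raw quantity.  Normalization across
conditions divides by the row maximum; an all-zero row normalizes to
zero by convention.

## Carbon-source screening

Each source is supplied at 1 C-mmol/gDCW-hr (molar uptake 1/n_C) with
every other carbon-containing exchange closed for uptake but open for
secretion, on otherwise unrestricted minimal medium (O₂, NH₄⁺,
phosphate, water).  NGAM defaults to zero in the screen so that the LP
is homogeneous (doubling the carbon supply doubles growth), which the
property tests exploit; any maintenance value can be passed in.  An
infeasible source is recorded with zero growth and a status flag.
Heat-map matrices are row-normalized absolute values.

## Flux-activity scan

Activity a_j = |v_j| is linearized per scanned reaction with one
binary: v = p − n, p ≤ My, n ≤ M(1−y), a = p + n, M = 1000.  The
growth floor defaults to 50 % of the condition-specific maximum; the
k-grid defaults to {0, 0.25, 0.5, 0.75, 1}.  Two clamp modes:

- **equality** (default): a_j = k·a_max — the semantics of an activity
  level reported on a k axis.  A clamp below a_min yields an empty
  feasible set; the achievable target flux is then reported as 0 with
  a flag, on the reading that an empty constraint set achieves
  nothing.  This matters for growth-essential reactions (the alcohol
  oxidase on methanol-only medium at k = 0).
- **inequality**: a_j ≤ k·a_max — always feasible when k = 1 is, and
  provably monotone in k; the invariant suite runs in this mode.

**Directional coupling.** A reaction is coupled to the target when the
maximum target flux (i) is 0 at k = 0 (infeasible counts as 0),
(ii) increases by more than 1e-6 from k = 0 to 1, (iii) is
non-decreasing in k, and (iv) is proportional to the clamp level with
least-squares R² ≥ 0.99.  The proportionality fit covers the
*clamp-binding region* — the rising limb plus the first plateau point
— rather than all k: once another resource caps the target (in the
bundled analysis, the 1 mmol/gDCW-hr acetoin supply), the clamp stops
binding and the plateau carries no information about coupling, yet
the reaction still imposes the upper limit that defines directional
coupling.  Fitting across the plateau would reject genuinely coupled
reactions whose activity headroom exceeds the external cap.

## The synthetic test bed

`build_toy_methanol_network` emulates, at ~59 reactions across
cytosol/mitochondria/peroxisome/extracellular space, the features the
analyses need: the full methanol pathway with both branches, three
alternative sugars/polyols, a respiratory chain with tunable P/O,
butanediol dehydrogenase, and a two-macromolecule biomass equation
(8 mmol protein-unit + 3 mmol glucan-unit per gDCW ≈ 42 C-mmol/gDCW,
GAM 25 mmol ATP/gDCW — yeast-like orders of magnitude).  Choices that
shape the test results:

- Lower glycolysis delivers its NADH directly to the mitochondrial
  pool (the lump subsumes the redox shuttle).  Consequently, on
  methanol the only *cytosolic* NADH sources are the dissimilatory
  FALDH and FDH steps, so the butanediol ceiling is set by
  dissimilation — the structure behind the AOD/FALDH/FDH coupling the
  scan must recover.  Glycerol and sorbitol regenerate cytosolic NADH
  through their dehydrogenases; glucose does not.
- Alanine synthesis is a redox-neutral lumped transamination, protein
  is an alanine polymer, carbohydrate a glucan unit.
- Every internal reaction balances C, N and O by constructed formulas;
  the biomass drain is the single flagged exception.
- Defaults: P/O 1.48, GAM 25, peroxisome included.  These are the
  study conditions for all tests and for the acceptance script.

What the toy network does **not** emulate: genome-scale redundancy
(isozymes beyond AOD, parallel pathways, byproduct secretion routes),
realistic biomass composition (lipids, nucleotides, cofactor
synthesis), regulation (e.g. glycerol repression of the methanol
pathway), and realistic magnitudes for absolute growth yields.
Passing tests therefore demonstrate that the *algorithms* are correct
and that the qualitative physiology (substrate ranking, energy
diversion on methanol, NADH-limited biotransformation) emerges from
the right mechanisms — not that numerical predictions transfer to a
real reconstruction.

Random oracle networks (4–15 reactions, all bounds finite) carry a
guaranteed substrate→biomass chain plus random connections; their LP
optima are cross-checked against exhaustive vertex enumeration, which
is exact for finite boxes.  Chemostat series follow q_s = D/Y_max +
m_s with multiplicative Gaussian noise, seeded.

## Problem sizes used in tests and acceptance

The acceptance run uses 50 random networks of 6–10 reactions for the
vertex-enumeration comparison (enumeration cost grows combinatorially;
these sizes keep the oracle exact and fast), 100 seeds for the noisy
maintenance recovery, and the full 58-reaction scan grid (58 reactions
× 5 clamp levels, two modes).  The complete suite plus acceptance
script runs in about a minute on one CPU.

## Known limitations

- The SBML reader covers the L3 core + fbc-v2 subset used by
  constraint-based models; kinetic laws, annotations and groups are
  ignored.
- Vertex enumeration requires finite bounds and ≲ 12 reactions.
- `set_po_ratio` assumes the proton-motive cycle is the sole coupling
  between the retuned oxidase and the synthase; in a network with
  proton leaks or alternative oxidases the realized operational P/O
  will differ from the target.
- Degenerate-optimum selection (min Σ|v|) is one of several accepted
  conventions; flux-sum values at alternate optima can differ even
  though the objective does not.
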