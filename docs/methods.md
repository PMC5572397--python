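# Methods

## The model

A genome-scale metabolic model (GEM) constrains steady-state fluxes `v`
(mmol/gDW/h) by mass balance `S v = 0` and bounds, and FBA optimizes a
cellular objective over that polytope. Fluxes through catalyzed reactions
are additionally limited by the catalytic capacity of the enzymes carrying
them: for enzyme *i* on reaction *j*,

    v_j ≤ kcat_ij · e_i ,

with `e_i` the enzyme's abundance (mmol/gDW) and `kcat_ij` its turnover
number. `enzgem` encodes this inequality *structurally* instead of as an
extra constraint row set: the stoichiometric matrix is enlarged with

* one **enzyme row** `prot_<accession>` per protein — a mass balance for
  enzyme capacity;
* a coefficient **−ν_i / kcat_ij** (kcat in 1/h) of that row in every
  catalyzed column, where ν_i is the subunit copy number within the
  enzyme's complex (1 for stand-alone enzymes);
* one **usage column** `draw_prot_<accession>` per enzyme producing one
  unit of its row, so the enlarged matrix has the original stoichiometry
  in the upper-left block, the kinetic coefficients in the lower-left
  block, and an identity over usages in the lower-right block.

Bounding the usage reaction then bounds every flux the enzyme carries.
Enzymes are *occupied*, not consumed: at steady state the usage flux is
the standing amount of enzyme committed to catalysis.

Four enzyme/reaction relationships need care, and each maps to a matrix
idiom:

* **Reversible reactions** are split into `<id>` and `<id>_REV` columns
  (both non-negative) so each direction can carry its own kcat; the same
  enzyme row serves both.
* **Isozymes** (OR in the gene rule): the reaction becomes an *arm
  reaction* `arm_<id>` (substrates → `pmet_<id>`, carrying the original
  flux bounds) plus one copy `<id>No1..Nok` per alternative
  (`pmet_<id>` → products, bounds [0, original ub]). The intermediate
  `pmet_` row forces the copies to sum to the arm flux, so the original
  bound caps the total. Copies are ordered by sorted protein ids.
* **Promiscuous enzymes** simply appear in several columns (possibly with
  different kcats); one usage column means the reactions compete for the
  same abundance.
* **Complexes** (AND in the gene rule): every subunit row gets a
  coefficient in the column, scaled by its stoichiometry ν_i; one shared
  kcat describes the complex's catalytic event.

Gene rules are normalized to disjunctive normal form (OR of ANDs) before
expansion, with duplicate and subsumed alternatives removed, so arbitrary
nesting such as `(A and B) or C` is handled uniformly.

## Turnover-number assignment

Each (reaction direction, enzyme group) pair is matched against a local
kinetics table (columns: EC, substrate, organism, kcat in 1/s) by stepwise
relaxation: L0 EC+substrate+organism; L1 drop organism; L2 drop substrate;
L3 EC only; L4 EC with the serial (last) digit wildcarded. At the first
level with hits the **maximum** kcat is taken — the fastest reported form
of the enzyme — which avoids over-constraining fluxes with slow outliers.
Choices behind this design:

* Organism is relaxed before substrate: the same catalytic step measured
  in another organism is biologically closer than a different substrate in
  the same organism. The level order is a parameter for users who
  disagree.
* Substrate matching is trimmed, case-insensitive, exact. No fuzzy
  chemistry — reproducibility beats recall, and the manual-curation table
  (reaction, protein, kcat overrides) covers misses.
* A complex is queried once with the union of its subunits' EC numbers.
* The backward direction of a reversible reaction is queried with the
  product side as substrates; if a restricted level order leaves it
  unmatched while the forward matched, the forward value is reused
  (recorded as such) rather than leaving the direction uncapped.
* Pairs with no hit anywhere are filled with the median of all successful
  assignments (or a user constant), flagged with provenance level −1.
  Median is robust to the heavy right tail of kcat distributions.

Ties at a level are broken by a stable sort (kcat descending, then EC,
substrate, organism), so assignment is deterministic.

## Units

Fixed package-wide: fluxes mmol/gDW/h; enzyme usage mmol/gDW; molecular
weight kDa ≡ g/mmol; kcat stored in 1/s in tables and converted once to
1/h (×3600) at expansion; protein masses and pool bounds g/gDW. Default
flux bound magnitude is 1000 mmol/gDW/h.

## Abundance constraints

Three regimes:

* **Shared pool** (no proteomics): a `prot_pool` row with one supply
  reaction bounded by σ·f·P_total (g/gDW); each usage draws MW_i g/mmol of
  pool, giving Σ MW_i·e_i ≤ σ·f·P_total. P_total is total cellular protein
  (g/gDW), f the mass fraction covered by model enzymes, σ the average
  in-vivo saturation — a single fitted scalar standing in for
  enzyme-specific saturations nobody has measured at scale.
* **Direct bounds** (measured enzymes): e_i ≤ μ_i + σ_i, the replicate
  mean plus one sample standard deviation (n−1; zero when only one
  replicate is detected). Proteins detected in fewer than a configurable
  number of replicates (default 2) are dropped. One SD is the
  flexibilization — not a multiplicative fudge — so tight, reproducible
  measurements constrain hard and noisy ones constrain softly.
* **Hybrid**: measured enzymes bounded directly; unmeasured ones share a
  pool bounded by σ·f_unmeasured·(P_total − matched mass), where matched
  mass is Σ MW_i·μ_i over measured model enzymes. The report exposes both
  the pre-σ pool mass (comparable to proteome databases) and the σ-scaled
  LP bound.

Measurements of multi-subunit complexes can be re-proportioned: each
measured subunit's mean is reset to ν_i times the complex's average
relative abundance (μ_i/ν_i), with SD scaled by the same factor — sensible
when some subunits sit at the detection floor.

Maintenance knobs: `apply_maintenance` rewrites the ATP-hydrolysis
coefficients of the biomass reaction to a given growth-associated
maintenance (GAM, mmol ATP/gDW) and sets the non-growth maintenance
reaction's lower bound (NGAM, mmol ATP/gDW/h). Typical literature values
shipped as CLI defaults: GAM 31 (aerobic) / 16 (anaerobic), NGAM 0.7,
σ ∈ {0.44 batch, 0.46, 0.51 chemostat contexts}, f = 0.4461 for the yeast
consensus network, amino-acid/nucleotide uptake cap 2 mmol/gDW/h in
non-minimal media.

## Simulation recipes

All LPs are solved with GLPK through COBRApy at feasibility tolerance
1e−9. Lexicographic recipes fix each stage's optimum with relative slack
1e−6 (exact equality re-fixing is brittle in floating point):

* **chemostat(D)** — fix growth = D, minimize substrate uptake, fix it,
  minimize enzyme mass Σ MW_i·e_i (unweighted Σ e_i available by flag).
* **batch(medium)** — open the medium bounds, maximize growth under the
  pool, then minimize total uptake, then enzyme mass. Unbounded growth is
  reported as a status telling the caller to add the pool.
* **yield envelope** — fix substrate uptake; for growth fractions
  0..100% of μ_max: fix growth, maximize the product exchange, fix it,
  minimize enzyme mass; convert to g/g with the supplied molar masses.
* **knockout** — usage upper bounds set to 0 for the listed proteins
  (blocks every reaction of a complex through its subunit row).
* **FVA** — per-reaction min/max at a fraction of the optimum;
  `fva_compare` converts the unconstrained model to irreversible format
  and maps each direction to its arm reaction (or same id) in the
  expanded model, reporting per-reaction range reduction and the
  fractions reduced/equal/increased.
* **Flux control coefficients** — each enzyme's kcats (in *all* its
  reactions: specific activity is one property of the protein) are scaled
  by 1+δ (δ = 1e−3 by default), the recipe re-run, and
  FCC_i = ((v′−v)/v)/δ. When the pool is the unique binding constraint
  the LP is homogeneous in the kcats and the coefficients sum to ~1.
* **σ fitting** — bisection on the pool bound until the observable
  (default: FBA optimum) is within 1e−4 of the target; errors out with
  the maximum attainable value when the target exceeds the σ = 1 optimum,
  and flags a boundary hit for targets at or below the σ→0 limit.

## Synthetic fixtures

`TOY1` is a four-metabolite linear chain covering every formalism exactly
once: a reversible enzyme with direction-specific kcats, an isozyme pair,
a two-subunit complex (stoichiometry 1 and 2), and a promiscuous enzyme.
kcats are round numbers (10, 5, 20, 4, 2, 1 s⁻¹) so the 1/h coefficients
are hand-checkable fractions (−1/36000 etc.), and every value resolves
from the bundled kinetics table at the exact-match level. `OVF1` is a
two-pathway resource-allocation model — high-yield/expensive respiration
versus low-yield/cheap fermentation under a 10 g/gDW pool — whose optimum
is a vertex of a two-variable polytope, derivable by hand and by the
brute-force vertex-enumeration oracle in the test suite. It reproduces
the overflow (Crabtree-type) switch analytically: respiration-pure for
substrate availability U ≤ 1, mixed for 1 < U < 10, fermentation-capped
ATP = 20 beyond.

What the fixtures deliberately do not emulate: realistic network size and
compartment structure, kcat measurement noise and annotation errors,
growth-rate-dependent biomass composition, and enzyme-specific
saturations. Passing tests therefore demonstrate the *mechanics* of the
transform and recipes — equivalence, capacity law, resource-allocation
switching — not predictive accuracy on a real organism, which depends on
the quality of the supplied kinetics and proteomics tables.

## Numerical choices and degenerate cases

* Solver tolerance 1e−9; structural validator tolerance 1e−12 on kinetic
  coefficients; stage-fixing slack 1e−6 relative.
* Isozyme alternatives with identical cost give degenerate flux splits;
  the minimized objective value is still unique and is what tests assert.
* An expanded model is detected (by `prot_`/`pmet_` ids) and refused as
  expansion input, so the transform is never double-applied.
* Reaction classes in the descriptor statistics are made disjoint with
  priority usage > pool > arm > exchange > transport > enzyme-matched >
  unmatched, so class counts add up to the totals by construction.
  Exchange = all ordinary metabolites on one side; transport = the same
  species (by name, else id stem) in two compartments.
* Numeric output in TSV files carries 12 significant digits.

## Known limitations

Upper bounds from kcat·abundance are soft constraints: regulation,
substrate-level under-saturation and post-translational control are not
modeled, so biologically infeasible solutions remain in the (smaller)
solution space. Compartment-specific enzyme pools, splice variants and
growth-rate-dependent protein content are out of scope. SBML round trips
preserve the stoichiometric structure but not assignment provenance;
`rehydrate_ec` reconstructs kcats and wiring from the coefficients and id
conventions, which requires those conventions to be intact.
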