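# Methods

## Model representation

A model is a list of rules `LHS -> RHS : rate` over named species. Rules
are parsed into multisets of (species, integer coefficient); writing
`X + X` and `2 X` is equivalent. `EMPTY` denotes the empty set, and
`(name)` marks a constant reservoir species whose abundance is a fixed
concentration, never part of the dynamic state. Rates are symbolic
expressions over parameters only: all state dependence comes from mass
action / combinatorics, so bimolecular kinetics with constant interaction
rates are the modelling scope (Hill or Michaelis–Menten forms are out of
scope). Reversible processes are written as two explicit rules. The symbols
`V` (system size), `t`, `E`, `P`, and the prefixes `Phi_` and `eta_` are
reserved for derived descriptions and rejected as user names.

Model algebra distinguishes two kinds of substitution:

* *parameter rewrites* (`g_A = v_A`, `v_A = mu + Delta/2`) are applied
  directly to the rate expressions;
* *species eliminations* (`U = N - A - B`) remove one species from the
  dynamic state and record a replacement expression that is applied to all
  **derived** objects (ODE drift, master-equation propensities, SSA
  propensities) rather than rewriting the rules. Each elimination lowers
  the dimension of every description by one. A symbol newly introduced this
  way (the conserved total `N`) becomes a parameter and is remembered so
  that finite-population descriptions can identify it with the system size.

## Count form versus concentration form

Two ODE representations are offered because they serve different purposes
and scale differently:

* the **count form** applies raw mass action to count symbols
  (`flux = rate · Π X^α`, no 1/V factors), matching how the reduced
  stop-signal equations are conventionally written;
* the **concentration form** applies mass action to proportions
  `Phi_X = X/V`. This form is the V → ∞ limit of the master equation, so it
  is the correct deterministic reference for SSA and agent simulations.
  Under a species elimination the conserved total is then measured in
  proportion units (`N = 1` for a closed population), and the van Kampen
  expansion substitutes `N = V` before collecting orders.

The finite-population propensity convention (used identically by the master
equation and the SSA) is `rate · V · Π_j ff(n_j, α_j)/V^{α_j}` with `ff`
the falling factorial, so a unimolecular propensity is `rate·n`, a
bimolecular one `rate·n(n−1)/V`, and a reservoir reactant contributes
`Phi^α`. Note the same-species pair count is `n(n−1)`, i.e. ordered pairs —
a convention choice that the agent-based compiler reproduces exactly.

## Numerical choices

* Integration: LSODA (automatic stiff/non-stiff switching), rtol 1e-8,
  atol 1e-10; failures report the time at which the state left the finite
  domain.
* Fixed points: symbolic polynomial solve first (mass-action drifts are
  polynomial, or rational with positive denominators), supplemented by an
  8-per-dimension grid of damped-Newton starts; roots accepted when the
  drift max-norm is below 1e-9 (scaled), merged within 1e-6, and classified
  by Jacobian eigenvalues with threshold |Re λ| > 1e-9. Eigenvalues inside
  the threshold are flagged marginal and conservatively reported unstable
  (a Lotka–Volterra centre is therefore "unstable", i.e. not attracting).
* Continuation: pseudo-arclength with tangent predictor and Newton
  corrector; initial step 1% of the parameter range, halved on corrector
  failure, grown 1.3× (capped at 4× the initial step) on success, at most
  2000 steps per direction. Tangents come from the SVD null space of the
  extended Jacobian `[J_x | J_p]`, so folds need no special casing. Test
  functions between accepted points: the tangent's parameter component
  (sign change ⇒ LP) and `det J_x` (sign change without a fold ⇒ BP;
  simultaneous change is reported as an LP with a warning). Special points
  are refined by bisection along the curve to 1e-6 in the parameter.
  Branch switching seeds the crossing curve along the Jacobian null
  direction at the BP, tries both orientations and both parameter sides,
  rejects seeds that fall back onto the original branch, and joins the two
  arms through the BP. On the joined curve through a pitchfork, the
  parameter direction itself reverses, so the tracer additionally reports
  an LP at the BP location — a labelling artefact of viewing the
  transversal curve as a single branch, kept for transparency. Hopf points
  are not detected; oscillatory regimes are identified by integration.
  When a diagram is built inside a state domain, continuation is confined
  to that box expanded by 25% per side, which keeps attention on the
  physically meaningful (e.g. non-negative proportion) equilibria.
* van Kampen expansion: exact symbolic Laurent expansion in `√V` — the
  substitution `n = VΦ + √V η` makes every term a finite polynomial in
  `√V` and `1/√V`, so orders are collected exactly, with step operators
  truncated at second derivatives (the linear noise approximation). The
  macroscopic drift is read off the order-`√V` terms, `A` and `B` off the
  order-`V⁰` Fokker–Planck operator; `A` equals the Jacobian of the
  macroscopic drift by construction and this identity is tested.
* Moment equations are produced by symbolic integration by parts of the
  FPE against `η_i` and `η_i η_j`; because the FPE is linear in `η`, the
  resulting system closes at second order.
* Lyapunov equation: exact linear solve on the independent entries of the
  symmetric covariance for dimension ≤ 3, `scipy` Bartels–Stewart solver
  otherwise; residual `‖AC + CAᵀ + B‖_max ≤ 1e-8` is asserted on every
  result. Noise ellipses are reported two ways, because the eigenvectors
  of a non-normal drift matrix need not be orthogonal: the principal-axis
  ellipse of `C` (orthonormal axes, lengths `√λ_i(C)`) and, separately,
  the variances of the noise projected on the normalised eigenvectors of
  `A` at the fixed point.
* SSA: direct method; per-run generators are `PCG64` streams spawned from
  a single `SeedSequence`, so ensembles are reproducible and runs
  statistically independent. Trajectories are event-resolved with optional
  step-function resampling on a fixed grid (200 points by default) for
  ensemble averaging.

## Agent-based simulation

Rules compile to a probabilistic finite state machine only when every rule
conserves the number of agents, involves at most two dynamic molecules and
no reservoirs; other rules are rejected with an error naming the rule.
Unimolecular rules become spontaneous transitions, bimolecular rules
interactive ones. Within a step, agents act in randomised sequential order
(an agent already involved in an event neither acts nor is chosen as a
partner again that step): each agent first attempts its spontaneous
transitions with probability `rate·dt` each, otherwise draws one uniform
neighbour and fires a matching interactive rule.

The per-initiation probability of an interactive rule between distinct
states is `rate·dt/2`, because either participant can initiate over a step
and the two directed forms together must reproduce the SSA propensity
`rate·n_X n_Y/V` on a complete graph; a same-state rule keeps `rate·dt`,
matching the ordered-pair propensity `rate·n(n−1)/V`. The timestep is
`dt = safety / R_max`, where `R_max` is the largest total outgoing rate of
any state with worst-case partner availability, and `safety` defaults to
0.5 so that per-step probabilities stay well below 1 and multi-event
distortion within a step is small. These choices are validated by the
complete-graph ⇄ SSA agreement test rather than taken on faith.

For dynamic geometric topologies, agents move at fixed speed (default 0.01
per step) with wrapped-normal heading increments (default σ = 0.3 rad) on
the unit square with periodic boundaries (chosen to avoid wall-density
artefacts), and the interaction graph is rebuilt from pair distances every
step.

## Fixture models and their reference parameter sets

The packaged fixtures are the models used throughout the tests: the
stop-signal model (full and reduced), the autocatalytic Brusselator
oscillator, Lotka–Volterra predator–prey kinetics, the reservoir-birth /
pair-annihilation toy model, and an immigration–death process. Reference
parameter sets carry the values at which the reference analyses were
originally reported (e.g. `Delta = 0, mu = 3, s = 10, N = 20` for the
bistable phase portrait; `Phi_beta = 2` versus `5.5` for the stable versus
oscillatory Brusselator regimes). For the Brusselator kinetics as written
here with equal rate constants, the oscillation threshold is
`Phi_beta > 1 + Phi_alpha²`; both reference sets lie clearly on their
respective sides of it.

Problem sizes used in the statistical tests — e.g. 400 Gillespie runs at
`V = 200` for the fluctuation-variance check, 20 runs of 500 agents and 100
runs of 50 agents for the cross-scale checks, a 2000-sample stationary
ensemble for the binomial oracle — were chosen so that three-standard-error
bands are tight enough to be informative while the whole suite remains
quick to run.

## What the tests do and do not show

The statistical tests validate *internal consistency* across description
levels (LNA ↔ SSA ↔ agents ↔ ODEs) on well-mixed or synthetic topologies
with constant rates. They do not validate any particular empirical system:
real collective-behaviour data involve state-dependent rates,
heterogeneous individuals and non-stationary environments that this
framework idealises away.

One behavioural caveat is worth recording. At the deadlock-breaking
reference conditions of the stop-signal model (`Delta = 0, mu = 3, s = 3`,
`V = 50`), the package's own linear-noise analysis gives a stationary
standard deviation of the commitment gap `(A−B)/N` of ≈ 0.245 against an
attractor gap of ≈ 0.588, so individual runs regularly visit gap values
below 0.2 even after symmetry breaking, and small ensembles need not all
sit above such a threshold at any fixed time. Deadlock breaking at this
system size is a statement about the ensemble distribution (strong
bimodality, mean gap far from zero), not about every run exceeding a fixed
gap.

## Known limitations

* Continuation is limited to one- and two-dimensional systems and
  codimension-one points (LP/BP); limit cycles are not continued and Hopf
  points are not flagged.
* The master equation is constructed symbolically but not solved
  numerically on large lattices (only small finite-lattice solves appear,
  as test oracles).
* Rates must be constant in the state; richer kinetics would change the
  mass-action, propensity and compilation layers simultaneously.
* The agent scheduler is O(n) per step in Python; it is comfortable at
  thousands of agents but not designed for very large swarms.
* No SBML import/export; the plain-text `.rxn` grammar is the only model
  interchange format.
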