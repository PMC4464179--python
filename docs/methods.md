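# Methods

## Model

A regulatory network is a signed directed graph: nodes are genes, proteins
or other molecular species with an activity level `x_i ∈ [0,1]`; a
connection `j → i` states that species `j` activates or inhibits species
`i` with positive weight `w_ji`.  Three continuous embeddings of the
underlying Boolean logic are implemented:

* **BooleCube** — the multilinear interpolation of a truth table `B`,
  `B̃(x) = Σ_v B(v) Π_i [x_i v_i + (1−x_i)(1−v_i)]` over the Boolean
  vertices `v`, with relaxation dynamics `dx/dt = (B̃(x) − x)/τ`.
* **HillCube** — BooleCube applied to Hill-transformed inputs
  `x^n/(x^n + k^n)`; the normalised variant rescales each Hill factor by
  its value at `x = 1` so Boolean vertices remain fixed points.  Default
  `n = 3`, `k = 0.5`.
* **SQDS** — the standardised qualitative dynamical system:
  `dx/dt = f_h(ω) − γx`, where `ω ∈ [0,1]` is the standardised weighted
  activator/inhibitor combination (activator part
  `((1+ΣW_a)/ΣW_a)·(Σw_a x_a)/(1+Σw_a x_a)`, inhibitor part analogous,
  both present ⇒ `ω = ω_a (1−ω_b)`) and
  `f_h(ω) = (−e^{h/2} + e^{−h(ω−1/2)}) / ((1−e^{h/2})(1+e^{−h(ω−1/2)}))`
  is an exponential sigmoid with `f_h(1/2) = 1/2` for every gain.
  Defaults `h = 10`, `γ = 1`, unit weights.

### Input nodes

A node without regulators cannot be computed from any rule, so its
behaviour is a modelling convention.  Three are provided
(`SimulationSettings.input_behavior`):

* `"zero"` (default): a bare input delivers no signal; its value is pinned
  at 0.  This realises the *intrinsic* behaviour of the network in the
  absence of external stimuli; an activating self-loop is what turns an
  input into a node that can receive and hold a state, which is why adding
  input loops changes network behaviour qualitatively.
* `"decay"`: the initial value acts as a transient stimulus relaxing to 0.
* `"hold"`: the input keeps its initial value (a clamped condition).

The zero convention is the default because it is the only one consistent
with the magnitudes the centralities are expected to take on the showcase
network (see "Showcase reconstruction" below): under `"hold"` the total
centrality of a pure relay into a sink is analytically pinned at
`(1/3)/n` regardless of topology, which is empirically wrong, and only
under `"zero"` do silent inputs have exactly zero value and dynamic
centrality while retaining a positive total centrality (deleting their
outgoing connections changes the standardisation of `ω` in their targets).

### Integration and convergence

Fixed-step classical Runge–Kutta (default `dt = 0.1`), states clamped to
`[0,1]` after every full step.  A sample counts as converged when the
derivative max-norm stays below `conv_eps = 1e-6` for 10 consecutive
steps; the tight threshold is what makes "centrality < 1e-10" a meaningful
statement.  Trajectories that never converge (limit cycles) are summarised
by their time-average over a final stretch of 10% of the horizon.
An optional step-size ramp (`relax_dt`, `relax_after`) switches to a
coarser step once the transient — where basins of attraction are decided —
is over; the asymptotic relaxation and cycle averaging are insensitive to
the step size.  A compiled (numba) per-sample integrator and a vectorised
numpy integrator implement identical semantics; they agree to 1e-15 and
the test suite checks it.

Known limitation: near saddle points the derivative can dip below the
threshold while the state is still in transit, so "converged" states close
to basin boundaries carry an error larger than `conv_eps` suggests.  All
comparisons use common random numbers, so this error largely cancels
between the two networks of a convergence difference.

## Convergence difference and centralities

`D(N1, N2)` is the Monte-Carlo estimate of the integral over uniform
initial vectors of the mean squared difference `μ` between the steady
states the two networks reach from the same start.  The same initial draws
(keyed by node name) are fed to both networks, so `D(N, N) = 0` holds
exactly and sub-`1e-10` discriminations are not drowned in Monte-Carlo
noise.  When one network contains surrogate nodes, `μ` runs over the
original network's nodes only.

* **Total centrality** of a connection: `D` between the network and the
  network with that connection deleted.  Deletion removes the weight from
  the SQDS sums (truth tables are marginalised with the lost input pinned
  at Boolean 0); a node's TC deletes all its outgoing connections,
  self-loop included.
* **Value centrality** of a node: the expected `μ` between two runs that
  differ only in that node's initial value (two independent uniform draws,
  all other coordinates shared).  One of the two draws is the base sample
  itself, so the cached base steady states serve as one side of every
  comparison.  The printed operational form carries no extra
  normalisation; this choice makes the VC of a node whose value cannot
  reach any steady state exactly zero, as required.
* **Dynamic centrality**: the node's (or connection's) outputs are rerouted
  through a fresh *constant* surrogate node and the surrogate value
  `c ∈ [0,1]` is chosen to minimise `D`; the minimum is the relay influence
  no constant signal can imitate.  The minimiser evaluates a coarse grid
  (default 11 points, batched into a single convergence run — the guard
  against non-unimodal `D(c)`) and refines the winning bracket by
  golden-section search to `dc_tol` (default `1e-4`).
  `split_node_outputs` reroutes the self-loop together with the other
  outputs (the exact structural analogue of node deletion);
  `include_self_loop=False` keeps it with the node, isolating the relay
  role from the state-holding role — both variants were evaluated and give
  statistically indistinguishable ensemble results.

Aggregates: controllability = mean node VC; vulnerability `V` = mean node
TC; robustness = `1 − V`; relative controllability `RC` = controllability
/ vulnerability (flagged undefined when `V = 0`); concentration is
summarised by the population Gini coefficient
`Σ_ij |c_i − c_j| / (2 n² mean)` and by the minimal number of nodes
holding more than half of the total value centrality.

## Showcase reconstruction

The six-node example (`grncontrol.examples.toy_network`) consists of an
input A activating a self-amplifying hub B, a feedback cycle
B → C ⊣ D → B, and an output pathway B → E → F.  The two cycle signs are
not determined by the textual description; all sixteen sign assignments
were evaluated under all three input conventions.  The adopted assignment
(C inhibits D; every other connection activates) is the only one in which
the hub dominates (TC_B ≈ 0.45, TC_E ≈ 0.13 at 1000 samples), the sink
scores exactly zero, and the silent input has exactly zero value and
dynamic centrality.  The expected magnitudes of VC_B and DC_B (≈ 0.2) are
not reached by any unit-weight assignment — with steeper self-amplification
(weight 2 on B → B) they appear, which suggests the original figure used
non-unit weights — so the package's tests check the robust ordering
constraints (TC_B ≫ TC_E > 0 = TC_F, VC_B ≫ VC_E, DC_B ≫ DC_A) plus the
attained magnitudes.

## Random ensembles

Defaults: 15 nodes, density 2.5 (connections per node), activating
self-loop probability 0.5 per node, edge sign probability 0.5, SQDS rules
with unit weights.  ER places each ordered pair with equal probability
`density/(n−1)`; SF grows a Barabási–Albert graph (complete seed graph
sized to keep the attachment count feasible, fractional attachment counts
randomised between neighbouring integers) and orients each edge uniformly
at random, preserving the power-law total-degree profile with exponent
near 3.  Rules for the cube interpolations are random linear-threshold
truth tables, which are sign-monotone by construction.  One ensemble seed
spawns per-network substreams, so ensembles are reproducible element by
element.

The self-loop probability is a study condition the source text leaves to
its supplement.  0.5 was fixed once, for two reasons: the loop analyses
need both looped and loop-free node populations well represented, and
under the zero-input convention a loop-free ensemble makes value
centrality almost everywhere exactly zero (nothing can hold a state), a
degenerate regime that plainly does not describe the data the survey
statistics summarise.  The density sweep, which studies how *emergent*
feedback creates controllability, uses loop-free ensembles (self-loops
are introduced as a separate arm by the loop-effect experiment).

### What the generator does and does not emulate

The ensembles emulate the degree structure, sparsity, signed-ness and
random logic of small regulatory networks.  They do not emulate
transcription-factor co-regulation patterns, autoregulation biases,
correlated motif usage, or measurement noise of inferred networks;
conclusions from passing tests transfer to real networks only insofar as
those depend on degree structure and signed feedback.

## Survey problem sizes

Ensemble surveys run 200 Monte-Carlo initial vectors per centrality over
100 networks, with a 60-time-unit horizon, the 0.1→0.5 step ramp after 10
time units, a 7-point neutral-value grid refined to `dc_tol = 0.02`, and
seeds derived per network.  Doubling any of these moves the reported
ensemble means by less than their standard errors (checked for the Gini
statistics on 8-network subsets).  The showcase network uses 1000 samples
and the default `dc_tol = 1e-4`.

## Known limitations

* The Gini of the total centralities in the scale-free survey comes out
  near 0.57–0.59, below the ≈ 0.7 reported for the original ensembles,
  and the node-level decomposition regressions (TC on DC + VC; VC on DC)
  reach R² ≈ 0.27 and ≈ 0.43 at the 100-network scale, far from the
  near-perfect decomposition and near-orthogonality reported there.  Both statistics
  are sensitive to the ensemble composition and to definitional details of
  the node-level dynamic centrality that are specified only in the
  original supplementary material; every variant implemented here (three
  input conventions, self-loop handling in the node split, drop-weight vs
  silenced-signal deletion, loop probabilities 0 and 0.5) leaves the
  qualitative picture — strong concentration of control in few driver
  nodes, value and dynamic centrality as complementary components — intact
  but does not reproduce those two numbers.
* Dynamic centrality of a node whose held value drives multistable
  downstream targets is bounded away from zero for any constant surrogate;
  consequently VC and DC correlate across hub nodes in these ensembles.
* The relative-controllability maximum at sparse densities is not
  reproduced: with self-loops RC declines monotonically with density, and
  without them RC stays near zero until high densities because zero-pinned
  inputs dilute the standardised `ω` and suppress emergent multistability.
* Near-saddle convergence (above) blurs centralities of nodes whose
  influence is confined to thin basin-boundary layers.
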