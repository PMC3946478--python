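# Methods

## Model

An iterative crisp clustering run is abstracted at two levels.

**Program graph.** The algorithm itself is a guarded-transition graph over
binary variables, with the two clustering actions `compare` (distance
evaluation; never changes a variable) and `allocate` (cluster assignment).
K-Means uses variables `rs_0..rs_{k-1}` (did cluster i's member set change
this sweep?) and `conv` (has the criterion stabilized?); DBSCAN uses `conv`
(is the current core object's density-reachable set exhausted?) and `deal`
(has every object been processed?). The published figures for these graphs
are not machine-readable, so the graphs here are reconstructed from the
accompanying prose; the one genuinely open choice is the outcome of
`allocate` before convergence, which we model nondeterministically (any
combination of rs flags, convergence reached or not) — this is what makes
mixed-flag states reachable, matching the worked state-transition diagram
for a 2-cluster run. For DBSCAN the semantically impossible outcome
`conv = 0 & deal = 1` (run complete mid-expansion) is excluded. Unfolding
(`vericlust.model.unfold`) enumerates reachable (location, valuation)
states breadth-first, self-loops terminal states, and is guarded by a
configurable cap (default 10^6); the reachable count per location can never
exceed `2^t * 2^k` for `t` condition variables and `k` cluster flags, which
the test suite asserts for k = 1..6.

**Iteration trace.** A concrete run is an ordered list of per-iteration
records: assignment vector (cluster ids 0..k-1, `-1` = unallocated),
`rs` flags, `conv`, `deal`, the Dunn and maximum-diameter values, and the
algorithm's own criterion. One K-Means iteration is one full
assign-then-update sweep; one DBSCAN iteration is one core-object expansion
round (records are taken when a round's reachable set is exhausted, so
their `conv` is 1 throughout and `deal` flips once at the end — both flags
are monotone along a trace). The trace is the verifier's only input, so any
algorithm — including hierarchical or neural-map methods we do not
instrument natively — can be verified by emitting the versioned JSON
schema; granularity of "iteration" is then the producer's choice.
Algorithms without an iterative assignment structure (constrained-
optimization or probabilistic methods such as EM) have no program graph in
this sense and are out of scope.

## Atomic propositions

The trace's linear Kripke structure `S1 -> ... -> ST` (terminal self-loop,
initial state S1) is labeled with:

* `converge` iff `conv = 1`; `handled` iff `deal = 1`.
* `DunnUp` at `S_t` iff t = 1, or either of dunn_t / dunn_{t-1} is
  undefined, or dunn_t >= dunn_{t-1}; `diamDown` symmetric with `<=`.
  Non-strict comparison keeps converged plateaus valid; vacuous truth at
  undefined values keeps early DBSCAN rounds (fewer than two clusters, no
  Dunn value) from spuriously violating the properties.
* `maxDunn` at `S_t` iff `converge & handled` hold there **and** dunn_t
  equals the maximum defined Dunn value over the whole trace; `minDiam`
  symmetric with the minimum. The terminal-extremum reading is deliberate:
  under a running-maximum reading, a run whose index rises and then decays
  would still satisfy `E[DunnUp U maxDunn]` at its peak and be judged
  valid, which contradicts the intended meaning ("rises *until it reaches
  its maximum*" at the converged end). Ties all receive the label.

Index conventions (`vericlust.indices`): Euclidean distance everywhere
(every geometric index takes a `metric` hook, but defaults and tests are
Euclidean); unallocated objects are excluded from every index; Dunn is the
classical single-linkage form (minimum pairwise inter-cluster distance over
maximum intra-cluster diameter), `None` with fewer than two clusters and
`+inf` when all clusters are singletons; entropy is the cluster-size-
weighted class entropy with natural logs normalized by `log(l)` so it lies
in [0, 1] (the 0.25-style decision thresholds quoted for it presume a
bounded scale), and is 0 by convention for a single class; Jaccard and
Fowlkes–Mallows return 0 with a warning on a vanishing denominator;
Davies–Bouldin uses mean member-to-centroid scatter and errors on
coincident centroids, naming the pair; RMSSTD divides pooled within-cluster
sum of squares by `n_features * sum_i (n_i - 1)` and is 0 when that
degrees-of-freedom term vanishes.

## Properties and verdict

Two CTL properties express validity over those propositions:

1. `EF[(converge & handled) -> (maxDunn & minDiam)]` — at convergence the
   indices are optimal. The literal `EF` form is vacuous in practice (any
   pre-convergence state falsifies the antecedent and witnesses it), so the
   verdict uses the universal `AG` form of the same implication; the `EF`
   form is still checked and reported for fidelity.
2. `E[DunnUp U maxDunn] & E[diamDown U minDiam]` — the indices improve
   monotonically until their terminal extrema. (The conjunction-of-untils
   form is implemented; on a single linear trace it coincides with the
   until-of-conjunctions variant.)

The model checker (`vericlust.ctl.sat`) is the standard explicit-state
labeling algorithm over the adequate set {EX, EU, AF} and friends: EX/AX by
pre-image, EF/EU by backward reachability, AF/AU by successor counting,
EG/AG by duality — O(|S| + |transitions|) per subformula, so checking a
fixed formula scales linearly in trace length (asserted empirically on
chains of 10^2 and 10^4 states). Every operator is also implemented a
second, independent time in `vericlust.reference.sat_bounded` directly from
path semantics (loop-free DFS for existential reachability; depth-|S|
survival search, justified by pigeonhole, for the lasso questions behind
AF/EG/AU); the two implementations are compared for exact satisfaction-set
equality on 1,000+ random systems in the test suite and the acceptance
script. `to_adequate` rewrites any formula into {EX, EU, AF} with the
textbook dualities and is verified to be idempotent, closed, and
satisfaction-preserving.

## Localization

For each failing verdict property: the error trace `T` is the full
execution path; the satisfying sub-trace `C` seeds every state where the
property's per-state obligation holds — `(converge & handled) ->
(maxDunn & minDiam)` for the optimality properties,
`(DunnUp | maxDunn) & (diamDown | minDiam)` for the until property — and
closes backwards over incoming transitions (the literal worklist
procedure, which does not stop at non-obligation states); the cause is
`T \ C`, and the report's `real_causes` is the order-preserving union over
properties. On prefix-shaped obligation regions (index rises then decays)
this reproduces the canonical walkthrough: C = (S1..S4), cause = (S5..S8)
on the 8-state dip fixture. On non-prefix regions the backward closure can
absorb the whole chain and leave an empty cause even though the property
fails; the report flags this explicitly, and object blame therefore anchors
at the first iteration whose *obligation* fails (identical to the first
cause state in the prefix case) rather than at the cause set.

**Object blame.** Starting from that iteration t: collect the objects whose
cluster at t differs from t-1 (at t = 1, from the empty initial
allocation). If the obligation holds again at t+1 (trend recovered),
remove the movers that stay put at t+1 — their move is judged beneficial;
if the trend is still abnormal and t+1 is not last, recurse on t+1 and
union; at the last iteration, add its fresh movers. O(r * n) for r
examined iterations and n objects. Runs whose only defect is a mistake in
the very first allocation that persists unchanged to termination produce no
membership changes to blame; such initial-allocation errors are detected
and reported as out of scope.

## Synthetic data

The generator (`vericlust.synth`) provides every test input:

* **Blobs** — k isotropic Gaussian clusters (default sigma 1) at centers
  spaced `separation * sigma` apart on a lattice (default separation 10:
  unambiguous clusters, which ground-truth fixtures need; tests also use
  2–5 to show Dunn grows with separation). Defaults of 20 points per
  cluster in 2-D keep every suite fast while leaving cluster structure
  unmistakable.
* **Pattern traces** — fabricated Dunn/diameter series with exact shape
  control: `monotone` (linear rise/fall, step 0.1), `dip(t*)` (rise through
  t*-1, decay 0.08 per step after), `plateau` (rise then constant);
  `conv = deal = 1` at the final record. Index series are written directly
  rather than recomputed from geometry because these fixtures exist to pin
  the labeling and localization logic to exact patterns.
* **Planted blame** — end-to-end realistic traces: a base run on
  well-separated blobs (first iteration has 3 scrambled objects, later
  iterations the true partition — Dunn jumps up then plateaus, a valid
  run), then 5 planted objects oscillate between their true and flipped
  clusters from t* = 4 of 6 onward, with rs flags, criterion and index
  series recomputed from the geometry. Oscillation rather than a one-shot
  flip is deliberate: a single flip makes the perturbed series plateau,
  which the non-strict trend convention treats as recovered, and the blame
  procedure then exonerates the settled movers *by design*. Measured over
  100 seeded replicates, blame recall and precision are both 1.0.

What passing these suites shows — and does not. The synthetic conditions
isolate each mechanism: exact index arithmetic, exact model-checking
semantics, exact localization on controlled violation shapes, and full
blame recovery when the violation is driven by identifiable movers. Real
datasets add effects the generator deliberately omits: overlapping
clusters whose index series dip for benign reasons, noise and border
ambiguity in DBSCAN, violations caused by several interacting object
groups, and initial-allocation errors invisible to iteration comparison.
Verdicts on real data should therefore be read as statements about the
recorded run's index trends, not about the dataset's "true" structure.

## Numerical and design choices

* K-Means: seeded-random initialization by default (k distinct data
  points), farthest-point heuristic and explicit centroids available;
  convergence when the within-cluster sum of squares changes by at most
  `tol` (default 1e-6) between sweeps, `max_iter` 100; an empty cluster is
  reseeded with the point farthest from that cluster's previous centroid
  (deterministic, never stealing a singleton's only member). Traces are
  byte-identical across runs for a fixed seed.
* DBSCAN: row-order scan; `eps`-neighborhoods include the point itself;
  degenerate parameters yield an all-noise trace with a single closing
  record rather than an error.
* Trace JSON: versioned; `-1` encodes unallocated; `Infinity` is encoded
  as a string so files remain strict JSON; validation errors name the
  offending field and record index.
* CTL concrete syntax: identifiers as atoms; `!`, `&`, `|`, `->`
  (precedence in that order, implication right-associative); `EX AX EF AF
  EG AG` prefix; `E[p U q]` / `A[p U q]`. The printer parenthesizes so
  that `parse(str(f)) == f`.
* Satisfaction sets are order-independent (asserted under state
  shuffling); state ids follow iteration order `S1..ST`.
* Verdict-relevant formulas are the `AG` optimality form and the until
  conjunction; an empty formula list is vacuously valid.

## Limitations

* Initial-allocation errors (wrong from the first assignment, never
  corrected) are flagged but not localized — there is no iteration
  comparison to exploit.
* The `EF` optimality form is reported but cannot drive a verdict; its
  vacuity is structural, not an implementation artifact.
* BIRCH, SOM and other algorithms enter only through the trace schema; the
  package does not define what their "iteration" is.
* Blame assumes violations are expressed as membership changes between
  adjacent iterations; collective drift with no adjacent-iteration
  signature is not attributed.
* The program graphs abstract data dependence into nondeterminism; the
  unfolded systems over-approximate the behaviors of any concrete run.
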