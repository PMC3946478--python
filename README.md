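# vericlust

Formal verification of crisp clustering runs by explicit-state CTL model
checking, with counterexample and object-level blame localization.

## The problem

Cluster validity is usually judged after the fact, from a single score:
external indices (purity, entropy, Rand, Jaccard, Fowlkes–Mallows) need
ground-truth labels that unsupervised analyses rarely have, and relative
indices (Dunn, Davies–Bouldin, RMSSTD) rank alternative clusterings but give
no yes/no answer for a single run. For iterative algorithms — K-Means
sweeps, DBSCAN core-object expansions, and anything else that refines a
partition step by step — the *process* carries more information than the
final score: in a well-behaved run the clusters tighten and separate
monotonically until convergence.

`vericlust` makes that intuition checkable. A run is recorded as an
**iteration trace** (one snapshot per iteration: assignments, per-cluster
change flags `rs`, convergence flag `conv`, allocation flag `deal`, and the
Dunn / maximum-diameter index values). The trace becomes a finite Kripke
structure `S1 -> S2 -> ... -> ST` (terminal self-loop) labeled with six
atomic propositions — `converge`, `handled`, `DunnUp`, `maxDunn`,
`diamDown`, `minDiam` — and is model checked against CTL validity
properties:

```
EF [ (converge & handled) -> (maxDunn & minDiam) ]
E [ DunnUp U maxDunn ]  &  E [ diamDown U minDiam ]
```

i.e. the Dunn index (minimum inter-cluster distance over maximum cluster
diameter) rises step by step until it peaks at the converged, fully
allocated end of the run, and the maximum diameter falls until it bottoms
out. (The `EF` form is vacuously satisfiable — any state falsifying the
antecedent witnesses it — so the verdict uses its universal `AG` form; the
literal `EF` form is still checked and reported.) On a violation the
verifier returns the error trace `T`, extracts the satisfying sub-trace `C`
by backward closure over the states where the per-state obligation holds,
reports the **cause** `T \ C` — the iterations responsible — and then
compares each violating iteration with its successor to name the **objects**
whose cluster switches drove the violation.

Intended users: anyone quality-controlling iterative clustering — e.g.
expression-profile clustering in biostatistics — who wants a reproducible
valid/invalid verdict plus a localization of what went wrong, not just an
index value. Any third-party algorithm can be verified by emitting the
versioned JSON trace format (`vericlust.traces`).

## What is in the box

| module                | contents |
| --------------------- | -------- |
| `vericlust.indices`   | purity, normalized entropy, SS/SD/DS/DD pair counts, Rand/Jaccard/Fowlkes–Mallows, Dunn, maximum diameter, Davies–Bouldin, RMSSTD |
| `vericlust.traces`    | instrumented K-Means (Lloyd) and DBSCAN, the trace JSON schema, round-trip I/O |
| `vericlust.model`     | program graphs for K-Means/DBSCAN, unfolding into transition systems (with the `2^t * 2^k` per-location state bound), trace labeling |
| `vericlust.ctl`       | CTL parser, adequate-set rewriting ({EX, EU, AF}), linear-time fixpoint labeling model checker |
| `vericlust.reference` | independent brute-force path-semantics oracle used for cross-checking |
| `vericlust.verifier`  | verdicts, satisfying-trace extraction, cause computation, object blame, report rendering |
| `vericlust.synth`     | Gaussian blobs, monotone/dip/plateau pattern traces, planted-blame traces with ground truth |
| `vericlust.cli`       | `vericlust trace / verify / indices / simulate` |

## Worked example

`examples/worked_counterexample.py` builds an 8-iteration trace whose Dunn
index rises through iteration 4 and falls afterwards, then verifies it:

```
Dunn series: [0.2, 0.3, 0.4, 0.5, 0.42, 0.34, 0.26, 0.18]

verdict: INVALID
  [ok] eventually_optimal (reported only): EF (converge & handled -> maxDunn & minDiam)
  [FAIL] always_optimal_at_convergence: AG (converge & handled -> maxDunn & minDiam)
      T     = (S1, S2, S3, S4, S5, S6, S7, S8)
      C     = (S1, S2, S3, S4, S5, S6, S7)
      cause = (S8)
  [FAIL] until_monotone: E[DunnUp U maxDunn] & E[diamDown U minDiam]
      T     = (S1, S2, S3, S4, S5, S6, S7, S8)
      C     = (S1, S2, S3, S4)
      cause = (S5, S6, S7, S8)
  real causes: (S5, S6, S7, S8)
```

The run is invalid; the until-property's satisfying sub-trace is
`(S1..S4)` and the cause `(S5..S8)` — exactly the iterations from which the
index stopped rising toward its terminal maximum. The other examples show a
valid instrumented K-Means run, object blame recovering five planted
misbehaving objects (recall 5/5, precision 5/5), an index report, and CTL
checks on the unfolded K-Means program graph. The same pipeline from a
shell:

```sh
vericlust simulate blobs --k 2 --n-per-cluster 10 --separation 12 --seed 1 --out blobs.csv
vericlust trace --algo kmeans --data blobs.csv --labels --k 2 --seed 7 --out run.json
vericlust verify --trace run.json --report report.json   # exit 0 valid, 3 invalid
```

## Documentation

`docs/methods.md` describes the formal model, the labeling conventions, the
verification algorithms, the synthetic-data generator and its limits, and
the package's design decisions.
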