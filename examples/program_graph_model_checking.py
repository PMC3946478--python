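"""Unfold the K-Means program graph and model check it directly.

The program graph abstracts a K-Means run over binary variables (per-
cluster change flags rs_i and a convergence flag). Unfolding yields every
reachable (location, valuation) state — never more than 2^t * 2^k
valuations per location — and arbitrary CTL formulas over those variables
can be checked on the result.
"""

from vericlust import check, kmeans_program_graph, parse, sat, unfold

pg = kmeans_program_graph(k=2)
ts = unfold(pg)
print(f"variables: {pg.variables}")
print(f"reachable states: {len(ts.states)} (bound per location:"
      f" 2^1 * 2^2 = {2 ** 1 * 2 ** 2})")

# convergence is reachable, and once reached the flags can all clear
for text in ("EF conv",
             "AG (conv -> EF (!rs0 & !rs1))",
             "AG rs0"):
    formula = parse(text)
    holds = check(ts, formula)
    print(f"  {text!s:32} -> {holds}  "
          f"({len(sat(ts, formula))}/{len(ts.states)} states satisfy)")
print()
print("The first two properties hold from the initial state; the last"
      " fails because cluster 0's membership is not always changing.")
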