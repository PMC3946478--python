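"""Object-level blame on a run with planted misbehaving objects.

Five objects oscillate between the two blobs from iteration 4 onward,
ruining the Dunn trend. The iteration-comparison blame procedure compares
each violating iteration with its successor and returns the objects whose
cluster switches track the violation; here it recovers the planted set
exactly.
"""

from vericlust import verify_trace
from vericlust.synth import make_planted_blame_case

case = make_planted_blame_case(seed=7, n_planted=5)
report = verify_trace(case.trace)

print("verdict:", "valid" if report.valid else "INVALID")
print("violating states:", ", ".join(report.real_causes) or "(none)")
print("planted objects: ", sorted(case.planted))
print("blamed objects:  ", list(report.blamed_objects))
overlap = set(report.blamed_objects) & case.planted
print(f"recall {len(overlap)}/{len(case.planted)},"
      f" precision {len(overlap)}/{len(report.blamed_objects)}")
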