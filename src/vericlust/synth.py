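"""Synthetic inputs: Gaussian blobs, pattern traces, planted-blame traces.

Everything the verifier consumes can be generated here without external
data:

* :func:`make_blobs` — seeded Gaussian clusters at mutually separated
  centers, the stand-in for real benchmark datasets.
* :func:`make_synthetic_trace` — fabricated iteration traces whose Dunn /
  diameter series follow an exact pattern (monotone rise, planted dip at a
  chosen iteration, plateau). Index series are written directly so the
  fixtures have exact control over the labeling; assignments and rs flags
  are fabricated consistently.
* :func:`plant_blame` / :func:`make_planted_blame_case` — traces in which a
  known set of objects flips cluster from iteration ``t*`` onward, with rs
  flags and index series *recomputed from the geometry*, giving end-to-end
  ground truth for blame recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .traces import (IterationRecord, IterationTrace, trace_from_assignments)

__all__ = [
    "BlobSpec",
    "PlantedTrace",
    "make_blobs",
    "make_synthetic_trace",
    "plant_blame",
    "make_planted_blame_case",
]


@dataclass(frozen=True)
class BlobSpec:
    """Specification of a Gaussian-blob dataset.

    ``separation`` is the center spacing in units of ``sigma``; with the
    default 10 the blobs are unambiguous, which is what the verifier's
    ground-truth fixtures need.
    """

    k: int = 3
    n_per_cluster: int = 20
    dim: int = 2
    sigma: float = 1.0
    separation: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1 or self.n_per_cluster < 1:
            raise InputError("k and n_per_cluster must be >= 1")
        if self.sigma <= 0:
            raise InputError("sigma must be > 0")
        if self.separation < 0:
            raise InputError("separation must be >= 0")


def make_blobs(spec: BlobSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``k`` Gaussian clusters of ``n_per_cluster`` points each.

    Centers sit on a one-dimensional lattice along the first coordinate at
    spacing ``separation * sigma`` (pairwise center distance is therefore
    at least the nominal separation); points are isotropic Gaussian with
    standard deviation ``sigma``. Returns ``(X, labels)`` with labels
    0..k-1 in blocks; reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    X = np.empty((spec.k * spec.n_per_cluster, spec.dim))
    labels = np.empty(spec.k * spec.n_per_cluster, dtype=np.int64)
    for c in range(spec.k):
        center = np.zeros(spec.dim)
        center[0] = c * spec.separation * spec.sigma
        rows = slice(c * spec.n_per_cluster, (c + 1) * spec.n_per_cluster)
        X[rows] = center + rng.normal(scale=spec.sigma,
                                      size=(spec.n_per_cluster, spec.dim))
        labels[rows] = c
    return X, labels


# ---------------------------------------------------------------------------
# pattern traces (index series written directly)
# ---------------------------------------------------------------------------

def _pattern_series(pattern: str, length: int, t_star: int | None):
    """Dunn (rising) and diameter (falling) series for a pattern fixture."""
    rise = [round(0.2 + 0.1 * t, 6) for t in range(length)]
    fall = [round(1.6 - 0.1 * t, 6) for t in range(length)]
    if pattern == "monotone":
        return rise, fall
    if pattern == "plateau":
        mid = max(1, length // 2)
        dunn = rise[:mid] + [rise[mid - 1]] * (length - mid)
        diam = fall[:mid] + [fall[mid - 1]] * (length - mid)
        return dunn, diam
    if pattern == "dip":
        if t_star is None:
            raise InputError("dip pattern requires t_star")
        if not 2 <= t_star <= length:
            raise InputError(f"t_star must be in 2..{length}, got {t_star}")
        # rises through t_star - 1, strictly falls from t_star on
        dunn, diam = [], []
        for t in range(1, length + 1):
            if t < t_star:
                dunn.append(rise[t - 1])
                diam.append(fall[t - 1])
            else:
                steps = t - t_star + 1
                dunn.append(round(rise[t_star - 2] - 0.08 * steps, 6))
                diam.append(round(fall[t_star - 2] + 0.08 * steps, 6))
        return dunn, diam
    raise InputError(f"unknown pattern {pattern!r}")


def make_synthetic_trace(
    pattern: str,
    length: int,
    seed: int | None = None,
    *,
    t_star: int | None = None,
    n_objects: int = 12,
    k: int = 2,
) -> IterationTrace:
    """Fabricate a trace whose index series follows a named pattern.

    ``pattern`` is ``"monotone"`` (Dunn strictly rising, diameter strictly
    falling — a valid run), ``"dip"`` (rising through ``t_star - 1``,
    falling from ``t_star`` — the planted-violation fixture), or
    ``"plateau"`` (rise then constant — valid under the non-strict trend
    convention). ``conv`` and ``deal`` are 1 at the final record; ``deal``
    is 1 throughout (all objects always allocated). Assignments change only
    over the first few iterations so the rs flags are consistent and the
    final records are stable.
    """
    if length < 2:
        raise InputError("length must be >= 2")
    if n_objects < 2 * k:
        raise InputError("need at least two objects per cluster")
    dunn_series, diam_series = _pattern_series(pattern, length, t_star)
    rng = np.random.default_rng(seed)

    base = np.repeat(np.arange(k), math.ceil(n_objects / k))[:n_objects]
    assignments = []
    previous = None
    settle = min(3, length - 1)   # membership settles before convergence
    for t in range(length):
        if t == 0:
            current = base.copy()
        elif t <= settle:
            current = previous.copy()
            mover = int(rng.integers(n_objects))
            current[mover] = (current[mover] + 1) % k
            counts = np.bincount(current, minlength=k)
            if counts.min() == 0:       # never empty a cluster
                current = previous.copy()
        else:
            current = previous.copy()
        assignments.append(current)
        previous = current

    records = []
    prev = None
    for t in range(1, length + 1):
        a = assignments[t - 1]
        rs = []
        for c in range(k):
            now = a == c
            if prev is None:
                rs.append(1 if now.any() else 0)
            else:
                rs.append(0 if np.array_equal(now, prev == c) else 1)
        records.append(IterationRecord(
            index=t,
            assignment=tuple(int(x) for x in a),
            rs=tuple(rs),
            conv=1 if t == length else 0,
            deal=1,
            dunn=dunn_series[t - 1],
            diam=diam_series[t - 1],
            criterion=float(length - t),
        ))
        prev = a
    return IterationTrace(
        algorithm=f"synthetic-{pattern}",
        parameters={"pattern": pattern, "length": length, "seed": seed,
                    "t_star": t_star},
        n_objects=n_objects,
        k=k,
        object_ids=tuple(range(1, n_objects + 1)),
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# planted object blame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTrace:
    """A perturbed trace plus its ground truth."""

    trace: IterationTrace
    t_star: int
    planted: frozenset[int]
    data: np.ndarray


def plant_blame(
    trace: IterationTrace,
    t_star: int,
    objects,
    data,
    *,
    oscillate: bool = False,
) -> PlantedTrace:
    """Flip the clusters of ``objects`` (1-based ids) from ``t_star`` onward.

    Each planted object moves to the next cluster id (mod k) in every
    record from ``t_star`` to the end (with ``oscillate`` it alternates
    between its original and flipped cluster). rs flags, criterion and the
    Dunn / diameter series are recomputed from ``data``; ``conv`` is 0 for
    every record except the last (the perturbed run terminates there) and
    ``deal`` flags are preserved. Raises if a flip would empty a cluster.
    """
    if t_star < 2 or t_star > len(trace.records):
        raise InputError(
            f"t_star must be in 2..{len(trace.records)}, got {t_star}")
    objects = sorted(set(int(o) for o in objects))
    id_to_row = {oid: i for i, oid in enumerate(trace.object_ids)}
    for oid in objects:
        if oid not in id_to_row:
            raise InputError(f"unknown object id {oid}")
    k = trace.k
    if k < 2 and objects:
        raise InputError("flipping requires at least two clusters")

    assignments = []
    for t, record in enumerate(trace.records, start=1):
        a = np.array(record.assignment, dtype=np.int64)
        if t >= t_star and objects:
            phase = (t - t_star) % 2 if oscillate else 0
            if phase == 0:
                for oid in objects:
                    row = id_to_row[oid]
                    if a[row] == -1:
                        raise InputError(
                            f"object {oid} is unassigned at iteration {t}")
                    a[row] = (a[row] + 1) % k
            counts = np.bincount(a[a >= 0], minlength=k)
            if counts.min() == 0:
                empty = int(counts.argmin())
                raise InputError(
                    f"flip would empty cluster {empty} at iteration {t}")
        assignments.append(a)

    perturbed = trace_from_assignments(
        np.asarray(data, dtype=float),
        assignments,
        algorithm=trace.algorithm + "+planted",
        parameters={**trace.parameters, "t_star": t_star,
                    "planted": objects, "oscillate": oscillate},
        k=k,
        deal_flags=[r.deal for r in trace.records],
    )
    return PlantedTrace(
        trace=perturbed,
        t_star=t_star,
        planted=frozenset(objects),
        data=np.asarray(data, dtype=float),
    )


def make_planted_blame_case(
    seed: int,
    *,
    k: int = 2,
    n_per_cluster: int = 12,
    length: int = 6,
    t_star: int = 4,
    n_planted: int = 5,
    n_scrambled: int = 3,
) -> PlantedTrace:
    """End-to-end planted-blame instance on well-separated blobs.

    The base trace emulates a convergent run: the first iteration assigns
    ``n_scrambled`` randomly chosen objects to the wrong blob, every later
    iteration is the true partition (so the Dunn series jumps up and then
    plateaus — a valid run). ``n_planted`` objects, disjoint from the
    scrambled ones, then oscillate between their true and flipped clusters
    from ``t_star`` onward, so the index trend stays abnormal through the
    end of the run.
    """
    if t_star < 3 or t_star > length:
        raise InputError("t_star must be in 3..length so the base run has "
                         "settled before the violation")
    rng = np.random.default_rng(seed)
    X, truth = make_blobs(BlobSpec(
        k=k, n_per_cluster=n_per_cluster, dim=2, sigma=1.0,
        separation=12.0, seed=int(rng.integers(2 ** 31)),
    ))
    n = len(truth)
    chosen = rng.choice(n, size=n_scrambled + n_planted, replace=False)
    scrambled, planted_rows = chosen[:n_scrambled], chosen[n_scrambled:]
    first = truth.copy()
    for row in scrambled:
        first[row] = (first[row] + 1) % k
    if np.bincount(first, minlength=k).min() == 0:
        first = truth.copy()    # degenerate scramble: fall back to clean start
    assignments = [first] + [truth.copy() for _ in range(length - 1)]
    base = trace_from_assignments(
        X, assignments, algorithm="synthetic-kmeans",
        parameters={"seed": seed, "length": length}, k=k)
    return plant_blame(
        base, t_star, [int(r) + 1 for r in planted_rows], X, oscillate=True)
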