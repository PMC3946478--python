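"""Instrumented clustering runs and the iteration-trace interchange format.

A clustering run is recorded as an :class:`IterationTrace`: one
:class:`IterationRecord` per iteration, each holding the full assignment
vector, per-cluster change flags (``rs``), a convergence flag (``conv``), an
all-objects-allocated flag (``deal``), the Dunn and maximum-diameter index
values at that iteration, and the algorithm's own objective (``criterion``).

Two algorithms are instrumented natively — Lloyd's K-Means (one record per
assign-then-update sweep) and DBSCAN (one record per core-object expansion
round). Any other iterative algorithm can be verified by producing a trace
file in the versioned JSON schema read/written here.

Object identifiers are 1-based row ordinals of the input matrix; cluster
identifiers are 0-based; unallocated objects carry -1 (``UNASSIGNED``).
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, squareform, pdist

from .errors import InputError, TraceSchemaError
from .indices import UNASSIGNED, dunn, max_diameter

SCHEMA_VERSION = 1

__all__ = [
    "SCHEMA_VERSION",
    "IterationRecord",
    "IterationTrace",
    "kmeans_trace",
    "dbscan_trace",
    "trace_from_assignments",
    "write_trace",
    "read_trace",
    "validate_trace_document",
]


@dataclass(frozen=True)
class IterationRecord:
    """Snapshot of one clustering iteration.

    ``rs[i]`` is 1 exactly when cluster ``i``'s member set differs from the
    previous record (first record: 1 for every non-empty cluster, matching
    an initially empty allocation). ``dunn``/``diam`` are ``None`` while the
    index is undefined (fewer than two clusters / nothing assigned).
    """

    index: int
    assignment: tuple[int, ...]
    rs: tuple[int, ...]
    conv: int
    deal: int
    dunn: float | None
    diam: float | None
    criterion: float


@dataclass(frozen=True)
class IterationTrace:
    """Ordered per-iteration snapshots of one clustering run."""

    algorithm: str
    parameters: dict
    n_objects: int
    k: int
    object_ids: tuple[int, ...]
    records: tuple[IterationRecord, ...] = field(default_factory=tuple)

    @property
    def final_assignment(self) -> tuple[int, ...]:
        if not self.records:
            raise InputError("trace has no records")
        return self.records[-1].assignment

    def assignment_matrix(self) -> np.ndarray:
        """Records-by-objects matrix of cluster labels."""
        return np.array([r.assignment for r in self.records], dtype=np.int64)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _membership_rs(previous: np.ndarray | None, current: np.ndarray,
                   k: int) -> tuple[int, ...]:
    """Per-cluster changed-membership flags against the previous assignment.

    With no previous record, every non-empty cluster is flagged 1 (its
    member set changed from the empty initial allocation).
    """
    flags = []
    for c in range(k):
        now = current == c
        if previous is None:
            flags.append(1 if now.any() else 0)
        else:
            flags.append(0 if np.array_equal(now, previous == c) else 1)
    return tuple(flags)


def _record(index, assignment, rs, conv, deal, criterion, data):
    assignment = np.asarray(assignment, dtype=np.int64)
    return IterationRecord(
        index=index,
        assignment=tuple(int(a) for a in assignment),
        rs=rs,
        conv=int(conv),
        deal=int(deal),
        dunn=dunn(data, assignment),
        diam=max_diameter(data, assignment),
        criterion=float(criterion),
    )


def trace_from_assignments(
    data,
    assignments,
    *,
    algorithm: str = "external",
    parameters: dict | None = None,
    k: int | None = None,
    conv_flags=None,
    deal_flags=None,
) -> IterationTrace:
    """Build a fully-consistent trace from a sequence of assignment vectors.

    ``rs`` flags, criterion (within-cluster sum of squares against the
    current centroids), Dunn and diameter are all recomputed from the data;
    ``conv`` defaults to 0 everywhere except the final record and ``deal``
    to 1 everywhere. This is the workhorse behind synthetic planted traces.
    """
    X = np.asarray(data, dtype=float)
    assignments = [np.asarray(a, dtype=np.int64) for a in assignments]
    if not assignments:
        raise InputError("at least one assignment vector is required")
    n = X.shape[0]
    for i, a in enumerate(assignments):
        if len(a) != n:
            raise InputError(f"assignment {i} has length {len(a)}, expected {n}")
    if k is None:
        k = int(max((int(a.max()) for a in assignments), default=-1)) + 1
    T = len(assignments)
    conv_flags = ([0] * (T - 1) + [1]) if conv_flags is None else list(conv_flags)
    deal_flags = [1] * T if deal_flags is None else list(deal_flags)
    records = []
    previous = None
    for t, a in enumerate(assignments, start=1):
        records.append(_record(
            index=t,
            assignment=a,
            rs=_membership_rs(previous, a, k),
            conv=conv_flags[t - 1],
            deal=deal_flags[t - 1],
            criterion=_wcss(X, a, k),
            data=X,
        ))
        previous = a
    return IterationTrace(
        algorithm=algorithm,
        parameters=dict(parameters or {}),
        n_objects=n,
        k=k,
        object_ids=tuple(range(1, n + 1)),
        records=tuple(records),
    )


def _wcss(X: np.ndarray, assignment: np.ndarray, k: int) -> float:
    """Within-cluster sum of squares against current cluster means."""
    total = 0.0
    for c in range(k):
        members = X[assignment == c]
        if len(members):
            total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# K-Means (Lloyd) with per-sweep instrumentation
# ---------------------------------------------------------------------------

def _init_centroids(X, k, init, rng):
    if isinstance(init, str):
        if init == "random":
            idx = rng.choice(X.shape[0], size=k, replace=False)
            return X[np.sort(idx)].copy()
        if init == "farthest":
            # farthest-point heuristic: seeded first pick, then greedy
            chosen = [int(rng.integers(X.shape[0]))]
            while len(chosen) < k:
                d = cdist(X, X[chosen]).min(axis=1)
                chosen.append(int(d.argmax()))
            return X[chosen].copy()
        raise InputError(f"unknown init strategy: {init!r}")
    centroids = np.asarray(init, dtype=float)
    if centroids.shape != (k, X.shape[1]):
        raise InputError(
            f"explicit centroids must have shape ({k}, {X.shape[1]})")
    return centroids.copy()


def kmeans_trace(
    data,
    k: int,
    *,
    init="random",
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> IterationTrace:
    """Run Lloyd's K-Means, recording one trace record per sweep.

    Each iteration assigns every object to its nearest centroid, repairs
    empty clusters (reseeding with the point farthest from the empty
    cluster's previous centroid), updates the centroids, and evaluates the
    criterion (within-cluster sum of squares). ``conv`` is 1 once the
    criterion changes by at most ``tol`` between consecutive sweeps; the run
    stops at the first convergent record (or ``max_iter``). ``deal`` is 1
    throughout: K-Means allocates every object every sweep.

    ``init`` is ``"random"`` (k distinct seeded data points), ``"farthest"``
    (farthest-point heuristic), or an explicit (k, d) centroid array.
    Deterministic for a fixed seed.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InputError("data must be a non-empty 2-D matrix")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise InputError(f"k must be in [1, {n}], got {k}")
    if max_iter < 1:
        raise InputError("max_iter must be >= 1")
    if tol < 0:
        raise InputError("tol must be >= 0")
    rng = np.random.default_rng(seed)
    centroids = _init_centroids(X, k, init, rng)

    records: list[IterationRecord] = []
    previous_assignment = None
    previous_criterion = None
    for t in range(1, max_iter + 1):
        assignment = cdist(X, centroids).argmin(axis=1)
        # empty-cluster repair: reseed with the point farthest from the
        # empty cluster's current centroid (deterministic, lowest index wins)
        for c in range(k):
            if not (assignment == c).any():
                distances = cdist(X, centroids[c:c + 1]).ravel()
                donor_ok = np.array([
                    (assignment == assignment[i]).sum() > 1 for i in range(n)
                ])
                distances[~donor_ok] = -math.inf
                assignment[int(distances.argmax())] = c
        centroids = np.stack([X[assignment == c].mean(axis=0)
                              for c in range(k)])
        criterion = float(((X - centroids[assignment]) ** 2).sum())
        conv = int(previous_criterion is not None
                   and abs(criterion - previous_criterion) <= tol)
        records.append(_record(
            index=t,
            assignment=assignment,
            rs=_membership_rs(previous_assignment, assignment, k),
            conv=conv,
            deal=1,
            criterion=criterion,
            data=X,
        ))
        if conv:
            break
        previous_assignment = assignment
        previous_criterion = criterion

    return IterationTrace(
        algorithm="kmeans",
        parameters={
            "k": k,
            "init": init if isinstance(init, str) else "explicit",
            "seed": seed,
            "max_iter": max_iter,
            "tol": tol,
        },
        n_objects=n,
        k=k,
        object_ids=tuple(range(1, n + 1)),
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# DBSCAN with per-expansion-round instrumentation
# ---------------------------------------------------------------------------

def dbscan_trace(data, *, eps: float, min_pts: int) -> IterationTrace:
    """Run DBSCAN, recording one record per core-object expansion round.

    Objects are scanned in row order; each unvisited core object seeds a
    cluster which absorbs its full density-reachable set in one round. The
    record taken at the end of a round has ``conv`` = 1 (the round's
    reachable set is exhausted — records are only emitted at that point) and
    ``deal`` = 1 once every object has been processed. Objects never reached
    stay ``UNASSIGNED`` (-1, noise). Degenerate parameters yield an
    all-noise trace with a single closing record.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InputError("data must be a non-empty 2-D matrix")
    if eps <= 0:
        raise InputError("eps must be > 0")
    if min_pts < 1:
        raise InputError("min_pts must be >= 1")
    n = X.shape[0]
    dist = squareform(pdist(X)) if n > 1 else np.zeros((1, 1))
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]  # incl. self

    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    snapshots: list[tuple[np.ndarray, int]] = []  # (assignment copy, deal flag)
    cluster_id = 0
    for p in range(n):
        if visited[p]:
            continue
        visited[p] = True
        if len(neighbors[p]) < min_pts:
            continue  # noise for now; may be claimed as border later
        labels[p] = cluster_id
        seeds = deque(int(q) for q in neighbors[p] if q != p)
        while seeds:
            q = seeds.popleft()
            if labels[q] == UNASSIGNED:
                labels[q] = cluster_id
            if not visited[q]:
                visited[q] = True
                if len(neighbors[q]) >= min_pts:
                    seeds.extend(int(r) for r in neighbors[q]
                                 if labels[r] == UNASSIGNED or not visited[r])
        snapshots.append((labels.copy(), int(visited.all())))
        cluster_id += 1

    if not snapshots or snapshots[-1][1] == 0:
        # trailing noise processed after the last expansion (or all noise):
        # close the trace with a fully-processed snapshot
        snapshots.append((labels.copy(), 1))

    k = cluster_id
    records = []
    previous = None
    for t, (assignment, deal) in enumerate(snapshots, start=1):
        records.append(_record(
            index=t,
            assignment=assignment,
            rs=_membership_rs(previous, assignment, k),
            conv=1,
            deal=deal,
            criterion=float((assignment == UNASSIGNED).sum()),
            data=X,
        ))
        previous = assignment
    return IterationTrace(
        algorithm="dbscan",
        parameters={"eps": eps, "min_pts": min_pts},
        n_objects=n,
        k=k,
        object_ids=tuple(range(1, n + 1)),
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def _encode_index(v: float | None):
    if v is None:
        return None
    if math.isinf(v):
        return "Infinity" if v > 0 else "-Infinity"
    return float(v)


def _decode_index(v, where: str):
    if v is None:
        return None
    if v == "Infinity":
        return math.inf
    if v == "-Infinity":
        return -math.inf
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return float(v)
    raise TraceSchemaError(f"{where}: expected number, null or 'Infinity', got {v!r}")


def trace_to_document(trace: IterationTrace) -> dict:
    """Plain-JSON representation of a trace (schema version 1)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "algorithm": trace.algorithm,
        "parameters": trace.parameters,
        "n_objects": trace.n_objects,
        "k": trace.k,
        "object_ids": list(trace.object_ids),
        "records": [
            {
                "index": r.index,
                "assignment": list(r.assignment),
                "rs": list(r.rs),
                "conv": r.conv,
                "deal": r.deal,
                "dunn": _encode_index(r.dunn),
                "diam": _encode_index(r.diam),
                "criterion": r.criterion,
            }
            for r in trace.records
        ],
    }


def validate_trace_document(doc: dict) -> None:
    """Check a trace document against the schema.

    Raises :class:`TraceSchemaError` naming the offending field and record
    index on the first violation found.
    """
    if not isinstance(doc, dict):
        raise TraceSchemaError("trace document must be a JSON object")
    for fld, typ in [("schema_version", int), ("algorithm", str),
                     ("parameters", dict), ("n_objects", int), ("k", int),
                     ("object_ids", list), ("records", list)]:
        if fld not in doc:
            raise TraceSchemaError(f"missing field: {fld}")
        if not isinstance(doc[fld], typ) or isinstance(doc[fld], bool):
            raise TraceSchemaError(f"{fld}: expected {typ.__name__}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise TraceSchemaError(
            f"schema_version: unsupported version {doc['schema_version']}")
    n, k = doc["n_objects"], doc["k"]
    if n < 1:
        raise TraceSchemaError("n_objects: must be >= 1")
    if k < 0:
        raise TraceSchemaError("k: must be >= 0")
    if len(doc["object_ids"]) != n:
        raise TraceSchemaError(
            f"object_ids: expected {n} entries, got {len(doc['object_ids'])}")
    if not doc["records"]:
        raise TraceSchemaError("records: must be non-empty")
    for i, rec in enumerate(doc["records"]):
        where = f"records[{i}]"
        if not isinstance(rec, dict):
            raise TraceSchemaError(f"{where}: expected object")
        for fld in ("index", "assignment", "rs", "conv", "deal",
                    "dunn", "diam", "criterion"):
            if fld not in rec:
                raise TraceSchemaError(f"{where}.{fld}: missing")
        if rec["index"] != i + 1:
            raise TraceSchemaError(
                f"{where}.index: expected {i + 1}, got {rec['index']}")
        if (not isinstance(rec["assignment"], list)
                or len(rec["assignment"]) != n):
            raise TraceSchemaError(
                f"{where}.assignment: expected list of length {n}")
        for a in rec["assignment"]:
            if not isinstance(a, int) or isinstance(a, bool) or a < -1 or a >= k:
                raise TraceSchemaError(
                    f"{where}.assignment: labels must be -1 or 0..{k - 1}, "
                    f"got {a!r}")
        if not isinstance(rec["rs"], list) or len(rec["rs"]) != k:
            raise TraceSchemaError(f"{where}.rs: expected list of length {k}")
        if any(f not in (0, 1) or isinstance(f, bool) for f in rec["rs"]):
            raise TraceSchemaError(f"{where}.rs: flags must be 0 or 1")
        for fld in ("conv", "deal"):
            if rec[fld] not in (0, 1) or isinstance(rec[fld], bool):
                raise TraceSchemaError(f"{where}.{fld}: must be 0 or 1")
        _decode_index(rec["dunn"], f"{where}.dunn")
        _decode_index(rec["diam"], f"{where}.diam")
        if not isinstance(rec["criterion"], (int, float)) \
                or isinstance(rec["criterion"], bool):
            raise TraceSchemaError(f"{where}.criterion: expected number")


def trace_from_document(doc: dict) -> IterationTrace:
    validate_trace_document(doc)
    records = tuple(
        IterationRecord(
            index=rec["index"],
            assignment=tuple(rec["assignment"]),
            rs=tuple(rec["rs"]),
            conv=rec["conv"],
            deal=rec["deal"],
            dunn=_decode_index(rec["dunn"], "dunn"),
            diam=_decode_index(rec["diam"], "diam"),
            criterion=float(rec["criterion"]),
        )
        for rec in doc["records"]
    )
    return IterationTrace(
        algorithm=doc["algorithm"],
        parameters=doc["parameters"],
        n_objects=doc["n_objects"],
        k=doc["k"],
        object_ids=tuple(doc["object_ids"]),
        records=records,
    )


def write_trace(trace: IterationTrace, path: str | Path) -> None:
    """Serialize a trace to schema-validated JSON."""
    doc = trace_to_document(trace)
    validate_trace_document(doc)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_trace(path: str | Path) -> IterationTrace:
    """Read and validate a trace JSON file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"trace file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise TraceSchemaError(f"not valid JSON: {exc}") from exc
    return trace_from_document(doc)
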