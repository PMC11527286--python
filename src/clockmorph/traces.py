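"""Traced-neuron domain model and I/O.

A traced LNv projection is a rooted tree of 3-D sample points (SWC
convention).  All morphometric distances in this package are measured in the
x–y plane, in µm: traces are derived from maximum-intensity projections, so z
is stored for fidelity but excluded from every length and intersection
computation.  The coordinate convention is: y increases dorsally and the
brain midline is the vertical line ``x = midline_x``.

Landmarks that SWC cannot carry (the POI where the sLNv and lLNv projections
intersect, the main branching point BP, the midline, and the optic-tract
path) live in a JSON sidecar file, one per brain, keeping the SWC files
standard-conformant.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TraceNode",
    "NeuronTrace",
    "Landmarks",
    "BrainRecord",
    "SWCParseError",
    "SWCStructureError",
    "NoBranchingPointError",
    "read_swc",
    "write_swc",
    "read_landmarks",
    "write_landmarks",
    "read_brain",
    "write_brain",
    "load_cohort",
    "save_cohort",
    "geodesic_length",
    "detect_branching_point",
]

NEURON_CLASSES = ("sLNv", "lLNv")
STAGES = ("adult", "L3")
HEMISPHERES = ("left", "right")


class SWCParseError(ValueError):
    """A malformed SWC or sidecar line (carries the line number)."""


class SWCStructureError(ValueError):
    """Node table violates tree structure (bad parent, duplicate id, ...)."""


class NoBranchingPointError(ValueError):
    """No branch node qualifies as the main branching point."""


@dataclass(frozen=True)
class TraceNode:
    """One SWC sample: id, structure code, position (µm), radius, parent."""

    node_id: int
    structure_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None

    def __post_init__(self) -> None:
        if self.node_id <= 0:
            raise ValueError(f"node_id must be positive, got {self.node_id}")
        for name in ("x", "y", "z", "radius"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name} on node {self.node_id}")
        if self.radius < 0:
            raise ValueError(f"negative radius on node {self.node_id}")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


def _xy_dist(a: TraceNode, b: TraceNode) -> float:
    return math.hypot(a.x - b.x, a.y - b.y)


@dataclass
class NeuronTrace:
    """A single traced neuron: a rooted tree of :class:`TraceNode`.

    Invariants enforced at construction: exactly one root, every non-root
    parent appears earlier in the node ordering (which makes the graph an
    acyclic tree), unique node ids, and strictly positive x–y edge lengths.
    """

    nodes: list[TraceNode]
    neuron_class: str = "sLNv"
    neuron_id: str = ""

    def __post_init__(self) -> None:
        if self.neuron_class not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron_class {self.neuron_class!r}")
        if not self.nodes:
            raise ValueError("trace must contain at least one node")
        seen: dict[int, TraceNode] = {}
        roots = 0
        for node in self.nodes:
            if node.node_id in seen:
                raise SWCStructureError(f"duplicate node_id {node.node_id}")
            if node.parent_id is None:
                roots += 1
            else:
                if node.parent_id not in seen:
                    raise SWCStructureError(
                        f"node {node.node_id}: parent {node.parent_id} "
                        "missing or defined later"
                    )
                if _xy_dist(node, seen[node.parent_id]) <= 0.0:
                    raise SWCStructureError(
                        f"edge {node.parent_id}->{node.node_id} has zero "
                        "x-y length"
                    )
            seen[node.node_id] = node
        if roots != 1:
            raise SWCStructureError(f"trace must have exactly 1 root, found {roots}")
        self._by_id = seen

    # -- structure helpers -------------------------------------------------

    def node(self, node_id: int) -> TraceNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id}") from None

    @property
    def root(self) -> TraceNode:
        return next(n for n in self.nodes if n.parent_id is None)

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                out[n.parent_id].append(n.node_id)
        return out

    def leaves(self) -> list[TraceNode]:
        cm = self.children_map()
        return [n for n in self.nodes if not cm[n.node_id]]

    def edges(self) -> list[tuple[TraceNode, TraceNode]]:
        return [
            (self._by_id[n.parent_id], n)
            for n in self.nodes
            if n.parent_id is not None
        ]

    def total_length(self) -> float:
        """Total cable length of the tree in the x–y plane (µm)."""
        return sum(_xy_dist(a, b) for a, b in self.edges())

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        node = self.node(node_id)
        while node.parent_id is not None:
            path.append(node.parent_id)
            node = self._by_id[node.parent_id]
        return path

    def path_between(self, a: int, b: int) -> list[int]:
        """Node ids along the unique tree path a→b (inclusive)."""
        pa = self.path_to_root(a)
        pb = self.path_to_root(b)
        in_pa = {nid: i for i, nid in enumerate(pa)}
        for j, nid in enumerate(pb):
            if nid in in_pa:
                # nid is the lowest common ancestor
                return pa[: in_pa[nid]] + pb[: j + 1][::-1]
        raise SWCStructureError("nodes are not connected")  # pragma: no cover

    def nearest_node(self, point: Sequence[float]) -> TraceNode:
        px, py = float(point[0]), float(point[1])
        return min(self.nodes, key=lambda n: math.hypot(n.x - px, n.y - py))


def geodesic_length(trace: NeuronTrace, a: int, b: int) -> float:
    """Sum of x–y-plane edge lengths along the unique tree path a→b (µm)."""
    path = trace.path_between(a, b)
    return sum(
        _xy_dist(trace.node(u), trace.node(v)) for u, v in zip(path, path[1:])
    )


@dataclass
class Landmarks:
    """Per-brain reference geometry shared by all morphometric measures.

    ``poi`` is mandatory (every measure is anchored there); ``bp`` may be
    absent, in which case it can be auto-detected from the traces;
    ``midline_x`` defines the brain midline as a vertical line; the
    ``optic_tract`` polyline stands in for the lLNv projection path when no
    lLNv trace is available.
    """

    poi: tuple[float, float]
    bp: tuple[float, float] | None = None
    midline_x: float | None = None
    optic_tract: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.poi = (float(self.poi[0]), float(self.poi[1]))
        if self.bp is not None:
            self.bp = (float(self.bp[0]), float(self.bp[1]))
            if self.bp == self.poi:
                raise ValueError("poi and bp must differ")
        if self.optic_tract is not None:
            if len(self.optic_tract) < 2:
                raise ValueError("optic_tract needs >= 2 vertices")
            self.optic_tract = [(float(x), float(y)) for x, y in self.optic_tract]


@dataclass
class BrainRecord:
    """One hemisphere's traced neurons plus landmarks; the unit of morphometry."""

    brain_id: str
    genotype: str
    stage: str
    hemisphere: str
    traces: list[NeuronTrace]
    landmarks: Landmarks

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if not any(t.neuron_class == "sLNv" for t in self.traces):
            raise ValueError("brain must contain at least one sLNv trace")

    def traces_of(self, neuron_class: str) -> list[NeuronTrace]:
        return [t for t in self.traces if t.neuron_class == neuron_class]


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def _format_float(v: float) -> str:
    # repr round-trips exactly through float(); keep integers compact
    return repr(float(v))


def read_swc(path: str | Path) -> list[NeuronTrace]:
    """Read a 7-column SWC file into one trace per connected component.

    A comment line ``# class <sLNv|lLNv> id=<label>`` assigns class and label
    to the next component encountered; components without metadata default to
    sLNv.  Node ids must be unique across the whole file.
    """
    path = Path(path)
    pending_meta: deque[tuple[str, str]] = deque()
    comp_of: dict[int, int] = {}  # node_id -> component index
    comps: list[dict] = []  # {"nodes": [...], "class": str, "id": str}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if fields[:1] == ["class"] and len(fields) >= 2:
                    cls = fields[1]
                    label = ""
                    for tok in fields[2:]:
                        if tok.startswith("id="):
                            label = tok[3:]
                    pending_meta.append((cls, label))
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"{path.name}:{lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                nid = int(fields[0])
                code = int(fields[1])
                x, y, z, radius = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(f"{path.name}:{lineno}: {exc}") from None
            if nid in comp_of:
                raise SWCStructureError(
                    f"{path.name}:{lineno}: duplicate node_id {nid}"
                )
            node = TraceNode(nid, code, x, y, z, radius,
                             None if parent == -1 else parent)
            if node.parent_id is None:
                cls, label = pending_meta.popleft() if pending_meta else ("sLNv", "")
                comps.append({"nodes": [node], "class": cls, "id": label})
                comp_of[nid] = len(comps) - 1
            else:
                if node.parent_id not in comp_of:
                    raise SWCStructureError(
                        f"{path.name}:{lineno}: node {nid} references "
                        f"undefined parent {node.parent_id}"
                    )
                ci = comp_of[node.parent_id]
                comps[ci]["nodes"].append(node)
                comp_of[nid] = ci
    traces = []
    for i, comp in enumerate(comps):
        traces.append(
            NeuronTrace(
                nodes=comp["nodes"],
                neuron_class=comp["class"],
                neuron_id=comp["id"] or f"neuron_{i}",
            )
        )
    return traces


def write_swc(traces: Iterable[NeuronTrace], path: str | Path) -> None:
    """Write traces as standard 7-column SWC with class metadata comments."""
    path = Path(path)
    lines = ["# SWC neuron traces (id type x y z radius parent)"]
    seen_ids: set[int] = set()
    for trace in traces:
        for n in trace.nodes:
            if n.node_id in seen_ids:
                raise SWCStructureError(
                    f"node id {n.node_id} occurs in more than one trace; "
                    "ids must be unique within a file"
                )
            seen_ids.add(n.node_id)
        lines.append(f"# class {trace.neuron_class} id={trace.neuron_id}")
        for n in trace.nodes:
            parent = -1 if n.parent_id is None else n.parent_id
            lines.append(
                f"{n.node_id} {n.structure_code} {_format_float(n.x)} "
                f"{_format_float(n.y)} {_format_float(n.z)} "
                f"{_format_float(n.radius)} {parent}"
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Landmark sidecar I/O (JSON)
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> Landmarks:
    """Read a JSON landmark sidecar; ``poi`` is mandatory."""
    data = json.loads(Path(path).read_text())
    if "poi" not in data:
        raise ValueError(f"{path}: landmark sidecar is missing mandatory key 'poi'")
    return Landmarks(
        poi=tuple(data["poi"]),
        bp=tuple(data["bp"]) if data.get("bp") is not None else None,
        midline_x=data.get("midline_x"),
        optic_tract=[tuple(p) for p in data["optic_tract"]]
        if data.get("optic_tract") is not None
        else None,
    )


def write_landmarks(landmarks: Landmarks, path: str | Path,
                    **extra: object) -> None:
    data: dict = {"poi": list(landmarks.poi)}
    if landmarks.bp is not None:
        data["bp"] = list(landmarks.bp)
    if landmarks.midline_x is not None:
        data["midline_x"] = landmarks.midline_x
    if landmarks.optic_tract is not None:
        data["optic_tract"] = [list(p) for p in landmarks.optic_tract]
    data.update(extra)
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def read_brain(swc_path: str | Path, sidecar_path: str | Path) -> BrainRecord:
    """Assemble a BrainRecord from an SWC file and its JSON sidecar."""
    traces = read_swc(swc_path)
    meta = json.loads(Path(sidecar_path).read_text())
    landmarks = read_landmarks(sidecar_path)
    return BrainRecord(
        brain_id=meta.get("brain_id", Path(swc_path).stem),
        genotype=meta.get("genotype", ""),
        stage=meta.get("stage", "adult"),
        hemisphere=meta.get("hemisphere", "right"),
        traces=traces,
        landmarks=landmarks,
    )


def write_brain(brain: BrainRecord, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    swc_path = out_dir / f"{brain.brain_id}.swc"
    sidecar_path = out_dir / f"{brain.brain_id}.json"
    write_swc(brain.traces, swc_path)
    write_landmarks(
        brain.landmarks,
        sidecar_path,
        brain_id=brain.brain_id,
        genotype=brain.genotype,
        stage=brain.stage,
        hemisphere=brain.hemisphere,
    )
    return swc_path, sidecar_path


def save_cohort(brains: Iterable[BrainRecord], out_dir: str | Path) -> Path:
    """Write each brain's SWC + sidecar plus a tab-separated manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for brain in brains:
        write_brain(brain, out_dir)
        rows.append((brain.brain_id, brain.genotype, brain.stage))
    manifest = out_dir / "manifest.tsv"
    lines = ["brain_id\tgenotype\tstage"]
    lines += ["\t".join(r) for r in rows]
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def load_cohort(in_dir: str | Path) -> list[BrainRecord]:
    in_dir = Path(in_dir)
    brains = []
    for swc_path in sorted(in_dir.glob("*.swc")):
        sidecar = swc_path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing landmark sidecar for {swc_path.name}")
        brains.append(read_brain(swc_path, sidecar))
    return brains


# ---------------------------------------------------------------------------
# Branching-point detection
# ---------------------------------------------------------------------------

def detect_branching_point(
    brain: BrainRecord, min_subtree_length: float = 10.0
) -> tuple[float, float]:
    """Locate the main branching point (BP) of the sLNv bundle.

    If the landmarks already annotate a BP it is returned unchanged.
    Otherwise the sLNv trace with the longest total cable is re-rooted at its
    node nearest the POI and walked distal-ward; the first node (in order of
    geodesic distance from the start) with at least two outgoing subtrees of
    total cable length >= ``min_subtree_length`` µm each is the BP.  The
    subtree-length floor skips micro-spurs so the detected point is the main
    ramification where the stereotypical dorsal arborization begins.
    """
    if brain.landmarks.bp is not None:
        return brain.landmarks.bp
    slnv = brain.traces_of("sLNv")
    if not slnv:
        raise ValueError("brain has no sLNv trace")
    trace = max(slnv, key=lambda t: t.total_length())
    start = trace.nearest_node(brain.landmarks.poi)

    # undirected adjacency with edge lengths
    adj: dict[int, list[tuple[int, float]]] = {n.node_id: [] for n in trace.nodes}
    for a, b in trace.edges():
        d = _xy_dist(a, b)
        adj[a.node_id].append((b.node_id, d))
        adj[b.node_id].append((a.node_id, d))

    # re-root at `start`: parent pointers + distances via BFS (tree => unique)
    parent: dict[int, int | None] = {start.node_id: None}
    dist: dict[int, float] = {start.node_id: 0.0}
    order = [start.node_id]
    queue = deque([start.node_id])
    while queue:
        u = queue.popleft()
        for v, d in adj[u]:
            if v not in parent:
                parent[v] = u
                dist[v] = dist[u] + d
                order.append(v)
                queue.append(v)

    # subtree cable length below each node in the re-rooted orientation
    subtree = {nid: 0.0 for nid in parent}
    for nid in reversed(order):
        p = parent[nid]
        if p is not None:
            subtree[p] += subtree[nid] + dist[nid] - dist[p]

    candidates = []
    # the start node is skipped: re-rooting makes its soma-side neighbour
    # look like a child, which is not a distal ramification
    for nid in order[1:]:
        heavy = [
            v for v, d in adj[nid]
            if parent.get(v) == nid and subtree[v] + d >= min_subtree_length
        ]
        if len(heavy) >= 2:
            candidates.append(nid)
    if not candidates:
        raise NoBranchingPointError(
            "no branching point: no node has >= 2 subtrees of length "
            f">= {min_subtree_length} um"
        )
    best = min(candidates, key=lambda nid: dist[nid])
    node = trace.node(best)
    return (node.x, node.y)
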