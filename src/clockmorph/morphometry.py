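"""LNv morphometry: the six projection measures.

All measures operate on :class:`~clockmorph.traces.BrainRecord` objects in
the x–y plane (µm):

1. total projection length — longest geodesic from the node nearest the POI
   to any sLNv terminal, truncated at the first midline crossing;
2. length to the branching point (POI → BP geodesic);
3. ventral defasciculation — modified Sholl count at the POI
   (6 circles, 25 µm apart);
4. dorsal termini branching — Sholl count at the BP
   (adult: 8 circles 12.5 µm apart; larval: 6 circles 12.5 µm apart);
5. lLNv defasciculation — the same POI circles applied to the lLNv traces;
6. sLNv–lLNv optic-tract contact — whether a post-BP sLNv segment turns
   ventrally and approaches the lLNv/optic-tract path within a tolerance.

Sholl counting is analytic (segment–circle intersection), with a strict
transversal-crossing rule: a point at distance exactly r from the center
belongs to the interior, so grazing contacts count 0 or 2 deterministically,
and a chord passing through an annulus counts both of its crossings — the
quantity counted is visible circle intersections, not neurites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .traces import (
    BrainRecord,
    NeuronTrace,
    NoBranchingPointError,
    detect_branching_point,
    geodesic_length,
)

__all__ = [
    "ShollPreset",
    "MorphometryResult",
    "ADULT_VENTRAL",
    "ADULT_DORSAL",
    "LARVAL_DORSAL",
    "LLNV_OT",
    "sholl_count",
    "total_projection_length",
    "length_to_branching_point",
    "optic_tract_contact",
    "measure_brain",
    "measure_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShollPreset:
    """A named concentric-circle configuration for modified Sholl counting."""

    name: str
    center: str  # "POI" or "BP"
    n_circles: int
    spacing: float  # µm
    target_class: str  # "sLNv" or "lLNv"

    def __post_init__(self) -> None:
        if self.center not in ("POI", "BP"):
            raise ValueError(f"center must be POI or BP, got {self.center!r}")
        if self.n_circles < 1:
            raise ValueError("n_circles must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def radii(self) -> np.ndarray:
        return self.spacing * np.arange(1, self.n_circles + 1)


ADULT_VENTRAL = ShollPreset("adult_ventral", "POI", 6, 25.0, "sLNv")
ADULT_DORSAL = ShollPreset("adult_dorsal", "BP", 8, 12.5, "sLNv")
LARVAL_DORSAL = ShollPreset("larval_dorsal", "BP", 6, 12.5, "sLNv")
LLNV_OT = ShollPreset("llnv_ot", "POI", 6, 25.0, "lLNv")


@dataclass
class MorphometryResult:
    """Per-brain measure row; optional fields are None when not applicable."""

    brain_id: str
    genotype: str
    stage: str
    total_length: float | None = None
    length_to_bp: float | None = None
    ventral_sholl: int | None = None
    dorsal_sholl: int | None = None
    llnv_sholl: int | None = None
    ot_contact: bool | None = None


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _class_edges(brain: BrainRecord, neuron_class: str) -> np.ndarray:
    """(E, 2, 2) array of x-y segment endpoints for all traces of a class."""
    segs = []
    for trace in brain.traces:
        if trace.neuron_class != neuron_class:
            continue
        for a, b in trace.edges():
            segs.append(((a.x, a.y), (b.x, b.y)))
    if not segs:
        return np.empty((0, 2, 2))
    return np.asarray(segs, dtype=float)


def _circle_crossings(segments: np.ndarray, center: Sequence[float],
                      radii: np.ndarray) -> int:
    """Total transversal crossings of ``segments`` with circles |p-c| = r.

    Per segment and radius: one crossing when exactly one endpoint is inside
    (distance <= r), two when both endpoints are outside but the interior of
    the segment dips strictly inside the circle, else zero.
    """
    if len(segments) == 0:
        return 0
    c = np.asarray(center, dtype=float)
    a = segments[:, 0, :] - c
    b = segments[:, 1, :] - c
    da = np.hypot(a[:, 0], a[:, 1])
    db = np.hypot(b[:, 0], b[:, 1])
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    # closest-approach parameter of the infinite line to the center
    t_star = np.where(seg_len2 > 0, -np.einsum("ij,ij->i", a, ab) /
                      np.where(seg_len2 > 0, seg_len2, 1.0), 0.0)
    interior = (t_star > 0.0) & (t_star < 1.0)
    closest = a + t_star[:, None] * ab
    d_min = np.hypot(closest[:, 0], closest[:, 1])

    total = 0
    for r in radii:
        in_a = da <= r
        in_b = db <= r
        one = in_a != in_b
        two = (~in_a) & (~in_b) & interior & (d_min < r)
        total += int(one.sum()) + 2 * int(two.sum())
    return total


def _resolve_center(brain: BrainRecord, preset: ShollPreset) -> tuple[float, float]:
    if preset.center == "POI":
        return brain.landmarks.poi
    return detect_branching_point(brain)


# ---------------------------------------------------------------------------
# the six measures
# ---------------------------------------------------------------------------

def sholl_count(brain: BrainRecord, preset: ShollPreset) -> int:
    """Total intersections of target-class traces with the preset's circles."""
    center = _resolve_center(brain, preset)
    segments = _class_edges(brain, preset.target_class)
    if len(segments) == 0:
        raise ValueError(
            f"brain {brain.brain_id} has no {preset.target_class} trace"
        )
    return _circle_crossings(segments, center, preset.radii)


def _clipped_path_length(trace: NeuronTrace, start_id: int, end_id: int,
                         midline_x: float | None) -> float:
    """Geodesic start→end, truncated at the first crossing of x = midline_x."""
    path = trace.path_between(start_id, end_id)
    length = 0.0
    prev = trace.node(path[0])
    for nid in path[1:]:
        node = trace.node(nid)
        step = math.hypot(node.x - prev.x, node.y - prev.y)
        if midline_x is not None and (prev.x - midline_x) * (node.x - midline_x) < 0:
            frac = (midline_x - prev.x) / (node.x - prev.x)
            return length + frac * step
        length += step
        if midline_x is not None and node.x == midline_x:
            return length
        prev = node
    return length


def total_projection_length(brain: BrainRecord) -> float:
    """Longest POI→terminal geodesic over all sLNv traces, midline-clipped."""
    best = 0.0
    midline = brain.landmarks.midline_x
    for trace in brain.traces_of("sLNv"):
        start = trace.nearest_node(brain.landmarks.poi)
        for leaf in trace.leaves():
            best = max(
                best,
                _clipped_path_length(trace, start.node_id, leaf.node_id, midline),
            )
    if best == 0.0 and not brain.traces_of("sLNv"):
        raise ValueError("brain has no sLNv trace")
    return best


def length_to_branching_point(brain: BrainRecord) -> float:
    """Geodesic from the node nearest the POI to the node nearest the BP.

    Measured along the sLNv trace with the longest total cable.
    """
    bp = detect_branching_point(brain)
    slnv = brain.traces_of("sLNv")
    trace = max(slnv, key=lambda t: t.total_length())
    start = trace.nearest_node(brain.landmarks.poi)
    end = trace.nearest_node(bp)
    return geodesic_length(trace, start.node_id, end.node_id)


def _point_seg_dist(pt: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    """Distance from points to segments; all arguments broadcast to (...,2)."""
    d = s1 - s0
    len2 = np.einsum("...i,...i->...", d, d)
    t = np.clip(
        np.einsum("...i,...i->...", pt - s0, d) / np.where(len2 > 0, len2, 1.0),
        0.0, 1.0,
    )
    diff = pt - (s0 + t[..., None] * d)
    return np.sqrt(np.einsum("...i,...i->...", diff, diff))


def _seg_seg_dist(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Pairwise (N, M) min distances between segment sets p (N,2,2), q (M,2,2).

    Computed as the min of the four endpoint-to-segment distances.  This is
    exact unless two segments cross (true distance 0); with ~2 µm trace
    steps the residual error is far below the contact tolerance.
    """
    p0 = p[:, None, 0, :]
    p1 = p[:, None, 1, :]
    q0 = q[None, :, 0, :]
    q1 = q[None, :, 1, :]
    return np.minimum.reduce([
        _point_seg_dist(p0, q0, q1),
        _point_seg_dist(p1, q0, q1),
        _point_seg_dist(q0, p0, p1),
        _point_seg_dist(q1, p0, p1),
    ])


def optic_tract_contact(brain: BrainRecord, tolerance: float = 2.0) -> bool:
    """True iff a post-BP sLNv segment approaches the lLNv/optic-tract path
    within ``tolerance`` µm while heading ventrally (y decreasing)."""
    ref_segments = _class_edges(brain, "lLNv")
    if len(ref_segments) == 0:
        ot = brain.landmarks.optic_tract
        if ot is None:
            raise ValueError(
                "nothing to test contact against: no lLNv trace and no "
                "optic_tract landmark"
            )
        pts = np.asarray(ot, dtype=float)
        ref_segments = np.stack([pts[:-1], pts[1:]], axis=1)

    bp = detect_branching_point(brain)
    for trace in brain.traces_of("sLNv"):
        start = trace.nearest_node(brain.landmarks.poi)
        bp_node = trace.nearest_node(bp)
        # nodes beyond the BP: flood-fill from the BP node in the undirected
        # tree, blocked along the edge that leads back toward the start
        bp_path = trace.path_between(start.node_id, bp_node.node_id)
        toward_start = bp_path[-2] if len(bp_path) >= 2 else None
        adj: dict[int, list[int]] = {n.node_id: [] for n in trace.nodes}
        for a, b in trace.edges():
            adj[a.node_id].append(b.node_id)
            adj[b.node_id].append(a.node_id)
        beyond: set[int] = {bp_node.node_id}
        stack = [n for n in adj[bp_node.node_id] if n != toward_start]
        while stack:
            nid = stack.pop()
            if nid in beyond:
                continue
            beyond.add(nid)
            stack.extend(v for v in adj[nid] if v not in beyond)
        segs = []
        headings = []
        for a, b in trace.edges():
            if a.node_id in beyond and b.node_id in beyond:
                segs.append(((a.x, a.y), (b.x, b.y)))
                headings.append(b.y - a.y)
        if not segs:
            continue
        seg_arr = np.asarray(segs)
        d = _seg_seg_dist(seg_arr, ref_segments).min(axis=1)
        ventral = np.asarray(headings) < 0
        if bool(np.any((d <= tolerance) & ventral)):
            return True
    return False


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def measure_brain(brain: BrainRecord, stage: str | None = None) -> MorphometryResult:
    """Compute the stage-appropriate measures; failures become missing values.

    Adult brains get ventral + dorsal + lLNv Sholl counts and the contact
    flag; L3 brains get lengths and larval dorsal branching only.
    """
    stage = stage or brain.stage
    result = MorphometryResult(brain.brain_id, brain.genotype, stage)

    def attempt(field_name, fn):
        try:
            setattr(result, field_name, fn())
        except (ValueError, NoBranchingPointError) as exc:
            logger.warning("%s: %s failed: %s", brain.brain_id, field_name, exc)

    attempt("total_length", lambda: total_projection_length(brain))
    attempt("length_to_bp", lambda: length_to_branching_point(brain))
    if stage == "adult":
        attempt("ventral_sholl", lambda: sholl_count(brain, ADULT_VENTRAL))
        attempt("dorsal_sholl", lambda: sholl_count(brain, ADULT_DORSAL))
        attempt("llnv_sholl", lambda: sholl_count(brain, LLNV_OT))
        attempt("ot_contact", lambda: optic_tract_contact(brain))
    else:
        attempt("dorsal_sholl", lambda: sholl_count(brain, LARVAL_DORSAL))
    return result


def measure_cohort(brains: Iterable[BrainRecord]) -> pd.DataFrame:
    """One measure row per brain, sorted by genotype then brain_id."""
    rows = [measure_brain(b).__dict__ for b in brains]
    df = pd.DataFrame(rows)
    return df.sort_values(["genotype", "brain_id"]).reset_index(drop=True)
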