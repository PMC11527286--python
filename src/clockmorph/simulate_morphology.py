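"""Synthetic LNv projection-bundle generator.

Emulates the geometry that the morphometry assumes: four sLNv axons that
share a common spine running from the ventral soma region through the POI
toward the dorsal protocerebrum, a main branching point (BP) at a controlled
geodesic distance from the POI where a random dorsal arbor sprouts, and lLNv
projections running along the optic tract.  Per-"genotype" knobs control
lateral bundle spread (fasciculation), where along the path spreading starts,
the probability of misrouting toward the optic tract, BP distance, and
dorsal-arbor richness.

The jitter model is a lateral Gaussian random walk per neuron (offsets
accumulate step to step rather than being redrawn i.i.d.), so bundles diverge
smoothly the way defasciculating axons do, rather than producing white-noise
wiggle around a common path.

Everything is reproducible: each brain's RNG is derived counter-style from
(seed, genotype, brain index), so cohorts are independent of generation
order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .traces import BrainRecord, Landmarks, NeuronTrace, TraceNode

__all__ = [
    "MorphGenParams",
    "generate_brain",
    "generate_cohort",
    "CONTROL_ADULT",
    "DEFASCICULATED_ADULT",
    "MISROUTED_ADULT",
    "CONTROL_L3",
]

_ADULT_WAYPOINTS = (
    (-10.0, -30.0),  # soma region, ventral to the POI
    (0.0, 0.0),      # POI: sLNv bundle crosses the lLNv/optic-tract path
    (10.0, 60.0),
    (25.0, 130.0),
    (45.0, 190.0),
    (70.0, 230.0),   # dorsal terminus of the spine
)
_ADULT_OPTIC_TRACT = ((-80.0, -12.0), (0.0, 0.0), (70.0, -15.0), (140.0, -45.0))
_L3_WAYPOINTS = (
    (-6.0, -18.0),
    (0.0, 0.0),
    (6.0, 35.0),
    (14.0, 75.0),
    (26.0, 110.0),
)
_L3_OPTIC_TRACT = ((-45.0, -8.0), (0.0, 0.0), (60.0, -18.0))


@dataclass(frozen=True)
class MorphGenParams:
    """Controls for one genotype's brain geometry.

    Units are µm throughout.  ``fasciculation_sd`` is the per-step standard
    deviation of the lateral random walk applied independently to each sLNv;
    0 collapses the bundle onto a single shared polyline.
    ``defasciculation_onset`` is the fraction of the spine's arc length
    before which the walk is frozen.  ``misroute_prob`` is the per-neuron
    probability of growing a deviant ventral extension from the dorsal
    terminus toward a random point on the optic tract.
    """

    n_slnv: int = 4
    n_llnv: int = 4
    path_waypoints: tuple[tuple[float, float], ...] = _ADULT_WAYPOINTS
    step: float = 2.0
    fasciculation_sd: float = 0.4
    defasciculation_onset: float = 0.7
    misroute_prob: float = 0.0
    bp_distance: float = 160.0
    dorsal_branch_mean: float = 3.0
    dorsal_branch_length_mean: float = 25.0
    midline_x: float = 110.0
    optic_tract_span: tuple[tuple[float, float], ...] = _ADULT_OPTIC_TRACT
    stage: str = "adult"
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_slnv < 1:
            bad.append("n_slnv >= 1")
        if self.n_llnv < 0:
            bad.append("n_llnv >= 0")
        if self.step <= 0:
            bad.append("step > 0")
        if self.fasciculation_sd < 0:
            bad.append("fasciculation_sd >= 0")
        if not 0.0 <= self.misroute_prob <= 1.0:
            bad.append("0 <= misroute_prob <= 1")
        if not 0.0 <= self.defasciculation_onset <= 1.0:
            bad.append("0 <= defasciculation_onset <= 1")
        if len(self.path_waypoints) < 2:
            bad.append("path_waypoints needs >= 2 vertices")
        else:
            total = _polyline_length(self.path_waypoints)
            poi_arc = _arc_at_nearest(self.path_waypoints, (0.0, 0.0))
            if self.bp_distance >= total - poi_arc:
                bad.append("bp_distance < spine length beyond the POI")
        if self.dorsal_branch_length_mean <= 0:
            bad.append("dorsal_branch_length_mean > 0")
        if self.stage not in ("adult", "L3"):
            bad.append("stage in {adult, L3}")
        if bad:
            raise ValueError("invalid MorphGenParams: " + "; ".join(bad))


# documented parameter presets used throughout the tests and examples -------

CONTROL_ADULT = MorphGenParams()
"""Tightly fasciculated bundle that only spreads past the BP (onset 0.7 of
the path, i.e. around the main branching point); the BP lies beyond the
outermost ventral Sholl circle, so ventral counts sit at the 4-neuron floor."""

DEFASCICULATED_ADULT = replace(
    CONTROL_ADULT,
    fasciculation_sd=1.5,
    defasciculation_onset=0.05,
    bp_distance=110.0,
)
"""Loose bundle spreading from the ventral brain with a proximalized BP."""

MISROUTED_ADULT = replace(CONTROL_ADULT, misroute_prob=1.0)
"""Every sLNv turns ventrally after the dorsal terminus toward the optic tract."""

CONTROL_L3 = MorphGenParams(
    n_llnv=0,
    path_waypoints=_L3_WAYPOINTS,
    bp_distance=60.0,
    dorsal_branch_length_mean=15.0,
    midline_x=60.0,
    optic_tract_span=_L3_OPTIC_TRACT,
    stage="L3",
)
"""Larval-scale bundle (no lLNvs at L3)."""


# ---------------------------------------------------------------------------
# polyline helpers
# ---------------------------------------------------------------------------

def _polyline_length(points: Sequence[Sequence[float]]) -> float:
    p = np.asarray(points, dtype=float)
    return float(np.hypot(*np.diff(p, axis=0).T).sum())


def _arc_at_nearest(points: Sequence[Sequence[float]], target) -> float:
    """Arc length at the polyline vertex nearest to ``target``."""
    p = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(p, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    d = np.hypot(p[:, 0] - target[0], p[:, 1] - target[1])
    return float(arc[int(np.argmin(d))])


def _resample(points: Sequence[Sequence[float]], step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing (endpoint kept)."""
    p = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(p, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(1, int(math.floor(total / step)))
    s = np.linspace(0.0, total, n + 1)
    x = np.interp(s, arc, p[:, 0])
    y = np.interp(s, arc, p[:, 1])
    return np.column_stack([x, y])


def _normals(path: np.ndarray) -> np.ndarray:
    """Unit normals (left of travel) at each vertex of a polyline."""
    d = np.gradient(path, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    t = d / norm[:, None]
    return np.column_stack([-t[:, 1], t[:, 0]])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _subseed(seed: int, genotype: str, index: int) -> np.random.SeedSequence:
    # counter-based derivation: order of generation cannot matter
    return np.random.SeedSequence((int(seed), zlib.crc32(genotype.encode()), int(index)))


class _IdAllocator:
    def __init__(self) -> None:
        self.next_id = 1

    def take(self) -> int:
        nid = self.next_id
        self.next_id += 1
        return nid


def _polyline_to_nodes(
    path: np.ndarray, ids: _IdAllocator, *, structure_code: int = 2,
    radius: float = 0.4, attach_to: TraceNode | None = None,
) -> list[TraceNode]:
    """Convert an x-y polyline into a chain of TraceNodes.

    Consecutive duplicate points (zero x-y step) are dropped so every edge
    has strictly positive planar length.
    """
    nodes: list[TraceNode] = []
    prev = attach_to
    for x, y in path:
        if prev is not None and math.hypot(x - prev.x, y - prev.y) < 1e-9:
            continue
        node = TraceNode(
            ids.take(), structure_code, float(x), float(y), 0.0, radius,
            None if prev is None else prev.node_id,
        )
        nodes.append(node)
        prev = node
    return nodes


def _grow_arbor_paths(
    bp_xy: np.ndarray, base_dir: np.ndarray, rng: np.random.Generator,
    params: MorphGenParams,
) -> list[np.ndarray]:
    """Random dorsal arbor skeleton: >= 2 branch polylines rooted at the BP.

    The skeleton is drawn once per brain (the arborization pattern is a
    property of the bundle's target territory); each neuron gets a jittered
    copy, so a zero-jitter bundle is geometrically a single shared polyline.
    """
    n_branches = max(2, int(rng.poisson(params.dorsal_branch_mean)))
    base_angle = math.atan2(base_dir[1], base_dir[0])
    paths = []
    for _ in range(n_branches):
        heading = base_angle + rng.uniform(-1.2, 1.2)
        length = max(12.0, rng.exponential(params.dorsal_branch_length_mean))
        n_steps = max(2, int(round(length / params.step)))
        pts = [bp_xy]
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.12)  # gentle meander
            pts.append(pts[-1] + params.step * np.array(
                [math.cos(heading), math.sin(heading)]))
        paths.append(np.asarray(pts))
    return paths


def _misroute_extension(
    origin: TraceNode, rng: np.random.Generator, params: MorphGenParams,
    ids: _IdAllocator,
) -> list[TraceNode]:
    """Deviant ventral extension from the dorsal terminus to the optic tract."""
    ot = np.asarray(params.optic_tract_span, dtype=float)
    dense = _resample(ot, params.step)
    target = dense[rng.integers(0, len(dense))]
    path = _resample(np.array([[origin.x, origin.y], target]), params.step)
    return _polyline_to_nodes(path[1:], ids, attach_to=origin)


def generate_brain(params: MorphGenParams, brain_id: str = "brain-000",
                   genotype: str = "control") -> BrainRecord:
    """Generate one BrainRecord from ``params``; reproducible from its seed."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    return _generate_brain_rng(params, rng, brain_id, genotype)


def _generate_brain_rng(
    params: MorphGenParams, rng: np.random.Generator, brain_id: str,
    genotype: str,
) -> BrainRecord:
    spine = _resample(np.asarray(params.path_waypoints, float), params.step)
    normals = _normals(spine)
    seg = np.hypot(*np.diff(spine, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    frac = arc / total

    poi_idx = int(np.argmin(np.hypot(spine[:, 0], spine[:, 1])))
    poi = (float(spine[poi_idx, 0]), float(spine[poi_idx, 1]))
    bp_arc = arc[poi_idx] + params.bp_distance
    bp_idx = int(np.argmin(np.abs(arc - bp_arc)))
    bp = (float(spine[bp_idx, 0]), float(spine[bp_idx, 1]))

    tangent = spine[min(bp_idx + 1, len(spine) - 1)] - spine[max(bp_idx - 1, 0)]
    arbor_paths = _grow_arbor_paths(spine[bp_idx], tangent, rng, params)

    ids = _IdAllocator()
    traces: list[NeuronTrace] = []
    for i in range(params.n_slnv):
        # lateral random walk along the spine, frozen before the onset
        active = frac >= params.defasciculation_onset
        steps = rng.normal(0.0, params.fasciculation_sd, size=len(spine))
        steps[~active] = 0.0
        offset = np.cumsum(steps)
        path = spine + offset[:, None] * normals
        spine_nodes = _polyline_to_nodes(path, ids, radius=0.4)
        nodes = list(spine_nodes)
        bp_node = spine_nodes[min(bp_idx, len(spine_nodes) - 1)]
        bp_shift = np.array([bp_node.x, bp_node.y]) - spine[bp_idx]
        for branch in arbor_paths:
            # jittered copy of the shared arbor, re-anchored at this
            # neuron's own BP position
            bsteps = rng.normal(0.0, params.fasciculation_sd, size=len(branch))
            bsteps[0] = 0.0
            boffset = np.cumsum(bsteps)
            bpath = branch + bp_shift + boffset[:, None] * _normals(branch)
            nodes += _polyline_to_nodes(bpath[1:], ids, radius=0.3,
                                        attach_to=bp_node)
        if rng.uniform() < params.misroute_prob:
            # deviant ventral growth from the dorsal terminus of the spine
            nodes += _misroute_extension(spine_nodes[-1], rng, params, ids)
        traces.append(NeuronTrace(nodes, "sLNv", f"sLNv_{i}"))

    ot_dense = _resample(np.asarray(params.optic_tract_span, float), params.step)
    ot_normals = _normals(ot_dense)
    for i in range(params.n_llnv):
        steps = rng.normal(0.0, 0.25, size=len(ot_dense))
        offset = np.cumsum(steps)
        path = ot_dense + offset[:, None] * ot_normals
        nodes = _polyline_to_nodes(path, ids, radius=0.6)
        traces.append(NeuronTrace(nodes, "lLNv", f"lLNv_{i}"))

    landmarks = Landmarks(
        poi=poi,
        bp=bp,
        midline_x=params.midline_x,
        optic_tract=[tuple(p) for p in np.asarray(params.optic_tract_span, float)],
    )
    return BrainRecord(
        brain_id=brain_id,
        genotype=genotype,
        stage=params.stage,
        hemisphere="right",
        traces=traces,
        landmarks=landmarks,
    )


def generate_cohort(
    params_by_genotype: Mapping[str, MorphGenParams],
    n_brains: int,
    seed: int = 0,
) -> list[BrainRecord]:
    """Generate ``n_brains`` per genotype with order-independent sub-seeds."""
    if n_brains < 1:
        raise ValueError("n_brains must be >= 1")
    brains = []
    for genotype, params in params_by_genotype.items():
        params.validate()
        for i in range(n_brains):
            rng = np.random.default_rng(_subseed(seed, genotype, i))
            brains.append(
                _generate_brain_rng(params, rng, f"{genotype}-{i:03d}", genotype)
            )
    return brains
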