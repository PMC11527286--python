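"""Trace model: SWC/sidecar I/O, geodesics, branch-point detection."""

import math

import numpy as np
import pytest

from clockmorph.traces import (
    BrainRecord,
    Landmarks,
    NeuronTrace,
    NoBranchingPointError,
    SWCParseError,
    SWCStructureError,
    TraceNode,
    detect_branching_point,
    geodesic_length,
    read_landmarks,
    read_swc,
    write_landmarks,
    write_swc,
)
from conftest import random_trace
from oracles import path_length_by_bfs


def chain(points, start_id=1, cls="sLNv"):
    nodes = []
    for i, (x, y) in enumerate(points):
        nodes.append(
            TraceNode(start_id + i, 2, float(x), float(y), 0.0, 0.5,
                      None if i == 0 else start_id + i - 1)
        )
    return NeuronTrace(nodes, cls, f"chain_{start_id}")


class TestSWC:
    def test_single_root_node_roundtrip(self, tmp_path):
        trace = NeuronTrace([TraceNode(1, 1, 0.0, 0.0, 0.0, 1.0, None)])
        path = tmp_path / "one.swc"
        write_swc([trace], path)
        back = read_swc(path)
        assert len(back) == 1
        assert len(back[0].nodes) == 1
        assert back[0].total_length() == 0.0

    def test_roundtrip_preserves_node_table(self, tmp_path, rng):
        traces = []
        next_id = 1
        for k in range(50):
            n = int(rng.integers(2, 40))
            cls = "sLNv" if rng.uniform() < 0.5 else "lLNv"
            traces.append(random_trace(rng, n, cls, start_id=next_id))
            next_id += n
        path = tmp_path / "many.swc"
        write_swc(traces, path)
        back = read_swc(path)
        assert len(back) == len(traces)
        for orig, rt in zip(traces, back):
            assert rt.neuron_class == orig.neuron_class
            assert rt.neuron_id == orig.neuron_id
            assert len(rt.nodes) == len(orig.nodes)
            for a, b in zip(orig.nodes, rt.nodes):
                assert a == b  # field-for-field dataclass equality

    def test_forward_parent_reference_rejected(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 2 0 1 0 1 5\n")
        with pytest.raises(SWCStructureError, match="parent 5"):
            read_swc(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 2 oops\n")
        with pytest.raises(SWCParseError, match=":2"):
            read_swc(path)

    def test_duplicate_node_id_rejected(self, tmp_path):
        path = tmp_path / "dup.swc"
        path.write_text("1 1 0 0 0 1 -1\n1 2 0 1 0 1 1\n")
        with pytest.raises(SWCStructureError, match="duplicate"):
            read_swc(path)

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.swc"
        write_swc([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_two_node_trace_child_references_root(self, tmp_path):
        path = tmp_path / "two.swc"
        write_swc([chain([(0, 0), (0, 5)])], path)
        data = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(data) == 2
        assert data[1].split()[-1] == data[0].split()[0]

    def test_zero_length_edge_rejected(self):
        with pytest.raises(SWCStructureError, match="zero"):
            NeuronTrace([
                TraceNode(1, 1, 0.0, 0.0, 0.0, 1.0, None),
                TraceNode(2, 2, 0.0, 0.0, 5.0, 1.0, 1),  # differs only in z
            ])

    def test_multiple_roots_in_one_trace_rejected(self):
        with pytest.raises(SWCStructureError, match="root"):
            NeuronTrace([
                TraceNode(1, 1, 0.0, 0.0, 0.0, 1.0, None),
                TraceNode(2, 1, 1.0, 0.0, 0.0, 1.0, None),
            ])


class TestLandmarks:
    def test_minimal_sidecar(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text('{"poi": [1.0, 2.0], "midline_x": 110.0}')
        lm = read_landmarks(path)
        assert lm.poi == (1.0, 2.0)
        assert lm.midline_x == 110.0
        assert lm.bp is None and lm.optic_tract is None

    def test_roundtrip(self, tmp_path):
        lm = Landmarks(poi=(0.5, -1.25), bp=(3.0, 4.0), midline_x=100.0,
                       optic_tract=[(-10.0, 0.0), (5.0, -2.0), (20.0, -8.0)])
        path = tmp_path / "lm.json"
        write_landmarks(lm, path)
        back = read_landmarks(path)
        assert back == lm

    def test_missing_poi_is_an_error(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text('{"midline_x": 100.0}')
        with pytest.raises(ValueError, match="poi"):
            read_landmarks(path)

    def test_poi_equal_bp_rejected(self):
        with pytest.raises(ValueError):
            Landmarks(poi=(1.0, 1.0), bp=(1.0, 1.0))

    def test_single_vertex_optic_tract_rejected(self):
        with pytest.raises(ValueError):
            Landmarks(poi=(0.0, 0.0), optic_tract=[(1.0, 1.0)])


class TestGeodesic:
    def test_identity(self):
        trace = chain([(0, 0), (3, 0), (3, 4)])
        assert geodesic_length(trace, 2, 2) == 0.0

    def test_pythagorean_chain(self):
        trace = chain([(0, 0), (3, 0), (3, 4)])
        assert geodesic_length(trace, 1, 3) == pytest.approx(7.0)

    def test_matches_bfs_oracle_on_random_trees(self, rng):
        for _ in range(20):
            trace = random_trace(rng, 40)
            ids = [n.node_id for n in trace.nodes]
            a, b = rng.choice(ids, 2, replace=False)
            expected = path_length_by_bfs(trace, int(a), int(b))
            assert geodesic_length(trace, int(a), int(b)) == pytest.approx(expected)

    def test_symmetry_and_triangle_additivity(self, rng):
        trace = random_trace(rng, 60)
        ids = [n.node_id for n in trace.nodes]
        a, c = (int(v) for v in rng.choice(ids, 2, replace=False))
        assert geodesic_length(trace, a, c) == pytest.approx(
            geodesic_length(trace, c, a)
        )
        path = trace.path_between(a, c)
        b = path[len(path) // 2]
        assert geodesic_length(trace, a, c) == pytest.approx(
            geodesic_length(trace, a, b) + geodesic_length(trace, b, c)
        )

    def test_unknown_node_raises(self):
        trace = chain([(0, 0), (1, 0)])
        with pytest.raises(KeyError):
            geodesic_length(trace, 1, 99)


def make_brain(traces, poi=(0.0, 0.0), bp=None):
    return BrainRecord("b0", "ctrl", "adult", "right", traces,
                       Landmarks(poi=poi, bp=bp, midline_x=1000.0))


class TestBranchingPoint:
    def test_unbranched_chain_has_no_bp(self):
        trace = chain([(0, 0), (0, 50), (0, 100)])
        with pytest.raises(NoBranchingPointError):
            detect_branching_point(make_brain([trace]))

    def test_y_shape_fork_detected(self):
        nodes = [TraceNode(1, 1, 0.0, 0.0, 0.0, 0.5, None)]
        # trunk up to (0, 100), then two 20 um arms
        for i, y in enumerate(range(10, 101, 10), start=2):
            nodes.append(TraceNode(i, 2, 0.0, float(y), 0.0, 0.5, i - 1))
        fork_id = nodes[-1].node_id
        nid = fork_id
        for k in range(1, 3):
            nodes.append(TraceNode(nid + 1, 2, 10.0 * k, 100.0 + 10.0 * k,
                                   0.0, 0.5, fork_id if k == 1 else nid))
            nid += 1
        for k in range(1, 3):
            nodes.append(TraceNode(nid + 1, 2, -10.0 * k, 100.0 + 10.0 * k,
                                   0.0, 0.5, fork_id if k == 1 else nid))
            nid += 1
        brain = make_brain([NeuronTrace(nodes)])
        assert detect_branching_point(brain) == (0.0, 100.0)

    def test_micro_spur_is_skipped(self):
        nodes = [TraceNode(1, 1, 0.0, 0.0, 0.0, 0.5, None)]
        for i, y in enumerate(range(10, 101, 10), start=2):
            nodes.append(TraceNode(i, 2, 0.0, float(y), 0.0, 0.5, i - 1))
        # 3 um spur at (0, 50) must not qualify as the BP
        nodes.append(TraceNode(50, 2, 3.0, 50.0, 0.0, 0.5, 6))
        fork_id = 11  # node at (0, 100)
        nodes.append(TraceNode(60, 2, 15.0, 110.0, 0.0, 0.5, fork_id))
        nodes.append(TraceNode(61, 2, -15.0, 110.0, 0.0, 0.5, fork_id))
        brain = make_brain([NeuronTrace(nodes)])
        assert detect_branching_point(brain) == (0.0, 100.0)

    def test_annotated_bp_returned_unchanged(self):
        trace = chain([(0, 0), (0, 50)])
        brain = make_brain([trace], bp=(12.5, 40.0))
        assert detect_branching_point(brain) == (12.5, 40.0)
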