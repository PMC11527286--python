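"""Morphometry: analytic Sholl vs dense sampling, clipping, contact, tables."""

import dataclasses
import math

import numpy as np
import pytest

from clockmorph.morphometry import (
    ADULT_DORSAL,
    ADULT_VENTRAL,
    LLNV_OT,
    ShollPreset,
    measure_brain,
    measure_cohort,
    optic_tract_contact,
    sholl_count,
    total_projection_length,
)
from clockmorph.simulate_morphology import (
    CONTROL_ADULT,
    DEFASCICULATED_ADULT,
    generate_brain,
    generate_cohort,
)
from clockmorph.traces import (
    BrainRecord,
    Landmarks,
    NeuronTrace,
    TraceNode,
    detect_branching_point,
)
from oracles import sholl_by_dense_sampling


def chain(points, start_id=1, cls="sLNv"):
    nodes = []
    for i, (x, y) in enumerate(points):
        nodes.append(TraceNode(start_id + i, 2, float(x), float(y), 0.0, 0.5,
                               None if i == 0 else start_id + i - 1))
    return NeuronTrace(nodes, cls, f"t{start_id}")


def brain_of(traces, poi=(0.0, 0.0), bp=None, midline_x=None, optic_tract=None):
    return BrainRecord("b0", "g", "adult", "right", traces,
                       Landmarks(poi=poi, bp=bp, midline_x=midline_x,
                                 optic_tract=optic_tract))


class TestShollCount:
    def test_four_radial_traces_cross_every_circle_once(self):
        traces = []
        for k, angle in enumerate(np.linspace(0, 2 * math.pi, 4, endpoint=False)):
            pts = [(r * math.cos(angle), r * math.sin(angle))
                   for r in np.linspace(1e-3, 200, 50)]
            traces.append(chain(pts, start_id=1 + 100 * k))
        brain = brain_of(traces)
        assert sholl_count(brain, ADULT_VENTRAL) == 4 * 6

    def test_trace_inside_innermost_circle_counts_zero(self):
        brain = brain_of([chain([(0, 0), (5, 5), (10, 0)])])
        assert sholl_count(brain, ADULT_VENTRAL) == 0

    def test_chord_through_annulus_counts_twice(self):
        # horizontal chord at y=24.9 dips inside the r=25 circle only
        brain = brain_of([chain([(-30, 24.9), (30, 24.9)])])
        preset = ShollPreset("one", "POI", 1, 25.0, "sLNv")
        assert sholl_count(brain, preset) == 2

    def test_missing_center_landmark_is_an_error(self):
        brain = brain_of([chain([(0, 0), (0, 50)])])  # unbranched: no BP
        with pytest.raises(Exception):
            sholl_count(brain, ADULT_DORSAL)

    def test_no_target_class_trace_is_an_error(self):
        brain = brain_of([chain([(0, 0), (0, 300)])])
        with pytest.raises(ValueError, match="lLNv"):
            sholl_count(brain, LLNV_OT)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_dense_sampling_oracle_on_random_bundles(self, seed):
        params = dataclasses.replace(
            DEFASCICULATED_ADULT if seed % 2 else CONTROL_ADULT, seed=seed
        )
        brain = generate_brain(params)
        for preset in (ADULT_VENTRAL, ADULT_DORSAL, LLNV_OT):
            center = (brain.landmarks.poi if preset.center == "POI"
                      else detect_branching_point(brain))
            assert sholl_count(brain, preset) == sholl_by_dense_sampling(
                brain, preset, center
            )

    def test_tangency_robust_to_tiny_vertex_perturbation(self, rng):
        brain = generate_brain(dataclasses.replace(CONTROL_ADULT, seed=4))
        baseline = sholl_count(brain, ADULT_VENTRAL)
        for trace in brain.traces:
            bumped = []
            for n in trace.nodes:
                bumped.append(dataclasses.replace(
                    n,
                    x=n.x + float(rng.choice([-1e-6, 1e-6])),
                    y=n.y + float(rng.choice([-1e-6, 1e-6])),
                ))
            trace.nodes = bumped
            trace.__post_init__()
        assert sholl_count(brain, ADULT_VENTRAL) == baseline

    def test_scaling_leaves_counts_unchanged(self):
        brain = generate_brain(dataclasses.replace(CONTROL_ADULT, seed=8))
        k = 3.7
        scaled_traces = []
        for trace in brain.traces:
            nodes = [dataclasses.replace(n, x=n.x * k, y=n.y * k)
                     for n in trace.nodes]
            scaled_traces.append(NeuronTrace(nodes, trace.neuron_class,
                                             trace.neuron_id))
        lm = brain.landmarks
        scaled = BrainRecord(
            "s", "g", "adult", "right", scaled_traces,
            Landmarks(poi=(lm.poi[0] * k, lm.poi[1] * k),
                      bp=(lm.bp[0] * k, lm.bp[1] * k),
                      midline_x=lm.midline_x * k,
                      optic_tract=[(x * k, y * k) for x, y in lm.optic_tract]),
        )
        for preset in (ADULT_VENTRAL, ADULT_DORSAL, LLNV_OT):
            scaled_preset = dataclasses.replace(preset, spacing=preset.spacing * k)
            assert sholl_count(scaled, scaled_preset) == sholl_count(brain, preset)
        assert total_projection_length(scaled) == pytest.approx(
            k * total_projection_length(brain)
        )


class TestTotalLength:
    def test_straight_path_without_midline_crossing(self):
        brain = brain_of([chain([(0.0, 0.0), (0.0, 150.0)])], midline_x=200.0)
        assert total_projection_length(brain) == pytest.approx(150.0)

    def test_path_clipped_at_midline_crossing(self):
        # 80 um run to the midline at x=80, then 70 um beyond it
        brain = brain_of([chain([(0.0, 0.0), (80.0, 0.0), (150.0, 0.0)])],
                         midline_x=80.0)
        assert total_projection_length(brain) == pytest.approx(80.0)

    def test_interpolated_crossing_inside_an_edge(self):
        brain = brain_of([chain([(0.0, 0.0), (100.0, 0.0)])], midline_x=33.25)
        assert total_projection_length(brain) == pytest.approx(33.25)

    def test_longest_terminal_wins(self):
        # fork: one short arm, one long arm
        nodes = [
            TraceNode(1, 1, 0.0, 0.0, 0.0, 0.5, None),
            TraceNode(2, 2, 0.0, 50.0, 0.0, 0.5, 1),
            TraceNode(3, 2, 10.0, 60.0, 0.0, 0.5, 2),
            TraceNode(4, 2, 0.0, 150.0, 0.0, 0.5, 2),
        ]
        brain = brain_of([NeuronTrace(nodes)], midline_x=500.0)
        assert total_projection_length(brain) == pytest.approx(150.0)


class TestOpticTractContact:
    def test_control_bundle_has_no_contact(self):
        brain = generate_brain(dataclasses.replace(CONTROL_ADULT, seed=13))
        assert optic_tract_contact(brain) is False

    def test_constructed_descending_branch_contacts(self):
        # sLNv: up the y axis, fork at (0,100), one arm descending onto the
        # lLNv path at y=0
        nodes = [TraceNode(1, 1, 0.0, 0.0, 0.0, 0.5, None)]
        for i, y in enumerate(range(20, 101, 20), start=2):
            nodes.append(TraceNode(i, 2, 0.0, float(y), 0.0, 0.5, i - 1))
        fork = nodes[-1].node_id
        nodes.append(TraceNode(20, 2, 15.0, 130.0, 0.0, 0.5, fork))
        nodes.append(TraceNode(21, 2, 30.0, 160.0, 0.0, 0.5, 20))
        nodes.append(TraceNode(30, 2, -20.0, 80.0, 0.0, 0.5, fork))
        nodes.append(TraceNode(31, 2, -40.0, 0.5, 0.0, 0.5, 30))
        slnv = NeuronTrace(nodes)
        llnv = chain([(-80.0, 0.0), (80.0, 0.0)], start_id=100, cls="lLNv")
        brain = brain_of([slnv, llnv], bp=(0.0, 100.0))
        assert optic_tract_contact(brain, tolerance=2.0) is True

    def test_nothing_to_test_against_is_an_error(self):
        brain = brain_of([chain([(0, 0), (0, 50), (10, 60), (-10, 60)])],
                         bp=(0.0, 50.0))
        with pytest.raises(ValueError, match="contact"):
            optic_tract_contact(brain)


class TestMeasureTables:
    def test_adult_row_fully_populated(self):
        brain = generate_brain(dataclasses.replace(CONTROL_ADULT, seed=1))
        row = measure_brain(brain)
        assert row.total_length > 0
        assert row.length_to_bp > 0
        assert row.ventral_sholl >= 0 and row.dorsal_sholl >= 0
        assert row.llnv_sholl >= 0
        assert row.ot_contact is False

    def test_l3_row_omits_adult_only_measures(self):
        from clockmorph.simulate_morphology import CONTROL_L3

        brain = generate_brain(dataclasses.replace(CONTROL_L3, seed=1))
        row = measure_brain(brain)
        assert row.llnv_sholl is None
        assert row.ot_contact is None
        assert row.dorsal_sholl is not None

    def test_cohort_table_sorted_by_genotype_then_brain(self):
        cohort = generate_cohort(
            {"z_geno": CONTROL_ADULT, "a_geno": DEFASCICULATED_ADULT},
            n_brains=3, seed=0,
        )
        table = measure_cohort(cohort)
        assert len(table) == 6
        assert list(table["genotype"]) == sorted(table["genotype"])
        for _, sub in table.groupby("genotype"):
            assert list(sub["brain_id"]) == sorted(sub["brain_id"])

    def test_measure_failure_becomes_missing_value_not_abort(self):
        # unbranched brain: BP detection fails, lengths still measured
        brain = brain_of([chain([(0.0, -10.0), (0.0, 0.0), (0.0, 120.0)])],
                         midline_x=500.0)
        row = measure_brain(brain)
        assert row.length_to_bp is None
        assert row.total_length == pytest.approx(120.0)
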