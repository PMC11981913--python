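"""Graph-filter behaviour, audit completeness, PR arithmetic."""

import copy

import numpy as np
import pytest

from neurodecomp.proofreading import (DEFAULT_RULES, apply_filters,
                                      evaluate_synapse_pr, rule_axon_degree,
                                      rule_double_back, rule_width_jump)
from neurodecomp.types import ROOT, SynapseRecord

from _helpers import toy_graph


def test_vacuous_angle_threshold_never_flags(neuron_run):
    assert rule_double_back(neuron_run.graph, compartment=None,
                            angle_threshold_deg=181.0) == []


def test_clean_neuron_barely_edited(neuron_run):
    g = copy.deepcopy(neuron_run.graph)
    edited, edits = apply_filters(g, DEFAULT_RULES)
    removed = sum(e.removed_skeletal_length for e in edits)
    assert removed <= 0.05 * neuron_run.graph.total_skeletal_length


def test_infinite_width_threshold_never_flags(neuron_run):
    assert rule_width_jump(neuron_run.graph,
                           jump_threshold_nm=float("inf")) == []


def test_high_degree_axon_point_flags_children():
    specs = [([[0, 0, 0], [20_000, 0, 0]], ROOT, 300)]
    for k in range(5):
        ang = (k - 2) * 0.4
        end = [20_000 + 15_000 * np.cos(ang), 15_000 * np.sin(ang), 0]
        specs.append(([[20_000, 0, 0], end], 0, 250))
    g = toy_graph(specs)
    for b in g.branches.values():
        b.compartment = "axon"
    flagged = rule_axon_degree(g, max_children=3)
    assert sorted(flagged) == [1, 2, 3, 4, 5]


def test_binary_axon_arbor_not_flagged():
    specs = [([[0, 0, 0], [20_000, 0, 0]], ROOT, 300),
             ([[20_000, 0, 0], [35_000, 10_000, 0]], 0, 250),
             ([[20_000, 0, 0], [35_000, -10_000, 0]], 0, 250)]
    g = toy_graph(specs)
    for b in g.branches.values():
        b.compartment = "axon"
    assert rule_axon_degree(g, max_children=3) == []


def test_spiny_side_branch_not_flagged_as_axon_like(neuron_run):
    from neurodecomp.proofreading import rule_axon_on_dendrite
    g = neuron_run.graph
    flagged = rule_axon_on_dendrite(g)
    # the clean neuron's dendritic side-branches are spiny: none axon-like
    for c in flagged:
        assert g.branches[c].compartment in ("axon", "AIS")
    assert len(flagged) == 0


def test_empty_rule_list_is_identity(neuron_run):
    g = copy.deepcopy(neuron_run.graph)
    edited, edits = apply_filters(g, [])
    assert edits == []
    assert set(edited.branches) == set(neuron_run.graph.branches)


def test_unknown_rule_rejected_before_edits(neuron_run):
    g = copy.deepcopy(neuron_run.graph)
    with pytest.raises(ValueError, match="unknown rule"):
        apply_filters(g, [{"rule": "bogus", "params": {}}])
    assert set(g.branches) == set(neuron_run.graph.branches)


def test_closure_removed_in_one_edit():
    # a stem with a subtree of 7 nodes below the flagged child
    specs = [([[0, 0, 0], [20_000, 0, 0]], ROOT, 1000)]
    parent = 0
    # chain of 7 nodes, the first of which doubles back toward the soma
    specs.append(([[20_000, 0, 0], [8_000, -1500, 0]], 0, 1000))
    prev = 1
    base = [8_000, -1500, 0]
    for k in range(6):
        end = [base[0] - 4000, base[1] - 2000, 0]
        specs.append(([base, end], prev, 900))
        prev = len(specs) - 1
        base = end
    g = toy_graph(specs)
    edited, edits = apply_filters(
        g, [{"rule": "double_back",
             "params": {"compartment": None, "min_length_nm": 1000.0}}])
    assert len(edits) == 1
    assert len(edits[0].removed_nodes) == 7
    assert set(edited.branches) == {0}


def test_orphan_axon_scene_edit_hits_weld(orphan_scene_run):
    run = orphan_scene_run
    g = copy.deepcopy(run.graph)
    edited, edits = apply_filters(g, DEFAULT_RULES)
    assert len(edits) >= 1
    weld = run.scene.error_truth[0].location
    dmin = min(np.linalg.norm(e.cut_location - weld) for e in edits)
    assert dmin < 10_000.0
    # audit completeness: removed synapse ids == synapses flipped invalid
    flipped = {sid for sid, s in edited.synapses.items()
               if not s.valid and run.graph.synapses[sid].valid}
    logged = {sid for e in edits for sid in e.removed_synapse_ids}
    assert flipped == logged


def test_monotone_fp_and_recall_over_rule_prefixes(orphan_scene_run):
    run = orphan_scene_run
    truth = {s.syn_id for s in run.scene.synapses
             if s.valid and s.syn_id in run.graph.synapses}
    prev_fp, prev_rec = None, None
    for k in range(len(DEFAULT_RULES) + 1):
        g = copy.deepcopy(run.graph)
        edited, _ = apply_filters(g, DEFAULT_RULES[:k])
        pred = {sid for sid, s in edited.synapses.items() if s.valid}
        pr = evaluate_synapse_pr(pred, truth)
        if prev_fp is not None:
            assert pr.fp <= prev_fp
            assert pr.recall <= prev_rec + 1e-12
        prev_fp, prev_rec = pr.fp, pr.recall


def test_idempotent_rule_stack(orphan_scene_run):
    g = copy.deepcopy(orphan_scene_run.graph)
    edited, edits1 = apply_filters(g, DEFAULT_RULES)
    edited2, edits2 = apply_filters(edited, DEFAULT_RULES)
    assert edits2 == []
    assert set(edited2.branches) == set(edited.branches)


# ---------------------------------------------------------------------------
# precision/recall arithmetic
# ---------------------------------------------------------------------------

def test_perfect_prediction():
    pr = evaluate_synapse_pr({1, 2, 3}, {1, 2, 3})
    assert pr.precision == 1.0 and pr.recall == 1.0


def test_empty_prediction_has_undefined_precision():
    pr = evaluate_synapse_pr(set(), {1, 2})
    assert pr.precision is None
    assert pr.recall == 0.0
    assert pr.fn == 2


def test_confusion_count_arithmetic():
    """Retaining 2,216 true and 324 false synapses gives precision 0.87;
    a raw set with 3,636 true of 28,390 total gives 0.13."""
    after_true = set(range(2216))
    after_false = set(range(100_000, 100_324))
    truth = set(range(3636))
    pr = evaluate_synapse_pr(after_true | after_false, truth)
    assert round(pr.precision, 2) == 0.87
    all_before = set(range(3636)) | set(range(100_000, 100_000 + 28_390 - 3_636))
    pr0 = evaluate_synapse_pr(all_before, truth)
    assert round(pr0.precision, 2) == 0.13


def test_stratified_pr():
    strata = {"compartment": {1: "axon", 2: "axon", 3: "dendrite"}}
    pr = evaluate_synapse_pr({1, 3}, {1, 2, 3}, strata=strata)
    axon = pr.strata[("compartment", "axon")]
    assert axon.tp == 1 and axon.fn == 1
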