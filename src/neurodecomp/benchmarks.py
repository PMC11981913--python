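"""Reproducible benchmark computations used by the acceptance harness.

Three self-contained computations:

* the synapse precision/recall worked example, evaluated from published
  excitatory-axon validation counts for a cortical EM volume (24,430 false
  and 1,420 true synapses removed; 2,216 true and 324 false retained);
* the two-proximity conversion-rate schematic (one axon passing a dendrite
  twice, one pass synapsed -> 50%);
* the spine-detection benchmark on seeded synthetic spiny neurons with
  ground-truth spine labels, restricted to spines with skeletal length
  above the 700 nm filter.
"""

from __future__ import annotations

import numpy as np

from . import preprocess, spines
from .decomposition import decompose
from .proofreading import evaluate_synapse_pr
from .proximity import compute_proximities, conversion_rate, link_synapses
from .synthetic import (KIND_SPINE, MorphologyParams, generate_neuron,
                        mesh_from_neuron)
from .types import ROOT, Branch, DecompGraph, SomaDetection, SynapseRecord

#: published excitatory-axon validation confusion counts
CONFUSION = dict(false_removed=24_430, true_removed=1_420,
                 true_retained=2_216, false_retained=324)


def synapse_pr_worked_example(counts: dict | None = None) -> dict:
    """Precision before/after proofreading and the recall reduction.

    The confusion counts are the worked-example inputs; the quantities are
    produced by :func:`evaluate_synapse_pr` on synthetic id sets realizing
    those counts.
    """
    c = counts or CONFUSION
    n_true = c["true_retained"] + c["true_removed"]
    n_false = c["false_retained"] + c["false_removed"]
    truth = set(range(n_true))
    false_ids = set(range(1_000_000, 1_000_000 + n_false))
    retained = (set(range(c["true_retained"]))
                | set(range(1_000_000, 1_000_000 + c["false_retained"])))
    before = evaluate_synapse_pr(truth | false_ids, truth)
    after = evaluate_synapse_pr(retained, truth)
    reduction = (before.recall - after.recall) / before.recall
    return {"precision_after": after.precision,
            "precision_before": before.precision,
            "recall_after": after.recall,
            "recall_reduction_percent": 100.0 * reduction,
            "n_synapses": n_true + n_false}


def _line_graph(points_list, compartment, soma_center) -> DecompGraph:
    import networkx as nx
    g = nx.DiGraph()
    g.add_node(ROOT)
    branches = {}
    for i, pts in enumerate(points_list):
        b = Branch(branch_id=i, points=np.asarray(pts, dtype=float),
                   width_profile=np.full(len(pts), 500.0),
                   compartment=compartment, parent=ROOT if i == 0 else i - 1)
        branches[i] = b
        g.add_edge(b.parent, i)
    soma = SomaDetection(centroid=np.asarray(soma_center, dtype=float),
                         radius=3000.0, face_ids=np.zeros(0, dtype=int),
                         surface_area=1.0, volume=1.0)
    return DecompGraph(soma=soma, branches=branches, graph=g)


def conversion_worked_example(radius_nm: float = 5000.0) -> dict:
    """One axon approaches a dendrite twice; one pass has a synapse.

    Returns the conversion rate as a percentage (expected: 50%).
    """
    axon = _line_graph([[[0, 10_000, 0], [0, 0, 0]],
                        [[0, 0, 0], [40_000, 0, 0]],
                        [[40_000, 0, 0], [40_000, 10_000, 0]]],
                       "axon", [0, 15_000, 0])
    # the dendrite crosses both arms ~1 um off-plane but stays > radius
    # away from the connecting run, giving exactly two separated events
    dendrite = _line_graph([[[-5000, 5000, 1000], [45_000, 5000, 1000]]],
                           "basal", [-10_000, 5000, 1000])
    events = compute_proximities(axon, dendrite, 1, 2, radius=radius_nm)
    syn = [SynapseRecord(syn_id=0, pre_id=1, post_id=2,
                         position=np.array([0.0, 5000.0, 500.0]), size=1000.0)]
    link_synapses(events, syn)
    rate = conversion_rate(events)
    return {"n_proximities": len(events),
            "n_converted": sum(1 for e in events if e.n_synapses),
            "conversion_rate_percent": 100.0 * rate if rate is not None else None}


def spine_detection_benchmark(n_neurons: int = 20, base_seed: int = 1,
                              resolution: int = 10,
                              min_skeletal_length: float = 700.0,
                              morphology: dict | None = None) -> dict:
    """Pooled spine precision/recall over seeded spiny neurons.

    Each neuron is meshed, skeletonized from scratch, decomposed, and
    scanned for spines; detections (after the length filter) match a
    ground-truth spine when they share >50% of their faces with it.
    """
    morphology = morphology or dict(n_dendrite_stems=3, branch_depth=1)
    tp = fp = fn = 0
    for k in range(n_neurons):
        seed = int(base_seed) + k
        neuron = generate_neuron(MorphologyParams(**morphology), seed)
        mesh, labels = mesh_from_neuron(neuron, resolution=resolution)
        somas = preprocess.detect_somas(mesh)
        sk = preprocess.skeletonize(mesh, somas)
        corr = preprocess.mesh_correspondence(mesh, sk)
        graph = decompose(sk, corr, somas, neuron.synapses)
        detected = spines.detect_spines_graph(mesh, graph, include_axon=True)
        detected = spines.filter_spines(detected, min_skeletal_length)
        truth = {s.spine_id: set(labels.faces_of(KIND_SPINE, s.spine_id).tolist())
                 for s in neuron.spines}
        long_truth = {sid for sid in truth
                      if neuron.spines[sid].truth_length > min_skeletal_length}
        matched: set[int] = set()
        for d in detected:
            dset = set(d.face_ids.tolist())
            best, best_ov = None, 0
            for sid, tset in truth.items():
                ov = len(dset & tset)
                if ov > best_ov:
                    best_ov, best = ov, sid
            if (best is not None and best_ov > 0.5 * len(dset)
                    and best in long_truth and best not in matched):
                tp += 1
                matched.add(best)
            else:
                fp += 1
        fn += len(long_truth - matched)
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
            "n_neurons": n_neurons}
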