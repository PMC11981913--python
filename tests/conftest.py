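"""Shared fixtures: desk-scale synthetic neurons run through the pipeline.

The benchmark morphology (3 dendritic stems, one branch level, apical +
axon, spine density 1/µm) keeps meshes around 10^5 faces so the whole
suite runs on one CPU in minutes while still exercising every stage.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from neurodecomp import classification, decomposition, preprocess, spines
from neurodecomp.synthetic import (MergeScene, MorphologyParams,
                                   generate_neuron, inject_merge_error,
                                   make_scene, mesh_from_neuron, preset_scene,
                                   weld_pair)

BENCH = dict(n_dendrite_stems=3, branch_depth=1)


def run_stages(mesh, synapses, spines_on=True, compartments=True):
    """mesh + synapse records -> decomposed, featured, labelled graph."""
    somas = preprocess.detect_somas(mesh)
    sk = preprocess.skeletonize(mesh, somas)
    corr = preprocess.mesh_correspondence(mesh, sk)
    graph = decomposition.decompose(sk, corr, somas, synapses)
    found = []
    if spines_on:
        found = spines.detect_spines_graph(mesh, graph, include_axon=True)
    axon_stem = classification.identify_axon(graph)
    if compartments:
        classification.label_compartments(graph, "excitatory",
                                          axon_stem=axon_stem)
    return SimpleNamespace(somas=somas, skeleton=sk, corr=corr, graph=graph,
                           spines=found, axon_stem=axon_stem)


@pytest.fixture(scope="session")
def bench_params():
    return dict(BENCH)


@pytest.fixture(scope="session")
def neuron_and_mesh():
    """One clean spiny neuron with its labelled mesh."""
    neuron = generate_neuron(MorphologyParams(**BENCH), 2)
    mesh, labels = mesh_from_neuron(neuron, resolution=10)
    return SimpleNamespace(neuron=neuron, mesh=mesh, labels=labels)


@pytest.fixture(scope="session")
def neuron_run(neuron_and_mesh):
    """The clean neuron pushed through every pipeline stage."""
    nm = neuron_and_mesh
    stages = run_stages(nm.mesh, [s.copy() for s in nm.neuron.synapses])
    stages.neuron = nm.neuron
    stages.mesh = nm.mesh
    stages.labels = nm.labels
    return stages


@pytest.fixture(scope="session")
def orphan_scene_run():
    """A neuron with an orphan axon welded onto a dendrite, fully staged."""
    scene = preset_scene("orphan-axon", 3, resolution=10, **BENCH)
    stages = run_stages(scene.mesh, scene.input_synapses())
    stages.scene = scene
    return stages


def build_pair_scene(seed: int) -> MergeScene:
    a = generate_neuron(MorphologyParams(neuron_id=0, **BENCH), seed)
    b = generate_neuron(MorphologyParams(neuron_id=1, **BENCH), seed + 100)
    b = b.translate(np.array([120_000.0, 30_000.0, 0.0]))
    scene = make_scene([a, b], resolution=10)
    return weld_pair(scene, seed)


@pytest.fixture(scope="session")
def merged_pair_scene():
    return build_pair_scene(5)


@pytest.fixture(scope="session")
def merged_pair_run(merged_pair_scene):
    scene = merged_pair_scene
    somas = preprocess.detect_somas(scene.mesh)
    sk = preprocess.skeletonize(scene.mesh, somas)
    corr = preprocess.mesh_correspondence(scene.mesh, sk)
    graph = decomposition.decompose(sk, corr, somas, scene.input_synapses())
    graphs, edits = decomposition.split_multi_soma(graph)
    return SimpleNamespace(scene=scene, somas=somas, skeleton=sk,
                           merged_graph=graph, graphs=graphs, edits=edits)
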