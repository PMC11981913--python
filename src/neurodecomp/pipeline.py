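"""End-to-end orchestration: mesh + synapses -> proofread annotated graphs.

Stages run in a fixed order (preprocess -> decompose -> features -> spines
-> classify -> proofread -> proximity -> motifs); every stage's outputs are
written to the run directory, a structured run log records counts per
stage, and reruns with the same config and inputs are deterministic.
All internal lengths are nm; only the SWC writer emits µm.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import trimesh

from . import classification, decomposition, features, motifs, preprocess
from . import proofreading, proximity as proximity_mod, spines as spines_mod
from . import synthetic
from .types import ROOT, DecompGraph, SynapseRecord


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults; unknown keys rejected."""

    seed: int = 0
    units: str = "nm"
    # inputs: either a mesh+synapse table, or a generator preset
    input_mesh: Optional[str] = None
    input_synapses: Optional[str] = None
    synth_preset: Optional[str] = None
    synth_params: dict = field(default_factory=dict)
    out_dir: str = "run_out"
    # stage toggles
    run_spines: bool = True
    run_classify: bool = True
    run_proofread: bool = True
    run_proximity: bool = True
    run_motifs: bool = True
    # preprocess
    step_nm: float = preprocess.DEFAULT_STEP_NM
    min_soma_radius_nm: float = preprocess.DEFAULT_MIN_SOMA_RADIUS_NM
    compactness_threshold: float = preprocess.DEFAULT_COMPACTNESS
    bridge_tol_nm: float = preprocess.DEFAULT_BRIDGE_TOL_NM
    prune_length_nm: float = preprocess.DEFAULT_PRUNE_NM
    # spines
    shaft_factor: float = spines_mod.DEFAULT_SHAFT_FACTOR
    min_spine_faces: int = spines_mod.DEFAULT_MIN_FACES
    neck_ratio: float = spines_mod.DEFAULT_NECK_RATIO
    spine_filter_nm: float = spines_mod.SPINE_LENGTH_FILTER_NM
    # classification
    ais_window_nm: float = classification.DEFAULT_AIS_WINDOW_NM
    depth_axis: tuple = (0.0, 1.0, 0.0)
    # proofreading thresholds (per-rule params live in the rule stack)
    rule_stack: list = field(default_factory=lambda: [dict(r) for r in
                                                      proofreading.DEFAULT_RULES])
    # proximity
    proximity_radius_nm: float = proximity_mod.DEFAULT_RADIUS_NM
    proximity_min_gap_nm: float = proximity_mod.DEFAULT_MIN_GAP_NM
    link_radius_nm: float = proximity_mod.DEFAULT_RADIUS_NM
    # motifs
    motif_min_synapses: int = 1
    null_samples: int = motifs.DEFAULT_NULL_SAMPLES

    @staticmethod
    def from_toml(path_or_text) -> "PipelineConfig":
        text = str(path_or_text)
        if "\n" not in text and "=" not in text:
            text = Path(text).read_text()
        doc = tomllib.loads(text)
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "depth_axis" in doc:
            doc["depth_axis"] = tuple(doc["depth_axis"])
        if "rule_stack" in doc:
            doc["rule_stack"] = [
                {"rule": r["rule"], "params": dict(r.get("params", {}))}
                for r in doc["rule_stack"]]
        return PipelineConfig(**doc)

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v}")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
            elif f.name == "synth_params":
                if v:
                    ps = ", ".join(f"{k} = {json.dumps(val)}" for k, val in v.items())
                    lines.append(f"synth_params = {{ {ps} }}")
            elif f.name == "rule_stack":
                parts = []
                for r in v:
                    ps = ", ".join(f'{k} = {json.dumps(val)}'
                                   for k, val in r.get("params", {}).items())
                    parts.append(f'{{ rule = "{r["rule"]}"'
                                 + (f", params = {{ {ps} }}" if ps else "") + " }")
                lines.append(f"rule_stack = [{', '.join(parts)}]")
        return "\n".join(lines) + "\n"


@dataclass
class NeuronResult:
    neuron_index: int
    graph: DecompGraph
    cell_class: str
    axon_stem: Optional[int]
    edits: list
    pre_edit_valid: set[int]


@dataclass
class PipelineResult:
    config: PipelineConfig
    results: list[NeuronResult]
    scene: Optional[synthetic.MergeScene]
    fragments: int
    glia: int
    proximities: list
    log: list[dict]

    def all_valid_synapse_ids(self) -> set[int]:
        out = set()
        for r in self.results:
            out |= {sid for sid, s in r.graph.synapses.items() if s.valid}
        return out


def _default_ei_model(seed: int = 12345) -> classification.EIModel:
    """E/I logistic model fit on generator-typical feature populations."""
    rng = np.random.default_rng([seed, 31])
    n = 300
    exc = np.column_stack([rng.normal(1.2, 0.3, n), rng.normal(0.15, 0.06, n)])
    inh = np.column_stack([rng.normal(0.05, 0.03, n), rng.normal(0.8, 0.2, n)])
    X = np.clip(np.vstack([exc, inh]), 0, None)
    y = np.array(["excitatory"] * n + ["inhibitory"] * n)
    return classification.fit_ei(X, y)


def read_synapse_table(path) -> list[SynapseRecord]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(SynapseRecord(
            syn_id=int(r.synapse_id), pre_id=int(r.pre_id), post_id=int(r.post_id),
            position=np.array([r.x_nm, r.y_nm, r.z_nm]), size=float(r.size_voxels),
            direction=(r.direction or None) if isinstance(r.direction, str) else None,
            valid=True))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; artifacts go to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name, **counts):
        log.append({"stage": name, **counts})

    scene = None
    if config.synth_preset:
        scene = synthetic.preset_scene(config.synth_preset, config.seed,
                                       **config.synth_params)
        synthetic.write_scene(scene, out / "input")
        mesh = scene.mesh
        synapses = scene.input_synapses()
    elif config.input_mesh:
        mesh = trimesh.load(config.input_mesh, process=False, force="mesh")
        synapses = (read_synapse_table(config.input_synapses)
                    if config.input_synapses else [])
    else:
        raise ValueError("config needs synth_preset or input_mesh")
    stage("load", faces=len(mesh.faces), synapses=len(synapses))

    mesh = preprocess.clean_mesh(mesh)
    components = preprocess.split_components(mesh, config.bridge_tol_nm)
    stage("preprocess", components=len(components))

    results: list[NeuronResult] = []
    fragments = 0
    glia = 0
    ei_model = _default_ei_model() if config.run_classify else None
    neuron_idx = 0
    for submesh, fids in components:
        somas = preprocess.detect_somas(
            submesh, config.min_soma_radius_nm, config.compactness_threshold)
        kind = preprocess.flag_non_neuronal(submesh, somas)
        if kind == "fragment":
            fragments += 1
            continue
        if kind == "glia_like":
            glia += 1
            continue
        sk = preprocess.skeletonize(submesh, somas, step=config.step_nm,
                                    bridge_tol_nm=config.bridge_tol_nm,
                                    prune_length_nm=config.prune_length_nm)
        corr = preprocess.mesh_correspondence(submesh, sk)
        graph = decomposition.decompose(sk, corr, somas, synapses)
        graphs, split_edits = decomposition.split_multi_soma(graph)
        stage("decompose", component_faces=len(fids), somas=len(somas),
              graphs=len(graphs), split_edits=len(split_edits))
        for g in graphs:
            gdir = out / f"neuron_{neuron_idx}"
            gdir.mkdir(exist_ok=True)
            if config.run_spines:
                spines_mod.detect_spines_graph(
                    submesh, g, shaft_factor=config.shaft_factor,
                    min_faces=config.min_spine_faces, include_axon=True)
            axon_stem = classification.identify_axon(g)
            cls = "excitatory"
            if config.run_classify and ei_model is not None:
                cls = classification.classify_ei(ei_model, g)
            classification.label_compartments(
                g, cls, depth_axis=config.depth_axis,
                ais_window_nm=config.ais_window_nm, axon_stem=axon_stem)
            pre_edit_valid = {sid for sid, s in g.synapses.items() if s.valid}
            edits = list(split_edits)
            if config.run_proofread:
                g, rule_edits = proofreading.apply_filters(g, config.rule_stack)
                edits += rule_edits
            features.write_feature_tables(g, gdir)
            decomposition.export_swc(g, gdir / "neuron.swc")
            (gdir / "graph.json").write_text(decomposition.graph_to_json(g))
            if config.run_spines and getattr(g, "spines", None):
                sp = spines_mod.spine_table(list(g.spines.values()),
                                            list(g.synapses.values()), submesh)
                sp.to_csv(gdir / "spines.csv", index=False)
            proofreading.write_edit_log(edits, gdir / "edits.jsonl")
            synthetic.synapse_table(
                list(g.synapses.values())).to_csv(gdir / "synapses.csv", index=False)
            results.append(NeuronResult(neuron_index=neuron_idx, graph=g,
                                        cell_class=cls, axon_stem=axon_stem,
                                        edits=edits,
                                        pre_edit_valid=pre_edit_valid))
            stage("neuron", index=neuron_idx, cell_class=cls,
                  branches=len(g.branches), edits=len(edits))
            neuron_idx += 1

    proximities = []
    if config.run_proximity and len(results) >= 2:
        for a in results:
            for b in results:
                if a is b:
                    continue
                recs = proximity_mod.compute_proximities(
                    a.graph, b.graph,
                    pre_id=a.neuron_index, post_id=b.neuron_index,
                    radius=config.proximity_radius_nm,
                    min_gap=config.proximity_min_gap_nm)
                proximities.extend(recs)
        proximity_mod.proximity_table(proximities).to_csv(
            out / "proximities.csv", index=False)
        stage("proximity", events=len(proximities))

    if config.run_motifs and results:
        frames = [synthetic.synapse_table(list(r.graph.synapses.values()))
                  for r in results]
        table = pd.concat(frames, ignore_index=True)
        g = motifs.build_graph(table, min_synapses=config.motif_min_synapses)
        census = motifs.triad_census(g)
        motifs.census_table(census).to_csv(out / "motif_census.csv", index=False)
        stage("motifs", nodes=g.number_of_nodes(), edges=g.number_of_edges())

    with open(out / "run_log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
    (out / "config.toml").write_text(PipelineConfig.to_toml(config))
    return PipelineResult(config=config, results=results, scene=scene,
                          fragments=fragments, glia=glia,
                          proximities=proximities, log=log)


# ---------------------------------------------------------------------------
# evaluation against generator ground truth
# ---------------------------------------------------------------------------

def evaluate_run(result: PipelineResult,
                 scene: Optional[synthetic.MergeScene] = None,
                 spine_filter_nm: float = spines_mod.SPINE_LENGTH_FILTER_NM
                 ) -> dict:
    """Score a pipeline run against the generator's ground truth.

    Reports synapse precision/recall (overall and per compartment), spine
    precision/recall above the skeletal-length filter, soma detection
    counts, merge-error hit rate and clean-skeleton over-removal.
    """
    scene = scene or result.scene
    if scene is None:
        raise ValueError("no ground-truth scene available")
    report: dict = {}
    truth_valid = scene.truth_valid_ids()
    assigned = set()
    predicted = set()
    pre_edit = set()
    for r in result.results:
        assigned |= set(r.graph.synapses)
        predicted |= {sid for sid, s in r.graph.synapses.items() if s.valid}
        pre_edit |= r.pre_edit_valid
    pr_after = proofreading.evaluate_synapse_pr(predicted, truth_valid & assigned)
    pr_before = proofreading.evaluate_synapse_pr(pre_edit, truth_valid & assigned)
    report["synapse_precision_after"] = pr_after.precision
    report["synapse_recall_after"] = pr_after.recall
    report["synapse_precision_before"] = pr_before.precision
    report["synapse_recall_before"] = pr_before.recall

    # spine PR above the length filter (only when spines were run)
    spines_all = []
    for r in result.results:
        spines_all.extend(getattr(r.graph, "spines", {}).values())
    det = spines_mod.filter_spines(spines_all, spine_filter_nm)
    truth_spines = {}
    for idx, comp in enumerate(scene.components):
        for s in comp.spines:
            # spine ids repeat across components: restrict by component
            faces = scene.labels.faces_of(synthetic.KIND_SPINE, s.spine_id,
                                          component=idx)
            truth_spines[(comp.neuron_id, s.spine_id)] = (
                set(faces.tolist()), s.truth_length)
    long_truth = {k for k, (fs, L) in truth_spines.items() if L > spine_filter_nm}
    tp = 0
    fp = 0
    matched = set()
    for d in det:
        dset = set(d.face_ids.tolist())
        best = None
        best_ov = 0
        for k, (fs, L) in truth_spines.items():
            ov = len(dset & fs)
            if ov > best_ov:
                best_ov = ov
                best = k
        if (best is not None and best_ov > 0.5 * len(dset)
                and best in long_truth and best not in matched):
            tp += 1
            matched.add(best)
        else:
            fp += 1
    fn = len(long_truth - matched)
    report["spine_tp"] = tp
    report["spine_fp"] = fp
    report["spine_fn"] = fn
    report["spine_precision"] = tp / (tp + fp) if (tp + fp) else None
    report["spine_recall"] = tp / (tp + fn) if (tp + fn) else None

    # soma detection counts
    report["n_neurons_detected"] = len(result.results)
    report["n_neurons_truth"] = len([c for c in scene.components
                                     if isinstance(c, synthetic.GroundTruthNeuron)])

    # merge-error hits: some edit cut within 10 um of the true weld
    hits = 0
    for e_truth in scene.error_truth:
        d = min((float(np.linalg.norm(np.asarray(ed.cut_location) - e_truth.location))
                 for r in result.results for ed in r.edits), default=np.inf)
        hits += d <= 10_000.0
    report["n_errors_truth"] = len(scene.error_truth)
    report["n_errors_hit"] = hits

    # clean-skeleton over-removal: removed true synapses as a proxy-free
    # length measure is not available; use removed skeletal length minus
    # matched foreign subtrees via the synapse labels
    removed_len = sum(ed.removed_skeletal_length
                      for r in result.results for ed in r.edits)
    clean_len = sum(c.total_skeletal_length() for c in scene.components
                    if isinstance(c, synthetic.GroundTruthNeuron))
    false_removed = len(truth_valid & assigned - predicted)
    report["removed_skeletal_length_nm"] = removed_len
    report["true_skeletal_length_nm"] = clean_len
    report["true_synapses_removed"] = false_removed
    return report
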