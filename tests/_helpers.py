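"""Small hand-built decomposition graphs for unit tests."""

import networkx as nx
import numpy as np

from neurodecomp.types import ROOT, Branch, DecompGraph, SomaDetection


def toy_graph(branch_specs, synapses=(), soma_center=(0, 0, 0),
              soma_radius=2000.0):
    """branch_specs: list of (points, parent, width)."""
    g = nx.DiGraph()
    g.add_node(ROOT)
    branches = {}
    for i, (pts, parent, width) in enumerate(branch_specs):
        pts = np.asarray(pts, dtype=float)
        b = Branch(branch_id=i, points=pts,
                   width_profile=np.full(len(pts), float(width)),
                   parent=parent)
        branches[i] = b
        g.add_edge(parent, i)
    soma = SomaDetection(centroid=np.array(soma_center, dtype=float),
                         radius=soma_radius, face_ids=np.zeros(0, dtype=int),
                         surface_area=1.0, volume=1.0)
    dg = DecompGraph(soma=soma, branches=branches, graph=g)
    for s in synapses:
        dg.synapses[s.syn_id] = s
        if s.branch_id is not None:
            dg.branches[s.branch_id].synapse_ids.append(s.syn_id)
    return dg
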