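import math

import numpy as np
import pytest

from sproutgraph import phantom as ph
from sproutgraph.segmentation import Circle
from sproutgraph.skeleton_graph import Node, Segment, SkeletonGraph, path_length_px


def acceptance_phantom_spec(seed: int = 0) -> ph.PhantomSpec:
    """Well-separated, anastomosis-free phantom used for round-trip checks."""
    return ph.PhantomSpec(
        n_primary=5,
        primary_placement="even",
        mean_segment_length_um=250.0,
        branch_angle_mean_deg=90.0,
        branch_angle_sd_deg=8.0,
        direction_noise_deg=1.0,
        radial_drift=0.0,
        logistic_params=(2500.0, 1.2, 6.0),
        n_days=12,
        sprout_width_um=5.0,
        min_clearance_px=25.0,
        rng_seed=seed,
    )


def straight_polyline(start, bearing_deg, length_px, step=1.0):
    """Polyline from start along a compass-style bearing (0° = +col axis,
    measured counterclockwise in (row, col) space)."""
    a = math.radians(bearing_deg)
    d = np.array([math.sin(a), math.cos(a)])
    n = int(length_px / step) + 1
    return np.asarray(start, dtype=float)[None, :] + step * np.arange(n)[:, None] * d[None, :]


def make_graph(segment_specs, node_kinds, bead=None, resolution=1.0):
    """Assemble a SkeletonGraph from explicit polylines.

    ``segment_specs``: list of (polyline, (node_a, node_b)); node positions
    are taken from the polyline ends; ``node_kinds``: id → kind.
    """
    graph = SkeletonGraph(bead=bead, resolution_um_per_px=resolution)
    for (poly, (a, b)) in segment_specs:
        poly = np.asarray(poly, dtype=float)
        if a not in graph.nodes:
            graph.nodes[a] = Node(position=tuple(poly[0]), kind=node_kinds[a])
        if b not in graph.nodes:
            graph.nodes[b] = Node(position=tuple(poly[-1]), kind=node_kinds[b])
        sid = len(graph.segments)
        graph.segments[sid] = Segment(
            polyline=poly,
            nodes=(a, b),
            length_um=path_length_px(poly) * resolution,
        )
    from sproutgraph.skeleton_graph import assign_classes

    assign_classes(graph)
    return graph


@pytest.fixture
def tri_junction_graph():
    """Degree-3 node at the origin-ish with arms at bearings 0°, 120°, 240°."""
    center = (200.0, 200.0)
    specs = [
        (straight_polyline(center, b, 100), (0, i + 1)) for i, b in enumerate((0, 120, 240))
    ]
    kinds = {0: "junction", 1: "tip", 2: "tip", 3: "tip"}
    return make_graph(specs, kinds, bead=Circle((200.0, 200.0), 10.0))
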