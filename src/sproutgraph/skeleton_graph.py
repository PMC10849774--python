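"""Skeletonization and conversion of the sprout mask into an annotated graph.

Nodes are junctions (≥3 skeleton neighbors, adjacent junction pixels merged
into one node), tips (single-neighbor endpoints) or bases (endpoints in
contact with the bead circle).  Maximal skeleton paths between nodes become
segments, classed ``primary`` (incident to a base), ``tip`` (incident to a
tip) or ``bifurcating`` (internal).  Tip segments shorter than the pruning
threshold are removed iteratively, except primaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .segmentation import Circle
from .units import DEFAULT_RESOLUTION_UM_PER_PX

DEFAULT_PRUNE_LENGTH_PX = 50
# Contact allowance between a skeleton endpoint and the bead-removal circle.
# Thinning retracts from a blunt cut by roughly the sprout half-width (more
# for oblique cuts), so this must exceed that retraction.
DEFAULT_BASE_CONTACT_PX = 10.0

SQRT2 = float(np.sqrt(2.0))

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Node:
    position: tuple[float, float]  # (row, col), cluster centroid for junctions
    kind: str  # 'junction' | 'tip' | 'base'


@dataclass
class Segment:
    polyline: np.ndarray  # (N, 2) pixel coordinates, endpoints on node pixels
    nodes: tuple[int, int]  # node ids at polyline[0] and polyline[-1]
    length_um: float
    classes: frozenset = frozenset()


@dataclass
class SkeletonGraph:
    nodes: dict[int, Node] = field(default_factory=dict)
    segments: dict[int, Segment] = field(default_factory=dict)
    bead: Circle | None = None
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    base_zone_px: float | None = None  # endpoints this close to the bead center are bases

    @property
    def n_tip(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == "tip")

    @property
    def n_primary(self) -> int:
        return sum(1 for s in self.segments.values() if "primary" in s.classes)

    @property
    def total_length_um(self) -> float:
        return sum(s.length_um for s in self.segments.values())

    def to_json_dict(self) -> dict:
        """Graph as plain data (nodes, polylines, classes) for JSON export."""
        return {
            "resolution_um_per_px": self.resolution_um_per_px,
            "bead": None
            if self.bead is None
            else {"center": list(self.bead.center), "radius": self.bead.radius},
            "nodes": {
                str(nid): {"position": list(n.position), "kind": n.kind}
                for nid, n in self.nodes.items()
            },
            "segments": {
                str(sid): {
                    "polyline": s.polyline.tolist(),
                    "nodes": list(s.nodes),
                    "length_um": s.length_um,
                    "classes": sorted(s.classes),
                }
                for sid, s in self.segments.items()
            },
        }

    def incident_segments(self, node_id: int) -> list[int]:
        """Segment ids incident to a node, self-loops listed twice."""
        out = []
        for sid, seg in self.segments.items():
            for nid in seg.nodes:
                if nid == node_id:
                    out.append(sid)
        return out

    def degree(self, node_id: int) -> int:
        return len(self.incident_segments(node_id))


def skeletonize(sprout_mask: np.ndarray) -> np.ndarray:
    """Homotopy-preserving thinning to a unit-width 8-connected centerline."""
    mask = np.asarray(sprout_mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return _sk_skeletonize(mask)


def path_length_px(polyline: np.ndarray) -> float:
    """Geodesic pixel length: axial steps count 1, diagonal steps √2."""
    if len(polyline) < 2:
        return 0.0
    steps = np.abs(np.diff(np.asarray(polyline, dtype=float), axis=0))
    return float(np.where((steps > 0).all(axis=1), SQRT2, 1.0).sum())


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def build_graph(
    skeleton: np.ndarray,
    bead: Circle | None,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    base_contact_px: float = DEFAULT_BASE_CONTACT_PX,
    bead_margin_px: float = 2.0,
) -> SkeletonGraph:
    """Convert a unit-width skeleton into a node/segment graph.

    Endpoint pixels within ``bead.radius + bead_margin_px + base_contact_px``
    of the bead center are classed ``base``; other endpoints are ``tip``;
    clusters of ≥3-neighbor pixels merge into single junction nodes at
    their rounded centroid.
    """
    from scipy import ndimage

    skel = np.asarray(skeleton, dtype=bool)
    base_zone = bead.radius + bead_margin_px + base_contact_px if bead is not None else None
    graph = SkeletonGraph(
        bead=bead, resolution_um_per_px=resolution_um_per_px, base_zone_px=base_zone
    )
    if not skel.any():
        return graph

    counts = _neighbor_counts(skel)
    counts[~skel] = -1
    junction_px = skel & (counts >= 3)
    endpoint_px = skel & (counts == 1)
    isolated_px = skel & (counts == 0)

    node_of_pixel: dict[tuple[int, int], int] = {}
    next_node = 0

    # junction clusters → one node each
    labels, n_clusters = ndimage.label(junction_px, structure=np.ones((3, 3), bool))
    for lab in range(1, n_clusters + 1):
        rows, cols = np.nonzero(labels == lab)
        pos = (float(rows.mean()), float(cols.mean()))
        graph.nodes[next_node] = Node(position=pos, kind="junction")
        for r, c in zip(rows, cols):
            node_of_pixel[(int(r), int(c))] = next_node
        next_node += 1

    def _is_base(r: int, c: int) -> bool:
        if bead is None:
            return False
        d = np.hypot(r - bead.center[0], c - bead.center[1])
        return d <= bead.radius + bead_margin_px + base_contact_px

    for r, c in zip(*np.nonzero(endpoint_px)):
        kind = "base" if _is_base(int(r), int(c)) else "tip"
        graph.nodes[next_node] = Node(position=(float(r), float(c)), kind=kind)
        node_of_pixel[(int(r), int(c))] = next_node
        next_node += 1

    # trace maximal paths between node pixels through degree-2 pixels
    visited_steps: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    next_seg = 0

    def _skel_neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = p
        out = []
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                out.append(q)
        return out

    def _add_segment(path: list[tuple[int, int]]) -> None:
        nonlocal next_seg
        a = node_of_pixel[path[0]]
        b = node_of_pixel[path[-1]]
        poly = np.asarray(path, dtype=float)
        graph.segments[next_seg] = Segment(
            polyline=poly, nodes=(a, b), length_um=path_length_px(poly) * resolution_um_per_px
        )
        next_seg += 1

    node_pixels = list(node_of_pixel.keys())
    for p in node_pixels:
        for q in _skel_neighbors(p):
            if (p, q) in visited_steps:
                continue
            if q in node_of_pixel:
                if node_of_pixel[q] == node_of_pixel[p]:
                    continue  # intra-cluster adjacency
                visited_steps.add((p, q))
                visited_steps.add((q, p))
                _add_segment([p, q])
                continue
            # walk through degree-2 pixels
            path = [p, q]
            visited_steps.add((p, q))
            prev, cur = p, q
            while cur not in node_of_pixel:
                nbrs = [x for x in _skel_neighbors(cur) if x != prev]
                if not nbrs:
                    break  # dead end not flagged as endpoint (should not happen)
                # prefer continuing away from the path; pick the first unvisited
                nxt = None
                for cand in nbrs:
                    if (cur, cand) not in visited_steps:
                        nxt = cand
                        break
                if nxt is None:
                    break
                visited_steps.add((cur, nxt))
                path.append(nxt)
                prev, cur = cur, nxt
            if cur in node_of_pixel:
                visited_steps.add((cur, prev))
                _add_segment(path)

    # pure cycles with no junctions/endpoints: register one artificial node
    traced = {tuple(map(int, pt)) for seg in graph.segments.values() for pt in seg.polyline}
    remaining = (
        set(zip(*(arr.tolist() for arr in np.nonzero(skel & (counts == 2)))))
        - traced
        - set(node_of_pixel)
    )
    while remaining:
        start = min(remaining)
        graph.nodes[next_node] = Node(position=(float(start[0]), float(start[1])), kind="junction")
        node_of_pixel[start] = next_node
        anchor = next_node
        next_node += 1
        path = [start]
        prev, cur = start, None
        for cand in _skel_neighbors(start):
            if cand in remaining:
                cur = cand
                break
        while cur is not None and cur != start:
            path.append(cur)
            nbrs = [x for x in _skel_neighbors(cur) if x != prev]
            prev, cur = cur, (nbrs[0] if nbrs else None)
        if cur == start:
            path.append(start)
        poly = np.asarray(path, dtype=float)
        graph.segments[next_seg] = Segment(
            polyline=poly,
            nodes=(anchor, anchor),
            length_um=path_length_px(poly) * resolution_um_per_px,
        )
        next_seg += 1
        remaining -= set(path)

    if isolated_px.any():
        warnings.warn("isolated skeleton pixels ignored", stacklevel=2)
    if bead is not None and not any(n.kind == "base" for n in graph.nodes.values()):
        warnings.warn("no skeleton endpoint near the bead; graph has no base nodes", stacklevel=2)

    _remove_artifact_loops(graph)
    collapse_base_stubs(graph)
    assign_classes(graph)
    return graph


def _remove_artifact_loops(graph: SkeletonGraph, max_px: float = 15.0) -> bool:
    """Drop tiny self-loop segments produced by thinning inside thick
    junction clusters; genuine anastomosis loops are far longer."""
    changed = False
    for sid in list(graph.segments):
        seg = graph.segments[sid]
        if seg.nodes[0] == seg.nodes[1] and path_length_px(seg.polyline) < max_px:
            del graph.segments[sid]
            changed = True
    return changed


def collapse_base_stubs(graph: SkeletonGraph, max_stub_px: float = 15.0) -> bool:
    """Remove fork artifacts the thinning creates at blunt stroke ends.

    Cutting a sprout stroke at the bead-removal circle leaves a blunt stump
    whose skeleton forks into short legs, each ending in its own endpoint
    node; base-ended legs would double-count primaries.  At any junction
    carrying such spur legs (endpoint-terminated, shorter than
    ``max_stub_px``) the legs are absorbed, and if any absorbed leg reached
    the bead-contact zone — or the junction itself lies in it — the junction
    becomes the base.  Returns True if anything was removed."""
    changed = False
    for nid in list(graph.nodes):
        node = graph.nodes.get(nid)
        if node is None or node.kind != "junction":
            continue
        incident = graph.incident_segments(nid)
        if len(set(incident)) < len(incident):
            continue  # self-loop present; leave untouched
        stubs = []
        for sid in incident:
            seg = graph.segments[sid]
            other = seg.nodes[0] if seg.nodes[1] == nid else seg.nodes[1]
            if graph.nodes[other].kind in ("base", "tip") and path_length_px(seg.polyline) < max_stub_px:
                stubs.append((sid, other))
        if not stubs or len(incident) - len(stubs) < 1:
            continue
        absorbed_base = False
        for sid, other in stubs:
            if graph.nodes[other].kind == "base":
                absorbed_base = True
            del graph.segments[sid]
            if not graph.incident_segments(other):
                del graph.nodes[other]
        changed = True
        in_zone = False
        if graph.base_zone_px is not None and graph.bead is not None:
            d = np.hypot(
                node.position[0] - graph.bead.center[0],
                node.position[1] - graph.bead.center[1],
            )
            in_zone = d <= graph.base_zone_px + max_stub_px
        if absorbed_base and in_zone:
            node.kind = "base"
    return changed


def _reclassify_dangling_junctions(graph: SkeletonGraph) -> bool:
    """Junction nodes left with a single incident segment after pruning are
    re-kinded as endpoints: base inside the bead contact zone, else tip."""
    changed = False
    for nid in list(graph.nodes):
        node = graph.nodes[nid]
        if node.kind != "junction":
            continue
        incident = graph.incident_segments(nid)
        if len(incident) == 0:
            del graph.nodes[nid]
            changed = True
        elif len(incident) == 1 and graph.segments[incident[0]].nodes[0] != graph.segments[incident[0]].nodes[1]:
            if graph.base_zone_px is not None and graph.bead is not None:
                d = np.hypot(
                    node.position[0] - graph.bead.center[0],
                    node.position[1] - graph.bead.center[1],
                )
                node.kind = "base" if d <= graph.base_zone_px else "tip"
            else:
                node.kind = "tip"
            changed = True
    return changed


def assign_classes(graph: SkeletonGraph) -> None:
    """(Re)assign segment classes from node kinds.

    ``tip``: one endpoint is a tip node.  ``bifurcating``: internal segment
    (no tip endpoint).  ``primary``: incident to a base node.  ``tip`` and
    ``bifurcating`` are mutually exclusive; ``primary`` may combine with
    either.
    """
    for seg in graph.segments.values():
        kinds = [graph.nodes[nid].kind for nid in seg.nodes]
        classes = set()
        if "tip" in kinds:
            classes.add("tip")
        else:
            classes.add("bifurcating")
        if "base" in kinds:
            classes.add("primary")
        seg.classes = frozenset(classes)


def _dissolve_degree2_junctions(graph: SkeletonGraph) -> bool:
    """Merge the two incident segments of any degree-2 junction node.

    Returns True if anything changed.  Length is conserved exactly because
    the merged polylines share the junction pixel.
    """
    changed = False
    for nid in list(graph.nodes):
        node = graph.nodes.get(nid)
        if node is None or node.kind != "junction":
            continue
        incident = graph.incident_segments(nid)
        if len(incident) != 2 or incident[0] == incident[1]:
            continue  # degree ≠ 2, or a self-loop
        sid_a, sid_b = incident
        seg_a, seg_b = graph.segments[sid_a], graph.segments[sid_b]
        # orient a to end at nid, b to start at nid
        poly_a = seg_a.polyline if seg_a.nodes[1] == nid else seg_a.polyline[::-1]
        end_a = seg_a.nodes[0] if seg_a.nodes[1] == nid else seg_a.nodes[1]
        poly_b = seg_b.polyline if seg_b.nodes[0] == nid else seg_b.polyline[::-1]
        end_b = seg_b.nodes[1] if seg_b.nodes[0] == nid else seg_b.nodes[0]
        merged = np.vstack([poly_a, poly_b[1:]])
        graph.segments[sid_a] = Segment(
            polyline=merged,
            nodes=(end_a, end_b),
            length_um=seg_a.length_um + seg_b.length_um,
        )
        del graph.segments[sid_b]
        del graph.nodes[nid]
        changed = True
    return changed


def prune(graph: SkeletonGraph, min_len_px: float = DEFAULT_PRUNE_LENGTH_PX) -> SkeletonGraph:
    """Iteratively remove tip segments shorter than ``min_len_px`` (pixel-path
    length), except those classed primary; dissolve degree-2 junctions after
    each sweep; repeat to fixpoint."""
    out = SkeletonGraph(
        nodes={k: replace(v) for k, v in graph.nodes.items()},
        segments={k: replace(v) for k, v in graph.segments.items()},
        bead=graph.bead,
        resolution_um_per_px=graph.resolution_um_per_px,
        base_zone_px=graph.base_zone_px,
    )
    assign_classes(out)
    while True:
        changed = False
        for sid in list(out.segments):
            seg = out.segments.get(sid)
            if seg is None or "tip" not in seg.classes or "primary" in seg.classes:
                continue
            if path_length_px(seg.polyline) >= min_len_px:
                continue
            tip_nodes = [nid for nid in seg.nodes if out.nodes[nid].kind == "tip"]
            del out.segments[sid]
            for nid in set(tip_nodes):
                if not out.incident_segments(nid):
                    del out.nodes[nid]
            changed = True
        if _dissolve_degree2_junctions(out):
            changed = True
        if _remove_artifact_loops(out):
            changed = True
        if collapse_base_stubs(out):
            changed = True
        if _reclassify_dangling_junctions(out):
            changed = True
        assign_classes(out)
        if not changed:
            break
    return out
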