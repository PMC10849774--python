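"""Bifurcation-angle measurement at degree-3 junction nodes.

For each junction with exactly three incident branches, a point is taken at
a fixed arclength (default 60 px) along each branch; the three sector
angles between the node→point vectors sum to 360° and the smallest is the
candidate bifurcation angle (hence never above 120°).  The bisector of that
angle is compared with the outward radial direction from the bead center:
pointing outwards (≤ 90°, inclusive) means a true bifurcation, inwards an
anastomosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .skeleton_graph import SkeletonGraph

DEFAULT_ARM_PX = 60
MIN_ARM_PX = 5.0


@dataclass
class AngleMeasurement:
    node_id: int
    node_position: tuple[float, float]
    arm_points: list[tuple[float, float]]
    raw_angles_deg: list[float]
    selected_angle_deg: float
    bisector: tuple[float, float] | None
    bisector_angle_to_radial_deg: float | None
    classification: str  # 'bifurcation' | 'anastomosis' | 'indeterminate'
    short_arm: bool = False


@dataclass
class SkippedNode:
    node_id: int
    reason: str


def laplacian_reference_angle() -> float:
    """The universal branching angle of planar Laplacian growth, 2π/5 rad
    expressed in degrees (72°)."""
    return math.degrees(2.0 * math.pi / 5.0)


def _walk_arm(polyline: np.ndarray, from_start: bool, arm_px: float) -> tuple[tuple[float, float], bool]:
    """Point at arclength ``arm_px`` along the polyline from one end, with
    linear interpolation between vertices; clamps to the far end (flagged)."""
    pts = np.asarray(polyline, dtype=float)
    if not from_start:
        pts = pts[::-1]
    deltas = np.diff(pts, axis=0)
    steps = np.hypot(deltas[:, 0], deltas[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    if total <= arm_px:
        return (float(pts[-1, 0]), float(pts[-1, 1])), True
    idx = int(np.searchsorted(cum, arm_px))
    t = (arm_px - cum[idx - 1]) / steps[idx - 1]
    p = pts[idx - 1] + t * deltas[idx - 1]
    return (float(p[0]), float(p[1])), False


def measure_node(graph: SkeletonGraph, node_id: int, arm_px: float = DEFAULT_ARM_PX) -> AngleMeasurement | SkippedNode:
    """Measure the bifurcation angle at a degree-3 node; other degrees are
    skipped with a reason."""
    incident = graph.incident_segments(node_id)
    if len(incident) != 3 or len(set(incident)) != len(incident):
        return SkippedNode(node_id, f"degree {len(incident)} != 3")
    node = graph.nodes[node_id]
    origin = np.asarray(node.position, dtype=float)

    arm_points: list[tuple[float, float]] = []
    short = False
    for sid in incident:
        seg = graph.segments[sid]
        from_start = seg.nodes[0] == node_id
        pt, clamped = _walk_arm(seg.polyline, from_start, arm_px)
        if clamped:
            short = True
            # branch too short to carry any direction
            if np.hypot(*(np.asarray(pt) - origin)) < MIN_ARM_PX:
                return AngleMeasurement(
                    node_id,
                    tuple(origin),
                    [pt],
                    [],
                    float("nan"),
                    None,
                    None,
                    "indeterminate",
                    short_arm=True,
                )
        arm_points.append(pt)

    vectors = [np.asarray(p) - origin for p in arm_points]
    bearings = np.array([math.atan2(v[0], v[1]) for v in vectors])  # (row, col) axes
    order = np.argsort(bearings)
    sorted_bearings = bearings[order]
    gaps = np.diff(np.concatenate([sorted_bearings, [sorted_bearings[0] + 2 * math.pi]]))
    raw = np.degrees(gaps)
    k = int(np.argmin(raw))
    selected = float(raw[k])
    # the two arms spanning the smallest sector
    i1 = order[k]
    i2 = order[(k + 1) % 3]
    u1 = vectors[i1] / np.linalg.norm(vectors[i1])
    u2 = vectors[i2] / np.linalg.norm(vectors[i2])
    bis = u1 + u2
    norm = np.linalg.norm(bis)
    if norm < 1e-12:
        return AngleMeasurement(
            node_id,
            tuple(origin),
            arm_points,
            raw.tolist(),
            selected,
            None,
            None,
            "indeterminate",
            short_arm=short,
        )
    bis = bis / norm
    return AngleMeasurement(
        node_id,
        tuple(origin),
        arm_points,
        raw.tolist(),
        selected,
        (float(bis[0]), float(bis[1])),
        None,
        "unclassified",
        short_arm=short,
    )


def classify(measure: AngleMeasurement, bead_center: tuple[float, float]) -> AngleMeasurement:
    """Set the bifurcation/anastomosis classification from the bisector
    direction: bifurcation iff the angle between the bisector and the
    outward radial vector is ≤ 90° (boundary inclusive)."""
    if measure.bisector is None or not np.isfinite(measure.selected_angle_deg):
        measure.classification = "indeterminate"
        return measure
    radial = np.asarray(measure.node_position, dtype=float) - np.asarray(bead_center, dtype=float)
    rnorm = np.linalg.norm(radial)
    if rnorm < 1e-12:
        measure.classification = "indeterminate"
        return measure
    radial = radial / rnorm
    cosang = float(np.clip(np.dot(measure.bisector, radial), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    measure.bisector_angle_to_radial_deg = angle
    measure.classification = "bifurcation" if angle <= 90.0 else "anastomosis"
    return measure


def measure_and_classify(graph: SkeletonGraph, node_id: int, arm_px: float = DEFAULT_ARM_PX):
    """Measure a node and classify it against the graph's bead center."""
    m = measure_node(graph, node_id, arm_px)
    if isinstance(m, SkippedNode):
        return m
    if graph.bead is None:
        m.classification = "indeterminate"
        return m
    return classify(m, graph.bead.center)


def angle_distribution(graph: SkeletonGraph, arm_px: float = DEFAULT_ARM_PX) -> dict:
    """Pool bifurcation-classified angles over all junction nodes of a graph.

    Returns ``{"angles": [...], "mean": ϕ*, "sem": sd/√n, "n": n,
    "measurements": [...], "skipped": [...]}``; mean/sem are None for n=0
    and sem is None for n=1.
    """
    angles: list[float] = []
    measurements: list[AngleMeasurement] = []
    skipped: list[SkippedNode] = []
    for nid, node in graph.nodes.items():
        if node.kind != "junction":
            continue
        m = measure_and_classify(graph, nid, arm_px)
        if isinstance(m, SkippedNode):
            skipped.append(m)
            continue
        measurements.append(m)
        if m.classification == "bifurcation":
            angles.append(m.selected_angle_deg)
    n = len(angles)
    mean = float(np.mean(angles)) if n else None
    sem = float(np.std(angles, ddof=1) / math.sqrt(n)) if n > 1 else (0.0 if n == 1 else None)
    return {
        "angles": angles,
        "mean": mean,
        "sem": sem,
        "n": n,
        "measurements": measurements,
        "skipped": skipped,
    }


def summarize_angles(angles: list[float]) -> dict:
    """Mean and SEM of a pooled angle sample."""
    n = len(angles)
    if n == 0:
        return {"mean": None, "sem": None, "n": 0}
    mean = float(np.mean(angles))
    sem = float(np.std(angles, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return {"mean": mean, "sem": sem, "n": n}
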