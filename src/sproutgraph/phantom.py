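"""Ground-truthed synthetic bead-sprouting networks.

A phantom network grows radially from a central bead: primaries start on
the bead rim, tips advance in 1-px arclength steps with Gaussian angular
jitter plus a weak outward radial drift, and each active tip bifurcates as
a Poisson process with rate 1/l* per unit arclength.  At a bifurcation the
two daughters deviate symmetrically by ±ϕ/2 from the parent direction with
ϕ drawn truncated-Normal on (0°, 180°).  Total length is scheduled to track
a logistic curve, sampled into per-day snapshots.  Networks render to
calibrated 16-bit images (bead disk + finite-width strokes + Gaussian
background noise) so the whole measurement pipeline can be exercised
against known ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.morphology import isotropic_dilation

from .growth_stats import logistic
from .imaging_io import CalibratedImage, TimeSeries
from .units import DEFAULT_BEAD_RADIUS_UM, DEFAULT_RESOLUTION_UM_PER_PX

FOREGROUND_LEVEL = 30000.0
STEP_PX = 1.0


class GeometryError(ValueError):
    """Raised when a spec cannot fit a growing network in the frame."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic bead-sprouting experiment."""

    bead_radius_um: float = DEFAULT_BEAD_RADIUS_UM
    n_primary: int = 5
    mean_segment_length_um: float = 150.0  # l*; inf disables branching
    branch_angle_mean_deg: float = 70.0
    branch_angle_sd_deg: float = 10.0
    sprout_width_um: float = 10.0
    tip_speed_um_per_day: float = 150.0  # per-tip daily elongation cap
    direction_noise_deg: float = 2.0  # per-step angular jitter (sd)
    radial_drift: float = 0.01  # per-step blend weight toward outward radial
    logistic_params: tuple[float, float, float] = (3000.0, 1.2, 7.0)  # Y_max, k, t1
    n_days: int = 14
    image_size_px: int = 1024
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    noise_sd: float = 300.0
    # Baseline intensity outside cells.  Realistic images carry background
    # signal; it also sets where the relative-mean threshold cuts the blurred
    # stroke edge (too low a background widens thin sprouts substantially).
    background_level: float = 20000.0
    rng_seed: int = 0
    primary_placement: str = "uniform"  # 'uniform' | 'even'
    min_clearance_px: float = 0.0  # >0: tips stop before touching other sprouts
    anastomosis: bool = False  # with clearance: fuse instead of stopping

    def __post_init__(self) -> None:
        if self.bead_radius_um <= 0 or self.sprout_width_um <= 0:
            raise ValueError("lengths must be strictly positive")
        if self.mean_segment_length_um <= 0:
            raise ValueError("mean segment length must be positive")
        if self.tip_speed_um_per_day <= 0:
            raise ValueError("tip speed must be positive")
        if self.n_primary < 0:
            raise ValueError("n_primary must be ≥ 0")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")
        y_max, k, _ = self.logistic_params
        if y_max <= 0 or k <= 0:
            raise ValueError("logistic Y_max and k must be positive")
        if self.primary_placement not in ("uniform", "even"):
            raise ValueError("primary_placement must be 'uniform' or 'even'")

    @property
    def bead_radius_px(self) -> float:
        return self.bead_radius_um / self.resolution_um_per_px


@dataclass
class GroundTruthSegment:
    points: list  # [(row, col), ...] float pixel coordinates
    parent: int | None
    generation: int
    children: list[int] = field(default_factory=list)
    branch_angle_deg: float | None = None  # ϕ drawn when this segment split
    fused: bool = False  # anastomosed tip

    @property
    def seg_class(self) -> str:
        return "bifurcating" if self.children else "tip"

    def length_px(self, n_points: int | None = None) -> float:
        pts = self.points if n_points is None else self.points[:n_points]
        if len(pts) < 2:
            return 0.0
        arr = np.asarray(pts)
        return float(np.hypot(*(np.diff(arr, axis=0).T)).sum())


@dataclass
class GroundTruthNetwork:
    bead_center_px: tuple[float, float]
    bead_radius_px: float
    resolution_um_per_px: float
    segments: dict[int, GroundTruthSegment] = field(default_factory=dict)
    snapshots: dict[int, dict[int, int]] = field(default_factory=dict)  # day → seg → n visible pts

    # -- queries ------------------------------------------------------------

    def visible(self, day: int) -> dict[int, int]:
        if day not in self.snapshots:
            raise KeyError(f"no snapshot for day {day}")
        return {sid: n for sid, n in self.snapshots[day].items() if n >= 2}

    def total_length_um(self, day: int) -> float:
        res = self.resolution_um_per_px
        return sum(
            self.segments[sid].length_px(n) * res for sid, n in self.visible(day).items()
        )

    def counts(self, day: int) -> tuple[int, int]:
        """(N_tip, N_pb) of the raw visible tree (no pruning applied)."""
        vis = self.visible(day)
        n_tip = sum(
            1
            for sid in vis
            if not any(c in vis for c in self.segments[sid].children)
        )
        n_pb = sum(1 for sid in vis if self.segments[sid].generation == 1)
        return n_tip, n_pb

    def measured_counts(self, day: int, min_tip_len_um: float) -> tuple[int, int, float]:
        """(N_tip, N_pb, L_um) after applying the measurement pruning rule to
        the ground-truth tree: leaves shorter than the threshold are removed
        (primaries exempt) and lone surviving children merge into their
        parent, iterated to fixpoint."""
        res = self.resolution_um_per_px
        vis = self.visible(day)
        length = {sid: self.segments[sid].length_px(n) * res for sid, n in vis.items()}
        children = {sid: [c for c in self.segments[sid].children if c in vis] for sid in vis}
        parent = {sid: self.segments[sid].parent for sid in vis}
        gen = {sid: self.segments[sid].generation for sid in vis}
        alive = set(vis)
        changed = True
        while changed:
            changed = False
            for sid in list(alive):
                if children[sid]:
                    continue
                if gen[sid] == 1:
                    continue  # primary exemption
                if length[sid] < min_tip_len_um:
                    alive.discard(sid)
                    p = parent[sid]
                    if p in alive:
                        children[p] = [c for c in children[p] if c != sid]
                    changed = True
            # dissolve: parent with exactly one remaining child merges
            for sid in list(alive):
                if len(children[sid]) == 1:
                    c = children[sid][0]
                    length[sid] += length[c]
                    children[sid] = children[c]
                    for gc in children[sid]:
                        parent[gc] = sid
                    alive.discard(c)
                    changed = True
        n_tip = sum(1 for sid in alive if not children[sid])
        n_pb = sum(1 for sid in alive if gen[sid] == 1)
        total = sum(length[sid] for sid in alive)
        return n_tip, n_pb, total

    def is_measurement_stable(
        self,
        day: int,
        min_tip_len_um: float,
        band_um: float = 12.0,
        junction_margin_px: float = 25.0,
    ) -> bool:
        """Whether the pruning outcome on this network is robust to the
        few-μm length differences between ground truth and skeleton paths.

        Replays the measurement pruning and rejects the network if any
        keep/prune decision falls within ``band_um`` of the threshold, or if
        a bifurcation point sits within ``junction_margin_px`` of the bead
        (where bead removal would swallow the junction).
        """
        res = self.resolution_um_per_px
        center = np.asarray(self.bead_center_px)
        vis = self.visible(day)
        for sid, n in vis.items():
            seg = self.segments[sid]
            if seg.children and any(c in vis for c in seg.children):
                branch_pt = np.asarray(seg.points[-1])
                if np.hypot(*(branch_pt - center)) < self.bead_radius_px + junction_margin_px:
                    return False
        length = {sid: self.segments[sid].length_px(n) * res for sid, n in vis.items()}
        children = {sid: [c for c in self.segments[sid].children if c in vis] for sid in vis}
        parent = {sid: self.segments[sid].parent for sid in vis}
        gen = {sid: self.segments[sid].generation for sid in vis}
        alive = set(vis)
        changed = True
        while changed:
            changed = False
            for sid in list(alive):
                if children[sid] or gen[sid] == 1:
                    continue
                if abs(length[sid] - min_tip_len_um) < band_um:
                    return False
                if length[sid] < min_tip_len_um:
                    alive.discard(sid)
                    p = parent[sid]
                    if p in alive:
                        children[p] = [c for c in children[p] if c != sid]
                    changed = True
            for sid in list(alive):
                if len(children[sid]) == 1:
                    c = children[sid][0]
                    length[sid] += length[c]
                    children[sid] = children[c]
                    for gc in children[sid]:
                        parent[gc] = sid
                    alive.discard(c)
                    changed = True
        return True

    def segment_lengths_um(self, day: int, seg_class: str | None = None) -> list[float]:
        res = self.resolution_um_per_px
        out = []
        for sid, n in self.visible(day).items():
            seg = self.segments[sid]
            visible_children = any(c in self.visible(day) for c in seg.children)
            cls = "bifurcating" if visible_children else "tip"
            if seg_class is None or cls == seg_class:
                out.append(seg.length_px(n) * res)
        return out

    def completed_segment_lengths_um(self) -> list[float]:
        """Lengths of all segments that finished growth by bifurcating."""
        res = self.resolution_um_per_px
        return [
            seg.length_px() * res for seg in self.segments.values() if seg.children
        ]

    @property
    def days(self) -> list[int]:
        return sorted(self.snapshots)

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "bead_center_px": list(self.bead_center_px),
            "bead_radius_px": self.bead_radius_px,
            "resolution_um_per_px": self.resolution_um_per_px,
            "segments": {
                str(sid): {
                    "points": [[round(float(r), 6), round(float(c), 6)] for r, c in seg.points],
                    "parent": seg.parent,
                    "generation": seg.generation,
                    "children": seg.children,
                    "branch_angle_deg": seg.branch_angle_deg,
                    "fused": seg.fused,
                }
                for sid, seg in self.segments.items()
            },
            "snapshots": {str(d): {str(s): n for s, n in snap.items()} for d, snap in self.snapshots.items()},
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthNetwork":
        d = json.loads(Path(path).read_text())
        net = cls(
            bead_center_px=tuple(d["bead_center_px"]),
            bead_radius_px=d["bead_radius_px"],
            resolution_um_per_px=d["resolution_um_per_px"],
        )
        for sid, s in d["segments"].items():
            net.segments[int(sid)] = GroundTruthSegment(
                points=[tuple(p) for p in s["points"]],
                parent=s["parent"],
                generation=s["generation"],
                children=list(s["children"]),
                branch_angle_deg=s["branch_angle_deg"],
                fused=s["fused"],
            )
        net.snapshots = {
            int(day): {int(s): n for s, n in snap.items()} for day, snap in d["snapshots"].items()
        }
        return net


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rotate(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _truncated_normal_angle(rng: np.random.Generator, mean: float, sd: float) -> float:
    """ϕ ~ Normal(mean, sd) truncated to the open interval (0°, 180°)."""
    if sd == 0:
        return float(np.clip(mean, 1e-6, 180 - 1e-6))
    for _ in range(1000):
        phi = rng.normal(mean, sd)
        if 0.0 < phi < 180.0:
            return float(phi)
    return float(np.clip(mean, 1e-6, 180 - 1e-6))


class _Grid:
    """Spatial hash of drawn points for clearance queries."""

    def __init__(self, cell: float):
        self.cell = max(cell, 1.0)
        self.cells: dict[tuple[int, int], list[tuple[int, int, float, float]]] = {}

    def add(self, seg_id: int, idx: int, pos: np.ndarray) -> None:
        key = (int(pos[0] // self.cell), int(pos[1] // self.cell))
        self.cells.setdefault(key, []).append((seg_id, idx, float(pos[0]), float(pos[1])))

    def near(self, pos: np.ndarray, radius: float):
        kr, kc = int(pos[0] // self.cell), int(pos[1] // self.cell)
        r2 = radius * radius
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for seg_id, idx, r, c in self.cells.get((kr + dr, kc + dc), ()):
                    if (r - pos[0]) ** 2 + (c - pos[1]) ** 2 <= r2:
                        yield seg_id, idx


def generate_network(spec: PhantomSpec) -> GroundTruthNetwork:
    """Grow a phantom network per the spec; deterministic in (spec, seed)."""
    rng = np.random.default_rng(spec.rng_seed)
    size = spec.image_size_px
    center = np.array([size / 2.0, size / 2.0])
    bead_r = spec.bead_radius_px
    res = spec.resolution_um_per_px
    margin = max(2.0, spec.sprout_width_um / res)
    if bead_r + 10 + margin > size / 2.0:
        raise GeometryError(
            f"bead radius {bead_r:.0f} px leaves no room for sprouts in a {size}-px frame"
        )

    net = GroundTruthNetwork(
        bead_center_px=(float(center[0]), float(center[1])),
        bead_radius_px=bead_r,
        resolution_um_per_px=res,
    )
    grid = _Grid(cell=max(spec.min_clearance_px, 4.0))

    if spec.primary_placement == "even" and spec.n_primary > 0:
        offset = rng.uniform(0, 2 * math.pi)
        thetas = offset + 2 * math.pi * np.arange(spec.n_primary) / spec.n_primary
    else:
        thetas = rng.uniform(0, 2 * math.pi, size=spec.n_primary)

    tips: list[dict] = []
    for i, theta in enumerate(thetas):
        direction = np.array([math.sin(theta), math.cos(theta)])
        start = center + bead_r * direction
        net.segments[i] = GroundTruthSegment(points=[tuple(start)], parent=None, generation=1)
        grid.add(i, 0, start)
        tips.append({"seg": i, "pos": start, "dir": direction, "steps_today": 0, "active": True})

    step_um = STEP_PX * res
    branch_prob = 0.0 if math.isinf(spec.mean_segment_length_um) else step_um / spec.mean_segment_length_um
    max_steps_per_day = max(1, int(round(spec.tip_speed_um_per_day / step_um)))
    noise_rad = math.radians(spec.direction_noise_deg)
    y_max, k, t1 = spec.logistic_params
    total_um = 0.0
    next_seg_id = spec.n_primary

    def _advance(tip: dict) -> None:
        nonlocal total_um, next_seg_id
        seg = net.segments[tip["seg"]]
        d = tip["dir"]
        if noise_rad > 0:
            d = _rotate(d, rng.normal(0.0, noise_rad))
        if spec.radial_drift > 0:
            radial = tip["pos"] - center
            rn = np.linalg.norm(radial)
            if rn > 1e-9:
                d = (1.0 - spec.radial_drift) * d + spec.radial_drift * (radial / rn)
        d = d / np.linalg.norm(d)
        new_pos = tip["pos"] + STEP_PX * d
        # frame bounds
        if not (margin <= new_pos[0] < size - margin and margin <= new_pos[1] < size - margin):
            tip["active"] = False
            return
        # clearance against other sprouts
        if spec.min_clearance_px > 0:
            own = tip["seg"]
            parent = seg.parent
            n_excl = int(2 * spec.min_clearance_px)
            for other, idx in grid.near(new_pos, spec.min_clearance_px):
                if other == own:
                    continue
                oseg = net.segments[other]
                if parent is not None:
                    if other == parent and idx >= len(oseg.points) - n_excl:
                        continue  # parent near the shared junction
                    if oseg.parent == parent and idx <= n_excl:
                        continue  # sibling near the shared junction
                if oseg.parent == own and idx <= n_excl:
                    continue  # own daughters near the junction
                if spec.anastomosis:
                    seg.points.append(tuple(new_pos))
                    seg.fused = True
                    total_um += step_um
                tip["active"] = False
                return
        tip["pos"] = new_pos
        tip["dir"] = d
        seg.points.append(tuple(new_pos))
        grid.add(tip["seg"], len(seg.points) - 1, new_pos)
        total_um += step_um
        tip["steps_today"] += 1
        # Poisson branching along arclength
        if branch_prob > 0 and len(seg.points) > 2 and rng.random() < branch_prob:
            phi = _truncated_normal_angle(rng, spec.branch_angle_mean_deg, spec.branch_angle_sd_deg)
            seg.branch_angle_deg = phi
            half = math.radians(phi) / 2.0
            for sign in (+1.0, -1.0):
                ddir = _rotate(d, sign * half)
                sid = next_seg_id
                next_seg_id += 1
                net.segments[sid] = GroundTruthSegment(
                    points=[tuple(new_pos)], parent=tip["seg"], generation=seg.generation + 1
                )
                seg.children.append(sid)
                tips.append(
                    {
                        "seg": sid,
                        "pos": new_pos.copy(),
                        "dir": ddir / np.linalg.norm(ddir),
                        "steps_today": tip["steps_today"],
                        "active": True,
                    }
                )
            tip["active"] = False

    for day in range(spec.n_days + 1):
        target = float(logistic(day, y_max, k, t1))
        for tip in tips:
            tip["steps_today"] = 0
        while total_um < target - 1e-9:
            progressed = False
            for tip in list(tips):
                if total_um >= target - 1e-9:
                    break
                if not tip["active"] or tip["steps_today"] >= max_steps_per_day:
                    continue
                _advance(tip)
                progressed = True
            if not progressed:
                break
        net.snapshots[day] = {sid: len(seg.points) for sid, seg in net.segments.items()}

    return net


def sample_branch_lengths(spec: PhantomSpec, n: int, rng_seed: int | None = None) -> np.ndarray:
    """Draw ``n`` arclengths-to-bifurcation from the tip-stepping primitive.

    This replays exactly the per-step Bernoulli branching trial a growing
    tip performs (including the two-step refractory gate after birth), free
    of the tree competition that right-censors completed segments inside a
    finite growth run.  The law is geometric with per-step probability
    step/l*, i.e. Exponential(l*) up to step discretization.
    """
    if math.isinf(spec.mean_segment_length_um):
        raise ValueError("branching disabled (infinite mean segment length)")
    rng = np.random.default_rng(spec.rng_seed if rng_seed is None else rng_seed)
    step_um = STEP_PX * spec.resolution_um_per_px
    p = step_um / spec.mean_segment_length_um
    out = np.empty(n)
    for i in range(n):
        n_points = 1
        while True:
            n_points += 1
            if n_points > 2 and rng.random() < p:
                break
        out[i] = (n_points - 1) * step_um
    return out


def generate_stable_network(
    spec: PhantomSpec,
    day: int,
    min_tip_len_um: float = 62.5,
    band_um: float = 12.0,
    max_tries: int = 100,
) -> tuple[GroundTruthNetwork, PhantomSpec]:
    """Generate a network whose pruning outcome at ``day`` is measurement-
    stable, bumping the seed until the screen passes (deterministic in the
    starting seed).  Returns (network, spec actually used)."""
    for i in range(max_tries):
        trial = replace_spec(spec, rng_seed=spec.rng_seed + i)
        net = generate_network(trial)
        if net.is_measurement_stable(day, min_tip_len_um, band_um):
            return net, trial
    raise RuntimeError(f"no measurement-stable network in {max_tries} tries")


def replace_spec(spec: PhantomSpec, **changes) -> PhantomSpec:
    import dataclasses

    return dataclasses.replace(spec, **changes)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def ground_truth_mask(net: GroundTruthNetwork, spec: PhantomSpec, day: int, include_bead: bool = True) -> np.ndarray:
    """Noise-free boolean rendering: bead disk + strokes of the spec width."""
    size = spec.image_size_px
    strokes = np.zeros((size, size), dtype=bool)
    for sid, n in net.snapshots[day].items():
        pts = np.asarray(net.segments[sid].points[:n])
        if len(pts) == 0:
            continue
        rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, size - 1)
        cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, size - 1)
        strokes[rows, cols] = True
    width_px = spec.sprout_width_um / spec.resolution_um_per_px
    if strokes.any() and width_px > 1:
        strokes = isotropic_dilation(strokes, radius=width_px / 2.0)
    if include_bead:
        rr, cc = _draw_disk(net.bead_center_px, net.bead_radius_px, shape=(size, size))
        strokes[rr, cc] = True
    return strokes


def render_image(
    net: GroundTruthNetwork,
    spec: PhantomSpec,
    day: int,
    bead_id: str | None = None,
    noise_seed: int | None = None,
) -> CalibratedImage:
    """Render one day's snapshot as a calibrated 16-bit-range image.

    Bead and sprouts are drawn at a fixed bright level; Gaussian background
    noise of scale ``spec.noise_sd`` is added; intensities clamp to
    [0, 65535].  The noise stream is seeded from (rng_seed, day), so the
    rendering is deterministic and ground truth is unaffected by noise.
    """
    if day not in net.snapshots:
        raise KeyError(f"no snapshot for day {day}")
    mask = ground_truth_mask(net, spec, day)
    img = np.where(mask, FOREGROUND_LEVEL, spec.background_level)
    if spec.noise_sd > 0:
        seed = spec.rng_seed if noise_seed is None else noise_seed
        rng = np.random.default_rng([seed, 7919, day])
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 65535.0)
    return CalibratedImage(img, spec.resolution_um_per_px, bead_id=bead_id, day=day)


# ---------------------------------------------------------------------------
# logistic time series
# ---------------------------------------------------------------------------


def generate_logistic_series(
    y_max: float,
    k: float,
    t1: float,
    days,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    name: str = "Y",
    units: str = "um",
) -> TimeSeries:
    """Sample Y(t) = Y_max/(1+exp(−k(t−t1))) on a day grid with additive
    Gaussian noise of scale ``noise_sd``."""
    if k <= 0:
        raise ValueError("k must be positive")
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("empty day grid")
    values = logistic(days, y_max, k, t1)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return TimeSeries(days=days, values=values, name=name, units=units)
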