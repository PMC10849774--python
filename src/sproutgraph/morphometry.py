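"""Per-bead, per-day global metrics and the tip-velocity time series.

Metrics: sprout area A, in-bead cell area A_c, total network length L,
mean sprout width λ = A/L, maximal tip radius r_max, tip count N_tip,
primary-branch count N_pb, and the generation number
G = 1 + log2(N_tip / N_pb).  Tip velocity v_tip = ΔL / (Δt · N_tip) with a
trailing moving average (default 2 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .imaging_io import TimeSeries
from .segmentation import SegmentationResult
from .skeleton_graph import SkeletonGraph

DEFAULT_VELOCITY_WINDOW_DAYS = 2.0


def generation_number(n_tip: int, n_pb: int) -> float | None:
    """G = 1 + log2(N_tip/N_pb); None if either count is zero."""
    if n_tip <= 0 or n_pb <= 0:
        return None
    return 1.0 + math.log2(n_tip / n_pb)


@dataclass
class MorphometricRecord:
    bead_id: str | None
    day: int | None
    condition: str = ""
    A_um2: float = 0.0
    Ac_um2: float = 0.0
    L_um: float = 0.0
    lambda_um: float | None = None
    rmax_um: float | None = None
    N_tip: int = 0
    N_pb: int = 0
    G: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VelocitySeries:
    days: np.ndarray  # the later day of each consecutive pair
    raw: np.ndarray  # v = ΔL/(Δt·N_tip), NaN where N_tip = 0
    smoothed: np.ndarray  # trailing moving average
    window_days: float = DEFAULT_VELOCITY_WINDOW_DAYS


def compute_record(
    seg: SegmentationResult,
    graph: SkeletonGraph,
    bead_id: str | None = None,
    day: int | None = None,
    condition: str = "",
    rmax_from_surface: bool = False,
) -> MorphometricRecord:
    """Assemble the metric vector from a segmentation result and its graph.

    ``rmax_from_surface`` subtracts the bead radius so r_max is measured
    from the bead surface instead of the center.
    """
    res = graph.resolution_um_per_px
    a = float(np.count_nonzero(seg.sprout_mask)) * res**2
    a_c = float(np.count_nonzero(seg.bead_region)) * res**2
    length = graph.total_length_um
    lam = a / length if length > 0 else None

    tip_positions = [n.position for n in graph.nodes.values() if n.kind == "tip"]
    rmax = None
    if tip_positions and graph.bead is not None:
        center = np.asarray(graph.bead.center)
        dists = [float(np.hypot(*(np.asarray(p) - center))) for p in tip_positions]
        rmax_px = max(dists)
        if rmax_from_surface:
            rmax_px -= graph.bead.radius
        rmax = rmax_px * res

    n_tip = graph.n_tip
    n_pb = graph.n_primary
    return MorphometricRecord(
        bead_id=bead_id,
        day=day,
        condition=condition,
        A_um2=a,
        Ac_um2=a_c,
        L_um=length,
        lambda_um=lam,
        rmax_um=rmax,
        N_tip=n_tip,
        N_pb=n_pb,
        G=generation_number(n_tip, n_pb),
    )


def tip_velocity(
    series_L: TimeSeries,
    series_Ntip: TimeSeries,
    window_days: float = DEFAULT_VELOCITY_WINDOW_DAYS,
) -> VelocitySeries:
    """v(d) = (L(d) − L(d_prev)) / (Δt · N_tip(d)) for consecutive day pairs,
    then a trailing moving average over ``window_days``.

    N_tip is taken at the later day of each pair (the tips that deposited
    the length increment).  Days with N_tip = 0 yield NaN and are excluded
    from the average.
    """
    if not np.array_equal(series_L.days, series_Ntip.days):
        raise ValueError("L and N_tip series must share the day grid")
    days = series_L.days
    if days.size < 2:
        raise ValueError("need at least two days")
    dl = np.diff(series_L.values)
    dt = np.diff(days)
    ntip = series_Ntip.values[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(ntip > 0, dl / (dt * ntip), np.nan)
    out_days = days[1:]
    smoothed = np.full_like(raw, np.nan)
    for i, d in enumerate(out_days):
        sel = (out_days > d - window_days) & (out_days <= d)
        vals = raw[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            smoothed[i] = vals.mean()
    return VelocitySeries(days=out_days, raw=raw, smoothed=smoothed, window_days=window_days)
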