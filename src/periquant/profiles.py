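"""Cross-vessel line profiles and lumen-edge alignment.

A 100 μm measuring line is placed across each annotated vessel; both channels
are sampled along it by bilinear interpolation at sub-pixel spacing.  The
lumen edge is the half-maximum crossing of the red (intravascular dye)
channel, found by walking outward from the central red maximum with local
background subtraction.  Green profiles are then re-indexed so each side's
abluminal axis starts at 0 μm at the detected edge — the coordinate system in
which the near/far window statistic is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .simulate import ImageFrame
from .units import um_to_index

__all__ = [
    "RawProfile",
    "EdgeAlignedProfile",
    "ProfileExtentError",
    "NoLumenSignalError",
    "OpenLumenError",
    "TruncatedSideError",
    "extract_profile",
    "locate_lumen_edges",
    "align_side",
    "align_abluminal",
    "estimate_cross_angle",
    "profiles_to_records",
]


class ProfileExtentError(ValueError):
    """The measuring line exits the imaged field."""


class NoLumenSignalError(ValueError):
    """Red profile has no plateau above background — no lumen to segment."""


class OpenLumenError(ValueError):
    """Red signal never falls below threshold on one side of the lumen."""


class TruncatedSideError(ValueError):
    """Less than the minimum abluminal extent remains on one side."""


@dataclass
class RawProfile:
    """Both channels sampled along the full cross-line, centred on the vessel.

    ``positions_um`` runs symmetrically from -length/2 to +length/2; 0 is the
    annotated vessel centre.
    """

    positions_um: np.ndarray
    green: np.ndarray
    red: np.ndarray
    step_um: float
    vessel_id: Optional[int] = None


@dataclass
class EdgeAlignedProfile:
    """Green samples on one side, re-gridded so the lumen edge sits at 0 μm."""

    side: str  # "left" | "right"
    abluminal_positions_um: np.ndarray
    green: np.ndarray
    edge_pos_um: float
    vessel_id: Optional[int] = None


def extract_profile(
    frame: ImageFrame,
    center_xy_um: tuple[float, float],
    angle_rad: float,
    length_um: float = 100.0,
    step_um: float = 0.25,
    vessel_id: Optional[int] = None,
) -> RawProfile:
    """Sample both channels along a line through ``center_xy_um``.

    Bilinear interpolation at sub-pixel positions; positions are μm relative
    to the line centre (negative towards one end).  Raises
    :class:`ProfileExtentError` if an endpoint leaves the field.
    """
    if step_um > frame.pixel_size_um:
        raise ValueError(
            f"step_um={step_um} exceeds pixel size {frame.pixel_size_um:.3f} um"
        )
    n_side = int(round((length_um / 2) / step_um))
    positions = np.arange(-n_side, n_side + 1) * step_um
    cx, cy = center_xy_um
    ux, uy = np.cos(angle_rad), np.sin(angle_rad)
    xs = cx + positions * ux
    ys = cy + positions * uy
    h, w = frame.shape
    extent_x = w * frame.pixel_size_um
    extent_y = h * frame.pixel_size_um
    for ex, ey in ((xs[0], ys[0]), (xs[-1], ys[-1])):
        over = max(0.0 - ex, ex - extent_x, 0.0 - ey, ey - extent_y, 0.0)
        if over > 0:
            who = f"vessel {vessel_id}" if vessel_id is not None else "line"
            raise ProfileExtentError(
                f"{who}: measuring line exits the field by {over:.2f} um "
                f"(endpoint ({ex:.1f}, {ey:.1f}) um, field "
                f"{extent_x:.1f} x {extent_y:.1f} um)"
            )
    coords = np.vstack(
        [um_to_index(ys, frame.pixel_size_um), um_to_index(xs, frame.pixel_size_um)]
    )
    green = map_coordinates(frame.green, coords, order=1, mode="nearest")
    red = map_coordinates(frame.red, coords, order=1, mode="nearest")
    return RawProfile(
        positions_um=positions, green=green, red=red, step_um=step_um, vessel_id=vessel_id
    )


def locate_lumen_edges(
    profile: RawProfile,
    threshold_frac: float = 0.5,
    search_radius_um: float = 12.0,
) -> tuple[float, float]:
    """Half-maximum lumen edges on the red channel.

    The plateau is the red maximum within ``search_radius_um`` of the line
    centre (the annotated vessel sits at 0; a 100 μm line may cross brighter
    neighbours further out).  Per side, background is the median of the outer
    20% of samples, and the edge is the first outward position where red
    falls below ``background + threshold_frac * (plateau - background)``,
    linearly interpolated between samples.
    """
    pos, red = profile.positions_um, profile.red
    central = np.abs(pos) <= search_radius_um
    if not central.any():
        central = np.ones_like(pos, dtype=bool)
    i_peak = int(np.flatnonzero(central)[np.argmax(red[central])])
    plateau = float(red[i_peak])

    n = len(pos)
    n_tail = max(1, int(round(0.2 * (n // 2))))
    edges = []
    for side, step in (("left", -1), ("right", +1)):
        tail = red[:n_tail] if side == "left" else red[-n_tail:]
        background = float(np.median(tail))
        if plateau - background <= 1e-9 * max(abs(plateau), 1.0):
            # no intensity drop towards this end: either the lumen runs off
            # the line (bright tail) or there is no lumen signal at all
            if background > 0.5 * plateau:
                raise OpenLumenError(
                    f"open lumen: red stays at plateau level to the {side} end"
                )
            raise NoLumenSignalError(
                f"no lumen signal: red plateau {plateau:.3g} <= background "
                f"{background:.3g} on {side} side"
            )
        thresh = background + threshold_frac * (plateau - background)
        i = i_peak
        edge = None
        while 0 <= i + step < n:
            j = i + step
            if red[j] < thresh:
                # linear interpolation of the crossing between samples i and j
                frac = (red[i] - thresh) / (red[i] - red[j])
                edge = float(pos[i] + frac * (pos[j] - pos[i]))
                break
            i = j
        if edge is None:
            raise OpenLumenError(
                f"open lumen: red never falls below threshold on {side} side"
            )
        edges.append(edge)
    left, right = edges
    return left, right


def align_side(
    profile: RawProfile,
    edge_um: float,
    side: str,
    min_extent_um: float = 10.0,
) -> EdgeAlignedProfile:
    """Re-index the green samples of one side onto the abluminal axis.

    Abluminal position = |position - edge| for samples outward of the edge;
    green is resampled onto a fixed grid (0, step, 2*step, ...) by linear
    interpolation.  Raises :class:`TruncatedSideError` if fewer than
    ``min_extent_um`` of abluminal extent remain.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    pos, green, step = profile.positions_um, profile.green, profile.step_um
    if side == "right":
        extent = float(pos[-1] - edge_um)
    else:
        extent = float(edge_um - pos[0])
    if extent < min_extent_um:
        raise TruncatedSideError(
            f"truncated side: only {extent:.2f} um of abluminal extent on the "
            f"{side} side (need >= {min_extent_um} um)"
            + (f" [vessel {profile.vessel_id}]" if profile.vessel_id is not None else "")
        )
    grid = np.arange(0.0, extent + 1e-9, step)
    # signed outward coordinate: increases away from the lumen on this side
    if side == "right":
        s, f = pos - edge_um, green
    else:
        s, f = (edge_um - pos)[::-1], green[::-1]
    g = np.interp(grid, s, f)
    return EdgeAlignedProfile(
        side=side,
        abluminal_positions_um=grid,
        green=g,
        edge_pos_um=float(edge_um),
        vessel_id=profile.vessel_id,
    )


def align_abluminal(
    profile: RawProfile,
    edges: tuple[float, float],
    min_extent_um: float = 10.0,
) -> tuple[EdgeAlignedProfile, EdgeAlignedProfile]:
    """Both sides of :func:`align_side`; raises if either side is truncated."""
    left_edge, right_edge = edges
    left = align_side(profile, left_edge, "left", min_extent_um)
    right = align_side(profile, right_edge, "right", min_extent_um)
    return left, right


def estimate_cross_angle(
    frame: ImageFrame, center_xy_um: tuple[float, float], window_um: float = 10.0
) -> float:
    """Auto-orientation helper: angle perpendicular to the local red ridge.

    Principal gradient direction of the red channel in a window around the
    centre (structure-tensor eigenvector).  Manual annotations take
    precedence over this helper in the pipeline.
    """
    from skimage.feature import structure_tensor

    ps = frame.pixel_size_um
    cx, cy = center_xy_um
    half = max(2, int(round(window_um / ps)))
    i, j = int(round(cy / ps - 0.5)), int(round(cx / ps - 0.5))
    h, w = frame.shape
    sl = (slice(max(0, i - half), min(h, i + half + 1)),
          slice(max(0, j - half), min(w, j + half + 1)))
    patch = frame.red[sl]
    Arr, Arc, Acc = structure_tensor(patch, sigma=1.0, order="rc")
    # dominant gradient direction = eigenvector of the summed tensor
    a, b, c = Arr.sum(), Arc.sum(), Acc.sum()
    theta = 0.5 * np.arctan2(2 * b, c - a)
    return float(theta)


def profiles_to_records(aligned: list[EdgeAlignedProfile]):
    """Tidy table (vessel_id, side, abluminal_um, green) for CSV export."""
    import pandas as pd

    rows = []
    for p in aligned:
        for x, g in zip(p.abluminal_positions_um, p.green):
            rows.append(
                {"vessel_id": p.vessel_id, "side": p.side, "abluminal_um": x, "green": g}
            )
    return pd.DataFrame(rows, columns=["vessel_id", "side", "abluminal_um", "green"])
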