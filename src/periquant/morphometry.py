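"""Vessel-wall morphometry on labelled masks.

Two measurements modelled on ultrastructural and histological wall analysis:
the area fractions of the wall occupied by endothelium, intramural cells and
basement membrane (BM), and the thickness of the *abluminal* BM at its
thickest point, found by casting rays from the lumen centroid.  Masks use
fixed integer codes: 0 background, 1 lumen, 2 endothelium, 3 intramural
cell, 4 basement membrane.  Perivascular spaces have no code — they are out
of the measurement by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps

LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_ENDOTHELIUM = 2
LABEL_INTRAMURAL = 3
LABEL_BASEMENT = 4

__all__ = [
    "WallMask",
    "CompositionResult",
    "wall_composition",
    "bm_thickness",
    "diameter_thickness_correlation",
    "synthetic_wall_mask",
]


@dataclass
class WallMask:
    """Integer-labelled vessel-wall image with physical pixel size."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D integer array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-coded")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")

    def validate_topology(self) -> None:
        """Exactly one connected lumen, not directly adjacent to background."""
        lumen = self.labels == LABEL_LUMEN
        if not lumen.any():
            raise ValueError("mask has no lumen")
        _, n = ndi.label(lumen)
        if n != 1:
            raise ValueError(f"mask has {n} lumen components (need exactly 1)")
        ring = ndi.binary_dilation(lumen) & ~lumen
        if (self.labels[ring] == LABEL_BACKGROUND).any():
            raise ValueError("lumen touches background: wall ring is broken")


@dataclass
class CompositionResult:
    """Wall area percentages as exact rationals, summing to 100 precisely.

    Fields are :class:`fractions.Fraction`; call ``float()`` for display.
    """

    pct_endothelium: Fraction
    pct_intramural: Fraction
    pct_basement: Fraction


def wall_composition(mask: WallMask) -> CompositionResult:
    """Percentage of the wall area held by each wall class.

    Areas are pixel counts (times the common pixel area, which cancels);
    percentages are exact rationals on those counts, so they always sum to
    100 with no rounding.
    """
    counts = {c: int(np.sum(mask.labels == c)) for c in (2, 3, 4)}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("mask has zero wall area (no pixels of class 2/3/4)")
    pct = {c: Fraction(100 * counts[c], total) for c in counts}
    return CompositionResult(
        pct_endothelium=pct[LABEL_ENDOTHELIUM],
        pct_intramural=pct[LABEL_INTRAMURAL],
        pct_basement=pct[LABEL_BASEMENT],
    )


def bm_thickness(
    mask: WallMask, n_rays: int = 360, oversample: float = 3.0
) -> Optional[float]:
    """Thickness (μm) of the abluminal basement membrane at its thickest.

    Rays are cast from the lumen centroid; along each ray the thickness is
    the run length of basement-membrane samples lying outward of the
    endothelium/intramural wall and reaching background abluminally.  The
    result is the maximum over rays; rays without an abluminal BM crossing
    are skipped.  Returns ``None`` when no ray qualifies (the vessel is not
    measurable under the abluminal-only rule).
    """
    lab = mask.labels
    ps = mask.pixel_size_um
    lumen = lab == LABEL_LUMEN
    if not lumen.any():
        raise ValueError("mask has no lumen to cast rays from")
    if not (lab == LABEL_BASEMENT).any():
        raise ValueError("mask has no basement-membrane class")
    ci, cj = ndi.center_of_mass(lumen)
    h, w = lab.shape
    max_r = math.hypot(h, w)  # px; rays always reach the border
    step = 1.0 / oversample  # px
    n_steps = int(max_r / step) + 1
    rr = np.arange(1, n_steps + 1) * step
    best = None
    for k in range(n_rays):
        th = 2 * math.pi * k / n_rays
        ii = np.clip(np.round(ci + rr * math.sin(th)).astype(int), 0, h - 1)
        jj = np.clip(np.round(cj + rr * math.cos(th)).astype(int), 0, w - 1)
        ray = lab[ii, jj]
        # outward scan: BM run must start after the last endo/intramural
        # sample and be followed by background (abluminal requirement)
        wall = np.flatnonzero((ray == LABEL_ENDOTHELIUM) | (ray == LABEL_INTRAMURAL))
        if wall.size == 0:
            continue
        start = wall[-1] + 1
        i = start
        n = len(ray)
        while i < n and ray[i] == LABEL_BASEMENT:
            i += 1
        run = i - start
        if run == 0:
            continue
        # must exit into background (or mask edge) to count as abluminal
        if i < n and ray[i] not in (LABEL_BACKGROUND,):
            continue
        thickness = run * step * ps
        if best is None or thickness > best:
            best = thickness
    return best


def diameter_thickness_correlation(
    diameters_um, thicknesses_um
) -> tuple[float, int, float]:
    """Pearson correlation between vessel diameter and wall thickness.

    Returns ``(r, df, p)`` with ``df = n - 2`` and the two-sided p-value from
    the exact t transform of r.
    """
    d = np.asarray(diameters_um, dtype=float)
    t = np.asarray(thicknesses_um, dtype=float)
    if d.shape != t.shape or d.ndim != 1:
        raise ValueError("diameters and thicknesses must be equal-length 1-D")
    if len(d) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(d).all() and np.isfinite(t).all()):
        raise ValueError("non-finite values in input")
    if np.std(d) == 0 or np.std(t) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(d, t)
    return float(res.statistic), len(d) - 2, float(res.pvalue)


def synthetic_wall_mask(
    image_px: int = 200,
    pixel_size_um: float = 0.05,
    lumen_radius_um: float = 2.0,
    endo_thickness_um: float = 0.3,
    intramural_thickness_um: float = 0.2,
    bm_thickness_um: float = 0.1,
    bm_sector: Optional[tuple[float, float, float]] = None,
    center_px: Optional[tuple[float, float]] = None,
) -> WallMask:
    """Parametric annular wall mask for tests and demos.

    Concentric rings: lumen, endothelium, intramural cells, basement
    membrane, background.  ``bm_sector = (theta_lo, theta_hi, extra_um)``
    thickens the BM over an angular sector, producing a known "thickest
    region".
    """
    if center_px is None:
        c = (image_px - 1) / 2.0
        center_px = (c, c)
    ci, cj = center_px
    ii, jj = np.mgrid[0:image_px, 0:image_px]
    r = np.hypot(ii - ci, jj - cj) * pixel_size_um
    theta = np.arctan2(ii - ci, jj - cj) % (2 * math.pi)
    r1 = lumen_radius_um
    r2 = r1 + endo_thickness_um
    r3 = r2 + intramural_thickness_um
    r4 = np.full_like(r, r3 + bm_thickness_um)
    if bm_sector is not None:
        lo, hi, extra = bm_sector
        in_sector = (theta >= lo % (2 * math.pi)) & (theta < hi % (2 * math.pi))
        r4 = np.where(in_sector, r3 + bm_thickness_um + extra, r4)
    lab = np.zeros((image_px, image_px), dtype=np.uint8)
    lab[r <= r4] = LABEL_BASEMENT
    lab[r <= r3] = LABEL_INTRAMURAL
    lab[r <= r2] = LABEL_ENDOTHELIUM
    lab[r <= r1] = LABEL_LUMEN
    return WallMask(labels=lab, pixel_size_um=pixel_size_um)
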