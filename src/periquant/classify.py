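"""The near/far window statistic and per-vessel positivity calls.

A vessel is tracer-positive when labelled peptide compacts on its abluminal
wall.  On an edge-aligned green profile this shows up as the mean intensity
over the first 3 μm beyond the lumen edge exceeding the mean over the next
7 μm.  The statistic here is that contrast, optionally standardized against
the local background noise scale; three decision modes are provided
(z-score of the contrast, near/far ratio, and a paired group test across
sides/frames).  Vessels without a single usable side are *excluded*: they
enter neither numerator nor denominator of any positive fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .profiles import EdgeAlignedProfile
from .simulate import ImageFrame

NEAR_WINDOW_UM = (0.0, 3.0)   # (0, 3] abluminal
FAR_WINDOW_UM = (3.0, 10.0)   # (3, 10]
NOISE_WINDOW_UM = (15.0, 25.0)

__all__ = [
    "ProfileStatistic",
    "ClassificationRule",
    "profile_statistic",
    "classify_vessel",
    "coloc_coefficient",
    "NEAR_WINDOW_UM",
    "FAR_WINDOW_UM",
    "NOISE_WINDOW_UM",
]


@dataclass
class ProfileStatistic:
    """Near/far window means and their contrast for one vessel side."""

    vessel_id: Optional[int]
    side: str
    mean_near: float
    mean_far: float
    contrast: float
    z_contrast: Optional[float]
    noise_scale: Optional[float]


@dataclass(frozen=True)
class ClassificationRule:
    """Decision rule turning profile statistics into a positivity call."""

    mode: str = "zscore"  # zscore | ratio | group_test
    z_threshold: float = 3.0
    ratio_threshold: float = 1.2
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in ("zscore", "ratio", "group_test"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        if self.z_threshold <= 0 or self.ratio_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def _window_mean(p: EdgeAlignedProfile, lo: float, hi: float) -> Optional[float]:
    """Mean green over abluminal positions in the half-open window (lo, hi]."""
    x = p.abluminal_positions_um
    sel = (x > lo) & (x <= hi + 1e-9)
    if not sel.any():
        return None
    return float(np.mean(p.green[sel]))


def robust_noise_scale(p: EdgeAlignedProfile) -> Optional[float]:
    """Robust background SD: 1.4826 * MAD of green in the 15–25 μm annulus."""
    x = p.abluminal_positions_um
    sel = (x > NOISE_WINDOW_UM[0]) & (x <= NOISE_WINDOW_UM[1] + 1e-9)
    if sel.sum() < 8:
        return None
    g = p.green[sel]
    mad = float(np.median(np.abs(g - np.median(g))))
    return 1.4826 * mad


def profile_statistic(
    p: EdgeAlignedProfile, noise_scale: Optional[float] = None
) -> ProfileStatistic:
    """Compute near (0–3 μm) and far (3–10 μm) window means and contrast.

    ``noise_scale`` defaults to the robust SD of green in the far 15–25 μm
    annulus of the same profile; ``z_contrast`` is undefined when no positive
    noise scale is available.
    """
    if p.abluminal_positions_um[-1] < FAR_WINDOW_UM[1]:
        raise ValueError(
            f"abluminal extent {p.abluminal_positions_um[-1]:.2f} um < "
            f"{FAR_WINDOW_UM[1]} um; side unusable"
        )
    mean_near = _window_mean(p, *NEAR_WINDOW_UM)
    mean_far = _window_mean(p, *FAR_WINDOW_UM)
    if mean_near is None or mean_far is None:  # cannot occur with step <= 0.25
        raise RuntimeError("internal error: empty near/far window")
    contrast = mean_near - mean_far
    if noise_scale is None:
        noise_scale = robust_noise_scale(p)
    z = None
    if noise_scale is not None and noise_scale > 0:
        z = contrast / noise_scale
    return ProfileStatistic(
        vessel_id=p.vessel_id,
        side=p.side,
        mean_near=mean_near,
        mean_far=mean_far,
        contrast=contrast,
        z_contrast=z,
        noise_scale=noise_scale,
    )


def classify_vessel(
    stats: Sequence[ProfileStatistic], rule: ClassificationRule = ClassificationRule()
) -> Optional[bool]:
    """Positivity call from the per-side statistics of one vessel.

    Returns ``None`` (excluded / "unclear profile") when no usable side is
    available.  Modes:

    * ``zscore`` (default): mean over sides of ``z_contrast`` >= z_threshold.
    * ``ratio``: side-averaged near mean over side-averaged far mean (floored
      at the noise scale) >= ratio_threshold.
    * ``group_test``: one-sided paired t-test of near vs far means across the
      provided statistics (sides and/or frames) at level alpha.
    """
    stats = [s for s in stats if s is not None]
    if not stats:
        return None
    if rule.mode == "zscore":
        zs = [s.z_contrast for s in stats if s.z_contrast is not None]
        if not zs:
            return None
        return bool(np.mean(zs) >= rule.z_threshold)
    if rule.mode == "ratio":
        near = float(np.mean([s.mean_near for s in stats]))
        far = float(np.mean([s.mean_far for s in stats]))
        scales = [s.noise_scale for s in stats if s.noise_scale]
        floor = float(np.mean(scales)) if scales else 0.0
        denom = max(far, floor)
        if denom <= 0:
            return None
        return bool(near / denom >= rule.ratio_threshold)
    # group_test
    near = np.array([s.mean_near for s in stats])
    far = np.array([s.mean_far for s in stats])
    if len(near) < 2:
        return bool(near[0] > far[0])  # single observation: sign only
    if np.allclose(near, far):
        return False
    res = sps.ttest_rel(near, far, alternative="greater")
    return bool(res.pvalue < rule.alpha)


def coloc_coefficient(
    frame: ImageFrame,
    center_xy_um: tuple[float, float],
    lumen_radius_um: float,
    annulus_um: tuple[float, float] = (0.0, 3.0),
    min_pixels: int = 30,
) -> Optional[float]:
    """Pearson correlation of red vs green over an abluminal annulus.

    The annulus is the pixel set at distance (r0+lo, r0+hi] from the vessel
    centre, with r0 the measured lumen radius — equivalent to morphological
    dilation of the lumen in μm units.  Returns ``None`` when either channel
    has zero variance over the annulus.
    """
    ps = frame.pixel_size_um
    h, w = frame.shape
    ys = (np.arange(h) + 0.5) * ps
    xs = (np.arange(w) + 0.5) * ps
    cx, cy = center_xy_um
    r = np.hypot(ys[:, None] - cy, xs[None, :] - cx)
    lo, hi = annulus_um
    sel = (r > lumen_radius_um + lo) & (r <= lumen_radius_um + hi)
    n = int(sel.sum())
    if n < min_pixels:
        raise ValueError(f"annulus contains only {n} pixels (< {min_pixels})")
    red = frame.red[sel]
    green = frame.green[sel]
    if np.std(red) == 0 or np.std(green) == 0:
        return None
    return float(sps.pearsonr(red, green).statistic)
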