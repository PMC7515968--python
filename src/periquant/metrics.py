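"""Frame-, animal- and group-level aggregation of vessel measurements.

Positive-vessel fractions, lumen diameters (FWHM convention on the red
channel), time courses with rise/plateau/decay segmentation, and
distance-to-injection stratification.  The statistical unit is the animal:
values are averaged per frame, then per animal, and only then compared
between groups — pooling all vessels is available but never the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import RawProfile, locate_lumen_edges

__all__ = [
    "FrameSummary",
    "AnimalSummary",
    "measure_diameter",
    "positive_fraction",
    "summarize_frame",
    "time_course",
    "distance_strata",
    "animal_summary",
    "group_values",
    "DEFAULT_DISTANCE_EDGES_UM",
]

DEFAULT_DISTANCE_EDGES_UM = tuple(float(x) for x in range(0, 361, 20)) + (np.inf,)


@dataclass
class FrameSummary:
    """Per-frame counts, positive fraction and diameters by class."""

    t_min: float
    n_vessels_usable: int
    n_positive: int
    positive_fraction_pct: Optional[float]
    mean_diam_pos_um: Optional[float]
    mean_diam_neg_um: Optional[float]


@dataclass
class AnimalSummary:
    """One animal's frame series reduced to animal-level means."""

    animal_id: str
    group: str  # e.g. control | treated
    volume_class: str  # small | large
    frames: list[FrameSummary] = field(default_factory=list)

    @property
    def mean_positive_fraction_pct(self) -> Optional[float]:
        vals = [f.positive_fraction_pct for f in self.frames if f.positive_fraction_pct is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_diam_pos_um(self) -> Optional[float]:
        vals = [f.mean_diam_pos_um for f in self.frames if f.mean_diam_pos_um is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_diam_neg_um(self) -> Optional[float]:
        vals = [f.mean_diam_neg_um for f in self.frames if f.mean_diam_neg_um is not None]
        return float(np.mean(vals)) if vals else None


def measure_diameter(profile: RawProfile) -> float:
    """Lumen diameter as the distance between the two half-maximum edges."""
    left, right = locate_lumen_edges(profile)
    return float(right - left)


def positive_fraction(classifications: Sequence[Optional[bool]]) -> Optional[float]:
    """100 * n_positive / n_usable; excluded (None) vessels omitted from both.

    Returns ``None`` (undefined) when no vessel is usable.
    """
    usable = [c for c in classifications if c is not None]
    if not usable:
        return None
    return 100.0 * sum(bool(c) for c in usable) / len(usable)


def summarize_frame(
    t_min: float,
    classifications: Sequence[Optional[bool]],
    diameters_um: Sequence[Optional[float]],
) -> FrameSummary:
    """Reduce one frame's per-vessel calls and diameters to a summary row."""
    if len(classifications) != len(diameters_um):
        raise ValueError("classifications and diameters must align per vessel")
    usable = [(c, d) for c, d in zip(classifications, diameters_um) if c is not None]
    n_usable = len(usable)
    n_pos = sum(bool(c) for c, _ in usable)
    d_pos = [d for c, d in usable if c and d is not None]
    d_neg = [d for c, d in usable if not c and d is not None]
    return FrameSummary(
        t_min=float(t_min),
        n_vessels_usable=n_usable,
        n_positive=n_pos,
        positive_fraction_pct=positive_fraction([c for c, _ in usable]),
        mean_diam_pos_um=float(np.mean(d_pos)) if d_pos else None,
        mean_diam_neg_um=float(np.mean(d_neg)) if d_neg else None,
    )


def time_course(summaries: Sequence[FrameSummary]) -> tuple[pd.DataFrame, Optional[dict]]:
    """Time-ordered positive-fraction series with descriptive segmentation.

    Segmentation (returned as a dict, or None when fewer than 3 frames):
    ``t_argmax`` (time of the maximum), ``plateau_start``/``plateau_end``
    (first/last frame at >= 90% of the maximum).
    """
    rows = sorted(summaries, key=lambda s: s.t_min)
    df = pd.DataFrame(
        {
            "t_min": [s.t_min for s in rows],
            "positive_fraction_pct": [s.positive_fraction_pct for s in rows],
            "n_vessels_usable": [s.n_vessels_usable for s in rows],
            "n_positive": [s.n_positive for s in rows],
        }
    )
    seg = None
    frac = df["positive_fraction_pct"].to_numpy(dtype=float)
    if len(df) >= 3 and np.isfinite(frac).any():
        peak = np.nanmax(frac)
        t = df["t_min"].to_numpy()
        if peak > 0:
            above = np.flatnonzero(frac >= 0.9 * peak)
            seg = {
                "t_argmax": float(t[int(np.nanargmax(frac))]),
                "plateau_start": float(t[above[0]]),
                "plateau_end": float(t[above[-1]]),
            }
        else:
            seg = {"t_argmax": float(t[0]), "plateau_start": None, "plateau_end": None}
    return df, seg


def distance_strata(
    distances_um: Sequence[float],
    classifications: Sequence[Optional[bool]],
    bin_edges_um: Sequence[float] = DEFAULT_DISTANCE_EDGES_UM,
    low_n: int = 3,
) -> pd.DataFrame:
    """Positive fractions stratified by distance to the injection source.

    Default bins are 20 μm wide up to 360 μm, then open-ended.  Bins with
    fewer than ``low_n`` usable vessels are flagged ``low_n=True``.
    """
    if len(distances_um) != len(classifications):
        raise ValueError("distances and classifications must align per vessel")
    edges = np.asarray(bin_edges_um, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [
            c
            for d, c in zip(distances_um, classifications)
            if lo <= d < hi and c is not None
        ]
        n = len(in_bin)
        rows.append(
            {
                "bin_lo_um": lo,
                "bin_hi_um": hi,
                "n_usable": n,
                "n_positive": sum(bool(c) for c in in_bin),
                "positive_fraction_pct": (100.0 * sum(bool(c) for c in in_bin) / n) if n else np.nan,
                "low_n": n < low_n,
            }
        )
    return pd.DataFrame(rows)


def animal_summary(
    animal_id: str,
    group: str,
    volume_class: str,
    frame_summaries: Sequence[FrameSummary],
) -> AnimalSummary:
    return AnimalSummary(
        animal_id=animal_id,
        group=group,
        volume_class=volume_class,
        frames=list(frame_summaries),
    )


def group_values(
    animals: Sequence[AnimalSummary], attr: str = "mean_positive_fraction_pct"
) -> dict[str, list[float]]:
    """Animal-level values keyed by group — the default inferential pathway.

    Group statistics are computed from one number per animal (frames averaged
    first), never from pooled vessels.
    """
    out: dict[str, list[float]] = {}
    for a in animals:
        v = getattr(a, attr)
        if v is not None:
            out.setdefault(a.group, []).append(float(v))
    return out


def plot_time_course(df: pd.DataFrame, ax=None):
    """Line plot of positive fraction vs time (one panel of the figure set)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(df["t_min"], df["positive_fraction_pct"], marker="o")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("positive vessels (%)")
    return ax


def plot_group_fractions(values_by_group: dict[str, list[float]], ax=None):
    """Bar chart of animal-mean positive fractions per group (mean ± SD)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = list(values_by_group)
    means = [np.mean(values_by_group[g]) for g in labels]
    sds = [np.std(values_by_group[g], ddof=1) if len(values_by_group[g]) > 1 else 0 for g in labels]
    ax.bar(labels, means, yerr=sds, capsize=4)
    ax.set_ylabel("positive vessels (%)")
    return ax
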