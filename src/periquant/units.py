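"""Micrometre/pixel coordinate conventions, centralized.

All physical coordinates are in micrometres, continuous, with the origin at
the field's top-left pixel *center* minus half a pixel — i.e. pixel ``i``
(row or column) is centred at ``(i + 0.5) * pixel_size_um``.  ``x`` runs
rightwards along columns, ``y`` downwards along rows.
"""

from __future__ import annotations

import numpy as np


def um_to_index(u, pixel_size_um: float):
    """Continuous μm coordinate -> fractional pixel index (center-of-pixel)."""
    return np.asarray(u, dtype=float) / pixel_size_um - 0.5


def index_to_um(i, pixel_size_um: float):
    """Fractional pixel index -> continuous μm coordinate."""
    return (np.asarray(i, dtype=float) + 0.5) * pixel_size_um


def pixel_centers_um(n_px: int, pixel_size_um: float) -> np.ndarray:
    """Centre coordinates (μm) of ``n_px`` pixels along one axis."""
    return (np.arange(n_px) + 0.5) * pixel_size_um
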