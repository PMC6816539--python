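"""Synthetic reference organ geometry for thoracic phantom sampling.

The thoracic (high-prior) phantom family needs a set of reference organ
boundaries -- two lungs, heart, aorta, spine -- drawn inside the unit disc.
The coordinates below are a *synthetic, illustrative* stand-in constructed
for this package: smooth parametric shapes laid out in a plausible 2D
thoracic cross-section (DICOM-style orientation, patient left on image
right).  They are not digitized from any measurement and can be overridden
by passing custom polygons to the phantom rule set.

All shapes are closed polygons (vertex lists, counter-clockwise) contained
in the disc of radius 0.95 and pairwise disjoint.
"""

from __future__ import annotations

import numpy as np

__all__ = ["default_organ_polygons", "ORGAN_LABELS"]

ORGAN_LABELS = ("left_lung", "right_lung", "spine", "heart", "aorta")


def _ellipse(center, a, b, angle_deg=0.0, n=16, squash=None):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    if squash is not None:
        # mild bean-like concavity on the side facing the mediastinum
        side, depth = squash
        x = x - side * depth * np.exp(-((y / (0.55 * b)) ** 2)) * (np.sign(x) == side)
    c = np.cos(np.deg2rad(angle_deg))
    s = np.sin(np.deg2rad(angle_deg))
    xr = c * x - s * y + center[0]
    yr = s * x + c * y + center[1]
    return np.column_stack([xr, yr])


def default_organ_polygons() -> dict[str, np.ndarray]:
    """Return the synthetic reference polygons, keyed by organ label.

    Image convention: ``x1`` increases to the image right (patient left),
    ``x2`` increases upward (anterior).
    """
    return {
        # lungs: large tilted ellipses with a slight medial concavity
        "left_lung": _ellipse((-0.44, -0.02), 0.28, 0.50, angle_deg=14.0,
                              squash=(1, 0.10)),
        "right_lung": _ellipse((0.45, 0.00), 0.26, 0.47, angle_deg=-12.0,
                               squash=(-1, 0.10)),
        # heart: anterior midline, slightly to image left
        "heart": _ellipse((-0.04, 0.42), 0.21, 0.17, angle_deg=-20.0, n=12),
        # aorta: small vessel between heart and spine
        "aorta": _ellipse((0.03, 0.06), 0.075, 0.075, n=8),
        # spine: posterior midline
        "spine": _ellipse((0.0, -0.62), 0.14, 0.115, n=10),
    }
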