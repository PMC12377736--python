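"""Sinus template geometry.

The dural venous sinuses form a characteristic branching pattern: a midline
sagittal sinus running caudally into the confluence of sinuses, two transverse
sinuses leaving the confluence laterally, and a rostral-rhinal extension at the
rostral end of the sagittal sinus.  Structure positions from different samples
are pooled by registering each sample's landmarks onto this template, so the
template lives in a normalized unit frame ([0, 1] x [0, 1], x rightward,
y downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

LANDMARK_NAMES = (
    "rostral_tip",
    "confluence",
    "left_transverse_end",
    "right_transverse_end",
)


class DegenerateGeometryError(ValueError):
    """Raised when geometry is too degenerate to process (collinear, zero-width...)."""


@dataclass(frozen=True)
class SinusTemplate:
    """Binary ribbon mask plus named landmarks in the unit frame.

    Attributes
    ----------
    mask:
        Boolean raster of the sinus ribbon; ``mask[i, j]`` covers the unit-frame
        point ``((j + 0.5) / W, (i + 0.5) / H)``.
    landmarks:
        Mapping of landmark name to ``(x, y)`` unit-frame coordinates.
    ribbon:
        The ribbon as a shapely polygon in the unit frame.
    """

    mask: np.ndarray
    landmarks: dict[str, tuple[float, float]] = field(repr=False)
    ribbon: shapely.Geometry = field(repr=False)

    def landmark_array(self, names=LANDMARK_NAMES) -> np.ndarray:
        return np.asarray([self.landmarks[n] for n in names], dtype=float)

    def contains(self, x, y) -> np.ndarray:
        """Point-in-ribbon test in the unit frame (vectorized)."""
        return shapely.contains_xy(self.ribbon, np.asarray(x, float), np.asarray(y, float))


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)


def make_sinus_template(
    ribbon_width: float = 0.06,
    mask_shape: tuple[int, int] = (256, 256),
    rostral_tip: tuple[float, float] = (0.42, 0.06),
    sagittal_top: tuple[float, float] = (0.50, 0.16),
    confluence: tuple[float, float] = (0.50, 0.74),
    left_transverse_end: tuple[float, float] = (0.12, 0.88),
    right_transverse_end: tuple[float, float] = (0.88, 0.88),
) -> SinusTemplate:
    """Build the branching sinus ribbon template.

    Parameters are unit-frame coordinates of the branch endpoints and the full
    ribbon width (also unit-frame).  The ribbon is the union of the rostral-rhinal
    segment, the midline sagittal segment, and the two transverse segments, all
    buffered to ``ribbon_width``.

    Raises
    ------
    DegenerateGeometryError
        If the ribbon width is non-positive, landmarks coincide, or all
        landmarks are collinear.
    """
    if ribbon_width <= 0:
        raise DegenerateGeometryError(f"ribbon_width must be > 0, got {ribbon_width}")
    landmarks = {
        "rostral_tip": tuple(map(float, rostral_tip)),
        "confluence": tuple(map(float, confluence)),
        "left_transverse_end": tuple(map(float, left_transverse_end)),
        "right_transverse_end": tuple(map(float, right_transverse_end)),
    }
    pts = np.asarray(list(landmarks.values()), float)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    if np.any(d[np.triu_indices(len(pts), 1)] < 1e-9):
        raise DegenerateGeometryError("coincident landmarks")
    if _collinear(pts):
        raise DegenerateGeometryError("landmarks are collinear")

    segments = [
        shapely.LineString([rostral_tip, sagittal_top]),
        shapely.LineString([sagittal_top, confluence]),
        shapely.LineString([confluence, left_transverse_end]),
        shapely.LineString([confluence, right_transverse_end]),
    ]
    ribbon = shapely.union_all([s.buffer(ribbon_width / 2) for s in segments])

    h, w = mask_shape
    xs = (np.arange(w) + 0.5) / w
    ys = (np.arange(h) + 0.5) / h
    gx, gy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(ribbon, gx.ravel(), gy.ravel()).reshape(h, w)
    return SinusTemplate(mask=mask, landmarks=landmarks, ribbon=ribbon)
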