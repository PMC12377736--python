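"""Landmark registration and hexagonal density maps.

Per-sample structure positions are registered into the common sinus-template
unit frame with a least-squares affine fit on named landmarks, then pooled into
a hex-binned density map: gray level encodes the structure count per hexagon
(displayed clipped to [0, 50]) and each structure is drawn as a circle whose
radius is proportional to the square root of its area (circle area tracks
structure area) and whose colour encodes its type (1 blue, 2 orange, 3 red).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Circle, RegularPolygon

from .template import DegenerateGeometryError, LANDMARK_NAMES, SinusTemplate

TYPE_COLORS = {1: "#1f77b4", 2: "#ff7f0e", 3: "#d62728"}  # blue / orange / red
DISPLAY_CAP = 50


@dataclass(frozen=True)
class AffineTransform2D:
    """x' = A @ x + b in 2D."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix.T + self.offset


def fit_affine(source: np.ndarray, target: np.ndarray) -> AffineTransform2D:
    """Least-squares 6-dof affine mapping source points onto target points."""
    src = np.asarray(source, float)
    dst = np.asarray(target, float)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 corresponding landmark pairs")
    centered = src - src.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("landmarks are collinear")
    design = np.c_[src, np.ones(len(src))]
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = dst - (src @ matrix.T + offset)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform2D(matrix=matrix, offset=offset, residual_rms=rms)


def fit_landmark_transform(
    source_landmarks: dict[str, tuple[float, float]],
    template: SinusTemplate,
    names=LANDMARK_NAMES,
) -> AffineTransform2D:
    """Affine transform taking a sample's named landmarks onto the template's."""
    missing = [n for n in names if n not in source_landmarks]
    if missing:
        raise ValueError(f"missing landmarks: {missing}")
    src = np.asarray([source_landmarks[n] for n in names], float)
    dst = template.landmark_array(names)
    return fit_affine(src, dst)


@dataclass
class DensityMap:
    """Hex-binned structure density in the template unit frame."""

    hex_centers: np.ndarray  # (m, 2)
    counts: np.ndarray  # (m,) raw non-negative ints
    circles: pd.DataFrame = field(repr=False)  # x, y, radius, els_type
    hex_diameter: float = 0.05
    label: str = ""

    @property
    def display_counts(self) -> np.ndarray:
        return np.clip(self.counts, 0, DISPLAY_CAP)


def _hex_assign(xy: np.ndarray, diameter: float) -> np.ndarray:
    """Assign points to pointy-top hexagons anchored at the origin.

    ``diameter`` is the vertex-to-vertex hex size (2x circumradius).  Each
    point goes to its nearest hex centre; exact boundary ties go to the
    lexicographically smaller centre.
    """
    radius = diameter / 2.0
    x, y = xy[:, 0] / radius, xy[:, 1] / radius
    # axial coordinates for pointy-top hexes
    q = (np.sqrt(3) / 3) * x - (1.0 / 3) * y
    r = (2.0 / 3) * y
    # cube rounding
    cx, cz = q, r
    cy = -cx - cz
    rx, ry, rz = np.round(cx), np.round(cy), np.round(cz)
    dx, dy, dz = np.abs(rx - cx), np.abs(ry - cy), np.abs(rz - cz)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)

    centers = np.empty_like(xy)
    best = np.stack([rx, rz], axis=1)
    # refine among the rounded hex and its 6 neighbours with a deterministic
    # (distance, center_x, center_y) tie-break
    neigh = np.array([(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)])
    for i, (bq, br) in enumerate(best):
        cand = neigh + (bq, br)
        hx = radius * np.sqrt(3) * (cand[:, 0] + cand[:, 1] / 2.0)
        hy = radius * 1.5 * cand[:, 1]
        d2 = (hx - xy[i, 0]) ** 2 + (hy - xy[i, 1]) ** 2
        order = np.lexsort((hy, hx, np.round(d2, 12)))
        centers[i] = hx[order[0]], hy[order[0]]
    return centers


def hexbin_density(
    structures: pd.DataFrame,
    hex_diameter: float = 0.05,
    circle_scale: float = 2e-4,
    label: str = "",
) -> DensityMap:
    """Bin registered structures into a hexagonal density map.

    ``structures`` must have unit-frame columns ``x, y`` plus ``area_um2`` and
    ``els_type``.  Raw counts are conserved (every structure lands in exactly
    one hex); display counts are clipped to [0, 50].  Circle radii are
    ``circle_scale * sqrt(area_um2)`` so that drawn circle area is
    proportional to structure area.
    """
    if hex_diameter <= 0:
        raise ValueError("hex_diameter must be > 0")
    circles = pd.DataFrame(
        {
            "x": structures["x"].to_numpy(float) if len(structures) else [],
            "y": structures["y"].to_numpy(float) if len(structures) else [],
            "radius": (
                circle_scale * np.sqrt(structures["area_um2"].to_numpy(float))
                if len(structures)
                else []
            ),
            "els_type": structures["els_type"].to_numpy(int) if len(structures) else [],
        }
    )
    if len(structures) == 0:
        return DensityMap(
            hex_centers=np.empty((0, 2)),
            counts=np.empty(0, dtype=int),
            circles=circles,
            hex_diameter=hex_diameter,
            label=label,
        )
    xy = structures[["x", "y"]].to_numpy(float)
    assigned = _hex_assign(xy, hex_diameter)
    centers, inverse = np.unique(np.round(assigned, 9), axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(centers)).astype(int)
    return DensityMap(
        hex_centers=centers,
        counts=counts,
        circles=circles,
        hex_diameter=hex_diameter,
        label=label,
    )


def render_density_map(
    maps: list[DensityMap],
    template: SinusTemplate,
    path: str,
    ncols: int = 3,
) -> dict:
    """Render one panel per density map over the template ribbon outline.

    Writes a PNG/SVG figure (by ``path`` extension) and returns metadata with
    the number of hexes and the circles drawn per type in each panel.
    """
    if not maps:
        maps = [
            DensityMap(
                hex_centers=np.empty((0, 2)),
                counts=np.empty(0, dtype=int),
                circles=pd.DataFrame(columns=["x", "y", "radius", "els_type"]),
            )
        ]
    n = len(maps)
    ncols = min(ncols, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 4 * nrows), squeeze=False)
    meta = {"path": path, "panels": []}
    for ax in axes.ravel():
        ax.set_axis_off()
    for m, ax in zip(maps, axes.ravel()):
        ax.set_xlim(0, 1)
        ax.set_ylim(1, 0)  # unit frame, y downward
        ax.set_aspect("equal")
        ax.set_title(m.label, fontsize=9)
        _draw_ribbon_outline(template, ax)
        hex_r = m.hex_diameter / 2.0
        for (hx, hy), dc in zip(m.hex_centers, m.display_counts):
            gray = 1.0 - dc / DISPLAY_CAP
            ax.add_patch(
                RegularPolygon(
                    (hx, hy), numVertices=6, radius=hex_r, orientation=0,
                    facecolor=(gray, gray, gray), edgecolor="none", zorder=1,
                )
            )
        by_type = {1: 0, 2: 0, 3: 0}
        for row in m.circles.itertuples(index=False):
            t = int(row.els_type)
            by_type[t] += 1
            ax.add_patch(
                Circle((row.x, row.y), radius=row.radius,
                       facecolor="none", edgecolor=TYPE_COLORS[t], lw=1.0, zorder=2)
            )
        meta["panels"].append(
            {"label": m.label, "n_hexes": int(len(m.hex_centers)),
             "circles_by_type": by_type, "total_count": int(m.counts.sum())}
        )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return meta


def _draw_ribbon_outline(template: SinusTemplate, ax):
    geom = template.ribbon
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        x, y = poly.exterior.xy
        ax.plot(x, y, color="0.4", lw=0.8, zorder=0)


def register_structures(
    structures: pd.DataFrame,
    landmarks: dict[str, tuple[float, float]],
    template: SinusTemplate,
) -> pd.DataFrame:
    """Map a sample's structure centroids into the template unit frame.

    ``structures`` needs ``centroid_x_um, centroid_y_um, area_um2, els_type``;
    the result has unit-frame columns ``x, y`` plus ``area_um2, els_type``.
    """
    tf = fit_landmark_transform(landmarks, template)
    out = structures.copy()
    if len(out):
        xy = tf.apply(out[["centroid_x_um", "centroid_y_um"]].to_numpy(float))
        out["x"], out["y"] = xy[:, 0], xy[:, 1]
    else:
        out["x"] = pd.Series(dtype=float)
        out["y"] = pd.Series(dtype=float)
    return out[["x", "y", "area_um2", "els_type"]]
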