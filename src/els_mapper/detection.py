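"""Cell detection, phenotype assignment and aggregate clustering.

Multichannel wholemount images (B = CD45R, T = CD3, Ki67, optional nuclei) are
reduced to tables of phenotyped cell points, which are then clustered into
candidate ectopic lymphoid structures (ELS) with a measured concave boundary.

All positions are expressed in micrometres.  Convention: origin at the image
top-left, x rightward, y downward, position = pixel index x pixel size
(0-based pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree
from skimage.feature import blob_log

from .template import DegenerateGeometryError

#: canonical column order of a detection table
DETECTION_COLUMNS = ["x_um", "y_um", "peak_intensity"]
#: canonical column order of a phenotyped-cell table
CELL_COLUMNS = ["x_um", "y_um", "lineage", "ki67", "peak_intensity"]

LINEAGES = ("B", "T")


class MissingChannelError(KeyError):
    """Requested channel absent from the image."""


@dataclass
class WholemountImage:
    """A multichannel 2D fluorescence image with physical pixel size.

    ``channels`` maps channel name ("B", "T", "Ki67", optionally "nuclei") to a
    2D float array; all channels must share dimensions.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm / px
    sample_id: str = ""

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {k: v.shape for k, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} not in {sorted(self.channels)}"
            ) from None


@dataclass
class Aggregate:
    """A density-connected cluster of phenotyped cells with measured geometry."""

    id: int
    cells: pd.DataFrame  # CELL_COLUMNS subset
    boundary: shapely.Geometry = field(repr=False)
    area_um2: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def empty_detections() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in DETECTION_COLUMNS})


def detect_cells(
    image: WholemountImage,
    channel: str,
    *,
    min_sigma_um: float = 2.5,
    max_sigma_um: float = 5.0,
    threshold: float = 0.3,
    num_sigma: int = 4,
) -> pd.DataFrame:
    """Detect blob-like cell puncta in one channel.

    Laplacian-of-Gaussian blob detection at the physical spot scale given by
    ``[min_sigma_um, max_sigma_um]``, followed by intensity-weighted sub-pixel
    centroid refinement.  Returns a table with columns ``x_um, y_um,
    peak_intensity`` (empty on a blank channel).
    """
    if min_sigma_um <= 0 or max_sigma_um <= 0:
        raise ValueError("spot scale must be positive")
    if max_sigma_um < min_sigma_um:
        raise ValueError("max_sigma_um < min_sigma_um")
    img = np.asarray(image.channel(channel), dtype=float)
    px = image.pixel_size
    blobs = blob_log(
        img,
        min_sigma=min_sigma_um / px,
        max_sigma=max_sigma_um / px,
        num_sigma=num_sigma,
        threshold=threshold,
    )
    if blobs.size == 0:
        return empty_detections()

    h, w = img.shape
    rows = []
    for by, bx, bsig in blobs:
        iy, ix = int(round(by)), int(round(bx))
        r = max(1, int(round(bsig)))
        y0, y1 = max(0, iy - r), min(h, iy + r + 1)
        x0, x1 = max(0, ix - r), min(w, ix + r + 1)
        win = np.clip(img[y0:y1, x0:x1], 0, None)
        tot = win.sum()
        if tot > 0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = float((win * yy).sum() / tot)
            cx = float((win * xx).sum() / tot)
        else:  # pragma: no cover - blob on non-positive plateau
            cy, cx = by, bx
        peak = float(img[y0:y1, x0:x1].max())
        rows.append((cx * px, cy * px, peak))
    out = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    return out.sort_values(["y_um", "x_um"], kind="stable").reset_index(drop=True)


def _greedy_match(a_xy: np.ndarray, b_xy: np.ndarray, radius: float):
    """Greedy one-to-one matching of points in ``a`` to points in ``b``.

    Candidate pairs within ``radius`` are processed by increasing distance,
    ties broken by (a index, b index); each point participates in at most one
    match.  Returns list of (i_a, i_b) pairs.
    """
    if len(a_xy) == 0 or len(b_xy) == 0:
        return []
    tree = cKDTree(b_xy)
    pairs = []
    for ia, p in enumerate(a_xy):
        for ib in tree.query_ball_point(p, radius):
            d = float(np.hypot(*(p - b_xy[ib])))
            pairs.append((d, ia, ib))
    pairs.sort()
    used_a, used_b, out = set(), set(), []
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        out.append((ia, ib))
    return out


def assign_phenotypes(
    b_dets: pd.DataFrame,
    t_dets: pd.DataFrame,
    ki67_dets: pd.DataFrame,
    coloc_radius: float = 5.0,
    bt_radius: float | None = None,
) -> pd.DataFrame:
    """Fuse per-channel detections into phenotyped cells.

    A detection appearing in both the B and T channel within ``bt_radius``
    (default: ``coloc_radius``; no biological double-positives are expected,
    so near-coincident B/T detections are one physical cell) is resolved to
    the channel with the higher peak intensity.  A tighter ``bt_radius`` than
    ``coloc_radius`` avoids fusing genuinely adjacent B and T cells in
    intermingled aggregates.  Each Ki67
    detection is then matched greedily by distance to the nearest unmatched
    lineage cell within ``coloc_radius``; matched cells get ``ki67 = True``.

    Returns the phenotyped cell table (columns ``x_um, y_um, lineage, ki67,
    peak_intensity``).
    """
    if coloc_radius <= 0:
        raise ValueError("coloc_radius must be > 0")
    if bt_radius is None:
        bt_radius = coloc_radius
    b_dets = b_dets.reset_index(drop=True)
    t_dets = t_dets.reset_index(drop=True)
    ki67_dets = ki67_dets.reset_index(drop=True)

    b_xy = b_dets[["x_um", "y_um"]].to_numpy(float).reshape(-1, 2)
    t_xy = t_dets[["x_um", "y_um"]].to_numpy(float).reshape(-1, 2)

    drop_b, drop_t = set(), set()
    for ib, it in _greedy_match(b_xy, t_xy, bt_radius):
        if b_dets.peak_intensity[ib] >= t_dets.peak_intensity[it]:
            drop_t.add(it)
        else:
            drop_b.add(ib)

    frames = []
    for dets, drop, lin in ((b_dets, drop_b, "B"), (t_dets, drop_t, "T")):
        keep = dets.drop(index=list(drop))
        frames.append(
            pd.DataFrame(
                {
                    "x_um": keep.x_um.to_numpy(float),
                    "y_um": keep.y_um.to_numpy(float),
                    "lineage": lin,
                    "ki67": False,
                    "peak_intensity": keep.peak_intensity.to_numpy(float),
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)

    k_xy = ki67_dets[["x_um", "y_um"]].to_numpy(float).reshape(-1, 2)
    c_xy = cells[["x_um", "y_um"]].to_numpy(float).reshape(-1, 2)
    for _, ic in _greedy_match(k_xy, c_xy, coloc_radius):
        cells.loc[ic, "ki67"] = True
    return cells[CELL_COLUMNS]


def cluster_aggregates(
    cells: pd.DataFrame,
    eps: float = 50.0,
    min_cells: int = 10,
    alpha: float | None = None,
) -> list[Aggregate]:
    """Cluster phenotyped cells into aggregates by eps-connectivity.

    Two cells are linked if their distance is <= ``eps`` (µm); clusters are the
    transitive closures of the link relation (single-linkage at eps).  Clusters
    with fewer than ``min_cells`` cells are discarded; the rest are measured
    with :func:`measure_aggregate`.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_cells < 3:
        raise ValueError("min_cells must be >= 3")
    n = len(cells)
    if n == 0:
        return []
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    pairs = np.asarray(sorted(cKDTree(xy).query_pairs(r=eps)), dtype=int).reshape(-1, 2)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)

    aggregates = []
    next_id = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_cells:
            continue
        sub = cells.iloc[idx].reset_index(drop=True)
        try:
            boundary, area, centroid = measure_aggregate(
                sub[["x_um", "y_um"]].to_numpy(float), alpha=alpha
            )
        except DegenerateGeometryError:
            continue  # collinear cluster: not a measurable structure
        aggregates.append(
            Aggregate(id=next_id, cells=sub, boundary=boundary, area_um2=area, centroid=centroid)
        )
        next_id += 1
    return aggregates


def _alpha_shape(points: np.ndarray, alpha: float) -> shapely.Geometry:
    """Union of Delaunay triangles with circumradius <= alpha."""
    tri = Delaunay(points)
    simplices = points[tri.simplices]  # (m, 3, 2)
    a = np.linalg.norm(simplices[:, 0] - simplices[:, 1], axis=1)
    b = np.linalg.norm(simplices[:, 1] - simplices[:, 2], axis=1)
    c = np.linalg.norm(simplices[:, 2] - simplices[:, 0], axis=1)
    s = (a + b + c) / 2
    area = np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = np.where(area > 0, a * b * c / (4 * area), np.inf)
    keep = simplices[circum_r <= alpha]
    if len(keep) == 0:
        return shapely.Polygon()
    return shapely.union_all([shapely.Polygon(t) for t in keep])


def measure_aggregate(
    positions: np.ndarray, alpha: float | None = None
) -> tuple[shapely.Geometry, float, tuple[float, float]]:
    """Boundary polygon, area (µm²) and centroid of a cell point set.

    The boundary is the alpha shape with ``alpha`` defaulting to twice the
    median nearest-neighbour distance; if the alpha shape is empty or
    disconnected the convex hull is used instead.  Elongated or concave
    follicles are therefore not over-measured the way a convex hull would.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or all points collinear.
    """
    pts = np.asarray(positions, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 cell positions")
    hull = shapely.MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise DegenerateGeometryError("collinear cell positions")
    if alpha is None:
        d, _ = cKDTree(pts).query(pts, k=2)
        alpha = 2.0 * float(np.median(d[:, 1]))
    shape = _alpha_shape(pts, alpha)
    if shape.is_empty or shape.geom_type != "Polygon":
        shape = hull
    return shape, float(shape.area), (float(shape.centroid.x), float(shape.centroid.y))
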