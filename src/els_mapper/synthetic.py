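"""Synthetic wholemount scenes and cohort tables with known ground truth.

Real dural wholemounts are not shipped with this package, so every downstream
stage is exercised on generated data: scenes place ectopic lymphoid structures
(ELS) of known type along a branching sinus ribbon and render each cell as a
Gaussian punctum in its lineage channel, and cohort generators draw per-mouse
ELS count tables with specified age/sex/genotype trends.

Type geometries (defaults):

* type 1 — a single-lineage disc, or both lineages locally interleaved in one
  disc ("mixed"): B and T cells are planted in pairs around shared anchor
  points, modelling a noncompartmentalized aggregate whose lineages are
  intimately intermingled rather than merely co-resident.
* type 2 — two tangent discs of radius r/2, one per lineage (adjacent
  compartments), with essentially no proliferation.
* type 3 — B cells uniform in a core disc of radius 0.5 r, T cells uniform in
  the annulus [0.6 r, r], with a Ki67+ fraction of the B cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import WholemountImage
from .template import SinusTemplate, make_sinus_template

LAYOUTS = ("mixed", "adjacent-compartments", "core-shell", "single-lineage")


@dataclass(frozen=True)
class StructureSpec:
    """Specification of one planted ELS."""

    center: tuple[float, float]  # µm
    target_type: int  # 1, 2 or 3
    n_b_cells: int
    n_t_cells: int
    ki67_fraction: float = 0.0  # fraction of B cells marked Ki67+
    radius: float = 40.0  # µm
    layout: str = "mixed"

    def __post_init__(self):
        if self.target_type not in (1, 2, 3):
            raise ValueError(f"target_type must be 1, 2 or 3, got {self.target_type}")
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_b_cells < 0 or self.n_t_cells < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0 <= self.ki67_fraction <= 1:
            raise ValueError("ki67_fraction must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        # type/layout consistency
        if self.target_type == 3:
            if self.layout != "core-shell" or self.ki67_fraction <= 0:
                raise ValueError("type 3 requires core-shell layout and ki67_fraction > 0")
        elif self.target_type == 2:
            if self.layout != "adjacent-compartments" or self.ki67_fraction > 0.02:
                raise ValueError(
                    "type 2 requires adjacent-compartments layout and ki67_fraction ~ 0"
                )
        else:
            if self.layout not in ("mixed", "single-lineage"):
                raise ValueError("type 1 requires mixed or single-lineage layout")
            if self.layout == "single-lineage" and self.n_b_cells > 0 and self.n_t_cells > 0:
                raise ValueError("single-lineage layout must have exactly one lineage")

    @property
    def n_cells(self) -> int:
        return self.n_b_cells + self.n_t_cells

    @property
    def n_ki67(self) -> int:
        return int(round(self.ki67_fraction * self.n_b_cells))

    @property
    def footprint_area(self) -> float:
        """Nominal planted area in µm² implied by the layout geometry."""
        r = self.radius
        if self.layout == "adjacent-compartments":
            return 2 * math.pi * (r / 2) ** 2
        return math.pi * r**2


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic wholemount scene."""

    canvas_size: tuple[int, int] = (2048, 2048)  # (H, W) px
    pixel_size: float = 2.0  # µm / px
    structures: tuple[StructureSpec, ...] = ()
    template: SinusTemplate | None = None
    background_noise: float = 0.0  # additive Gaussian std, intensity units
    cell_radius: float = 5.0  # µm
    seed: int = 0
    allow_overlap: bool = False
    sample_id: str = "scene"

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.background_noise < 0:
            raise ValueError("background_noise must be >= 0")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be > 0")
        h, w = self.canvas_size
        xmax, ymax = w * self.pixel_size, h * self.pixel_size
        for s in self.structures:
            x, y = s.center
            if not (0 <= x < xmax and 0 <= y < ymax):
                raise ValueError(f"structure center {s.center} outside canvas")
        if not self.allow_overlap:
            for i, a in enumerate(self.structures):
                for b in self.structures[i + 1 :]:
                    d = math.dist(a.center, b.center)
                    if d < 2 * max(a.radius, b.radius):
                        raise ValueError(
                            f"structures at {a.center} and {b.center} closer than "
                            "2x their radii (set allow_overlap=True to permit)"
                        )

    @property
    def extent_um(self) -> tuple[float, float]:
        h, w = self.canvas_size
        return w * self.pixel_size, h * self.pixel_size


@dataclass
class GroundTruth:
    """Planted cells, structures and landmark positions of one scene.

    ``cells`` columns: x_um, y_um, lineage, ki67, structure_id.
    ``structures`` columns: structure_id, center_x_um, center_y_um, els_type,
    area_um2, n_b, n_t, n_ki67, radius_um, layout.
    """

    cells: pd.DataFrame
    structures: pd.DataFrame
    landmarks: dict[str, tuple[float, float]] = field(default_factory=dict)  # µm


def _uniform_disc(rng, n, radius, center):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.c_[center[0] + r * np.cos(th), center[1] + r * np.sin(th)]


def _uniform_annulus(rng, n, r_in, r_out, center):
    r = np.sqrt(rng.uniform(r_in**2, r_out**2, size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.c_[center[0] + r * np.cos(th), center[1] + r * np.sin(th)]


def _place_structure(spec: StructureSpec, rng, jitter: float):
    """Return (b_xy, t_xy) cell positions for one structure."""
    c, r = spec.center, spec.radius
    nb, nt = spec.n_b_cells, spec.n_t_cells
    if spec.layout == "single-lineage":
        pts = _uniform_disc(rng, nb + nt, r, c)
        return (pts, np.empty((0, 2))) if nb else (np.empty((0, 2)), pts)
    if spec.layout == "mixed":
        m = max(nb, nt, 1)
        anchors = _uniform_disc(rng, m, max(r - jitter, r / 2), c)
        b = anchors[np.arange(nb) % m] + rng.normal(0, jitter / 2, size=(nb, 2))
        t = anchors[np.arange(nt) % m] + rng.normal(0, jitter / 2, size=(nt, 2))
        return b, t
    if spec.layout == "adjacent-compartments":
        th = rng.uniform(0, 2 * np.pi)
        off = np.array([np.cos(th), np.sin(th)]) * (r / 2)
        b = _uniform_disc(rng, nb, r / 2, (c[0] - off[0], c[1] - off[1]))
        t = _uniform_disc(rng, nt, r / 2, (c[0] + off[0], c[1] + off[1]))
        return b, t
    # core-shell
    b = _uniform_disc(rng, nb, 0.5 * r, c)
    t = _uniform_annulus(rng, nt, 0.6 * r, r, c)
    return b, t


def generate_ground_truth(spec: SceneSpec) -> GroundTruth:
    """Sample planted cell positions and structure records (no rendering)."""
    rng = np.random.default_rng(spec.seed)
    cell_rows, struct_rows = [], []
    for sid, s in enumerate(spec.structures):
        b_xy, t_xy = _place_structure(s, rng, jitter=spec.cell_radius)
        n_k = s.n_ki67
        ki67_idx = set(rng.choice(s.n_b_cells, size=n_k, replace=False)) if n_k else set()
        for i, (x, y) in enumerate(b_xy):
            cell_rows.append((x, y, "B", i in ki67_idx, sid))
        for x, y in t_xy:
            cell_rows.append((x, y, "T", False, sid))
        struct_rows.append(
            (sid, s.center[0], s.center[1], s.target_type, s.footprint_area,
             s.n_b_cells, s.n_t_cells, n_k, s.radius, s.layout)
        )
    cells = pd.DataFrame(
        cell_rows, columns=["x_um", "y_um", "lineage", "ki67", "structure_id"]
    )
    structures = pd.DataFrame(
        struct_rows,
        columns=["structure_id", "center_x_um", "center_y_um", "els_type", "area_um2",
                 "n_b", "n_t", "n_ki67", "radius_um", "layout"],
    )
    landmarks = {}
    if spec.template is not None:
        xmax, ymax = spec.extent_um
        landmarks = {
            name: (u * xmax, v * ymax) for name, (u, v) in spec.template.landmarks.items()
        }
    return GroundTruth(cells=cells, structures=structures, landmarks=landmarks)


def _stamp_gaussian(img: np.ndarray, x_px: float, y_px: float, sigma_px: float):
    """Add a unit-amplitude isotropic Gaussian at (x_px, y_px) in place."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma_px))
    iy, ix = int(round(y_px)), int(round(x_px))
    y0, y1 = max(0, iy - r), min(h, iy + r + 1)
    x0, x1 = max(0, ix - r), min(w, ix + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y_px
    xx = np.arange(x0, x1)[None, :] - x_px
    img[y0:y1, x0:x1] += np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))


def render_scene(spec: SceneSpec, gt: GroundTruth) -> WholemountImage:
    """Render planted cells as Gaussian puncta (sigma = cell_radius / 2).

    Each cell contributes a peak-amplitude-1.0 Gaussian to its lineage channel;
    Ki67+ cells additionally to the Ki67 channel at the same position.  Additive
    Gaussian background noise with std ``spec.background_noise`` is drawn from
    a generator seeded independently of cell placement, so the same spec and
    seed give bit-identical images.
    """
    h, w = spec.canvas_size
    px = spec.pixel_size
    sigma_px = (spec.cell_radius / 2) / px
    channels = {name: np.zeros((h, w), dtype=np.float32) for name in ("B", "T", "Ki67")}
    for row in gt.cells.itertuples(index=False):
        x_px, y_px = row.x_um / px, row.y_um / px
        _stamp_gaussian(channels[row.lineage], x_px, y_px, sigma_px)
        if row.ki67:
            _stamp_gaussian(channels["Ki67"], x_px, y_px, sigma_px)
    if spec.background_noise > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB10B]))
        for name in channels:
            channels[name] += noise_rng.normal(
                0, spec.background_noise, size=(h, w)
            ).astype(np.float32)
    return WholemountImage(channels=channels, pixel_size=px, sample_id=spec.sample_id)


def generate_scene(spec: SceneSpec) -> tuple[WholemountImage, GroundTruth]:
    """Generate one scene: ground truth plus rendered multichannel image."""
    gt = generate_ground_truth(spec)
    return render_scene(spec, gt), gt


# ---------------------------------------------------------------------------
# default benchmark scene recipe
# ---------------------------------------------------------------------------

def random_scene_spec(
    seed: int,
    n_structures: int | None = None,
    *,
    canvas_size: tuple[int, int] = (2048, 2048),
    pixel_size: float = 2.0,
    background_noise: float = 0.2,
    template: SinusTemplate | None = None,
    min_separation: float = 250.0,
    type_mix: tuple[float, float, float] = (0.4, 0.35, 0.25),
    sample_id: str | None = None,
) -> SceneSpec:
    """Draw a benchmark scene: ~10 structures of mixed type along the ribbon.

    Structure centers are sampled from the sinus ribbon with a minimum pairwise
    separation; per-type cell counts are drawn so that each structure is
    unambiguous under the default classification thresholds (each lineage
    clears the minority minimum, the type-3 Ki67+ fraction clears the
    proliferation threshold, and the T shell is dense enough to close around
    the core).
    """
    rng = np.random.default_rng(seed)
    if template is None:
        template = make_sinus_template()
    if n_structures is None:
        n_structures = int(rng.integers(8, 13))
    h, w = canvas_size
    xmax, ymax = w * pixel_size, h * pixel_size

    # candidate centers on the ribbon, rejection-sampled for separation
    mh, mw = template.mask.shape
    ribbon_idx = np.flatnonzero(template.mask)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_structures and attempts < 10_000:
        attempts += 1
        flat = int(rng.choice(ribbon_idx))
        i, j = divmod(flat, mw)
        x = (j + rng.uniform()) / mw * xmax
        y = (i + rng.uniform()) / mh * ymax
        if all(math.dist((x, y), c) >= min_separation for c in centers):
            centers.append((x, y))
    if len(centers) < n_structures:  # pragma: no cover - recipe guard
        raise RuntimeError("could not place structures with requested separation")

    # radii are drawn large enough that the planted nearest-neighbour spacing
    # stays above ~2 spot sigmas, i.e. the cells are opticaly resolvable
    structures = []
    for c in centers:
        t = int(rng.choice([1, 2, 3], p=np.asarray(type_mix) / sum(type_mix)))
        if t == 1:
            flavor = rng.choice(["b-only", "t-only", "mixed"])
            if flavor == "mixed":
                nb = int(rng.integers(10, 21))
                nt = int(rng.integers(10, 21))
                layout = "mixed"
            else:
                nb = int(rng.integers(15, 36)) if flavor == "b-only" else 0
                nt = 0 if flavor == "b-only" else int(rng.integers(15, 36))
                layout = "single-lineage"
            structures.append(
                StructureSpec(center=c, target_type=1, n_b_cells=nb, n_t_cells=nt,
                              radius=float(rng.uniform(50, 75)), layout=layout)
            )
        elif t == 2:
            structures.append(
                StructureSpec(center=c, target_type=2,
                              n_b_cells=int(rng.integers(12, 25)),
                              n_t_cells=int(rng.integers(12, 25)),
                              radius=float(rng.uniform(70, 100)),
                              layout="adjacent-compartments")
            )
        else:
            structures.append(
                StructureSpec(center=c, target_type=3,
                              n_b_cells=int(rng.integers(25, 36)),
                              n_t_cells=int(rng.integers(55, 76)),
                              ki67_fraction=float(rng.uniform(0.30, 0.40)),
                              radius=float(rng.uniform(85, 110)),
                              layout="core-shell")
            )
    return SceneSpec(
        canvas_size=canvas_size,
        pixel_size=pixel_size,
        structures=tuple(structures),
        template=template,
        background_noise=background_noise,
        seed=int(rng.integers(0, 2**31 - 1)),
        sample_id=sample_id or f"scene{seed:04d}",
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

COUNT_MODELS = ("negative-binomial", "lognormal-rounded")


@dataclass(frozen=True)
class GroupDesign:
    """One cohort cell: genotype x sex x age group."""

    genotype: str
    sex: str
    age_group: str  # e.g. "1", "12", "18+"
    n_mice: int
    mean_count: float
    dispersion: float  # variance = mean + dispersion * mean^2; 0 = variance-free
    mean_structure_area: float = 3000.0  # µm²
    type_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)

    def __post_init__(self):
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.mean_count < 0 or self.mean_structure_area < 0:
            raise ValueError("means must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if abs(sum(self.type_mix) - 1) > 1e-9:
            raise ValueError("type_mix must sum to 1")


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupDesign, ...]
    count_model: str = "negative-binomial"
    area_cv: float = 0.8  # coefficient of variation of per-structure areas
    seed: int = 0

    def __post_init__(self):
        if self.count_model not in COUNT_MODELS:
            raise ValueError(f"count_model must be one of {COUNT_MODELS}")
        if self.area_cv < 0:
            raise ValueError("area_cv must be >= 0")


@dataclass
class CohortTable:
    """Per-mouse summaries plus the long per-structure size table.

    ``mice`` columns: mouse_id, genotype, sex, age_group, n_type1, n_type2,
    n_type3, total_count, total_area_um2.
    ``sizes`` columns: mouse_id, els_type, area_um2.
    """

    mice: pd.DataFrame
    sizes: pd.DataFrame


def _draw_counts(rng, model, mean, dispersion, n):
    if dispersion == 0:
        return np.full(n, int(round(mean)))
    if model == "negative-binomial":
        # variance = mean + dispersion * mean^2  =>  size k = 1 / dispersion
        k = 1.0 / dispersion
        p = k / (k + mean)
        return rng.negative_binomial(k, p, size=n)
    # lognormal-rounded: E[exp(N(mu, s2))] = mean, squared CV = dispersion
    s2 = math.log1p(dispersion)
    mu = math.log(mean) - s2 / 2 if mean > 0 else -np.inf
    return np.round(rng.lognormal(mu, math.sqrt(s2), size=n)).astype(int)


def generate_cohort_counts(design: CohortDesign) -> CohortTable:
    """Draw a per-mouse ELS count/size/type table for the designed cohort."""
    rng = np.random.default_rng(design.seed)
    mouse_rows, size_rows = [], []
    midx = 0
    for g in design.groups:
        counts = _draw_counts(rng, design.count_model, g.mean_count, g.dispersion, g.n_mice)
        for c in counts:
            midx += 1
            mid = f"{g.genotype}_{g.sex}_{g.age_group}_m{midx:03d}"
            c = int(c)
            types = rng.choice([1, 2, 3], size=c, p=g.type_mix)
            if design.area_cv > 0 and g.mean_structure_area > 0:
                s2 = math.log1p(design.area_cv**2)
                mu = math.log(g.mean_structure_area) - s2 / 2
                areas = rng.lognormal(mu, math.sqrt(s2), size=c)
            else:
                areas = np.full(c, g.mean_structure_area, dtype=float)
            for t, a in zip(types, areas):
                size_rows.append((mid, int(t), float(a)))
            mouse_rows.append(
                (mid, g.genotype, g.sex, g.age_group,
                 int(np.sum(types == 1)), int(np.sum(types == 2)), int(np.sum(types == 3)),
                 c, float(areas.sum()))
            )
    mice = pd.DataFrame(
        mouse_rows,
        columns=["mouse_id", "genotype", "sex", "age_group",
                 "n_type1", "n_type2", "n_type3", "total_count", "total_area_um2"],
    )
    sizes = pd.DataFrame(size_rows, columns=["mouse_id", "els_type", "area_um2"])
    return CohortTable(mice=mice, sizes=sizes)


def wt_cohort_design(sex: str = "M", seed: int = 0, dispersion: float = 0.15) -> CohortDesign:
    """Wild-type cohort emulating the reported age trends.

    Males: monotone increase in mean ELS count over age groups 1, 12 and >18
    months (6 -> 10.75 -> 21.63, n = 8 per group).  Females: bell-shaped trend
    peaking at 12 months (7 -> 30.22 -> 14.25, n = 8/9/8).  Dispersion is an
    explicit input; the printed spreads in the source data are of unspecified
    kind and are never inferred.
    """
    if sex == "M":
        means, ns = (6.0, 10.75, 21.63), (8, 8, 8)
        mixes = [(0.8, 0.15, 0.05), (0.6, 0.25, 0.15), (0.5, 0.3, 0.2)]
    else:
        means, ns = (7.0, 30.22, 14.25), (8, 9, 8)
        mixes = [(0.8, 0.15, 0.05), (0.55, 0.3, 0.15), (0.6, 0.25, 0.15)]
    areas = (2000.0, 3500.0, 5000.0)
    groups = tuple(
        GroupDesign(genotype="WT", sex=sex, age_group=ag, n_mice=n, mean_count=m,
                    dispersion=dispersion, mean_structure_area=a, type_mix=mix)
        for ag, n, m, a, mix in zip(("1", "12", "18+"), ns, means, areas, mixes)
    )
    return CohortDesign(groups=groups, seed=seed)
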