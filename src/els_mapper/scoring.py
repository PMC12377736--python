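"""ELS typing and per-mouse quantity/complexity summaries.

Aggregates of phenotyped B and T cells are classified into three phenotypes of
increasing organisation:

* **Type 1** — B cells, T cells or both in a noncompartmentalized arrangement.
* **Type 2** — B and T cells in structurally compartmentalized regions with
  little to no proliferation.
* **Type 3** — a B-cell zone surrounded by T cells, with some Ki67+
  proliferating cells (germinal-centre-like).

"Compartmentalized" is operationalized as a low k-nearest-neighbour lineage
mixing score relative to a label-permutation null, and "surrounded" via radial
medians plus angular coverage of the outer T cells.  The classification is a
total cascade 3 -> 2 -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import Aggregate

DEFAULT_K = 5
DEFAULT_N_PERM = 999
DEFAULT_ALPHA = 0.05
DEFAULT_P_PROLIF = 0.05
DEFAULT_MIN_MINORITY = 5


class SingleLineageError(ValueError):
    """Statistic not applicable: only one lineage present."""


@dataclass(frozen=True)
class ELSFeatures:
    n_b: int
    n_t: int
    mixed: bool
    mixing_score: float  # NaN when not mixed
    segregation_p: float  # 1.0 when not mixed
    surrounded: bool
    ki67_fraction: float


@dataclass
class ELSRecord:
    aggregate: Aggregate
    features: ELSFeatures
    els_type: int
    sample_id: str = ""


@dataclass(frozen=True)
class MouseSummary:
    """Quantity-and-complexity summary of one mouse's ELS records."""

    mouse_id: str
    n_type1: int
    n_type2: int
    n_type3: int
    total_area_um2: float
    sizes: tuple[float, ...]  # sorted ascending

    @property
    def total_count(self) -> int:
        return self.n_type1 + self.n_type2 + self.n_type3


def _neighbor_indices(xy: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours of each point (self excluded).

    Distance ties are broken by index: a stable argsort of the distance matrix
    keeps lower indices first among equals.
    """
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def mixing_score(
    cells: pd.DataFrame,
    k: int = DEFAULT_K,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> tuple[float, float]:
    """k-NN lineage mixing score with a one-sided permutation p-value.

    The score is the mean, over cells, of the fraction of each cell's ``k``
    nearest neighbours (Euclidean, ties broken by index) carrying the opposite
    lineage.  Low scores indicate segregation.  ``segregation_p`` is the
    permutation p-value ``(1 + #{perm score <= observed}) / (n_perm + 1)``
    under random relabelling with lineage counts fixed.

    Raises
    ------
    SingleLineageError
        If only one lineage is present (callers must treat the aggregate as
        noncompartmentalized).
    """
    labels = (cells["lineage"].to_numpy() == "T")
    n = len(labels)
    if labels.all() or not labels.any():
        raise SingleLineageError("mixing score needs both lineages")
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n cells, got k={k}, n={n}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    nbrs = _neighbor_indices(xy, k)

    score = float((labels[nbrs] != labels[:, None]).mean())

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)
    perm_scores = (perm[:, nbrs] != perm[:, :, None]).mean(axis=(1, 2))
    p = (1 + int(np.sum(perm_scores <= score + 1e-12))) / (n_perm + 1)
    return score, float(p)


def surroundedness(
    cells: pd.DataFrame,
    centroid: tuple[float, float] | None = None,
    *,
    n_sectors: int = 12,
    coverage_deg: float = 270.0,
    rank_alpha: float = 0.05,
) -> tuple[bool, float, float, float]:
    """Test the type-3 topology: a B-cell core enclosed by a T-cell shell.

    Radii are measured from ``centroid`` (default: mean cell position).  The
    aggregate is "surrounded" when (a) the median B radius is smaller than the
    median T radius with a one-sided rank-sum p < ``rank_alpha`` and (b) the
    T cells in the outer radial half (radius >= the median radius over all
    cells) occupy at least ``coverage_deg`` of ``n_sectors`` equal angular
    sectors.

    Returns ``(surrounded, median_b_radius, median_t_radius,
    t_angular_coverage_deg)``.
    """
    lin = cells["lineage"].to_numpy()
    if (lin == "B").sum() == 0 or (lin == "T").sum() == 0:
        raise SingleLineageError("surroundedness needs both lineages")
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    c = np.asarray(centroid if centroid is not None else xy.mean(axis=0), float)
    rel = xy - c
    r = np.hypot(rel[:, 0], rel[:, 1])
    b_r, t_r = r[lin == "B"], r[lin == "T"]

    med_b, med_t = float(np.median(b_r)), float(np.median(t_r))
    core_ok = med_b < med_t
    if core_ok:
        core_ok = sps.mannwhitneyu(b_r, t_r, alternative="less").pvalue < rank_alpha

    outer = (lin == "T") & (r >= np.median(r))
    sector_width = 360.0 / n_sectors
    angles = np.degrees(np.arctan2(rel[outer, 1], rel[outer, 0])) % 360.0
    occupied = np.unique(np.floor(angles / sector_width).astype(int))
    coverage = float(len(occupied) * sector_width)
    return bool(core_ok and coverage >= coverage_deg), med_b, med_t, coverage


def compute_features(
    cells: pd.DataFrame,
    *,
    k: int = DEFAULT_K,
    n_perm: int = DEFAULT_N_PERM,
    min_minority: int = DEFAULT_MIN_MINORITY,
    centroid: tuple[float, float] | None = None,
    seed: int | None = None,
) -> ELSFeatures:
    """Compute all classification features for one aggregate's cell table."""
    lin = cells["lineage"].to_numpy()
    n_b, n_t = int((lin == "B").sum()), int((lin == "T").sum())
    mixed = n_b >= min_minority and n_t >= min_minority
    ki67_fraction = float(cells["ki67"].to_numpy().mean()) if len(cells) else 0.0
    if not mixed:
        return ELSFeatures(n_b, n_t, False, float("nan"), 1.0, False, ki67_fraction)
    score, p = mixing_score(cells, k=k, n_perm=n_perm, seed=seed)
    surrounded, *_ = surroundedness(cells, centroid=centroid)
    return ELSFeatures(n_b, n_t, True, score, p, surrounded, ki67_fraction)


def classify_els(
    features: ELSFeatures,
    alpha: float = DEFAULT_ALPHA,
    p_prolif: float = DEFAULT_P_PROLIF,
) -> int:
    """Assign the ELS type by the 3 -> 2 -> 1 decision cascade.

    Type 3 iff mixed, significantly segregated, surrounded, and the Ki67+
    fraction reaches ``p_prolif``; else type 2 iff mixed and significantly
    segregated; else type 1.
    """
    f = features
    if f.mixed and f.segregation_p < alpha:
        if f.surrounded and f.ki67_fraction >= p_prolif:
            return 3
        return 2
    return 1


def classify_cells(
    cells: pd.DataFrame,
    *,
    k: int = DEFAULT_K,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    p_prolif: float = DEFAULT_P_PROLIF,
    min_minority: int = DEFAULT_MIN_MINORITY,
    centroid: tuple[float, float] | None = None,
    seed: int | None = None,
) -> tuple[int, ELSFeatures]:
    """Convenience wrapper: features + cascade for one cell table."""
    f = compute_features(
        cells, k=k, n_perm=n_perm, min_minority=min_minority, centroid=centroid, seed=seed
    )
    return classify_els(f, alpha=alpha, p_prolif=p_prolif), f


def summarize_mouse(records: list[ELSRecord], mouse_id: str | None = None) -> MouseSummary:
    """Per-type counts, total area and the ordered size list of one mouse."""
    ids = {r.sample_id for r in records if r.sample_id}
    if mouse_id is None:
        if len(ids) > 1:
            raise ValueError(f"records from multiple mice: {sorted(ids)}")
        mouse_id = next(iter(ids), "")
    elif ids and ids != {mouse_id}:
        raise ValueError(f"records from multiple mice: {sorted(ids | {mouse_id})}")
    counts = {1: 0, 2: 0, 3: 0}
    sizes = []
    for r in records:
        counts[r.els_type] += 1
        sizes.append(float(r.aggregate.area_um2))
    sizes.sort()
    return MouseSummary(
        mouse_id=mouse_id,
        n_type1=counts[1],
        n_type2=counts[2],
        n_type3=counts[3],
        total_area_um2=float(sum(sizes)),
        sizes=tuple(sizes),
    )


def records_to_frame(records: list[ELSRecord]) -> pd.DataFrame:
    """Flatten ELS records to the canonical export table."""
    rows = []
    for r in records:
        f = r.features
        rows.append(
            {
                "sample_id": r.sample_id,
                "els_id": r.aggregate.id,
                "els_type": r.els_type,
                "area_um2": r.aggregate.area_um2,
                "n_b": f.n_b,
                "n_t": f.n_t,
                "ki67_fraction": f.ki67_fraction,
                "mixing_score": f.mixing_score,
                "segregation_p": f.segregation_p,
                "surrounded": f.surrounded,
                "centroid_x_um": r.aggregate.centroid[0],
                "centroid_y_um": r.aggregate.centroid[1],
            }
        )
    cols = ["sample_id", "els_id", "els_type", "area_um2", "n_b", "n_t",
            "ki67_fraction", "mixing_score", "segregation_p", "surrounded",
            "centroid_x_um", "centroid_y_um"]
    return pd.DataFrame(rows, columns=cols)
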