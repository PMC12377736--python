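"""End-to-end pipeline: images or cell tables -> records, summaries, maps, stats.

Each sample passes through detection (unless a phenotyped cell table is
supplied directly), eps-connectivity clustering, feature computation, the
3 -> 2 -> 1 type cascade, landmark registration into the template frame, hex
density mapping per cohort group, and the cohort statistics.  Runs are
deterministic given the configuration seed: per-aggregate permutation seeds
are derived from (config seed, sample, aggregate).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as els_io
from .config import PipelineConfig
from .detection import (
    Aggregate,
    MissingChannelError,
    WholemountImage,
    assign_phenotypes,
    cluster_aggregates,
    detect_cells,
)
from .scoring import (
    ELSRecord,
    classify_els,
    compute_features,
    records_to_frame,
    summarize_mouse,
)
from .spatial import hexbin_density, register_structures, render_density_map
from .stats import bell_fit, dunn_posthoc, kruskal_wallis, size_distribution, spearman
from .template import SinusTemplate, make_sinus_template

log = logging.getLogger("els_mapper")


class MetadataMismatchError(KeyError):
    """Sample ids in inputs and metadata disagree."""


def _derived_seed(base_seed: int, *parts) -> int:
    h = hashlib.sha256(("|".join(map(str, (base_seed, *parts)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def detect_sample(image: WholemountImage, config: PipelineConfig) -> pd.DataFrame:
    """Image -> phenotyped cell table."""
    d = config.detection
    dets = {
        ch: detect_cells(
            image, ch,
            min_sigma_um=d.min_sigma_um, max_sigma_um=d.max_sigma_um,
            threshold=d.threshold,
        )
        for ch in ("B", "T", "Ki67")
    }
    return assign_phenotypes(
        dets["B"], dets["T"], dets["Ki67"], d.coloc_radius_um, bt_radius=d.bt_radius_um
    )


def classify_sample(
    cells: pd.DataFrame, sample_id: str, config: PipelineConfig
) -> list[ELSRecord]:
    """Cell table -> classified ELS records."""
    d, s = config.detection, config.scoring
    records = []
    for agg in cluster_aggregates(cells, eps=d.eps_um, min_cells=d.min_cells):
        feats = compute_features(
            agg.cells,
            k=s.k, n_perm=s.n_perm, min_minority=s.min_minority,
            centroid=agg.centroid,
            seed=_derived_seed(config.seed, sample_id, agg.id),
        )
        records.append(
            ELSRecord(
                aggregate=agg,
                features=feats,
                els_type=classify_els(feats, alpha=s.alpha, p_prolif=s.p_prolif),
                sample_id=sample_id,
            )
        )
    return records


@dataclass
class PipelineResult:
    records: pd.DataFrame
    summaries: pd.DataFrame
    sizes: pd.DataFrame
    stats_report: dict = field(default_factory=dict)
    map_meta: dict = field(default_factory=dict)


def _summaries_frame(per_sample_records: dict[str, list[ELSRecord]], metadata: pd.DataFrame):
    rows = []
    for sid, recs in per_sample_records.items():
        s = summarize_mouse(recs, mouse_id=sid)
        rows.append(
            {"sample_id": sid, "n_type1": s.n_type1, "n_type2": s.n_type2,
             "n_type3": s.n_type3, "total_count": s.total_count,
             "total_area_um2": s.total_area_um2}
        )
    summaries = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    return summaries.merge(metadata, on="sample_id", how="left")


def cohort_statistics(summaries: pd.DataFrame, config: PipelineConfig) -> dict:
    """Spearman age trend, bell fit and Kruskal-Wallis + Dunn per cohort cell."""
    coding = config.stats.age_coding
    report = {}
    for (genotype, sex), sub in summaries.groupby(["genotype", "sex"], sort=True):
        entry = {}
        ages = sub["age_group"].map(coding)
        counts = sub["total_count"].to_numpy(float)
        if ages.notna().all() and ages.nunique() >= 2 and np.ptp(counts) > 0:
            r, p = spearman(ages.to_numpy(float), counts)
            entry["spearman"] = {"r": r, "p": p}
            if ages.nunique() >= 3:
                fit = bell_fit(ages.to_numpy(float), counts, model=config.stats.bell_model)
                entry["bell_fit"] = {
                    "model": fit.model, "r_squared": fit.r_squared,
                    "peak": fit.peak, **fit.params,
                }
        by_age = [g.to_numpy(float) for _, g in sub.groupby("age_group")["total_count"]]
        age_labels = sorted(sub["age_group"].unique())
        if len(by_age) >= 2 and all(len(g) >= 2 for g in by_age):
            h, p = kruskal_wallis(by_age)
            entry["kruskal_wallis"] = {"H": h, "p": p}
            dunn = dunn_posthoc(by_age, labels=age_labels)
            entry["dunn"] = dunn.to_dict(orient="records")
        report[f"{genotype}/{sex}"] = entry
    return report


def run_pipeline(
    input_dir: str | Path,
    metadata: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path,
    template: SinusTemplate | None = None,
    from_cells: bool = False,
) -> PipelineResult:
    """Run the full pipeline over a directory of samples.

    ``input_dir`` holds either ``<sample_id>.tif`` + ``.json`` sidecars (the
    image entry point) or ``<sample_id>.cells.csv`` phenotyped-cell tables
    (``from_cells=True``; detection skipped).  ``metadata`` must map every
    ``sample_id`` to genotype, sex and age_group.  Writes the ELS record CSV,
    mouse summary CSV, density-map figures and a stats report under
    ``out_dir``.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if template is None:
        template = make_sinus_template()
    required_cols = {"sample_id", "genotype", "sex", "age_group"}
    if not required_cols <= set(metadata.columns):
        raise MetadataMismatchError(
            f"metadata lacks columns {sorted(required_cols - set(metadata.columns))}"
        )

    if from_cells:
        sample_paths = sorted(input_dir.glob("*.cells.csv"))
        sample_ids = [p.name[: -len(".cells.csv")] for p in sample_paths]
    else:
        sample_paths = sorted(input_dir.glob("*.tif"))
        sample_ids = [p.stem for p in sample_paths]
    if not sample_ids:
        raise els_io.UnreadableInputError(f"no input samples found in {input_dir}")
    known = set(metadata["sample_id"])
    unknown = [s for s in sample_ids if s not in known]
    if unknown:
        raise MetadataMismatchError(f"samples without metadata: {unknown}")

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    log.info("pipeline config sha256=%s", hashlib.sha256(config_json.encode()).hexdigest())

    per_sample: dict[str, list[ELSRecord]] = {}
    landmark_sets: dict[str, dict] = {}
    for sid, path in zip(sample_ids, sample_paths):
        if from_cells:
            cells = els_io.read_cell_table(path)
            lm_path = input_dir / f"{sid}.json"
            if lm_path.exists():
                landmark_sets[sid] = els_io.read_landmarks(input_dir / f"{sid}.tif")
        else:
            image = els_io.read_scene(path)
            for ch in ("B", "T", "Ki67"):
                if ch not in image.channels:
                    raise MissingChannelError(f"sample {sid} lacks channel {ch}")
            cells = detect_sample(image, config)
            landmark_sets[sid] = els_io.read_landmarks(path)
        per_sample[sid] = classify_sample(cells, sid, config)
        log.info("sample %s: %d cells, %d ELS", sid, len(cells), len(per_sample[sid]))

    records = pd.concat(
        [records_to_frame(r) for r in per_sample.values()], ignore_index=True
    )
    summaries = _summaries_frame(per_sample, metadata)
    sizes = records.merge(metadata, on="sample_id", how="left")[
        ["sample_id", "genotype", "sex", "age_group", "els_type", "area_um2"]
    ]

    els_io.write_table(records, out_dir / "els_records.csv")
    els_io.write_table(summaries, out_dir / "mouse_summaries.csv")
    els_io.write_table(sizes, out_dir / "els_sizes.csv")

    # density maps: pool per (genotype, sex, age_group) group by default
    map_meta = {}
    maps = []
    meta_by_sample = metadata.set_index("sample_id")
    grouped: dict[str, list[pd.DataFrame]] = {}
    for sid, recs in per_sample.items():
        lms = landmark_sets.get(sid) or {}
        if len(lms) < 3:
            continue
        frame = records_to_frame(recs)
        reg = register_structures(frame, lms, template)
        row = meta_by_sample.loc[sid]
        key = f"{row.genotype}/{row.sex}/{row.age_group}"
        grouped.setdefault(key, []).append(reg)
    for key in sorted(grouped):
        pooled = pd.concat(grouped[key], ignore_index=True)
        maps.append(
            hexbin_density(
                pooled,
                hex_diameter=config.spatial.hex_diameter,
                circle_scale=config.spatial.circle_scale,
                label=key,
            )
        )
    if maps:
        map_meta = render_density_map(maps, template, str(out_dir / "density_maps.png"))

    stats_report = cohort_statistics(summaries, config)
    size_long, size_med = size_distribution(sizes, by=["genotype", "sex", "age_group"])
    els_io.write_table(size_med, out_dir / "size_medians.csv")
    (out_dir / "stats_report.json").write_text(
        json.dumps(stats_report, indent=2, sort_keys=True, default=float)
    )
    return PipelineResult(
        records=records, summaries=summaries, sizes=size_long,
        stats_report=stats_report, map_meta=map_meta,
    )
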