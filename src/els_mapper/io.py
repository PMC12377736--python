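"""Scene and table I/O.

Scenes are stored as one multi-page TIFF per sample (pages in channel order
B, T, Ki67[, nuclei]) with a JSON sidecar recording pixel size and landmark
positions, plus ground-truth CSVs when simulated.  All tables are UTF-8 CSV
with a header row and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import WholemountImage
from .synthetic import GroundTruth

CHANNEL_ORDER = ("B", "T", "Ki67", "nuclei")
FLOAT_FORMAT = "%.6g"


class UnreadableInputError(OSError):
    """Input file missing or malformed."""


def write_scene(
    out_dir: str | Path,
    image: WholemountImage,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write a sample's TIFF stack, sidecar JSON and (optional) ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = image.sample_id or "sample"
    channels = [c for c in CHANNEL_ORDER if c in image.channels]
    stack = np.stack([image.channels[c] for c in channels])
    tif_path = out_dir / f"{sid}.tif"
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    sidecar = {
        "sample_id": sid,
        "pixel_size_um": image.pixel_size,
        "channels": channels,
        "landmarks_um": {
            k: list(v) for k, v in (ground_truth.landmarks if ground_truth else {}).items()
        },
    }
    (out_dir / f"{sid}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    if ground_truth is not None:
        write_table(ground_truth.cells, out_dir / f"{sid}.cells.csv")
        write_table(ground_truth.structures, out_dir / f"{sid}.structures.csv")
    return tif_path


def read_scene(tif_path: str | Path) -> WholemountImage:
    """Read a sample TIFF + JSON sidecar back into a WholemountImage."""
    tif_path = Path(tif_path)
    sidecar_path = tif_path.with_suffix(".json")
    if not tif_path.exists():
        raise UnreadableInputError(f"missing image file {tif_path}")
    if not sidecar_path.exists():
        raise UnreadableInputError(f"missing sidecar {sidecar_path}")
    try:
        stack = tifffile.imread(tif_path)
        sidecar = json.loads(sidecar_path.read_text())
    except Exception as err:
        raise UnreadableInputError(f"cannot read {tif_path}: {err}") from err
    if stack.ndim == 2:
        stack = stack[None]
    names = sidecar.get("channels", list(CHANNEL_ORDER[: len(stack)]))
    return WholemountImage(
        channels={n: stack[i] for i, n in enumerate(names)},
        pixel_size=float(sidecar["pixel_size_um"]),
        sample_id=sidecar.get("sample_id", tif_path.stem),
    )


def read_landmarks(tif_path: str | Path) -> dict[str, tuple[float, float]]:
    sidecar = json.loads(Path(tif_path).with_suffix(".json").read_text())
    return {k: tuple(v) for k, v in sidecar.get("landmarks_um", {}).items()}


def write_table(df: pd.DataFrame, path: str | Path):
    """Deterministic CSV export (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a phenotyped-cell CSV (x_um, y_um, lineage, ki67[, ...])."""
    path = Path(path)
    if not path.exists():
        raise UnreadableInputError(f"missing cell table {path}")
    df = pd.read_csv(path)
    required = {"x_um", "y_um", "lineage", "ki67"}
    missing = required - set(df.columns)
    if missing:
        raise UnreadableInputError(f"cell table {path} lacks columns {sorted(missing)}")
    df["ki67"] = df["ki67"].astype(bool)
    return df
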