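"""File formats: TIFF/PNG images, GeoJSON ROIs, CSV manifests and cohorts.

All CSV output is UTF-8, comma-separated, with a header row and ``.`` as
the decimal mark, independent of locale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .quantify import ROIPolygon
from .stains import RGBImage

__all__ = [
    "read_image",
    "write_image",
    "read_roi_geojson",
    "write_roi_geojson",
    "read_manifest",
    "MANIFEST_COLUMNS",
    "COHORT_REQUIRED_COLUMNS",
    "read_cohort_csv",
]

MANIFEST_COLUMNS = (
    "sample_id",
    "stained_path",
    "control_path",
    "roi_stained_path",
    "roi_control_path",
)

COHORT_REQUIRED_COLUMNS = (
    "id",
    "physician_call",
    "digital_call",
    "bor_responder",
    "pfs_months",
    "os_months",
    "pfs_event",
    "os_event",
)


def read_image(path: str | Path) -> RGBImage:
    """Read an RGB TIFF or PNG as an :class:`RGBImage`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = np.asarray(Image.open(path).convert("RGB"))
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:
        px = px[..., :3]
    return RGBImage(px)


def write_image(img: RGBImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels, photometric="rgb")
    else:
        Image.fromarray(img.pixels).save(path)


def read_roi_geojson(path: str | Path) -> ROIPolygon:
    """Read a GeoJSON Polygon (pixel coordinates) as an ROI."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    if obj.get("type") != "Polygon":
        raise ValueError(f"{path}: expected a GeoJSON Polygon, got {obj.get('type')!r}")
    ring = obj["coordinates"][0]
    verts = [(float(x), float(y)) for x, y in ring]
    if len(verts) > 1 and verts[0] == verts[-1]:
        verts = verts[:-1]  # GeoJSON rings repeat the first vertex
    return ROIPolygon(verts)


def write_roi_geojson(roi: ROIPolygon, path: str | Path) -> None:
    ring = [[float(x), float(y)] for x, y in roi.vertices]
    ring.append(ring[0])
    obj = {"type": "Polygon", "coordinates": [ring]}
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample manifest CSV.

    Requires the columns in :data:`MANIFEST_COLUMNS` and unique sample
    ids; an optional ``physician_pct`` column is carried through.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise ValueError(f"unreadable manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"manifest {path} has duplicate sample_ids: {dupes}")
    return df


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and schema-check a cohort CSV (one row per patient)."""
    df = pd.read_csv(path)
    for col in COHORT_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file {path} is missing required column: {col!r}")
    return df
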