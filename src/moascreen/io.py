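"""Standard-format adapters: multi-page TIFF sites, CSV tables, JSON.

Site images are stored one TIFF per site with channels (FL stains or BF
z-planes) as pages and the provenance (modality, plate, well, site) in the
ImageDescription tag as JSON.  Tables travel as CSV with schema headers;
floats round-trip at full precision (Python repr).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import SiteImage

PLATEMAP_COLUMNS = ["plate_id", "well", "well_row", "well_col", "compound_id",
                    "moa_label", "biological_rep_index", "technical_rep_index"]


def site_tiff_name(plate_id: str, well: str, site_index: int,
                   modality: str) -> str:
    return f"{plate_id}_{well}_s{site_index}_{modality}.tif"


def write_site_tiff(image: SiteImage, path: str | Path) -> None:
    """Write one site as a multi-page TIFF (one page per channel).

    Integer inputs keep their dtype (16-bit acquisitions round-trip
    exactly); float pixel data is stored as float32.
    """
    pixels = image.pixels
    if not np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float32)
    desc = json.dumps({"modality": image.modality, "plate_id": image.plate_id,
                       "well": image.well, "site_index": image.site_index})
    tifffile.imwrite(path, pixels, description=desc,
                     photometric="minisblack")


def read_site_tiff(path: str | Path) -> SiteImage:
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: missing site metadata tag")
        meta = json.loads(desc.value)
    if pixels.ndim == 2:
        pixels = pixels[None]
    return SiteImage(pixels=pixels.astype(np.float64), modality=meta["modality"],
                     plate_id=meta["plate_id"], well=meta["well"],
                     site_index=int(meta["site_index"]))


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path, required: list[str] | None = None
               ) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    if required:
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return table


def validate_platemap(platemap: pd.DataFrame) -> pd.DataFrame:
    """Schema and uniqueness checks for a plate map table."""
    missing = [c for c in PLATEMAP_COLUMNS if c not in platemap.columns]
    if missing:
        raise ValueError(f"plate map missing column(s) {missing}")
    dup = platemap.duplicated(subset=["plate_id", "well"])
    if dup.any():
        rows = platemap[dup][["plate_id", "well"]].drop_duplicates()
        pairs = [f"{r.plate_id}:{r.well}" for r in rows.itertuples()]
        raise ValueError(f"duplicate well assignment(s): {pairs}")
    if platemap.compound_id.isna().any() or platemap.moa_label.isna().any():
        raise ValueError("plate map has empty compound or MoA entries")
    return platemap


def read_platemap(path: str | Path) -> pd.DataFrame:
    return validate_platemap(read_table(path, required=PLATEMAP_COLUMNS))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
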