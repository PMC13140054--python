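"""File I/O: images, truth sidecars, and deterministic CSV/JSON writing.

Images are 8-bit grayscale PNG or BMP; each synthetic section carries a
JSON sidecar holding the generating spec and the exact ground truth.
All text outputs are written with fixed numeric formatting so repeated runs
with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthdata import Bundle, CrossSectionImage, GroundTruth, SectionSpec

FLOAT_FORMAT = "%.10g"


def save_image(image: CrossSectionImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="L").save(str(path))


def load_image(path: str | Path, pixel_size: float,
               sample_id: str | None = None, slice_index: int = 0) -> CrossSectionImage:
    with Image.open(str(path)) as im:
        px = np.array(im.convert("L"), dtype=np.uint8)  # writable copy
    return CrossSectionImage(px, pixel_size,
                             sample_id=sample_id or Path(path).stem,
                             slice_index=slice_index)


def save_truth(spec: SectionSpec, truth: GroundTruth, path: str | Path) -> None:
    """Write the generating SectionSpec + ground-truth sidecar JSON."""
    payload = {
        "spec": dataclasses.asdict(spec),
        "truth": {
            "center_um": list(truth.center_um),
            "semi_axes_um": list(truth.semi_axes_um),
            "ez_thickness_um": truth.ez_thickness_um,
            "pz_thickness_um": truth.pz_thickness_um,
            "seed": truth.seed,
            "bundles": [
                {"id": b.id, "centroid_um": list(b.centroid_um),
                 "radius_um": b.radius_um, "zone": b.zone}
                for b in truth.bundles
            ],
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_truth(path: str | Path) -> tuple[SectionSpec, GroundTruth]:
    payload = json.loads(Path(path).read_text())
    s = payload["spec"]
    for key in ("image_shape", "stem_center", "semi_axes", "pz_radius_dist",
                "iz_radius_dist", "intensity_levels"):
        s[key] = tuple(s[key])
    spec = SectionSpec(**s)
    t = payload["truth"]
    truth = GroundTruth(
        center_um=tuple(t["center_um"]),
        semi_axes_um=tuple(t["semi_axes_um"]),
        ez_thickness_um=t["ez_thickness_um"],
        pz_thickness_um=t["pz_thickness_um"],
        bundles=tuple(Bundle(b["id"], tuple(b["centroid_um"]),
                             b["radius_um"], b["zone"])
                      for b in t["bundles"]),
        seed=t["seed"],
    )
    return spec, truth


def save_zone_png(labels: np.ndarray, path: str | Path) -> None:
    """Zone label raster as a paletted PNG (background/EZ/PZ/IZ)."""
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    im.putpalette([0, 0, 0,        # background
                   220, 220, 60,   # EZ
                   70, 160, 220,   # PZ
                   180, 90, 160]   # IZ
                  + [0, 0, 0] * 252)
    im.save(str(path))


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """CSV with fixed float formatting and Unix newlines (deterministic)."""
    df.to_csv(str(path), index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
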