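"""Reading and writing of images, fields, permutations and ground truth.

Conventions:

* grayscale images: 8-bit PNG or TIFF (wider integer ranges go to TIFF);
* displacement fields: two-channel 32-bit float TIFF, channel 0 = u_x,
  channel 1 = u_y;
* pixel permutations: two-column plain-text table (fixed_index,
  moving_index), row-major flat indices;
* ground truth: region-label map as 8-bit PNG (A=1, B=2, C=3, D=4) plus a
  JSON sidecar with the shift, region size, and label -> admissible-set
  table.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .scenes import REGION_CODES, AdmissibleTruth, SceneSpec

__all__ = [
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_permutation",
    "write_permutation",
    "read_truth",
    "write_truth",
]


def write_image(path, image) -> None:
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        if image.dtype != np.uint8:
            if image.ndim == 2 and np.issubdtype(image.dtype, np.integer) \
                    and image.min() >= 0 and image.max() <= 255:
                image = image.astype(np.uint8)
            else:
                raise ValueError(
                    f"cannot write dtype {image.dtype} as PNG; use a .tif path"
                )
        iio.imwrite(path, image)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] >= 3 and \
            (img[..., :3] == img[..., :1]).all():
        img = img[..., 0]  # collapse redundant channels of grayscale PNGs
    return img


def write_field(path, field) -> None:
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 3 or field.shape[2] != 2:
        raise ValueError(f"field must have shape (H, W, 2), got {field.shape}")
    # channel-first planes: page 0 = u_x, page 1 = u_y
    tifffile.imwrite(path, np.moveaxis(field, 2, 0))


def read_field(path) -> np.ndarray:
    planes = tifffile.imread(path)
    if planes.ndim != 3 or planes.shape[0] != 2:
        raise ValueError(f"expected a 2-channel field TIFF, got shape {planes.shape}")
    return np.moveaxis(planes, 0, 2).astype(np.float64)


def write_permutation(path, p) -> None:
    p = np.asarray(p)
    table = np.column_stack([np.arange(p.size), p])
    np.savetxt(path, table, fmt="%d", header="fixed_index moving_index")


def read_permutation(path) -> np.ndarray:
    table = np.loadtxt(path, dtype=np.int64, ndmin=2)
    p = np.empty(table.shape[0], dtype=np.intp)
    p[table[:, 0]] = table[:, 1]
    return p


def write_truth(label_png_path, json_path, truth: AdmissibleTruth) -> None:
    write_image(label_png_path, truth.labels.astype(np.uint8))
    meta = {
        "shift": truth.shift,
        "label_codes": REGION_CODES,
        "admissible_sets": {
            lab: [list(u) for u in truth.admissible(lab)] for lab in "ABCD"
        },
        "region_areas": truth.region_areas(),
    }
    if truth.spec is not None:
        meta["scene_spec"] = truth.spec.to_dict()
        meta["region_size"] = [truth.spec.region_width, truth.spec.region_height]
    Path(json_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_truth(label_png_path, json_path) -> AdmissibleTruth:
    labels = np.asarray(read_image(label_png_path), dtype=np.uint8)
    meta = json.loads(Path(json_path).read_text())
    spec = None
    if "scene_spec" in meta:
        spec = SceneSpec.from_dict(meta["scene_spec"])
    return AdmissibleTruth(labels=labels, shift=int(meta["shift"]), spec=spec)
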