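"""Bit-exact image-stack I/O.

One file per frame of little-endian unsigned 32-bit integers, row-major
(slow, fast), plus a JSON sidecar with the raster dimensions and scan
metadata.  A 16-bit TIFF export is provided for viewing.
"""

from __future__ import annotations

import json
import os

import numpy as np


def save_stack(directory, images: np.ndarray, experiment=None, prefix: str = "image") -> str:
    """Write ``images`` (n, slow, fast) as raw <u4 frames plus a sidecar.

    Returns the sidecar path."""
    os.makedirs(directory, exist_ok=True)
    images = np.ascontiguousarray(images)
    n, nslow, nfast = images.shape
    names = []
    for i in range(n):
        name = f"{prefix}_{i:04d}.u32"
        images[i].astype("<u4").tofile(os.path.join(directory, name))
        names.append(name)
    meta = {
        "format": "raw-u32-le",
        "n_images": int(n),
        "image_size": [int(nfast), int(nslow)],
        "frames": names,
    }
    if experiment is not None:
        meta["scan"] = {
            "image_range": list(experiment.scan.image_range),
            "phi_start": experiment.scan.phi_start,
            "oscillation": experiment.scan.oscillation,
        }
        meta["pixel_size"] = list(experiment.detector[0].pixel_size)
    path = os.path.join(directory, f"{prefix}_meta.json")
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_stack(meta_path) -> np.ndarray:
    """Read a stack written by :func:`save_stack`; returns (n, slow, fast) uint32."""
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format") != "raw-u32-le":
        raise ValueError(f"unsupported image format: {meta.get('format')!r}")
    nfast, nslow = meta["image_size"]
    directory = os.path.dirname(os.path.abspath(meta_path))
    frames = []
    for name in meta["frames"]:
        arr = np.fromfile(os.path.join(directory, name), dtype="<u4")
        if arr.size != nfast * nslow:
            raise ValueError(f"frame {name} has {arr.size} pixels, expected {nfast * nslow}")
        frames.append(arr.reshape(nslow, nfast))
    return np.stack(frames)


def export_tiff(path, image: np.ndarray) -> None:
    """Save one frame as 16-bit TIFF (values clipped at 65535)."""
    import tifffile

    tifffile.imwrite(path, np.clip(image, 0, 65535).astype(np.uint16))
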