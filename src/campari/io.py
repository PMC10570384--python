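"""Reading and writing the pipeline's on-disk formats.

Stacks are multi-page TIFFs ordered z-major with the two channels
interleaved per slice (green page, then red page), with acquisition
metadata in a JSON sidecar next to the file. Label masks are
integer-label TIFFs; tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import ImageStack

__all__ = ["write_stack", "read_stack", "write_labels", "read_labels"]

CHANNEL_ORDER = ("green", "red")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a two-channel stack as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    pages = np.empty((stack.n_slices * 2,) + stack.green.shape[1:], dtype=np.float32)
    pages[0::2] = stack.green
    pages[1::2] = stack.red
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "channel_order": list(CHANNEL_ORDER),
        "page_layout": "z-major, channels interleaved per slice",
        "n_slices": stack.n_slices,
        "z_step_um": stack.z_step_um,
        "pixel_size_um": stack.pixel_size_um,
        "phase": stack.phase,
        "hemisphere": stack.hemisphere,
        "dose": stack.dose,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path) -> ImageStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pages = tifffile.imread(path)
    return ImageStack(
        green=np.asarray(pages[0::2], dtype=np.float64),
        red=np.asarray(pages[1::2], dtype=np.float64),
        z_step_um=meta["z_step_um"],
        pixel_size_um=meta["pixel_size_um"],
        phase=meta["phase"],
        hemisphere=meta.get("hemisphere", "both"),
        dose=meta.get("dose", 0.0),
    )


def write_labels(labels: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32), photometric="minisblack")
    return path


def read_labels(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))
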