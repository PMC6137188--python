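"""TIFF image stacks, CSV tables, and JSON-lines run logs."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import UnsupportedFormatError
from .imaging import SyntheticScene

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "scene_to_uint16",
    "RunLog",
]

_CHANNEL_ORDER = ("membrane", "scars", "gfp")


def scene_to_uint16(scene: SyntheticScene, scale: float = 64.0) -> np.ndarray:
    """Quantise a rendered scene to a uint16 page stack (clipped at 65535)."""
    stack = scene.channel_stack(_CHANNEL_ORDER)
    return np.clip(stack * scale, 0, 65535).astype(np.uint16)


def write_image_stack(
    path: str | Path,
    channels: dict[str, np.ndarray] | np.ndarray,
    channel_names: list[str] | None = None,
) -> None:
    """Write a multi-page grayscale TIFF, one page per channel.

    Accepts a mapping of name -> 2-D uint8/uint16 array or a 3-D stack
    with ``channel_names``.  Channel names are stored in the image
    description so a round trip restores them.
    """
    if isinstance(channels, dict):
        names = list(channels)
        stack = np.stack([channels[n] for n in names])
    else:
        stack = np.asarray(channels)
        if stack.ndim == 2:
            stack = stack[None]
        names = channel_names or [f"channel_{i}" for i in range(len(stack))]
    if stack.dtype not in (np.uint8, np.uint16):
        raise UnsupportedFormatError(
            "only 8- or 16-bit grayscale stacks are written; quantise first"
        )
    tifffile.imwrite(
        str(path), stack, description=json.dumps({"channels": names}), photometric="minisblack"
    )


def read_image_stack(path: str | Path) -> dict[str, np.ndarray]:
    """Read a multi-page grayscale TIFF back into named channel arrays.

    Raises on missing files and on RGB or float TIFFs (no declared
    convention for those).  Pages are returned in file order; names come
    from the stored metadata when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        if tif.pages[0].samplesperpixel != 1:
            raise UnsupportedFormatError(
                "RGB/multi-sample TIFF has no declared channel convention"
            )
        stack = tif.asarray()
        desc = tif.pages[0].description or ""
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise UnsupportedFormatError("expected a stack of single-channel pages")
    if stack.dtype not in (np.uint8, np.uint16):
        raise UnsupportedFormatError(
            f"unsupported TIFF sample format {stack.dtype}; need 8/16-bit grayscale"
        )
    names = None
    try:
        names = json.loads(desc).get("channels")
    except (json.JSONDecodeError, AttributeError):
        pass
    if not names or len(names) != len(stack):
        names = [f"channel_{i}" for i in range(len(stack))]
    return {name: stack[i] for i, name in enumerate(names)}


class RunLog:
    """JSON-lines structured log: parameters, seeds, and stage counts."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.events: list[dict] = []

    def log(self, stage: str, **fields) -> dict:
        event = {"t": time.time(), "stage": stage, **fields}
        self.events.append(event)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(event, default=str) + "\n")
        return event

    def counts(self, stage: str, n_in: int, n_out: int, **fields) -> dict:
        return self.log(stage, n_in=int(n_in), n_out=int(n_out), **fields)
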