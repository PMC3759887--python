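"""Image containers and multi-page TIFF input/output.

A field is stored on disk as a plane-major multi-page TIFF: pages run
[plane 0: DAPI, gH2AX, pericentrin, plane 1: DAPI, ...]. Spatial metadata
(pixel size, z-step, field id) travels in the TIFF ImageDescription as
JSON so a round trip through disk is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

CHANNELS = ("DAPI", "gH2AX", "pericentrin")
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


@dataclass
class ZStackField:
    """One captured field: 3 channels x z-planes of pixel data.

    ``pixels`` has shape (3, z_planes, height, width), non-negative
    integer dtype, channel order DAPI / gH2AX (Cy3) / pericentrin (FITC).
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    field_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 4 or px.shape[0] != len(CHANNELS):
            raise ValueError(
                f"pixels must have shape (3, z, h, w), got {px.shape}"
            )
        if px.shape[1] < 1:
            raise ValueError("at least one z-plane required")
        self.pixels = px

    @property
    def z_planes(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, h, w) stack for a named channel."""
        if name not in CHANNEL_INDEX:
            raise ValueError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return self.pixels[CHANNEL_INDEX[name]]

    def max_projection(self, name: str) -> np.ndarray:
        """Maximum-intensity projection of a channel over z."""
        return self.channel(name).max(axis=0)


def write_field_tiff(field: ZStackField, path: str | Path) -> Path:
    """Write a field as a plane-major multi-page TIFF with JSON metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    z = field.z_planes
    # (3, z, h, w) -> (z, 3, h, w) page order: plane-major, channels inner
    pages = np.transpose(field.pixels, (1, 0, 2, 3))
    meta = {
        "pixel_size_um": field.pixel_size_um,
        "z_step_um": field.z_step_um,
        "field_id": field.field_id,
        "channels": list(CHANNELS),
        "z_planes": z,
    }
    tifffile.imwrite(
        path,
        pages.reshape(z * len(CHANNELS), *field.pixels.shape[2:]),
        description=json.dumps(meta, sort_keys=True),
        photometric="minisblack",
    )
    return path


def read_field_tiff(path: str | Path, *, channel_order: tuple[str, ...] = CHANNELS,
                    pixel_size_um: float | None = None,
                    z_step_um: float | None = None) -> ZStackField:
    """Read a plane-major 3-channel stack written by :func:`write_field_tiff`.

    ``channel_order`` maps the on-disk within-plane page order to the
    canonical DAPI/gH2AX/pericentrin order, for stacks from other sources.
    Metadata arguments override (or supply, if absent) the JSON sidecar.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    n_ch = len(CHANNELS)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.shape[0] % n_ch:
        raise ValueError(
            f"{path.name}: expected pages divisible into {n_ch} channels, got shape {data.shape}"
        )
    z = data.shape[0] // n_ch
    stack = data.reshape(z, n_ch, *data.shape[1:]).transpose(1, 0, 2, 3)
    if tuple(channel_order) != CHANNELS:
        if sorted(channel_order) != sorted(CHANNELS):
            raise ValueError(f"channel_order must be a permutation of {CHANNELS}")
        perm = [list(channel_order).index(c) for c in CHANNELS]
        stack = stack[perm]
    return ZStackField(
        pixels=stack,
        pixel_size_um=pixel_size_um or float(meta.get("pixel_size_um", 1.0)),
        z_step_um=z_step_um or float(meta.get("z_step_um", 1.0)),
        field_id=str(meta.get("field_id", path.stem)),
    )
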