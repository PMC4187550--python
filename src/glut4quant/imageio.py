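"""Calibrated multi-channel image I/O.

Images are stored as multi-page TIFF (one page per channel) next to a JSON
sidecar that records the channel roles in page order, the pixel size in
μm/pixel and the image id.  Arrays round-trip bit-exactly for integer dtypes.

Coordinate convention used throughout the package: origin at the top-left
pixel, x rightward (columns), y downward (rows), 0-based indices, a pixel's
position is its centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError, ChannelRoleError, FormatError

CHANNEL_ROLES = ("glut4", "dystrophin", "mhc1", "dapi", "dhpr")
MANDATORY_ROLES = ("glut4", "dystrophin")


@dataclass
class CalibratedImage:
    """A pixel-size calibrated multi-channel 2D fluorescence image.

    Parameters
    ----------
    channels
        Mapping from channel role (``glut4``, ``dystrophin``, ``mhc1``,
        ``dapi``, ``dhpr``) to a 2D intensity array.  ``glut4`` and
        ``dystrophin`` are mandatory; all channels must share one shape.
    pixel_size
        Lateral calibration in μm/pixel (> 0).
    image_id
        Stable identifier used in manifests and output tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    image_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size is None or not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise CalibrationError(f"pixel_size must be positive, got {self.pixel_size!r}")
        for role in MANDATORY_ROLES:
            if role not in self.channels:
                raise ChannelRoleError(f"mandatory channel role {role!r} missing")
        shapes = {role: np.asarray(arr).shape for role, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        for role, shp in shapes.items():
            if len(shp) != 2:
                raise FormatError(f"channel {role!r} is not 2D (shape {shp})")
            if shp != first:
                raise FormatError(f"channel shapes differ: {shapes}")
        self.channels = {role: np.asarray(arr) for role, arr in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise ChannelRoleError(f"channel role {role!r} not present")
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(path, image: CalibratedImage) -> Path:
    """Write a multi-page TIFF plus JSON sidecar; returns the sidecar path."""
    path = Path(path)
    order = [r for r in CHANNEL_ROLES if r in image.channels]
    order += [r for r in image.channels if r not in order]
    pages = np.stack([image.channels[r] for r in order])
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "image_id": image.image_id or path.stem,
        "pixel_size_um": float(image.pixel_size),
        "channels": order,
    }
    if image.meta:
        sidecar["meta"] = image.meta
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=1))
    return sc_path


def read_image(path, sidecar=None) -> CalibratedImage:
    """Read a multi-page TIFF with its JSON sidecar.

    Raises :class:`CalibrationError` if the sidecar lacks a pixel size,
    :class:`FormatError` if pages differ in shape, :class:`ChannelRoleError`
    if a mandatory role is absent.
    """
    path = Path(path)
    sc_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sc_path.exists():
        raise CalibrationError(f"sidecar not found: {sc_path}")
    sc = json.loads(sc_path.read_text())
    if "pixel_size_um" not in sc:
        raise CalibrationError(f"sidecar {sc_path} lacks pixel_size_um")
    roles = sc.get("channels")
    if not roles:
        raise ChannelRoleError(f"sidecar {sc_path} lacks channel roles")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != len(roles):
        raise FormatError(
            f"{path}: {pages.shape[0]} pages but {len(roles)} declared roles"
        )
    channels = {role: pages[i] for i, role in enumerate(roles)}
    return CalibratedImage(
        channels=channels,
        pixel_size=sc["pixel_size_um"],
        image_id=sc.get("image_id", path.stem),
        meta=sc.get("meta", {}),
    )
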