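"""Calibrated multichannel image container and TIFF round-trip.

Images are multi-page TIFFs (one page per channel/plane) with the pixel
size stored both in the TIFF resolution tags and in a JSON sidecar that
also carries channel names/roles, axis order and frame times.  The sidecar
is authoritative for non-spatial metadata; the two pixel-size records must
agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "CalibrationError", "read_image", "write_image"]

_ALLOWED_AXES = ("cyx", "ctyx", "czyx")


class CalibrationError(ValueError):
    """Missing or inconsistent pixel-size calibration."""


@dataclass
class ImageStack:
    """Pixel data with spatial calibration and channel roles.

    ``axes`` is one of ``cyx`` (single frame), ``ctyx`` (time-lapse) or
    ``czyx`` (z-stack); axis 0 always indexes channels, in the order of
    ``channel_names``.  ``roles`` maps a channel name to its function:
    ``nuclear``, ``membrane`` (sender/membrane marker) or ``signal``.
    """

    data: np.ndarray
    um_per_px: float
    channel_names: list[str]
    axes: str = "cyx"
    roles: dict[str, str] = field(default_factory=dict)
    t_hours: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise CalibrationError(f"um_per_px must be > 0, got {self.um_per_px}")
        if self.axes not in _ALLOWED_AXES:
            raise ValueError(f"axes must be one of {_ALLOWED_AXES}")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} axes but axes string is {self.axes!r}"
            )
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names must match data.shape[0]")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def channel_by_role(self, role: str) -> np.ndarray:
        for name, r in self.roles.items():
            if r == role:
                return self.channel(name)
        raise KeyError(f"no channel with role {role!r}")

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = stack.data.reshape(-1, *stack.shape_yx)
    px_per_cm = 1e4 / stack.um_per_px
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    meta = {
        "um_per_px": stack.um_per_px,
        "axes": stack.axes,
        "shape": list(stack.data.shape),
        "channel_names": stack.channel_names,
        "roles": stack.roles,
        "t_hours": None if stack.t_hours is None else list(map(float, stack.t_hours)),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path, um_per_px: float | None = None) -> ImageStack:
    """Read a TIFF written by :func:`write_image` (or any calibrated TIFF).

    Calibration resolution order: explicit ``um_per_px`` override, else
    sidecar + TIFF tags (which must agree to 1e-6 relative), else TIFF tags
    alone, else sidecar alone; with none, raises :class:`CalibrationError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        tag_um = _um_per_px_from_tags(tif)

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None

    side_um = meta.get("um_per_px") if meta else None
    if um_per_px is not None:
        resolved = um_per_px
    elif side_um is not None and tag_um is not None:
        if abs(side_um - tag_um) > 1e-6 * max(abs(side_um), abs(tag_um)):
            raise CalibrationError(
                f"pixel size conflict: TIFF tags say {tag_um!r} um/px but "
                f"sidecar says {side_um!r} um/px"
            )
        resolved = side_um
    elif tag_um is not None:
        resolved = tag_um
    elif side_um is not None:
        resolved = side_um
    else:
        raise CalibrationError(
            f"{path} carries no pixel-size calibration; pass um_per_px "
            "explicitly to override"
        )

    if meta:
        data = pages.reshape(meta["shape"])
        return ImageStack(
            data=data,
            um_per_px=resolved,
            channel_names=list(meta["channel_names"]),
            axes=meta["axes"],
            roles=dict(meta.get("roles", {})),
            t_hours=None
            if meta.get("t_hours") is None
            else np.asarray(meta["t_hours"], float),
        )
    if pages.ndim == 2:
        pages = pages[None]
    return ImageStack(
        data=pages,
        um_per_px=resolved,
        channel_names=[f"ch{i}" for i in range(pages.shape[0])],
        axes="cyx",
    )


def _um_per_px_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if xres is None or unit is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    px_per_unit = num / den
    unit_val = getattr(unit.value, "value", unit.value)
    if unit_val == 3:  # centimeter
        return 1e4 / px_per_unit
    if unit_val == 2:  # inch
        return 25400.0 / px_per_unit
    return None
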