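"""Synthetic microscopy renderer: turns simulated states or parametric
profiles into calibrated multichannel images with known ground truth.

Emulates the two experimental geometries: circular micropatterned colonies
(700 um diameter) with radially organized expression, and sender/receiver
juxtaposition cultures with a straight border, a receiver-side exponential
gradient for diffusible species and a one-cell-tier band for juxtacrine
ones.  Every render is deterministic given its seed and returns the
generating truth alongside the image, so the quantification pipeline can
be validated by recovery tests instead of real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .imageio import ImageStack
from .lattice import Lattice, _hex_grid

__all__ = [
    "RenderParams",
    "GroundTruth",
    "render_colony_image",
    "render_colony_timelapse",
    "render_juxtaposition_image",
    "scatter_nuclei",
    "save_ground_truth",
]

ProfileFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class RenderParams:
    """Camera/optics model for synthetic images.

    Defaults approximate a low-magnification epifluorescence acquisition:
    2 um pixels, dim uniform background, Poisson shot noise plus Gaussian
    read noise when enabled.  ``psf_sigma_um = 0`` disables blurring so
    geometric tests can assert exact pixel values.
    """

    shape_px: tuple[int, int] = (400, 400)   # (ny, nx)
    um_per_px: float = 2.0
    background: float = 10.0
    gain: float = 100.0                      # signal channels: counts per unit profile
    nucleus_radius_um: float = 4.0
    nucleus_gain: float = 150.0
    cell_spacing_um: float = 10.0            # nucleus packing distance
    nucleus_jitter_um: float = 0.0
    psf_sigma_um: float = 0.0
    poisson_noise: bool = False
    read_noise_sd: float = 0.0
    hot_pixel_rate: float = 0.0
    hot_pixel_value: float = 5000.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.shape_px[0] * self.um_per_px,
                self.shape_px[1] * self.um_per_px)


@dataclass
class GroundTruth:
    """Generator-side record of what a synthetic image actually contains."""

    seed: int
    um_per_px: float
    center_um: tuple[float, float] | None = None      # colony center
    radius_um: float | None = None                    # colony radius
    border_x_um: float | None = None                  # juxtaposition border
    profiles: dict[str, ProfileFn] = field(default_factory=dict)
    decay_length_um: dict[str, float] = field(default_factory=dict)
    nucleus_centers_um: np.ndarray | None = None
    nucleus_radius_um: float | None = None
    cell_states: pd.DataFrame | None = None           # per-cell simulator truth


def _pixel_coords_um(params: RenderParams) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in um; x along axis 1, y along axis 0."""
    ny, nx = params.shape_px
    y = (np.arange(ny) + 0.5) * params.um_per_px
    x = (np.arange(nx) + 0.5) * params.um_per_px
    return np.meshgrid(y, x, indexing="ij")


def _paint_nuclei(
    canvas: np.ndarray, centers_um: np.ndarray, radius_um: float,
    gain: float, um_per_px: float,
) -> None:
    """Anti-aliased disks, combined by max so touching nuclei don't sum."""
    r_px = radius_um / um_per_px
    pad = int(np.ceil(r_px)) + 1
    ny, nx = canvas.shape
    for cy, cx in centers_um[:, ::-1]:  # centers stored (x, y)
        py, px = cy / um_per_px - 0.5, cx / um_per_px - 0.5
        y0, y1 = max(0, int(py) - pad), min(ny, int(py) + pad + 1)
        x0, x1 = max(0, int(px) - pad), min(nx, int(px) + pad + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
        d = np.hypot(yy - py, xx - px)
        cover = np.clip(r_px - d + 0.5, 0.0, 1.0)
        np.maximum(canvas[y0:y1, x0:x1], gain * cover, out=canvas[y0:y1, x0:x1])


def _apply_noise(
    data: np.ndarray, params: RenderParams, rng: np.random.Generator
) -> np.ndarray:
    out = data
    if params.psf_sigma_um > 0:
        sig = params.psf_sigma_um / params.um_per_px
        out = np.stack([gaussian_filter(ch, sig, mode="nearest") for ch in out])
    if params.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, out.shape)
    if params.hot_pixel_rate > 0:
        hot = rng.random(out.shape) < params.hot_pixel_rate
        out = np.where(hot, params.hot_pixel_value, out)
    return out


def scatter_nuclei(
    n: int,
    extent_um: tuple[float, float],
    min_dist_um: float,
    rng: np.random.Generator,
    margin_um: float = 10.0,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Random non-overlapping nucleus centers (x, y) by dart throwing."""
    placed: list[tuple[float, float]] = []
    ey, ex = extent_um
    for _ in range(max_tries):
        if len(placed) == n:
            break
        x = rng.uniform(margin_um, ex - margin_um)
        y = rng.uniform(margin_um, ey - margin_um)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_dist_um**2 for px, py in placed):
            placed.append((x, y))
    if len(placed) < n:
        raise RuntimeError(f"could only place {len(placed)}/{n} nuclei")
    return np.array(placed)


def _colony_nuclei(
    params: RenderParams, center_um: tuple[float, float], radius_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    d = params.cell_spacing_um
    n_side = int(np.ceil(2 * radius_um / d)) + 3
    pts = _hex_grid(d, n_side, n_side)
    pts -= pts.mean(axis=0)
    if params.nucleus_jitter_um > 0:
        pts = pts + rng.normal(0.0, params.nucleus_jitter_um, pts.shape)
    pts = pts + np.asarray(center_um)
    r = np.hypot(*(pts - np.asarray(center_um)).T)
    return pts[r <= radius_um - d / 2.0]


def render_colony_image(
    state_or_profile,
    render_params: RenderParams = RenderParams(),
    seed: int = 0,
    colony_radius_um: float = 350.0,
    channel_names: list[str] | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render one circular colony frame.

    ``state_or_profile`` is either a mapping {channel: profile(r_um)} of
    radial generating profiles (callables, vectorized over radius), or a
    tuple ``(lattice, {channel: per_cell_values})`` from a relay run, in
    which case each in-colony pixel takes the value of its nearest cell.
    The nuclear channel ("dapi") is always rendered first.
    """
    p = render_params
    rng = np.random.default_rng(seed)
    ey, ex = p.extent_um
    center = (ex / 2.0, ey / 2.0)  # (x, y)
    yy, xx = _pixel_coords_um(p)
    r = np.hypot(xx - center[0], yy - center[1])
    inside = r <= colony_radius_um

    if isinstance(state_or_profile, tuple):
        lattice, cell_values = state_or_profile
        if not isinstance(lattice, Lattice):
            raise TypeError("state tuple must be (Lattice, {channel: values})")
        centers = lattice.positions_um - lattice.positions_um.mean(axis=0) \
            + np.asarray(center)
        tree = cKDTree(centers)
        _, nearest = tree.query(np.column_stack([xx[inside], yy[inside]]))
        sig_channels = {}
        for name, vals in cell_values.items():
            img = np.full(p.shape_px, p.background, float)
            img[inside] += p.gain * np.asarray(vals, float)[nearest]
            sig_channels[name] = img
        profiles: dict[str, ProfileFn] = {}
        nuclei = centers
        states = pd.DataFrame(
            {"x_um": centers[:, 0], "y_um": centers[:, 1],
             **{k: np.asarray(v, float) for k, v in cell_values.items()}}
        )
    else:
        if callable(state_or_profile):
            state_or_profile = {"signal": state_or_profile}
        sig_channels = {}
        for name, fn in state_or_profile.items():
            img = np.full(p.shape_px, p.background, float)
            img[inside] += p.gain * np.asarray(fn(r[inside]), float)
            sig_channels[name] = img
        profiles = dict(state_or_profile)
        nuclei = _colony_nuclei(p, center, colony_radius_um, rng)
        states = None

    dapi = np.full(p.shape_px, p.background, float)
    _paint_nuclei(dapi, nuclei, p.nucleus_radius_um, p.nucleus_gain, p.um_per_px)

    names = ["dapi"] + (channel_names or list(sig_channels))
    data = np.stack([dapi] + [sig_channels[n] for n in names[1:]])
    data = _apply_noise(data, p, rng)

    stack = ImageStack(
        data=data,
        um_per_px=p.um_per_px,
        channel_names=names,
        axes="cyx",
        roles={"dapi": "nuclear", **{n: "signal" for n in names[1:]}},
    )
    truth = GroundTruth(
        seed=seed,
        um_per_px=p.um_per_px,
        center_um=center,
        radius_um=colony_radius_um,
        profiles=profiles,
        nucleus_centers_um=nuclei,
        nucleus_radius_um=p.nucleus_radius_um,
        cell_states=states,
    )
    return stack, truth


def render_colony_timelapse(
    profile_fn_t: Callable[[float, np.ndarray], np.ndarray],
    times_h: np.ndarray,
    render_params: RenderParams = RenderParams(),
    seed: int = 0,
    colony_radius_um: float = 350.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a colony time-lapse from a profile ``f(t_h, r_um)``."""
    frames = []
    truth = None
    for k, t in enumerate(times_h):
        stack, gt = render_colony_image(
            {"signal": lambda r, t=t: profile_fn_t(t, r)},
            render_params, seed=seed + k, colony_radius_um=colony_radius_um,
        )
        frames.append(stack.data)
        truth = gt
    data = np.stack(frames, axis=1)  # (c, t, y, x)
    stack = ImageStack(
        data=data,
        um_per_px=render_params.um_per_px,
        channel_names=["dapi", "signal"],
        axes="ctyx",
        roles={"dapi": "nuclear", "signal": "signal"},
        t_hours=np.asarray(times_h, float),
    )
    return stack, truth


def render_juxtaposition_image(
    profile_spec: dict,
    render_params: RenderParams = RenderParams(),
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a sender/receiver juxtaposition frame.

    ``profile_spec``::

        {"border_x_um": 300.0,          # senders occupy x < border
         "marker_gain": 120.0,          # membrane marker level in senders
         "channels": {
             "lefty": {"kind": "exp", "a": 100, "lambda_um": 60, "c": 10,
                       "sender_value": 110},
             "nodal": {"kind": "band", "width_um": 10, "amplitude": 80,
                       "c": 5, "sender_value": 90}}}

    Receiver-side intensity is ``a*exp(-d/lambda) + c`` (exponential) or
    ``amplitude + c`` for ``d <= width_um`` else ``c`` (one-tier band),
    with d the distance from the border along x.  Channel values are
    absolute counts (the gain is part of a/amplitude), so the defining
    relation I(lambda) = c + a/e holds exactly at zero noise.
    """
    p = render_params
    rng = np.random.default_rng(seed)
    yy, xx = _pixel_coords_um(p)
    border = float(profile_spec["border_x_um"])
    ey, ex = p.extent_um
    if not (0 < border < ex):
        raise ValueError("border_x_um must lie inside the frame")
    sender = xx < border
    d = np.maximum(0.0, xx - border)

    marker = np.full(p.shape_px, p.background, float)
    marker[sender] += float(profile_spec.get("marker_gain", 120.0))

    sig_channels: dict[str, np.ndarray] = {}
    profiles: dict[str, ProfileFn] = {}
    decay: dict[str, float] = {}
    for name, spec in profile_spec.get("channels", {}).items():
        img = np.empty(p.shape_px, float)
        c = float(spec.get("c", 0.0))
        if spec["kind"] == "exp":
            a, lam = float(spec["a"]), float(spec["lambda_um"])
            img[:] = a * np.exp(-d / lam) + c
            profiles[name] = lambda dd, a=a, lam=lam, c=c: a * np.exp(-dd / lam) + c
            decay[name] = lam
        elif spec["kind"] == "band":
            w, amp = float(spec["width_um"]), float(spec["amplitude"])
            img[:] = np.where(d <= w, amp + c, c)
            profiles[name] = lambda dd, w=w, amp=amp, c=c: np.where(
                dd <= w, amp + c, c)
        else:
            raise ValueError(f"unknown channel kind {spec['kind']!r}")
        img[sender] = float(spec.get("sender_value", c))
        sig_channels[name] = img

    nuclei = _hex_grid(p.cell_spacing_um,
                       int(ex / p.cell_spacing_um),
                       int(ey / (p.cell_spacing_um * np.sqrt(3) / 2)))
    if p.nucleus_jitter_um > 0:
        nuclei = nuclei + rng.normal(0.0, p.nucleus_jitter_um, nuclei.shape)
    keep = (nuclei[:, 0] > 2) & (nuclei[:, 0] < ex - 2) \
        & (nuclei[:, 1] > 2) & (nuclei[:, 1] < ey - 2)
    nuclei = nuclei[keep]
    dapi = np.full(p.shape_px, p.background, float)
    _paint_nuclei(dapi, nuclei, p.nucleus_radius_um, p.nucleus_gain, p.um_per_px)

    names = ["dapi", "marker"] + list(sig_channels)
    data = np.stack([dapi, marker] + list(sig_channels.values()))
    data = _apply_noise(data, p, rng)

    stack = ImageStack(
        data=data,
        um_per_px=p.um_per_px,
        channel_names=names,
        axes="cyx",
        roles={"dapi": "nuclear", "marker": "membrane",
               **{n: "signal" for n in sig_channels}},
    )
    truth = GroundTruth(
        seed=seed,
        um_per_px=p.um_per_px,
        border_x_um=border,
        profiles=profiles,
        decay_length_um=decay,
        nucleus_centers_um=nuclei,
        nucleus_radius_um=p.nucleus_radius_um,
    )
    return stack, truth


def save_ground_truth(truth: GroundTruth, path: str | Path,
                      sample_step_um: float = 1.0,
                      max_distance_um: float = 500.0) -> Path:
    """JSON sidecar (+ per-cell CSV if present); profiles sampled on a grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dd = np.arange(0.0, max_distance_um, sample_step_um)
    meta = {
        "seed": truth.seed,
        "um_per_px": truth.um_per_px,
        "center_um": truth.center_um,
        "radius_um": truth.radius_um,
        "border_x_um": truth.border_x_um,
        "decay_length_um": truth.decay_length_um,
        "nucleus_radius_um": truth.nucleus_radius_um,
        "n_nuclei": None if truth.nucleus_centers_um is None
        else int(len(truth.nucleus_centers_um)),
        "profiles": {
            name: {"distance_um": dd.tolist(),
                   "value": np.asarray(fn(dd), float).tolist()}
            for name, fn in truth.profiles.items()
        },
    }
    path.write_text(json.dumps(meta))
    if truth.cell_states is not None:
        truth.cell_states.to_csv(path.with_suffix(".cells.csv"), index=False)
    return path
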