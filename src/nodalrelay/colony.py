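"""Colony-level quantification: detection, angular-averaged radial
profiles, cross-colony ensembles, kymographs and apical-basal z-profiles.

The central readout of the micropattern experiments is the mean intensity
of a channel as a function of radial distance from the colony center,
averaged over the angular coordinate in 10 um bins; per-condition curves
are means +/- SEM across colonies.  Kymographs stack the per-frame radial
profile of a time-lapse row by row, optionally averaged over pie segments
and colonies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = [
    "ColonyGeometry",
    "ColonyRejection",
    "RadialProfile",
    "ProfileEnsemble",
    "Kymograph",
    "detect_colony",
    "radial_profile",
    "ensemble_profile",
    "build_kymograph",
    "z_axis_profile",
]


class ColonyRejection(ValueError):
    """Colony failed detection QC; carries a reason code."""

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(f"[{reason}] {message}")


@dataclass
class ColonyGeometry:
    """Detected colony: center and radius in um plus the pixel mask."""

    center_um: tuple[float, float]   # (x, y)
    radius_um: float
    mask: np.ndarray
    um_per_px: float


@dataclass
class RadialProfile:
    """Angularly averaged intensity vs. distance from the colony center.

    Bins are half-open [k*w, (k+1)*w) in um. ``mean`` is NaN where
    ``count`` is 0.  The conservation identity sum(mean*count) ==
    sum(binned pixel intensities) holds by construction.
    """

    bin_edges_um: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    channel: str = "signal"
    colony_id: str = "colony"
    t_h: float = 0.0

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "colony_id": self.colony_id,
            "channel": self.channel,
            "t_h": self.t_h,
            "bin_lo_um": self.bin_edges_um[:-1],
            "bin_hi_um": self.bin_edges_um[1:],
            "mean": self.mean,
            "count": self.count,
        })


@dataclass
class ProfileEnsemble:
    """Across-colony mean and SEM per radial bin."""

    bin_centers_um: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    channel: str = "signal"
    normalization: str = "none"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.channel,
            "bin_center_um": self.bin_centers_um,
            "mean": self.mean,
            "sem": self.sem,
            "n": self.n,
        })


@dataclass
class Kymograph:
    """time x radial-bin mean-intensity matrix."""

    times_h: np.ndarray
    bin_edges_um: np.ndarray
    values: np.ndarray               # (n_times, n_bins)
    n_segments: int = 1
    counts: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])
        t, r = np.meshgrid(self.times_h, centers, indexing="ij")
        return pd.DataFrame({
            "t_h": t.ravel(), "bin_center_um": r.ravel(),
            "mean": self.values.ravel(),
        })


def detect_colony(
    nuclear_channel: np.ndarray,
    um_per_px: float,
    expected_diameter_um: float = 700.0,
    radius_tolerance: float = 0.20,
) -> ColonyGeometry:
    """Locate a filled circular colony in the nuclear channel.

    Otsu threshold, morphological closing and hole filling, largest
    component; the center is the intensity-weighted centroid and the
    radius comes from the component area (r = sqrt(A/pi)).  Colonies whose
    radius deviates from expectation by more than ``radius_tolerance``
    (default 20%) are rejected — the half-filled or merged patterns the
    experimental workflow would discard by eye.
    """
    img = np.asarray(nuclear_channel, float)
    if img.max() == img.min():
        raise ColonyRejection("no_component", "blank nuclear channel")
    mask = img > filters.threshold_otsu(img)
    close_px = max(3, int(10.0 / um_per_px))
    mask = morphology.closing(mask, morphology.disk(close_px))
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ColonyRejection("no_component", "nothing above threshold")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest

    area_px = mask.sum()
    radius_um = np.sqrt(area_px / np.pi) * um_per_px
    expected_r = expected_diameter_um / 2.0
    if abs(radius_um - expected_r) > radius_tolerance * expected_r:
        raise ColonyRejection(
            "radius_out_of_tolerance",
            f"radius {radius_um:.1f} um vs expected {expected_r:.1f} um "
            f"(+/-{radius_tolerance:.0%})",
        )

    weights = np.where(mask, img, 0.0)
    total = weights.sum()
    yy, xx = np.indices(img.shape)
    cy = (weights * yy).sum() / total
    cx = (weights * xx).sum() / total
    center_um = ((cx + 0.5) * um_per_px, (cy + 0.5) * um_per_px)
    return ColonyGeometry(center_um, float(radius_um), mask, um_per_px)


def radial_profile(
    channel: np.ndarray,
    geometry: ColonyGeometry,
    bin_width_um: float = 10.0,
    channel_name: str = "signal",
    colony_id: str = "colony",
    t_h: float = 0.0,
) -> RadialProfile:
    """Mean intensity per radial bin over the angular coordinate.

    Every pixel center inside the colony mask is assigned to the half-open
    bin containing its distance from the colony center; the per-bin value
    is the arithmetic mean.  Bins span [0, max radius in mask].
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    if bin_width_um <= geometry.um_per_px:
        raise ValueError("bin width must exceed the pixel size")
    img = np.asarray(channel, float)
    if img.shape != geometry.mask.shape:
        raise ValueError("channel and colony mask shapes differ")

    yy, xx = np.indices(img.shape)
    cx_px = geometry.center_um[0] / geometry.um_per_px - 0.5
    cy_px = geometry.center_um[1] / geometry.um_per_px - 0.5
    r_um = np.hypot(xx - cx_px, yy - cy_px) * geometry.um_per_px

    r_in = r_um[geometry.mask]
    v_in = img[geometry.mask]
    n_bins = int(np.floor(r_in.max() / bin_width_um)) + 1
    edges = bin_width_um * np.arange(n_bins + 1)
    idx = np.floor(r_in / bin_width_um).astype(int)
    count = np.bincount(idx, minlength=n_bins).astype(float)
    total = np.bincount(idx, weights=v_in, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return RadialProfile(edges, mean, count, channel_name, colony_id, t_h)


def ensemble_profile(
    profiles: list[RadialProfile],
    normalization: str = "none",
) -> ProfileEnsemble:
    """Across-colony mean and SEM per bin.

    ``normalization``: ``none``, or ``max`` (divide each colony's profile
    by its own maximum bin before averaging — the convention used for
    "normalized mean intensity" plots).  SEM uses the n-1 sample SD over
    colonies divided by sqrt(n); with a single colony the SEM is NaN and a
    warning is issued.
    """
    if not profiles:
        raise ValueError("no profiles to ensemble")
    edges0 = profiles[0].bin_edges_um
    n_common = min(len(p.mean) for p in profiles)
    for p in profiles:
        if p.channel != profiles[0].channel:
            raise ValueError("profiles mix channels")
        if not np.allclose(p.bin_edges_um[: n_common + 1],
                           edges0[: n_common + 1]):
            raise ValueError("profiles have mismatched bin edges")

    rows = []
    for p in profiles:
        vals = p.mean[:n_common].astype(float)
        if normalization == "max":
            peak = np.nanmax(vals)
            if peak > 0:
                vals = vals / peak
        elif normalization != "none":
            raise ValueError(f"unknown normalization {normalization!r}")
        rows.append(vals)
    arr = np.vstack(rows)
    n = len(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
    if n == 1:
        warnings.warn("single colony: SEM undefined, reporting NaN")
        sem = np.full(n_common, np.nan)
    else:
        sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(n)
    centers = 0.5 * (edges0[:n_common] + edges0[1: n_common + 1])
    return ProfileEnsemble(centers, mean, sem, n,
                           profiles[0].channel, normalization)


def build_kymograph(
    timelapse: np.ndarray,
    geometry: ColonyGeometry,
    times_h: np.ndarray | None = None,
    n_segments: int = 12,
    bin_width_um: float = 10.0,
) -> Kymograph:
    """Radial-profile kymograph of a (t, y, x) single-channel time-lapse.

    Each frame is profiled per angular pie segment and the segments
    combined weighted by pixel count, which makes each row identical to
    the whole-colony radial profile of that frame; the segment bookkeeping
    exists so segments from several colonies can be pooled upstream.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    frames = np.asarray(timelapse, float)
    if frames.ndim != 3:
        raise ValueError("timelapse must be (t, y, x)")
    nt = frames.shape[0]
    times = np.arange(nt, dtype=float) if times_h is None else np.asarray(times_h, float)

    yy, xx = np.indices(frames.shape[1:])
    cx_px = geometry.center_um[0] / geometry.um_per_px - 0.5
    cy_px = geometry.center_um[1] / geometry.um_per_px - 0.5
    r_um = np.hypot(xx - cx_px, yy - cy_px) * geometry.um_per_px
    angle = np.arctan2(yy - cy_px, xx - cx_px)  # [-pi, pi)
    seg = np.minimum(
        ((angle + np.pi) / (2 * np.pi) * n_segments).astype(int), n_segments - 1
    )

    r_in = r_um[geometry.mask]
    seg_in = seg[geometry.mask]
    n_bins = int(np.floor(r_in.max() / bin_width_um)) + 1
    edges = bin_width_um * np.arange(n_bins + 1)
    bin_idx = np.floor(r_in / bin_width_um).astype(int)
    flat_idx = seg_in * n_bins + bin_idx

    seg_counts = np.bincount(flat_idx, minlength=n_segments * n_bins)
    values = np.empty((nt, n_bins))
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    for k in range(nt):
        v_in = frames[k][geometry.mask]
        seg_totals = np.bincount(flat_idx, weights=v_in,
                                 minlength=n_segments * n_bins)
        # count-weighted combination across segments == pooled mean
        tot = seg_totals.reshape(n_segments, n_bins).sum(axis=0)
        cnt = seg_counts.reshape(n_segments, n_bins).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            values[k] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return Kymograph(times, edges, values, n_segments, counts)


def z_axis_profile(
    zstack: np.ndarray,
    membrane_zstack: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-slice target intensity normalized to the membrane marker.

    Both stacks are (z, y, x); the result is, per slice, mean(target in
    mask) / mean(membrane in mask) — ratio-invariant to global gain, which
    is what makes apical-vs-basolateral enrichment comparable across
    samples.  Raises if a membrane slice mean is not positive.
    """
    target = np.asarray(zstack, float)
    membrane = np.asarray(membrane_zstack, float)
    if target.shape != membrane.shape or target.ndim != 3:
        raise ValueError("stacks must be equal-shape (z, y, x)")
    if mask is None:
        mask = np.ones(target.shape[1:], bool)
    out = np.empty(target.shape[0])
    for z in range(target.shape[0]):
        mem = membrane[z][mask].mean()
        if mem <= 0:
            raise ValueError(f"membrane mean <= 0 in slice {z}")
        out[z] = target[z][mask].mean() / mem
    return out
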