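"""Sender/receiver juxtaposition quantification.

Protein or transcript range is read out as mean intensity in receiver
territory versus Euclidean distance from the sender border, in narrow
(default 5 um) bins; an exponential fit I(d) = a*exp(-d/lambda) + c
summarizes diffusible gradients, and ranges are converted to cell tiers —
the natural unit for a juxtacrine relay, where signal should not pass the
first receiver tier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "BorderProfile",
    "DecayFit",
    "distance_to_border",
    "border_profile",
    "fit_exponential_decay",
    "range_in_cell_tiers",
]


@dataclass
class BorderProfile:
    """Binned receiver-side intensity vs. distance from the sender border.

    ``sender_mean`` summarizes sender-territory intensity separately (the
    two territories are plotted apart, not mixed into bin 0).
    """

    bin_edges_um: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    sender_mean: float
    sender_count: int
    channel: str = "signal"
    t_h: float = 0.0

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "channel": self.channel,
            "t_h": self.t_h,
            "distance_lo_um": self.bin_edges_um[:-1],
            "distance_hi_um": self.bin_edges_um[1:],
            "mean": self.mean,
            "count": self.count,
            "territory": "receiver",
        })
        sender = pd.DataFrame({
            "channel": [self.channel], "t_h": [self.t_h],
            "distance_lo_um": [np.nan], "distance_hi_um": [np.nan],
            "mean": [self.sender_mean], "count": [self.sender_count],
            "territory": ["sender"],
        })
        return pd.concat([sender, df], ignore_index=True)


@dataclass
class DecayFit:
    """Exponential range fit. ``no_decay`` flags flat profiles; consumers
    must check ``converged`` before using lambda."""

    amplitude: float
    decay_length_um: float
    offset: float
    residual: float
    converged: bool
    no_decay: bool = False


def distance_to_border(sender_mask: np.ndarray, um_per_px: float) -> np.ndarray:
    """Per-pixel Euclidean distance (um) to the nearest sender pixel.

    Sender pixels map to 0.  Distances are center-to-center, computed with
    an exact Euclidean distance transform.  An empty or full mask leaves
    no border and raises.
    """
    mask = np.asarray(sender_mask, bool)
    if um_per_px <= 0:
        raise ValueError("um_per_px must be > 0")
    if not mask.any():
        raise ValueError("empty sender mask: no border to measure from")
    if mask.all():
        raise ValueError("sender mask covers the frame: no receivers")
    return ndimage.distance_transform_edt(~mask) * um_per_px


def border_profile(
    channel: np.ndarray,
    sender_mask: np.ndarray,
    receiver_mask: np.ndarray,
    um_per_px: float,
    bin_width_um: float = 5.0,
    channel_name: str = "signal",
    t_h: float = 0.0,
) -> BorderProfile:
    """Bin receiver-territory pixels by distance from the sender border.

    Masks must be disjoint; receiver pixels outside the analyzed territory
    are simply excluded, and the conservation identity
    sum(mean*count) == sum(included intensities) holds on what remains.
    """
    img = np.asarray(channel, float)
    sender = np.asarray(sender_mask, bool)
    receiver = np.asarray(receiver_mask, bool)
    if (sender & receiver).any():
        raise ValueError("sender and receiver masks overlap")
    if not receiver.any():
        raise ValueError("empty receiver mask")
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")

    dist = distance_to_border(sender, um_per_px)
    d_in = dist[receiver]
    v_in = img[receiver]
    n_bins = int(np.floor(d_in.max() / bin_width_um)) + 1
    edges = bin_width_um * np.arange(n_bins + 1)
    idx = np.floor(d_in / bin_width_um).astype(int)
    count = np.bincount(idx, minlength=n_bins).astype(float)
    total = np.bincount(idx, weights=v_in, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return BorderProfile(
        edges, mean, count,
        sender_mean=float(img[sender].mean()),
        sender_count=int(sender.sum()),
        channel=channel_name, t_h=t_h,
    )


def fit_exponential_decay(
    profile: BorderProfile, flat_rel_range: float = 0.05
) -> DecayFit:
    """Least-squares fit of mean(d) = a*exp(-d/lambda) + c.

    Initialized from a log-linear regression of the offset-subtracted
    means.  A profile whose dynamic range is below ``flat_rel_range`` of
    its mean level is flagged ``no_decay`` instead of being fit; a fit
    that fails to converge is flagged, never silently numeric.
    """
    good = profile.count > 0
    d = profile.bin_centers_um[good]
    y = profile.mean[good]
    if len(d) < 5:
        raise ValueError("need at least 5 nonempty bins to fit a decay")

    span = y.max() - y.min()
    level = max(abs(y).max(), 1e-12)
    if span < flat_rel_range * level:
        return DecayFit(0.0, np.nan, float(y.mean()), 0.0,
                        converged=False, no_decay=True)

    c0 = y.min()
    pos = y - c0 > 1e-12 * level
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(d[pos], np.log(y[pos] - c0 + 1e-12 * level), 1)
        lam0 = -1.0 / slope if slope < 0 else d.max()
        a0 = np.exp(intercept)
    else:
        lam0, a0 = d.max() / 3, span
    lam0 = float(np.clip(lam0, 1e-3, 100 * d.max()))

    def model(dd, a, lam, c):
        return a * np.exp(-dd / lam) + c

    try:
        popt, _ = optimize.curve_fit(
            model, d, y, p0=(max(a0, 1e-9), lam0, c0),
            bounds=([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return DecayFit(np.nan, np.nan, np.nan, np.nan,
                        converged=False, no_decay=False)
    resid = float(np.sqrt(np.mean((model(d, *popt) - y) ** 2)))
    return DecayFit(float(popt[0]), float(popt[1]), float(popt[2]), resid,
                    converged=True)


def range_in_cell_tiers(
    profile_or_fit: BorderProfile | DecayFit,
    cell_diameter_um: float = 10.0,
    threshold_frac: float = 0.1,
) -> float:
    """Signal range expressed in cell tiers.

    From a fit: the distance where the background-subtracted exponential
    falls to ``threshold_frac`` of its border value, lambda * ln(1/frac),
    divided by the cell diameter.  From a raw profile the binned mean is a
    step function of distance, so the smallest distance where it sits
    below ``threshold_frac`` of its first-bin value is the lower edge of
    the first sub-threshold bin.
    """
    if cell_diameter_um <= 0:
        raise ValueError("cell_diameter_um must be positive")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")

    if isinstance(profile_or_fit, DecayFit):
        fit = profile_or_fit
        if fit.no_decay or not fit.converged:
            raise ValueError("cannot convert a flagged fit to a range")
        return float(fit.decay_length_um * np.log(1.0 / threshold_frac)
                     / cell_diameter_um)

    profile = profile_or_fit
    good = np.nonzero(profile.count > 0)[0]
    if len(good) == 0:
        raise ValueError("profile has no populated bins")
    lo = profile.bin_edges_um[:-1][good]
    hi = profile.bin_edges_um[1:][good]
    y = profile.mean[good].astype(float)
    y = y - y.min()            # background-subtract on the profile's own floor
    ref = y[0]
    if ref <= 0:
        raise ValueError("no signal in the first bin; range undefined")
    below = np.nonzero(y < threshold_frac * ref)[0]
    if len(below) == 0:
        return float(hi[-1] / cell_diameter_um)  # never decays inside the frame
    return float(lo[below[0]] / cell_diameter_um)
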