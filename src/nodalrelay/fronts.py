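"""Signaling-front extraction from relay or reaction-diffusion runs.

The front is the farthest distance from the source (colony edge, or sender
border) at which signaling activity exceeds a threshold — the readout used
to compare propagation speed between genotypes (e.g. wild type vs.
Lefty1/2 knockout, where loss of the inhibitor accelerates the front).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import FieldTrajectory
from .lattice import RelayTrajectory

__all__ = ["FrontSeries", "front_from_profile", "front_position", "time_to_distance"]

#: sentinel reported when no position exceeds the threshold
NO_FRONT = float("nan")


@dataclass
class FrontSeries:
    """Front distance vs. time, in um and in cell tiers."""

    times: np.ndarray
    distance_um: np.ndarray      # NaN where nowhere exceeds threshold
    cell_diameter_um: float

    @property
    def tiers(self) -> np.ndarray:
        return self.distance_um / self.cell_diameter_um

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_h": self.times, "front_um": self.distance_um,
             "front_tiers": self.tiers}
        )


def front_from_profile(
    distance_um: np.ndarray, values: np.ndarray, threshold: float
) -> float:
    """Farthest distance at which ``values`` exceeds ``threshold``.

    Samples are sorted by distance; the front is placed at the linear
    interpolation between the last supra-threshold sample and the next
    sample, so a sharp step is located at the crossing rather than at a
    sample point. Returns NaN if no sample exceeds the threshold.
    """
    distance_um = np.asarray(distance_um, float)
    values = np.asarray(values, float)
    if distance_um.shape != values.shape or distance_um.size == 0:
        raise ValueError("distance and value arrays must be equal-length, nonempty")
    order = np.argsort(distance_um)
    d = distance_um[order]
    v = values[order]
    above = v > threshold
    if not above.any():
        return NO_FRONT
    last = int(np.max(np.nonzero(above)[0]))
    if last == len(d) - 1:
        return float(d[last])
    d0, d1 = d[last], d[last + 1]
    v0, v1 = v[last], v[last + 1]
    if v1 >= v0:  # non-monotone tail; stop at the sample itself
        return float(d0)
    frac = (v0 - threshold) / (v0 - v1)
    return float(d0 + frac * (d1 - d0))


def _profile_from_field(traj: FieldTrajectory, frame: np.ndarray):
    """Distance-from-source profile of a field frame (max over equidistant
    pixels, binned at the grid spacing)."""
    from scipy import ndimage

    dist = ndimage.distance_transform_edt(~traj.source) * traj.dx_um
    dist = dist[traj.domain]
    vals = frame[traj.domain]
    bins = np.round(dist / traj.dx_um).astype(int)
    out_d, out_v = [], []
    for b in np.unique(bins):
        sel = bins == b
        out_d.append(dist[sel].mean())
        out_v.append(vals[sel].max())
    return np.array(out_d), np.array(out_v)


def front_position(
    trajectory: RelayTrajectory | FieldTrajectory,
    threshold: float,
    field: str = "S",
    cell_diameter_um: float | None = None,
) -> FrontSeries:
    """Front distance vs. time for a simulated trajectory.

    For a relay run the profiled quantity is the per-tier maximum of
    ``field`` (default the signaling activity S) against tier distance from
    the source. For a reaction-diffusion run it is the named field ("N" or
    "L") against distance from the source mask.
    """
    if isinstance(trajectory, RelayTrajectory):
        lat = trajectory.lattice
        if len(trajectory.times) == 0:
            raise ValueError("empty trajectory")
        cell_d = cell_diameter_um or lat.cell_diameter_um
        tiers = lat.tiers()
        tier_ids = np.unique(tiers)
        tier_dist = tier_ids * cell_d
        states = getattr(trajectory, field)
        fronts = np.empty(len(trajectory.times))
        for k in range(len(trajectory.times)):
            per_tier = np.array(
                [states[k][tiers == t].max() for t in tier_ids]
            )
            fronts[k] = front_from_profile(tier_dist, per_tier, threshold)
        return FrontSeries(trajectory.times.copy(), fronts, cell_d)

    if isinstance(trajectory, FieldTrajectory):
        if len(trajectory.times) == 0:
            raise ValueError("empty trajectory")
        cell_d = cell_diameter_um or 10.0
        frames = getattr(trajectory, field if field in ("N", "L") else "N")
        fronts = np.empty(len(trajectory.times))
        for k in range(len(trajectory.times)):
            d, v = _profile_from_field(trajectory, frames[k])
            fronts[k] = front_from_profile(d, v, threshold)
        return FrontSeries(trajectory.times.copy(), fronts, cell_d)

    raise TypeError(f"unsupported trajectory type: {type(trajectory)!r}")


def time_to_distance(series: FrontSeries, distance_um: float) -> float:
    """First sampled time at which the front reaches ``distance_um``.

    NaN if the front never gets there within the sampled window.
    """
    reached = np.nonzero(
        ~np.isnan(series.distance_um) & (series.distance_um >= distance_um)
    )[0]
    if len(reached) == 0:
        return float("nan")
    return float(series.times[reached[0]])
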