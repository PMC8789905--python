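"""Differential-diffusivity activator-inhibitor field simulator.

The alternative to the transcriptional relay: Nodal (activator, N) and
Lefty (inhibitor, L) are secreted proteins that spread by extracellular
diffusion, with Lefty diffusing farther (D_L > D_N).  Each field obeys a
linear reaction-diffusion equation

    dN/dt = D_N * lap(N) + prod_N * source(x) - k_N * N
    dL/dt = D_L * lap(L) + prod_L * source(x) - k_L * L

integrated by explicit finite differences on a regular grid with no-flux
boundaries.  At steady state away from a localized source each field decays
as exp(-x / lambda) with lambda = sqrt(D / k), so the ratio of decay
lengths is sqrt((D_L * k_N) / (D_N * k_L)) — the model's testable
signature, contrasted with the one-tier Nodal range the relay predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FieldParams", "FieldTrajectory", "StabilityError", "simulate_diffusion"]


class StabilityError(ValueError):
    """Explicit-scheme stability condition dt <= dx^2 / (4 max D) violated."""


@dataclass(frozen=True)
class FieldParams:
    """Rates and geometry for the two-field reaction-diffusion model.

    No measured diffusion coefficients exist for this system; defaults give
    lambda_N ~ 20 um and lambda_L ~ 80 um, matching the observed one-to-two
    cell Nodal range against a Lefty gradient over several cell tiers.
    """

    D_N: float = 4.0       # Nodal diffusivity (um^2/h)
    D_L: float = 64.0      # Lefty diffusivity (um^2/h); must exceed D_N
    k_N: float = 0.01      # Nodal degradation (1/h)
    k_L: float = 0.01      # Lefty degradation (1/h)
    prod_N: float = 1.0    # production rate inside the source mask (a.u./h)
    prod_L: float = 1.0
    dx_um: float = 5.0     # grid spacing
    dt: float = 0.05       # time step (h)
    geometry: str = "rectangle"   # "rectangle" | "disc"

    def __post_init__(self) -> None:
        if self.D_L <= self.D_N:
            raise ValueError(
                "the model requires the inhibitor to diffuse farther: D_L > D_N"
            )
        if min(self.D_N, self.k_N, self.k_L, self.prod_N, self.prod_L) < 0:
            raise ValueError("rates must be nonnegative")
        if self.dx_um <= 0 or self.dt <= 0:
            raise ValueError("dx_um and dt must be positive")

    @property
    def decay_length_N(self) -> float:
        return float(np.sqrt(self.D_N / self.k_N))

    @property
    def decay_length_L(self) -> float:
        return float(np.sqrt(self.D_L / self.k_L))

    def check_stability(self) -> None:
        limit = self.dx_um**2 / (4.0 * max(self.D_N, self.D_L))
        if self.dt > limit:
            raise StabilityError(
                f"dt={self.dt} h exceeds the explicit stability limit "
                f"dx^2/(4 max D) = {limit:.4g} h"
            )


@dataclass
class FieldTrajectory:
    """Sampled N and L fields: arrays of shape (n_times, *grid_shape)."""

    params: FieldParams
    times: np.ndarray
    N: np.ndarray
    L: np.ndarray
    source: np.ndarray          # boolean source mask
    domain: np.ndarray          # boolean integration domain
    dx_um: float


def _laplacian_flux(field: np.ndarray, domain: np.ndarray, dx: float) -> np.ndarray:
    """Flux-form 5-point Laplacian with no-flux (reflecting) boundaries.

    Fluxes across faces between a domain pixel and an out-of-domain (or
    out-of-grid) pixel are zero, so the scheme conserves total mass exactly
    when production and degradation vanish.
    """
    out = np.zeros_like(field)
    # shifted differences along each axis; zero flux where either side
    # leaves the domain
    for axis in (0, 1) if field.ndim == 2 else (0,):
        lo = [slice(None)] * field.ndim
        hi = [slice(None)] * field.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        face_open = domain[lo] & domain[hi]
        flux = (field[hi] - field[lo]) * face_open
        out[lo] += flux
        out[hi] -= flux
    return out / dx**2


def simulate_diffusion(
    params: FieldParams,
    t_max: float,
    source_mask: np.ndarray,
    grid_shape: tuple[int, ...] | None = None,
    sample_interval: float | None = None,
    initial_N: np.ndarray | None = None,
    initial_L: np.ndarray | None = None,
) -> FieldTrajectory:
    """Integrate both fields to ``t_max`` hours.

    ``source_mask`` (1D or 2D boolean) marks producing pixels and defines
    the grid shape. For ``geometry="disc"`` the integration domain is the
    largest centered disc inscribed in the grid; otherwise the full
    rectangle. Raises :class:`StabilityError` before integrating if dt is
    too large.
    """
    params.check_stability()
    source = np.asarray(source_mask, dtype=bool)
    if grid_shape is not None and source.shape != tuple(grid_shape):
        raise ValueError("source_mask shape disagrees with grid_shape")
    if source.ndim not in (1, 2):
        raise ValueError("only 1D and 2D grids are supported")

    if params.geometry == "disc" and source.ndim == 2:
        yy, xx = np.indices(source.shape)
        cy, cx = (source.shape[0] - 1) / 2, (source.shape[1] - 1) / 2
        domain = np.hypot(yy - cy, xx - cx) <= min(cy, cx)
    else:
        domain = np.ones_like(source, dtype=bool)

    N = np.zeros(source.shape) if initial_N is None else np.array(initial_N, float)
    L = np.zeros(source.shape) if initial_L is None else np.array(initial_L, float)
    N[~domain] = 0.0
    L[~domain] = 0.0

    n_steps = int(round(t_max / params.dt))
    if sample_interval is None:
        sample_every = max(1, n_steps)
    else:
        sample_every = max(1, int(round(sample_interval / params.dt)))

    times, Ns, Ls = [0.0], [N.copy()], [L.copy()]
    src = source & domain
    for step in range(1, n_steps + 1):
        N = N + params.dt * (
            params.D_N * _laplacian_flux(N, domain, params.dx_um)
            + params.prod_N * src
            - params.k_N * N
        )
        L = L + params.dt * (
            params.D_L * _laplacian_flux(L, domain, params.dx_um)
            + params.prod_L * src
            - params.k_L * L
        )
        if step % sample_every == 0 or step == n_steps:
            times.append(step * params.dt)
            Ns.append(N.copy())
            Ls.append(L.copy())

    return FieldTrajectory(
        params=params,
        times=np.array(times),
        N=np.array(Ns),
        L=np.array(Ls),
        source=src,
        domain=domain,
        dx_um=params.dx_um,
    )
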