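"""Validated run configuration.

A single YAML file drives the whole pipeline; unknown keys are rejected
up front (typos should fail before any computation), every consumed
parameter appears in the resolved-config dump written next to the
outputs, and one top-level seed fans out to per-stage child seeds by
fixed offsets so each stage is reproducible in isolation.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimBlock(_Strict):
    colony_radius_um: float = 150.0
    cell_diameter_um: float = 10.0
    t_max_h: float = 20.0
    sample_interval_h: float = 2.0
    genotypes: list[str] = Field(default_factory=lambda: ["WT", "L12KO"])
    threshold: float = 0.5
    relay_overrides: dict[str, float] = Field(default_factory=dict)


class RenderBlock(_Strict):
    shape_px: tuple[int, int] = (240, 240)
    um_per_px: float = 1.5
    background: float = 10.0
    gain: float = 100.0
    nucleus_radius_um: float = 4.0
    nucleus_gain: float = 150.0
    cell_spacing_um: float = 10.0
    psf_sigma_um: float = 1.0
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    hot_pixel_rate: float = 0.0
    n_colonies: int = 3


class PrepBlock(_Strict):
    background_method: str = "morphological_open"
    background_radius_um: float = 50.0
    outlier_radius_px: int = 2
    outlier_k_sd: float = 5.0
    min_nucleus_diam_um: float = 4.0
    max_nucleus_diam_um: float = 20.0


class ColonyBlock(_Strict):
    bin_width_um: float = 10.0
    expected_diameter_um: float | None = None  # default: 2x sim colony radius
    normalization: str = "none"
    kymograph_segments: int = 12


class JuxtaBlock(_Strict):
    bin_width_um: float = 5.0
    lambda_um: float = 60.0
    amplitude: float = 100.0
    offset: float = 10.0
    band_width_um: float = 10.0
    band_amplitude: float = 80.0
    border_x_um: float = 180.0
    cell_diameter_um: float = 10.0
    threshold_frac: float = 0.1


class CellsBlock(_Strict):
    cyto_ring_um: float = 3.0


class RunConfig(_Strict):
    """Top-level pipeline configuration."""

    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"
    um_per_px_override: float | None = None
    sim: SimBlock = Field(default_factory=SimBlock)
    render: RenderBlock = Field(default_factory=RenderBlock)
    prep: PrepBlock = Field(default_factory=PrepBlock)
    colony: ColonyBlock = Field(default_factory=ColonyBlock)
    juxta: JuxtaBlock = Field(default_factory=JuxtaBlock)
    cells: CellsBlock = Field(default_factory=CellsBlock)

    # child-seed offsets: fixed so each stage reruns identically alone
    def stage_seed(self, stage: str) -> int:
        offsets = {"sim": 0, "render": 1000, "juxta": 2000, "cells": 3000}
        return (self.seed + offsets[stage]) % (2**31 - 1)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML config; keyword overrides win."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return RunConfig.model_validate(data)
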