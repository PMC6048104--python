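"""Pipeline configuration with published defaults.

All tunable parameters of the segmentation pipeline live in one dataclass so
that the CLI, the library API and the tests share a single source of truth.
Defaults are the values used for clinical CT; phantom-scale runs override the
distance thresholds (``phi_s``/``phi_t``) to match the smaller geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    # -- graph domain -------------------------------------------------------
    #: interior distance threshold defining hard source seeds
    phi_s: float = 25.0
    #: exterior distance threshold defining the band edge / sink region
    phi_t: float = 35.0
    #: "mm" computes distances with voxel spacing; "voxels" ignores spacing
    threshold_units: str = "mm"

    # -- energy weights -----------------------------------------------------
    alpha: float = 10.0   # data term weight
    beta: float = 10.0    # appearance term weight
    gamma: float = 80.0   # shape term weight
    iterations: int = 5
    #: balance coefficient of the intensity-only baseline
    lam: float = 10.0
    #: boundary term scale
    sigma1: float = 0.1

    # -- texture features ---------------------------------------------------
    lbp_points: int = 8       # P
    lbp_radius: float = 1.0   # R (in-plane)
    lbp_interval: int = 2     # L (z-extent of XZ/YZ plane sampling)
    #: pooling window (wx, wy, wz) for per-voxel LBP histograms; odd dims
    window: tuple[int, int, int] = (15, 15, 7)

    # -- spin descriptor / boundary weight ----------------------------------
    spin_bins: tuple[int, int] = (4, 4)
    sigma_d: float = 0.5
    sigma_i: float = 0.5
    spin_radius: int = 4      # patch radius in voxels

    # -- feature stack ------------------------------------------------------
    sigma_blur: float = 1.0   # Gaussian blur scale, voxel units
    #: min-max normalize intensities to [0, 1] before feature extraction so
    #: sigma1 is meaningful on arbitrary intensity scales
    normalize_intensity: bool = True

    # -- atlas fusion -------------------------------------------------------
    phi: float = 0.8          # atlas selection ratio threshold
    nmi_bins: int = 32
    #: "atlas_union_dilated" (union of warped labels dilated 5 mm) or "whole_image"
    region_policy: str = "atlas_union_dilated"
    region_dilate_mm: float = 5.0

    # -- model fitting ------------------------------------------------------
    #: background model is fitted on the exterior shell dist in (phi_t, phi_t + bg_shell]
    bg_shell: float = 10.0
    #: re-fit Gaussian/histogram models every iteration (False: freeze at iter 0)
    refit_models: bool = True

    # -- misc ---------------------------------------------------------------
    connectivity: int = 6
    #: reject volumes whose direction matrix is not axis-aligned
    allow_oblique: bool = False

    def __post_init__(self) -> None:
        if self.phi_s <= 0 or self.phi_t <= 0:
            raise ValueError("phi_s and phi_t must be positive")
        if self.threshold_units not in ("mm", "voxels"):
            raise ValueError(f"unknown threshold_units {self.threshold_units!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if min(self.alpha, self.beta, self.gamma, self.lam) < 0:
            raise ValueError("energy weights must be non-negative")
        if any(w % 2 == 0 or w < 1 for w in self.window):
            raise ValueError("window dims must be odd positive integers")
        if not 0 < self.phi <= 1:
            raise ValueError("phi must lie in (0, 1]")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        """Load a config from a TOML file; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window", "spin_bins"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
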