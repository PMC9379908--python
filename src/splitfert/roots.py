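"""Logistic maize root growth: rooting-depth front and root length density.

The rooting front z_r(t) and the surface root length density L(t) both
follow logistic growth from a 1% seed value, so the crop develops
deterministically and identically every season (growth is never water or
nitrogen limited).  Below the front the density is zero; above it the
density declines exponentially with depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RootParams:
    max_root_depth: float = 55.0  # cm
    depth_growth_rate: float = 0.085  # 1/day
    max_rld_surface: float = 4.0  # cm root / cm^3 soil
    rld_growth_rate: float = 0.10  # 1/day
    rld_depth_shape: float = 3.0  # e-folding factor over max_root_depth
    seed_fraction: float = 0.01  # logistic initial condition, fraction of max

    def __post_init__(self) -> None:
        for name in (
            "max_root_depth",
            "depth_growth_rate",
            "max_rld_surface",
            "rld_growth_rate",
            "rld_depth_shape",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.seed_fraction < 1.0:
            raise ValueError("seed_fraction must be in (0, 1)")


def _logistic(t: np.ndarray | float, maximum: float, rate: float, seed_fraction: float):
    ratio = (1.0 - seed_fraction) / seed_fraction
    return maximum / (1.0 + ratio * np.exp(-rate * np.asarray(t, dtype=float)))


def root_depth(t: float, params: RootParams) -> float:
    """Rooting-front depth (cm) at day ``t`` of the season."""
    return float(_logistic(t, params.max_root_depth, params.depth_growth_rate, params.seed_fraction))


def surface_rld(t: float, params: RootParams) -> float:
    """Root length density at the surface (cm cm^-3) at day ``t``."""
    return float(_logistic(t, params.max_rld_surface, params.rld_growth_rate, params.seed_fraction))


def root_profile(t: float, params: RootParams, z: np.ndarray) -> np.ndarray:
    """Root length density (cm cm^-3) at depths ``z`` (cm) on day ``t``.

    RLD(z, t) = L(t) exp(-beta z / z_max) above the rooting front, zero
    below it; L(t) and the front are logistic in time.
    """
    z = np.asarray(z, dtype=float)
    front = root_depth(t, params)
    rld = surface_rld(t, params) * np.exp(
        -params.rld_depth_shape * z / params.max_root_depth
    )
    rld[z > front] = 0.0
    return rld
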