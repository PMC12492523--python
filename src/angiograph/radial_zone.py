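"""Radial zone analysis: spatial heterogeneity across concentric annuli.

Graph nodes are binned into concentric annular zones of fixed width
delta_r (50 px by default, 6 zones, covering radii up to 300 px) around
the geometric image center.  A node at distance d from the center falls
in zone k = floor(d / delta_r) + 1; distances exactly on a boundary
belong to the outer zone, and nodes beyond the outermost zone are counted
as excluded rather than silently dropped.  Zone counts are normalized by
the annular areas pi (r_out^2 - r_in^2) = pi delta_r^2 (2k - 1) to give
comparable node densities (nodes / px^2).

Five heterogeneity statistics summarize the density profile: standard
deviation (population), Shannon entropy in nats of the density-mass
distribution (ln(n_zones) for a perfectly even spread), coefficient of
variation, the center-to-edge radial gradient density_1 - density_n, and
the ordinary-least-squares slope of density against zone index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ZoneProfile",
    "HeterogeneityMetrics",
    "image_center",
    "assign_zones",
    "zone_profile_from_graph",
    "heterogeneity",
    "HETEROGENEITY_NAMES",
]


@dataclass
class ZoneProfile:
    """Per-zone node counts, annular areas, and area-normalized densities."""

    center: tuple[float, float]  # (x_c, y_c) pixel coordinates
    delta_r: float
    n_zones: int
    counts: np.ndarray  # int, length n_zones
    areas: np.ndarray  # px^2, length n_zones
    densities: np.ndarray  # nodes / px^2, length n_zones
    n_excluded: int  # nodes farther than n_zones * delta_r


@dataclass
class HeterogeneityMetrics:
    std_dev: float
    entropy: float  # nats; in [0, ln n_zones]
    cv: float
    radial_gradient: float  # density_1 - density_{n_zones}
    linear_slope: float  # density units per zone index

    def to_dict(self) -> dict:
        return {
            "zone_std_dev": self.std_dev,
            "zone_entropy": self.entropy,
            "zone_cv": self.cv,
            "zone_radial_gradient": self.radial_gradient,
            "zone_linear_slope": self.linear_slope,
        }


HETEROGENEITY_NAMES: tuple[str, ...] = (
    "zone_std_dev",
    "zone_entropy",
    "zone_cv",
    "zone_radial_gradient",
    "zone_linear_slope",
)


def image_center(image_shape: tuple[int, int]) -> tuple[float, float]:
    """Geometric center ((width-1)/2, (height-1)/2) in (x, y) pixel coords.

    Symmetric for both odd and even image dimensions.
    """
    height, width = image_shape[:2]
    return (width - 1) / 2.0, (height - 1) / 2.0


def assign_zones(
    coords: np.ndarray,
    image_shape: tuple[int, int],
    delta_r: float = 50.0,
    n_zones: int = 6,
) -> ZoneProfile:
    """Bin node coordinates into concentric annular zones.

    Parameters
    ----------
    coords
        (n, 2) array of (row, col) node coordinates (may be empty).
    image_shape
        (height, width) of the source image; defines the center.
    delta_r
        Annulus width in pixels.
    n_zones
        Number of zones; nodes beyond ``n_zones * delta_r`` are excluded
        from the profile but reported in ``n_excluded``.
    """
    if delta_r <= 0:
        raise ValueError("delta_r must be > 0")
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    x_c, y_c = image_center(image_shape)

    counts = np.zeros(n_zones, dtype=int)
    n_excluded = 0
    if coords.size:
        # (row, col) -> (x, y) = (col, row)
        d = np.hypot(coords[:, 1] - x_c, coords[:, 0] - y_c)
        k = np.floor(d / delta_r).astype(int) + 1  # boundary -> outer zone
        inside = k <= n_zones
        n_excluded = int(np.count_nonzero(~inside))
        counts = np.bincount(k[inside] - 1, minlength=n_zones).astype(int)

    zone_idx = np.arange(1, n_zones + 1)
    areas = math.pi * delta_r**2 * (2 * zone_idx - 1)
    return ZoneProfile(
        center=(x_c, y_c),
        delta_r=float(delta_r),
        n_zones=n_zones,
        counts=counts,
        areas=areas,
        densities=counts / areas,
        n_excluded=n_excluded,
    )


def zone_profile_from_graph(
    g: nx.Graph,
    image_shape: tuple[int, int],
    delta_r: float = 50.0,
    n_zones: int = 6,
) -> ZoneProfile:
    """Zone profile of a pixel graph's nodes (``row``/``col`` attributes)."""
    coords = np.array(
        [(g.nodes[v]["row"], g.nodes[v]["col"]) for v in g.nodes], dtype=float
    ).reshape(-1, 2)
    return assign_zones(coords, image_shape, delta_r=delta_r, n_zones=n_zones)


def heterogeneity(
    profile: ZoneProfile, sample_std: bool = False
) -> HeterogeneityMetrics:
    """Five heterogeneity statistics of the zone density profile.

    ``sample_std`` switches the SD (and CV numerator) from the population
    form (divide by n_zones, default) to the sample form (n_zones - 1).
    Raises on an all-zero profile (no network in the field).
    """
    if profile.n_zones < 2:
        raise ValueError("heterogeneity requires at least 2 zones")
    dens = np.asarray(profile.densities, dtype=float)
    total = dens.sum()
    if total == 0:
        raise ValueError("all zone densities are zero: no network in field")

    sd = float(np.std(dens, ddof=1 if sample_std else 0))
    mean = float(np.mean(dens))
    p = dens / total
    nonzero = p > 0
    entropy = float(-(p[nonzero] * np.log(p[nonzero])).sum())
    zone_idx = np.arange(1, profile.n_zones + 1, dtype=float)
    slope = float(np.polyfit(zone_idx, dens, 1)[0])
    return HeterogeneityMetrics(
        std_dev=sd,
        entropy=entropy,
        cv=sd / mean,
        radial_gradient=float(dens[0] - dens[-1]),
        linear_slope=slope,
    )
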