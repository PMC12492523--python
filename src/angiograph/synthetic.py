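"""Synthetic tube-formation images and toy skeletons with known ground truth.

Endothelial cells on basement-membrane matrix self-organize into polygonal,
capillary-like meshes.  The generator emulates this morphology: seed points
scattered over the field are joined by the edges of their Delaunay
triangulation, drawn as dark tubes of finite width on a bright background
(brightfield polarity).  Two dials move the image across the biologically
relevant axes:

* ``n_seeds`` — few seeds give a sparse network, many a dense,
  highly interconnected one (the seeding-density axis);
* ``fragmentation`` — the fraction of mesh edges deleted, emulating the
  fragmented, poorly integrated networks of early timepoints versus the
  consolidated single-component networks of late ones.

Salt-like noise specks (each well under the 64-px cleanup threshold) can be
sprinkled in to exercise small-object removal.  The exact tube mask is
returned as ground truth, and the whole construction is integer geometry
driven by a single seed, so identical configs reproduce identical images.

``toy_skeletons`` provides tiny hand-checkable skeleton fixtures (lines,
triangle, ring, cross, multi-component fields) whose metric values are known
in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from skimage.draw import disk, line
from skimage.morphology import dilation, disk as disk_footprint

__all__ = [
    "SyntheticConfig",
    "PRESETS",
    "generate_mesh_image",
    "toy_skeletons",
    "BACKGROUND_LEVEL",
    "TUBE_LEVEL",
]

logger = logging.getLogger(__name__)

#: Grey levels of the rendered image (8-bit), brightfield-like: dark tubes
#: on a bright background.
BACKGROUND_LEVEL = 220
TUBE_LEVEL = 40


@dataclass
class SyntheticConfig:
    """Study conditions of one synthetic tube-formation image."""

    image_size: tuple[int, int] = (512, 512)  # (height, width)
    n_seeds: int = 25
    tube_width: int = 5
    noise_level: float = 0.0  # salt-speck density in [0, 1)
    fragmentation: float = 0.0  # fraction of mesh edges deleted
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 2:
            raise ValueError("n_seeds must be >= 2")
        if self.tube_width < 1:
            raise ValueError("tube_width must be >= 1")
        if not 0 <= self.noise_level < 1:
            raise ValueError("noise_level must be in [0, 1)")
        if not 0 <= self.fragmentation <= 1:
            raise ValueError("fragmentation must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d


#: Named presets emulating the two seeding-density morphologies: a sparse,
#: partially fragmented network versus a dense, fully interconnected mesh.
PRESETS: dict[str, dict] = {
    "sparse": {"n_seeds": 8, "fragmentation": 0.25},
    "dense": {"n_seeds": 40, "fragmentation": 0.0},
}


def _mesh_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected edges of the Delaunay triangulation, sorted."""
    if len(points) == 2:
        return np.array([[0, 1]], dtype=int)
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        a, b, c = (int(v) for v in simplex)
        edges.add((min(a, b), max(a, b)))
        edges.add((min(a, c), max(a, c)))
        edges.add((min(b, c), max(b, c)))
    return np.array(sorted(edges), dtype=int)


def _scatter_seeds(
    rng: np.random.Generator,
    n_seeds: int,
    height: int,
    width: int,
    margin: int,
    min_separation: float,
) -> np.ndarray:
    """Integer seed points with a minimum pairwise separation.

    The separation (3 x tube width) guarantees every drawn tube segment is
    comfortably larger than the small-object cleanup threshold, so no true
    network fragment is mistaken for noise.  Falls back to unconstrained
    placement (logged) if the field is too crowded.
    """
    points: list[tuple[int, int]] = []
    for _ in range(n_seeds):
        for _attempt in range(500):
            r = int(rng.integers(margin, height - margin))
            c = int(rng.integers(margin, width - margin))
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 >= min_separation**2
                for pr, pc in points
            ):
                points.append((r, c))
                break
        else:
            logger.warning(
                "field too crowded for min separation %.0f px; relaxing",
                min_separation,
            )
            points.append(
                (
                    int(rng.integers(margin, height - margin)),
                    int(rng.integers(margin, width - margin)),
                )
            )
    return np.array(points, dtype=int)


def generate_mesh_image(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic tube image.

    Returns ``(image, ground_truth)``: a uint8 grayscale image and the
    boolean mask of true tube pixels (noise specks are *not* part of the
    ground truth).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    height, width = cfg.image_size
    margin = 2 * cfg.tube_width + 2
    if height <= 2 * margin or width <= 2 * margin:
        raise ValueError("image_size too small for the requested tube_width")

    for attempt in range(10):
        points = _scatter_seeds(
            rng, cfg.n_seeds, height, width, margin, 3.0 * cfg.tube_width
        )
        try:
            edges = _mesh_edges(points.astype(float))
            break
        except QhullError:
            logger.info(
                "degenerate seed geometry (attempt %d), resampling", attempt + 1
            )
    else:
        raise RuntimeError("could not draw non-degenerate seed points")

    # fragmentation: delete a fixed fraction of mesh edges at random
    n_drop = int(round(cfg.fragmentation * len(edges)))
    if n_drop:
        keep = rng.permutation(len(edges))[n_drop:]
        edges = edges[np.sort(keep)]

    centerline = np.zeros((height, width), dtype=bool)
    for a, b in edges:
        rr, cc = line(*points[a], *points[b])
        centerline[rr, cc] = True
    radius = cfg.tube_width // 2
    truth = (
        dilation(centerline, disk_footprint(radius)) if radius else centerline.copy()
    )

    image = np.full((height, width), BACKGROUND_LEVEL, dtype=np.uint8)
    image[truth] = TUBE_LEVEL

    # bounded-size noise specks, always < 64 px each
    n_specks = int(round(cfg.noise_level * height * width / 1000))
    for _ in range(n_specks):
        r = int(rng.integers(0, height))
        c = int(rng.integers(0, width))
        speck_radius = int(rng.integers(1, 4))  # area <= ~38 px
        rr, cc = disk((r, c), speck_radius, shape=(height, width))
        image[rr, cc] = TUBE_LEVEL

    return image, truth


def _diamond_ring(radius: int) -> np.ndarray:
    """Discrete ring |r| + |c| = radius: a single cycle, every pixel with
    exactly two (diagonal) neighbors and no triangles."""
    size = 2 * radius + 1
    grid = np.zeros((size, size), dtype=bool)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    grid[np.abs(rr - radius) + np.abs(cc - radius) == radius] = True
    return grid


def toy_skeletons() -> dict[str, np.ndarray]:
    """Named hand-checkable skeleton fixtures (boolean masks).

    line3
        Horizontal 3-pixel line: 3 nodes, 2 unit edges; avg degree 4/3,
        clustering 0, efficiency 5/6, avg betweenness 1/3, tortuosity 1,
        one component, density 2/3.
    line9
        Horizontal 9-pixel line (straight path, tortuosity exactly 1).
    l_triangle
        Pixels (0,0),(0,1),(1,1): a 3-cycle with weights {1, 1, sqrt 2};
        clustering 1, density 1, tortuosity 1.
    ring
        Diamond ring of radius 6: one cycle, all degrees 2, no triangles.
    cross
        Plus-shaped skeleton with a single degree-4 hub.
    two_component
        3-pixel line plus one isolated far pixel: components (2, 3, 0.75).
    isolated_pixels
        Pixels pairwise farther than Chebyshev 1: nodes but no edges.
    """
    fixtures: dict[str, np.ndarray] = {}

    line3 = np.zeros((3, 5), dtype=bool)
    line3[1, 1:4] = True
    fixtures["line3"] = line3

    line9 = np.zeros((3, 11), dtype=bool)
    line9[1, 1:10] = True
    fixtures["line9"] = line9

    l_tri = np.zeros((4, 4), dtype=bool)
    l_tri[1, 1] = l_tri[1, 2] = l_tri[2, 2] = True
    fixtures["l_triangle"] = l_tri

    fixtures["ring"] = np.pad(_diamond_ring(6), 1)

    cross = np.zeros((9, 9), dtype=bool)
    cross[4, 1:8] = True
    cross[1:8, 4] = True
    fixtures["cross"] = cross

    two_comp = np.zeros((6, 8), dtype=bool)
    two_comp[1, 1:4] = True
    two_comp[4, 6] = True
    fixtures["two_component"] = two_comp

    iso = np.zeros((7, 7), dtype=bool)
    iso[np.ix_([0, 2, 4, 6], [0, 2, 4, 6])] = True
    fixtures["isolated_pixels"] = iso

    return fixtures
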