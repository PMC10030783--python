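"""Conductive-network templates: binary grids marking mycelium-occupied nodes.

A template is the substrate on which the excitable-medium engine runs: node
``(i, j)`` is *conductive* (participates in the reaction-diffusion dynamics)
when the corresponding pixel of a colony image passes an RGB threshold rule,
or when a synthetic hyphal-growth model has deposited a filament there.
Templates are optionally shaped by a foot-outline ("insole") mask.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "BinarizationThresholds",
    "ConductiveTemplate",
    "GrowthParams",
    "binarize_image",
    "dilate",
    "insole_mask",
    "generate_mycelium",
    "connectivity_report",
    "resize_nearest",
    "load_image",
]

#: 3x3 square structuring element; used both for morphological dilation and
#: for 8-connected component labelling (Moore neighbourhood).
_MOORE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BinarizationThresholds:
    """RGB threshold rule selecting mycelium pixels.

    A pixel is conductive iff ``r > r_min and g > g_min and b < b_max``
    (strict inequalities). Mycelium strands are rendered light green on a
    dark background, hence high red/green floors and a blue ceiling.
    """

    r_min: int = 170
    g_min: int = 170
    b_max: int = 200

    def __post_init__(self) -> None:
        for name in ("r_min", "g_min", "b_max"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")


@dataclass
class ConductiveTemplate:
    """Binary grid of conductive nodes, optionally clipped to an insole mask.

    Attributes
    ----------
    grid
        Boolean array of shape ``(n_i, n_j)``; ``True`` marks a conductive
        node.
    mask
        Optional boolean array of the same shape delimiting the insole
        outline. When present, every conductive node lies inside the mask.
    """

    grid: np.ndarray
    mask: np.ndarray | None = None
    _stepper_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("template grid must be a non-empty 2-D array")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape differs from grid shape")
            if np.any(self.grid & ~self.mask):
                raise ValueError("conductive nodes fall outside the insole mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_conductive(self) -> int:
        return int(self.grid.sum())

    @property
    def conductive_fraction(self) -> float:
        return self.n_conductive / self.grid.size

    # -- text / raster persistence -------------------------------------------------

    def to_text(self) -> str:
        """Plain-text 0/1 matrix, one row per line."""
        return "\n".join("".join("1" if c else "0" for c in row) for row in self.grid)

    @classmethod
    def from_text(cls, text: str) -> "ConductiveTemplate":
        rows = [line for line in text.splitlines() if line.strip()]
        grid = np.array([[ch == "1" for ch in row.strip()] for row in rows])
        return cls(grid)

    def save_png(self, path) -> None:
        """8-bit greyscale PNG: 255 = conductive, 0 = non-conductive."""
        Image.fromarray((self.grid * 255).astype(np.uint8)).save(path)

    @classmethod
    def load_png(cls, path) -> "ConductiveTemplate":
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr > 127)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the synthetic branching-random-walk hyphal model.

    The walk emulates apical extension of hyphae: each walker advances
    ``step_length`` nodes per step along its heading, the heading diffuses
    with Gaussian turning noise of standard deviation ``turn_sd`` radians,
    and with probability ``branch_prob`` per step the tip spawns a lateral
    branch at +/- pi/4 relative heading.  Filaments are clipped to the mask
    and finally thickened by morphological dilation.
    """

    n_inoculation_points: int = 6
    step_length: float = 1.0
    branch_prob: float = 0.01
    turn_sd: float = 0.2
    max_steps: int = 1500
    max_walkers: int = 100
    dilation_iterations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.step_length < 1:
            raise ValueError("step_length must be >= 1 node")
        if self.n_inoculation_points < 1:
            raise ValueError("need at least one inoculation point")


def load_image(path) -> np.ndarray:
    """Read a raster file into an ``(n_i, n_j, 3)`` uint8 RGB array."""
    return np.asarray(Image.open(path).convert("RGB"))


def binarize_image(
    image: np.ndarray,
    thresholds: BinarizationThresholds = BinarizationThresholds(),
) -> ConductiveTemplate:
    """Convert an RGB colony image to a conductive matrix.

    Node ``(i, j)`` is conductive iff ``r > r_min``, ``g > g_min`` and
    ``b < b_max``, all strict.  Grid dimensions equal image dimensions.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected an (n_i, n_j, 3) RGB array, got shape {image.shape}")
    r = image[..., 0].astype(np.int64)
    g = image[..., 1].astype(np.int64)
    b = image[..., 2].astype(np.int64)
    grid = (r > thresholds.r_min) & (g > thresholds.g_min) & (b < thresholds.b_max)
    return ConductiveTemplate(grid)


def dilate(template: ConductiveTemplate, iterations: int = 1) -> ConductiveTemplate:
    """Morphological dilation with a 3x3 square structuring element.

    Every node 8-adjacent to a conductive node becomes conductive, repeated
    ``iterations`` times.  With a mask present, growth is clipped to it.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    grid = template.grid
    if iterations > 0:
        grid = ndimage.binary_dilation(grid, structure=_MOORE, iterations=iterations)
        if template.mask is not None:
            grid = grid & template.mask
    return ConductiveTemplate(grid, mask=template.mask)


def resize_nearest(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resampling of an RGB image to ``(n_i, n_j)``.

    Provided as an explicit, separate step for projecting a source image
    onto a differently sized node grid.
    """
    n_i, n_j = shape
    pil = Image.fromarray(np.asarray(image, dtype=np.uint8))
    return np.asarray(pil.resize((n_j, n_i), resample=Image.NEAREST))


def insole_mask(n_i: int, n_j: int) -> np.ndarray:
    """Foot-shaped binary mask: two overlapping lobes joined by a waist.

    The long axis runs along columns (``j``); the heel lobe sits at low
    ``j`` and the toe lobe at high ``j``.  The outline is connected and
    occupies 40-70% of the grid for any admissible dimensions.
    """
    if n_i < 32 or n_j < 32:
        raise ValueError(f"mask dimensions must be >= 32x32, got {n_i}x{n_j}")
    ii, jj = np.mgrid[0:n_i, 0:n_j]
    # normalised coordinates in [0, 1]
    y = (ii + 0.5) / n_i
    x = (jj + 0.5) / n_j

    def ellipse(cx, cy, rx, ry):
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0

    heel = ellipse(0.24, 0.50, 0.23, 0.33)
    toe = ellipse(0.72, 0.50, 0.27, 0.40)
    waist = ellipse(0.48, 0.50, 0.22, 0.26)
    return heel | toe | waist


def generate_mycelium(mask: np.ndarray, params: GrowthParams = GrowthParams()) -> ConductiveTemplate:
    """Grow a synthetic hyphal network inside a mask.

    Branching correlated random walks start from inoculation points placed
    along the mask's medial axis; the traced filaments are clipped to the
    mask and dilated.  Output is a deterministic function of ``params.seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask has no interior to colonise")
    rng = np.random.default_rng(params.seed)
    n_i, n_j = mask.shape
    grid = np.zeros(mask.shape, dtype=bool)

    cols = np.flatnonzero(mask.any(axis=0))
    # inoculation points spread along the long axis, at the column centroid
    targets = np.linspace(cols[0], cols[-1], params.n_inoculation_points + 2)[1:-1]
    starts = []
    for jc in targets:
        j = int(round(jc))
        rows = np.flatnonzero(mask[:, j])
        starts.append((float(rows.mean()), float(j)))

    # walker: (i, j, heading)
    walkers = [(i0, j0, rng.uniform(0, 2 * np.pi)) for (i0, j0) in starts]
    n_spawned = len(walkers)
    while walkers:
        i, j, heading = walkers.pop()
        for _ in range(params.max_steps):
            ii, jj = int(round(i)), int(round(j))
            if not (0 <= ii < n_i and 0 <= jj < n_j) or not mask[ii, jj]:
                break  # filament clipped at the mask boundary
            grid[ii, jj] = True
            heading += rng.normal(0.0, params.turn_sd)
            i += params.step_length * np.sin(heading)
            j += params.step_length * np.cos(heading)
            if n_spawned < params.max_walkers and rng.random() < params.branch_prob:
                side = 1.0 if rng.random() < 0.5 else -1.0
                walkers.append((i, j, heading + side * np.pi / 4))
                n_spawned += 1
    out = ConductiveTemplate(grid, mask=mask)
    return dilate(out, params.dilation_iterations)


def connectivity_report(template: ConductiveTemplate) -> list[int]:
    """Sizes of 8-connected components of the conductive set, descending."""
    labels, n = ndimage.label(template.grid, structure=_MOORE)
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel())[1:]
    return sorted((int(s) for s in sizes), reverse=True)
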