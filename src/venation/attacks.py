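"""Attack operators: random vein-pixel removal and circular-hole folivory.

Both attacks spare the structural vein absolutely and act only on the
attackable set (network pixels outside the structural vein).  The vein-level
attack abstracts damage to the veins themselves (embolism, bacterial
blockage); the blade-level attack is an idealized hole-feeding herbivore
punching 60-px circular holes out of the leaf blade, removing whatever vein
segments lie underneath.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .raster_io import LeafRaster

__all__ = ["AttackSpec", "DiscKernel", "disc_offsets", "vein_attack", "blade_attack"]

#: Hole size of the folivory attack, in pixels (10 um/px).
DEFAULT_HOLE_AREA_PX = 60


@dataclass(frozen=True)
class DiscKernel:
    """Pixel offsets of a rasterized disc, nearest-to-origin first.

    ``offsets`` is an (area, 2) integer array of (row, col) displacements.
    Construction guarantees no excluded lattice point lies strictly nearer
    the origin than any included one.
    """

    offsets: np.ndarray
    area: int


def disc_offsets(area_px: int) -> DiscKernel:
    """Build the disc kernel with exactly ``area_px`` pixels.

    Lattice points are ranked by squared Euclidean distance from the origin,
    ties broken lexicographically by (row, col), and the first ``area_px``
    taken.  Deterministic; for 60 px the result is a slightly asymmetric
    disc (3 of the 4 points at squared radius 18 are kept).
    """
    if area_px < 1:
        raise ValueError(f"area_px must be >= 1, got {area_px}")
    r = int(np.ceil(np.sqrt(area_px))) + 1
    g = np.arange(-r, r + 1)
    rr, cc = np.meshgrid(g, g, indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    d2 = (pts**2).sum(axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], d2))
    return DiscKernel(offsets=pts[order[:area_px]].copy(), area=area_px)


@dataclass(frozen=True)
class AttackSpec:
    """Serializable description of one attack.

    Exactly one of ``p`` (vein) or ``n_holes`` (blade) is set, matching
    ``kind``.
    """

    kind: str
    p: Optional[float] = None
    n_holes: Optional[int] = None
    hole_area_px: int = DEFAULT_HOLE_AREA_PX
    seed: int = 0

    def __post_init__(self):
        if self.kind == "vein":
            if self.p is None or self.n_holes is not None:
                raise ValueError("vein attack requires p and forbids n_holes")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"removal fraction p must lie in [0, 1], got {self.p}")
        elif self.kind == "blade":
            if self.n_holes is None or self.p is not None:
                raise ValueError("blade attack requires n_holes and forbids p")
            if self.n_holes < 0:
                raise ValueError(f"n_holes must be >= 0, got {self.n_holes}")
        else:
            raise ValueError(f"kind must be 'vein' or 'blade', got {self.kind!r}")
        if self.hole_area_px < 1:
            raise ValueError(f"hole_area_px must be >= 1, got {self.hole_area_px}")


def vein_attack(leaf: "LeafRaster", p: float, rng: np.random.Generator) -> np.ndarray:
    """Remove a fraction ``p`` of the attackable network pixels uniformly.

    Exactly ``round(p * n_original)`` pixels are sampled without replacement,
    so the remaining fraction equals ``p`` up to rounding and the draw is
    reproducible from the generator state.  Returns the damaged network mask;
    the structural mask is untouched by construction.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"removal fraction p must lie in [0, 1], got {p}")
    n_remove = int(round(p * leaf.n_original))
    damaged = leaf.network.copy()
    if n_remove > 0:
        candidates = np.flatnonzero(leaf.attackable.ravel())
        kill = rng.choice(candidates, size=n_remove, replace=False)
        damaged.ravel()[kill] = False
    return damaged


def blade_attack(
    leaf: "LeafRaster",
    n_holes: int,
    kernel: Optional[DiscKernel] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Punch ``n_holes`` circular holes into the leaf blade.

    Hole centres are drawn i.i.d. uniformly over the bounding box of the
    leaf's foreground (network plus structural vein) — the least speculative
    stand-in for the blade outline, which the rasters do not record.  Holes
    may extend past the image border (clipped); overlapping holes do not
    double-count; only attackable pixels are removed.
    """
    if n_holes < 0:
        raise ValueError(f"n_holes must be >= 0, got {n_holes}")
    damaged = leaf.network.copy()
    if n_holes == 0:
        return damaged
    if kernel is None:
        kernel = disc_offsets(DEFAULT_HOLE_AREA_PX)
    if rng is None:
        rng = np.random.default_rng()

    fg = leaf.network | leaf.structural
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])

    centre_r = rng.integers(r0, r1 + 1, size=n_holes)
    centre_c = rng.integers(c0, c1 + 1, size=n_holes)
    pix_r = (centre_r[:, None] + kernel.offsets[None, :, 0]).ravel()
    pix_c = (centre_c[:, None] + kernel.offsets[None, :, 1]).ravel()
    h, w = leaf.shape
    inside = (pix_r >= 0) & (pix_r < h) & (pix_c >= 0) & (pix_c < w)

    removal = np.zeros(leaf.shape, dtype=bool)
    removal[pix_r[inside], pix_c[inside]] = True
    damaged[removal & leaf.attackable] = False
    return damaged
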