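"""Parameterized synthetic venation rasters for the three venation classes.

The generators emulate the raster conventions of traced leaves — 10 um per
pixel, 3-px-wide network veins, a wide protected structural vein — while the
geometry itself is schematic: a rectangular pinnule-like blade with a
straight midrib.  What matters for the damage analysis is topology and
density, not outline fidelity:

``branched``
    laterals leave the midrib and dichotomize ``branch_depth`` times without
    ever reconnecting (a tree: zero loops, like *Rhacopteris*).
``net``
    laterals plus cross-veins form a polygonal mesh whose loop count equals
    the configured number of mesh cells (like *Linopteris*).
``hierarchical``
    a tapering midrib plus wide secondary veins (all structural) overlay a
    mesh twice as dense as the net class (like *Betula alba*).

Every generated leaf is fully 8-connected to its structural vein when
pristine; the generators verify this and fail loudly otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .connectivity import attached_fraction
from .raster_io import VENATION_CLASSES, LeafRaster

__all__ = [
    "SyntheticLeafSpec",
    "default_spec",
    "rasterize_polyline",
    "generate",
    "generate_branched",
    "generate_net",
    "generate_hierarchical",
    "net_loop_count",
    "branched_geometry",
]


@dataclass(frozen=True)
class SyntheticLeafSpec:
    """Parameters of a synthetic leaf.

    Defaults describe an elongate 6.4 x 1.2 mm pinnule at the standard
    magnification (640 x 120 px at 10 um/px) with 3-px network veins and a
    12-px midrib.  The blade is small enough that the standard attack
    intensities (removal fraction up to 1; up to 2000 holes of 60 px) sweep
    the full damage range, as the published response curves do.
    Class-specific fields: ``lateral_spacing``/``branch_depth`` (branched),
    ``mesh_cell`` (net and hierarchical), ``secondary_count``/
    ``secondary_width`` (hierarchical).  ``seed`` jitters vein placement so
    replicate leaves of one class differ without changing their topology.
    """

    venation_class: str
    height: int = 120
    width: int = 640
    margin: int = 16
    midrib_width: int = 12
    vein_width: int = 3
    lateral_spacing: int = 32
    branch_depth: int = 2
    mesh_cell: int = 16
    secondary_count: int = 9
    secondary_width: int = 5
    taxon: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.venation_class not in VENATION_CLASSES:
            raise ValueError(
                f"venation_class must be one of {VENATION_CLASSES}, "
                f"got {self.venation_class!r}"
            )
        for name in ("midrib_width", "vein_width", "secondary_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.height < 4 * self.margin or self.width < 4 * self.margin:
            raise ValueError(
                f"canvas {self.height}x{self.width} too small for margin {self.margin}"
            )

    @property
    def mid_row(self) -> int:
        return self.height // 2

    @property
    def half_run(self) -> int:
        """Vertical extent available to veins on each side of the midrib."""
        return self.mid_row - self.margin


def default_spec(venation_class: str, seed: int = 0, **overrides) -> SyntheticLeafSpec:
    """Build the default spec for a venation class.

    The hierarchical class defaults to a mesh denser than the net class
    (``mesh_cell`` 12 vs 16), mirroring the much higher minor-vein density
    of angiosperm leaves.
    """
    spec = SyntheticLeafSpec(
        venation_class=venation_class,
        taxon=f"synthetic-{venation_class}",
        seed=seed,
    )
    if venation_class == "hierarchical" and "mesh_cell" not in overrides:
        spec = replace(spec, mesh_cell=12)
    if overrides:
        spec = replace(spec, **overrides)
    return spec


# ---------------------------------------------------------------------------
# Rasterization

def _stroke(out: np.ndarray, p0, p1, width: float) -> None:
    """OR into ``out`` all pixels within width/2 of the segment p0 -> p1."""
    half = width / 2.0
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    h, w = out.shape
    r_lo = max(0, int(np.floor(min(p0[0], p1[0]) - half)))
    r_hi = min(h - 1, int(np.ceil(max(p0[0], p1[0]) + half)))
    c_lo = max(0, int(np.floor(min(p0[1], p1[1]) - half)))
    c_hi = min(w - 1, int(np.ceil(max(p0[1], p1[1]) + half)))
    if r_lo > r_hi or c_lo > c_hi:
        return
    rr = np.arange(r_lo, r_hi + 1, dtype=float)
    cc = np.arange(c_lo, c_hi + 1, dtype=float)
    R, C = np.meshgrid(rr, cc, indexing="ij")
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0.0:
        dist2 = (R - p0[0]) ** 2 + (C - p0[1]) ** 2
    else:
        t = np.clip(((R - p0[0]) * d[0] + (C - p0[1]) * d[1]) / len2, 0.0, 1.0)
        dist2 = (R - (p0[0] + t * d[0])) ** 2 + (C - (p0[1] + t * d[1])) ** 2
    out[r_lo : r_hi + 1, c_lo : c_hi + 1] |= dist2 <= half * half + 1e-9
    # Thin strokes may slip between pixel centres; a dense sample along the
    # segment, rounded to nearest pixels, guarantees an 8-connected spine.
    n_steps = max(2, int(np.ceil(np.sqrt(len2) / 0.4)) + 1)
    ts = np.linspace(0.0, 1.0, n_steps)
    spine_r = np.rint(p0[0] + ts * d[0]).astype(int)
    spine_c = np.rint(p0[1] + ts * d[1]).astype(int)
    keep = (spine_r >= 0) & (spine_r < h) & (spine_c >= 0) & (spine_c < w)
    out[spine_r[keep], spine_c[keep]] = True


def rasterize_polyline(points, width: float, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polyline: all pixels within width/2 of it are set.

    ``points`` is a sequence of (row, col) vertices (a single point draws a
    dot).  The result is one 8-connected component for any width >= 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("polyline needs at least one point")
    pts = pts.reshape(-1, 2)
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    out = np.zeros(shape, dtype=bool)
    if len(pts) == 1:
        _stroke(out, pts[0], pts[0], width)
    else:
        for a, b in zip(pts[:-1], pts[1:]):
            _stroke(out, a, b, width)
    return out


# ---------------------------------------------------------------------------
# Branched (tree) venation

def _branched_layout(spec: SyntheticLeafSpec) -> dict:
    """Deterministic layout (lateral positions, split heights, spreads)."""
    rng = np.random.default_rng(spec.seed)
    depth = spec.branch_depth
    if depth < 1:
        raise ValueError(f"branch_depth must be >= 1, got {depth}")
    # Horizontal half-spreads of successive dichotomies; halve each level.
    base = spec.lateral_spacing * 3 / 16
    spreads = [max(2, int(round(base / 2**k))) for k in range(depth)]
    span_half = sum(spreads) + spec.vein_width  # fan half-extent incl. stroke
    if 2 * span_half + 4 > spec.lateral_spacing:
        raise ValueError(
            f"branch fan of half-extent {span_half} px does not fit the "
            f"lateral spacing {spec.lateral_spacing} px"
        )
    if 2 * spreads[-1] < 4:
        raise ValueError("terminal branches would touch: reduce branch_depth")
    x_lo = spec.margin + span_half
    x_hi = spec.width - spec.margin - span_half
    if x_hi < x_lo:
        raise ValueError("canvas too narrow for any lateral")
    xs = np.arange(x_lo, x_hi + 1, spec.lateral_spacing)
    jitter = rng.integers(-3, 4, size=len(xs))
    xs = np.clip(xs + jitter, x_lo, x_hi)

    run = spec.half_run
    fracs = [1.0 - 0.65 ** (k + 1) for k in range(depth)]
    if run < 8 * depth:
        raise ValueError(f"blade half-height {run} px too small for depth {depth}")
    return {"xs": xs, "run": run, "fracs": fracs, "spreads": spreads}


def branched_geometry(spec: SyntheticLeafSpec) -> dict:
    """Expose the branched layout: lateral x positions, split rows, spreads.

    ``split_rows_up``/``split_rows_down`` list the rows of the successive
    dichotomies (first bifurcation first); ``tip_row_up``/``tip_row_down``
    are the rows where terminal branches end.
    """
    lay = _branched_layout(spec)
    mid = spec.mid_row
    run, fracs = lay["run"], lay["fracs"]
    return {
        "xs": lay["xs"],
        "spreads": lay["spreads"],
        "split_rows_up": [mid - int(round(f * run)) for f in fracs],
        "split_rows_down": [mid + int(round(f * run)) for f in fracs],
        "tip_row_up": mid - run,
        "tip_row_down": mid + run,
    }


def _fan_segments(x: int, levels: list[int], tip: int, spreads: list[int]) -> list:
    """Axis-aligned segments of one dichotomizing fan (a tree, never rejoining)."""
    segments = []

    def rec(cx: float, k: int) -> None:
        if k == len(levels):
            segments.append(((levels[-1] if levels else None, cx), (tip, cx)))
            return
        y_from = levels[k - 1] if k > 0 else None
        segments.append(((y_from, cx), (levels[k], cx)))
        h = spreads[k]
        segments.append(((levels[k], cx - h), (levels[k], cx + h)))
        rec(cx - h, k + 1)
        rec(cx + h, k + 1)

    rec(float(x), 0)
    return segments


def generate_branched(spec: SyntheticLeafSpec) -> LeafRaster:
    """Branched (open) venation: midrib plus dichotomizing laterals, no loops."""
    lay = _branched_layout(spec)
    mid = spec.mid_row
    structural = rasterize_polyline(
        [(mid, spec.margin), (mid, spec.width - spec.margin)],
        spec.midrib_width,
        (spec.height, spec.width),
    )
    network = np.zeros((spec.height, spec.width), dtype=bool)
    for sign in (-1, +1):
        levels = [mid + sign * int(round(f * lay["run"])) for f in lay["fracs"]]
        tip = mid + sign * lay["run"]
        for x in lay["xs"]:
            for (y0, c0), (y1, c1) in _fan_segments(int(x), levels, tip, lay["spreads"]):
                _stroke(network, (mid if y0 is None else y0, c0), (y1, c1), spec.vein_width)
    return _finish(spec, network, structural)


# ---------------------------------------------------------------------------
# Mesh (net and hierarchical) venation

def _mesh_counts(spec: SyntheticLeafSpec) -> tuple[int, int]:
    """(number of vertical lines, number of cross-veins per side) for a mesh."""
    cell = spec.mesh_cell
    if cell < spec.vein_width + 4:
        raise ValueError(f"mesh_cell {cell} px too small for {spec.vein_width}-px veins")
    n_vx = (spec.width - 2 * spec.margin) // cell + 1
    n_h = spec.half_run // cell
    if n_vx < 2 or n_h < 1:
        raise ValueError(f"canvas too small for mesh_cell {cell}")
    return n_vx, n_h


def net_loop_count(spec: SyntheticLeafSpec) -> int:
    """Mesh cells the generator constructs: loops of the pristine net leaf."""
    n_vx, n_h = _mesh_counts(spec)
    return 2 * (n_vx - 1) * n_h


def _mesh_layout(spec: SyntheticLeafSpec, rng: np.random.Generator) -> dict:
    """Jittered mesh line positions; counts are invariant to the jitter."""
    cell = spec.mesh_cell
    n_vx, n_h = _mesh_counts(spec)
    xs = spec.margin + np.arange(n_vx) * cell
    dx_max = min(cell // 4, spec.width - spec.margin - int(xs[-1]))
    xs = xs + int(rng.integers(0, dx_max + 1))
    mid = spec.mid_row
    ys = {}
    for sign in (-1, +1):
        slack = spec.half_run - n_h * cell
        dy = int(rng.integers(0, min(cell // 4, slack) + 1))
        ys[sign] = [mid + sign * (k * cell + dy) for k in range(1, n_h + 1)]
    return {"xs": xs, "ys": ys, "n_vx": n_vx, "n_h": n_h}


def _draw_mesh(spec: SyntheticLeafSpec, lay: dict, out: np.ndarray) -> None:
    mid = spec.mid_row
    xs = lay["xs"]
    for sign in (-1, +1):
        outer = lay["ys"][sign][-1]
        for x in xs:
            _stroke(out, (mid, x), (outer, x), spec.vein_width)
        for y in lay["ys"][sign]:
            _stroke(out, (y, xs[0]), (y, xs[-1]), spec.vein_width)


def generate_net(spec: SyntheticLeafSpec) -> LeafRaster:
    """Net-like reticulate venation: a polygonal mesh anchored on the midrib.

    Every contact between veins is drawn at full raster width, so all mesh
    contacts are functional loops; the pristine leaf has exactly
    :func:`net_loop_count` holes.
    """
    rng = np.random.default_rng(spec.seed)
    mid = spec.mid_row
    structural = rasterize_polyline(
        [(mid, spec.margin), (mid, spec.width - spec.margin)],
        spec.midrib_width,
        (spec.height, spec.width),
    )
    network = np.zeros((spec.height, spec.width), dtype=bool)
    _draw_mesh(spec, _mesh_layout(spec, rng), network)
    return _finish(spec, network, structural)


def generate_hierarchical(spec: SyntheticLeafSpec) -> LeafRaster:
    """Hierarchical reticulate venation: tapering midrib, wide secondaries,
    and a minor-vein mesh denser than the net class.

    The midrib tapers from ``midrib_width`` at the base to 4 px at the tip;
    ``secondary_count`` secondary veins of ``secondary_width`` px cross the
    blade.  Midrib and secondaries are all structural (protected), so the
    network has many independent attachment points.
    """
    rng = np.random.default_rng(spec.seed)
    mid = spec.mid_row
    h, w = spec.height, spec.width
    x0, x1 = spec.margin, w - spec.margin

    structural = np.zeros((h, w), dtype=bool)
    widths = np.linspace(spec.midrib_width, 4, 4)
    xs_seg = np.linspace(x0, x1, 5)
    for k in range(4):
        _stroke(structural, (mid, xs_seg[k]), (mid, xs_seg[k + 1]), float(widths[k]))

    n_s = spec.secondary_count
    if n_s < 2:
        raise ValueError(f"secondary_count must be >= 2, got {n_s}")
    gap = (x1 - x0) / (n_s + 1)
    for i in range(1, n_s + 1):
        x = x0 + i * gap + int(rng.integers(-3, 4))
        x = float(np.clip(x, x0 + 4, x1 - 4))
        _stroke(structural, (spec.margin, x), (h - spec.margin, x), spec.secondary_width)

    network = np.zeros((h, w), dtype=bool)
    _draw_mesh(spec, _mesh_layout(spec, rng), network)
    return _finish(spec, network, structural)


_GENERATORS = {
    "branched": generate_branched,
    "net": generate_net,
    "hierarchical": generate_hierarchical,
}


def generate(spec: SyntheticLeafSpec) -> LeafRaster:
    """Generate the leaf described by ``spec`` (dispatch on venation class)."""
    return _GENERATORS[spec.venation_class](spec)


def _finish(spec: SyntheticLeafSpec, network: np.ndarray, structural: np.ndarray) -> LeafRaster:
    """Assemble and validate: generated leaves must be fully attached."""
    leaf = LeafRaster(
        taxon=spec.taxon or f"synthetic-{spec.venation_class}",
        venation_class=spec.venation_class,
        network=network,
        structural=structural,
    )
    _, f_connected = attached_fraction(leaf.network, leaf.structural, leaf.n_original)
    if f_connected < 1.0:
        raise RuntimeError(
            f"generator bug: pristine attached fraction {f_connected} < 1 "
            f"for {spec.venation_class} spec {spec}"
        )
    return leaf
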