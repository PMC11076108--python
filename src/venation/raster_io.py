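"""Loading, validation and persistence of binary leaf rasters and outcomes.

A leaf arrives as a pair of binary raster images at a standard magnification
of 10 um per pixel: one mask for the venation network (minor veins, 3 px
wide) and one for the structural vein (midrib, plus primary and secondary
veins in hierarchical leaves).  The structural vein is absolutely protected
during attacks; pixels present in both masks are classified as structural.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .connectivity import _STRUCTURES, _as_mask, attached_fraction

__all__ = [
    "VENATION_CLASSES",
    "LeafRaster",
    "PristineReport",
    "load_leaf",
    "save_mask",
    "pristine_report",
    "prune_small_components",
    "rescale_nearest",
    "write_outcomes",
    "read_outcomes",
]

VENATION_CLASSES = ("branched", "net", "hierarchical")

#: Columns of the outcomes CSV interchange format.
OUTCOME_COLUMNS = ("taxon", "attack_kind", "param", "seed", "f_remain", "f_connected")


@dataclass
class LeafRaster:
    """A taxon's binary venation-network and structural-vein masks.

    Attributes
    ----------
    taxon : str
        Label for the leaf (e.g. a species name).
    venation_class : str
        One of ``branched``, ``net``, ``hierarchical``.
    network, structural : 2-D bool arrays of identical shape
    pixel_size_um : float
        Physical size of one pixel; 10 um at the standard magnification.

    The *attackable* set is ``network & ~structural`` and its pixel count
    ``n_original`` is fixed here at construction; all remaining/attached
    fractions are reported relative to it.
    """

    taxon: str
    venation_class: str
    network: np.ndarray
    structural: np.ndarray
    pixel_size_um: float = 10.0
    attackable: np.ndarray = field(init=False, repr=False)
    n_original: int = field(init=False)

    def __post_init__(self):
        if self.venation_class not in VENATION_CLASSES:
            raise ValueError(
                f"venation_class must be one of {VENATION_CLASSES}, "
                f"got {self.venation_class!r}"
            )
        self.network = np.ascontiguousarray(_as_mask(self.network))
        self.structural = np.ascontiguousarray(_as_mask(self.structural))
        if self.network.shape != self.structural.shape:
            raise ValueError(
                f"dimension mismatch: network {self.network.shape} vs "
                f"structural {self.structural.shape}"
            )
        if not self.network.any():
            raise ValueError("empty venation network")
        if not self.structural.any():
            raise ValueError("empty structural vein")
        self.attackable = self.network & ~self.structural
        self.n_original = int(self.attackable.sum())
        if self.n_original == 0:
            raise ValueError(
                "attackable set is empty: venation network lies entirely "
                "within the structural vein"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.network.shape


def _binarize(img: np.ndarray, foreground: str) -> np.ndarray:
    """Map an image array to a boolean mask per the stated foreground convention.

    Any pixel on the foreground side of the mid-grey threshold maps to 1, all
    else to 0, so palette encodings of the same drawing binarize identically.
    """
    arr = np.asarray(img)
    if arr.ndim == 4:  # animated container: first frame
        arr = arr[0]
    if arr.ndim == 3 and arr.shape[-1] in (2, 3, 4):
        arr = arr[..., : min(arr.shape[-1], 3)].mean(axis=-1)
    elif arr.ndim == 3:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {np.asarray(img).shape}")
    if arr.dtype == bool:
        dark = ~arr
    else:
        if np.issubdtype(arr.dtype, np.integer):
            mid = (np.iinfo(arr.dtype).max + 1) / 2
        else:
            mid = 0.5
        dark = arr < mid
    if foreground == "dark":
        return dark
    if foreground == "light":
        return ~dark
    raise ValueError(f"foreground convention must be 'dark' or 'light', got {foreground!r}")


def load_leaf(
    network_image_path,
    structural_image_path,
    taxon: str,
    venation_class: str,
    foreground: str = "dark",
    prune_min_size: int = 0,
) -> LeafRaster:
    """Load a venation-network / structural-vein image pair into a LeafRaster.

    Parameters
    ----------
    network_image_path, structural_image_path : path-like
        Binary GIF or PNG images of identical dimensions.
    foreground : {'dark', 'light'}
        Which side of mid-grey is vein.  Published tracings are dark-on-light;
        the convention is explicit and never inferred, since GIF palettes vary.
    prune_min_size : int
        If positive, drop 8-connected network components smaller than this
        many pixels before analysis.  Off by default: the analysis pipeline
        does no cleaning, and stray disconnected pixels surface as a
        pristine-attached-fraction warning instead.
    """
    network = _binarize(iio.imread(network_image_path), foreground)
    structural = _binarize(iio.imread(structural_image_path), foreground)
    if network.shape != structural.shape:
        raise ValueError(
            f"dimension mismatch: {network_image_path} is {network.shape} but "
            f"{structural_image_path} is {structural.shape}"
        )
    if prune_min_size > 0:
        network = prune_small_components(network, prune_min_size)
    return LeafRaster(
        taxon=taxon,
        venation_class=venation_class,
        network=network,
        structural=structural,
    )


def save_mask(mask, path, foreground: str = "dark") -> None:
    """Write a boolean mask as a binary GIF/PNG (format from the extension)."""
    arr = _as_mask(mask)
    if foreground == "dark":
        img = np.where(arr, 0, 255).astype(np.uint8)
    elif foreground == "light":
        img = np.where(arr, 255, 0).astype(np.uint8)
    else:
        raise ValueError(f"foreground convention must be 'dark' or 'light', got {foreground!r}")
    iio.imwrite(path, img)


def prune_small_components(mask, min_size: int, connectivity: int = 8) -> np.ndarray:
    """Return a copy of ``mask`` with components smaller than ``min_size`` removed."""
    arr = _as_mask(mask)
    raw, n = ndimage.label(arr, structure=_STRUCTURES[connectivity])
    if n == 0:
        return arr.copy()
    sizes = np.bincount(raw.ravel(), minlength=n + 1)
    keep = sizes >= min_size
    keep[0] = False
    return keep[raw]


def rescale_nearest(mask, factor: float) -> np.ndarray:
    """Nearest-neighbour rescale of a binary mask.

    Utility only: analysis inputs are expected to arrive already rescaled to
    the standard magnification (10 um/px, 3-px network veins).
    """
    arr = _as_mask(mask)
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    h = max(1, int(round(arr.shape[0] * factor)))
    w = max(1, int(round(arr.shape[1] * factor)))
    rows = np.minimum((np.arange(h) / factor).astype(int), arr.shape[0] - 1)
    cols = np.minimum((np.arange(w) / factor).astype(int), arr.shape[1] - 1)
    return arr[np.ix_(rows, cols)]


@dataclass(frozen=True)
class PristineReport:
    """Summary counts and attachment of an undamaged leaf."""

    taxon: str
    n_network: int
    n_structural: int
    n_attackable: int
    pristine_attached_fraction: float


def pristine_report(leaf: LeafRaster) -> PristineReport:
    """Summarize an undamaged leaf; warn if its network is not fully attached.

    A pristine attached fraction below 1.0 means some traced network pixels
    have no 8-connected path to the structural vein (usually stray pixels from
    tracing); they can never count as attached in any attack.
    """
    _, f_connected = attached_fraction(leaf.network, leaf.structural, leaf.n_original)
    if f_connected < 1.0:
        warnings.warn(
            f"leaf {leaf.taxon!r}: pristine attached fraction is "
            f"{f_connected:.6f} < 1; some network pixels are disconnected "
            "from the structural vein before any attack",
            stacklevel=2,
        )
    return PristineReport(
        taxon=leaf.taxon,
        n_network=int(leaf.network.sum()),
        n_structural=int(leaf.structural.sum()),
        n_attackable=leaf.n_original,
        pristine_attached_fraction=f_connected,
    )


def write_outcomes(outcomes, path) -> None:
    """Write attack outcomes to CSV (lossless to >= 6 significant digits)."""
    rows = [
        {
            "taxon": o.taxon,
            "attack_kind": o.kind,
            "param": o.param,
            "seed": o.seed,
            "f_remain": o.f_remain,
            "f_connected": o.f_connected,
        }
        for o in outcomes
    ]
    frame = pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS))
    # shortest round-trip float representation: lossless read-back
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_outcomes(path):
    """Read an outcomes CSV written by :func:`write_outcomes`.

    Returns a list of :class:`venation.experiment.AttackOutcome`.  Malformed
    files raise ``ValueError`` naming the offending line.
    """
    from .experiment import AttackOutcome  # deferred: experiment imports this module's types

    try:
        frame = pd.read_csv(Path(path), float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed outcomes file {path}: {exc}") from exc
    missing = set(OUTCOME_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(
            f"malformed outcomes file {path}, line 1: missing columns {sorted(missing)}"
        )
    outcomes = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            outcomes.append(
                AttackOutcome(
                    f_remain=float(row.f_remain),
                    f_connected=float(row.f_connected),
                    kind=str(row.attack_kind),
                    param=float(row.param),
                    seed=int(row.seed),
                    taxon=str(row.taxon),
                )
            )
        except (TypeError, ValueError) as exc:
            # +2: header line plus 1-based numbering.
            raise ValueError(f"malformed outcomes file {path}, line {i + 2}: {exc}") from exc
    return outcomes
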