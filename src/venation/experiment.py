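"""Randomized attack campaigns, binned response curves and the robustness score.

Each campaign repeats an attack many times (250 by default) with a randomly
drawn intensity: the removal fraction p ~ Uniform[0, 1] for vein attacks, the
hole count ~ discrete Uniform{0..2000} for blade attacks.  Every outcome is a
point (f_remain, f_connected).  Outcomes are binned into 20 equal bins over
f_remain; the per-bin mean of f_connected traces the damage-response curve,
and the sum of the bin means approximates its integral — the robustness
score, on a 0 to 10.5 scale (10.0 is the graceful-degradation limit where no
damage ever disconnects anything).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .attacks import DEFAULT_HOLE_AREA_PX, DiscKernel, blade_attack, disc_offsets, vein_attack
from .connectivity import attached_fraction

if TYPE_CHECKING:  # pragma: no cover
    from .raster_io import LeafRaster

__all__ = [
    "ATTACK_KINDS",
    "AttackOutcome",
    "BinnedResponse",
    "RobustnessScore",
    "spawn_seed",
    "run_attacks",
    "bin_outcomes",
    "robustness_score",
]

ATTACK_KINDS = ("vein", "blade")

DEFAULT_N_ATTACKS = 250
DEFAULT_HOLE_RANGE = (0, 2000)
DEFAULT_N_BINS = 20


@dataclass(frozen=True)
class AttackOutcome:
    """One randomized attack's measured (f_remain, f_connected) pair."""

    f_remain: float
    f_connected: float
    kind: str
    param: float  # p for vein attacks, n_holes for blade attacks
    seed: int
    taxon: str = ""

    def __post_init__(self):
        if not 0.0 <= self.f_remain <= 1.0 or not 0.0 <= self.f_connected <= 1.0:
            raise ValueError(
                f"fractions must lie in [0, 1], got ({self.f_remain}, {self.f_connected})"
            )
        if self.f_connected > self.f_remain + 1e-12:
            raise ValueError(
                f"f_connected ({self.f_connected}) cannot exceed f_remain ({self.f_remain})"
            )


@dataclass(frozen=True)
class BinnedResponse:
    """Per-bin summary of outcomes over f_remain.

    Bin i covers [i/n, (i+1)/n); the last bin is closed at 1.  Empty bins
    carry count 0 and NaN mean/SD.  SD uses the population denominator
    (descriptive whiskers, not inferential intervals).
    """

    edges: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_bins,)
    means: np.ndarray  # (n_bins,), NaN where empty
    sds: np.ndarray  # (n_bins,), NaN where empty

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RobustnessScore:
    """Sum of the bin means: area-under-curve proxy on a 0-10.5 scale."""

    value: float
    kind: str = ""
    taxon: str = ""
    n_nonempty_bins: int = 0


def spawn_seed(*path: int) -> int:
    """Derive a reproducible child seed (< 2**31) from an integer path."""
    return int(np.random.SeedSequence(list(path)).generate_state(1)[0] & 0x7FFFFFFF)


def run_attacks(
    leaf: "LeafRaster",
    kind: str,
    n_attacks: int = DEFAULT_N_ATTACKS,
    master_seed: int = 0,
    hole_range: tuple[int, int] = DEFAULT_HOLE_RANGE,
    hole_area_px: int = DEFAULT_HOLE_AREA_PX,
    kernel: Optional[DiscKernel] = None,
) -> list[AttackOutcome]:
    """Run a randomized attack campaign on one leaf.

    The master seed spawns one child seed per attack by counter, and each
    outcome records its own seed, so any individual attack can be replayed in
    isolation.  For ``kind='vein'`` the intensity is p ~ Uniform[0, 1]; for
    ``kind='blade'`` it is n_holes ~ discrete Uniform over ``hole_range``
    (inclusive).
    """
    if kind not in ATTACK_KINDS:
        raise ValueError(f"kind must be one of {ATTACK_KINDS}, got {kind!r}")
    if n_attacks < 0:
        raise ValueError(f"n_attacks must be >= 0, got {n_attacks}")
    if kind == "blade" and kernel is None:
        kernel = disc_offsets(hole_area_px)

    outcomes: list[AttackOutcome] = []
    for i in range(n_attacks):
        seed_i = spawn_seed(master_seed, i)
        rng = np.random.default_rng(seed_i)
        if kind == "vein":
            param: float = float(rng.uniform())
            damaged = vein_attack(leaf, param, rng)
        else:
            param = int(rng.integers(hole_range[0], hole_range[1] + 1))
            damaged = blade_attack(leaf, param, kernel=kernel, rng=rng)
        f_remain, f_connected = attached_fraction(damaged, leaf.structural, leaf.n_original)
        outcomes.append(
            AttackOutcome(
                f_remain=f_remain,
                f_connected=f_connected,
                kind=kind,
                param=param,
                seed=seed_i,
                taxon=leaf.taxon,
            )
        )
    return outcomes


def bin_outcomes(outcomes: Sequence[AttackOutcome], n_bins: int = DEFAULT_N_BINS) -> BinnedResponse:
    """Bin outcomes by f_remain into ``n_bins`` equal bins over [0, 1]."""
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    f_remain = np.array([o.f_remain for o in outcomes], dtype=float)
    f_connected = np.array([o.f_connected for o in outcomes], dtype=float)

    if len(outcomes) == 0:
        nan = np.full(n_bins, np.nan)
        return BinnedResponse(edges=edges, counts=np.zeros(n_bins, dtype=int),
                              means=nan.copy(), sds=nan.copy())

    idx = np.minimum((f_remain * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=f_connected, minlength=n_bins)
    sq_sums = np.bincount(idx, weights=f_connected**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
        variances = np.where(counts > 0, sq_sums / counts - means**2, np.nan)
    sds = np.sqrt(np.clip(variances, 0.0, None))
    return BinnedResponse(edges=edges, counts=counts.astype(int), means=means, sds=sds)


def robustness_score(
    binned: BinnedResponse, kind: str = "", taxon: str = ""
) -> RobustnessScore:
    """Sum the bin means of a binned response into a single robustness value.

    Empty bins contribute nothing (the mean of an empty bin is undefined);
    the score records how many bins contributed, and warns when fewer than
    all bins did — e.g. blade attacks on a large network may never reach low
    f_remain, which is surfaced rather than hidden.
    """
    nonempty = binned.counts > 0
    value = float(binned.means[nonempty].sum()) if nonempty.any() else 0.0
    n_nonempty = int(nonempty.sum())
    if n_nonempty < binned.n_bins:
        warnings.warn(
            f"robustness score for {taxon or 'leaf'}/{kind or 'attack'} summed over "
            f"{n_nonempty}/{binned.n_bins} non-empty bins",
            stacklevel=2,
        )
    return RobustnessScore(value=value, kind=kind, taxon=taxon, n_nonempty_bins=n_nonempty)
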