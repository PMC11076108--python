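"""End-to-end campaign runner: leaves x attack kinds x replicates -> tables.

A campaign is a pure function of (config, input rasters, master seed).  For
each leaf and attack kind it writes the raw outcomes, the 20-bin response
curve, and contributes one row to the robustness table; optional figures
mirror the standard response-curve plot (crosses for attacks, circles and
whiskers for bin means and SDs, a dashed trendline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import raster_io
from .experiment import (
    ATTACK_KINDS,
    DEFAULT_HOLE_RANGE,
    DEFAULT_N_ATTACKS,
    DEFAULT_N_BINS,
    BinnedResponse,
    bin_outcomes,
    robustness_score,
    run_attacks,
    spawn_seed,
)
from .attacks import DEFAULT_HOLE_AREA_PX, disc_offsets
from .raster_io import LeafRaster, load_leaf
from .synthetic_leaves import SyntheticLeafSpec, default_spec, generate

__all__ = ["LeafEntry", "RunConfig", "CampaignResult", "run_campaign", "plot_response"]

log = logging.getLogger("venation.pipeline")


@dataclass(frozen=True)
class LeafEntry:
    """One leaf of a campaign: either an image pair on disk or a synthetic spec."""

    taxon: str
    venation_class: str
    network_path: Optional[str] = None
    structural_path: Optional[str] = None
    synthetic: Optional[SyntheticLeafSpec] = None
    foreground: str = "dark"

    def __post_init__(self):
        from_files = self.network_path is not None and self.structural_path is not None
        if from_files == (self.synthetic is not None):
            raise ValueError(
                f"leaf {self.taxon!r}: provide either an image pair or a "
                "synthetic spec, not both"
            )


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of a full campaign."""

    leaves: Sequence[LeafEntry] = ()
    attack_kinds: Sequence[str] = ATTACK_KINDS
    n_attacks: int = DEFAULT_N_ATTACKS
    hole_range: tuple[int, int] = DEFAULT_HOLE_RANGE
    hole_area_px: int = DEFAULT_HOLE_AREA_PX
    n_bins: int = DEFAULT_N_BINS
    master_seed: int = 0
    out_dir: str = "campaign-out"
    make_plots: bool = False

    def __post_init__(self):
        for kind in self.attack_kinds:
            if kind not in ATTACK_KINDS:
                raise ValueError(f"unknown attack kind {kind!r}")
        if self.n_attacks < 0 or self.n_bins < 1 or self.hole_area_px < 1:
            raise ValueError("campaign parameters must be positive where required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        leaves = []
        for entry in raw.pop("leaves", []):
            synth = entry.pop("synthetic", None)
            if synth is not None:
                synth = default_spec(
                    entry["venation_class"],
                    taxon=entry.get("taxon", ""),
                    **synth,
                )
            leaves.append(LeafEntry(synthetic=synth, **entry))
        if "hole_range" in raw:
            raw["hole_range"] = tuple(raw["hole_range"])
        return cls(leaves=tuple(leaves), **raw)


@dataclass
class CampaignResult:
    """Outputs of a campaign run."""

    robustness: pd.DataFrame
    out_dir: Path
    outcome_files: dict = field(default_factory=dict)
    binned_files: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def _load_entry(entry: LeafEntry) -> LeafRaster:
    if entry.synthetic is not None:
        return generate(entry.synthetic)
    return load_leaf(
        entry.network_path,
        entry.structural_path,
        taxon=entry.taxon,
        venation_class=entry.venation_class,
        foreground=entry.foreground,
    )


def _slug(taxon: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in taxon)


def binned_frame(binned: BinnedResponse) -> pd.DataFrame:
    """Tabulate a binned response (bin interval, count, mean, SD)."""
    return pd.DataFrame(
        {
            "bin_lo": binned.edges[:-1],
            "bin_hi": binned.edges[1:],
            "count": binned.counts,
            "mean_f_connected": binned.means,
            "sd_f_connected": binned.sds,
        }
    )


def run_campaign(config: RunConfig) -> CampaignResult:
    """Run every (leaf, attack kind) pair of the config and write all tables.

    A leaf that fails its load invariants is logged and skipped; the campaign
    continues with the remaining leaves.  Deterministic given the master
    seed: per-(leaf, kind) seeds are spawned by counter and logged.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "campaign.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    kernel = disc_offsets(config.hole_area_px)
    result = CampaignResult(robustness=pd.DataFrame(), out_dir=out_dir)
    rows = []
    try:
        for leaf_idx, entry in enumerate(config.leaves):
            try:
                leaf = _load_entry(entry)
                report = raster_io.pristine_report(leaf)
            except Exception as exc:  # noqa: BLE001 - one bad leaf must not kill the campaign
                log.error("leaf %r failed to load: %s", entry.taxon, exc)
                result.failures.append((entry.taxon, str(exc)))
                continue
            log.info(
                "leaf %r (%s): %d network px, %d structural px, %d attackable, "
                "pristine attached fraction %.6f",
                leaf.taxon, leaf.venation_class, report.n_network,
                report.n_structural, report.n_attackable,
                report.pristine_attached_fraction,
            )
            for kind_idx, kind in enumerate(config.attack_kinds):
                seed = spawn_seed(config.master_seed, leaf_idx, kind_idx)
                log.info("attacking %r with %s campaign, master seed %d, %d attacks",
                         leaf.taxon, kind, seed, config.n_attacks)
                outcomes = run_attacks(
                    leaf, kind,
                    n_attacks=config.n_attacks,
                    master_seed=seed,
                    hole_range=config.hole_range,
                    hole_area_px=config.hole_area_px,
                    kernel=kernel if kind == "blade" else None,
                )
                binned = bin_outcomes(outcomes, n_bins=config.n_bins)
                score = robustness_score(binned, kind=kind, taxon=leaf.taxon)

                stem = f"{_slug(leaf.taxon)}_{kind}"
                outcome_path = out_dir / f"{stem}_outcomes.csv"
                raster_io.write_outcomes(outcomes, outcome_path)
                binned_path = out_dir / f"{stem}_binned.csv"
                binned_frame(binned).to_csv(binned_path, index=False, float_format="%.12g")
                result.outcome_files[(leaf.taxon, kind)] = outcome_path
                result.binned_files[(leaf.taxon, kind)] = binned_path
                if config.make_plots:
                    plot_response(binned, outcomes, out_dir / f"{stem}_response.png")
                rows.append(
                    {
                        "taxon": leaf.taxon,
                        "venation_class": leaf.venation_class,
                        "attack_kind": kind,
                        "robustness": score.value,
                        "n_nonempty_bins": score.n_nonempty_bins,
                        "n_attacks": len(outcomes),
                        "seed": seed,
                    }
                )
    finally:
        log.removeHandler(handler)
        handler.close()

    result.robustness = pd.DataFrame(
        rows,
        columns=["taxon", "venation_class", "attack_kind", "robustness",
                 "n_nonempty_bins", "n_attacks", "seed"],
    )
    result.robustness.to_csv(out_dir / "robustness.csv", index=False, float_format="%.12g")
    return result


def plot_response(binned: BinnedResponse, outcomes, path=None):
    """Standard response-curve figure.

    Crosses: individual attacks; closed circles: bin means; whiskers: bin
    SDs; dashed line: trendline through the means.  Both axes span [0, 1].
    Figures are output artifacts only — no analysis value is read off them.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    if len(outcomes):
        ax.plot(
            [o.f_remain for o in outcomes],
            [o.f_connected for o in outcomes],
            "x", color="0.6", ms=4, mew=0.8, label="attacks",
        )
    centres = (binned.edges[:-1] + binned.edges[1:]) / 2
    filled = binned.counts > 0
    if filled.any():
        ax.errorbar(
            centres[filled], binned.means[filled], yerr=binned.sds[filled],
            fmt="o", color="k", ms=4, capsize=2, lw=1, label="bin mean ± SD",
        )
        ax.plot(centres[filled], binned.means[filled], "k--", lw=1)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("fraction of venation network remaining")
    ax.set_ylabel("fraction attached to structural vein")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
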