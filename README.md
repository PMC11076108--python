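# venation

Robustness of leaf venation networks to simulated damage.

Leaf venation comes in two broad architectures: open, dichotomously
*branching* trees (many ferns, *Ginkgo*) and *reticulate* (loopy) networks
(flowering plants, and — for the first time in the fossil record — some
Pennsylvanian seed ferns).  Loops provide alternative transport paths, so a
reticulate network can keep functioning when veins are severed by embolism,
bacterial blockage or chewing insects, while a branching network loses every
vein distal to a cut.  This package quantifies that contrast on binary
venation rasters: it attacks a traced venation network *in silico*, measures
how much of it stays connected to the protected structural vein, and
summarizes each leaf's damage response in a single robustness score.  It is
aimed at palaeobotanists and network scientists studying venation evolution,
and ships a parameterized synthetic-leaf generator so the whole pipeline can
be exercised without any tracing data.

## Model

A leaf is a pair of binary masks at 10 µm/pixel: the **venation network**
(minor veins, 3 px wide) and the **structural vein** (midrib, plus primary
and secondary veins in hierarchical leaves), which is absolutely protected.
With N = |network \ structural| the pristine attackable pixel count, an
attack produces a damaged network and the outcome pair

- *f_remain* — fraction of the N original pixels still present,
- *f_connected* — fraction of the N original pixels lying in an
  8-connected component (of damaged network ∪ structural vein) that touches
  the structural vein.

Two attack operators are provided, both sparing the structural vein:

- **vein attack** — remove exactly round(p·N) pixels uniformly at random
  (vein-level damage: embolism, blockage), p ∈ [0, 1];
- **blade attack** — punch n circular holes of 60 px area at uniform random
  centres over the leaf's bounding box (idealized hole-feeding folivory),
  n ∈ {0, …, 2000}.

A campaign repeats an attack 250 times with random intensity, bins the
outcomes into 20 equal bins of *f_remain*, and reports per-bin mean ± SD of
*f_connected*.  The **robustness score** R = Σ (20 bin means) approximates
the area under the damage-response curve: R = 10 is the graceful-degradation
limit (*f_connected* = *f_remain* everywhere), lower values mean the network
disconnects before it is destroyed.

The synthetic generator produces the three venation classes as pinnule-like
rasters with the same conventions: `branched` (loop-free dichotomizing
laterals), `net` (a polygonal mesh whose loop count equals its configured
cell count exactly), and `hierarchical` (tapering midrib plus wide
structural secondaries over a dense minor-vein mesh).

## Worked example

```python
import numpy as np
from venation import (default_spec, generate, pristine_report, vein_attack,
                      attached_fraction, run_attacks, bin_outcomes,
                      robustness_score)

leaf = generate(default_spec("net", seed=0))
rep = pristine_report(leaf)
print(f"{rep.taxon}: {rep.n_network} network px, {rep.n_structural} structural px,\n"
      f"               {rep.n_attackable} attackable, "
      f"pristine attached fraction {rep.pristine_attached_fraction:.2f}")

damaged = vein_attack(leaf, 0.25, np.random.default_rng(5))
f_remain, f_connected = attached_fraction(damaged, leaf.structural, leaf.n_original)
print(f"vein attack, p=0.25: f_remain={f_remain:.2f}, f_connected={f_connected:.2f}")

for kind in ("vein", "blade"):
    outcomes = run_attacks(leaf, kind, n_attacks=250, master_seed=0)
    score = robustness_score(bin_outcomes(outcomes), kind=kind)
    print(f"{kind} robustness: {score.value:.2f} "
          f"(over {score.n_nonempty_bins} non-empty bins)")
```

prints

```
synthetic-net: 14586 network px, 8017 structural px, 13069 attackable,
               pristine attached fraction 1.00
vein attack, p=0.25: f_remain=0.75, f_connected=0.73
vein robustness: 6.40 (over 20 non-empty bins)
blade robustness: 6.91 (over 19 non-empty bins)
```

Read: the pristine net leaf is fully attached; removing a quarter of its
vein pixels leaves 75% of the network present of which 73% is still
connected (the loops reroute around most cuts); over full randomized
campaigns the leaf scores 6.40 (vein) and 6.91 (blade) on the 0–10.5 scale.

The same pipeline runs from the shell — `venation generate` writes synthetic
mask images, `venation attack` runs a single attack, `venation campaign`
executes a config-driven experiment (leaves × attack kinds × replicates,
outcome/binned/robustness CSVs plus optional response-curve figures), and
`venation plot` renders a saved outcomes file.

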