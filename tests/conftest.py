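"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from venation import default_spec, generate, run_attacks

VENATION_CLASSES = ("branched", "net", "hierarchical")
ATTACK_KINDS = ("vein", "blade")

_OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)),
}


def flood_fill_labels(mask: np.ndarray, connectivity: int = 8):
    """Brute-force flood-fill labelling oracle, independent of the package.

    Scans row-major and grows each component with an explicit stack; labels
    are assigned in first-encounter order, so a correct implementation must
    reproduce the label grid exactly.
    """
    offsets = _OFFSETS[connectivity]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    n = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                n += 1
                labels[i, j] = n
                stack = [(i, j)]
                while stack:
                    a, b = stack.pop()
                    for da, db in offsets:
                        x, y = a + da, b + db
                        if 0 <= x < h and 0 <= y < w and mask[x, y] and labels[x, y] == 0:
                            labels[x, y] = n
                            stack.append((x, y))
    return labels, n


def flood_fill_holes(mask: np.ndarray) -> int:
    """Oracle for foreground holes: 4-connected background components
    that do not touch the image border."""
    bg = ~mask
    labels, n = flood_fill_labels(bg, connectivity=4)
    border = set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(labels[:, -1])
    border.discard(0)
    return n - len(border)


@pytest.fixture(scope="session")
def default_leaves():
    """One default synthetic leaf per venation class (seed 0)."""
    return {cls: generate(default_spec(cls, seed=0)) for cls in VENATION_CLASSES}


@pytest.fixture(scope="session")
def campaigns():
    """Full 250-attack campaigns: (class, kind, seed) -> (leaf, outcomes).

    Three generator seeds per class, both attack kinds, at the standard
    replicate count; shared across the invariant and pattern tests.
    """
    results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in (0, 1, 2):
            for cls in VENATION_CLASSES:
                leaf = generate(default_spec(cls, seed=seed))
                for kind_idx, kind in enumerate(ATTACK_KINDS):
                    outcomes = run_attacks(
                        leaf, kind, n_attacks=250, master_seed=seed * 100 + kind_idx
                    )
                    results[(cls, kind, seed)] = (leaf, outcomes)
    return results
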