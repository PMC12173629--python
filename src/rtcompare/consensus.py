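"""Consensus ("mean") structure from multiple observers' masks.

Each voxel's agreement is the fraction of observers occupying it; voxels with
agreement >= 0.5 form the consensus mask.  The threshold is inclusive, so
with an even number of observers an exact tie is included and the consensus
is a superset of strict majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import StructureMask

__all__ = ["ConsensusStructure", "mean_structure", "agreement_histogram"]


@dataclass
class ConsensusStructure:
    """Per-voxel observer agreement plus the >=0.5-thresholded mask."""

    agreement: np.ndarray
    mask: StructureMask
    n_observers: int


def mean_structure(masks: list[StructureMask], label: str | None = None) -> ConsensusStructure:
    """Build the consensus structure from one mask per observer.

    The per-voxel agreement is ``(# observers occupying the voxel) / n``;
    the consensus mask contains exactly the voxels with agreement >= 0.5.
    The result is invariant to observer ordering.  Thresholding is done on
    integer counts (``2 * count >= n``) so exact ties are never lost to
    floating-point rounding.
    """
    if not masks:
        raise ValueError("consensus of an empty observer list is undefined")
    grid = masks[0].grid
    counts = np.zeros(grid.dims, dtype=np.int32)
    for m in masks:
        if not m.grid.matches(grid):
            raise ValueError(f"mask {m.label!r} is on a different grid")
        counts += m.occupancy
    n = len(masks)
    agreement = counts / n
    occ = (2 * counts) >= n
    out_label = label or f"{masks[0].label}-mean"
    return ConsensusStructure(agreement, StructureMask(out_label, grid, occ), n)


def agreement_histogram(consensus: ConsensusStructure) -> dict[float, int]:
    """Voxel counts per agreement level, including the zero (background) level.

    Levels are the attainable fractions k/n for k = 0..n; absent levels are
    reported with count 0 so the histogram shape is predictable.
    """
    n = consensus.n_observers
    counts = np.rint(consensus.agreement * n).astype(np.int64)
    tally = np.bincount(counts.ravel(), minlength=n + 1)
    return {k / n: int(tally[k]) for k in range(n + 1)}
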