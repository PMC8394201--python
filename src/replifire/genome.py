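"""Potential-origin maps and firing-probability segmentation of the genome.

Coordinates are 0-based block indices with half-open intervals
``[start, end)``; one block represents 1 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OriginMap:
    """Positions of potential (licensed) replication origins.

    ``eligible`` is a boolean array over the lattice: in the continuous
    layout every block is a potential origin; in the discrete layout each
    block independently carries an origin with probability
    ``1 / mean_spacing``.
    """

    eligible: np.ndarray  # bool, shape (L,)
    layout: str = "continuous"

    @property
    def L(self) -> int:
        return self.eligible.size

    @property
    def n_origins(self) -> int:
        return int(np.count_nonzero(self.eligible))

    def origin_indices(self) -> np.ndarray:
        return np.flatnonzero(self.eligible)

    def mean_spacing(self) -> float:
        """Mean nearest-neighbour distance between consecutive origins (kb)."""
        idx = self.origin_indices()
        if idx.size < 2:
            return float("nan")
        return float(np.diff(idx).mean())


@dataclass
class RegionMask:
    """Per-block segmentation into high- (IN) and low- (OUT) probability blocks.

    Two construction modes are supported: *block-level*, where ``theta*L``
    individual blocks are chosen uniformly at random, and *region-level*,
    where contiguous non-overlapping regions covering a fraction ``theta``
    of the genome are placed at random.
    """

    is_in: np.ndarray  # bool, shape (L,)
    mode: str = "block"
    regions: list[tuple[int, int]] = field(default_factory=list)  # (start, length)

    @property
    def L(self) -> int:
        return self.is_in.size

    @property
    def n_in(self) -> int:
        return int(np.count_nonzero(self.is_in))

    @property
    def theta(self) -> float:
        return self.n_in / self.L

    def to_bed(self, path, chrom: str = "chrSim") -> None:
        """Write IN intervals as BED-like 3-column text."""
        x = np.asarray(self.is_in, dtype=np.int8)
        edges = np.flatnonzero(np.diff(x))
        starts = edges[x[edges] == 0] + 1
        ends = edges[x[edges] == 1] + 1
        if x[0]:
            starts = np.r_[0, starts]
        if x[-1]:
            ends = np.r_[ends, x.size]
        with open(path, "w") as fh:
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def generate_origin_map(
    L: int, layout: str, mean_spacing: float = 2.3, rng: np.random.Generator | None = None
) -> OriginMap:
    """Place potential origins on an ``L``-block lattice.

    Continuous layout: one potential origin per block (all eligible).
    Discrete layout: each block independently eligible with probability
    ``1 / mean_spacing``, giving the stated average origin density.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if layout == "continuous":
        return OriginMap(np.ones(L, dtype=bool), layout)
    if layout != "discrete":
        raise ValueError(f"unknown layout {layout!r}")
    if mean_spacing < 1:
        raise ValueError(f"mean_spacing must be >= 1 kb, got {mean_spacing}")
    if rng is None:
        rng = np.random.default_rng()
    eligible = rng.random(L) < 1.0 / mean_spacing
    return OriginMap(eligible, layout)


def generate_region_mask(
    L: int,
    theta: float,
    mode: str = "block",
    rng: np.random.Generator | None = None,
    region_length_max: int | None = None,
) -> RegionMask:
    """Segment the genome into IN (probability ``Pin``) and OUT blocks.

    Block-level mode labels exactly ``round(theta * L)`` uniformly chosen
    blocks IN.  Region-level mode draws region lengths uniformly in
    ``(0, region_length_max]`` until their sum reaches ``theta * L``, trims
    the last region to hit the target exactly, and places the regions
    without overlap by distributing the remaining OUT blocks as random
    inter-region gaps (uniform multinomial composition), which is feasible
    for every ``theta`` up to 1.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    if rng is None:
        rng = np.random.default_rng()
    target = int(round(theta * L))
    if target > L:
        raise ValueError("infeasible packing: theta*L exceeds L")
    is_in = np.zeros(L, dtype=bool)
    if mode == "block":
        if target:
            is_in[rng.choice(L, size=target, replace=False)] = True
        return RegionMask(is_in, "block")
    if mode != "region":
        raise ValueError(f"unknown mask mode {mode!r}")

    if region_length_max is None:
        region_length_max = max(1, L // 100)
    region_length_max = min(region_length_max, max(1, L))
    # Draw lengths until the cumulative coverage reaches the target, then
    # trim the final region so the total is exact.
    lengths: list[int] = []
    total = 0
    while total < target:
        li = int(rng.integers(1, region_length_max + 1))
        li = min(li, target - total)
        lengths.append(li)
        total += li
    # Distribute the OUT blocks as random gaps around the shuffled regions.
    order = rng.permutation(len(lengths))
    lengths = [lengths[i] for i in order]
    k = len(lengths)
    spare = L - total
    gaps = rng.multinomial(spare, np.full(k + 1, 1.0 / (k + 1))) if spare else np.zeros(k + 1, int)
    placed: list[tuple[int, int]] = []
    pos = 0
    for li, gap in zip(lengths, gaps[:-1]):
        pos += int(gap)
        is_in[pos : pos + li] = True
        placed.append((pos, li))
        pos += li
    return RegionMask(is_in, "region", placed)
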