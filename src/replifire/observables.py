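"""Replication observables measured on lattices and on single molecules.

Follows the standard DNA-combing conventions: an *eye* is a maximal
replicated track, a *gap* is the unreplicated stretch between two eyes and
the eye-to-eye distance is measured centre-to-centre between adjacent eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TrackAnnotation:
    """Eyes, gaps and eye-to-eye distances of one molecule (kb units)."""

    length: float
    eye_start: np.ndarray
    eye_end: np.ndarray
    gap_start: np.ndarray
    gap_end: np.ndarray
    eted: np.ndarray  # centre-to-centre distances between adjacent eyes

    @property
    def eye_lengths(self) -> np.ndarray:
        return self.eye_end - self.eye_start

    @property
    def gap_lengths(self) -> np.ndarray:
        return self.gap_end - self.gap_start

    @property
    def f(self) -> float:
        return float(self.eye_lengths.sum() / self.length)

    @property
    def n_eyes(self) -> int:
        return self.eye_start.size

    def interior_eye_count(self) -> int:
        """Eyes not touching either molecule end (carrying two visible forks)."""
        touch = (self.eye_start <= 0) | (self.eye_end >= self.length)
        return int(np.count_nonzero(~touch))

    def end_eye_count(self) -> int:
        """Eyes touching exactly one molecule end (one visible fork)."""
        left = self.eye_start <= 0
        right = self.eye_end >= self.length
        return int(np.count_nonzero(left ^ right))

    def to_frame(self, molecule_id=0) -> pd.DataFrame:
        rows = []
        for s, e in zip(self.eye_start, self.eye_end):
            rows.append((molecule_id, "eye", s, e, e - s))
        for s, e in zip(self.gap_start, self.gap_end):
            rows.append((molecule_id, "gap", s, e, e - s))
        for i, d in enumerate(self.eted):
            rows.append((molecule_id, "eted", np.nan, np.nan, d))
        return pd.DataFrame(
            rows, columns=["molecule_id", "kind", "start", "end", "length"]
        )


def replicated_fraction(x) -> float:
    """Replicated fraction: mean of the binary block values."""
    from .simulator import LatticeState

    if isinstance(x, LatticeState):
        return x.f
    arr = np.asarray(x)
    return float(arr.mean())


def initiation_rate(n1: float, f: float, L: float, dt: float = 3.0) -> float:
    """Origin-firing rate per unreplicated length per time:
    ``I = N1 / ((1 - f) * L * dt)``, in initiations kb^-1 min^-1."""
    if f >= 1.0:
        raise ZeroDivisionError(
            "initiation rate undefined on fully replicated DNA (f >= 1)"
        )
    return n1 / ((1.0 - f) * L * dt)


def fork_density(x) -> float:
    """Density of active forks: ('01' + '10' boundary count) / L."""
    from .simulator import LatticeState

    blocks = x.blocks if isinstance(x, LatticeState) else np.asarray(x)
    L = blocks.size
    n = int(np.count_nonzero(blocks[1:] != blocks[:-1]))
    return n / L


def annotate_intervals(
    eye_start: np.ndarray, eye_end: np.ndarray, length: float
) -> TrackAnnotation:
    """Build the full annotation from sorted, disjoint eye intervals."""
    eye_start = np.asarray(eye_start, dtype=float)
    eye_end = np.asarray(eye_end, dtype=float)
    # gaps: the complement of the eyes on [0, length]
    bounds_s = np.r_[0.0, eye_end]
    bounds_e = np.r_[eye_start, length]
    keep = bounds_e > bounds_s
    gap_start, gap_end = bounds_s[keep], bounds_e[keep]
    centres = (eye_start + eye_end) / 2.0
    eted = np.diff(centres)
    return TrackAnnotation(
        length=float(length),
        eye_start=eye_start,
        eye_end=eye_end,
        gap_start=gap_start,
        gap_end=gap_end,
        eted=eted,
    )


def extract_tracks(blocks: np.ndarray) -> TrackAnnotation:
    """Annotate a binary molecule: maximal 1-runs are eyes, 0-runs gaps."""
    blocks = np.asarray(blocks).astype(np.uint8)
    if blocks.size < 1:
        raise ValueError("molecule must span at least one block")
    x = blocks.astype(np.int8)
    step = np.diff(x)
    starts = np.flatnonzero(step == 1) + 1
    ends = np.flatnonzero(step == -1) + 1
    if x[0]:
        starts = np.r_[0, starts]
    if x[-1]:
        ends = np.r_[ends, x.size]
    return annotate_intervals(starts.astype(float), ends.astype(float), float(x.size))
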