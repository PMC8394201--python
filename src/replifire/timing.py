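"""Replication-timing profiles of a fictitious chromosome.

A chromosome carrying contiguous high-firing-probability (Pin) regions is
replicated repeatedly; the per-position replication time is pooled over
replicates, loess-smoothed and segmented into early/late constant timing
regions (CTRs) separated by timing transition regions (TTRs) -- the
structure reported by population replication-timing assays in human and
mouse cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .genome import RegionMask, generate_origin_map, generate_region_mask
from .parameters import ModelParameters, validate_parameters
from .simulator import init_state, step


@dataclass
class TimingProfile:
    """Pooled per-position replication timing (minutes) over replicates."""

    mean_time: np.ndarray  # minutes, shape (L,)
    firing_abundance: np.ndarray  # fraction of replicates firing at position
    mask: RegionMask
    params: ModelParameters
    replicates: int
    times: np.ndarray | None = None  # (replicates, L) rounds, optional
    event_position: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    event_round: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    event_replicate: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    smoothed: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.mean_time.size

    def event_minutes(self) -> np.ndarray:
        return self.event_round * self.params.round_minutes

    def to_bedgraph(self, path, chrom: str = "chrSim", smoothed: bool = False) -> None:
        vals = self.smoothed if smoothed and self.smoothed is not None else self.mean_time
        with open(path, "w") as fh:
            for i, v in enumerate(vals):
                fh.write(f"{chrom}\t{i}\t{i + 1}\t{v:.4f}\n")


@dataclass
class TimingSegments:
    """CTR/TTR segmentation: (start, end, class) tiles of the chromosome."""

    segments: list[tuple[int, int, str]]
    L: int

    CLASSES = ("early-CTR", "late-CTR", "TTR")

    def __post_init__(self):
        pos = 0
        for s, e, c in self.segments:
            if s != pos or e <= s or c not in self.CLASSES:
                raise ValueError("segments must tile the chromosome in order")
            pos = e
        if pos != self.L:
            raise ValueError("segments do not cover the chromosome")

    def count(self, cls: str) -> int:
        """Number of segments of a class; ``"CTR"`` counts both early and
        late constant timing regions."""
        return sum(
            1 for _, _, c in self.segments if c == cls or c.endswith(cls)
        )

    def class_of_positions(self) -> np.ndarray:
        out = np.empty(self.L, dtype=object)
        for s, e, c in self.segments:
            out[s:e] = c
        return out

    def total_length(self, cls: str) -> int:
        return sum(e - s for s, e, c in self.segments if c == cls or (cls == "CTR" and c.endswith("CTR")))

    def to_bed(self, path, chrom: str = "chrSim") -> None:
        with open(path, "w") as fh:
            for s, e, c in self.segments:
                fh.write(f"{chrom}\t{s}\t{e}\t{c}\n")


def simulate_timing(
    p: ModelParameters,
    chrom_L: int,
    replicates: int = 100,
    rng: np.random.Generator | int | None = None,
    n_regions: int | None = None,
    region_length_max: int | None = None,
    max_rounds: int = 100_000,
    keep_times: bool = False,
) -> TimingProfile:
    """Replicate a region-segmented chromosome ``replicates`` times and pool.

    The high-probability regions are contiguous (region-level mask), drawn
    once and shared by all replicates, so the pooled per-position mean
    replication time reflects the fixed genomic organization.  Each
    replicate records the round at which every block replicated and the
    origin-firing events (position, round).
    """
    validate_parameters(p)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if region_length_max is None:
        target = p.theta * chrom_L
        if n_regions:
            region_length_max = max(1, int(round(2.0 * target / n_regions)))
        else:
            region_length_max = max(1, chrom_L // 100)
    mask = generate_region_mask(
        chrom_L, p.theta if p.variant in ("MM4", "MM5") else 0.0,
        "region", rng, region_length_max,
    )
    times = np.empty((replicates, chrom_L), dtype=np.int32)
    fired_any = np.zeros((replicates, chrom_L), dtype=bool)
    ev_pos, ev_round, ev_rep = [], [], []
    for r in range(replicates):
        omap = generate_origin_map(chrom_L, p.origin_layout, p.mean_origin_spacing, rng)
        state = init_state(p, omap, mask)
        t_rep = np.full(chrom_L, -1, dtype=np.int32)
        while state.f < 1.0:
            if state.t >= max_rounds:
                raise RuntimeError(
                    f"replicate {r} did not complete within {max_rounds} rounds"
                )
            _, _, _, fired = step(state, p, omap, mask, rng)
            newly = (t_rep < 0) & (state.blocks == 1)
            t_rep[newly] = state.t
            if fired.size:
                fired_any[r, fired] = True
                ev_pos.append(fired.copy())
                ev_round.append(np.full(fired.size, state.t))
                ev_rep.append(np.full(fired.size, r))
        times[r] = t_rep
    mean_time = times.mean(axis=0) * p.round_minutes
    abundance = fired_any.mean(axis=0)
    return TimingProfile(
        mean_time=mean_time,
        firing_abundance=abundance,
        mask=mask,
        params=p,
        replicates=replicates,
        times=times if keep_times else None,
        event_position=np.concatenate(ev_pos) if ev_pos else np.empty(0, int),
        event_round=np.concatenate(ev_round) if ev_round else np.empty(0, int),
        event_replicate=np.concatenate(ev_rep) if ev_rep else np.empty(0, int),
    )


def smooth_profile(profile, span: float = 0.02) -> np.ndarray:
    """Loess-smooth a timing profile (locally weighted regression).

    ``profile`` may be a TimingProfile (its smoothed field is filled in)
    or a plain array of per-position values; ``span`` is the loess window
    as a fraction of the chromosome.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    values = profile.mean_time if isinstance(profile, TimingProfile) else np.asarray(profile, float)
    x = np.arange(values.size, dtype=float)
    sm_vals = sm.nonparametric.lowess(
        values, x, frac=span, it=0, return_sorted=False
    )
    if isinstance(profile, TimingProfile):
        profile.smoothed = sm_vals
    return sm_vals


def segment_ctr_ttr(
    smoothed: np.ndarray,
    slope_threshold: float = 0.5,
    min_len: int = 10,
    rise_threshold: float | None = None,
) -> TimingSegments:
    """Segment a smoothed timing profile into early/late CTRs and TTRs.

    Positions where |d timing / d position| stays below ``slope_threshold``
    (minutes per kb) over a run of at least ``min_len`` kb form constant
    timing regions, classed early or late against the chromosome median
    timing.  Any other run is a timing transition region when its net
    timing change is at least ``rise_threshold`` minutes (default: 20% of
    the profile range); smaller excursions are local noise and are
    absorbed into the neighbouring plateau.  The segments tile the
    chromosome.
    """
    if slope_threshold <= 0 or min_len <= 0:
        raise ValueError("slope_threshold and min_len must be positive")
    v = np.asarray(smoothed, dtype=float)
    L = v.size
    if rise_threshold is None:
        rise_threshold = 0.2 * float(v.max() - v.min())
    slope = np.gradient(v)
    flat = np.abs(slope) < slope_threshold
    median = np.median(v)
    # run-length scan over the flat mask
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, L]
    raw: list[list] = []
    for s, e in zip(starts, ends):
        is_ctr = bool(flat[s]) and (e - s) >= min_len
        if is_ctr:
            cls = "early-CTR" if np.mean(v[s:e]) <= median else "late-CTR"
        elif abs(v[e - 1] - v[s]) >= rise_threshold:
            cls = "TTR"
        else:
            cls = None  # local noise, absorbed below
        raw.append([int(s), int(e), cls])
    for k, (s, e, cls) in enumerate(raw):
        if cls is None:
            prev = next(
                (raw[j][2] for j in range(k - 1, -1, -1) if raw[j][2]), None
            )
            nxt = next(
                (raw[j][2] for j in range(k + 1, len(raw)) if raw[j][2]), None
            )
            raw[k][2] = prev or nxt or "TTR"
    out: list[tuple[int, int, str]] = []
    for s, e, c in raw:
        if out and out[-1][2] == c:
            out[-1] = (out[-1][0], e, c)
        else:
            out.append((s, e, c))
    return TimingSegments(out, L)


def event_density_by_class(
    profile: TimingProfile,
    segments: TimingSegments,
    early_quantile: float | None = None,
) -> dict[str, float]:
    """Origin-firing event density (events per kb per replicate) in CTRs
    vs. TTRs.

    With ``early_quantile`` set, only events firing within that initial
    fraction of the S-phase time axis (between the first and last firing
    round) are counted — e.g. 0.25 selects origins firing in the first
    quarter of S phase.
    """
    pos = profile.event_position
    rounds = profile.event_round
    if early_quantile is not None and rounds.size:
        rmin, rmax = rounds.min(), rounds.max()
        cut = rmin + early_quantile * (rmax - rmin)
        keep = rounds <= cut
        pos = pos[keep]
    cls = segments.class_of_positions()
    out = {}
    for name in ("CTR", "TTR"):
        if name == "CTR":
            in_cls = np.array([c.endswith("CTR") for c in cls])
        else:
            in_cls = cls == "TTR"
        span = int(np.count_nonzero(in_cls))
        n = int(np.count_nonzero(in_cls[pos])) if pos.size else 0
        out[name] = n / span / profile.replicates if span else float("nan")
    return out
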