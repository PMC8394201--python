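"""Dynamic Monte Carlo engine for one S phase on the block lattice.

One round of calculation represents ``round_minutes`` (default 2 min).  Per
round, every unreplicated origin-eligible block draws a uniform number that
is compared with its local firing probability (``Pout``, ``Pin`` or
``Plocal``); the number of actual firings is capped by the free
limiting-factor pool ``Nf(t) = N0 + J*t - Nb``; existing replication eyes
then grow symmetrically at the fork speed, coalescing when forks meet, and
each coalescence returns one sequestered factor to the pool (a fork
terminating at a lattice end returns half a factor, so the two ends of a
molecule jointly return one).

Factor bookkeeping is derived exactly from the lattice: the number of bound
factors equals the number of replication eyes minus half a factor for each
already-replicated lattice end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import OriginMap, RegionMask, generate_origin_map, generate_region_mask
from .parameters import ModelParameters, validate_parameters

_LOCAL_VARIANTS = ("MM3", "MM5")


@dataclass
class LatticeState:
    """Mutable replication state of the lattice."""

    blocks: np.ndarray  # uint8, 1 = replicated
    t: int = 0
    fired_total: int = 0
    released_total: float = 0.0

    @property
    def L(self) -> int:
        return self.blocks.size

    @property
    def nb(self) -> float:
        """Bound factors, Nb = fired_total - released_total."""
        return self.fired_total - self.released_total

    @property
    def replicated_blocks(self) -> int:
        return int(np.count_nonzero(self.blocks))

    @property
    def f(self) -> float:
        return self.replicated_blocks / self.L

    @property
    def boundary_count(self) -> int:
        """Number of interior 0/1 boundaries = number of active forks."""
        b = self.blocks
        return int(np.count_nonzero(b[1:] != b[:-1]))

    @property
    def eye_count(self) -> int:
        b = self.blocks
        return (self.boundary_count + int(b[0]) + int(b[-1])) // 2

    def fork_positions(self) -> list[tuple[int, str]]:
        """Active forks as (block index of the fork's replicated edge, direction)."""
        b = self.blocks
        step = np.diff(b.astype(np.int8))
        right = np.flatnonzero(step == -1)  # "10": rightward fork at index i
        left = np.flatnonzero(step == 1) + 1  # "01": leftward fork at i+1
        out = [(int(i), "right") for i in right]
        out += [(int(i), "left") for i in left]
        return sorted(out)


@dataclass
class Trajectory:
    """Per-round record of one simulated S phase."""

    params: ModelParameters
    L: int
    seed: int | None
    rounds: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    f: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_initiations: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    n_new_blocks: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    fork_count: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    nb: np.ndarray = field(default_factory=lambda: np.empty(0))
    fired_total: int = 0
    released_total: float = 0.0
    completed: bool = True
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    event_rounds: np.ndarray | None = None
    event_positions: np.ndarray | None = None

    @property
    def minutes(self) -> np.ndarray:
        return self.rounds * self.params.round_minutes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": self.rounds,
                "minutes": self.minutes,
                "f": self.f,
                "n_initiations": self.n_initiations,
                "n_new_blocks": self.n_new_blocks,
                "fork_count": self.fork_count,
                "nb": self.nb,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def round_nearest_f(self, target: float) -> int:
        """Round index whose genome replicated fraction is nearest ``target``."""
        return int(self.rounds[np.argmin(np.abs(self.f - target))])


def init_state(
    p: ModelParameters, origin_map: OriginMap, region_mask: RegionMask
) -> LatticeState:
    """Fresh all-unreplicated lattice at round 0 with N0 factors available."""
    validate_parameters(p)
    if origin_map.L != region_mask.L:
        raise ValueError(
            f"origin map ({origin_map.L}) and region mask ({region_mask.L}) "
            "cover different lattice sizes"
        )
    return LatticeState(blocks=np.zeros(origin_map.L, dtype=np.uint8))


def force_fire(state: LatticeState, blocks: np.ndarray | list[int]) -> LatticeState:
    """Manually fire origins at the given block indices (testing/seeding aid)."""
    idx = np.asarray(blocks, dtype=np.intp)
    if np.any(state.blocks[idx]):
        raise ValueError("cannot fire an already-replicated block")
    state.blocks[idx] = 1
    state.fired_total += idx.size
    return state


def fork_proximal_zone(state: LatticeState, d: float) -> np.ndarray:
    """Boolean mask of unreplicated blocks within ``d`` blocks ahead of a fork.

    "Ahead" means the fork's direction of travel; the zone is truncated at
    lattice ends and at the next replicated block, which is equivalent to
    selecting unreplicated blocks whose distance to the nearest replicated
    block on the relevant side is at most ``d``.
    """
    L = state.L
    d = int(round(d))
    if d <= 0:
        return np.zeros(L, dtype=bool)
    starts, ends = _runs(state.blocks)
    if starts.size == 0:
        return np.zeros(L, dtype=bool)
    # rightward forks at eye ends: zone [end, end + d), truncated at the
    # next eye (or lattice end, where the fork has terminated)
    next_start = np.r_[starts[1:], L]
    rs = ends
    re = np.minimum(ends + d, next_start)
    # leftward forks at eye starts: zone [start - d, start), truncated at
    # the previous eye
    prev_end = np.r_[0, ends[:-1]]
    ls = np.maximum(starts - d, prev_end)
    le = starts
    delta = np.zeros(L + 1, dtype=np.int16)
    ok = rs < re
    np.add.at(delta, rs[ok], 1)
    np.add.at(delta, re[ok], -1)
    ok = ls < le
    np.add.at(delta, ls[ok], 1)
    np.add.at(delta, le[ok], -1)
    return np.cumsum(delta[:-1]) > 0


def base_probability(p: ModelParameters, region_mask: RegionMask) -> np.ndarray | float:
    """Per-block firing probability outside fork-proximal zones (constant
    across rounds, so it can be computed once per simulation)."""
    if p.variant in ("MM4", "MM5"):
        return np.where(region_mask.is_in, p.Pin, p.Pout)
    return p.Pout


def firing_probability(
    state: LatticeState, p: ModelParameters, region_mask: RegionMask
) -> np.ndarray:
    """Per-block reference firing probability for the current round."""
    prob = np.broadcast_to(
        np.asarray(base_probability(p, region_mask), dtype=float), (state.L,)
    ).copy()
    if p.variant in _LOCAL_VARIANTS and p.d > 0:
        zone = fork_proximal_zone(state, p.d)
        prob[zone] = p.Plocal
    return prob


def candidate_blocks(
    state: LatticeState,
    p: ModelParameters,
    origin_map: OriginMap,
    region_mask: RegionMask,
    rng: np.random.Generator,
    base_prob: np.ndarray | float | None = None,
) -> np.ndarray:
    """Unreplicated eligible blocks whose uniform draw falls below their
    reference probability (Plocal in the fork-proximal zone for MM3/MM5,
    otherwise Pin/Pout by region)."""
    if base_prob is None:
        base_prob = base_probability(p, region_mask)
    u = rng.random(state.L)
    cand = u < base_prob
    if p.variant in _LOCAL_VARIANTS and p.d > 0:
        zone = fork_proximal_zone(state, p.d)
        np.copyto(cand, u < p.Plocal, where=zone)
    cand &= state.blocks == 0
    if origin_map.layout != "continuous":
        cand &= origin_map.eligible
    return np.flatnonzero(cand)


def apply_factor_cap(
    candidates: np.ndarray,
    state: LatticeState,
    p: ModelParameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Limit candidate firings to the free factor pool Nf(t)."""
    nf = max(0, int(np.floor(p.N0 + p.J * state.t - state.nb)))
    m = candidates.size
    if m <= nf:
        return candidates
    if nf == 0:
        return candidates[:0]
    return rng.choice(candidates, size=nf, replace=False)


def _runs(blocks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [start, end) intervals of the 1-runs (eyes) of the lattice."""
    x = blocks.astype(np.int8)
    step = np.diff(x)
    starts = np.flatnonzero(step == 1) + 1
    ends = np.flatnonzero(step == -1) + 1
    if x[0]:
        starts = np.r_[0, starts]
    if x[-1]:
        ends = np.r_[ends, x.size]
    return starts, ends


def fire_and_propagate(
    state: LatticeState,
    firing: np.ndarray,
    p: ModelParameters,
    rng: np.random.Generator,
) -> int:
    """Advance every pre-existing fork, then light the firing blocks.

    Eyes grow symmetrically by the per-round fork displacement; overlapping
    (crossing) eyes coalesce; origins overrun by a fork were never returned
    as candidates, so passive replication inactivates them permanently.
    Returns the number of newly replicated blocks this round.
    """
    old = state.blocks
    before = state.replicated_blocks
    if p.variant == "MM2":
        starts, ends = _runs(old)
        if starts.size:
            vl = rng.choice(p.speed_choices, size=starts.size)
            vr = rng.choice(p.speed_choices, size=ends.size)
            ext_l = np.rint(vl * p.round_minutes).astype(np.int64)
            ext_r = np.rint(vr * p.round_minutes).astype(np.int64)
            # forks already terminated at a lattice end do not exist
            ext_l[starts == 0] = 0
            ext_r[ends == state.L] = 0
            ns = np.maximum(starts - ext_l, 0)
            ne = np.minimum(ends + ext_r, state.L)
            delta = np.zeros(state.L + 1, dtype=np.int64)
            np.add.at(delta, ns, 1)
            np.add.at(delta, ne, -1)
            state.blocks = (np.cumsum(delta[:-1]) > 0).astype(np.uint8)
    else:
        s = p.blocks_per_round
        si = int(round(s))
        if abs(s - si) > 1e-9:
            raise ValueError(
                "fork displacement per round must be an integer number of "
                f"blocks; got v*round_minutes = {s}"
            )
        if si > 0 and old.any():
            new = old.copy()
            for k in range(1, si + 1):
                new[:-k] |= old[k:]
                new[k:] |= old[:-k]
            state.blocks = new
    if firing.size:
        state.blocks[firing] = 1
        state.fired_total += int(firing.size)
    return state.replicated_blocks - before


def release_factors(state: LatticeState) -> LatticeState:
    """Update factor release bookkeeping from the lattice.

    The bound-factor count equals the number of eyes, minus one half per
    replicated lattice end (a fork that terminated at an end released half
    a factor; the two ends together release one).
    """
    b = state.blocks
    nb = state.eye_count - 0.5 * (int(b[0]) + int(b[-1]))
    state.released_total = state.fired_total - nb
    return state


def step(
    state: LatticeState,
    p: ModelParameters,
    origin_map: OriginMap,
    region_mask: RegionMask,
    rng: np.random.Generator,
    base_prob: np.ndarray | float | None = None,
) -> tuple[LatticeState, int, int, np.ndarray]:
    """One round: candidates -> factor cap -> fire & propagate -> release.

    Returns ``(state, n_initiations, n_new_blocks, fired_positions)``.
    """
    cand = candidate_blocks(state, p, origin_map, region_mask, rng, base_prob)
    firing = apply_factor_cap(cand, state, p, rng)
    n_new = fire_and_propagate(state, firing, p, rng)
    release_factors(state)
    state.t += 1
    return state, int(firing.size), n_new, firing


def run_simulation(
    p: ModelParameters,
    L: int,
    rng: np.random.Generator | int | None = None,
    f_target: float = 1.0,
    max_rounds: int = 100_000,
    origin_map: OriginMap | None = None,
    region_mask: RegionMask | None = None,
    snapshot_f: list[float] | None = None,
    snapshot_window: float = 0.03,
    record_events: bool = False,
    record_rounds: list[int] | None = None,
    warn_on_cap: bool = True,
) -> Trajectory:
    """Run one S phase until ``f >= f_target`` (or completion / round cap).

    The origin map and region mask are generated from ``p`` when not given
    (block-level region segmentation, as used for fitting).  Snapshots of
    the full lattice are kept for every round whose genome replicated
    fraction lies within ``snapshot_window`` of a requested ``snapshot_f``
    value, plus any explicitly listed ``record_rounds``.
    """
    validate_parameters(p)
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    if origin_map is None:
        origin_map = generate_origin_map(L, p.origin_layout, p.mean_origin_spacing, rng)
    if region_mask is None:
        theta = p.theta if p.variant in ("MM4", "MM5") else 0.0
        region_mask = generate_region_mask(L, theta, "block", rng)
    state = init_state(p, origin_map, region_mask)

    rec: dict[str, list] = {k: [] for k in ("rounds", "f", "n_init", "n_new", "forks", "nb")}
    snapshots: dict[int, np.ndarray] = {}
    ev_rounds: list[np.ndarray] = []
    ev_pos: list[np.ndarray] = []

    prev_f = [0.0]

    def record(n_init: int, n_new: int) -> None:
        rec["rounds"].append(state.t)
        rec["f"].append(state.f)
        rec["n_init"].append(n_init)
        rec["n_new"].append(n_new)
        rec["forks"].append(state.boundary_count)
        rec["nb"].append(state.nb)
        keep = record_rounds is not None and state.t in record_rounds
        if snapshot_f is not None and not keep:
            fr = state.f
            keep = any(abs(fr - tf) <= snapshot_window for tf in snapshot_f)
            # always keep the round that first crosses a target, so fast
            # trajectories still offer a matching candidate
            keep = keep or any(
                prev_f[0] < tf <= fr for tf in snapshot_f
            )
        if keep:
            snapshots[state.t] = state.blocks.copy()
        prev_f[0] = state.f

    record(0, 0)
    base_prob = base_probability(p, region_mask)
    completed = True
    while state.f < f_target and state.f < 1.0:
        if state.t >= max_rounds:
            completed = False
            if warn_on_cap:
                warnings.warn(
                    f"round cap {max_rounds} reached at f={state.f:.4f} "
                    f"before target {f_target}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            break
        _, n_init, n_new, fired = step(
            state, p, origin_map, region_mask, rng, base_prob
        )
        record(n_init, n_new)
        if record_events and fired.size:
            ev_rounds.append(np.full(fired.size, state.t))
            ev_pos.append(fired.copy())

    traj = Trajectory(
        params=p,
        L=L,
        seed=seed,
        rounds=np.asarray(rec["rounds"], int),
        f=np.asarray(rec["f"]),
        n_initiations=np.asarray(rec["n_init"], int),
        n_new_blocks=np.asarray(rec["n_new"], int),
        fork_count=np.asarray(rec["forks"], int),
        nb=np.asarray(rec["nb"]),
        fired_total=state.fired_total,
        released_total=state.released_total,
        completed=completed,
        snapshots=snapshots,
    )
    if record_events:
        traj.event_rounds = (
            np.concatenate(ev_rounds) if ev_rounds else np.empty(0, int)
        )
        traj.event_positions = (
            np.concatenate(ev_pos) if ev_pos else np.empty(0, int)
        )
    return traj


def kjma_fraction(p_fire: float, rounds: np.ndarray) -> np.ndarray:
    """Closed-form replicated fraction for the unlimited-factor mean-field model.

    With a constant per-block per-round firing probability ``p_fire``, a
    continuous origin layout, no factor limitation and symmetric growth of
    one block per fork per round, a block remains unreplicated after round
    ``t`` only if none of the ``2(t-s)+1`` sites that could have covered it
    by growth fired in round ``s``, for every ``s = 1..t``; by the standard
    nucleation-and-growth (phantom-nucleus) argument real coverage contains
    phantom coverage, so

        1 - f(t) = (1 - p)**(t**2)   (t = 0, 1, 2, ...)

    the discrete-lattice analogue of the KJMA expression
    ``f = 1 - exp(-I v t^2)``.  Evaluated by numerically accumulating the
    per-round exponents, so lattice ends aside it is exact.
    """
    rounds = np.asarray(rounds)
    log_surv = np.log1p(-p_fire) * np.array(
        [np.sum(2 * np.arange(t) + 1) for t in rounds], dtype=float
    )
    return 1.0 - np.exp(log_surv)
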