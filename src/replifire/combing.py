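"""DNA-combing emulation: shredding a simulated genome into molecules and
reshaping tracks to combing resolution.

Experimental combing resolves replicated tracks only above ~1 kb, so both
experimental and simulated molecules go through the same reshaping: gaps of
at most 1 kb are merged into their flanking eyes, then eyes of at most 1 kb
are discarded.  Eyes between 1 and 3 kb are scored as new origin-firing
events, which at a fork speed of 0.5 kb/min corresponds to a 3-min
detection window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .observables import TrackAnnotation, annotate_intervals

DEFAULT_MIN_EYE = 1.0  # kb; eyes strictly larger are scored
DEFAULT_MIN_GAP = 1.0  # kb; gaps strictly larger are significant
DEFAULT_NEW_FIRING_MAX = 3.0  # kb; upper eye length of a "new firing"
DEFAULT_DT = 3.0  # min; detection window of new firings


class MatchError(RuntimeError):
    """No simulation round matches the requested global replicated fraction."""


@dataclass
class CombingDataset:
    """A collection of combed molecules with their replication eyes.

    Molecules are stored as flat arrays: ``lengths[i]`` is the length (kb)
    of molecule ``i``; eyes are rows ``(eye_mol, eye_start, eye_end)`` with
    coordinates in kb relative to the molecule, sorted by molecule then
    start.
    """

    lengths: np.ndarray
    eye_mol: np.ndarray
    eye_start: np.ndarray
    eye_end: np.ndarray
    provenance: str = "experimental"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.eye_mol = np.asarray(self.eye_mol, dtype=np.intp)
        self.eye_start = np.asarray(self.eye_start, dtype=float)
        self.eye_end = np.asarray(self.eye_end, dtype=float)
        if np.any(self.lengths <= 0):
            raise ValueError("every molecule length must be > 0")

    @property
    def n_molecules(self) -> int:
        return self.lengths.size

    @property
    def n_eyes(self) -> int:
        return self.eye_mol.size

    @property
    def eye_lengths(self) -> np.ndarray:
        return self.eye_end - self.eye_start

    @property
    def global_fraction(self) -> float:
        """Sum of all eye lengths divided by the sum of all molecule lengths."""
        return float(self.eye_lengths.sum() / self.lengths.sum())

    def molecule_fractions(self) -> np.ndarray:
        rep = np.bincount(
            self.eye_mol, weights=self.eye_lengths, minlength=self.n_molecules
        )
        return rep / self.lengths

    def molecule(self, i: int) -> TrackAnnotation:
        sel = self.eye_mol == i
        return annotate_intervals(
            self.eye_start[sel], self.eye_end[sel], self.lengths[i]
        )

    def subsample(self, n: int, rng: np.random.Generator) -> "CombingDataset":
        """Uniform random subset of ``n`` molecules (without replacement)."""
        if n >= self.n_molecules:
            return self
        keep = np.sort(rng.choice(self.n_molecules, size=n, replace=False))
        remap = -np.ones(self.n_molecules, dtype=np.intp)
        remap[keep] = np.arange(n)
        sel = remap[self.eye_mol] >= 0
        meta = dict(self.meta)
        for key in ("mol_start", "mol_end"):
            if key in meta and np.size(meta[key]) == self.n_molecules:
                meta[key] = np.asarray(meta[key])[keep]
        return CombingDataset(
            self.lengths[keep],
            remap[self.eye_mol[sel]],
            self.eye_start[sel],
            self.eye_end[sel],
            self.provenance,
            meta,
        )

    # ---- I/O: tab-delimited molecule tables ------------------------------

    def to_tsv(self, path) -> None:
        """Write `molecule_id <TAB> length_kb <TAB> eye_start:eye_end;...`."""
        eyes_by_mol: list[list[str]] = [[] for _ in range(self.n_molecules)]
        for m, s, e in zip(self.eye_mol, self.eye_start, self.eye_end):
            eyes_by_mol[m].append(f"{s:g}:{e:g}")
        with open(path, "w") as fh:
            fh.write("molecule_id\tlength_kb\teyes\n")
            for i, (length, ee) in enumerate(zip(self.lengths, eyes_by_mol)):
                fh.write(f"{i}\t{length:g}\t{';'.join(ee)}\n")

    @classmethod
    def from_tsv(cls, path, provenance: str = "experimental") -> "CombingDataset":
        df = pd.read_csv(path, sep="\t", dtype={"eyes": str}, keep_default_na=False)
        lengths, mol, starts, ends = [], [], [], []
        for i, row in enumerate(df.itertuples(index=False)):
            lengths.append(float(row.length_kb))
            if row.eyes:
                for tok in str(row.eyes).split(";"):
                    s, e = tok.split(":")
                    mol.append(i)
                    starts.append(float(s))
                    ends.append(float(e))
        return cls(
            np.array(lengths), np.array(mol, dtype=np.intp),
            np.array(starts), np.array(ends), provenance,
        )

    @classmethod
    def from_molecules(
        cls, molecules, provenance: str = "experimental"
    ) -> "CombingDataset":
        """Build from ``[(length, [(eye_start, eye_end), ...]), ...]``."""
        lengths, mol, starts, ends = [], [], [], []
        for i, (length, eyes) in enumerate(molecules):
            lengths.append(float(length))
            for s, e in sorted(eyes):
                mol.append(i)
                starts.append(float(s))
                ends.append(float(e))
        return cls(
            np.array(lengths), np.array(mol, dtype=np.intp),
            np.array(starts), np.array(ends), provenance,
        )


@dataclass
class ObservableCurves:
    """The six combing observables on fixed bin grids.

    ``firing_rate`` and ``fork_density`` are bin averages over molecules
    sorted by their replicated fraction f; ``frac_hist`` is the normalized
    histogram of per-molecule f; the three length histograms (eye, gap,
    eye-to-eye) share 2-kb bins and are normalized to unit mass.
    """

    f_edges: np.ndarray
    firing_rate: np.ndarray
    fork_density: np.ndarray
    frac_hist: np.ndarray
    len_edges: np.ndarray
    eye_hist: np.ndarray
    gap_hist: np.ndarray
    eted_hist: np.ndarray
    n_molecules: int = 0
    global_fraction: float = float("nan")

    OBSERVABLES = (
        "firing_rate",
        "fork_density",
        "frac_hist",
        "eye_hist",
        "gap_hist",
        "eted_hist",
    )

    @property
    def f_centers(self) -> np.ndarray:
        return 0.5 * (self.f_edges[:-1] + self.f_edges[1:])

    @property
    def len_centers(self) -> np.ndarray:
        return 0.5 * (self.len_edges[:-1] + self.len_edges[1:])

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in self.OBSERVABLES}

    def same_grid(self, other: "ObservableCurves") -> bool:
        return np.array_equal(self.f_edges, other.f_edges) and np.array_equal(
            self.len_edges, other.len_edges
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("firing_rate", "fork_density", "frac_hist"):
            for c, v in zip(self.f_centers, getattr(self, name)):
                rows.append((name, c, v))
        for name in ("eye_hist", "gap_hist", "eted_hist"):
            for c, v in zip(self.len_centers, getattr(self, name)):
                rows.append((name, c, v))
        return pd.DataFrame(rows, columns=["observable", "bin_center", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Shredding


def _genome_runs(blocks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(blocks).astype(np.int8)
    step = np.diff(x)
    starts = np.flatnonzero(step == 1) + 1
    ends = np.flatnonzero(step == -1) + 1
    if x.size and x[0]:
        starts = np.r_[0, starts]
    if x.size and x[-1]:
        ends = np.r_[ends, x.size]
    return starts, ends


def shred_genome(
    blocks: np.ndarray,
    length_sampler,
    rng: np.random.Generator,
    provenance: str = "shredded-simulation",
) -> CombingDataset:
    """Cut a simulated genome into combing-equivalent molecules.

    Molecule lengths (kb) are drawn i.i.d. from ``length_sampler(n, rng)``
    and placed sequentially from a uniformly random genome offset until the
    genome is exhausted: first over ``[offset, L)``, then over
    ``[0, offset)``; the partial fragment left at the end of each stretch
    is discarded to keep the length distribution unbiased.
    """
    blocks = np.asarray(blocks)
    L = blocks.size
    offset = int(rng.integers(0, L))

    def fill(span: int) -> np.ndarray:
        lens: list[np.ndarray] = []
        total = 0
        mean_guess = None
        while total < span:
            n_draw = (
                64 if mean_guess is None
                else max(16, int((span - total) / mean_guess) + 8)
            )
            draw = np.asarray(length_sampler(n_draw, rng), dtype=float)
            draw = np.maximum(1.0, np.rint(draw))
            lens.append(draw)
            total += int(draw.sum())
            mean_guess = max(1.0, float(draw.mean()))
        lengths = np.concatenate(lens) if lens else np.empty(0)
        cum = np.cumsum(lengths, dtype=np.int64)
        n_mol = int(np.searchsorted(cum, span, side="right"))
        return lengths[:n_mol].astype(np.int64)

    len_hi = fill(L - offset)  # molecules tiling [offset, L)
    len_lo = fill(offset)  # molecules tiling [0, offset)

    def starts_of(lens: np.ndarray, base: int) -> np.ndarray:
        if lens.size == 0:
            return np.empty(0, np.int64)
        return base + np.cumsum(np.r_[np.int64(0), lens[:-1]])

    mol_start = np.r_[starts_of(len_lo, 0), starts_of(len_hi, offset)]
    lengths = np.r_[len_lo, len_hi].astype(np.int64)
    mol_end = mol_start + lengths
    n_mol = lengths.size
    if n_mol == 0:
        return CombingDataset(
            np.empty(0), np.empty(0, np.intp), np.empty(0), np.empty(0), provenance
        )

    gs, ge = _genome_runs(blocks)
    if gs.size:
        # molecules overlapping each genome eye (mol_end > gs, mol_start < ge)
        first = np.searchsorted(mol_end, gs, side="right")
        last = np.searchsorted(mol_start, ge, side="left") - 1
        reps = np.maximum(last - first + 1, 0)
        total_pieces = int(reps.sum())
        piece_of_eye = np.repeat(np.arange(gs.size), reps)
        within = np.arange(total_pieces) - np.repeat(
            np.cumsum(reps) - reps, reps
        )
        mol = first[piece_of_eye] + within
        ps = np.maximum(gs[piece_of_eye], mol_start[mol])
        pe = np.minimum(ge[piece_of_eye], mol_end[mol])
        eye_mol = mol.astype(np.intp)
        eye_start = (ps - mol_start[mol]).astype(float)
        eye_end = (pe - mol_start[mol]).astype(float)
    else:
        eye_mol = np.empty(0, np.intp)
        eye_start = np.empty(0)
        eye_end = np.empty(0)
    return CombingDataset(
        lengths.astype(float), eye_mol, eye_start, eye_end, provenance,
        {
            "offset": offset,
            "mol_start": mol_start.copy(),
            "mol_end": mol_end.copy(),
        },
    )


# ---------------------------------------------------------------------------
# Reshaping


def reshape_dataset(
    ds: CombingDataset,
    min_gap: float = DEFAULT_MIN_GAP,
    min_eye: float = DEFAULT_MIN_EYE,
) -> CombingDataset:
    """Apply combing-resolution reshaping to every molecule (vectorized).

    Interior gaps of at most ``min_gap`` kb merge their flanking eyes;
    merging never changes the surviving gaps, so a single simultaneous pass
    reaches the fixed point.  Eyes of at most ``min_eye`` kb are then
    dropped (becoming gap); since all surviving gaps exceed ``min_gap``,
    dropping can only widen gaps and no rescan is needed.  The result is
    idempotent.
    """
    if ds.n_eyes == 0:
        return ds
    mol, s, e = ds.eye_mol, ds.eye_start, ds.eye_end
    first = np.empty(mol.size, dtype=bool)
    first[0] = True
    first[1:] = mol[1:] != mol[:-1]
    gap_prev = np.empty(mol.size)
    gap_prev[0] = np.inf
    gap_prev[1:] = s[1:] - e[:-1]
    keep_boundary = first | (gap_prev > min_gap)
    group_start = np.flatnonzero(keep_boundary)
    m_mol = mol[group_start]
    m_s = s[group_start]
    m_e = np.maximum.reduceat(e, group_start)
    big = (m_e - m_s) > min_eye
    return CombingDataset(
        ds.lengths, m_mol[big], m_s[big], m_e[big], ds.provenance, dict(ds.meta)
    )


def reshape_tracks(
    molecule: TrackAnnotation,
    min_gap: float = DEFAULT_MIN_GAP,
    min_eye: float = DEFAULT_MIN_EYE,
) -> TrackAnnotation:
    """Reshape a single annotated molecule (see :func:`reshape_dataset`)."""
    ds = CombingDataset(
        np.array([molecule.length]),
        np.zeros(molecule.n_eyes, dtype=np.intp),
        molecule.eye_start,
        molecule.eye_end,
    )
    out = reshape_dataset(ds, min_gap, min_eye)
    return out.molecule(0)


def classify_new_firings(
    x: TrackAnnotation | CombingDataset,
    min_eye: float = DEFAULT_MIN_EYE,
    new_max: float = DEFAULT_NEW_FIRING_MAX,
) -> int | np.ndarray:
    """Count eyes scored as new origin-firing events (length in (1, 3] kb).

    For a single molecule returns an int; for a dataset, the per-molecule
    counts.  Assumes reshaped input (eyes <= 1 kb already removed).
    """
    if isinstance(x, TrackAnnotation):
        ln = x.eye_lengths
        return int(np.count_nonzero((ln > min_eye) & (ln <= new_max)))
    ln = x.eye_lengths
    new = (ln > min_eye) & (ln <= new_max)
    return np.bincount(x.eye_mol[new], minlength=x.n_molecules)


# ---------------------------------------------------------------------------
# Fraction matching and per-molecule curves


def match_global_fraction(
    trajectory,
    length_sampler,
    target: float,
    tol: float = 0.005,
    rng: np.random.Generator | None = None,
    n_candidates: int = 5,
    reshape: bool = True,
) -> CombingDataset:
    """Shred the simulation round whose global replicated fraction matches
    ``target`` and return the resulting molecules.

    Candidate rounds (those with lattice snapshots) are ranked by the
    distance of their genome fraction to the target; each candidate is
    shredded and the dataset whose *shredded* global fraction is nearest
    the target is returned, provided it lies within ``tol``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not trajectory.snapshots:
        raise MatchError("trajectory carries no lattice snapshots to shred")
    rounds = np.array(sorted(trajectory.snapshots))
    f_by_round = dict(zip(trajectory.rounds.tolist(), trajectory.f.tolist()))
    dist = np.array([abs(f_by_round[t] - target) for t in rounds])
    order = rounds[np.argsort(dist)][:n_candidates]
    best = None
    best_err = np.inf
    for t in order:
        ds = shred_genome(trajectory.snapshots[int(t)], length_sampler, rng)
        if reshape:
            ds = reshape_dataset(ds)
        if ds.n_molecules == 0:
            continue
        err = abs(ds.global_fraction - target)
        if err < best_err:
            best, best_err = ds, err
            best.meta.update(
                source_round=int(t), genome_fraction=f_by_round[int(t)],
                target_fraction=target,
            )
    if best is None or best_err > tol:
        raise MatchError(
            f"no shredded round within {tol} of target fraction {target} "
            f"(best error {best_err:.4f})"
        )
    return best


def per_molecule_curves(
    ds: CombingDataset,
    n_f_bins: int = 20,
    dt: float = DEFAULT_DT,
    len_max: float = 100.0,
    len_bw: float = 2.0,
    min_eye: float = DEFAULT_MIN_EYE,
    new_max: float = DEFAULT_NEW_FIRING_MAX,
) -> ObservableCurves:
    """Compute the six combing observables from a (reshaped) dataset.

    Per molecule: the firing rate ``I = n_new / ((1 - f) * length * dt)``
    (new firings are eyes of length in (1, 3] kb; fully replicated
    molecules are excluded) and the visible fork density
    ``(2 * interior eyes + 1 * end-touching eyes) / length``.  Both are
    averaged within equal-width bins of the molecule replicated fraction.
    Length histograms use interior gaps only and clip values at the last
    bin edge so no mass is lost.
    """
    f_edges = np.linspace(0.0, 1.0, n_f_bins + 1)
    len_edges = np.arange(0.0, len_max + len_bw, len_bw)
    n_len = len_edges.size - 1
    if ds.n_molecules == 0:
        nanf = np.full(n_f_bins, np.nan)
        z = np.zeros(n_len)
        return ObservableCurves(
            f_edges, nanf.copy(), nanf.copy(), np.zeros(n_f_bins),
            len_edges, z.copy(), z.copy(), z.copy(), 0,
        )

    fmol = ds.molecule_fractions()
    n_new = classify_new_firings(ds, min_eye, new_max)

    # visible forks: each eye edge strictly inside the molecule is a fork
    left_in = ds.eye_start > 0
    right_in = ds.eye_end < ds.lengths[ds.eye_mol]
    forks = np.bincount(
        ds.eye_mol,
        weights=left_in.astype(float) + right_in.astype(float),
        minlength=ds.n_molecules,
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        i_mol = np.where(
            fmol < 1.0, n_new / ((1.0 - fmol) * ds.lengths * dt), np.nan
        )
    rho_mol = forks / ds.lengths

    bin_id = np.clip(np.digitize(fmol, f_edges) - 1, 0, n_f_bins - 1)

    def bin_mean(vals: np.ndarray) -> np.ndarray:
        ok = np.isfinite(vals)
        cnt = np.bincount(bin_id[ok], minlength=n_f_bins).astype(float)
        tot = np.bincount(bin_id[ok], weights=vals[ok], minlength=n_f_bins)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    firing_rate = bin_mean(i_mol)
    fork_density = bin_mean(rho_mol)
    frac_hist = np.bincount(bin_id, minlength=n_f_bins) / ds.n_molecules

    def length_hist(values: np.ndarray) -> np.ndarray:
        if values.size == 0:
            return np.zeros(n_len)
        v = np.clip(values, None, len_edges[-1] - 1e-9)
        h, _ = np.histogram(v, bins=len_edges)
        return h / values.size

    eye_hist = length_hist(ds.eye_lengths)

    # interior gaps and centre-to-centre eye distances, per molecule
    mol = ds.eye_mol
    same = np.empty(mol.size, dtype=bool)
    if mol.size:
        same[0] = False
        same[1:] = mol[1:] == mol[:-1]
    gaps = (ds.eye_start[same] - np.r_[np.nan, ds.eye_end[:-1]][same]) if mol.size else np.empty(0)
    centres = (ds.eye_start + ds.eye_end) / 2.0
    eted = (centres[same] - np.r_[np.nan, centres[:-1]][same]) if mol.size else np.empty(0)

    return ObservableCurves(
        f_edges, firing_rate, fork_density, frac_hist,
        len_edges, eye_hist, length_hist(gaps), length_hist(eted),
        ds.n_molecules, ds.global_fraction,
    )


def average_curves(curves: list[ObservableCurves]) -> ObservableCurves:
    """Pointwise mean of curves from independent experiments (shared grid)."""
    if not curves:
        raise ValueError("need at least one set of curves")
    base = curves[0]
    for c in curves[1:]:
        if not base.same_grid(c):
            raise ValueError("curves are not on a common bin grid")
    kw = {}
    with np.errstate(invalid="ignore"):
        for name in ObservableCurves.OBSERVABLES:
            kw[name] = np.nanmean([getattr(c, name) for c in curves], axis=0)
    return dc_replace(
        base,
        n_molecules=int(np.mean([c.n_molecules for c in curves])),
        global_fraction=float(np.mean([c.global_fraction for c in curves])),
        **kw,
    )
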