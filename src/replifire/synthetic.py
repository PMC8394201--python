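"""Ground-truth pseudo-experimental combing datasets.

The generator runs the lattice simulator with known ("true") parameters,
matches the requested global replicated fractions, shreds the genome into
molecules with an empirical-style length distribution and applies the
standard combing reshaping, so every downstream stage (observables,
fitting) can be exercised against a known answer without any external
data.  An optional noise model (eye-edge jitter, false gaps) emulates
measurement artifacts; it is an addition for robustness testing, not part
of the replication model, and is off by default.

The default true parameter set is the published Fig-7-style MM5 condition
scaled to a 10^5-kb synthetic genome (factor counts N0 and J scale with
genome size; probabilities, theta and d do not).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .combing import CombingDataset, match_global_fraction, reshape_dataset, shred_genome
from .parameters import ModelParameters, validate_parameters
from .simulator import run_simulation

#: Global replicated fractions of the emulated experimental samples.
STUDY_FRACTIONS = (0.08, 0.19, 0.22, 0.46, 0.53)


class LengthModel:
    """Sampler of combed-molecule lengths (kb): ``model(n, rng) -> lengths``."""

    def __init__(self, sampler, kind: str, params: dict):
        self._sampler = sampler
        self.kind = kind
        self.params = params

    def __call__(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._sampler(n, rng)

    @classmethod
    def lognormal(
        cls, median: float = 100.0, sigma: float = 0.5, min_length: float = 2.0
    ) -> "LengthModel":
        """Lognormal lengths, the typical shape of combed-fiber length
        distributions (long right tail, few very short fibers)."""

        def sample(n, rng):
            x = median * np.exp(sigma * rng.standard_normal(n))
            return np.maximum(min_length, x)

        return cls(sample, "lognormal", dict(median=median, sigma=sigma))

    @classmethod
    def point(cls, length: float) -> "LengthModel":
        def sample(n, rng):
            return np.full(n, float(length))

        return cls(sample, "point", dict(length=length))

    @classmethod
    def from_histogram(cls, centers, weights, min_length: float = 2.0) -> "LengthModel":
        """Empirical histogram sampler; weights are renormalized to sum 1
        and lengths are drawn uniformly within the chosen bin."""
        centers = np.asarray(centers, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("histogram weights must be non-negative, nonzero")
        p = weights / weights.sum()
        width = np.diff(centers).mean() if centers.size > 1 else 1.0

        def sample(n, rng):
            c = rng.choice(centers, size=n, p=p)
            x = c + width * (rng.random(n) - 0.5)
            return np.maximum(min_length, x)

        return cls(sample, "histogram", dict(centers=centers.tolist(), p=p.tolist()))


def default_true_parameters() -> ModelParameters:
    """Fig-7-style MM5 truth scaled to a 10^5-kb genome (1/10 of the
    published simulation lattice; N0 and J scaled accordingly)."""
    return ModelParameters(
        N0=123, J=28.7, Pout=0.01, Pin=0.34, Plocal=0.34, theta=0.46, d=138.0,
        variant="MM5", origin_layout="discrete", mean_origin_spacing=2.3,
    )


def recovery_true_parameters() -> ModelParameters:
    """MM5 ground truth used for the parameter-recovery experiments.

    Chosen once to give an S phase of ~25 two-minute rounds on a 10^5-kb
    genome with both a factor-limited early phase (identifying N0 and J)
    and a candidate-limited late phase (identifying theta and the firing
    probabilities), with the qualitative ordering Plocal > Pin >> Pout of
    the fitted values reported for Xenopus extracts.
    """
    return ModelParameters(
        N0=300, J=60.0, Pout=0.01, Pin=0.15, Plocal=0.3, theta=0.45, d=15.0,
        variant="MM5", origin_layout="discrete", mean_origin_spacing=2.3,
    )


@dataclass
class SyntheticSpec:
    """Recipe for one pseudo-experimental dataset family."""

    params: ModelParameters = field(default_factory=default_true_parameters)
    L: int = 100_000
    fractions: tuple[float, ...] = (0.1, 0.2, 0.5)
    length_model: LengthModel = field(default_factory=LengthModel.lognormal)
    molecules_per_sample: int | None = None  # None = keep every shredded molecule
    jitter_sd: float = 0.0  # kb, per eye edge
    false_gap_rate: float = 0.0  # per-eye probability of a spurious gap
    false_gap_width: float = 1.5  # kb
    # one 2-min round moves the genome fraction by up to ~0.02 in mid-S
    # phase, so the achievable matching accuracy is round-granularity bound
    match_tol: float = 0.015
    max_rounds: int = 2000

    def __post_init__(self):
        validate_parameters(self.params)
        if any(not 0.0 < f < 1.0 for f in self.fractions):
            raise ValueError("target fractions must lie in (0, 1)")


def apply_edge_jitter(
    ds: CombingDataset, sd: float, rng: np.random.Generator
) -> CombingDataset:
    """Perturb every eye edge by N(0, sd) kb, clipping to the molecule and
    merging eyes that come to overlap."""
    if sd <= 0 or ds.n_eyes == 0:
        return ds
    s = ds.eye_start + sd * rng.standard_normal(ds.n_eyes)
    e = ds.eye_end + sd * rng.standard_normal(ds.n_eyes)
    lim = ds.lengths[ds.eye_mol]
    s = np.clip(s, 0.0, lim)
    e = np.clip(e, 0.0, lim)
    keep = e > s
    mol, s, e = ds.eye_mol[keep], s[keep], e[keep]
    order = np.lexsort((s, mol))
    mol, s, e = mol[order], s[order], e[order]
    jittered = CombingDataset(ds.lengths, mol, s, e, ds.provenance, dict(ds.meta))
    # merge any overlaps created by the jitter (gap <= 0), keep all eyes
    return reshape_dataset(jittered, min_gap=0.0, min_eye=0.0)


def insert_false_gaps(
    ds: CombingDataset, rate: float, width: float, rng: np.random.Generator
) -> CombingDataset:
    """Split each sufficiently long eye with probability ``rate`` by a
    spurious unreplicated gap of the given width (measurement artifact)."""
    if rate <= 0 or ds.n_eyes == 0:
        return ds
    ln = ds.eye_lengths
    split = (rng.random(ds.n_eyes) < rate) & (ln > 2 * width)
    mol, s, e = [], [], []
    for i in range(ds.n_eyes):
        if split[i]:
            pos = ds.eye_start[i] + width + rng.random() * (ln[i] - 2 * width)
            mol += [ds.eye_mol[i]] * 2
            s += [ds.eye_start[i], pos + width]
            e += [pos, ds.eye_end[i]]
        else:
            mol.append(ds.eye_mol[i])
            s.append(ds.eye_start[i])
            e.append(ds.eye_end[i])
    return CombingDataset(
        ds.lengths, np.array(mol, np.intp), np.array(s), np.array(e),
        ds.provenance, dict(ds.meta),
    )


def generate_dataset(
    spec: SyntheticSpec, rng: np.random.Generator | int | None = None
) -> tuple[dict[float, CombingDataset], dict]:
    """Simulate with the true parameters and emit one combing dataset per
    target global fraction, plus a ground-truth record.

    The truth record carries the true parameters, the simulation seed, and
    for every sample: the source round, the genome fraction, the retained
    molecules' genome coordinates and the true initiation events (position,
    round) that fall inside retained molecules up to the source round.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = spec.params
    traj = run_simulation(
        p, spec.L, rng,
        f_target=min(1.0, max(spec.fractions) + 0.05),
        max_rounds=spec.max_rounds,
        snapshot_f=list(spec.fractions),
        record_events=True,
    )
    datasets: dict[float, CombingDataset] = {}
    truth: dict = {
        "parameters": p.to_dict(),
        "L": spec.L,
        "noise": {"jitter_sd": spec.jitter_sd, "false_gap_rate": spec.false_gap_rate},
        "samples": {},
    }
    for tf in spec.fractions:
        ds = match_global_fraction(
            traj, spec.length_model, tf, tol=spec.match_tol, rng=rng, reshape=False
        )
        matched_fraction = ds.global_fraction
        ds = insert_false_gaps(ds, spec.false_gap_rate, spec.false_gap_width, rng)
        ds = apply_edge_jitter(ds, spec.jitter_sd, rng)
        ds = reshape_dataset(ds)
        if spec.molecules_per_sample is not None:
            ds = ds.subsample(spec.molecules_per_sample, rng)
        ds.provenance = "shredded-simulation"
        datasets[tf] = ds
        # true initiation events within the retained molecules
        t_src = ds.meta["source_round"]
        ms = np.asarray(ds.meta["mol_start"])
        me = np.asarray(ds.meta["mol_end"])
        ev_t, ev_x = traj.event_rounds, traj.event_positions
        upto = ev_t <= t_src
        pos = ev_x[upto]
        rounds = ev_t[upto]
        mol_idx = np.searchsorted(ms, pos, side="right") - 1
        inside = (mol_idx >= 0) & (pos < me[np.clip(mol_idx, 0, ms.size - 1)])
        truth["samples"][tf] = {
            "source_round": int(t_src),
            "genome_fraction": float(ds.meta["genome_fraction"]),
            "matched_fraction": float(matched_fraction),
            "dataset_fraction": float(ds.global_fraction),
            "n_molecules": int(ds.n_molecules),
            "n_true_initiations": int(np.count_nonzero(inside)),
            "initiation_positions": pos[inside].tolist(),
            "initiation_rounds": rounds[inside].tolist(),
            "molecule_genome_start": ms.tolist(),
            "molecule_genome_end": me.tolist(),
        }
    truth["fired_total"] = int(traj.fired_total)
    return datasets, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
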