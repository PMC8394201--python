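"""Six-observable fitness and genetic-algorithm parameter inference.

The fitness of a candidate parameter set is the sum, over the six combing
observables (firing rate I(f), fork density, per-molecule replicated
fraction distribution, eye-, gap- and eye-to-eye length histograms), of
the squared simulated-minus-experimental differences divided by the
squared mean of the experimental curve.  It is minimized by a real-coded
genetic algorithm (three subpopulations, elitism, scattered crossover,
uniform mutation, ring migration), repeated independently to build a
parameter ensemble whose per-parameter mean and standard deviation are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .combing import (
    MatchError,
    ObservableCurves,
    match_global_fraction,
    per_molecule_curves,
)
from .parameters import (
    ACTIVE_PARAMETERS,
    PARAM_BOUNDS,
    ModelParameters,
    params_from_vector,
)
from .simulator import run_simulation

#: Penalty assigned when a candidate cannot reach / match a target fraction.
PENALTY = 1.0e4

#: Scale parameters whose plausible values span orders of magnitude are
#: searched on a log10 scale (with a small offset where the lower bound is
#: 0); uniform initialization and mutation then explore decades uniformly
#: instead of being concentrated near the upper bound.  theta is a
#: bounded fraction and stays linear.
GENE_LOG_EPS: dict[str, float] = {
    "N0": 0.0,
    "J": 1.0,
    "d": 1.0,
    "Pout": 1e-4,
    "Pin": 1e-4,
    "Plocal": 1e-4,
}


class GeneCoding:
    """Map between raw parameter vectors and GA gene space."""

    def __init__(self, names: tuple[str, ...], log_scale: bool = True):
        self.names = names
        self.eps = [
            GENE_LOG_EPS.get(n) if log_scale else None for n in names
        ]

    def encode(self, raw) -> np.ndarray:
        out = np.array(raw, dtype=float)
        for i, e in enumerate(self.eps):
            if e is not None:
                out[i] = np.log10(out[i] + e)
        return out

    def decode(self, genes) -> np.ndarray:
        out = np.array(genes, dtype=float)
        for i, e in enumerate(self.eps):
            if e is not None:
                out[i] = 10.0 ** out[i] - e
        return out

    def encode_bounds(self, bounds) -> list[tuple[float, float]]:
        out = []
        for (lo, hi), e in zip(bounds, self.eps):
            if e is not None:
                lo, hi = np.log10(lo + e), np.log10(hi + e)
            out.append((float(lo), float(hi)))
        return out


# ---------------------------------------------------------------------------
# Fitness


def fitness_from_arrays(
    sim: dict[str, np.ndarray], exp: dict[str, np.ndarray]
) -> float:
    """Core fitness: sum over observables of sum((sim-exp)^2)/mean(exp)^2.

    Points where the experimental curve is undefined (NaN) are skipped;
    a simulated point that is undefined where the experiment is defined
    counts as zero (nothing was observed there).  Observables whose
    experimental curve has zero mean carry no information and are skipped.
    """
    total = 0.0
    for name, e in exp.items():
        s = np.asarray(sim[name], dtype=float)
        e = np.asarray(e, dtype=float)
        if s.shape != e.shape:
            raise ValueError(f"{name}: curves are on different grids")
        ok = np.isfinite(e)
        if not ok.any():
            continue
        e_ok = e[ok]
        s_ok = np.where(np.isfinite(s[ok]), s[ok], 0.0)
        m = e_ok.mean()
        if m == 0.0:
            continue
        total += float(np.sum((s_ok - e_ok) ** 2) / m**2)
    return total


def fitness(sim: ObservableCurves, exp: ObservableCurves) -> float:
    """Fitness between simulated and experimental observable curves."""
    if not sim.same_grid(exp):
        raise ValueError("simulated and experimental curves use different bins")
    return fitness_from_arrays(sim.as_dict(), exp.as_dict())


# ---------------------------------------------------------------------------
# Genetic algorithm


@dataclass
class GAConfig:
    """Settings of the genetic optimizer (defaults follow the study design)."""

    subpopulations: int = 3
    individuals: int = 20
    elite_count: int = 3
    crossover_fraction: float = 0.6
    mutation_probability: float = 0.2
    migration_fraction: float = 0.1
    migration_interval: int = 5
    generations: int = 50
    repeats: int = 100
    #: re-evaluate surviving elites each generation and select on their
    #: running-mean fitness; essential when the objective is stochastic,
    #: otherwise a single lucky evaluation locks in
    reevaluate_elites: bool = True

    def __post_init__(self):
        if self.elite_count >= self.individuals:
            raise ValueError("elite_count must be below the subpopulation size")
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must lie in [0, 1]")


@dataclass
class FitResult:
    """Outcome of one GA run."""

    x: np.ndarray  # best individual (gene vector)
    fun: float  # its fitness
    trace: np.ndarray  # best-so-far fitness per generation
    names: tuple[str, ...]
    seed: int | None = None
    n_evals: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(dict(zip(self.names, self.x)))


def _roulette(fit: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Roulette selection on transformed minimization ranks.

    Raw fitness values span orders of magnitude (penalties vs. good fits),
    so proportional weights on raw values would wash out selection among
    the good individuals; weights proportional to 1/sqrt(rank) of the
    minimization ranking give a scale-free selection pressure.
    """
    order = np.argsort(np.argsort(fit, kind="stable"), kind="stable")  # rank, 0 = best
    w = 1.0 / np.sqrt(order + 1.0)
    w = w / w.sum()
    return rng.choice(fit.size, size=n, p=w)


def ga_optimize(
    objective,
    bounds: list[tuple[float, float]],
    config: GAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    names: tuple[str, ...] | None = None,
    callback=None,
) -> FitResult:
    """Minimize ``objective(x, rng)`` over box bounds with the GA.

    Per subpopulation and generation: the ``elite_count`` best individuals
    survive unchanged (with their cached fitness, since the objective may
    be stochastic); of the remainder, a fraction ``crossover_fraction``
    comes from scattered crossover between two roulette-selected parents
    (each gene copied from either parent with probability 1/2) and the rest
    from uniform mutation of a roulette-selected parent (each gene redrawn
    uniformly within its bounds with probability
    ``mutation_probability``).  Every ``migration_interval`` generations
    the best ``migration_fraction`` of each subpopulation replaces the
    worst individuals of the next subpopulation on a ring.
    """
    cfg = config or GAConfig()
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    g = lo.size
    if names is None:
        names = tuple(f"x{i}" for i in range(g))

    n_sub, n_ind, n_el = cfg.subpopulations, cfg.individuals, cfg.elite_count
    n_rest = n_ind - n_el
    n_cross = int(round(cfg.crossover_fraction * n_rest))
    n_mut = n_rest - n_cross
    n_mig = max(1, int(round(cfg.migration_fraction * n_ind)))

    n_evals = 0

    def evaluate(X: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            out[i] = objective(x, rng)
        n_evals += X.shape[0]
        return out

    pops = [lo + rng.random((n_ind, g)) * (hi - lo) for _ in range(n_sub)]
    fits = [evaluate(P) for P in pops]
    cnts = [np.ones(n_ind, int) for _ in range(n_sub)]

    best_x = None
    best_f = np.inf
    trace = []

    def note_best() -> None:
        # cumulative best of the running-mean fitness (monotone record)
        nonlocal best_x, best_f
        for P, F in zip(pops, fits):
            i = int(np.argmin(F))
            if F[i] < best_f:
                best_f = float(F[i])
                best_x = P[i].copy()

    note_best()
    for gen in range(1, cfg.generations + 1):
        for si in range(n_sub):
            P, F, C = pops[si], fits[si], cnts[si]
            order = np.argsort(F, kind="stable")
            elites, efit, ecnt = P[order[:n_el]], F[order[:n_el]], C[order[:n_el]]
            if cfg.reevaluate_elites:
                fresh = evaluate(elites)
                efit = (efit * ecnt + fresh) / (ecnt + 1)
                ecnt = ecnt + 1
            children = np.empty((n_rest, g))
            # scattered crossover
            for c in range(n_cross):
                i, j = _roulette(F, 2, rng)
                mask = rng.random(g) < 0.5
                children[c] = np.where(mask, P[i], P[j])
            # uniform mutation
            for c in range(n_cross, n_rest):
                (i,) = _roulette(F, 1, rng)
                child = P[i].copy()
                mut = rng.random(g) < cfg.mutation_probability
                child[mut] = lo[mut] + rng.random(int(mut.sum())) * (hi - lo)[mut]
                children[c] = child
            cfit = evaluate(children)
            pops[si] = np.vstack([elites, children])
            fits[si] = np.concatenate([efit, cfit])
            cnts[si] = np.concatenate([ecnt, np.ones(n_rest, int)])
        if n_sub > 1 and gen % cfg.migration_interval == 0:
            # ring migration of copies of the best individuals
            snap = [
                (P.copy(), F.copy(), C.copy())
                for P, F, C in zip(pops, fits, cnts)
            ]
            for si in range(n_sub):
                src_p, src_f, src_c = snap[si]
                dst = (si + 1) % n_sub
                mig = np.argsort(src_f, kind="stable")[:n_mig]
                worst = np.argsort(fits[dst], kind="stable")[-n_mig:]
                pops[dst][worst] = src_p[mig]
                fits[dst][worst] = src_f[mig]
                cnts[dst][worst] = src_c[mig]
        note_best()
        trace.append(best_f)
        if callback is not None:
            callback(gen, best_x, best_f)
    if cfg.reevaluate_elites:
        # report the multiply-evaluated current best rather than the
        # historical single-draw minimum (robust to objective noise)
        cand_x, cand_f = [], []
        for P, F, C in zip(pops, fits, cnts):
            seen = C >= max(2, int(C.max() * 0.5)) if C.max() > 1 else C >= 1
            idx = np.flatnonzero(seen)
            i = idx[np.argmin(F[idx])]
            cand_x.append(P[i])
            cand_f.append(F[i])
        i = int(np.argmin(cand_f))
        best_x, best_f = cand_x[i].copy(), float(cand_f[i])
    return FitResult(
        x=best_x, fun=best_f, trace=np.asarray(trace), names=names,
        seed=seed, n_evals=n_evals,
    )


# ---------------------------------------------------------------------------
# Condition fitting (simulate -> shred -> reshape -> curves -> fitness)


@dataclass
class ParameterEnsemble:
    """Per-parameter statistics over independent GA repeats."""

    elites: pd.DataFrame  # one row per repeat, one column per parameter
    fitness: np.ndarray
    condition: str = ""
    results: list[FitResult] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.elites)

    @property
    def mean(self) -> pd.Series:
        return self.elites.mean()

    @property
    def sd(self) -> pd.Series:
        return self.elites.std(ddof=1)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "n": self.n}
        )

    def correlation(self) -> pd.DataFrame:
        """Ensemble correlation between parameters (identifiability check)."""
        return self.elites.corr()


def make_objective(
    experiments: dict[float, ObservableCurves],
    variant: str,
    L: int,
    length_sampler,
    template: ModelParameters | None = None,
    match_tol: float = 0.02,
    max_rounds: int = 300,
    curve_kw: dict | None = None,
):
    """Build the GA objective for a set of samples keyed by global fraction.

    Each evaluation simulates one S phase up to just beyond the largest
    target fraction, shreds the lattice at the rounds matching each
    sample's global replicated fraction, reshapes, computes the combing
    curves and sums the six-observable fitness over the samples.  A
    candidate that cannot reach or match a target receives a penalty that
    grows with the shortfall, keeping the search directed.
    """
    curve_kw = curve_kw or {}
    targets = sorted(experiments)
    f_stop = min(1.0, max(targets) + 0.05)

    def objective(x: np.ndarray, rng: np.random.Generator) -> float:
        p = params_from_vector(x, variant, template)
        traj = run_simulation(
            p, L, rng, f_target=f_stop, max_rounds=max_rounds,
            snapshot_f=targets, snapshot_window=0.04, warn_on_cap=False,
        )
        total = 0.0
        if not traj.completed:
            total += PENALTY * (1.0 + f_stop - traj.f[-1])
        for tf in targets:
            exp = experiments[tf]
            # a trajectory that crossed the target always yields a usable
            # nearest round: any residual fraction mismatch shows up in
            # the curve fitness itself.  The tolerance gate only rejects
            # trajectories that never came close.
            reached = traj.f[-1] >= tf - match_tol
            try:
                ds = match_global_fraction(
                    traj, length_sampler, tf,
                    tol=1.0 if reached else match_tol, rng=rng,
                )
            except MatchError:
                # graded penalty: how close did the trajectory ever get?
                err = float(np.min(np.abs(traj.f - tf)))
                total += PENALTY * (1.0 + err)
                continue
            sim = per_molecule_curves(
                ds, n_f_bins=exp.f_edges.size - 1,
                len_max=exp.len_edges[-1],
                len_bw=exp.len_edges[1] - exp.len_edges[0],
                **curve_kw,
            )
            total += fitness(sim, exp)
        return total

    return objective


def fit_condition(
    experiments: dict[float, ObservableCurves] | ObservableCurves,
    variant: str = "MM5",
    config: GAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    L: int = 100_000,
    length_sampler=None,
    template: ModelParameters | None = None,
    condition: str = "",
    match_tol: float = 0.02,
    max_rounds: int = 300,
    log_genes: bool = True,
) -> ParameterEnsemble:
    """Repeat the GA independently and collect the best elite of each run.

    ``experiments`` maps each sample's global replicated fraction to its
    (reshaped) observable curves; a single ``ObservableCurves`` is accepted
    and keyed by its own global fraction.  With ``log_genes`` (default)
    the GA searches scale parameters on a log10 axis within the same
    bounds; the returned ensemble is always on the raw parameter scale.
    """
    cfg = config or GAConfig()
    if isinstance(experiments, ObservableCurves):
        experiments = {float(experiments.global_fraction): experiments}
    if length_sampler is None:
        from .synthetic import LengthModel

        length_sampler = LengthModel.lognormal()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    names = ACTIVE_PARAMETERS[variant]
    coding = GeneCoding(names, log_scale=log_genes)
    bounds = coding.encode_bounds([PARAM_BOUNDS[n] for n in names])
    objective = make_objective(
        experiments, variant, L, length_sampler, template, match_tol, max_rounds
    )

    def gene_objective(genes: np.ndarray, orng: np.random.Generator) -> float:
        return objective(coding.decode(genes), orng)

    results = []
    for child in rng.spawn(cfg.repeats):
        res = ga_optimize(gene_objective, bounds, cfg, child, names=names)
        # decode to the raw scale and canonicalize (Pin >= Pout)
        p = params_from_vector(coding.decode(res.x), variant, template)
        res.x = np.array([getattr(p, n) for n in names], dtype=float)
        results.append(res)
    elites = pd.DataFrame([r.as_series() for r in results]).reset_index(drop=True)
    return ParameterEnsemble(
        elites=elites,
        fitness=np.array([r.fun for r in results]),
        condition=condition,
        results=results,
    )


# ---------------------------------------------------------------------------
# Cross-condition comparison


def compare_parameters(
    a: ParameterEnsemble,
    b: ParameterEnsemble,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-parameter Welch two-sample t-test between two fitted ensembles.

    Returns one row per fitted parameter with the means, the effect
    direction (sign of mean_b - mean_a), the Welch t statistic, the raw
    and Bonferroni-adjusted p-values, and a significance flag at ``alpha``.
    """
    if list(a.elites.columns) != list(b.elites.columns):
        raise ValueError("ensembles fit different parameter sets")
    rows = []
    k = len(a.elites.columns)
    for name in a.elites.columns:
        xa = a.elites[name].to_numpy()
        xb = b.elites[name].to_numpy()
        if np.allclose(xa.std(), 0) and np.allclose(xb.std(), 0):
            t, pval = 0.0, 1.0 if np.allclose(xa.mean(), xb.mean()) else 0.0
        else:
            t, pval = stats.ttest_ind(xa, xb, equal_var=False)
        p_adj = min(1.0, float(pval) * k)
        rows.append(
            {
                "parameter": name,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "direction": int(np.sign(xb.mean() - xa.mean())),
                "t": float(t),
                "p": float(pval),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
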