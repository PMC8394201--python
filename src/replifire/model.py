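"""High-level Model/Results interface for origin-firing inference.

`OriginFiringModel` holds combing data (one or several samples) and the
model variant; `fit()` runs the repeated genetic-algorithm optimization and
returns an `OriginFiringResults` carrying the parameter ensemble, its
uncertainties and diagnostics, in the style of statsmodels estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .combing import CombingDataset, ObservableCurves, per_molecule_curves, reshape_dataset
from .fitting import GAConfig, ParameterEnsemble, compare_parameters, fit_condition
from .parameters import ACTIVE_PARAMETERS, ModelParameters
from .simulator import Trajectory, run_simulation
from .synthetic import LengthModel


class OriginFiringModel:
    """Origin-firing model (MM1--MM5) to be fitted to combing data.

    Parameters
    ----------
    data
        A `CombingDataset`, a mapping ``{global fraction: CombingDataset}``
        or ``{global fraction: ObservableCurves}``.  Datasets are reshaped
        to combing resolution and converted to observable curves.
    variant
        Model variant; determines the fitted parameters.
    genome_length
        Lattice size (kb) used for the simulations inside the objective.
    length_model
        Molecule-length sampler used to shred simulated genomes; defaults
        to the lognormal model.
    template
        Base `ModelParameters` supplying the non-fitted settings (origin
        layout, fork speed, round duration).
    """

    def __init__(
        self,
        data,
        variant: str = "MM5",
        genome_length: int = 100_000,
        length_model: LengthModel | None = None,
        template: ModelParameters | None = None,
        ga_config: GAConfig | None = None,
        condition: str = "",
        reshape: bool = True,
        max_rounds: int = 300,
    ):
        if variant not in ACTIVE_PARAMETERS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.genome_length = int(genome_length)
        self.length_model = length_model or LengthModel.lognormal()
        self.template = template or ModelParameters(
            variant=variant, origin_layout="discrete"
        )
        self.ga_config = ga_config or GAConfig()
        self.condition = condition
        self.max_rounds = max_rounds
        self.curves: dict[float, ObservableCurves] = {}
        if isinstance(data, CombingDataset):
            data = {data.global_fraction: data}
        for key, value in data.items():
            if isinstance(value, CombingDataset):
                ds = reshape_dataset(value) if reshape else value
                value = per_molecule_curves(ds)
            # match simulations against the sample's actual (post-reshaping)
            # global fraction; reshaping shifts it from the nominal target
            key = value.global_fraction if np.isfinite(value.global_fraction) else key
            self.curves[float(key)] = value

    @classmethod
    def from_tsv(cls, paths, **kw) -> "OriginFiringModel":
        """Build from molecule TSV files: a single path or a mapping
        ``{global fraction: path}``; with a single path the sample's own
        global fraction is used as the matching target."""
        if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
            ds = CombingDataset.from_tsv(paths)
            return cls(ds, **kw)
        data = {
            float(f): CombingDataset.from_tsv(path) for f, path in paths.items()
        }
        return cls(data, **kw)

    @property
    def exog_names(self) -> tuple[str, ...]:
        return ACTIVE_PARAMETERS[self.variant]

    def fit(
        self,
        repeats: int | None = None,
        generations: int | None = None,
        seed: int | np.random.Generator | None = None,
    ) -> "OriginFiringResults":
        """Run the repeated GA inference and return the results object."""
        cfg = self.ga_config
        if repeats is not None or generations is not None:
            cfg = GAConfig(
                **{
                    **cfg.__dict__,
                    **({"repeats": repeats} if repeats is not None else {}),
                    **({"generations": generations} if generations is not None else {}),
                }
            )
        ensemble = fit_condition(
            self.curves,
            variant=self.variant,
            config=cfg,
            rng=seed,
            L=self.genome_length,
            length_sampler=self.length_model,
            template=self.template,
            condition=self.condition,
            max_rounds=self.max_rounds,
        )
        return OriginFiringResults(self, ensemble)

    def simulate(
        self,
        params: ModelParameters | None = None,
        seed: int | np.random.Generator | None = None,
        **kw,
    ) -> Trajectory:
        """Run one S phase with the given (or template) parameters."""
        p = params or self.template
        return run_simulation(p, self.genome_length, seed, **kw)


class OriginFiringResults:
    """Fitted parameter ensemble with uncertainties and diagnostics."""

    def __init__(self, model: OriginFiringModel, ensemble: ParameterEnsemble):
        self.model = model
        self.ensemble = ensemble

    @property
    def params(self) -> pd.Series:
        """Ensemble mean of each fitted parameter (the reported estimate)."""
        return self.ensemble.mean

    @property
    def sd(self) -> pd.Series:
        """Ensemble standard deviation (run-to-run uncertainty)."""
        return self.ensemble.sd

    @property
    def fitness(self) -> np.ndarray:
        return self.ensemble.fitness

    @property
    def nobs(self) -> int:
        return self.ensemble.n

    def best_params(self) -> ModelParameters:
        """Parameter set of the single best run (lowest fitness)."""
        from .parameters import params_from_vector

        i = int(np.argmin(self.ensemble.fitness))
        row = self.ensemble.elites.iloc[i]
        return params_from_vector(
            row.to_numpy(), self.model.variant, self.model.template
        )

    def identifiability(self) -> pd.DataFrame:
        """Ensemble correlation matrix between fitted parameters; strong
        off-diagonal entries flag parameter trade-offs (e.g. Pin/Plocal)."""
        return self.ensemble.correlation()

    def compare(self, other: "OriginFiringResults", alpha: float = 0.01) -> pd.DataFrame:
        """Per-parameter Welch test against another fitted condition."""
        return compare_parameters(self.ensemble, other.ensemble, alpha=alpha)

    def summary(self) -> SimpleTable:
        """Summary table: mean, SD and range of each fitted parameter."""
        e = self.ensemble.elites
        rows = []
        for name in e.columns:
            rows.append(
                [
                    f"{e[name].mean():.4g}",
                    f"{e[name].std(ddof=1):.3g}",
                    f"{e[name].min():.4g}",
                    f"{e[name].max():.4g}",
                ]
            )
        title = (
            f"Origin firing model {self.model.variant} "
            f"({self.nobs} GA repeats, best fitness "
            f"{self.fitness.min():.4g})"
        )
        return SimpleTable(
            rows,
            headers=["mean", "sd", "min", "max"],
            stubs=list(e.columns),
            title=title,
        )

    def plot_ensemble(self, ax=None):
        """Box plot of the fitted ensemble per parameter (normalized to the
        ensemble mean) for a quick dispersion check."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        e = self.ensemble.elites
        norm = e / e.mean()
        ax.boxplot([norm[c] for c in norm.columns], tick_labels=list(norm.columns))
        ax.set_ylabel("value / ensemble mean")
        ax.set_title(f"{self.model.variant} parameter ensemble (n={self.nobs})")
        return ax
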