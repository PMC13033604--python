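"""Top-level modelling interface: a model object built from cohort data
whose ``fit`` returns a results object carrying estimates, uncertainty and
the downstream analyses.

    >>> model = AbscopalModel.from_csv("cohort.csv")
    >>> res = model.fit(seed=7, bootstrap=10)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    BootstrapEnsemble,
    CalibrationProblem,
    FitResult,
    GaConfig,
    TumorGrowthDataset,
    bootstrap_refit,
    fit_ga,
)
from .engine import Trajectory, simulate
from .parameters import FITTED_VECTOR_NAMES, UNITS, ParameterSet
from .physiology import CompartmentId, PhysiologyTable, build_default_physiology
from .radiotherapy import build_protocol
from .sensitivity import default_baselines, totvar_table
from .correlation import correlation_table

_TUMORS = {"T1": CompartmentId.TUMOR1, "T2": CompartmentId.TUMOR2}


class AbscopalModel:
    """PBPK-QSP tumor-immune model bound to a tumor-growth cohort.

    Parameters
    ----------
    data
        Long-format cohort (subject, group, tumor, day, volume_mm3).
    start_params
        Starting/fixed parameter values; defaults to the shipped set.
    free_parameters
        Scalars of the fitted vector the optimizer may move.
    """

    def __init__(
        self,
        data: TumorGrowthDataset | pd.DataFrame,
        start_params: ParameterSet | None = None,
        free_parameters: tuple[str, ...] = FITTED_VECTOR_NAMES,
        physiology: PhysiologyTable | None = None,
        weight_growth: float | None = None,
        horizon_days: float = 24.0,
    ):
        if isinstance(data, pd.DataFrame):
            data = TumorGrowthDataset(data)
        self.data = data
        self.start_params = start_params or ParameterSet.default()
        self.free_parameters = tuple(free_parameters)
        self.physiology = physiology or build_default_physiology()
        self.weight_growth = weight_growth
        self.horizon_days = horizon_days

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "AbscopalModel":
        return cls(TumorGrowthDataset(frame), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AbscopalModel":
        return cls(TumorGrowthDataset.from_csv(path), **kwargs)

    def _problem(self) -> CalibrationProblem:
        return CalibrationProblem(
            dataset=self.data,
            base=self.start_params,
            free_parameters=self.free_parameters,
            weight_growth=self.weight_growth,
            horizon_days=self.horizon_days,
            physiology=self.physiology,
        )

    def fit(
        self,
        ga_config: GaConfig | None = None,
        seed: int = 0,
        bootstrap: int | None = None,
        init_spread: float = 0.7,
        init_population: np.ndarray | None = None,
    ) -> "AbscopalResults":
        """Calibrate by log-space GA, optionally with bootstrap refits.

        The initial population is drawn log-uniformly within
        ``+/- init_spread`` (natural-log units) of the starting values
        unless given explicitly.
        """
        config = ga_config or GaConfig()
        problem = self._problem()
        rng = np.random.default_rng(seed)
        center = problem.log_from_params(self.start_params)
        if init_population is None:
            init_population = center[None, :] + rng.uniform(
                -init_spread, init_spread,
                size=(config.population_size, center.size),
            )
            init_population[0] = center
        base_fit = fit_ga(problem, init_population, config, seed=seed)
        ensemble = None
        if bootstrap:
            ensemble = bootstrap_refit(
                problem,
                base_fit,
                n_replicates=bootstrap,
                config=config,
                seed=seed + 1,
            )
        return AbscopalResults(self, base_fit, ensemble)

    def simulate(
        self, group: str, params: ParameterSet | None = None, **kwargs
    ) -> Trajectory:
        kwargs.setdefault("physiology", self.physiology)
        return simulate(
            params or self.start_params,
            build_protocol(group),
            kwargs.pop("horizon_days", self.horizon_days),
            **kwargs,
        )


@dataclass
class AbscopalResults:
    """Calibration results: point estimates, bootstrap uncertainty, and
    entry points to the sweep analyses."""

    model: AbscopalModel
    fit_result: FitResult
    bootstrap: BootstrapEnsemble | None = None

    @property
    def params(self) -> ParameterSet:
        return self.fit_result.to_parameter_set(self.model.start_params)

    @property
    def sse(self) -> float:
        return self.fit_result.sse

    def baseline_parameter_sets(self, n: int = 5, seed: int = 0) -> list[ParameterSet]:
        """Baselines for the sweep analyses: bootstrap optima when
        available, else a jittered stand-in ensemble around the optimum."""
        if self.bootstrap is not None:
            sets = self.bootstrap.parameter_sets(self.model.start_params)
            return sets[:n] if n else sets
        return default_baselines(self.params, n, seed)

    def summary(self) -> str:
        lines = [
            "Abscopal PBPK-QSP model calibration",
            "=" * 64,
            f"groups: {', '.join(self.model.data.groups)}",
            f"curves: {len(list(self.model.data.curves()))}   SSE: {self.sse:.6g}",
            f"GA: pop={self.fit_result.population_size} "
            f"gens={self.fit_result.generations_run} seed={self.fit_result.seed}",
            "-" * 64,
            f"{'parameter':<16}{'estimate':>12}  {'unit':<14}"
            + ("ci5        ci95" if self.bootstrap is not None else ""),
        ]
        stats = self.bootstrap.statistics() if self.bootstrap is not None else None
        for name, value in self.fit_result.params_linear.items():
            row = f"{name:<16}{value:>12.4g}  {UNITS.get(name, ''):<14}"
            if stats is not None:
                s = stats[stats.parameter == name]
                if len(s):
                    row += f"{float(s.ci5.iloc[0]):<11.4g}{float(s.ci95.iloc[0]):.4g}"
            lines.append(row)
        if self.bootstrap is not None:
            lines.append("-" * 64)
            lines.append(f"bootstrap replicates: {self.bootstrap.n_replicates}")
        return "\n".join(lines)

    def simulate(self, group: str, **kwargs) -> Trajectory:
        return self.model.simulate(group, params=self.params, **kwargs)

    def predicted_frame(self) -> pd.DataFrame:
        """Model predictions at the observed (group, tumor, day) points."""
        rows = []
        sims = {g: self.simulate(g) for g in self.model.data.groups}
        for subj, group, tumor, days, volumes in self.model.data.curves():
            tr = sims[group]
            pred = np.interp(days, tr.times, tr.tumor_volume_series(_TUMORS[tumor]))
            for d, obs, prd in zip(days, volumes, pred):
                rows.append(
                    {
                        "subject": subj,
                        "group": group,
                        "tumor": tumor,
                        "day": d,
                        "observed_mm3": obs,
                        "predicted_mm3": prd,
                    }
                )
        return pd.DataFrame(rows)

    def sensitivity_table(
        self, n_baselines: int = 5, seed: int = 0, **kwargs
    ) -> pd.DataFrame:
        """Time-integrated total-variance heatmap table (long format)."""
        baselines = self.baseline_parameter_sets(n_baselines, seed)
        kwargs.setdefault("physiology", self.model.physiology)
        return totvar_table(baselines, **kwargs)

    def correlation_table(
        self, n_baselines: int = 5, seed: int = 0, **kwargs
    ) -> pd.DataFrame:
        """Bootstrap-stable Spearman correlation table."""
        baselines = self.baseline_parameter_sets(n_baselines, seed)
        kwargs.setdefault("physiology", self.model.physiology)
        return correlation_table(baselines, **kwargs)

    def plot_fit(self, ax=None):
        """Observed group means vs model predictions per tumor."""
        import matplotlib.pyplot as plt

        frame = self.predicted_frame()
        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        else:
            axes = ax
        for k, tumor in enumerate(("T1", "T2")):
            a = axes[k]
            sub = frame[frame.tumor == tumor]
            for group, grp in sub.groupby("group"):
                mean_obs = grp.groupby("day")["observed_mm3"].mean()
                mean_prd = grp.groupby("day")["predicted_mm3"].mean()
                a.plot(mean_obs.index, mean_obs.values, "o-", label=f"{group} obs")
                a.plot(mean_prd.index, mean_prd.values, "--", label=f"{group} model")
            a.set_xlabel("day")
            a.set_title(tumor)
            if k == 0:
                a.set_ylabel("tumor volume (mm$^3$)")
        axes[0].legend(fontsize=7)
        return axes
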