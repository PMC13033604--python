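"""Log-space genetic-algorithm calibration with bootstrap uncertainty.

The fitting objective is the sum of squared errors between simulated and
observed tumor volumes plus a weighted term on empirical growth rates
(central differences of the volume measurements), evaluated per subject
curve.  Optimization runs in log-parameter space to enforce positivity;
search bounds are set adaptively around the initial population with a
randomized expansion of up to 10% in log space.  Uncertainty comes from
resampling whole subject-tumor curves with replacement within each
(group, tumor) stratum and refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory, simulate, summarize_ensemble
from .parameters import FITTED_VECTOR_NAMES, ParameterSet
from .physiology import CompartmentId, PhysiologyTable
from .radiotherapy import TreatmentProtocol, build_protocol

_REQUIRED_COLUMNS = ("subject", "group", "tumor", "day", "volume_mm3")
_TUMOR_IDS = {"T1": CompartmentId.TUMOR1, "T2": CompartmentId.TUMOR2}


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

class TumorGrowthDataset:
    """Long-format per-subject tumor-volume time series.

    Columns: subject, group, tumor (T1/T2), day, volume_mm3.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        extra = [c for c in frame.columns if c not in _REQUIRED_COLUMNS]
        if extra:
            import warnings

            warnings.warn(f"ignoring extra dataset columns: {extra}")
        frame = frame[list(_REQUIRED_COLUMNS)].copy()
        frame["day"] = frame["day"].astype(float)
        frame["volume_mm3"] = frame["volume_mm3"].astype(float)
        if (frame["volume_mm3"] <= 0).any():
            raise ValueError("volumes must be strictly positive")
        bad_tumor = set(frame["tumor"]) - set(_TUMOR_IDS)
        if bad_tumor:
            raise ValueError(f"unknown tumor ids: {sorted(bad_tumor)}")
        for (subj, tumor), grp in frame.groupby(["subject", "tumor"]):
            days = grp["day"].to_numpy()
            if np.any(np.diff(days) <= 0):
                raise ValueError(
                    f"days must be strictly increasing for ({subj}, {tumor})"
                )
        per_subject = frame.groupby("subject")["tumor"].nunique()
        if (per_subject < 2).any():
            lacking = per_subject[per_subject < 2].index.tolist()
            raise ValueError(f"subjects missing a tumor: {lacking}")
        self.frame = frame.sort_values(["group", "subject", "tumor", "day"]).reset_index(
            drop=True
        )

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def group_sizes(self) -> pd.Series:
        return self.frame.groupby(["group", "tumor"])["subject"].nunique()

    def curves(self):
        """Iterate (subject, group, tumor, days, volumes)."""
        for (subj, group, tumor), grp in self.frame.groupby(
            ["subject", "group", "tumor"], sort=False
        ):
            yield subj, group, tumor, grp["day"].to_numpy(), grp["volume_mm3"].to_numpy()

    def resample(self, rng: np.random.Generator) -> tuple["TumorGrowthDataset", dict]:
        """Bootstrap: draw whole subject-tumor curves with replacement
        within each (group, tumor) stratum, preserving stratum sizes."""
        pieces = []
        index_lists: dict[str, list] = {}
        for (group, tumor), grp in self.frame.groupby(["group", "tumor"]):
            subjects = sorted(grp["subject"].unique())
            draw = rng.integers(0, len(subjects), size=len(subjects))
            index_lists[f"{group}/{tumor}"] = [subjects[i] for i in draw]
            for new_id, i in enumerate(draw):
                curve = grp[grp["subject"] == subjects[i]].copy()
                curve["subject"] = f"{group}:{tumor}:boot{new_id}"
                pieces.append(curve)
        frame = pd.concat(pieces, ignore_index=True)
        # resampled curves are per-(group, tumor); rebuild subject pairing so
        # the both-tumors invariant holds for the validator
        frame["subject"] = (
            frame["subject"].str.replace(":T1:", ":", regex=False).str.replace(":T2:", ":", regex=False)
        )
        return TumorGrowthDataset(frame), index_lists

    # -- IO -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps the volume round-trip lossless
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TumorGrowthDataset":
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover
            raise ValueError(f"cannot read cohort CSV {path}: {exc}") from exc
        return cls(frame)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def central_difference_growth(days: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Empirical growth rate (mm^3/day): central differences at interior
    points, one-sided at the ends; exact for linear data."""
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if days.size < 2:
        raise ValueError("need at least two measurements")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing (no duplicates)")
    rates = np.empty_like(volumes)
    rates[0] = (volumes[1] - volumes[0]) / (days[1] - days[0])
    rates[-1] = (volumes[-1] - volumes[-2]) / (days[-1] - days[-2])
    if days.size > 2:
        rates[1:-1] = (volumes[2:] - volumes[:-2]) / (days[2:] - days[:-2])
    return rates


@dataclass
class CalibrationProblem:
    """Shared context for objective evaluations.

    ``free_parameters`` selects which scalars of the fitted vector the
    optimizer moves; the rest stay at ``base`` values.  One simulation per
    treatment group serves every subject curve of that group.
    """

    dataset: TumorGrowthDataset
    base: ParameterSet
    free_parameters: tuple[str, ...] = FITTED_VECTOR_NAMES
    weight_growth: float | None = None  # None -> control-variance normalization
    horizon_days: float = 24.0
    rtol: float = 1.0e-4          # SSE needs far less accuracy than analysis runs
    method: str = "LSODA"
    grid_spacing: float = 1.0
    physiology: PhysiologyTable | None = None
    n_failures: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        unknown = set(self.free_parameters) - set(FITTED_VECTOR_NAMES)
        if unknown:
            raise KeyError(f"unknown fitted parameters: {sorted(unknown)}")
        self.protocols = {g: build_protocol(g) for g in self.dataset.groups}
        self._curves = list(self.dataset.curves())
        self._cache: dict[bytes, float] = {}
        if self.weight_growth is None:
            self.weight_growth = self._default_weight()

    def _default_weight(self) -> float:
        """Normalize the growth term by the ratio of control-group data
        variances (volume variance / growth-rate variance)."""
        control = [
            (d, v) for _, g, _, d, v in self._curves if g.upper().startswith("CONTROL")
        ]
        if not control:
            control = [(d, v) for _, _, _, d, v in self._curves]
        vols = np.concatenate([v for _, v in control])
        rates = np.concatenate([central_difference_growth(d, v) for d, v in control])
        var_r = np.var(rates)
        return float(np.var(vols) / var_r) if var_r > 0 else 1.0

    def params_from_log(self, log_values: np.ndarray) -> ParameterSet:
        updates = {
            name: float(np.exp(lv))
            for name, lv in zip(self.free_parameters, log_values)
        }
        return self.base.with_updates(**updates)

    def log_from_params(self, params: ParameterSet) -> np.ndarray:
        return np.log([getattr(params, n) for n in self.free_parameters])

    def objective(self, log_values: np.ndarray) -> float:
        """SSE on volumes plus weighted SSE on empirical growth rates;
        +inf (with a counted cause) if a candidate fails to simulate.
        Repeated candidates (GA elites) are served from a cache."""
        log_values = np.asarray(log_values, dtype=float)
        key = np.round(log_values, 12).tobytes()
        if key in self._cache:
            return self._cache[key]
        try:
            params = self.params_from_log(log_values)
            sims: dict[str, Trajectory] = {
                g: simulate(
                    params,
                    proto,
                    self.horizon_days,
                    rtol=self.rtol,
                    method=self.method,
                    grid_spacing=self.grid_spacing,
                    physiology=self.physiology,
                )
                for g, proto in self.protocols.items()
            }
        except Exception:
            self.n_failures += 1
            self._cache[key] = float("inf")
            return float("inf")
        sse = 0.0
        for _, group, tumor, days, volumes in self._curves:
            tr = sims[group]
            sim_v = np.interp(days, tr.times, tr.tumor_volume_series(_TUMOR_IDS[tumor]))
            sse += float(((sim_v - volumes) ** 2).sum())
            if self.weight_growth:
                g_obs = central_difference_growth(days, volumes)
                g_sim = central_difference_growth(days, sim_v)
                sse += self.weight_growth * float(((g_sim - g_obs) ** 2).sum())
        self._cache[key] = sse
        return sse


def sse_objective(
    log_params: np.ndarray,
    dataset: TumorGrowthDataset,
    base: ParameterSet,
    free_parameters: tuple[str, ...] = FITTED_VECTOR_NAMES,
    weight_growth: float | None = None,
    **kwargs,
) -> float:
    """One-shot objective evaluation (builds a throwaway problem)."""
    problem = CalibrationProblem(
        dataset=dataset,
        base=base,
        free_parameters=free_parameters,
        weight_growth=weight_growth,
        **kwargs,
    )
    return problem.objective(np.asarray(log_params, dtype=float))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaConfig:
    population_size: int = 40
    generations: int = 60
    crossover_rate: float = 0.9
    mutation_rate: float = 0.25
    mutation_sigma: float = 0.20   # log-space step
    mutation_decay: float = 0.96   # sigma shrink per generation (anneal)
    tournament_k: int = 3
    n_elite: int = 2
    stall_generations: int | None = None  # early stop; None = run all
    stall_rel_improvement: float = 1e-3   # smaller gains count as stalled
    polish_maxfev: int = 0                # hybrid Nelder-Mead refinement budget


@dataclass
class FitResult:
    log_params: np.ndarray
    parameter_names: tuple[str, ...]
    sse: float
    generations_run: int
    population_size: int
    seed: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.sse) or self.sse < 0:
            raise ValueError("SSE must be finite and non-negative")

    @property
    def params_linear(self) -> dict[str, float]:
        return {
            n: float(np.exp(v)) for n, v in zip(self.parameter_names, self.log_params)
        }

    def to_parameter_set(self, base: ParameterSet) -> ParameterSet:
        return base.with_updates(**self.params_linear)

    def to_json(self) -> str:
        return json.dumps(
            {
                "log_params": list(map(float, self.log_params)),
                "parameter_names": list(self.parameter_names),
                "params_linear": self.params_linear,
                "sse": self.sse,
                "generations_run": self.generations_run,
                "population_size": self.population_size,
                "seed": self.seed,
            },
            indent=2,
        )


def adaptive_log_bounds(
    initial_population: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter search bounds around the initial population: the
    column min/max expanded outward by an independent Uniform(0, 10%)
    fraction of the bound magnitude, in log space.  Bounds always contain
    the initial population."""
    pop = np.atleast_2d(np.asarray(initial_population, dtype=float))
    if pop.size == 0:
        raise ValueError("empty initial population")
    lo = pop.min(axis=0)
    hi = pop.max(axis=0)
    u_lo = rng.uniform(0.0, 1.0, size=lo.shape)
    u_hi = rng.uniform(0.0, 1.0, size=hi.shape)
    lower = lo - u_lo * 0.1 * np.abs(lo)
    upper = hi + u_hi * 0.1 * np.abs(hi)
    return lower, upper


def run_ga(
    objective,
    init_population: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    config: GaConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """Real-coded GA: tournament selection, blend crossover, Gaussian
    mutation, elitism.  Returns (best_x, best_f, generations_run)."""
    lower, upper = bounds
    ndim = lower.size
    pop_size = config.population_size
    pop = np.atleast_2d(np.asarray(init_population, dtype=float)).copy()
    if pop.shape[1] != ndim:
        raise ValueError("population dimension mismatch")
    # fill to pop_size with uniform draws inside the bounds
    if pop.shape[0] < pop_size:
        fill = rng.uniform(lower, upper, size=(pop_size - pop.shape[0], ndim))
        pop = np.vstack([pop, fill])
    else:
        pop = pop[:pop_size]
    pop = np.clip(pop, lower, upper)
    fitness = np.array([objective(x) for x in pop])
    if not np.isfinite(fitness).any():
        raise RuntimeError("all initial candidates evaluate to +inf")

    best_idx = int(np.argmin(fitness))
    best_x, best_f = pop[best_idx].copy(), float(fitness[best_idx])
    stall = 0
    gens_run = 0
    sigma = config.mutation_sigma
    for _ in range(config.generations):
        gens_run += 1
        order = np.argsort(fitness)
        elite = pop[order[: config.n_elite]].copy()
        children = []
        while len(children) < pop_size - config.n_elite:
            p1 = _tournament(pop, fitness, config.tournament_k, rng)
            p2 = _tournament(pop, fitness, config.tournament_k, rng)
            if rng.uniform() < config.crossover_rate:
                alpha = rng.uniform(-0.25, 1.25, size=ndim)
                child = alpha * p1 + (1 - alpha) * p2
            else:
                child = p1.copy()
            mask = rng.uniform(size=ndim) < config.mutation_rate
            child[mask] += rng.normal(0.0, sigma, size=mask.sum())
            children.append(np.clip(child, lower, upper))
        sigma *= config.mutation_decay
        pop = np.vstack([elite] + children)
        fitness = np.concatenate(
            [
                [objective(x) for x in elite],
                [objective(x) for x in children],
            ]
        ).astype(float)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f - 1e-12:
            significant = fitness[gen_best] < best_f * (
                1.0 - config.stall_rel_improvement
            )
            best_x, best_f = pop[gen_best].copy(), float(fitness[gen_best])
            stall = 0 if significant else stall + 1
        else:
            stall += 1
        if config.stall_generations and stall >= config.stall_generations:
            break
    return best_x, best_f, gens_run


def _tournament(pop, fitness, k, rng):
    idx = rng.integers(0, pop.shape[0], size=k)
    return pop[idx[np.argmin(fitness[idx])]].copy()


def fit_ga(
    problem: CalibrationProblem,
    init_population: np.ndarray,
    config: GaConfig = GaConfig(),
    seed: int = 0,
    objective=None,
) -> FitResult:
    """Fit the problem's free parameters by log-space GA.

    ``init_population`` rows are log-parameter vectors (e.g. the baseline
    optimum plus prior bootstrap optima); bounds are drawn adaptively
    around it.  Reproducible for fixed seed and config.
    """
    rng = np.random.default_rng(seed)
    init_population = np.atleast_2d(np.asarray(init_population, dtype=float))
    bounds = adaptive_log_bounds(init_population, rng)
    obj = objective if objective is not None else problem.objective
    best_x, best_f, gens = run_ga(obj, init_population, bounds, config, rng)
    if config.polish_maxfev:
        # hybrid local refinement from the GA optimum (narrow curved
        # valleys defeat isotropic mutation); stays inside the bounds
        from scipy.optimize import minimize

        lower, upper = bounds

        def clipped(x):
            return obj(np.clip(x, lower, upper))

        res = minimize(
            clipped, best_x, method="Nelder-Mead",
            options=dict(maxfev=config.polish_maxfev, xatol=1e-5, fatol=1e-6),
        )
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lower, upper), float(res.fun)
    return FitResult(
        log_params=best_x,
        parameter_names=tuple(problem.free_parameters) if problem else (),
        sse=best_f,
        generations_run=gens,
        population_size=config.population_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapEnsemble:
    fits: list[FitResult]
    resample_indices: list[dict]
    parameter_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.fits:
            raise ValueError("ensemble needs at least one fit")

    @property
    def n_replicates(self) -> int:
        return len(self.fits)

    def log_matrix(self) -> np.ndarray:
        return np.vstack([f.log_params for f in self.fits])

    def parameter_sets(self, base: ParameterSet) -> list[ParameterSet]:
        return [f.to_parameter_set(base) for f in self.fits]

    def statistics(self) -> pd.DataFrame:
        """Per-parameter mean/median/sd and 90% CI on the linear scale."""
        linear = np.exp(self.log_matrix())
        return pd.DataFrame(
            {
                "parameter": self.parameter_names,
                "mean": linear.mean(axis=0),
                "median": np.median(linear, axis=0),
                "sd": linear.std(axis=0, ddof=1) if linear.shape[0] > 1 else 0.0,
                "ci5": np.quantile(linear, 0.05, axis=0),
                "ci95": np.quantile(linear, 0.95, axis=0),
            }
        )

    def trajectory_bands(
        self,
        base: ParameterSet,
        group: str,
        tumor: CompartmentId = CompartmentId.TUMOR1,
        horizon_days: float = 24.0,
        quantiles: tuple[float, float] = (0.05, 0.95),
        **sim_kwargs,
    ) -> pd.DataFrame:
        trajectories = [
            simulate(ps, build_protocol(group), horizon_days, **sim_kwargs)
            for ps in self.parameter_sets(base)
        ]
        return summarize_ensemble(trajectories, quantiles, tumor=tumor)

    def to_json(self) -> str:
        return json.dumps(
            {
                "parameter_names": list(self.parameter_names),
                "log_params": [list(map(float, f.log_params)) for f in self.fits],
                "sse": [f.sse for f in self.fits],
                "resample_indices": self.resample_indices,
                "statistics": self.statistics().to_dict(orient="list"),
            },
            indent=2,
        )


def bootstrap_refit(
    problem: CalibrationProblem,
    base_fit: FitResult,
    n_replicates: int = 50,
    config: GaConfig = GaConfig(),
    seed: int = 0,
    force_identity_resample: bool = False,
) -> BootstrapEnsemble:
    """Resample-and-refit: each replicate draws a stratified bootstrap of
    the cohort, seeds its GA with the baseline optimum plus prior
    replicate optima, and refits under fresh adaptive bounds."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    fits: list[FitResult] = []
    resamples: list[dict] = []
    prior_optima = [base_fit.log_params]
    for b in range(n_replicates):
        if force_identity_resample:
            boot_data, idx = problem.dataset, {"identity": True}
        else:
            boot_data, idx = problem.dataset.resample(rng)
        resamples.append(idx)
        boot_problem = CalibrationProblem(
            dataset=boot_data,
            base=problem.base,
            free_parameters=problem.free_parameters,
            weight_growth=problem.weight_growth,
            horizon_days=problem.horizon_days,
            rtol=problem.rtol,
            method=problem.method,
            grid_spacing=problem.grid_spacing,
            physiology=problem.physiology,
        )
        init = np.vstack(prior_optima)
        fit = fit_ga(
            boot_problem, init, config, seed=int(rng.integers(0, 2**31 - 1))
        )
        fits.append(fit)
        prior_optima.append(fit.log_params)
    return BootstrapEnsemble(
        fits=fits,
        resample_indices=resamples,
        parameter_names=tuple(problem.free_parameters),
    )
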