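import numpy as np
import pandas as pd
import pytest

from abscopal.calibration import (
    CalibrationProblem,
    GaConfig,
    TumorGrowthDataset,
    adaptive_log_bounds,
    bootstrap_refit,
    central_difference_growth,
    fit_ga,
    run_ga,
)


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "days, volumes, expected",
    [
        ([0, 1, 2], [1, 2, 4], [1.0, 1.5, 2.0]),
        ([0, 2, 5], [3, 3, 3], [0.0, 0.0, 0.0]),
        ([0, 1, 3, 7], [0, 3, 9, 21], [3.0, 3.0, 3.0, 3.0]),  # exact on linear
    ],
)
def test_central_difference_growth(days, volumes, expected):
    np.testing.assert_allclose(
        central_difference_growth(np.array(days, float), np.array(volumes, float)),
        expected,
    )


def test_central_difference_rejects_duplicate_days():
    with pytest.raises(ValueError, match="strictly increasing"):
        central_difference_growth(np.array([0.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def test_dataset_schema_validation(clean_cohort):
    dataset, _ = clean_cohort
    frame = dataset.frame
    with pytest.raises(ValueError, match="missing columns"):
        TumorGrowthDataset(frame.drop(columns=["volume_mm3"]))
    bad = frame.copy()
    bad.loc[0, "volume_mm3"] = -1.0
    with pytest.raises(ValueError, match="strictly positive"):
        TumorGrowthDataset(bad)
    with pytest.warns(UserWarning, match="extra"):
        TumorGrowthDataset(frame.assign(note="x"))


def test_bootstrap_preserves_stratum_sizes(noisy_cohort, rng):
    dataset, _ = noisy_cohort
    original = dataset.group_sizes()
    for _ in range(5):
        boot, idx = dataset.resample(rng)
        pd.testing.assert_series_equal(
            boot.group_sizes(), original, check_names=False
        )
        assert set(idx) == {
            f"{g}/{t}" for g, t in original.index
        }


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def test_sse_self_consistency_on_noise_free_data(clean_cohort, params):
    """Data generated at the candidate parameters give near-zero SSE."""
    dataset, _ = clean_cohort
    problem = CalibrationProblem(dataset=dataset, base=params)
    sse = problem.objective(problem.log_from_params(params))
    # nonzero only through integrator tolerance differences
    scale = float((dataset.frame.volume_mm3**2).sum())
    assert sse < 1e-5 * scale


def test_sse_constant_offset_algebra(clean_cohort, params):
    """+c on every volume of one subject curve adds m*c^2 to the volume
    term and leaves the growth term unchanged (central differences kill
    constant offsets)."""
    dataset, _ = clean_cohort
    base_problem = CalibrationProblem(
        dataset=dataset, base=params, weight_growth=0.7
    )
    log_p = base_problem.log_from_params(params)
    sse0 = base_problem.objective(log_p)

    frame = dataset.frame.copy()
    subject = frame.subject.iloc[0]
    mask = (frame.subject == subject) & (frame.tumor == "T1")
    m = int(mask.sum())
    c = 50.0
    frame.loc[mask, "volume_mm3"] += c
    shifted = CalibrationProblem(
        dataset=TumorGrowthDataset(frame), base=params, weight_growth=0.7
    )
    sse1 = shifted.objective(log_p)
    # the cross term 2*c*sum(residuals) is not zero in general, so compare
    # against the exact algebraic prediction
    tr_days = dataset.frame[mask.values]["day"].to_numpy()
    import abscopal.engine as eng
    from abscopal.physiology import CompartmentId
    from abscopal.radiotherapy import build_protocol

    # reconstruct exactly the parameters the objective simulates with
    # (exp(log(x)) differs from x by an ulp, enough to shift solver steps)
    sim_params = base_problem.params_from_log(log_p)
    sim = eng.simulate(sim_params, build_protocol(frame.loc[mask, "group"].iloc[0]),
                       24.0, rtol=1e-4, method="LSODA", grid_spacing=1.0)
    sim_v = np.interp(tr_days, sim.times, sim.tumor_volume_series(CompartmentId.TUMOR1))
    obs_v = dataset.frame[mask.values]["volume_mm3"].to_numpy()
    predicted_delta = m * c**2 + 2 * c * float((obs_v - sim_v).sum())
    assert sse1 - sse0 == pytest.approx(predicted_delta, rel=1e-6)


def test_weight_zero_reduces_to_volume_sse(clean_cohort, params):
    dataset, _ = clean_cohort
    p0 = CalibrationProblem(dataset=dataset, base=params, weight_growth=0.0)
    log_p = p0.log_from_params(params.scaled("lg_tumor", 1.1))
    sse = p0.objective(log_p)
    # recompute volume term by hand
    from abscopal.physiology import CompartmentId
    from abscopal.radiotherapy import build_protocol
    import abscopal.engine as eng

    total = 0.0
    sims = {
        g: eng.simulate(params.scaled("lg_tumor", 1.1), build_protocol(g), 24.0,
                        rtol=1e-4, method="LSODA", grid_spacing=1.0)
        for g in dataset.groups
    }
    comp = {"T1": CompartmentId.TUMOR1, "T2": CompartmentId.TUMOR2}
    for _, group, tumor, days, volumes in dataset.curves():
        sim_v = np.interp(days, sims[group].times,
                          sims[group].tumor_volume_series(comp[tumor]))
        total += float(((sim_v - volumes) ** 2).sum())
    assert sse == pytest.approx(total, rel=1e-9)


# ---------------------------------------------------------------------------
# GA machinery
# ---------------------------------------------------------------------------

def test_adaptive_bounds_bracket_population(rng):
    pop = rng.normal(-5.0, 2.0, size=(12, 6))
    lower, upper = adaptive_log_bounds(pop, rng)
    assert (lower <= pop.min(axis=0) + 1e-12).all()
    assert (upper >= pop.max(axis=0) - 1e-12).all()
    # expansion is at most 10% of the bound magnitude
    assert (pop.min(axis=0) - lower <= 0.1 * np.abs(pop.min(axis=0)) + 1e-12).all()
    assert (upper - pop.max(axis=0) <= 0.1 * np.abs(pop.max(axis=0)) + 1e-12).all()


def test_adaptive_bounds_single_member_and_determinism():
    x = np.array([[-3.0, 1.5, -0.2]])
    lo1, hi1 = adaptive_log_bounds(x, np.random.default_rng(5))
    lo2, hi2 = adaptive_log_bounds(x, np.random.default_rng(5))
    np.testing.assert_array_equal(lo1, lo2)
    np.testing.assert_array_equal(hi1, hi2)
    assert (lo1 <= x[0]).all() and (hi1 >= x[0]).all()
    assert (x[0] - lo1 <= 0.1 * np.abs(x[0])).all()
    with pytest.raises(ValueError):
        adaptive_log_bounds(np.empty((0, 3)), np.random.default_rng(0))


def test_ga_finds_analytic_minimum_of_toy_bowl(rng):
    """Quadratic bowl in log space; the GA lands within 1% of the known
    minimizer."""
    target = np.array([-2.0, 1.0])

    def bowl(x):
        return float(((x - target) ** 2).sum())

    init = rng.uniform(-4.0, 3.0, size=(30, 2))
    best_x, best_f, _ = run_ga(
        bowl, init, (np.full(2, -6.0), np.full(2, 5.0)),
        GaConfig(population_size=30, generations=80),
        np.random.default_rng(11),
    )
    assert np.abs(best_x - target).max() < 0.01 * np.abs(target).max() + 0.005
    assert best_f < 1e-3


def test_ga_elitism_contract(rng):
    """An initial population containing the optimum can never end worse."""
    target = np.array([0.5, -1.5, 2.0])

    def bowl(x):
        return float(((x - target) ** 2).sum())

    init = np.vstack([target, rng.uniform(-3, 3, size=(10, 3))])
    best_x, best_f, _ = run_ga(
        bowl, init, (np.full(3, -5.0), np.full(3, 5.0)),
        GaConfig(population_size=20, generations=10),
        np.random.default_rng(2),
    )
    assert best_f <= bowl(target) + 1e-15


def test_ga_is_deterministic_for_fixed_seed(clean_cohort, params):
    dataset, _ = clean_cohort
    free = ("lg_tumor", "vi_tumor0_mm3")
    config = GaConfig(population_size=8, generations=3)
    results = []
    for _ in range(2):
        problem = CalibrationProblem(
            dataset=dataset, base=params, free_parameters=free
        )
        center = problem.log_from_params(params)
        init = center[None, :] + np.random.default_rng(9).uniform(
            -0.5, 0.5, size=(8, 2)
        )
        results.append(fit_ga(problem, init, config, seed=21))
    np.testing.assert_array_equal(results[0].log_params, results[1].log_params)
    assert results[0].sse == results[1].sse


def test_bootstrap_refit_identity_resample(clean_cohort, params):
    """B=1 with the resample forced to identity reduces to a plain refit."""
    dataset, _ = clean_cohort
    free = ("lg_tumor",)
    problem = CalibrationProblem(dataset=dataset, base=params, free_parameters=free)
    center = problem.log_from_params(params)
    init = center[None, :] + np.linspace(-0.3, 0.3, 6)[:, None]
    config = GaConfig(population_size=6, generations=2)
    base_fit = fit_ga(problem, init, config, seed=3)
    ensemble = bootstrap_refit(
        problem, base_fit, n_replicates=1, config=config, seed=3,
        force_identity_resample=True,
    )
    assert ensemble.n_replicates == 1
    assert ensemble.resample_indices == [{"identity": True}]
    stats = ensemble.statistics()
    assert set(stats.parameter) == set(free)
    with pytest.raises(ValueError):
        bootstrap_refit(problem, base_fit, n_replicates=0, config=config)
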