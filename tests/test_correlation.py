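import numpy as np
import pytest
from math import factorial

from abscopal.correlation import (
    _null_abs_rho,
    group_difference,
    spearman_exact,
    stability_filter,
)

LEVELS = np.array([10.0, 1.5, 1.1, 0.9, 0.5, 0.1])


# ---------------------------------------------------------------------------
# time-averaged group difference
# ---------------------------------------------------------------------------

def test_group_difference_basics():
    t = np.linspace(0, 24, 97)
    f = np.exp(0.1 * t)
    assert group_difference(f, f, t) == 0.0
    assert group_difference(f + 3.0, f, t) == pytest.approx(3.0, rel=1e-12)
    # antisymmetry
    g = np.sin(t) + 5
    assert group_difference(f, g, t) == pytest.approx(
        -group_difference(g, f, t), rel=1e-12
    )


def test_group_difference_matches_fine_grid_quadrature(rng):
    t = np.linspace(0, 24, 97)
    a = np.sin(0.4 * t) + 0.05 * rng.normal(size=t.size) + 4
    b = np.cos(0.3 * t) + 0.05 * rng.normal(size=t.size) + 3
    got = group_difference(a, b, t)
    t_fine = np.linspace(0, 24, 961)
    oracle = np.trapezoid(
        np.interp(t_fine, t, a) - np.interp(t_fine, t, b), t_fine
    ) / (t_fine[-1] - t_fine[0])
    assert got == pytest.approx(oracle, rel=1e-8)


def test_group_difference_rejects_mismatched_grids():
    t = np.linspace(0, 10, 11)
    with pytest.raises(ValueError, match="grid"):
        group_difference(np.ones(11), np.ones(10), t)


# ---------------------------------------------------------------------------
# exact Spearman
# ---------------------------------------------------------------------------

def test_monotone_deltas_give_exact_p():
    deltas = np.argsort(np.argsort(LEVELS)).astype(float)  # increasing with level
    rho, p = spearman_exact(LEVELS, deltas)
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / factorial(6), rel=1e-12)
    rho, p = spearman_exact(LEVELS, -deltas)
    assert rho == pytest.approx(-1.0)
    assert p == pytest.approx(2 / factorial(6), rel=1e-12)


def test_exact_null_matches_brute_force_recomputation():
    """Independent oracle: rebuild the permutation null from scratch with
    a different code path (scipy rank correlation per permutation)."""
    from itertools import permutations
    from scipy.stats import spearmanr

    for n in (4, 5):
        base = np.arange(n, dtype=float)
        oracle = np.sort(
            [abs(spearmanr(base, np.array(p)).statistic) for p in permutations(base)]
        )
        np.testing.assert_allclose(_null_abs_rho(n), oracle, atol=1e-12)


def test_exact_p_for_n6_rejection_rate_is_discrete():
    """Under the null the exact two-sided p is sub-uniform: its achievable
    values for n=6 are multiples of 2/720 with P(p <= x) <= x."""
    null = _null_abs_rho(6)
    ps = np.array([np.sum(null >= r - 1e-12) / 720 for r in null])
    for x in (0.01, 0.05, 0.1):
        assert np.mean(ps <= x) <= x + 1e-12


def test_spearman_invariant_under_monotone_transforms(rng):
    deltas = rng.normal(size=6)
    rho0, p0 = spearman_exact(LEVELS, deltas)
    rho1, p1 = spearman_exact(np.log(LEVELS), deltas)  # monotone in levels
    rho2, p2 = spearman_exact(LEVELS, np.exp(deltas))  # monotone in deltas
    assert rho0 == pytest.approx(rho1) and p0 == p1
    assert rho0 == pytest.approx(rho2) and p0 == p2


def test_spearman_handles_ties_with_average_ranks():
    deltas = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    rho, p = spearman_exact(LEVELS, deltas[np.argsort(np.argsort(LEVELS))])
    assert -1.0 <= rho <= 1.0
    assert 0.0 < p <= 1.0


def test_spearman_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="constant"):
        spearman_exact(LEVELS, np.full(6, 2.0))
    with pytest.raises(ValueError, match="three"):
        spearman_exact(np.array([1.0, 2.0]), np.array([0.1, 0.2]))


# ---------------------------------------------------------------------------
# stability filter
# ---------------------------------------------------------------------------

def test_filter_passes_consistent_significant_replicates():
    rhos = [0.9] * 10
    pvals = [0.01] * 10
    assert stability_filter(rhos, pvals) == pytest.approx(0.9)


def test_filter_rejects_sign_flip():
    rhos = [0.9] * 9 + [-0.1]
    pvals = [0.01] * 10
    assert np.isnan(stability_filter(rhos, pvals))


def test_filter_enforces_significance_fraction():
    rhos = [0.8] * 10
    pvals = [0.01] * 6 + [0.2] * 4  # 60% significant
    assert np.isnan(stability_filter(rhos, pvals, 0.70))
    pvals = [0.01] * 7 + [0.2] * 3  # 70% exactly
    assert stability_filter(rhos, pvals, 0.70) == pytest.approx(0.8)


def test_filter_monotone_in_threshold(rng):
    """Raising the required fraction can only turn values into NaN."""
    for _ in range(20):
        rhos = np.abs(rng.normal(0.5, 0.2, 8)) * rng.choice([1, 1, 1, -1])
        pvals = rng.uniform(0, 0.15, 8)
        prev = stability_filter(rhos, pvals, 0.3)
        for thr in (0.5, 0.7, 0.9, 1.0):
            cur = stability_filter(rhos, pvals, thr)
            if np.isnan(prev):
                assert np.isnan(cur)
            prev = cur


def test_filter_input_validation():
    with pytest.raises(ValueError):
        stability_filter([], [])
    with pytest.raises(ValueError):
        stability_filter([0.5], [0.01], frac_threshold=0.0)


# ---------------------------------------------------------------------------
# simulation-backed table
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_table(params, physiology):
    from abscopal.correlation import correlation_table
    from abscopal.sensitivity import default_baselines

    baselines = default_baselines(params, 2, seed=4)
    kwargs = dict(
        params_to_sweep=("clear_c_dead",),
        outputs=("tumor_volume", "apc"),
        multipliers=(3.0, 1.5, 1.0, 0.67, 0.33),
        physiology=physiology,
    )
    fwd = correlation_table(baselines, group_pairs=(("CONTROL", "T1_RT"),), **kwargs)
    rev = correlation_table(baselines, group_pairs=(("T1_RT", "CONTROL"),), **kwargs)
    return fwd, rev


def test_table_antisymmetry_under_pair_swap(small_table):
    """Swapping the group pair flips both the direction sign and rho."""
    fwd, rev = small_table
    for (_, f), (_, r) in zip(fwd.iterrows(), rev.iterrows()):
        assert f.delta_sign == -r.delta_sign
        if np.isfinite(f.stable_mean_rho) or np.isfinite(r.stable_mean_rho):
            assert f.stable_mean_rho == pytest.approx(-r.stable_mean_rho)


def test_tumor_volume_difference_direction(small_table):
    """Control-minus-treated tumor volume is positive: radiotherapy
    shrinks the irradiated tumor."""
    fwd, _ = small_table
    cell = fwd[(fwd.output == "tumor_volume") & (fwd.tumor == "TUMOR1")]
    assert cell.delta_sign.iloc[0] == 1.0


def test_no_effect_parameter_gives_nan_column(params, physiology):
    """Nodal radiosensitivity has no pathway outside the LN-irradiated
    arm, so a control-vs-T1RT comparison reports a flagged NaN."""
    from abscopal.correlation import correlation_table

    table = correlation_table(
        [params],
        group_pairs=(("CONTROL", "T1_RT"),),
        params_to_sweep=("a_im",),
        outputs=("tumor_volume",),
        multipliers=(2.0, 1.0, 0.5),
        physiology=physiology,
    )
    assert table.no_effect.all()
    assert table.stable_mean_rho.isna().all()
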