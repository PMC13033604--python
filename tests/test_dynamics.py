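"""Kernel closed forms, conservation structure, and RHS assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abscopal.dynamics import (
    LAYOUT,
    QspSystem,
    assemble_rhs,
    cytolysis_rate,
    debris_clearance,
    ln_priming_rates,
    phagocytosis_rates,
    tumor_volume,
)
from abscopal.physiology import (
    CompartmentId,
    SpeciesId,
    TRAFFICKING_SPECIES,
)

TUMORS = (CompartmentId.TUMOR1, CompartmentId.TUMOR2)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tv, td, v_cell, expected",
    [
        (0.0, 0.0, 5e-6, 0.0),
        (1e8, 0.0, 1e-6, 100.0),
        (5e7, 5e7, 1e-6, 100.0),  # invariant to viable/dead split
    ],
)
def test_tumor_volume_closed_form(tv, td, v_cell, expected):
    assert tumor_volume(tv, td, v_cell) == pytest.approx(expected)


def test_tumor_volume_rejects_negative():
    with pytest.raises(ValueError):
        tumor_volume(-1.0, 0.0, 1e-6)


def test_cytolysis_closed_form_and_monotonicity():
    assert cytolysis_rate(0.0, 1e6, 1e-6, 0.0, 0.0, 1e-7, 1e-7) == 0.0
    # suppression off: bilinear mass action exactly
    base = cytolysis_rate(2e5, 1e6, 1e-6, 5e5, 5e5, 0.0, 0.0)
    assert base == pytest.approx(1e-6 * 2e5 * 1e6)
    # doubling suppressors never increases the rate
    r1 = cytolysis_rate(2e5, 1e6, 1e-6, 5e5, 5e5, 1e-7, 1e-7)
    r2 = cytolysis_rate(2e5, 1e6, 1e-6, 1e6, 5e5, 1e-7, 1e-7)
    assert r2 <= r1 <= base


def test_phagocytosis_rates_structure(params):
    v = 0.015
    # no phagocytes -> all four fluxes vanish
    r = phagocytosis_rates(0.0, 0.0, 0.0, 1e7, 1e6, params, v)
    assert all(val == 0.0 for val in r.values())
    # M1 rates off -> no M1 maturation, debris removal via DC only
    p = params.with_updates(ac_m1=0.0, ac_dead_m1=0.0)
    r = phagocytosis_rates(1e4, 2e3, 5e3, 1e7, 1e6, p, v)
    assert r["m1_to_apc"] == 0.0
    assert r["td_removal"] == pytest.approx(
        p.ac_dead_dc * (1e4 + 2e3) / v * 1e6
    )
    # per-encounter bookkeeping: DC loss equals DC-driven tumor-cell removal
    r = phagocytosis_rates(1e4, 0.0, 0.0, 1e7, 0.0, params, v)
    assert r["dc_to_apc"] == pytest.approx(r["tv_removal"])


def test_phagocytosis_requires_positive_volume(params):
    with pytest.raises(ValueError):
        phagocytosis_rates(1.0, 1.0, 1.0, 1.0, 1.0, params, 0.0)


def test_ln_priming_fixed_point_and_conservation(params):
    # baseline pool with no antigen-presenting cells: nothing moves
    r = ln_priming_rates(params.tn0, 0.0, params)
    assert r["tn_regen"] == 0.0
    assert r["tn_activation"] == 0.0
    # logistic regeneration at half-pool
    r = ln_priming_rates(params.tn0 / 2, 0.0, params)
    assert r["tn_regen"] == pytest.approx(params.k_prol_tn * params.tn0 / 4)
    # unit expansion: effector output equals naive consumption
    p1 = params.with_updates(n_exp=1.0)
    r = ln_priming_rates(1e5, 3e4, p1, group="rt")
    assert r["te1_production"] == pytest.approx(r["tn_activation"])


def test_debris_clearance_first_order():
    assert debris_clearance(0.0, 0.7) == 0.0
    assert debris_clearance(1e6, 0.0) == 0.0
    assert debris_clearance(1e6, 0.3) == pytest.approx(3e5)


# ---------------------------------------------------------------------------
# assembled RHS
# ---------------------------------------------------------------------------

def test_rhs_zero_when_all_rates_zero(params, physiology):
    dead = {s.value: 0.0 for s in TRAFFICKING_SPECIES}
    from abscopal.parameters import FITTED_VECTOR_NAMES

    zeros = {n: 0.0 for n in FITTED_VECTOR_NAMES if n != "vi_tumor0_mm3"}
    p = params.with_updates(source_rates=dead, death_rates=dead, **zeros)
    system = QspSystem(params=p, physiology=physiology, enable_transport=False)
    x = np.abs(np.random.default_rng(0).normal(1e4, 1e3, LAYOUT.size))
    np.testing.assert_allclose(system.rhs(0.0, x), 0.0, atol=1e-30)


def test_transport_only_conserves_each_species(params, physiology, rng):
    system = QspSystem(
        params=params,
        physiology=physiology,
        enable_sources=False,
        enable_deaths=False,
        enable_interactions=False,
    )
    x = np.abs(rng.normal(1e5, 1e4, LAYOUT.size))
    dx = system.rhs(0.0, x)
    for sp in TRAFFICKING_SPECIES:
        slots = LAYOUT.species_slots(sp)
        assert abs(dx[slots].sum()) < 1e-9 * np.abs(dx[slots]).max()


def test_conversion_fluxes_are_pairwise_conservative(params, physiology, rng):
    """Cytolysis (TV->TD), maturation (DC/M1->APC) and priming (TN->TE1 at
    unit expansion) move cells between pools without net creation."""
    p = params.with_updates(n_exp=1.0)
    full = QspSystem(params=p, physiology=physiology, group="rt")
    bare = QspSystem(
        params=p, physiology=physiology, group="rt", enable_interactions=False
    )
    x = np.abs(rng.normal(1e5, 3e4, LAYOUT.size))
    inter = full.rhs(0.0, x) - bare.rhs(0.0, x)  # interaction terms only
    for comp in TUMORS:
        i_tv, i_td = LAYOUT.tv[comp], LAYOUT.td[comp]
        i_dc = LAYOUT.index(SpeciesId.DC, comp, "interstitial")
        i_m1 = LAYOUT.index(SpeciesId.M1, comp, "interstitial")
        i_apc = LAYOUT.index(SpeciesId.APC, comp, "interstitial")
        # tumor-cell bookkeeping: growth - removals - clearance
        v_int = 0.5 * max((x[i_tv] + x[i_td]) * p.v_cell_mm3, 1.0) * 1e-3
        ph = phagocytosis_rates(
            x[i_dc], x[i_apc], x[i_m1], x[i_tv], x[i_td], p, v_int
        )
        expected_tumor_net = (
            p.lg_tumor * x[i_tv]
            - ph["tv_removal"]
            - ph["td_removal"]
            - p.clear_c_dead * x[i_td]
        )
        assert inter[i_tv] + inter[i_td] == pytest.approx(
            expected_tumor_net, rel=1e-9
        )
        # maturation conserves phagocytes
        assert inter[i_dc] + inter[i_m1] + inter[i_apc] == pytest.approx(
            0.0, abs=1e-9 * max(abs(inter[i_apc]), 1.0)
        )
    # priming: TE1 gain equals TN loss beyond logistic regeneration
    tn = x[LAYOUT.tn]
    regen = p.k_prol_tn * tn * (1 - tn / p.tn0)
    i_te1_ln = LAYOUT.index(SpeciesId.TE1, CompartmentId.LYMPH_NODES, "interstitial")
    assert inter[LAYOUT.tn] - regen == pytest.approx(-inter[i_te1_ln], rel=1e-9)


def test_rhs_matches_kernel_functions(params, physiology, rng):
    """The integrator's inlined hot path equals the public kernel ops."""
    system = QspSystem(params=params, physiology=physiology, group="rt")
    x = np.abs(rng.normal(1e5, 3e4, LAYOUT.size))
    dx = system.rhs(0.0, x)
    comp = CompartmentId.TUMOR1
    i_tv, i_td = LAYOUT.tv[comp], LAYOUT.td[comp]
    v = tumor_volume(x[i_tv], x[i_td], params.v_cell_mm3)
    v_int = 0.5 * max(v, 1.0) * 1e-3
    te1 = x[LAYOUT.index(SpeciesId.TE1, comp, "interstitial")]
    treg = x[LAYOUT.index(SpeciesId.TREG, comp, "interstitial")]
    m2 = x[LAYOUT.index(SpeciesId.M2, comp, "interstitial")]
    cyt = cytolysis_rate(
        te1 / v_int, x[i_tv], params.k_rc1_rt, treg / v_int, m2 / v_int,
        params.s_treg, params.s_m2,
    )
    ph = phagocytosis_rates(
        x[LAYOUT.index(SpeciesId.DC, comp, "interstitial")],
        x[LAYOUT.index(SpeciesId.APC, comp, "interstitial")],
        x[LAYOUT.index(SpeciesId.M1, comp, "interstitial")],
        x[i_tv], x[i_td], params, v_int,
    )
    expected_dtv = params.lg_tumor * x[i_tv] - cyt - ph["tv_removal"]
    assert dx[i_tv] == pytest.approx(expected_dtv, rel=1e-12)
    expected_dtd = cyt - ph["td_removal"] - debris_clearance(x[i_td], params.clear_c_dead)
    assert dx[i_td] == pytest.approx(expected_dtd, rel=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_transport_rhs_is_homogeneous(scale):
    """Without bilinear interactions the RHS is linear: f(c*x) = c*f(x).

    Tumor pools are held empty so the tumor sub-volumes (which scale with
    tumor burden) stay at their floor and transport coefficients are fixed.
    """
    from abscopal.parameters import ParameterSet
    from abscopal.physiology import build_default_physiology

    params = ParameterSet.default()
    physiology = build_default_physiology()
    system = QspSystem(
        params=params,
        physiology=physiology,
        enable_sources=False,
        enable_interactions=False,
    )
    x = np.abs(np.random.default_rng(7).normal(1e5, 1e4, LAYOUT.size))
    for comp in TUMORS:
        x[LAYOUT.tv[comp]] = 0.0
        x[LAYOUT.td[comp]] = 0.0
    np.testing.assert_allclose(
        system.rhs(0.0, scale * x), scale * system.rhs(0.0, x), rtol=1e-9
    )


def test_assemble_rhs_validates_state(params, physiology):
    x = np.zeros(LAYOUT.size)
    x[3] = np.nan
    with pytest.raises(ValueError, match="index 3"):
        assemble_rhs(0.0, x, params, physiology)
    x = np.zeros(LAYOUT.size)
    x[10] = -5.0
    with pytest.raises(ValueError, match="index 10"):
        assemble_rhs(0.0, x, params, physiology)


def test_layout_pack_unpack_round_trip(rng):
    values = {key: float(v) for key, v in zip(
        LAYOUT.labels(), rng.uniform(0, 1e6, LAYOUT.size)
    )}
    x = LAYOUT.pack(values)
    assert LAYOUT.unpack(x) == values
    assert LAYOUT.size == 161
    # confinement: TN only in lymph nodes; TV/TD only in tumors
    labels = LAYOUT.labels()
    assert sum(1 for s, c, _ in labels if s == "TN") == 1
    assert {c for s, c, _ in labels if s in ("TV", "TD")} == {
        "TUMOR1", "TUMOR2"
    }


def test_jacobian_matches_finite_differences(params, physiology, rng):
    system = QspSystem(params=params, physiology=physiology, group="rt")
    x = np.abs(rng.normal(1e5, 3e4, LAYOUT.size))
    J = system.jac(0.0, x)
    f0 = system.rhs(0.0, x)
    cols = rng.choice(LAYOUT.size, size=12, replace=False)
    for j in cols:
        h = 1e-4 * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        fd = (system.rhs(0.0, xp) - f0) / h
        np.testing.assert_allclose(J[:, j], fd, rtol=5e-3, atol=1e-8 * np.abs(fd).max() + 1e-12)
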