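"""Kinetic oracle: steady states, conservation, and finite-perturbation responses."""

import numpy as np
import pytest

from fluxcomp import MassActionModel, MassActionParams, ValidationError
from fluxcomp.competition import response_matrix
from fluxcomp.massaction import (
    numerical_response,
    ode_rhs,
    scan_target,
    sigma_network_params,
    steady_state_analytic,
    steady_state_ode,
)


def random_params(rng, n=None):
    n = int(rng.integers(1, 5)) if n is None else n
    return MassActionParams(
        k_f=rng.uniform(0.05, 50, n),
        k_r=rng.uniform(0.05, 50, n),
        k_cat=rng.uniform(0.05, 50, n),
        T=float(rng.uniform(1, 2000)),
        C=rng.uniform(1, 2000, n),
    )


def test_rhs_zero_at_analytic_steady_state(rng):
    for _ in range(5):
        params = random_params(rng)
        state, _ = steady_state_analytic(params)
        deriv = ode_rhs(params, state.tc)
        scale = max(params.T, params.C.max())
        assert np.max(np.abs(deriv)) < 1e-9 * scale


def test_rhs_positive_from_empty_complexes():
    params = sigma_network_params()
    assert np.all(ode_rhs(params, np.zeros(3)) > 0)


def test_single_competitor_closed_form():
    """For n = 1 the free target solves a quadratic; the flux must match
    k_cat K t C / (1 + K t) with that root."""
    params = MassActionParams(k_f=[2.0], k_r=[1.0], k_cat=[3.0], T=10.0, C=[4.0])
    K = 2.0 / (1.0 + 3.0)
    a, b, c = K, 1 + K * 4.0 - K * 10.0, -10.0
    t_root = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    expected_flux = 3.0 * K * t_root * 4.0 / (1 + K * t_root)
    state, fluxes = steady_state_analytic(params)
    assert fluxes[0] == pytest.approx(expected_flux, rel=1e-12)
    assert state.free_target == pytest.approx(t_root, rel=1e-10)


def test_degenerate_and_limit_totals():
    params = sigma_network_params().with_target(0.0)
    state, fluxes = steady_state_analytic(params)
    assert np.all(state.tc == 0) and np.all(fluxes == 0)
    # huge target saturates every competitor
    big, _ = steady_state_analytic(sigma_network_params().with_target(1e9))
    assert big.saturations == pytest.approx(np.ones(3), abs=1e-3)


def test_ode_matches_analytic(rng):
    for params in [sigma_network_params()] + [random_params(rng) for _ in range(3)]:
        state_a, flux_a = steady_state_analytic(params)
        state_o, flux_o = steady_state_ode(params)
        assert state_o.tc == pytest.approx(state_a.tc, rel=1e-6, abs=1e-9 * params.T)
        assert flux_o == pytest.approx(flux_a, rel=1e-6, abs=1e-12)
        # conservation at the integrated state
        assert state_o.free_target + state_o.tc.sum() == pytest.approx(
            params.T, rel=1e-9
        )


def test_small_perturbation_matches_formulas(rng):
    for params in [sigma_network_params()] + [random_params(rng, n=3) for _ in range(3)]:
        state, _ = steady_state_analytic(params)
        rm = response_matrix(state)
        num_T = numerical_response(params, "T", delta=1e-4)
        assert num_T == pytest.approx(rm.table["T"].to_numpy(), rel=1e-3)
        for k, lab in enumerate(params.labels):
            num_C = numerical_response(params, k, delta=1e-4)
            assert num_C == pytest.approx(
                rm.table[lab].to_numpy(), rel=1e-3, abs=1e-6
            )


def test_central_difference_is_more_accurate():
    params = sigma_network_params()
    state, _ = steady_state_analytic(params)
    exact = response_matrix(state).table["T"].to_numpy()
    fwd = numerical_response(params, "T", delta=0.01)
    cen = numerical_response(params, "T", delta=0.01, central=True)
    assert np.max(np.abs(cen - exact)) < np.max(np.abs(fwd - exact))


def test_deviation_grows_with_perturbation_size():
    params = sigma_network_params()
    state, _ = steady_state_analytic(params)
    exact = response_matrix(state).table["T"].to_numpy()
    devs = [
        np.abs(numerical_response(params, "T", delta=d) - exact)
        for d in (0.01, 0.05, 0.10, 0.15)
    ]
    for lo, hi in zip(devs, devs[1:]):
        assert np.all(hi >= lo)


def test_symmetric_competitors_have_equal_cross_responses():
    params = MassActionParams(
        k_f=[5.0, 5.0], k_r=[2.0, 2.0], k_cat=[1.0, 1.0], T=50.0, C=[30.0, 30.0]
    )
    r01 = numerical_response(params, 0, delta=0.01)
    r10 = numerical_response(params, 1, delta=0.01)
    assert r01[1] == pytest.approx(r10[0], rel=1e-10)
    assert r01[0] == pytest.approx(r10[1], rel=1e-10)


def test_scan_target_limits():
    params = sigma_network_params()
    scan = scan_target(params, [1e-3, 700.0, 1e6], delta=0.01)
    # low-target limit: response approaches the free-competitor fraction
    low = scan.iloc[0]
    for lab in params.labels:
        assert low[f"RT_formula_{lab}"] == pytest.approx(
            1 - low[f"sat_{lab}"], abs=1e-3
        )
    # high-target limit: all responses vanish
    high = scan.iloc[-1]
    assert all(abs(high[f"RT_formula_{lab}"]) < 1e-2 for lab in params.labels)
    # at the calibration point the least saturated competitor is ultrasensitive
    mid = scan.iloc[1]
    sats = {lab: mid[f"sat_{lab}"] for lab in params.labels}
    least = min(sats, key=sats.get)
    most = max(sats, key=sats.get)
    assert mid[f"RT_formula_{least}"] > 1
    assert mid[f"RT_formula_{most}"] <= 1


def test_model_fit_and_summary():
    res = MassActionModel(sigma_network_params()).fit()
    assert res.state.T == 700.0
    rm = res.response_matrix()
    assert rm.table.shape == (3, 4)
    assert "steady state" in res.summary()


def test_invalid_params_rejected():
    with pytest.raises(ValidationError):
        MassActionParams(k_f=[0.0], k_r=[1.0], k_cat=[1.0], T=1.0, C=[1.0])
    with pytest.raises(ValidationError):
        MassActionParams(k_f=[1.0], k_r=[1.0], k_cat=[1.0], T=-1.0, C=[1.0])
    with pytest.raises(ValidationError):
        MassActionParams(k_f=[1.0, 2.0], k_r=[1.0], k_cat=[1.0], T=1.0, C=[1.0])
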