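"""Closed-form response coefficients on the sigma-factor competition state."""

import numpy as np
import pytest

from fluxcomp import (
    CompetitionModel,
    CompetitionState,
    DegenerateStateError,
    UndefinedRatioError,
    ValidationError,
    response_matrix,
    response_to_competitor_total,
    response_to_own_total,
    response_to_target,
    saturation,
    saturation_ratio,
    ultrasensitivity_threshold,
)
from fluxcomp.competition import competitor_strength_ratio, target_response_ratio

from conftest import round_sig

# measured bound/total amounts reproduce these twelve published coefficients
# at two significant figures
SIGMA_COEFFS = [
    ("s70", "T", 0.70),
    ("s70", "s70", 0.45),
    ("s70", "s54", -0.055),
    ("s70", "s28", -0.10),
    ("s54", "T", 1.6),
    ("s54", "s70", -1.2),
    ("s54", "s54", 0.88),
    ("s54", "s28", -0.23),
    ("s28", "T", 2.3),
    ("s28", "s70", -1.8),
    ("s28", "s54", -0.18),
    ("s28", "s28", 0.67),
]


@pytest.mark.parametrize("flux,param,expected", SIGMA_COEFFS)
def test_sigma_matrix_reproduces_published_values(sigma_state, flux, param, expected):
    matrix = response_matrix(sigma_state)
    assert round_sig(matrix[flux, param], 2) == pytest.approx(expected)


def test_saturation_values(sigma_state):
    assert saturation(sigma_state, "s70") == pytest.approx(545 / 700)
    zero = CompetitionState(T=10, C=[5.0], tc=[0.0])
    assert saturation(zero, 0) == 0.0
    full = CompetitionState(T=10, C=[5.0], tc=[5.0])
    assert saturation(full, 0) == 1.0
    with pytest.raises(ValidationError):
        saturation(CompetitionState(T=1, C=[0.0], tc=[0.0]), 0)


def test_all_free_competitors_give_first_order_response():
    state = CompetitionState(T=50, C=[10, 20], tc=[0, 0])
    assert response_to_target(state, 0) == pytest.approx(1.0)
    assert response_to_target(state, 1) == pytest.approx(1.0)


def test_single_unbound_competitor_matrix():
    state = CompetitionState(T=5, C=[3.0], tc=[0.0])
    m = response_matrix(state).table.to_numpy()
    assert m == pytest.approx(np.array([[1.0, 1.0]]))


def test_exhausted_target_gives_zero_self_response():
    # all target bound to the single competitor: flux cannot rise with C
    state = CompetitionState(T=5, C=[10.0], tc=[5.0])
    assert response_to_target(state, 0) == pytest.approx(1.0)
    assert response_to_own_total(state, 0) == pytest.approx(0.0, abs=1e-15)


def test_matrix_invariants_and_row_identity(sigma_state):
    res = CompetitionModel(sigma_state).fit()
    table = res.matrix.table
    assert (table["T"] >= 0).all()
    diag = np.diag(table[list(sigma_state.labels)].to_numpy())
    assert np.all((diag >= 0) & (diag <= 1))
    off = table[list(sigma_state.labels)].to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    assert np.all(off <= 0)
    assert np.all(np.abs(off) <= table["T"].to_numpy()[:, None] + 1e-15)
    assert res.row_identity_residual().abs().max() < 1e-12
    # no free RNAP in this state: each row sums to exactly 1
    assert table.sum(axis=1).to_numpy() == pytest.approx(1.0, abs=1e-12)


def test_zero_crosstalk_from_unbound_competitor():
    state = CompetitionState(T=10, C=[4, 6], tc=[2, 0])
    assert response_to_competitor_total(state, 0, 1) == 0.0


def test_self_response_misuse_raises(sigma_state):
    with pytest.raises(ValidationError):
        response_to_competitor_total(sigma_state, "s70", "s70")


def test_degenerate_fully_bound_state_raises():
    state = CompetitionState(T=5, C=[5.0], tc=[5.0])
    with pytest.raises(DegenerateStateError):
        response_to_target(state, 0)


def test_saturation_ratio(sigma_state):
    rho = saturation_ratio(sigma_state, "s28", "s70")
    assert rho == pytest.approx((545 / 700) / (100 / 370), rel=1e-12)
    assert round(rho, 2) == 2.88
    assert saturation_ratio(sigma_state, "s70", "s70") == 1.0
    state = CompetitionState(T=10, C=[4, 6], tc=[0, 3])
    with pytest.raises(UndefinedRatioError):
        saturation_ratio(state, 0, 1)


def test_ultrasensitivity_sigma_state(sigma_state):
    threshold, ultra = ultrasensitivity_threshold(sigma_state, "s28")
    assert ultra and sigma_state.free_target < threshold
    assert response_to_target(sigma_state, "s28") > 1
    # most saturated competitor can never be ultrasensitive
    _, ultra70 = ultrasensitivity_threshold(sigma_state, "s70")
    assert not ultra70 and response_to_target(sigma_state, "s70") <= 1


def test_equally_saturated_never_ultrasensitive():
    state = CompetitionState(T=100, C=[10, 20, 40], tc=[5, 10, 20])
    for i in range(3):
        threshold, ultra = ultrasensitivity_threshold(state, i)
        assert threshold == pytest.approx(0.0, abs=1e-12)
        assert not ultra


def test_unbound_competitor_threshold_is_infinite():
    state = CompetitionState(T=100, C=[10, 20], tc=[0, 10])
    threshold, ultra = ultrasensitivity_threshold(state, 0)
    assert np.isinf(threshold)
    assert ultra == (response_to_target(state, 0) > 1)


def test_target_response_ratio(sigma_state):
    ratio = target_response_ratio(sigma_state, "s54", "s70")
    assert ratio == pytest.approx((1 - 0.5) / (1 - 545 / 700), rel=1e-12)
    assert round_sig(ratio, 2) == 2.3
    assert ratio == pytest.approx(
        response_to_target(sigma_state, "s54") / response_to_target(sigma_state, "s70"),
        rel=1e-12,
    )
    full = CompetitionState(T=10, C=[4, 6], tc=[1, 6])
    with pytest.raises(UndefinedRatioError):
        target_response_ratio(full, 0, 1)


def test_competitor_strength_ratio(sigma_state):
    ratio = competitor_strength_ratio(sigma_state, "s28", "s54")
    assert ratio == pytest.approx(100 / 55, rel=1e-12)
    # equals the ratio of cross-responses on any third flux
    num = response_to_competitor_total(sigma_state, "s70", "s28")
    den = response_to_competitor_total(sigma_state, "s70", "s54")
    assert ratio == pytest.approx(num / den, rel=1e-12)
    with pytest.raises(UndefinedRatioError):
        competitor_strength_ratio(CompetitionState(T=10, C=[4, 6], tc=[2, 0]), 0, 1)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(T=10, C=[5], tc=[6]),          # complex exceeds total competitor
        dict(T=5, C=[10, 10], tc=[4, 4]),   # complexes exceed total target
        dict(T=-1, C=[5], tc=[1]),          # negative amount
        dict(T=10, C=[], tc=[]),            # no competitors
    ],
)
def test_invalid_states_rejected(kwargs):
    with pytest.raises(ValidationError):
        CompetitionState(**kwargs)


def test_summary_mentions_key_quantities(sigma_state):
    text = CompetitionModel(sigma_state).fit().summary()
    assert "free target" in text and "s28" in text and "ultra" in text
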