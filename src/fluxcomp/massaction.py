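"""Mass-action kinetic model of n competitors binding one target pool.

The validation counterpart of :mod:`fluxcomp.competition`: an explicit
kinetic model in which competitor ``i`` reversibly binds the free target
(rate constants ``k_f_i``, ``k_r_i``) and the complex converts substrate
to product with apparent constant ``k_cat_i`` (substrate subsumed),
releasing both partners.  Mass balance of the complexes gives

    d tc_i / dt = k_f_i * t * c_i - (k_r_i + k_cat_i) * tc_i

with the free pools substituted through the conservation relations
``t = T - sum_j tc_j`` and ``c_i = C_i - tc_i``.  The steady state is
available in closed form: with ``K_i = k_f_i / (k_r_i + k_cat_i)`` each
complex is ``tc_i = K_i t C_i / (1 + K_i t)`` and the free target solves
the strictly increasing scalar equation ``t + sum_i tc_i(t) = T``.
Steady-state fluxes are ``J_i = k_cat_i * tc_i``.

Response coefficients are measured here *numerically*, by re-solving the
steady state after a fractional perturbation of a total pool and taking
the log-difference of the flux — an oracle entirely independent of the
closed-form coefficients it is used to validate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .competition import CompetitionState, response_matrix
from .exceptions import ConvergenceError, UndefinedRatioError, ValidationError

__all__ = [
    "MassActionParams",
    "MassActionModel",
    "MassActionResults",
    "ode_rhs",
    "steady_state_analytic",
    "steady_state_ode",
    "numerical_response",
    "scan_target",
    "sigma_network_params",
]


@dataclass(frozen=True)
class MassActionParams:
    """Rate constants and conserved totals of the n-competitor network.

    Units are free as long as they are consistent: ``k_f`` in
    amount^-1 time^-1, ``k_r`` and ``k_cat`` in time^-1, totals in the
    amount unit.
    """

    k_f: np.ndarray
    k_r: np.ndarray
    k_cat: np.ndarray
    T: float
    C: np.ndarray
    labels: tuple = field(default=None)

    def __post_init__(self):
        for name in ("k_f", "k_r", "k_cat", "C"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            )
        object.__setattr__(self, "T", float(self.T))
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"c{i + 1}" for i in range(self.C.size))
            )
        else:
            object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        n = self.C.size
        if not (self.k_f.size == self.k_r.size == self.k_cat.size == n == len(self.labels)):
            raise ValidationError("per-competitor parameter arrays must share a length")
        if np.any(self.k_f <= 0) or np.any(self.k_r <= 0) or np.any(self.k_cat <= 0):
            raise ValidationError("rate constants must be positive")
        if self.T < 0 or np.any(self.C < 0):
            raise ValidationError("totals must be non-negative")

    @property
    def n(self) -> int:
        return self.C.size

    @property
    def K(self) -> np.ndarray:
        """Effective association constants K_i = k_f_i / (k_r_i + k_cat_i)."""
        return self.k_f / (self.k_r + self.k_cat)

    def with_target(self, T) -> "MassActionParams":
        return replace(self, T=float(T))

    def with_competitor(self, k, C_k) -> "MassActionParams":
        C = self.C.copy()
        C[k] = C_k
        return replace(self, C=C)


def sigma_network_params() -> MassActionParams:
    """Three-competitor parameter set calibrated to the sigma-factor example.

    Totals 700/370/110 molecules per cell with binding constants chosen so
    that the steady state at T = 700 falls in the regime of the measured
    sigma-factor competition state.
    """
    return MassActionParams(
        k_f=[24.0, 8.0, 11.0],
        k_r=[3.0, 6.0, 30.0],
        k_cat=[5.0, 5.0, 5.0],
        T=700.0,
        C=[700.0, 370.0, 110.0],
    )


def ode_rhs(params: MassActionParams, tc: np.ndarray) -> np.ndarray:
    """Time derivative of the complex amounts at state ``tc``."""
    tc = np.asarray(tc, dtype=float)
    t = params.T - tc.sum()
    c = params.C - tc
    return params.k_f * t * c - (params.k_r + params.k_cat) * tc


def _free_target_root(params: MassActionParams) -> float:
    """Free target at steady state: unique root of t + sum tc_i(t) - T on [0, T]."""
    K, C, T = params.K, params.C, params.T
    if T == 0:
        return 0.0

    def g(t):
        return t + float((K * t * C / (1.0 + K * t)).sum()) - T

    # g is strictly increasing with g(0) = -T <= 0 and g(T) >= 0
    return brentq(g, 0.0, T, xtol=1e-15 * max(T, 1.0), rtol=8.9e-16)


def _result_from_tc(params, tc):
    state = CompetitionState(T=params.T, C=params.C, tc=tc, labels=params.labels)
    fluxes = params.k_cat * tc
    return state, fluxes


def steady_state_analytic(params: MassActionParams):
    """Closed-form steady state.

    Returns
    -------
    (state, fluxes)
        The :class:`CompetitionState` at steady state and the per-flux
        vector J_i = k_cat_i tc_i.
    """
    t = _free_target_root(params)
    tc = params.K * t * params.C / (1.0 + params.K * t)
    # clip round-off so the state validates
    tc = np.minimum(tc, params.C)
    if tc.sum() > params.T:
        tc *= params.T / tc.sum()
    return _result_from_tc(params, tc)


def steady_state_ode(
    params: MassActionParams,
    rtol: float = 1e-10,
    atol: float | None = None,
    ss_tol: float = 1e-10,
    max_time: float = 1e7,
):
    """Steady state by stiff integration from empty complexes (tc = 0).

    Integrates in doubling time chunks until the derivative norm satisfies
    ``max_i |dtc_i| <= ss_tol * max(max(tc), 1e-30)``; the steady state of
    this model class is unique so the initial condition is immaterial.

    Raises
    ------
    ConvergenceError
        If the criterion is not met within ``max_time``; carries the last
        state reached.
    """
    if atol is None:
        atol = 1e-12 * max(params.T, 1.0)
    tc = np.zeros(params.n)
    if params.T == 0:
        return _result_from_tc(params, tc)
    # chunk length from the slowest unimolecular relaxation
    tau = 10.0 / float(np.min(params.k_r + params.k_cat))
    elapsed = 0.0
    while elapsed < max_time:
        sol = solve_ivp(
            lambda _, y: ode_rhs(params, y),
            (0.0, tau),
            tc,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(f"integrator failed: {sol.message}", last_state=tc)
        tc = sol.y[:, -1]
        elapsed += tau
        tau *= 2.0
        deriv = ode_rhs(params, tc)
        if np.max(np.abs(deriv)) <= ss_tol * max(float(np.max(tc)), 1e-30):
            tc = np.clip(tc, 0.0, params.C)
            return _result_from_tc(params, tc)
    raise ConvergenceError(
        f"no steady state within t = {max_time:g}", last_state=tc
    )


def _solve(params, solver):
    if solver == "analytic":
        return steady_state_analytic(params)
    if solver == "ode":
        return steady_state_ode(params)
    raise ValidationError(f"unknown solver {solver!r}")


def _perturbed(params, selector, factor):
    if selector == "T":
        return params.with_target(params.T * factor)
    k = params.labels.index(selector) if isinstance(selector, str) else int(selector)
    return params.with_competitor(k, params.C[k] * factor)


def numerical_response(
    params: MassActionParams,
    selector,
    delta: float = 0.01,
    solver: str = "analytic",
    central: bool = False,
) -> np.ndarray:
    """Finite-perturbation response coefficients of every flux.

    Perturbs the selected total pool (``"T"`` or a competitor index/label)
    by the fraction ``delta``, re-solves the steady state, and returns
    ``[ln J(p(1+delta)) - ln J(p)] / ln(1+delta)`` per flux.  With
    ``central=True`` the symmetric variant
    ``[ln J(p(1+delta)) - ln J(p/(1+delta))] / (2 ln(1+delta))`` is used,
    which converges one order faster in ``delta``.
    """
    if delta <= 0:
        raise ValidationError("perturbation fraction delta must be positive")
    _, J0 = _solve(params, solver)
    if np.any(J0 <= 0):
        raise UndefinedRatioError("zero reference flux; response undefined")
    _, J_up = _solve(_perturbed(params, selector, 1.0 + delta), solver)
    if central:
        _, J_dn = _solve(_perturbed(params, selector, 1.0 / (1.0 + delta)), solver)
        return (np.log(J_up) - np.log(J_dn)) / (2.0 * np.log1p(delta))
    return (np.log(J_up) - np.log(J0)) / np.log1p(delta)


def scan_target(
    params: MassActionParams,
    T_grid,
    delta: float = 0.01,
    solver: str = "analytic",
) -> pd.DataFrame:
    """Steady states and response coefficients across a grid of target totals.

    For each T in the grid the returned frame carries the free target, the
    per-competitor saturations, the closed-form responses to T and to
    competitor 1, and their finite-perturbation counterparts.
    """
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        p = params.with_target(T)
        state, fluxes = _solve(p, solver)
        rm = response_matrix(state)
        num_T = numerical_response(p, "T", delta=delta, solver=solver)
        num_C1 = numerical_response(p, params.labels[0], delta=delta, solver=solver)
        row = {"T": T, "free_target": state.free_target}
        for i, lab in enumerate(params.labels):
            row[f"sat_{lab}"] = state.saturations[i]
            row[f"RT_formula_{lab}"] = rm[lab, "T"]
            row[f"RT_numeric_{lab}"] = num_T[i]
            row[f"RC1_formula_{lab}"] = rm[lab, params.labels[0]]
            row[f"RC1_numeric_{lab}"] = num_C1[i]
        rows.append(row)
    return pd.DataFrame(rows)


class MassActionModel:
    """Kinetic competition model with analytic and integrated steady states."""

    def __init__(self, params: MassActionParams):
        self.params = params

    def fit(self, method: str = "analytic") -> "MassActionResults":
        state, fluxes = _solve(self.params, method)
        return MassActionResults(self, state, fluxes, method)

    def numerical_response(self, selector, delta=0.01, **kw) -> np.ndarray:
        return numerical_response(self.params, selector, delta=delta, **kw)

    def scan_target(self, T_grid, **kw) -> pd.DataFrame:
        return scan_target(self.params, T_grid, **kw)


class MassActionResults:
    """Steady state of the kinetic model plus derived response analysis."""

    def __init__(self, model, state, fluxes, method):
        self.model = model
        self.state = state
        self.fluxes = fluxes
        self.method = method

    @property
    def params(self) -> MassActionParams:
        return self.model.params

    def response_matrix(self):
        """Closed-form response matrix evaluated on the simulated state."""
        return response_matrix(self.state)

    def summary(self) -> str:
        st = self.state
        lines = [
            f"Mass-action steady state ({self.method})",
            "=" * 60,
            f"T = {st.T:g}    free target t = {st.free_target:.6g}",
            "-" * 60,
            f"{'competitor':<12}{'C':>10}{'tc':>12}{'saturation':>12}{'flux J':>12}",
        ]
        for i, lab in enumerate(st.labels):
            lines.append(
                f"{lab:<12}{st.C[i]:>10.4g}{st.tc[i]:>12.6g}"
                f"{st.saturations[i]:>12.4f}{self.fluxes[i]:>12.6g}"
            )
        lines.append("-" * 60)
        return "\n".join(lines)
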