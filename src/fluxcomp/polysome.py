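"""Ribosome-traffic simulator: codon-resolved translation with steric exclusion.

Mean-field ODE model of several mRNA species drawing ribosomes from one
shared pool.  For each species, state variable ``p_j`` is the fraction of
molecules of that species carrying a ribosome front at codon ``j``
(j = 1..n); a ribosome occludes ``L`` codons.  The elementary steps are

* initiation — bimolecular in the free ribosomes and the fraction of
  molecules whose first ``L`` codons are empty:
  ``k_init * r_free * (1 - sum_{j<=L} p_j)``;
* elongation ``j -> j+1`` — first order in ``p_j``, weighted by the
  conditional probability that the codon ahead is not blocked:
  ``k_elong * p_j * (1 - sum_{m=j+1}^{j+L} p_m) / (1 - sum_{m=j+1}^{j+L-1} p_m)``
  with both window sums truncated at the last codon (codons past the stop
  are treated as free);
* termination — first order in the last-codon occupation, ``k_term * p_n``.

Ribosome conservation is built in: the free pool is
``r_free = T - sum_species C * sum_j p_j``.  Per-species protein synthesis
flux is ``J = C * k_term * p_n``.  Steric feasibility requires every
window of ``L`` consecutive codons to carry total occupation <= 1.

This model makes none of the simplifying assumptions behind the
closed-form translation response coefficients (all-or-nothing binding, no
steric interference), which is what makes it an independent oracle for
them: finite perturbations of the pool or of an mRNA abundance yield
numerical response coefficients to compare with the formulas evaluated on
the simulated mean loads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .exceptions import ConvergenceError, UndefinedRatioError, ValidationError
from .translation import TranslationState

__all__ = [
    "PolysomeSpecies",
    "PolysomeParams",
    "PolysomeState",
    "PolysomeModel",
    "PolysomeResults",
    "initiation_rate",
    "elongation_rate",
    "termination_rate",
    "simulate_to_steady_state",
    "numerical_response",
    "two_mrna_example",
]


@dataclass(frozen=True)
class PolysomeSpecies:
    """One mRNA species: ORF length, rate constants and abundance."""

    label: str
    n_codons: int
    k_init: float   # amount^-1 time^-1
    k_elong: float  # time^-1, per-codon stepping constant
    k_term: float   # time^-1
    C: float        # mRNA abundance


@dataclass(frozen=True)
class PolysomeParams:
    """Shared ribosome pool plus the list of competing species."""

    species: tuple
    T: float
    L: int = 12

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "T", float(self.T))
        if self.L < 1:
            raise ValidationError("footprint L must be >= 1")
        if self.T < 0:
            raise ValidationError("ribosome pool T must be >= 0")
        if not self.species:
            raise ValidationError("need at least one mRNA species")
        for sp in self.species:
            if sp.n_codons < self.L:
                raise ValidationError(
                    f"species {sp.label!r}: ORF of {sp.n_codons} codons is "
                    f"shorter than the footprint L = {self.L}"
                )
            if min(sp.k_init, sp.k_elong, sp.k_term) <= 0:
                raise ValidationError(f"species {sp.label!r}: rate constants must be > 0")
            if sp.C < 0:
                raise ValidationError(f"species {sp.label!r}: abundance must be >= 0")

    @property
    def labels(self) -> tuple:
        return tuple(sp.label for sp in self.species)

    def with_target(self, T) -> "PolysomeParams":
        return replace(self, T=float(T))

    def with_abundance(self, k, C_k) -> "PolysomeParams":
        sp = list(self.species)
        sp[k] = replace(sp[k], C=float(C_k))
        return replace(self, species=tuple(sp))

    def index(self, key) -> int:
        if isinstance(key, (int, np.integer)):
            return int(key)
        return self.labels.index(str(key))


def two_mrna_example(T: float = 2.0) -> PolysomeParams:
    """Two competing mRNAs with strongly asymmetric initiation strengths.

    240-codon ORFs, footprint 12 codons; abundances 0.2 and 2 uM;
    initiation constants 0.2 and 5 (uM min)^-1; elongation and termination
    50 min^-1 for species 1 and 20 min^-1 for species 2.
    """
    return PolysomeParams(
        species=(
            PolysomeSpecies("mRNA1", 240, k_init=0.2, k_elong=50.0, k_term=50.0, C=0.2),
            PolysomeSpecies("mRNA2", 240, k_init=5.0, k_elong=20.0, k_term=20.0, C=2.0),
        ),
        T=T,
        L=12,
    )


class PolysomeState:
    """Per-species codon occupancy profiles tied to a parameter set."""

    def __init__(self, params: PolysomeParams, profiles):
        self.params = params
        self.profiles = tuple(np.asarray(p, dtype=float) for p in profiles)
        if len(self.profiles) != len(params.species):
            raise ValidationError("one profile per species required")
        for sp, p in zip(params.species, self.profiles):
            if p.size != sp.n_codons:
                raise ValidationError(
                    f"profile of {sp.label!r} has {p.size} entries, "
                    f"expected {sp.n_codons}"
                )

    @property
    def bound_per_mrna(self) -> np.ndarray:
        """P per species: mean ribosomes bound per mRNA molecule."""
        return np.array([p.sum() for p in self.profiles])

    @property
    def free_ribosomes(self) -> float:
        C = np.array([sp.C for sp in self.params.species])
        return self.params.T - float(C @ self.bound_per_mrna)

    @property
    def fluxes(self) -> np.ndarray:
        """Protein synthesis flux J = C * k_term * p_n per species."""
        return np.array(
            [sp.C * sp.k_term * p[-1] for sp, p in zip(self.params.species, self.profiles)]
        )

    def max_window_sum(self) -> float:
        """Largest occupation over any L consecutive codons, across species."""
        L = self.params.L
        worst = 0.0
        for p in self.profiles:
            if p.size >= L:
                kernel = np.convolve(p, np.ones(L), mode="valid")
                worst = max(worst, float(kernel.max(initial=0.0)))
            else:
                worst = max(worst, float(p.sum()))
        return worst

    def check_feasible(self, tol: float = 1e-9):
        if any(np.any(p < -tol) or np.any(p > 1 + tol) for p in self.profiles):
            raise ValidationError("codon occupations must lie in [0, 1]")
        if self.max_window_sum() > 1 + tol:
            raise ValidationError(
                f"steric exclusion violated: window occupation "
                f"{self.max_window_sum():.6g} > 1"
            )
        if self.free_ribosomes < -tol * max(self.params.T, 1.0):
            raise ValidationError("negative free ribosome pool")


# ---------------------------------------------------------------------------
# elementary rates (codon indices are 1-based, as in the model description)


def initiation_rate(state: PolysomeState, species) -> float:
    """Per-mRNA initiation rate k_init * r_free * (free start-site fraction)."""
    s = state.params.index(species)
    sp = state.params.species[s]
    p = state.profiles[s]
    blocked = float(p[: state.params.L].sum())
    return sp.k_init * state.free_ribosomes * max(0.0, 1.0 - blocked)


def elongation_rate(state: PolysomeState, species, j: int) -> float:
    """Stepping rate from codon j to j+1 (1 <= j < n_codons)."""
    s = state.params.index(species)
    sp = state.params.species[s]
    p = state.profiles[s]
    n, L = sp.n_codons, state.params.L
    if not 1 <= j < n:
        raise ValidationError(f"codon index {j} outside 1..{n - 1}")
    j0 = j - 1
    num = 1.0 - float(p[j0 + 1 : min(j0 + L, n - 1) + 1].sum())
    den = 1.0 - float(p[j0 + 1 : min(j0 + L - 1, n - 1) + 1].sum())
    if den <= 0:
        raise ValidationError(
            f"exclusion violated downstream of codon {j} of {sp.label!r}"
        )
    return sp.k_elong * p[j0] * num / den


def termination_rate(state: PolysomeState, species) -> float:
    """Per-mRNA termination rate k_term * p_n."""
    s = state.params.index(species)
    sp = state.params.species[s]
    return sp.k_term * float(state.profiles[s][-1])


# ---------------------------------------------------------------------------
# right-hand side and steady-state solver


def _make_rhs(params: PolysomeParams):
    """Vectorised RHS over the concatenated occupancy vector."""
    L = params.L
    sizes = [sp.n_codons for sp in params.species]
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    C = np.array([sp.C for sp in params.species])
    k_init = np.array([sp.k_init for sp in params.species])
    k_elong = np.array([sp.k_elong for sp in params.species])
    k_term = np.array([sp.k_term for sp in params.species])
    # window index bounds per species, precomputed (0-based, inclusive ends)
    windows = []
    for n in sizes:
        j0 = np.arange(n - 1)
        num_end = np.minimum(j0 + L, n - 1)
        den_end = np.minimum(j0 + L - 1, n - 1)
        windows.append((j0, num_end, den_end))

    def rhs(_, y):
        dy = np.empty_like(y)
        bound = np.array([y[offsets[s] : offsets[s + 1]].sum() for s in range(len(sizes))])
        r_free = params.T - float(C @ bound)
        for s, n in enumerate(sizes):
            p = y[offsets[s] : offsets[s + 1]]
            cs = np.concatenate(([0.0], np.cumsum(p)))
            j0, num_end, den_end = windows[s]
            if n > 1:
                s_num = cs[num_end + 1] - cs[j0 + 1]
                s_den = cs[den_end + 1] - cs[j0 + 1]
                # clip to keep the mean-field weight defined under transient
                # overshoot of the exclusion boundary
                v = k_elong[s] * p[:-1] * np.clip(1.0 - s_num, 0.0, None) / np.maximum(
                    1.0 - s_den, 1e-12
                )
            else:
                v = np.empty(0)
            a = k_init[s] * r_free * max(0.0, 1.0 - cs[min(L, n)])
            d = dy[offsets[s] : offsets[s + 1]]
            d[0] = a - (v[0] if n > 1 else k_term[s] * p[0])
            if n > 1:
                d[1:-1] = v[:-1] - v[1:]
                d[-1] = v[-1] - k_term[s] * p[-1]
        return dy

    return rhs, offsets


def _unpack(params, offsets, y):
    return PolysomeState(
        params,
        [y[offsets[s] : offsets[s + 1]] for s in range(len(params.species))],
    )


def _try_newton(params, rhs, offsets, y0, ss_tol):
    """Fixed-point solve; returns a feasible state or None."""
    res = root(lambda v: rhs(0.0, v), y0, method="hybr", tol=1e-13)
    if np.max(np.abs(rhs(0.0, res.x))) > ss_tol:
        return None
    y = res.x
    if np.any(y < -1e-9) or np.any(y > 1 + 1e-9):
        return None
    state = _unpack(params, offsets, np.clip(y, 0.0, 1.0))
    try:
        state.check_feasible()
    except ValidationError:
        return None
    return state


def simulate_to_steady_state(
    params: PolysomeParams,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    ss_tol: float = 1e-9,
    max_time: float = 1e6,
    y0: np.ndarray | None = None,
    polish: bool = True,
) -> PolysomeState:
    """Relax the traffic model to its (unique) steady state.

    A Newton-type fixed-point solve from ``y0`` (empty mRNAs by default,
    or a warm start from a nearby solution) is attempted first; if it does
    not land on a feasible occupancy pattern, the ODEs are integrated with
    a stiff-capable solver in doubling time chunks until
    ``max|dp/dt| <= ss_tol`` (occupancies are order-1 quantities) and the
    fixed point is then polished.

    Raises
    ------
    ConvergenceError
        When ``max_time`` is exhausted; carries the last state.
    """
    rhs, offsets = _make_rhs(params)
    n_tot = offsets[-1]
    y = np.zeros(n_tot) if y0 is None else np.asarray(y0, dtype=float).copy()
    state = _try_newton(params, rhs, offsets, y, ss_tol)
    if state is not None:
        return state
    k_slow = min(min(sp.k_elong, sp.k_term) for sp in params.species)
    tau = 5.0 * max(sp.n_codons for sp in params.species) / k_slow
    elapsed = 0.0
    converged = False
    while elapsed < max_time:
        sol = solve_ivp(rhs, (0.0, tau), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise ConvergenceError(
                f"integrator failed: {sol.message}",
                last_state=_unpack(params, offsets, y),
            )
        y = sol.y[:, -1]
        elapsed += tau
        tau *= 2.0
        if np.max(np.abs(rhs(0.0, y))) <= ss_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no steady state within t = {max_time:g}",
            last_state=_unpack(params, offsets, y),
        )
    if polish:
        res = root(lambda v: rhs(0.0, v), y, method="hybr", tol=1e-13)
        if res.success and np.max(np.abs(rhs(0.0, res.x))) < np.max(np.abs(rhs(0.0, y))):
            y = res.x
    y = np.clip(y, 0.0, 1.0)
    state = _unpack(params, offsets, y)
    state.check_feasible()
    return state


def numerical_response(
    params: PolysomeParams,
    selector,
    delta: float = 0.01,
    base_state: PolysomeState | None = None,
    **solver_kw,
) -> np.ndarray:
    """Finite-perturbation response of every species flux.

    ``selector`` is ``"T"`` for the ribosome pool or a species label/index
    for an mRNA abundance.  Returns ``dln J / dln p`` per species using a
    forward log-difference at fraction ``delta``; the perturbed solve is
    warm-started from the reference steady state.
    """
    if delta <= 0:
        raise ValidationError("delta must be positive")
    if base_state is None:
        base_state = simulate_to_steady_state(params, **solver_kw)
    J0 = base_state.fluxes
    if np.any(J0 <= 0):
        raise UndefinedRatioError("zero reference flux; response undefined")
    if selector == "T":
        pert = params.with_target(params.T * (1.0 + delta))
    else:
        k = params.index(selector)
        pert = params.with_abundance(k, params.species[k].C * (1.0 + delta))
    y0 = np.concatenate(base_state.profiles)
    pert_state = simulate_to_steady_state(pert, y0=y0, **solver_kw)
    return (np.log(pert_state.fluxes) - np.log(J0)) / np.log1p(delta)


# ---------------------------------------------------------------------------
# model layer


class PolysomeModel:
    """Traffic model entry point; ``fit()`` relaxes to the steady state."""

    def __init__(self, params: PolysomeParams):
        self.params = params

    def fit(self, **solver_kw) -> "PolysomeResults":
        state = simulate_to_steady_state(self.params, **solver_kw)
        return PolysomeResults(self, state)


class PolysomeResults:
    """Steady-state profiles with fluxes, loads and response utilities."""

    def __init__(self, model, state: PolysomeState):
        self.model = model
        self.state = state

    @property
    def params(self) -> PolysomeParams:
        return self.model.params

    @property
    def fluxes(self) -> np.ndarray:
        return self.state.fluxes

    @property
    def bound_per_mrna(self) -> np.ndarray:
        return self.state.bound_per_mrna

    @property
    def free_ribosomes(self) -> float:
        return self.state.free_ribosomes

    def flux_balance_residual(self) -> np.ndarray:
        """Relative initiation-vs-termination imbalance per species."""
        out = np.empty(len(self.params.species))
        for s, sp in enumerate(self.params.species):
            a = initiation_rate(self.state, s)
            t = termination_rate(self.state, s)
            out[s] = abs(a - t) / max(abs(t), 1e-300)
        return out

    def to_translation_state(self) -> TranslationState:
        """Sufficient statistics (C, N, simulated P) for the closed formulas."""
        sp = self.params.species
        return TranslationState(
            T=self.params.T,
            C=[x.C for x in sp],
            N=[x.n_codons for x in sp],
            P=self.bound_per_mrna,
            L=self.params.L,
            ids=self.params.labels,
        )

    def numerical_response(self, selector, delta=0.01, **kw) -> np.ndarray:
        return numerical_response(
            self.params, selector, delta=delta, base_state=self.state, **kw
        )

    def summary(self) -> str:
        P = self.bound_per_mrna
        lines = [
            "Polysome traffic steady state",
            "=" * 64,
            f"T = {self.params.T:g}    free ribosomes = {self.free_ribosomes:.6g}"
            f"    L = {self.params.L}",
            "-" * 64,
            f"{'species':<10}{'C':>8}{'P':>12}{'saturation':>12}{'flux J':>14}",
        ]
        for s, sp in enumerate(self.params.species):
            sat = P[s] * self.params.L / sp.n_codons
            lines.append(
                f"{sp.label:<10}{sp.C:>8.3g}{P[s]:>12.5g}{sat:>12.4f}"
                f"{self.fluxes[s]:>14.6g}"
            )
        lines.append("-" * 64)
        return "\n".join(lines)
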