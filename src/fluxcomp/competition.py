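"""Closed-form flux response coefficients for competition for a shared target.

Many gene-expression processes are organised as parallel pathways whose
first step is reversible binding of a *competitor* (a sigma factor, an
mRNA) to a shared, limiting *target* (RNA polymerase core enzyme, the
ribosome pool).  At steady state the flux carried through competitor *i*
responds to changes in the total target pool ``T`` and in every total
competitor pool ``C_k``, and the response coefficients — fractional flux
change per fractional parameter change — are fully determined by the
conserved totals and the bound-complex amounts ``tc_i``:

    s_i = tc_i / C_i                      (competitor saturation)
    f_i = tc_i / T                        (fraction of target bound to i)

    R_i^T    = (1 - s_i) / (1 - sum_j f_j s_j)
    R_i^Ci   = 1 - R_i^T * f_i
    R_i^Ck   = -R_i^T * f_k              (k != i)

No kinetic parameters enter: the complexes are the sufficient statistics.
A coefficient above 1 means ultrasensitivity; the criterion

    sum_j tc_j s_j > s_i T

is algebraically equivalent to ``R_i^T > 1`` and is evaluated without
dividing by ``s_i`` so that unbound competitors need no special casing.

The module exposes the formulas as plain functions over a
:class:`CompetitionState` and wraps them in a statsmodels-style
:class:`CompetitionModel` whose :meth:`~CompetitionModel.fit` returns a
:class:`CompetitionResults` with the full response matrix and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateStateError, UndefinedRatioError, ValidationError

__all__ = [
    "CompetitionState",
    "ResponseMatrix",
    "CompetitionModel",
    "CompetitionResults",
    "saturation",
    "response_to_target",
    "response_to_own_total",
    "response_to_competitor_total",
    "response_matrix",
    "saturation_ratio",
    "ultrasensitivity_threshold",
    "target_response_ratio",
    "competitor_strength_ratio",
    "response_kernel",
]

#: relative slack used when validating user-supplied amounts, to absorb
#: rounding in input tables
REL_SLACK = 1e-9


def response_kernel(s: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, float]:
    """Vector of target-response coefficients from saturations and bound fractions.

    Parameters
    ----------
    s : array
        Competitor saturations ``s_i`` in [0, 1].
    f : array
        Fractions of total target bound to each competitor; ``sum(f) <= 1``.

    Returns
    -------
    (R_T, denom)
        The per-competitor response to the total target and the shared
        denominator ``1 - sum_j f_j s_j``.

    Raises
    ------
    DegenerateStateError
        If the denominator is not positive (all target bound to fully
        saturated competitors).
    """
    s = np.asarray(s, dtype=float)
    f = np.asarray(f, dtype=float)
    denom = 1.0 - float(np.dot(f, s))
    if denom <= 0.0:
        full = np.flatnonzero((s >= 1.0 - REL_SLACK) & (f > 0))
        raise DegenerateStateError(
            "response denominator 1 - sum_j f_j*s_j = "
            f"{denom:.3g} <= 0: all target is bound to fully saturated "
            f"competitors (indices {full.tolist()})"
        )
    return (1.0 - s) / denom, denom


@dataclass(frozen=True)
class CompetitionState:
    """Sufficient statistics of an n-competitor / single-target network.

    Parameters
    ----------
    T : float
        Total target amount (free + all complexes).  Any consistent unit;
        ``T``, ``C`` and ``tc`` must share it.
    C : array
        Total amount of each competitor, length n.
    tc : array
        Target-bound complex amount for each competitor, length n.
    labels : sequence of str, optional
        Competitor identifiers; defaults to ``c1 .. cn``.
    """

    T: float
    C: np.ndarray
    tc: np.ndarray
    labels: tuple = field(default=None)

    def __post_init__(self):
        C = np.atleast_1d(np.asarray(self.C, dtype=float))
        tc = np.atleast_1d(np.asarray(self.tc, dtype=float))
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "tc", tc)
        object.__setattr__(self, "T", float(self.T))
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"c{i + 1}" for i in range(C.size))
            )
        else:
            object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        self._validate()

    def _validate(self):
        n = self.C.size
        if n < 1:
            raise ValidationError("need at least one competitor")
        if self.tc.size != n or len(self.labels) != n:
            raise ValidationError(
                f"length mismatch: C has {n}, tc has {self.tc.size}, "
                f"labels has {len(self.labels)} entries"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("competitor labels must be unique")
        if self.T < 0 or np.any(self.C < 0) or np.any(self.tc < 0):
            raise ValidationError("amounts must be non-negative")
        slack = REL_SLACK * np.maximum(self.C, 1.0)
        bad = np.flatnonzero(self.tc > self.C + slack)
        if bad.size:
            raise ValidationError(
                f"bound complex exceeds competitor total for {bad.tolist()}"
            )
        if self.tc.sum() > self.T * (1 + REL_SLACK) + REL_SLACK:
            raise ValidationError(
                f"sum of complexes {self.tc.sum():g} exceeds total target {self.T:g}"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def n(self) -> int:
        return self.C.size

    @property
    def free_target(self) -> float:
        """Free target t = T - sum(tc), clipped at 0 against table rounding."""
        return max(self.T - float(self.tc.sum()), 0.0)

    @property
    def free_competitor(self) -> np.ndarray:
        """Free competitor amounts c_i = C_i - tc_i."""
        return np.maximum(self.C - self.tc, 0.0)

    @property
    def saturations(self) -> np.ndarray:
        """s_i = tc_i / C_i; 0 where C_i = 0 (then tc_i = 0 too)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(self.C > 0, self.tc / np.where(self.C > 0, self.C, 1.0), 0.0)
        return np.clip(s, 0.0, 1.0)

    @property
    def bound_fractions(self) -> np.ndarray:
        """f_i = tc_i / T."""
        if self.T <= 0:
            return np.zeros(self.n)
        return self.tc / self.T

    def index(self, i) -> int:
        """Resolve a competitor given as integer position or label."""
        if isinstance(i, (int, np.integer)):
            if not 0 <= i < self.n:
                raise ValidationError(f"competitor index {i} out of range 0..{self.n - 1}")
            return int(i)
        try:
            return self.labels.index(str(i))
        except ValueError:
            raise ValidationError(f"unknown competitor label {i!r}") from None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, T: float) -> "CompetitionState":
        """Build a state from a DataFrame with columns ``label``, ``C``, ``tc``."""
        missing = {"label", "C", "tc"} - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        return cls(
            T=T,
            C=df["C"].to_numpy(float),
            tc=df["tc"].to_numpy(float),
            labels=tuple(df["label"].astype(str)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "C": self.C, "tc": self.tc})


# ---------------------------------------------------------------------------
# formula layer


def saturation(state: CompetitionState, i) -> float:
    """Fraction of competitor *i* occupied by target, tc_i / C_i."""
    i = state.index(i)
    if state.C[i] <= 0:
        raise ValidationError(
            f"saturation undefined for competitor {state.labels[i]!r} with C = 0"
        )
    return float(state.tc[i] / state.C[i])


def _require_positive_target(state: CompetitionState):
    if state.T <= 0:
        raise ValidationError("total target T must be positive")


def response_to_target(state: CompetitionState, i) -> float:
    """Response of flux i to the total target pool, R_i^T = (1-s_i)/(1-sum f_j s_j)."""
    _require_positive_target(state)
    i = state.index(i)
    R_T, _ = response_kernel(state.saturations, state.bound_fractions)
    return float(R_T[i])


def response_to_own_total(state: CompetitionState, i) -> float:
    """Self-response R_i^{C_i} = 1 - R_i^T * tc_i/T, always in [0, 1]."""
    i = state.index(i)
    return 1.0 - response_to_target(state, i) * float(state.bound_fractions[i])


def response_to_competitor_total(state: CompetitionState, i, k) -> float:
    """Cross-response R_i^{C_k} = -R_i^T * tc_k/T for k != i (non-positive)."""
    i, k = state.index(i), state.index(k)
    if i == k:
        raise ValidationError(
            "i == k: the self-response is given by response_to_own_total"
        )
    return -response_to_target(state, i) * float(state.bound_fractions[k])


def saturation_ratio(state: CompetitionState, i, j) -> float:
    """Relative saturation rho_ij = s_j / s_i of competitor j w.r.t. i."""
    i, j = state.index(i), state.index(j)
    s = state.saturations
    if s[i] <= 0:
        raise UndefinedRatioError(
            f"saturation ratio undefined: competitor {state.labels[i]!r} binds no target"
        )
    return float(s[j] / s[i])


def ultrasensitivity_threshold(state: CompetitionState, i) -> tuple[float, bool]:
    """Free-target threshold below which flux i responds ultrasensitively.

    The threshold is ``sum_{j != i} tc_j (rho_ij - 1)``; the flux is
    ultrasensitive (R_i^T > 1) iff the free target lies below it.  The
    boolean is computed from the equivalent division-free inequality
    ``sum_j tc_j s_j > s_i T``, so competitors with ``s_i = 0`` are handled
    (their threshold is +inf whenever any other competitor binds target).
    """
    _require_positive_target(state)
    i = state.index(i)
    s = state.saturations
    others = np.arange(state.n) != i
    if s[i] > 0:
        rho = s[others] / s[i]
        threshold = float(np.dot(state.tc[others], rho - 1.0))
    else:
        threshold = math.inf if np.dot(state.tc, s) > 0 else 0.0
    is_ultra = bool(np.dot(state.tc, s) > s[i] * state.T)
    return threshold, is_ultra


def target_response_ratio(state: CompetitionState, i, j) -> float:
    """R_i^T / R_j^T = (1 - s_i) / (1 - s_j): ratio of free competitor fractions."""
    i, j = state.index(i), state.index(j)
    s = state.saturations
    if s[j] >= 1.0:
        raise UndefinedRatioError(
            f"competitor {state.labels[j]!r} is fully saturated; ratio diverges"
        )
    return float((1.0 - s[i]) / (1.0 - s[j]))


def competitor_strength_ratio(state: CompetitionState, k, l) -> float:
    """tc_k / tc_l: relative strength of competitors k and l on any third flux."""
    k, l = state.index(k), state.index(l)
    if state.tc[l] <= 0:
        raise UndefinedRatioError(
            f"competitor {state.labels[l]!r} binds no target; strength ratio undefined"
        )
    return float(state.tc[k] / state.tc[l])


# ---------------------------------------------------------------------------
# matrix / model layer


class ResponseMatrix:
    """n x (n+1) table of flux response coefficients.

    Row *i* holds the responses of flux J_i to the total target (column
    ``T``) and to every total competitor amount (columns named by the
    competitor labels).  Carries the free target and the per-competitor
    saturations as metadata.
    """

    def __init__(self, table: pd.DataFrame, free_target: float, saturations: pd.Series):
        self.table = table
        self.free_target = float(free_target)
        self.saturations = saturations

    @property
    def labels(self) -> tuple:
        return tuple(self.table.index)

    def __getitem__(self, key):
        flux, param = key
        return float(self.table.loc[flux, param])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def __repr__(self):
        return f"ResponseMatrix(n={len(self.table)}, free_target={self.free_target:g})"


def response_matrix(state: CompetitionState) -> ResponseMatrix:
    """Assemble the full response matrix for every flux and parameter."""
    _require_positive_target(state)
    s = state.saturations
    f = state.bound_fractions
    R_T, _ = response_kernel(s, f)
    # R_i^{C_k} = -R_i^T f_k off-diagonal, 1 - R_i^T f_i on the diagonal
    mat = -np.outer(R_T, f)
    np.fill_diagonal(mat, 1.0 + np.diagonal(mat))
    table = pd.DataFrame(
        np.column_stack([R_T, mat]),
        index=pd.Index(state.labels, name="flux"),
        columns=["T", *state.labels],
    )
    return ResponseMatrix(
        table,
        free_target=state.free_target,
        saturations=pd.Series(s, index=list(state.labels), name="saturation"),
    )


class CompetitionModel:
    """Response analysis of an observed competition state.

    Statsmodels-style entry point: construct from a
    :class:`CompetitionState` (or a table of totals and bound amounts) and
    call :meth:`fit` to obtain a :class:`CompetitionResults`.

    Examples
    --------
    >>> state = CompetitionState(T=700, C=[700, 370, 110], tc=[545, 100, 55],
    ...                          labels=("s70", "s28", "s54"))
    >>> res = CompetitionModel(state).fit()
    >>> round(res.matrix["s28", "T"], 1)
    2.3
    """

    def __init__(self, state: CompetitionState):
        self.state = state

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, T: float) -> "CompetitionModel":
        return cls(CompetitionState.from_dataframe(df, T=T))

    @classmethod
    def from_tsv(cls, path) -> "CompetitionModel":
        from .io import read_competition_table

        return cls(read_competition_table(path))

    def fit(self) -> "CompetitionResults":
        """Evaluate all closed-form coefficients for the stored state."""
        matrix = response_matrix(self.state)
        thresholds, ultra = zip(
            *(ultrasensitivity_threshold(self.state, i) for i in range(self.state.n))
        )
        return CompetitionResults(self, matrix, np.asarray(thresholds), np.asarray(ultra))


class CompetitionResults:
    """Fitted response coefficients with diagnostics.

    Attributes
    ----------
    matrix : ResponseMatrix
        Flux-by-parameter coefficient table.
    ultrasensitive : ndarray of bool
        Per-flux flag for R_i^T > 1.
    thresholds : ndarray
        Free-target thresholds for ultrasensitivity (may be +inf).
    """

    def __init__(self, model, matrix, thresholds, ultrasensitive):
        self.model = model
        self.matrix = matrix
        self.thresholds = thresholds
        self.ultrasensitive = ultrasensitive

    @property
    def state(self) -> CompetitionState:
        return self.model.state

    @property
    def free_target(self) -> float:
        return self.matrix.free_target

    @property
    def saturations(self) -> pd.Series:
        return self.matrix.saturations

    def row_identity_residual(self) -> pd.Series:
        """Residual of the row identity R_T + sum_k R_Ck = 1 + R_T t/T."""
        table = self.matrix.table
        lhs = table.sum(axis=1)
        rhs = 1.0 + table["T"] * (self.free_target / self.state.T)
        return lhs - rhs

    def summary(self) -> str:
        """Plain-text summary in the style of a regression results table."""
        st = self.state
        lines = []
        lines.append("Competition response analysis")
        lines.append("=" * 66)
        lines.append(
            f"Competitors: {st.n}    total target T = {st.T:g}    "
            f"free target t = {self.free_target:g}"
        )
        lines.append("-" * 66)
        header = f"{'flux':<10}{'saturation':>11}{'R_T':>9}" + "".join(
            f"{'R_' + lab:>10}" for lab in st.labels
        ) + f"{'ultra':>7}"
        lines.append(header)
        table = self.matrix.table
        for idx, lab in enumerate(st.labels):
            row = table.loc[lab]
            vals = "".join(f"{row[c]:>10.3g}" for c in st.labels)
            lines.append(
                f"{lab:<10}{self.saturations[lab]:>11.3f}{row['T']:>9.3g}"
                + vals
                + f"{'yes' if self.ultrasensitive[idx] else 'no':>7}"
            )
        lines.append("-" * 66)
        lines.append(
            "R_T: response to total target; R_<label>: response to that "
            "competitor's total."
        )
        return "\n".join(lines)

    def to_tsv(self, path):
        from .io import write_response_matrix

        write_response_matrix(self.matrix, path)

    def to_json(self, path):
        from .io import write_response_matrix_json

        write_response_matrix_json(self.matrix, path)
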