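"""Response coefficients for mRNAs competing for ribosomes.

An mRNA is a competitor that binds several identical targets at once: up
to ``N_i / L`` ribosomes fit on an ORF of ``N_i`` codons when each
ribosome occludes ``L`` codons (default 12).  With ``P_i`` the mean
number of ribosomes bound per mRNA molecule, the single-site formulas of
:mod:`fluxcomp.competition` carry over under the substitutions

    s_i = P_i * L / N_i            (effective saturation)
    f_i = C_i * P_i / T            (fraction of the ribosome pool on mRNA i)

which turn them into the multi-site response coefficients for the protein
synthesis flux of each transcript.  ``P_i`` is typically the product of
the *ribosome occupancy* (fraction of molecules of mRNA i carrying at
least one ribosome) and the *polysome size* (mean ribosomes on the
occupied molecules); it can also be derived from a *ribosome density*
expressed in ribosomes per 100 codons, physically capped at ``100 / L``
(8.33 for L = 12).

The derivation assumes all-or-nothing binding of the average load and no
steric interference; :mod:`fluxcomp.polysome` provides the detailed
traffic simulator against which these formulas are validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .competition import response_kernel
from .exceptions import UndefinedRatioError, ValidationError

__all__ = [
    "TranscriptRecord",
    "TranslationState",
    "TranslationModel",
    "TranslationResults",
    "density_cap",
    "bound_from_density",
    "per_kilobase_to_per_100_codons",
    "fill_occupancy",
    "resolve_bound_ribosomes",
    "effective_saturation",
    "ribosome_fraction",
    "response_to_ribosome",
    "response_to_own_mrna",
    "response_to_other_mrna",
    "translation_ultrasensitive",
    "crosstalk_ratio",
    "strength_ratio",
]

DEFAULT_FOOTPRINT = 12
DEFAULT_OCCUPANCY = 0.75
#: default distance (in density units, ribosomes per 100 codons) kept below
#: the physical cap when clamping impossible densities
DENSITY_CLAMP_EPSILON = 0.005

_REL_SLACK = 1e-9


def density_cap(L: int = DEFAULT_FOOTPRINT) -> float:
    """Physical maximum ribosome density, 100 / L ribosomes per 100 codons."""
    return 100.0 / L


def per_kilobase_to_per_100_codons(density_per_1000_nt) -> np.ndarray:
    """Convert ribosomes per 1000 nucleotides to ribosomes per 100 codons.

    1000 nucleotides span 1000/3 codons, so the factor is 100/(1000/3) = 0.3.
    """
    return np.asarray(density_per_1000_nt, dtype=float) * 0.3


def bound_from_density(
    density,
    n_codons,
    L: int = DEFAULT_FOOTPRINT,
    epsilon: float = DENSITY_CLAMP_EPSILON,
):
    """Mean bound ribosomes P from a density in ribosomes per 100 codons.

    Densities above the physical cap ``100/L`` are clamped to the cap minus
    ``epsilon`` (they arise from measurement noise in compiled tables and
    would imply saturations above 1).

    Returns
    -------
    (P, n_clamped)
        ``P = density * n_codons / 100`` after clamping, and the number of
        entries that were clamped.
    """
    density = np.asarray(density, dtype=float)
    n_codons = np.asarray(n_codons, dtype=float)
    if np.any(density < 0):
        raise ValidationError("ribosome density must be non-negative")
    cap = density_cap(L)
    over = density > cap
    clamped = np.where(over, cap - epsilon, density)
    P = clamped * n_codons / 100.0
    return P, int(np.count_nonzero(over))


def fill_occupancy(df: pd.DataFrame, default: float = DEFAULT_OCCUPANCY):
    """Fill missing ribosome occupancies and recompute P = occupancy x polysome size.

    Parameters
    ----------
    df : DataFrame
        Must carry ``occupancy`` and ``polysome_size`` columns; occupancy
        may contain NaN for transcripts absent from the occupancy
        compilation.
    default : float in (0, 1]
        Occupancy assigned to the missing entries.

    Returns
    -------
    (df, n_filled)
        A copy with occupancy completed and a ``P`` column set to
        occupancy x polysome_size, plus the count of filled records.
    """
    if not 0 < default <= 1:
        raise ValidationError("default occupancy must lie in (0, 1]")
    out = df.copy()
    missing = out["occupancy"].isna()
    out.loc[missing, "occupancy"] = default
    out["P"] = out["occupancy"] * out["polysome_size"]
    return out, int(missing.sum())


@dataclass
class TranscriptRecord:
    """One mRNA species; P may be given directly or via its components."""

    id: str
    C: float
    N: int
    P: Optional[float] = None
    occupancy: Optional[float] = None
    polysome_size: Optional[float] = None
    density: Optional[float] = None


def resolve_bound_ribosomes(
    df: pd.DataFrame,
    L: int = DEFAULT_FOOTPRINT,
    default_occupancy: float = DEFAULT_OCCUPANCY,
    density_epsilon: float = DENSITY_CLAMP_EPSILON,
):
    """Resolve the mean bound-ribosome count P for every transcript.

    Precedence per record: an explicit ``P`` column wins; otherwise
    ``occupancy x polysome_size`` (missing occupancies filled with
    ``default_occupancy``); otherwise a ``density`` column in ribosomes per
    100 codons, clamped at the physical cap.

    Returns
    -------
    (P, report)
        P as a float array aligned with ``df`` and a dict with keys
        ``source``, ``n_filled_occupancy``, ``n_clamped_density``.
    """
    report = {"source": None, "n_filled_occupancy": 0, "n_clamped_density": 0}
    if "P" in df.columns and df["P"].notna().all():
        report["source"] = "P"
        return df["P"].to_numpy(float), report
    if {"occupancy", "polysome_size"} <= set(df.columns):
        filled, n_filled = fill_occupancy(df, default=default_occupancy)
        report["source"] = "occupancy*polysome_size"
        report["n_filled_occupancy"] = n_filled
        return filled["P"].to_numpy(float), report
    if "density" in df.columns:
        P, n_clamped = bound_from_density(
            df["density"].to_numpy(float),
            df["orf_codons"].to_numpy(float),
            L=L,
            epsilon=density_epsilon,
        )
        report["source"] = "density"
        report["n_clamped_density"] = n_clamped
        return P, report
    raise ValidationError(
        "cannot resolve bound ribosomes: need a P column, or occupancy + "
        "polysome_size, or density"
    )


class TranslationState:
    """Ribosome pool and per-transcript sufficient statistics.

    Parameters
    ----------
    T : float
        Total ribosome pool, same unit family as the abundances
        (e.g. micromolar).
    C, N, P : arrays
        Per-transcript abundance, ORF length in codons, and mean bound
        ribosomes per molecule.
    L : int
        Ribosome footprint in codons.
    ids : sequence of str, optional
    """

    def __init__(self, T, C, N, P, L: int = DEFAULT_FOOTPRINT, ids=None):
        self.T = float(T)
        self.C = np.atleast_1d(np.asarray(C, dtype=float))
        self.N = np.atleast_1d(np.asarray(N, dtype=float))
        self.P = np.atleast_1d(np.asarray(P, dtype=float))
        self.L = int(L)
        if ids is None:
            ids = [f"g{i + 1}" for i in range(self.C.size)]
        self.ids = tuple(str(x) for x in ids)
        self._validate()

    def _validate(self):
        n = self.C.size
        if not (self.N.size == self.P.size == len(self.ids) == n):
            raise ValidationError("C, N, P and ids must have equal length")
        if self.L < 1:
            raise ValidationError("footprint L must be >= 1")
        if self.T <= 0:
            raise ValidationError("ribosome pool T must be positive")
        if np.any(self.C < 0) or np.any(self.P < 0):
            raise ValidationError("abundances and bound counts must be >= 0")
        if np.any(self.N < self.L):
            bad = np.flatnonzero(self.N < self.L)
            raise ValidationError(
                f"ORF shorter than one footprint for records {bad.tolist()}"
            )
        cap = self.N / self.L
        if np.any(self.P > cap * (1 + _REL_SLACK)):
            bad = np.flatnonzero(self.P > cap * (1 + _REL_SLACK))
            raise ValidationError(
                f"bound ribosomes exceed packing limit N/L for records {bad.tolist()}"
            )
        bound = float(self.C @ self.P)
        if bound > self.T * (1 + _REL_SLACK):
            raise ValidationError(
                f"total bound ribosomes {bound:g} exceed the pool T = {self.T:g}"
            )

    @property
    def n(self) -> int:
        return self.C.size

    @property
    def saturations(self) -> np.ndarray:
        """Effective saturation s_i = P_i L / N_i."""
        return self.P * self.L / self.N

    @property
    def bound_fractions(self) -> np.ndarray:
        """f_i = C_i P_i / T."""
        return self.C * self.P / self.T

    @property
    def free_ribosomes(self) -> float:
        return self.T - float(self.C @ self.P)

    def index(self, i) -> int:
        if isinstance(i, (int, np.integer)):
            if not 0 <= i < self.n:
                raise ValidationError(f"transcript index {i} out of range")
            return int(i)
        try:
            return self.ids.index(str(i))
        except ValueError:
            raise ValidationError(f"unknown transcript id {i!r}") from None

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        T: float,
        L: int = DEFAULT_FOOTPRINT,
        default_occupancy: float = DEFAULT_OCCUPANCY,
        density_epsilon: float = DENSITY_CLAMP_EPSILON,
    ):
        """Build a state from a transcriptome table, resolving P as needed.

        Expects columns ``id``, ``abundance``, ``orf_codons`` and a P
        source (see :func:`resolve_bound_ribosomes`).  Returns
        ``(state, report)``.
        """
        missing = {"id", "abundance", "orf_codons"} - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        P, report = resolve_bound_ribosomes(
            df, L=L, default_occupancy=default_occupancy,
            density_epsilon=density_epsilon,
        )
        state = cls(
            T=T,
            C=df["abundance"].to_numpy(float),
            N=df["orf_codons"].to_numpy(float),
            P=P,
            L=L,
            ids=df["id"].astype(str).tolist(),
        )
        return state, report

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "abundance": self.C,
                "orf_codons": self.N.astype(int),
                "P": self.P,
            }
        )


# ---------------------------------------------------------------------------
# formula layer (thin wrappers over the shared kernel)


def effective_saturation(state: TranslationState, i) -> float:
    """s_i = P_i L / N_i, the fraction of mRNA i's capacity occupied."""
    i = state.index(i)
    s = float(state.saturations[i])
    if s > 1.0 + _REL_SLACK:
        raise ValidationError(
            f"record {state.ids[i]!r} has saturation {s:g} > 1 "
            "(density above the physical cap?)"
        )
    return min(s, 1.0)


def ribosome_fraction(state: TranslationState, i) -> float:
    """f_i = C_i P_i / T, the share of the ribosome pool held by mRNA i."""
    return float(state.bound_fractions[state.index(i)])


def _kernel(state: TranslationState):
    return response_kernel(state.saturations, state.bound_fractions)


def response_to_ribosome(state: TranslationState, i) -> float:
    """Response of the synthesis flux of mRNA i to the total ribosome pool."""
    R_T, _ = _kernel(state)
    return float(R_T[state.index(i)])


def response_to_ribosome_all(state: TranslationState) -> np.ndarray:
    """Vectorised responses of all synthesis fluxes to the ribosome pool."""
    R_T, _ = _kernel(state)
    return R_T


def response_to_own_mrna(state: TranslationState, i) -> float:
    """Self-response of flux i to its own mRNA abundance, in [0, 1]."""
    i = state.index(i)
    R_T, _ = _kernel(state)
    return 1.0 - float(R_T[i] * state.bound_fractions[i])


def response_to_other_mrna(state: TranslationState, i, k) -> float:
    """Cross-response of flux i to the abundance of mRNA k (non-positive)."""
    i, k = state.index(i), state.index(k)
    if i == k:
        raise ValidationError("i == k: use response_to_own_mrna")
    R_T, _ = _kernel(state)
    return -float(R_T[i] * state.bound_fractions[k])


def translation_ultrasensitive(state: TranslationState, i=None):
    """Whether flux i (or every flux) responds ultrasensitively to ribosomes.

    Uses the division-free criterion ``sum_j C_j P_j s_j > s_i T``, exactly
    equivalent to the response coefficient exceeding 1.
    """
    s = state.saturations
    lhs = float((state.C * state.P) @ s)
    flags = lhs > s * state.T
    if i is None:
        return flags
    return bool(flags[state.index(i)])


def crosstalk_ratio(state: TranslationState, i, j, k) -> float:
    """R_i^{C_k} / R_j^{C_k}: relative sensitivity of fluxes i and j to mRNA k.

    Independent of k; equals the ratio of target responses R_i^T / R_j^T.
    """
    i, j, k = state.index(i), state.index(j), state.index(k)
    if k in (i, j):
        raise ValidationError("k must differ from both i and j")
    if state.bound_fractions[k] <= 0:
        raise UndefinedRatioError(
            f"mRNA {state.ids[k]!r} binds no ribosomes; crosstalk ratio is 0/0"
        )
    R_T, _ = _kernel(state)
    if R_T[j] == 0:
        raise UndefinedRatioError(f"flux {state.ids[j]!r} has zero target response")
    return float(R_T[i] / R_T[j])


def strength_ratio(state: TranslationState, k, l) -> float:
    """C_k P_k / (C_l P_l): relative competitor strength of mRNAs k and l."""
    k, l = state.index(k), state.index(l)
    denom = state.C[l] * state.P[l]
    if denom <= 0:
        raise UndefinedRatioError(
            f"mRNA {state.ids[l]!r} binds no ribosomes; strength ratio undefined"
        )
    return float(state.C[k] * state.P[k] / denom)


# ---------------------------------------------------------------------------
# model layer


class TranslationModel:
    """Genome-scale response analysis of a translation state.

    ``fit()`` evaluates the ribosome-pool and self responses for every
    transcript and returns a :class:`TranslationResults`.
    """

    def __init__(self, state: TranslationState):
        self.state = state

    @classmethod
    def from_dataframe(cls, df, T, L=DEFAULT_FOOTPRINT, **kw) -> "TranslationModel":
        state, report = TranslationState.from_dataframe(df, T=T, L=L, **kw)
        model = cls(state)
        model.resolution_report = report
        return model

    @classmethod
    def from_tsv(cls, path, **kw) -> "TranslationModel":
        from .io import read_transcriptome_table

        state, report = read_transcriptome_table(path, **kw)
        model = cls(state)
        model.resolution_report = report
        return model

    def fit(self) -> "TranslationResults":
        state = self.state
        R_T, denom = _kernel(state)
        R_own = 1.0 - R_T * state.bound_fractions
        ultra = translation_ultrasensitive(state)
        table = pd.DataFrame(
            {
                "id": state.ids,
                "saturation": state.saturations,
                "ribosome_fraction": state.bound_fractions,
                "R_T": R_T,
                "R_own": R_own,
                "ultrasensitive": ultra,
            }
        )
        return TranslationResults(self, table, denominator=denom)


class TranslationResults:
    """Per-transcript response coefficients and genome-wide summaries."""

    def __init__(self, model, table: pd.DataFrame, denominator: float):
        self.model = model
        self.table = table
        self.denominator = denominator

    @property
    def state(self) -> TranslationState:
        return self.model.state

    @property
    def fraction_ultrasensitive(self) -> float:
        return float(self.table["ultrasensitive"].mean())

    def cross_response(self, i, k) -> float:
        return response_to_other_mrna(self.state, i, k)

    def quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.Series:
        return self.table["R_T"].quantile(list(q))

    def summary(self) -> str:
        st = self.state
        q = self.quantiles()
        lines = [
            "Translation response analysis",
            "=" * 60,
            f"Transcripts: {st.n}    ribosome pool T = {st.T:g}    "
            f"footprint L = {st.L}",
            f"Free ribosomes: {st.free_ribosomes:g} "
            f"({st.free_ribosomes / st.T:.1%} of pool)",
            "-" * 60,
            f"Response to ribosome pool (R_T): median {q[0.5]:.3g}, "
            f"IQR [{q[0.25]:.3g}, {q[0.75]:.3g}]",
            f"5%-95% range: [{q[0.05]:.3g}, {q[0.95]:.3g}]",
            f"Ultrasensitive transcripts (R_T > 1): "
            f"{self.fraction_ultrasensitive:.1%}",
            "-" * 60,
        ]
        return "\n".join(lines)
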