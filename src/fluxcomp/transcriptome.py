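"""Synthetic genome-scale transcriptome tables and the response-distribution pipeline.

Emulates the structure of compiled yeast translation datasets: several
thousand transcripts with right-skewed abundances, log-normal ORF
lengths, ribosome densities bounded by the physical packing limit, and
ribosome occupancies averaging about 0.75 with a small fraction of
transcripts missing an occupancy measurement.  The defaults describe a
budding-yeast-like cell with a 79 uM ribosome pool and a 12-codon
footprint; 4621 transcripts matches the size of the dataset the genome
pipeline is designed around.

The generated table feeds :class:`fluxcomp.translation.TranslationModel`
to produce the whole-transcriptome distribution of flux response
coefficients to the ribosome pool, including the occupancy = 1 variant
(every mRNA molecule assumed ribosome-bound) and the ranked 5% tail bins
exported for downstream annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .translation import (
    DEFAULT_FOOTPRINT,
    DEFAULT_OCCUPANCY,
    TranslationModel,
    TranslationState,
    bound_from_density,
    density_cap,
    fill_occupancy,
)

__all__ = [
    "TranscriptomeConfig",
    "generate",
    "build_state",
    "genome_response_distribution",
    "tail_bins",
]


@dataclass
class TranscriptomeConfig:
    """Distributional recipe for a synthetic transcriptome.

    Lengths, abundances and densities are log-normal (``*_meanlog`` /
    ``*_sdlog`` are the parameters of the underlying normal); occupancy is
    Beta-distributed with the given mean and concentration (default mean
    0.75); a configurable fraction of occupancies is withheld as missing.
    ``T`` is the ribosome pool in uM and ``L`` the footprint in codons.
    """

    n_genes: int = 4621
    T: float = 79.0
    L: int = DEFAULT_FOOTPRINT
    # ORF length in codons, log-normal bounded to [L, length_max]
    length_meanlog: float = math.log(400.0)
    length_sdlog: float = 0.55
    length_max: int = 5000
    # mRNA abundance in uM (positive skew); scale chosen so a default-size
    # draw commits roughly the whole ribosome pool, as the compiled yeast
    # data do (most ribosomes engaged in translation)
    abundance_meanlog: float = math.log(0.0026)
    abundance_sdlog: float = 1.0
    # ribosome density in ribosomes per 100 codons, capped at 100/L
    density_meanlog: float = math.log(0.8)
    density_sdlog: float = 0.8
    # ribosome occupancy: Beta with mean ~0.75, support (0, 1)
    occupancy_mean: float = DEFAULT_OCCUPANCY
    occupancy_concentration: float = 8.0
    missing_occupancy_fraction: float = 0.02
    # fraction of the pool left free when rescaling an over-committed draw
    free_fraction: float = 0.05
    seed: int | None = None

    def validate(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0 < self.occupancy_mean <= 1:
            raise ValidationError("occupancy mean must lie in (0, 1]")
        if not 0 <= self.missing_occupancy_fraction < 1:
            raise ValidationError("missing fraction must lie in [0, 1)")
        if not 0 <= self.free_fraction < 1:
            raise ValidationError("free fraction must lie in [0, 1)")
        if self.T <= 0 or self.L < 1:
            raise ValidationError("need T > 0 and L >= 1")


def generate(config: TranscriptomeConfig) -> pd.DataFrame:
    """Draw a transcriptome table; byte-identical for a given seed.

    Returns a DataFrame with columns ``id``, ``abundance``, ``orf_codons``,
    ``density`` (raw draw, may exceed the cap), ``polysome_size`` (from the
    capped density) and ``occupancy`` (NaN where withheld).  Conservation
    against the pool is enforced later, in :func:`build_state`, so the raw
    table keeps the drawn values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = len(str(n))
    ids = [f"YSYN{i + 1:0{width}d}" for i in range(n)]

    N = np.exp(rng.normal(config.length_meanlog, config.length_sdlog, n))
    N = np.clip(np.round(N), config.L, config.length_max).astype(int)
    abundance = np.exp(rng.normal(config.abundance_meanlog, config.abundance_sdlog, n))
    density = np.exp(rng.normal(config.density_meanlog, config.density_sdlog, n))

    ps, _ = bound_from_density(density, N, L=config.L)
    mu, conc = config.occupancy_mean, config.occupancy_concentration
    occupancy = rng.beta(mu * conc, (1.0 - mu) * conc, n)
    missing = rng.random(n) < config.missing_occupancy_fraction
    occupancy = np.where(missing, np.nan, occupancy)

    return pd.DataFrame(
        {
            "id": ids,
            "abundance": abundance,
            "orf_codons": N,
            "density": density,
            "polysome_size": ps,
            "occupancy": occupancy,
        }
    )


def build_state(
    df: pd.DataFrame,
    T: float,
    L: int = DEFAULT_FOOTPRINT,
    occupancy_one: bool = False,
    default_occupancy: float = DEFAULT_OCCUPANCY,
    free_fraction: float = 0.05,
):
    """Resolve a transcriptome table into a conservation-respecting state.

    Missing occupancies are filled with ``default_occupancy`` (or every
    occupancy forced to 1 with ``occupancy_one``); the mean bound-ribosome
    count is ``P = occupancy x polysome_size``, with the polysome size
    taken from the density column capped at ``100/L`` when not already
    present.  If the drawn table demands more bound ribosomes than the
    pool holds, all P are rescaled by one common factor so that
    ``free_fraction`` of the pool stays free.

    Returns
    -------
    (state, report)
        The :class:`TranslationState` and a dict with ``n_clamped_density``,
        ``n_filled_occupancy``, ``rescale_factor`` (1.0 when no rescaling
        was needed).
    """
    df = df.copy()
    report = {"n_clamped_density": 0, "n_filled_occupancy": 0, "rescale_factor": 1.0}
    if "polysome_size" not in df.columns:
        if "density" not in df.columns:
            raise ValidationError("table needs a polysome_size or density column")
        ps, n_clamped = bound_from_density(
            df["density"].to_numpy(float), df["orf_codons"].to_numpy(float), L=L
        )
        df["polysome_size"] = ps
        report["n_clamped_density"] = n_clamped
    elif "density" in df.columns:
        cap = density_cap(L)
        report["n_clamped_density"] = int((df["density"] > cap).sum())

    if occupancy_one:
        df["occupancy"] = 1.0
        df["P"] = df["polysome_size"]
    else:
        df, n_filled = fill_occupancy(df, default=default_occupancy)
        report["n_filled_occupancy"] = n_filled

    C = df["abundance"].to_numpy(float)
    P = df["P"].to_numpy(float)
    bound = float(C @ P)
    if bound > T:
        factor = (1.0 - free_fraction) * T / bound
        if factor <= 0:
            raise ValidationError("infeasible: pool too small for any rescaling")
        P = P * factor
        report["rescale_factor"] = factor

    state = TranslationState(
        T=T,
        C=C,
        N=df["orf_codons"].to_numpy(float),
        P=P,
        L=L,
        ids=df["id"].astype(str).tolist(),
    )
    return state, report


def genome_response_distribution(
    state: TranslationState,
    bin_edges=None,
):
    """Per-gene ribosome-pool response coefficients plus distribution summary.

    Returns
    -------
    (table, summary)
        ``table`` is the per-gene frame from
        :class:`~fluxcomp.translation.TranslationModel`; ``summary`` holds
        the gene count, the fraction of coefficients above 1, quantiles,
        and histogram counts at the given bin edges (default 0 to 3 in
        steps of 0.1, with any overflow counted in the last bin).
    """
    res = TranslationModel(state).fit()
    table = res.table
    coeffs = table["R_T"].to_numpy()
    if bin_edges is None:
        bin_edges = np.round(np.arange(0.0, 3.01, 0.1), 10)
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(np.clip(coeffs, bin_edges[0], bin_edges[-1]), bins=bin_edges)
    summary = {
        "n_genes": int(len(table)),
        "fraction_above_1": float((coeffs > 1).mean()),
        "fraction_ultrasensitive": res.fraction_ultrasensitive,
        "quantiles": {
            str(q): float(v) for q, v in res.quantiles().items()
        },
        "free_ribosome_fraction": state.free_ribosomes / state.T,
        "histogram": {
            "bin_edges": bin_edges.tolist(),
            "counts": counts.tolist(),
        },
    }
    return table, summary


def tail_bins(coefficients: pd.Series, fraction: float = 0.05):
    """Lowest- and highest-response gene lists at the given tail fraction.

    ``coefficients`` is indexed by gene id.  Genes are ranked by
    coefficient with ties broken by id; each bin holds
    ``floor(fraction * n)`` genes (4621 genes at 5% gives 231).

    Returns
    -------
    (low_ids, high_ids)
        Lists of gene identifiers, each sorted by (coefficient, id).
    """
    if not 0 < fraction <= 0.5:
        raise ValidationError("tail fraction must lie in (0, 0.5]")
    n = len(coefficients)
    m = int(math.floor(fraction * n))
    order = (
        pd.DataFrame({"coef": coefficients.values, "id": coefficients.index.astype(str)})
        .sort_values(["coef", "id"], kind="mergesort")
    )
    low = order["id"].head(m).tolist()
    high = order["id"].tail(m).tolist()
    return low, high
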