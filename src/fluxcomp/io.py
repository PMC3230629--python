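"""Tab-separated table formats with ``#key=value`` headers, plus JSON mirrors.

One TSV dialect is used throughout: UTF-8, tab separators, ``.`` decimal,
with scalar metadata (total pools, footprint) carried in leading comment
lines of the form ``#T=700``.  Readers raise
:class:`~fluxcomp.exceptions.ValidationError` with line numbers on
malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .competition import CompetitionState, ResponseMatrix
from .exceptions import ValidationError
from .translation import DEFAULT_FOOTPRINT, TranslationState

__all__ = [
    "read_competition_table",
    "write_competition_table",
    "read_transcriptome_table",
    "write_transcriptome_table",
    "write_response_matrix",
    "read_response_matrix",
    "write_response_matrix_json",
    "write_gene_list",
    "write_histogram",
]


def _read_headers(path):
    """Leading ``#key=value`` lines -> (dict, number of header lines)."""
    meta = {}
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n


def _read_table(path, required, n_header):
    try:
        df = pd.read_csv(path, sep="\t", skiprows=n_header)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: line {n_header + 1}: missing columns {sorted(missing)}"
        )
    if df.empty:
        raise ValidationError(f"{path}: table has no data rows")
    return df


def _float_meta(meta, key, path):
    if key not in meta:
        raise ValidationError(f"{path}: missing '#{key}=<value>' header line")
    try:
        return float(meta[key])
    except ValueError:
        raise ValidationError(f"{path}: header {key}={meta[key]!r} is not numeric") from None


# -- competition states -----------------------------------------------------


def read_competition_table(path) -> CompetitionState:
    """Read a competition state: ``#T=<total>`` then columns label, C, tc."""
    meta, n_header = _read_headers(path)
    T = _float_meta(meta, "T", path)
    df = _read_table(path, ("label", "C", "tc"), n_header)
    for col in ("C", "tc"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: line {n_header + 2 + bad[0]}: non-numeric {col!r} value"
            )
    return CompetitionState.from_dataframe(df, T=T)


def write_competition_table(state: CompetitionState, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#T={state.T:.12g}\n")
        state.to_dataframe().to_csv(fh, sep="\t", index=False)


# -- transcriptome tables ---------------------------------------------------


def read_transcriptome_table(path, **from_df_kw):
    """Read a transcriptome: ``#T=`` and ``#L=`` headers then per-gene rows.

    Columns: ``id``, ``abundance``, ``orf_codons`` plus a bound-ribosome
    source (``P``, or ``occupancy`` + ``polysome_size``, or ``density``).
    Returns ``(state, report)`` as from
    :meth:`fluxcomp.translation.TranslationState.from_dataframe`.
    """
    meta, n_header = _read_headers(path)
    T = _float_meta(meta, "T", path)
    L = int(_float_meta(meta, "L", path)) if "L" in meta else DEFAULT_FOOTPRINT
    df = _read_table(path, ("id", "abundance", "orf_codons"), n_header)
    return TranslationState.from_dataframe(df, T=T, L=L, **from_df_kw)


def write_transcriptome_table(df: pd.DataFrame, path, T: float, L: int = DEFAULT_FOOTPRINT):
    """Write a per-gene table with the pool and footprint in the header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#T={T:.12g}\n#L={L}\n")
        df.to_csv(fh, sep="\t", index=False)


# -- response matrices ------------------------------------------------------


def write_response_matrix(matrix: ResponseMatrix, path):
    """TSV with columns ``flux``, ``R_T``, ``R_<label>``... plus metadata headers."""
    table = matrix.table.copy()
    table.columns = ["R_T"] + [f"R_{lab}" for lab in matrix.labels]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#free_target={matrix.free_target:.12g}\n")
        sats = ",".join(f"{s:.12g}" for s in matrix.saturations)
        fh.write(f"#saturations={sats}\n")
        table.to_csv(fh, sep="\t", index=True, index_label="flux")


def read_response_matrix(path) -> ResponseMatrix:
    meta, n_header = _read_headers(path)
    df = _read_table(path, ("flux", "R_T"), n_header).set_index("flux")
    labels = [c[2:] for c in df.columns if c != "R_T"]
    df.columns = ["T", *labels]
    sats = pd.Series(
        [float(x) for x in meta.get("saturations", "").split(",")] if meta.get("saturations")
        else np.nan,
        index=labels,
        name="saturation",
    )
    return ResponseMatrix(df, free_target=float(meta.get("free_target", "nan")), saturations=sats)


def write_response_matrix_json(matrix: ResponseMatrix, path):
    payload = {
        "free_target": matrix.free_target,
        "saturations": {k: float(v) for k, v in matrix.saturations.items()},
        "coefficients": {
            flux: {
                ("T" if col == "T" else col): float(matrix.table.loc[flux, col])
                for col in matrix.table.columns
            }
            for flux in matrix.table.index
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# -- misc outputs -----------------------------------------------------------


def write_gene_list(ids, path):
    Path(path).write_text("\n".join(str(x) for x in ids) + "\n", encoding="utf-8")


def write_histogram(bin_edges, counts, path, variant: str = "default"):
    """Histogram TSV: bin_left, bin_right, count, variant."""
    df = pd.DataFrame(
        {
            "bin_left": np.asarray(bin_edges)[:-1],
            "bin_right": np.asarray(bin_edges)[1:],
            "count": np.asarray(counts, dtype=int),
            "variant": variant,
        }
    )
    df.to_csv(path, sep="\t", index=False)
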