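"""MM-PBSA / MM-GBSA free-energy bookkeeping.

End-point continuum-solvent free energies decompose into molecular-
mechanics terms (ELE electrostatic, VDW van der Waals, INT internal/
torsional), implicit-solvent terms (PBSUR non-polar and PBCAL polar
solvation), and a normal-mode entropy column (TS).  This module only does
the bookkeeping over such term tables: derived sums, conformer-to-
conformer differences with error propagation, Boltzmann population ↔ ΔG
conversion, and per-residue decomposition ranking.  It never solves the
PB/GB equations — term values are inputs.

Derived columns follow the printed-table convention

    PROT  = ELE + VDW + INT
    SOLV  = PBSUR + PBCAL
    PBTOT = PROT + SOLV

with the entropy column carried separately; ``include_ts=True`` adds TS
into PBTOT for tables that fold the entropy term into the total.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .synthetic import KB_KCAL

R_KCAL = KB_KCAL  # gas constant in kcal mol^-1 K^-1 (molar energy units)

BASE_TERMS = ("ELE", "VDW", "INT", "PBSUR", "PBCAL", "TS")


def load_reference_table() -> pd.DataFrame:
    """Packaged MM-PBSA term table for the open / semi-closed MBP conformers.

    Rows: the two conformers plus a statistical-error row ("STE");
    columns: the six base terms (kcal/mol).
    """
    with resources.files("hingepre.data").joinpath("mmpbsa_mbp.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def derive_totals(table: pd.DataFrame, include_ts: bool = False) -> pd.DataFrame:
    """Complete a base-term table with PROT, SOLV and PBTOT columns.

    Derived columns are always recomputed from the base terms, never
    trusted from the input.  Error rows (index "STE") are combined in
    quadrature instead of summed.
    """
    for conformer, row in table.iterrows():
        for term in BASE_TERMS:
            if term not in table.columns or pd.isna(row.get(term)):
                raise ValueError(f"conformer {conformer!r} is missing term {term}")
    out = table.copy()
    is_err = out.index.astype(str).str.upper() == "STE"

    def combine(cols):
        vals = out[list(cols)].to_numpy(dtype=float)
        plain = vals.sum(axis=1)
        quad = np.sqrt((vals ** 2).sum(axis=1))
        return np.where(is_err, quad, plain)

    out["PROT"] = combine(["ELE", "VDW", "INT"])
    out["SOLV"] = combine(["PBSUR", "PBCAL"])
    total_cols = ["PROT", "SOLV"] + (["TS"] if include_ts else [])
    out["PBTOT"] = combine(total_cols)
    return out


def conformer_delta(table: pd.DataFrame, a: str, b: str,
                    include_ts: bool = False) -> pd.Series:
    """Per-term ΔG row (a − b) over base and derived terms.

    If the table carries an "STE" row, a companion Series of quadrature-
    combined standard errors is attached as ``result.attrs["ste"]``.
    """
    totals = derive_totals(table, include_ts=include_ts)
    for name in (a, b):
        if name not in totals.index:
            raise ValueError(f"conformer {name!r} not in table")
    delta = totals.loc[a] - totals.loc[b]
    delta.name = f"dG({a} - {b})"
    if "STE" in totals.index.astype(str).str.upper().tolist():
        ste_row = totals.loc[totals.index.astype(str).str.upper() == "STE"].iloc[0]
        delta.attrs["ste"] = np.sqrt(2.0) * ste_row
    return delta


def population_from_dg(dg: float, temperature: float = 300.0) -> float:
    """Minor-state probability of a two-level system with ΔG = G_minor − G_major.

    p_minor = exp(−ΔG/RT) / (1 + exp(−ΔG/RT)).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = np.exp(-dg / (R_KCAL * temperature))
    return float(z / (1.0 + z))


def dg_from_population(p_minor: float, temperature: float = 300.0) -> float:
    """Inverse of :func:`population_from_dg`: ΔG = −RT ln(p/(1−p))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not (0.0 < p_minor < 1.0):
        raise ValueError("p_minor must lie strictly in (0, 1)")
    return float(-R_KCAL * temperature * np.log(p_minor / (1.0 - p_minor)))


def rank_residue_contributions(decomposition: pd.DataFrame) -> pd.DataFrame:
    """Sort a per-residue ΔΔG table by descending |ΔΔG|.

    Sign convention: positive ΔΔG favors the open state.  Ties break
    stably by residue id.  Adds a ``favors`` column ("open" /
    "semi-closed" / "neutral").
    """
    if len(decomposition) == 0:
        raise ValueError("decomposition table is empty")
    if decomposition["residue_id"].duplicated().any():
        raise ValueError("residue ids must be unique")
    out = decomposition.copy()
    out["abs_ddg"] = out["ddg"].abs()
    out = out.sort_values(["abs_ddg", "residue_id"],
                          ascending=[False, True], kind="mergesort")
    out["favors"] = np.select(
        [out["ddg"] > 0, out["ddg"] < 0], ["open", "semi-closed"], "neutral")
    return out.drop(columns="abs_ddg").reset_index(drop=True)
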