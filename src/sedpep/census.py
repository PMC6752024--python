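"""Secreted-peptidase gene census by family and sediment zone.

Consumes per-gene annotation tables: gene id, depth zone (sulfate-reduction
zone SRZ, sulfate-methane transition zone SMTZ, methane-rich zone MRZ),
MEROPS-style family label, and one boolean column per signal-peptide
predictor (the predictors themselves run upstream; only their flags are
used here).  A gene is "SP-positive" — likely secreted through the
Sec-dependent pathway — when flagged by at least one predictor, or by a
specific predictor in per-tool mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .merops import validate_family

__all__ = ["ZONES", "SP_COLUMNS", "validate_gene_table", "zone_totals",
           "sp_family_frequencies", "ZoneTotals"]

ZONES = ("SRZ", "SMTZ", "MRZ")
SP_COLUMNS = ("sp_predisi", "sp_predsignal", "sp_psort", "sp_signalp")


def _sp_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("sp_")]
    if not cols:
        raise ConfigurationError("gene table has no sp_* predictor columns")
    return cols


def validate_gene_table(table: pd.DataFrame, check_families: bool = True) -> pd.DataFrame:
    """Schema validation: required columns, unique ids, known zones."""
    for col in ("gene_id", "zone", "family"):
        if col not in table.columns:
            raise ConfigurationError(f"gene table missing column {col!r}")
    _sp_columns(table)
    dups = table["gene_id"][table["gene_id"].duplicated()].unique().tolist()
    if dups:
        raise ValidationError(f"duplicated gene ids: {dups[:10]}")
    bad = sorted(set(table["zone"]) - set(ZONES))
    if bad:
        raise ValidationError(f"unknown zone labels: {bad}")
    if check_families:
        for fam in pd.unique(table["family"]):
            validate_family(fam)
    return table


@dataclass
class ZoneTotals:
    per_zone: pd.Series  # indexed by ZONES, including zeros
    total: int


def zone_totals(table: pd.DataFrame) -> ZoneTotals:
    """Gene counts per depth zone and their grand total.

    Every allowed zone is reported, with a zero count if absent.
    """
    if len(table) == 0:
        raise ValidationError("empty gene table")
    validate_gene_table(table, check_families=False)
    counts = table.groupby("zone").size().reindex(ZONES, fill_value=0)
    counts.name = "n_genes"
    return ZoneTotals(counts, int(counts.sum()))


def sp_family_frequencies(table: pd.DataFrame, mode: str = "any-tool") -> pd.DataFrame:
    """Per-zone, per-family frequency of signal-peptide-positive genes.

    frequency(family, zone) = SP-positive genes of that family in the zone
    divided by *all* peptidase genes in the zone, so frequencies within a
    zone sum to at most 1 (the SP-negative share makes up the rest).

    ``mode='any-tool'`` calls a gene SP-positive when any predictor flags
    it; ``mode='per-tool'`` returns one block per predictor with a ``tool``
    column.  Returns columns (zone, family, n_total_zone, n_sp, frequency
    [, tool]).
    """
    validate_gene_table(table, check_families=False)
    sp_cols = _sp_columns(table)
    if mode == "per-tool":
        blocks = []
        for col in sp_cols:
            block = _frequencies_for(table, table[col].astype(bool))
            block.insert(0, "tool", col)
            blocks.append(block)
        return pd.concat(blocks, ignore_index=True)
    if mode != "any-tool":
        raise ConfigurationError(f"unknown mode {mode!r}; use 'any-tool' or 'per-tool'")
    positive = table[sp_cols].astype(bool).any(axis=1)
    return _frequencies_for(table, positive)


def _frequencies_for(table: pd.DataFrame, positive: pd.Series) -> pd.DataFrame:
    zone_n = table.groupby("zone").size()
    sp = table[positive]
    counts = (sp.groupby(["zone", "family"]).size()
              .rename("n_sp").reset_index())
    # carry zone totals for every zone/family combination observed in the table
    all_pairs = (table.groupby(["zone", "family"]).size()
                 .rename("n_zone_family").reset_index()[["zone", "family"]])
    out = all_pairs.merge(counts, on=["zone", "family"], how="left").fillna({"n_sp": 0})
    out["n_sp"] = out["n_sp"].astype(int)
    out["n_total_zone"] = out["zone"].map(zone_n).astype(int)
    out["frequency"] = out["n_sp"] / out["n_total_zone"]
    return out[["zone", "family", "n_total_zone", "n_sp", "frequency"]].sort_values(
        ["zone", "family"], ignore_index=True
    )
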