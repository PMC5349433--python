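"""Per-chain score columns, median imputation and rank aggregation.

Each peptide-ligand chain is described by seven evidence columns:

================  ============================================  ==========
column            meaning                                       bad end
================  ============================================  ==========
bond_len_frac     >5σ bond-length outliers per residue          high
bond_ang_frac     >5σ bond-angle outliers per residue           high
rama_frac         Ramachandran-outlier residues per residue     high
rota_frac         rotamer-outlier residues per residue          high
rsrz_gt2_frac     residues with RSRZ > 2 per eligible residue   high
bdiff_percentile  cohort percentile of the chain-vs-6 Å
                  environment B-factor difference               high
rscc_prob         chance probability P(Sₙ ≤ sₙ) of the chain's
                  summed RSCC                                   low
================  ============================================  ==========

Missing measurements are replaced by the median of the respective column.
The columns are combined in the style of rank-aggregation gene
prioritization: each column is ranked with its most suspicious value at
rank 1 (ties averaged), the rank is divided by the number of scored
chains, and the natural logarithms of these normalized ranks are summed,
optionally weighted.  Sorting ascending by the combined score puts the
chains most worthy of examination at the top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .validation_xml import ChainOutlierCounts

__all__ = [
    "SCORE_COLUMNS",
    "COLUMN_BAD_END",
    "ChainScoreRecord",
    "ScoreTable",
    "outlier_fractions",
    "impute_median",
    "impute_table",
    "metaranker_combine",
    "rank_table",
    "write_score_table",
    "read_score_table",
]

SCORE_COLUMNS = (
    "bond_len_frac",
    "bond_ang_frac",
    "rama_frac",
    "rota_frac",
    "rsrz_gt2_frac",
    "bdiff_percentile",
    "rscc_prob",
)

#: direction of suspicion per column: "high" means large values are bad
COLUMN_BAD_END = {
    "bond_len_frac": "high",
    "bond_ang_frac": "high",
    "rama_frac": "high",
    "rota_frac": "high",
    "rsrz_gt2_frac": "high",
    "bdiff_percentile": "high",
    "rscc_prob": "low",
}


@dataclass
class ChainScoreRecord:
    """One peptide-ligand chain's score columns plus combined score/rank."""

    entry_id: str
    chain_id: str
    n_residues: int
    bond_len_frac: float | None = None
    bond_ang_frac: float | None = None
    rama_frac: float | None = None
    rota_frac: float | None = None
    rsrz_gt2_frac: float | None = None
    bdiff: float | None = None  # raw Å² difference, kept for audit
    bdiff_percentile: float | None = None
    rscc_sum: float | None = None
    rscc_n: int = 0
    rscc_prob: float | None = None
    n_rscc_missing: int = 0
    combined_score: float | None = None
    rank: int | None = None

    def column(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass
class ScoreTable:
    """Ordered collection of chain score records plus run provenance."""

    records: list[ChainScoreRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, name: str) -> list[float | None]:
        return [r.column(name) for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f.name for f in dc_fields(ChainScoreRecord)]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=cols
        )


def outlier_fractions(counts: ChainOutlierCounts) -> dict[str, float | None]:
    """Chain-length-independent outlier fractions from raw counts.

    Geometry and torsion counts are divided by the number of scored
    residues; the RSRZ fraction is divided by the number of residues for
    which an RSRZ is reported (standard amino acids only).  A zero
    denominator yields a missing value.
    """
    n = counts.n_residues
    out: dict[str, float | None] = {}
    if n > 0:
        out["bond_len_frac"] = counts.n_bond_len / n
        out["bond_ang_frac"] = counts.n_bond_ang / n
        out["rama_frac"] = counts.n_rama / n
        out["rota_frac"] = counts.n_rota / n
    else:
        out.update(
            bond_len_frac=None, bond_ang_frac=None, rama_frac=None, rota_frac=None
        )
    out["rsrz_gt2_frac"] = (
        counts.n_rsrz_gt2 / counts.n_rsrz_eligible if counts.n_rsrz_eligible > 0 else None
    )
    return out


def impute_median(column: list[float | None]) -> list[float]:
    """Replace missing entries by the median of the non-missing ones.

    The median of the completed column equals the median of the original
    non-missing values (imputing at the median cannot move it).
    """
    present = [v for v in column if v is not None]
    if not present:
        raise ValueError("cannot impute an all-missing column")
    med = float(np.median(present))
    return [med if v is None else float(v) for v in column]


def impute_table(table: ScoreTable) -> dict[str, float]:
    """Median-impute every score column in place; returns the medians used."""
    medians: dict[str, float] = {}
    for name in SCORE_COLUMNS:
        column = table.column(name)
        try:
            completed = impute_median(column)
        except ValueError as exc:
            raise ValueError(f"column {name!r}: {exc}") from exc
        medians[name] = float(np.median(completed))
        for rec, value in zip(table.records, completed):
            setattr(rec, name, value)
    table.provenance.setdefault("imputation_medians", {}).update(medians)
    return medians


def metaranker_combine(
    table: ScoreTable, weights: dict[str, float] | None = None
) -> ScoreTable:
    """Combine the columns into one score by summed log normalized ranks.

    Each column is ranked so the most suspicious value gets rank 1 (ties
    averaged), normalized by the number of records, and the natural logs of
    the normalized ranks are summed with the given per-column weights
    (default 1).  Scores are ≤ 0; more negative is more suspect.
    """
    if not table.records:
        return table
    weights = dict(weights or {})
    for name in SCORE_COLUMNS:
        weights.setdefault(name, 1.0)
    bad = [k for k, w in weights.items() if w <= 0]
    if bad:
        raise ValueError(f"non-positive weights for columns: {bad}")
    n = len(table.records)
    total = np.zeros(n)
    for name in SCORE_COLUMNS:
        values = np.array(table.column(name), dtype=float)
        if np.isnan(values).any():
            raise ValueError(f"column {name!r} has missing values; impute first")
        ordered = -values if COLUMN_BAD_END[name] == "high" else values
        ranks = rankdata(ordered, method="average")
        total += weights[name] * np.log(ranks / n)
    for rec, score in zip(table.records, total):
        rec.combined_score = float(score)
    table.provenance["weights"] = {k: weights[k] for k in SCORE_COLUMNS}
    return table


def rank_table(table: ScoreTable) -> ScoreTable:
    """Sort ascending by combined score and assign ranks 1..N.

    Rank 1 is the most suspect chain.  Exact score ties are broken by
    (entry_id, chain_id) for reproducibility.
    """
    if any(r.combined_score is None for r in table.records):
        raise ValueError("combined_score must be set on every record before ranking")
    table.records.sort(key=lambda r: (r.combined_score, r.entry_id, r.chain_id))
    for i, rec in enumerate(table.records, start=1):
        rec.rank = i
    return table


_FLOAT_FORMAT = "%.6g"


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write the table as tab-delimited text with a header row."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_score_table(path: str | Path) -> ScoreTable:
    """Read a tab-delimited score table written by :func:`write_score_table`."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed score table {path}: {exc}") from exc
    expected = [f.name for f in dc_fields(ChainScoreRecord)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"score table {path} lacks columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ChainScoreRecord(
                    **{
                        c: _from_cell(row[c], c)
                        for c in expected
                    }
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"score table {path}, data row {i + 1}: {exc}") from exc
    return ScoreTable(records=records)


_INT_FIELDS = {"n_residues", "rscc_n", "n_rscc_missing", "rank"}
_STR_FIELDS = {"entry_id", "chain_id"}


def _from_cell(value, name: str):
    if name in _STR_FIELDS:
        return str(value)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None if name not in {"rscc_n", "n_rscc_missing"} else 0
    if name in _INT_FIELDS:
        return int(value)
    return float(value)
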