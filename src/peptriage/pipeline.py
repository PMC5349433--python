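"""End-to-end scoring: coordinates + validation reports → ranked table.

The cohort matters: the B-factor difference percentile and the empirical
RSCC density f₁ are both defined over *all* chains scored in a run, so the
pipeline first collects per-chain evidence across every entry, then closes
over the cohort to finish the two cohort-relative columns, imputes
missing values by column medians, and rank-aggregates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .bfactor_env import bfactor_difference, empirical_percentile
from .chain_alignment import AlignmentFailedError, map_modeled_residues
from .rscc_stats import (
    ConvolutionTable,
    EmpiricalPDF,
    build_empirical_pdf,
    chain_rscc_probability,
)
from .score_combine import (
    ChainScoreRecord,
    ScoreTable,
    impute_table,
    metaranker_combine,
    outlier_fractions,
    rank_table,
)
from .structure_io import (
    EntryModel,
    PeptideLigandCriteria,
    detect_peptide_ligand_chains,
    parse_structure,
)
from .validation_xml import EntryValidation, chain_outlier_counts, parse_validation_xml

logger = logging.getLogger(__name__)

__all__ = ["PipelineStats", "score_cohort", "score_directories"]


@dataclass
class PipelineStats:
    """Per-stage counters for one scoring run."""

    n_entries: int = 0
    n_candidate_chains: int = 0
    n_alignment_failed: int = 0
    n_no_validation: int = 0
    n_scored: int = 0
    dropped: list[str] = field(default_factory=list)


def score_cohort(
    pairs: list[tuple[EntryModel, EntryValidation]],
    criteria: PeptideLigandCriteria | None = None,
    env_radius: float = 6.0,
    bin_width: float = 0.01,
    weights: dict[str, float] | None = None,
    f1: EmpiricalPDF | None = None,
) -> tuple[ScoreTable, PipelineStats]:
    """Score every peptide-ligand chain found in ``pairs`` and rank them.

    Parameters
    ----------
    pairs:
        (coordinate model, validation facts) per entry.
    criteria:
        Peptide-ligand detection thresholds.
    env_radius:
        Radius (Å) of the B-factor comparison neighbourhood.
    bin_width:
        Bin width of the empirical RSCC density.
    weights:
        Per-column weights for the rank combination (default all 1).
    f1:
        Optional precomputed RSCC density; by default it is built from the
        pooled per-residue RSCC values of the scored chains themselves.
    """
    criteria = criteria or PeptideLigandCriteria()
    stats = PipelineStats(n_entries=len(pairs))
    records: list[ChainScoreRecord] = []
    chain_rsccs: list[tuple[float, ...]] = []
    for entry, validation in pairs:
        for chain_id in detect_peptide_ligand_chains(entry, criteria):
            stats.n_candidate_chains += 1
            chain = entry.chain(chain_id)
            try:
                accepted = map_modeled_residues(chain)
            except AlignmentFailedError as exc:
                stats.n_alignment_failed += 1
                stats.dropped.append(f"{entry.entry_id}/{chain_id}: {exc}")
                continue
            try:
                counts = chain_outlier_counts(validation, chain_id, set(accepted))
            except KeyError as exc:
                stats.n_no_validation += 1
                stats.dropped.append(f"{entry.entry_id}/{chain_id}: {exc}")
                continue
            fractions = outlier_fractions(counts)
            bdiff = bfactor_difference(entry, chain_id, radius=env_radius)
            rec = ChainScoreRecord(
                entry_id=entry.entry_id,
                chain_id=chain_id,
                n_residues=counts.n_residues,
                bdiff=bdiff.diff,
                rscc_sum=float(sum(counts.rscc_values)) if counts.rscc_values else None,
                rscc_n=len(counts.rscc_values),
                n_rscc_missing=counts.n_residues - len(counts.rscc_values),
                **fractions,
            )
            records.append(rec)
            chain_rsccs.append(counts.rscc_values)
            stats.n_scored += 1

    # cohort-relative columns
    if f1 is None:
        pooled = [v for values in chain_rsccs for v in values]
        f1 = build_empirical_pdf(pooled, bin_width=bin_width) if pooled else None
    conv_table = ConvolutionTable(f1) if f1 is not None else None
    for rec, values in zip(records, chain_rsccs):
        if f1 is not None and values:
            rec.rscc_prob = chain_rscc_probability(f1, values, table=conv_table).probability
    bdiff_cohort = [r.bdiff for r in records if r.bdiff is not None]
    for rec in records:
        if rec.bdiff is not None and bdiff_cohort:
            rec.bdiff_percentile = empirical_percentile(rec.bdiff, bdiff_cohort)

    table = ScoreTable(
        records=records,
        provenance={
            "env_radius": env_radius,
            "bin_width": bin_width,
            "n_entries": stats.n_entries,
            "n_rscc_pooled": f1.n_samples if f1 is not None else 0,
        },
    )
    if records:
        impute_table(table)
        metaranker_combine(table, weights)
        rank_table(table)
    logger.info(
        "scored %d/%d candidate chains from %d entries (%d alignment-failed, %d without validation)",
        stats.n_scored,
        stats.n_candidate_chains,
        stats.n_entries,
        stats.n_alignment_failed,
        stats.n_no_validation,
    )
    return table, stats


def score_directories(
    structures_dir: str | Path,
    reports_dir: str | Path,
    **kwargs,
) -> tuple[ScoreTable, PipelineStats]:
    """Score all coordinate files in a directory tree.

    Coordinate files (``*.pdb``, ``*.cif``, ``*.mmcif``) are matched to
    validation reports in ``reports_dir`` by entry stem: ``<stem>.xml`` or
    ``<stem>_validation.xml``.  Entries without a report are skipped with a
    warning.
    """
    structures_dir = Path(structures_dir)
    reports_dir = Path(reports_dir)
    pairs = []
    paths = sorted(
        p
        for pattern in ("*.pdb", "*.ent", "*.cif", "*.mmcif")
        for p in structures_dir.glob(pattern)
    )
    seen_stems = set()
    for path in paths:
        stem = path.stem
        if stem in seen_stems:  # same entry in two dialects
            continue
        report = None
        for candidate in (f"{stem}.xml", f"{stem}_validation.xml"):
            if (reports_dir / candidate).exists():
                report = reports_dir / candidate
                break
        if report is None:
            logger.warning("no validation report for %s; entry skipped", path.name)
            continue
        pairs.append((parse_structure(path), parse_validation_xml(report)))
        seen_stems.add(stem)
    return score_cohort(pairs, **kwargs)
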