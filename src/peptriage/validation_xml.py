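"""Parsing of wwPDB-dialect structure-validation XML reports.

A validation report carries one ``ModelledSubgroup`` element per modelled
residue with, among others, per-residue electron-density fit statistics
(``rscc``, ``rsrz``), Ramachandran and rotamer classes, and nested
``bond-outlier`` / ``angle-outlier`` elements for covalent-geometry
deviations greater than five standard deviations.  Absent attributes are
mapped to *missing*, never to zero: the downstream score columns treat the
two very differently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueValidation",
    "EntryValidation",
    "ChainOutlierCounts",
    "ValidationParseError",
    "parse_validation_xml",
    "chain_outlier_counts",
]


class ValidationParseError(ValueError):
    """Raised for malformed validation XML."""


@dataclass(frozen=True)
class ResidueValidation:
    """Per-residue quality facts from a validation report.

    ``rama_outlier`` / ``rota_outlier`` are ``None`` when the report does
    not assign a class (e.g. glycine rotamers); ``bond_length_outliers`` and
    ``bond_angle_outliers`` count individual >5σ deviations, not residues.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = " "
    residue_name: str = ""
    rscc: float | None = None
    rsrz: float | None = None
    rama_outlier: bool | None = None
    rota_outlier: bool | None = None
    bond_length_outliers: int = 0
    bond_angle_outliers: int = 0

    def __post_init__(self) -> None:
        if self.rscc is not None and not -1.0 <= self.rscc <= 1.0:
            raise ValueError(
                f"RSCC {self.rscc} outside [-1, 1] for "
                f"{self.chain_id}/{self.residue_number}{self.insertion_code.strip()}"
            )
        if self.bond_length_outliers < 0 or self.bond_angle_outliers < 0:
            raise ValueError("outlier counts must be non-negative")

    @property
    def residue_id(self) -> tuple[int, str]:
        return (self.residue_number, self.insertion_code)


@dataclass
class EntryValidation:
    """All per-residue validation facts for one entry."""

    entry_id: str
    residues: list[ResidueValidation]
    resolution: float | None = None
    errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entry_id = self.entry_id.lower()
        seen = set()
        for r in self.residues:
            key = (r.chain_id, r.residue_number, r.insertion_code)
            if key in seen:
                raise ValueError(f"duplicate residue {key} in entry {self.entry_id}")
            seen.add(key)

    def chain_residues(self, chain_id: str) -> list[ResidueValidation]:
        out = [r for r in self.residues if r.chain_id == chain_id]
        if not out:
            raise KeyError(f"chain {chain_id!r} not found in validation data for {self.entry_id!r}")
        return out


@dataclass(frozen=True)
class ChainOutlierCounts:
    """Raw per-chain counts, before length normalization.

    ``n_rsrz_eligible`` is the number of residues for which the report
    states an RSRZ at all (standard amino acids only); it is the
    denominator of the RSRZ-outlier fraction downstream.  ``rscc_values``
    preserves residue order.
    """

    n_residues: int
    n_rama: int
    n_rota: int
    n_bond_len: int
    n_bond_ang: int
    n_rsrz_gt2: int
    n_rsrz_eligible: int
    rscc_values: tuple[float, ...]


_OUTLIER_LITERAL = "OUTLIER"


def _parse_float(element, attr: str) -> float | None:
    raw = element.get(attr)
    if raw is None or raw == "":
        return None
    return float(raw)


def _parse_class(element, attr: str) -> bool | None:
    raw = element.get(attr)
    if raw is None or raw == "":
        return None
    return raw.strip().upper() == _OUTLIER_LITERAL


def parse_validation_xml(file: str | Path) -> EntryValidation:
    """Parse one wwPDB-dialect validation report.

    Residue elements lacking chain/residue identifiers are collected into
    ``EntryValidation.errors`` and parsing continues; malformed XML raises
    :class:`ValidationParseError`.
    """
    path = Path(file)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValidationParseError(f"cannot parse validation XML {path}: {exc}") from exc
    root = tree.getroot()

    entry_el = root.find("Entry")
    entry_id = ""
    resolution = None
    if entry_el is not None:
        entry_id = entry_el.get("pdbid") or ""
        resolution = _parse_float(entry_el, "PDB-resolution")
    if not entry_id:
        entry_id = path.stem.split("_")[0]

    residues: list[ResidueValidation] = []
    errors: list[str] = []
    for el in root.iter("ModelledSubgroup"):
        chain = el.get("chain")
        resnum = el.get("resnum")
        if chain is None or resnum is None:
            errors.append(
                f"ModelledSubgroup at line {el.sourceline}: missing chain/resnum identifiers"
            )
            continue
        icode = (el.get("icode") or " ").strip() or " "
        try:
            residues.append(
                ResidueValidation(
                    chain_id=chain,
                    residue_number=int(resnum),
                    insertion_code=icode,
                    residue_name=el.get("resname") or "",
                    rscc=_parse_float(el, "rscc"),
                    rsrz=_parse_float(el, "rsrz"),
                    rama_outlier=_parse_class(el, "rama"),
                    rota_outlier=_parse_class(el, "rota"),
                    bond_length_outliers=len(el.findall("bond-outlier")),
                    bond_angle_outliers=len(el.findall("angle-outlier")),
                )
            )
        except ValueError as exc:
            errors.append(f"ModelledSubgroup at line {el.sourceline}: {exc}")
    if errors:
        logger.warning("%s: %d residue records skipped", path, len(errors))
    return EntryValidation(
        entry_id=entry_id, residues=residues, resolution=resolution, errors=errors
    )


def chain_outlier_counts(
    ev: EntryValidation,
    chain_id: str,
    residue_ids: set[tuple[int, str]] | None = None,
) -> ChainOutlierCounts:
    """Aggregate one chain's outlier counts.

    ``residue_ids`` optionally restricts the aggregation to a subset of
    residues (the alignment-accepted peptide residues); by default all
    residues reported for the chain are counted.  RSRZ outliers use the
    strict inequality RSRZ > 2, and only residues with a reported RSRZ
    enter either side of that fraction.
    """
    residues = ev.chain_residues(chain_id)
    if residue_ids is not None:
        residues = [r for r in residues if r.residue_id in residue_ids]
    n_rsrz_eligible = sum(1 for r in residues if r.rsrz is not None)
    return ChainOutlierCounts(
        n_residues=len(residues),
        n_rama=sum(1 for r in residues if r.rama_outlier is True),
        n_rota=sum(1 for r in residues if r.rota_outlier is True),
        n_bond_len=sum(r.bond_length_outliers for r in residues),
        n_bond_ang=sum(r.bond_angle_outliers for r in residues),
        n_rsrz_gt2=sum(1 for r in residues if r.rsrz is not None and r.rsrz > 2),
        n_rsrz_eligible=n_rsrz_eligible,
        rscc_values=tuple(r.rscc for r in residues if r.rscc is not None),
    )
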