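"""Coordinate-file parsing and peptide-ligand chain detection.

Reads PDB or mmCIF coordinate files into a lightweight in-memory model
(:class:`EntryModel`) and applies the screening definition of a
*peptide-ligand chain*: a protein chain with fewer than ``max_residues``
residues (default 50) that is also shorter than ``max_fraction_of_longest``
(default 1/5) of the longest protein chain of the multimer.  Entries must
contain at least two protein chains and, by default, no nucleic-acid chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import gemmi

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueAtoms",
    "ChainModel",
    "EntryModel",
    "PeptideLigandCriteria",
    "StructureParseError",
    "parse_structure",
    "detect_peptide_ligand_chains",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be read or interpreted."""


_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the deposited model.

    ``occupancy`` is the fraction of unit cells in which the atom occupies
    its site; ``b_factor`` (Å²) is the isotropic atomic displacement
    parameter.  Both enter the occupancy-weighted B-factor averages used by
    the environment-contrast score.
    """

    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    @property
    def residue_id(self) -> tuple[int, str]:
        return (self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class ResidueAtoms:
    """A residue actually present in the coordinates, with its atoms."""

    residue_id: tuple[int, str]
    residue_name: str
    atoms: tuple[AtomRecord, ...]


@dataclass
class ChainModel:
    """One deposited chain: canonical sequence plus modelled residues.

    ``seqres_tokens`` is the canonical full sequence (SEQRES or the mmCIF
    entity sequence) and may be empty for depositions lacking it;
    ``atom_residues`` lists only residues with coordinate records, ordered
    by residue number and insertion code.
    """

    chain_id: str
    seqres_tokens: list[str]
    atom_residues: list[ResidueAtoms]
    polymer_class: str  # protein | dna | rna | other

    @property
    def seqres_length(self) -> int:
        return len(self.seqres_tokens)

    @property
    def modeled_length(self) -> int:
        return len(self.atom_residues)

    @property
    def length(self) -> int:
        """Chain length used by the detection rules.

        The canonical (SEQRES) length when available, since that is the
        chain as deposited; the modelled residue count otherwise.
        """
        return self.seqres_length if self.seqres_tokens else self.modeled_length

    def atoms(self) -> list[AtomRecord]:
        return [a for res in self.atom_residues for a in res.atoms]


@dataclass
class EntryModel:
    """A parsed coordinate entry (one PDB/mmCIF file, first model)."""

    entry_id: str
    chains: list[ChainModel]
    experiment: str = ""

    def __post_init__(self) -> None:
        self.entry_id = self.entry_id.lower()

    def chain(self, chain_id: str) -> ChainModel:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"chain {chain_id!r} not present in entry {self.entry_id!r}")


@dataclass
class PeptideLigandCriteria:
    """Detection thresholds for peptide-ligand chains.

    A candidate must have strictly fewer than ``max_residues`` residues and
    be strictly shorter than ``max_fraction_of_longest`` times the longest
    protein chain.  Each entry-level condition can be switched off
    independently for testing.
    """

    max_residues: int = 50
    max_fraction_of_longest: Fraction = field(default_factory=lambda: Fraction(1, 5))
    require_min_chains: int = 2
    forbid_nucleic: bool = True

    def __post_init__(self) -> None:
        if self.max_residues <= 0:
            raise ValueError("max_residues must be positive")
        frac = Fraction(self.max_fraction_of_longest)
        if not 0 < frac < 1:
            raise ValueError("max_fraction_of_longest must lie in (0, 1)")
        self.max_fraction_of_longest = frac


def _classify_residue(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return "other"
    if info.is_amino_acid():
        return "protein"
    if info.is_nucleic_acid():
        # distinguish DNA from RNA by the tabulated one-letter convention:
        # deoxy residues are DA/DC/DG/DT/DU plus known modified codes
        return "dna" if name.upper().startswith("D") and len(name) <= 2 else "rna"
    return "other"


def _classify_chain(residue_names: list[str]) -> str:
    """Majority vote over the residue-name vocabulary.

    A chain is protein (or nucleic) if more than half of its residues carry
    amino-acid (or nucleotide) codes; waters and small heterogens on the
    same chain ID do not flip the call.
    """
    if not residue_names:
        return "other"
    tallies = {"protein": 0, "dna": 0, "rna": 0, "other": 0}
    for name in residue_names:
        tallies[_classify_residue(name)] += 1
    n = len(residue_names)
    for cls in ("protein", "dna", "rna"):
        if tallies[cls] * 2 > n:
            return cls
    return "other"


def _dedupe_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per atom name: the highest-occupancy alternative."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of first appearance
    seen: list[gemmi.Atom] = []
    names_done = set()
    for atom in residue:
        if atom.name not in names_done:
            seen.append(best[atom.name])
            names_done.add(atom.name)
    return seen


def _sequence_tokens(entity: gemmi.Entity | None) -> list[str]:
    if entity is None:
        return []
    return [gemmi.Entity.first_mon(item) for item in entity.full_sequence]


def parse_structure(file: str | Path, dialect: str | None = None) -> EntryModel:
    """Parse a PDB or mmCIF coordinate file into an :class:`EntryModel`.

    Parameters
    ----------
    file:
        Path to the coordinate file.
    dialect:
        ``"pdb"`` or ``"mmcif"``; inferred from the file extension when
        omitted.

    Only the first model of multi-model files is used.  Alternate-location
    atoms are reduced to the highest-occupancy alternative per atom name.
    """
    path = Path(file)
    if not path.exists():
        raise StructureParseError(f"coordinate file not found: {path}")
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    if dialect not in {"pdb", "mmcif"}:
        raise StructureParseError(f"unknown coordinate dialect {dialect!r}")
    try:
        fmt = gemmi.CoorFormat.Pdb if dialect == "pdb" else gemmi.CoorFormat.Mmcif
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path} as {dialect}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models in file")
    st.setup_entities()

    model = st[0]
    chains: list[ChainModel] = []
    for chain in model:
        residues: list[ResidueAtoms] = []
        for residue in chain:
            atoms = tuple(
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    x=a.pos.x,
                    y=a.pos.y,
                    z=a.pos.z,
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or " ").strip() or " ",
                    residue_name=residue.name,
                )
                for a in _dedupe_altlocs(residue)
            )
            residues.append(
                ResidueAtoms(
                    residue_id=(residue.seqid.num, (residue.seqid.icode or " ").strip() or " "),
                    residue_name=residue.name,
                    atoms=atoms,
                )
            )
        residues.sort(key=lambda r: (r.residue_id[0], r.residue_id[1]))

        polymer = chain.get_polymer()
        entity = st.get_entity_of(polymer) if polymer else None
        seqres = _sequence_tokens(entity)
        chains.append(
            ChainModel(
                chain_id=chain.name,
                seqres_tokens=seqres,
                atom_residues=residues,
                polymer_class=_classify_chain([r.residue_name for r in residues]),
            )
        )
    if not chains:
        raise StructureParseError(f"{path}: no chains in first model")

    entry_id = (st.name or path.stem).strip().lower() or path.stem.lower()
    try:
        experiment = st.info["_exptl.method"]
    except KeyError:
        experiment = ""
    return EntryModel(entry_id=entry_id, chains=chains, experiment=experiment)


def detect_peptide_ligand_chains(
    entry: EntryModel, criteria: PeptideLigandCriteria | None = None
) -> list[str]:
    """Return the chain IDs qualifying as peptide-ligand chains.

    A chain qualifies when it is a protein chain with strictly fewer than
    ``criteria.max_residues`` residues and a length strictly below
    ``criteria.max_fraction_of_longest`` of the longest protein chain.
    Entries with fewer than ``require_min_chains`` protein chains, or (when
    ``forbid_nucleic``) with any DNA/RNA chain, yield an empty list.
    """
    criteria = criteria or PeptideLigandCriteria()
    protein_chains = [ch for ch in entry.chains if ch.polymer_class == "protein"]
    if len(protein_chains) < criteria.require_min_chains:
        return []
    if criteria.forbid_nucleic and any(
        ch.polymer_class in {"dna", "rna"} for ch in entry.chains
    ):
        return []
    longest = max(ch.length for ch in protein_chains)
    hits = []
    for ch in protein_chains:
        if ch.length < criteria.max_residues and ch.length < criteria.max_fraction_of_longest * longest:
            hits.append(ch.chain_id)
    return hits
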