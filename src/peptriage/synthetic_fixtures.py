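"""Synthetic multi-chain entries with planted, known pathologies.

The generator produces matched coordinate models and validation facts for
protein–peptide complexes: one long target chain plus one or more short
peptide-ligand chains placed within contact distance of the target, so the
6 Å B-factor neighbourhood is never empty.  Pathologies are planted per
peptide chain with known ground truth:

* ``b_inflation`` — additive Å² offset on the peptide's atomic B factors,
  emulating a density-unsupported peptide refined to high displacement;
* ``rscc_shift`` — downward shift of the per-residue RSCC draws;
* ``rama_rate`` / ``rota_rate`` — per-residue Bernoulli rates of
  Ramachandran and rotamer outliers;
* ``bond_outlier_rate`` — per-residue rate of planting one bond-length and
  one bond-angle >5σ deviation;
* ``rsrz_rate`` — per-residue rate of RSRZ > 2 outliers;
* ``missing_terminal`` — N-terminal residues present in the canonical
  sequence but absent from the coordinates.

Geometric realism is limited to what the pipeline measures — distances,
occupancies, B factors.  Chains are persistent random walks with ~3.8 Å
consecutive Cα spacing and lightweight backbone atoms; no physically valid
stereochemistry is attempted, because torsion outliers are read from the
validation facts, never recomputed from coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from lxml import etree
from scipy.stats import truncnorm

from .structure_io import AtomRecord, ChainModel, EntryModel, ResidueAtoms
from .validation_xml import EntryValidation, ResidueValidation

__all__ = [
    "PeptidePathology",
    "FixtureSpec",
    "GeneratedChain",
    "GeneratedEntry",
    "generate_entry",
    "generate_cohort",
    "generate_rscc_population",
    "rscc_mixture_moments",
    "write_entry_files",
    "write_validation_xml",
]

AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

#: default two-component RSCC mixture: a well-fit component concentrated
#: near 0.93 and a broad poor-fit tail, both truncated to [-1, 1]
RSCC_MIXTURE = {
    "w_good": 0.9,
    "good_loc": 0.93,
    "good_scale": 0.04,
    "tail_loc": 0.55,
    "tail_scale": 0.15,
}


@dataclass(frozen=True)
class PeptidePathology:
    """Planted per-chain pathology rates and offsets (all default clean)."""

    b_inflation: float = 0.0
    rscc_shift: float = 0.0
    rama_rate: float = 0.0
    rota_rate: float = 0.0
    bond_outlier_rate: float = 0.0
    rsrz_rate: float = 0.0
    missing_terminal: int = 0

    def __post_init__(self) -> None:
        for name in ("rama_rate", "rota_rate", "bond_outlier_rate", "rsrz_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        if self.missing_terminal < 0:
            raise ValueError("missing_terminal must be >= 0")

    @property
    def is_clean(self) -> bool:
        return self == PeptidePathology()


@dataclass
class FixtureSpec:
    """Cohort-level generation parameters.

    ``target_length_range`` and ``peptide_length_range`` bound the drawn
    chain lengths; a peptide's length is additionally capped below one
    fifth of its target's length so every generated peptide satisfies the
    detection rules.
    """

    n_entries: int = 10
    peptides_per_entry: tuple[int, int] = (1, 2)
    target_length_range: tuple[int, int] = (150, 300)
    peptide_length_range: tuple[int, int] = (5, 49)
    base_b: float = 40.0
    b_sigma: float = 3.0
    pathologies: dict[tuple[int, int], PeptidePathology] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peptide_length_range
        if not 1 <= lo <= hi <= 49:
            raise ValueError("peptide lengths must lie within [1, 49]")


@dataclass
class GeneratedChain:
    """Ground truth for one generated chain."""

    chain_id: str
    is_peptide: bool
    length: int  # canonical (SEQRES) length
    pathology: PeptidePathology | None
    rscc_values: list[float] = field(default_factory=list)
    rsrz_values: list[float] = field(default_factory=list)
    n_rama: int = 0
    n_rota: int = 0
    n_bond_len: int = 0
    n_bond_ang: int = 0
    n_rsrz_gt2: int = 0
    mean_b: float = 0.0


@dataclass
class GeneratedEntry:
    """One synthetic entry: parsed models plus complete ground truth."""

    entry: EntryModel
    validation: EntryValidation
    chains: list[GeneratedChain]

    def peptide_truth(self) -> list[GeneratedChain]:
        return [c for c in self.chains if c.is_peptide]


def _walk(rng: np.random.Generator, n: int, start: np.ndarray, step: float = 3.8,
          persistence: float = 0.7) -> np.ndarray:
    """Persistent random walk: consecutive points ~``step`` Å apart."""
    pts = np.empty((n, 3))
    pts[0] = start
    direction = _unit(rng.normal(size=3))
    for i in range(1, n):
        direction = _unit(persistence * direction + rng.normal(scale=0.6, size=3))
        pts[i] = pts[i - 1] + step * direction
    return pts


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.8, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.3, 0.6, 0.3]),
    "O": np.array([1.6, 1.7, 0.5]),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _build_chain_atoms(
    chain_id: str,
    residue_names: list[str],
    ca_positions: np.ndarray,
    b_values: np.ndarray,
    first_residue_number: int = 1,
) -> list[ResidueAtoms]:
    residues = []
    for k, (name, ca, b) in enumerate(zip(residue_names, ca_positions, b_values)):
        resnum = first_residue_number + k
        atoms = tuple(
            AtomRecord(
                name=atom_name,
                element=_BACKBONE_ELEMENTS[atom_name],
                x=float(ca[0] + off[0]),
                y=float(ca[1] + off[1]),
                z=float(ca[2] + off[2]),
                occupancy=1.0,
                b_factor=float(b),
                chain_id=chain_id,
                residue_number=resnum,
                insertion_code=" ",
                residue_name=name,
            )
            for atom_name, off in _BACKBONE_OFFSETS.items()
        )
        residues.append(ResidueAtoms(residue_id=(resnum, " "), residue_name=name, atoms=atoms))
    return residues


def _draw_rscc(rng: np.random.Generator, n: int, shift: float = 0.0,
               mixture: dict | None = None) -> np.ndarray:
    mix = mixture or RSCC_MIXTURE
    good = _truncated_normal(rng, n, mix["good_loc"], mix["good_scale"])
    tail = _truncated_normal(rng, n, mix["tail_loc"], mix["tail_scale"])
    pick_good = rng.random(n) < mix["w_good"]
    values = np.where(pick_good, good, tail) - shift
    return np.clip(values, -1.0, 1.0)


def _truncated_normal(rng: np.random.Generator, n: int, loc: float, scale: float,
                      lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def generate_rscc_population(
    n: int, mixture: dict | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` RSCC values from the two-component mixture.

    Stands in for an archive-wide pool of per-residue RSCC values when
    building the empirical density f₁ at scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_rscc(rng, n, shift=0.0, mixture=mixture)


def rscc_mixture_moments(mixture: dict | None = None) -> tuple[float, float]:
    """Closed-form (mean, variance) of the truncated-normal mixture."""
    mix = mixture or RSCC_MIXTURE
    moments = []
    for loc, scale in ((mix["good_loc"], mix["good_scale"]),
                       (mix["tail_loc"], mix["tail_scale"])):
        a, b = (-1.0 - loc) / scale, (1.0 - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        moments.append((float(m), float(v)))
    w = mix["w_good"]
    (m1, v1), (m2, v2) = moments
    mean = w * m1 + (1 - w) * m2
    var = w * (v1 + m1**2) + (1 - w) * (v2 + m2**2) - mean**2
    return mean, var


def generate_entry(
    entry_id: str,
    target_length: int,
    peptide_lengths: list[int],
    pathologies: list[PeptidePathology],
    rng: np.random.Generator,
    base_b: float = 40.0,
    b_sigma: float = 3.0,
    n_chain_heterogens: int = 0,
) -> GeneratedEntry:
    """Generate one entry: a target chain plus peptide-ligand chains.

    Each peptide walk starts within ~4.5 Å of a randomly chosen target
    residue so the 6 Å neighbourhood is populated.  ``n_chain_heterogens``
    appends that many water/glycerol residues to each peptide chain's
    coordinate records (sharing its chain ID) to exercise the alignment
    filter.
    """
    if len(peptide_lengths) != len(pathologies):
        raise ValueError("one pathology per peptide chain required")
    for length in peptide_lengths:
        if not 1 <= length <= 49:
            raise ValueError(f"peptide length {length} outside [1, 49]")
        if length * 5 >= target_length:
            raise ValueError(
                f"peptide length {length} not under a fifth of target length {target_length}"
            )

    chain_ids = ["A"] + [chr(ord("B") + i) for i in range(len(peptide_lengths))]
    chains: list[ChainModel] = []
    truths: list[GeneratedChain] = []
    vres: list[ResidueValidation] = []

    # --- target chain ---
    target_names = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=target_length)]
    target_ca = _walk(rng, target_length, start=np.zeros(3))
    target_b = np.maximum(rng.normal(base_b, b_sigma, size=target_length), 1.0)
    target_residues = _build_chain_atoms("A", target_names, target_ca, target_b)
    chains.append(
        ChainModel(
            chain_id="A",
            seqres_tokens=list(target_names),
            atom_residues=target_residues,
            polymer_class="protein",
        )
    )
    target_rscc = _draw_rscc(rng, target_length)
    target_rsrz = rng.normal(0.0, 1.0, size=target_length)
    for res, rscc, rsrz in zip(target_residues, target_rscc, target_rsrz):
        vres.append(
            ResidueValidation(
                chain_id="A",
                residue_number=res.residue_id[0],
                residue_name=res.residue_name,
                rscc=round(float(rscc), 3),
                rsrz=round(float(rsrz), 2),
                rama_outlier=False,
                rota_outlier=False,
            )
        )
    truths.append(
        GeneratedChain(
            chain_id="A",
            is_peptide=False,
            length=target_length,
            pathology=None,
            rscc_values=[round(float(v), 3) for v in target_rscc],
            mean_b=float(target_b.mean()),
        )
    )

    # --- peptide-ligand chains ---
    for chain_id, length, pathology in zip(chain_ids[1:], peptide_lengths, pathologies):
        seqres = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
        n_missing = min(pathology.missing_terminal, length - 1)
        modeled_names = seqres[n_missing:]
        n_modeled = len(modeled_names)

        anchor = target_ca[rng.integers(0, target_length)]
        start = anchor + 4.5 * _unit(rng.normal(size=3))
        pep_ca = _walk(rng, n_modeled, start=start)
        pep_b = np.maximum(
            rng.normal(base_b + pathology.b_inflation, b_sigma, size=n_modeled), 1.0
        )
        residues = _build_chain_atoms(
            chain_id, modeled_names, pep_ca, pep_b, first_residue_number=n_missing + 1
        )
        if n_chain_heterogens:
            het_names = ["HOH", "GOL"] * ((n_chain_heterogens + 1) // 2)
            for k in range(n_chain_heterogens):
                resnum = n_missing + n_modeled + 10 + k
                pos = pep_ca[-1] + rng.normal(scale=8.0, size=3)
                atoms = (
                    AtomRecord(
                        name="O",
                        element="O",
                        x=float(pos[0]),
                        y=float(pos[1]),
                        z=float(pos[2]),
                        occupancy=1.0,
                        b_factor=float(base_b),
                        chain_id=chain_id,
                        residue_number=resnum,
                        insertion_code=" ",
                        residue_name=het_names[k],
                    ),
                )
                residues.append(
                    ResidueAtoms(residue_id=(resnum, " "), residue_name=het_names[k], atoms=atoms)
                )
        chains.append(
            ChainModel(
                chain_id=chain_id,
                seqres_tokens=seqres,
                atom_residues=residues,
                polymer_class="protein",
            )
        )

        rscc = _draw_rscc(rng, n_modeled, shift=pathology.rscc_shift)
        rama = rng.random(n_modeled) < pathology.rama_rate
        rota = rng.random(n_modeled) < pathology.rota_rate
        bond = rng.random(n_modeled) < pathology.bond_outlier_rate
        rsrz_out = rng.random(n_modeled) < pathology.rsrz_rate
        rsrz = np.where(
            rsrz_out,
            rng.normal(3.0, 0.5, size=n_modeled),
            rng.normal(0.0, 1.0, size=n_modeled),
        )
        truth = GeneratedChain(
            chain_id=chain_id,
            is_peptide=True,
            length=length,
            pathology=pathology,
            rscc_values=[round(float(v), 3) for v in rscc],
            rsrz_values=[round(float(v), 2) for v in rsrz],
            n_rama=int(rama.sum()),
            n_rota=int(rota.sum()),
            n_bond_len=int(bond.sum()),
            n_bond_ang=int(bond.sum()),
            n_rsrz_gt2=int(np.sum(np.round(rsrz, 2) > 2)),
            mean_b=float(pep_b.mean()),
        )
        truths.append(truth)
        for k in range(n_modeled):
            vres.append(
                ResidueValidation(
                    chain_id=chain_id,
                    residue_number=n_missing + 1 + k,
                    residue_name=modeled_names[k],
                    rscc=truth.rscc_values[k],
                    rsrz=truth.rsrz_values[k],
                    rama_outlier=bool(rama[k]),
                    rota_outlier=bool(rota[k]),
                    bond_length_outliers=int(bond[k]),
                    bond_angle_outliers=int(bond[k]),
                )
            )

    entry = EntryModel(entry_id=entry_id, chains=chains, experiment="X-RAY DIFFRACTION")
    validation = EntryValidation(entry_id=entry_id, residues=vres, resolution=1.8)
    return GeneratedEntry(entry=entry, validation=validation, chains=truths)


def generate_cohort(spec: FixtureSpec) -> list[GeneratedEntry]:
    """Generate ``spec.n_entries`` entries with a shared seeded RNG.

    ``spec.pathologies`` maps (entry index, peptide index) to a planted
    pathology; all other peptide chains are clean.
    """
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for i in range(spec.n_entries):
        n_pep = int(rng.integers(spec.peptides_per_entry[0], spec.peptides_per_entry[1] + 1))
        target_length = int(
            rng.integers(spec.target_length_range[0], spec.target_length_range[1] + 1)
        )
        lengths = []
        for _ in range(n_pep):
            cap = min(spec.peptide_length_range[1], (target_length - 1) // 5)
            lo = min(spec.peptide_length_range[0], cap)
            lengths.append(int(rng.integers(lo, cap + 1)))
        pathologies = [
            spec.pathologies.get((i, j), PeptidePathology()) for j in range(n_pep)
        ]
        cohort.append(
            generate_entry(
                entry_id=f"s{i:03d}",
                target_length=target_length,
                peptide_lengths=lengths,
                pathologies=pathologies,
                rng=rng,
                base_b=spec.base_b,
                b_sigma=spec.b_sigma,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# file writers (PDB / mmCIF / validation XML / ground-truth TSV)
# ---------------------------------------------------------------------------


def _entry_to_gemmi(entry: EntryModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = entry.entry_id
    model = gemmi.Model("1")
    for chain in entry.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.atom_residues:
            gres = gemmi.Residue()
            gres.name = res.residue_name
            gres.seqid = gemmi.SeqId(res.residue_id[0], res.residue_id[1])
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    for chain in entry.chains:
        if not chain.seqres_tokens:
            continue
        polymer = st[0][chain.chain_id].get_polymer()
        entity = st.get_entity_of(polymer)
        if entity is not None:
            entity.full_sequence = list(chain.seqres_tokens)
    return st


def write_validation_xml(validation: EntryValidation, path: str | Path) -> None:
    """Write validation facts in the wwPDB report dialect the parser reads."""
    root = etree.Element("wwPDB-validation-information")
    entry_el = etree.SubElement(root, "Entry")
    entry_el.set("pdbid", validation.entry_id)
    if validation.resolution is not None:
        entry_el.set("PDB-resolution", str(validation.resolution))
    for res in validation.residues:
        el = etree.SubElement(root, "ModelledSubgroup")
        el.set("model", "1")
        el.set("chain", res.chain_id)
        el.set("resnum", str(res.residue_number))
        el.set("icode", res.insertion_code)
        el.set("resname", res.residue_name)
        if res.rscc is not None:
            el.set("rscc", repr(res.rscc))
        if res.rsrz is not None:
            el.set("rsrz", repr(res.rsrz))
        if res.rama_outlier is not None:
            el.set("rama", "OUTLIER" if res.rama_outlier else "Favored")
        if res.rota_outlier is not None:
            el.set("rota", "OUTLIER" if res.rota_outlier else "m-80")
        for _ in range(res.bond_length_outliers):
            bond = etree.SubElement(el, "bond-outlier")
            bond.set("atom0", "N")
            bond.set("atom1", "CA")
            bond.set("z", "6.0")
        for _ in range(res.bond_angle_outliers):
            angle = etree.SubElement(el, "angle-outlier")
            angle.set("atom0", "N")
            angle.set("atom1", "CA")
            angle.set("atom2", "C")
            angle.set("z", "6.0")
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def write_entry_files(generated: GeneratedEntry, out_dir: str | Path) -> dict[str, Path]:
    """Write PDB, mmCIF, validation XML and ground-truth TSV for one entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = generated.entry.entry_id
    st = _entry_to_gemmi(generated.entry)
    paths = {
        "pdb": out_dir / f"{stem}.pdb",
        "mmcif": out_dir / f"{stem}.cif",
        "xml": out_dir / f"{stem}.xml",
        "truth": out_dir / f"{stem}_truth.tsv",
    }
    st.write_pdb(str(paths["pdb"]))
    st.make_mmcif_document().write_file(str(paths["mmcif"]))
    write_validation_xml(generated.validation, paths["xml"])
    with open(paths["truth"], "w") as fh:
        fh.write(
            "chain_id\tis_peptide\tlength\tn_rama\tn_rota\tn_bond_len\t"
            "n_bond_ang\tn_rsrz_gt2\tmean_b\tb_inflation\trscc_shift\n"
        )
        for c in generated.chains:
            p = c.pathology or PeptidePathology()
            fh.write(
                f"{c.chain_id}\t{int(c.is_peptide)}\t{c.length}\t{c.n_rama}\t"
                f"{c.n_rota}\t{c.n_bond_len}\t{c.n_bond_ang}\t{c.n_rsrz_gt2}\t"
                f"{c.mean_b:.3f}\t{p.b_inflation}\t{p.rscc_shift}\n"
            )
    return paths
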