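import numpy as np
import pytest

from peptriage.structure_io import AtomRecord, ChainModel, EntryModel, ResidueAtoms


def make_atom(
    x=0.0,
    y=0.0,
    z=0.0,
    b=30.0,
    occ=1.0,
    element="C",
    chain_id="A",
    residue_number=1,
    name="CA",
    residue_name="ALA",
):
    return AtomRecord(
        name=name,
        element=element,
        x=x,
        y=y,
        z=z,
        occupancy=occ,
        b_factor=b,
        chain_id=chain_id,
        residue_number=residue_number,
        insertion_code=" ",
        residue_name=residue_name,
    )


def make_chain(chain_id, atoms, seqres=None, polymer_class="protein"):
    """Group a flat atom list into one residue per residue_number."""
    residues = {}
    for a in atoms:
        residues.setdefault((a.residue_number, " "), []).append(a)
    atom_residues = [
        ResidueAtoms(residue_id=rid, residue_name=group[0].residue_name, atoms=tuple(group))
        for rid, group in sorted(residues.items())
    ]
    return ChainModel(
        chain_id=chain_id,
        seqres_tokens=list(seqres or []),
        atom_residues=atom_residues,
        polymer_class=polymer_class,
    )


def length_only_chain(chain_id, n, polymer_class="protein"):
    """A chain whose only relevant property is its canonical length."""
    return ChainModel(
        chain_id=chain_id,
        seqres_tokens=["ALA"] * n,
        atom_residues=[],
        polymer_class=polymer_class,
    )


def make_entry(chains, entry_id="test"):
    return EntryModel(entry_id=entry_id, chains=chains)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
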