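"""B-factor contrast between a peptide-ligand chain and its surroundings.

A peptide modelled into absent or weak electron density is typically
"refined away": the refinement program inflates the atomic displacement
parameters (B factors) of the offending atoms to damp their scattering
contribution.  The resulting signature is a chain whose occupancy-weighted
mean B factor sits well above that of the spatially neighbouring atoms
(within 6 Å) that belong to other chains.  The difference of the two means
is converted to a percentile against the cohort of all scored chains.

Distances are computed in the deposited asymmetric unit only; no
crystallographic symmetry mates are generated (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, EntryModel

__all__ = [
    "BFactorDifference",
    "occupancy_weighted_mean_b",
    "neighbourhood_atoms",
    "bfactor_difference",
    "empirical_percentile",
]


@dataclass
class BFactorDifference:
    """Chain-vs-environment occupancy-weighted B-factor contrast (Å²)."""

    chain_mean_b: float | None
    env_mean_b: float | None
    n_chain_atoms: int
    n_env_atoms: int
    percentile: float | None = None

    @property
    def diff(self) -> float | None:
        if self.chain_mean_b is None or self.env_mean_b is None:
            return None
        return self.chain_mean_b - self.env_mean_b


def _qualifying(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Non-hydrogen atoms with positive occupancy."""
    return [a for a in atoms if not a.is_hydrogen and a.occupancy > 0]


def occupancy_weighted_mean_b(atoms: list[AtomRecord]) -> float | None:
    """Occupancy-weighted mean B factor over non-hydrogen atoms.

    Returns ``Σ occ·B / Σ occ``, or ``None`` when no non-hydrogen atom with
    positive occupancy is present (the missing value propagates to median
    imputation downstream).
    """
    selected = _qualifying(atoms)
    if not selected:
        return None
    weights = np.array([a.occupancy for a in selected])
    bs = np.array([a.b_factor for a in selected])
    return float(np.dot(weights, bs) / weights.sum())


def neighbourhood_atoms(
    entry: EntryModel, chain_id: str, radius: float = 6.0
) -> list[AtomRecord]:
    """Non-hydrogen atoms of other chains within ``radius`` Å of the chain.

    An atom qualifies when its distance to *any* non-hydrogen atom of
    ``chain_id`` is at most ``radius`` (inclusive boundary).  Waters and
    heterogens on other chain IDs are part of the environment.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    chain = entry.chain(chain_id)
    chain_atoms = [a for a in chain.atoms() if not a.is_hydrogen]
    if not chain_atoms:
        return []
    other_atoms = [
        a
        for ch in entry.chains
        if ch.chain_id != chain_id
        for a in ch.atoms()
        if not a.is_hydrogen
    ]
    if not other_atoms:
        return []
    tree = cKDTree(np.array([[a.x, a.y, a.z] for a in chain_atoms]))
    coords = np.array([[a.x, a.y, a.z] for a in other_atoms])
    dmin, _ = tree.query(coords, k=1)
    return [a for a, d in zip(other_atoms, dmin) if d <= radius]


def bfactor_difference(
    entry: EntryModel, chain_id: str, radius: float = 6.0
) -> BFactorDifference:
    """Occupancy-weighted B-factor difference chain minus 6 Å environment.

    Positive values mean the chain is "hotter" than its surroundings, the
    hallmark of a density-unsupported peptide.  An empty neighbourhood
    yields a missing difference.
    """
    chain = entry.chain(chain_id)
    env = neighbourhood_atoms(entry, chain_id, radius)
    chain_mean = occupancy_weighted_mean_b(chain.atoms())
    env_mean = occupancy_weighted_mean_b(env)
    return BFactorDifference(
        chain_mean_b=chain_mean,
        env_mean_b=env_mean,
        n_chain_atoms=len(_qualifying(chain.atoms())),
        n_env_atoms=len(_qualifying(env)),
    )


def empirical_percentile(value: float, cohort: list[float] | np.ndarray) -> float:
    """Midrank empirical percentile of ``value`` within ``cohort``.

    ``100 · (#{x < value} + 0.5·#{x = value}) / N``; ties get the average
    of the ranks they span, so a cohort evaluated on itself is uniform on
    (0, 100) up to ties.
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.size == 0:
        raise ValueError("empirical_percentile requires a non-empty cohort")
    below = np.count_nonzero(cohort < value)
    equal = np.count_nonzero(cohort == value)
    return 100.0 * (below + 0.5 * equal) / cohort.size
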