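"""Local alignment of residue-token sequences over arbitrary alphabets.

The canonical (SEQRES) sequence of a deposited chain lists every residue of
the covalently bonded peptide, including residues never modelled in
coordinates; conversely the ATOM/HETATM records of the same chain ID often
carry waters, buffer molecules or ions.  Locally aligning the two token
sequences identifies the residues that are both part of the canonical
peptide and actually present in three dimensions — only those enter
scoring.

Tokens are opaque strings (three-letter or longer residue codes) compared
for exact equality, so modified residues such as MSE are distinct symbols
that can still align through surrounding context via the mismatch score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .structure_io import ChainModel

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentResult",
    "AlignmentFailedError",
    "local_align",
    "map_modeled_residues",
    "AMINO_VOCAB_FALLBACK",
]

GAP = None  # sentinel used in alignment pairs


class AlignmentFailedError(RuntimeError):
    """Raised when no aligned residue pair can be produced for a chain."""


@dataclass(frozen=True)
class AlignmentResult:
    """Best-scoring local alignment between two token sequences.

    ``pairs`` holds ``(index_a, index_b)`` tuples where either side may be
    ``None`` for a gap; indices are strictly increasing along each
    sequence.
    """

    pairs: tuple[tuple[int | None, int | None], ...]
    score: float
    aligned_span: tuple[int, int] | None  # first/last b index aligned

    def b_indices(self) -> list[int]:
        return [j for _, j in self.pairs if j is not None]

    def a_indices(self) -> list[int]:
        return [i for i, _ in self.pairs if i is not None]


def _rescore(
    pairs: Sequence[tuple[int | None, int | None]],
    a: Sequence[str],
    b: Sequence[str],
    match: float,
    mismatch: float,
    gap: float,
) -> float:
    total = 0.0
    for i, j in pairs:
        if i is None or j is None:
            total += gap
        elif a[i] == b[j]:
            total += match
        else:
            total += mismatch
    return total


def local_align(
    a: Sequence[str],
    b: Sequence[str],
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Smith–Waterman best local alignment of token sequences ``a`` and ``b``.

    Linear gap penalty.  Ties between equally scoring alignments are broken
    deterministically: smallest ending ``b`` index, then smallest ending
    ``a`` index, with a traceback preference of diagonal over a-gap over
    b-gap (which favours fewer gaps among diagonal-heavy optima).

    An all-mismatch input yields an empty alignment with score 0.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("local_align requires two non-empty sequences")
    m, n = len(a), len(b)
    # H[i][j] = best local alignment score ending at a[i-1], b[j-1]
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best_score = 0.0
    best_cell = (0, 0)
    for i in range(1, m + 1):
        row = H[i]
        prev = H[i - 1]
        ai = a[i - 1]
        for j in range(1, n + 1):
            sub = match if ai == b[j - 1] else mismatch
            score = max(0.0, prev[j - 1] + sub, prev[j] + gap, row[j - 1] + gap)
            row[j] = score
            # tie-break: iterate i ascending, j ascending; strict > keeps
            # the smallest (j, i) among maxima reachable in this order --
            # prefer smaller j first
            if score > best_score or (
                score == best_score
                and best_score > 0
                and (j, i) < (best_cell[1], best_cell[0])
            ):
                best_score = score
                best_cell = (i, j)
    if best_score <= 0:
        return AlignmentResult(pairs=(), score=0.0, aligned_span=None)

    pairs: list[tuple[int | None, int | None]] = []
    i, j = best_cell
    while i > 0 and j > 0 and H[i][j] > 0:
        sub = match if a[i - 1] == b[j - 1] else mismatch
        if abs(H[i][j] - (H[i - 1][j - 1] + sub)) < 1e-9:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif abs(H[i][j] - (H[i - 1][j] + gap)) < 1e-9:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    b_idx = [jj for _, jj in pairs if jj is not None]
    result = AlignmentResult(
        pairs=tuple(pairs),
        score=best_score,
        aligned_span=(b_idx[0], b_idx[-1]) if b_idx else None,
    )
    assert abs(result.score - _rescore(result.pairs, a, b, match, mismatch, gap)) < 1e-9
    return result


#: residue tokens accepted by the no-SEQRES fallback (standard amino acids
#: plus the most common modified residues)
AMINO_VOCAB_FALLBACK = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE SEC PYL SEP TPO PTR CSO HYP KCX LLP MLY M3L CME OCS
    UNK""".split()
)


def map_modeled_residues(
    chain: ChainModel,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[tuple[int, str]]:
    """Residue IDs of a chain accepted as genuine peptide residues.

    Aligns the chain's SEQRES tokens against the residue names implied by
    its coordinate records and returns the residue IDs participating in the
    alignment, in chain order.  Waters and buffer molecules sharing the
    chain ID fall outside the aligned region and are excluded.  Chains
    without SEQRES fall back to an amino-acid-vocabulary filter on the
    modelled residues.

    Raises :class:`AlignmentFailedError` when no residue pair aligns; such
    chains are excluded from scoring.
    """
    if not chain.atom_residues:
        raise AlignmentFailedError(f"chain {chain.chain_id!r} has no modelled residues")
    if not chain.seqres_tokens:
        logger.info(
            "chain %s has no SEQRES; falling back to amino-acid vocabulary filter",
            chain.chain_id,
        )
        return [
            (res.residue_id[0], res.residue_id[1])
            for res in chain.atom_residues
            if res.residue_name.upper() in AMINO_VOCAB_FALLBACK
        ]
    atom_tokens = [res.residue_name for res in chain.atom_residues]
    result = local_align(chain.seqres_tokens, atom_tokens, match, mismatch, gap)
    if not result.pairs:
        raise AlignmentFailedError(
            f"chain {chain.chain_id!r}: no aligned residue pair between SEQRES and coordinates"
        )
    return [chain.atom_residues[j].residue_id for j in result.b_indices()]
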