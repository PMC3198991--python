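"""Pairwise global alignment and reference-anchored position mapping.

The anchoring idea: align any rhodopsin homolog globally against a fixed
reference (H. salinarum bacteriorhodopsin by default) and read functional
residues off the query at reference-numbered positions.  Reference numbering
follows the precursor convention (mature sequence index + ``numbering_offset``,
+13 by default), so the Schiff-base proton acceptor and donor are positions
98 and 109.

Alignment is Needleman-Wunsch with affine gaps (Gotoh), delegated to
Biopython's :class:`Bio.Align.PairwiseAligner`; a gap of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GAP, ProteinRecord

UNALIGNED = "unaligned"


class AlignError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters for global protein alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise AlignError("require gap_open <= gap_extend < 0")


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    aligner.mode = "global"
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored global alignment as two equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignError("aligned rows differ in length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == GAP and cb == GAP:
                raise AlignError("column with gaps in both rows")


def global_align(
    a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme = ScoringScheme()
) -> PairwiseAlignment:
    """Optimal global alignment of two proteins under ``scheme``.

    The traceback is deterministic for fixed inputs (the aligner's first
    reported optimum).
    """
    result = _aligner(scheme).align(a.residues, b.residues)
    best = result[0]
    return PairwiseAlignment(
        aligned_a=str(best[0]), aligned_b=str(best[1]), score=float(best.score)
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identical columns / residue-residue columns.

    Gap columns (terminal and internal) are excluded from the denominator;
    this is the most common convention for "percent amino acid identity".
    """
    both = ident = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != GAP and cb != GAP:
            both += 1
            if ca == cb:
                ident += 1
    if both == 0:
        raise AlignError("alignment has no residue-residue columns")
    return 100.0 * ident / both


@dataclass(frozen=True)
class PositionMap:
    """Mapping from reference numbering to 1-based query positions.

    ``mapping[p]`` is the query position aligned to reference position ``p``
    (reference numbering = reference sequence index + offset), or absent when
    the query has a gap in that column.
    """

    reference_id: str
    query_id: str
    offset: int
    mapping: dict[int, int] = field(repr=False)

    def __post_init__(self) -> None:
        items = sorted(self.mapping.items())
        qpos = [q for _, q in items]
        if any(q2 <= q1 for q1, q2 in zip(qpos, qpos[1:])):
            raise AlignError("position map is not strictly increasing")

    @property
    def reference_positions(self) -> list[int]:
        return sorted(self.mapping)


def map_positions(
    query: ProteinRecord,
    reference: ProteinRecord,
    numbering_offset: int = 13,
    scheme: ScoringScheme = ScoringScheme(),
) -> PositionMap:
    """Build the reference-numbering -> query-position map via global alignment."""
    aln = global_align(reference, query, scheme)
    mapping: dict[int, int] = {}
    rpos = qpos = 0
    for cr, cq in zip(aln.aligned_a, aln.aligned_b):
        if cr != GAP:
            rpos += 1
        if cq != GAP:
            qpos += 1
        if cr != GAP and cq != GAP:
            mapping[rpos + numbering_offset] = qpos
    return PositionMap(
        reference_id=reference.id,
        query_id=query.id,
        offset=numbering_offset,
        mapping=mapping,
    )


def residue_at(pmap: PositionMap, query: ProteinRecord, ref_pos: int) -> str:
    """Query residue aligned to ``ref_pos``, or the ``"unaligned"`` sentinel.

    Never raises for an unmapped position.
    """
    q = pmap.mapping.get(ref_pos)
    if q is None:
        return UNALIGNED
    return query.residues[q - 1]


def aligned_fraction(pmap: PositionMap, reference: ProteinRecord) -> float:
    """Fraction of reference positions covered by the query."""
    return len(pmap.mapping) / len(reference)


def reference_anchored_alignment(
    records: list[ProteinRecord],
    reference: ProteinRecord,
    numbering_offset: int = 13,
    scheme: ScoringScheme = ScoringScheme(),
):
    """Pseudo-multiple-alignment with one column per reference position.

    Every query is aligned pairwise to the reference; column ``p`` of the
    result holds the query residue mapped to reference position ``p`` (or a
    gap).  Insertions relative to the reference are dropped, so this is a
    projection, not a true MSA -- adequate for distance-based trees of
    reference-anchorable homologs.
    """
    from .seqio import AlignedSet

    rows = []
    for rec in records:
        pmap = map_positions(rec, reference, numbering_offset, scheme)
        row = "".join(
            rec.residues[pmap.mapping[p + numbering_offset + 1] - 1]
            if (p + numbering_offset + 1) in pmap.mapping
            else GAP
            for p in range(len(reference))
        )
        rows.append((rec.id, row))
    return AlignedSet(records=tuple(rows))
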