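"""Pairwise alignment and reciprocal-best-hit homology detection.

Local alignment with affine gaps stands in for BLASTP; hits are filtered at
the thresholds used for orthologue detection (E-value < 1e-10, score > 200,
positives > 70%) and, more stringently, for within-genome paralogue
detection (E-value < 1e-50, score > 200, positives > 80%).  E-values come
from the Karlin-Altschul formula E = K*m*n*exp(-lambda*score) with fixed
gapped-BLOSUM62 constants; any monotone surrogate preserves the threshold
semantics and the constants are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import SequenceRecord

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "HomologyThresholds",
    "ORTHOLOG_THRESHOLDS",
    "PARALOG_THRESHOLDS",
    "smith_waterman",
    "global_alignment",
    "karlin_altschul_evalue",
    "reciprocal_best_hits",
    "find_paralogs",
]


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend`` (both negative).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    # Karlin-Altschul surrogate constants (gapped BLOSUM62)
    ka_K: float = 0.041
    ka_lambda: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        self.substitution = substitution_matrices.load(self.matrix_name)

    def aligner(self, mode: str = "local") -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = self.substitution
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        if mode == "global":
            # do not penalize terminal gaps (BLAST-like semi-global behaviour)
            aligner.end_gap_score = 0.0
        return aligner


def nucleotide_scheme() -> ScoringScheme:
    """NUC.4.4-based scheme for EST / cDNA evidence alignments."""
    return ScoringScheme(matrix_name="NUC.4.4", gap_open=-10.0, gap_extend=-1.0)


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    aligned_pairs: list[tuple[int | None, int | None]] = field(default_factory=list)
    identity_pct: float = 0.0
    positive_pct: float = 0.0
    aligned_length: int = 0
    evalue: float = math.inf

    def passes(self, thresholds: "HomologyThresholds") -> bool:
        return (
            self.evalue < thresholds.max_evalue
            and self.score > thresholds.min_score
            and self.positive_pct > thresholds.min_positive_pct
        )


@dataclass(frozen=True)
class HomologyThresholds:
    max_evalue: float
    min_score: float
    min_positive_pct: float

    def __post_init__(self) -> None:
        for v in (self.max_evalue, self.min_score, self.min_positive_pct):
            if not math.isfinite(v):
                raise ValueError("homology thresholds must be finite")


ORTHOLOG_THRESHOLDS = HomologyThresholds(1e-10, 200.0, 70.0)
PARALOG_THRESHOLDS = HomologyThresholds(1e-50, 200.0, 80.0)


def karlin_altschul_evalue(
    score: float, m: int, n: int, K: float = 0.041, lam: float = 0.267
) -> float:
    """E = K * m * n * exp(-lambda * score); monotone decreasing in score."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return K * m * n * math.exp(-lam * score)


def _empty_result(a: SequenceRecord, b: SequenceRecord) -> AlignmentResult:
    return AlignmentResult(a.id, b.id, 0.0)


def smith_waterman(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal local alignment of two sequences under affine gaps.

    Identity and positives are computed over aligned (non-gap) columns, the
    BLAST convention; a positive is an aligned pair with substitution score
    > 0.  Empty input yields a zero-score empty alignment.
    """
    scheme = scheme or ScoringScheme()
    if not a.residues or not b.residues:
        return _empty_result(a, b)
    aligner = scheme.aligner("local")
    if aligner.score(a.residues, b.residues) <= 0:
        return _empty_result(a, b)
    alignments = aligner.align(a.residues, b.residues)
    # the number of co-optimal alignments can be astronomically large; take
    # the aligner's first (deterministic) traceback without counting them
    aln = alignments[0]
    score = float(aln.score)
    pairs: list[tuple[int | None, int | None]] = []
    matches = positives = cols = 0
    blocks_a, blocks_b = aln.aligned
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            pairs.extend((i, None) for i in range(prev_a_end, a0))
            pairs.extend((None, j) for j in range(prev_b_end, b0))
        for i, j in zip(range(a0, a1), range(b0, b1)):
            ra, rb = a.residues[i], b.residues[j]
            pairs.append((i, j))
            cols += 1
            if ra == rb:
                matches += 1
            if float(scheme.substitution[ra, rb]) > 0:
                positives += 1
        prev_a_end, prev_b_end = a1, b1
    identity = 100.0 * matches / cols if cols else 0.0
    positive = 100.0 * positives / cols if cols else 0.0
    evalue = karlin_altschul_evalue(
        score, len(a.residues), len(b.residues), scheme.ka_K, scheme.ka_lambda
    )
    return AlignmentResult(
        a.id, b.id, score, pairs, identity, positive, cols, evalue
    )


def global_alignment(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> tuple[str, str]:
    """Gapped full-length rows of the optimal global alignment (used to
    thread codon alignments from protein pairs)."""
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner("global")
    aln = aligner.align(a.residues, b.residues)[0]
    return str(aln[0]), str(aln[1])


def _best_hits(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    exclude_self: bool = False,
) -> dict[str, tuple[str, AlignmentResult]]:
    """Best subject per query (highest score, ties to lexicographically
    smallest subject id)."""
    best: dict[str, tuple[str, AlignmentResult]] = {}
    for q in queries:
        top: tuple[float, str, AlignmentResult] | None = None
        for s in subjects:
            if exclude_self and s.id == q.id:
                continue
            aln = smith_waterman(q, s, scheme)
            if top is None or aln.score > top[0] or (aln.score == top[0] and s.id < top[1]):
                top = (aln.score, s.id, aln)
        if top is not None:
            best[q.id] = (top[1], top[2])
    return best


def reciprocal_best_hits(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    thresholds: HomologyThresholds = ORTHOLOG_THRESHOLDS,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two sequence sets.

    ``(a, b)`` is reported iff ``b`` is ``a``'s best hit in B, ``a`` is
    ``b``'s best hit in A, and their alignment passes all thresholds.
    The result is a partial matching (each id appears at most once).
    """
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    ids_a = {r.id for r in set_a}
    if ids_a & {r.id for r in set_b}:
        raise ValueError("sequence sets must have disjoint id spaces")
    scheme = scheme or ScoringScheme()
    fwd = _best_hits(set_a, set_b, scheme)
    rev = _best_hits(set_b, set_a, scheme)
    pairs = []
    for a_id, (b_id, aln) in sorted(fwd.items()):
        if rev.get(b_id, (None,))[0] == a_id and aln.passes(thresholds):
            pairs.append((a_id, b_id))
    return pairs


def find_paralogs(
    records: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    thresholds: HomologyThresholds = PARALOG_THRESHOLDS,
) -> list[tuple[str, str]]:
    """Within-genome reciprocal best hits (self-hits excluded); unordered
    pairs reported once, sorted."""
    scheme = scheme or ScoringScheme()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    best = _best_hits(records, records, scheme, exclude_self=True)
    pairs = set()
    for a_id, (b_id, aln) in best.items():
        if best.get(b_id, (None,))[0] == a_id and aln.passes(thresholds):
            pairs.add(tuple(sorted((a_id, b_id))))
    return sorted(pairs)
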