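"""Motif scanning, domain architectures and subfamily classification.

The family is defined by the TIFY domain with its TIF[F/Y]XG core motif;
the JAZ subfamily additionally carries a C-terminal Jas motif
(SLX2FX2KRX2RX5PY), the ZML subfamily a CCT motif and a C2C2-GATA
zinc-finger domain, and the PPD subfamily an N-terminal PPD domain.

Profile-HMM search is replaced here by degenerate-consensus / PSSM scanning:
a consensus pattern is a string of literal residues, ``X`` wildcards and
``[ABC]`` alternative classes.  A window is a hit when every *anchor*
position matches, at most ``max_mismatches`` non-anchor positions mismatch,
and the BLOSUM62 window score reaches the model threshold.  The default CCT,
GATA and PPD patterns are stylized surrogates with the field's canonical
anchor residues (e.g. the C-X2-C ... C-X2-C zinc-finger spacing); trained
PSSMs can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .sequence_io import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")

MOTIF_NAMES = ("TIFY", "Jas", "CCT", "GATA", "PPD")


def _parse_consensus(pattern: str) -> list[frozenset[str] | None]:
    """Parse a degenerate pattern into per-position residue sets
    (``None`` = wildcard)."""
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            chars = pattern[i + 1 : j]
            if not chars or any(c not in AMINO_ACIDS for c in chars):
                raise ValueError(f"bad residue class {pattern[i:j+1]!r} in {pattern!r}")
            positions.append(frozenset(chars))
            i = j + 1
        elif ch == "X":
            positions.append(None)
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"illegal character {ch!r} in consensus {pattern!r}")
    if len(positions) < 4:
        raise ValueError(f"consensus {pattern!r} shorter than 4 positions")
    return positions


@dataclass
class MotifModel:
    """A consensus- or PSSM-based motif model.

    ``anchors`` are 0-based positions that must match for consensus models;
    ``max_mismatches`` bounds mismatches at the remaining non-wildcard
    positions.
    """

    name: str
    model_kind: str = "consensus"
    consensus: str | None = None
    pssm: np.ndarray | None = None  # L x 20, columns in AMINO_ACIDS order
    score_threshold: float = 0.0
    anchors: frozenset[int] = frozenset()
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.score_threshold):
            raise ValueError("score threshold must be finite")
        if self.model_kind == "consensus":
            if self.consensus is None:
                raise ValueError("consensus model needs a pattern")
            self._positions = _parse_consensus(self.consensus)
        elif self.model_kind == "pssm":
            if self.pssm is None or self.pssm.ndim != 2 or self.pssm.shape[1] != 20:
                raise ValueError("pssm model needs an L x 20 matrix")
            if self.pssm.shape[0] < 4:
                raise ValueError("pssm shorter than 4 positions")
        else:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        self.anchors = frozenset(self.anchors)

    @property
    def length(self) -> int:
        if self.model_kind == "consensus":
            return len(self._positions)
        return self.pssm.shape[0]

    def score_window(self, window: str) -> float | None:
        """Score one window; ``None`` when the window is not a hit."""
        if self.model_kind == "pssm":
            score = 0.0
            for i, res in enumerate(window):
                k = AMINO_ACIDS.find(res)
                if k < 0:
                    return None
                score += float(self.pssm[i, k])
            return score if score >= self.score_threshold else None
        score = 0.0
        mismatches = 0
        for i, allowed in enumerate(self._positions):
            if allowed is None:
                continue
            res = window[i]
            matched = res in allowed
            if matched:
                score += max(float(_BLOSUM62[a, res]) for a in allowed)
            else:
                if i in self.anchors:
                    return None
                mismatches += 1
                if mismatches > self.max_mismatches:
                    return None
                score += max(
                    float(_BLOSUM62[a, res]) for a in allowed
                ) if res in AMINO_ACIDS else -4.0
        return score if score >= self.score_threshold else None

    def sample_instance(self, rng: np.random.Generator) -> str:
        """Draw a concrete motif instance from the model (wildcards uniform
        over the 20 residues, classes uniform within the class)."""
        if self.model_kind == "pssm":
            return "".join(
                AMINO_ACIDS[int(np.argmax(row))] for row in self.pssm
            )
        out = []
        for allowed in self._positions:
            if allowed is None:
                out.append(AMINO_ACIDS[rng.integers(20)])
            else:
                choices = sorted(allowed)
                out.append(choices[rng.integers(len(choices))])
        return "".join(out)


def default_motif_models() -> dict[str, MotifModel]:
    """The default consensus models for the five diagnostic motifs."""
    return {
        "TIFY": MotifModel(
            "TIFY", consensus="TIF[FY]XG", anchors={3, 5},
            max_mismatches=3, score_threshold=15.0,
        ),
        "Jas": MotifModel(
            "Jas", consensus="SLXXFXXKRXXRXXXXXPY", anchors={7, 8, 11, 17, 18},
            max_mismatches=3, score_threshold=25.0,
        ),
        "CCT": MotifModel(
            "CCT", consensus="RYREKRKXXRKFXK", anchors={1, 4, 6, 11},
            max_mismatches=4, score_threshold=30.0,
        ),
        "GATA": MotifModel(
            "GATA", consensus="CXXCXXXXXXXXLWRXXXXXXXCNXCG",
            anchors={0, 3, 13, 23, 26}, max_mismatches=4, score_threshold=40.0,
        ),
        "PPD": MotifModel(
            "PPD", consensus="PPDVXXLXXKXXGXPW", anchors={0, 1, 2, 15},
            max_mismatches=3, score_threshold=30.0,
        ),
    }


@dataclass(frozen=True)
class DomainHit:
    motif: str
    start: int  # 1-based inclusive
    end: int
    score: float


@dataclass
class Architecture:
    """The ordered motif hits on one protein."""

    protein_id: str
    hits: list[DomainHit] = field(default_factory=list)

    def motif_names(self) -> set[str]:
        return {h.motif for h in self.hits}

    def hits_for(self, motif: str) -> list[DomainHit]:
        return [h for h in self.hits if h.motif == motif]


def _resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Keep the highest-scoring of overlapping same-motif hits (ties ->
    leftmost)."""
    chosen: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.start)):
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


def scan_motifs(
    protein: SequenceRecord, models: Iterable[MotifModel] | Mapping[str, MotifModel]
) -> Architecture:
    """Scan a protein with a set of motif models.

    Every window scoring at or above a model's threshold is reported;
    overlapping hits of the same motif are resolved to the highest-scoring
    one (ties to the leftmost).  Hits are sorted by start coordinate.
    """
    if protein.alphabet != "protein":
        raise ValueError(f"{protein.id}: motif scanning requires a protein sequence")
    if isinstance(models, Mapping):
        models = models.values()
    seq = protein.residues
    arch = Architecture(protein.id)
    all_hits: list[DomainHit] = []
    for model in models:
        L = model.length
        model_hits = []
        for off in range(len(seq) - L + 1):
            score = model.score_window(seq[off : off + L])
            if score is not None:
                model_hits.append(DomainHit(model.name, off + 1, off + L, score))
        all_hits.extend(_resolve_overlaps(model_hits))
    arch.hits = sorted(all_hits, key=lambda h: (h.start, h.motif))
    return arch


def classify_subfamily(arch: Architecture) -> str:
    """Assign the subfamily from the domain architecture.

    Decision order: no TIFY domain -> unassigned; PPD -> PPD; GATA (a ZML
    hallmark, and it outranks a co-occurring Jas motif) -> ZML; CCT without
    Jas -> ZML; Jas -> JAZ; TIFY alone -> TIFY.
    """
    names = arch.motif_names()
    if "TIFY" not in names:
        return "unassigned"
    if "PPD" in names:
        return "PPD"
    if "GATA" in names:
        return "ZML"
    if "CCT" in names and "Jas" not in names:
        return "ZML"
    if "Jas" in names:
        return "JAZ"
    return "TIFY"


def extract_tify_hexamer(arch: Architecture, protein: SequenceRecord) -> str:
    """The 6 residues at the core of the highest-scoring TIFY hit."""
    tify_hits = arch.hits_for("TIFY")
    if not tify_hits:
        raise ValueError(f"{protein.id}: no TIFY hit in architecture")
    best = max(tify_hits, key=lambda h: (h.score, -h.start))
    return protein.residues[best.start - 1 : best.start + 5]


def position_frequency_matrix(instances: Sequence[str]) -> pd.DataFrame:
    """Per-position residue frequencies of aligned motif instances.

    Returns a 20 x L DataFrame (rows: amino acids, columns: 1-based motif
    positions); each column sums to 1.  This is the matrix underlying a
    sequence logo.
    """
    if not instances:
        raise ValueError("need at least one motif instance")
    L = len(instances[0])
    if any(len(s) != L for s in instances):
        raise ValueError("motif instances differ in length")
    mat = np.zeros((20, L))
    for s in instances:
        for j, res in enumerate(s.upper()):
            k = AMINO_ACIDS.find(res)
            if k < 0:
                raise ValueError(f"illegal residue {res!r} in motif instance {s!r}")
            mat[k, j] += 1
    mat /= len(instances)
    return pd.DataFrame(mat, index=list(AMINO_ACIDS), columns=range(1, L + 1))


def consensus_from_pfm(pfm: pd.DataFrame) -> str:
    """Most-frequent residue per column (ties to alphabetic order)."""
    return "".join(pfm[c].idxmax() for c in pfm.columns)


@dataclass(frozen=True)
class EvidenceHit:
    evidence_id: str
    identity_pct: float
    score: float
    coverage: float  # aligned columns / query length


def evidence_support(
    query: SequenceRecord, est_set: Sequence[SequenceRecord]
) -> EvidenceHit | None:
    """Best expressed-sequence evidence for a gene.

    Aligns the query CDS against each EST / full-length cDNA with local
    alignment and returns the highest-scoring EST with its percent identity
    and query coverage, or ``None`` when the set is empty.  Callers mark the
    gene "supported" at a configurable identity floor (default 80%) and
    coverage floor — identity alone would pass short spurious local hits of
    unrelated sequences.
    """
    from . import homology  # deferred to avoid a module cycle

    if not est_set:
        return None
    scheme = homology.nucleotide_scheme() if query.alphabet == "dna" else homology.ScoringScheme()
    best: tuple[float, str, EvidenceHit] | None = None
    for est in est_set:
        aln = homology.smith_waterman(query, est, scheme)
        hit = EvidenceHit(
            est.id, aln.identity_pct, aln.score,
            aln.aligned_length / max(1, len(query.residues)),
        )
        if best is None or aln.score > best[0] or (aln.score == best[0] and est.id < best[1]):
            best = (aln.score, est.id, hit)
    return best[2]


def is_supported(
    hit: EvidenceHit | None,
    identity_floor: float = 80.0,
    coverage_floor: float = 0.5,
) -> bool:
    return (
        hit is not None
        and hit.identity_pct >= identity_floor
        and hit.coverage >= coverage_floor
    )
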