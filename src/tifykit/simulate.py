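"""Synthetic data generation with recorded ground truth.

Generates every input the pipeline consumes: protein families with planted
TIFY/Jas/CCT/GATA/PPD motifs, codon sequence pairs diverged at controlled
synonymous and non-synonymous rates, a three-genome orthologue/paralogue
scenario, negative-binomial count matrices with planted stress inductions,
and qPCR Cq tables — all deterministic under a fixed seed, with the planted
truth recorded for parameter-recovery tests.

Codon evolution targets the observed divergence directly: the synonymous
difference budget is p_s * S with p_s the inverse Jukes-Cantor transform of
the target Ks (likewise for Ka), placed at distinct nucleotide positions
with stop-creating changes rejected.  Motif codons are protected from
non-synonymous change (synonymous changes allowed), emulating the purifying
selection that keeps diagnostic motifs recognizable across genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from . import molevol
from .expression import QpcrRecord
from .motifs import AMINO_ACIDS, DomainHit, MotifModel, default_motif_models
from .phylogeny import MultipleAlignment
from .sequence_io import CountMatrix, GeneModel, SequenceRecord

# reverse genetic code: amino acid -> codons
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon in molevol.SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(molevol.translate_codon(_codon), []).append(_codon)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def inverse_jukes_cantor(k: float) -> float:
    """Observed difference proportion giving a Jukes-Cantor distance of k."""
    if k < 0:
        raise ValueError("divergence must be non-negative")
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


@dataclass
class FamilySimConfig:
    """Study conditions of the simulated family.

    Defaults mirror the bamboo family design: 24 focal-genome members
    (18 JAZ, 5 ZML, 1 TIFY) arising from 18 ancestors plus 6 within-genome
    duplications (5 JAZ, 1 ZML); orthologue divergence Ks of 0.51 / 0.51 /
    0.58 between the three genome pairs and paralogue Ks of 0.22; omega 0.5
    throughout (purifying selection); stress expression with 11
    dehydration-induced genes nested inside 13 cold-induced genes, two
    repressed genes, planted fold 4, negative-binomial dispersion 0.05 and
    2e7 mapped reads per library.
    """

    n_per_subfamily: dict[str, int] = field(
        default_factory=lambda: {"JAZ": 18, "ZML": 5, "TIFY": 1}
    )
    duplication_pairs: dict[str, int] = field(
        default_factory=lambda: {"JAZ": 5, "ZML": 1}
    )
    genomes: tuple[str, ...] = ("Pe", "Os", "Bd")
    ortholog_ks: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Pe", "Os"): 0.51,
            ("Pe", "Bd"): 0.51,
            ("Os", "Bd"): 0.58,
        }
    )
    paralog_ks: float = 0.22
    omega: float = 0.5
    background_length_aa: tuple[int, int] = (240, 240)
    lam: float = molevol.DEFAULT_LAMBDA
    # expression design
    conditions: tuple[str, ...] = ("dehydration", "cold")
    timepoints: tuple[str, ...] = ("2h", "8h")
    n_replicates: int = 2
    n_up: dict[str, int] = field(
        default_factory=lambda: {"dehydration": 11, "cold": 13}
    )
    n_down: int = 2
    planted_fold: float = 4.0
    down_fold: float = 0.2
    baseline_rpkm_range: tuple[float, float] = (2.0, 64.0)
    nb_dispersion: float = 0.05
    library_size: int = 20_000_000
    # qPCR
    qpcr_sigma: float = 0.1
    # EST evidence
    n_supported: int = 16
    est_identity_range: tuple[float, float] = (81.0, 100.0)
    seed: int = 0

    def branch_ks(self) -> dict[str, float]:
        """Per-genome branch Ks from the pairwise targets (three-point
        formulas on a star phylogeny)."""
        a, b, c = self.genomes
        dab = self.ortholog_ks[(a, b)]
        dac = self.ortholog_ks[(a, c)]
        dbc = self.ortholog_ks[(b, c)]
        return {
            a: 0.5 * (dab + dac - dbc),
            b: 0.5 * (dab + dbc - dac),
            c: 0.5 * (dac + dbc - dab),
        }


@dataclass
class MemberTruth:
    subfamily: str
    hits: list[DomainHit]
    tify_hexamer: str
    protected_aa: frozenset[int]  # 0-based residue indices under the motifs


@dataclass
class RealizedCounts:
    events: list[tuple[int, str, str, str]]  # (nt position, from, to, syn|nonsyn)

    @property
    def n_syn(self) -> int:
        return sum(1 for e in self.events if e[3] == "syn")

    @property
    def n_nonsyn(self) -> int:
        return sum(1 for e in self.events if e[3] == "nonsyn")


_REQUIRED_MOTIFS = {
    "JAZ": ("TIFY", "Jas"),
    "ZML": ("TIFY", "CCT", "GATA"),
    "TIFY": ("TIFY",),
    "PPD": ("PPD", "TIFY", "Jas"),
}


def _plant_positions(
    subfamily: str, length: int, models: Mapping[str, MotifModel],
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Non-overlapping 0-based start offsets for the subfamily's motifs.

    The TIFY domain sits N-terminal of the Jas motif, which lies near the
    C terminus; the PPD domain is N-terminal of everything.
    """
    required = _REQUIRED_MOTIFS[subfamily]
    total = sum(models[m].length for m in required)
    margin = 4 * (len(required) + 1)
    if length < total + margin + 10:
        raise ValueError(
            f"protein length {length} too short for motifs {required}"
        )
    placements: list[tuple[str, int]] = []
    cursor = 2
    # spread the leftover length into the gaps before each motif, so the
    # last required motif (Jas for JAZ proteins) ends near the C terminus
    slack = length - total - cursor - 3
    gaps = rng.multinomial(slack, [1.0 / len(required)] * len(required))
    if len(required) == 1:
        gaps = [int(gaps[0]) // 3]  # a lone TIFY domain sits N-terminal-ish
    for motif, gap in zip(required, gaps):
        start = cursor + int(gap)
        placements.append((motif, start))
        cursor = start + models[motif].length
    return placements


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein, codons drawn uniformly among synonymous codons."""
    return "".join(
        _CODONS_FOR_AA[aa][rng.integers(len(_CODONS_FOR_AA[aa]))] for aa in protein
    )


def simulate_member(
    subfamily: str,
    config: FamilySimConfig,
    rng: np.random.Generator,
    gene_id: str = "sim",
    models: Mapping[str, MotifModel] | None = None,
) -> tuple[SequenceRecord, SequenceRecord, MemberTruth]:
    """One family member: background residues i.i.d. uniform over the 20
    amino acids with the subfamily's motifs planted at non-overlapping
    positions, plus a back-translated CDS."""
    models = models or default_motif_models()
    lo, hi = config.background_length_aa
    length = int(rng.integers(lo, hi + 1))
    residues = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
    hits: list[DomainHit] = []
    protected: set[int] = set()
    for motif, start in _plant_positions(subfamily, length, models, rng):
        inst = models[motif].sample_instance(rng)
        residues[start : start + len(inst)] = list(inst)
        hits.append(DomainHit(motif, start + 1, start + len(inst), 0.0))
        protected.update(range(start, start + len(inst)))
    protein = "".join(residues)
    tify = next(h for h in hits if h.motif == "TIFY")
    truth = MemberTruth(
        subfamily, sorted(hits, key=lambda h: h.start),
        protein[tify.start - 1 : tify.start + 5], frozenset(protected),
    )
    cds = back_translate(protein, rng)
    return (
        SequenceRecord(gene_id, protein, "protein"),
        SequenceRecord(gene_id, cds, "dna"),
        truth,
    )


def evolve_codons(
    cds: str,
    target_ks: float,
    target_ka: float,
    rng: np.random.Generator,
    protected_aa: frozenset[int] = frozenset(),
    conservative_nonsyn: bool = True,
) -> tuple[str, RealizedCounts]:
    """Derive a diverged CDS with controlled synonymous / non-synonymous
    divergence.

    Difference budgets are p * (NG86 site totals) with p the inverse
    Jukes-Cantor transform of each target; substitutions are placed at
    distinct nucleotide positions, changes creating stop codons are
    rejected, and non-synonymous changes are rejected inside protected
    residues.  With ``conservative_nonsyn`` (the default) amino-acid
    replacements are restricted to BLOSUM62-positive exchanges, emulating
    purifying selection on protein physicochemistry — this keeps alignment
    "positives" high between homologs, as in real protein families.  Raises
    when the targets are unreachable (e.g. a non-zero Ka target on a fully
    protected sequence).
    """
    codons = molevol._split_codons(cds.upper())
    for k, codon in enumerate(codons):
        if molevol.is_stop(codon):
            raise ValueError(f"stop codon {codon} at codon {k + 1}")
    S_anc = sum(molevol.ng86_site_counts(c)[0] for c in codons)
    N_anc = 3.0 * len(codons) - S_anc
    derived = list(codons)
    mutated: set[int] = set()
    events: list[tuple[int, str, str, str]] = []
    n_nt = 3 * len(codons)

    def place(kind: str, budget: int) -> None:
        attempts = 0
        max_attempts = 2000 + 500 * budget
        remaining = budget
        while remaining > 0 and attempts < max_attempts:
            attempts += 1
            pos = int(rng.integers(n_nt))
            if pos in mutated:
                continue
            ci, off = divmod(pos, 3)
            codon = derived[ci]
            old = codon[off]
            alt = molevol.BASES[rng.integers(4)]
            if alt == old:
                continue
            new_codon = codon[:off] + alt + codon[off + 1 :]
            if molevol.is_stop(new_codon):
                continue
            synonymous = (
                molevol.translate_codon(new_codon) == molevol.translate_codon(codon)
            )
            if synonymous != (kind == "syn"):
                continue
            if kind == "nonsyn":
                if ci in protected_aa:
                    continue
                if conservative_nonsyn and float(
                    _BLOSUM62[
                        molevol.translate_codon(codon),
                        molevol.translate_codon(new_codon),
                    ]
                ) <= 0:
                    continue
            derived[ci] = new_codon
            mutated.add(pos)
            events.append((pos, old, alt, kind))
            remaining -= 1
        if remaining > 0:
            raise ValueError(
                f"divergence targets unreachable: {remaining} {kind} changes "
                "could not be placed"
            )

    # non-synonymous changes first: they shift the codon composition, so the
    # synonymous budget is computed against the mean site count of the final
    # pair (the denominator NG86 itself uses), not the ancestor's alone
    place("nonsyn", int(round(inverse_jukes_cantor(target_ka) * N_anc)))
    S_derived = sum(molevol.ng86_site_counts(c)[0] for c in derived)
    S_pair = 0.5 * (S_anc + S_derived)
    place("syn", int(round(inverse_jukes_cantor(target_ks) * S_pair)))
    return "".join(derived), RealizedCounts(events)


def translate_cds(cds: str) -> str:
    return str(Seq(cds).translate())


# ---------------------------------------------------------------------------
# three-genome scenario


@dataclass
class ScenarioTruth:
    subfamily: dict[str, str]
    architectures: dict[str, list[DomainHit]]
    tify_hexamer: dict[str, str]
    ortholog_pairs: dict[tuple[str, str], list[tuple[str, str]]]
    paralog_pairs: list[tuple[str, str]]
    branch_ks: dict[str, float]
    pair_ks: dict[tuple[str, str], float]  # planted Ks per genome pair + paralogs
    response: dict[str, dict[str, str]]  # focal gene -> condition -> call
    folds: dict[str, dict[str, dict[str, float]]]  # gene -> condition -> tp -> fold
    est_support: dict[str, str]  # focal gene -> evidence id


@dataclass
class SimulatedFamily:
    config: FamilySimConfig
    proteins: dict[str, list[SequenceRecord]]  # genome -> records
    cds: dict[str, list[SequenceRecord]]
    msa: MultipleAlignment | None
    counts: CountMatrix
    qpcr: list[QpcrRecord]
    ests: list[SequenceRecord]
    gene_models: list[GeneModel]
    truth: ScenarioTruth

    def all_proteins(self) -> list[SequenceRecord]:
        return [r for genome in self.config.genomes for r in self.proteins[genome]]


def _ancestor_plan(config: FamilySimConfig) -> list[str]:
    """Subfamily of each ancestral member; duplications reduce the ancestor
    count below the focal-genome family size."""
    plan = []
    for sub, n in config.n_per_subfamily.items():
        dups = config.duplication_pairs.get(sub, 0)
        if dups > n - dups:
            raise ValueError(f"too many duplications for subfamily {sub}")
        plan.extend([sub] * (n - dups))
    return plan


def simulate_three_genome_scenario(config: FamilySimConfig | None = None) -> SimulatedFamily:
    """The full study design: an ancestral family speciated into three
    genomes, within-focal-genome duplications, stress expression counts and
    qPCR tables, with every planted relationship recorded."""
    config = config or FamilySimConfig()
    rng = np.random.default_rng(config.seed)
    models = default_motif_models()
    plan = _ancestor_plan(config)
    branch_ks = config.branch_ks()
    focal = config.genomes[0]

    ancestors = []
    for i, sub in enumerate(plan):
        ancestors.append(
            simulate_member(sub, config, rng, gene_id=f"anc{i + 1:02d}", models=models)
        )

    proteins: dict[str, list[SequenceRecord]] = {g: [] for g in config.genomes}
    cds: dict[str, list[SequenceRecord]] = {g: [] for g in config.genomes}
    truth_sub: dict[str, str] = {}
    truth_arch: dict[str, list[DomainHit]] = {}
    truth_hex: dict[str, str] = {}

    def add_gene(genome: str, gid: str, cds_str: str, member_truth: MemberTruth) -> None:
        prot = translate_cds(cds_str)
        proteins[genome].append(SequenceRecord(gid, prot, "protein"))
        cds[genome].append(SequenceRecord(gid, cds_str, "dna"))
        truth_sub[gid] = member_truth.subfamily
        truth_arch[gid] = member_truth.hits
        truth_hex[gid] = member_truth.tify_hexamer

    for i, (prot, anc_cds, mtruth) in enumerate(ancestors):
        for genome in config.genomes:
            ks = branch_ks[genome]
            derived, _ = evolve_codons(
                anc_cds.residues, ks, config.omega * ks, rng, mtruth.protected_aa
            )
            add_gene(genome, f"{genome}_g{i + 1:02d}", derived, mtruth)

    # within-focal-genome duplications: the new copy diverges from its parent
    # at the paralogue Ks target
    dup_parents: list[int] = []
    for sub, n_dup in config.duplication_pairs.items():
        dup_parents.extend(
            [i for i, s in enumerate(plan) if s == sub][:n_dup]
        )
    paralog_pairs = []
    next_idx = len(plan) + 1
    for parent_idx in dup_parents:
        parent = cds[focal][parent_idx]
        mtruth = ancestors[parent_idx][2]
        derived, _ = evolve_codons(
            parent.residues, config.paralog_ks, config.omega * config.paralog_ks,
            rng, mtruth.protected_aa,
        )
        gid = f"{focal}_g{next_idx:02d}"
        add_gene(focal, gid, derived, mtruth)
        paralog_pairs.append((parent.id, gid))
        next_idx += 1

    ortho = {}
    for (ga, gb), ks in config.ortholog_ks.items():
        ortho[(ga, gb)] = [
            (f"{ga}_g{i + 1:02d}", f"{gb}_g{i + 1:02d}") for i in range(len(plan))
        ]
    pair_ks = dict(config.ortholog_ks)
    pair_ks[(focal, focal)] = config.paralog_ks

    focal_ids = [r.id for r in proteins[focal]]
    lengths = pd.Series(
        {r.id: len(r.residues) * 3 for r in cds[focal]}, name="length_bp"
    )
    counts, response, folds = simulate_counts(config, rng, focal_ids, lengths)
    qpcr = simulate_qpcr(config, rng, folds)
    ests, est_support = simulate_ests(config, rng, cds[focal])
    gene_models = simulate_gene_models(rng, cds[focal])

    msa = None
    if len({len(r.residues) for g in config.genomes for r in proteins[g]}) == 1:
        msa = MultipleAlignment.from_records(
            [r for g in config.genomes for r in proteins[g]]
        )

    truth = ScenarioTruth(
        truth_sub, truth_arch, truth_hex, ortho, paralog_pairs,
        branch_ks, pair_ks, response, folds, est_support,
    )
    return SimulatedFamily(
        config, proteins, cds, msa, counts, qpcr, ests, gene_models, truth
    )


# ---------------------------------------------------------------------------
# expression counts, qPCR, ESTs, gene models


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: FamilySimConfig,
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    gene_length_bp: pd.Series,
) -> tuple[CountMatrix, dict[str, dict[str, str]], dict]:
    """Count matrix for control + stress/timepoint samples with planted
    fold changes.

    The first ``n_up[cold]`` genes are cold-induced and the first
    ``n_up[dehydration]`` of those are also dehydration-induced (the nested
    design); the next ``n_down`` genes are repressed under both stresses.
    Counts are negative binomial around length x library x RPKM / 1e9.
    """
    n = len(gene_ids)
    lo, hi = config.baseline_rpkm_range
    baseline = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    n_up_sorted = sorted(config.n_up.items(), key=lambda kv: -kv[1])
    largest_cond, largest_n = n_up_sorted[0]
    if largest_n + config.n_down > n:
        raise ValueError("more planted responses than genes")
    response: dict[str, dict[str, str]] = {}
    folds: dict[str, dict[str, dict[str, float]]] = {}
    for i, gid in enumerate(gene_ids):
        response[gid] = {}
        folds[gid] = {}
        for cond in config.conditions:
            if i < config.n_up.get(cond, 0):
                call, fold = "up", config.planted_fold
            elif largest_n <= i < largest_n + config.n_down:
                call, fold = "down", config.down_fold
            else:
                call, fold = "none", 1.0
            response[gid][cond] = call
            folds[gid][cond] = {tp: fold for tp in config.timepoints}

    samples = [f"control_r{k + 1}" for k in range(config.n_replicates)]
    true_rpkm = {s: baseline for s in samples}
    for cond in config.conditions:
        for tp in config.timepoints:
            vals = np.array(
                [baseline[i] * folds[g][cond][tp] for i, g in enumerate(gene_ids)]
            )
            for k in range(config.n_replicates):
                s = f"{cond}_{tp}_r{k + 1}"
                samples.append(s)
                true_rpkm[s] = vals
    lengths = gene_length_bp.reindex(gene_ids).astype(float)
    data = {}
    for s in samples:
        mean = true_rpkm[s] * lengths.values * config.library_size / 1e9
        data[s] = _nb_counts(mean, config.nb_dispersion, rng)
    counts = pd.DataFrame(data, index=list(gene_ids))
    lib = pd.Series(config.library_size, index=samples, name="library_size")
    return CountMatrix(counts, lengths.astype(int), lib), response, folds


def simulate_qpcr(
    config: FamilySimConfig,
    rng: np.random.Generator,
    folds: Mapping[str, Mapping[str, Mapping[str, float]]],
) -> list[QpcrRecord]:
    """Triplicate Cq tables consistent with the planted fold changes:
    Cq_target = base - log2(fold) + noise, constant reference gene."""
    records = []
    sigma = config.qpcr_sigma
    for gene, by_cond in folds.items():
        base = float(rng.uniform(22.0, 28.0))
        tgt = {"control": [base + sigma * rng.standard_normal() for _ in range(3)]}
        ref = {"control": [20.0 + sigma * rng.standard_normal() for _ in range(3)]}
        for cond, by_tp in by_cond.items():
            for tp, fold in by_tp.items():
                sample = f"{cond}_{tp}"
                mu = base - math.log2(fold)
                tgt[sample] = [mu + sigma * rng.standard_normal() for _ in range(3)]
                ref[sample] = [20.0 + sigma * rng.standard_normal() for _ in range(3)]
        records.append(QpcrRecord(gene, tgt, ref))
    return records


def simulate_ests(
    config: FamilySimConfig,
    rng: np.random.Generator,
    focal_cds: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Expressed-sequence evidence for the first ``n_supported`` focal genes,
    mutated to a planted nucleotide identity."""
    ests = []
    support = {}
    lo, hi = config.est_identity_range
    for i, rec in enumerate(focal_cds[: config.n_supported]):
        identity = float(rng.uniform(lo, hi))
        seq = list(rec.residues)
        n_mut = int(round(len(seq) * (1.0 - identity / 100.0)))
        positions = rng.choice(len(seq), size=n_mut, replace=False)
        for pos in positions:
            choices = [b for b in molevol.BASES if b != seq[pos]]
            seq[pos] = choices[rng.integers(3)]
        est_id = f"est{i + 1:03d}"
        ests.append(SequenceRecord(est_id, "".join(seq), "dna"))
        support[rec.id] = est_id
    return ests, support


def simulate_gene_models(
    rng: np.random.Generator, focal_cds: Sequence[SequenceRecord],
    single_exon_fraction: float = 0.2,
) -> list[GeneModel]:
    """Exon structures for the focal genes: CDS split into 1-5 exons on a
    scaffold with random intron lengths."""
    models = []
    for i, rec in enumerate(focal_cds):
        cds_len = len(rec.residues)
        if rng.random() < single_exon_fraction:
            n_exons = 1
        else:
            n_exons = int(rng.integers(2, 6))
        cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        pieces = np.diff([0, *[int(c) for c in cuts], cds_len])
        start = int(rng.integers(1000, 50_000))
        exons = []
        pos = start
        for piece in pieces:
            exons.append((pos, pos + int(piece) - 1))
            pos += int(piece) + int(rng.integers(80, 2000))  # intron
        models.append(
            GeneModel(rec.id, f"scaffold{i + 1:04d}", "+" if rng.random() < 0.5 else "-", exons)
        )
    return models
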