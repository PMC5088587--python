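"""Codon-level molecular evolution: NG86 Ka/Ks and molecular-clock dating.

Implements the Nei-Gojobori (1986) counting method: degeneracy-based
synonymous/non-synonymous site counting per codon, pathway-averaged
difference counting for codon pairs differing at 2-3 positions, Jukes-Cantor
correction Ks = -3/4 ln(1 - 4 ps / 3) (likewise Ka), and clock dating
T = Ks / (2 lambda) with the grass synonymous rate lambda = 6.5e-9
substitutions per site per year as default.

Changes to and paths through stop codons are excluded; when every pathway
between a codon pair crosses a stop codon the average falls back to all
pathways (stop-crossing steps counted as non-synonymous) and the result is
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TABLE))

DEFAULT_LAMBDA = 6.5e-9  # synonymous substitutions / site / year (grasses)


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


# ---------------------------------------------------------------------------
# codon alignment threading


@dataclass
class CodonAlignment:
    """Codon-resolved alignment of two CDSs threaded through a protein
    alignment; gap codons are ``---``."""

    id_a: str
    id_b: str
    codon_columns: list[tuple[str, str]]

    def gap_free_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb) for ca, cb in self.codon_columns if "-" not in ca and "-" not in cb
        ]


def _split_codons(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def thread_codon_alignment(
    row_a: str, row_b: str, cds_a: str, cds_b: str,
    id_a: str = "a", id_b: str = "b",
) -> CodonAlignment:
    """Back-thread a pairwise protein alignment onto the two CDSs.

    A trailing stop codon on either CDS is stripped; the remaining CDS must
    translate, codon by codon, to the ungapped protein row.
    """
    if len(row_a) != len(row_b):
        raise ValueError("protein alignment rows differ in length")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) % 3 == 0 and cds_a and is_stop(cds_a[-3:]):
        cds_a = cds_a[:-3]
    if len(cds_b) % 3 == 0 and cds_b and is_stop(cds_b[-3:]):
        cds_b = cds_b[:-3]
    codons_a, codons_b = _split_codons(cds_a), _split_codons(cds_b)
    for label, row, codons in ((id_a, row_a, codons_a), (id_b, row_b, codons_b)):
        ungapped = row.replace("-", "")
        if len(ungapped) != len(codons):
            raise ValueError(
                f"{label}: protein length {len(ungapped)} does not match "
                f"{len(codons)} codons"
            )
        for k, (aa, codon) in enumerate(zip(ungapped, codons)):
            if translate_codon(codon) != aa.upper():
                raise ValueError(
                    f"{label}: codon {k + 1} ({codon}) translates to "
                    f"{translate_codon(codon)}, protein has {aa.upper()}"
                )
    cols = []
    ia = ib = 0
    for ra, rb in zip(row_a, row_b):
        ca = "---"
        cb = "---"
        if ra != "-":
            ca = codons_a[ia]
            ia += 1
        if rb != "-":
            cb = codons_b[ib]
            ib += 1
        cols.append((ca, cb))
    return CodonAlignment(id_a, id_b, cols)


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts (s, n) of a sense codon.

    At each of the 3 positions, s accrues the fraction of single-nucleotide
    changes that are synonymous, with changes to stop codons excluded from
    both numerator and denominator; n = 3 - s.
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        total = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            total += 1
            if translate_codon(mutant) == aa:
                syn += 1
        if total:
            s += syn / total
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_difference_counts(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Pathway-averaged synonymous/non-synonymous difference counts
    (sd, nd, stop_fallback) between two sense codons.

    For k differing positions, all k! orderings of single-base steps are
    enumerated; each step is classified synonymous or non-synonymous and the
    step counts are averaged over the pathways that avoid stop codons.  When
    every pathway crosses a stop codon the average is taken over all
    pathways instead (steps to or from a stop counted as non-synonymous) and
    the fallback flag is set.  Always sd + nd = k.
    """
    a, b = codon_a.upper(), codon_b.upper()
    if is_stop(a) or is_stop(b):
        raise ValueError(f"stop codon in pair ({a}, {b})")
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0, False
    paths = []  # (syn_steps, nonsyn_steps, valid)
    for order in permutations(diff_positions):
        current = a
        syn = nonsyn = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if is_stop(current) or is_stop(nxt):
                valid = False
                nonsyn += 1
            elif translate_codon(current) == translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((syn, nonsyn, valid))
    valid_paths = [(s, n) for s, n, ok in paths if ok]
    fallback = not valid_paths
    use = valid_paths if valid_paths else [(s, n) for s, n, _ in paths]
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd, fallback


@dataclass
class KaKsResult:
    """NG86 site/difference counts with Jukes-Cantor-corrected rates.

    ``Ka``/``Ks`` (and ``omega``) are ``None`` when undefined: the JC
    argument 1 - 4p/3 is non-positive at p >= 0.75, and omega is undefined
    when Ks = 0.
    """

    id_a: str
    id_b: str
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None
    omega: float | None
    n_codons_used: int
    method: str = "NG86"
    flags: list[str] = field(default_factory=list)


def jukes_cantor(p: float) -> float | None:
    """JC correction -3/4 ln(1 - 4p/3); ``None`` when undefined (p >= 3/4)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def kaks(codon_aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks over the gap-free, stop-free codon columns of an
    alignment."""
    flags: list[str] = []
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    used = 0
    for ca, cb in codon_aln.gap_free_columns():
        if is_stop(ca) or is_stop(cb):
            flags.append(f"stop_column_skipped:{ca}/{cb}")
            continue
        sa, _ = ng86_site_counts(ca)
        sb, _ = ng86_site_counts(cb)
        sd, nd, fb = ng86_difference_counts(ca, cb)
        if fb:
            flags.append(f"stop_pathway_fallback:{ca}/{cb}")
        S_a += sa
        S_b += sb
        Sd += sd
        Nd += nd
        used += 1
    if used == 0:
        raise ValueError(
            f"no usable codon columns for pair ({codon_aln.id_a}, {codon_aln.id_b})"
        )
    S = 0.5 * (S_a + S_b)
    N = 3.0 * used - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    if Ks is None:
        flags.append("Ks_undefined")
    if Ka is None:
        flags.append("Ka_undefined")
    omega = None
    if Ka is not None and Ks is not None and Ks > 0:
        omega = Ka / Ks
    elif Ks is not None and Ks == 0:
        flags.append("omega_undefined")
    return KaKsResult(
        codon_aln.id_a, codon_aln.id_b, S, N, Sd, Nd, ps, pn, Ks, Ka, omega, used,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# dating and selection


@dataclass
class DivergenceEstimate:
    ks_mean: float
    lam: float
    T_years: float
    T_mya: float  # rounded to 1 decimal
    T_mya_nearest: int
    n_pairs: int
    n_excluded: int = 0


def divergence_time(
    ks_values: Iterable[float | None], lam: float = DEFAULT_LAMBDA
) -> DivergenceEstimate:
    """Molecular-clock dating T = Ks / (2 lambda) from a set of pairwise Ks.

    Undefined (None / non-finite) Ks values are excluded with a warning
    count; an all-undefined input is an error.  E.g. mean Ks 0.51 at
    lambda = 6.5e-9 dates to 39.2 MYA.
    """
    values = list(ks_values)
    usable = [k for k in values if k is not None and math.isfinite(k)]
    n_excluded = len(values) - len(usable)
    if not usable:
        raise ValueError("no defined Ks values to date from")
    ks_mean = sum(usable) / len(usable)
    t_years = ks_mean / (2.0 * lam)
    t_mya = t_years / 1e6
    return DivergenceEstimate(
        ks_mean, lam, t_years, round(t_mya, 1), int(round(t_mya)),
        len(usable), n_excluded,
    )


def selection_class(omega: float | None, neutrality_band: float = 0.0) -> str:
    """Classify the selection regime from omega = Ka/Ks.

    omega < 1 purifying, omega = 1 neutral, omega > 1 positive, with an
    optional symmetric neutrality band around 1.
    """
    if omega is None or not math.isfinite(omega):
        return "undefined"
    if omega < 1.0 - neutrality_band:
        return "purifying"
    if omega > 1.0 + neutrality_band:
        return "positive"
    return "neutral"
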