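"""Readers and writers for the formats the pipeline touches.

Covers FASTA (protein / CDS), the family catalog table (gene id, subfamily,
protein length, TIFY-motif hexamer, expressed-sequence evidence), gene models
as exon coordinate tables (plain TSV or a gene/exon-only GFF3 subset), and
gene-level read-count matrices with gene lengths and library sizes.

Coordinates are 1-based inclusive throughout, matching the convention of
gene-structure displays; :func:`to_zero_based` / :func:`from_zero_based`
convert to half-open intervals for internal arithmetic.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")
DNA_ALPHABET = set("ACGTN-")

SUBFAMILIES = ("JAZ", "ZML", "TIFY", "PPD", "unassigned")


@dataclass
class SequenceRecord:
    """A named sequence with an alphabet tag (``protein`` or ``dna``)."""

    id: str
    residues: str
    alphabet: str = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = self.residues.upper()
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} residue {ch!r} at position {pos} "
                    f"in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Evidence:
    """One expressed-sequence (EST / full-length cDNA) support record."""

    evidence_id: str
    identity_pct: float | None = None
    evalue_text: str | None = None

    def __post_init__(self) -> None:
        if self.identity_pct is not None and not 0 <= self.identity_pct <= 100:
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")


@dataclass
class CatalogEntry:
    gene_id: str
    subfamily: str
    protein_length_aa: int
    tify_hexamer: str
    evidence: list[Evidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r} for {self.gene_id}")
        if self.protein_length_aa <= 0:
            raise ValueError(f"protein_length_aa must be positive for {self.gene_id}")
        if len(self.tify_hexamer) != 6:
            raise ValueError(f"TIFY hexamer must have 6 residues for {self.gene_id}")


@dataclass
class GeneModel:
    """Exon structure of one gene on its scaffold (1-based inclusive)."""

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-' for {self.gene_id}")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"exon start > end ({start} > {end}) in {self.gene_id}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"exons unsorted or overlapping at ({start}, {end}) in {self.gene_id}"
                )
            prev_end = end

    @property
    def cds_length_bp(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def genomic_length_bp(self) -> int:
        return self.exons[-1][1] - self.exons[0][0] + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class CountMatrix:
    """Gene x sample read counts plus gene lengths and library sizes.

    ``library_size`` is the total mapped reads of each library genome-wide;
    it is not required to bound the column sums (family-level counts are a
    small slice of the library).
    """

    counts: pd.DataFrame  # genes x samples, integers
    gene_length_bp: pd.Series  # indexed by gene id
    library_size: pd.Series  # indexed by sample id

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.gene_length_bp <= 0).any():
            raise ValueError("gene_length_bp must be positive")
        if (self.library_size <= 0).any():
            raise ValueError("library_size must be positive")
        self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.gene_length_bp.isna().any() or self.library_size.isna().any():
            raise ValueError("gene lengths / library sizes do not match the count matrix")
        self.counts.index.name = "gene_id"
        self.gene_length_bp.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# coordinate converters


def to_zero_based(interval: tuple[int, int]) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    start, end = interval
    return start - 1, end


def from_zero_based(interval: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    start, end = interval
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file; order preserved, residues uppercased.

    Raises on duplicate ids (naming the id) and on residues outside the
    declared alphabet (naming the position).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet, desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# family catalog


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """Read a family-catalog TSV.

    Continuation rows (empty ``gene_id``) carry a second piece of
    expressed-sequence evidence for the preceding gene and are merged into
    that entry's evidence list.
    """
    entries: list[CatalogEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")

            def get(col: str) -> str:
                i = idx.get(col)
                return cells[i].strip() if i is not None and i < len(cells) else ""

            ev = None
            if get("evidence_id"):
                ident = get("identity_pct")
                ev = Evidence(
                    get("evidence_id"),
                    float(ident) if ident else None,
                    get("evalue") or None,
                )
            if not get("gene_id"):
                if ev is None:
                    continue
                if not entries:
                    raise ValueError(f"continuation row before any entry (line {lineno})")
                entries[-1].evidence.append(ev)
                continue
            try:
                length = int(get("length_aa"))
            except ValueError:
                raise ValueError(
                    f"non-integer protein length {get('length_aa')!r} (line {lineno})"
                ) from None
            entries.append(
                CatalogEntry(
                    gene_id=get("gene_id"),
                    subfamily=get("subfamily"),
                    protein_length_aa=length,
                    tify_hexamer=get("tify_hexamer"),
                    evidence=[ev] if ev else [],
                )
            )
    return entries


def write_catalog(entries: Sequence[CatalogEntry], path: str | Path) -> None:
    cols = ["gene_id", "subfamily", "length_aa", "tify_hexamer",
            "evidence_id", "identity_pct", "evalue"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in entries:
            evs = e.evidence or [None]
            for i, ev in enumerate(evs):
                if i == 0:
                    row = [e.gene_id, e.subfamily, str(e.protein_length_aa), e.tify_hexamer]
                else:
                    row = ["", "", "", ""]
                if ev is None:
                    row += ["", "", ""]
                else:
                    row += [
                        ev.evidence_id,
                        "" if ev.identity_pct is None else format(ev.identity_pct, "g"),
                        ev.evalue_text or "",
                    ]
                fh.write("\t".join(row).rstrip("\t") + "\n")


def load_packaged_catalog() -> list[CatalogEntry]:
    """The family catalog shipped with the package (24 bamboo TIFY genes)."""
    ref = resources.files("tifykit").joinpath("data/family_catalog.tsv")
    with resources.as_file(ref) as p:
        return read_catalog(p)


def subfamily_histogram(entries: Iterable[CatalogEntry]) -> dict[str, int]:
    hist: dict[str, int] = {}
    for e in entries:
        hist[e.subfamily] = hist.get(e.subfamily, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a 4-column TSV or a gene/exon-only GFF3 subset."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gene_models_gff(path)
    return _read_gene_models_tsv(path)


def _read_gene_models_tsv(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"gene-model TSV missing header in {path}")
        for line in fh:
            if not line.strip():
                continue
            gene_id, scaffold, strand, exon_str = line.rstrip("\n").split("\t")
            exons = []
            for span in exon_str.split(","):
                start, end = span.split("-")
                exons.append((int(start), int(end)))
            models.append(GeneModel(gene_id, scaffold, strand, exons))
    return models


def _read_gene_models_gff(path: Path) -> list[GeneModel]:
    raw: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF line in {path}: {line!r}")
            scaffold, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            if ftype not in ("gene", "exon"):
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr_map.get("ID")
                if gid not in raw:
                    raw[gid] = {"scaffold": scaffold, "strand": strand, "exons": []}
                    order.append(gid)
            else:
                gid = attr_map.get("Parent") or attr_map.get("ID")
                entry = raw.setdefault(
                    gid, {"scaffold": scaffold, "strand": strand, "exons": []}
                )
                if gid not in order:
                    order.append(gid)
                entry["exons"].append((int(start), int(end)))
    return [
        GeneModel(gid, raw[gid]["scaffold"], raw[gid]["strand"], sorted(raw[gid]["exons"]))
        for gid in order
    ]


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tscaffold_id\tstrand\texons\n")
        for m in models:
            spans = ",".join(f"{s}-{e}" for s, e in m.exons)
            fh.write(f"{m.gene_id}\t{m.scaffold_id}\t{m.strand}\t{spans}\n")


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV with a ``#library_size`` header line and a
    ``length_bp`` column."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#library_size"):
            raise ValueError(f"counts file {path} missing #library_size header line")
        lib = {}
        for tok in first.split("\t")[1:]:
            sample, size = tok.split("=")
            lib[sample] = int(size)
        table = pd.read_csv(fh, sep="\t", index_col=0)
    lengths = table.pop("length_bp")
    table = table.astype(int)
    return CountMatrix(table, lengths.astype(int), pd.Series(lib, name="library_size"))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        toks = [f"{s}={int(cm.library_size[s])}" for s in cm.sample_ids]
        fh.write("#library_size\t" + "\t".join(toks) + "\n")
        out = cm.counts.copy()
        out.insert(0, "length_bp", cm.gene_length_bp)
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t")


def write_tsv_matrix(df: pd.DataFrame, path: str | Path, float_fmt: str = "%.6g") -> None:
    """Write a generic labelled matrix as TSV (fixed float precision for
    reproducible reruns)."""
    df.to_csv(path, sep="\t", float_format=float_fmt)


# ---------------------------------------------------------------------------


def implied_protein_length(cds_length_bp: int, has_stop: bool = True) -> int:
    """Protein length implied by a CDS length.

    A complete CDS of 3(n+1) bp with a stop codon encodes n residues, e.g. a
    5,157 bp CDS encodes 1,718 amino acids.
    """
    if cds_length_bp % 3 != 0:
        raise ValueError(f"CDS length {cds_length_bp} not divisible by 3")
    n = cds_length_bp // 3
    return n - 1 if has_stop else n
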