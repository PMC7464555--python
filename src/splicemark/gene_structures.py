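"""Gene structures, coding splice sites, and exact spliced mapping.

Coordinates follow GFF3 conventions: 1-based, inclusive, strand "+"/"-".
A *coding splice site* is an internal coding-exon boundary labelled by the
protein residue whose codon contains the exon's last nucleotide, together
with the codon position (frame +1/+2/+3) of that nucleotide.  A boundary
after the k-th coding nucleotide therefore satisfies

    k = 3 * (protein_index - 1) + frame,   frame in {1, 2, 3}

so e.g. a first exon of 650 coding nucleotides ends in frame +2 of residue
217 and is written ``V217.frame+2`` when that residue is a valine.  In
intron-phase terms, phase 0/1/2 introns carry frame +3/+1/+2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Default splice-signal pairs accepted by the mapper (donor, acceptor).
CANONICAL_SPLICE = (("GT", "AG"),)
#: GT..AG plus the minor GC..AG signal.
EXTENDED_SPLICE = (("GT", "AG"), ("GC", "AG"))


class Gff3ParseError(ValueError):
    """Raised for malformed GFF3 input; carries the offending line number."""


class ValidationError(ValueError):
    """Raised when a gene model violates a structural invariant."""


class MappingError(ValueError):
    """Raised when a CDS cannot be placed on the genomic sequence."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"coordinates must be positive: {self}")
        if self.start > self.end:
            raise ValidationError(f"start > end: {self}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-': {self}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A strand-aware chain of coding exons on one sequence.

    ``intervals`` are kept in *transcription* order: ascending genomic
    coordinates on the plus strand, descending on the minus strand, so that
    concatenating exon sequences (reverse-complemented on minus) yields the
    CDS 5'->3'.
    """

    gene_id: str
    intervals: list[GenomicInterval]
    strand: str
    source_seq: str | None = None
    #: Set by the mapper when several exon chains were consistent.
    ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def seq_id(self) -> str:
        return self.intervals[0].seq_id

    @property
    def coding_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def exon_lengths(self) -> list[int]:
        return [len(iv) for iv in self.intervals]

    def validate(self) -> None:
        if not self.intervals:
            raise ValidationError(f"{self.gene_id}: gene model has no exons")
        seq_ids = {iv.seq_id for iv in self.intervals}
        if len(seq_ids) > 1:
            raise ValidationError(f"{self.gene_id}: exons span sequences {seq_ids}")
        if any(iv.strand != self.strand for iv in self.intervals):
            raise ValidationError(f"{self.gene_id}: mixed strands")
        genomic_order = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(genomic_order, genomic_order[1:]):
            if a.end >= b.start:
                raise ValidationError(f"{self.gene_id}: overlapping exons {a} / {b}")
        expected = genomic_order if self.strand == "+" else genomic_order[::-1]
        if list(self.intervals) != expected:
            raise ValidationError(f"{self.gene_id}: exons not in transcription order")
        if self.coding_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: coding length {self.coding_length} "
                "not divisible by 3"
            )
        if self.source_seq is not None:
            cds = self.coding_sequence()
            for i in range(0, len(cds) - 3, 3):
                if cds[i : i + 3] in STOP_CODONS:
                    raise ValidationError(
                        f"{self.gene_id}: internal stop codon at CDS position {i + 1}"
                    )

    def coding_sequence(self, genomic: str | None = None) -> str:
        """Concatenated coding sequence, 5'->3' of the transcript."""
        seq = genomic if genomic is not None else self.source_seq
        if seq is None:
            raise ValueError(f"{self.gene_id}: no genomic sequence available")
        parts = []
        for iv in self.intervals:
            exon = seq[iv.start - 1 : iv.end]
            if len(exon) != len(iv):
                raise ValidationError(
                    f"{self.gene_id}: interval {iv} outside sequence of "
                    f"length {len(seq)}"
                )
            if self.strand == "-":
                exon = str(Seq(exon).reverse_complement())
            parts.append(exon.upper())
        return "".join(parts)


@dataclass(frozen=True)
class CodingSpliceSite:
    """An internal coding-exon boundary in residue/frame notation."""

    protein_index: int
    frame: int
    coding_offset: int
    residue: str

    def __post_init__(self) -> None:
        if not 1 <= self.frame <= 3:
            raise ValidationError(f"frame must be 1..3, got {self.frame}")
        if self.coding_offset != 3 * (self.protein_index - 1) + self.frame:
            raise ValidationError(
                f"inconsistent site: offset {self.coding_offset} != "
                f"3*({self.protein_index}-1)+{self.frame}"
            )

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``V217.frame+2``."""
        return f"{self.residue}{self.protein_index}.frame+{self.frame}"

    @classmethod
    def from_offset(cls, coding_offset: int, protein: str) -> "CodingSpliceSite":
        """Build a site from its 1-based coding-nucleotide offset."""
        if coding_offset < 1:
            raise ValidationError(f"coding offset must be >= 1: {coding_offset}")
        protein_index = (coding_offset + 2) // 3
        frame = coding_offset - 3 * (protein_index - 1)
        if protein_index <= len(protein):
            residue = protein[protein_index - 1]
        elif protein_index == len(protein) + 1:
            warnings.warn(
                f"splice site at offset {coding_offset} falls inside the "
                "terminal stop codon; residue reported as '*'",
                stacklevel=2,
            )
            residue = "*"
        else:
            raise ValidationError(
                f"coding offset {coding_offset} beyond protein of length "
                f"{len(protein)}"
            )
        return cls(protein_index, frame, coding_offset, residue)


def translate_cds(cds: str) -> str:
    """Translate a complete CDS with the standard code.

    A terminal stop codon is allowed and stripped; an internal stop or a
    length not divisible by 3 raises :class:`ValidationError`.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValidationError(
            f"internal stop codon at residue {protein.index('*') + 1}"
        )
    return protein


def derive_coding_splice_sites(
    model: GeneModel, cds_protein: str
) -> list[CodingSpliceSite]:
    """Derive one coding splice site per internal exon boundary.

    ``cds_protein`` must be the translation of the model's CDS (the model's
    coding length may include the terminal stop codon).  Sites are returned
    sorted by coding offset; a model with a single exon yields none.
    """
    n_codons = model.coding_length // 3
    if len(cds_protein) not in (n_codons, n_codons - 1):
        raise ValidationError(
            f"{model.gene_id}: protein length {len(cds_protein)} does not "
            f"match coding length {model.coding_length}"
        )
    sites = []
    cumulative = 0
    for length in model.exon_lengths[:-1]:
        cumulative += length
        sites.append(CodingSpliceSite.from_offset(cumulative, cds_protein))
    return sites


# ---------------------------------------------------------------------------
# GFF3 I/O


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_gff3(text: str) -> list[GeneModel]:
    """Parse CDS features of a GFF3 document into gene models.

    One model is produced per coding transcript, keyed by the CDS features'
    ``Parent`` attribute (falling back to ``gene_id`` then ``ID``).  When
    several transcripts carry the same ``gene`` attribute, the longest CDS
    is kept and the choice logged.  Minus-strand exons are reported in
    transcript order (higher coordinates first).
    """
    groups: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise Gff3ParseError(
                f"line {lineno}: expected 9 tab-separated fields, "
                f"got {len(fields)}"
            )
        seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
        if ftype != "CDS":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise Gff3ParseError(f"line {lineno}: non-integer coordinate") from exc
        if strand not in ("+", "-"):
            raise Gff3ParseError(f"line {lineno}: CDS strand must be '+' or '-'")
        attrs = _parse_attributes(attr_s)
        parent = attrs.get("Parent") or attrs.get("gene_id") or attrs.get("ID")
        if parent is None:
            raise Gff3ParseError(
                f"line {lineno}: CDS feature lacks Parent/gene_id/ID attribute"
            )
        try:
            iv = GenomicInterval(seq_id, start, end, strand)
        except ValidationError as exc:
            raise Gff3ParseError(f"line {lineno}: {exc}") from exc
        if parent not in groups:
            groups[parent] = []
            order.append(parent)
        groups[parent].append(iv)
        if "gene" in attrs:
            gene_of[parent] = attrs["gene"]

    models = []
    for parent in order:
        ivs = sorted(groups[parent], key=lambda iv: iv.start)
        strand = ivs[0].strand
        if strand == "-":
            ivs = ivs[::-1]
        models.append(GeneModel(parent, ivs, strand))

    # one transcript per gene: keep the longest CDS
    by_gene: dict[str, GeneModel] = {}
    kept = []
    for model in models:
        gene = gene_of.get(model.gene_id)
        if gene is None:
            kept.append(model)
            continue
        best = by_gene.get(gene)
        if best is None:
            by_gene[gene] = model
            kept.append(model)
        elif model.coding_length > best.coding_length:
            logger.info(
                "gene %s: keeping transcript %s (%d nt) over %s (%d nt)",
                gene, model.gene_id, model.coding_length,
                best.gene_id, best.coding_length,
            )
            kept[kept.index(best)] = model
            by_gene[gene] = model
        else:
            logger.info(
                "gene %s: dropping shorter transcript %s", gene, model.gene_id
            )
    return kept


def write_gff3(models: list[GeneModel], source: str = "splicemark") -> str:
    """Serialise gene models as a GFF3 document (CDS features only)."""
    lines = ["##gff-version 3"]
    for model in models:
        cds_pos = 0
        for iv in model.intervals:
            phase = (3 - cds_pos % 3) % 3
            lines.append(
                "\t".join(
                    [
                        iv.seq_id,
                        source,
                        "CDS",
                        str(iv.start),
                        str(iv.end),
                        ".",
                        model.strand,
                        str(phase),
                        f"ID=cds-{model.gene_id};Parent={model.gene_id}",
                    ]
                )
            )
            cds_pos += len(iv)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Exact spliced mapping


def map_cds_to_genome(
    cds: str,
    genomic: str,
    min_intron: int = 20,
    splice_dinucleotides: tuple[tuple[str, str], ...] = CANONICAL_SPLICE,
    seq_id: str = "genomic",
    gene_id: str = "mapped",
) -> GeneModel:
    """Place a CDS on a genomic sequence under the exact-match model.

    The CDS must be recoverable from the genomic sequence by excising zero
    or more introns, each at least ``min_intron`` nt long and flanked by an
    allowed donor..acceptor dinucleotide pair (GT..AG by default).  Leading
    and trailing genomic flanks are permitted.  When several exon chains
    are consistent, the chain with the leftmost intron start at each
    boundary is returned and the model is flagged ``ambiguous``.  Noisy or
    inexact matches are out of scope and raise :class:`MappingError`.
    """
    cds = cds.upper()
    genomic = genomic.upper()
    if not cds:
        raise MappingError("empty CDS")
    if min_intron < 4:
        raise ValueError("min_intron must be >= 4")
    n, g = len(cds), len(genomic)
    solutions: list[list[tuple[int, int]]] = []  # chains of (g_start0, length)

    def match_run(ci: int, gi: int) -> int:
        k = 0
        while ci + k < n and gi + k < g and cds[ci + k] == genomic[gi + k]:
            k += 1
        return k

    def search(ci: int, gi: int, chain: list[tuple[int, int]]) -> None:
        if len(solutions) >= 2:
            return
        run = match_run(ci, gi)
        # exon lengths ascending => leftmost intron start wins
        for length in range(1, run + 1):
            if ci + length == n:
                solutions.append(chain + [(gi, length)])
                if len(solutions) >= 2:
                    return
                continue
            s = gi + length  # 0-based intron start
            for donor, acceptor in splice_dinucleotides:
                if genomic[s : s + 2] != donor:
                    continue
                nxt = cds[ci + length]
                for e in range(s + min_intron, g):  # e = next exon start
                    if genomic[e - 2 : e] == acceptor and genomic[e] == nxt:
                        search(ci + length, e, chain + [(gi, length)])
                        if len(solutions) >= 2:
                            return

    start = 0
    while len(solutions) < 2:
        start = genomic.find(cds[0], start)
        if start == -1:
            break
        search(0, start, [])
        start += 1

    if not solutions:
        raise MappingError(
            f"{gene_id}: CDS cannot be placed on '{seq_id}' with introns "
            f">= {min_intron} nt and signals "
            f"{'/'.join(d + '..' + a for d, a in splice_dinucleotides)}"
        )
    if len(solutions) > 1:
        logger.warning(
            "%s: multiple consistent placements on '%s'; keeping the "
            "leftmost and flagging ambiguous", gene_id, seq_id,
        )
    chain = solutions[0]
    intervals = [
        GenomicInterval(seq_id, gs + 1, gs + length, "+") for gs, length in chain
    ]
    model = GeneModel(gene_id, intervals, "+", source_seq=genomic)
    model.ambiguous = len(solutions) > 1
    return model
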