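"""tRNA gene reference models.

Builds the three reference objects fragments are mapped onto:

* :class:`TRNAGene` — the annotated gene as it sits in the genome,
  oriented 5'->3' of the tRNA (minus-strand genes are reverse-complemented).
* :class:`MatureTRNA` — spliced exons with the post-transcriptionally added
  CCA tail and cloverleaf landmarks (acceptor stem, D-loop, anticodon loop,
  T-loop) in 1-based mature coordinates.
* :class:`PrecursorTRNA` — unspliced gene body flanked by a 5' leader and a
  3' trailer (default 30 nt, the region tRF-1 fragments derive from).

Genomic coordinates follow the BED convention (0-based, half-open);
mature/precursor coordinates are 1-based closed intervals, matching tRNA
numbering practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TRNAGene",
    "MatureTRNA",
    "PrecursorTRNA",
    "load_trna_annotation",
    "build_mature_trna",
    "build_precursor",
    "load_landmark_table",
    "read_genome",
]

NUCLEOTIDES = set("ACGTN")

#: Cloverleaf landmarks on the mature body (before CCA), standard numbering.
DEFAULT_LANDMARKS = {
    "d_loop": (14, 21),
    "anticodon_loop": (32, 38),
    "t_loop": (54, 60),
}

LOOP_LABELS = {
    "d_loop": "D-loop",
    "anticodon_loop": "anticodon-loop",
    "t_loop": "T-loop",
}


class AnnotationError(ValueError):
    """Raised for invalid or inconsistent annotation input."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TRNAGene:
    """One annotated tRNA gene copy.

    ``genomic_sequence`` reads 5'->3' of the tRNA (reverse-complemented for
    minus-strand genes).  ``exon_spans`` are genomic half-open intervals in
    transcript orientation (descending genomic position on the minus strand).
    """

    gene_id: str
    chromosome: str
    start: int  # genomic, 0-based
    end: int  # genomic, half-open
    strand: str
    genomic_sequence: str
    isotype: str = ""
    anticodon: str = ""
    exon_spans: list[tuple[int, int]] = field(default_factory=list)
    cca_encoded: bool = False  # genomically encoded CCA: do not append another

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise AnnotationError(f"{self.gene_id}: empty genomic span")
        if not self.exon_spans:
            self.exon_spans = [(self.start, self.end)]
        self._validate_exons()
        if len(self.genomic_sequence) != self.end - self.start:
            raise AnnotationError(
                f"{self.gene_id}: sequence length {len(self.genomic_sequence)}"
                f" != span length {self.end - self.start}"
            )
        bad = set(self.genomic_sequence.upper()) - NUCLEOTIDES
        if bad:
            raise AnnotationError(f"{self.gene_id}: non-nucleotide characters {bad}")
        self.genomic_sequence = self.genomic_sequence.upper()

    def _validate_exons(self) -> None:
        spans = sorted(self.exon_spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.gene_id}: overlapping exon spans")
        for s, e in spans:
            if s < self.start or e > self.end or e <= s:
                raise AnnotationError(f"{self.gene_id}: exon outside gene span")
        # transcript orientation: ascending for +, descending for -
        self.exon_spans = spans if self.strand == "+" else spans[::-1]

    @property
    def spliced_sequence(self) -> str:
        """Exon concatenation, 5'->3' of the tRNA (introns removed)."""
        parts = []
        for s, e in self.exon_spans:
            if self.strand == "+":
                off = s - self.start
                parts.append(self.genomic_sequence[off : off + (e - s)])
            else:
                off = self.end - e
                parts.append(self.genomic_sequence[off : off + (e - s)])
        return "".join(parts)


@dataclass
class MatureTRNA:
    gene_id: str
    sequence: str
    landmarks: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not self.sequence.endswith("CCA"):
            raise AnnotationError(f"{self.gene_id}: mature sequence must end in CCA")
        if self.landmarks.get("cca_tail") != (n - 2, n):
            raise AnnotationError(f"{self.gene_id}: cca_tail must be the last 3 positions")
        for name, (s, e) in self.landmarks.items():
            if s < 1 or e > n or e < s:
                raise AnnotationError(f"{self.gene_id}: landmark {name} outside [1,{n}]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrecursorTRNA:
    gene_id: str
    leader: str
    body: str
    trailer: str

    @property
    def sequence(self) -> str:
        return self.leader + self.body + self.trailer

    @property
    def leader_len(self) -> int:
        return len(self.leader)

    @property
    def body_len(self) -> int:
        return len(self.body)

    def __len__(self) -> int:
        return len(self.sequence)


def read_genome(genome_path) -> dict[str, str]:
    """Load a FASTA genome into a chromosome -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_path), "fasta")}


def _parse_blocks(start: int, n: str, sizes: str, starts: str) -> list[tuple[int, int]]:
    count = int(n)
    size_l = [int(x) for x in sizes.rstrip(",").split(",")]
    start_l = [int(x) for x in starts.rstrip(",").split(",")]
    if not (len(size_l) == len(start_l) == count):
        raise AnnotationError("block count does not match block lists")
    return [(start + s, start + s + z) for s, z in zip(start_l, size_l)]


def _parse_bed_row(fields: list[str], lineno: int) -> dict:
    if len(fields) < 6:
        raise AnnotationError(f"line {lineno}: need at least 6 BED columns")
    row = {
        "chromosome": fields[0],
        "start": int(fields[1]),
        "end": int(fields[2]),
        "gene_id": fields[3],
        "strand": fields[5],
        "isotype": "",
        "anticodon": "",
        "blocks": None,
    }
    extra = fields[6:]
    # Full BED12: thickStart thickEnd itemRgb blockCount blockSizes blockStarts
    if len(extra) >= 6 and extra[0].isdigit() and extra[1].isdigit():
        row["blocks"] = _parse_blocks(row["start"], extra[3], extra[4], extra[5])
        extra = extra[6:]
    if extra:
        row["isotype"] = extra[0]
    if len(extra) > 1:
        row["anticodon"] = extra[1]
    # BED6+ dialect: isotype anticodon [blockCount blockSizes blockStarts]
    if len(extra) >= 5 and row["blocks"] is None:
        row["blocks"] = _parse_blocks(row["start"], extra[2], extra[3], extra[4])
    return row


def load_trna_annotation(annotation_path, genome_path) -> list[TRNAGene]:
    """Parse a BED-like tRNA gene annotation against a genomic FASTA.

    Minus-strand genes are reverse-complemented so ``genomic_sequence`` reads
    5'->3' of the tRNA.  A row referencing a chromosome absent from the FASTA
    is fatal and names the offending row.
    """
    genome = read_genome(genome_path)
    genes: list[TRNAGene] = []
    with open(annotation_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            row = _parse_bed_row(line.split("\t"), lineno)
            chrom = row["chromosome"]
            if chrom not in genome:
                raise AnnotationError(
                    f"line {lineno} ({row['gene_id']}): chromosome {chrom!r} not in FASTA"
                )
            if row["end"] > len(genome[chrom]):
                raise AnnotationError(
                    f"line {lineno} ({row['gene_id']}): interval beyond contig end"
                )
            seq = genome[chrom][row["start"] : row["end"]]
            if row["strand"] == "-":
                seq = revcomp(seq)
            genes.append(
                TRNAGene(
                    gene_id=row["gene_id"],
                    chromosome=chrom,
                    start=row["start"],
                    end=row["end"],
                    strand=row["strand"],
                    genomic_sequence=seq,
                    isotype=row["isotype"],
                    anticodon=row["anticodon"],
                    exon_spans=row["blocks"] or [],
                )
            )
    return genes


def load_landmark_table(path) -> dict[str, dict[str, tuple[int, int]]]:
    """Read a TSV of (gene_id, landmark, start, end) rows."""
    table: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gene_id, name, s, e = line.split("\t")[:4]
            table.setdefault(gene_id, {})[name] = (int(s), int(e))
    return table


def default_landmarks(body_len: int) -> dict[str, tuple[int, int]]:
    """Standard-numbering loop intervals clipped to the mature body length."""
    marks = {}
    for name, (s, e) in DEFAULT_LANDMARKS.items():
        if s <= body_len:
            marks[name] = (s, min(e, body_len))
    marks["cca_tail"] = (body_len + 1, body_len + 3)
    return marks


def build_mature_trna(
    gene: TRNAGene,
    landmark_table: dict[str, dict[str, tuple[int, int]]] | None = None,
) -> MatureTRNA:
    """Splice exons, append CCA, and place cloverleaf landmarks.

    Landmarks come from ``landmark_table`` when the gene is listed there,
    otherwise from the standard-numbering default (D-loop [14,21], anticodon
    loop [32,38], T-loop [54,60], clipped to the body length).  CCA is always
    appended unless the gene's ``cca_encoded`` flag says the genomic sequence
    already carries it.
    """
    body = gene.spliced_sequence
    if gene.cca_encoded and body.endswith("CCA"):
        body = body[:-3]
    sequence = body + "CCA"
    body_len = len(body)
    marks = default_landmarks(body_len)
    if landmark_table and gene.gene_id in landmark_table:
        for name, (s, e) in landmark_table[gene.gene_id].items():
            if s < 1 or e > len(sequence):
                raise AnnotationError(
                    f"{gene.gene_id}: landmark {name} [{s},{e}] outside mature sequence"
                )
            marks[name] = (s, e)
    marks["cca_tail"] = (body_len + 1, body_len + 3)
    return MatureTRNA(gene_id=gene.gene_id, sequence=sequence, landmarks=marks)


def build_precursor(
    gene: TRNAGene,
    genome: dict[str, str] | str,
    leader_len: int = 20,
    trailer_len: int = 30,
) -> PrecursorTRNA:
    """Extract leader/body/trailer strand-aware; the body stays unspliced.

    ``genome`` is either a path to the FASTA or an already-loaded dict.  At a
    contig edge the flank is truncated with a warning.
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    chrom_seq = genome[gene.chromosome]
    if gene.strand == "+":
        up = chrom_seq[max(0, gene.start - leader_len) : gene.start]
        down = chrom_seq[gene.end : gene.end + trailer_len]
        leader, trailer = up, down
    else:
        # transcript downstream is genomic left of the interval
        up = chrom_seq[gene.end : gene.end + leader_len]
        down = chrom_seq[max(0, gene.start - trailer_len) : gene.start]
        leader, trailer = revcomp(up), revcomp(down)
    if len(leader) < leader_len or len(trailer) < trailer_len:
        warnings.warn(
            f"{gene.gene_id}: flank truncated at contig edge "
            f"(leader {len(leader)}/{leader_len}, trailer {len(trailer)}/{trailer_len})"
        )
    return PrecursorTRNA(
        gene_id=gene.gene_id,
        leader=leader,
        body=gene.genomic_sequence,
        trailer=trailer,
    )
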