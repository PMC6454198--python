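"""Transcript models, GTF I/O, and the interval arithmetic shared by all genomic stages.

Coordinates are 0-based half-open internally; GTF on disk is 1-based
inclusive. Conversion happens only at the file boundary, so every distance
and overlap computation inside the package uses one convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-")

# biotype label <-> GTF transcript_biotype attribute value
_BIOTYPE_TO_GTF = {
    "coding": "protein_coding",
    "annotated_lncRNA": "lncRNA",
    "unknown": "unknown",
}
_GTF_TO_BIOTYPE = {v: k for k, v in _BIOTYPE_TO_GTF.items()}


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted; carries the line number."""


class AnnotationError(ValueError):
    """Raised when transcript/gene structure violates an invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def genomic_gap(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Number of bases strictly between two intervals.

    Returns ``None`` when the intervals sit on different chromosomes
    (distance undefined), 0 when they overlap or abut, and the base count
    of the intervening gap otherwise. Strand is ignored: the gap is a
    property of position only.
    """
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript with a biotype label."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.biotype not in _BIOTYPE_TO_GTF:
            raise AnnotationError(f"{self.transcript_id}: bad biotype {self.biotype!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for e in exons:
            if e.chrom != self.chrom:
                raise AnnotationError(
                    f"{self.transcript_id}: exon on {e.chrom}, transcript on {self.chrom}"
                )
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start < prev.end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        """Mature transcript length: sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start > prev.end:
                out.append(GenomicInterval(self.chrom, prev.end, nxt.start, self.strand))
        return out


@dataclass
class GeneModel:
    """A gene: the set of transcripts sharing one gene_id on one chromosome."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: gene needs >=1 transcript")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise AnnotationError(f"{self.gene_id}: transcripts span chromosomes {chroms}")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"{self.gene_id}: member transcript {t.transcript_id} "
                    f"carries gene_id {t.gene_id}"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Locus span: min exon start to max exon end, introns included."""
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


class GenomeAnnotation:
    """A collection of genes with per-chromosome interval lookup.

    The index holds transcript spans; queries return every transcript whose
    span overlaps the query interval (strand-blind), which brute-force
    scanning verifies in the test suite.
    """

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self.genes: dict[str, GeneModel] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.add_gene(g)

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id}")
        for t in gene.transcripts:
            if t.transcript_id in self.transcripts:
                raise AnnotationError(f"duplicate transcript_id {t.transcript_id}")
        self.genes[gene.gene_id] = gene
        for t in gene.transcripts:
            self.transcripts[t.transcript_id] = t
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            sp = t.span
            tree.addi(sp.start, sp.end, t.transcript_id)

    def __len__(self) -> int:
        return len(self.genes)

    def query(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return [self.transcripts[h.data] for h in hits]

    def gene_of(self, transcript_id: str) -> GeneModel:
        t = self.transcripts.get(transcript_id)
        if t is None:
            raise AnnotationError(f"unknown transcript {transcript_id}")
        return self.genes[t.gene_id]

    def coding_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.biotype == "coding"]

    def lnc_transcripts(self) -> list[TranscriptModel]:
        return [
            t for t in self.transcripts.values() if t.biotype == "annotated_lncRNA"
        ]


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path) -> GenomeAnnotation:
    """Parse an exon-level GTF (2.2 dialect) into a :class:`GenomeAnnotation`.

    Only ``exon`` features are used. 1-based inclusive disk coordinates are
    converted to the internal 0-based half-open convention.
    """
    per_tx: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw = cols
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise GtfParseError(
                    f"line {lineno}: strand {strand!r} not allowed (need + or -)"
                )
            attrs = _parse_attributes(raw, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon missing transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon missing gene_id")
            tid = attrs["transcript_id"]
            rec = per_tx.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": _GTF_TO_BIOTYPE.get(
                        attrs.get("transcript_biotype", "unknown"), "unknown"
                    ),
                    "exons": [],
                },
            )
            if rec["chrom"] != chrom:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} has exons on multiple chromosomes"
                )
            rec["exons"].append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, rec in per_tx.items():
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        by_gene.setdefault(tx.gene_id, []).append(tx)
    return GenomeAnnotation(
        GeneModel(gene_id=gid, transcripts=txs) for gid, txs in by_gene.items()
    )


def write_gtf(ann: GenomeAnnotation, path) -> None:
    """Emit exon records, converting back to 1-based inclusive coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in ann.genes.values():
            for tx in gene.transcripts:
                bt = _BIOTYPE_TO_GTF[tx.biotype]
                for i, e in enumerate(tx.exons, start=1):
                    attrs = (
                        f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'exon_number "{i}"; transcript_biotype "{bt}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                tx.chrom,
                                "lncpair",
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                tx.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def iter_transcripts(ann: GenomeAnnotation) -> Iterator[TranscriptModel]:
    yield from ann.transcripts.values()
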