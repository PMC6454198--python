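"""Raw-read filtering and clean-data quality summaries (Q20/Q30/GC).

A read is removed under the first failing rule, in order: (a) the adapter
occurs as an exact substring; (b) the N fraction exceeds a cap; (c) the
fraction of bases at or below a low-quality Phred score exceeds a cap.
Thresholds are configurable; the defaults are conventional vendor-style QC
settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_ADAPTER = "AGATCGGAAGAGC"
DEFAULT_MAX_N_FRAC = 0.10
DEFAULT_LOW_QUAL_PHRED = 5
DEFAULT_LOW_QUAL_FRAC = 0.5


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise FastqFormatError(
                f"{self.id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )


@dataclass
class FilterReport:
    adapter: int = 0
    poly_n: int = 0
    low_quality: int = 0
    clean: int = 0

    @property
    def total(self) -> int:
        return self.adapter + self.poly_n + self.low_quality + self.clean

    def as_dict(self) -> dict[str, int]:
        return {
            "adapter": self.adapter,
            "poly_n": self.poly_n,
            "low_quality": self.low_quality,
            "clean": self.clean,
        }


@dataclass
class QCStats:
    n_reads: int
    total_bases: int
    q20_frac: Optional[float]
    q30_frac: Optional[float]
    gc_frac: Optional[float]


def read_fastq(path) -> Iterator[ReadRecord]:
    with open(path, encoding="ascii") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(
                id=title.split()[0],
                seq=seq.upper(),
                quals=tuple(ord(c) - 33 for c in qual),
            )


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")


def filter_reads(
    reads: Iterable[ReadRecord],
    adapter: str = DEFAULT_ADAPTER,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
    low_qual_phred: int = DEFAULT_LOW_QUAL_PHRED,
    low_qual_frac: float = DEFAULT_LOW_QUAL_FRAC,
) -> tuple[list[ReadRecord], FilterReport]:
    """Split a read stream into clean survivors and per-rule removal counts."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    for frac in (max_n_frac, low_qual_frac):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    report = FilterReport()
    clean: list[ReadRecord] = []
    for r in reads:
        if adapter in r.seq:
            report.adapter += 1
        elif r.seq and r.seq.count("N") / len(r.seq) > max_n_frac:
            report.poly_n += 1
        elif r.quals and (
            sum(1 for q in r.quals if q <= low_qual_phred) / len(r.quals)
            > low_qual_frac
        ):
            report.low_quality += 1
        else:
            report.clean += 1
            clean.append(r)
    return clean, report


def summarize_quality(reads: Iterable[ReadRecord]) -> QCStats:
    """Per-base tallies: read/base totals, Q20, Q30, and GC fractions.

    GC is computed over called (non-N) bases. An empty stream reports the
    fractions as missing rather than zero.
    """
    n_reads = 0
    total_bases = 0
    q20 = q30 = 0
    gc = called = 0
    for r in reads:
        n_reads += 1
        total_bases += len(r.seq)
        for q in r.quals:
            if q >= 20:
                q20 += 1
            if q >= 30:
                q30 += 1
        for b in r.seq:
            if b != "N":
                called += 1
                if b in "GC":
                    gc += 1
    if total_bases == 0:
        return QCStats(n_reads=n_reads, total_bases=0,
                       q20_frac=None, q30_frac=None, gc_frac=None)
    return QCStats(
        n_reads=n_reads,
        total_bases=total_bases,
        q20_frac=q20 / total_bases,
        q30_frac=q30 / total_bases,
        gc_frac=gc / called if called else None,
    )
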