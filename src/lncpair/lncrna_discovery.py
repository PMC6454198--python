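"""The five-step lncRNA filtration cascade and positional classification.

Candidates from transcript assembly are filtered in strict order:

1. exon count >= 2;
2. mature length > 200 bp;
3. comparison with the reference annotation — same-strand exonic overlap
   with a coding exon eliminates the candidate, exonic overlap with an
   annotated lncRNA labels it as such (it still has to be expressed);
4. expression: FPKM at or above a floor (max across samples by default);
5. coding potential: predicted coding by any predictor makes the survivor
   a TUCP (transcript of uncertain coding potential); by none, a novel
   lncRNA.

Strandedness of step 3 is deliberate: an opposite-strand exonic overlap
must survive to be classifiable as an antisense lncRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .annotation_io import GenomeAnnotation, TranscriptModel

DEFAULT_MIN_EXONS = 2
DEFAULT_MIN_LEN = 200
DEFAULT_MIN_FPKM = 0.5

OUTCOMES = ("novel_lncRNA", "annotated_lncRNA", "TUCP", "rejected")
STEP_NAMES = ("exon_count", "length", "coding_exon_overlap", "expression")

_STOPS = {"TAA", "TAG", "TGA"}


class DiscoveryInputError(ValueError):
    pass


@dataclass
class FiltrationReport:
    """Per-candidate outcome plus survivor counts along the cascade."""

    outcome: dict[str, str] = field(default_factory=dict)
    first_failing_step: dict[str, str] = field(default_factory=dict)
    survivors_per_step: dict[str, int] = field(default_factory=dict)

    def of(self, outcome: str) -> list[str]:
        return sorted(t for t, o in self.outcome.items() if o == outcome)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": t,
                "outcome": o,
                "first_failing_step": self.first_failing_step.get(t, "."),
            }
            for t, o in sorted(self.outcome.items())
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "outcome",
                                           "first_failing_step"])


def _exonic_overlap(tx: TranscriptModel, other: TranscriptModel,
                    same_strand: Optional[bool] = None) -> bool:
    """>=1 bp of exon-exon intersection; optionally strand-restricted."""
    if tx.chrom != other.chrom:
        return False
    if same_strand is True and tx.strand != other.strand:
        return False
    if same_strand is False and tx.strand == other.strand:
        return False
    for a in tx.exons:
        for b in other.exons:
            if a.start < b.end and b.start < a.end:
                return True
    return False


def filter_candidates(
    candidates: Iterable[TranscriptModel],
    ann: GenomeAnnotation,
    fpkm: pd.DataFrame,
    calls: Optional[pd.DataFrame],
    min_exons: int = DEFAULT_MIN_EXONS,
    min_len: int = DEFAULT_MIN_LEN,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    expression_rule: str = "max",
) -> FiltrationReport:
    """Run the cascade; ``calls`` is a boolean transcript x predictor frame.

    Outcomes partition the candidate set exhaustively. ``expression_rule``
    selects whether the FPKM floor applies to the per-sample maximum
    (default, permissive) or the mean.
    """
    if expression_rule not in ("max", "mean"):
        raise ValueError("expression_rule must be 'max' or 'mean'")
    candidates = list(candidates)
    report = FiltrationReport()
    n_in = len(candidates)
    survivors = {name: 0 for name in STEP_NAMES + ("coding_potential",)}

    for tx in candidates:
        tid = tx.transcript_id
        # step 1: exon count
        if tx.n_exons < min_exons:
            report.outcome[tid] = "rejected"
            report.first_failing_step[tid] = "exon_count"
            continue
        survivors["exon_count"] += 1
        # step 2: mature length
        if tx.length <= min_len:
            report.outcome[tid] = "rejected"
            report.first_failing_step[tid] = "length"
            continue
        survivors["length"] += 1
        # step 3: reference comparison
        sp = tx.span
        nearby = ann.query(tx.chrom, sp.start, sp.end)
        annotated_match = False
        eliminated = False
        for other in nearby:
            if other.biotype == "coding":
                if other.transcript_id != tid and \
                        _exonic_overlap(tx, other, same_strand=True):
                    eliminated = True
                    break
            elif other.biotype == "annotated_lncRNA":
                # the candidate being the annotation's own record counts
                # as a match, as does any exonic overlap with one
                if other.transcript_id == tid or _exonic_overlap(tx, other):
                    annotated_match = True
        if eliminated:
            report.outcome[tid] = "rejected"
            report.first_failing_step[tid] = "coding_exon_overlap"
            continue
        survivors["coding_exon_overlap"] += 1
        # step 4: expression
        if tid not in fpkm.index:
            raise DiscoveryInputError(f"candidate {tid} has no FPKM row")
        row = fpkm.loc[tid]
        level = row.max() if expression_rule == "max" else row.mean()
        if level < min_fpkm:
            report.outcome[tid] = "rejected"
            report.first_failing_step[tid] = "expression"
            continue
        survivors["expression"] += 1
        if annotated_match:
            # expressed match to a known lncRNA: no coding-potential step
            report.outcome[tid] = "annotated_lncRNA"
            continue
        # step 5: coding potential
        if calls is None or tid not in calls.index:
            raise DiscoveryInputError(f"candidate {tid} has no coding-potential call")
        verdicts = calls.loc[tid]
        if len(verdicts) == 0:
            raise DiscoveryInputError(f"candidate {tid}: empty coding call")
        report.outcome[tid] = "TUCP" if bool(verdicts.any()) else "novel_lncRNA"
        survivors["coding_potential"] += 1

    report.survivors_per_step = {"input": n_in, **survivors}
    return report


def classify_positional(lnc: TranscriptModel, ann: GenomeAnnotation) -> str:
    """lincRNA / antisense / intronic, with precedence antisense > intronic.

    Antisense: any exon of the lncRNA overlaps a coding exon on the
    opposite strand. Intronic: the lncRNA lies entirely inside one intron
    of a coding transcript with no exonic overlap. Everything else is
    lincRNA.
    """
    sp = lnc.span
    coding = [t for t in ann.query(lnc.chrom, sp.start, sp.end)
              if t.biotype == "coding"]
    for tx in coding:
        if _exonic_overlap(lnc, tx, same_strand=False):
            return "antisense"
    for tx in coding:
        if _exonic_overlap(lnc, tx):
            continue
        for intron in tx.introns():
            if intron.start <= sp.start and sp.end <= intron.end:
                return "intronic"
    return "lincRNA"


def orf_coding_heuristic(seq: str, min_orf_aa: int = 100) -> bool:
    """Simple built-in coding-potential predictor.

    True iff any of the three forward frames contains an ATG-initiated run
    of at least ``min_orf_aa`` codons before a stop (or the end of the
    sequence). The codon count includes the initiator methionine.
    """
    seq = seq.upper()
    best = 0
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        run = 0
        in_orf = False
        for codon in codons:
            if codon in _STOPS:
                best = max(best, run)
                run = 0
                in_orf = False
            elif in_orf:
                run += 1
            elif codon == "ATG":
                in_orf = True
                run = 1
        best = max(best, run)
    return best >= min_orf_aa


def summarize_lnc_features(lncs: Iterable[TranscriptModel],
                           mrnas: Iterable[TranscriptModel],
                           fpkm: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Five-number-plus-mean summaries of length, exon count, and FPKM per class."""
    def _summary(values: pd.Series, cls: str, what: str) -> dict:
        q = values.quantile([0, 0.25, 0.5, 0.75, 1.0])
        return {
            "class": cls, "metric": what, "n": len(values),
            "min": q.iloc[0], "q25": q.iloc[1], "median": q.iloc[2],
            "q75": q.iloc[3], "max": q.iloc[4], "mean": values.mean(),
        }

    rows = []
    for cls, txs in (("lncRNA", list(lncs)), ("mRNA", list(mrnas))):
        if not txs:
            raise DiscoveryInputError(f"no transcripts supplied for {cls}")
        lengths = pd.Series([t.length for t in txs], dtype=float)
        exons = pd.Series([t.n_exons for t in txs], dtype=float)
        rows.append(_summary(lengths, cls, "length"))
        rows.append(_summary(exons, cls, "exon_count"))
        if fpkm is not None:
            ids = [t.transcript_id for t in txs if t.transcript_id in fpkm.index]
            if ids:
                rows.append(_summary(fpkm.loc[ids].mean(axis=1), cls, "fpkm"))
    return pd.DataFrame(rows)
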