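"""Expression matrices: FPKM from counts, and gene-level aggregation.

FPKM here is the plain definition: fragments per kilobase of exon per
million mapped fragments, with the mature transcript length (sum of exon
lengths) in the denominator. Gene-level values are the sum of member
transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation_io import GenomeAnnotation


class ExpressionError(ValueError):
    pass


@dataclass
class StudyDesign:
    """Sample-to-group assignment plus the ordered list of comparisons.

    Comparisons are (B, A) pairs read as "B vs A": fold changes are B
    relative to A.
    """

    samples: list[str]
    group_of: dict[str, str]
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.samples:
            if s not in self.group_of:
                raise ExpressionError(f"sample {s} has no group")
        groups = set(self.group_of[s] for s in self.samples)
        for b, a in self.comparisons:
            if b == a:
                raise ExpressionError(f"comparison {b!r} vs itself")
            for g in (b, a):
                if g not in groups:
                    raise ExpressionError(f"comparison names unknown group {g!r}")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   comparisons: Optional[list[tuple[str, str]]] = None
                   ) -> "StudyDesign":
        """Build from a two-column (sample, group) table.

        When ``comparisons`` is omitted, all ordered pairs of groups in
        first-appearance order are used: (g2,g1), (g3,g1), (g2,g3) for a
        three-group design.
        """
        samples = df.iloc[:, 0].astype(str).tolist()
        group_of = dict(zip(samples, df.iloc[:, 1].astype(str)))
        design = cls(samples=samples, group_of=group_of, comparisons=[])
        if comparisons is None:
            g = design.groups
            if len(g) == 2:
                comparisons = [(g[1], g[0])]
            elif len(g) >= 3:
                comparisons = [(g[1], g[0]), (g[2], g[0]), (g[1], g[2])]
            else:
                comparisons = []
        design.comparisons = comparisons
        design.__post_init__()
        return design


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with feature lengths.

    ``library_sizes`` defaults to the per-sample column sums, standing in
    for total mapped fragments when no alignment totals are available.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ExpressionError("negative counts")
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ExpressionError(f"features without lengths: {list(missing)[:5]}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """FPKM[f, s] = counts[f, s] * 1e9 / (length[f] * library_size[s])."""
    if (cm.lengths <= 0).any():
        raise ExpressionError("feature lengths must be > 0")
    if (cm.library_sizes <= 0).any():
        raise ExpressionError("library sizes must be > 0")
    denom = np.outer(cm.lengths.to_numpy(dtype=float),
                     cm.library_sizes.to_numpy(dtype=float))
    fpkm = cm.counts.to_numpy(dtype=float) * 1e9 / denom
    return pd.DataFrame(fpkm, index=cm.counts.index, columns=cm.counts.columns)


def gene_level_fpkm(fpkm: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Sum member-transcript FPKM per gene, per sample."""
    gene_of = {}
    for tid in fpkm.index:
        tx = ann.transcripts.get(tid)
        if tx is None:
            raise ExpressionError(f"transcript {tid} not in annotation")
        gene_of[tid] = tx.gene_id
    out = fpkm.groupby([gene_of[t] for t in fpkm.index]).sum()
    out.index.name = "gene_id"
    return out


def gene_level_counts(cm: CountMatrix, ann: GenomeAnnotation) -> CountMatrix:
    """Sum transcript counts per gene; gene length = max member length.

    The length choice only matters for gene-level FPKM reporting, which the
    pipeline does not use (gene FPKM comes from summing transcript FPKM).
    """
    gene_of = {}
    for tid in cm.counts.index:
        tx = ann.transcripts.get(tid)
        if tx is None:
            raise ExpressionError(f"transcript {tid} not in annotation")
        gene_of[tid] = tx.gene_id
    counts = cm.counts.groupby([gene_of[t] for t in cm.counts.index]).sum()
    counts.index.name = "gene_id"
    lengths = cm.lengths.groupby([gene_of[t] for t in cm.lengths.index]).max()
    return CountMatrix(counts=counts, lengths=lengths,
                       library_sizes=cm.library_sizes)
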