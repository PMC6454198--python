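"""Co-expression and co-localization edges between DE lncRNAs and DE mRNAs.

Co-expression: Pearson correlation over ALL samples (not per comparison;
a pair has one r regardless of which comparison flagged its members as
DE), with a two-sided t test on n-2 degrees of freedom. Co-localization:
genomic gap between the lncRNA transcript span and the mRNA gene span,
within a cis window, oriented relative to the mRNA's strand. A candidate
interaction is a pair carrying both kinds of edge; candidates shared by
every inter-group comparison are the headline output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GenomeAnnotation, genomic_gap

DEFAULT_MIN_ABS_R = 0.95
DEFAULT_MAX_P = 1e-4
DEFAULT_WINDOW = 100_000

_MIN_P = float(np.nextafter(0, 1))


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CoexpressionEdge:
    lnc_id: str
    mrna_id: str
    r: float
    p: float


@dataclass(frozen=True)
class ColocalizationEdge:
    lnc_id: str
    mrna_id: str
    distance_bp: int
    location: str  # upstream / downstream / overlapping, lncRNA to mRNA


@dataclass(frozen=True)
class InteractionCandidate:
    lnc_id: str
    mrna_id: str
    coexpression: CoexpressionEdge
    colocalization: ColocalizationEdge
    comparisons: tuple[str, ...] = ()

    @property
    def pair(self) -> tuple[str, str]:
        return (self.lnc_id, self.mrna_id)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r at n observations (t, df = n-2)."""
    if n < 3:
        raise CorrelationError("need n >= 3")
    if abs(r) >= 1.0:
        return _MIN_P
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(np.clip(2.0 * stats.t.sf(abs(t), df), _MIN_P, 1.0))


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise CorrelationError("need n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise CorrelationError("undefined correlation: zero variance")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    return r, pearson_pvalue(r, n)


def coexpression_edges(
    de_lnc: Iterable[str],
    de_mrna: Iterable[str],
    expr: pd.DataFrame,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
    max_p: float = DEFAULT_MAX_P,
) -> list[CoexpressionEdge]:
    """Test every DElnc x DEmRNA pair over all samples; keep passing edges.

    Pairs with an undefined correlation (a constant profile) are skipped.
    """
    de_lnc, de_mrna = sorted(set(de_lnc)), sorted(set(de_mrna))
    for fid in (*de_lnc, *de_mrna):
        if fid not in expr.index:
            raise CorrelationError(f"feature {fid} missing from expression matrix")
    mat = expr.loc[[*de_lnc, *de_mrna]].to_numpy(dtype=float)
    edges = []
    for i, lnc in enumerate(de_lnc):
        x = mat[i]
        for j, mrna in enumerate(de_mrna):
            y = mat[len(de_lnc) + j]
            try:
                r, p = pearson_test(x, y)
            except CorrelationError:
                continue
            if abs(r) >= min_abs_r and p <= max_p:
                edges.append(CoexpressionEdge(lnc, mrna, r, p))
    return edges


def _locate(lnc_span, mrna_span, gap: int) -> str:
    if gap == 0:
        return "overlapping"
    lnc_is_right = lnc_span.start >= mrna_span.end
    if mrna_span.strand == "+":
        return "downstream" if lnc_is_right else "upstream"
    return "upstream" if lnc_is_right else "downstream"


def colocalization_edges(
    de_lnc: Iterable[str],
    de_mrna: Iterable[str],
    ann: GenomeAnnotation,
    window: int = DEFAULT_WINDOW,
) -> list[ColocalizationEdge]:
    """Same-chromosome pairs with a genomic gap at most ``window`` bp.

    The lncRNA feature is a transcript (its span), the mRNA a gene (its
    locus span); upstream/downstream follow the mRNA's reading direction.
    """
    edges = []
    for lnc, mrna in product(sorted(set(de_lnc)), sorted(set(de_mrna))):
        if lnc not in ann.transcripts:
            raise CorrelationError(f"lncRNA {lnc} not in annotation")
        if mrna not in ann.genes:
            raise CorrelationError(f"mRNA gene {mrna} not in annotation")
        lnc_span = ann.transcripts[lnc].span
        mrna_span = ann.genes[mrna].span
        gap = genomic_gap(lnc_span, mrna_span)
        if gap is None or gap > window:
            continue
        edges.append(
            ColocalizationEdge(lnc, mrna, gap, _locate(lnc_span, mrna_span, gap))
        )
    return edges


def overlap_interactions(
    coexp: Iterable[CoexpressionEdge],
    coloc: Iterable[ColocalizationEdge],
) -> list[InteractionCandidate]:
    """Pairs carrying both a co-expression and a co-localization edge."""
    by_pair = {(e.lnc_id, e.mrna_id): e for e in coloc}
    out = []
    for e in coexp:
        other = by_pair.get((e.lnc_id, e.mrna_id))
        if other is not None:
            out.append(InteractionCandidate(e.lnc_id, e.mrna_id, e, other))
    return out


def intersect_across_comparisons(
    per_comparison: Mapping[str, Sequence[InteractionCandidate]],
) -> list[InteractionCandidate]:
    """Candidates present in every comparison's list, comparisons attached."""
    if not per_comparison:
        raise ValueError("need at least one comparison")
    labels = list(per_comparison)
    shared = None
    for label in labels:
        pairs = {c.pair for c in per_comparison[label]}
        shared = pairs if shared is None else shared & pairs
    first = {c.pair: c for c in per_comparison[labels[0]]}
    return [
        InteractionCandidate(
            p[0], p[1], first[p].coexpression, first[p].colocalization,
            comparisons=tuple(labels),
        )
        for p in sorted(shared)
    ]


def venn_counts(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive membership-region counts for 2 or 3 labelled sets."""
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError("venn_counts supports exactly 2 or 3 sets")
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    from itertools import combinations
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            regions[combo] = 0
    for el in universe:
        membership = tuple(lb for lb in labels if el in sets[lb])
        regions[membership] += 1
    return regions


def candidates_to_frame(cands: Iterable[InteractionCandidate]) -> pd.DataFrame:
    rows = [
        {
            "lnc_id": c.lnc_id,
            "mrna_id": c.mrna_id,
            "r": c.coexpression.r,
            "p": c.coexpression.p,
            "distance_bp": c.colocalization.distance_bp,
            "location": c.colocalization.location,
            "comparisons": ";".join(c.comparisons) if c.comparisons else ".",
        }
        for c in cands
    ]
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "r", "p",
                                       "distance_bp", "location", "comparisons"])
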