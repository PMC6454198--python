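"""Hypergeometric over-representation analysis with BH correction.

A study gene set is tested against each term's membership within a
declared universe: p = P[X >= k] for X ~ Hypergeometric(N, K, n). The
rich factor k/K (study hits over annotated term size) accompanies each
row. Terms with fewer than two universe members are untestable and
skipped (counted in the result's attrs).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


class EnrichmentInputError(ValueError):
    pass


def hypergeom_enrich(
    study: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    term_names: Mapping[str, str] | None = None,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per term, BH-adjusted across terms."""
    universe = set(universe)
    if not universe:
        raise EnrichmentInputError("empty universe")
    study = set(study)
    if not study <= universe:
        extra = sorted(study - universe)[:5]
        raise EnrichmentInputError(f"study genes outside universe: {extra}")
    n, big_n = len(study), len(universe)

    rows = []
    skipped = 0
    for term, members in terms.items():
        members = set(members) & universe
        big_k = len(members)
        if big_k < min_term_size:
            skipped += 1
            continue
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term": term,
                "name": term_names.get(term, ".") if term_names else ".",
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "rich_factor": k / big_k,
                "p": min(max(p, 0.0), 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N", "rich_factor", "p"]
    )
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["padj", "p"], kind="stable").reset_index(drop=True)
    else:
        out["padj"] = pd.Series(dtype=float)
    out.attrs["n_untestable"] = skipped
    return out


def read_term_map(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Load a (term_id, term_name, gene_id) TSV, one row per membership."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for _, row in df.iterrows():
        terms.setdefault(row.iloc[0], set()).add(row.iloc[2])
        names[row.iloc[0]] = row.iloc[1]
    return terms, names
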