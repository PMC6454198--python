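"""Bundled validation tables from the tongue sole DHA/EPA feeding study.

Three small published tables ship with the package so that the worked
examples can be recomputed without the raw sequencing archive: the dietary
fatty-acid composition (percent of total fatty acids, per diet), the
per-group clean-read totals, and the published lncRNA-mRNA interaction
matches (co-expression r and p, co-localization distance and location,
per inter-group comparison).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("lncpair.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_diet_composition() -> pd.DataFrame:
    """Fatty-acid percentages indexed by fatty-acid name, one column per diet."""
    return _load("diet_fatty_acids.tsv").set_index("fatty_acid")


def load_clean_read_totals() -> pd.DataFrame:
    """Per-group clean-read counts and read length for the sequenced libraries."""
    return _load("clean_read_totals.tsv").set_index("group")


def load_interaction_matches() -> pd.DataFrame:
    """Published per-comparison lncRNA-mRNA matches (r, p, distance, location)."""
    df = _load("published_interaction_matches.tsv")
    df["mrna_id"] = df["mrna_id"].astype(str)
    return df
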