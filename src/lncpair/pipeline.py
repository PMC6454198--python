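"""End-to-end orchestration: discover -> FPKM -> DE -> edges -> overlap -> enrich.

The pipeline consumes a candidate GTF, a reference annotation GTF, a
transcript count table (with a length column), a study design, optional
coding-potential calls, and optional term maps; it persists every
intermediate table as TSV under one output directory together with a run
manifest. Interaction analysis pairs transcript-level lncRNA features
with gene-level mRNA features.

Also houses the diet-composition arithmetic used for the study's
fixture metadata (the DHA/EPA ratio that labels each dietary group).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotation_io import GenomeAnnotation, read_gtf
from .diffexpr import DEFAULT_ALPHA, call_de, estimate_dispersion, \
    estimate_size_factors, nb_test
from .enrichment import hypergeom_enrich, read_term_map
from .expression import CountMatrix, StudyDesign, compute_fpkm, \
    gene_level_counts, gene_level_fpkm
from .interaction import DEFAULT_MAX_P, DEFAULT_MIN_ABS_R, DEFAULT_WINDOW, \
    candidates_to_frame, coexpression_edges, colocalization_edges, \
    intersect_across_comparisons, overlap_interactions, venn_counts
from .lncrna_discovery import DEFAULT_MIN_EXONS, DEFAULT_MIN_FPKM, \
    DEFAULT_MIN_LEN, classify_positional, filter_candidates

logger = logging.getLogger("lncpair")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    candidates_gtf: Path
    annotation_gtf: Path
    counts_tsv: Path
    design_tsv: Path
    out_dir: Path
    coding_calls_tsv: Optional[Path] = None
    term_map_tsv: Optional[Path] = None
    min_exons: int = DEFAULT_MIN_EXONS
    min_len: int = DEFAULT_MIN_LEN
    min_fpkm: float = DEFAULT_MIN_FPKM
    de_alpha: float = DEFAULT_ALPHA
    min_abs_r: float = DEFAULT_MIN_ABS_R
    max_p: float = DEFAULT_MAX_P
    window: int = DEFAULT_WINDOW
    seed: int = 0

    def as_manifest_dict(self) -> dict[str, str]:
        return {k: str(v) for k, v in vars(self).items()}


@dataclass
class ResultBundle:
    filtration: pd.DataFrame
    lnc_classes: pd.DataFrame
    de_tables: dict[str, dict[str, pd.DataFrame]]  # kind -> comparison -> table
    de_counts: dict[str, dict[str, dict[str, int]]]
    candidates: dict[str, pd.DataFrame]
    shared_candidates: pd.DataFrame
    venn: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)


def read_counts_tsv(path) -> CountMatrix:
    """Counts TSV: feature id column, a ``length`` column, then samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError("counts table needs a 'length' column")
    lengths = df["length"].astype(int)
    counts = df.drop(columns=["length"]).astype(int)
    return CountMatrix(counts=counts, lengths=lengths)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.to_csv(path, sep="\t")


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=".")


def _venn_frame(regions: dict[tuple[str, ...], int]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"region": "&".join(k), "count": v} for k, v in sorted(regions.items())]
    )


def run_pipeline(cfg: PipelineConfig) -> ResultBundle:
    """Execute every stage in order and persist all tables under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "load"
        candidates_ann = read_gtf(cfg.candidates_gtf)
        ref_ann = read_gtf(cfg.annotation_gtf)
        cm = read_counts_tsv(cfg.counts_tsv)
        design = StudyDesign.from_table(pd.read_csv(cfg.design_tsv, sep="\t"))
        calls = None
        if cfg.coding_calls_tsv is not None:
            calls = pd.read_csv(cfg.coding_calls_tsv, sep="\t", index_col=0).astype(bool)

        stage = "fpkm"
        fpkm = compute_fpkm(cm)
        _write(fpkm, out / "fpkm_transcripts.tsv", index=True)

        stage = "discover"
        cand_txs = list(candidates_ann.transcripts.values())
        report = filter_candidates(
            cand_txs, ref_ann, fpkm, calls,
            min_exons=cfg.min_exons, min_len=cfg.min_len, min_fpkm=cfg.min_fpkm,
        )
        filtration = report.to_frame()
        _write(filtration, out / "filtration_report.tsv")
        lnc_ids = report.of("novel_lncRNA") + report.of("annotated_lncRNA")
        classes = pd.DataFrame(
            [
                {"lnc_id": t,
                 "class": classify_positional(candidates_ann.transcripts[t], ref_ann)}
                for t in lnc_ids
            ],
            columns=["lnc_id", "class"],
        )
        _write(classes, out / "lnc_classes.tsv")
        logger.info("discovery: %s", report.survivors_per_step)

        stage = "merge-annotation"
        merged = GenomeAnnotation(list(ref_ann.genes.values()))
        for gene in candidates_ann.genes.values():
            if gene.gene_id not in merged.genes:
                merged.add_gene(gene)

        stage = "de"
        known = [f for f in cm.counts.index if f in merged.transcripts]
        cm_known = CountMatrix(counts=cm.counts.loc[known],
                               lengths=cm.lengths.loc[known],
                               library_sizes=cm.library_sizes)
        gene_cm = gene_level_counts(cm_known, merged)
        mrna_genes = sorted(
            {t.gene_id for t in ref_ann.coding_transcripts()
             if t.gene_id in gene_cm.counts.index}
        )
        tucp_ids = report.of("TUCP")
        de_tables: dict[str, dict[str, pd.DataFrame]] = {"lncRNA": {}, "mRNA": {},
                                                         "TUCP": {}}
        de_counts: dict[str, dict[str, dict[str, int]]] = {"lncRNA": {}, "mRNA": {},
                                                           "TUCP": {}}
        sf_tx = estimate_size_factors(cm.counts)
        phi_tx = estimate_dispersion(cm.counts, design, sf_tx)
        sf_gene = estimate_size_factors(gene_cm.counts)
        phi_gene = estimate_dispersion(gene_cm.counts, design, sf_gene)
        for comp in design.comparisons:
            label = f"{comp[0]} vs {comp[1]}"
            res_tx = nb_test(cm.counts, design, comp, phi_tx, sf_tx)
            res_gene = nb_test(gene_cm.counts, design, comp, phi_gene, sf_gene)
            for kind, ids, res in (
                ("lncRNA", lnc_ids, res_tx),
                ("TUCP", tucp_ids, res_tx),
                ("mRNA", mrna_genes, res_gene),
            ):
                ids = [i for i in ids if i in res.index]
                table, counts = call_de(res.loc[ids], comp, cfg.de_alpha)
                de_tables[kind][label] = table
                de_counts[kind][label] = counts
                fname = f"de_{kind}_{label.replace(' ', '_').replace('/', '-')}.tsv"
                _write(table, out / fname, index=True)
            logger.info(
                "%s: lncRNA up/down %d/%d  mRNA up/down %d/%d  TUCP up/down %d/%d",
                label,
                de_counts["lncRNA"][label]["up"], de_counts["lncRNA"][label]["down"],
                de_counts["mRNA"][label]["up"], de_counts["mRNA"][label]["down"],
                de_counts["TUCP"][label]["up"], de_counts["TUCP"][label]["down"],
            )

        stage = "interaction"
        gene_fpkm = gene_level_fpkm(fpkm.loc[known], merged)
        expr = pd.concat([fpkm.loc[[i for i in lnc_ids if i in fpkm.index]],
                          gene_fpkm.loc[mrna_genes]])
        per_comp_candidates: dict[str, list] = {}
        candidate_frames: dict[str, pd.DataFrame] = {}
        for comp in design.comparisons:
            label = f"{comp[0]} vs {comp[1]}"
            de_lnc = set(de_tables["lncRNA"][label]
                         .query("is_de").index)
            de_mrna = set(de_tables["mRNA"][label].query("is_de").index)
            coexp = coexpression_edges(de_lnc, de_mrna, expr,
                                       cfg.min_abs_r, cfg.max_p)
            coloc = colocalization_edges(de_lnc, de_mrna, merged, cfg.window)
            cands = overlap_interactions(coexp, coloc)
            per_comp_candidates[label] = cands
            frame = candidates_to_frame(cands)
            candidate_frames[label] = frame
            slug = label.replace(" ", "_").replace("/", "-")
            _write(frame, out / f"candidates_{slug}.tsv")
            logger.info("%s: coexpression %d, colocalization %d, overlap %d",
                        label, len(coexp), len(coloc), len(cands))

        shared = intersect_across_comparisons(per_comp_candidates) \
            if per_comp_candidates else []
        shared_frame = candidates_to_frame(shared)
        _write(shared_frame, out / "candidates_shared.tsv")

        stage = "venn"
        venn: dict[str, pd.DataFrame] = {}
        labels = list(per_comp_candidates)
        if len(labels) in (2, 3):
            for kind in ("lncRNA", "mRNA"):
                sets = {
                    lb: set(de_tables[kind][lb].query("is_de").index)
                    for lb in labels
                }
                venn[kind] = _venn_frame(venn_counts(sets))
                _write(venn[kind], out / f"venn_{kind}.tsv")

        stage = "enrich"
        enrichment: dict[str, pd.DataFrame] = {}
        if cfg.term_map_tsv is not None:
            terms, names = read_term_map(cfg.term_map_tsv)
            universe = set(gene_fpkm.index[(gene_fpkm >= cfg.min_fpkm).any(axis=1)])
            universe &= set(mrna_genes)
            for label, frame in candidate_frames.items():
                study = set(frame["mrna_id"].astype(str)) & universe
                table = hypergeom_enrich(study, terms, universe, names)
                enrichment[label] = table
                slug = label.replace(" ", "_").replace("/", "-")
                _write(table, out / f"enrichment_{slug}.tsv")

        stage = "manifest"
        manifest = {
            "lncpair_version": __version__,
            "python": sys.version.split()[0],
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            **cfg.as_manifest_dict(),
        }
        with open(out / "manifest.txt", "w", encoding="utf-8") as fh:
            for k, v in manifest.items():
                fh.write(f"{k}\t{v}\n")

        return ResultBundle(
            filtration=filtration,
            lnc_classes=classes,
            de_tables=de_tables,
            de_counts=de_counts,
            candidates=candidate_frames,
            shared_candidates=shared_frame,
            venn=venn,
            enrichment=enrichment,
            manifest=manifest,
        )
    except PipelineStageError:
        raise
    except Exception as exc:
        (Path(cfg.out_dir) / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineStageError(stage, exc) from exc


def diet_ratio(table: pd.DataFrame, numerator: str, denominator: str,
               diet: str) -> tuple[float, float]:
    """Ratio of two fatty-acid percentages for one diet.

    Returns (full precision, rounded to 2 decimals), e.g. the DHA/EPA
    ratio C22:6n-3 / C20:5n-3 that names each dietary group.
    """
    for fa in (numerator, denominator):
        if fa not in table.index:
            raise KeyError(f"fatty acid {fa!r} not in composition table")
    if diet not in table.columns:
        raise KeyError(f"diet {diet!r} not in composition table")
    den = float(table.loc[denominator, diet])
    if den == 0:
        raise ZeroDivisionError(f"{denominator} is zero for diet {diet}")
    ratio = float(table.loc[numerator, diet]) / den
    return ratio, round(ratio, 2)
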