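"""Synthetic study generator: annotation, counts, and reads with a truth ledger.

The generator emulates the study conditions the pipeline is built for: a
3-group x 3-replicate RNA-seq design over a compact genome in which a
handful of lncRNA loci sit at controlled genomic distances from coding
genes, are strongly differentially expressed between diet groups, and are
tightly co-expressed with their neighbouring mRNA. Everything else is decoy
structure: coding genes and lncRNA loci placed farther than any plausible
cis-regulation window from each other, with or without planted fold
changes.

Geometry is exact by construction (the ledger's distances and locations are
recomputable from the emitted annotation); expression is stochastic but
reproducible from the master seed, with one RNG stream per artifact type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)
from .expression import CountMatrix, StudyDesign

# gene slots every 300 kb keep non-planted loci far outside any window
_SLOT = 300_000
_SLOT_OFFSET = 150_000
_DECOY_GAP = 140_000
MAX_PLANT_DISTANCE = 120_000

_RNG_ANNOTATION = 11
_RNG_COUNTS = 23
_RNG_READS = 37

FAILURE_KINDS = (
    "single_exon",
    "short",
    "coding_overlap",
    "low_expression",
    "coding_potential",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally unsatisfiable."""


@dataclass(frozen=True)
class PlantedPair:
    """A lncRNA-mRNA pair with planted geometry, fold changes, and coupling.

    ``location`` is the lncRNA's position relative to the mRNA in the
    mRNA's strand orientation (upstream / downstream / overlapping);
    ``target_r`` is the Pearson correlation of log-expression the latent
    coupling aims for.
    """

    lnc_index: int
    mrna_index: int
    distance_bp: int
    location: str
    target_r: float = 0.99

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ConfigurationError("planted distance must be >= 0")
        if abs(self.target_r) > 1:
            raise ConfigurationError("|target_r| must be <= 1")
        if self.location not in ("upstream", "downstream", "overlapping"):
            raise ConfigurationError(f"bad location {self.location!r}")
        if self.location == "overlapping" and self.distance_bp != 0:
            raise ConfigurationError("overlapping pairs must have distance 0")
        if self.location != "overlapping" and self.distance_bp == 0:
            raise ConfigurationError("distance 0 implies location 'overlapping'")


@dataclass(frozen=True)
class ReadFixtureConfig:
    """Per-rule read counts for the FASTQ fixture."""

    n_clean: int = 80
    n_adapter: int = 10
    n_poly_n: int = 5
    n_low_quality: int = 5
    read_length: int = 100
    adapter: str = "AGATCGGAAGAGC"

    def __post_init__(self) -> None:
        for n in (self.n_clean, self.n_adapter, self.n_poly_n, self.n_low_quality):
            if n < 0:
                raise ConfigurationError("read counts must be >= 0")


def _default_pairs() -> tuple[PlantedPair, ...]:
    return (
        PlantedPair(0, 0, 200, "downstream"),
        PlantedPair(1, 1, 837, "downstream"),
        PlantedPair(2, 2, 5_000, "upstream"),
        PlantedPair(3, 3, 20_000, "upstream"),
        PlantedPair(4, 4, 75_000, "downstream"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 3
    n_coding_genes: int = 60
    n_lnc_loci: int = 20
    planted_pairs: tuple[PlantedPair, ...] = field(default_factory=_default_pairs)
    groups: tuple[str, ...] = ("D/E-0.61", "D/E-1.46", "D/E-2.75")
    n_replicates: int = 3
    dispersion: float = 0.1
    pair_dispersion: float = 0.01
    pair_base_mean: float = 800.0
    base_mean_log2_range: tuple[float, float] = (5.0, 9.0)
    # per-pair fold-change pattern relative to the first group, log2 units;
    # sign alternates by pair index so both directions are exercised
    pair_log2fc_pattern: tuple[float, ...] = (0.0, 3.0, -3.0)
    n_extra_de_mrna_up: int = 8
    n_extra_de_mrna_down: int = 8
    n_extra_de_mrna_late: int = 4
    n_extra_de_lnc_up: int = 3
    n_extra_de_lnc_down: int = 2
    frac_annotated_lnc: float = 0.3
    cascade_failures: tuple[str, ...] = ()
    read_fixture: ReadFixtureConfig = field(default_factory=ReadFixtureConfig)

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.n_coding_genes, self.n_lnc_loci) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.dispersion < 0 or self.pair_dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        for k in self.cascade_failures:
            if k not in FAILURE_KINDS:
                raise ConfigurationError(f"unknown cascade failure kind {k!r}")

    @property
    def comparisons(self) -> tuple[tuple[str, str], ...]:
        g = self.groups
        if len(g) >= 3:
            return ((g[1], g[0]), (g[2], g[0]), (g[1], g[2]))
        if len(g) == 2:
            return ((g[1], g[0]),)
        return ()


@dataclass
class PairTruth:
    lnc_id: str
    mrna_gene_id: str
    distance_bp: int
    location: str
    target_r: float


@dataclass
class SimulationTruth:
    """What was planted: geometry, DE memberships, and NB parameters."""

    pairs: list[PairTruth] = field(default_factory=list)
    lnc_ids: list[str] = field(default_factory=list)
    mrna_gene_ids: list[str] = field(default_factory=list)
    candidate_ids: list[str] = field(default_factory=list)
    failure_kinds: dict[str, str] = field(default_factory=dict)
    exon_counts: dict[str, int] = field(default_factory=dict)
    coding_calls: Optional[pd.DataFrame] = None
    group_means: Optional[pd.DataFrame] = None
    dispersion: Optional[pd.Series] = None
    de_features: dict[str, dict[str, str]] = field(default_factory=dict)

    def de_set(self, comparison_label: str) -> set[str]:
        return set(self.de_features.get(comparison_label, {}))


def comparison_label(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]} vs {comparison[1]}"


# ---------------------------------------------------------------------------
# annotation


def _make_coding_gene(rng, gene_id: str, chrom: str, start: int, strand: str):
    n_ex = int(rng.integers(3, 7))
    pos = start
    exons = []
    for i in range(n_ex):
        ex_len = int(rng.integers(150, 401))
        exons.append(GenomicInterval(chrom, pos, pos + ex_len, strand))
        pos += ex_len + int(rng.integers(300, 1501))
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        biotype="coding",
    )
    return GeneModel(gene_id=gene_id, transcripts=[tx])


def _make_lnc_exons(rng, chrom, start, strand, n_ex=None, total_len=None):
    """Build >=2 short exons totalling >200 bp starting at ``start``."""
    if n_ex is None:
        n_ex = int(rng.integers(2, 4))
    if total_len is None:
        total_len = int(rng.integers(300, 801))
    # every exon needs >=100 bp of headroom for the cut positions
    n_ex = max(2, min(n_ex, (total_len - 1) // 100))
    cuts = np.sort(rng.integers(100, total_len - 100 * (n_ex - 1), size=n_ex - 1)) \
        if n_ex > 1 else np.array([], dtype=int)
    lens = np.diff(np.concatenate([[0], cuts, [total_len]]))
    lens = np.maximum(lens, 80)
    pos = start
    exons = []
    for L in lens:
        exons.append(GenomicInterval(chrom, pos, pos + int(L), strand))
        pos += int(L) + int(rng.integers(100, 801))
    return tuple(exons)


def _place_lnc_for_pair(rng, pair: PlantedPair, gene: GeneModel):
    """Realize the planted distance/location exactly against the gene span."""
    span = gene.span
    chrom = span.chrom
    if pair.location == "overlapping":
        # span-overlap the gene tail on the opposite strand (no same-strand
        # exonic overlap, so the candidate survives the cascade)
        strand = "-" if gene.strand == "+" else "+"
        start = span.end - 50
        return _make_lnc_exons(rng, chrom, start, strand)
    # downstream = 3' side of the mRNA in its own orientation
    right_side = (pair.location == "downstream") == (gene.strand == "+")
    strand = "+" if rng.random() < 0.5 else "-"
    if right_side:
        start = span.end + pair.distance_bp
        return _make_lnc_exons(rng, chrom, start, strand)
    exons = _make_lnc_exons(rng, chrom, 0, strand)
    genomic_span = exons[-1].end - exons[0].start
    start = span.start - pair.distance_bp - genomic_span
    if start < 0:
        raise ConfigurationError(
            f"planted pair (lnc {pair.lnc_index}) does not fit left of "
            f"{gene.gene_id} at distance {pair.distance_bp}"
        )
    return tuple(
        GenomicInterval(chrom, e.start + start, e.end + start, strand) for e in exons
    )


def generate_annotation(cfg: SimulationConfig):
    """Lay out coding genes and lncRNA loci; return (annotation, truth).

    Planted pairs are realized exactly; every non-planted lncRNA locus and
    every cascade-failure candidate is placed farther than
    ``MAX_PLANT_DISTANCE`` + margin from all coding genes (geometric decoys).
    """
    rng = np.random.default_rng([cfg.seed, _RNG_ANNOTATION])
    truth = SimulationTruth()

    pair_by_lnc = {p.lnc_index: p for p in cfg.planted_pairs}
    if len(pair_by_lnc) != len(cfg.planted_pairs):
        raise ConfigurationError("planted pairs must use distinct lnc indices")
    for p in cfg.planted_pairs:
        if p.lnc_index >= cfg.n_lnc_loci or p.mrna_index >= cfg.n_coding_genes:
            raise ConfigurationError("planted pair index out of range")
        if p.distance_bp > MAX_PLANT_DISTANCE:
            raise ConfigurationError(
                f"planted distance {p.distance_bp} exceeds the satisfiable "
                f"maximum {MAX_PLANT_DISTANCE} for the synthetic layout"
            )
    n_anchors = max(cfg.n_lnc_loci, 0) + len(cfg.cascade_failures)
    if n_anchors > cfg.n_coding_genes:
        raise ConfigurationError(
            "need at least one coding-gene slot per lncRNA locus and failure"
        )

    genes: list[GeneModel] = []
    for i in range(cfg.n_coding_genes):
        chrom = f"chr{i % cfg.n_chrom + 1}"
        slot = i // cfg.n_chrom
        start = _SLOT_OFFSET + slot * _SLOT
        strand = "+" if i % 2 == 0 else "-"
        gene = _make_coding_gene(rng, f"GENE_{i:04d}", chrom, start, strand)
        genes.append(gene)
        truth.mrna_gene_ids.append(gene.gene_id)
        truth.exon_counts[gene.transcripts[0].transcript_id] = gene.transcripts[0].n_exons

    lnc_genes: list[GeneModel] = []
    n_annotated = int(round(cfg.frac_annotated_lnc * cfg.n_lnc_loci))
    annotated_cutoff = cfg.n_lnc_loci - n_annotated  # last loci are pre-annotated
    for j in range(cfg.n_lnc_loci):
        lnc_id = f"LNC_{j:04d}"
        pair = pair_by_lnc.get(j)
        anchor = genes[pair.mrna_index if pair else j]
        if pair is not None:
            exons = _place_lnc_for_pair(rng, pair, anchor)
            truth.pairs.append(
                PairTruth(lnc_id, anchor.gene_id, pair.distance_bp, pair.location,
                          pair.target_r)
            )
        else:
            start = anchor.span.end + _DECOY_GAP
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_lnc_exons(rng, anchor.chrom, start, strand)
        biotype = "unknown" if (pair is not None or j < annotated_cutoff) \
            else "annotated_lncRNA"
        tx = TranscriptModel(
            transcript_id=lnc_id,
            gene_id=f"LNCG_{j:04d}",
            chrom=exons[0].chrom,
            strand=exons[0].strand,
            exons=exons,
            biotype=biotype,
        )
        lnc_genes.append(GeneModel(gene_id=tx.gene_id, transcripts=[tx]))
        truth.lnc_ids.append(lnc_id)
        truth.exon_counts[lnc_id] = tx.n_exons
        if biotype == "unknown":
            truth.candidate_ids.append(lnc_id)

    fail_genes: list[GeneModel] = []
    for k, kind in enumerate(cfg.cascade_failures):
        fid = f"FAIL_{kind.upper()}_{k:02d}"
        anchor = genes[cfg.n_lnc_loci + k]
        chrom, strand = anchor.chrom, anchor.strand
        if kind == "single_exon":
            start = anchor.span.end + _DECOY_GAP
            exons = (GenomicInterval(chrom, start, start + 500, strand),)
        elif kind == "short":
            start = anchor.span.end + _DECOY_GAP
            exons = (
                GenomicInterval(chrom, start, start + 90, strand),
                GenomicInterval(chrom, start + 300, start + 390, strand),
            )
        elif kind == "coding_overlap":
            # same-strand exonic overlap with the anchor's first coding exon
            e0 = anchor.transcripts[0].exons[0]
            exons = (
                GenomicInterval(chrom, e0.start, e0.start + 120, strand),
                GenomicInterval(chrom, e0.start + 400, e0.start + 600, strand),
            )
        else:  # low_expression / coding_potential: geometrically clean decoys
            start = anchor.span.end + _DECOY_GAP + 5_000
            exons = _make_lnc_exons(rng, chrom, start, strand)
        tx = TranscriptModel(
            transcript_id=fid,
            gene_id=f"FAILG_{k:02d}",
            chrom=chrom,
            strand=strand,
            exons=exons,
            biotype="unknown",
        )
        fail_genes.append(GeneModel(gene_id=tx.gene_id, transcripts=[tx]))
        truth.candidate_ids.append(fid)
        truth.failure_kinds[fid] = kind
        truth.exon_counts[fid] = tx.n_exons

    ann = GenomeAnnotation(genes + lnc_genes + fail_genes)

    # coding-potential calls: plain stand-ins for external predictors
    cand = truth.candidate_ids
    calls = pd.DataFrame(
        False, index=pd.Index(cand, name="transcript_id"),
        columns=["CPC", "CNCI", "PFAM"],
    )
    for fid, kind in truth.failure_kinds.items():
        if kind == "coding_potential":
            calls.loc[fid, "CPC"] = True
    truth.coding_calls = calls
    return ann, truth


# ---------------------------------------------------------------------------
# counts


def make_design(cfg: SimulationConfig) -> StudyDesign:
    samples, group_of = [], {}
    for gi, g in enumerate(cfg.groups):
        for ri in range(cfg.n_replicates):
            sid = f"g{gi + 1}r{ri + 1}"
            samples.append(sid)
            group_of[sid] = g
    return StudyDesign(samples=samples, group_of=group_of,
                       comparisons=list(cfg.comparisons))


def _solve_latent_sigma2(target_r, pattern_cov, v1, v2):
    """Latent log-variance needed so corr(log x1, log x2) hits target_r.

    Shared variance = pattern covariance (aligned planted fold changes)
    plus the latent sigma^2; residual per-member noise v_i from the NB
    delta approximation Var(log X) ~ 1/mu + phi. Returns 0 when the
    fold-change pattern alone already meets the target.
    """
    def corr(s2):
        shared = pattern_cov + s2
        return shared / math.sqrt((shared + v1) * (shared + v2))

    if target_r <= 0 or corr(0.0) >= target_r:
        return 0.0
    hi = 1.0
    while corr(hi) < target_r and hi < 1e6:
        hi *= 2
    if corr(hi) < target_r:
        return hi
    return brentq(lambda s2: corr(s2) - target_r, 0.0, hi)


def _sample_nb(rng, mu, phi):
    mu = np.asarray(mu, dtype=float)
    if phi < 1e-12:
        return rng.poisson(mu)
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    return rng.negative_binomial(n_param, p_param)


def generate_counts(cfg: SimulationConfig, ann: GenomeAnnotation,
                    truth: Optional[SimulationTruth] = None):
    """Draw the NB count matrix and extend the truth ledger.

    Counts are transcript-level. Planted-pair members share both a fold-
    change pattern across groups and a per-sample lognormal latent factor
    sized (numerically) so the expected Pearson correlation of their
    log-expression reaches the pair's target.
    """
    if truth is None:
        truth = SimulationTruth()
    rng = np.random.default_rng([cfg.seed, _RNG_COUNTS])
    design = make_design(cfg)
    features = sorted(ann.transcripts)
    ln2 = math.log(2.0)

    pair_member_tx: dict[str, int] = {}  # transcript id -> pair index
    for pi, pt in enumerate(truth.pairs):
        pair_member_tx[pt.lnc_id] = pi
        pair_member_tx[ann.genes[pt.mrna_gene_id].transcripts[0].transcript_id] = pi

    base = pd.Series(
        np.exp2(rng.uniform(*cfg.base_mean_log2_range, size=len(features))),
        index=features,
    )
    phi = pd.Series(cfg.dispersion, index=features, dtype=float)
    lfc = pd.DataFrame(0.0, index=features, columns=list(cfg.groups))

    for tid, pi in pair_member_tx.items():
        base[tid] = cfg.pair_base_mean
        phi[tid] = cfg.pair_dispersion
        sign = 1.0 if pi % 2 == 0 else -1.0
        lfc.loc[tid, :] = sign * np.asarray(cfg.pair_log2fc_pattern[: len(cfg.groups)])

    # extra planted DE among decoy features (deterministic assignment)
    if len(cfg.groups) >= 3:
        g1, g2, g3 = cfg.groups[:3]
        free_genes = [g for g in truth.mrna_gene_ids
                      if ann.genes[g].transcripts[0].transcript_id
                      not in pair_member_tx]
        free_tx = [ann.genes[g].transcripts[0].transcript_id for g in free_genes]
        k = 0
        if free_tx:
            for _ in range(cfg.n_extra_de_mrna_up):
                lfc.loc[free_tx[k % len(free_tx)], g2] = 2.0; k += 1
            for _ in range(cfg.n_extra_de_mrna_down):
                lfc.loc[free_tx[k % len(free_tx)], g2] = -2.0; k += 1
            for _ in range(cfg.n_extra_de_mrna_late):
                lfc.loc[free_tx[k % len(free_tx)], g3] = 1.5; k += 1
        free_lnc = [t for t in truth.lnc_ids if t not in pair_member_tx]
        k = 0
        for _ in range(cfg.n_extra_de_lnc_up):
            if k < len(free_lnc):
                lfc.loc[free_lnc[k], g2] = 2.0; k += 1
        for _ in range(cfg.n_extra_de_lnc_down):
            if k < len(free_lnc):
                lfc.loc[free_lnc[k], g3] = -1.5; k += 1

    for fid, kind in truth.failure_kinds.items():
        if kind == "low_expression":
            base[fid] = 0.05
            lfc.loc[fid, :] = 0.0

    group_means = pd.DataFrame(
        {g: base * np.exp2(lfc[g]) for g in cfg.groups}, index=features
    )
    if (group_means <= 0).any().any():
        raise ConfigurationError("group means must be strictly positive")

    # latent coupling per pair: one shared standard-normal draw per sample
    n_samples = len(design.samples)
    latent_z = {pi: rng.standard_normal(n_samples) for pi in range(len(truth.pairs))}
    sigma2 = {}
    for pi, pt in enumerate(truth.pairs):
        members = [t for t, p in pair_member_tx.items() if p == pi]
        pat = np.repeat(
            [lfc.loc[members[0], design.group_of[s]] for s in design.samples], 1
        ).astype(float) * ln2
        pattern_cov = float(np.var(pat))
        vs = [1.0 / group_means.loc[m].mean() + phi[m] for m in members]
        sigma2[pi] = _solve_latent_sigma2(pt.target_r, pattern_cov, vs[0], vs[-1])

    counts = np.zeros((len(features), n_samples), dtype=np.int64)
    for fi, fid in enumerate(features):
        mu = np.array([group_means.loc[fid, design.group_of[s]]
                       for s in design.samples])
        pi = pair_member_tx.get(fid)
        if pi is not None and sigma2[pi] > 0:
            s2 = sigma2[pi]
            mu = mu * np.exp(math.sqrt(s2) * latent_z[pi] - s2 / 2.0)
        counts[fi] = _sample_nb(rng, mu, float(phi[fid]))

    counts_df = pd.DataFrame(counts, index=pd.Index(features, name="feature"),
                             columns=design.samples)
    lengths = pd.Series({f: ann.transcripts[f].length for f in features})
    cm = CountMatrix(counts=counts_df, lengths=lengths)

    truth.group_means = group_means
    truth.dispersion = phi
    for comp in cfg.comparisons:
        label = comparison_label(comp)
        de: dict[str, str] = {}
        for fid in features:
            mb, ma = group_means.loc[fid, comp[0]], group_means.loc[fid, comp[1]]
            if abs(math.log2(mb / ma)) > 1e-9:
                de[fid] = "up" if mb > ma else "down"
        truth.de_features[label] = de
    return cm, truth


# ---------------------------------------------------------------------------
# reads


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def generate_reads(cfg: SimulationConfig, path) -> dict[str, int]:
    """Write a Phred+33 FASTQ fixture; read ids carry their planted class.

    Returns the ledger of per-class read counts actually written.
    """
    rng = np.random.default_rng([cfg.seed, _RNG_READS])
    fx = cfg.read_fixture
    L = fx.read_length
    hi_qual = "".join(chr(33 + int(q)) for q in [38] * L)

    records = []
    for i in range(fx.n_adapter):
        seq = _random_seq(rng, L)
        pos = int(rng.integers(0, L - len(fx.adapter) + 1))
        seq = seq[:pos] + fx.adapter + seq[pos + len(fx.adapter):]
        records.append((f"adapter_{i:05d}", seq, hi_qual))
    for i in range(fx.n_poly_n):
        seq = list(_random_seq(rng, L))
        n_ns = max(int(0.2 * L), 1)
        for p in rng.choice(L, size=n_ns, replace=False):
            seq[p] = "N"
        records.append((f"polyN_{i:05d}", "".join(seq), hi_qual))
    for i in range(fx.n_low_quality):
        seq = _random_seq(rng, L)
        quals = [2] * (int(0.6 * L) + 1) + [38] * (L - int(0.6 * L) - 1)
        records.append((f"lowqual_{i:05d}", seq,
                        "".join(chr(33 + q) for q in quals)))
    for i in range(fx.n_clean):
        records.append((f"clean_{i:05d}", _random_seq(rng, L), hi_qual))

    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return {
        "adapter": fx.n_adapter,
        "poly_n": fx.n_poly_n,
        "low_quality": fx.n_low_quality,
        "clean": fx.n_clean,
    }


# ---------------------------------------------------------------------------
# convenience


def simulate_study(cfg: SimulationConfig):
    """Annotation + counts + design + truth in one call."""
    ann, truth = generate_annotation(cfg)
    cm, truth = generate_counts(cfg, ann, truth)
    return ann, cm, make_design(cfg), truth


def write_study(cfg: SimulationConfig, out_dir) -> "SimulationTruth":
    """Persist a full synthetic study as the pipeline's input files.

    Writes reference.gtf (coding genes + pre-annotated lncRNAs),
    candidates.gtf (novel transcripts to be filtered), counts.tsv,
    design.tsv, coding_calls.tsv, reads.fastq, and truth_pairs.tsv under
    ``out_dir``; returns the truth ledger.
    """
    import dataclasses
    from pathlib import Path

    from .annotation_io import write_gtf
    from .pipeline import write_counts_tsv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann, truth = generate_annotation(cfg)
    cm, truth = generate_counts(cfg, ann, truth)
    design = make_design(cfg)

    ref = GenomeAnnotation(
        g for g in ann.genes.values()
        if g.transcripts[0].biotype in ("coding", "annotated_lncRNA")
    )
    cands = GenomeAnnotation(
        g for g in ann.genes.values()
        if g.transcripts[0].transcript_id in truth.candidate_ids
        or g.transcripts[0].biotype == "annotated_lncRNA"
    )
    write_gtf(ref, out_dir / "reference.gtf")
    write_gtf(cands, out_dir / "candidates.gtf")
    write_counts_tsv(cm, out_dir / "counts.tsv")
    pd.DataFrame(
        {"sample": design.samples,
         "group": [design.group_of[s] for s in design.samples]}
    ).to_csv(out_dir / "design.tsv", sep="\t", index=False)
    calls = truth.coding_calls.copy()
    for tid in cands.transcripts:
        if tid not in calls.index:
            calls.loc[tid] = False
    calls.sort_index().to_csv(out_dir / "coding_calls.tsv", sep="\t")
    generate_reads(cfg, out_dir / "reads.fastq")
    pd.DataFrame(
        [dataclasses.asdict(p) for p in truth.pairs]
    ).to_csv(out_dir / "truth_pairs.tsv", sep="\t", index=False)
    return truth


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=seed)
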