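"""Filtration cascade, positional classes, and the ORF stand-in predictor."""

import numpy as np
import pandas as pd
import pytest

from lncpair.lncrna_discovery import (
    DiscoveryInputError,
    classify_positional,
    filter_candidates,
    orf_coding_heuristic,
    summarize_lnc_features,
)

from conftest import make_ann, make_tx

STOPS = {"TAA", "TAG", "TGA"}


def oracle_cascade(candidates, ref_transcripts, fpkm, calls,
                   min_exons=2, min_len=200, min_fpkm=0.5):
    """Independent rule-by-rule reimplementation with plain loops."""
    out = {}
    for tx in candidates:
        if len(tx.exons) < min_exons:
            out[tx.transcript_id] = ("rejected", "exon_count")
            continue
        if sum(e.end - e.start for e in tx.exons) <= min_len:
            out[tx.transcript_id] = ("rejected", "length")
            continue
        killed = False
        known = False
        for other in ref_transcripts:
            if other.chrom != tx.chrom:
                continue
            hit = any(
                a.start < b.end and b.start < a.end
                for a in tx.exons for b in other.exons
            )
            if not hit:
                continue
            if other.biotype == "coding" and other.strand == tx.strand:
                killed = True
            if other.biotype == "annotated_lncRNA":
                known = True
        if killed:
            out[tx.transcript_id] = ("rejected", "coding_exon_overlap")
            continue
        if fpkm.loc[tx.transcript_id].max() < min_fpkm:
            out[tx.transcript_id] = ("rejected", "expression")
            continue
        if known:
            out[tx.transcript_id] = ("annotated_lncRNA", ".")
            continue
        if calls.loc[tx.transcript_id].any():
            out[tx.transcript_id] = ("TUCP", ".")
        else:
            out[tx.transcript_id] = ("novel_lncRNA", ".")
    return out


@pytest.fixture
def engineered_cascade():
    """Candidates engineered to fail each rule once, plus survivors."""
    ref = make_ann(
        make_tx("cod.t1", "chr1", "+", [(1000, 1400), (2000, 2400)],
                gene_id="cod", biotype="coding"),
        make_tx("known.t1", "chr1", "+", [(50000, 50400), (51000, 51400)],
                gene_id="known", biotype="annotated_lncRNA"),
    )
    cands = [
        make_tx("c_single", "chr1", "+", [(100000, 100500)]),
        make_tx("c_short", "chr1", "+", [(110000, 110090), (110300, 110390)]),
        make_tx("c_codeov", "chr1", "+", [(1100, 1300), (3000, 3300)]),
        make_tx("c_lowexpr", "chr1", "+", [(120000, 120300), (121000, 121300)]),
        make_tx("c_multi", "chr1", "-", [(130000, 130090)]),  # fails 1 and 2
        make_tx("c_known", "chr1", "+", [(50100, 50300), (51100, 51300)]),
        make_tx("c_known_low", "chr1", "+", [(50050, 50350), (51050, 51350)]),
        make_tx("c_anti", "chr1", "-", [(1100, 1300), (3000, 3300)]),
        make_tx("c_tucp1", "chr1", "+", [(140000, 140300), (141000, 141300)]),
        make_tx("c_tucp2", "chr2", "-", [(1000, 1300), (2000, 2300)]),
        make_tx("c_nov1", "chr1", "-", [(150000, 150300), (151000, 151300)]),
        make_tx("c_nov2", "chr2", "+", [(10000, 10300), (11000, 11300)]),
    ]
    ids = [t.transcript_id for t in cands]
    fpkm = pd.DataFrame({"s1": 5.0, "s2": 8.0}, index=ids)
    fpkm.loc["c_lowexpr"] = 0.2
    fpkm.loc["c_known_low"] = 0.1
    calls = pd.DataFrame(False, index=ids, columns=["CPC", "CNCI", "PFAM"])
    calls.loc["c_tucp1", "CPC"] = True
    calls.loc["c_tucp2", "PFAM"] = True
    return ref, cands, fpkm, calls


class TestCascade:
    def test_single_exon_forced(self, engineered_cascade):
        ref, cands, fpkm, calls = engineered_cascade
        report = filter_candidates(cands, ref, fpkm, calls)
        assert report.outcome["c_single"] == "rejected"
        assert report.first_failing_step["c_single"] == "exon_count"

    def test_short_transcript_forced(self, engineered_cascade):
        ref, cands, fpkm, calls = engineered_cascade
        report = filter_candidates(cands, ref, fpkm, calls)
        assert report.first_failing_step["c_short"] == "length"

    def test_matches_rule_by_rule_oracle(self, engineered_cascade):
        ref, cands, fpkm, calls = engineered_cascade
        report = filter_candidates(cands, ref, fpkm, calls)
        expected = oracle_cascade(cands, list(ref.transcripts.values()),
                                  fpkm, calls)
        for tid, (outcome, step) in expected.items():
            assert report.outcome[tid] == outcome, tid
            assert report.first_failing_step.get(tid, ".") == step, tid
        assert sorted(report.of("TUCP")) == ["c_tucp1", "c_tucp2"]
        assert sorted(report.of("novel_lncRNA")) == ["c_anti", "c_nov1", "c_nov2"]
        assert report.of("annotated_lncRNA") == ["c_known"]

    def test_partition_is_exhaustive(self, engineered_cascade):
        ref, cands, fpkm, calls = engineered_cascade
        report = filter_candidates(cands, ref, fpkm, calls)
        n = sum(len(report.of(o)) for o in
                ("novel_lncRNA", "annotated_lncRNA", "TUCP", "rejected"))
        assert n == len(cands)

    def test_survivor_counts_non_increasing(self, engineered_cascade):
        ref, cands, fpkm, calls = engineered_cascade
        report = filter_candidates(cands, ref, fpkm, calls)
        s = report.survivors_per_step
        order = ["input", "exon_count", "length", "coding_exon_overlap",
                 "expression"]
        vals = [s[k] for k in order]
        assert vals == sorted(vals, reverse=True)

    def test_opposite_strand_overlap_survives(self, engineered_cascade):
        # an any-strand elimination at step 3 would make antisense
        # lncRNAs impossible; c_anti must survive to be classified
        ref, cands, fpkm, calls = engineered_cascade
        report = filter_candidates(cands, ref, fpkm, calls)
        assert report.outcome["c_anti"] == "novel_lncRNA"
        assert classify_positional(
            next(t for t in cands if t.transcript_id == "c_anti"), ref
        ) == "antisense"

    def test_missing_fpkm_row_rejected(self, engineered_cascade):
        ref, cands, fpkm, calls = engineered_cascade
        with pytest.raises(DiscoveryInputError):
            filter_candidates(cands, ref, fpkm.drop(index="c_nov1"), calls)

    def test_missing_coding_call_rejected(self, engineered_cascade):
        ref, cands, fpkm, calls = engineered_cascade
        with pytest.raises(DiscoveryInputError):
            filter_candidates(cands, ref, fpkm, calls.drop(index="c_nov1"))


class TestPositional:
    def test_no_coding_genes_is_lincRNA(self, simple_ann):
        lnc = make_tx("l", "chr9", "+", [(100, 300), (500, 700)])
        assert classify_positional(lnc, simple_ann) == "lincRNA"

    def test_intronic_same_strand(self, simple_ann):
        # inside cod1's intron (1400..2000), no exonic overlap
        lnc = make_tx("l", "chr1", "+", [(1450, 1600), (1700, 1900)])
        assert classify_positional(lnc, simple_ann) == "intronic"

    def test_antisense_beats_intronic(self, simple_ann):
        lnc = make_tx("l", "chr1", "-", [(1350, 1450), (1700, 1900)])
        assert classify_positional(lnc, simple_ann) == "antisense"

    def test_never_intronic_with_exonic_overlap(self, simple_ann):
        # same-strand exonic overlap: not intronic, falls through to lincRNA
        lnc = make_tx("l", "chr1", "+", [(1350, 1450), (1700, 1900)])
        assert classify_positional(lnc, simple_ann) != "intronic"


def oracle_orf(seq, min_aa):
    best = 0
    seq = seq.upper()
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        for i, c in enumerate(codons):
            if c != "ATG":
                continue
            n = 0
            for c2 in codons[i:]:
                if c2 in STOPS:
                    break
                n += 1
            best = max(best, n)
    return best >= min_aa


class TestOrfHeuristic:
    def test_boundary_100_codons(self):
        seq = "ATG" + "GCT" * 99 + "TAA"
        assert orf_coding_heuristic(seq, min_orf_aa=100) is True
        assert orf_coding_heuristic("ATG" + "GCT" * 98 + "TAA", 100) is False

    def test_all_stop_codons(self):
        assert orf_coding_heuristic("TAATAGTGA" * 40, 10) is False

    def test_open_ended_orf_counts(self):
        assert orf_coding_heuristic("ATG" + "GCT" * 99, 100) is True

    def test_matches_three_frame_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
            for min_aa in (5, 20, 60):
                assert orf_coding_heuristic(seq, min_aa) == oracle_orf(seq, min_aa)


class TestSummaries:
    def test_identical_sets_identical_summaries(self):
        txs = [make_tx("a", "chr1", "+", [(0, 300), (400, 700)]),
               make_tx("b", "chr1", "+", [(0, 500)])]
        df = summarize_lnc_features(txs, txs)
        lnc = df[df["class"] == "lncRNA"].drop(columns="class").reset_index(drop=True)
        mrna = df[df["class"] == "mRNA"].drop(columns="class").reset_index(drop=True)
        pd.testing.assert_frame_equal(lnc, mrna)

    def test_single_transcript_degenerate_quantiles(self):
        t = make_tx("a", "chr1", "+", [(0, 300)])
        df = summarize_lnc_features([t], [t])
        row = df[(df["class"] == "lncRNA") & (df["metric"] == "length")].iloc[0]
        assert row["min"] == row["q25"] == row["median"] == row["q75"] \
            == row["max"] == 300

    def test_generator_plants_shorter_lncs(self):
        from lncpair.synthetic_data import SimulationConfig, generate_annotation

        ann, truth = generate_annotation(SimulationConfig(seed=8))
        lncs = [ann.transcripts[t] for t in truth.lnc_ids]
        mrnas = [ann.genes[g].transcripts[0] for g in truth.mrna_gene_ids]
        df = summarize_lnc_features(lncs, mrnas).set_index(["class", "metric"])
        assert df.loc[("lncRNA", "length"), "median"] \
            < df.loc[("mRNA", "length"), "median"]
        assert df.loc[("lncRNA", "exon_count"), "median"] \
            < df.loc[("mRNA", "exon_count"), "median"]
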