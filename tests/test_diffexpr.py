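"""NB test statistics, size factors, dispersion recovery, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from lncpair.diffexpr import (
    NormalizationError,
    bh_adjust,
    call_de,
    estimate_dispersion,
    estimate_size_factors,
    nb_test,
)
from lncpair.expression import StudyDesign


def two_group_design(n_per_group=3):
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    group_of = {s: ("A" if i < n_per_group else "B")
                for i, s in enumerate(samples)}
    return StudyDesign(samples=samples, group_of=group_of,
                       comparisons=[("B", "A")])


def nb_counts(rng, mu, phi, size):
    if phi < 1e-12:
        return rng.poisson(mu, size=size)
    n = 1.0 / phi
    return rng.negative_binomial(n, n / (n + mu), size=size)


class TestSizeFactors:
    def test_identical_columns_all_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_ratio_two_geomean_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = estimate_size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(50, 4)),
                              columns=list("abcd"))
        sf = estimate_size_factors(counts)
        # independent oracle: literal median of count/geometric-mean ratios
        geomean = np.exp(np.log(counts.to_numpy()).mean(axis=1))
        ratios = counts.to_numpy() / geomean[:, None]
        oracle = np.median(ratios, axis=0)
        oracle = oracle / np.exp(np.log(oracle).mean())
        assert np.allclose(sf.to_numpy(), oracle)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(NormalizationError):
            estimate_size_factors(counts)


class TestDispersion:
    def test_poisson_truth_near_zero(self):
        rng = np.random.default_rng(1)
        design = two_group_design(50)
        counts = pd.DataFrame(nb_counts(rng, 200.0, 0.0, (500, 100)),
                              columns=design.samples)
        phi = estimate_dispersion(counts, design, moderate=False)
        assert phi.median() < 0.01

    def test_recovers_planted_dispersion_large_n(self):
        rng = np.random.default_rng(2)
        design = two_group_design(50)
        counts = pd.DataFrame(nb_counts(rng, 500.0, 0.1, (500, 100)),
                              columns=design.samples)
        phi = estimate_dispersion(counts, design, moderate=False)
        frac_close = ((phi > 0.05) & (phi < 0.15)).mean()
        assert frac_close > 0.5

    def test_constant_counts_floor(self):
        design = two_group_design(3)
        counts = pd.DataFrame(100, index=range(5), columns=design.samples)
        phi = estimate_dispersion(counts, design, moderate=False)
        assert np.allclose(phi.to_numpy(), 1e-8)


class TestNbTest:
    def test_equal_means_z_zero(self):
        design = two_group_design(3)
        counts = pd.DataFrame([[50, 50, 50, 50, 50, 50]],
                              columns=design.samples)
        res = nb_test(counts, design, ("B", "A"),
                      pd.Series(0.1, index=counts.index))
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res["log2fc"].iloc[0] == 0.0

    def test_all_zero_feature_no_signal_convention(self):
        design = two_group_design(3)
        counts = pd.DataFrame([[0] * 6, [10, 12, 9, 50, 60, 55]],
                              columns=design.samples)
        res = nb_test(counts, design, ("B", "A"),
                      pd.Series(0.1, index=counts.index))
        assert res["p"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0

    def test_swap_groups_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(3)
        design = two_group_design(3)
        counts = pd.DataFrame(rng.integers(5, 500, size=(40, 6)),
                              columns=design.samples)
        phi = pd.Series(0.1, index=counts.index)
        fwd = nb_test(counts, design, ("B", "A"), phi)
        rev = nb_test(counts, design, ("A", "B"), phi)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_within_group_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        design = two_group_design(3)
        counts = pd.DataFrame(rng.integers(5, 500, size=(30, 6)),
                              columns=design.samples)
        phi = pd.Series(0.1, index=counts.index)
        base = nb_test(counts, design, ("B", "A"), phi)
        shuffled = counts[["s1", "s2", "s0", "s4", "s5", "s3"]]
        shuffled.columns = design.samples
        perm = nb_test(shuffled, design, ("B", "A"), phi)
        assert np.allclose(base["p"], perm["p"])

    def test_null_type_one_error_band(self):
        # 3 vs 3, mu=100, phi=0.1, 2000 features: raw p<0.05 in [0.03, 0.08]
        rng = np.random.default_rng(7)
        design = two_group_design(3)
        counts = pd.DataFrame(nb_counts(rng, 100.0, 0.1, (2000, 6)),
                              columns=design.samples)
        res = nb_test(counts, design, ("B", "A"),
                      pd.Series(0.1, index=counts.index))
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.08

    def test_power_on_planted_fourfold_change(self):
        # planted 4-fold features among a null majority that anchors the
        # size-factor normalization
        rng = np.random.default_rng(8)
        design = two_group_design(3)
        a = nb_counts(rng, 200.0, 0.05, (300, 3))
        b = nb_counts(rng, 800.0, 0.05, (300, 3))
        null = nb_counts(rng, 300.0, 0.05, (900, 6))
        counts = pd.DataFrame(
            np.vstack([np.hstack([a, b]), null]), columns=design.samples)
        res = nb_test(counts, design, ("B", "A"),
                      pd.Series(0.05, index=counts.index))
        planted = res.iloc[:300]
        assert (planted["p"] < 0.05).mean() >= 0.9
        assert (planted["log2fc"] > 0).mean() > 0.95


def oracle_bh(p):
    """Literal per-element evaluation of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        out[idx] = min(1.0, min(candidates))
    return out


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_forced_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            mine = bh_adjust(p)
            assert np.allclose(mine, oracle_bh(p))
            _, sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(mine, sm)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_p(self, pvals):
        adj = bh_adjust(pvals)
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDe:
    def test_all_padj_one_no_calls(self):
        res = pd.DataFrame({"log2fc": [1.0, -2.0], "p": [1.0, 1.0]},
                           index=["f1", "f2"])
        table, counts = call_de(res, ("B", "A"))
        assert not table["is_de"].any()
        assert counts == {"up": 0, "down": 0}

    def test_zero_log2fc_direction_none(self):
        res = pd.DataFrame({"log2fc": [0.0], "p": [1e-10]}, index=["f"])
        table, counts = call_de(res, ("B", "A"))
        assert table["is_de"].iloc[0]
        assert table["direction"].iloc[0] == "none"
        assert counts == {"up": 0, "down": 0}

    def test_recovers_planted_up_down_partition(self):
        rng = np.random.default_rng(10)
        design = two_group_design(3)
        up = nb_counts(rng, 100.0, 0.02, (20, 3)), nb_counts(rng, 800.0, 0.02, (20, 3))
        down = nb_counts(rng, 800.0, 0.02, (20, 3)), nb_counts(rng, 100.0, 0.02, (20, 3))
        null = nb_counts(rng, 300.0, 0.02, (60, 6))
        counts = pd.DataFrame(
            np.vstack([np.hstack(up), np.hstack(down), null]),
            columns=design.samples,
            index=[f"u{i}" for i in range(20)] + [f"d{i}" for i in range(20)]
                  + [f"n{i}" for i in range(60)],
        )
        res = nb_test(counts, design, ("B", "A"),
                      estimate_dispersion(counts, design))
        table, tallies = call_de(res, ("B", "A"))
        de_up = {f for f in table.query("is_de and direction == 'up'").index}
        de_down = {f for f in table.query("is_de and direction == 'down'").index}
        assert len(de_up & {f"u{i}" for i in range(20)}) >= 18
        assert len(de_down & {f"d{i}" for i in range(20)}) >= 18
        assert tallies["up"] >= 18 and tallies["down"] >= 18
        # few nulls called
        assert len((de_up | de_down) & {f"n{i}" for i in range(60)}) <= 3
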