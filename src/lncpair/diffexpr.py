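"""Two-group negative-binomial differential expression with BH-FDR.

The test is a documented NB Wald test on median-of-ratios-normalized
counts: per feature, z = (log mu_B - log mu_A) / SE with the SE from the
delta method under the NB variance mu + phi mu^2, evaluated at the pooled
mean under the null (the score-flavoured plug-in, which is better behaved
than per-group plug-ins at 3 replicates per group). P-values are two-sided
normal tails, adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, StudyDesign

DEFAULT_ALPHA = 0.05
_PHI_FLOOR = 1e-8
_LOG2FC_PSEUDO = 1.0  # pseudo-count (normalized scale) for ratio reporting


class NormalizationError(ValueError):
    pass


@dataclass
class DiffExprResult:
    feature: str
    comparison: str
    log2fc: float
    p: float
    padj: float
    is_de: bool
    direction: Optional[str]  # "up" / "down" / "none" when is_de


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scale factors, rescaled to geometric mean 1."""
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        raise NormalizationError("sample with all-zero counts")
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    ref = log_arr.mean(axis=1)  # log geometric mean per feature
    usable = np.isfinite(ref)
    if not usable.any():
        raise NormalizationError("no feature observed in every sample")
    ratios = arr[usable] / np.exp(ref[usable])[:, None]
    factors = np.median(ratios, axis=0)
    factors /= np.exp(np.log(factors).mean())  # geometric mean of factors = 1
    return pd.Series(factors, index=counts.columns)


def normalize_counts(counts: pd.DataFrame,
                     size_factors: Optional[pd.Series] = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    return counts / size_factors


def estimate_dispersion(counts: pd.DataFrame, design: StudyDesign,
                        size_factors: Optional[pd.Series] = None,
                        moderate: bool = True) -> pd.Series:
    """Method-of-moments NB dispersion, pooled across groups.

    Per group g: phi_g = max(0, (s^2 - m) / m^2) on normalized counts; the
    per-feature estimate is the mean over groups with a positive mean,
    floored at a small constant so downstream variances stay positive.

    With ``moderate`` (default), each per-feature estimate is raised to at
    least the dataset-wide median estimate. At two or three replicates per
    group the raw moment estimator is so variable that roughly half the
    features get a severe underestimate, which makes the Wald test
    anticonservative; bounding from below by the common value restores
    null calibration at the cost of some power on genuinely
    low-dispersion features (the same compromise classic NB pipelines make
    by sharing dispersion information across features).
    """
    norm = normalize_counts(counts, size_factors)
    per_group = []
    for g in design.groups:
        cols = design.samples_of(g)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), np.nan)
        per_group.append(phi)
    if not per_group:
        raise NormalizationError("dispersion needs >=2 replicates in a group")
    stacked = np.vstack(per_group)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled = np.nanmean(stacked, axis=0)
    pooled = np.where(np.isnan(pooled), 0.0, pooled)
    pooled = np.maximum(pooled, _PHI_FLOOR)
    if moderate:
        pooled = np.maximum(pooled, np.median(pooled))
    return pd.Series(pooled, index=counts.index)


def nb_test(counts: pd.DataFrame, design: StudyDesign,
            comparison: tuple[str, str], phi: pd.Series,
            size_factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-feature Wald test of equal NB means for B vs A.

    Returns a frame with columns (log2fc, p). Features with zero counts in
    both groups get the no-signal convention p = 1, log2fc = 0.
    """
    b, a = comparison
    cols_b, cols_a = design.samples_of(b), design.samples_of(a)
    if len(cols_b) < 2 or len(cols_a) < 2:
        raise NormalizationError("both groups need >=2 samples")
    norm = normalize_counts(counts, size_factors)
    mu_b = norm[cols_b].mean(axis=1).to_numpy()
    mu_a = norm[cols_a].mean(axis=1).to_numpy()
    phi_arr = phi.reindex(counts.index).to_numpy(dtype=float)

    c = _LOG2FC_PSEUDO
    log2fc = np.log2((mu_b + c) / (mu_a + c))

    n_b, n_a = len(cols_b), len(cols_a)
    mu_0 = (mu_b * n_b + mu_a * n_a) / (n_b + n_a)
    both_zero = (mu_b == 0) & (mu_a == 0)
    mu_0_safe = np.where(mu_0 > 0, mu_0, 1.0)
    se = np.sqrt((1.0 / mu_0_safe + phi_arr) * (1.0 / n_b + 1.0 / n_a))
    z = (np.log(mu_b + c) - np.log(mu_a + c)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    p[both_zero] = 1.0
    log2fc[both_zero] = 0.0
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=counts.index)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, in input order.

    adj_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def call_de(results: pd.DataFrame, comparison: tuple[str, str],
            alpha: float = DEFAULT_ALPHA) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach padj / is_de / direction and tally up- and down-regulation.

    Significant features with a log2 fold change of exactly 0 (possible
    through ties) are flagged with direction "none" and excluded from both
    tallies.
    """
    label = f"{comparison[0]} vs {comparison[1]}"
    out = results.copy()
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["is_de"] = out["padj"] < alpha
    direction = np.where(out["log2fc"] > 0, "up",
                         np.where(out["log2fc"] < 0, "down", "none"))
    out["direction"] = np.where(out["is_de"], direction, ".")
    out["comparison"] = label
    counts = {
        "up": int(((out["is_de"]) & (out["direction"] == "up")).sum()),
        "down": int(((out["is_de"]) & (out["direction"] == "down")).sum()),
    }
    return out, counts


def run_de(cm: CountMatrix, design: StudyDesign,
           alpha: float = DEFAULT_ALPHA) -> dict[str, pd.DataFrame]:
    """All configured comparisons end to end: normalize, test, adjust, call."""
    sf = estimate_size_factors(cm.counts)
    phi = estimate_dispersion(cm.counts, design, sf)
    out = {}
    for comp in design.comparisons:
        res = nb_test(cm.counts, design, comp, phi, sf)
        table, _ = call_de(res, comp, alpha)
        out[f"{comp[0]} vs {comp[1]}"] = table
    return out


def de_feature_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    de = table[table["is_de"]]
    return {
        "all": set(de.index),
        "up": set(de[de["direction"] == "up"].index),
        "down": set(de[de["direction"] == "down"].index),
    }
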