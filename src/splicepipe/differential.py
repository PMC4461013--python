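"""Two-condition differential tests.

Three pieces: a Pearson chi-square for cassette-exon inclusion counts; a
simplified negative-binomial exact test for raw counts (genes, junctions,
poly(A) sites) in which the variance decomposes into a shot-noise term and
a biological overdispersion term, var = mu + alpha * mu^2, with alpha
pooled across features of similar expression; and Benjamini-Hochberg
step-up adjustment of each analysis family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, NormalizationError, ZeroMarginError

STATUS_TESTED = "tested"
STATUS_LOW_COUNT = "low_count"
STATUS_ZERO = "zero"


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    p: float
    low_count: bool  # any expected cell < 5


def chisq_inclusion(
    n_inc_a: int, n_skip_a: int, n_inc_b: int, n_skip_b: int
) -> ChisqResult:
    """Pearson chi-square (no continuity correction) on the 2x2 table of
    inclusion/skipping counts in two conditions.

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); 1 df.  Tables with
    any expected cell below 5 are still tested but flagged low_count.
    """
    a, b, c, d = n_inc_a, n_skip_a, n_inc_b, n_skip_b
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ZeroMarginError("2x2 table has a zero margin; untestable")
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(stat, df=1))
    expected_min = min(r * col / n for r in margins[:2] for col in margins[2:])
    return ChisqResult(float(stat), p, expected_min < 5)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_size_factors(
    counts: pd.DataFrame, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors (features x samples matrix).

    factor_j = median over features of count_ij / geometric-mean_i, using
    only features with all-positive counts.  With none available, the
    pseudo-reference fallback (opt-in) restricts each feature's geometric
    mean to its positive entries.
    """
    m = counts.to_numpy(dtype=float)
    if m.ndim != 2 or np.any(m < 0):
        raise ValueError("counts must be a non-negative features x samples matrix")
    if m.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    all_pos = np.all(m > 0, axis=1)
    if all_pos.any():
        logm = np.log(m[all_pos])
        log_geo = logm.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logm - log_geo, axis=0))
    elif allow_pseudo_reference:
        with np.errstate(divide="ignore"):
            logm = np.where(m > 0, np.log(m), np.nan)
        log_geo = np.nanmean(logm, axis=1, keepdims=True)
        ratios = logm - log_geo
        factors = np.exp(np.nanmedian(ratios, axis=0))
        if np.any(~np.isfinite(factors)):
            raise NormalizationError("pseudo-reference fallback failed: a sample has no positive counts")
    else:
        raise NormalizationError(
            "no feature has positive counts in every sample; "
            "set allow_pseudo_reference=True to use the positive-entry fallback"
        )
    return pd.Series(factors, index=counts.columns)


# --- simplified NB exact test ----------------------------------------------

def _pooled_dispersions(
    norm: np.ndarray,
    size_factors: np.ndarray,
    cond_idx: list[np.ndarray],
    min_bin: int = 20,
) -> np.ndarray:
    """Per-feature dispersion alpha in var = mu + alpha mu^2.

    Method-of-moments across within-condition replicates of the normalized
    counts, with the shot-noise term mu * mean(1/s_j) subtracted before
    dividing by mu^2; the per-feature estimate is left unclipped so that
    the trend over features of similar expression (binned by normalized
    mean, >= min_bin per bin where possible) is itself unbiased.  The
    final dispersion is the larger of the feature's own estimate and the
    trend — a conservative sharing rule that protects features whose
    replicate variance is understated by chance.  Without replicates the
    cross-condition estimate stands in, fully pooled by expression bin — a
    documented low-power fallback.
    """
    n_feat = norm.shape[0]
    has_reps = any(len(ix) >= 2 for ix in cond_idx)
    mean_all = norm.mean(axis=1)
    num = np.zeros(n_feat)
    den = 0.0
    groups = (
        [ix for ix in cond_idx if len(ix) >= 2]
        if has_reps
        else [np.arange(norm.shape[1])]
    )
    for ix in groups:
        mu = norm[:, ix].mean(axis=1)
        var = norm[:, ix].var(axis=1, ddof=1)
        shot = mu * float(np.mean(1.0 / size_factors[ix]))
        w = len(ix) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - shot) / mu**2, 0.0)
        num += w * a
        den += w
    raw = num / max(den, 1.0)

    # expression-level pooling: bin by normalized mean
    order = np.argsort(mean_all)
    n_bins = max(1, min(n_feat // min_bin, 50))
    bins = np.array_split(order, n_bins)
    trend = np.zeros(n_feat)
    for b in bins:
        trend[b] = max(0.0, raw[b].mean()) if len(b) else 0.0
    if not has_reps:
        return trend
    return np.clip(np.maximum(raw, trend), 0.0, None)


def _nb_pmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    """NB pmf parameterized by mean and variance; Poisson when var <= mu."""
    if mu <= 0:
        return np.where(x == 0, 1.0, 0.0)
    if var <= mu * (1 + 1e-12):
        return stats.poisson.pmf(x, mu)
    size = mu * mu / (var - mu)
    p = size / (size + mu)
    return stats.nbinom.pmf(x, size, p)


def _exact_test(
    ka: int, kb: int, mu_a: float, var_a: float, mu_b: float, var_b: float
) -> float:
    """Two-sided p conditioning on the total ka + kb: sum the probabilities
    of all splits as or less likely than the observed one."""
    n = ka + kb
    a = np.arange(n + 1)
    pa = _nb_pmf(a, mu_a, var_a)
    pb = _nb_pmf(n - a, mu_b, var_b)
    joint = pa * pb
    total = joint.sum()
    if total <= 0:
        return 1.0
    p_obs = joint[ka]
    return float(min(1.0, joint[joint <= p_obs * (1 + 1e-10)].sum() / total))


def count_diff(
    counts: pd.DataFrame,
    conditions: dict[str, str] | pd.Series,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Simplified NB exact test per feature between two conditions.

    ``counts`` is features x samples (integers); ``conditions`` maps sample
    to one of exactly two condition labels.  Returns a DataFrame with
    baseMeanA/baseMeanB (normalized means), log2FC, stat (NaN for the exact
    test), p, BH-adjusted q and a status column.
    """
    cond = pd.Series(conditions).reindex(counts.columns)
    if cond.isna().any():
        raise DesignError("every sample needs a condition label")
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise DesignError(f"exactly two conditions required, got {levels}")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    m = counts.to_numpy(dtype=float)
    norm = m / sf
    ix_a = np.flatnonzero((cond == levels[0]).to_numpy())
    ix_b = np.flatnonzero((cond == levels[1]).to_numpy())
    alpha = _pooled_dispersions(norm, sf, [ix_a, ix_b])

    sa, sb = sf[ix_a], sf[ix_b]
    rows = []
    for i, feat in enumerate(counts.index):
        ka = int(round(m[i, ix_a].sum()))
        kb = int(round(m[i, ix_b].sum()))
        mean_a = norm[i, ix_a].mean()
        mean_b = norm[i, ix_b].mean()
        if ka + kb == 0:
            rows.append((feat, 0.0, 0.0, 0.0, np.nan, 1.0, STATUS_ZERO))
            continue
        with np.errstate(divide="ignore"):
            log2fc = (
                math.inf if mean_a == 0
                else -math.inf if mean_b == 0
                else math.log2(mean_b / mean_a)
            )
        q_hat = (ka + kb) / (sa.sum() + sb.sum())  # pooled per-unit rate
        mu_a = q_hat * sa.sum()
        mu_b = q_hat * sb.sum()
        # summed variance over replicates: shot noise + overdispersion
        var_a = mu_a + alpha[i] * float(((q_hat * sa) ** 2).sum())
        var_b = mu_b + alpha[i] * float(((q_hat * sb) ** 2).sum())
        p = _exact_test(ka, kb, mu_a, var_a, mu_b, var_b)
        rows.append((feat, mean_a, mean_b, log2fc, np.nan, p, STATUS_TESTED))
    out = pd.DataFrame(
        rows,
        columns=["feature", "baseMeanA", "baseMeanB", "log2FC", "stat", "p", "status"],
    ).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["baseMeanA", "baseMeanB", "log2FC", "stat", "p", "q", "status"]]


def write_diff_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", float_format="%.6g")
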