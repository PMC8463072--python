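"""Differential expression with empirical-Bayes moderated t-statistics.

The model is the standard hierarchical variance model for two-group
expression contrasts: per-protein residual variances ``s^2`` with ``d``
residual degrees of freedom are assumed to follow a scaled F distribution
around a prior variance ``s0^2`` with prior degrees of freedom ``d0``.  The
prior is estimated by moment matching on log variances (digamma/trigamma
equations); the posterior variance

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces ``s^2`` in the t statistic, which is then referred to a t
distribution with ``d0 + d`` degrees of freedom.  ``d0 = 0`` recovers the
ordinary pooled two-sample t test; ``d0 = +inf`` fixes every variance at
``s0^2``.

Significance classes follow the fold-change-distribution convention used
throughout the study: with ``m`` and ``sd`` the median and standard
deviation of the contrast's log2 fold changes,

* ``***``  : p < 1e-4 and |log2fc - m| >= 1.5 * sd
* ``**``   : p < 1e-3 and |log2fc - m| >= 1.0 * sd
* enrichment candidates (for ORA): p < 1e-3 and |log2fc - m| >= 1.5 * sd,
  split into an up and a down set.

Storey q-values (smoother pi0 estimate over a lambda grid) are attached for
protein-level FDR; Welch's unequal-variance t test covers aggregate
quantities such as summed gene-set copy numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, special, stats

__all__ = [
    "ModerationPrior",
    "FoldChangeDistribution",
    "ModeratedTTest",
    "ModeratedTTestResults",
    "log_transform",
    "fit_moderation_prior",
    "moderated_t_test",
    "storey_qvalues",
    "welch_t",
    "classify_significance",
    "select_enrichment_candidates",
    "exclusive_proteins",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 (may be +inf) and s0^2."""

    d0: float
    s0_sq: float
    residual_df: float

    def posterior_variance(self, s2: np.ndarray, df: float | np.ndarray) -> np.ndarray:
        s2 = np.asarray(s2, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(s2, self.s0_sq)
        return (self.d0 * self.s0_sq + df * s2) / (self.d0 + df)


@dataclass(frozen=True)
class FoldChangeDistribution:
    """Median and SD of the tested contrast's log2 fold changes."""

    median: float
    sd: float


def log_transform(values, pseudocount: float = 1.0):
    """``log2(x + pseudocount)`` elementwise; rejects negative entries."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    arr = values.to_numpy() if hasattr(values, "to_numpy") else np.asarray(values, float)
    if np.any(arr < 0):
        raise ValueError("negative entries cannot be log-transformed")
    out = np.log2(arr + pseudocount)
    if hasattr(values, "to_numpy"):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_moderation_prior(
    residual_variances, residual_df: float, min_genes: int = 10
) -> ModerationPrior:
    """Estimate (d0, s0^2) by moment matching of log residual variances.

    With z = log s^2 and e = z - digamma(d/2) + log(d/2), the scaled-F model
    implies E[e] = log s0^2 - digamma(d0/2) + log(d0/2) and
    Var[e] = trigamma(d/2) + trigamma(d0/2); solving the second equation for
    d0 (trigamma inverse) and substituting gives s0^2.  When the observed
    spread of log variances is at or below its expectation under equal true
    variances, d0 = +inf and s0^2 is the geometric-mean-based common value.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if np.all(s2 <= 0):
        raise ValueError("all residual variances are zero: degenerate input")
    pos = s2[s2 > 0]
    if pos.size < s2.size:
        logger.warning("fit_moderation_prior: dropping %d zero variance(s)", s2.size - pos.size)
    if pos.size < min_genes:
        raise ValueError(f"need >= {min_genes} positive residual variances, got {pos.size}")
    if residual_df <= 0:
        raise ValueError("residual_df must be > 0")
    d = float(residual_df)
    e = np.log(pos) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return ModerationPrior(d0=np.inf, s0_sq=float(np.exp(e_mean)), residual_df=d)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq, residual_df=d)


def _two_sided_p(t: np.ndarray, df: float) -> np.ndarray:
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


class ModeratedTTest:
    """Two-group moderated-t model over a log2 expression matrix.

    Parameters
    ----------
    log2_matrix
        Proteins x samples DataFrame of log2 values.
    group_a, group_b
        Column labels of the two groups (each >= 2, disjoint).  The fold
        change is reported as a - b.
    prior
        Optional fixed :class:`ModerationPrior`; by default the prior is
        estimated from the data during :meth:`fit`.
    """

    def __init__(self, log2_matrix: pd.DataFrame, group_a, group_b,
                 prior: ModerationPrior | None = None):
        group_a, group_b = list(group_a), list(group_b)
        if set(group_a) & set(group_b):
            raise ValueError("group columns overlap")
        if len(group_a) < 2 or len(group_b) < 2:
            raise ValueError("each group needs >= 2 columns")
        missing = (set(group_a) | set(group_b)) - set(log2_matrix.columns)
        if missing:
            raise ValueError(f"unknown column(s): {sorted(missing)}")
        self.data = log2_matrix
        self.group_a = group_a
        self.group_b = group_b
        self.prior = prior

    def fit(self, lambda_grid=None) -> "ModeratedTTestResults":
        a = self.data[self.group_a].to_numpy(dtype=float)
        b = self.data[self.group_b].to_numpy(dtype=float)
        ok = (np.isfinite(a).sum(axis=1) >= 2) & (np.isfinite(b).sum(axis=1) >= 2)
        excluded = list(self.data.index[~ok])
        if excluded:
            logger.warning("moderated t: excluding %d protein(s) with < 2 finite values per group",
                           len(excluded))
        a, b = a[ok], b[ok]
        na, nb = a.shape[1], b.shape[1]
        df = na + nb - 2
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        fc = mean_a - mean_b
        ss = np.nansum((a - mean_a[:, None]) ** 2, axis=1) + \
             np.nansum((b - mean_b[:, None]) ** 2, axis=1)
        s2 = ss / df

        prior = self.prior
        if prior is None:
            try:
                prior = fit_moderation_prior(s2, df)
            except ValueError as exc:
                # too few genes to estimate a prior: fall back to the
                # ordinary pooled t (no moderation)
                logger.warning("moderated t: %s; falling back to d0 = 0", exc)
                prior = ModerationPrior(d0=0.0, s0_sq=float(np.mean(s2)) or 1.0,
                                        residual_df=df)
        s2_post = prior.posterior_variance(s2, df)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, fc / np.where(se == 0, 1.0, se), 0.0)
        df_total = prior.d0 + df
        p = _two_sided_p(t, df_total)
        p = np.where((fc == 0), 1.0, p)  # exact-zero fold change
        p = np.clip(p, 0.0, 1.0)
        q = storey_qvalues(p, lambda_grid=lambda_grid)

        fc_dist = FoldChangeDistribution(median=float(np.median(fc)),
                                         sd=float(np.std(fc, ddof=1)) if fc.size > 1 else 0.0)
        table = pd.DataFrame(
            {
                "mean_log2_a": mean_a,
                "mean_log2_b": mean_b,
                "log2fc": fc,
                "s2": s2,
                "s2_post": s2_post,
                "t": t,
                "p_value": p,
                "q_value": q,
            },
            index=self.data.index[ok],
        )
        table["star"] = classify_significance(table["log2fc"], table["p_value"], fc_dist)
        return ModeratedTTestResults(
            model=self, table=table, prior=prior, fc_dist=fc_dist,
            excluded=excluded, df_residual=df,
        )


@dataclass
class ModeratedTTestResults:
    """Fitted moderated-t contrast: per-protein estimates and diagnostics."""

    model: ModeratedTTest
    table: pd.DataFrame
    prior: ModerationPrior
    fc_dist: FoldChangeDistribution
    excluded: list
    df_residual: float

    def candidates(self, p_threshold: float = 1e-3, sd_multiple: float = 1.5):
        """Up/down enrichment candidate ids at the study's selection rule."""
        return select_enrichment_candidates(
            self.table, self.fc_dist, p_threshold=p_threshold, sd_multiple=sd_multiple
        )

    def summary(self) -> str:
        n = len(self.table)
        stars = self.table["star"].value_counts()
        up, down = self.candidates()
        lines = [
            "Moderated two-sample t-test (empirical-Bayes variance moderation)",
            "=" * 66,
            f"proteins tested:      {n}  (excluded: {len(self.excluded)})",
            f"groups:               a={len(self.model.group_a)} columns, "
            f"b={len(self.model.group_b)} columns (log2fc = a - b)",
            f"residual df:          {self.df_residual}",
            f"prior d0:             {self.prior.d0:.4g}",
            f"prior s0^2:           {self.prior.s0_sq:.4g}",
            f"log2fc median:        {self.fc_dist.median:.4g}",
            f"log2fc sd:            {self.fc_dist.sd:.4g}",
            f"'**' calls:           {int(stars.get('**', 0))}",
            f"'***' calls:          {int(stars.get('***', 0))}",
            f"candidates (up/down): {len(up)}/{len(down)}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="group_id", float_format="%.6g")


def moderated_t_test(
    log2_matrix: pd.DataFrame, group_a, group_b, prior: ModerationPrior | None = None
) -> ModeratedTTestResults:
    """Functional wrapper: fit a :class:`ModeratedTTest` in one call."""
    return ModeratedTTest(log2_matrix, group_a, group_b, prior=prior).fit()


def storey_qvalues(p_values, lambda_grid=None, min_for_estimation: int = 20) -> np.ndarray:
    """Storey q-values with the smoother pi0 convention.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated over the
    grid (default 0.05..0.95 step 0.05); a cubic smoothing spline is
    evaluated at the largest lambda and clipped to (0, 1].  With a single
    grid value the raw estimate at that lambda is used.  Fewer than
    ``min_for_estimation`` p-values fall back to pi0 = 1 (Benjamini-
    Hochberg).  q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lam = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if m < min_for_estimation:
        pi0 = 1.0
    else:
        pi0_lam = np.array([(p > L).sum() / (m * (1.0 - L)) for L in lam])
        if lam.size == 1:
            pi0 = float(pi0_lam[0])
        else:
            spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spline(lam.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)  # clip to (0, 1]
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_t(values_a, values_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: returns (t, df_welch, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each side needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    if num == 0:  # both variances zero: degenerate, decide by the mean difference
        diff = a.mean() - b.mean()
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0
    return float(res.statistic), float(num / den), float(res.pvalue)


def classify_significance(
    log2fc, p_values, fc_dist: FoldChangeDistribution
) -> np.ndarray:
    """Assign ns / ** / *** by p-value and fold-change-distribution cutoffs.

    ``***`` iff p < 1e-4 and |log2fc - median| >= 1.5 sd; else ``**`` iff
    p < 1e-3 and |log2fc - median| >= 1 sd; else ``ns``.  A zero sd
    suppresses all non-ns labels (with a warning).
    """
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p_values, dtype=float)
    star = np.full(fc.shape, "ns", dtype=object)
    if fc_dist.sd == 0:
        logger.warning("classify_significance: sd of fold changes is 0; all labels ns")
        return star
    dev = np.abs(fc - fc_dist.median)
    star[(p < 1e-3) & (dev >= 1.0 * fc_dist.sd)] = "**"
    star[(p < 1e-4) & (dev >= 1.5 * fc_dist.sd)] = "***"
    return star


def select_enrichment_candidates(
    results: pd.DataFrame,
    fc_dist: FoldChangeDistribution,
    p_threshold: float = 1e-3,
    sd_multiple: float = 1.5,
) -> tuple[set, set]:
    """Up/down candidate sets for overrepresentation analysis.

    up = {p < p_threshold and log2fc >= median + k sd},
    down = {p < p_threshold and log2fc <= median - k sd}; disjoint for sd > 0.
    """
    fc = results["log2fc"].to_numpy(dtype=float)
    p = results["p_value"].to_numpy(dtype=float)
    hi = fc_dist.median + sd_multiple * fc_dist.sd
    lo = fc_dist.median - sd_multiple * fc_dist.sd
    sig = p < p_threshold
    up = set(results.index[sig & (fc >= hi)]) if fc_dist.sd > 0 else set()
    down = set(results.index[sig & (fc <= lo)]) if fc_dist.sd > 0 else set()
    return up, down


def exclusive_proteins(
    values: pd.DataFrame, cols_a, cols_b, min_detect_frac: float = 0.5
) -> tuple[set, set]:
    """Proteins detected in only one of two populations.

    A protein is exclusive to a if it is zero in every b sample and nonzero
    in at least ``min_detect_frac`` of a's samples (and vice versa).  These
    are reported separately instead of being given unbounded fold changes.
    """
    a = values[list(cols_a)].to_numpy(dtype=float)
    b = values[list(cols_b)].to_numpy(dtype=float)
    det_a = (a > 0).mean(axis=1)
    det_b = (b > 0).mean(axis=1)
    only_a = (det_a >= min_detect_frac) & (det_b == 0)
    only_b = (det_b >= min_detect_frac) & (det_a == 0)
    return set(values.index[only_a]), set(values.index[only_b])
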