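"""Global proteome-structure summaries over a copy-number matrix.

Covers the descriptive analyses that sit alongside differential testing:
sample-level PCA, pairwise population correlations of log copy numbers,
abundance-ranked mass-fraction categories ("which families make up the top
half of the proteome mass"), and gene-set copy-number sums with Welch tests
between two populations.

Copy numbers span ~6 orders of magnitude, so PCA and correlations operate
on log-transformed values by default (log2(x+1) and log10(x+1)); both
transforms are switchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffstats import welch_t
from .enrich import GeneSetCollection
from .ruler import CopyNumberMatrix

__all__ = [
    "PcaResult",
    "pca_samples",
    "population_correlation",
    "category_mass_fractions",
    "geneset_sums",
]

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Sample scores, per-component variance fractions and loadings."""

    scores: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray
    loadings: pd.DataFrame  # proteins x components
    transform: str


def pca_samples(
    matrix: CopyNumberMatrix,
    transform: str = "log2",
    scope: str = "complete",
    pseudocount: float = 1.0,
) -> PcaResult:
    """PCA of samples on (transformed) copy numbers.

    Features are per-protein mean-centred; components come from the SVD of
    the samples x proteins matrix with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).  ``scope``
    ``"complete"`` restricts to proteins detected (> 0) in every sample;
    ``"all"`` uses every row.  Variance fractions over all components sum
    to 1.
    """
    values = matrix.values
    if scope == "complete":
        values = values[(values > 0).all(axis=1)]
    elif scope != "all":
        raise ValueError(f"unknown scope: {scope!r}")
    if values.shape[0] < 2:
        raise ValueError("scope empty (or singleton) after filtering")
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    if transform == "log2":
        X = np.log2(values.to_numpy(dtype=float) + pseudocount)
    elif transform == "none":
        X = values.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown transform: {transform!r}")
    X = X.T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=comp),
        variance_fractions=frac,
        loadings=pd.DataFrame(Vt.T, index=values.index, columns=comp),
        transform=transform,
    )


def population_correlation(
    pop_medians: pd.DataFrame,
    pseudocount: float = 1.0,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log10 population copy numbers.

    For each population pair, r is computed on ``log10(x + pseudocount)``
    over the proteins detected (> 0) in both populations.  Pairs with fewer
    than ``min_shared`` shared proteins, or with a zero-variance vector,
    yield NaN (reported missing, never coerced to 0).  The matrix is
    symmetric with unit diagonal.
    """
    pops = list(pop_medians.columns)
    vals = pop_medians.to_numpy(dtype=float)
    out = pd.DataFrame(np.eye(len(pops)), index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            mask = (vals[:, i] > 0) & (vals[:, j] > 0)
            if mask.sum() < min_shared:
                logger.warning(
                    "population_correlation: only %d shared proteins for (%s, %s)",
                    int(mask.sum()), pops[i], pops[j],
                )
                r = np.nan
            else:
                x = np.log10(vals[mask, i] + pseudocount)
                y = np.log10(vals[mask, j] + pseudocount)
                if x.std() == 0 or y.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


def category_mass_fractions(
    matrix: CopyNumberMatrix,
    categories: GeneSetCollection,
    basis: str = "mass",
    top_fraction: float = 0.5,
) -> pd.DataFrame:
    """Category composition of the abundance-ranked top of the proteome.

    Per sample, proteins are ranked by ``basis`` (``"mass"`` = copies x MW,
    ``"copies"``) and the top set is the smallest prefix whose cumulative
    basis reaches ``top_fraction`` of the sample total (the crossing protein
    is included).  Categories are matched on gene names; overlapping
    categories are rejected.  Returns tidy rows (sample, category, value,
    proportion) including an ``other`` remainder, with proportions summing
    to 1 per sample.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    if basis == "mass":
        data = matrix.mass_pg()
    elif basis == "copies":
        data = matrix.values
    else:
        raise ValueError(f"unknown basis: {basis!r}")
    # reject overlap between categories
    seen: dict[str, str] = {}
    for name, members in categories.sets.items():
        for g in members:
            if g in seen:
                raise ValueError(f"categories overlap: {g!r} in both {seen[g]!r} and {name!r}")
            seen[g] = name
    genes = matrix.row_meta["gene_name"]
    rows = []
    for sample in data.columns:
        col = data[sample].to_numpy(dtype=float)
        total = col.sum()
        if total <= 0:
            continue
        order = np.argsort(-col, kind="mergesort")
        cum = np.cumsum(col[order])
        cutoff = int(np.searchsorted(cum, top_fraction * total)) + 1
        top_idx = order[:cutoff]
        top_genes = genes.iloc[top_idx]
        top_vals = col[top_idx]
        top_total = top_vals.sum()
        assigned = np.zeros(len(top_idx), dtype=bool)
        for name, members in categories.sets.items():
            mask = top_genes.isin(members).to_numpy()
            assigned |= mask
            val = float(top_vals[mask].sum())
            rows.append((sample, name, val, val / top_total))
        other = float(top_vals[~assigned].sum())
        rows.append((sample, "other", other, other / top_total))
    return pd.DataFrame(rows, columns=["sample", "category", "value", "proportion"])


def geneset_sums(
    matrix: CopyNumberMatrix,
    sets: GeneSetCollection,
    contrast: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summed copy numbers per gene set and sample, with optional Welch tests.

    Returns ``(sums, tests)``: ``sums`` is sets x samples; ``tests`` has one
    row per set with Welch t/df/p for the requested two-population contrast
    (empty when ``contrast`` is None).  Sets resolving to zero matrix rows
    are skipped with a warning.
    """
    genes = matrix.row_meta["gene_name"]
    sum_rows = {}
    for name, members in sets.sets.items():
        mask = genes.isin(members).to_numpy()
        if not mask.any():
            logger.warning("geneset_sums: set %r resolves to 0 rows, skipped", name)
            continue
        sum_rows[name] = matrix.values.loc[mask].sum(axis=0)
    sums = pd.DataFrame(sum_rows).T
    sums.index.name = "set"
    if contrast is None or sums.empty:
        return sums, pd.DataFrame(columns=["set", "t", "df_welch", "p_value"])
    pop_a, pop_b = contrast
    cols_a = matrix.samples_for(pop_a)
    cols_b = matrix.samples_for(pop_b)
    rows = []
    for name in sums.index:
        t, df, p = welch_t(sums.loc[name, cols_a], sums.loc[name, cols_b])
        rows.append((name, t, df, p))
    return sums, pd.DataFrame(rows, columns=["set", "t", "df_welch", "p_value"])
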