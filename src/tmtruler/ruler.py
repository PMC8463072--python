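"""Histone proteomic ruler: MS1 allocation and per-cell copy numbers.

The two quantification levels of an SPS-MS3 TMT experiment are combined in
two steps:

1. **Allocation** — each protein group's summed MS1 intensity is distributed
   across channels in proportion to its fractional MS3 reporter intensities,
   giving a per-sample intensity matrix whose rows sum back to MS1 exactly.
2. **Ruler** — per sample, intensities are converted to copies per cell by
   anchoring the summed histone signal to the cell's DNA mass::

       copies[p, s] = I[p, s] / MW_p * (m_DNA * N_A) / sum_h I[h, s]

   with ``m_DNA`` in grams and the sum over histone rows.  The estimator is
   a ratio, hence invariant to any per-sample intensity rescaling, and it
   conserves the anchor: summed histone mass per cell equals ``m_DNA`` in
   every sample by construction.

Protein content (pg/cell) follows as ``sum_p copies * MW / N_A``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ChannelDesign

__all__ = [
    "AVOGADRO",
    "CopyNumberMatrix",
    "ContentSummary",
    "allocate_ms1",
    "allocate_table",
    "estimate_copy_numbers",
    "protein_content",
    "aggregate_population",
]

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
PG_PER_G = 1e12

#: default DNA mass per diploid mouse cell, picograms
#: (~2 x 2.7 Gbp at ~615 g/mol per base pair)
DEFAULT_DNA_MASS_PG = 5.52


@dataclass
class CopyNumberMatrix:
    """Proteins x samples matrix of estimated copies per cell.

    ``values`` is indexed by group_id with sample-label columns; ``row_meta``
    carries gene_name, mol_weight_da and is_histone per group; ``col_meta``
    carries population and replicate per sample.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame
    dna_mass_pg: float
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.row_meta.index):
            raise ValueError("row_meta index must match values index")
        if list(self.values.columns) != list(self.col_meta.index):
            raise ValueError("col_meta index must match values columns")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, population: str) -> list[str]:
        mask = self.col_meta["population"] == population
        if not mask.any():
            raise KeyError(f"unknown population: {population!r}")
        return list(self.col_meta.index[mask])

    def drop_samples(self, samples) -> "CopyNumberMatrix":
        keep = [s for s in self.values.columns if s not in set(samples)]
        return CopyNumberMatrix(
            values=self.values[keep],
            row_meta=self.row_meta,
            col_meta=self.col_meta.loc[keep],
            dna_mass_pg=self.dna_mass_pg,
            avogadro=self.avogadro,
        )

    def mass_pg(self) -> pd.DataFrame:
        """Per-protein, per-sample mass in picograms (copies x MW / N_A)."""
        mw = self.row_meta["mol_weight_da"].to_numpy()
        return self.values.mul(mw, axis=0) / self.avogadro * PG_PER_G

    def to_tsv(self, path) -> None:
        out = pd.concat([self.row_meta, self.values], axis=1)
        out.to_csv(path, sep="\t", index_label="group_id", float_format="%.10g")


@dataclass
class ContentSummary:
    """Per-sample total protein content (pg/cell) with population summaries."""

    per_sample: pd.Series  # pg per cell, indexed by sample
    per_population: pd.DataFrame = field(default=None)  # mean, sd, n per population

    def to_tsv(self, path) -> None:
        self.per_sample.rename("content_pg").to_csv(path, sep="\t", index_label="sample")


def allocate_ms1(ms1_intensity: float, reporters: np.ndarray) -> np.ndarray:
    """Allocate one record's summed MS1 intensity by fractional reporters.

    ``allocated_k = ms1 * r_k / sum_j r_j``; channels with zero reporter get
    zero and the allocations sum to the MS1 intensity exactly.  Raises if
    MS1 > 0 but every reporter is zero (unallocatable record).
    """
    reporters = np.asarray(reporters, dtype=float)
    if np.any(reporters < 0):
        raise ValueError("negative reporter intensity")
    if ms1_intensity < 0:
        raise ValueError("negative MS1 intensity")
    total = reporters.sum()
    if ms1_intensity == 0:
        return np.zeros_like(reporters)
    if total == 0:
        raise ValueError("unallocatable record: MS1 > 0 with all reporters zero")
    return ms1_intensity * (reporters / total)


def allocate_table(
    table: pd.DataFrame, design: ChannelDesign
) -> tuple[pd.DataFrame, list[str]]:
    """Vectorised allocation over a canonical protein-group table.

    Returns ``(allocated, dropped_ids)`` where ``allocated`` is a proteins x
    samples intensity DataFrame indexed by group_id and ``dropped_ids`` lists
    unallocatable records (MS1 > 0, all reporters zero), which are excluded
    rather than silently zeroed.
    """
    samples = design.samples
    rep = table[samples].to_numpy(dtype=float)
    ms1 = table["ms1_intensity"].to_numpy(dtype=float)
    if np.any(rep < 0) or np.any(ms1 < 0):
        raise ValueError("negative intensity in table")
    total = rep.sum(axis=1)
    unalloc = (ms1 > 0) & (total == 0)
    dropped = list(table.loc[unalloc, "group_id"])
    if dropped:
        logger.warning("dropping %d unallocatable record(s)", len(dropped))
    keep = ~unalloc
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total[:, None] > 0, rep / np.where(total == 0, 1.0, total)[:, None], 0.0)
    alloc = ms1[:, None] * frac
    out = pd.DataFrame(alloc[keep], index=table.loc[keep, "group_id"], columns=samples)
    return out, dropped


def estimate_copy_numbers(
    allocated: pd.DataFrame,
    row_meta: pd.DataFrame,
    col_meta: pd.DataFrame,
    dna_mass_pg: float = DEFAULT_DNA_MASS_PG,
) -> CopyNumberMatrix:
    """Convert allocated intensities to copies per cell with the histone ruler.

    ``row_meta`` must provide ``mol_weight_da`` (> 0) and ``is_histone``
    (>= 1 histone with positive intensity required in every sample).
    """
    row_meta = row_meta.loc[allocated.index]
    mw = row_meta["mol_weight_da"].to_numpy(dtype=float)
    if np.any(~(mw > 0)):
        raise ValueError("mol_weight_da must be > 0 for all rows")
    inten = allocated.to_numpy(dtype=float)
    if np.any(inten < 0):
        raise ValueError("negative intensity")
    hist = row_meta["is_histone"].to_numpy(dtype=bool)
    if not hist.any():
        raise ValueError("ruler undefined: no histone rows")
    hist_sum = inten[hist].sum(axis=0)
    zero = hist_sum <= 0
    if zero.any():
        bad = list(np.asarray(allocated.columns)[zero])
        raise ValueError(f"zero histone intensity in sample(s): {bad}")
    dna_mass_g = dna_mass_pg * 1e-12
    copies = (inten / mw[:, None]) * (dna_mass_g * AVOGADRO) / hist_sum[None, :]
    return CopyNumberMatrix(
        values=pd.DataFrame(copies, index=allocated.index, columns=allocated.columns),
        row_meta=row_meta[["gene_name", "mol_weight_da", "is_histone"]]
        if set(["gene_name", "mol_weight_da", "is_histone"]).issubset(row_meta.columns)
        else row_meta,
        col_meta=col_meta.loc[list(allocated.columns)],
        dna_mass_pg=dna_mass_pg,
    )


def protein_content(matrix: CopyNumberMatrix) -> ContentSummary:
    """Total protein mass per cell (pg): ``sum_p copies * MW / N_A``."""
    totals = matrix.mass_pg().sum(axis=0)
    pops = matrix.col_meta["population"]
    per_pop = totals.groupby(pops).agg(["mean", "std", "count"])
    per_pop.columns = ["mean_pg", "sd_pg", "n"]
    return ContentSummary(per_sample=totals, per_population=per_pop)


def aggregate_population(
    matrix: CopyNumberMatrix, statistic: str = "median"
) -> pd.DataFrame:
    """Per-protein per-population summary (median or mean) of copy numbers."""
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    pops = matrix.col_meta["population"]
    grouped = matrix.values.T.groupby(pops)
    agg = grouped.median() if statistic == "median" else grouped.mean()
    # preserve design population order
    order = list(dict.fromkeys(pops))
    return agg.T[order]
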