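"""Reading and quality-filtering MaxQuant-style protein-group tables.

The reader consumes the tab-delimited ``proteinGroups.txt`` dialect (one row
per protein group, ``+``-style boolean flags, ``Mol. weight [kDa]``) and
returns a DataFrame with canonical column names plus one reporter-intensity
column per sample in the channel design.  Row filters and the replicate
protein-content QC implement the study-standard rules: drop contaminant /
reverse / only-identified-by-site rows and rows with fewer than two
razor+unique peptides, and flag replicates whose protein content deviates
from the leave-one-out median of their population by at least a threshold
(default 15%, mirroring the magnitudes that motivated the rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .design import ChannelDesign

__all__ = [
    "ProteinGroup",
    "read_protein_groups",
    "filter_protein_groups",
    "identify_histones",
    "default_histone_genes",
    "qc_replicates",
]

logger = logging.getLogger(__name__)

#: canonical metadata columns of the parsed table, in order
META_COLUMNS = [
    "group_id",
    "protein_ids",
    "gene_name",
    "mol_weight_da",
    "ms1_intensity",
    "razor_unique_peptides",
    "is_contaminant",
    "is_reverse",
    "only_by_site",
    "is_histone",
]

_MANDATORY = {
    "group_id": ["id"],
    "protein_ids": ["Protein IDs", "Majority protein IDs"],
    "gene_name": ["Gene names"],
    "mol_weight_da": ["Mol. weight [kDa]"],
    "ms1_intensity": ["Intensity"],
    "razor_unique_peptides": ["Razor + unique peptides", "Unique peptides"],
}
_FLAGS = {
    "is_contaminant": ["Potential contaminant", "Contaminant"],
    "is_reverse": ["Reverse"],
    "only_by_site": ["Only identified by site"],
}


@dataclass(frozen=True)
class ProteinGroup:
    """One quantified protein group (record view of a table row)."""

    group_id: str
    protein_ids: str
    gene_name: str
    mol_weight_da: float
    ms1_intensity: float
    reporter_intensities: tuple[float, ...]
    razor_unique_peptides: int
    is_contaminant: bool = False
    is_reverse: bool = False
    only_by_site: bool = False
    is_histone: bool = False


def _resolve(df: pd.DataFrame, candidates: list[str], what: str) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise ValueError(f"missing mandatory column for {what!r}: expected one of {candidates}")


def read_protein_groups(
    path,
    design: ChannelDesign,
    peptide_column: str = "Razor + unique peptides",
) -> pd.DataFrame:
    """Parse a proteinGroups.txt-dialect TSV into the canonical table.

    Reporter columns are taken as ``Reporter intensity corrected <label>``
    when present, else ``Reporter intensity <label>`` (logged).  Returns a
    DataFrame with :data:`META_COLUMNS` plus one column per sample label,
    holding that channel's reporter intensity (missing cells -> 0).

    ``peptide_column`` switches between MaxQuant's razor+unique and
    unique-only peptide counts for the downstream >= 2 peptide filter.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = pd.DataFrame()
    for name, candidates in _MANDATORY.items():
        cands = [peptide_column] + candidates if name == "razor_unique_peptides" else candidates
        col = _resolve(raw, cands, name)
        out[name] = raw[col]
    for name, candidates in _FLAGS.items():
        found = [c for c in candidates if c in raw.columns]
        out[name] = raw[found[0]].str.strip().eq("+") if found else False

    for name, empty in [("mol_weight_da", "nan"), ("ms1_intensity", "0"),
                        ("razor_unique_peptides", "0")]:
        col = out[name].replace("", empty)
        try:
            out[name] = pd.to_numeric(col, errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(col, errors="coerce").isna()
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric value in column for {name!r} at data row {i}: {col.iloc[i]!r}"
            ) from None
    out["mol_weight_da"] = out["mol_weight_da"] * 1000.0  # kDa -> Da
    out["razor_unique_peptides"] = out["razor_unique_peptides"].astype(int)
    out["is_histone"] = False

    if out["group_id"].duplicated().any():
        dup = out.loc[out["group_id"].duplicated(), "group_id"].iloc[0]
        raise ValueError(f"duplicate group id: {dup!r}")

    corrected = all(f"Reporter intensity corrected {c.label}" in raw.columns for c in design.channels)
    prefix = "Reporter intensity corrected" if corrected else "Reporter intensity"
    logger.info("using reporter columns %r", prefix)
    for c in design.channels:
        col = f"{prefix} {c.label}"
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column for channel {c.label!r}: {col!r}")
        vals = pd.to_numeric(raw[col].replace("", "0"), errors="coerce")
        if vals.isna().any():
            i = int(np.argmax(vals.isna().to_numpy()))
            raise ValueError(f"non-numeric intensity at data row {i}, column {col!r}")
        out[c.sample] = vals.astype(float)

    return out[META_COLUMNS + design.samples]


def records(table: pd.DataFrame, design: ChannelDesign) -> list[ProteinGroup]:
    """Record (dataclass) view of a canonical table."""
    return [
        ProteinGroup(
            group_id=row.group_id,
            protein_ids=row.protein_ids,
            gene_name=row.gene_name,
            mol_weight_da=row.mol_weight_da,
            ms1_intensity=row.ms1_intensity,
            reporter_intensities=tuple(getattr(row, s) for s in design.samples),
            razor_unique_peptides=row.razor_unique_peptides,
            is_contaminant=row.is_contaminant,
            is_reverse=row.is_reverse,
            only_by_site=row.only_by_site,
            is_histone=row.is_histone,
        )
        for row in table.itertuples(index=False)
    ]


def filter_protein_groups(
    table: pd.DataFrame, min_peptides: int = 2
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the standard row filters.

    Retains rows with contaminant/reverse/only-by-site all false and at
    least ``min_peptides`` razor+unique peptides.  The report counts removed
    rows per reason (a row is counted once per failing reason) plus the
    number of unique rows removed.
    """
    contam = table["is_contaminant"].to_numpy(bool)
    rev = table["is_reverse"].to_numpy(bool)
    site = table["only_by_site"].to_numpy(bool)
    lowpep = table["razor_unique_peptides"].to_numpy() < min_peptides
    bad = contam | rev | site | lowpep
    report = {
        "contaminant": int(contam.sum()),
        "reverse": int(rev.sum()),
        "only_by_site": int(site.sum()),
        "low_peptides": int(lowpep.sum()),
        "removed": int(bad.sum()),
        "retained": int((~bad).sum()),
    }
    return table.loc[~bad].reset_index(drop=True), report


def default_histone_genes() -> list[str]:
    """The shipped default list of mouse core and linker histone gene symbols."""
    text = resources.files("tmtruler.data").joinpath("histone_genes_mouse.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def identify_histones(
    table: pd.DataFrame, histone_genes: list[str] | None = None
) -> pd.DataFrame:
    """Set ``is_histone`` by case-insensitive exact gene-symbol match.

    Raises if no retained row matches: the proteomic ruler is undefined
    without at least one histone anchor.
    """
    if histone_genes is None:
        histone_genes = default_histone_genes()
    if not histone_genes:
        raise ValueError("histone_genes must be non-empty")
    wanted = {g.casefold() for g in histone_genes}
    out = table.copy()
    out["is_histone"] = out["gene_name"].fillna("").str.casefold().isin(wanted)
    if not out["is_histone"].any():
        raise ValueError("ruler undefined: no histone gene matched the table")
    return out


def qc_replicates(
    content: pd.Series,
    design: ChannelDesign,
    threshold: float = 0.15,
) -> pd.DataFrame:
    """Flag replicates whose protein content deviates from their population.

    ``content`` maps sample label -> protein content (pg/cell).  Within each
    population with >= 3 replicates, a replicate is flagged iff
    ``|c - median(others)| / median(others) >= threshold``.  Populations with
    fewer than 3 replicates are skipped with a warning (the leave-one-out
    median is unstable there).

    Returns a DataFrame indexed by sample with columns population, content,
    deviation, flagged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rows = []
    for pop in design.populations:
        samples = [s for s in design.samples_for(pop) if s in content.index]
        if len(samples) < 3:
            logger.warning("qc_replicates: population %r has < 3 replicates, skipped", pop)
            for s in samples:
                rows.append((s, pop, float(content[s]), np.nan, False))
            continue
        vals = content[samples].astype(float)
        for s in samples:
            others = vals.drop(s)
            med = float(others.median())
            dev = abs(float(vals[s]) - med) / med
            # tiny relative tolerance so the inclusive boundary survives
            # float round-off (e.g. a planted deviation of exactly 15%)
            rows.append((s, pop, float(vals[s]), dev, dev >= threshold * (1.0 - 1e-9)))
    out = pd.DataFrame(rows, columns=["sample", "population", "content_pg", "deviation", "flagged"])
    return out.set_index("sample")
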