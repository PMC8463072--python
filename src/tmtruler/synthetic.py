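"""Synthetic TMT protein-group tables with known ground truth.

The generator emulates a multiplexed isobaric-label (TMT SPS-MS3) experiment
on five CD8 T cell populations — two lymph-node naive populations and three
intestinal intraepithelial (T-IEL) subsets — quantified as a MaxQuant-style
protein-group table.  It produces both the observable table and the latent
truth (per-cell copy numbers, planted fold changes, planted QC anomalies) so
every downstream stage of the pipeline can be tested for recovery.

Two-level noise structure: per-protein "true" channel intensities are exact
(copies x molecular weight x per-channel scale), the summed MS1 intensity is
their noise-free sum, and only the observed reporter intensities carry
multiplicative log-normal noise.  Reallocating MS1 by fractional reporter
intensities is therefore a genuine estimation problem, not an identity.

Histone anchors are drawn from the high-abundance tail and rescaled once so
their summed mass per cell equals the configured DNA mass; with zero reporter
noise the full pipeline then reproduces the true copy numbers exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Channel, ChannelDesign

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_protein_groups",
    "write_fixture",
]

AVOGADRO = 6.02214076e23
PG_PER_G = 1e12

#: Pre-QC replicate counts of the emulated study design (five populations,
#: 24 channels in total).
DEFAULT_POPULATIONS: dict[str, int] = {
    "LN_WT": 6,
    "LN_P14": 6,
    "IEL_ab_ab": 4,
    "IEL_ab_aa": 4,
    "IEL_gd_aa": 4,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A category-level planted fold change.

    ``members`` is either a fraction of the eligible (non-histone, real)
    proteins or an explicit list of gene names.  The effect multiplies true
    copy numbers by ``2**log2fc`` in every listed population.
    """

    name: str
    members: float | tuple[str, ...] | list[str]
    populations: tuple[str, ...] | list[str]
    log2fc: float


@dataclass
class SyntheticConfig:
    n_proteins: int = 8000
    populations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS)
    )
    n_histones: int = 30
    baseline_log10_mean: float = 4.0
    baseline_log10_sd: float = 1.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    reporter_cv: float = 0.10
    n_contaminants: int = 40
    n_reverse: int = 40
    n_low_peptide: int = 60
    absence_fraction: float = 0.05
    planted_outlier: tuple[str, str, float] | None = None  # (population, replicate, multiplier)
    dna_mass_pg: float = 5.52
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_proteins", "n_histones", "n_contaminants", "n_reverse", "n_low_peptide"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_histones == 0:
            raise ValueError("n_histones: must be >= 1 (proteomic ruler undefined without histones)")
        if self.n_histones > self.n_proteins:
            raise ValueError("n_histones: cannot exceed n_proteins")
        if self.reporter_cv < 0:
            raise ValueError("reporter_cv must be >= 0")
        if not 0.0 <= self.absence_fraction <= 1.0:
            raise ValueError("absence_fraction must be in [0, 1]")
        if self.baseline_log10_sd < 0:
            raise ValueError("baseline_log10_sd must be >= 0")
        if self.dna_mass_pg <= 0:
            raise ValueError("dna_mass_pg must be > 0")
        if not self.populations:
            raise ValueError("populations must be non-empty")
        for pop, n in self.populations.items():
            if n < 2:
                raise ValueError(f"populations: {pop} needs >= 2 replicates, got {n}")
        for eff in self.planted_effects:
            if isinstance(eff.members, float) and not 0.0 <= eff.members <= 1.0:
                raise ValueError(f"planted_effects: member fraction of {eff.name!r} must be in [0, 1]")
            unknown = set(eff.populations) - set(self.populations)
            if unknown:
                raise ValueError(f"planted_effects: {eff.name!r} names unknown population(s) {sorted(unknown)}")
        if self.planted_outlier is not None:
            pop, _rep, mult = self.planted_outlier
            if pop not in self.populations:
                raise ValueError(f"planted_outlier: unknown population {pop!r}")
            if mult <= 0:
                raise ValueError("planted_outlier: multiplier must be > 0")

    def design(self) -> ChannelDesign:
        channels = []
        k = 1
        for pop, n in self.populations.items():
            for r in range(1, n + 1):
                channels.append(Channel(str(k), pop, f"r{r}"))
                k += 1
        return ChannelDesign(channels)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated protein-group table."""

    true_copies: pd.DataFrame  # proteins x samples, copies per cell
    planted_log2fc: pd.DataFrame  # proteins x populations
    histone_ids: set[str]
    outlier_samples: set[str]
    category_membership: dict[str, list[str]]


# mouse core and linker histone gene symbols used for simulated histone rows
_HISTONE_SYMBOL_POOL = [
    "H1f0", "Hist1h1a", "Hist1h1b", "Hist1h1c", "Hist1h1d", "Hist1h1e",
    "Hist1h2aa", "Hist1h2ab", "Hist1h2ac", "Hist1h2ad", "Hist1h2ae",
    "Hist1h2ba", "Hist1h2bb", "Hist1h2bc", "Hist1h2be", "Hist1h2bf",
    "Hist1h3a", "Hist1h3b", "Hist1h3c", "Hist1h3d", "Hist1h3e",
    "Hist1h4a", "Hist1h4b", "Hist1h4c", "Hist1h4d", "Hist1h4f",
    "Hist2h2aa1", "Hist2h2ab", "Hist2h2be", "Hist2h3b",
    "Hist3h2a", "Hist3h2ba", "H2afz", "H2afx", "H2afy", "H3f3a", "H3f3b",
    "Hist1h1t", "Hist1h2bg", "Hist1h2bh", "Hist1h2bj", "Hist1h2bk",
    "Hist1h3f", "Hist1h4h", "Hist1h4i", "Hist1h4j", "Hist1h4k",
]


def _histone_symbols(n: int) -> list[str]:
    if n <= len(_HISTONE_SYMBOL_POOL):
        return _HISTONE_SYMBOL_POOL[:n]
    extra = [f"Hist9h9x{i}" for i in range(n - len(_HISTONE_SYMBOL_POOL))]
    return _HISTONE_SYMBOL_POOL + extra


def simulate_protein_groups(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a MaxQuant-dialect protein-group table plus its ground truth.

    Returns ``(table, truth)`` where ``table`` has one row per real protein
    group and per decoy/edge row, with columns in the ``proteinGroups.txt``
    dialect, and ``truth`` carries per-cell copy numbers and planted effects.
    Generation is a pure function of ``config`` (same seed, same bytes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = config.design()
    samples = design.samples
    n_samples = len(samples)
    populations = design.populations
    n = config.n_proteins
    n_hist = config.n_histones

    # --- identities -------------------------------------------------------
    histone_idx = np.arange(n_hist)  # first rows are histones
    genes = _histone_symbols(n_hist) + [f"Gene{i:05d}" for i in range(n_hist, n)]
    group_ids = [f"PG{i:05d}" for i in range(n)]
    protein_ids = [f"P{i:05d}" for i in range(n)]

    # molecular weights (Da): histones 11-22 kDa, the rest log-normal ~50 kDa
    mw = 10 ** rng.normal(4.65, 0.25, size=n)
    mw[histone_idx] = 10 ** rng.uniform(4.05, 4.35, size=n_hist)

    # --- baseline copies and planted effects ------------------------------
    base = 10 ** rng.normal(config.baseline_log10_mean, config.baseline_log10_sd, size=n)
    # histones at the high-abundance tail so they dominate as in real cells
    base[histone_idx] = 10 ** rng.normal(
        config.baseline_log10_mean + 1.5 * config.baseline_log10_sd, 0.2, size=n_hist
    )

    eligible = list(range(n_hist, n))  # non-histone real rows
    planted = np.zeros((n, len(populations)))
    pop_index = {p: j for j, p in enumerate(populations)}
    membership: dict[str, list[str]] = {}
    free = list(eligible)
    for eff in config.planted_effects:
        if isinstance(eff.members, float):
            k = int(round(eff.members * len(eligible)))
            if k > len(free):
                raise ValueError(f"planted_effects: not enough unassigned proteins for {eff.name!r}")
            pick_pos = rng.choice(len(free), size=k, replace=False)
            pick = sorted(free[i] for i in pick_pos)
            free = [g for i, g in enumerate(free) if i not in set(pick_pos)]
        else:
            wanted = set(eff.members)
            pick = [i for i in range(n) if genes[i] in wanted]
            if len(pick) != len(wanted):
                missing = wanted - {genes[i] for i in pick}
                raise ValueError(f"planted_effects: unknown gene(s) in {eff.name!r}: {sorted(missing)[:5]}")
        membership[eff.name] = [group_ids[i] for i in pick]
        for pop in eff.populations:
            planted[pick, pop_index[pop]] += eff.log2fc

    # population-specific absence: a random population per affected protein
    id_to_row = {g: i for i, g in enumerate(group_ids)}
    in_effect = {id_to_row[g] for ids in membership.values() for g in ids}
    absent_pool = [i for i in eligible if i not in in_effect]
    n_absent = int(round(config.absence_fraction * len(absent_pool)))
    absent_rows = rng.choice(len(absent_pool), size=n_absent, replace=False) if n_absent else np.array([], dtype=int)
    absent_idx = np.array([absent_pool[i] for i in absent_rows], dtype=int)
    absent_pop = rng.integers(0, len(populations), size=n_absent)

    # --- true copies per sample ------------------------------------------
    sample_pop = np.array([pop_index[c.population] for c in design.channels])
    copies = base[:, None] * 2.0 ** planted[:, sample_pop]
    for row, jpop in zip(absent_idx, absent_pop):
        copies[row, sample_pop == jpop] = 0.0

    # rescale histones so their summed mass per cell equals the DNA mass;
    # this anchors the absolute scale exactly as the ruler assumes
    hist_mass = float(np.sum(base[histone_idx] * mw[histone_idx])) / AVOGADRO * PG_PER_G
    copies[histone_idx, :] *= config.dna_mass_pg / hist_mass

    outliers: set[str] = set()
    if config.planted_outlier is not None:
        # the multiplier acts on measured protein content: because histone
        # mass is pinned to the DNA mass by the ruler, only the non-histone
        # copies are scaled, by (m - h) / (1 - h) with h the histone mass
        # fraction, so that total content comes out exactly m-fold
        pop, rep, mult = config.planted_outlier
        label = f"{pop}_{rep}"
        if label not in samples:
            raise ValueError(f"planted_outlier: no sample {label!r} in the design")
        j = samples.index(label)
        nonhist = np.ones(n, dtype=bool)
        nonhist[histone_idx] = False
        total_mass = float(np.sum(copies[:, j] * mw)) / AVOGADRO * PG_PER_G
        h = config.dna_mass_pg / total_mass
        if mult <= h:
            raise ValueError(
                f"planted_outlier: content multiplier {mult} not achievable; "
                f"histone mass fraction is {h:.3f}"
            )
        copies[nonhist, j] *= (mult - h) / (1.0 - h)
        outliers.add(label)

    # --- intensities ------------------------------------------------------
    # per-channel acquisition scale (the ruler must be invariant to it)
    channel_scale = 10 ** rng.normal(0.0, 0.1, size=n_samples)
    true_intensity = copies * mw[:, None] * channel_scale[None, :]
    ms1 = true_intensity.sum(axis=1)
    if config.reporter_cv > 0:
        sigma = np.sqrt(np.log1p(config.reporter_cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=true_intensity.shape))
    else:
        noise = 1.0
    reporters = true_intensity * noise

    # --- decoy and edge rows ---------------------------------------------
    def _junk_rows(count: int):
        mw_j = 10 ** rng.normal(4.65, 0.25, size=count)
        inten = 10 ** rng.normal(
            config.baseline_log10_mean, config.baseline_log10_sd, size=(count, n_samples)
        ) * mw_j[:, None]
        return mw_j, inten

    rows = {
        "id": list(group_ids),
        "Protein IDs": list(protein_ids),
        "Gene names": list(genes),
        "Mol. weight [kDa]": list(mw / 1000.0),
        "Intensity": list(ms1),
        "Razor + unique peptides": list(2 + rng.poisson(10, size=n)),
        "Potential contaminant": [""] * n,
        "Reverse": [""] * n,
        "Only identified by site": [""] * n,
    }
    rep_cols = {f"Reporter intensity corrected {c.label}": list(reporters[:, j])
                for j, c in enumerate(design.channels)}

    extra_specs = [
        ("CON", config.n_contaminants, "Potential contaminant"),
        ("REV", config.n_reverse, "Reverse"),
        ("LOWPEP", config.n_low_peptide, None),
    ]
    next_id = n
    for tag, count, flag_col in extra_specs:
        if count == 0:
            continue
        mw_j, inten = _junk_rows(count)
        rows["id"] += [f"PG{next_id + i:05d}" for i in range(count)]
        rows["Protein IDs"] += [f"{tag}_{i:04d}" for i in range(count)]
        rows["Gene names"] += [f"{tag.lower()}{i:04d}" for i in range(count)]
        rows["Mol. weight [kDa]"] += list(mw_j / 1000.0)
        rows["Intensity"] += list(inten.sum(axis=1))
        if flag_col is None:
            rows["Razor + unique peptides"] += list(rng.integers(0, 2, size=count))
        else:
            rows["Razor + unique peptides"] += list(2 + rng.poisson(10, size=count))
        for col in ("Potential contaminant", "Reverse", "Only identified by site"):
            rows[col] += ["+" if col == flag_col else ""] * count
        for j, c in enumerate(design.channels):
            rep_cols[f"Reporter intensity corrected {c.label}"] += list(inten[:, j])
        next_id += count

    table = pd.DataFrame({**rows, **rep_cols})

    truth = SyntheticTruth(
        true_copies=pd.DataFrame(copies, index=group_ids, columns=samples),
        planted_log2fc=pd.DataFrame(planted, index=group_ids, columns=list(populations)),
        histone_ids={group_ids[i] for i in histone_idx},
        outlier_samples=outliers,
        category_membership=membership,
    )
    return table, truth


def write_fixture(
    table: pd.DataFrame,
    truth: SyntheticTruth,
    design: ChannelDesign,
    directory,
) -> dict[str, Path]:
    """Write a fixture directory: protein-group TSV, channel design TSV and
    truth tables.  Round-trips losslessly through :func:`mq_io.read_protein_groups`
    for every field the reader exposes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": directory / "proteinGroups.txt",
        "channel_design": directory / "channel_design.tsv",
        "true_copies": directory / "truth_copies.tsv",
        "planted_log2fc": directory / "truth_planted_log2fc.tsv",
        "truth_meta": directory / "truth_meta.json",
    }
    table.to_csv(paths["protein_groups"], sep="\t", index=False, float_format="%.10g")
    design.to_tsv(paths["channel_design"])
    truth.true_copies.to_csv(paths["true_copies"], sep="\t", float_format="%.10g")
    truth.planted_log2fc.to_csv(paths["planted_log2fc"], sep="\t", float_format="%.10g")
    with open(paths["truth_meta"], "w") as fh:
        json.dump(
            {
                "histone_ids": sorted(truth.histone_ids),
                "outlier_samples": sorted(truth.outlier_samples),
                "category_membership": {k: sorted(v) for k, v in truth.category_membership.items()},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


def read_truth(directory) -> SyntheticTruth:
    """Re-load a truth written by :func:`write_fixture`."""
    directory = Path(directory)
    with open(directory / "truth_meta.json") as fh:
        meta = json.load(fh)
    return SyntheticTruth(
        true_copies=pd.read_csv(directory / "truth_copies.tsv", sep="\t", index_col=0),
        planted_log2fc=pd.read_csv(directory / "truth_planted_log2fc.tsv", sep="\t", index_col=0),
        histone_ids=set(meta["histone_ids"]),
        outlier_samples=set(meta["outlier_samples"]),
        category_membership={k: list(v) for k, v in meta["category_membership"].items()},
    )
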