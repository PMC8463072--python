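"""End-to-end pipeline: table -> filters -> ruler -> QC -> contrasts -> ORA.

Stage order mirrors the analysis workflow: parse the protein-group table,
apply row filters, anchor copy numbers with the histone ruler, drop
replicates failing the protein-content QC, run the moderated-t contrasts
with significance classes and candidate selection, then overrepresentation
and landscape summaries.  Every intermediate table is written to the run
directory together with a metadata JSON carrying the configuration, input
hashes, per-stage row counts and warning counts, so reruns with unchanged
inputs are byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import ChannelDesign
from . import mq_io, ruler, landscape
from .diffstats import (
    ModeratedTTest,
    exclusive_proteins,
    log_transform,
)
from .enrich import GeneSetCollection, exhaustion_enrichment, overrepresentation

__all__ = ["RunConfig", "run_pipeline", "table_to_copy_numbers", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def table_to_copy_numbers(
    filtered_table: pd.DataFrame,
    design: ChannelDesign,
    dna_mass_pg: float = ruler.DEFAULT_DNA_MASS_PG,
) -> tuple[ruler.CopyNumberMatrix, list[str]]:
    """Filtered canonical table -> copy-number matrix (allocation + ruler).

    Returns the matrix and the ids of unallocatable records that were
    dropped.  ``filtered_table`` must already have ``is_histone`` assigned.
    """
    allocated, dropped = ruler.allocate_table(filtered_table, design)
    col_meta = pd.DataFrame(
        {
            "population": [c.population for c in design.channels],
            "replicate": [c.replicate for c in design.channels],
        },
        index=design.samples,
    )
    row_meta = filtered_table.set_index("group_id")[
        ["gene_name", "mol_weight_da", "is_histone"]
    ]
    matrix = ruler.estimate_copy_numbers(allocated, row_meta, col_meta, dna_mass_pg=dna_mass_pg)
    return matrix, dropped


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML/JSON loadable)."""

    protein_groups: str
    channel_design: str
    out_dir: str = "tmtruler_run"
    gene_sets: str | None = None  # GMT for ORA
    exhaustion_sets: str | None = None  # GMT with exhaustion_up/exhaustion_down
    categories: str | None = None  # GMT for mass-fraction categories
    histone_genes: str | None = None  # file overriding the shipped histone list
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    dna_mass_pg: float = ruler.DEFAULT_DNA_MASS_PG
    pseudocount: float = 1.0
    qc_threshold: float = 0.15
    min_peptides: int = 2
    peptide_column: str = "Razor + unique peptides"
    star_p: tuple[float, float] = (1e-3, 1e-4)
    candidate_p: float = 1e-3
    candidate_sd_multiple: float = 1.5
    ora_fdr: float = 0.05
    min_detect_frac: float = 0.5
    top_fraction: float = 0.5
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        for name in ("dna_mass_pg", "qc_threshold", "candidate_p",
                     "candidate_sd_multiple", "ora_fdr", "top_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        for path_attr in ("protein_groups", "channel_design", "gene_sets",
                          "exhaustion_sets", "categories", "histone_genes"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{path_attr}: no such file {p!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        cfg = cls(**data)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Raises :class:`PipelineError` naming the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "tool_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "input_hashes": {
            "protein_groups": _sha256(config.protein_groups),
            "channel_design": _sha256(config.channel_design),
        },
        "stages": {},
        "warnings": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # label the failing stage
                raise PipelineError(name, str(exc)) from exc
        return deco

    # --- read -------------------------------------------------------------
    @stage("read")
    def _read():
        design = ChannelDesign.from_tsv(config.channel_design)
        table = mq_io.read_protein_groups(
            config.protein_groups, design, peptide_column=config.peptide_column
        )
        return design, table

    design, table = _read
    meta["stages"]["read"] = {"rows": len(table), "channels": len(design)}

    # --- filter -----------------------------------------------------------
    @stage("filter")
    def _filter():
        filtered, report = mq_io.filter_protein_groups(table, min_peptides=config.min_peptides)
        histone_genes = None
        if config.histone_genes:
            histone_genes = [
                line.strip()
                for line in Path(config.histone_genes).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]
        filtered = mq_io.identify_histones(filtered, histone_genes)
        return filtered, report

    filtered, filter_report = _filter
    meta["stages"]["filter"] = filter_report
    pd.DataFrame([filter_report]).to_csv(out / "filter_report.tsv", sep="\t", index=False)

    # --- allocate + ruler + content ----------------------------------------
    @stage("ruler")
    def _ruler():
        return table_to_copy_numbers(filtered, design, dna_mass_pg=config.dna_mass_pg)

    matrix, dropped = _ruler
    meta["stages"]["ruler"] = {"rows": matrix.values.shape[0], "samples": matrix.values.shape[1]}
    meta["warnings"]["unallocatable_records"] = len(dropped)

    content = ruler.protein_content(matrix)
    content.to_tsv(out / "protein_content_pre_qc.tsv")

    # --- replicate QC -------------------------------------------------------
    @stage("qc")
    def _qc():
        report = mq_io.qc_replicates(content.per_sample, design, threshold=config.qc_threshold)
        flagged = list(report.index[report["flagged"]])
        return report, flagged

    qc_report, flagged = _qc
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", float_format="%.6g")
    meta["stages"]["qc"] = {"flagged_samples": flagged}
    design_post = design.drop_samples(flagged)
    matrix = matrix.drop_samples(flagged)
    content = ruler.protein_content(matrix)
    content.to_tsv(out / "protein_content.tsv")
    matrix.to_tsv(out / "copy_numbers.tsv")

    # --- differential expression per contrast -------------------------------
    gene_sets = GeneSetCollection.from_gmt(config.gene_sets) if config.gene_sets else None
    exhaustion = (
        GeneSetCollection.from_gmt(config.exhaustion_sets) if config.exhaustion_sets else None
    )
    log2 = log_transform(matrix.values, config.pseudocount)
    id_to_gene = matrix.row_meta["gene_name"].to_dict()
    meta["stages"]["contrasts"] = {}

    for pop_a, pop_b in config.contrasts:
        tag = f"{pop_a}_vs_{pop_b}"

        @stage(f"diffexp:{tag}")
        def _contrast(pop_a=pop_a, pop_b=pop_b, tag=tag):
            cols_a = matrix.samples_for(pop_a)
            cols_b = matrix.samples_for(pop_b)
            excl_a, excl_b = exclusive_proteins(
                matrix.values, cols_a, cols_b, min_detect_frac=config.min_detect_frac
            )
            tested = log2.drop(index=sorted(excl_a | excl_b))
            res = ModeratedTTest(tested, cols_a, cols_b).fit()
            res.table["exclusive"] = "no"
            frame = res.table
            for ids, label in ((excl_a, f"only_{pop_a}"), (excl_b, f"only_{pop_b}")):
                if ids:
                    extra = pd.DataFrame(index=sorted(ids))
                    extra["exclusive"] = label
                    frame = pd.concat([frame, extra])
            frame.to_csv(out / f"diffexp_{tag}.tsv", sep="\t", index_label="group_id",
                         float_format="%.6g")
            return res, excl_a, excl_b

        res, excl_a, excl_b = _contrast
        up, down = res.candidates(config.candidate_p, config.candidate_sd_multiple)
        meta["stages"]["contrasts"][tag] = {
            "tested": len(res.table),
            "exclusive_a": len(excl_a),
            "exclusive_b": len(excl_b),
            "candidates_up": len(up),
            "candidates_down": len(down),
            "prior_d0": res.prior.d0 if res.prior.d0 != float("inf") else "inf",
            "prior_s0_sq": res.prior.s0_sq,
            "fc_median": res.fc_dist.median,
            "fc_sd": res.fc_dist.sd,
        }

        # ORA: background = detected in either contrasted population,
        # hits = candidates union population-exclusive proteins
        if gene_sets is not None or exhaustion is not None:

            @stage(f"enrich:{tag}")
            def _enrich(pop_a=pop_a, pop_b=pop_b, tag=tag, up=up, down=down,
                        excl_a=excl_a, excl_b=excl_b):
                cols_a = matrix.samples_for(pop_a)
                cols_b = matrix.samples_for(pop_b)
                det_a = (matrix.values[cols_a] > 0).mean(axis=1) >= config.min_detect_frac
                det_b = (matrix.values[cols_b] > 0).mean(axis=1) >= config.min_detect_frac
                background_ids = set(matrix.values.index[det_a | det_b])
                to_genes = lambda ids: {id_to_gene[i] for i in ids if id_to_gene.get(i)}
                bg = to_genes(background_ids)
                hits_up = to_genes((up | excl_a) & background_ids)
                hits_down = to_genes((down | excl_b) & background_ids)
                if gene_sets is not None:
                    for direction, hits in (("up", hits_up), ("down", hits_down)):
                        if not hits:
                            continue
                        res_ora = overrepresentation(hits, bg, gene_sets)
                        res_ora.to_csv(out / f"ora_{tag}_{direction}.tsv", sep="\t",
                                       index=False, float_format="%.6g")
                if exhaustion is not None and (hits_up or hits_down):
                    res_exh = exhaustion_enrichment(hits_up, hits_down, exhaustion, bg)
                    res_exh.to_csv(out / f"ora_{tag}_exhaustion.tsv", sep="\t",
                                   index=False, float_format="%.6g")
                return len(bg)

            meta["stages"]["contrasts"][tag]["ora_background"] = _enrich

    # --- landscape summaries ------------------------------------------------
    @stage("landscape")
    def _landscape():
        pca = landscape.pca_samples(matrix)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample",
                          float_format="%.6g")
        pd.Series(pca.variance_fractions,
                  index=pca.scores.columns, name="variance_fraction").to_csv(
            out / "pca_variance.tsv", sep="\t", index_label="component")
        medians = ruler.aggregate_population(matrix)
        corr = landscape.population_correlation(medians)
        corr.to_csv(out / "population_correlation.tsv", sep="\t", float_format="%.6g")
        if config.categories:
            cats = GeneSetCollection.from_gmt(config.categories)
            frac = landscape.category_mass_fractions(matrix, cats,
                                                     top_fraction=config.top_fraction)
            frac.to_csv(out / "category_mass_fractions.tsv", sep="\t", index=False,
                        float_format="%.6g")
        if config.gene_sets and config.contrasts:
            sums, tests = landscape.geneset_sums(
                matrix, GeneSetCollection.from_gmt(config.gene_sets),
                contrast=config.contrasts[0],
            )
            sums.to_csv(out / "geneset_sums.tsv", sep="\t", float_format="%.6g")
            tests.to_csv(out / "geneset_welch.tsv", sep="\t", index=False,
                         float_format="%.6g")
        return pca.variance_fractions.shape[0]

    meta["stages"]["landscape"] = {"pca_components": _landscape}

    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=str)
    return out
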