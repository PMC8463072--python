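"""Shared fixtures: small synthetic datasets processed through the pipeline."""

import numpy as np
import pandas as pd
import pytest

from tmtruler import (
    PlantedEffect,
    SyntheticConfig,
    identify_histones,
    filter_protein_groups,
    read_protein_groups,
    simulate_protein_groups,
    table_to_copy_numbers,
)


def process(table, design, dna_mass_pg):
    """Filter a simulated table and run it through allocation + ruler."""
    filtered, report = filter_protein_groups(table_as_parsed(table, design))
    filtered = identify_histones(filtered)
    matrix, dropped = table_to_copy_numbers(filtered, design, dna_mass_pg=dna_mass_pg)
    return matrix, report, dropped


def table_as_parsed(table, design):
    """Round-trip a simulated table through the TSV reader."""
    import io

    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_protein_groups(buf, design)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_proteins=600,
        n_histones=20,
        n_contaminants=8,
        n_reverse=6,
        n_low_peptide=10,
        reporter_cv=0.10,
        absence_fraction=0.05,
        planted_effects=[
            PlantedEffect("ribosomal_like", 0.10, ("IEL_ab_ab", "IEL_ab_aa", "IEL_gd_aa"), -1.0),
            PlantedEffect("adhesion_like", 0.05, ("IEL_ab_ab", "IEL_ab_aa", "IEL_gd_aa"), 1.5),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    table, truth = simulate_protein_groups(small_config)
    return table, truth, small_config.design()


@pytest.fixture(scope="session")
def small_matrix(small_dataset, small_config):
    table, truth, design = small_dataset
    matrix, report, dropped = process(table, design, small_config.dna_mass_pg)
    return matrix
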