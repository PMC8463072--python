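"""Allocation and proteomic-ruler arithmetic against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtruler import (
    AVOGADRO,
    Channel,
    ChannelDesign,
    aggregate_population,
    allocate_ms1,
    allocate_table,
    estimate_copy_numbers,
    protein_content,
)
from tmtruler.ruler import CopyNumberMatrix


def brute_force_copies(intensities, mol_weights, is_histone, dna_mass_pg):
    """Independent per-protein, per-sample loop over the ruler formula."""
    n_prot, n_samp = intensities.shape
    out = np.zeros((n_prot, n_samp))
    for s in range(n_samp):
        hist_sum = 0.0
        for p in range(n_prot):
            if is_histone[p]:
                hist_sum += intensities[p, s]
        for p in range(n_prot):
            dna_mass_g = dna_mass_pg * 1e-12
            out[p, s] = (intensities[p, s] / mol_weights[p]) * (dna_mass_g * AVOGADRO) / hist_sum
    return out


def make_matrix(values, mw, is_histone, samples=None, populations=None, dna=5.52):
    n, m = values.shape
    samples = samples or [f"S_r{j + 1}" for j in range(m)]
    populations = populations or ["S"] * m
    ids = [f"g{i}" for i in range(n)]
    return CopyNumberMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples),
        row_meta=pd.DataFrame(
            {"gene_name": ids, "mol_weight_da": mw, "is_histone": is_histone}, index=ids
        ),
        col_meta=pd.DataFrame(
            {"population": populations, "replicate": [s.split("_")[-1] for s in samples]},
            index=samples,
        ),
        dna_mass_pg=dna,
    )


class TestAllocation:
    def test_hand_fractions(self):
        np.testing.assert_allclose(
            allocate_ms1(1000.0, np.array([1.0, 1.0, 2.0, 0.0])),
            [250.0, 250.0, 500.0, 0.0],
        )

    def test_single_nonzero_reporter_gets_everything(self):
        np.testing.assert_allclose(allocate_ms1(77.0, np.array([0.0, 3.0, 0.0])), [0, 77.0, 0])

    def test_zero_ms1_all_zero(self):
        assert allocate_ms1(0.0, np.array([1.0, 2.0])).sum() == 0.0

    def test_unallocatable_raises(self):
        with pytest.raises(ValueError, match="unallocatable"):
            allocate_ms1(10.0, np.array([0.0, 0.0]))

    @settings(max_examples=200, deadline=None)
    @given(
        ms1=st.floats(0.0, 1e12),
        reporters=st.lists(st.floats(0.0, 1e9), min_size=1, max_size=16).filter(
            lambda r: sum(r) > 0
        ),
    )
    def test_conservation(self, ms1, reporters):
        """Allocated intensities sum back to MS1 within 1e-12 relative."""
        alloc = allocate_ms1(ms1, np.array(reporters))
        assert alloc.sum() == pytest.approx(ms1, rel=1e-12, abs=1e-300)

    def test_table_allocation_drops_unallocatable(self, caplog):
        design = ChannelDesign([Channel("1", "A", "r1"), Channel("2", "A", "r2")])
        table = pd.DataFrame(
            {
                "group_id": ["a", "b"],
                "ms1_intensity": [100.0, 50.0],
                "A_r1": [1.0, 0.0],
                "A_r2": [3.0, 0.0],
            }
        )
        with caplog.at_level("WARNING"):
            alloc, dropped = allocate_table(table, design)
        assert dropped == ["b"]
        np.testing.assert_allclose(alloc.loc["a"], [25.0, 75.0])
        assert "unallocatable" in caplog.text


class TestRuler:
    def test_worked_example(self):
        """Two histones 3e6 + 1e6; protein 2e6 at 50 kDa -> ~3.324e7 copies."""
        inten = np.array([[3e6], [1e6], [2e6]])
        mw = np.array([12000.0, 14000.0, 50000.0])
        hist = np.array([True, True, False])
        ids = ["h1", "h2", "x"]
        alloc = pd.DataFrame(inten, index=ids, columns=["A_r1"])
        row_meta = pd.DataFrame(
            {"gene_name": ids, "mol_weight_da": mw, "is_histone": hist}, index=ids
        )
        col_meta = pd.DataFrame({"population": ["A"], "replicate": ["r1"]}, index=["A_r1"])
        m = estimate_copy_numbers(alloc, row_meta, col_meta, dna_mass_pg=5.52)
        expected = (2e6 / 5e4) * (5.52e-12 * AVOGADRO) / 4e6
        assert expected == pytest.approx(3.324e7, rel=1e-3)
        assert m.values.loc["x", "A_r1"] == pytest.approx(expected, rel=1e-12)

    def test_ruler_conservation(self):
        """Summed histone mass per cell equals the DNA mass in every sample."""
        rng = np.random.default_rng(0)
        inten = rng.uniform(1e3, 1e7, size=(50, 6))
        mw = rng.uniform(1e4, 2e5, size=50)
        hist = np.zeros(50, dtype=bool)
        hist[:5] = True
        ids = [f"g{i}" for i in range(50)]
        samples = [f"A_r{j}" for j in range(6)]
        alloc = pd.DataFrame(inten, index=ids, columns=samples)
        row_meta = pd.DataFrame({"gene_name": ids, "mol_weight_da": mw, "is_histone": hist}, index=ids)
        col_meta = pd.DataFrame({"population": "A", "replicate": samples}, index=samples)
        m = estimate_copy_numbers(alloc, row_meta, col_meta, dna_mass_pg=5.52)
        hist_mass = m.mass_pg()[hist].sum(axis=0)
        np.testing.assert_allclose(hist_mass, 5.52, rtol=1e-9)

    def test_matches_brute_force_oracle(self):
        """Vectorised ruler equals the per-protein loop on 100 random proteins."""
        rng = np.random.default_rng(123)
        inten = rng.uniform(0.0, 1e8, size=(100, 5))
        mw = rng.uniform(5e3, 5e5, size=100)
        hist = np.zeros(100, dtype=bool)
        hist[rng.choice(100, 8, replace=False)] = True
        ids = [f"g{i}" for i in range(100)]
        samples = [f"A_r{j}" for j in range(5)]
        alloc = pd.DataFrame(inten, index=ids, columns=samples)
        row_meta = pd.DataFrame({"gene_name": ids, "mol_weight_da": mw, "is_histone": hist}, index=ids)
        col_meta = pd.DataFrame({"population": "A", "replicate": samples}, index=samples)
        m = estimate_copy_numbers(alloc, row_meta, col_meta, dna_mass_pg=5.52)
        oracle = brute_force_copies(inten, mw, hist, 5.52)
        np.testing.assert_allclose(m.values.to_numpy(), oracle, rtol=1e-12)

    def test_scale_invariance(self):
        """Multiplying a sample's intensities by c > 0 leaves its copies unchanged."""
        rng = np.random.default_rng(5)
        inten = rng.uniform(1.0, 1e6, size=(30, 3))
        mw = rng.uniform(1e4, 1e5, size=30)
        hist = np.zeros(30, dtype=bool)
        hist[:3] = True
        ids = [f"g{i}" for i in range(30)]
        samples = ["A_r1", "A_r2", "A_r3"]
        row_meta = pd.DataFrame({"gene_name": ids, "mol_weight_da": mw, "is_histone": hist}, index=ids)
        col_meta = pd.DataFrame({"population": "A", "replicate": samples}, index=samples)
        m1 = estimate_copy_numbers(pd.DataFrame(inten, index=ids, columns=samples),
                                   row_meta, col_meta)
        scaled = inten.copy()
        scaled[:, 1] *= 437.5
        m2 = estimate_copy_numbers(pd.DataFrame(scaled, index=ids, columns=samples),
                                   row_meta, col_meta)
        np.testing.assert_allclose(m1.values.to_numpy(), m2.values.to_numpy(), rtol=1e-12)

    def test_zero_histone_sample_raises(self):
        ids = ["h", "x"]
        alloc = pd.DataFrame([[0.0, 1.0], [5.0, 5.0]], index=ids, columns=["A_r1", "A_r2"])
        row_meta = pd.DataFrame(
            {"gene_name": ids, "mol_weight_da": [1e4, 5e4], "is_histone": [True, False]},
            index=ids,
        )
        col_meta = pd.DataFrame({"population": "A", "replicate": ["r1", "r2"]},
                                index=["A_r1", "A_r2"])
        with pytest.raises(ValueError, match="A_r1"):
            estimate_copy_numbers(alloc, row_meta, col_meta)


class TestContent:
    def test_single_protein_unit_conversion(self):
        """1e6 copies of a 50 kDa protein weigh 8.3027e-2 pg."""
        m = make_matrix(np.array([[1e6]]), [5e4], [True])
        content = protein_content(m)
        expected_pg = 1e6 * 5e4 / AVOGADRO * 1e12
        assert expected_pg == pytest.approx(8.3027e-2, rel=1e-4)
        assert content.per_sample.iloc[0] == pytest.approx(expected_pg, rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1e6, size=(20, 4))
        mw = rng.uniform(1e4, 1e5, size=20)
        hist = np.zeros(20, dtype=bool)
        hist[0] = True
        c1 = protein_content(make_matrix(vals, mw, hist)).per_sample
        c2 = protein_content(make_matrix(2 * vals, mw, hist)).per_sample
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)


class TestAggregate:
    def test_median_mean_and_singleton(self):
        vals = np.array([[10.0, 20.0, 90.0, 7.0]])
        m = make_matrix(vals, [5e4], [True],
                        samples=["A_r1", "A_r2", "A_r3", "B_r1"],
                        populations=["A", "A", "A", "B"])
        med = aggregate_population(m, "median")
        assert med.loc["g0", "A"] == 20.0
        assert med.loc["g0", "B"] == 7.0  # singleton population = that column
        assert aggregate_population(m, "mean").loc["g0", "A"] == 40.0
        with pytest.raises(ValueError, match="statistic"):
            aggregate_population(m, "mode")
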