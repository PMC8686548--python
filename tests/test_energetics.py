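"""Unit and property tests of the per-gene ATP/elemental accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egtcost import (
    CellModel,
    ChromosomeRecord,
    CostTable,
    GeneRecord,
    abundance_to_copies,
    delta_D,
    delta_E_EGT,
    dna_atp_cost,
    dna_savings_bp,
    elemental_savings,
    machinery_overhead_per_residue,
    nucleosome_atp_cost,
    per_gene_chromosome_cost,
    protein_import_cost,
    retention_threshold,
)


def make_cell(**kw) -> CellModel:
    base = dict(total_proteins=1e7, organellar_fraction=0.02, c_end=100, import_cost=2.0)
    base.update(kw)
    return CellModel(**base)


class TestDnaAtpCost:
    @pytest.mark.parametrize(
        "length,gc,expected",
        [
            (1, 1.0, 40.14),  # one G:C pair
            (1, 0.0, 40.55),  # one A:T pair
            (0, 0.5, 0.0),
            (1000, 0.5, 40_345.0),  # 500*40.55 + 500*40.14
        ],
    )
    def test_known_values(self, length, gc, expected, cost_table):
        assert dna_atp_cost(length, gc, cost_table) == pytest.approx(expected)

    def test_gc_out_of_range_rejected(self, cost_table):
        with pytest.raises(ValueError):
            dna_atp_cost(100, 1.5, cost_table)

    def test_vectorized_matches_scalar(self, cost_table):
        lengths = np.array([100, 500, 999])
        gcs = np.array([0.2, 0.5, 0.8])
        vec = dna_atp_cost(lengths, gcs, cost_table)
        for i in range(3):
            assert vec[i] == pytest.approx(dna_atp_cost(int(lengths[i]), float(gcs[i])))


class TestNucleosomeCost:
    def test_zero_length_is_free(self, cost_table):
        assert nucleosome_atp_cost(0, cost_table) == 0.0

    def test_ceiling_step_adds_exactly_one_octamer(self, cost_table):
        one = nucleosome_atp_cost(180, cost_table)
        two = nucleosome_atp_cost(181, cost_table)
        assert two - one == pytest.approx(one)

    def test_ten_windows(self, cost_table):
        assert nucleosome_atp_cost(1800, cost_table) == pytest.approx(
            10 * nucleosome_atp_cost(180, cost_table)
        )

    def test_octamer_from_lengths_uses_mean_residue_cost(self, cost_table):
        histone_residues = sum(cost_table.histones[h] for h in ("H2A", "H2B", "H3", "H4"))
        expected = 2 * histone_residues * cost_table.mean_residue_cost
        assert nucleosome_atp_cost(180, cost_table) == pytest.approx(expected)

    def test_sequence_entries_are_summed_exactly(self):
        table = CostTable(histones={"H2A": "AAAA", "H2B": "G", "H3": "W", "H4": "W"})
        expected = 2 * (4 * 11.7 + 11.7 + 74.3 + 74.3)
        assert nucleosome_atp_cost(100, table) == pytest.approx(expected)

    def test_missing_histone_is_configuration_error(self):
        table = CostTable(histones={"H2A": 132})
        with pytest.raises(KeyError):
            nucleosome_atp_cost(180, table)


class TestChromosomeCost:
    def test_organellar_chromosome_arithmetic(self, cost_table):
        chrom = ChromosomeRecord(
            length_bp=150_000, gc=0.4, n_genes=60, copies_per_cell=1500, nucleosomes=False
        )
        expected = 1500 * dna_atp_cost(150_000, 0.4, cost_table) / 60
        assert per_gene_chromosome_cost(chrom, cost_table) == pytest.approx(expected)

    def test_zero_copies_costs_nothing(self, cost_table):
        chrom = ChromosomeRecord(length_bp=1000, gc=0.5, n_genes=2, copies_per_cell=0)
        assert per_gene_chromosome_cost(chrom, cost_table) == 0.0

    def test_nucleosomes_never_cheapen(self, cost_table):
        bare = ChromosomeRecord(length_bp=10_000, gc=0.5, n_genes=5, copies_per_cell=2)
        packed = ChromosomeRecord(
            length_bp=10_000, gc=0.5, n_genes=5, copies_per_cell=2, nucleosomes=True
        )
        assert per_gene_chromosome_cost(packed, cost_table) > per_gene_chromosome_cost(
            bare, cost_table
        )


class TestDnaSavings:
    @pytest.mark.parametrize(
        "c_end,expected",
        [(5000, 5_000_000), (200, 200_000), (100, 100_000), (1500, 1_500_000), (0, 0)],
    )
    def test_headline_per_cell_savings(self, c_end, expected):
        assert dna_savings_bp(1000, c_end) == expected


class TestDeltaD:
    def test_equal_copy_numbers_save_nothing(self, gene, cost_table):
        assert delta_D(gene, make_cell(c_end=2), cost_table) == 0.0

    def test_hand_arithmetic(self, gene, cost_table):
        # 40,345 ATP per copy saved over (1500 - 2) copies
        cell = make_cell(c_end=1500)
        assert delta_D(gene, cell, cost_table) == pytest.approx(60_436_810.0)

    def test_fewer_organellar_than_nuclear_copies_is_negative(self, gene, cost_table):
        assert delta_D(gene, make_cell(c_end=1), cost_table) < 0


class TestAbundanceToCopies:
    def test_arithmetic(self):
        gene = GeneRecord("g", 300, 0.5, 99, abundance_ppm=1000.0)
        cell = make_cell(total_proteins=1e9, organellar_fraction=0.05)
        assert abundance_to_copies(gene, cell) == pytest.approx(50_000.0)

    def test_turnover_is_linear(self, gene):
        base = abundance_to_copies(gene, make_cell(turnover=1))
        assert abundance_to_copies(gene, make_cell(turnover=50)) == pytest.approx(50 * base)

    def test_zero_abundance(self):
        gene = GeneRecord("g", 300, 0.5, 99, abundance_ppm=0.0)
        assert abundance_to_copies(gene, make_cell()) == 0.0


class TestImportCost:
    def test_arithmetic(self):
        # L=300 residues, 2 ATP/residue, N_p=1e5 -> 6e7 ATP
        gene = GeneRecord("g", 903, 0.5, 300, abundance_ppm=1e5 / (0.02 * 1e7) * 1e6)
        cell = make_cell(import_cost=2.0)
        assert protein_import_cost(gene, cell) == pytest.approx(6.0e7)

    def test_low_bound_arithmetic(self):
        gene = GeneRecord("g", 303, 0.5, 100, abundance_ppm=1000 / (0.02 * 1e7) * 1e6)
        cell = make_cell(import_cost=0.05)
        assert protein_import_cost(gene, cell) == pytest.approx(5_000.0)

    def test_zero_copies_import_free(self):
        gene = GeneRecord("g", 300, 0.5, 99, abundance_ppm=0.0)
        assert protein_import_cost(gene, make_cell()) == 0.0


class TestDeltaEEGT:
    def test_transfer_favorable_example(self, cost_table):
        # dD = 60,436,810 and import = 6e7 leaves +436,810 ATP for transfer
        ppm = 1e5 / (0.02 * 1e7) * 1e6
        gene = GeneRecord("g", 1000, 0.5, 300, abundance_ppm=ppm)
        cell = make_cell(c_end=1500, import_cost=2.0)
        r = delta_E_EGT(gene, cell, cost_table)
        assert r.delta_E_EGT == pytest.approx(436_810.0)
        assert r.classification == "transfer"

    def test_zero_import_reduces_to_delta_D(self, gene, cost_table):
        silent = GeneRecord("g", 1000, 0.5, 300, abundance_ppm=0.0)
        cell = make_cell(c_end=1500)
        r = delta_E_EGT(silent, cell, cost_table)
        assert r.delta_E_EGT == delta_D(silent, cell, cost_table)

    def test_identity_holds_exactly(self, gene, cost_table):
        r = delta_E_EGT(gene, make_cell(c_end=1500), cost_table)
        assert r.delta_E_EGT == r.delta_D - r.p_import

    def test_abundance_above_threshold_flips_to_retention(self, cost_table):
        cell = make_cell(c_end=1500, import_cost=2.0)
        probe = GeneRecord("g", 1000, 0.5, 300, abundance_ppm=1.0)
        n_star = retention_threshold(probe, cell, cost_table)
        ppm_over = 2 * n_star / (cell.organellar_fraction * cell.total_proteins) * 1e6
        heavy = GeneRecord("g", 1000, 0.5, 300, abundance_ppm=ppm_over)
        assert delta_E_EGT(heavy, cell, cost_table).classification == "retention"

    @settings(deadline=None, max_examples=60)
    @given(
        length=st.integers(min_value=90, max_value=6000).map(lambda n: 3 * (n // 3)),
        gc=st.floats(0.0, 1.0),
        ppm=st.floats(0.0, 1e5),
        c_end=st.floats(0.0, 10_000.0),
        import_cost=st.floats(0.05, 50.0),
        turnover=st.floats(1.0, 50.0),
    )
    def test_energy_balance_identity_property(self, length, gc, ppm, c_end, import_cost, turnover):
        """dE_EGT == dD - dP exactly, for any admissible gene and cell."""
        gene = GeneRecord("g", max(length, 90), gc, max(length, 90) // 3 - 1, ppm)
        cell = make_cell(c_end=c_end, import_cost=import_cost, turnover=turnover)
        r = delta_E_EGT(gene, cell)
        assert r.delta_E_EGT == r.delta_D - r.p_import

    def test_monotonic_in_cell_parameters(self, gene, cost_table):
        base = delta_E_EGT(gene, make_cell(c_end=100), cost_table).delta_E_EGT
        assert delta_E_EGT(gene, make_cell(c_end=200), cost_table).delta_E_EGT > base
        assert (
            delta_E_EGT(gene, make_cell(c_end=100, import_cost=4.0), cost_table).delta_E_EGT < base
        )
        assert delta_E_EGT(gene, make_cell(c_end=100, turnover=5), cost_table).delta_E_EGT < base
        richer = GeneRecord("g", 1000, 0.5, 300, abundance_ppm=2000.0)
        assert delta_E_EGT(richer, make_cell(c_end=100), cost_table).delta_E_EGT < base


class TestRetentionThreshold:
    def test_arithmetic(self, cost_table):
        gene = GeneRecord("g", 1000, 0.5, 300, abundance_ppm=1.0)
        cell = make_cell(c_end=1500, import_cost=2.0)
        assert retention_threshold(gene, cell, cost_table) == pytest.approx(
            60_436_810.0 / 600.0
        )

    def test_zero_at_equal_copy_numbers(self, gene, cost_table):
        assert retention_threshold(gene, make_cell(c_end=2), cost_table) == 0.0

    def test_doubling_import_cost_halves_threshold(self, gene, cost_table):
        n1 = retention_threshold(gene, make_cell(c_end=1500, import_cost=2.0), cost_table)
        n2 = retention_threshold(gene, make_cell(c_end=1500, import_cost=4.0), cost_table)
        assert n2 == pytest.approx(n1 / 2)

    def test_undefined_without_import_cost(self, gene, cost_table):
        with pytest.raises(ValueError):
            retention_threshold(gene, make_cell(import_cost=0.0), cost_table)

    @settings(deadline=None, max_examples=60)
    @given(
        ppm=st.floats(0.1, 1e5),
        c_end=st.floats(0.0, 10_000.0),
        import_cost=st.floats(0.05, 50.0),
    )
    def test_threshold_agrees_with_classification(self, ppm, c_end, import_cost):
        """N_p > N* if and only if the gene is retention-favorable."""
        gene = GeneRecord("g", 1000, 0.5, 300, abundance_ppm=ppm)
        cell = make_cell(c_end=c_end, import_cost=import_cost)
        n_star = retention_threshold(gene, cell)
        r = delta_E_EGT(gene, cell)
        if r.n_p > n_star:
            assert r.delta_E_EGT < 0
        elif r.n_p < n_star:
            assert r.delta_E_EGT > 0


class TestMachineryOverhead:
    def test_empty_machinery_is_free(self):
        assert machinery_overhead_per_residue([], 1e9) == 0.0

    def test_arithmetic(self):
        assert machinery_overhead_per_residue([(100, 1e4, 25.0)], 1e9) == pytest.approx(0.025)

    def test_linear_in_abundance(self):
        one = machinery_overhead_per_residue([(100, 1e4, 25.0)], 1e9)
        two = machinery_overhead_per_residue([(100, 2e4, 25.0)], 1e9)
        assert two == pytest.approx(2 * one)

    def test_zero_imported_residues_rejected(self):
        with pytest.raises(ValueError):
            machinery_overhead_per_residue([(100, 1e4, 25.0)], 0.0)


class TestElementalSavings:
    def test_single_at_pair(self, cost_table):
        gene = GeneRecord("g", 1, 0.0, 1, 0.0)
        assert elemental_savings(gene, 1, cost_table) == (20.0, 7.0, 2.0)

    def test_single_gc_pair(self, cost_table):
        gene = GeneRecord("g", 1, 1.0, 1, 0.0)
        assert elemental_savings(gene, 1, cost_table) == (19.0, 8.0, 2.0)

    def test_no_copies_no_savings(self, gene, cost_table):
        assert elemental_savings(gene, 0, cost_table) == (0.0, 0.0, 0.0)

    def test_scales_with_length_and_copies(self, cost_table):
        gene = GeneRecord("g", 1000, 0.5, 300, 0.0)
        c, n, p = elemental_savings(gene, 100, cost_table)
        assert c == pytest.approx(100 * (500 * 20 + 500 * 19))
        assert n == pytest.approx(100 * (500 * 7 + 500 * 8))
        assert p == pytest.approx(100 * 1000 * 2)


class TestBruteForceOracle:
    def test_ten_gene_hand_evaluation(self, cost_table):
        """Gene-by-gene scalar re-derivation of the energy balance matches
        the package path to 1 part in 1e12."""
        rng = np.random.default_rng(7)
        cell = make_cell(c_end=350, import_cost=2.0, turnover=5)
        for i in range(10):
            length = int(rng.integers(30, 2000)) * 3
            gc = float(rng.uniform(0, 1))
            ppm = float(rng.uniform(0, 5e4))
            gene = GeneRecord(f"g{i}", length, gc, length // 3 - 1, ppm)
            # independent scalar evaluation, written out step by step
            a_dna = length * (gc * 40.14 + (1 - gc) * 40.55)
            d_end = a_dna * 350
            d_nuc = a_dna * 2
            n_p = ppm / 1e6 * 0.02 * 1e7 * 5
            p_import = (length // 3 - 1) * 2.0 * n_p
            expected = (d_end - d_nuc) - p_import
            got = delta_E_EGT(gene, cell, cost_table).delta_E_EGT
            assert got == pytest.approx(expected, rel=1e-12)
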