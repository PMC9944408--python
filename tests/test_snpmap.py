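"""SNP filtering, window genotyping, marker collapse, recombination, cM map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rilqtl import simdata, snpmap
from rilqtl.pipeline import AnalysisParams, genotype_stage

from conftest import genotype_matrix, toy_snp_table

NA = np.nan


class TestFilterConsistentSnps:
    samples = ["MM_1", "MM_2", "MM_3", "PI_1", "PI_2", "PI_3", "R1", "R2"]

    def _filter(self, rows):
        raw = toy_snp_table(rows, self.samples)
        return snpmap.filter_consistent_snps(
            raw, ["MM_1", "MM_2", "MM_3"], ["PI_1", "PI_2", "PI_3"], ["R1", "R2"]
        )

    def test_consistent_polymorphic_complete_site_is_retained(self):
        out = self._filter([(100, "A", "G", 0, 0, 0, 1, 1, 1, 0, 1)])
        assert out.n_sites == 1
        assert out.sites.iloc[0]["mm_allele"] == "A"
        assert out.sites.iloc[0]["pi_allele"] == "G"
        # RIL calls are re-coded to MM=0 / PI=1
        assert list(out.calls.iloc[0]) == [snpmap.MM, snpmap.PI]

    def test_recoding_honours_which_allele_each_parent_carries(self):
        # MM parent carries the ALT allele here
        out = self._filter([(100, "A", "G", 1, 1, 1, 0, 0, 0, 0, 1)])
        assert out.sites.iloc[0]["mm_allele"] == "G"
        assert list(out.calls.iloc[0]) == [snpmap.PI, snpmap.MM]

    def test_parental_inconsistency_drops_site(self):
        out = self._filter([(100, "A", "G", 0, 1, 0, 1, 1, 1, 0, 1)])
        assert out.n_sites == 0

    def test_monomorphic_site_drops(self):
        out = self._filter([(100, "A", "G", 0, 0, 0, 0, 0, 0, 0, 0)])
        assert out.n_sites == 0

    def test_missing_ril_call_drops_site(self):
        out = self._filter([(100, "A", "G", 0, 0, 0, 1, 1, 1, NA, 1)])
        assert out.n_sites == 0

    def test_zero_retained_warns_not_raises(self):
        with pytest.warns(UserWarning, match="no consistent"):
            out = self._filter([(100, "A", "G", 0, 1, 0, 1, 1, 1, 0, 1)])
        assert out.n_sites == 0


def _coded_table(calls_matrix, positions=None):
    """Parent-coded SnpTable for two RILs from a sites x lines 0/1 matrix."""
    calls_matrix = np.asarray(calls_matrix, float)
    n = len(calls_matrix)
    positions = positions or [(i + 1) * 1000 for i in range(n)]
    sites = pd.DataFrame(
        {
            "chrom": "chr01",
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "mm_allele": "A",
            "pi_allele": "G",
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="site"),
    )
    calls = pd.DataFrame(
        calls_matrix, index=sites.index,
        columns=[f"R{j}" for j in range(calls_matrix.shape[1])],
    )
    return snpmap.SnpTable(sites=sites, calls=calls, parent_coded=True)


class TestCallBinGenotypes:
    def test_pure_mm_window_has_probability_one(self):
        snps = _coded_table(np.zeros((100, 1)))
        gm, mm = snpmap.call_bin_genotypes(snps, bin_size=100)
        assert gm.codes.iloc[0, 0] == snpmap.MM
        assert gm.prob_mm.iloc[0, 0] == 1.0
        # mean position of the 100 member SNPs
        assert mm.table.iloc[0]["pos_bp"] == np.mean([(i + 1) * 1000 for i in range(100)])

    def test_majority_vote_calls_most_likely_genotype(self):
        calls = np.zeros((100, 1))
        calls[:10] = 1  # 90 MM / 10 PI
        gm, _ = snpmap.call_bin_genotypes(_coded_table(calls), bin_size=100)
        assert gm.prob_mm.iloc[0, 0] == pytest.approx(0.9)
        assert gm.codes.iloc[0, 0] == snpmap.MM

    def test_exact_tie_gives_na(self):
        calls = np.zeros((100, 1))
        calls[:50] = 1
        gm, _ = snpmap.call_bin_genotypes(_coded_table(calls), bin_size=100)
        assert np.isnan(gm.codes.iloc[0, 0])

    def test_uninformative_window_gives_na(self):
        calls = np.full((100, 1), NA)
        calls[:5] = 0.0  # 5% informative < 10% minimum
        gm, _ = snpmap.call_bin_genotypes(_coded_table(calls), bin_size=100)
        assert np.isnan(gm.codes.iloc[0, 0])

    def test_short_chromosome_yields_single_window(self):
        snps = _coded_table(np.zeros((30, 2)))
        gm, mm = snpmap.call_bin_genotypes(snps, bin_size=100)
        assert len(mm.table) == 1
        assert mm.table.iloc[0]["n_snps"] == 30

    def test_sliding_step_is_one_snp(self):
        snps = _coded_table(np.zeros((120, 1)))
        _, mm = snpmap.call_bin_genotypes(snps, bin_size=100)
        assert len(mm.table) == 21  # 120 - 100 + 1


class TestCollapseUniqueMarkers:
    def test_adjacent_identical_columns_merge(self):
        gm, mm = genotype_matrix([[0, 0, 1], [1, 1, 0]])
        out_gm, out_mm = snpmap.collapse_unique_markers(gm, mm)
        assert len(out_mm.table) == 2
        # merged marker takes the mean position of its members
        assert out_mm.table.iloc[0]["pos_bp"] == pytest.approx(1.5e5)

    def test_columns_differing_in_one_line_stay_distinct(self):
        gm, mm = genotype_matrix([[0, 0], [1, 0]])
        _, out_mm = snpmap.collapse_unique_markers(gm, mm)
        assert len(out_mm.table) == 2

    def test_collapse_is_idempotent(self, small_population):
        snps, _, _ = small_population
        mm_s = [c for c in snps.samples if c.startswith("MM_")]
        pi_s = [c for c in snps.samples if c.startswith("PI_")]
        rils = [c for c in snps.samples if c not in mm_s + pi_s]
        filt = snpmap.filter_consistent_snps(snps, mm_s, pi_s, rils)
        gm, mm = snpmap.call_bin_genotypes(filt, bin_size=50)
        g1, m1 = snpmap.collapse_unique_markers(gm, mm)
        g2, m2 = snpmap.collapse_unique_markers(g1, m1)
        pd.testing.assert_frame_equal(g1.codes, g2.codes)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_noise_free_blocks_collapse_to_true_breakpoint_count(self):
        """Per-SNP genotyping of a clean mosaic yields one marker per block."""
        cfg = simdata.SimulationConfig(
            n_snps=1200, n_genes=5, n_rils_hp=10, n_rils_ln=10, hotspots=[],
            n_chromosomes=2, rng_seed=21,
        )
        snps, truth_gm, truth = simdata.simulate_population(cfg)
        for chrom in cfg.chromosomes:
            cols = truth_gm.codes.columns[
                truth_gm.codes.columns.str.startswith(chrom)
            ]
            codes = truth_gm.codes[cols].to_numpy()
            expected_blocks = 1 + int((codes[:, 1:] != codes[:, :-1]).any(axis=0).sum())
            gm, mm = genotype_matrix(
                codes, chrom=chrom,
                positions=snps.sites.loc[cols, "pos"].to_numpy(float),
            )
            _, out_mm = snpmap.collapse_unique_markers(gm, mm)
            assert len(out_mm.table) == expected_blocks


class TestRecombinations:
    def test_single_switch_counts_one(self):
        gm, mm = genotype_matrix([[0, 0, 1, 1]])
        counts, bp = snpmap.count_recombinations(gm, mm)
        assert counts.iloc[0, 0] == 1
        assert (bp[["left_bp", "right_bp"]].to_numpy() == [[2e5, 3e5]]).all()

    def test_na_markers_are_skipped(self):
        gm, mm = genotype_matrix([[0, NA, 1]])
        counts, bp = snpmap.count_recombinations(gm, mm)
        assert counts.iloc[0, 0] == 1
        # breakpoint interval spans the NA gap
        assert (bp[["left_bp", "right_bp"]].to_numpy() == [[1e5, 3e5]]).all()

    def test_all_na_line_warns_and_counts_zero(self):
        gm, mm = genotype_matrix([[NA, NA, NA]])
        with pytest.warns(UserWarning):
            counts, _ = snpmap.count_recombinations(gm, mm)
        assert counts.iloc[0, 0] == 0

    def test_dense_markers_recover_true_crossover_total_within_2pct(self):
        cfg = simdata.SimulationConfig(
            n_snps=24000, n_genes=5, hotspots=[], rng_seed=3
        )
        snps, _, truth = simdata.simulate_population(cfg)
        mm_s = [c for c in snps.samples if c.startswith("MM_")]
        pi_s = [c for c in snps.samples if c.startswith("PI_")]
        rils = [c for c in snps.samples if c not in mm_s + pi_s]
        geno = genotype_stage(snps, mm_s, pi_s, rils, AnalysisParams(bin_size=2))
        recovered = geno["recombination_counts"].to_numpy().sum()
        assert abs(recovered - truth.n_crossovers) / truth.n_crossovers < 0.02


class TestCmMap:
    def test_identical_adjacent_columns_give_zero_increment(self):
        gm, mm = genotype_matrix([[0, 0], [1, 1]])
        out = snpmap.build_cm_map(gm, mm)
        assert list(out.table["cm"]) == [0.0, 0.0]

    def test_one_recombinant_of_fifty_gives_two_cm(self):
        codes = np.zeros((50, 2))
        codes[0, 1] = 1  # one line switches between the two markers
        gm, mm = genotype_matrix(codes)
        out = snpmap.build_cm_map(gm, mm)
        assert out.table["cm"].iloc[1] == pytest.approx(2.0)  # 100 * (1/50)

    def test_first_marker_of_each_chromosome_is_zero(self, small_population):
        snps, truth_gm, _ = small_population
        gm, mm = genotype_matrix(
            truth_gm.codes.to_numpy()[:, :20], chrom="chr01",
        )
        out = snpmap.build_cm_map(gm, mm)
        assert out.table["cm"].iloc[0] == 0.0
        assert out.table["cm"].is_monotonic_increasing

    def test_duplicating_a_marker_changes_no_increments(self):
        codes = np.array([[0, 1, 1], [1, 1, 0], [0, 0, 1]], float)
        gm, mm = genotype_matrix(codes)
        total = snpmap.build_cm_map(gm, mm).table["cm"].iloc[-1]
        dup = np.column_stack([codes[:, 0], codes[:, 0], codes[:, 1], codes[:, 2]])
        gm2, mm2 = genotype_matrix(dup)
        total2 = snpmap.build_cm_map(gm2, mm2).table["cm"].iloc[-1]
        assert total2 == pytest.approx(total)

    def test_haldane_exceeds_morgan_distance(self):
        codes = np.zeros((10, 2))
        codes[:3, 1] = 1  # r = 0.3
        gm, mm = genotype_matrix(codes)
        morgan = snpmap.build_cm_map(gm, mm, "morgan").table["cm"].iloc[1]
        haldane = snpmap.build_cm_map(gm, mm, "haldane").table["cm"].iloc[1]
        assert morgan == pytest.approx(30.0)
        assert haldane > morgan


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    codes=st.lists(
        st.lists(st.sampled_from([0.0, 1.0]), min_size=3, max_size=8),
        min_size=2, max_size=6,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_collapse_idempotence_property(codes):
    gm, mm = genotype_matrix(np.asarray(codes))
    g1, m1 = snpmap.collapse_unique_markers(gm, mm)
    g2, m2 = snpmap.collapse_unique_markers(g1, m1)
    assert g1.codes.shape == g2.codes.shape
    assert (g1.codes.to_numpy() == g2.codes.to_numpy()).all()
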