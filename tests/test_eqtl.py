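"""Single-marker mapping, FDR threshold arithmetic, peaks, cis/trans calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rilqtl import eqtl

from conftest import genotype_matrix


def _traits(values, lines):
    return pd.DataFrame(
        np.atleast_2d(np.asarray(values, float)),
        index=[f"g{i}" for i in range(np.atleast_2d(values).shape[0])],
        columns=lines,
    )


class TestMarkerScan:
    def test_worked_anova_example_at_marker(self):
        """Genotypes MM,MM,MM,PI,PI,PI with trait 1..6: F = 13.5 on (1,4)."""
        gm, mm = genotype_matrix(np.array([[0], [0], [0], [1], [1], [1]]))
        traits = _traits([1, 2, 3, 4, 5, 6], gm.lines)
        neg, eff = eqtl.marker_scan(gm, traits)
        expected = -np.log10(stats.f.sf(13.5, 1, 4))
        assert neg.iloc[0, 0] == pytest.approx(expected)
        assert eff.iloc[0, 0] == pytest.approx(-3.0)  # PI allele raises trait

    def test_perfect_cis_marker_attains_profile_maximum(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(40, 5)).astype(float)
        gm, mm = genotype_matrix(x)
        traits = _traits(x[:, 2], gm.lines)  # trait = genotype at marker 2
        neg, _ = eqtl.marker_scan(gm, traits)
        assert neg.iloc[0].idxmax() == "m2"

    def test_monomorphic_marker_scores_zero_with_na_effect(self):
        gm, mm = genotype_matrix(np.array([[0, 0], [0, 1], [0, 1], [0, 0]]))
        traits = _traits([1, 2, 3, 4], gm.lines)
        neg, eff = eqtl.marker_scan(gm, traits)
        assert neg.iloc[0, 0] == 0.0
        assert np.isnan(eff.iloc[0, 0])

    def test_na_genotypes_dropped_marker_wise(self):
        codes = np.array([[0.0], [0.0], [np.nan], [1.0], [1.0], [1.0], [0.0]])
        gm, mm = genotype_matrix(codes)
        traits = _traits([1, 2, 99, 4, 5, 6, 3], gm.lines)
        neg, _ = eqtl.marker_scan(gm, traits)
        # equals the clean fit on the 6 informative lines
        gm2, _ = genotype_matrix(np.array([[0], [0], [1], [1], [1], [0]]))
        neg2, _ = eqtl.marker_scan(gm2, _traits([1, 2, 4, 5, 6, 3], gm2.lines))
        assert neg.iloc[0, 0] == pytest.approx(neg2.iloc[0, 0])

    def test_line_order_relabeling_leaves_maxima_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=(30, 8)).astype(float)
        gm, _ = genotype_matrix(x)
        y = rng.normal(size=(10, 30))
        traits = _traits(y, gm.lines)
        neg, _ = eqtl.marker_scan(gm, traits)
        perm = rng.permutation(30)
        neg2, _ = eqtl.marker_scan(gm, traits.iloc[:, perm])
        np.testing.assert_allclose(
            neg.max(axis=1), neg2.max(axis=1), rtol=1e-9
        )


class TestFdrThreshold:
    def test_bound_right_side_worked_example(self):
        """m=14772, RDS=4281: RHS = (10491/14772) * 0.05 * ln(14772)."""
        m, rds = 14772, 4281
        oracle = (m - rds) / m * 0.05 * np.log(m)
        assert eqtl.fdr_bound_rhs(m, rds, 0.05) == pytest.approx(oracle)
        assert oracle == pytest.approx(0.3410, abs=5e-4)

    def test_all_signal_data_chooses_lowest_cutoff(self):
        real = pd.Series(np.full(50, 8.0))
        perm = np.zeros((10, 50))
        thr = eqtl.fdr_threshold(real, perm, q=0.05)
        assert thr.cutoff == pytest.approx(0.1)
        row = thr.grid.iloc[0]
        assert row["rds"] == 50 and row["fds"] == 0.0

    def test_null_data_returns_sentinel(self):
        rng = np.random.default_rng(0)
        real = pd.Series(rng.uniform(0.5, 2.0, size=100))
        perm = rng.uniform(0.5, 2.5, size=(10, 100))  # permutations look alike
        thr = eqtl.fdr_threshold(real, perm, q=0.001)
        assert thr.cutoff is None
        assert not thr.significant

    def test_rds_and_fds_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(2)
        real = pd.Series(rng.exponential(1.5, size=300))
        perm = rng.exponential(1.0, size=(10, 300))
        thr = eqtl.fdr_threshold(real, perm)
        assert (np.diff(thr.grid["rds"]) <= 0).all()
        assert (np.diff(thr.grid["fds"]) <= 1e-12).all()


class TestPeakAndInterval:
    def _records(self, scores, threshold=2.0, effects=None):
        scores = np.atleast_2d(np.asarray(scores, float))
        gm, mm = genotype_matrix(np.zeros((2, scores.shape[1])))
        neg = pd.DataFrame(scores, index=["g0"], columns=gm.markers)
        eff = pd.DataFrame(
            effects if effects is not None else np.ones_like(scores),
            index=["g0"], columns=gm.markers,
        )
        return eqtl.peak_and_interval(neg, eff, mm, threshold)

    def test_sharp_peak_has_single_marker_interval(self):
        rec = self._records([1, 5, 1])
        assert len(rec) == 1
        assert rec.iloc[0]["peak_bp"] == 2e5
        assert rec.iloc[0]["ci_left_bp"] == 2e5
        assert rec.iloc[0]["ci_right_bp"] == 2e5

    def test_plateau_peak_leftmost_and_drop_rule(self):
        """Scores [4,5,5,5,1]: peak at first 5; CI spans the 4 and all 5s."""
        rec = self._records([4, 5, 5, 5, 1])
        assert rec.iloc[0]["peak_bp"] == 2e5
        assert rec.iloc[0]["ci_left_bp"] == 1e5   # 4 >= 5 - 1.5
        assert rec.iloc[0]["ci_right_bp"] == 4e5
        assert rec.iloc[0]["neg_log10_p"] == 5.0

    def test_below_threshold_profile_yields_no_record(self):
        assert len(self._records([1.0, 1.5, 1.0])) == 0

    def test_two_chromosomes_two_records_per_gene(self):
        gm, mm = genotype_matrix(
            np.zeros((2, 4)),
            chrom=pd.Series(["chr01", "chr01", "chr02", "chr02"]),
        )
        neg = pd.DataFrame([[5.0, 1.0, 1.0, 6.0]], index=["g0"], columns=gm.markers)
        eff = pd.DataFrame(np.ones((1, 4)), index=["g0"], columns=gm.markers)
        rec = eqtl.peak_and_interval(neg, eff, mm, 2.0)
        assert len(rec) == 2
        assert set(rec["chrom"]) == {"chr01", "chr02"}


class TestClassify:
    def _rec(self, chrom="chr01", peak=10.5e6, ci=(10.5e6, 10.5e6)):
        return pd.DataFrame(
            [{"gene": "g0", "chrom": chrom, "peak_bp": peak, "peak_cm": 0.0,
              "neg_log10_p": 5.0, "effect": 1.0, "ci_left_bp": ci[0],
              "ci_right_bp": ci[1], "peak_marker": "m0"}]
        )

    def _ann(self, chrom="chr01", start=10.0e6, end=10.01e6):
        return pd.DataFrame(
            {"chrom": [chrom], "start": [start], "end": [end], "strand": "+",
             "length": [end - start + 1]},
            index=pd.Index(["g0"], name="gene"),
        )

    def test_within_one_mb_is_cis(self):
        out = eqtl.classify_eqtl(self._rec(peak=10.5e6), self._ann())
        assert out["type"].iloc[0] == "cis"

    def test_other_chromosome_is_trans(self):
        out = eqtl.classify_eqtl(self._rec(chrom="chr05"), self._ann())
        assert out["type"].iloc[0] == "trans"

    def test_distant_but_inside_ci_is_cis(self):
        rec = self._rec(peak=10e6, ci=(9e6, 13e6))
        out = eqtl.classify_eqtl(rec, self._ann(start=12e6, end=12.01e6))
        assert out["type"].iloc[0] == "cis"

    def test_distant_outside_ci_is_trans(self):
        rec = self._rec(peak=10e6, ci=(9.9e6, 10.1e6))
        out = eqtl.classify_eqtl(rec, self._ann(start=12e6, end=12.01e6))
        assert out["type"].iloc[0] == "trans"

    def test_unannotated_gene_warns_and_gets_na(self):
        ann = self._ann().rename(index={"g0": "other"})
        with pytest.warns(UserWarning, match="missing"):
            out = eqtl.classify_eqtl(self._rec(), ann)
        assert out["type"].isna().all()
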