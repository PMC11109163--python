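"""Merge semantics, filter rules and the origin classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utr3qtl import variant_pipeline as vp
from utr3qtl.variant_pipeline import FILTERED, NO_COVERAGE, ClassifierConfig


class TestMerge:
    def test_three_sample_toy_by_hand_rules(self, make_calls):
        # S1: tumor het call; S2: genotyper hom-ref; S3: absent from both
        tumor = make_calls([("S1", "chr1", 100, "A", "G", "0/1")])
        geno = make_calls([("S2", "chr1", 100, "A", "G", "0/0",
                            {"caller": "genotyper"}),
                           ("S3", "chr1", 200, "C", "T", "0/0",
                            {"caller": "genotyper"})])
        m = vp.merge_caller_calls(tumor, geno)
        assert m.dosage.at["chr1:100:A:G", "S1"] == 1
        assert m.dosage.at["chr1:100:A:G", "S2"] == 0
        assert m.dosage.at["chr1:100:A:G", "S3"] == NO_COVERAGE
        # carrier denominator excludes the uncovered sample
        assert m.tested_counts()["chr1:100:A:G"] == 2

    def test_hom_calls_and_missing_gt(self, make_calls):
        tumor = make_calls([("S1", "chr1", 5, "A", "T", "1/1"),
                            ("S2", "chr1", 5, "A", "T", "0/1")])
        m = vp.merge_caller_calls(tumor, tumor.iloc[:0])
        assert m.dosage.at["chr1:5:A:T", "S1"] == 2
        assert m.dosage.at["chr1:5:A:T", "S2"] == 1

    def test_conflicting_ref_alleles_error(self, make_calls):
        tumor = make_calls([("S1", "chr1", 9, "A", "G", "0/1"),
                            ("S2", "chr1", 9, "C", "G", "0/1")])
        with pytest.raises(ValueError, match="chr1:9"):
            vp.merge_caller_calls(tumor, tumor.iloc[:0])

    def test_fixed_point_on_expanded_records(self, small_matrix, make_calls):
        """Expanding a matrix back into records and re-merging reproduces it."""
        dosage = small_matrix.dosage.replace(FILTERED, 0)
        tumor_rows, geno_rows = [], []
        for key in dosage.index[:20]:
            chrom, pos, ref, alt = key.split(":")
            for sample in dosage.columns:
                d = dosage.at[key, sample]
                if d > 0:
                    gt = "1/1" if d == 2 else "0/1"
                    tumor_rows.append((sample, chrom, int(pos), ref, alt, gt))
                elif d == 0:
                    geno_rows.append((sample, chrom, int(pos), ref, alt, "0/0",
                                      {"caller": "genotyper"}))
        merged = vp.merge_caller_calls(make_calls(tumor_rows), make_calls(geno_rows))
        sub = dosage.iloc[:20]
        pd.testing.assert_frame_equal(
            merged.dosage.loc[sub.index, sub.columns], sub, check_dtype=False
        )


class TestFilters:
    def test_low_carrier_variant_dropped(self, make_calls):
        rows = [(f"S{i}", "chr1", 10, "A", "G", "0/1") for i in range(4)]
        rows += [(f"S{i}", "chr1", 20, "C", "T", "0/1") for i in range(5)]
        tumor = make_calls(rows)
        m = vp.merge_caller_calls(tumor, tumor.iloc[:0])
        out, log = vp.apply_filters(m, tumor, min_carriers=5)
        assert "chr1:10:A:G" not in out.dosage.index
        assert "chr1:20:C:T" in out.dosage.index
        assert log["low_carrier_variants"] == 1

    def test_tagged_everywhere_drops_variant(self, make_calls):
        rows = [(f"S{i}", "chr1", 30, "G", "A", "0/1", {"flt": "slippage"})
                for i in range(6)]
        tumor = make_calls(rows)
        m = vp.merge_caller_calls(tumor, tumor.iloc[:0])
        out, log = vp.apply_filters(m, tumor, min_carriers=1)
        assert "chr1:30:G:A" not in out.dosage.index
        assert log["cells_filtered"] == 6

    def test_multiallelic_sites_dropped(self, make_calls):
        rows = [(f"S{i}", "chr1", 40, "A", "G", "0/1") for i in range(5)]
        rows += [(f"S{i}", "chr1", 40, "A", "T", "0/1") for i in range(5, 10)]
        tumor = make_calls(rows)
        m = vp.merge_caller_calls(tumor, tumor.iloc[:0])
        out, log = vp.apply_filters(m, tumor, min_carriers=1)
        assert log["multiallelic_variants"] == 2
        assert len(out.dosage) == 0

    def test_unknown_tags_retained_and_logged(self, make_calls):
        rows = [(f"S{i}", "chr1", 50, "T", "C", "0/1", {"flt": "weird_tag"})
                for i in range(5)]
        tumor = make_calls(rows)
        m = vp.merge_caller_calls(tumor, tumor.iloc[:0])
        out, log = vp.apply_filters(m, tumor, min_carriers=5)
        assert "chr1:50:T:C" in out.dosage.index
        assert log["unknown_tags"] == 5

    def test_six_variant_toy_matches_brute_force(self, make_calls):
        """Survivor set equals exhaustive application of all three rules."""
        tags = vp.DEFAULT_FILTER_TAGS
        rng = np.random.default_rng(3)
        rows = []
        for v in range(6):
            n_car = int(rng.integers(2, 8))
            for i in range(n_car):
                flt = "base_qual" if rng.random() < 0.3 else "PASS"
                rows.append((f"S{i}", "chr1", 100 + v, "A", "G", "0/1",
                             {"flt": flt}))
        tumor = make_calls(rows)
        m = vp.merge_caller_calls(tumor, tumor.iloc[:0])
        out, _ = vp.apply_filters(m, tumor, min_carriers=4)
        # brute-force oracle over the record list
        survivors = set()
        for v in range(6):
            sub = tumor[tumor["pos"] == 100 + v]
            carriers = sum(1 for f in sub["filter"] if f not in tags)
            if carriers >= 4:
                survivors.add(f"chr1:{100 + v}:A:G")
        assert set(out.dosage.index) == survivors


class TestClassifier:
    def _single_variant_matrix(self, vaf_value=0.1):
        dosage = pd.DataFrame([[1, 1, 0]], index=["chr1:100:A:G"],
                              columns=["S1", "S2", "S3"], dtype=np.int8)
        return vp.GenotypeMatrix(dosage)

    def test_blood_membership_is_hard_germline(self):
        m = self._single_variant_matrix()
        post = vp.classify_origin(
            m, {"S1": frozenset({"chr1:100:A:G"})},
            vp.PanelOfNormals(pd.Series(dtype=int)),
            pd.Series(dtype=float), set(), pd.Series(dtype=float),
        )
        row = post.loc["chr1:100:A:G"]
        assert row["p_germline"] == 1.0 and row["label"] == "germline"

    def test_low_vaf_unknown_af_is_somatic_by_hand_bayes(self):
        """Posterior matches a hand-computed update with the Beta components."""
        cfg = ClassifierConfig()
        m = self._single_variant_matrix()
        post = vp.classify_origin(
            m, {}, vp.PanelOfNormals(pd.Series(dtype=int)),
            pd.Series(dtype=float), set(),
            pd.Series({"chr1:100:A:G": 0.10}), cfg,
        )
        prior = cfg.af_floor  # AF 0 floors the carrier prior at 1e-4
        odds = prior / (1 - prior)
        lr = stats.beta.pdf(0.10, 20, 20) / stats.beta.pdf(0.10, 2, 6)
        expected_p_germ = odds * lr / (1 + odds * lr)
        row = post.loc["chr1:100:A:G"]
        assert row["p_somatic"] > 0.5
        assert row["p_germline"] == pytest.approx(expected_p_germ, rel=1e-9)
        assert row["p_germline"] + row["p_somatic"] == pytest.approx(1.0, abs=1e-9)

    def test_editing_site_overlap_label(self):
        m = self._single_variant_matrix()
        post = vp.classify_origin(
            m, {}, vp.PanelOfNormals(pd.Series(dtype=int)),
            pd.Series(dtype=float), {("chr1", 100)},
            pd.Series({"chr1:100:A:G": 0.10}),
        )
        assert post.loc["chr1:100:A:G", "label"] == "somatic_editing_overlap"

    def test_pon_membership_shifts_towards_germline(self):
        m = self._single_variant_matrix()
        pon = vp.PanelOfNormals(pd.Series({"chr1:100:A:G": 3}))
        no_pon = vp.classify_origin(
            m, {}, vp.PanelOfNormals(pd.Series(dtype=int)), pd.Series(dtype=float),
            set(), pd.Series({"chr1:100:A:G": 0.3}),
        )
        with_pon = vp.classify_origin(
            m, {}, pon, pd.Series(dtype=float), set(),
            pd.Series({"chr1:100:A:G": 0.3}),
        )
        assert (with_pon.loc["chr1:100:A:G", "p_germline"]
                > no_pon.loc["chr1:100:A:G", "p_germline"])

    def test_accuracy_on_synthetic_truth(self, small_cohort, small_matrix):
        pon = vp.build_pon(small_cohort.normal_calls)
        vaf = vp.mean_carrier_vaf(small_cohort.tumor_calls)
        editing = set(zip(small_cohort.editing_sites["chrom"],
                          small_cohort.editing_sites["pos"]))
        post = vp.classify_origin(
            small_matrix, small_cohort.blood_sets, pon,
            small_cohort.pop_af, editing, vaf,
        )
        mapping = {"germline": "germline", "likely_somatic": "somatic",
                   "somatic_editing_overlap": "somatic_editing"}
        pred = post["label"].map(mapping)
        truth = small_cohort.truth.origins.loc[pred.index]
        acc = (pred == truth).mean()
        assert acc >= 0.9
        # empirical oracle: best blood-union + VAF-threshold rule on the truth
        blood_union = frozenset().union(*small_cohort.blood_sets.values())
        is_germ = truth.str.startswith("germline")
        best = 0.0
        for thr in np.linspace(0, 1, 101):
            call_germ = pred.index.isin(blood_union) | (
                vaf.reindex(pred.index).to_numpy() > thr
            )
            best = max(best, float((call_germ == is_germ.to_numpy()).mean()))
        assert acc >= best - 0.02


class TestSummary:
    def test_reported_cohort_percentages(self):
        s = vp.VariantSummary.from_counts(5431118, 3283340, 2147778, 1429039)
        assert s.germline_pct == 60.5
        assert s.somatic_pct == 39.5
        assert s.editing_pct_of_somatic == 66.5

    def test_percentages_sum_to_hundred(self, small_cohort, small_matrix):
        pon = vp.build_pon(small_cohort.normal_calls)
        vaf = vp.mean_carrier_vaf(small_cohort.tumor_calls)
        post = vp.classify_origin(
            small_matrix, small_cohort.blood_sets, pon, small_cohort.pop_af,
            set(), vaf,
        )
        s = vp.summarize_landscape(post)
        assert s.germline_pct + s.somatic_pct == pytest.approx(100.0, abs=0.1)

    def test_empty_input_zeroed(self):
        s = vp.summarize_landscape(pd.DataFrame())
        assert (s.total, s.germline_pct, s.editing_pct_of_somatic) == (0, 0.0, 0.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            vp.VariantSummary.from_counts(10, 5, 4, 0)


class TestConcordance:
    def test_identity_and_disjoint(self):
        a = {f"k{i}" for i in range(5)}
        assert vp.concordance(a, a) == (5, 1.0, 1.0)
        assert vp.concordance(a, {"x"}) == (0, 0.0, 0.0)

    def test_partial_overlap_enumeration(self):
        a = {f"k{i}" for i in range(10)}
        b = {f"k{i}" for i in range(5)} | {"x1", "x2"}
        n, fa, fb = vp.concordance(a, b)
        assert (n, fa) == (5, 0.5)
        assert fb == pytest.approx(5 / 7)


def test_carrier_frequency_threshold():
    assert vp.carrier_frequency_threshold(5, 375) == pytest.approx(5 / 375)
    assert vp.carrier_frequency_threshold(5, 375) > 0.013
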