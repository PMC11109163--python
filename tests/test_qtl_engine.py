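"""Normalization, covariates and the cis-QTL association engine."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utr3qtl import qtl_engine as qe
from utr3qtl.variant_pipeline import GenotypeMatrix


def tmm_factor_oracle(counts, ref_col, col, logratio_trim=0.30, sum_trim=0.05):
    """Independently coded trimmed-mean-of-M factor for one column."""
    y = counts[:, col].astype(float)
    r = counts[:, ref_col].astype(float)
    ny, nr = y.sum(), r.sum()
    ok = (y > 0) & (r > 0)
    m = np.log2((y[ok] / ny) / (r[ok] / nr))
    a = 0.5 * np.log2((y[ok] / ny) * (r[ok] / nr))
    w = 1.0 / ((ny - y[ok]) / (ny * y[ok]) + (nr - r[ok]) / (nr * r[ok]))
    n = m.size
    lo_l, hi_l = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_s, hi_s = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rm, ra = stats.rankdata(m), stats.rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    return 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80])
        counts = pd.DataFrame({"a": col, "b": col})
        factors, _ = qe.tmm_normalize(counts)
        np.testing.assert_allclose(factors, [1.0, 1.0], atol=1e-12)

    def test_global_scaling_invariance(self):
        col = np.array([10, 50, 200, 5, 80])
        counts = pd.DataFrame({"a": col, "b": 3 * col})
        factors, _ = qe.tmm_normalize(counts)
        np.testing.assert_allclose(factors.iloc[0], factors.iloc[1], atol=1e-9)

    def test_matches_direct_formula_oracle(self, rng):
        counts = rng.integers(1, 500, size=(40, 2))
        df = pd.DataFrame(counts, columns=["a", "b"])
        factors, _ = qe.tmm_normalize(df)
        lib = counts.sum(axis=0)
        q75 = [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(2)]
        ref = int(np.argmin(np.abs(np.array(q75) - np.mean(q75))))
        other = 1 - ref
        raw = tmm_factor_oracle(counts, ref, other)
        expected = np.ones(2)
        expected[other] = raw
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(factors.to_numpy(), expected, atol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_edger_calcnormfactors(self, rng):
        counts = rng.integers(0, 400, size=(60, 4))
        df = pd.DataFrame(counts, columns=list("abcd"))
        factors, _ = qe.tmm_normalize(df)
        flat = ",".join(str(int(v)) for v in counts.T.ravel())
        script = (
            "suppressMessages(library(edgeR));"
            f"m <- matrix(c({flat}), ncol=4);"
            "cat(calcNormFactors(m, method='TMM'), sep=',')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(factors.to_numpy(), ref, atol=1e-6)

    def test_zero_library_named_in_error(self):
        counts = pd.DataFrame({"a": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            qe.tmm_normalize(counts)

    def test_cpm_scaling(self):
        col = np.array([250000, 750000])
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        _, cpm = qe.tmm_normalize(counts)
        # unit factors here, so normalized columns are plain counts-per-million
        assert cpm.to_numpy().sum(axis=0) == pytest.approx([1e6, 1e6], rel=1e-6)
        np.testing.assert_allclose(cpm["a"], [250000.0, 750000.0], rtol=1e-9)


class TestFilterGenes:
    def test_threshold_fraction(self):
        counts = pd.DataFrame(np.ones((2, 100)))
        counts.iloc[0, :21] = 0  # expressed in 79% of samples
        out = qe.filter_genes(counts)
        assert list(out.index) == [1]

    def test_all_ones_unchanged(self):
        counts = pd.DataFrame(np.ones((5, 10)))
        pd.testing.assert_frame_equal(qe.filter_genes(counts), counts)

    def test_ten_gene_pattern_matches_enumeration(self, rng):
        counts = pd.DataFrame(rng.integers(0, 3, size=(10, 20)))
        out = qe.filter_genes(counts, min_count=1, min_frac=0.8)
        expected = [g for g in range(10)
                    if (counts.iloc[g] >= 1).sum() >= np.ceil(0.8 * 20)]
        assert list(out.index) == expected


class TestGeneticPCs:
    def test_identical_samples_identical_coordinates(self, rng):
        base = rng.integers(0, 3, size=(30, 4))
        dosage = pd.DataFrame(base, columns=list("wxyz"))
        dosage["w2"] = dosage["w"]
        pcs = qe.compute_genetic_pcs(dosage, k=2)
        np.testing.assert_allclose(pcs.loc["w"], pcs.loc["w2"], atol=1e-8)

    def test_planted_clusters_separate_on_pc1(self, rng):
        n_var, half = 50, 10
        freq_a, freq_b = 0.1, 0.9
        ga = rng.binomial(2, freq_a, size=(n_var, half))
        gb = rng.binomial(2, freq_b, size=(n_var, half))
        dosage = pd.DataFrame(np.hstack([ga, gb]),
                              columns=[f"s{i}" for i in range(2 * half)])
        pcs = qe.compute_genetic_pcs(dosage, k=2)
        pc1 = pcs["gPC1"].to_numpy()
        assert np.sign(pc1[:half]).mean() == -np.sign(pc1[half:]).mean()
        assert abs(pc1[:half].mean() - pc1[half:].mean()) > 2 * pc1.std() / 2

    def test_axes_orthogonal(self, rng):
        dosage = pd.DataFrame(rng.integers(0, 3, size=(80, 25)))
        pcs = qe.compute_genetic_pcs(dosage, k=5).to_numpy()
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_k_exceeding_rank_errors(self, rng):
        dosage = pd.DataFrame(rng.integers(0, 3, size=(50, 3)))
        with pytest.raises(ValueError):
            qe.compute_genetic_pcs(dosage, k=5)


class TestSurrogateVariables:
    def test_nothing_left_after_known_covariates(self, rng):
        n = 100
        cov = pd.DataFrame({"c": rng.normal(size=n)})
        expr = pd.DataFrame(
            np.outer(rng.normal(size=30), cov["c"]) + 0.01 * rng.normal(size=(30, n))
        )
        svs = qe.estimate_surrogate_variables(expr, cov, k=2)
        total_var = expr.to_numpy().var(axis=1).sum()
        sv_var = (svs.to_numpy() ** 2).sum() / expr.shape[0]
        assert sv_var / total_var < 0.05

    def test_planted_batch_factor_recovered(self, rng):
        n = 200
        batch = rng.normal(size=n)
        cov = pd.DataFrame({"age": rng.normal(size=n)})
        load = rng.normal(size=60)
        expr = pd.DataFrame(np.outer(load, batch) + 0.5 * rng.normal(size=(60, n)))
        svs = qe.estimate_surrogate_variables(expr, cov, k=3)
        r = np.corrcoef(svs["SV1"], batch)[0, 1]
        assert abs(r) > 0.9

    def test_orthogonal_to_covariates(self, rng):
        n = 80
        cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        expr = pd.DataFrame(rng.normal(size=(40, n)))
        svs = qe.estimate_surrogate_variables(expr, cov, k=4)
        cross = np.abs(svs.to_numpy().T @ cov.to_numpy())
        assert cross.max() < 1e-8 * np.abs(svs.to_numpy()).max() * n

    def test_k_zero_returns_empty(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 20)))
        svs = qe.estimate_surrogate_variables(expr, pd.DataFrame(index=range(20)), k=0)
        assert svs.shape == (20, 0)


class TestFitQTL:
    def test_noiseless_fit_recovers_beta(self, rng):
        x = rng.integers(0, 3, size=60).astype(float)
        fit = qe.fit_qtl(x, 0.5 * x)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.p < 1e-12

    def test_scaling_equivariance(self, rng):
        x = rng.integers(0, 3, size=100).astype(float)
        y = 0.3 * x + rng.normal(size=100)
        f1 = qe.fit_qtl(x, y)
        f2 = qe.fit_qtl(x, 7.0 * y)
        assert f2.beta == pytest.approx(7.0 * f1.beta, rel=1e-10)
        assert f2.se == pytest.approx(7.0 * f1.se, rel=1e-10)
        assert f2.p == pytest.approx(f1.p, rel=1e-9)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 80
        x = rng.integers(0, 3, size=n).astype(float)
        cov = pd.DataFrame({"age": rng.normal(size=n), "sex": rng.integers(0, 2, n)})
        y = 0.4 * x + 0.2 * cov["age"].to_numpy() + rng.normal(size=n)
        fit = qe.fit_qtl(x, y, cov)
        design = sm.add_constant(np.column_stack([x, cov.to_numpy()]))
        ref = sm.OLS(y, design).fit()
        assert fit.beta == pytest.approx(ref.params[1], rel=1e-9)
        assert fit.se == pytest.approx(ref.bse[1], rel=1e-9)
        assert fit.p == pytest.approx(ref.pvalues[1], rel=1e-9)

    def test_zero_variance_dosage_untestable(self):
        fit = qe.fit_qtl(np.ones(30), np.random.default_rng(0).normal(size=30))
        assert fit.untestable

    def test_missing_codes_excluded_pairwise(self, rng):
        x = rng.integers(0, 3, size=50).astype(float)
        y = 0.5 * x + rng.normal(size=50)
        x_missing = x.copy()
        x_missing[:5] = -1  # NO_COVERAGE code
        fit = qe.fit_qtl(x_missing, y)
        ref = qe.fit_qtl(x[5:], y[5:])
        assert fit.n == 45
        assert fit.beta == pytest.approx(ref.beta, rel=1e-12)


class TestEGeneProcedure:
    def test_single_nonsignificant_variant(self):
        res = pd.DataFrame({"phenotype_id": ["g1"], "key": ["k1"], "p": [1.0]})
        egenes, _, _ = qe.call_egenes(res)
        assert not egenes["egene"].iloc[0]

    def test_hand_bh_and_gene_threshold(self):
        res = pd.DataFrame({
            "phenotype_id": "g1",
            "key": [f"k{i}" for i in range(4)],
            "p": [1e-9, 1e-8, 0.4, 0.9],
        })
        egenes, out, _ = qe.call_egenes(res)
        np.testing.assert_allclose(
            out.sort_values("p")["q"], [4e-9, 2e-8, 0.4 * 4 / 3, 0.9], rtol=1e-9
        )
        assert egenes["egene"].iloc[0]
        assert egenes["gene_threshold"].iloc[0] == pytest.approx(1e-8)

    def test_horizontal_threshold_log_median_of_two(self):
        res = pd.DataFrame({
            "phenotype_id": ["g1", "g2"],
            "key": ["k1", "k2"],
            "p": [1e-6, 1e-8],
        })
        _, _, horizontal = qe.call_egenes(res)
        assert horizontal == pytest.approx(1e-7, rel=1e-9)

    def test_significance_needs_both_gates(self):
        res = pd.DataFrame({
            "phenotype_id": ["g1", "g1", "g2", "g2"],
            "key": list("abcd"),
            "p": [1e-12, 1e-3, 1e-4, 0.5],
        })
        _, out, horizontal = qe.call_egenes(res)
        sig = out[out["significant"]]
        assert set(sig["key"]) <= set("abc")
        assert all(sig["p"] < horizontal)


class TestIlQTL:
    def _matrix(self, rng, n_var=200, n=375):
        dosage = rng.binomial(2, 0.2, size=(n_var, n)).astype(np.int8)
        keys = [f"chr1:{i + 1}:A:G" for i in range(n_var)]
        return GenotypeMatrix(pd.DataFrame(
            dosage, index=keys, columns=[f"S{j}" for j in range(n)]
        ))

    def test_planted_effect_is_top_association(self, rng):
        hits = 0
        for sim in range(100):
            gm = self._matrix(rng, n_var=200)
            x = gm.dosage.iloc[0].to_numpy(dtype=float)
            immune = pd.DataFrame(
                {"CD8_T_fraction": 0.6 * x + rng.normal(size=x.size)},
                index=gm.samples,
            )
            res, _ = qe.run_ilqtl(gm, immune, None)
            if res.loc[res["p"].idxmin(), "key"] == gm.dosage.index[0]:
                hits += 1
        assert hits >= 95

    def test_permuted_features_mostly_null(self, rng):
        # one feature, BH family of 1000 variant tests per run
        clean = 0
        for sim in range(20):
            gm = self._matrix(rng, n_var=1000, n=200)
            immune = pd.DataFrame({"f": rng.normal(size=200)}, index=gm.samples)
            res, _ = qe.run_ilqtl(gm, immune, None)
            if res["significant"].sum() == 0:
                clean += 1
        assert clean >= 18

    def test_duplicated_feature_gives_identical_rows(self, rng):
        gm = self._matrix(rng, n_var=50, n=100)
        f = rng.normal(size=100)
        immune = pd.DataFrame({"a": f, "b": f}, index=gm.samples)
        res, _ = qe.run_ilqtl(gm, immune, None)
        a = res[res["phenotype_id"] == "a"].set_index("key")
        b = res[res["phenotype_id"] == "b"].set_index("key")
        np.testing.assert_allclose(a["p"], b.loc[a.index, "p"], rtol=1e-12)

    def test_constant_feature_skipped(self, rng):
        gm = self._matrix(rng, n_var=10, n=50)
        immune = pd.DataFrame(
            {"flat": np.ones(50), "ok": rng.normal(size=50)}, index=gm.samples
        )
        res, skipped = qe.run_ilqtl(gm, immune, None)
        assert skipped == ["flat"]
        assert set(res["phenotype_id"]) == {"ok"}


def test_planted_beta_recovery_slope():
    """Downstream estimates regress on planted betas with slope near 1."""
    from utr3qtl import synthdata, variant_pipeline as vp

    betas = [0.5 if i % 2 == 0 else -0.5 for i in range(50)]
    planted = [(f"v{i:05d}", f"g{i:04d}", b) for i, b in enumerate(betas)]
    cfg = synthdata.SimulationConfig(
        n_tumors=375, n_normals=20, n_genes=120, n_variants=400,
        planted_eqtl_effects=planted, seed=21,
    )
    cohort = synthdata.generate_cohort(cfg)
    matrix = vp.merge_caller_calls(cohort.tumor_calls, cohort.genotyper_calls)
    filtered, _ = vp.apply_filters(matrix, cohort.tumor_calls)
    counts = qe.filter_genes(cohort.counts)
    _, cpm = qe.tmm_normalize(counts)
    expr = pd.DataFrame(
        {g: qe.inverse_normal_transform(cpm.loc[g].to_numpy()) for g in cpm.index},
        index=cpm.columns,
    )
    _, res, _ = qe.run_eqtl(filtered, expr, cohort.covariates, cohort.transcripts)
    key_of = cohort.truth.variants.set_index("variant_id")["key"]
    pairs = []
    for (vid, gid), beta in cohort.truth.eqtl_betas.items():
        hit = res[(res["key"] == key_of[vid]) & (res["phenotype_id"] == gid)]
        if len(hit):
            pairs.append((beta, hit["beta"].iloc[0]))
    a = np.array(pairs)
    assert len(a) >= 40
    slope = np.polyfit(a[:, 0], a[:, 1], 1)[0]
    assert 0.9 <= slope <= 1.1
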