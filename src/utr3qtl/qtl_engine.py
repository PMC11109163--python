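"""Expression normalization, covariate construction and cis-QTL mapping.

The association model per (variant, phenotype) pair is ordinary least
squares:

    phenotype ~ alt_dosage + age + sex + gPC1..gPC5 + SV1..SV5

with the phenotype inverse-normal-transformed beforehand. Significance for
cis-eQTLs uses a two-stage procedure: Benjamini-Hochberg within each gene's
cis variants defines eGenes (any q < 0.05) and a per-gene nominal threshold
(the largest nominal p among q < 0.05 variants); the cohort-wide horizontal
threshold is the median of per-eGene thresholds taken on the log10 scale,
and a call is significant when q < 0.05 and nominal p is below it.
Immune-landscape QTLs reuse the same engine with immune features as
phenotypes and a per-feature BH family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, inverse_normal_transform
from .variant_pipeline import GenotypeMatrix

__all__ = [
    "tmm_normalize",
    "filter_genes",
    "inverse_normal_transform",
    "compute_genetic_pcs",
    "estimate_surrogate_variables",
    "QTLFit",
    "fit_qtl",
    "fit_qtl_block",
    "map_cis_pairs",
    "run_eqtl",
    "call_egenes",
    "run_ilqtl",
]


# ---------------------------------------------------------------------------
# normalization


def tmm_normalize(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values scaling factors plus a CPM matrix.

    The reference sample is the column whose 75th-percentile count/library
    ratio is closest to the mean across samples. Per sample, M (log2 ratio)
    and A (average log2 abundance) values against the reference are doubly
    trimmed (30% on M, 5% on A by default) and averaged with inverse
    asymptotic-variance weights. Factors are rescaled to geometric mean 1 and
    the normalized value is count / (library size x factor) x 1e6.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = np.nonzero(lib == 0)[0]
    if zero.size:
        raise ValueError(f"sample {counts.columns[zero[0]]} has zero library size")
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")

    q75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(mat.shape[1])
    yr, nr = mat[:, ref], lib[ref]
    for j in range(mat.shape[1]):
        yk, nk = mat[:, j], lib[j]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            continue
        pk, pr = yk[ok] / nk, yr[ok] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        if np.max(np.abs(m)) < 1e-6:
            continue
        w = 1.0 / ((nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        n = m.size
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if keep.any():
            f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
            if np.isfinite(f) and abs(f) > 1e-10:
                factors[j] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    cpm = mat / (lib * factors)[None, :] * 1e6
    return (
        pd.Series(factors, index=counts.columns, name="tmm_factor"),
        pd.DataFrame(cpm, index=counts.index, columns=counts.columns),
    )


def filter_genes(
    counts: pd.DataFrame, min_count: int = 1, min_frac: float = 0.8
) -> pd.DataFrame:
    """Keep genes with count >= min_count in at least ceil(min_frac * n) samples."""
    need = int(np.ceil(min_frac * counts.shape[1]))
    keep = (counts >= min_count).sum(axis=1) >= need
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# covariates


def _signed(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| coordinate positive."""
    out = scores.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def compute_genetic_pcs(dosage: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Principal components of the standardized germline dosage matrix.

    ``dosage`` is variants x samples in {0,1,2}; negative codes and NaN are
    mean-imputed per variant. Columns are centred at 2p and divided by
    sqrt(p(1-p)) with p the allele frequency (Patterson scaling);
    zero-variance variants are excluded.
    """
    x = dosage.to_numpy(dtype=float).T  # samples x variants
    x[x < 0] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    ok = (p > 0) & (p < 1) & (np.nanstd(x, axis=0) > 0)
    xs = (x[:, ok] - 2 * p[ok]) / np.sqrt(p[ok] * (1 - p[ok]))
    xs = xs - xs.mean(axis=0)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"requested {k} PCs but matrix rank is {rank}")
    scores = _signed(u[:, :k] * s[:k])
    return pd.DataFrame(
        scores, index=dosage.columns, columns=[f"gPC{i + 1}" for i in range(k)]
    )


def estimate_surrogate_variables(
    expression: pd.DataFrame, covariates: pd.DataFrame, k: int = 5
) -> pd.DataFrame:
    """Residual-PCA surrogate variables for hidden expression structure.

    Expression (genes x samples) is regressed on the known covariates (plus
    intercept) per gene; the top-k principal components of the residual
    matrix across samples are returned. They are orthogonal to the known
    covariates by construction.
    """
    samples = expression.columns
    if k == 0:
        return pd.DataFrame(index=samples)
    c = np.column_stack([np.ones(len(samples)), covariates.loc[samples].to_numpy(float)])
    rank_c = np.linalg.matrix_rank(c)
    if k >= len(samples) - rank_c:
        raise ValueError("k must be below the residual degrees of freedom")
    q, _ = np.linalg.qr(c)
    y = expression.to_numpy(dtype=float).T  # samples x genes
    resid = y - q @ (q.T @ y)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    scores = _signed(u[:, :k] * s[:k])
    return pd.DataFrame(scores, index=samples, columns=[f"SV{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# association engine


@dataclass
class QTLFit:
    beta: float
    se: float
    t: float
    p: float
    n: int
    untestable: bool = False


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])


def fit_qtl(
    dosage, phenotype, covariates: pd.DataFrame | None = None
) -> QTLFit:
    """OLS dosage coefficient with a two-sided t test, pairwise-complete."""
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    x = np.where(x < 0, np.nan, x)
    keep = np.isfinite(x) & np.isfinite(y)
    cov = covariates.loc[keep] if covariates is not None else None
    x, y = x[keep], y[keep]
    c = _design(cov, x.size)
    if x.size - c.shape[1] - 1 < 1 or np.ptp(x) == 0:
        return QTLFit(np.nan, np.nan, np.nan, np.nan, int(x.size), untestable=True)
    beta, se, t, p = fit_qtl_block(x[:, None], y, c)
    return QTLFit(float(beta[0]), float(se[0]), float(t[0]), float(p[0]), int(x.size))


def fit_qtl_block(x: np.ndarray, y: np.ndarray, design: np.ndarray):
    """Vectorized OLS of y on each column of x, adjusting for ``design``.

    ``design`` must include the intercept. Returns (beta, se, t, p) arrays;
    zero-variance columns yield NaN.
    """
    q, _ = np.linalg.qr(design)
    yr = y - q @ (q.T @ y)
    xr = x - q @ (q.T @ x)
    bxx = np.einsum("ij,ij->j", xr, xr)
    bxy = xr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(bxx > 0, bxy / np.where(bxx > 0, bxx, 1.0), np.nan)
        df = y.size - design.shape[1] - 1
        rss = (yr @ yr) - beta**2 * bxx
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / np.where(bxx > 0, bxx, np.nan))
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


def map_cis_pairs(variant_keys, transcripts: pd.DataFrame) -> pd.DataFrame:
    """(variant key, gene) pairs for variants inside a gene's transcript span."""
    parts = pd.Series(list(variant_keys)).str.split(":", expand=True)
    var = pd.DataFrame(
        {"key": list(variant_keys), "chrom": parts[0], "pos": parts[1].astype(int)}
    )
    rows = []
    for _, t in transcripts.iterrows():
        hit = var[
            (var["chrom"] == t["chrom"])
            & (var["pos"] - 1 >= t["tx_start"])
            & (var["pos"] - 1 < t["tx_end"])
        ]
        for key in hit["key"]:
            rows.append({"key": key, "gene_id": t["gene_id"]})
    return pd.DataFrame(rows, columns=["key", "gene_id"]).drop_duplicates()


def _scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,  # samples x phenotype columns (already transformed)
    covariates: pd.DataFrame | None,
    pairs: pd.DataFrame,  # key, phenotype_id
) -> pd.DataFrame:
    samples = genotypes.samples
    dosage = genotypes.dosage.to_numpy(dtype=float)
    dosage = np.where(dosage < 0, np.nan, dosage)
    key_pos = {k: i for i, k in enumerate(genotypes.variant_keys)}
    design = _design(covariates.loc[samples] if covariates is not None else None,
                     len(samples))
    out = []
    for pheno_id, grp in pairs.groupby("phenotype_id", sort=True):
        if pheno_id not in phenotypes.columns:
            continue
        y = phenotypes[pheno_id].loc[samples].to_numpy(dtype=float)
        idx = [key_pos[k] for k in grp["key"] if k in key_pos]
        keys = [k for k in grp["key"] if k in key_pos]
        if not idx:
            continue
        x = dosage[idx].T  # samples x variants
        complete = ~np.isnan(x).any(axis=0) & ~np.isnan(y).any()
        if complete.all() and np.isfinite(y).all():
            beta, se, t, p = fit_qtl_block(x, y, design)
            n = np.full(len(keys), len(samples))
        else:
            beta = np.empty(len(keys)); se = np.empty(len(keys))
            t = np.empty(len(keys)); p = np.empty(len(keys))
            n = np.empty(len(keys), dtype=int)
            cov = covariates.loc[samples] if covariates is not None else None
            for j in range(len(keys)):
                fit = fit_qtl(x[:, j], y, cov)
                beta[j], se[j], t[j], p[j], n[j] = fit.beta, fit.se, fit.t, fit.p, fit.n
        out.append(
            pd.DataFrame(
                {"phenotype_id": pheno_id, "key": keys, "beta": beta, "se": se,
                 "t": t, "p": p, "n": n}
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["phenotype_id", "key", "beta", "se", "t", "p", "n"]
        )
    return pd.concat(out, ignore_index=True)


def call_egenes(
    results: pd.DataFrame, q_threshold: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Two-stage eGene procedure over per-gene cis results.

    Adds a per-gene BH ``q`` column, flags eGenes (any q < threshold),
    records each eGene's nominal threshold (largest p with q < threshold) and
    the horizontal threshold (log10-scale median of per-eGene thresholds;
    for an even count, the geometric mean of the central pair). The final
    ``significant`` flag requires q < threshold and p < horizontal threshold.
    """
    res = results.copy()
    res["q"] = np.nan
    for g, grp in res.groupby("phenotype_id"):
        ok = np.isfinite(grp["p"].to_numpy())
        q = np.full(len(grp), np.nan)
        if ok.any():
            q[ok] = bh_adjust(grp["p"].to_numpy()[ok])
        res.loc[grp.index, "q"] = q
    egene_rows = []
    for g, grp in res.groupby("phenotype_id"):
        sig = grp[grp["q"] < q_threshold]
        egene_rows.append(
            {
                "gene_id": g,
                "n_cis_variants": len(grp),
                "egene": len(sig) > 0,
                "gene_threshold": float(sig["p"].max()) if len(sig) else np.nan,
            }
        )
    egenes = pd.DataFrame(egene_rows)
    thresholds = egenes.loc[egenes["egene"], "gene_threshold"].to_numpy(dtype=float)
    if thresholds.size:
        horizontal = float(10.0 ** np.median(np.log10(thresholds)))
    else:
        horizontal = np.nan
    res["significant"] = (res["q"] < q_threshold) & (res["p"] < horizontal)
    egenes["horizontal_threshold"] = horizontal
    return egenes, res, horizontal


def run_eqtl(
    genotypes: GenotypeMatrix,
    expression_int: pd.DataFrame,  # samples x genes, already INT-transformed
    covariates: pd.DataFrame | None,
    transcripts: pd.DataFrame,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """cis-eQTL scan plus the two-stage eGene significance procedure."""
    pairs = map_cis_pairs(genotypes.variant_keys, transcripts).rename(
        columns={"gene_id": "phenotype_id"}
    )
    results = _scan(genotypes, expression_int, covariates, pairs)
    return call_egenes(results, q_threshold)


def run_ilqtl(
    genotypes: GenotypeMatrix,
    immune: pd.DataFrame,  # samples x features, raw scale
    covariates: pd.DataFrame | None,
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Immune-landscape QTL scan: every variant against every immune feature.

    Features are inverse-normal-transformed; constant features are skipped
    and reported. Multiple testing is BH per feature across all tested
    variants, significant at q < 0.05.
    """
    skipped = []
    cols = {}
    for f in immune.columns:
        v = immune[f].to_numpy(dtype=float)
        if np.nanmax(v) == np.nanmin(v):
            skipped.append(f)
            continue
        cols[f] = inverse_normal_transform(v)
    pheno = pd.DataFrame(cols, index=immune.index)
    pairs = pd.DataFrame(
        [
            {"key": k, "phenotype_id": f}
            for f in pheno.columns
            for k in genotypes.variant_keys
        ]
    )
    res = _scan(genotypes, pheno, covariates, pairs)
    res["q"] = np.nan
    for f, grp in res.groupby("phenotype_id"):
        ok = np.isfinite(grp["p"].to_numpy())
        q = np.full(len(grp), np.nan)
        if ok.any():
            q[ok] = bh_adjust(grp["p"].to_numpy()[ok])
        res.loc[grp.index, "q"] = q
    res["significant"] = res["q"] < q_threshold
    return res, skipped
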