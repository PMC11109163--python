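"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure of an RNA-seq-derived 3'-UTR variant study
in a tumor cohort: a tumor-caller call table plus genotyper coverage records
per sample, SNP-array-style blood germline calls per patient, matched-normal
calls for a panel of normals, a gene-level count matrix with planted cis
effects, immune-phenotype tables with planted immune-landscape effects, an
RNA-editing-site list, MPRA barcode count tables, and an immunotherapy (ICI)
cohort with responder-enriched variants.

Every draw comes from one ``numpy`` Generator seeded by the config, so a seed
fully determines all outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "Cohort",
    "generate_cohort",
    "generate_mpra_counts",
    "generate_ici_cohort",
    "variant_key",
    "write_cohort",
]

BASES = np.array(["A", "C", "G", "T"])
FILTER_TAGS = ("base_qual", "map_qual", "n_ratio", "slippage")
IMMUNE_FEATURES = (
    "CD8_T_fraction",
    "NK_fraction",
    "Treg_fraction",
    "TCR_entropy",
    "BCR_entropy",
    "leukocyte_fraction",
)


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the emulated cohort.

    Betas for planted cis effects are on the inverse-normal-transform scale
    (per alternative-allele dose); MPRA effects are log2 fold changes of the
    alternative over the reference allele.
    """

    n_tumors: int = 375
    n_normals: int = 40
    n_genes: int = 500
    n_variants: int = 2000
    germline_fraction: float = 0.605
    editing_fraction_of_somatic: float = 0.665
    maf_range: tuple[float, float] = (0.013, 0.5)
    somatic_carrier_range: tuple[float, float] = (0.02, 0.15)
    planted_eqtl_effects: list[tuple[str, str, float]] = field(default_factory=list)
    planted_ilqtl_effects: list[tuple[str, str, float]] = field(default_factory=list)
    mpra_planted_log2fc: list[tuple[str, float]] = field(default_factory=list)
    ici_enriched_variants: list[tuple[str, float]] = field(default_factory=list)
    # noise / nuisance structure
    count_dispersion: float = 0.03
    expression_sd: float = 1.0
    base_mean_counts: float = 500.0
    library_size_sd: float = 0.2
    latent_factor_sd: float = 0.0
    depth_mean: float = 60.0
    coverage_rate: float = 0.95
    blood_dropout: float = 0.05
    filter_tag_rate: float = 0.01
    region_weights: tuple[float, float, float] = (0.10, 0.15, 0.75)  # 5'UTR, CDS, 3'UTR
    n_decoy_editing_sites: int = 50
    # MPRA
    mpra_rna_replicates: int = 3
    mpra_dna_depth: float = 200.0
    mpra_rna_depth: float = 200.0
    mpra_dispersion: float = 0.15
    mpra_barcode_sd: float = 0.3
    # ICI cohort
    ici_n: int = 135
    ici_responders: int = 55
    ici_gastric_n: int = 45
    ici_background_variants: int = 100
    ici_carriage_range: tuple[float, float] = (0.05, 0.30)
    pdl1_responder_shift: float = 0.358  # Gaussian shift giving AUC ~0.6
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumors", "n_normals", "n_genes", "n_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_normals > self.n_tumors:
            raise ValueError("n_normals must not exceed n_tumors")
        for name in (
            "germline_fraction",
            "editing_fraction_of_somatic",
            "coverage_rate",
            "blood_dropout",
            "filter_tag_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("maf_range must be an ordered interval in [0, 1]")
        for vid, odds in self.ici_enriched_variants:
            if odds < 0:
                raise ValueError(f"odds ratio for {vid} must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthTable:
    """Planted ground truth: origins, effect sizes and response probabilities."""

    variants: pd.DataFrame  # variant_id, key, chrom, pos, ref, alt, gene_id, region, origin, freq, pop_af
    dosage: pd.DataFrame  # variants (key) x tumor samples, int8
    eqtl_betas: dict[tuple[str, str], float]
    ilqtl_betas: dict[tuple[str, str], float]
    mpra_log2fc: dict[str, float]
    ici_response_prob: pd.Series | None = None

    @property
    def origins(self) -> pd.Series:
        return self.variants.set_index("key")["origin"]

    def key_of(self, variant_id: str) -> str:
        row = self.variants.loc[self.variants["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return row["key"].iloc[0]


@dataclass
class Cohort:
    config: SimulationConfig
    tumor_calls: pd.DataFrame
    genotyper_calls: pd.DataFrame
    normal_calls: pd.DataFrame
    blood_sets: dict[str, frozenset[str]]
    counts: pd.DataFrame  # genes x tumor samples
    immune: pd.DataFrame  # tumor samples x features
    covariates: pd.DataFrame  # tumor samples x (age, sex)
    transcripts: pd.DataFrame
    genome: dict[str, str]
    editing_sites: pd.DataFrame  # chrom, pos (1-based)
    pop_af: pd.Series  # key -> population allele frequency
    truth: TruthTable

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# transcript models and genome


def _generate_transcripts(rng, n_genes: int, chrom: str = "chr1") -> pd.DataFrame:
    """Lay one transcript per gene along a chromosome with intergenic gaps."""
    rows = []
    cursor = 1000
    for g in range(n_genes):
        utr5 = int(rng.integers(100, 300))
        cds = int(rng.integers(600, 1500))
        utr3 = int(rng.integers(400, 1200))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        if strand == "+":
            u5 = (start, start + utr5)
            c = (u5[1], u5[1] + cds)
            u3 = (c[1], c[1] + utr3)
        else:  # genomic left-to-right: 3'UTR, CDS, 5'UTR
            u3 = (start, start + utr3)
            c = (u3[1], u3[1] + cds)
            u5 = (c[1], c[1] + utr5)
        end = start + utr5 + cds + utr3
        rows.append(
            {
                "gene_id": f"g{g:04d}",
                "transcript_id": f"g{g:04d}.t1",
                "chrom": chrom,
                "strand": strand,
                "tx_start": start,
                "tx_end": end,
                "utr5_start": u5[0],
                "utr5_end": u5[1],
                "cds_start": c[0],
                "cds_end": c[1],
                "utr3_start": u3[0],
                "utr3_end": u3[1],
            }
        )
        cursor = end + int(rng.integers(500, 1500))
    return pd.DataFrame(rows)


def _generate_genome(rng, transcripts: pd.DataFrame) -> dict[str, str]:
    out = {}
    for chrom, sub in transcripts.groupby("chrom"):
        length = int(sub["tx_end"].max()) + 1000
        seq = rng.integers(0, 4, size=length)
        out[chrom] = "".join(BASES[seq])
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _place_variants(rng, config: SimulationConfig, transcripts: pd.DataFrame, genome):
    """Assign each variant a gene, genic region, unique position and alleles."""
    n_v = config.n_variants
    gene_ids = transcripts["gene_id"].to_numpy()
    by_gene = transcripts.set_index("gene_id")

    gene_idx = rng.integers(0, len(gene_ids), size=n_v)
    regions = rng.choice(["utr5", "cds", "utr3"], size=n_v, p=np.asarray(config.region_weights))

    forced_gene: dict[str, str] = {}
    for vid, gid, _ in config.planted_eqtl_effects:
        forced_gene[vid] = gid
    used: set[tuple[str, int]] = set()
    recs = []
    for i in range(n_v):
        vid = f"v{i:05d}"
        gid = forced_gene.get(vid, gene_ids[gene_idx[i]])
        region = "utr3" if vid in forced_gene else regions[i]
        row = by_gene.loc[gid]
        start, end = int(row[f"{region}_start"]), int(row[f"{region}_end"])
        chrom = row["chrom"]
        for _ in range(100):
            pos0 = int(rng.integers(start, end))
            if (chrom, pos0) not in used:
                break
        else:  # pragma: no cover - only under extreme variant density
            raise RuntimeError("could not place variant at a unique position")
        used.add((chrom, pos0))
        ref = genome[chrom][pos0]
        alt = str(rng.choice(BASES[BASES != ref]))
        recs.append(
            {
                "variant_id": vid,
                "key": variant_key(chrom, pos0 + 1, ref, alt),
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": alt,
                "gene_id": gid,
                "region": {"utr5": "5'UTR", "cds": "CDS", "utr3": "3'UTR"}[region],
            }
        )
    return pd.DataFrame(recs)


def _call_rows(rng, config, variants, dosage, sample_ids, origin, vaf_means=None):
    """Long-format tumor-caller rows for all carrier cells of ``dosage``."""
    vi, si = np.nonzero(dosage > 0)
    n = vi.size
    dos = dosage[vi, si]
    orig = origin[vi]
    vaf = np.empty(n)
    het_g = (orig == "germline") & (dos == 1)
    hom_g = (orig == "germline") & (dos == 2)
    som = orig != "germline"
    vaf[het_g] = rng.beta(20, 20, het_g.sum())
    vaf[hom_g] = rng.beta(40, 2, hom_g.sum())
    vaf[som] = rng.beta(2, 6, som.sum())
    dp = np.maximum(rng.poisson(config.depth_mean, n), 8)
    ad_alt = np.clip(rng.binomial(dp, vaf), 1, dp)
    tagged = rng.random(n) < config.filter_tag_rate
    tags = np.where(tagged, rng.choice(FILTER_TAGS, n), "PASS")
    return pd.DataFrame(
        {
            "sample_id": np.asarray(sample_ids)[si],
            "chrom": variants["chrom"].to_numpy()[vi],
            "pos": variants["pos"].to_numpy()[vi],
            "ref": variants["ref"].to_numpy()[vi],
            "alt": variants["alt"].to_numpy()[vi],
            "gt": np.where(dos == 2, "1/1", "0/1"),
            "dp": dp,
            "ad_ref": dp - ad_alt,
            "ad_alt": ad_alt,
            "filter": tags,
            "caller": "tumor-caller",
        }
    )


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate every pipeline input for one synthetic tumor cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    transcripts = _generate_transcripts(rng, config.n_genes)
    genome = _generate_genome(rng, transcripts)
    variants = _place_variants(rng, config, transcripts, genome)
    n_v = config.n_variants
    tumors = [f"T{i:04d}" for i in range(config.n_tumors)]
    normals = [f"M{i:04d}" for i in range(config.n_normals)]

    # origin labels
    is_germ = rng.random(n_v) < config.germline_fraction
    is_edit = (~is_germ) & (rng.random(n_v) < config.editing_fraction_of_somatic)
    origin = np.where(is_germ, "germline", np.where(is_edit, "somatic_editing", "somatic"))
    variants["origin"] = origin

    # genotypes: germline HWE dosages shared with matched normal/blood tissue;
    # somatic calls are tumor-only het-like events with a subclonal VAF
    maf = rng.uniform(*config.maf_range, n_v)
    som_f = rng.uniform(*config.somatic_carrier_range, n_v)
    dosage = np.zeros((n_v, config.n_tumors), dtype=np.int8)
    g = np.nonzero(is_germ)[0]
    s = np.nonzero(~is_germ)[0]
    dosage[g] = rng.binomial(2, maf[g][:, None], (g.size, config.n_tumors))
    dosage[s] = rng.binomial(1, som_f[s][:, None], (s.size, config.n_tumors))
    variants["freq"] = np.where(is_germ, maf, som_f)

    # population allele frequency: tracks the true MAF for germline variants,
    # floor-level for somatic ones (a small minority have a nonzero entry)
    pop = np.where(is_germ, np.clip(maf * rng.lognormal(0, 0.2, n_v), 1e-5, 0.5), 0.0)
    rare = (~is_germ) & (rng.random(n_v) < 0.05)
    pop[rare] = rng.uniform(1e-5, 0.01, rare.sum())
    pop_af = pd.Series(pop, index=variants["key"].to_numpy(), name="pop_af")

    tumor_calls = _call_rows(rng, config, variants, dosage, tumors, origin)

    # genotyper coverage rows for hom-ref cells (tumor-called cells are
    # covered by construction and take precedence during the merge)
    homref = dosage == 0
    covered = homref & (rng.random(dosage.shape) < config.coverage_rate)
    vi, si = np.nonzero(covered)
    dp0 = np.maximum(rng.poisson(config.depth_mean, vi.size), 5)
    genotyper_calls = pd.DataFrame(
        {
            "sample_id": np.asarray(tumors)[si],
            "chrom": variants["chrom"].to_numpy()[vi],
            "pos": variants["pos"].to_numpy()[vi],
            "ref": variants["ref"].to_numpy()[vi],
            "alt": variants["alt"].to_numpy()[vi],
            "gt": "0/0",
            "dp": dp0,
            "ad_ref": dp0,
            "ad_alt": 0,
            "filter": "PASS",
            "caller": "genotyper",
        }
    )

    # matched normals share the patient's germline genotypes
    normal_dosage = np.zeros((n_v, config.n_normals), dtype=np.int8)
    normal_dosage[g] = dosage[g][:, : config.n_normals]
    normal_calls = _call_rows(
        rng, config, variants, normal_dosage, normals, np.full(n_v, "germline")
    )

    # blood germline call set per patient, with dropout
    keys = variants["key"].to_numpy()
    blood_sets = {}
    blood_carrier = (dosage > 0) & is_germ[:, None]
    keep = rng.random(dosage.shape) >= config.blood_dropout
    blood_carrier &= keep
    for j, t in enumerate(tumors):
        blood_sets[t] = frozenset(keys[np.nonzero(blood_carrier[:, j])[0]])

    # expression counts with planted cis effects on the latent log scale
    gene_ids = transcripts["gene_id"].to_numpy()
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    vid_pos = {vid: i for i, vid in enumerate(variants["variant_id"])}
    latent = rng.normal(size=(config.n_genes, config.n_tumors))
    eqtl_betas = {}
    for vid, gid, beta in config.planted_eqtl_effects:
        latent[gene_pos[gid]] += beta * dosage[vid_pos[vid]]
        eqtl_betas[(vid, gid)] = float(beta)
    if config.latent_factor_sd > 0:
        u = rng.normal(size=config.n_tumors)
        load = rng.normal(size=config.n_genes)
        latent += config.latent_factor_sd * np.outer(load, u)
    base = rng.normal(np.log(config.base_mean_counts), 1.0, config.n_genes)
    libfac = rng.lognormal(0.0, config.library_size_sd, config.n_tumors)
    mu = np.exp(base[:, None] + config.expression_sd * latent) * libfac[None, :]
    if config.count_dispersion > 0:
        shape = 1.0 / config.count_dispersion
        counts_arr = rng.negative_binomial(shape, shape / (shape + mu))
    else:
        counts_arr = rng.poisson(mu)
    counts = pd.DataFrame(counts_arr, index=gene_ids, columns=tumors)

    # immune phenotypes with planted immune-landscape effects
    feats = list(IMMUNE_FEATURES)
    imm = rng.normal(size=(config.n_tumors, len(feats)))
    ilqtl_betas = {}
    for vid, fid, beta in config.planted_ilqtl_effects:
        imm[:, feats.index(fid)] += beta * dosage[vid_pos[vid]]
        ilqtl_betas[(vid, fid)] = float(beta)
    immune = pd.DataFrame(imm, index=tumors, columns=feats)

    covariates = pd.DataFrame(
        {
            "age": np.round(rng.uniform(40, 85, config.n_tumors), 1),
            "sex": rng.integers(0, 2, config.n_tumors),
        },
        index=tumors,
    )

    edit_pos = variants.loc[variants["origin"] == "somatic_editing", ["chrom", "pos"]]
    occupied = set(zip(variants["chrom"], variants["pos"]))
    decoys = []
    chrom = transcripts["chrom"].iloc[0]
    limit = int(transcripts["tx_end"].max())
    while len(decoys) < config.n_decoy_editing_sites:
        p = int(rng.integers(1, limit))
        if (chrom, p) not in occupied:
            decoys.append({"chrom": chrom, "pos": p})
            occupied.add((chrom, p))
    editing_sites = pd.concat([edit_pos, pd.DataFrame(decoys)], ignore_index=True)

    truth = TruthTable(
        variants=variants,
        dosage=pd.DataFrame(dosage, index=keys, columns=tumors),
        eqtl_betas=eqtl_betas,
        ilqtl_betas=ilqtl_betas,
        mpra_log2fc=dict(config.mpra_planted_log2fc),
    )
    return Cohort(
        config=config,
        tumor_calls=tumor_calls,
        genotyper_calls=genotyper_calls,
        normal_calls=normal_calls,
        blood_sets=blood_sets,
        counts=counts,
        immune=immune,
        covariates=covariates,
        transcripts=transcripts,
        genome=genome,
        editing_sites=editing_sites,
        pop_af=pop_af,
        truth=truth,
    )


def generate_binding_sites(
    transcripts: pd.DataFrame,
    seed: int | None = None,
    mean_sites_per_utr: float = 2.0,
    length_range: tuple[int, int] = (7, 22),
    source: str = "miRNA-predicted",
) -> pd.DataFrame:
    """Random regulatory-element intervals inside 3'-UTRs (BED-like, 0-based)."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, t in transcripts.iterrows():
        start, end = int(t["utr3_start"]), int(t["utr3_end"])
        for _ in range(rng.poisson(mean_sites_per_utr)):
            length = int(rng.integers(*length_range))
            if end - start <= length:
                continue
            s = int(rng.integers(start, end - length))
            rows.append({"chrom": t["chrom"], "start": s, "end": s + length,
                         "source": source})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "source"])


# ---------------------------------------------------------------------------
# MPRA counts


def generate_mpra_counts(
    pool: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Barcode count table for a designed pool: one DNA column plus RNA replicates.

    ``pool`` needs columns barcode, variant_id, allele. RNA means of
    alternative-allele barcodes are multiplied by 2**log2fc for planted
    variants. ``mpra_dispersion = 0`` and ``mpra_barcode_sd = 0`` give the
    noiseless limit with deterministic expected counts.
    """
    if pool["barcode"].duplicated().any():
        dup = pool.loc[pool["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"duplicate barcode in pool: {dup}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lfc = dict(config.mpra_planted_log2fc)
    n = len(pool)
    if config.mpra_barcode_sd > 0:
        weight = rng.lognormal(0.0, config.mpra_barcode_sd, n)
    else:
        weight = np.ones(n)
    effect = np.where(
        pool["allele"].to_numpy() == "alt",
        2.0 ** np.array([lfc.get(v, 0.0) for v in pool["variant_id"]]),
        1.0,
    )
    out = pd.DataFrame({"barcode": pool["barcode"], "variant_id": pool["variant_id"],
                        "allele": pool["allele"]})
    mu_dna = config.mpra_dna_depth * weight
    noiseless = config.mpra_dispersion == 0 and config.mpra_barcode_sd == 0
    out["DNA"] = np.round(mu_dna).astype(int) if noiseless else rng.poisson(mu_dna)
    for r in range(config.mpra_rna_replicates):
        mu = config.mpra_rna_depth * weight * effect
        if noiseless:
            col = np.round(mu).astype(int)
        elif config.mpra_dispersion == 0:
            col = rng.poisson(mu)
        else:
            shape = 1.0 / config.mpra_dispersion
            col = rng.negative_binomial(shape, shape / (shape + mu))
        out[f"RNA_rep{r + 1}"] = col
    return out


# ---------------------------------------------------------------------------
# ICI cohort


def _class_rates(overall: float, odds_ratio: float, pi: float) -> tuple[float, float]:
    """Carriage rates (f_R, f_NR) with marginal rate ``overall`` and the given OR."""
    if odds_ratio == 1.0:
        return overall, overall
    lo, hi = 0.0, min(1.0, overall / max(pi, 1e-12))
    for _ in range(200):
        f_nr = (lo + hi) / 2
        odds_nr = f_nr / (1.0 - f_nr) if f_nr < 1 else np.inf
        f_r = (odds_ratio * odds_nr) / (1.0 + odds_ratio * odds_nr)
        if pi * f_r + (1 - pi) * f_nr > overall:
            hi = f_nr
        else:
            lo = f_nr
    f_nr = (lo + hi) / 2
    odds_nr = f_nr / (1.0 - f_nr)
    f_r = (odds_ratio * odds_nr) / (1.0 + odds_ratio * odds_nr)
    return f_r, f_nr


def generate_ici_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TruthTable]:
    """ICI cohort whose response follows a logistic model over variant carriage.

    Responder labels are fixed at the configured count; carriage of each
    candidate variant is drawn per response class with rates solved so that
    the marginal carriage rate matches the configured range draw and the
    carriage-response odds ratio equals the planted value (so a Fisher test
    on a large cohort recovers it). Under independent carriage given
    response this retrospective construction is exactly a logistic model of
    response on carriage with per-variant coefficient log(OR); the implied
    per-patient response probability is recorded in the truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.ici_n
    pi = config.ici_responders / n
    enriched = list(config.ici_enriched_variants)
    background = [f"bg{i:04d}" for i in range(config.ici_background_variants)]
    all_ids = [v for v, _ in enriched] + background
    odds_ratios = np.array([o for _, o in enriched] + [1.0] * len(background))

    response = np.zeros(n, dtype=bool)
    response[rng.choice(n, size=config.ici_responders, replace=False)] = True

    carriage_rate = rng.uniform(*config.ici_carriage_range, len(all_ids))
    carriage = np.zeros((n, len(all_ids)), dtype=bool)
    f_r_all = np.empty(len(all_ids))
    f_nr_all = np.empty(len(all_ids))
    for j, (f, orr) in enumerate(zip(carriage_rate, odds_ratios)):
        f_r, f_nr = _class_rates(float(f), float(orr), pi)
        f_r_all[j], f_nr_all[j] = f_r, f_nr
        p_j = np.where(response, f_r, f_nr)
        carriage[:, j] = rng.random(n) < p_j

    # implied logistic response probability given the carried set (Bayes)
    with np.errstate(divide="ignore"):
        w1 = np.log(f_r_all) - np.log(f_nr_all)
        w0 = np.log(1 - f_r_all) - np.log(1 - f_nr_all)
    eta = (
        np.log(pi / (1 - pi))
        + carriage @ np.nan_to_num(w1, neginf=-50.0)
        + (~carriage) @ np.nan_to_num(w0, neginf=-50.0)
    )
    prob = 1.0 / (1.0 + np.exp(-eta))

    pdl1 = rng.normal(size=n) + config.pdl1_responder_shift * response
    patients = [f"P{i:04d}" for i in range(n)]
    cancer = np.array(["gastric"] * config.ici_gastric_n + ["melanoma"] * (n - config.ici_gastric_n))
    cohort = pd.DataFrame(
        {
            "patient_id": patients,
            "cancer_type": cancer,
            "response": np.where(response, "R", "NR"),
            "pdl1": pdl1,
            "variants": [frozenset(np.asarray(all_ids)[carriage[i]]) for i in range(n)],
        }
    )
    truth = TruthTable(
        variants=pd.DataFrame({"variant_id": all_ids, "key": all_ids,
                               "carriage_rate": carriage_rate}),
        dosage=pd.DataFrame(index=[], columns=[]),
        eqtl_betas={},
        ilqtl_betas={},
        mpra_log2fc={},
        ici_response_prob=pd.Series(prob, index=patients),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# writers (TSV dialect shared with the pipeline readers)

CALL_COLUMNS = {
    "chrom": "CHROM", "pos": "POS", "ref": "REF", "alt": "ALT", "gt": "GT",
    "dp": "DP", "ad_ref": "AD_REF", "ad_alt": "AD_ALT", "filter": "FILTER",
    "caller": "CALLER",
}


def _write_calls(calls: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, sub in calls.groupby("sample_id", sort=True):
        sub = sub.drop(columns="sample_id").rename(columns=CALL_COLUMNS)
        sub.to_csv(outdir / f"{sample}.tsv", sep="\t", index=False)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write every generated table in the pipeline's TSV dialect."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_calls(pd.concat([cohort.tumor_calls, cohort.genotyper_calls]), out / "calls")
    _write_calls(cohort.normal_calls, out / "normals")
    blood_dir = out / "blood"
    blood_dir.mkdir(exist_ok=True)
    for patient, keys in sorted(cohort.blood_sets.items()):
        pd.DataFrame({"KEY": sorted(keys)}).to_csv(
            blood_dir / f"{patient}.tsv", sep="\t", index=False
        )
    cohort.counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
    cohort.immune.rename_axis("sample_id").to_csv(out / "immune.tsv", sep="\t")
    cohort.covariates.rename_axis("sample_id").to_csv(out / "covariates.tsv", sep="\t")
    cohort.editing_sites.rename(columns={"chrom": "CHROM", "pos": "POS"}).to_csv(
        out / "editing_sites.tsv", sep="\t", index=False
    )
    cohort.pop_af.rename_axis("KEY").to_csv(out / "pop_af.tsv", sep="\t")
    cohort.transcripts.to_csv(out / "transcripts.tsv", sep="\t", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    cohort.truth.variants.to_csv(truth_dir / "variants.tsv", sep="\t", index=False)
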