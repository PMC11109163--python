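"""RNA-seq variant merging, filtering and germline/somatic classification.

The cohort genotype matrix distinguishes two missing states: NO_COVERAGE
(neither caller saw the site in that sample) and FILTERED (the call carried a
disqualifying filter tag). Hom-ref dosage 0 is asserted only where the
genotyper covered the site — an RNA-seq-specific subtlety, since absent
expression silently removes the ability to call a variant at all.

Origin classification is Bayesian: prior odds of a germline origin come from
the population allele frequency (carrier probability 1-(1-AF)^2 under
Hardy-Weinberg, floored for unobserved variants), updated by a likelihood
ratio of the mean carrier VAF under a germline-het Beta component centred at
0.5 versus a subclonal somatic Beta component centred at 0.25. Hard evidence
short-circuits the update: presence in the patient-matched blood call set
fixes a germline origin; membership in the panel of normals multiplies the
germline side by a configurable factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NO_COVERAGE",
    "FILTERED",
    "GenotypeMatrix",
    "PanelOfNormals",
    "ClassifierConfig",
    "VariantSummary",
    "merge_caller_calls",
    "apply_filters",
    "build_pon",
    "mean_carrier_vaf",
    "classify_origin",
    "summarize_landscape",
    "concordance",
    "carrier_frequency_threshold",
]

NO_COVERAGE = -1
FILTERED = -2

DEFAULT_FILTER_TAGS = frozenset({"base_qual", "map_qual", "n_ratio", "slippage"})

_GT_DOSAGE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
              "1/1": 2, "1|1": 2}


def _keys(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str)
        + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str)
    )


@dataclass
class GenotypeMatrix:
    """Variants x samples alternative-allele dosage with coded missing states."""

    dosage: pd.DataFrame  # int8; values in {0,1,2, NO_COVERAGE, FILTERED}

    @property
    def variant_keys(self) -> pd.Index:
        return self.dosage.index

    @property
    def samples(self) -> pd.Index:
        return self.dosage.columns

    def carrier_counts(self) -> pd.Series:
        return (self.dosage > 0).sum(axis=1)

    def tested_counts(self) -> pd.Series:
        """Denominator per variant: samples that are not NO_COVERAGE."""
        return (self.dosage != NO_COVERAGE).sum(axis=1)


@dataclass
class PanelOfNormals:
    """Variants recurrently observed in matched normals (carrier count >= 2)."""

    carrier_counts: pd.Series  # key -> normal carrier count, all >= min_carriers
    min_carriers: int = 2

    def __contains__(self, key: str) -> bool:
        return key in self.carrier_counts.index

    @property
    def keys(self) -> frozenset:
        return frozenset(self.carrier_counts.index)


def merge_caller_calls(
    tumor_calls: pd.DataFrame, genotyper_calls: pd.DataFrame
) -> GenotypeMatrix:
    """Merge tumor-caller calls with genotyper coverage into a dosage matrix.

    Precedence per cell: a tumor-caller call contributes its dosage; a
    genotyper record at the site asserts hom-ref (dosage 0); otherwise the
    cell is NO_COVERAGE. Conflicting REF alleles at one position are an error.
    """
    frames = [f for f in (tumor_calls, genotyper_calls) if len(f)]
    if not frames:
        raise ValueError("no call records supplied")
    both = pd.concat(frames, ignore_index=True)
    refs = both.groupby(["chrom", "pos"])["ref"].nunique()
    bad = refs[refs > 1]
    if len(bad):
        chrom, pos = bad.index[0]
        raise ValueError(f"conflicting REF alleles at {chrom}:{pos}")

    samples = pd.Index(sorted(both["sample_id"].unique()))
    keys = pd.Index(sorted(_keys(both).unique()))
    mat = np.full((len(keys), len(samples)), NO_COVERAGE, dtype=np.int8)
    key_pos = {k: i for i, k in enumerate(keys)}
    sample_pos = {s: j for j, s in enumerate(samples)}

    if len(genotyper_calls):
        gi = _keys(genotyper_calls).map(key_pos).to_numpy()
        gj = genotyper_calls["sample_id"].map(sample_pos).to_numpy()
        mat[gi, gj] = 0
    if len(tumor_calls):
        ti = _keys(tumor_calls).map(key_pos).to_numpy()
        tj = tumor_calls["sample_id"].map(sample_pos).to_numpy()
        dos = tumor_calls["gt"].map(_GT_DOSAGE).fillna(NO_COVERAGE).astype(np.int8)
        mat[ti, tj] = dos
    return GenotypeMatrix(pd.DataFrame(mat, index=keys, columns=samples))


def apply_filters(
    matrix: GenotypeMatrix,
    records: pd.DataFrame,
    filter_tags: frozenset[str] = DEFAULT_FILTER_TAGS,
    min_carriers: int = 5,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply caller filter tags, drop multi-allelic sites and rare variants.

    Cells whose record carries any disqualifying tag become FILTERED; sites
    with more than one ALT allele are dropped; variants carried by fewer than
    ``min_carriers`` samples (NO_COVERAGE excluded from the denominator but
    carriers counted over remaining cells) are dropped. Unknown tags are
    retained and logged. Returns the filtered matrix and a removal log.
    """
    dosage = matrix.dosage.copy()
    log = {"cells_filtered": 0, "multiallelic_variants": 0,
           "low_carrier_variants": 0, "unknown_tags": 0}

    if len(records):
        rec = records.copy()
        rec["key"] = _keys(rec)
        tags = rec["filter"].fillna("PASS").astype(str)
        split = tags.str.split(r"[;,]")
        known_hit = split.map(lambda ts: any(t in filter_tags for t in ts))
        unknown = split.map(
            lambda ts: any(t not in filter_tags and t != "PASS" and t != "." for t in ts)
        )
        log["unknown_tags"] = int(unknown.sum())
        hit = rec.loc[known_hit]
        for key, sample in zip(hit["key"], hit["sample_id"]):
            if key in dosage.index and sample in dosage.columns:
                if dosage.at[key, sample] > 0:
                    dosage.at[key, sample] = FILTERED
                    log["cells_filtered"] += 1

    parts = dosage.index.to_series().str.split(":", expand=True)
    site = parts[0] + ":" + parts[1] + ":" + parts[2]
    multi = site.duplicated(keep=False)
    log["multiallelic_variants"] = int(multi.sum())
    dosage = dosage.loc[~multi.to_numpy()]

    carriers = (dosage > 0).sum(axis=1)
    low = carriers < min_carriers
    log["low_carrier_variants"] = int(low.sum())
    dosage = dosage.loc[~low.to_numpy()]
    return GenotypeMatrix(dosage), log


def build_pon(normal_calls: pd.DataFrame, min_carriers: int = 2) -> PanelOfNormals:
    """Panel of normals: variants seen in >= min_carriers matched normals."""
    if not len(normal_calls):
        return PanelOfNormals(pd.Series(dtype=int), min_carriers)
    key_carriers = (
        pd.DataFrame({"key": _keys(normal_calls), "sample_id": normal_calls["sample_id"]})
        .drop_duplicates()
        .groupby("key")
        .size()
    )
    return PanelOfNormals(key_carriers[key_carriers >= min_carriers], min_carriers)


def mean_carrier_vaf(tumor_calls: pd.DataFrame) -> pd.Series:
    """Mean alternative-allele fraction over carrier calls, per variant key."""
    vaf = tumor_calls["ad_alt"] / tumor_calls["dp"].replace(0, np.nan)
    return vaf.groupby(_keys(tumor_calls).to_numpy()).mean()


@dataclass
class ClassifierConfig:
    """Shape of the origin-posterior model; all parameters are explicit."""

    af_floor: float = 1e-4
    germline_beta: tuple[float, float] = (20.0, 20.0)  # het VAF component
    somatic_beta: tuple[float, float] = (2.0, 6.0)  # subclonal VAF component
    pon_factor: float = 20.0  # germline-side likelihood multiplier


def classify_origin(
    matrix: GenotypeMatrix,
    blood_sets: dict[str, frozenset[str]],
    pon: PanelOfNormals,
    pop_af: pd.Series,
    editing_sites: set[tuple[str, int]],
    vaf: pd.Series,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Per-variant germline/somatic posterior with evidence breakdown.

    Hard rule first: a variant present in any carrier patient's blood call
    set is germline with posterior 1. Otherwise posterior odds =
    prior odds (from population AF) x VAF likelihood ratio x PoN factor.
    Somatic calls at editing-site positions are labelled as editing overlap.
    """
    cfg = config or ClassifierConfig()
    dosage = matrix.dosage
    rows = []
    ga, gb = cfg.germline_beta
    sa, sb = cfg.somatic_beta
    for key in dosage.index:
        chrom, pos, _ref, _alt = key.split(":")
        carriers = dosage.columns[dosage.loc[key].to_numpy() > 0]
        in_blood = any(key in blood_sets.get(s, frozenset()) for s in carriers)
        in_pon = key in pon
        edit = (chrom, int(pos)) in editing_sites
        af = float(pop_af.get(key, 0.0))
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"population AF out of range for {key}")
        v = float(vaf.get(key, np.nan))
        if in_blood:
            p_germ = 1.0
        else:
            prior = np.clip(1.0 - (1.0 - af) ** 2, cfg.af_floor, 1.0 - cfg.af_floor)
            odds = prior / (1.0 - prior)
            if np.isfinite(v) and 0.0 < v < 1.0:
                lr = stats.beta.pdf(v, ga, gb) / stats.beta.pdf(v, sa, sb)
                odds *= lr
            if in_pon:
                odds *= cfg.pon_factor
            p_germ = odds / (1.0 + odds)
        p_som = 1.0 - p_germ
        if p_som > 0.5:
            label = "somatic_editing_overlap" if edit else "likely_somatic"
        else:
            label = "germline"
        rows.append(
            {
                "key": key,
                "p_germline": p_germ,
                "p_somatic": p_som,
                "label": label,
                "in_blood": in_blood,
                "in_pon": in_pon,
                "pop_af": af,
                "mean_vaf": v,
                "editing_overlap": edit,
            }
        )
    return pd.DataFrame(rows).set_index("key")


@dataclass
class VariantSummary:
    """Cohort landscape counts with one-decimal percentages."""

    total: int
    germline: int
    somatic: int
    editing_overlap: int
    germline_pct: float = field(init=False)
    somatic_pct: float = field(init=False)
    editing_pct_of_somatic: float = field(init=False)

    def __post_init__(self):
        if self.germline + self.somatic != self.total:
            raise ValueError("germline + somatic must equal total")
        self.germline_pct = _pct(self.germline, self.total)
        self.somatic_pct = _pct(self.somatic, self.total)
        self.editing_pct_of_somatic = _pct(self.editing_overlap, self.somatic)

    @classmethod
    def from_counts(cls, total, germline, somatic, editing_overlap) -> "VariantSummary":
        return cls(total, germline, somatic, editing_overlap)


def _pct(part: int, whole: int) -> float:
    return round(100.0 * part / whole, 1) if whole else 0.0


def summarize_landscape(posteriors: pd.DataFrame) -> VariantSummary:
    """Counts and percentages of the classified variant landscape."""
    if not len(posteriors):
        return VariantSummary(0, 0, 0, 0)
    germ = int((posteriors["label"] == "germline").sum())
    som = int(len(posteriors) - germ)
    edit = int((posteriors["label"] == "somatic_editing_overlap").sum())
    return VariantSummary(len(posteriors), germ, som, edit)


def concordance(set_a: set, set_b: set) -> tuple[int, float, float]:
    """Overlap count and recall fractions |A∩B|/|A| and |A∩B|/|B|."""
    inter = len(set(set_a) & set(set_b))
    fa = inter / len(set_a) if set_a else 0.0
    fb = inter / len(set_b) if set_b else 0.0
    return inter, fa, fb


def carrier_frequency_threshold(min_carriers: int = 5, n_samples: int = 375) -> float:
    """Minor-allele-frequency floor implied by a minimum-carrier rule."""
    return min_carriers / n_samples
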