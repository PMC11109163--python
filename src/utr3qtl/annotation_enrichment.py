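"""Genic-region assignment and the three enrichment statistics.

Coordinates follow the conventions used throughout the package: variant
positions are 1-based (VCF style), interval files are 0-based half-open
(BED style). When transcripts disagree, the per-variant region label is
collapsed by a configurable priority (default 3'UTR > 5'UTR > CDS).

Enrichment of variant loci in regulatory-element sets uses a resampling
permutation test over a vocabulary of fixed-width 3'-UTR windows: the
statistic is the number of query elements overlapping at least one feature,
and each permutation redraws the same number of windows uniformly (with
replacement) from the sampling space. Over-representation of gene sets uses
a one-sided Fisher (hypergeometric upper tail) with BH across sets, and the
region-count test against expected genomic fractions is a Pearson
goodness-of-fit chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "TranscriptModel",
    "models_from_frame",
    "assign_genic_region",
    "relative_utr_position",
    "EnrichmentResult",
    "permutation_enrichment",
    "overrepresentation_test",
    "chi_square_length_enrichment",
]

REGION_PRIORITY = ("3'UTR", "5'UTR", "CDS")


@dataclass
class TranscriptModel:
    """One transcript's region intervals, 0-based half-open, genomic order."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    utr5: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def region_intervals(self):
        yield from (("5'UTR", iv) for iv in self.utr5)
        yield from (("CDS", iv) for iv in self.cds)
        yield from (("3'UTR", iv) for iv in self.utr3)


def models_from_frame(transcripts: pd.DataFrame) -> list[TranscriptModel]:
    """Build transcript models from the flat single-interval table dialect."""
    out = []
    for _, t in transcripts.iterrows():
        out.append(
            TranscriptModel(
                gene_id=t["gene_id"],
                transcript_id=t["transcript_id"],
                chrom=t["chrom"],
                strand=t["strand"],
                utr5=[(int(t["utr5_start"]), int(t["utr5_end"]))],
                cds=[(int(t["cds_start"]), int(t["cds_end"]))],
                utr3=[(int(t["utr3_start"]), int(t["utr3_end"]))],
            )
        )
    return out


def assign_genic_region(
    variants: pd.DataFrame,  # columns chrom, pos (1-based); any extra kept
    models: list[TranscriptModel],
    priority: tuple[str, ...] = REGION_PRIORITY,
) -> pd.DataFrame:
    """Label each variant with its collapsed genic region and host gene.

    Per (variant, transcript) labels are collapsed across transcripts by
    ``priority``; variants outside every model are labelled ``other``.
    """
    trees: dict[str, IntervalTree] = {}
    known_chroms = {m.chrom for m in models}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for region, (start, end) in m.region_intervals():
            if end > start:
                tree.addi(start, end, (region, m.gene_id, m.transcript_id))
    rank = {r: i for i, r in enumerate(priority)}
    labels, genes = [], []
    for chrom, pos in zip(variants["chrom"], variants["pos"]):
        if chrom not in known_chroms:
            raise ValueError(f"unknown sequence name: {chrom}")
        hits = trees[chrom][int(pos) - 1] if chrom in trees else set()
        if not hits:
            labels.append("other")
            genes.append(None)
            continue
        best = min(hits, key=lambda h: rank.get(h.data[0], len(rank)))
        labels.append(best.data[0])
        genes.append(best.data[1])
    out = variants.copy()
    out["region"] = labels
    out["region_gene_id"] = genes
    return out


def relative_utr_position(
    pos: int, utr_intervals: list[tuple[int, int]], strand: str
) -> float:
    """Fractional position of a variant along the transcript-oriented 3'-UTR.

    ``pos`` is 1-based genomic; intervals are 0-based half-open in genomic
    order, concatenated in transcript orientation (reversed for the minus
    strand). Returns offset/length in [0, 1).
    """
    p0 = int(pos) - 1
    ordered = sorted(utr_intervals)
    total = sum(e - s for s, e in ordered)
    if total <= 0:
        raise ValueError("empty UTR")
    if strand == "-":
        ordered = ordered[::-1]
    offset = 0
    for s, e in ordered:
        if s <= p0 < e:
            offset += (p0 - s) if strand != "-" else (e - 1 - p0)
            return offset / total
        offset += e - s
    raise ValueError(f"position {pos} outside the UTR")


@dataclass
class EnrichmentResult:
    observed: float
    perm_mean: float
    perm_sd: float
    n_perm: int
    p: float
    z: float
    alternative: str
    seed: int | None = None


def permutation_enrichment(
    query_windows: np.ndarray,  # indices into the sampling space
    window_hits: np.ndarray,  # bool per window of the space: overlaps >=1 feature
    n_perm: int = 5000,
    seed: int | None = None,
    alternative: str = "enrichment",
) -> EnrichmentResult:
    """Window-resampling permutation test of feature overlap.

    ``window_hits`` encodes, for every window in the sampling space, whether
    it overlaps at least one feature; the observed statistic is the number of
    query windows that do. Each permutation redraws ``len(query_windows)``
    windows uniformly with replacement. The empirical p uses the +1
    correction and never returns 0.
    """
    hits = np.asarray(window_hits, dtype=bool)
    if hits.size == 0:
        raise ValueError("empty sampling space")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    q = np.asarray(query_windows, dtype=int)
    observed = int(hits[q].sum())
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, hits.size, size=(n_perm, q.size))
    perm = hits[draws].sum(axis=1)
    if alternative == "enrichment":
        extreme = int((perm >= observed).sum())
    elif alternative == "depletion":
        extreme = int((perm <= observed).sum())
    else:
        raise ValueError("alternative must be 'enrichment' or 'depletion'")
    p = (1 + extreme) / (1 + n_perm)
    sd = float(perm.std(ddof=1))
    z = (observed - perm.mean()) / sd if sd > 0 else 0.0
    return EnrichmentResult(
        observed=float(observed),
        perm_mean=float(perm.mean()),
        perm_sd=sd,
        n_perm=n_perm,
        p=float(p),
        z=float(z),
        alternative=alternative,
        seed=seed,
    )


def windows_hit_features(
    windows: list[tuple[str, int, int]], features: list[tuple[str, int, int]]
) -> np.ndarray:
    """Boolean per window: overlaps at least one feature interval (half-open)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in features:
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return np.array(
        [bool(trees[c].overlap(s, e)) if c in trees else False for c, s, e in windows]
    )


def overrepresentation_test(
    hit_genes: set,
    universe: set,
    gene_sets: dict[str, set],
) -> pd.DataFrame:
    """One-sided Fisher over-representation of each gene set, BH across sets.

    The 2x2 margin is hit/non-hit x in-set/out-of-set within the universe;
    p is the hypergeometric upper tail. Sets disjoint from the universe are
    skipped (flagged in the output).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not set(hit_genes) <= set(universe):
        raise ValueError("hit genes must be a subset of the universe")
    n = len(universe)
    k = len(hit_genes)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & set(universe)
        if not in_universe:
            rows.append({"gene_set": name, "n_set": 0, "n_hit_in_set": 0,
                         "p": np.nan, "skipped": True})
            continue
        m = len(in_universe)
        x = len(set(hit_genes) & in_universe)
        # upper tail: P(X >= x) for X ~ Hypergeom(N=n, K=m, n=k)
        p = float(stats.hypergeom.sf(x - 1, n, m, k))
        rows.append({"gene_set": name, "n_set": m, "n_hit_in_set": x,
                     "p": p, "skipped": False})
    out = pd.DataFrame(rows)
    ok = ~out["skipped"]
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out.sort_values(["q", "p"], na_position="last").reset_index(drop=True)


def chi_square_length_enrichment(
    region_counts: dict[str, int], expected_fractions: dict[str, float]
) -> tuple[float, float]:
    """Pearson goodness-of-fit of region counts against expected fractions.

    Tests whether variants distribute across genic regions in proportion to
    the regions' share of sequence length; df = #regions - 1.
    """
    regions = list(region_counts)
    fr = np.array([expected_fractions[r] for r in regions], dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("expected fractions must sum to 1")
    obs = np.array([region_counts[r] for r in regions], dtype=float)
    total = obs.sum()
    if total <= 0:
        raise ValueError("no observed counts")
    if np.any((fr == 0) & (obs > 0)):
        raise ValueError("zero expected fraction with nonzero count")
    keep = fr > 0
    chi2, p = stats.chisquare(obs[keep], total * fr[keep])
    return float(chi2), float(p)
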