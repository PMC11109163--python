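"""Barcoded reporter pool design and allelic-effect statistics.

Each oligo carries a 101-base insert (the variant allele centred between
50-base reference flanks, filler-padded near transcript ends), an 8-base
barcode drawn from a screened vocabulary, and 20-base cloning adapters. Ten
barcodes represent each allele.

Analysis follows the barcode-ratio convention: counts are depth-normalized
per sample, a log RNA/DNA ratio per barcode per replicate is quantile
normalized across replicates, reference and alternative barcode activities
are compared per replicate by a two-sided Wilcoxon rank-sum test, replicate
p-values are combined with Stouffer's method using direction-signed
z-scores, and BH correction is applied across variants within a cell line.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, quantile_normalize, stouffer_combine, wilcoxon_two_sided

__all__ = [
    "PoolDesign",
    "barcode_vocabulary",
    "design_pool",
    "normalize_counts",
    "compute_activity",
    "test_alleles",
    "combine_cell_lines",
]

ADAPTER_5 = "CTAGAGTCGACCTCGAGACG"  # 20-base cloning arms; configurable constants
ADAPTER_3 = "GCGGCCGCTTAATTAAGCTT"
SPACER = "A"  # single base between insert and barcode; 20+101+1+8+20 = 150
INSERT_LEN = 101
BARCODE_LEN = 8
FLANK = 50
DEFAULT_FILLER = "CACGATCAGCTGACGTCATGACGTCAGCTGATCGTGCACGATCAGCTGAC"


@dataclass
class PoolDesign:
    manifest: pd.DataFrame  # variant_id, transcript_id, allele, barcode, insert, oligo
    filler: str

    def oligo_fasta(self) -> str:
        recs = []
        for _, r in self.manifest.iterrows():
            name = f"{r['variant_id']}|{r['transcript_id']}|{r['allele']}|{r['barcode']}"
            recs.append(f">{name}\n{r['oligo']}")
        return "\n".join(recs) + "\n"


def _has_homopolymer(seq: str, run: int = 5) -> bool:
    return any(b * run in seq for b in "ACGT")


def barcode_vocabulary(forbidden_motifs=(), max_homopolymer: int = 4) -> list[str]:
    """All 8-mers minus forbidden-motif matches and long homopolymer runs."""
    for m in forbidden_motifs:
        if not 7 <= len(m) <= 8:
            raise ValueError("forbidden motifs must be 7 or 8 bases long")
    forb7 = {m for m in forbidden_motifs if len(m) == 7}
    forb8 = {m for m in forbidden_motifs if len(m) == 8}
    vocab = []
    for tup in itertools.product("ACGT", repeat=BARCODE_LEN):
        bc = "".join(tup)
        if _has_homopolymer(bc, max_homopolymer + 1):
            continue
        if bc in forb8 or bc[:7] in forb7 or bc[1:] in forb7:
            continue
        vocab.append(bc)
    return vocab


def _build_insert(left: str, allele: str, right: str, filler: str) -> str:
    left = left[-FLANK:]
    right = right[:FLANK]
    # pad the deficient side(s) with the shared screened filler sequence
    left = filler[-(FLANK - len(left)):] + left if len(left) < FLANK else left
    insert = left + allele + right
    if len(insert) < INSERT_LEN:
        insert = insert + filler[: INSERT_LEN - len(insert)]
    return insert[:INSERT_LEN]


def design_pool(
    variants: pd.DataFrame,  # variant_id, transcript_id, ref, alt, left_flank, right_flank
    n_barcodes_per_allele: int = 10,
    forbidden_motifs=(),
    filler: str = DEFAULT_FILLER,
    seed: int | None = None,
) -> PoolDesign:
    """Design the barcoded oligo pool for a set of variants.

    One insert per (variant, transcript isoform, allele); each allele gets
    ``n_barcodes_per_allele`` barcodes sampled without replacement from the
    screened 8-mer vocabulary. Deterministic under ``seed``.
    """
    vocab = np.array(barcode_vocabulary(forbidden_motifs))
    demand = 2 * n_barcodes_per_allele * len(variants)
    if demand > vocab.size:
        raise ValueError(
            f"barcode vocabulary exhausted: need {demand}, have {vocab.size}"
        )
    rng = np.random.default_rng(seed)
    chosen = vocab[rng.choice(vocab.size, size=demand, replace=False)]
    rows = []
    i = 0
    for _, v in variants.iterrows():
        for allele_name, allele_seq in (("ref", v["ref"]), ("alt", v["alt"])):
            insert = _build_insert(v["left_flank"], allele_seq, v["right_flank"], filler)
            for _ in range(n_barcodes_per_allele):
                bc = chosen[i]
                i += 1
                rows.append(
                    {
                        "variant_id": v["variant_id"],
                        "transcript_id": v.get("transcript_id", "t1"),
                        "allele": allele_name,
                        "barcode": bc,
                        "insert": insert,
                        "oligo": ADAPTER_5 + insert + SPACER + bc + ADAPTER_3,
                    }
                )
    manifest = pd.DataFrame(rows)
    assert (manifest["oligo"].str.len() == 150).all()
    return PoolDesign(manifest=manifest, filler=filler)


def _count_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c == "DNA" or c.startswith("RNA")]


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Scale every count column to counts-per-million of its own total."""
    out = table.copy()
    for c in _count_columns(table):
        total = float(table[c].sum())
        if total <= 0:
            raise ValueError(f"column {c} has zero total count")
        out[c] = table[c] / total * 1e6
    return out


def compute_activity(
    table: pd.DataFrame,
    pseudocount: float = 1.0,
    dna_col: str = "DNA",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-barcode, per-replicate activity from a raw barcode count table.

    Activity is log((RNA_cpm + pc') / (DNA_cpm + pc')) where pc' is the raw
    pseudocount carried through each column's CPM scaling, followed by
    quantile normalization across replicate columns. With the pseudocount
    disabled, zero-DNA barcodes are excluded and reported.
    """
    if dna_col not in table.columns:
        raise ValueError(f"missing DNA column {dna_col!r}")
    rna_cols = [c for c in _count_columns(table) if c != dna_col]
    norm = normalize_counts(table)
    excluded: list[str] = []
    if pseudocount == 0:
        zero = norm[dna_col] == 0
        excluded = list(table.loc[zero, "barcode"])
        norm = norm.loc[~zero.to_numpy()]
    pc = {
        c: pseudocount * 1e6 / float(table[c].sum()) for c in [dna_col] + rna_cols
    }
    dna = norm[dna_col].to_numpy(dtype=float) + pc[dna_col]
    acts = np.column_stack(
        [np.log((norm[c].to_numpy(dtype=float) + pc[c]) / dna) for c in rna_cols]
    )
    acts = quantile_normalize(acts)
    out = pd.DataFrame(acts, columns=rna_cols, index=norm.index)
    out.insert(0, "barcode", norm["barcode"].to_numpy())
    return out, excluded


def test_alleles(
    activities: pd.DataFrame,
    design: pd.DataFrame,  # manifest with variant_id, allele, barcode
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variant combined allelic-effect statistic for one cell line.

    Per replicate, a two-sided rank-sum test compares alternative- vs
    reference-allele barcode activities (exact tie-free enumeration for
    small groups, normal approximation with tie correction otherwise).
    Replicates are combined with Stouffer's method on direction-signed
    z-scores; BH runs across variants. Per-allele activity is the median
    over the allele's barcode-replicate values; fold change is reported in
    linear space (alt over ref) with a log2 convenience column.
    """
    rep_cols = [c for c in activities.columns if c != "barcode"]
    merged = activities.merge(
        design[["variant_id", "allele", "barcode"]].drop_duplicates("barcode"),
        on="barcode",
        how="inner",
    ).sort_values(["variant_id", "allele"], kind="stable")
    acts = merged[rep_cols].to_numpy(dtype=float)
    is_alt = merged["allele"].to_numpy() == "alt"
    vids, starts = np.unique(merged["variant_id"].to_numpy(), return_index=True)
    bounds = np.append(starts, len(merged))
    rows = []
    for g, vid in enumerate(vids):
        sl = slice(bounds[g], bounds[g + 1])
        a_mask = is_alt[sl]
        alt_acts = acts[sl][a_mask]
        ref_acts = acts[sl][~a_mask]
        row: dict = {"variant_id": vid}
        if len(ref_acts) < 2 or len(alt_acts) < 2:
            row.update({"p_combined": np.nan, "z_combined": np.nan,
                        "untestable": True})
            rows.append(row)
            continue
        zs = []
        for i in range(len(rep_cols)):
            p, direction = wilcoxon_two_sided(alt_acts[:, i], ref_acts[:, i])
            if direction == 0:
                # orient by mean shift when medians tie exactly
                direction = float(np.sign(alt_acts[:, i].mean()
                                          - ref_acts[:, i].mean())) or 1.0
            z = direction * stats.norm.isf(min(p / 2.0, 1.0 - 1e-16))
            zs.append(z)
            row[f"p_rep{i + 1}"] = p
        z_comb, p_comb = stouffer_combine(zs)
        med_ref = float(np.exp(np.median(ref_acts)))
        med_alt = float(np.exp(np.median(alt_acts)))
        row.update(
            {
                "z_combined": z_comb,
                "p_combined": p_comb,
                "median_ref_activity": med_ref,
                "median_alt_activity": med_alt,
                "fold_change": med_alt / med_ref,
                "untestable": False,
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["log2_fold_change"] = np.log2(out.get("fold_change", np.nan))
    ok = ~out["untestable"]
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p_combined"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def combine_cell_lines(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-cell-line results; significant means adjusted p < 0.05 in >= 1."""
    frames = []
    for line, df in results.items():
        d = df.copy()
        d["cell_line"] = line
        frames.append(d)
    allr = pd.concat(frames, ignore_index=True)
    sig = allr.groupby("variant_id")["significant"].any().rename("significant_any")
    return allr.merge(sig, on="variant_id")
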