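"""Responder-enriched variant signature and polygenic risk score for ICI response.

The cohort (responders R vs non-responders NR) is split into stratified
train/test halves. On the training half, each candidate variant's carriage is
tested for enrichment in responders by a one-sided Fisher exact test, BH
corrected across candidates; survivors are ranked by odds ratio (with the
Haldane-Anscombe 0.5 correction for zero cells), optionally deduplicated to
one variant per gene, and truncated at a cap. A patient's score is simply the
number of signature variants detected in their tumor, so it ranges from 0 to
the signature size. Evaluation on the untouched test half reports a rank-sum
comparison of scores between R and NR plus ROC curves and trapezoidal AUCs
for the score, a PD-L1-expression baseline, and an OLS-combined model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from ._stats import bh_adjust

__all__ = [
    "Signature",
    "PRSResult",
    "split_cohort",
    "select_signature",
    "score_prs",
    "roc_auc",
    "evaluate",
]


@dataclass
class Signature:
    """Selected variant set with training-set statistics and split metadata."""

    table: pd.DataFrame  # variant_id, gene_id, odds_ratio, p, q
    train_patients: frozenset[str]
    seed: int | None
    q_threshold: float
    one_per_gene: bool
    cap: int

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PRSResult:
    scores: pd.Series  # per test patient
    ranksum_p: float
    roc: dict[str, pd.DataFrame] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)


def split_cohort(
    cohort: pd.DataFrame, train_fraction: float = 0.5, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition stratified by response label."""
    if len(cohort) < 4:
        raise ValueError("cohort too small to split")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for label, grp in cohort.groupby("response"):
        if len(grp) < 2:
            raise ValueError(f"degenerate stratum for label {label!r}")
        n_train = int(round(train_fraction * len(grp)))
        n_train = min(max(n_train, 1), len(grp) - 1)
        picked = rng.choice(len(grp), size=n_train, replace=False)
        train_idx.extend(grp.index[picked])
    train = cohort.loc[sorted(train_idx)]
    test = cohort.drop(index=train_idx).sort_index()
    return train, test


def _carrier_table(split: pd.DataFrame, variant_id: str) -> tuple[int, int, int, int]:
    """(carrier_R, carrier_NR, noncarrier_R, noncarrier_NR) counts."""
    carries = split["variants"].map(lambda s: variant_id in s)
    resp = split["response"].to_numpy() == "R"
    a = int((carries & resp).sum())
    b = int((carries & ~resp).sum())
    c = int((~carries & resp).sum())
    d = int((~carries & ~resp).sum())
    return a, b, c, d


def select_signature(
    train: pd.DataFrame,
    candidate_variants: set[str],
    q_threshold: float = 0.05,
    one_per_gene: bool = False,
    gene_of: dict[str, str] | None = None,
    cap: int = 28,
    seed: int | None = None,
) -> Signature:
    """Training-set selection of responder-enriched variants.

    One-sided Fisher p (enrichment of carriage among responders), BH q
    across candidates, survivors at q < threshold ranked by Haldane-Anscombe
    odds ratio (ties: smaller p, then lexicographic id), optional
    one-per-gene deduplication, truncation at ``cap``.
    """
    if not candidate_variants:
        raise ValueError("candidate set is empty")
    rows = []
    for vid in sorted(candidate_variants):
        a, b, c, d = _carrier_table(train, vid)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append({"variant_id": vid, "carrier_R": a, "carrier_NR": b,
                     "odds_ratio": orr, "p": float(p)})
    tab = pd.DataFrame(rows)
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    keep = tab[tab["q"] < q_threshold].copy()
    keep = keep.sort_values(
        ["odds_ratio", "p", "variant_id"], ascending=[False, True, True]
    )
    if one_per_gene and gene_of:
        keep["gene_id"] = keep["variant_id"].map(gene_of)
        keep = keep.drop_duplicates(subset="gene_id", keep="first")
    keep = keep.head(cap).reset_index(drop=True)
    return Signature(
        table=keep,
        train_patients=frozenset(train["patient_id"]),
        seed=seed,
        q_threshold=q_threshold,
        one_per_gene=one_per_gene,
        cap=cap,
    )


def score_prs(signature: Signature, patient_variants) -> int:
    """Number of signature variants detected in the patient's tumor."""
    return len(set(signature.variant_ids) & set(patient_variants))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Empirical ROC points and trapezoidal AUC (ties -> midpoint steps)."""
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def evaluate(
    test: pd.DataFrame,
    signature: Signature,
    pdl1_col: str = "pdl1",
    train: pd.DataFrame | None = None,
    logistic: bool = False,
) -> PRSResult:
    """Score the test split and compare the PRS with the PD-L1 baseline.

    Refuses a test set that shares patients with the signature's training
    split. When the training split is supplied, a combined model (response ~
    PRS + PD-L1, least squares on the 0/1 label, or logistic behind the
    flag) is fitted on it and its linear predictor evaluated on the test set.
    """
    shared = set(test["patient_id"]) & signature.train_patients
    if shared:
        raise ValueError(f"test split shares {len(shared)} patients with training")
    labels = (test["response"] == "R").to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("test split must contain both responders and non-responders")
    scores = test["variants"].map(lambda s: score_prs(signature, s)).astype(int)
    scores.index = test["patient_id"].to_numpy()
    r = scores.to_numpy()[labels]
    nr = scores.to_numpy()[~labels]
    ranksum_p = float(
        stats.mannwhitneyu(r, nr, alternative="two-sided").pvalue
    )
    result = PRSResult(scores=scores, ranksum_p=ranksum_p)
    roc, auc = roc_auc(labels, scores.to_numpy())
    result.roc["prs"], result.auc["prs"] = roc, auc
    pdl1 = test[pdl1_col].to_numpy(dtype=float)
    roc, auc = roc_auc(labels, pdl1)
    result.roc["pdl1"], result.auc["pdl1"] = roc, auc
    if train is not None:
        x_tr = np.column_stack(
            [
                np.ones(len(train)),
                train["variants"].map(lambda s: score_prs(signature, s)).to_numpy(float),
                train[pdl1_col].to_numpy(dtype=float),
            ]
        )
        y_tr = (train["response"] == "R").to_numpy(dtype=float)
        if logistic:
            from sklearn.linear_model import LogisticRegression

            model = LogisticRegression(penalty=None).fit(x_tr[:, 1:], y_tr)
            coef = np.concatenate([[model.intercept_[0]], model.coef_[0]])
        else:
            coef, *_ = np.linalg.lstsq(x_tr, y_tr, rcond=None)
        x_te = np.column_stack([np.ones(len(test)), scores.to_numpy(float), pdl1])
        pred = x_te @ coef
        roc, auc = roc_auc(labels, pred)
        result.roc["combined"], result.auc["combined"] = roc, auc
    return result
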