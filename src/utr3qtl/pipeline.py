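"""End-to-end orchestration of the synthetic-cohort analysis chain.

Stages run in dependency order — synth, variants, qtl, enrichment, mpra,
prs, report — against a single YAML-configurable PipelineConfig with one
global seed; per-stage seeds are derived from it, so an identical config and
seed reproduce byte-identical result files. A run manifest records, per
stage, the files written with their SHA-256 checksums, the parameter
snapshot and wall time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_enrichment as ann
from . import mpra as mpra_mod
from . import prs_ici, qtl_engine, synthdata
from . import variant_pipeline as vp

__all__ = ["PipelineConfig", "PipelineError", "demo_config", "run_pipeline", "report"]

STAGES = ("synth", "variants", "qtl", "enrichment", "mpra", "prs", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    carrier_min: int = 5
    q_threshold: float = 0.05
    n_perm: int = 5000
    n_genetic_pcs: int = 5
    n_surrogate_variables: int = 5
    barcodes_per_allele: int = 10
    signature_cap: int = 28
    mpra_top_n: int = 40
    mpra_cell_lines: tuple[str, ...] = ("AGS", "SNU719")
    write_inputs: bool = False
    sim: synthdata.SimulationConfig = field(default_factory=synthdata.SimulationConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise PipelineError("stages must respect dependency order")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", {})
        sim_known = {f.name for f in dataclasses.fields(synthdata.SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise PipelineError(f"unknown sim config keys: {sorted(sim_unknown)}")
        for key in ("maf_range", "somatic_carrier_range", "ici_carriage_range",
                    "region_weights"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        for key in ("planted_eqtl_effects", "planted_ilqtl_effects",
                    "mpra_planted_log2fc", "ici_enriched_variants"):
            if key in sim_raw:
                sim_raw[key] = [tuple(x) for x in sim_raw[key]]
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "mpra_cell_lines" in raw:
            raw["mpra_cell_lines"] = tuple(raw["mpra_cell_lines"])
        cfg = cls(sim=synthdata.SimulationConfig(**sim_raw), **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["mpra_cell_lines"] = list(self.mpra_cell_lines)
        sim = d["sim"]
        for k, v in list(sim.items()):
            if isinstance(v, tuple):
                sim[k] = list(v)
            if isinstance(v, list):
                sim[k] = [list(x) if isinstance(x, tuple) else x for x in v]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def demo_config(out_dir: str | Path, seed: int = 0, small: bool = False) -> PipelineConfig:
    """The synthetic end-to-end demo: cohort sizes mirror the emulated study.

    ``small=True`` scales every dimension down for quick runs and tests.
    """
    if small:
        n_eqtl, n_ilqtl, n_mpra, n_ici = 8, 2, 5, 10
        sim = synthdata.SimulationConfig(
            n_tumors=80, n_normals=10, n_genes=60, n_variants=200, seed=seed
        )
        extra = {"n_perm": 300, "mpra_top_n": 10, "signature_cap": 10}
    else:
        n_eqtl, n_ilqtl, n_mpra, n_ici = 50, 5, 20, 28
        sim = synthdata.SimulationConfig(seed=seed)
        extra = {"n_perm": 2000}
    eqtl = [(f"v{i:05d}", f"g{i:04d}", 0.5) for i in range(n_eqtl)]
    ilqtl = [
        (f"v{n_eqtl + i:05d}", "CD8_T_fraction", 0.6) for i in range(n_ilqtl)
    ]
    mpra_fx = [(f"v{i:05d}", 1.0) for i in range(n_mpra)]
    ici = [(f"v{n_eqtl + n_ilqtl + i:05d}", 6.0) for i in range(n_ici)]
    sim = sim.replace(
        planted_eqtl_effects=eqtl,
        planted_ilqtl_effects=ilqtl,
        mpra_planted_log2fc=mpra_fx,
        ici_enriched_variants=ici,
    )
    return PipelineConfig(out_dir=str(out_dir), seed=seed, sim=sim, **extra)


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k * 7919 + 1) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    tmp.replace(path)


class _Run:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"seed": config.seed, "stages": {}}
        self.state: dict = {}

    def record(self, stage: str, files: list[Path], params: dict, t0: float) -> None:
        self.manifest["stages"][stage] = {
            "files": {str(f.relative_to(self.out)): _sha256(f) for f in sorted(files)},
            "params": params,
            "seed": params.get("seed"),
            "duration_s": round(time.time() - t0, 3),
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the run manifest (also on disk)."""
    config.validate()
    run = _Run(config)
    handlers = {
        "synth": _stage_synth,
        "variants": _stage_variants,
        "qtl": _stage_qtl,
        "enrichment": _stage_enrichment,
        "mpra": _stage_mpra,
        "prs": _stage_prs,
        "report": _stage_report,
    }
    for stage in config.stages:
        t0 = time.time()
        try:
            files, params = handlers[stage](run)
        except PipelineError:
            raise
        except Exception as exc:  # halt naming the stage
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        run.record(stage, files, params, t0)
        _write_json(run.out / "manifest.json", run.manifest)
    return run.manifest


# ---------------------------------------------------------------------------
# stages


def _stage_synth(run: _Run):
    cfg = run.config
    seed = _derive_seed(cfg.seed, 0)
    cohort = synthdata.generate_cohort(cfg.sim.replace(seed=seed))
    run.state["cohort"] = cohort
    files: list[Path] = []
    if cfg.write_inputs:
        synthdata.write_cohort(cohort, run.out / "inputs")
        files = sorted((run.out / "inputs").rglob("*.tsv"))
    return files, {"seed": seed, "n_tumors": cfg.sim.n_tumors,
                   "n_variants": cfg.sim.n_variants, "n_genes": cfg.sim.n_genes}


def _stage_variants(run: _Run):
    cfg = run.config
    cohort = run.state["cohort"]
    matrix = vp.merge_caller_calls(cohort.tumor_calls, cohort.genotyper_calls)
    filtered, flog = vp.apply_filters(
        matrix, cohort.tumor_calls, min_carriers=cfg.carrier_min
    )
    pon = vp.build_pon(cohort.normal_calls)
    vaf = vp.mean_carrier_vaf(cohort.tumor_calls)
    editing = set(zip(cohort.editing_sites["chrom"], cohort.editing_sites["pos"]))
    posteriors = vp.classify_origin(
        filtered, cohort.blood_sets, pon, cohort.pop_af, editing, vaf
    )
    summary = vp.summarize_landscape(posteriors)
    run.state.update(matrix=filtered, posteriors=posteriors, filter_log=flog)
    f1 = run.out / "posteriors.tsv"
    posteriors.to_csv(f1, sep="\t")
    f2 = run.out / "variant_summary.json"
    _write_json(f2, dataclasses.asdict(summary))
    f3 = run.out / "filter_log.json"
    _write_json(f3, flog)
    return [f1, f2, f3], {"carrier_min": cfg.carrier_min,
                          "n_post_filter": summary.total}


def _stage_qtl(run: _Run):
    cfg = run.config
    cohort = run.state["cohort"]
    matrix: vp.GenotypeMatrix = run.state["matrix"]
    posteriors = run.state["posteriors"]

    counts = qtl_engine.filter_genes(cohort.counts)
    _factors, cpm = qtl_engine.tmm_normalize(counts)
    expr_int = pd.DataFrame(
        {g: qtl_engine.inverse_normal_transform(cpm.loc[g].to_numpy())
         for g in cpm.index},
        index=cpm.columns,
    )
    germ_keys = posteriors.index[posteriors["label"] == "germline"]
    germ = matrix.dosage.loc[matrix.dosage.index.intersection(germ_keys)]
    k_pc = min(cfg.n_genetic_pcs, max(1, len(germ) - 1))
    gpcs = qtl_engine.compute_genetic_pcs(germ, k=k_pc)
    covs = pd.concat([cohort.covariates, gpcs], axis=1)
    svs = qtl_engine.estimate_surrogate_variables(
        np.log2(cpm + 1.0), covs, k=cfg.n_surrogate_variables
    )
    covs = pd.concat([covs, svs], axis=1)
    egenes, eqtl_res, horizontal = qtl_engine.run_eqtl(
        matrix, expr_int, covs, cohort.transcripts, q_threshold=cfg.q_threshold
    )
    ilqtl_res, skipped = qtl_engine.run_ilqtl(
        matrix, cohort.immune, covs, q_threshold=cfg.q_threshold
    )
    run.state.update(eqtl=eqtl_res, egenes=egenes, ilqtl=ilqtl_res,
                     covariates=covs, horizontal=horizontal)
    f1 = run.out / "eqtl_results.tsv"
    eqtl_res.to_csv(f1, sep="\t", index=False)
    f2 = run.out / "egenes.tsv"
    egenes.to_csv(f2, sep="\t", index=False)
    f3 = run.out / "ilqtl_results.tsv"
    ilqtl_res.to_csv(f3, sep="\t", index=False)
    return [f1, f2, f3], {
        "horizontal_threshold": None if np.isnan(horizontal) else horizontal,
        "n_egenes": int(egenes["egene"].sum()),
        "n_significant_eqtl": int(eqtl_res["significant"].sum()),
        "n_significant_ilqtl": int(ilqtl_res["significant"].sum()),
        "skipped_features": skipped,
    }


def _stage_enrichment(run: _Run):
    cfg = run.config
    cohort = run.state["cohort"]
    eqtl = run.state["eqtl"]
    seed = _derive_seed(cfg.seed, 4)

    sig = eqtl[eqtl["significant"]]
    parts = sig["key"].str.split(":", expand=True)
    if len(sig):
        var = pd.DataFrame({"chrom": parts[0], "pos": parts[1].astype(int)})
    else:
        var = pd.DataFrame(columns=["chrom", "pos"])
    models = ann.models_from_frame(cohort.transcripts)
    assigned = ann.assign_genic_region(var, models) if len(var) else var.assign(region=[])
    region_counts = {r: int((assigned["region"] == r).sum())
                     for r in ("5'UTR", "CDS", "3'UTR")}
    tx = cohort.transcripts
    lengths = {
        "5'UTR": float((tx["utr5_end"] - tx["utr5_start"]).sum()),
        "CDS": float((tx["cds_end"] - tx["cds_start"]).sum()),
        "3'UTR": float((tx["utr3_end"] - tx["utr3_start"]).sum()),
    }
    total_len = sum(lengths.values())
    fractions = {r: v / total_len for r, v in lengths.items()}
    if sum(region_counts.values()) > 0:
        chi2, chi_p = ann.chi_square_length_enrichment(region_counts, fractions)
    else:
        chi2, chi_p = float("nan"), float("nan")

    # 50-bp window sampling space over all 3'-UTRs (walking step configurable)
    window = 50
    starts, chroms = [], []
    for _, t in tx.iterrows():
        s, e = int(t["utr3_start"]), int(t["utr3_end"])
        if e - s >= window:
            starts.append(np.arange(s, e - window + 1))
            chroms.append(t["chrom"])
    starts_arr = np.concatenate(starts) if starts else np.array([], dtype=int)
    sites = synthdata.generate_binding_sites(tx, seed=_derive_seed(cfg.seed, 5))
    hits = np.zeros(starts_arr.size, dtype=bool)
    for _, f in sites.iterrows():
        lo = np.searchsorted(starts_arr, f["start"] - window + 1, side="left")
        hi = np.searchsorted(starts_arr, f["end"], side="left")
        hits[lo:hi] = True
    utr3_pos = assigned.loc[assigned.get("region", pd.Series(dtype=str)) == "3'UTR", "pos"]
    query = []
    for pos in utr3_pos:
        p0 = int(pos) - 1
        i = int(np.searchsorted(starts_arr, p0, side="right")) - 1
        if i >= 0 and starts_arr[i] <= p0 < starts_arr[i] + window:
            query.append(i)
    perm = None
    if query and starts_arr.size:
        perm = ann.permutation_enrichment(
            np.array(query), hits, n_perm=cfg.n_perm, seed=seed
        )
    out = {
        "region_counts": region_counts,
        "expected_fractions": fractions,
        "chi2": chi2,
        "chi2_p": chi_p,
        "permutation": dataclasses.asdict(perm) if perm else None,
    }
    f1 = run.out / "enrichment.json"
    _write_json(f1, out)
    run.state["enrichment"] = out
    return [f1], {"seed": seed, "n_windows": int(starts_arr.size),
                  "n_query": len(query)}


def _stage_mpra(run: _Run):
    cfg = run.config
    cohort = run.state["cohort"]
    eqtl = run.state["eqtl"]
    seed = _derive_seed(cfg.seed, 6)

    ranked = eqtl.sort_values(["significant", "p"], ascending=[False, True])
    keys = ranked["key"].drop_duplicates().head(cfg.mpra_top_n)
    truth = cohort.truth.variants.set_index("key")
    rows = []
    for key in keys:
        if key not in truth.index:
            continue
        t = truth.loc[key]
        chrom, pos = t["chrom"], int(t["pos"])
        p0 = pos - 1
        seq = cohort.genome[chrom]
        rows.append(
            {
                "variant_id": t["variant_id"],
                "transcript_id": f"{t['gene_id']}.t1",
                "ref": t["ref"],
                "alt": t["alt"],
                "left_flank": seq[max(0, p0 - 50):p0],
                "right_flank": seq[p0 + 1:p0 + 51],
            }
        )
    if not rows:
        _write_json(run.out / "mpra_results.json", {"note": "no variants selected"})
        return [run.out / "mpra_results.json"], {"seed": seed, "n_variants": 0}
    pool = mpra_mod.design_pool(
        pd.DataFrame(rows), n_barcodes_per_allele=cfg.barcodes_per_allele, seed=seed
    )
    per_line = {}
    for i, line in enumerate(cfg.mpra_cell_lines):
        counts = synthdata.generate_mpra_counts(
            pool.manifest, cfg.sim, seed=_derive_seed(cfg.seed, 7 + i)
        )
        acts, _dropped = mpra_mod.compute_activity(counts)
        per_line[line] = mpra_mod.test_alleles(acts, pool.manifest)
    results = mpra_mod.combine_cell_lines(per_line)
    run.state["mpra"] = results
    f1 = run.out / "mpra_results.tsv"
    results.to_csv(f1, sep="\t", index=False)
    f2 = run.out / "mpra_manifest.tsv"
    pool.manifest.to_csv(f2, sep="\t", index=False)
    return [f1, f2], {"seed": seed, "n_variants": len(rows),
                      "n_significant": int(
                          results.groupby("variant_id")["significant_any"].first().sum())}


def _stage_prs(run: _Run):
    cfg = run.config
    seed = _derive_seed(cfg.seed, 9)
    ici, truth = synthdata.generate_ici_cohort(cfg.sim, seed=seed)
    train, test = prs_ici.split_cohort(ici, seed=_derive_seed(cfg.seed, 10))
    candidates = set(truth.variants["variant_id"])
    signature = prs_ici.select_signature(
        train, candidates, q_threshold=cfg.q_threshold, cap=cfg.signature_cap,
        seed=_derive_seed(cfg.seed, 10),
    )
    result = prs_ici.evaluate(test, signature, train=train)
    run.state["prs"] = result
    f1 = run.out / "prs_signature.tsv"
    signature.table.to_csv(f1, sep="\t", index=False)
    f2 = run.out / "prs_scores.tsv"
    result.scores.rename_axis("patient_id").rename("prs").to_csv(f2, sep="\t")
    f3 = run.out / "prs_eval.json"
    _write_json(f3, {"ranksum_p": result.ranksum_p, "auc": result.auc,
                     "signature_size": len(signature)})
    files = [f1, f2, f3]
    for name, roc in result.roc.items():
        f = run.out / f"roc_{name}.tsv"
        roc.to_csv(f, sep="\t", index=False)
        files.append(f)
    return files, {"seed": seed, "signature_size": len(signature),
                   "auc": result.auc}


def _stage_report(run: _Run):
    f = run.out / "report.txt"
    f.write_text(report(run.out))
    return [f], {}


def report(out_dir: str | Path) -> str:
    """Deterministic text summary regenerated from the result files."""
    out = Path(out_dir)
    lines = ["3'-UTR variant pipeline report", "=" * 31, ""]

    def load(name):
        p = out / name
        return json.loads(p.read_text()) if p.exists() else None

    summary = load("variant_summary.json")
    if summary:
        lines += [
            "Variant landscape:",
            f"  total post-filter: {summary['total']}",
            f"  germline overlap: {summary['germline']} ({summary['germline_pct']}%)",
            f"  likely somatic:   {summary['somatic']} ({summary['somatic_pct']}%)",
            f"  editing overlap:  {summary['editing_overlap']} "
            f"({summary['editing_pct_of_somatic']}% of somatic)",
            "",
        ]
    egenes_p = out / "egenes.tsv"
    if egenes_p.exists():
        eg = pd.read_csv(egenes_p, sep="\t")
        lines += [
            "cis-eQTL:",
            f"  genes tested: {len(eg)}; eGenes: {int(eg['egene'].sum())}",
            "",
        ]
    ilqtl_p = out / "ilqtl_results.tsv"
    if ilqtl_p.exists():
        il = pd.read_csv(ilqtl_p, sep="\t")
        lines += [
            "ilQTL:",
            f"  tests: {len(il)}; significant: {int(il['significant'].sum())}",
            "",
        ]
    enr = load("enrichment.json")
    if enr:
        lines += [
            "Enrichment:",
            f"  region counts: {enr['region_counts']}",
            f"  chi-square vs length fractions: {enr['chi2']:.3f} (p={enr['chi2_p']:.3g})",
            "",
        ]
    mpra_p = out / "mpra_results.tsv"
    if mpra_p.exists():
        mr = pd.read_csv(mpra_p, sep="\t")
        n_var = mr["variant_id"].nunique()
        n_sig = int(mr.groupby("variant_id")["significant_any"].first().sum())
        lines += ["MPRA:", f"  variants tested: {n_var}; significant: {n_sig}", ""]
    prs = load("prs_eval.json")
    if prs:
        auc = prs["auc"]
        lines += [
            "ICI PRS:",
            f"  signature size: {prs['signature_size']}",
            f"  test rank-sum p (R vs NR): {prs['ranksum_p']:.3g}",
            "  AUC: " + ", ".join(f"{k}={v:.3f}" for k, v in sorted(auc.items())),
            "",
        ]
    if len(lines) == 3:
        lines.append("(no results found)")
    return "\n".join(lines) + "\n"
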