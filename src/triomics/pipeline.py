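"""Config-driven end-to-end runs.

Stage order mirrors the analysis it automates: QC -> parental/hybrid
differential calls -> F1-vs-mid-parent calls -> 12-type inheritance
classification -> mid-parent heterosis -> co-expression network ->
enrichment.  Every stage writes plain TSV outputs into the run directory
and records its parameters and output hashes in ``manifest.json``; the
manifest contains no timestamps or absolute paths, so re-running with the
same inputs, parameters and seed reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coexpression as cx
from . import enrichment as en
from . import heterosis as ht
from . import inheritance as ih
from . import qc as qcmod
from .core import (
    DEFAULT_CROSSES,
    ThresholdConfig,
    TriomicsError,
    build_trio,
    cpm_normalize,
    filter_low_expression,
    read_matrix,
    read_sample_sheet,
    write_matrix,
    write_sample_sheet,
)
from .simulate import (
    MODE_CATEGORY,
    SimulationDesign,
    expected_category,
    simulate_biomass,
    simulate_trio_counts,
)

log = logging.getLogger("triomics")


@dataclass
class PipelineConfig:
    outdir: str = "triomics_run"
    seed: int = 0
    counts: str | None = None          # TSV path; None -> simulate
    sample_sheet: str | None = None
    annotation: str | None = None      # GMT path; None -> synthesize from the run
    biomass: str | None = None         # TSV path; None -> simulate
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    network: cx.NetworkConfig = field(default_factory=cx.NetworkConfig)
    design: SimulationDesign = field(default_factory=SimulationDesign)
    enrich: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key, val in raw.items():
            if key == "thresholds":
                kwargs[key] = ThresholdConfig(**val)
            elif key == "network":
                kwargs[key] = cx.NetworkConfig(**val)
            elif key == "design":
                if "conditions" in val:
                    val["conditions"] = tuple(val["conditions"])
                if "module_spec" in val:
                    val["module_spec"] = tuple(tuple(m) for m in val["module_spec"])
                kwargs[key] = SimulationDesign(**val)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = val
            else:
                raise TriomicsError(f"unknown config key {key!r}")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "params": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"stages": self.stages}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _synthetic_annotation(truth: pd.DataFrame, seed: int, n_terms: int = 25) -> en.Annotation:
    """Annotation synthesized from the simulated gene universe for enrichment demos.

    Random terms plus one term per planted non-additive mode (so enrichment
    of the non-additive call set has true signal to find).
    """
    rng = np.random.default_rng(seed + 17)
    genes = list(truth.index)
    terms: dict[str, tuple[str, frozenset]] = {}
    for i in range(n_terms):
        size = int(rng.integers(15, max(16, len(genes) // 10)))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        terms[f"TERM:{i+1:04d}"] = (f"random term {i+1}", frozenset(members))
    for mode in ("ELD_F", "ELD_M", "over_high", "over_low"):
        members = truth.index[truth["mode"] == mode]
        if len(members):
            sub = rng.choice(members, size=max(2, len(members) // 2), replace=False)
            terms[f"MODE:{mode}"] = (f"planted {mode} genes", frozenset(sub))
    return en.Annotation(terms=terms, universe=frozenset(genes))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written as report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    manifest = Manifest(outdir)
    cfg = config.thresholds
    report: dict[str, Any] = {"seed": config.seed}

    # -- stage: input (simulate or load) -----------------------------------
    truth = None
    if config.counts is None:
        log.info("simulating trio counts (seed=%d)", config.seed)
        design = SimulationDesign(**{**asdict(config.design), "seed": config.seed})
        counts, sheet, truth = simulate_trio_counts(design)
        cpath, spath, tpath = (outdir / "counts.tsv", outdir / "samples.tsv",
                               outdir / "truth.tsv")
        write_matrix(counts, cpath)
        write_sample_sheet(sheet, spath)
        truth.to_csv(tpath, sep="\t")
        manifest.record("simulate", _jsonable(design), [cpath, spath, tpath])
    else:
        if config.sample_sheet is None:
            raise TriomicsError("config needs 'sample_sheet' when 'counts' is given")
        counts = read_matrix(config.counts, "counts")
        sheet = read_sample_sheet(config.sample_sheet)
        manifest.record("load", {"counts": config.counts,
                                 "sample_sheet": config.sample_sheet}, [])

    # -- stage: filter + normalize -----------------------------------------
    filtered = filter_low_expression(counts, cfg, min_samples=sheet.min_group_size())
    norm = cpm_normalize(filtered)
    npath = outdir / "cpm.tsv"
    write_matrix(norm, npath)
    manifest.record("normalize", {"cpm_min": cfg.cpm_min,
                                  "kept_genes": filtered.shape[0]}, [npath])
    report["genes_after_filter"] = filtered.shape[0]

    # -- stage: qc ----------------------------------------------------------
    cors = qcmod.replicate_correlation(norm, sheet)
    qdf = pd.DataFrame(
        [(c.group, c.mean_r, c.mean_r2) for c in cors],
        columns=["group", "mean_r", "mean_r2"],
    )
    qpath = outdir / "qc_replicate_correlation.tsv"
    qdf.to_csv(qpath, sep="\t", index=False)
    pca = qcmod.pca_samples(norm, n_components=2)
    ppath = outdir / "qc_pca_scores.tsv"
    pca.scores.assign(variance_fraction_pc1=pca.variance_fraction[0]).to_csv(
        ppath, sep="\t"
    )
    manifest.record("qc", {"log": True}, [qpath, ppath])
    report["mean_replicate_r"] = float(qdf["mean_r"].mean())

    # -- stages: classification + F1-vs-MPV per cross x condition ----------
    crosses = {c: DEFAULT_CROSSES[c] for c in DEFAULT_CROSSES}
    class_tables, mpv_tables = [], []
    category_counts: dict[str, dict[str, int]] = {}
    for cross in crosses:
        for cond in sheet.conditions:
            trio = build_trio(sheet, cross, cond, crosses)
            cls = ih.classify_trio(filtered, trio, cfg)
            cls.insert(0, "condition", cond)
            cls.insert(0, "cross", cross)
            class_tables.append(cls)
            counts_cat = ih.categorize(cls)["category"]
            category_counts[f"{cross}|{cond}"] = counts_cat
            res = ih.f1_vs_mpv(norm, trio, cfg)
            res.insert(0, "condition", cond)
            res.insert(0, "cross", cross)
            mpv_tables.append(res)
    cls_all = pd.concat(class_tables, ignore_index=True)
    clpath = outdir / "inheritance.tsv"
    cls_all.to_csv(clpath, sep="\t", index=False)
    mpv_all = pd.concat(mpv_tables, ignore_index=True)
    mpath = outdir / "f1_vs_mpv.tsv"
    mpv_all.to_csv(mpath, sep="\t", index=False)
    manifest.record(
        "classify",
        {"fc_cut": cfg.fc_cut, "fdr_genes": cfg.fdr_genes},
        [clpath, mpath],
    )
    report["category_counts"] = category_counts

    deg = mpv_all.loc[mpv_all["call"] != "ns"]
    n_up = int((deg["call"] == "up").sum())
    n_down = int((deg["call"] == "down").sum())
    report["f1_mpv_degs"] = {"up": n_up, "down": n_down}
    if n_up + n_down:
        chi2, p = ih.updown_asymmetry(n_up, n_down)
        report["updown_chi2"] = {"chi2": chi2, "p": p}

    if truth is not None:
        # recovery of planted modes, pooled over crosses and conditions; the
        # expected category is cross-aware (ELD labels mirror in the reciprocal)
        merged = cls_all.merge(
            truth["mode"].rename("true_mode"), left_on="feature_id", right_index=True
        )
        merged["expected"] = [
            expected_category(mo, crosses[cr][0])
            for mo, cr in zip(merged["true_mode"], merged["cross"])
        ]
        rec = {}
        for mode in MODE_CATEGORY:
            sub = merged.loc[merged["true_mode"] == mode]
            if len(sub):
                rec[mode] = float((sub["category"] == sub["expected"]).mean())
        report["mode_recovery"] = rec

    # -- stage: MPH ---------------------------------------------------------
    if config.biomass is None:
        targets = {c: {cond: 55.0 for cond in sheet.conditions} for c in crosses}
        biomass = simulate_biomass(targets, noise_cv=0.05, reps=6, seed=config.seed)
        manifest_params = {"simulated": True, "target_mph": 55.0}
    else:
        biomass = pd.read_csv(config.biomass, sep="\t")
        manifest_params = {"simulated": False, "path": config.biomass}
    bm = ht.biomass_mph(biomass, crosses)
    bpath = outdir / "biomass_mph.tsv"
    bm.to_csv(bpath, sep="\t", index=False)
    manifest.record("mph", manifest_params, [bpath])
    report["biomass_mph_mean"] = float(bm["mph"].mean())

    # -- stage: co-expression network on F1-vs-MPV DEGs ---------------------
    deg_ids = sorted(set(deg["feature_id"]))
    report["n_f1_mpv_degs"] = len(deg_ids)
    if len(deg_ids) >= 2 * config.network.min_module_size:
        expr = np.log2(norm.subset_features(deg_ids).values + 1.0)
        expr = pd.DataFrame(expr, index=deg_ids, columns=norm.sample_ids)
        adj = cx.soft_adjacency(expr, config.network)
        tom = cx.tom_similarity(adj)
        modules = cx.cut_modules(1.0 - tom, config.network, expr=expr.loc[tom.index])
        lpath = outdir / "modules.tsv"
        modules.labels.rename("module").to_csv(lpath, sep="\t", header=True)
        outputs = [lpath]
        if len(modules.eigengenes):
            epath = outdir / "eigengenes.tsv"
            modules.eigengenes.to_csv(epath, sep="\t")
            is_hybrid = sheet.table.set_index("sample_id")["role"].loc[
                modules.eigengenes.columns
            ].eq("hybrid").astype(int)
            mt = cx.module_trait_correlation(modules.eigengenes, is_hybrid.to_numpy())
            mtpath = outdir / "module_trait.tsv"
            mt.to_csv(mtpath, sep="\t", index=False)
            outputs += [epath, mtpath]
            report["n_modules"] = int(len(modules.eigengenes))
        manifest.record("network", _jsonable(config.network), outputs)
    else:
        log.info("too few F1-MPV DEGs (%d) for a network; stage skipped", len(deg_ids))
        manifest.record("network", {"skipped": True, "n_degs": len(deg_ids)}, [])

    # -- stage: enrichment ---------------------------------------------------
    if config.enrich:
        if config.annotation is not None:
            annot = en.read_gmt(config.annotation, universe=filtered.feature_ids)
        elif truth is not None:
            annot = _synthetic_annotation(truth, config.seed)
            gpath = outdir / "annotation.gmt"
            en.write_gmt(annot, gpath)
        else:
            raise TriomicsError("config needs 'annotation' for enrichment on real data")
        if deg_ids:
            res = en.hypergeom_enrich(deg_ids, annot)
            res = res.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
            epath = outdir / "enrichment.tsv"
            res.to_csv(epath, sep="\t", index=False)
            sig = en.filter_enrichment(res, cfg.go_p)
            manifest.record("enrich", {"p_cut": cfg.go_p, "n_terms": len(res)}, [epath])
            report["enriched_terms"] = int(len(sig))

    rpath = outdir / "report.json"
    with open(rpath, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.record("report", {}, [rpath])
    manifest.write()
    return report
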