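"""End-to-end orchestration: data -> QC -> gene filter -> network -> modules
-> hub screen -> clinical -> enrichment, from a single validated config.

Artifacts are persisted under the output directory with fixed names and a
machine-readable run report (stage counts, parameter echo, wall time,
version, seed).  Given a seed the result tables are byte-identical across
reruns; wall times live only in the report and are excluded from any
determinism contract.
"""

from __future__ import annotations

import configparser
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import association_table, cox_fit, dichotomize_expression, km_estimate, logrank_test
from .enrichment import gsea_permutation, immune_correlation, immune_survival_association, ssgsea_scores
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    SampleInfo,
    read_clinical,
    read_expression_matrix,
    read_gene_sets,
    read_ppi_edges,
    write_table,
)
from .network import (
    NetworkConfig,
    adjacency,
    cluster_genes,
    cut_modules,
    export_edges,
    merge_modules,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
)
from .ppi_hub import compute_candidates, map_to_ppi, screen_hubs
from .preprocess import cv_filter, select_consistent_pairs
from .synthetic_data import (
    SimulationConfig,
    simulate_clinical_table,
    simulate_expression,
    simulate_gene_sets,
    simulate_ppi,
)

log = logging.getLogger("hepanet")

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

_STAGES = ("data", "qc", "gene_filter", "network", "hub_screen", "clinical", "enrichment")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with study-default parameters."""

    # inputs; all None -> synthetic mode
    expression: str | None = None
    samples: str | None = None
    ppi: str | None = None
    gene_sets: str | None = None
    clinical: str | None = None
    # sample QC
    tumor_groups: int = 2
    normal_groups: int = 3
    # gene filter: top-N by CV by default (robust to the input's intensity
    # scale); set cv_cutoff (e.g. 3.6) and cv_top_n = None for a hard cutoff
    cv_cutoff: float | None = None
    cv_top_n: int | None = 200
    cv_scale: str = "linear"
    # network
    power: int = 6
    min_module_size: int = 30
    merge_height: float = 0.25
    edge_threshold: float = 0.1
    sign: str = "unsigned"
    n_selected_modules: int = 3
    module_selection: str = "abs"  # "abs" | "positive"
    # hub screen
    proportion_threshold: float = 0.10
    alpha: float = 0.05
    adjust_method: str = "bonferroni"
    # clinical / enrichment
    covariates: tuple[str, ...] = ("age_class", "sex", "tnm", "tumor_size", "afp")
    n_perm: int = 1000
    gsea_metric: str = "s2n"
    ssgsea_alpha: float = 0.25
    # run
    outdir: str = "hepanet_run"
    seed: int = 0
    synth_n_subjects: int = 54
    synth_n_genes: int = 250

    def __post_init__(self) -> None:
        if self.power < 1 or int(self.power) != self.power:
            raise ValueError("config field 'power' must be an integer >= 1")
        for name in ("merge_height", "edge_threshold", "proportion_threshold", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"config field {name!r} must be in (0,1), got {v}")
        if self.min_module_size < 2:
            raise ValueError("config field 'min_module_size' must be >= 2")
        if self.adjust_method not in ("bonferroni", "bh"):
            raise ValueError("config field 'adjust_method' must be bonferroni or bh")
        if self.module_selection not in ("abs", "positive"):
            raise ValueError("config field 'module_selection' must be abs or positive")
        if self.n_perm < 100:
            raise ValueError("config field 'n_perm' must be >= 100")
        if (self.cv_cutoff is None) == (self.cv_top_n is None):
            raise ValueError("exactly one of cv_cutoff / cv_top_n must be set")

    @property
    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            power=self.power,
            min_module_size=self.min_module_size,
            merge_height=self.merge_height,
            edge_threshold=self.edge_threshold,
            sign=self.sign,
        )


@dataclass
class RunReport:
    seed: int
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float, **counts) -> None:
        self.stages[stage] = {"status": status, "wall_seconds": round(seconds, 3), **counts}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


_FIELD_TYPES = {f.name: f for f in fields(PipelineConfig)}


def _coerce(name: str, value: str):
    v = value.strip()
    if v.lower() in ("none", ""):
        return None
    if name == "covariates":
        return tuple(x.strip() for x in v.split(",") if x.strip())
    for cast in (int, float):
        try:
            out = cast(v)
            if cast is int and "." in v:
                continue
            return out
        except ValueError:
            continue
    return v


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a flat ``key = value`` config file.

    Sections are allowed but ignored (keys must be globally unique); unknown
    keys and out-of-range values are rejected with the offending name.  An
    empty file yields all defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = configparser.ConfigParser()
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith("["):
        text = "[run]\n" + text
    parser.read_string(text)
    kwargs: dict = {}
    for section in parser.sections():
        for key, value in parser.items(section):
            if key not in _FIELD_TYPES:
                raise ValueError(f"unknown config key {key!r}")
            if key in kwargs:
                raise ValueError(f"duplicate config key {key!r}")
            kwargs[key] = _coerce(key, value)
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config back out in the flat key = value dialect."""
    with open(path, "w") as fh:
        fh.write("[run]\n")
        for f in fields(PipelineConfig):
            v = getattr(config, f.name)
            if isinstance(v, tuple):
                v = ",".join(v)
            fh.write(f"{f.name} = {v}\n")


def _load_samples(path: str) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    return [SampleInfo(r.sample_id, r.subject_id, r.tissue) for r in df.itertuples()]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order, persisting artifacts under ``outdir``.

    With no input paths the run is fully synthetic (planted modules, hubs,
    survival effects) and deterministic given the seed.  A clinical stage is
    skipped and marked as such when no clinical source exists.  Any stage
    failure aborts with the stage name; the partial report is still written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, parameters=asdict(config))
    for stage in _STAGES:
        report.stages[stage] = {"status": "pending"}

    current = "data"
    try:
        # ---- data -------------------------------------------------------
        t0 = time.perf_counter()
        synthetic = config.expression is None
        truth = None
        if synthetic:
            sim = SimulationConfig(
                n_subjects=config.synth_n_subjects,
                n_genes=config.synth_n_genes,
                seed=config.seed,
            )
            expr, samples, truth = simulate_expression(sim)
            ppi = simulate_ppi(sim, truth)
            gene_sets = simulate_gene_sets(truth, seed=config.seed)
            clin = simulate_clinical_table(
                sim.n_subjects, survival=sim.survival, seed=config.seed
            )
        else:
            expr = read_expression_matrix(config.expression)
            if config.samples is None:
                raise ValueError("sample metadata required with a real expression matrix")
            samples = _load_samples(config.samples)
            ppi = read_ppi_edges(config.ppi) if config.ppi else None
            gene_sets = read_gene_sets(config.gene_sets) if config.gene_sets else []
            clin = read_clinical(config.clinical) if config.clinical else None
        report.record("data", "completed", time.perf_counter() - t0,
                      n_genes=len(expr.gene_ids), n_samples=len(expr.sample_ids),
                      synthetic=synthetic)

        # ---- sample QC --------------------------------------------------
        current = "qc"
        t0 = time.perf_counter()
        qc = select_consistent_pairs(
            expr, samples, tumor_groups=config.tumor_groups,
            normal_groups=config.normal_groups,
        )
        expr_qc = expr.subset_samples(qc.retained_samples)
        kept = set(qc.retained_samples)
        samples_qc = [s for s in samples if s.sample_id in kept]
        pd.DataFrame(qc.dropped, columns=["sample_id", "reason"]).to_csv(
            outdir / "qc_dropped.tsv", sep="\t", index=False
        )
        report.record("qc", "completed", time.perf_counter() - t0,
                      n_retained_samples=len(qc.retained_samples),
                      n_retained_pairs=len(qc.retained_subjects),
                      n_dropped=len(qc.dropped))

        # ---- gene filter -------------------------------------------------
        current = "gene_filter"
        t0 = time.perf_counter()
        gf = cv_filter(expr_qc, cutoff=config.cv_cutoff, top_n=config.cv_top_n,
                       scale=config.cv_scale)
        if len(gf.retained_genes) < max(10, config.min_module_size):
            raise ValueError(
                f"CV filter retained only {len(gf.retained_genes)} genes; "
                "lower cv_cutoff or use cv_top_n"
            )
        expr_deg = expr_qc.subset_genes(gf.retained_genes)
        write_table(
            pd.DataFrame({"gene": gf.cv.index, "cv": gf.cv.to_numpy(),
                          "retained": gf.cv.index.isin(gf.retained_genes)}),
            outdir / "gene_filter.tsv",
        )
        report.record("gene_filter", "completed", time.perf_counter() - t0,
                      n_genes_in=len(expr_qc.gene_ids), n_degs=len(gf.retained_genes))

        # ---- network -----------------------------------------------------
        current = "network"
        t0 = time.perf_counter()
        ncfg = config.network_config
        sft, recommended = pick_soft_threshold(expr_deg, config=ncfg)
        write_table(sft, outdir / "soft_threshold.tsv")
        adj = adjacency(expr_deg, ncfg)
        tom = tom_similarity(adj)
        dend = cluster_genes(tom)
        modules = cut_modules(dend, tom, ncfg)
        n_initial = len([m for m in modules.unique() if m != "grey"])
        if n_initial == 0:
            raise ValueError("no co-expression module detected")
        me, varexp = module_eigengenes(expr_deg, modules)
        modules, me = merge_modules(expr_deg, modules, me, ncfg)
        trait = pd.Series(
            {s.sample_id: s.trait for s in samples_qc}, dtype=float
        ).loc[expr_deg.sample_ids]
        mt = module_trait_correlation(me, trait)
        if config.module_selection == "positive":
            mt_rank = mt[mt["r"] > 0]
        else:
            mt_rank = mt
        selected = list(mt_rank["module"].head(config.n_selected_modules))
        edges = export_edges(tom, modules, selected, config.edge_threshold)
        write_table(pd.DataFrame({"gene": modules.index, "module": modules.to_numpy()}),
                    outdir / "modules.tsv")
        me.to_csv(outdir / "eigengenes.tsv", sep="\t", float_format="%.12g")
        write_table(mt, outdir / "module_trait.tsv")
        write_table(edges, outdir / "edges.tsv")
        report.record("network", "completed", time.perf_counter() - t0,
                      recommended_power=recommended, power_used=ncfg.power,
                      n_modules=len(me.index), selected_modules=",".join(selected),
                      n_edges=len(edges))

        # ---- hub screen --------------------------------------------------
        current = "hub_screen"
        hubs: list[str] = []
        if ppi is None:
            report.record("hub_screen", "skipped", 0.0, reason="no interaction network")
            hub_table = None
        else:
            t0 = time.perf_counter()
            coexpr_genes = [g for g in modules.index if modules[g] in set(selected)]
            coverage = map_to_ppi(coexpr_genes, ppi)
            cands = compute_candidates(coexpr_genes, ppi, method=config.adjust_method)
            hubs, hub_table = screen_hubs(cands, config.proportion_threshold, config.alpha)
            write_table(hub_table, outdir / "hub_screen.tsv")
            report.record("hub_screen", "completed", time.perf_counter() - t0,
                          n_network_genes=coverage.n_network_genes,
                          mean_degree=round(coverage.mean_degree, 3),
                          n_covered=coverage.n_covered, n_hubs=len(hubs),
                          hubs=",".join(hubs[:10]))

        # ---- clinical ----------------------------------------------------
        current = "clinical"
        if clin is None:
            report.record("clinical", "skipped", 0.0, reason="no clinical table")
        else:
            t0 = time.perf_counter()
            df = clin.data.copy()
            assoc = association_table(df, [c for c in config.covariates if c in df.columns])
            write_table(assoc, outdir / "clinical_associations.tsv")
            km_rows = []
            for grp in ("low", "high"):
                sub = df[df["expression"] == grp]
                km = km_estimate(sub["time"].to_numpy(), sub["event"].to_numpy())
                km["group"] = grp
                km_rows.append(km)
            write_table(pd.concat(km_rows, ignore_index=True), outdir / "km_curves.tsv")
            _, lr_p = logrank_test(df["time"].to_numpy(), df["event"].to_numpy(),
                                   df["expression"].to_numpy())
            covs_num = {"expression_high": (df["expression"] == "high").astype(float)}
            for cov in config.covariates:
                if cov in df.columns:
                    levels = sorted(df[cov].dropna().unique())
                    if len(levels) == 2:
                        covs_num[f"{cov}_{levels[1]}"] = (df[cov] == levels[1]).astype(float)
            fit_df = pd.DataFrame({"time": df["time"], "event": df["event"], **covs_num})
            uni = cox_fit(fit_df, list(covs_num), mode="univariate")
            multi = cox_fit(fit_df, list(covs_num), mode="multivariate")
            cox_rows = [
                {"model": model, "covariate": r.covariate, "hr": r.hr,
                 "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p}
                for model, results in (("univariate", uni), ("multivariate", multi))
                for r in results
            ]
            write_table(pd.DataFrame(cox_rows), outdir / "cox_models.tsv")
            report.record("clinical", "completed", time.perf_counter() - t0,
                          n_patients=len(df), logrank_p=float(lr_p))

        # ---- enrichment --------------------------------------------------
        current = "enrichment"
        if not gene_sets:
            report.record("enrichment", "skipped", 0.0, reason="no gene sets")
        else:
            t0 = time.perf_counter()
            # two-class comparison: split tumor samples by the top hub gene
            # (fall back to tumor-vs-normal when no hub was found)
            tumor_ids = [s.sample_id for s in samples_qc if s.tissue == "tumor"]
            if hubs and len(tumor_ids) >= 6:
                key_gene = hubs[0]
                gvals = expr_deg.data.loc[key_gene, tumor_ids]
                glabels = dichotomize_expression(gvals.to_numpy(), rule="median")
                gsea_expr = expr_deg.subset_samples(tumor_ids)
                # "high" first so positive ES means enriched with high expression
                glabels = np.where(glabels == "high", "high", "low")
                order = np.argsort(glabels != "high", kind="stable")
                gsea_expr = gsea_expr.subset_samples([tumor_ids[i] for i in order])
                glabels = glabels[order]
            else:
                key_gene = None
                gsea_expr = expr_deg
                glabels = np.asarray(
                    ["tumor" if s.tissue == "tumor" else "normal" for s in samples_qc]
                )
            gsea_table, scheme = gsea_permutation(
                gsea_expr, glabels, gene_sets, n_perm=config.n_perm,
                seed=config.seed, metric=config.gsea_metric,
            )
            write_table(gsea_table, outdir / "gsea.tsv")
            scores, flagged = ssgsea_scores(expr_deg, gene_sets, alpha=config.ssgsea_alpha)
            scores.to_csv(outdir / "ssgsea_scores.tsv", sep="\t", float_format="%.12g")
            if key_gene is not None:
                corr = immune_correlation(scores, expr_deg.data.loc[key_gene])
                write_table(corr, outdir / "immune_correlation.tsv")
            if clin is not None and synthetic:
                # synthetic clinical rows are indexed by patient, scores by
                # sample: align on the tumor sample of each subject
                surv = clin.data.copy()
                surv.index = [f"S{i:03d}T" for i in range(len(surv))]
                surv = surv.loc[[s for s in surv.index if s in scores.columns]]
                if len(surv) >= 10:
                    imm_surv = immune_survival_association(scores, surv[["time", "event"]])
                    write_table(imm_surv, outdir / "immune_survival.tsv")
            report.record("enrichment", "completed", time.perf_counter() - t0,
                          n_sets=len(gsea_table), permutation=scheme,
                          n_flagged_sets=len(flagged), key_gene=key_gene)
    except Exception:
        report.stages[current]["status"] = "failed"
        report.to_json(outdir / "run_report.json")
        log.exception("pipeline failed at stage %s", current)
        raise
    report.to_json(outdir / "run_report.json")
    return report
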