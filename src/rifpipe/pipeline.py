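"""End-to-end orchestration of the analysis stages from one config.

Stages: simulate (optional) -> de -> rif -> qpcr -> variants -> phenotypes.
Each stage reads its inputs from the previous stage's artifacts (or from
user-supplied paths), applies the study thresholds, and persists its
outputs under ``output_dir``.  A structured report records the counts at
every filter step, the RIF significance table, qPCR concordance, and the
variant summaries; every threshold and seed used is logged.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("rifpipe")


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults = study values) plus paths and seed."""

    output_dir: str = "rifpipe_out"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_de: bool = True
    run_rif: bool = True
    run_qpcr: bool = True
    run_variants: bool = True
    run_phenotypes: bool = True
    # expression / DE thresholds
    min_fpkm: float = 0.5
    min_abs_fc: float = 1.5
    max_p: float = 0.01
    log_offset: float = 0.25
    # RIF
    boot_reps: int = 10000
    ci_levels: tuple[int, ...] = (95, 99)
    # variants
    min_coverage: int = 30
    candidate_min_coverage: int = 10
    min_freq: float = 0.05
    fixed_threshold: float = 0.90
    # synthetic-data parameters (used when run_simulate)
    simulation: dict = field(default_factory=dict)
    # external input paths (used when run_simulate is False)
    counts_tsv: str | None = None
    genes_tsv: str | None = None
    design_tsv: str | None = None
    trf_list: str | None = None
    qpcr_csv: str | None = None
    efficiency_csv: str | None = None
    vcf_a: str | None = None
    vcf_b: str | None = None
    fatty_acid_csv: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fixed_threshold <= 1):
            raise ValueError("fixed_threshold must lie in (0, 1]")
        if self.min_fpkm < 0 or self.min_abs_fc < 1 or not 0 < self.max_p <= 1:
            raise ValueError("DE thresholds outside documented ranges")
        if self.min_coverage < 0 or not 0 <= self.min_freq <= 1:
            raise ValueError("variant thresholds outside documented ranges")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ci_levels" in raw:
            raw["ci_levels"] = tuple(raw["ci_levels"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the structured run report.

    A stage failure is recorded and aborts only the stages that depend on
    its outputs.
    """
    from rifpipe import (
        ExpressionDataset,
        QpcrDataset,
        bootstrap_null_ci,
        classify_trf,
        coexpression_correlations,
        compare_groups,
        compute_rif,
        concordance_ccc,
        de_test,
        estimate_diff_tg,
        expressed_gene_set,
        filter_de,
        filter_variants,
        generate_expression_dataset,
        generate_fatty_acid_profiles,
        generate_qpcr_dataset,
        generate_variant_dataset,
        generate_toy_gene_models,
    )
    from rifpipe.phenotypes import group_compare, profile_table_summaries
    from rifpipe.reference_data import piglet_fatty_acid_means
    from rifpipe.simulate import SimulationConfig, write_gene_models
    from rifpipe.variants import read_variant_tsv, read_vcf, write_vcf

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "pipeline.log")
    report: dict = {"config": _jsonable(asdict(config)), "stages": {}}
    log.info("pipeline start: seed=%d output=%s", config.seed, out)

    expr = truth = None
    qpcr_ds = None
    var_a = var_b = None
    fa_profiles = None

    # ----------------------------------------------------------- simulate
    if config.run_simulate:
        t0 = time.monotonic()
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        expr, truth = generate_expression_dataset(sim)
        expr.to_files(out / "synthetic")
        (out / "trf_list.txt").write_text("\n".join(expr.trf_ids()) + "\n")
        qpcr_ds = generate_qpcr_dataset(
            n_targets=5,
            n_reference=2,
            animals_per_group=sim.samples_per_group,
            replicates=3,
            true_diff={"TGT1": -2.0, "TGT2": 1.0, "TGT3": 0.0, "TGT4": -1.0,
                       "TGT5": 0.5},
            seed=config.seed,
        )
        qpcr_ds.write(out / "qpcr.csv", out / "efficiencies.csv")
        models, genome = generate_toy_gene_models(seed=config.seed)
        write_gene_models(models, genome, out / "models.gff3", out / "genome.fa")
        var_a, var_b = generate_variant_dataset(
            n_loci=500,
            p_fixed_group_a=0.4,
            p_shared=0.7,
            toy_gene_models=models,
            genome=genome,
            seed=config.seed,
            p_fixed_group_b=0.3,
        )
        contigs = {c: len(s) for c, s in genome.items()}
        write_vcf(var_a, out / "variants_IB.vcf", contigs)
        write_vcf(var_b, out / "variants_IBxDU.vcf", contigs)
        fa_profiles = generate_fatty_acid_profiles(
            animals_per_group=6,
            group_means={
                "IB": piglet_fatty_acid_means("IB"),
                "IBxDU": piglet_fatty_acid_means("IBxDU"),
            },
            sd=0.5,
            seed=config.seed,
        )
        fa_profiles.to_csv(out / "fatty_acids.csv", index=False)
        log.info("simulate stage: %.2fs", time.monotonic() - t0)
        report["stages"]["simulate"] = {
            "status": "ok",
            "n_genes": len(expr.gene_ids),
            "n_trf": len(expr.trf_ids()),
            "n_de_true": len(truth.de_gene_ids),
        }
    else:
        if config.counts_tsv:
            expr = ExpressionDataset.from_files(
                config.counts_tsv, config.genes_tsv, config.design_tsv
            )
        if config.qpcr_csv:
            qpcr_ds = QpcrDataset.read(config.qpcr_csv, config.efficiency_csv)
        if config.vcf_a:
            reader = read_vcf if str(config.vcf_a).endswith(".vcf") else read_variant_tsv
            var_a = reader(config.vcf_a)
            var_b = reader(config.vcf_b)
        if config.fatty_acid_csv:
            fa_profiles = pd.read_csv(config.fatty_acid_csv)

    # ----------------------------------------------------------------- de
    de_set = None
    if config.run_de and expr is not None:
        t0 = time.monotonic()
        log.info(
            "DE filters: min_fpkm>%.3g, |FC|>=%.3g, p<=%.3g",
            config.min_fpkm, config.min_abs_fc, config.max_p,
        )
        p = de_test(expr.counts, expr.design)
        de_set = filter_de(
            expr, p,
            min_fpkm=config.min_fpkm,
            min_abs_fc=config.min_abs_fc,
            max_p=config.max_p,
            log_offset=config.log_offset,
        )
        de_set.write(out / "de_genes.tsv")
        expressed = expressed_gene_set(expr.fpkm, expr.design, config.min_fpkm)
        report["stages"]["de"] = {
            "status": "ok",
            "n_expressed": len(expressed),
            "n_de": de_set.n_de,
        }
    elif config.run_de:
        report["stages"]["de"] = {"status": "skipped", "reason": "no expression data"}

    # ---------------------------------------------------------------- rif
    if config.run_rif and de_set is not None and de_set.n_de >= 2:
        t0 = time.monotonic()
        trf_all = expr.trf_ids()
        if not trf_all and config.trf_list:
            trf_all = Path(config.trf_list).read_text().split()
        expressed = expressed_gene_set(expr.fpkm, expr.design, config.min_fpkm)
        trf = sorted(set(trf_all) & expressed)
        de_ids = [g for g in de_set.gene_ids if g not in set(trf)]
        co = coexpression_correlations(expr, trf, de_ids, offset=config.log_offset)
        raw = compute_rif(de_set, co)
        n_draw = min(len(de_ids), len(expressed - set(trf)))
        ci = bootstrap_null_ci(
            expr, expressed, trf,
            n_de_drawn=n_draw,
            reps=config.boot_reps,
            seed=config.seed,
            levels=config.ci_levels,
            offset=config.log_offset,
            keep_pooled=False,
        )
        rif_res = classify_trf(raw, ci)
        rif_res.write(out / "rif_table.tsv")
        (out / "rif_ci.json").write_text(json.dumps(ci.to_dict(), indent=2))
        report["stages"]["rif"] = {
            "status": "ok",
            "n_trf_tested": len(trf),
            "boot_reps": config.boot_reps,
            "n_sig95_rif1": len(rif_res.significant("rif1", 95)),
            "n_sig95_rif2": len(rif_res.significant("rif2", 95)),
            "ci": ci.to_dict()["intervals"],
        }
    elif config.run_rif:
        report["stages"]["rif"] = {"status": "skipped", "reason": "no DE gene set"}

    # --------------------------------------------------------------- qpcr
    if config.run_qpcr and qpcr_ds is not None:
        t0 = time.monotonic()
        from rifpipe import fit_qpcr_model

        fit = fit_qpcr_model(qpcr_ds)
        refs = qpcr_ds.reference_genes
        results = [
            estimate_diff_tg(fit, g, refs) for g in qpcr_ds.target_genes
        ]
        qtab = pd.DataFrame(
            [
                {
                    "gene": r.gene, "diff_tg": r.diff_tg, "se": r.se,
                    "t": r.t_stat, "p": r.p_value, "fc": r.fc,
                }
                for r in results
            ]
        )
        qtab.to_csv(out / "qpcr_results.tsv", sep="\t", index=False)
        stage = {
            "status": "ok",
            "fit_method": fit.method,
            "n_targets": len(results),
        }
        # Concordance with RNA-seq FCs where gene names overlap.
        if de_set is not None:
            common = [g for g in qtab["gene"] if g in de_set.table.index]
            if len(common) >= 2:
                x = de_set.table.loc[common, "fc"].to_numpy()
                y = qtab.set_index("gene").loc[common, "fc"].to_numpy()
                stage["ccc"] = concordance_ccc(x, y)
        report["stages"]["qpcr"] = stage
    elif config.run_qpcr:
        report["stages"]["qpcr"] = {"status": "skipped", "reason": "no qPCR data"}

    # ----------------------------------------------------------- variants
    if config.run_variants and var_a is not None:
        t0 = time.monotonic()
        log.info(
            "variant filters: coverage>=%d, freq>=%.3g, fixed>=%.3g",
            config.min_coverage, config.min_freq, config.fixed_threshold,
        )
        fa = filter_variants(var_a, config.min_coverage, config.min_freq)
        fb = filter_variants(var_b, config.min_coverage, config.min_freq)
        cmp_res = compare_groups(fa, fb, fixed_threshold=config.fixed_threshold)
        cmp_res.loci.to_csv(out / "variant_comparison.tsv", sep="\t", index=False)
        (out / "variant_summary.json").write_text(
            json.dumps(cmp_res.summary, indent=2)
        )
        report["stages"]["variants"] = {
            "status": "ok",
            "summary": cmp_res.summary,
        }
    elif config.run_variants:
        report["stages"]["variants"] = {
            "status": "skipped", "reason": "no variant tables"
        }

    # --------------------------------------------------------- phenotypes
    if config.run_phenotypes and fa_profiles is not None:
        t0 = time.monotonic()
        summaries = profile_table_summaries(fa_profiles)
        summaries.to_csv(out / "fatty_acid_summary.tsv", sep="\t")
        per_animal = profile_table_summaries_per_animal(fa_profiles)
        tests = {}
        for col in ("sum_sfa", "sum_mufa", "ui"):
            res = group_compare(per_animal[col], per_animal["group"])
            tests[col] = {"means": res.means, "sem": res.sem, "p": res.p_value}
        report["stages"]["phenotypes"] = {
            "status": "ok",
            "group_means": summaries.to_dict(orient="index"),
            "tests": tests,
        }
    elif config.run_phenotypes:
        report["stages"]["phenotypes"] = {
            "status": "skipped", "reason": "no fatty-acid profiles"
        }

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    log.info("pipeline done")
    return report


def profile_table_summaries_per_animal(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-animal summary indices with the group column retained."""
    from rifpipe.phenotypes import _FA_NAME, summary_indices

    fa_cols = [c for c in profiles.columns if _FA_NAME.match(str(c))]
    rows = []
    for _, row in profiles.iterrows():
        idx = summary_indices(row[fa_cols])
        idx["group"] = row["group"]
        rows.append(idx)
    return pd.DataFrame(rows, index=profiles.index)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _setup_logging(logfile: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(sh)
    if not any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == str(logfile)
        for h in log.handlers
    ):
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
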