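"""End-to-end pipeline: simulate -> infer -> topology -> annotate -> motifs.

A run is driven by a single declarative config (YAML on disk, pydantic in
memory) with every seed explicit and unknown keys rejected. A JSON manifest
recording the full configuration is written before any stage executes and is
updated with per-stage timings and outputs as stages complete, so a run can
be reproduced from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import go_annotation as goa
from . import inference, io, motifs as motif_mod, synthetic, topology

log = logging.getLogger("trnkit")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_StrictModel):
    seed: int
    n_tf: int = 20
    n_genes: int = 500
    m: int = 200
    density: float = 0.1
    noise_sd: float = 0.1
    promoter_length: int = 1577
    motif_k: int = 7
    insertion_prob: float = 0.5
    n_go_terms: int = 50
    annotation_prob: float = 0.8
    go_background_rate: float = 0.05
    pwm_width: int = 11
    pwm_conservation: float = 0.85
    categories: list[str] | None = None


class InferConfig(_StrictModel):
    seed: int
    lasso_lambda: float = Field(default=0.008, alias="lambda")
    lambda_grid: list[float] | None = None
    alpha: float = 0.075
    cv_folds: int = 10
    r2_percentile: float = 25.0
    per_treatment: bool = False
    standardize: bool = False
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class AnnotateConfig(_StrictModel):
    seed: int
    threshold: float = 0.05
    null_reps: int = 100
    null_sizes: list[int] | None = None


class MotifsConfig(_StrictModel):
    seed: int
    ks: list[int] = Field(default_factory=lambda: [7])
    fdr: float = 0.05
    null_reps: int = 100
    both_strands: bool = False


class RunConfig(_StrictModel):
    schema_version: int = 1
    outdir: str = "trnkit_run"
    simulate: SimulateConfig
    infer: InferConfig
    annotate: AnnotateConfig
    motifs: MotifsConfig


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


class _Manifest:
    def __init__(self, path: Path, config: RunConfig):
        self.path = path
        self.data = {
            "trnkit_version": __version__,
            "config": config.model_dump(by_alias=True),
            "stages": {},
            "status": "running",
        }
        self.write()

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, default=str) + "\n")

    def stage(self, name: str, seconds: float, outputs: list[str]) -> None:
        self.data["stages"][name] = {
            "seconds": round(seconds, 3),
            "outputs": outputs,
        }
        self.write()

    def finish(self, status: str = "completed") -> None:
        self.data["status"] = status
        self.write()


def simulate_stage(cfg: SimulateConfig, outdir: Path) -> dict:
    """Generate the synthetic study inputs and write them to disk."""
    expr, model = synthetic.generate_expression(
        cfg.n_tf, cfg.n_genes, cfg.m, cfg.density, cfg.noise_sd, cfg.seed
    )
    if cfg.categories:
        expr.sample_category = {
            s: cfg.categories[i % len(cfg.categories)]
            for i, s in enumerate(expr.sample_ids)
        }
    model.motif_plants = synthetic.random_motif_plants(
        model.tf_ids, k=cfg.motif_k, pi=cfg.insertion_prob, seed=cfg.seed + 1
    )
    model.go_plants = synthetic.assign_go_plants(model.tf_ids, rho=cfg.annotation_prob)
    truth = model.true_network()
    promoters = synthetic.generate_promoters(
        model, truth, length=cfg.promoter_length, seed=cfg.seed + 2
    )
    corpus = synthetic.generate_go_corpus(
        model, truth, n_terms=cfg.n_go_terms, seed=cfg.seed + 3,
        background_rate=cfg.go_background_rate,
    )
    pwms = synthetic.generate_reference_pwms(
        model, width=cfg.pwm_width, conservation=cfg.pwm_conservation, seed=cfg.seed + 4
    )
    lengths = synthetic.generate_gene_lengths(model.gene_ids, seed=cfg.seed + 5)

    io.write_expression(expr, outdir / "expression.tsv")
    (outdir / "tf_list.txt").write_text("\n".join(expr.tf_ids) + "\n")
    io.write_promoters(promoters, outdir / "promoters.fasta")
    io.write_obo(corpus.dag, outdir / "ontology.obo")
    direct = {g: sorted(ts) for g, ts in corpus.annotations.items()}
    io.write_annotations(direct, outdir / "annotations.tsv")
    io.write_pwms(pwms.values(), outdir / "reference_pwms.meme")
    io.write_network(truth, outdir / "true_edges.tsv")
    io.write_gene_lengths(lengths, outdir / "gene_lengths.tsv")
    reference = {tf: [term] for tf, (term, _) in model.go_plants.items()}
    pd.DataFrame(
        [(tf, t) for tf, ts in reference.items() for t in ts], columns=["tf", "term"]
    ).to_csv(outdir / "reference_tf_go.tsv", sep="\t", index=False)
    return {
        "expr": expr, "model": model, "truth": truth, "promoters": promoters,
        "corpus": corpus, "pwms": pwms, "lengths": lengths, "reference": reference,
        "outputs": [
            "expression.tsv", "tf_list.txt", "promoters.fasta", "ontology.obo",
            "annotations.tsv", "reference_pwms.meme", "true_edges.tsv",
            "gene_lengths.tsv", "reference_tf_go.tsv",
        ],
    }


def infer_stage(cfg: InferConfig, expr, outdir: Path) -> dict:
    if cfg.lambda_grid:
        lam, report = inference.tune_lambda(
            expr, cfg.lambda_grid, folds=cfg.cv_folds, seed=cfg.seed,
            standardize=cfg.standardize,
        )
    else:
        lam = cfg.lasso_lambda
        r2 = inference.cv_r2(expr, lam, folds=cfg.cv_folds, seed=cfg.seed,
                             standardize=cfg.standardize)
        report = inference.FitReport(
            lambda_star=lam, per_gene_r2=r2, fold_seed=cfg.seed,
            per_lambda=pd.DataFrame([{"lambda": lam, "mean_r2": r2.mean()}]),
        )
    retained, cutoff = inference.filter_by_r2(report, cfg.r2_percentile)
    A = inference.fit_coefficients(expr, lam, genes=retained, standardize=cfg.standardize,
                                   r2=report.per_gene_r2)
    net = inference.threshold_network(A, cfg.alpha)
    log.info("inferred network: lambda=%.4g alpha=%.4g cutoff_r2=%.3f %s",
             lam, cfg.alpha, cutoff, net)
    io.write_network(net, outdir / "edges.tsv")
    report.per_gene_r2.rename("mean_cv_r2").to_csv(outdir / "fit_report.tsv", sep="\t",
                                                   index_label="gene_id")
    report.per_lambda.to_csv(outdir / "lambda_scan.tsv", sep="\t", index=False)
    out = {"net": net, "A": A, "report": report, "lambda": lam, "r2_cutoff": cutoff,
           "outputs": ["edges.tsv", "fit_report.tsv", "lambda_scan.tsv"]}
    if cfg.per_treatment and expr.sample_category:
        nets = inference.infer_treatment_networks(expr, lam, net.n_edges,
                                                  standardize=cfg.standardize)
        for cat, tnet in nets.items():
            fname = f"edges.{cat.replace(' ', '_')}.tsv"
            io.write_network(tnet, outdir / fname)
            out["outputs"].append(fname)
        out["treatment_nets"] = nets
    return out


def topology_stage(net, expr, lengths, outdir: Path) -> dict:
    summary = topology.summarize(net)
    table, hist = topology.degree_distribution(net)
    corr = topology.architecture_correlations(expr, net, lengths)
    (outdir / "topology_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n"
    )
    table.to_csv(outdir / "degrees.tsv", sep="\t")
    hist.to_csv(outdir / "degree_histogram.tsv", sep="\t", index=False)
    corr.to_csv(outdir / "architecture_correlations.tsv", sep="\t", index=False)
    return {"summary": summary, "correlations": corr,
            "outputs": ["topology_summary.json", "degrees.tsv",
                        "degree_histogram.tsv", "architecture_correlations.tsv"]}


def annotate_stage(cfg: AnnotateConfig, net, corpus, outdir: Path, reference=None) -> dict:
    sizes = cfg.null_sizes or goa.default_null_sizes()
    usable = [k for k in sizes if k <= corpus.n_universe]
    if len(usable) < len(sizes):
        log.warning("dropped %d null sizes exceeding the universe (%d genes)",
                    len(sizes) - len(usable), corpus.n_universe)
    curves = goa.build_null_curves(corpus, usable, reps=cfg.null_reps,
                                   threshold=cfg.threshold, seed=cfg.seed)
    records, summary = goa.annotate_network(net.target_pools(), corpus,
                                            threshold=cfg.threshold, curves=curves)
    records.to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "tf_annotation_summary.tsv", sep="\t", index=False)
    curves.to_frame().to_csv(outdir / "null_curves.tsv", sep="\t", index=False)
    out = {"records": records, "summary": summary, "curves": curves,
           "outputs": ["go_enrichment.tsv", "tf_annotation_summary.tsv", "null_curves.tsv"]}
    if reference is not None:
        predicted = {
            tf: set(records.loc[records["tf"] == tf, "term"]) for tf in net.tfs
        }
        comparison = goa.compare_with_reference(predicted, reference, corpus)
        comparison.to_csv(outdir / "reference_comparison.tsv", sep="\t", index=False)
        out["comparison"] = comparison
        out["outputs"].append("reference_comparison.tsv")
    return out


def motifs_stage(cfg: MotifsConfig, net, promoters, outdir: Path, pwms=None) -> dict:
    index = motif_mod.index_promoters(promoters, ks=cfg.ks,
                                      both_strands=cfg.both_strands)
    pairs = motif_mod.discover_motifs(net, index, q=cfg.fdr)
    null = motif_mod.rewire_null(net, index, reps=cfg.null_reps, seed=cfg.seed,
                                 q=cfg.fdr)
    pairs.to_csv(outdir / "tf_motif_pairs.tsv", sep="\t", index=False)
    pd.DataFrame({"rep": np.arange(len(null.null_counts)),
                  "significant_pairs": null.null_counts}).to_csv(
        outdir / "rewire_null_counts.tsv", sep="\t", index=False)
    out = {"index": index, "pairs": pairs, "null": null,
           "outputs": ["tf_motif_pairs.tsv", "rewire_null_counts.tsv"]}
    if pwms:
        assignments = {
            tf: pairs.loc[pairs["tf"] == tf, "motif"].tolist()
            for tf in pairs["tf"].unique()
        }
        assignments = {tf: ms for tf, ms in assignments.items() if ms}
        scores = motif_mod.score_assignments(assignments, pwms)
        scores.to_csv(outdir / "ic_alignments.tsv", sep="\t", index=False)
        out["scores"] = scores
        out["outputs"].append("ic_alignments.tsv")
        if len([tf for tf in assignments if tf in pwms]) >= 2:
            baseline = motif_mod.score_shuffle_baseline(assignments, pwms,
                                                        seed=cfg.seed)
            out["baseline"] = baseline
            (outdir / "score_baseline.json").write_text(json.dumps({
                "t_statistic": baseline.t_statistic, "p_value": baseline.p_value,
                "true_mean": float(np.mean(baseline.true_scores)),
                "shuffled_mean": float(np.mean(baseline.shuffled_scores)),
            }, indent=2) + "\n")
            out["outputs"].append("score_baseline.json")
    return out


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on a simulated dataset; returns stage results.

    The manifest is written before the first stage and updated after each.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json", config)
    results: dict = {}
    try:
        t0 = time.perf_counter()
        sim = simulate_stage(config.simulate, outdir)
        manifest.stage("simulate", time.perf_counter() - t0, sim["outputs"])
        results["simulate"] = sim

        t0 = time.perf_counter()
        inf = infer_stage(config.infer, sim["expr"], outdir)
        manifest.stage("infer", time.perf_counter() - t0, inf["outputs"])
        results["infer"] = inf

        t0 = time.perf_counter()
        top = topology_stage(inf["net"], sim["expr"], sim["lengths"], outdir)
        manifest.stage("topology", time.perf_counter() - t0, top["outputs"])
        results["topology"] = top

        t0 = time.perf_counter()
        ann = annotate_stage(config.annotate, inf["net"], sim["corpus"], outdir,
                             reference=sim["reference"])
        manifest.stage("annotate", time.perf_counter() - t0, ann["outputs"])
        results["annotate"] = ann

        t0 = time.perf_counter()
        mot = motifs_stage(config.motifs, inf["net"], sim["promoters"], outdir,
                           pwms=sim["pwms"])
        manifest.stage("motifs", time.perf_counter() - t0, mot["outputs"])
        results["motifs"] = mot
    except Exception:
        manifest.finish("failed")
        raise
    manifest.finish()
    return results
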