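"""End-to-end orchestration of the integration cascade.

Stage outputs are plain-text tables with headers, one directory per run, so
any stage can be re-run in isolation from the persisted intermediates of
the previous ones.  The run order mirrors the analysis flow:

    simulate -> consensus -> annotate -> de -> scan -> integrate ->
    enrich -> quant -> report

``run_pipeline`` executes all stages and returns a :class:`RunReport` with
the paths of every table plus summary counts; the summary satisfies, by
construction, |DEG| = |up| + |down| = |RDG| + |RIG| and
comm_DGs ⊆ direct targets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import integrate as integ
from .config import InputPaths, PipelineConfig
from .diffexpr import CountMatrix, de_test, filter_low_counts
from .intervals import (
    BedGraphCoverage,
    GenomicInterval,
    annotate_peaks,
    feature_distribution,
    intersect_consensus,
    metaprofile,
    read_bed,
    read_fasta,
    read_gtf,
    write_bed,
)
from .motifs import extract_promoter_window, read_meme, scan_windows
from .quant import QPCRMeasurement, ddct_relative_expression
from .synthetic import SimConfig, generate_study

log = logging.getLogger("lnctarget")

FLOAT_FMT = "%.6g"


@dataclass
class RunReport:
    run_dir: str
    paths: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _timed(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return str(path)


def _require(cfg: PipelineConfig, *names: str) -> list[str]:
    out = []
    for n in names:
        p = getattr(cfg.inputs, n)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input {n!r} missing: {p}")
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


@_timed("simulate")
def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> PipelineConfig:
    """Generate synthetic inputs and point the config at them."""
    sim_cfg = SimConfig.from_dict(cfg.simulate or {})
    sim_dir = run_dir / "sim"
    paths, _truth = generate_study(sim_cfg, cfg.random_seed, sim_dir)
    cfg.inputs = InputPaths(**paths)
    log.info("simulated study in %s", sim_dir)
    return cfg


@_timed("consensus")
def stage_consensus(cfg: PipelineConfig, run_dir: Path) -> dict:
    even_path, odd_path = _require(cfg, "chirp_even_bed", "chirp_odd_bed")
    even = read_bed(even_path)
    odd = read_bed(odd_path)
    # peak-level q filtering (score column = q) before intersecting
    def q_filter(peaks):
        return [
            p for p in peaks if p.score is None or p.score < cfg.peak_q
        ]
    even_f, odd_f = q_filter(even), q_filter(odd)
    peaks = intersect_consensus(even_f, odd_f)
    rows = [
        {
            "peak_id": f"cons{k:05d}",
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "even_sources": ";".join(p.even_sources),
            "odd_sources": ";".join(p.odd_sources),
        }
        for k, p in enumerate(peaks)
    ]
    df = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "even_sources", "odd_sources"]
    )
    out = run_dir / "consensus"
    out.mkdir(parents=True, exist_ok=True)
    path = _write(df, out / "consensus_peaks.tsv")
    write_bed(
        [
            GenomicInterval(r["chrom"], r["start"], r["end"], name=r["peak_id"])
            for r in rows
        ],
        out / "consensus_peaks.bed",
    )
    log.info("consensus: %d EVEN + %d ODD -> %d peaks", len(even_f), len(odd_f), len(df))
    return {"consensus_peaks": path, "n_consensus": len(df)}


def _consensus_intervals(run_dir: Path) -> list[GenomicInterval]:
    df = pd.read_csv(run_dir / "consensus" / "consensus_peaks.tsv", sep="\t")
    return [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), name=r["peak_id"])
        for _, r in df.iterrows()
    ]


@_timed("annotate")
def stage_annotate(cfg: PipelineConfig, run_dir: Path) -> dict:
    (gtf_path,) = _require(cfg, "annotation_gtf")
    genes = read_gtf(gtf_path)
    out = run_dir / "annotate"
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    peaks = _consensus_intervals(run_dir)
    ann = annotate_peaks(peaks, genes, cfg.tss_window_bp)
    paths["peak_annotations"] = _write(ann, out / "peak_annotations.tsv")
    if len(ann):
        dist = feature_distribution(ann)
        paths["feature_distribution"] = _write(
            pd.DataFrame(
                [{"feature_class": k, "fraction": v} for k, v in sorted(dist.items())]
            ),
            out / "feature_distribution.tsv",
        )

    chip_path = cfg.inputs.chip_bed
    if chip_path and Path(chip_path).exists():
        chip = [
            p
            for p in read_bed(chip_path)
            if p.score is None or p.score < cfg.peak_q
        ]
        chip_ann = annotate_peaks(chip, genes, cfg.tss_window_bp)
        paths["chip_annotations"] = _write(chip_ann, out / "chip_annotations.tsv")

    cov_path = cfg.inputs.coverage_bedgraph
    if cov_path and Path(cov_path).exists():
        fasta = cfg.inputs.genome_fasta
        sizes = None
        if fasta and Path(fasta).exists():
            sizes = {c: len(s) for c, s in read_fasta(fasta).items()}
        cov = BedGraphCoverage.from_file(cov_path, chrom_sizes=sizes)
        bound = ann.dropna(subset=["gene_id"])
        by_id = {g.gene_id: g for g in genes}
        anchors = sorted(
            {
                (by_id[g].chrom, by_id[g].tss, by_id[g].strand)
                for g in bound["gene_id"].unique()
                if g in by_id
            }
        )
        if anchors:
            prof = metaprofile(cov, anchors, half_window_bp=3000, n_bins=60)
            centers = np.arange(60) * 100 - 3000 + 50
            paths["metaprofile"] = _write(
                pd.DataFrame({"position": centers, "mean_signal": prof}),
                out / "metaprofile.tsv",
            )
    log.info("annotated %d consensus peaks", len(ann))
    return paths


def _load_counts_checked(path: str, genes: set[str], label: str) -> CountMatrix:
    cm = CountMatrix.from_tsv(path)
    unknown = sorted(set(cm.counts.index) - genes)
    if unknown:
        raise ValueError(
            f"{label}: count matrix gene id(s) absent from annotation: "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}"
        )
    return cm


@_timed("de")
def stage_de(cfg: PipelineConfig, run_dir: Path) -> dict:
    gtf_path, a_path, b_path = _require(
        cfg, "annotation_gtf", "counts_model_a", "counts_model_b"
    )
    gene_ids = {g.gene_id for g in read_gtf(gtf_path)}
    out = run_dir / "de"
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    jobs = {"de_model_a": a_path, "de_model_b": b_path}
    if cfg.inputs.counts_tf_model_b and Path(cfg.inputs.counts_tf_model_b).exists():
        jobs["de_tf_model_b"] = cfg.inputs.counts_tf_model_b
    for name, path in jobs.items():
        cm = _load_counts_checked(path, gene_ids, name)
        cm = filter_low_counts(cm, cfg.low_count_min_total)
        res = de_test(cm, de_fdr=cfg.de_fdr)
        paths[name] = _write(res, out / f"{name}.tsv")
        n_sig = int((res["padj"] < cfg.de_fdr).sum())
        log.info("%s: %d genes tested, %d significant", name, len(res), n_sig)
    return paths


def _deg_sets(run_dir: Path, de_fdr: float) -> dict[str, pd.DataFrame]:
    out = {}
    for name in ("de_model_a", "de_model_b", "de_tf_model_b"):
        p = run_dir / "de" / f"{name}.tsv"
        if p.exists():
            out[name] = pd.read_csv(p, sep="\t")
    return out


@_timed("scan")
def stage_scan(cfg: PipelineConfig, run_dir: Path) -> dict:
    """Scan promoters of genes deregulated in both cell models with the
    PWMs of the coherent direct-target TFs."""
    gtf_path, fasta_path, pwm_path, cat_path = _require(
        cfg, "annotation_gtf", "genome_fasta", "pwm_file", "tf_catalog"
    )
    genes = read_gtf(gtf_path)
    de = _deg_sets(run_dir, cfg.de_fdr)
    deg_a = set(de["de_model_a"].loc[de["de_model_a"]["padj"] < cfg.de_fdr, "gene_id"])
    deg_b = set(de["de_model_b"].loc[de["de_model_b"]["padj"] < cfg.de_fdr, "gene_id"])
    common = sorted(deg_a & deg_b)
    out = run_dir / "scan"
    out.mkdir(parents=True, exist_ok=True)

    # the scanning PWM set: catalog TFs that qualified as coherent direct
    # targets (computed in-line from persisted stage outputs)
    ann = pd.read_csv(run_dir / "annotate" / "peak_annotations.tsv", sep="\t")
    targets_a, _ = integ.classify_targets(ann, de["de_model_a"], cfg.de_fdr)
    catalog = pd.read_csv(cat_path, sep="\t")
    rdg_tfs = integ.identify_rdg_tfs(targets_a, de["de_model_b"], catalog, cfg.de_fdr)
    pwms = read_meme(pwm_path)
    tf_with_pwm = {p.tf_id for p in pwms}
    scan_tfs = [t for t in rdg_tfs["gene_id"] if t in tf_with_pwm]
    missing_pwm = sorted(set(rdg_tfs["gene_id"]) - tf_with_pwm)
    pwms = [p for p in pwms if p.tf_id in set(scan_tfs)]

    if not common or not pwms:
        hits = pd.DataFrame(
            columns=["tf_id", "gene_id", "strand", "offset", "score", "p", "q"]
        )
    else:
        genome = read_fasta(fasta_path)
        by_id = {g.gene_id: g for g in genes}
        windows = [
            extract_promoter_window(by_id[g], genome, cfg)
            for g in common
            if g in by_id
        ]
        hits, _tables = scan_windows(pwms, windows, cfg)
    path = _write(hits, out / "motif_hits.tsv")
    _write(
        pd.DataFrame({"tf_id_without_pwm": missing_pwm}),
        out / "tfs_without_pwm.tsv",
    )
    log.info(
        "scanned %d promoters with %d PWMs -> %d hits", len(common), len(pwms), len(hits)
    )
    return {"motif_hits": path, "n_hits": len(hits)}


@_timed("integrate")
def stage_integrate(cfg: PipelineConfig, run_dir: Path) -> dict:
    (cat_path,) = _require(cfg, "tf_catalog")
    de = _deg_sets(run_dir, cfg.de_fdr)
    ann = pd.read_csv(run_dir / "annotate" / "peak_annotations.tsv", sep="\t")
    out = run_dir / "integrate"
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    targets_a, summary = integ.classify_targets(ann, de["de_model_a"], cfg.de_fdr)
    paths["target_classes"] = _write(targets_a, out / "target_classes.tsv")

    catalog = pd.read_csv(cat_path, sep="\t")
    rdg_tfs = integ.identify_rdg_tfs(targets_a, de["de_model_b"], catalog, cfg.de_fdr)
    paths["rdg_tfs"] = _write(rdg_tfs, out / "rdg_tfs.tsv")

    deg_a = set(de["de_model_a"].loc[de["de_model_a"]["padj"] < cfg.de_fdr, "gene_id"])
    deg_b = set(de["de_model_b"].loc[de["de_model_b"]["padj"] < cfg.de_fdr, "gene_id"])
    common_degs = deg_a & deg_b
    hits_path = run_dir / "scan" / "motif_hits.tsv"
    hits = (
        pd.read_csv(hits_path, sep="\t")
        if hits_path.exists()
        else pd.DataFrame(columns=["tf_id", "gene_id", "strand", "offset", "score", "p", "q"])
    )
    edges, tf_counts = integ.build_network(rdg_tfs, hits, common_degs, targets_a)
    paths["network_edges"] = _write(edges, out / "network_edges.tsv")
    paths["network_tf_counts"] = _write(tf_counts, out / "network_tf_counts.tsv")

    # common direct-target core: lncRNA-direct & TF-direct in model A,
    # deregulated by both knockdowns in model B
    lnc_direct_a = set(targets_a.loc[targets_a["target_class"] == "RDG", "gene_id"])
    chip_ann_path = run_dir / "annotate" / "chip_annotations.tsv"
    comm = None
    if chip_ann_path.exists() and "de_tf_model_b" in de:
        chip_ann = pd.read_csv(chip_ann_path, sep="\t")
        tf_direct_a = set(chip_ann["gene_id"].dropna())
        tfb = de["de_tf_model_b"]
        tf_deg_b = set(tfb.loc[tfb["padj"] < cfg.de_fdr, "gene_id"])
        comm = integ.common_direct_targets(lnc_direct_a, tf_direct_a, deg_b, tf_deg_b)
        paths["comm_dgs"] = _write(comm, out / "comm_dgs.tsv")
        summary["n_comm_dg"] = int(comm["is_common_direct"].sum())

    # pairwise correlation of the coherent TFs across model-A samples
    if len(rdg_tfs) >= 2:
        cm = CountMatrix.from_tsv(cfg.inputs.counts_model_a)
        from .diffexpr import size_factors

        norm = cm.counts / size_factors(cm)
        expr = norm.loc[[g for g in rdg_tfs["gene_id"] if g in norm.index]]
        if expr.shape[0] >= 2 and expr.shape[1] >= 4:
            R, P, sig = integ.spearman_matrix(expr)
            Rr = R.reset_index().rename(columns={"index": "gene_id"})
            Pr = P.reset_index().rename(columns={"index": "gene_id"})
            paths["spearman_r"] = _write(Rr, out / "spearman_r.tsv")
            paths["spearman_p"] = _write(Pr, out / "spearman_p.tsv")

    summary["n_rdg_tf"] = int((rdg_tfs["role"] == "tf").sum())
    summary["n_rdg_cofactor"] = int((rdg_tfs["role"] == "cofactor").sum())
    summary["n_network_edges"] = len(edges)
    summary["n_common_deg"] = len(common_degs)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    paths["summary"] = str(out / "summary.json")
    log.info(
        "classified: %d DEG = %d RDG + %d RIG; %d coherent TFs/co-factors; %d edges",
        summary["n_deg"], summary["n_rdg"], summary["n_rig"],
        len(rdg_tfs), len(edges),
    )
    return paths


@_timed("enrich")
def stage_enrich(cfg: PipelineConfig, run_dir: Path) -> dict:
    (gmt_path,) = _require(cfg, "gene_sets_gmt")
    de = _deg_sets(run_dir, cfg.de_fdr)
    targets = pd.read_csv(run_dir / "integrate" / "target_classes.tsv", sep="\t")
    rdgs = sorted(targets.loc[targets["target_class"] == "RDG", "gene_id"])
    out = run_dir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    gene_sets = enr.read_gmt(gmt_path)
    universe = set(de["de_model_a"]["gene_id"])
    if not rdgs:
        paths["enrichment"] = _write(
            pd.DataFrame(
                columns=["term_id", "term_name", "k", "K", "n", "N", "p", "genes",
                         "padj", "significant"]
            ),
            out / "enrichment.tsv",
        )
        return paths
    res = enr.ora(rdgs, gene_sets, universe, alpha=cfg.enrich_alpha)
    paths["enrichment"] = _write(res, out / "enrichment.tsv")
    sig_terms = list(res.loc[res["significant"], "term_id"])
    if sig_terms:
        sets = {t: gene_sets[t][1] & universe for t in sig_terms}
        J = enr.jaccard_matrix(sets)
        clusters = enr.cluster_terms(
            J, cfg.jaccard_edge_min, term_sizes={t: len(s) for t, s in sets.items()}
        )
        paths["term_clusters"] = _write(
            pd.DataFrame(
                [
                    {
                        "cluster_id": c.cluster_id,
                        "representative": c.representative,
                        "members": ";".join(c.members),
                    }
                    for c in clusters
                ]
            ),
            out / "term_clusters.tsv",
        )
    log.info("enrichment: %d terms tested, %d significant", len(res), len(sig_terms))
    return paths


@_timed("quant")
def stage_quant(cfg: PipelineConfig, run_dir: Path) -> dict:
    path = cfg.inputs.qpcr_table
    if not path or not Path(path).exists():
        return {}
    df = pd.read_csv(path, sep="\t")
    out = run_dir / "quant"
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for gene, sub in df.groupby("gene_id"):
        ref_cols = [c for c in sub.columns if c.startswith("ct_ref")]
        samples = [
            QPCRMeasurement(
                target_ct=row["ct_target"],
                reference_cts=[row[c] for c in ref_cols],
                condition=row["condition"],
                replicate=str(row["replicate"]),
            )
            for _, row in sub.iterrows()
        ]
        rel = ddct_relative_expression(samples, control_condition="control")
        rel.insert(0, "gene_id", gene)
        frames.append(rel)
    res = pd.concat(frames, ignore_index=True)
    return {"relative_expression": _write(res, out / "relative_expression.tsv")}


@_timed("report")
def stage_report(cfg: PipelineConfig, run_dir: Path, paths: dict) -> dict:
    with open(run_dir / "integrate" / "summary.json") as fh:
        summary = json.load(fh)
    # internal consistency of the cascade's bookkeeping
    if summary["n_deg"] != summary["n_rdg"] + summary["n_rig"]:
        raise AssertionError("summary inconsistency: |DEG| != |RDG| + |RIG|")
    if summary["n_deg"] != summary["n_up"] + summary["n_down"]:
        raise AssertionError("summary inconsistency: |DEG| != |up| + |down|")
    if "n_comm_dg" in summary:
        comm = pd.read_csv(run_dir / "integrate" / "comm_dgs.tsv", sep="\t")
        targets = pd.read_csv(run_dir / "integrate" / "target_classes.tsv", sep="\t")
        rdg = set(targets.loc[targets["target_class"] == "RDG", "gene_id"])
        members = set(comm.loc[comm["is_common_direct"], "gene_id"])
        if not members <= rdg:
            raise AssertionError("comm_DGs must be a subset of the direct targets")
    report = {"summary": summary, "outputs": {k: str(v) for k, v in paths.items()}}
    with open(run_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return {"run_report": str(run_dir / "run_report.json"), **summary}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig, run_dir: Optional[str | Path] = None) -> RunReport:
    """Execute all stages; returns paths of stage outputs and summary counts."""
    if run_dir is None:
        if cfg.output_dir is None:
            raise ValueError("config.output_dir or run_dir must be set")
        run_dir = cfg.output_dir
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")

    paths: dict = {}
    if cfg.simulate is not None:
        cfg = stage_simulate(cfg, run_dir)
        cfg.to_yaml(run_dir / "config.yaml")  # persist resolved input paths
    paths.update(stage_consensus(cfg, run_dir))
    paths.update(stage_annotate(cfg, run_dir))
    paths.update(stage_de(cfg, run_dir))
    paths.update(stage_scan(cfg, run_dir))
    paths.update(stage_integrate(cfg, run_dir))
    paths.update(stage_enrich(cfg, run_dir))
    paths.update(stage_quant(cfg, run_dir))
    summary = stage_report(cfg, run_dir, paths)
    return RunReport(run_dir=str(run_dir), paths=paths, summary=summary)
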