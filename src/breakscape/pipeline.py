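"""End-to-end orchestration: simulate -> features -> motif -> enrich -> score -> qpcr.

A YAML config either carries a ``simulate:`` block (synthetic inputs are
generated into the output directory) or an ``inputs:`` block of explicit
file paths — never both.  Every stage writes its outputs under the output
directory and the run ends with a single TSV report of headline statistics
plus a machine-readable JSON manifest (config hash, input checksums,
per-stage outputs).  Identical configs reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .break_enrichment import (
    enrichment_ratio,
    four_set_density,
    fraction_in_regions,
    genes_with_break,
    motif_proximity,
    sample_overlap_fraction,
    select_top_expressed,
    tss_profile,
)
from .feature_builder import build_features
from .genome_model import GenomicInterval, merge
from .io_formats import (
    SequenceSource,
    read_breaks_bed,
    read_expression_table,
    read_gene_annotation,
    read_gene_list,
    read_peaks_bed,
    read_pwm_jaspar,
    write_breaks_bed,
    write_expression_table,
    write_fasta,
    write_gene_annotation,
    write_peaks_bed,
    write_pwm_jaspar,
    write_regions_bed,
)
from .motif_scan import scan_regions, write_hits_bed
from .qpcr import copies_from_ct, fit_standard_curve, stoichiometry_report
from .signature_scores import (
    log2_pseudocount,
    quartile_dichotomize,
    signature_score,
    zscore_genes,
)
from .synthetic import (
    QpcrConfig,
    SyntheticConfig,
    generate_breaks,
    generate_ct_series,
    generate_genome,
    generate_stoichiometry_cts,
    synthetic_are_pfm,
)

log = logging.getLogger(__name__)

DEFAULT_PARAMS: Dict[str, Any] = {
    "expression_threshold": 1.0,
    "promoter_flank_bp": 2000,
    "enhancer_top_n": 200,
    "insulator_top_n": 300,
    "min_tss_distance_bp": 2000,
    "motif_threshold_fraction": 1.0,
    "overlap_windows": [0, 8, 100],
    "profile_window_bp": 200,
    "profile_bin_bp": 20,
    "top_k_genes": 100,
    "proximity_distance_bp": 50,
    "signature_size": 30,
    "reference_sample": None,  # default: first expression column
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    version: str
    input_checksums: Dict[str, str]
    stage_outputs: Dict[str, List[str]]
    summary: Dict[str, float]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} does not contain a mapping")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise PipelineError(
            "config", "exactly one of 'simulate' or 'inputs' must be present"
        )
    return cfg


def _build_synthetic_config(block: Mapping[str, Any], seed: int) -> SyntheticConfig:
    block = dict(block or {})
    qpcr = QpcrConfig(**block.pop("qpcr", {}))
    if "chrom_lengths" in block:
        block["chrom_lengths"] = {str(k): int(v) for k, v in block["chrom_lengths"].items()}
    for tuple_key in ("gene_length_range", "expression_lognormal"):
        if tuple_key in block:
            block[tuple_key] = tuple(block[tuple_key])
    return SyntheticConfig(seed=seed, qpcr=qpcr, **block)


def _simulate_stage(cfg: Dict[str, Any], out: Path, rng: np.random.Generator) -> Dict[str, Path]:
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    scfg = _build_synthetic_config(cfg.get("simulate"), seed=int(cfg.get("seed", 0)))
    genome = generate_genome(scfg, rng)
    treated = generate_breaks(scfg, genome, rng, sample="treated", enriched=True)
    comparison = generate_breaks(scfg, genome, rng, sample="comparison", enriched=True)
    background = generate_breaks(
        scfg, genome, rng, sample="background", enriched=False,
        rate_scale=scfg.null_rate_scale,
    )
    dil_n = generate_ct_series(scfg, rng, assay="norad")
    dil_m = generate_ct_series(scfg, rng, assay="mir")
    cts = generate_stoichiometry_cts(scfg, rng)

    paths = {
        "fasta": sim_dir / "genome.fa",
        "genes": sim_dir / "genes.tsv",
        "expression": sim_dir / "expression.tsv",
        "breaks": sim_dir / "breaks_treated.bed",
        "comparison_breaks": sim_dir / "breaks_comparison.bed",
        "background_breaks": sim_dir / "breaks_background.bed",
        "h3k27ac": sim_dir / "h3k27ac.bed",
        "ctcf": sim_dir / "ctcf.bed",
        "pwm": sim_dir / "are_synthetic.pfm",
        "qpcr_dilutions": sim_dir / "dilutions.tsv",
        "qpcr_samples": sim_dir / "sample_cts.tsv",
        "nas_genes": sim_dir / "nas_genes.txt",
        "ddr_genes": sim_dir / "ddr_genes.txt",
        "truth": sim_dir / "truth.json",
    }
    write_fasta(genome.sequences, paths["fasta"])
    write_gene_annotation(genome.genes, paths["genes"])
    write_expression_table(genome.expression, paths["expression"])
    write_breaks_bed(treated, paths["breaks"])
    write_breaks_bed(comparison, paths["comparison_breaks"])
    write_breaks_bed(background, paths["background_breaks"])
    write_peaks_bed(genome.h3k27ac_peaks, paths["h3k27ac"])
    write_peaks_bed(genome.ctcf_peaks, paths["ctcf"])
    write_pwm_jaspar(synthetic_are_pfm(), paths["pwm"])
    import pandas as pd

    pd.concat([dil_n, dil_m]).to_csv(paths["qpcr_dilutions"], sep="\t", index=False)
    pd.DataFrame(sorted(cts.items()), columns=["measurement", "ct"]).to_csv(
        paths["qpcr_samples"], sep="\t", index=False
    )
    # stand-in signature gene lists: random gene subsets of the synthetic genome
    size = int(cfg.get("params", {}).get("signature_size", DEFAULT_PARAMS["signature_size"]))
    gene_ids = [g.gene_id for g in genome.genes]
    nas = sorted(rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False))
    ddr = sorted(rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False))
    paths["nas_genes"].write_text("\n".join(nas) + "\n")
    paths["ddr_genes"].write_text("\n".join(ddr) + "\n")
    truth = {
        "expected_break_total": genome.truth.expected_break_total,
        "rho_tss": scfg.rho_tss,
        "rho_are": scfg.rho_are,
        "top_gene_ids": genome.truth.top_gene_ids,
        "are_positive_gene_ids": genome.truth.are_positive_gene_ids,
        "qpcr_slope": genome.truth.qpcr_slope,
        "qpcr_intercept": genome.truth.qpcr_intercept,
        "cells_per_reaction": scfg.qpcr.cells_per_reaction,
        "sites_per_norad": scfg.qpcr.sites_per_norad,
        "chrom_lengths": scfg.chrom_lengths,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths


def _require(inputs: Mapping[str, Any], key: str, stage: str) -> Path:
    if key not in inputs:
        raise PipelineError(stage, f"missing required input {key!r}")
    p = Path(inputs[key])
    if not p.exists():
        raise PipelineError(stage, f"input file not found: {p}")
    return p


def run_pipeline(config_path, out_dir) -> Tuple[RunManifest, Path]:
    """Run every stage; returns (manifest, report path)."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    rng = np.random.default_rng(seed)
    params = {**DEFAULT_PARAMS, **(cfg.get("params") or {})}
    stage_outputs: Dict[str, List[str]] = {}

    if "simulate" in cfg:
        inputs = {k: str(v) for k, v in _simulate_stage(cfg, out, rng).items()}
        stage_outputs["simulate"] = sorted(inputs.values())
    else:
        inputs = dict(cfg["inputs"])

    report_rows: List[Tuple[str, str]] = []
    summary: Dict[str, float] = {}

    def add(metric: str, value, fmt: str = "%.6g") -> None:
        report_rows.append((metric, fmt % value if isinstance(value, float) else str(value)))
        if isinstance(value, (int, float)):
            summary[metric] = float(value)

    # ---- load shared inputs -------------------------------------------------
    stage = "load"
    try:
        genes = read_gene_annotation(
            _require(inputs, "genes", stage),
            dialect=inputs.get("annotation_dialect", "tabular"),
        )
        expression = read_expression_table(_require(inputs, "expression", stage))
        breaks, n_wide = read_breaks_bed(_require(inputs, "breaks", stage), sample="treated")
        if n_wide:
            log.warning("%d break records wider than 1 bp reduced to their start", n_wide)
        h3k27ac = read_peaks_bed(_require(inputs, "h3k27ac", stage))
        ctcf = read_peaks_bed(_require(inputs, "ctcf", stage))
        pwm = read_pwm_jaspar(_require(inputs, "pwm", stage))
        fasta = SequenceSource(_require(inputs, "fasta", stage))
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive re-labelling
        raise PipelineError(stage, str(exc)) from exc

    ref_sample = params["reference_sample"] or expression.samples[0]
    chrom_lengths = {c: fasta.length(c) for c in fasta.chroms}
    add("n_genes", len(genes))
    add("n_breaks_treated", len(breaks))

    # ---- features + motif ---------------------------------------------------
    stage = "features"
    try:
        from .feature_builder import define_enhancers, define_insulators, define_promoters

        promoters = define_promoters(
            genes, expression, ref_sample,
            expression_threshold=params["expression_threshold"],
            flank_bp=params["promoter_flank_bp"],
            chrom_lengths=chrom_lengths,
        )
        enhancers = define_enhancers(
            h3k27ac, [(g.chrom, g.tss) for g in genes],
            top_n=params["enhancer_top_n"],
            min_tss_distance_bp=params["min_tss_distance_bp"],
        )
        insulators = define_insulators(
            ctcf, promoters, enhancers, top_n=params["insulator_top_n"]
        )
        scan_targets = merge(
            list(promoters.intervals()) + list(enhancers.intervals()), name="scan"
        )
        hits, n_short = scan_regions(
            scan_targets, fasta, pwm,
            threshold_fraction=params["motif_threshold_fraction"],
        )
        from .feature_builder import FeatureClasses, partition_by_are

        pp, pn = partition_by_are(promoters, hits)
        ep, en = partition_by_are(enhancers, hits)
        features = FeatureClasses(promoters, enhancers, insulators, pp, pn, ep, en)
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        outs = []
        for label, rs in {
            "promoters": promoters, "enhancers": enhancers, "insulators": insulators,
            "are_pos_promoters": pp, "are_neg_promoters": pn,
            "are_pos_enhancers": ep, "are_neg_enhancers": en,
        }.items():
            p = feat_dir / f"{label}.bed"
            write_regions_bed(rs, p)
            outs.append(str(p))
        hits_path = feat_dir / "are_hits.bed"
        write_hits_bed(hits, hits_path)
        outs.append(str(hits_path))
        stage_outputs["features"] = outs
        add("n_are_hits", len(hits))
        add("promoter_total_bp", promoters.total_bp)
        add("enhancer_total_bp", enhancers.total_bp)
        add("insulator_total_bp", insulators.total_bp)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- enrichment ---------------------------------------------------------
    stage = "enrich"
    try:
        if "comparison_breaks" in inputs:
            comparison, _ = read_breaks_bed(
                Path(inputs["comparison_breaks"]), sample="comparison"
            )
            for w in params["overlap_windows"]:
                add(f"overlap_fraction_w{w}",
                    sample_overlap_fraction(breaks, comparison, int(w)))
        dens = four_set_density(breaks, features)
        for label, d in dens.items():
            key = label.replace(" ", "_").replace("+", "pos").replace("-", "neg")
            add(f"density_per_kb_{key}", d.density_per_kb)
        if dens["ARE- promoters"].break_count:
            add("promoter_are_density_ratio",
                dens["ARE+ promoters"].density_per_kb
                / dens["ARE- promoters"].density_per_kb)
        if dens["ARE- enhancers"].break_count:
            add("enhancer_are_density_ratio",
                dens["ARE+ enhancers"].density_per_kb
                / dens["ARE- enhancers"].density_per_kb)
        prof_all = tss_profile(
            breaks, genes,
            window_bp=params["profile_window_bp"], bin_bp=params["profile_bin_bp"],
        )
        top = select_top_expressed(genes, expression, ref_sample, params["top_k_genes"])
        prof_top = tss_profile(
            breaks, top,
            window_bp=params["profile_window_bp"], bin_bp=params["profile_bin_bp"],
        )
        add("tss_per_100kb_all_genes", prof_all.per_100kb)
        add(f"tss_per_100kb_top{params['top_k_genes']}", prof_top.per_100kb)
        if prof_all.per_100kb > 0:
            add("tss_enrichment_top_vs_all", prof_top.per_100kb / prof_all.per_100kb)
        gwb = genes_with_break(breaks, genes)
        add("genes_with_break_percent", gwb.percent, fmt="%.1f")
        bodies = merge([g.body for g in genes], name="gene_bodies")
        add("fraction_breaks_in_gene_bodies", fraction_in_regions(breaks, bodies))
        if "background_breaks" in inputs:
            background, _ = read_breaks_bed(
                Path(inputs["background_breaks"]), sample="background"
            )
            f_treated = motif_proximity(breaks, hits, params["proximity_distance_bp"])
            f_background = motif_proximity(
                background, hits, params["proximity_distance_bp"]
            )
            add("motif_proximity_treated", f_treated)
            add("motif_proximity_background", f_background)
            if f_background > 0:
                add("motif_proximity_enrichment",
                    enrichment_ratio(f_treated, f_background))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- signature scores ---------------------------------------------------
    stage = "score"
    try:
        z, n_dropped = zscore_genes(log2_pseudocount(expression))
        add("n_constant_genes_dropped", n_dropped)
        for sig_key, sig_name in (("nas_genes", "NAS"), ("ddr_genes", "DDR")):
            if sig_key not in inputs:
                continue
            gene_set = read_gene_list(Path(inputs[sig_key]))
            score = signature_score(z, gene_set, signature_name=sig_name)
            add(f"{sig_name.lower()}_score_mean",
                float(score.per_sample_scores.mean()))
            add(f"{sig_name.lower()}_score_sd",
                float(score.per_sample_scores.std(ddof=1)))
            if sig_name == "NAS" and len(score.per_sample_scores) >= 4:
                high, low, _mid = quartile_dichotomize(score.per_sample_scores)
                add("nas_high_n", len(high))
                add("nas_low_n", len(low))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- qPCR stoichiometry -------------------------------------------------
    stage = "qpcr"
    try:
        if "qpcr_dilutions" in inputs:
            import pandas as pd

            dil = pd.read_csv(Path(inputs["qpcr_dilutions"]), sep="\t")
            curves = {
                assay: fit_standard_curve(sub["copies"], sub["ct"])
                for assay, sub in dil.groupby("assay")
            }
            for assay, curve in sorted(curves.items()):
                add(f"qpcr_slope_{assay}", curve.slope)
                add(f"qpcr_efficiency_{assay}", curve.efficiency)
            if "qpcr_samples" in inputs and "truth" in inputs:
                samples = pd.read_csv(Path(inputs["qpcr_samples"]), sep="\t")
                ct = dict(zip(samples["measurement"], samples["ct"]))
                truth = json.loads(Path(inputs["truth"]).read_text())
                cells = float(truth["cells_per_reaction"])
                norad = copies_from_ct(curves["norad"], ct["norad_unperturbed"], cells)
                mir = copies_from_ct(curves["mir"], ct["mir_unperturbed"], cells)
                norad_sil = copies_from_ct(curves["norad"], ct["norad_silenced"], cells)
                mir_sil = copies_from_ct(curves["mir"], ct["mir_silenced"], cells)
                rep = stoichiometry_report(
                    norad, mir,
                    sites_per_norad=int(truth["sites_per_norad"]),
                    mir_copies_gained=mir_sil - mir,
                    norad_copies_lost=norad - norad_sil,
                )
                add("norad_copies_per_cell", rep.norad_copies_per_cell)
                add("mir_copies_per_cell", rep.mir_copies_per_cell)
                add("tdmd_site_to_mir_ratio", rep.site_to_mir_ratio)
                if rep.turnover_per_norad is not None:
                    add("tdmd_turnover_per_norad", rep.turnover_per_norad)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- report + manifest --------------------------------------------------
    report_path = out / "report.tsv"
    with open(report_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for metric, value in report_rows:
            fh.write(f"{metric}\t{value}\n")
    checksums = {
        k: _sha256(Path(v)) for k, v in sorted(inputs.items()) if Path(str(v)).is_file()
    }
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        version=__version__,
        input_checksums=checksums,
        stage_outputs=stage_outputs,
        summary=summary,
    )
    manifest.write(out / "manifest.json")
    return manifest, report_path
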