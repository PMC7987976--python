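"""End-to-end pipeline orchestration, representation QC, and cross-method
concordance.

The pipeline follows the published analysis order: quantify (or load/simulate
counts) -> control-minimum filter on raw counts -> total normalization ->
removal of all-zero guides -> percentile hit calling and joint-model ranking
-> QC and a concordance section listing genes top-ranked by both methods.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from guidescreen import counts as cp
from guidescreen import joint as jm
from guidescreen import percentile as pm
from guidescreen.counts import CountMatrix
from guidescreen.library import GuideLibrary, build_synthetic_library, read_library, write_library
from guidescreen.quantify import SampleSheet, quantify_fastq
from guidescreen.simulate import (
    CONTROL_GROUP,
    ScreenDesign,
    SelectionProfile,
    simulate_screen,
)

log = logging.getLogger("guidescreen")


class WorkflowError(ValueError):
    pass


@dataclass
class RepresentationReport:
    per_sample: pd.DataFrame  # sample_id, group, fraction_detected
    per_group: pd.DataFrame  # group, mean, sd, union_fraction, n_samples
    min_reads: int


def representation_fraction(
    cm: CountMatrix, lib: GuideLibrary, min_reads: int = 1
) -> RepresentationReport:
    """Per-sample fraction of library guides with count >= min_reads, plus
    group mean/SD and the union coverage across each group's samples."""
    if lib.n_total == 0:
        raise WorkflowError("empty library")
    unknown = set(cm.guide_ids) - set(lib.guide_ids)
    if unknown:
        raise WorkflowError(f"matrix guides not in library: {sorted(unknown)[:5]}")
    detected = cm.values >= min_reads
    frac = detected.sum(axis=0) / lib.n_total
    rows = [
        dict(sample_id=s, group=cm.sample_groups.get(s, ""), fraction_detected=float(frac[s]))
        for s in cm.values.columns
    ]
    per_sample = pd.DataFrame(rows)
    grows = []
    for group, sub in per_sample.groupby("group"):
        samples = sub["sample_id"].tolist()
        union = detected[samples].any(axis=1).sum() / lib.n_total
        grows.append(
            dict(
                group=group,
                mean=float(sub["fraction_detected"].mean()),
                sd=float(sub["fraction_detected"].std(ddof=1)) if len(sub) > 1 else 0.0,
                union_fraction=float(union),
                n_samples=len(sub),
            )
        )
    return RepresentationReport(per_sample, pd.DataFrame(grows), min_reads)


def enrichment_profile(cm: CountMatrix, k: int = 10) -> pd.DataFrame:
    """Abundance share of each sample's top-k guides (clonal-dominance QC)."""
    rows = []
    for s in cm.values.columns:
        col = cm.values[s].to_numpy(dtype=float)
        total = col.sum()
        if total == 0:
            share = 0.0
        else:
            kk = min(k, len(col))
            share = float(np.sort(col)[-kk:].sum() / total)
        rows.append(dict(sample_id=s, group=cm.sample_groups.get(s, ""), top_k_share=share, k=k))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed for a deterministic end-to-end run."""

    out_dir: str = "guidescreen_out"
    seed: int = 0
    # inputs (exactly one of: simulate block, fastq paths, counts TSV)
    library_path: str | None = None
    sample_sheet_path: str | None = None
    fastq_paths: list[str] = field(default_factory=list)
    counts_path: str | None = None
    simulate: dict | None = None  # {"design": {...}, "selection": {...}, "library": {...}}
    # quantification offsets
    barcode_offset: int = 0
    spacer_offset: int = 30
    # processing parameters (defaults follow the published analysis)
    min_reads: int = 30
    pct: float = 98.0
    min_samples: int = 2
    alpha: float = 0.5
    control_group: str = CONTROL_GROUP
    hit_group: str = "lung_19d"
    ref_group: str = "lung_4h"
    top_n: int = 10
    tol: float = 1e-9
    max_iter: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise WorkflowError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _build_simulation(cfg: PipelineConfig):
    block = cfg.simulate or {}
    libspec = block.get("library", {})
    lib = build_synthetic_library(
        n_genes=libspec.get("n_genes", 2195),
        guides_per_gene=libspec.get("guides_per_gene", 5),
        n_controls=libspec.get("n_controls", 250),
        protospacer_length=libspec.get("protospacer_length", 20),
        seed=cfg.seed,
    )
    design = ScreenDesign(**{k: v for k, v in block.get("design", {}).items()})
    sel_kwargs = dict(block.get("selection", {}))
    n_planted = sel_kwargs.pop("n_planted", 0)
    planted_beta = sel_kwargs.pop("planted_beta", 0.5)
    if n_planted:
        rng = np.random.default_rng(cfg.seed + 1)
        genes = sorted({g.gene for g in lib if not g.is_control})
        planted = list(rng.choice(genes, size=n_planted, replace=False))
        sel_kwargs.setdefault("gene_effect", {})
        for g in planted:
            sel_kwargs["gene_effect"][g] = planted_beta
    sel = SelectionProfile(**sel_kwargs)
    screen = simulate_screen(design, sel, lib, cfg.seed)
    return lib, screen


def concordant_genes(
    percentile_gene_table: pd.DataFrame, joint_ranking: pd.DataFrame, top_n: int = 10
) -> list[str]:
    """Genes present in the top-N of both methods (order-independent)."""
    top_p = set(percentile_gene_table.head(top_n)["gene"]) if len(percentile_gene_table) else set()
    top_j = set(joint_ranking.head(top_n)["gene"]) if len(joint_ranking) else set()
    return sorted(top_p & top_j)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle to cfg.out_dir.

    Returns a dict with every intermediate object plus the machine-readable
    summary that is also written to report.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    summary: dict = {"seed": cfg.seed, "stages": {}}
    try:
        # ---- inputs ----
        stage = "inputs"
        truth = None
        sheet_df = None
        if cfg.simulate is not None:
            lib, screen = _build_simulation(cfg)
            raw = screen.counts
            truth = screen.truth
            sheet_df = screen.sample_sheet
            write_library(lib, out / "library.csv")
            sheet_df.to_csv(out / "sample_sheet.csv", index=False)
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1, default=str)
        else:
            if cfg.library_path is None:
                raise WorkflowError("library_path required when not simulating")
            lib = read_library(cfg.library_path)
            if cfg.fastq_paths:
                if cfg.sample_sheet_path is None:
                    raise WorkflowError("sample_sheet_path required for FASTQ input")
                sheet = SampleSheet.read_csv(cfg.sample_sheet_path)
                sheet_df = sheet.records
                raw, demux_summary, concordance = quantify_fastq(
                    cfg.fastq_paths, sheet, lib, cfg.barcode_offset, cfg.spacer_offset
                )
                demux_summary.to_csv(out / "demux_summary.tsv", sep="\t", index=False)
                if len(concordance):
                    concordance.to_csv(out / "duplicate_concordance.tsv", sep="\t", index=False)
            elif cfg.counts_path:
                groups = {}
                if cfg.sample_sheet_path:
                    sheet = SampleSheet.read_csv(cfg.sample_sheet_path)
                    sheet_df = sheet.records
                    groups = sheet.groups()
                raw = CountMatrix.read_tsv(cfg.counts_path, sample_groups=groups)
            else:
                raise WorkflowError("no input: set simulate, fastq_paths or counts_path")
        raw.write_tsv(out / "counts_raw.tsv")
        summary["stages"]["inputs"] = dict(n_guides=raw.values.shape[0], n_samples=raw.values.shape[1])
        log.info("inputs: %d guides x %d samples", *raw.values.shape)

        # ---- processing ----
        stage = "filter"
        control_ids = raw.samples_in_group(cfg.control_group)
        if not control_ids:
            raise WorkflowError(f"no samples in control group {cfg.control_group!r}")
        filtered, removed_low = cp.filter_by_control_minimum(raw, control_ids, cfg.min_reads)
        (out / "removed_low_control.txt").write_text("\n".join(removed_low) + ("\n" if removed_low else ""))
        summary["stages"]["filter"] = dict(min_reads=cfg.min_reads, removed=len(removed_low),
                                           remaining=filtered.values.shape[0])

        stage = "normalize"
        normed = cp.total_normalize(filtered)
        normed.size_factors.to_csv(out / "size_factors.tsv", sep="\t", header=["size_factor"])

        stage = "drop_absent"
        normed, removed_absent = cp.drop_absent_guides(normed)
        (out / "removed_absent.txt").write_text("\n".join(removed_absent) + ("\n" if removed_absent else ""))
        normed.write_tsv(out / "counts_normalized.tsv")
        summary["stages"]["drop_absent"] = dict(removed=len(removed_absent),
                                                remaining=normed.values.shape[0])

        # ---- percentile method ----
        stage = "percentile"
        pres = pm.call_percentile_hits(
            normed, control=cfg.control_group, hit_group=cfg.hit_group,
            pct=cfg.pct, min_samples=cfg.min_samples,
        )
        pres["zmatrix"].z.round(6).to_csv(out / "zscores.tsv", sep="\t")
        membership = [
            dict(sample_id=s, guide_id=g, z=float(pres["zmatrix"].z.loc[g, s]))
            for s, gs in sorted(pres["sets"].items())
            for g in sorted(gs)
        ]
        pd.DataFrame(membership, columns=["sample_id", "guide_id", "z"]).to_csv(
            out / "percentile_membership.tsv", sep="\t", index=False
        )
        pres["hit_table"].to_csv(out / "percentile_hits.tsv", sep="\t", index=False)
        pres["gene_table"].to_csv(out / "percentile_genes.tsv", sep="\t", index=False)
        summary["stages"]["percentile"] = dict(n_hits=len(pres["hit_table"]))

        # ---- joint model ----
        stage = "joint"
        joint_ranking = None
        fit = None
        lung_conditions = {g for s, g in normed.sample_groups.items()
                           if g != cfg.control_group and s in normed.values.columns}
        if {cfg.hit_group, cfg.ref_group} <= lung_conditions:
            lfm = jm.compute_log_ratios(normed, cfg.control_group, cfg.alpha)
            fit = jm.fit_joint_model(lfm, tol=cfg.tol, max_iter=cfg.max_iter)
            joint_ranking = jm.rank_genes(fit, test=cfg.hit_group, ref=cfg.ref_group)
            joint_ranking.to_csv(out / "joint_genes.tsv", sep="\t", index=False)
            guide_tab = pd.DataFrame(
                dict(guide_id=fit.guide_efficacy.index,
                     gene=normed.genes.reindex(fit.guide_efficacy.index).to_numpy(),
                     x=fit.guide_efficacy.to_numpy(),
                     sd_x=fit.guide_efficacy_sd.to_numpy())
            )
            guide_tab.to_csv(out / "joint_guides.tsv", sep="\t", index=False)
            with open(out / "joint_fit.json", "w") as fh:
                json.dump(dict(n_iter=fit.n_iter, converged=fit.converged,
                               noise_variance=fit.noise_variance, tol=cfg.tol), fh, indent=1)
            summary["stages"]["joint"] = dict(converged=fit.converged, n_iter=fit.n_iter)
        else:
            log.warning("joint model skipped: need both %r and %r lung groups",
                        cfg.hit_group, cfg.ref_group)
            summary["stages"]["joint"] = dict(skipped=True)

        # ---- QC ----
        stage = "qc"
        rep = representation_fraction(raw, lib, min_reads=1)
        rep.per_sample.to_csv(out / "representation_per_sample.tsv", sep="\t", index=False)
        rep.per_group.to_csv(out / "representation_per_group.tsv", sep="\t", index=False)
        enr = enrichment_profile(raw, k=10)
        enr.to_csv(out / "enrichment_topk.tsv", sep="\t", index=False)
        summary["stages"]["qc"] = dict(
            group_representation={r["group"]: round(r["mean"], 4) for _, r in rep.per_group.iterrows()}
        )

        # ---- concordance ----
        stage = "concordance"
        if joint_ranking is not None:
            both = concordant_genes(pres["gene_table"], joint_ranking, cfg.top_n)
        else:
            both = []
        summary["concordant_genes"] = both
        summary["ok"] = True
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        _write_report_md(out, summary, pres, joint_ranking, rep)
        return dict(
            library=lib, raw=raw, filtered=filtered, normalized=normed,
            percentile=pres, joint_fit=fit, joint_ranking=joint_ranking,
            representation=rep, enrichment=enr, concordant_genes=both,
            truth=truth, summary=summary, sample_sheet=sheet_df,
        )
    except Exception as exc:
        raise WorkflowError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_report_md(out: Path, summary: dict, pres: dict,
                     joint_ranking: pd.DataFrame | None, rep: RepresentationReport) -> None:
    lines = ["# Screen analysis report", ""]
    lines.append(f"Seed: {summary['seed']}")
    for name, info in summary["stages"].items():
        lines.append(f"- **{name}**: {info}")
    lines.append("")
    lines.append("## Representation (fraction of library detected)")
    for _, r in rep.per_group.iterrows():
        lines.append(f"- {r['group']}: mean {r['mean']:.3f} (sd {r['sd']:.3f}), "
                     f"union {r['union_fraction']:.3f} over {int(r['n_samples'])} samples")
    lines.append("")
    lines.append("## Top percentile-method genes")
    for _, r in pres["gene_table"].head(10).iterrows():
        lines.append(f"- {r['gene']}: best guide in {r['best_guide_recurrence']} samples "
                     f"({r['n_guides_in_sets']} distinct guides)")
    if joint_ranking is not None:
        lines.append("")
        lines.append("## Top joint-model genes (by effect contrast d)")
        for _, r in joint_ranking.head(10).iterrows():
            lines.append(f"- {r['gene']}: d = {r['d']:.3f}, z = {r['z']:.2f}")
    lines.append("")
    lines.append(f"## Concordant genes (top-{summary.get('top_n', 10)} of both methods)")
    lines.append(", ".join(summary["concordant_genes"]) or "(none)")
    (out / "report.md").write_text("\n".join(lines) + "\n")
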