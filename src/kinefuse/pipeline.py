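"""End-to-end orchestration: detect -> cohort filters -> annotate -> report.

All outputs are deterministic for fixed inputs: files are written in sorted
order, contain no timestamps, and the run manifest records the full
configuration and a SHA-256 checksum of every emitted file.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import pandas as pd

from .annotate import VERDICT_DRIVER, FusionAnnotation, annotate_candidate
from .annotation import (ExpressionMatrix, GeneIndex, load_annotation,
                         load_expression, load_genome)
from .cohort import (CohortCallSet, NormalsPanel, apply_normals_panel,
                     cohort_summary, flag_improbable, select_recurrent_kinase)
from .config import FilterConfig
from .detect import (DetectionStats, FusionCandidate, HomologyIndex,
                     detect_sample, write_bedpe, write_candidates_tsv)
from .evidence import read_evidence

logger = logging.getLogger(__name__)


def _pkg_version() -> str:
    try:
        return version("kinefuse")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort", "evidence"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return sheet


RECURRENT_COLUMNS = ("kinase", "partner", "cohort", "sample_id", "gene5",
                     "gene3", "n_chimeric", "n_split", "breakpoint5",
                     "breakpoint3")


def write_recurrent_tsv(path: Path, recurrent: list[FusionCandidate]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RECURRENT_COLUMNS) + "\n")
        for c in recurrent:
            kinase = c.gene3 if c.gene3.is_kinase else c.gene5
            partner = c.gene5 if kinase is c.gene3 else c.gene3
            fh.write("\t".join([
                kinase.symbol, partner.symbol, c.cohort or ".", c.sample_id,
                c.gene5.gene_id, c.gene3.gene_id,
                str(c.n_chimeric), str(c.n_split),
                "." if c.breakpoint5 is None else str(c.breakpoint5 + 1),
                "." if c.breakpoint3 is None else str(c.breakpoint3 + 1),
            ]) + "\n")


def write_annotations(json_path: Path, tsv_path: Path,
                      annotations: list[FusionAnnotation]) -> None:
    records = [a.to_dict() for a in annotations]
    with open(json_path, "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cols = ("sample_id", "cohort", "symbol5", "symbol3", "junction_class",
            "frame_status", "kinase_gene", "kinase_domain_status",
            "partner_contrib_aa", "artifact_flags", "verdict")
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r["sample_id"], r["cohort"] or ".", r["symbol5"], r["symbol3"],
                r["junction_class"], r["frame_status"] or ".",
                r["kinase_gene"] or ".", r["kinase_domain_status"] or ".",
                str(r["partner_contrib_aa"]),
                ",".join(r["artifact_flags"]) or ".", r["verdict"],
            ]) + "\n")


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    callsets: list[CohortCallSet]
    recurrent: list[FusionCandidate]
    annotations: list[FusionAnnotation]
    summary: pd.DataFrame
    driver_pairs: set[tuple[str, str]] = field(default_factory=set)


def run_all(sample_sheet: str | Path, gtf: str | Path,
            registry: str | Path | None, fasta: str | Path | None,
            expression: str | Path | None, normals: str | Path | None,
            outdir: str | Path, config: Optional[FilterConfig] = None,
            seed: int = 0, mode: str = "kinase",
            paralogs=None) -> RunResult:
    """Run the full pipeline over a sample sheet and write all reports.

    ``normals`` may be a directory of per-normal evidence TSVs (the panel is
    then built with the identical detection procedure) or a precomputed
    panel TSV.  Reruns on identical inputs are byte-identical.
    """
    config = (config or FilterConfig()).validate()
    outdir = Path(outdir)
    (outdir / "candidates").mkdir(parents=True, exist_ok=True)
    (outdir / "breakpoints").mkdir(parents=True, exist_ok=True)

    sheet = read_sample_sheet(sample_sheet)
    sheet_dir = Path(sample_sheet).parent
    missing = [str(sheet_dir / e) for e in sheet["evidence"]
               if not (sheet_dir / e).exists()]
    if missing:
        raise FileNotFoundError(f"missing evidence files: {missing}")

    index = load_annotation(gtf, registry)
    genome = load_genome(fasta) if fasta else None
    expr: Optional[ExpressionMatrix] = (
        load_expression(expression, sample_sheet) if expression else None)
    homology = HomologyIndex(genome, config, paralogs or ())

    # ---- per-sample detection --------------------------------------------
    stage_counts = {"n_samples": len(sheet), "n_evidence": 0,
                    "n_candidates_retained": 0}
    by_cohort: dict[str, list[FusionCandidate]] = {}
    for _, row in sheet.sort_values("sample_id").iterrows():
        sample, cohort = row["sample_id"], row["cohort"]
        records = read_evidence(sheet_dir / row["evidence"], sample)
        stats = DetectionStats()
        all_cands = detect_sample(records, index, config, homology,
                                  include_filtered=True, stats=stats)
        stage_counts["n_evidence"] += stats.n_evidence
        retained = [c for c in all_cands if c.retained]
        stage_counts["n_candidates_retained"] += len(retained)
        write_candidates_tsv(outdir / "candidates" / f"{sample}.tsv", all_cands)
        write_bedpe(outdir / "breakpoints" / f"{sample}.bedpe", retained)
        by_cohort.setdefault(cohort, []).extend(retained)

    cohort_sizes = sheet.groupby("cohort")["sample_id"].nunique().to_dict()
    callsets = [CohortCallSet(cid, int(cohort_sizes[cid]), by_cohort.get(cid, []))
                for cid in sorted(cohort_sizes)]

    # ---- cohort filters ---------------------------------------------------
    callsets = [flag_improbable(cs, config) for cs in callsets]
    panel = NormalsPanel({})
    if normals:
        normals = Path(normals)
        if normals.is_dir():
            panel = NormalsPanel.from_evidence_files(
                sorted(normals.glob("*.tsv")), index, config, homology)
        else:
            panel = NormalsPanel.from_tsv(normals)
    panel.to_tsv(outdir / "normals_panel.tsv")
    filtered = [apply_normals_panel(cs, panel, config) for cs in callsets]
    stage_counts["n_after_normals"] = sum(
        sum(c.retained for c in cs.candidates) for cs in filtered)

    recurrent = select_recurrent_kinase(filtered, config, mode)
    stage_counts["n_recurrent_kinase"] = len(recurrent)
    write_recurrent_tsv(outdir / "recurrent_kinase.tsv", recurrent)

    # ---- functional annotation -------------------------------------------
    annotations = []
    for c in recurrent:
        annotations.append(annotate_candidate(
            c, genome, expr, config,
            recurrent=True, homologous=homology.is_homologous(c.gene5, c.gene3)))
    write_annotations(outdir / "annotations.json", outdir / "annotations.tsv",
                      annotations)
    driver_pairs = {(a.candidate.gene5.symbol, a.candidate.gene3.symbol)
                    for a in annotations if a.verdict == VERDICT_DRIVER}
    stage_counts["n_candidate_driver_pairs"] = len(driver_pairs)

    summary = cohort_summary(filtered, recurrent)
    summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False,
                   float_format="%.4f")

    # ---- manifest ---------------------------------------------------------
    outputs = sorted(str(p.relative_to(outdir))
                     for p in outdir.rglob("*")
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": _pkg_version(),
        "seed": seed,
        "mode": mode,
        "config": config.to_dict(),
        "inputs": {"sample_sheet": str(sample_sheet), "gtf": str(gtf),
                   "registry": str(registry) if registry else None,
                   "fasta": str(fasta) if fasta else None,
                   "expression": str(expression) if expression else None,
                   "normals": str(normals) if normals else None},
        "stage_counts": stage_counts,
        "outputs": {rel: _sha256(outdir / rel) for rel in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(outdir=outdir, manifest=manifest, callsets=filtered,
                     recurrent=recurrent, annotations=annotations,
                     summary=summary, driver_pairs=driver_pairs)
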