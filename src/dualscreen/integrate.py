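"""Pipeline driver: run both screening arms and intersect the focused lists.

One configuration object (loadable from YAML) carries every input path
and threshold.  Defaults follow the analysis the pipeline reproduces:
hits deconvoluted to targets and focused at k = 3 distinct chemicals;
deletion-recurrence genes focused at ~10% of the cohort (ceil); both
arms' gene lists profiled against the category map at a 5-gene minimum
category size; and the two focused lists intersected into the
candidate set.  Every filter logs its in/out counts so the funnel is
visible in the run log, and the report carries full provenance (config
snapshot, input digests, package version) so each number can be
re-derived.  Identical inputs and config produce byte-identical report
files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

import dualscreen
from dualscreen import chemscreen, cnvscreen, function_class
from dualscreen.io_model import (
    ChemicalScreenRecord,
    ChemicalTargetMap,
    FormatError,
    FunctionalCategoryMap,
    GeneAnnotation,
    IntegrationReport,
    PatientCNVSet,
    SharedCategoryRow,
    ValidationError,
    file_digest,
    normalize_symbol,
    read_category_map,
    read_cnv_table,
    read_gene_annotation,
    read_screen_table,
    read_target_map,
)

log = logging.getLogger(__name__)


def intersect_focused_lists(
    targets: Sequence[str], genes: Sequence[str]
) -> list[str]:
    """Candidate symbols: the intersection of the two focused lists.

    Both sides are symbol-normalized first (case, whitespace, homeolog
    suffixes), so frog target names meet human gene symbols on equal
    footing.  Returned in alphabetical order; an empty intersection is
    a valid, explicitly reported outcome.
    """
    t = {normalize_symbol(s) for s in targets}
    g = {normalize_symbol(s) for s in genes}
    return sorted(t & g)


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Paths may be left ``None`` when the corresponding in-memory object
    is passed to :func:`run_pipeline_objects` directly.
    """

    # inputs
    screen_table: str | None = None
    screen_dialect: str = "long"
    target_map: str | None = None
    cnv_table: str | None = None
    cnv_dialect: str = "one_based_inclusive"
    annotation: str | None = None
    annotation_dialect: str = "tsv"
    category_map: str | None = None
    # arm 1
    hit_mode: str = "majority"
    hit_fraction: float = 0.5
    count_no_mouth: bool = False
    k_min_chemicals: int = 3
    # arm 2
    overlap_rule: str = "any_overlap"
    patient_fraction: float = 0.10
    threshold_mode: str = "ceil"
    harmonize_chroms: bool = True
    # categories
    min_genes: int = 5
    min_genes_chem: int | None = None  # None -> min_genes
    min_genes_cnv: int | None = None
    # extras
    highlights: list[str] = field(default_factory=list)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def hit_rule(self) -> chemscreen.HitRule:
        return chemscreen.HitRule(
            mode=self.hit_mode,
            fraction=self.hit_fraction,
            count_no_mouth=self.count_no_mouth,
        )


def run_pipeline_objects(
    screen_records: Sequence[ChemicalScreenRecord],
    target_map: ChemicalTargetMap,
    cohort: Sequence[PatientCNVSet],
    annotation: GeneAnnotation,
    category_map: FunctionalCategoryMap,
    config: PipelineConfig | None = None,
    provenance: Mapping | None = None,
) -> IntegrationReport:
    """Run both arms on in-memory objects and assemble the report."""
    cfg = config or PipelineConfig()

    # ---- arm 1: chemical screen -> focused targets
    try:
        hits = chemscreen.call_hits(screen_records, cfg.hit_rule())
    except ValidationError as exc:
        raise ValidationError(f"[chemscreen] {exc}") from exc
    _, unique_targets, unmapped = chemscreen.map_hits_to_targets(hits, target_map)
    tfreq = chemscreen.target_frequency(hits, target_map)
    focused_targets = chemscreen.filter_targets_min_chemicals(
        tfreq, cfg.k_min_chemicals
    )
    log.info(
        "[chemscreen] %d chemicals -> %d hits -> %d targets -> %d focused (k=%d)",
        len(screen_records), len(hits), len(unique_targets),
        len(focused_targets), cfg.k_min_chemicals,
    )

    # ---- arm 2: CNV cohort -> focused genes
    try:
        gfreq = cnvscreen.gene_patient_frequency(
            cohort, annotation, cfg.overlap_rule, cfg.harmonize_chroms
        )
        if len(cohort) == 0:
            # an empty cohort cannot resolve a fraction threshold; the
            # focused list is vacuously empty
            focused = cnvscreen.FocusedGenes(
                (), 0, cfg.patient_fraction, cfg.threshold_mode, 0
            )
        else:
            focused = cnvscreen.filter_genes_by_patient_fraction(
                gfreq, cfg.patient_fraction, cfg.threshold_mode
            )
    except ValidationError as exc:
        raise ValidationError(f"[cnvscreen] {exc}") from exc
    log.info(
        "[cnvscreen] %d patients -> %d genes -> %d focused (t=%d)",
        len(cohort), len(gfreq.rows), len(focused.symbols), focused.threshold,
    )

    # ---- functional categories on both arms' full gene lists
    arm_b_genes = [r.gene_symbol for r in gfreq.rows]
    try:
        prof_a = function_class.classify_functional(
            sorted(unique_targets), category_map, cfg.min_genes_chem or cfg.min_genes
        ) if unique_targets else None
        prof_b = function_class.classify_functional(
            arm_b_genes, category_map, cfg.min_genes_cnv or cfg.min_genes
        ) if arm_b_genes else None
    except ValidationError as exc:
        raise ValidationError(f"[function_class] {exc}") from exc
    shared: list[SharedCategoryRow] = (
        function_class.shared_categories(prof_a, prof_b)
        if prof_a is not None and prof_b is not None
        else []
    )

    candidates = intersect_focused_lists(focused_targets, list(focused.symbols))
    log.info("[integrate] %d shared categories; candidates: %s",
             len(shared), ", ".join(candidates) or "(none)")

    prov = dict(provenance or {})
    prov.setdefault("config", asdict(cfg))
    prov.setdefault("version", dualscreen.__version__)
    if cfg.seed is not None:
        prov.setdefault("seed", cfg.seed)
    prov["funnel"] = {
        "n_chemicals": len(screen_records),
        "n_hit_chemicals": len(hits),
        "n_unique_targets": len(unique_targets),
        "n_focused_targets": len(focused_targets),
        "cohort_size": len(cohort),
        "n_deleted_genes": len(gfreq.rows),
        "n_focused_genes": len(focused.symbols),
        "n_candidates": len(candidates),
    }

    highlights = sorted(
        {normalize_symbol(h) for h in cfg.highlights}
        & (set(arm_b_genes) | set(unique_targets))
    )

    return IntegrationReport(
        focused_targets=list(focused_targets),
        target_threshold=cfg.k_min_chemicals,
        focused_genes=list(focused.symbols),
        gene_threshold=focused.threshold,
        gene_fraction=focused.fraction,
        shared_categories=shared,
        candidates=candidates,
        target_frequency=tfreq,
        gene_frequency=gfreq,
        chem_categories=None if prof_a is None else prof_a.counts,
        cnv_categories=None if prof_b is None else prof_b.counts,
        hit_chemicals=list(hits),
        unmapped_chemicals=list(unmapped),
        unclassified_targets=[] if prof_a is None else list(prof_a.unclassified),
        unclassified_genes=[] if prof_b is None else list(prof_b.unclassified),
        highlights=highlights,
        provenance=prov,
    )


def run_pipeline(config: PipelineConfig) -> IntegrationReport:
    """Read every input named in the config, run both arms, and report.

    Any stage's validation error aborts the run tagged with the stage
    name; no outputs are produced on failure.
    """
    required = {
        "screen_table": config.screen_table,
        "target_map": config.target_map,
        "cnv_table": config.cnv_table,
        "annotation": config.annotation,
        "category_map": config.category_map,
    }
    missing = [k for k, v in required.items() if not v]
    if missing:
        raise ValidationError(f"config is missing input path(s): {', '.join(missing)}")

    try:
        screen_records = read_screen_table(config.screen_table, config.screen_dialect)
        target_map = read_target_map(config.target_map)
        cohort = read_cnv_table(config.cnv_table, config.cnv_dialect)
        annotation = read_gene_annotation(config.annotation, config.annotation_dialect)
        category_map = read_category_map(config.category_map)
    except (ValidationError, FormatError, OSError) as exc:
        raise ValidationError(f"[io_model] {exc}") from exc

    provenance = {
        "inputs": {k: {"path": str(v), "sha256": file_digest(v)}
                   for k, v in required.items()},
    }
    return run_pipeline_objects(
        screen_records, target_map, cohort, annotation, category_map,
        config=config, provenance=provenance,
    )


# --------------------------------------------------------------------------
# report serialization
# --------------------------------------------------------------------------


def report_summary(report: IntegrationReport) -> dict:
    """The machine-readable summary of a report (JSON-serializable)."""
    return {
        "focused_targets": list(report.focused_targets),
        "target_threshold": report.target_threshold,
        "focused_genes": list(report.focused_genes),
        "gene_threshold": report.gene_threshold,
        "gene_fraction": report.gene_fraction,
        "candidates": list(report.candidates),
        "shared_categories": [
            {
                "category_id": r.category_id,
                "category_name": r.category_name,
                "n_genes_arm1": r.n_genes_arm1,
                "n_genes_arm2": r.n_genes_arm2,
            }
            for r in report.shared_categories
        ],
        "hit_chemicals": list(report.hit_chemicals),
        "unmapped_chemicals": list(report.unmapped_chemicals),
        "unclassified_targets": list(report.unclassified_targets),
        "unclassified_genes": list(report.unclassified_genes),
        "highlights": list(report.highlights),
        "provenance": report.provenance,
    }


def write_report(report: IntegrationReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report directory: summary.json + human-readable TSVs.

    All file contents are rendered in memory before anything touches
    disk, so a failure never leaves a partial report behind.  Output is
    deterministic (sorted keys, no timestamps): identical reports give
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise OSError(f"report directory {out} is not writable")

    files: dict[str, str] = {}
    files["summary.json"] = json.dumps(
        report_summary(report), indent=2, sort_keys=True
    ) + "\n"
    files["target_frequency.tsv"] = report.target_frequency.to_frame().to_csv(
        sep="\t", index=False
    )
    files["gene_frequency.tsv"] = report.gene_frequency.to_frame().to_csv(
        sep="\t", index=False
    )
    files["focused_targets.tsv"] = "target_symbol\n" + "".join(
        f"{s}\n" for s in report.focused_targets
    )
    files["focused_genes.tsv"] = "gene_symbol\n" + "".join(
        f"{s}\n" for s in report.focused_genes
    )
    files["candidates.tsv"] = "candidate_symbol\n" + "".join(
        f"{s}\n" for s in report.candidates
    )
    files["shared_categories.tsv"] = function_class.shared_categories_frame(
        report.shared_categories
    ).to_csv(sep="\t", index=False)
    if report.chem_categories is not None:
        files["categories_chemscreen.tsv"] = report.chem_categories.to_csv(
            sep="\t", index=False
        )
    if report.cnv_categories is not None:
        files["categories_cnvscreen.tsv"] = report.cnv_categories.to_csv(
            sep="\t", index=False
        )

    written: dict[str, Path] = {}
    for name, text in files.items():
        path = out / name
        path.write_text(text)
        written[name] = path
    return written


def load_report_summary(out_dir: str | Path) -> dict:
    """Re-parse a written report's machine-readable summary."""
    return json.loads((Path(out_dir) / "summary.json").read_text())
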