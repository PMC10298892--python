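"""Arm 2 — gene recurrence across patient copy-number deletions.

Patients ascertained for a clinical phenotype (here Choanal Atresia)
carry heterogeneous deletion intervals, some spanning large chromosome
regions.  Each patient's deletions are mapped to the genes they
overlap; genes are then ranked by the number of distinct patients whose
deletions disrupt them, and the ranking is focused by keeping genes
affected in at least a given fraction of the cohort (default ~10%).

Interval lookup uses an interval tree per chromosome; a brute-force
pairwise scan serves as the independent oracle in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from dualscreen.io_model import (
    GeneAnnotation,
    GeneFrequencyRow,
    GeneFrequencyTable,
    GenomicInterval,
    PatientCNVSet,
    ValidationError,
    strip_chr_prefix,
)

log = logging.getLogger(__name__)

_OVERLAP_RULES = {"any_overlap", "full_containment"}


def _index_for(annotation: GeneAnnotation) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over gene loci, cached on the annotation.

    Chromosome names are chr-prefix harmonized at index time; the
    annotation's records are immutable after construction, so the cache
    never goes stale.
    """
    trees = getattr(annotation, "_interval_trees", None)
    if trees is None:
        trees = {}
        for sym, iv in annotation.records:
            chrom = strip_chr_prefix(iv.chrom)
            trees.setdefault(chrom, IntervalTree()).addi(iv.start, iv.end, (sym, iv))
        annotation._interval_trees = trees
    return trees


def _check_chrom_naming(
    deletion_chroms: set[str], annotation: GeneAnnotation, harmonize: bool
) -> None:
    ann_raw = {str(c) for c in annotation.chroms}
    if harmonize:
        return
    ann_stripped = {strip_chr_prefix(c) for c in ann_raw}
    for chrom in deletion_chroms:
        if chrom not in ann_raw and strip_chr_prefix(chrom) in ann_stripped:
            raise ValidationError(
                f"chromosome {chrom!r} does not match the annotation's naming "
                f"scheme (e.g. {sorted(ann_raw)[:3]}); enable chr-prefix "
                "harmonization or rename one side"
            )


def map_cnv_to_genes(
    patient: PatientCNVSet,
    annotation: GeneAnnotation,
    overlap_rule: str = "any_overlap",
    harmonize_chroms: bool = True,
) -> frozenset[str]:
    """Symbols of genes disrupted by a patient's deletions.

    ``any_overlap`` (default) counts a gene when any of its loci shares
    at least one base pair with a deletion; ``full_containment``
    requires the whole locus to lie inside a deletion.  Chromosome
    names are harmonized across the 'chr1'/'1' styles by default; with
    harmonization off, a prefix-only mismatch raises instead of
    silently yielding zero overlaps.
    """
    if overlap_rule not in _OVERLAP_RULES:
        raise ValidationError(f"overlap_rule must be one of {sorted(_OVERLAP_RULES)}")
    _check_chrom_naming(
        {d.chrom for d in patient.deletions}, annotation, harmonize_chroms
    )
    trees = _index_for(annotation)
    genes: set[str] = set()
    for deletion in patient.deletions:
        tree = trees.get(strip_chr_prefix(deletion.chrom))
        if tree is None:
            continue
        for hit in tree.overlap(deletion.start, deletion.end):
            sym, locus = hit.data
            if overlap_rule == "full_containment" and not (
                deletion.start <= locus.start and locus.end <= deletion.end
            ):
                continue
            genes.add(sym)
    return frozenset(genes)


def map_cnv_to_genes_bruteforce(
    patient: PatientCNVSet,
    annotation: GeneAnnotation,
    overlap_rule: str = "any_overlap",
) -> frozenset[str]:
    """Exhaustive pairwise deletion x locus scan — the oracle for the index."""
    if overlap_rule not in _OVERLAP_RULES:
        raise ValidationError(f"overlap_rule must be one of {sorted(_OVERLAP_RULES)}")
    genes: set[str] = set()
    for deletion in patient.deletions:
        dchrom = strip_chr_prefix(deletion.chrom)
        for sym, locus in annotation.records:
            if strip_chr_prefix(locus.chrom) != dchrom:
                continue
            if overlap_rule == "any_overlap":
                if deletion.start < locus.end and locus.start < deletion.end:
                    genes.add(sym)
            else:
                if deletion.start <= locus.start and locus.end <= deletion.end:
                    genes.add(sym)
    return frozenset(genes)


def gene_patient_frequency(
    cohort: Sequence[PatientCNVSet],
    annotation: GeneAnnotation,
    overlap_rule: str = "any_overlap",
    harmonize_chroms: bool = True,
) -> GeneFrequencyTable:
    """Count, per gene, the DISTINCT patients whose deletions overlap it.

    A patient with several deletions over the same gene counts once.
    Sorted by patient count descending, ties alphabetical; the cohort
    size (all ascertained patients, informative or not) is recorded.
    """
    ids = [p.patient_id for p in cohort]
    if len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate patient_id(s) in cohort: {', '.join(dups)}")
    by_gene: dict[str, set[str]] = {}
    for patient in cohort:
        for sym in map_cnv_to_genes(patient, annotation, overlap_rule, harmonize_chroms):
            by_gene.setdefault(sym, set()).add(patient.patient_id)
    rows = [
        GeneFrequencyRow(
            gene_symbol=sym, n_patients=len(pids), patient_ids=frozenset(pids)
        )
        for sym, pids in by_gene.items()
    ]
    rows.sort(key=lambda r: (-r.n_patients, r.gene_symbol))
    return GeneFrequencyTable(rows=tuple(rows), cohort_size=len(cohort))


def gene_patient_frequency_from_lists(
    gene_lists: dict[str, Iterable[str]],
) -> GeneFrequencyTable:
    """Recurrence table from pre-listed per-patient gene sets.

    For cohorts whose source database already reports the genes each
    deletion affects, this bypasses interval mapping entirely.  Keys
    are patient ids; symbols are normalized and de-duplicated per
    patient before counting.
    """
    from dualscreen.io_model import normalize_symbol

    by_gene: dict[str, set[str]] = {}
    for pid, genes in gene_lists.items():
        for g in {normalize_symbol(g) for g in genes}:
            by_gene.setdefault(g, set()).add(pid)
    rows = [
        GeneFrequencyRow(gene_symbol=g, n_patients=len(p), patient_ids=frozenset(p))
        for g, p in by_gene.items()
    ]
    rows.sort(key=lambda r: (-r.n_patients, r.gene_symbol))
    return GeneFrequencyTable(rows=tuple(rows), cohort_size=len(gene_lists))


_THRESHOLD_MODES = {"ceil", "floor", "at_least"}


def resolve_patient_threshold(
    cohort_size: int, fraction: float, threshold_mode: str = "ceil"
) -> int:
    """Integer patient-count threshold implied by a cohort fraction.

    ``ceil`` (default) and ``at_least`` both require n_patients >=
    fraction * cohort_size (``ceil`` via the rounded-up integer);
    ``floor`` rounds the product down, the permissive reading of an
    'approximately X%' rule.  Always at least 1.
    """
    if threshold_mode not in _THRESHOLD_MODES:
        raise ValidationError(
            f"threshold_mode must be one of {sorted(_THRESHOLD_MODES)}"
        )
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"patient fraction must lie in (0, 1], got {fraction}")
    if cohort_size <= 0:
        raise ValidationError("cohort_size must be positive to resolve a threshold")
    product = fraction * cohort_size
    if threshold_mode == "floor":
        t = math.floor(product)
    else:  # ceil and at_least coincide on integer counts
        t = math.ceil(product)
    return max(1, t)


@dataclass(frozen=True)
class FocusedGenes:
    """Focused gene list plus the threshold actually applied."""

    symbols: tuple[str, ...]
    threshold: int
    fraction: float
    threshold_mode: str
    cohort_size: int


def filter_genes_by_patient_fraction(
    table: GeneFrequencyTable,
    fraction: float = 0.10,
    threshold_mode: str = "ceil",
) -> FocusedGenes:
    """Keep genes affected in at least ``fraction`` of the cohort.

    The fraction is resolved to an integer threshold ``t`` (see
    :func:`resolve_patient_threshold`); genes with ``n_patients >= t``
    are kept in table order.  Antitone in ``fraction``.
    """
    t = resolve_patient_threshold(table.cohort_size, fraction, threshold_mode)
    kept = tuple(r.gene_symbol for r in table.rows if r.n_patients >= t)
    log.info(
        "patient-fraction filter (%.3f of %d -> t=%d): %d -> %d genes",
        fraction,
        table.cohort_size,
        t,
        len(table.rows),
        len(kept),
    )
    return FocusedGenes(
        symbols=kept,
        threshold=t,
        fraction=fraction,
        threshold_mode=threshold_mode,
        cohort_size=table.cohort_size,
    )
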