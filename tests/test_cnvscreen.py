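"""Deletion-to-gene mapping, patient recurrence, fraction threshold."""

from dataclasses import replace

import numpy as np
import pytest

from dualscreen.cnvscreen import (
    filter_genes_by_patient_fraction,
    gene_patient_frequency,
    gene_patient_frequency_from_lists,
    map_cnv_to_genes,
    map_cnv_to_genes_bruteforce,
    resolve_patient_threshold,
)
from dualscreen.io_model import (
    GeneAnnotation,
    GenomicInterval,
    PatientCNVSet,
    ValidationError,
)
from dualscreen.synthetic import SyntheticSpec, generate_cnv_cohort


def ann(*records):
    return GeneAnnotation(records)


def patient(pid, *dels):
    return PatientCNVSet(patient_id=pid, deletions=tuple(dels))


# ---------------------------------------------------------------- mapping


def test_contained_gene_counts_under_both_rules():
    a = ann(("G", GenomicInterval("chr1", 200, 300)))
    p = patient("P1", GenomicInterval("chr1", 100, 500))
    assert map_cnv_to_genes(p, a, "any_overlap") == {"G"}
    assert map_cnv_to_genes(p, a, "full_containment") == {"G"}


def test_other_chromosome_never_counts():
    a = ann(("G", GenomicInterval("chr1", 200, 300)))
    p = patient("P1", GenomicInterval("chr2", 100, 500))
    assert map_cnv_to_genes(p, a) == frozenset()


def test_partial_overlap_counts_only_under_any_overlap():
    a = ann(("G", GenomicInterval("chr1", 200, 300)))
    p = patient("P1", GenomicInterval("chr1", 250, 500))
    assert map_cnv_to_genes(p, a, "any_overlap") == {"G"}
    assert map_cnv_to_genes(p, a, "full_containment") == frozenset()


def test_half_open_boundaries_do_not_touch():
    a = ann(("G", GenomicInterval("chr1", 200, 300)))
    assert map_cnv_to_genes(patient("P1", GenomicInterval("chr1", 100, 200)), a) == frozenset()
    assert map_cnv_to_genes(patient("P1", GenomicInterval("chr1", 300, 400)), a) == frozenset()
    assert map_cnv_to_genes(patient("P1", GenomicInterval("chr1", 299, 400)), a) == {"G"}


def test_chr_prefix_harmonization_and_mismatch_error():
    a = ann(("G", GenomicInterval("1", 200, 300)))  # annotation without prefix
    p = patient("P1", GenomicInterval("chr1", 100, 500))
    assert map_cnv_to_genes(p, a, harmonize_chroms=True) == {"G"}
    with pytest.raises(ValidationError, match="harmoniz"):
        map_cnv_to_genes(p, a, harmonize_chroms=False)


def test_multi_locus_gene_any_locus_counts():
    a = ann(
        ("G", GenomicInterval("chr1", 100, 200)),
        ("G", GenomicInterval("chr2", 100, 200)),
    )
    assert map_cnv_to_genes(patient("P1", GenomicInterval("chr2", 150, 160)), a) == {"G"}


@pytest.mark.parametrize("rule", ["any_overlap", "full_containment"])
@pytest.mark.parametrize("seed", range(5))
def test_indexed_engine_matches_bruteforce(rule, seed):
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(200):
        start = int(rng.integers(0, 100_000))
        genes.append(
            (f"G{i}", GenomicInterval(f"chr{rng.integers(1, 4)}", start,
                                      start + int(rng.integers(1, 2_000))))
        )
    a = ann(*genes)
    dels = []
    for _ in range(300):
        start = int(rng.integers(0, 100_000))
        dels.append(GenomicInterval(f"chr{rng.integers(1, 4)}", start,
                                    start + int(rng.integers(1, 5_000))))
    p = patient("P1", *dels)
    assert map_cnv_to_genes(p, a, rule) == map_cnv_to_genes_bruteforce(p, a, rule)


def test_containment_subset_of_overlap():
    rng = np.random.default_rng(3)
    genes = [(f"G{i}", GenomicInterval("chr1", int(s), int(s) + 500))
             for i, s in enumerate(rng.integers(0, 50_000, size=50))]
    a = ann(*genes)
    p = patient("P1", *[GenomicInterval("chr1", int(s), int(s) + 3_000)
                        for s in rng.integers(0, 50_000, size=20)])
    assert map_cnv_to_genes(p, a, "full_containment") <= map_cnv_to_genes(p, a, "any_overlap")


# ---------------------------------------------------------------- recurrence


def test_patient_counted_once_per_gene():
    a = ann(("G", GenomicInterval("chr1", 100, 200)))
    cohort = [
        patient("P1", GenomicInterval("chr1", 90, 150), GenomicInterval("chr1", 150, 250)),
        patient("P2", GenomicInterval("chr1", 120, 130)),
    ]
    table = gene_patient_frequency(cohort, a)
    assert [(r.gene_symbol, r.n_patients) for r in table.rows] == [("G", 2)]
    assert table.cohort_size == 2


def test_empty_cohort():
    table = gene_patient_frequency([], ann(("G", GenomicInterval("chr1", 0, 10))))
    assert table.rows == () and table.cohort_size == 0


def test_duplicate_patient_ids_rejected():
    a = ann(("G", GenomicInterval("chr1", 0, 10)))
    with pytest.raises(ValidationError, match="P1"):
        gene_patient_frequency([patient("P1"), patient("P1")], a)


def test_uninformative_patients_stay_in_cohort_size():
    a = ann(("G", GenomicInterval("chr1", 100, 200)))
    cohort = [patient("P1", GenomicInterval("chr1", 120, 130)), patient("P2")]
    table = gene_patient_frequency(cohort, a)
    assert table.cohort_size == 2


def test_planted_gene_count_recovered_and_cross_checked(small_spec):
    cohort, annotation, truth = generate_cnv_cohort(small_spec)
    table = gene_patient_frequency(cohort, annotation)
    by_symbol = {r.gene_symbol: r for r in table.rows}
    row = by_symbol[small_spec.planted_gene]
    assert row.n_patients == small_spec.planted_gene_patients == 12
    # independent per-patient membership scan with the brute-force oracle
    n = sum(
        small_spec.planted_gene in map_cnv_to_genes_bruteforce(p, annotation)
        for p in cohort
    )
    assert n == 12


def test_adding_patient_never_decreases_counts(small_spec):
    cohort, annotation, _ = generate_cnv_cohort(small_spec)
    base = gene_patient_frequency(cohort[:-1], annotation)
    full = gene_patient_frequency(cohort, annotation)
    base_counts = {r.gene_symbol: r.n_patients for r in base.rows}
    full_counts = {r.gene_symbol: r.n_patients for r in full.rows}
    for sym, n in base_counts.items():
        assert full_counts[sym] >= n


def test_enlarging_deletion_never_shrinks_gene_set():
    rng = np.random.default_rng(7)
    genes = [(f"G{i}", GenomicInterval("chr1", int(s), int(s) + 300))
             for i, s in enumerate(rng.integers(0, 20_000, size=40))]
    a = ann(*genes)
    for s in rng.integers(0, 20_000, size=10):
        small = map_cnv_to_genes(patient("P", GenomicInterval("chr1", int(s), int(s) + 500)), a)
        big = map_cnv_to_genes(patient("P", GenomicInterval("chr1", max(0, int(s) - 400), int(s) + 1_500)), a)
        assert small <= big


def test_pre_listed_gene_sets_match_interval_mapping(small_spec):
    """A database-supplied per-patient gene list bypasses interval mapping
    but must give the same recurrence table."""
    cohort, annotation, _ = generate_cnv_cohort(small_spec)
    lists = {p.patient_id: map_cnv_to_genes(p, annotation) for p in cohort}
    direct = gene_patient_frequency_from_lists(lists)
    mapped = gene_patient_frequency(cohort, annotation)
    assert direct.rows == mapped.rows
    assert direct.cohort_size == mapped.cohort_size


def test_pre_listed_gene_sets_deduplicate_homeologs():
    table = gene_patient_frequency_from_lists(
        {"P1": ["jak2.L", "JAK2", " jak2 "], "P2": ["JAK2"], "P3": []}
    )
    assert [(r.gene_symbol, r.n_patients) for r in table.rows] == [("JAK2", 2)]
    assert table.cohort_size == 3


# ---------------------------------------------------------------- threshold


def test_threshold_arithmetic_83_patients():
    assert resolve_patient_threshold(83, 0.10, "ceil") == 9
    assert resolve_patient_threshold(83, 0.10, "floor") == 8
    assert resolve_patient_threshold(83, 0.10, "at_least") == 9


def test_threshold_validation():
    with pytest.raises(ValidationError):
        resolve_patient_threshold(83, 0.0)
    with pytest.raises(ValidationError):
        resolve_patient_threshold(83, 1.5)
    with pytest.raises(ValidationError):
        resolve_patient_threshold(0, 0.1)
    with pytest.raises(ValidationError):
        resolve_patient_threshold(83, 0.1, "round")


def test_fraction_filter_identity_at_t1():
    a = ann(("G1", GenomicInterval("chr1", 0, 100)), ("G2", GenomicInterval("chr1", 200, 300)))
    cohort = [patient("P1", GenomicInterval("chr1", 50, 60)),
              patient("P2", GenomicInterval("chr1", 250, 260))]
    table = gene_patient_frequency(cohort, a)
    focused = filter_genes_by_patient_fraction(table, fraction=0.5)
    assert focused.threshold == 1
    assert set(focused.symbols) == {"G1", "G2"}


def test_fraction_filter_antitone(small_spec):
    cohort, annotation, _ = generate_cnv_cohort(small_spec)
    table = gene_patient_frequency(cohort, annotation)
    prev = None
    for f in (0.02, 0.05, 0.10, 0.20, 0.40):
        kept = set(filter_genes_by_patient_fraction(table, f).symbols)
        if prev is not None:
            assert kept <= prev
        prev = kept
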