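"""Seeded generators emulating the dual-screen inputs, with planted signals.

Each generator is a pure function of a :class:`SyntheticSpec` (seed
included): a chemical screen whose hit wells satisfy the hit rule and
whose chemical→target graph links a planted target to an exact number
of distinct hit chemicals; a patient cohort whose deletion intervals
recurrently hit a planted gene in an exact number of patients; and a
gene→category map in which an exact number of categories clears the
size cutoff in both arms.  Background signal is kept strictly below
every filter threshold by rejection sampling, so planted quantities
are recovered exactly by the pipeline — the generator tests the
pipeline, not the biology.

Default scales mirror the study design the pipeline targets: 1200
screened chemicals with a ~3.4% hit rate, 6 embryos per well, an
83-patient deletion cohort, and a genome of 5000 non-overlapping gene
loci over 23 chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from dualscreen.io_model import (
    ChemicalScreenRecord,
    ChemicalTargetMap,
    FunctionalCategoryMap,
    GeneAnnotation,
    GenomicInterval,
    PatientCNVSet,
    PhenotypeScore,
    ValidationError,
    write_category_map,
    write_cnv_table,
    write_gene_annotation,
    write_screen_table,
    write_target_map,
)


class SpecError(ValidationError):
    """A SyntheticSpec requests an unachievable planted structure."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic input bundle.

    Planted margins default to two units above the pipeline's default
    thresholds (k = 3 chemicals; ceil(0.10 * 83) = 9 patients), so the
    planted symbol clears both filters while every background target
    and gene stays strictly below them.
    """

    seed: int = 0
    # chemical-screen arm
    n_chemicals: int = 1200
    hit_rate: float = 41 / 1200
    n_targets: int = 400
    targets_per_chemical: tuple[int, int] = (1, 10)
    planted_target: str = "PLNT1"
    planted_target_chemicals: int = 5
    k_min_chemicals: int = 3  # background targets stay below this
    embryos_per_well: int = 6
    # CNV arm
    n_patients: int = 83
    n_genes: int = 5000
    n_chromosomes: int = 23
    gene_length_range: tuple[int, int] = (5_000, 200_000)
    gene_spacing_range: tuple[int, int] = (5_000, 100_000)
    deletions_per_patient: tuple[int, int] = (1, 4)
    planted_gene: str = "PLNT1"
    planted_gene_patients: int = 11
    patient_fraction: float = 0.10  # background genes stay below ceil(f*N)
    # functional-category map
    n_categories: int = 40
    n_shared_categories: int = 7
    min_genes_per_category: int = 5
    phenotype_tag: str = "Choanal Atresia"

    def __post_init__(self) -> None:
        n_hits = self.n_hits
        if self.n_chemicals > 0 and self.planted_target_chemicals > n_hits:
            raise SpecError(
                f"planted target requires {self.planted_target_chemicals} hit "
                f"chemicals but the screen only produces {n_hits} hits"
            )
        if self.planted_gene_patients > self.n_patients:
            raise SpecError(
                f"planted gene requires {self.planted_gene_patients} patients "
                f"but the cohort has only {self.n_patients}"
            )
        if self.n_genes > 0 and self.n_chromosomes < 1:
            raise SpecError("need at least one chromosome")
        if not (0.0 <= self.hit_rate <= 1.0):
            raise SpecError("hit_rate must lie in [0, 1]")

    @property
    def n_hits(self) -> int:
        return int(round(self.hit_rate * self.n_chemicals))

    @property
    def background_gene_cap(self) -> int:
        """Max patients allowed to share any background gene (< threshold)."""
        return max(0, math.ceil(self.patient_fraction * self.n_patients) - 1)


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


# --------------------------------------------------------------------------
# chemical screen
# --------------------------------------------------------------------------

_PERSISTENT = PhenotypeScore(stomodeum_present=True, mouth_open=False)
_OPEN = PhenotypeScore(stomodeum_present=True, mouth_open=True)
_CLEFT = PhenotypeScore(stomodeum_present=True, mouth_open=True, cleft_like=True)
_NO_MOUTH = PhenotypeScore(stomodeum_present=False, mouth_open=False, no_mouth=True)


def generate_chemical_screen(
    spec: SyntheticSpec,
) -> tuple[list[ChemicalScreenRecord], ChemicalTargetMap, dict]:
    """Synthetic screen table plus chemical→target map.

    Returns ``(records, target_map, truth)`` where ``truth`` records
    the planted ground truth (hit ids, planted target, its exact
    distinct-hit-chemical degree).
    """
    rng = _rng(spec, 1)
    n = spec.n_chemicals
    ids = [f"NSC{i + 1:05d}" for i in range(n)]
    n_hits = spec.n_hits
    hit_idx = set(rng.choice(n, size=n_hits, replace=False).tolist()) if n else set()

    records: list[ChemicalScreenRecord] = []
    for i, cid in enumerate(ids):
        if i in hit_idx:
            # persistent membrane in every embryo: satisfies any hit rule
            scores = (_PERSISTENT,) * spec.embryos_per_well
        else:
            draws = rng.random(spec.embryos_per_well)
            scores = tuple(
                _NO_MOUTH if d < 0.05 else (_CLEFT if d < 0.15 else _OPEN)
                for d in draws
            )
        records.append(
            ChemicalScreenRecord(
                chemical_id=cid, embryo_scores=scores, concentration_um=30.0
            )
        )

    hits = [ids[i] for i in sorted(hit_idx)]
    background = [f"TGT{j + 1:04d}" for j in range(spec.n_targets)]
    cap = max(0, spec.k_min_chemicals - 1)
    hit_degree: dict[str, int] = {t: 0 for t in background}
    pairs: list[tuple[str, str]] = []
    lo, hi = spec.targets_per_chemical
    for i, cid in enumerate(ids):
        n_t = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
        if i in hit_idx:
            pool = [t for t in background if hit_degree[t] < cap]
            if len(pool) < n_t:
                n_t = len(pool)
            chosen = rng.choice(len(pool), size=n_t, replace=False) if n_t else []
            for j in chosen:
                pairs.append((cid, pool[j]))
                hit_degree[pool[j]] += 1
        else:
            chosen = rng.choice(spec.n_targets, size=min(n_t, spec.n_targets), replace=False)
            pairs.extend((cid, background[j]) for j in chosen)

    planted_hits: list[str] = []
    if spec.planted_target_chemicals and n_hits:
        picked = rng.choice(n_hits, size=spec.planted_target_chemicals, replace=False)
        planted_hits = [hits[j] for j in sorted(picked)]
        pairs.extend((cid, spec.planted_target) for cid in planted_hits)

    cmap = ChemicalTargetMap.from_pairs(pairs, provenance="synthetic")
    truth = {
        "hit_chemicals": hits,
        "planted_target": spec.planted_target,
        "planted_target_chemicals": planted_hits,
        "planted_target_degree": len(planted_hits),
    }
    return records, cmap, truth


# --------------------------------------------------------------------------
# CNV cohort
# --------------------------------------------------------------------------


def generate_cnv_cohort(
    spec: SyntheticSpec,
) -> tuple[list[PatientCNVSet], GeneAnnotation, dict]:
    """Synthetic patient cohort plus gene annotation.

    Gene loci are laid out non-overlapping per chromosome with
    log-uniform lengths and spacings.  Deletions confined to the
    planted gene's locus give it exactly the requested distinct-patient
    count; background deletion lengths are log-uniform between one
    gene length and half a chromosome, re-drawn whenever they would
    touch the planted gene or push any background gene to the patient
    threshold.
    """
    rng = _rng(spec, 2)
    n_genes = spec.n_genes
    per_chrom = [n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for j in range(n_genes % spec.n_chromosomes):
        per_chrom[j] += 1

    symbols: list[str] = []
    records: list[tuple[str, GenomicInterval]] = []
    chrom_genes: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    chrom_len: dict[str, int] = {}
    gi = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        starts, ends, idxs = [], [], []
        pos = 0
        for _ in range(per_chrom[c]):
            pos += _log_uniform_int(rng, *spec.gene_spacing_range)
            length = _log_uniform_int(rng, *spec.gene_length_range)
            starts.append(pos)
            ends.append(pos + length)
            idxs.append(gi)
            symbols.append(f"G{gi + 1:05d}")
            pos += length
            gi += 1
        chrom_genes[chrom] = (np.asarray(starts), np.asarray(ends), idxs)
        chrom_len[chrom] = pos + _log_uniform_int(rng, *spec.gene_spacing_range)

    planted_idx = -1
    if n_genes and spec.planted_gene_patients:
        planted_idx = int(rng.integers(n_genes))
        symbols[planted_idx] = spec.planted_gene

    gi = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        starts, ends, idxs = chrom_genes[chrom]
        for s, e, idx in zip(starts, ends, idxs):
            records.append((symbols[idx], GenomicInterval(chrom, int(s), int(e))))
    annotation = GeneAnnotation(records)

    patient_ids = [f"P{i + 1:03d}" for i in range(spec.n_patients)]
    planted_patients: set[int] = set()
    if spec.planted_gene_patients and spec.n_patients:
        planted_patients = set(
            rng.choice(
                spec.n_patients, size=spec.planted_gene_patients, replace=False
            ).tolist()
        )

    planted_locus = None
    if planted_idx >= 0:
        _, iv = annotation.records[planted_idx]
        planted_locus = iv

    cap = spec.background_gene_cap
    patients_per_gene: dict[int, set[int]] = {}
    chroms = list(chrom_genes)
    cohort: list[PatientCNVSet] = []
    lo_d, hi_d = spec.deletions_per_patient
    min_len = spec.gene_length_range[0]

    for p in range(spec.n_patients):
        deletions: list[GenomicInterval] = []
        if p in planted_patients and planted_locus is not None:
            # a deletion strictly inside the planted locus: hits it and
            # nothing else, so neighbors never inherit its recurrence
            span = len(planted_locus)
            length = int(rng.integers(max(1, span // 4), span + 1))
            offset = int(rng.integers(0, span - length + 1))
            deletions.append(
                GenomicInterval(
                    planted_locus.chrom,
                    planted_locus.start + offset,
                    planted_locus.start + offset + length,
                )
            )
        n_bg = int(rng.integers(lo_d, hi_d + 1)) if hi_d >= lo_d else 0
        n_bg = max(0, n_bg - len(deletions))
        for _ in range(n_bg):
            placed = False
            for _attempt in range(200):
                chrom = chroms[int(rng.integers(len(chroms)))] if chroms else None
                if chrom is None:
                    break
                clen = chrom_len[chrom]
                length = _log_uniform_int(rng, min_len, max(min_len + 1, clen // 2))
                start = int(rng.integers(0, max(1, clen - length)))
                end = start + length
                starts, ends, idxs = chrom_genes[chrom]
                i0 = int(np.searchsorted(ends, start, side="right"))
                i1 = int(np.searchsorted(starts, end, side="left"))
                hit_genes = idxs[i0:i1]
                if planted_idx in hit_genes:
                    continue
                if any(
                    len(patients_per_gene.get(g, set()) | {p}) > cap
                    for g in hit_genes
                ):
                    continue
                for g in hit_genes:
                    patients_per_gene.setdefault(g, set()).add(p)
                deletions.append(GenomicInterval(chrom, start, end))
                placed = True
                break
            if not placed:
                continue  # drop this deletion rather than violate the caps
        cohort.append(
            PatientCNVSet(
                patient_id=patient_ids[p],
                deletions=tuple(deletions),
                phenotype_tag=spec.phenotype_tag,
            )
        )

    truth = {
        "planted_gene": spec.planted_gene if planted_idx >= 0 else None,
        "planted_gene_patients": sorted(
            patient_ids[p] for p in planted_patients
        ),
        "planted_gene_count": len(planted_patients),
    }
    return cohort, annotation, truth


# --------------------------------------------------------------------------
# functional-category map
# --------------------------------------------------------------------------


def generate_functional_map(
    spec: SyntheticSpec,
    arm_a_genes: Sequence[str],
    arm_b_genes: Sequence[str],
) -> FunctionalCategoryMap:
    """Category map in which exactly ``n_shared_categories`` clear the
    size cutoff in BOTH arms.

    Shared categories draw ``min_genes_per_category`` members from each
    arm; arm-exclusive categories draw only from that arm's genes not
    present in the other (so the other arm's count is zero); the
    remaining categories stay below the cutoff everywhere.
    """
    rng = _rng(spec, 3)
    m = spec.min_genes_per_category
    a = sorted({g for g in arm_a_genes})
    b = sorted({g for g in arm_b_genes})
    if spec.n_shared_categories > 0 and (len(a) < m or len(b) < m):
        raise SpecError(
            f"cannot plant {spec.n_shared_categories} shared categories: "
            f"arms have {len(a)} and {len(b)} genes but each needs >= {m}"
        )
    if spec.n_shared_categories > spec.n_categories:
        raise SpecError("n_shared_categories exceeds n_categories")

    rows: list[tuple[str, str, str]] = []
    a_only = sorted(set(a) - set(b))
    b_only = sorted(set(b) - set(a))
    n_exclusive = max(0, (spec.n_categories - spec.n_shared_categories) // 2)

    cat_i = 0

    def next_cat() -> tuple[str, str]:
        nonlocal cat_i
        cat_i += 1
        return f"C{cat_i:03d}", f"synthetic pathway {cat_i}"

    for _ in range(spec.n_shared_categories):
        cid, name = next_cat()
        for g in rng.choice(len(a), size=m, replace=False):
            rows.append((a[g], cid, name))
        for g in rng.choice(len(b), size=m, replace=False):
            rows.append((b[g], cid, name))

    for pool in (a_only, b_only):
        n_from_pool = min(n_exclusive, len(pool) // m)
        for _ in range(n_from_pool):
            cid, name = next_cat()
            for g in rng.choice(len(pool), size=m, replace=False):
                rows.append((pool[g], cid, name))

    both = a + [g for g in b if g not in set(a)]
    while cat_i < spec.n_categories and both:
        cid, name = next_cat()
        size = int(rng.integers(1, m)) if m > 1 else 0
        for g in rng.choice(len(both), size=min(size, len(both)), replace=False):
            rows.append((both[g], cid, name))

    return FunctionalCategoryMap.from_rows(rows)


# --------------------------------------------------------------------------
# full bundle
# --------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """All pipeline inputs for one seed, plus planted ground truth."""

    spec: SyntheticSpec
    screen_records: list[ChemicalScreenRecord]
    target_map: ChemicalTargetMap
    cohort: list[PatientCNVSet]
    annotation: GeneAnnotation
    category_map: FunctionalCategoryMap
    truth: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle's tables in the canonical dialects."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "screen_table": out / "screen.tsv",
            "target_map": out / "target_map.tsv",
            "cnv_table": out / "cnv.tsv",
            "annotation": out / "genes.tsv",
            "category_map": out / "categories.tsv",
        }
        write_screen_table(self.screen_records, paths["screen_table"])
        write_target_map(self.target_map, paths["target_map"])
        write_cnv_table(self.cohort, paths["cnv_table"])
        write_gene_annotation(self.annotation, paths["annotation"])
        write_category_map(self.category_map, paths["category_map"])
        return paths


def generate_bundle(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate every pipeline input for one seed.

    The functional map is planted around the two arms' gene lists: the
    hit chemicals' union of targets, and the union of genes deleted in
    any patient.
    """
    from dualscreen.cnvscreen import map_cnv_to_genes

    records, cmap, chem_truth = generate_chemical_screen(spec)
    cohort, annotation, cnv_truth = generate_cnv_cohort(spec)

    arm_a: set[str] = set()
    for cid in chem_truth["hit_chemicals"]:
        arm_a |= cmap.targets_of(cid)
    arm_b: set[str] = set()
    for patient in cohort:
        arm_b |= map_cnv_to_genes(patient, annotation)

    category_map = generate_functional_map(spec, sorted(arm_a), sorted(arm_b))
    truth = {**chem_truth, **cnv_truth, "arm_a_genes": sorted(arm_a),
             "arm_b_genes": sorted(arm_b)}
    return SyntheticBundle(
        spec=spec,
        screen_records=records,
        target_map=cmap,
        cohort=cohort,
        annotation=annotation,
        category_map=category_map,
        truth=truth,
    )
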