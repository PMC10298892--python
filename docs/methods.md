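# Methods

## The analysis

`dualscreen` prioritizes candidate regulators of buccopharyngeal
membrane (BPM) rupture — the final step of embryonic mouth formation —
by requiring two independent lines of evidence to converge on the same
gene:

1. **Chemical-screen arm.** *Xenopus* embryos are exposed to a chemical
   library during mouth development and each well's embryos are scored
   for four mouth characteristics: stomodeum present, mouth open,
   cleft-like open mouth, no observable mouth. A chemical is a *hit*
   when its embryos retain a stomodeum but the mouth fails to open
   (persistent BPM) — a specific late defect, distinguished from
   earlier mouth-development failures (no stomodeum / no mouth) and
   from normal rupture (open mouth). Hits are deconvoluted to the
   proteins they are known to act on via a frozen chemical→target
   lookup (standing in for PubChem/GeneCards queries), and each target
   is ranked by the number of **distinct** hit chemicals acting on it.
   The focused list keeps targets hit by at least `k` chemicals
   (default `k = 3`): a protein perturbed by several independent
   chemistries is less likely to be an off-target artifact.

2. **CNV arm.** Patients ascertained for Choanal Atresia (a congenital
   airway blockage plausibly caused by a persistent BPM) carry copy-
   number deletions of very different sizes. Each patient's deletion
   intervals are mapped to the genes they overlap, and each gene is
   ranked by the number of **distinct** patients whose deletions
   disrupt it (a patient with several deletions over one gene counts
   once). The focused list keeps genes affected in at least a fraction
   `f` of the cohort (default `f = 0.10`, resolved as
   `t = ceil(f·N)`; for an 83-patient cohort, `t = 9`).

The candidate set is the intersection of the two focused lists after
symbol normalization. As a validity check, both arms' full gene lists
are profiled against a frozen gene→functional-category map
(PANTHER-style); categories reaching a minimum size (default 5 genes)
in **both** arms are reported as shared. No enrichment statistics are
attached: the shared-category table and the intersection are
descriptive, by design.

## Symbol and coordinate conventions

- **Symbols.** All comparisons use `normalize_symbol`: optional synonym
  substitution, whitespace strip, uppercase, and repeated removal of
  trailing *X. laevis* homeolog suffixes (`.L`/`.S`). This is what
  makes an intersection between frog protein targets and human gene
  symbols meaningful. The function is idempotent (property-tested).
- **Coordinates.** Internally everything is 0-based half-open.
  DECIPHER-style inputs (1-based inclusive) are converted on read
  (`start − 1`); BED-style inputs pass through. Writers always emit the
  canonical dialect and a header comment naming it. Conversion is a
  bijection, so round-tripping a dialect restores the original
  integers.
- **Chromosome names.** `chr1` and `1` styles are harmonized by
  default; with harmonization off, a prefix-only mismatch raises a
  validation error rather than silently producing zero overlaps.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| hit rule | `majority` | fraction of scoreable embryos that must show persistent BPM; `all` and an explicit `fraction` are available |
| `count_no_mouth` | false | whether mouthless embryos enter the hit denominator; excluded by default since a hit requires an observable stomodeum, and a mouthless embryo reflects an earlier defect. Under the `all` rule they always count (a well is only "all persistent" if every embryo is) |
| `k_min_chemicals` | 3 | distinct hit chemicals required to keep a target |
| `patient_fraction` | 0.10 | cohort fraction required to keep a gene |
| `threshold_mode` | `ceil` | how `f·N` becomes an integer; `floor` is the permissive reading of an "approximately 10%" rule (8 vs 9 for N = 83); `at_least` coincides with `ceil` on integer counts and exists for interface clarity |
| `overlap_rule` | `any_overlap` | ≥1 bp overlap counts a gene (a partial deletion still disrupts it); `full_containment` is available for sensitivity analysis |
| `min_genes` | 5 | minimum category size in the functional profile; applied to both arms by default, configurable per arm |

Patients with zero mapped genes remain in the cohort size: the
fraction's denominator is ascertained patients, not informative ones.
Cohorts whose source database already lists the genes each deletion
affects can bypass interval mapping entirely via
`gene_patient_frequency_from_lists`, which produces the same table
shape from per-patient gene sets.
Ranked tables break ties alphabetically so output is deterministic.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a `SyntheticSpec` (seed included)
and emulate the study conditions the pipeline targets:

- 1200 screened chemicals, hit rate 41/1200, 6 embryos per well at
  30 µM (concentration is metadata only);
- a chemical→target pool of 400 symbols with 1–10 targets per chemical,
  chosen once so the ~41 hits deconvolute to roughly 170–190 distinct
  targets — the scale of the screen being emulated;
- an 83-patient cohort over a genome of 5000 non-overlapping gene loci
  on 23 chromosomes (log-uniform gene lengths 5–200 kb, spacings
  5–100 kb), 1–4 deletions per patient with log-uniform lengths from
  one gene length up to half a chromosome — yielding ~2100–2200
  distinct deleted genes;
- a category map of 40 categories in which exactly 7 (by default)
  clear the 5-gene cutoff in both arms.

A planted symbol is wired two units above both default thresholds
(5 hit chemicals ≥ k+2; 11 patients ≥ ceil(0.10·83)+2) while
rejection sampling keeps every background target and gene strictly
below its threshold. Recovery of exactly the planted symbol is
therefore guaranteed *by construction* — the generator tests the
pipeline's bookkeeping (distinct-counting, thresholds, normalization,
intersection), not the biology. Two deliberate artificialities follow:
planted deletions are confined within the planted gene's locus (so its
recurrence never leaks onto neighbors), and background rejection gives
gene recurrence a hard ceiling real cohorts do not have. Passing the
planted-recovery suite says the machinery is correct; it says nothing
about whether real screens have signal this clean.

## Numerical and degenerate-input choices

- Boolean phenotype cells accept exactly `1/0, true/false, yes/no, y/n`
  (case-insensitive); anything else is an error, never a coercion.
- Readers reject malformed rows with the row number; writers render all
  content in memory before touching disk, so failures never leave a
  partial report.
- An empty candidate intersection, an empty cohort, or a screen with no
  hits are all valid outcomes producing valid (empty-table) reports;
  only an empty cohort combined with a fraction filter is special-cased
  (the threshold is unresolvable, so the focused list is vacuously
  empty).
- Reports contain no timestamps and use sorted JSON keys: identical
  inputs and config give byte-identical output, which the test suite
  checks at the byte level.
- Percentages in phenotype proportion tables are rounded to one decimal,
  matching the reporting convention of the screens being reproduced.

## Problem sizes used in the checks

The planted-recovery check runs 20 seeds at the full emulated scale
(1200 chemicals / 83 patients / 5000 genes; ~0.3 s per seed). The
interval-engine equivalence check compares the interval-tree index
against an exhaustive vectorized pairwise scan on 100 random fixtures
of 1000 intervals × 200 genes (the acceptance script samples 25 such
fixtures; the test suite runs the full 100). Monotonicity is checked
on a 6-point `k` grid and a 5-point fraction grid on one bundle.

## Known limitations

- Target deconvolution is only as good as the frozen lookup table;
  chemicals absent from it are logged and contribute nothing.
- Genome build is whatever the user's annotation uses; no liftover is
  performed, and the annotation's digest is recorded in provenance.
- The intersection carries no statistical significance; with permissive
  thresholds a large candidate set is expected and is reported as-is.
- Manual curation steps of the original analyses (hand-picking known
  developmental regulators) are represented only as an optional
  user-supplied highlight list echoed in the report.
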