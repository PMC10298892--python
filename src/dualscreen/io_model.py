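"""Domain types, validation, and table I/O for the dual-screen pipeline.

All genomic intervals are held internally in a single canonical
convention — 0-based, half-open, like BED — and every reader converts
into it at the boundary.  DECIPHER-style extracts use 1-based inclusive
coordinates; pass ``coordinate_dialect="one_based_inclusive"`` and the
reader subtracts one from the start.  Writers always emit the canonical
dialect and record it in a header comment.

Gene/protein symbols arriving from different sources (human gene
symbols, protein target names, *Xenopus laevis* homeologs carrying
``.L``/``.S`` suffixes) are reconciled through :func:`normalize_symbol`
before any cross-arm comparison.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class ValidationError(ValueError):
    """Input violates a domain invariant (duplicate ids, bad coordinates...)."""


class FormatError(ValueError):
    """A file could not be parsed into the expected table shape."""


# --------------------------------------------------------------------------
# symbol normalization
# --------------------------------------------------------------------------

_HOMEOLOG_SUFFIXES = (".L", ".S")


def normalize_symbol(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Return the canonical form of a gene/protein symbol.

    Steps, in order: optional synonym substitution (case-insensitive key
    match on the stripped input), whitespace strip, uppercase, and
    repeated removal of trailing *X. laevis* homeolog suffixes
    (``.L``/``.S``) so frog targets compare against human symbols.
    The function is idempotent.

    Raises
    ------
    ValidationError
        If ``raw`` is empty or whitespace-only.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("gene symbol is empty or whitespace-only")
    sym = str(raw).strip()
    if synonyms:
        folded = {str(k).strip().upper(): v for k, v in synonyms.items()}
        if sym.upper() in folded:
            sym = str(folded[sym.upper()]).strip()
    sym = sym.upper()
    while sym.endswith(_HOMEOLOG_SUFFIXES) and len(sym) > 2:
        sym = sym[:-2]
    if not sym:
        raise ValidationError(f"symbol {raw!r} normalizes to an empty string")
    return sym


_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def parse_bool(value: object, *, column: str = "?", row: int | None = None) -> bool:
    """Strictly parse a boolean cell; accepted spellings are fixed.

    Exactly ``1/0, true/false, yes/no, y/n`` (case-insensitive) are
    accepted; anything else raises :class:`FormatError` rather than
    being coerced, so scoring mistakes surface immediately.
    """
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    where = f" (row {row})" if row is not None else ""
    raise FormatError(
        f"unparseable boolean {value!r} in column {column!r}{where}; "
        "accepted: 1/0, true/false, yes/no, y/n"
    )


# --------------------------------------------------------------------------
# phenotype scoring types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeScore:
    """Mouth phenotype of a single embryo at the end of the screen window.

    The four recorded characteristics: presence of a stomodeum, an open
    mouth (= ruptured buccopharyngeal membrane), a cleft-like appearance
    of the open mouth, and no observable sign of a mouth at all.
    """

    stomodeum_present: bool
    mouth_open: bool
    cleft_like: bool = False
    no_mouth: bool = False

    def __post_init__(self) -> None:
        if self.no_mouth and (self.stomodeum_present or self.mouth_open):
            raise ValidationError(
                "no_mouth is incompatible with stomodeum_present or mouth_open"
            )

    @property
    def phenotype_class(self) -> str:
        """One of ``no_mouth``, ``cleft_open``, ``open``, ``persistent_bpm``,
        ``no_stomodeum``.

        ``persistent_bpm`` — stomodeum present but mouth not open — is
        the screen's phenotype of interest.
        """
        if self.no_mouth:
            return "no_mouth"
        if self.mouth_open:
            return "cleft_open" if self.cleft_like else "open"
        if self.stomodeum_present:
            return "persistent_bpm"
        return "no_stomodeum"


@dataclass(frozen=True)
class ChemicalScreenRecord:
    """One screened chemical (one well) with its per-embryo scores."""

    chemical_id: str
    embryo_scores: tuple[PhenotypeScore, ...]
    concentration_um: float | None = None
    replicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not str(self.chemical_id).strip():
            raise ValidationError("chemical_id must be non-empty")
        object.__setattr__(self, "embryo_scores", tuple(self.embryo_scores))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))


# --------------------------------------------------------------------------
# chemical -> target map
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalTargetMap:
    """Bipartite chemical–protein-target relation, symbols normalized."""

    pairs: frozenset[tuple[str, str]]
    provenance: str = ""

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        provenance: str = "",
        synonyms: Mapping[str, str] | None = None,
    ) -> "ChemicalTargetMap":
        norm = frozenset(
            (str(c).strip(), normalize_symbol(t, synonyms)) for c, t in pairs
        )
        return cls(pairs=norm, provenance=provenance)

    def targets_of(self, chemical_id: str) -> frozenset[str]:
        cid = str(chemical_id).strip()
        return frozenset(t for c, t in self.pairs if c == cid)

    @property
    def chemical_ids(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.pairs)

    @property
    def target_symbols(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)


# --------------------------------------------------------------------------
# genomic types
# --------------------------------------------------------------------------

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic span; strand ``.`` means unknown."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not str(self.chrom).strip():
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start (0-based half-open); got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"strand must be one of +, -, .; got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class PatientCNVSet:
    """A patient's copy-number deletions; may be empty (contributes no genes)."""

    patient_id: str
    deletions: tuple[GenomicInterval, ...] = ()
    phenotype_tag: str = ""

    def __post_init__(self) -> None:
        if not str(self.patient_id).strip():
            raise ValidationError("patient_id must be non-empty")
        object.__setattr__(self, "deletions", tuple(self.deletions))


def strip_chr_prefix(chrom: str) -> str:
    """Harmonize 'chr1' / '1' chromosome naming to the bare form."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") and len(c) > 3 else c


class GeneAnnotation:
    """Gene loci indexed by symbol and by chromosome.

    A symbol may map to multiple loci (multi-locus genes); all are
    indexed, and an overlap with any locus counts the gene.
    """

    def __init__(self, records: Iterable[tuple[str, GenomicInterval]]):
        self.records: tuple[tuple[str, GenomicInterval], ...] = tuple(
            (normalize_symbol(sym), iv) for sym, iv in records
        )
        self._by_symbol: dict[str, list[GenomicInterval]] = {}
        for sym, iv in self.records:
            self._by_symbol.setdefault(sym, []).append(iv)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self._by_symbol)

    @property
    def chroms(self) -> frozenset[str]:
        return frozenset(iv.chrom for _, iv in self.records)

    def loci_of(self, symbol: str) -> tuple[GenomicInterval, ...]:
        return tuple(self._by_symbol.get(normalize_symbol(symbol), ()))


@dataclass(frozen=True)
class FunctionalCategoryMap:
    """Gene -> functional-category assignments (PANTHER-style, frozen)."""

    assignments: frozenset[tuple[str, str, str]]  # (symbol, category_id, name)

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, str]]
    ) -> "FunctionalCategoryMap":
        norm = set()
        names: dict[str, str] = {}
        for sym, cid, name in rows:
            cid = str(cid).strip()
            if not cid:
                raise ValidationError("category_id must be non-empty")
            names.setdefault(cid, str(name).strip())
            norm.add((normalize_symbol(sym), cid, names[cid]))
        return cls(assignments=frozenset(norm))

    def categories_of(self, symbol: str) -> frozenset[tuple[str, str]]:
        sym = normalize_symbol(symbol)
        return frozenset((cid, name) for s, cid, name in self.assignments if s == sym)

    @property
    def category_ids(self) -> frozenset[str]:
        return frozenset(cid for _, cid, _ in self.assignments)


# --------------------------------------------------------------------------
# frequency tables and the report
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetFrequencyRow:
    target_symbol: str
    n_hit_chemicals: int
    chemical_ids: frozenset[str]


@dataclass(frozen=True)
class TargetFrequencyTable:
    """Per-target count of distinct hit chemicals, ranked."""

    rows: tuple[TargetFrequencyRow, ...]

    def __post_init__(self) -> None:
        for r in self.rows:
            if r.n_hit_chemicals != len(r.chemical_ids) or r.n_hit_chemicals < 1:
                raise ValidationError(
                    f"inconsistent frequency row for {r.target_symbol}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_symbol": [r.target_symbol for r in self.rows],
                "n_hit_chemicals": [r.n_hit_chemicals for r in self.rows],
                "chemical_ids": [",".join(sorted(r.chemical_ids)) for r in self.rows],
            }
        )


@dataclass(frozen=True)
class GeneFrequencyRow:
    gene_symbol: str
    n_patients: int
    patient_ids: frozenset[str]


@dataclass(frozen=True)
class GeneFrequencyTable:
    """Per-gene count of distinct patients with an overlapping deletion."""

    rows: tuple[GeneFrequencyRow, ...]
    cohort_size: int

    def __post_init__(self) -> None:
        for r in self.rows:
            if r.n_patients != len(r.patient_ids):
                raise ValidationError(f"inconsistent frequency row for {r.gene_symbol}")
            if r.n_patients > self.cohort_size:
                raise ValidationError(
                    f"{r.gene_symbol}: n_patients {r.n_patients} exceeds "
                    f"cohort size {self.cohort_size}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_symbol": [r.gene_symbol for r in self.rows],
                "n_patients": [r.n_patients for r in self.rows],
                "patient_ids": [",".join(sorted(r.patient_ids)) for r in self.rows],
            }
        )


@dataclass(frozen=True)
class SharedCategoryRow:
    category_id: str
    category_name: str
    n_genes_arm1: int
    n_genes_arm2: int


@dataclass
class IntegrationReport:
    """Complete, provenance-carrying result of one pipeline run."""

    focused_targets: list[str]
    target_threshold: int
    focused_genes: list[str]
    gene_threshold: int
    gene_fraction: float
    shared_categories: list[SharedCategoryRow]
    candidates: list[str]
    target_frequency: TargetFrequencyTable
    gene_frequency: GeneFrequencyTable
    chem_categories: "pd.DataFrame | None" = None
    cnv_categories: "pd.DataFrame | None" = None
    hit_chemicals: list[str] = field(default_factory=list)
    unmapped_chemicals: list[str] = field(default_factory=list)
    unclassified_targets: list[str] = field(default_factory=list)
    unclassified_genes: list[str] = field(default_factory=list)
    highlights: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.candidates) != set(self.focused_targets) & set(self.focused_genes):
            raise ValidationError(
                "candidates must equal the intersection of the focused lists"
            )


# --------------------------------------------------------------------------
# table readers / writers
# --------------------------------------------------------------------------

_CANONICAL_COMMENT = "# coordinates: 0-based half-open"
_SCREEN_BOOL_COLS = ("stomodeum_present", "mouth_open", "cleft_like", "no_mouth")
_WIDE_COUNT_COLS = ("n_persistent", "n_open", "n_cleft", "n_no_mouth")


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(f"{path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_screen_table(
    path: str | Path, dialect: str = "long"
) -> list[ChemicalScreenRecord]:
    """Read a chemical-screen table.

    ``long`` dialect: one row per embryo with columns ``chemical_id`` +
    the four boolean phenotype columns (optional ``concentration_um``,
    ``replicate_id``).  ``wide`` dialect: one row per well with
    per-class embryo counts ``n_persistent, n_open, n_cleft,
    n_no_mouth``.
    """
    df = _read_tsv(path)
    records: list[ChemicalScreenRecord] = []
    if dialect == "long":
        _require_columns(df, ("chemical_id",) + _SCREEN_BOOL_COLS, path)
        seen_order: list[str] = []
        scores: dict[str, list[PhenotypeScore]] = {}
        conc: dict[str, float | None] = {}
        reps: dict[str, list[str]] = {}
        prev_cid: str | None = None
        duplicated: set[str] = set()
        for i, row in enumerate(df.itertuples(index=False), start=2):
            cid = str(row.chemical_id).strip()
            vals = {
                c: parse_bool(getattr(row, c), column=c, row=i)
                for c in _SCREEN_BOOL_COLS
            }
            if cid in scores and cid != prev_cid:
                # rows of one well must be contiguous; a reappearing id
                # is a duplicated well, not extra embryos
                duplicated.add(cid)
            prev_cid = cid
            if cid not in scores:
                scores[cid] = []
                seen_order.append(cid)
                conc[cid] = (
                    float(row.concentration_um)
                    if "concentration_um" in df.columns
                    and str(row.concentration_um) not in ("", "nan")
                    else None
                )
                reps[cid] = []
            try:
                scores[cid].append(PhenotypeScore(**vals))
            except ValidationError as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
            if "replicate_id" in df.columns and str(row.replicate_id) not in (
                "",
                "nan",
            ):
                reps[cid].append(str(row.replicate_id))
        if duplicated:
            raise ValidationError(
                f"{path}: duplicate chemical_id(s): {', '.join(sorted(duplicated))}"
            )
        for cid in seen_order:
            records.append(
                ChemicalScreenRecord(
                    chemical_id=cid,
                    embryo_scores=tuple(scores[cid]),
                    concentration_um=conc[cid],
                    replicate_ids=tuple(dict.fromkeys(reps[cid])),
                )
            )
    elif dialect == "wide":
        _require_columns(df, ("chemical_id",) + _WIDE_COUNT_COLS, path)
        dup = df["chemical_id"].str.strip()[df["chemical_id"].str.strip().duplicated()]
        if not dup.empty:
            raise ValidationError(
                f"{path}: duplicate chemical_id(s): {', '.join(sorted(set(dup)))}"
            )
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                counts = {c: int(getattr(row, c)) for c in _WIDE_COUNT_COLS}
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path} row {i}: unparseable count") from exc
            scores_list = (
                [PhenotypeScore(True, False)] * counts["n_persistent"]
                + [PhenotypeScore(True, True)] * counts["n_open"]
                + [PhenotypeScore(True, True, cleft_like=True)] * counts["n_cleft"]
                + [PhenotypeScore(False, False, no_mouth=True)]
                * counts["n_no_mouth"]
            )
            conc_val = (
                float(row.concentration_um)
                if "concentration_um" in df.columns
                and str(row.concentration_um) not in ("", "nan")
                else None
            )
            records.append(
                ChemicalScreenRecord(
                    chemical_id=str(row.chemical_id).strip(),
                    embryo_scores=tuple(scores_list),
                    concentration_um=conc_val,
                )
            )
    else:
        raise ValidationError(f"unknown screen-table dialect {dialect!r}")
    ids = [r.chemical_id for r in records]
    dups = sorted({c for c in ids if ids.count(c) > 1})
    if dups:
        raise ValidationError(f"{path}: duplicate chemical_id(s): {', '.join(dups)}")
    return records


def write_screen_table(
    records: Iterable[ChemicalScreenRecord], path: str | Path
) -> None:
    """Write a screen table in the canonical long dialect."""
    rows = []
    for rec in records:
        for j, s in enumerate(rec.embryo_scores):
            rows.append(
                {
                    "chemical_id": rec.chemical_id,
                    "stomodeum_present": int(s.stomodeum_present),
                    "mouth_open": int(s.mouth_open),
                    "cleft_like": int(s.cleft_like),
                    "no_mouth": int(s.no_mouth),
                    "concentration_um": (
                        "" if rec.concentration_um is None else rec.concentration_um
                    ),
                    "replicate_id": (
                        rec.replicate_ids[j] if j < len(rec.replicate_ids) else ""
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_target_map(
    path: str | Path, synonyms: Mapping[str, str] | None = None
) -> ChemicalTargetMap:
    """Read a chemical_id -> target_symbol TSV (frozen lookup stand-in)."""
    df = _read_tsv(path)
    _require_columns(df, ("chemical_id", "target_symbol"), path)
    pairs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sym = str(row.target_symbol)
        if not sym.strip() or sym == "nan":
            raise ValidationError(f"{path} row {i}: empty target_symbol")
        pairs.append((str(row.chemical_id), sym))
    return ChemicalTargetMap.from_pairs(pairs, provenance=str(path), synonyms=synonyms)


def write_target_map(cmap: ChemicalTargetMap, path: str | Path) -> None:
    df = pd.DataFrame(sorted(cmap.pairs), columns=["chemical_id", "target_symbol"])
    df.to_csv(path, sep="\t", index=False)


_CNV_DIALECTS = {"bed0half", "one_based_inclusive"}


def read_cnv_table(
    path: str | Path, coordinate_dialect: str = "one_based_inclusive"
) -> list[PatientCNVSet]:
    """Read a patient CNV-deletion table and group intervals by patient.

    ``one_based_inclusive`` (the DECIPHER convention) converts a row
    ``(chr1, 101, 200)`` to canonical ``(chr1, 100, 200)``;
    ``bed0half`` rows pass through unchanged.
    """
    if coordinate_dialect not in _CNV_DIALECTS:
        raise ValidationError(
            f"coordinate_dialect must be one of {sorted(_CNV_DIALECTS)}"
        )
    df = _read_tsv(path)
    _require_columns(df, ("patient_id", "chrom", "start", "end"), path)
    order: list[str] = []
    dels: dict[str, list[GenomicInterval]] = {}
    tags: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.patient_id).strip()
        if pid not in dels:
            dels[pid] = []
            order.append(pid)
            tags[pid] = (
                str(row.phenotype) if "phenotype" in df.columns else ""
            ).replace("nan", "")
        if str(row.chrom) == "nan" or str(row.start) == "nan":
            continue  # patient row with no deletion coordinates
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {i}: unparseable coordinate") from exc
        if coordinate_dialect == "one_based_inclusive":
            start -= 1
        try:
            dels[pid].append(GenomicInterval(str(row.chrom).strip(), start, end))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return [
        PatientCNVSet(patient_id=p, deletions=tuple(dels[p]), phenotype_tag=tags[p])
        for p in order
    ]


def write_cnv_table(cohort: Iterable[PatientCNVSet], path: str | Path) -> None:
    """Write the cohort in the canonical (bed0half) dialect."""
    buf = io.StringIO()
    buf.write(_CANONICAL_COMMENT + "\n")
    buf.write("patient_id\tchrom\tstart\tend\tphenotype\n")
    for p in cohort:
        for iv in p.deletions:
            buf.write(
                f"{p.patient_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{p.phenotype_tag}\n"
            )
    Path(path).write_text(buf.getvalue())


def read_gene_annotation(path: str | Path, dialect: str = "tsv") -> GeneAnnotation:
    """Read gene loci as a headered TSV (canonical coordinates) or BED6."""
    records: list[tuple[str, GenomicInterval]] = []
    if dialect == "tsv":
        df = _read_tsv(path)
        _require_columns(df, ("symbol", "chrom", "start", "end"), path)
        for i, row in enumerate(df.itertuples(index=False), start=2):
            strand = str(row.strand) if "strand" in df.columns else "."
            if strand in ("nan", ""):
                strand = "."
            try:
                iv = GenomicInterval(
                    str(row.chrom).strip(), int(row.start), int(row.end), strand
                )
            except (TypeError, ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
            records.append((str(row.symbol), iv))
    elif dialect == "bed6":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path} line {i}: expected >=4 BED fields")
            strand = parts[5] if len(parts) >= 6 else "."
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} line {i}: {exc}") from exc
            records.append((parts[3], iv))
    else:
        raise ValidationError(f"unknown annotation dialect {dialect!r}")
    return GeneAnnotation(records)


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write(_CANONICAL_COMMENT + "\n")
    buf.write("symbol\tchrom\tstart\tend\tstrand\n")
    for sym, iv in annotation.records:
        buf.write(f"{sym}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")
    Path(path).write_text(buf.getvalue())


def read_category_map(path: str | Path) -> FunctionalCategoryMap:
    df = _read_tsv(path)
    _require_columns(df, ("gene_symbol", "category_id", "category_name"), path)
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if str(row.category_id) in ("", "nan"):
            raise ValidationError(f"{path} row {i}: empty category_id")
        rows.append((str(row.gene_symbol), str(row.category_id), str(row.category_name)))
    return FunctionalCategoryMap.from_rows(rows)


def write_category_map(cmap: FunctionalCategoryMap, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(cmap.assignments),
        columns=["gene_symbol", "category_id", "category_name"],
    )
    df.to_csv(path, sep="\t", index=False)


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, recorded in report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
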