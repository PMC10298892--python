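"""Arm 1 — the phenotypic chemical screen.

A *hit* is a chemical whose treated embryos retain a stomodeum but fail
to open the mouth: the buccopharyngeal membrane persists past its
normal rupture window.  Hits are deconvoluted to their known protein
targets through a frozen chemical→target lookup table, targets are
ranked by how many distinct hit chemicals act on them, and the ranking
is focused with a minimum-chemicals filter (default: at least three).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from dualscreen.io_model import (
    ChemicalScreenRecord,
    ChemicalTargetMap,
    TargetFrequencyRow,
    TargetFrequencyTable,
    ValidationError,
)

log = logging.getLogger(__name__)

_HIT_MODES = {"majority", "all", "fraction"}


@dataclass(frozen=True)
class HitRule:
    """How per-embryo phenotypes aggregate into a per-well hit call.

    ``majority`` (default): more than half of the *scoreable* embryos
    show the persistent-membrane phenotype.  Embryos with no observable
    mouth at all are excluded from both numerator and denominator by
    default — a hit requires an observable stomodeum, and mouthless
    embryos are evidence of an earlier, different defect.

    ``all``: every embryo in the well (mouthless ones included) shows
    the phenotype — the strictest reading.

    ``fraction``: at least ``fraction`` of scoreable embryos show it.
    """

    mode: str = "majority"
    fraction: float = 0.5
    count_no_mouth: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _HIT_MODES:
            raise ValidationError(f"hit-rule mode must be one of {sorted(_HIT_MODES)}")
        if self.mode == "fraction" and not (0.0 < self.fraction <= 1.0):
            raise ValidationError("hit-rule fraction must lie in (0, 1]")


def call_hit(
    record: ChemicalScreenRecord, rule: HitRule = HitRule()
) -> tuple[bool, list[str]]:
    """Call hit status for one well; also return per-embryo classes.

    Returns ``(hit, classes)`` where ``classes[i]`` is the phenotype
    class of embryo *i* (``persistent_bpm``, ``open``, ``cleft_open``,
    ``no_mouth``, ``no_stomodeum``).  Deterministic and invariant under
    permutation of the embryo scores.
    """
    if not record.embryo_scores:
        raise ValidationError(
            f"chemical {record.chemical_id}: no embryo scores to call a hit from"
        )
    classes = [s.phenotype_class for s in record.embryo_scores]
    n_persistent = sum(c == "persistent_bpm" for c in classes)
    n_total = len(classes)
    if rule.mode == "all":
        return n_persistent == n_total, classes
    n_scoreable = (
        n_total if rule.count_no_mouth else sum(c != "no_mouth" for c in classes)
    )
    if n_scoreable == 0:
        return False, classes
    if rule.mode == "majority":
        return n_persistent > 0.5 * n_scoreable, classes
    return n_persistent >= rule.fraction * n_scoreable, classes


def call_hits(
    records: Iterable[ChemicalScreenRecord], rule: HitRule = HitRule()
) -> list[str]:
    """Hit chemical ids for a whole screen, in input order."""
    return [r.chemical_id for r in records if call_hit(r, rule)[0]]


_MEMBRANE_CATEGORIES = ("intact", "partial", "absent")


def tabulate_phenotypes(
    scores: Mapping[str, Sequence[str]], decimals: int = 1
) -> pd.DataFrame:
    """Per-group membrane-state proportion table.

    ``scores`` maps a group label to that group's per-embryo membrane
    categories (``intact`` / ``partial`` / ``absent``).  Output carries
    raw counts alongside percentages rounded to ``decimals`` places;
    within rounding, each group's percentages sum to 100.
    """
    rows = []
    for group, cats in scores.items():
        bad = sorted({c for c in cats if c not in _MEMBRANE_CATEGORIES})
        if bad:
            raise ValidationError(
                f"group {group!r}: unknown membrane category label(s) "
                f"{', '.join(bad)}; expected {_MEMBRANE_CATEGORIES}"
            )
        n = len(cats)
        row: dict[str, object] = {"group": group, "n": n}
        for cat in _MEMBRANE_CATEGORIES:
            count = sum(c == cat for c in cats)
            row[f"n_{cat}"] = count
            row[f"pct_{cat}"] = round(100.0 * count / n, decimals) if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def map_hits_to_targets(
    hits: Iterable[str], cmap: ChemicalTargetMap
) -> tuple[dict[str, frozenset[str]], frozenset[str], list[str]]:
    """Deconvolute hit chemicals to their protein targets.

    Returns ``(per_chemical, unique_targets, unmapped)``: the target set
    of every hit chemical, their union after symbol normalization, and
    the hit chemicals absent from the lookup table.  Unmapped chemicals
    yield empty sets and are logged, never dropped silently.
    """
    per_chemical: dict[str, frozenset[str]] = {}
    unmapped: list[str] = []
    for cid in hits:
        targets = cmap.targets_of(cid)
        per_chemical[str(cid).strip()] = targets
        if not targets:
            unmapped.append(str(cid).strip())
    if unmapped:
        log.warning(
            "%d hit chemical(s) have no known targets: %s",
            len(unmapped),
            ", ".join(unmapped),
        )
    unique = frozenset().union(*per_chemical.values()) if per_chemical else frozenset()
    return per_chemical, unique, unmapped


def target_frequency(
    hits: Iterable[str], cmap: ChemicalTargetMap
) -> TargetFrequencyTable:
    """Rank targets by the number of DISTINCT hit chemicals acting on them.

    Sorted by count descending; ties broken alphabetically by symbol.
    """
    per_chemical, _, _ = map_hits_to_targets(hits, cmap)
    by_target: dict[str, set[str]] = {}
    for cid, targets in per_chemical.items():
        for t in targets:
            by_target.setdefault(t, set()).add(cid)
    rows = [
        TargetFrequencyRow(
            target_symbol=t, n_hit_chemicals=len(cids), chemical_ids=frozenset(cids)
        )
        for t, cids in by_target.items()
    ]
    rows.sort(key=lambda r: (-r.n_hit_chemicals, r.target_symbol))
    return TargetFrequencyTable(rows=tuple(rows))


def filter_targets_min_chemicals(
    table: TargetFrequencyTable, k: int = 3
) -> list[str]:
    """Focused target list: symbols hit by at least ``k`` distinct chemicals.

    Order is preserved from the ranked frequency table; antitone in
    ``k`` (raising ``k`` can only shrink the list).
    """
    if k < 1:
        raise ValidationError(f"minimum-chemicals threshold k must be >= 1, got {k}")
    kept = [r.target_symbol for r in table.rows if r.n_hit_chemicals >= k]
    log.info(
        "minimum-chemicals filter (k=%d): %d -> %d targets", k, len(table.rows), len(kept)
    )
    return kept
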