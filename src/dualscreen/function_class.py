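"""Functional-category profiling and cross-arm shared categories.

Re-implements the classification step as plain counting over a frozen
gene→category table (a PANTHER-style extract): per input gene list,
count members of each category, keep categories reaching a minimum
size (default 5), and report the categories that survive the cutoff in
both screening arms.  No enrichment statistics are computed — the
analysis is a raw-count profile, matched across arms by category id
(display names drift; identifiers do not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from dualscreen.io_model import (
    FunctionalCategoryMap,
    SharedCategoryRow,
    ValidationError,
    normalize_symbol,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryProfile:
    """Category count table for one gene list, min-size filtered.

    ``counts`` has columns ``category_id, category_name, n_genes,
    genes``; ``unclassified`` lists input genes absent from the map —
    reported, never silently dropped (functional-annotation coverage is
    partial and the gap should stay visible).
    """

    counts: pd.DataFrame
    unclassified: tuple[str, ...]
    min_genes: int
    n_input_genes: int


def classify_functional(
    genes: Iterable[str],
    cmap: FunctionalCategoryMap,
    min_genes: int = 5,
) -> CategoryProfile:
    """Count input genes per functional category; keep categories with
    at least ``min_genes`` members.

    Multi-membership is respected (a gene contributes to every category
    it belongs to) but a gene never counts twice within one category.
    Sorted by count descending, ties alphabetical by category id.
    """
    if min_genes < 1:
        raise ValidationError(f"min_genes must be >= 1, got {min_genes}")
    gene_set = {normalize_symbol(g) for g in genes}
    members: dict[tuple[str, str], set[str]] = {}
    classified: set[str] = set()
    for sym, cid, name in cmap.assignments:
        if sym in gene_set:
            members.setdefault((cid, name), set()).add(sym)
            classified.add(sym)
    rows = [
        {
            "category_id": cid,
            "category_name": name,
            "n_genes": len(syms),
            "genes": ",".join(sorted(syms)),
        }
        for (cid, name), syms in members.items()
        if len(syms) >= min_genes
    ]
    rows.sort(key=lambda r: (-r["n_genes"], r["category_id"]))
    unclassified = tuple(sorted(gene_set - classified))
    if unclassified:
        log.info(
            "%d of %d genes have no category assignment", len(unclassified), len(gene_set)
        )
    return CategoryProfile(
        counts=pd.DataFrame(
            rows, columns=["category_id", "category_name", "n_genes", "genes"]
        ),
        unclassified=unclassified,
        min_genes=min_genes,
        n_input_genes=len(gene_set),
    )


def shared_categories(
    profile_a: CategoryProfile, profile_b: CategoryProfile
) -> list[SharedCategoryRow]:
    """Categories surviving the size cutoff in BOTH arms.

    Matched on category id; each row carries both arms' counts, ordered
    by combined count descending, ties alphabetical by id.  Symmetric:
    swapping the arguments permutes the two count columns only.
    """
    a = {r.category_id: r for r in profile_a.counts.itertuples(index=False)}
    b = {r.category_id: r for r in profile_b.counts.itertuples(index=False)}
    rows = [
        SharedCategoryRow(
            category_id=cid,
            category_name=a[cid].category_name,
            n_genes_arm1=int(a[cid].n_genes),
            n_genes_arm2=int(b[cid].n_genes),
        )
        for cid in set(a) & set(b)
    ]
    rows.sort(key=lambda r: (-(r.n_genes_arm1 + r.n_genes_arm2), r.category_id))
    return rows


def shared_categories_frame(rows: list[SharedCategoryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category_id": r.category_id,
                "category_name": r.category_name,
                "n_genes_arm1": r.n_genes_arm1,
                "n_genes_arm2": r.n_genes_arm2,
            }
            for r in rows
        ],
        columns=["category_id", "category_name", "n_genes_arm1", "n_genes_arm2"],
    )
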