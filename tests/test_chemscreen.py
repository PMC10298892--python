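"""Hit calling, target deconvolution, frequency ranking, focus filter."""

import random

import pytest

from dualscreen.chemscreen import (
    HitRule,
    call_hit,
    call_hits,
    filter_targets_min_chemicals,
    map_hits_to_targets,
    tabulate_phenotypes,
    target_frequency,
)
from dualscreen.io_model import (
    ChemicalScreenRecord,
    ChemicalTargetMap,
    PhenotypeScore,
    ValidationError,
)
from dualscreen.synthetic import SyntheticSpec, generate_chemical_screen

PERSISTENT = PhenotypeScore(True, False)
OPEN = PhenotypeScore(True, True)
NO_MOUTH = PhenotypeScore(False, False, no_mouth=True)


def well(*scores, cid="NSC1"):
    return ChemicalScreenRecord(chemical_id=cid, embryo_scores=tuple(scores))


# ---------------------------------------------------------------- hit calling


def test_all_persistent_embryos_is_a_hit():
    hit, classes = call_hit(well(*[PERSISTENT] * 6))
    assert hit and classes == ["persistent_bpm"] * 6


def test_all_open_mouths_is_not_a_hit():
    hit, _ = call_hit(well(*[OPEN] * 6))
    assert not hit


def test_no_mouth_embryos_shift_majority_vs_all_rules():
    # 4/6 persistent, 2/6 mouthless: mouthless embryos are excluded
    # under the default majority rule but count against an all-embryos rule
    w = well(*([PERSISTENT] * 4 + [NO_MOUTH] * 2))
    assert call_hit(w, HitRule(mode="majority"))[0]
    assert not call_hit(w, HitRule(mode="all"))[0]


def test_all_no_mouth_is_never_a_hit():
    assert not call_hit(well(*[NO_MOUTH] * 6))[0]


def test_fraction_rule_boundary():
    w = well(*([PERSISTENT] * 3 + [OPEN] * 3))
    assert call_hit(w, HitRule(mode="fraction", fraction=0.5))[0]
    assert not call_hit(w, HitRule(mode="majority"))[0]  # strict majority


def test_hit_call_invariant_under_embryo_permutation():
    scores = [PERSISTENT] * 4 + [OPEN] + [NO_MOUTH]
    rnd = random.Random(5)
    calls = set()
    for _ in range(10):
        rnd.shuffle(scores)
        calls.add(call_hit(well(*scores))[0])
    assert calls == {True}


def test_empty_scores_rejected():
    rec = ChemicalScreenRecord.__new__(ChemicalScreenRecord)
    object.__setattr__(rec, "chemical_id", "NSC1")
    object.__setattr__(rec, "embryo_scores", ())
    with pytest.raises(ValidationError):
        call_hit(rec)


def test_invalid_hit_rule_rejected():
    with pytest.raises(ValidationError):
        HitRule(mode="plurality")
    with pytest.raises(ValidationError):
        HitRule(mode="fraction", fraction=0.0)


# ---------------------------------------------------------------- proportions


def test_tabulate_single_category_group():
    df = tabulate_phenotypes({"treated": ["absent"] * 60})
    row = df.iloc[0]
    assert row["pct_absent"] == 100.0 and row["n"] == 60


def test_tabulate_percentages_match_print_convention():
    # 49 of 60 embryos retain some membrane -> 81.7% to one decimal
    cats = ["intact"] * 30 + ["partial"] * 19 + ["absent"] * 11
    df = tabulate_phenotypes({"inhibitor": cats})
    row = df.iloc[0]
    assert round(row["pct_intact"] + row["pct_partial"], 1) == 81.7
    assert row["n_intact"] + row["n_partial"] + row["n_absent"] == 60


def test_tabulate_identical_groups_identical_rows():
    cats = ["intact", "partial", "absent"] * 4
    df = tabulate_phenotypes({"a": cats, "b": list(cats)})
    assert df.iloc[0].drop("group").equals(df.iloc[1].drop("group"))


def test_tabulate_unknown_category_rejected():
    with pytest.raises(ValidationError, match="ruptured"):
        tabulate_phenotypes({"g": ["intact", "ruptured"]})


# ---------------------------------------------------------------- deconvolution


def test_map_hits_union(toy_target_map):
    cmap = ChemicalTargetMap.from_pairs([("A", "T1"), ("A", "T2"), ("B", "T2")])
    _, unique, unmapped = map_hits_to_targets(["A", "B"], cmap)
    assert unique == {"T1", "T2"} and unmapped == []


def test_map_hits_empty_and_unmapped(toy_target_map):
    assert map_hits_to_targets([], toy_target_map)[1] == frozenset()
    per, unique, unmapped = map_hits_to_targets(["ZZZ"], toy_target_map)
    assert unique == frozenset() and unmapped == ["ZZZ"]
    assert per["ZZZ"] == frozenset()


def test_target_frequency_ranking(toy_target_map):
    table = target_frequency(["A", "B", "C", "D"], toy_target_map)
    assert [(r.target_symbol, r.n_hit_chemicals) for r in table.rows] == [
        ("T1", 3), ("T2", 2), ("T3", 1)
    ]


def test_duplicate_map_pairs_count_once():
    cmap = ChemicalTargetMap.from_pairs([("A", "T1"), ("A", "t1 "), ("A", "T1")])
    table = target_frequency(["A"], cmap)
    assert [(r.target_symbol, r.n_hit_chemicals) for r in table.rows] == [("T1", 1)]


def test_empty_hits_empty_table(toy_target_map):
    assert target_frequency([], toy_target_map).rows == ()


def test_frequency_ties_broken_alphabetically():
    cmap = ChemicalTargetMap.from_pairs([("A", "ZZZ"), ("A", "AAA"), ("B", "MMM")])
    table = target_frequency(["A", "B"], cmap)
    assert [r.target_symbol for r in table.rows] == ["AAA", "MMM", "ZZZ"]


# ---------------------------------------------------------------- focus filter


def test_filter_min_chemicals(toy_target_map):
    table = target_frequency(["A", "B", "C", "D"], toy_target_map)
    assert filter_targets_min_chemicals(table, 3) == ["T1"]
    assert filter_targets_min_chemicals(table, 1) == ["T1", "T2", "T3"]
    with pytest.raises(ValidationError):
        filter_targets_min_chemicals(table, 0)


def test_filter_antitone_in_k(toy_target_map):
    table = target_frequency(["A", "B", "C", "D"], toy_target_map)
    lists = [set(filter_targets_min_chemicals(table, k)) for k in range(1, 6)]
    for smaller_k, larger_k in zip(lists, lists[1:]):
        assert larger_k <= smaller_k


# ---------------------------------------------------------------- properties


def test_degree_sum_identity_on_synthetic_screen(small_spec):
    """Sum of per-target counts equals sum of per-hit-chemical degrees."""
    records, cmap, truth = generate_chemical_screen(small_spec)
    hits = call_hits(records)
    table = target_frequency(hits, cmap)
    lhs = sum(r.n_hit_chemicals for r in table.rows)
    rhs = sum(len(cmap.targets_of(c)) for c in hits)
    assert lhs == rhs


@pytest.mark.parametrize("seed", range(20))
def test_planted_target_degree_recovered(seed, small_spec):
    from dataclasses import replace

    spec = replace(small_spec, seed=seed)
    records, cmap, truth = generate_chemical_screen(spec)
    hits = call_hits(records)
    assert set(truth["hit_chemicals"]) == set(hits)
    table = target_frequency(hits, cmap)
    by_symbol = {r.target_symbol: r.n_hit_chemicals for r in table.rows}
    assert by_symbol[spec.planted_target] == spec.planted_target_chemicals
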