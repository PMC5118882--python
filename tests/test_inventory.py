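"""Inventory ranking, domain filtering, prior comparison and semantic
annotation tests."""

import itertools
import random

import pandas as pd
import pytest

from _oracles import brute_force_ranking
from cdeharvest import (
    assign_domains,
    cluster_labels,
    compare_inventories,
    filter_domains,
    rank_elements,
)
from cdeharvest.domains import FormDomainAssignment
from cdeharvest.inventory import (
    CanonicalElement,
    annotate,
    inventory_from_frame,
    inventory_to_frame,
)
from cdeharvest.model import TrialMeta
from cdeharvest.normalize import ElementCluster


def _dom_table(rows):
    return pd.DataFrame(
        rows, columns=["domain_key", "display_name", "sdtm_code",
                       "n_trials", "n_forms", "n_unique_elements"]
    )


def test_filter_domains_drops_singletons():
    table = _dom_table([
        ("VS", "Vital Signs", "VS", 3, 5, 10),
        ("RS", "Tumor response", "RS", 1, 1, 4),   # one form -> dropped
        ("PE", "Physical Examination", "PE", 1, 2, 3),  # two forms, one trial -> kept
    ])
    out = filter_domains(table)
    assert list(out.domain_key) == ["VS", "PE"]


def test_filter_domains_empty_table():
    empty = _dom_table([])
    assert filter_domains(empty).empty


def _cluster(cid, label, members):
    return ElementCluster(
        cluster_id=cid, canonical_label=label,
        variants={(label, tr, fid) for tr, fid, _ in members},
        members=sorted(members),
    )


TRIALS = [
    TrialMeta("T1", "oncology", 1000, 201),
    TrialMeta("T2", "diabetes", 2500, 300),
    TrialMeta("T3", "respiratory", 4000, 400),
]
ASSIGN = [
    FormDomainAssignment("F1", "VS", "keyword"),
    FormDomainAssignment("F2", "VS", "keyword"),
    FormDomainAssignment("F3", "LB", "keyword"),
]


def test_weighted_score_sums_distinct_trial_enrollments():
    clusters = [
        _cluster("C1", "Heart Rate",
                 [("T1", "F1", "I1"), ("T2", "F2", "I1"), ("T2", "F2", "I9")]),
    ]
    rows = rank_elements(clusters, ASSIGN, TRIALS)
    assert rows[0].weighted_score == 3500  # 1000 + 2500, T2 counted once
    assert rows[0].n_trials == 2


def test_rank_tie_break_by_trials_then_label():
    clusters = [
        _cluster("C1", "Zeta", [("T3", "F1", "I1")]),
        _cluster("C2", "Alpha", [("T1", "F1", "I2"), ("T2", "F2", "I2")]),
        _cluster("C3", "Beta", [("T3", "F2", "I3")]),
    ]
    rows = rank_elements(clusters, ASSIGN, TRIALS)
    # C1: 4000/1 trial; C2: 3500/2 trials; C3: 4000/1 trial
    assert [r.element.canonical_label for r in rows] == ["Beta", "Zeta", "Alpha"]
    assert [r.rank for r in rows] == [1, 2, 3]


def test_score_monotone_in_added_trial():
    base = [_cluster("C1", "Heart Rate", [("T1", "F1", "I1")])]
    more = [_cluster("C1", "Heart Rate",
                     [("T1", "F1", "I1"), ("T3", "F2", "I1")])]
    s0 = rank_elements(base, ASSIGN, TRIALS)[0].weighted_score
    s1 = rank_elements(more, ASSIGN, TRIALS)[0].weighted_score
    assert s1 >= s0


def test_element_spanning_domains_gets_row_per_domain():
    clusters = [
        _cluster("C1", "Assessment Date",
                 [("T1", "F1", "I1"), ("T2", "F3", "I1")]),
    ]
    rows = rank_elements(clusters, ASSIGN, TRIALS)
    assert sorted(r.element.domain_key for r in rows) == ["LB", "VS"]
    assert {r.element.cde_id for r in rows} == {"C1@VS", "C1@LB"}


def test_rank_matches_brute_force_under_permutation(small_corpus):
    """Ranking equals an independent recomputation for every tested
    permutation of the cluster input order."""
    ss, _ = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    assignments = assign_domains(ss)
    expected = brute_force_ranking(clusters, assignments, ss.trials)
    rng = random.Random(5)
    orders = [clusters, list(reversed(clusters))]
    shuffled = list(clusters)
    rng.shuffle(shuffled)
    orders.append(shuffled)
    for order in orders:
        rows = rank_elements(order, assignments, ss.trials)
        got = [
            (r.element.cde_id, r.element.canonical_label,
             r.element.domain_key, r.weighted_score, r.n_trials,
             r.n_form_occurrences)
            for r in rows
        ]
        assert got == expected
        assert [r.rank for r in rows] == list(range(1, len(rows) + 1))


def test_rank_small_exhaustive_permutations():
    clusters = [
        _cluster("C1", "A", [("T1", "F1", "I1")]),
        _cluster("C2", "B", [("T2", "F2", "I1")]),
        _cluster("C3", "C", [("T3", "F3", "I1")]),
    ]
    expected = brute_force_ranking(clusters, ASSIGN, TRIALS)
    for perm in itertools.permutations(clusters):
        rows = rank_elements(list(perm), ASSIGN, TRIALS)
        assert [
            (r.element.cde_id, r.element.canonical_label, r.element.domain_key,
             r.weighted_score, r.n_trials, r.n_form_occurrences)
            for r in rows
        ] == expected


def test_per_form_weighting_counts_form_occurrences():
    clusters = [
        _cluster("C1", "Heart Rate", [("T1", "F1", "I1"), ("T1", "F2", "I1")]),
    ]
    per_trial = rank_elements(clusters, ASSIGN, TRIALS)[0].weighted_score
    per_form = rank_elements(clusters, ASSIGN, TRIALS,
                             weight="per_form")[0].weighted_score
    assert per_trial == 1000
    assert per_form == 2000


# --- comparison ------------------------------------------------------------

def _inv_rows(specs):
    rows = rank_elements(
        [_cluster(f"C{k}", label, [("T1", "F1", f"I{k}")])
         for k, (label, _cui) in enumerate(specs, start=1)],
        ASSIGN, TRIALS,
    )
    for r, (_label, cui) in zip(sorted(rows, key=lambda r: r.element.cde_id), specs):
        r.element.umls_cui = cui
    return rows


def test_compare_inventories_counts_partition():
    current = _inv_rows([("Heart Rate", None), ("Weight", None)])
    prior = pd.DataFrame({"canonical_label": ["heart rate"], "umls_cui": [""]})
    cmp = compare_inventories(current, prior)
    assert (cmp.n_identical, cmp.n_new) == (1, 1)
    assert cmp.n_identical + cmp.n_new == len(current)


def test_compare_empty_prior_all_new():
    current = _inv_rows([("Heart Rate", None)])
    cmp = compare_inventories(current, pd.DataFrame(columns=["canonical_label"]))
    assert cmp.n_new == 1 and cmp.n_identical == 0


def test_compare_cui_beats_label():
    current = _inv_rows([("Pulse", "C0018810")])
    prior = pd.DataFrame(
        {"canonical_label": ["heart rate"], "umls_cui": ["C0018810"]}
    )
    assert compare_inventories(current, prior).n_identical == 1


def test_compare_duplicate_prior_keys_fatal():
    current = _inv_rows([("Heart Rate", None)])
    prior = pd.DataFrame({"canonical_label": ["x", "x"]})
    with pytest.raises(ValueError, match="duplicate"):
        compare_inventories(current, prior)


# --- annotation ------------------------------------------------------------

def test_annotate_attaches_codes_and_flags_unmapped():
    rows = _inv_rows([("Heart Rate", None), ("Weight", None)])
    code_map = pd.DataFrame(
        [{"key": "Heart Rate", "umls_cui": "C0018810",
          "snomed_code": "364075005", "definition": "beats per minute"}]
    )
    out = annotate(rows, code_map)
    coded = next(r for r in out if r.element.canonical_label == "Heart Rate")
    other = next(r for r in out if r.element.canonical_label == "Weight")
    assert coded.element.umls_cui == "C0018810"
    assert coded.element.snomed_code == "364075005"
    assert not coded.uncoded
    assert other.uncoded


def test_annotate_invalid_code_fatal():
    rows = _inv_rows([("Heart Rate", None)])
    bad = pd.DataFrame([{"key": "Heart Rate", "umls_cui": "18810",
                         "snomed_code": ""}])
    with pytest.raises(ValueError, match="row 0"):
        annotate(rows, bad)


def test_annotate_empty_map_all_uncoded():
    rows = _inv_rows([("Heart Rate", None)])
    assert all(r.uncoded for r in annotate(rows, None))


def test_canonical_element_code_syntax():
    with pytest.raises(ValueError, match="CUI"):
        CanonicalElement("X", "X", "VS", umls_cui="0018810")
    with pytest.raises(ValueError, match="SNOMED"):
        CanonicalElement("X", "X", "VS", snomed_code="36-40")


def test_inventory_frame_round_trip(small_corpus):
    ss, _ = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    rows = rank_elements(clusters, assign_domains(ss), ss.trials)
    back = inventory_from_frame(inventory_to_frame(rows))
    assert [(r.element.cde_id, r.rank, r.weighted_score) for r in back] == [
        (r.element.cde_id, r.rank, r.weighted_score) for r in rows
    ]
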