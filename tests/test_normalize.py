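"""Label cleaning, matching-rule and clustering tests."""

import random

import pandas as pd
import pytest

from cdeharvest import (
    SimilarityConfig,
    apply_overrides,
    clean_label,
    cluster_labels,
    is_match,
)
from cdeharvest.evaluate import exact_recovery, pairwise_cluster_score
from cdeharvest.model import ItemRecord
from cdeharvest.normalize import clusters_from_frame, clusters_to_frame


@pytest.mark.parametrize(
    "raw,text,units",
    [
        ("<b>Heart Rate</b> (bpm)", "Heart Rate", "bpm"),
        ("Bilirubin,   total", "Bilirubin, total", None),
        ("<span style='x'>Weight</span> [kg]", "Weight", "kg"),
        ("  Plain label  ", "Plain label", None),
        ("Temperature (axillary)", "Temperature (axillary)", None),  # not a unit
        ("Gr&ouml;&szlig;e", "Größe", None),
    ],
)
def test_clean_label(raw, text, units):
    cl = clean_label(raw)
    assert cl.text == text
    assert cl.removed_units == units


def test_clean_label_empty_after_clean_flagged():
    cl = clean_label("<b> </b>")
    assert cl.empty
    with pytest.raises(ValueError):
        clean_label(None)


def test_is_match_exact_casefold():
    ok, reason = is_match("Heart Rate", "heart rate")
    assert ok and reason == "exact"


def test_is_match_unequal_hard_keys_veto():
    ok, reason = is_match("Systolic BP", "Diastolic BP", "SYSBP", "DIABP")
    assert not ok
    # even identical text loses to unequal variable names
    assert not is_match("Blood Pressure", "Blood Pressure", "SYSBP", "DIABP")[0]


def test_is_match_equal_hard_keys_win():
    ok, reason = is_match("totally", "different", "VSHR", "vshr")
    assert ok and reason == "cdisc"


def test_is_match_fuzzy_spelling_variant():
    ok, reason = is_match("Hemoglobin", "Haemoglobin")
    assert ok and reason == "fuzzy"


def test_is_match_rejects_distant_labels():
    assert not is_match("Heart Rate", "Respiratory Rate")[0]


def test_similarity_config_validation():
    with pytest.raises(ValueError):
        SimilarityConfig(jw_threshold=1.5)
    with pytest.raises(ValueError):
        SimilarityConfig(lev_len_ratio=0.0)
    with pytest.raises(ValueError):
        SimilarityConfig(winkler_prefix_weight=0.5)


def _items(labels, form="F1", varnames=None):
    varnames = varnames or [None] * len(labels)
    return [
        ItemRecord(item_id=f"I{k}", form_id=form, raw_label=lab,
                   cdisc_variable_name=vn)
        for k, (lab, vn) in enumerate(zip(labels, varnames), start=1)
    ]


def test_cluster_merges_markup_case_and_unit_variants():
    items = _items(["Heart Rate", "heart rate", "<b>Heart Rate</b> (bpm)"])
    clusters = cluster_labels(items)
    assert len(clusters) == 1
    assert clusters[0].canonical_label == "Heart Rate"
    assert len(clusters[0].members) == 3


def test_cluster_output_is_partition(small_corpus):
    ss, _ = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    member_keys = [m for c in clusters for m in c.members]
    assert len(member_keys) == ss.n_items  # conservation
    assert len(set(member_keys)) == len(member_keys)  # disjointness


def test_cluster_invariant_under_input_permutation(small_corpus):
    ss, _ = small_corpus
    items = list(ss.iter_items())
    ref = cluster_labels(items, form_trial=ss.form_trial_map())
    rng = random.Random(3)
    for _ in range(3):
        rng.shuffle(items)
        got = cluster_labels(items, form_trial=ss.form_trial_map())
        assert [(c.cluster_id, c.canonical_label, tuple(c.members))
                for c in got] == [
            (c.cluster_id, c.canonical_label, tuple(c.members)) for c in ref
        ]


def test_cluster_recovery_on_noisy_small_corpus(small_corpus):
    ss, truth = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    score = pairwise_cluster_score(clusters, truth.true_partition)
    assert score.precision >= 0.95
    assert score.recall >= 0.95


def test_cluster_exact_recovery_without_noise(small_corpus_clean):
    ss, truth = small_corpus_clean
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    assert exact_recovery(clusters, truth.true_partition)


def test_cluster_blowup_warning():
    # one giant exact-duplicate cluster dominates the input
    labels = ["Heart Rate"] * 30 + ["Weight", "Calcium"]
    with pytest.warns(UserWarning, match="largest cluster"):
        cluster_labels(_items(labels))


def test_cluster_round_trip_via_frame(small_corpus):
    ss, _ = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    back = clusters_from_frame(clusters_to_frame(clusters))
    assert {c.cluster_id: tuple(c.members) for c in back} == {
        c.cluster_id: tuple(c.members) for c in clusters
    }


# --- overrides -------------------------------------------------------------

def _toy_clusters():
    items = _items(["Heart Rate", "heart rate", "Weight", "Calcium"])
    return cluster_labels(items)


def _ov(rows):
    return pd.DataFrame(rows, columns=["action", "target", "argument"])


def test_override_rename_locks():
    clusters = _toy_clusters()
    cid = next(c.cluster_id for c in clusters if c.canonical_label == "Heart Rate")
    out = apply_overrides(clusters, _ov([("rename", cid, "Heart rate")]))
    renamed = next(c for c in out if c.cluster_id == cid)
    assert renamed.canonical_label == "Heart rate"
    assert renamed.locked


def test_override_merge_then_split_conserves_variants():
    clusters = _toy_clusters()
    ids = {c.canonical_label: c.cluster_id for c in clusters}
    before = sorted(v for c in clusters for v in c.variants)
    out = apply_overrides(
        clusters,
        _ov([
            ("merge", ids["Weight"], ids["Calcium"]),
            ("split", ids["Weight"], "Calcium"),
        ]),
    )
    after = sorted(v for c in out for v in c.variants)
    assert after == before
    member_keys = [m for c in out for m in c.members]
    assert len(member_keys) == len(set(member_keys)) == 4


def test_override_remove_and_recategorize():
    clusters = _toy_clusters()
    ids = {c.canonical_label: c.cluster_id for c in clusters}
    out = apply_overrides(
        clusters,
        _ov([
            ("remove", ids["Weight"], "irrelevant"),
            ("recategorize", ids["Calcium"], "administrative"),
        ]),
    )
    assert all(c.cluster_id != ids["Weight"] for c in out)
    assert next(c for c in out if c.cluster_id == ids["Calcium"]).category == (
        "administrative"
    )


def test_override_empty_table_is_identity():
    clusters = _toy_clusters()
    out = apply_overrides(clusters, None)
    assert [(c.cluster_id, c.canonical_label) for c in out] == [
        (c.cluster_id, c.canonical_label) for c in clusters
    ]


def test_override_unknown_target_is_fatal():
    clusters = _toy_clusters()
    with pytest.raises(ValueError, match="unknown"):
        apply_overrides(clusters, _ov([("rename", "NOPE", "x")]))
    with pytest.raises(ValueError, match="clinical"):
        apply_overrides(
            clusters,
            _ov([("recategorize", clusters[0].cluster_id, "banana")]),
        )


def test_clusters_never_mix_distinct_variable_names(small_corpus):
    ss, _ = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    form_items = {(f.form_id, i.item_id): i for f in ss.forms for i in f.items}
    for c in clusters:
        names = {
            form_items[(fid, iid)].cdisc_variable_name
            for _tr, fid, iid in c.members
        } - {None}
        assert len(names) <= 1
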