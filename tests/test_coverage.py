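"""Frequency-of-documentation and heat-map tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdeharvest import (
    CoverageCell,
    SiteExport,
    build_heatmap,
    classify_cell,
    compute_frequency,
    coverage_pipeline,
)
from cdeharvest.coverage import (
    AVAILABLE,
    FREQUENCY,
    NOT_AVAILABLE,
    ExportRowError,
    match_element,
)
from cdeharvest.domains import FormDomainAssignment
from cdeharvest.inventory import rank_elements
from cdeharvest.model import TrialMeta
from cdeharvest.normalize import ElementCluster


@pytest.mark.parametrize(
    "n_values,n_patients,expected",
    [
        (9574, 31493, 30.4),   # bilirubin worked example
        (0, 1000, 0.0),
        (2000, 1000, 200.0),   # several values per patient
        (15, 10000, 0.2),      # 0.15 rounds half-up to 0.2
        (125, 1000, 12.5),
        (1, 3, 33.3),
    ],
)
def test_compute_frequency(n_values, n_patients, expected):
    assert compute_frequency(n_values, n_patients) == expected


def test_compute_frequency_errors():
    with pytest.raises(ExportRowError):
        compute_frequency(10, 0)
    with pytest.raises(ExportRowError):
        compute_frequency(-1, 10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 100_000), st.integers(1, 50))
def test_frequency_scale_invariant(n, d, k):
    assert compute_frequency(k * n, k * d) == compute_frequency(n, d)


def test_classify_cell_variants():
    freq = classify_cell(SiteExport("s1", "e", 9574, 31493, AVAILABLE))
    assert freq.status == FREQUENCY and freq.frequency_pct == 30.4
    avail = classify_cell(SiteExport("s1", "e", None, None, AVAILABLE))
    assert avail.status == AVAILABLE and avail.frequency_pct is None
    na = classify_cell(SiteExport("s1", "e", None, None, NOT_AVAILABLE))
    assert na.status == NOT_AVAILABLE
    # bare unknown degrades to not_available
    unk = classify_cell(SiteExport("s1", "e", None, None))
    assert unk.status == NOT_AVAILABLE


def test_export_row_invariants():
    with pytest.raises(ExportRowError):
        SiteExport("s1", "e", 5, 100, NOT_AVAILABLE)
    with pytest.raises(ExportRowError):
        SiteExport("s1", "e", -1, 100, AVAILABLE)
    with pytest.raises(ExportRowError):
        SiteExport("s1", "e", 1, 1, "sometimes")


def test_coverage_cell_consistency():
    with pytest.raises(ValueError):
        CoverageCell("s1", "e", FREQUENCY, None)
    with pytest.raises(ValueError):
        CoverageCell("s1", "e", AVAILABLE, 10.0)
    assert CoverageCell("s1", "e", FREQUENCY, 30.4).render() == "30.4"
    assert CoverageCell("s1", "e", AVAILABLE).render() == "A"
    assert CoverageCell("s1", "e", NOT_AVAILABLE).render() == "N/A"


def _inventory(labels, domain="VS"):
    trials = [TrialMeta("T1", "oncology", 1000, 201)]
    assign_ = [FormDomainAssignment("F1", domain, "keyword")]
    clusters = [
        ElementCluster(
            cluster_id=f"C{k}", canonical_label=lab,
            variants={(lab, "T1", "F1")}, members=[("T1", "F1", f"I{k}")],
        )
        for k, lab in enumerate(labels, start=1)
    ]
    return rank_elements(clusters, assign_, trials)


def test_heatmap_orders_by_site_coverage():
    inv = _inventory(["Aaa", "Bbb"])
    ids = {r.element.canonical_label: r.element.cde_id for r in inv}
    cells = [
        CoverageCell(s, ids["Aaa"], AVAILABLE) for s in ("s1", "s2", "s3")
    ] + [CoverageCell("s1", ids["Bbb"], FREQUENCY, 99.0)]
    m = build_heatmap(cells, inv, sites=["s1", "s2", "s3"])
    assert m.rows == [ids["Aaa"], ids["Bbb"]]  # 3 sites beat 1
    assert len(m.cells) == 2 * 3  # complete grid after defaulting
    assert m.cells[(ids["Bbb"], "s2")].status == NOT_AVAILABLE


def test_heatmap_all_not_available_sorts_by_label():
    inv = _inventory(["Zulu", "Echo", "Mike"])
    m = build_heatmap([], inv, sites=["s1"])
    labels = {r.element.cde_id: r.element.canonical_label for r in inv}
    assert [labels[c] for c in m.rows] == ["Echo", "Mike", "Zulu"]


def test_heatmap_duplicate_cells_fatal():
    inv = _inventory(["Aaa"])
    cid = inv[0].element.cde_id
    cells = [CoverageCell("s1", cid, AVAILABLE),
             CoverageCell("s1", cid, NOT_AVAILABLE)]
    with pytest.raises(ExportRowError, match="duplicate"):
        build_heatmap(cells, inv)


def test_match_element_precedence_and_ambiguity():
    inv = _inventory(["Heart Rate", "Weight"])
    inv[0].element.umls_cui = "C0018810"
    cde = inv[0].element.cde_id
    assert match_element(cde, inv) == cde
    assert match_element("C0018810", inv) == cde
    assert match_element("heart rate", inv) == cde
    assert match_element("nonexistent", inv) is None
    inv[1].element.canonical_label = "Heart Rate"  # force ambiguity
    with pytest.raises(ExportRowError, match="several"):
        match_element("heart rate", inv)


def test_coverage_pipeline_matches_export_truth(small_corpus):
    """Every generated export cell reappears in the heat map with the
    brute-force recomputed status/frequency."""
    from cdeharvest import assign_domains, cluster_labels, generate_exports

    ss, _ = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    inv = rank_elements(clusters, assign_domains(ss), ss.trials)
    exports, truth = generate_exports(inv, 5, seed=3)
    full, sae, summary = coverage_pipeline(inv, exports)
    assert summary["n_cells"] == len(full.rows) * len(full.cols)
    key_to_cde = {}
    for r in inv:
        key_to_cde[r.element.umls_cui or r.element.cde_id] = r.element.cde_id
    for row in exports:
        cde = key_to_cde[row.element_key]
        cell = full.cells[(cde, row.site_id)]
        if row.availability == NOT_AVAILABLE:
            assert cell.status == NOT_AVAILABLE
        elif row.n_values is not None and row.n_patients:
            assert cell.status == FREQUENCY
            assert cell.frequency_pct == pytest.approx(
                round(100.0 * row.n_values / row.n_patients, 1), abs=0.05
            )
        else:
            assert cell.status == AVAILABLE
    # SAE submatrix only holds AE-domain elements
    if sae is not None:
        ae_ids = {r.element.cde_id for r in inv if r.element.domain_key == "AE"}
        assert set(sae.rows) <= ae_ids


def test_heatmap_row_order_invariant_under_export_order(small_corpus):
    from cdeharvest import assign_domains, cluster_labels, generate_exports

    ss, _ = small_corpus
    clusters = cluster_labels(ss.iter_items(), form_trial=ss.form_trial_map())
    inv = rank_elements(clusters, assign_domains(ss), ss.trials)
    exports, _ = generate_exports(inv, 4, seed=9)
    a, _, _ = coverage_pipeline(inv, exports)
    b, _, _ = coverage_pipeline(inv, list(reversed(exports)))
    assert a.rows == b.rows and a.cols == b.cols
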