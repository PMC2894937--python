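"""Hypergeometric overrepresentation and BH correction against exact oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdnet import (
    AnnotationMap,
    Category,
    RegulationCall,
    bh_adjust,
    enrich,
    generate_enrichment_instance,
    hypergeom_upper_tail,
)

from conftest import bh_stepup_oracle, hypergeom_tail_oracle


def test_upper_tail_trivial_cases():
    assert hypergeom_upper_tail(10, 5, 5, 0) == 1.0
    assert hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252, abs=1e-15)


def test_upper_tail_argument_validation():
    for bad in [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (10, 5, 2, 3), (-1, 0, 0, 0)]:
        with pytest.raises(ValueError):
            hypergeom_upper_tail(*bad)


def test_upper_tail_matches_enumeration_small():
    """Exact-integer tail sums agree to 1e-12 on a random slice of N<=30."""
    rng = np.random.default_rng(0)
    for _ in range(300):
        N = int(rng.integers(1, 31))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
            hypergeom_tail_oracle(N, K, n, k), abs=1e-12
        )


def test_bh_single_pvalue_identity():
    p_adj, sig = bh_adjust([0.04], alpha=0.05)
    assert p_adj[0] == pytest.approx(0.04)
    assert sig[0]


def test_bh_hand_example():
    p_adj, sig = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05], alpha=0.05)
    assert np.allclose(p_adj, [0.05, 0.05, 0.05, 0.05, 0.05])
    assert sig.all()


def test_bh_matches_independent_oracle():
    rng = np.random.default_rng(1)
    for _ in range(200):
        m = int(rng.integers(1, 60))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        p_adj, _ = bh_adjust(p)
        assert np.allclose(p_adj, bh_stepup_oracle(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
@settings(max_examples=100, derandomize=True)
def test_bh_monotone_in_raw_order(pvalues):
    """Adjusted p-values re-sorted by raw p are non-decreasing and bounded."""
    p = np.asarray(pvalues)
    p_adj, _ = bh_adjust(p)
    assert np.all(p_adj >= p - 1e-12)
    assert np.all(p_adj <= 1.0 + 1e-12)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(p_adj[order]) >= -1e-12)


def _toy_calls_and_ann():
    genes = [f"G{i}" for i in range(20)]
    de = frozenset(genes[:5])
    calls = RegulationCall(de, frozenset(), frozenset(genes[5:]))
    ann = AnnotationMap(
        [
            Category("HIT", "exactly the DE set", frozenset(genes[:5])),
            Category("PART", "partial overlap", frozenset(genes[3:10])),
            Category("MISS", "disjoint", frozenset(genes[10:15])),
        ]
    )
    return calls, ann


def test_enrich_maximal_overlap_has_smallest_p():
    calls, ann = _toy_calls_and_ann()
    res = enrich(calls, ann)
    assert res.iloc[0]["category"] == "HIT"
    assert res["p_raw"].min() == res.iloc[0]["p_raw"]


def test_enrich_drops_zero_overlap_but_counts_them_for_bh():
    calls, ann = _toy_calls_and_ann()
    res = enrich(calls, ann)
    assert "MISS" not in set(res["category"])
    # m = 3 tested categories, so the best adjusted p is raw * 3 (step-up upper bound)
    hit = res[res["category"] == "HIT"].iloc[0]
    assert hit["p_adj"] == pytest.approx(min(1.0, hit["p_raw"] * 3), rel=1e-9)


def test_enrich_empty_de_is_an_error():
    calls = RegulationCall(frozenset(), frozenset(), frozenset({"A", "B"}))
    ann = AnnotationMap([Category("C", "c", frozenset({"A"}))])
    with pytest.raises(ValueError):
        enrich(calls, ann)


def test_enrich_de_disjoint_from_all_categories_is_empty():
    genes = [f"G{i}" for i in range(10)]
    calls = RegulationCall(frozenset(genes[:2]), frozenset(), frozenset(genes[2:]))
    ann = AnnotationMap([Category("C", "c", frozenset(genes[5:]))])
    assert len(enrich(calls, ann)) == 0


def test_enrich_category_order_invariance():
    calls, ann = _toy_calls_and_ann()
    reversed_ann = AnnotationMap(list(ann.categories.values())[::-1])
    a = enrich(calls, ann).set_index("category").sort_index()
    b = enrich(calls, reversed_ann).set_index("category").sort_index()
    assert np.allclose(a["p_adj"], b["p_adj"])


def test_planted_category_detected():
    """A 10x-enriched planted category is flagged significant at alpha 0.05."""
    rng = np.random.default_rng(5)
    hits = 0
    reps = 25
    for _ in range(reps):
        calls, ann, planted = generate_enrichment_instance(rng, planted=True)
        res = enrich(calls, ann)
        row = res[res["category"] == planted]
        if len(row) and bool(row.iloc[0]["significant"]):
            hits += 1
    assert hits >= 24  # power ~1 at this effect size


def test_annotation_map_consistency(small_study):
    ann = small_study.annotation
    for gene, cats in ann.memberships.items():
        for cid in cats:
            assert gene in ann.categories[cid].members
    for cid, cat in ann.categories.items():
        for gene in cat.members:
            assert cid in ann.memberships[gene]
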