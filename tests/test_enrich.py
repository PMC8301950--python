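"""Hypergeometric enrichment, BH adjustment and network export."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sporomir import enrich as en


def _annotation(mapping, namespace="BP"):
    rows = [(g, t, namespace, t + "-name")
            for g, terms in mapping.items() for t in terms]
    return en.Annotation(pd.DataFrame(rows, columns=["gene", "term",
                                                     "namespace", "name"]))


def exact_upper_tail(N, K, n, k):
    """Oracle: P(X >= k) by full enumeration of n-subsets of N genes."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for g in draw if g < K) >= k:
            hits += 1
    return hits / total


def test_certain_event_has_p_one():
    ann = _annotation({"g1": ["T"]})
    rec = en.hypergeom_enrich({"g1"}, ann)
    assert rec.loc[0, "p_value"] == 1.0


def test_textbook_case_matches_enumeration():
    genes = [f"g{i}" for i in range(10)]
    ann = _annotation({g: (["T"] if i < 4 else ["U"])
                       for i, g in enumerate(genes)})
    selected = set(genes[:4]) | {genes[9]}               # k=4 of K=4, n=5
    rec = en.hypergeom_enrich(selected, ann).set_index("term")
    expect = exact_upper_tail(10, 4, 5, 4)               # 6/252
    assert rec.loc["T", "p_value"] == pytest.approx(expect, abs=1e-12)
    assert expect == pytest.approx(6 / 252)


def test_exactness_for_all_small_configurations():
    """p agrees with full enumeration for every N <= 8 configuration
    (the exhaustive N <= 12 sweep runs in the acceptance suite)."""
    for N in range(2, 9):
        genes = [f"g{i}" for i in range(N)]
        for K in range(1, N + 1):
            ann = _annotation({g: (["T"] if i < K else ["Z"])
                               for i, g in enumerate(genes)})
            for n in range(1, N + 1):
                selected = set(genes[N - n:])
                k = len(selected & set(genes[:K]))
                if k < 1:
                    continue
                rec = en.hypergeom_enrich(selected, ann).set_index("term")
                assert rec.loc["T", "p_value"] == pytest.approx(
                    exact_upper_tail(N, K, n, k), abs=1e-10), (N, K, n, k)


def bh_stepup(pvals):
    """Independent BH oracle."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def test_bh_adjustment_matches_independent_stepup():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(30)]
    mapping = {g: [f"T{j}" for j in rng.choice(8, 3, replace=False)]
               for g in genes}
    ann = _annotation(mapping)
    rec = en.hypergeom_enrich(set(genes[:10]), ann)
    expect = bh_stepup(rec.p_value.values)
    assert np.allclose(rec.p_adjust.values, expect, atol=1e-12)
    assert (rec.p_adjust.values >= rec.p_value.values - 1e-12).all()


def test_bh_is_applied_within_each_namespace():
    rows = ([("g1", "A", "BP", "a"), ("g2", "A", "BP", "a"),
             ("g1", "B", "MF", "b")])
    ann = en.Annotation(pd.DataFrame(rows, columns=["gene", "term",
                                                    "namespace", "name"]))
    rec = en.hypergeom_enrich({"g1"}, ann).set_index("term")
    # each namespace holds a single term, so p_adjust == p_value
    assert rec.loc["A", "p_adjust"] == rec.loc["A", "p_value"]
    assert rec.loc["B", "p_adjust"] == rec.loc["B", "p_value"]


def test_selected_outside_background_is_an_error():
    ann = _annotation({"g1": ["T"]})
    with pytest.raises(ValueError, match="stranger"):
        en.hypergeom_enrich({"g1", "stranger"}, ann)


def test_networks_match_brute_force_intersections():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(20)]
    mapping = {g: [f"T{j}" for j in rng.choice(5, 2, replace=False)]
               for g in genes}
    ann = _annotation(mapping)
    selected = set(genes[:12])
    rec = en.hypergeom_enrich(selected, ann)
    targets = pd.DataFrame({"mirna_id": ["mirA"] * 6 + ["mirB"] * 6,
                            "gene_id": genes[:12]})
    tt, mt = en.build_networks(rec, targets, {"mirA": "up"})
    members = {r.term: set(r.members.split(";")) for r in rec.itertuples()}
    for r in tt.itertuples():
        assert r.weight == len(members[r.term1] & members[r.term2]) > 0
    seen = {(r.term1, r.term2) for r in tt.itertuples()}
    for t1, t2 in itertools.combinations(members, 2):
        inter = members[t1] & members[t2]
        if inter:
            assert (t1, t2) in seen or (t2, t1) in seen
    for r in mt.itertuples():
        by_mirna = set(targets.loc[targets.mirna_id == r.mirna_id,
                                   "gene_id"])
        assert r.n_genes == len(by_mirna & members[r.term]) > 0
    assert (mt.loc[mt.mirna_id == "mirA", "direction"] == "up").all()


def test_disjoint_terms_share_no_edge():
    ann = _annotation({"g1": ["A"], "g2": ["B"]})
    rec = en.hypergeom_enrich({"g1", "g2"}, ann)
    tt, _ = en.build_networks(rec, pd.DataFrame(columns=["mirna_id",
                                                         "gene_id"]))
    assert len(tt) == 0
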