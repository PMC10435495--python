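"""Unit and property tests for gene-set concordance and resampling enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from l1regkit import setstats as ss

from conftest import gene_set, make_de_table


# --------------------------------------------------------------------------- #
# jaccard

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, 0.5),
        ({"g1"}, {"g1"}, 1.0),
        ({"g1"}, set(), 0.0),
        (set(), set(), 0.0),
    ],
)
def test_jaccard_basic(a, b, expected):
    assert ss.jaccard(a, b) == expected


@settings(max_examples=50, derandomize=True)
@given(
    a=st.frozensets(st.integers(0, 30), max_size=20),
    b=st.frozensets(st.integers(0, 30), max_size=20),
)
def test_jaccard_symmetric_bounded(a, b):
    j = ss.jaccard(a, b)
    assert j == ss.jaccard(b, a)
    assert 0.0 <= j <= 1.0
    assert (j == 1.0) == (a == b and len(a) > 0)


# --------------------------------------------------------------------------- #
# Fisher overlap

def enumerate_overlap_tail(n_universe: int, n_a: int, n_b: int, k: int) -> float:
    """Exhaustive P[|A cap B| >= k] for a uniform random size-n_a subset A."""
    items = range(n_universe)
    b = set(range(n_b))
    total = hits = 0
    for a in itertools.combinations(items, n_a):
        total += 1
        if len(b.intersection(a)) >= k:
            hits += 1
    return hits / total


def test_fisher_complete_overlap_matches_enumeration():
    u = ss.GeneUniverse(f"g{i}" for i in range(10))
    a = gene_set(*[f"g{i}" for i in range(5)], label="a")
    res = ss.fisher_overlap(a, a, u)
    expected = 1 / math.comb(10, 5)
    assert res.fisher_p == pytest.approx(expected, rel=1e-9)
    assert res.fisher_p == pytest.approx(enumerate_overlap_tail(10, 5, 5, 5), rel=1e-9)
    assert res.intersection == 5


def test_fisher_overlap_at_expectation_is_not_significant():
    u = ss.GeneUniverse(f"g{i}" for i in range(1000))
    genes = list(u.genes)
    a = gene_set(*genes[:100], label="a")
    # overlap 10 = |A||B|/|U| exactly
    b = gene_set(*(genes[:10] + genes[100:190]), label="b")
    res = ss.fisher_overlap(a, b, u)
    assert res.intersection == 10
    assert res.fisher_p > 0.05


def test_fisher_disjoint_sets_not_enriched():
    u = ss.GeneUniverse(f"g{i}" for i in range(30))
    genes = list(u.genes)
    res = ss.fisher_overlap(gene_set(*genes[:5]), gene_set(*genes[5:10]), u)
    assert res.fisher_p >= 0.5
    assert res.intersection == 0


def test_fisher_rejects_genes_outside_universe(small_universe):
    with pytest.raises(ValueError, match="outside the universe"):
        ss.fisher_overlap(gene_set("nope"), gene_set("g1"), small_universe)


# --------------------------------------------------------------------------- #
# resampling enrichment

def test_resample_maximal_overlap_is_extreme():
    u = ss.GeneUniverse(f"g{i}" for i in range(5000))
    q = gene_set(*list(u.genes)[:50], label="q")
    r = ss.resample_enrichment(q, q, u, B=1000, seed=1)
    assert r.k_obs == 50
    assert r.p < 1e-6
    assert r.z > 5


def test_resample_degenerate_null_falls_back_to_hypergeometric(small_universe):
    q = gene_set(*small_universe.genes, label="all")
    t = gene_set(*list(small_universe.genes)[:5], label="t")
    r = ss.resample_enrichment(q, t, small_universe, B=100, seed=0)
    assert r.exact_fallback
    assert r.null_sd == 0.0
    assert r.p == pytest.approx(1.0)  # overlap is certain
    assert math.isnan(r.z)


@pytest.mark.parametrize("n_u, n_q, n_t", [(20, 8, 6), (15, 5, 9), (18, 9, 9)])
def test_resample_normal_p_close_to_exact_hypergeometric(n_u, n_q, n_t):
    """On tiny universes the normal approximation of the resampled null stays
    close to the exact hypergeometric tail (for non-extreme p).

    The z-score carries no continuity correction (it standardises the
    observed count directly against the resampled null), so the matching
    exact quantity on a discrete support is the mid-p tail
    P[X > k] + P[X = k]/2; against it the approximation holds within 0.05.
    """
    u = ss.GeneUniverse(f"g{i}" for i in range(n_u))
    genes = list(u.genes)
    rng = np.random.default_rng(42)
    for rep in range(5):
        q = gene_set(*rng.choice(genes, n_q, replace=False), label="q")
        t = gene_set(*rng.choice(genes, n_t, replace=False), label="t")
        r = ss.resample_enrichment(q, t, u, B=4000, seed=rng)
        p_exact = stats.hypergeom.sf(r.k_obs - 1, n_u, n_t, n_q)
        if 0.001 <= p_exact <= 0.999 and not r.exact_fallback:
            mid_p = p_exact - 0.5 * stats.hypergeom.pmf(r.k_obs, n_u, n_t, n_q)
            assert abs(r.p - mid_p) < 0.05
            # against the plain tail the gap is bounded by half the point mass
            half_mass = 0.5 * stats.hypergeom.pmf(r.k_obs, n_u, n_t, n_q)
            assert abs(r.p - p_exact) < 0.05 + half_mass


def test_resample_null_moments_match_hypergeometric():
    u = ss.GeneUniverse(f"g{i}" for i in range(500))
    genes = list(u.genes)
    q = gene_set(*genes[:50], label="q")
    t = gene_set(*genes[100:200], label="t")
    r = ss.resample_enrichment(q, t, u, B=20000, seed=9)
    mean, var = stats.hypergeom.stats(500, 100, 50, moments="mv")
    assert r.null_mean == pytest.approx(float(mean), rel=0.03)
    assert r.null_sd == pytest.approx(float(np.sqrt(var)), rel=0.05)


def test_resample_input_validation(small_universe):
    q = gene_set("g1", "g2")
    with pytest.raises(ValueError, match="non-empty"):
        ss.resample_enrichment(gene_set(), q, small_universe)
    with pytest.raises(ValueError, match="B must be"):
        ss.resample_enrichment(q, q, small_universe, B=1)


def test_resample_many_applies_bh_over_the_call():
    u = ss.GeneUniverse(f"g{i}" for i in range(2000))
    genes = list(u.genes)
    q = gene_set(*genes[:100], label="q")
    targets = [
        gene_set(*genes[:100], label="hit"),       # complete overlap
        gene_set(*genes[1000:1200], label="null"),  # disjoint
    ]
    results = ss.resample_enrichment_many(q, targets, u, B=500, seed=5)
    assert [r.label for r in results] == ["hit", "null"]
    assert all(r.q is not None for r in results)
    expected_q = ss.bh_adjust([r.p for r in results])
    assert [r.q for r in results] == pytest.approx(list(expected_q))


def test_resample_deterministic_for_fixed_seed():
    u = ss.GeneUniverse(f"g{i}" for i in range(300))
    genes = list(u.genes)
    q = gene_set(*genes[:30], label="q")
    t = gene_set(*genes[20:80], label="t")
    r1 = ss.resample_enrichment(q, t, u, B=500, seed=11)
    r2 = ss.resample_enrichment(q, t, u, B=500, seed=11)
    assert r1 == r2


# --------------------------------------------------------------------------- #
# BH adjustment

def test_bh_stepup_worked_example():
    assert list(ss.bh_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])


@pytest.mark.parametrize("pvals", [[0.2], [1.0, 1.0, 1.0]])
def test_bh_identity_cases(pvals):
    assert list(ss.bh_adjust(pvals)) == pytest.approx(pvals)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        ss.bh_adjust([0.5, 1.5])


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
def test_bh_permutation_equivariant_and_bounded(pvals):
    q = ss.bh_adjust(pvals)
    assert np.all(q >= np.asarray(pvals) - 1e-12)
    assert np.all(q <= 1.0)
    perm = np.random.default_rng(0).permutation(len(pvals))
    q_perm = ss.bh_adjust([pvals[i] for i in perm])
    assert q_perm == pytest.approx(q[perm])


# --------------------------------------------------------------------------- #
# DE-table set operations

def test_consistent_degs_intersects_all_tables():
    tables = [
        make_de_table(up=("g1", "g2"), label="a"),
        make_de_table(up=("g2", "g3"), label="b"),
        make_de_table(up=("g2", "g4"), label="c"),
        make_de_table(up=("g2",), label="d"),
    ]
    assert ss.consistent_degs(tables, "up").members == {"g2"}


def test_consistent_degs_disjoint_gives_empty():
    tables = [make_de_table(up=("g1",)), make_de_table(up=("g2",))]
    assert len(ss.consistent_degs(tables, "up")) == 0


def test_consistent_degs_needs_two_tables():
    with pytest.raises(ValueError):
        ss.consistent_degs([], "up")
    with pytest.raises(ValueError):
        ss.consistent_degs([make_de_table(up=("g1",))], "up")


def test_directional_concordance_partitions_by_sign():
    x = make_de_table(up=("g1", "g2"), down=("g3",), null=("g4",), label="x")
    y = make_de_table(up=("g2", "g3"), down=("g1",), null=("g4",), label="y")
    d = ss.directional_concordance(x, y)
    assert d.up_up.members == {"g2"}
    assert d.up_down.members == {"g1"}
    assert d.down_up.members == {"g3"}
    assert len(d.down_down) == 0


def test_directional_concordance_identical_tables_has_no_opposites():
    x = make_de_table(up=("g1", "g2"), down=("g3",), label="x")
    d = ss.directional_concordance(x, x)
    assert len(d.up_down) == 0 and len(d.down_up) == 0
    assert d.up_up.members == {"g1", "g2"}


def test_de_table_validation():
    with pytest.raises(ValueError, match="missing column"):
        ss.DETable(pd.DataFrame({"gene": ["g1"], "log2fc": [1.0]}))
    with pytest.raises(ValueError, match="duplicated"):
        ss.DETable(
            pd.DataFrame({"gene": ["g1", "g1"], "log2fc": [1, 2], "fdr": [0.1, 0.2]})
        )
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        ss.DETable(pd.DataFrame({"gene": ["g1"], "log2fc": [1.0], "fdr": [1.5]}))


def test_gene_set_strips_whitespace_and_warns_on_duplicates():
    with pytest.warns(UserWarning, match="duplicate"):
        gs = ss.GeneSet.from_iterable("s", [" g1 ", "g1", "g2"])
    assert gs.members == {"g1", "g2"}
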