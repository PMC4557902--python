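import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from diego.comparison import (
    adjust_pvalues,
    compare_profiles,
    jaccard,
    overlap_method,
    write_comparison,
    z_comparative,
)
from diego.enrichment import ContingencyTable, enrich, z_single
from diego.ontology import AnnotationSet
from diego.simulate import SimConfig, simulate


def null_profiles(seed, n_terms=100):
    out = simulate(SimConfig(seed=seed, n_terms=n_terms), n_experiments=2)
    p1 = enrich(out.gene_lists["expt1"], out.annotations, label="expt1")
    p2 = enrich(out.gene_lists["expt2"], out.annotations, label="expt2")
    return p1, p2


class TestZComparative:
    def test_identical_tables_zero(self):
        s = z_single(ContingencyTable(20, 80, 10, 190))
        zk, _ = z_comparative(s, s)
        assert zk == 0.0

    def test_hand_arithmetic(self):
        si = z_single(ContingencyTable(20, 80, 10, 190))
        sj = z_single(ContingencyTable(10, 90, 10, 190))
        zk, se_ij = z_comparative(si, sj)
        assert se_ij == pytest.approx(0.6198, abs=1e-4)
        assert zk == pytest.approx(1.308, abs=1e-3)

    def test_antisymmetric(self):
        si = z_single(ContingencyTable(20, 80, 10, 190))
        sj = z_single(ContingencyTable(10, 90, 10, 190))
        assert z_comparative(si, sj)[0] == -z_comparative(sj, si)[0]

    def test_undefined_score_rejected(self):
        si = z_single(ContingencyTable(0, 100, 10, 190), zero_correction="skip")
        sj = z_single(ContingencyTable(10, 90, 10, 190))
        with pytest.raises(ValueError, match="defined"):
            z_comparative(si, sj)


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, 0.5),
        ({"g1"}, {"g1"}, 1.0),
        ({"g1"}, {"g2"}, 0.0),
        (set(), set(), 0.0),
    ])
    def test_values(self, a, b, expected):
        assert jaccard(a, b) == expected

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_bounded_and_symmetric(self, a, b):
        j = jaccard(map(str, a), map(str, b))
        assert 0 <= j <= 1
        assert j == jaccard(map(str, b), map(str, a))


class TestAdjustPvalues:
    def test_bh_step_up(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bh") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.2], "bh") == [0.2]

    def test_none_is_identity(self):
        ps = [0.5, 0.001, 1.0]
        assert adjust_pvalues(ps, "none") == ps

    def test_adjusted_at_least_raw(self):
        ps = [0.04, 0.2, 0.001, 0.9]
        for method in ("bh", "bonferroni"):
            adj = adjust_pvalues(ps, method)
            assert all(a >= p for a, p in zip(adj, ps))
            assert max(adj) <= 1.0

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [math.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_pvalues(bad, "bh")

    @pytest.mark.parametrize("seed", range(5))
    def test_bh_matches_textbook_stepup(self, seed):
        """BH equals an independently coded sort-based step-up oracle."""
        rng = np.random.default_rng(seed)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            ps = rng.uniform(1e-6, 1.0, size=n)
            order = np.argsort(ps)
            ranked = ps[order]
            stepped = ranked * n / np.arange(1, n + 1)
            for i in range(n - 2, -1, -1):
                stepped[i] = min(stepped[i], stepped[i + 1])
            expected = np.empty(n)
            expected[order] = np.minimum(stepped, 1.0)
            assert adjust_pvalues(list(ps), "bh") == pytest.approx(
                list(expected), rel=1e-12
            )


class TestCompareProfiles:
    def test_self_comparison_is_null(self):
        p1, _ = null_profiles(seed=5)
        res = compare_profiles(p1, p1)
        assert all(r.z_k == 0 for r in res.records)
        assert all(r.p == 1.0 for r in res.records)
        assert all(r.jc == 1.0 for r in res.records if r.genes_i)
        assert res.n_diegos == 0

    def test_antisymmetry(self):
        p1, p2 = null_profiles(seed=6)
        fwd = compare_profiles(p1, p2)
        rev = compare_profiles(p2, p1)
        f = {r.term: r for r in fwd.records}
        r_ = {r.term: r for r in rev.records}
        assert f.keys() == r_.keys()
        for t in f:
            assert f[t].z_k == pytest.approx(-r_[t].z_k, rel=1e-12)
            assert f[t].p == r_[t].p
            assert f[t].jc == r_[t].jc

    def test_sorted_by_abs_zk(self):
        p1, p2 = null_profiles(seed=7)
        res = compare_profiles(p1, p2)
        mags = [abs(r.z_k) for r in res.records]
        assert mags == sorted(mags, reverse=True)

    def test_no_shared_terms_errors(self):
        universe = [f"g{i}" for i in range(40)]
        a1 = AnnotationSet({}, {"TA": set(universe[:10])}, set(universe))
        a2 = AnnotationSet({}, {"TB": set(universe[5:15])}, set(universe))
        p1 = enrich(universe[:20], a1, label="a")
        p2 = enrich(universe[:20], a2, label="b")
        with pytest.raises(ValueError, match="no scoreable terms"):
            compare_profiles(p1, p2)

    def test_tsv_dump_has_all_records(self, tmp_path):
        import io as _io

        p1, p2 = null_profiles(seed=8)
        res = compare_profiles(p1, p2)
        buf = _io.StringIO()
        write_comparison(res, buf)
        lines = [l for l in buf.getvalue().splitlines()
                 if l and not l.startswith("#")]
        assert len(lines) == len(res.records) + 1  # header + rows


def depletion_fixture():
    """Term flat in experiment i, depleted in j, on a 400-gene universe."""
    universe = [f"u{i:04d}" for i in range(400)]
    term_genes = set(universe[:100])
    annot = AnnotationSet({}, {"T:0000001": term_genes}, set(universe))
    query_i = universe[:25] + universe[100:175]      # 25/100 hits, rate 0.25
    query_j = universe[:5] + universe[175:270]       # 5/100 hits, depleted
    pi = enrich(query_i, annot, label="i", min_count=1)
    pj = enrich(query_j, annot, label="j", min_count=1)
    return pi, pj


class TestOverlapMethod:
    def test_identical_profiles_no_specific_terms(self):
        p1, _ = null_profiles(seed=9)
        membership = overlap_method(p1, p1)
        assert all(m in ("both", "neither") for m in membership.values())

    def test_hard_threshold_artifact(self):
        """A term straddling alpha lands in i-only despite near-equal evidence."""
        universe = [f"g{i}" for i in range(300)]
        term_genes = set(universe[:60])
        annot = AnnotationSet({}, {"T:0000001": term_genes}, set(universe))
        # 26 vs 25 term hits out of 100: Fisher p = 0.048 vs 0.085
        qi = universe[:26] + universe[60:134]
        qj = universe[:25] + universe[60:135]
        pi = enrich(qi, annot, label="i", min_count=1)
        pj = enrich(qj, annot, label="j", min_count=1)
        memb = overlap_method(pi, pj, alpha=0.05, adjust="none")
        assert memb["T:0000001"] == "i-only"
        # the direct comparison sees no difference
        res = compare_profiles(pi, pj, adjust="none")
        assert res.records[0].p > 0.5

    def test_underrepresentation_seen_only_by_comparative_z(self):
        pi, pj = depletion_fixture()
        memb = overlap_method(pi, pj, alpha=0.05, adjust="none")
        assert memb["T:0000001"] == "neither"  # one-sided tests both quiet
        res = compare_profiles(pi, pj, adjust="none")
        rec = res.records[0]
        assert rec.term == "T:0000001"
        assert rec.z_k > 0 and rec.p < 0.05
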