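import numpy as np
import pandas as pd
import pytest

from micronetfun.containers import SupportEntry, SupportMap
from micronetfun.diversity import (
    combination_coverage,
    functional_complexity,
    functional_link_count,
    functional_uniqueness,
    jaccard_dissimilarity,
    redundancy,
    sample_uniqueness,
)
from micronetfun.subnetworks import SubNetwork, link_count
from .oracles import coverage_bruteforce, rao_q_bruteforce


def make_support(sets, otu_universe=None):
    """SupportMap from {function: {otu: +1/-1}} shorthand."""
    entries = {}
    for f, members in sets.items():
        ids = pd.Index(sorted(members))
        coefs = pd.Series([float(members[o]) for o in ids], index=ids, name=f)
        entries[f] = SupportEntry(function=f, coefficients=coefs,
                                  alpha=1.0, lam=0.1, cv_mse=0.0)
    return SupportMap(entries)


class TestRedundancy:
    def test_two_function_example(self):
        sm = make_support({"f1": {"a": 1, "b": 1, "c": 1}, "f2": {"c": 1}})
        presence = pd.Series(True, index=["a", "b", "c"])
        assert redundancy(presence, sm) == pytest.approx(2.0)

    def test_no_supporters_present(self):
        sm = make_support({"f1": {"a": 1}})
        presence = pd.Series(False, index=["a", "b"])
        assert redundancy(presence, sm) == 0.0

    def test_matches_bruteforce_counts(self, rng):
        otus = [f"o{i}" for i in range(20)]
        sets = {
            f"f{k}": {o: 1 for o in rng.choice(otus, size=5, replace=False)}
            for k in range(6)
        }
        sm = make_support(sets)
        presence = pd.Series(rng.random(20) < 0.6, index=otus)
        present = {o for o in otus if presence[o]}
        expect = np.mean([len(set(s) & present) for s in sets.values()])
        assert redundancy(presence, sm) == pytest.approx(expect)

    def test_empty_support_map_rejected(self):
        with pytest.raises(ValueError):
            redundancy(pd.Series(True, index=["a"]), SupportMap({}))


class TestUniqueness:
    def test_single_taxon_zero(self):
        assert functional_uniqueness(np.array([1.0]), np.zeros((1, 1))) == 0.0

    def test_two_disjoint_taxa(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        u = functional_uniqueness(np.array([0.5, 0.5]), d)
        assert u == pytest.approx(1.0)  # Q = 0.5, inverse Simpson = 2

    @pytest.mark.parametrize("m", [2, 3, 5, 8])
    def test_equidistant_closed_form(self, m):
        # m equally abundant, maximally distinct taxa: uniqueness = m - 1
        d = 1.0 - np.eye(m)
        u = functional_uniqueness(np.full(m, 1.0 / m), d)
        assert u == pytest.approx(m - 1, abs=1e-10)

    def test_matches_bruteforce_double_sum(self, rng):
        p = rng.random(5)
        p /= p.sum()
        d = rng.random((5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        q = rao_q_bruteforce(p, d)
        simpson = (p**2).sum()
        assert functional_uniqueness(p, d) == pytest.approx(q / simpson)

    def test_relabeling_invariance(self, rng):
        p = rng.random(6)
        p /= p.sum()
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        perm = rng.permutation(6)
        assert functional_uniqueness(p[perm], d[np.ix_(perm, perm)]) == \
            pytest.approx(functional_uniqueness(p, d))

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            functional_uniqueness(np.array([]), np.zeros((0, 0)))

    def test_jaccard_profiles(self):
        prof = pd.DataFrame(
            [[1, 0], [0, 1], [1, 1]], index=["a", "b", "c"],
            columns=["f1", "f2"])
        d = jaccard_dissimilarity(prof)
        assert d.loc["a", "b"] == 1.0
        assert d.loc["a", "c"] == pytest.approx(0.5)
        assert (np.diag(d) == 0).all()

    def test_sample_uniqueness_table(self, rng):
        sm = make_support({"f1": {"a": 1, "b": 1}, "f2": {"b": 1, "c": 1}})
        ab = pd.DataFrame(rng.random((4, 4)),
                          index=list("wxyz"), columns=["a", "b", "c", "d"])
        u = sample_uniqueness(ab, sm)
        assert (u >= 0).all()


class TestCoverage:
    SETS = {"f1": {1: 1, 2: 1}, "f2": {2: 1, 3: 1}}

    def test_single_function_mean(self):
        mean, vals = combination_coverage(make_support(self.SETS), 4, 1)
        assert mean == pytest.approx(0.5)

    def test_both_functions_union(self):
        mean, _ = combination_coverage(make_support(self.SETS), 4, 2)
        assert mean == pytest.approx(0.75)

    def test_monotone_in_k_exhaustive(self, rng):
        otus = list(range(12))
        sets = {
            f"f{k}": {o: 1 for o in rng.choice(otus, size=4, replace=False)}
            for k in range(6)
        }
        sm = make_support(sets)
        means = [combination_coverage(sm, 12, k)[0] for k in range(1, 7)]
        assert (np.diff(means) >= -1e-12).all()

    def test_matches_bruteforce_enumeration(self, rng):
        otus = list(range(10))
        sets = {
            f"f{k}": {o: 1 for o in rng.choice(otus, size=3, replace=False)}
            for k in range(5)
        }
        sm = make_support(sets)
        for k in (1, 2, 3):
            mean, _ = combination_coverage(sm, 10, k)
            expect, _ = coverage_bruteforce(
                {f: set(s) for f, s in sets.items()}, 10, k)
            assert mean == pytest.approx(expect)

    def test_full_combination_equals_total_union(self):
        sm = make_support(self.SETS)
        mean, _ = combination_coverage(sm, 4, 2)
        union = set(self.SETS["f1"]) | set(self.SETS["f2"])
        assert mean == pytest.approx(len(union) / 4)

    def test_exclusion_list(self):
        sm = make_support(self.SETS)
        mean, _ = combination_coverage(sm, 4, 1, exclude=["f1"])
        assert mean == pytest.approx(0.5)  # only f2 remains

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            combination_coverage(make_support(self.SETS), 4, 3)


def make_sub(adj, ids):
    from micronetfun.containers import kingdom_from_ids

    adj = np.asarray(adj, dtype=bool)
    ids = pd.Index(ids)
    return SubNetwork(otu_ids=ids, adjacency=adj,
                      kingdom=kingdom_from_ids(ids))


class TestFunctionalComplexity:
    def test_shared_function_link_counted(self):
        sub = make_sub([[0, 1], [1, 0]], ["b_1", "b_2"])
        sm = make_support({"f1": {"b_1": 1, "b_2": 1}})
        assert functional_complexity(sub, sm, "all", "strict") == \
            pytest.approx(0.5)

    def test_disjoint_functions_strict_vs_relaxed(self):
        sub = make_sub([[0, 1], [1, 0]], ["b_1", "b_2"])
        sm = make_support({"f1": {"b_1": 1}, "f2": {"b_2": 1}})
        assert functional_complexity(sub, sm, "all", "strict") == 0.0
        assert functional_complexity(sub, sm, "all", "relaxed") == \
            pytest.approx(0.5)

    def test_no_supporters_warns_zero(self):
        sub = make_sub([[0, 1], [1, 0]], ["b_1", "b_2"])
        sm = make_support({"f1": {"b_9": 1}})
        with pytest.warns(UserWarning):
            assert functional_complexity(sub, sm) == 0.0

    def test_matches_bruteforce_shared_function_check(self, rng):
        p = 15
        ids = [f"b_{i}" for i in range(9)] + [f"f_{i}" for i in range(6)]
        adj = rng.random((p, p)) < 0.3
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        sub = make_sub(adj, ids)
        sets = {
            f"fn{k}": {ids[i]: 1
                       for i in rng.choice(p, size=4, replace=False)}
            for k in range(4)
        }
        sm = make_support(sets)
        profiles = {o: {f for f, s in sets.items() if o in s} for o in ids}
        expect = 0
        for i in range(p):
            for j in range(i + 1, p):
                if adj[i, j] and profiles[ids[i]] & profiles[ids[j]]:
                    expect += 1
        assert functional_link_count(sub, sm, "all", "strict") == expect

    def test_strict_le_relaxed_le_overall_link_counts(self, rng):
        p = 20
        ids = [f"b_{i}" for i in range(12)] + [f"f_{i}" for i in range(8)]
        adj = rng.random((p, p)) < 0.25
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        sub = make_sub(adj, ids)
        sets = {
            f"fn{k}": {ids[i]: 1
                       for i in rng.choice(p, size=5, replace=False)}
            for k in range(3)
        }
        sm = make_support(sets)
        strict = functional_link_count(sub, sm, "all", "strict")
        relaxed = functional_link_count(sub, sm, "all", "relaxed")
        overall = link_count(sub, "all")
        assert strict <= relaxed <= overall
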