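"""DEC state space, rate matrix, likelihood, fitting, reconstruction."""

import math

import numpy as np
import pytest

from rangearc.dec_model import (
    AreaCoding,
    DecModel,
    ancestral_splits,
    build_state_space,
    cladogenesis_events,
    fit_dec,
    read_coding_tsv,
    state_label,
    tree_likelihood,
    tree_likelihood_bruteforce,
    write_coding_tsv,
)
from rangearc.phylo_io import parse_tree


class TestStateSpace:
    @pytest.mark.parametrize("areas, n", [(["A"], 1), (["A", "B"], 3),
                                          (["W", "C", "H", "E"], 15)])
    def test_counts(self, areas, n):
        states, index = build_state_space(areas)
        assert len(states) == n == len(index)

    def test_canonical_order_size_then_lex(self):
        states, _ = build_state_space(["A", "B", "C"])
        labels = [state_label(s, ["A", "B", "C"]) for s in states]
        assert labels == ["A", "B", "C", "AB", "AC", "BC", "ABC"]

    def test_duplicate_areas_rejected(self):
        with pytest.raises(ValueError):
            build_state_space(["A", "A"])


class TestRateMatrix:
    def test_two_area_entries_and_row_sums(self):
        m = DecModel(["A", "B"], d=0.1, e=0.05)
        s, idx = m.states, m.index
        A, B, AB = frozenset("A"), frozenset("B"), frozenset("AB")
        assert m.Q[idx[A], idx[AB]] == pytest.approx(0.1)
        assert m.Q[idx[AB], idx[A]] == pytest.approx(0.05)
        assert m.Q[idx[AB], idx[B]] == pytest.approx(0.05)
        # no extinction exit from single-area ranges
        assert m.Q[idx[A], idx[A]] == pytest.approx(-0.1)
        assert np.allclose(m.Q.sum(axis=1), 0.0)

    def test_dispersal_scales_with_occupied_sources(self):
        m = DecModel(["A", "B", "C"], d=0.1, e=0.0)
        AB, ABC = frozenset("AB"), frozenset("ABC")
        assert m.Q[m.index[AB], m.index[ABC]] == pytest.approx(0.2)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            DecModel(["A", "B"], d=-0.1, e=0.0)


class TestCladogenesis:
    def test_single_area_identity(self):
        ev = cladogenesis_events(frozenset("A"))
        assert ev == [(frozenset("A"), frozenset("A"), 1.0)]

    def test_two_area_six_events_uniform(self):
        ev = cladogenesis_events(frozenset("AB"))
        assert len(ev) == 6
        assert all(w == pytest.approx(1 / 6) for *_, w in ev)
        pairs = {(state_label(l, ["A", "B"]), state_label(r, ["A", "B"]))
                 for l, r, _ in ev}
        assert pairs == {("A", "B"), ("B", "A"), ("A", "AB"), ("AB", "A"),
                         ("B", "AB"), ("AB", "B")}

    def test_three_area_twelve_events(self):
        ev = cladogenesis_events(frozenset("ABC"))
        assert len(ev) == 12
        # every event is a legal DEC scenario: one daughter single-area,
        # the other the complement or the full range
        for l, r, w in ev:
            small, other = (l, r) if len(l) <= len(r) else (r, l)
            assert len(small) == 1
            assert other in (frozenset("ABC") - small, frozenset("ABC"))

    def test_empty_state_rejected(self):
        with pytest.raises(ValueError):
            cladogenesis_events(frozenset())


class TestLikelihood:
    def test_identity_transitions_root_fixed(self):
        t = parse_tree("(a:1,b:1);")
        cod = AreaCoding(["A", "B"], {"a": (1, 0), "b": (1, 0)})
        prior = np.array([1.0, 0.0, 0.0])  # root fixed at {A}
        m = DecModel(["A", "B"], d=0.0, e=0.0, root_prior=prior)
        assert tree_likelihood(t, cod, m) == pytest.approx(0.0)

    def test_impossible_tip_state_lowers_likelihood(self):
        t = parse_tree("(a:1,b:1);")
        m = DecModel(["A", "B"], d=0.01, e=0.005)
        ll_same = tree_likelihood(t, AreaCoding(["A", "B"], {"a": (1, 0), "b": (1, 0)}), m)
        ll_diff = tree_likelihood(t, AreaCoding(["A", "B"], {"a": (1, 0), "b": (0, 1)}), m)
        assert ll_diff < ll_same

    def test_pruning_matches_enumeration(self):
        t = parse_tree("((a:1,b:1):1,c:2);")
        cod = AreaCoding(["A", "B"], {"a": (1, 0), "b": (0, 1), "c": (1, 1)})
        m = DecModel(["A", "B"], d=0.1, e=0.05)
        ll = tree_likelihood(t, cod, m)
        oracle = tree_likelihood_bruteforce(t, cod, m)
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_invariant_to_child_rotation(self):
        t1 = parse_tree("((a:1,b:1):1,c:2);")
        t2 = parse_tree("(c:2,(b:1,a:1):1);")
        cod = AreaCoding(["A", "B"], {"a": (1, 0), "b": (0, 1), "c": (1, 1)})
        m = DecModel(["A", "B"], d=0.07, e=0.03)
        assert tree_likelihood(t1, cod, m) == pytest.approx(
            tree_likelihood(t2, cod, m), rel=1e-12
        )

    def test_uncoded_tip_rejected(self):
        t = parse_tree("(a:1,b:1);")
        with pytest.raises(KeyError, match="b"):
            tree_likelihood(t, AreaCoding(["A"], {"a": (1,)}),
                            DecModel(["A"], 0.1, 0.0))


class TestFitDec:
    def test_uniform_single_area_drives_dispersal_to_bound(self):
        t = parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        cod = AreaCoding(["W", "C", "H", "E"],
                         {x: (0, 0, 1, 0) for x in "abcd"})
        m = fit_dec(t, cod)
        assert m.d == pytest.approx(1e-8, rel=10)  # lower bound
        assert m.fit_info["at_bound"]
        rec = ancestral_splits(t, cod, m)
        for nid in rec.scenarios:
            L, R, p = rec.top(nid)
            assert state_label(L, m.areas) == "H" == state_label(R, m.areas)

    def test_optimum_beats_grid_starts(self):
        from rangearc.synthetic_data import simulate_dec_history, simulate_yule_tree

        tree = simulate_yule_tree(12, 0.5, seed=5)
        truth = DecModel(["A", "B", "C"], d=0.08, e=0.02)
        cod, _ = simulate_dec_history(tree, truth, seed=5)
        m = fit_dec(tree, cod)
        best = m.fit_info["log_likelihood"]
        for d0 in (0.001, 0.01, 0.1):
            for e0 in (0.001, 0.01, 0.1):
                ll = tree_likelihood(tree, cod, DecModel(["A", "B", "C"], d0, e0))
                assert best >= ll - 1e-6


class TestAncestralSplits:
    def test_two_tips_same_area_identity_scenario(self):
        t = parse_tree("(a:1,b:1);")
        cod = AreaCoding(["A", "B"], {"a": (1, 0), "b": (1, 0)})
        m = DecModel(["A", "B"], d=1e-9, e=1e-9)
        rec = ancestral_splits(t, cod, m)
        L, R, p = rec.top("n0")
        assert rec.slash_label("n0") == "A/A"
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_two_tips_different_areas_vicariance_tops(self):
        t = parse_tree("(a:1,b:1);")
        cod = AreaCoding(["A", "B"], {"a": (1, 0), "b": (0, 1)})
        m = DecModel(["A", "B"], d=0.01, e=0.005)
        rec = ancestral_splits(t, cod, m)
        assert rec.slash_label("n0") == "A/B"
        # scenario likelihoods agree with clamped brute-force recomputation
        total = math.exp(tree_likelihood(t, cod, m))
        top_p = rec.top("n0")[2]
        # vicariance A|B from ancestor AB: prior(AB) * 1/6 * P[A->A] * P[B->B]
        from scipy.linalg import expm

        P = expm(m.Q * 1.0)
        iA, iB, iAB = (m.index[frozenset(x)] for x in ("A", "B", "AB"))
        manual = m.root_prior[iAB] * (1 / 6) * P[iA, iA] * P[iB, iB]
        assert top_p == pytest.approx(manual / total, rel=1e-9)

    def test_scenario_likelihoods_sum_to_one(self, prunellid):
        m = DecModel(["W", "C", "H", "E"], d=0.1, e=0.05)
        rec = ancestral_splits(prunellid.tree, prunellid.coding, m)
        assert len(rec.scenarios) == 14
        for nid, rows in rec.scenarios.items():
            assert sum(p for *_, p in rows) == pytest.approx(1.0, abs=1e-9)

    def test_fixture_root_range_includes_himalaya(self, prunellid):
        m = fit_dec(prunellid.tree, prunellid.coding)
        rec = ancestral_splits(prunellid.tree, prunellid.coding, m)
        L, R, _ = rec.top("n0")
        assert "H" in (L | R)


class TestCodingIO:
    def test_tsv_roundtrip(self, tmp_path):
        cod = AreaCoding(["W", "C"], {"a": (1, 0), "b": (1, 1)})
        write_coding_tsv(cod, tmp_path / "c.tsv")
        back = read_coding_tsv(tmp_path / "c.tsv")
        assert back.areas == ["W", "C"] and back.tips == cod.tips

    def test_empty_range_coding_rejected(self):
        with pytest.raises(ValueError, match="no area"):
            AreaCoding(["A", "B"], {"a": (0, 0)})
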