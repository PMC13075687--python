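"""DEC model: state spaces, rates, likelihoods, reconstructions, arrival times."""


import numpy as np
import pytest

import divscape as dv
from divscape.dec_ranges import (DECParams, _outcomes, anagenetic_Q,
                                 build_state_space, cladogenesis_table,
                                 transition_probs)


# ---------------------------------------------------------------------------
# independent brute-force oracle (no pruning): enumerate every state history
# ---------------------------------------------------------------------------

def brute_force_likelihood(phy, tip_ranges, params, space):
    """Sum over all root states, cladogenetic outcomes and node states."""
    Q = anagenetic_Q(space, params)
    P = {v: transition_probs(Q, phy.branch_length[v])
         for v in range(phy.n_nodes) if v != phy.root}
    ns = space.n_states
    tip_idx = {phy.tip_index(lab): space.state_index(r)
               for lab, r in tip_ranges.items()}

    def subtree(v, top_state_idx, t_known=None):
        # probability of data below v given the state at the TOP of v's branch
        if phy.is_tip[v]:
            return P[v][top_state_idx, tip_idx[v]]
        total = 0.0
        for s in range(ns):  # state at node v (bottom of its branch)
            pv = P[v][top_state_idx, s] if v != phy.root else (top_state_idx == s)
            if pv == 0:
                continue
            total += pv * node_value(v, s)
        return total

    def node_value(v, s):
        c1, c2 = phy.children[v]
        out = 0.0
        for l, r, w in _outcomes(space.states[s]):
            out += (w * subtree(c1, space.index[l])
                    * subtree(c2, space.index[r]))
        return out

    lik = sum(node_value(phy.root, s) / ns for s in range(ns))
    return np.log(lik)


SHAPES = ["(A:1.0,B:0.7);", "((A:0.6,B:1.1):0.5,C:1.9);", "(A:2.5,B:0.2);"]
RANGESETS = [
    {"A": {1}, "B": {2}, "C": {1, 2}},
    {"A": {1, 2}, "B": {1}, "C": {2}},
    {"A": {2}, "B": {2}, "C": {2}},
]


class TestStateSpace:
    @pytest.mark.parametrize("A,mmax,count", [(2, 2, 3), (3, 3, 7), (10, 10, 1023)])
    def test_counts(self, A, mmax, count):
        sp = build_state_space(A, mmax)
        assert sp.n_states == count
        assert sp.null_index == count

    def test_deterministic_order(self):
        sp = build_state_space(3)
        sizes = [bin(m).count("1") for m in sp.states]
        assert sizes == sorted(sizes)

    def test_guards(self):
        with pytest.raises(ValueError):
            build_state_space(11)
        with pytest.raises(ValueError):
            build_state_space(3, 0)


class TestAnageneticQ:
    def test_hand_rates(self):
        sp = build_state_space(2)
        Q = anagenetic_Q(sp, DECParams(0.1, 0.05))
        i1, i12 = sp.state_index({1}), sp.state_index({1, 2})
        assert Q[i1, i12] == pytest.approx(0.1)     # {1} -> {1,2} at d*|R|
        assert Q[i1, sp.null_index] == pytest.approx(0.05)  # {1} -> null at e
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_zero_rates_zero_generator(self):
        Q = anagenetic_Q(build_state_space(3), DECParams(0, 0))
        assert np.allclose(Q, 0)


class TestTransitionProbs:
    def test_identity_at_zero(self):
        Q = anagenetic_Q(build_state_space(2), DECParams(0.2, 0.1))
        assert np.allclose(transition_probs(Q, 0.0), np.eye(4))

    def test_single_area_closed_form(self):
        sp = build_state_space(1)
        e = 0.3
        Q = anagenetic_Q(sp, DECParams(0.1, e))
        for t in (0.5, 2.0, 7.0):
            P = transition_probs(Q, t)
            assert P[0, sp.null_index] == pytest.approx(1 - np.exp(-e * t), rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_truncated_series(self, seed):
        rng = np.random.default_rng(seed)
        sp = build_state_space(2)
        Q = anagenetic_Q(sp, DECParams(rng.uniform(0, 1), rng.uniform(0, 1)))
        t = rng.uniform(0.1, 2.0)
        import math
        series = sum(np.linalg.matrix_power(Q * t, k) / math.factorial(k)
                     for k in range(30))
        assert np.allclose(transition_probs(Q, t), series, atol=1e-8)

    def test_stochastic_rows(self):
        Q = anagenetic_Q(build_state_space(3), DECParams(0.4, 0.2))
        for t in (0.1, 1.0, 10.0):
            P = transition_probs(Q, t)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
            assert (P >= 0).all()


class TestCladogenesis:
    def test_single_area(self):
        sp = build_state_space(2)
        assert cladogenesis_table(sp, {1}) == [(frozenset({1}), frozenset({1}), 1.0)]

    def test_two_area_enumeration(self):
        sp = build_state_space(2)
        table = cladogenesis_table(sp, {1, 2})
        assert len(table) == 6
        assert all(w == pytest.approx(1 / 6) for _, _, w in table)

    def test_weights_sum_to_one_every_state(self):
        sp = build_state_space(3)
        for mask in sp.states:
            tot = sum(w for _, _, w in cladogenesis_table(sp, sp.areas_of(mask)))
            assert tot == pytest.approx(1.0)

    def test_null_state_errors(self):
        with pytest.raises(ValueError):
            cladogenesis_table(build_state_space(2), set())


class TestLikelihood:
    @pytest.mark.parametrize("nwk,ranges", [
        (SHAPES[0], RANGESETS[0]), (SHAPES[1], RANGESETS[0]),
        (SHAPES[1], RANGESETS[1]), (SHAPES[2], RANGESETS[2]),
    ])
    def test_matches_enumeration(self, nwk, ranges):
        phy = dv.read_newick(nwk)
        ranges = {k: v for k, v in ranges.items() if k in phy.tip_labels}
        sp = build_state_space(2)
        params = DECParams(0.13, 0.07)
        got = dv.dec_loglik(phy, ranges, params, space=sp)
        want = brute_force_likelihood(phy, ranges, params, sp)
        assert got == pytest.approx(want, rel=1e-10)

    def test_child_order_invariance(self):
        sp = build_state_space(2)
        params = DECParams(0.2, 0.05)
        a = dv.dec_loglik(dv.read_newick("((A:1,B:1):1,C:2);"),
                          RANGESETS[0], params, space=sp)
        b = dv.dec_loglik(dv.read_newick("(C:2,(B:1,A:1):1);"),
                          RANGESETS[0], params, space=sp)
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_in_extinction_for_disjoint_tips(self):
        phy = dv.read_newick("(A:1,B:1);")
        sp = build_state_space(2)
        lls = [dv.dec_loglik(phy, {"A": {1}, "B": {2}}, DECParams(0.05, e), space=sp)
               for e in (1.0, 3.0, 8.0, 20.0)]
        assert all(np.diff(lls) < 0)

    def test_bad_tip_range_errors(self):
        phy = dv.read_newick("(A:1,B:1);")
        sp = build_state_space(2, mmax=1)
        with pytest.raises(ValueError):
            dv.dec_loglik(phy, {"A": {1, 2}, "B": {2}}, DECParams(0.1, 0.1), space=sp)


class TestFitDec:
    def test_optimum_beats_local_grid(self):
        rng = np.random.default_rng(2)
        phy = dv.read_newick(
            "((A:1.2,B:0.8):0.6,((C:0.5,D:0.5):0.9,E:1.4):0.4);")
        sp = build_state_space(2)
        ranges = dv.simulate_dec_ranges(phy, sp, DECParams(0.4, 0.1), rng)
        fit = dv.fit_dec(phy, ranges, space=sp)
        best = fit.loglik
        lo, hi = 1e-4, 50.0  # optimizer's feasible box
        for fd in (0.7, 0.85, 1.0, 1.18, 1.4):
            for fe in (0.7, 0.85, 1.0, 1.18, 1.4):
                d = min(max(fit.params.d * fd, lo), hi)
                e = min(max(fit.params.e * fe, lo), hi)
                ll = dv.dec_loglik(phy, ranges, DECParams(d, e), space=sp)
                assert ll <= best + 1e-6

    def test_single_area_data_drives_e_to_floor(self):
        phy = dv.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sp = build_state_space(2)
        fit = dv.fit_dec(phy, {t: {1} for t in "ABCD"}, space=sp)
        assert fit.params.e < 1e-3


class TestAncestral:
    def test_marginals_match_enumeration(self):
        """Brute-force joint enumeration for a 3-tip tree."""
        phy = dv.read_newick("((A:1.0,B:1.5):0.8,C:2.2);")
        sp = build_state_space(2)
        params = DECParams(0.13, 0.07)
        tips = RANGESETS[0]
        Q = anagenetic_Q(sp, params)
        P = lambda t: transition_probs(Q, t)
        ns = sp.n_states
        ti = {lab: sp.state_index(s) for lab, s in tips.items()}
        tot = 0.0
        m_root = np.zeros(ns)
        m_ab = np.zeros(ns)
        tA = phy.branch_length[phy.tip_index("A")]
        tB = phy.branch_length[phy.tip_index("B")]
        tC = phy.branch_length[phy.tip_index("C")]
        ab = phy.mrca({"A", "B"})
        t_ab = phy.branch_length[ab]
        for r0 in range(ns):
            for l0, g0, w0 in _outcomes(sp.states[r0]):
                for s_ab in range(ns):
                    p_ab = P(t_ab)[sp.index[l0], s_ab]
                    for l1, g1, w1 in _outcomes(sp.states[s_ab]):
                        c = (w0 * w1 * p_ab / ns
                             * P(tA)[sp.index[l1], ti["A"]]
                             * P(tB)[sp.index[g1], ti["B"]]
                             * P(tC)[sp.index[g0], ti["C"]])
                        tot += c
                        m_root[r0] += c
                        m_ab[s_ab] += c
        rec = dv.ancestral_ranges(phy, tips, params, space=sp)
        assert np.allclose(rec.marginals[phy.root], m_root / tot, atol=1e-8)
        assert np.allclose(rec.marginals[ab], m_ab / tot, atol=1e-8)
        for v, m in rec.marginals.items():
            assert m.sum() == pytest.approx(1.0, abs=1e-8)

    def test_low_rate_limit_root_keeps_shared_area(self):
        phy = dv.read_newick("((A:1,B:1):1,C:2);")
        sp = build_state_space(2)
        tips = {"A": {1}, "B": {1, 2}, "C": {1}}
        rec = dv.ancestral_ranges(phy, tips, DECParams(1e-4, 1e-4), space=sp)
        assert 1 in rec.argmax_range[phy.root]


class TestArrival:
    def _fixture(self):
        # tip X at age 0; parent at 5 Ma holds {A,B}; grandparent (root) at
        # 12 Ma holds only {B}
        phy = dv.read_newick("((X:5,Y:5):7,Z:12);")
        sp = build_state_space(2)
        rec = dv.AncestralReconstruction(
            space=sp, marginals={},
            argmax_range={phy.mrca({"X", "Y"}): frozenset({1, 2}),
                          phy.root: frozenset({2})},
            params=DECParams(0.1, 0.1))
        return phy, rec

    def test_deepest_uninterrupted_node(self):
        phy, rec = self._fixture()
        assert dv.arrival_time("X", 1, rec, phy) == pytest.approx(5.0)

    def test_full_chain_reaches_root(self):
        phy, rec = self._fixture()
        assert dv.arrival_time("X", 2, rec, phy) == pytest.approx(12.0)

    def test_floor_when_parent_lacks_region(self):
        phy = dv.read_newick("((X:5,Y:5):7,Z:12);")
        sp = build_state_space(2)
        rec = dv.AncestralReconstruction(
            space=sp, marginals={},
            argmax_range={phy.mrca({"X", "Y"}): frozenset({2}),
                          phy.root: frozenset({1})},
            params=DECParams(0.1, 0.1))
        assert dv.arrival_time("X", 1, rec, phy) == pytest.approx(1e-5)
        # without the continuity requirement the deeper root occupancy counts
        assert dv.arrival_time("X", 1, rec, phy,
                               continuous=False) == pytest.approx(12.0)

    def test_assemblage_ages(self):
        pam = dv.PresenceAbsenceMatrix(
            ["c0", "c1", "c2"], np.zeros((3, 2)), ["X", "Y"],
            np.array([[1, 0], [1, 1], [0, 1]]))
        emap = dv.EvoregionMap({"c0": 1, "c1": 1, "c2": 2}, 2, 0.5, np.array([]))
        table = dv.ArrivalTable({("X", 1): 4.0, ("Y", 1): 6.0, ("Y", 2): 1e-5})
        ages = dv.assemblage_ages(table, pam, emap)
        assert ages["c0"] == pytest.approx(4.0)
        assert ages["c1"] == pytest.approx(5.0)
        assert ages["c2"] == pytest.approx(1e-5)


def test_parameter_recovery_smoke():
    """Fitted rates land within an order of magnitude on a 60-tip simulation."""
    from conftest import random_ultrametric
    rng = np.random.default_rng(7)
    phy = random_ultrametric(60, 7, birth_rate=1.0)
    sp = build_state_space(3)
    truth = DECParams(0.15, 0.05)
    ranges = dv.simulate_dec_ranges(phy, sp, truth, rng, max_tries=5000)
    fit = dv.fit_dec(phy, ranges, space=sp)
    assert 0.1 < fit.params.d / truth.d < 10
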