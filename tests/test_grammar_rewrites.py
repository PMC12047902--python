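"""Graph rewrites: elongation, retraction, branching, capping, bundling,
severing; mass bookkeeping invariants."""

import math

import numpy as np
import pytest

import spinedgg.grammar as gr
import spinedgg.state as st
from spinedgg import ModelParams, analysis
from spinedgg.state import validate_state


def total_actin_mass(s, n_cg=50):
    ids = s.actin_ids()
    bound = sum(n_cg for i in ids if int(s.a_sub[i]) in st.ACTIN_SUBTYPES)
    return s.pools["actin"] + bound


@pytest.fixture
def spine(params):
    s = analysis.fixture("default_spine", seed=3)
    return s


class TestElongation:
    def test_barbed_shape(self, params):
        s = analysis.fixture("straight_filament", n=2)
        s.pools["actin"] = 1e4
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        new = gr.apply_elongation(s, end, params, theta=0.0)
        assert int(s.a_sub[end]) == st.INTERIOR
        assert int(s.a_sub[new]) == st.END
        assert int(s.a_next[end]) == new
        assert int(s.a_atp[new]) == params.n_cg
        assert validate_state(s) == []

    def test_branch_seed_variant(self, spine, params):
        seed = [int(i) for i in spine.actin_ids()
                if s_sub(spine, i) == st.ARP_END][0]
        new = gr.apply_elongation(spine, seed, params, theta=0.0)
        assert s_sub(spine, seed) == st.ARP_INTERIOR   # ■ → □
        assert s_sub(spine, new) == st.END
        assert validate_state(spine) == []

    def test_pointed_variant_grows_at_prev(self, params):
        s = analysis.fixture("straight_filament", n=3)
        s.pools["actin"] = 1e4
        pe = [int(i) for i in s.actin_ids() if s.is_pointed_end(int(i))][0]
        new = gr.apply_elongation(s, pe, params, theta=0.0)
        assert int(s.a_prev[new]) == -1
        assert int(s.a_next[new]) == pe
        assert validate_state(s) == []

    def test_empty_pool_blocks(self, params):
        s = analysis.fixture("straight_filament", n=2)
        s.pools["actin"] = params.n_cg - 1
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        with pytest.raises(ValueError):
            gr.apply_elongation(s, end, params)

    def test_mass_conserved(self, params):
        s = analysis.fixture("straight_filament", n=3)
        s.pools["actin"] = 1e4
        m0 = total_actin_mass(s)
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        gr.apply_elongation(s, end, params)
        assert total_actin_mass(s) == pytest.approx(m0)


def s_sub(s, i):
    return int(s.a_sub[i])


class TestRetraction:
    def test_three_node_filament_shrinks(self, params):
        s = analysis.fixture("straight_filament", n=3)
        m0 = total_actin_mass(s)
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        gr.apply_retraction(s, end, params)
        assert s.n_actin == 2
        assert total_actin_mass(s) == pytest.approx(m0)
        assert validate_state(s) == []

    def test_pointed_variant_removes_pointed_node(self, params):
        s = analysis.fixture("straight_filament", n=3)
        pe = [int(i) for i in s.actin_ids() if s.is_pointed_end(int(i))][0]
        gr.apply_retraction(s, pe, params)
        assert not s.a_alive[pe]
        assert validate_state(s) == []

    def test_dimer_dissolves_entirely(self, params):
        s = analysis.fixture("straight_filament", n=2)
        m0 = total_actin_mass(s)
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        gr.apply_retraction(s, end, params)
        assert s.n_actin == 0
        assert total_actin_mass(s) == pytest.approx(m0)

    def test_retraction_propensity_from_composition(self, params):
        s = analysis.fixture("straight_filament", n=3)
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        s.a_atp[end] = 0
        s.a_adp[end] = 50
        assert gr.node_off_rate(s, end, params, "barbed") == pytest.approx(
            7.2 / 50)

    def test_bound_cofilin_returns_to_pool(self, params):
        s = analysis.fixture("straight_filament", n=3)
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        s.a_atp[end] = 40
        s.a_cof[end] = 10
        gr.apply_retraction(s, end, params)
        assert s.pools["cofilin"] == 10
        assert s.pools["actin"] == 50


class TestBranching:
    def test_daughter_at_seventy_degrees(self, spine, params):
        mother = None
        # grow the mother filament so an interior ◯ exists
        barbed = [int(i) for i in spine.actin_ids()
                  if s_sub(spine, i) == st.END and spine.a_next[i] == -1][0]
        spine.pools["actin"] = 1e5
        gr.apply_elongation(spine, barbed, params, theta=0.0)
        mother = barbed  # now interior
        seed = gr.apply_branching(spine, mother, params, side=1.0, jitter=0.0)
        axis = (spine.a_pos[int(spine.a_next[mother])]
                - spine.a_pos[int(spine.a_prev[mother])])
        d = spine.a_pos[seed] - spine.a_pos[mother]
        ang = math.acos(float(axis @ d) / (np.linalg.norm(axis) * np.linalg.norm(d)))
        assert ang == pytest.approx(params.theta_arp, abs=1e-9)
        assert s_sub(spine, mother) == st.JUNCTION
        assert validate_state(spine) == []

    def test_unbranch_restores_interior(self, spine, params):
        barbed = [int(i) for i in spine.actin_ids()
                  if s_sub(spine, i) == st.END and spine.a_next[i] == -1][0]
        spine.pools["actin"] = 1e5
        gr.apply_elongation(spine, barbed, params, theta=0.0)
        arp0 = spine.pools["arp_active"]
        seed = gr.apply_branching(spine, barbed, params)
        assert spine.pools["arp_active"] == arp0 - 1
        gr.apply_unbranching(spine, barbed, params)
        assert s_sub(spine, barbed) == st.INTERIOR
        assert spine.pools["arp_active"] == arp0
        assert validate_state(spine) == []

    def test_zero_arp_pool_blocks(self, params):
        s = analysis.fixture("straight_filament", n=5)
        s.pools["arp_active"] = 0
        mid = [int(i) for i in s.actin_ids()][2]
        with pytest.raises(ValueError):
            gr.apply_branching(s, mid, params)

    def test_junction_mother_rejected(self, spine, params):
        jid = [int(i) for i in spine.actin_ids()
               if s_sub(spine, i) == st.JUNCTION][0]
        with pytest.raises(ValueError):
            gr.apply_branching(spine, jid, params)


class TestCapping:
    def test_cap_removes_from_elongable_set(self, params):
        s = analysis.fixture("straight_filament", n=3)
        s.pools["cap"] = 10
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        assert gr.barbed_elongable(s, end)
        gr.apply_capping(s, end, params)
        assert not gr.barbed_elongable(s, end)
        assert not gr.cappable(s, end)

    def test_cap_uncap_round_trip(self, params):
        s = analysis.fixture("straight_filament", n=3)
        s.pools["cap"] = 10
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        before = s.to_dict()
        gr.apply_capping(s, end, params)
        gr.apply_uncapping(s, end, params)
        after = s.to_dict()
        assert before["actin"] == after["actin"]
        assert before["pools"] == after["pools"]

    def test_uncap_rate_is_first_order(self, params):
        # the off-rate constant does not scale with the pool
        assert params.k_cap_off == pytest.approx(9.5e-4)


class TestBundling:
    @pytest.mark.parametrize("sep,angle,expect", [
        (0.9, 5 * math.pi / 180, True),
        (0.9, 20 * math.pi / 180, False),
        (1.1, 5 * math.pi / 180, False),
    ])
    def test_eligibility_thresholds(self, params, sep, angle, expect):
        s = st.SimState()
        a = [s.add_actin((k, 0.0), st.END if k in (0, 2) else st.INTERIOR,
                         atp=50) for k in range(3)]
        # second filament at the given separation and axis angle
        c, sn = math.cos(angle), math.sin(angle)
        b = [s.add_actin((k * c, sep + k * sn),
                         st.END if k in (0, 2) else st.INTERIOR, atp=50)
             for k in range(3)]
        for ids in (a, b):
            for u, v in zip(ids, ids[1:]):
                s.a_next[u] = v
                s.a_prev[v] = u
        assert gr.bundling_eligibility(s, a[1], b[1], params) is expect

    def test_self_bundling_raises(self, params):
        s = analysis.fixture("straight_filament", n=3)
        i = int(s.actin_ids()[1])
        with pytest.raises(ValueError):
            gr.bundling_eligibility(s, i, i, params)

    def test_adjacent_nodes_ineligible(self, params):
        s = analysis.fixture("straight_filament", n=3)
        ids = [int(i) for i in s.actin_ids()]
        assert not gr.bundling_eligibility(s, ids[0], ids[1], params)

    def test_bond_stores_rest_length(self, params):
        s = analysis.fixture("bundled_pair")
        (a, b, rest) = list(s.bundles.values())[0]
        assert rest == pytest.approx(
            math.hypot(*(s.a_pos[a] - s.a_pos[b])))

    def test_bundle_unbundle_pools(self, params):
        s = analysis.fixture("straight_filament", n=3)
        ids = [int(i) for i in s.actin_ids()]
        s2 = analysis.fixture("bundled_pair")
        s2.pools["cam"] = 5
        bid = list(s2.bundles)[0]
        gr.apply_unbundle(s2, bid, params)
        assert s2.pools["cam"] == 6
        assert not s2.bundles


class TestSevering:
    DEG = math.pi / 180

    @pytest.mark.parametrize("t1,t2,c1,c2,d,expect", [
        (60 * DEG, 0.0, 0, 0, 1.0, True),     # bare-actin clause
        (60 * DEG, 0.0, 50, 0, 1.0, True),    # boundary clause (60 > 31, unequal)
        (60 * DEG, 0.0, 50, 50, 1.0, False),  # 60 < 73, equal cofilin
        (20 * DEG, 0.0, 10, 10, 1.6, True),   # distance clause
        (56 * DEG, 0.0, 0, 0, 1.0, False),    # below bare threshold
        (57 * DEG, 0.0, 0, 0, 1.0, True),     # H(0) = 1: fires at equality
        (75 * DEG, 0.0, 50, 50, 1.0, True),   # cofilactin clause
    ])
    def test_clause_table(self, params, t1, t2, c1, c2, d, expect):
        assert gr.severing_predicate(t1, t2, c1, c2, d, params) is expect

    def test_monotone_in_angle_and_distance(self, params):
        for base in np.linspace(0, math.pi / 2, 25):
            for d in np.linspace(0.5, 2.0, 7):
                if gr.severing_predicate(base, 0, 0, 0, d, params):
                    assert gr.severing_predicate(base + 0.1, 0, 0, 0, d, params)
                    assert gr.severing_predicate(base, 0, 0, 0, d + 0.2, params)

    def test_apply_sever_makes_two_ends(self, params):
        s = analysis.fixture("straight_filament", n=5)
        ids = [int(i) for i in s.actin_ids()]
        gr.apply_sever(s, ids[1], ids[2], params)
        assert s_sub(s, ids[1]) == st.END and s_sub(s, ids[2]) == st.END
        assert validate_state(s) == []

    def test_check_local_breaks_fires_on_bent_edge(self, params):
        s = analysis.fixture("bent_filament", n=5, theta=1.2)  # ~69° bends
        ids = [int(i) for i in s.actin_ids()]
        touched = gr.check_local_breaks(s, ids, params)
        assert touched  # bare actin severs beyond 57°
        assert validate_state(s) == []

    def test_distance_break_dissolves_orphan(self, params):
        s = analysis.fixture("straight_filament", n=3)
        ids = [int(i) for i in s.actin_ids()]
        m0 = total_actin_mass(s)
        s.a_pos[ids[2]] = (4.0, 0.0)   # stretch the end bond past d_break
        gr.check_local_breaks(s, [ids[2]], params)
        assert not s.a_alive[ids[2]]   # orphaned single segment dissolved
        assert total_actin_mass(s) == pytest.approx(m0)
        assert validate_state(s) == []


class TestJunctionBreaking:
    def test_bent_branch_detaches(self, params):
        s = analysis.fixture("branched_Y")
        jid = [int(i) for i in s.actin_ids() if s_sub(s, i) == st.JUNCTION][0]
        seed = int(s.a_arp[jid])
        # rotate the branch to 20° off the mother axis (|20-70| = 50 > 25)
        s.a_pos[seed] = (math.cos(0.35), math.sin(0.35))
        assert gr.junction_break_predicate(s, jid, params)
        arp0 = s.pools["arp_active"]
        gr.apply_junction_break(s, jid, params)
        assert s.pools["arp_active"] == arp0 + 1
        assert s_sub(s, jid) == st.INTERIOR
        assert validate_state(s) == []

    def test_branch_at_seventy_stays(self, params):
        s = analysis.fixture("branched_Y")
        jid = [int(i) for i in s.actin_ids() if s_sub(s, i) == st.JUNCTION][0]
        assert not gr.junction_break_predicate(s, jid, params)


class TestPerNodeCountInvariant:
    def test_cofilin_and_phosphate_rules_preserve_sum(self, params, rng):
        s = analysis.fixture("straight_filament", n=4)
        s.pools["cofilin"] = 100
        ids = [int(i) for i in s.actin_ids()]
        for _ in range(300):
            i = ids[int(rng.integers(len(ids)))]
            op = rng.integers(4)
            try:
                if op == 0:
                    gr.apply_hydrolysis(s, i)
                elif op == 1:
                    gr.apply_pi_release(s, i)
                elif op == 2:
                    gr.apply_cofilin_bind(s, i, params)
                else:
                    gr.apply_cofilin_unbind(s, i, params)
            except ValueError:
                continue
            total = int(s.a_atp[i] + s.a_adp[i] + s.a_adppi[i] + s.a_cof[i])
            assert total == params.n_cg
        assert validate_state(s) == []
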