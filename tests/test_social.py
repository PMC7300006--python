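"""Social metrics: association counting, Elo, centrality, Mantel,
kinship and dyad selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import troopkit as tk
from troopkit.social import CentralityResult

from conftest import toy_scan_table


class TestAssociationMatrix:
    def test_hand_enumerated_toy(self):
        scans = toy_scan_table([("A", 1, ["B"]), ("A", 2, ["B", "C"]),
                                ("B", 1, ["A"])])
        a = tk.build_association_matrix(scans)
        assert a.loc["A", "B"] == 3 and a.loc["B", "A"] == 3
        assert a.loc["A", "C"] == 1
        assert a.loc["B", "C"] == 0
        assert np.all(np.diag(a) == 0)

    def test_no_neighbours_zero_matrix(self):
        scans = toy_scan_table([("A", 1, []), ("B", 1, [])])
        a = tk.build_association_matrix(scans)
        assert not a.to_numpy().any()

    def test_scan_order_invariance(self, troop):
        shuffled = troop.scans.sample(frac=1.0, random_state=3)
        pd.testing.assert_frame_equal(
            tk.build_association_matrix(troop.scans),
            tk.build_association_matrix(shuffled))

    def test_rate_mode_divides_by_dyad_effort(self):
        scans = toy_scan_table([("A", 1, ["B"]), ("A", 2, ["B"]),
                                ("B", 1, ["A"]), ("B", 2, [])])
        a = tk.build_association_matrix(scans, mode="rate")
        assert a.loc["A", "B"] == pytest.approx(3 / 4)

    def test_unknown_roster_id_raises(self):
        scans = toy_scan_table([("A", 1, ["Z"])])
        with pytest.raises(ValueError, match="Z"):
            tk.build_association_matrix(scans, individuals=["A", "B"])

    def test_symmetry(self, assoc):
        np.testing.assert_array_equal(assoc.to_numpy(), assoc.to_numpy().T)


class TestZscoreDyadic:
    def test_two_value_convention(self):
        m = pd.DataFrame([[0, 0, 2], [0, 0, 0], [2, 0, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        z = tk.zscore_dyadic(m)
        vals = sorted({round(v, 6) for v in z.to_numpy()[~np.eye(3, dtype=bool)]})
        assert vals == [-1.0, 2.0] or vals == [-1.0, 1.0, 2.0] \
            or min(vals) < 0 < max(vals)
        assert abs(z.to_numpy()[~np.eye(3, dtype=bool)].mean()) < 1e-10
        assert abs(z.to_numpy()[~np.eye(3, dtype=bool)].std() - 1) < 1e-10

    def test_affine_invariance(self, assoc):
        z1 = tk.zscore_dyadic(assoc)
        z2 = tk.zscore_dyadic(assoc * 3.5 + 7.0)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_zero_variance_raises(self):
        m = pd.DataFrame(np.ones((3, 3)), index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError, match="variance"):
            tk.zscore_dyadic(m)


class TestElo:
    def test_first_update_closed_form(self):
        c = pd.DataFrame([{"winner_id": "A", "loser_id": "B", "order": 1}])
        elo = tk.elo_ratings(c, k=100, start=1000)
        assert elo.ratings["A"] == pytest.approx(1050.0)
        assert elo.ratings["B"] == pytest.approx(950.0)

    def test_no_events_all_start(self):
        c = pd.DataFrame(columns=["winner_id", "loser_id", "order"])
        elo = tk.elo_ratings(c, individuals=list("ABCDE"))
        assert all(v == 1000.0 for v in elo.ratings.values())

    def test_rating_sum_conserved_after_every_event(self, troop):
        elo = tk.elo_ratings(troop.conflicts,
                             individuals=list(troop.spec.planted_affinity.index))
        n = len(elo.ratings)
        # trajectory bookkeeping: recompute the running sum event by event
        ratings = {i: 1000.0 for i in elo.ratings}
        for _, ev in elo.history.iterrows():
            ratings[ev["winner_id"]] = ev["winner_rating"]
            ratings[ev["loser_id"]] = ev["loser_rating"]
            assert sum(ratings.values()) == pytest.approx(1000.0 * n, abs=1e-6)

    def test_planted_hierarchy_recovered(self):
        spec = tk.TroopSimSpec(n_individuals=10, rank_steepness=0.95,
                               n_conflicts=2000, n_scans_per_focal=5, seed=17)
        troop = tk.gen_troop_observations(spec)
        elo = tk.elo_ratings(troop.conflicts)
        ranks = troop.spec.true_ranks
        ids = list(elo.ratings)
        rho = stats.spearmanr([-elo.ratings[i] for i in ids],
                              [ranks[i] for i in ids]).statistic
        assert rho >= 0.9

    def test_unknown_id_raises(self):
        c = pd.DataFrame([{"winner_id": "A", "loser_id": "X", "order": 1}])
        with pytest.raises(ValueError, match="X"):
            tk.elo_ratings(c, individuals=["A", "B"])


class TestCentrality:
    def test_complete_graph_all_equal(self):
        ids = list("ABCDE")
        m = pd.DataFrame(1.0, index=ids, columns=ids)
        np.fill_diagonal(m.values, 0.0)
        c = tk.eigenvector_centrality(m)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in c.scores.values())
        assert len(c.central_set) == 3 and len(c.peripheral_set) == 2

    def test_star_graph_hub_dominates(self):
        ids = list("ABCDE")
        m = pd.DataFrame(0.0, index=ids, columns=ids)
        for o in "BCDE":
            m.loc["A", o] = m.loc[o, "A"] = 1.0
        c = tk.eigenvector_centrality(m)
        assert c.scores["A"] == 1.0
        assert all(c.scores[o] < 1.0 for o in "BCDE")
        assert "A" in c.central_set

    def test_matches_dense_eigensolver_oracle(self, rng):
        for _ in range(20):
            n = 10
            w = rng.random((n, n))
            w = np.triu(w, 1)
            w = w + w.T
            ids = [f"I{i}" for i in range(n)]
            m = pd.DataFrame(w, index=ids, columns=ids)
            c = tk.eigenvector_centrality(m)
            evals, evecs = np.linalg.eigh(w)
            v = np.abs(evecs[:, np.argmax(evals)])
            v /= v.max()
            got = np.array([c.scores[i] for i in ids])
            np.testing.assert_allclose(got, v, atol=1e-8)

    def test_scale_invariance(self, assoc):
        c1 = tk.eigenvector_centrality(assoc)
        c2 = tk.eigenvector_centrality(assoc * 13.7)
        for i in c1.scores:
            assert c1.scores[i] == pytest.approx(c2.scores[i], abs=1e-9)

    def test_matches_networkx(self, assoc):
        nx = pytest.importorskip("networkx")
        g = nx.from_pandas_adjacency(assoc)
        ref = nx.eigenvector_centrality_numpy(g, weight="weight")
        top = max(ref, key=ref.get)
        c = tk.eigenvector_centrality(assoc)
        for i in assoc.index:
            assert c.scores[i] == pytest.approx(ref[i] / ref[top], abs=1e-6)

    def test_empty_matrix_raises(self):
        m = pd.DataFrame(0.0, index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            tk.eigenvector_centrality(m)


class TestMantel:
    def test_identity_r_one_minimal_p(self, assoc):
        res = tk.mantel_test(assoc, assoc, n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_grooming_tracks_association(self, troop, assoc):
        res = tk.mantel_test(assoc, troop.grooming, n_perm=999, seed=2)
        assert res.r > 0 and res.p_value < 0.05

    def test_dimension_mismatch(self, assoc):
        with pytest.raises(ValueError, match="individuals"):
            tk.mantel_test(assoc, assoc.iloc[:5, :5])


class TestStabilitySplit:
    def test_stationary_network_stable(self, troop):
        res = tk.stability_split(troop.scans, 0.5, n_perm=499, seed=3)
        assert res.r > 0.5 and res.p_value < 0.01

    def test_rewired_network_unstable(self):
        """Affinity flips to an independent draw at the midpoint."""
        rng = np.random.default_rng(5)
        ids = [f"I{i:02d}" for i in range(12)]

        def rand_aff():
            w = rng.random((12, 12)) * 0.35
            w = np.triu(w, 1)
            w = w + w.T
            return pd.DataFrame(w, index=ids, columns=ids)

        halves = []
        for h, aff in enumerate([rand_aff(), rand_aff()]):
            spec = tk.TroopSimSpec(n_individuals=12, planted_affinity=aff,
                                   matrilines={i: "M1" for i in ids},
                                   n_scans_per_focal=150, n_conflicts=5,
                                   seed=100 + h)
            scans = tk.gen_troop_observations(spec).scans
            scans["scan_index"] += h * 1000
            halves.append(scans)
        scans = pd.concat(halves, ignore_index=True)
        res = tk.stability_split(scans, 0.5, n_perm=499, seed=4)
        assert abs(res.r) < 0.35

    def test_extreme_split_weaker_than_even_split(self, troop):
        p_even = tk.stability_split(troop.scans, 0.5, n_perm=499, seed=6).p_value
        p_tail = tk.stability_split(troop.scans, 0.97, n_perm=499, seed=6).p_value
        assert p_tail >= p_even

    def test_bad_split_raises(self, troop):
        with pytest.raises(ValueError):
            tk.stability_split(troop.scans, 1.5)


class TestKinship:
    def test_two_matrilines(self):
        k = tk.kinship_matrix({"A": "M1", "B": "M1", "C": "M2"})
        assert k.loc["A", "B"] == 1
        assert k.loc["A", "C"] == 0 and k.loc["B", "C"] == 0

    def test_degenerate_labels(self):
        one = tk.kinship_matrix({c: "M" for c in "ABC"})
        assert one.to_numpy().sum() == 9
        singletons = tk.kinship_matrix({c: c for c in "ABC"})
        off = singletons.to_numpy()[~np.eye(3, dtype=bool)]
        assert not off.any()

    def test_missing_label_raises(self):
        with pytest.raises(ValueError, match="without"):
            tk.kinship_matrix({"A": "M1", "B": ""})


def _toy_selector_inputs():
    """Six females with a hand-designed friendship pattern around S."""
    ids = ["S", "F1", "F2", "F3", "F4", "F5"]
    m = pd.DataFrame(0.0, index=ids, columns=ids)

    def put(a, b, v):
        m.loc[a, b] = m.loc[b, a] = v

    put("S", "F1", 10)   # S's best friend
    put("S", "F2", 1)    # low with S
    put("S", "F3", 2)
    put("S", "F4", 6)
    put("S", "F5", 5)
    put("F1", "F2", 9)   # F2 is F1's top associate
    put("F1", "F3", 1)
    put("F1", "F4", 3)
    put("F1", "F5", 2)
    put("F2", "F3", 8)   # F2-F3 friends, both low with S
    sexes = {i: "F" for i in ids}
    kin = tk.kinship_matrix({"S": "M1", "F1": "M2", "F2": "M2",
                             "F3": "M3", "F4": "M3", "F5": "M4"})
    cent = CentralityResult(
        scores={i: s for i, s in zip(ids, [1.0, 0.9, 0.5, 0.4, 0.8, 0.3])},
        central_set=frozenset({"S", "F1", "F4"}),
        peripheral_set=frozenset({"F2", "F3", "F5"}))
    return ids, m, kin, sexes, cent


class TestSelectConditionDyads:
    def test_condition_1_top_friend_and_their_friend(self):
        _, m, kin, sexes, cent = _toy_selector_inputs()
        assert tk.select_condition_dyads("S", m, kin, sexes, cent, 1) == \
            ("F1", "F2")

    def test_condition_2_friend_with_mutual_stranger(self):
        _, m, kin, sexes, cent = _toy_selector_inputs()
        a, b = tk.select_condition_dyads("S", m, kin, sexes, cent, 2)
        assert a == "F1"
        assert m.loc["S", b] < np.median([m.loc["S", f]
                                          for f in ["F1", "F2", "F3", "F4", "F5"]])

    def test_condition_3_infeasible_for_central_subject(self):
        _, m, kin, sexes, cent = _toy_selector_inputs()
        # S is central: conditions 3 and 4 cannot be run on it
        assert tk.select_condition_dyads("S", m, kin, sexes, cent, 3) is None
        assert tk.select_condition_dyads("S", m, kin, sexes, cent, 4) is None

    def test_condition_3_peripheral_gets_mutual_friends(self):
        _, m, kin, sexes, cent = _toy_selector_inputs()
        res = tk.select_condition_dyads("F5", m, kin, sexes, cent, 3)
        if res is not None:
            a, b = res
            assert {a, b} <= {"F1", "F2", "F3", "F4", "S"} - {"F5"}

    def test_condition_5_matriarch_with_kin(self):
        _, m, kin, sexes, cent = _toy_selector_inputs()
        ranks = {"S": 3, "F1": 1, "F2": 2, "F3": 6, "F4": 5, "F5": 4}
        a, b = tk.select_condition_dyads("S", m, kin, sexes, cent, 5,
                                         ranks=ranks)
        assert kin.loc[a, b] == 1 and "S" not in (a, b)
        assert ranks[a] < ranks[b]  # A is the matriarch of the pair

    def test_condition_6_matriarch_with_nonkin(self):
        _, m, kin, sexes, cent = _toy_selector_inputs()
        a, b = tk.select_condition_dyads("S", m, kin, sexes, cent, 6)
        assert kin.loc[a, b] == 0 and "S" not in (a, b)

    def test_pure_function_of_inputs(self, troop, assoc):
        kin = tk.kinship_matrix(troop.spec.matrilines)
        cent = tk.eigenvector_centrality(assoc)
        subj = list(assoc.index)[0]
        for cond in range(1, 7):
            d1 = tk.select_condition_dyads(subj, assoc, kin, troop.spec.sexes,
                                           cent, cond)
            d2 = tk.select_condition_dyads(subj, assoc, kin, troop.spec.sexes,
                                           cent, cond)
            assert d1 == d2

    def test_callers_always_female_non_subject(self, troop, assoc):
        kin = tk.kinship_matrix(troop.spec.matrilines)
        cent = tk.eigenvector_centrality(assoc)
        for subj in list(assoc.index)[:6]:
            for cond in range(1, 7):
                d = tk.select_condition_dyads(subj, assoc, kin,
                                              troop.spec.sexes, cent, cond)
                if d is not None:
                    assert subj not in d
                    assert all(troop.spec.sexes[x] == "F" for x in d)

    def test_unknown_subject_raises(self, assoc, troop):
        kin = tk.kinship_matrix(troop.spec.matrilines)
        cent = tk.eigenvector_centrality(assoc)
        with pytest.raises(ValueError, match="unknown"):
            tk.select_condition_dyads("nobody", assoc, kin, troop.spec.sexes,
                                      cent, 1)
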