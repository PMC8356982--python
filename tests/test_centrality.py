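"""Degree, HITS, and Katz centralities against closed forms and oracles."""

import numpy as np
import pytest

from spesnet.centrality import (
    centrality_table,
    degree_centrality,
    group_centralities,
    hits_centrality,
    katz_centrality,
    node_location,
)
from spesnet.types import EffectiveNetwork

from conftest import make_contact


def _net(w, stimulated=None, possible=None):
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    contacts = [make_contact(f"n{i}", index=i) for i in range(n)]
    if possible is None:
        possible = np.ones((n, n), dtype=bool)
        np.fill_diagonal(possible, False)
    stim = np.ones(n, dtype=bool) if stimulated is None else np.asarray(stimulated)
    return EffectiveNetwork(
        w, possible, [c.contact_id for c in contacts], contacts, stim, threshold=5.9
    )


class TestDegree:
    def test_hand_computed_outdegree(self):
        w = np.zeros((3, 3))
        w[0, 1], w[0, 2] = 8.0, 6.0
        poss = np.zeros((3, 3), dtype=bool)
        poss[0, 1] = poss[0, 2] = True
        deg = degree_centrality(_net(w, possible=poss))
        assert deg.loc[0, "outdegree"] == pytest.approx(7.0)

    def test_isolated_stimulated_node_has_zero_outdegree(self):
        w = np.zeros((3, 3))
        w[0, 1] = 8.0
        deg = degree_centrality(_net(w))
        assert deg.loc[2, "outdegree"] == 0.0

    def test_unobservable_indegree_is_missing_not_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = 8.0
        poss = np.zeros((3, 3), dtype=bool)
        poss[0, 1] = True
        deg = degree_centrality(_net(w, possible=poss))
        assert np.isnan(deg.loc[2, "indegree"])
        assert np.isnan(deg.loc[2, "outdegree"]) or deg.loc[2, "outdegree"] == 0.0


class TestHITS:
    def test_single_edge_closed_form(self):
        w = np.zeros((2, 2))
        w[0, 1] = 8.0
        h = hits_centrality(_net(w))
        assert np.allclose(h["hub"], [1.0, 0.0], atol=1e-10)
        assert np.allclose(h["authority"], [0.0, 1.0], atol=1e-10)

    def test_star_authorities_uniform(self):
        w = np.zeros((4, 4))
        w[0, 1:] = 7.0
        h = hits_centrality(_net(w))
        assert np.allclose(h["authority"][1:], 1.0 / np.sqrt(3), atol=1e-10)
        assert np.allclose(h["hub"], [1, 0, 0, 0], atol=1e-10)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            w = np.where(rng.random((n, n)) < 0.5, 6.0 + 10 * rng.random((n, n)), 0.0)
            np.fill_diagonal(w, 0)
            if not (w > 0).any():
                continue
            h = hits_centrality(_net(w))
            a = np.abs(np.linalg.eigh(w.T @ w)[1][:, -1])
            assert np.allclose(h["authority"], a / np.linalg.norm(a), atol=1e-8)

    def test_cross_checked_against_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        n = 8
        w = np.where(rng.random((n, n)) < 0.5, 6 + 10 * rng.random((n, n)), 0.0)
        np.fill_diagonal(w, 0)
        net = _net(w)
        g = nx.from_numpy_array(w, create_using=nx.DiGraph)
        hub, auth = nx.hits(g, max_iter=1000, tol=1e-12)
        hv = np.array([hub[i] for i in range(n)])
        av = np.array([auth[i] for i in range(n)])
        mine = hits_centrality(net)
        assert np.allclose(mine["hub"], hv / np.linalg.norm(hv), atol=1e-10)
        assert np.allclose(mine["authority"], av / np.linalg.norm(av), atol=1e-10)
        lam = float(np.max(np.abs(np.linalg.eigvals(w))))
        kx = nx.katz_centrality(
            g, alpha=0.5 / lam, beta=1.0, normalized=True, weight="weight",
            max_iter=5000, tol=1e-12,
        )
        kv = np.array([kx[i] for i in range(n)])
        assert np.allclose(
            katz_centrality(net, alpha_frac=0.5)["katz_receive"], kv, atol=1e-10
        )

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(12)
        w = np.where(rng.random((6, 6)) < 0.5, 6.0 + 10 * rng.random((6, 6)), 0.0)
        np.fill_diagonal(w, 0)
        h1 = hits_centrality(_net(w))
        h2 = hits_centrality(_net(w * 3.7))
        assert np.allclose(h1["authority"], h2["authority"], atol=1e-10)

    def test_empty_graph_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="empty"):
            h = hits_centrality(_net(np.zeros((3, 3))))
        assert (h["authority"] == 0).all() and (h["hub"] == 0).all()


class TestKatz:
    def test_chain_broadcast_monotone(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = 8.0
        k = katz_centrality(_net(w))
        kb = k["katz_broadcast"].to_numpy()
        assert kb[0] > kb[1] > kb[2]

    def test_small_alpha_limit_matches_degree_ranking(self):
        rng = np.random.default_rng(13)
        w = np.where(rng.random((6, 6)) < 0.5, 6.0 + 10 * rng.random((6, 6)), 0.0)
        np.fill_diagonal(w, 0)
        k = katz_centrality(_net(w), alpha_frac=1e-6)
        order = np.argsort(k["katz_broadcast"].to_numpy())
        deg_order = np.argsort(w.sum(axis=1))
        assert np.array_equal(order, deg_order)

    def test_matches_neumann_series_oracle(self):
        w = np.zeros((3, 3))
        w[0, 1], w[1, 2], w[2, 0] = 8.0, 7.0, 6.5
        lam = float(np.max(np.abs(np.linalg.eigvals(w))))
        alpha_frac = 0.1 * lam / lam  # α·λ = 0.1: 50 terms converge below 1e-10
        k = katz_centrality(_net(w), alpha_frac=0.1)
        alpha = 0.1 / lam
        acc = np.ones(3)
        term = np.ones(3)
        for _ in range(50):
            term = alpha * (w.T @ term)
            acc += term
        acc /= np.linalg.norm(acc)
        assert np.allclose(k["katz_receive"], acc, atol=1e-10)

    def test_rescaling_invariance_via_adaptive_alpha(self):
        w = np.zeros((4, 4))
        w[0, 1], w[1, 2], w[2, 3], w[3, 0] = 8.0, 7.0, 9.0, 6.5
        k1 = katz_centrality(_net(w))
        k2 = katz_centrality(_net(w * 5.0))
        assert np.allclose(k1["katz_receive"], k2["katz_receive"], atol=1e-12)

    def test_invalid_attenuation_rejected(self):
        with pytest.raises(ValueError, match="alpha_frac"):
            katz_centrality(_net(np.zeros((2, 2))), alpha_frac=1.0)


class TestGrouping:
    def test_unit_norm_over_patient_nodes(self):
        rng = np.random.default_rng(14)
        w = np.where(rng.random((8, 8)) < 0.4, 6.0 + 10 * rng.random((8, 8)), 0.0)
        np.fill_diagonal(w, 0)
        table = centrality_table(_net(w))
        for col in ("authority", "hub", "katz_receive", "katz_broadcast"):
            vals = table[col].dropna().to_numpy()
            assert np.linalg.norm(table[col].fillna(0)) == pytest.approx(1.0, abs=1e-6)

    def test_outgoing_measures_masked_for_unstimulated(self):
        w = np.zeros((3, 3))
        w[0, 1] = 8.0
        stim = np.array([True, False, True])
        table = centrality_table(_net(w, stimulated=stim))
        assert np.isnan(table.loc[1, "outdegree"])
        assert np.isnan(table.loc[1, "hub"])
        assert not np.isnan(table.loc[1, "indegree"])

    def test_location_tags(self):
        left_hip = make_contact("h", "hippocampus")
        right_hip = make_contact("rh", "hippocampus", hemisphere="right")
        lat = make_contact("l", "other")
        lat_soz = make_contact("ls", "other", in_soz=True)
        assert node_location(left_hip, "left") == "ipsi_mtr"
        assert node_location(right_hip, "left") == "contra_mtr"
        assert node_location(lat, "left") == "outside_nonepi"
        assert node_location(lat_soz, "left") is None

    def test_single_node_location_mean_is_the_node_value(self):
        contacts = [
            make_contact("h", "hippocampus", index=0),
            make_contact("l1", index=1),
            make_contact("l2", index=2),
        ]
        w = np.zeros((3, 3))
        w[0, 1] = 8.0
        poss = np.ones((3, 3), dtype=bool)
        np.fill_diagonal(poss, False)
        net = EffectiveNetwork(
            w, poss, [c.contact_id for c in contacts], contacts,
            np.ones(3, dtype=bool), threshold=5.9,
        )
        table = centrality_table(net)
        pooled, means = group_centralities(table, contacts, "left")
        mtr_mean = means.set_index("location").loc["ipsi_mtr", "outdegree"]
        assert mtr_mean == pooled.set_index("node_id").loc["h", "outdegree"]

    def test_unilateral_patient_has_empty_contra_group(self):
        contacts = [
            make_contact("h", "hippocampus", index=0),
            make_contact("l", index=1),
        ]
        w = np.zeros((2, 2))
        w[0, 1] = 8.0
        poss = np.ones((2, 2), dtype=bool)
        np.fill_diagonal(poss, False)
        net = EffectiveNetwork(
            w, poss, ["h", "l"], contacts, np.ones(2, dtype=bool), threshold=5.9
        )
        pooled, _ = group_centralities(centrality_table(net), contacts, "left")
        assert "contra_mtr" not in set(pooled["location"])
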