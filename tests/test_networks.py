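import numpy as np
import pandas as pd
import pytest

from iena import (
    OTUTable,
    SampleMetadata,
    build_edge_network,
    build_node_network,
    compute_edge_reference_stats,
    compute_reference_stats,
    select_markers,
    shpcc_sample,
    spcc_sample,
)
from iena.networks import EdgeNetwork


def _meta(sample_ids, is_ref):
    return SampleMetadata(
        pd.DataFrame(
            {
                "subject_id": "subj1",
                "time_point": range(len(sample_ids)),
                "is_reference": is_ref,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


@pytest.fixture()
def hand_fixture():
    """Reference x=(1,2,3), y=2x; test sample (3, 6)."""
    df = pd.DataFrame(
        {"x": [1.0, 2.0, 3.0, 3.0], "y": [2.0, 4.0, 6.0, 6.0]},
        index=pd.Index(["r1", "r2", "r3", "t1"], name="sample_id"),
    )
    meta = _meta(list(df.index), [True, True, True, False])
    table = OTUTable(df)
    return table, meta, compute_reference_stats(table, meta)


class TestSpcc:
    def test_hand_computed_value(self, hand_fixture):
        table, _, stats = hand_fixture
        S = spcc_sample("t1", table, stats)
        # z_x = (3-2)/sqrt(2/3) = 1.22474, product = 1.5
        assert S.loc["x", "y"] == pytest.approx(1.5, abs=1e-10)
        assert S.loc["y", "x"] == S.loc["x", "y"]

    def test_sample_at_reference_mean_gives_zero_row(self, seeded_stats):
        table, _, stats = seeded_stats
        data = table.data.copy()
        data.loc["t0", stats.otu_ids[0]] = stats.mu[0]
        S = spcc_sample("t0", OTUTable(data), stats)
        np.testing.assert_allclose(S.iloc[0].to_numpy(), 0.0, atol=1e-12)

    def test_reference_average_reproduces_rho(self, seeded_stats):
        table, meta, stats = seeded_stats
        acc = np.zeros_like(stats.rho)
        for sid in meta.reference_ids():
            acc += spcc_sample(sid, table, stats).to_numpy()
        avg = acc / stats.n_ref
        np.fill_diagonal(avg, 1.0)
        assert np.max(np.abs(avg - stats.rho)) < 1e-12


class TestNodeNetwork:
    def test_matches_bruteforce_allpairs_ranking(self, seeded_stats):
        """With k = C(p,2) the network equals an exhaustive sort."""
        table, _, stats = seeded_stats
        p = len(stats.otu_ids)
        k = p * (p - 1) // 2
        net = build_node_network("t1", table, stats, k=k)
        S = spcc_sample("t1", table, stats)
        brute = sorted(
            (
                (str(a), str(b), S.loc[a, b])
                for i, a in enumerate(stats.otu_ids)
                for b in stats.otu_ids[i + 1:]
            ),
            key=lambda r: (-abs(r[2]), r[0], r[1]),
        )
        assert [(a, b) for a, b, _ in brute] == net.edges
        np.testing.assert_allclose([v for _, _, v in brute], net.spcc, atol=1e-14)

    def test_capacity_exceeding_universe_returns_all(self, hand_fixture):
        table, _, stats = hand_fixture
        net = build_node_network("t1", table, stats, k=10)
        assert len(net.edges) == 1  # 2 OTUs -> single pair

    def test_permutation_invariance(self, seeded_fixture):
        table, meta = seeded_fixture
        perm = table.data.sample(frac=1, axis=1, random_state=7)
        t2 = OTUTable(perm)
        s1 = compute_reference_stats(table, meta)
        s2 = compute_reference_stats(t2, meta)
        n1 = build_node_network("t2", table, s1, k=25)
        n2 = build_node_network("t2", t2, s2, k=25)
        assert n1.edges == n2.edges
        np.testing.assert_allclose(n1.spcc, n2.spcc, atol=1e-14)


class TestShpcc:
    def _setup(self, seeded_stats, k=40):
        table, meta, stats = seeded_stats
        net = build_node_network("t1", table, stats, k=k)
        es = compute_edge_reference_stats(table, meta, stats, net.edges)
        return table, meta, stats, net, es

    def test_self_pair_is_a_nonnegative_square(self, seeded_stats):
        table, meta, stats, net, es = self._setup(seeded_stats)
        e = es.edges[0]
        v = shpcc_sample("t1", e, e, table, stats, es)
        assert v >= 0

    def test_symmetry(self, seeded_stats):
        table, meta, stats, net, es = self._setup(seeded_stats)
        e1, e2 = es.edges[0], es.edges[1]
        assert shpcc_sample("t1", e1, e2, table, stats, es) == pytest.approx(
            shpcc_sample("t1", e2, e1, table, stats, es)
        )

    def test_reference_average_equals_edge_variable_correlation(self, seeded_stats):
        """Same population identity one level up, against numpy's corrcoef."""
        table, meta, stats, net, es = self._setup(seeded_stats, k=15)
        from iena.reference import zscore_matrix

        Z = zscore_matrix(table, stats).loc[meta.reference_ids()].to_numpy()
        ia = stats.index_of([a for a, _ in es.edges])
        ib = stats.index_of([b for _, b in es.edges])
        E = Z[:, ia] * Z[:, ib]
        C = np.corrcoef(E, rowvar=False)
        for i in range(min(5, len(es.edges))):
            for j in range(i + 1, min(5, len(es.edges))):
                avg = np.mean(
                    [
                        shpcc_sample(sid, es.edges[i], es.edges[j], table, stats, es)
                        for sid in meta.reference_ids()
                    ]
                )
                assert avg == pytest.approx(C[i, j], abs=1e-12)

    def test_uncalibrated_edge_rejected(self, seeded_stats):
        table, meta, stats, net, es = self._setup(seeded_stats)
        with pytest.raises(KeyError, match="calibration"):
            shpcc_sample("t1", ("nope", "nope2"), es.edges[0], table, stats, es)


class TestEdgeNetwork:
    def test_three_edges_three_pairs(self, seeded_stats):
        table, meta, stats = seeded_stats
        net = build_node_network("t1", table, stats, k=3)
        es = compute_edge_reference_stats(table, meta, stats, net.edges)
        en = build_edge_network("t1", net, table, stats, es, m=10)
        assert len(en.pairs) == 3  # C(3,2)

    def test_sorted_desc_with_lexicographic_ties(self, seeded_stats):
        table, meta, stats = seeded_stats
        net = build_node_network("t1", table, stats, k=20)
        es = compute_edge_reference_stats(table, meta, stats, net.edges)
        en = build_edge_network("t1", net, table, stats, es, m=50)
        mags = np.abs(en.shpcc)
        assert (np.diff(mags) <= 1e-14).all()
        for p in en.pairs:
            assert p[0] < p[1]  # canonical pair order

    def test_values_match_scalar_shpcc(self, seeded_stats):
        table, meta, stats = seeded_stats
        net = build_node_network("t1", table, stats, k=10)
        es = compute_edge_reference_stats(table, meta, stats, net.edges)
        en = build_edge_network("t1", net, table, stats, es, m=5)
        for (e1, e2), v in zip(en.pairs, en.shpcc):
            assert v == pytest.approx(shpcc_sample("t1", e1, e2, table, stats, es), abs=1e-12)

    def test_disjoint_mode_excludes_shared_otus(self, seeded_stats):
        table, meta, stats = seeded_stats
        net = build_node_network("t1", table, stats, k=30)
        es = compute_edge_reference_stats(table, meta, stats, net.edges)
        en = build_edge_network("t1", net, table, stats, es, m=100, disjoint=True)
        for (a, b), (c, d) in en.pairs:
            assert len({a, b, c, d}) == 4

    def test_fewer_than_two_edges_rejected(self, hand_fixture):
        table, meta, stats = hand_fixture
        net = build_node_network("t1", table, stats, k=5)
        es = compute_edge_reference_stats(table, meta, stats, net.edges)
        with pytest.raises(ValueError, match="fewer than 2"):
            build_edge_network("t1", net, table, stats, es, m=5)


class TestSelectMarkers:
    def _net(self, sample_id, pairs, vals, m=10):
        return EdgeNetwork(sample_id=sample_id, pairs=pairs, shpcc=np.array(vals), m=m)

    def test_union_of_constituents(self):
        net = self._net("s1", [((("A"), ("B")), (("C"), ("D")))], [5.0])
        net = self._net("s1", [(("A", "B"), ("C", "D"))], [5.0])
        ms = select_markers("subj1", {3: net}, n_markers=1)
        assert ms.otus == {"A", "B", "C", "D"}
        assert list(ms.provenance) == [3]

    def test_repeated_pair_counted_once_with_full_provenance(self):
        pair = (("A", "B"), ("C", "D"))
        nets = {1: self._net("s1", [pair], [5.0]), 2: self._net("s2", [pair], [7.0])}
        ms = select_markers("subj1", nets, n_markers=1)
        assert ms.otus == {"A", "B", "C", "D"}
        assert sorted(ms.provenance) == [1, 2]

    def test_peak_mode_keeps_only_strongest_time_point(self):
        nets = {
            1: self._net("s1", [(("A", "B"), ("C", "D"))], [2.0]),
            2: self._net("s2", [(("E", "F"), ("G", "H"))], [9.0]),
        }
        ms = select_markers("subj1", nets, n_markers=1, peaks="max")
        assert ms.otus == {"E", "F", "G", "H"}

    def test_weighted_mode_requires_zscores(self):
        nets = {1: self._net("s1", [(("A", "B"), ("C", "D"))], [2.0])}
        with pytest.raises(ValueError, match="zscores"):
            select_markers("subj1", nets, method="weighted")

    def test_weighted_mode_prefers_recurrent_deviating_otus(self):
        # A appears in both pairs and deviates strongly; H appears once, weakly
        nets = {
            1: self._net(
                "s1",
                [(("A", "B"), ("C", "D")), (("A", "C"), ("B", "E")), (("F", "G"), ("H", "I"))],
                [9.0, 8.0, 7.0],
            )
        }
        z = pd.DataFrame(
            [[5.0, 4.0, 4.0, 3.0, 3.0, 0.2, 0.2, 0.1, 0.1]],
            index=["s1"],
            columns=list("ABCDEFGHI"),
        )
        ms = select_markers("subj1", nets, n_markers=3, method="weighted", zscores=z)
        assert ms.otus == {"A", "B", "C"}
        assert ms.weights["A"] > ms.weights["B"]

    def test_empty_networks_rejected(self):
        with pytest.raises(ValueError, match="no edge networks"):
            select_markers("subj1", {})
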