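import numpy as np
import networkx as nx
import pytest

from nhnet import ownership_network as net
from nhnet.nhc_io import FacilitySnapshot, OwnerRecord

from conftest import make_snapshot, org_owner
from oracles import max_modularity_partition, pairwise_projection_oracle, random_bipartite


class TestBipartite:
    def test_shared_owner_edges(self):
        facs = [make_snapshot("A"), make_snapshot("B")]
        owners = [org_owner("A", "O LLC"), org_owner("B", "O LLC")]
        bip = net.build_bipartite(owners, facs, "H1", 1)
        assert bip.facility_nodes == {"A", "B"}
        assert len(bip.owner_nodes) == 1
        assert bip.graph.number_of_edges() == 2

    def test_isolated_facility_kept(self):
        facs = [make_snapshot("C")]
        bip = net.build_bipartite([], facs, "H1", 1)
        assert bip.facility_nodes == {"C"}
        assert bip.graph.degree("C") == 0

    def test_owner_record_for_unknown_provider_skipped(self):
        facs = [make_snapshot("A")]
        owners = [org_owner("ZZZ", "O LLC")]
        bip = net.build_bipartite(owners, facs, "H1", 1)
        assert bip.owner_nodes == set()


class TestProjection:
    def test_double_shared_owner_weight(self):
        facs = [make_snapshot("A"), make_snapshot("B")]
        owners = [
            org_owner("A", "O1 LLC"),
            org_owner("B", "O1 LLC"),
            org_owner("A", "O2 LLC"),
            org_owner("B", "O2 LLC"),
        ]
        proj = net.project_facilities(net.build_bipartite(owners, facs, "H1", 1))
        assert proj.graph["A"]["B"]["weight"] == 2

    def test_star_owner_gives_unit_triangle(self):
        facs = [make_snapshot(p) for p in "ABC"]
        owners = [org_owner(p, "O LLC") for p in "ABC"]
        proj = net.project_facilities(net.build_bipartite(owners, facs, "H1", 1))
        assert proj.graph.number_of_edges() == 3
        assert all(d["weight"] == 1 for _, _, d in proj.graph.edges(data=True))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bip = random_bipartite(rng)
        proj = net.project_facilities(bip)
        oracle = pairwise_projection_oracle(bip)
        edges = {
            tuple(sorted((a, b))): d["weight"] for a, b, d in proj.graph.edges(data=True)
        }
        assert edges == oracle


class TestAffiliation:
    def test_isolated_single_and_triangle_multiple(self):
        facs = [make_snapshot(p) for p in "ABCD"]
        owners = [org_owner(p, "O LLC") for p in "ABC"]
        proj = net.project_facilities(net.build_bipartite(owners, facs, "H1", 1))
        classes = {c.provider_id: c for c in net.classify_affiliation(proj)}
        assert classes["D"].affiliation == "single" and classes["D"].degree == 0
        assert classes["A"].affiliation == "multiple" and classes["A"].degree == 2

    def test_fig2_style_fixture_counts(self, fig2_hrr):
        facs, owners = fig2_hrr
        proj = net.project_facilities(net.build_bipartite(owners, facs, "H1", 1))
        classes = net.classify_affiliation(proj)
        counts = {"single": 0, "multiple": 0}
        for c in classes:
            counts[c.affiliation] += 1
        assert counts == {"multiple": 8, "single": 6}


class TestGroups:
    def _proj(self, memberships):
        facs, owners = [], []
        for gi, members in enumerate(memberships):
            for p in members:
                facs.append(make_snapshot(p))
                owners.append(org_owner(p, f"G{gi} LLC"))
        return net.project_facilities(net.build_bipartite(owners, facs, "H1", 1))

    def test_two_dyads(self):
        groups = net.detect_ownership_groups(self._proj([["A", "B"], ["C", "D"]]))
        assert sorted(sorted(g.members) for g in groups) == [["A", "B"], ["C", "D"]]

    def test_five_clique(self):
        groups = net.detect_ownership_groups(self._proj([list("ABCDE")]))
        assert len(groups) == 1 and groups[0].size == 5

    def test_empty_projection(self):
        proj = net.project_facilities(net.build_bipartite([], [make_snapshot("A")], "H1", 1))
        assert net.detect_ownership_groups(proj) == []

    def test_groups_partition_multiple_affiliation_set(self, fig2_hrr):
        facs, owners = fig2_hrr
        proj = net.project_facilities(net.build_bipartite(owners, facs, "H1", 1))
        groups = net.detect_ownership_groups(proj)
        multi = {c.provider_id for c in net.classify_affiliation(proj) if c.degree >= 1}
        covered = set().union(*(g.members for g in groups))
        assert covered == multi
        assert sum(g.size for g in groups) == len(multi)
        assert all(g.size >= 2 for g in groups)

    def test_modularity_not_below_components_partition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            bip = random_bipartite(rng)
            proj = net.project_facilities(bip)
            linked = [n for n in proj.graph.nodes if proj.graph.degree(n) >= 1]
            if not linked:
                continue
            sub = proj.graph.subgraph(linked)
            groups = net.detect_ownership_groups(proj)
            q = net.partition_modularity(proj, groups)
            comp_q = nx.community.modularity(
                sub, list(nx.connected_components(sub)), weight="weight"
            )
            assert q >= comp_q - 1e-12

    def test_row_order_invariance(self, fig2_hrr):
        facs, owners = fig2_hrr
        rng = np.random.default_rng(0)
        baseline = None
        for _ in range(3):
            fs, ow = list(facs), list(owners)
            rng.shuffle(fs)
            rng.shuffle(ow)
            proj = net.project_facilities(net.build_bipartite(ow, fs, "H1", 1))
            groups = net.detect_ownership_groups(proj, seed=11)
            result = sorted(sorted(g.members) for g in groups)
            classes = sorted(
                (c.provider_id, c.affiliation) for c in net.classify_affiliation(proj)
            )
            if baseline is None:
                baseline = (result, classes)
            assert (result, classes) == baseline


class TestLouvainVersusExhaustive:
    def test_near_optimal_on_small_random_graphs(self):
        from oracles import detector_partition_modularity

        rng = np.random.default_rng(3)
        checked = 0
        while checked < 40:
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9), seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            best = max_modularity_partition(g)
            q = detector_partition_modularity(g)
            assert q >= 0.97 * best - 1e-9 if best > 0 else q >= best - 1e-9
            checked += 1

    def test_exact_partition_on_disconnected_cliques(self):
        for sizes in [(2, 2), (3, 4), (2, 3, 4), (5, 5)]:
            facs, owners = [], []
            offset = 0
            parts = []
            for gi, s in enumerate(sizes):
                members = [f"F{offset + k:02d}" for k in range(s)]
                for pid in members:
                    facs.append(make_snapshot(pid))
                    owners.append(org_owner(pid, f"CLIQUE {gi} LLC"))
                parts.append(set(members))
                offset += s
            proj = net.project_facilities(net.build_bipartite(owners, facs, "H1", 1))
            groups = net.detect_ownership_groups(proj)
            assert sorted(sorted(g.members) for g in groups) == sorted(
                map(sorted, parts)
            )
            best = max_modularity_partition(proj.graph)
            assert net.partition_modularity(proj, groups) == pytest.approx(
                best, abs=1e-12
            )


def test_count_coowning_organizations_hand_example():
    facs = [make_snapshot(p) for p in "AB"]
    owners = [
        org_owner("A", "O LLC"),
        org_owner("B", "O LLC"),
        org_owner("A", "P LLC"),
        org_owner("B", "Q LLC"),
    ]
    bip = net.build_bipartite(owners, facs, "H1", 1)
    groups = net.detect_ownership_groups(net.project_facilities(bip))
    assert net.count_coowning_organizations(bip, groups) == 3
    assert net.count_coowning_organizations(bip, []) == 0
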