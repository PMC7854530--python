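"""Per-HRR ownership networks: bipartite graphs, projection, communities.

Each hospital referral region (HRR) at each processing date yields a
two-mode graph whose levels are nursing home facilities and registered
organization owners, with an edge wherever an owner holds a facility.
Projecting onto facilities gives a one-mode graph in which two facilities
are tied iff they share at least one owner key; the edge weight is the
number of shared owners.  A facility with any tie has "multiple
affiliation" (super-organization); an isolated facility has "single
affiliation".  Ownership groups are communities of the multiple-affiliation
facilities found by Louvain modularity on the weighted projection.

Community detection runs on the one-mode projection (ownership groups are
groups of *facilities*); running Louvain on the bipartite graph itself is
the untaken alternative.  Determinism: Louvain local moves are randomized,
so the detector runs a fixed number of seeded restarts and keeps the
highest-modularity partition, with the connected-components and singleton
partitions always included as candidates.  That makes the reported
partition's modularity never worse than either baseline, and runs
reproducible for a given seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .nhc_io import FacilitySnapshot, OwnerRecord

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20160301
DEFAULT_RESOLUTION = 1.0
DEFAULT_RESTARTS = 5


@dataclass
class BipartiteGraph:
    """Two-mode facility/owner graph for one HRR at one date."""

    graph: nx.Graph
    hrr: str
    date: int

    @property
    def facility_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["level"] == "facility"}

    @property
    def owner_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["level"] == "owner"}


@dataclass
class FacilityProjection:
    """One-mode facility graph; edge weight = number of shared owner keys."""

    graph: nx.Graph
    hrr: str
    date: int

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass(frozen=True)
class AffiliationClass:
    provider_id: str
    affiliation: str  # "single" | "multiple"
    degree: int


@dataclass
class OwnershipGroup:
    group_id: int
    members: frozenset[str]
    hrr: str
    date: int

    @property
    def size(self) -> int:
        return len(self.members)


def _owner_node(key: str) -> str:
    # Owner keys live in the same node namespace as provider ids; prefix
    # guards against the (unlikely) collision of a legal name with an id.
    return f"owner::{key}"


def build_bipartite(
    owners: Sequence[OwnerRecord],
    facilities: Sequence[FacilitySnapshot],
    hrr: str,
    date: int,
) -> BipartiteGraph:
    """Assemble the two-mode graph for one HRR and date.

    ``owners`` must already be filtered to organization-kind records with
    normalized keys.  Facilities without any owner in the HRR remain as
    isolated facility nodes.  Owner records pointing at providers absent
    from the HRR snapshot are skipped (and counted in the log).
    """
    g = nx.Graph()
    fac_ids = set()
    for f in facilities:
        if f.hrr == hrr and f.date == date:
            g.add_node(f.provider_id, level="facility")
            fac_ids.add(f.provider_id)
    skipped = 0
    for r in owners:
        if r.date != date:
            continue
        if r.provider_id not in fac_ids:
            skipped += 1
            continue
        node = _owner_node(r.owner_key)
        g.add_node(node, level="owner")
        g.add_edge(r.provider_id, node)
    if skipped:
        logger.debug(
            "HRR %s date %s: skipped %d owner records for providers outside snapshot",
            hrr,
            date,
            skipped,
        )
    return BipartiteGraph(graph=g, hrr=hrr, date=date)


def project_facilities(bip: BipartiteGraph) -> FacilityProjection:
    """Project the two-mode graph onto facilities.

    Two facilities receive an edge with weight *w* iff they share exactly
    *w* owner keys.  All facility nodes are retained (isolates included).
    """
    proj = nx.Graph()
    proj.add_nodes_from(bip.facility_nodes)
    for owner in bip.owner_nodes:
        holders = sorted(bip.graph.neighbors(owner))
        for a, b in itertools.combinations(holders, 2):
            if proj.has_edge(a, b):
                proj[a][b]["weight"] += 1
            else:
                proj.add_edge(a, b, weight=1)
    return FacilityProjection(graph=proj, hrr=bip.hrr, date=bip.date)


def classify_affiliation(proj: FacilityProjection) -> list[AffiliationClass]:
    """Degree-based centrality and the single/multiple affiliation class.

    Degree counts *distinct* other facilities tied through at least one
    shared owner (unweighted); any tie at all means multiple affiliation.
    """
    out = []
    for node in sorted(proj.graph.nodes):
        deg = proj.graph.degree(node)
        out.append(
            AffiliationClass(
                provider_id=node,
                affiliation="multiple" if deg >= 1 else "single",
                degree=deg,
            )
        )
    return out


def _partition_modularity(g: nx.Graph, partition: Iterable[set]) -> float:
    return nx.community.modularity(g, partition, weight="weight")


def _modularity_matrix(g: nx.Graph, resolution: float):
    """Nodes, and the matrix B with Q(partition) = sum of within-block B."""
    import numpy as np

    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, d in g.edges(data=True):
        w = d.get("weight", 1)
        A[idx[a], idx[b]] += w
        A[idx[b], idx[a]] += w
    two_m = A.sum()
    k = A.sum(axis=1)
    B = (A - resolution * np.outer(k, k) / two_m) / two_m
    return nodes, B


def _label_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label tuples."""
    import numpy as np

    labels = np.zeros(n, dtype=np.int64)

    def rec(i, max_label):
        if i == n:
            yield labels
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    if n == 1:
        yield labels
    else:
        yield from rec(1, 0)


def _exact_component_partition(comp_nodes, node_index, B) -> list[set]:
    """Exhaustive maximum-modularity partition of one small component.

    Modularity is additive over connected components (merging blocks
    across components only subtracts degree products), so optimizing each
    component against the global modularity matrix yields the global
    optimum.
    """
    import numpy as np

    comp = sorted(comp_nodes)
    ids = [node_index[v] for v in comp]
    Bc = B[np.ix_(ids, ids)]
    best_q = -np.inf
    best_labels = None
    for labels in _label_partitions(len(comp)):
        same = labels[:, None] == labels[None, :]
        q = float(Bc[same].sum())
        if q > best_q:
            best_q = q
            best_labels = labels.copy()
    out: dict[int, set] = {}
    for v, lab in zip(comp, best_labels):
        out.setdefault(int(lab), set()).add(v)
    return list(out.values())


def best_partition(
    g: nx.Graph,
    seed: int = DEFAULT_SEED,
    resolution: float = DEFAULT_RESOLUTION,
    n_restarts: int = DEFAULT_RESTARTS,
    exact_max_size: int = 8,
) -> list[set]:
    """Community partition of a weighted graph, component by component.

    Connected components with up to ``exact_max_size`` nodes are solved
    exactly (exhaustive maximum-modularity search — ownership components
    are typically small near-cliques, where greedy local moves can miss
    shallow optima).  Larger components take the best of ``n_restarts``
    seeded Louvain runs, with the whole-component and all-singleton
    partitions as extra candidates.  Deterministic for a fixed seed.
    """
    import numpy as np

    if g.number_of_nodes() == 0:
        return []
    if g.number_of_edges() == 0:
        return [{v} for v in g.nodes]
    nodes, B = _modularity_matrix(g, resolution)
    node_index = {v: i for i, v in enumerate(nodes)}
    parts: list[set] = []
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            parts.append(set(comp))
        elif len(comp) <= exact_max_size:
            parts.extend(_exact_component_partition(comp, node_index, B))
        else:
            sub = g.subgraph(comp)
            candidates = [
                [set(c) for c in nx.community.louvain_communities(
                    sub, weight="weight", resolution=resolution, seed=seed + i
                )]
                for i in range(n_restarts)
            ]
            candidates.append([set(comp)])
            candidates.append([{v} for v in comp])

            def contribution(partition):
                q = 0.0
                for block in partition:
                    ids = [node_index[v] for v in block]
                    q += float(B[np.ix_(ids, ids)].sum())
                return q

            parts.extend(max(candidates, key=contribution))
    return parts


def detect_ownership_groups(
    proj: FacilityProjection,
    seed: int = DEFAULT_SEED,
    resolution: float = DEFAULT_RESOLUTION,
    n_restarts: int = DEFAULT_RESTARTS,
    exact_max_size: int = 8,
) -> list[OwnershipGroup]:
    """Community detection on the weighted facility projection.

    Only multiple-affiliation facilities (degree >= 1) can belong to a
    group; isolates are excluded up front.  The partition comes from
    :func:`best_partition` (exact modularity optimization for small
    components, best-of-restarts Louvain for large ones); its modularity
    is therefore never below the connected-components or all-singletons
    baselines.  Should the winning partition leave a connected node in a
    singleton community, that node is merged into the adjacent community
    with the largest total edge weight, so the returned groups (all of
    size >= 2) exactly partition the multiple-affiliation set.

    Deterministic for a fixed ``seed``; group ids are assigned by the
    sorted smallest member id.
    """
    linked = [n for n in proj.graph.nodes if proj.graph.degree(n) >= 1]
    if not linked:
        return []
    sub = proj.graph.subgraph(linked).copy()

    best = best_partition(
        sub,
        seed=seed,
        resolution=resolution,
        n_restarts=n_restarts,
        exact_max_size=exact_max_size,
    )

    # Repair singleton communities of connected nodes (possible in
    # principle for adversarial graphs, never for planted cliques).
    merged = [set(c) for c in best]
    changed = True
    while changed:
        changed = False
        for c in list(merged):
            if len(c) == 1:
                (node,) = c
                weights: dict[int, float] = {}
                for j, other in enumerate(merged):
                    if other is c:
                        continue
                    w = sum(
                        sub[node][nb].get("weight", 1)
                        for nb in sub.neighbors(node)
                        if nb in other
                    )
                    if w > 0:
                        weights[j] = w
                if weights:
                    target = max(sorted(weights), key=lambda j: weights[j])
                    merged[target] |= c
                    merged.remove(c)
                    changed = True
                    break

    groups = [c for c in merged if len(c) >= 2]
    groups.sort(key=lambda c: min(c))
    return [
        OwnershipGroup(group_id=i + 1, members=frozenset(c), hrr=proj.hrr, date=proj.date)
        for i, c in enumerate(groups)
    ]


def count_coowning_organizations(
    bip: BipartiteGraph, groups: Sequence[OwnershipGroup]
) -> int:
    """Distinct owner keys incident to at least one grouped facility.

    This is the "organization owners" tally of the HRR: every registered
    organization holding a facility that sits inside some ownership group,
    whether or not that particular owner is itself shared.
    """
    grouped = set().union(*(g.members for g in groups)) if groups else set()
    owners = set()
    for node in grouped:
        owners.update(
            nb for nb in bip.graph.neighbors(node)
            if bip.graph.nodes[nb]["level"] == "owner"
        )
    return len(owners)


def partition_modularity(proj: FacilityProjection, groups: Sequence[OwnershipGroup]) -> float:
    """Weighted modularity of the reported grouping on the linked subgraph.

    Ungrouped linked nodes (none, by construction) would count as
    singletons.
    """
    linked = [n for n in proj.graph.nodes if proj.graph.degree(n) >= 1]
    sub = proj.graph.subgraph(linked)
    covered = set().union(*(g.members for g in groups)) if groups else set()
    parts = [set(g.members) for g in groups]
    parts += [{n} for n in linked if n not in covered]
    if not parts:
        return 0.0
    return _partition_modularity(sub, parts)


# ---------------------------------------------------------------------------
# Exports


def export_graphml(bip: BipartiteGraph, proj: FacilityProjection, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b_path = out_dir / f"bipartite_hrr{bip.hrr}_d{bip.date}.graphml"
    p_path = out_dir / f"projection_hrr{proj.hrr}_d{proj.date}.graphml"
    nx.write_graphml(bip.graph, b_path)
    nx.write_graphml(proj.graph, p_path)
    return [b_path, p_path]


def affiliation_table(classes: Sequence[AffiliationClass], hrr: str, date: int):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "provider_id": c.provider_id,
                "hrr": hrr,
                "date": date,
                "affiliation": c.affiliation,
                "degree": c.degree,
            }
            for c in classes
        ]
    )


def groups_table(groups: Sequence[OwnershipGroup]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "hrr": g.hrr,
                "date": g.date,
                "size": g.size,
                "members": ";".join(sorted(g.members)),
            }
            for g in groups
        ]
    )
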