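"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the projection oracle
counts shared owners pairwise instead of iterating owners, and the
modularity oracle enumerates every set partition instead of running any
community-detection heuristic.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def pairwise_projection_oracle(bip) -> dict[tuple[str, str], int]:
    """Shared-owner count for every facility pair, by direct enumeration."""
    g = bip.graph
    facs = sorted(bip.facility_nodes)
    owners_of = {
        f: {nb for nb in g.neighbors(f) if g.nodes[nb]["level"] == "owner"}
        for f in facs
    }
    out = {}
    for a, b in itertools.combinations(facs, 2):
        w = len(owners_of[a] & owners_of[b])
        if w:
            out[(a, b)] = w
    return out


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n > 1 else iter([labels.copy()])


def max_modularity_partition(g: nx.Graph) -> float:
    """Exhaustive maximum weighted modularity over all set partitions."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for a, b, d in g.edges(data=True):
        w = d.get("weight", 1)
        A[idx[a], idx[b]] += w
        A[idx[b], idx[a]] += w
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    B = (A - np.outer(k, k) / two_m) / two_m
    best = -np.inf
    for labels in set_partitions(n):
        same = labels[:, None] == labels[None, :]
        q = float(B[same].sum())
        if q > best:
            best = q
    return best


def detector_partition_modularity(g: nx.Graph) -> float:
    """Modularity achieved by the package's community partition on any graph."""
    from nhnet.ownership_network import best_partition

    parts = best_partition(g)
    if g.number_of_edges() == 0:
        return 0.0
    return nx.community.modularity(g, parts, weight="weight")


def random_bipartite(rng: np.random.Generator, max_fac: int = 12, max_own: int = 8):
    """A random two-mode graph in the package's own container."""
    from nhnet.nhc_io import FacilitySnapshot, OwnerRecord
    from nhnet.ownership_network import build_bipartite

    n_fac = int(rng.integers(2, max_fac + 1))
    n_own = int(rng.integers(1, max_own + 1))
    facs = [
        FacilitySnapshot(provider_id=f"F{i:03d}", date=1, zip="00000", state="AA", hrr="H1")
        for i in range(n_fac)
    ]
    owners = []
    p_edge = rng.uniform(0.1, 0.5)
    for j in range(n_own):
        key = f"OWNER {j} LLC"
        for f in facs:
            if rng.uniform() < p_edge:
                owners.append(
                    OwnerRecord(
                        provider_id=f.provider_id,
                        owner_name_raw=key,
                        owner_key=key,
                        owner_kind="organization",
                        date=1,
                    )
                )
    return build_bipartite(owners, facs, "H1", 1)
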