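"""Cross-site cluster repertoire comparison.

Sites are compared by their cluster consensuses: greedy one-to-one matching of
equal-length consensuses within a Hamming tolerance gives pairwise match
edges; Venn regions come from the transitive closure of those edges. Also:
abundance concentration (smallest cluster fraction holding a target share of
spacers) and self-complementary consensus detection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .cluster import SpacerCluster
from .seqs import hamming, revcomp


@dataclass(frozen=True)
class MatchEdge:
    site_a: str
    idx_a: int
    site_b: str
    idx_b: int
    distance: int


@dataclass
class SharingReport:
    sites: Tuple[str, ...]
    region_components: Dict[frozenset, int]        # site-set -> number of components
    region_clusters: Dict[frozenset, Dict[str, int]]  # site-set -> per-site cluster counts
    percent_unique: Dict[str, float]
    pairwise_shared_percent: Dict[Tuple[str, str], float]
    edges: List[MatchEdge] = field(default_factory=list)

    def common_to_all(self) -> int:
        return self.region_components.get(frozenset(self.sites), 0)

    def to_json_dict(self) -> dict:
        return {
            "sites": list(self.sites),
            "region_components": {"+".join(sorted(k)): v
                                  for k, v in sorted(self.region_components.items(),
                                                     key=lambda kv: sorted(kv[0]))},
            "region_clusters": {"+".join(sorted(k)): dict(sorted(v.items()))
                                for k, v in sorted(self.region_clusters.items(),
                                                   key=lambda kv: sorted(kv[0]))},
            "percent_unique": dict(sorted(self.percent_unique.items())),
            "pairwise_shared_percent": {f"{a}->{b}": p for (a, b), p in
                                        sorted(self.pairwise_shared_percent.items())},
        }


def match_clusters(a: Sequence[SpacerCluster], b: Sequence[SpacerCluster],
                   max_mismatch: int = 5) -> List[MatchEdge]:
    """Greedy one-to-one matching of equal-length consensuses.

    Candidate pairs within ``max_mismatch`` are taken by ascending Hamming
    distance, ties to the higher combined abundance, then to the
    lexicographically smaller (unordered) consensus pair, so
    ``match_clusters(a, b)`` and ``match_clusters(b, a)`` yield the same edges.
    """
    candidates = []
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            if len(ca.consensus) != len(cb.consensus):
                continue
            d = hamming(ca.consensus, cb.consensus)
            if d <= max_mismatch:
                pair_key = tuple(sorted((ca.consensus, cb.consensus)))
                candidates.append((d, -(ca.abundance + cb.abundance), pair_key, i, j))
    candidates.sort()
    used_a, used_b = set(), set()
    edges = []
    site_a = a[0].site if a else ""
    site_b = b[0].site if b else ""
    for d, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        edges.append(MatchEdge(site_a, i, site_b, j, d))
    return edges


def venn_counts(clusterings: Dict[str, Sequence[SpacerCluster]],
                max_mismatch: int = 5) -> SharingReport:
    """Venn-region accounting over 2-4 sites via transitive closure of match edges.

    A cluster belongs to the region given by the set of sites its connected
    component spans; ``region_components`` counts components (the Venn-diagram
    numbers), ``region_clusters`` counts clusters per site so per-site totals
    are conserved exactly.
    """
    sites = tuple(sorted(clusterings))
    if not 2 <= len(sites) <= 4:
        raise ValueError("venn_counts supports 2-4 sites")

    # union-find over (site, index) nodes
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for s in sites:
        for i in range(len(clusterings[s])):
            parent[(s, i)] = (s, i)
    all_edges: List[MatchEdge] = []
    for ai in range(len(sites)):
        for bi in range(ai + 1, len(sites)):
            sa, sb = sites[ai], sites[bi]
            edges = match_clusters(clusterings[sa], clusterings[sb], max_mismatch)
            all_edges.extend(edges)
            for e in edges:
                union((sa, e.idx_a), (sb, e.idx_b))

    components: dict = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    region_components: Dict[frozenset, int] = {}
    region_clusters: Dict[frozenset, Dict[str, int]] = {}
    unique_count = {s: 0 for s in sites}
    shared_with = {(a, b): 0 for a in sites for b in sites if a != b}
    for nodes in components.values():
        span = frozenset(s for s, _ in nodes)
        region_components[span] = region_components.get(span, 0) + 1
        per_site = region_clusters.setdefault(span, {s: 0 for s in span})
        for s, _ in nodes:
            per_site[s] += 1
        if len(span) == 1:
            (only,) = span
            unique_count[only] += len(nodes)
        for s, _ in nodes:
            for t in span:
                if t != s:
                    shared_with[(s, t)] += 1

    totals = {s: len(clusterings[s]) for s in sites}
    percent_unique = {s: 100.0 * unique_count[s] / totals[s] if totals[s] else 0.0
                      for s in sites}
    pairwise = {(a, b): 100.0 * n / totals[a] if totals[a] else 0.0
                for (a, b), n in shared_with.items()}
    return SharingReport(sites=sites, region_components=region_components,
                         region_clusters=region_clusters,
                         percent_unique=percent_unique,
                         pairwise_shared_percent=pairwise, edges=all_edges)


def abundance_concentration(clusters: Sequence[SpacerCluster], q: float = 0.95) -> float:
    """Percent of clusters (smallest prefix by descending abundance) holding
    at least a ``q`` share of all spacers."""
    if not clusters:
        raise ValueError("empty cluster list")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    order = sorted(clusters, key=lambda c: (-c.abundance, c.consensus))
    total = sum(c.abundance for c in order)
    cum = 0
    for k, c in enumerate(order, start=1):
        cum += c.abundance
        if cum / total >= q - 1e-12:
            return 100.0 * k / len(order)
    return 100.0


@dataclass(frozen=True)
class ComplementPair:
    idx_a: int
    idx_b: int
    consensus_a: str
    consensus_b: str
    abundance_a: int
    abundance_b: int
    distance: int

    @property
    def palindromic(self) -> bool:
        return self.idx_a == self.idx_b


def self_complementary_pairs(clusters: Sequence[SpacerCluster],
                             max_mismatch: int = 0) -> List[ComplementPair]:
    """Cluster pairs (i <= j) whose consensuses are reverse complements within
    ``max_mismatch``; i == j flags a palindromic consensus."""
    out = []
    for i, ca in enumerate(clusters):
        rc = revcomp(ca.consensus)
        for j in range(i, len(clusters)):
            cb = clusters[j]
            if len(cb.consensus) != len(rc):
                continue
            d = hamming(rc, cb.consensus)
            if d <= max_mismatch:
                out.append(ComplementPair(i, j, ca.consensus, cb.consensus,
                                          ca.abundance, cb.abundance, d))
    return out
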