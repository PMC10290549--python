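"""Molecular cluster graphs: BNGL complex strings <-> graphs, summaries, fixtures.

A cluster is a connected molecular network: nodes are individual multivalent
molecules, edges are site--site bonds.  The degree of a node is the number of
bonds engaging that molecule; a molecule's degree can never exceed its
valence.  The cluster-level bound fraction (BF) is the ratio of bound sites
(two per bond) to total sites present in the cluster; the per-molecule bound
fraction is the occupied fraction of one molecule's own sites.

The built-in simulator only produces tree-shaped clusters (bonds = size - 1),
but the read side tolerates cyclic complexes such as those emitted by
external network-free simulators; non-tree clusters are flagged in their
summaries.
"""

from __future__ import annotations

import re
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np

from .model_io import BnglError, ModelSpec

__all__ = [
    "MoleculeNode",
    "Bond",
    "ClusterGraph",
    "ClusterSummary",
    "parse_complex",
    "emit_complex",
    "summarize",
    "molecule_bound_fraction",
    "generate_synthetic_clusters",
    "summaries_from_species",
]

_MOL_RE = re.compile(r"([A-Za-z_]\w*)\(([^()]*)\)")
_SITE_RE = re.compile(r"^([A-Za-z_]\w*)(?:!(\d+))?$")


@dataclass
class MoleculeNode:
    """One molecule instance.

    ``occupancy`` maps every declared site (in declared order) to either
    ``None`` (free) or the integer id of the bond occupying it.  Insertion
    order of ``occupancy`` is the declared site order of the molecule type;
    all constructors in this package maintain that invariant, and canonical
    string emission relies on it.
    """

    id: int
    type_name: str
    occupancy: dict[str, Optional[int]]

    @property
    def valence(self) -> int:
        return len(self.occupancy)

    @property
    def degree(self) -> int:
        return sum(1 for b in self.occupancy.values() if b is not None)


@dataclass(frozen=True)
class Bond:
    """A site--site bond between two molecules, optionally tagged by rule name."""

    a: tuple[int, str]  # (node id, site name)
    b: tuple[int, str]
    rule: Optional[str] = None


@dataclass
class ClusterGraph:
    """One connected molecular network.

    Bond ids are indices into ``edges``; each bond id appears on exactly one
    site of each of its two endpoint nodes.
    """

    nodes: list[MoleculeNode]
    edges: list[Bond]

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def is_tree(self) -> bool:
        return len(self.edges) == len(self.nodes) - 1

    def node(self, node_id: int) -> MoleculeNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, type_name=n.type_name)
        for i, e in enumerate(self.edges):
            g.add_edge(e.a[0], e.b[0], key=i, sites=(e.a[1], e.b[1]), rule=e.rule)
        return g

    def validate(self) -> None:
        """Check structural well-formedness; raises ``BnglError`` on violation."""
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise BnglError("duplicate node ids in cluster")
        by_id = {n.id: n for n in self.nodes}
        seen: dict[int, list[tuple[int, str]]] = {}
        for n in self.nodes:
            for site, b in n.occupancy.items():
                if b is not None:
                    seen.setdefault(b, []).append((n.id, site))
        for i, e in enumerate(self.edges):
            ends = seen.get(i, [])
            if sorted(ends) != sorted([e.a, e.b]):
                raise BnglError(f"bond {i} endpoints inconsistent with occupancy")
            for nid, site in (e.a, e.b):
                if nid not in by_id or site not in by_id[nid].occupancy:
                    raise BnglError(f"bond {i} references unknown node/site")
        if len(seen) != len(self.edges):
            raise BnglError("occupancy references a bond id with no edge")
        if self.nodes and not nx.is_connected(nx.Graph(self.to_networkx())):
            raise BnglError("cluster graph is not connected")


@dataclass
class ClusterSummary:
    """Per-cluster statistics record.

    ``bound_sites`` counts two sites per bond; ``bound_fraction`` is
    bound_sites / total_sites.  ``degree_by_node`` maps node id to its bond
    count and ``node_types`` maps node id to its molecule type, so per-type
    degree statistics can be pooled without keeping the full graphs around.
    """

    size: int
    type_counts: dict[str, int]
    n_bonds: int
    total_sites: int
    bound_sites: int
    bound_fraction: float
    degree_by_node: dict[int, int]
    node_types: dict[int, str]
    is_tree: bool


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_complex(string: str, model: ModelSpec) -> list[ClusterGraph]:
    """Parse a BNGL complex string into one ClusterGraph per connected component.

    Molecules are dot-separated ``Type(site, site!label, ...)`` terms listing
    every declared site; each bond label must occur exactly twice across the
    whole string.  A well-formed complex string yields exactly one cluster,
    but disconnected strings are tolerated and split.
    """
    s = string.strip()
    if not s:
        raise BnglError("empty complex string")
    by_name = {mt.name: mt for mt in model.molecule_types}

    # tokenize: the grammar has no nesting, so splitting on '.' is safe
    mol_tokens = [tok.strip() for tok in s.split(".")]
    nodes: list[MoleculeNode] = []
    label_sites: dict[int, list[tuple[int, str]]] = {}
    for nid, tok in enumerate(mol_tokens):
        m = _MOL_RE.fullmatch(tok)
        if not m:
            raise BnglError(f"malformed molecule term {tok!r}")
        name, body = m.group(1), m.group(2)
        if name not in by_name:
            raise BnglError(f"undeclared molecule {name!r}")
        mt = by_name[name]
        listed: dict[str, Optional[int]] = {}
        if body.strip():
            for part in body.split(","):
                sm = _SITE_RE.match(part.strip())
                if not sm:
                    raise BnglError(f"malformed site term {part.strip()!r} in {tok!r}")
                site, label = sm.group(1), sm.group(2)
                if site not in mt.sites:
                    raise BnglError(f"undeclared site {site!r} on {name!r}")
                if site in listed:
                    raise BnglError(f"site {site!r} listed twice in {tok!r}")
                listed[site] = int(label) if label is not None else None
        if set(listed) != set(mt.sites):
            raise BnglError(
                f"molecule term {tok!r} must list all declared sites of {name!r}"
            )
        occupancy = {site: listed[site] for site in mt.sites}  # declared order
        for site, label in occupancy.items():
            if label is not None:
                label_sites.setdefault(label, []).append((nid, site))
        nodes.append(MoleculeNode(nid, name, occupancy))

    edges: list[Bond] = []
    label_to_bond: dict[int, int] = {}
    rule_lookup = {
        frozenset(((r.site_a[0], r.site_a[1]), (r.site_b[0], r.site_b[1]))): r.name
        for r in model.rules
    }
    for label in sorted(label_sites):
        ends = label_sites[label]
        if len(ends) == 1:
            raise BnglError(f"dangling bond label !{label} (occurs once)")
        if len(ends) > 2:
            raise BnglError(f"bond label !{label} occurs {len(ends)} times")
        (na, sa), (nb, sb) = ends
        key = frozenset(((nodes[na].type_name, sa), (nodes[nb].type_name, sb)))
        label_to_bond[label] = len(edges)
        edges.append(Bond((na, sa), (nb, sb), rule=rule_lookup.get(key)))
    # re-key occupancy from labels to bond ids
    for n in nodes:
        for site, label in n.occupancy.items():
            if label is not None:
                n.occupancy[site] = label_to_bond[label]

    # split into connected components
    g = nx.MultiGraph()
    g.add_nodes_from(range(len(nodes)))
    for i, e in enumerate(edges):
        g.add_edge(e.a[0], e.b[0], key=i)
    clusters: list[ClusterGraph] = []
    for comp in sorted(nx.connected_components(g), key=min):
        comp_nodes = [nodes[i] for i in sorted(comp)]
        bond_ids = sorted({b for n in comp_nodes for b in n.occupancy.values() if b is not None})
        remap = {old: new for new, old in enumerate(bond_ids)}
        comp_edges = [edges[old] for old in bond_ids]
        for n in comp_nodes:
            for site, b in n.occupancy.items():
                if b is not None:
                    n.occupancy[site] = remap[b]
        clusters.append(ClusterGraph(comp_nodes, comp_edges))
    return clusters


# ---------------------------------------------------------------------------
# canonical emission
# ---------------------------------------------------------------------------


def _adjacency(cluster: ClusterGraph) -> dict[int, list[tuple[str, int, int]]]:
    """node id -> list of (site on node, bond id, neighbour id), declared site order."""
    other = {}
    for i, e in enumerate(cluster.edges):
        other[(i, e.a[0], e.a[1])] = e.b[0]
        other[(i, e.b[0], e.b[1])] = e.a[0]
    adj: dict[int, list[tuple[str, int, int]]] = {}
    for n in cluster.nodes:
        lst = []
        for site, b in n.occupancy.items():
            if b is not None:
                lst.append((site, b, other[(b, n.id, site)]))
        adj[n.id] = lst
    return adj


def _tree_centers(cluster: ClusterGraph, adj) -> list[int]:
    degree = {n.id: len(adj[n.id]) for n in cluster.nodes}
    remaining = set(degree)
    leaves = deque(sorted(i for i, d in degree.items() if d <= 1))
    n_left = len(remaining)
    while n_left > 2:
        next_leaves = []
        for _ in range(len(leaves)):
            leaf = leaves.popleft()
            remaining.discard(leaf)
            n_left -= 1
            for _, _, nb in adj[leaf]:
                if nb in remaining:
                    degree[nb] -= 1
                    if degree[nb] == 1:
                        next_leaves.append(nb)
        leaves.extend(sorted(next_leaves))
    return sorted(remaining)


def _emit_from(cluster: ClusterGraph, root: int) -> str:
    """Deterministic DFS emission from a chosen root.

    Children are visited in the declared site order of each node, which is
    unambiguous because a site holds at most one bond.  Bond labels are
    assigned in order of first appearance in the emitted string.  Works for
    cyclic clusters too (visited nodes are not re-entered, but their bonds
    still print the shared label).
    """
    by_id = {n.id: n for n in cluster.nodes}
    adj = _adjacency(cluster)
    labels: dict[int, int] = {}
    parts: list[str] = []
    visited: set[int] = set()
    stack = [root]
    while stack:
        nid = stack.pop()
        if nid in visited:
            continue
        visited.add(nid)
        node = by_id[nid]
        site_strs = []
        for site, b in node.occupancy.items():
            if b is None:
                site_strs.append(site)
            else:
                if b not in labels:
                    labels[b] = len(labels) + 1
                site_strs.append(f"{site}!{labels[b]}")
        parts.append(f"{node.type_name}({','.join(site_strs)})")
        # push children in reverse declared-site order so they pop in order
        for site, b, nb in reversed(adj[nid]):
            if nb not in visited:
                stack.append(nb)
    return ".".join(parts)


_MAX_EXHAUSTIVE_ROOTS = 200


def emit_complex(cluster: ClusterGraph) -> str:
    """Emit a canonical BNGL complex string.

    Trees (the only shape the built-in simulator produces) are canonicalized
    exactly: the traversal is rooted at the tree center (comparing the two
    candidate strings when the center is an edge), so any node ordering of
    the same tree yields the identical string.  Cyclic clusters are emitted
    deterministically by taking the lexicographically smallest emission over
    all roots (over the first node only for very large cyclic clusters, where
    only exact-string duplicate detection is claimed).
    """
    if not cluster.nodes:
        raise BnglError("cannot emit an empty cluster")
    if cluster.is_tree:
        adj = _adjacency(cluster)
        roots = _tree_centers(cluster, adj)
    elif cluster.size <= _MAX_EXHAUSTIVE_ROOTS:
        roots = [n.id for n in cluster.nodes]
    else:
        roots = [min(n.id for n in cluster.nodes)]
    return min(_emit_from(cluster, r) for r in roots)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(cluster: ClusterGraph) -> ClusterSummary:
    """Summarize one cluster: size, composition, bonds, degrees, bound fraction."""
    if not cluster.nodes:
        raise BnglError("cannot summarize an empty cluster")
    size = cluster.size
    n_bonds = len(cluster.edges)
    total_sites = sum(n.valence for n in cluster.nodes)
    bound_sites = 2 * n_bonds
    return ClusterSummary(
        size=size,
        type_counts=dict(Counter(n.type_name for n in cluster.nodes)),
        n_bonds=n_bonds,
        total_sites=total_sites,
        bound_sites=bound_sites,
        bound_fraction=bound_sites / total_sites,
        degree_by_node={n.id: n.degree for n in cluster.nodes},
        node_types={n.id: n.type_name for n in cluster.nodes},
        is_tree=cluster.is_tree,
    )


def molecule_bound_fraction(node: MoleculeNode, model: ModelSpec | None = None) -> float:
    """Per-molecule bound fraction: occupied sites over the molecule's valence."""
    if model is not None and set(node.occupancy) != set(model.molecule(node.type_name).sites):
        raise BnglError(
            f"node occupancy does not cover declared sites of {node.type_name!r}"
        )
    return node.degree / node.valence


def summaries_from_species(
    entries: Iterable[tuple[str, int]], model: ModelSpec
) -> list[ClusterSummary]:
    """Expand ``(complex string, count)`` entries into per-cluster summaries."""
    out: list[ClusterSummary] = []
    for spec, count in entries:
        for cluster in parse_complex(spec, model):
            summ = summarize(cluster)
            out.extend([summ] * count)
    return out


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


def generate_synthetic_clusters(
    size_spectrum: Mapping[int, int], model: ModelSpec, seed: int
) -> list[ClusterGraph]:
    """Assemble random rule-respecting tree clusters with prescribed sizes.

    ``size_spectrum`` maps cluster size to the number of clusters wanted at
    that size.  Each cluster is grown by uniformly random attachment: pick a
    free site on the current tree that participates in some binding rule,
    pick a compatible rule endpoint, and attach a fresh molecule of the
    partner type through it.  Reproducible for a fixed seed.  Raises
    ``BnglError`` when a requested size is unreachable under the model's
    rules (e.g. any size > 2 when every type has a single site).
    """
    rng = np.random.default_rng(seed)
    # endpoint -> list of partner endpoints, in rule order
    partners: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for r in model.rules:
        partners.setdefault(r.site_a, []).append(r.site_b)
        if not r.is_symmetric:
            partners.setdefault(r.site_b, []).append(r.site_a)
    connectable_types = sorted({mol for (mol, _site) in partners})
    all_types = [mt.name for mt in model.molecule_types]

    def fresh_node(nid: int, type_name: str) -> MoleculeNode:
        mt = model.molecule(type_name)
        return MoleculeNode(nid, type_name, {s: None for s in mt.sites})

    def try_build(size: int) -> ClusterGraph | None:
        if size == 1:
            start = all_types[rng.integers(len(all_types))]
            return ClusterGraph([fresh_node(0, start)], [])
        if not connectable_types:
            return None
        start = connectable_types[rng.integers(len(connectable_types))]
        nodes = [fresh_node(0, start)]
        edges: list[Bond] = []
        while len(nodes) < size:
            options = [
                (n.id, site, partner)
                for n in nodes
                for site, b in n.occupancy.items()
                if b is None
                for partner in partners.get((n.type_name, site), ())
            ]
            if not options:
                return None
            nid, site, (ptype, psite) = options[rng.integers(len(options))]
            new = fresh_node(len(nodes), ptype)
            bond_id = len(edges)
            nodes[nid].occupancy[site] = bond_id
            new.occupancy[psite] = bond_id
            edges.append(Bond((nid, site), (new.id, psite)))
            nodes.append(new)
        return ClusterGraph(nodes, edges)

    clusters: list[ClusterGraph] = []
    for size in sorted(size_spectrum):
        count = size_spectrum[size]
        if size < 1:
            raise BnglError(f"cluster size must be >= 1, got {size}")
        if count < 0:
            raise BnglError(f"cluster count must be >= 0, got {count}")
        for _ in range(count):
            built = None
            for _attempt in range(50):
                built = try_build(size)
                if built is not None:
                    break
            if built is None:
                raise BnglError(
                    f"cluster size {size} unreachable under the model's binding rules"
                )
            clusters.append(built)
    return clusters
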