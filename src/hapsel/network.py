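"""Statistical-parsimony haplotype network construction and mutation
classification.

The network connects observed haplotypes by single-mutation edges, inserting
inferred (unsampled) intermediate haplotypes where observed sequences differ
at more than one site, up to the number of steps justified by the
probability-of-parsimony criterion.  After rooting against an outgroup, each
edge becomes a polarized mutation that is classified synonymous or
nonsynonymous from its ancestral codon context and as *tip* (the derived side
contains exactly one observed haplotype) or *interior*.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx

from .codons import SubstitutionClass, classify_substitution
from .seqdata import HaplotypeSet, Region


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    kind: str  # "observed" | "inferred"
    seq: str
    count: int = 0
    hap_id: str | None = None


@dataclass
class MutationRecord:
    edge: tuple[str, str]  # (ancestral node, derived node)
    site: int  # 1-based nt position
    codon_index: int | None
    allele_from: str
    allele_to: str
    subst_class: SubstitutionClass
    position_class: str  # "tip" | "interior"
    derived_observed_count: int  # distinct observed haplotypes on derived side
    region: str = ""
    label: str = ""


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    nodes: dict[str, NetworkNode]
    frame_offset: int = 0
    root: str | None = None
    ambiguous_edges: set[frozenset] = field(default_factory=set)

    @property
    def observed_ids(self) -> list[str]:
        return [k for k, v in self.nodes.items() if v.kind == "observed"]

    def edge_list(self):
        for a, b, data in self.graph.edges(data=True):
            yield a, b, data


# ---------------------------------------------------------------------------
# parsimony connection limit
# ---------------------------------------------------------------------------
def parsimony_probability(j: int, L: int) -> float:
    """Probability that *j* observed differences over *L* sites all arose as
    single hits.

    Per-site change counts are modelled as Poisson; the rate is fitted to the
    observed proportion of differing sites p = j/L through p = 1 - exp(-lam).
    A differing site then changed exactly once with probability
    lam*exp(-lam)/(1 - exp(-lam)), and the j differences are treated as
    independent.
    """
    if j <= 0:
        return 1.0
    if j >= L:
        return 0.0
    p = j / L
    lam = -math.log1p(-p)
    single = lam * math.exp(-lam) / p
    return single**j


def parsimony_limit(L: int, q: float = 0.95, max_steps: int | None = None) -> int:
    """Largest number of steps whose probability of parsimony is >= q.

    ``max_steps`` acts as an explicit user override: when given it is
    returned unchanged.
    """
    if max_steps is not None:
        return max_steps
    if L <= 0:
        raise ValueError("alignment length must be positive")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    j = 0
    while j + 1 < L and parsimony_probability(j + 1, L) >= q:
        j += 1
    return max(j, 1)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------
def _hamming_detail(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def build_network(hs: HaplotypeSet, limit: int, frame_offset: int = 0) -> HaplotypeNetwork:
    """TCS-style agglomerative network.

    All distance-1 node pairs are joined first (an edge that closes a cycle
    is retained and flagged ambiguous).  Components are then merged in order
    of increasing distance, always through the closest pair of *current*
    nodes - observed haplotypes or previously inferred intermediates - so
    chains attach to median-like intermediates instead of spanning full
    haplotype-to-haplotype paths.  A merge at distance d instantiates d-1
    inferred nodes (sites mutated in ascending position order); each new
    intermediate immediately participates in the next round, and distance-1
    adjacencies it creates are added before further merging.  Components
    farther than ``limit`` steps apart stay unconnected.  Tie-breaking is
    deterministic (distance, then node id), so the result is independent of
    input order.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    import numpy as np

    haps = sorted(hs.haplotypes, key=lambda h: (-h.count, h.seq))
    L = len(haps[0].seq)
    if any(len(h.seq) != L for h in haps):
        raise ValueError("haplotype sequences have unequal lengths")

    g = nx.Graph()
    nodes: dict[str, NetworkNode] = {}
    order: list[str] = []  # deterministic node ordering
    rows: list[np.ndarray] = []
    dist_rows: list[np.ndarray] = []  # lower-triangular distance rows
    by_seq: dict[str, str] = {}
    ambiguous: set[frozenset] = set()
    n_inferred = 0

    def _add_node(node: NetworkNode) -> None:
        row = np.frombuffer(node.seq.encode(), dtype=np.uint8)
        if rows:
            dist_rows.append((np.vstack(rows) != row).sum(axis=1))
        else:
            dist_rows.append(np.zeros(0, dtype=np.int64))
        nodes[node.node_id] = node
        order.append(node.node_id)
        rows.append(row)
        by_seq[node.seq] = node.node_id
        g.add_node(node.node_id)

    def _dist(i: int, j: int) -> int:
        if i == j:
            return 0
        lo, hi = (i, j) if i < j else (j, i)
        return int(dist_rows[hi][lo])

    def _add_edge(a: str, b: str) -> None:
        diff = _hamming_detail(nodes[a].seq, nodes[b].seq)
        site = diff[0]
        closes_cycle = nx.has_path(g, a, b)
        g.add_edge(
            a, b, site=site + 1, allele_a=nodes[a].seq[site], allele_b=nodes[b].seq[site]
        )
        if closes_cycle:
            ambiguous.add(frozenset((a, b)))

    def _connect_singles() -> None:
        for j in range(len(order)):
            hits = np.nonzero(dist_rows[j] == 1)[0]
            for i in hits:
                a, b = order[int(i)], order[j]
                if not g.has_edge(a, b):
                    _add_edge(a, b)

    for h in haps:
        _add_node(NetworkNode(h.hap_id, "observed", h.seq, h.count, h.hap_id))
    _connect_singles()

    while True:
        comp_of: dict[str, int] = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for k in comp:
                comp_of[k] = ci
        best = None
        for j in range(1, len(order)):
            dj = dist_rows[j]
            cj = comp_of[order[j]]
            for i in np.nonzero((dj >= 2) & (dj <= limit))[0]:
                if comp_of[order[int(i)]] == cj:
                    continue
                key = (int(dj[int(i)]), order[int(i)], order[j])
                if best is None or key < best:
                    best = key
        if best is None:
            break
        d, a, b = best
        cur_id, cur_seq = a, nodes[a].seq
        diff = sorted(_hamming_detail(nodes[a].seq, nodes[b].seq))
        for step, site in enumerate(diff):
            nxt_seq = cur_seq[:site] + nodes[b].seq[site] + cur_seq[site + 1 :]
            if step == d - 1:
                nxt_id = b
            elif nxt_seq in by_seq:
                nxt_id = by_seq[nxt_seq]
            else:
                n_inferred += 1
                nxt_id = f"i{n_inferred}"
                _add_node(NetworkNode(nxt_id, "inferred", nxt_seq, 0))
            if not g.has_edge(cur_id, nxt_id):
                _add_edge(cur_id, nxt_id)
            cur_id, cur_seq = nxt_id, nxt_seq
        _connect_singles()
    return HaplotypeNetwork(g, nodes, frame_offset=frame_offset, ambiguous_edges=ambiguous)


# ---------------------------------------------------------------------------
# rooting / polarization
# ---------------------------------------------------------------------------
def polarize(net: HaplotypeNetwork, outgroup_seq: str) -> HaplotypeNetwork:
    """Root the network at the observed haplotype closest to the outgroup.

    Ties prefer the higher-count haplotype, then the lexicographically
    smaller id.  Every bridge edge gets an ancestral->derived orientation
    away from the root; edges inside loops cannot be oriented and are flagged
    ambiguous.
    """
    obs = [net.nodes[k] for k in net.observed_ids]
    if len(outgroup_seq) != len(obs[0].seq):
        raise ValueError("outgroup not aligned to haplotype length")

    def dist(node: NetworkNode) -> int:
        return sum(1 for x, y in zip(node.seq, outgroup_seq) if x != y)

    root = min(obs, key=lambda h: (dist(h), -h.count, h.node_id)).node_id
    net.root = root
    bridges = set(frozenset(e) for e in nx.bridges(net.graph))
    for a, b, data in net.graph.edges(data=True):
        e = frozenset((a, b))
        if e not in bridges:
            data["parent"] = None
            data["child"] = None
            net.ambiguous_edges.add(e)
            continue
        # the side not containing the root is derived
        h = net.graph.copy()
        h.remove_edge(a, b)
        if nx.has_path(h, root, a):
            data["parent"], data["child"] = a, b
        else:
            data["parent"], data["child"] = b, a
    return net


# ---------------------------------------------------------------------------
# mutation classification
# ---------------------------------------------------------------------------
def classify_mutations(
    net: HaplotypeNetwork, regions: list[Region] | None = None
) -> list[MutationRecord]:
    """One MutationRecord per oriented edge.

    The codon context comes from the ancestral node's full sequence; the
    derived codon is that codon with the edge's single site changed, so
    successive mutations within one codon along a path are classified
    sequentially.  Tip status asks whether the derived-side component
    contains exactly one *observed* haplotype (inferred intermediates never
    count).
    """
    if net.root is None:
        raise ValueError("network must be polarized before classifying mutations")
    regions = regions or []
    records: list[MutationRecord] = []
    label_iter = _labels()
    for a, b, data in net.graph.edges(data=True):
        if data.get("parent") is None:
            continue
        parent, child = data["parent"], data["child"]
        site = data["site"]  # 1-based
        pseq = net.nodes[parent].seq
        ci = _codon_index(site, net.frame_offset, len(pseq))
        if ci is None:
            subst = SubstitutionClass.AMBIGUOUS
            cfrom = cto = ""
        else:
            a0 = net.frame_offset + 3 * ci
            cfrom = pseq[a0 : a0 + 3]
            cto = cfrom[: site - 1 - a0] + net.nodes[child].seq[site - 1] + cfrom[site - a0 :]
            if set(cfrom + cto) <= set("ACGT"):
                subst = classify_substitution(cfrom, cto)
            else:
                subst = SubstitutionClass.AMBIGUOUS
        h = net.graph.copy()
        h.remove_edge(a, b)
        derived_side = nx.node_connected_component(h, child)
        derived_obs = sum(1 for k in derived_side if net.nodes[k].kind == "observed")
        region_name = ""
        for r in regions:
            if r.start <= site <= r.end:
                region_name = r.name
                break
        records.append(
            MutationRecord(
                edge=(parent, child),
                site=site,
                codon_index=ci,
                allele_from=net.nodes[parent].seq[site - 1],
                allele_to=net.nodes[child].seq[site - 1],
                subst_class=subst,
                position_class="tip" if derived_obs == 1 else "interior",
                derived_observed_count=derived_obs,
                region=region_name,
                label=next(label_iter),
            )
        )
    return records


def _codon_index(site: int, frame_offset: int, L: int) -> int | None:
    idx = (site - 1 - frame_offset) // 3
    if site <= frame_offset or frame_offset + 3 * (idx + 1) > L:
        return None
    return idx


def _labels():
    letters = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(letters, repeat=size):
            yield "".join(combo)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------
def edge_table(net: HaplotypeNetwork, records: list[MutationRecord] | None = None):
    """Plain edge list as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    if records is not None:
        return pd.DataFrame(
            [
                {
                    "node_a": r.edge[0],
                    "node_b": r.edge[1],
                    "site": r.site,
                    "class": r.subst_class.value,
                    "position": r.position_class,
                    "derived_observed_count": r.derived_observed_count,
                    "region": r.region,
                    "label": r.label,
                }
                for r in records
            ]
        )
    return pd.DataFrame(
        [
            {"node_a": a, "node_b": b, "site": d.get("site"), "oriented": d.get("parent") is not None}
            for a, b, d in net.graph.edges(data=True)
        ]
    )


def write_graphml(net: HaplotypeNetwork, path) -> None:
    g = nx.Graph()
    for k, v in net.nodes.items():
        g.add_node(k, kind=v.kind, count=v.count, seq=v.seq)
    for a, b, d in net.graph.edges(data=True):
        g.add_edge(a, b, site=d.get("site", 0), ambiguous=frozenset((a, b)) in net.ambiguous_edges)
    nx.write_graphml(g, str(path))
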