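"""BGC similarity networks: pairwise raw distances, families, singletons.

The raw distance between two clusters combines the Jaccard index of
their domain sets (weight 0.7) with the Jaccard index of their sets of
adjacent ordered domain pairs (weight 0.3): distance = 1 - (0.7 J +
0.3 AI). Clusters within a raw distance of 0.3 are connected; connected
components are the gene cluster families and degree-0 nodes are
singletons — candidate novel clusters with no relative in the set.
Networks are built only from complete clusters by default, since a
truncated domain list distorts both similarity terms. The per-domain
sequence-similarity term of the full BiG-SCAPE raw distance needs
pairwise domain alignments and is deliberately omitted; the two
remaining weights are renormalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .errors import ValidationError
from .records import BgcRecord


@dataclass(frozen=True)
class NetworkConfig:
    cutoff: float = 0.3
    w_jaccard: float = 0.7
    w_adjacency: float = 0.3
    scope: str = "complete_only"

    def __post_init__(self):
        if not (0 < self.cutoff <= 1):
            raise ValidationError("cutoff must be in (0, 1]")
        if abs(self.w_jaccard + self.w_adjacency - 1.0) > 1e-9:
            raise ValidationError("w_jaccard + w_adjacency must sum to 1")
        if min(self.w_jaccard, self.w_adjacency) < 0:
            raise ValidationError("weights must be non-negative")
        if self.scope not in ("complete_only", "all_regions"):
            raise ValidationError("scope must be complete_only or all_regions")


@dataclass
class BgcNetwork:
    """Nodes, thresholded edges, connected-component families, singletons."""

    nodes: list[BgcRecord]
    edges: list[tuple[str, str, float]]  # (a, b, distance), a < b
    components: dict[str, str]  # bgc_id -> component id
    singletons: list[str] = field(default_factory=list)
    cutoff: float = 0.3

    @property
    def n_families(self) -> int:
        """Number of multi-member families (components of size >= 2)."""
        sizes: dict[str, int] = {}
        for comp in self.components.values():
            sizes[comp] = sizes.get(comp, 0) + 1
        return sum(1 for s in sizes.values() if s >= 2)


def _adjacency_pairs(domains: Sequence[str]) -> set[tuple[str, str]]:
    return {(domains[i], domains[i + 1]) for i in range(len(domains) - 1)}


def pairwise_raw_distance(a: BgcRecord, b: BgcRecord, cfg: NetworkConfig = NetworkConfig()) -> float:
    """1 - (w_J * Jaccard(domain sets) + w_AI * Jaccard(adjacent ordered pairs)).

    Conventions for degenerate inputs: two records with no domains at
    all are maximally distant (1.0). When both records lack adjacent
    pairs (single-domain records), AI is 1 if their domain sets are
    equal — so identical single-domain clusters are at distance 0 — and
    0 otherwise; a single-domain record vs a multi-domain record has
    AI = 0.
    """
    set_a, set_b = set(a.domains), set(b.domains)
    if not set_a and not set_b:
        return 1.0
    union = set_a | set_b
    j = len(set_a & set_b) / len(union) if union else 0.0
    pa, pb = _adjacency_pairs(a.domains), _adjacency_pairs(b.domains)
    if pa or pb:
        ai = len(pa & pb) / len(pa | pb)
    else:
        ai = 1.0 if set_a == set_b else 0.0
    return 1.0 - (cfg.w_jaccard * j + cfg.w_adjacency * ai)


def build_network(records: Sequence[BgcRecord], cfg: NetworkConfig = NetworkConfig()) -> BgcNetwork:
    """All-pairs raw distances; edge iff distance <= cutoff (inclusive).

    Components are labelled C0001, C0002, ... ordered by their
    lexicographically smallest member, so the labelling is deterministic
    and input-order independent. Fewer than two in-scope records give a
    valid edge-free network.
    """
    nodes = [r for r in records if cfg.scope == "all_regions" or r.complete]
    ids = [r.bgc_id for r in nodes]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate bgc_id among network nodes")
    g = nx.Graph()
    g.add_nodes_from(ids)
    nodes_sorted = sorted(nodes, key=lambda r: r.bgc_id)
    edges = []
    for i in range(len(nodes_sorted)):
        for k in range(i + 1, len(nodes_sorted)):
            d = pairwise_raw_distance(nodes_sorted[i], nodes_sorted[k], cfg)
            if d <= cfg.cutoff:
                edges.append((nodes_sorted[i].bgc_id, nodes_sorted[k].bgc_id, d))
                g.add_edge(nodes_sorted[i].bgc_id, nodes_sorted[k].bgc_id)
    comps = sorted(nx.connected_components(g), key=min)
    width = max(4, len(str(len(comps))))
    components = {}
    for idx, comp in enumerate(comps, start=1):
        for node in comp:
            components[node] = f"C{idx:0{width}d}"
    singletons = sorted(n for n in ids if g.degree[n] == 0)
    return BgcNetwork(
        nodes=nodes, edges=edges, components=components, singletons=singletons, cutoff=cfg.cutoff
    )


def annotate_with_reference(
    net: BgcNetwork,
    reference_records: Sequence[BgcRecord],
    cfg: NetworkConfig = NetworkConfig(),
    label_of: Mapping[str, str] | None = None,
) -> dict[str, str | None]:
    """Label each component with the family of the nearest reference
    cluster within the cutoff (MIBiG-style annotation).

    Reference records carry their family label in ``planted_gcf`` unless
    ``label_of`` (bgc_id -> label) overrides. A component is labelled if
    ANY member is within the cutoff of ANY reference record; among
    qualifying references the nearest wins, ties break on the
    lexicographically smallest label. Components with no reference
    within the cutoff map to None; an empty reference labels nothing.
    """

    def label(ref: BgcRecord) -> str:
        if label_of is not None and ref.bgc_id in label_of:
            return label_of[ref.bgc_id]
        if ref.planted_gcf is not None:
            return ref.planted_gcf
        return ref.bgc_id

    members: dict[str, list[BgcRecord]] = {}
    for node in net.nodes:
        members.setdefault(net.components[node.bgc_id], []).append(node)
    result: dict[str, str | None] = {}
    for comp_id in sorted(members):
        best: tuple[float, str] | None = None
        for node in members[comp_id]:
            for ref in reference_records:
                d = pairwise_raw_distance(node, ref, cfg)
                if d <= cfg.cutoff:
                    cand = (d, label(ref))
                    if best is None or cand < best:
                        best = cand
        result[comp_id] = best[1] if best else None
    return result
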