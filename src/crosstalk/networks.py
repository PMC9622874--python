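"""Bipartite interaction networks, degree-based hub selection, and the
tripartite mRNA-miRNA-lncRNA view.

Hub ("significant") nodes are chosen by whole degree tiers: tiers are
scanned in descending degree order and accumulated while the cumulative
node count stays within ``max_nodes``.  A tier is taken whole or not at
all — ties within a tier are never broken.  With the default budget of 15
this reproduces the study's choices of 7 top-degree miRNAs and 11
top-two-tier lncRNAs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core_io import InteractionEdge, LayerTag, normalize_id

logger = logging.getLogger("crosstalk")

__all__ = ["BipartiteNetwork", "HubSelection", "build_network", "select_hubs",
           "assemble_tripartite", "write_tripartite_tsv"]


@dataclass(frozen=True)
class BipartiteNetwork:
    """Two disjoint node sets joined by an edge list of one layer."""

    left_ids: tuple[str, ...]
    right_ids: tuple[str, ...]
    edges: tuple[InteractionEdge, ...]
    layer: LayerTag

    def degrees(self, side: str) -> dict[str, int]:
        """Degree of every node on ``side`` ('left' or 'right'), zeros included."""
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        ids = self.left_ids if side == "left" else self.right_ids
        counts = Counter(
            e.key[0] if side == "left" else e.key[1] for e in self.edges
        )
        return {i: counts.get(normalize_id(i), 0) for i in ids}


@dataclass(frozen=True)
class HubSelection:
    """The exactly-at-or-above-cutoff node set on one side of a network."""

    side: str
    degree_cutoff: int
    selected_ids: tuple[str, ...]
    degree_table: tuple[tuple[str, int], ...]
    overflow: bool = False  # top tier alone exceeded the budget


def build_network(
    edges: Iterable[InteractionEdge],
    *,
    extra_left: Sequence[str] = (),
    extra_right: Sequence[str] = (),
) -> BipartiteNetwork:
    """Assemble a bipartite network from one layer's edges.

    Node sets are the endpoints observed in the edges plus any explicitly
    supplied isolated nodes (``extra_left`` / ``extra_right``), which keep
    degree 0 — mirroring input node lists that mention partnerless entries.
    """
    edges = tuple(edges)
    if not edges:
        raise ValueError("cannot build a network from an empty edge collection")
    layers = {e.layer for e in edges}
    if len(layers) > 1:
        raise ValueError(f"mixed layer tags in edge collection: {sorted(l.value for l in layers)}")

    left: dict[str, str] = {}   # normalized -> first-seen spelling
    right: dict[str, str] = {}
    for e in edges:
        left.setdefault(e.key[0], e.source_id)
        right.setdefault(e.key[1], e.target_id)
    for i in extra_left:
        left.setdefault(normalize_id(i), i)
    for i in extra_right:
        right.setdefault(normalize_id(i), i)
    return BipartiteNetwork(
        tuple(left.values()), tuple(right.values()), edges, layers.pop()
    )


def select_hubs(net: BipartiteNetwork, side: str, max_nodes: int = 15) -> HubSelection:
    """Accumulate whole degree tiers from the top until the budget is hit.

    Returns the >=-cutoff set for the largest cutoff whose tier-cumulative
    size does not exceed ``max_nodes``.  If even the maximum-degree tier is
    larger than the budget it is returned whole with ``overflow=True``.
    Zero-degree (isolated) nodes never qualify as hubs.
    """
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")
    degrees = net.degrees(side)
    if not degrees:
        raise ValueError(f"network has no nodes on the {side} side")
    positive = {n: d for n, d in degrees.items() if d > 0}
    tiers = sorted({d for d in positive.values()}, reverse=True)

    selected: list[str] = []
    cutoff = tiers[0]
    overflow = False
    for tier_degree in tiers:
        tier = [n for n, d in positive.items() if d == tier_degree]
        if not selected and len(tier) > max_nodes:
            selected, cutoff, overflow = tier, tier_degree, True
            break
        if len(selected) + len(tier) > max_nodes:
            break
        selected.extend(tier)
        cutoff = tier_degree
    table = tuple(sorted(positive.items(), key=lambda kv: (-kv[1], normalize_id(kv[0]))))
    ordered = tuple(sorted(selected, key=lambda n: (-positive[n], normalize_id(n))))
    logger.info(
        "select_hubs side=%s cutoff=%d selected=%d overflow=%s",
        side, cutoff, len(ordered), overflow,
    )
    return HubSelection(side, cutoff, ordered, table, overflow)


def _restrict(
    edges: Iterable[InteractionEdge], left_keep: set[str], right_keep: set[str]
) -> list[InteractionEdge]:
    return [e for e in edges if e.key[0] in left_keep and e.key[1] in right_keep]


def assemble_tripartite(
    p_net: BipartiteNetwork,
    m_hubs: HubSelection,
    l_net: BipartiteNetwork,
    l_hubs: HubSelection,
) -> list[tuple[str, str, str]]:
    """Edge list of the final three-layer network, restricted to hubs.

    Rows are ``(layer, source, target)``: mRNA-miRNA edges keep only edges
    incident to a hub miRNA; miRNA-lncRNA edges keep only hub-miRNA to
    hub-lncRNA edges.  mRNAs that lose all their edges drop out of the view.
    """
    m_keys = {normalize_id(i) for i in m_hubs.selected_ids}
    l_keys = {normalize_id(i) for i in l_hubs.selected_ids}
    if not m_keys & {normalize_id(i) for i in p_net.right_ids}:
        raise ValueError("miRNA hub set is disjoint from the mRNA-miRNA network")
    if not l_keys & {normalize_id(i) for i in l_net.right_ids}:
        raise ValueError("lncRNA hub set is disjoint from the miRNA-lncRNA network")

    first = _restrict(p_net.edges, {normalize_id(i) for i in p_net.left_ids}, m_keys)
    second = _restrict(l_net.edges, m_keys, l_keys)
    rows = [(p_net.layer.value, e.source_id, e.target_id) for e in first]
    rows += [(l_net.layer.value, e.source_id, e.target_id) for e in second]
    return rows


def write_tripartite_tsv(rows: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("layer\tsource\ttarget\n")
        for layer, s, t in rows:
            fh.write(f"{layer}\t{s}\t{t}\n")
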