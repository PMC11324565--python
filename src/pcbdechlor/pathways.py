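"""Single-chlorine-removal reaction networks and dechlorination processes.

Microbial reductive dechlorination removes one chlorine at a time, so
the 209-congener space carries a natural directed acyclic graph: an
edge links a parent congener to the canonical form of the parent minus
one substituent.  Edges are annotated with the position class of the
removed chlorine (ortho/meta/para), its flanking context (whether
ring-adjacent positions are also chlorinated), and the chlorophenyl
group of the attacked ring written in the literature's digit shorthand
(e.g. "245").

Named dechlorination processes from the Aroclor literature (process N,
process H/H') are encoded as rules pairing a chlorophenyl group with the
attacked position; the default tables target flanked meta (N) and para
(H/H') chlorines and are fully overridable via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .congeners import (
    BIPHENYL,
    Congener,
    CongenerTable,
    canonicalize,
    get_table,
    parse_congener,
    position_class,
)

__all__ = [
    "DechlorReaction",
    "ReactionNetwork",
    "ProcessRule",
    "single_dechlor_products",
    "build_network",
    "default_process_rules",
    "classify_process",
    "load_process_rules",
]

ALL_POSITIONS = frozenset({"ortho", "meta", "para"})

_FLIP_MAP = {2: 6, 3: 5, 4: 4, 5: 3, 6: 2}
_FLANKING = ("unflanked", "singly-flanked", "doubly-flanked")


def _group_string(ring) -> str:
    return "".join(str(p) for p in sorted(ring))


def normalize_group(group: str, position: int) -> tuple:
    """Map a (chlorophenyl group, position) pair to flip-minimal coordinates.

    A ring pattern and its flip about the 1-4 axis (2<->6, 3<->5)
    describe the same chlorophenyl group; rules and reaction annotations
    are stored in the flip-minimal frame so they compare equal.
    """
    ring = frozenset(int(d) for d in group)
    if not ring <= {2, 3, 4, 5, 6}:
        raise ValueError(f"invalid chlorophenyl group {group!r}")
    if position not in ring:
        raise ValueError(f"position {position} is not substituted in group {group!r}")
    flipped = frozenset(_FLIP_MAP[p] for p in ring)
    if tuple(sorted(flipped)) < tuple(sorted(ring)):
        return _group_string(flipped), _FLIP_MAP[position]
    return _group_string(ring), position


@dataclass(frozen=True)
class DechlorReaction:
    """One parent -> product dechlorination step.

    ``multiplicity`` counts the symmetry-equivalent chlorines whose
    removal yields this same (product, position-class) pair; it scales
    the kinetic rate of the step.
    """

    parent: Congener
    product: Congener
    position: str            # ortho | meta | para
    removed_position: int    # digit within `group` coordinates
    flanking: str            # unflanked | singly-flanked | doubly-flanked
    group: str               # chlorophenyl group of the attacked ring
    multiplicity: int = 1

    def __post_init__(self):
        if self.product.n_cl != self.parent.n_cl - 1:
            raise ValueError("product must have exactly one chlorine fewer than parent")


def single_dechlor_products(c: Congener) -> tuple:
    """All single-chlorine-removal reactions from a congener.

    One reaction per distinct (canonical product, position class);
    symmetry-equivalent removals are folded into ``multiplicity``.
    Flanking is along the ring path 2-3-4-5-6 (the ring-bond position 1
    never flanks).  Returns an empty tuple for biphenyl.
    """
    found: dict[tuple, DechlorReaction] = {}
    for ring, other in ((c.ringA, c.ringB), (c.ringB, c.ringA)):
        ring_set = set(ring)
        for p in ring:
            product = canonicalize(ring_set - {p}, other)
            cls = position_class(p)
            key = (product, cls)
            if key in found:
                r = found[key]
                found[key] = DechlorReaction(
                    parent=c, product=product, position=cls,
                    removed_position=r.removed_position, flanking=r.flanking,
                    group=r.group, multiplicity=r.multiplicity + 1,
                )
                continue
            n_flank = sum(1 for q in (p - 1, p + 1) if q in ring_set)
            group, removed = normalize_group(_group_string(ring), p)
            found[key] = DechlorReaction(
                parent=c, product=product, position=cls,
                removed_position=removed, flanking=_FLANKING[n_flank],
                group=group, multiplicity=1,
            )
    return tuple(sorted(
        found.values(),
        key=lambda r: (r.position, r.product.sort_key),
    ))


@dataclass(frozen=True)
class ProcessRule:
    """A named dechlorination process: a set of (group, position) targets."""

    name: str
    targets: frozenset  # {(group string, attacked position), ...}

    @classmethod
    def from_pairs(cls, name: str, pairs) -> "ProcessRule":
        normalized = frozenset(normalize_group(g, int(p)) for g, p in pairs)
        return cls(name=name, targets=normalized)

    def matches(self, reaction: DechlorReaction) -> bool:
        return (reaction.group, reaction.removed_position) in self.targets


def _flanked_meta_positions(group: str):
    ring = {int(d) for d in group}
    for p in ring & {3, 5}:
        if (p - 1) in ring or (p + 1) in ring:
            yield p


def default_process_rules() -> tuple:
    """Default process N and H/H' rule tables.

    Process N removes flanked meta chlorines from the 236, 245, 2345 and
    2356 chlorophenyl groups; process H/H' removes para chlorines from
    234, 245 and 2345.  These tables are a configuration default, not a
    fixed fact: the group->position assignments in the primary
    literature vary, so pipelines may override them.
    """
    n_pairs = [
        (g, p)
        for g in ("236", "245", "2345", "2356")
        for p in _flanked_meta_positions(g)
    ]
    h_pairs = [(g, 4) for g in ("234", "245", "2345")]
    return (
        ProcessRule.from_pairs("N", n_pairs),
        ProcessRule.from_pairs("H/H'", h_pairs),
    )


def classify_process(reaction: DechlorReaction, rules=None) -> frozenset:
    """Names of all processes whose rule matches a reaction (may be empty)."""
    if rules is None:
        rules = default_process_rules()
    return frozenset(rule.name for rule in rules if rule.matches(reaction))


def load_process_rules(mapping) -> tuple:
    """Build rules from ``{name: [[group, position], ...]}`` (e.g. YAML)."""
    return tuple(
        ProcessRule.from_pairs(str(name), [(str(g), int(p)) for g, p in pairs])
        for name, pairs in mapping.items()
    )


class ReactionNetwork:
    """Directed single-removal network over congeners.

    Nodes are congeners (plus biphenyl as the global sink); edges are
    :class:`DechlorReaction` objects restricted to an allowed set of
    position classes.  The graph is acyclic since every edge strictly
    decreases the chlorine count.
    """

    def __init__(self, table: CongenerTable | None = None, allowed=ALL_POSITIONS,
                 rules=None):
        allowed = frozenset(allowed)
        if not allowed:
            raise ValueError("the allowed position set must be non-empty")
        bad = allowed - ALL_POSITIONS
        if bad:
            raise ValueError(f"unknown position class(es) {sorted(bad)}")
        self.table = table if table is not None else get_table()
        self.allowed = allowed
        self.rules = tuple(rules) if rules is not None else default_process_rules()
        self.graph = nx.DiGraph()
        self.reactions: dict[tuple, DechlorReaction] = {}
        for c in self.table:
            self.graph.add_node(c)
        self.graph.add_node(BIPHENYL)
        for c in self.table:
            for r in single_dechlor_products(c):
                if r.position not in allowed:
                    continue
                processes = classify_process(r, self.rules)
                self.reactions[(c, r.product)] = r
                self.graph.add_edge(
                    c, r.product,
                    position=r.position, group=r.group,
                    flanking=r.flanking, multiplicity=r.multiplicity,
                    processes=",".join(sorted(processes)),
                )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def out_reactions(self, congener) -> tuple:
        c = parse_congener(congener)
        return tuple(
            self.reactions[(c, p)] for p in sorted(
                self.graph.successors(c), key=lambda x: x.sort_key
            )
        )

    def reachable(self, parent, targets, return_path: bool = True):
        """Breadth-first reachability from ``parent`` to any of ``targets``.

        Returns ``(True, shortest path as a congener list)`` or
        ``(False, None)``.  A parent trivially reaches itself.
        """
        start = parse_congener(parent)
        goal = {parse_congener(t) for t in (targets if isinstance(targets, (list, tuple, set, frozenset)) else [targets])}
        best = None
        for t in sorted(goal, key=lambda x: x.sort_key):
            try:
                path = nx.shortest_path(self.graph, start, t)
            except nx.NetworkXNoPath:
                continue
            if best is None or len(path) < len(best):
                best = path
        if best is None:
            return False, None
        return True, (best if return_path else None)

    def terminal_congeners(self, parents) -> set:
        """Zero-out-degree congeners reachable from the given parents."""
        seen = set()
        for p in parents:
            seen |= nx.descendants(self.graph, parse_congener(p))
            seen.add(parse_congener(p))
        return {c for c in seen if self.graph.out_degree(c) == 0}

    # -- export ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (parent, product), r in sorted(
            self.reactions.items(), key=lambda kv: (kv[0][0].sort_key, kv[0][1].sort_key)
        ):
            rows.append(
                {
                    "parent_bz": parent.bz,
                    "product_bz": product.bz if product.n_cl else 0,
                    "parent": parent.structure,
                    "product": product.structure,
                    "position": r.position,
                    "removed_position": r.removed_position,
                    "flanking": r.flanking,
                    "group": r.group,
                    "multiplicity": r.multiplicity,
                    "processes": self.graph.edges[parent, product]["processes"],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for u, v, data in self.graph.edges(data=True):
            g.add_edge(
                f"PCB{u.bz}" if u.n_cl else "biphenyl",
                f"PCB{v.bz}" if v.n_cl else "biphenyl",
                **data,
            )
        for node in self.graph.nodes:
            label = f"PCB{node.bz}" if node.n_cl else "biphenyl"
            if label not in g:
                g.add_node(label)
            g.nodes[label]["structure"] = node.structure
            g.nodes[label]["n_cl"] = node.n_cl
        nx.write_graphml(g, path)


def build_network(table: CongenerTable | None = None, allowed=ALL_POSITIONS,
                  rules=None) -> ReactionNetwork:
    """Construct the single-removal network restricted to ``allowed`` classes."""
    return ReactionNetwork(table=table, allowed=allowed, rules=rules)
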