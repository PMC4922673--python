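"""Rearrangement characters, outgroup polarity, and Dollo parsimony trees.

Characters are chromosomal rearrangements scored per taxon as absent,
polymorphic, fixed, X-linked or Y-linked.  Polarity comes from outgroup
comparison and is arm-limited: an arm too scrambled to align with any
outgroup yields unresolvable cells that never contribute to a tree score.

Tree inference enumerates every rooted binary topology over the ingroup
(exhaustive, so capped at 8 taxa) and scores each character under Dollo
parsimony: a derived state arises once and may only be lost afterwards.
State changes run along a star with the polymorphic state at its centre
(absent <-> polymorphic <-> fixed/X-linked/Y-linked): fixation or linkage of
a rearrangement must pass through a polymorphic stage, and distinct
non-polymorphic fates on one edge are disallowed rather than priced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

ABSENT = "absent"
POLYMORPHIC = "polymorphic"
FIXED = "fixed"
X_LINKED = "X_linked"
Y_LINKED = "Y_linked"
UNRESOLVABLE = "unresolvable"

STATES = (ABSENT, POLYMORPHIC, FIXED, X_LINKED, Y_LINKED)


def state_distance(a: str, b: str) -> int:
    """Steps between states on the polymorphic-centred star: fixation,
    linkage or loss of a rearrangement passes through a polymorphic stage
    (counted even when the transient stage falls inside one branch)."""
    if a == b:
        return 0
    return 1 if POLYMORPHIC in (a, b) else 2


INF = 10 ** 9


class PhylogenyError(ValueError):
    pass


@dataclass
class CharacterMatrix:
    """Taxa x rearrangement-character state matrix with polarity metadata."""

    ingroup: list[str]
    outgroups: list[str]
    characters: list[str]
    states: dict[tuple[str, str], str]                  # (taxon, character) -> state
    resolvable_against: dict[str, frozenset] = field(default_factory=dict)
    polarity: dict[str, str] = field(default_factory=dict)   # character -> derived/ancestral/unresolvable
    polarity_outgroups: dict[str, frozenset] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return self.ingroup + self.outgroups

    def state(self, taxon: str, character: str) -> str:
        return self.states.get((taxon, character), ABSENT)


def polarize(matrix: CharacterMatrix, outgroups: Sequence[str] | None = None) -> CharacterMatrix:
    """Mark each character derived, ancestral or unresolvable.

    Derived: absent from every outgroup against which the character's arm can
    be resolved.  Ancestral: present in some resolvable outgroup.
    Unresolvable: no outgroup comparison possible.  The supporting outgroup
    set is recorded per character (a single-outgroup call stays flagged)."""
    outgroups = list(outgroups) if outgroups is not None else matrix.outgroups
    if not outgroups:
        raise PhylogenyError("polarity requires at least one outgroup")
    for ch in matrix.characters:
        resolvable = matrix.resolvable_against.get(ch, frozenset(outgroups))
        usable = frozenset(o for o in outgroups if o in resolvable)
        matrix.polarity_outgroups[ch] = usable
        if not usable:
            matrix.polarity[ch] = UNRESOLVABLE
        elif all(matrix.state(o, ch) == ABSENT for o in usable):
            matrix.polarity[ch] = "derived"
        else:
            matrix.polarity[ch] = "ancestral"
    return matrix


def synapomorphy_partition(matrix: CharacterMatrix, clade: Sequence[str]
                           ) -> dict[str, list[str]]:
    """Derived characters present throughout ``clade`` and absent outside it,
    split into fixed-in-all versus polymorphic-in-at-least-one."""
    clade = list(clade)
    if not clade:
        raise PhylogenyError("empty clade")
    if not set(clade) <= set(matrix.ingroup):
        raise PhylogenyError("clade must be a subset of the ingroup")
    if not matrix.polarity:
        polarize(matrix)
    outside = [t for t in matrix.taxa if t not in clade]
    part = {"fixed": [], "polymorphic": []}
    for ch in matrix.characters:
        if matrix.polarity.get(ch) != "derived":
            continue
        inside_states = [matrix.state(t, ch) for t in clade]
        if any(s == ABSENT for s in inside_states):
            continue
        if any(matrix.state(t, ch) != ABSENT for t in outside):
            continue
        if all(s in (FIXED, X_LINKED, Y_LINKED) for s in inside_states):
            part["fixed"].append(ch)
        else:
            part["polymorphic"].append(ch)
    return part


# ---------------------------------------------------------------------------
# rooted topologies


def enumerate_rooted_topologies(taxa: Sequence[str]):
    """All rooted binary topologies over ``taxa`` as nested tuples."""
    taxa = list(taxa)
    if len(taxa) == 1:
        yield taxa[0]
        return

    def insert(tree, leaf):
        # replace any subtree s by (s, leaf)
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insert(left, leaf):
                yield (t, right)
            for t in insert(right, leaf):
                yield (left, t)

    trees = [taxa[0]]
    for leaf in taxa[1:]:
        trees = [t for tree in trees for t in insert(tree, leaf)]
    yield from trees


def _leaves(tree) -> tuple:
    if isinstance(tree, tuple):
        return _leaves(tree[0]) + _leaves(tree[1])
    return (tree,)


def _clades(tree) -> list[frozenset]:
    if not isinstance(tree, tuple):
        return [frozenset([tree])]
    out = _clades(tree[0]) + _clades(tree[1])
    out.append(frozenset(_leaves(tree)))
    return out


def tree_newick(tree, order: Sequence[str] | None = None) -> str:
    def fmt(node):
        if isinstance(node, tuple):
            kids = [fmt(k) for k in node]
            if order is not None:
                kids.sort(key=lambda s: min(order.index(x) for x in s.replace("(", "").replace(")", "").split(",")))
            return "(" + ",".join(kids) + ")"
        return node
    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# Dollo scoring


def _dollo_char_table(tree, tip_states: Mapping[str, str]):
    """DP over (state, gains-in-subtree) -> minimal cost.

    Edge costs are star distances; a gain is any edge leaving the absent
    state.  Dollo allows one origin in total, a non-absent root state
    counting as the origin sitting on the stem."""
    if not isinstance(tree, tuple):
        s = tip_states[tree]
        return {(s, 0): 0}
    left = _dollo_char_table(tree[0], tip_states)
    right = _dollo_char_table(tree[1], tip_states)
    table: dict[tuple[str, int], int] = {}
    for s in STATES:
        for (ls, lg), lc in left.items():
            for (rs, rg), rc in right.items():
                cost = lc + rc
                gains = lg + rg
                for child in (ls, rs):
                    cost += state_distance(s, child)
                    if s == ABSENT and child != ABSENT:
                        gains += 1
                gains = min(gains, 2)
                key = (s, gains)
                if cost < table.get(key, INF):
                    table[key] = cost
    return table


def dollo_char_score(tree, tip_states: Mapping[str, str]) -> int:
    """Minimal Dollo change count for one character on a rooted tree,
    including the stem cost of acquiring the derived state from absence."""
    table = _dollo_char_table(tree, tip_states)
    best = INF
    for (s, gains), cost in table.items():
        origins = gains + (0 if s == ABSENT else 1)
        if origins <= 1:
            best = min(best, cost + state_distance(ABSENT, s))
    if best >= INF:
        raise PhylogenyError("no Dollo-consistent reconstruction")
    return best


def dollo_tree_score(tree, matrix: CharacterMatrix,
                     include_polymorphic: bool = True) -> int:
    if not matrix.polarity:
        polarize(matrix)
    total = 0
    for ch in matrix.characters:
        if matrix.polarity.get(ch) != "derived":
            continue
        states = {t: matrix.state(t, ch) for t in matrix.ingroup}
        if not include_polymorphic and any(s == POLYMORPHIC for s in states.values()):
            continue
        total += dollo_char_score(tree, states)
    return total


@dataclass
class Cladogram:
    topology: tuple
    score: int
    support: dict[frozenset, list[tuple[str, str]]]   # clade -> (character, class)
    ties: list[tuple] = field(default_factory=list)

    def newick(self, order: Sequence[str] | None = None) -> str:
        return tree_newick(self.topology, order)


def _support_map(tree, matrix: CharacterMatrix) -> dict[frozenset, list[tuple[str, str]]]:
    clades = _clades(tree)
    support: dict[frozenset, list[tuple[str, str]]] = {c: [] for c in clades}
    ambiguous = frozenset()
    for ch in matrix.characters:
        if matrix.polarity.get(ch) != "derived":
            continue
        present = frozenset(t for t in matrix.ingroup if matrix.state(t, ch) != ABSENT)
        if not present:
            continue
        states = [matrix.state(t, ch) for t in present]
        if present in support:
            klass = ("fixed synapomorphy"
                     if all(s in (FIXED, X_LINKED, Y_LINKED) for s in states)
                     else "polymorphic synapomorphy")
            support[present].append((ch, klass))
        else:
            support.setdefault(ambiguous, []).append((ch, "ambiguous"))
    return support


def infer_tree(matrix: CharacterMatrix, include_polymorphic: bool = True,
               max_taxa: int = 8) -> Cladogram:
    """Exhaustive Dollo-parsimony search over rooted topologies.

    Returns the minimal-score cladogram with its branch support; co-optimal
    topologies are reported in ``ties``, never silently broken."""
    if len(matrix.ingroup) > max_taxa:
        raise PhylogenyError(
            f"{len(matrix.ingroup)} taxa exceeds the exhaustive-search cap {max_taxa}")
    if not matrix.polarity:
        polarize(matrix)
    scored = [(dollo_tree_score(t, matrix, include_polymorphic), t)
              for t in enumerate_rooted_topologies(matrix.ingroup)]
    best = min(s for s, _ in scored)
    winners = [t for s, t in scored if s == best]
    primary = winners[0]
    return Cladogram(primary, best, _support_map(primary, matrix), winners[1:])


# ---------------------------------------------------------------------------
# ancestral states


def _internal_nodes(tree) -> list[tuple]:
    if not isinstance(tree, tuple):
        return []
    return _internal_nodes(tree[0]) + _internal_nodes(tree[1]) + [tree]


def ancestral_state(matrix: CharacterMatrix, character: str, tree
                    ) -> dict[frozenset, str]:
    """Minimal-change Dollo assignment of one character to internal nodes,
    keyed by the clade below each node.  Where co-minimal reconstructions
    disagree at a node the polymorphic state is reported: a node whose
    descendants demand different fates is by necessity segregating."""
    tips = _leaves(tree)
    for t in tips:
        if (t, character) not in matrix.states and t not in matrix.ingroup:
            raise PhylogenyError(f"character {character} not scored in tip {t}")
    internals = _internal_nodes(tree)
    tip_states = {t: matrix.state(t, character) for t in tips}
    best_cost = INF
    best_assignments: list[dict] = []
    for combo in itertools.product(STATES, repeat=len(internals)):
        assign = dict(zip(map(id, internals), combo))

        def node_state(node):
            return tip_states[node] if not isinstance(node, tuple) else assign[id(node)]

        cost = gains = 0
        for node in internals:
            s = node_state(node)
            for child in node:
                cs = node_state(child)
                cost += state_distance(s, cs)
                if s == ABSENT and cs != ABSENT:
                    gains += 1
        root_state = assign[id(internals[-1])]
        cost += state_distance(ABSENT, root_state)   # stem acquisition
        if gains + (0 if root_state == ABSENT else 1) > 1:
            continue
        if cost < best_cost:
            best_cost = cost
            best_assignments = [dict(zip(range(len(internals)), combo))]
        elif cost == best_cost:
            best_assignments.append(dict(zip(range(len(internals)), combo)))
    if not best_assignments:
        raise PhylogenyError("no Dollo-consistent reconstruction")
    out = {}
    for i, node in enumerate(internals):
        vals = {a[i] for a in best_assignments}
        out[frozenset(_leaves(node))] = vals.pop() if len(vals) == 1 else POLYMORPHIC
    return out
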