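"""PQ-tree for consecutive-ones ordering of ancestral markers.

A PQ-tree over a universe U compactly represents the set of permutations of U
in which every previously inserted constraint set appears consecutively.
P-nodes allow arbitrary permutation of their children; Q-nodes fix the child
order up to reversal. ``reduce(S)`` narrows the tree so that the elements of
S are consecutive in every admissible frontier, failing (and leaving the tree
untouched) when no such permutation survives.

The implementation is a recursive formulation of the Booth–Lueker templates:
a partial subtree is normalised into a Q-sequence whose frontier reads
empty-to-full, and the pertinent root splices such sequences around its full
children.
"""

from __future__ import annotations

import copy
from math import factorial


class _Fail(Exception):
    pass


class Leaf:
    __slots__ = ("label",)

    def __init__(self, label):
        self.label = label

    def frontier(self, out):
        out.append(self.label)

    def leafset(self):
        return frozenset((self.label,))


class PNode:
    __slots__ = ("children",)

    def __init__(self, children):
        self.children = list(children)

    def frontier(self, out):
        for c in self.children:
            c.frontier(out)

    def leafset(self):
        s = set()
        for c in self.children:
            s |= c.leafset()
        return frozenset(s)


class QNode:
    __slots__ = ("children",)

    def __init__(self, children):
        self.children = list(children)

    def frontier(self, out):
        for c in self.children:
            c.frontier(out)

    def leafset(self):
        s = set()
        for c in self.children:
            s |= c.leafset()
        return frozenset(s)


def _reverse(node):
    """Mirror a subtree in place (always admissible)."""
    if isinstance(node, Leaf):
        return node
    node.children = [_reverse(c) for c in node.children]
    if isinstance(node, QNode):
        node.children.reverse()
    return node


def _group(children, cls=PNode):
    """Wrap a child list into a single node (unwrapped if singleton)."""
    if len(children) == 1:
        return children[0]
    return cls(children)


def _normalize(node):
    """Collapse degenerate nodes: unary internals, binary Q -> P.

    Q-in-Q is deliberately NOT flattened here: a wholly-empty/full Q child
    spliced under a Q parent keeps its own reversal freedom; merging happens
    only inside the reduction templates, where a constraint ties orientations.
    """
    if isinstance(node, Leaf):
        return node
    node.children = [_normalize(c) for c in node.children]
    if len(node.children) == 1:
        return node.children[0]
    if isinstance(node, QNode) and len(node.children) == 2:
        return PNode(node.children)
    return node


class PQTree:
    """PQ-tree over a fixed universe of hashable labels."""

    def __init__(self, universe):
        universe = list(universe)
        if len(universe) != len(set(universe)):
            raise ValueError("universe labels must be unique")
        if len(universe) == 1:
            self.root = Leaf(universe[0])
        else:
            self.root = PNode([Leaf(x) for x in sorted(universe, key=str)])
        self.universe = frozenset(universe)

    # -- queries -----------------------------------------------------------

    def frontier(self) -> list:
        out: list = []
        self.root.frontier(out)
        return out

    def n_arrangements(self) -> int:
        """Number of admissible frontiers (including full reversals)."""
        def walk(node):
            if isinstance(node, Leaf):
                return 1
            n = 1
            for c in node.children:
                n *= walk(c)
            if isinstance(node, PNode):
                n *= factorial(len(node.children))
            else:
                n *= 2
            return n
        return walk(self.root)

    # -- reduction ---------------------------------------------------------

    def reduce(self, S) -> bool:
        """Constrain S to be consecutive. Returns False (tree unchanged) if impossible."""
        S = frozenset(S)
        if not S <= self.universe:
            raise ValueError("constraint contains labels outside the universe")
        if len(S) <= 1 or S == self.universe:
            return True
        backup = copy.deepcopy(self.root)
        try:
            self.root = _normalize(self._reduce_root(self.root, S))
            return True
        except _Fail:
            self.root = backup
            return False

    def _classify(self, node, S):
        ls = node.leafset()
        if ls <= S:
            return "full"
        if not (ls & S):
            return "empty"
        return "partial"

    def _reduce_root(self, node, S):
        # descend to the pertinent root: the deepest node covering all of S
        if not isinstance(node, Leaf):
            for i, c in enumerate(node.children):
                if S <= c.leafset():
                    node.children[i] = self._reduce_root(c, S)
                    return node
        return self._apply_root(node, S)

    def _apply_root(self, node, S):
        if isinstance(node, Leaf) or self._classify(node, S) == "full":
            return node
        if isinstance(node, PNode):
            empty, full, partial = [], [], []
            for c in node.children:
                {"empty": empty, "full": full, "partial": partial}[
                    self._classify(c, S)].append(c)
            if len(partial) == 0:
                if len(full) <= 1:
                    return node
                node.children = empty + [PNode(full)]
                return _group(node.children, PNode) if not empty else node
            if len(partial) == 1:
                seq = self._make_partial(partial[0], S)  # empty -> full
                if full:
                    seq = seq + [_group(full, PNode)]
                q = QNode(seq)
                if not empty:
                    return q
                node.children = empty + [q]
                return node
            if len(partial) == 2:
                left = self._make_partial(partial[0], S)          # empty -> full
                right = self._make_partial(partial[1], S)         # empty -> full
                right = [_reverse(c) for c in reversed(right)]    # full -> empty
                mid = [_group(full, PNode)] if full else []
                q = QNode(left + mid + right)
                if not empty:
                    return q
                node.children = empty + [q]
                return node
            raise _Fail
        # Q-node root
        kinds = [self._classify(c, S) for c in node.children]
        nonempty = [i for i, k in enumerate(kinds) if k != "empty"]
        if not nonempty:
            return node
        lo, hi = nonempty[0], nonempty[-1]
        if nonempty != list(range(lo, hi + 1)):
            raise _Fail
        for i in range(lo + 1, hi):
            if kinds[i] != "full":
                raise _Fail
        new_children = list(node.children[:lo])
        if kinds[lo] == "partial":
            new_children += self._make_partial(node.children[lo], S)  # empty->full
        else:
            new_children.append(node.children[lo])
        new_children += node.children[lo + 1:hi]
        if hi > lo:
            if kinds[hi] == "partial":
                seq = self._make_partial(node.children[hi], S)
                new_children += [_reverse(c) for c in reversed(seq)]  # full->empty
            else:
                new_children.append(node.children[hi])
        new_children += node.children[hi + 1:]
        node.children = new_children
        return node

    def _make_partial(self, node, S):
        """Normalise a partial subtree into a child sequence reading empty->full.

        Every returned element is a wholly-empty or wholly-full subtree; their
        relative order is fixed (they will be spliced into a Q-node).
        """
        if isinstance(node, Leaf):
            return [node]
        if isinstance(node, PNode):
            empty, full, partial = [], [], []
            for c in node.children:
                {"empty": empty, "full": full, "partial": partial}[
                    self._classify(c, S)].append(c)
            if len(partial) > 1:
                raise _Fail
            seq = []
            if empty:
                seq.append(_group(empty, PNode))
            if partial:
                seq.extend(self._make_partial(partial[0], S))
            if full:
                seq.append(_group(full, PNode))
            return seq
        # Q-node: children must read empty* [partial] full* in one direction
        kinds = [self._classify(c, S) for c in node.children]
        children = list(node.children)
        if not self._q_pattern_ok(kinds):
            kinds.reverse()
            children = [_reverse(c) for c in reversed(children)]
            if not self._q_pattern_ok(kinds):
                raise _Fail
        seq = []
        for c, k in zip(children, kinds):
            if k == "partial":
                seq.extend(self._make_partial(c, S))
            else:
                seq.append(c)
        return seq

    @staticmethod
    def _q_pattern_ok(kinds):
        """True if kinds matches empty* partial? full*."""
        state = 0  # 0: empties, 1: fulls
        for k in kinds:
            if state == 0:
                if k == "empty":
                    continue
                state = 1
                if k in ("partial", "full"):
                    continue
            else:
                if k != "full":
                    return False
        return True


def sandwich_satisfied(order, ones, zeros) -> bool:
    """Check one sandwich-matrix row against a column order.

    The row holds when, in ``order`` restricted to ones+zeros, no 0 column
    lies between two 1 columns (X columns may interleave freely).
    """
    seq = [x for x in order if x in ones or x in zeros]
    pos = [i for i, x in enumerate(seq) if x in ones]
    if not pos:
        return True
    return pos[-1] - pos[0] + 1 == len(pos)


def exact_c1p_order(universe, rows):
    """Exhaustive-with-pruning search for an order satisfying every row.

    ``rows`` is a list of (ones, zeros) pairs. Returns an order or None.
    Intended for small instances (|universe| <= ~9).
    """
    universe = sorted(universe, key=str)
    n = len(universe)
    rows = [(frozenset(o), frozenset(z)) for o, z in rows]

    def prefix_ok(prefix):
        for ones, zeros in rows:
            state = 0  # 0 before ones, 1 inside run, 2 run closed
            for x in prefix:
                if x in ones:
                    if state == 2:
                        return False
                    state = 1
                elif x in zeros and state == 1:
                    state = 2
        return True

    order: list = []
    used = [False] * n

    def dfs():
        if len(order) == n:
            return all(sandwich_satisfied(order, o, z) for o, z in rows)
        for i in range(n):
            if used[i]:
                continue
            used[i] = True
            order.append(universe[i])
            if prefix_ok(order) and dfs():
                return True
            order.pop()
            used[i] = False
        return False

    return list(order) if dfs() else None
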