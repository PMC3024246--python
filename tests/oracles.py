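"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or naive
recounting, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import inf

import numpy as np

from cnetrace.align import Scoring
from cnetrace.io import SpeciesTree, TreeNode


# ---------------------------------------------------------------------------
# Alignment: exhaustive enumeration over all global affine-gap alignments
# ---------------------------------------------------------------------------


def brute_force_score(a: str, b: str, scoring: Scoring = Scoring()) -> float:
    """Max score over every global alignment, enumerated move by move.

    A gap of length L costs gap_open + L * gap_extend; N matches nothing.
    """
    best = -inf
    la, lb = len(a), len(b)

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            col = (
                scoring.match
                if a[i] == b[j] and a[i] != "N"
                else scoring.mismatch
            )
            rec(i + 1, j + 1, "M", score + col)
        if i < la:
            gap = scoring.gap_extend + (0 if prev == "D" else scoring.gap_open)
            rec(i + 1, j, "D", score + gap)
        if j < lb:
            gap = scoring.gap_extend + (0 if prev == "I" else scoring.gap_open)
            rec(i, j + 1, "I", score + gap)

    rec(0, 0, "", 0.0)
    return best


# ---------------------------------------------------------------------------
# Identity profile: naive per-window recount straight from the row strings
# ---------------------------------------------------------------------------


def naive_windowed_identity(ref_row: str, qry_row: str, window: int) -> list[float]:
    """Recount every window position by position from the gapped rows."""
    ref_cols = [i for i, ch in enumerate(ref_row) if ch != "-"]
    L = len(ref_cols)
    out: list[float] = []
    for p in range(L - window + 1):
        lo = ref_cols[p]
        hi = ref_cols[p + window - 1]
        matches = 0
        total = 0
        for col in range(lo, hi + 1):
            total += 1
            r, q = ref_row[col], qry_row[col]
            if r == q and r in "ACGT":
                matches += 1
        out.append(100.0 * matches / total)
    return out


# ---------------------------------------------------------------------------
# Integration: position sweep for constant-support runs within an element
# ---------------------------------------------------------------------------


def sweep_support_runs(
    intervals: list[tuple[int, int, str]], span: tuple[int, int]
) -> list[tuple[int, int, frozenset[str]]]:
    """Maximal runs of constant covering-species set across ``span``."""
    start, end = span
    runs: list[tuple[int, int, frozenset[str]]] = []
    prev: frozenset[str] | None = None
    run_start = start
    for pos in range(start, end):
        cover = frozenset(sp for s, e, sp in intervals if s <= pos < e)
        if prev is None:
            prev = cover
        elif cover != prev:
            runs.append((run_start, pos, prev))
            run_start = pos
            prev = cover
    if prev is not None:
        runs.append((run_start, end, prev))
    return runs


# ---------------------------------------------------------------------------
# Dollo: exhaustive minimum over all single-gain / loss-set assignments
# ---------------------------------------------------------------------------


def _descendants(node: TreeNode) -> list[TreeNode]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def min_dollo_events(tree: SpeciesTree, states: dict[str, int | None]) -> int | None:
    """Exhaustive minimum of 1 + |losses| over all consistent histories.

    Returns None for vacuous characters (no observed presence).
    """
    if not any(s == 1 for s in states.values()):
        return None

    def consistent(gain: TreeNode, leaves_under: set[str], loss_labels: set[str]) -> bool:
        for leaf, s in states.items():
            if s is None:
                continue
            inside = leaf in leaves_under
            lost = False
            if inside:
                cur = tree.node(leaf)
                while True:
                    if cur.label in loss_labels:
                        lost = True
                        break
                    if cur is gain:
                        break
                    cur = cur.parent
            present = inside and not lost
            if (s == 1) != present:
                return False
        return True

    best: int | None = None
    for gain in tree.preorder():
        under = _descendants(gain)
        leaves_under = {n.label for n in under if n.is_leaf}
        if any(s == 1 and leaf not in leaves_under for leaf, s in states.items()):
            continue  # presence outside the gain clade: inconsistent
        # only subtrees without observed presence can be wholly lost
        candidates = []
        for n in under:
            n_leaves = {x.label for x in _descendants(n) if x.is_leaf}
            if not any(states.get(l) == 1 for l in n_leaves):
                candidates.append(n)
        found: int | None = None
        for r in range(len(candidates) + 1):
            if best is not None and 1 + r >= best:
                break
            for combo in itertools.combinations(candidates, r):
                if consistent(gain, leaves_under, {n.label for n in combo}):
                    found = 1 + r
                    break
            if found is not None:
                break
        if found is not None and (best is None or found < best):
            best = found
    return best


# ---------------------------------------------------------------------------
# Tree shapes
# ---------------------------------------------------------------------------


def rooted_binary_shapes(n_leaves: int) -> list[str]:
    """Newick strings for every rooted binary tree shape with n leaves.

    Leaves are labelled L1..Ln left to right (shape enumeration; leaf
    relabelling invariance is checked separately).
    """

    def shapes(n: int) -> list[str]:
        if n == 1:
            return ["*"]
        out = []
        for i in range(1, n // 2 + 1):
            left = shapes(i)
            right = shapes(n - i)
            if i == n - i:
                for a_idx, a in enumerate(left):
                    for b in right[a_idx:]:
                        out.append(f"({a},{b})")
            else:
                for a in left:
                    for b in right:
                        out.append(f"({a},{b})")
        return out

    results = []
    for skeleton in shapes(n_leaves):
        label = iter(range(1, n_leaves + 1))
        newick = "".join(
            f"L{next(label)}" if ch == "*" else ch for ch in skeleton
        )
        results.append(newick + ";")
    return results


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary tree by sequential joining, with leaf labels T1..Tn."""
    nodes = [f"T{i+1}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
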