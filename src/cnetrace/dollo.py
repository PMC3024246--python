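"""Most-parsimonious single-origin (Dollo) gain/loss reconstruction.

Under Dollo parsimony a binary character (a CNE, a gene) arises exactly
once and may be lost independently any number of times; the most
parsimonious history minimizes ``1 + number_of_losses``.  Re-gain of a
homologous element is treated as biologically implausible.

For each character the gain is placed on the stem branch above the most
recent common ancestor of the taxa observed present, then raised toward
the root across any sibling subtrees whose leaves are all unknown (``?``)
— this costs nothing and resolves ties toward presence in the parent,
which is how characters conserved in every sequenced species but
unscorable in one lineage map to the root stem.  Losses are the roots of
the maximal subtrees under the gain node whose observed leaves are all
absent; ``?`` leaves are absorbed into whichever state avoids an extra
event.

Characters whose origin is known a priori — paralogs born at a dated
whole-genome duplication — may be pinned to their origin branch via
``forced_gains``; this also admits characters absent from every extant
leaf (gained then lost everywhere), which are otherwise flagged vacuous
and skipped.

Branches are identified by the label of their child node; the branch
above the root is the root stem and carries the root's label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io import CharacterMatrix, SpeciesTree, TreeNode

__all__ = [
    "CharacterHistory",
    "DolloReconstruction",
    "dollo_reconstruct",
    "fitch_events",
    "list_synapomorphies",
    "event_report",
    "annotated_newick",
]


@dataclass(frozen=True)
class CharacterHistory:
    """Single-gain history of one character on the tree."""

    character: str
    gain_branch: str
    loss_branches: frozenset[str]
    node_states: Mapping[str, int]

    @property
    def n_events(self) -> int:
        return 1 + len(self.loss_branches)


@dataclass(frozen=True)
class DolloReconstruction:
    """Per-character gain/loss histories plus the tree they live on."""

    tree: SpeciesTree
    histories: tuple[CharacterHistory, ...]
    vacuous: tuple[str, ...] = ()

    @property
    def total_events(self) -> int:
        return sum(h.n_events for h in self.histories)

    def history(self, character: str) -> CharacterHistory:
        for h in self.histories:
            if h.character == character:
                return h
        raise KeyError(f"no reconstruction for character {character!r}")


def _single_character(
    tree: SpeciesTree,
    states: Mapping[str, int | None],
    forced_gain: str | None,
) -> tuple[str, frozenset[str], dict[str, int]] | None:
    present = [t for t, s in states.items() if s == 1]

    # per-node observed summary over the leaves below it
    has1: dict[str, bool] = {}
    has0: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = states.get(node.label)
            has1[node.label] = s == 1
            has0[node.label] = s == 0
        else:
            has1[node.label] = any(has1[c.label] for c in node.children)
            has0[node.label] = any(has0[c.label] for c in node.children)

    if forced_gain is not None:
        gain = tree.node(forced_gain)
        outside = [
            t for t in present if t not in tree.leafset(gain.label)
        ]
        if outside:
            raise ValueError(
                f"forced gain on {forced_gain!r} excludes present taxa {sorted(outside)}"
            )
    else:
        if not present:
            return None  # vacuous
        gain = tree.mrca(present)
        # raise the gain while every sibling subtree is observation-free
        while gain.parent is not None:
            parent = gain.parent
            if any(
                has1[sib.label] or has0[sib.label]
                for sib in parent.children
                if sib is not gain
            ):
                break
            gain = parent

    # losses: roots of maximal all-absent subtrees under the gain node
    losses: list[str] = []

    def all_absent(label: str) -> bool:
        return not has1[label]

    stack = [gain]
    while stack:
        node = stack.pop()
        if all_absent(node.label):
            if has0[node.label]:
                losses.append(node.label)
            # subtrees of pure '?' absorb the parent's state: no event
        else:
            stack.extend(node.children)

    # inferred state per node: present iff under the gain with no loss above
    node_states: dict[str, int] = {}
    loss_set = frozenset(losses)

    def fill(node: TreeNode, state: int) -> None:
        if node.label in loss_set:
            state = 0
        node_states[node.label] = state
        for child in node.children:
            fill(child, state)

    fill(tree.root, 0)
    fill(gain, 1)
    return gain.label, loss_set, node_states


def dollo_reconstruct(
    matrix: CharacterMatrix,
    tree: SpeciesTree,
    forced_gains: Mapping[str, str] | None = None,
) -> DolloReconstruction:
    """Reconstruct every character of the matrix on the tree.

    Raises if a matrix taxon is absent from the tree.  Characters with no
    observed presence and no forced gain are flagged vacuous and skipped.
    """
    leaf_labels = set(tree.leaf_labels)
    missing = [t for t in matrix.taxa if t not in leaf_labels]
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    forced_gains = dict(forced_gains or {})
    for char, branch in forced_gains.items():
        if not tree.has_node(branch):
            raise ValueError(f"forced gain branch {branch!r} not in tree")

    histories: list[CharacterHistory] = []
    vacuous: list[str] = []
    for char in matrix.characters:
        states = matrix.column(char)
        result = _single_character(tree, states, forced_gains.get(char))
        if result is None:
            vacuous.append(char)
            continue
        gain, losses, node_states = result
        histories.append(
            CharacterHistory(
                character=char,
                gain_branch=gain,
                loss_branches=losses,
                node_states=node_states,
            )
        )
    return DolloReconstruction(
        tree=tree, histories=tuple(histories), vacuous=tuple(vacuous)
    )


def fitch_events(matrix: CharacterMatrix, tree: SpeciesTree) -> dict[str, int]:
    """Unrestricted-parsimony (Fitch) change counts, for comparison only.

    Returns the minimum number of state changes per character, with no
    single-origin restriction.  ``?`` leaves are unconstrained.
    """
    counts: dict[str, int] = {}
    for char in matrix.characters:
        states = matrix.column(char)
        changes = 0
        sets: dict[str, set[int]] = {}
        for node in tree.postorder():
            if node.is_leaf:
                s = states.get(node.label)
                sets[node.label] = {0, 1} if s is None else {s}
            else:
                inter = set([0, 1])
                for c in node.children:
                    inter &= sets[c.label]
                if inter:
                    sets[node.label] = inter
                else:
                    union: set[int] = set()
                    for c in node.children:
                        union |= sets[c.label]
                    sets[node.label] = union
                    changes += 1
        counts[char] = changes
    return counts


def list_synapomorphies(rec: DolloReconstruction, branch: str) -> list[str]:
    """Characters whose gain maps to the given branch, in matrix order."""
    if not rec.tree.has_node(branch):
        raise KeyError(f"unknown branch {branch!r}")
    return [h.character for h in rec.histories if h.gain_branch == branch]


def event_report(rec: DolloReconstruction) -> pd.DataFrame:
    """Per-branch table of gained and lost characters (preorder rows)."""
    gained: dict[str, list[str]] = {}
    lost: dict[str, list[str]] = {}
    for h in rec.histories:
        gained.setdefault(h.gain_branch, []).append(h.character)
        for b in sorted(h.loss_branches):
            lost.setdefault(b, []).append(h.character)
    rows = []
    for node in rec.tree.preorder():
        rows.append(
            {
                "branch": node.label,
                "gained": ",".join(gained.get(node.label, [])),
                "lost": ",".join(lost.get(node.label, [])),
                "n_gains": len(gained.get(node.label, [])),
                "n_losses": len(lost.get(node.label, [])),
            }
        )
    return pd.DataFrame(rows)


def annotated_newick(rec: DolloReconstruction) -> str:
    """Newick with per-branch event counts in node comments."""
    report = event_report(rec).set_index("branch")

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")" + node.label
        g = int(report.at[node.label, "n_gains"])
        l = int(report.at[node.label, "n_losses"])
        if g or l:
            s += f"[&gains={g},losses={l}]"
        if node.length is not None:
            s += f":{node.length:g}"
        return s

    return render(rec.tree.root) + ";"
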