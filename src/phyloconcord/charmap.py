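"""Maximum-parsimony mapping of discrete morphological characters.

Characters are unordered (Fitch-type) multistate; ``?`` marks missing
observations. The minimum step count is obtained by unit-cost dynamic
programming over the rooted tree, which reduces to the classic Fitch
pass on binary trees and stays exact on polytomies. Ambiguous ancestral
states are resolved two ways: ACCTRAN accelerates changes toward the
root (favoring early gains with later reversals) and DELTRAN delays
them toward the tips (favoring parallel gains); both realizations
always carry exactly the minimum number of steps. Remaining ties are
broken by the smallest state in a fixed ordering, so all outputs are
deterministic.

Internal branches are identified by the leaf set of the child node
("clade key"), which is stable across traversals.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .treeio import Tree

MISSING = "?"
_INF = float("inf")


class CharacterError(ValueError):
    pass


@dataclass
class CharacterMatrix:
    """Rectangular taxon-by-character matrix of discrete states."""

    taxa: list[str]
    characters: list[str]
    states: dict[tuple[str, str], str]  # (taxon, character) -> state or "?"

    def __post_init__(self) -> None:
        for t in self.taxa:
            for c in self.characters:
                if (t, c) not in self.states:
                    raise CharacterError(f"matrix not rectangular: missing ({t},{c})")
        for c in self.characters:
            if not self.observed_states(c):
                raise CharacterError(f"character {c!r} has zero observed states")

    def observed_states(self, character: str) -> list[str]:
        return sorted(
            {
                self.states[(t, character)]
                for t in self.taxa
                if self.states[(t, character)] != MISSING
            }
        )

    def column(self, character: str) -> dict[str, str]:
        return {t: self.states[(t, character)] for t in self.taxa}

    @classmethod
    def from_tsv(cls, path: str) -> "CharacterMatrix":
        """Rows = taxa, first column ``taxon``, remaining columns = characters."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            characters = [c for c in reader.fieldnames if c != "taxon"]
            taxa, states = [], {}
            for row in reader:
                taxon = row["taxon"]
                taxa.append(taxon)
                for c in characters:
                    states[(taxon, c)] = (row[c] or MISSING).strip() or MISSING
        return cls(taxa=taxa, characters=characters, states=states)


@dataclass
class AncestralStateMap:
    character: str
    method: str  # "acctran" | "deltran"
    node_states: dict[frozenset, str]  # clade key -> state (leaves included)
    total_steps: int
    change_list: list[tuple[frozenset, str, str]]  # (child clade key, from, to)


def _char_states(
    character: Mapping[str, str], tree: Tree
) -> tuple[dict[str, str], list[str]]:
    """Leaf state lookup restricted to the tree, with the state universe."""
    lookup = {}
    for leaf in tree.leaves():
        state = character.get(leaf.taxon, MISSING)
        lookup[leaf.taxon] = state
    universe = sorted({s for s in lookup.values() if s != MISSING})
    if not universe:
        raise CharacterError("character has zero observed states on this tree")
    return lookup, universe


def _down_pass(
    tree: Tree, leaf_states: Mapping[str, str], states: Sequence[str]
) -> dict[int, dict[str, float]]:
    """Unit-cost minimum subtree cost per (node, state)."""
    cost: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            obs = leaf_states[node.taxon]
            cost[id(node)] = {
                s: (0.0 if obs in (s, MISSING) else _INF) for s in states
            }
        else:
            here = {}
            for s in states:
                total = 0.0
                for child in node.children:
                    ccost = cost[id(child)]
                    total += min(
                        ccost[t] + (0.0 if t == s else 1.0) for t in states
                    )
                here[s] = total
            cost[id(node)] = here
    return cost


def fitch_length(tree: Tree, character: Mapping[str, str]) -> int:
    """Minimum number of state changes for one character on the tree.

    ``character`` maps taxon -> state ("?" or absent = missing, which
    contributes the full state set at that leaf).
    """
    leaf_states, states = _char_states(character, tree)
    cost = _down_pass(tree, leaf_states, states)
    return int(min(cost[id(tree.root)].values()))


def _resolve(
    tree: Tree,
    character: Mapping[str, str],
    accelerate: bool,
    method: str,
    character_id: str = "",
) -> AncestralStateMap:
    leaf_states, states = _char_states(character, tree)
    cost = _down_pass(tree, leaf_states, states)

    assignment: dict[int, str] = {}
    root_costs = cost[id(tree.root)]
    best = min(root_costs.values())
    assignment[id(tree.root)] = min(
        s for s in states if root_costs[s] == best
    )

    for node in tree.preorder():
        if node is tree.root:
            continue
        p = assignment[id(node.parent)]
        ncost = cost[id(node)]
        total_best = min(ncost[s] + (0.0 if s == p else 1.0) for s in states)
        optimal = [
            s for s in states if ncost[s] + (0.0 if s == p else 1.0) == total_best
        ]
        if accelerate:
            changed = [s for s in optimal if s != p]
            assignment[id(node)] = changed[0] if changed else optimal[0]
        else:
            assignment[id(node)] = p if p in optimal else optimal[0]

    node_states: dict[frozenset, str] = {}
    changes: list[tuple[frozenset, str, str]] = []
    for node in tree.preorder():
        key = node.leaf_taxa()
        node_states[key] = assignment[id(node)]
        if node is not tree.root:
            p, s = assignment[id(node.parent)], assignment[id(node)]
            if p != s:
                changes.append((key, p, s))
    return AncestralStateMap(
        character=character_id,
        method=method,
        node_states=node_states,
        total_steps=len(changes),
        change_list=changes,
    )


def acctran(
    tree: Tree, character: Mapping[str, str], character_id: str = ""
) -> AncestralStateMap:
    """Root-ward (accelerated) resolution of the optimal reconstruction."""
    return _resolve(tree, character, accelerate=True, method="acctran",
                    character_id=character_id)


def deltran(
    tree: Tree, character: Mapping[str, str], character_id: str = ""
) -> AncestralStateMap:
    """Tip-ward (delayed) resolution of the optimal reconstruction."""
    return _resolve(tree, character, accelerate=False, method="deltran",
                    character_id=character_id)


def map_diagnoses(
    tree: Tree,
    matrix: CharacterMatrix,
    groups: Mapping[str, Iterable[str]],
) -> dict[str, dict[str, list[str]]]:
    """Stem-branch synapomorphy candidates per group.

    For every group monophyletic on the tree (others are skipped with a
    warning), lists the characters whose ACCTRAN / DELTRAN
    reconstruction places a change on the group's stem branch.
    """
    out: dict[str, dict[str, list[str]]] = {}
    recon = {
        c: (
            acctran(tree, matrix.column(c), c),
            deltran(tree, matrix.column(c), c),
        )
        for c in matrix.characters
    }
    for name, tip_set in groups.items():
        present = frozenset(tip_set) & tree.tips
        node = tree.find_clade(present) if present else None
        if node is None or node is tree.root:
            warnings.warn(
                f"group {name!r} is not a proper clade on the tree; skipped",
                stacklevel=2,
            )
            continue
        key = node.leaf_taxa()
        entry = {"acctran": [], "deltran": []}
        for c in matrix.characters:
            acc, dele = recon[c]
            if any(k == key for k, _, _ in acc.change_list):
                entry["acctran"].append(c)
            if any(k == key for k, _, _ in dele.change_list):
                entry["deltran"].append(c)
        out[name] = entry
    return out


def write_state_map(asm: AncestralStateMap, path: str) -> None:
    """Per-node state TSV; nodes keyed by their sorted clade tip list."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["character", "method", "clade", "state"])
        for key in sorted(asm.node_states, key=lambda k: (len(k), tuple(sorted(k)))):
            w.writerow(
                [asm.character, asm.method, ",".join(sorted(key)), asm.node_states[key]]
            )
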