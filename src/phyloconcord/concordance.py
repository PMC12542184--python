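"""Tree concordance factors (tCFs).

For every internal branch of a reference species tree, each tree in a
collection of alternative species trees is classified as *concordant*
(it recovers the same unrooted bipartition after pruning to the shared
taxa), *conflicting* (it contains an incompatible split), or
*uninformative* (the branch degenerates after pruning, or the tree is
compatible but unresolved, e.g. a polytomy). The most frequent single
conflicting split is reported as the branch's *best alternative*; the
remaining conflicts are pooled. Each whole tree plays the role a gene
tree plays in gene concordance factors, so the fractions are always
multiples of 1/n_trees and the uninformative trees stay in the
denominator.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._util import round_half_away
from .treeio import Bipartition, Tree


VERDICT_CONCORDANT = "concordant"
VERDICT_CONFLICTING = "conflicting"
VERDICT_UNINFORMATIVE_MISSING = "uninformative_missing"
VERDICT_UNINFORMATIVE_UNRESOLVED = "uninformative_unresolved"

_UNINFORMATIVE = {VERDICT_UNINFORMATIVE_MISSING, VERDICT_UNINFORMATIVE_UNRESOLVED}


def classify_tree_for_branch(
    reference_split: Bipartition, tree: Tree
) -> tuple[str, Optional[Bipartition]]:
    """Classify one input tree against one reference branch.

    Returns (verdict, attributed_split). The attributed split is the
    conflicting tree split with the largest overlap with the reference
    branch's clade side (ties broken by canonical split order); it is
    None for non-conflicting verdicts.
    """
    shared = reference_split.universe & tree.tips
    restricted = reference_split.restrict(shared)
    if restricted is None:
        return VERDICT_UNINFORMATIVE_MISSING, None

    tree_splits = set()
    for split in tree.bipartitions():
        r = split.restrict(shared)
        if r is not None:
            tree_splits.add(r)

    if restricted in tree_splits:
        return VERDICT_CONCORDANT, None

    conflicts = [s for s in tree_splits if restricted.conflicts_with(s)]
    if not conflicts:
        return VERDICT_UNINFORMATIVE_UNRESOLVED, None

    clade = restricted.smaller_side()
    conflicts.sort(
        key=lambda s: (
            -max(len(s.side_a & clade), len(s.side_b & clade)),
            s.sort_key(),
        )
    )
    return VERDICT_CONFLICTING, conflicts[0]


@dataclass
class BranchConcordance:
    """Per-branch tCF record over a tree collection."""

    reference_bipartition: Bipartition
    n_trees: int
    n_concordant: int
    n_best_alternative: int
    best_alternative_split: Optional[Bipartition]
    n_other_conflict: int
    n_uninformative: int
    per_tree_verdicts: list[tuple[str, str]] = field(default_factory=list)

    @property
    def concordant_fraction(self) -> float:
        return self.n_concordant / self.n_trees

    @property
    def best_alternative_fraction(self) -> float:
        return self.n_best_alternative / self.n_trees

    @property
    def other_conflict_fraction(self) -> float:
        return self.n_other_conflict / self.n_trees

    @property
    def uninformative_fraction(self) -> float:
        return self.n_uninformative / self.n_trees

    @property
    def concordant_percent(self) -> int:
        """Integer display percent, halves away from zero (92 for 12/13)."""
        return int(round_half_away(100.0 * self.concordant_fraction))

    @property
    def best_alternative_percent(self) -> int:
        return int(round_half_away(100.0 * self.best_alternative_fraction))


@dataclass
class ConcordanceReport:
    branches: list[BranchConcordance]
    tree_ids: list[str]

    @property
    def n_trees(self) -> int:
        return len(self.tree_ids)

    def branch_for(self, split: Bipartition) -> BranchConcordance:
        for b in self.branches:
            if b.reference_bipartition == split:
                return b
        raise KeyError(f"no branch record for {split.notation()}")


def tree_concordance(
    reference: Tree,
    inputs: Sequence[Tree],
    tree_ids: Optional[Sequence[str]] = None,
) -> ConcordanceReport:
    """Aggregate per-branch verdicts of every input tree.

    The denominator of every fraction is the full collection size;
    uninformative trees are not dropped.
    """
    if not inputs:
        raise ValueError("input tree collection is empty")
    if len(reference.tips) < 4:
        raise ValueError("reference tree needs >= 4 tips")
    if tree_ids is None:
        tree_ids = [f"tree{i + 1:02d}" for i in range(len(inputs))]
    if len(tree_ids) != len(inputs):
        raise ValueError("tree_ids length does not match inputs")

    branches = []
    for ref_split in sorted(reference.bipartitions(), key=Bipartition.sort_key):
        verdicts: list[tuple[str, str]] = []
        conflict_counter: Counter[Bipartition] = Counter()
        n_conc = n_unin = 0
        for tid, tree in zip(tree_ids, inputs):
            verdict, attributed = classify_tree_for_branch(ref_split, tree)
            verdicts.append((tid, verdict))
            if verdict == VERDICT_CONCORDANT:
                n_conc += 1
            elif verdict in _UNINFORMATIVE:
                n_unin += 1
            else:
                conflict_counter[attributed] += 1
        if conflict_counter:
            best_split, best_n = min(
                conflict_counter.items(), key=lambda kv: (-kv[1], kv[0].sort_key())
            )
            n_other = sum(conflict_counter.values()) - best_n
        else:
            best_split, best_n, n_other = None, 0, 0
        branches.append(
            BranchConcordance(
                reference_bipartition=ref_split,
                n_trees=len(inputs),
                n_concordant=n_conc,
                n_best_alternative=best_n,
                best_alternative_split=best_split,
                n_other_conflict=n_other,
                n_uninformative=n_unin,
                per_tree_verdicts=verdicts,
            )
        )
    return ConcordanceReport(branches=branches, tree_ids=list(tree_ids))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_COLUMNS = [
    "branch",
    "n_trees",
    "n_concordant",
    "n_best_alternative",
    "n_other_conflict",
    "n_uninformative",
    "concordant_fraction",
    "best_alternative_fraction",
    "other_conflict_fraction",
    "uninformative_fraction",
    "concordant_percent",
    "best_alternative_split",
    "per_tree_verdicts",
]


def render_concordance(
    report: ConcordanceReport, out: str, plots: Optional[str] = None
) -> None:
    """Write the per-branch TSV (and, optionally, one pie chart per branch)."""
    if not report.branches:
        raise ValueError("empty concordance report")
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for b in report.branches:
            w.writerow(
                [
                    b.reference_bipartition.notation(),
                    b.n_trees,
                    b.n_concordant,
                    b.n_best_alternative,
                    b.n_other_conflict,
                    b.n_uninformative,
                    repr(b.concordant_fraction),
                    repr(b.best_alternative_fraction),
                    repr(b.other_conflict_fraction),
                    repr(b.uninformative_fraction),
                    b.concordant_percent,
                    b.best_alternative_split.notation()
                    if b.best_alternative_split
                    else "",
                    ";".join(f"{tid}={v}" for tid, v in b.per_tree_verdicts),
                ]
            )
    if plots:
        plot_pies(report, plots)


def read_concordance_tsv(path: str) -> ConcordanceReport:
    """Re-read a rendered report; inverse of :func:`render_concordance`."""
    branches = []
    tree_ids: list[str] = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            verdicts = [
                tuple(item.split("=", 1)) for item in row["per_tree_verdicts"].split(";")
            ]
            if not tree_ids:
                tree_ids = [tid for tid, _ in verdicts]
            branches.append(
                BranchConcordance(
                    reference_bipartition=Bipartition.from_notation(row["branch"]),
                    n_trees=int(row["n_trees"]),
                    n_concordant=int(row["n_concordant"]),
                    n_best_alternative=int(row["n_best_alternative"]),
                    best_alternative_split=(
                        Bipartition.from_notation(row["best_alternative_split"])
                        if row["best_alternative_split"]
                        else None
                    ),
                    n_other_conflict=int(row["n_other_conflict"]),
                    n_uninformative=int(row["n_uninformative"]),
                    per_tree_verdicts=verdicts,
                )
            )
    return ConcordanceReport(branches=branches, tree_ids=tree_ids)


def plot_pies(report: ConcordanceReport, outdir: str) -> list[str]:
    """One pie per branch: concordant (blue), best alternative (green),
    other conflict (red), uninformative (grey)."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i, b in enumerate(report.branches, start=1):
        fig, ax = plt.subplots(figsize=(2.2, 2.2))
        counts = [
            b.n_concordant,
            b.n_best_alternative,
            b.n_other_conflict,
            b.n_uninformative,
        ]
        colors = ["#2166ac", "#1b7837", "#b2182b", "#bdbdbd"]
        ax.pie(counts, colors=colors, startangle=90, counterclock=False)
        ax.set_title(f"branch {i}: {b.concordant_percent}%", fontsize=8)
        path = os.path.join(outdir, f"branch_{i:03d}.png")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
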