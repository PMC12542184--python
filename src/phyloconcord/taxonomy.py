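"""Taxonomy registry and monophyly evaluation.

The registry maps genera to families (one family per genus within a
classification scheme) and carries per-genus valid-species counts, so
family diversity lines ("327 species in 27 genera") are recomputable.
Monophyly of a named group on a tree is a purely unrooted question:
the group is monophyletic iff the group-versus-rest split exists in the
tree (equivalently, the group is a clade under some rooting). Groups
reduced to a single tip in a tree are *monotypic* — rendered as a
checkmark but kept distinct internally; groups absent from a tree are
*not evaluable* and render as a dash.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .treeio import Bipartition, Tree, normalize_taxon

MONOPHYLETIC = "monophyletic"
NON_MONOPHYLETIC = "non_monophyletic"
MONOTYPIC = "monotypic"
NOT_EVALUABLE = "not_evaluable"

_CHECKMARK = {
    MONOPHYLETIC: "✓",
    MONOTYPIC: "✓",
    NON_MONOPHYLETIC: "✗",
    NOT_EVALUABLE: "—",
}


@dataclass
class TaxonomyMap:
    """Genus-to-family registry for one classification scheme."""

    scheme_id: str
    genus_to_family: dict[str, str]
    species_counts: dict[str, int] = field(default_factory=dict)
    tip_to_genus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genus, count in self.species_counts.items():
            if count < 0:
                raise ValueError(f"negative species count for genus {genus}")

    @classmethod
    def from_tsv(cls, path: str, scheme: Optional[str] = None) -> "TaxonomyMap":
        """Load a registry from a TSV with columns genus, family,
        species_count and (optionally) scheme; rows of other schemes are
        skipped when ``scheme`` is given."""
        g2f: dict[str, str] = {}
        counts: dict[str, int] = {}
        seen_scheme = None
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                row_scheme = row.get("scheme") or "default"
                if scheme is not None and row_scheme != scheme:
                    continue
                seen_scheme = seen_scheme or row_scheme
                genus = row["genus"].strip()
                family = row["family"].strip()
                if genus in g2f and g2f[genus] != family:
                    raise ValueError(
                        f"genus {genus} mapped to two families within scheme"
                    )
                g2f[genus] = family
                if row.get("species_count"):
                    counts[genus] = int(row["species_count"])
        if not g2f:
            raise ValueError(f"no rows loaded from {path} (scheme={scheme!r})")
        return cls(scheme_id=scheme or seen_scheme, genus_to_family=g2f,
                   species_counts=counts)

    # -- resolution --------------------------------------------------------

    def genus_of_tip(self, tip: str) -> str:
        """Tip -> genus; explicit table first, else the first underscore
        token of the normalized tip label."""
        tip = normalize_taxon(tip)
        if tip in self.tip_to_genus:
            return self.tip_to_genus[tip]
        return tip.split("_", 1)[0]

    def family_of_genus(self, genus: str) -> Optional[str]:
        return self.genus_to_family.get(genus)

    def family_of_tip(self, tip: str) -> Optional[str]:
        return self.family_of_genus(self.genus_of_tip(tip))

    @property
    def families(self) -> list[str]:
        return sorted(set(self.genus_to_family.values()))

    def family_groups(self, tips: Iterable[str]) -> dict[str, frozenset]:
        """Partition ``tips`` into family-named groups; unmapped tips are
        dropped (they belong to no group of this scheme)."""
        groups: dict[str, set] = {}
        for tip in tips:
            fam = self.family_of_tip(tip)
            if fam is not None:
                groups.setdefault(fam, set()).add(normalize_taxon(tip))
        return {k: frozenset(v) for k, v in groups.items()}

    # -- diversity ---------------------------------------------------------

    def diversity_totals(self) -> pd.DataFrame:
        """Per-family genus and species totals (the 'Diversity.' lines)."""
        rows = []
        for family in self.families:
            genera = [g for g, f in self.genus_to_family.items() if f == family]
            rows.append(
                {
                    "family": family,
                    "n_genera": len(genera),
                    "n_species": sum(self.species_counts.get(g, 0) for g in genera),
                }
            )
        return pd.DataFrame(rows).set_index("family")


def load_stomiiformes_taxonomy() -> TaxonomyMap:
    """The bundled eight-family Stomiiformes registry (genus -> family,
    per-genus valid species counts from the family accounts)."""
    path = resources.files("phyloconcord.data") / "stomiiformes_taxonomy.tsv"
    return TaxonomyMap.from_tsv(str(path), scheme="this-study-8")


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

def group_status(tree: Tree, group_tips: Iterable[str]) -> str:
    """Monophyly status of a named tip set on one tree (rooting-invariant)."""
    present = frozenset(normalize_taxon(t) for t in group_tips) & tree.tips
    if len(present) == 0:
        return NOT_EVALUABLE
    if len(present) == 1:
        return MONOTYPIC
    rest = tree.tips - present
    if len(rest) <= 1:
        # The whole tree, or all-but-one tip: a clade under some rooting.
        return MONOPHYLETIC
    split = Bipartition(present, rest)
    return MONOPHYLETIC if split in tree.bipartitions() else NON_MONOPHYLETIC


def monophyly_matrix(
    trees: Sequence[Tree],
    groups: Mapping[str, Iterable[str]],
    tree_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Status of every (group, tree) pair: rows = groups, columns = trees."""
    if tree_ids is None:
        tree_ids = [f"tree{i + 1:02d}" for i in range(len(trees))]
    if len(tree_ids) != len(trees):
        raise ValueError("tree_ids length does not match trees")
    names = list(groups)
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    data = {
        tid: [group_status(tree, groups[name]) for name in names]
        for tid, tree in zip(tree_ids, trees)
    }
    return pd.DataFrame(data, index=names)


def render_matrix_markdown(matrix: pd.DataFrame) -> str:
    """Checkmark rendering: monophyletic/monotypic -> ✓, non -> ✗, absent -> —."""
    header = "| group | " + " | ".join(matrix.columns) + " |"
    sep = "|" + "---|" * (len(matrix.columns) + 1)
    lines = [header, sep]
    for name, row in matrix.iterrows():
        cells = " | ".join(_CHECKMARK[v] for v in row)
        lines.append(f"| {name} | {cells} |")
    return "\n".join(lines) + "\n"


def write_matrix_tsv(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", index_label="group")
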