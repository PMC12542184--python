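"""Synthetic inputs for every stage of the pipeline.

Three generators, all fully deterministic under a fixed integer seed
(one RNG stream per operation, so adding generators never shifts the
draws of existing ones):

* discordant tree collections with exact planted per-branch concordance
  counts, discordance being introduced by a nearest-neighbor
  interchange (NNI) across the focal branch only — an NNI across an
  internal edge replaces exactly that edge's bipartition and no other;
* barcode label sets on a guide tree with planted misidentification
  (name swapped to another sampled species), nonspecific-name and
  rogue-sequence fates, with a ground-truth table;
* multi-locus alignment sets with controlled lengths, per-locus taxon
  coverage, cell-level missingness, anchor loci with full coverage, and
  optionally a forced number of low-coverage loci.

The default shapes emulate a phylogenomic study of a mid-size fish
order: 13-tree collections, ~64-taxon panels, 936-locus sets with nine
anchors and a mean of ~20 species per locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import stream
from .qc import SequenceLabel
from .supermatrix import LocusAlignment
from .taxonomy import TaxonomyMap
from .treeio import Bipartition, Node, Tree


# ---------------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------------

def simulate_reference_tree(
    n_taxa: int, seed: int, taxon_prefix: str = "T"
) -> Tree:
    """Uniform random unrooted binary topology via sequential attachment.

    Leaf k+1 is attached to one of the 2k-3 edges of the growing tree
    chosen uniformly, which makes every labeled topology equiprobable.
    Supports are set to 100; the tree is stored with a trifurcating
    root (the natural unrooted representation).
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    rng = stream(seed, "reference_tree")
    taxa = [f"{taxon_prefix}{i + 1:03d}" for i in range(n_taxa)]

    # Start from the 3-taxon star; edges are (parent, child) pairs.
    root = Node()
    for t in taxa[:3]:
        root.add(Node(t))
    edges = [(root, c) for c in root.children]
    for t in taxa[3:]:
        idx = int(rng.integers(len(edges)))
        parent, child = edges[idx]
        mid = Node()
        pos = parent.children.index(child)
        parent.children[pos] = mid
        mid.parent = parent
        mid.add(child)
        leaf = mid.add(Node(t))
        edges[idx] = (parent, mid)
        edges.append((mid, child))
        edges.append((mid, leaf))
    tree = Tree(root, rooted=False)
    for node in tree.preorder():
        if not node.is_leaf and node is not tree.root:
            node.support = 100.0
    return tree


def _nni_at(tree: Tree, clade: frozenset, which: int = 0) -> None:
    """In place: NNI across the internal edge whose child clade is ``clade``.

    Swaps child ``which % d`` of the lower node with the first available
    sibling subtree; only the focal edge's bipartition changes.
    """
    node = tree.find_clade(clade)
    if node is None:
        node = tree.find_clade(tree.tips - clade)
    if node is None or node.is_leaf or node is tree.root:
        raise ValueError(f"no internal edge with clade {sorted(clade)[:5]}...")
    parent = node.parent
    siblings = [c for c in parent.children if c is not node]
    if not siblings:
        raise ValueError("edge has no exchangeable sibling subtree")
    a = node.children[which % len(node.children)]
    s = siblings[0]
    ai, si = node.children.index(a), parent.children.index(s)
    node.children[ai], parent.children[si] = s, a
    s.parent, a.parent = node, parent


@dataclass
class PlantedTruth:
    """Ground truth for a simulated tree collection."""

    table: pd.DataFrame  # columns: tree_id, branch, concordant
    planted: dict[Bipartition, int]

    def planted_count(self, split: Bipartition) -> int:
        return self.planted[split]


def simulate_tree_collection(
    reference: Tree,
    n_trees: int,
    planted: Optional[Mapping[Union[Bipartition, frozenset], int]] = None,
    nni_moves: int = 0,
    seed: int = 0,
    shared_alternative: bool = True,
) -> tuple[list[Tree], PlantedTruth]:
    """A collection of species trees with controlled branch concordance.

    ``planted`` maps reference branches (Bipartition or child clade tip
    set) to the exact number of trees that must keep them; the others
    receive one NNI across the focal branch. Disrupted trees are chosen
    at random; with ``shared_alternative`` the same subtree exchange is
    used in every disrupted tree, so they share a single alternative
    bipartition. With ``nni_moves`` > 0 (and no planting), each tree is
    instead perturbed by that many random NNIs.
    """
    universe = reference.tips
    ref_splits = reference.bipartitions()

    norm_planted: dict[Bipartition, int] = {}
    for key, count in (planted or {}).items():
        split = (
            key
            if isinstance(key, Bipartition)
            else Bipartition(frozenset(key), universe - frozenset(key))
        )
        if split not in ref_splits:
            raise ValueError(f"planted branch {split.notation()} not in reference")
        if not 0 <= count <= n_trees:
            raise ValueError(
                f"planted count {count} for {split.notation()} outside [0, {n_trees}]"
            )
        norm_planted[split] = count

    rng = stream(seed, "tree_collection")
    disrupted: dict[Bipartition, set[int]] = {}
    for split, count in norm_planted.items():
        picks = rng.choice(n_trees, size=n_trees - count, replace=False)
        disrupted[split] = set(int(i) for i in picks)

    trees: list[Tree] = []
    rows = []
    for j in range(n_trees):
        t = reference.clone()
        for split in sorted(norm_planted, key=Bipartition.sort_key):
            if j in disrupted[split]:
                clade = (
                    split.side_a
                    if reference.find_clade(split.side_a) is not None
                    else split.side_b
                )
                which = 0 if shared_alternative else int(rng.integers(2))
                _nni_at(t, clade, which)
        if nni_moves and not norm_planted:
            for _ in range(nni_moves):
                internal = [
                    s for s in t.bipartitions()
                ]
                if not internal:
                    break
                pick = internal[int(rng.integers(len(internal)))]
                clade = (
                    pick.side_a
                    if t.find_clade(pick.side_a) is not None
                    else pick.side_b
                )
                _nni_at(t, clade, int(rng.integers(2)))
        trees.append(t)
        for split in sorted(norm_planted, key=Bipartition.sort_key):
            rows.append(
                {
                    "tree_id": f"tree{j + 1:02d}",
                    "branch": split.notation(),
                    "concordant": j not in disrupted[split],
                }
            )
    truth = PlantedTruth(
        table=pd.DataFrame(rows, columns=["tree_id", "branch", "concordant"]),
        planted=norm_planted,
    )
    return trees, truth


# ---------------------------------------------------------------------------
# Barcode datasets
# ---------------------------------------------------------------------------

_FATES = ("ok", "mismatch", "nonspecific", "rogue")


@dataclass
class BarcodeTruth:
    table: pd.DataFrame  # sequence_id, species_true, reported_name, fate

    def count(self, fate: str) -> int:
        return int((self.table["fate"] == fate).sum())


def simulate_barcode_dataset(
    n_species: int,
    seqs_per_species: tuple[int, int] = (3, 8),
    rates: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    taxonomy: Optional[TaxonomyMap] = None,
) -> tuple[Tree, dict[str, SequenceLabel], BarcodeTruth]:
    """Guide tree plus label table with planted QC failures.

    Species names are drawn from the taxonomy registry's genera when one
    is given (epithets are synthetic), else from synthetic genera. Each
    species expands into a clade of 3-8 sequences (uniform). Error
    fates are assigned per sequence with the given probabilities:
    ``mismatch_rate`` (name swapped to another sampled species),
    ``nonspecific_rate`` ("Genus sp." or an order-level placeholder),
    ``rogue_rate`` (the tip is regrafted onto a deep backbone branch
    spanning at least two other species, keeping its correct name).
    """
    rates = dict(rates or {})
    m_rate = rates.get("mismatch_rate", 0.0)
    n_rate = rates.get("nonspecific_rate", 0.0)
    r_rate = rates.get("rogue_rate", 0.0)
    if min(m_rate, n_rate, r_rate) < 0 or m_rate + n_rate + r_rate > 1:
        raise ValueError("rates must be nonnegative and sum to <= 1")
    if n_species < 4:
        raise ValueError("need at least 4 species")

    rng = stream(seed, "barcode_dataset")

    # Species names.
    if taxonomy is not None:
        genera = sorted(taxonomy.genus_to_family)
    else:
        genera = [f"Genus{chr(65 + i % 26)}{i // 26 or ''}" for i in range(n_species)]
    species = []
    for i in range(n_species):
        genus = genera[i % len(genera)]
        species.append(f"{genus} v{i + 1:03d}")

    backbone = simulate_reference_tree(
        n_species, seed=int(rng.integers(2**31 - 1)), taxon_prefix="SP"
    )
    placeholder_to_species = {
        f"SP{i + 1:03d}": sp for i, sp in enumerate(species)
    }

    # Expand each species placeholder into a caterpillar clade of k tips.
    labels: dict[str, SequenceLabel] = {}
    truth_rows = []
    lo, hi = seqs_per_species
    tip_species: dict[str, str] = {}
    for leaf in list(backbone.leaves()):
        sp = placeholder_to_species[leaf.taxon]
        k = int(rng.integers(lo, hi + 1))
        genus, epithet = sp.split(" ", 1)
        ids = [f"{genus}_{epithet}_{i + 1:03d}" for i in range(k)]
        if k == 1:
            leaf.taxon = ids[0]
            tip_species[ids[0]] = sp
            continue
        leaf.taxon = None
        node = leaf
        for i, sid in enumerate(ids):
            tip_species[sid] = sp
            if i < k - 1 and k - i > 2:
                node.add(Node(sid))
                nxt = node.add(Node())
                node = nxt
            elif k - i == 2:
                node.add(Node(sid))
            else:
                node.add(Node(sid))
    guide = Tree(backbone.root, rooted=True)

    sequence_ids = sorted(tip_species)
    fates = rng.choice(
        len(_FATES),
        size=len(sequence_ids),
        p=[1 - m_rate - n_rate - r_rate, m_rate, n_rate, r_rate],
    )

    # Rogue regrafting targets: internal edges spanning >= 2 species.
    species_clades = {
        sp: frozenset(t for t, s in tip_species.items() if s == sp)
        for sp in species
    }

    def backbone_edges(tree: Tree) -> list[Node]:
        out = []
        for node in tree.preorder():
            if node is tree.root or node.is_leaf:
                continue
            clade = node.leaf_taxa()
            spanned = {tip_species[t] for t in clade}
            if len(spanned) >= 2 and not any(
                clade == c for c in species_clades.values()
            ):
                out.append(node)
        return out

    for sid, fate_idx in zip(sequence_ids, fates):
        fate = _FATES[fate_idx]
        sp = tip_species[sid]
        genus = sp.split(" ", 1)[0]
        reported = sp
        if fate == "mismatch":
            others = [s for s in species if s != sp]
            reported = others[int(rng.integers(len(others)))]
        elif fate == "nonspecific":
            reported = (
                "Stomiiformes sp."
                if rng.random() < 0.15
                else f"{genus} sp."
            )
        elif fate == "rogue":
            targets = backbone_edges(guide)
            if targets:
                leaf_node = next(
                    n for n in guide.leaves() if n.taxon == sid
                )
                parent = leaf_node.parent
                parent.children.remove(leaf_node)
                if len(parent.children) == 1 and parent is not guide.root:
                    only = parent.children[0]
                    gp = parent.parent
                    gp.children[gp.children.index(parent)] = only
                    only.parent = gp
                target = targets[int(rng.integers(len(targets)))]
                tp = target.parent
                mid = Node()
                tp.children[tp.children.index(target)] = mid
                mid.parent = tp
                mid.add(target)
                mid.add(leaf_node)
            else:
                fate = "ok"
        labels[sid] = SequenceLabel(
            sequence_id=sid, reported_name=reported, source="repository"
        )
        truth_rows.append(
            {
                "sequence_id": sid,
                "species_true": sp,
                "reported_name": reported,
                "fate": fate,
            }
        )
    guide = Tree(guide.root, rooted=True)  # re-validate after grafting
    truth = BarcodeTruth(
        table=pd.DataFrame(
            truth_rows,
            columns=["sequence_id", "species_true", "reported_name", "fate"],
        )
    )
    return guide, labels, truth


# ---------------------------------------------------------------------------
# Locus sets
# ---------------------------------------------------------------------------

@dataclass
class LocusSetConfig:
    """Shape parameters for a synthetic multi-locus alignment set.

    Defaults emulate an exon-capture phylogenomic matrix: 936 loci over
    a 64-taxon panel, nine full-coverage anchor exons, locus lengths of
    a few hundred bp, and a mean of about 20 species per locus.
    """

    n_loci: int = 936
    n_taxa: int = 64
    n_anchors: int = 9
    length_range: tuple[int, int] = (251, 420)
    lengths: Optional[Sequence[int]] = None  # overrides length_range
    coverage_range: tuple[int, int] = (6, 34)
    missing_rate: float = 0.0
    n_low_coverage: int = 0  # loci forced below 4 sequences


def simulate_locus_set(
    config: LocusSetConfig, seed: int
) -> tuple[list[LocusAlignment], list[str]]:
    """Random nucleotide loci; returns (loci, taxon_panel).

    Anchors (ids ``A0001``...) carry the full panel; ordinary loci
    (``L0001``...) draw a random taxon subset; the first
    ``n_low_coverage`` ordinary loci get 1-3 sequences. Missing cells
    are planted at ``missing_rate`` inside present sequences.
    """
    cfg = config
    if cfg.n_anchors > cfg.n_loci:
        raise ValueError("n_anchors exceeds n_loci")
    rng = stream(seed, "locus_set")
    panel = [f"T{i + 1:03d}" for i in range(cfg.n_taxa)]
    n_ordinary = cfg.n_loci - cfg.n_anchors
    if cfg.lengths is not None:
        if len(cfg.lengths) != cfg.n_loci:
            raise ValueError("lengths must have n_loci entries")
        lengths = list(cfg.lengths)
    else:
        lengths = [
            int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            for _ in range(cfg.n_loci)
        ]

    alphabet = np.array(list("ACGT"))

    def random_block(n_rows: int, n_cols: int) -> list[str]:
        draw = rng.integers(0, 4, size=(n_rows, n_cols))
        block = alphabet[draw]
        if cfg.missing_rate > 0:
            mask = rng.random((n_rows, n_cols)) < cfg.missing_rate
            block[mask] = "-"
        return ["".join(row) for row in block]

    loci: list[LocusAlignment] = []
    for a in range(cfg.n_anchors):
        L = lengths[a]
        rows = random_block(cfg.n_taxa, L)
        loci.append(
            LocusAlignment(
                locus_id=f"A{a + 1:04d}",
                sequences=dict(zip(panel, rows)),
                is_anchor=True,
            )
        )
    lo, hi = cfg.coverage_range
    lo, hi = min(lo, cfg.n_taxa), min(hi, cfg.n_taxa)
    for i in range(n_ordinary):
        L = lengths[cfg.n_anchors + i]
        if i < cfg.n_low_coverage:
            k = int(rng.integers(1, 4))
        else:
            k = int(rng.integers(lo, hi + 1))
        chosen = sorted(
            panel[j] for j in rng.choice(cfg.n_taxa, size=k, replace=False)
        )
        rows = random_block(k, L)
        loci.append(
            LocusAlignment(
                locus_id=f"L{i + 1:04d}", sequences=dict(zip(chosen, rows))
            )
        )
    return loci, panel
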