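"""Per-locus alignment statistics, filtering, concatenation, and the
anchor-replicated balanced partitioner.

Conventions: missing characters are ``-``, ``?`` and ``N`` (other IUPAC
ambiguity codes count as present); a parsimony-informative site is a
column with at least two distinct non-missing states each carried by at
least two sequences. Locus-level missingness is computed over the
sequences actually present in the locus; matrix-level missingness is
computed over the full taxon panel, with absent taxon-by-locus blocks
filled with ``-``. Partition-table coordinates are 1-based inclusive,
RAxML style.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._util import round_half_away

MISSING_CHARS = frozenset("-?N")


class AlignmentError(ValueError):
    pass


@dataclass
class LocusAlignment:
    """One locus: taxon -> aligned sequence (uppercase), equal lengths."""

    locus_id: str
    sequences: dict[str, str]
    is_anchor: bool = False

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"locus {self.locus_id}: no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {self.locus_id}: ragged alignment (lengths {sorted(lengths)})"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError(f"locus {self.locus_id}: zero-length alignment")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_fasta(
        cls, path: str, locus_id: Optional[str] = None, is_anchor: bool = False
    ) -> "LocusAlignment":
        from Bio import SeqIO

        seqs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")
        }
        if locus_id is None:
            locus_id = os.path.splitext(os.path.basename(path))[0]
        return cls(locus_id=locus_id, sequences=seqs, is_anchor=is_anchor)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for taxon in sorted(self.sequences):
                fh.write(f">{taxon}\n{self.sequences[taxon]}\n")


@dataclass(frozen=True)
class LocusStats:
    locus_id: str
    n_taxa: int
    length: int
    missing_fraction: float
    parsimony_informative_sites: int


def locus_stats(locus: LocusAlignment) -> LocusStats:
    """Missingness over present sequences and the PI-site census."""
    n, L = locus.n_taxa, locus.length
    missing = 0
    pi = 0
    cols = zip(*locus.sequences.values())
    for col in cols:
        counts = Counter(col)
        missing += sum(v for c, v in counts.items() if c in MISSING_CHARS)
        informative = [
            c for c, v in counts.items() if c not in MISSING_CHARS and v >= 2
        ]
        if len(informative) >= 2:
            pi += 1
    return LocusStats(
        locus_id=locus.locus_id,
        n_taxa=n,
        length=L,
        missing_fraction=missing / (n * L),
        parsimony_informative_sites=pi,
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_loci(
    loci: Sequence[LocusAlignment],
    min_sequences: int = 4,
    min_length: int = 0,
    min_taxa: int = 0,
) -> tuple[list[LocusAlignment], list[tuple[str, str]]]:
    """Joint locus filter with an exclusion log.

    A locus is retained iff it has >= ``min_sequences`` sequences, length
    strictly > ``min_length``, and strictly more than ``min_taxa`` taxa
    (the length/taxon thresholds are strict by convention: "greater than
    250 bp", "more than 20 taxa"). The log names every dropped locus and
    the first rule it failed.
    """
    retained: list[LocusAlignment] = []
    excluded: list[tuple[str, str]] = []
    for locus in loci:
        if locus.n_taxa < min_sequences:
            excluded.append(
                (locus.locus_id, f"fewer than {min_sequences} sequences")
            )
        elif locus.length <= min_length:
            excluded.append((locus.locus_id, f"length <= {min_length}"))
        elif locus.n_taxa <= min_taxa:
            excluded.append((locus.locus_id, f"taxa <= {min_taxa}"))
        else:
            retained.append(locus)
    return retained, excluded


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (locus_id, start, end), 1-based
    total_length: int
    n_taxa: int
    missing_fraction: float          # over panel x length, all missing chars
    absent_block_fraction: float     # cells from absent taxon-locus blocks only
    mean_species_per_locus: int

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for taxon in sorted(self.sequences):
                fh.write(f">{taxon}\n{self.sequences[taxon]}\n")

    def write_phylip(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.total_length}\n")
            for taxon in sorted(self.sequences):
                fh.write(f"{taxon}  {self.sequences[taxon]}\n")

    def write_partitions(self, path: str) -> None:
        with open(path, "w") as fh:
            for locus_id, start, end in self.partitions:
                fh.write(f"{locus_id} = {start}-{end}\n")


def concatenate(
    loci: Sequence[LocusAlignment], taxon_panel: Iterable[str]
) -> Supermatrix:
    """Column-wise concatenation over a common taxon panel.

    Absent taxon-by-locus blocks are gap-filled and counted as missing.
    Both the total missing fraction (gap/?/N cells plus filled blocks)
    and the absent-block-only fraction are reported, along with the
    rounded mean number of species per locus.
    """
    panel = sorted(set(taxon_panel))
    panel_set = set(panel)
    for locus in loci:
        extra = locus.taxa - panel_set
        if extra:
            raise AlignmentError(
                f"locus {locus.locus_id}: taxa outside panel: {sorted(extra)[:5]}"
            )
    if not loci:
        raise AlignmentError("no loci to concatenate")

    parts: dict[str, list[str]] = {t: [] for t in panel}
    partitions = []
    pos = 1
    missing_cells = 0
    absent_cells = 0
    for locus in loci:
        L = locus.length
        partitions.append((locus.locus_id, pos, pos + L - 1))
        pos += L
        filler = "-" * L
        for t in panel:
            seq = locus.sequences.get(t)
            if seq is None:
                parts[t].append(filler)
                absent_cells += L
                missing_cells += L
            else:
                parts[t].append(seq)
                missing_cells += sum(1 for c in seq if c in MISSING_CHARS)

    total_length = pos - 1
    n_taxa = len(panel)
    cells = n_taxa * total_length
    mean_species = int(
        round_half_away(sum(l.n_taxa for l in loci) / len(loci))
    )
    return Supermatrix(
        sequences={t: "".join(chunks) for t, chunks in parts.items()},
        partitions=partitions,
        total_length=total_length,
        n_taxa=n_taxa,
        missing_fraction=missing_cells / cells,
        absent_block_fraction=absent_cells / cells,
        mean_species_per_locus=mean_species,
    )


# ---------------------------------------------------------------------------
# Anchor-replicated partitioning
# ---------------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """Assignment of non-anchor loci to k disjoint subsets, with the
    anchor loci (and any extras, e.g. a barcode locus) replicated into
    every subset."""

    k: int
    assignment: dict[str, int]  # non-anchor locus_id -> subset index
    anchors: tuple[str, ...]
    extras: tuple[str, ...] = ()

    def subset_ids(self, i: int) -> list[str]:
        own = sorted(l for l, s in self.assignment.items() if s == i)
        return own + list(self.anchors) + list(self.extras)

    def subset_sizes(self) -> list[int]:
        return [len(self.subset_ids(i)) for i in range(self.k)]

    def non_anchor_counts(self) -> list[int]:
        counts = [0] * self.k
        for s in self.assignment.values():
            counts[s] += 1
        return counts


def partition_with_anchors(
    loci: Sequence[LocusAlignment],
    anchors: Iterable[str],
    k: int = 3,
    extras: Iterable[str] = (),
    seed: Optional[int] = None,
) -> PartitionScheme:
    """Deal non-anchor loci into k near-balanced subsets.

    Non-anchors are sorted by (PI sites desc, length desc, locus_id) and
    dealt in boustrophedon (snake) order, which forces subset
    cardinalities to differ by at most one while keeping the PI and
    length sums balanced. Anchors and extras are replicated into every
    subset. Deterministic; ``seed`` is accepted for interface symmetry
    but only perturbs nothing unless future tie policies use it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    anchor_set = set(anchors)
    ids = {l.locus_id for l in loci}
    missing = anchor_set - ids
    if missing:
        raise ValueError(f"anchors not among loci: {sorted(missing)}")
    non_anchors = [l for l in loci if l.locus_id not in anchor_set]
    if k > len(non_anchors):
        raise ValueError(
            f"k={k} exceeds number of non-anchor loci ({len(non_anchors)})"
        )
    stats = {l.locus_id: locus_stats(l) for l in non_anchors}
    order = sorted(
        non_anchors,
        key=lambda l: (
            -stats[l.locus_id].parsimony_informative_sites,
            -l.length,
            l.locus_id,
        ),
    )
    assignment: dict[str, int] = {}
    for i, locus in enumerate(order):
        row, col = divmod(i, k)
        subset = col if row % 2 == 0 else k - 1 - col
        assignment[locus.locus_id] = subset
    return PartitionScheme(
        k=k,
        assignment=assignment,
        anchors=tuple(sorted(anchor_set)),
        extras=tuple(sorted(set(extras))),
    )


def write_subset_manifests(
    scheme: PartitionScheme, outdir: str, prefix: str = "subset"
) -> list[str]:
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i in range(scheme.k):
        path = os.path.join(outdir, f"{prefix}_{i + 1}.txt")
        with open(path, "w") as fh:
            fh.write("\n".join(scheme.subset_ids(i)) + "\n")
        paths.append(path)
    return paths
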