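"""Barcode quality control against phylogenetic species bins.

Public-repository COI sequences arrive with reported taxon names of very
uneven quality. The protocol implemented here mirrors manual curation of
a guide tree, made operational:

1. every reported name is parsed (proper binomial vs. "Genus sp." vs.
   order/family-level placeholders);
2. species *bins* are derived from the guide tree: for each binomial
   name, the defining clade is the clade containing the most tips of
   that name whose binomial membership is sufficiently pure, where
   nonspecific labels and lone foreign-named tips (suspected
   misidentifications, not supported clusters) do not count against
   purity — a cluster only counts if backed by ``min_members`` or more
   individuals;
3. every sequence gets exactly one verdict: ``pass`` (member of its own
   species' bin), ``nonspecific_name``, ``mismatch`` (sits inside a
   different species' bin — misidentification), or ``no_bin``
   ("ID cannot be determined").

The module is fully deterministic.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._util import percent
from .taxonomy import TaxonomyMap
from .treeio import Bipartition, Tree, normalize_taxon

PASS = "pass"
NO_BIN = "no_bin"
NONSPECIFIC = "nonspecific_name"
MISMATCH = "mismatch"

VERDICTS = (PASS, NO_BIN, NONSPECIFIC, MISMATCH)

# Epithets that do not pin a name to a species.
_NONSPECIFIC_EPITHETS = {"sp", "sp.", "spp", "spp.", "n.sp.", "nsp", "sp.nov", "sp.nov."}
_QUALIFIERS = {"cf", "cf.", "aff", "aff."}
_ABOVE_GENUS_SUFFIXES = ("iformes", "idae", "inae", "oidei", "oidea")


@dataclass(frozen=True)
class ParsedLabel:
    status: str  # "binomial" | "genus_only" | "above_genus"
    genus: Optional[str] = None
    epithet: Optional[str] = None
    rank_name: Optional[str] = None
    flagged: bool = False  # cf./aff. qualifiers

    @property
    def species(self) -> Optional[str]:
        if self.status == "binomial":
            return f"{self.genus} {self.epithet}"
        return None


def parse_label(
    reported_name: str, taxonomy: Optional[TaxonomyMap] = None
) -> ParsedLabel:
    """Classify a reported name as binomial / genus_only / above_genus.

    "Stomias sp." -> genus_only; "Stomiiformes sp." -> above_genus;
    "Chauliodus sloani" -> binomial. Qualified names ("Stomias cf.
    boa") are genus_only and flagged.
    """
    if not reported_name or not reported_name.strip():
        raise ValueError("empty reported name")
    tokens = re.split(r"[\s_]+", reported_name.strip())
    first = tokens[0]

    def is_above_genus(token: str) -> bool:
        if taxonomy is not None and token in taxonomy.families:
            return True
        return token.lower().endswith(_ABOVE_GENUS_SUFFIXES)

    if is_above_genus(first):
        return ParsedLabel(status="above_genus", rank_name=first)
    if len(tokens) == 1:
        return ParsedLabel(status="genus_only", genus=first)
    second = tokens[1]
    if second.lower() in _NONSPECIFIC_EPITHETS:
        return ParsedLabel(status="genus_only", genus=first)
    if second.lower() in _QUALIFIERS:
        return ParsedLabel(status="genus_only", genus=first, flagged=True)
    return ParsedLabel(status="binomial", genus=first, epithet=second)


@dataclass(frozen=True)
class SequenceLabel:
    sequence_id: str
    reported_name: str
    source: str = "repository"  # "study" | "repository"
    family_hint: Optional[str] = None


def read_labels(path: str) -> dict[str, SequenceLabel]:
    """TSV with columns sequence_id, reported_name, source, family_hint."""
    out: dict[str, SequenceLabel] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sid = normalize_taxon(row["sequence_id"])
            if sid in out:
                raise ValueError(f"duplicate sequence_id {sid}")
            out[sid] = SequenceLabel(
                sequence_id=sid,
                reported_name=row["reported_name"],
                source=row.get("source") or "repository",
                family_hint=row.get("family_hint") or None,
            )
    return out


def write_labels(labels: Mapping[str, SequenceLabel], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence_id", "reported_name", "source", "family_hint"])
        for lab in labels.values():
            w.writerow(
                [lab.sequence_id, lab.reported_name, lab.source, lab.family_hint or ""]
            )


@dataclass
class Bin:
    """A species-level cluster of same-named sequences on the guide tree.

    ``clade_tips`` is the defining clade (it may absorb lone foreign-named
    tips sitting at its edge — the misidentification suspects);
    ``core_tips`` is the minimal clade spanned by the members themselves.
    """

    bin_name: str  # parsed binomial, "Genus epithet"
    member_ids: frozenset
    clade_tips: frozenset
    core_tips: frozenset = frozenset()

    def defining_clade(self, universe: frozenset) -> Optional[Bipartition]:
        rest = universe - self.clade_tips
        if not rest:
            return None
        return Bipartition(self.clade_tips, rest)


@dataclass
class QCRecord:
    sequence_id: str
    reported_name: str
    verdict: str
    assigned_bin: Optional[str] = None
    note: str = ""


# ---------------------------------------------------------------------------
# Bin assignment
# ---------------------------------------------------------------------------

def assign_bins(
    guide_tree: Tree,
    labels: Mapping[str, SequenceLabel],
    min_members: int = 2,
    purity: float = 1.0,
    taxonomy: Optional[TaxonomyMap] = None,
    allow_singletons: bool = False,
) -> dict[str, Bin]:
    """Derive species bins from the guide tree.

    For each binomial name the candidate defining clades are the nodes
    whose binomial-labeled membership is >= ``purity`` pure, where
    (a) nonspecific labels are ignored and (b) a foreign binomial name
    represented by fewer than ``min_members`` tips inside the clade is
    treated as a suspected misidentification and also ignored. Among
    candidates the clade with the most own-name tips wins (ties: most
    total tips, so suspects at the clade edge are absorbed into the
    defining clade; then canonical order). Names whose best clade holds
    fewer than ``min_members`` own tips form no bin (one tip suffices
    when ``allow_singletons``).
    """
    tips = guide_tree.tips
    missing = sorted(t for t in tips if t not in labels)
    if missing:
        raise ValueError(f"unlabeled guide-tree tips: {missing[:10]}")

    species_of_tip: dict[str, Optional[str]] = {}
    for tip in tips:
        parsed = parse_label(labels[tip].reported_name, taxonomy)
        species_of_tip[tip] = parsed.species

    min_req = 1 if allow_singletons else min_members

    # Bottom-up per-clade species counters plus clade tip sets.
    counters: dict[int, dict[str, int]] = {}
    clade_sets: dict[int, frozenset] = {}
    candidates: dict[str, list[tuple[int, int, tuple, frozenset]]] = {}
    for node in guide_tree.postorder():
        if node.is_leaf:
            sp = species_of_tip[node.taxon]
            counters[id(node)] = {sp: 1} if sp else {}
            clade_sets[id(node)] = frozenset((node.taxon,))
        else:
            merged: dict[str, int] = {}
            cset: set[str] = set()
            for c in node.children:
                cset |= clade_sets[id(c)]
                for sp, n in counters[id(c)].items():
                    merged[sp] = merged.get(sp, 0) + n
            counters[id(node)] = merged
            clade_sets[id(node)] = frozenset(cset)
        counter = counters[id(node)]
        clade = clade_sets[id(node)]
        for sp, own in counter.items():
            if own < min_req:
                continue
            contaminants = sum(
                n for other, n in counter.items()
                if other != sp and n >= min_members
            )
            pur = own / (own + contaminants)
            if pur + 1e-12 < purity:
                continue
            key = (-own, -len(clade), tuple(sorted(clade)))
            candidates.setdefault(sp, []).append((own, len(clade), key, clade))

    bins: dict[str, Bin] = {}
    for sp, cands in candidates.items():
        cands.sort(key=lambda item: item[2])
        _, _, _, clade = cands[0]
        members = frozenset(t for t in clade if species_of_tip[t] == sp)
        core = guide_tree.mrca(members).leaf_taxa() if len(members) > 1 else members
        bins[sp] = Bin(
            bin_name=sp, member_ids=members, clade_tips=clade, core_tips=core
        )
    return bins


def classify_sequences(
    guide_tree: Tree,
    labels: Mapping[str, SequenceLabel],
    bins: Mapping[str, Bin],
    taxonomy: Optional[TaxonomyMap] = None,
) -> list[QCRecord]:
    """One verdict per sequence; precedence nonspecific > mismatch > no_bin."""
    records: list[QCRecord] = []
    for tip in sorted(guide_tree.tips):
        lab = labels[tip]
        parsed = parse_label(lab.reported_name, taxonomy)
        if parsed.status != "binomial":
            note = (
                f"non-specific designation ({parsed.status})"
                + (" [qualified name]" if parsed.flagged else "")
            )
            records.append(
                QCRecord(tip, lab.reported_name, NONSPECIFIC, None, note)
            )
            continue
        own = parsed.species
        own_bin = bins.get(own)
        if own_bin is not None and tip in own_bin.member_ids:
            records.append(
                QCRecord(tip, lab.reported_name, PASS, own, "member of own bin")
            )
            continue
        hosts = [
            b for sp, b in bins.items() if sp != own and tip in b.clade_tips
        ]
        if hosts:
            host = min(hosts, key=lambda b: (len(b.clade_tips), b.bin_name))
            # A tip merely absorbed at the edge of a foreign clade is only a
            # misidentification if its own name is supported by a bin
            # elsewhere; a lone, otherwise-unsupported name adjacent to a
            # cluster cannot be told apart from a genuine rarity.
            if tip in host.core_tips or own_bin is not None:
                records.append(
                    QCRecord(
                        tip,
                        lab.reported_name,
                        MISMATCH,
                        host.bin_name,
                        f"reported {own} but clusters inside bin {host.bin_name}",
                    )
                )
                continue
            records.append(
                QCRecord(
                    tip,
                    lab.reported_name,
                    NO_BIN,
                    None,
                    f"ID cannot be determined (adjacent to bin {host.bin_name})",
                )
            )
            continue
        records.append(
            QCRecord(tip, lab.reported_name, NO_BIN, None, "ID cannot be determined")
        )
    return records


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _family_of_record(rec: QCRecord, taxonomy: TaxonomyMap) -> str:
    parsed = parse_label(rec.reported_name, taxonomy)
    if parsed.status == "above_genus":
        if parsed.rank_name in taxonomy.families:
            return parsed.rank_name
        return "unplaced"
    fam = taxonomy.family_of_genus(parsed.genus)
    return fam if fam is not None else "unplaced"


def summarize_qc(
    records: Sequence[QCRecord], taxonomy: TaxonomyMap
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Per-family verdict counts, overall totals, and the pass list.

    Percentages are reported to one decimal, halves away from zero
    (130 failures of 350 -> 37.1). Returns (per_family, overall,
    pass_ids).
    """
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        fam = _family_of_record(rec, taxonomy)
        row = rows.setdefault(
            fam, {v: 0 for v in VERDICTS}
        )
        row[rec.verdict] += 1
    table = []
    for fam in sorted(rows):
        row = rows[fam]
        total = sum(row.values())
        fails = total - row[PASS]
        table.append(
            {
                "family": fam,
                "n_total": total,
                "n_pass": row[PASS],
                "n_no_bin": row[NO_BIN],
                "n_nonspecific": row[NONSPECIFIC],
                "n_mismatch": row[MISMATCH],
                "n_fail": fails,
                "fail_percent": percent(fails, total),
            }
        )
    per_family = pd.DataFrame(
        table,
        columns=[
            "family",
            "n_total",
            "n_pass",
            "n_no_bin",
            "n_nonspecific",
            "n_mismatch",
            "n_fail",
            "fail_percent",
        ],
    ).set_index("family")

    n_total = len(records)
    n_fail = sum(1 for r in records if r.verdict != PASS)
    overall = {
        "n_total": n_total,
        "n_pass": n_total - n_fail,
        "n_no_bin": sum(1 for r in records if r.verdict == NO_BIN),
        "n_nonspecific": sum(1 for r in records if r.verdict == NONSPECIFIC),
        "n_mismatch": sum(1 for r in records if r.verdict == MISMATCH),
        "n_fail": n_fail,
        "fail_percent": percent(n_fail, n_total),
    }
    pass_ids = [r.sequence_id for r in records if r.verdict == PASS]
    return per_family, overall, pass_ids


def records_to_frame(records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "reported_name": r.reported_name,
                "verdict": r.verdict,
                "assigned_bin": r.assigned_bin or "",
                "note": r.note,
            }
            for r in records
        ]
    )
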