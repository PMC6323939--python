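"""Family-boundary diagnostics on multiple sequence alignments.

Four criteria flag families whose alignments suggest the family is too
diverse (or wrongly merged) to align reliably:

* E1 — more than 50% of members do not align to the retained core alignment
  (fewer than 30 non-gap residues inside core columns);
* E2 — the core alignment is short (<100 columns) while the total alignment
  is at least 4x longer than the core;
* P1 — at least 10% of members each align to fewer than 30 (core) columns;
* P2 — some internal tree edge splits the family into two subtrees whose
  alignments share fewer than 30 amino-acid sites.

The "core" is defined by column occupancy: a column is core when at least
half of the members have a residue there (the occupancy threshold is
configurable).  A flagged family is a candidate for re-clustering into
smaller families; after re-clustering, old family identifiers are
forward-tracked to the new cluster holding the largest share of former
members.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, StructureError
from .phylo import FamilyTree

GAP = "-"

# 30-residue floor the diagnostics use for "aligns to" (E1, P1, P2)
MIN_ALIGNED_COLUMNS = 30


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped sequences with unique member ids."""

    member_ids: list[str]
    sequences: list[str]
    matrix: np.ndarray  # bool, True where non-gap; shape (n_members, width)

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise InputError("alignment needs at least 2 rows")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise InputError("duplicate member ids in alignment")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.member_ids):
            raise InputError("matrix shape does not match member list")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "MultipleAlignment":
        ids, seqs = [], []
        for member_id, seq in rows:
            ids.append(member_id)
            seqs.append(seq)
        widths = {len(s) for s in seqs}
        if len(widths) != 1:
            raise InputError(f"rows have unequal lengths: {sorted(widths)}")
        matrix = np.array(
            [[c != GAP for c in s] for s in seqs], dtype=bool
        )
        return cls(member_ids=ids, sequences=seqs, matrix=matrix)

    def rows(self) -> list[tuple[str, str]]:
        return list(zip(self.member_ids, self.sequences))

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])


def parse_fasta_alignment(stream: TextIO | str) -> MultipleAlignment:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    msa = AlignIO.read(stream, "fasta")
    return MultipleAlignment.from_rows((rec.id, str(rec.seq)) for rec in msa)


def write_fasta_alignment(
    rows: Iterable[tuple[str, str]], stream: TextIO
) -> None:
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=member_id, description="")
        for member_id, seq in rows
    )
    AlignIO.write(msa, stream, "fasta")


# -- criteria ----------------------------------------------------------------


def core_columns(msa: MultipleAlignment, occupancy: float = 0.5) -> list[int]:
    """0-based indices of columns whose non-gap fraction >= ``occupancy``."""
    if not 0 < occupancy <= 1:
        raise InputError("occupancy must be in (0, 1]")
    frac = msa.matrix.mean(axis=0)
    return [i for i in range(msa.width) if frac[i] >= occupancy]


def _core_aligned_counts(
    msa: MultipleAlignment, occupancy: float
) -> np.ndarray:
    """Per member: number of core columns where the member has a residue."""
    core = core_columns(msa, occupancy)
    if not core:
        return np.zeros(msa.n_members, dtype=int)
    return msa.matrix[:, core].sum(axis=1)


def criterion_E1(
    msa: MultipleAlignment,
    occupancy: float = 0.5,
    min_core_residues: int = MIN_ALIGNED_COLUMNS,
    member_fraction: float = 0.5,
) -> tuple[bool, float]:
    """Flag when >50% of members do not align to the core alignment.

    A member does not align to the core when it has residues in fewer than
    ``min_core_residues`` core columns.  The flag requires a strictly
    greater fraction than ``member_fraction``.
    """
    counts = _core_aligned_counts(msa, occupancy)
    fraction = float(np.mean(counts < min_core_residues))
    return fraction > member_fraction, fraction


def criterion_E2(
    msa: MultipleAlignment,
    occupancy: float = 0.5,
    short_core: int = 100,
    length_ratio: float = 4.0,
) -> bool:
    """Flag when the core is short (<100 columns) and the total alignment is
    at least 4x longer than the core."""
    n_core = len(core_columns(msa, occupancy))
    return n_core < short_core and msa.width >= length_ratio * n_core


def criterion_P1(
    msa: MultipleAlignment,
    occupancy: float = 0.5,
    min_columns: int = MIN_ALIGNED_COLUMNS,
    member_fraction: float = 0.10,
    use_core: bool = True,
) -> tuple[bool, float]:
    """Flag when at least 10% of members each align to fewer than 30 columns.

    Aligned columns are counted against the core by default (``use_core``),
    so residues confined to junk columns do not count.
    """
    if use_core:
        counts = _core_aligned_counts(msa, occupancy)
    else:
        counts = msa.matrix.sum(axis=1)
    fraction = float(np.mean(counts < min_columns))
    return fraction >= member_fraction, fraction


def _internal_bipartitions(tree: FamilyTree) -> list[frozenset[str]]:
    """Leaf sets under each internal non-root node (one per internal edge)."""
    out = []
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        out.append(frozenset(leaf.gene_id for leaf in node.leaves()))
    return out


def criterion_P2(
    msa: MultipleAlignment,
    tree: FamilyTree,
    min_shared: int = MIN_ALIGNED_COLUMNS,
    side_occupancy: float = 0.5,
) -> tuple[bool, int]:
    """Flag when some internal tree edge splits the family into two subtrees
    sharing fewer than 30 aligned sites.

    A column is shared across a split when at least ``side_occupancy`` of the
    members on EACH side have a residue there.  Returns the minimum shared
    count over all splits (the alignment width when the tree has no internal
    edge, in which case the criterion cannot fire).
    """
    if set(msa.member_ids) != set(tree.leaf_index):
        raise StructureError("alignment members and tree leaves differ")
    row_of = {m: i for i, m in enumerate(msa.member_ids)}
    worst = msa.width
    for side_a in _internal_bipartitions(tree):
        rows_a = [row_of[m] for m in side_a]
        rows_b = [row_of[m] for m in tree.leaf_index if m not in side_a]
        if not rows_a or not rows_b:
            continue
        occ_a = msa.matrix[rows_a].mean(axis=0)
        occ_b = msa.matrix[rows_b].mean(axis=0)
        shared = int(np.sum((occ_a >= side_occupancy) & (occ_b >= side_occupancy)))
        worst = min(worst, shared)
    return worst < min_shared, worst


@dataclass
class QCReport:
    """Per-family record of the four boundary diagnostics."""

    family_id: str
    core_column_count: int
    noncore_member_fraction: float
    sparse_member_fraction: float
    worst_split_shared_sites: int
    flags: set[str] = field(default_factory=set)

    FLAG_NAMES = (
        "E1_noncore_members",
        "E2_short_core",
        "P1_sparse_members",
        "P2_disjoint_subtrees",
    )

    @property
    def flagged(self) -> bool:
        return bool(self.flags)

    def to_row(self) -> dict:
        row = {
            "family_id": self.family_id,
            "core_column_count": self.core_column_count,
            "noncore_member_fraction": round(self.noncore_member_fraction, 6),
            "sparse_member_fraction": round(self.sparse_member_fraction, 6),
            "worst_split_shared_sites": self.worst_split_shared_sites,
        }
        for name in self.FLAG_NAMES:
            row[name] = int(name in self.flags)
        return row


def flag_family(
    msa: MultipleAlignment,
    tree: FamilyTree | None = None,
    occupancy: float = 0.5,
) -> QCReport:
    """Run all four criteria; the report's flags are their union.

    P2 needs the family tree; without one the split diagnostic is skipped
    and ``worst_split_shared_sites`` is the alignment width.
    """
    e1, noncore_frac = criterion_E1(msa, occupancy)
    e2 = criterion_E2(msa, occupancy)
    p1, sparse_frac = criterion_P1(msa, occupancy)
    if tree is not None:
        p2, worst = criterion_P2(msa, tree)
    else:
        p2, worst = False, msa.width
    flags = set()
    if e1:
        flags.add("E1_noncore_members")
    if e2:
        flags.add("E2_short_core")
    if p1:
        flags.add("P1_sparse_members")
    if p2:
        flags.add("P2_disjoint_subtrees")
    return QCReport(
        family_id=tree.family_id if tree is not None else "FAM",
        core_column_count=len(core_columns(msa, occupancy)),
        noncore_member_fraction=noncore_frac,
        sparse_member_fraction=sparse_frac,
        worst_split_shared_sites=worst,
        flags=flags,
    )


def write_qc_tsv(reports: Iterable[QCReport], stream: TextIO) -> None:
    rows = [r.to_row() for r in reports]
    if not rows:
        return
    cols = list(rows[0])
    stream.write("\t".join(cols) + "\n")
    for row in rows:
        stream.write("\t".join(str(row[c]) for c in cols) + "\n")


# -- family-id forward tracking ----------------------------------------------


@dataclass
class ForwardTrackResult:
    """Outcome of forward-tracking old family ids onto new clusters."""

    mapping: dict[str, str]  # old family id -> cluster id
    retired: list[str]  # old ids with no surviving members
    fresh: dict[str, str]  # cluster id -> newly minted family id


def forward_track_ids(
    old_members: Mapping[str, set[str]],
    new_clusters: Mapping[str, set[str]],
    fresh_prefix: str = "NEWFAM",
) -> ForwardTrackResult:
    """Map each old family id to the new cluster with the largest count of
    its former members; clusters receiving no old id get fresh identifiers.

    Ties are broken to the lexicographically smallest cluster id.  An old
    family with no members in any cluster is retired.
    """
    mapping: dict[str, str] = {}
    retired: list[str] = []
    for old_id in sorted(old_members):
        members = old_members[old_id]
        best, best_n = None, 0
        for cluster_id in sorted(new_clusters):
            n = len(members & new_clusters[cluster_id])
            if n > best_n:
                best, best_n = cluster_id, n
        if best is None:
            retired.append(old_id)
        else:
            mapping[old_id] = best
    tracked = set(mapping.values())
    fresh = {}
    counter = 1
    for cluster_id in sorted(new_clusters):
        if cluster_id not in tracked:
            fresh[cluster_id] = f"{fresh_prefix}{counter:05d}"
            counter += 1
    return ForwardTrackResult(mapping=mapping, retired=retired, fresh=fresh)
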