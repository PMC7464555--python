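"""Projection of coding splice sites onto a protein alignment.

Sites derived per gene (residue index + codon frame) are lifted into the
column space of a shared protein multiple alignment.  Two sites from
different proteins are *shared* when they occupy the same column with the
same frame — evidence of a common ancestral intron.  Proteins lacking a
site at a shared column are annotated ``n.s.`` (no splice site), split by
whether the aligned residue is conserved, and a site whose boundary lies
exactly one nucleotide away on the unrolled codon grid is annotated as
*shifted* (intron sliding) rather than shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import pandas as pd
from Bio import SeqIO

from splicemark.gene_structures import CodingSpliceSite

GAP = "-"

#: non-member statuses
NO_SITE_CONSERVED = "no_site_conserved_residue"
NO_SITE_NONCONSERVED = "no_site_nonconserved_residue"
SHIFTED = "shifted_one_nt"


class ProjectionError(ValueError):
    """Raised when sites and alignment rows are inconsistent."""


@dataclass
class ProteinAlignment:
    """A protein multiple alignment as a mapping protein_id -> gapped row."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ProjectionError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, protein_id: str) -> str:
        return self.rows[protein_id].replace(GAP, "")

    @classmethod
    def from_fasta(cls, handle_or_text) -> "ProteinAlignment":
        """Read an aligned FASTA file, path, handle, or literal text."""
        if isinstance(handle_or_text, str) and handle_or_text.lstrip().startswith(">"):
            handle_or_text = StringIO(handle_or_text)
        records = SeqIO.parse(handle_or_text, "fasta")
        return cls({rec.id: str(rec.seq).upper() for rec in records})

    @classmethod
    def identity(cls, proteins: dict[str, str]) -> "ProteinAlignment":
        """Gap-free alignment of equal-length proteins (the no-indel truth)."""
        return cls(dict(proteins))


@dataclass(frozen=True)
class AlignedSiteCall:
    """A coding splice site lifted into alignment coordinates."""

    protein_id: str
    column: int  # 1-based alignment column of the site's residue
    frame: int
    residue: str
    source_site: CodingSpliceSite


@dataclass(frozen=True)
class NonMemberCall:
    """Annotation for a protein absent from a shared-site group."""

    status: str  # one of NO_SITE_CONSERVED / NO_SITE_NONCONSERVED / SHIFTED
    residue: str  # residue at the group column, "-" when gapped
    residue_index: int | None  # that residue's own protein index
    shifted_site: CodingSpliceSite | None = None  # the nearby site, if SHIFTED


@dataclass
class SharedSiteGroup:
    """An equivalence class of same-column, same-frame site calls."""

    name: str
    column: int
    frame: int
    members: list[AlignedSiteCall]
    non_members: dict[str, NonMemberCall] = field(default_factory=dict)

    @property
    def shared(self) -> bool:
        return len(self.members) >= 2

    def member_ids(self) -> set[str]:
        return {c.protein_id for c in self.members}

    def status_of(self, protein_id: str) -> str | None:
        entry = self.non_members.get(protein_id)
        return entry.status if entry else None


def residue_to_column(row: str, protein_index: int) -> int:
    """Column (1-based) of the ``protein_index``-th non-gap character."""
    if protein_index < 1:
        raise IndexError(f"protein index must be >= 1: {protein_index}")
    seen = 0
    for col, char in enumerate(row, start=1):
        if char != GAP:
            seen += 1
            if seen == protein_index:
                return col
    raise IndexError(
        f"protein index {protein_index} exceeds {seen} residues in row"
    )


def column_to_residue_index(row: str, column: int) -> int | None:
    """1-based residue index at a column, or None if the column is a gap."""
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} outside row of length {len(row)}")
    if row[column - 1] == GAP:
        return None
    return len(row[:column].replace(GAP, ""))


def project_sites(
    alignment: ProteinAlignment,
    sites: dict[str, list[CodingSpliceSite]],
) -> list[AlignedSiteCall]:
    """Lift per-protein splice sites into alignment columns.

    Each site's residue is cross-checked against the alignment row; a
    mismatch signals a wrong protein/alignment pairing and raises
    :class:`ProjectionError`.  Output order is stable: by protein (input
    order), then by coding offset.
    """
    calls = []
    for protein_id, site_list in sites.items():
        if protein_id not in alignment.rows:
            raise ProjectionError(f"protein {protein_id} not in alignment")
        row = alignment.rows[protein_id]
        for site in sorted(site_list, key=lambda s: s.coding_offset):
            try:
                column = residue_to_column(row, site.protein_index)
            except IndexError as exc:
                raise ProjectionError(f"{protein_id}: {exc}") from exc
            aligned = row[column - 1]
            if site.residue not in ("*",) and aligned != site.residue:
                raise ProjectionError(
                    f"{protein_id}: site {site.label} expects residue "
                    f"{site.residue} but alignment column {column} holds "
                    f"{aligned}"
                )
            calls.append(
                AlignedSiteCall(protein_id, column, site.frame, aligned, site)
            )
    return calls


def _unrolled_position(row_a: str, row_b: str, column: int, frame: int) -> int:
    """Nucleotide-grid position of a boundary in the pairwise alignment.

    Columns gapped in *both* rows are deleted first, so the distance
    reflects the two sequences' mutual alignment and ignores gaps induced
    by third parties.  Each remaining column spans three nucleotide slots.
    """
    kept = sum(
        1
        for c in range(column - 1)
        if not (row_a[c] == GAP and row_b[c] == GAP)
    )
    return 3 * kept + frame


def detect_one_nt_shift(
    a: AlignedSiteCall, b: AlignedSiteCall, alignment: ProteinAlignment
) -> bool:
    """True iff the two boundaries are exactly one nucleotide apart.

    The distance is measured on the unrolled codon grid of the pairwise
    alignment of the two proteins (both-gap columns deleted).  Symmetric
    in its arguments.
    """
    row_a = alignment.rows[a.protein_id]
    row_b = alignment.rows[b.protein_id]
    pos_a = _unrolled_position(row_a, row_b, a.column, a.frame)
    pos_b = _unrolled_position(row_a, row_b, b.column, b.frame)
    return abs(pos_a - pos_b) == 1


def _group_name(call: AlignedSiteCall, prefix_length: int) -> str:
    prefix = call.protein_id[:prefix_length] if prefix_length else call.protein_id
    return f"{prefix}{call.source_site.protein_index}"


def classify_site_groups(
    calls: list[AlignedSiteCall],
    alignment: ProteinAlignment,
    reference_protein: str | None = None,
    shift_window: int = 1,
    name_prefix_length: int = 3,
) -> list[SharedSiteGroup]:
    """Partition aligned site calls into shared-site groups.

    Groups are the equivalence classes of (column, frame).  Each group is
    named after the reference protein's member when present (e.g. the
    reference ``CinGH6-1`` with a member at residue 316 yields ``Cin316``),
    otherwise after its leftmost member.  Every protein of the alignment
    absent from a group receives a status: ``shifted_one_nt`` when one of
    its own sites lies within ``shift_window`` nucleotides of the group
    boundary (default exactly 1, i.e. intron sliding by a single
    nucleotide); otherwise ``n.s.`` split by whether its residue at the
    group column matches the majority residue of the group members (ties
    count as non-conserved).  Singleton groups are retained; their
    ``shared`` property is False.
    """
    for call in calls:
        if call.protein_id not in alignment.rows:
            raise ProjectionError(f"call references unknown row {call.protein_id}")
    if reference_protein is None and alignment.rows:
        reference_protein = next(iter(alignment.rows))

    by_key: dict[tuple[int, int], list[AlignedSiteCall]] = {}
    for call in calls:
        by_key.setdefault((call.column, call.frame), []).append(call)

    by_protein: dict[str, list[AlignedSiteCall]] = {}
    for call in calls:
        by_protein.setdefault(call.protein_id, []).append(call)

    groups = []
    for (column, frame) in sorted(by_key):
        members = sorted(by_key[(column, frame)], key=lambda c: c.protein_id)
        ref_members = [m for m in members if m.protein_id == reference_protein]
        named_after = ref_members[0] if ref_members else members[0]
        group = SharedSiteGroup(
            name=_group_name(named_after, name_prefix_length),
            column=column,
            frame=frame,
            members=members,
        )
        member_ids = group.member_ids()
        residues = [m.residue for m in members]
        counts = pd.Series(residues).value_counts()
        majority = (
            counts.index[0]
            if len(counts) == 1 or counts.iloc[0] > counts.iloc[1]
            else None
        )
        anchor = members[0]
        for protein_id in alignment.rows:
            if protein_id in member_ids:
                continue
            row = alignment.rows[protein_id]
            residue = row[column - 1]
            residue_index = (
                column_to_residue_index(row, column) if residue != GAP else None
            )
            own_calls = by_protein.get(protein_id, [])
            shifted_call = next(
                (
                    c
                    for c in own_calls
                    if _within_shift(anchor, c, alignment, shift_window)
                ),
                None,
            )
            if shifted_call is not None:
                group.non_members[protein_id] = NonMemberCall(
                    SHIFTED, residue, residue_index, shifted_call.source_site
                )
                continue
            if majority is not None and residue == majority:
                status = NO_SITE_CONSERVED
            else:
                status = NO_SITE_NONCONSERVED
            group.non_members[protein_id] = NonMemberCall(
                status, residue, residue_index
            )
        groups.append(group)
    return groups


def _within_shift(
    a: AlignedSiteCall, b: AlignedSiteCall, alignment: ProteinAlignment, window: int
) -> bool:
    row_a = alignment.rows[a.protein_id]
    row_b = alignment.rows[b.protein_id]
    pos_a = _unrolled_position(row_a, row_b, a.column, a.frame)
    pos_b = _unrolled_position(row_a, row_b, b.column, b.frame)
    return 1 <= abs(pos_a - pos_b) <= window


def render_site_table(
    groups: list[SharedSiteGroup],
    proteins: list[str],
    site_counts: dict[str, int] | None = None,
    shared_only: bool = True,
) -> pd.DataFrame:
    """Tabulate groups as one row per protein, one column per group.

    Member cells read ``R{index}, +{frame}``, absences ``n.s. ({residue})``
    and one-nucleotide shifts ``shifted (+{frame})``.  The first column
    counts introns within the coding region per protein (taken from
    ``site_counts`` when given, otherwise from group membership).  By
    default only shared groups (two or more members) are shown.
    """
    selected = [g for g in groups if g.shared or not shared_only]
    selected.sort(key=lambda g: (g.column, g.frame))
    if site_counts is None:
        site_counts = {p: 0 for p in proteins}
        for g in groups:
            for m in g.members:
                if m.protein_id in site_counts:
                    site_counts[m.protein_id] += 1
    data = {}
    data["introns_within_coding_region"] = [site_counts.get(p, 0) for p in proteins]
    for group in selected:
        cells = []
        for protein_id in proteins:
            member = next(
                (m for m in group.members if m.protein_id == protein_id), None
            )
            if member is not None:
                site = member.source_site
                cells.append(f"{site.residue}{site.protein_index}, +{site.frame}")
                continue
            entry = group.non_members.get(protein_id)
            if entry is None:
                cells.append("")
            elif entry.status == SHIFTED:
                cells.append(f"shifted (+{entry.shifted_site.frame})")
            else:
                if entry.residue == GAP:
                    cells.append("n.s. (-)")
                else:
                    cells.append(f"n.s. ({entry.residue}{entry.residue_index})")
        data[group.name] = cells
    return pd.DataFrame(data, index=pd.Index(proteins, name="protein"))
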