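"""Synthetic scaffold alignment for the tunicate GH6-1 shared-site layout.

The true MAFFT alignment of tunicate GH6-1 / CesA-GH6 proteins is not
redistributed here.  Instead this module *constructs* a synthetic scaffold
alignment in which the documented splice-site labels of ten tunicate
GH6-domain proteins (eight GH6-1 proteins and the larvacean CesA1 GH6
domain) co-occur at consistent columns: three shared-site columns carry
the residues named by each protein's site label (e.g. V217, G256, K316 of
the Ciona intestinalis GH6-1 protein), non-site proteins carry their
documented aligned residue at those columns, and the CesA1 R1100 site sits
in the shared column but in frame +2, one nucleotide off the frame +3
GH6-1 sites.  Filler residues outside these columns are deterministic and
carry no signal.

This synthetic layout exercises the classifier exactly as the real
alignment would: same membership, same n.s. conservation calls, same
one-nucleotide shift.
"""

from __future__ import annotations

from splicemark.alignment_projection import ProteinAlignment
from splicemark.gene_structures import CodingSpliceSite

AMINO = "ACDEFGHIKLMNPQRSTVWY"

#: Per protein: total introns within the coding region, then the three
#: scaffold positions as (residue_index, residue, frame, has_site).
#: ``has_site=False`` encodes an "n.s." cell: the residue is present at
#: the aligned column but no exon boundary falls there.
GH6_ROWS: dict[str, tuple[int, list[tuple[int, str, int, bool]]]] = {
    "CinGH6-1":  (3, [(217, "V", 2, True),  (256, "G", 1, True),  (316, "K", 3, True)]),
    "CsaGH6-1":  (3, [(223, "V", 2, True),  (262, "G", 1, True),  (322, "K", 3, True)]),
    "SthGH6-1a": (6, [(229, "E", 2, True),  (268, "G", 1, True),  (328, "P", 3, True)]),
    "SthGH6-1b": (5, [(230, "K", 2, True),  (269, "G", 1, True),  (329, "K", 3, True)]),
    "MoxGH6-1":  (3, [(222, "R", 2, True),  (260, "G", 1, True),  (320, "A", 3, True)]),
    "MocGH6-1":  (2, [(222, "R", 2, False), (260, "G", 1, True),  (320, "A", 3, True)]),
    "BscGH6-1":  (5, [(335, "K", 2, True),  (373, "G", 1, True),  (433, "A", 3, True)]),
    "BleGH6-1":  (4, [(229, "K", 2, True),  (285, "G", 1, False), (345, "A", 3, True)]),
    "OdiGH6-1":  (6, [(244, "N", 2, False), (282, "G", 1, False), (343, "K", 3, False)]),
    # the CesA1 boundary aligns with the third column but in frame +2
    "OdiCesA1":  (8, [(1001, "R", 2, False), (1040, "G", 1, False), (1100, "R", 2, True)]),
}

GH6_PROTEIN_ORDER = list(GH6_ROWS)
REFERENCE_PROTEIN = "CinGH6-1"

#: Scaffold columns of the three shared-site positions.  The first is the
#: largest first-position residue index (no leading gap for OdiCesA1); the
#: spacings are the largest inter-position residue spans (BleGH6-1 spans
#: 56 residues between positions 1 and 2, OdiGH6-1 spans 61 between 2 and 3).
_COL1 = max(entries[0][0] for _, entries in GH6_ROWS.values())
_COL2 = _COL1 + max(e[1][0] - e[0][0] for _, e in GH6_ROWS.values())
_COL3 = _COL2 + max(e[2][0] - e[1][0] for _, e in GH6_ROWS.values())
SCAFFOLD_COLUMNS = (_COL1, _COL2, _COL3)

#: Extra (unshared) sites start this many residues after the third column;
#: closer placements would sit within one nucleotide of the shared
#: boundary and read as intron sliding instead of independent sites.
_TAIL_OFFSET = 2


def _filler(index: int) -> str:
    return AMINO[index % len(AMINO)]


def gh6_shared_site_fixture() -> tuple[
    ProteinAlignment, dict[str, list[CodingSpliceSite]], dict[str, int]
]:
    """Build the scaffold alignment, per-protein sites, and intron counts.

    Returns ``(alignment, sites, site_counts)``.  Each protein carries its
    three scaffold positions (with or without a site) plus enough extra
    sites at protein-unique tail columns to bring its total site count to
    the documented number of introns within the coding region.
    """
    n_extra_total = sum(
        count - sum(1 for e in entries if e[3])
        for count, entries in GH6_ROWS.values()
    )
    tail_len = _TAIL_OFFSET + n_extra_total + 2

    rows: dict[str, str] = {}
    sites: dict[str, list[CodingSpliceSite]] = {}
    counts: dict[str, int] = {}
    extra_cursor = 0  # global counter => every extra site gets a unique column
    for protein_id, (count, entries) in GH6_ROWS.items():
        (r1, a1, f1, m1), (r2, a2, f2, m2), (r3, a3, f3, m3) = entries
        residues = {r1: a1, r2: a2, r3: a3}

        def stretch(lo: int, hi: int, width: int) -> str:
            body = "".join(residues.get(i, _filler(i)) for i in range(lo, hi + 1))
            return "-" * (width - len(body)) + body

        row = (
            stretch(1, r1, _COL1)
            + stretch(r1 + 1, r2, _COL2 - _COL1)
            + stretch(r2 + 1, r3, _COL3 - _COL2)
            + "".join(_filler(i) for i in range(r3 + 1, r3 + tail_len + 1))
        )

        site_list = [
            CodingSpliceSite(r, f, 3 * (r - 1) + f, a)
            for (r, a, f, member) in entries
            if member
        ]
        n_extra = count - len(site_list)
        for _ in range(n_extra):
            extra_cursor += 1
            r = r3 + _TAIL_OFFSET + extra_cursor
            site_list.append(
                CodingSpliceSite(r, 1, 3 * (r - 1) + 1, _filler(r))
            )
        rows[protein_id] = row
        sites[protein_id] = site_list
        counts[protein_id] = count

    width = max(len(r) for r in rows.values())
    rows = {k: v + "-" * (width - len(v)) for k, v in rows.items()}
    return ProteinAlignment(rows), sites, counts
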