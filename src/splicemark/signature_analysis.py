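"""PROSITE-style signature patterns and catalytic-residue conservation.

Implements the pattern grammar of PROSITE entries (e.g. the glycosyl
hydrolase family 6 "signature 2", PS00656:
``[LIVMYA]-[LIVA]-[LIVT]-[LIV]-E-P-D-[SAL]-[LI]-[PSAG]``), an overlapping
scanner for ungapped sequences, a per-row window scorer that counts how
many pattern positions a region of an alignment satisfies ("8-9 out of
10"-style statements), and a check of whether each aligned protein keeps
an expected residue (e.g. the catalytic aspartate) at a reference-anchored
alignment column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from splicemark.alignment_projection import (
    GAP,
    ProteinAlignment,
    column_to_residue_index,
    residue_to_column,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FIXED = "fixed"
ANY = "any"
CLASS = "class"
NEGATED = "negated"


class PatternError(ValueError):
    """Raised on malformed PROSITE pattern syntax."""


@dataclass(frozen=True)
class PatternElement:
    kind: str  # FIXED / ANY / CLASS / NEGATED
    residues: frozenset[str]  # allowed (CLASS) or forbidden (NEGATED) set
    min_repeat: int = 1
    max_repeat: int = 1

    def matches(self, residue: str) -> bool:
        """One aligned/ungapped character against this element.

        Gaps never match.  An ``X`` in the sequence is credited only to an
        ``x`` (any) element — unknown residues earn no class credit.
        """
        residue = residue.upper()
        if residue == GAP:
            return False
        if self.kind == ANY:
            return True
        if residue == "X":
            return False
        if self.kind == FIXED or self.kind == CLASS:
            return residue in self.residues
        return residue not in self.residues  # NEGATED


@dataclass(frozen=True)
class SignaturePattern:
    accession: str
    elements: tuple[PatternElement, ...]
    n_anchor: bool = False  # '<' : match must start at the N terminus
    c_anchor: bool = False  # '>' : match must end at the C terminus

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternError(f"{self.accession}: pattern has no elements")

    @property
    def fixed_length(self) -> int | None:
        """Window length if every repeat is fixed, else None."""
        total = 0
        for el in self.elements:
            if el.min_repeat != el.max_repeat:
                return None
            total += el.min_repeat
        return total

    def expand_fixed(self) -> list[PatternElement]:
        """Unroll fixed repeats into one element per position."""
        if self.fixed_length is None:
            raise PatternError(
                f"{self.accession}: variable-length repeats cannot be "
                "expanded into a fixed window"
            )
        out = []
        for el in self.elements:
            single = PatternElement(el.kind, el.residues)
            out.extend([single] * el.min_repeat)
        return out

    def to_regex(self) -> str:
        parts = []
        if self.n_anchor:
            parts.append("^")
        for el in self.elements:
            if el.kind == ANY:
                core = "."
            elif el.kind == FIXED:
                core = next(iter(el.residues))
            elif el.kind == CLASS:
                core = "[" + "".join(sorted(el.residues)) + "]"
            else:
                # X earns no credit from a negated class either
                core = "[^" + "".join(sorted(el.residues)) + "X]"
            if (el.min_repeat, el.max_repeat) != (1, 1):
                core += f"{{{el.min_repeat},{el.max_repeat}}}"
            parts.append(core)
        if self.c_anchor:
            parts.append("$")
        return "".join(parts)


_REPEAT_RE = re.compile(r"^\((\d+)(?:,(\d+))?\)$")


def _parse_element(token: str, position: int) -> PatternElement:
    min_rep = max_rep = 1
    if "(" in token:
        idx = token.index("(")
        token, repeat = token[:idx], token[idx:]
        m = _REPEAT_RE.match(repeat)
        if not m:
            raise PatternError(f"element {position}: malformed repeat '{repeat}'")
        min_rep = int(m.group(1))
        max_rep = int(m.group(2)) if m.group(2) else min_rep
        if min_rep > max_rep:
            raise PatternError(
                f"element {position}: repeat minimum exceeds maximum in '{repeat}'"
            )
    if token.startswith("["):
        if not token.endswith("]") or len(token) < 3:
            raise PatternError(f"element {position}: unbalanced or empty class")
        residues = token[1:-1].upper()
        if not residues.isalpha():
            raise PatternError(f"element {position}: bad class '{token}'")
        return PatternElement(CLASS, frozenset(residues), min_rep, max_rep)
    if token.startswith("{"):
        if not token.endswith("}") or len(token) < 3:
            raise PatternError(
                f"element {position}: unbalanced or empty negated class"
            )
        residues = token[1:-1].upper()
        if not residues.isalpha():
            raise PatternError(f"element {position}: bad negated class '{token}'")
        return PatternElement(NEGATED, frozenset(residues), min_rep, max_rep)
    if token in ("x", "X"):
        return PatternElement(ANY, frozenset(), min_rep, max_rep)
    if len(token) == 1 and token.upper() in AMINO_ACIDS:
        return PatternElement(FIXED, frozenset(token.upper()), min_rep, max_rep)
    raise PatternError(f"element {position}: unrecognised token '{token}'")


def parse_prosite_pattern(text: str, accession: str = "pattern") -> SignaturePattern:
    """Parse a hyphen-separated PROSITE pattern string.

    Supports fixed residues, ``x``, ``x(n)``, ``x(n,m)``, ``[..]`` classes,
    ``{..}`` negated classes, the ``<``/``>`` terminal anchors and an
    optional trailing period.
    """
    text = text.strip().rstrip(".")
    if not text:
        raise PatternError("empty pattern")
    n_anchor = text.startswith("<")
    if n_anchor:
        text = text[1:]
    c_anchor = text.endswith(">")
    if c_anchor:
        text = text[:-1]
    tokens = [t.strip() for t in text.split("-")]
    elements = []
    for position, token in enumerate(tokens, start=1):
        if not token:
            raise PatternError(f"element {position}: empty token")
        elements.append(_parse_element(token, position))
    return SignaturePattern(accession, tuple(elements), n_anchor, c_anchor)


def scan_sequence(
    pattern: SignaturePattern, seq: str
) -> list[tuple[int, int]]:
    """All matches of a pattern in an ungapped sequence.

    Returns 1-based inclusive ``(start, end)`` spans.  Overlapping matches
    are all reported (one per start position); variable repeats are
    resolved greedily with backtracking, so the span at a given start is
    the longest consistent one.
    """
    seq = seq.upper()
    regex = re.compile("(?=(" + pattern.to_regex() + "))")
    spans = []
    for m in regex.finditer(seq):
        matched = m.group(1)
        if pattern.c_anchor and m.start() + len(matched) != len(seq):
            continue
        spans.append((m.start() + 1, m.start() + len(matched)))
    return spans


@dataclass(frozen=True)
class SignatureWindowScore:
    protein_id: str
    window_start_column: int
    matches: int
    out_of: int
    per_position: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.out_of:
            raise ValueError("matches outside [0, out_of]")


def score_signature_window(
    pattern: SignaturePattern,
    alignment: ProteinAlignment,
    anchor: tuple[str, int],
) -> list[SignatureWindowScore]:
    """Score every alignment row against a fixed-length signature window.

    The window is placed by the anchor protein: its residues
    ``start .. start+L-1`` (1-based) are lifted to alignment columns, and
    each row is scored position by position at those columns.  Gaps count
    as mismatches — the signature is "out of L amino acids", so a deletion
    loses the position.  Variable-repeat patterns cannot be window-scored.
    """
    anchor_id, start_index = anchor
    elements = pattern.expand_fixed()
    if anchor_id not in alignment.rows:
        raise KeyError(f"anchor protein {anchor_id} not in alignment")
    anchor_row = alignment.rows[anchor_id]
    n_residues = len(anchor_row.replace(GAP, ""))
    if start_index < 1 or start_index + len(elements) - 1 > n_residues:
        raise IndexError(
            f"window {start_index}..{start_index + len(elements) - 1} crosses "
            f"the end of {anchor_id} ({n_residues} residues)"
        )
    columns = [
        residue_to_column(anchor_row, start_index + i)
        for i in range(len(elements))
    ]
    scores = []
    for protein_id, row in alignment.rows.items():
        flags = tuple(
            el.matches(row[col - 1]) for el, col in zip(elements, columns)
        )
        scores.append(
            SignatureWindowScore(
                protein_id, columns[0], sum(flags), len(elements), flags
            )
        )
    return scores


@dataclass(frozen=True)
class CatalyticCheckResult:
    protein_id: str
    aligned_residue: str  # "-" when the row is gapped at the column
    aligned_protein_index: int | None
    is_expected: bool
    status: str  # "residue" or "gap"

    @property
    def label(self) -> str:
        """e.g. ``E197``, or ``-`` for a gap."""
        if self.status == "gap":
            return "-"
        return f"{self.aligned_residue}{self.aligned_protein_index}"


def catalytic_residue_check(
    alignment: ProteinAlignment,
    ref_id: str,
    ref_protein_index: int,
    expected: str,
) -> list[CatalyticCheckResult]:
    """Check conservation of an expected residue at an anchored column.

    The column is the one holding residue ``ref_protein_index`` of
    ``ref_id`` (e.g. the catalytic D221 of a reference exoglucanase); each
    row reports its residue there, that residue's own index, and whether it
    equals ``expected``.  A reference residue differing from ``expected``
    is tolerated with a warning so non-canonical anchors remain usable.
    """
    import warnings

    expected = expected.upper()
    if ref_id not in alignment.rows:
        raise KeyError(f"reference protein {ref_id} not in alignment")
    ref_row = alignment.rows[ref_id]
    column = residue_to_column(ref_row, ref_protein_index)
    if ref_row[column - 1].upper() != expected:
        warnings.warn(
            f"reference residue {ref_row[column - 1]}{ref_protein_index} of "
            f"{ref_id} is not the expected '{expected}'",
            stacklevel=2,
        )
    results = []
    for protein_id, row in alignment.rows.items():
        residue = row[column - 1].upper()
        if residue == GAP:
            results.append(
                CatalyticCheckResult(protein_id, GAP, None, False, "gap")
            )
        else:
            idx = column_to_residue_index(row, column)
            results.append(
                CatalyticCheckResult(
                    protein_id, residue, idx, residue == expected, "residue"
                )
            )
    return results
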