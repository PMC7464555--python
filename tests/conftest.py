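"""Shared helpers: random stop-free CDSs and intron-insertion builders."""

from __future__ import annotations

import numpy as np
import pytest

from splicemark.gene_structures import (
    GeneModel,
    GenomicInterval,
    STOP_CODONS,
)

BASES = "ACGT"
NONSTOP = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def random_cds(rng: np.random.Generator, n_codons: int, stop: bool = True) -> str:
    """A stop-free random CDS of ``n_codons`` codons (+ terminal stop)."""
    body = "".join(NONSTOP[i] for i in rng.integers(len(NONSTOP), size=n_codons))
    return body + ("TAA" if stop else "")


def random_intron(rng: np.random.Generator, length: int) -> str:
    interior = "".join(BASES[i] for i in rng.integers(4, size=length - 4))
    return "GT" + interior + "AG"


def insert_introns(
    cds: str, cuts: list[int], introns: list[str], seq_id: str = "chr"
) -> tuple[str, GeneModel]:
    """Insert introns after the given 1-based CDS offsets; return genome+model."""
    assert cuts == sorted(cuts) and len(cuts) == len(introns)
    pieces, intervals, prev, pos = [], [], 0, 0
    for cut, intron in zip(cuts, introns):
        exon = cds[prev:cut]
        pieces.append(exon)
        intervals.append(GenomicInterval(seq_id, pos + 1, pos + len(exon), "+"))
        pos += len(exon) + len(intron)
        pieces.append(intron)
        prev = cut
    exon = cds[prev:]
    pieces.append(exon)
    intervals.append(GenomicInterval(seq_id, pos + 1, pos + len(exon), "+"))
    genome = "".join(pieces)
    return genome, GeneModel("toy", intervals, "+", source_seq=genome)
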