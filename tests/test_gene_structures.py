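"""Gene-model parsing, translation, site derivation, and spliced mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicemark.gene_structures import (
    CodingSpliceSite,
    GeneModel,
    GenomicInterval,
    Gff3ParseError,
    MappingError,
    ValidationError,
    derive_coding_splice_sites,
    map_cds_to_genome,
    parse_gff3,
    translate_cds,
    write_gff3,
)

from conftest import NONSTOP, insert_introns, random_cds, random_intron

# independent codon-table oracle: codons enumerated in TCAG order
_TCAG = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_ORACLE = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_TCAG)
    for j, b in enumerate(_TCAG)
    for k, c in enumerate(_TCAG)
}


class TestTranslateCds:
    @pytest.mark.parametrize(
        "cds, protein",
        [("ATG", "M"), ("ATGGATTAA", "MD"), ("atggat", "MD")],
    )
    def test_simple(self, cds, protein):
        assert translate_cds(cds) == protein

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError, match="internal stop"):
            translate_cds("ATGTAAGAT")

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValidationError, match="divisible by 3"):
            translate_cds("ATGG")

    def test_agrees_with_codon_table_oracle(self, rng):
        cds = random_cds(rng, 60)
        expected = "".join(
            CODON_ORACLE[cds[i : i + 3]] for i in range(0, len(cds) - 3, 3)
        )
        assert translate_cds(cds) == expected


class TestGff3:
    def test_empty_document(self):
        assert parse_gff3("") == []
        assert parse_gff3("##gff-version 3\n") == []

    def test_two_exon_plus_strand(self):
        # exons 100-250 and 301-401: 151 + 101 = 252 nt, divisible by 3
        text = (
            "##gff-version 3\n"
            "chr1\tsrc\tCDS\t100\t250\t.\t+\t0\tID=c1;Parent=g1\n"
            "chr1\tsrc\tCDS\t301\t401\t.\t+\t2\tID=c1;Parent=g1\n"
        )
        (model,) = parse_gff3(text)
        assert model.gene_id == "g1"
        assert [(iv.start, iv.end) for iv in model.intervals] == [
            (100, 250),
            (301, 401),
        ]
        assert model.coding_length == 252

    def test_length_not_divisible_by_3_names_gene(self):
        text = (
            "chr1\tsrc\tCDS\t100\t250\t.\t+\t0\tParent=gene42\n"
            "chr1\tsrc\tCDS\t301\t400\t.\t+\t2\tParent=gene42\n"
        )
        with pytest.raises(ValidationError, match="gene42"):
            parse_gff3(text)

    def test_malformed_line_reports_line_number(self):
        text = "chr1\tsrc\tCDS\t100\t250\t.\t+\t0\tParent=g1\nnot a gff line\n"
        with pytest.raises(Gff3ParseError, match="line 2"):
            parse_gff3(text)

    def test_minus_strand_transcript_order_and_cds(self, rng):
        # a 60-nt toy genome; CDS exons at 31-45 and 1-15 on the minus strand
        genome = random_cds(rng, 20, stop=False)
        text = (
            "chrM\tsrc\tCDS\t31\t45\t.\t-\t0\tParent=gm\n"
            "chrM\tsrc\tCDS\t1\t15\t.\t-\t0\tParent=gm\n"
        )
        (model,) = parse_gff3(text)
        assert [(iv.start, iv.end) for iv in model.intervals] == [(31, 45), (1, 15)]
        # reverse-complement oracle
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = lambda s: "".join(comp[c] for c in reversed(s))
        expected = rc(genome[30:45]) + rc(genome[0:15])
        assert model.coding_sequence(genome) == expected

    def test_round_trip(self):
        text = (
            "##gff-version 3\n"
            "chr1\tsrc\tCDS\t100\t250\t.\t+\t0\tID=cds-g1;Parent=g1\n"
            "chr1\tsrc\tCDS\t301\t401\t.\t+\t2\tID=cds-g1;Parent=g1\n"
        )
        models = parse_gff3(text)
        assert parse_gff3(write_gff3(models)) == models

    def test_longest_cds_kept_per_gene(self):
        text = (
            "chr1\tsrc\tCDS\t1\t30\t.\t+\t0\tParent=t1;gene=gX\n"
            "chr1\tsrc\tCDS\t1\t60\t.\t+\t0\tParent=t2;gene=gX\n"
        )
        (model,) = parse_gff3(text)
        assert model.gene_id == "t2"


class TestSiteDerivation:
    def test_single_exon_has_no_sites(self, rng):
        cds = random_cds(rng, 30)
        _, model = insert_introns(cds, [], [])
        assert derive_coding_splice_sites(model, translate_cds(cds)) == []

    @pytest.mark.parametrize(
        "first_exon_nt, index, frame",
        [(650, 217, 2), (948, 316, 3)],
    )
    def test_residue_frame_labelling(self, rng, first_exon_nt, index, frame):
        """A boundary after coding nucleotide k labels residue ceil(k/3)."""
        cds = random_cds(rng, 400)
        genome, model = insert_introns(cds, [first_exon_nt], [random_intron(rng, 40)])
        protein = translate_cds(cds)
        (site,) = derive_coding_splice_sites(model, protein)
        assert (site.protein_index, site.frame) == (index, frame)
        assert site.coding_offset == first_exon_nt
        assert site.label == f"{protein[index - 1]}{index}.frame+{frame}"

    def test_matches_nucleotide_unrolling_oracle(self, rng):
        """Sites of a 4-exon model equal those from cumulative unrolling."""
        cds = random_cds(rng, 100)
        cuts = sorted(int(c) for c in rng.choice(np.arange(5, 295), 3, replace=False))
        genome, model = insert_introns(
            cds, cuts, [random_intron(rng, 30) for _ in cuts]
        )
        protein = translate_cds(cds)
        # oracle: walk the CDS nucleotide by nucleotide across exons
        expected = []
        consumed = 0
        for length in model.exon_lengths[:-1]:
            consumed += length
            codon_idx = (consumed - 1) // 3  # 0-based codon of last nucleotide
            frame = (consumed - 1) % 3 + 1
            expected.append((codon_idx + 1, frame, consumed))
        got = derive_coding_splice_sites(model, protein)
        assert [(s.protein_index, s.frame, s.coding_offset) for s in got] == expected

    def test_protein_length_mismatch_rejected(self, rng):
        cds = random_cds(rng, 30)
        _, model = insert_introns(cds, [10], [random_intron(rng, 20)])
        with pytest.raises(ValidationError, match="protein length"):
            derive_coding_splice_sites(model, "MKV")

    def test_boundary_in_stop_codon_warns(self, rng):
        cds = random_cds(rng, 30)  # 90 coding nt + TAA
        genome, model = insert_introns(cds, [91], [random_intron(rng, 20)])
        with pytest.warns(UserWarning, match="stop codon"):
            (site,) = derive_coding_splice_sites(model, translate_cds(cds))
        assert site.protein_index == 31
        assert site.residue == "*"


class TestSpliceSiteInvariants:
    @given(offset=st.integers(min_value=1, max_value=3000))
    @settings(max_examples=300, derandomize=True)
    def test_offset_residue_frame_bijection(self, offset):
        protein = "A" * 1001
        site = CodingSpliceSite.from_offset(offset, protein)
        assert site.protein_index == -(-offset // 3)
        assert site.coding_offset == 3 * (site.protein_index - 1) + site.frame
        assert 1 <= site.frame <= 3

    @given(
        n_exons=st.integers(min_value=1, max_value=6),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=60, derandomize=True)
    def test_site_count_is_exons_minus_one(self, n_exons, seed):
        rng = np.random.default_rng(seed)
        cds = random_cds(rng, 40)
        cuts = sorted(
            int(c) for c in rng.choice(np.arange(1, 120), n_exons - 1, replace=False)
        )
        _, model = insert_introns(cds, cuts, [random_intron(rng, 20) for _ in cuts])
        sites = derive_coding_splice_sites(model, translate_cds(cds))
        assert len(sites) == n_exons - 1
        assert [s.coding_offset for s in sites] == cuts


class TestMapCdsToGenome:
    def test_identity_single_exon(self, rng):
        cds = random_cds(rng, 20)
        model = map_cds_to_genome(cds, cds, min_intron=8)
        assert [(iv.start, iv.end) for iv in model.intervals] == [(1, len(cds))]
        assert not model.ambiguous

    def test_recovers_planted_intron(self, rng):
        cds = random_cds(rng, 80)  # 243 nt
        genome, planted = insert_introns(cds, [100], [random_intron(rng, 50)])
        model = map_cds_to_genome(cds, genome, min_intron=20)
        assert [(iv.start, iv.end) for iv in model.intervals] == [
            (1, 100),
            (151, len(genome)),
        ]

    def test_mapping_failure_raises(self, rng):
        cds = random_cds(rng, 20)
        with pytest.raises(MappingError):
            map_cds_to_genome(cds, cds[:-3] + "GGG"[: 3], min_intron=8)

    def test_flanked_gene_is_found(self, rng):
        cds = random_cds(rng, 40)
        genome, _ = insert_introns(cds, [60], [random_intron(rng, 25)])
        flanked = "CCCCCCCCCC" + genome + "GGGGGGGGGG"
        model = map_cds_to_genome(cds, flanked, min_intron=20)
        assert model.coding_sequence() == cds


def _is_intron(seq: str, min_intron: int) -> bool:
    return len(seq) >= min_intron and seq[:2] == "GT" and seq[-2:] == "AG"


def enumerate_placements(cds: str, genome: str, min_intron: int):
    """Brute-force oracle: every flanked placement with up to two introns.

    Enumerates (start offset, split points, intron lengths) tuples directly
    and string-compares each candidate, independent of the mapper's search.
    Returns interval chains as lists of 1-based (start, end) tuples.
    """
    n, g = len(cds), len(genome)
    found = []
    for o in range(g - n + 1):
        if genome[o : o + n] == cds:
            found.append([(o + 1, o + n)])
    for o in range(g):
        for c in range(1, n):
            if genome[o : o + c] != cds[:c]:
                continue
            for l in range(min_intron, g - o - n + 1):
                e = o + c + l  # start of exon 2
                if genome[e : e + n - c] == cds[c:] and _is_intron(
                    genome[o + c : e], min_intron
                ):
                    found.append([(o + 1, o + c), (e + 1, e + n - c)])
                # 2-intron chains: split the remaining suffix again
                for c2 in range(c + 1, n):
                    if genome[e : e + c2 - c] != cds[c:c2]:
                        continue
                    for l2 in range(min_intron, g - e - (n - c) + 1):
                        e2 = e + (c2 - c) + l2
                        if (
                            genome[e2 : e2 + n - c2] == cds[c2:]
                            and _is_intron(genome[o + c : e], min_intron)
                            and _is_intron(genome[e + c2 - c : e2], min_intron)
                        ):
                            found.append(
                                [
                                    (o + 1, o + c),
                                    (e + 1, e + c2 - c),
                                    (e2 + 1, e2 + n - c2),
                                ]
                            )
    return found


class TestMapperOracle:
    """Exhaustive comparison with split-point enumeration on toy cases."""

    def test_all_one_intron_splits(self, rng):
        cds = random_cds(rng, 9, stop=False)  # 27 nt
        intron = random_intron(rng, 10)
        for cut in range(1, len(cds)):
            genome = cds[:cut] + intron + cds[cut:]
            solutions = enumerate_placements(cds, genome, min_intron=8)
            assert solutions, f"cut={cut}"
            expected = min(solutions)  # leftmost chain
            model = map_cds_to_genome(cds, genome, min_intron=8)
            assert [(iv.start, iv.end) for iv in model.intervals] == expected
            assert model.ambiguous == (len(solutions) > 1)

    def test_all_two_intron_splits(self, rng):
        cds = random_cds(rng, 5, stop=False)  # 15 nt
        introns = [random_intron(rng, 8), random_intron(rng, 8)]
        for c1 in range(1, len(cds) - 1):
            for c2 in range(c1 + 1, len(cds)):
                genome = cds[:c1] + introns[0] + cds[c1:c2] + introns[1] + cds[c2:]
                solutions = enumerate_placements(cds, genome, min_intron=8)
                assert solutions, f"cuts={c1},{c2}"
                expected = min(solutions)
                model = map_cds_to_genome(cds, genome, min_intron=8)
                assert [(iv.start, iv.end) for iv in model.intervals] == expected
                assert model.ambiguous == (len(solutions) > 1)


class TestIntervalValidation:
    def test_bad_interval_rejected(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr", 10, 5, "+")
        with pytest.raises(ValidationError):
            GenomicInterval("chr", 0, 5, "+")

    def test_overlapping_exons_rejected(self):
        ivs = [GenomicInterval("c", 1, 10, "+"), GenomicInterval("c", 5, 13, "+")]
        with pytest.raises(ValidationError, match="overlap"):
            GeneModel("g", ivs, "+")

    def test_internal_stop_with_source_rejected(self):
        seq = "ATGTAAATT"
        ivs = [GenomicInterval("c", 1, 9, "+")]
        with pytest.raises(ValidationError, match="stop"):
            GeneModel("g", ivs, "+", source_seq=seq)
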