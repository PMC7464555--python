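"""Simulation of orthologous gene families with known intron histories.

A root coding sequence evolves along a phylogeny: a configurable number of
ancestral introns is planted at distinct coding offsets, branch-specific
intron gains and losses occur either at Poisson rates per unit branch
length or as an exact planted number of events, and nucleotide
substitutions accumulate without indels.  Because no indels occur, the
true protein alignment is the identity, every homologous intron keeps its
coding offset in every descendant, and site homology is known exactly —
which makes the simulator an oracle for the whole splice-site pipeline
(mapping, site derivation, projection, shared-site classification).

Genomes are emitted with GT..AG introns and short flanks; intron and flank
sequences are resampled until exact spliced mapping of the CDS back onto
the genome is certified unique, so the mapper's output equals the planted
gene structure by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from splicemark.gene_structures import (
    GeneModel,
    GenomicInterval,
    MappingError,
    STOP_CODONS,
    map_cds_to_genome,
    translate_cds,
    write_gff3,
)

#: An 8-taxon tunicate-like topology: the larvacean (Odi) branches first,
#: then the salp (Sth), then ascidian lineages.
DEFAULT_TREE = (
    "(Odi:0.50,(Sth:0.35,((Bsc:0.20,Ble:0.20):0.10,"
    "((Mox:0.12,Moc:0.12):0.10,(Cin:0.15,Csa:0.15):0.07):0.08):0.05):0.05);"
)

_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]

#: Gains (and ancestral placements) keep at least this nucleotide distance
#: between any two intron offsets, so no two truth classes can be confused
#: with a one-nucleotide shift of one another.
MIN_OFFSET_SEPARATION = 4


class SimulationError(ValueError):
    """Raised when a configuration cannot be satisfied."""


@dataclass
class SimulationConfig:
    """Parameters of a gene-family simulation.

    Branch-specific events can be specified either as rates (events per
    unit branch length, sampled as Poisson processes) or as exact planted
    counts (``n_gain_events`` / ``n_loss_events``) distributed over
    branches with probability proportional to branch length.
    """

    tree: str = DEFAULT_TREE
    n_ancestral_introns: int = 5
    gain_rate: float = 0.0
    loss_rate: float = 0.0
    n_gain_events: int | None = None
    n_loss_events: int | None = None
    substitution_prob: float = 0.0  # per site per unit branch length
    intron_length: tuple[int, int] = (50, 80)
    cds_length_codons: int = 300
    flank_length: int = 30
    min_intron: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length_codons < 10:
            raise SimulationError("cds_length_codons must be >= 10")
        if self.n_ancestral_introns < 0:
            raise SimulationError("n_ancestral_introns must be >= 0")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise SimulationError("rates must be >= 0")
        if self.substitution_prob < 0:
            raise SimulationError("substitution_prob must be >= 0")
        lo, hi = self.intron_length
        if lo > hi or lo < self.min_intron:
            raise SimulationError(
                f"intron_length {self.intron_length} must satisfy "
                f"min >= min_intron ({self.min_intron}) and min <= max"
            )


@dataclass(frozen=True)
class IntronClass:
    """One homologous intron position: a truth label for recovery tests."""

    class_id: int
    coding_offset: int  # boundary after this 1-based coding nucleotide
    origin: str  # "root" or the name of the node below the gaining branch
    taxa: frozenset[str]

    def offsets_by_taxon(self) -> dict[str, int]:
        # no indels: the offset is identical in every carrying taxon
        return {taxon: self.coding_offset for taxon in self.taxa}


@dataclass
class SimulatedFamily:
    config: SimulationConfig
    genomes: dict[str, str]
    models: dict[str, GeneModel]
    cds: dict[str, str]
    proteins: dict[str, str]
    truth: list[IntronClass]
    n_gain_events: int = 0
    n_loss_events: int = 0

    def truth_pairs(self) -> set[tuple[str, int]]:
        """(taxon, coding_offset) membership pairs of the truth table."""
        return {
            (taxon, cls.coding_offset) for cls in self.truth for taxon in cls.taxa
        }

    def site_counts(self) -> dict[str, int]:
        counts = {taxon: 0 for taxon in self.genomes}
        for cls in self.truth:
            for taxon in cls.taxa:
                counts[taxon] += 1
        return counts


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(body) + stop


def _sample_offsets(
    rng: np.random.Generator, n: int, lo: int, hi: int, taken: set[int]
) -> list[int]:
    """Sample n offsets in [lo, hi], all >= MIN_OFFSET_SEPARATION apart."""
    chosen: list[int] = []
    candidates = list(range(lo, hi + 1))
    for _ in range(n):
        valid = [
            k
            for k in candidates
            if all(
                abs(k - other) >= MIN_OFFSET_SEPARATION
                for other in chosen + list(taken)
            )
        ]
        if not valid:
            raise SimulationError(
                "cannot place another intron: no coding offset is at least "
                f"{MIN_OFFSET_SEPARATION} nt from all existing sites"
            )
        chosen.append(int(valid[rng.integers(len(valid))]))
    return chosen


def _mutate_branch(
    rng: np.random.Generator, cds: str, prob: float
) -> str:
    """Substitute nucleotides without indels or internal stop creation."""
    if prob <= 0:
        return cds
    seq = list(cds)
    n = len(seq)
    hits = np.nonzero(rng.random(n - 3) < min(prob, 1.0))[0]  # spare the stop
    for pos in hits:
        old = seq[pos]
        new = _BASES[rng.integers(4)]
        while new == old:
            new = _BASES[rng.integers(4)]
        seq[pos] = new
        codon_start = (pos // 3) * 3
        if "".join(seq[codon_start : codon_start + 3]) in STOP_CODONS:
            seq[pos] = old  # would create an internal stop; revert
    return "".join(seq)


def _random_intron(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    interior = "".join(_BASES[i] for i in rng.integers(4, size=length - 4))
    return "GT" + interior + "AG"


def _random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=length))


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Run one gene-family simulation; fully reproducible given the seed.

    Draw order: root CDS, ancestral offsets, planted-event branch
    assignment (if counts are given), then per branch in preorder losses,
    gains and substitutions, then per leaf intron/flank sequences (with
    resampling until spliced mapping back to the genome is certified
    unique and unambiguous).
    """
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise SimulationError("duplicate taxon labels in tree")

    root_cds = _random_cds(rng, config.cds_length_codons)
    protein_len = config.cds_length_codons - 1
    lo_off, hi_off = 4, 3 * protein_len - 3
    used_offsets: set[int] = set()
    ancestral = _sample_offsets(
        rng, config.n_ancestral_introns, lo_off, hi_off, used_offsets
    )
    used_offsets.update(ancestral)

    classes: dict[int, dict] = {}
    for offset in sorted(ancestral):
        cid = len(classes)
        classes[cid] = {"offset": offset, "origin": "root", "taxa": set()}

    branches = [
        node
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    lengths = np.array([node.edge.length or 0.0 for node in branches])

    def _node_name(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or f"node{branches.index(node)}"

    planted_gains: dict[int, int] = {i: 0 for i in range(len(branches))}
    planted_losses: dict[int, int] = {i: 0 for i in range(len(branches))}
    if config.n_gain_events or config.n_loss_events:
        if lengths.sum() <= 0:
            raise SimulationError("tree has no branch length to place events on")
        probs = lengths / lengths.sum()
        for _ in range(config.n_gain_events or 0):
            planted_gains[int(rng.choice(len(branches), p=probs))] += 1
        for _ in range(config.n_loss_events or 0):
            planted_losses[int(rng.choice(len(branches), p=probs))] += 1

    # evolve (cds, set of class ids) down the tree
    state: dict[int, tuple[str, frozenset[int]]] = {
        id(tree.seed_node): (root_cds, frozenset(classes))
    }
    n_gains_applied = 0
    n_losses_applied = 0
    for b_idx, node in enumerate(branches):
        parent_cds, parent_classes = state[id(node.parent_node)]
        bl = node.edge.length or 0.0
        present = set(parent_classes)

        if config.n_loss_events is None and config.loss_rate > 0:
            n_loss = int(rng.poisson(config.loss_rate * bl))
        else:
            n_loss = planted_losses[b_idx]
        for _ in range(n_loss):
            if not present:
                break
            victims = sorted(present)
            present.discard(victims[int(rng.integers(len(victims)))])
            n_losses_applied += 1

        if config.n_gain_events is None and config.gain_rate > 0:
            n_gain = int(rng.poisson(config.gain_rate * bl))
        else:
            n_gain = planted_gains[b_idx]
        if n_gain:
            new_offsets = _sample_offsets(rng, n_gain, lo_off, hi_off, used_offsets)
            used_offsets.update(new_offsets)
            for offset in new_offsets:
                cid = len(classes)
                classes[cid] = {
                    "offset": offset,
                    "origin": _node_name(node),
                    "taxa": set(),
                }
                present.add(cid)
                n_gains_applied += 1

        child_cds = _mutate_branch(rng, parent_cds, config.substitution_prob * bl)
        state[id(node)] = (child_cds, frozenset(present))
        if node.is_leaf():
            for cid in present:
                classes[cid]["taxa"].add(node.taxon.label)

    genomes: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    cds_by_taxon: dict[str, str] = {}
    proteins: dict[str, str] = {}
    lo_i, hi_i = config.intron_length
    for node in tree.leaf_node_iter():
        taxon = node.taxon.label
        cds, present = state[id(node)]
        offsets = sorted(classes[cid]["offset"] for cid in present)
        for attempt in range(200):
            left = _random_flank(rng, config.flank_length)
            right = _random_flank(rng, config.flank_length)
            introns = [_random_intron(rng, lo_i, hi_i) for _ in offsets]
            pieces, prev = [left], 0
            intervals = []
            pos = len(left)
            for offset, intron in zip(offsets, introns):
                exon = cds[prev:offset]
                pieces.append(exon)
                intervals.append((pos + 1, pos + len(exon)))
                pos += len(exon)
                pieces.append(intron)
                pos += len(intron)
                prev = offset
            exon = cds[prev:]
            pieces.append(exon)
            intervals.append((pos + 1, pos + len(exon)))
            pieces.append(right)
            genome = "".join(pieces)
            try:
                mapped = map_cds_to_genome(
                    cds, genome, min_intron=config.min_intron,
                    seq_id=taxon, gene_id=taxon,
                )
            except MappingError:
                continue
            planted = [
                GenomicInterval(taxon, s, e, "+") for s, e in intervals
            ]
            if mapped.ambiguous or list(mapped.intervals) != planted:
                continue
            genomes[taxon] = genome
            models[taxon] = GeneModel(
                taxon, planted, "+", source_seq=genome
            )
            break
        else:
            raise SimulationError(
                f"{taxon}: could not emit an unambiguously mappable genome"
            )
        cds_by_taxon[taxon] = cds
        proteins[taxon] = translate_cds(cds)

    truth = [
        IntronClass(
            cid,
            info["offset"],
            info["origin"],
            frozenset(info["taxa"]),
        )
        for cid, info in classes.items()
        if info["taxa"]
    ]
    truth.sort(key=lambda c: c.coding_offset)
    return SimulatedFamily(
        config=config,
        genomes=genomes,
        models=models,
        cds=cds_by_taxon,
        proteins=proteins,
        truth=truth,
        n_gain_events=n_gains_applied,
        n_loss_events=n_losses_applied,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float
    n_true_pairs: int
    n_predicted_pairs: int
    empty_prediction: bool = False


def evaluate_recovery(truth, predicted) -> RecoveryMetrics:
    """Score predicted shared-site groups against a simulation's truth.

    Membership is evaluated at the (taxon, intron-homology-class) level;
    predicted groups are matched to truth classes by coding-offset
    identity.  ``truth`` may be a :class:`SimulatedFamily` or a set of
    (taxon, offset) pairs.  An empty prediction has undefined precision,
    reported as 1.0 with ``empty_prediction`` set.
    """
    if isinstance(truth, SimulatedFamily):
        true_pairs = truth.truth_pairs()
    else:
        true_pairs = set(truth)
    predicted_pairs: set[tuple[str, int]] = set()
    for group in predicted:
        for member in group.members:
            predicted_pairs.add(
                (member.protein_id, member.source_site.coding_offset)
            )
    correct = len(true_pairs & predicted_pairs)
    empty = not predicted_pairs
    precision = 1.0 if empty else correct / len(predicted_pairs)
    recall = 1.0 if not true_pairs else correct / len(true_pairs)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return RecoveryMetrics(
        precision, recall, f1, len(true_pairs), len(predicted_pairs), empty
    )


def write_family(family: SimulatedFamily, outdir: str | Path) -> dict[str, Path]:
    """Emit genomes/CDS/protein FASTA, GFF3, newick echo and a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fa",
        "cds": outdir / "cds.fa",
        "proteins": outdir / "proteins.fa",
        "models": outdir / "models.gff3",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.tsv",
    }

    def _fasta(records: dict[str, str]) -> str:
        out = []
        for name, seq in records.items():
            out.append(f">{name}")
            out.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
        return "\n".join(out) + "\n"

    paths["genomes"].write_text(_fasta(family.genomes))
    paths["cds"].write_text(_fasta(family.cds))
    paths["proteins"].write_text(_fasta(family.proteins))
    paths["models"].write_text(write_gff3(list(family.models.values())))
    paths["tree"].write_text(family.config.tree.strip() + "\n")
    lines = ["class_id\tcoding_offset\torigin\ttaxa"]
    for cls in family.truth:
        lines.append(
            f"{cls.class_id}\t{cls.coding_offset}\t{cls.origin}\t"
            + ",".join(sorted(cls.taxa))
        )
    paths["truth"].write_text("\n".join(lines) + "\n")
    return paths
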