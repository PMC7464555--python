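# Methods

## Splice-site labelling

A gene model is a chain of coding exons on one sequence and strand, kept
in transcription order; the coding length must be a multiple of three and
(when genomic sequence is attached) free of internal stop codons. Each
internal exon boundary is labelled by the coding-nucleotide offset *k* of
the exon's last nucleotide, decomposed as `k = 3·(i−1) + f`: residue index
`i = ⌈k/3⌉` and codon frame `f ∈ {1,2,3}` (written +1/+2/+3). This is a
bijection between offsets and (residue, frame) pairs, property-tested as
such. Frames relate to the usual intron-phase notation as phase 0 → +3,
phase 1 → +1, phase 2 → +2; a frame +3 boundary falls between codons and
is assigned to the *preceding* residue's column (a boundary after codon
316's third nucleotide is "K316, +3", not a site at residue 317). A
boundary inside the terminal stop codon is legal, assigned residue index
`protein length + 1` with residue `*` and a warning. Models must be
start-to-stop complete; partial fragments are rejected upstream.

## Exact spliced mapping

`map_cds_to_genome` places a CDS on genomic sequence under an exact-match
model: the CDS must be recoverable by excising introns that are at least
`min_intron` nt (default 20) long and flanked by GT..AG (GC..AG optionally
accepted). Leading and trailing genomic flanks are allowed, so a gene
region extracted with context maps correctly. The search is a
depth-first enumeration that prefers, at every exon boundary, the leftmost
intron start (and then the shortest intron); when more than one exon chain
is consistent the leftmost chain is returned and the model is flagged
`ambiguous` — never silently. This is intentionally *not* a spliced
aligner: mismatches, frameshifts and sequencing errors are out of scope,
which keeps the mapper's behaviour fully checkable against a brute-force
enumeration of (start offset, split points, intron lengths), and is the
regime the simulator guarantees.

## Projection and shared-site classification

Sites are lifted into a protein multiple alignment by counting non-gap
characters: site residue `i` of a protein maps to the column of its `i`-th
non-gap character, and the site's residue letter is cross-checked against
the row (a mismatch aborts the projection, since it means the alignment
and the gene-derived protein disagree). Shared-site groups are the
equivalence classes of (column, frame): residue identity plays no role in
membership. Groups are named after the reference protein's member when it
has one (first three characters of its id plus the residue index, giving
names like `Cin316`), else after the leftmost member.

For every protein absent from a group we assign one status:

- `shifted_one_nt` — one of the protein's own boundaries lies exactly one
  nucleotide from the group boundary on the unrolled codon grid. The grid
  gives each alignment column three nucleotide slots; before measuring,
  columns gapped in *both* rows of the measured pair are deleted, so the
  distance reflects the two sequences' mutual alignment and not gaps
  induced by third sequences. The window is exactly 1 nt by default
  (classical intron sliding); wider windows are a configuration option,
  off by default.
- `no_site_conserved_residue` / `no_site_nonconserved_residue` —
  otherwise, split by whether the protein's residue at the group column
  equals the majority residue of the group members; ties count as
  non-conserved. The conservation rule is a package choice — simple,
  deterministic, and reproduces the documented annotations on the GH6
  scaffold — not a claim about how any particular published table was
  annotated.

Singleton groups are kept (flagged unshared) so per-protein intron counts
and recovery scoring see every site.

## PROSITE engine

The pattern grammar supports fixed residues, `x`, repeats `(n)`/`(n,m)`,
classes `[..]`, negated classes `{..}`, terminal anchors `<`/`>` and a
trailing period. Scanning compiles the pattern to a regular expression
inside a lookahead so overlapping matches are all reported; variable
repeats resolve greedily with backtracking. The scanner is verified
against an oracle that exhaustively enumerates repeat expansions. Window
scoring requires a fixed-length pattern (PS00656 is 10 positions): the
window is anchored by one protein's residue range, lifted to columns, and
every row is scored position by position. Gaps never match — the score is
"out of N amino acids", so a deletion loses its position. An `X` in a
sequence matches only `x` elements; it earns no credit from classes or
negated classes. No PROSITE database entries are bundled: patterns are
supplied as strings (PS00655's definition, for instance, must come from
the user).

The catalytic check anchors a column by a reference protein's residue
(e.g. an exoglucanase's catalytic D221) and reports, for every row, the
aligned residue, that residue's own index (so substitutions are reported
in each protein's own numbering, e.g. `E197`), and whether it equals the
expected residue; gapped rows are reported as `gap`. A reference residue
that is not the expected one warns instead of failing, so non-canonical
anchors remain usable.

## The family simulator

The simulator is the package's source of ground truth. A root CDS
(default 300 codons: `ATG`, random stop-free codons, one stop codon)
evolves along a newick tree — the default is an 8-taxon tunicate-like
topology with the larvacean branching first. Ancestral introns (default
5) are planted at distinct coding offsets; every pair of offsets, whether
ancestral or gained, is kept at least 4 nt apart so that no two truth
classes can masquerade as one-nucleotide shifts of each other. Gains and
losses are sampled per branch either as Poisson processes (events per
unit branch length) or as exact planted counts distributed over branches
in proportion to branch length. Substitutions are applied per site at
`substitution_prob × branch length`, never creating internal stops and
never touching the terminal stop codon; there are no indels by default,
so the true protein alignment is the identity and each homologous intron
keeps one coding offset in all carriers. An optional external alignment
can be supplied by a test harness for indel stress tests; the default
regime deliberately avoids them so that classification errors cannot be
blamed on alignment errors.

Leaf genomes are emitted as flank + exons interleaved with fresh GT..AG
introns (length uniform in 50–80 nt, ≥ the mapper's minimum of 20) +
flank. Intron and flank sequences are resampled (up to 200 times) until
exact spliced mapping of the CDS back onto the genome is certified to
return the planted chain unambiguously; a configuration that cannot be
certified raises an error rather than emitting misleading truth. All
randomness flows from one seeded NumPy generator with a documented draw
order (root CDS, ancestral offsets, event placement, per-branch events
and substitutions in preorder, per-leaf emission), so identical seeds
give byte-identical output files.

What the simulator does *not* emulate: realistic codon models or rate
heterogeneity, indel processes, alignment error, intron sequence homology,
annotation noise, or the donor side of any horizontal transfer. Passing
recovery tests therefore demonstrates that the pipeline is exact in the
exact-match regime — mapping, labelling, projection and grouping introduce
no errors of their own — not that it is robust to noisy real annotations
or to alignment artefacts.

## Recovery scoring

Predicted groups are compared with truth at the level of
(taxon, intron-class) membership pairs, with classes matched by coding
offset. Precision is correct predicted pairs over all predicted pairs
(an empty prediction is reported as precision 1.0 with an explicit flag),
recall the analogue over truth pairs, F1 their harmonic mean. Under the
no-indel regime the full pipeline achieves F1 = 1.0 across seeds — this is
asserted over 20 seeds in the test suite with 5 ancestral introns, 2
planted gains, 1 planted loss and substitution probability 0.05.

## Pipeline runs

A run is configured in one YAML file; exactly one site source is chosen
(`simulate`, `gff` + `genome_fasta`, or `cds_fasta` + `genome_fasta`).
Reports are TSVs (sites; shared-site table; signature and catalytic
scores) plus `summary.json`, which embeds a hash of the configuration
(excluding the output directory) and the seed; logs go to stderr and
`run.log`. Reruns with equal configuration and seed are byte-identical;
this is tested. The co-location check reports whether two gene models
share a sequence and, if so, the gap in base pairs between their nearest
interval ends (0 when overlapping; undefined across sequences).

When a GFF3 document carries several transcripts with the same `gene`
attribute, the longest CDS is kept and the choice logged. GFF3 reading is
restricted to CDS features and reports malformed lines by line number;
the writer emits the version pragma, and write∘parse is the identity on
CDS structure.

## Problem sizes

Defaults are desk-scale by design: 300-codon genes, 8 taxa, ≤ 10 introns
per gene, introns of 50–80 nt. The brute-force oracles used in tests run
on 15–30 nt toy CDSs with 8–10 nt introns, where exhaustive enumeration
of placements is cheap and complete.

## Known limitations

- The mapper requires exact CDS/genome agreement; any mismatch is a
  mapping failure, not a tolerated variant.
- The one-nucleotide-shift convention measures distance after pairwise
  both-gap deletion; other gap conventions are conceivable and would
  differ only in heavily gapped regions.
- Majority-residue conservation for `n.s.` annotation is a deliberate,
  simple rule; it has no statistical calibration.
- No statistical significance is attached to shared-site counts; the
  package reports structure, not probabilities.
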