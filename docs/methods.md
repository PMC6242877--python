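# Methods

This note documents the models, parameter choices and numerical
conventions behind `mirevol`, and what the synthetic-data validation does
and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand;
conversions to 1-based inclusive systems (GFF3, outfmt-6 spans) happen
only at I/O boundaries, where they are exact bijections. `U` is
normalised to `T` on FASTA read, so genomic and small-RNA sequence space
share one alphabet. Readers reject malformed records with file and line
context rather than repairing them. Conservation score tracks are sparse:
a position without data returns a missing marker, never 0, because
phastCons-style tracks have gaps and "no data" must not masquerade as "no
conservation".

## Locus curation

A candidate locus carries a hairpin sequence, 5p/3p arm offsets and a
read stack.

**Folding.** The default engine is a deterministic Nussinov-style
maximum-pairing fold (Watson–Crick + GU pairs, minimum loop 3); ViennaRNA
minimum-free-energy folding is available behind `engine="vienna"` but the
default keeps results independent of an optional binding. Traceback
prefers leaving the right end unpaired, which makes the structure a pure
function of the sequence.

**miRNA-likeness.** The acceptance criteria operationalise what a curator
checks visually: (a) exactly one terminal loop, (b) ≥ 60 % of arm bases
paired, (c) the arms flank the loop (4 nt of slack tolerates
mismatch-shifted closing pairs), (d) no arm pairs within itself. Before
loop counting, helices shorter than 3 stacked pairs are treated as
unpaired: a maximum-pairing objective happily adds isolated pairs that no
stable structure would hold, and counting them as loops would reject
genuine stem-loops. Three stacked pairs is the conventional minimum for a
stable helix. With these settings the classifier accepts ≥ 95 % of
simulated clean hairpins and ≤ 10 % of dinucleotide-shuffled decoys
(calibrated once on 100 seeded draws of each; the acceptance script
recomputes both rates).

**Duplex evidence.** A read belongs to an arm when ≥ 80 % of its span
lies within the arm extended by 3 nt — enough slack for ±1 nt
Drosha/Dicer end wobble without letting loop-spanning reads vote. A locus
passes with ≥ 1 read per arm and ≥ 10 reads total. The two filters are
independent of order.

**Known/novel.** A locus is *known* when any reference mature (either
orientation) maps ungapped along the hairpin with ≤ 1 mismatch, found by
exhaustive sliding comparison; this is deliberately gap-free because a
gapped placement of a 22-nt mature is not the same annotation.

## Orthogroups and synteny

Greedy clustering follows CD-HIT's semantics: sequences sorted by
(length desc, id asc); each sequence joins the first cluster (in creation
order) whose representative it matches at ≥ 80 % identity, where identity
is identical positions in a global alignment divided by the shorter
length. Identity counting uses match 1 / mismatch 0 / indel 0, so the
optimal alignment score *is* the number of identical positions. The
lexicographic tie-break makes output independent of input order. Family
recovery is exact for families whose pairwise divergence stays ≤ 15 %;
copies mutated independently by 15 % *each* can be 30 % apart and are not
guaranteed to cluster — the generator used for validation therefore bounds
per-copy divergence at half the threshold margin.

Synteny support compares the nearest protein-coding gene upstream and
downstream of the query locus and subject hit (a containing gene counts
as both flanks), after strand normalisation; one homologous flank pair in
matching orientation suffices. Presence evidence in the matrix is ranked
annotated > synteny_homolog > unaligned_read, direct annotation being the
strongest claim.

## Dollo reconstruction

For a presence vector with at least one present species, the gain is
placed on the stem above the MRCA of present leaves and losses on the
stems of the maximal all-absent subtrees below it. Moving the gain higher
adds at least one lost subtree per intervening node, so this placement is
the *unique* minimum-loss single-gain reconstruction — verified in the
tests by exhaustive enumeration over all internal-state assignments for
every presence vector on the five-leaf tree. Characters reconstructed as
gained at the root are assigned to a synthetic root stem whose length is
a user parameter (`root_stem_length`), reported separately, since no data
constrain the stem's true length.

Net rate is (gains − losses)/branch length (Myr). The default tree is a
Laurasiatheria-plus-rabbit topology, (((cow,pig),(dog,horse)),rabbit),
with round divergence times (cow–pig 60, dog–horse 78, their common
ancestor 85, root 90 Myr); the tree is a user input in every entry point
and nothing depends on these defaults beyond the simulations.

Seed-family turnover applies the same machinery to presence matrices
keyed by 7-nt seed instead of orthogroup; because presence is per seed, a
species losing one orthogroup while retaining another with the same seed
shows no seed-level loss (loss compensation).

## Genomic origins

**Repeat-derived calling.** Repeats with any original hit are each
shuffled `n_shuffles` times (mononucleotide permutation by default, a
dinucleotide-preserving mode behind a flag); all miRNA hairpins are
locally aligned against every shuffle and the maximum bit score observed
becomes the threshold. Shuffles are generated from a per-(repeat, index)
seed stream, so the first *k* shuffles are identical for any run with
n ≥ k — the threshold is reproducible bit-for-bit and non-decreasing in
`n_shuffles`. The threshold is always recomputed per run, never
hard-coded. Local alignment uses match +1 / mismatch −2 / gap open −5 /
extend −2, and bit scores come from the Karlin–Altschul transform with
the published ungapped parameters for +1/−2 (λ = 1.28, K = 0.46). A
locus is flagged with alignment length ≥ 30 nt and bit score strictly
above the threshold.

**Other classifiers.** Antisense couples require ≥ 95 % overlap of at
least one locus on opposite strands; the cross-mapping check reports
pairwise mismatch counts between equal-length reads of the two partners
and flags ≤ 1-mismatch pairs with their abundance ratio. miRtrons require
≥ 90 % reciprocal intron overlap on the same strand plus duplex evidence.
Duplications require ≥ 2 copies in one species, excluding opposite-strand
pairs overlapping ≥ 95 % — an antisense couple occupies one genomic
sequence and is not a pair of paralogous copies, even though a hairpin is
nearly its own reverse complement and therefore clusters with its
antisense partner. The tandem window is 100 kb on one contig. Genomic
context is majority-overlap against 3′UTR/5′UTR/intron feature space with
tie precedence UTR3 > UTR5 > intron (favouring the rarer annotation);
intergenic means no gene overlap, and a locus overlapping only coding
exons falls back to the host gene's category so the four categories stay
a partition.

## Expression statistics

An orthogroup is expressed in a tissue when its reads summed across
species reach the presence threshold (default 1 read — the weakest
defensible notion of "evidence of expression"; configurable). The
two-proportion z-test is pooled, two-sided, without continuity
correction; its type-I error is checked against 0.05 ± 0.02 over 1000
seeded null replicates. The hypergeometric overlap test returns the
upper tail P(X ≥ k) and matches exact combinatorial enumeration on every
configuration with N ≤ 12.

## Targets and conservation

Site discovery scans the ungapped UTR for the reverse complement of the
seed: 8mer (m8–m2 match + A), 7mer-m8 (no trailing A), 7mer-A1 (m7–m2
match + A, not preceded by the m8 base). All overlapping occurrences are
reported. Cross-species filtering keeps site groups (same gene,
homologous position, same seed) present in the outgroup (rabbit by
default) plus at least one other species; occurrences with a context++
score above −0.1 are dropped when scores are supplied, and the context
filter is skipped with a notice when they are not (context++ scores are
consumed, never computed — the scoring model is out of scope).

MSA lifting maps ungapped positions to alignment columns bijectively per
species; a projection is gap-flagged when the target species' gap pattern
differs from the source's inside the lifted columns, which makes the
round trip to the source species an exact identity. Pairwise site
similarity counts identical non-gap pairs over the six seed-match
columns; a gap counts as a mismatch.

The conservation profile tiles site ± 49 nt into 15 consecutive 7-nt bins
(the site in bin 8 of 15). The default statistic is the median across
sites of per-site bin means; a pooled-positions variant is available
behind `statistic="pooled"` (the choice matters little on the synthetic
fixtures; per-site means weight each site equally regardless of track
coverage). Confidence intervals are seeded bootstrap percentile
intervals (B = 1000 by default) resampling sites, the exchangeable unit.
Missing positions drop out of a site's bin mean; sites with a fully
missing bin drop out of that bin's median.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (config, seed) and emit ground-truth
labels next to every object. Defaults: 500 orthogroups, loss rate
0.002/Myr (a moderate regime giving ~10 % per-branch loss probability on
long branches), read depth 30 per arm (Poisson), per-base read error
0.005, ±1 nt end wobble, three repeat families, Beta-distributed
conservation scores with means 0.9 at sites and 0.35 in background.
Histories are simulated under the enforced Dollo regime — one gain
(branch drawn proportional to length), losses only below it, all-absent
draws rejected. The planted genome carries one labelled example of each
origin class (miRtron coinciding with an intron, plain intronic,
intergenic, a perfectly overlapping antisense couple, tandem and
dispersed duplicate pairs, repeat-derived hairpins sharing a 30-nt exact
block with a consensus) plus unlabelled random negatives.

Passing on these fixtures shows the machinery is correct and calibrated
under its own assumptions. It does not show robustness to what real data
add: isomiR end heterogeneity beyond ±1 nt, indel sequencing errors,
assembly gaps and annotation errors, repeat families diverged far from
their consensus, alignment uncertainty in real MSAs, or expression
normalisation across libraries (out of scope throughout). Validation
problem sizes (500 histories, 100 curation draws per class, 200 shuffles
per repeat, 40 profiled genes, 1000 scanned UTRs) were chosen so the full
suite runs in seconds while keeping binomial noise well inside the
asserted margins.

## Degenerate inputs and tie-breaks

All-absent presence vectors are a reconstruction error (no Dollo history
explains them) and are rejected, as are empty clustering inputs, empty
site lists for profiling, zero-length branches, and group sizes of zero
in the z-test. Equal-length clustering candidates order lexicographically
by ID; the shuffle-null threshold floors at the bit score of raw score 1
when no alignment scores positively; windows that do not tile into whole
bins are rejected rather than silently truncated.
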