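# Methods

This note documents the models, algorithms and numerical choices behind
`strainpair`, in the spirit of the methods documentation of packages like
msprime or statsmodels: enough detail that a user can predict what the
code does on their data and what the tests do and do not establish.

## Genome model and I/O

A genome is a single (circular) replicon with an ordered list of features
(CDS, rRNA, tRNA, other RNA). Coordinates are 0-based half-open internally;
GenBank and GFF3 I/O convert from/to 1-based inclusive. Each gene's
ordinal is its rank by start coordinate; orthology, synteny and region
calling all operate on ordinals, so the analysis is annotation-order based,
not base-pair based (BED output converts back to base pairs).

CDS features are translated with bacterial translation table 11; annotated
GTG/TTG initiators are rendered as M, matching deposited proteomes. A CDS
whose length is not a multiple of 3, or whose translation contains an
internal stop, is flagged *partial*, kept in the gene list (it still
occupies an ordinal) but excluded from all protein-level analyses. Compound
(join) locations are accepted only for two-segment origin-spanning
features; anything else is rejected loudly rather than silently
mis-handled. GC% is 100·(G+C)/(A+C+G+T) with ambiguity codes excluded from
numerator and denominator, reported to one decimal.

Marker-copy comparison (e.g. the two 16S rRNA copies of a chromosome
against a comparator's) uses unit-cost global alignment (edlib); the
reported distance counts substitutions plus indels.

## Orthology

Scoring: global (end-to-end) alignment with affine gaps under BLOSUM62,
gap open 11 / extend 1 (Biopython's `PairwiseAligner`). Identity is
identical columns divided by alignment columns excluding terminal gap
runs, so a truncated or frameshift-split gene is not penalised for its
missing tail; coverage per side is the fraction of that sequence lying
inside the non-terminal columns. Arguments are internally aligned in a
canonical order so identity is exactly symmetric even when co-optimal
alignments with different column counts exist.

A hit is accepted when both coverages are ≥ 0.5 and the raw score exceeds
50. The score floor is deliberately above zero: global BLOSUM62 scores of
*unrelated* proteins fluctuate around slightly negative values and small
positive excursions (tens of raw units) occur regularly when many random
pairs are examined; 50 raw units — roughly a 10-residue exact match — is
far below any credible ortholog (a 60-codon gene at 45% identity scores
~100+) yet above that noise floor. Ties on score break toward the lowest
counterpart ordinal, making results deterministic.

Candidate search: aligning all ~n² pairs is wasteful, so pairs sharing at
least two amino-acid 5-mers are aligned first; any gene still without a
passing hit is then re-screened by protein edit distance (edlib, unit
costs) against all counterparts and its 10 best-ranked candidates are
aligned with the full scoring model. The edit-distance rescue is what
recovers homologs in the 40–60% identity range, which share too few exact
5-mers to seed reliably. Proteomes of ≤ 12 genes skip the filter entirely,
and the filtered path is validated against exhaustive scoring in the test
suite. Scores are symmetric, so each pair is aligned once and reused for
both directions.

Classification: BBH iff each gene is the other's best hit; unidirectional
iff a best hit exists one way only; unique iff no hit passes. These three
sets partition each proteome.

## Synteny and difference regions

BBH anchors sorted by genome-*a* ordinal form the profile. Inversions are
maximal runs (≥3 anchors) of strictly decreasing counterpart ordinals;
translocations are runs whose counterpart step deviates from the own-side
step by more than 25 genes and later rejoin the diagonal (a jump that
never returns is a terminal offset, not a translocation).

Region calling classifies each gene of genome *a* as: a high-identity
in-order BBH anchor; a *soft* BBH (identity < 70%, or counterpart ordinal
falling outside the bracket of the two nearest anchors on each side ± 10);
or strictly non-BBH (unidirectional/unique). RNA genes are transparent. A
candidate region is a maximal run of soft/non-BBH genes; runs separated by
at most 3 consecutive high-identity anchors are merged, but only when both
flanking segments are substantive (≥ 2 genes, or at least one strictly
non-BBH gene) — an isolated low-identity BBH sitting in conserved backbone
never recruits its neighbourhood. A candidate is reported when it contains
a run of ≥ 5 consecutive strictly non-BBH genes and ≥ 20 genes overall
(all three thresholds are `RegionParams` fields). The counterpart interval
on genome *b* is delimited by the innermost flanking anchors, and both
intervals get unique/unidirectional/BBH accounting. The caller formalizes
what is usually read off a synteny plot by eye; the defaults were chosen to
report multi-gene islands while suppressing singleton indels.

## Modal codon usage

Only amino-acid families with ≥ 2 synonymous codons are informative; Met,
Trp and stops are excluded, and the initiator and terminator codons of each
gene are skipped by default (they are not synonymous choices). Codons
containing ambiguity codes are skipped without discarding the gene.

The mode of a gene set is estimated by iterative trimming: initialize
frequencies from the pooled counts of all genes; score each gene with a
G-statistic summed over families, G = 2 Σ O·log(O/E) with E from the
current frequencies and df = Σ (family size − 1) over families the gene
observes, giving one χ² p-value per gene; retain genes with p > 0.1
(`conformity_p`); re-pool; iterate until the retained set is stable
(`max_iter` 50; a cycling or exhausted run returns the last iterate
flagged non-converged — not observed in practice at these scales). A gene
hitting a zero-frequency codon gets G = ∞, hence p = 0. If a trim would
empty the set, the best-fitting gene(s) are kept. At the fixed point the
reported frequencies are exactly the pooled frequencies of the conforming
genes (a property the tests assert). Note the fixed point retains roughly
75–80% of genes even when all genes share one bias — each iteration trims
the p ≤ 0.1 tail against re-sharpened frequencies — so conforming-set size
should be read comparatively, not as an absolute fraction.

Distance between modes: for each family, half the L1 distance between the
two frequency vectors, averaged with weights equal to the mean amino-acid
composition (over informative families) of the two conforming gene sets.
This is symmetric, bounded in [0, 1], zero iff the family frequencies
coincide, and scale-free. The formula is this package's own definition —
fixed here because "distance between modes" is reported in the literature
without one — so cross-software numeric comparisons should allow a
generous tolerance even when the qualitative conclusion (observed ≫ null)
is robust.

Shuffled-pool null: the two gene sets are pooled; each round draws, without
replacement, two disjoint random sets of the original sizes and computes
their inter-mode distance; the null mean and sd are taken over 10 rounds
(`n_rounds`, configurable upward — the sd estimate from 10 rounds is
noisy). Round *r* uses the RNG substream `[seed, r]`, so runs are
bit-reproducible from one seed and rounds are independent of each other.
With the 2·sd rule the measured per-run false-positive rate is ~7% (the
distance is right-skewed and the sd is noisy); at the 3·sd level used to
flag transfers it is ~1%.

The report generator produces one row per comparison — each region vs the
chromosome excluding all regions, each region pair, and whole chromosome vs
whole chromosome — with observed distance, null mean ± sd, round count and
seed; a region without usable CDS yields a flagged row, not a failure.

## ANI

Goris-style parameters: consecutive 1,020-bp fragments, retained at ≥ 30%
identity, both directions averaged (weighted by retained fragment counts);
the trailing partial fragment is discarded. Fragment placement: a shared
15-mer locates candidate windows (up to 4 positions per 15-mer are
indexed and up to 3 distinct windows tried — repeated AT-rich 15-mers
would otherwise misplace fragments); the fragment is then aligned inside
the window (± 200 bp margin) with edlib's infix mode, on both strands, and
identity is matched columns over alignment columns. Infix alignment
consumes the entire fragment, so the conventional 70%-coverage retention
criterion reduces to "a seeded alignment exists and passes the identity
floor". Fragments with no seed are aligned against the whole subject only
when the subject is ≤ 200 kb; beyond that they are dropped (at that size a
1,020-bp fragment without a single shared 15-mer has no credible match).
Unit-cost alignment slightly understates identity relative to
substitution-matrix tools in indel-rich regions; for the near-identical
genomes ANI is designed for, the effect is far below the spread between
published ANI implementations.

## Synthetic genome pairs

The generator emulates a clonal strain pair. Per backbone gene: length
~Normal(250, 80) codons (min 60); residues i.i.d. from a fixed
bacterial-like amino-acid background; codons sampled per residue from the
backbone bias (each family's AT-richest codon carries weight 0.7, the rest
uniform — an AT-rich genome). The second copy draws a target amino-acid
identity from a band mixture — default (98,100]:0.86, (96,98]:0.08,
(70,96]:0.051, (55,70]:0.009, echoing the heavily right-skewed identity
distribution of real clonal pairs — and is mutated by substitutions only
(the initiator is never touched; the substitution kernel draws the
replacement from the background excluding the original residue);
synonymous codons of conserved residues are resampled with probability
0.05 so nucleotide divergence accrues silently. Ortholog pairs share
strand and stop codon, as real strains conserve them.

Planted regions insert blocks of donor-biased genes (donor bias = backbone
with mass `donor_tv` moved, per family, from the preferred codon to the
least-preferred or runner-up codon — two distinguishable donors). A
fraction of block genes is unique to genome A, arranged in operon-like
clusters (as horizontally acquired genes are); optional extra genes are
unique to genome B; the remainder are homolog pairs at 45–62% identity.
The default study conditions are a 300-gene backbone with two regions of
53 and 48 genes (unique fractions 0.55 and 0.67, B-side extras 25 and 56,
donor TV 0.4), mirroring the region structure of a real predatory-marine-
bacterium strain pair at one-tenth scale.

Intergenic spacers are i.i.d. bases whose GC is solved, per genome, from
the realized coding GC so the whole replicon hits the GC target (default
36.7%); spacers are generated independently per genome. All randomness
flows from the single config seed; identical seeds give byte-identical
FASTA/GFF3 output.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: indels and pseudogenization (identity is
substitution-only, so real truncated orthologs stress the coverage rules
in ways the simulator does not), rearrangements beyond toy inversions,
shared intergenic sequence (synthetic ANI is therefore depressed:
independent spacers and the disproportionately large planted regions put
desk-scale pair ANI near 83–92%, where a real clonal pair sits near 98%),
amelioration of transferred genes toward host usage, and annotation error.

## Numerical and degenerate-input conventions

Ties in best-hit scoring break to the lowest ordinal. Empty inputs raise
`ValueError` with the offending quantity named; a difference-region set may
legitimately be empty. Mode frequencies of an unobserved family are all
zero and drop out of the weighted distance. `shuffled_null` requires both
sets non-empty; identical sets give observed distance exactly 0. The
pipeline hashes the effective configuration (excluding the output
directory) into the report for provenance, and re-running with the same
inputs and seed reproduces `report.json` byte-for-byte.

## Scale choices

The default test suite runs entirely on synthetic data: 300-gene backbones
for pipeline-level checks, 200–300-gene sets for codon-usage calibration,
100 ≤10-gene proteome pairs for the best-hit oracle, and 10–50-kb
sequences for ANI constructions. These sizes keep the full suite to a few
minutes while leaving every statistical check well-powered; the same code
paths handle 3.4-Mb chromosomes (the k-mer pre-filter and seeded fragment
alignment exist for exactly that), which the optional real-data suite
exercises when the two deposited chromosomes are supplied.
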