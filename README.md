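# strainpair

Pairwise comparative genomics for closely related bacterial strains:
reciprocal-best-hit orthology, synteny and gene-content difference regions,
fragment-based average nucleotide identity (ANI), and a modal codon usage
test with a shuffled-pool null for detecting horizontally transferred
regions.

The package is aimed at the common situation where two complete, annotated
chromosomes of the same (or sister) species are in hand — for example two
isolates of a predatory marine bacterium sampled years apart — and the
questions are: how conserved are gene content, gene order and sequence;
where exactly does the correspondence break down; and do those breakdown
regions carry the codon-usage signature of foreign DNA?

## What it computes

**Orthologs.** Every CDS of genome *A* is globally aligned (affine gaps,
BLOSUM62, open 11 / extend 1) against candidate counterparts in genome *B*;
a pair in which each gene is the other's highest-scoring passing hit is a
*bidirectional best hit* (BBH), the standard ortholog proxy. Percent
amino-acid identity is computed over alignment columns excluding terminal
gap runs. Genes whose best hit does not reciprocate are *unidirectional*;
genes with no passing hit are *unique*.

**Difference regions.** BBH anchors ordered along both chromosomes give the
synteny profile. Maximal runs of genes that are not high-identity, in-order
anchors — runs of unique and unidirectional genes, through which
low-identity (<70%) or locally unordered BBHs do not restore correspondence
— are called as *regions of gene-content difference*, with per-genome gene
accounting and flanking anchor genes.

**Modal codon usage.** For a gene set *G* with per-gene codon counts, the
*mode* is the synonymous-codon frequency set consistent with the largest
number of genes: starting from pooled frequencies, each gene's fit is scored
with a multinomial G-test summed over codon families (one χ² p-value per
gene), genes with p ≤ 0.1 are dropped, frequencies are re-pooled, and the
procedure iterates to a fixed point. The distance between two modes m₁, m₂
is the amino-acid-frequency-weighted total variation

    d(m1, m2) = Σ_aa w_aa · ½ Σ_{c∈aa} | f1(c|aa) − f2(c|aa) |,

a pseudometric on [0, 1]. Significance comes from a *shuffled-pool null*:
the two gene sets are pooled and repeatedly re-split at random into sets of
the original sizes (10 rounds by default); the observed distance is compared
with the null mean ± sd. A region whose distance to the rest of the
chromosome far exceeds the null is a candidate horizontal-transfer import.

**ANI.** Each genome is cut into 1,020-bp fragments; each fragment is
aligned to its best match in the other genome (both strands, k-mer seeded,
retained at ≥30% identity) and ANI is the mean identity of retained
fragments over both directions — ~95–96% is the conventional species
boundary.

**Synthetic pairs.** `simulate_pair` generates annotated genome pairs with
a conserved ortholog backbone (right-skewed identity mixture, most pairs
≥96–98%), planted donor-biased regions with unique genes and diverged
homologs, and a truth record, so every stage is testable without downloads.

## Worked example

```python
import strainpair as sp
from strainpair.codon import compute_mode, mode_distance, shuffled_null

backbone = sp.default_backbone_bias()
island_bias = sp.shifted_bias(backbone, tv=0.4)
chromosome = sp.sample_codon_counts(backbone, 250, rng=1, prefix="chr_")
island = sp.sample_codon_counts(island_bias, 50, rng=2, prefix="isl_")

res = shuffled_null(island, chromosome, n_rounds=10, seed=0)
print(f"{res.observed_distance:.4f} {res.null_mean:.4f} {res.null_sd:.4f}")
```

prints `0.3975 0.0269 0.0030`: the island's codon-usage mode is 0.3975 away
from the chromosome's, while random re-splits of the pooled genes produce
distances of only 0.027 ± 0.003 — the island's usage cannot be a random
sample of the chromosome's gene pool (z ≈ 122), the signature expected of
horizontally acquired DNA.

The full pipeline on a simulated pair (`examples/01_simulate_and_compare.py`):

```text
BBH ortholog pairs: 340
difference regions called: 2 (planted: 2)
  region A: genes (75, 127), 29 unique
  region B: genes (203, 250), 32 unique
ANI: 83.4%
  Region A  Chromosome (excluding regions)  0.3980  0.0243  0.0035
  ...
```

Both planted regions are recovered at their exact gene boundaries with
exact unique-gene counts, and each shows a region-vs-chromosome codon
distance two orders of magnitude above its null. (The synthetic ANI of
~83% reflects desk scale: the planted foreign regions make up a quarter of
the small simulated chromosome, against a few percent of a real one.)

The same pipeline runs from the shell:

```sh
strainpair simulate --out sim --seed 1
strainpair compare --genome-a sim/simA.fasta --genome-b sim/simB.fasta \
    --format fasta+gff3 --gff3-a sim/simA.gff3 --gff3-b sim/simB.gff3 --out results
strainpair ani --genome-a A.gbk --genome-b B.gbk        # GenBank input
```

`compare` writes `report.json`, `table2.tsv`, `identity_distribution.tsv`,
`regions.bed`, `regions.tsv`, `codon_distances.tsv`, `ani.json` and
`synteny_points.tsv` (plot-ready anchor coordinates).

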