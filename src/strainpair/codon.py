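"""Modal codon usage and the shuffled-pool test for horizontal gene transfer.

Modal codon usage is the set of synonymous-codon frequencies consistent with
the largest number of genes in a collection — more robust than average usage
when the collection mixes gene classes (e.g. native backbone plus a
horizontally acquired island). It is estimated by an iterative trimming
procedure: start from the pooled frequencies of all genes, score each gene's
fit to the current frequencies with a multinomial goodness-of-fit G-test
(summed over synonymous families, one chi-square p-value per gene), drop
genes with combined p <= ``conformity_p``, re-pool, and iterate to a fixed
point.

The distance between two modes is an amino-acid-frequency-weighted total
variation: for each family, half the L1 difference of the two frequency
vectors, averaged with weights given by the mean amino-acid composition of
the two conforming gene sets. It is a pseudometric in [0, 1].

Whether an observed inter-mode distance is larger than chance is judged
against a shuffled-pool null: both gene sets are pooled and repeatedly
re-split at random into sets of the original sizes; the mean and standard
deviation of the resulting inter-mode distances estimate the distance
expected when the two sets share one usage mode.

Only families with two or more synonymous codons are informative; Met, Trp
and the stop codons are excluded, and by default the initiator and
terminator codon of each gene are not counted (they are not synonymous
choices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome import Gene, Genome
from .synteny import DifferenceRegion

#: the 64 codons in lexicographic order; all count vectors use this indexing
CODONS: tuple[str, ...] = tuple(
    "".join(t) for t in itertools.product("ACGT", repeat=3)
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_TABLE = unambiguous_dna_by_id[11]


def _build_families() -> dict[str, tuple[int, ...]]:
    by_aa: dict[str, list[int]] = {}
    for codon, aa in _TABLE.forward_table.items():
        by_aa.setdefault(aa, []).append(CODON_INDEX[codon])
    # only multi-codon families carry synonymous-choice information
    return {aa: tuple(sorted(v)) for aa, v in sorted(by_aa.items()) if len(v) >= 2}


#: synonymous families (amino acid -> codon indices), stops/Met/Trp excluded
FAMILIES: dict[str, tuple[int, ...]] = _build_families()
_FAMILY_NAMES = tuple(FAMILIES)
_FAMILY_OF = np.full(64, -1, dtype=int)
for _fi, (_aa, _idx) in enumerate(FAMILIES.items()):
    for _c in _idx:
        _FAMILY_OF[_c] = _fi
_N_FAM = len(FAMILIES)
_FAM_SIZE = np.array([len(v) for v in FAMILIES.values()])
# 64 x n_families indicator
_FAM_MATRIX = np.zeros((64, _N_FAM))
for _c in range(64):
    if _FAMILY_OF[_c] >= 0:
        _FAM_MATRIX[_c, _FAMILY_OF[_c]] = 1.0


@dataclass
class CodonCounts:
    gene_id: str
    counts: np.ndarray  # length-64 nonnegative ints, CODONS order
    n_codons: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("counts must be a length-64 vector")
        if int(self.counts.sum()) != self.n_codons:
            raise ValueError("n_codons must equal sum(counts)")


@dataclass
class CodonUsageMode:
    """Fixed point of the iterative modal-usage estimate."""

    freqs: dict[str, np.ndarray]  # per family, sums to 1 (or all-zero if unobserved)
    family_totals: dict[str, int]  # pooled codon tally per family over conforming genes
    conforming_genes: frozenset[str]
    n_iterations: int
    converged: bool

    @property
    def flat(self) -> np.ndarray:
        """Length-64 vector of within-family frequencies (0 outside families)."""
        v = np.zeros(64)
        for aa, idx in FAMILIES.items():
            v[list(idx)] = self.freqs[aa]
        return v


@dataclass
class NullDistanceResult:
    observed_distance: float
    null_mean: float
    null_sd: float
    n_rounds: int
    per_round_distances: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def z_score(self) -> float:
        if self.null_sd == 0:
            return float("inf") if self.observed_distance > self.null_mean else 0.0
        return (self.observed_distance - self.null_mean) / self.null_sd


# ---------------------------------------------------------------------------
# counting

def count_codons(gene: Gene, exclude_termini: bool = True) -> CodonCounts:
    """Tally the codons of an in-frame CDS.

    With ``exclude_termini`` the initiator and terminator codons are
    omitted. Codons containing ambiguity codes are skipped.
    """
    if not gene.is_cds:
        raise ValueError(f"{gene.locus_tag}: codon counting requires a CDS")
    if gene.partial or len(gene.nt_seq) % 3 != 0:
        raise ValueError(f"{gene.locus_tag}: partial CDS cannot be codon-counted")
    counts = np.zeros(64, dtype=np.int64)
    codons = [gene.nt_seq[i : i + 3] for i in range(0, len(gene.nt_seq), 3)]
    if exclude_termini:
        codons = codons[1:-1]
    for c in codons:
        i = CODON_INDEX.get(c)
        if i is not None:
            counts[i] += 1
    return CodonCounts(gene_id=gene.locus_tag, counts=counts, n_codons=int(counts.sum()))


def genome_codon_counts(
    genome: Genome, ordinals: set[int] | None = None, exclude_termini: bool = True
) -> list[CodonCounts]:
    """Codon counts for (a subset of) the usable CDS genes of a genome."""
    out = []
    for g in genome.cds:
        if ordinals is not None and g.ordinal not in ordinals:
            continue
        out.append(count_codons(g, exclude_termini))
    return out


def _matrix(genes: list[CodonCounts]) -> np.ndarray:
    return np.stack([g.counts for g in genes]).astype(float)


# ---------------------------------------------------------------------------
# modal usage

def _pooled_freqs(C: np.ndarray) -> np.ndarray:
    """Within-family frequencies (length 64) from a pooled count matrix."""
    pooled = C.sum(axis=0)
    fam_tot = pooled @ _FAM_MATRIX  # per family
    denom = fam_tot[_FAMILY_OF]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where((_FAMILY_OF >= 0) & (denom > 0), pooled / np.where(denom > 0, denom, 1), 0.0)
    return f


def _gene_pvalues(C: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-gene G-test p-value against within-family frequencies ``f``."""
    N = C @ _FAM_MATRIX  # (n_genes, n_fam) family totals per gene
    E = N.take(np.where(_FAMILY_OF >= 0, _FAMILY_OF, 0), axis=1) * f
    E = np.where(_FAMILY_OF >= 0, E, 0.0)
    Cf = np.where(_FAMILY_OF >= 0, C, 0.0)  # codons outside families carry no signal
    with np.errstate(invalid="ignore", divide="ignore"):
        G = 2.0 * (xlogy(Cf, Cf).sum(axis=1) - xlogy(Cf, E).sum(axis=1))
    df = ((N > 0) * (_FAM_SIZE - 1)).sum(axis=1)
    p = np.ones(len(C))
    pos = df > 0
    # a gene whose counts hit a zero-frequency codon has infinite G -> p = 0
    G = np.where(np.isfinite(G), G, np.inf)
    p[pos] = chi2.sf(G[pos], df[pos])
    return p


def compute_mode(
    genes: list[CodonCounts], conformity_p: float = 0.1, max_iter: int = 50
) -> CodonUsageMode:
    """Estimate the modal codon usage of a gene set.

    Iterates pooled-frequency estimation and G-test trimming until the
    conforming set is stable. Raises on empty input; a non-converged run
    (cycling or hitting ``max_iter``) returns the last iterate flagged.
    """
    if not genes:
        raise ValueError("compute_mode requires at least one gene")
    C = _matrix(genes)
    if (C @ _FAM_MATRIX).sum() == 0:
        raise ValueError("no codons in any informative family")
    mask = np.ones(len(genes), dtype=bool)
    seen: set[bytes] = set()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        f = _pooled_freqs(C[mask])
        p = _gene_pvalues(C, f)
        new_mask = p > conformity_p
        if not new_mask.any():
            # degenerate trim: keep the best-fitting gene(s) and stop
            new_mask = p == p.max()
        if (new_mask == mask).all():
            converged = True
            mask = new_mask
            break
        key = new_mask.tobytes()
        if key in seen:  # cycle; accept current iterate
            mask = new_mask
            break
        seen.add(key)
        mask = new_mask
    f = _pooled_freqs(C[mask])
    pooled = C[mask].sum(axis=0)
    freqs = {aa: f[list(idx)] for aa, idx in FAMILIES.items()}
    totals = {aa: int(pooled[list(idx)].sum()) for aa, idx in FAMILIES.items()}
    return CodonUsageMode(
        freqs=freqs,
        family_totals=totals,
        conforming_genes=frozenset(genes[i].gene_id for i in np.where(mask)[0]),
        n_iterations=n_iter,
        converged=converged,
    )


def mode_distance(m1: CodonUsageMode, m2: CodonUsageMode) -> float:
    """Amino-acid-frequency-weighted total variation between two usage modes.

    Weights are the mean amino-acid composition of the two conforming gene
    sets, renormalized over the multi-codon families. Symmetric, in [0, 1],
    zero iff the family frequencies coincide.
    """
    if set(m1.freqs) != set(m2.freqs):
        raise ValueError("modes are defined over different codon families")
    t1 = np.array([m1.family_totals[aa] for aa in _FAMILY_NAMES], dtype=float)
    t2 = np.array([m2.family_totals[aa] for aa in _FAMILY_NAMES], dtype=float)
    w = 0.0
    if t1.sum() > 0:
        w = t1 / t1.sum()
    if t2.sum() > 0:
        w = (w + t2 / t2.sum()) / (2.0 if t1.sum() > 0 else 1.0)
    w = np.asarray(w, dtype=float)
    if w.sum() == 0:
        raise ValueError("both modes have empty family totals")
    w = w / w.sum()
    d = 0.0
    for wi, aa in zip(w, _FAMILY_NAMES):
        tv = 0.5 * float(np.abs(m1.freqs[aa] - m2.freqs[aa]).sum())
        d += wi * tv
    return float(d)


# ---------------------------------------------------------------------------
# shuffled-pool null

def shuffled_null(
    set1: list[CodonCounts],
    set2: list[CodonCounts],
    n_rounds: int = 10,
    seed: int = 0,
    conformity_p: float = 0.1,
    max_iter: int = 50,
) -> NullDistanceResult:
    """Observed inter-mode distance versus the shuffled-pool null.

    Each round pools the genes of both sets and draws, without replacement,
    two disjoint random sets of the original sizes; the null mean and sd are
    taken over the per-round inter-mode distances. Reproducible from
    ``seed`` via counter-based per-round substreams.
    """
    if not set1 or not set2:
        raise ValueError("both gene sets must be non-empty")
    m1 = compute_mode(set1, conformity_p, max_iter)
    m2 = compute_mode(set2, conformity_p, max_iter)
    observed = mode_distance(m1, m2)
    pool = list(set1) + list(set2)
    n1 = len(set1)
    dists = []
    for r in range(n_rounds):
        rng = np.random.default_rng([seed, r])
        perm = rng.permutation(len(pool))
        s1 = [pool[i] for i in perm[:n1]]
        s2 = [pool[i] for i in perm[n1:]]
        dists.append(
            mode_distance(
                compute_mode(s1, conformity_p, max_iter),
                compute_mode(s2, conformity_p, max_iter),
            )
        )
    arr = np.array(dists)
    return NullDistanceResult(
        observed_distance=observed,
        null_mean=float(arr.mean()),
        null_sd=float(arr.std(ddof=1)) if n_rounds > 1 else 0.0,
        n_rounds=n_rounds,
        per_round_distances=[float(x) for x in dists],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# report over difference regions

def _region_ordinals(region: DifferenceRegion, side: str) -> set[int]:
    lo, hi = region.a_interval if side == "a" else region.b_interval
    return set(range(lo, hi + 1))


def hgt_report(
    a: Genome,
    b: Genome,
    regions: list[DifferenceRegion],
    n_rounds: int = 10,
    seed: int = 0,
    conformity_p: float = 0.1,
    exclude_termini: bool = True,
) -> pd.DataFrame:
    """Codon-distance table: regions vs. chromosome remainder, region pairs,
    and whole chromosome vs. whole chromosome.

    One row per comparison with the observed inter-mode distance and the
    shuffled-pool null mean +/- sd. Regions with no usable CDS are flagged
    rather than fatal.
    """
    rows = []

    def _counts(genome: Genome, ordinals: set[int] | None) -> list[CodonCounts]:
        return genome_codon_counts(genome, ordinals, exclude_termini)

    def _row(comparison, s1_name, s2_name, set1, set2, sub_seed):
        if not set1 or not set2:
            rows.append(
                {
                    "comparison": comparison, "sequence_1": s1_name, "sequence_2": s2_name,
                    "observed_distance": float("nan"), "null_mean": float("nan"),
                    "null_sd": float("nan"), "n_rounds": n_rounds, "seed": sub_seed,
                    "flag": "no CDS in one of the sets",
                }
            )
            return
        res = shuffled_null(set1, set2, n_rounds, sub_seed, conformity_p)
        rows.append(
            {
                "comparison": comparison, "sequence_1": s1_name, "sequence_2": s2_name,
                "observed_distance": res.observed_distance, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "n_rounds": n_rounds, "seed": sub_seed, "flag": "",
            }
        )

    _row(
        "Whole chromosomes", a.genome_id, b.genome_id,
        _counts(a, None), _counts(b, None), seed,
    )
    sub = 1
    for genome, side in ((a, "a"), (b, "b")):
        all_ords = {g.ordinal for g in genome.cds}
        region_ords = {r.region_id: _region_ordinals(r, side) & all_ords for r in regions}
        rest = all_ords - set().union(*region_ords.values()) if region_ords else all_ords
        rest_counts = _counts(genome, rest)
        for r in regions:
            _row(
                f"{genome.genome_id} regions", f"Region {r.region_id}",
                "Chromosome (excluding regions)",
                _counts(genome, region_ords[r.region_id]), rest_counts, seed + sub,
            )
            sub += 1
        for r1, r2 in itertools.combinations(regions, 2):
            _row(
                f"{genome.genome_id} regions", f"Region {r1.region_id}", f"Region {r2.region_id}",
                _counts(genome, region_ords[r1.region_id]),
                _counts(genome, region_ords[r2.region_id]), seed + sub,
            )
            sub += 1
    return pd.DataFrame(rows)


def counts_tsv(genes: list[CodonCounts]) -> str:
    """Gene codon counts as TSV (gene_id + 64 codon columns)."""
    header = "gene_id\t" + "\t".join(CODONS)
    lines = [header]
    for g in genes:
        lines.append(g.gene_id + "\t" + "\t".join(str(int(x)) for x in g.counts))
    return "\n".join(lines) + "\n"


def counts_from_tsv(text: str) -> list[CodonCounts]:
    lines = [ln for ln in text.strip().splitlines() if ln]
    header = lines[0].split("\t")
    if header[1:] != list(CODONS):
        raise ValueError("codon column order does not match the canonical CODONS order")
    out = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        counts = np.array([int(x) for x in parts[1:]], dtype=np.int64)
        out.append(CodonCounts(parts[0], counts, int(counts.sum())))
    return out
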