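"""Reciprocal-best-hit orthology between two proteomes.

Each CDS is globally aligned (affine gaps, BLOSUM62) against candidate
counterparts in the other genome; the highest-scoring counterpart passing
score and coverage thresholds is its best hit. Genes whose best hits
reciprocate are bidirectional best hits (BBHs, the ortholog proxy); genes
whose best hit does not reciprocate are unidirectional; genes with no
passing hit are unique. Percent amino-acid identity is computed over
alignment columns excluding terminal gap runs, so a truncated gene is not
penalised for its missing tail.

A shared k-mer pre-filter restricts which pairs are aligned; it is validated
against exhaustive all-vs-all scoring on small inputs (and disabled
automatically for tiny proteomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import Gene, Genome

_AA = set("ACDEFGHIKLMNPQRSTVWYX*BZJUO")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and acceptance settings for best-hit search."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_coverage: float = 0.5  # per side, fraction of sequence inside non-terminal columns
    # unrelated proteins occasionally reach small positive global scores; 50
    # raw BLOSUM62 units (~ a 10-residue perfect match) is far below any
    # credible ortholog yet above that noise floor
    min_score: float = 50.0
    kmer_size: int = 5
    min_shared_kmers: int = 2
    rescue_top: int = 10  # edit-distance-ranked candidates aligned per unmatched gene
    prefilter: bool = True
    exhaustive_below: int = 12  # proteomes with <= this many CDS skip the pre-filter


@dataclass
class Hit:
    query_ordinal: int
    subject_ordinal: int
    score: float
    aa_identity: float
    query_coverage: float
    subject_coverage: float
    alignment_length: int


@dataclass
class OrthologMap:
    bbh_pairs: list[tuple[int, int, float]]
    unidirectional_a: list[Hit]
    unidirectional_b: list[Hit]
    unique_a: set[int]
    unique_b: set[int]
    a_id: str = ""
    b_id: str = ""

    @property
    def bbh_a(self) -> dict[int, tuple[int, float]]:
        return {a: (b, ident) for a, b, ident in self.bbh_pairs}

    @property
    def bbh_b(self) -> dict[int, tuple[int, float]]:
        return {b: (a, ident) for a, b, ident in self.bbh_pairs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bbh_pairs, columns=["a_ordinal", "b_ordinal", "aa_identity"])


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    return al


def align_pair(p: str, q: str, params: AlignmentParams | None = None) -> Hit:
    """Globally align two protein sequences and report identity and coverage.

    aa_identity = 100 * identical columns / alignment columns excluding the
    terminal gap runs; coverage per side is the fraction of that sequence's
    residues lying inside the non-terminal columns.
    """
    params = params or AlignmentParams()
    if not p or not q:
        raise ValueError("empty protein sequence")
    for name, s in (("p", p), ("q", q)):
        bad = set(s.upper()) - _AA
        if bad:
            raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)}")
    # canonical argument order makes identity exactly symmetric even when
    # co-optimal alignments with different column counts exist
    p_up, q_up = p.upper(), q.upper()
    swapped = p_up > q_up
    if swapped:
        p_up, q_up = q_up, p_up
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend)
    aln = aligner.align(p_up, q_up)[0]
    c = aln.counts()
    core_cols = c.identities + c.mismatches + c.internal_gaps
    identity = 100.0 * c.identities / core_cols if core_cols else 0.0
    # terminal insertions are query (q) residues outside the core; terminal
    # deletions are target (p) residues outside the core
    p_cov = (len(p_up) - c.left_deletions - c.right_deletions) / len(p_up)
    q_cov = (len(q_up) - c.left_insertions - c.right_insertions) / len(q_up)
    if swapped:
        p_cov, q_cov = q_cov, p_cov
    return Hit(
        query_ordinal=-1,
        subject_ordinal=-1,
        score=float(aln.score),
        aa_identity=identity,
        query_coverage=p_cov,
        subject_coverage=q_cov,
        alignment_length=core_cols,
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(
    prots_a: dict[int, str], prots_b: dict[int, str], k: int, min_shared: int
) -> set[tuple[int, int]]:
    """Pairs sharing at least ``min_shared`` amino-acid k-mers."""
    index: dict[str, list[int]] = {}
    for j, q in prots_b.items():
        for km in _kmers(q, k):
            index.setdefault(km, []).append(j)
    pairs: set[tuple[int, int]] = set()
    for i, p in prots_a.items():
        counts: dict[int, int] = {}
        for km in _kmers(p, k):
            for j in index.get(km, ()):
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            if c >= min_shared:
                pairs.add((i, j))
    return pairs


def _rescue_pairs(
    queries: dict[int, str], subjects: dict[int, str], top: int
) -> set[tuple[int, int]]:
    """Most promising counterparts per unmatched gene, ranked by protein
    edit distance (cheap unit-cost screen; the substitution-matrix alignment
    still decides acceptance)."""
    pairs: set[tuple[int, int]] = set()
    for i, p in queries.items():
        ranked = sorted(
            (
                (edlib.align(p, q, mode="NW")["editDistance"] / max(len(p), len(q)), j)
                for j, q in subjects.items()
            ),
        )
        pairs.update((i, j) for _, j in ranked[:top])
    return pairs


def _passes(hit: Hit, params: AlignmentParams) -> bool:
    return (
        hit.score > params.min_score
        and hit.query_coverage >= params.min_coverage
        and hit.subject_coverage >= params.min_coverage
    )


def best_hits(
    a: Genome, b: Genome, params: AlignmentParams | None = None
) -> tuple[dict[int, Hit], dict[int, Hit]]:
    """Best passing hit per CDS in each direction.

    Scores are symmetric (global alignment under a symmetric matrix), so each
    candidate pair is aligned once and reused for both directions. Ties on
    score break toward the lowest counterpart ordinal.
    """
    params = params or AlignmentParams()
    prots_a = {g.ordinal: g.aa_seq for g in a.cds if g.aa_seq}
    prots_b = {g.ordinal: g.aa_seq for g in b.cds if g.aa_seq}
    if not prots_a or not prots_b:
        raise ValueError("both genomes must contain at least one CDS")
    use_prefilter = params.prefilter and (
        len(prots_a) > params.exhaustive_below or len(prots_b) > params.exhaustive_below
    )
    if use_prefilter:
        pairs = _candidate_pairs(prots_a, prots_b, params.kmer_size, params.min_shared_kmers)
    else:
        pairs = {(i, j) for i in prots_a for j in prots_b}

    best_ab: dict[int, Hit] = {}
    best_ba: dict[int, Hit] = {}

    def _align_pairs(pair_set: set[tuple[int, int]]) -> None:
        for i, j in sorted(pair_set):
            hit = align_pair(prots_a[i], prots_b[j], params)
            fwd = Hit(i, j, hit.score, hit.aa_identity, hit.query_coverage,
                      hit.subject_coverage, hit.alignment_length)
            rev = Hit(j, i, hit.score, hit.aa_identity, hit.subject_coverage,
                      hit.query_coverage, hit.alignment_length)
            if _passes(fwd, params):
                cur = best_ab.get(i)
                if cur is None or (fwd.score, -fwd.subject_ordinal) > (cur.score, -cur.subject_ordinal):
                    best_ab[i] = fwd
            if _passes(rev, params):
                cur = best_ba.get(j)
                if cur is None or (rev.score, -rev.subject_ordinal) > (cur.score, -cur.subject_ordinal):
                    best_ba[j] = rev

    _align_pairs(pairs)
    if use_prefilter:
        # rescue: genes left without any passing hit are re-screened by edit
        # distance, so low-identity homologs missed by the k-mer filter are found
        miss_a = {i: prots_a[i] for i in set(prots_a) - set(best_ab)}
        miss_b = {j: prots_b[j] for j in set(prots_b) - set(best_ba)}
        rescue: set[tuple[int, int]] = set()
        if miss_a:
            rescue |= _rescue_pairs(miss_a, prots_b, params.rescue_top)
        if miss_b:
            rescue |= {(i, j) for j, i in _rescue_pairs(miss_b, prots_a, params.rescue_top)}
        _align_pairs(rescue - pairs)
    return best_ab, best_ba


def classify(
    hits_ab: dict[int, Hit],
    hits_ba: dict[int, Hit],
    a: Genome,
    b: Genome,
) -> OrthologMap:
    """Partition CDS into bidirectional best hits, unidirectional hits, unique."""
    bbh: list[tuple[int, int, float]] = []
    uni_a: list[Hit] = []
    uni_b: list[Hit] = []
    for i, hit in hits_ab.items():
        back = hits_ba.get(hit.subject_ordinal)
        if back is not None and back.subject_ordinal == i:
            bbh.append((i, hit.subject_ordinal, hit.aa_identity))
        else:
            uni_a.append(hit)
    bbh_b_set = {j for _, j, _ in bbh}
    for j, hit in hits_ba.items():
        if j not in bbh_b_set:
            uni_b.append(hit)
    cds_a = {g.ordinal for g in a.cds if g.aa_seq}
    cds_b = {g.ordinal for g in b.cds if g.aa_seq}
    unique_a = cds_a - {i for i, _, _ in bbh} - {h.query_ordinal for h in uni_a}
    unique_b = cds_b - bbh_b_set - {h.query_ordinal for h in uni_b}
    bbh.sort()
    return OrthologMap(
        bbh_pairs=bbh,
        unidirectional_a=sorted(uni_a, key=lambda h: h.query_ordinal),
        unidirectional_b=sorted(uni_b, key=lambda h: h.query_ordinal),
        unique_a=unique_a,
        unique_b=unique_b,
        a_id=a.genome_id,
        b_id=b.genome_id,
    )


def build_ortholog_map(a: Genome, b: Genome, params: AlignmentParams | None = None) -> OrthologMap:
    """Convenience wrapper: best hits in both directions, then classification."""
    hits_ab, hits_ba = best_hits(a, b, params)
    return classify(hits_ab, hits_ba, a, b)


def identity_distribution(
    omap: OrthologMap, thresholds: tuple[float, ...] = (96.0, 98.0), tail_below: float = 70.0
) -> pd.DataFrame:
    """Cumulative identity distribution of BBH pairs.

    One row per threshold t with the count and fraction of pairs at identity
    >= t, plus a final row counting the low-identity tail (< ``tail_below``).
    """
    if not omap.bbh_pairs:
        raise ValueError("ortholog map has no BBH pairs")
    idents = np.array([ident for _, _, ident in omap.bbh_pairs])
    n = len(idents)
    rows = []
    for t in sorted(thresholds, reverse=True):
        c = int((idents >= t).sum())
        rows.append({"threshold": f">={t:g}", "count": c, "fraction": c / n})
    c_tail = int((idents < tail_below).sum())
    rows.append({"threshold": f"<{tail_below:g}", "count": c_tail, "fraction": c_tail / n})
    return pd.DataFrame(rows)


def hits_table(hits: dict[int, Hit]) -> pd.DataFrame:
    """Blast-tabular-like frame of best hits."""
    return pd.DataFrame(
        [
            {
                "query": h.query_ordinal,
                "subject": h.subject_ordinal,
                "pident": round(h.aa_identity, 2),
                "length": h.alignment_length,
                "score": h.score,
                "qcov": round(h.query_coverage, 3),
                "scov": round(h.subject_coverage, 3),
            }
            for h in sorted(hits.values(), key=lambda h: h.query_ordinal)
        ]
    )
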