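"""Independent brute-force oracle for best-hit search, used by acceptance tests.

The oracle re-scores every query/subject pair with ``align_pair`` and applies
the acceptance thresholds and the lowest-ordinal tie-break directly, without
any of the candidate pre-filtering or score-reuse machinery of ``best_hits``.
"""

import numpy as np

import strainpair as sp
from strainpair.orthology import align_pair

AA = "ACDEFGHIKLMNPQRSTVWY"


def _toy_genome(gid, proteins):
    genes = []
    pos = 0
    for i, p in enumerate(proteins):
        genes.append(
            sp.Gene(
                locus_tag=f"{gid}_{i}", ordinal=i, start=pos, end=pos + 3 * len(p) + 3,
                strand="+", feature_kind=sp.FeatureKind.CDS, product="x",
                nt_seq="A" * (3 * len(p) + 3), aa_seq=p,
            )
        )
        pos += 3 * len(p) + 10
    return sp.Genome(gid, "A" * (pos + 10), genes)


def random_toy_pair(seed):
    """Two toy proteomes (<=10 genes each) with duplicates, truncations and
    unrelated genes mixed in."""
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(2, 11))
    n_b = int(rng.integers(2, 11))

    def protein(n):
        return "M" + "".join(rng.choice(list(AA), n - 1))

    def mutate(p, frac):
        s = list(p)
        n_sub = max(1, int(frac * len(s)))
        for i in rng.choice(np.arange(1, len(s)), size=min(n_sub, len(s) - 1), replace=False):
            s[i] = rng.choice([a for a in AA if a != s[i]])
        return "".join(s)

    ancestors = [protein(int(rng.integers(20, 61))) for _ in range(max(n_a, n_b))]
    prots_a, prots_b = [], []
    for i in range(n_a):
        p = ancestors[i % len(ancestors)]
        roll = rng.random()
        if roll < 0.2:
            p = protein(int(rng.integers(20, 61)))  # unrelated
        elif roll < 0.4:
            p = mutate(p, rng.uniform(0.05, 0.4))
        elif roll < 0.5:
            p = p[: max(10, len(p) // 2)]  # truncated
        prots_a.append(p)
    for i in range(n_b):
        p = ancestors[i % len(ancestors)]
        roll = rng.random()
        if roll < 0.2:
            p = protein(int(rng.integers(20, 61)))
        elif roll < 0.5:
            p = mutate(p, rng.uniform(0.05, 0.4))
        prots_b.append(p)
    return _toy_genome("a", prots_a), _toy_genome("b", prots_b)


def exhaustive_best_hits(a, b, params):
    """All-vs-all rescoring oracle; returns {query: (subject, score)} per direction."""

    def passes(hit):
        return (
            hit.score > params.min_score
            and hit.query_coverage >= params.min_coverage
            and hit.subject_coverage >= params.min_coverage
        )

    prots_a = {g.ordinal: g.aa_seq for g in a.cds if g.aa_seq}
    prots_b = {g.ordinal: g.aa_seq for g in b.cds if g.aa_seq}
    best_ab, best_ba = {}, {}
    for i, p in prots_a.items():
        scored = []
        for j, q in sorted(prots_b.items()):
            hit = align_pair(p, q, params)
            if passes(hit):
                scored.append((hit.score, -j))
        if scored:
            s, nj = max(scored)
            best_ab[i] = (-nj, s)
    for j, q in prots_b.items():
        scored = []
        for i, p in sorted(prots_a.items()):
            hit = align_pair(q, p, params)
            if passes(hit):
                scored.append((hit.score, -i))
        if scored:
            s, ni = max(scored)
            best_ba[j] = (-ni, s)
    return best_ab, best_ba
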