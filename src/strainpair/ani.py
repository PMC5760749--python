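"""Fragment-based average nucleotide identity (ANI).

The query genome is cut into consecutive fixed-size fragments (1,020 bp by
convention); each fragment is aligned to its best local match in the
subject genome and retained when the match reaches the identity and
coverage thresholds (30% identity over 70% of the fragment, the
JSpecies-style convention). ANI is the mean identity of retained
fragments; both directions are computed and averaged.

Fragment placement uses a shared 15-mer seed to locate the candidate
window, then an infix (semi-global) alignment of the whole fragment inside
that window via edlib; the infix mode consumes the entire fragment, so the
coverage requirement reduces to the existence of a seeded alignment passing
the identity threshold. For subjects without a seed hit the fragment is
aligned against the whole subject when the subject is small, else dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .genome import Genome

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ANIParams:
    fragment_bp: int = 1020
    min_identity: float = 0.3
    min_coverage: float = 0.7
    seed_k: int = 15
    window_margin: int = 200
    max_unseeded_subject: int = 200_000  # full-subject fallback limit


@dataclass
class ANIResult:
    ani_percent: float
    n_fragments_total: int
    n_fragments_retained: int
    retained_fraction: float
    fragment_size: int
    direction: str  # a_vs_b | b_vs_a | mean

    def to_dict(self) -> dict:
        return {
            "ani_percent": round(self.ani_percent, 2),
            "n_fragments_total": self.n_fragments_total,
            "n_fragments_retained": self.n_fragments_retained,
            "retained_fraction": round(self.retained_fraction, 4),
            "fragment_size": self.fragment_size,
            "direction": self.direction,
        }


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """(identity fraction, alignment columns) from an extended cigar."""
    matches = cols = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        cols += n
        if op == "=":
            matches += n
    return (matches / cols if cols else 0.0), cols


def _seed_index(subject: str, k: int, max_per_kmer: int = 4) -> dict[str, list[int]]:
    """Occurrence positions of each k-mer of the subject (capped per k-mer)."""
    idx: dict[str, list[int]] = {}
    for i in range(0, len(subject) - k + 1):
        positions = idx.setdefault(subject[i : i + k], [])
        if len(positions) < max_per_kmer:
            positions.append(i)
    return idx


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _oriented_identity(
    frag: str, subject: str, index: dict[str, list[int]], p: ANIParams
) -> float | None:
    """Best identity over candidate seeded windows (repeated k-mers can seed
    several plausible placements; all are tried and the best kept)."""
    k = p.seed_k
    starts: list[int] = []
    for off in range(0, len(frag) - k + 1, k):
        for pos in index.get(frag[off : off + k], ()):
            start = pos - off
            if all(abs(start - s) > p.window_margin for s in starts):
                starts.append(start)
        if len(starts) >= 3:
            break
    windows = [
        subject[max(0, s - p.window_margin) : min(len(subject), s + len(frag) + p.window_margin)]
        for s in starts
    ]
    if not windows:
        if len(subject) > p.max_unseeded_subject:
            return None
        windows = [subject]
    best = None
    for window in windows:
        res = edlib.align(frag, window, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        ident, _ = _cigar_identity(res["cigar"])
        if best is None or ident > best:
            best = ident
    return best


def _fragment_identity(frag: str, subject: str, index: dict[str, int], p: ANIParams) -> float | None:
    """Best local-match identity of a fragment in the subject, searching
    both strands, or None when no alignment is found."""
    fwd = _oriented_identity(frag, subject, index, p)
    if fwd is not None and fwd >= 0.9:  # unambiguous forward match; skip the rc pass
        return fwd
    rev = _oriented_identity(_revcomp(frag), subject, index, p)
    if fwd is None:
        return rev
    if rev is None:
        return fwd
    return max(fwd, rev)


def _one_direction(query: Genome, subject: Genome, p: ANIParams, direction: str) -> ANIResult:
    q, s = query.sequence, subject.sequence
    if len(q) < p.fragment_bp or len(s) < p.fragment_bp:
        raise ValueError(f"sequences must be at least fragment_bp={p.fragment_bp} long")
    index = _seed_index(s, p.seed_k)
    n_total = len(q) // p.fragment_bp  # trailing partial fragment discarded
    idents = []
    for i in range(n_total):
        frag = q[i * p.fragment_bp : (i + 1) * p.fragment_bp]
        ident = _fragment_identity(frag, s, index, p)
        if ident is not None and ident >= p.min_identity:
            idents.append(ident)
    ani = 100.0 * sum(idents) / len(idents) if idents else 0.0
    return ANIResult(
        ani_percent=ani,
        n_fragments_total=n_total,
        n_fragments_retained=len(idents),
        retained_fraction=len(idents) / n_total if n_total else 0.0,
        fragment_size=p.fragment_bp,
        direction=direction,
    )


def compute_ani(a: Genome, b: Genome, params: ANIParams | None = None) -> ANIResult:
    """Bidirectional fragment ANI; the reported value is the mean of both
    directions (weighted by retained fragment counts)."""
    p = params or ANIParams()
    fwd = _one_direction(a, b, p, "a_vs_b")
    rev = _one_direction(b, a, p, "b_vs_a")
    n_ret = fwd.n_fragments_retained + rev.n_fragments_retained
    if n_ret:
        ani = (
            fwd.ani_percent * fwd.n_fragments_retained
            + rev.ani_percent * rev.n_fragments_retained
        ) / n_ret
    else:
        ani = 0.0
    return ANIResult(
        ani_percent=ani,
        n_fragments_total=fwd.n_fragments_total + rev.n_fragments_total,
        n_fragments_retained=n_ret,
        retained_fraction=(
            n_ret / (fwd.n_fragments_total + rev.n_fragments_total)
            if fwd.n_fragments_total + rev.n_fragments_total
            else 0.0
        ),
        fragment_size=p.fragment_bp,
        direction="mean",
    )


def compute_ani_directional(a: Genome, b: Genome, params: ANIParams | None = None) -> dict[str, ANIResult]:
    p = params or ANIParams()
    fwd = _one_direction(a, b, p, "a_vs_b")
    rev = _one_direction(b, a, p, "b_vs_a")
    return {"a_vs_b": fwd, "b_vs_a": rev}
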