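"""Synteny profile and gene-content difference regions.

BBH anchors ordered along genome *a* form the synteny profile; runs where
the counterpart ordinals decrease are flagged as inversions, and anchors
displaced far off the local diagonal as translocated. Contiguous stretches
where orthologous correspondence breaks down — runs of unique and
unidirectional genes, through which low-identity or out-of-order BBHs do
not restore correspondence — are called as difference regions, the
candidate footprints of horizontal gene transfer.

Region-calling rules: a region is a maximal run of genes that are not
high-identity in-order BBH anchors, except that up to
``max_bbh_interruptions`` CONSECUTIVE such anchors may be bridged when more
divergent content follows. A called region must contain a run of at least
``min_nonbbh_run`` strictly non-BBH genes and at least ``min_region_genes``
genes in total. Low-identity (< ``low_identity_max``) or locally unordered
BBHs never terminate a region and are not limited in number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome
from .orthology import OrthologMap


@dataclass(frozen=True)
class RegionParams:
    min_nonbbh_run: int = 5
    max_bbh_interruptions: int = 3
    min_region_genes: int = 20
    low_identity_max: float = 70.0  # BBHs below this identity do not anchor synteny
    order_tolerance: int = 10  # counterpart-ordinal deviation from local diagonal
    inversion_min_run: int = 3
    translocation_gap: int = 25


@dataclass
class SyntenyProfile:
    """BBH anchors sorted along genome a, with per-anchor order flags."""

    anchors: list[tuple[int, int, float]]
    inverted: np.ndarray  # bool per anchor
    displaced: np.ndarray  # bool per anchor
    n_inversions: int
    n_translocations: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.anchors, columns=["a_ordinal", "b_ordinal", "aa_identity"])
        df["inverted"] = self.inverted
        df["displaced"] = self.displaced
        return df


@dataclass
class DifferenceRegion:
    region_id: str
    a_interval: tuple[int, int]  # first/last ordinal, inclusive
    b_interval: tuple[int, int]
    a_anchors: tuple[str, str]  # bounding locus tags on genome a
    b_anchors: tuple[str, str]
    counts_a: dict[str, int] = field(default_factory=dict)
    counts_b: dict[str, int] = field(default_factory=dict)

    def n_genes(self, side: str = "a") -> int:
        return (self.counts_a if side == "a" else self.counts_b).get("n_genes", 0)


def build_profile(omap: OrthologMap, params: RegionParams | None = None) -> SyntenyProfile:
    """Order anchors along genome a and flag inversion/translocation runs."""
    params = params or RegionParams()
    anchors = sorted(omap.bbh_pairs)
    if len(anchors) < 2:
        raise ValueError("need at least 2 BBH anchors to build a synteny profile")
    b = np.array([x[1] for x in anchors])
    n = len(anchors)
    inverted = np.zeros(n, dtype=bool)
    # maximal runs of strictly decreasing counterpart ordinals
    n_inversions = 0
    i = 0
    while i < n - 1:
        j = i
        while j < n - 1 and b[j + 1] < b[j]:
            j += 1
        if j - i + 1 >= params.inversion_min_run:
            inverted[i : j + 1] = True
            n_inversions += 1
        i = max(j, i + 1)
    # translocation: counterpart ordinal jumps off the local diagonal
    # (relative to the step along genome a, so plain indel gaps do not flag)
    displaced = np.zeros(n, dtype=bool)
    a_ord = np.array([x[0] for x in anchors])
    steps = np.abs(np.diff(b.astype(int)) - np.diff(a_ord.astype(int)))
    jump = steps > params.translocation_gap
    n_translocations = 0
    k = 0
    while k < len(jump):
        if jump[k]:
            # displaced run extends until the diagonal is rejoined
            start = k + 1
            end = start
            while end < len(jump) and not jump[end]:
                end += 1
            if end < len(jump):
                displaced[start : end + 1] = True
                n_translocations += 1
                k = end
            # a single jump that never returns is a terminal offset, not a
            # translocated run
        k += 1
    return SyntenyProfile(
        anchors=[(int(a), int(bb), float(x)) for (a, bb, x) in anchors],
        inverted=inverted,
        displaced=displaced,
        n_inversions=n_inversions,
        n_translocations=n_translocations,
    )


# gene status codes along genome a
_ANCHOR = 0  # high-identity, in-order BBH
_SOFT = 1  # BBH that is low-identity or locally unordered
_NONBBH = 2  # unidirectional or unique
_NONCDS = 3  # RNA genes etc.; transparent to the caller


def _statuses(genome: Genome, omap: OrthologMap, side: str, params: RegionParams) -> np.ndarray:
    bbh = omap.bbh_a if side == "a" else omap.bbh_b
    cds = {g.ordinal for g in genome.cds if g.aa_seq}
    n = len(genome.genes)
    status = np.full(n, _NONCDS, dtype=int)
    anchors = sorted(bbh.items())  # (own ordinal, (counterpart, identity))
    cpart = np.array([c for _, (c, _) in anchors])
    n_anch = len(anchors)
    tol = params.order_tolerance
    for idx, (o, (c, ident)) in enumerate(anchors):
        if ident < params.low_identity_max:
            status[o] = _SOFT
            continue
        # locally unordered: the counterpart ordinal falls outside the
        # bracket spanned by the nearest preceding and following anchors
        # (two on each side, so a single displaced neighbour cannot
        # implicate an innocent anchor)
        prev_ok = idx == 0 or c >= cpart[max(0, idx - 2) : idx].min() - tol
        next_ok = idx == n_anch - 1 or c <= cpart[idx + 1 : idx + 3].max() + tol
        status[o] = _ANCHOR if (prev_ok and next_ok) else _SOFT
    for o in range(n):
        if status[o] == _NONCDS and o in cds:
            status[o] = _NONBBH
    return status


def _scan_runs(status: np.ndarray, params: RegionParams) -> list[tuple[int, int]]:
    """Maximal candidate intervals of non-anchor genes.

    Maximal segments of soft/non-BBH genes are merged across runs of at most
    ``max_bbh_interruptions`` consecutive high-identity anchors, but only when
    both flanking segments are substantive region content (two or more genes,
    or at least one strictly non-BBH gene) — an isolated low-identity BBH in
    an otherwise conserved stretch never recruits its neighbourhood.
    """
    n = len(status)
    # maximal soft/non-BBH segments (NONCDS genes are transparent)
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if status[i] in (_SOFT, _NONBBH):
            j = i
            last = i
            while j + 1 < n and status[j + 1] in (_SOFT, _NONBBH, _NONCDS):
                j += 1
                if status[j] != _NONCDS:
                    last = j
            segments.append((i, last))
            i = j + 1
        else:
            i += 1

    def qualifies(seg: tuple[int, int]) -> bool:
        genes = [s for s in status[seg[0] : seg[1] + 1] if s != _NONCDS]
        return len(genes) >= 2 or _NONBBH in genes

    regions: list[tuple[int, int]] = []
    for seg in segments:
        if regions:
            prev = regions[-1]
            between = status[prev[1] + 1 : seg[0]]
            n_anchors = int(np.sum(between == _ANCHOR))
            if (
                n_anchors <= params.max_bbh_interruptions
                and qualifies(prev)
                and qualifies(seg)
            ):
                regions[-1] = (prev[0], seg[1])
                continue
        regions.append(seg)
    return regions


def _count_interval(
    genome: Genome, omap: OrthologMap, side: str, interval: tuple[int, int]
) -> dict[str, int]:
    lo, hi = interval
    bbh = omap.bbh_a if side == "a" else omap.bbh_b
    uni = {
        h.query_ordinal
        for h in (omap.unidirectional_a if side == "a" else omap.unidirectional_b)
    }
    unique = omap.unique_a if side == "a" else omap.unique_b
    ords = [g.ordinal for g in genome.cds if lo <= g.ordinal <= hi and g.aa_seq]
    return {
        "n_genes": len(ords),
        "n_unique": sum(1 for o in ords if o in unique),
        "n_unidirectional": sum(1 for o in ords if o in uni),
        "n_bbh": sum(1 for o in ords if o in bbh),
    }


def call_regions(
    omap: OrthologMap,
    a: Genome,
    b: Genome,
    params: RegionParams | None = None,
) -> list[DifferenceRegion]:
    """Call contiguous gene-content difference regions along genome a.

    Each region is reported with its counterpart interval on genome b,
    delimited by the innermost flanking high-identity BBH anchors, and with
    per-genome gene accounting.
    """
    params = params or RegionParams()
    status = _statuses(a, omap, "a", params)
    bbh_a = omap.bbh_a
    regions: list[DifferenceRegion] = []
    label = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    for start, end in _scan_runs(status, params):
        seg = status[start : end + 1]
        # longest run of strictly non-BBH genes inside the candidate
        best_run = run = 0
        for s in seg:
            if s == _NONBBH:
                run += 1
                best_run = max(best_run, run)
            elif s != _NONCDS:
                run = 0
        n_genes = int(np.sum((seg == _NONBBH) | (seg == _SOFT) | (seg == _ANCHOR)))
        if best_run < params.min_nonbbh_run or n_genes < params.min_region_genes:
            continue
        # innermost flanking high-identity anchors
        left = next((o for o in range(start - 1, -1, -1) if status[o] == _ANCHOR), None)
        right = next((o for o in range(end + 1, len(status)) if status[o] == _ANCHOR), None)
        b_left = bbh_a[left][0] if left is not None else -1
        b_right = bbh_a[right][0] if right is not None else len(b.genes)
        b_lo, b_hi = sorted((b_left, b_right))
        b_interval = (b_lo + 1, b_hi - 1)
        region = DifferenceRegion(
            region_id=next(label),
            a_interval=(start, end),
            b_interval=b_interval,
            a_anchors=(
                a.genes[left].locus_tag if left is not None else "",
                a.genes[right].locus_tag if right is not None else "",
            ),
            b_anchors=(
                b.genes[b_lo].locus_tag if b_lo >= 0 else "",
                b.genes[b_hi].locus_tag if b_hi < len(b.genes) else "",
            ),
        )
        region.counts_a = _count_interval(a, omap, "a", region.a_interval)
        region.counts_b = _count_interval(b, omap, "b", region.b_interval)
        regions.append(region)
    return regions


def account_regions(
    regions: list[DifferenceRegion], omap: OrthologMap
) -> pd.DataFrame:
    """Per-region accounting plus the fraction of chromosome-wide unique genes captured."""
    rows = []
    captured_a: set[int] = set()
    captured_b: set[int] = set()
    for r in regions:
        for side, counts, interval in (
            ("a", r.counts_a, r.a_interval),
            ("b", r.counts_b, r.b_interval),
        ):
            unique = omap.unique_a if side == "a" else omap.unique_b
            in_iv = {o for o in unique if interval[0] <= o <= interval[1]}
            (captured_a if side == "a" else captured_b).update(in_iv)
            rows.append({"region": r.region_id, "genome": side, **counts})
    df = pd.DataFrame(rows)
    df.attrs["unique_captured_a"] = len(captured_a)
    df.attrs["unique_total_a"] = len(omap.unique_a)
    df.attrs["unique_captured_b"] = len(captured_b)
    df.attrs["unique_total_b"] = len(omap.unique_b)
    df.attrs["capture_fraction_a"] = (
        len(captured_a) / len(omap.unique_a) if omap.unique_a else float("nan")
    )
    df.attrs["capture_fraction_b"] = (
        len(captured_b) / len(omap.unique_b) if omap.unique_b else float("nan")
    )
    return df


def regions_bed(regions: list[DifferenceRegion], a: Genome) -> str:
    """Regions as BED lines (0-based half-open nucleotide coordinates on genome a)."""
    lines = []
    for r in regions:
        lo, hi = r.a_interval
        start_bp = a.genes[lo].start
        end_bp = min(a.genes[hi].end, len(a))
        lines.append(f"{a.genome_id}\t{start_bp}\t{end_bp}\tregion_{r.region_id}")
    return "\n".join(lines) + ("\n" if lines else "")


def regions_table(regions: list[DifferenceRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "region": r.region_id,
                "a_first": r.a_interval[0],
                "a_last": r.a_interval[1],
                "b_first": r.b_interval[0],
                "b_last": r.b_interval[1],
                "a_anchor_left": r.a_anchors[0],
                "a_anchor_right": r.a_anchors[1],
                **{f"a_{k}": v for k, v in r.counts_a.items()},
                **{f"b_{k}": v for k, v in r.counts_b.items()},
            }
        )
    return pd.DataFrame(rows)
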