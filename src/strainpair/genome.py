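"""Annotated genome model and I/O.

A :class:`Genome` is a single circular bacterial replicon plus an ordered
list of :class:`Gene` features. Coordinates are stored 0-based half-open
internally; GenBank and GFF3 readers/writers convert from/to the 1-based
inclusive convention of those formats. CDS features are translated with
bacterial translation table 11, with annotated non-ATG initiators (GTG/TTG)
rendered as methionine, matching how deposited bacterial proteomes are
translated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import edlib
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTNRYSWKMBDHV")


class FeatureKind(str, Enum):
    CDS = "CDS"
    rRNA = "rRNA"
    tRNA = "tRNA"
    other_RNA = "other_RNA"


#: GenBank/GFF3 feature types mapped onto the internal feature kinds.
_KIND_MAP = {
    "CDS": FeatureKind.CDS,
    "rRNA": FeatureKind.rRNA,
    "tRNA": FeatureKind.tRNA,
    "tmRNA": FeatureKind.other_RNA,
    "ncRNA": FeatureKind.other_RNA,
    "misc_RNA": FeatureKind.other_RNA,
    "RNase_P_RNA": FeatureKind.other_RNA,
    "SRP_RNA": FeatureKind.other_RNA,
    "antisense_RNA": FeatureKind.other_RNA,
}


@dataclass
class Gene:
    """One annotated feature, strand-corrected.

    ``nt_seq`` is the coding-strand sequence (reverse-complemented for
    minus-strand features); ``aa_seq`` is the table-11 translation for CDS
    features with the terminal stop removed.
    """

    locus_tag: str
    ordinal: int
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    feature_kind: FeatureKind
    product: str = ""
    nt_seq: str = ""
    aa_seq: str = ""
    partial: bool = False

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_cds(self) -> bool:
        return self.feature_kind is FeatureKind.CDS


@dataclass
class Genome:
    genome_id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    source_format: str = "genbank"

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")

    @property
    def cds(self) -> list[Gene]:
        """CDS genes usable for protein analyses (non-partial)."""
        return [g for g in self.genes if g.is_cds and not g.partial]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeSummary:
    length_bp: int
    gc_percent: float
    n_genes: int
    n_cds: int
    n_trna: int
    n_rrna: int
    n_other_rna: int
    n_hypothetical: int

    def to_rows(self) -> list[tuple[str, object]]:
        """Rows in the conventional chromosome-statistics layout."""
        return [
            ("Genome size (bp)", self.length_bp),
            ("GC content (%)", self.gc_percent),
            ("Genes (no.)", self.n_genes),
            ("Protein-coding genes (no.)", self.n_cds),
            ("Hypothetical proteins (no.)", self.n_hypothetical),
            ("tRNA (no.)", self.n_trna),
            ("rRNA (no.)", self.n_rrna),
            ("Other RNAs (no.)", self.n_other_rna),
        ]


def _translate_cds(nt_seq: str, partial: bool) -> tuple[str, bool]:
    """Translate a coding sequence with table 11.

    Returns (aa_seq, partial). A length not divisible by 3 or an internal
    stop marks the gene partial and yields an empty protein. The initiator
    codon is rendered as M regardless of whether it is ATG/GTG/TTG.
    """
    if len(nt_seq) % 3 != 0:
        return "", True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aa = str(Seq(nt_seq).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        return "", True
    if aa:
        aa = "M" + aa[1:]
    return aa, partial


def _extract_gene(
    seq: str, locus_tag: str, start: int, end: int, strand: str, kind: FeatureKind,
    product: str, origin_span: bool = False,
) -> Gene:
    n = len(seq)
    if origin_span:
        if not (0 <= start < n and 0 < end <= n):
            raise ValueError(f"{locus_tag}: origin-spanning coordinates outside sequence")
        nt = seq[start:] + seq[:end]
        g_end = end + n  # keeps end > start for the stored interval
    else:
        if not (0 <= start < end <= n):
            raise ValueError(
                f"{locus_tag}: coordinates [{start}, {end}) outside sequence of length {n}"
            )
        nt = seq[start:end]
        g_end = end
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    aa, partial = "", False
    if kind is FeatureKind.CDS:
        aa, partial = _translate_cds(nt, False)
        if partial:
            logger.warning("CDS %s flagged partial; excluded from protein analyses", locus_tag)
    return Gene(
        locus_tag=locus_tag, ordinal=-1, start=start, end=g_end, strand=strand,
        feature_kind=kind, product=product, nt_seq=nt, aa_seq=aa, partial=partial,
    )


def _finalize(genome_id: str, seq: str, genes: list[Gene], source_format: str) -> Genome:
    genes.sort(key=lambda g: (g.start, g.end))
    for i, g in enumerate(genes):
        g.ordinal = i
    return Genome(genome_id=genome_id, sequence=seq, genes=genes, source_format=source_format)


def load_genome(path: str | Path, format: str = "genbank", gff3: str | Path | None = None) -> Genome:
    """Load an annotated genome from GenBank or FASTA+GFF3.

    Parameters
    ----------
    path
        GenBank flat file, or the FASTA file when ``format="fasta+gff3"``.
    format
        ``"genbank"`` or ``"fasta+gff3"``.
    gff3
        Companion GFF3 annotation (required for ``fasta+gff3``).
    """
    path = Path(path)
    if format == "genbank":
        return _load_genbank(path)
    if format == "fasta+gff3":
        if gff3 is None:
            raise ValueError("fasta+gff3 format requires a gff3 path")
        return _load_fasta_gff3(path, Path(gff3))
    raise ValueError(f"unknown format: {format!r}")


def _single_record(records: list, path: Path):
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly one replicon, found {len(records)} records"
        )
    return records[0]


def _load_genbank(path: Path) -> Genome:
    record = _single_record(list(SeqIO.parse(str(path), "genbank")), path)
    seq = str(record.seq).upper()
    genes: list[Gene] = []
    for feat in record.features:
        kind = _KIND_MAP.get(feat.type)
        if kind is None:
            continue
        quals = feat.qualifiers
        locus = quals.get("locus_tag", quals.get("gene", [f"feat_{len(genes)}"]))[0]
        product = quals.get("product", [""])[0]
        parts = feat.location.parts
        if len(parts) == 1:
            start, end = int(feat.location.start), int(feat.location.end)
            origin_span = False
        elif len(parts) == 2:
            # accept only a two-segment join that wraps the origin
            p1, p2 = parts
            if not (int(p1.end) == len(seq) and int(p2.start) == 0):
                raise ValueError(f"{locus}: unsupported compound location {feat.location}")
            start, end = int(p1.start), int(p2.end)
            origin_span = True
        else:
            raise ValueError(f"{locus}: unsupported {len(parts)}-segment compound location")
        strand = "-" if feat.location.strand == -1 else "+"
        genes.append(_extract_gene(seq, locus, start, end, strand, kind, product, origin_span))
    return _finalize(record.id or path.stem, seq, genes, "genbank")


def _load_fasta_gff3(fasta_path: Path, gff3_path: Path) -> Genome:
    record = _single_record(list(SeqIO.parse(str(fasta_path), "fasta")), fasta_path)
    seq = str(record.seq).upper()
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[Gene] = []
    for feat in db.all_features():
        kind = _KIND_MAP.get(feat.featuretype)
        if kind is None:
            continue
        if feat.seqid != record.id:
            raise ValueError(
                f"GFF3 seqid {feat.seqid!r} does not match FASTA header {record.id!r}"
            )
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", ["?"]))[0]
        product = feat.attributes.get("product", [""])[0]
        start = feat.start - 1  # GFF3 is 1-based inclusive
        end = feat.end
        strand = "-" if feat.strand == "-" else "+"
        genes.append(_extract_gene(seq, locus, start, end, strand, kind, product))
    return _finalize(record.id, seq, genes, "fasta+gff3")


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: Genome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_gff3(genome: Genome, path: str | Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {genome.genome_id} 1 {len(genome)}"]
    for g in genome.genes:
        ftype = g.feature_kind.value if g.feature_kind is not FeatureKind.other_RNA else "misc_RNA"
        attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
        if g.product:
            attrs.append(f"product={g.product}")
        if g.partial:
            attrs.append("partial=true")
        lines.append(
            "\t".join(
                [
                    genome.genome_id, "strainpair", ftype,
                    str(g.start + 1), str(min(g.end, len(genome))), ".",
                    g.strand, "0" if g.is_cds else ".", ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_genbank(genome: Genome, path: str | Path) -> None:
    rec = SeqRecord(
        Seq(genome.sequence), id=genome.genome_id, name=genome.genome_id[:16],
        description="", annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for g in genome.genes:
        ftype = g.feature_kind.value if g.feature_kind is not FeatureKind.other_RNA else "misc_RNA"
        loc = FeatureLocation(g.start, min(g.end, len(genome)), strand=1 if g.strand == "+" else -1)
        quals = {"locus_tag": [g.locus_tag]}
        if g.product:
            quals["product"] = [g.product]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# summaries and marker comparison

def summarize(genome: Genome) -> GenomeSummary:
    """Chromosome statistics: length, GC%, and feature counts.

    GC% is computed over unambiguous bases only: 100*(G+C)/(A+C+G+T),
    rounded to one decimal.
    """
    if not genome.sequence:
        raise ValueError("empty sequence")
    seq = genome.sequence
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    gc = round(100.0 * (counts["G"] + counts["C"]) / denom, 1)
    n_cds = sum(1 for g in genome.genes if g.feature_kind is FeatureKind.CDS)
    n_trna = sum(1 for g in genome.genes if g.feature_kind is FeatureKind.tRNA)
    n_rrna = sum(1 for g in genome.genes if g.feature_kind is FeatureKind.rRNA)
    n_other = sum(1 for g in genome.genes if g.feature_kind is FeatureKind.other_RNA)
    n_hypo = sum(
        1
        for g in genome.genes
        if g.feature_kind is FeatureKind.CDS and "hypothetical protein" in g.product.lower()
    )
    return GenomeSummary(
        length_bp=len(seq),
        gc_percent=gc,
        n_genes=len(genome.genes),
        n_cds=n_cds,
        n_trna=n_trna,
        n_rrna=n_rrna,
        n_other_rna=n_other,
        n_hypothetical=n_hypo,
    )


def compare_marker_copies(
    a: Genome,
    b: Genome,
    feature_kind: FeatureKind = FeatureKind.rRNA,
    product_filter: str = "16S",
) -> list[tuple[tuple[str, str], int]]:
    """Edit distance of each marker copy in ``a`` to its closest copy in ``b``.

    Global (Needleman-Wunsch) alignment with unit costs; the distance counts
    substitutions plus indels. Typical use: the two 16S rRNA copies of a
    bacterial chromosome against the comparator's copies.
    """
    def _select(g: Genome) -> list[Gene]:
        return [
            x
            for x in g.genes
            if x.feature_kind is feature_kind and product_filter.lower() in x.product.lower()
        ]

    copies_a, copies_b = _select(a), _select(b)
    if not copies_a or not copies_b:
        raise ValueError(
            f"no {feature_kind.value} feature matching {product_filter!r} in "
            f"{'both genomes' if not copies_a and not copies_b else (a.genome_id if not copies_a else b.genome_id)}"
        )
    out = []
    for ca in copies_a:
        best = min(
            ((edlib.align(ca.nt_seq, cb.nt_seq, mode="NW")["editDistance"], cb) for cb in copies_b),
            key=lambda t: t[0],
        )
        out.append(((ca.locus_tag, best[1].locus_tag), best[0]))
    return out


def summary_tsv(summaries: dict[str, GenomeSummary]) -> str:
    """Multi-genome summary table as TSV, one row per statistic."""
    ids = list(summaries)
    lines = ["Parameter\t" + "\t".join(ids)]
    rows = {gid: dict(s.to_rows()) for gid, s in summaries.items()}
    for name, _ in next(iter(summaries.values())).to_rows():
        lines.append(name + "\t" + "\t".join(str(rows[gid][name]) for gid in ids))
    return "\n".join(lines) + "\n"
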