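"""End-to-end two-genome comparison.

Runs genome loading, reciprocal-best-hit orthology, synteny/difference-region
calling, the modal codon usage HGT test, and fragment ANI, and serializes a
machine-readable report plus per-stage intermediates into an output
directory. Every number in the report is re-derivable from the serialized
intermediates, and all randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ani import ANIParams, ANIResult, compute_ani
from .codon import hgt_report
from .genome import Genome, load_genome, summarize, summary_tsv
from .orthology import AlignmentParams, OrthologMap, build_ortholog_map, identity_distribution
from .synteny import (
    DifferenceRegion,
    RegionParams,
    SyntenyProfile,
    account_regions,
    build_profile,
    call_regions,
    regions_bed,
    regions_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_a: str = ""
    genome_b: str = ""
    format: str = "genbank"  # genbank | fasta+gff3
    gff3_a: str | None = None
    gff3_b: str | None = None
    out_dir: str = "strainpair_out"
    seed: int = 0
    n_rounds: int = 10
    conformity_p: float = 0.1
    skip_ani: bool = False
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    regions: RegionParams = field(default_factory=RegionParams)
    ani: ANIParams = field(default_factory=ANIParams)
    identity_thresholds: tuple[float, ...] = (96.0, 98.0)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


@dataclass
class ComparisonReport:
    summaries: dict
    identity_distribution: pd.DataFrame
    ortholog_map: OrthologMap
    profile: SyntenyProfile
    regions: list[DifferenceRegion]
    region_accounting: pd.DataFrame
    codon_distances: pd.DataFrame
    ani: ANIResult | None
    provenance: dict

    def to_json_dict(self) -> dict:
        acct = self.region_accounting
        return {
            "provenance": self.provenance,
            "summaries": self.summaries,
            "orthology": {
                "n_bbh": len(self.ortholog_map.bbh_pairs),
                "n_unidirectional_a": len(self.ortholog_map.unidirectional_a),
                "n_unidirectional_b": len(self.ortholog_map.unidirectional_b),
                "n_unique_a": len(self.ortholog_map.unique_a),
                "n_unique_b": len(self.ortholog_map.unique_b),
                "identity_distribution": self.identity_distribution.to_dict("records"),
            },
            "synteny": {
                "n_anchors": len(self.profile.anchors),
                "n_inversions": self.profile.n_inversions,
                "n_translocations": self.profile.n_translocations,
            },
            "regions": regions_table(self.regions).to_dict("records"),
            "region_capture": {
                k: acct.attrs.get(k)
                for k in (
                    "unique_captured_a", "unique_total_a", "capture_fraction_a",
                    "unique_captured_b", "unique_total_b", "capture_fraction_b",
                )
            },
            "codon_distances": self.codon_distances.to_dict("records"),
            "ani": self.ani.to_dict() if self.ani else None,
        }


def run_compare(
    config: RunConfig,
    genome_a: Genome | None = None,
    genome_b: Genome | None = None,
) -> ComparisonReport:
    """Execute the full comparison; pass Genome objects to skip file loading."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_yaml()
    (out / "config.yaml").write_text(cfg_text)

    if genome_a is None:
        genome_a = load_genome(config.genome_a, config.format, config.gff3_a)
    if genome_b is None:
        genome_b = load_genome(config.genome_b, config.format, config.gff3_b)
    logger.info("stage=load a=%s (%d genes) b=%s (%d genes)",
                genome_a.genome_id, len(genome_a.genes), genome_b.genome_id, len(genome_b.genes))

    summaries = {g.genome_id: summarize(g) for g in (genome_a, genome_b)}
    (out / "table2.tsv").write_text(summary_tsv(summaries))

    omap = build_ortholog_map(genome_a, genome_b, config.alignment)
    logger.info("stage=orthology n_bbh=%d unique_a=%d unique_b=%d",
                len(omap.bbh_pairs), len(omap.unique_a), len(omap.unique_b))
    idd = identity_distribution(omap, config.identity_thresholds)
    idd.to_csv(out / "identity_distribution.tsv", sep="\t", index=False)
    omap.to_frame().to_csv(out / "bbh_pairs.tsv", sep="\t", index=False)

    profile = build_profile(omap, config.regions)
    profile.to_frame().to_csv(out / "synteny_points.tsv", sep="\t", index=False)
    regions = call_regions(omap, genome_a, genome_b, config.regions)
    logger.info("stage=regions n=%d", len(regions))
    acct = account_regions(regions, omap)
    regions_table(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    (out / "regions.bed").write_text(regions_bed(regions, genome_a))

    codon_df = hgt_report(
        genome_a, genome_b, regions,
        n_rounds=config.n_rounds, seed=config.seed, conformity_p=config.conformity_p,
    )
    logger.info("stage=codon rows=%d", len(codon_df))
    codon_df.to_csv(out / "codon_distances.tsv", sep="\t", index=False)

    ani = None
    if not config.skip_ani:
        ani = compute_ani(genome_a, genome_b, config.ani)
        logger.info("stage=ani ani=%.2f retained=%d/%d",
                    ani.ani_percent, ani.n_fragments_retained, ani.n_fragments_total)
        (out / "ani.json").write_text(json.dumps(ani.to_dict(), indent=2))

    # hash of the analysis parameters only; output location is not part of it
    cfg_dict = asdict(config)
    cfg_dict.pop("out_dir", None)
    provenance = {
        "strainpair_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "genome_a": genome_a.genome_id,
        "genome_b": genome_b.genome_id,
    }
    report = ComparisonReport(
        summaries={gid: asdict(s) for gid, s in summaries.items()},
        identity_distribution=idd,
        ortholog_map=omap,
        profile=profile,
        regions=regions,
        region_accounting=acct,
        codon_distances=codon_df,
        ani=ani,
        provenance=provenance,
    )
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2, default=float))
    return report
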