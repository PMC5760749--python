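"""Reciprocal-best-hit orthologs and the synteny profile.

Shows the low-level API: align two proteins, build the best-hit tables,
classify genes into BBH / unidirectional / unique, and inspect gene-order
conservation.
"""

import strainpair as sp

# a single protein pair: identity is computed over alignment columns
# excluding terminal gap runs, so the truncated copy still scores 100%
hit = sp.align_pair("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "MKTAYIAKQRQISFVK")
print(f"identity {hit.aa_identity:.1f}%  coverage {hit.query_coverage:.2f}/"
      f"{hit.subject_coverage:.2f}  score {hit.score:.0f}")

genome_a, genome_b, _ = sp.simulate_pair(sp.SimulationConfig(seed=3, n_backbone_genes=80))
omap = sp.build_ortholog_map(genome_a, genome_b)
print(f"{len(omap.bbh_pairs)} BBH pairs, {len(omap.unique_a)} unique to A, "
      f"{len(omap.unique_b)} unique to B")

profile = sp.build_profile(omap)
# for a clonal strain pair the anchor ordinals lie on the diagonal:
# no inversions or translocations
print(f"anchors {len(profile.anchors)}, inversions {profile.n_inversions}, "
      f"translocations {profile.n_translocations}")
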