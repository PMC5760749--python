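"""Shared helpers for codon-usage tests."""

import numpy as np

import strainpair as sp


def family_tvs(mode, bias):
    """Per-family total variation between an estimated mode and a true bias."""
    return {aa: 0.5 * float(np.abs(mode.freqs[aa] - bias[aa]).sum()) for aa in sp.FAMILIES}


def weighted_tv(mode, bias):
    """Amino-acid-frequency-weighted TV (the package's distance weighting)."""
    totals = np.array([mode.family_totals[aa] for aa in sp.FAMILIES], dtype=float)
    w = totals / totals.sum()
    tvs = family_tvs(mode, bias)
    return float(sum(wi * tvs[aa] for wi, aa in zip(w, sp.FAMILIES)))


def family_noise_floor(mode, n_sd=3.0):
    """Binomial sampling error of each family's frequency estimate.

    A family observed n times has per-codon frequency sd ~ sqrt(f(1-f)/n);
    the TV of the estimate against the truth cannot be expected to beat a
    few of those, so rare families (Cys, His) get a wider band than
    abundant ones.
    """
    floors = {}
    for aa in sp.FAMILIES:
        n = max(mode.family_totals[aa], 1)
        f = mode.freqs[aa]
        sd_sum = 0.5 * float(np.sqrt(np.clip(f * (1 - f), 0, None) / n).sum())
        floors[aa] = n_sd * sd_sum
    return floors
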