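"""Genetic-code lookups shared by the CDS simulator and the Ka/Ks estimator.

The codon-to-amino-acid map comes from Biopython's standard table; on top of
it we precompute the Nei-Gojobori per-codon synonymous/nonsynonymous site
fractions.  Changes producing a stop codon are excluded from the site count
(so a codon's synonymous + nonsynonymous sites can fall slightly short of 3
when it neighbours a stop).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

_standard = _BioCodonTable.unambiguous_dna_by_id[1]

CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS: tuple[str, ...] = tuple(_standard.stop_codons)
NON_STOP_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes 1/3 of a site per possible change; mutations
    to stop codons are dropped from both tallies.
    """
    if CODON_TABLE.get(codon, "*") == "*":
        raise ValueError(f"cannot count sites of stop/invalid codon {codon!r}")
    aa = CODON_TABLE[codon]
    syn = 0.0
    non = 0.0
    for p in range(3):
        for nt in "ACGT":
            if nt == codon[p]:
                continue
            mut = codon[:p] + nt + codon[p + 1 :]
            target = CODON_TABLE[mut]
            if target == "*":
                continue
            if target == aa:
                syn += 1.0 / 3.0
            else:
                non += 1.0 / 3.0
    return syn, non


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) difference counts for a codon pair.

    Averages over all orders of the single-nucleotide steps separating the
    codons; pathways passing through a stop codon are discarded (all
    pathways are kept if every one hits a stop).
    """
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0
    from itertools import permutations

    paths: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = non = 0.0
        hit_stop = False
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1 :]
            if CODON_TABLE[nxt] == "*":
                hit_stop = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        (fallback if hit_stop else paths).append((syn, non))
    if not paths:
        paths = fallback
    arr = np.asarray(paths, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())
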