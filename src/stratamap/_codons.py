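"""Standard genetic code helpers shared by the simulator and the statistics.

The table is built once from Biopython's standard codon table.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid one-letter code, with '*' for stop codons
CODON_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_AA[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)

#: two-base prefixes whose codon family is fourfold degenerate
FOURFOLD_PREFIXES = frozenset(
    p
    for p in (a + b for a in BASES for b in BASES)
    if len({CODON_AA[p + c] for c in BASES}) == 1 and CODON_AA[p + "A"] != "*"
)


def translate(codon: str) -> str:
    return CODON_AA[codon]


@lru_cache(maxsize=None)
def syn_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of the 3 possible changes that are synonymous.

    Changes producing a stop codon count as non-synonymous; stop codons
    themselves have zero synonymous fraction everywhere.
    """
    if codon in STOP_CODONS:
        return (0.0, 0.0, 0.0)
    aa = CODON_AA[codon]
    out = []
    for pos in range(3):
        n_syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_AA[alt] == aa:
                n_syn += 1
        out.append(n_syn / 3.0)
    return tuple(out)  # type: ignore[return-value]


@lru_cache(maxsize=None)
def syn_alternatives(codon: str, pos: int) -> tuple[str, ...]:
    """Bases != codon[pos] giving a synonymous, non-stop codon at ``pos``."""
    if codon in STOP_CODONS:
        return ()
    aa = CODON_AA[codon]
    alts = []
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and CODON_AA[alt] == aa:
            alts.append(b)
    return tuple(alts)
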