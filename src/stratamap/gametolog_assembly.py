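"""Reconstruct Y-linked gametolog CDSs from allele-tagged reads.

Reads carrying the alt allele at one or more Y-SNP positions are
assigned wholly to the Y; a per-position majority consensus over the
selected reads yields the Y CDS, with N at uncovered or tied positions.
Completeness and premature-stop status are reported against the X CDS.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from stratamap._codons import STOP_CODONS
from stratamap.formats_io import AlignedRead, GeneModel, VariantSite

logger = logging.getLogger(__name__)


@dataclass
class YConsensus:
    gene_id: str
    seq: str  # same length as the X CDS, over ACGTN
    completeness_pct: float
    premature_stop: bool
    n_supporting_reads: int


def select_y_reads(
    reads: Sequence[AlignedRead], ysnps: Sequence[VariantSite]
) -> list[AlignedRead]:
    """Reads whose base matches the alt allele at >= 1 Y-SNP position.

    Reads that overlap Y-SNPs but show only reference alleles there are
    excluded, as are reads overlapping no Y-SNP at all.
    """
    alt_at = {s.cds_pos: s.alt for s in ysnps}
    selected = []
    for r in reads:
        for pos, alt in alt_at.items():
            if r.start <= pos <= r.end and r.seq[pos - r.start] == alt:
                selected.append(r)
                break
    logger.info("select_y_reads: %d/%d reads selected", len(selected), len(reads))
    return selected


def call_consensus(
    y_reads: Sequence[AlignedRead], gene: GeneModel, min_depth: int = 1
) -> YConsensus:
    """Per-position majority consensus over the selected Y reads.

    N bases in reads are ignored; positions with coverage below
    ``min_depth`` or with an exact tie between top bases become N.  An
    empty read set yields an all-N consensus.
    """
    L = gene.length
    piles: list[Counter] = [Counter() for _ in range(L)]
    for r in y_reads:
        for offset, b in enumerate(r.seq):
            if b != "N":
                piles[r.start - 1 + offset][b] += 1
    out = []
    for pile in piles:
        total = sum(pile.values())
        if total < min_depth or not pile:
            out.append("N")
            continue
        ranked = pile.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out.append("N")  # tie: neither allele trusted
        else:
            out.append(ranked[0][0])
    seq = "".join(out)
    stop, _ = check_premature_stops(seq)
    return YConsensus(
        gene_id=gene.gene_id,
        seq=seq,
        completeness_pct=completeness_report(seq),
        premature_stop=stop,
        n_supporting_reads=len(y_reads),
    )


def completeness_report(consensus: YConsensus | str) -> float:
    """Percent of non-N positions relative to the full CDS length."""
    seq = consensus.seq if isinstance(consensus, YConsensus) else consensus
    if not seq:
        return 0.0
    return 100.0 * sum(b != "N" for b in seq) / len(seq)


def check_premature_stops(seq_or_consensus: YConsensus | str) -> tuple[bool, list[int]]:
    """In-frame stop codons before the terminal codon.

    Codons containing N are skipped.  Returns (has_premature_stop,
    1-based codon indices of the premature stops).
    """
    seq = (
        seq_or_consensus.seq
        if isinstance(seq_or_consensus, YConsensus)
        else seq_or_consensus
    )
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    positions = []
    n_codons = len(seq) // 3
    for c in range(n_codons - 1):  # exclude the terminal codon
        codon = seq[3 * c : 3 * c + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            positions.append(c + 1)
    return (bool(positions), positions)


def assemble_gene(
    reads: Sequence[AlignedRead],
    ysnps: Sequence[VariantSite],
    gene: GeneModel,
    min_depth: int = 1,
) -> YConsensus:
    """Select Y reads and call the consensus in one step."""
    return call_consensus(select_y_reads(reads, ysnps), gene, min_depth=min_depth)
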