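"""Per-gene population-genetic statistics.

* fourfold-degenerate site masks over CDS alignments,
* nucleotide diversity (pi) with pairwise deletion of missing data,
* Kelly's ZnS linkage-disequilibrium statistic (mean r^2 over site pairs),
* pairwise synonymous / non-synonymous divergence between two CDSs using
  Nei-Gojobori (1986) counting with Jukes-Cantor correction.

The divergence estimator is the plain NG86 method; no codon-model
maximum-likelihood estimate is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np

from stratamap._codons import CODON_AA, FOURFOLD_PREFIXES, STOP_CODONS, syn_fractions
from stratamap.formats_io import HET, HOM_ALT, HOM_REF, MISSING, VariantSite

logger = logging.getLogger(__name__)


@dataclass
class DivergenceResult:
    gene_id: str
    ks: float
    ka: float
    s_sites: float
    n_sites: float
    n_codons_used: int
    saturated_s: bool = False
    saturated_n: bool = False


@dataclass
class DiversityResult:
    gene_id: str
    pi_4fold: float | None
    n_4fold_sites: int
    n_segregating: int
    zns: float | None


@dataclass
class StratumStat:
    mean: float
    se: float | None
    n: int


# ---------------------------------------------------------------------------
# fourfold-degenerate site mask
# ---------------------------------------------------------------------------


def fourfold_mask(seqs: Sequence[str]) -> list[int]:
    """0-based column indices of usable fourfold-degenerate third positions.

    A third-codon-position column is kept iff every sequence with a fully
    resolved (N-free) codon at that codon has an identical two-base prefix
    and that prefix belongs to a fourfold-degenerate codon family.  Codons
    unresolved in all sequences are dropped.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    if L % 3 != 0:
        raise ValueError(f"alignment length {L} not divisible by 3")
    mask: list[int] = []
    for c in range(L // 3):
        prefixes = {
            s[3 * c : 3 * c + 2]
            for s in seqs
            if "N" not in s[3 * c : 3 * c + 3]
        }
        if len(prefixes) == 1 and next(iter(prefixes)) in FOURFOLD_PREFIXES:
            mask.append(3 * c + 2)
    return mask


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def nucleotide_diversity(seqs: Sequence[str], mask: Sequence[int]) -> float | None:
    """Average per-site pairwise difference over the masked columns.

    Per site, pairs involving an N are deleted; sites with fewer than two
    resolved bases do not enter the average.  Returns None (logged) when
    no masked site is usable.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    if not mask:
        logger.info("nucleotide_diversity: empty mask")
        return None
    total = 0.0
    n_used = 0
    for i in mask:
        bases = [s[i] for s in seqs if s[i] != "N"]
        k = len(bases)
        if k < 2:
            continue
        n_pairs = k * (k - 1) // 2
        diffs = sum(a != b for a, b in combinations(bases, 2))
        total += diffs / n_pairs
        n_used += 1
    if n_used == 0:
        logger.info("nucleotide_diversity: no masked site with >= 2 resolved bases")
        return None
    return total / n_used


def count_segregating(seqs: Sequence[str], mask: Sequence[int]) -> int:
    n = 0
    for i in mask:
        alleles = {s[i] for s in seqs} - {"N"}
        if len(alleles) > 1:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Kelly's ZnS
# ---------------------------------------------------------------------------


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over entries where both vectors are >= 0.

    Missing values are encoded as -1.
    """
    ok = (x >= 0) & (y >= 0)
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if len(xs) < 2:
        raise ValueError("fewer than 2 complete observations for an r^2 pair")
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        raise ValueError("monomorphic site in ZnS input")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r * r


def zns_from_matrix(matrix: np.ndarray) -> float | None:
    """ZnS from an (S x n) allele matrix (0/1 alleles or 0/1/2 dosages, -1 = missing)."""
    S = matrix.shape[0]
    if S < 2:
        return None
    for row in matrix:
        vals = row[row >= 0]
        if len(set(vals.tolist())) < 2:
            raise ValueError("monomorphic site in ZnS input")
    r2s = [
        _pairwise_r2(matrix[i], matrix[j]) for i, j in combinations(range(S), 2)
    ]
    return float(np.mean(r2s))


_DOSAGE = {HOM_REF: 0, HET: 1, HOM_ALT: 2, MISSING: -1}


def kelly_zns(
    sites: Sequence[VariantSite],
    samples: Sequence[str] | None = None,
    haplotypes: Sequence[str] | None = None,
) -> float | None:
    """ZnS = mean r^2 over all pairs of segregating sites.

    Two routes are supported:

    * ``haplotypes`` given (phased sequences covering the gene's CDS):
      r^2 of 0/1 alt-allele indicators on the haplotypes;
    * otherwise genotype dosages (0/1/2) across ``samples`` are used as the
      unphased proxy.

    Returns None when fewer than 2 sites are supplied; raises on
    monomorphic input sites.
    """
    if len(sites) < 2:
        return None
    if haplotypes is not None:
        matrix = np.empty((len(sites), len(haplotypes)), dtype=int)
        for i, site in enumerate(sites):
            for j, hap in enumerate(haplotypes):
                base = hap[site.cds_pos - 1]
                if base == site.alt:
                    matrix[i, j] = 1
                elif base == site.ref:
                    matrix[i, j] = 0
                else:
                    matrix[i, j] = -1
    else:
        if samples is None:
            samples = sorted(sites[0].genotypes)
        matrix = np.empty((len(sites), len(samples)), dtype=int)
        for i, site in enumerate(sites):
            for j, sid in enumerate(samples):
                matrix[i, j] = _DOSAGE[site.genotypes.get(sid, MISSING)]
    return zns_from_matrix(matrix)


# ---------------------------------------------------------------------------
# Nei-Gojobori pairwise divergence
# ---------------------------------------------------------------------------


def _pathway_diff_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Synonymous/non-synonymous difference counts for one codon pair.

    Averages over all minimal mutational pathways between the codons;
    pathways passing through a stop codon are excluded.  Returns None when
    every pathway is blocked by a stop.
    """
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return (0.0, 0.0)
    valid: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_AA[nxt] == CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            valid.append((sd, nd))
    if not valid:
        return None
    return (
        sum(v[0] for v in valid) / len(valid),
        sum(v[1] for v in valid) / len(valid),
    )


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; requires p < 3/4."""
    if p >= 0.75:
        raise ValueError("proportion saturated (p >= 3/4)")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def pairwise_divergence(x_cds: str, y_cds: str, gene_id: str = "") -> DivergenceResult:
    """Nei-Gojobori (1986) Ks/Ka between two in-frame CDSs of equal length.

    Codons containing N in either sequence are excluded, as are codons that
    are stops in either sequence and codon pairs connected only by
    stop-crossing pathways.  Proportions are Jukes-Cantor corrected;
    saturation (p >= 3/4) is flagged and yields NaN for the affected rate.
    """
    if len(x_cds) != len(y_cds):
        raise ValueError("sequence length mismatch")
    if len(x_cds) % 3 != 0:
        raise ValueError("length not divisible by 3")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for c in range(len(x_cds) // 3):
        cx = x_cds[3 * c : 3 * c + 3]
        cy = y_cds[3 * c : 3 * c + 3]
        if "N" in cx or "N" in cy:
            continue
        if cx in STOP_CODONS or cy in STOP_CODONS:
            continue
        counts = _pathway_diff_counts(cx, cy)
        if counts is None:
            continue
        fx = sum(syn_fractions(cx))
        fy = sum(syn_fractions(cy))
        s_sites += (fx + fy) / 2.0
        n_sites += 3.0 - (fx + fy) / 2.0
        sd += counts[0]
        nd += counts[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError(f"{gene_id}: no usable codons for divergence")
    ks = ka = float("nan")
    sat_s = sat_n = False
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    if ps >= 0.75:
        sat_s = True
    else:
        ks = jukes_cantor(ps)
    if pn >= 0.75:
        sat_n = True
    else:
        ka = jukes_cantor(pn)
    return DivergenceResult(
        gene_id=gene_id,
        ks=ks,
        ka=ka,
        s_sites=s_sites,
        n_sites=n_sites,
        n_codons_used=n_codons,
        saturated_s=sat_s,
        saturated_n=sat_n,
    )


# ---------------------------------------------------------------------------
# per-gene diversity convenience and stratum summaries
# ---------------------------------------------------------------------------


def diversity_from_alignment(gene_id: str, seqs: Sequence[str]) -> DiversityResult:
    """Fourfold-site pi, segregating-site count and ZnS for one alignment."""
    mask = fourfold_mask(seqs)
    pi = nucleotide_diversity(seqs, mask) if mask else None
    n_seg = count_segregating(seqs, mask)
    zns = None
    if n_seg >= 2:
        cols = []
        for i in mask:
            alleles = sorted({s[i] for s in seqs} - {"N"})
            if len(alleles) != 2:
                continue
            ref = alleles[0]
            cols.append(
                [
                    -1 if s[i] == "N" else (0 if s[i] == ref else 1)
                    for s in seqs
                ]
            )
        if len(cols) >= 2:
            zns = zns_from_matrix(np.array(cols, dtype=int))
    return DiversityResult(
        gene_id=gene_id,
        pi_4fold=pi,
        n_4fold_sites=len(mask),
        n_segregating=n_seg,
        zns=zns,
    )


def stratum_summary(
    per_gene_values: Mapping[str, float | None],
    strata_labels: Mapping[str, str],
) -> dict[str, StratumStat]:
    """Mean and standard error of a per-gene statistic within each stratum."""
    by_stratum: dict[str, list[float]] = {}
    for gene_id, value in per_gene_values.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        label = strata_labels.get(gene_id)
        if label is None:
            continue
        by_stratum.setdefault(label, []).append(float(value))
    out: dict[str, StratumStat] = {}
    for label, vals in by_stratum.items():
        n = len(vals)
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else None
        out[label] = StratumStat(mean=mean, se=se, n=n)
    return out
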