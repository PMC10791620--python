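"""Infer PAR/stratum boundaries from the per-gene evidence table.

Coordinate convention: "distal" means smaller pos_kb (the PAR occupies
the low-coordinate chromosome end); boundaries are reported as the
position of the distal-most gene carrying the relevant evidence class.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from stratamap.formats_io import EvidenceTableRow

logger = logging.getLogger(__name__)

EVIDENCE_CLASSES = ("segr", "lat", "dio")


@dataclass
class StratumBoundaries:
    """Inferred boundary positions, in kb on the X reference."""

    segregation_boundary_kb: float | None
    par_str3_boundary_kb: float | None
    str3_str2_boundary_kb: float | None


@dataclass
class GradientTestResult:
    slope: float  # OLS slope of ks on pos_kb (per kb)
    p_perm: float  # one-sided permutation p-value for slope > 0
    n_genes: int
    n_permutations: int


def infer_boundary(
    rows: Sequence[EvidenceTableRow],
    evidence_class: str,
    min_count: int = 1,
    robust: tuple[int, int] | None = None,
) -> float | None:
    """Position (kb) of the distal-most gene with >= min_count evidence.

    ``evidence_class`` is one of ``segr``/``lat``/``dio``; absent counts
    are treated as zero.  With ``robust=(k, m)`` the qualifying gene must
    additionally be confirmed by at least k of the next m proximal genes
    also qualifying.  Returns None (with a log message) when no gene
    qualifies.
    """
    if evidence_class not in EVIDENCE_CLASSES:
        raise ValueError(f"unknown evidence class {evidence_class!r}")
    ordered = sorted(rows, key=lambda r: r.pos_kb)
    qualifies = [r.count(evidence_class) >= min_count for r in ordered]
    for i, (row, ok) in enumerate(zip(ordered, qualifies)):
        if not ok:
            continue
        if robust is not None:
            k, m = robust
            if sum(qualifies[i + 1 : i + 1 + m]) < k:
                continue
        return row.pos_kb
    logger.info("infer_boundary(%s): no qualifying gene", evidence_class)
    return None


def infer_all_boundaries(
    rows: Sequence[EvidenceTableRow],
    min_count: int = 1,
    robust: tuple[int, int] | None = None,
) -> StratumBoundaries:
    """All three boundaries; warns when the expected ordering is violated."""
    seg = infer_boundary(rows, "segr", min_count, robust)
    par = infer_boundary(rows, "lat", min_count, robust)
    s32 = infer_boundary(rows, "dio", min_count, robust)
    present = [b for b in (seg, par, s32) if b is not None]
    if present != sorted(present):
        warnings.warn(
            f"boundary ordering violated: segr={seg}, lat={par}, dio={s32}",
            stacklevel=2,
        )
    return StratumBoundaries(seg, par, s32)


def classify_strata(
    rows: Sequence[EvidenceTableRow], boundaries: StratumBoundaries
) -> dict[str, str]:
    """Assign each gene exactly one stratum label from the boundaries.

    PAR below the PAR/Str3 boundary, Str3 up to the Str3/Str2 boundary,
    Str2 beyond; ``unknown`` when the needed boundaries are absent.
    """
    par_b = boundaries.par_str3_boundary_kb
    s32_b = boundaries.str3_str2_boundary_kb
    labels: dict[str, str] = {}
    for r in rows:
        if par_b is None:
            labels[r.gene_id] = "unknown"
        elif r.pos_kb < par_b:
            labels[r.gene_id] = "PAR"
        elif s32_b is None:
            labels[r.gene_id] = "unknown"
        elif r.pos_kb < s32_b:
            labels[r.gene_id] = "Str3"
        else:
            labels[r.gene_id] = "Str2"
    return labels


def classification_mismatches(
    rows: Sequence[EvidenceTableRow], labels: dict[str, str]
) -> list[tuple[str, str, str]]:
    """(gene_id, table label, inferred label) where the two disagree."""
    out = []
    for r in rows:
        if r.stratum_label != "unknown" and labels.get(r.gene_id) not in (
            None,
            r.stratum_label,
        ):
            out.append((r.gene_id, r.stratum_label, labels[r.gene_id]))
    return out


def stratum_length_mb(boundaries: StratumBoundaries) -> int | None:
    """Stratum-3 length in whole Mb (positions truncated to integer Mb).

    Whole-Mb truncation of each boundary before subtracting mirrors the
    headline rounding convention; exact kb positions remain available on
    the boundaries object.
    """
    lo = boundaries.par_str3_boundary_kb
    hi = boundaries.str3_str2_boundary_kb
    if lo is None or hi is None:
        return None
    return math.floor(hi / 1000.0) - math.floor(lo / 1000.0)


def gradient_test(
    rows: Sequence[EvidenceTableRow],
    stratum: str,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> GradientTestResult | None:
    """One-sided permutation test for ks increasing with position.

    Uses the genes of ``stratum`` with a defined ks; the observed OLS
    slope of ks on pos_kb is compared against slopes with ks shuffled
    across positions.  p = (1 + #{permuted >= observed}) / (1 + n_perm).
    Returns None when fewer than 3 genes are available.
    """
    pts = [
        (r.pos_kb, r.ks)
        for r in rows
        if r.stratum_label == stratum and r.ks is not None and not math.isnan(r.ks)
    ]
    if len(pts) < 3:
        logger.info("gradient_test(%s): only %d genes with ks", stratum, len(pts))
        return None
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    xc = x - x.mean()

    def _slope(vals: np.ndarray) -> float:
        return float(xc @ (vals - vals.mean()) / (xc @ xc))

    observed = _slope(y)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        if _slope(rng.permutation(y)) >= observed:
            n_ge += 1
    return GradientTestResult(
        slope=observed,
        p_perm=(1 + n_ge) / (1 + n_permutations),
        n_genes=len(pts),
        n_permutations=n_permutations,
    )
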