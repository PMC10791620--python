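"""Classify SNPs as Y-linked from two evidence classes.

Segregation evidence: sites heterozygous in the father and homozygous
reference in the mother that are transmitted to sons and never to
daughters.  Population evidence: sites whose alt allele is carried by
nearly all wild males and by no wild female of the same species.

All filters operate on :class:`~stratamap.formats_io.VariantSite` lists
and preserve input order.  "Carries the alt allele" means the genotype
is het or hom_alt: sons are hemizygous for Y alleles but RNA-based calls
appear heterozygous because X reads map to the same CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from stratamap.formats_io import EvidenceTableRow, GeneModel, Sample, VariantSite

logger = logging.getLogger(__name__)

DEFAULT_MIN_QUAL = 500.0
DEFAULT_MAX_MISSING = 10
DEFAULT_MIN_SONS_WITH_ALT = 10
DEFAULT_MIN_WILD_MALES = 6


@dataclass(frozen=True)
class Pedigree:
    father: str
    mother: str
    sons: tuple[str, ...]
    daughters: tuple[str, ...]

    @classmethod
    def from_samples(cls, samples: Iterable[Sample]) -> "Pedigree":
        father = mother = None
        sons: list[str] = []
        daughters: list[str] = []
        for s in samples:
            if s.role == "father":
                father = s.sample_id
            elif s.role == "mother":
                mother = s.sample_id
            elif s.role == "son":
                sons.append(s.sample_id)
            elif s.role == "daughter":
                daughters.append(s.sample_id)
        if father is None or mother is None:
            raise ValueError("pedigree requires a father and a mother")
        return cls(father, mother, tuple(sons), tuple(daughters))


@dataclass
class YsnpEvidence:
    """Per-site record of which Y-linkage criteria the site satisfies."""

    site: VariantSite
    passes_segregation: bool | None = None
    passes_population: dict[str, bool] = field(default_factory=dict)
    #: (sons carrying alt, daughters carrying alt, progeny with missing data)
    n_informative_progeny: tuple[int, int, int] | None = None


def quality_filter(
    sites: Sequence[VariantSite], min_qual: float = DEFAULT_MIN_QUAL
) -> list[VariantSite]:
    """Keep sites with quality strictly greater than ``min_qual``."""
    kept = [s for s in sites if s.quality > min_qual]
    logger.info("quality_filter: %d/%d sites retained (> %g)", len(kept), len(sites), min_qual)
    return kept


def candidate_parental_sites(
    sites: Sequence[VariantSite], father_id: str, mother_id: str
) -> list[VariantSite]:
    """Sites heterozygous in the father and hom-ref in the mother.

    Missing data in either parent excludes the site; unknown parent ids
    are an error.
    """
    kept = []
    for s in sites:
        if father_id not in s.genotypes or mother_id not in s.genotypes:
            raise ValueError(
                f"sample id {father_id!r}/{mother_id!r} not present at "
                f"{s.gene_id}:{s.cds_pos}"
            )
        if s.genotypes[father_id] == "het" and s.genotypes[mother_id] == "hom_ref":
            kept.append(s)
    logger.info("candidate_parental_sites: %d/%d sites retained", len(kept), len(sites))
    return kept


def segregation_filter(
    sites: Sequence[VariantSite],
    pedigree: Pedigree,
    max_missing: int = DEFAULT_MAX_MISSING,
    min_males_with_alt: int = DEFAULT_MIN_SONS_WITH_ALT,
) -> list[YsnpEvidence]:
    """Score candidate parental sites for father-to-son-only segregation.

    A site passes iff the number of progeny with missing genotypes is
    strictly below ``max_missing``, no daughter carries the alt allele,
    and at least ``min_males_with_alt`` sons carry it.
    """
    if not pedigree.sons:
        raise ValueError("pedigree has no sons; segregation filter unsatisfiable")
    out: list[YsnpEvidence] = []
    n_pass = 0
    for s in sites:
        sons_alt = sum(s.carries_alt(x) for x in pedigree.sons)
        daughters_alt = sum(s.carries_alt(x) for x in pedigree.daughters)
        missing = sum(
            s.is_missing(x) for x in (*pedigree.sons, *pedigree.daughters)
        )
        ok = (
            missing < max_missing
            and daughters_alt == 0
            and sons_alt >= min_males_with_alt
        )
        n_pass += ok
        out.append(
            YsnpEvidence(
                site=s,
                passes_segregation=ok,
                n_informative_progeny=(sons_alt, daughters_alt, missing),
            )
        )
    logger.info("segregation_filter: %d/%d sites pass", n_pass, len(sites))
    return out


def population_filter(
    sites: Sequence[VariantSite],
    samples: Sequence[Sample],
    species: str,
    min_males: int = DEFAULT_MIN_WILD_MALES,
) -> list[YsnpEvidence]:
    """Score sites for male-specificity in one species' wild cohort.

    A site passes iff at least ``min_males`` wild males carry the alt
    allele and no wild female does.
    """
    males = [s.sample_id for s in samples if s.role == "wild" and s.species == species and s.sex == "M"]
    females = [s.sample_id for s in samples if s.role == "wild" and s.species == species and s.sex == "F"]
    if len(males) < min_males:
        raise ValueError(
            f"only {len(males)} wild {species} males available; "
            f"criterion (>= {min_males}) unsatisfiable"
        )
    out: list[YsnpEvidence] = []
    n_pass = 0
    for s in sites:
        males_alt = sum(s.carries_alt(x) for x in males)
        females_alt = sum(s.carries_alt(x) for x in females)
        ok = males_alt >= min_males and females_alt == 0
        n_pass += ok
        ev = YsnpEvidence(site=s, n_informative_progeny=(males_alt, females_alt, 0))
        ev.passes_population[species] = ok
        out.append(ev)
    logger.info(
        "population_filter(%s): %d/%d sites pass", species, n_pass, len(sites)
    )
    return out


def per_gene_ysnp_counts(
    segregation_evidence: Sequence[YsnpEvidence] = (),
    population_evidence: Mapping[str, Sequence[YsnpEvidence]] | None = None,
    genes: Sequence[GeneModel] | Sequence[str] = (),
) -> dict[str, dict[str, int | None]]:
    """Per-gene counts of passing sites for each evidence class.

    ``population_evidence`` maps species name to its evidence list.  Genes
    with at least one scored site in a class get an integer count (zero
    included); genes with no scored sites at all get ``None`` for every
    class.  Returns gene_id -> {n_segr, n_lat, n_dio}.
    """
    population_evidence = population_evidence or {}
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else g for g in genes]
    counts: dict[str, dict[str, int | None]] = {
        gid: {"n_segr": None, "n_lat": None, "n_dio": None} for gid in gene_ids
    }
    class_of = {"latifolia": "n_lat", "dioica": "n_dio"}

    def _tally(evidence: Sequence[YsnpEvidence], key: str, passed) -> None:
        for ev in evidence:
            gid = ev.site.gene_id
            if gid not in counts:
                counts[gid] = {"n_segr": None, "n_lat": None, "n_dio": None}
            if counts[gid][key] is None:
                counts[gid][key] = 0
            if passed(ev):
                counts[gid][key] += 1  # type: ignore[operator]

    _tally(segregation_evidence, "n_segr", lambda ev: bool(ev.passes_segregation))
    for species, evidence in population_evidence.items():
        key = class_of[species]
        _tally(evidence, key, lambda ev: ev.passes_population.get(species, False))
    return counts


def evidence_rows_from_counts(
    counts: Mapping[str, Mapping[str, int | None]],
    genes: Sequence[GeneModel],
) -> list[EvidenceTableRow]:
    """Assemble evidence-table rows (stratum label left ``unknown``)."""
    rows = []
    for g in genes:
        c = counts.get(g.gene_id, {})
        rows.append(
            EvidenceTableRow(
                gene_id=g.gene_id,
                pos_kb=g.pos_kb,
                stratum_label="unknown",
                n_segr=c.get("n_segr"),
                n_lat=c.get("n_lat"),
                n_dio=c.get("n_dio"),
                map_f_cM=g.map_pos_female_cM,
                map_m_cM=g.map_pos_male_cM,
            )
        )
    rows.sort(key=lambda r: r.pos_kb)
    return rows
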