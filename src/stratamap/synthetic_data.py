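"""Synthetic datasets with the statistical structure the pipeline assumes.

Per gene the simulator produces an X-haplotype pool from a standard
neutral coalescent (no intragenic recombination), derives a Y haplotype
by adding synonymous-biased substitutions whose expected number per
synonymous site equals the stratum's divergence parameter ``d``, and
transmits haplotypes through a genetic cross (father, mother, sons,
daughters) and to wild diploid samples of two species.  In the PAR the
Y slot is simply one more draw from the X pool (d = 0) and transmission
may recombine; in the non-recombining strata sons always inherit the
father's Y.  Reads with sequencing error and a naive genotype caller
close the loop so every downstream stage is testable without downloads.

Species structure: the region corresponding to stratum 3 is sex-linked
in *latifolia* only; in *dioica* it behaves pseudoautosomally and only
the stratum-2 region is sex-linked.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from stratamap._codons import BASES, STOP_CODONS, syn_alternatives, syn_fractions
from stratamap.formats_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AlignedRead,
    GeneModel,
    Sample,
    VariantSite,
    write_fasta,
    write_gene_table,
    write_sam_reads,
    write_sample_table,
    write_vcf,
)

logger = logging.getLogger(__name__)

LATIFOLIA = "latifolia"
DIOICA = "dioica"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All knobs of the simulator; every probability is per meiosis/gene."""

    seed: int = 0
    n_genes: int = 30
    chrom_span_kb: tuple[float, float] = (20000.0, 46000.0)
    #: (segregation detection limit, PAR/Str3 boundary, Str3/Str2 boundary)
    boundaries_kb: tuple[float, float, float] = (24800.0, 27000.0, 41500.0)
    theta_per_site: float = 0.02
    #: stratum -> constant d, or (d at distal end, d at proximal end) for a
    #: linear gradient across the stratum (expected substitutions per
    #: synonymous site on the Y branch)
    divergence_profile: dict = field(
        default_factory=lambda: {"PAR": 0.0, "Str3": (0.01, 0.08), "Str2": 0.10}
    )
    #: probability that a transmitted PAR allele recombines off the parent's
    #: sex-chromosome background, for PAR genes proximal to the segregation
    #: detection limit (rare recombination near the boundary); PAR genes
    #: distal to the limit recombine freely (probability 0.5)
    par_recomb_prob: float = 0.02
    cds_len: int = 600
    n_sons: int = 21
    n_daughters: int = 32
    n_wild_males: int = 7
    n_wild_females: int = 7
    depth: float = 30.0
    read_len: int = 80
    err: float = 0.0
    frac_silent_genes: float = 0.0

    def __post_init__(self) -> None:
        for name in ("par_recomb_prob", "err", "frac_silent_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        b = self.boundaries_kb
        if not (b[0] <= b[1] <= b[2]):
            raise ValueError("boundaries_kb must be ascending")
        if self.cds_len % 3 != 0 or self.cds_len <= 0:
            raise ValueError("cds_len must be a positive multiple of 3")
        if self.theta_per_site < 0:
            raise ValueError("theta_per_site must be >= 0")
        for stratum, d in self.divergence_profile.items():
            vals = d if isinstance(d, (tuple, list)) else (d,)
            if any(v < 0 for v in vals):
                raise ValueError(f"divergence for {stratum} must be >= 0")

    @property
    def n_pool(self) -> int:
        """X haplotypes needed per species pool (cross founders + wild)."""
        return 3 + 2 * (self.n_wild_males + self.n_wild_females)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("chrom_span_kb", "boundaries_kb"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "divergence_profile" in raw:
            raw["divergence_profile"] = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["divergence_profile"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class GeneTruth:
    """Ground truth for one gene: pools, Y haplotypes and individual genomes."""

    gene: GeneModel
    stratum: str  # latifolia stratum: PAR / Str3 / Str2
    recomb_prob: float  # per-meiosis PAR swap probability (0 in NRY)
    x_pool: list[str]
    y_hap: str
    fixed_diffs: list[int]  # 0-based sites: X pool monomorphic, Y differs
    dio_x_pool: list[str]
    dio_y_hap: str
    dio_fixed_diffs: list[int]
    #: sample_id -> (haplotype A, haplotype B); for males of sex-linked
    #: genes haplotype B is the Y
    haplotypes: dict[str, tuple[str, str]]


@dataclass
class TruthBundle:
    config: SimConfig
    genes: list[GeneTruth]
    samples: list[Sample]

    def samples_by_role(self, *roles: str, species: str | None = None) -> list[Sample]:
        return [
            s
            for s in self.samples
            if s.role in roles and (species is None or s.species == species)
        ]


# ---------------------------------------------------------------------------
# coalescent
# ---------------------------------------------------------------------------


def _coalescent_branches(
    n: int, rng: np.random.Generator
) -> list[tuple[frozenset[int], float]]:
    """Branches of a standard coalescent tree as (leaf set, length) pairs.

    Times are in units of 2N generations; coalescence rate k(k-1)/2.
    """
    active: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    t = 0.0
    branches: list[tuple[frozenset[int], float]] = []
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False).tolist())
        (leaves_j, birth_j) = active.pop(j)
        (leaves_i, birth_i) = active.pop(i)
        branches.append((leaves_i, t - birth_i))
        branches.append((leaves_j, t - birth_j))
        active.append((leaves_i | leaves_j, t))
    return branches


def simulate_x_haplotypes(
    n: int,
    L: int,
    theta_per_site: float,
    rng: np.random.Generator,
    ancestral: str | None = None,
) -> list[str]:
    """Sample ``n`` haplotypes of length ``L`` under the neutral coalescent.

    Mutations fall on branches at rate ``theta_per_site * L / 2`` per unit
    of coalescent time and are placed on distinct positions (infinite
    sites), each changing the ancestral base to a random different base.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    if ancestral is None:
        ancestral = "".join(rng.choice(list(BASES), size=L))
    elif len(ancestral) != L:
        raise ValueError("ancestral length != L")
    branches = _coalescent_branches(n, rng)
    lengths = np.array([b[1] for b in branches])
    total = float(lengths.sum())
    n_mut = int(rng.poisson(theta_per_site * L / 2.0 * total))
    if n_mut > L:
        raise RuntimeError(
            f"{n_mut} mutations for {L} sites: theta too high for infinite sites"
        )
    haps = [list(ancestral) for _ in range(n)]
    if n_mut:
        sites = rng.choice(L, size=n_mut, replace=False)
        probs = lengths / total
        branch_idx = rng.choice(len(branches), size=n_mut, p=probs)
        for site, bi in zip(sites.tolist(), branch_idx.tolist()):
            anc = ancestral[site]
            derived = BASES[int(rng.integers(4))]
            while derived == anc:
                derived = BASES[int(rng.integers(4))]
            for leaf in branches[bi][0]:
                haps[leaf][site] = derived
    return ["".join(h) for h in haps]


# ---------------------------------------------------------------------------
# gametologs
# ---------------------------------------------------------------------------


def resolve_divergence(pos_kb: float, stratum: str, config: SimConfig) -> float:
    """Stratum divergence d at a position; Str3 interpolates linearly."""
    d = config.divergence_profile.get(stratum, 0.0)
    if isinstance(d, (tuple, list)):
        lo, hi = config.boundaries_kb[1], config.boundaries_kb[2]
        if hi <= lo:
            return float(d[0])
        frac = min(max((pos_kb - lo) / (hi - lo), 0.0), 1.0)
        return float(d[0] + (d[1] - d[0]) * frac)
    return float(d)


def _add_synonymous_substitutions(
    seq: str, d: float, rng: np.random.Generator
) -> str:
    """Add Poisson(d * synonymous sites) synonymous substitutions.

    Sites are drawn with probability proportional to their Nei-Gojobori
    synonymous fraction, so realized synonymous divergence per synonymous
    site is approximately d.  Codon context is updated after each change.
    """
    hap = list(seq)
    n_codons = len(seq) // 3
    weights = np.zeros(len(seq))
    for c in range(n_codons):
        codon = seq[3 * c : 3 * c + 3]
        f = syn_fractions(codon)
        weights[3 * c : 3 * c + 3] = f
    total = float(weights.sum())
    if total == 0:
        return seq
    n_sub = int(rng.poisson(d * total))
    for _ in range(n_sub):
        w = weights.sum()
        if w == 0:
            break
        site = int(rng.choice(len(hap), p=weights / w))
        c = site // 3
        codon = "".join(hap[3 * c : 3 * c + 3])
        alts = syn_alternatives(codon, site % 3)
        if not alts:  # weights stale only if codon drifted; rebuild and retry
            weights[site] = 0.0
            continue
        hap[site] = alts[int(rng.integers(len(alts)))]
        new_codon = "".join(hap[3 * c : 3 * c + 3])
        f = syn_fractions(new_codon)
        weights[3 * c : 3 * c + 3] = f
    return "".join(hap)


def _fixed_differences(x_pool: Sequence[str], y_hap: str) -> list[int]:
    """Sites where the X pool is monomorphic and the Y base differs."""
    out = []
    for i, y_base in enumerate(y_hap):
        col = {h[i] for h in x_pool}
        if len(col) == 1 and y_base not in col:
            out.append(i)
    return out


def simulate_gametologs(
    gene: GeneModel,
    stratum: str,
    config: SimConfig,
    rng: np.random.Generator,
    n_pool: int | None = None,
) -> tuple[list[str], str, list[int]]:
    """X pool and Y haplotype for one gene.

    The Y starts as one extra coalescent draw; outside the PAR it then
    accumulates synonymous-biased substitutions at the stratum's rate d.
    Returns (x_pool, y_hap, fixed_difference_sites).
    """
    if n_pool is None:
        n_pool = config.n_pool
    pool = simulate_x_haplotypes(
        n_pool + 1, gene.length, config.theta_per_site, rng, ancestral=gene.cds
    )
    x_pool, y_src = pool[:-1], pool[-1]
    d = resolve_divergence(gene.pos_kb, stratum, config)
    if d > 0:
        y_hap = _add_synonymous_substitutions(y_src, d, rng)
        fixed = _fixed_differences(x_pool, y_hap)
    else:
        # PAR (or zero-divergence stratum): the Y slot is just another X
        # draw; its private alleles are segregating X variation, not
        # fixed X-Y differences
        y_hap, fixed = y_src, []
    return x_pool, y_hap, fixed


# ---------------------------------------------------------------------------
# samples and transmission
# ---------------------------------------------------------------------------


def make_samples(config: SimConfig) -> list[Sample]:
    samples = [
        Sample("father", LATIFOLIA, "M", "father"),
        Sample("mother", LATIFOLIA, "F", "mother"),
    ]
    samples += [
        Sample(f"son{i:02d}", LATIFOLIA, "M", "son") for i in range(1, config.n_sons + 1)
    ]
    samples += [
        Sample(f"dau{i:02d}", LATIFOLIA, "F", "daughter")
        for i in range(1, config.n_daughters + 1)
    ]
    for species, tag in ((LATIFOLIA, "lat"), (DIOICA, "dio")):
        samples += [
            Sample(f"{tag}_m{i}", species, "M", "wild")
            for i in range(1, config.n_wild_males + 1)
        ]
        samples += [
            Sample(f"{tag}_f{i}", species, "F", "wild")
            for i in range(1, config.n_wild_females + 1)
        ]
    return samples


def simulate_cross(
    x_f: str,
    y_slot: str,
    mother_haps: tuple[str, str],
    recomb_prob: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[str, str]]:
    """Transmit one gene through the cross.

    Sons receive the father's Y-slot haplotype, daughters his X; with
    probability ``recomb_prob`` the transmitted PAR allele swaps to the
    other paternal haplotype (for both sexes — the PAR recombines in every
    male meiosis).  The maternal haplotype is drawn per offspring.
    """
    out: dict[str, tuple[str, str]] = {
        "father": (x_f, y_slot),
        "mother": mother_haps,
    }
    for i in range(1, config.n_sons + 1):
        pat = y_slot if rng.random() >= recomb_prob else x_f
        mat = mother_haps[int(rng.integers(2))]
        out[f"son{i:02d}"] = (mat, pat)
    for i in range(1, config.n_daughters + 1):
        pat = x_f if rng.random() >= recomb_prob else y_slot
        mat = mother_haps[int(rng.integers(2))]
        out[f"dau{i:02d}"] = (mat, pat)
    return out


def _assign_wild(
    pool: list[str],
    y_hap: str,
    sex_linked: bool,
    tag: str,
    config: SimConfig,
) -> dict[str, tuple[str, str]]:
    """Deal pool haplotypes to wild individuals of one species.

    Wild males of a sex-linked gene all carry the species Y haplotype
    (negligible Y diversity); otherwise both of their haplotypes are pool
    draws.  Pool layout: [0:3] cross founders, then two per wild male,
    then two per wild female.
    """
    out: dict[str, tuple[str, str]] = {}
    base = 3
    for i in range(config.n_wild_males):
        a, b = pool[base + 2 * i], pool[base + 2 * i + 1]
        out[f"{tag}_m{i + 1}"] = (a, y_hap) if sex_linked else (a, b)
    base += 2 * config.n_wild_males
    for i in range(config.n_wild_females):
        out[f"{tag}_f{i + 1}"] = (pool[base + 2 * i], pool[base + 2 * i + 1])
    return out


# ---------------------------------------------------------------------------
# full truth
# ---------------------------------------------------------------------------


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """Random in-frame CDS without stop codons."""
    codons = []
    non_stop = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in STOP_CODONS
    ]
    for _ in range(length // 3):
        codons.append(non_stop[int(rng.integers(len(non_stop)))])
    return "".join(codons)


def stratum_of(pos_kb: float, config: SimConfig) -> str:
    _, par_str3, str3_str2 = config.boundaries_kb
    if pos_kb < par_str3:
        return "PAR"
    if pos_kb < str3_str2:
        return "Str3"
    return "Str2"


def build_truth(config: SimConfig, rng: np.random.Generator | None = None) -> TruthBundle:
    """Simulate ground truth for every gene and individual."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.chrom_span_kb
    positions = np.sort(rng.uniform(lo, hi, size=config.n_genes))
    samples = make_samples(config)
    genes: list[GeneTruth] = []
    seg_limit = config.boundaries_kb[0]
    for idx, pos in enumerate(positions, 1):
        silent = rng.random() < config.frac_silent_genes
        gene = GeneModel(
            gene_id=f"g{idx:04d}",
            pos_kb=float(round(pos, 3)),
            cds=_random_cds(config.cds_len, rng),
            fpkm=0.5 if silent else 10.0,
        )
        stratum = stratum_of(gene.pos_kb, config)
        if stratum == "PAR":
            recomb = 0.5 if gene.pos_kb < seg_limit else config.par_recomb_prob
        else:
            recomb = 0.0
        x_pool, y_hap, fixed = simulate_gametologs(gene, stratum, config, rng)
        dio_stratum = "Str2" if stratum == "Str2" else "PAR"
        dio_pool, dio_y, dio_fixed = simulate_gametologs(gene, dio_stratum, config, rng)
        haps = simulate_cross(
            x_pool[0], y_hap, (x_pool[1], x_pool[2]), recomb, config, rng
        )
        haps.update(_assign_wild(x_pool, y_hap, stratum != "PAR", "lat", config))
        haps.update(
            _assign_wild(dio_pool, dio_y, dio_stratum != "PAR", "dio", config)
        )
        genes.append(
            GeneTruth(
                gene=gene,
                stratum=stratum,
                recomb_prob=recomb,
                x_pool=x_pool,
                y_hap=y_hap,
                fixed_diffs=fixed,
                dio_x_pool=dio_pool,
                dio_y_hap=dio_y,
                dio_fixed_diffs=dio_fixed,
                haplotypes=haps,
            )
        )
    return TruthBundle(config=config, genes=genes, samples=samples)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def emit_reads(
    sample_id: str,
    haps: tuple[str, str],
    gene: GeneModel,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[AlignedRead]:
    """Sequencing reads for one individual at one gene.

    Reads are drawn from the two haplotypes with equal probability, start
    positions are uniform and each base flips to a random different base
    with probability ``err``.  Silent genes (fpkm < 1) yield no reads.
    """
    if gene.is_silent:
        return []
    L = gene.length
    read_len = config.read_len
    if read_len > L:
        logger.info(
            "emit_reads: read_len %d > CDS %d for %s; emitting full-length reads",
            read_len,
            L,
            gene.gene_id,
        )
        read_len = L
        n_reads = int(rng.poisson(config.depth))
    else:
        n_reads = int(rng.poisson(config.depth * L / read_len))
    reads: list[AlignedRead] = []
    for k in range(n_reads):
        hap = haps[int(rng.integers(2))]
        start = int(rng.integers(1, L - read_len + 2))
        seq = list(hap[start - 1 : start - 1 + read_len])
        if config.err > 0:
            for i in range(read_len):
                if rng.random() < config.err:
                    b = BASES[int(rng.integers(4))]
                    while b == seq[i]:
                        b = BASES[int(rng.integers(4))]
                    seq[i] = b
        reads.append(
            AlignedRead(
                read_id=f"{gene.gene_id}:{sample_id}:{k}",
                sample_id=sample_id,
                gene_id=gene.gene_id,
                start=start,
                seq="".join(seq),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# naive genotype caller
# ---------------------------------------------------------------------------


def naive_genotype_caller(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    gene: GeneModel,
    min_depth: int = 5,
) -> list[VariantSite]:
    """Call biallelic SNPs from per-sample pileups.

    A site is emitted when at least one sample shows a non-reference
    allele in >= 2 reads making up >= 20% of its coverage.  Genotypes per
    sample: alt fraction < 20% hom_ref, 20-80% het, > 80% hom_alt;
    coverage below ``min_depth`` is missing.  Quality is 50 per
    alt-supporting read, capped at 3000.
    """
    L = gene.length
    # counts[sample][site][base]
    counts: dict[str, np.ndarray] = {}
    base_idx = {b: i for i, b in enumerate(BASES)}
    for sid, reads in reads_by_sample.items():
        arr = np.zeros((L, 4), dtype=int)
        for r in reads:
            for offset, b in enumerate(r.seq):
                if b == "N":
                    continue
                arr[r.start - 1 + offset, base_idx[b]] += 1
        counts[sid] = arr
    sites: list[VariantSite] = []
    sample_ids = list(reads_by_sample)
    for pos0 in range(L):
        ref = gene.cds[pos0]
        ref_i = base_idx[ref]
        pooled = np.zeros(4, dtype=int)
        for sid in sample_ids:
            pooled += counts[sid][pos0]
        nonref = [(pooled[i], i) for i in range(4) if i != ref_i]
        alt_count, alt_i = max(nonref)
        if alt_count == 0:
            continue
        alt = BASES[alt_i]
        emit = False
        for sid in sample_ids:
            cov = int(counts[sid][pos0].sum())
            ac = int(counts[sid][pos0][alt_i])
            if ac >= 2 and cov > 0 and ac >= 0.2 * cov:
                emit = True
                break
        if not emit:
            continue
        genotypes: dict[str, str] = {}
        total_alt = 0
        for sid in sample_ids:
            cov = int(counts[sid][pos0].sum())
            ac = int(counts[sid][pos0][alt_i])
            total_alt += ac
            if cov < min_depth:
                genotypes[sid] = MISSING
            else:
                frac = ac / cov
                if frac < 0.2:
                    genotypes[sid] = HOM_REF
                elif frac <= 0.8:
                    genotypes[sid] = HET
                else:
                    genotypes[sid] = HOM_ALT
        sites.append(
            VariantSite(
                gene_id=gene.gene_id,
                cds_pos=pos0 + 1,
                ref=ref,
                alt=alt,
                quality=min(3000.0, 50.0 * total_alt),
                genotypes=genotypes,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# exact genotypes from truth (error-free route)
# ---------------------------------------------------------------------------


def variant_sites_from_truth(
    gene_truth: GeneTruth,
    sample_ids: Sequence[str],
    quality: float = 1000.0,
) -> list[VariantSite]:
    """Exact biallelic VariantSites from true haplotypes (no error, no missingness).

    Multi-allelic positions are skipped with a logged count, mirroring the
    VCF reader contract.
    """
    gene = gene_truth.gene
    sites: list[VariantSite] = []
    n_multi = 0
    haps = {sid: gene_truth.haplotypes[sid] for sid in sample_ids}
    for pos0 in range(gene.length):
        ref = gene.cds[pos0]
        alleles = {h[pos0] for pair in haps.values() for h in pair}
        non_ref = alleles - {ref}
        if not non_ref:
            continue
        if len(non_ref) > 1:
            n_multi += 1
            continue
        alt = next(iter(non_ref))
        genotypes = {}
        for sid, (a, b) in haps.items():
            n_alt = (a[pos0] == alt) + (b[pos0] == alt)
            genotypes[sid] = (HOM_REF, HET, HOM_ALT)[n_alt]
        sites.append(
            VariantSite(
                gene_id=gene.gene_id,
                cds_pos=pos0 + 1,
                ref=ref,
                alt=alt,
                quality=quality,
                genotypes=genotypes,
            )
        )
    if n_multi:
        logger.info(
            "variant_sites_from_truth(%s): skipped %d multi-allelic sites",
            gene.gene_id,
            n_multi,
        )
    return sites


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------


def _truth_to_json(truth: TruthBundle) -> dict:
    return {
        "genes": [
            {
                "gene_id": gt.gene.gene_id,
                "pos_kb": gt.gene.pos_kb,
                "fpkm": gt.gene.fpkm,
                "stratum": gt.stratum,
                "recomb_prob": gt.recomb_prob,
                "y_hap": gt.y_hap,
                "dio_y_hap": gt.dio_y_hap,
                "fixed_diffs": gt.fixed_diffs,
                "dio_fixed_diffs": gt.dio_fixed_diffs,
                "haplotypes": {k: list(v) for k, v in gt.haplotypes.items()},
            }
            for gt in truth.genes
        ]
    }


def generate_dataset(
    config: SimConfig, outdir: str | Path, force: bool = False
) -> dict[str, str]:
    """Write a complete synthetic dataset; returns the manifest mapping.

    Outputs (all plain text): CDS FASTA, gene table, sample table, one VCF
    per cohort (cross, wild latifolia, wild dioica; exact genotypes from
    truth), SAM-dialect reads for all male cross individuals, per-gene
    wild-female alignment FASTAs, the truth bundle as JSON, a config echo
    and a manifest TSV.  Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = build_truth(config, rng)

    manifest: dict[str, str] = {}

    def _reg(key: str, name: str) -> Path:
        manifest[key] = name
        return outdir / name

    write_fasta(
        [(gt.gene.gene_id, gt.gene.cds) for gt in truth.genes],
        _reg("cds_fasta", "genes.fasta"),
    )
    write_gene_table([gt.gene for gt in truth.genes], _reg("gene_table", "genes.tsv"))
    write_sample_table(truth.samples, _reg("sample_table", "samples.tsv"))

    cross_ids = [
        s.sample_id
        for s in truth.samples_by_role("father", "mother", "son", "daughter")
    ]
    lat_ids = [s.sample_id for s in truth.samples_by_role("wild", species=LATIFOLIA)]
    dio_ids = [s.sample_id for s in truth.samples_by_role("wild", species=DIOICA)]
    for key, name, ids in (
        ("cross_vcf", "cross.vcf", cross_ids),
        ("wild_latifolia_vcf", "wild_latifolia.vcf", lat_ids),
        ("wild_dioica_vcf", "wild_dioica.vcf", dio_ids),
    ):
        sites: list[VariantSite] = []
        for gt in truth.genes:
            sites.extend(variant_sites_from_truth(gt, ids))
        write_vcf(sites, ids, _reg(key, name))

    male_ids = [s.sample_id for s in truth.samples if s.sex == "M" and s.species == LATIFOLIA and s.role != "wild"]
    reads: list[AlignedRead] = []
    for gt in truth.genes:
        for sid in male_ids:
            reads.extend(emit_reads(sid, gt.haplotypes[sid], gt.gene, config, rng))
    write_sam_reads(reads, _reg("male_reads", "reads_males.sam"))

    lat_female_ids = [
        s.sample_id for s in truth.samples_by_role("wild", species=LATIFOLIA) if s.sex == "F"
    ]
    for gt in truth.genes:
        recs = []
        for sid in lat_female_ids:
            a, b = gt.haplotypes[sid]
            recs.append((f"{sid}_hapA", a))
            recs.append((f"{sid}_hapB", b))
        write_fasta(recs, outdir / "alignments" / f"{gt.gene.gene_id}.fasta")
    manifest["alignments_dir"] = "alignments"

    with open(_reg("truth", "truth.json"), "w") as fh:
        json.dump(_truth_to_json(truth), fh)
    config.to_yaml(_reg("config", "config.yaml"))

    manifest["n_genes"] = str(config.n_genes)
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in sorted(manifest.items()):
            fh.write(f"{k}\t{v}\n")
    manifest["manifest"] = "manifest.tsv"
    return manifest
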