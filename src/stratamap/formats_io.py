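"""Readers and writers for every external format the pipeline touches.

All formats are deliberately small text dialects:

* FASTA, wrapped at a fixed column width;
* a VCF 4.2 subset (CHROM holds the gene id, POS is a 1-based CDS
  coordinate, single ALT, ``GT`` per sample);
* a SAM-like tab-separated read dialect restricted to ungapped,
  all-match alignments (CIGAR ``<len>M``);
* TSV tables for gene models and the per-gene evidence table.

Genotypes are represented with the string constants ``HOM_REF``,
``HET``, ``HOM_ALT`` and ``MISSING``.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

FASTA_WIDTH = 60

DNA = set("ACGT")
DNA_N = set("ACGTN")

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = (HOM_REF, HET, HOM_ALT, MISSING)

STRATUM_LABELS = ("PAR", "Str3", "Str2", "Str1", "unknown")


class FormatError(ValueError):
    """Malformed input in one of the supported text dialects."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene on the X reference: position, CDS and expression level."""

    gene_id: str
    pos_kb: float
    cds: str
    map_pos_female_cM: float | None = None
    map_pos_male_cM: float | None = None
    fpkm: float | None = None

    def __post_init__(self) -> None:
        if not self.cds or len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.cds)} not a positive multiple of 3"
            )
        if set(self.cds) - DNA_N:
            raise ValueError(f"{self.gene_id}: CDS contains non-ACGTN characters")
        if self.pos_kb <= 0:
            raise ValueError(f"{self.gene_id}: pos_kb must be > 0")

    @property
    def length(self) -> int:
        return len(self.cds)

    @property
    def is_silent(self) -> bool:
        """Weakly expressed genes (fpkm < 1) yield no transcriptome reads."""
        return self.fpkm is not None and self.fpkm < 1.0


@dataclass(frozen=True)
class Sample:
    sample_id: str
    species: str
    sex: str
    role: str

    def __post_init__(self) -> None:
        if self.species not in ("latifolia", "dioica"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.role not in ("father", "mother", "son", "daughter", "wild"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in ("father", "son") and self.sex != "M":
            raise ValueError(f"{self.sample_id}: role {self.role} requires sex M")
        if self.role in ("mother", "daughter") and self.sex != "F":
            raise ValueError(f"{self.sample_id}: role {self.role} requires sex F")


@dataclass
class VariantSite:
    """One biallelic SNP in CDS coordinates with per-sample genotypes."""

    gene_id: str
    cds_pos: int  # 1-based position within the CDS
    ref: str
    alt: str
    quality: float
    genotypes: dict[str, str]

    def __post_init__(self) -> None:
        if self.ref not in DNA or self.alt not in DNA or self.ref == self.alt:
            raise ValueError(
                f"{self.gene_id}:{self.cds_pos}: invalid ref/alt {self.ref}/{self.alt}"
            )
        if self.cds_pos < 1:
            raise ValueError(f"{self.gene_id}: cds_pos must be >= 1")
        if self.quality < 0:
            raise ValueError("quality must be non-negative")
        bad = {g for g in self.genotypes.values()} - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype codes {bad}")

    def carries_alt(self, sample_id: str) -> bool:
        """True when the sample's genotype contains >= 1 alt allele."""
        return self.genotypes.get(sample_id, MISSING) in (HET, HOM_ALT)

    def is_missing(self, sample_id: str) -> bool:
        return self.genotypes.get(sample_id, MISSING) == MISSING


@dataclass(frozen=True)
class AlignedRead:
    """An ungapped read aligned to a gene's CDS (1-based start)."""

    read_id: str
    sample_id: str
    gene_id: str
    start: int
    seq: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.read_id}: start must be >= 1")
        if not self.seq or set(self.seq) - DNA_N:
            raise ValueError(f"{self.read_id}: sequence must be non-empty over ACGTN")

    @property
    def end(self) -> int:
        """1-based inclusive end position on the CDS."""
        return self.start + len(self.seq) - 1


@dataclass
class EvidenceTableRow:
    """One record of the per-gene evidence table driving boundary inference."""

    gene_id: str
    pos_kb: float
    stratum_label: str = "unknown"
    n_segr: int | None = None
    n_lat: int | None = None
    n_dio: int | None = None
    ks: float | None = None
    ycds_bp: int | None = None
    ycds_pct: float | None = None
    map_f_cM: float | None = None
    map_m_cM: float | None = None
    uncertain: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.stratum_label not in STRATUM_LABELS:
            raise ValueError(f"unknown stratum label {self.stratum_label!r}")
        for name in ("n_segr", "n_lat", "n_dio", "ycds_bp"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, int) or v < 0):
                raise ValueError(f"{self.gene_id}: {name} must be a non-negative int")
        if self.ycds_bp is not None and self.ycds_bp == 0:
            raise ValueError(f"{self.gene_id}: ycds_bp must be positive when present")
        if self.ks is not None and self.ks < 0:
            raise ValueError(f"{self.gene_id}: ks must be non-negative")
        if self.ycds_pct is not None and not 0 <= self.ycds_pct <= 100:
            raise ValueError(f"{self.gene_id}: ycds_pct must be in [0, 100]")

    def count(self, evidence_class: str) -> int:
        """Evidence count for class ``segr``/``lat``/``dio``; absent -> 0."""
        v = {"segr": self.n_segr, "lat": self.n_lat, "dio": self.n_dio}[evidence_class]
        return 0 if v is None else v


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, sequence)`` pairs, order preserved.

    Sequences must be over ``ACGTN``; violations raise :class:`FormatError`
    naming the offending line.
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence before any FASTA header"
                    )
                if set(line) - DNA_N:
                    raise FormatError(
                        f"{path}: line {lineno}: illegal sequence character"
                    )
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = FASTA_WIDTH
) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

_GT_FROM_VCF = {
    "0/0": HOM_REF,
    "0|0": HOM_REF,
    "0/1": HET,
    "1/0": HET,
    "0|1": HET,
    "1|0": HET,
    "1/1": HOM_ALT,
    "1|1": HOM_ALT,
    "./.": MISSING,
    ".|.": MISSING,
    ".": MISSING,
}

_GT_TO_VCF = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def vcf_header_samples(path: str | Path) -> list[str]:
    """Sample ids from the #CHROM header line of the VCF dialect."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                return line.rstrip("\n").split("\t")[9:]
    raise FormatError(f"{path}: no #CHROM header line")


def read_vcf(path: str | Path, samples: Sequence[str]) -> list[VariantSite]:
    """Read the VCF dialect: CHROM = gene id, POS = CDS position, one ALT.

    Multi-allelic and indel records are skipped (count logged).  A header
    sample line, when present, must match ``samples`` exactly.
    """
    sites: list[VariantSite] = []
    n_skipped = 0
    samples = list(samples)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                header_samples = cols[9:]
                if header_samples != samples:
                    raise FormatError(
                        f"{path}: sample columns {header_samples} do not match "
                        f"expected {samples}"
                    )
                continue
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise FormatError(
                    f"{path}: line {lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(cols)}"
                )
            chrom, pos, _id, ref, alt, qual = cols[0], cols[1], cols[2], cols[3], cols[4], cols[5]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                n_skipped += 1
                continue
            try:
                quality = float(qual)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric QUAL {qual!r}"
                ) from None
            fmt = cols[8].split(":")
            if "GT" not in fmt:
                raise FormatError(f"{path}: line {lineno}: FORMAT lacks GT")
            gt_idx = fmt.index("GT")
            genotypes: dict[str, str] = {}
            for sample_id, cell in zip(samples, cols[9:]):
                gt = cell.split(":")[gt_idx]
                if gt not in _GT_FROM_VCF:
                    raise FormatError(
                        f"{path}: line {lineno}: unsupported genotype {gt!r}"
                    )
                genotypes[sample_id] = _GT_FROM_VCF[gt]
            sites.append(
                VariantSite(
                    gene_id=chrom,
                    cds_pos=int(pos),
                    ref=ref,
                    alt=alt,
                    quality=quality,
                    genotypes=genotypes,
                )
            )
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d multi-allelic/indel records", path, n_skipped)
    return sites


def write_vcf(sites: Iterable[VariantSite], samples: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for s in sites:
            qual = str(s.quality)  # shortest exact repr: QUAL round-trips
            gts = "\t".join(_GT_TO_VCF[s.genotypes.get(sid, MISSING)] for sid in samples)
            fh.write(
                f"{s.gene_id}\t{s.cds_pos}\t.\t{s.ref}\t{s.alt}\t{qual}\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# SAM-like read dialect
# ---------------------------------------------------------------------------


def read_sam_reads(
    path: str | Path, cds_lengths: Mapping[str, int] | None = None
) -> list[AlignedRead]:
    """Read the SAM-like TSV dialect.

    Columns: read_id, sample_id, gene_id, start (1-based), CIGAR, seq.
    Only all-match CIGARs (``<len>M``) are in dialect; other records are
    rejected with a logged reason, as are reads overhanging the CDS end
    when ``cds_lengths`` is supplied.
    """
    reads: list[AlignedRead] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("@"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns")
            read_id, sample_id, gene_id, start_s, cigar, seq = cols
            if not cigar.endswith("M") or not cigar[:-1].isdigit():
                logger.info("read_sam_reads: line %d rejected (CIGAR %r not all-match)", lineno, cigar)
                n_rejected += 1
                continue
            if int(cigar[:-1]) != len(seq):
                logger.info("read_sam_reads: line %d rejected (CIGAR span != seq length)", lineno)
                n_rejected += 1
                continue
            read = AlignedRead(read_id, sample_id, gene_id, int(start_s), seq)
            if cds_lengths is not None:
                L = cds_lengths.get(gene_id)
                if L is None:
                    logger.info("read_sam_reads: line %d rejected (unknown gene %s)", lineno, gene_id)
                    n_rejected += 1
                    continue
                if read.end > L:
                    logger.info("read_sam_reads: line %d rejected (read overhangs CDS end)", lineno)
                    n_rejected += 1
                    continue
            reads.append(read)
    if n_rejected:
        logger.info("read_sam_reads(%s): rejected %d records", path, n_rejected)
    return reads


def write_sam_reads(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tsample_id\tgene_id\tstart\tcigar\tseq\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.sample_id}\t{r.gene_id}\t{r.start}\t{len(r.seq)}M\t{r.seq}\n"
            )


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

_GENE_TABLE_COLS = ["gene_id", "pos_kb", "map_f_cM", "map_m_cM", "fpkm"]


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TABLE_COLS) + "\n")
        for g in genes:
            cells = [
                g.gene_id,
                f"{g.pos_kb:.10g}",
                "" if g.map_pos_female_cM is None else f"{g.map_pos_female_cM:g}",
                "" if g.map_pos_male_cM is None else f"{g.map_pos_male_cM:g}",
                "" if g.fpkm is None else f"{g.fpkm:g}",
            ]
            fh.write("\t".join(cells) + "\n")


def load_gene_models(table_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Join the gene table TSV with the CDS FASTA into GeneModel objects."""
    seqs = dict(read_fasta(fasta_path))
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_TABLE_COLS:
            raise FormatError(f"{table_path}: unexpected gene table header {header}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            row = dict(zip(_GENE_TABLE_COLS, cells))
            gid = row["gene_id"]
            if gid in seen:
                raise FormatError(f"{table_path}: duplicate gene_id {gid}")
            seen.add(gid)
            if gid not in seqs:
                raise FormatError(f"{table_path}: gene {gid} missing from FASTA")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    pos_kb=float(row["pos_kb"]),
                    cds=seqs[gid],
                    map_pos_female_cM=float(row["map_f_cM"]) if row.get("map_f_cM") else None,
                    map_pos_male_cM=float(row["map_m_cM"]) if row.get("map_m_cM") else None,
                    fpkm=float(row["fpkm"]) if row.get("fpkm") else None,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------


def write_sample_table(samples: Iterable[Sample], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\tsex\trole\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.species}\t{s.sex}\t{s.role}\n")


def read_sample_table(path: str | Path) -> list[Sample]:
    samples: list[Sample] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "species", "sex", "role"]:
            raise FormatError(f"{path}: unexpected sample table header")
        for line in fh:
            if not line.strip():
                continue
            sid, species, sex, role = line.rstrip("\n").split("\t")
            samples.append(Sample(sid, species, sex, role))
    return samples


# ---------------------------------------------------------------------------
# evidence table
# ---------------------------------------------------------------------------

EVIDENCE_COLS = [
    "gene_id",
    "pos_kb",
    "map_f_cM",
    "map_m_cM",
    "stratum",
    "n_segr",
    "n_lat",
    "n_dio",
    "ks",
    "ycds_bp",
    "ycds_pct",
    "uncertain",
]


def _opt_int(cell: str) -> int | None:
    return int(cell) if cell else None


def _opt_float(cell: str) -> float | None:
    return float(cell) if cell else None


def load_evidence_table(path: str | Path) -> list[EvidenceTableRow]:
    """Load an evidence table TSV; blank cells become absent optionals.

    Rows are returned sorted by ``pos_kb`` (ascending, i.e. distal to
    proximal).  Comment lines (``#``) are ignored; duplicate gene ids are
    an error.
    """
    rows: list[EvidenceTableRow] = []
    seen: set[str] = set()
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if header != EVIDENCE_COLS:
                    raise FormatError(
                        f"{path}: line {lineno}: unexpected evidence header {header}"
                    )
                continue
            # ragged rows: trailing blank cells may be omitted
            cells += [""] * (len(EVIDENCE_COLS) - len(cells))
            row = dict(zip(EVIDENCE_COLS, cells))
            gid = row["gene_id"]
            if gid in seen:
                raise FormatError(f"{path}: duplicate gene_id {gid}")
            seen.add(gid)
            rows.append(
                EvidenceTableRow(
                    gene_id=gid,
                    pos_kb=float(row["pos_kb"]),
                    stratum_label=row["stratum"] or "unknown",
                    n_segr=_opt_int(row["n_segr"]),
                    n_lat=_opt_int(row["n_lat"]),
                    n_dio=_opt_int(row["n_dio"]),
                    ks=_opt_float(row["ks"]),
                    ycds_bp=_opt_int(row["ycds_bp"]),
                    ycds_pct=_opt_float(row["ycds_pct"]),
                    map_f_cM=_opt_float(row["map_f_cM"]),
                    map_m_cM=_opt_float(row["map_m_cM"]),
                    uncertain=tuple(t for t in row["uncertain"].split(",") if t),
                )
            )
    rows.sort(key=lambda r: r.pos_kb)
    counts: dict[str, int] = {}
    for r in rows:
        counts[r.stratum_label] = counts.get(r.stratum_label, 0) + 1
    logger.info("load_evidence_table(%s): rows per stratum %s", path, counts)
    return rows


def write_evidence_table(rows: Iterable[EvidenceTableRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EVIDENCE_COLS) + "\n")
        for r in sorted(rows, key=lambda r: r.pos_kb):
            cells = [
                r.gene_id,
                f"{r.pos_kb:.10g}",
                "" if r.map_f_cM is None else f"{r.map_f_cM:g}",
                "" if r.map_m_cM is None else f"{r.map_m_cM:g}",
                r.stratum_label,
                "" if r.n_segr is None else str(r.n_segr),
                "" if r.n_lat is None else str(r.n_lat),
                "" if r.n_dio is None else str(r.n_dio),
                "" if r.ks is None else f"{r.ks:g}",
                "" if r.ycds_bp is None else str(r.ycds_bp),
                "" if r.ycds_pct is None else f"{r.ycds_pct:g}",
                ",".join(r.uncertain),
            ]
            fh.write("\t".join(cells) + "\n")


def table1_fixture_path() -> Path:
    """Path to the hand-transcribed per-gene evidence table shipped as data."""
    ref = importlib.resources.files("stratamap") / "data" / "table1_evidence.tsv"
    return Path(str(ref))


def load_table1_fixture() -> list[EvidenceTableRow]:
    return load_evidence_table(table1_fixture_path())
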