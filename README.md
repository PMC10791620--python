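# stratamap

Locate evolutionary strata on a young sex chromosome from per-gene
Y-linked SNP evidence.

The pipeline re-implements, as tested reusable components, a workflow for
mapping the pseudoautosomal-region (PAR) and stratum boundaries of a
recently evolved sex-linked region:

1. **Y-SNP detection** (`stratamap.ysnp_detection`) — SNPs are classified
   as Y-linked from two evidence classes: *segregation* in a genetic cross
   (father heterozygous, mother homozygous reference, alt transmitted to
   sons and never to daughters; quality > 500, missing data in < 10
   progeny, >= 10 sons with the alt allele) and *male-specificity* in wild
   cohorts (alt in >= 6 of 7 wild males and no wild female, per species).
2. **Y gametolog assembly** (`stratamap.gametolog_assembly`) — reads
   carrying the alt allele at >= 1 Y-SNP are assigned wholly to the Y;
   a per-position majority consensus (ties and uncovered positions -> N)
   yields the Y CDS with completeness and premature-stop reporting.
3. **Statistics** (`stratamap.popgen_stats`) — fourfold-degenerate site
   masks, nucleotide diversity π with pairwise deletion, Kelly's ZnS
   (mean r² over site pairs; phased and genotype-dosage routes), and
   Nei–Gojobori (1986) Ks/Ka with Jukes–Cantor correction between the X
   CDS and the reconstructed Y consensus.
4. **Strata mapping** (`stratamap.strata_mapping`) — each boundary is the
   position of the distal-most gene carrying its evidence class
   (segregation → segregation-detection boundary; wild-latifolia SNPs →
   PAR/stratum-3 boundary; wild-dioica SNPs → strata-2/3 boundary),
   stratum classification, whole-Mb stratum length, and a one-sided
   permutation test for divergence increasing proximally.
5. **Synthetic data** (`stratamap.synthetic_data`) — a coalescent-based
   simulator producing X-haplotype pools, Y haplotypes with per-stratum
   synonymous divergence (including a linear gradient in stratum 3),
   cross transmission with rare PAR recombination, wild diploid samples
   of two species, sequencing reads with errors and a naive genotype
   caller — so every stage is testable without external data.

A hand-transcribed per-gene evidence table (positions, stratum labels,
Y-SNP counts by evidence class, Ks, Y-CDS completeness for 64 genes) is
shipped as package data (`stratamap/data/table1_evidence.tsv`);
typographically ambiguous cells are flagged in its `uncertain` column.

## Command line

```sh
stratamap simulate --seed 1 --out dataset/            # synthetic dataset
stratamap detect-ysnps --vcf dataset/cross.vcf --pedigree dataset/samples.tsv \
    --cohort cross --out cross_sites.tsv
stratamap assemble-y --reads dataset/reads_males.sam --ysnps cross_sites.tsv \
    --cds dataset/genes.fasta --out-fasta y.fasta --out-report y_report.tsv
stratamap stats --alignments dataset/alignments --out diversity.tsv
stratamap map-strata --evidence src/stratamap/data/table1_evidence.tsv \
    --seed 1 --out-dir map/
stratamap run-all --config run.yaml                   # everything, one config
```

`run-all` reads a YAML config (run_dir, seed, input paths or an embedded
`simulate:` block, stage toggles, thresholds) and writes evidence,
consensus, statistics, boundary and gradient reports plus a manifest into
the run directory; partial outputs of a failed stage are quarantined.

### File dialects

* **FASTA** wrapped at 60 columns, sequences over `ACGTN`.
* **VCF subset** — CHROM holds the gene id, POS the 1-based CDS position,
  one ALT, numeric QUAL, `GT` per sample; multi-allelic/indel records are
  skipped with a logged count.
* **SAM-like reads** — TSV of `read_id, sample_id, gene_id, start,
  cigar, seq` with CIGAR restricted to `<len>M` (ungapped, all-match).
* **Evidence table** — TSV with columns `gene_id, pos_kb, map_f_cM,
  map_m_cM, stratum, n_segr, n_lat, n_dio, ks, ycds_bp, ycds_pct,
  uncertain`; blank cells are absent optionals.

## Notes

* Coordinates: CDS positions are 1-based inclusive; genomic positions are
  kept in kb and divided by 1000 only for reporting. "Distal" means the
  low-coordinate (PAR) chromosome end.
* The Ks/Ka estimator is plain Nei–Gojobori counting with Jukes–Cantor
  correction; no codon-model maximum likelihood is attempted, so absolute
  values should be compared method-consistently.
* Consensus-based Ks is computed only over non-N codons; because selected
  Y reads cluster around Y-SNPs, sparse-read consensuses carry an
  ascertainment bias toward divergent regions (visible at low depth).
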