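import filecmp
from itertools import combinations
from pathlib import Path

import numpy as np
import pytest

from stratamap.formats_io import HET, HOM_ALT, HOM_REF, MISSING, AlignedRead, GeneModel
from stratamap.synthetic_data import (
    SimConfig,
    build_truth,
    emit_reads,
    generate_dataset,
    naive_genotype_caller,
    resolve_divergence,
    simulate_cross,
    simulate_gametologs,
    simulate_x_haplotypes,
    variant_sites_from_truth,
)


def mean_pairwise_diff(haps):
    pairs = list(combinations(haps, 2))
    return sum(sum(a != b for a, b in zip(x, y)) for x, y in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# coalescent
# ---------------------------------------------------------------------------


def test_zero_theta_gives_identical_haplotypes(rng):
    haps = simulate_x_haplotypes(6, 90, 0.0, rng)
    assert len(set(haps)) == 1


def test_L_below_one_is_error(rng):
    with pytest.raises(ValueError):
        simulate_x_haplotypes(4, 0, 0.01, rng)


def test_expected_pairwise_diversity_matches_theta(rng):
    # analytic oracle: E[pi] per site = theta under the standard coalescent
    theta, L, n, reps = 0.02, 200, 6, 1200
    total = 0.0
    for _ in range(reps):
        haps = simulate_x_haplotypes(n, L, theta, rng)
        total += mean_pairwise_diff(haps) / L
    assert np.mean(total / reps) == pytest.approx(theta, rel=0.05)


def test_expected_segregating_sites_matches_watterson(rng):
    # Watterson oracle: E[S] = theta * L * a_n, a_n = sum_{i<n} 1/i
    theta, L, n, reps = 0.02, 200, 8, 1200
    a_n = sum(1.0 / i for i in range(1, n))
    count = 0
    for _ in range(reps):
        haps = simulate_x_haplotypes(n, L, theta, rng)
        count += sum(len({h[i] for h in haps}) > 1 for i in range(L))
    assert count / reps == pytest.approx(theta * L * a_n, rel=0.05)


# ---------------------------------------------------------------------------
# gametologs
# ---------------------------------------------------------------------------


def test_divergence_profile_interpolates_in_str3():
    cfg = SimConfig(boundaries_kb=(24800, 27000, 41500))
    assert resolve_divergence(20000, "PAR", cfg) == 0.0
    assert resolve_divergence(27000, "Str3", cfg) == pytest.approx(0.01)
    assert resolve_divergence(41500, "Str3", cfg) == pytest.approx(0.08)
    mid = resolve_divergence((27000 + 41500) / 2, "Str3", cfg)
    assert mid == pytest.approx(0.045)
    assert resolve_divergence(42000, "Str2", cfg) == 0.10


def test_par_gene_y_is_a_pool_draw(rng, toy_gene):
    cfg = SimConfig(theta_per_site=0.0)
    pool, y, fixed = simulate_gametologs(toy_gene, "PAR", cfg, rng, n_pool=5)
    assert y == pool[0]  # theta 0: everyone identical, no divergence added
    assert fixed == []


def test_str3_substitution_counts_scale_with_d(rng):
    # Poisson-mean oracle at the two ends of the stratum-3 gradient
    cfg = SimConfig(theta_per_site=0.0, boundaries_kb=(27000, 27000, 41500))
    cds = "GGA" * 200  # every third position fourfold => 200 syn sites at pos 3
    counts = {"distal": [], "proximal": []}
    for _ in range(150):
        g_d = GeneModel("gd", 27000.0, cds)
        g_p = GeneModel("gp", 41500.0, cds)
        _, y_d, _ = simulate_gametologs(g_d, "Str3", cfg, rng, n_pool=3)
        _, y_p, _ = simulate_gametologs(g_p, "Str3", cfg, rng, n_pool=3)
        counts["distal"].append(sum(a != b for a, b in zip(cds, y_d)))
        counts["proximal"].append(sum(a != b for a, b in zip(cds, y_p)))
    from stratamap._codons import syn_fractions

    syn_sites = sum(syn_fractions("GGA")) * 200
    assert np.mean(counts["distal"]) == pytest.approx(0.01 * syn_sites, rel=0.25)
    assert np.mean(counts["proximal"]) == pytest.approx(0.08 * syn_sites, rel=0.15)


def test_d_zero_everywhere_gives_zero_divergence(rng, toy_gene):
    cfg = SimConfig(
        theta_per_site=0.01,
        divergence_profile={"PAR": 0.0, "Str3": 0.0, "Str2": 0.0},
    )
    pool, y, fixed = simulate_gametologs(toy_gene, "Str2", cfg, rng, n_pool=5)
    assert y in pool or fixed == []  # Y equals its source X draw


# ---------------------------------------------------------------------------
# cross transmission
# ---------------------------------------------------------------------------


def test_zero_recomb_sons_all_carry_y(rng):
    cfg = SimConfig(n_sons=21, n_daughters=32)
    haps = simulate_cross("A" * 30, "G" * 30, ("C" * 30, "T" * 30), 0.0, cfg, rng)
    for i in range(1, 22):
        assert haps[f"son{i:02d}"][1] == "G" * 30
    for i in range(1, 33):
        assert haps[f"dau{i:02d}"][1] == "A" * 30


def test_half_recomb_half_sons_carry_xf(rng):
    cfg = SimConfig(n_sons=400, n_daughters=0)
    haps = simulate_cross("A" * 9, "G" * 9, ("C" * 9, "C" * 9), 0.5, cfg, rng)
    n_xf = sum(haps[f"son{i:02d}"][1] == "A" * 9 for i in range(1, 401))
    # binomial(400, 0.5): 3.5 sigma band
    assert abs(n_xf - 200) < 3.5 * np.sqrt(400 * 0.25)


def test_daughters_never_carry_y_specific_allele():
    cfg = SimConfig(seed=3, n_genes=10, cds_len=300, par_recomb_prob=0.0)
    truth = build_truth(cfg)
    daughters = [s.sample_id for s in truth.samples if s.role == "daughter"]
    checked = 0
    for gt in truth.genes:
        for site in gt.fixed_diffs:
            y_base = gt.y_hap[site]
            for d in daughters:
                a, b = gt.haplotypes[d]
                assert a[site] != y_base and b[site] != y_base
                checked += 1
    assert checked > 0  # the bundle must actually contain fixed differences


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def test_silent_gene_emits_no_reads(rng):
    gene = GeneModel("g", 10.0, "ATG" * 50, fpkm=0.5)
    cfg = SimConfig(depth=30)
    assert emit_reads("s", ("A" * 150, "A" * 150), gene, cfg, rng) == []


def test_error_free_reads_contain_only_true_alleles(rng):
    cds = "ATG" * 60
    hapA = cds
    hapB = cds[:10] + "C" + cds[11:]
    gene = GeneModel("g", 10.0, cds, fpkm=10.0)
    cfg = SimConfig(depth=50, read_len=40, err=0.0)
    reads = emit_reads("s", (hapA, hapB), gene, cfg, rng)
    alleles = {
        r.seq[10 - (r.start - 1)] for r in reads if r.start <= 11 <= r.end
    }
    assert alleles == {hapA[10], "C"}  # only the two true alleles observed


def test_mean_coverage_approximates_depth(rng):
    cds = "ACG" * 100
    gene = GeneModel("g", 10.0, cds, fpkm=10.0)
    cfg = SimConfig(depth=20, read_len=50)
    cov = np.zeros(300)
    reps = 30
    for _ in range(reps):
        for r in emit_reads("s", (cds, cds), gene, cfg, rng):
            cov[r.start - 1 : r.end] += 1
    # averaged over the whole CDS: total bases / L = depth exactly in
    # expectation (read count ~ Poisson(depth * L / read_len))
    assert np.mean(cov) / reps == pytest.approx(20, rel=0.1)


def test_read_longer_than_cds_emits_full_length(rng):
    gene = GeneModel("g", 10.0, "ATGAAA", fpkm=10.0)
    cfg = SimConfig(depth=10, read_len=80)
    reads = emit_reads("s", (gene.cds, gene.cds), gene, cfg, rng)
    assert reads and all(len(r.seq) == 6 and r.start == 1 for r in reads)


# ---------------------------------------------------------------------------
# naive caller
# ---------------------------------------------------------------------------


def make_reads(sample_id, gene, base_at_10, n, start=1, length=30):
    reads = []
    for k in range(n):
        seq = list(gene.cds[start - 1 : start - 1 + length])
        seq[10 - start] = base_at_10
        reads.append(
            AlignedRead(f"{sample_id}.{k}", sample_id, gene.gene_id, start, "".join(seq))
        )
    return reads


@pytest.fixture
def caller_gene():
    return GeneModel("g", 10.0, "ACG" * 20, fpkm=10.0)


def test_caller_all_ref_emits_nothing(caller_gene):
    reads = {"s1": make_reads("s1", caller_gene, caller_gene.cds[9], 10)}
    assert naive_genotype_caller(reads, caller_gene) == []


def test_caller_balanced_alt_is_het(caller_gene):
    reads = {
        "s1": make_reads("s1", caller_gene, "T", 10) + make_reads("s1", caller_gene, caller_gene.cds[9], 10)
    }
    (site,) = naive_genotype_caller(reads, caller_gene)
    assert site.cds_pos == 10 and site.alt == "T"
    assert site.genotypes["s1"] == HET
    assert site.quality == 50.0 * 10


def test_caller_low_coverage_is_missing(caller_gene):
    reads = {
        "s1": make_reads("s1", caller_gene, "T", 10),
        "s2": make_reads("s2", caller_gene, caller_gene.cds[9], 4),
    }
    (site,) = naive_genotype_caller(reads, caller_gene)
    assert site.genotypes["s2"] == MISSING
    assert site.genotypes["s1"] == HOM_ALT


# ---------------------------------------------------------------------------
# truth-exact variant sites
# ---------------------------------------------------------------------------


def test_variant_sites_from_truth_genotypes(small_truth):
    gt = next(g for g in small_truth.genes if g.fixed_diffs)
    ids = ["father", "mother", "son01", "dau01"]
    sites = variant_sites_from_truth(gt, ids)
    by_pos = {s.cds_pos: s for s in sites}
    for pos0 in gt.fixed_diffs:
        site = by_pos[pos0 + 1]
        assert site.alt == gt.y_hap[pos0]
        assert site.genotypes["father"] == HET
        assert site.genotypes["mother"] == HOM_REF
        assert site.genotypes["son01"] == HET
        assert site.genotypes["dau01"] == HOM_REF


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def dir_signature(root: Path) -> dict[str, bytes]:
    return {
        str(p.relative_to(root)): p.read_bytes()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SimConfig(seed=5, n_genes=4, cds_len=150, depth=5)
    generate_dataset(cfg, tmp_path / "a")
    generate_dataset(cfg, tmp_path / "b")
    assert dir_signature(tmp_path / "a") == dir_signature(tmp_path / "b")


def test_zero_genes_yields_valid_empty_dataset(tmp_path):
    cfg = SimConfig(seed=1, n_genes=0)
    manifest = generate_dataset(cfg, tmp_path / "d")
    assert manifest["n_genes"] == "0"
    assert (tmp_path / "d" / "manifest.tsv").exists()


def test_existing_nonempty_dir_without_force_is_error(tmp_path):
    out = tmp_path / "d"
    out.mkdir()
    (out / "junk").write_text("x")
    with pytest.raises(FileExistsError):
        generate_dataset(SimConfig(n_genes=1), out)


def test_manifest_gene_count_matches_config(tmp_path):
    cfg = SimConfig(seed=2, n_genes=3, cds_len=150, depth=5)
    manifest = generate_dataset(cfg, tmp_path / "d")
    assert manifest["n_genes"] == "3"
    fasta = (tmp_path / "d" / "genes.fasta").read_text()
    assert fasta.count(">") == 3
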