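"""Simulator unit and property tests: pedigree structure, meiosis,
founder LD, QTL architecture, breeding values and phenotyping."""

import numpy as np
import pytest

from gsbench.simulate import (ArchitectureError, GenomeMap, GenotypeData,
                              Pedigree, SimParams, build_genome_map,
                              build_pedigree, assign_architecture, compute_tbv,
                              compute_genotypic_values,
                              epistatic_marginal_effects, gene_drop, meiose,
                              _meiose_batch, simulate_dataset,
                              simulate_founder_genomes, simulate_phenotypes)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ns,dps,opd,total", [
    (20, 10, 15, 3220),    # workshop scale
    (1, 1, 1, 3),
    (2, 3, 4, 32),
])
def test_pedigree_counts(ns, dps, opd, total):
    ped = build_pedigree(ns, dps, opd)
    assert ped.n == total
    assert ped.is_founder.sum() == ns + ns * dps
    # full-sib families = distinct (sire, dam) pairs among offspring
    off = ~ped.is_founder
    fams = set(zip(ped.sire[off].tolist(), ped.dam[off].tolist()))
    assert len(fams) == ns * dps
    # half-sib families = distinct sires
    assert len(set(ped.sire[off].tolist())) == ns
    # each dam mated to exactly one sire
    dam_to_sire = {}
    for s, d in fams:
        assert dam_to_sire.setdefault(d, s) == s


@pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, 0), (1.5, 1, 1)])
def test_pedigree_rejects_nonpositive_counts(bad):
    with pytest.raises(ValueError):
        build_pedigree(*bad)


def test_pedigree_invariants():
    ped = build_pedigree(3, 2, 2)
    pos = {int(i): k for k, i in enumerate(ped.ids)}
    for k in range(ped.n):
        s, d = int(ped.sire[k]), int(ped.dam[k])
        if ped.generation[k] == "founder":
            assert s == 0 and d == 0
        else:
            assert s != 0 and d != 0
            assert pos[s] < k and pos[d] < k


def test_pedigree_rejects_offspring_before_parent():
    with pytest.raises(ValueError, match="precede"):
        Pedigree(ids=[1, 2, 3], sire=[3, 0, 0], dam=[2, 0, 0],
                 generation=["offspring", "founder", "founder"])


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def test_meiose_zero_distance_coinherited():
    gmap = GenomeMap(np.array(["a", "b"], dtype=object), np.array([1, 1]),
                     np.array([0.3, 0.3]), {1: 1.0})
    parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
    rng = np.random.default_rng(0)
    for _ in range(200):
        g = meiose(parent, gmap, rng)
        assert g[0] == g[1]


def test_meiose_haldane_one_morgan():
    """Empirical recombination fraction at 1 Morgan ~ (1-e^-2)/2 = 0.4323."""
    gmap = GenomeMap(np.array(["a", "b"], dtype=object), np.array([1, 1]),
                     np.array([0.0, 1.0]), {1: 1.0})
    parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)  # phase-known
    rng = np.random.default_rng(1)
    n = 100_000
    pop = parent[None, :, :]
    gam = _meiose_batch(pop, np.zeros(n, dtype=np.int64), gmap, rng)
    rec = np.mean(gam[:, 0] != gam[:, 1])
    expect = (1 - np.exp(-2.0)) / 2
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(rec - expect) < 3 * se


def test_meiose_single_locus_mendelian():
    gmap = GenomeMap(np.array(["a"], dtype=object), np.array([1]),
                     np.array([0.5]), {1: 1.0})
    parent = np.array([[0], [1]], dtype=np.uint8)
    rng = np.random.default_rng(2)
    draws = [meiose(parent, gmap, rng)[0] for _ in range(2000)]
    assert abs(np.mean(draws) - 0.5) < 0.04


# ---------------------------------------------------------------------------
# founder genomes
# ---------------------------------------------------------------------------

def test_founders_deterministic_and_seed_sensitive():
    gmap = build_genome_map(2, 40)
    a = simulate_founder_genomes(gmap, 30, ne=20, n_hist_generations=5, seed=9)
    b = simulate_founder_genomes(gmap, 30, ne=20, n_hist_generations=5, seed=9)
    c = simulate_founder_genomes(gmap, 30, ne=20, n_hist_generations=5, seed=10)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert not np.array_equal(a.haplotypes, c.haplotypes)


def test_founders_maf_floor():
    gmap = build_genome_map(2, 60)
    g = simulate_founder_genomes(gmap, 50, ne=20, n_hist_generations=40, seed=3)
    freq = g.allele_frequencies()
    assert np.minimum(freq, 1 - freq).min() >= 0.0  # population-level floor applied
    # floor is enforced in the historical population; founders may drift a little
    assert (np.minimum(freq, 1 - freq) == 0).mean() < 0.05


def test_founder_ld_decays_with_distance():
    """Mean r^2 for tightly linked loci exceeds that of distant loci; without
    history, distant-locus correlation is pure sampling noise."""
    gmap = build_genome_map(2, 150)
    g = simulate_founder_genomes(gmap, 120, ne=50, n_hist_generations=40, seed=4)
    dos = g.dosages
    c1 = np.flatnonzero(gmap.chrom == 1)
    R2 = np.corrcoef(dos[:, c1].T) ** 2
    d = np.abs(gmap.pos[c1][:, None] - gmap.pos[c1][None, :])
    near = (d > 0) & (d < 0.02)
    far = d > 0.5
    assert np.nanmean(R2[near]) > np.nanmean(R2[far])

    g0 = simulate_founder_genomes(gmap, 120, ne=50, n_hist_generations=0, seed=4)
    R0 = np.corrcoef(g0.dosages[:, c1].T) ** 2
    # ~1/n sampling noise for independent loci
    assert np.nanmean(R0[far]) < 3.0 / 120


# ---------------------------------------------------------------------------
# gene drop and genotype invariants
# ---------------------------------------------------------------------------

def test_gene_drop_mendelian_and_dosage_consistency(small_ds):
    ds = small_ds
    ped, geno = ds.pedigree, ds.genotypes
    dos = geno.dosages
    assert np.array_equal(dos, geno.haplotypes.sum(axis=1))
    pos = {int(i): k for k, i in enumerate(ped.ids)}
    off = np.flatnonzero(~ped.is_founder)
    for r in off[:20]:
        s, d = pos[int(ped.sire[r])], pos[int(ped.dam[r])]
        # paternal allele must be carried by the sire, maternal by the dam
        pat, mat = geno.haplotypes[r, 0], geno.haplotypes[r, 1]
        assert np.all((pat == geno.haplotypes[s, 0]) | (pat == geno.haplotypes[s, 1]))
        assert np.all((mat == geno.haplotypes[d, 0]) | (mat == geno.haplotypes[d, 1]))


def test_dataset_determinism():
    params = SimParams(n_sires=2, dams_per_sire=2, offspring_per_dam=4,
                       snps_per_chrom=30, ne=15, n_hist_generations=4)
    a = simulate_dataset(params, seed=5)
    b = simulate_dataset(params, seed=5)
    c = simulate_dataset(params, seed=6)
    assert np.array_equal(a.genotypes.haplotypes, b.genotypes.haplotypes)
    assert np.array_equal(np.nan_to_num(a.phenotypes.y), np.nan_to_num(b.phenotypes.y))
    assert not np.array_equal(a.genotypes.haplotypes, c.genotypes.haplotypes)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def test_architecture_layout_and_scaling(small_ds):
    arch = small_ds.arch
    counts = {}
    for q in arch.qtls:
        counts[q.chrom] = counts.get(q.chrom, 0) + 1
    assert counts == {1: 1, 2: 2, 3: 2, 4: 1, 5: 2}
    kinds = sorted(q.kind for q in arch.qtls)
    assert kinds.count("additive") == 5
    assert kinds.count("imprinted") == 1
    assert kinds.count("epistatic") == 2
    # linked pairs on chromosomes 2 and 3
    for c in (2, 3):
        pos = [q.pos for q in arch.qtls if q.chrom == c]
        assert abs(pos[0] - pos[1]) < 0.2
    assert arch.sigma2_e == pytest.approx(arch.sigma2_g * 0.7 / 0.3)


def test_chr1_qtl_has_largest_variance(small_ds):
    """Recompute per-QTL variance from effects and founder genotypes."""
    ds = small_ds
    founders = GenotypeData(ds.genotypes.gmap, ds.pedigree.ids[ds.pedigree.is_founder],
                            ds.genotypes.haplotypes[ds.pedigree.is_founder])
    dos = founders.dosages
    pat = founders.haplotypes[:, 0, :].astype(float)
    var_by_chrom = {}
    for q in ds.arch.qtls:
        if q.kind == "additive":
            v = q.effect ** 2 * np.var(dos[:, q.locus_index])
        elif q.kind == "imprinted":
            v = q.effect ** 2 * np.var(pat[:, q.locus_index])
        else:
            continue
        var_by_chrom[q.chrom] = max(var_by_chrom.get(q.chrom, 0.0), v)
    assert var_by_chrom[1] == max(var_by_chrom.values())


def test_architecture_rejects_sparse_genome():
    gmap = build_genome_map(5, 2)
    rng = np.random.default_rng(0)
    haps = np.zeros((30, 2, gmap.n_loci), dtype=np.uint8)  # monomorphic
    g = GenotypeData(gmap, np.arange(1, 31), haps)
    with pytest.raises(ArchitectureError):
        assign_architecture(gmap, g, seed=0)


def test_epistatic_marginals_match_enumeration():
    """Weighted-regression marginal effects vs brute-force 9-cell oracle."""
    rng = np.random.default_rng(8)
    for _ in range(5):
        table = rng.normal(0, 1, (3, 3))
        p1, p2 = rng.uniform(0.1, 0.9, 2)
        a1, a2 = epistatic_marginal_effects(table, p1, p2)
        # oracle: weighted least squares by explicit enumeration of 9 cells
        w1 = np.array([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1 ** 2])
        w2 = np.array([(1 - p2) ** 2, 2 * p2 * (1 - p2), p2 ** 2])
        rows = []
        for g1 in range(3):
            for g2 in range(3):
                rows.append((w1[g1] * w2[g2], g1, g2, table[g1, g2]))
        W = np.diag([r[0] for r in rows])
        X = np.array([[1.0, r[1], r[2]] for r in rows])
        v = np.array([r[3] for r in rows])
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ v)
        assert a1 == pytest.approx(coef[1], abs=1e-10)
        assert a2 == pytest.approx(coef[2], abs=1e-10)


def test_default_epistasis_has_zero_marginals(small_ds):
    arch = small_ds.arch
    epi = [q for q in arch.qtls if q.kind == "epistatic"]
    a1, a2 = epistatic_marginal_effects(arch.epistasis_table, epi[0].freq, epi[1].freq)
    assert abs(a1) < 1e-10 and abs(a2) < 1e-10


# ---------------------------------------------------------------------------
# TBV and phenotypes
# ---------------------------------------------------------------------------

def test_tbv_zero_effects(small_ds):
    arch = small_ds.arch
    zeroed = type(arch)(qtls=[type(q)(q.locus_index, q.chrom, q.pos, q.kind, 0.0,
                                      q.freq, q.partner_index) for q in arch.qtls],
                        sigma2_g=arch.sigma2_g, h2=arch.h2, sigma2_e=arch.sigma2_e,
                        epistasis_table=np.zeros((3, 3)))
    assert np.allclose(compute_tbv(small_ds.genotypes, zeroed), 0.0)


def test_tbv_single_additive_centering():
    """One QTL with p=0.5: TBV in {-a, 0, +a} for dosages {0, 1, 2}."""
    from gsbench.simulate import QTL, TraitArchitecture
    gmap = GenomeMap(np.array(["s1"], dtype=object), np.array([1]),
                     np.array([0.5]), {1: 1.0})
    haps = np.array([[[0], [0]], [[1], [0]], [[1], [1]]], dtype=np.uint8)
    geno = GenotypeData(gmap, np.array([1, 2, 3]), haps)
    a = 0.7
    arch = TraitArchitecture(
        qtls=[QTL(0, 1, 0.5, "additive", a, 0.5)], sigma2_g=1.0, h2=0.3,
        sigma2_e=7 / 3, epistasis_table=np.zeros((3, 3)))
    assert compute_tbv(geno, arch) == pytest.approx([-a, 0.0, a])


def test_phenotype_count_and_noise_free_limit(small_ds):
    ds = small_ds
    # first ceil(2/3 * 8) = 6 offspring per full-sib family carry records
    assert ds.phenotypes.n_phenotyped == 6 * 24
    assert not ds.phenotypes.phenotyped_mask[ds.pedigree.is_founder].any()

    arch0 = ds.arch
    arch0_no_noise = type(arch0)(qtls=arch0.qtls, sigma2_g=arch0.sigma2_g,
                                 h2=0.999999, sigma2_e=0.0,
                                 epistasis_table=arch0.epistasis_table)
    gvals = compute_genotypic_values(ds.genotypes, arch0)
    ph = simulate_phenotypes(ds.phenotypes.tbv, gvals, arch0_no_noise,
                             ds.pedigree, seed=1)
    m = ph.phenotyped_mask
    assert np.allclose(ph.y[m] - arch0.mu, gvals[m])


def test_phenotype_fraction_validation(small_ds):
    with pytest.raises(ValueError):
        simulate_phenotypes(small_ds.phenotypes.tbv,
                            np.zeros(small_ds.pedigree.n), small_ds.arch,
                            small_ds.pedigree, phenotyped_fraction=0.0, seed=0)


def test_realised_heritability_near_target(small_ds):
    ph = small_ds.phenotypes
    m = ph.phenotyped_mask
    h2 = np.var(ph.tbv[m]) / np.var(ph.y[m])
    assert 0.15 < h2 < 0.45   # single small replicate; tight band in acceptance
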