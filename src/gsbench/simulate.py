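"""Pedigree, genome and trait simulator for genomic-selection benchmarking.

Generates a workshop-style benchmark dataset: a two-generation pedigree of
half-sib/full-sib families, founder haplotypes with linkage disequilibrium
built up by gene-dropping through a small historical population, meiosis
under the Haldane (no-interference) map function, and a quantitative trait
controlled by eight QTL (five additive, one imprinted, one epistatic pair)
with a narrow-sense heritability target.

Default parameters reproduce the published dataset structure: 20 sires x
10 dams x 15 offspring = 3220 individuals, five chromosomes of 1 Morgan
carrying 2000 equally spaced loci each, h2 = 0.3, and two thirds of the
offspring phenotyped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Pedigree",
    "GenomeMap",
    "GenotypeData",
    "QTL",
    "TraitArchitecture",
    "PhenotypeSet",
    "SimParams",
    "SimulatedDataset",
    "ArchitectureError",
    "DegenerateLocusError",
    "build_pedigree",
    "build_genome_map",
    "meiose",
    "simulate_founder_genomes",
    "gene_drop",
    "assign_architecture",
    "compute_tbv",
    "compute_genotypic_values",
    "simulate_phenotypes",
    "simulate_dataset",
]


class ArchitectureError(ValueError):
    """Raised when a QTL architecture cannot be placed on the given genome."""


class DegenerateLocusError(RuntimeError):
    """Raised when a locus cannot be made polymorphic within bounded resampling."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Two-column parent pedigree, parents listed before offspring.

    ``sire`` / ``dam`` use 0 for an unknown parent. ``generation`` is
    "founder" or "offspring".
    """

    ids: np.ndarray          # int64, unique, positive
    sire: np.ndarray         # int64, 0 = unknown
    dam: np.ndarray          # int64, 0 = unknown
    generation: np.ndarray   # object/str array

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=object)
        if len(set(self.ids.tolist())) != self.ids.size:
            raise ValueError("pedigree ids must be unique")
        if np.any(self.ids <= 0):
            raise ValueError("pedigree ids must be positive")
        pos = {int(i): k for k, i in enumerate(self.ids)}
        for k, (s, d) in enumerate(zip(self.sire, self.dam)):
            for p in (int(s), int(d)):
                if p != 0:
                    if p not in pos:
                        raise ValueError(f"unknown parent id {p}")
                    if pos[p] >= k:
                        raise ValueError("parents must precede offspring")

    @property
    def n(self) -> int:
        return int(self.ids.size)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == 0) & (self.dam == 0)

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        pos = {int(i): k for k, i in enumerate(self.ids)}
        return np.array([pos[int(i)] for i in np.asarray(ids)], dtype=np.int64)


def build_pedigree(n_sires: int, dams_per_sire: int, offspring_per_dam: int) -> Pedigree:
    """Build the nested half-sib / full-sib mating design.

    Each sire is mated to ``dams_per_sire`` dams; each dam produces
    ``offspring_per_dam`` offspring. Sires and dams are unrelated founders.
    The default workshop scale (20, 10, 15) yields 3220 individuals in
    20 half-sib and 200 full-sib families.
    """
    for name, v in (("n_sires", n_sires), ("dams_per_sire", dams_per_sire),
                    ("offspring_per_dam", offspring_per_dam)):
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    n_sires, dams_per_sire, offspring_per_dam = map(int, (n_sires, dams_per_sire, offspring_per_dam))

    n_dams = n_sires * dams_per_sire
    n_off = n_dams * offspring_per_dam
    n_total = n_sires + n_dams + n_off

    ids = np.arange(1, n_total + 1, dtype=np.int64)
    sire = np.zeros(n_total, dtype=np.int64)
    dam = np.zeros(n_total, dtype=np.int64)
    gen = np.array(["founder"] * (n_sires + n_dams) + ["offspring"] * n_off, dtype=object)

    k = n_sires + n_dams
    for s in range(n_sires):
        sire_id = s + 1
        for d in range(dams_per_sire):
            dam_id = n_sires + s * dams_per_sire + d + 1
            for _ in range(offspring_per_dam):
                sire[k] = sire_id
                dam[k] = dam_id
                k += 1
    return Pedigree(ids=ids, sire=sire, dam=dam, generation=gen)


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------

@dataclass
class GenomeMap:
    """SNP map: identifiers, chromosome assignment and position in Morgans."""

    snp_id: np.ndarray      # str
    chrom: np.ndarray       # int, 1..C
    pos: np.ndarray         # float, Morgans from chromosome start
    chrom_lengths: dict = field(default_factory=dict)   # chrom -> length (Morgan)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.float64)
        if len(set(self.snp_id.tolist())) != self.snp_id.size:
            raise ValueError("snp ids must be unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions must be non-decreasing on chromosome {c}")
            length = self.chrom_lengths.setdefault(int(c), 1.0)
            if p.size and (p.min() < 0 or p.max() > length):
                raise ValueError(f"positions outside [0, {length}] on chromosome {c}")

    @property
    def n_loci(self) -> int:
        return int(self.snp_id.size)

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """Contiguous index slice per chromosome (map is stored chrom-sorted)."""
        out = []
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            out.append((int(c), slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    def subset(self, keep: np.ndarray) -> "GenomeMap":
        return GenomeMap(self.snp_id[keep], self.chrom[keep], self.pos[keep],
                         dict(self.chrom_lengths))


def build_genome_map(n_chrom: int = 5, snps_per_chrom: int = 2000,
                     chrom_length: float = 1.0) -> GenomeMap:
    """Equally spaced loci on ``n_chrom`` chromosomes of ``chrom_length`` Morgans."""
    snp_id, chrom, pos = [], [], []
    for c in range(1, n_chrom + 1):
        p = np.linspace(0.0, chrom_length, snps_per_chrom, endpoint=False)
        p += chrom_length / (2 * snps_per_chrom)   # centred spacing, off the ends
        for j in range(snps_per_chrom):
            snp_id.append(f"snp_{c}_{j + 1}")
        chrom.extend([c] * snps_per_chrom)
        pos.extend(p.tolist())
    return GenomeMap(np.array(snp_id, dtype=object), np.array(chrom),
                     np.array(pos), {c: chrom_length for c in range(1, n_chrom + 1)})


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeData:
    """Phased biallelic genotypes with parental-origin labels.

    ``haplotypes`` has shape (n_individuals, 2, n_loci) with alleles in {0, 1};
    index 0 of the middle axis is the paternally inherited haplotype, index 1
    the maternal one. Dosages are allele counts in {0, 1, 2}.
    """

    gmap: GenomeMap
    ids: np.ndarray                 # int64
    haplotypes: np.ndarray          # uint8 (n, 2, L)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, L)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise ValueError("haplotype loci do not match the map")
        if self.haplotypes.shape[0] != self.ids.size:
            raise ValueError("ids do not match haplotype rows")

    @property
    def n(self) -> int:
        return int(self.ids.size)

    @property
    def dosages(self) -> np.ndarray:
        """Allele-count matrix (n_individuals x n_loci), dtype float64."""
        return self.haplotypes.sum(axis=1, dtype=np.int64).astype(np.float64)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1), dtype=np.float64)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeData":
        return GenotypeData(self.gmap.subset(keep), self.ids,
                            self.haplotypes[:, :, keep])


def meiose(parent_haplotypes: np.ndarray, gmap: GenomeMap,
           rng: np.random.Generator) -> np.ndarray:
    """Sample one gamete from a parent's two haplotypes.

    Crossovers follow a Poisson process along each chromosome (Haldane, no
    interference): the recombination fraction between loci d Morgans apart is
    (1 - exp(-2d)) / 2. The starting haplotype is chosen with probability 1/2
    independently per chromosome.
    """
    L = gmap.n_loci
    gam = np.empty(L, dtype=np.uint8)
    for c, sl in gmap.chrom_slices():
        pos = gmap.pos[sl]
        length = gmap.chrom_lengths[c]
        n_x = rng.poisson(length)
        start = rng.integers(2)
        if n_x == 0:
            gam[sl] = parent_haplotypes[start, sl]
            continue
        xpos = np.sort(rng.uniform(0.0, length, size=n_x))
        hap_idx = (start + np.searchsorted(xpos, pos)) % 2
        block = parent_haplotypes[:, sl]
        gam[sl] = np.where(hap_idx == 0, block[0], block[1])
    return gam


def _meiose_batch(pop_haps: np.ndarray, parent_rows: np.ndarray,
                  gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """Vectorised gamete sampling: one gamete per entry of ``parent_rows``.

    Equivalent to calling :func:`meiose` per parent but batched per
    chromosome for speed; same Haldane crossover model.
    """
    G = parent_rows.size
    L = gmap.n_loci
    out = np.empty((G, L), dtype=np.uint8)
    for c, sl in gmap.chrom_slices():
        pos = gmap.pos[sl]
        length = gmap.chrom_lengths[c]
        starts = rng.integers(0, 2, size=G)
        n_x = rng.poisson(length, size=G)
        pat = pop_haps[parent_rows, 0][:, sl]
        mat = pop_haps[parent_rows, 1][:, sl]
        hap_idx = np.empty((G, pos.size), dtype=np.int64)
        for g in range(G):
            if n_x[g] == 0:
                hap_idx[g] = starts[g]
            else:
                xpos = np.sort(rng.uniform(0.0, length, size=n_x[g]))
                hap_idx[g] = (starts[g] + np.searchsorted(xpos, pos)) % 2
        out[:, sl] = np.where(hap_idx == 0, pat, mat)
    return out


def simulate_founder_genomes(gmap: GenomeMap, n_founders: int, ne: int = 100,
                             n_hist_generations: int = 100, seed: int = 0,
                             maf_floor: float = 0.01,
                             max_resample: int = 20) -> GenotypeData:
    """Founder haplotypes from a drifting historical population.

    A random-mating population of ``ne`` individuals is initialised with
    allele frequencies drawn uniform on [0.05, 0.95], independent across
    loci, and evolved for ``n_hist_generations`` generations of meiosis.
    Drift plus linkage builds up LD that decays with map distance. Loci
    whose final minor-allele frequency falls below ``maf_floor`` are
    redrawn independently (up to ``max_resample`` attempts) so every locus
    stays polymorphic. Founders are then bred from random pairs of the
    final historical generation.
    """
    if gmap.n_loci == 0:
        raise ValueError("empty genome map")
    if ne < 2:
        raise ValueError("ne must be >= 2")
    rng = np.random.default_rng(seed)
    L = gmap.n_loci

    p0 = rng.uniform(0.05, 0.95, size=L)
    pop = (rng.random((ne, 2, L)) < p0).astype(np.uint8)

    for _ in range(n_hist_generations):
        sires = rng.integers(0, ne, size=ne)
        dams = (sires + 1 + rng.integers(0, ne - 1, size=ne)) % ne  # no selfing
        pat = _meiose_batch(pop, sires, gmap, rng)
        mat = _meiose_batch(pop, dams, gmap, rng)
        pop = np.stack([pat, mat], axis=1)

    # keep every locus segregating: i.i.d. redraw of failed columns
    for _ in range(max_resample):
        freq = pop.mean(axis=(0, 1))
        maf = np.minimum(freq, 1.0 - freq)
        bad = np.flatnonzero(maf < maf_floor)
        if bad.size == 0:
            break
        p_new = rng.uniform(0.2, 0.8, size=bad.size)
        pop[:, :, bad] = (rng.random((ne, 2, bad.size)) < p_new).astype(np.uint8)
    else:
        raise DegenerateLocusError(
            f"{bad.size} loci below MAF {maf_floor} after {max_resample} resampling rounds")

    sires = rng.integers(0, ne, size=n_founders)
    dams = (sires + 1 + rng.integers(0, ne - 1, size=n_founders)) % ne
    pat = _meiose_batch(pop, sires, gmap, rng)
    mat = _meiose_batch(pop, dams, gmap, rng)
    haps = np.stack([pat, mat], axis=1)
    ids = np.arange(1, n_founders + 1, dtype=np.int64)
    return GenotypeData(gmap=gmap, ids=ids, haplotypes=haps)


def gene_drop(pedigree: Pedigree, founder_genomes: GenotypeData,
              seed: int = 0) -> GenotypeData:
    """Drop founder haplotypes through the pedigree by meiosis.

    Founders take the rows of ``founder_genomes`` in pedigree order; every
    offspring receives one paternal gamete from its sire and one maternal
    gamete from its dam. Parental origin is preserved: haplotype 0 is always
    the paternally inherited one.
    """
    gmap = founder_genomes.gmap
    rng = np.random.default_rng(seed)
    n = pedigree.n
    L = gmap.n_loci
    haps = np.zeros((n, 2, L), dtype=np.uint8)
    pos = {int(i): k for k, i in enumerate(pedigree.ids)}

    founder_rows = np.flatnonzero(pedigree.is_founder)
    if founder_rows.size > founder_genomes.n:
        raise ValueError("not enough founder genomes for the pedigree")
    haps[founder_rows] = founder_genomes.haplotypes[:founder_rows.size]

    # offspring grouped by (sire, dam) are batched through the same parents
    off_rows = np.flatnonzero(~pedigree.is_founder)
    sire_rows = np.array([pos[int(s)] for s in pedigree.sire[off_rows]], dtype=np.int64)
    dam_rows = np.array([pos[int(d)] for d in pedigree.dam[off_rows]], dtype=np.int64)
    haps[off_rows, 0] = _meiose_batch(haps, sire_rows, gmap, rng)
    haps[off_rows, 1] = _meiose_batch(haps, dam_rows, gmap, rng)
    return GenotypeData(gmap=gmap, ids=pedigree.ids.copy(), haplotypes=haps)


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------

@dataclass
class QTL:
    """One quantitative-trait locus.

    ``kind`` is "additive", "imprinted" or "epistatic"; ``effect`` is the
    allele-substitution effect for additive loci, the paternal-allele effect
    for the imprinted locus, and unused for epistatic members (their action
    is defined by the pair's genotype-value table). ``freq`` is the founder
    allele frequency of the 1 allele.
    """

    locus_index: int
    chrom: int
    pos: float
    kind: str
    effect: float
    freq: float
    partner_index: Optional[int] = None   # locus index of the epistatic partner


@dataclass
class TraitArchitecture:
    """Eight-QTL genetic architecture with additive, imprinted and epistatic loci."""

    qtls: list
    sigma2_g: float
    h2: float
    sigma2_e: float
    epistasis_table: np.ndarray      # 3x3 genotype-value table for the chr5 pair
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")
        self.epistasis_table = np.asarray(self.epistasis_table, dtype=np.float64)
        if self.epistasis_table.shape != (3, 3):
            raise ValueError("epistasis table must be 3x3")

    @property
    def qtl_locus_indices(self) -> np.ndarray:
        return np.array([q.locus_index for q in self.qtls], dtype=np.int64)

    def to_json_dict(self) -> dict:
        return {
            "sigma2_g": self.sigma2_g,
            "h2": self.h2,
            "sigma2_e": self.sigma2_e,
            "mu": self.mu,
            "epistasis_table": self.epistasis_table.tolist(),
            "qtls": [
                {"locus_index": int(q.locus_index), "chrom": int(q.chrom),
                 "pos": float(q.pos), "kind": q.kind, "effect": float(q.effect),
                 "freq": float(q.freq),
                 "partner_index": None if q.partner_index is None else int(q.partner_index)}
                for q in self.qtls
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TraitArchitecture":
        qtls = [QTL(**q) for q in d["qtls"]]
        return cls(qtls=qtls, sigma2_g=d["sigma2_g"], h2=d["h2"],
                   sigma2_e=d["sigma2_e"],
                   epistasis_table=np.array(d["epistasis_table"]),
                   mu=d.get("mu", 0.0))


def _per_qtl_variance(q: QTL, dosages_col: np.ndarray,
                      pat_col: np.ndarray) -> float:
    if q.kind == "additive":
        return float(q.effect ** 2 * np.var(dosages_col))
    if q.kind == "imprinted":
        return float(q.effect ** 2 * np.var(pat_col))
    return 0.0   # epistatic members carry no marginal effect parameter


def assign_architecture(gmap: GenomeMap, founder_genomes: GenotypeData,
                        h2: float = 0.3, sigma2_g: float = 1.0, seed: int = 0,
                        linked_max_dist: float = 0.2,
                        epistatic_var_fraction: float = 0.10,
                        min_qtl_maf: float = 0.1,
                        max_reject: int = 10000) -> TraitArchitecture:
    """Place the eight-QTL layout and draw effect sizes.

    Layout on the five chromosomes: one large additive QTL on chromosome 1,
    two linked additive QTL (< ``linked_max_dist`` Morgans apart) on each of
    chromosomes 2 and 3, one paternally expressed imprinted QTL on
    chromosome 4, and one epistatic pair on chromosome 5 whose 3x3
    genotype-value table has zero marginal (average) effects.

    Raw additive effects are drawn from a signed gamma; draws are rejected
    until the chromosome-1 QTL has the largest single-locus variance. All
    effects are then rescaled by one common factor so the realised additive
    genetic variance (variance of the true breeding value) among founders
    equals ``sigma2_g``; the epistatic interaction strength is set to
    contribute ``epistatic_var_fraction`` of ``sigma2_g`` as non-additive
    variance. The environmental variance follows from the h2 target:
    sigma2_e = sigma2_g * (1 - h2) / h2.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    freq = founder_genomes.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)

    layout = {1: 1, 2: 2, 3: 2, 4: 1, 5: 2}
    chrom_loci: dict[int, np.ndarray] = {}
    for c, want in layout.items():
        usable = np.flatnonzero((gmap.chrom == c) & (maf >= min_qtl_maf))
        if usable.size < want:
            raise ArchitectureError(
                f"chromosome {c}: {usable.size} segregating loci, need {want}")
        chrom_loci[c] = usable

    def pick_one(c: int) -> int:
        return int(rng.choice(chrom_loci[c]))

    def pick_linked_pair(c: int) -> tuple[int, int]:
        usable = chrom_loci[c]
        for _ in range(1000):
            a = int(rng.choice(usable))
            near = usable[(np.abs(gmap.pos[usable] - gmap.pos[a]) <= linked_max_dist)
                          & (usable != a)]
            if near.size:
                return a, int(rng.choice(near))
        raise ArchitectureError(f"no linked pair within {linked_max_dist} M on chromosome {c}")

    loc1 = pick_one(1)
    loc2a, loc2b = pick_linked_pair(2)
    loc3a, loc3b = pick_linked_pair(3)
    loc4 = pick_one(4)
    # epistatic pair: distinct loci anywhere on chromosome 5
    loc5a = pick_one(5)
    loc5b = loc5a
    while loc5b == loc5a:
        loc5b = pick_one(5)

    add_idx = [loc1, loc2a, loc2b, loc3a, loc3b]
    dos = founder_genomes.dosages
    pat = founder_genomes.haplotypes[:, 0, :].astype(np.float64)

    # reject until the chr1 locus carries the largest single-QTL variance
    for _ in range(max_reject):
        a_eff = rng.gamma(shape=1.2, scale=1.0, size=5) * rng.choice([-1.0, 1.0], size=5)
        imp_eff = rng.gamma(shape=1.2, scale=1.0) * rng.choice([-1.0, 1.0])
        v_add = [e ** 2 * np.var(dos[:, j]) for e, j in zip(a_eff, add_idx)]
        v_imp = imp_eff ** 2 * np.var(pat[:, loc4])
        if v_add[0] >= max(max(v_add[1:]), v_imp):
            break
    else:
        raise ArchitectureError("could not realise a dominant chr1 QTL by rejection")

    # additive score (TBV before scaling): additive loci + paternal imprinted term
    p = freq
    tbv_raw = np.zeros(founder_genomes.n)
    for e, j in zip(a_eff, add_idx):
        tbv_raw += e * (dos[:, j] - 2 * p[j])
    tbv_raw += imp_eff * (pat[:, loc4] - p[loc4])
    v_raw = float(np.var(tbv_raw))
    if v_raw <= 0:
        raise ArchitectureError("degenerate additive variance")
    c_scale = float(np.sqrt(sigma2_g / v_raw))
    a_eff = a_eff * c_scale
    imp_eff = imp_eff * c_scale

    # epistatic interaction k*(g1-2p1)*(g2-2p2): zero marginal average effects
    prod = (dos[:, loc5a] - 2 * p[loc5a]) * (dos[:, loc5b] - 2 * p[loc5b])
    v_prod = float(np.var(prod))
    if v_prod <= 0:
        raise ArchitectureError("degenerate epistatic product variance")
    k_epi = float(np.sqrt(epistatic_var_fraction * sigma2_g / v_prod))
    g1 = np.arange(3.0)
    table = k_epi * np.outer(g1 - 2 * p[loc5a], g1 - 2 * p[loc5b])

    qtls = [
        QTL(loc1, 1, float(gmap.pos[loc1]), "additive", float(a_eff[0]), float(p[loc1])),
        QTL(loc2a, 2, float(gmap.pos[loc2a]), "additive", float(a_eff[1]), float(p[loc2a])),
        QTL(loc2b, 2, float(gmap.pos[loc2b]), "additive", float(a_eff[2]), float(p[loc2b])),
        QTL(loc3a, 3, float(gmap.pos[loc3a]), "additive", float(a_eff[3]), float(p[loc3a])),
        QTL(loc3b, 3, float(gmap.pos[loc3b]), "additive", float(a_eff[4]), float(p[loc3b])),
        QTL(loc4, 4, float(gmap.pos[loc4]), "imprinted", float(imp_eff), float(p[loc4])),
        QTL(loc5a, 5, float(gmap.pos[loc5a]), "epistatic", 0.0, float(p[loc5a]),
            partner_index=loc5b),
        QTL(loc5b, 5, float(gmap.pos[loc5b]), "epistatic", 0.0, float(p[loc5b]),
            partner_index=loc5a),
    ]
    sigma2_e = sigma2_g * (1.0 - h2) / h2
    return TraitArchitecture(qtls=qtls, sigma2_g=sigma2_g, h2=h2,
                             sigma2_e=sigma2_e, epistasis_table=table)


def _hwe_weights(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])


def epistatic_marginal_effects(table: np.ndarray, p1: float, p2: float
                               ) -> tuple[float, float]:
    """Average (allele-substitution) effects of a 2-locus genotype-value table.

    Weighted least-squares regression of the 9 genotype values on the two
    dosages under Hardy-Weinberg and linkage equilibrium at frequencies
    p1, p2. Returns the two substitution-effect slopes.
    """
    table = np.asarray(table, dtype=np.float64)
    w = np.outer(_hwe_weights(p1), _hwe_weights(p2)).ravel()
    g1, g2 = np.meshgrid(np.arange(3.0), np.arange(3.0), indexing="ij")
    X = np.column_stack([np.ones(9), g1.ravel(), g2.ravel()])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], table.ravel() * sw, rcond=None)
    return float(coef[1]), float(coef[2])


def compute_tbv(genotypes: GenotypeData, arch: TraitArchitecture) -> np.ndarray:
    """True breeding value: the sum of average-effect contributions.

    Additive QTL contribute a * (dosage - 2p); the imprinted QTL acts through
    the paternally inherited allele only, a * (paternal allele - p); the
    epistatic pair contributes the marginal substitution effects of its
    genotype-value table under founder frequencies (zero for the default
    pure-interaction table).
    """
    dos = genotypes.dosages
    tbv = np.zeros(genotypes.n)
    epi_pair = []
    for q in arch.qtls:
        if q.kind == "additive":
            tbv += q.effect * (dos[:, q.locus_index] - 2 * q.freq)
        elif q.kind == "imprinted":
            pat = genotypes.haplotypes[:, 0, q.locus_index].astype(np.float64)
            tbv += q.effect * (pat - q.freq)
        elif q.kind == "epistatic":
            epi_pair.append(q)
    if epi_pair:
        if len(epi_pair) != 2:
            raise ArchitectureError("epistatic QTL must come as one pair")
        qa, qb = epi_pair
        a1, a2 = epistatic_marginal_effects(arch.epistasis_table, qa.freq, qb.freq)
        tbv += a1 * (dos[:, qa.locus_index] - 2 * qa.freq)
        tbv += a2 * (dos[:, qb.locus_index] - 2 * qb.freq)
    return tbv


def compute_genotypic_values(genotypes: GenotypeData,
                             arch: TraitArchitecture) -> np.ndarray:
    """Full genotypic value: non-marginalised imprinting and epistasis terms."""
    dos = genotypes.dosages
    g = np.zeros(genotypes.n)
    epi_pair = []
    for q in arch.qtls:
        if q.kind == "additive":
            g += q.effect * (dos[:, q.locus_index] - 2 * q.freq)
        elif q.kind == "imprinted":
            pat = genotypes.haplotypes[:, 0, q.locus_index].astype(np.float64)
            g += q.effect * (pat - q.freq)
        elif q.kind == "epistatic":
            epi_pair.append(q)
    if epi_pair:
        qa, qb = epi_pair
        d1 = dos[:, qa.locus_index].astype(np.int64)
        d2 = dos[:, qb.locus_index].astype(np.int64)
        vals = arch.epistasis_table[d1, d2]
        w = np.outer(_hwe_weights(qa.freq), _hwe_weights(qb.freq))
        g += vals - float((w * arch.epistasis_table).sum())
    return g


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSet:
    """Trait records, phenotyping mask and true breeding values."""

    ids: np.ndarray
    y: np.ndarray                # float, NaN = missing
    phenotyped_mask: np.ndarray  # bool
    tbv: np.ndarray

    @property
    def n_phenotyped(self) -> int:
        return int(self.phenotyped_mask.sum())


def simulate_phenotypes(tbv: np.ndarray, genotypic_values: np.ndarray,
                        arch: TraitArchitecture, pedigree: Pedigree,
                        phenotyped_fraction: float = 2.0 / 3.0,
                        seed: int = 0) -> PhenotypeSet:
    """Phenotypes y = mu + genotypic value + N(0, sigma2_e) noise.

    The genotypic value carries the full imprinting and epistasis terms, not
    their additive marginalisations. Within each full-sib family the first
    ceil(fraction * k) offspring (in id order) are phenotyped; founders never
    are. At the default scale (200 families of 15, fraction 2/3) exactly
    2000 offspring carry records.
    """
    if not (0.0 < phenotyped_fraction <= 1.0):
        raise ValueError("phenotyped_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = pedigree.n
    e = rng.normal(0.0, np.sqrt(arch.sigma2_e), size=n)
    y = arch.mu + genotypic_values + e

    mask = np.zeros(n, dtype=bool)
    off = np.flatnonzero(~pedigree.is_founder)
    # full-sib family = unique (sire, dam) pair, offspring kept in id order
    fams: dict[tuple[int, int], list[int]] = {}
    for r in off:
        fams.setdefault((int(pedigree.sire[r]), int(pedigree.dam[r])), []).append(int(r))
    for rows in fams.values():
        k = int(np.ceil(phenotyped_fraction * len(rows)))
        mask[rows[:k]] = True
    y = np.where(mask, y, np.nan)
    return PhenotypeSet(ids=pedigree.ids.copy(), y=y, phenotyped_mask=mask, tbv=tbv)


# ---------------------------------------------------------------------------
# End-to-end dataset
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Simulation parameters; defaults reproduce the workshop-scale dataset."""

    n_sires: int = 20
    dams_per_sire: int = 10
    offspring_per_dam: int = 15
    n_chrom: int = 5
    snps_per_chrom: int = 2000
    chrom_length: float = 1.0
    ne: int = 100
    n_hist_generations: int = 100
    h2: float = 0.3
    sigma2_g: float = 1.0
    phenotyped_fraction: float = 2.0 / 3.0
    epistatic_var_fraction: float = 0.10

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class SimulatedDataset:
    """Complete simulated dataset plus the marker panel the analyses see.

    ``genotypes`` holds every locus including the 8 QTL; ``markers`` is the
    analysis panel with the QTL columns removed (QTL are unobserved loci).
    """

    params: SimParams
    seed: int
    pedigree: Pedigree
    genotypes: GenotypeData
    markers: GenotypeData
    arch: TraitArchitecture
    phenotypes: PhenotypeSet

    @property
    def marker_dosages(self) -> np.ndarray:
        return self.markers.dosages


def simulate_dataset(params: SimParams | None = None, seed: int = 0) -> SimulatedDataset:
    """Run the full simulator: pedigree, founders, gene drop, trait, phenotypes.

    One master seed spawns independent child streams per stage, so any stage
    is reproducible in isolation.
    """
    params = params or SimParams()
    ss = np.random.SeedSequence(seed)
    s_founder, s_drop, s_arch, s_pheno = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)]

    ped = build_pedigree(params.n_sires, params.dams_per_sire, params.offspring_per_dam)
    gmap = build_genome_map(params.n_chrom, params.snps_per_chrom, params.chrom_length)
    n_founders = int(ped.is_founder.sum())
    founders = simulate_founder_genomes(gmap, n_founders, ne=params.ne,
                                        n_hist_generations=params.n_hist_generations,
                                        seed=s_founder)
    geno = gene_drop(ped, founders, seed=s_drop)
    founder_view = GenotypeData(gmap, founders.ids, geno.haplotypes[ped.is_founder])
    arch = assign_architecture(gmap, founder_view, h2=params.h2,
                               sigma2_g=params.sigma2_g, seed=s_arch,
                               epistatic_var_fraction=params.epistatic_var_fraction)
    tbv = compute_tbv(geno, arch)
    gvals = compute_genotypic_values(geno, arch)
    pheno = simulate_phenotypes(tbv, gvals, arch, ped,
                                phenotyped_fraction=params.phenotyped_fraction,
                                seed=s_pheno)
    keep = np.ones(gmap.n_loci, dtype=bool)
    keep[arch.qtl_locus_indices] = False
    markers = geno.subset_loci(np.flatnonzero(keep))
    return SimulatedDataset(params=params, seed=seed, pedigree=ped, genotypes=geno,
                            markers=markers, arch=arch, phenotypes=pheno)
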