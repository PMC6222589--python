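"""Forward-in-time breeding simulator.

Generates a synthetic phased base population and breeds discrete descendant
generations under a hierarchical sire/dam mating design: each sire is mated
to a fixed number of dams, one offspring per mating, and one mating per sire
is repeated (a fresh meiosis) so the census size stays constant across
generations.  Recombination follows a no-interference Poisson model: the
number of crossovers on a chromosome is Poisson with mean equal to the
chromosome length in Morgans, and crossover positions are uniform on the
genetic map.  There is no mutation and no selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "HaplotypePanel",
    "DEFAULT_CHROM_MBP",
    "default_map",
    "generate_base_panel",
    "simulate_meiosis",
    "breed_generation",
    "simulate_generations",
    "write_panel",
    "read_panel",
    "write_map",
    "read_map",
    "write_pedigree",
    "read_pedigree",
    "write_vcf",
]

#: Chromosome lengths (Mbp) of the default five-chromosome genome.  With the
#: default 1 cM/Mbp map these give 1-Mbp windows of 159/139/127/121/125 bins.
DEFAULT_CHROM_MBP = (159, 139, 127, 121, 125)

MALE, FEMALE = 0, 1
UNKNOWN_PARENT = -1


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Physical and genetic coordinates of the SNP panel.

    Parameters
    ----------
    lengths_bp
        Chromosome lengths in base pairs.
    lengths_morgan
        Chromosome lengths in Morgans; the Poisson crossover rate per meiosis.
    snp_pos_bp
        Per chromosome, ordered SNP positions in bp, strictly within
        ``(0, length_bp]``.
    snp_pos_morgan
        Per chromosome, SNP positions on the genetic map in Morgans,
        monotone non-decreasing and within ``[0, length_morgan]``.
    """

    lengths_bp: tuple[int, ...]
    lengths_morgan: tuple[float, ...]
    snp_pos_bp: tuple[np.ndarray, ...]
    snp_pos_morgan: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if not (len(self.lengths_bp) == len(self.lengths_morgan)
                == len(self.snp_pos_bp) == len(self.snp_pos_morgan)):
            raise ValueError("per-chromosome fields have unequal lengths")
        for c, (lb, lm, pb, pm) in enumerate(
                zip(self.lengths_bp, self.lengths_morgan,
                    self.snp_pos_bp, self.snp_pos_morgan)):
            if len(pb) != len(pm):
                raise ValueError(f"chromosome {c}: bp/Morgan position count mismatch")
            if len(pb) and (pb[0] <= 0 or pb[-1] > lb):
                raise ValueError(f"chromosome {c}: bp positions outside (0, {lb}]")
            if np.any(np.diff(pb) <= 0):
                raise ValueError(f"chromosome {c}: bp positions not strictly increasing")
            if len(pm) and (pm[0] < 0 or pm[-1] > lm):
                raise ValueError(f"chromosome {c}: genetic positions outside [0, {lm}]")
            if np.any(np.diff(pm) < 0):
                raise ValueError(f"chromosome {c}: genetic positions decreasing")

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths_bp)

    @property
    def n_snps_per_chrom(self) -> np.ndarray:
        return np.array([len(p) for p in self.snp_pos_bp])

    @property
    def n_snps(self) -> int:
        return int(self.n_snps_per_chrom.sum())

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Start index of each chromosome in the concatenated SNP order."""
        return np.concatenate([[0], np.cumsum(self.n_snps_per_chrom)])

    @property
    def snp_chrom(self) -> np.ndarray:
        """Chromosome index of each SNP in concatenated order."""
        return np.repeat(np.arange(self.n_chromosomes), self.n_snps_per_chrom)

    @property
    def all_pos_bp(self) -> np.ndarray:
        return np.concatenate(self.snp_pos_bp) if self.n_chromosomes else np.array([], int)


def default_map(n_snps: int = 11_154,
                chrom_mbp: tuple[int, ...] = DEFAULT_CHROM_MBP,
                cm_per_mbp: float = 1.0) -> GeneticMap:
    """Evenly spaced SNP map on the default genome.

    ``n_snps`` is split across chromosomes proportionally to physical length
    (largest-remainder rounding, so the counts sum exactly).  The genetic map
    is linear at ``cm_per_mbp`` (default 1 cM per Mbp, i.e. a 159 Mbp
    chromosome is 1.59 Morgans long).
    """
    lengths_bp = tuple(int(m * 1_000_000) for m in chrom_mbp)
    total = sum(lengths_bp)
    exact = np.array([n_snps * lb / total for lb in lengths_bp])
    counts = np.floor(exact).astype(int)
    rem = n_snps - counts.sum()
    counts[np.argsort(exact - np.floor(exact))[::-1][:rem]] += 1

    pos_bp, pos_m = [], []
    morgan_per_bp = cm_per_mbp / 100.0 / 1_000_000.0
    for lb, k in zip(lengths_bp, counts):
        if k < 1:
            raise ValueError("each chromosome needs at least one SNP")
        p = np.round((np.arange(k) + 0.5) / k * lb).astype(np.int64)
        p = np.maximum(p, 1)
        pos_bp.append(p)
        pos_m.append(p * morgan_per_bp)
    lengths_m = tuple(lb * morgan_per_bp for lb in lengths_bp)
    return GeneticMap(lengths_bp, lengths_m, tuple(pos_bp), tuple(pos_m))


# ---------------------------------------------------------------------------
# haplotype panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased genotypes of one generation.

    ``haplotypes`` has shape ``(n_individuals, 2, n_snps)`` with alleles in
    {0, 1}.  ``sex`` is 0 for males, 1 for females.
    """

    ids: np.ndarray
    haplotypes: np.ndarray
    gmap: GeneticMap
    sex: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        n, two, m = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_snps)")
        if m != self.gmap.n_snps:
            raise ValueError("haplotype length does not match the genetic map")
        if self.haplotypes.max(initial=0) > 1:
            raise ValueError("alleles must be 0/1")
        if len(self.ids) != n or len(self.sex) != n:
            raise ValueError("ids/sex length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """0/1/2 allele-count matrix (individuals x SNPs)."""
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.reshape(-1, self.n_snps).mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _meiosis_pattern(gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Sample which parental haplotype (0/1) each SNP is copied from.

    Crossover counts are Poisson(chromosome length in Morgans), positions
    uniform on the genetic map; each chromosome independently starts from a
    random haplotype.  A 0-Morgan chromosome is transmitted intact.
    """
    pattern = np.empty(gmap.n_snps, dtype=np.uint8)
    off = gmap.chrom_offsets
    for c in range(gmap.n_chromosomes):
        lm = gmap.lengths_morgan[c]
        start = rng.integers(0, 2)
        n_co = rng.poisson(lm) if lm > 0 else 0
        pos = gmap.snp_pos_morgan[c]
        if n_co == 0:
            pattern[off[c]:off[c + 1]] = start
            continue
        locs = np.sort(rng.uniform(0.0, lm, size=n_co))
        seg = np.searchsorted(locs, pos, side="right")
        pattern[off[c]:off[c + 1]] = (start + seg) % 2
    return pattern


def simulate_meiosis(parent_haplotypes: np.ndarray, gmap: GeneticMap,
                     rng: np.random.Generator) -> np.ndarray:
    """Produce one gamete from a parent's two phased haplotypes."""
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape != (2, gmap.n_snps):
        raise ValueError("parent haplotypes must have shape (2, n_snps)")
    pattern = _meiosis_pattern(gmap, rng)
    return parent_haplotypes[pattern, np.arange(gmap.n_snps)]


# ---------------------------------------------------------------------------
# base panel
# ---------------------------------------------------------------------------

def generate_base_panel(n_individuals: int, gmap: GeneticMap,
                        maf_floor: float = 0.01,
                        seed: int | np.random.Generator | None = None,
                        n_males: int | None = None,
                        effective_size: float = 100.0,
                        mutation_rate: float = 2e-8) -> HaplotypePanel:
    """Synthesize a phased base population with realistic local LD.

    Per chromosome a neutral coalescent with recombination is simulated
    (``effective_size`` defaults to 100, the order of a commercial dairy
    cattle effective population; the recombination rate comes from the
    genetic map), and the panel is then "array-ascertained": for each target
    SNP position of the map, the nearby segregating site whose MAF is
    closest to a Uniform(maf_floor, 0.5) draw is kept.  This mimics the
    flat, common-variant-enriched spectrum of a genotyping array (mean SNP
    MAF around 0.25) while preserving the coalescent's within-chromosome
    linkage disequilibrium, and guarantees exactly the requested SNP count.

    ``n_males`` individuals (default: a tenth, the 1:10 sire:dam design) are
    flagged male, the rest female, at random positions.
    """
    import msprime

    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if not 0.0 <= maf_floor < 0.5:
        raise ValueError(f"maf_floor must be in [0, 0.5); got {maf_floor} "
                         "(no SNP can have MAF >= 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = gmap.n_snps
    if m == 0 or np.any(gmap.n_snps_per_chrom < 1):
        raise ValueError("every chromosome must carry at least one SNP")

    n = n_individuals
    haps = np.empty((n, 2, m), dtype=np.uint8)
    off = gmap.chrom_offsets
    for c in range(gmap.n_chromosomes):
        L = gmap.lengths_bp[c]
        rate = gmap.lengths_morgan[c] / L  # Morgan per bp
        ts = msprime.sim_ancestry(
            samples=n, ploidy=2, sequence_length=L,
            recombination_rate=rate, population_size=effective_size,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        mts = msprime.sim_mutations(
            ts, rate=mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(rng.integers(1, 2**31 - 1)))
        G = mts.genotype_matrix()          # sites x haplotypes, 0/1
        site_pos = mts.tables.sites.position
        freq = G.mean(axis=1)
        maf = np.minimum(freq, 1.0 - freq)
        min_maf = max(maf_floor, 0.5 / n)  # at least not a singleton
        usable = maf >= min_maf
        targets = gmap.snp_pos_bp[c]
        if usable.sum() < len(targets):
            raise RuntimeError(
                f"chromosome {c}: only {int(usable.sum())} segregating sites "
                f"with MAF >= {min_maf:.3g} for {len(targets)} target SNPs; "
                "increase mutation_rate or lower maf_floor")
        cand_pos = site_pos[usable]
        cand_maf = maf[usable]
        cand_rows = np.flatnonzero(usable)
        used = np.zeros(len(cand_pos), dtype=bool)
        window = 40                        # nearest sites considered per target
        for t, bp in enumerate(targets):
            centre = np.searchsorted(cand_pos, bp)
            lo = max(centre - window, 0)
            hi = min(centre + window, len(cand_pos))
            free = np.flatnonzero(~used[lo:hi]) + lo
            if len(free) == 0:
                raise RuntimeError(
                    f"chromosome {c}: no unused segregating site near "
                    f"position {bp}")
            target_maf = rng.uniform(maf_floor, 0.5)
            pick = free[np.argmin(np.abs(cand_maf[free] - target_maf))]
            used[pick] = True
            haps[:, :, off[c] + t] = G[cand_rows[pick]].reshape(n, 2)

    if n_males is None:
        n_males = max(1, round(n / 11))  # 1 sire : 10 dams census ratio
    if not 0 < n_males < n:
        raise ValueError("n_males must be in (0, n_individuals)")
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[rng.choice(n, size=n_males, replace=False)] = MALE

    return HaplotypePanel(ids=np.arange(n), haplotypes=haps, gmap=gmap,
                          sex=sex, generation=0)


# ---------------------------------------------------------------------------
# breeding
# ---------------------------------------------------------------------------

def _pedigree_frame(ids, sires, dams, sexes, generation, replicate) -> pd.DataFrame:
    return pd.DataFrame({
        "id": np.asarray(ids, dtype=np.int64),
        "sire": np.asarray(sires, dtype=np.int64),
        "dam": np.asarray(dams, dtype=np.int64),
        "sex": np.asarray(sexes, dtype=np.int8),
        "generation": generation,
        "replicate": np.asarray(replicate, dtype=np.int8),
    })


def base_pedigree(panel: HaplotypePanel) -> pd.DataFrame:
    """Pedigree rows for founder animals (unknown parents, coded -1)."""
    n = panel.n_individuals
    return _pedigree_frame(panel.ids, np.full(n, UNKNOWN_PARENT),
                           np.full(n, UNKNOWN_PARENT), panel.sex,
                           panel.generation, np.zeros(n))


def breed_generation(panel: HaplotypePanel, rng: np.random.Generator,
                     dams_per_sire: int = 10,
                     next_id: int | None = None
                     ) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Breed one generation under the hierarchical mating design.

    Every male is used as a sire and mated to ``dams_per_sire`` distinct
    females (a random partition of the dams), one offspring per mating; one
    of each sire's matings, chosen uniformly, is repeated with a fresh
    meiosis.  With :math:`s` sires this yields ``s * (dams_per_sire + 1)``
    offspring — 2,200 under the full 200-sire design — of which a fraction
    equal to the parental male fraction is flagged male at random.
    """
    males = np.flatnonzero(panel.sex == MALE)
    females = np.flatnonzero(panel.sex == FEMALE)
    n_sires = len(males)
    need_dams = n_sires * dams_per_sire
    if n_sires < 1:
        raise ValueError("no males available to use as sires")
    if len(females) < need_dams:
        raise ValueError(
            f"need {need_dams} females for {n_sires} sires x {dams_per_sire} "
            f"dams, have {len(females)}")

    dams = rng.permutation(females)[:need_dams].reshape(n_sires, dams_per_sire)
    sire_col, dam_col = [], []
    replicate = []
    for k, s in enumerate(males):
        for d in dams[k]:
            sire_col.append(s)
            dam_col.append(d)
            replicate.append(0)
        # the repeated mating: a new meiosis, not a copied offspring
        sire_col.append(s)
        dam_col.append(dams[k, rng.integers(dams_per_sire)])
        replicate.append(1)
    sire_idx = np.array(sire_col)
    dam_idx = np.array(dam_col)
    n_off = len(sire_idx)

    m = panel.n_snps
    off_haps = np.empty((n_off, 2, m), dtype=np.uint8)
    for i in range(n_off):
        off_haps[i, 0] = simulate_meiosis(panel.haplotypes[sire_idx[i]], panel.gmap, rng)
        off_haps[i, 1] = simulate_meiosis(panel.haplotypes[dam_idx[i]], panel.gmap, rng)

    n_parents = len(males) + len(females)
    n_off_males = max(1, round(n_off * n_sires / n_parents))
    sex = np.full(n_off, FEMALE, dtype=np.int8)
    sex[rng.choice(n_off, size=n_off_males, replace=False)] = MALE

    if next_id is None:
        next_id = int(panel.ids.max()) + 1
    ids = np.arange(next_id, next_id + n_off)
    offspring = HaplotypePanel(ids=ids, haplotypes=off_haps, gmap=panel.gmap,
                               sex=sex, generation=panel.generation + 1)
    ped = _pedigree_frame(ids, panel.ids[sire_idx], panel.ids[dam_idx], sex,
                          offspring.generation, replicate)
    return offspring, ped


def simulate_generations(base: HaplotypePanel, n_generations: int,
                         rng: np.random.Generator, dams_per_sire: int = 10
                         ) -> tuple[list[HaplotypePanel], pd.DataFrame]:
    """Chain ``breed_generation`` for G1..Gn starting from a base panel.

    Returns the descendant panels (the base panel is generation 0, the
    reference population) and the full pedigree including founders.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    panels = []
    peds = [base_pedigree(base)]
    current = base
    for _ in range(n_generations):
        current, ped = breed_generation(current, rng, dams_per_sire=dams_per_sire)
        panels.append(current)
        peds.append(ped)
    return panels, pd.concat(peds, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_panel(panel: HaplotypePanel, path) -> None:
    """Delimited text, one row per haplotype: id, hap index, alleles."""
    n, _, m = panel.haplotypes.shape
    with open(path, "w") as fh:
        fh.write("id\thap\t" + "\t".join(f"s{j}" for j in range(m)) + "\n")
        for i in range(n):
            for h in range(2):
                alleles = "\t".join(map(str, panel.haplotypes[i, h]))
                fh.write(f"{panel.ids[i]}\t{h}\t{alleles}\n")


def read_panel(path, gmap: GeneticMap, sex: np.ndarray | None = None,
               generation: int = 0) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    ids = df["id"].to_numpy()[::2]
    haps = df.iloc[:, 2:].to_numpy(dtype=np.uint8).reshape(len(ids), 2, -1)
    if sex is None:
        sex = np.full(len(ids), FEMALE, dtype=np.int8)
    return HaplotypePanel(ids=ids, haplotypes=haps, gmap=gmap, sex=sex,
                          generation=generation)


def write_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tsnp_id\tpos_bp\tpos_cM\n")
        j = 0
        for c in range(gmap.n_chromosomes):
            for bp, morgan in zip(gmap.snp_pos_bp[c], gmap.snp_pos_morgan[c]):
                fh.write(f"{c + 1}\ts{j}\t{bp}\t{morgan * 100:.6f}\n")
                j += 1


def read_map(path, lengths_bp=None, cm_per_mbp: float = 1.0) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    pos_bp, pos_m, lb, lm = [], [], [], []
    for _, grp in df.groupby("chrom", sort=True):
        pb = grp["pos_bp"].to_numpy(dtype=np.int64)
        pm = grp["pos_cM"].to_numpy(dtype=float) / 100.0
        pos_bp.append(pb)
        pos_m.append(pm)
        length = int(np.ceil(pb[-1] / 1_000_000) * 1_000_000)
        lb.append(length)
        lm.append(length * cm_per_mbp / 100.0 / 1_000_000.0)
    if lengths_bp is not None:
        lb = list(lengths_bp)
        lm = [x * cm_per_mbp / 100.0 / 1_000_000.0 for x in lb]
    return GeneticMap(tuple(lb), tuple(lm), tuple(pos_bp), tuple(pos_m))


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.astype({"id": np.int64, "sire": np.int64, "dam": np.int64,
                      "sex": np.int8, "replicate": np.int8})


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Minimal phased VCFv4.2 export (GT only) for interoperability."""
    gmap = panel.gmap
    chroms = gmap.snp_chrom
    pos = gmap.all_pos_bp
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=wgblup.popsim\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID={c + 1},length={gmap.lengths_bp[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{int(i)}" for i in panel.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        H = panel.haplotypes
        for j in range(panel.n_snps):
            gts = "\t".join(f"{H[i, 0, j]}|{H[i, 1, j]}" for i in range(panel.n_individuals))
            fh.write(f"{chroms[j] + 1}\t{pos[j]}\ts{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")
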