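"""Forward simulator of the digenic-recessive breeding design.

Simulates the crossing scheme used to dissect a duplicate-recessive
(epistatic) leaf-colour trait: two fully homozygous parents (the mutant and
a wild doubled-haploid line), reciprocal F1, a selfed F2, backcrosses to
both parents, F2:3 families from selfed green F2 plants, and F3:4 families
from green plants of the 3:1-segregating F2:3 families.  On top of the
pedigree it generates the two downstream sequencing-style datasets: pooled
per-SNP allele read counts for the extreme bulks (bulked-segregant
analysis) and per-gene expression read counts for the two pools.

Meiosis is a Poisson crossover process without interference on the cM
axis; at the simulated loci this is realised exactly by independent
Bernoulli haplotype switches per adjacent-locus interval with the Haldane
probability (1 − e^(−2d/100))/2, which keeps gamete generation fully
vectorised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import MUTANT_ALLELE, WILD_ALLELE, GenomeModel, default_genome

__all__ = [
    "GREEN",
    "YELLOW",
    "DiploidIndividual",
    "Family",
    "BulkSpec",
    "StudyConfig",
    "StudyDataset",
    "NoSegregatingFamilyError",
    "phenotype_of",
    "gametogenesis",
    "gametes",
    "make_offspring",
    "make_founder",
    "simulate_study",
    "simulate_mapping_population",
    "simulate_bulk_counts",
    "simulate_expression_counts",
    "marker_genotype_table",
    "expected_pool_frequencies",
    "DeGene",
    "make_gene_annotation",
]

GREEN = "green"
YELLOW = "yellow"


class NoSegregatingFamilyError(RuntimeError):
    """Raised when a requested generation cannot be built from the realized
    families (e.g. no 3:1 F2:3 family appeared; re-seed or enlarge)."""


def phenotype_of(causal_genotypes) -> str:
    """Phenotype from the diploid genotypes at the causal loci.

    The trait is recessive-epistatic: the mutant (yellow) phenotype appears
    only when *every* causal locus is homozygous for the mutant allele;
    neither locus alone produces it.  ``causal_genotypes`` is a sequence of
    ``(allele, allele)`` pairs, one per causal locus (two for the digenic
    model).
    """
    genotypes = list(causal_genotypes)
    if not genotypes:
        raise ValueError("no causal genotypes supplied: malformed individual")
    for g in genotypes:
        if g is None or len(g) != 2 or any(a is None for a in g):
            raise ValueError("missing causal genotype: malformed individual")
    return (
        YELLOW
        if all(g[0] == MUTANT_ALLELE and g[1] == MUTANT_ALLELE for g in genotypes)
        else GREEN
    )


@dataclass
class DiploidIndividual:
    """One plant: two haplotypes over the genome's flat locus layout."""

    id: str
    generation: str
    hap1: np.ndarray
    hap2: np.ndarray
    genome: GenomeModel
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        n = self.genome.n_loci
        if len(self.hap1) != n or len(self.hap2) != n:
            raise ValueError("haplotype length does not match genome locus count")

    def causal_genotypes(self) -> list[tuple[int, int]]:
        idx = self.genome.causal_indices
        return [(int(self.hap1[i]), int(self.hap2[i])) for i in idx]

    @property
    def phenotype(self) -> str:
        return phenotype_of(self.causal_genotypes())

    def allele_counts(self) -> np.ndarray:
        """Mutant-allele dosage (0/1/2) at every locus."""
        return self.hap1.astype(np.int64) + self.hap2.astype(np.int64)


@dataclass
class Family:
    id: str
    generation: str
    parents: tuple[str, str]
    members: list[DiploidIndividual]
    #: phenotype of the family's own parent plant(s), for bookkeeping
    parent_individuals: tuple[DiploidIndividual, ...] = ()

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_green(self) -> int:
        return sum(1 for m in self.members if m.phenotype == GREEN)

    @property
    def n_yellow(self) -> int:
        return len(self.members) - self.n_green

    def phenotype_counts(self) -> tuple[int, int, int]:
        g = self.n_green
        return len(self.members), g, len(self.members) - g

    def members_with_phenotype(self, phenotype: str) -> list[DiploidIndividual]:
        return [m for m in self.members if m.phenotype == phenotype]


def make_founder(genome: GenomeModel, allele: int, id: str, generation: str = "P") -> DiploidIndividual:
    """Fully homozygous founder (doubled-haploid) carrying one allele
    everywhere: ``MUTANT_ALLELE`` for the mutant line, ``WILD_ALLELE`` for
    the wild line."""
    hap = np.full(genome.n_loci, allele, dtype=np.int8)
    return DiploidIndividual(id, generation, hap.copy(), hap.copy(), genome)


def gametes(parent: DiploidIndividual, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` gametes from ``parent`` as an ``(n, n_loci)`` allele array.

    The strand in use at each locus follows the cumulative parity of
    Bernoulli switches whose probabilities are the Haldane recombination
    fractions of the inter-locus intervals (0.5 across chromosome
    boundaries), i.e. the exact marginal law of Poisson crossovers at the
    simulated loci.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = parent.genome._switch_p
    switches = rng.random((n, len(p))) < p
    source = np.cumsum(switches, axis=1) & 1  # 0 → hap1, 1 → hap2
    return np.where(source == 1, parent.hap2[None, :], parent.hap1[None, :]).astype(np.int8)


def gametogenesis(parent: DiploidIndividual, rng: np.random.Generator) -> np.ndarray:
    """One gamete (haplotype vector) from ``parent``."""
    return gametes(parent, 1, rng)[0]


def make_offspring(
    p1: DiploidIndividual,
    p2: DiploidIndividual,
    n: int,
    rng: np.random.Generator,
    generation: str = "offspring",
    id_prefix: str | None = None,
) -> list[DiploidIndividual]:
    """Cross ``p1`` × ``p2`` (selfing when ``p1 is p2``), returning ``n``
    offspring, each from one independent gamete per parent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if p1.genome is not p2.genome:
        raise ValueError("parents must share a genome model")
    g1 = gametes(p1, n, rng)
    g2 = gametes(p2, n, rng)
    prefix = id_prefix or generation
    return [
        DiploidIndividual(
            f"{prefix}_{i + 1}", generation, g1[i], g2[i], p1.genome, (p1.id, p2.id)
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Family sizes for each generation of the breeding design.

    Defaults are the observed population sizes of the study this design
    emulates (F1 reciprocal 258/226, BC1 669/720, F2 2376); F2:3/F3:4 family
    sizes are not printed there and are set to realistic selfed-family
    sizes.  ``n_f23_families=0`` stops the design after BC1/F2.
    """

    n_f1_forward: int = 258
    n_f1_reverse: int = 226
    n_bc1_wild: int = 669
    n_bc1_mutant: int = 720
    n_f2: int = 2376
    n_f23_families: int = 20
    f23_family_size: int = 100
    n_f23_selfed_per_family: int = 8
    f34_family_size: int = 200
    seed: int | None = None


@dataclass
class StudyDataset:
    genome: GenomeModel
    config: StudyConfig
    parents: dict[str, DiploidIndividual]
    families: dict[str, Family]
    f23_families: list[Family] = field(default_factory=list)
    f34_families: list[Family] = field(default_factory=list)

    def all_families(self) -> list[Family]:
        return [*self.families.values(), *self.f23_families, *self.f34_families]

    def all_individuals(self):
        for fam in self.all_families():
            yield from fam.members


def _family_segregation_label(n_total: int, n_green: int, n_yellow: int) -> str:
    # local import: segregation depends only on counts, not on the simulator
    from .segregation import SegregationCount, classify_family

    return classify_family(SegregationCount(n_total, n_green, n_yellow)).label


def simulate_study(
    config: StudyConfig,
    rng: np.random.Generator | int | None = None,
    genome: GenomeModel | None = None,
) -> StudyDataset:
    """Run the full breeding design and return all families with pedigree.

    F3:4 families are produced only by selfing green plants of the
    3:1-segregating F2:3 families, mirroring the design that separates the
    two causal genes.  If the design requests F3:4 families but no F2:3
    family realized a 3:1 segregation, a
    :class:`NoSegregatingFamilyError` is raised (re-seed or enlarge).
    """
    if genome is None:
        genome = default_genome()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))

    mutant = make_founder(genome, MUTANT_ALLELE, "pylm", "P2")
    wild = make_founder(genome, WILD_ALLELE, "FT", "P1")
    parents = {"mutant": mutant, "wild": wild}

    families: dict[str, Family] = {}
    f1_fwd = make_offspring(wild, mutant, config.n_f1_forward, rng, "F1", "F1f")
    f1_rev = make_offspring(mutant, wild, config.n_f1_reverse, rng, "F1", "F1r")
    families["F1_forward"] = Family("F1_forward", "F1", (wild.id, mutant.id), f1_fwd)
    families["F1_reverse"] = Family("F1_reverse", "F1", (mutant.id, wild.id), f1_rev)

    f1_plant = f1_fwd[0]
    families["BC1_wild"] = Family(
        "BC1_wild",
        "BC1",
        (f1_plant.id, wild.id),
        make_offspring(f1_plant, wild, config.n_bc1_wild, rng, "BC1", "BC1w"),
    )
    families["BC1_mutant"] = Family(
        "BC1_mutant",
        "BC1",
        (f1_plant.id, mutant.id),
        make_offspring(f1_plant, mutant, config.n_bc1_mutant, rng, "BC1", "BC1m"),
    )
    f2_members = make_offspring(f1_plant, f1_plant, config.n_f2, rng, "F2")
    families["F2"] = Family("F2", "F2", (f1_plant.id, f1_plant.id), f2_members)

    dataset = StudyDataset(genome, config, parents, families)
    if config.n_f23_families <= 0:
        return dataset

    green_f2 = families["F2"].members_with_phenotype(GREEN)
    if len(green_f2) < config.n_f23_families:
        raise NoSegregatingFamilyError("not enough green F2 plants to self")
    chosen = rng.choice(len(green_f2), size=config.n_f23_families, replace=False)
    for k, idx in enumerate(chosen, start=1):
        parent = green_f2[int(idx)]
        members = make_offspring(
            parent, parent, config.f23_family_size, rng, "F2:3", f"F23_{k}"
        )
        dataset.f23_families.append(
            Family(f"F23_{k}", "F2:3", (parent.id, parent.id), members, (parent,))
        )

    if config.f34_family_size <= 0:
        return dataset

    seg31 = [
        fam
        for fam in dataset.f23_families
        if _family_segregation_label(*fam.phenotype_counts()) == "seg_3_1"
    ]
    if not seg31:
        raise NoSegregatingFamilyError(
            "no 3:1-segregating F2:3 family realized; re-seed or enlarge the design"
        )
    fam_no = 0
    for fam in seg31:
        green_plants = fam.members_with_phenotype(GREEN)
        take = min(config.n_f23_selfed_per_family, len(green_plants))
        chosen = rng.choice(len(green_plants), size=take, replace=False)
        for idx in chosen:
            fam_no += 1
            parent = green_plants[int(idx)]
            members = make_offspring(
                parent, parent, config.f34_family_size, rng, "F3:4", f"F34_{fam_no}"
            )
            dataset.f34_families.append(
                Family(
                    f"F34_{fam_no}", "F3:4", (parent.id, parent.id), members, (parent,)
                )
            )
    return dataset


def simulate_mapping_population(
    parent: DiploidIndividual,
    n_recessive: int,
    rng: np.random.Generator,
    max_batches: int = 200,
) -> list[DiploidIndividual]:
    """Self ``parent`` until ``n_recessive`` yellow (recessive-class)
    offspring are collected — the fine-mapping population design, where
    every plant is homozygous mutant at the target locus."""
    collected: list[DiploidIndividual] = []
    batch = max(4 * n_recessive, 64)
    for _ in range(max_batches):
        for ind in make_offspring(parent, parent, batch, rng, "F3:4", "map"):
            if ind.phenotype == YELLOW:
                collected.append(ind)
                if len(collected) == n_recessive:
                    for i, m in enumerate(collected, start=1):
                        m.id = f"map_{i}"
                    return collected
    raise NoSegregatingFamilyError(
        "parent cannot produce enough recessive offspring (is it segregating?)"
    )


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------


@dataclass
class BulkSpec:
    """One extreme bulk: which phenotype, how many plants, sequencing model."""

    name: str  # "G-pool" or "Y-pool"
    phenotype: str
    pool_size: int = 100
    mean_depth: float = 30.0
    base_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool size must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be > 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base error rate must be in [0, 0.5)")


def _pool_alt_frequencies(
    family: Family, spec: BulkSpec, rng: np.random.Generator
) -> np.ndarray:
    members = family.members_with_phenotype(spec.phenotype)
    if len(members) < spec.pool_size:
        raise ValueError(
            f"family has only {len(members)} {spec.phenotype} plants; "
            f"pool of {spec.pool_size} requested"
        )
    chosen = rng.choice(len(members), size=spec.pool_size, replace=False)
    dosage = np.zeros(family.members[0].genome.n_loci, dtype=np.int64)
    for idx in chosen:
        dosage += members[int(idx)].allele_counts()
    return dosage / (2 * spec.pool_size)


def simulate_bulk_counts(
    f2_family: Family,
    g_spec: BulkSpec,
    y_spec: BulkSpec,
    rng: np.random.Generator,
    genome: GenomeModel | None = None,
) -> pd.DataFrame:
    """Pooled per-SNP read counts for the two extreme bulks.

    For each locus of the genome panel (background markers plus the causal
    positions) the pool's true alternate-allele frequency is the mean
    mutant-allele dosage of the sampled plants; sequencing applies a
    symmetric base-error e (observed frequency f(1−e) + (1−f)e), a
    Poisson-distributed total depth and binomial allele sampling.
    """
    if genome is None:
        genome = f2_family.members[0].genome
    out = {}
    for spec in (g_spec, y_spec):
        f = _pool_alt_frequencies(f2_family, spec, rng)
        e = spec.base_error_rate
        f_obs = f * (1 - e) + (1 - f) * e
        depth = rng.poisson(spec.mean_depth, size=len(f))
        alt = rng.binomial(depth, f_obs)
        out[spec.name] = (depth - alt, alt)
    return pd.DataFrame(
        {
            "chrom": genome.locus_chrom,
            "pos": genome.locus_pos_bp,
            "ref": "A",
            "alt": "G",
            "ref_count_G": out[g_spec.name][0],
            "alt_count_G": out[g_spec.name][1],
            "ref_count_Y": out[y_spec.name][0],
            "alt_count_Y": out[y_spec.name][1],
        }
    )


def expected_pool_frequencies() -> dict[str, float]:
    """Expected mutant-allele frequency at a causal locus in each bulk,
    by exhaustive enumeration of the 16 F2 gamete combinations.

    Yellow plants are homozygous mutant at both loci (frequency 1); green
    F2 plants are a 4:8:3 mix of PP:Pp:pp at either causal locus, giving
    7/15.  Computed, not hard-coded.
    """
    from fractions import Fraction

    gametes_ = list(itertools.product((WILD_ALLELE, MUTANT_ALLELE), repeat=2))
    green_dosage = Fraction(0)
    n_green = 0
    for gam1, gam2 in itertools.product(gametes_, repeat=2):
        g_locus1 = (gam1[0], gam2[0])
        g_locus2 = (gam1[1], gam2[1])
        if phenotype_of([g_locus1, g_locus2]) == GREEN:
            n_green += 1
            green_dosage += Fraction(sum(g_locus1), 2)
    return {
        "Y-pool": 1.0,
        "G-pool": float(green_dosage / n_green),
    }


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeGene:
    """A configured differentially expressed gene: Y-pool rate = fold ×
    G-pool rate (fold < 1 means downregulated in the mutant pool)."""

    gene_id: str
    fold: float
    base_mean: float = 400.0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold change must be > 0")
        if self.base_mean <= 0:
            raise ValueError("base mean must be > 0")


def make_gene_annotation(
    genome: GenomeModel,
    genes_per_chromosome: int = 500,
    gene_length_bp: int = 2000,
) -> pd.DataFrame:
    """Synthetic gene annotation on an even grid, with one gene spanning
    each causal locus (named after it) so the causal genes exist in the
    annotation.  Columns: gene_id, chrom, start, end, strand."""
    rows = []
    for c in genome.chromosomes:
        spacing = c.length_bp / genes_per_chromosome
        for j in range(genes_per_chromosome):
            start = int(round(j * spacing)) + 1
            rows.append(
                {
                    "gene_id": f"G{c.id}_{j + 1:04d}",
                    "chrom": c.id,
                    "start": start,
                    "end": start + gene_length_bp - 1,
                    "strand": "+",
                }
            )
    ann = pd.DataFrame(rows)
    for locus in genome.causal_loci:
        sel = ann["chrom"] == locus.chrom
        span = (ann["start"] <= locus.pos_bp) & (ann["end"] >= locus.pos_bp) & sel
        if span.any():
            ann.loc[span[span].index[0], "gene_id"] = f"gene_{locus.id}"
        else:
            # move the nearest gene on that chromosome to span the locus
            idx = (ann.loc[sel, "start"] - locus.pos_bp).abs().idxmin()
            half = gene_length_bp // 2
            ann.loc[idx, ["gene_id", "start", "end"]] = [
                f"gene_{locus.id}",
                locus.pos_bp - half,
                locus.pos_bp - half + gene_length_bp - 1,
            ]
    return ann.sort_values(["chrom", "start"], ignore_index=True)


def simulate_expression_counts(
    annotation: pd.DataFrame,
    de_genes: list[DeGene],
    rng: np.random.Generator,
    base_mean: float = 80.0,
    dispersion_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-gene read counts for the G-pool and Y-pool.

    Non-DE genes share one expected rate in both pools (log-normal across
    genes around ``base_mean``); configured DE genes use their own base
    mean in the G-pool scaled by ``fold`` in the Y-pool.  Counts are
    Poisson.  Columns: gene_id, chrom, start, end, length_bp, count_G,
    count_Y.
    """
    de_by_id = {d.gene_id: d for d in de_genes}
    unknown = set(de_by_id) - set(annotation["gene_id"])
    if unknown:
        raise ValueError(f"DE genes not in annotation: {sorted(unknown)[:5]}")
    n = len(annotation)
    mu_g = np.exp(rng.normal(np.log(base_mean), dispersion_sd, size=n))
    mu_y = mu_g.copy()
    gene_ids = annotation["gene_id"].to_numpy()
    for i, gid in enumerate(gene_ids):
        d = de_by_id.get(gid)
        if d is not None:
            mu_g[i] = d.base_mean
            mu_y[i] = d.base_mean * d.fold
    table = annotation[["gene_id", "chrom", "start", "end"]].copy()
    table["length_bp"] = table["end"] - table["start"] + 1
    table["count_G"] = rng.poisson(mu_g)
    table["count_Y"] = rng.poisson(mu_y)
    return table


# ---------------------------------------------------------------------------
# marker genotype export
# ---------------------------------------------------------------------------


def marker_genotype_table(
    individuals: list[DiploidIndividual],
    genome: GenomeModel | None = None,
    chrom: str | None = None,
    informative_parent: DiploidIndividual | None = None,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Individuals × markers A/H/B genotype table for linkage analysis.

    A = homozygous mutant-parent allele, H = heterozygous, B = homozygous
    wild-parent allele; optional random missing calls ('-') emulate failed
    PCR scores.  Causal loci are excluded (they are not scorable markers).
    When ``informative_parent`` is given, only markers heterozygous in that
    plant are kept — the marker-screening step of a selfed mapping family,
    where markers fixed in the family's parent are uninformative.
    """
    if not individuals:
        raise ValueError("no individuals")
    if genome is None:
        genome = individuals[0].genome
    keep = ~genome.locus_is_causal
    if chrom is not None:
        keep &= genome.locus_chrom == chrom
    if informative_parent is not None:
        keep &= informative_parent.hap1 != informative_parent.hap2
    idx = np.flatnonzero(keep)
    codes = np.array(["B", "H", "A"])
    rows = {}
    for ind in individuals:
        dosage = ind.allele_counts()[idx]
        calls = codes[dosage]
        if missing_rate > 0:
            if rng is None:
                raise ValueError("missing_rate > 0 requires an rng")
            calls = np.where(rng.random(len(calls)) < missing_rate, "-", calls)
        rows[ind.id] = calls
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[str(n) for n in genome.locus_names[idx]]
    )
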