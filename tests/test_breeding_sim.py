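"""Breeding simulator: phenotype rule, meiosis, crosses, study design,
pooled read counts and expression counts."""

import math

import numpy as np
import pytest

from digenic_mapper.breeding_sim import (
    GREEN,
    YELLOW,
    BulkSpec,
    DeGene,
    NoSegregatingFamilyError,
    StudyConfig,
    expected_pool_frequencies,
    gametes,
    make_founder,
    make_gene_annotation,
    make_offspring,
    marker_genotype_table,
    phenotype_of,
    simulate_bulk_counts,
    simulate_expression_counts,
    simulate_mapping_population,
    simulate_study,
)
from digenic_mapper.genome import (
    MUTANT_ALLELE,
    WILD_ALLELE,
    CausalLocus,
    Chromosome,
    GenomeModel,
    Marker,
    default_genome,
)

P, p = WILD_ALLELE, MUTANT_ALLELE


@pytest.mark.parametrize(
    "g1, g2, expected",
    [
        ((p, p), (p, p), YELLOW),  # double homozygous mutant
        ((P, p), (p, p), GREEN),  # one locus heterozygous: not sufficient
        ((p, p), (P, p), GREEN),
        ((P, P), (P, P), GREEN),  # wild type
        ((P, p), (P, p), GREEN),  # F1
    ],
)
def test_phenotype_requires_both_loci_homozygous_mutant(g1, g2, expected):
    assert phenotype_of([g1, g2]) == expected


def test_phenotype_rejects_missing_genotypes():
    with pytest.raises(ValueError):
        phenotype_of([])
    with pytest.raises(ValueError):
        phenotype_of([(p, p), None])


def _two_locus_genome(d_cm: float, same_chrom: bool = True) -> GenomeModel:
    """Two marker loci d_cm apart (same or different chromosomes) plus the
    two causal loci far away on their own chromosomes."""
    chroms = [
        Chromosome("C01", 10_000_000, 100.0),
        Chromosome("C02", 10_000_000, 100.0),
        Chromosome("A07", 10_000_000, 100.0),
        Chromosome("A09", 10_000_000, 100.0),
    ]
    bp = lambda cm: max(int(cm * 100_000), 1)
    markers = [Marker("L1", "C01", bp(10.0), 10.0)]
    if same_chrom:
        markers.append(Marker("L2", "C01", bp(10.0 + d_cm), 10.0 + d_cm))
    else:
        markers.append(Marker("L2", "C02", bp(10.0), 10.0))
    causal = [
        CausalLocus("PY1", "A09", 5_000_000, 50.0),
        CausalLocus("PY2", "A07", 5_000_000, 50.0),
    ]
    return GenomeModel(chroms, markers, causal)


def _recombinant_fraction(genome, n, rng):
    """Fraction of gametes recombinant between markers L1 and L2 for a
    parent carrying mutant alleles on one haplotype and wild on the other."""
    parent = make_founder(genome, MUTANT_ALLELE, "mut")
    wildhap = np.zeros(genome.n_loci, dtype=np.int8)
    parent.hap2 = wildhap
    g = gametes(parent, n, rng)
    i, j = genome.locus_index("L1"), genome.locus_index("L2")
    return float(np.mean(g[:, i] != g[:, j]))


def test_zero_distance_loci_never_recombine(rng):
    genome = _two_locus_genome(0.0)
    assert _recombinant_fraction(genome, 20_000, rng) == 0.0


def test_unlinked_loci_assort_independently(rng):
    genome = _two_locus_genome(0.0, same_chrom=False)
    r = _recombinant_fraction(genome, 100_000, rng)
    assert abs(r - 0.5) < 3 * math.sqrt(0.25 / 100_000)


def test_50cm_recombination_matches_haldane_closed_form(rng):
    """No-interference crossovers: r = (1 - e^(-2d/100)) / 2, so 50 cM
    gives ~0.3161."""
    genome = _two_locus_genome(50.0)
    expected = 0.5 * (1 - math.exp(-1.0))
    r = _recombinant_fraction(genome, 100_000, rng)
    assert abs(r - expected) < 3 * math.sqrt(expected * (1 - expected) / 100_000)


def test_cross_of_mutant_and_wild_gives_green_double_heterozygotes(sparse_genome, rng):
    mut = make_founder(sparse_genome, MUTANT_ALLELE, "mut")
    wild = make_founder(sparse_genome, WILD_ALLELE, "wild")
    f1 = make_offspring(wild, mut, 10, rng)
    assert all(ind.phenotype == GREEN for ind in f1)
    assert all(g == (P, p) for ind in f1 for g in ind.causal_genotypes())


def test_self_of_mutant_is_all_yellow(sparse_genome, rng):
    mut = make_founder(sparse_genome, MUTANT_ALLELE, "mut")
    assert all(x.phenotype == YELLOW for x in make_offspring(mut, mut, 50, rng))


def test_f2_yellow_fraction_near_one_sixteenth(sparse_genome, rng):
    mut = make_founder(sparse_genome, MUTANT_ALLELE, "mut")
    wild = make_founder(sparse_genome, WILD_ALLELE, "wild")
    f1 = make_offspring(wild, mut, 1, rng)[0]
    f2 = make_offspring(f1, f1, 16_000, rng)
    frac = sum(1 for x in f2 if x.phenotype == YELLOW) / 16_000
    sd = math.sqrt((1 / 16) * (15 / 16) / 16_000)
    assert abs(frac - 1 / 16) < 3 * sd


def test_simulate_study_conserves_counts_and_pedigree(sparse_genome, small_study_config, rng):
    ds = simulate_study(small_study_config, rng, sparse_genome)
    for fam in ds.all_families():
        n, g, y = fam.phenotype_counts()
        assert g + y == n == len(fam)
    assert len(ds.families["F2"]) == small_study_config.n_f2
    assert len(ds.f23_families) == small_study_config.n_f23_families
    # F1 from homozygous parents is uniformly green both ways (nuclear trait)
    assert ds.families["F1_forward"].n_yellow == 0
    assert ds.families["F1_reverse"].n_yellow == 0
    # BC1 to the wild parent can never be yellow
    assert ds.families["BC1_wild"].n_yellow == 0


def test_f34_families_come_only_from_3_to_1_f23_parents(sparse_genome, small_study_config, rng):
    from digenic_mapper.segregation import SegregationCount, classify_family

    ds = simulate_study(small_study_config, rng, sparse_genome)
    assert ds.f34_families
    parent_ids = {fam.parents[0] for fam in ds.f34_families}
    seg31_green = set()
    for fam in ds.f23_families:
        if classify_family(SegregationCount(*fam.phenotype_counts())).label == "seg_3_1":
            seg31_green |= {m.id for m in fam.members_with_phenotype(GREEN)}
    assert parent_ids <= seg31_green


def test_simulate_study_errors_when_no_31_family_realized(sparse_genome):
    """With a single tiny F2:3 family the 3:1 class is often missed; the
    design then cannot build F3:4 and must say so."""
    config = StudyConfig(
        n_f1_forward=2, n_f1_reverse=2, n_bc1_wild=2, n_bc1_mutant=2,
        n_f2=60, n_f23_families=1, f23_family_size=30, f34_family_size=10,
    )
    with pytest.raises(NoSegregatingFamilyError):
        # seed chosen so the one selfed family is not 3:1
        simulate_study(config, np.random.default_rng(0), sparse_genome)


def test_bulk_spec_validation():
    with pytest.raises(ValueError):
        BulkSpec("G-pool", GREEN, pool_size=0)
    with pytest.raises(ValueError):
        BulkSpec("G-pool", GREEN, mean_depth=0)
    with pytest.raises(ValueError):
        BulkSpec("G-pool", GREEN, base_error_rate=0.5)


def test_bulk_counts_causal_locus_frequencies(sparse_genome, rng):
    """Y-pool is fixed for the mutant allele at the causal loci; the green
    pool sits near the 7/15 enumeration expectation."""
    config = StudyConfig(n_f2=2376, n_f23_families=0)
    ds = simulate_study(config, rng, sparse_genome)
    table = simulate_bulk_counts(
        ds.families["F2"],
        BulkSpec("G-pool", GREEN, 100, 500.0, 0.0),
        BulkSpec("Y-pool", YELLOW, 100, 500.0, 0.0),
        rng,
        sparse_genome,
    )
    for locus in sparse_genome.causal_loci:
        row = table[
            (table["chrom"] == locus.chrom)
            & (table["pos"] == locus.pos_bp)
        ].iloc[0]
        f_y = row["alt_count_Y"] / (row["ref_count_Y"] + row["alt_count_Y"])
        f_g = row["alt_count_G"] / (row["ref_count_G"] + row["alt_count_G"])
        assert f_y == 1.0
        # pool-sampling SD at n=100 is ~0.035; allow 3.5 SD plus depth noise
        assert abs(f_g - 7 / 15) < 0.13


def test_bulk_counts_unlinked_marker_frequency_difference_small(sparse_genome, rng):
    config = StudyConfig(n_f2=2000, n_f23_families=0)
    ds = simulate_study(config, rng, sparse_genome)
    table = simulate_bulk_counts(
        ds.families["F2"],
        BulkSpec("G-pool", GREEN, 100, 2000.0, 0.0),
        BulkSpec("Y-pool", YELLOW, 100, 2000.0, 0.0),
        rng,
        sparse_genome,
    )
    # markers on chromosomes without a causal locus
    causal_chroms = {c.chrom for c in sparse_genome.causal_loci}
    bg = table[~table["chrom"].isin(causal_chroms)]
    f_g = bg["alt_count_G"] / (bg["ref_count_G"] + bg["alt_count_G"])
    f_y = bg["alt_count_Y"] / (bg["ref_count_Y"] + bg["alt_count_Y"])
    assert (f_g - f_y).abs().mean() < 0.06


def test_bulk_counts_requires_enough_yellow_plants(sparse_genome, rng):
    config = StudyConfig(n_f2=100, n_f23_families=0)
    ds = simulate_study(config, rng, sparse_genome)
    with pytest.raises(ValueError, match="pool"):
        simulate_bulk_counts(
            ds.families["F2"],
            BulkSpec("G-pool", GREEN, 100),
            BulkSpec("Y-pool", YELLOW, 100),
            rng,
            sparse_genome,
        )


def test_expected_pool_frequencies_enumeration():
    freqs = expected_pool_frequencies()
    assert freqs["Y-pool"] == 1.0
    assert freqs["G-pool"] == pytest.approx(7 / 15)


def test_mapping_population_is_recessive_class(sparse_genome, rng):
    mut = make_founder(sparse_genome, MUTANT_ALLELE, "mut")
    wild = make_founder(sparse_genome, WILD_ALLELE, "wild")
    f1 = make_offspring(wild, mut, 1, rng)[0]
    # force a 3:1-type parent: heterozygous at PY1, homozygous mutant at PY2
    i1 = sparse_genome.locus_index("PY1")
    i2 = sparse_genome.locus_index("PY2")
    parent = make_founder(sparse_genome, MUTANT_ALLELE, "par")
    parent.hap1[i1] = WILD_ALLELE
    pop = simulate_mapping_population(parent, 200, rng)
    assert len(pop) == 200
    assert all(x.phenotype == YELLOW for x in pop)
    assert all(x.allele_counts()[i2] == 2 for x in pop)
    assert f1.phenotype == GREEN  # sanity on the cross itself


def test_marker_genotype_table_codes_and_informative_filter(sparse_genome, rng):
    mut = make_founder(sparse_genome, MUTANT_ALLELE, "mut")
    wild = make_founder(sparse_genome, WILD_ALLELE, "wild")
    f1 = make_offspring(wild, mut, 3, rng)
    table = marker_genotype_table(f1, sparse_genome)
    assert (table == "H").all().all()  # F1 is heterozygous everywhere
    table_mut = marker_genotype_table([mut], sparse_genome)
    assert (table_mut == "A").all().all()
    # a homozygous "parent" leaves no informative marker
    empty = marker_genotype_table(f1, sparse_genome, informative_parent=mut)
    assert empty.shape[1] == 0


def test_expression_counts_fold_change_and_validation(rng):
    genome = default_genome(markers_per_chromosome=1)
    ann = make_gene_annotation(genome, genes_per_chromosome=30)
    with pytest.raises(ValueError):
        DeGene("gene_PY1", fold=0.0)
    de = [DeGene("gene_PY1", 0.25, base_mean=40_000), DeGene("gene_PY2", 1.0, base_mean=40_000)]
    table = simulate_expression_counts(ann, de, rng)
    assert set(table.columns) >= {"gene_id", "length_bp", "count_G", "count_Y"}
    r1 = table[table["gene_id"] == "gene_PY1"].iloc[0]
    # fold 1/4 -> log2(Y/G) ~ -2 at deep counts
    assert math.log2(r1["count_Y"] / r1["count_G"]) == pytest.approx(-2.0, abs=0.15)
    r2 = table[table["gene_id"] == "gene_PY2"].iloc[0]
    assert math.log2(r2["count_Y"] / r2["count_G"]) == pytest.approx(0.0, abs=0.15)
    with pytest.raises(ValueError, match="annotation"):
        simulate_expression_counts(ann, [DeGene("nonexistent", 2.0)], rng)


def test_gene_annotation_contains_causal_genes(dense_genome):
    ann = make_gene_annotation(dense_genome, genes_per_chromosome=100)
    for locus in dense_genome.causal_loci:
        row = ann[ann["gene_id"] == f"gene_{locus.id}"]
        assert len(row) == 1
        assert row.iloc[0]["start"] <= locus.pos_bp <= row.iloc[0]["end"]
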