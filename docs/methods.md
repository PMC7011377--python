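# Methods

## Genetic model

The simulated trait is duplicate-recessive (digenic) epistasis: two
biallelic nuclear loci, *PY1* on chromosome A09 and *PY2* on A07, with the
mutant phenotype expressed only in the double homozygote
*py1 py1 py2 py2*. Both founder lines are fully homozygous
(doubled-haploid-like): the mutant parent carries the mutant allele at
every locus, the wild parent the wild allele, so every marker in the cross
is informative. The phenotype function is implemented for one or two
causal loci; with a single locus the same machinery produces an ordinary
monogenic recessive trait (3:1 F2), which the pipeline exposes as
`single_locus: true` for contrast experiments.

All analytic expectations (15:1 F2, 3:1 BC1×mutant, the 7:4:4 composition
of selfed-green-F2 family types, the 2:1 segregating:non-segregating split
of F3:4 families) are computed by exact enumeration of parental gamete
combinations with `fractions.Fraction` — the code contains no hard-coded
ratio — and are verified in tests against an independent 16×16 outcome
enumeration.

## Meiosis

Crossovers follow a Poisson process without interference on the cM axis
(expected count = map length / 100 Morgans, breakpoints uniform). At the
finitely many simulated loci this process is realised exactly by its
finite-dimensional projection: between adjacent loci d cM apart the
haplotype-source indicator switches with the Haldane probability
`(1 − e^(−2d/100))/2`, independently across intervals, and with
probability ½ across chromosome boundaries (independent assortment). This
is distributionally identical to simulating breakpoints explicitly and
lets a whole family's gametes be drawn as one vectorised operation. A
Monte-Carlo test checks the 50 cM closed form r ≈ 0.3161 at 10⁵ gametes.

Map distances in the *analysis* direction use Kosambi's function
`d = 25·ln((1+2r)/(1−2r))`, as is conventional for linkage reporting; the
generator is Haldane-consistent, so Kosambi estimates are mildly
compressed relative to generating distances at large r. At the r ≤ 0.05
scales of fine mapping the two functions differ by < 0.7%, which is far
below the counting noise of 2N ≈ 3000 gametes.

## Breeding design

`simulate_study` reproduces the study structure: reciprocal F1 (defaults
258/226), BC1 to both parents (669/720), selfed F2 (2376), twenty F2:3
families from selfed green F2 plants, and F3:4 families produced only
from green plants (default 8 per family, the number used in the emulated
design) of the F2:3 families that classify as 3:1 at the 3.84 critical
value. If no 3:1 F2:3 family is realized the simulator raises an explicit
error rather than silently substituting. F2:3/F3:4 family sizes are not
published for the emulated study; defaults of 100 and 200 plants are
ordinary selfed-family sizes. Fine-mapping populations are generated
separately at the published scales (1520 recessive plants for *PY1*, 1860
for *PY2*) by selfing an eligible family parent and collecting
mutant-phenotype offspring.

## Pooled sequencing model

Each bulk samples `pool_size` plants (default 100) of one phenotype
without replacement from the F2. Per SNP, the pool's true alternate
frequency f is the mean mutant-allele dosage / 2; sequencing applies a
symmetric base error e (default 10⁻³), f′ = f(1−e) + (1−f)e, then total
depth ~ Poisson(30) and alternate reads ~ Binomial(depth, f′). Depth 30×
is a package default (the emulated study does not publish per-SNP depth
targets).

The SNP panel is an even grid of 800 markers per chromosome (30 Mb / 100
cM each, uniform map) plus the two causal positions — about 8 000 loci
genome-wide. Real bulked-segregant RNA-seq panels in this species run to
~150 000 SNPs; 8 000 (≈5%) is the smallest density at which the
top-1%-then-cluster logic retains its intended geometry. At sparse
densities (~1 000 loci genome-wide) the handful of flagged loci scatter
within the linked region and called regions frequently split around or
miss the causal base pair: measured containment of both true loci across
50 seeds was 28/50 at 100 markers/chromosome, 47/50 at 400, 50/50 at 800.
Density is configurable (`markers_per_chromosome`).

## ED⁵ stage

Loci need total depth ≥ 4 ("> 3×") in *each* pool. ED uses both
allele-frequency coordinates, `ED = √2·|f_G − f_Y|` ∈ [0, √2], and is
raised to the fifth power. The significance threshold is the k-th largest
ED⁵ with k = ⌈0.01·n⌉; ties at the threshold are all flagged. Flagged
loci within 2 Mb on one chromosome join a region; regions need ≥ 2 loci.
Coordinates are 1-based inclusive and a region's length is end − start
(marker-to-marker span). Defaults (`top_fraction`, `max_gap_bp`,
`min_loci`, `min_depth`) are all exposed as library arguments and CLI
flags.

Expected causal-locus geometry, derived by enumeration: the yellow pool
is fixed (f_Y = 1), the green pool is a 4:8:3 mix of PP:Pp:pp, f_G = 7/15,
so E[ΔAF] = 8/15 and E[ED] ≈ 0.754.

## Fine mapping

Mapping populations are recessive-class: every plant is homozygous mutant
at the target, so each plant scores two gametes per marker (A = 0
recombinants, H = 1, B = 2), r = R/2N, missing calls reduce 2N rather
than being imputed. Markers homozygous in the family's parent are
uninformative and excluded (`informative_parent`), mirroring real marker
screening; the pipeline additionally prefers a family whose parent
retains coupling-phase heterozygous markers on both sides of the target.
Markers with r ≥ 0.5 (repulsion phase or unlinked) are flagged rather
than mapped.

Marker sides relative to the target come either from an explicit position
hint or from the recombinant structure itself: around the minimum-r
marker, markers on the opposite side of the target share essentially no
recombinant individuals with it (double crossovers aside), while markers
on the same side nest; comparing the anchor's recombinant overlap with
its two physical neighbours locates the target interval. Full multipoint
ordering is out of scope (dedicated mapping software territory). The
interval is delimited by the minimum-r marker with R > 0 on each side;
co-segregating markers (R = 0) lie inside and cannot bound it; if only
one side carries recombinants the result is flagged one-sided rather than
silently closed.

## Expression stage

RPKM = 10⁹·count/(library·length); genes with RPKM ≥ 0.1 in at least one
pool count as expressed and only those are tested. With two pooled
libraries and no replicates, differential expression is assessed by an
exact two-proportion test of the gene's count against the library size —
Fisher's exact test by default, with a conditional-binomial exact test
and a χ² approximation as pluggable alternatives — BH-adjusted across the
expressed genes. A gene is a DEG iff |log₂FC| ≥ 1 and FDR ≤ 0.05, where
log₂FC uses library-size-normalised counts with a pseudocount of 1 read.
Candidate genes are the DEGs overlapping the mapped interval (any
overlap). The 2^−ΔΔCt helper converts qPCR Ct values to relative
expression for candidate validation.

The synthetic expression generator gives non-DE genes one expected rate in
both pools (log-normal across genes, median 80 reads, σ = 1) and scales
configured DE genes (default base mean 400, fold 4) in the yellow pool;
counts are Poisson. The default scenario configures 90 up- and 91
down-regulated genes with the two causal genes among the down set at fold
¼; at these depths the caller recovers essentially all configured DEGs
plus the small number of false calls the BH procedure admits (~5% of
calls).

## What the generator does and does not emulate

It emulates: the crossing design and its Mendelian structure, pooled
allele-frequency signal and binomial sequencing noise, marker screening
and recessive-class linkage scoring, and DEG-scale expression contrasts.
It does not model read-level artefacts (alignment error, allele-specific
expression, base-quality structure), linkage disequilibrium with
population structure, transcript-level SNP density variation, crossover
interference, or segregation distortion. Passing tests therefore show the
statistical machinery is correct under clean Mendelian sampling, not that
the pipeline is robust to real sequencing artefacts.

Quantities from the emulated study that depend on its real data — raw
read totals, the ~155 000/157 000 SNP counts, the 412 flagged loci, the
55 250 expressed genes and 181 real DEGs, the 258.3-kb/4.4-kb physical
intervals and the printed cM values — are not reproducible from synthetic
data and are not asserted anywhere; the 181/90 DEG counts are used only
as the configured synthetic scenario above.

## Numerical conventions

- Observed ratios round half-up to two decimals (`decimal.Decimal`), the
  table-report convention.
- The Yates deviation truncates at zero, so a perfect fit scores exactly 0.
- `classify_family` requires literally zero yellow plants for all-green;
  when both 3:1 and 15:1 fit, the smaller χ² wins.
- All stochastic stages draw from one `numpy.random.Generator`; the
  pipeline seed fully determines every output file (byte-identical
  reruns), and the run report records seed, config hash and version.
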