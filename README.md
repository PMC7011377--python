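# digenic-mapper

Simulation and analysis pipeline for mapping a trait controlled by **two
unlinked recessive nuclear genes** (duplicate-recessive epistasis), the
situation found in plant etiolation/chlorophyll-deficiency mutants where
neither locus alone produces the mutant phenotype. The package targets
geneticists who want a tested, reusable desk-scale implementation of the
classic workflow:

1. **Genetic analysis** — reciprocal F1, F2, BC1 phenotype counts;
   Yates-corrected χ² goodness-of-fit against Mendelian ratios.
2. **Bulked-segregant localisation (BSR-Seq style)** — extreme green/yellow
   F2 bulks, per-SNP pooled allele depths, the ED⁵ statistic, top-1%
   thresholding and candidate-region calling.
3. **Fine mapping** — recessive-class F3:4 mapping populations,
   gamete-count recombination fractions, Kosambi map distances,
   flanking-marker interval delimitation.
4. **Candidate genes** — RPKM, DEG calling between the pooled libraries
   (|log₂FC| ≥ 1, BH-FDR ≤ 0.05), intersected with the mapped interval;
   2^−ΔΔCt relative expression for qPCR-style validation.

## The model

The trait phenotype is a pure function of two biallelic loci *PY1* (A09)
and *PY2* (A07): a plant is mutant (yellow) iff its genotype is
*py1 py1 py2 py2*. Selfing the double heterozygote therefore yields

- F2 green : yellow = **15 : 1**, BC1 (× mutant) = **3 : 1**,
- selfed green-F2 family types all-green : 3:1 : 15:1 = **7 : 4 : 4**,
- selfed green plants of a 3:1 family: segregating : all-green = **2 : 1**,

all of which the `segregation` module derives by exact gamete enumeration
rather than hard-coding. Ratio tests use the Yates-corrected χ²
`Σ (max(|O−E|−0.5, 0))²/E` with critical value 3.84 (df = 1, α = 0.05).

For the bulks, each SNP's Euclidean distance between the pools' allele
frequency vectors is `ED = √((f_G−f_Y)² + ((1−f_G)−(1−f_Y))²) = √2·|f_G−f_Y|`,
raised to the fifth power to suppress background noise; loci in the top 1%
of ED⁵ are clustered into regions (gap ≤ 2 Mb, ≥ 2 loci). At a causal
locus the yellow pool is fixed (f_Y = 1) while the green pool is expected
at 7/15, so E[ED] = √2·8/15 ≈ 0.754.

Fine mapping uses the recessive-class convention: every mutant-phenotype
plant contributes two scored gametes per marker (H = 1 recombinant, B = 2,
A = 0), r = R/2N, and `d = 25·ln((1+2r)/(1−2r))` cM (Kosambi).

## Worked example

```bash
digenic-mapper report --seed 1 --out run1
```

runs the full simulate → analyze → report chain at the default study
scale (F2 of 2376; bulks of 100 plants at 30×; 8 000 SNP loci;
1520/1860-plant mapping populations; 5 000 annotated genes with 90 up- and
91 down-regulated, the two causal genes among the latter at fold ¼).
`run1/report.md` from that exact command contains:

```
       family generation  total  green  yellow    ratio hypothesis  chi2
0  F1_forward         F1    258    258       0
1  F1_reverse         F1    226    226       0
2    BC1_wild        BC1    669    669       0
3  BC1_mutant        BC1    720    550     170   3.24:1        3:1  0.67
4          F2         F2   2376   2216     160  13.85:1       15:1  0.87
```

— the F2 fits 15:1 and the backcross 3:1, so the trait is digenic
recessive; identical reciprocal F1s give `inheritance mode: nuclear`. The
region table calls five candidate regions, among them
`A07 5193750..21543750` and `A09 20418750..26643750`, each containing the
true simulated locus; fine mapping narrows these to
`PY1: A09 24,993,750–25,031,250 (1 gene)` and
`PY2: A07 12,956,250–13,031,250 (2 genes)`, and the DEG × interval
intersection reports the causal genes `gene_PY1` (log₂FC −2.04) and
`gene_PY2` (log₂FC −2.20) as candidates (this seed also catches one
coincidental upregulated DEG adjacent to *PY2*, a realistic false lead).

The same stages are available as composable subcommands (`simulate`,
`segtest`, `bsr`, `map`, `deg`) over TSV files, with a minimal-VCF adapter
for allelic depths and GFF3 for gene models; see `--help` on each.

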