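"""End-to-end driver: simulate → segregation → BSR → linkage → candidates.

Mirrors the order of the mapping study the package emulates: genetic
analysis of the cross, bulked-segregant ED⁵ localisation, fine mapping in
recessive-class F3:4 populations, and DEG-based candidate-gene prediction.
Every stage writes its table to the output directory and the run report
records seed, config hash and package version so each number is traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breeding_sim import (
    GREEN,
    YELLOW,
    BulkSpec,
    DeGene,
    StudyConfig,
    StudyDataset,
    make_gene_annotation,
    marker_genotype_table,
    simulate_bulk_counts,
    simulate_expression_counts,
    simulate_mapping_population,
    simulate_study,
)
from .bsr_ed import plot_ed_track, run_bsr
from .expression import call_degs, candidate_genes
from .genome import MUTANT_ALLELE, default_genome
from .io import write_expression, write_gff3_genes, write_snp_counts
from .linkage import analyze_markers, delimit_interval, genes_in_interval
from .segregation import (
    DEFAULT_CRITICAL,
    SegregationCount,
    classify_family,
    infer_inheritance_mode,
    ratio_test,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of the simulate→analyze→report driver in one place."""

    seed: int = 1
    # genome / design
    markers_per_chromosome: int = 800
    single_locus: bool = False
    study: StudyConfig = field(default_factory=StudyConfig)
    # bulks
    pool_size: int = 100
    mean_depth: float = 30.0
    base_error_rate: float = 0.001
    # ED stage
    min_depth: int = 4
    top_fraction: float = 0.01
    max_gap_bp: int = 2_000_000
    min_loci: int = 2
    # segregation
    critical: float = DEFAULT_CRITICAL
    # fine mapping
    mapping_pop_sizes: dict = field(default_factory=lambda: {"PY1": 1520, "PY2": 1860})
    # expression / DEG
    genes_per_chromosome: int = 500
    n_up: int = 90
    n_down: int = 91  # includes the causal genes, downregulated in the Y-pool
    de_fold: float = 4.0
    de_base_mean: float = 400.0
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    pseudocount: float = 1.0
    deg_test: str = "fisher"
    # output; full per-locus genotype strings are bulky at the default
    # marker density, so they are opt-in
    write_genotypes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study = StudyConfig(**raw.pop("study", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(study=study, **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    segregation_table: pd.DataFrame
    family_class_table: pd.DataFrame
    inheritance_mode: str
    region_table: pd.DataFrame
    ed5_threshold: float
    linkage_tables: dict
    intervals: dict  # locus id -> dict(chrom, start, end, n_genes, one_sided)
    deg_summary: dict
    candidate_table: pd.DataFrame

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
        }


def _segregation_tables(dataset: StudyDataset, config: PipelineConfig):
    """Table-1-style ratio tests plus the F2:3/F3:4 family classification."""
    f2_ratio = (3, 1) if config.single_locus else (15, 1)
    rows = []
    tests = {
        "F1_forward": None,
        "F1_reverse": None,
        "BC1_wild": None,
        "BC1_mutant": (3, 1),
        "F2": f2_ratio,
    }
    for name, hypothesis in tests.items():
        fam = dataset.families[name]
        n, g, y = fam.phenotype_counts()
        c = SegregationCount(n, g, y)
        row = {
            "family": name,
            "generation": fam.generation,
            "total": n,
            "green": g,
            "yellow": y,
            "ratio": "",
            "hypothesis": "",
            "chi2": "",
        }
        if hypothesis is not None and y > 0:
            res = ratio_test(c, hypothesis, config.critical)
            row.update(
                ratio=f"{res.observed_ratio:.2f}:1",
                hypothesis=f"{hypothesis[0]}:{hypothesis[1]}",
                chi2=f"{res.chi2:.2f}",
            )
        rows.append(row)
    seg_table = pd.DataFrame(rows)

    class_rows = []
    for fam in [*dataset.f23_families, *dataset.f34_families]:
        n, g, y = fam.phenotype_counts()
        cls = classify_family(SegregationCount(n, g, y), config.critical)
        class_rows.append(
            {
                "family": fam.id,
                "generation": fam.generation,
                "total": n,
                "green": g,
                "yellow": y,
                "class": cls.label,
                "chi2_3_1": "" if cls.chi2_3_1 is None else f"{cls.chi2_3_1:.2f}",
                "chi2_15_1": "" if cls.chi2_15_1 is None else f"{cls.chi2_15_1:.2f}",
            }
        )
    class_table = pd.DataFrame(
        class_rows,
        columns=[
            "family",
            "generation",
            "total",
            "green",
            "yellow",
            "class",
            "chi2_3_1",
            "chi2_15_1",
        ],
    )
    f1f = dataset.families["F1_forward"]
    f1r = dataset.families["F1_reverse"]
    mode = infer_inheritance_mode(
        SegregationCount(*f1f.phenotype_counts()),
        SegregationCount(*f1r.phenotype_counts()),
    )
    return seg_table, class_table, mode


def _mapping_parent(dataset: StudyDataset, target_idx: int, other_idx: int | None):
    """A green plant whose selfed family segregates 3:1 for the target
    locus: heterozygous at the target, homozygous mutant at the other.

    Among the eligible family parents, prefer one that still carries
    heterozygous *coupling-phase* markers on both sides of the target
    (marker mutant allele on the same haplotype as the target mutant
    allele) — the marker-screening step that selects a family in which
    flanking markers are informative."""
    genome = next(iter(dataset.families.values())).members[0].genome
    locus = genome.causal_loci[target_idx]
    t_flat = genome.locus_index(locus.id)
    on_chrom = (genome.locus_chrom == locus.chrom) & ~genome.locus_is_causal
    left = on_chrom & (genome.locus_pos_bp < locus.pos_bp)
    right = on_chrom & (genome.locus_pos_bp > locus.pos_bp)
    candidates = dataset.f34_families or dataset.f23_families
    fallback = None
    for fam in candidates:
        parent = fam.parent_individuals[0] if fam.parent_individuals else None
        if parent is None:
            continue
        g = parent.causal_genotypes()
        if set(g[target_idx]) != {0, 1}:
            continue
        if other_idx is not None and g[other_idx] != (MUTANT_ALLELE, MUTANT_ALLELE):
            continue
        fallback = fallback or parent
        het = parent.hap1 != parent.hap2
        mutant_hap = parent.hap1 if parent.hap1[t_flat] == MUTANT_ALLELE else parent.hap2
        coupling = het & (mutant_hap == MUTANT_ALLELE)
        if (coupling & left).any() and (coupling & right).any():
            return parent
    return fallback


def _write_individuals(dataset: StudyDataset, path: Path, with_genotypes: bool) -> None:
    codes = np.array(["B", "H", "A"])
    rows = []
    for fam in dataset.all_families():
        for ind in fam.members:
            row = {
                "id": ind.id,
                "generation": ind.generation,
                "family": fam.id,
                "parents": ";".join(ind.parents or ()),
                "phenotype": ind.phenotype,
            }
            if with_genotypes:
                row["genotype"] = "".join(codes[ind.allele_counts()])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Run every stage and write all tables plus ``report.md`` to
    ``outdir``.  Deterministic given ``config.seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = default_genome(
        markers_per_chromosome=config.markers_per_chromosome,
        py2_pos=None if config.single_locus else ("A07", 13_000_000),
    )

    # 1. breeding design ---------------------------------------------------
    dataset = simulate_study(config.study, rng, genome)
    seg_table, class_table, mode = _segregation_tables(dataset, config)
    seg_table.to_csv(outdir / "segregation.tsv", sep="\t", index=False)
    class_table.to_csv(outdir / "family_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "family_id": fam.id,
                "generation": fam.generation,
                "parents": ";".join(fam.parents),
                "n_total": len(fam),
                "n_green": fam.n_green,
                "n_yellow": fam.n_yellow,
            }
            for fam in dataset.all_families()
        ]
    ).to_csv(outdir / "families.tsv", sep="\t", index=False)
    _write_individuals(dataset, outdir / "individuals.tsv", config.write_genotypes)

    # 2. bulked-segregant ED⁵ stage ---------------------------------------
    g_spec = BulkSpec("G-pool", GREEN, config.pool_size, config.mean_depth, config.base_error_rate)
    y_spec = BulkSpec("Y-pool", YELLOW, config.pool_size, config.mean_depth, config.base_error_rate)
    snp_table = simulate_bulk_counts(dataset.families["F2"], g_spec, y_spec, rng, genome)
    write_snp_counts(snp_table, outdir / "snp_counts.tsv")
    track, regions, threshold = run_bsr(
        snp_table,
        min_depth=config.min_depth,
        top_fraction=config.top_fraction,
        max_gap_bp=config.max_gap_bp,
        min_loci=config.min_loci,
    )
    track.to_csv(outdir / "ed_track.tsv", sep="\t", index=False)
    regions.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    try:
        plot_ed_track(track, threshold, outdir / "ed5_track.png")
    except Exception:  # noqa: BLE001 - the figure is a convenience output
        pass

    # 3. gene annotation + expression --------------------------------------
    annotation = make_gene_annotation(genome, config.genes_per_chromosome)
    write_gff3_genes(annotation, outdir / "genes.gff3")
    causal_ids = [f"gene_{c.id}" for c in genome.causal_loci]
    non_causal = [g for g in annotation["gene_id"] if g not in causal_ids]
    n_other_down = max(config.n_down - len(causal_ids), 0)
    chosen = rng.choice(len(non_causal), size=config.n_up + n_other_down, replace=False)
    de_genes = [
        DeGene(causal, 1.0 / config.de_fold, config.de_base_mean) for causal in causal_ids
    ]
    de_genes += [
        DeGene(non_causal[int(i)], config.de_fold, config.de_base_mean)
        for i in chosen[: config.n_up]
    ]
    de_genes += [
        DeGene(non_causal[int(i)], 1.0 / config.de_fold, config.de_base_mean)
        for i in chosen[config.n_up :]
    ]
    expr = simulate_expression_counts(annotation, de_genes, rng)
    write_expression(expr, outdir / "expression.tsv")
    degs = call_degs(
        expr,
        lfc_min=config.lfc_min,
        fdr_max=config.fdr_max,
        pseudocount=config.pseudocount,
        test=config.deg_test,
    )
    degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
    deg_summary = {
        "n_tested": int(len(degs)),
        "n_deg": int(degs["is_deg"].sum()),
        "n_up": int((degs["is_deg"] & (degs["direction"] == "up")).sum()),
        "n_down": int((degs["is_deg"] & (degs["direction"] == "down")).sum()),
    }

    # 4. fine mapping -------------------------------------------------------
    linkage_tables: dict[str, pd.DataFrame] = {}
    intervals: dict[str, dict] = {}
    candidate_frames = []
    for t_idx, locus in enumerate(genome.causal_loci):
        o_idx = 1 - t_idx if genome.is_digenic else None
        parent = _mapping_parent(dataset, t_idx, o_idx)
        if parent is None:
            intervals[locus.id] = {"error": "no 3:1 family segregating for this locus"}
            continue
        n_map = int(config.mapping_pop_sizes.get(locus.id, 500))
        population = simulate_mapping_population(parent, n_map, rng)
        genotypes = marker_genotype_table(
            population, genome, chrom=locus.chrom, informative_parent=parent
        )
        if genotypes.shape[1] == 0:
            intervals[locus.id] = {"error": "no informative marker on the target chromosome"}
            continue
        positions = {
            str(name): int(bp)
            for name, bp in zip(genome.locus_names, genome.locus_pos_bp)
        }
        # marker sides inferred from the recombinant structure of the family
        results = analyze_markers(genotypes, positions)
        linkage_tables[locus.id] = pd.DataFrame(
            [
                {
                    "marker": m.marker,
                    "pos_bp": m.pos_bp,
                    "R": m.n_recombinant,
                    "2N": m.n_gametes,
                    "r": m.r,
                    "cM": "" if m.distance_cm is None else f"{m.distance_cm:.4f}",
                    "side": m.side,
                }
                for m in results
            ]
        )
        linkage_tables[locus.id].to_csv(
            outdir / f"linkage_{locus.id}.tsv", sep="\t", index=False
        )
        interval = delimit_interval(results)
        if interval.left is None and interval.right is None:
            intervals[locus.id] = {"error": "no recombinant marker found"}
            continue
        start = interval.start if interval.start is not None else interval.end
        end = interval.end if interval.end is not None else interval.start
        genes = genes_in_interval(annotation, locus.chrom, start, end)
        intervals[locus.id] = {
            "chrom": locus.chrom,
            "start": int(start),
            "end": int(end),
            "n_genes": int(len(genes)),
            "one_sided": interval.one_sided,
        }
        cands = candidate_genes(degs, annotation, locus.chrom, start, end)
        cands.insert(0, "target", locus.id)
        candidate_frames.append(cands)

    candidate_table = (
        pd.concat(candidate_frames, ignore_index=True)
        if candidate_frames
        else pd.DataFrame(columns=["target", "gene_id"])
    )
    candidate_table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    report = RunReport(
        seed=config.seed,
        config_hash=config.hash(),
        version=__version__,
        segregation_table=seg_table,
        family_class_table=class_table,
        inheritance_mode=mode,
        region_table=regions,
        ed5_threshold=threshold,
        linkage_tables=linkage_tables,
        intervals=intervals,
        deg_summary=deg_summary,
        candidate_table=candidate_table,
    )
    _write_report_md(report, outdir / "report.md")
    (outdir / "provenance.json").write_text(
        json.dumps(report.provenance(), indent=2, sort_keys=True) + "\n"
    )
    return report


def _write_report_md(report: RunReport, path: Path) -> None:
    lines = [
        "# digenic-mapper run report",
        "",
        f"- seed: {report.seed}",
        f"- config hash: {report.config_hash}",
        f"- version: {report.version}",
        f"- inheritance mode (reciprocal F1): {report.inheritance_mode}",
        "",
        "## Segregation analysis",
        "",
        report.segregation_table.to_string(index=False),
        "",
        "## Family classification (F2:3 / F3:4)",
        "",
        report.family_class_table["class"].value_counts().to_string()
        if not report.family_class_table.empty
        else "(no selfed families simulated)",
        "",
        f"## Candidate regions (ED5 threshold {report.ed5_threshold:.5f})",
        "",
        report.region_table.to_string(index=False)
        if not report.region_table.empty
        else "(no region called)",
        "",
        "## Fine-mapped intervals",
        "",
    ]
    for locus, info in report.intervals.items():
        lines.append(f"- {locus}: {info}")
    lines += [
        "",
        "## Differential expression",
        "",
        f"- {report.deg_summary}",
        "",
        "## Candidate genes (DEG × interval)",
        "",
        report.candidate_table.to_string(index=False)
        if not report.candidate_table.empty
        else "(none)",
        "",
    ]
    path.write_text("\n".join(lines))
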