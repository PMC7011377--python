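"""Table formats and adapters.

Every stage of the pipeline exchanges small rectangular tables, so TSV is
the canonical interchange format; minimal VCF (with per-sample allelic
depths) and GFF3 adapters sit at the edges.  Readers validate the schema
and report malformed rows with their line numbers.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .bsr_ed import SNP_COLUMNS

__all__ = [
    "InputError",
    "read_snp_counts",
    "write_snp_counts",
    "read_expression",
    "write_expression",
    "read_family_counts",
    "read_marker_genotypes",
    "read_gff3_genes",
    "write_gff3_genes",
    "snp_counts_to_vcf",
    "vcf_to_snp_counts",
]

EXPRESSION_COLUMNS = ["gene_id", "chrom", "start", "end", "length_bp", "count_G", "count_Y"]
FAMILY_COLUMNS = ["family_id", "generation", "n_green", "n_yellow"]


class InputError(ValueError):
    """Malformed input file: message names the file, column and line."""


def _read_tsv(path, required: list[str], int_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap as input error
        raise InputError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    for col in int_cols:
        parsed = pd.to_numeric(table[col], errors="coerce")
        bad = parsed.isna() & table[col].notna()
        if bad.any():
            line = int(bad[bad].index[0]) + 2  # +1 header, +1 1-based
            raise InputError(f"{path}: column {col!r}, line {line}: not an integer")
        table[col] = parsed.astype("int64")
    return table


def read_snp_counts(path) -> pd.DataFrame:
    """Per-SNP pooled read-count table (chrom, pos, ref, alt, four count
    columns); 1-based positions, strictly increasing within a chromosome."""
    table = _read_tsv(path, SNP_COLUMNS, SNP_COLUMNS[1:2] + SNP_COLUMNS[4:])
    if (table["pos"] < 1).any():
        line = int(table.index[table["pos"] < 1][0]) + 2
        raise InputError(f"{path}: column 'pos', line {line}: positions are 1-based")
    counts = table[SNP_COLUMNS[4:]]
    if (counts < 0).any().any():
        raise InputError(f"{path}: negative read count")
    for chrom, group in table.groupby("chrom"):
        if not group["pos"].is_monotonic_increasing:
            raise InputError(f"{path}: positions not increasing on {chrom}")
    return table[SNP_COLUMNS]


def write_snp_counts(table: pd.DataFrame, path) -> None:
    table[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    table = _read_tsv(path, EXPRESSION_COLUMNS, EXPRESSION_COLUMNS[2:])
    if (table["length_bp"] <= 0).any():
        line = int(table.index[table["length_bp"] <= 0][0]) + 2
        raise InputError(f"{path}: column 'length_bp', line {line}: must be > 0")
    return table[EXPRESSION_COLUMNS]


def write_expression(table: pd.DataFrame, path) -> None:
    table[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_family_counts(path) -> pd.DataFrame:
    table = _read_tsv(path, FAMILY_COLUMNS, FAMILY_COLUMNS[2:])
    if (table[["n_green", "n_yellow"]] < 0).any().any():
        raise InputError(f"{path}: negative phenotype count")
    return table[FAMILY_COLUMNS]


def read_marker_genotypes(path) -> pd.DataFrame:
    """Individuals × markers A/H/B/- table; first column is the individual
    id (index)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    valid = {"A", "H", "B", "-"}
    for col in table.columns:
        bad = ~table[col].fillna("-").isin(valid)
        if bad.any():
            line = int(pd.Index(table.index).get_loc(bad[bad].index[0])) + 2
            raise InputError(
                f"{path}: column {col!r}, line {line}: genotype must be one of A/H/B/-"
            )
    return table


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene models from a GFF3 file (features of type ``gene``), as a
    DataFrame with gene_id, chrom, start, end, strand.  Rejects records
    with start > end, naming the offending line."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    # pre-validate coordinates so the error can carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise InputError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: bad coordinates") from exc
            if start > end:
                raise InputError(f"{path}: line {lineno}: start > end")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = [
        {
            "gene_id": feature.id,
            "chrom": feature.seqid,
            "start": feature.start,
            "end": feature.end,
            "strand": feature.strand,
        }
        for feature in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )


def write_gff3_genes(annotation: pd.DataFrame, path) -> None:
    """Write gene models as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            strand = getattr(row, "strand", "+")
            fh.write(
                f"{row.chrom}\tdigenic_mapper\tgene\t{row.start}\t{row.end}\t.\t"
                f"{strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# minimal VCF with allelic depths
# ---------------------------------------------------------------------------


def snp_counts_to_vcf(table: pd.DataFrame, path, contig_lengths: dict | None = None) -> None:
    """Write the SNP count table as a minimal VCF with two samples (G_pool,
    Y_pool) carrying AD-format allelic depths."""
    chroms = list(dict.fromkeys(table["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tG_pool\tY_pool\n"
        )
        for row in table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tAD\t"
                f"{row.ref_count_G},{row.alt_count_G}\t{row.ref_count_Y},{row.alt_count_Y}\n"
            )


def vcf_to_snp_counts(path) -> pd.DataFrame:
    """Read a (minimal) VCF with per-sample AD allelic depths back into the
    SNP count table schema.  Samples must be named G_pool and Y_pool."""
    import pysam

    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"{path}: no such file")
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    if set(samples) != {"G_pool", "Y_pool"}:
        raise InputError(f"{path}: expected samples G_pool and Y_pool, got {samples}")
    rows = []
    for rec in vcf:
        ad_g = rec.samples["G_pool"]["AD"]
        ad_y = rec.samples["Y_pool"]["AD"]
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
                "ref_count_G": int(ad_g[0]),
                "alt_count_G": int(ad_g[1]),
                "ref_count_Y": int(ad_y[0]),
                "alt_count_Y": int(ad_y[1]),
            }
        )
    return pd.DataFrame(rows, columns=SNP_COLUMNS)
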