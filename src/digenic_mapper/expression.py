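"""Expression stage: RPKM, DEG calling between pools, candidate genes.

The two bulks are sequenced without biological replicates, so differential
expression between the pooled libraries is assessed with an exact
two-proportion test of each gene's read count against the library sizes
(Fisher's exact test by default; a conditional-binomial exact test and a
chi-square approximation are available), with Benjamini–Hochberg FDR
control over the expressed genes tested.  A gene is called differentially
expressed when |log2 fold change| ≥ 1 and FDR ≤ 0.05.  Candidate genes are
the DEGs lying inside a mapped interval.  The qPCR-style 2^−ΔΔCt relative
expression is included for validating candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .linkage import genes_in_interval

__all__ = [
    "rpkm",
    "add_rpkm",
    "detect_expressed",
    "call_degs",
    "candidate_genes",
    "ddct_relative_expression",
]


def rpkm(count, length_bp, library_size):
    """Reads per kilobase of gene model per million mapped reads:
    10⁹ · count / (library_size · length_bp).  Accepts scalars or arrays."""
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("gene length must be > 0")
    if np.any(library_size <= 0):
        raise ValueError("library size must be > 0")
    out = 1e9 * np.asarray(count, dtype=float) / (library_size * length_bp)
    return float(out) if out.ndim == 0 else out


def _library_sizes(table: pd.DataFrame) -> tuple[int, int]:
    return int(table["count_G"].sum()), int(table["count_Y"].sum())


def add_rpkm(
    table: pd.DataFrame, library_sizes: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Add rpkm_G / rpkm_Y columns; library sizes default to the column
    totals (all counts mapped)."""
    n_g, n_y = library_sizes or _library_sizes(table)
    out = table.copy()
    out["rpkm_G"] = rpkm(table["count_G"], table["length_bp"], n_g)
    out["rpkm_Y"] = rpkm(table["count_Y"], table["length_bp"], n_y)
    return out


def detect_expressed(table: pd.DataFrame, rpkm_min: float = 0.1) -> pd.Series:
    """Boolean mask of expressed genes: RPKM ≥ ``rpkm_min`` in at least one
    pool."""
    if table.empty:
        return pd.Series(dtype=bool)
    t = table if "rpkm_G" in table.columns else add_rpkm(table)
    return (t["rpkm_G"] >= rpkm_min) | (t["rpkm_Y"] >= rpkm_min)


def _two_proportion_pvalues(
    count_g: np.ndarray, count_y: np.ndarray, n_g: int, n_y: int, test: str
) -> np.ndarray:
    if test == "fisher":
        return np.array(
            [
                stats.fisher_exact(
                    [[y, n_y - y], [g, n_g - g]], alternative="two-sided"
                ).pvalue
                for g, y in zip(count_g, count_y)
            ]
        )
    if test == "binom":
        # conditional on the total count, the Y-pool count is binomial with
        # the library-size proportion under the null of equal rates
        p_null = n_y / (n_g + n_y)
        return np.array(
            [
                stats.binomtest(int(y), int(g + y), p_null).pvalue if g + y > 0 else 1.0
                for g, y in zip(count_g, count_y)
            ]
        )
    if test == "chi2":
        out = np.empty(len(count_g))
        for i, (g, y) in enumerate(zip(count_g, count_y)):
            if g + y == 0:
                out[i] = 1.0
            else:
                out[i] = stats.chi2_contingency(
                    [[y, n_y - y], [g, n_g - g]]
                ).pvalue
        return out
    raise ValueError(f"unknown test {test!r}")


def call_degs(
    table: pd.DataFrame,
    library_sizes: tuple[int, int] | None = None,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    pseudocount: float = 1.0,
    rpkm_min: float = 0.1,
    test: str = "fisher",
) -> pd.DataFrame:
    """Differential expression between the Y-pool and the G-pool.

    Only expressed genes (RPKM ≥ ``rpkm_min`` in at least one pool) are
    tested; log2fc is the library-size-normalised Y/G ratio with a
    pseudocount to handle zeros; p-values come from an exact two-proportion
    test of count against library size, BH-adjusted over the tested genes.
    A gene is a DEG iff |log2fc| ≥ ``lfc_min`` and FDR ≤ ``fdr_max``.
    """
    n_g, n_y = library_sizes or _library_sizes(table)
    out = add_rpkm(table, (n_g, n_y))
    expressed = detect_expressed(out, rpkm_min)
    out = out[expressed].reset_index(drop=True)
    if out.empty:
        out["log2fc"] = out["p_value"] = out["fdr"] = np.nan
        out["is_deg"] = np.array([], dtype=bool)
        out["direction"] = ""
        return out
    cg = out["count_G"].to_numpy()
    cy = out["count_Y"].to_numpy()
    out["log2fc"] = np.log2((cy + pseudocount) / n_y) - np.log2(
        (cg + pseudocount) / n_g
    )
    out["p_value"] = _two_proportion_pvalues(cg, cy, n_g, n_y, test)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["is_deg"] = (out["log2fc"].abs() >= lfc_min) & (out["fdr"] <= fdr_max)
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def candidate_genes(
    degs: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
) -> pd.DataFrame:
    """DEGs inside a mapped interval: genes that both overlap
    [start, end] on ``chrom`` and carry ``is_deg``.  Empty result means no
    expression-supported candidate in the interval."""
    inside = genes_in_interval(annotation, chrom, start, end)
    flagged = degs[degs["is_deg"]]
    return flagged[flagged["gene_id"].isin(inside["gene_id"])].reset_index(drop=True)


def ddct_relative_expression(
    ct_target_mut: float,
    ct_ref_mut: float,
    ct_target_wt: float,
    ct_ref_wt: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method: the mutant sample's
    target gene expression normalised to a reference gene and calibrated
    against the wild-type sample."""
    for ct in (ct_target_mut, ct_ref_mut, ct_target_wt, ct_ref_wt):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_mut - ct_ref_mut) - (ct_target_wt - ct_ref_wt)
    return float(2.0 ** (-ddct))
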