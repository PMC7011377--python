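"""ED⁵ bulked-segregant statistic and candidate-region calling.

Given per-SNP pooled allele depths for the two extreme bulks (G-pool of
green plants, Y-pool of yellow plants), this module applies the depth
screen (total depth > 3× in each pool), computes per-SNP alternate-allele
frequencies, the Euclidean distance between the two pools' allele-frequency
vectors

    ED = sqrt((fG − fY)² + ((1 − fG) − (1 − fY))²) = √2 · |fG − fY|,

raises it to the fifth power (ED⁵) to suppress background noise, flags the
top 1% of loci, and joins flagged loci into candidate chromosome regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SNP_COLUMNS",
    "CandidateRegion",
    "screen_differential",
    "ed_statistic",
    "significance_threshold",
    "call_regions",
    "run_bsr",
    "plot_ed_track",
]

SNP_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count_G",
    "alt_count_G",
    "ref_count_Y",
    "alt_count_Y",
]


@dataclass(frozen=True)
class CandidateRegion:
    """One candidate interval: bounded by its first and last significant
    locus; length is end − start, matching marker-to-marker span
    arithmetic (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    n_loci: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_loci < 1:
            raise ValueError("a region contains at least one locus")

    @property
    def length(self) -> int:
        return self.end - self.start


def _depths(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    return (
        table["ref_count_G"] + table["alt_count_G"],
        table["ref_count_Y"] + table["alt_count_Y"],
    )


def screen_differential(table: pd.DataFrame, min_depth: int = 4) -> pd.DataFrame:
    """Keep loci with total depth ≥ ``min_depth`` (i.e. > 3× with the
    default) in *each* pool; row order preserved."""
    if table.empty:
        return table.copy()
    depth_g, depth_y = _depths(table)
    return table[(depth_g >= min_depth) & (depth_y >= min_depth)].copy()


def ed_statistic(table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP allele frequencies, ED and ED⁵.

    Returns the input columns plus freq_G, freq_Y, ed, ed5.  Zero depth in
    either pool is an error: such loci should have been removed by
    :func:`screen_differential`.
    """
    depth_g, depth_y = _depths(table)
    if ((depth_g == 0) | (depth_y == 0)).any():
        raise ValueError("zero-depth locus present; run screen_differential first")
    out = table.copy()
    out["freq_G"] = table["alt_count_G"] / depth_g
    out["freq_Y"] = table["alt_count_Y"] / depth_y
    out["ed"] = math.sqrt(2.0) * (out["freq_G"] - out["freq_Y"]).abs()
    out["ed5"] = out["ed"] ** 5
    return out


def significance_threshold(
    ed5: np.ndarray | pd.Series, top_fraction: float = 0.01
) -> tuple[float, np.ndarray]:
    """Top-fraction threshold on ED⁵ and the per-locus significance flags.

    The threshold is the k-th largest value with k = ceil(top_fraction·n);
    all loci with ED⁵ ≥ threshold are flagged, so ties at the threshold are
    all included.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    values = np.asarray(ed5, dtype=float)
    if values.size == 0:
        raise ValueError("no ED5 values")
    k = math.ceil(top_fraction * values.size)
    threshold = float(np.sort(values)[::-1][k - 1])
    return threshold, values >= threshold


def call_regions(
    flagged: pd.DataFrame,
    max_gap_bp: int = 2_000_000,
    min_loci: int = 2,
) -> pd.DataFrame:
    """Join significant loci into candidate regions.

    Consecutive flagged loci on one chromosome whose gap is ≤ ``max_gap_bp``
    form one region; regions with fewer than ``min_loci`` loci are dropped.
    ``flagged`` needs columns chrom, pos (sorted by chrom, pos).  Returns a
    region table with chrom, start, end, n_loci, length.
    """
    regions: list[CandidateRegion] = []
    for chrom, group in flagged.groupby("chrom", sort=False):
        pos = np.sort(group["pos"].to_numpy())
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        for chunk in np.split(pos, breaks + 1):
            if chunk.size >= min_loci:
                regions.append(
                    CandidateRegion(chrom, int(chunk[0]), int(chunk[-1]), int(chunk.size))
                )
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_loci": r.n_loci,
                "length": r.length,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "n_loci", "length"],
    )


def run_bsr(
    table: pd.DataFrame,
    min_depth: int = 4,
    top_fraction: float = 0.01,
    max_gap_bp: int = 2_000_000,
    min_loci: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Full ED⁵ stage: depth screen → ED/ED⁵ → top-1% flags → regions.

    Returns (per-SNP track with `significant` column, region table,
    ED⁵ threshold).
    """
    screened = screen_differential(table, min_depth)
    if screened.empty:
        raise ValueError("no loci pass the depth screen")
    track = ed_statistic(screened)
    threshold, flags = significance_threshold(track["ed5"], top_fraction)
    track["significant"] = flags
    regions = call_regions(track[track["significant"]], max_gap_bp, min_loci)
    return track, regions, threshold


def plot_ed_track(track: pd.DataFrame, threshold: float, path) -> None:
    """Static per-chromosome ED⁵ scatter with the top-1% threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(11, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, group) in enumerate(track.groupby("chrom", sort=True)):
        x = group["pos"].to_numpy() + offset
        ax.scatter(x, group["ed5"], s=6, color=f"C{i % 10}")
        ticks.append(offset + group["pos"].max() / 2)
        labels.append(str(chrom))
        offset += group["pos"].max()
    ax.axhline(threshold, color="black", lw=1)
    ax.set_xticks(ticks, labels, rotation=60, fontsize=7)
    ax.set_ylabel("ED$^5$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
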