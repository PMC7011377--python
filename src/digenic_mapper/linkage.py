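"""Linkage fine mapping in recessive-class populations.

The mapping populations consist solely of mutant-phenotype (homozygous
recessive) plants, so each plant contributes two independently scored
gametes per marker: a heterozygous call (H) is one recombinant gamete, a
homozygous wild-parent call (B) is two, a homozygous mutant-parent call
(A) none.  The recombination fraction is the direct gamete count
r = R / 2N, converted to map distance with Kosambi's function

    d = 25 · ln((1 + 2r) / (1 − 2r))  cM.

The target is then delimited by the most tightly linked marker with at
least one recombinant on each side, and the genes overlapping the physical
interval are extracted from the annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "MarkerLinkage",
    "IntervalResult",
    "recomb_fraction_recessive",
    "kosambi_cM",
    "haldane_cM",
    "estimate_target_position",
    "analyze_markers",
    "delimit_interval",
    "genes_in_interval",
]

#: recognised missing-genotype codes in marker tables
MISSING = {"-", "", "NA", None}

_GAMETES_PER_CALL = {"A": (0, 2), "H": (1, 2), "B": (2, 2)}


@dataclass(frozen=True)
class MarkerLinkage:
    """Two-point linkage of one marker to the target locus."""

    marker: str
    pos_bp: int
    n_recombinant: int  # R
    n_gametes: int  # 2N (scored gametes)
    side: str = "?"  # L | R | ? (relative to the target)

    @property
    def r(self) -> float:
        return self.n_recombinant / self.n_gametes

    @property
    def linked(self) -> bool:
        return self.r < 0.5

    @property
    def distance_cm(self) -> float | None:
        return kosambi_cM(self.r) if self.linked else None


@dataclass
class IntervalResult:
    """Flanking-marker delimitation of the target locus."""

    left: MarkerLinkage | None
    right: MarkerLinkage | None
    cosegregating: list[MarkerLinkage] = field(default_factory=list)

    @property
    def one_sided(self) -> bool:
        return (self.left is None) != (self.right is None)

    @property
    def start(self) -> int | None:
        return self.left.pos_bp if self.left else None

    @property
    def end(self) -> int | None:
        return self.right.pos_bp if self.right else None


def recomb_fraction_recessive(calls) -> tuple[int, int, float]:
    """Recombinant-gamete count from one marker column of a recessive-class
    population.

    ``calls`` is an iterable of {'A', 'H', 'B'} plus missing codes; missing
    cells are excluded from the scored gametes (no imputation).  Returns
    (R, 2N, r).  r = 1 marks a marker behaving as fully unlinked/repulsed;
    callers should treat r ≥ 0.5 as unlinked.
    """
    R = 0
    two_n = 0
    for call in calls:
        if call in MISSING or (isinstance(call, float) and math.isnan(call)):
            continue
        try:
            rec, scored = _GAMETES_PER_CALL[call]
        except KeyError:
            raise ValueError(f"unknown genotype call {call!r}") from None
        R += rec
        two_n += scored
    if two_n == 0:
        raise ValueError("all genotype calls missing for this marker")
    return R, two_n, R / two_n


def kosambi_cM(r: float) -> float:
    """Kosambi map distance d = 25·ln((1+2r)/(1−2r)) cM for r ∈ [0, 0.5)."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def haldane_cM(r: float) -> float:
    """Haldane map distance d = −50·ln(1−2r) cM for r ∈ [0, 0.5)."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -50.0 * math.log(1 - 2 * r)


def _recombinant_dosage(calls: pd.Series) -> np.ndarray:
    """Recombinant gametes per individual for one marker (0/1/2, NaN for
    missing calls)."""
    dosage = {"A": 0.0, "H": 1.0, "B": 2.0}
    return np.array(
        [
            np.nan
            if (c in MISSING or (isinstance(c, float) and math.isnan(c)))
            else dosage[c]
            for c in calls
        ]
    )


def estimate_target_position(
    genotypes: pd.DataFrame, results: list[MarkerLinkage]
) -> int:
    """Locate the target between markers from the recombinant structure.

    Around the minimum-r marker (anchor), individuals recombinant at
    markers on *opposite* sides of the target are (barring double
    crossovers) disjoint sets, while markers on the same side share their
    recombinants.  Comparing the anchor's recombinant overlap with its two
    physical neighbours therefore tells which inter-marker interval holds
    the target; the returned bp position is that interval's midpoint (or
    the anchor position itself when the anchor co-segregates).
    """
    # markers in repulsion phase or unlinked (r >= 0.5) carry no usable
    # two-point signal here and are excluded
    ordered = [m for m in sorted(results, key=lambda m: m.pos_bp) if m.linked]
    if not ordered:
        return min(results, key=lambda m: m.r).pos_bp
    k = min(range(len(ordered)), key=lambda i: ordered[i].r)
    anchor = ordered[k]
    if anchor.n_recombinant == 0 or len(ordered) == 1:
        return anchor.pos_bp

    d_anchor = _recombinant_dosage(genotypes[anchor.marker])

    def nested(m: MarkerLinkage) -> bool:
        # same side as the anchor <=> the anchor's recombinants recur at m
        d = _recombinant_dosage(genotypes[m.marker])
        shared = float(np.nansum(np.minimum(d_anchor, d)))
        return shared >= 0.5 * anchor.n_recombinant

    left = ordered[k - 1] if k > 0 else None
    right = ordered[k + 1] if k + 1 < len(ordered) else None
    left_nested = left is not None and nested(left)
    right_nested = right is not None and nested(right)
    if right_nested and not left_nested:
        # anchor and its right neighbour flank the target from the right
        return (left.pos_bp + anchor.pos_bp) // 2 if left is not None else anchor.pos_bp - 1
    if left_nested and not right_nested:
        return (anchor.pos_bp + right.pos_bp) // 2 if right is not None else anchor.pos_bp + 1
    # ambiguous (shared recombinants on both sides or neither): lean toward
    # the tighter neighbour
    neighbour = min((m for m in (left, right) if m is not None), key=lambda m: m.r)
    return (anchor.pos_bp + neighbour.pos_bp) // 2


def analyze_markers(
    genotypes: pd.DataFrame,
    marker_positions: dict[str, int] | pd.Series,
    target_pos_hint: int | None = None,
) -> list[MarkerLinkage]:
    """Two-point linkage of every marker column against the target.

    ``genotypes`` is individuals × markers (A/H/B/missing).  Marker sides
    are oriented relative to the target: either an explicit
    ``target_pos_hint`` (e.g. the bulked-segregant peak) or, by default,
    the position inferred from the recombinant structure by
    :func:`estimate_target_position` (full multipoint ordering is
    delegated to dedicated mapping software and out of scope here).
    """
    results = []
    for marker in genotypes.columns:
        if marker not in marker_positions:
            raise KeyError(f"no position for marker {marker}")
        pos = int(marker_positions[marker])
        R, two_n, _ = recomb_fraction_recessive(genotypes[marker])
        results.append(MarkerLinkage(str(marker), pos, R, two_n))
    results.sort(key=lambda m: m.pos_bp)
    if target_pos_hint is None:
        target_pos_hint = estimate_target_position(genotypes, results)
    return [
        MarkerLinkage(
            m.marker,
            m.pos_bp,
            m.n_recombinant,
            m.n_gametes,
            "L" if m.pos_bp < target_pos_hint else "R",
        )
        for m in results
    ]


def delimit_interval(
    results: list[MarkerLinkage], target_pos_hint: int | None = None
) -> IntervalResult:
    """Flanking-marker interval around the target locus.

    The flank on each side is the minimum-r linked marker with at least one
    recombinant (a co-segregating marker, R = 0, lies inside the interval
    and cannot bound it).  When only one side carries recombinant markers
    the interval is one-sided and flagged.
    """
    if target_pos_hint is not None:
        results = [
            MarkerLinkage(
                m.marker,
                m.pos_bp,
                m.n_recombinant,
                m.n_gametes,
                "L" if m.pos_bp < target_pos_hint else "R",
            )
            for m in results
        ]
    coseg = [m for m in results if m.n_recombinant == 0]
    flanks: dict[str, MarkerLinkage | None] = {"L": None, "R": None}
    for m in results:
        if m.n_recombinant == 0 or not m.linked or m.side not in flanks:
            continue
        best = flanks[m.side]
        if best is None or m.r < best.r:
            flanks[m.side] = m
    return IntervalResult(flanks["L"], flanks["R"], coseg)


def genes_in_interval(
    annotation: pd.DataFrame, chrom: str, start: int, end: int
) -> pd.DataFrame:
    """Genes whose span overlaps [start, end] on ``chrom`` (any overlap,
    1-based inclusive), in positional order.  ``annotation`` needs columns
    gene_id, chrom, start, end."""
    if start > end:
        start, end = end, start
    hit = (
        (annotation["chrom"] == chrom)
        & (annotation["start"] <= end)
        & (annotation["end"] >= start)
    )
    return annotation[hit].sort_values("start", ignore_index=True)
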