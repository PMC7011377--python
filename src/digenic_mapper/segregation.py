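"""Segregation-ratio statistics for the digenic recessive model.

Covers the genetic-analysis stage of the study design: observed
green:yellow ratios, Yates-corrected chi-square goodness-of-fit against a
hypothesized Mendelian ratio, family classification (all-green / 3:1 /
15:1), nuclear-vs-cytoplasmic inference from reciprocal F1, and the exact
model expectations (15:1 F2, 3:1 BC1×mutant, 7:4:4 F2:3 family types,
2:1 F3:4 family types) computed by enumeration of gamete combinations
rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from .genome import MUTANT_ALLELE, WILD_ALLELE

__all__ = [
    "SegregationCount",
    "RatioTestResult",
    "FamilyClass",
    "DEFAULT_CRITICAL",
    "phenotype_ratio",
    "chi_square_yates",
    "ratio_test",
    "classify_family",
    "expected_composition",
    "infer_inheritance_mode",
]

#: chi-square critical value at df = 1, alpha = 0.05
DEFAULT_CRITICAL = 3.84


@dataclass(frozen=True)
class SegregationCount:
    n_total: int
    n_green: int
    n_yellow: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_green, self.n_yellow) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_green + self.n_yellow != self.n_total:
            raise ValueError("green + yellow must equal total")


@dataclass(frozen=True)
class RatioTestResult:
    observed_ratio: float | None  # green per one yellow, 2 dp; None if no yellow
    hypothesized: tuple[float, float]
    chi2: float
    critical: float = DEFAULT_CRITICAL

    @property
    def consistent(self) -> bool:
        return self.chi2 < self.critical


@dataclass(frozen=True)
class FamilyClass:
    label: str  # all_green | seg_3_1 | seg_15_1 | other
    chi2_3_1: float | None = None
    chi2_15_1: float | None = None


def _round2(x: Fraction | float) -> float:
    """Half-up rounding to two decimals (table-report convention)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(x))
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def phenotype_ratio(c: SegregationCount) -> float:
    """Observed green:yellow ratio (green per one yellow), 2 decimals."""
    if c.n_yellow == 0:
        raise ZeroDivisionError(
            "no yellow plants: ratio undefined (family is all_green)"
        )
    return _round2(Fraction(c.n_green, c.n_yellow))


def chi_square_yates(
    c: SegregationCount,
    ratio: tuple[float, float],
    yates: bool = True,
) -> float:
    """Chi-square goodness of fit against a hypothesized green:yellow ratio.

    With the (default) Yates continuity correction each term is
    (max(|O−E|−0.5, 0))²/E, df = 1.  The correction is truncated at zero
    so a perfect fit gives exactly 0.
    """
    g, y = ratio
    if g <= 0 or y <= 0:
        raise ValueError("ratio terms must be positive")
    if c.n_total <= 0:
        raise ValueError("empty family")
    total = g + y
    chi2 = 0.0
    for obs, weight in ((c.n_green, g), (c.n_yellow, y)):
        expected = c.n_total * weight / total
        if expected == 0:
            raise ValueError("zero expected count")
        dev = abs(obs - expected)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / expected
    return chi2


def ratio_test(
    c: SegregationCount,
    ratio: tuple[float, float],
    critical: float = DEFAULT_CRITICAL,
    yates: bool = True,
) -> RatioTestResult:
    observed = phenotype_ratio(c) if c.n_yellow > 0 else None
    return RatioTestResult(observed, ratio, chi_square_yates(c, ratio, yates), critical)


def classify_family(
    c: SegregationCount, critical: float = DEFAULT_CRITICAL, yates: bool = True
) -> FamilyClass:
    """Classify a selfed family as all_green, 3:1, 15:1 or other.

    All-green requires literally zero yellow plants; otherwise the family
    is assigned to whichever of the 3:1 / 15:1 hypotheses it fits at the
    critical value (the smaller chi-square when both fit)."""
    if c.n_total <= 0:
        raise ValueError("empty family")
    if c.n_yellow == 0:
        return FamilyClass("all_green")
    chi31 = chi_square_yates(c, (3, 1), yates)
    chi151 = chi_square_yates(c, (15, 1), yates)
    fits31 = chi31 < critical
    fits151 = chi151 < critical
    if fits31 and (not fits151 or chi31 <= chi151):
        label = "seg_3_1"
    elif fits151:
        label = "seg_15_1"
    else:
        label = "other"
    return FamilyClass(label, chi31, chi151)


# ---------------------------------------------------------------------------
# exact expectations by enumeration
# ---------------------------------------------------------------------------

def _norm(genotype):
    """Genotype over the two loci as a tuple of sorted allele pairs."""
    return tuple(tuple(sorted(locus)) for locus in genotype)


def _gamete_dist(genotype) -> dict:
    """Gamete distribution of a two-locus genotype (unlinked loci)."""
    out: dict[tuple[int, int], Fraction] = {}
    for a in genotype[0]:
        for b in genotype[1]:
            g = (a, b)
            out[g] = out.get(g, Fraction(0)) + Fraction(1, 4)
    return out


def _cross_dist(g1, g2) -> dict:
    """Offspring genotype distribution of g1 × g2 by gamete enumeration."""
    d1, d2 = _gamete_dist(g1), _gamete_dist(g2)
    out: dict[tuple, Fraction] = {}
    for gam1, p1 in d1.items():
        for gam2, p2 in d2.items():
            geno = _norm(((gam1[0], gam2[0]), (gam1[1], gam2[1])))
            out[geno] = out.get(geno, Fraction(0)) + p1 * p2
    return out


def _is_yellow(genotype) -> bool:
    return all(locus == (MUTANT_ALLELE, MUTANT_ALLELE) for locus in genotype)


def _yellow_prob(dist) -> Fraction:
    return sum((p for g, p in dist.items() if _is_yellow(g)), Fraction(0))


def _family_type_of_parent(genotype) -> str:
    """Selfed-family type implied by a green parent's two-locus genotype."""
    q = _yellow_prob(_cross_dist(genotype, genotype))
    if q == 0:
        return "all_green"
    if q == Fraction(1, 4):
        return "seg_3_1"
    if q == Fraction(1, 16):
        return "seg_15_1"
    return "other"


_F1 = _norm(((WILD_ALLELE, MUTANT_ALLELE), (WILD_ALLELE, MUTANT_ALLELE)))
_MUTANT = _norm(((MUTANT_ALLELE, MUTANT_ALLELE), (MUTANT_ALLELE, MUTANT_ALLELE)))


def expected_composition(tag: str) -> dict[str, Fraction]:
    """Exact expected composition of a generation under the digenic model.

    Computed by enumerating parental gamete combinations and conditioning:

    - ``F2_phenotypes``: green:yellow = 15:1 in the selfed F1.
    - ``BC1_mutant_phenotypes``: green:yellow = 3:1 in F1 × mutant.
    - ``F23_family_types``: selfing a random *green* F2 gives all_green :
      3:1 : 15:1 families in 7:4:4.
    - ``F34_family_types``: selfing a random green plant of a 3:1 family
      gives segregating (3:1) : all_green in 2:1.
    """
    if tag == "F2_phenotypes":
        dist = _cross_dist(_F1, _F1)
        q = _yellow_prob(dist)
        return {"green": 1 - q, "yellow": q}
    if tag == "BC1_mutant_phenotypes":
        dist = _cross_dist(_F1, _MUTANT)
        q = _yellow_prob(dist)
        return {"green": 1 - q, "yellow": q}
    if tag == "F23_family_types":
        f2 = _cross_dist(_F1, _F1)
        green = {g: p for g, p in f2.items() if not _is_yellow(g)}
        total = sum(green.values(), Fraction(0))
        out: dict[str, Fraction] = {}
        for g, p in green.items():
            t = _family_type_of_parent(g)
            out[t] = out.get(t, Fraction(0)) + p / total
        return out
    if tag == "F34_family_types":
        # green plants of a 3:1-segregating F2:3 family, selfed
        f2 = _cross_dist(_F1, _F1)
        parents_31 = {
            g: p
            for g, p in f2.items()
            if not _is_yellow(g) and _family_type_of_parent(g) == "seg_3_1"
        }
        out = {}
        norm = Fraction(0)
        for parent, pw in parents_31.items():
            offspring = _cross_dist(parent, parent)
            for g, p in offspring.items():
                if _is_yellow(g):
                    continue
                t = _family_type_of_parent(g)
                out[t] = out.get(t, Fraction(0)) + pw * p
                norm += pw * p
        return {t: p / norm for t, p in out.items()}
    raise ValueError(f"unknown generation tag: {tag}")


def infer_inheritance_mode(
    f1_forward: SegregationCount, f1_reverse: SegregationCount
) -> str:
    """Nuclear vs cytoplasmic inheritance from reciprocal F1 phenotypes.

    Identical phenotype distributions in the reciprocal crosses indicate
    nuclear inheritance; a phenotype tracking the maternal parent
    (all green one way, all yellow the other) suggests cytoplasmic."""
    for c in (f1_forward, f1_reverse):
        if c.n_total == 0:
            raise ValueError("empty F1 family")
    p_fwd = Fraction(f1_forward.n_yellow, f1_forward.n_total)
    p_rev = Fraction(f1_reverse.n_yellow, f1_reverse.n_total)
    maternal_tracking = {p_fwd, p_rev} == {Fraction(0), Fraction(1)}
    return "cytoplasmic_suspected" if maternal_tracking else "nuclear"
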