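"""Genome model for the breeding simulator.

A :class:`GenomeModel` describes the chromosomes, the marker panel and the
causal loci of the simulated cross.  The default genome mimics a *Brassica
rapa*-like A genome: ten chromosomes A01–A10, 30 Mb / 100 cM each with a
uniform physical↔genetic map, and two unlinked recessive causal loci, *PY1*
on A09 and *PY2* on A07.  Because the causal loci sit on different
chromosomes they assort independently, which is what produces the 15:1
F2 phenotype ratio of a duplicate-recessive (digenic epistatic) trait.

All loci (markers plus causal positions) are kept in a single sorted
per-genome array layout so that gamete formation can be vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Chromosome", "CausalLocus", "Marker", "GenomeModel", "default_genome"]

#: Allele codes used on haplotypes: 0 = wild-parent allele (P / reference),
#: 1 = mutant-parent allele (p / alternate).
WILD_ALLELE = 0
MUTANT_ALLELE = 1


@dataclass(frozen=True)
class Chromosome:
    id: str
    length_bp: int
    length_cm: float

    def cm_of(self, pos_bp: int) -> float:
        """Genetic position of a physical position under a uniform map."""
        return pos_bp / self.length_bp * self.length_cm


@dataclass(frozen=True)
class Marker:
    id: str
    chrom: str
    pos_bp: int
    pos_cm: float


@dataclass(frozen=True)
class CausalLocus:
    id: str
    chrom: str
    pos_bp: int
    pos_cm: float
    wild_allele: str = "P"
    mutant_allele: str = "p"


@dataclass
class GenomeModel:
    """Chromosomes + marker panel + causal loci, with a flat locus layout.

    Parameters
    ----------
    chromosomes:
        Chromosome list in karyotype order.
    markers:
        Marker loci; cM positions must be non-decreasing with bp within a
        chromosome.
    causal_loci:
        One or two recessive causal loci.  The digenic default has exactly
        two, on distinct chromosomes (independent assortment, 15:1 in F2).
        A single locus yields an ordinary monogenic recessive trait (3:1).
    """

    chromosomes: list[Chromosome]
    markers: list[Marker]
    causal_loci: list[CausalLocus]

    # flat arrays over all loci, filled in __post_init__
    locus_names: np.ndarray = field(init=False, repr=False)
    locus_chrom: np.ndarray = field(init=False, repr=False)
    locus_pos_bp: np.ndarray = field(init=False, repr=False)
    locus_pos_cm: np.ndarray = field(init=False, repr=False)
    locus_is_causal: np.ndarray = field(init=False, repr=False)
    causal_indices: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        if not 1 <= len(self.causal_loci) <= 2:
            raise ValueError("expected one or two causal loci")
        if len(self.causal_loci) == 2:
            c1, c2 = self.causal_loci
            if c1.chrom == c2.chrom:
                raise ValueError(
                    "the two causal loci must lie on distinct chromosomes "
                    "(unlinked, 15:1 F2 segregation)"
                )
        chrom_ids = [c.id for c in self.chromosomes]
        if len(set(chrom_ids)) != len(chrom_ids):
            raise ValueError("duplicate chromosome ids")
        by_id = {c.id: c for c in self.chromosomes}
        for locus in [*self.markers, *self.causal_loci]:
            if locus.chrom not in by_id:
                raise ValueError(f"locus {locus.id} on unknown chromosome {locus.chrom}")

        order = {cid: i for i, cid in enumerate(chrom_ids)}
        entries = [
            (order[m.chrom], m.pos_bp, m.id, m.chrom, m.pos_cm, False) for m in self.markers
        ] + [
            (order[c.chrom], c.pos_bp, c.id, c.chrom, c.pos_cm, True) for c in self.causal_loci
        ]
        entries.sort(key=lambda e: (e[0], e[1]))
        self.locus_names = np.array([e[2] for e in entries], dtype=object)
        self.locus_chrom = np.array([e[3] for e in entries], dtype=object)
        self.locus_pos_bp = np.array([e[1] for e in entries], dtype=np.int64)
        self.locus_pos_cm = np.array([e[4] for e in entries], dtype=float)
        self.locus_is_causal = np.array([e[5] for e in entries], dtype=bool)
        # in causal_loci list order (not genome position order)
        name_to_idx = {name: i for i, name in enumerate(self.locus_names)}
        self.causal_indices = np.array(
            [name_to_idx[c.id] for c in self.causal_loci], dtype=np.int64
        )

        # marker cM must be non-decreasing in bp within each chromosome
        for cid in chrom_ids:
            sel = self.locus_chrom == cid
            cms = self.locus_pos_cm[sel]
            if np.any(np.diff(cms) < 0):
                raise ValueError(f"cM positions not monotone with bp on {cid}")

        # Haplotype-switch probabilities between consecutive loci: the
        # Haldane probability of an odd number of Poisson crossovers in the
        # interval; 0.5 across chromosome boundaries (independent
        # assortment) and for the leading locus (fair starting strand).
        p = np.empty(len(entries))
        p[0] = 0.5
        same_chrom = self.locus_chrom[1:] == self.locus_chrom[:-1]
        d_cm = np.diff(self.locus_pos_cm)
        p[1:] = np.where(same_chrom, 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0)), 0.5)
        self._switch_p = p

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def is_digenic(self) -> bool:
        return len(self.causal_loci) == 2

    def chromosome(self, cid: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def locus_index(self, name: str) -> int:
        hits = np.flatnonzero(self.locus_names == name)
        if len(hits) == 0:
            raise KeyError(name)
        return int(hits[0])


def default_genome(
    markers_per_chromosome: int = 800,
    n_chromosomes: int = 10,
    chrom_length_bp: int = 30_000_000,
    chrom_length_cm: float = 100.0,
    py1_pos: tuple[str, int] = ("A09", 25_000_000),
    py2_pos: tuple[str, int] | None = ("A07", 13_000_000),
) -> GenomeModel:
    """Build the default ten-chromosome genome with an even marker grid.

    Markers are evenly spaced with a half-spacing offset so no marker
    coincides with a causal position.  ``py2_pos=None`` gives the
    single-locus (monogenic recessive) variant of the model.
    """
    chroms = [
        Chromosome(f"A{i + 1:02d}", chrom_length_bp, chrom_length_cm)
        for i in range(n_chromosomes)
    ]
    by_id = {c.id: c for c in chroms}
    markers = []
    for c in chroms:
        spacing = c.length_bp / markers_per_chromosome
        for j in range(markers_per_chromosome):
            bp = int(round((j + 0.5) * spacing))
            markers.append(Marker(f"M{c.id}_{j + 1:03d}", c.id, bp, c.cm_of(bp)))
    causal = [
        CausalLocus("PY1", py1_pos[0], py1_pos[1], by_id[py1_pos[0]].cm_of(py1_pos[1]))
    ]
    if py2_pos is not None:
        causal.append(
            CausalLocus("PY2", py2_pos[0], py2_pos[1], by_id[py2_pos[0]].cm_of(py2_pos[1]))
        )
    return GenomeModel(chroms, markers, causal)
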