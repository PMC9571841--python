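"""Core domain objects shared across the pipeline.

The experimental design these objects model: a recessive, EMS-induced point
mutation in a cultivated (reference-like) background is mapped by crossing the
mutant to a distant wild relative, selfing the F1, and sequencing two pooled
DNA samples of phenotypically contrasting F2 plants.  At every interspecific
marker the *non-reference* allele is the wild-parent allele, so the mutant
pool's non-reference allele frequency collapses to zero around the causal
locus while staying near 1/2 elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

# Parental origins of a haplotype segment.
CULTIVATED = 0
WILD = 1
PARENT_LABELS = {CULTIVATED: "CULTIVATED", WILD: "WILD"}

# Variant origins.
MARKER = "MARKER"       # fixed interspecific difference, informative for linkage
INDUCED = "INDUCED"     # mutagen-induced lesion on the cultivated background

# Pool / phenotype labels.
MUT_POOL = "MUT"
WT_POOL = "WT"
PHENO_MUT = "MUT"
PHENO_WT = "WT"


def natural_key(name: str):
    """Sort key treating digit runs numerically, so chr2 < chr11."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name))


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the genetic map: physical and genetic length."""

    name: str
    length_bp: int
    length_cM: float

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError(f"{self.name}: length_bp must be >= 1")
        if self.length_cM < 0:
            raise ValueError(f"{self.name}: length_cM must be >= 0")


@dataclass
class GeneticMap:
    """Genome skeleton for the simulation: chromosomes, marker grid, causal locus.

    ``causal_locus`` is ``(chromosome_name, position_bp)`` of the recessive
    lesion carried by the cultivated parent, or ``None`` for a null genome.
    """

    chromosomes: list[Chromosome]
    marker_spacing_bp: int = 100_000
    causal_locus: tuple[str, int] | None = None

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("GeneticMap needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.marker_spacing_bp < 1:
            raise ValueError("marker_spacing_bp must be >= 1")
        if self.causal_locus is not None:
            chrom, pos = self.causal_locus
            length = self.chromosome(chrom).length_bp
            if not 1 <= pos <= length:
                raise ValueError(
                    f"causal locus {chrom}:{pos} outside [1, {length}]"
                )

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def contigs(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}


@dataclass
class Haplotype:
    """A single gametic haplotype as a step function of parental origin.

    ``ends[i]`` is the (1-based, inclusive) last position of segment ``i``;
    ``origins[i]`` is CULTIVATED or WILD.  The first segment implicitly starts
    at position 1 and ``ends[-1]`` equals the chromosome length.
    """

    ends: np.ndarray
    origins: np.ndarray

    def __post_init__(self):
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.origins = np.asarray(self.origins, dtype=np.int8)
        if self.ends.ndim != 1 or self.ends.shape != self.origins.shape:
            raise ValueError("ends and origins must be 1-D arrays of equal length")
        if len(self.ends) == 0:
            raise ValueError("haplotype needs at least one segment")
        if np.any(np.diff(self.ends) <= 0):
            raise ValueError("segment ends must be strictly increasing")

    def origin_at(self, pos: int) -> int:
        return int(self.origins[np.searchsorted(self.ends, pos)])

    def origins_at(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized parental origin lookup at many positions."""
        idx = np.searchsorted(self.ends, np.asarray(positions, dtype=np.int64))
        return self.origins[idx]

    @property
    def segments(self) -> list[tuple[int, int, str]]:
        """Explicit (start, end, parent) breakpoint list."""
        starts = np.concatenate([[1], self.ends[:-1] + 1])
        return [
            (int(s), int(e), PARENT_LABELS[int(o)])
            for s, e, o in zip(starts, self.ends, self.origins)
        ]


@dataclass
class F2Individual:
    """One F2 plant: two haplotypes per chromosome plus a phenotype label."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype: str | None = None

    def genotype_at(self, chrom: str, pos: int) -> tuple[int, int]:
        h1, h2 = self.haplotypes[chrom]
        return h1.origin_at(pos), h2.origin_at(pos)


@dataclass
class VariantSite:
    """One biallelic site with per-pool allele-depth counts.

    ``counts[pool]`` is ``(ref_count, nonref_count)`` or ``None`` when the
    pool has no data at the site (e.g. zero sampled depth, empty pool).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str = MARKER
    counts: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref equals alt")
        for pool, c in self.counts.items():
            if c is not None and (c[0] < 0 or c[1] < 0):
                raise ValueError(f"negative counts for pool {pool}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def depth(self, pool: str) -> int | None:
        c = self.counts.get(pool)
        return None if c is None else c[0] + c[1]
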