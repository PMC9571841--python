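"""Synthetic data for the bulk-segregant mapping pipeline.

Everything downstream stages consume can be generated here with known ground
truth: an F2 population from a cultivated-mutant x wild-relative cross,
phenotype-stratified DNA pools, interspecific marker sites, an EMS-spectrum
set of induced mutations (including the causal lesion inside a synthetic gene
model), pooled sequencing counts, segregating-family counts, and
dose-response germination/fertility tables.

Recombination follows the Haldane model: crossover counts per gamete are
Poisson with mean ``length_cM / 100`` (the map length in Morgans) and
crossover positions are uniform in physical coordinates, i.e. a constant
recombination rate along the chromosome and no interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .types import (
    CULTIVATED,
    WILD,
    MARKER,
    INDUCED,
    MUT_POOL,
    WT_POOL,
    PHENO_MUT,
    PHENO_WT,
    Chromosome,
    F2Individual,
    GeneticMap,
    Haplotype,
    VariantSite,
    natural_key,
)
from .variants import GeneModel

# EMS mutation spectrum categories.
GC_TO_AT = "GC_to_AT_transition"
OTHER_SUB = "other_substitution"
SINGLE_DEL = "single_base_deletion"

#: Default spectrum: EMS overwhelmingly alkylates G, yielding G:C -> A:T
#: transitions; the remainder is split between other substitutions and
#: single-base deletions (the lesion class of the causal mutation).
DEFAULT_SPECTRUM = {GC_TO_AT: 0.90, OTHER_SUB: 0.05, SINGLE_DEL: 0.05}

_TRANSITIONS_GC = [("G", "A"), ("C", "T")]
_OTHER_SNVS = [
    ("A", "G"), ("T", "C"),                     # AT->GC transitions
    ("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
    ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G"),
]
_BASES = "ACGT"


def default_map() -> GeneticMap:
    """Desk-scale analog of the mapping design: 2 chromosomes x 50 Mb.

    Each chromosome carries ~60 cM; the recessive causal lesion sits near the
    distal end of the second chromosome, echoing a telomere-proximal causal
    gene.
    """
    return GeneticMap(
        chromosomes=[
            Chromosome("chr1", 50_000_000, 60.0),
            Chromosome("chr2", 50_000_000, 60.0),
        ],
        marker_spacing_bp=100_000,
        causal_locus=("chr2", 42_000_000),
    )


# ---------------------------------------------------------------------------
# F2 population
# ---------------------------------------------------------------------------

def simulate_gamete(chrom: Chromosome, rng: np.random.Generator) -> Haplotype:
    """One recombinant gamete from a fully heterozygous F1."""
    n_x = rng.poisson(chrom.length_cM / 100.0)
    if n_x > 0:
        cuts = np.unique(rng.integers(1, chrom.length_bp, size=n_x))
    else:
        cuts = np.empty(0, dtype=np.int64)
    ends = np.concatenate([cuts, [chrom.length_bp]])
    start = int(rng.integers(0, 2))
    origins = (start + np.arange(len(ends))) % 2
    return Haplotype(ends=ends, origins=origins)


def simulate_gametes(chrom: Chromosome, n: int, seed: int) -> list[Haplotype]:
    """``n`` independent gametes on one chromosome (for map-function checks)."""
    rng = np.random.default_rng(seed)
    return [simulate_gamete(chrom, rng) for _ in range(n)]


def simulate_f2_population(
    gmap: GeneticMap,
    n: int,
    seed: int,
    assign_phenotype: bool = True,
) -> list[F2Individual]:
    """Simulate ``n`` F2 individuals as unions of two independent F1 gametes.

    Phenotype is assigned by the fully penetrant recessive rule: MUT iff both
    haplotypes are CULTIVATED at the causal locus (the lesion arose in, and is
    linked to, the cultivated background).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if assign_phenotype and gmap.causal_locus is None:
        raise ValueError("phenotype assignment requested but the map has no causal locus")
    rng = np.random.default_rng(seed)
    population = []
    for _ in range(n):
        haps = {
            c.name: (simulate_gamete(c, rng), simulate_gamete(c, rng))
            for c in gmap.chromosomes
        }
        ind = F2Individual(haplotypes=haps)
        if assign_phenotype:
            chrom, pos = gmap.causal_locus
            g = ind.genotype_at(chrom, pos)
            ind.phenotype = PHENO_MUT if g == (CULTIVATED, CULTIVATED) else PHENO_WT
        population.append(ind)
    return population


def build_pools(
    individuals: list[F2Individual],
    n_mut: int = 15,
    n_wt: int = 15,
    seed: int = 0,
) -> tuple[list[F2Individual], list[F2Individual]]:
    """Draw disjoint random pools stratified by phenotype."""
    rng = np.random.default_rng(seed)
    mut_idx = [i for i, ind in enumerate(individuals) if ind.phenotype == PHENO_MUT]
    wt_idx = [i for i, ind in enumerate(individuals) if ind.phenotype == PHENO_WT]
    if len(mut_idx) < n_mut:
        raise ValueError(f"need {n_mut} MUT individuals, only {len(mut_idx)} available")
    if len(wt_idx) < n_wt:
        raise ValueError(f"need {n_wt} WT individuals, only {len(wt_idx)} available")
    mut_sel = rng.choice(mut_idx, size=n_mut, replace=False) if n_mut else []
    wt_sel = rng.choice(wt_idx, size=n_wt, replace=False) if n_wt else []
    return ([individuals[i] for i in mut_sel], [individuals[i] for i in wt_sel])


def build_random_pools(
    individuals: list[F2Individual],
    n_mut: int = 15,
    n_wt: int = 15,
    seed: int = 0,
) -> tuple[list[F2Individual], list[F2Individual]]:
    """Phenotype-blind pools: the null model for calibration runs."""
    if len(individuals) < n_mut + n_wt:
        raise ValueError("not enough individuals for two disjoint pools")
    rng = np.random.default_rng(seed)
    sel = rng.choice(len(individuals), size=n_mut + n_wt, replace=False)
    return ([individuals[i] for i in sel[:n_mut]],
            [individuals[i] for i in sel[n_mut:]])


# ---------------------------------------------------------------------------
# Variant sites
# ---------------------------------------------------------------------------

# Deterministic cosmetic allele pairs for marker sites (alleles at markers
# carry no information; linkage lives in the counts).
_MARKER_ALLELES = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]


def place_markers(gmap: GeneticMap, spacing_bp: int | None = None) -> list[VariantSite]:
    """Interspecific markers on a regular grid.

    The non-reference (alt) allele at a marker is by convention the
    wild-parent allele; the reference genome is cultivated-like.
    """
    spacing = gmap.marker_spacing_bp if spacing_bp is None else spacing_bp
    if spacing < 1:
        raise ValueError("spacing_bp must be >= 1")
    sites = []
    for c in gmap.chromosomes:
        for i, pos in enumerate(range(spacing, c.length_bp + 1, spacing)):
            ref, alt = _MARKER_ALLELES[i % len(_MARKER_ALLELES)]
            sites.append(VariantSite(c.name, pos, ref, alt, origin=MARKER))
    return sites


def _draw_alleles(category: str, rng: np.random.Generator,
                  ref_base: str | None = None) -> tuple[str, str]:
    """ref/alt pair for one induced mutation of a given spectrum category.

    When the true reference base at the position is known (inside a patched
    gene region) it is respected; a base incompatible with the requested
    category demotes the category to the nearest compatible one.
    """
    if category == GC_TO_AT:
        if ref_base is None:
            ref, alt = _TRANSITIONS_GC[rng.integers(0, 2)]
        elif ref_base == "G":
            ref, alt = "G", "A"
        elif ref_base == "C":
            ref, alt = "C", "T"
        else:  # A/T base cannot host a G:C->A:T transition
            return _draw_alleles(OTHER_SUB, rng, ref_base)
        return ref, alt
    if category == OTHER_SUB:
        if ref_base is None:
            return _OTHER_SNVS[rng.integers(0, len(_OTHER_SNVS))]
        choices = [(r, a) for r, a in _OTHER_SNVS if r == ref_base]
        return choices[rng.integers(0, len(choices))]
    if category == SINGLE_DEL:
        anchor = ref_base or _BASES[rng.integers(0, 4)]
        deleted = _BASES[rng.integers(0, 4)]
        return anchor + deleted, anchor
    raise ValueError(f"unknown spectrum category {category!r}")


def spike_ems_mutations(
    gmap: GeneticMap,
    n_mutations: int,
    spectrum: dict[str, float] | None = None,
    seed: int = 0,
    causal: VariantSite | None = None,
    reference: "ReferenceBundle | None" = None,
) -> list[VariantSite]:
    """Scatter induced background mutations over the genome.

    All induced mutations ride on the CULTIVATED haplotype (they arose in the
    mutagenized cultivar), so near the causal locus the mutant pool is
    homozygous for them.  ``causal``, when given, is included exactly once
    with its configured coordinates.  ``reference`` (optional) supplies real
    reference bases for positions falling inside synthesized gene regions.
    """
    spectrum = dict(DEFAULT_SPECTRUM if spectrum is None else spectrum)
    if abs(sum(spectrum.values()) - 1.0) > 1e-9:
        raise ValueError("spectrum fractions must sum to 1")
    unknown = set(spectrum) - {GC_TO_AT, OTHER_SUB, SINGLE_DEL}
    if unknown:
        raise ValueError(f"unknown spectrum categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cats = list(spectrum.keys())
    probs = np.array([spectrum[c] for c in cats])
    lengths = np.array([c.length_bp for c in gmap.chromosomes], dtype=float)
    chrom_p = lengths / lengths.sum()

    taken = set()
    if causal is not None:
        taken.add((causal.chrom, causal.pos))
    sites: list[VariantSite] = []
    for _ in range(n_mutations):
        for _attempt in range(100):
            ci = rng.choice(len(gmap.chromosomes), p=chrom_p)
            chrom = gmap.chromosomes[ci]
            # keep room for an anchored deletion's second base
            pos = int(rng.integers(1, chrom.length_bp))
            if (chrom.name, pos) not in taken:
                break
        taken.add((chrom.name, pos))
        category = cats[rng.choice(len(cats), p=probs)]
        ref_base = None
        if reference is not None:
            ref_base = reference.genome.base_at(chrom.name, pos)
        ref, alt = _draw_alleles(category, rng, ref_base)
        sites.append(VariantSite(chrom.name, pos, ref, alt, origin=INDUCED))
    if causal is not None:
        sites.append(VariantSite(causal.chrom, causal.pos, causal.ref,
                                 causal.alt, origin=INDUCED))
    sites.sort(key=lambda s: (natural_key(s.chrom), s.pos))
    return sites


def _pool_nonref_freqs(
    sites_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    pool: list[F2Individual],
) -> dict[str, np.ndarray]:
    """True non-reference allele frequency per site for one pool.

    MARKER sites: non-reference = WILD allele -> q = wild-haplotype fraction.
    INDUCED sites: the lesion sits on every CULTIVATED haplotype -> q =
    cultivated-haplotype fraction.
    """
    out = {}
    for chrom, (positions, is_induced) in sites_by_chrom.items():
        wild = np.zeros(len(positions))
        for ind in pool:
            h1, h2 = ind.haplotypes[chrom]
            wild += (h1.origins_at(positions) == WILD)
            wild += (h2.origins_at(positions) == WILD)
        q_wild = wild / (2 * len(pool))
        out[chrom] = np.where(is_induced, 1.0 - q_wild, q_wild)
    return out


def simulate_pool_counts(
    sites: list[VariantSite],
    pools: dict[str, list[F2Individual]],
    depth_mean: float = 50.0,
    error_rate: float = 0.002,
    seed: int = 0,
) -> list[VariantSite]:
    """Pooled sequencing counts: depth ~ Poisson(depth_mean), non-reference
    reads ~ Binomial(depth, q(1-eps) + (1-q)eps).

    An empty pool leaves that pool's counts missing (``None``).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    chroms = sorted({s.chrom for s in sites}, key=natural_key)
    index: dict[str, list[int]] = {c: [] for c in chroms}
    for i, s in enumerate(sites):
        index[s.chrom].append(i)
    sites_by_chrom = {
        c: (
            np.array([sites[i].pos for i in idx], dtype=np.int64),
            np.array([sites[i].origin == INDUCED for i in idx]),
        )
        for c, idx in index.items()
    }
    freqs = {
        name: (_pool_nonref_freqs(sites_by_chrom, pool) if pool else None)
        for name, pool in pools.items()
    }
    out = [
        VariantSite(s.chrom, s.pos, s.ref, s.alt, origin=s.origin, counts={})
        for s in sites
    ]
    for name in pools:
        for chrom in chroms:
            idx = index[chrom]
            if freqs[name] is None:
                for i in idx:
                    out[i].counts[name] = None
                continue
            q = freqs[name][chrom]
            depth = rng.poisson(depth_mean, size=len(idx))
            p = q * (1 - error_rate) + (1 - q) * error_rate
            nonref = rng.binomial(depth, p)
            for j, i in enumerate(idx):
                out[i].counts[name] = (int(depth[j] - nonref[j]), int(nonref[j]))
    return out


# ---------------------------------------------------------------------------
# Synthetic reference (gene models + sparse sequence)
# ---------------------------------------------------------------------------

class PatchedGenome:
    """Synthetic sparse reference: real sequence only where gene models live.

    Chromosome-scale FASTA is never materialized; annotation only ever reads
    sequence inside coding regions, which are covered by explicit patches.
    """

    def __init__(self, patches: dict[str, list[tuple[int, str]]] | None = None):
        # patches[chrom] = [(start_1based, sequence), ...], non-overlapping
        self.patches = patches or {}

    def add(self, chrom: str, start: int, seq: str) -> None:
        self.patches.setdefault(chrom, []).append((start, seq))
        self.patches[chrom].sort()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice; raises if outside any patch."""
        for pstart, seq in self.patches.get(chrom, []):
            pend = pstart + len(seq) - 1
            if pstart <= start and end <= pend:
                return seq[start - pstart : end - pstart + 1]
        raise KeyError(f"{chrom}:{start}-{end} not covered by any sequence patch")

    def base_at(self, chrom: str, pos: int) -> str | None:
        try:
            return self.fetch(chrom, pos, pos)
        except KeyError:
            return None


@dataclass
class ReferenceBundle:
    """Gene models plus the sparse sequence backing them, with the causal
    lesion pre-computed as an anchored VCF-style deletion."""

    models: list[GeneModel]
    genome: PatchedGenome
    causal_site: VariantSite | None


def _random_stopfree_codons(n: int, rng: np.random.Generator) -> str:
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in stops:
            codons.append(codon)
    return "".join(codons)


def make_reference_bundle(
    gmap: GeneticMap,
    seed: int = 0,
    n_codons: int = 450,
    intron_bp: int = 400,
    flank_bp: int = 300,
) -> ReferenceBundle:
    """Synthesize a two-exon gene model harbouring the causal lesion.

    The spliced CDS is ``n_codons`` long (ATG start, single terminal stop, no
    internal stops), split 40/60 across two exons so the causal single-base
    deletion falls in the second exon.  The causal deletion is anchored at the
    map's causal locus position.
    """
    if gmap.causal_locus is None:
        return ReferenceBundle(models=[], genome=PatchedGenome(), causal_site=None)
    rng = np.random.default_rng(seed)
    chrom, causal_pos = gmap.causal_locus
    cds_len = 3 * n_codons
    cds_seq = "ATG" + _random_stopfree_codons(n_codons - 2, rng) + "TGA"
    exon1_len = (cds_len * 2 // 5) // 3 * 3  # codon-aligned split, ~40%
    exon2_len = cds_len - exon1_len

    # Place exon 2 so the causal position sits inside it with room for the
    # anchored deletion (pos and pos+1 both inside the exon).
    exon2_start = causal_pos - exon2_len // 3
    exon2_end = exon2_start + exon2_len - 1
    exon1_end = exon2_start - intron_bp - 1
    exon1_start = exon1_end - exon1_len + 1
    if exon1_start < 1:
        raise ValueError("causal locus too close to the chromosome start for the gene model")

    exon1_seq = cds_seq[:exon1_len]
    exon2_seq = cds_seq[exon1_len:]
    intron_seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=intron_bp))
    left_flank = "".join(_BASES[i] for i in rng.integers(0, 4, size=flank_bp))
    right_flank = "".join(_BASES[i] for i in rng.integers(0, 4, size=flank_bp))
    region_start = exon1_start - flank_bp
    region_seq = left_flank + exon1_seq + intron_seq + exon2_seq + right_flank

    genome = PatchedGenome()
    genome.add(chrom, region_start, region_seq)

    model = GeneModel(
        gene_id="synthetic_causal_gene",
        chrom=chrom,
        strand="+",
        cds=[(exon1_start, exon1_end), (exon2_start, exon2_end)],
        gene_start=region_start,
        gene_end=region_start + len(region_seq) - 1,
    )
    ref = genome.fetch(chrom, causal_pos, causal_pos + 1)
    causal_site = VariantSite(chrom, causal_pos, ref, ref[0], origin=INDUCED)
    return ReferenceBundle(models=[model], genome=genome, causal_site=causal_site)


# ---------------------------------------------------------------------------
# Whole-experiment driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment, serializable to JSON."""

    seed: int
    pool_size_mut: int
    pool_size_wt: int
    depth_mean: float
    error_rate: float
    causal: dict | None
    background: list[dict]
    spectrum: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationResult:
    gmap: GeneticMap
    population: list[F2Individual]
    pools: dict[str, list[F2Individual]]
    sites: list[VariantSite]
    reference: ReferenceBundle
    truth: SimulationTruth


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds, all below 2**31."""
    return [int(s) for s in
            (np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1))]


def simulate_experiment(
    gmap: GeneticMap | None = None,
    n_f2: int = 150,
    n_mut: int = 15,
    n_wt: int = 15,
    depth_mean: float = 50.0,
    error_rate: float = 0.002,
    n_background: int = 300,
    spectrum: dict[str, float] | None = None,
    marker_spacing_bp: int | None = None,
    seed: int = 0,
    random_phenotypes: bool = False,
) -> SimulationResult:
    """One full bulk-segregant experiment with ground truth.

    ``random_phenotypes=True`` builds phenotype-blind pools (no linkage
    signal anywhere) for null calibration.
    """
    gmap = default_map() if gmap is None else gmap
    s_ref, s_pop, s_pool, s_mut, s_counts = _stage_seeds(seed, 5)
    reference = make_reference_bundle(gmap, seed=s_ref)
    population = simulate_f2_population(
        gmap, n_f2, seed=s_pop, assign_phenotype=gmap.causal_locus is not None
    )
    if random_phenotypes:
        mut_pool, wt_pool = build_random_pools(population, n_mut, n_wt, seed=s_pool)
    else:
        mut_pool, wt_pool = build_pools(population, n_mut, n_wt, seed=s_pool)
    markers = place_markers(gmap, marker_spacing_bp)
    induced = spike_ems_mutations(
        gmap, n_background, spectrum, seed=s_mut,
        causal=reference.causal_site, reference=reference,
    )
    all_sites = sorted(markers + induced, key=lambda s: (natural_key(s.chrom), s.pos))
    pools = {MUT_POOL: mut_pool, WT_POOL: wt_pool}
    counted = simulate_pool_counts(all_sites, pools, depth_mean, error_rate, seed=s_counts)
    spectrum_used = dict(DEFAULT_SPECTRUM if spectrum is None else spectrum)
    causal = None
    if reference.causal_site is not None:
        c = reference.causal_site
        causal = {"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt}
    truth = SimulationTruth(
        seed=seed,
        pool_size_mut=n_mut,
        pool_size_wt=n_wt,
        depth_mean=depth_mean,
        error_rate=error_rate,
        causal=causal,
        background=[
            {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
            for s in induced
        ],
        spectrum=spectrum_used,
    )
    return SimulationResult(gmap, population, pools, counted, reference, truth)


# ---------------------------------------------------------------------------
# Family counts and dose-response tables
# ---------------------------------------------------------------------------

def simulate_segregation_family(n: int, ratio: list[float], seed: int = 0) -> np.ndarray:
    """Multinomial phenotype counts for one family under a hypothesized ratio."""
    if n < 1:
        raise ValueError("family size must be >= 1")
    ratio = np.asarray(ratio, dtype=float)
    if len(ratio) < 2:
        raise ValueError("ratio needs at least two classes")
    if np.any(ratio < 0) or ratio.sum() <= 0:
        raise ValueError("ratio must be non-negative with positive sum")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, ratio / ratio.sum())


@dataclass(frozen=True)
class DoseResponseParams:
    """Logistic declines for germination and (conditional) fertility.

    Each endpoint follows ``top / (1 + exp(slope * (dose - midpoint)))`` so
    the curve starts near ``top`` at dose 0 and declines through ``top/2`` at
    the midpoint.  Defaults echo a mutagenesis pilot where germination stays
    high through moderate doses while fertility collapses around 0.7%.
    """

    germination_max: float = 1.0
    germination_midpoint: float = 0.9
    germination_slope: float = 6.0
    fertility_max: float = 1.0
    fertility_midpoint: float = 0.78
    fertility_slope: float = 6.0

    def germination(self, dose: float) -> float:
        return self.germination_max / (
            1.0 + math.exp(self.germination_slope * (dose - self.germination_midpoint))
        )

    def fertility(self, dose: float) -> float:
        return self.fertility_max / (
            1.0 + math.exp(self.fertility_slope * (dose - self.fertility_midpoint))
        )


def simulate_dose_response(
    doses: list[float],
    replicates: int = 5,
    seeds_per_replicate: int = 100,
    params: DoseResponseParams | None = None,
    seed: int = 0,
):
    """Germination/fertility counts per dose and replicate.

    Returns a pandas DataFrame with columns dose, replicate, seeds,
    germinated, fertile; germinated ~ Binomial(seeds, g(dose)) and fertile ~
    Binomial(germinated, f(dose)).
    """
    import pandas as pd

    params = params or DoseResponseParams()
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    for top in (params.germination_max, params.fertility_max):
        if not 0 <= top <= 1:
            raise ValueError("endpoint maxima must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        g = params.germination(dose)
        f = params.fertility(dose)
        for rep in range(1, replicates + 1):
            germinated = int(rng.binomial(seeds_per_replicate, g))
            fertile = int(rng.binomial(germinated, f)) if germinated else 0
            rows.append((dose, rep, seeds_per_replicate, germinated, fertile))
    return pd.DataFrame(
        rows, columns=["dose", "replicate", "seeds", "germinated", "fertile"]
    )
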