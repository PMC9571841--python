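import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emsmap.types import CULTIVATED, WILD, Chromosome, F2Individual, GeneticMap, Haplotype
from emsmap.variants import GeneModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Hand-coded standard genetic code, independent of any library translation.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate_until_stop(cds: str) -> str:
    """Brute-force translation stopping at the first stop codon."""
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)


def make_cds(n_codons: int, seed: int) -> str:
    """Stop-free CDS with ATG start and TAA end, from a seeded generator."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
        if c not in stops:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def toy_plus_gene():
    """60-codon two-exon gene on the + strand of a 1 kb toy chromosome."""
    cds = make_cds(60, seed=7)  # 180 bp
    chrom_seq = list(random_dna(1000, seed=8))
    exon1 = (101, 190)
    exon2 = (251, 340)
    chrom_seq[exon1[0] - 1 : exon1[1]] = cds[:90]
    chrom_seq[exon2[0] - 1 : exon2[1]] = cds[90:]
    genome = {"toy1": "".join(chrom_seq)}
    model = GeneModel("toygene_plus", "toy1", "+", [exon1, exon2],
                      gene_start=90, gene_end=360)
    return model, genome, cds


@pytest.fixture(scope="session")
def toy_minus_gene():
    """Same CDS content on the - strand: genomic sequence is its revcomp."""
    cds = make_cds(60, seed=11)
    genomic = revcomp(cds)  # concatenated genomic CDS, 5'->3' on + strand
    chrom_seq = list(random_dna(1000, seed=12))
    exon1 = (101, 190)
    exon2 = (251, 340)
    chrom_seq[exon1[0] - 1 : exon1[1]] = genomic[:90]
    chrom_seq[exon2[0] - 1 : exon2[1]] = genomic[90:]
    genome = {"toy2": "".join(chrom_seq)}
    model = GeneModel("toygene_minus", "toy2", "-", [exon1, exon2],
                      gene_start=90, gene_end=360)
    return model, genome, cds


def uniform_individual(gmap: GeneticMap, parents: dict[str, tuple[int, int]],
                       phenotype=None) -> F2Individual:
    """Individual with breakpoint-free haplotypes of fixed parental origin."""
    haps = {}
    for c in gmap.chromosomes:
        p1, p2 = parents[c.name]
        haps[c.name] = (
            Haplotype(ends=np.array([c.length_bp]), origins=np.array([p1])),
            Haplotype(ends=np.array([c.length_bp]), origins=np.array([p2])),
        )
    return F2Individual(haplotypes=haps, phenotype=phenotype)


@pytest.fixture()
def tiny_map():
    return GeneticMap(
        chromosomes=[Chromosome("chrA", 1_000_000, 1.0)],
        marker_spacing_bp=100_000,
        causal_locus=("chrA", 500_000),
    )
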