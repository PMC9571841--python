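"""Candidate-variant triage inside a mapped region.

Mirrors the triage a mapping-by-sequencing analysis applies once a candidate
interval is localized: keep only variants that are homozygous in the mutant
pool and absent from a known-variants panel, classify them against the EMS
mutational spectrum, and annotate functional impact against gene models
(frameshift / nonsense / missense / synonymous / intronic / intergenic).
A small CAPS-marker helper checks whether a restriction site distinguishes
the mutant and wild-type amplicons for downstream genotyping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .types import MUT_POOL, VariantSite

# Effect categories.
INTERGENIC = "intergenic"
INTRONIC = "intronic"
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
OTHER = "other"

_DNA = set("ACGT")


@dataclass
class GeneModel:
    """Single-transcript gene model: ordered CDS segments on one strand.

    ``cds`` holds 1-based inclusive (start, end) pairs sorted by genomic
    start; for minus-strand genes the spliced CDS is the reverse complement
    of the concatenated segments.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]
    gene_start: int | None = None
    gene_end: int | None = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.cds:
            raise ValueError(f"{self.gene_id}: gene model without CDS segments")
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        prev_end = 0
        for s, e in self.cds:
            if s > e:
                raise ValueError(f"{self.gene_id}: CDS segment {s}-{e} reversed")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
            prev_end = e
        if self.gene_start is None:
            self.gene_start = self.cds[0][0]
        if self.gene_end is None:
            self.gene_end = self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.gene_start <= pos <= self.gene_end

    def cds_index(self, pos: int) -> int | None:
        """0-based index of a genomic position in the spliced (5'->3') CDS."""
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                plus_idx = offset + (pos - s)
                if self.strand == "+":
                    return plus_idx
                return self.cds_length - 1 - plus_idx
            offset += e - s + 1
        return None

    def spliced_cds(self, genome) -> str:
        """Spliced coding sequence, reverse-complemented for minus strand."""
        seq = "".join(_fetch(genome, self.chrom, s, e) for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class VariantEffect:
    """Predicted functional consequence of one variant."""

    category: str
    gene_id: str | None = None
    protein_change: str | None = None
    truncated_protein_length_aa: int | None = None
    diagnostic: str | None = None

    def __post_init__(self):
        if (self.truncated_protein_length_aa is not None
                and self.category not in {FRAMESHIFT, NONSENSE}):
            raise ValueError("truncation length only applies to frameshift/nonsense")


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive sequence access for dicts and fetch-style objects."""
    if hasattr(genome, "fetch"):
        return str(genome.fetch(chrom, start, end)).upper()
    seq = genome[chrom]
    return str(seq[start - 1 : end]).upper()


# ---------------------------------------------------------------------------
# Filtering and spectrum classification
# ---------------------------------------------------------------------------

def filter_candidates(
    sites: list[VariantSite],
    region,
    panel: set[tuple[str, int, str, str]],
    hom_af: float = 0.9,
    min_depth: int = 10,
    pool: str = MUT_POOL,
) -> list[VariantSite]:
    """Homozygous-and-novel filter inside a candidate region.

    Keeps sites within the region whose mutant-pool non-reference allele
    frequency is at least ``hom_af`` at depth >= ``min_depth`` and whose
    (chrom, pos, ref, alt) key is absent from the known-variants panel.
    """
    if not 0.5 < hom_af <= 1:
        raise ValueError("hom_af must lie in (0.5, 1]")
    if not any(s.chrom == region.chrom for s in sites):
        warnings.warn(f"no sites on region chromosome {region.chrom}")
        return []
    kept = []
    for s in sites:
        if s.chrom != region.chrom or not region.start_bp <= s.pos <= region.end_bp:
            continue
        counts = s.counts.get(pool)
        if counts is None:
            continue
        depth = counts[0] + counts[1]
        if depth < min_depth or counts[1] / depth < hom_af:
            continue
        if s.key in panel:
            continue
        kept.append(s)
    kept.sort(key=lambda s: s.pos)
    return kept


def classify_substitution(ref: str, alt: str) -> str:
    """EMS-spectrum category of an allele pair.

    SNVs: {G>A, C>T} are the canonical EMS GC_to_AT_transition class; {A>G,
    T>C} are AT_to_GC transitions; the remaining eight ordered pairs are
    transversions.  Length changes map to single_base_deletion /
    single_base_insertion / other_indel.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if not (set(ref) <= _DNA and set(alt) <= _DNA):
        raise ValueError(f"non-ACGT alleles: {ref!r}/{alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        if (ref, alt) in {("G", "A"), ("C", "T")}:
            return "GC_to_AT_transition"
        if (ref, alt) in {("A", "G"), ("T", "C")}:
            return "AT_to_GC_transition"
        return "transversion"
    if len(ref) - len(alt) == 1:
        return "single_base_deletion"
    if len(alt) - len(ref) == 1:
        return "single_base_insertion"
    return "other_indel"


# ---------------------------------------------------------------------------
# Functional annotation
# ---------------------------------------------------------------------------

def _translate_until_stop(cds: str) -> int:
    """Number of amino acids emitted before the first stop codon."""
    usable = len(cds) // 3 * 3
    protein = Seq(cds[:usable]).translate(to_stop=True)
    return len(protein)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _affected_gene(models: list[GeneModel], chrom: str, positions: list[int]):
    for m in models:
        if m.chrom == chrom and any(m.contains(p) for p in positions):
            return m
    return None


def _annotate_snv(v: VariantSite, model: GeneModel, genome) -> VariantEffect:
    idx = model.cds_index(v.pos)
    if idx is None:
        return VariantEffect(INTRONIC, gene_id=model.gene_id)
    cds = model.spliced_cds(genome)
    alt_base = v.alt if model.strand == "+" else _revcomp(v.alt)
    mutated = cds[:idx] + alt_base + cds[idx + 1 :]
    codon_i = idx // 3
    ref_aa = str(Seq(cds[3 * codon_i : 3 * codon_i + 3]).translate())
    alt_aa = str(Seq(mutated[3 * codon_i : 3 * codon_i + 3]).translate())
    change = f"p.{ref_aa}{codon_i + 1}{alt_aa}"
    if alt_aa == ref_aa:
        return VariantEffect(SYNONYMOUS, model.gene_id, change)
    if alt_aa == "*":
        return VariantEffect(NONSENSE, model.gene_id, change,
                             truncated_protein_length_aa=codon_i)
    return VariantEffect(MISSENSE, model.gene_id, change)


def _annotate_indel(v: VariantSite, model: GeneModel, genome) -> VariantEffect:
    """VCF-style anchored indel: first base of ref/alt is shared context."""
    if len(v.ref) > 1 and len(v.alt) == 1:       # deletion of ref[1:]
        changed = list(range(v.pos + 1, v.pos + len(v.ref)))
        inserted = ""
    elif len(v.ref) == 1 and len(v.alt) > 1:     # insertion of alt[1:]
        changed = []
        inserted = v.alt[1:]
    else:
        return VariantEffect(OTHER, model.gene_id,
                             diagnostic="unsupported multi-base substitution")

    net = len(v.alt) - len(v.ref)
    cds = model.spliced_cds(genome)
    if changed:  # deletion
        indices = [model.cds_index(p) for p in changed]
        in_cds = [i for i in indices if i is not None]
        if not in_cds:
            return VariantEffect(INTRONIC, gene_id=model.gene_id)
        if len(in_cds) != len(indices):
            return VariantEffect(
                OTHER, model.gene_id,
                diagnostic="deletion overlaps a CDS/intron boundary",
            )
        in_cds = sorted(in_cds)
        if in_cds[-1] - in_cds[0] != len(in_cds) - 1:
            return VariantEffect(
                OTHER, model.gene_id,
                diagnostic="deletion spans non-contiguous CDS positions",
            )
        mutated = cds[: in_cds[0]] + cds[in_cds[-1] + 1 :]
        first_codon = in_cds[0] // 3 + 1
    else:  # insertion between pos and pos+1
        idx = model.cds_index(v.pos)
        nxt = model.cds_index(v.pos + 1)
        if idx is None and nxt is None:
            return VariantEffect(INTRONIC, gene_id=model.gene_id)
        if idx is None or nxt is None:
            return VariantEffect(
                OTHER, model.gene_id,
                diagnostic="insertion at a CDS/intron boundary",
            )
        if model.strand == "+":
            at = idx + 1
            ins = inserted
        else:
            at = nxt + 1
            ins = _revcomp(inserted)
        mutated = cds[:at] + ins + cds[at:]
        first_codon = min(idx, nxt) // 3 + 1

    if net % 3 != 0:
        return VariantEffect(
            FRAMESHIFT,
            model.gene_id,
            protein_change=f"p.{first_codon}fs",
            truncated_protein_length_aa=_translate_until_stop(mutated),
        )
    return VariantEffect(OTHER, model.gene_id,
                         diagnostic="in-frame indel (no frameshift)")


def annotate_variant(
    v: VariantSite,
    models: list[GeneModel],
    genome,
) -> VariantEffect:
    """Functional impact of one variant against single-transcript gene models.

    ``genome`` may be a mapping name -> sequence or any object exposing
    ``fetch(chrom, start, end)`` with 1-based inclusive coordinates.
    """
    span = list(range(v.pos, v.pos + max(len(v.ref), 1)))
    model = _affected_gene(models, v.chrom, span)
    if model is None:
        return VariantEffect(INTERGENIC)
    if len(v.ref) == 1 and len(v.alt) == 1:
        return _annotate_snv(v, model, genome)
    return _annotate_indel(v, model, genome)


# ---------------------------------------------------------------------------
# CAPS marker feasibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CAPSReport:
    cuts_wt: int
    cuts_mut: int

    @property
    def distinguishable(self) -> bool:
        return self.cuts_wt != self.cuts_mut


def _count_occurrences(seq: str, pattern: str) -> int:
    n, i = 0, seq.find(pattern)
    while i != -1:
        n += 1
        i = seq.find(pattern, i + 1)
    return n


def caps_feasibility(
    wt_amplicon: str, mut_amplicon: str, recognition_site: str
) -> CAPSReport:
    """Does a restriction site digest the two amplicons differently?

    Counts exact occurrences of the recognition site on both strands of each
    amplicon; alleles are distinguishable on a gel iff the cut counts differ.
    """
    site = recognition_site.upper()
    if not site:
        raise ValueError("empty recognition site")
    for name, seq in (("wt", wt_amplicon), ("mut", mut_amplicon), ("site", site)):
        if not set(seq.upper()) <= _DNA:
            raise ValueError(f"non-ACGT characters in {name} sequence")

    def cuts(amplicon: str) -> int:
        amplicon = amplicon.upper()
        total = _count_occurrences(amplicon, site)
        rc = _revcomp(site)
        if rc != site:
            total += _count_occurrences(amplicon, rc)
        return total

    return CAPSReport(cuts_wt=cuts(wt_amplicon), cuts_mut=cuts(mut_amplicon))
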