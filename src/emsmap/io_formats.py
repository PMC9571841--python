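"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (two samples MUT and WT carrying AD/DP) is the canonical interchange
for pooled allele counts; a TSV mirror is kept for human inspection.  Gene
models travel as GFF3, sequences as FASTA, summary tables as TSV with
'#'-prefixed provenance headers.  All writers are deterministic: identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import MARKER, MUT_POOL, WT_POOL, VariantSite, natural_key
from .variants import GeneModel

log = logging.getLogger(__name__)

_SAMPLES = (MUT_POOL, WT_POOL)
_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "origin",
                "mut_ref", "mut_alt", "wt_ref", "wt_alt"]


@dataclass
class CountTable:
    """Ordered variant-site rows plus provenance metadata.

    ``metadata`` may carry ``contigs`` (name -> length) and free-form
    provenance strings (command line, seed, config hash).
    """

    sites: list[VariantSite]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sites = sorted(self.sites, key=lambda s: (natural_key(s.chrom), s.pos))
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos, ref, alt) rows")

    @property
    def contigs(self) -> dict[str, int]:
        contigs = self.metadata.get("contigs")
        if contigs:
            return dict(contigs)
        out: dict[str, int] = {}
        for s in self.sites:
            out[s.chrom] = max(out.get(s.chrom, 0), s.pos + len(s.ref))
        return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf_counts(table: CountTable, path: str | Path) -> None:
    """Write pooled counts as VCF 4.2 with MUT and WT samples (AD, DP)."""
    header = pysam.VariantHeader()
    for name, length in sorted(table.contigs.items(), key=lambda kv: natural_key(kv[0])):
        header.contigs.add(name, length=length)
    header.info.add("ORIGIN", 1, "String", "Site origin: MARKER or INDUCED")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for key, value in table.metadata.items():
        if key == "contigs":
            continue
        header.add_line(f"##emsmap_{key}={value}")
    for sample in _SAMPLES:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in table.sites:
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt)
            )
            rec.info["ORIGIN"] = s.origin
            for sample in _SAMPLES:
                counts = s.counts.get(sample)
                if counts is not None:
                    rec.samples[sample]["AD"] = counts
                    rec.samples[sample]["DP"] = counts[0] + counts[1]
            vcf.write(rec)


def read_vcf_counts(path: str | Path) -> CountTable:
    """Parse a VCF with MUT/WT samples carrying AD into a CountTable.

    Multi-allelic records are skipped with a logged warning.  A VCF whose
    FORMAT declares no AD field, or a record omitting AD from its FORMAT, is
    an error naming the offending sample and line; a present-but-missing AD
    value ('.,.') yields a retained row with missing counts.
    """
    with pysam.VariantFile(str(path)) as vcf:
        if "AD" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF FORMAT declares no AD field")
        samples = list(vcf.header.samples)
        for sample in _SAMPLES:
            if sample not in samples:
                raise ValueError(f"{path}: missing required sample {sample}")
        contigs = {
            name: c.length
            for name, c in vcf.header.contigs.items()
            if c.length is not None
        }
        metadata: dict = {"contigs": contigs} if contigs else {}
        for rec_line in str(vcf.header).splitlines():
            if rec_line.startswith("##emsmap_"):
                key, _, value = rec_line[len("##emsmap_"):].partition("=")
                metadata[key] = value
        sites = []
        for line_no, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                log.warning("skipping multi-allelic record %s:%s", rec.chrom, rec.pos)
                continue
            counts: dict[str, tuple[int, int] | None] = {}
            for sample in _SAMPLES:
                fmt = rec.samples[sample]
                if "AD" not in fmt:
                    raise ValueError(
                        f"{path}: record {line_no} sample {sample} lacks AD"
                    )
                ad = fmt["AD"]
                if ad is None or any(v is None for v in ad):
                    counts[sample] = None
                else:
                    counts[sample] = (int(ad[0]), int(ad[1]))
            try:
                origin = rec.info.get("ORIGIN", MARKER)
            except ValueError:  # ORIGIN absent from this VCF's header
                origin = MARKER
            sites.append(
                VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                            origin=str(origin), counts=counts)
            )
    return CountTable(sites=sites, metadata=metadata)


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t", newline="" if "w" in mode else None)
    return open(path, mode, newline="" if "w" in mode else None)


def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    """Human-readable mirror of the VCF counts ('.' marks missing)."""
    with _open_text(path, "w") as fh:
        for key, value in table.metadata.items():
            if key == "contigs":
                for name, length in sorted(value.items(),
                                           key=lambda kv: natural_key(kv[0])):
                    fh.write(f"#contig={name}:{length}\n")
            else:
                fh.write(f"#{key}={value}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for s in table.sites:
            mut = s.counts.get(MUT_POOL)
            wt = s.counts.get(WT_POOL)
            row = [s.chrom, str(s.pos), s.ref, s.alt, s.origin,
                   "." if mut is None else str(mut[0]),
                   "." if mut is None else str(mut[1]),
                   "." if wt is None else str(wt[0]),
                   "." if wt is None else str(wt[1])]
            fh.write("\t".join(row) + "\n")


def read_counts_tsv(path: str | Path) -> CountTable:
    metadata: dict = {}
    contigs: dict[str, int] = {}
    with _open_text(path, "r") as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("#contig="):
            name, _, length = line[len("#contig="):].partition(":")
            contigs[name] = int(length)
        elif line.startswith("#"):
            key, _, value = line[1:].partition("=")
            metadata[key] = value
        else:
            body.append(line)
    if contigs:
        metadata["contigs"] = contigs
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t", dtype=str,
                     na_values=".", keep_default_na=False)
    sites = []
    for row in df.itertuples(index=False):
        counts: dict[str, tuple[int, int] | None] = {}
        for sample, rc, ac in ((MUT_POOL, row.mut_ref, row.mut_alt),
                               (WT_POOL, row.wt_ref, row.wt_alt)):
            if pd.isna(rc) or pd.isna(ac):
                counts[sample] = None
            else:
                counts[sample] = (int(rc), int(ac))
        sites.append(VariantSite(row.chrom, int(row.pos), row.ref, row.alt,
                                 origin=row.origin, counts=counts))
    return CountTable(sites=sites, metadata=metadata)


def write_tsv(df: pd.DataFrame, path: str | Path,
              provenance: dict | None = None) -> None:
    """Generic deterministic TSV writer with '#'-prefixed provenance lines."""
    with _open_text(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".",
                  float_format="%.6f", lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=".",
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Name -> upper-case sequence mapping; empty file yields an empty dict."""
    with _open_text(path, "r") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_gff3_models(path: str | Path) -> list[GeneModel]:
    """Assemble single-transcript gene models from GFF3 CDS features.

    CDS features are grouped by their Parent chain (CDS -> mRNA -> gene, or
    CDS directly under gene).  A CDS without a resolvable parent is an error.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    models = []
    genes = {g.id: g for g in db.features_of_type("gene")}

    def owning_gene(feature):
        current = feature
        while True:
            parents = current.attributes.get("Parent")
            if not parents:
                return current.id if current.featuretype == "gene" else None
            parent_id = parents[0]
            if parent_id in genes:
                return parent_id
            try:
                current = db[parent_id]
            except gffutils.FeatureNotFoundError:
                return None

    cds_by_gene: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        gene_id = owning_gene(cds)
        if gene_id is None:
            raise ValueError(f"CDS at {cds.seqid}:{cds.start} has no gene parent")
        cds_by_gene.setdefault(gene_id, []).append(cds)
    for gene_id, segments in cds_by_gene.items():
        gene = genes[gene_id]
        models.append(GeneModel(
            gene_id=gene_id,
            chrom=gene.seqid,
            strand=gene.strand,
            cds=[(c.start, c.end) for c in segments],
            gene_start=gene.start,
            gene_end=gene.end,
        ))
    models.sort(key=lambda m: (natural_key(m.chrom), m.gene_start))
    return models


def write_gff3_models(models: list[GeneModel], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write("\t".join([
                m.chrom, "emsmap", "gene", str(m.gene_start), str(m.gene_end),
                ".", m.strand, ".", f"ID={m.gene_id}",
            ]) + "\n")
            mrna_id = f"{m.gene_id}.1"
            fh.write("\t".join([
                m.chrom, "emsmap", "mRNA", str(m.gene_start), str(m.gene_end),
                ".", m.strand, ".", f"ID={mrna_id};Parent={m.gene_id}",
            ]) + "\n")
            phase = 0
            segments = m.cds if m.strand == "+" else list(reversed(m.cds))
            for i, (s, e) in enumerate(segments):
                fh.write("\t".join([
                    m.chrom, "emsmap", "CDS", str(s), str(e), ".", m.strand,
                    str(phase), f"ID={mrna_id}.cds{i};Parent={mrna_id}",
                ]) + "\n")
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
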