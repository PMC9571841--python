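# Methods

## The experimental design being modelled

A recessive mutation induced by EMS in a cultivated, reference-like
background is mapped by crossing the mutant to a genetically distant wild
relative and selfing the F1. In the F2, every chromosome is a mosaic of
cultivated (C) and wild (W) haplotypes. DNA from phenotypically mutant and
wild-type F2 plants is pooled (15 + 15 by default) and sequenced. At a
biallelic site the *non-reference allele-frequency ratio* of a pool is
non-reference reads / total reads. Interspecific markers carry the wild
allele as their non-reference allele, so:

- **Mutant pool** at the causal locus: all plants are C/C → wild-allele
  frequency q = 0 (plus sequencing error). Linkage decays with distance at
  the recombination rate.
- **WT pool** at the causal locus: the phenotypically wild-type class is
  2 C/W : 1 W/W, so q = (2·1 + 1·2)/6 = **2/3**. (Note: a 1/3 figure
  sometimes quoted for this design is the *cultivated*-allele frequency;
  the non-reference/wild frequency is 2/3, and the detection band below is
  set accordingly.)
- Both pools ≈ 1/2 at unlinked loci.

Induced lesions ride exclusively on cultivated haplotypes (they arose in
the mutagenized cultivar), so near the causal locus the mutant pool is
homozygous for them — the basis of the homozygous filter.

## Simulator

**Recombination.** Haldane model, no interference: per gamete and
chromosome, crossover count ~ Poisson(length_cM/100), positions uniform in
bp, starting parent fair. Recombinant fraction between loci d Morgans apart
is r = (1 − e^(−2d))/2, which the tests verify directly at 5, 10 and 20 cM.

**Default scale.** Two 50-Mb chromosomes of 60 cM (1.2 cM/Mb, a typical
euchromatic rate), markers every 100 kb, causal lesion at chr2:42 Mb
(telomere-proximal, echoing the motivating case), F2 population of 150
(comfortably supplies 15 + 15 pools under the 3:1 segregation), 300
background EMS mutations with spectrum 0.90 G:C→A:T transitions / 0.05
other substitutions / 0.05 single-base deletions. These are desk-scale
choices: large enough that window statistics and linkage decay behave like
a real genome scan, small enough that a full replicate runs in well under a
second.

**Pooled counts.** Per site and pool: depth ~ Poisson(λ = 50); observed
non-reference reads ~ Binomial(depth, q(1−ε) + (1−q)ε) with ε = 0.002. An
empty pool yields missing counts, never a crash. Identical seeds give
bit-identical tables; each pipeline stage receives a child seed derived
from the master seed via `numpy.random.SeedSequence`.

**Synthetic reference.** Chromosome-scale FASTA is never materialized. A
sparse "patched" genome holds real sequence only around gene models — the
only places annotation ever fetches sequence. The causal gene is a two-exon
model with a 450-codon spliced CDS (ATG start, single terminal stop,
stop-free internally) whose second exon contains the causal single-base
deletion, anchored VCF-style (ref `XY`, alt `X`). The `simulate` CLI
exports this gene as a small FASTA/GFF3 cassette in local coordinates with
the absolute placement recorded alongside. Background mutations falling
inside a patch take their reference base from it; elsewhere alleles are
generator-assigned (annotation never reads sequence there).

**What the simulator does not model:** read-level artefacts (mapping bias,
duplicates, indel realignment), segregation distortion, variable marker
density, reference errors, polyploidy, incomplete penetrance. Passing tests
therefore demonstrate the *statistical logic* of the pipeline, not
robustness to alignment pathology.

## Mapping

**Profiles.** Non-reference AF per marker site (induced sites are excluded
from linkage profiles — they are not informative markers), summarized in
1-Mb windows stepped every 250 kb; windows need ≥ 3 usable sites at depth
≥ 10 or their summaries are missing. Mean and median are both reported;
detection uses the mean.

**Detection.** A window is a *hit* when the mutant-pool mean ≤ τ_mut = 0.05
and the WT-pool mean lies in (0.30, 0.85) — a band containing both the
unlinked value 1/2 and the at-locus value 2/3, while vetoing windows where
*both* pools collapse (a shared artefact, not linkage). Maximal runs of
≥ 3 consecutive hits become candidate regions, padded by 2 Mb per side
(yielding ≥ 5-Mb reported intervals), ranked by run length, then lower
mutant mean, then position. Missing windows never count as hits and break
runs — conservative localization. With these defaults τ_mut admits windows
out to roughly r + ε ≈ 0.05, i.e. ~4 Mb from the lesion at 1.2 cM/Mb, so
the true locus sits well inside the reported interval.

**Calibration.** Under phenotype-blind pools the per-site q is ~Binomial
(30, 1/2)/30 (σ ≈ 0.09), so a window mean ≤ 0.05 is a ≥ 5σ event; requiring
three consecutive hit windows makes false regions vanishingly rare, which
the null-calibration test (100 replicates) confirms empirically.

## Variant triage

Inside a region, candidates must have mutant-pool AF ≥ 0.9 at depth ≥ 10
(homozygous; the thresholds are ours — "homozygous state" is qualitative in
the field) and be absent from a user-supplied known-variants panel. In the
simulation the panel is the interspecific marker set; in real use it is
whatever resequencing panels exist for the species. Spectrum classification
is total over the 12 ordered SNV pairs ({G→A, C→T} = the canonical EMS
class; {A→G, T→C} = the other transition; 8 transversions) plus indel
classes.

Annotation is deliberately minimal — the effect categories this triage
needs, not a general-purpose annotator: single-transcript gene models,
1-based inclusive coordinates, VCF-style anchored indels. SNVs are
translated codon-wise (strand-aware); coding indels with length change not
divisible by 3 are frameshifts whose truncated protein length is the number
of amino acids before the first stop when translating the mutated spliced
CDS (if no stop appears within the CDS the full mutated length is
reported). Variants overlapping a CDS/intron boundary return category
`other` with a diagnostic rather than a guess; in-frame indels likewise.
Multi-isoform genes are out of scope.

The CAPS helper counts exact restriction-site occurrences on both strands
of the WT and mutant amplicons (palindromic sites counted once per locus);
alleles are gel-distinguishable iff the counts differ.

## Genetics statistics

- **Chi-square goodness of fit**: Pearson Σ(o−e)²/e, no Yates correction
  (the published family statistics 0.4 and 0.85 match the uncorrected
  statistic exactly), p from the upper tail of χ²(k−1) — the regularized
  upper incomplete gamma function Q(df/2, x/2).
- **Inheritance classification** at α = 0.05 (the conventional level): a
  mutant-phenotype M1 whose M2 fits 3:1 mutant-major is dominant; otherwise
  a 3:1 WT-major fit is recessive; failing both is complex.
- **Rates** are plain percentages rounded to 2 decimals; the fertility
  denominator is configurable (germinated plants by default, treated seeds
  optionally) because pilot and campaign reports differ in convention.
- **LD50** by linear interpolation of pooled per-dose rates at the 50%
  crossing — matching how a pilot experiment actually picks its working
  dose (the tested dose nearest the crossing) — rather than probit/logit
  fitting, which would be future work. Non-monotone pooled rates use the
  first crossing with a warning. The dose-response generator draws
  germinated ~ Binomial(seeds, g(dose)) and fertile ~ Binomial(germinated,
  f(dose)) with logistic declines; midpoint recovery within ±0.05 over 200
  simulated pilots is part of the acceptance checks.

## Numerical and interface choices

- Coordinates 1-based inclusive throughout (VCF/GFF3 convention);
  chromosome names natural-sorted (chr2 < chr11).
- All writers deterministic (fixed column order, `.` missing markers, LF
  endings); gzip transparent for TSV.
- VCF I/O via pysam, GFF3 via gffutils (in-memory DB), FASTA and
  translation via Biopython. Test oracles (codon table, window averaging,
  full-sequence mutate-and-translate) are hand-coded and independent of
  those libraries.
- One master seed per run; stage seeds derived deterministically; the truth
  file records the seed.

## Known limitations

Single causal locus, full penetrance, biallelic sites only; pool-level
simulation only for the recessive mode (dominant/complex modes are
simulated at the family-count level); no read-level simulation; annotation
assumes clean single-transcript models. The detection defaults are tuned to
the default simulation scale — a genome with much lower marker density or
depth would need wider windows or a relaxed `min_sites` via the config.
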