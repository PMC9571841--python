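"""Published summary counts from the tomato EMS mutagenesis campaign that
motivated this package.

These are *inputs* (printed count tables), not results: every percentage,
chi-square statistic or LD50 derived from them in tests, examples and the
acceptance script is recomputed by the package at run time.
"""

from __future__ import annotations

from .genetics_stats import SegregationObservation

#: Large-scale campaign counts: EMS-treated seeds, M1 plants obtained
#: (germinated), M1 plants that produced M2 progenies, M2 families screened,
#: mutant lines detected.  Keys match ``compute_rates``.
SCREENING_COUNTS = {
    "treated_seeds": 16_104,
    "germinated": 12_560,
    "m2_producing": 7_379,
    "families_screened": 7_379,
    "mutants_found": 2_800,
}

#: Phenotypic classes of the screened mutant collection with per-class counts
#: by inheritance mode (dominant, recessive, complex).
PHENOTYPIC_CLASS_COUNTS = {
    "I": ("Seedling lethality and albinism", 0, 243, 10),
    "II": ("Root development", 5, 177, 13),
    "III": ("Plant size, architecture, and branching", 74, 1038, 84),
    "IV": ("Leaf morphology and color", 45, 21, 9),
    "V": ("Shoot apical and leaf senescence", 15, 17, 3),
    "VI": ("Flowering time", 0, 2, 2),
    "VII": ("Inflorescence architecture", 11, 139, 33),
    "VIII": ("Flower morphology and color", 17, 182, 21),
    "IX": ("Flower abscission zone", 2, 3, 0),
    "X": ("Fruit setting", 20, 35, 12),
    "XI": ("Fruit morphology/color", 14, 197, 18),
    "XII": ("Parthenocarpy (seedless fruits)", 0, 218, 21),
    "XIII": ("Fruit ripening", 11, 55, 12),
    "XIV": ("Cuticle/cracked fruit", 8, 10, 3),
}


def phenotypic_class_lines() -> list[tuple[str, str]]:
    """Expand the per-class counts into one (class, mode) pair per mutant line."""
    lines = []
    for cls, (_name, dom, rec, cpx) in PHENOTYPIC_CLASS_COUNTS.items():
        lines.extend([(cls, "dominant")] * dom)
        lines.extend([(cls, "recessive")] * rec)
        lines.extend([(cls, "complex")] * cpx)
    return lines


#: M2 phenotype segregation of the mapped recessive mutant family.
SIN_M2_SEGREGATION = SegregationObservation(
    labels=["WT", "mutant"], observed=[87, 33], hypothesized_ratio=[3, 1]
)

#: Genotype-class co-segregation at the causal variant in the same family:
#: homozygous WT allele, heterozygous, homozygous mutant allele.
SIN_COSEGREGATION = SegregationObservation(
    labels=["hom_WT", "het", "hom_mut"],
    observed=[26, 61, 33],
    hypothesized_ratio=[1, 2, 1],
)

#: Dose-response pilot: percent of treated seeds by EMS dose (% v/v).
#: Fertility here means plants producing viable M2 seed, out of treated seeds.
DOSE_RESPONSE_RATES = {
    "doses_pct": [0.5, 0.7, 1.0],
    "germination_pct": [91.95, 78.5, None],   # not reported at 1.0%
    "fertility_pct": [79.2, 48.8, 20.7],
}
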