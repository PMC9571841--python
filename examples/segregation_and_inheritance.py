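"""Segregation chi-square tests and inheritance-mode classification.

An M2 family of 120 plants segregating 87 wild-type : 33 mutant is tested
against the 3:1 expectation of a monogenic recessive; the genotype classes
at the candidate variant (26 hom-WT : 61 het : 33 hom-mutant) are tested
against 1:2:1.  Small chi-square statistics (large p) mean the Mendelian
model is not rejected.
"""

from emsmap.datasets import SIN_COSEGREGATION, SIN_M2_SEGREGATION
from emsmap.genetics_stats import (
    SegregationObservation,
    chi_square_gof,
    classify_inheritance,
)

m2 = chi_square_gof(SIN_M2_SEGREGATION)
print(f"M2 phenotypes 87:33 vs 3:1   -> chi2 = {m2.statistic:.2f}, "
      f"df = {m2.df}, p = {m2.p_value:.2f}")

coseg = chi_square_gof(SIN_COSEGREGATION)
print(f"genotypes 26:61:33 vs 1:2:1  -> chi2 = {coseg.statistic:.2f}, "
      f"df = {coseg.df}, p = {coseg.p_value:.2f}")

mode = classify_inheritance(m1_phenotype_mutant=False, m2_obs=SIN_M2_SEGREGATION)
print(f"inheritance mode: {mode}")

skewed = SegregationObservation(["WT", "mutant"], [50, 50], [3, 1])
print(f"a 50:50 family classifies as: "
      f"{classify_inheritance(False, skewed)} "
      f"(chi2 = {chi_square_gof(skewed).statistic:.1f}, 3:1 rejected)")
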