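"""Campaign rates and the phenotypic-class summary table.

From the raw counts of a large mutagenesis screen (treated seeds, M1 plants,
fertile M1, families screened, mutant lines found) the headline percentages
are recomputed, and the per-line phenotypic classifications are re-tabulated
into the fourteen-class summary with inheritance-mode counts.
"""

from emsmap.datasets import SCREENING_COUNTS, phenotypic_class_lines
from emsmap.genetics_stats import compute_rates, tabulate_classes

rates = compute_rates(**SCREENING_COUNTS)
print(f"germination: {rates['germination_pct']}%   "
      f"fertile M1: {rates['fertility_pct']}%   "
      f"sterile M1: {rates['sterility_pct']}%   "
      f"mutant detection: {rates['detection_pct']}%")

table = tabulate_classes(phenotypic_class_lines())
print(table.to_string(index=False))
# frequency_pct is each class's share of all mutant lines; the TOTAL row
# carries the campaign-wide dominant/recessive/complex breakdown.
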