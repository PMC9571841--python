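"""Classical genetics statistics for a mutagenesis program.

Chi-square goodness-of-fit tests of Mendelian segregation ratios (3:1 for a
monogenic recessive in an M2 family, 1:2:1 for genotype-class co-segregation
at a candidate variant), inheritance-mode classification, phenotypic-class
tabulation of a screening campaign, germination/fertility/detection rates,
and LD50 interpolation from dose-response tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DOMINANT = "dominant"
RECESSIVE = "recessive"
COMPLEX = "complex"

#: Roman-numeral ordering used for phenotypic-class tables.
ROMAN_ORDER = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
               "XI", "XII", "XIII", "XIV"]


@dataclass
class SegregationObservation:
    """Observed phenotype (or genotype-class) counts and a hypothesized ratio."""

    labels: list[str]
    observed: list[int]
    hypothesized_ratio: list[float]

    def __post_init__(self):
        if not (len(self.labels) == len(self.observed) == len(self.hypothesized_ratio)):
            raise ValueError("labels, observed and ratio must have equal length")
        if len(self.labels) < 2:
            raise ValueError("need at least two classes")
        if any(o < 0 for o in self.observed):
            raise ValueError("observed counts must be non-negative")
        if sum(self.observed) < 1:
            raise ValueError("need at least one observation")
        if any(r < 0 for r in self.hypothesized_ratio) or sum(self.hypothesized_ratio) <= 0:
            raise ValueError("ratio must be non-negative with positive sum")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_gof(obs: SegregationObservation) -> ChiSquareResult:
    """Pearson chi-square goodness of fit, no continuity correction.

    Expected counts are total * ratio_i / sum(ratio); the p-value is the
    upper tail of the chi-square distribution with k-1 degrees of freedom.
    """
    observed = np.asarray(obs.observed, dtype=float)
    ratio = np.asarray(obs.hypothesized_ratio, dtype=float)
    expected = observed.sum() * ratio / ratio.sum()
    if np.any(expected <= 0):
        raise ValueError("every class must have positive expected count")
    statistic, p = stats.chisquare(observed, f_exp=expected)
    return ChiSquareResult(statistic=float(statistic), df=len(observed) - 1,
                           p_value=float(p))


def classify_inheritance(
    m1_phenotype_mutant: bool,
    m2_obs: SegregationObservation,
    alpha: float = 0.05,
) -> str:
    """Dominant / recessive / complex call from an M2 (WT, mutant) segregation.

    A mutant-phenotype M1 plant whose M2 fits 3:1 mutant:WT is dominant;
    otherwise an M2 fitting 3:1 WT:mutant is recessive; failing both fits is
    complex inheritance.
    """
    labels = [l.lower() for l in m2_obs.labels]
    try:
        wt = m2_obs.observed[labels.index("wt")]
        mut_count = m2_obs.observed[[l.startswith("mut") for l in labels].index(True)]
    except (ValueError, IndexError):
        raise ValueError("m2_obs must carry classes labelled 'WT' and 'mutant'")
    if m1_phenotype_mutant:
        dominant_fit = chi_square_gof(
            SegregationObservation(["mutant", "WT"], [mut_count, wt], [3, 1])
        )
        if dominant_fit.p_value >= alpha:
            return DOMINANT
    recessive_fit = chi_square_gof(
        SegregationObservation(["WT", "mutant"], [wt, mut_count], [3, 1])
    )
    if recessive_fit.p_value >= alpha:
        return RECESSIVE
    return COMPLEX


def tabulate_classes(lines: list[tuple[str, str]]) -> pd.DataFrame:
    """Screening summary: per phenotypic class, counts by inheritance mode.

    ``lines`` holds one (phenotypic_class, inheritance_mode) pair per mutant
    line.  Output has dominant/recessive/complex counts, a row total, and the
    class frequency as a percentage of the grand total (2 decimals), plus a
    TOTAL row.  Empty input yields a TOTAL row of zeros with missing
    frequency.
    """
    modes = [DOMINANT, RECESSIVE, COMPLEX]
    counts: dict[str, dict[str, int]] = {}
    for cls, mode in lines:
        mode = mode.lower()
        if mode not in modes:
            raise ValueError(f"unknown inheritance mode {mode!r}")
        counts.setdefault(cls, dict.fromkeys(modes, 0))[mode] += 1

    def class_key(name: str):
        return (ROMAN_ORDER.index(name), name) if name in ROMAN_ORDER else (99, name)

    rows = []
    grand_total = sum(sum(v.values()) for v in counts.values())
    for cls in sorted(counts, key=class_key):
        row = counts[cls]
        total = sum(row.values())
        freq = round(total / grand_total * 100, 2) if grand_total else np.nan
        rows.append((cls, row[DOMINANT], row[RECESSIVE], row[COMPLEX], total, freq))
    rows.append((
        "TOTAL",
        sum(r[1] for r in rows),
        sum(r[2] for r in rows),
        sum(r[3] for r in rows),
        grand_total,
        100.0 if grand_total else np.nan,
    ))
    return pd.DataFrame(
        rows,
        columns=["phenotypic_class", "dominant", "recessive", "complex",
                 "total", "frequency_pct"],
    )


def compute_rates(
    treated_seeds: int,
    germinated: int,
    m2_producing: int,
    families_screened: int,
    mutants_found: int,
    fertility_denominator: str = "germinated",
) -> dict[str, float]:
    """Headline percentages of a mutagenesis campaign, rounded to 2 decimals.

    germination = germinated/treated; fertility = m2_producing over either
    the germinated plants (default) or the treated seeds; sterility is the
    germinated complement of fertility; detection = mutants/families.
    """
    if fertility_denominator not in {"germinated", "treated"}:
        raise ValueError("fertility_denominator must be 'germinated' or 'treated'")
    pairs = {
        "germination": (germinated, treated_seeds),
        "m2_producing": (m2_producing, germinated),
        "detection": (mutants_found, families_screened),
    }
    for name, (num, den) in pairs.items():
        if den <= 0:
            raise ValueError(f"zero denominator for {name}")
        if num > den:
            raise ValueError(f"{name}: numerator {num} exceeds denominator {den}")
    fert_den = germinated if fertility_denominator == "germinated" else treated_seeds
    return {
        "germination_pct": round(germinated / treated_seeds * 100, 2),
        "fertility_pct": round(m2_producing / fert_den * 100, 2),
        "sterility_pct": round((fert_den - m2_producing) / fert_den * 100, 2),
        "detection_pct": round(mutants_found / families_screened * 100, 2),
    }


def interpolate_ld50(doses: list[float], rates_pct: list[float]) -> float:
    """Dose at which a pooled rate crosses 50%, by linear interpolation.

    Doses are sorted ascending; the first adjacent pair bracketing 50% is
    interpolated.  A dose hitting 50% exactly is returned as-is.  If the
    pooled rates are not monotone the first crossing is used with a warning.
    """
    order = np.argsort(doses)
    d = np.asarray(doses, dtype=float)[order]
    r = np.asarray(rates_pct, dtype=float)[order]
    if len(d) < 2 or len(np.unique(d)) < 2:
        raise ValueError("need at least two distinct doses")
    if np.all(r > 50) or np.all(r < 50):
        raise ValueError("rates never cross 50%")
    if np.any(np.diff(r) > 0):
        warnings.warn("pooled rates are not monotone; using the first 50% crossing")
    for i in range(len(d)):
        if r[i] == 50:
            return float(d[i])
        if i + 1 < len(d) and (r[i] - 50) * (r[i + 1] - 50) < 0:
            frac = (r[i] - 50) / (r[i] - r[i + 1])
            return float(d[i] + (d[i + 1] - d[i]) * frac)
    raise ValueError("no bracketing dose pair found")  # pragma: no cover


def estimate_ld50(
    table: pd.DataFrame,
    endpoint: str = "fertility",
    denominator: str = "seeds",
) -> float:
    """LD50 from a dose-response table of (dose, seeds, germinated, fertile).

    Replicates are pooled per dose into a single rate before interpolation.
    ``endpoint`` picks the numerator column ('germination' -> germinated,
    'fertility' -> fertile); ``denominator`` is 'seeds' (treated seeds, the
    default: a plant that never germinated counts as a loss) or 'germinated'.
    """
    col = {"germination": "germinated", "fertility": "fertile"}.get(endpoint)
    if col is None:
        raise ValueError("endpoint must be 'germination' or 'fertility'")
    if denominator not in {"seeds", "germinated"}:
        raise ValueError("denominator must be 'seeds' or 'germinated'")
    pooled = table.groupby("dose", sort=True).agg(
        num=(col, "sum"), den=(denominator, "sum")
    )
    rates = pooled["num"] / pooled["den"] * 100
    return interpolate_ld50(list(pooled.index), list(rates))
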