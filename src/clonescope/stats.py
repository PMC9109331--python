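"""Per-donor clonal statistics and two-sample group comparisons.

Summaries per donor: qualified-cell count, mutant-cell percentage, detected
mutation count, non-WT clone count and Shannon clonal diversity (natural log
by default).  Group comparisons use the two tests the analyses call for —
the Mann–Whitney U test (exact enumeration at small tie-free samples,
tie-corrected normal approximation otherwise) and the two-sided Student's
t test (Welch by default).  MDS donors can additionally be stratified by
bone-marrow blast percentage into a low (1–9%) and a high (>9%) group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clones import Clone
from .errors import EmptyStratumError, UndefinedStatisticError, ValidationError
from .genotype import GenotypeMatrix, mutant_cell_fraction, mutation_count

STRATUM_LOW = "low"
STRATUM_HIGH = "high"
STRATUM_NA = "NA"

#: exact Mann-Whitney enumeration is used up to this combined sample size
#: (when the pooled values are tie-free)
_MW_EXACT_MAX_N = 25


def shannon_diversity(clone_sizes, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over clone proportions.

    ``base=None`` gives nats (natural log).  The WT clone must already be
    excluded; an empty list (a donor with no mutant clones) is undefined,
    not zero.
    """
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size == 0:
        raise UndefinedStatisticError("Shannon diversity is undefined for zero clones")
    if (sizes <= 0).any():
        raise ValidationError("clone sizes must be positive")
    p = sizes / sizes.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    # clamp the -0.0 that a single clone produces
    return abs(h) if h == 0 else h


def populations_involved(clone: Clone) -> int:
    """Number of populations (out of all 7, including H) the clone occurs in."""
    return len(clone.populations)


def clone_size_table(clone_df: pd.DataFrame) -> pd.DataFrame:
    """Absolute size and within-donor fraction per clone.

    Fractions are relative to the donor's clone-assigned (mutant, non-WT,
    non-NA) cells and sum to 1 within each donor; comparisons default to the
    fraction because donors contribute unequal cell numbers.
    """
    out = clone_df[["clone_id", "donor_id", "clone_class", "double_mutant", "origin"]].copy()
    out["size"] = clone_df["size"]
    totals = clone_df.groupby("donor_id")["size"].transform("sum")
    out["size_fraction"] = clone_df["size"] / totals
    return out


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # "mann_whitney_u" | "students_t"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # "exact" | "asymptotic" | "welch" | "pooled" | "degenerate"
    sidedness: str = "two-sided"

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": [self.n_a, self.n_b],
            "method": self.method,
            "sidedness": self.sidedness,
        }


def compare_groups(values_a, values_b, test: str = "mann_whitney_u", equal_var: bool = False) -> ComparisonResult:
    """Two-sided two-sample comparison.

    ``mann_whitney_u``: exact enumeration when the pooled sample is tie-free
    and small, else the tie-corrected normal approximation.  ``students_t``:
    Welch's unequal-variance t by default (``equal_var=True`` for the pooled
    classical form).  Two identical constant samples carry no evidence of a
    difference and return p = 1 with method "degenerate".
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(test, float("nan"), 1.0, a.size, b.size, "degenerate")
    if test == "mann_whitney_u":
        has_ties = np.unique(pooled).size < pooled.size
        exact = (not has_ties) and (a.size + b.size <= _MW_EXACT_MAX_N)
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
        return ComparisonResult(
            test, float(res.statistic), float(min(res.pvalue, 1.0)), a.size, b.size,
            "exact" if exact else "asymptotic",
        )
    if test == "students_t":
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return ComparisonResult(
            test, float(res.statistic), float(res.pvalue), a.size, b.size,
            "pooled" if equal_var else "welch",
        )
    raise ValidationError(f"unknown test {test!r}; expected mann_whitney_u or students_t")


def blast_stratum(blast_pct: float | None) -> str:
    """Map a blast percentage to its stratum: 1–9% low, >9% high, else NA."""
    if blast_pct is None or (isinstance(blast_pct, float) and math.isnan(blast_pct)):
        return STRATUM_NA
    if 1.0 <= blast_pct <= 9.0:
        return STRATUM_LOW
    if blast_pct > 9.0:
        return STRATUM_HIGH
    return STRATUM_NA


def donor_summary_table(
    gm: GenotypeMatrix,
    clone_df: pd.DataFrame,
    exclusions: pd.DataFrame,
    blast_pct: dict[str, float] | None = None,
    shannon_base: float | None = None,
) -> pd.DataFrame:
    """One summary row per donor with at least one qualified cell.

    Shannon diversity is NaN (absent) for a donor without mutant clones.
    """
    blast_pct = blast_pct or {}
    groups = gm.cells.groupby("donor_id")["group"].first()
    rows = []
    for donor_id in gm.donor_ids:
        n_q = len(gm.qualified_index(donor_id))
        if n_q == 0:
            continue
        donor_clones = clone_df[clone_df["donor_id"] == donor_id]
        sizes = donor_clones["size"].to_numpy()
        try:
            h = shannon_diversity(sizes, base=shannon_base) if sizes.size else float("nan")
        except UndefinedStatisticError:
            h = float("nan")
        b = blast_pct.get(donor_id, float("nan"))
        rows.append(
            {
                "donor_id": donor_id,
                "group": groups[donor_id],
                "n_qualified_cells": n_q,
                "mutant_cell_pct": mutant_cell_fraction(gm, donor_id),
                "n_mutations": mutation_count(gm, donor_id),
                "n_clones": len(donor_clones),
                "shannon_diversity": h,
                "excluded_wt": int(exclusions.loc[donor_id, "excluded_wt"]),
                "excluded_na": int(exclusions.loc[donor_id, "excluded_na"]),
                "blast_pct": b,
                "blast_stratum": blast_stratum(b),
            }
        )
    return pd.DataFrame(rows)


def compare_donor_groups(summaries: pd.DataFrame) -> dict[str, ComparisonResult]:
    """The HD-vs-MDS panel of donor-level comparisons.

    Mann–Whitney for mutant-cell percentage, clone number and Shannon
    diversity; two-sided Student's t for the mutation count.
    """
    hd = summaries[summaries["group"] == "HD"]
    mds = summaries[summaries["group"] == "MDS"]
    if len(hd) == 0 or len(mds) == 0:
        raise ValidationError("both HD and MDS groups are required for group comparisons")
    out = {
        "mutant_cell_pct": compare_groups(hd["mutant_cell_pct"], mds["mutant_cell_pct"]),
        "n_mutations": compare_groups(hd["n_mutations"], mds["n_mutations"], test="students_t"),
        "n_clones": compare_groups(hd["n_clones"], mds["n_clones"]),
    }
    hd_h = hd["shannon_diversity"].dropna()
    mds_h = mds["shannon_diversity"].dropna()
    if len(hd_h) and len(mds_h):
        out["shannon_diversity"] = compare_groups(hd_h, mds_h)
    return out


def blast_stratified_comparison(
    summaries: pd.DataFrame, clone_df: pd.DataFrame
) -> dict[str, ComparisonResult]:
    """Compare clone size (fraction) and populations involved between the
    low-blast (1–9%) and high-blast (>9%) MDS strata, per clone."""
    strata = summaries.set_index("donor_id")["blast_stratum"]
    for name in (STRATUM_LOW, STRATUM_HIGH):
        if not (strata == name).any():
            raise EmptyStratumError(f"no donors in the {name!r} blast stratum")
    sized = clone_size_table(clone_df)
    sized["stratum"] = sized["donor_id"].map(strata)
    pops = clone_df.set_index("clone_id")["n_populations"]
    low = sized[sized["stratum"] == STRATUM_LOW]
    high = sized[sized["stratum"] == STRATUM_HIGH]
    if len(low) == 0 or len(high) == 0:
        which = STRATUM_LOW if len(low) == 0 else STRATUM_HIGH
        raise EmptyStratumError(f"no clones in the {which!r} blast stratum")
    return {
        "clone_size": compare_groups(low["size_fraction"], high["size_fraction"]),
        "populations_involved": compare_groups(
            pops[low["clone_id"]], pops[high["clone_id"]]
        ),
    }
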