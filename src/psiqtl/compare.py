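"""Statistical contrasts between exon groups.

Compares structural/sequence features of exon sets (constitutive vs
variable, high- vs low-inclusion, genetically controlled vs not,
trait-colocalizing vs not) with two-sided Mann-Whitney U tests for
numeric features and Fisher exact tests for binary ones, plus a
Spearman correlation of structural-change magnitude against gene
constraint.  Raw p-values are reported per comparison; a
Benjamini-Hochberg column is added across a report purely as a
convenience for readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compare_feature",
    "compare_binary",
    "correlate_constraint",
    "run_comparisons",
    "ComparisonSpec",
]

GROUP_LABELS = (
    "constitutive",
    "variable",
    "high-PSI",
    "low-PSI",
    "sExon",
    "non-sExon",
    "colocalizing",
    "non-colocalizing",
)

NUMERIC_FEATURES = ("rsa_q1", "plddt_q3", "pct_asn", "pct_cys", "aa_length")
BINARY_FEATURES = ("has_domain_signal", "transmembrane", "symmetric")

#: Median-PSI threshold splitting high- from low-inclusion exons.
HIGH_PSI_THRESHOLD = 0.5


@dataclass(frozen=True)
class ComparisonSpec:
    """One cell of the comparison grid: two groups and one feature."""

    group_a: str
    group_b: str
    feature: str


def compare_feature(
    values_a: Sequence[float],
    values_b: Sequence[float],
    min_n: int = 10,
) -> dict:
    """Two-sided Mann-Whitney U contrast of a numeric feature.

    Missing values are dropped pairwise.  Reports the U statistic, the
    tie-corrected two-sided p, both group medians and which group sits
    higher.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < min_n or b.size < min_n:
        raise ValueError(f"groups too small ({a.size}, {b.size}); need {min_n} each")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": med_a,
        "median_b": med_b,
        "higher_median": "a" if med_a > med_b else ("b" if med_b > med_a else "tie"),
    }


def compare_binary(
    flags_a: Sequence[bool],
    flags_b: Sequence[bool],
) -> dict:
    """Fisher exact contrast of a binary feature between two groups."""
    a = pd.Series(flags_a).dropna().astype(bool)
    b = pd.Series(flags_b).dropna().astype(bool)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    table = np.array(
        [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
    )
    orr, p = stats.fisher_exact(table, alternative="two-sided")
    corrected = False
    if (table == 0).any():
        t = table + 0.5
        orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        corrected = True
    return {
        "odds_ratio": float(orr),
        "p": float(p),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "table": table,
        "haldane_corrected": corrected,
    }


def correlate_constraint(
    structural_change: Sequence[float],
    loeuf: Sequence[float],
    min_n: int = 10,
) -> dict:
    """Spearman correlation of structural change against gene constraint.

    A positive rho means larger isoform rearrangements in less
    constrained (higher-LOEUF) genes.  Constant inputs leave the
    correlation undefined (NaN, flagged).
    """
    x = np.asarray(structural_change, dtype=float)
    y = np.asarray(loeuf, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": np.nan, "p": np.nan, "n": int(x.size), "degenerate": True}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": int(x.size), "degenerate": False}


def run_comparisons(
    summaries: pd.DataFrame,
    specs: Sequence[ComparisonSpec],
    group_col: str = "group",
    min_n: int = 10,
) -> pd.DataFrame:
    """Evaluate a grid of group contrasts over a feature table.

    ``summaries`` holds one exon per row with a group label column and
    feature columns.  Numeric features go through
    :func:`compare_feature`, binary ones through
    :func:`compare_binary`.  A Benjamini-Hochberg ``p_bh`` column is
    appended across all evaluated cells.
    """
    rows = []
    for spec in specs:
        sub_a = summaries[summaries[group_col] == spec.group_a][spec.feature]
        sub_b = summaries[summaries[group_col] == spec.group_b][spec.feature]
        try:
            if spec.feature in BINARY_FEATURES or summaries[spec.feature].dtype == bool:
                res = compare_binary(sub_a, sub_b)
                stat = res["odds_ratio"]
                extra = {"odds_ratio": res["odds_ratio"]}
            else:
                res = compare_feature(sub_a, sub_b, min_n=min_n)
                stat = res["statistic"]
                extra = {
                    "median_a": res["median_a"],
                    "median_b": res["median_b"],
                    "higher_median": res["higher_median"],
                }
        except ValueError:
            continue
        rows.append(
            {
                "group_a": spec.group_a,
                "group_b": spec.group_b,
                "feature": spec.feature,
                "n_a": res["n_a"],
                "n_b": res["n_b"],
                "statistic": stat,
                "p": res["p"],
                **extra,
            }
        )
    report = pd.DataFrame(rows)
    if not report.empty:
        report["p_bh"] = multipletests(report["p"], method="fdr_bh")[1]
    return report
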