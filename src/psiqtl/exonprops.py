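"""Properties of splicing-QTL target exons.

Characterizes the exons whose inclusion is under genetic control:
reading-frame symmetry (length divisible by 3, so skipping preserves
frame), position within the transcript, variant location relative to
the target gene, and derived-allele effect directions with their
allele-frequency contrasts.  A derived allele that triggers skipping of
an exon removes coding sequence from the dominant transcript, so an
excess of skipping-direction derived alleles — and lower frequencies of
those alleles — is the signature of purifying selection on exon loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "exon_symmetry",
    "relative_position",
    "classify_variant_location",
    "direction_and_daf_tests",
    "daf_cutoff_sweep",
    "chi2_uniformity",
    "symmetry_enrichment",
    "DirectionSummary",
]


def exon_symmetry(length_bp: int) -> bool:
    """True iff the exon length in bp is divisible by 3.

    Symmetric exons encode whole codons, so their skipping leaves the
    downstream reading frame intact.
    """
    if length_bp <= 0:
        raise ValueError(f"exon length must be positive, got {length_bp}")
    return length_bp % 3 == 0


def relative_position(ordinal: int, n_exons: int) -> float:
    """Fractional transcript position of an exon, ordinal / n_exons.

    ``ordinal`` counts 5'->3' (strand-aware, 1-based), so the last exon
    of any gene maps to 1.0 regardless of strand.
    """
    if n_exons < 1 or not (1 <= ordinal <= n_exons):
        raise ValueError(f"invalid ordinal {ordinal} of {n_exons}")
    return ordinal / n_exons


def classify_variant_location(
    chrom: str,
    pos: int,
    gene_exons: pd.DataFrame,
) -> str:
    """Classify a variant as exonic / intronic / flanking for its gene.

    ``gene_exons`` is the annotation subset for one gene (1-based
    inclusive start/end).  Flanking covers anything outside the gene
    span (the cis window guarantees it is near the gene).
    """
    chroms = gene_exons["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("gene exons must be on a single chromosome")
    if chrom != chroms[0]:
        raise ValueError(f"variant on {chrom} but gene on {chroms[0]}")
    starts = gene_exons["start"].to_numpy()
    ends = gene_exons["end"].to_numpy()
    if ((starts <= pos) & (pos <= ends)).any():
        return "exonic"
    if gene_exons["start"].min() <= pos <= gene_exons["end"].max():
        return "intronic"
    return "flanking"


@dataclass
class DirectionSummary:
    """Derived-allele effect directions and frequency contrasts."""

    n_increase: int
    n_decrease: int
    binomial_p: float
    daf_increase: np.ndarray
    daf_decrease: np.ndarray
    ks_D: float
    ks_p: float
    mw_p: float
    delta_psi_cutoff: float


def direction_and_daf_tests(
    records: pd.DataFrame,
    delta_psi_cutoff: float = 0.035,
    min_records: int = 10,
) -> DirectionSummary:
    """Test whether derived alleles preferentially trigger skipping.

    ``records`` is a collapsed QTL table with columns
    ``derived_direction`` ({increases, decreases, unknown}),
    ``delta_psi`` and ``daf``.  Records with |delta PSI| above the
    cutoff and a known direction are counted; the direction split is
    tested with an exact two-sided binomial test against 0.5, and the
    derived-allele frequencies of the two direction groups are
    contrasted with a two-sample KS statistic and a Mann-Whitney test.
    """
    known = records[
        (records["derived_direction"].isin(["increases", "decreases"]))
        & (records["delta_psi"].abs() > delta_psi_cutoff)
    ]
    if len(known) < min_records:
        raise ValueError(
            f"only {len(known)} usable records above cutoff; need {min_records}"
        )
    inc = known[known["derived_direction"] == "increases"]
    dec = known[known["derived_direction"] == "decreases"]
    n_inc, n_dec = len(inc), len(dec)
    binom_p = stats.binomtest(n_inc, n_inc + n_dec, 0.5, alternative="two-sided").pvalue
    daf_inc = inc["daf"].to_numpy(float)
    daf_dec = dec["daf"].to_numpy(float)
    if n_inc and n_dec:
        ks = stats.ks_2samp(daf_inc, daf_dec)
        mw = stats.mannwhitneyu(daf_inc, daf_dec, alternative="two-sided")
        ks_D, ks_p, mw_p = float(ks.statistic), float(ks.pvalue), float(mw.pvalue)
    else:
        ks_D = ks_p = mw_p = np.nan
    return DirectionSummary(
        n_increase=n_inc,
        n_decrease=n_dec,
        binomial_p=float(binom_p),
        daf_increase=daf_inc,
        daf_decrease=daf_dec,
        ks_D=ks_D,
        ks_p=ks_p,
        mw_p=mw_p,
        delta_psi_cutoff=delta_psi_cutoff,
    )


def daf_cutoff_sweep(
    records: pd.DataFrame,
    cutoffs: Sequence[float] = (0.0, 0.035, 0.05, 0.1, 0.15, 0.2),
    min_records: int = 10,
) -> pd.DataFrame:
    """KS D between direction-split DAF distributions per effect cutoff.

    Larger-effect splicing QTLs are expected to show a larger frequency
    separation between skipping and inclusion derived alleles; the
    sweep makes that trend visible.
    """
    rows = []
    for cut in cutoffs:
        try:
            s = direction_and_daf_tests(records, delta_psi_cutoff=cut, min_records=min_records)
        except ValueError:
            continue
        rows.append(
            {
                "delta_psi_cutoff": cut,
                "ks_D": s.ks_D,
                "ks_p": s.ks_p,
                "n_increase": s.n_increase,
                "n_decrease": s.n_decrease,
            }
        )
    return pd.DataFrame(rows)


def chi2_uniformity(positions: Sequence[float], n_bins: int = 10) -> tuple[float, float]:
    """Chi-squared test of uniformity of relative positions in (0, 1].

    Bins are equal width; the statistic is 0 when all bins hold equal
    counts.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("no positions given")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(pos, 1e-12, 1.0), bins=edges)
    res = stats.chisquare(counts)
    return float(res.statistic), float(res.pvalue)


def symmetry_enrichment(
    n_symmetric_a: int,
    n_total_a: int,
    n_symmetric_b: int,
    n_total_b: int,
) -> dict:
    """Fisher exact test of symmetry fraction between two exon sets."""
    table = np.array(
        [
            [n_symmetric_a, n_total_a - n_symmetric_a],
            [n_symmetric_b, n_total_b - n_symmetric_b],
        ]
    )
    if (table < 0).any():
        raise ValueError("counts inconsistent")
    orr, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "pct_symmetric_a": 100.0 * n_symmetric_a / n_total_a if n_total_a else np.nan,
        "pct_symmetric_b": 100.0 * n_symmetric_b / n_total_b if n_total_b else np.nan,
        "odds_ratio": float(orr),
        "fisher_p": float(p),
    }
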