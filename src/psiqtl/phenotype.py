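"""Exon percent-spliced-in (PSI) phenotypes.

PSI for an exon is estimated from split reads: reads supporting the two
inclusion junctions (upstream and downstream of the exon) versus reads
that splice over the exon entirely.  With I = (incl_left + incl_right)/2
and E = excl,

    psi = I / (I + E)

and the value is left missing when fewer than ``min_informative`` reads
(I + E) support it.  Averaging the two flanking junctions treats them
symmetrically and halves the variance of the inclusion estimate.

For QTL mapping the filtered PSI matrix is rank inverse-normal
transformed per exon, with ties broken by a seeded random permutation so
that heavily tied exons (e.g. PSI pinned at 1) still yield a
full-rank-spread phenotype.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import JunctionCounts, PsiPhenotype


def compute_psi(
    jc: JunctionCounts,
    exons: Optional[pd.DataFrame] = None,
    min_informative: int = 10,
) -> PsiPhenotype:
    """Compute raw PSI per exon x sample from junction counts.

    Parameters
    ----------
    jc
        Junction read counts; negative counts are rejected by the
        container itself.
    exons
        Optional exon annotation table (index exon_id, columns per
        :data:`psiqtl.containers.EXON_TABLE_COLUMNS`) used to fill the
        gene grouping and TSS anchor.  Without it the phenotype carries
        an empty grouping and must be annotated before mapping.
    min_informative
        Minimum supporting reads I + E for a defined value.
    """
    incl = (jc.incl_left.to_numpy(float) + jc.incl_right.to_numpy(float)) / 2.0
    excl = jc.excl.to_numpy(float)
    total = incl + excl
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total >= min_informative, incl / total, np.nan)
    psi_df = pd.DataFrame(psi, index=jc.exons, columns=jc.samples)

    if exons is not None:
        common = jc.exons.intersection(exons.index)
        gene_group = exons.loc[common, "gene_id"]
        tss = (
            exons.loc[common, ["gene_id", "gene_tss"]]
            .drop_duplicates("gene_id")
            .set_index("gene_id")["gene_tss"]
        )
        gene_group = gene_group.reindex(jc.exons)
    else:
        gene_group = pd.Series(index=jc.exons, dtype=object)
        tss = pd.Series(dtype=float)
    return PsiPhenotype(psi=psi_df, gene_group=gene_group, tss_anchor=tss)


def filter_exons(
    pheno: PsiPhenotype,
    min_donor_frac: float = 0.5,
    min_unique: int = 10,
) -> PsiPhenotype:
    """Keep exons measurable and variable enough for QTL mapping.

    An exon is retained iff (a) PSI is defined in at least
    ``min_donor_frac`` of samples and (b) it has at least ``min_unique``
    distinct non-missing values.  Both bounds are inclusive; an exon
    seen in exactly half the donors with exactly ten unique values
    passes.  The number removed by each rule is recorded in
    ``filter_log``.
    """
    psi = pheno.psi
    if psi.shape[0] == 0:
        warnings.warn("filter_exons called on an empty phenotype", stacklevel=2)
        out = pheno.subset([])
        out.filter_log = {"n_input": 0, "removed_low_coverage": 0, "removed_low_unique": 0}
        return out
    n_samples = psi.shape[1]
    frac_defined = psi.notna().sum(axis=1) / n_samples
    n_unique = psi.apply(lambda row: row.dropna().nunique(), axis=1)
    pass_cov = frac_defined >= min_donor_frac
    pass_unique = n_unique >= min_unique
    keep = pass_cov & pass_unique
    out = pheno.subset(psi.index[keep])
    out.filter_log = {
        "n_input": int(psi.shape[0]),
        "removed_low_coverage": int((~pass_cov).sum()),
        "removed_low_unique": int((pass_cov & ~pass_unique).sum()),
        "n_retained": int(keep.sum()),
    }
    return out


def _rank_with_random_ties(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """1-based ranks with ties broken uniformly at random."""
    jitter = rng.random(values.shape[0])
    order = np.lexsort((jitter, values))
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, values.shape[0] + 1)
    return ranks


def inverse_normal_transform(pheno: PsiPhenotype, seed: int) -> PsiPhenotype:
    """Fill ``normalized`` with a per-exon rank inverse-normal transform.

    Per exon, non-missing samples are ranked with random tie-breaking
    (seeded), then mapped through Phi^-1((r - 0.5) / n).  Missing stays
    missing.  Exons with fewer than two non-missing values are rejected.
    """
    rng = np.random.default_rng(seed)
    psi = pheno.psi.to_numpy(float)
    norm = np.full_like(psi, np.nan)
    for i in range(psi.shape[0]):
        mask = ~np.isnan(psi[i])
        n = int(mask.sum())
        if n < 2:
            raise ValueError(
                f"exon {pheno.psi.index[i]} has {n} non-missing values; "
                "filter before transforming"
            )
        ranks = _rank_with_random_ties(psi[i, mask], rng)
        norm[i, mask] = stats.norm.ppf((ranks - 0.5) / n)
    out = PsiPhenotype(
        psi=pheno.psi,
        gene_group=pheno.gene_group,
        tss_anchor=pheno.tss_anchor,
        normalized=pd.DataFrame(norm, index=pheno.psi.index, columns=pheno.psi.columns),
        filter_log=dict(pheno.filter_log),
    )
    return out


def call_constitutive_exons(
    psi_by_tissue: Sequence[PsiPhenotype],
    exons: pd.DataFrame,
    max_nonunit_donors: int = 10,
    min_tissues: int = 9,
    seed: int = 0,
) -> pd.Index:
    """Identify one constitutive exon per gene across tissues.

    An exon is constitutive in a tissue when its PSI equals 1 in all but
    at most ``max_nonunit_donors`` donors with data.  Tissue support is
    the number of tissues where that holds; exons with support below
    ``min_tissues`` are dropped, as are terminal exons.  Within a gene
    the exon with the highest support wins; ties are broken by a seeded
    random draw so the result is reproducible but unbiased.
    """
    if len(psi_by_tissue) < min_tissues:
        raise ValueError(
            f"need at least {min_tissues} tissues, got {len(psi_by_tissue)}"
        )
    support: dict[str, int] = {}
    for pheno in psi_by_tissue:
        psi = pheno.psi
        non_unit = ((psi < 1.0) & psi.notna()).sum(axis=1)
        has_data = psi.notna().any(axis=1)
        flags = has_data & (non_unit <= max_nonunit_donors)
        for exon_id in psi.index[flags]:
            support[exon_id] = support.get(exon_id, 0) + 1

    kept = [e for e, s in support.items() if s >= min_tissues]
    kept = [e for e in kept if e in exons.index and not exons.loc[e, "is_terminal"]]
    if not kept:
        return pd.Index([], dtype=object)

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "gene_id": exons.loc[kept, "gene_id"],
            "support": [support[e] for e in kept],
        },
        index=pd.Index(kept, name="exon_id"),
    )
    chosen = []
    for _, grp in table.sort_index().groupby("gene_id"):
        best = grp[grp["support"] == grp["support"].max()]
        if len(best) == 1:
            chosen.append(best.index[0])
        else:
            chosen.append(best.index[rng.integers(len(best))])
    return pd.Index(sorted(chosen), dtype=object)
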