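"""cis splicing-QTL mapping on PSI phenotypes.

The scan regresses the inverse-normal transformed PSI of each exon on
variant dosage with covariates, for all variants within a window of the
gene's transcription start site.  Covariates are projected out of both
phenotype and dosage first (Frisch-Waugh-Lovell), so the reported slope
and t-test match the full joint regression with residual degrees of
freedom n - k - 2 (k covariates).

Gene-level significance uses grouped permutations: sample labels of all
exons of a gene are permuted jointly, preserving the inter-exon splicing
correlation within the gene, and the minimum nominal p over all
exon x variant pairs is recorded per permutation.  A Beta(a, b)
distribution fitted to the permutation minima by maximum likelihood
yields a smooth gene-level adjusted p-value; the rank-based empirical
permutation p is returned alongside as a cross-check.

Effect sizes (delta PSI) are deliberately computed on the raw PSI scale
as the difference of genotype-class medians, so they are interpretable
as an inclusion-fraction change per two alternate alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, PsiPhenotype

__all__ = [
    "nominal_scan",
    "permutation_adjust",
    "delta_psi",
    "collapse_and_label",
    "replication_pi1",
    "map_tissue",
    "DeltaPsi",
    "Pi1Result",
]


def _design_q(cov: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the covariate design (with intercept)."""
    n = cov.shape[0]
    design = np.column_stack([np.ones(n), cov])
    q, _ = np.linalg.qr(design)
    return q


def _residualize(rows: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Project covariates out of each row (features x samples)."""
    return rows - (rows @ q) @ q.T


def _p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p of the regression t-test from the partial correlation."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def nominal_scan(
    pheno: PsiPhenotype,
    geno: GenotypeMatrix,
    cov: pd.DataFrame,
    cis_window: int = 1_000_000,
    maf_min: float = 0.05,
    gene_chrom: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Exon x variant association scan within the cis window.

    Returns a table with one row per tested pair: exon_id, gene_id,
    variant_id, n, af, maf, slope, se, nominal_p.  Pairs with zero
    genotype variance after residualization are skipped (counted in the
    table attribute ``skipped_pairs``).
    """
    if pheno.normalized is None:
        raise ValueError("phenotype must be inverse-normal transformed first")
    samples = pheno.samples
    if not geno.samples.equals(samples) or not cov.index.equals(samples):
        raise ValueError("samples of phenotype, genotypes and covariates must align")

    norm = pheno.normalized.to_numpy(float)
    dos = geno.dosages.to_numpy(float)
    cov_arr = cov.to_numpy(float)
    k = cov_arr.shape[1]
    af = geno.alt_freq()
    maf = np.minimum(af, 1.0 - af)
    pos = geno.variants["pos"].to_numpy()
    vchrom = geno.variants["chrom"].to_numpy()

    rows = []
    skipped = 0
    exon_index = pheno.exons
    for gene, tss in pheno.tss_anchor.items():
        gene_exons = exon_index[pheno.gene_group.loc[exon_index] == gene]
        if len(gene_exons) == 0:
            continue
        in_window = np.abs(pos - tss) <= cis_window
        if gene_chrom is not None and gene in gene_chrom.index:
            in_window &= vchrom == gene_chrom.loc[gene]
        in_window &= maf.to_numpy() >= maf_min
        vidx = np.nonzero(in_window)[0]
        if vidx.size == 0:
            continue
        variant_ids = geno.variants.index[vidx]

        for exon in gene_exons:
            ei = exon_index.get_loc(exon)
            y = norm[ei]
            ymask = ~np.isnan(y)
            G = dos[vidx]
            gmask = ~np.isnan(G)
            # fast path: one shared complete-case mask for the block
            shared = ymask & gmask.all(axis=0)
            blocks: list[tuple[np.ndarray, np.ndarray]] = []
            if gmask[:, ymask].all():
                blocks.append((np.arange(vidx.size), ymask))
            else:
                complete = gmask[:, ymask].all(axis=1)
                if complete.any():
                    blocks.append((np.nonzero(complete)[0], ymask))
                for j in np.nonzero(~complete)[0]:
                    blocks.append((np.array([j]), ymask & gmask[j]))
            for rel, mask in blocks:
                n = int(mask.sum())
                df = n - k - 2
                if df < 1:
                    skipped += len(rel)
                    continue
                q = _design_q(cov_arr[mask])
                y_r = _residualize(y[mask][None, :], q)[0]
                G_r = _residualize(G[np.ix_(rel, mask)], q)
                xx = (G_r * G_r).sum(axis=1)
                ok = xx > 1e-12
                skipped += int((~ok).sum())
                if not ok.any():
                    continue
                G_r = G_r[ok]
                xx = xx[ok]
                yy = float(y_r @ y_r)
                xy = G_r @ y_r
                slope = xy / xx
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = xy / np.sqrt(xx * yy) if yy > 0 else np.zeros_like(xy)
                    sigma2 = np.maximum(yy - xy * xy / xx, 0.0) / df
                    se = np.sqrt(sigma2 / xx)
                pvals = _p_from_r(r, df)
                for v_rel, s, e_, p_ in zip(rel[ok], slope, se, pvals):
                    vid = variant_ids[v_rel]
                    rows.append(
                        (
                            exon,
                            gene,
                            vid,
                            n,
                            float(af.loc[vid]),
                            float(maf.loc[vid]),
                            float(s),
                            float(e_),
                            float(p_),
                        )
                    )
    out = pd.DataFrame(
        rows,
        columns=[
            "exon_id",
            "gene_id",
            "variant_id",
            "n",
            "af",
            "maf",
            "slope",
            "se",
            "nominal_p",
        ],
    )
    out.attrs["skipped_pairs"] = skipped
    return out


def _fit_beta_mle(pvals: np.ndarray) -> tuple[float, float, bool]:
    """Beta(a, b) maximum-likelihood fit with method-of-moments start."""
    pvals = np.clip(pvals, 1e-300, 1.0 - 1e-16)
    m, v = pvals.mean(), pvals.var()
    if v <= 0:
        return np.nan, np.nan, False
    common = m * (1 - m) / v - 1.0
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(pvals, a0, b0, floc=0, fscale=1)
    except Exception:
        return np.nan, np.nan, False
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        return np.nan, np.nan, False
    return float(a), float(b), True


def permutation_adjust(
    assoc: pd.DataFrame,
    pheno: PsiPhenotype,
    geno: GenotypeMatrix,
    cov: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level adjusted p-values by grouped permutation.

    ``assoc`` is the output of :func:`nominal_scan`; its exon x variant
    universe defines what is permuted.  One sample-label permutation is
    applied jointly to all exons of a gene, and the minimum nominal p
    over the gene's pairs is recorded per permutation.  Permutations are
    evaluated on the samples complete for every exon and variant of the
    gene, which keeps the joint permutation well defined under
    missingness.

    Returns a per-gene table: top exon/variant, observed minimum p,
    beta-adjusted p, empirical permutation p, and the fitted Beta
    parameters (``beta_ok`` False marks an empirical-only fallback).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; adjusted p will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    cov_arr = cov.to_numpy(float)
    k = cov_arr.shape[1]
    out_rows = []
    for gene, gene_assoc in assoc.groupby("gene_id", sort=True):
        exon_ids = pd.Index(sorted(gene_assoc["exon_id"].unique()))
        variant_ids = pd.Index(sorted(gene_assoc["variant_id"].unique()))
        Y = pheno.normalized.loc[exon_ids].to_numpy(float)
        G = geno.dosages.loc[variant_ids].to_numpy(float)
        mask = ~np.isnan(Y).any(axis=0) & ~np.isnan(G).any(axis=0)
        n = int(mask.sum())
        df = n - k - 2
        if df < 1:
            continue
        q = _design_q(cov_arr[mask])
        Y_r = _residualize(Y[:, mask], q)
        G_r = _residualize(G[:, mask], q)
        ynorm = np.linalg.norm(Y_r, axis=1, keepdims=True)
        gnorm = np.linalg.norm(G_r, axis=1, keepdims=True)
        keep_v = gnorm[:, 0] > 1e-9
        if not keep_v.any() or (ynorm[:, 0] <= 1e-12).any():
            continue
        G_u = G_r[keep_v] / gnorm[keep_v]
        Y_u = Y_r / ynorm
        r_obs = Y_u @ G_u.T
        p_obs = _p_from_r(r_obs, df)
        flat = np.argmin(p_obs)
        ei, vi = np.unravel_index(flat, p_obs.shape)
        obs_min_p = float(p_obs[ei, vi])

        perm_idx = rng.permuted(
            np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
        )
        # (exons, n_perm, n) @ (n, variants) in one BLAS call
        Yp = Y_u[:, perm_idx]
        r_perm = np.tensordot(Yp, G_u.T, axes=([2], [0]))
        max_abs_r = np.abs(r_perm).max(axis=(0, 2))
        p_min = _p_from_r(max_abs_r, df)

        a, b, beta_ok = _fit_beta_mle(p_min)
        if beta_ok:
            adjusted = float(stats.beta.cdf(obs_min_p, a, b))
        else:
            adjusted = np.nan
        empirical = float((1 + np.sum(p_min <= obs_min_p)) / (n_perm + 1))
        if not beta_ok:
            adjusted = empirical
        out_rows.append(
            {
                "gene_id": gene,
                "exon_id": exon_ids[ei],
                "variant_id": variant_ids[keep_v][vi],
                "n": n,
                "nominal_p": obs_min_p,
                "slope": float(
                    r_obs[ei, vi] * ynorm[ei, 0] / gnorm[keep_v][vi, 0]
                ),
                "adjusted_p": adjusted,
                "empirical_p": empirical,
                "beta_a": a,
                "beta_b": b,
                "beta_ok": beta_ok,
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(out_rows).set_index("gene_id") if out_rows else pd.DataFrame(
        columns=[
            "exon_id",
            "variant_id",
            "n",
            "nominal_p",
            "slope",
            "adjusted_p",
            "empirical_p",
            "beta_a",
            "beta_b",
            "beta_ok",
            "n_perm",
        ]
    )


@dataclass
class DeltaPsi:
    """Raw-scale splicing effect size."""

    value: float
    extrapolated: bool = False
    defined: bool = True


def delta_psi(psi_values: np.ndarray | pd.Series, dosages: np.ndarray | pd.Series) -> DeltaPsi:
    """Difference of genotype-class PSI medians, ALT/ALT minus REF/REF.

    When one homozygote class is unobserved the difference is
    extrapolated from the heterozygote step (twice the het-vs-observed-
    homozygote median difference, signed toward the missing class) and
    flagged.  With both homozygote classes empty the effect is
    undefined.
    """
    psi_values = np.asarray(psi_values, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(psi_values) & ~np.isnan(dosages)
    psi_values, dosages = psi_values[ok], dosages[ok]

    def med(d: int) -> float:
        vals = psi_values[dosages == d]
        return float(np.median(vals)) if vals.size else np.nan

    m0, m1, m2 = med(0), med(1), med(2)
    if not np.isnan(m0) and not np.isnan(m2):
        return DeltaPsi(m2 - m0)
    if np.isnan(m0) and np.isnan(m2):
        return DeltaPsi(np.nan, defined=False)
    if np.isnan(m1):
        return DeltaPsi(np.nan, defined=False)
    anchor = m0 if not np.isnan(m0) else m2
    step = m1 - anchor
    value = 2.0 * step if not np.isnan(m0) else -2.0 * step
    return DeltaPsi(value, extrapolated=True)


REQUIRED_TISSUE_COLUMNS = [
    "exon_id",
    "variant_id",
    "slope",
    "adjusted_p",
    "delta_psi",
    "ref",
    "alt",
    "af",
]


def collapse_and_label(
    records_by_tissue: Mapping[str, pd.DataFrame],
    exons: pd.DataFrame,
    ancestral: Optional[Mapping[str, str] | pd.Series] = None,
    alpha: float = 0.05,
    null_alpha: float = 0.2,
) -> tuple[pd.DataFrame, pd.Index]:
    """Collapse per-tissue top associations to one record per gene.

    Each tissue table is indexed by gene_id with the columns of
    :data:`REQUIRED_TISSUE_COLUMNS`.  Among tissues where the gene's
    adjusted p is below ``alpha``, the tissue with the largest |delta
    PSI| is kept.  Genes whose winning exon is terminal are dropped
    (restricting the catalogue to internal exon-skipping events).
    Alleles are labeled from the slope sign (alt is the high-inclusion
    allele iff slope > 0) and, when an ancestral-allele map is supplied,
    by derived-allele direction.

    Also returns the comparator set: genes whose best association stayed
    above ``null_alpha`` in every tissue where the gene was tested.
    """
    if ancestral is None:
        ancestral = {}
    if isinstance(ancestral, pd.Series):
        ancestral = ancestral.to_dict()

    frames = []
    for tissue, tab in records_by_tissue.items():
        missing = [c for c in REQUIRED_TISSUE_COLUMNS if c not in tab.columns]
        if missing:
            raise ValueError(f"tissue {tissue} table missing columns {missing}")
        t = tab.copy()
        t["tissue"] = tissue
        t["gene_id"] = t.index
        frames.append(t)
    allrec = pd.concat(frames, ignore_index=True)

    nonqtl = []
    for gene, grp in allrec.groupby("gene_id"):
        if (grp["adjusted_p"] > null_alpha).all():
            nonqtl.append(gene)

    sig = allrec[allrec["adjusted_p"] < alpha].copy()
    sig = sig[np.isfinite(sig["delta_psi"])]
    records = []
    for gene, grp in sig.groupby("gene_id"):
        top = grp.loc[grp["delta_psi"].abs().idxmax()]
        if top["exon_id"] in exons.index and exons.loc[top["exon_id"], "is_terminal"]:
            continue
        slope = float(top["slope"])
        high = top["alt"] if slope > 0 else top["ref"]
        anc = ancestral.get(top["variant_id"])
        if anc == top["ref"]:
            derived = top["alt"]
        elif anc == top["alt"]:
            derived = top["ref"]
        else:
            derived = "unknown"
        if derived == "unknown":
            direction = "unknown"
            daf = np.nan
        else:
            direction = "increases" if derived == high else "decreases"
            daf = float(top["af"]) if derived == top["alt"] else 1.0 - float(top["af"])
        records.append(
            {
                "gene_id": gene,
                "exon_id": top["exon_id"],
                "variant_id": top["variant_id"],
                "tissue": top["tissue"],
                "slope": slope,
                "adjusted_p": float(top["adjusted_p"]),
                "delta_psi": float(top["delta_psi"]),
                "ref": top["ref"],
                "alt": top["alt"],
                "af": float(top["af"]),
                "high_inclusion_allele": high,
                "derived_allele": derived,
                "derived_direction": direction,
                "daf": daf,
            }
        )
    qtl = (
        pd.DataFrame(records).set_index("gene_id")
        if records
        else pd.DataFrame(
            columns=[
                "exon_id",
                "variant_id",
                "tissue",
                "slope",
                "adjusted_p",
                "delta_psi",
                "ref",
                "alt",
                "af",
                "high_inclusion_allele",
                "derived_allele",
                "derived_direction",
                "daf",
            ]
        )
    )
    return qtl, pd.Index(sorted(nonqtl))


@dataclass
class Pi1Result:
    """Storey replication estimate between a discovery and a test set."""

    pi1: float
    pi0: float
    n_pairs: int
    discovery: str = ""
    test: str = ""


def replication_pi1(
    pvalues: Sequence[float] | np.ndarray,
    discovery: str = "",
    test: str = "",
    lambdas: Optional[np.ndarray] = None,
) -> Pi1Result:
    """Estimated fraction of true positives (pi1 = 1 - pi0).

    pi0 is estimated on a lambda grid (0.05..0.95 by 0.05) as
    #{p > lambda} / (m (1 - lambda)), smoothed with a cubic polynomial
    and read off at the largest lambda, then clamped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 50:
        raise ValueError(f"need at least 50 p-values for a stable pi0, got {p.size}")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    pi0 = min(max(pi0, 0.0), 1.0)
    return Pi1Result(pi1=1.0 - pi0, pi0=pi0, n_pairs=int(p.size), discovery=discovery, test=test)


def map_tissue(
    pheno: PsiPhenotype,
    geno: GenotypeMatrix,
    cov: pd.DataFrame,
    exons: pd.DataFrame,
    cis_window: int = 1_000_000,
    maf_min: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full single-tissue pass: scan, grouped permutations, delta PSI.

    Returns (nominal association table, per-gene table).  The per-gene
    table carries everything :func:`collapse_and_label` needs.
    """
    assoc = nominal_scan(pheno, geno, cov, cis_window=cis_window, maf_min=maf_min)
    genes = permutation_adjust(assoc, pheno, geno, cov, n_perm=n_perm, seed=seed)
    if genes.empty:
        return assoc, genes
    dpsi, flags = [], []
    for gene, row in genes.iterrows():
        d = delta_psi(
            pheno.psi.loc[row["exon_id"]].to_numpy(),
            geno.dosages.loc[row["variant_id"]].to_numpy(),
        )
        dpsi.append(d.value)
        flags.append(d.extrapolated)
    genes = genes.copy()
    genes["delta_psi"] = dpsi
    genes["delta_psi_extrapolated"] = flags
    genes["ref"] = geno.variants.loc[genes["variant_id"], "ref"].to_numpy()
    genes["alt"] = geno.variants.loc[genes["variant_id"], "alt"].to_numpy()
    genes["af"] = geno.alt_freq().loc[genes["variant_id"]].to_numpy()
    genes["is_terminal_exon"] = exons.loc[genes["exon_id"], "is_terminal"].to_numpy()
    return assoc, genes
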