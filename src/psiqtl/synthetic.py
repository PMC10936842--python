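"""Synthetic cohorts, summary statistics and structure pairs.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so every stage is testable
at desk scale:

* genotypes under Hardy-Weinberg equilibrium at a tunable allele
  frequency, with local LD from a first-order Gaussian copula on the
  latent allele variables (neighbor correlation ``ld_rho`` per
  haplotype);
* exon PSI following a logit-linear model,
  logit(psi) = alpha + beta * dosage + gamma' covariates + eps, with
  junction counts drawn binomially under a negative-binomial total
  depth (overdispersed like RNA-seq; depth 0 leaves PSI missing);
* paired GWAS / splicing-QTL summary statistics over one LD block with
  a shared or distinct causal variant, computed from individual-level
  draws so betas and standard errors are internally consistent;
* idealized multi-domain CA traces for spliced-in/spliced-out isoform
  pairs, with domain-structured pLDDT and PAE matrices.

All randomness flows from the seed in the configuration (or the
explicit seed argument); identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .containers import (
    GenotypeMatrix,
    IsoformStructurePair,
    JunctionCounts,
    SimTruth,
    StructureModel,
)

__all__ = [
    "SimConfig",
    "sim_cohort",
    "sim_gwas_pair",
    "sim_isoform_structures",
    "sim_ancestral_map",
    "sim_planted_exon",
    "effect_beta_for_delta_psi",
]

GENE_SPACING = 3_000_000
EXON_SPACING = 2_000
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Parameters of the simulated splicing-QTL study.

    Defaults describe a mid-size bulk RNA-seq cohort: 200 donors,
    ~50x junction coverage, common regulatory variants (MAF 0.3) with a
    moderate local LD decay, and a logit-scale allelic effect sized to
    shift PSI by ~0.2 between homozygote classes at a 0.5 baseline.
    """

    n_samples: int = 200
    n_genes: int = 20
    exons_per_gene: int = 4
    n_variants: int = 50
    maf: float = 0.3
    ld_rho: float = 0.5
    effect_beta: float = 0.4236
    baseline_psi: float = 0.5
    depth_mean: float = 50.0
    depth_dispersion: float = 0.3
    noise_sd: float = 0.3
    n_covariates: int = 3
    covariate_effect_sd: float = 0.2
    frac_symmetric: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "maf", "ld_rho", "effect_beta", "baseline_psi",
            "depth_mean", "depth_dispersion", "noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name}")
        if self.n_samples < 10:
            raise ValueError("n_samples < 10: too small to populate genotype classes")
        if not 0.05 <= self.maf <= 0.5:
            raise ValueError("maf must be in [0.05, 0.5] (the common-variant regime)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 < self.baseline_psi < 1.0:
            raise ValueError("baseline_psi must be in (0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.exons_per_gene < 3:
            raise ValueError("need >= 3 exons per gene for a non-terminal causal exon")


def effect_beta_for_delta_psi(delta_psi: float, baseline_psi: float = 0.5) -> float:
    """Logit effect per alt allele giving a target homozygote PSI difference."""
    target = baseline_psi + delta_psi
    if not 0.0 < target < 1.0:
        raise ValueError("baseline + delta outside (0, 1)")
    return float((logit(target) - logit(baseline_psi)) / 2.0)


def _simulate_dosages(
    rng: np.random.Generator, n_samples: int, n_variants: int, maf: float, ld_rho: float
) -> np.ndarray:
    """HWE dosages with AR(1) latent-Gaussian LD. Shape (variants, samples)."""
    thr = norm.ppf(maf)
    z = np.empty((2 * n_samples, n_variants))
    z[:, 0] = rng.standard_normal(2 * n_samples)
    scale = np.sqrt(1.0 - ld_rho**2)
    for j in range(1, n_variants):
        z[:, j] = ld_rho * z[:, j - 1] + scale * rng.standard_normal(2 * n_samples)
    alleles = (z < thr).astype(np.int8)
    dosage = alleles[0::2] + alleles[1::2]  # (samples, variants)
    return dosage.T.astype(float)


def _draw_depth(rng: np.random.Generator, config: SimConfig, size) -> np.ndarray:
    """Negative-binomial total junction depth (var = mu + disp * mu^2)."""
    size_param = 1.0 / config.depth_dispersion
    p = size_param / (size_param + config.depth_mean)
    return rng.negative_binomial(size_param, p, size=size)


def sim_cohort(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, JunctionCounts, pd.DataFrame, SimTruth]:
    """Simulate a full QTL cohort.

    Returns (genotypes, covariates, junction counts, exon annotation
    table, truth).  Each gene carries one causal variant acting on one
    non-terminal exon; the remaining exons are variable but genetically
    unregulated.
    """
    rng = np.random.default_rng(config.seed)
    samples = pd.Index([f"S{i:04d}" for i in range(config.n_samples)], name="sample")
    E, V = config.exons_per_gene, config.n_variants

    exon_rows = []
    var_rows = []
    dosage_blocks = []
    truth_rows = []
    incl_l, incl_r, excl = [], [], []
    exon_ids_all = []
    bases = np.array(list("ACGT"))

    for g in range(config.n_genes):
        gene_id = f"G{g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_left = 500_000 + g * GENE_SPACING
        lengths = []
        for _ in range(E):
            base = int(rng.integers(20, 100)) * 3
            if rng.random() < config.frac_symmetric:
                lengths.append(base)
            else:
                lengths.append(base + int(rng.integers(1, 3)))
        starts = []
        for ordinal in range(1, E + 1):
            slot = ordinal - 1 if strand == "+" else E - ordinal
            starts.append(gene_left + slot * EXON_SPACING)
        ends = [s + L - 1 for s, L in zip(starts, lengths)]
        tss = min(starts) if strand == "+" else max(ends)
        for ordinal in range(1, E + 1):
            exon_rows.append(
                {
                    "exon_id": f"{gene_id}_E{ordinal}",
                    "gene_id": gene_id,
                    "chrom": "chr1",
                    "start": starts[ordinal - 1],
                    "end": ends[ordinal - 1],
                    "strand": strand,
                    "ordinal": ordinal,
                    "n_exons": E,
                    "is_terminal": ordinal in (1, E),
                    "gene_tss": tss,
                    "length_bp": lengths[ordinal - 1],
                }
            )

        # variants in the cis window around the TSS
        pos = np.sort(rng.integers(tss - 500_000, tss + 500_000, size=V))
        dos = _simulate_dosages(rng, config.n_samples, V, config.maf, config.ld_rho)
        causal_idx = V // 2
        for j in range(V):
            ref, alt = rng.choice(bases, size=2, replace=False)
            var_rows.append(
                {
                    "variant_id": f"{gene_id}_V{j:03d}",
                    "chrom": "chr1",
                    "pos": int(pos[j]),
                    "ref": str(ref),
                    "alt": str(alt),
                }
            )
        dosage_blocks.append(dos)

        causal_ordinal = E // 2 + 1  # guaranteed non-terminal for E >= 3
        truth_rows.append(
            {
                "gene_id": gene_id,
                "causal_variant": f"{gene_id}_V{causal_idx:03d}",
                "causal_exon": f"{gene_id}_E{causal_ordinal}",
                "true_beta": config.effect_beta,
                "true_delta_psi": float(
                    expit(logit(config.baseline_psi) + 2 * config.effect_beta)
                    - expit(logit(config.baseline_psi))
                ),
            }
        )

    exons = pd.DataFrame(exon_rows).set_index("exon_id")
    variants = pd.DataFrame(var_rows).set_index("variant_id")
    dosages = pd.DataFrame(np.vstack(dosage_blocks), index=variants.index, columns=samples)
    covariates = pd.DataFrame(
        rng.standard_normal((config.n_samples, config.n_covariates)),
        index=samples,
        columns=[f"cov{i+1}" for i in range(config.n_covariates)],
    )

    # phenotype model and junction counts, gene by gene
    for g in range(config.n_genes):
        gene_id = f"G{g:03d}"
        causal_ordinal = E // 2 + 1
        causal_dos = dosages.loc[f"{gene_id}_V{V // 2:03d}"].to_numpy()
        gamma = rng.normal(0.0, config.covariate_effect_sd, size=(E, config.n_covariates))
        for ordinal in range(1, E + 1):
            exon_id = f"{gene_id}_E{ordinal}"
            if ordinal == causal_ordinal:
                alpha = logit(config.baseline_psi)
                genetic = config.effect_beta * causal_dos
            else:
                alpha = logit(rng.uniform(0.25, 0.9))
                genetic = 0.0
            eta = (
                alpha
                + genetic
                + covariates.to_numpy() @ gamma[ordinal - 1]
                + rng.normal(0.0, config.noise_sd, size=config.n_samples)
            )
            psi = expit(eta)
            depth = _draw_depth(rng, config, config.n_samples)
            incl_l.append(rng.binomial(depth, psi))
            incl_r.append(rng.binomial(depth, psi))
            excl.append(rng.binomial(depth, 1.0 - psi))
            exon_ids_all.append(exon_id)

    exon_index = pd.Index(exon_ids_all, name="exon_id")
    jc = JunctionCounts(
        incl_left=pd.DataFrame(np.array(incl_l), index=exon_index, columns=samples),
        incl_right=pd.DataFrame(np.array(incl_r), index=exon_index, columns=samples),
        excl=pd.DataFrame(np.array(excl), index=exon_index, columns=samples),
    )
    truth = SimTruth(table=pd.DataFrame(truth_rows).set_index("gene_id"))
    geno = GenotypeMatrix(variants=variants, dosages=dosages)
    return geno, covariates, jc, exons, truth


def sim_ancestral_map(
    geno: GenotypeMatrix, seed: int = 0, frac_known: float = 0.9
) -> pd.Series:
    """Assign an ancestral allele (ref or alt, 50/50) to most variants.

    A fraction of variants stays unlabeled, mimicking sites with no
    confident ancestral-state call.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for vid, row in geno.variants.iterrows():
        if rng.random() < frac_known:
            out[vid] = row["ref"] if rng.random() < 0.5 else row["alt"]
    return pd.Series(out, dtype=object)


def _marginal_sumstats(dosage: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple-regression beta and se. dosage: (V, n)."""
    n = y.shape[0]
    gc = dosage - dosage.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=1)
    sxy = gc @ yc
    beta = sxy / sxx
    sse = (yc @ yc) - beta * sxy
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
    return beta, se


def sim_gwas_pair(
    config: SimConfig,
    shared: bool,
    seed: Optional[int] = None,
    n_gwas: int = 5000,
    gwas_effect: float = 0.15,
    qtl_effect: float = 1.0,
    max_causal_r2: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Paired GWAS and splicing-QTL summary statistics over one LD block.

    Both traits are quantitative, simulated at the individual level on
    independent cohorts drawn from the same LD structure, then reduced
    to marginal per-variant (beta, se, n, freq).  With ``shared`` both
    traits are driven by the same causal variant; otherwise by two
    variants whose realized r^2 must stay below ``max_causal_r2``
    (raises when the block is too small or LD too long-range to place
    them).
    """
    if config.n_variants < 50:
        raise ValueError("locus too small: need >= 50 variants")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    V = config.n_variants
    causal_qtl = V // 4
    causal_gwas = causal_qtl if shared else 3 * V // 4

    dos_qtl = _simulate_dosages(rng, config.n_samples, V, config.maf, config.ld_rho)
    dos_gwas = _simulate_dosages(rng, n_gwas, V, config.maf, config.ld_rho)
    if not shared:
        r = np.corrcoef(dos_gwas[causal_qtl], dos_gwas[causal_gwas])[0, 1]
        if r * r >= max_causal_r2:
            raise ValueError(
                f"cannot place two causal variants with r^2 < {max_causal_r2} "
                f"in this block (realized r^2 = {r*r:.3f})"
            )

    y_qtl = qtl_effect * dos_qtl[causal_qtl] + rng.standard_normal(config.n_samples)
    y_gwas = gwas_effect * dos_gwas[causal_gwas] + rng.standard_normal(n_gwas)

    beta_q, se_q = _marginal_sumstats(dos_qtl, y_qtl)
    beta_g, se_g = _marginal_sumstats(dos_gwas, y_gwas)
    vids = pd.Index([f"L_V{j:03d}" for j in range(V)], name="variant_id")
    qtl = pd.DataFrame(
        {
            "beta": beta_q,
            "se": se_q,
            "n": config.n_samples,
            "freq": dos_qtl.mean(axis=1) / 2.0,
        },
        index=vids,
    )
    gwas = pd.DataFrame(
        {
            "beta": beta_g,
            "se": se_g,
            "n": n_gwas,
            "freq": dos_gwas.mean(axis=1) / 2.0,
        },
        index=vids,
    )
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "gene_id": ["locus"],
                "causal_variant": [vids[causal_qtl]],
                "causal_exon": [""],
                "true_beta": [qtl_effect],
                "true_delta_psi": [np.nan],
                "gwas_causal_variant": [vids[causal_gwas]],
            }
        ).set_index("gene_id"),
        shared_gwas_causal=shared,
    )
    return gwas, qtl, truth


def _domain_layout(length: int, domain_size: int, linker_size: int) -> np.ndarray:
    """Domain id per residue; -1 marks linker residues."""
    ids = np.full(length, -1, dtype=int)
    pos, d = 0, 0
    while pos < length:
        end = min(pos + domain_size, length)
        ids[pos:end] = d
        pos = end + linker_size
        d += 1
    return ids


def sim_isoform_structures(
    protein_length: int,
    exon_interval: tuple[int, int],
    seed: int,
    domain_size: int = 40,
    linker_size: int = 10,
    displacement_deg: float = 15.0,
    displacement_shift: float = 2.0,
    noise_sd: float = 0.2,
    pae_shift: float = 3.0,
) -> IsoformStructurePair:
    """Idealized spliced-in / spliced-out CA-trace pair.

    The spliced-in model is a chain of helical domains separated by
    linkers; pLDDT is high inside domains and low in linkers, and PAE
    is low within domains and high between.  The spliced-out model
    deletes the exon residues and applies a rigid rotation
    (``displacement_deg`` about the z axis through the splice hinge)
    plus a translation and Gaussian coordinate noise to everything
    downstream, emulating a domain rearrangement.  Exons touching
    either terminus are rejected (terminal exons are excluded from the
    study design).
    """
    s, e = exon_interval
    if not (1 < s <= e < protein_length):
        raise ValueError("exon interval must be strictly internal")
    rng = np.random.default_rng(seed)
    L = protein_length
    domain_id = _domain_layout(L, domain_size, linker_size)
    n_domains = domain_id.max() + 1

    # helical backbone with per-domain spatial offsets
    i = np.arange(L, dtype=float)
    angle = np.deg2rad(100.0) * i
    base = np.column_stack([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i])
    offsets = np.array([[18.0 * d, 10.0 * (d % 2), 0.0] for d in range(n_domains)])
    res_offset = np.zeros((L, 3))
    for idx in range(L):
        d = domain_id[idx]
        if d >= 0:
            res_offset[idx] = offsets[d]
        else:
            prev = domain_id[:idx][domain_id[:idx] >= 0]
            nxt = domain_id[idx:][domain_id[idx:] >= 0]
            lo = offsets[prev[-1]] if prev.size else offsets[0]
            hi = offsets[nxt[0]] if nxt.size else offsets[-1]
            res_offset[idx] = (lo + hi) / 2.0
    coords = base + res_offset

    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    plddt = np.where(
        domain_id >= 0,
        np.clip(88.0 + rng.normal(0.0, 2.0, L), 0, 100),
        np.clip(45.0 + rng.normal(0.0, 5.0, L), 0, 100),
    )

    same_domain = (domain_id[:, None] == domain_id[None, :]) & (domain_id[:, None] >= 0)
    sep = np.abs(i[:, None] - i[None, :])
    pae_in = np.where(
        same_domain,
        1.5 + 0.05 * sep + np.abs(rng.normal(0.0, 0.2, (L, L))),
        14.0 + rng.normal(0.0, 2.0, (L, L)),
    )
    np.fill_diagonal(pae_in, 0.2)
    pae_in = np.clip(pae_in, 0.2, 31.75)

    keep = np.ones(L, dtype=bool)
    keep[s - 1 : e] = False
    coords_out = coords[keep].copy()
    n_up = s - 1  # retained residues upstream of the exon
    theta = np.deg2rad(displacement_deg)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    pivot = coords_out[n_up - 1] if n_up else np.zeros(3)
    down = coords_out[n_up:]
    down = (down - pivot) @ rot.T + pivot + np.array([displacement_shift, 0.0, 0.0])
    if noise_sd > 0:
        down = down + rng.normal(0.0, noise_sd, down.shape)
    coords_out[n_up:] = down

    pae_out = pae_in[np.ix_(keep, keep)].copy()
    if pae_shift != 0.0:
        cross = np.zeros_like(pae_out, dtype=bool)
        cross[:n_up, n_up:] = True
        cross[n_up:, :n_up] = True
        pae_out[cross] += pae_shift + rng.normal(0.0, 0.5, int(cross.sum()))
        pae_out = np.clip(pae_out, 0.2, 31.75)

    spliced_in = StructureModel(coords=coords, sequence=sequence, plddt=plddt)
    spliced_out = StructureModel(
        coords=coords_out,
        sequence="".join(np.array(list(sequence))[keep]),
        plddt=plddt[keep],
    )
    return IsoformStructurePair(
        spliced_in=spliced_in,
        spliced_out=spliced_out,
        pae_in=pae_in,
        pae_out=pae_out,
        exon_residues=(s, e),
    )


# codon usage for reverse translation (one common codon per amino acid)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTG", "CTT", "CTC", "CTA", "TTA", "TTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


def sim_planted_exon(
    seed: int,
    n_proteins: int = 5,
    protein_length: int = 300,
    exon_aa: int = 30,
) -> dict:
    """Synthetic gene set with one in-frame exon planted in one protein.

    Random protein sequences are generated; a residue interval of the
    target protein is reverse-translated with random synonymous codons
    to form the exon's nucleotide sequence.  Returns the exon sequence,
    the protein dictionary, the target protein id and the true residue
    interval — the ground truth for translated-alignment recovery.
    """
    rng = np.random.default_rng(seed)
    proteins = {
        f"P{k:02d}": "".join(rng.choice(list(AMINO_ACIDS), size=protein_length))
        for k in range(n_proteins)
    }
    target = f"P{rng.integers(n_proteins):02d}"
    start = int(rng.integers(2, protein_length - exon_aa - 1))
    peptide = proteins[target][start - 1 : start - 1 + exon_aa]
    exon_nt = "".join(
        _SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))] for aa in peptide
    )
    return {
        "exon_nt": exon_nt,
        "proteins": proteins,
        "target_protein": target,
        "aa_start": start,
        "aa_end": start + exon_aa - 1,
    }
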