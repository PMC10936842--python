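# Methods

## Phenotype: exon percent spliced in

PSI is estimated per exon and sample from three split-read counts: the
two inclusion junctions flanking the exon and the exclusion junction
that skips it. The two inclusion counts are averaged — they measure the
same inclusion event twice, and averaging treats the flanks
symmetrically while halving the variance of the inclusion estimate —
and ψ = I/(I+E) is left missing when fewer than `min_informative = 10`
reads support it, which stabilizes the estimate at low coverage.
Samples without informative reads are excluded from ranks rather than
imputed.

Two filters precede mapping, both with inclusive boundaries: an exon
must have PSI defined in at least 50% of donors and take at least 10
distinct values (exons pinned at a constant, usually 1, carry no
mappable variation). The retained matrix is rank inverse-normal
transformed per exon: ties are broken by a seeded uniform permutation
of tied ranks, then values map through Φ⁻¹((r − 0.5)/n). The half-rank
offset avoids ±∞ at the extremes; random tie-breaking means heavily
tied exons still produce an exchangeable standard-normal phenotype, at
the cost of a seed-dependent (but reproducible) assignment within tie
groups.

Constitutive exons — used as a comparison group, not mapped — are
exons with PSI equal to 1 in all but at most 10 donors within a tissue,
required in at least 9 of the available tissues, excluding terminal
exons, and reduced to at most one exon per gene (highest tissue
support; seeded random tie-break).

## cis-QTL scan and grouped permutations

The scan regresses normalized PSI on dosage for every variant with
minor-allele frequency ≥ 0.05 within 1 Mb of the gene's TSS (the
window is anchored at the gene, not the exon, so all exons of a gene
see the same variant universe). Covariates are removed by projecting
both phenotype and dosage on the orthonormal covariate basis
(Frisch–Waugh–Lovell); the resulting slope and t-test are identical to
the full joint regression with df = n − k − 2, which the test suite
verifies against statsmodels OLS to 1e-8. Missing dosages are handled
pairwise-complete per variant; pairs with zero genotype variance after
residualization are skipped and counted.

Gene-level multiplicity is controlled by grouped permutations: one
permutation of sample labels is applied jointly to all exons of a gene
— preserving the inter-exon splicing correlation that motivates
grouping — and the minimum nominal p over the gene's exon × variant
pairs is recorded. A Beta(a, b) distribution is fitted to the 1,000
permutation minima by maximum likelihood (method-of-moments start;
scipy's MLE), and the adjusted p is the Beta CDF at the observed
minimum. The rank-based empirical permutation p is returned alongside;
the two agree with Spearman ρ > 0.999 in the calibration runs, and
degenerate Beta fits fall back to the empirical p with a flag.
Permutations are evaluated on the samples jointly complete for the
gene's exons and variants, which keeps the joint permutation well
defined under missingness; the observed minimum is recomputed on the
same set so the adjusted p compares like with like. Under the
generator's null, the fraction of genes with adjusted p < 0.05 is
0.05 ± binomial noise (500-gene runs land in 0.048–0.08 across seeds).

Effect sizes deliberately return to the raw scale:
ΔPSI = median(ψ|ALT/ALT) − median(ψ|REF/REF). When one homozygote
class is unobserved, twice the heterozygote step is used and flagged
as extrapolated; with both missing the effect is undefined. Cross-
tissue collapse keeps, per gene, the significant tissue (adjusted
p < 0.05) with the largest |ΔPSI| — the absolute value resolves the
sign ambiguity of "largest effect" — and drops genes whose winning
exon is terminal, restricting the catalogue to internal skipping
events. The alt allele is the high-inclusion allele iff the slope is
positive; combined with an ancestral-allele map this yields the
derived-allele direction and frequency used by the selection
contrasts. The comparator ("no splicing QTL") set contains genes whose
best association stayed above adjusted p 0.2 in every tested tissue.
Ties in the top-pair choice break by smaller nominal p, then
lexicographic exon id — deterministic by construction.

Replication between tissues uses Storey's π1 = 1 − π0, with π0
estimated on the λ grid 0.05…0.95 (step 0.05) as #{p>λ}/(m(1−λ)),
smoothed by a cubic polynomial evaluated at λ = 0.95 and clamped to
[0, 1]. Fewer than 50 p-values are refused — the extrapolation is
unstable there. At n = 2,000 the estimator recovers a true π1 of 0.6
within ±0.1; its null bias is below 0.02 at n = 5,000.

## Colocalization and fine-mapping

Per-variant evidence is the Wakefield log approximate Bayes factor
lABF = ½ln(V/(V+W)) + z²W/(2(V+W)) with V = se², W = prior_sd², and
prior_sd = 0.15 for quantitative traits; hypothesis priors are
p1 = p2 = 1e-4 and p12 = 1e-5 (the conventional single-causal ABF
defaults, exposed as arguments). Hypothesis sums run over single-causal
configurations in log space; the test suite checks them against
exhaustive configuration enumeration to 1e-10.

On top of PP.H0–H4 the classifier computes PP.power = PP.H3 + PP.H4
and PP.coloc = PP.H4/(PP.H3+PP.H4) and calls a locus colocalized when
the Euclidean distance from (PP.power, PP.coloc) to (1, 1) is below
0.25. Compared with a hard PP.H4 cutoff, the rule admits loci where
power is split across hypotheses but the shared-causal signal
dominates; it is monotone in PP.H4 at fixed PP.H3. Under the
generator's large-effect conditions, shared-causal loci classify as
colocalized in ≥ 80% of seeds and distinct-causal loci in ≤ 20% (in
practice 50/50 and 0/50).

Fine-mapping is single-effect: PIPs are softmax(lABF) and the 95%
credible set is the smallest PIP-descending prefix reaching coverage.
This is an intentional simplification — the aggregation step, not
multi-effect regression, is the contribution here; with near-uniform
evidence the set legally grows toward the whole locus, and a
multi-effect fine-mapper is the documented extension point. Per gene,
the per-exon credible sets are merged transitively on variant overlap
(connected components of the set-overlap graph) until pairwise
disjoint; "all possible unions" has no other reading that produces
disjoint sets. eQTL sharing is a non-empty intersection between a
gene's collapsed splicing credible sets and its eQTL credible sets,
and the per-tissue enrichment of non-symmetric exons among sharing
genes is a Fisher exact test with Haldane 0.5 correction (flagged) on
zero margins.

## Exon properties

Symmetry is length divisible by 3 — a symmetric exon encodes whole
codons and its skipping preserves the reading frame. Relative
transcript position is ordinal/n_exons with the ordinal counted 5'→3'
(the bp-midpoint alternative is deliberately not used: the ordinal is
robust to intron length); uniformity is tested by χ² over 10
equal-width bins. Variant location relative to the target gene is a
three-way interval classification (exonic / intronic / flanking), a
deliberate simplification of consequence annotation sufficient for the
location contrast. Direction tests count derived alleles that increase
vs decrease inclusion among records with |ΔPSI| above a cutoff
(default 0.035) and compare by an exact two-sided binomial test;
derived-allele frequencies split by direction are contrasted by the
two-sample KS D and a Mann-Whitney test, with a cutoff sweep exposing
the growth of D with effect size. All two-group tests are two-sided
and report raw p-values; a Benjamini–Hochberg column is emitted in
grid reports purely as a convenience.

## Protein structure

Exon→protein mapping translates the three forward frames (the exon
strand is known, so reverse frames are never valid), Smith–Waterman
aligns each peptide against candidate proteins under BLOSUM62 with
BLAST-style affine gaps (a length-k gap costs 11 + k), and converts
scores to e-values with gapped Karlin–Altschul constants λ = 0.267,
K = 0.041 over the search space (query aa length × total database
length). A hit is kept only if its e-value is ≤ 0.001 and the best hit
lies in the exon's own gene product. On planted in-frame exons ≥ 10 aa
the mapping recovers the exact residue interval in 100/100 synthetic
genes; random 9-nt exons are rejected by the e-value filter.

Solvent accessibility uses an in-repo Shrake–Rupley implementation:
each atom's solvent sphere (vdW radius + 1.4 Å probe) is sampled with
a deterministic golden-spiral point set (default 100 points/atom), and
residue RSA is 100 × SASA / maxASA with the Tien et al. theoretical
maxima; RSA < 25 is classified buried. A single isolated atom
reproduces 4π(r+probe)² to well under the 2% quadrature budget, and
doubling the point count changes a 50-residue toy total by < 1%.
Exon summaries report the first quartile of RSA and the third quartile
of pLDDT (linear-interpolation quantiles), asparagine and cysteine
percentages of the aligned peptide, aligned length, and whether the
interval touches any annotation from the recognized UniProt-style
category list; closed intervals that merely touch count as overlap.

Structure comparison deletes the exon's rows and columns from the
spliced-in PAE matrix so both matrices index the shared residues, then
reports the element-wise RMS difference in Å. The RMS normalization —
rather than a raw Frobenius norm — keeps values on the PAE scale and
comparable across protein lengths of hundreds of residues (typical
values 1.7–3.2 Å on the synthetic pairs); the raw Frobenius norm is
available via `normalized=False`. Superposition RMSD uses Kabsch
least squares on shared CA atoms (proper rotation enforced by the SVD
determinant correction) followed by iterative rejection of pairs
deviating by more than 2 × current RMSD, up to 5 cycles and never below
3 pairs — the analogue of an "align"-style refinement that discounts
segments genuinely displaced by the splice. Models longer than 1,300
residues are outside the intended regime of single-chain comparisons.
pLDDT is read from the B-factor column of AlphaFold-style PDB files.

## Synthetic data: what it emulates, and what it does not

Genotypes are drawn per haplotype from an AR(1) latent Gaussian
(neighbor correlation `ld_rho`, default 0.5) thresholded at Φ⁻¹(MAF),
giving HWE margins with local LD — sufficient structure for
colocalization and fine-mapping tests, but not a realistic
recombination landscape. PSI follows
logit(ψ) = α + β·dosage + γᵀC + ε with ε ~ N(0, 0.3); junction counts
are binomial given a negative-binomial total depth
(var = μ + 0.3μ², mean 50), so zero-depth samples exercise the
missingness filters. Defaults describe the targeted regime: 200
donors, common variants (MAF 0.3), 50 variants per gene, and an
allelic effect sized to a 0.2 homozygote PSI difference at a 0.5
baseline. GWAS/QTL pairs are simulated at the individual level on
independent cohorts from the same LD block (QTL n = 200 with
standardized effect 1.0; GWAS n = 5,000 with effect 0.15 — strong,
well-powered signals) and reduced to marginal beta/se, so the summary
statistics are internally consistent; distinct-causal loci place the
two causals a quarter and three quarters along the block and verify
realized r² < 0.1. Structure pairs are idealized helical-domain CA
traces with domain-structured pLDDT and PAE and a rigid
rotation+translation+noise applied downstream of the splice.

Passing tests therefore demonstrate statistical correctness and
calibration of the methods under their stated assumptions — they do
not establish performance on real RNA-seq (no mapping bias, overlapping
genes, annotation error, population structure, or multi-tissue
correlation beyond shared effects), and the structure generator
contains no protein physics.

## Numerical choices and degenerate inputs

- All randomness flows from explicit seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical
  outputs.
- Beta-fit failures, zero-variance genotype pairs, empty homozygote
  classes, zero-margin contingency tables, unclassifiable
  colocalizations (PP.H3+PP.H4 = 0), constant correlation inputs and
  unknown residue types all return flagged results or raise with
  specific messages rather than propagating NaNs silently.
- Quantiles use linear interpolation between order statistics
  throughout; log-space accumulation (logsumexp) is used everywhere
  Bayes factors are summed.
- Problem sizes in the test suite and acceptance script (100–500 genes,
  1,000 permutations, 50-variant loci, 50-seed operating-characteristic
  runs) were chosen as the smallest sizes at which the binomial noise
  of each rate estimate is comfortably inside its tolerance.

## Known limitations

- Single-effect fine-mapping cannot separate multiple independent
  causal signals in one exon's locus; the aggregation layer is
  agnostic to the fine-mapper and would accept multi-effect sets.
- The PSI estimator uses junction averaging without read-level
  overhang/entropy filtering; exon definitions are taken as given.
- Conditional/secondary association passes, trans effects, and
  multi-trait colocalization are out of scope.
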