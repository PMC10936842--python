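"""QTL scan, grouped permutations, effect sizes, collapsing and pi1."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from psiqtl import mapping, phenotype, synthetic
from psiqtl.containers import GenotypeMatrix, PsiPhenotype


def _geno(dosages, positions=None, samples=None):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    V, n = dosages.shape
    vids = [f"v{i}" for i in range(V)]
    samples = samples or [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": positions if positions is not None else np.arange(V) * 100 + 1000,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(vids, name="variant_id"),
    )
    return GenotypeMatrix(variants=variants, dosages=pd.DataFrame(dosages, index=variants.index, columns=samples))


def _pheno(norm_matrix, gene="G0", tss=1000, samples=None):
    norm_matrix = np.atleast_2d(np.asarray(norm_matrix, dtype=float))
    E, n = norm_matrix.shape
    samples = samples or [f"s{i}" for i in range(n)]
    idx = pd.Index([f"e{i}" for i in range(E)], name="exon_id")
    mat = pd.DataFrame(norm_matrix, index=idx, columns=samples)
    return PsiPhenotype(
        psi=mat,
        gene_group=pd.Series(gene, index=idx),
        tss_anchor=pd.Series({gene: tss}),
        normalized=mat,
    )


class TestNominalScan:
    def test_matches_full_design_ols(self):
        """Residualized scan equals the joint regression, slope and p to 1e-8."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(30, 80))
            k = int(rng.integers(1, 4))
            g = rng.binomial(2, 0.3, size=n).astype(float)
            C = rng.standard_normal((n, k))
            y = 0.3 * g + C @ rng.standard_normal(k) + rng.standard_normal(n)
            pheno = _pheno(y[None, :])
            geno = _geno(g[None, :])
            cov = pd.DataFrame(C, index=pheno.samples, columns=[f"c{j}" for j in range(k)])
            out = mapping.nominal_scan(pheno, geno, cov, maf_min=0.0)
            X = sm.add_constant(np.column_stack([g, C]))
            fit = sm.OLS(y, X).fit()
            assert out["slope"].iloc[0] == pytest.approx(fit.params[1], abs=1e-8)
            assert out["nominal_p"].iloc[0] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_recovers_simulated_slope(self):
        rng = np.random.default_rng(1)
        n, beta = 500, 0.5
        g = rng.binomial(2, 0.4, size=n).astype(float)
        C = rng.standard_normal((n, 3))
        y = beta * g + C @ np.array([0.2, -0.1, 0.3]) + rng.standard_normal(n)
        pheno = _pheno(y[None, :])
        cov = pd.DataFrame(C, index=pheno.samples, columns=list("abc"))
        out = mapping.nominal_scan(pheno, _geno(g[None, :]), cov, maf_min=0.0)
        assert out["slope"].iloc[0] == pytest.approx(beta, abs=0.1)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        n, V, E = 60, 50, 40  # 2000 independent null pairs
        pvals = []
        for e in range(E):
            g = rng.binomial(2, 0.3, size=(V, n)).astype(float)
            y = rng.standard_normal(n)
            pheno = _pheno(y[None, :])
            cov = pd.DataFrame(rng.standard_normal((n, 2)), index=pheno.samples, columns=["a", "b"])
            out = mapping.nominal_scan(pheno, _geno(g), cov, maf_min=0.0)
            pvals.extend(out["nominal_p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_low_maf_variant_excluded(self):
        rng = np.random.default_rng(3)
        n = 200
        g_common = rng.binomial(2, 0.3, size=n).astype(float)
        g_rare = np.zeros(n)
        g_rare[: int(0.04 * 2 * n) // 2] = 1.0  # MAF 0.04
        pheno = _pheno(rng.standard_normal((1, n)))
        cov = pd.DataFrame(index=pheno.samples)
        out = mapping.nominal_scan(pheno, _geno(np.vstack([g_common, g_rare])), cov, maf_min=0.05)
        assert set(out["variant_id"]) == {"v0"}

    def test_out_of_window_variant_excluded(self):
        rng = np.random.default_rng(4)
        n = 50
        g = rng.binomial(2, 0.5, size=(2, n)).astype(float)
        pheno = _pheno(rng.standard_normal((1, n)), tss=1_000_000)
        cov = pd.DataFrame(index=pheno.samples)
        geno = _geno(g, positions=[1_000_500, 2_500_000])
        out = mapping.nominal_scan(pheno, geno, cov, cis_window=1_000_000, maf_min=0.0)
        assert set(out["variant_id"]) == {"v0"}

    def test_monomorphic_variant_skipped(self):
        n = 40
        g = np.vstack([np.ones(n), np.random.default_rng(5).binomial(2, 0.5, n)]).astype(float)
        pheno = _pheno(np.random.default_rng(6).standard_normal((1, n)))
        cov = pd.DataFrame(index=pheno.samples)
        out = mapping.nominal_scan(pheno, _geno(g), cov, maf_min=0.0)
        assert "v0" not in set(out["variant_id"])
        assert out.attrs["skipped_pairs"] == 1


def _run_gene(seed, beta, n=200, n_perm=500, exons=2, variants=30):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, size=(variants, n)).astype(float)
    C = rng.standard_normal((n, 2))
    Y = np.vstack(
        [beta * g[variants // 2] + rng.standard_normal(n) for _ in range(exons)]
    )
    pheno = _pheno(Y)
    cov = pd.DataFrame(C, index=pheno.samples, columns=["a", "b"])
    geno = _geno(g)
    assoc = mapping.nominal_scan(pheno, geno, cov, maf_min=0.0)
    return mapping.permutation_adjust(assoc, pheno, geno, cov, n_perm=n_perm, seed=seed)


class TestPermutationAdjust:
    def test_beta_vs_empirical_consistency(self):
        """Beta-approximated and rank-based permutation p agree in ranking."""
        adj, emp = [], []
        for s in range(50):
            out = _run_gene(seed=100 + s, beta=0.12, n=120, n_perm=300)
            adj.append(out["adjusted_p"].iloc[0])
            emp.append(out["empirical_p"].iloc[0])
        rho, _ = stats.spearmanr(adj, emp)
        assert rho > 0.99

    def test_strong_effect_significant(self):
        out = _run_gene(seed=0, beta=0.8, n=200)
        assert out["adjusted_p"].iloc[0] < 0.05
        assert out["beta_ok"].iloc[0]

    def test_null_adjusted_p_not_inflated(self):
        ps = [
            _run_gene(seed=200 + s, beta=0.0, n=80, n_perm=200)["adjusted_p"].iloc[0]
            for s in range(40)
        ]
        assert 0.25 < float(np.mean(ps)) < 0.75

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            _run_gene(seed=1, beta=0.5, n=60, n_perm=50)


class TestDeltaPsi:
    def test_median_difference(self):
        psi = np.array([0.8, 0.8, 0.8, 0.6, 0.6, 0.6, 0.7, 0.7])
        dos = np.array([0, 0, 0, 2, 2, 2, 1, 1])
        d = mapping.delta_psi(psi, dos)
        assert d.value == pytest.approx(-0.2)
        assert not d.extrapolated

    def test_identical_distributions_zero(self):
        psi = np.tile([0.4, 0.5, 0.6], 3)
        dos = np.repeat([0, 1, 2], 3)
        assert mapping.delta_psi(psi, dos).value == pytest.approx(0.0)

    def test_missing_homozygote_extrapolated(self):
        psi = np.array([0.6, 0.6, 0.7, 0.7])
        dos = np.array([0, 0, 1, 1])
        d = mapping.delta_psi(psi, dos)
        assert d.value == pytest.approx(0.2)
        assert d.extrapolated

    def test_both_homozygotes_missing_undefined(self):
        d = mapping.delta_psi(np.array([0.5, 0.6]), np.array([1, 1]))
        assert not d.defined


def _tissue_table(rows):
    return pd.DataFrame(rows).set_index("gene_id")


class TestCollapseAndLabel:
    def _exons(self):
        return pd.DataFrame(
            {
                "gene_id": ["G1"] * 3,
                "chrom": "chr1",
                "start": [1, 100, 200],
                "end": [50, 150, 250],
                "strand": "+",
                "ordinal": [1, 2, 3],
                "n_exons": 3,
                "is_terminal": [True, False, True],
                "gene_tss": 1,
            },
            index=pd.Index(["E1", "E2", "E3"], name="exon_id"),
        )

    def _row(self, **kw):
        base = dict(
            gene_id="G1",
            exon_id="E2",
            variant_id="v1",
            slope=1.0,
            adjusted_p=0.01,
            delta_psi=0.1,
            ref="A",
            alt="G",
            af=0.4,
        )
        base.update(kw)
        return base

    def test_largest_effect_tissue_wins(self):
        tissues = {
            "t1": _tissue_table([self._row(delta_psi=0.10)]),
            "t2": _tissue_table([self._row(delta_psi=-0.25)]),
        }
        qtl, _ = mapping.collapse_and_label(tissues, self._exons())
        assert qtl.loc["G1", "tissue"] == "t2"
        assert qtl.loc["G1", "delta_psi"] == pytest.approx(-0.25)

    def test_high_inclusion_allele_from_slope(self):
        qtl, _ = mapping.collapse_and_label(
            {"t": _tissue_table([self._row(slope=2.0)])}, self._exons()
        )
        assert qtl.loc["G1", "high_inclusion_allele"] == "G"
        qtl, _ = mapping.collapse_and_label(
            {"t": _tissue_table([self._row(slope=-2.0)])}, self._exons()
        )
        assert qtl.loc["G1", "high_inclusion_allele"] == "A"

    def test_derived_direction_composition(self):
        # ancestral = ref -> derived = alt; slope < 0 -> alt lowers inclusion
        qtl, _ = mapping.collapse_and_label(
            {"t": _tissue_table([self._row(slope=-1.0)])},
            self._exons(),
            ancestral={"v1": "A"},
        )
        assert qtl.loc["G1", "derived_allele"] == "G"
        assert qtl.loc["G1", "derived_direction"] == "decreases"
        assert qtl.loc["G1", "daf"] == pytest.approx(0.4)

    def test_unknown_ancestral_gives_unknown_direction(self):
        qtl, _ = mapping.collapse_and_label(
            {"t": _tissue_table([self._row()])}, self._exons(), ancestral={}
        )
        assert qtl.loc["G1", "derived_direction"] == "unknown"

    def test_terminal_top_exon_removes_gene(self):
        tissues = {"t": _tissue_table([self._row(exon_id="E1")])}
        qtl, _ = mapping.collapse_and_label(tissues, self._exons())
        assert "G1" not in qtl.index

    def test_non_qtl_comparator_set(self):
        tissues = {
            "t1": _tissue_table([self._row(gene_id="G1", adjusted_p=0.5), self._row(gene_id="G2", adjusted_p=0.01)]),
            "t2": _tissue_table([self._row(gene_id="G1", adjusted_p=0.3), self._row(gene_id="G2", adjusted_p=0.6)]),
        }
        _, nonqtl = mapping.collapse_and_label(tissues, self._exons())
        assert list(nonqtl) == ["G1"]


class TestReplicationPi1:
    def test_saturated_signal(self):
        res = mapping.replication_pi1(np.full(200, 1e-7))
        assert res.pi1 == pytest.approx(1.0, abs=1e-6)

    def test_uniform_null(self):
        rng = np.random.default_rng(8)
        res = mapping.replication_pi1(rng.random(5000))
        assert res.pi1 < 0.1

    def test_mixture_recovery(self):
        rng = np.random.default_rng(9)
        signal = rng.beta(0.5, 40, size=1200)  # strongly enriched near 0
        null = rng.random(800)
        res = mapping.replication_pi1(np.concatenate([signal, null]))
        assert res.pi1 == pytest.approx(0.6, abs=0.1)

    def test_too_few_pvalues_refused(self):
        with pytest.raises(ValueError, match="50"):
            mapping.replication_pi1(np.random.default_rng(0).random(30))


class TestEndToEnd:
    def test_pipeline_recovers_causal_pairs(self, small_cohort, mapped_phenotype):
        geno, cov = small_cohort["geno"], small_cohort["cov"]
        truth = small_cohort["truth"].table
        assoc, genes = mapping.map_tissue(
            mapped_phenotype, geno, cov, small_cohort["exons"], n_perm=300, seed=0
        )
        sig = genes[genes["adjusted_p"] < 0.05]
        assert len(sig) >= 3  # power at beta ~0.42, n=120
        for gene in sig.index:
            assert sig.loc[gene, "exon_id"] == truth.loc[gene, "causal_exon"]

    def test_high_inclusion_label_matches_raw_trend(self, small_cohort, mapped_phenotype):
        geno, cov = small_cohort["geno"], small_cohort["cov"]
        _, genes = mapping.map_tissue(
            mapped_phenotype, geno, cov, small_cohort["exons"], n_perm=200, seed=1
        )
        for gene, row in genes[genes["adjusted_p"] < 0.05].iterrows():
            trend = row["delta_psi"]
            if abs(trend) >= 0.1:
                high = row["alt"] if row["slope"] > 0 else row["ref"]
                expected = row["alt"] if trend > 0 else row["ref"]
                assert high == expected
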