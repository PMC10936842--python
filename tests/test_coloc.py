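"""Colocalization posteriors, classification rule, credible sets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psiqtl import coloc, synthetic


def _sumstats(betas, ses):
    return pd.DataFrame(
        {"beta": betas, "se": ses},
        index=pd.Index([f"v{i}" for i in range(len(betas))], name="variant_id"),
    )


def _sumstats_from_labf(labf, se=0.1, prior_sd=coloc.DEFAULT_PRIOR_SD, normalize=True):
    """Construct (beta, se) pairs whose Wakefield lABF equal the targets.

    Targets are shifted to be non-negative first (the Wakefield lABF is
    bounded below at z = 0); a per-trait constant shift preserves both
    softmax PIPs and the H4/(H3+H4) balance.
    """
    labf = np.asarray(labf, dtype=float)
    if normalize:
        labf = labf - labf.min()
    V, W = se**2, prior_sd**2
    const = 0.5 * np.log(V / (V + W))
    z2 = np.maximum(labf - const, 0.0) * 2.0 * (V + W) / W
    return _sumstats(np.sqrt(z2) * se, np.full(labf.shape, se))


def brute_force_coloc(l1, l2, p1, p2, p12):
    """Exhaustive enumeration over all single-causal configurations."""
    n = len(l1)
    weights = {h: [] for h in range(5)}
    weights[0].append(1.0)
    for i in range(n):
        weights[1].append(p1 * np.exp(l1[i]))
        weights[2].append(p2 * np.exp(l2[i]))
    for i, j in itertools.product(range(n), repeat=2):
        w = p1 * p2 * np.exp(l1[i] + l2[j])
        if i == j:
            weights[4].append(p12 / (p1 * p2) * w)
        else:
            weights[3].append(w)
    sums = np.array([np.sum(weights[h]) for h in range(5)])
    return sums / sums.sum()


class TestWakefieldLabf:
    def test_closed_form_value(self):
        # 0.5 * ln(0.01 / 0.0325) at z = 0
        assert coloc.wakefield_labf(0.0, 0.1, 0.15) == pytest.approx(-0.58939, abs=1e-4)

    def test_monotone_in_abs_z(self):
        zs = np.linspace(0, 50, 30)
        vals = [coloc.wakefield_labf(z * 0.1, 0.1) for z in zs]
        assert np.all(np.diff(vals) > 0)

    def test_vanishing_prior_gives_zero(self):
        assert coloc.wakefield_labf(0.5, 0.1, prior_sd=1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            coloc.wakefield_labf(np.nan, 0.1)
        with pytest.raises(ValueError):
            coloc.wakefield_labf(0.1, 0.0)


class TestColocAbf:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            l1 = rng.normal(0, 4, n)
            l2 = rng.normal(0, 4, n)
            qtl = _sumstats_from_labf(l1)
            gwas = _sumstats_from_labf(l2)
            rec = coloc.coloc_abf(qtl, gwas, min_variants=2)
            # oracle works from the exact lABFs the implementation sees
            l1x = np.asarray(coloc.wakefield_labf(qtl["beta"], qtl["se"]))
            l2x = np.asarray(coloc.wakefield_labf(gwas["beta"], gwas["se"]))
            expected = brute_force_coloc(l1x, l2x, rec.p1, rec.p2, rec.p12)
            got = np.array([rec.pp_h0, rec.pp_h1, rec.pp_h2, rec.pp_h3, rec.pp_h4])
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            qtl = _sumstats(rng.normal(0, 0.2, 30), rng.uniform(0.05, 0.2, 30))
            gwas = _sumstats(rng.normal(0, 0.2, 30), rng.uniform(0.05, 0.2, 30))
            rec = coloc.coloc_abf(qtl, gwas)
            total = rec.pp_h0 + rec.pp_h1 + rec.pp_h2 + rec.pp_h3 + rec.pp_h4
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_dominating_shared_variant(self):
        l = np.zeros(20)
        l[7] = 20.0
        rec = coloc.coloc_abf(_sumstats_from_labf(l), _sumstats_from_labf(l))
        assert rec.pp_h4 > 0.99

    def test_flat_evidence_matches_enumeration(self):
        l = np.zeros(5)
        rec = coloc.coloc_abf(_sumstats_from_labf(l), _sumstats_from_labf(l), min_variants=2)
        expected = brute_force_coloc(l, l, rec.p1, rec.p2, rec.p12)
        got = np.array([rec.pp_h0, rec.pp_h1, rec.pp_h2, rec.pp_h3, rec.pp_h4])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_shift_invariance_of_one_trait(self):
        """Adding a constant to all lABFs of one trait preserves H3/H4 ratio."""
        rng = np.random.default_rng(2)
        l1 = rng.uniform(0, 6, 12)
        l2 = rng.uniform(0, 6, 12)
        r1 = coloc.coloc_abf(
            _sumstats_from_labf(l1, normalize=False),
            _sumstats_from_labf(l2, normalize=False),
            min_variants=2,
        )
        r2 = coloc.coloc_abf(
            _sumstats_from_labf(l1 + 5.0, normalize=False),
            _sumstats_from_labf(l2, normalize=False),
            min_variants=2,
        )
        assert r1.pp_coloc == pytest.approx(r2.pp_coloc, abs=1e-9)

    def test_no_shared_variants_rejected(self):
        a = _sumstats([0.1] * 12, [0.1] * 12)
        b = a.copy()
        b.index = [f"w{i}" for i in range(12)]
        with pytest.raises(ValueError, match="shared"):
            coloc.coloc_abf(a, b)


class TestClassifyColoc:
    def test_corner_cases(self):
        rec = coloc.ColocRecord(0, 0, 0, 0.0, 1.0, 10)
        assert rec.distance == pytest.approx(0.0)
        assert coloc.classify_coloc(rec)
        rec = coloc.ColocRecord(0, 0, 0, 1.0, 0.0, 10)
        assert rec.distance == pytest.approx(1.0)
        assert not coloc.classify_coloc(rec)

    def test_worked_example(self):
        rec = coloc.ColocRecord(0.0, 0.0, 0.05, 0.1, 0.85, 10)
        assert rec.pp_power == pytest.approx(0.95)
        assert rec.pp_coloc == pytest.approx(0.85 / 0.95)
        assert rec.distance == pytest.approx(np.hypot(0.05, 1 - 0.85 / 0.95), abs=1e-9)
        assert coloc.classify_coloc(rec)

    def test_grid_matches_direct_arithmetic(self):
        for h3 in np.linspace(0.01, 0.99, 10):
            for h4 in np.linspace(0.01, 0.99, 10):
                s = h3 + h4
                if s > 1:
                    continue
                rec = coloc.ColocRecord(1 - s, 0, 0, h3, h4, 10)
                d = np.hypot(1 - (h3 + h4), 1 - h4 / (h3 + h4))
                assert coloc.classify_coloc(rec) == (d < 0.25)

    def test_monotone_in_h4(self):
        h3 = 0.05
        flags = [
            coloc.classify_coloc(coloc.ColocRecord(0, 0, 0, h3, h4, 10))
            for h4 in np.linspace(0.01, 0.95, 40)
        ]
        # once colocalized, stays colocalized as H4 grows
        assert flags == sorted(flags)

    def test_zero_power_unclassifiable(self):
        rec = coloc.ColocRecord(1.0, 0, 0, 0.0, 0.0, 10)
        with pytest.raises(ValueError, match="undefined"):
            coloc.classify_coloc(rec)


class TestCredibleSets:
    def test_cumulative_prefix(self):
        pips = np.array([0.9, 0.06, 0.04])
        labf = np.log(pips)  # softmax of log p recovers p
        cs = coloc.abf_credible_sets(_sumstats_from_labf(labf))
        assert cs.variants == ["v0", "v1"]
        assert cs.total_pip >= 0.95

    def test_singleton(self):
        labf = np.array([12.0, 0.0, 0.0, 0.0])
        cs = coloc.abf_credible_sets(_sumstats_from_labf(labf))
        assert cs.variants == ["v0"]

    def test_uniform_pips_need_nineteen_of_twenty(self):
        cs = coloc.abf_credible_sets(_sumstats_from_labf(np.zeros(20)))
        assert len(cs) == 19

    def test_members_sorted_by_pip(self):
        rng = np.random.default_rng(3)
        cs = coloc.abf_credible_sets(_sumstats_from_labf(rng.normal(0, 2, 15)))
        assert np.all(np.diff(cs.pip) <= 0)

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError):
            coloc.abf_credible_sets(_sumstats([0.1], [0.1]))


def union_find_components(sets):
    """Independent oracle: plain union-find over set-overlap."""
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for s in sets:
        for v in s:
            parent.setdefault(v, v)
    for s in sets:
        s = list(s)
        for v in s[1:]:
            union(s[0], v)
    comps = {}
    for v in parent:
        comps.setdefault(find(v), set()).add(v)
    return sorted(frozenset(c) for c in comps.values())


class TestAggregateCredibleSets:
    def test_chain_merge(self):
        out = coloc.aggregate_credible_sets([{"a", "b"}, {"b", "c"}, {"d"}])
        assert sorted(map(frozenset, out)) == [frozenset({"d"}), frozenset({"a", "b", "c"})] or \
            sorted(map(sorted, out)) == [["a", "b", "c"], ["d"]]

    def test_disjoint_unchanged(self):
        inp = [{"a"}, {"b", "c"}, {"d"}]
        out = coloc.aggregate_credible_sets(inp)
        assert sorted(map(frozenset, out)) == sorted(map(frozenset, inp))

    def test_empty(self):
        assert coloc.aggregate_credible_sets([]) == []

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n_sets = int(rng.integers(1, 8))
            universe = [f"x{i}" for i in range(12)]
            sets = [
                set(rng.choice(universe, size=rng.integers(1, 5), replace=False))
                for _ in range(n_sets)
            ]
            got = sorted(frozenset(s) for s in coloc.aggregate_credible_sets(sets))
            assert got == union_find_components(sets)

    def test_output_pairwise_disjoint(self):
        rng = np.random.default_rng(5)
        sets = [set(rng.choice(20, size=4)) for _ in range(10)]
        out = coloc.aggregate_credible_sets(sets)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert not (out[i] & out[j])


class TestEqtlOverlapEnrichment:
    def _table(self, a, b, c, d, tissue="t1"):
        rows = []
        rows += [{"tissue": tissue, "eqtl_overlap": True, "symmetric": False}] * a
        rows += [{"tissue": tissue, "eqtl_overlap": True, "symmetric": True}] * b
        rows += [{"tissue": tissue, "eqtl_overlap": False, "symmetric": False}] * c
        rows += [{"tissue": tissue, "eqtl_overlap": False, "symmetric": True}] * d
        return pd.DataFrame(rows)

    def test_balanced_table_or_one(self):
        out = coloc.eqtl_overlap_enrichment(self._table(10, 10, 10, 10))
        assert out.loc["t1", "odds_ratio"] == pytest.approx(1.0)

    def test_strong_table_matches_hypergeometric(self):
        out = coloc.eqtl_overlap_enrichment(self._table(20, 5, 5, 20))
        assert out.loc["t1", "odds_ratio"] == pytest.approx(16.0)
        _, p = stats.fisher_exact([[20, 5], [5, 20]])
        assert out.loc["t1", "fisher_p"] == pytest.approx(p)

    def test_zero_margin_haldane_flagged(self):
        out = coloc.eqtl_overlap_enrichment(self._table(0, 0, 10, 10))
        assert bool(out.loc["t1", "haldane_corrected"])
        assert np.isfinite(out.loc["t1", "odds_ratio"])


class TestSimGwasPairBehaviour:
    def test_shared_causal_yields_h4(self):
        config = synthetic.SimConfig(seed=0)
        hits = 0
        for s in range(15):
            gwas, qtl, _ = synthetic.sim_gwas_pair(config, shared=True, seed=s)
            rec = coloc.coloc_abf(qtl, gwas)
            hits += rec.pp_h4 > 0.9
        assert hits >= 12

    def test_distinct_causal_yields_h3(self):
        config = synthetic.SimConfig(seed=0)
        hits = 0
        for s in range(15):
            gwas, qtl, _ = synthetic.sim_gwas_pair(config, shared=False, seed=s)
            rec = coloc.coloc_abf(qtl, gwas)
            hits += max(
                (rec.pp_h0, rec.pp_h1, rec.pp_h2, rec.pp_h3, rec.pp_h4)
            ) == rec.pp_h3
        assert hits >= 12

    def test_null_effects_give_h0(self):
        config = synthetic.SimConfig(seed=0)
        gwas, qtl, _ = synthetic.sim_gwas_pair(
            config, shared=True, seed=3, gwas_effect=0.0, qtl_effect=0.0
        )
        rec = coloc.coloc_abf(qtl, gwas)
        assert rec.pp_h0 == max(rec.pp_h0, rec.pp_h1, rec.pp_h2, rec.pp_h3, rec.pp_h4)
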