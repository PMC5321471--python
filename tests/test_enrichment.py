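"""Association statistics: Fisher enrichment, Kruskal–Wallis, Empirical
Brown's Method, BH-FDR, direction calls, and drug-response tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import mutclust as mc
from mutclust.enrichment_assoc import Direction, _ebm_transform


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherEnrichment:
    @pytest.mark.parametrize(
        "table", [[[0, 10], [10, 0]], [[1, 9], [11, 3]], [[5, 2], [3, 8]], [[2, 2], [2, 2]]]
    )
    def test_matches_enumeration_oracle(self, table):
        assert mc.fisher_enrichment(table) == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_identical_proportions_give_one(self):
        assert mc.fisher_enrichment([[5, 5], [7, 7]]) == 1.0

    def test_empty_margin_gives_one(self):
        assert mc.fisher_enrichment([[0, 0], [5, 9]]) == 1.0

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            mc.fisher_enrichment([[1, 2, 3], [4, 5, 6]])


class TestKruskalWallis:
    def test_identical_groups_give_one(self):
        f = np.array([1, 1, 0, 0])
        v = np.array([3.0, 5.0, 3.0, 5.0])
        assert mc.kruskal_wallis(f, v) == pytest.approx(1.0)

    def test_separated_groups_match_permutation_oracle(self):
        """Exact permutation distribution of H for total separation."""
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(5, 6, 10)])
        f = np.array([0] * 10 + [1] * 10)
        p = mc.kruskal_wallis(f, v)
        # permutation oracle on the H statistic (label permutations, sampled)
        h_obs = stats.kruskal(v[f == 1], v[f == 0])[0]
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            fp = rng.permutation(f)
            if stats.kruskal(v[fp == 1], v[fp == 0])[0] >= h_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p == pytest.approx(p_perm, abs=max(0.1 * p_perm, 5e-4))

    def test_missing_values_dropped_first(self):
        f = np.array([1, 1, 0, 0, 1])
        v = np.array([2.0, 3.0, 1.0, 1.5, np.nan])
        assert mc.kruskal_wallis(f, v) == mc.kruskal_wallis(f[:4], v[:4])

    def test_empty_group_gives_nan(self):
        assert np.isnan(mc.kruskal_wallis(np.array([1, 1]), np.array([1.0, 2.0])))


class TestEmpiricalBrowns:
    def test_single_test_passthrough(self):
        rng = np.random.default_rng(1)
        for p in (0.001, 0.04, 0.5):
            assert mc.empirical_browns(rng.normal(size=(1, 40)), [p]) == pytest.approx(p)

    def test_duplicated_rows_collapse_to_single_p(self):
        """Perfect dependence: combining a p-value with itself returns it."""
        rng = np.random.default_rng(2)
        row = rng.normal(size=1000)
        for p in (0.01, 0.2):
            combined = mc.empirical_browns(np.vstack([row, row]), [p, p])
            assert combined == pytest.approx(p, rel=0.08)

    def test_independence_limit_matches_fishers_method(self):
        """For independent rows and many samples, the empirical covariance
        vanishes and the combination approaches Fisher's method."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = rng.normal(size=(6, 400))
            ps = rng.uniform(0.01, 0.9, size=6)
            ebm = mc.empirical_browns(data, ps)
            fisher = mc.fishers_method(ps)
            if abs(ebm - fisher) <= 0.2 * fisher:
                ok += 1
        assert ok >= 95

    def test_zero_covariance_rows_reduce_to_fisher(self):
        """Rows engineered so their -2 ln(survival) transforms have (near)
        zero sample covariance reproduce Fisher's method."""
        s = 24
        base = np.arange(s, dtype=float)
        w1 = _ebm_transform(base)
        rng = np.random.default_rng(3)
        best_perm, best_cov = None, np.inf
        for _ in range(20000):
            perm = rng.permutation(s)
            cov = np.cov(w1, _ebm_transform(base[perm]))[0, 1]
            if abs(cov) < abs(best_cov):
                best_cov, best_perm = cov, perm
        assert abs(best_cov) < 5e-3
        data = np.vstack([base, base[best_perm]])
        ps = [0.03, 0.2]
        assert mc.empirical_browns(data, ps) == pytest.approx(
            mc.fishers_method(ps), rel=1e-2
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mc.empirical_browns(np.empty((0, 5)), [])


class TestBhFdr:
    def bh_oracle(self, p, q):
        """Literal step-up rule: find the largest i with p_(i) <= iq/m."""
        m = len(p)
        order = np.argsort(p)
        thresh = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i * q / m:
                thresh = i
        flags = np.zeros(m, dtype=bool)
        flags[order[:thresh]] = True
        return flags

    def test_hand_example(self):
        flags = mc.bh_fdr([0.001, 0.2, 0.9], 0.05)
        assert flags.tolist() == [True, False, False]

    def test_all_ones_no_rejections(self):
        assert not mc.bh_fdr([1.0] * 5, 0.1).any()

    def test_monotone_in_q(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        low = mc.bh_fdr(p, 0.01)
        high = mc.bh_fdr(p, 0.10)
        assert (high | ~low).all()  # low-q rejections are a subset

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            q = float(rng.choice([0.01, 0.05, 0.1, 0.25]))
            assert np.array_equal(mc.bh_fdr(p, q), self.bh_oracle(p, q))


class TestGlobalAndPathways:
    def _setup(self, seed=0, shift=0.0, shifted_genes=()):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(60)]
        genes = [f"G{i}" for i in range(20)]
        feature = (rng.random(60) < 0.25).astype(int)
        mut = [s for s, f in zip(samples, feature) if f]
        expression = mc.generate_expression_matrix(
            genes, samples, {g: mut for g in shifted_genes}, shift=shift, seed=seed + 1
        )
        fmx = mc.FeatureMatrix("BRCA", pd.DataFrame({"G:1-5": feature}, index=samples))
        kw = mc.expression_kw_pvalues(fmx, expression)
        return kw, expression, fmx

    def test_whole_set_pathway_equals_global(self):
        kw, expression, _ = self._setup()
        pathways = {"ALL": list(expression.index)}
        glob, path = mc.combine_global_and_pathways(kw, expression, pathways)
        assert glob[0].p_value == pytest.approx(path[0].p_value)

    def test_planted_pathway_has_smallest_p(self):
        """A shift confined to one pathway's genes makes that pathway the
        top hit in nearly all replicates."""
        genes = [f"G{i}" for i in range(20)]
        pathways = {"HIT": genes[:5]}
        pathways.update({f"PW{j}": genes[5 + 3 * j : 8 + 3 * j] for j in range(5)})
        wins = 0
        for seed in range(20):
            kw, expression, _ = self._setup(seed=seed, shift=1.5, shifted_genes=genes[:5])
            _, path = mc.combine_global_and_pathways(kw, expression, pathways)
            best = min(path, key=lambda r: r.p_value)
            wins += best.target == "HIT"
        assert wins >= 18

    def test_pathway_without_measured_members_skipped(self):
        kw, expression, _ = self._setup()
        _, path = mc.combine_global_and_pathways(
            kw, expression, {"GHOST": ["NOT_MEASURED"]}
        )
        assert path == []


class TestDirectionCalls:
    def _expr(self, feature, shift, seed=0):
        samples = [f"S{i}" for i in range(80)]
        mut = [s for s, f in zip(samples, feature) if f]
        return mc.generate_expression_matrix(
            ["G0", "G1"], samples, {"G0": mut}, shift=shift, seed=seed
        )

    def test_positive_shift_called_up(self):
        rng = np.random.default_rng(6)
        feature = (rng.random(80) < 0.4).astype(int)
        calls = mc.direction_calls(feature, self._expr(feature, +2.0), ["G0", "G1"])
        assert calls.get("G0") is Direction.UP

    def test_negative_shift_called_down(self):
        rng = np.random.default_rng(7)
        feature = (rng.random(80) < 0.4).astype(int)
        calls = mc.direction_calls(feature, self._expr(feature, -2.0), ["G0", "G1"])
        assert calls.get("G0") is Direction.DOWN

    def test_null_rejections_bounded(self):
        """No planted effect: per-pathway BH at 1% rejects ~never."""
        total, rejected = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            feature = (rng.random(80) < 0.4).astype(int)
            calls = mc.direction_calls(feature, self._expr(feature, 0.0, seed), ["G0", "G1"])
            rejected += len(calls)
            total += 2
        assert rejected / total <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / total)


class TestDrugAssociations:
    def _features(self, positives, n=40):
        lines = [f"CL{i}" for i in range(n)]
        return pd.DataFrame(
            {"G:1-5": [1] * positives + [0] * (n - positives)}, index=lines
        )

    def test_few_positives_excluded(self):
        feats = self._features(4)
        ic50 = mc.generate_drug_response(list(feats.index), ["D1"], seed=1)
        assert mc.drug_associations(feats, ic50) == []

    def test_planted_sensitivity_detected(self):
        """A 2-SD ln-IC50 drop in mutated lines is BH-significant at 10%."""
        hits = 0
        for seed in range(20):
            feats = self._features(10)
            sens = {"D1": [f"CL{i}" for i in range(10)]}
            ic50 = mc.generate_drug_response(
                list(feats.index), ["D1", "D2", "D3"], sensitive=sens,
                effect=2.0, missing_fraction=0.15, seed=seed,
            )
            res = mc.drug_associations(feats, ic50)
            d1 = [r for r in res if r.target == "D1"]
            if d1 and d1[0].significant_at[0.10] and d1[0].direction is Direction.DOWN:
                hits += 1
        assert hits >= 18

    def test_all_missing_drug_skipped(self, caplog):
        feats = self._features(10)
        ic50 = mc.generate_drug_response(list(feats.index), ["D1"], seed=2)
        ic50["D1"] = np.nan
        with caplog.at_level("INFO"):
            assert mc.drug_associations(feats, ic50) == []
        assert "skipped" in caplog.text


class TestCelllineEnrichment:
    def test_full_coverage_uninformative(self):
        c = mc.Cluster("G", 1, 100, 50, 10, 0.5, 20, 1.0)
        assert mc.cellline_cluster_enrichment(100, list(range(1, 11)), [c]) == 1.0

    def test_extreme_concentration_tail(self):
        """10/10 mutations inside clusters covering 10% of the protein."""
        c = mc.Cluster("G", 1, 10, 5, 2, 0.5, 10, 1.0)
        p = mc.cellline_cluster_enrichment(100, [1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [c])
        assert p == pytest.approx(0.1**10, rel=1e-6)

    def test_below_min_mutations_uninformative(self):
        c = mc.Cluster("G", 1, 10, 5, 2, 0.5, 10, 1.0)
        assert mc.cellline_cluster_enrichment(100, [1, 2, 3], [c]) == 1.0

    def test_null_type_one_error_controlled(self):
        """Uniform mutations reject at most at the nominal rate."""
        c = mc.Cluster("G", 41, 60, 50, 4, 0.5, 10, 1.0)
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            pos = rng.integers(1, 101, size=15)
            if mc.cellline_cluster_enrichment(100, pos, [c]) <= 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestClusterTumorEnrichment:
    def test_concentrated_tumor_type_enriched(self):
        rng = np.random.default_rng(9)
        samples_a = [f"A{i}" for i in range(50)]
        samples_b = [f"B{i}" for i in range(50)]
        cid = "G:10-20"
        ma = mc.FeatureMatrix("BRCA", pd.DataFrame({cid: [1] * 20 + [0] * 30}, index=samples_a))
        mb = mc.FeatureMatrix("UCEC", pd.DataFrame({cid: [0] * 50}, index=samples_b))
        c = mc.Cluster("G", 10, 20, 15, 2, 0.5, 20, 5.0)
        res = mc.cluster_tumor_enrichment({"BRCA": ma, "UCEC": mb}, [c])
        brca = next(r for r in res if r.target == "BRCA")
        assert brca.p_value < 1e-5
        assert brca.significant_at[0.01]
        # monotone significance in FDR level
        for r in res:
            qs = sorted(r.significant_at)
            assert all(
                r.significant_at[a] <= r.significant_at[b]
                for a, b in zip(qs, qs[1:])
            )
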