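"""Max-statistic permutation FWE, map comparisons, confound analyses, consensus parcels."""

import hashlib

import numpy as np
import pytest
from scipy import stats

import parcelclass as pc
from parcelclass import classify as clf
from parcelclass.inference import (
    consensus_top_parcels,
    difference_vector_correlation,
    fd_group_test,
    gmv_accuracy_correlation,
    misclassification_gmv_test,
    permutation_fwe,
    sex_difference_vector,
    spearman_map_correlation,
)
from parcelclass.results import AccuracyMap, DifferenceVector


@pytest.fixture(scope="module")
def perm_run(small_cohort, small_zstack):
    """One shared permutation run on the small planted cohort."""
    amap, _ = pc.classify_all_parcels(
        small_zstack, small_cohort.atlas, small_cohort.sexes,
        small_cohort.ages[:, None], k=5, seed=0,
    )
    corrected, null = permutation_fwe(
        small_zstack, small_cohort.atlas, small_cohort.sexes,
        small_cohort.ages[:, None], observed=amap, n_perm=50, seed=3, k=5,
    )
    return corrected, null


class TestPermutationFWE:
    def test_p_value_bounds_and_formula(self, perm_run):
        corrected, null = perm_run
        n_perm = null.n_permutations
        assert np.all(corrected.p_fwe >= 1.0 / (n_perm + 1))
        assert np.all(corrected.p_fwe <= 1.0)
        # add-one formula recomputed directly from the stored null
        for acc, p in zip(corrected.accuracy, corrected.p_fwe):
            expect = (1 + np.sum(null.max_accuracies >= acc)) / (1 + n_perm)
            assert p == expect

    def test_monotonicity_in_accuracy(self, perm_run):
        corrected, _ = perm_run
        order = np.argsort(corrected.accuracy)
        p_sorted = corrected.p_fwe[order]
        assert np.all(np.diff(p_sorted) <= 1e-12)

    def test_low_accuracy_parcel_p_one(self, perm_run):
        corrected, null = perm_run
        fake = AccuracyMap(parcel_ids=corrected.parcel_ids,
                           accuracy=np.zeros(len(corrected)), metadata={"k": 5})
        p = (1 + np.sum(null.max_accuracies >= 0.0)) / (1 + null.n_permutations)
        assert p == 1.0
        assert fake.accuracy[0] <= null.max_accuracies.min()

    def test_determinism(self, small_cohort, small_zstack):
        amap, _ = pc.classify_all_parcels(
            small_zstack, small_cohort.atlas, small_cohort.sexes, None, k=5, seed=0)
        runs = [
            permutation_fwe(small_zstack, small_cohort.atlas, small_cohort.sexes,
                            None, observed=amap, n_perm=10, seed=5, k=5)[1].max_accuracies
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_every_parcel_sees_identical_permuted_labels(self, small_cohort, small_zstack, monkeypatch):
        """Exchangeability bookkeeping: one shared label shuffle per permutation."""
        seen = {}
        real = clf.cross_validated_accuracy

        def spy(features, labels, *args, **kwargs):
            pid = kwargs.get("parcel_id")
            h = hashlib.sha1("".join(np.asarray(labels)).encode()).hexdigest()
            seen.setdefault(pid, []).append(h)
            return real(features, labels, *args, **kwargs)

        monkeypatch.setattr("parcelclass.inference.cross_validated_accuracy", spy)
        amap, _ = pc.classify_all_parcels(
            small_zstack, small_cohort.atlas, small_cohort.sexes, None, k=5, seed=0)
        permutation_fwe(small_zstack, small_cohort.atlas, small_cohort.sexes, None,
                        observed=amap, n_perm=4, seed=1, k=5)
        hash_lists = list(seen.values())
        assert len(hash_lists) == small_cohort.atlas.n_parcels
        for hl in hash_lists[1:]:
            assert hl == hash_lists[0]

    def test_invalid_n_perm_rejected(self, small_cohort, small_zstack):
        amap, _ = pc.classify_all_parcels(
            small_zstack, small_cohort.atlas, small_cohort.sexes, None, k=5, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_fwe(small_zstack, small_cohort.atlas, small_cohort.sexes, None,
                            observed=amap, n_perm=0, k=5)

    def test_planted_parcel_significant(self, perm_run):
        corrected, _ = perm_run
        idx = np.flatnonzero(corrected.parcel_ids == 3)[0]  # delta = 0.5 planted
        assert corrected.p_fwe[idx] < 0.1


class TestMapComparisons:
    def _map(self, acc):
        return AccuracyMap(parcel_ids=np.arange(1, len(acc) + 1), accuracy=np.asarray(acc))

    def test_self_correlation_one(self, rng):
        m = self._map(rng.uniform(0.4, 0.9, 30))
        assert spearman_map_correlation(m, m).rho == pytest.approx(1.0)

    def test_reverse_ranking_minus_one(self):
        acc = np.linspace(0.4, 0.9, 20)
        assert spearman_map_correlation(self._map(acc), self._map(acc[::-1])).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        a, b = rng.uniform(0.3, 0.9, 50), rng.uniform(0.3, 0.9, 50)
        got = spearman_map_correlation(self._map(a), self._map(b))
        ranks = lambda v: stats.rankdata(v)  # average-rank ties
        num = np.corrcoef(ranks(a), ranks(b))[0, 1]
        assert abs(got.rho - num) < 1e-12

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman_map_correlation(self._map([0.5, 0.6]), self._map([0.5, 0.6]))


class TestDifferenceVectors:
    def test_identical_groups_zero(self, rng):
        x = rng.standard_normal((60, 4))
        ts = [pc.TimeSeriesMatrix(x, [1, 2, 3, 4]) for _ in range(6)]
        cons = [pc.compute_connectome(t) for t in ts]
        d = sex_difference_vector(cons, ["M", "F", "M", "F", "M", "F"], 2)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(0)
        cons = []
        sexes = []
        for i in range(40):
            x = rng.standard_normal((200, 3))
            c = pc.compute_connectome(pc.TimeSeriesMatrix(x, [1, 2, 3]))
            if i % 2 == 0:
                c.z[0, 1] = c.z[1, 0] = c.z[0, 1] + 0.25
                c.z[1, 2] = c.z[2, 1] = c.z[1, 2] + 0.25
                sexes.append("M")
            else:
                sexes.append("F")
            cons.append(c)
        d = sex_difference_vector(cons, sexes, 2)
        np.testing.assert_allclose(d.values, 0.25, atol=0.05)

    def test_planted_delta_on_target_edges(self, mc_cohort, mc_connectomes):
        from parcelclass.simulate import expected_sex_difference

        delta = expected_sex_difference(mc_cohort.config)
        i5 = mc_cohort.atlas.index_of(5)
        target_cols = np.flatnonzero(delta[i5] != 0)
        d = sex_difference_vector(mc_connectomes, mc_cohort.sexes, 5)
        # positions in the length-(P-1) vector after removing the diagonal entry
        pos = np.array([c - 1 if c > i5 else c for c in target_cols])
        assert abs(d.values[pos].mean() - 0.3) < 0.05
        off = np.setdiff1d(np.arange(len(d.values)), pos)
        assert abs(d.values[off].mean()) < 0.05

    def test_missing_sex_rejected(self, rng):
        x = rng.standard_normal((50, 3))
        cons = [pc.compute_connectome(pc.TimeSeriesMatrix(x, [1, 2, 3]))] * 3
        with pytest.raises(ValueError, match="both sexes"):
            sex_difference_vector(cons, ["M", "M", "M"], 1)

    def test_vector_correlation_trivial_cases(self, rng):
        v = rng.standard_normal(50)
        a = DifferenceVector(parcel_id=1, values=v)
        b = DifferenceVector(parcel_id=1, values=-v)
        r, _ = difference_vector_correlation(a, a)
        assert r == pytest.approx(1.0)
        r, _ = difference_vector_correlation(a, b)
        assert r == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            difference_vector_correlation(a, DifferenceVector(parcel_id=1, values=np.zeros(50)))


class TestGMVConfound:
    def test_accuracy_equal_to_directed_difference(self, rng):
        n_sub, p = 40, 20
        sexes = np.array(["M", "F"] * (n_sub // 2))
        gmv = rng.uniform(100, 900, size=(n_sub, p))
        directed = gmv[sexes == "M"].mean(0) - gmv[sexes == "F"].mean(0)
        acc = (directed - directed.min()) / (directed.max() - directed.min()) * 0.4 + 0.5
        amap = AccuracyMap(parcel_ids=np.arange(1, p + 1), accuracy=acc)
        d, _a = gmv_accuracy_correlation(gmv, sexes, amap)
        assert d.rho == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        n_sub, p = 30, 15
        sexes = np.array(["M", "F"] * 15)
        gmv = rng.uniform(100, 900, size=(n_sub, p))
        acc = rng.uniform(0.5, 0.8, p)
        amap = AccuracyMap(parcel_ids=np.arange(1, p + 1), accuracy=acc)
        d, a = gmv_accuracy_correlation(gmv, sexes, amap)
        diff = gmv[sexes == "M"].mean(0) - gmv[sexes == "F"].mean(0)
        oracle_d = np.corrcoef(stats.rankdata(diff), stats.rankdata(acc))[0, 1]
        oracle_a = np.corrcoef(stats.rankdata(np.abs(diff)), stats.rankdata(acc))[0, 1]
        assert abs(d.rho - oracle_d) < 1e-12
        assert abs(a.rho - oracle_a) < 1e-12

    def test_subsets(self, rng):
        p = 30
        sexes = np.array(["M", "F"] * 20)
        gmv = rng.uniform(100, 900, size=(40, p))
        amap = AccuracyMap(parcel_ids=np.arange(1, p + 1),
                           accuracy=rng.uniform(0.5, 0.9, p),
                           p_fwe=rng.uniform(0.0, 0.1, p))
        d, _ = gmv_accuracy_correlation(gmv, sexes, amap, subset="top_decile")
        assert d.n_parcels == 3
        d, _ = gmv_accuracy_correlation(gmv, sexes, amap, subset="significant")
        assert d.n_parcels >= 1
        with pytest.raises(ValueError, match="subset"):
            gmv_accuracy_correlation(gmv, sexes, amap, subset="bogus")


class TestMisclassificationGMV:
    def test_null_gmv_few_raw_none_fdr(self, rng):
        n_sub, p = 200, 60
        gmv = rng.normal(500, 50, size=(n_sub, p))
        correct = rng.random(n_sub) < 0.7
        out = misclassification_gmv_test(gmv, correct)
        frac_raw = np.mean(out["p"] < 0.05)
        assert frac_raw < 0.20  # ~5% expected under the null
        assert out["n_significant"] <= 1

    def test_planted_gap_survives_fdr(self, rng):
        n_sub, p = 200, 30
        gmv = rng.normal(500, 20, size=(n_sub, p))
        correct = rng.random(n_sub) < 0.7
        gmv[correct, 4] += 100.0  # large gap aligned with correctness
        out = misclassification_gmv_test(gmv, correct)
        assert out["p_fdr"][4] < 0.05

    def test_constant_parcel_recorded_as_nan(self, rng):
        gmv = rng.normal(500, 20, size=(50, 3))
        gmv[:, 1] = 400.0
        correct = np.array([True, False] * 25)
        out = misclassification_gmv_test(gmv, correct)
        assert np.isnan(out["t"][1]) and np.isnan(out["p_fdr"][1])
        assert np.isfinite(out["t"][0])

    def test_empty_group_returns_na_with_message(self, rng):
        out = misclassification_gmv_test(rng.normal(size=(20, 4)), np.ones(20, dtype=bool))
        assert np.all(np.isnan(out["t"])) and "message" in out


class TestConsensus:
    def test_top_three_percent_of_436(self):
        rng = np.random.default_rng(0)
        acc = rng.permutation(np.linspace(0.5, 0.9, 436))  # distinct values
        amap = AccuracyMap(parcel_ids=np.arange(1, 437), accuracy=acc)
        top = consensus_top_parcels([amap], fraction=0.03)
        assert len(top) == 13  # floor(436 * 0.03)

    def test_identical_maps_consensus_equals_top_set(self, rng):
        acc = rng.uniform(0.5, 0.9, 100)
        amap = AccuracyMap(parcel_ids=np.arange(1, 101), accuracy=acc)
        t1 = consensus_top_parcels([amap], 0.1)
        t3 = consensus_top_parcels([amap, amap, amap], 0.1)
        assert t1 == t3

    def test_disjoint_top_sets_empty(self):
        a = AccuracyMap(parcel_ids=np.arange(1, 11), accuracy=np.linspace(0.5, 0.9, 10))
        b = AccuracyMap(parcel_ids=np.arange(1, 11), accuracy=np.linspace(0.9, 0.5, 10))
        assert consensus_top_parcels([a, b], 0.2) == set()

    def test_ties_at_cutoff_included(self):
        acc = np.array([0.9, 0.8, 0.8, 0.8, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        amap = AccuracyMap(parcel_ids=np.arange(1, 11), accuracy=acc)
        assert consensus_top_parcels([amap], 0.2) == {1, 2, 3, 4}

    def test_invalid_fraction_rejected(self):
        amap = AccuracyMap(parcel_ids=np.arange(1, 5), accuracy=np.full(4, 0.5))
        with pytest.raises(ValueError, match="fraction"):
            consensus_top_parcels([amap], 0.0)


class TestFDGroupTest:
    def test_equal_groups_nonsignificant_typically(self, small_cohort):
        t, p = fd_group_test(small_cohort)
        assert np.isfinite(t) and 0 <= p <= 1

    def test_shifted_groups_detected(self, rng):
        class _C:
            mean_fd = np.concatenate([rng.normal(0.30, 0.01, 50), rng.normal(0.15, 0.01, 50)])
            sexes = np.array(["M"] * 50 + ["F"] * 50)

        t, p = fd_group_test(_C())
        assert p < 1e-6

    def test_single_subject_group_rejected(self):
        class _C:
            mean_fd = np.array([0.1, 0.2, 0.3])
            sexes = np.array(["M", "F", "F"])

        with pytest.raises(ValueError, match="two subjects"):
            fd_group_test(_C())
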