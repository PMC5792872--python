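import numpy as np
import pytest

import nirtrace as nt
from nirtrace.classify import (
    ClassModel,
    DEFAULT_STEP1_REGIONS,
    DEFAULT_STEP2_REGIONS,
    classify,
    fit_class_models,
    fit_pca,
    hit_threshold,
    mahalanobis_distance,
    run_two_step,
    scale_to_first_range,
    selectivity,
)
from nirtrace.spectra import SpectraSet, WavelengthRegions, make_split, restrict_to_regions


def euclid_model(label, centre, d_threshold):
    centre = np.asarray(centre, float)
    return ClassModel(label, centre, np.array([d_threshold]), d_threshold,
                      0.25, "euclidean")


def make_labeled(X, origins, start=1000.0):
    X = np.asarray(X, float)
    wl = start + 2.0 * np.arange(X.shape[1])
    ids = [f"s{i}" for i in range(X.shape[0])]
    return SpectraSet(wl, X, ids, origins)


class TestDefaultRegions:
    def test_region_sets_cover_the_working_window(self):
        for regs in (DEFAULT_STEP1_REGIONS, DEFAULT_STEP2_REGIONS):
            lo = regs.regions[0][0]
            hi = regs.regions[-1][1]
            assert 1000.0 <= lo and hi <= 1798.0

    def test_step1_sees_1568_1602_but_not_1604_1622(self):
        wl = np.arange(1560.0, 1640.0, 2.0)
        m1 = DEFAULT_STEP1_REGIONS.mask(wl)
        m2 = DEFAULT_STEP2_REGIONS.mask(wl)
        assert m1[(wl >= 1568) & (wl <= 1602)].all()
        assert not m1[(wl >= 1604) & (wl <= 1622)].any()
        assert m2[(wl >= 1604) & (wl <= 1622)].all()


class TestFitPca:
    def test_planar_data_has_two_components(self, rng):
        basis = rng.normal(0, 1, (2, 12))
        X = rng.normal(0, 1, (30, 2)) @ basis
        p = fit_pca(make_labeled(X, ["a"] * 30), used_components=(0, 1))
        assert p.explained_variance_ratio[:2].sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(0, 1, (15, 6))
        p = fit_pca(make_labeled(X, ["a"] * 15), used_components=(0, 1, 2))
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        for i in range(3):
            v = evecs[:, order[i]]
            cos = abs(v @ p.loadings[i])
            assert cos == pytest.approx(1.0, abs=1e-9)
        total = evals.sum()
        np.testing.assert_allclose(
            p.explained_variance_ratio, evals[order[:3]] / total, rtol=1e-9
        )

    def test_duplicated_dataset_same_loadings(self, rng):
        X = rng.normal(0, 1, (12, 5))
        a = fit_pca(make_labeled(X, ["a"] * 12), (0, 1))
        b = fit_pca(make_labeled(np.vstack([X, X]), ["a"] * 24), (0, 1))
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-9)

    def test_component_index_out_of_range(self, rng):
        X = rng.normal(0, 1, (5, 8))
        with pytest.raises(ValueError, match="not available"):
            fit_pca(make_labeled(X, ["a"] * 5), used_components=(4,))


class TestMahalanobis:
    def test_centre_gives_zero(self):
        m = ClassModel("a", np.array([1.0, 2.0]), np.array([1.0]), 1.0, 0.25,
                       "mahalanobis", np.eye(2))
        assert mahalanobis_distance(np.array([1.0, 2.0]), m) == 0.0

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        c = rng.normal(0, 1, 3)
        x = rng.normal(0, 1, 3)
        m = ClassModel("a", c, np.array([1.0]), 1.0, 0.25, "mahalanobis", np.eye(3))
        assert mahalanobis_distance(x, m) == pytest.approx(np.linalg.norm(x - c))

    def test_hand_computed_diagonal_case(self):
        # offset (2, 1) under diag(4, 1): sqrt(4/4 + 1/1) = sqrt(2)
        m = ClassModel("a", np.zeros(2), np.array([1.0]), 1.0, 0.25,
                       "mahalanobis", np.diag([4.0, 1.0]))
        assert mahalanobis_distance(np.array([2.0, 1.0]), m) == pytest.approx(np.sqrt(2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariance_under_invertible_linear_maps(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(0, 1, 3)
        cov = rng.normal(0, 1, (3, 3))
        cov = cov @ cov.T + 0.5 * np.eye(3)
        x = rng.normal(0, 1, 3)
        A = rng.normal(0, 1, (3, 3)) + 2 * np.eye(3)
        m = ClassModel("a", c, np.array([1.0]), 1.0, 0.25, "mahalanobis", cov)
        mt = ClassModel("a", A @ c, np.array([1.0]), 1.0, 0.25,
                        "mahalanobis", A @ cov @ A.T)
        d1 = mahalanobis_distance(x, m)
        d2 = mahalanobis_distance(A @ x, mt)
        assert d2 == pytest.approx(d1, rel=1e-9)


class TestScaleToFirstRange:
    regions = WavelengthRegions([(1000.0, 1006.0), (1020.0, 1030.0)])
    wl = 1000.0 + 2.0 * np.arange(20)

    def test_first_region_maps_to_unit_interval(self, rng):
        x = rng.normal(0.5, 0.2, 20)
        out = scale_to_first_range(x, self.wl, self.regions)
        first = out[:4]
        assert first.min() == 0.0 and first.max() == 1.0

    def test_idempotent(self, rng):
        x = rng.normal(0.5, 0.2, 20)
        once = scale_to_first_range(x, self.wl, self.regions)
        np.testing.assert_allclose(
            scale_to_first_range(once, self.wl, self.regions), once, atol=1e-12
        )

    def test_affine_invariance(self, rng):
        x = rng.normal(0.5, 0.2, 20)
        a = scale_to_first_range(x, self.wl, self.regions)
        b = scale_to_first_range(3.0 * x + 1.7, self.wl, self.regions)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_flat_first_region_rejected(self):
        x = np.ones(20)
        with pytest.raises(ValueError, match="flat"):
            scale_to_first_range(x, self.wl, self.regions)

    def test_single_point_first_region_rejected(self, rng):
        r = WavelengthRegions([(1000.0, 1000.0), (1020.0, 1030.0)])
        with pytest.raises(ValueError, match="two grid points"):
            scale_to_first_range(rng.normal(0, 1, 20), self.wl, r)


class TestHitThreshold:
    def test_hand_oracle(self):
        # sd({1,2,3}) = 1, so D_T = 3 + 0.25 * 1
        assert hit_threshold([1.0, 2.0, 3.0], 0.25) == pytest.approx(3.25)

    def test_q_zero_is_max_hit(self):
        assert hit_threshold([0.5, 2.0, 1.0], 0.0) == 2.0

    def test_q_monotonicity(self):
        hits = [0.3, 1.1, 0.8, 2.0]
        qs = [0.0, 0.1, 0.25, 0.5, 1.0]
        ts = [hit_threshold(hits, q) for q in qs]
        assert all(a <= b for a, b in zip(ts, ts[1:]))

    def test_negative_hits_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            hit_threshold([-1.0, 2.0])


class TestSelectivity:
    def test_contact_case_is_exactly_one(self):
        a = euclid_model("A", [0.0, 0.0], 2.0)
        b = euclid_model("B", [5.0, 0.0], 3.0)
        rep = selectivity([a, b])
        assert rep.pairwise_S[0, 1] == 1.0

    def test_symmetry_is_exact(self, rng):
        models = [
            euclid_model(f"c{i}", rng.normal(0, 3, 4), rng.uniform(0.5, 2))
            for i in range(5)
        ]
        rep = selectivity(models)
        np.testing.assert_array_equal(rep.pairwise_S, rep.pairwise_S.T)
        np.testing.assert_array_equal(rep.pairwise_D, rep.pairwise_D.T)

    def test_ambiguity_groups_are_connected_components(self):
        # chain: A-B overlap, B-C overlap, C far from A; D isolated
        models = [
            euclid_model("A", [0.0], 0.3),
            euclid_model("B", [0.5], 0.3),
            euclid_model("C", [1.0], 0.3),
            euclid_model("D", [10.0], 0.3),
        ]
        rep = selectivity(models)
        assert rep.pairwise_S[0, 2] > 1  # A and C individually separated
        assert rep.ambiguous_groups == (frozenset({"A", "B", "C"}),)

    def test_larger_q_weakly_decreases_selectivity(self, rng):
        X = rng.normal(0, 1, (40, 30)) + 0.2
        origins = ["a"] * 20 + ["b"] * 20
        X[20:, :5] += 1.5
        s = make_labeled(X, origins)
        regions = WavelengthRegions([(1000.0, 1058.0)])
        s_lo = selectivity(fit_class_models(s, regions, "pca_md", q=0.1,
                                            used_components=(0, 1)))
        s_hi = selectivity(fit_class_models(s, regions, "pca_md", q=1.0,
                                            used_components=(0, 1)))
        assert s_hi.pairwise_S[0, 1] <= s_lo.pairwise_S[0, 1]

    def test_needs_two_models(self):
        with pytest.raises(ValueError, match="at least two"):
            selectivity([euclid_model("A", [0.0], 1.0)])


class TestFitClassModels:
    def test_default_q_is_quarter(self, rng):
        X = rng.normal(0, 0.1, (12, 20)) + np.linspace(0.2, 0.8, 20)
        s = make_labeled(X, ["a"] * 6 + ["b"] * 6)
        ms = fit_class_models(s, WavelengthRegions([(1000.0, 1038.0)]),
                              "first_range")
        assert all(m.q == 0.25 for m in ms)

    def test_small_class_rejected(self, rng):
        X = rng.normal(0, 1, (5, 10))
        s = make_labeled(X, ["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_class_models(s, WavelengthRegions([(1000.0, 1018.0)]), "pca_md",
                             used_components=(0,))

    def test_origin_labels_required(self, rng):
        X = rng.normal(0, 1, (6, 10))
        s = SpectraSet(1000 + 2.0 * np.arange(10), X,
                       [f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="origin"):
            fit_class_models(s, WavelengthRegions([(1000.0, 1018.0)]), "pca_md")


class TestClassify:
    @pytest.fixture
    def two_class_models(self, rng):
        X = np.vstack([
            rng.normal(0.0, 0.05, (15, 10)) + np.linspace(0, 1, 10),
            rng.normal(0.0, 0.05, (15, 10)) + np.linspace(1, 0, 10),
        ])
        s = make_labeled(X, ["a"] * 15 + ["b"] * 15)
        return fit_class_models(s, WavelengthRegions([(1000.0, 1018.0)]),
                                "pca_md", used_components=(0, 1))

    def test_class_centre_classified_to_itself(self, two_class_models):
        ms = two_class_models
        centre_spec = ms.pca.mean + ms.models[0].centre @ np.vstack(
            [ms.pca.loadings[i] for i in ms.pca.used_components]
        )
        s = SpectraSet(1000 + 2.0 * np.arange(10), centre_spec[None, :], ["x"])
        out = classify(s, ms)
        assert out.assigned[0] == "a"
        assert out.distance[0] == pytest.approx(0.0, abs=1e-9)
        assert bool(out.within_threshold[0])

    def test_far_sample_is_unknown(self, two_class_models):
        s = SpectraSet(1000 + 2.0 * np.arange(10), np.full((1, 10), 50.0), ["x"])
        out = classify(s, two_class_models)
        assert bool(out.unknown[0])


@pytest.fixture(scope="module")
def study_split(study_data):
    plan = make_split(study_data, "per_origin_count", n_test_per_origin=5, seed=0)
    return plan.apply(study_data)



class TestRunTwoStep:
    def test_designed_ambiguity_and_perfect_identification(self, study_split):
        cal, test = study_split
        res = run_two_step(cal, test)
        assert res.report_step1.ambiguous_groups == (
            frozenset({"CH", "PLD", "ZZ"}),
        )
        # each clustered origin's nearest class overlaps it (S < 1)
        for o in ("CH", "PLD", "ZZ"):
            nearest, s_val = res.report_step1.nearest_class[o]
            assert nearest in {"CH", "PLD", "ZZ"} and s_val < 1
        # every singleton origin is separated in one step
        for o in ("WFD", "QD", "RS", "YT", "LZ", "XP"):
            _, s_val = res.report_step1.nearest_class[o]
            assert s_val > 1
        rep2 = res.reports_step2[frozenset({"CH", "PLD", "ZZ"})]
        assert all(s > 1 for _, s in rep2.nearest_class.values())
        assert res.correct_rate["calibration"] == 1.0
        assert res.correct_rate["test"] == 1.0

    def test_confusion_matrices_diagonal(self, study_split):
        cal, test = study_split
        res = run_two_step(cal, test)
        for role, cm in res.confusion.items():
            common = [c for c in cm.columns if c in cm.index]
            diag = sum(cm.loc[c, c] for c in common)
            assert diag / cm.values.sum() >= 0.99

    def test_single_origin_is_degenerate_but_works(self, rng):
        from nirtrace.simulate import GeneratorConfig, OriginProfile, generate

        prof = [OriginProfile("solo", 30, 5.0, 0.8, (0.3, 1.0, 1.0, 1.0))]
        s = generate(prof, GeneratorConfig(seed=3))
        s = restrict_to_regions(s, WavelengthRegions([nt.WORKING_RANGE]))
        plan = make_split(s, "per_origin_count", n_test_per_origin=5, seed=3)
        cal, test = plan.apply(s)
        res = run_two_step(cal, test)
        assert res.report_step1 is None
        assert (res.assignments.final == "solo").mean() > 0.9
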