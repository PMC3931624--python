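"""PCoA, RDA, permutation tests, Bonferroni and forward axis selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from pvrda import (PCoA, RDA, ForwardAxisSelector, ValidationError,
                   bonferroni, build_design, pcoa, permutation_test, rda,
                   select_axes, single_trait_test)


def frame(arr, prefix="c"):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr,
                        columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestPCoA:
    def test_unit_square_two_unit_eigenvalues(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = squareform(pdist(pts))
        model = PCoA().fit(D)
        lam = model.eigenvalues_
        assert lam[0] == pytest.approx(1.0, abs=1e-8)
        assert lam[1] == pytest.approx(1.0, abs=1e-8)
        assert np.abs(lam[2:]).max() < 1e-8

    def test_all_zero_distances(self):
        model = PCoA().fit(np.zeros((5, 5)))
        assert np.abs(model.eigenvalues_).max() < 1e-12
        assert model.coordinates_.shape[1] == 0

    def test_euclidean_distances_recovered(self, rng):
        X = rng.normal(size=(12, 5))
        D = squareform(pdist(X))
        C = PCoA().fit(D).coordinates_.to_numpy()
        assert np.abs(squareform(pdist(C)) - D).max() < 1e-8

    def test_axis_scaling_and_orthogonality(self, rng):
        X = rng.normal(size=(10, 4))
        D = squareform(pdist(X))
        model = PCoA().fit(D)
        C = model.coordinates_.to_numpy()
        lam = model.eigenvalues_[:C.shape[1]]
        assert np.allclose((C ** 2).sum(axis=0), lam, atol=1e-8)
        assert np.allclose(C.mean(axis=0), 0.0, atol=1e-10)
        gram = C.T @ C
        assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-8

    def test_eigenvalue_sum_equals_gower_trace(self, rng):
        X = rng.normal(size=(9, 3))
        D = squareform(pdist(X))
        model = PCoA().fit(D)
        B = PCoA._gower(D ** 2)
        assert model.eigenvalues_.sum() == pytest.approx(np.trace(B),
                                                         abs=1e-8)

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa
        X = rng.normal(size=(8, 4))
        D = squareform(pdist(X))
        ours = PCoA().fit(D)
        theirs = skbio_pcoa(D, number_of_dimensions=0)
        lam_ref = np.sort(theirs.eigvals.to_numpy())[::-1]
        k = min(len(ours.eigenvalues_), len(lam_ref))
        assert np.allclose(ours.eigenvalues_[:k], lam_ref[:k], atol=1e-8)

    def test_validation(self):
        with pytest.raises(ValidationError):
            PCoA().fit(np.array([[0, 1], [1, 0]]))  # n < 3
        bad = np.zeros((4, 4))
        bad[0, 1] = 1.0  # asymmetric
        with pytest.raises(ValidationError):
            PCoA().fit(bad)

    def test_lingoes_correction_removes_negatives(self):
        # a star-like tree metric is not Euclidean-embeddable
        D = np.array([[0, 1, 1, 1], [1, 0, 2, 2],
                      [1, 2, 0, 2], [1, 2, 2, 0]], dtype=float)
        plain = PCoA().fit(D)
        assert plain.n_negative_eigenvalues_ == 1
        fixed = PCoA(correction="lingoes").fit(D)
        assert fixed.n_negative_eigenvalues_ == 0


class TestRDA:
    def test_single_pair_equals_squared_correlation(self, rng):
        x = rng.normal(size=25)
        y = 1.3 * x + rng.normal(size=25)
        model = rda(frame(y, "y"), frame(x, "x"))
        assert model.explained_fraction_ == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_orthogonal_response_zero_fraction(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0]) - 1 / 3
        model = rda(frame(y, "y"), frame(x, "x"))
        assert model.explained_fraction_ < 1e-10

    def test_design_inside_covariate_span_absorbed(self, rng):
        w = rng.normal(size=20)
        x = 2.0 * w + 1.0   # X lies in span([1, W])
        y = rng.normal(size=20)
        model = rda(frame(y, "y"), frame(x, "x"), covariates=frame(w, "w"))
        assert model.explained_ss_ < 1e-16

    def test_partial_with_no_covariates_is_plain(self, rng):
        Y = frame(rng.normal(size=(15, 4)), "y")
        X = frame(rng.normal(size=(15, 2)), "x")
        a = rda(Y, X)
        b = rda(Y, X, covariates=None)
        assert a.explained_ss_ == b.explained_ss_
        assert a.pseudo_f_ == b.pseudo_f_

    def test_ss_decomposition_exact(self, rng):
        Y = frame(rng.normal(size=(18, 5)), "y")
        X = frame(rng.normal(size=(18, 3)), "x")
        W = frame(rng.normal(size=(18, 2)), "w")
        model = rda(Y, X, covariates=W)
        assert model.explained_ss_ + model.residual_ss_ == pytest.approx(
            model.total_ss_, abs=1e-9)

    def test_matches_reference_implementation(self):
        # expected values computed with vegan::rda / vegan::anova on the
        # identical seed-0 data (constrained proportion and pseudo-F)
        r = np.random.default_rng(0)
        Y = frame(r.normal(size=(14, 5)), "y")
        X = frame(r.normal(size=(14, 2)), "x")
        ours = rda(Y, X)
        assert ours.explained_fraction_ == pytest.approx(0.2286415,
                                                         abs=1e-6)
        assert ours.pseudo_f_ == pytest.approx(1.630277, abs=1e-5)

    def test_duplicated_trait_column_keeps_fraction(self, rng):
        Y = frame(rng.normal(size=(16, 3)), "y")
        X = frame(rng.normal(size=(16, 2)), "x")
        base = rda(Y, X).explained_fraction_
        Y2 = pd.concat([Y, Y.add_suffix("_dup")], axis=1)
        assert rda(Y2, X).explained_fraction_ == pytest.approx(base,
                                                               abs=1e-10)


class TestPermutation:
    def test_noise_free_relationship_minimal_p(self, rng):
        x = rng.normal(size=30)
        res = permutation_test(frame(2 * x, "y"), frame(x, "x"),
                               nperm=199, seed=0)
        assert res.pvalue == pytest.approx(1 / 200)

    def test_joint_relabeling_leaves_f_unchanged(self, rng):
        Y = frame(rng.normal(size=(20, 3)), "y")
        X = frame(rng.normal(size=(20, 2)), "x")
        perm = rng.permutation(20)
        a = rda(Y, X)
        b = rda(Y.iloc[perm].reset_index(drop=True),
                X.iloc[perm].reset_index(drop=True))
        assert a.pseudo_f_ == pytest.approx(b.pseudo_f_, rel=1e-10)

    def test_p_reproducible_under_seed(self, rng):
        Y = frame(rng.normal(size=(25, 2)), "y")
        X = frame(rng.normal(size=(25, 1)), "x")
        p1 = permutation_test(Y, X, nperm=299, seed=11).pvalue
        p2 = permutation_test(Y, X, nperm=299, seed=11).pvalue
        assert p1 == p2

    def test_null_p_distribution_roughly_uniform(self):
        from scipy.stats import kstest
        pvals = []
        for i in range(300):
            r = np.random.default_rng(1000 + i)
            y = frame(r.normal(size=30), "y")
            x = frame(r.normal(size=30), "x")
            pvals.append(permutation_test(y, x, nperm=99,
                                          seed=r).pvalue)
        # p-values live on the grid k/100; KS against uniform is approximate
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_invalid_nperm(self, rng):
        Y = frame(rng.normal(size=(10, 1)), "y")
        with pytest.raises(ValidationError):
            permutation_test(Y, Y, nperm=0)


class TestSingleTrait:
    def test_increasing_trait_positive_sign(self, rng):
        x = np.linspace(0, 1, 24)
        y = (x > 0.5).astype(float)
        res = single_trait_test(pd.Series(y), pd.Series(x), nperm=199,
                                seed=1)
        assert res.sign == 1
        assert res.pvalue == pytest.approx(1 / 200)

    def test_sign_antisymmetric_under_predictor_negation(self, rng):
        x = pd.Series(rng.normal(size=30))
        y = pd.Series((x + rng.normal(scale=0.5, size=30) > 0).astype(float))
        a = single_trait_test(y, x, nperm=99, seed=2)
        b = single_trait_test(y, -x, nperm=99, seed=2)
        assert a.sign == -b.sign

    def test_explained_equals_squared_partial_correlation(self, rng):
        n = 40
        w = rng.normal(size=n)
        x = 0.8 * w + rng.normal(size=n)
        y = 0.5 * x + 0.7 * w + rng.normal(size=n)
        res = single_trait_test(pd.Series(y), pd.Series(x),
                                covariates=frame(w, "w"), nperm=9, seed=3)
        # partial correlation via residuals
        def resid(v, c):
            Z = np.column_stack([np.ones(n), c])
            return v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
        r = np.corrcoef(resid(y, w), resid(x, w))[0, 1]
        assert res.explained_fraction_partial == pytest.approx(r ** 2,
                                                               abs=1e-10)

    def test_factor_predictor_reports_no_sign(self, rng):
        y = pd.Series(rng.integers(0, 2, 24).astype(float))
        f = pd.Series(list("abc") * 8)
        res = single_trait_test(y, f, nperm=99, seed=4)
        assert res.sign is None

    def test_missing_species_dropped(self, rng):
        y = pd.Series([0, 1, np.nan, 1, 0, 1, 0, 0],
                      index=list("ABCDEFGH"))
        x = pd.Series(rng.normal(size=8), index=list("ABCDEFGH"))
        res = single_trait_test(y, x, nperm=49, seed=5)
        assert res.n_used == 7
        assert res.dropped_species == ("C",)

    def test_zero_variance_trait_flagged_excluded(self, rng):
        y = pd.Series(np.ones(10))
        x = pd.Series(rng.normal(size=10))
        res = single_trait_test(y, x, nperm=49, seed=6)
        assert res.excluded


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni([0.004], m=15)[0] == pytest.approx(0.06)
        assert bonferroni([0.5], m=10)[0] == 1.0

    def test_families(self):
        adj = bonferroni([0.01, 0.01, 0.01], families=["a", "a", "b"])
        assert np.allclose(adj, [0.02, 0.02, 0.01])

    def test_monotone_fewer_significant(self, rng):
        p = rng.uniform(size=50)
        adj = bonferroni(p)
        assert (adj <= 0.05).sum() <= (p <= 0.05).sum()


class TestForwardSelection:
    def test_trait_equal_to_axis_selected_first(self, rng):
        X = rng.normal(size=(20, 6))
        D = squareform(pdist(X))
        model = PCoA().fit(D)
        axis1 = model.coordinates_[["PCo1"]]
        traits = pd.concat([axis1] * 3, axis=1)
        traits.columns = ["t1", "t2", "t3"]
        sel = select_axes(model, traits, alpha=0.05, nperm=199, seed=0)
        assert sel.axes[0] == "PCo1"
        assert sel.pvalues[0] == pytest.approx(1 / 200)
        assert sel.cumulative_r2[0] == pytest.approx(1.0, abs=1e-9)

    def test_alpha_zero_selects_nothing(self, rng):
        X = rng.normal(size=(12, 4))
        D = squareform(pdist(X))
        model = PCoA().fit(D)
        traits = frame(rng.normal(size=(12, 5)), "t")
        traits.index = model.coordinates_.index
        sel = select_axes(model, traits, alpha=0.0, nperm=99, seed=0)
        assert sel.axes == ()

    def test_selection_invariant_to_row_permutation(self, rng):
        X = rng.normal(size=(16, 5))
        D = squareform(pdist(X))
        coords = PCoA().fit(D).coordinates_
        traits = frame(rng.normal(size=(16, 6)), "t")
        traits.index = coords.index
        sel1 = select_axes(coords, traits, alpha=0.3, nperm=99, seed=7)
        perm = rng.permutation(16)
        sel2 = select_axes(coords.iloc[perm], traits.iloc[perm],
                           alpha=0.3, nperm=99, seed=7)
        assert sel1.axes == sel2.axes
        assert sel1.pvalues == sel2.pvalues

    def test_noise_first_step_type_one_calibrated(self):
        # with pure-noise traits the first admission should happen in
        # about alpha of replicate runs
        hits = 0
        R = 120
        for i in range(R):
            r = np.random.default_rng(3000 + i)
            X = r.normal(size=(15, 4))
            D = squareform(pdist(X))
            coords = PCoA().fit(D).coordinates_
            traits = frame(r.normal(size=(15, 3)), "t")
            traits.index = coords.index
            sel = select_axes(coords, traits, alpha=0.05, nperm=99,
                              seed=int(r.integers(2**31)))
            hits += len(sel.axes) > 0
        # binomial 99.9% band around 0.05 for R=120 runs, adjusting for
        # selection of the best axis (mild multiplicity inflation)
        assert hits / R < 0.35

    def test_empty_traits_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        coords = PCoA().fit(squareform(pdist(X))).coordinates_
        with pytest.raises(ValidationError):
            ForwardAxisSelector().fit(coords, pd.DataFrame(index=coords.index))


class TestBuildDesign:
    def test_factor_full_indicator_centred(self):
        p = pd.DataFrame({"habitat": ["a", "b", "a", "c"],
                          "elevation": [10.0, 20.0, 30.0, 40.0]})
        X = build_design(p)
        hab_cols = [c for c in X.columns if c.startswith("habitat")]
        assert len(hab_cols) == 3            # full coding, no reference drop
        assert np.allclose(X.mean(), 0.0)    # everything centred
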