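import numpy as np
import pandas as pd
import pytest

from zetascreen import io_preprocess as iop
from zetascreen import zeta_core as zc

from conftest import brute_force_zeta


def _screen(values, classes, col_ids=None):
    arr = np.asarray(values, dtype=float)
    rows = [f"r{i}" for i in range(arr.shape[0])]
    cols = col_ids or [f"c{j}" for j in range(arr.shape[1])]
    m = iop.ScreenMatrix(pd.DataFrame(arr, index=rows, columns=cols))
    ann = pd.Series(classes, index=rows)
    return m, ann


class TestZTransform:
    def test_hand_computed_column(self):
        # column [1,2,3] with negatives {1,3}: mu=2, sigma=sqrt(2) (sample sd)
        m, ann = _screen(
            [[1.0, 0.0], [2.0, 1.0], [3.0, 2.0]],
            ["negative_control", "sample", "negative_control"],
        )
        zm = zc.z_transform(m, ann)
        np.testing.assert_allclose(
            zm.z["c0"].to_numpy(), [-0.70710678, 0.0, 0.70710678], atol=1e-8
        )

    def test_negative_controls_self_normalize(self, small_screen, small_screen_zm):
        neg = small_screen_zm.z.loc[small_screen.annotation == "negative_control"]
        assert np.allclose(neg.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(neg.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_negative_column_dropped_with_warning(self):
        m, ann = _screen(
            [[1.0, 5.0], [1.0, 6.0], [2.0, 7.0]],
            ["negative_control", "negative_control", "sample"],
        )
        with pytest.warns(UserWarning, match="zero negative-control SD"):
            zm = zc.z_transform(m, ann)
        assert list(zm.z.columns) == ["c1"]

    def test_single_negative_control_errors(self):
        m, ann = _screen([[1.0], [2.0]], ["negative_control", "sample"])
        with pytest.raises(ValueError, match="negative-control"):
            zc.z_transform(m, ann)


def _zmatrix(Z):
    Z = np.asarray(Z, dtype=float)
    rows = [f"g{i}" for i in range(Z.shape[0])]
    cols = [f"c{j}" for j in range(Z.shape[1])]
    return zc.ZMatrix(
        z=pd.DataFrame(Z, index=rows, columns=cols),
        mu=pd.Series(0.0, index=cols),
        sigma=pd.Series(1.0, index=cols),
    )


class TestZetaCurves:
    def test_sub_threshold_rows_are_flat_zero(self):
        rng = np.random.default_rng(0)
        Z = np.clip(rng.normal(0, 0.5, size=(5, 50)), -1.9, 1.9)
        Z[0, :] = 8.0  # a responsive row to open up the cutoff range
        zm = _zmatrix(Z)
        for d in ("positive", "negative"):
            curve = zc.build_zeta_curves(zm, d)
            assert np.all(curve.P.to_numpy()[1:] == 0.0)

    def test_survival_fraction_counts_beyond_cutoff(self):
        Z = np.zeros((1, 10))
        Z[0, :3] = 5.0
        Z = np.vstack([Z, np.full((1, 10), 6.0)])  # second row widens range
        curve = zc.build_zeta_curves(_zmatrix(Z), "positive")
        m = np.searchsorted(curve.cutoffs, 4.0)
        assert curve.P.iloc[0, m] == pytest.approx(0.3)

    def test_monotone_non_increasing_in_cutoff(self, small_screen_zm):
        for d in ("positive", "negative"):
            P = zc.build_zeta_curves(small_screen_zm, d).P.to_numpy()
            assert (np.diff(P, axis=1) <= 1e-12).all()

    def test_range_below_noise_threshold_errors(self):
        Z = np.full((4, 30), 0.5)
        with pytest.raises(ValueError, match="noise threshold"):
            zc.build_zeta_curves(_zmatrix(Z), "positive")


def _band_curves(level, n_curves, cutoffs, jitter, seed):
    rng = np.random.default_rng(seed)
    P = np.clip(level + rng.normal(0, jitter, size=(n_curves, cutoffs.size)), 0, 1)
    return zc.ZetaCurve(
        direction="positive",
        cutoffs=cutoffs,
        step=float(cutoffs[1] - cutoffs[0]),
        P=pd.DataFrame(P, index=[f"k{seed}_{i}" for i in range(n_curves)]),
    )


class TestSvmBoundary:
    cutoffs = np.linspace(2, 10, 101)

    def test_boundary_lies_between_separable_bands(self):
        pos = _band_curves(0.5, 8, self.cutoffs, 0.01, 1)
        neg = _band_curves(0.1, 8, self.cutoffs, 0.01, 2)
        b = zc.fit_svm_boundary(pos, neg, seed=0)
        assert (b.S > 0.1).all() and (b.S < 0.5).all()

    def test_training_accuracy_high_on_separable_controls(self):
        pos = _band_curves(0.6, 10, self.cutoffs, 0.02, 3)
        neg = _band_curves(0.05, 10, self.cutoffs, 0.02, 4)
        b = zc.fit_svm_boundary(pos, neg, seed=0)
        assert b.model_params["train_accuracy"] >= 0.95

    def test_identical_classes_warn(self):
        pos = _band_curves(0.3, 6, self.cutoffs, 0.0, 5)
        neg = _band_curves(0.3, 6, self.cutoffs, 0.0, 5)
        with pytest.warns(UserWarning, match="poorly separated"):
            zc.fit_svm_boundary(pos, neg, seed=0)

    def test_too_few_control_curves_errors(self):
        pos = _band_curves(0.5, 3, self.cutoffs, 0.01, 6)
        neg = _band_curves(0.1, 8, self.cutoffs, 0.01, 7)
        with pytest.raises(ValueError, match="5 control curves"):
            zc.fit_svm_boundary(pos, neg, seed=0)


class TestZetaScore:
    def test_curve_on_boundary_scores_zero(self):
        cutoffs = np.linspace(2, 12, 101)
        curve = _band_curves(0.4, 3, cutoffs, 0.0, 8)
        boundary = zc.SVMBoundary(S=np.full(101, 0.4))
        assert np.allclose(zc.zeta_score(curve, boundary, weighted=False), 0.0)

    def test_flat_half_curve_rectangle_area(self):
        # P = 0.5 over [2, 12] in 100 bins of step 0.1: zeta = 100 * 0.5 * 0.1 = 5
        cutoffs = np.linspace(2, 12, 101)
        curve = _band_curves(0.5, 1, cutoffs, 0.0, 9)
        z = zc.zeta_score(curve, boundary=None, weighted=False)
        assert z.iloc[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("weighted", [False, True])
    @pytest.mark.parametrize("use_svm", [False, True])
    def test_matches_scalar_brute_force(self, weighted, use_svm):
        rng = np.random.default_rng(10)
        cutoffs = np.linspace(2, 9, 101)
        step = cutoffs[1] - cutoffs[0]
        for _ in range(25):
            P = np.sort(rng.random(101))[::-1]
            S = np.sort(rng.random(101))[::-1] * 0.3
            curve = zc.ZetaCurve(
                "positive", cutoffs, float(step), pd.DataFrame(P[None, :], index=["g"])
            )
            boundary = zc.SVMBoundary(S=S) if use_svm else None
            got = zc.zeta_score(curve, boundary, weighted=weighted).iloc[0]
            want = brute_force_zeta(P, S, cutoffs, step, weighted, use_svm)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-14)

    def test_svm_subtraction_never_increases_score(self, small_screen_scores):
        scores, details = small_screen_scores
        for d in ("positive", "negative"):
            curve = details["curves"][d]
            with_svm = zc.zeta_score(curve, details["boundaries"][d])
            without = zc.zeta_score(curve, None)
            assert (without + 1e-12 >= with_svm).all()
            assert (with_svm >= 0).all()

    def test_invariant_under_readout_permutation(self, small_screen):
        rng = np.random.default_rng(1)
        m, ann = small_screen.matrix, small_screen.annotation
        zm = zc.z_transform(m, ann)
        perm_cols = rng.permutation(m.col_ids)
        m2 = iop.ScreenMatrix(m.values[perm_cols])
        zm2 = zc.z_transform(m2, ann)
        for d in ("positive", "negative"):
            a = zc.zeta_score(zc.build_zeta_curves(zm, d), None)
            b = zc.zeta_score(zc.build_zeta_curves(zm2, d), None)
            pd.testing.assert_series_equal(a, b)

    def test_extra_responsive_readout_never_decreases_zeta(self):
        rng = np.random.default_rng(12)
        Z = rng.normal(0, 1, size=(30, 40))
        Z[0] = rng.normal(0, 3, size=40)
        zm = _zmatrix(Z)
        curve = zc.build_zeta_curves(zm, "positive")
        base = zc.zeta_score(curve, None)
        # append a readout beyond every cutoff for every row
        Z2 = np.column_stack([Z, np.full(30, np.abs(Z).max() + 1)])
        curve2 = zc.build_zeta_curves(_zmatrix(Z2), "positive")
        boosted = zc.zeta_score(curve2, None)
        assert (boosted.to_numpy() + 1e-9 >= base.to_numpy()).all()


class TestCombineDirections:
    def test_sum_and_identity(self):
        pos = pd.Series([1.2, 0.0], index=["a", "b"])
        neg = pd.Series([0.8, 0.0], index=["a", "b"])
        combined = zc.combine_directions(pos, neg)
        assert combined["a"] == pytest.approx(2.0)
        assert combined["b"] == pytest.approx(pos["b"])

    def test_separate_mode_returns_both_columns(self):
        pos = pd.Series([1.0], index=["a"])
        neg = pd.Series([2.0], index=["a"])
        out = zc.combine_directions(pos, neg, combine=False)
        assert list(out.columns) == ["zeta_pos", "zeta_neg"]

    def test_default_output_is_combined(self):
        import inspect

        sig = inspect.signature(zc.combine_directions)
        assert sig.parameters["combine"].default is True


class TestRegulatorRecovery:
    def test_regulators_outscore_non_expressors(self, small_screen, small_screen_scores):
        """Planted regulators must separate cleanly from pure-noise genes."""
        scores, _ = small_screen_scores
        truth = small_screen.truth
        reg = scores[truth.index[truth["is_regulator"]]]
        ne = scores[small_screen.annotation == "non_expressor"]
        assert reg.median() > ne.quantile(0.95)
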