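import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from neurocoloc.hlm import (
    ModelFrame,
    build_edge_model_frame,
    build_volume_model_frame,
    contrast_one_vs_two,
    fit_reml,
    reml_loglik,
    shuffle_null,
    threshold_scan,
)
from neurocoloc.normative import AbnormalityMask, ZTable
from tests.helpers import (
    intercept_only_frame,
    naive_reml_loglik,
    simulate_edge_frame,
    simulate_volume_frame,
)


def _mask(df, kind, frame="anatomical", tau=-1.96):
    return AbnormalityMask(df, threshold=tau, kind=kind, frame=frame)


class TestBuildEdgeFrame:
    def _inputs(self):
        edge_cols = ["a--b", "a--c", "b--c"]
        ez = ZTable(pd.DataFrame([[0.1, -0.2, 0.3]], index=["p1"], columns=edge_cols),
                    kind="edge")
        vm = pd.DataFrame([[False, True, False]], index=["p1"], columns=["a", "b", "c"])
        return ez, _mask(vm, "node")

    def test_indicator_coding(self):
        ez, vm = self._inputs()
        fr = build_edge_model_frame(ez, vm)
        # a--b: one abnormal (b); a--c: none; b--c: one abnormal
        np.testing.assert_array_equal(fr.X[:, 1], [1, 0, 1])
        np.testing.assert_array_equal(fr.X[:, 2], [0, 0, 0])

    def test_both_abnormal(self):
        ez, _ = self._inputs()
        vm = _mask(pd.DataFrame([[True, True, False]], index=["p1"],
                                columns=["a", "b", "c"]), "node")
        fr = build_edge_model_frame(ez, vm)
        np.testing.assert_array_equal(fr.X[:, 1], [0, 1, 1])
        np.testing.assert_array_equal(fr.X[:, 2], [1, 0, 0])

    def test_counts_partition(self):
        fr = simulate_edge_frame(0, n_subjects=5, n_edges=30)
        counts = fr.category_counts()
        assert sum(counts.values()) == fr.n_rows == 5 * 30

    def test_missing_region_rejected(self):
        ez, _ = self._inputs()
        vm = _mask(pd.DataFrame([[True]], index=["p1"], columns=["a"]), "node")
        with pytest.raises(ValueError, match="absent"):
            build_edge_model_frame(ez, vm)

    def test_frame_mismatch_rejected(self):
        ez, vm = self._inputs()
        vm.frame = "ipsicontra"
        with pytest.raises(ValueError, match="frames differ"):
            build_edge_model_frame(ez, vm)


class TestBuildVolumeFrame:
    def test_mean_endpoint_response(self):
        vz = ZTable(pd.DataFrame([[-2.0, 0.0]], index=["p1"], columns=["a", "b"]),
                    kind="node")
        em = _mask(pd.DataFrame([[True]], index=["p1"], columns=["a--b"]), "edge")
        fr = build_volume_model_frame(vz, em)
        assert fr.y[0] == pytest.approx(-1.0)
        assert fr.X[0, 1] == 1.0

    def test_all_normal_reduces_to_intercept(self):
        vz = ZTable(pd.DataFrame([[-2.0, 0.0, 1.0]], index=["p1"],
                                 columns=["a", "b", "c"]), kind="node")
        em = _mask(pd.DataFrame([[False, False]], index=["p1"],
                                columns=["a--b", "b--c"]), "edge")
        fr = build_volume_model_frame(vz, em)
        assert not fr.X[:, 1].any()
        fit = fit_reml(fr)
        assert "edge_abnormal" in fit.dropped
        assert np.isnan(fit.beta["edge_abnormal"])


class TestFitREML:
    def test_near_noiseless_recovery(self):
        rng = np.random.default_rng(3)
        fr = simulate_edge_frame(3, n_subjects=20, n_edges=50,
                                 alpha=-0.4, beta=-0.1, gamma=-0.2,
                                 sd_u=0.0, sd_v=0.0, sd_w=0.0, sd_e=1e-7)
        fit = fit_reml(fr)
        assert fit.beta["intercept"] == pytest.approx(-0.4, abs=1e-6)
        assert fit.beta["one_abnormal"] == pytest.approx(-0.1, abs=1e-6)
        assert fit.beta["two_abnormal"] == pytest.approx(-0.2, abs=1e-6)
        assert np.all(np.diag(fit.D.to_numpy()) < 1e-10)

    def test_balanced_anova_equivalence(self):
        """Balanced random-intercept REML equals closed-form ANOVA estimators."""
        rng = np.random.default_rng(7)
        K, m = 10, 20
        groups = [2.0 + rng.normal(0, 0.8) + rng.normal(0, 1.0, m) for _ in range(K)]
        fr = intercept_only_frame(groups)
        fit = fit_reml(fr)
        y = np.array(groups)
        group_means = y.mean(axis=1)
        msb = m * group_means.var(ddof=1)
        mse = ((y - group_means[:, None]) ** 2).sum() / (K * (m - 1))
        assert fit.sigma2 == pytest.approx(mse, abs=1e-6)
        assert fit.D.iloc[0, 0] == pytest.approx((msb - mse) / m, abs=1e-6)

    def test_matches_lme4(self, tmp_path):
        """Independent oracle: lme4's lmer on the identical frame."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        fr = simulate_edge_frame(42, n_subjects=30, n_edges=40)
        fit = fit_reml(fr)
        df = pd.DataFrame({"y": fr.y, "v1": fr.X[:, 1], "v2": fr.X[:, 2],
                           "subj": fr.subject})
        csv = tmp_path / "frame.csv"
        df.to_csv(csv, index=False)
        rcode = (
            f'd <- read.csv("{csv}"); suppressMessages(library(lme4)); '
            'm <- lmer(y ~ v1 + v2 + (1 + v1 + v2 | subj), data=d, REML=TRUE); '
            'cat(fixef(m), sqrt(diag(vcov(m))), sigma(m)^2, sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        vals = [float(v) for v in out.stdout.split()]
        np.testing.assert_allclose(fit.beta.to_numpy(), vals[:3], atol=5e-4)
        np.testing.assert_allclose(fit.se.to_numpy(), vals[3:6], atol=5e-4)
        assert fit.sigma2 == pytest.approx(vals[6], abs=1e-4)

    def test_criterion_beats_random_points(self):
        fr = simulate_edge_frame(5, n_subjects=12, n_edges=15)
        fit = fit_reml(fr)
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = rng.normal(0, 1, fit.theta.shape)
            assert fit.loglik >= reml_loglik(fr, theta) - 1e-6

    def test_profiled_criterion_matches_dense_oracle(self):
        fr = simulate_edge_frame(6, n_subjects=8, n_edges=10)
        fit = fit_reml(fr)
        from neurocoloc.hlm import _lam_from_theta

        Lam = _lam_from_theta(fit.theta, 3)
        oracle = naive_reml_loglik(fr, Lam, fit.sigma2)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_row_reordering(self):
        fr = simulate_edge_frame(8, n_subjects=10, n_edges=12)
        rng = np.random.default_rng(1)
        perm = rng.permutation(fr.n_rows)
        fr2 = ModelFrame(fr.y[perm], fr.X[perm], fr.subject[perm],
                         fr.subject_ids, fr.predictor_names, fr.direction)
        f1, f2 = fit_reml(fr), fit_reml(fr2)
        np.testing.assert_allclose(f1.beta.to_numpy(), f2.beta.to_numpy(), atol=1e-6)

    def test_single_subject_gls_fallback(self):
        fr = simulate_edge_frame(9, n_subjects=1, n_edges=50)
        with pytest.warns(UserWarning, match="single subject"):
            fit = fit_reml(fr)
        assert fit.converged

    def test_random_effects_shape(self):
        fr = simulate_edge_frame(10, n_subjects=7, n_edges=20)
        fit = fit_reml(fr)
        assert fit.random_effects.shape == (7, 3)
        # BLUPs are shrunken deviations and average out near zero
        assert abs(fit.random_effects.mean().mean()) < 0.2


class TestContrast:
    def test_requires_edge_direction(self):
        fr = simulate_volume_frame(0, n_subjects=5, n_edges=10)
        fit = fit_reml(fr)
        with pytest.raises(ValueError, match="edge-direction"):
            contrast_one_vs_two(fit)

    def test_zero_variance_boundary_gives_p_one(self):
        fr = simulate_edge_frame(11, n_subjects=10, n_edges=40,
                                 alpha=1.0, beta=2.0, gamma=2.0,
                                 sd_u=0, sd_v=0, sd_w=0, sd_e=0.0)
        res = contrast_one_vs_two(fit_reml(fr))
        assert res.p_wald == 1.0

    def test_planted_difference_detected(self):
        fr = simulate_edge_frame(12, n_subjects=100, n_edges=200,
                                 beta=-0.45, gamma=-0.95)
        res = contrast_one_vs_two(fit_reml(fr), satterthwaite=True)
        assert res.estimate < 0
        assert res.p_wald < 0.05
        assert res.p_satterthwaite < 0.05


class TestShuffleNull:
    def test_multiset_preserved_per_subject(self):
        fr = simulate_edge_frame(13, n_subjects=6, n_edges=25)
        sh = shuffle_null(fr, seed=4)
        for k in range(6):
            rows = fr.subject == k
            assert sorted(fr.y[rows]) == pytest.approx(sorted(sh.y[rows]))
        np.testing.assert_array_equal(fr.X, sh.X)

    def test_deterministic(self):
        fr = simulate_edge_frame(14, n_subjects=4, n_edges=10)
        a, b = shuffle_null(fr, seed=9), shuffle_null(fr, seed=9)
        np.testing.assert_array_equal(a.y, b.y)

    def test_null_estimates_near_zero(self):
        fr = simulate_edge_frame(15, n_subjects=60, n_edges=100)
        fit = fit_reml(shuffle_null(fr, seed=1))
        for name in ("one_abnormal", "two_abnormal"):
            assert abs(fit.beta[name]) < 3 * fit.se[name] + 0.05


class TestThresholdScan:
    def _tables(self, seed=0, n_subj=12, n_regions=8):
        rng = np.random.default_rng(seed)
        regions = [f"r{i}" for i in range(n_regions)]
        edges = [f"r{i}--r{j}" for i in range(n_regions) for j in range(i + 1, n_regions)]
        ids = [f"p{i}" for i in range(n_subj)]
        vz = ZTable(pd.DataFrame(rng.normal(-0.5, 1, (n_subj, n_regions)),
                                 index=ids, columns=regions), kind="node")
        ez = ZTable(pd.DataFrame(rng.normal(-0.3, 1, (n_subj, len(edges))),
                                 index=ids, columns=edges), kind="edge")
        return vz, ez

    def test_sixteen_point_grid(self):
        vz, ez = self._tables()
        taus = np.round(np.arange(-1.0, -2.51, -0.1), 10)
        assert len(taus) == 16
        out = threshold_scan(ez, vz, taus, direction="edge")
        assert len(out) == 16

    def test_counts_monotone_in_tau(self):
        vz, ez = self._tables(seed=1)
        taus = [-1.0, -1.5, -2.0, -2.5]
        out = threshold_scan(ez, vz, taus, direction="edge")
        ones = out["count_one_abnormal"].to_numpy()
        twos = out["count_two_abnormal"].to_numpy()
        assert (np.diff(ones + twos) <= 0).all()
        assert (np.diff(twos) <= 0).all()

    def test_volume_direction_runs(self):
        vz, ez = self._tables(seed=2)
        out = threshold_scan(ez, vz, [-1.3, -1.96], direction="volume")
        assert {"est_intercept", "est_edge_abnormal"} <= set(out.columns)
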