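import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocoloc.normative import (
    DEFAULT_COLOC_THRESHOLD,
    DEFAULT_NODE_THRESHOLD,
    ZTable,
    fit_normative,
    flip_to_anatomical,
    flip_to_ipsicontra,
    percentile_threshold,
    threshold_abnormal,
    zscore,
)
from tests.conftest import make_subjects


def control_data(n=120, f=10, seed=0, outlier_frac=0.0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 60, n)
    sex = rng.integers(0, 2, n)
    icv = rng.normal(0, 1, n)
    cov = pd.DataFrame({"age": age, "sex": sex, "icv": icv},
                       index=[f"s{i}" for i in range(n)])
    slopes = rng.uniform(-0.05, 0.05, (3, f))
    intercept = rng.uniform(1, 3, f)
    X = cov.to_numpy()
    y = intercept[None, :] + X @ slopes + rng.normal(0, 1, (n, f))
    if outlier_frac > 0:
        n_out = int(outlier_frac * n)
        rows = rng.choice(n, n_out, replace=False)
        y[rows] += rng.choice([-10.0, 10.0], size=(n_out, f))
    feats = pd.DataFrame(y, columns=[f"f{i}" for i in range(f)], index=cov.index)
    return feats, cov, intercept, slopes


class TestThresholdConstants:
    def test_node_threshold(self):
        assert percentile_threshold(0.025, 2) == -1.96
        assert DEFAULT_NODE_THRESHOLD == -1.96

    def test_coloc_threshold(self):
        assert percentile_threshold(0.05, 3) == -1.645
        assert DEFAULT_COLOC_THRESHOLD == -1.645


class TestFitNormative:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(1)
        n, f = 50, 4
        cov = pd.DataFrame({"age": rng.uniform(20, 60, n), "sex": rng.integers(0, 2, n)})
        slopes = np.array([[0.5, -0.2, 0.1, 0.0], [1.0, 0.0, -1.0, 2.0]])
        y = 3.0 + cov.to_numpy() @ slopes
        y += rng.normal(0, 1e-9, y.shape)  # keep residual scale positive
        feats = pd.DataFrame(y, columns=list("abcd"))
        model = fit_normative(feats, cov)
        assert np.allclose(model.coef.loc["age"], slopes[0], atol=1e-6)
        assert np.allclose(model.coef.loc["sex"], slopes[1], atol=1e-6)

    def test_robust_to_gross_outliers(self):
        feats, cov, _, slopes = control_data(n=300, f=8, seed=2, outlier_frac=0.10)
        model = fit_normative(feats, cov)
        X = np.column_stack([np.ones(len(cov)), cov.to_numpy()])
        ols = np.linalg.lstsq(X, feats.to_numpy(), rcond=None)[0]
        err_huber = np.abs(model.coef.to_numpy()[1:] - slopes)
        err_ols = np.abs(ols[1:] - slopes)
        # robust fit beats OLS on average under 10% +-10 sigma contamination
        assert err_huber.mean() < err_ols.mean()
        assert err_huber.mean() < 0.1

    def test_positive_sigma(self):
        feats, cov, *_ = control_data(seed=3)
        model = fit_normative(feats, cov)
        assert (model.sigma > 0).all()

    def test_too_few_controls_rejected(self):
        feats, cov, *_ = control_data(n=10, seed=4)
        with pytest.raises(ValueError, match="at least"):
            fit_normative(feats, cov)

    def test_matches_statsmodels_rlm(self):
        """Independent oracle: statsmodels RLM with the same Huber tuning."""
        import statsmodels.api as sm

        feats, cov, _, slopes = control_data(n=200, f=5, seed=12, outlier_frac=0.05)
        model = fit_normative(feats, cov)
        X = sm.add_constant(cov.to_numpy())
        for j, c in enumerate(feats.columns):
            rlm = sm.RLM(feats[c].to_numpy(), X,
                         M=sm.robust.norms.HuberT(t=1.345)).fit()
            np.testing.assert_allclose(
                model.coef[c].to_numpy(), rlm.params, atol=0.02
            )

    def test_rank_deficient_rejected(self):
        feats, cov, *_ = control_data(seed=5)
        cov["age2"] = cov["age"]
        with pytest.raises(ValueError, match="rank"):
            fit_normative(feats, cov)


class TestZScore:
    def test_zero_at_prediction(self):
        feats, cov, *_ = control_data(seed=6)
        model = fit_normative(feats, cov)
        pred = model.predict(cov.iloc[[0]])
        z = zscore(pred, cov.iloc[[0]], model, kind="node")
        assert np.allclose(z.values.to_numpy(), 0.0, atol=1e-12)

    def test_linearity(self):
        feats, cov, *_ = control_data(seed=7)
        model = fit_normative(feats, cov)
        z1 = zscore(feats, cov, model, kind="node")
        bumped = feats.copy()
        bumped.iloc[:, 0] += 2.0 * model.sigma.iloc[0]
        z2 = zscore(bumped, cov, model, kind="node")
        np.testing.assert_allclose(
            z2.values.iloc[:, 0] - z1.values.iloc[:, 0], 2.0, atol=1e-10
        )

    def test_held_out_calibration(self):
        # n=400 held out: the (-0.15, 0.15) per-feature mean band is ~3 SEs
        feats, cov, *_ = control_data(n=800, f=20, seed=2)
        fit_rows = feats.index[:400]
        test_rows = feats.index[400:]
        model = fit_normative(feats.loc[fit_rows], cov.loc[fit_rows])
        z = zscore(feats.loc[test_rows], cov.loc[test_rows], model, kind="node")
        means = z.values.mean(axis=0)
        sds = z.values.std(axis=0, ddof=1)
        assert means.between(-0.15, 0.15).all()
        assert sds.between(0.85, 1.15).all()

    def test_missing_covariate_rejected(self):
        feats, cov, *_ = control_data(seed=9)
        model = fit_normative(feats, cov)
        with pytest.raises(ValueError, match="missing covariate"):
            zscore(feats, cov.drop(columns=["age"]), model, kind="node")


class TestThresholdAbnormal:
    def test_control_rates(self):
        rng = np.random.default_rng(10)
        z = ZTable(pd.DataFrame(rng.normal(size=(2000, 50))), kind="node")
        for tau, expected in ((-1.96, 0.025), (-1.645, 0.05)):
            frac = threshold_abnormal(z, tau).values.to_numpy().mean()
            se = np.sqrt(expected * (1 - expected) / z.values.size)
            assert abs(frac - expected) < 3 * se

    def test_zero_z_empty_mask(self):
        z = ZTable(pd.DataFrame(np.zeros((3, 4))), kind="node")
        assert not threshold_abnormal(z, -1.0).values.to_numpy().any()

    def test_positive_tau_rejected(self):
        z = ZTable(pd.DataFrame(np.zeros((2, 2))), kind="node")
        with pytest.raises(ValueError, match="negative"):
            threshold_abnormal(z, 1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6),
           st.floats(-2.5, -0.5), st.floats(-2.5, -0.5))
    def test_monotone_in_tau(self, seed, t1, t2):
        rng = np.random.default_rng(seed)
        z = ZTable(pd.DataFrame(rng.normal(size=(5, 8))), kind="node")
        lo, hi = min(t1, t2), max(t1, t2)
        m_lo = threshold_abnormal(z, lo).values.to_numpy()
        m_hi = threshold_abnormal(z, hi).values.to_numpy()
        assert (m_lo <= m_hi).all()


class TestFlip:
    def _node_ztable(self, toy_parcellation, subjects, rng):
        cols = toy_parcellation.names
        vals = rng.normal(size=(len(subjects), len(cols)))
        return ZTable(
            pd.DataFrame(vals, index=subjects["subject_id"], columns=cols), kind="node"
        )

    def test_ltle_values_unchanged(self, toy_parcellation, rng):
        subjects = make_subjects(1, 1, lateralities=["L"])
        z = self._node_ztable(toy_parcellation, subjects, rng)
        out = flip_to_ipsicontra(z, subjects, toy_parcellation)
        assert out.frame == "ipsicontra"
        np.testing.assert_array_equal(out.values.to_numpy(), z.values.to_numpy())
        assert list(out.values.columns)[:3] == ["ipsi_hippocampus", "ipsi_thalamus", "ipsi_insula"]

    def test_rtle_relabel_semantics(self, toy_parcellation, rng):
        subjects = make_subjects(0, 1, lateralities=["R"])
        z = self._node_ztable(toy_parcellation, subjects, rng)
        z.values.loc[:, "rh_hippocampus"] = -3.0
        out = flip_to_ipsicontra(z, subjects, toy_parcellation)
        assert out.values.loc[subjects["subject_id"][0], "ipsi_hippocampus"] == -3.0

    def test_involution_nodes(self, toy_parcellation, rng):
        subjects = make_subjects(2, 4)
        z = self._node_ztable(toy_parcellation, subjects, rng)
        out = flip_to_anatomical(
            flip_to_ipsicontra(z, subjects, toy_parcellation), subjects, toy_parcellation
        )
        np.testing.assert_allclose(out.values.to_numpy(), z.values.to_numpy())
        assert list(out.values.columns) == list(z.values.columns)

    def test_involution_edges(self, toy_parcellation, toy_edge_index, rng):
        subjects = make_subjects(2, 4)
        vals = rng.normal(size=(len(subjects), toy_edge_index.n_edges))
        z = ZTable(
            pd.DataFrame(vals, index=subjects["subject_id"], columns=toy_edge_index.names),
            kind="edge",
        )
        ic = flip_to_ipsicontra(z, subjects, toy_parcellation, toy_edge_index)
        assert ic.values.shape == z.values.shape  # complete graph is mirror-symmetric
        back = flip_to_anatomical(ic, subjects, toy_parcellation, toy_edge_index)
        np.testing.assert_allclose(
            back.values[z.values.columns].to_numpy(), z.values.to_numpy()
        )

    def test_unmirrored_edges_dropped(self, toy_parcellation, rng):
        from neurocoloc.parcellation import EdgeIndex

        # lh_hippocampus-lh_thalamus has a mirror; lh_hippocampus-rh_thalamus's
        # mirror (lh_thalamus-rh_hippocampus) is absent
        ei = EdgeIndex(toy_parcellation, [(0, 1), (3, 4), (0, 4)])
        subjects = make_subjects(1, 1)
        vals = rng.normal(size=(2, ei.n_edges))
        z = ZTable(pd.DataFrame(vals, index=subjects["subject_id"], columns=ei.names),
                   kind="edge")
        out = flip_to_ipsicontra(z, subjects, toy_parcellation, ei)
        assert out.values.shape[1] == 2

    def test_patient_without_laterality_rejected(self, toy_parcellation, rng):
        subjects = make_subjects(0, 1, lateralities=[""])
        z = self._node_ztable(toy_parcellation, subjects, rng)
        with pytest.raises(ValueError, match="laterality"):
            flip_to_ipsicontra(z, subjects, toy_parcellation)
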