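"""Filtering, normalization, downshifted-normal imputation, t-test, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdpquant.quant import (
    QuantMatrix,
    filter_min_samples,
    impute_downshifted,
    log2_transform,
    normalize_median,
    run_pca,
    ttest_unpaired,
)


def qm_from(values, samples=None, groups=None, stage="raw"):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=samples,
                      index=[f"r{i}" for i in range(values.shape[0])])
    return QuantMatrix(df, sample_groups=groups, stage=stage)


class TestFilterMinSamples:
    def test_toy_matrix_survivors(self):
        nan = np.nan
        qm = qm_from([
            [1.0, nan, nan],   # 1 observed -> dropped
            [1.0, 2.0, nan],   # 2 -> kept
            [nan, nan, nan],   # 0 -> dropped
            [1.0, 2.0, 3.0],   # 3 -> kept
            [nan, 5.0, 6.0],   # 2 -> kept
        ])
        out = filter_min_samples(qm, k=2)
        assert list(out.data.index) == ["r1", "r3", "r4"]


class TestNormalizeMedian:
    def test_equal_medians_unchanged(self):
        qm = qm_from([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        out = normalize_median(qm)
        assert np.allclose(out.data.values, qm.data.values, rtol=1e-12)

    def test_doubled_sample_equalized(self):
        base = np.array([[1.0], [2.0], [3.0]])
        qm = qm_from(np.hstack([base, 2 * base]))
        out = normalize_median(qm)
        med = out.data.median(axis=0)
        assert np.allclose(med.values, med.values[0])

    def test_property_equal_medians_random(self, rng):
        for _ in range(20):
            x = np.exp(rng.normal(15, 2, size=(40, 6)))
            x[rng.random(x.shape) < 0.2] = np.nan
            out = normalize_median(qm_from(x))
            med = out.data.median(axis=0, skipna=True).values
            assert np.allclose(med, med[0], rtol=1e-12)

    def test_stage_is_one_way(self):
        out = normalize_median(qm_from([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            normalize_median(out)


class TestImputeDownshifted:
    def test_no_missing_identity(self):
        qm = qm_from([[20.0, 21.0], [19.0, 22.0]], stage="log2")
        out = impute_downshifted(qm, seed=1)
        assert np.array_equal(out.data.values, qm.data.values)

    def test_distribution_of_draws(self):
        """Sample with log2 mean 20, sd 2: draws converge to mean
        20 - 1.8*2 = 16.4 and sd 0.3*2 = 0.6."""
        n_obs, n_miss = 5000, 10_000
        obs = np.random.default_rng(7).normal(0, 1, size=n_obs)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 20.0  # exact mu, sigma
        col = np.concatenate([obs, np.full(n_miss, np.nan)])
        qm = qm_from(col[:, None], stage="log2")
        out = impute_downshifted(qm, seed=42)
        drawn = out.data.values[n_obs:, 0]
        assert drawn.mean() == pytest.approx(16.4, abs=0.02)
        assert drawn.std(ddof=1) == pytest.approx(0.6, abs=0.02)

    def test_deterministic_under_seed(self):
        x = np.array([[20.0, np.nan], [np.nan, 21.0], [19.0, 23.0], [21.0, 22.0]])
        a = impute_downshifted(qm_from(x, stage="log2"), seed=9)
        b = impute_downshifted(qm_from(x, stage="log2"), seed=9)
        c = impute_downshifted(qm_from(x, stage="log2"), seed=10)
        assert np.array_equal(a.data.values, b.data.values)
        assert not np.array_equal(a.data.values, c.data.values)

    def test_imputed_below_observed_median(self, rng):
        """Downshift 1.8 sd puts draws in the low tail: even the 99th
        percentile of imputed values stays under the observed median."""
        obs = rng.normal(20, 2, size=2000)
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        out = impute_downshifted(qm_from(col[:, None], stage="log2"), seed=3)
        drawn = out.data.values[2000:, 0]
        assert np.quantile(drawn, 0.99) < np.median(obs)


class TestTtest:
    def test_identical_groups(self):
        groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        x = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = ttest_unpaired(qm_from(x, list(groups), groups, stage="imputed"), "A", "B")
        assert res["t"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_closed_form_student(self):
        """A=[1,2,3], B=[2,3,4]: t = -1.2247 on 4 df, p ~= 0.288."""
        groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        x = np.array([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]])
        res = ttest_unpaired(qm_from(x, list(groups), groups, stage="imputed"), "A", "B")
        assert res["t"].iloc[0] == pytest.approx(-1.2247, abs=1e-4)
        assert res["p"].iloc[0] == pytest.approx(2 * stats.t.sf(1.22474, df=4), abs=1e-4)
        assert res["p"].iloc[0] == pytest.approx(0.288, abs=5e-3)
        assert res["log2fc"].iloc[0] == pytest.approx(-1.0)

    def test_welch_option_differs_under_unequal_variance(self, rng):
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(4)}
        x = np.hstack([rng.normal(0, 5, size=(30, 5)), rng.normal(1, 0.1, size=(30, 4))])
        qm = qm_from(x, list(groups), groups, stage="imputed")
        student = ttest_unpaired(qm, "A", "B", equal_var=True)
        welch = ttest_unpaired(qm, "A", "B", equal_var=False)
        assert not np.allclose(student["p"], welch["p"])

    def test_type_one_error_rate(self):
        """2000 null rows (n = 5 vs 4): rejection rate at alpha=0.05 in [0.04, 0.06]."""
        rng = np.random.default_rng(2024)
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(4)}
        x = rng.normal(20, 2, size=(2000, 9))
        res = ttest_unpaired(qm_from(x, list(groups), groups, stage="imputed"), "A", "B")
        rate = float((res["p"] < 0.05).mean())
        assert 0.04 <= rate <= 0.06

    def test_fold_change_recovery(self):
        """Two-fold effects, n=5 vs 4, lognormal noise CV 20%: median |log2FC|
        within 0.25 of 1.0 and the sign correct for >=95% of affected rows."""
        rng = np.random.default_rng(77)
        n = 400
        sigma = np.sqrt(np.log(1 + 0.2**2)) / np.log(2)  # CV 20% on log2 scale
        sign = rng.choice([-1.0, 1.0], size=n)
        a = 20.0 + sign[:, None] * 0.5 + rng.normal(0, sigma, size=(n, 5))
        b = 20.0 - sign[:, None] * 0.5 + rng.normal(0, sigma, size=(n, 4))
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(4)}
        qm = qm_from(np.hstack([a, b]), list(groups), groups, stage="imputed")
        res = ttest_unpaired(qm, "A", "B")
        assert abs(np.median(np.abs(res["log2fc"])) - 1.0) < 0.25
        assert float((np.sign(res["log2fc"]) == sign).mean()) >= 0.95

    def test_bh_qvalues_monotone_vs_p(self):
        rng = np.random.default_rng(5)
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(4)}
        x = rng.normal(20, 2, size=(50, 9))
        res = ttest_unpaired(qm_from(x, list(groups), groups, stage="imputed"), "A", "B")
        assert (res["q"] >= res["p"] - 1e-12).all()


class TestPca:
    def test_duplicated_samples_identical_scores(self, rng):
        x = rng.normal(20, 2, size=(60, 4))
        x = np.hstack([x, x[:, [0]]])  # sample 5 duplicates sample 1
        scores = run_pca(qm_from(x, ["a", "b", "c", "d", "a2"], stage="imputed"))
        assert np.allclose(scores.loc["a", ["PC1", "PC2"]].astype(float),
                           scores.loc["a2", ["PC1", "PC2"]].astype(float), atol=1e-8)

    def test_group_separation_on_pc1(self, rng):
        """A strong region effect separates the two groups along PC1."""
        n = 200
        effect = rng.normal(0, 1, size=n)
        a = 20 + np.outer(effect, np.ones(5)) + rng.normal(0, 0.3, size=(n, 5))
        b = 20 - np.outer(effect, np.ones(4)) + rng.normal(0, 0.3, size=(n, 4))
        groups = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(4)}
        scores = run_pca(qm_from(np.hstack([a, b]), list(groups), groups, stage="imputed"))
        pa = scores.loc[[s for s in scores.index if s.startswith("a")], "PC1"]
        pb = scores.loc[[s for s in scores.index if s.startswith("b")], "PC1"]
        # complete linear separation, with a wide margin relative to spread
        lo, hi = (pa, pb) if pa.mean() < pb.mean() else (pb, pa)
        assert lo.max() < hi.min()
        # silhouette-style margin
        gap = hi.min() - lo.max()
        spread = max(pa.std(), pb.std())
        assert gap > spread

    def test_variance_ratio_non_increasing(self, rng):
        x = rng.normal(0, 1, size=(80, 6))
        scores = run_pca(qm_from(x, stage="imputed"), n_components=4)
        evr = scores.attrs["explained_variance_ratio"]
        assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))

    def test_pairwise_complete_path_matches_complete_case(self, rng):
        """With no missing cells the pairwise-complete covariance route and
        the SVD route give the same subspace (up to sign)."""
        x = rng.normal(0, 1, size=(100, 5))
        qm = qm_from(x, stage="log2")
        svd_scores = run_pca(qm)
        x_miss = x.copy()
        x_miss[0, 0] = np.nan  # one missing cell switches the estimator
        cov_scores = run_pca(qm_from(x_miss, stage="log2"))
        for pc in ("PC1", "PC2"):
            a = svd_scores[pc].astype(float).values
            b = cov_scores[pc].astype(float).values
            r = abs(np.corrcoef(a, b)[0, 1])
            assert r > 0.99


def test_pipeline_stage_order_enforced():
    qm = qm_from([[1.0, 2.0], [3.0, 4.0]])
    with pytest.raises(ValueError):
        impute_downshifted(qm)  # raw -> imputed skips log2
    qm2 = log2_transform(normalize_median(qm))
    assert qm2.stage == "log2"
    with pytest.raises(ValueError):
        normalize_median(qm2)
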