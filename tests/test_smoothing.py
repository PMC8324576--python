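import math
import shutil
import subprocess

import numpy as np
import pytest

from forestsignal import (
    DerivativeSign,
    SourceKind,
    ValidationError,
    basis_rank,
    derivative,
    fit_gam,
    standardize,
)


class TestStandardize:
    def test_zscore_moments(self):
        s = standardize([0.1, 0.5, 0.9, 0.3], ages=[0, 1, 2, 3],
                        source_kind=SourceKind.PERCENTAGE)
        assert np.mean(s.values) == pytest.approx(0.0, abs=1e-9)
        assert np.std(s.values, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_logit_antisymmetry(self):
        """p and 1-p are equidistant from logit(0.5)=0, so z-scores mirror."""
        s = standardize([0.1, 0.5, 0.9], ages=[0, 1, 2],
                        source_kind=SourceKind.PERCENTAGE)
        assert s.values[1] == pytest.approx(0.0, abs=1e-12)
        assert s.values[0] == pytest.approx(-s.values[2], abs=1e-12)

    def test_log_transform_for_counts(self):
        s = standardize([0.0, math.e - 1.0], ages=[0, 1],
                        source_kind=SourceKind.COUNT_OR_FREQUENCY)
        # log1p maps to [0, 1]; after z-scoring the gap is sqrt(2)
        assert s.values[1] - s.values[0] == pytest.approx(math.sqrt(2.0))

    def test_constant_series_flagged(self):
        s = standardize([0.4, 0.4, 0.4], ages=[0, 1, 2],
                        source_kind=SourceKind.PERCENTAGE)
        assert s.constant_flag and np.all(s.values == 0.0)

    def test_clamp_epsilon_from_counts(self):
        s = standardize([0.0, 1.0, 0.5], ages=[0, 1, 2],
                        source_kind=SourceKind.PERCENTAGE, max_count=500)
        assert s.transform_constant == pytest.approx(1.0 / 1000.0)

    @pytest.mark.parametrize("bad", [[-0.1, 0.5], [0.2, 1.4]])
    def test_percentage_domain_enforced(self, bad):
        with pytest.raises(ValidationError):
            standardize(bad, ages=[0, 1], source_kind=SourceKind.PERCENTAGE)


class TestBasisRank:
    @pytest.mark.parametrize(
        "n,k",
        [(10, 5), (47, 5), (50, 5), (51, 6), (100, 10), (260, 26), (5, 4), (2, 1)],
    )
    def test_rule(self, n, k):
        assert basis_rank(n) == k


def _standardized(ages, values):
    from forestsignal.smoothing import StandardizedSeries, SourceKind, Transform

    v = np.asarray(values, dtype=float)
    return StandardizedSeries(
        ages=np.asarray(ages, dtype=float), values=v,
        transform=Transform.LOGIT, source_kind=SourceKind.PERCENTAGE,
        transform_constant=1e-3,
    )


class TestFit:
    def test_linear_input_reproduced(self):
        """The order-2 penalty leaves straight lines unpenalized, so a
        noiseless linear series is recovered as the least-squares line."""
        t = np.linspace(0, 1950, 40)
        y = 0.002 * t - 1.3
        fit = fit_gam(_standardized(t, y), k=5)
        assert np.max(np.abs(fit.predict(t) - y)) < 1e-6
        d = derivative(fit)
        assert all(s is DerivativeSign.POS for s in d.sign)

    def test_constant_input(self):
        t = np.linspace(0, 100, 30)
        fit = fit_gam(_standardized(t, np.zeros(30)), k=5)
        assert np.max(np.abs(fit.predict(t))) < 1e-8
        d = derivative(fit)
        assert all(s is DerivativeSign.NONE for s in d.sign)

    def test_smoother_beats_raw_on_smooth_truth(self):
        rng = np.random.default_rng(99)
        t = np.sort(rng.uniform(0, 10, 200))
        truth = np.sin(t)
        y = truth + rng.normal(0, 0.4, t.size)
        fit = fit_gam(_standardized(t, y), k=20)
        rmse_fit = np.sqrt(np.mean((fit.predict(t) - truth) ** 2))
        rmse_raw = np.sqrt(np.mean((y - truth) ** 2))
        assert rmse_fit < rmse_raw

    def test_band_contains_mean(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 100, 50))
        fit = fit_gam(_standardized(t, rng.normal(0, 1, 50)), k=6)
        grid = np.linspace(t.min(), t.max(), 77)
        lo, hi = fit.band(grid)
        mu = fit.predict(grid)
        assert np.all(lo <= mu) and np.all(mu <= hi)

    def test_age_shift_equivariance(self):
        rng = np.random.default_rng(17)
        t = np.sort(rng.uniform(0, 50, 40))
        y = rng.normal(0, 1, 40)
        f0 = fit_gam(_standardized(t, y), k=6)
        f1 = fit_gam(_standardized(t + 500.0, y), k=6)
        grid = np.linspace(t.min(), t.max(), 31)
        assert np.allclose(f0.predict(grid), f1.predict(grid + 500.0), atol=1e-6)

    def test_value_scale_equivariance(self):
        rng = np.random.default_rng(23)
        t = np.sort(rng.uniform(0, 50, 40))
        y = rng.normal(0, 1, 40)
        f0 = fit_gam(_standardized(t, y), k=6)
        f2 = fit_gam(_standardized(t, 2.0 * y), k=6)
        grid = np.linspace(t.min(), t.max(), 31)
        assert np.allclose(2.0 * f0.predict(grid), f2.predict(grid), atol=1e-6)
        assert np.allclose(2.0 * f0.se(grid), f2.se(grid), atol=1e-6)

    def test_rank_reduced_with_warning(self):
        t = np.linspace(0, 10, 6)
        with pytest.warns(UserWarning, match="reduced"):
            fit_gam(_standardized(t, np.sin(t)), k=10)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 100, 30))
        y = rng.normal(0, 1, 30)
        a = fit_gam(_standardized(t, y), k=5)
        b = fit_gam(_standardized(t, y), k=5)
        assert a.lam == b.lam and np.array_equal(a.beta, b.beta)

    def test_pointwise_coverage_near_nominal(self):
        """95% pointwise bands should cover a known smooth truth at >=90% of
        grid points on average over replicate simulations."""
        rng = np.random.default_rng(2024)
        t = np.linspace(0, 10, 80)
        truth = np.sin(t)
        grid = np.linspace(0, 10, 101)
        truth_g = np.sin(grid)
        rates = []
        for _ in range(25):
            y = truth + rng.normal(0, 0.5, t.size)
            fit = fit_gam(_standardized(t, y), k=10)
            lo, hi = fit.band(grid)
            rates.append(np.mean((lo <= truth_g) & (truth_g <= hi)))
        assert np.mean(rates) >= 0.90


class TestDerivative:
    def test_linear_slope_recovered(self):
        t = np.linspace(0, 100, 30)
        fit = fit_gam(_standardized(t, 0.05 * t), k=5)
        d = derivative(fit)
        assert np.allclose(d.dmu, 0.05, atol=1e-4)

    def test_step_trend_detections_localized(self):
        """With an abrupt drop mid-record, decline detections concentrate
        around the transition rather than in the flat flanks."""
        rng = np.random.default_rng(42)
        t = np.linspace(0, 1000, 120)
        truth = np.where(t < 500, 1.0, -1.0)
        y = truth + rng.normal(0, 0.3, t.size)
        fit = fit_gam(_standardized(t, y), k=12)
        d = derivative(fit)
        neg_inside = d.detected(DerivativeSign.NEG, (350.0, 650.0))
        neg_outside = d.detected(DerivativeSign.NEG) - neg_inside
        assert neg_inside > 0
        assert neg_inside >= neg_outside

    def test_interval_seed_reproducible(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 100, 40))
        fit = fit_gam(_standardized(t, rng.normal(0, 1, 40)), k=5)
        d1 = derivative(fit, seed=7)
        d2 = derivative(fit, seed=7)
        assert np.array_equal(d1.lower, d2.lower)

    def test_grid_outside_span_rejected(self):
        t = np.linspace(0, 100, 30)
        fit = fit_gam(_standardized(t, np.sin(t)), k=5)
        with pytest.raises(ValidationError):
            derivative(fit, grid=np.linspace(-10, 50, 20))


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R unavailable for the cross-implementation check")
class TestAgainstMgcv:
    def test_matches_mgcv_reml_fit(self, tmp_path):
        """Independent oracle: mgcv's thin-plate REML fit on the same data
        should agree with ours in fitted mean, SE and edf."""
        rng = np.random.default_rng(314)
        t = np.sort(rng.uniform(0, 1950, 45))
        y = np.sin(t / 300.0) + rng.normal(0, 0.5, t.size)
        y = (y - y.mean()) / y.std(ddof=1)
        fit = fit_gam(_standardized(t, y), k=6)
        grid = np.linspace(t.min(), t.max(), 40)
        data = tmp_path / "d.csv"
        np.savetxt(data, np.column_stack([t, y]), delimiter=",",
                   header="t,y", comments="")
        out = tmp_path / "out.csv"
        script = f"""
        suppressMessages(library(mgcv))
        d <- read.csv('{data}')
        m <- gam(y ~ s(t, k=6, bs='tp'), data=d, method='REML')
        g <- seq(min(d$t), max(d$t), length.out=40)
        p <- predict(m, newdata=data.frame(t=g), se.fit=TRUE)
        write.csv(data.frame(mu=p$fit, se=p$se.fit, edf=sum(m$edf)),
                  '{out}', row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = np.genfromtxt(out, delimiter=",", names=True)
        assert np.allclose(fit.predict(grid), ref["mu"], atol=1e-4)
        assert np.allclose(fit.se(grid), ref["se"], atol=1e-4)
        assert fit.edf == pytest.approx(float(ref["edf"][0]), abs=1e-3)
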