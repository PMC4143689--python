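import numpy as np
import pytest

from puregxe import fit_ppr, residualize_stepwise
from puregxe.ppr import LevelMeansSmoother, LowessSmoother


def test_exact_linear_relation_has_zero_residuals():
    rngl = np.random.default_rng(0)
    x = rngl.uniform(-2, 2, 200)
    y = 2 * x + 1
    m = fit_ppr(x, y, smoother="lowess")
    assert np.max(np.abs(m.residuals)) < 1e-3
    xd = rngl.integers(0, 3, 200).astype(float)
    yd = 2 * xd + 1
    md = fit_ppr(xd, yd, smoother="level-means")
    assert np.max(np.abs(md.residuals)) < 1e-6


def test_level_means_residuals_center_each_genotype_level():
    rngl = np.random.default_rng(1)
    g = rngl.integers(0, 3, 300).astype(float)
    y = 3.0 * g + rngl.normal(0, 1, 300)
    m = fit_ppr(g, y, smoother="level-means")
    for level in (0.0, 1.0, 2.0):
        assert abs(m.residuals[g == level].sum()) < 1e-9


def test_fitted_plus_residuals_reconstruct_response():
    rngl = np.random.default_rng(2)
    x = rngl.normal(0, 1, 100)
    y = np.sin(x) + rngl.normal(0, 0.2, 100)
    m = fit_ppr(x, y)
    np.testing.assert_allclose(m.fitted_values + m.residuals, y,
                               atol=1e-12)


def test_constant_response_gives_constant_model():
    x = np.arange(20, dtype=float)
    m = fit_ppr(x, np.full(20, 7.0))
    assert np.all(m.residuals == 0)
    assert m.residual_variance == 0
    np.testing.assert_allclose(m.predict(x), 7.0)


def test_residuals_invariant_under_constant_shift():
    rngl = np.random.default_rng(3)
    x = rngl.uniform(0, 1, 150)
    y = np.cos(3 * x) + rngl.normal(0, 0.1, 150)
    r1 = fit_ppr(x, y).residuals
    r2 = fit_ppr(x, y + 100.0).residuals
    np.testing.assert_allclose(r1, r2, atol=1e-8)


def test_two_column_direction_recovery_against_grid_oracle():
    """Gauss-Newton direction matches a brute-force unit-circle search."""
    rngl = np.random.default_rng(4)
    n = 500
    x = rngl.uniform(-1, 1, (n, 2))
    sigma = 0.1
    y = np.sin(x[:, 0] + x[:, 1]) + rngl.normal(0, sigma, n)

    def running_mean_rss(theta, k=25):
        alpha = np.array([np.cos(theta), np.sin(theta)])
        p = x @ alpha
        order = np.argsort(p)
        ys = y[order]
        c = np.concatenate([[0.0], np.cumsum(ys)])
        lo = np.maximum(np.arange(n) - k, 0)
        hi = np.minimum(np.arange(n) + k + 1, n)
        smooth = (c[hi] - c[lo]) / (hi - lo)
        return float(np.sum((ys - smooth) ** 2))

    thetas = np.linspace(0, np.pi, 181)
    best_theta = thetas[np.argmin([running_mean_rss(t) for t in thetas])]
    oracle_dir = np.array([np.cos(best_theta), np.sin(best_theta)])

    m = fit_ppr(x, y, M=1, smoother="lowess")
    fitted_dir = m.directions[0]
    assert abs(fitted_dir @ oracle_dir) > 0.98
    assert m.residual_variance == pytest.approx(sigma**2, rel=0.2)


def test_lowess_rss_monotone_in_span():
    rngl = np.random.default_rng(5)
    x = rngl.uniform(0, 1, 300)
    y = np.sin(2 * np.pi * x) + rngl.normal(0, 0.3, 300)
    rss = []
    for frac in (0.8, 0.5, 0.3, 0.2):
        sm = LowessSmoother(frac=frac).fit(x, y)
        rss.append(float(np.sum((y - sm.fitted_) ** 2)))
    assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))


def test_level_means_rejects_too_many_levels():
    x = np.arange(50, dtype=float)
    with pytest.raises(ValueError, match="max_levels"):
        LevelMeansSmoother(max_levels=10).fit(x, x)


def test_too_few_samples_rejected():
    with pytest.raises(ValueError, match="at least 8"):
        fit_ppr(np.arange(5.0), np.arange(5.0))


def test_matches_r_ppr_on_smooth_signal(tmp_path):
    """Independent oracle: R's stats::ppr on the same 1-D problem."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rngl = np.random.default_rng(6)
    x = rngl.uniform(-2, 2, 300)
    y = np.sin(1.5 * x) + rngl.normal(0, 0.2, 300)
    data = tmp_path / "xy.csv"
    np.savetxt(data, np.column_stack([x, y]), delimiter=",",
               header="x,y", comments="")
    script = (
        f'd <- read.csv("{data}"); '
        "m <- ppr(y ~ x, data=d, nterms=1); "
        "cat(mean(residuals(m)^2))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True,
        check=True,
    )
    r_resvar = float(out.stdout.strip())
    ours = fit_ppr(x, y, smoother="lowess").residual_variance
    assert ours == pytest.approx(r_resvar, rel=0.25)


class TestResidualizeStepwise:
    def test_env_main_effect_removed(self):
        rngl = np.random.default_rng(7)
        n = 500
        e = rngl.normal(50, 10, n)
        g = rngl.integers(0, 3, n).astype(float)
        y = 3.0 * e + rngl.normal(0, 1, n)
        res = residualize_stepwise(y, e, g).values
        corr = np.corrcoef(res, e)[0, 1]
        assert abs(corr) < 0.05

    def test_pure_interaction_survives_both_steps(self):
        import puregxe as pgx

        cfg = pgx.SimConfig(
            n_samples=600, n_snps=5, seed=11, noise_sd=1.0,
            age_slope=0.0, smoke_effect=0.0, medication_effect=0.0,
            causal=[pgx.CausalSNP(0, "pure-interaction", 5.0)],
        )
        g, c, truth = pgx.simulate_cohort(cfg)
        y = c.trait("SBP")
        res = residualize_stepwise(
            y, c.env("age"), g.codes[:, 0].astype(float)
        ).values
        # nearly all response variance is interaction + noise: it survives
        assert np.var(res) > 0.85 * np.var(y)

    def test_constant_trait_gives_zero_residuals(self):
        e = np.linspace(0, 1, 50)
        g = np.tile([0.0, 1.0], 25)
        res = residualize_stepwise(np.full(50, 5.0), e, g)
        assert np.all(res.values == 0)

    def test_monomorphic_genotype_flagged(self):
        rngl = np.random.default_rng(8)
        e = rngl.normal(0, 1, 60)
        y = e + rngl.normal(0, 1, 60)
        res = residualize_stepwise(y, e, np.zeros(60))
        assert "no-genotype-variation" in res.flags
        assert abs(res.values.mean()) < 1e-10

    def test_level_means_annihilates_both_margins_exactly(self):
        rngl = np.random.default_rng(9)
        n = 400
        e = (rngl.random(n) < 0.4).astype(float)
        g = rngl.integers(0, 3, n).astype(float)
        y = 2 * e + g + e * g + rngl.normal(0, 1, n)
        res = residualize_stepwise(y, e, g).values
        for level in (0.0, 1.0):
            assert abs(res[e == level].mean()) < 1e-10
        for level in np.unique(g):
            assert abs(res[g == level].mean()) < 1e-10
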