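import numpy as np
import pandas as pd
import pytest

from phyloindel import (
    Phylogeny,
    effect_size,
    pgls_fit,
    regression_diagnostics,
    relative_testes_mass,
    velocity_pca,
)
from phyloindel.comparative_stats import _gls_profile, _pagel_cov
from phyloindel.errors import (
    CollinearityError,
    DegenerateVarianceError,
    SampleSizeError,
    UnitError,
)
from phyloindel.io_formats import VELOCITY_DESCRIPTORS
from phyloindel.synthetic_data import SimulationConfig, simulate_tree


def star_tree(n, height=1.0):
    tips = ",".join(f"s{i}:{height}" for i in range(n))
    return Phylogeny.from_newick(f"({tips});")


def brownian_xy(tree, species, slope, rng, sigma=0.5):
    V = tree.brownian_covariance(species).values
    L = np.linalg.cholesky(V + 1e-10 * np.eye(len(species)))
    x = L @ rng.standard_normal(len(species))
    y = slope * x + sigma * (L @ rng.standard_normal(len(species)))
    return (
        pd.Series(x, index=species, name="x"),
        pd.Series(y, index=species, name="y"),
    )


class TestRelativeTestesMass:
    def test_identity_allometry(self):
        body = pd.Series({"a": 10.0})
        testes = pd.Series({"a": 5.0})
        rtm = relative_testes_mass(body, testes, a=1.0, b=1.0)
        assert rtm.data["RTM"].iloc[0] == pytest.approx(0.5)

    def test_doubling_testes_doubles_rtm(self):
        body = pd.Series({"a": 25.0})
        r1 = relative_testes_mass(body, pd.Series({"a": 1.0}), 0.03, 0.77)
        r2 = relative_testes_mass(body, pd.Series({"a": 2.0}), 0.03, 0.77)
        assert r2.data["RTM"].iloc[0] == pytest.approx(
            2 * r1.data["RTM"].iloc[0]
        )

    def test_zero_exponent_warns(self):
        with pytest.warns(UserWarning, match="b=0"):
            relative_testes_mass(
                pd.Series({"a": 10.0}), pd.Series({"a": 1.0}), 1.0, 0.0
            )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(UnitError):
            relative_testes_mass(
                pd.Series({"a": -1.0}), pd.Series({"a": 1.0}), 1.0, 1.0
            )


class TestVelocityPCA:
    def test_two_perfectly_correlated_descriptors(self, rng):
        x = rng.normal(size=20)
        table = pd.DataFrame({"VCL": 100 + 10 * x, "VSL": 50 + 4 * x})
        pca = velocity_pca(table)
        assert pca.variance_fractions[0] == pytest.approx(1.0)

    def test_constant_descriptor_rejected(self, rng):
        table = pd.DataFrame(
            {"VCL": rng.normal(size=10), "VSL": np.ones(10)}
        )
        with pytest.raises(DegenerateVarianceError):
            velocity_pca(table)

    def test_pc1_oriented_with_principal_velocities(self, rng):
        f = rng.normal(size=30)
        table = pd.DataFrame(
            {
                "VCL": 100 + 10 * f + rng.normal(size=30),
                "VSL": 50 + 5 * f + rng.normal(size=30),
                "VAP": 70 + 7 * f + rng.normal(size=30),
                "LIN": 50 - 2 * f + rng.normal(size=30),
            }
        )
        pca = velocity_pca(table)
        r = np.corrcoef(table["VCL"], pca.pc1)[0, 1]
        assert r > 0

    def test_variance_fractions_invariant_to_descriptor_order(self, rng):
        data = {
            d: rng.normal(size=15) for d in VELOCITY_DESCRIPTORS
        }
        t1 = pd.DataFrame(data)
        t2 = t1[list(reversed(VELOCITY_DESCRIPTORS))]
        assert np.allclose(
            velocity_pca(t1).variance_fractions,
            velocity_pca(t2).variance_fractions,
        )

    def test_one_factor_model_matches_closed_form_share(self):
        # equal loadings lam: corr matrix has off-diagonal lam^2, so PC1
        # carries (1 + 6*lam^2)/7 of the variance
        lam = 0.8
        expected = (1 + 6 * lam**2) / 7
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            f = rng.normal(size=400)
            table = pd.DataFrame(
                {
                    d: lam * f + np.sqrt(1 - lam**2) * rng.normal(size=400)
                    for d in VELOCITY_DESCRIPTORS
                }
            )
            fracs.append(velocity_pca(table).variance_fractions[0])
        assert abs(np.mean(fracs) - expected) < 0.05


class TestPGLS:
    def test_lambda_zero_equals_ols_exactly(self, rng):
        tree = simulate_tree(SimulationConfig(n_species=12), seed=3)
        species = tree.ingroup_tip_labels()
        x = pd.Series(np.linspace(0, 5, len(species)), index=species)
        y = 2.0 * x + 1.0
        fit = pgls_fit(y, pd.DataFrame({"x": x}), tree, lam=0.0)
        assert fit.slopes["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_lambda_zero_matches_ols_on_noisy_data(self, rng):
        tree = simulate_tree(SimulationConfig(n_species=15), seed=4)
        species = tree.ingroup_tip_labels()
        x = pd.Series(rng.normal(size=len(species)), index=species)
        y = pd.Series(
            1.5 * x.values + rng.normal(size=len(species)), index=species
        )
        fit = pgls_fit(y, pd.DataFrame({"x": x}), tree, lam=0.0)
        X = np.column_stack([np.ones(len(species)), x.values])
        beta = np.linalg.lstsq(X, y.values, rcond=None)[0]
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slopes["x"] == pytest.approx(beta[1], abs=1e-8)

    def test_star_tree_makes_lambda_irrelevant(self, rng):
        tree = star_tree(12)
        species = tree.tip_labels()
        x = pd.Series(rng.normal(size=12), index=species)
        y = pd.Series(0.7 * x.values + rng.normal(size=12) * 0.3, index=species)
        f0 = pgls_fit(y, pd.DataFrame({"x": x}), tree, lam=0.0)
        f1 = pgls_fit(y, pd.DataFrame({"x": x}), tree, lam=1.0)
        assert f0.slopes["x"] == pytest.approx(f1.slopes["x"], abs=1e-8)
        assert f0.f_statistic == pytest.approx(f1.f_statistic, rel=1e-8)

    def test_profile_likelihood_peaks_at_lambda_hat(self, rng):
        tree = simulate_tree(SimulationConfig(n_species=20), seed=9)
        species = tree.ingroup_tip_labels()
        x, y = brownian_xy(tree, species, slope=1.0, rng=rng)
        fit = pgls_fit(y, pd.DataFrame({"x": x}), tree)

        V = tree.prune_to(species).brownian_covariance(species).values
        design = np.column_stack([np.ones(len(species)), x.values])
        for lam in (0.0, 1.0):
            lnl = _gls_profile(y.values, design, _pagel_cov(V, lam))[0]
            assert fit.lnl_lambda >= lnl - 1e-8

    def test_sequential_ss_sums_to_model_ss(self, rng):
        tree = simulate_tree(SimulationConfig(n_species=18), seed=2)
        species = tree.ingroup_tip_labels()
        x1 = pd.Series(rng.normal(size=len(species)), index=species)
        x2 = pd.Series(rng.normal(size=len(species)), index=species)
        y = pd.Series(
            x1.values + 0.5 * x2.values + rng.normal(size=len(species)),
            index=species,
        )
        fit = pgls_fit(y, pd.DataFrame({"x1": x1, "x2": x2}), tree)
        # sequential SS partition the model SS, so per-predictor F values
        # (each SS_j / MSE) must sum to p * overall F (model SS / p / MSE)
        assert fit.sequential["F"].sum() == pytest.approx(
            2 * fit.f_statistic, rel=1e-10
        )
        assert (fit.sequential["SS"] >= -1e-12).all()

    def test_collinear_design_rejected(self, rng):
        tree = simulate_tree(SimulationConfig(n_species=10), seed=5)
        species = tree.ingroup_tip_labels()
        x = pd.Series(rng.normal(size=len(species)), index=species)
        y = pd.Series(rng.normal(size=len(species)), index=species)
        with pytest.raises(CollinearityError):
            pgls_fit(y, pd.DataFrame({"x1": x, "x2": 2 * x}), tree)


class TestAgainstRImplementation:
    @pytest.mark.parametrize("lam", [0.0, 0.7, 1.0])
    def test_fixed_lambda_gls_matches_nlme_corpagel(self, tmp_path, lam):
        """Coefficients agree with R's nlme::gls + ape::corPagel (fixed
        lambda, ML) on the same tree and data."""
        import subprocess

        from phyloindel import SimulationConfig, simulate_tree, write_tree

        tree = simulate_tree(SimulationConfig(n_species=12), seed=8)
        species = tree.ingroup_tip_labels()
        sub = tree.prune_to(species)
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=len(species)), index=species)
        y = pd.Series(
            1.2 * x.values + rng.normal(size=len(species)), index=species
        )
        fit = pgls_fit(y, pd.DataFrame({"x": x}), sub, lam=lam)

        write_tree(sub, tmp_path / "t.nwk")
        pd.DataFrame(
            {"species": species, "x": x.values, "y": y.values}
        ).to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages({library(ape); library(nlme)})\n"
            f'tr <- read.tree("{tmp_path}/t.nwk")\n'
            f'df <- read.csv("{tmp_path}/d.csv", row.names=1)\n'
            "df <- df[tr$tip.label,]\n"
            f"fit <- gls(y ~ x, data=df, correlation=corPagel({lam}, "
            'phy=tr, fixed=TRUE), method="ML")\n'
            'cat(sprintf("%.10f %.10f", coef(fit)[1], coef(fit)[2]))\n'
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True,
            check=True,
        )
        r_intercept, r_slope = map(float, res.stdout.split())
        assert fit.intercept == pytest.approx(r_intercept, abs=1e-6)
        assert fit.slopes["x"] == pytest.approx(r_slope, abs=1e-6)


class TestEffectSize:
    @pytest.mark.parametrize(
        "f,df,n,es,lo,hi",
        [
            (14.682, 13, 15, 0.925, 0.359, 1.491),
            (32.795, 9, 11, 1.402, 0.709, 2.095),
            (15.06, 9, 11, 1.074, 0.381, 1.767),
            (10.03, 9, 11, 0.920, 0.227, 1.613),
        ],
    )
    def test_reproduces_published_fisher_z_rows(self, f, df, n, es, lo, hi):
        got_es, got_lo, got_hi = effect_size(f, df, n)
        assert got_es == pytest.approx(es, abs=1.1e-3)
        assert got_lo == pytest.approx(lo, abs=1.1e-3)
        assert got_hi == pytest.approx(hi, abs=1.1e-3)

    def test_zero_f_gives_symmetric_interval(self):
        es, lo, hi = effect_size(0.0, 10, 12)
        assert es == 0.0
        assert lo == pytest.approx(-1.96 / np.sqrt(9))
        assert hi == pytest.approx(1.96 / np.sqrt(9))

    def test_tiny_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            effect_size(5.0, 1, 3)


class TestDiagnostics:
    def _fit(self, y, x, tree):
        return pgls_fit(y, pd.DataFrame({"x": x}), tree, lam=0.0)

    def test_noise_free_data_has_no_flags(self):
        tree = star_tree(10)
        species = tree.tip_labels()
        x = pd.Series(np.linspace(0, 9, 10), index=species)
        y = 3.0 * x + 2.0
        report = regression_diagnostics(self._fit(y, x, tree))
        assert report.flagged == []

    def test_planted_outlier_is_flagged(self, rng):
        tree = star_tree(15)
        species = tree.tip_labels()
        x = pd.Series(np.linspace(0, 14, 15), index=species)
        y = 2.0 * x + pd.Series(rng.normal(size=15) * 0.5, index=species)
        y.iloc[7] += 5.0 * 10  # ten-sigma offset
        report = regression_diagnostics(self._fit(y, x, tree))
        assert species[7] in report.flagged

    def test_flags_invariant_to_species_order(self, rng):
        tree = star_tree(12)
        species = tree.tip_labels()
        x = pd.Series(rng.normal(size=12), index=species)
        y = pd.Series(x.values + rng.normal(size=12) * 0.2, index=species)
        y.iloc[3] += 8.0
        r1 = regression_diagnostics(self._fit(y, x, tree))
        perm = list(reversed(species))
        r2 = regression_diagnostics(self._fit(y.loc[perm], x.loc[perm], tree))
        assert sorted(r1.flagged) == sorted(r2.flagged)
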