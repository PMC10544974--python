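"""Variance components, broad-sense heritability, adjusted means."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import phenospectra as ps
from phenospectra.errors import UndefinedHeritabilityError
from phenospectra.heritability import VarianceComponents, _anova_moments


def _vc(g, ge, eps):
    return VarianceComponents(sigma_G2=g, sigma_GE2=ge, sigma_eps2=eps)


class TestH2Formula:
    def test_hand_computed_value(self):
        res = ps.broad_sense_heritability(_vc(2.0, 1.0, 3.0), x=2, r=3)
        assert res.H2 == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_limits(self):
        assert ps.broad_sense_heritability(_vc(1, 0, 0), x=1, r=1).H2 == 1.0
        assert ps.broad_sense_heritability(_vc(0, 1, 1), x=2, r=2).H2 == 0.0

    def test_all_zero_components_undefined(self):
        with pytest.raises(UndefinedHeritabilityError):
            ps.broad_sense_heritability(_vc(0, 0, 0), x=1, r=1)

    def test_monotonicity_grid(self):
        """H2 increases in genetic variance, decreases in error variance."""
        grid = np.linspace(0.1, 5, 12)
        for x, r in [(1, 1), (2, 3), (3, 2)]:
            h_up = [
                ps.broad_sense_heritability(_vc(g, 0.5, 1.0), x=x, r=r).H2
                for g in grid
            ]
            assert np.all(np.diff(h_up) > 0)
            h_down = [
                ps.broad_sense_heritability(_vc(1.0, 0.5, e), x=x, r=r).H2
                for e in grid
            ]
            assert np.all(np.diff(h_down) < 0)

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            ps.broad_sense_heritability(_vc(1, 0, 1), x=0, r=1)


def _ems_oracle(table, trait):
    """Independent expected-mean-squares estimator, written as explicit loops."""
    g_levels = sorted(table["genotype"].unique())
    e_levels = sorted(table["environment"].unique())
    n_g, n_e = len(g_levels), len(e_levels)
    r = len(table) // (n_g * n_e)
    y = {
        (g, e): table[(table["genotype"] == g) & (table["environment"] == e)][
            trait
        ].to_numpy()
        for g in g_levels
        for e in e_levels
    }
    grand = table[trait].mean()
    gm = {g: np.mean([y[(g, e)].mean() for e in e_levels]) for g in g_levels}
    em = {e: np.mean([y[(g, e)].mean() for g in g_levels]) for e in e_levels}
    ss_g = n_e * r * sum((gm[g] - grand) ** 2 for g in g_levels)
    ss_ge = r * sum(
        (y[(g, e)].mean() - gm[g] - em[e] + grand) ** 2
        for g in g_levels
        for e in e_levels
    )
    ss_err = sum(
        ((y[(g, e)] - y[(g, e)].mean()) ** 2).sum() for g in g_levels for e in e_levels
    )
    ms_g = ss_g / (n_g - 1)
    ms_ge = ss_ge / ((n_g - 1) * (n_e - 1))
    ms_err = ss_err / (n_g * n_e * (r - 1))
    return (
        max(0.0, (ms_g - ms_ge) / (n_e * r)),
        max(0.0, (ms_ge - ms_err) / r),
        ms_err,
    )


class TestMomentsEstimator:
    def test_matches_ems_oracle_on_5x2x2_grid(self):
        rng = np.random.default_rng(9)
        rows = [
            {"genotype": f"g{i}", "environment": f"e{j}", "replicate": f"r{k}",
             "block": "b1", "y": rng.normal()}
            for i in range(5)
            for j in range(2)
            for k in range(2)
        ]
        table = pd.DataFrame(rows)
        comp = ps.estimate_variance_components(table, "y", method="anova_moments")
        s_g, s_ge, s_eps = _ems_oracle(table, "y")
        assert comp.sigma_G2 == pytest.approx(s_g, abs=1e-12)
        assert comp.sigma_GE2 == pytest.approx(s_ge, abs=1e-12)
        assert comp.sigma_eps2 == pytest.approx(s_eps, abs=1e-12)

    def test_unbalanced_data_rejected(self):
        table = pd.DataFrame(
            {
                "genotype": ["g1", "g1", "g2"],
                "environment": ["e1", "e2", "e1"],
                "replicate": "r1",
                "block": "b1",
                "y": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="balanced"):
            ps.estimate_variance_components(table, "y", method="anova_moments")


class TestReml:
    def test_constant_data_gives_zero_components(self, balanced_trial):
        _, table, _ = balanced_trial
        flat = table.assign(latent_trait=1.0)
        comp = ps.estimate_variance_components(flat, "latent_trait")
        assert comp.sigma_G2 == 0 and comp.sigma_GE2 == 0 and comp.sigma_eps2 == 0
        assert comp.converged

    def test_reml_and_moments_agree_on_balanced_fixture(self):
        """Agreement within 2% on a balanced trial with n >= 200 entries."""
        d = ps.generate_trial_design(
            "alpha_lattice", 200, r=3, x=2, block_size=200, seed=31
        )
        table, _ = ps.simulate_genetic_values(
            d, sigma_G2=2.0, sigma_GE2=0.5, sigma_eps2=1.0, seed=32
        )
        reml = ps.estimate_variance_components(table, "latent_trait")
        mom = ps.estimate_variance_components(
            table, "latent_trait", method="anova_moments"
        )
        for attr in ("sigma_G2", "sigma_GE2", "sigma_eps2"):
            assert getattr(reml, attr) == pytest.approx(
                getattr(mom, attr), rel=0.02
            ), attr

    def test_single_environment_emits_model_reduction_warning(self):
        d = ps.generate_trial_design("alpha_lattice", 20, r=2, block_size=20, seed=33)
        table, _ = ps.simulate_genetic_values(d, seed=34)
        with pytest.warns(UserWarning, match="single environment"):
            comp = ps.estimate_variance_components(table, "latent_trait")
        assert comp.sigma_GE2 == 0.0

    def test_augmented_design_identifies_genotype_variance_via_checks(self):
        d = ps.generate_trial_design(
            "augmented_with_checks", 120, n_checks=6, check_reps=8, x=2, seed=35
        )
        table, _ = ps.simulate_genetic_values(
            d, sigma_G2=1.0, sigma_GE2=0.1, sigma_eps2=0.3, seed=36
        )
        comp = ps.estimate_variance_components(table, "latent_trait")
        assert comp.converged
        assert 0.3 < comp.sigma_G2 < 2.5

    def test_matches_lme4_on_small_fixture(self, tmp_path, balanced_trial):
        """Independent oracle: R lme4 REML fit of the same crossed model."""
        _, table, _ = balanced_trial
        csv = tmp_path / "trial.csv"
        table.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$gxe <- interaction(d$genotype, d$environment)
            d$rep <- interaction(d$environment, d$replicate)
            m <- suppressMessages(lmer(
              latent_trait ~ (1|genotype) + (1|environment) + (1|gxe) + (1|rep),
              data = d,
              control = lmerControl(check.nobs.vs.nlev = "ignore",
                                    check.nobs.vs.nRE = "ignore")))
            vc <- as.data.frame(VarCorr(m))
            cat(sprintf("%s %.10f\\n", vc$grp, vc$vcov))
            """
        )
        res = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True,
            timeout=120,
        )
        assert res.returncode == 0, res.stderr
        r_comp = {}
        for line in res.stdout.strip().splitlines():
            name, value = line.rsplit(" ", 1)
            r_comp[name.strip()] = float(value)
        comp = ps.estimate_variance_components(table, "latent_trait")
        assert comp.sigma_G2 == pytest.approx(r_comp["genotype"], rel=1e-3)
        assert comp.sigma_GE2 == pytest.approx(r_comp["gxe"], rel=1e-3, abs=1e-3)
        assert comp.sigma_eps2 == pytest.approx(r_comp["Residual"], rel=1e-3)


class TestAdjustedEntryMeans:
    def test_balanced_design_equals_raw_means(self, balanced_trial):
        _, table, _ = balanced_trial
        out = ps.adjusted_entry_means(table, "yield_")
        raw_env = table.groupby(["genotype", "environment"])["yield_"].mean()
        raw = raw_env.groupby("genotype").mean()
        merged = out.set_index("genotype")["adjusted_mean"]
        np.testing.assert_allclose(
            merged.sort_index(), raw.sort_index(), atol=1e-8
        )

    def test_inflated_block_effect_reduces_rmse_vs_truth(self):
        d = ps.generate_trial_design(
            "alpha_lattice", 30, r=3, x=1, block_size=6, seed=41
        )
        table, truth = ps.simulate_genetic_values(
            d, sigma_G2=1.0, sigma_GE2=0.0, sigma_eps2=0.1, seed=42
        )
        # inject a large effect into one incomplete block
        bad = table["block"] == "rep_1_b01"
        table.loc[bad, "yield_"] += 5.0
        adj = ps.adjusted_entry_means(table, "yield_").set_index("genotype")
        raw = table.groupby("genotype")["yield_"].mean()
        target = truth.genotype_effects.set_index("genotype")["yield_effect"]

        def rmse(est):
            est = est.sort_index() - est.mean()
            return np.sqrt(((est - target.sort_index()) ** 2).mean())

        assert rmse(adj["adjusted_mean"]) < rmse(raw)

    def test_missing_genotype_is_simply_absent(self, balanced_trial):
        _, table, _ = balanced_trial
        dropped = table[table["genotype"] != "entry_0001"]
        out = ps.adjusted_entry_means(dropped, "yield_")
        assert "entry_0001" not in set(out["genotype"])
        assert len(out) == table["genotype"].nunique() - 1
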