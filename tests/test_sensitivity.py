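"""NFSI elasticities, Latin hypercube sampling, and PRCC."""

import numpy as np
import pandas as pd
import pytest

import smad
from smad.model import InvalidInputError
from smad.sensitivity import NFSI_NAMES

from conftest import draw_params


class TestNfsiClosedForm:
    def test_exposed_exit_rate_index_at_table_values(self, baseline_params):
        # tau/(tau+sigma) with tau=0.05, sigma=0.25 -> 1/6
        p = baseline_params
        assert p.tau == 0.05 and p.sigma == 0.25
        assert smad.nfsi_closed_form(p, "sigma") == pytest.approx(0.16666, abs=1e-4)

    @pytest.mark.parametrize("name", ["Lambda", "phi", "chi", "Phi"])
    def test_multiplicative_parameters_have_unit_elasticity(self, name):
        rng = np.random.default_rng(50)
        for _ in range(20):
            assert smad.nfsi_closed_form(draw_params(rng), name) == 1.0

    def test_quit_rate_index(self, baseline_params):
        # -beta/(beta+tau) with beta=0.01, tau=0.05
        assert smad.nfsi_closed_form(baseline_params, "beta") == pytest.approx(-1 / 6, rel=1e-12)

    def test_depression_rate_index_at_reference_parameters(self, case1_params):
        expected = -0.5 / (0.09 + 0.5 + 0.0027)
        assert smad.nfsi_closed_form(case1_params, "alpha") == pytest.approx(expected, rel=1e-12)

    def test_sign_pattern(self):
        rng = np.random.default_rng(8)
        positive = {"Lambda", "sigma", "phi", "chi", "Phi"}
        for _ in range(50):
            p = draw_params(rng)
            for name in NFSI_NAMES:
                value = smad.nfsi_closed_form(p, name)
                assert (value > 0) == (name in positive)

    def test_unknown_name_rejected(self, case1_params):
        with pytest.raises(InvalidInputError):
            smad.nfsi_closed_form(case1_params, "upsilon")  # not a parameter of R0


class TestNfsiNumeric:
    def test_contact_probability_elasticity_is_one(self, case1_params):
        assert smad.nfsi_numeric(case1_params, "chi") == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("name", NFSI_NAMES)
    def test_agrees_with_closed_form(self, name):
        rng = np.random.default_rng(abs(hash(name)) % 2**31)
        for _ in range(100):
            p = draw_params(rng)
            assert smad.nfsi_numeric(p, name) == pytest.approx(
                smad.nfsi_closed_form(p, name), abs=1e-6
            )

    def test_rejects_zero_parameter(self, case1_params):
        with pytest.raises(InvalidInputError):
            smad.nfsi_numeric(case1_params.replace(beta=0.0), "beta")


class TestLhsSample:
    def test_one_draw_per_stratum(self):
        design = smad.lhs_sample({"x": (0.0, 1.0)}, n=4, seed=0)
        strata = np.floor(design.samples["x"].to_numpy() * 4).astype(int)
        assert sorted(strata) == [0, 1, 2, 3]

    def test_stratification_in_scaled_range(self):
        design = smad.lhs_sample({"x": (2.0, 10.0)}, n=8, seed=1)
        strata = np.floor((design.samples["x"].to_numpy() - 2.0) / 1.0).astype(int)
        assert sorted(strata) == list(range(8))

    def test_reproducible_for_fixed_seed(self):
        ranges = {"a": (0.0, 1.0), "b": (5.0, 6.0)}
        d1 = smad.lhs_sample(ranges, n=100, seed=42)
        d2 = smad.lhs_sample(ranges, n=100, seed=42)
        pd.testing.assert_frame_equal(d1.samples, d2.samples)

    def test_column_mean_close_to_midpoint(self):
        n = 5000
        design = smad.lhs_sample({"x": (0.0, 1.0)}, n=n, seed=7)
        sigma = 1.0 / np.sqrt(12.0)
        assert abs(design.samples["x"].mean() - 0.5) < 3 * sigma / np.sqrt(n)

    @pytest.mark.parametrize("bad", [{"x": (1.0, 1.0)}, {"x": (2.0, 1.0)}])
    def test_invalid_range_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            smad.lhs_sample(bad, n=10, seed=0)

    def test_too_small_design_rejected(self):
        with pytest.raises(InvalidInputError):
            smad.lhs_sample({"x": (0.0, 1.0)}, n=1, seed=0)


class TestPrcc:
    @staticmethod
    def _noise_design(n=200, p=4, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(size=(n, p)), columns=[f"x{j}" for j in range(p)]
        )

    def test_perfect_monotone_dependence(self):
        X = self._noise_design()
        y = np.exp(3 * X["x1"])  # monotone in x1 alone
        report = smad.prcc(X, y)
        table = report.table.set_index("parameter")
        assert table.loc["x1", "prcc"] > 0.999
        assert table.loc["x1", "p_value"] < 1e-10

    def test_antisymmetry_under_output_negation(self):
        # a noisy output keeps the rank residuals well conditioned, so the
        # exact rank-reversal antisymmetry survives floating point
        X = self._noise_design(seed=3)
        y = np.exp(3 * X["x2"]) + 0.5 * np.random.default_rng(3).normal(size=len(X))
        r_pos = smad.prcc(X, y).table.set_index("parameter")["prcc"]
        r_neg = smad.prcc(X, -y).table.set_index("parameter")["prcc"]
        np.testing.assert_allclose(r_neg, -r_pos, atol=1e-9)
        assert r_pos["x2"] > 0.9

    def test_invariant_under_monotone_transforms(self):
        # ranks are unchanged by strictly monotone maps of columns or output
        X = self._noise_design(seed=5)
        y = 2 * X["x0"] - X["x3"] + 0.1 * np.random.default_rng(5).normal(size=len(X))
        base = smad.prcc(X, y).table["prcc"].to_numpy()
        X_t = X.copy()
        X_t["x0"] = np.exp(X_t["x0"])
        X_t["x3"] = np.log(X_t["x3"] + 1.0)
        transformed = smad.prcc(X_t, np.exp(y / 10)).table["prcc"].to_numpy()
        np.testing.assert_allclose(transformed, base, atol=1e-12)

    def test_values_bounded(self):
        X = self._noise_design(seed=9)
        y = X.sum(axis=1) + np.random.default_rng(9).normal(size=len(X))
        table = smad.prcc(X, y).table
        assert (table["prcc"].abs() <= 1).all()
        assert table["p_value"].between(0, 1).all()

    def test_constant_column_rejected(self):
        X = self._noise_design()
        X["x1"] = 0.5
        with pytest.raises(InvalidInputError):
            smad.prcc(X, X["x0"])

    def test_too_few_rows_rejected(self):
        X = self._noise_design(n=5, p=4)
        with pytest.raises(InvalidInputError):
            smad.prcc(X, X["x0"])

    def test_matches_independent_partial_correlation(self):
        # cross-check the residual-regression route against pingouin's
        # partial correlation on rank-transformed data
        import pingouin as pg
        from scipy.stats import rankdata

        X = self._noise_design(n=150, p=3, seed=11)
        y = X["x0"] - 2 * X["x2"] + 0.3 * np.random.default_rng(11).normal(size=len(X))
        ours = smad.prcc(X, y).table.set_index("parameter")["prcc"]
        data = X.apply(lambda c: rankdata(c))
        data["y"] = rankdata(y)
        for j, name in enumerate(X.columns):
            covar = [c for c in X.columns if c != name]
            expected = pg.partial_corr(data=data, x=name, y="y", covar=covar)["r"].iloc[0]
            assert ours[name] == pytest.approx(expected, abs=1e-10)


class TestPrccExperiment:
    def test_reproduction_number_sign_pattern(self, case1_params):
        # reference design: n = 5000, +-25% ranges; signs of every
        # significant coefficient match the NFSI elasticity signs; psi's
        # elasticity (-0.0046) is below the design's resolution, so its
        # coefficient must be statistically indistinguishable from zero
        report = smad.run_prcc_experiment(case1_params, n=5000, seed=0, outputs=("R0",))["R0"]
        table = report.table.set_index("parameter")
        nfsi = smad.nfsi_table(case1_params).indices
        for name, row in table.iterrows():
            if row["p_value"] < 0.01:
                assert np.sign(row["prcc"]) == np.sign(nfsi[name]), name
        for name in ("Lambda", "sigma", "phi", "chi", "Phi"):
            assert table.loc[name, "prcc"] > 0.3
        for name in ("beta", "tau", "alpha"):
            assert table.loc[name, "prcc"] < -0.1
        assert abs(table.loc["psi", "prcc"]) < 0.05

    def test_smoke_run_is_seed_reproducible(self, case1_params):
        r1 = smad.run_prcc_experiment(case1_params, n=200, seed=9)["R0"]
        r2 = smad.run_prcc_experiment(case1_params, n=200, seed=9)["R0"]
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.n == 200

    def test_report_covers_all_varied_parameters(self, case1_params):
        report = smad.run_prcc_experiment(case1_params, n=200, seed=1)["R0"]
        assert sorted(report.table["parameter"]) == sorted(NFSI_NAMES)
        assert (report.table["prcc"].abs() <= 1).all()

    def test_compartment_output_runs_through_integrator(self, case1_params):
        reports = smad.run_prcc_experiment(
            case1_params, n=30, seed=2, outputs=("I1",), t_eval=5.0, h=0.05
        )
        table = reports["I1"].table
        assert reports["I1"].output == "I1@t=5"
        assert (table["prcc"].abs() <= 1).all()

    def test_unknown_output_rejected(self, case1_params):
        with pytest.raises(InvalidInputError):
            smad.run_prcc_experiment(case1_params, n=50, seed=0, outputs=("X",))

    def test_default_ranges_respect_admissibility(self, case1_params):
        ranges = smad.default_prcc_ranges(case1_params.replace(chi=0.9))
        lo, hi = ranges["chi"]
        assert hi <= 1.0
        assert all(lo >= 0 for lo, _ in ranges.values())
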