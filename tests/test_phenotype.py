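"""Chlorophyll quantification, wax-dip calibration, retained fraction, ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

import acclimkit as ak
from acclimkit.design import ValidationError


class TestChlorophyllA:
    def test_zero_absorbances_zero_chl(self):
        assert ak.chlorophyll_a([0, 0, 0, 0]) == 0.0

    def test_linearity_in_absorbance_and_volume(self):
        a = (0.10, 0.05, 0.30, 0.02)
        one = ak.chlorophyll_a(a, volume=3.0)
        assert ak.chlorophyll_a(np.array(a) * 2, volume=3.0) == pytest.approx(2 * one)
        assert ak.chlorophyll_a(a, volume=6.0) == pytest.approx(2 * one)

    def test_default_coefficient_worked_example(self):
        # hand dot product: 0.0604*0.10 - 4.5224*0.05 + 13.2969*0.30
        #                   - 1.7453*0.02 = 3.734084; x3 ml = 11.202252
        total = ak.chlorophyll_a((0.10, 0.05, 0.30, 0.02), volume=3.0)
        assert total == pytest.approx(11.202252, abs=1e-6)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValidationError):
            ak.chlorophyll_a((-0.1, 0, 0, 0))


class TestAreaCurve:
    def test_exact_proportional_standards(self):
        std = pd.DataFrame({"weight_gain": [1.0, 2.0, 4.0], "area": [10.0, 20.0, 40.0]})
        curve = ak.fit_area_curve(std)
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_duplicate_weight_gains_rejected(self):
        std = pd.DataFrame({"weight_gain": [1.0, 1.0, 1.0], "area": [10, 20, 30]})
        with pytest.raises(ValidationError, match="distinct"):
            ak.fit_area_curve(std)

    def test_too_few_standards_rejected(self):
        std = pd.DataFrame({"weight_gain": [1.0, 2.0], "area": [10, 20]})
        with pytest.raises(ValidationError, match=">=3"):
            ak.fit_area_curve(std)

    def test_noisy_standards_within_three_se(self):
        from scipy import stats

        misses = 0
        for s in range(20):
            r = np.random.default_rng(s)
            dw = np.linspace(0.5, 4, 8)
            area = 25.0 * dw + r.normal(0, 1.0, 8)
            curve = ak.fit_area_curve(pd.DataFrame({"weight_gain": dw, "area": area}))
            se = stats.linregress(dw, area).stderr
            misses += abs(curve.slope - 25.0) > 3 * se
        assert misses <= 2

    def test_branch_area_linear(self):
        curve = ak.AreaStandardCurve(slope=10.0, intercept=0.0, r_squared=1.0, n_standards=3)
        assert ak.branch_area(1.0, 3.0, curve) == pytest.approx(20.0)

    def test_zero_gain_zero_intercept_rejected(self):
        curve = ak.AreaStandardCurve(slope=10.0, intercept=0.0, r_squared=1.0, n_standards=3)
        with pytest.raises(ValidationError, match="positive"):
            ak.branch_area(2.0, 2.0, curve)


class TestRetainedFraction:
    def _setup(self, stressed_density, nonstressed_density):
        d = ak.canonical_design(treatments=("control29",), days=(7,),
                                colonies_per_treatment=2)
        dens = pd.DataFrame(index=d.sample_ids)
        stressed = d.table["condition"] == "stressed"
        dens["chl_density"] = np.where(stressed, stressed_density, nonstressed_density)
        return d, dens

    def test_equal_densities_fraction_one(self):
        d, dens = self._setup(2.0, 2.0)
        frac = ak.retained_fraction(dens, d)
        assert (frac["retained_fraction"] == 1.0).all()

    def test_two_vs_four_gives_half(self):
        d, dens = self._setup(2.0, 4.0)
        frac = ak.retained_fraction(dens, d)
        assert (frac["retained_fraction"] == 0.5).all()

    def test_scale_invariance(self):
        d, dens = self._setup(2.0, 4.0)
        a = ak.retained_fraction(dens, d)["retained_fraction"]
        dens10 = dens * 10
        b = ak.retained_fraction(dens10, d)["retained_fraction"]
        assert np.allclose(a, b)

    def test_zero_denominator_names_colony(self):
        d, dens = self._setup(2.0, 0.0)
        with pytest.raises(ValidationError, match="colony"):
            ak.retained_fraction(dens, d)

    def test_treatment_means_match_arithmetic_oracle(self):
        d = ak.canonical_design(days=(7,), colonies_per_treatment=2)
        gen = ak.GeneratorConfig(seed=4, days=(7,), colonies_per_treatment=2)
        rec, std, truth = ak.simulate_phenotype(d, gen)
        curve = ak.fit_area_curve(std[["weight_gain", "area"]])
        dens = ak.chlorophyll_density_table(rec, curve)
        frac = ak.retained_fraction(dens, d)
        by_trt = frac.groupby("treatment")["retained_fraction"].mean()
        oracle = (
            dens.join(d.table)
            .groupby(["colony_id", "day"])
            .apply(
                lambda g: g.loc[g.condition == "stressed", "chl_density"].mean()
                / g.loc[g.condition == "nonstressed", "chl_density"].mean(),
                include_groups=False,
            )
        )
        oracle_by_trt = oracle.groupby(
            oracle.index.get_level_values(0).map(d.table.groupby("colony_id")["treatment"].first())
        ).mean()
        assert np.allclose(by_trt.sort_index(), oracle_by_trt.sort_index())


class TestPhenotypeAnova:
    def test_constant_values_p_one(self):
        factors = pd.DataFrame(
            {"treatment": ["control29", "control29", "stable31", "stable31"] * 2,
             "day": [7, 11] * 4}
        )
        vals = pd.Series(1.0, index=factors.index)
        res = ak.phenotype_anova(vals, factors, n_permutations=99, seed=0)
        assert res[["p_treatment", "p_day", "p_treatment_x_day"]].eq(1.0).all()

    def test_day0_excluded_by_default(self):
        factors = pd.DataFrame(
            {"treatment": ["control29", "stable31"] * 6,
             "day": [0, 0, 2, 2, 7, 7, 11, 11, 2, 2, 7, 7]}
        )
        r = np.random.default_rng(0)
        vals = pd.Series(r.normal(size=12), index=factors.index)
        # with day 0 removed, a wild day-0 value cannot influence the test
        vals2 = vals.copy()
        vals2.iloc[0] = 1e6
        a = ak.phenotype_anova(vals, factors, n_permutations=99, seed=1)
        b = ak.phenotype_anova(vals2, factors, n_permutations=99, seed=1)
        assert a["F_treatment"] == pytest.approx(b["F_treatment"])

    def test_exhaustive_matches_enumeration_oracle(self):
        import numpy.linalg as la

        factors = pd.DataFrame(
            {"treatment": ["control29", "control29", "control29",
                           "stable31", "stable31", "stable31"],
             "day": [7, 7, 11, 7, 11, 11]}
        )
        r = np.random.default_rng(5)
        y = r.normal(size=6)

        def cellwise_f(yv):
            trt = factors["treatment"].to_numpy()
            day = factors["day"].to_numpy()
            I = np.ones((6, 1))
            Da = pd.get_dummies(trt).to_numpy(float)
            Db = pd.get_dummies(day).to_numpy(float)
            cell = pd.get_dummies([f"{a}|{b}" for a, b in zip(trt, day)]).to_numpy(float)

            def rss(X):
                beta, *_ = la.lstsq(X, yv, rcond=None)
                res = yv - X @ beta
                return float(res @ res)

            r_a = rss(np.hstack([I, Da]))
            r_b = rss(np.hstack([I, Db]))
            r_ab = rss(np.hstack([I, Da, Db]))
            r_full = rss(cell)
            df_res = 6 - la.matrix_rank(cell)
            return (
                (r_b - r_ab) / 1 / (r_full / df_res),
                (r_a - r_ab) / 1 / (r_full / df_res),
                (r_ab - r_full) / 1 / (r_full / df_res),
            )

        obs = cellwise_f(y)
        counts, total = [0, 0, 0], 0
        for perm in itertools.permutations(range(6)):
            f = cellwise_f(y[list(perm)])
            for k in range(3):
                counts[k] += f[k] >= obs[k] - 1e-12
            total += 1
        res = ak.phenotype_anova(
            pd.Series(y, index=factors.index), factors,
            exclude_day0=False, exhaustive=True,
        )
        assert res["p_treatment"] == pytest.approx(counts[0] / total, abs=1e-12)
        assert res["p_day"] == pytest.approx(counts[1] / total, abs=1e-12)
        assert res["p_treatment_x_day"] == pytest.approx(counts[2] / total, abs=1e-12)

    def test_planted_treatment_effect_power(self):
        detected = 0
        for s in range(20):
            r = np.random.default_rng(500 + s)
            rows = []
            for trt in ("control29", "stable31", "variable29_33"):
                shift = 0.0 if trt == "control29" else 0.3
                for day in (2, 7, 11):
                    for _ in range(6):
                        rows.append(
                            {"treatment": trt, "day": day,
                             "value": 0.4 + shift + r.normal(0, 0.1)}
                        )
            df = pd.DataFrame(rows)
            res = ak.phenotype_anova(
                df["value"], df[["treatment", "day"]],
                n_permutations=199, seed=s,
            )
            detected += res["p_treatment"] <= 0.05
        assert detected >= 18


class TestZeroNoiseRoundTrip:
    def test_full_pipeline_recovers_planted_densities_exactly(self, design144):
        gen = ak.GeneratorConfig(
            seed=3, sigma_fraction=0.0, sigma_density=0.0,
            weight_noise_sd=0.0, absorbance_noise_sd=0.0,
        )
        rec, std, truth = ak.simulate_phenotype(design144, gen)
        curve = ak.fit_area_curve(std[["weight_gain", "area"]])
        dens = ak.chlorophyll_density_table(rec, curve)
        assert np.max(np.abs(dens["chl_density"] - rec["true_density"])) < 1e-9
        frac = ak.retained_fraction(dens, design144)
        merged = frac.join(truth, rsuffix="_true")
        assert np.max(
            np.abs(merged["retained_fraction"] - merged["retained_fraction_true"])
        ) < 1e-9

    def test_areas_round_trip_within_five_percent(self, design144):
        gen = ak.GeneratorConfig(seed=8)
        rec, std, _ = ak.simulate_phenotype(design144, gen)
        curve = ak.fit_area_curve(std[["weight_gain", "area"]])
        dens = ak.chlorophyll_density_table(rec, curve)
        rel = np.abs(dens["area_cm2"] / rec["true_area"] - 1)
        assert rel.max() < 0.05
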