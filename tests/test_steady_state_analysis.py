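import itertools
import math

import numpy as np
import pandas as pd
import pytest

from metpk import steady_state as ssa
from metpk import nlme, pk
from conftest import make_fit


def bands_from_printed():
    """Bands built directly from the reference report's steady-state CIs."""
    return ssa.SteadyStateBands(
        c_min={250.0: ssa.Band(0.05, 0.10), 500.0: ssa.Band(0.10, 0.20),
               1000.0: ssa.Band(0.20, 0.40)},
        c_avg={250.0: ssa.Band(0.28, 0.42), 500.0: ssa.Band(0.57, 0.84),
               1000.0: ssa.Band(1.13, 1.68)},
        c_max={250.0: ssa.Band(0.63, 0.84), 500.0: ssa.Band(1.26, 1.69),
               1000.0: ssa.Band(2.53, 3.37)},
    )


def troughs(pid, values, dose=250.0):
    return pd.DataFrame(
        {
            "patient_id": pid,
            "visit": range(1, len(values) + 1),
            "day_post_first_dose": [7.0 * i for i in range(1, len(values) + 1)],
            "dose": dose,
            "concentration": values,
        }
    )


class TestClassification:
    def test_two_exceedances_is_group1(self):
        df = troughs("a", [0.09, 0.12, 0.11, 0.10])
        (cls,) = ssa.classify_patients(df, bands_from_printed())
        assert cls.group == "group1"
        assert cls.n_above_cmin_upper == 2  # 0.10 is on the boundary: inside

    def test_all_below_is_group2(self):
        df = troughs("a", [0.06, 0.08, 0.09])
        (cls,) = ssa.classify_patients(df, bands_from_printed())
        assert cls.group == "group2" and cls.n_above_cmin_upper == 0

    def test_single_exceedance_is_group2(self):
        df = troughs("a", [0.06, 0.30, 0.08])
        (cls,) = ssa.classify_patients(df, bands_from_printed())
        assert cls.group == "group2" and cls.n_above_cmin_upper == 1

    def test_invariant_to_visit_order_and_inner_additions(self):
        base = troughs("a", [0.06, 0.30, 0.08])
        shuffled = base.sample(frac=1.0, random_state=1)
        (c1,) = ssa.classify_patients(base, bands_from_printed())
        (c2,) = ssa.classify_patients(shuffled, bands_from_printed())
        assert (c1.group, c1.n_above_cmin_upper) == (c2.group, c2.n_above_cmin_upper)
        # adding strictly-inside-band visits cannot flip a clean group-2 patient
        clean = troughs("a", [0.06, 0.07])
        extended = troughs("a", [0.06, 0.07, 0.08, 0.09])
        (c3,) = ssa.classify_patients(clean, bands_from_printed())
        (c4,) = ssa.classify_patients(extended, bands_from_printed())
        assert c3.group == c4.group == "group2"

    def test_missing_band_names_dose(self):
        df = troughs("a", [0.1], dose=750.0)
        with pytest.raises(KeyError, match="750"):
            ssa.classify_patients(df, bands_from_printed())


class TestViolationFlags:
    def test_peak_band_visit_flagged(self):
        df = troughs("a", [0.08, 0.74, 0.09])
        flags = ssa.flag_violations(df, bands_from_printed())
        assert flags == {"a": [2]}

    def test_no_flags_when_all_in_trough_band(self):
        df = troughs("a", [0.06, 0.08, 0.09])
        assert ssa.flag_violations(df, bands_from_printed()) == {}

    def test_three_peak_visits_not_flagged(self):
        df = troughs("a", [0.70, 0.74, 0.80, 0.08])
        assert ssa.flag_violations(df, bands_from_printed()) == {}

    def test_flags_are_labels_only(self):
        df = troughs("a", [0.08, 0.74, 0.09])
        before = df.copy()
        ssa.flag_violations(df, bands_from_printed())
        ssa.classify_patients(df, bands_from_printed())
        pd.testing.assert_frame_equal(df, before)


class TestWilcoxon:
    def test_known_small_case(self):
        res = ssa.wilcoxon_rank_sum([1, 2, 3], [4, 5])
        assert res.W == 0
        assert res.p_two_sided == pytest.approx(0.2)
        assert res.method == "exact"

    def test_symmetry_under_swap(self):
        x, y = [3.1, 4.5, 7.2, 1.0], [2.2, 5.5, 9.9]
        r1 = ssa.wilcoxon_rank_sum(x, y)
        r2 = ssa.wilcoxon_rank_sum(y, x)
        assert r1.W + r2.W == len(x) * len(y)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)
        assert r1.hl_estimate == pytest.approx(-r2.hl_estimate)

    def test_hodges_lehmann_shift_equivariance(self):
        x = np.array([1.2, 3.4, 5.1, 2.2, 8.0])
        delta = 2.5
        res = ssa.wilcoxon_rank_sum(x + delta, x)
        assert res.hl_estimate == pytest.approx(delta)
        assert res.hl_ci[0] <= delta <= res.hl_ci[1]

    def test_exact_p_matches_enumeration_small(self):
        # brute-force over all rank splits for a handful of shapes
        for n, m in [(3, 3), (4, 2), (2, 5)]:
            values = np.arange(1.0, n + m + 1)
            for comb in itertools.combinations(range(n + m), n):
                x = values[list(comb)]
                y = np.delete(values, list(comb))
                res = ssa.wilcoxon_rank_sum(x, y)
                # enumeration oracle
                us = []
                for c2 in itertools.combinations(range(n + m), n):
                    xx = values[list(c2)]
                    yy = np.delete(values, list(c2))
                    us.append(np.sum(np.subtract.outer(xx, yy) > 0))
                us = np.array(us)
                lower = np.mean(us <= res.W)
                upper = np.mean(us >= res.W)
                p_oracle = min(1.0, 2 * min(lower, upper))
                assert res.p_two_sided == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ssa.wilcoxon_rank_sum([], [1.0])

    def test_ties_fall_back_to_normal(self):
        res = ssa.wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "normal_tie_corrected"
        assert 0 <= res.p_two_sided <= 1


class TestLogTroughModel:
    @staticmethod
    def simulate_lmm(n_pat=40, beta_crcl=-0.87, beta_dose=0.0016, sd_int=0.3,
                     sd_res=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows_t, rows_c = [], []
        for i in range(n_pat):
            pid = f"p{i}"
            crcl = rng.uniform(1.0, 2.5)  # L/h
            dose = rng.choice([250.0, 500.0, 1000.0])
            bmi = rng.uniform(25, 45)
            u = rng.normal(0, sd_int)
            rows_c.append({"patient_id": pid, "crcl": crcl, "dose": dose, "bmi": bmi})
            for v in range(4):
                log_c = -1.0 + beta_dose * dose + beta_crcl * crcl + u + rng.normal(0, sd_res)
                rows_t.append(
                    {"patient_id": pid, "visit": v + 1,
                     "day_post_first_dose": 7.0 * (v + 1),
                     "concentration": math.exp(log_c)}
                )
        return pd.DataFrame(rows_t), pd.DataFrame(rows_c)

    def test_recovers_crcl_coefficient(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            tr, cov = self.simulate_lmm(seed=100 + rep)
            table = ssa.log_trough_lmm(tr, cov).set_index("term")
            assert "crcl" in table.index
            row = table.loc["crcl"]
            if row["ci_lower"] <= -0.87 <= row["ci_upper"]:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_zero_variance_matches_ols(self):
        # no patient effect, tiny residual: mixed model collapses onto OLS
        tr, cov = self.simulate_lmm(n_pat=30, sd_int=0.0, sd_res=0.05, seed=7)
        table = ssa.log_trough_lmm(tr, cov, start_with_interactions=False).set_index("term")
        import statsmodels.formula.api as smf

        df = tr.merge(cov, on="patient_id")
        df["log_conc"] = np.log(df["concentration"])
        kept = [t for t in ("dose", "crcl", "bmi") if t in table.index]
        ols = smf.ols("log_conc ~ " + " + ".join(kept), df).fit()
        for term in kept:
            assert table.loc[term, "estimate"] == pytest.approx(
                ols.params[term], abs=2e-3
            )

    def test_nonpositive_concentration_rejected(self):
        tr, cov = self.simulate_lmm(n_pat=5, seed=1)
        tr.loc[0, "concentration"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            ssa.log_trough_lmm(tr, cov)

    def test_exponentiated_effect(self):
        tr, cov = self.simulate_lmm(seed=3)
        table = ssa.log_trough_lmm(tr, cov)
        for _, row in table.iterrows():
            assert row["exp_estimate"] == pytest.approx(math.exp(row["estimate"]))
        assert round(math.exp(-0.87), 2) == 0.42


class TestDoseTable:
    def test_requires_crcl_variant(self):
        with pytest.raises(ValueError):
            ssa.dose_recommendation_table(make_fit(variant="plain"))

    def test_monotonicity_and_linearity(self):
        fit = make_fit(variant="crcl_scaled", clearance=17.4)
        table = ssa.dose_recommendation_table(fit, crcl_grid_ml_min=(30, 40, 50))
        for d in (250.0, 500.0, 1000.0):
            col = table[table["dose"] == d].sort_values("crcl_ml_min")["c_max_ss"]
            assert col.is_monotonic_decreasing
        at30 = table[table["crcl_ml_min"] == 30.0].set_index("dose")["c_max_ss"]
        assert at30[1000.0] == pytest.approx(4 * at30[250.0], rel=1e-9)

    def test_halving_crcl_doubles_concentration(self):
        fit = make_fit(variant="crcl_scaled", clearance=17.4)
        table = ssa.dose_recommendation_table(fit, crcl_grid_ml_min=(20, 40))
        g = table[table["dose"] == 500.0].set_index("crcl_ml_min")["c_max_ss"]
        assert g[20.0] == pytest.approx(2 * g[40.0], rel=1e-9)

    def test_reduces_to_plain_model_at_matching_clearance(self):
        # ratio·CrCl = Cl/F -> identical steady-state predictions
        ratio, cl = 17.4, 29.6
        crcl_ml_min = cl / ratio * 1000.0 / 60.0  # L/h -> mL/min
        fit = make_fit(variant="crcl_scaled", clearance=ratio)
        table = ssa.dose_recommendation_table(fit, crcl_grid_ml_min=(crcl_ml_min,))
        plain = pk.steady_state(
            pk.PKParameters(K=0.119, ka=0.65, cl_over_f=cl, dose=500.0)
        )
        got = table[table["dose"] == 500.0]["c_max_ss"].iloc[0]
        assert got == pytest.approx(plain.c_max_ss, rel=1e-9)

    def test_bands_from_fit_are_ordered(self):
        fit = make_fit()
        bands = ssa.steady_state_bands(fit, doses=(250, 1000))
        for d in (250.0, 1000.0):
            bmin, bavg, bmax = bands.for_dose(d)
            assert bmin.lower < bmin.upper
            assert bmin.upper < bmax.lower  # trough and peak bands well separated
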