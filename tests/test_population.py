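"""Person-time, standardization weights, rates, demographics."""

import numpy as np
import pandas as pd
import pytest

from heatccx import (
    demographic_ratio_table,
    incidence_rate,
    person_time_from_enrollment,
    person_time_from_population,
    ratios_from_shares,
    split_age_15_19,
    standardization_weights,
    standardize_counts,
)


def pop_table(rows):
    return pd.DataFrame(rows, columns=["county", "age_group", "sex", "year", "count"])


class TestAgeSplit:
    def raw(self, teen=1000):
        rows = [("C0", "15-19", "F", 2015, teen), ("C0", "20-24", "F", 2015, 500),
                ("C0", "25-29", "F", 2015, 300), ("C0", "30-34", "F", 2015, 200)]
        return pop_table(rows)

    def test_deterministic_fraction(self):
        out = split_age_15_19(self.raw())
        band = out.set_index("age_group")["count"]
        assert band["18-24"] == 400 + 500
        assert band["25-34"] == 500

    def test_zero_fraction_identity(self):
        out = split_age_15_19(self.raw(), fraction=0.0)
        assert out.set_index("age_group")["count"]["18-24"] == 500

    def test_conservation(self):
        # moved + excluded(under-18 remainder) = original 15-19 band
        teen = 987
        out = split_age_15_19(self.raw(teen))
        moved = out.set_index("age_group")["count"]["18-24"] - 500
        assert moved == round(teen * 0.4)
        assert moved + (teen - moved) == teen

    def test_sampled_mode_binomial_moments(self):
        teen = 1000
        moved = []
        for s in range(400):
            out = split_age_15_19(self.raw(teen), mode="sampled", seed=s)
            moved.append(out.set_index("age_group")["count"]["18-24"] - 500)
        moved = np.array(moved)
        # Binomial(1000, .4): mean 400, var 240
        assert abs(moved.mean() - 400) < 3 * np.sqrt(240 / 400)
        assert 0.7 * 240 < moved.var(ddof=1) < 1.3 * 240

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_age_15_19(self.raw(), fraction=1.5)


class TestPersonTime:
    def enrollment(self, count=100):
        return pd.DataFrame(
            {"county": "C0", "age_group": "35-44", "sex": "F",
             "year": 2015, "month": [6], "count": count}
        )

    def test_month_expansion(self):
        pt = person_time_from_enrollment(self.enrollment(), ("2015-06-01", "2015-06-30"))
        assert len(pt) == 30
        assert pt["person_days"].sum() == 3000

    def test_zero_enrollment(self):
        pt = person_time_from_enrollment(self.enrollment(0), ("2015-06-01", "2015-06-30"))
        assert pt["person_days"].sum() == 0

    @pytest.mark.parametrize("year,days", [(2015, 365), (2016, 366)])
    def test_full_year_calendar_sum(self, year, days):
        enr = pd.DataFrame(
            {"county": "C0", "age_group": "35-44", "sex": "F", "year": year,
             "month": list(range(1, 13)), "count": 7}
        )
        pt = person_time_from_enrollment(enr, (f"{year}-01-01", f"{year}-12-31"))
        assert pt["person_days"].sum() == 7 * days

    def test_annual_population_constant_within_year(self):
        pop = pop_table([("C0", "35-44", "F", 2015, 50)])
        pt = person_time_from_population(pop, ("2015-01-01", "2015-12-31"))
        assert pt["person_days"].nunique() == 1
        assert pt["person_days"].sum() == 50 * 365

    def test_missing_month_strict(self):
        with pytest.raises(ValueError):
            person_time_from_enrollment(
                self.enrollment(), ("2015-06-01", "2015-07-31"), strict=True
            )


class TestWeights:
    def test_identity(self):
        pop = pop_table(
            [("C0", "18-24", "F", 2015, 10), ("C0", "25-34", "F", 2015, 30)]
        )
        w = standardization_weights(pop, pop)
        assert np.allclose(w["weight"], 1.0)

    def test_hand_ratio_of_shares(self):
        ins = pop_table([("C0", "A", "F", 2015, 80), ("C0", "B", "F", 2015, 20)])
        ref = pop_table([("C0", "A", "F", 2015, 50), ("C0", "B", "F", 2015, 50)])
        w = standardization_weights(ins, ref).set_index("age_group")["weight"]
        assert w["A"] == pytest.approx(0.625)
        assert w["B"] == pytest.approx(2.5)

    def test_share_preservation(self):
        rng = np.random.default_rng(4)
        rows_i, rows_r = [], []
        for y in (2014, 2015):
            for c in ("C0", "C1"):
                for a in ("18-24", "25-34", "75+"):
                    for s in ("F", "M"):
                        rows_i.append((c, a, s, y, int(rng.integers(1, 500))))
                        rows_r.append((c, a, s, y, int(rng.integers(100, 5000))))
        ins, ref = pop_table(rows_i), pop_table(rows_r)
        w = standardization_weights(ins, ref)
        m = ins.merge(w, on=["county", "age_group", "sex", "year"])
        m["reweighted"] = m["count"] * m["weight"]
        got = m.groupby("year")["reweighted"].transform("sum")
        shares = (m["reweighted"] / got).to_numpy()
        ref_tot = ref.groupby("year")["count"].transform("sum")
        ref_shares = (
            ref.assign(s=ref["count"] / ref_tot)
            .merge(m[["county", "age_group", "sex", "year"]], on=["county", "age_group", "sex", "year"])
        )["s"].to_numpy()
        assert np.allclose(shares, ref_shares, atol=1e-9)
        # normalization forced by the formula
        m["ins_share"] = m["count"] / m.groupby("year")["count"].transform("sum")
        per_year = m.groupby("year").apply(
            lambda g: (g["weight"] * g["ins_share"]).sum(), include_groups=False
        )
        assert np.allclose(per_year, 1.0, atol=1e-12)

    def test_zero_insured_year_errors(self):
        ins = pop_table([("C0", "A", "F", 2015, 0)])
        ref = pop_table([("C0", "A", "F", 2015, 10)])
        with pytest.raises(ValueError):
            standardization_weights(ins, ref)


class TestStandardizeAndRates:
    def counts(self):
        return pd.DataFrame(
            {
                "dataset": "insured",
                "date": pd.to_datetime(["2015-06-01", "2015-06-02"]),
                "county": "C0",
                "age_group": ["A", "B"],
                "sex": "F",
                "cause": "all-cause",
                "encounter_type": "ED",
                "count": [10, 4],
            }
        )

    def weights(self, wa=1.0, wb=1.0):
        return pd.DataFrame(
            {"county": "C0", "age_group": ["A", "B"], "sex": "F",
             "year": 2015, "weight": [wa, wb]}
        )

    def test_identity_weights(self):
        out = standardize_counts(self.counts(), self.weights())
        assert np.allclose(out["count"], [10, 4])

    def test_multiplication(self):
        out = standardize_counts(self.counts(), self.weights(wa=2.5))
        assert out["count"].iloc[0] == pytest.approx(25.0)

    def test_missing_weight_errors(self):
        w = self.weights().iloc[:1]
        with pytest.raises(ValueError):
            standardize_counts(self.counts(), w)

    def test_rate_definition(self):
        counts = self.counts().assign(count=[1, 0])
        pt = pd.DataFrame({"person_days": [1e6]})
        assert incidence_rate(counts, pt) == pytest.approx(1.0)
        assert incidence_rate(counts.assign(count=0), pt) == 0.0

    def test_rate_margins_match_groupby_oracle(self):
        rng = np.random.default_rng(8)
        counts = pd.concat([self.counts()] * 5, ignore_index=True)
        counts["cause"] = rng.choice(["a", "b"], size=len(counts))
        counts["count"] = rng.integers(0, 20, size=len(counts))
        pt = pd.DataFrame({"person_days": rng.uniform(1e5, 1e6, size=4)})
        out = incidence_rate(counts, pt, by=["cause"]).set_index("cause")["rate"]
        tot = pt["person_days"].sum()
        for cause, g in counts.groupby("cause"):
            assert out[cause] == pytest.approx(1e6 * g["count"].sum() / tot)

    def test_scale_equivariance(self):
        counts = self.counts()
        pt = pd.DataFrame({"person_days": [5e5]})
        r = incidence_rate(counts, pt)
        assert incidence_rate(counts.assign(count=counts["count"] * 2), pt) == pytest.approx(2 * r)
        assert incidence_rate(counts, pt.assign(person_days=1e6)) == pytest.approx(r / 2)

    def test_zero_person_time_errors(self):
        pt = pd.DataFrame({"person_days": [0.0]})
        with pytest.raises(ValueError):
            incidence_rate(self.counts(), pt)


class TestDemographics:
    def test_identical_tables_unit_ratios(self):
        pop = pop_table(
            [("C0", "18-24", "F", 2015, 100), ("C0", "25-34", "M", 2015, 200),
             ("C1", "25-34", "F", 2015, 300)]
        )
        out = demographic_ratio_table(pop, pop)
        assert np.allclose(out["ratio"].dropna(), 1.0)

    def test_ratio_rounding_and_missing(self):
        assert ratios_from_shares([20.5, 10.7], [18.6, 4.9]).tolist() == [1.10, 2.18]
        assert np.isnan(ratios_from_shares([1.0], [0.0])[0])

    def test_total_population_row(self):
        ins = pop_table([("C0", "18-24", "F", 2015, 34), ("C0", "18-24", "F", 2016, 34)])
        ref = pop_table([("C0", "18-24", "F", 2015, 1000), ("C0", "18-24", "F", 2016, 1000)])
        out = demographic_ratio_table(ins, ref)
        total = out[out["category"] == "total"].iloc[0]
        assert total["ratio"] == pytest.approx(0.03)

    def test_empty_errors(self):
        pop = pop_table([("C0", "18-24", "F", 2015, 1)])
        with pytest.raises(ValueError):
            demographic_ratio_table(pop.iloc[:0], pop)
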