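"""Age-length keys, catch expansion, descending limb, catch-curve slope."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatfish import mortality as mt


def _aged_df(areas, ages, lengths):
    return pd.DataFrame({"area": areas, "age": ages, "length_at_catch": lengths})


class TestBuildAlk:
    def test_proportions_from_counts(self):
        df = _aged_df(["heated"] * 5, [1, 1, 1, 1, 2], [11.0, 11.2, 10.1, 12.3, 11.9])
        alk = mt.build_alk(df, "heated")
        assert alk.class_lowers.tolist() == [10.0]
        assert np.allclose(alk.proportions[0], [0.8, 0.2])

    def test_single_age_gives_unit_column(self):
        df = _aged_df(["heated"] * 4, [3] * 4, [10.0, 12.6, 15.1, 17.7])
        alk = mt.build_alk(df, "heated")
        assert alk.proportions.shape[1] == 1
        assert np.allclose(alk.proportions, 1.0)

    def test_missing_area_raises(self):
        df = _aged_df(["heated"], [1], [10.0])
        with pytest.raises(ValueError, match="no aged fish"):
            mt.build_alk(df, "reference")

    def test_rows_sum_to_one_on_random_data(self, rng):
        df = _aged_df(
            ["reference"] * 500,
            rng.integers(1, 9, size=500),
            rng.uniform(5, 45, size=500),
        )
        alk = mt.build_alk(df, "reference")
        assert np.allclose(alk.proportions.sum(axis=1), 1.0, atol=1e-12)

    def test_alk_matches_true_conditional_proportions(self, rng):
        """Within one length class, the ALK row estimates the conditional age
        distribution; binomial error at n=1000 per class."""
        n = 1000
        ages = rng.choice([2, 3], p=[0.7, 0.3], size=n)
        lengths = np.full(n, 13.0)
        alk = mt.build_alk(_aged_df(["heated"] * n, ages, lengths), "heated")
        assert np.allclose(alk.proportions[0], [0.7, 0.3], atol=3 * 0.46 / np.sqrt(n))


class TestExpandCatch:
    def _catch(self, counts, area="heated", year=1995, width=2.5):
        return pd.DataFrame(
            {
                "area": area,
                "year": year,
                "net_id": 0,
                "length_class_lower": list(counts),
                "length_class_width": width,
                "count": list(counts.values()),
            }
        )

    def test_simple_split(self):
        alk = mt.AgeLengthKey(
            area="heated", class_lowers=[10.0], ages=[1, 2],
            proportions=[[0.8, 0.2]],
        )
        out = mt.expand_catch(self._catch({10.0: 50}), alk)
        # one net deployment -> effort 1, so cpue equals fish numbers
        assert out.set_index("age")["cpue"].tolist() == [40.0, 10.0]

    def test_identity_alk_relabels(self):
        alk = mt.AgeLengthKey(
            area="heated", class_lowers=[10.0, 12.5], ages=[1, 2],
            proportions=[[1.0, 0.0], [0.0, 1.0]],
        )
        out = mt.expand_catch(self._catch({10.0: 7, 12.5: 9}), alk)
        assert out.set_index("age")["cpue"].tolist() == [7.0, 9.0]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_random_instances(self, seed):
        """Total fish is identical before and after ALK expansion."""
        rng = np.random.default_rng(seed)
        n_classes = int(rng.integers(2, 8))
        n_ages = int(rng.integers(2, 6))
        lowers = 2.5 * np.arange(n_classes) + 5.0
        props = rng.dirichlet(np.ones(n_ages), size=n_classes)
        alk = mt.AgeLengthKey(
            area="heated", class_lowers=lowers,
            ages=np.arange(1, n_ages + 1), proportions=props,
        )
        counts = {lo: int(rng.integers(0, 400)) for lo in lowers}
        catch = self._catch(counts)
        out = mt.expand_catch(catch, alk)
        assert out["cpue"].sum() == pytest.approx(sum(counts.values()), rel=1e-12)

    def test_missing_class_imputed_from_neighbor(self):
        alk = mt.AgeLengthKey(
            area="heated", class_lowers=[10.0], ages=[1, 2],
            proportions=[[0.5, 0.5]],
        )
        out = mt.expand_catch(self._catch({12.5: 10}), alk)
        assert out["cpue"].sum() == pytest.approx(10.0)


class TestDescendingLimb:
    def test_keeps_mode_and_older(self):
        df = pd.DataFrame(
            {"area": "heated", "year": 1995, "age": [1, 2, 3, 4, 5],
             "cpue": [1.0, 5.0, 9.0, 4.0, 2.0]}
        )
        out = mt.select_descending_limb(df)
        assert sorted(out["age"]) == [3, 4, 5]
        assert out.attrs["modal_age"]["heated"] == 3

    def test_strictly_decreasing_keeps_everything(self):
        df = pd.DataFrame(
            {"area": "reference", "year": 1990, "age": [1, 2, 3],
             "cpue": [9.0, 4.0, 1.0]}
        )
        out = mt.select_descending_limb(df)
        assert len(out) == 3

    def test_all_zero_raises(self):
        df = pd.DataFrame(
            {"area": "heated", "year": 1990, "age": [1, 2], "cpue": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            mt.select_descending_limb(df)


class TestCatchCurveSlope:
    def test_noiseless_exponential_recovered_exactly(self):
        ages = np.arange(2, 7)
        df = pd.DataFrame(
            {"area": "heated", "year": 2000, "age": ages,
             "cpue": 1000.0 * np.exp(-0.7 * ages)}
        )
        assert mt.catch_curve_slope_ols(df, "heated") == pytest.approx(0.7, abs=1e-10)

    def test_annual_mortality_values(self):
        assert round(100 * mt.annual_mortality(0.73)) == 52
        assert round(100 * mt.annual_mortality(0.62)) == 46
        assert mt.annual_mortality(0.0) == 0.0


class TestFilterDisturbed:
    def test_disturbed_rows_dropped(self):
        df = pd.DataFrame(
            {
                "area": ["heated", "heated"],
                "year": [1996, 1997],
                "net_id": [0, 0],
                "length_class_lower": [10.0, 10.0],
                "length_class_width": [2.5, 2.5],
                "count": [5, 7],
                "disturbed": [True, False],
            }
        )
        out = mt.filter_disturbed(df)
        assert out["year"].tolist() == [1997]


class TestBayesianCatchCurve:
    def test_area_relabeling_swaps_z(self):
        """Swapping area labels swaps the mortality estimates."""
        from heatfish import synthetic_data as synth
        from heatfish.bayes_engine import SamplerConfig

        cfg = synth.SimConfig(seed=21)
        caa = synth.simulate_catch_curve_data(cfg, n_years=8, ages=(2, 7))
        swapped = caa.copy()
        swapped["area"] = swapped["area"].map(
            {"heated": "reference", "reference": "heated"})
        sc = SamplerConfig(chains=2, iterations=1200, thin=2, seed=5)
        fit = mt.fit_catch_curve(caa, config=sc)
        fit_sw = mt.fit_catch_curve(swapped, config=sc)
        assert float(fit.median("Z_heated")) == pytest.approx(
            float(fit_sw.median("Z_reference")), abs=0.05)
        assert float(fit.median("Z_reference")) == pytest.approx(
            float(fit_sw.median("Z_heated")), abs=0.05)

    def test_too_few_ages_rejected(self):
        df = pd.DataFrame(
            {"area": ["heated"] * 4, "year": [2000] * 4, "age": [2, 2, 3, 3],
             "cpue": [5.0, 4.0, 3.0, 2.0]}
        )
        with pytest.raises(ValueError, match="3 distinct ages"):
            mt.CatchCurveModel(df)
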