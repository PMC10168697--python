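"""Structure and statistical properties of the synthetic populations."""

import numpy as np
import pytest

from heatfish import synthetic_data as synth


class TestRecordInvariants:
    def test_cohort_age_year_identity(self, fish_small):
        for f in fish_small:
            assert f.catch_year - f.age == f.cohort
            assert len(f.radii) == f.age
            assert np.all(np.diff(f.radii) > 0) or f.age == 1
            assert f.length_at_catch > 0

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            synth.FishRecord(
                id=0, area="heated", cohort=1990, catch_year=1995, age=4,
                length_at_catch=20.0, radii=np.array([0.2, 0.5, 0.8, 1.0]),
            )

    def test_catch_class_alignment_enforced(self):
        with pytest.raises(ValueError):
            synth.CatchRecord(
                area="heated", year=1995, net_id=0,
                length_class_lower=11.0, length_class_width=2.5, count=3,
            )


class TestDeterminism:
    def test_same_seed_identical_tables(self, small_config):
        a = synth.fish_to_frame(synth.simulate_cohorts(small_config))
        b = synth.fish_to_frame(synth.simulate_cohorts(small_config))
        assert a.to_csv(index=False) == b.to_csv(index=False)
        ca = synth.catch_to_frame(
            synth.simulate_catch(synth.simulate_cohorts(small_config), small_config))
        cb = synth.catch_to_frame(
            synth.simulate_catch(synth.simulate_cohorts(small_config), small_config))
        assert ca.to_csv(index=False) == cb.to_csv(index=False)

    def test_different_seed_differs(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = synth.fish_to_frame(synth.simulate_cohorts(small_config))
        b = synth.fish_to_frame(synth.simulate_cohorts(other))
        assert not a.equals(b)


class TestSurvival:
    def test_exponential_survival_fraction(self):
        """P(lifespan >= a+1) / P(lifespan >= a) ~= exp(-Z)."""
        z = 0.7
        cfg = synth.SimConfig(
            seed=42,
            heated=synth.AreaParams(45.7, 0.19, -0.5, 3.0, 0.03, z, 512.0, -1.13),
            recruits_per_cohort=10_000,
            cohort_first=1990, cohort_last=1990,
            catch_first=1987, catch_last=2020,
            sel_mode=None,
        )
        fish = [f for f in synth.simulate_cohorts(cfg) if f.area == "heated"]
        ages = np.array([f.age for f in fish])
        # ages are last attained integer age: P(age >= a) = exp(-Z a)
        frac = np.mean(ages >= 3) / np.mean(ages >= 2)
        assert frac == pytest.approx(np.exp(-z), abs=0.03)

    def test_survival_curve_matches_exponential(self):
        z = 0.62
        cfg = synth.SimConfig(
            seed=17,
            reference=synth.AreaParams(39.4, 0.15, -0.5, 3.0, 0.03, z, 433.0, -1.18),
            recruits_per_cohort=20_000,
            cohort_first=1990, cohort_last=1990,
            catch_first=1987, catch_last=2030, sel_mode=None,
        )
        fish = [f for f in synth.simulate_cohorts(cfg) if f.area == "reference"]
        ages = np.array([f.age for f in fish])
        for a in range(1, 6):
            emp = np.mean(ages >= a)
            expect = np.exp(-z * a) / np.exp(-z)  # conditioned on age >= 1
            se = 3 * np.sqrt(expect * (1 - expect) / len(ages))
            assert abs(emp - expect) < max(se, 0.01)


class TestZeroNoise:
    def test_lengths_on_vbge_curve(self):
        cfg = synth.SimConfig(
            seed=3, sigma_obs=0.0,
            heated=synth.AreaParams(45.7, 0.19, -0.5, 0.0, 0.0, 0.73, 512.0, -1.13),
            reference=synth.AreaParams(39.4, 0.15, -0.5, 0.0, 0.0, 0.62, 433.0, -1.18),
            recruits_per_cohort=200, cohort_first=1990, cohort_last=1991,
        )
        for f in synth.simulate_cohorts(cfg):
            pars = cfg.area_params(f.area)
            expect = synth.vbge_length(f.age, pars.mu_linf, pars.mu_k, pars.t0)
            assert f.length_at_catch == pytest.approx(expect, rel=1e-12)


class TestSimulateCatch:
    def test_full_selectivity_conserves_fish(self, small_config, fish_small):
        import dataclasses

        cfg = dataclasses.replace(small_config, sel_mode=None, nets_per_year=1)
        catch = synth.simulate_catch(fish_small, cfg)
        assert sum(c.count for c in catch) == len(fish_small)

    def test_binning_to_2p5_grid(self):
        recs = [
            synth.FishRecord(
                id=i, area="heated", cohort=1990, catch_year=1993, age=3,
                length_at_catch=11.3, radii=np.array([0.3, 0.7, 1.0]),
            )
            for i in range(20)
        ]
        cfg = synth.SimConfig(seed=0, sel_mode=None, nets_per_year=1)
        catch = synth.simulate_catch(recs, cfg)
        assert len(catch) == 1
        assert catch[0].length_class_lower == 10.0
        assert catch[0].length_class_width == 2.5
        assert catch[0].count == 20

    def test_one_cm_years_use_fine_classes(self):
        recs = [
            synth.FishRecord(
                id=i, area="heated", cohort=1999, catch_year=2002, age=3,
                length_at_catch=11.3, radii=np.array([0.3, 0.7, 1.0]),
            )
            for i in range(5)
        ]
        cfg = synth.SimConfig(seed=0, sel_mode=None, nets_per_year=1)
        catch = synth.simulate_catch(recs, cfg)
        assert catch[0].length_class_width == 1.0
        assert catch[0].length_class_lower == 11.0

    def test_dome_selectivity_shifts_mean_length_up(self):
        """With the dome mode above most fish, retention favours large fish."""
        rng = np.random.default_rng(0)
        lengths = rng.uniform(5, 18, size=3000)  # population mostly < 20 cm
        recs = [
            synth.FishRecord(
                id=i, area="heated", cohort=1990, catch_year=1992, age=2,
                length_at_catch=float(l), radii=np.array([0.5, 1.0]),
            )
            for i, l in enumerate(lengths)
        ]
        cfg = synth.SimConfig(seed=1, sel_mode=20.0, sel_spread=0.4)
        catch = synth.simulate_catch(recs, cfg)
        mean_retained = np.average(
            [c.length_class_lower + 1.25 for c in catch],
            weights=[c.count for c in catch],
        )
        assert mean_retained > lengths.mean() + 0.5

    def test_empty_fish_list_raises(self, small_config):
        with pytest.raises(ValueError):
            synth.simulate_catch([], small_config)


class TestConfigValidation:
    def test_incompatible_windows_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            synth.SimConfig(cohort_first=2010, cohort_last=2012,
                            catch_first=1987, catch_last=2003)

    def test_bad_area_params_rejected(self):
        with pytest.raises(ValueError):
            synth.AreaParams(-1.0, 0.2, -0.5, 3.0, 0.03, 0.7, 500.0, -1.1)
        with pytest.raises(ValueError):
            synth.AreaParams(45.0, 0.2, -0.5, 3.0, 0.03, -0.7, 500.0, -1.1)


class TestAuxiliaryGenerators:
    def test_growth_data_matches_allometric_mean(self):
        cfg = synth.SimConfig(
            seed=2, growth_sigma_cohort=0.0, growth_sigma_id=0.0,
            growth_sigma_obs=1e-12,
        )
        obs = synth.simulate_growth_data(cfg, n_individuals=30)
        for area in synth.AREAS:
            pars = cfg.area_params(area)
            sub = obs[obs["area"] == area]
            assert np.allclose(
                sub["G"], pars.alpha * sub["L_geo"] ** pars.theta, rtol=1e-6
            )

    def test_catch_curve_data_declines_at_z(self):
        cfg = synth.SimConfig(seed=4)
        caa = synth.simulate_catch_curve_data(
            cfg, n_years=400, ages=(2, 8), sigma_year=0.0, sigma_obs=0.0)
        sub = caa[caa["area"] == "heated"]
        slope = np.polyfit(sub["age"], np.log(sub["cpue"]), 1)[0]
        assert -slope == pytest.approx(0.73, abs=1e-9)
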