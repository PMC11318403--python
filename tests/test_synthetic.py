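"""Synthetic study generator: shapes, round trips, determinism, cohorts."""

import numpy as np
import pytest

from oxykin import (
    PhysioConstants,
    cbv_from_co,
    estimate_kw,
    normalize_well_counts,
    plasma_to_wholeblood_water,
)
from oxykin.synthetic import (
    CohortScenario,
    GroundTruth,
    InhalationProfile,
    generate_cohort,
    make_inhalation_aif,
    simulate_blood_samples,
    simulate_co_scan,
    simulate_dual_scan,
)


class TestInhalationAif:
    def test_zero_before_onset(self):
        prof = InhalationProfile(onset=1.0, duration=8.0)
        aif = make_inhalation_aif(prof)
        assert np.all(aif.values[aif.times < 1.0] == 0.0)

    def test_fast_rise_approaches_step(self):
        prof = InhalationProfile(rise_time_constant=1e-4, plateau_level=50.0)
        aif = make_inhalation_aif(prof)
        inside = (aif.times > 0.1) & (aif.times < prof.duration)
        np.testing.assert_allclose(aif.values[inside], 50.0, rtol=1e-6)

    def test_end_of_inhalation_value(self):
        prof = InhalationProfile(duration=8.0, rise_time_constant=2.0, plateau_level=100.0)
        aif = make_inhalation_aif(prof)
        expected = 100.0 * (1.0 - np.exp(-4.0))
        assert aif(8.0) == pytest.approx(expected, rel=1e-9)

    def test_nonnegative_and_washout_decays(self):
        aif = make_inhalation_aif(InhalationProfile())
        assert np.all(aif.values >= 0.0)
        tail = aif.values[aif.times > 8.0]
        assert np.all(np.diff(tail) <= 1e-12)


@pytest.fixture(scope="module")
def aif():
    return make_inhalation_aif(
        InhalationProfile(onset=0.25, duration=5.75, rise_time_constant=2.0, plateau_level=80.0),
        t_end=6.0,
    )


class TestBloodSampleSimulation:
    def test_noise_free_round_trip(self, aif, consts):
        from oxykin.kinetics import metabolized_water_curve

        truth = GroundTruth(kw=0.33)
        s = simulate_blood_samples(aif, truth, noise_cv=0.0, constants=consts)
        wb, plasma = normalize_well_counts(s, consts.lambda_decay)
        water = plasma_to_wholeblood_water(plasma, consts.plasma_wb_water_ratio)
        np.testing.assert_allclose(wb.values, aif(s.draw_times), rtol=1e-12)
        np.testing.assert_allclose(
            water.values, metabolized_water_curve(aif, truth.kw)(s.draw_times), rtol=1e-12
        )

    def test_zero_kw_gives_zero_plasma_water(self, aif, consts):
        truth = GroundTruth(kw=0.0)
        s = simulate_blood_samples(aif, truth, noise_cv=0.0, constants=consts)
        assert np.all(s.plasma_counts == 0.0)

    def test_seeded_determinism(self, aif, consts):
        truth = GroundTruth(kw=0.33)
        s1 = simulate_blood_samples(aif, truth, noise_cv=0.05, seed=42, constants=consts)
        s2 = simulate_blood_samples(aif, truth, noise_cv=0.05, seed=42, constants=consts)
        np.testing.assert_array_equal(s1.wb_counts, s2.wb_counts)
        np.testing.assert_array_equal(s1.plasma_counts, s2.plasma_counts)

    def test_negative_noise_rejected(self, aif):
        with pytest.raises(ValueError):
            simulate_blood_samples(aif, GroundTruth(), noise_cv=-0.1)


class TestDualScanSimulation:
    def test_identical_truth_gives_identical_clean_tacs(self, consts):
        t1 = GroundTruth(f=1.0, oef=0.5, seed=1)
        t2 = GroundTruth(f=1.0, oef=0.5, seed=2)  # different seed, zero noise
        a = simulate_dual_scan(t1, constants=consts)
        b = simulate_dual_scan(t2, constants=consts)
        np.testing.assert_array_equal(a[0].activities, b[0].activities)
        np.testing.assert_array_equal(a[1].activities, b[1].activities)

    def test_noise_variance_scales_inversely_with_frame_duration(self, consts):
        from oxykin.kinetics import FrameSchedule
        from oxykin.synthetic import _frame_noise

        rng = np.random.default_rng(0)
        short = FrameSchedule.uniform(500.0, 0.5)
        noise_short = _frame_noise(rng, short, 1.0)
        rng = np.random.default_rng(0)
        long = FrameSchedule.uniform(1000.0, 1.0)
        noise_long = _frame_noise(rng, long, 1.0)
        assert np.var(noise_short) == pytest.approx(2.0 * np.var(noise_long), rel=0.1)

    def test_aif_conservation_on_generated_set(self, consts):
        _, _, aifs, _ = simulate_dual_scan(GroundTruth(), constants=consts)
        resid = aifs.total.values - (aifs.water.values + aifs.oxygen.values)
        assert np.max(np.abs(resid)) < 1e-10

    def test_oxygen_aif_plateaus_while_total_keeps_rising(self, consts):
        # with kw = 0.33 the oxygen component levels off after ~3 min while
        # the total nearly doubles over the rest of the inhalation, and the
        # water component overtakes the oxygen component mid-inhalation
        _, _, aifs, _ = simulate_dual_scan(GroundTruth(kw=0.33), constants=consts)
        t = aifs.total.times
        in_3_8 = (t >= 3.0) & (t <= 8.0)
        oxy = aifs.oxygen.values[in_3_8]
        assert (oxy.max() - oxy.min()) / oxy.max() < 0.2
        assert aifs.total(8.0) > 1.5 * aifs.total(3.0)
        crossing = t[np.argmax(aifs.water.values > aifs.oxygen.values)]
        assert 2.5 < crossing < 5.5


class TestCoScanSimulation:
    def test_round_trip_recovers_cbv(self):
        truth = GroundTruth(cbv=0.051)
        tissue, lv = simulate_co_scan(truth)
        assert cbv_from_co(tissue, lv) == pytest.approx(truth.cbv, rel=1e-12)

    def test_zero_cbv_gives_zero_tissue(self):
        tissue, _ = simulate_co_scan(GroundTruth(cbv=0.0))
        assert np.all(tissue.activities == 0.0)

    def test_seeded_repeatability(self):
        truth = GroundTruth(cbv=0.05)
        a, _ = simulate_co_scan(truth, seed=9, noise_scale=0.5)
        b, _ = simulate_co_scan(truth, seed=9, noise_scale=0.5)
        np.testing.assert_array_equal(a.activities, b.activities)


class TestCohort:
    def test_reproducible_from_seed(self, consts):
        b1 = generate_cohort(seed=11, n_per_group={"HIE": 2, "non-operated": 1, "sham": 0})
        b2 = generate_cohort(seed=11, n_per_group={"HIE": 2, "non-operated": 1, "sham": 0})
        assert b1.truth_table.equals(b2.truth_table)
        for s1, s2 in zip(b1.sessions, b2.sessions):
            np.testing.assert_array_equal(
                s1.o2_tacs["ipsi"].activities, s2.o2_tacs["ipsi"].activities
            )

    def test_no_depression_makes_hie_match_control(self, consts):
        scenario = CohortScenario(day2_depression=1.0, oef_elevation_day2=1.0, animal_cv=0.0)
        bundle = generate_cohort(scenario, n_per_group={"HIE": 1, "non-operated": 1, "sham": 0})
        tt = bundle.truth_table
        hie = tt[(tt.group == "HIE") & (tt.day == 2)]
        ratio = (
            hie[hie.hemisphere == "ipsi"].f.values / hie[hie.hemisphere == "contra"].f.values
        )
        assert ratio == pytest.approx(1.0)

    def test_truth_nadir_at_day_two(self):
        scenario = CohortScenario(animal_cv=0.0)
        bundle = generate_cohort(scenario, n_per_group={"HIE": 1, "non-operated": 0, "sham": 0})
        tt = bundle.truth_table
        ipsi = tt[(tt.hemisphere == "ipsi")].set_index("day")
        assert ipsi.f.idxmin() == 2
        assert ipsi.cmro2.idxmin() == 2

    def test_control_maturation_factors(self):
        scenario = CohortScenario(animal_cv=0.0)
        bundle = generate_cohort(scenario, n_per_group={"HIE": 0, "non-operated": 1, "sham": 0})
        tt = bundle.truth_table
        contra = tt[tt.hemisphere == "contra"].set_index("day")
        assert contra.f[14] / contra.f[0] == pytest.approx(2.5, rel=1e-9)
        assert contra.cmro2[14] / contra.cmro2[0] == pytest.approx(2.0, rel=1e-9)
        assert np.all(np.diff(contra.f.sort_index().values) > 0)

    def test_generated_truths_within_physiological_bounds(self):
        bundle = generate_cohort(seed=3, n_per_group={"HIE": 2, "non-operated": 2, "sham": 1})
        tt = bundle.truth_table
        assert (tt.f > 0).all()
        assert tt.oef.between(0, 1).all()
        assert tt.cbv.between(0, 0.5).all()
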