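"""Microsimulation engine: initialization, annual cycles, conservation,
and closed-form oracles."""

import numpy as np
import pytest

from crcsim import (
    DiseaseParams,
    HealthState,
    Person,
    initialize_cohort,
    simulate_lifetime,
    step_year,
)
from crcsim.lifetable import expected_life_years, life_years_variance
from crcsim.natural_history import (
    NO_SCREENING,
    EventType,
    ScreeningPolicy,
    _advance_cycle,
    _Recorder,
)
from crcsim.screening import StrategyRule
from crcsim.states import AdenomaTier, Group
from crcsim.tables import TEST_PERFORMANCE, status_quo_profile


def _params(zero: DiseaseParams, **overrides) -> DiseaseParams:
    return zero.with_updates(**overrides)


class TestInitializeCohort:
    def test_rejects_bad_inputs(self, zero_disease, white_men):
        with pytest.raises(ValueError, match="cohort size"):
            initialize_cohort(0, white_men, 40, zero_disease, 1)
        with pytest.raises(ValueError, match="unknown group"):
            initialize_cohort(5, "Martian men", 40, zero_disease, 1)

    def test_zero_rates_all_lesion_free(self, zero_disease, white_men):
        coh = initialize_cohort(10, white_men, 40, zero_disease, 3)
        assert len(coh) == 10
        assert coh.age == 40
        assert np.all(coh.state == HealthState.NO_LESION)
        assert np.all(coh.alive)

    def test_deterministic(self, nominal_params, white_men):
        a = initialize_cohort(2000, white_men, 40, nominal_params, 9)
        b = initialize_cohort(2000, white_men, 40, nominal_params, 9)
        np.testing.assert_array_equal(a.state, b.state)
        np.testing.assert_array_equal(a.origin, b.origin)

    def test_geometric_accumulation_oracle(self, zero_disease, white_men):
        """With a single onset rate p and no growth, the fraction with any
        adenoma at 40 is 1-(1-p)^20 (closed-form geometric accumulation
        over the 20 burn-in years)."""
        p = 0.01
        params = _params(zero_disease, adenoma_onset=np.full(7, p))
        n = 50_000
        coh = initialize_cohort(n, white_men, 40, params, 17)
        frac = float((coh.state == HealthState.ADENOMA_DIMINUTIVE).mean())
        expected = 1 - (1 - p) ** 20
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestStepYear:
    def test_zero_rates_absorbing(self, zero_disease):
        person = Person(0, 50)
        out = step_year(person, zero_disease, np.random.default_rng(0))
        assert out.state is HealthState.NO_LESION
        assert out.age == 51

    def test_forced_transition_chain(self, zero_disease):
        params = _params(zero_disease, large_to_preclinical=1.0)
        person = Person(0, 50, HealthState.ADENOMA_LARGE)
        out = step_year(person, params, np.random.default_rng(0))
        assert out.state is HealthState.PRECLINICAL_CRC_I

    def test_rejects_dead_person(self, zero_disease):
        person = Person(0, 50, HealthState.DEAD_OTHER)
        with pytest.raises(ValueError, match="living"):
            step_year(person, zero_disease, np.random.default_rng(0))

    def test_growth_fraction_binomial_oracle(self, zero_disease, white_men):
        """One cycle moves a DIMINUTIVE->SMALL fraction matching the rate."""
        g = 0.1
        params = _params(zero_disease, growth_dim_to_small=g)
        n = 100_000
        coh = initialize_cohort(n, white_men, 40, zero_disease, 21)
        coh.state[:] = HealthState.ADENOMA_DIMINUTIVE
        _advance_cycle(coh, params, NO_SCREENING, _Recorder(), burn_in=False)
        frac = float((coh.state == HealthState.ADENOMA_SMALL).mean())
        se = np.sqrt(g * (1 - g) / n)
        assert abs(frac - g) < 3 * se


class TestSimulateLifetime:
    def test_zero_disease_only_other_cause_deaths(self, zero_disease, white_men):
        coh = initialize_cohort(2000, white_men, 40, zero_disease, 5)
        led = simulate_lifetime(coh, zero_disease)
        events = set(led.frame["event"].unique())
        assert events <= {EventType.DEATH_OTHER.value, EventType.ALIVE_AT_END.value}
        assert led.conservation_ok()

    def test_crc_cases_definitional(self, truth_white_men):
        sc = truth_white_men.scenario()
        led = sc.run("no_screening", 5000, 7)
        dx = led.events(EventType.CRC_DIAGNOSIS)
        assert led.count(EventType.CRC_DIAGNOSIS) == len(dx)
        # one diagnosis per person at most (never returns to preclinical)
        assert dx["person_id"].is_unique
        assert led.conservation_ok()

    def test_bit_identical_replay(self, truth_white_men):
        sc = truth_white_men.scenario()
        a = sc.run("status_quo", 3000, 13)
        b = sc.run("status_quo", 3000, 13)
        assert a.frame.equals(b.frame)

    def test_life_years_match_life_table_closed_form(self, zero_disease, white_men):
        """With all disease rates zero, simulated life years equal the
        discrete life-table expectation within 3 Monte-Carlo SE."""
        n = 30_000
        coh = initialize_cohort(n, white_men, 40, zero_disease, 29)
        led = simulate_lifetime(coh, zero_disease, max_age=100)
        ly = led.person_table()["life_years"].to_numpy()
        q = zero_disease.other_cause_mortality
        expected = expected_life_years(q, 40, 100)
        se = np.sqrt(life_years_variance(q, 40, 100) / n)
        assert abs(ly.mean() - expected) < 3 * se

    def test_permutation_invariance(self, truth_white_men):
        """Permuting person order leaves summary statistics unchanged:
        draws are keyed by person id, not array position."""
        sc = truth_white_men.scenario()
        coh = sc.make_cohort(2000, 3)
        perm = np.random.default_rng(0).permutation(2000)
        led_a = simulate_lifetime(coh, sc.disease, sc.policy_for("status_quo"))
        led_b = simulate_lifetime(coh.permuted(perm), sc.disease, sc.policy_for("status_quo"))
        for ev in EventType:
            assert led_a.count(ev) == led_b.count(ev)

    def test_incidence_monotone_in_sensitivity(self, truth_white_men):
        """Raising every colonoscopy sensitivity (0 vs 1) cannot raise
        cumulative clinical CRC incidence under common random numbers."""
        sc_lo = truth_white_men.scenario()
        for f in ("sens_diminutive", "sens_small", "sens_large", "sens_crc"):
            for m in sc_lo.performance:
                setattr(sc_lo.performance[m], f, 0.0)
        sc_hi = truth_white_men.scenario()
        for f in ("sens_diminutive", "sens_small", "sens_large", "sens_crc"):
            for m in sc_hi.performance:
                setattr(sc_hi.performance[m], f, 1.0)
        cases = {}
        for name, sc in (("lo", sc_lo), ("hi", sc_hi)):
            led = sc.run("colonoscopy_only", 4000, 37)
            cases[name] = led.count(EventType.CRC_DIAGNOSIS)
        assert cases["hi"] <= cases["lo"]

    def test_conservation_under_screening(self, truth_white_men):
        sc = truth_white_men.scenario()
        for strat in ("status_quo", "ctc_only", "fit_only"):
            led = sc.run(strat, 2000, 19)
            assert led.conservation_ok(), strat

    def test_ledger_round_trip(self, truth_white_men, tmp_path):
        sc = truth_white_men.scenario()
        led = sc.run("ctc_only", 500, 23)
        path = tmp_path / "ledger.tsv"
        led.write(path)
        from crcsim.natural_history import EventLedger

        back = EventLedger.read(path, n=led.n, start_age=led.start_age, max_age=led.max_age)
        assert back.frame["event"].equals(led.frame["event"])
        assert back.conservation_ok()


class TestSurveillanceHandoff:
    def test_no_routine_screening_after_polypectomy_with_history(self, truth_white_men):
        """A small/large polypectomy moves the person from routine
        screening into interval surveillance: after it, the ledger shows
        surveillance colonoscopies but no further routine screens."""
        sc = truth_white_men.scenario()
        led = sc.run("colonoscopy_only", 4000, 41)
        polyps = led.events(EventType.POLYPECTOMY)
        tiered = polyps[polyps["detail"] >= int(HealthState.ADENOMA_SMALL)]
        first_tiered = tiered.groupby("person_id")["age"].min()
        screens = led.events(EventType.SCREEN).set_index("person_id")
        assert len(first_tiered) > 0
        for person, age0 in first_tiered.items():
            if person in screens.index:
                ages = np.atleast_1d(screens.loc[person, "age"])
                assert ages.max() <= age0

    def test_diagnostic_colonoscopies_bounded_by_positives(self, truth_white_men):
        """Diagnostic colonoscopies can only follow positive non-colonoscopy
        tests, so their count never exceeds the non-colonoscopy test count."""
        sc = truth_white_men.scenario()
        for strat in ("ctc_only", "fit_only", "mtsdna_only", "status_quo"):
            led = sc.run(strat, 3000, 43)
            screens = led.events(EventType.SCREEN)
            noncolo = int((screens["detail"] != 0).sum())
            assert led.count(EventType.DIAGNOSTIC_COLONOSCOPY) <= noncolo, strat
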