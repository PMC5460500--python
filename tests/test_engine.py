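import numpy as np
import pytest
from scipy import stats

from cmost import Individual, Lesion, LifeTable, simulate_population
from cmost import _kernel as K
from cmost.engine import (cancer_stage_at, initiate_cancer,
                          load_location_distribution, partition_dwell,
                          resolve_death, step_natural_history,
                          survival_to_quarterly_hazard)
from cmost.params import AnchorCDF


def tallies_equal(a, b, keys=None):
    keys = keys or a.tallies.keys()
    return all(np.array_equal(a.tallies[k], b.tallies[k]) for k in keys)


class TestLifeTable:
    def test_probabilities_in_range(self, life_table):
        assert np.all(life_table.qx >= 0) and np.all(life_table.qx <= 1)

    def test_death_cdf_monotone_ends_at_one(self, life_table):
        cdf = life_table.natural_death_cdf()
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == 1.0

    def test_bad_table_rejected(self):
        with pytest.raises(ValueError):
            LifeTable(qx=np.full(101, 1.5))
        with pytest.raises(ValueError):
            LifeTable(qx=np.zeros(50))


class TestSimulatePopulation:
    def test_no_lesion_params_give_zero_disease(self, no_lesion_params,
                                                life_table):
        r = simulate_population(no_lesion_params, life_table, None,
                                n=20_000, seed=3)
        assert r.total_cases == 0
        assert r.total_crc_deaths == 0
        assert r.misc[K.M_INITIATED] == 0

    def test_life_table_survivorship_without_crc(self, no_lesion_params,
                                                 life_table):
        """chi-square agreement of simulated deaths with the life table."""
        n = 100_000
        r = simulate_population(no_lesion_params, life_table, None, n=n, seed=3)
        cdf = life_table.natural_death_cdf()
        # expected deaths per age-year from the closed-form death CDF
        by_year = np.diff(np.concatenate([[0.0], cdf]))
        exp_age = by_year.reshape(-1, 4).sum(axis=1) * n
        obs_age = r.other_death[:101]
        keep = exp_age > 20
        chi2 = np.sum((obs_age[keep] - exp_age[keep]) ** 2 / exp_age[keep])
        dof = keep.sum() - 1
        assert stats.chi2.sf(chi2, dof) > 1e-4

    def test_same_seed_bit_identical(self, default_params, life_table):
        a = simulate_population(default_params, life_table, None, n=4000, seed=9)
        b = simulate_population(default_params, life_table, None, n=4000, seed=9)
        assert tallies_equal(a, b)

    def test_different_seed_differs(self, default_params, life_table):
        a = simulate_population(default_params, life_table, None, n=4000, seed=9)
        b = simulate_population(default_params, life_table, None, n=4000, seed=10)
        assert not tallies_equal(a, b)

    def test_n_must_be_positive(self, default_params, life_table):
        with pytest.raises(ValueError):
            simulate_population(default_params, life_table, None, n=0, seed=1)

    def test_conservation_of_adenomas(self, default_params, life_table):
        r = simulate_population(default_params, life_table, None,
                                n=20_000, seed=5)
        m = r.misc
        assert m[K.M_INITIATED] == pytest.approx(
            m[K.M_REGRESSED] + m[K.M_RESECTED] + m[K.M_TOCANCER]
            + m[K.M_REMAIN], abs=0.5)

    def test_monotone_in_a0(self, default_params, life_table):
        lo = simulate_population(default_params, life_table, None,
                                 n=40_000, seed=11)
        hi = simulate_population(default_params.replace(a0=default_params.a0 * 2),
                                 life_table, None, n=40_000, seed=11)
        assert (hi.prevalence("early", "A", 60)
                > lo.prevalence("early", "A", 60))

    def test_origin_pathways_switch_off(self, default_params, life_table,
                                        unit_anchors):
        p = default_params.replace(stage_cancer_risk=(0.0,) * 5,
                                   direct_cancer_risk=(0.0,) * 13,
                                   **unit_anchors)
        r = simulate_population(p, life_table, None, n=20_000, seed=2)
        assert r.misc[K.M_ORIGIN_FAST] == 0
        assert r.misc[K.M_ORIGIN_DIRECT] == 0
        assert r.misc[K.M_ORIGIN_ADE] > 0


class TestSojournSampler:
    def test_moments(self):
        years = K.sample_sojourns(42, 100_000, 12.0, 2.0) / 4.0
        assert years.mean() == pytest.approx(3.0, abs=0.01)
        assert years.std() == pytest.approx(0.5, abs=0.01)

    def test_truncation_never_nonpositive(self):
        # heavy truncation regime: mean close to zero
        assert K.sample_sojourns(7, 1_000_000, 0.4, 4.0).min() >= 1


class TestDwellPartition:
    def test_boundaries_monotone_and_capped(self):
        for soj in (1, 3, 8, 20):
            for s in (1, 2, 3, 4):
                cum = partition_dwell(soj, s, (0.45, 0.3, 0.15, 0.10))
                assert all(0 <= c <= soj for c in cum)
                assert all(b >= a for a, b in zip(cum, cum[1:]))
                assert cum[s - 1] == soj   # symptomatic stage absorbs the rest

    def test_stage_never_exceeds_symptomatic(self, default_params, rng):
        les = initiate_cancer(5, "direct", 100, default_params, rng)
        stages = [cancer_stage_at(les, 100 + e)
                  for e in range(les.sojourn_quarters)]
        assert max(stages) <= les.symptomatic_stage
        assert all(b >= a for a, b in zip(stages, stages[1:]))   # ratchet

    def test_unknown_origin_rejected(self, default_params, rng):
        with pytest.raises(ValueError):
            initiate_cancer(5, "spontaneous", 100, default_params, rng)


class TestReferenceStepper:
    def test_stage_one_regression_removes_lesion(self, default_params, rng):
        p = default_params.replace(b0=0.0, c0=0.0,
                                   stage_regression=(1.0, 0, 0, 0, 0, 0),
                                   a0=0.0, direct_cancer_risk=(0.0,) * 13)
        ind = Individual(sex=0, risk_multiplier=1.0, natural_death_quarter=400)
        ind.lesions.append(Lesion(kind="adenoma", segment=3, birth_quarter=10))
        loc = load_location_distribution()
        step_natural_history(ind, 12, p, loc, rng)
        assert ind.lesions[0].removed
        assert ind.counters["regressed"] == 1

    def test_stage_six_progression_yields_stage1_cancer(self, default_params,
                                                        rng):
        p = default_params.replace(b0=0.0, c0=1.0, c1=0.0, c2=0.0,
                                   stage_progression=(1,) * 6,
                                   stage_regression=(0.0,) * 6,
                                   stage_cancer_risk=(0.0,) * 5,
                                   a0=0.0, direct_cancer_risk=(0.0,) * 13)
        flat = AnchorCDF((0.0, 1.0), (1.0, 1.0))
        p = p.replace(adenoma_risk_anchors_advanced=flat)
        ind = Individual(sex=0, risk_multiplier=1.0, natural_death_quarter=400)
        les = Lesion(kind="adenoma", segment=3, birth_quarter=10,
                     adenoma_stage=6, mult_advanced=1.0)
        ind.lesions.append(les)
        step_natural_history(ind, 12, p, load_location_distribution(), rng)
        assert les.kind == "cancer"
        assert les.origin == "adenomatous"
        assert les.cancer_stage == 1

    def test_adenoma_stage_moves_by_at_most_one(self, default_params, rng):
        loc = load_location_distribution()
        ind = Individual(sex=1, risk_multiplier=2.0, natural_death_quarter=400)
        ind.lesions.append(Lesion(kind="adenoma", segment=2, birth_quarter=0,
                                  adenoma_stage=3, mult_early=5.0,
                                  mult_advanced=5.0))
        for q in range(4, 200):
            prev = ind.lesions[0].adenoma_stage
            kind_prev = ind.lesions[0].kind
            step_natural_history(ind, q, default_params, loc, rng)
            les = ind.lesions[0]
            if kind_prev == "adenoma" and les.kind == "adenoma" and not les.removed:
                assert abs(les.adenoma_stage - prev) <= 1

    def test_dead_individual_rejected(self, default_params, rng):
        ind = Individual(sex=0, risk_multiplier=1.0, natural_death_quarter=100,
                         alive=False)
        with pytest.raises(ValueError):
            step_natural_history(ind, 10, default_params,
                                 load_location_distribution(), rng)


class TestResolveDeath:
    def test_zero_survival_kills_in_diagnosis_quarter(self, rng):
        haz = survival_to_quarterly_hazard(np.array([1.0, 1.0, 1.0, 0.0]))
        ind = Individual(sex=0, risk_multiplier=1.0, natural_death_quarter=390,
                         diagnosis_quarter=200, diagnosis_stage=4)
        resolve_death(ind, 200, haz, rng)
        assert not ind.alive and ind.cause_of_death == "crc"

    def test_years_lost_nonnegative(self, rng):
        haz = survival_to_quarterly_hazard(np.array([0.0] * 4))
        ind = Individual(sex=0, risk_multiplier=1.0, natural_death_quarter=390,
                         diagnosis_quarter=200, diagnosis_stage=2)
        resolve_death(ind, 201, haz, rng)
        assert ind.years_lost >= 0
        assert ind.years_lost == pytest.approx((390 - 201) / 4.0)

    def test_no_crc_death_beyond_five_years(self, rng):
        haz = survival_to_quarterly_hazard(np.array([1e-12] * 4))
        ind = Individual(sex=0, risk_multiplier=1.0, natural_death_quarter=400,
                         diagnosis_quarter=100, diagnosis_stage=4)
        for q in range(121, 200):
            resolve_death(ind, q, haz, rng)
            assert ind.cause_of_death != "crc"


class TestMarkovOracle:
    def test_two_compartment_incidence(self, life_table, unit_anchors,
                                       default_params):
        """Constant-rate single-pathway model vs an independent discrete
        Markov computation of expected cancer initiations."""
        lam, mu = 0.004, 0.01
        p = default_params.replace(
            a0=2 * lam, a1=0.0, a2=0.0,          # sigmoid == a0/2 == lam
            b0=0.0,                               # no stage progression
            c0=1.0, c1=0.0, c2=0.0,               # advanced rate == 1
            stage_cancer_risk=(mu, 0, 0, 0, 0),   # stage-I fast cancer == mu
            stage_regression=(0.0,) * 6,
            stage_progression=(0.0,) * 6,
            direct_cancer_risk=(0.0,) * 13,
            sex_factors=(1.0, 1.0, 1.0), rectum_factors=(1.0, 1.0),
            **unit_anchors)
        n = 120_000
        # no CRC death feedback (survival == 1) and no adenoma removal at
        # diagnostic exams, so compartments evolve freely
        from cmost import EndoscopyModel
        endo = EndoscopyModel(detection_by_stage=(0.0,) * 6,
                              complication_p=(0.0,) * 4)
        r = simulate_population(p, life_table, None, n=n, seed=21,
                                survival5=np.ones(4), endoscopy=endo)
        # oracle: E[new cancers at quarter q] = lam * mu
        #         * sum_{q0<q} S(q0 alive path) (1-mu)^(q-q0-1), with death
        # independent of lesions -> weight by P(alive at q).
        cdf = life_table.natural_death_cdf()
        alive = np.concatenate([[1.0], 1.0 - cdf[:-1]])
        expected = 0.0
        qmax = K.MAX_Q
        decay = (1.0 - mu) ** np.arange(qmax)
        for q in range(1, qmax):
            q0 = np.arange(q)
            expected += alive[q] * lam * mu * decay[q - 1 - q0].sum()
        observed = r.misc[K.M_TOTAL_CANCERS] / n
        sd = np.sqrt(expected / n)   # Poisson-scale Monte-Carlo error
        assert observed == pytest.approx(expected, abs=4 * sd + 0.002)

    def test_dwell_times_geometric(self, life_table, unit_anchors,
                                   default_params):
        """With a constant fast-cancer hazard, adenoma dwell is geometric.

        The hazard is large enough that death-censoring of pending lesions
        is negligible."""
        mu = 0.1
        p = default_params.replace(
            a0=0.01, a1=0.0, a2=0.0, b0=0.0, c0=1.0, c1=0.0, c2=0.0,
            stage_cancer_risk=(mu, 0, 0, 0, 0), stage_regression=(0.0,) * 6,
            stage_progression=(0.0,) * 6, direct_cancer_risk=(0.0,) * 13,
            sex_factors=(1.0, 1.0, 1.0), rectum_factors=(1.0, 1.0),
            **unit_anchors)
        from cmost import EndoscopyModel
        endo = EndoscopyModel(detection_by_stage=(0.0,) * 6,
                              complication_p=(0.0,) * 4)
        r = simulate_population(p, life_table, None, n=60_000, seed=22,
                                survival5=np.ones(4), endoscopy=endo)
        h = r.dwell_hist
        total = h.sum()
        assert total > 2000
        emp = np.cumsum(h)[:61] / total          # P(dwell <= k quarters)
        exp = 1.0 - (1.0 - mu) ** np.arange(61)
        assert np.max(np.abs(emp - exp)) < 0.02
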