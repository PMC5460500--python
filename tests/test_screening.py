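import numpy as np
import pytest

from cmost import (EndoscopyModel, Individual, Lesion, ScreeningPlan,
                   StoolTestModel, simulate_population)
from cmost import _kernel as K
from cmost.screening import (Findings, SurveillanceRules, perform_colonoscopy,
                             perform_sigmoidoscopy, perform_stool_test,
                             schedule_surveillance)


def make_individual(*lesions):
    ind = Individual(sex=0, risk_multiplier=1.0, natural_death_quarter=400)
    ind.lesions.extend(lesions)
    return ind


class TestEndoscopyModel:
    def test_reach_distribution_sums_to_one(self):
        m = EndoscopyModel()
        assert m.reach_distribution().sum() == pytest.approx(1.0)
        assert m.sig_reach_distribution().sum() == pytest.approx(1.0)

    def test_cecal_reach_fraction(self, rng):
        """95% of colonoscopies reach the cecum, +-0.005 at 1e5 draws."""
        m = EndoscopyModel()
        cdf = np.cumsum(m.reach_distribution())
        reach = np.searchsorted(cdf, rng.random(100_000)) + 1
        assert np.mean(reach == 13) == pytest.approx(0.95, abs=0.005)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            EndoscopyModel(cecal_intubation=1.5)

    def test_flexure_penalty_applied(self):
        m = EndoscopyModel()
        inside = Lesion(kind="adenoma", segment=6, birth_quarter=0,
                        adenoma_stage=5)
        outside = Lesion(kind="adenoma", segment=5, birth_quarter=0,
                         adenoma_stage=5)
        assert m.detection(inside) == pytest.approx(
            m.detection(outside) * m.flexure_penalty)


class TestColonoscopy:
    def test_no_lesions_no_findings(self, rng):
        ind = make_individual()
        f = perform_colonoscopy(ind, EndoscopyModel(), rng)
        assert not f.any and not f.polypectomy

    def test_resection_completeness(self, rng):
        """Full reach + perfect detection empties the adenoma list."""
        m = EndoscopyModel(cecal_intubation=1.0,
                           detection_by_stage=(1.0,) * 6,
                           detection_cancer=1.0, flexure_penalty=1.0)
        lesions = [Lesion(kind="adenoma", segment=s, birth_quarter=0,
                          adenoma_stage=st)
                   for s, st in [(1, 1), (6, 3), (10, 5), (13, 6)]]
        ind = make_individual(*lesions)
        f = perform_colonoscopy(ind, m, rng)
        assert f.n_small + f.n_advanced == 4
        assert all(les.removed for les in ind.lesions)

    def test_polypectomy_doubles_perforation(self):
        """Perforation frequency 14/10^4 after polypectomy (7/10^4 base)."""
        m = EndoscopyModel(detection_by_stage=(1.0,) * 6,
                           complication_fatality=(0.0,) * 4)
        rng = np.random.default_rng(5)
        n = 200_000
        perfs = 0
        for _ in range(n):
            ind = make_individual(Lesion(kind="adenoma", segment=1,
                                         birth_quarter=0))
            f = perform_colonoscopy(ind, m, rng)
            assert f.polypectomy
            perfs += 3 in f.complications
        rate = perfs / n
        sd = np.sqrt(14e-4 / n)
        assert rate == pytest.approx(14e-4, abs=4 * sd)

    def test_dead_individual_rejected(self, rng):
        ind = make_individual()
        ind.alive = False
        with pytest.raises(ValueError):
            perform_colonoscopy(ind, EndoscopyModel(), rng)


class TestSigmoidoscopy:
    def test_cecum_lesion_never_detected(self):
        m = EndoscopyModel()
        rng = np.random.default_rng(2)
        for _ in range(2000):
            ind = make_individual(Lesion(kind="adenoma", segment=13,
                                         birth_quarter=0, adenoma_stage=6))
            f = perform_sigmoidoscopy(ind, m, rng)
            assert f.n_small + f.n_advanced + f.n_cancers == 0

    def test_no_resection_and_referral(self):
        m = EndoscopyModel(detection_by_stage=(1.0,) * 6, sig_penalty_early=1.0,
                           sig_penalty_advanced=1.0)
        rng = np.random.default_rng(3)
        ind = make_individual(Lesion(kind="adenoma", segment=1,
                                     birth_quarter=0, adenoma_stage=5))
        f = perform_sigmoidoscopy(ind, m, rng)
        assert f.referral
        assert not ind.lesions[0].removed

    def test_advanced_detection_penalty(self):
        """Advanced adenoma in rectum detected at 0.875 x colonoscopy prob."""
        m = EndoscopyModel()
        rng = np.random.default_rng(4)
        n = 60_000
        hits = 0
        for _ in range(n):
            ind = make_individual(Lesion(kind="adenoma", segment=1,
                                         birth_quarter=0, adenoma_stage=5))
            hits += perform_sigmoidoscopy(ind, m, rng).n_advanced
        expect = 0.875 * m.detection_by_stage[4]
        assert hits / n == pytest.approx(expect, abs=4 * np.sqrt(expect / n))


class TestStoolTest:
    def test_perfect_specificity_no_lesions_always_negative(self, rng):
        m = StoolTestModel(specificity=1.0)
        for _ in range(2000):
            pos, _ = perform_stool_test(make_individual(), m, rng)
            assert not pos

    def test_zero_sensitivity_equivalent_to_no_screening(self, default_params,
                                                         life_table):
        """Paired-seed tally identity for disease outcomes."""
        stool = StoolTestModel(sensitivity_early=0.0, sensitivity_advanced=0.0,
                               sensitivity_cancer=0.0, specificity=1.0)
        plan = ScreeningPlan(modality="fobt", start_age=50, stop_age=75,
                             interval_y=1)
        a = simulate_population(default_params, life_table, plan, n=8000,
                                seed=13, stool=stool)
        b = simulate_population(default_params, life_table, None, n=8000,
                                seed=13)
        for key in ("inc", "crc_death", "py", "other_death", "ge1_early"):
            assert np.array_equal(a.tallies[key], b.tallies[key]), key


class TestSurveillance:
    def test_no_findings_no_surveillance(self):
        assert schedule_surveillance(Findings()) is None

    def test_advanced_adenoma_three_years(self):
        assert schedule_surveillance(Findings(n_advanced=1)) == 3

    def test_three_small_adenomas_three_years(self):
        assert schedule_surveillance(Findings(n_small=3)) == 3

    def test_small_findings_five_years(self):
        assert schedule_surveillance(Findings(n_small=2)) == 5

    def test_post_crc_one_year(self):
        assert schedule_surveillance(Findings(n_cancers=1)) == 1

    def test_custom_rules(self):
        rules = SurveillanceRules(advanced_or_multiple_y=2, small_y=7)
        assert schedule_surveillance(Findings(n_advanced=2), rules) == 2
        assert schedule_surveillance(Findings(n_small=1), rules) == 7


class TestScreeningPlan:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScreeningPlan(modality="colonoscopy", start_age=70, stop_age=60)
        with pytest.raises(ValueError):
            ScreeningPlan(modality="colonoscopy", interval_y=0)
        with pytest.raises(ValueError):
            ScreeningPlan(modality="colonoscopy", adherence=1.2)
        with pytest.raises(ValueError):
            ScreeningPlan(modality="mri")

    def test_screen_quarters(self):
        plan = ScreeningPlan(modality="colonoscopy", start_age=50,
                             stop_age=75, interval_y=10)
        assert plan.screen_quarters() == [200, 240, 280]

    def test_adherence_scales_procedures(self, default_params, life_table):
        plans = {a: ScreeningPlan(modality="colonoscopy", start_age=50,
                                  stop_age=75, interval_y=10, adherence=a,
                                  surveillance=False)
                 for a in (0.5, 1.0)}
        runs = {a: simulate_population(default_params, life_table, pl,
                                       n=30_000, seed=17)
                for a, pl in plans.items()}
        full = runs[1.0].procedures[:, K.P_COLO, K.CTX_SCREEN].sum()
        half = runs[0.5].procedures[:, K.P_COLO, K.CTX_SCREEN].sum()
        assert half / full == pytest.approx(0.5, abs=0.02)

    def test_no_screening_invariant_to_screening_parameters(self,
                                                            default_params,
                                                            life_table):
        """The baseline arm ignores plan and stool-test settings entirely
        (diagnostic endoscopy quality is a care parameter, not screening)."""
        a = simulate_population(default_params, life_table, None, n=5000,
                                seed=19)
        zero = ScreeningPlan(modality="colonoscopy", start_age=50,
                             stop_age=75, interval_y=5, adherence=0.0)
        b = simulate_population(default_params, life_table, zero, n=5000,
                                seed=19)
        c = simulate_population(default_params, life_table, None, n=5000,
                                seed=19,
                                stool=StoolTestModel(sensitivity_cancer=0.9))
        for other in (b, c):
            assert all(np.array_equal(a.tallies[k], other.tallies[k])
                       for k in a.tallies)


class TestKernelComplicationRates:
    def test_baseline_rates_no_polypectomy(self, no_lesion_params, life_table):
        """4/11/3/7 per 10,000 colonoscopies without polypectomy."""
        plan = ScreeningPlan(modality="colonoscopy", start_age=50, stop_age=59,
                             interval_y=1, surveillance=False)
        endo = EndoscopyModel(complication_fatality=(0.0,) * 4)
        r = simulate_population(no_lesion_params, life_table, plan,
                                n=110_000, seed=23, endoscopy=endo)
        total = r.procedures[:, K.P_COLO, :].sum()
        assert total > 1_000_000
        rates = r.compl_counts / total
        for rate, target in zip(rates, (4e-4, 11e-4, 3e-4, 7e-4)):
            sd = np.sqrt(target / total)
            assert rate == pytest.approx(target, abs=4 * sd)

    def test_rates_double_with_polypectomy(self, default_params, life_table):
        """Observed complication frequency matches the polypectomy-share
        mixture of baseline and doubled rates."""
        from cmost.params import AnchorCDF
        flat = AnchorCDF((0.0, 1.0), (1.0, 1.0))
        p = default_params.replace(a0=0.3, a1=1.0,   # frequent new adenomas
                                   individual_risk_anchors=flat)
        endo = EndoscopyModel(detection_by_stage=(1.0,) * 6,
                              flexure_penalty=1.0, cecal_intubation=1.0,
                              complication_fatality=(0.0,) * 4)
        plan = ScreeningPlan(modality="colonoscopy", start_age=50, stop_age=59,
                             interval_y=1, surveillance=False)
        r = simulate_population(p, life_table, plan, n=100_000, seed=29,
                                endoscopy=endo)
        total = r.procedures[:, K.P_COLO, :].sum()
        polyp_share = r.polypectomies.sum() / total
        assert total > 800_000
        assert polyp_share > 0.5
        rates = r.compl_counts / total
        for rate, base in zip(rates, (4e-4, 11e-4, 3e-4, 7e-4)):
            target = base * (1.0 + polyp_share)
            sd = np.sqrt(target / total)
            assert rate == pytest.approx(target, abs=4 * sd)
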