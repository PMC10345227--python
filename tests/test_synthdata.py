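"""Cohort generator: structure, trends, calibration, determinism."""

import dataclasses

import numpy as np
import pytest

import hmotriad as ht
from hmotriad.synthdata import (ConfigError, _default_hmo_trends,
                                _default_outcome_models)


class TestConfig:
    def test_invalid_fields_named_in_error(self):
        with pytest.raises(ConfigError, match="p_singleton"):
            ht.default_config(p_singleton=1.5).validate()
        with pytest.raises(ConfigError, match="age_range"):
            ht.default_config(age_range_months=(0.0, 13.0)).validate()
        with pytest.raises(ConfigError, match="max_visits"):
            ht.default_config(max_visits=0).validate()

    def test_single_subject_single_visit(self):
        cohort = ht.generate_cohort(ht.default_config(n_subjects=1,
                                                      p_singleton=1.0, seed=0))
        assert len(cohort) == 1


class TestCohortStructure:
    def test_default_size_near_170_visits(self):
        totals = [len(ht.generate_cohort(ht.default_config(seed=s)))
                  for s in range(8)]
        # 105 subjects, 60 expected singletons: ~170 visits on average
        assert 150 <= np.mean(totals) <= 190

    def test_deterministic_under_seed(self):
        a = ht.generate_cohort(ht.default_config(seed=9))
        b = ht.generate_cohort(ht.default_config(seed=9))
        assert a.samples == b.samples

    def test_atetra_constant_within_mother(self, cohort105):
        by_subject = {}
        for s in cohort105:
            det = s.hmo["atetra"] > ht.ATETRA_LOD_MGL
            by_subject.setdefault(s.subject_id, set()).add(det)
        assert all(len(v) == 1 for v in by_subject.values())

    def test_visits_ordered_by_age(self, cohort105):
        by_subject = {}
        for s in cohort105:
            by_subject.setdefault(s.subject_id, []).append(
                (s.visit_index, s.age_months))
        for visits in by_subject.values():
            visits.sort()
            ages = [a for _, a in visits]
            assert ages == sorted(ages)


class TestHMOSimulation:
    def test_atetra_negative_mother_is_zero(self):
        rng = np.random.default_rng(0)
        prof = ht.simulate_hmo(6.0, False, _default_hmo_trends(), rng)
        assert prof["atetra"] == 0.0

    def test_age_trend_signs(self):
        rng = np.random.default_rng(1)
        params = _default_hmo_trends()
        m = {h: {} for h in ("3fl", "2fl")}
        for age in (3.0, 10.0):
            draws = [ht.simulate_hmo(age, False, params, rng)
                     for _ in range(2000)]
            for h in m:
                m[h][age] = np.mean([d[h] for d in draws])
        assert m["3fl"][10.0] > m["3fl"][3.0]   # 3-FL rises with age
        assert m["2fl"][10.0] < m["2fl"][3.0]   # 2'-FL falls with age

    def test_3fl_group_means_match_calibration(self):
        cohort = ht.generate_cohort(ht.default_config(n_subjects=3000, seed=4))
        pos = [s.hmo["3fl"] for s in cohort if s.hmo["atetra"] > 4.4]
        neg = [s.hmo["3fl"] for s in cohort if s.hmo["atetra"] <= 4.4]
        assert np.mean(pos) == pytest.approx(1243.26, rel=0.06)
        assert np.mean(neg) == pytest.approx(1550.97, rel=0.06)

    def test_negative_age_errors(self):
        with pytest.raises(ValueError):
            ht.simulate_hmo(-1.0, True, _default_hmo_trends(),
                            np.random.default_rng(0))


class TestMicrobiotaSimulation:
    def test_compositions_close(self, cohort105):
        for s in cohort105:
            total = sum(s.microbiota.abundances.values()) + s.microbiota.remainder
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_bif_longum_mean_near_calibration(self):
        rng = np.random.default_rng(2)
        params = ht.default_config().microbiota_params
        ages = rng.uniform(2.9, 12.0, size=1000)
        means = [ht.simulate_microbiota(a, params, rng)["bif_longum"]
                 for a in ages]
        assert np.mean(means) == pytest.approx(0.38, abs=0.04)

    def test_symmetric_weights_give_equal_means(self):
        rng = np.random.default_rng(3)
        params = {s: ht.SpeciesParams(weight=0.5) for s in ht.SPECIES_NAMES}
        draws = np.array([[ht.simulate_microbiota(6.0, params, rng)[s]
                           for s in ht.SPECIES_NAMES] for _ in range(4000)])
        means = draws.mean(axis=0)
        assert means.max() - means.min() < 0.02

    def test_nonpositive_weight_errors(self):
        params = dict(ht.default_config().microbiota_params)
        params["bif_longum"] = ht.SpeciesParams(weight=0.0)
        with pytest.raises(ValueError):
            ht.simulate_microbiota(6.0, params, np.random.default_rng(0))


def _zero_fixed_row():
    row = {c: 0.0 for c in ht.COVARIATE_NAMES}
    row.update({f"z_{h}": 0.0 for h in ht.HMO_NAMES})
    row.update({f"z_{s}": 0.0 for s in ht.SPECIES_NAMES})
    row["atetra_pos"] = 0.0
    return row


class TestMSELSimulation:
    def test_degenerate_noise_returns_intercept(self):
        models = {o: ht.OutcomeModel(intercept=50.0, sigma_subject=0.0,
                                     sigma_resid=0.0) for o in ht.MSEL_OUTCOMES}
        scores = ht.simulate_msel(_zero_fixed_row(), models,
                                  {o: 0.0 for o in ht.MSEL_OUTCOMES},
                                  np.random.default_rng(0))
        assert all(scores[o] == 50.0 for o in ht.MSEL_OUTCOMES)

    def test_known_intercept_is_exact(self):
        models = {o: ht.OutcomeModel(intercept=48.0, sigma_subject=0.0,
                                     sigma_resid=0.0) for o in ht.MSEL_OUTCOMES}
        row = _zero_fixed_row()
        row["z_2fl"] = 1.5
        models["composite"] = dataclasses.replace(
            models["composite"],
            beta_hmo=(2.0,) + (0.0,) * 7, sigma_resid=0.0)
        scores = ht.simulate_msel(row, models, {"composite": 3.0},
                                  np.random.default_rng(0))
        assert scores["composite"] == pytest.approx(48.0 + 2.0 * 1.5 + 3.0)

    def test_missing_predictor_errors(self):
        row = _zero_fixed_row()
        del row["z_2fl"]
        models = {o: ht.OutcomeModel() for o in ht.MSEL_OUTCOMES}
        with pytest.raises(ValueError, match="missing"):
            ht.simulate_msel(row, models, {}, np.random.default_rng(0))

    def test_ols_recovers_planted_interaction(self):
        """On 2000 visits a planted gamma=0.5 is recovered by OLS within 3 SE."""
        models = _default_outcome_models()
        models["composite"] = ht.OutcomeModel(
            intercept=108.0, gamma=(ht.GammaSpec("3sl", "bif_longum", 0.5),),
            sigma_subject=0.0, sigma_resid=7.0)
        cfg = ht.default_config(n_subjects=1100, p_singleton=0.4, seed=6,
                                outcome_models=models)
        cohort = ht.generate_cohort(cfg)
        z3 = np.array([s.hmo["3sl"] for s in cohort])
        zl = np.array([s.microbiota["bif_longum"] for s in cohort])
        z3 = (z3 - z3.mean()) / z3.std(ddof=1)
        zl = (zl - zl.mean()) / zl.std(ddof=1)
        y = np.array([s.msel.composite for s in cohort])
        X = np.column_stack([np.ones_like(y), z3, zl, z3 * zl])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (y.size - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[3, 3])
        assert abs(beta[3] - 0.5) < 3 * se

    def test_derived_composite_mode(self):
        cfg = ht.default_config(n_subjects=30, seed=8, derived_composite=True)
        for s in ht.generate_cohort(cfg):
            manual = 2.0 * np.mean([s.msel.visual_reception, s.msel.fine_motor,
                                    s.msel.receptive_language,
                                    s.msel.expressive_language])
            assert s.msel.composite == pytest.approx(manual)
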