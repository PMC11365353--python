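"""LOSO cross-validation and the MSPE / RMSPE% / RSR / CCC metric suite."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import kexmeta.mixed_model
from kexmeta.database import StudyDatabase
from kexmeta.evaluation import (
    EvaluationError,
    ccc,
    decompose_mspe,
    loso_cv,
    plot_data,
    rank_models,
)
from kexmeta.mixed_model import ModelSpec
from kexmeta.synthetic_data import SyntheticConfig, generate

from _oracles import lin_ccc, mspe_parts

SPEC = ModelSpec("k_ur", "k_intake")


class TestDecomposeMspe:
    def test_hand_computed_shrunk_predictions(self):
        # r = 1, population SDs: MSPE = 1/6 all of it slope bias
        m = decompose_mspe(((1.0, 2.0, 3.0), (1.5, 2.0, 2.5)))
        assert m.mspe == pytest.approx(1 / 6)
        assert m.mb == pytest.approx(0.0, abs=1e-15)
        assert m.sb == pytest.approx(1 / 6)
        assert m.ed == pytest.approx(0.0, abs=1e-12)
        assert m.mb_pct + m.sb_pct + m.ed_pct == pytest.approx(100.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_perfect_agreement(self):
        m = decompose_mspe(((1.0, 2.0, 5.0), (1.0, 2.0, 5.0)))
        assert m.mspe == m.mb == m.sb == m.ed == 0.0
        assert m.ccc == 1.0 and m.rsr == 0.0

    def test_anticorrelated_all_slope_bias(self):
        m = decompose_mspe(((1.0, 2.0, 3.0), (3.0, 2.0, 1.0)))
        assert m.pearson_r == pytest.approx(-1.0)
        assert m.mspe == pytest.approx(8 / 3)
        assert m.sb == pytest.approx(8 / 3)  # (S_p + S_o)^2
        assert m.mb == pytest.approx(0.0, abs=1e-15)
        assert m.ed == pytest.approx(0.0, abs=1e-12)

    def test_identity_on_random_pairs(self):
        # MB + SB + ED = MSPE exactly under population SDs
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            obs = rng.normal(100, 30, n)
            pred = rng.normal(100, 30, n)
            if np.ptp(obs) == 0 or np.ptp(pred) == 0:
                continue
            m = decompose_mspe((obs, pred))
            assert abs(m.mb + m.sb + m.ed - m.mspe) <= 1e-10 * max(m.mspe, 1e-30)
            ms, mb, sb, ed = mspe_parts(obs, pred)
            assert m.mspe == pytest.approx(ms)
            assert m.sb == pytest.approx(sb, abs=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, st.integers(3, 25), elements=st.floats(1, 500)),
        st.data(),
    )
    def test_identity_property(self, obs, data):
        pred = data.draw(arrays(np.float64, obs.size, elements=st.floats(1, 500)))
        if np.ptp(obs) == 0:
            return
        m = decompose_mspe((obs, pred))
        scale = max(m.mspe, m.sd_obs_pop**2, 1e-12)
        assert abs(m.mb + m.sb + m.ed - m.mspe) <= 1e-10 * scale
        assert abs(m.ccc) <= abs(m.pearson_r) + 1e-12
        assert -1 - 1e-12 <= m.ccc <= 1 + 1e-12

    def test_constant_predictions_degenerate_r(self):
        m = decompose_mspe(((1.0, 2.0, 3.0), (2.0, 2.0, 2.0)))
        assert m.degenerate_r
        assert m.pearson_r == 0.0
        assert m.sb == 0.0  # (0 - 0*S_o)^2
        assert m.ed == pytest.approx(m.sd_obs_pop**2)

    def test_constant_observations_error(self):
        with pytest.raises(EvaluationError, match="constant"):
            decompose_mspe(((2.0, 2.0, 2.0), (1.0, 2.0, 3.0)))

    def test_order_invariance_of_scale_metrics(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(200, 50, 20)
        pred = obs + rng.normal(0, 20, 20)
        m1 = decompose_mspe((obs, pred))
        perm = rng.permutation(20)
        m2 = decompose_mspe((obs[perm], pred[perm]))
        assert m1.rmspe_pct == pytest.approx(m2.rmspe_pct)
        assert m1.rsr == pytest.approx(m2.rsr)

    def test_rsr_uses_sample_sd(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(200, 50, 15)
        pred = obs + rng.normal(0, 25, 15)
        m = decompose_mspe((obs, pred))
        assert m.rsr == pytest.approx(np.sqrt(m.mspe) / np.std(obs, ddof=1))

    def test_bias_pvalues_detect_planted_biases(self):
        rng = np.random.default_rng(8)
        pred = rng.uniform(100, 400, 60)
        obs_mb = pred + 50.0 + rng.normal(0, 5, 60)      # pure mean bias
        m = decompose_mspe((obs_mb, pred))
        assert m.p_mean_bias < 0.01 and m.p_slope_bias > 0.05
        obs_sb = 1.5 * (pred - pred.mean()) + pred.mean() + rng.normal(0, 5, 60)
        m2 = decompose_mspe((obs_sb, pred))
        assert m2.p_slope_bias < 0.01


class TestCcc:
    def test_identity_line(self):
        assert ccc(((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert ccc(((1.0, 2.0, 3.0), (1.5, 2.0, 2.5))) == pytest.approx(0.8)

    def test_negative_for_anticorrelated(self):
        assert ccc(((1.0, 2.0, 3.0), (3.0, 2.0, 1.0))) == pytest.approx(-1.0)

    def test_matches_literal_transcription(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            obs = rng.normal(0, 1, n) * rng.uniform(1, 100) + rng.uniform(-50, 50)
            pred = rng.normal(0, 1, n) * rng.uniform(1, 100) + rng.uniform(-50, 50)
            if np.ptp(obs) == 0 or np.ptp(pred) == 0:
                continue
            assert abs(ccc((obs, pred)) - lin_ccc(obs, pred)) <= 1e-12

    def test_constant_sequence_raises(self):
        with pytest.raises(EvaluationError):
            ccc(((1.0, 1.0, 1.0), (1.0, 2.0, 3.0)))


class TestLosoCv:
    def test_fold_count_and_coverage(self, urinary_db):
        cv = loso_cv(urinary_db, SPEC)
        assert cv.n_folds == len(urinary_db.study_ids())
        assert len(cv.pairs) == len(urinary_db.complete_cases("k_intake"))
        assert [p.record_id for p in cv.pairs] == [r.record_id for r in urinary_db.records]

    def test_performs_exactly_k_fits(self, urinary_db, monkeypatch):
        calls = []
        real_fit = kexmeta.mixed_model.fit

        def counting_fit(db, spec):
            calls.append(1)
            return real_fit(db, spec)

        monkeypatch.setattr("kexmeta.mixed_model.fit", counting_fit)
        loso_cv(urinary_db, SPEC)
        assert len(calls) == len(urinary_db.study_ids())

    def test_heldout_predictions_independent_of_heldout_responses(self, urinary_db):
        cv = loso_cv(urinary_db, SPEC)
        target = urinary_db.study_ids()[3]
        perturbed = urinary_db.map_records(
            lambda r: dataclasses.replace(r, k_ur=r.k_ur * 3.0) if r.study_id == target else r
        )
        cv2 = loso_cv(perturbed, SPEC)
        for p1, p2 in zip(cv.pairs, cv2.pairs):
            if p1.study_id == target:
                assert p2.predicted == p1.predicted  # same training data, exactly
        # and removing a study only drops its own pairs
        dropped = dataclasses.replace(
            urinary_db, records=tuple(r for r in urinary_db.records if r.study_id != target)
        )
        cv3 = loso_cv(dropped, SPEC)
        kept = {p.record_id: p.predicted for p in cv3.pairs}
        for p in cv.pairs:
            if p.study_id != target:
                assert p.record_id in kept

    def test_noiseless_limit_recovers_observations(self):
        cfg = SyntheticConfig(n_studies=5, records_per_study=(3, 3), tau=0.0, sigma=1e-5, seed=9)
        db = generate(cfg)
        cv = loso_cv(db, SPEC)
        obs, pred = cv.arrays()
        np.testing.assert_allclose(pred, obs, rtol=1e-4)

    def test_too_few_studies_raises(self):
        cfg = SyntheticConfig(n_studies=2, records_per_study=(4, 4), seed=1)
        db = generate(cfg)
        with pytest.raises(EvaluationError, match="3 studies"):
            loso_cv(db, SPEC)


class TestRankModels:
    def _metrics(self, rsr, ccc_val, rmspe_pct=50.0):
        m = decompose_mspe(((1.0, 2.0, 3.0), (1.1, 2.0, 2.9)))
        return dataclasses.replace(m, rsr=rsr, ccc=ccc_val, rmspe_pct=rmspe_pct)

    def test_lowest_rsr_first(self):
        a = (ModelSpec("k_ur", "k_intake"), self._metrics(0.28, 0.96))
        b = (ModelSpec("k_ur", "dmi"), self._metrics(0.98, 0.19))
        assert rank_models([b, a])[0][0].predictor_name == "k_intake"

    def test_ccc_breaks_ties(self):
        a = (ModelSpec("k_ur", "k_intake"), self._metrics(0.5, 0.9))
        b = (ModelSpec("k_ur", "dmi"), self._metrics(0.5, 0.2))
        assert rank_models([b, a])[0][0].predictor_name == "k_intake"

    def test_singleton_and_full_tie_deterministic(self):
        a = (ModelSpec("k_ur", "k_intake"), self._metrics(0.5, 0.9))
        assert rank_models([a]) == [a]
        b = (ModelSpec("k_ur", "dmi"), self._metrics(0.5, 0.9))
        assert rank_models([b, a])[0][0].predictor_name == "dmi"  # lexicographic

    def test_empty_raises(self):
        with pytest.raises(EvaluationError):
            rank_models([])


class TestPlotData:
    def test_rows_and_trends(self, urinary_db):
        cv = loso_cv(urinary_db, SPEC)
        pd_ = plot_data(cv)
        assert len(pd_["rows"]) == len(cv.pairs)
        row = pd_["rows"][0]
        assert row["residual"] == pytest.approx(row["observed"] - row["predicted"])
        assert pd_["identity_line"] == {"slope": 1.0, "intercept": 0.0}
        # near-perfect model: observed trend close to the identity line
        assert pd_["observed_trend"]["slope"] == pytest.approx(1.0, abs=0.15)
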