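"""Rank selection, calibration, postprocessing, and the end-to-end drivers.

Heavier pipeline behavior (full noiseless/noisy runs on toy molecules at
the study conditions) lives in test_acceptance.py; here the stages are
exercised on small synthetic inputs.
"""

import numpy as np
import pytest

import rdmcomplete as rc
from rdmcomplete.protocol import (
    _f_grid,
    _rdm_error,
    aggregate_error,
    calibrate_sampling_noiseless,
)


def _fast_config(**kw):
    kw.setdefault("seed", 0)
    kw.setdefault("coherence_starts", 3)
    kw.setdefault("f_grid_points", 8)
    return rc.ProtocolConfig(**kw)


class TestSelectRank:
    def test_truncation_budget_example(self):
        lam = np.array([2.0, 1.0, 0.1, 0.01])
        # eps_trunc(2) ~ 0.0449 > 0.005 >= eps_trunc(3) ~ 0.00447
        assert rc.select_rank(lam, eps0=0.01, kappa=0.5) == 3

    def test_exact_low_rank_spectrum(self):
        lam = np.array([3.0, 1.0, 0.0, 0.0, 0.0])
        assert rc.select_rank(lam, eps0=0.01, kappa=0.5) <= 2

    def test_default_kappa_is_one_half(self):
        import inspect
        sig = inspect.signature(rc.select_rank)
        assert sig.parameters["kappa"].default == 0.5
        assert rc.ProtocolConfig().kappa == 0.5

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ValueError):
            rc.select_rank(np.array([1.0, 2.0]))


class TestCalibrationNoiseless:
    def test_low_coherence_exact_rank_calibrates_near_bound(self):
        model, _ = rc.synth_two_rdm(4, 1, 1, rank=2, decay=0.0,
                                    coherence=0.0, seed=3)
        config = rc.ProtocolConfig(seed=0)  # full 12-point grid
        calib = calibrate_sampling_noiseless(model, {"abab": 2}, config)
        res = calib["abab"]
        assert res["calibrated"]
        bound = rc.information_bound(2, 16)
        assert res["f_sample"] <= 2.0 * bound
        assert res["successes"] >= 9

    def test_success_criterion_counts_ten_samplings(self):
        model, _ = rc.synth_two_rdm(3, 1, 1, rank=1, decay=0.0, seed=4)
        config = _fast_config()
        calib = calibrate_sampling_noiseless(model, {"abab": 1}, config)
        res = calib["abab"]
        assert len(res["errors"]) == 10
        assert res["successes"] >= 9

    def test_full_sampling_always_succeeds_at_low_truncation(self, lih_like):
        # at f = 1 the only error left is rank truncation, which the rank
        # rule bounds by kappa * eps0
        config = _fast_config(f_grid_points=2)
        ranks = rc.select_ranks(lih_like.model)
        calib = calibrate_sampling_noiseless(lih_like.model, ranks, config)
        assert all(c["calibrated"] for c in calib.values())

    def test_grid_spans_bound_to_one(self):
        g = _f_grid(2, 10, 12)
        assert g[0] == pytest.approx(rc.information_bound(2, 10) / 2)
        assert g[-1] == 1.0
        assert len(g) == 12


class TestPostprocess:
    def _completed_pair(self, seed=0):
        model, target = rc.synth_two_rdm(3, 1, 1, rank=2, decay=1.0,
                                         perturbation=0.02, seed=seed)
        # a crude "completed" estimate: target plus noise
        rng = np.random.default_rng(seed)
        est = target.copy()
        for sec in est.sectors.values():
            g = 0.01 * rng.standard_normal(sec.values.shape)
            sec.values += g + g.T
        return model, target, est

    def test_trace_normalization_hits_targets(self):
        _, _, est = self._completed_pair()
        out = rc.postprocess(est, None, None, mode="noisy")
        targets = rc.sector_trace_targets(1, 1)
        for label, sec in out.sectors.items():
            assert np.trace(sec.values) == pytest.approx(targets[label])

    def test_sampled_entries_become_exact(self):
        # replacement gives zero residual on the sampled set; with the
        # sector trace already on target, normalization leaves it intact
        model, target, _ = self._completed_pair(1)
        d = target.sectors["abab"].d
        omega = rc.sample_elements(d, n_sample=12, rng_seed=5)
        sampled = {"abab": omega.values_from(target.sectors["abab"].values)}
        est = target.copy()  # trace-correct estimate with wrong entries
        rng = np.random.default_rng(9)
        g = 0.02 * rng.standard_normal((d, d))
        hollow = g + g.T - np.diag(np.diag(g + g.T))  # keep the trace
        est.sectors["abab"].values = est.sectors["abab"].values + hollow
        out = rc.postprocess(est, sampled, None, mode="noiseless")
        for (i, j), v in sampled["abab"].items():
            assert out.sectors["abab"].values[i, j] == pytest.approx(
                v, abs=1e-10)

    def test_model_correction_identity_case(self):
        # if target == model, replacing entries and adding the model's own
        # completion residual returns the exact target
        model, _ = rc.synth_two_rdm(3, 1, 1, rank=2, decay=1.0, seed=2)
        target = model.copy()
        d = target.sectors["abab"].d
        omega = rc.sample_elements(d, n_sample=15, rng_seed=6)
        res = rc.complete(omega.values_from(target.sectors["abab"].values),
                          d, 2, seed=7)
        est = target.copy()
        est.sectors["abab"].values = res.completed.copy()
        est_m = target.copy()
        est_m.sectors["abab"].values = res.completed.copy()
        sampled = {"abab": omega.values_from(target.sectors["abab"].values)}
        processed_m = rc.postprocess(est_m, sampled, None, mode="noiseless")
        out = rc.postprocess(est, sampled, (model, processed_m),
                             mode="noiseless")
        assert _rdm_error(out, target) < 1e-10

    def test_zero_trace_rejected(self):
        sec = rc.PackedSectorMatrix("abab", 1, np.array([[0.0]]))
        est = rc.TwoRDM({"abab": sec}, 1, 1, 1)
        with pytest.raises(ValueError, match="trace"):
            rc.postprocess(est, None, None, mode="noisy")

    def test_unknown_mode_rejected(self):
        _, _, est = self._completed_pair()
        with pytest.raises(ValueError):
            rc.postprocess(est, None, None, mode="other")


class TestAggregateError:
    def test_matches_blockwise_norm(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((4, 4)), rng.standard_normal((3, 3))
        da, db = 0.1 * rng.standard_normal((4, 4)), np.zeros((3, 3))
        expected = np.sqrt(np.sum(da ** 2)
                           / (np.sum(a ** 2) + np.sum(b ** 2)))
        assert aggregate_error([da, db], [a, b]) == pytest.approx(expected)


class TestNoiselessDriver:
    def test_self_completion_meets_target(self):
        # model == target: the calibrated pipeline must reach eps0 in at
        # least 90% of trials by construction of the calibration
        model, _ = rc.synth_two_rdm(4, 1, 1, rank=3, decay=1.5,
                                    coherence=0.3, seed=11)
        config = _fast_config(seed=2)
        rep = rc.run_noiseless(model, model.copy(), None, config)
        good = [e for e, ok in zip(rep.eps_post, rep.converged) if ok]
        assert len(good) >= 8
        frac = np.mean([e <= config.eps0 for e in good])
        assert frac >= 0.8

    def test_mismatched_spaces_rejected(self):
        m1, _ = rc.synth_two_rdm(3, 1, 1, rank=1, seed=0)
        m2, _ = rc.synth_two_rdm(4, 1, 1, rank=1, seed=0)
        with pytest.raises(ValueError):
            rc.run_noiseless(m1, m2, None, _fast_config())

    def test_rank_one_system_has_anomalously_small_error(self, lih_like):
        # a two-electron active space has an exactly rank-one abab sector,
        # so calibrated completion recovers it essentially exactly
        config = _fast_config(seed=4)
        rep = rc.run_noiseless(lih_like.model, lih_like.target,
                               lih_like.ints, config)
        good = [e for e, ok in zip(rep.eps_post, rep.converged) if ok]
        assert len(good) >= 5
        assert np.mean(good) < 0.2 * config.eps0

    def test_report_serializes_to_json(self):
        import json
        model, target = rc.synth_two_rdm(3, 1, 1, rank=2, decay=1.0,
                                         perturbation=0.01, seed=13)
        rep = rc.run_noiseless(model, target, None, _fast_config(seed=3))
        blob = json.dumps(rep.to_dict(), default=float)
        assert "eps_mean" in blob


class TestNoisyTrends:
    """Reduced-size trend checks of the shot/sampling co-calibration."""

    def test_model_error_monotone_in_shots(self, beh_like):
        from rdmcomplete.protocol import _noisy_model_error, _prepare
        config = _fast_config(seed=5, n_samplings=4)
        ranks, _, _, model_r, _, _ = _prepare(
            beh_like.model, beh_like.target, beh_like.ints, config)
        m1 = rc.contract_to_1rdm(model_r)
        cache = {}
        rng = np.random.default_rng(1)
        med = []
        for shots in (10 ** 3, 10 ** 4, 10 ** 5):
            errs = _noisy_model_error(model_r, m1, ranks, 1.0, shots,
                                      config, rng, cache)
            med.append(np.median([e for e in errs if np.isfinite(e)]))
        assert med[0] > med[1] > med[2]

    def test_shot_reduction_tracks_relative_rank(self):
        # two-electron toys in growing spaces: the relative rank r/d of
        # the rank-1 sector falls with the orbital count and the shot
        # ratio f_m = m/m0 falls with it
        config = _fast_config(seed=6, n_samplings=4, f_grid_points=4,
                              shot_grid=tuple(10 ** k
                                              for k in range(2, 8)))
        f_m = {}
        rel_rank = {}
        for preset in ("pair_n3", "pair_n5"):
            fx = rc.toy_molecule_fixtures(preset)
            rep = rc.run_noisy(fx.model, fx.model_1rdm, fx.target,
                               fx.target_1rdm, fx.ints, config)
            assert rep.calibration["calibrated"]
            d = fx.target.sectors["abab"].d
            rel_rank[preset] = rep.ranks["abab"] / d
            f_m[preset] = rep.f_m
        assert rel_rank["pair_n5"] < rel_rank["pair_n3"]
        assert f_m["pair_n5"] <= f_m["pair_n3"]


class TestCompletionErrorShape:
    def test_error_spikes_near_information_bound(self):
        # the characteristic failure just above the counting bound and
        # recovery well beyond it, on an approximately low-rank matrix
        m = rc.synth_psd_matrix(rc.fixtures.SyntheticSpec(
            d=16, rank=3, decay=2.5, coherence=0.0, seed=21))
        bound = rc.information_bound(3, 16)
        med = {}
        for f in (1.05 * bound, min(2.2 * bound, 1.0)):
            errs = []
            for s in range(8):
                om = rc.sample_elements(16, f_sample=f, rng_seed=s)
                res = rc.complete(om.values_from(m), 16, 3, seed=s,
                                  reference=m)
                errs.append(res.relative_error)
            med[f] = np.median(errs)
        near, far = med.values()
        assert near > 2.0 * far
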