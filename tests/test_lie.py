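"""Unit tests for the iterative Boltzmann-weighted LIE core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poselie import (
    KB,
    CalibrationSet,
    Compound,
    EnergyRecord,
    FitOptions,
    LIEModel,
    LIEParams,
    PoseDescriptor,
    RankDeficientError,
    ThermodynamicConstants,
    average_replicates,
    boltzmann_weights,
    calibrate_model,
    fit_lie_iterative,
    loo_sdep,
    pose_dg,
    predict_dg,
    rank_poses,
    weighted_descriptors,
)
from conftest import ols


class TestAverageReplicates:
    def test_mean_and_difference(self):
        records = [
            EnergyRecord("c", "p", 1, -50.0, -10.0),
            EnergyRecord("c", "p", 2, -60.0, -20.0),
            EnergyRecord("c", None, 1, -30.0, -40.0),
        ]
        (d,) = average_replicates(records)
        assert d.dv_lj == pytest.approx(-25.0)
        assert d.dv_coul == pytest.approx(25.0)

    def test_bound_equal_to_free_gives_zero(self):
        records = [
            EnergyRecord("c", "p", 1, -30.0, -40.0),
            EnergyRecord("c", "p", 2, -30.0, -40.0),
            EnergyRecord("c", None, 1, -30.0, -40.0),
        ]
        (d,) = average_replicates(records)
        assert d.dv_lj == 0.0 and d.dv_coul == 0.0

    def test_descriptor_count(self):
        records = []
        for c in range(3):
            records.append(EnergyRecord(f"c{c}", None, 1, -100.0, -120.0))
            for p in range(2):
                for r in (1, 2):
                    records.append(
                        EnergyRecord(f"c{c}", f"p{p}", r, -150.0 - p, -140.0)
                    )
        assert len(average_replicates(records)) == 6

    def test_missing_free_state_names_compound(self):
        records = [EnergyRecord("orphan", "p", 1, -1.0, -1.0)]
        with pytest.raises(ValueError, match="orphan"):
            average_replicates(records)

    def test_single_replicate_warns(self):
        records = [
            EnergyRecord("c", "p", 1, -50.0, -10.0),
            EnergyRecord("c", None, 1, -30.0, -40.0),
        ]
        with pytest.warns(UserWarning, match="single replicate"):
            average_replicates(records)

    def test_non_finite_energy_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            EnergyRecord("c", "p", 1, float("nan"), -1.0)

    def test_duplicate_key_rejected(self):
        records = [
            EnergyRecord("c", "p", 1, -1.0, -1.0),
            EnergyRecord("c", "p", 1, -2.0, -2.0),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            average_replicates(records)


class TestPoseDg:
    def test_zero_coefficients(self):
        p = PoseDescriptor("c", "p", -123.4, 56.7)
        assert pose_dg(LIEParams(0.0, 0.0), p) == 0.0

    def test_midpoint_arithmetic(self):
        p = PoseDescriptor("c", "p", -40.0, -20.0)
        assert pose_dg(LIEParams(0.5, 0.5), p) == pytest.approx(-30.0)

    def test_published_cyp_coefficients(self):
        # alpha=0.587, beta=0.267: hand arithmetic -58.7 - 2.67 = -61.37
        p = PoseDescriptor("c", "p", -100.0, -10.0)
        assert pose_dg(LIEParams(0.587, 0.267), p) == pytest.approx(-61.37)

    def test_gamma_added_when_enabled(self):
        p = PoseDescriptor("c", "p", -40.0, -20.0)
        assert pose_dg(LIEParams(0.5, 0.5, -13.0, True), p) == pytest.approx(-43.0)


class TestBoltzmannWeights:
    def test_single_pose(self):
        assert boltzmann_weights([-30.0]) == pytest.approx([1.0])

    def test_symmetric_pair(self):
        assert boltzmann_weights([-30.0, -30.0]) == pytest.approx([0.5, 0.5])

    def test_exp_ratio_two_to_one(self):
        kt = KB * 300.0
        w = boltzmann_weights([0.0, kt * np.log(2.0)])
        assert w == pytest.approx([2 / 3, 1 / 3])

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            boltzmann_weights([])

    def test_extreme_values_stable(self):
        w = boltzmann_weights([-1e6, 0.0])
        assert np.isfinite(w).all() and w[0] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=200)
    @given(
        dgs=st.lists(
            st.floats(min_value=-200, max_value=200), min_size=1, max_size=8
        ),
        shift=st.floats(min_value=-500, max_value=500),
    )
    def test_normalisation_and_shift_invariance(self, dgs, shift):
        w = boltzmann_weights(dgs)
        assert abs(w.sum() - 1.0) < 1e-9
        w2 = boltzmann_weights([d + shift for d in dgs])
        assert np.allclose(w, w2, atol=1e-9)


class TestWeightedDescriptors:
    def test_identity_single_pose(self):
        p = PoseDescriptor("c", "p", -10.0, -2.0)
        assert weighted_descriptors([p], [1.0]) == pytest.approx((-10.0, -2.0))

    def test_midpoint(self):
        ps = [PoseDescriptor("c", "a", -10.0, -2.0), PoseDescriptor("c", "b", -20.0, -4.0)]
        assert weighted_descriptors(ps, [0.5, 0.5]) == pytest.approx((-15.0, -3.0))

    def test_degenerate_weight(self):
        ps = [PoseDescriptor("c", "a", -10.0, -2.0), PoseDescriptor("c", "b", -20.0, -4.0)]
        assert weighted_descriptors(ps, [1.0, 0.0]) == pytest.approx((-10.0, -2.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_descriptors([PoseDescriptor("c", "a", 0.0, 0.0)], [0.5, 0.5])


class TestIterativeFit:
    def test_recovers_ols_on_single_pose_data(self, single_pose_set):
        calib, truth = single_pose_set
        params, weights = fit_lie_iterative(calib)
        x = np.array([[c.poses[0].dv_lj, c.poses[0].dv_coul] for c in calib])
        y = np.array([c.dg_obs for c in calib])
        expected = ols(x, y)
        assert params.alpha == pytest.approx(expected[0], abs=1e-8)
        assert params.beta == pytest.approx(expected[1], abs=1e-8)
        assert params.alpha == pytest.approx(0.5, abs=1e-8)
        assert params.beta == pytest.approx(0.3, abs=1e-8)
        assert all(w == {"pose00": pytest.approx(1.0)} for w in weights.values())

    def test_recovers_fxr_scale_offset(self):
        from poselie import GeneratorSpec, gen_energy_dataset

        spec = GeneratorSpec(
            n_compounds=20,
            poses_per_compound=1,
            true_params=LIEParams(0.333, 0.121, -13.0, True),
            seed=23,
        )
        _, calib, _ = gen_energy_dataset(spec)
        params, _ = fit_lie_iterative(calib, FitOptions(include_gamma=True))
        x = np.array([[c.poses[0].dv_lj, c.poses[0].dv_coul] for c in calib])
        y = np.array([c.dg_obs for c in calib])
        expected = ols(x, y, intercept=True)
        assert params.gamma == pytest.approx(-13.0, abs=1e-6)
        assert params.gamma == pytest.approx(expected[2], abs=1e-8)

    def test_multi_pose_fixed_point_is_stationary(self, multi_pose_set):
        calib, truth = multi_pose_set
        true_params = truth["params"]
        opts = FitOptions(init_params=true_params, tol=1e-6)
        params, _ = fit_lie_iterative(calib, opts)
        assert params.alpha == pytest.approx(true_params.alpha, abs=1e-6)
        assert params.beta == pytest.approx(true_params.beta, abs=1e-6)

    def test_default_init_converges_to_fixed_point(self, multi_pose_set):
        calib, truth = multi_pose_set
        params, _ = fit_lie_iterative(calib)
        assert params.alpha == pytest.approx(truth["params"].alpha, abs=1e-4)
        assert params.beta == pytest.approx(truth["params"].beta, abs=1e-4)

    def test_rank_deficient_design_names_column(self):
        compounds = [
            Compound(f"c{i}", -40.0 - i, [PoseDescriptor(f"c{i}", "p", -50.0 - i, -20.0)])
            for i in range(5)
        ]
        with pytest.raises(RankDeficientError, match="dv_coul"):
            fit_lie_iterative(CalibrationSet(compounds))

    def test_too_few_compounds(self):
        c = Compound("a", -40.0, [PoseDescriptor("a", "p", -50.0, -20.0)])
        with pytest.raises(ValueError, match=">= 2"):
            fit_lie_iterative(CalibrationSet([c]))

    def test_scale_consistency(self, single_pose_set):
        calib, _ = single_pose_set
        params, _ = fit_lie_iterative(calib)
        scaled = CalibrationSet(
            [
                Compound(
                    c.compound_id,
                    c.dg_obs,
                    [
                        PoseDescriptor(p.compound_id, p.pose_id, 2 * p.dv_lj, 2 * p.dv_coul)
                        for p in c.poses
                    ],
                )
                for c in calib
            ]
        )
        params2, _ = fit_lie_iterative(scaled)
        assert params2.alpha == pytest.approx(params.alpha / 2, abs=1e-8)
        assert params2.beta == pytest.approx(params.beta / 2, abs=1e-8)

    def test_weighted_dg_consistency(self, multi_pose_set):
        """Sum W_i * pose_dg_i must equal the fit applied to weighted descriptors."""
        calib, _ = multi_pose_set
        params, weights = fit_lie_iterative(calib)
        for c in calib:
            w = np.array([weights[c.compound_id][p.pose_id] for p in c.poses])
            lhs = sum(wi * pose_dg(params, p) for wi, p in zip(w, c.poses))
            dv_lj_w, dv_coul_w = weighted_descriptors(c.poses, w)
            rhs = params.alpha * dv_lj_w + params.beta * dv_coul_w
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_noisy_estimates_unbiased(self):
        """Coefficient estimates under dG noise are unbiased across seeds."""
        from poselie import GeneratorSpec, gen_energy_dataset

        errs = []
        for seed in range(200):
            spec = GeneratorSpec(
                n_compounds=15,
                poses_per_compound=1,
                observation_noise_sd=3.0,
                seed=1000 + seed,
            )
            _, calib, _ = gen_energy_dataset(spec)
            params, _ = fit_lie_iterative(calib)
            errs.append([params.alpha - 0.5, params.beta - 0.3])
        errs = np.array(errs)
        mean = errs.mean(axis=0)
        se = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
        assert np.all(np.abs(mean) < 2 * se + 1e-12)


class TestRankAndSelect:
    def test_rank_orders_by_dg(self):
        params = LIEParams(1.0, 0.0)
        c = Compound(
            "c",
            -40.0,
            [PoseDescriptor("c", "hi", -10.0, 0.0), PoseDescriptor("c", "lo", -20.0, 0.0)],
        )
        ranking = rank_poses(CalibrationSet([c]), params)
        assert ranking["c"] == ["lo", "hi"]

    def test_tie_broken_lexicographically(self):
        params = LIEParams(1.0, 0.0)
        c = Compound(
            "c",
            -40.0,
            [PoseDescriptor("c", "b", -10.0, 0.0), PoseDescriptor("c", "a", -10.0, 0.0)],
        )
        assert rank_poses(CalibrationSet([c]), params)["c"] == ["a", "b"]

    def test_loo_sdep_zero_on_noiseless_data(self, single_pose_set):
        calib, _ = single_pose_set
        assert loo_sdep(calib) == pytest.approx(0.0, abs=1e-6)

    def test_loo_sdep_matches_explicit_fold_loop(self, tiny_set):
        opts = FitOptions()
        expected = []
        for i in range(len(tiny_set)):
            rest = tiny_set.subset([j for j in range(len(tiny_set)) if j != i])
            x = np.array([[c.poses[0].dv_lj, c.poses[0].dv_coul] for c in rest])
            y = np.array([c.dg_obs for c in rest])
            coef = ols(x, y)
            held = tiny_set.compounds[i]
            pred = coef[0] * held.poses[0].dv_lj + coef[1] * held.poses[0].dv_coul
            expected.append(pred - held.dg_obs)
        oracle = np.sqrt(np.mean(np.square(expected)))
        assert loo_sdep(tiny_set, opts) == pytest.approx(oracle, abs=1e-7)

    def test_loo_sdep_outlier_monotonicity(self, single_pose_set):
        calib, _ = single_pose_set
        clean = loo_sdep(calib)
        corrupted = CalibrationSet(
            [Compound(c.compound_id, c.dg_obs + (50.0 if i == 0 else 0.0), c.poses)
             for i, c in enumerate(calib)]
        )
        assert loo_sdep(corrupted) > clean

    def test_pose_containment_in_j_sweep(self, multi_pose_set):
        calib, _ = multi_pose_set
        params, _ = fit_lie_iterative(calib)
        ranking = rank_poses(calib, params)
        for cid, ids in ranking.items():
            for j in range(1, len(ids)):
                assert set(ids[:j]) <= set(ids[: j + 1])


class TestCalibrateModel:
    def test_single_pose_collapse(self, single_pose_set):
        calib, _ = single_pose_set
        model = calibrate_model(calib)
        params, _ = fit_lie_iterative(calib)
        assert model.n_poses == 1
        assert model.params.alpha == pytest.approx(params.alpha, abs=1e-10)
        assert model.training_stats["rmse"] == pytest.approx(0.0, abs=1e-6)

    def test_selects_single_pose_when_only_lowest_carries_signal(self):
        """Decoy poses with large unfavourable shifts must be discarded."""
        rng = np.random.default_rng(42)
        true = LIEParams(0.5, 0.3)
        compounds = []
        for i in range(12):
            lj, coul = rng.normal(-80, 20), rng.normal(-30, 10)
            signal = PoseDescriptor(f"c{i}", "p_sig", lj, coul)
            decoys = [
                PoseDescriptor(
                    f"c{i}",
                    f"p_noise{k}",
                    rng.normal(60, 30),  # strongly unfavourable: near-zero weight
                    rng.normal(40, 20),
                )
                for k in range(2)
            ]
            dg = pose_dg(true, signal)
            compounds.append(Compound(f"c{i}", dg, [signal] + decoys))
        model = calibrate_model(CalibrationSet(compounds))
        assert model.n_poses == 1
        assert model.params.alpha == pytest.approx(0.5, abs=1e-4)

    def test_tie_prefers_smaller_j(self, multi_pose_set):
        """Noiseless self-consistent data: SDEP ~0 for every j, so j=1 wins."""
        calib, _ = multi_pose_set
        model = calibrate_model(calib)
        assert model.n_poses >= 1
        sweep = []
        params, _ = fit_lie_iterative(calib)
        ranking = rank_poses(calib, params)
        for j in range(1, 4):
            keep = {cid: ids[:j] for cid, ids in ranking.items()}
            sweep.append(loo_sdep(calib.restrict_poses(keep), n_poses=j))
        assert model.training_stats["sdep_cv"] == pytest.approx(min(sweep), abs=1e-8)
        best = min(range(len(sweep)), key=lambda i: (round(sweep[i], 12), i))
        assert model.n_poses == best + 1

    def test_training_weights_normalised(self, multi_pose_set):
        calib, _ = multi_pose_set
        model = calibrate_model(calib)
        for w in model.training_weights.values():
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)


class TestPredict:
    def _model(self, params, n_poses=1):
        return LIEModel(params, n_poses, {}, ThermodynamicConstants(), {})

    def test_single_pose_equals_pose_dg(self):
        p = PoseDescriptor("q", "p", -80.0, -30.0)
        model = self._model(LIEParams(0.5, 0.3))
        pred = predict_dg(model, [p])
        assert pred.dg_bind == pytest.approx(pose_dg(model.params, p))

    def test_equal_descriptors_split_weights(self):
        ps = [PoseDescriptor("q", "a", -80.0, -30.0), PoseDescriptor("q", "b", -80.0, -30.0)]
        pred = predict_dg(self._model(LIEParams(0.5, 0.3), n_poses=2), ps)
        assert pred.weights["a"] == pytest.approx(0.5)
        assert pred.dg_bind == pytest.approx(pose_dg(LIEParams(0.5, 0.3), ps[0]))

    def test_n_poses_one_takes_minimum(self):
        params = LIEParams(0.5, 0.3)
        ps = [
            PoseDescriptor("q", "a", -80.0, -30.0),
            PoseDescriptor("q", "b", -60.0, -30.0),
            PoseDescriptor("q", "c", -90.0, -30.0),
        ]
        pred = predict_dg(self._model(params, n_poses=1), ps)
        assert pred.dg_bind == pytest.approx(min(pose_dg(params, p) for p in ps))
        assert pred.n_poses_used == 1

    def test_gamma_added_once(self):
        params = LIEParams(0.5, 0.3, -13.0, True)
        ps = [PoseDescriptor("q", "a", -80.0, -30.0), PoseDescriptor("q", "b", -82.0, -28.0)]
        pred = predict_dg(self._model(params, n_poses=2), ps)
        w = np.array([pred.weights[p.pose_id] for p in ps])
        manual = sum(wi * pose_dg(params, p) for wi, p in zip(w, ps))
        assert pred.dg_bind == pytest.approx(manual, abs=1e-9)

    def test_empty_pose_list_errors(self):
        with pytest.raises(ValueError):
            predict_dg(self._model(LIEParams(0.5, 0.3)), [])
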