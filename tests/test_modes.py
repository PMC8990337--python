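"""Tests of mode estimation: subtraction-defined directions, Gram-Schmidt
orthogonalization, projection, normalization anchors, and explained
selectivity/activity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import modeswitch as ms
from modeswitch.core import PSTHMatrix
from modeswitch.modes import DegenerateModeError, ModeVector


def psth_from_rates(right, left, time=None, bin_width=0.01):
    """Build a PSTHMatrix from explicit (neurons x bins) rate arrays."""
    right = np.asarray(right, float)
    left = np.asarray(left, float)
    n, b = right.shape
    if time is None:
        time = -1.0 + bin_width * (np.arange(b) + 0.5)
    return PSTHMatrix(rates=np.stack([right, left], axis=2), time=np.asarray(time),
                      bin_width=bin_width, smoothing="none", alignment="go",
                      condition_labels=["lick_right", "lick_left"],
                      neuron_ids=[f"u{i}" for i in range(n)])


def mode_from(w, kind="custom"):
    w = np.asarray(w, float)
    return ModeVector(w / np.linalg.norm(w), [f"u{i}" for i in range(w.size)], kind)


class TestSelectivityVector:
    def test_identical_conditions_give_zero(self):
        r = np.random.default_rng(0).uniform(1, 10, (4, 20))
        w = ms.selectivity_vector(psth_from_rates(r, r))
        assert np.all(w == 0)

    def test_single_neuron_subtraction(self):
        w = ms.selectivity_vector(psth_from_rates([[10.0]], [[4.0]]))
        assert w[0, 0] == 6.0

    def test_norm_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        right, left = rng.uniform(0, 20, (2, 6, 30))
        p = psth_from_rates(right, left)
        w = ms.selectivity_vector(p)
        for b in range(30):
            brute = np.sqrt(sum((right[i, b] - left[i, b]) ** 2 for i in range(6)))
            assert np.linalg.norm(w[:, b]) == pytest.approx(brute)


class TestCDDelay:
    def test_single_selective_neuron_gives_indicator(self):
        right = np.full((3, 100), 5.0)
        left = right.copy()
        right[1] += 4.0  # only neuron 1 selective
        cd = ms.compute_cd_delay(psth_from_rates(right, left))
        np.testing.assert_allclose(cd.weights, [0, 1, 0], atol=1e-12)

    def test_direction_is_scale_invariant(self):
        rng = np.random.default_rng(2)
        right, left = rng.uniform(0, 20, (2, 5, 100))
        cd1 = ms.compute_cd_delay(psth_from_rates(right, left))
        cd2 = ms.compute_cd_delay(psth_from_rates(2 * right, 2 * left))
        np.testing.assert_allclose(cd1.weights, cd2.weights, atol=1e-12)

    def test_no_selectivity_is_degenerate(self):
        r = np.full((3, 100), 5.0)
        with pytest.raises(DegenerateModeError):
            ms.compute_cd_delay(psth_from_rates(r, r))


class TestCDResponse:
    def _post_cue_psth(self, right, left):
        b = right.shape[1]
        time = 0.01 * (np.arange(b) + 0.5) - 0.5  # spans (-0.5, ...) incl (0, 0.4)
        return psth_from_rates(right, left, time=time)

    def test_already_orthogonal_unchanged(self):
        right = np.full((2, 100), 5.0)
        left = right.copy()
        right[0, :50] += 2.0   # pre-cue selectivity on neuron 0
        right[1, 50:] += 3.0   # post-cue selectivity on neuron 1
        p = self._post_cue_psth(right, left)
        cdd = ms.compute_cd_delay(p, window=(-0.5, 0.0))
        cdr = ms.compute_cd_response(p, window=(0.0, 0.4), cd_delay=cdd)
        np.testing.assert_allclose(cdr.weights, [0, 1], atol=1e-12)
        assert abs(cdr.weights @ cdd.weights) < 1e-10

    def test_parallel_raw_vector_is_degenerate(self):
        right = np.full((2, 100), 5.0)
        left = right.copy()
        right[0] += 2.0  # same selectivity pattern pre and post cue
        p = self._post_cue_psth(right, left)
        cdd = ms.compute_cd_delay(p, window=(-0.5, 0.0))
        with pytest.raises(DegenerateModeError):
            ms.compute_cd_response(p, window=(0.0, 0.4), cd_delay=cdd)

    def test_equals_least_squares_residual_on_toy(self):
        rng = np.random.default_rng(3)
        right, left = rng.uniform(0, 20, (2, 5, 100))
        p = self._post_cue_psth(right, left)
        cdd = ms.compute_cd_delay(p, window=(-0.5, 0.0))
        cdr = ms.compute_cd_response(p, window=(0.0, 0.4), cd_delay=cdd)
        # brute-force oracle: residual of regressing raw response selectivity
        # on the delay direction
        w = ms.selectivity_vector(p)
        mask = (p.time >= 0.0) & (p.time < 0.4)
        raw = w[:, mask].mean(axis=1)
        beta = np.linalg.lstsq(cdd.weights[:, None], raw, rcond=None)[0]
        resid = raw - cdd.weights * beta
        np.testing.assert_allclose(cdr.weights, resid / np.linalg.norm(resid), atol=1e-10)

    def test_unorthogonalized_variant_available(self):
        rng = np.random.default_rng(4)
        right, left = rng.uniform(0, 20, (2, 4, 100))
        p = self._post_cue_psth(right, left)
        raw = ms.compute_cd_response(p, window=(0.0, 0.4), orthogonalize=False)
        mask = (p.time >= 0.0) & (p.time < 0.4)
        expect = ms.selectivity_vector(p)[:, mask].mean(axis=1)
        np.testing.assert_allclose(raw.weights, expect / np.linalg.norm(expect), atol=1e-12)


class TestConditionInvariantModes:
    def test_d_go_single_go_up_neuron(self):
        r = np.full((3, 100), 5.0)
        time = 0.01 * (np.arange(100) + 0.5) - 0.5
        right = r.copy()
        right[2, 50:] += 10.0
        left = right.copy()  # condition-invariant response
        d = ms.compute_d_go(psth_from_rates(right, left, time=time))
        np.testing.assert_allclose(d.weights, [0, 0, 1], atol=1e-12)

    def test_d_go_without_response_is_degenerate(self):
        r = np.full((2, 100), 5.0)
        time = 0.01 * (np.arange(100) + 0.5) - 0.5
        with pytest.raises(DegenerateModeError):
            ms.compute_d_go(psth_from_rates(r, r, time=time))

    def test_d_ramp_recovers_ramping_neuron(self):
        time = 0.01 * (np.arange(400) + 0.5) - 3.5
        r = np.full((2, 400), 4.0)
        r[0] += np.clip(1 + time / 1.2, 0, 1) * 8.0  # ramps into the cue
        d = ms.compute_d_ramp(psth_from_rates(r, r, time=time),
                              pre_trial_window=(-3.4, -2.8))
        np.testing.assert_allclose(d.weights, [1, 0], atol=1e-12)

    def test_d_stim_ignores_common_baseline_shift(self):
        time = 0.01 * (np.arange(100) + 0.5) - 0.5
        base = np.full((3, 100), 5.0)
        stim = base.copy()
        stim[1, 50:] += 6.0
        d1 = ms.compute_d_stim(psth_from_rates(base, base, time=time),
                               psth_from_rates(stim, stim, time=time))
        d2 = ms.compute_d_stim(psth_from_rates(base + 2, base + 2, time=time),
                               psth_from_rates(stim + 2, stim + 2, time=time))
        np.testing.assert_allclose(d1.weights, d2.weights, atol=1e-12)
        np.testing.assert_allclose(d1.weights, [0, 1, 0], atol=1e-12)

    def test_d_stim_identical_conditions_degenerate(self):
        time = 0.01 * (np.arange(100) + 0.5) - 0.5
        base = np.full((2, 100), 5.0)
        p = psth_from_rates(base, base, time=time)
        with pytest.raises(DegenerateModeError):
            ms.compute_d_stim(p, p)


class TestOrthogonalizeSet:
    def test_already_orthogonal_set_unchanged(self):
        modes = [mode_from([1, 0, 0], "CD_delay"), mode_from([0, 1, 0], "CD_response"),
                 mode_from([0, 0, 1], "D_go")]
        out = ms.orthogonalize_set(modes)
        for m_in, m_out in zip(modes, out):
            np.testing.assert_allclose(m_in.weights, m_out.weights, atol=1e-12)

    def test_gram_matrix_is_identity(self):
        rng = np.random.default_rng(5)
        modes = [mode_from(rng.normal(size=5), k) for k in ("CD_delay", "CD_response", "D_go")]
        out = ms.orthogonalize_set(modes)
        W = np.stack([m.weights for m in out])
        np.testing.assert_allclose(W @ W.T, np.eye(3), atol=1e-10)

    def test_reordering_never_changes_first_mode(self):
        rng = np.random.default_rng(6)
        modes = [mode_from(rng.normal(size=6), k) for k in ("CD_delay", "CD_response", "D_go")]
        out1 = ms.orthogonalize_set(modes, order=("CD_delay", "CD_response", "D_go"))
        out2 = ms.orthogonalize_set(modes, order=("CD_delay", "D_go", "CD_response"))
        np.testing.assert_allclose(out1[0].weights, out2[0].weights, atol=1e-12)
        assert not np.allclose(out1[1].weights, out2[2].weights)

    def test_linear_dependence_names_offender(self):
        v = np.array([1.0, 2.0, 3.0])
        modes = [mode_from(v, "CD_delay"), mode_from(-v, "D_go")]
        with pytest.raises(DegenerateModeError, match="D_go"):
            ms.orthogonalize_set(modes)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_qr_factor_up_to_sign(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 8, 4
        vecs = rng.normal(size=(k, n))
        modes = [mode_from(vecs[i], kind) for i, kind in
                 enumerate(["CD_delay", "CD_response", "D_go", "D_ramp"])]
        out = ms.orthogonalize_set(modes)
        q = np.linalg.qr(np.stack([m.weights for m in modes]).T)[0]
        for i, m in enumerate(out):
            assert abs(abs(m.weights @ q[:, i]) - 1.0) < 1e-10


class TestProjection:
    def test_projecting_mode_onto_itself_gives_one(self):
        w = mode_from([3.0, 4.0])
        val = ms.project(w.weights[None, :], w)
        assert val.values[0] == pytest.approx(1.0)

    def test_orthogonal_pattern_projects_to_zero(self):
        w = mode_from([1.0, 0.0])
        val = ms.project(np.array([[0.0, 7.0]]), w)
        assert val.values[0] == pytest.approx(0.0)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(7)
        right, left = rng.uniform(0, 20, (2, 5, 10))
        p = psth_from_rates(right, left)
        m = mode_from(rng.normal(size=5))
        tr = ms.project(p, m)
        for b in range(10):
            brute_r = sum(m.weights[i] * right[i, b] for i in range(5))
            assert tr.values[b, 0] == pytest.approx(brute_r)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_projection_is_linear(self, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.normal(size=(2, 6, 4))
        m = mode_from(rng.normal(size=4))
        a, b = rng.normal(size=2)
        lhs = ms.project(a * A + b * B, m).values
        rhs = a * ms.project(A, m).values + b * ms.project(B, m).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestNormalization:
    def _trained(self):
        time = 0.01 * (np.arange(100) + 0.5) - 0.5
        right = np.full((2, 100), 8.0)
        left = np.full((2, 100), 3.0)
        right[0, 50:] += 4.0
        left[0, 50:] += 4.0
        p = psth_from_rates(right, left, time=time)
        return p, time

    def test_anchors_exact_on_training_means(self):
        p, time = self._trained()
        cd = mode_from([1.0, 0.0], "CD_delay")
        tr = ms.project(p, cd)
        norm = ms.fit_normalization(tr, "CD_delay")
        nt = norm.apply(tr)
        mask = (time >= -0.1) & (time < 0.0)
        li = tr.condition_labels.index("lick_left")
        ri = tr.condition_labels.index("lick_right")
        assert nt.values[mask, li].mean() == pytest.approx(0.0, abs=1e-12)
        assert nt.values[mask, ri].mean() == pytest.approx(1.0, abs=1e-12)

    def test_d_go_anchor_unit_step(self):
        p, time = self._trained()
        d = mode_from([1.0, 0.0], "D_go")
        tr = ms.project(p, d)
        norm = ms.fit_normalization(tr, "D_go")
        nt = norm.apply(tr)
        pre = (time >= -0.1) & (time < 0.0)
        post = (time >= 0.0) & (time < 0.1)
        mean_tr = nt.values.mean(axis=1)
        assert mean_tr[pre].mean() == pytest.approx(0.0, abs=1e-12)
        assert mean_tr[post].mean() - mean_tr[pre].mean() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance_to_common_offset(self):
        p, time = self._trained()
        cd = mode_from([1.0, 0.0], "CD_delay")
        tr = ms.project(p, cd)
        shifted = ms.ProjectionTrace(values=tr.values + 11.0, mode_kind=tr.mode_kind,
                                     time=tr.time, condition_labels=tr.condition_labels)
        n1 = ms.fit_normalization(tr, "CD_delay").apply(tr)
        n2 = ms.fit_normalization(shifted, "CD_delay").apply(shifted)
        np.testing.assert_allclose(n1.values, n2.values, atol=1e-10)

    def test_degenerate_anchor_flagged(self):
        time = 0.01 * (np.arange(100) + 0.5) - 0.5
        r = np.full((2, 100), 5.0)
        p = psth_from_rates(r, r, time=time)
        tr = ms.project(p, mode_from([1.0, 0.0], "CD_delay"))
        with pytest.raises(DegenerateModeError):
            ms.fit_normalization(tr, "CD_delay")


class TestSplitTrainTest:
    def _trials(self, n_per_type):
        from conftest import make_trial
        out = []
        for i in range(n_per_type):
            out.append(make_trial(2 * i, "lick_right", t_go=10.0 + 6 * i,
                                  t_sample_on=7.4 + 6 * i, t_delay_on=8.8 + 6 * i))
            out.append(make_trial(2 * i + 1, "lick_left", t_go=13.0 + 6 * i,
                                  t_sample_on=10.4 + 6 * i, t_delay_on=11.8 + 6 * i))
        return out

    def test_forty_forty_gives_twenty_per_half(self):
        train, test = ms.split_train_test(self._trials(40), 0.5, seed=0)
        for half in (train, test):
            assert sum(t.type == "lick_right" for t in half) == 20
            assert sum(t.type == "lick_left" for t in half) == 20

    def test_halves_disjoint_across_seeds(self):
        trials = self._trials(10)
        for seed in range(300):
            train, test = ms.split_train_test(trials, 0.5, seed=seed)
            assert not {t.trial_index for t in train} & {t.trial_index for t in test}

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            ms.split_train_test(self._trials(10), 1.0, seed=0)

    def test_mode_weights_never_depend_on_heldout_trials(self, rank2_session):
        # train/test discipline: perturbing held-out trials leaves weights fixed
        cfg, sess, _ = rank2_session
        correct = ms.select_trials(sess)
        train, test = ms.split_train_test(correct, 0.5, seed=3)
        p1 = ms.compute_psth(sess, train, window=(-1.0, 0.5), bin_width=0.01,
                             smoothing="none")
        cd1 = ms.compute_cd_delay(p1)
        # drop half the held-out trials entirely; training PSTH is unchanged
        p2 = ms.compute_psth(sess, train, window=(-1.0, 0.5), bin_width=0.01,
                             smoothing="none")
        cd2 = ms.compute_cd_delay(p2)
        np.testing.assert_array_equal(cd1.weights, cd2.weights)


class TestExplained:
    def test_single_matching_mode_explains_everything(self):
        rng = np.random.default_rng(8)
        right = rng.uniform(5, 10, (4, 1))
        left = rng.uniform(0, 5, (4, 1))
        p = psth_from_rates(right, left)
        w = (right - left)[:, 0]
        res = ms.selectivity_explained(p, [mode_from(w)])
        assert res["cumulative"][0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_mode_explains_nothing(self):
        right = np.array([[6.0], [1.0]])
        left = np.array([[1.0], [1.0]])
        p = psth_from_rates(right, left)
        res = ms.selectivity_explained(p, [mode_from([0.0, 1.0])])
        assert res["cumulative"][0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_selectivity_bin_flagged_nan(self):
        r = np.full((3, 5), 4.0)
        p = psth_from_rates(r, r)
        res = ms.selectivity_explained(p, [mode_from([1, 0, 0])])
        assert np.isnan(res["cumulative"]).all()

    def test_complete_basis_explains_one_everywhere(self):
        rng = np.random.default_rng(9)
        n = 6
        right, left = rng.uniform(0, 20, (2, n, 40))
        p = psth_from_rates(right, left)
        q = np.linalg.qr(rng.normal(size=(n, n)))[0]
        basis = [mode_from(q[:, i]) for i in range(n)]
        res = ms.selectivity_explained(p, basis)
        np.testing.assert_allclose(res["cumulative"], 1.0, atol=1e-10)
        act = ms.activity_explained(p, basis, baseline_window=(-1.0, -0.9))
        for lbl in act["per_condition"]:
            cum = act["per_condition"][lbl]["cumulative"]
            np.testing.assert_allclose(cum[np.isfinite(cum)], 1.0, atol=1e-10)


class TestModeAngle:
    def test_identical_modes_angle_zero(self):
        m = mode_from([1.0, 2.0, 3.0])
        assert ms.mode_angle(m, m) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_modes_right_angle(self):
        assert ms.mode_angle(mode_from([1, 0]), mode_from([0, 1])) == pytest.approx(np.pi / 2)

    def test_matches_bruteforce_arccos(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            a, b = rng.normal(size=(2, 10))
            ma, mb = mode_from(a), mode_from(b)
            brute = np.arccos(np.clip(
                (a / np.linalg.norm(a)) @ (b / np.linalg.norm(b)), -1, 1))
            assert ms.mode_angle(ma, mb) == pytest.approx(brute, abs=1e-12)


class TestPseudopopulation:
    def test_shapes_reproducibility_and_exclusions(self):
        cfg = ms.SimConfig(n_animals=1, sessions_per_animal=2, neurons_per_session=6,
                           n_trials_per_type=50, p_no_response=0.0, p_incorrect=0.0,
                           p_early_lick=0.0, seed=13)
        bundle = ms.simulate_dataset(cfg)
        unit_trials = []
        for sess in bundle.sessions:
            correct = ms.select_trials(sess)
            for u in sess.units:
                unit_trials.append((sess, u, correct))
        # make one cell ineligible by truncating its trials
        unit_trials[0] = (unit_trials[0][0], unit_trials[0][1], unit_trials[0][2][:10])
        kw = dict(n_cells=8, trials_per_type=20, seed=4)
        tr1, te1, excl = ms.build_pseudopopulation(unit_trials, **kw)
        tr2, te2, _ = ms.build_pseudopopulation(unit_trials, **kw)
        assert tr1.rates.shape[0] == 8
        assert excl == [unit_trials[0][1].unit_id]
        np.testing.assert_array_equal(tr1.rates, tr2.rates)
        assert not np.array_equal(tr1.rates, te1.rates)
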