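"""Forward, backward and smoothing observers against independent oracles."""

import numpy as np
import pytest

import crnobserver as co
from crnobserver.errors import SchemaError, ZeroLikelihoodError

from oracles import DiscretizedHMM


def make_obs(times, outputs, **kw):
    return co.ObservationSequence(times, outputs, **kw)


class TestForwardDiscrete:
    def test_empty_sequence_is_plain_cme(self, birth_death, three_band):
        _, space, A = birth_death
        rho0 = np.zeros(space.n)
        rho0[10] = 1.0
        fwd = co.forward_discrete(
            A, three_band, make_obs([], [], t_start=0.0, t_end=2.0),
            rho0, space, n_interior=4,
        )
        assert fwd.log_evidence == 0.0
        assert np.abs(fwd.final - co.propagate(rho0, A, 2.0)).max() < 1e-9

    def test_certain_observation_collapses(self, two_state):
        _, space, A = two_state
        sensor = co.count_partition("X")
        fwd = co.forward_discrete(
            A, sensor, make_obs([0.0], [1], t_end=0.0),
            np.array([0.5, 0.5]), space,
        )
        assert np.allclose(fwd.final, [0.0, 1.0])

    def test_bayes_update_arithmetic(self, two_state):
        # rho- = (.5,.5), b = (.2,.6)  ->  rho+ = (.25,.75), evidence log .4
        _, space, A = two_state
        g = co.GaussianEmission("X", sd=1.0)

        class FixedDensity:
            def density(self, y, space):
                return np.array([0.2, 0.6])

        fwd = co.forward_discrete(
            A, FixedDensity(), make_obs([0.0], ["y"], t_end=0.0),
            np.array([0.5, 0.5]), space,
        )
        assert np.allclose(fwd.at(0.0, "post"), [0.25, 0.75])
        assert fwd.log_evidence == pytest.approx(np.log(0.4))

    def test_zero_likelihood_identified(self, two_state):
        _, space, A = two_state
        sensor = co.count_partition("X")
        # a frozen chain cannot leave state 0, so observing 1 is impossible
        import scipy.sparse as sp

        A0 = sp.csc_matrix((2, 2))
        with pytest.raises(ZeroLikelihoodError) as err:
            co.forward_discrete(
                A0, sensor, make_obs([0.5], [1], t_start=0.0, t_end=1.0),
                np.array([1.0, 0.0]), space,
            )
        assert err.value.time == 0.5

    def test_forward_uses_no_future_data(self, birth_death, three_band):
        _, space, A = birth_death
        rho0 = co.builtin("birth_death").initial_distribution(space)
        obs_short = make_obs([0.1, 0.2], ["MEDIUM", "HIGH"], t_start=0, t_end=0.2)
        obs_long = make_obs([0.1, 0.2, 0.3, 0.4], ["MEDIUM", "HIGH", "LOW", "LOW"],
                            t_start=0, t_end=0.4)
        a = co.forward_discrete(A, three_band, obs_short, rho0, space, n_interior=3)
        b = co.forward_discrete(A, three_band, obs_long, rho0, space, n_interior=3)
        assert np.abs(a.at(0.2, "post") - b.at(0.2, "post")).max() < 1e-12
        assert np.abs(a.at(0.15, "interior") - b.at(0.15, "interior")).max() < 1e-12


class TestBackward:
    def test_no_observations_all_ones(self, two_state):
        _, space, A = two_state
        bwd = co.backward(
            A, co.count_partition("X"),
            make_obs([], [], t_start=0.0, t_end=1.0), 1.0,
            t_start=0.0, space=space, n_interior=3,
        )
        for row, ls in zip(bwd.values, bwd.log_scale):
            assert np.allclose(row * np.exp(ls), 1.0)

    def test_single_observation_one_step(self, two_state):
        _, space, A = two_state

        class FixedDensity:
            def density(self, y, space):
                return np.array([0.2, 0.6])

        bwd = co.backward(
            A, FixedDensity(), make_obs([1.0], ["y"], t_start=0, t_end=1.0),
            1.0, t_start=0.9, space=space, n_interior=0,
        )
        beta_pre = bwd.at(1.0, "pre") * np.exp(bwd.log_scale[-1])
        # just before the only observation, beta equals the density vector
        got = bwd.at(1.0, "pre")
        assert np.allclose(got / got.max(), np.array([0.2, 0.6]) / 0.6)

    def test_matches_discretized_oracle(self, two_state):
        _, space, A = two_state
        sensor = co.GaussianEmission("X", sd=0.7)
        obs = [(0.25, 0.8), (0.75, 0.1)]
        seq = make_obs([t for t, _ in obs], [y for _, y in obs],
                       t_start=0.0, t_end=1.0)
        bwd = co.backward(A, sensor, seq, 1.0, t_start=0.0, space=space,
                          n_interior=0)
        hmm = DiscretizedHMM(A, 1e-3)
        grid = hmm.backward(0.0, 1.0, obs, lambda y: sensor.density(y, space))
        ref = grid[0]
        got = bwd.start_value
        assert np.abs(got / got.max() - ref / ref.max()).max() < 1e-4


class TestForwardContinual:
    def test_single_class_equals_cme(self, birth_death):
        _, space, A = birth_death
        one = co.DeterministicPartition(species="X", mode="bands",
                                        thresholds=(), labels=("ALL",))
        split = co.split_generator(A, one, space)
        rho0 = np.zeros(space.n)
        rho0[5] = 1.0
        path = co.OutputPath(t_start=0.0, y0="ALL", jump_times=[],
                             jump_outputs=[], t_end=2.0)
        fwd = co.forward_continual(split, path, rho0)
        assert np.abs(fwd.final - co.propagate(rho0, A, 2.0)).max() < 1e-9
        assert fwd.log_evidence == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_jump_update(self, two_state):
        _, space, A = two_state
        sensor = co.count_partition("X")
        split = co.split_generator(A, sensor, space)
        path = co.OutputPath(t_start=0.0, y0=0, jump_times=[0.3],
                             jump_outputs=[1], t_end=0.3)
        fwd = co.forward_continual(split, path, np.array([1.0, 0.0]))
        assert np.allclose(fwd.at(0.3, "post"), [0.0, 1.0])

    def test_fine_sampling_limit_matches_discrete(self, three_band):
        # continual filtering of the exact output path is the limit of
        # discrete noise-free sampling as the sampling interval vanishes
        net = co.builtin("birth_death")
        space = net.state_space()
        A = co.build_generator(net, space)
        split = co.split_generator(A, three_band, space)
        rho0 = net.initial_distribution(space)
        traj = co.ssa(net, {"X": 10}, 2.0, seed=3, space=space)
        path = co.observe(traj, three_band, "continual", space)
        with pytest.warns(UserWarning):  # Poisson prior has off-class mass
            fc = co.forward_continual(split, path, rho0)
        delta = 1e-3
        times = np.arange(delta, 2.0 + 1e-12, delta)
        seq = co.observe(traj, three_band, times, space)
        fd = co.forward_discrete(A, three_band, seq, rho0, space, n_interior=0)
        assert 0.5 * np.abs(fc.final - fd.final).sum() < 1e-3

    def test_nonlinear_form_agrees(self, birth_death, three_band):
        net, space, A = birth_death
        split = co.split_generator(A, three_band, space)
        rho0 = net.initial_distribution(space)
        traj = co.ssa(net, {"X": 10}, 1.0, seed=5, space=space)
        path = co.observe(traj, three_band, "continual", space)
        with pytest.warns(UserWarning):
            lin = co.forward_continual(split, path, rho0)
        with pytest.warns(UserWarning):
            non = co.forward_continual(split, path, rho0, form="nonlinear")
        assert np.abs(lin.final - non.final).max() < 1e-8
        assert lin.log_evidence == pytest.approx(non.log_evidence, abs=1e-6)

    def test_consecutive_equal_outputs_rejected(self):
        with pytest.raises(SchemaError):
            co.OutputPath(t_start=0.0, y0="A", jump_times=[0.5],
                          jump_outputs=["A"], t_end=1.0)

    def test_offclass_prior_mass_warns(self, two_state):
        _, space, A = two_state
        split = co.split_generator(A, co.count_partition("X"), space)
        path = co.OutputPath(t_start=0.0, y0=0, jump_times=[],
                             jump_outputs=[], t_end=0.1)
        with pytest.warns(UserWarning):
            co.forward_continual(split, path, np.array([0.5, 0.5]))


@pytest.fixture(scope="module")
def run(birth_death, three_band):
    net, space, A = birth_death
    rho0 = net.initial_distribution(space)
    traj = co.ssa(net, {"X": 10}, 3.0, seed=2, space=space)
    obs = co.observe(traj, three_band, ("periodic", 0.1), space)
    fwd, bwd, sm = co.smoother(A, three_band, obs, rho0, space, n_interior=4)
    return space, obs, fwd, bwd, sm


class TestSmoothing:

    def test_smoothed_equals_forward_at_end(self, run, tv_dist):
        _, obs, fwd, _, sm = run
        assert tv_dist(sm.final, fwd.final) < 1e-8

    def test_continuous_across_observations_while_forward_jumps(self, run, tv_dist):
        _, obs, fwd, _, sm = run
        fwd_jumps = []
        for t in obs.times:
            assert tv_dist(sm.at(t, "pre"), sm.at(t, "post")) < 1e-6
            fwd_jumps.append(tv_dist(fwd.at(t, "pre"), fwd.at(t, "post")))
        assert max(fwd_jumps) > 1e-3

    def test_smoothed_equals_filter_when_no_future_data(self, birth_death,
                                                        three_band, tv_dist):
        net, space, A = birth_death
        rho0 = net.initial_distribution(space)
        obs = make_obs([0.5], ["MEDIUM"], t_start=0.0, t_end=2.0)
        fwd, bwd, sm = co.smoother(A, three_band, obs, rho0, space, n_interior=4)
        # beta is constant 1 after the last observation: smoothed == filtered
        for t, side in zip(sm.times, sm.sides):
            if t > 0.5:
                assert tv_dist(sm.at(t, side), fwd.at(t, side)) < 1e-10

    def test_grid_realignment_by_repropagation(self, birth_death, three_band,
                                               tv_dist):
        net, space, A = birth_death
        rho0 = net.initial_distribution(space)
        obs = co.observe(co.ssa(net, {"X": 10}, 1.0, seed=9, space=space),
                         three_band, ("periodic", 0.25), space)
        fwd = co.forward_discrete(A, three_band, obs, rho0, space, n_interior=7)
        bwd = co.backward(A, three_band, obs, space=space, n_interior=2)
        ref = co.smoother(A, three_band, obs, rho0, space, n_interior=7)[2]
        sm = co.smooth(fwd, bwd, A=A)  # grids differ; re-propagation path
        for t, side in zip(ref.times, ref.sides):
            assert tv_dist(sm.at(t, side), ref.at(t, side)) < 1e-8


class TestMMSE:
    def test_point_mass_moments(self, birth_death):
        _, space, _ = birth_death
        p = np.zeros(space.n)
        p[5] = 1.0
        series = co.SmoothedResult(np.array([0.0]), np.array(["interior"]),
                                   p[None, :])
        _, mean, sd = co.mmse(series, space, "X")
        assert mean[0] == 5.0 and sd[0] == 0.0

    def test_two_point_moments(self, birth_death):
        _, space, _ = birth_death
        p = np.zeros(space.n)
        p[0] = p[10] = 0.5
        series = co.SmoothedResult(np.array([0.0]), np.array(["interior"]),
                                   p[None, :])
        _, mean, sd = co.mmse(series, space, "X")
        assert mean[0] == pytest.approx(5.0)
        assert sd[0] == pytest.approx(5.0)

    def test_truncated_poisson_moments(self):
        net = co.builtin("birth_death", k=10, gamma=1, cap=40)
        space = net.state_space()
        p = net.initial_distribution(space)  # truncated Poisson(10)
        series = co.SmoothedResult(np.array([0.0]), np.array(["interior"]),
                                   p[None, :])
        _, mean, sd = co.mmse(series, space, "X")
        assert mean[0] == pytest.approx(10.0, abs=1e-6)
        assert sd[0] == pytest.approx(np.sqrt(10.0), abs=1e-6)

    def test_unknown_species_rejected(self, birth_death):
        _, space, _ = birth_death
        series = co.SmoothedResult(np.array([0.0]), np.array(["interior"]),
                                   np.ones((1, space.n)) / space.n)
        with pytest.raises(Exception):
            co.mmse(series, space, "Q")


class TestEvidence:
    def test_joint_probability_matches_bruteforce(self, two_state):
        _, space, A = two_state
        sensor = co.GaussianEmission("X", sd=0.5)
        rho0 = np.array([0.7, 0.3])
        obs = make_obs([0.2, 0.6, 1.1], [0.9, 0.2, 1.2], t_start=0.0, t_end=1.2)
        fwd = co.forward_discrete(A, sensor, obs, rho0, space, n_interior=0)
        from scipy.linalg import expm

        a = rho0.copy()
        t_cur, total = 0.0, 1.0
        for t, y in zip(obs.times, obs.outputs):
            a = expm(A.toarray() * (t - t_cur)) @ a
            b = sensor.density(y, space)
            w = float(b @ a)
            total *= w
            a = b * a / w
            t_cur = t
        assert np.exp(fwd.log_evidence) == pytest.approx(total, rel=1e-8)
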