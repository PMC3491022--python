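"""Composed-observer model discrimination and distinguishability."""

import numpy as np
import pytest

import crnobserver as co


def two_state_net(up, down, name):
    return co.ReactionNetwork(
        name=name,
        species=[co.Species("X", cap=1)],
        reactions=[
            co.Reaction(name="up", changes={"X": +1}, rate=up),
            co.Reaction(name="down", changes={"X": -1}, rate=down),
        ],
        initial_condition=co.InitialCondition(kind="point", state={"X": 0}),
    )


def indicator_propensity(table):
    return lambda x, t=dict(table): t.get(int(x[0]), 0.0)


@pytest.fixture(scope="module")
def bd_pair_ensemble():
    nets = [co.builtin("birth_death", k=8.0, gamma=1.0),
            co.builtin("birth_death", k=12.0, gamma=1.0)]
    nets[0].name, nets[1].name = "slow", "fast"
    sensor = co.three_band_partition("X")
    models = [co.CandidateModel.from_network(n, name=n.name) for n in nets]
    return co.ModelEnsemble(models=models, sensor=sensor)


class TestComposition:
    def test_single_model_identity(self):
        net = co.builtin("birth_death", cap=10)
        ens = co.ModelEnsemble(
            models=[co.CandidateModel.from_network(net)],
            sensor=co.three_band_partition("X"),
        )
        comp = co.compose(ens)
        A = co.build_generator(net, net.state_space())
        assert (comp.A - A).nnz == 0
        assert np.allclose(comp.rho0, net.initial_distribution(net.state_space()))

    def test_block_structure_and_size(self, tvo_trio):
        sensor = co.count_partition("P")
        ens = co.ModelEnsemble(
            models=[co.CandidateModel.from_network(n) for n in tvo_trio],
            sensor=sensor,
        )
        comp = co.compose(ens)
        assert comp.A.shape == (3 * 3171, 3 * 3171)
        # no cross-block transitions: the model index never changes
        coo = comp.A.tocoo()
        blk = np.zeros(comp.A.shape[0], dtype=int)
        for i, s in enumerate(comp.slices):
            blk[s] = i
        assert np.all(blk[coo.row] == blk[coo.col])

    def test_identical_models_posterior_stays_at_prior(self, tv_dist):
        net = co.builtin("birth_death", cap=15)
        sensor = co.three_band_partition("X")
        ens = co.ModelEnsemble(
            models=[co.CandidateModel.from_network(net, name="a"),
                    co.CandidateModel.from_network(net, name="b")],
            sensor=sensor,
        )
        comp = co.compose(ens)
        space = net.state_space()
        traj = co.ssa(net, {"X": 10}, 4.0, seed=1, space=space)
        seq = co.observe(traj, sensor, ("periodic", 0.2), space)
        fwd = co.forward_discrete(comp.A, comp.sensor_view, seq, comp.rho0, None)
        mp = co.model_posterior(fwd, comp)
        assert np.abs(mp.to_numpy() - 0.5).max() < 1e-9

    def test_prior_weights_before_any_observation(self, bd_pair_ensemble):
        ens = bd_pair_ensemble
        comp = co.compose(ens)
        assert comp.block_sums(comp.rho0) == pytest.approx([0.5, 0.5])

    def test_posterior_equals_softmax_of_per_model_evidence(self,
                                                            bd_pair_ensemble):
        ens = bd_pair_ensemble
        comp = co.compose(ens)
        gen = ens.models[1]  # simulate from the fast model
        traj = co.ssa(gen.network, {"X": 10}, 5.0, seed=2, space=gen.space)
        seq = co.observe(traj, ens.sensor, ("periodic", 0.25), gen.space)
        fwd = co.forward_discrete(comp.A, comp.sensor_view, seq, comp.rho0, None)
        mp = co.model_posterior(fwd, comp)
        # independent route: two separate single-model filters + Bayes
        levs = []
        for cand in ens.models:
            f = co.forward_discrete(cand.A, ens.sensor, seq, cand.rho0, cand.space)
            levs.append(f.log_evidence)
        levs = np.array(levs) + np.log(ens.weights)
        ref = np.exp(levs - levs.max())
        ref /= ref.sum()
        got = mp.iloc[-1].to_numpy()
        assert np.abs(got - ref).max() < 1e-6
        # every row of the posterior table is normalized
        assert np.abs(mp.sum(axis=1) - 1.0).max() < 1e-8

    def test_alphabet_mismatch_rejected(self):
        nets = [co.builtin("birth_death", cap=10), co.builtin("birth_death", cap=12)]
        with pytest.raises(co.ModelError):
            co.ModelEnsemble(
                models=[co.CandidateModel.from_network(n) for n in nets],
                sensor=co.count_partition("X"),
            )


class TestHazardProfiles:
    def test_single_output_class_no_contexts(self):
        net = co.builtin("birth_death", cap=10)
        sensor = co.DeterministicPartition(species="X", mode="bands",
                                           thresholds=(), labels=("ALL",))
        profiles, skipped, out_dist, _ = co.model_hazard_profiles(net, sensor)
        assert profiles == {} and skipped == []
        assert out_dist["ALL"] == pytest.approx(1.0)

    def test_two_state_constant_exponential_hazard(self, two_state):
        # a single-state output class relaxes nowhere: its hazard is flat
        net, space, A = two_state
        sensor = co.count_partition("X")
        profiles, _, _, grid = co.model_hazard_profiles(net, sensor)
        h = profiles[(0, 1)].hazards[0]
        assert np.allclose(h, 0.8, atol=1e-12)  # the down-rate
        h2 = profiles[(1, 0)].hazards[1]
        assert np.allclose(h2, 1.2, atol=1e-12)

    def test_self_transition_context_rejected(self, two_state):
        net, space, A = two_state
        sensor = co.count_partition("X")
        split = co.split_generator(A, sensor, space)
        p = co.steady_state(A)
        with pytest.raises(co.ModelError):
            co.hazard_profile(A, split, p, 1, 1, np.array([0.1]))

    def test_hazard_matches_empirical_dwell_times(self):
        """Medium-band dwell hazard vs an SSA sojourn estimate (3 SE)."""
        net = co.builtin("birth_death")
        space = net.state_space()
        A = co.build_generator(net, space)
        sensor = co.three_band_partition("X")
        split = co.split_generator(A, sensor, space)
        p_ss = co.steady_state(A)
        # empirical: long stationary run, sojourns in MEDIUM entered from LOW
        traj = co.ssa(net, {"X": 10}, 30_000.0, seed=8, space=space)
        labels = [sensor.output_of(s, space) for s in traj.states]
        spans = []  # (dwell duration, exited_to) for LOW->MEDIUM entries
        for i in range(1, len(labels)):
            if labels[i] == "MEDIUM" and labels[i - 1] == "LOW":
                j = i
                while j + 1 < len(labels) and labels[j + 1] == "MEDIUM":
                    j += 1
                if j + 1 < len(labels):
                    spans.append((traj.times[j + 1] - traj.times[i], labels[j + 1]))
        spans = spans[:20_000]
        durations = np.array([d for d, _ in spans])
        # survival-conditional exit probability in a dwell-time bin [a, b):
        # 1 - exp(-int_a^b h_total) with h_total from the profile, vs the
        # at-risk empirical fraction, within three binomial standard errors
        grid = np.linspace(1e-4, 0.3, 601)
        prof = co.hazard_profile(A, split, p_ss, "LOW", "MEDIUM", grid)
        total_h = prof.total_exit
        for a, b in [(0.0, 0.05), (0.05, 0.15), (0.15, 0.3)]:
            at_risk = durations >= a
            exits = at_risk & (durations < b)
            n_risk = at_risk.sum()
            p_exit = exits.sum() / n_risk
            se = np.sqrt(p_exit * (1 - p_exit) / n_risk)
            mask = (grid >= a) & (grid <= b)
            p_model = 1.0 - np.exp(-np.trapezoid(total_h[mask], grid[mask]))
            assert abs(p_exit - p_model) < 3 * se + 0.005


class TestDistinguishability:
    def test_model_vs_itself_indistinguishable(self):
        net = co.builtin("birth_death")
        r = co.distinguishable(net, net, co.three_band_partition("X"))
        assert not r.distinguishable
        assert r.max_relative_discrepancy < 1e-12
        assert r.stationary_output_tv < 1e-12

    def test_different_rates_distinguishable(self):
        a = co.builtin("birth_death", k=8.0)
        b = co.builtin("birth_death", k=12.0)
        r = co.distinguishable(a, b, co.three_band_partition("X"))
        assert r.distinguishable

    def test_symmetry_of_verdict(self):
        a = co.builtin("birth_death", k=8.0)
        b = co.builtin("birth_death", k=12.0)
        sensor = co.three_band_partition("X")
        assert (co.distinguishable(a, b, sensor).distinguishable
                == co.distinguishable(b, a, sensor).distinguishable)

    def test_exact_lumping_indistinguishable(self):
        """Splitting one state into two with identical output and preserved
        aggregate rates (exact lumpability) leaves the output law unchanged."""
        two = two_state_net(2.0, 3.0, "two")
        three = co.ReactionNetwork(
            name="three",
            species=[co.Species("X", cap=2)],
            reactions=[
                co.Reaction(name="u1", changes={"X": 1},
                            propensity=indicator_propensity({0: 0.8})),
                co.Reaction(name="u2", changes={"X": 2},
                            propensity=indicator_propensity({0: 1.2})),
                co.Reaction(name="d1", changes={"X": -1},
                            propensity=indicator_propensity({1: 3.0})),
                co.Reaction(name="d2", changes={"X": -2},
                            propensity=indicator_propensity({2: 3.0})),
            ],
            initial_condition=co.InitialCondition(kind="point", state={"X": 0}),
        )
        sensor = co.DeterministicPartition(species="X", mode="bands",
                                           thresholds=(0,), labels=("off", "on"))
        r = co.distinguishable(two, three, sensor)
        assert not r.distinguishable
        assert r.max_relative_discrepancy < 1e-10

    def test_unequal_exit_rates_break_lumpability(self):
        two = two_state_net(2.0, 3.0, "two")
        bad = co.ReactionNetwork(
            name="bad",
            species=[co.Species("X", cap=2)],
            reactions=[
                co.Reaction(name="u1", changes={"X": 1},
                            propensity=indicator_propensity({0: 0.8})),
                co.Reaction(name="u2", changes={"X": 2},
                            propensity=indicator_propensity({0: 1.2})),
                co.Reaction(name="d1", changes={"X": -1},
                            propensity=indicator_propensity({1: 1.0})),
                co.Reaction(name="d2", changes={"X": -2},
                            propensity=indicator_propensity({2: 5.0})),
            ],
            initial_condition=co.InitialCondition(kind="point", state={"X": 0}),
        )
        sensor = co.DeterministicPartition(species="X", mode="bands",
                                           thresholds=(0,), labels=("off", "on"))
        assert co.distinguishable(two, bad, sensor).distinguishable

    def test_grid_refinement_stability(self):
        a = co.builtin("birth_death", k=8.0, cap=20)
        b = co.builtin("birth_death", k=12.0, cap=20)
        sensor = co.three_band_partition("X")
        coarse = co.distinguishable(a, b, sensor, n_tau=100)
        _, _, _, grid = co.model_hazard_profiles(a, sensor)
        fine_grid = np.geomspace(grid[0], grid[-1], 2 * len(grid))
        fine = co.distinguishable(a, b, sensor, tau_grid=fine_grid)
        rel_change = abs(fine.max_relative_discrepancy
                         - coarse.max_relative_discrepancy)
        assert rel_change < 0.1 * coarse.max_relative_discrepancy

    def test_taylor_coefficients_agree_for_identical_models(self):
        net = co.builtin("birth_death", cap=15)
        sensor = co.three_band_partition("X")
        pa, _, _, _ = co.model_hazard_profiles(net, sensor, taylor_order=10)
        pb, _, _, _ = co.model_hazard_profiles(net, sensor, taylor_order=10)
        for key in pa:
            for d in pa[key].taylor:
                assert np.allclose(pa[key].taylor[d], pb[key].taylor[d])


class TestConsistency:
    def test_posterior_concentrates_on_generating_model(self, bd_pair_ensemble):
        """Data from one member of a distinguishable pair: its posterior
        should win by the end of a long window in most replicates."""
        ens = bd_pair_ensemble
        comp = co.compose(ens)
        wins = 0
        n_rep = 12
        for seed in range(n_rep):
            gen = ens.models[seed % 2]
            traj = co.ssa(gen.network, {"X": gen.network.reactions[0].rate
                                        and 10}, 40.0, seed=seed,
                          space=gen.space)
            seq = co.observe(traj, ens.sensor, ("periodic", 0.5), gen.space)
            fwd = co.forward_discrete(comp.A, comp.sensor_view, seq,
                                      comp.rho0, None)
            mp = co.model_posterior(fwd, comp).iloc[-1]
            wins += mp.idxmax() == gen.name
        assert wins >= 0.9 * n_rep
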