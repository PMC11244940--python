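"""Restricted neuron: transmissions, form conversion, loss, gradients."""

import numpy as np
import pytest

from parasyn.patterns import PatternSet, generate_patterns, make_fixture
from parasyn.restricted import (
    RestrictedNeuron,
    RestrictedNeuronModel,
    SynapseParams,
    TrainConfig,
    convert_tanh_to_sigmoid,
    gradient_step,
    hinge_loss,
    margin_violation_set,
    resurrect_dead_synapses,
    sigmoid_transmission,
    tanh_form_transmission,
    train_restricted,
)


class TestTransmissions:
    @pytest.mark.parametrize("a,s,t,x,expected", [
        (1, 4, 0.5, 0.5, 0.5),            # logistic at threshold: a^2/2
        (2, 10, 0.0, 100.0, 4.0),          # saturation at amplitude a^2
        (1, 2, 0.0, 1.0, 1 / (1 + np.exp(-2))),
    ])
    def test_sigmoid_closed_forms(self, a, s, t, x, expected):
        p = SynapseParams(a=a, s=s, t=t)
        assert sigmoid_transmission(p, x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("a,s,t,x,expected", [
        (1, 1, 0.5, 0.5, 0.0),
        (1, 1, 0.0, 50.0, 1.0),
        (1, 1, 0.0, 1.0, np.tanh(1)),
    ])
    def test_tanh_closed_forms(self, a, s, t, x, expected):
        p = SynapseParams(a=a, s=s, t=t)
        assert tanh_form_transmission(p, x) == pytest.approx(expected, abs=1e-12)

    def test_sigmoid_bounded_and_increasing(self):
        p = SynapseParams(a=1.5, s=3.0, t=0.4)
        xs = np.linspace(-5, 5, 200)
        h = sigmoid_transmission(p, xs)
        assert (h >= 0).all() and (h <= p.a**2).all()
        assert (np.diff(h) > 0).all()

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams(a=1, s=-0.1, t=0)


class TestFormConversion:
    def test_single_synapse_mapping(self):
        n = RestrictedNeuron(a=[[1.0]], s=[[1.0]], t=[[0.5]], theta=0.0,
                             parameterization="tanh")
        c = convert_tanh_to_sigmoid(n)
        assert c.parameterization == "sigmoid"
        assert c.a[0, 0] ** 2 == pytest.approx(2.0)
        assert c.s[0, 0] == pytest.approx(2.0)
        assert c.t[0, 0] == pytest.approx(0.5)
        # z - theta preservation forces theta' + a'^2 (cross-checked
        # numerically in test_margin_preserved_on_random_neurons)
        assert c.theta == pytest.approx(1.0)

    def test_zero_amplitude_fixed_point(self):
        n = RestrictedNeuron(a=np.zeros((2, 2)), s=np.ones((2, 2)),
                             t=np.zeros((2, 2)), theta=0.7, parameterization="tanh")
        c = convert_tanh_to_sigmoid(n)
        np.testing.assert_array_equal(c.a, 0.0)
        assert c.theta == pytest.approx(0.7)

    def test_margin_preserved_on_random_neurons(self, rng):
        n = RestrictedNeuron(a=rng.normal(0, 1, (3, 2)), s=rng.uniform(0, 5, (3, 2)),
                             t=rng.uniform(0, 1, (3, 2)), theta=rng.normal(),
                             parameterization="tanh")
        c = convert_tanh_to_sigmoid(n)
        X = rng.uniform(0, 1, (50, 3))
        np.testing.assert_allclose(
            np.asarray(n.total_current(X)) - n.theta,
            np.asarray(c.total_current(X)) - c.theta,
            atol=1e-10,
        )
        np.testing.assert_array_equal(n.predict(X), c.predict(X))

    def test_requires_tanh_tag(self):
        n = RestrictedNeuron(a=[[1.0]], s=[[1.0]], t=[[0.0]], theta=0.0,
                             parameterization="sigmoid")
        with pytest.raises(ValueError):
            convert_tanh_to_sigmoid(n)


class TestTotalCurrentAndPredict:
    def test_zero_amplitudes(self):
        n = RestrictedNeuron(a=np.zeros((3, 2)), s=np.full((3, 2), 5.0),
                             t=np.zeros((3, 2)), theta=0.0)
        assert n.total_current(np.array([0.1, 0.5, 0.9])) == 0.0

    def test_single_synapse_equals_transmission(self):
        n = RestrictedNeuron(a=[[1.3]], s=[[4.0]], t=[[0.2]], theta=0.0)
        p = SynapseParams(a=1.3, s=4.0, t=0.2)
        x = 0.77
        assert n.total_current(np.array([x])) == pytest.approx(
            float(sigmoid_transmission(p, x)))

    def test_hand_summed_grid(self):
        # 2 axons x 2 identical synapses at their thresholds: 4 * a^2/2 = 2
        n = RestrictedNeuron(a=np.ones((2, 2)), s=np.full((2, 2), 4.0),
                             t=np.full((2, 2), 0.5), theta=0.0)
        assert n.total_current(np.array([0.5, 0.5])) == pytest.approx(2.0)

    def test_dimension_mismatch(self):
        n = RestrictedNeuron(a=np.ones((2, 1)), s=np.ones((2, 1)),
                             t=np.zeros((2, 1)), theta=0.0)
        with pytest.raises(ValueError):
            n.total_current(np.array([0.5, 0.5, 0.5]))

    def test_tie_rule_predicts_negative(self):
        n = RestrictedNeuron(a=np.zeros((1, 1)), s=np.ones((1, 1)),
                             t=np.zeros((1, 1)), theta=0.0)
        assert n.predict(np.array([0.5])) == -1  # z - theta == 0
        n.theta = -5.0
        assert n.predict(np.array([0.5])) == 1
        n.theta = 5.0
        assert n.predict(np.array([0.5])) == -1


class TestHingeLossAndViolations:
    def _neuron_with_margins(self, margins, labels):
        """1-axon zero-amplitude neuron with theta chosen per pattern is not
        possible; instead realize margins via theta=0 and direct z values by
        monkey construction: use amplitude 0 and shift labels/margins through
        theta. Simplest: evaluate loss formula through a neuron whose z==0 and
        theta = -margin*label per pattern is impossible, so use the public
        functions with crafted data on a rich neuron instead."""

    def test_zero_loss_when_all_margins_met(self):
        n = RestrictedNeuron(a=[[2.0]], s=[[8.0]], t=[[0.5]], theta=2.0 - 0.0)
        # z in (0, 4); choose points far from threshold
        data = PatternSet(inputs=np.array([[0.99], [0.01]]), labels=np.array([1, -1]))
        # z(0.99) ~ 4, z(0.01) ~ 0 -> margins ~ 2 each with theta = 2
        assert hinge_loss(n, data, 0.1) == 0.0
        assert margin_violation_set(n, data, 0.1).size == 0

    def test_loss_values_on_boundary_cases(self):
        # zero-amplitude neuron: z = 0 for every pattern
        n = RestrictedNeuron(a=np.zeros((1, 1)), s=np.ones((1, 1)),
                             t=np.zeros((1, 1)), theta=0.0)
        data1 = PatternSet(inputs=np.array([[0.5]]), labels=np.array([1]))
        assert hinge_loss(n, data1, 0.1) == pytest.approx(0.1)  # z-theta = 0
        n2 = RestrictedNeuron(a=np.zeros((1, 1)), s=np.ones((1, 1)),
                              t=np.zeros((1, 1)), theta=1.0)
        assert hinge_loss(n2, data1, 0.1) == pytest.approx(1.1)  # margin -1

    def test_violation_set_strictness(self):
        # margins exactly epsilon are excluded (strict inequality)
        n = RestrictedNeuron(a=np.zeros((1, 1)), s=np.ones((1, 1)),
                             t=np.zeros((1, 1)), theta=-0.1)
        data = PatternSet(inputs=np.array([[0.5]]), labels=np.array([1]))
        # margin = (0 - (-0.1))*1 = 0.1 == epsilon -> excluded
        assert margin_violation_set(n, data, 0.1).size == 0
        assert hinge_loss(n, data, 0.1) == 0.0

    def test_violation_set_selection(self):
        # three 1-axon patterns with distinct margins via distinct inputs
        n = RestrictedNeuron(a=[[1.0]], s=[[30.0]], t=[[0.5]], theta=0.5)
        data = PatternSet(inputs=np.array([[0.51], [0.9], [0.1]]),
                          labels=np.array([1, 1, 1]))
        m = (np.asarray(n.total_current(data.inputs)) - n.theta) * data.labels
        assert 0 < m[0] < 0.1 and m[1] > 0.1 and m[2] < 0
        np.testing.assert_array_equal(margin_violation_set(n, data, 0.1), [0, 2])


class TestGradientStep:
    def test_empty_violation_set_is_identity(self):
        n = RestrictedNeuron(a=[[2.0]], s=[[8.0]], t=[[0.5]], theta=2.0)
        data = PatternSet(inputs=np.array([[0.99], [0.01]]), labels=np.array([1, -1]))
        cfg = TrainConfig()
        out = gradient_step(n, data, cfg)
        np.testing.assert_array_equal(out.a, n.a)
        np.testing.assert_array_equal(out.t, n.t)
        assert out.theta == n.theta

    def test_theta_rule_two_positive_violators(self):
        n = RestrictedNeuron(a=np.zeros((1, 1)), s=np.ones((1, 1)),
                             t=np.zeros((1, 1)), theta=1.0)
        data = PatternSet(inputs=np.array([[0.2], [0.8]]), labels=np.array([1, 1]))
        cfg = TrainConfig(lr_theta=0.05)
        out = gradient_step(n, data, cfg)
        assert out.theta == pytest.approx(1.0 - 2 * 0.05)

    def test_slope_projection_nonnegative(self):
        n = RestrictedNeuron(a=[[1.0]], s=[[0.001]], t=[[0.9]], theta=0.0,
                             parameterization="sigmoid")
        data = PatternSet(inputs=np.array([[0.1]]), labels=np.array([-1]))
        cfg = TrainConfig(lr_s=10.0)
        out = gradient_step(n, data, cfg)
        assert (out.s >= 0).all()

    @pytest.mark.parametrize("form", ["sigmoid", "tanh"])
    def test_matches_finite_difference_gradient(self, form):
        """Analytic updates equal the negative central-difference gradient of
        the hinge loss (tolerance 1e-4) on >=100 random configurations,
        skipping draws that sit on the hinge nondifferentiability."""
        rng = np.random.default_rng(99)
        lr = 1e-7
        h = 1e-6
        checked = 0
        trial = 0
        while checked < 100 and trial < 600:
            trial += 1
            N, M = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            n = RestrictedNeuron(
                a=rng.normal(0, 0.7, (N, M)), s=rng.uniform(0.5, 6, (N, M)),
                t=rng.uniform(0, 1, (N, M)), theta=rng.normal(0, 0.5),
                parameterization=form)
            data = generate_patterns(4, N, seed=int(rng.integers(1 << 30)))
            m = (np.asarray(n.total_current(data.inputs)) - n.theta) * data.labels
            if np.any(np.abs(0.1 - m) < 1e-4):
                continue
            cfg = TrainConfig(lr_a=lr, lr_s=lr, lr_t=lr, lr_theta=lr)
            new = gradient_step(n, data, cfg)
            for name in ("a", "s", "t"):
                upd = (getattr(new, name) - getattr(n, name)) / lr
                for idx in np.ndindex((N, M)):
                    if name == "s" and getattr(n, name)[idx] < h:
                        continue
                    n1, n2 = n.copy(), n.copy()
                    getattr(n1, name)[idx] += h
                    getattr(n2, name)[idx] -= h
                    fd = -(hinge_loss(n1, data, 0.1) - hinge_loss(n2, data, 0.1)) / (2 * h)
                    if abs(fd) > 1e-3:
                        assert upd[idx] == pytest.approx(fd, rel=1e-4)
                        checked += 1
            n1, n2 = n.copy(), n.copy()
            n1.theta += h
            n2.theta -= h
            fd = -(hinge_loss(n1, data, 0.1) - hinge_loss(n2, data, 0.1)) / (2 * h)
            if abs(fd) > 1e-3:
                assert (new.theta - n.theta) / lr == pytest.approx(fd, rel=1e-4)
                checked += 1
        assert checked >= 100

    def test_loss_descends_at_small_rates(self):
        """With all rates 1e-4, ten consecutive steps do not increase the
        hinge loss in at least 95% of random trials."""
        rng = np.random.default_rng(17)
        ok = 0
        trials = 40
        cfg = TrainConfig(lr_a=1e-4, lr_s=1e-4, lr_t=1e-4, lr_theta=1e-4)
        for i in range(trials):
            n = RestrictedNeuron(
                a=rng.normal(0, 0.5, (2, 2)), s=rng.uniform(0.5, 6, (2, 2)),
                t=rng.uniform(0, 1, (2, 2)), theta=rng.normal(0, 0.3),
                parameterization="tanh")
            data = generate_patterns(6, 2, seed=1000 + i)
            losses = [hinge_loss(n, data, cfg.margin)]
            good = True
            for _ in range(10):
                n = gradient_step(n, data, cfg)
                losses.append(hinge_loss(n, data, cfg.margin))
                if losses[-1] > losses[-2] + 1e-12:
                    good = False
            ok += good
        assert ok / trials >= 0.95


class TestResurrection:
    def _cfg(self):
        return TrainConfig(resurrection_floor=0.01)

    def test_live_synapses_untouched(self, rng):
        n = RestrictedNeuron(a=np.full((2, 2), 1.0), s=np.ones((2, 2)),
                             t=np.full((2, 2), 0.5), theta=0.0,
                             parameterization="sigmoid")
        out, count = resurrect_dead_synapses(n, self._cfg(), rng)
        assert count == 0
        np.testing.assert_array_equal(out.a, n.a)
        np.testing.assert_array_equal(out.t, n.t)

    def test_dead_synapse_raised_to_floor(self, rng):
        n = RestrictedNeuron(a=np.array([[1e-3, 1.0]]), s=np.ones((1, 2)),
                             t=np.full((1, 2), 0.5), theta=0.0,
                             parameterization="sigmoid")
        out, count = resurrect_dead_synapses(n, self._cfg(), rng)
        assert count == 1
        assert out.a[0, 0] ** 2 == pytest.approx(0.01)
        assert 0.0 <= out.t[0, 0] <= 1.0
        assert out.t[0, 1] == 0.5  # live synapse keeps its threshold
        np.testing.assert_array_equal(out.s, n.s)

    def test_tanh_form_floor_on_effective_amplitude(self, rng):
        n = RestrictedNeuron(a=np.array([[1e-3]]), s=np.ones((1, 1)),
                             t=np.full((1, 1), 0.5), theta=0.0,
                             parameterization="tanh")
        out, _ = resurrect_dead_synapses(n, self._cfg(), rng)
        assert 2 * out.a[0, 0] ** 2 == pytest.approx(0.01)

    def test_deterministic_given_rng_state(self):
        n = RestrictedNeuron(a=np.full((3, 3), 1e-4), s=np.ones((3, 3)),
                             t=np.zeros((3, 3)), theta=0.0,
                             parameterization="sigmoid")
        out1, _ = resurrect_dead_synapses(n, self._cfg(), np.random.default_rng(5))
        out2, _ = resurrect_dead_synapses(n, self._cfg(), np.random.default_rng(5))
        np.testing.assert_array_equal(out1.t, out2.t)


class TestMonotonicityInvariant:
    def test_aggregate_nondecreasing_through_training(self):
        data = make_fixture("xor4")
        cfg = TrainConfig(seed=0, max_epochs=300)
        neuron, _ = train_restricted(data, 2, 2, cfg)
        grid = np.linspace(0, 1, 101)
        for axon in range(2):
            vals = neuron.aggregate_axon_values(axon, grid)
            assert (np.diff(vals) >= -1e-12).all()


class TestTrainRestricted:
    def test_two_point_separable_single_synapse(self, sep2):
        _, report = train_restricted(sep2, 1, 1, TrainConfig(seed=0))
        assert report.success

    def test_xor_fixture_solved_for_some_seed(self, xor4):
        wins = 0
        for seed in range(5):
            _, report = train_restricted(xor4, 2, 2, TrainConfig(seed=seed))
            wins += report.success
        assert wins >= 1

    def test_empty_dataset_immediate_success(self):
        data = PatternSet(inputs=np.empty((0, 3)), labels=np.empty((0,), dtype=int))
        _, report = train_restricted(data, 3, 2, TrainConfig(seed=0))
        assert report.success and report.epochs == 0

    def test_dimension_mismatch(self, xor4):
        with pytest.raises(ValueError):
            train_restricted(xor4, 5, 2, TrainConfig(seed=0))

    def test_form_equivalence_after_training(self, xor4):
        neuron, report = train_restricted(xor4, 2, 2, TrainConfig(seed=0))
        if neuron.parameterization == "tanh":
            sig = convert_tanh_to_sigmoid(neuron)
            np.testing.assert_array_equal(sig.predict(xor4.inputs),
                                          neuron.predict(xor4.inputs))


class TestSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        n = RestrictedNeuron(a=rng.normal(0, 1, (3, 2)), s=rng.uniform(0, 5, (3, 2)),
                             t=rng.uniform(0, 1, (3, 2)), theta=0.123456789012345,
                             parameterization="tanh")
        path = tmp_path / "neuron.json"
        n.to_json(path)
        back = RestrictedNeuron.from_json(path)
        np.testing.assert_array_equal(back.a, n.a)
        np.testing.assert_array_equal(back.s, n.s)
        np.testing.assert_array_equal(back.t, n.t)
        assert back.theta == n.theta
        assert back.parameterization == "tanh"


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, sep2):
        res = RestrictedNeuronModel(sep2, synapses_per_axon=1).fit()
        assert res.converged
        text = res.summary()
        assert "synapses/axon" in text and "converged" in text
        np.testing.assert_array_equal(res.predict(sep2.inputs), sep2.labels)
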