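"""Tests for ESN construction, training, the protocol, and CPP detection."""

import numpy as np
import pytest

from phidyn.errors import InvalidInputError, ValidationError
from phidyn.esn import (
    CPPProbeSpec,
    ESNConfig,
    ProtocolSpec,
    StateRecord,
    Transition,
    build_esn,
    detect_cpp,
    invalid_condition_catalogue,
    load_esn,
    make_cpp_probe,
    make_training_sequence,
    run_esn,
    save_esn,
    train_readout,
    validate_condition_order,
)
from phidyn.esn import _condition_outputs, _forbidden_transition


class TestBuild:
    def test_spectral_radius_hit_exactly(self):
        model = build_esn(ESNConfig(seed=3))
        sr = np.abs(np.linalg.eigvals(model.W_res)).max()
        assert sr == pytest.approx(0.9, abs=1e-6)
        assert model.eig_magnitudes.max() == pytest.approx(0.9, abs=1e-6)

    def test_sparsity_within_binomial_tolerance(self):
        model = build_esn(ESNConfig(seed=3))
        frac_zero = np.mean(model.W_res == 0.0)
        # 5 sigma of Binomial(40000, 0.8)
        assert frac_zero == pytest.approx(0.8, abs=5 * np.sqrt(0.8 * 0.2 / 40000))
        frac_zero_in = np.mean(model.W_in == 0.0)
        assert frac_zero_in == pytest.approx(0.8, abs=5 * np.sqrt(0.8 * 0.2 / 1200))

    def test_alpha_range_and_shapes(self):
        cfg = ESNConfig(seed=5)
        model = build_esn(cfg)
        assert model.W_res.shape == (200, 200)
        assert model.W_in.shape == (200, 6)
        assert np.all((model.alpha >= 0.1) & (model.alpha <= 0.3))

    def test_seed_determinism(self):
        a = build_esn(ESNConfig(seed=11))
        b = build_esn(ESNConfig(seed=11))
        c = build_esn(ESNConfig(seed=12))
        np.testing.assert_array_equal(a.W_res, b.W_res)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        assert not np.array_equal(a.W_res, c.W_res)

    @pytest.mark.parametrize("field,value", [
        ("res_sparsity", 1.5), ("alpha_low", 0.0), ("alpha_high", 1.2),
        ("spectral_radius", -0.1),
    ])
    def test_config_validation(self, field, value):
        with pytest.raises(ValidationError):
            ESNConfig(**{field: value})


class TestRun:
    def test_zero_input_converges_to_recurrence_fixed_point(self, small_cfg):
        model = build_esn(small_cfg)
        record = run_esn(model, np.zeros((2000, 6)))
        x_end = record.X[-1, :-1]
        # self-consistency of x = f(W x + b) at the settled state
        f = 1 / (1 + np.exp(-(model.W_res @ x_end + model.b)))
        np.testing.assert_allclose(x_end, f, atol=1e-9)
        assert np.all((x_end > 0) & (x_end < 1))

    def test_constant_last_column(self, small_cfg):
        model = build_esn(small_cfg)
        record = run_esn(model, np.zeros((50, 6)))
        np.testing.assert_array_equal(record.X[:, -1], np.ones(50))

    def test_stream_consistency(self, small_cfg, rng):
        model = build_esn(small_cfg)
        u = rng.random((400, 6))
        full = run_esn(model, u)
        first = run_esn(model, u[:150])
        second = run_esn(model, u[150:], x0=first.X[-1, :-1])
        np.testing.assert_allclose(
            np.vstack([first.X, second.X]), full.X, atol=1e-12)

    def test_input_shape_checked(self, small_cfg):
        model = build_esn(small_cfg)
        with pytest.raises(InvalidInputError):
            run_esn(model, np.zeros((10, 4)))

    def test_untrained_record_has_no_outputs(self, small_cfg):
        model = build_esn(small_cfg)
        assert run_esn(model, np.zeros((10, 6))).Y is None


class TestTrainReadout:
    def test_state_column_is_exactly_representable(self, small_cfg, rng):
        model = build_esn(small_cfg)
        record = run_esn(model, rng.random((500, 6)))
        y = np.column_stack([record.X[:, 3]] * 5)
        trained = train_readout(model, record, y, washout=0)
        resid = record.X @ trained.W_out - y
        assert np.abs(resid).max() < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        # small well-conditioned instance solved both ways
        X = np.column_stack([rng.normal(0, 1, (50, 5)), np.ones(50)])
        Y = rng.normal(0, 1, (50, 3))
        W_oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        model = build_esn(ESNConfig(n_reservoir=5, seed=0))
        trained = train_readout(model, StateRecord(X=X), Y, washout=0)
        np.testing.assert_allclose(trained.W_out, W_oracle, atol=1e-8)

    def test_duplicated_row_leaves_solution_unchanged(self, rng):
        X = np.column_stack([rng.normal(0, 1, (60, 4)), np.ones(60)])
        Y = rng.normal(0, 1, (60, 2))
        model = build_esn(ESNConfig(n_reservoir=4, seed=0))
        base = train_readout(model, StateRecord(X=X), Y, washout=0).W_out
        X2 = np.vstack([X, X[7]])
        Y2 = np.vstack([Y, Y[7]])
        dup = train_readout(model, StateRecord(X=X2), Y2, washout=0).W_out
        W_oracle = np.linalg.solve(X2.T @ X2, X2.T @ Y2)
        np.testing.assert_allclose(dup, W_oracle, atol=1e-8)
        # appending a duplicate can only reweight, never worsen, the fit
        assert np.linalg.norm(X2 @ dup - Y2) <= np.linalg.norm(X2 @ base - Y2) + 1e-10

    def test_residual_beats_random_perturbations(self, rng):
        X = np.column_stack([rng.normal(0, 1, (100, 10)), np.ones(100)])
        Y = rng.normal(0, 1, (100, 5))
        model = build_esn(ESNConfig(n_reservoir=10, seed=0))
        W = train_readout(model, StateRecord(X=X), Y, washout=0).W_out
        best = np.linalg.norm(X @ W - Y)
        for _ in range(100):
            W_p = W + rng.normal(0, 0.01, W.shape)
            assert np.linalg.norm(X @ W_p - Y) >= best - 1e-12

    def test_washout_bounds_checked(self, small_cfg, rng):
        model = build_esn(small_cfg)
        record = run_esn(model, rng.random((100, 6)))
        with pytest.raises(InvalidInputError):
            train_readout(model, record, np.zeros((100, 5)), washout=100)


@pytest.fixture(scope="module")
def seq():
    return make_training_sequence(ProtocolSpec(), seed=0)


class TestTrainingSequence:
    def test_valid_single_invalid_multi(self, seq):
        for seg in seq.segments:
            active = np.unique(
                np.count_nonzero(seq.inputs[seg.start:seg.end], axis=1))
            if seg.valid:
                assert len(seg.channels) == 1
                assert active.tolist() == [1]
            else:
                assert len(seg.channels) >= 2
                assert active.min() >= 2

    def test_invalid_segment_starts_at_configured_step(self, seq):
        first_invalid = min(s.start for s in seq.segments if not s.valid)
        assert first_invalid >= 13000
        last_valid = max(s.end for s in seq.segments if s.valid)
        assert last_valid <= 13000

    def test_desired_all_zero_during_invalid_conditions(self, seq):
        for seg in seq.segments:
            if not seg.valid:
                window = seq.desired[seg.start:seg.end + 40]
                assert np.all(window == 0)

    def test_desired_shifted_twenty_steps(self, seq):
        seg = next(s for s in seq.segments if s.valid)
        pos, col = _condition_outputs(seg.channels[0])
        assert np.all(seq.desired[seg.start:seg.start + 20, pos] == 0)
        assert seq.desired[seg.start + 20, pos] == 1.0
        assert seq.desired[seg.start + 20, col] == 1.0

    def test_no_forbidden_transitions(self, seq):
        valid = [s.channels[0] for s in seq.segments if s.valid]
        validate_condition_order(valid)  # raises on violation
        for prev, nxt in zip(valid[:-1], valid[1:]):
            assert not _forbidden_transition(prev, nxt)

    def test_forbidden_order_rejected(self):
        with pytest.raises(ValidationError):
            validate_condition_order([0, 5])  # left-red -> right-blue

    def test_catalogue_covers_pairs_and_all_on(self):
        cat = invalid_condition_catalogue()
        assert len(cat) == 16
        assert tuple(range(6)) in cat
        assert all(len(set(c)) == len(c) for c in cat)

    def test_determinism(self):
        a = make_training_sequence(ProtocolSpec(), seed=4)
        b = make_training_sequence(ProtocolSpec(), seed=4)
        np.testing.assert_array_equal(a.inputs, b.inputs)
        assert a.segments == b.segments


class TestProbe:
    def test_single_channel_pulses_and_annotations(self):
        inputs, transitions = make_cpp_probe(CPPProbeSpec())
        active = np.count_nonzero(inputs, axis=1)
        assert active.max() == 1  # pulses never overlap
        assert len(transitions) == 16
        gaps = [t.gap for t in transitions]
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))
        # jumps alternate between left-red (0) and right-blue (5)
        assert {t.from_channel for t in transitions} == {0, 5}
        for t in transitions:
            assert inputs[t.step, t.to_channel] == 1.0
            assert inputs[t.step - 1].sum() == 0 or t.gap == 0

    def test_zero_pulses(self):
        inputs, transitions = make_cpp_probe(CPPProbeSpec(gaps=()))
        assert transitions == []
        assert np.all(inputs == 0)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValidationError):
            CPPProbeSpec(gaps=(50, -10))

    def test_increasing_gaps_rejected(self):
        with pytest.raises(ValidationError):
            CPPProbeSpec(gaps=(50, 100))


def _fake_record(rows: dict[int, list[float]], length: int = 400) -> StateRecord:
    Y = np.full((length, 5), 0.1)
    for step, vals in rows.items():
        Y[step] = vals
    return StateRecord(X=np.zeros((length, 3)), Y=Y)


class TestDetect:
    TRANSITIONS = [Transition(index=0, step=100, gap=50,
                              from_channel=0, to_channel=5)]

    def test_constructed_positive(self):
        # middle high, destination (right) still low, destination color high
        record = _fake_record({150: [0.1, 0.8, 0.3, 0.1, 0.7]})
        det = detect_cpp(record, self.TRANSITIONS)
        assert det.detected and det.first_step == 150
        assert det.transition_index == 0

    def test_all_low_not_detected(self):
        assert not detect_cpp(_fake_record({}), self.TRANSITIONS).detected

    def test_signature_outside_window_not_detected(self):
        record = _fake_record({350: [0.1, 0.8, 0.3, 0.1, 0.7]})
        det = detect_cpp(record, self.TRANSITIONS, window=200)
        assert not det.detected

    def test_color_requirement_flag(self):
        record = _fake_record({150: [0.1, 0.8, 0.3, 0.1, 0.2]})
        assert not detect_cpp(record, self.TRANSITIONS).detected
        assert detect_cpp(record, self.TRANSITIONS,
                          require_color=False).detected

    def test_destination_position_must_stay_low(self):
        record = _fake_record({150: [0.1, 0.8, 0.9, 0.1, 0.7]})
        assert not detect_cpp(record, self.TRANSITIONS).detected

    def test_untrained_record_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_cpp(StateRecord(X=np.zeros((10, 3))), self.TRANSITIONS)


class TestTrainedNetwork:
    def test_echo_state_washout_forgets_initial_state(self, trained_default,
                                                      default_probe, rng):
        inputs, _ = default_probe
        a = run_esn(trained_default, inputs)
        b = run_esn(trained_default, inputs,
                    x0=rng.random(trained_default.n_reservoir))
        diff = np.abs(a.X[200:] - b.X[200:]).max()
        assert diff < 1e-6

    def test_held_out_valid_conditions_classified(self, trained_default):
        # qualitative training-quality contract: on unseen valid conditions
        # the correct position/color outputs are high and the others low for
        # most of the (shifted) condition duration
        held = make_training_sequence(
            ProtocolSpec(k_total=4000, invalid_start=4000), seed=99)
        record = run_esn(trained_default, held.inputs)
        ok = total = 0
        for seg in held.segments:
            lo, hi = seg.start + 20, min(seg.end + 20, len(held.inputs))
            pos, col = _condition_outputs(seg.channels[0])
            others = [i for i in range(5) if i not in (pos, col)]
            Y = record.Y[lo:hi]
            good = (Y[:, pos] > 0.5) & (Y[:, col] > 0.5) \
                & np.all(Y[:, others] < 0.5, axis=1)
            ok += good.sum()
            total += hi - lo
        assert ok / total >= 0.8

    def test_save_load_round_trip(self, tmp_path, small_cfg, rng):
        model = build_esn(small_cfg)
        record = run_esn(model, rng.random((300, 6)))
        trained = train_readout(model, record, rng.random((300, 5)), washout=50)
        save_esn(trained, tmp_path / "model")
        back = load_esn(tmp_path / "model")
        np.testing.assert_array_equal(back.W_res, trained.W_res)
        np.testing.assert_array_equal(back.W_out, trained.W_out)
        assert back.config == trained.config
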