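"""Training loops: convergence, determinism, hybrid/multi-session/adapt."""

import numpy as np
import pytest

from neuroclr.data import MultiSessionDataset, make_session
from neuroclr.encoders import EncoderSpec
from neuroclr.objective import SimilarityConfig
from neuroclr.sampling import ConfigError, SamplingConfig
from neuroclr.solver import (FitConfig, adapt, evaluate_loss, fit,
                             fit_hybrid, fit_multisession, transform)
from neuroclr.synthetic import SyntheticDatasetSpec, generate_dataset


@pytest.fixture(scope="module")
def toy_benchmark():
    """A small synthetic session (1,200 x 30, Poisson) with ground truth."""
    spec = SyntheticDatasetSpec(n_samples=1200, n_neurons=30, seed=5)
    return generate_dataset(spec)


def _configs(n_neurons=30, steps=100, batch=128, seed=0, out=2):
    enc = EncoderSpec(1, num_input=n_neurons, num_hidden=16, output_dim=out,
                      normalize=False)
    samp = SamplingConfig(mode="delta", delta=0.1)
    sim = SimilarityConfig(kind="negative_mse")
    fitc = FitConfig(max_iterations=steps, batch_size=batch,
                     learning_rate=1e-3, seed=seed)
    return enc, samp, sim, fitc


class TestFit:
    def test_loss_drops_below_log_n(self, toy_benchmark):
        """100 steps on the benchmark bring the loss under the log n level
        of an uninformative embedding."""
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs()
        model = fit(session, enc, samp, sim, fitc)
        assert model.loss_history[-1] < np.log(fitc.batch_size)
        assert model.gof_history[-1] < 0

    def test_bit_identical_given_seed(self, toy_benchmark):
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=30)
        a = fit(session, enc, samp, sim, fitc)
        b = fit(session, enc, samp, sim, fitc)
        assert a.loss_history == b.loss_history
        for (wa, _), (wb, _) in zip(a.encoder.layers, b.encoder.layers):
            np.testing.assert_array_equal(wa.data, wb.data)

    def test_full_batch_covers_every_window(self, rng):
        session = make_session(rng.standard_normal((300, 5)),
                               continuous_context=np.arange(300.0))
        enc, samp, sim, fitc = _configs(n_neurons=5, steps=3, batch="full")
        model = fit(session, enc, samp, sim, fitc)
        # loss recorded with n = all valid windows
        from neuroclr.objective import goodness_of_fit
        assert model.gof_history[-1] == pytest.approx(
            goodness_of_fit(model.loss_history[-1], 300))

    def test_inconsistent_configs_rejected_before_training(self, rng):
        session = make_session(rng.standard_normal((100, 4)))
        enc = EncoderSpec(1, num_input=4, normalize=True)
        samp = SamplingConfig(mode="time", time_offsets=(1,))
        sim = SimilarityConfig(kind="negative_mse")
        with pytest.raises(Exception):
            fit(session, enc, samp, sim, FitConfig(max_iterations=1))


class TestHybrid:
    def test_degenerate_split_equals_plain_fit(self, toy_benchmark):
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=25)
        plain = fit(session, enc, samp, sim, fitc)
        fitc_h = FitConfig(max_iterations=25, batch_size=128,
                           learning_rate=1e-3, seed=0, hybrid_split=(2, 0))
        hybrid = fit_hybrid(session, enc, samp, sim, fitc_h)
        assert plain.loss_history == hybrid.loss_history

    def test_split_must_sum_to_output_dim(self, toy_benchmark):
        session, _ = toy_benchmark
        enc, samp, sim, _ = _configs()
        with pytest.raises(ConfigError):
            fit_hybrid(session, enc, samp, sim,
                       FitConfig(max_iterations=1, hybrid_split=(3, 2)))

    def test_both_blocks_receive_gradient(self, toy_benchmark):
        """With a (3, 2) split on E=5 both coordinate blocks train."""
        session, _ = toy_benchmark
        enc = EncoderSpec(1, num_input=30, num_hidden=16, output_dim=5,
                          normalize=False)
        samp = SamplingConfig(mode="delta", delta=0.1, time_offsets=(1,))
        sim = SimilarityConfig(kind="negative_mse")
        fitc = FitConfig(max_iterations=12, batch_size=64,
                         learning_rate=1e-3, seed=1, hybrid_split=(3, 2))
        start = None
        model = fit_hybrid(session, enc, samp, sim, fitc)
        w_final = model.encoder.layers[-1][0].data  # (5, hidden//2)
        from neuroclr.encoders import build_encoder
        w_init = build_encoder(enc, np.random.default_rng(1)).layers[-1][0]
        moved = np.abs(w_final - w_init.data).sum(axis=1)
        assert (moved[:3] > 0).all() and (moved[3:] > 0).all()


class TestMultiSession:
    def test_single_session_reduces_to_fit(self, toy_benchmark):
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=20)
        a = fit(session, enc, samp, sim, fitc)
        b = fit_multisession(MultiSessionDataset([session]), enc, samp, sim,
                             fitc)
        assert a.loss_history == b.loss_history

    def test_one_encoder_per_session_into_shared_space(self, rng):
        c = np.cumsum(rng.standard_normal(400))
        s1 = make_session(rng.standard_normal((400, 6)),
                          continuous_context=c, session_id="a")
        s2 = make_session(rng.standard_normal((300, 9)),
                          continuous_context=np.cumsum(
                              rng.standard_normal(300)), session_id="b")
        ds = MultiSessionDataset([s1, s2])
        enc, samp, sim, fitc = _configs(n_neurons=6, steps=15, batch=64)
        model = fit_multisession(ds, enc, samp, sim, fitc)
        assert len(model.encoders) == 2
        assert model.encoders[0].spec.num_input == 6
        assert model.encoders[1].spec.num_input == 9
        e1, _ = transform(model, s1, session_index=0)
        e2, _ = transform(model, s2, session_index=1)
        assert e1.shape[1] == e2.shape[1] == 2

    def test_context_dim_mismatch_rejected(self, rng):
        s1 = make_session(rng.standard_normal((100, 3)),
                          continuous_context=rng.standard_normal((100, 1)))
        s2 = make_session(rng.standard_normal((100, 3)),
                          continuous_context=rng.standard_normal((100, 2)))
        with pytest.raises(Exception):
            ds = MultiSessionDataset([s1, s2])
            enc, samp, sim, fitc = _configs(n_neurons=3, steps=1)
            fit_multisession(ds, enc, samp, sim, fitc)


class TestAdapt:
    def test_one_step_decreases_new_session_loss(self, toy_benchmark, rng):
        """One adaptation step improves on the fresh input layer."""
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=150)
        model = fit(session, enc, samp, sim, fitc)
        new = make_session(rng.standard_normal((800, 12)) +
                           session.signal[:800, :12],
                           continuous_context=session.continuous_context[:800])
        fitc_a = FitConfig(max_iterations=1, batch_size=256,
                           learning_rate=1e-3, seed=3)
        before = adapt(model, new, fitc_a, adapt_steps=0)
        loss_before = evaluate_loss(before, new, 256, seed=11).total
        after = adapt(model, new, fitc_a, adapt_steps=1)
        loss_after = evaluate_loss(after, new, 256, seed=11).total
        assert loss_after < loss_before

    def test_zero_steps_same_dim_is_noop(self, toy_benchmark):
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=30)
        model = fit(session, enc, samp, sim, fitc)
        adapted = adapt(model, session, fitc, adapt_steps=0)
        e1, _ = transform(model, session)
        e2, _ = transform(adapted, session)
        np.testing.assert_array_equal(e1, e2)

    def test_trunk_layers_frozen(self, toy_benchmark, rng):
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=30)
        model = fit(session, enc, samp, sim, fitc)
        new = make_session(rng.standard_normal((500, 7)),
                           continuous_context=session.continuous_context[:500])
        adapted = adapt(model, new, fitc, adapt_steps=5)
        for i in range(1, len(model.encoder.layers)):
            np.testing.assert_array_equal(model.encoder.layers[i][0].data,
                                          adapted.encoder.layers[i][0].data)
        assert adapted.encoder.layers[0][0].data.shape == (16, 7)


class TestTransform:
    def test_row_count_and_determinism(self, toy_benchmark):
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=20)
        model = fit(session, enc, samp, sim, fitc)
        e1, idx = transform(model, session)
        e2, _ = transform(model, session)
        assert e1.shape[0] == session.n_samples  # RF 1
        np.testing.assert_array_equal(e1, e2)

    def test_label_free(self, toy_benchmark):
        """Removing contexts from the session leaves the output unchanged."""
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=20)
        model = fit(session, enc, samp, sim, fitc)
        bare = make_session(session.signal)
        e1, _ = transform(model, session)
        e2, _ = transform(model, bare)
        np.testing.assert_array_equal(e1, e2)

    def test_dimension_mismatch_suggests_adapt(self, toy_benchmark, rng):
        session, _ = toy_benchmark
        enc, samp, sim, fitc = _configs(steps=5)
        model = fit(session, enc, samp, sim, fitc)
        other = make_session(rng.standard_normal((50, 11)))
        with pytest.raises(ValueError, match="adapt"):
            transform(model, other)
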