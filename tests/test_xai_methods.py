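"""Attribution methods: axioms, structural limits and naive-loop oracles."""

import itertools
import math

import numpy as np
import pytest

from xairob import chem_data as cd
from xairob import transformer_models as tm
from xairob import xai_methods as xm
from xairob.autograd import Tensor, concatenate
from xairob.transformer_models import AttentionTrace, GradientTrace


def random_trace(rng, layers=2, heads=3, S=5, E=4):
    raw = rng.random((layers, heads, S, S))
    alpha = raw / raw.sum(axis=-1, keepdims=True)
    return (
        AttentionTrace(
            alpha=alpha, h_out=rng.normal(size=(layers, S, E)),
            logits=rng.normal(size=2),
        ),
        GradientTrace(
            d_alpha=rng.normal(size=(layers, heads, S, S)),
            d_hout=rng.normal(size=(layers, S, E)),
            class_index=1,
        ),
    )


class TestReductionAndNormalization:
    def test_reduce_embedding_is_row_mean(self, rng):
        mat = rng.normal(size=(6, 4))
        np.testing.assert_allclose(xm.reduce_embedding(mat), mat.mean(axis=1))
        np.testing.assert_allclose(
            xm.reduce_embedding(np.full((3, 2), 7.0)), [7.0, 7.0, 7.0]
        )
        np.testing.assert_allclose(
            xm.reduce_embedding(np.array([[1.0], [2.0]])), [1.0, 2.0]
        )

    def test_reduce_embedding_rejects_empty_axis(self):
        with pytest.raises(ValueError):
            xm.reduce_embedding(np.empty((3, 0)))

    def test_normalize_anchor_case(self):
        att = xm.Attribution(method="IG", values=np.array([2.0, -1.0, 1.0]))
        out = xm.normalize_attribution(att)
        np.testing.assert_allclose(out.values, [0.5, -0.25, 0.25])
        assert np.abs(out.values).sum() == pytest.approx(1.0)

    def test_normalize_zero_vector_flagged(self):
        out = xm.normalize_attribution(
            xm.Attribution(method="Grads", values=np.zeros(4))
        )
        assert out.zero_flag and not out.values.any()

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            xm.Attribution(method="IG", values=np.array([1.0, np.nan]))


class TestAttentionFamily:
    def test_uniform_attention_gives_uniform_map(self, rng):
        S = 6
        trace, _ = random_trace(rng, S=S)
        trace.alpha[:] = 1.0 / S
        att = xm.attention_map_attribution(trace)
        np.testing.assert_allclose(att.values, 1.0 / S)

    def test_attention_map_values_bounded(self, rng):
        trace, _ = random_trace(rng)
        att = xm.attention_map_attribution(trace)
        assert ((att.values >= 0) & (att.values <= 1)).all()

    def test_hand_computed_3x3_mean(self):
        alpha = np.array([[[0.2, 0.3, 0.5], [0.1, 0.6, 0.3], [0.3, 0.3, 0.4]]])
        trace = AttentionTrace(
            alpha=alpha[None], h_out=np.zeros((1, 3, 2)), logits=np.zeros(2)
        )
        att = xm.attention_map_attribution(trace)
        np.testing.assert_allclose(att.values, [0.2, 0.4, 0.4])

    def test_rollout_equals_attention_map_for_single_layer(self, rng):
        trace, _ = random_trace(rng, layers=1)
        np.testing.assert_allclose(
            xm.rollout_attribution(trace, literal=True).values,
            xm.attention_map_attribution(trace).values,
        )

    def test_rollout_product_stays_stochastic(self, rng):
        # the (alpha+I)/2 convention keeps every depth's product row-stochastic
        trace, _ = random_trace(rng, layers=4, S=6)
        S = 6
        joint = np.eye(S)
        for layer in range(4):
            a = 0.5 * (trace.alpha[layer].mean(axis=0) + np.eye(S))
            a /= a.sum(axis=-1, keepdims=True)
            joint = a @ joint
            np.testing.assert_allclose(joint.sum(axis=-1), 1.0, atol=1e-12)
        att = xm.rollout_attribution(trace)
        assert att.values.sum() == pytest.approx(1.0)

    def test_identity_attention_rollout(self):
        alpha = np.eye(2)[None, None].repeat(2, axis=0)
        trace = AttentionTrace(
            alpha=alpha, h_out=np.zeros((2, 2, 2)), logits=np.zeros(2)
        )
        np.testing.assert_allclose(
            xm.rollout_attribution(trace).values, [0.5, 0.5]
        )


class TestGradientFamilyOracles:
    """Vectorized implementations against naive index-by-index loops."""

    def test_attgrad_matches_loop_oracle(self, rng):
        trace, grads = random_trace(rng)
        L, _, S, _ = trace.alpha.shape
        expected = np.zeros(S)
        for j in range(S):
            acc = 0.0
            for i in range(S):
                for layer in range(L):
                    a = trace.alpha[layer, :, i, j].mean()
                    g = grads.d_alpha[layer, :, i, j].mean()
                    acc += g * a
            expected[j] = acc / S
        np.testing.assert_allclose(
            xm.attgrad_attribution(trace, grads).values, expected
        )

    def test_cat_matches_loop_oracle(self, rng):
        trace, grads = random_trace(rng)
        L, S, E = trace.h_out.shape
        expected = np.zeros(S)
        for i in range(S):
            acc = 0.0
            for j in range(E):
                for layer in range(L):
                    acc += grads.d_hout[layer, i, j] * trace.h_out[layer, i, j]
            expected[i] = acc / E
        np.testing.assert_allclose(xm.cat_attribution(trace, grads).values, expected)

    def test_attcat_matches_loop_oracle(self, rng):
        trace, grads = random_trace(rng)
        L, S, E = trace.h_out.shape
        expected = np.zeros(S)
        for i in range(S):
            acc = 0.0
            for layer in range(L):
                a_i = trace.alpha[layer].mean(axis=0)[:, i].mean()
                for j in range(E):
                    acc += a_i * grads.d_hout[layer, i, j] * trace.h_out[layer, i, j]
            expected[i] = acc / E
        np.testing.assert_allclose(
            xm.attcat_attribution(trace, grads).values, expected
        )

    def test_zero_gradients_give_zero_attributions(self, rng):
        trace, grads = random_trace(rng)
        grads.d_alpha[:] = 0.0
        grads.d_hout[:] = 0.0
        for fn in (
            xm.grad_attribution,
            xm.attgrad_attribution,
            xm.cat_attribution,
            xm.attcat_attribution,
        ):
            assert not fn(trace, grads).values.any()

    def test_layer_mismatch_rejected(self, rng):
        trace, _ = random_trace(rng, layers=2)
        _, grads = random_trace(rng, layers=3)
        with pytest.raises(ValueError):
            xm.attgrad_attribution(trace, grads)


@pytest.fixture(scope="module")
def uniform_setup():
    cfg = tm.ModelConfig(
        max_len=40, embed_dim=32, heads=4, layers=1, ff_mult=2,
        force_uniform_attention=True,
    )
    model = tm.build_model(cfg, seed=0)
    seq = cd.tokenize("CCOc1ccccc1")  # unpadded: attention exactly 1/S
    _, trace = tm.forward_with_trace(model, seq)
    grads = tm.class_gradients(model, seq, 1)
    return seq, trace, grads


class TestUniformAttentionLimits:
    def test_attention_is_exactly_uniform(self, uniform_setup):
        seq, trace, _ = uniform_setup
        np.testing.assert_allclose(trace.alpha, 1.0 / seq.length)

    def test_attgrads_equals_grads_over_S(self, uniform_setup):
        seq, trace, grads = uniform_setup
        np.testing.assert_allclose(
            xm.attgrad_attribution(trace, grads).values,
            xm.grad_attribution(trace, grads).values / seq.length,
        )

    def test_attcat_equals_cat_over_S(self, uniform_setup):
        seq, trace, grads = uniform_setup
        np.testing.assert_allclose(
            xm.attcat_attribution(trace, grads).values,
            xm.cat_attribution(trace, grads).values / seq.length,
        )


class _LinearStub:
    """f_1(x) = sum(w * inputs), f_0 = 0, on a fixed embedding table."""

    class _Encoder:
        def __init__(self, table, pad_id):
            self.table = table
            self.pad_id = pad_id

        def embed(self, ids):
            return Tensor(self.table[np.atleast_2d(ids)])

    def __init__(self, w, vocab_size=68, pad_id=2, seed=0):
        rng = np.random.default_rng(seed)
        self.w = w
        self.encoder = self._Encoder(
            rng.normal(size=(vocab_size, w.shape[1])), pad_id
        )

    def forward_tensors(self, ids=None, inputs=None, key_mask=None, **_):
        if inputs is None:
            inputs = self.encoder.embed(ids)
        B = inputs.shape[0]
        z = (inputs * Tensor(self.w)).sum(axis=2).sum(axis=1).reshape(B, 1)
        logits = concatenate([z * 0.0, z], axis=1)
        return logits, [], [], key_mask

    def logits(self, ids):
        out, _, _, _ = self.forward_tensors(ids=np.atleast_2d(ids))
        return out.data


class TestIntegratedGradients:
    def test_linear_model_closed_form_any_steps(self, rng):
        w = rng.normal(size=(9, 4))
        stub = _LinearStub(w)
        seq = cd.tokenize("CCOCC", pad_to=9)
        ids = np.asarray(seq.ids)
        x = stub.encoder.embed(ids).data[0]
        x_bar = stub.encoder.embed(np.full_like(ids, seq.vocab.pad_id)).data[0]
        expected = (w * (x - x_bar)).mean(axis=1)
        for steps in (1, 4, 64):
            att = xm.integrated_gradients(stub, seq, class_index=1, steps=steps)
            np.testing.assert_allclose(att.values, expected, atol=1e-10)
            assert att.extra["completeness_gap"] < 1e-9

    def test_completeness_on_toy_transformer(self, tiny_model, short_seq):
        att = xm.integrated_gradients(tiny_model, short_seq, 1, steps=256)
        assert att.extra["completeness_gap_relative"] < 0.01

    def test_step_counts_agree(self, tiny_model, short_seq):
        coarse = xm.integrated_gradients(tiny_model, short_seq, 1, steps=64).values
        dense = xm.integrated_gradients(tiny_model, short_seq, 1, steps=1024).values
        scale = np.abs(dense).max()
        assert np.abs(coarse - dense).max() <= 0.05 * scale

    def test_mismatched_baseline_rejected(self, tiny_model, short_seq):
        with pytest.raises(ValueError):
            xm.integrated_gradients(
                tiny_model, short_seq, 1, baseline_ids=np.zeros(3, dtype=np.intp)
            )


def shapley_by_permutations(n, value):
    """Independent oracle: average marginal contribution over all n! orders."""
    phi = np.zeros(n)
    for order in itertools.permutations(range(n)):
        seen = []
        prev = value(tuple(seen))
        for player in order:
            seen_sorted = tuple(sorted(seen + [player]))
            now = value(seen_sorted)
            phi[player] += now - prev
            prev = now
            seen.append(player)
    return phi / math.factorial(n)


class TestShapley:
    def test_textbook_two_player_game(self):
        v = {(): 0.0, (0,): 1.0, (1,): 2.0, (0, 1): 4.0}
        phi = xm._shapley_exact(2, lambda c: v[tuple(sorted(c))])
        np.testing.assert_allclose(phi, [1.5, 2.5])

    def test_exact_matches_permutation_oracle_on_games(self, rng):
        for n in (3, 4, 5):
            table = {
                tuple(sorted(c)): rng.normal()
                for size in range(n + 1)
                for c in itertools.combinations(range(n), size)
            }
            value = lambda c: table[tuple(sorted(c))]
            np.testing.assert_allclose(
                xm._shapley_exact(n, value),
                shapley_by_permutations(n, value),
                atol=1e-12,
            )

    def test_symmetry_and_null_player(self):
        # players 0 and 1 are interchangeable; player 2 never contributes
        def value(coalition):
            members = set(coalition) & {0, 1}
            return float(len(members)) + (3.0 if len(members) == 2 else 0.0)

        phi = xm._shapley_exact(3, value)
        assert phi[0] == pytest.approx(phi[1])
        assert phi[2] == pytest.approx(0.0)

    def test_exact_mode_on_model_satisfies_efficiency(self, tiny_model):
        seq = cd.tokenize("CCOCC", pad_to=10)
        att = xm.shap_attribution(tiny_model, seq, 1, mode="exact")
        assert att.extra["efficiency_gap"] < 1e-10
        ids = np.asarray(seq.ids)
        pad = seq.vocab.pad_id
        empty = ids.copy()
        empty[seq.smiles_positions()] = pad
        expected = tiny_model.logits(ids)[0, 1] - tiny_model.logits(empty)[0, 1]
        assert att.values.sum() == pytest.approx(expected, abs=1e-10)

    def test_exact_mode_matches_model_level_permutation_oracle(self, tiny_model):
        seq = cd.tokenize("CCO", pad_to=8)
        att = xm.shap_attribution(tiny_model, seq, 1, mode="exact")
        positions = seq.smiles_positions()
        ids = np.asarray(seq.ids)
        pad = seq.vocab.pad_id

        def value(coalition):
            masked = ids.copy()
            absent = [positions[p] for p in range(len(positions)) if p not in coalition]
            masked[absent] = pad
            return float(tiny_model.logits(masked)[0, 1])

        oracle = shapley_by_permutations(len(positions), value)
        np.testing.assert_allclose(att.values[positions], oracle, atol=1e-10)

    def test_sampled_mode_seeded_and_near_exact(self, tiny_model):
        seq = cd.tokenize("CCOCC", pad_to=10)
        exact = xm.shap_attribution(tiny_model, seq, 1, mode="exact")
        sampled = xm.shap_attribution(
            tiny_model, seq, 1, mode="sampled", budget=200, seed=3
        )
        again = xm.shap_attribution(
            tiny_model, seq, 1, mode="sampled", budget=200, seed=3
        )
        np.testing.assert_array_equal(sampled.values, again.values)
        scale = np.abs(exact.values).max()
        assert np.abs(sampled.values - exact.values).max() < 0.2 * scale

    def test_exact_mode_rejects_long_inputs(self, tiny_model):
        seq = cd.tokenize("CCOCCNCCOCCNCC")
        with pytest.raises(ValueError, match="sampled"):
            xm.shap_attribution(tiny_model, seq, 1, mode="exact")


class TestDispatch:
    def test_all_methods_run_on_randomized_model(self, tiny_config):
        model = tm.randomize_model(tiny_config, seed=9)
        seq = cd.tokenize("CCOC", pad_to=10)
        for method in xm.METHODS:
            att = xm.compute_attribution(
                method, model, seq, ig_steps=16, shap_mode="exact"
            )
            assert att.values.shape == (seq.length,)
            assert np.isfinite(att.values).all()

    def test_zero_head_model_gives_zero_gradient_attributions(self, tiny_config):
        model = tm.build_model(tiny_config, seed=2)
        model.head.l2.W.data[:] = 0.0
        model.head.l2.b.data[:] = 0.0
        seq = cd.tokenize("CCOC", pad_to=10)
        for method in ("Grads", "AttGrads", "CAT", "AttCAT"):
            att = xm.compute_attribution(method, model, seq, class_index=1)
            assert not att.values.any()

    def test_unknown_method_rejected(self, tiny_model, short_seq):
        with pytest.raises(ValueError):
            xm.compute_attribution("LIME", tiny_model, short_seq)
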