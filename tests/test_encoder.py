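"""Tiny encoder construction, surgery conservation laws, and gradients."""

import numpy as np
import pytest

from layerprune.encoder import (
    EncoderConfig,
    TinyEncoder,
    build_tiny_encoder,
    clone_model,
    count_parameters,
    iter_params,
    layer_param_count,
    load_external_encoder,
    remove_layers,
    tiny_param_count_closed_form,
)
from layerprune.errors import (
    InvalidArgumentError,
    InvalidDataError,
    ResourceError,
)

CFG = EncoderConfig(n_layers=4, d_model=16, n_heads=2, d_ff=24, max_len=20)


def fixed_batch(model, n=8, L=12, seed=0):
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
    return model.tokenize(seqs)


class TestConstruction:
    def test_layer_enumeration(self):
        m = build_tiny_encoder(CFG, seed=0)
        assert m.n_layers == 4
        assert m.layers == [0, 1, 2, 3]
        assert m.original_indices == [0, 1, 2, 3]

    def test_seed_determinism(self):
        a = build_tiny_encoder(CFG, seed=9)
        b = build_tiny_encoder(CFG, seed=9)
        c = build_tiny_encoder(CFG, seed=10)
        assert a.checksum() == b.checksum() != c.checksum()

    def test_indivisible_heads_rejected(self):
        with pytest.raises(InvalidArgumentError):
            EncoderConfig(d_model=30, n_heads=4)

    def test_zero_layers_rejected(self):
        with pytest.raises(InvalidArgumentError):
            EncoderConfig(n_layers=0)

    def test_head_must_end_in_two_logits(self):
        with pytest.raises(InvalidArgumentError):
            EncoderConfig(head_dims=(8,))

    def test_too_long_sequence_rejected(self):
        m = build_tiny_encoder(CFG, seed=0)
        with pytest.raises(InvalidDataError):
            m.tokenize(["A" * 25])


class TestClone:
    def test_clone_outputs_identical(self):
        m = build_tiny_encoder(CFG, seed=1)
        c = clone_model(m)
        tokens = fixed_batch(m)
        np.testing.assert_array_equal(
            m.forward_logits(tokens), c.forward_logits(tokens)
        )

    def test_clone_is_independent(self):
        m = build_tiny_encoder(CFG, seed=1)
        c = clone_model(m)
        c.params["layers"][0]["Wq"][:] = 0.0
        assert m.checksum() != c.checksum()
        c2 = remove_layers(c, [1])
        assert c.n_layers == 4 and c2.n_layers == 3

    def test_clone_of_clone(self):
        m = build_tiny_encoder(CFG, seed=1)
        cc = clone_model(clone_model(m))
        tokens = fixed_batch(m)
        np.testing.assert_array_equal(
            m.forward_logits(tokens), cc.forward_logits(tokens)
        )


class TestSurgery:
    def test_remove_empty_set_is_identity(self):
        m = build_tiny_encoder(CFG, seed=2)
        out = remove_layers(m, [])
        tokens = fixed_batch(m)
        np.testing.assert_array_equal(
            m.forward_logits(tokens), out.forward_logits(tokens)
        )

    def test_published_removal_pattern(self):
        """Removing 7 of 12 layers leaves 5, original order preserved."""
        cfg = EncoderConfig(n_layers=12, d_model=8, n_heads=2, d_ff=8, max_len=16)
        m = build_tiny_encoder(cfg, seed=0)
        out = remove_layers(m, {0, 1, 2, 3, 4, 9, 10})
        assert out.n_layers == 5
        assert out.original_indices == [5, 6, 7, 8, 11]
        assert out.metadata["removed_history"] == [[0, 1, 2, 3, 4, 9, 10]]

    def test_parameter_conservation_single(self):
        m = build_tiny_encoder(CFG, seed=3)
        for i in range(m.n_layers):
            out = remove_layers(m, [i])
            assert count_parameters(out) == count_parameters(m) - layer_param_count(m, i)

    def test_parameter_conservation_all_pairs(self):
        m = build_tiny_encoder(CFG, seed=3)
        total = count_parameters(m)
        for i in range(m.n_layers):
            for j in range(i + 1, m.n_layers):
                out = remove_layers(m, [i, j])
                expect = total - layer_param_count(m, i) - layer_param_count(m, j)
                assert count_parameters(out) == expect

    def test_closed_form_count(self):
        m = build_tiny_encoder(CFG, seed=4)
        assert count_parameters(m) == tiny_param_count_closed_form(CFG)

    def test_count_independent_of_weights(self):
        a = build_tiny_encoder(CFG, seed=0)
        b = build_tiny_encoder(CFG, seed=99)
        assert count_parameters(a) == count_parameters(b)

    def test_out_of_range_and_duplicates_rejected(self):
        m = build_tiny_encoder(CFG, seed=0)
        with pytest.raises(InvalidArgumentError):
            remove_layers(m, [4])
        with pytest.raises(InvalidArgumentError):
            remove_layers(m, [1, 1])
        with pytest.raises(InvalidArgumentError):
            remove_layers(m, [0, 1, 2, 3])

    def test_composability(self):
        """remove(remove(m,{a}),{b'}) equals remove(m,{a,b}) on outputs."""
        m = build_tiny_encoder(CFG, seed=5)
        once = remove_layers(m, [1, 3])
        # after removing layer 1, original layer 3 sits at position 2
        twice = remove_layers(remove_layers(m, [1]), [2])
        assert once.original_indices == twice.original_indices == [0, 2]
        tokens = fixed_batch(m)
        np.testing.assert_array_equal(
            once.forward_logits(tokens), twice.forward_logits(tokens)
        )

    def test_original_model_untouched(self):
        m = build_tiny_encoder(CFG, seed=6)
        before = m.checksum()
        remove_layers(m, [0, 2])
        assert m.checksum() == before

    def test_order_preservation_via_hooks(self):
        """Hidden states visit surviving layers in original relative order."""
        m = build_tiny_encoder(CFG, seed=7)
        out = remove_layers(m, [1])
        visited = []
        out.forward_logits(
            fixed_batch(out), layer_hook=lambda i, h: visited.append(i)
        )
        assert visited == [0, 2, 3]


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences everywhere."""
        cfg = EncoderConfig(
            n_layers=2, d_model=8, n_heads=2, d_ff=12, max_len=12, head_dims=(4, 2)
        )
        m = build_tiny_encoder(cfg, seed=3)
        rng = np.random.default_rng(0)
        tokens = m.tokenize(["".join(rng.choice(list("ACGT"), 8)) for _ in range(4)])
        labels = np.array([0, 1, 1, 0])
        _, grads = m.loss_and_grads(tokens, labels)
        gd = dict(iter_params(grads))
        eps = 1e-6
        for path, arr in iter_params(m.params):
            flat = arr.reshape(-1)
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _ = m.loss_and_grads(tokens, labels)
                flat[i] = old - eps
                lm, _ = m.loss_and_grads(tokens, labels)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = gd[path].reshape(-1)[i]
                assert ana == pytest.approx(num, abs=5e-8), path

    def test_mean_pooling_gradients(self):
        cfg = EncoderConfig(
            n_layers=1, d_model=8, n_heads=2, d_ff=8, max_len=10, pooling="mean"
        )
        m = build_tiny_encoder(cfg, seed=1)
        tokens = m.tokenize(["ACGTAC", "TTGGCA"])
        labels = np.array([1, 0])
        _, grads = m.loss_and_grads(tokens, labels)
        gd = dict(iter_params(grads))
        arr = m.params["tok_emb"]
        eps = 1e-6
        i = 10
        old = arr.reshape(-1)[i]
        arr.reshape(-1)[i] = old + eps
        lp, _ = m.loss_and_grads(tokens, labels)
        arr.reshape(-1)[i] = old - eps
        lm, _ = m.loss_and_grads(tokens, labels)
        arr.reshape(-1)[i] = old
        assert gd["tok_emb"].reshape(-1)[i] == pytest.approx(
            (lp - lm) / (2 * eps), abs=5e-8
        )


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        m = build_tiny_encoder(CFG, seed=8)
        m2 = remove_layers(m, [2])
        path = m2.save(tmp_path / "model.npz")
        back = TinyEncoder.load(path)
        assert back.checksum() == m2.checksum()
        assert back.original_indices == [0, 1, 3]
        tokens = fixed_batch(m2)
        np.testing.assert_array_equal(
            m2.forward_logits(tokens), back.forward_logits(tokens)
        )

    def test_describe_report(self):
        m = build_tiny_encoder(CFG, seed=0)
        d = remove_layers(m, [0]).describe()
        assert d["n_layers"] == 3
        assert d["removed_history"] == [[0]]
        assert d["parameter_count"] == count_parameters(m) - layer_param_count(m, 0)


class TestExternalAdapter:
    def test_missing_backend_is_resource_error(self):
        with pytest.raises(ResourceError):
            load_external_encoder("any/checkpoint")

    def test_empty_ref_rejected(self):
        with pytest.raises(InvalidArgumentError):
            load_external_encoder("")
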