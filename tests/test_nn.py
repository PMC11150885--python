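"""Neural-network engine: exact length geometry, architecture census, forward
determinism, gradient correctness and checkpointing."""

import numpy as np
import pytest

from chromacast.errors import ConfigError, DataError
from chromacast.nn import (
    ModelConfig,
    build_model,
    compute_conv_geometry,
    load_checkpoint,
    predict_rates,
    save_checkpoint,
    stitch_chunks,
)
from chromacast.genome import GenomeSequence, chunk_genome
from chromacast.training import poisson_loss_grad

# Architecture variants: census expectations as (family, batch_norm, dropout_p,
# expected counts {conv, tconv, lstm, bilstm, batch_norm, dropout}).
VARIANTS = [
    ("unet", False, 0.0, dict(conv=3, tconv=3, lstm=0, bilstm=0, batch_norm=0, dropout=0)),
    ("hybrid", False, 0.0, dict(conv=3, tconv=3, lstm=2, bilstm=0, batch_norm=0, dropout=0)),
    ("bihybrid", False, 0.0, dict(conv=3, tconv=3, lstm=0, bilstm=2, batch_norm=0, dropout=0)),
    ("bihybrid", True, 0.0, dict(conv=3, tconv=3, lstm=0, bilstm=2, batch_norm=6, dropout=0)),
    ("bihybrid", True, 0.3, dict(conv=3, tconv=3, lstm=0, bilstm=2, batch_norm=6, dropout=1)),
    ("bihybrid", True, 0.5, dict(conv=3, tconv=3, lstm=0, bilstm=2, batch_norm=6, dropout=1)),
]


def small_cfg(family="bihybrid", batch_norm=True, dropout_p=0.0, subseq_len=1024,
              **kw):
    defaults = dict(n_conv=3, filters=[2, 2, 2], kernel=5, step=2, n_lstm=2,
                    lstm_units=2, n_outputs=2)
    defaults.update(kw)
    return ModelConfig(family=family, batch_norm=batch_norm, dropout_p=dropout_p,
                       subseq_len=subseq_len, **defaults)


class TestConvGeometry:
    def test_three_levels_of_default_length(self):
        L = 21_384
        for _ in range(3):
            L = compute_conv_geometry(L, kernel=9, step=2)["out_len"]
        assert L == 2_673

    def test_step_one_is_same_padding(self):
        geo = compute_conv_geometry(100, kernel=9, step=1)
        assert geo["out_len"] == 100
        assert geo["pad_left"] + geo["pad_right"] == 8

    def test_indivisible_length_rejected(self):
        with pytest.raises(ConfigError, match="divisible"):
            compute_conv_geometry(10, kernel=3, step=3)

    def test_kernel_smaller_than_step_rejected(self):
        with pytest.raises(ConfigError, match="kernel"):
            compute_conv_geometry(12, kernel=2, step=3)


class TestArchitecture:
    @pytest.mark.parametrize("family,bn,p,expected", VARIANTS)
    def test_layer_census(self, family, bn, p, expected):
        model = build_model(small_cfg(family, bn, p), seed=0)
        assert model.layer_census() == expected

    def test_dropout_probability_recorded(self):
        model = build_model(small_cfg(dropout_p=0.3), seed=0)
        drops = [l for l in model.rec_stack if type(l).__name__ == "Dropout"]
        assert len(drops) == 1 and drops[0].p == 0.3

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError, match="family"):
            build_model(small_cfg("resnet"), seed=0)

    def test_indivisible_subseq_len_rejected(self):
        # 1020 = 4·255 is divisible by step² but not by step³ = 8
        with pytest.raises(ConfigError, match="divisible"):
            build_model(small_cfg(subseq_len=1020), seed=0)

    @pytest.mark.parametrize("family,bn,p,expected", VARIANTS)
    @pytest.mark.parametrize("subseq_len", [1024, 21_384])
    def test_shape_contract(self, family, bn, p, expected, subseq_len):
        """Forward output length equals input length for every variant."""
        model = build_model(small_cfg(family, bn, p, subseq_len=subseq_len), seed=0)
        x = np.random.default_rng(0).random((1, subseq_len, 4))
        out = model.forward(x)
        assert out.shape == (1, subseq_len, 2)
        assert np.all(np.isfinite(out))


class TestForward:
    def test_all_zero_padded_input_is_finite(self):
        model = build_model(small_cfg(), seed=0)
        out = model.forward(np.zeros((1, 1024, 4)))
        assert np.all(np.isfinite(out))

    def test_duplicated_rows_identical_in_eval(self):
        model = build_model(small_cfg(dropout_p=0.3), seed=0)
        x = np.random.default_rng(1).random((1, 1024, 4))
        out = model.forward(np.concatenate([x, x]))
        assert np.array_equal(out[0], out[1])

    def test_repeat_is_bit_stable(self):
        model = build_model(small_cfg(), seed=1)
        x = np.random.default_rng(2).random((2, 1024, 4))
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_rates_strictly_positive(self):
        model = build_model(small_cfg(), seed=3)
        x = np.random.default_rng(3).random((2, 1024, 4))
        rates = np.exp(model.forward(x))
        assert np.all(rates > 0) and np.all(np.isfinite(rates))

    def test_wrong_channel_count_rejected(self):
        model = build_model(small_cfg(), seed=0)
        with pytest.raises(DataError, match=r"\(B, L, 4\)"):
            model.forward(np.zeros((1, 1024, 5)))

    def test_wrong_length_rejected(self):
        model = build_model(small_cfg(), seed=0)
        with pytest.raises(DataError, match="subseq_len"):
            model.forward(np.zeros((1, 512, 4)))


class TestGradients:
    """Finite-difference checks of the hand-written backward passes."""

    @pytest.mark.parametrize("family,bn", [
        ("unet", True), ("hybrid", False), ("bihybrid", True),
    ])
    def test_full_model_gradcheck(self, family, bn):
        rng = np.random.default_rng(11)
        cfg = ModelConfig(family=family, n_conv=2, filters=[3, 4], kernel=5, step=2,
                          n_lstm=2, lstm_units=3, batch_norm=bn, dropout_p=0.0,
                          n_outputs=2, subseq_len=16)
        model = build_model(cfg, seed=5)
        # move every parameter off its initialisation: zero-initialised biases
        # put whole channels exactly on the ReLU kink (upstream ReLUs emit
        # exact zeros), where central differences are biased while the
        # analytic subgradient convention relu'(0) = 0 is fine
        for _, arr, _, _ in model.named_params():
            arr += rng.normal(0, 0.05, size=arr.shape)
        x = rng.random((2, 16, 4))
        y = rng.poisson(1.0, (2, 16, 2)).astype(float)
        mask = rng.random((2, 16, 2)) > 0.2

        out = model.forward(x, train=True)
        _, g = poisson_loss_grad(out, y, mask)
        model.backward(g)
        analytic = {name: grads[key].copy()
                    for name, _, grads, key in model.named_params()}

        def loss():
            out = model.forward(x, train=True)
            val, _ = poisson_loss_grad(out, y, mask, need_grad=False)
            return val

        eps = 1e-6
        for name, arr, _, _ in model.named_params():
            flat = arr.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                ana = analytic[name].ravel()[i]
                assert numeric == pytest.approx(ana, rel=1e-4, abs=1e-9), name


class TestPredictRates:
    def _paired(self, seq, L):
        return chunk_genome(seq, L, "+"), chunk_genome(seq, L, "-")

    def test_strand_average_recomputed_by_hand(self, rng):
        seq = GenomeSequence("s", 40, "".join(rng.choice(list("ACGT"), 40)))
        plus, minus = self._paired(seq, 16)
        cfg = small_cfg(subseq_len=16, kernel=5, n_outputs=1)
        model = build_model(cfg, seed=7)
        rp, rm, avg = predict_rates(model, plus, minus)
        assert np.allclose(avg, 0.5 * (rp + rm))
        # minus-strand rates are the reversed raw model output
        raw_m = np.exp(model.forward(np.stack([c.matrix for c in minus])))
        assert np.allclose(rm, raw_m[:, ::-1, :])

    def test_identical_strand_predictions_average_to_either(self):
        seq = GenomeSequence("s", 16, "ACGT" * 4)
        plus, minus = self._paired(seq, 16)
        model = build_model(small_cfg(subseq_len=16, kernel=5, n_outputs=1), seed=0)
        # palindromic-by-construction: feed the same matrices for both strands
        minus_same = [
            type(m)(m.seq_id, m.start, m.end, "-", p.matrix, p.pad_mask, m.is_gap)
            for p, m in zip(plus, minus)
        ]
        rp, rm, avg = predict_rates(model, plus, minus_same)
        assert np.allclose(avg, 0.5 * (rp + rm))

    def test_unpaired_strands_rejected(self):
        seq = GenomeSequence("s", 32, "ACGT" * 8)
        plus, minus = self._paired(seq, 16)
        model = build_model(small_cfg(subseq_len=16, kernel=5, n_outputs=1), seed=0)
        with pytest.raises(DataError, match="unpaired|differ"):
            predict_rates(model, plus, minus[:1])
        with pytest.raises(DataError, match="unpaired"):
            predict_rates(model, plus, plus)

    def test_stitching_drops_padding(self, rng):
        seq = GenomeSequence("s", 20, "".join(rng.choice(list("ACGT"), 20)))
        plus, minus = self._paired(seq, 16)
        model = build_model(small_cfg(subseq_len=16, kernel=5, n_outputs=1), seed=0)
        _, _, avg = predict_rates(model, plus, minus)
        track = stitch_chunks(avg, plus, 20)
        assert track.shape == (20, 1)
        assert np.allclose(track[16:, 0], avg[1, :4, 0])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_model(small_cfg(dropout_p=0.3), seed=9)
        x = np.random.default_rng(4).random((1, 1024, 4))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, extra={"epoch": 3})
        loaded, extra = load_checkpoint(path)
        assert extra == {"epoch": 3}
        assert np.array_equal(model.forward(x), loaded.forward(x))

    def test_non_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "x.npz"
        np.savez(path, a=np.zeros(3))
        with pytest.raises(DataError):
            load_checkpoint(path)
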