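"""Transformer stacks: embedding composition, attention-oracle equivalence,
causality, feature extraction, training contracts, sampling and the
property-conditioning shift protocol."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from cardioforge import features
from cardioforge.tokenizer import MaskingPlan, build_vocabulary, preprocess_corpus
from cardioforge.transformer import (
    Checkpoint,
    TransformerConfig,
    TransformerTrainSettings,
    extract_feature,
    sample,
    train_bidirectional,
    train_generator,
)


def _toy_model(vocab_size=12, block_len=6, n_blocks=1, n_heads=1, embed_dim=8,
               conditioned=False, seed=0):
    from cardioforge.transformer import SmilesTransformer

    cfg = TransformerConfig(vocab_size=vocab_size, block_len=block_len, n_blocks=n_blocks,
                            n_heads=n_heads, embed_dim=embed_dim, dropout=0.0,
                            conditioned=conditioned)
    model = SmilesTransformer(cfg, seed=seed)
    model.eval()
    return model


class TestEmbedding:
    def test_output_shape(self):
        model = _toy_model(embed_dim=8, block_len=6)
        x = model.embed_inputs(np.zeros((2, 6), dtype=int))
        assert x.shape == (2, 6, 8)

    def test_unconditioned_is_token_plus_position(self):
        model = _toy_model()
        ids = np.zeros((1, 6), dtype=int)
        x = model.embed_inputs(ids)
        expected = model.token_emb.weight.data[0] + model.pos_emb.weight.data[:6]
        assert np.allclose(x.data[0], expected)

    def test_conditioning_is_additive(self):
        """The conditioned embedding decomposes as token+position plus the
        scaffold-token embedding plus the projected property vector."""
        model = _toy_model(conditioned=True)
        ids = np.array([[1, 4, 5, 2, 0, 0]])
        scaffold = np.array([[1, 2, 0, 0, 0, 0]])
        props = np.zeros((1, 10))
        x = model.embed_inputs(ids, scaffold, props)
        base = model.token_emb.weight.data[ids[0]] + model.pos_emb.weight.data[:6]
        scaf = model.scaffold_emb.weight.data[scaffold[0]]
        normed = (props[0] - model.prop_mean) / model.prop_std
        proj = normed @ model.prop_proj.weight.data + model.prop_proj.bias.data
        assert np.allclose(x.data[0], base + scaf + proj[None, :])
        # with all-zero normalized properties the projection reduces to its bias
        assert np.allclose(proj, model.prop_proj.bias.data)

    def test_length_overflow_raises(self):
        model = _toy_model(block_len=6)
        with pytest.raises(ValueError):
            model.embed_inputs(np.zeros((1, 7), dtype=int))


def _reference_block(x, model, causal):
    """Independent single-block, single-head attention implementation."""
    blk = model.blocks[0]

    def layernorm(v, gamma, beta, eps=1e-5):
        mu = v.mean(-1, keepdims=True)
        var = ((v - mu) ** 2).mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + eps) * gamma + beta

    h = layernorm(x, blk.ln1.gamma.data, blk.ln1.beta.data)
    qkv = h @ blk.attn.qkv.weight.data + blk.attn.qkv.bias.data
    d = model.config.embed_dim
    q, k, v = qkv[:, :d], qkv[:, d:2 * d], qkv[:, 2 * d:]
    scores = q @ k.T / np.sqrt(d)
    if causal:
        scores = scores + np.triu(np.full(scores.shape, -1e9), k=1)
    scores -= scores.max(-1, keepdims=True)
    attn = np.exp(scores)
    attn /= attn.sum(-1, keepdims=True)
    x = x + (attn @ v) @ blk.attn.proj.weight.data + blk.attn.proj.bias.data
    h = layernorm(x, blk.ln2.gamma.data, blk.ln2.beta.data)
    h1 = h @ blk.fc1.weight.data + blk.fc1.bias.data
    from scipy.special import erf

    h1 = h1 * 0.5 * (1 + erf(h1 / np.sqrt(2)))
    x = x + h1 @ blk.fc2.weight.data + blk.fc2.bias.data
    penult = layernorm(x, model.ln_f.gamma.data, model.ln_f.beta.data)
    logits = penult @ model.head.weight.data + model.head.bias.data
    return logits, penult


class TestAttentionOracle:
    @pytest.mark.parametrize("causal", [True, False])
    def test_matches_hand_rolled_block(self, causal):
        model = _toy_model(vocab_size=9, block_len=4, n_blocks=1, n_heads=1, embed_dim=8, seed=3)
        ids = np.array([[1, 4, 5, 2]])
        x = model.embed_inputs(ids)
        logits, penult = model.forward_embedded(x, causal=causal)
        ref_logits, ref_penult = _reference_block(x.data[0], model, causal)
        assert np.abs(logits.data[0] - ref_logits).max() < 1e-5
        assert np.abs(penult.data[0] - ref_penult).max() < 1e-5

    def test_logits_shape(self):
        model = _toy_model(vocab_size=9, block_len=4)
        logits, penult = model.forward(np.array([[1, 4, 5, 2]]), causal=True)
        assert logits.shape == (1, 4, 9)
        assert penult.shape[-1] == model.config.embed_dim


class TestCausality:
    def test_decoder_ignores_future(self):
        model = _toy_model(vocab_size=10, block_len=8, n_blocks=2, n_heads=2, embed_dim=8)
        ids = np.array([[1, 4, 5, 6, 7, 4, 5, 2]])
        base, _ = model.forward(ids, causal=True)
        for t in range(7):
            perturbed = ids.copy()
            perturbed[0, t + 1:] = (perturbed[0, t + 1:] + 3) % 10
            out, _ = model.forward(perturbed, causal=True)
            assert np.allclose(out.data[0, :t + 1], base.data[0, :t + 1]), f"position {t}"

    def test_encoder_is_bidirectional(self):
        model = _toy_model(vocab_size=10, block_len=8)
        ids = np.array([[1, 4, 5, 6, 7, 4, 5, 2]])
        _, base = model.forward(ids, causal=False)
        perturbed = ids.copy()
        perturbed[0, -1] = 9
        _, out = model.forward(perturbed, causal=False)
        assert not np.allclose(out.data[0, 0], base.data[0, 0])


class TestFeatureExtraction:
    def test_vector_length_and_determinism(self, featurizer_ckpt):
        v1 = extract_feature(featurizer_ckpt, "CCO")
        v2 = extract_feature(featurizer_ckpt, "CCO")
        assert v1.shape == (featurizer_ckpt.model.config.embed_dim,)
        assert (v1 == v2).all()

    def test_distinct_molecules_distinct_vectors(self, featurizer_ckpt):
        a = extract_feature(featurizer_ckpt, "CCOc1ccccc1")
        b = extract_feature(featurizer_ckpt, "CN1CCNCC1")
        assert not np.allclose(a, b)

    def test_oov_token_is_error(self, featurizer_ckpt):
        with pytest.raises(KeyError, match="vocabulary"):
            extract_feature(featurizer_ckpt, "[Se]")


class TestCheckpoint:
    def test_round_trip_bit_identical(self, tmp_path, featurizer_ckpt):
        path = tmp_path / "feat.npz"
        featurizer_ckpt.save(path)
        loaded = Checkpoint.load(path)
        before = extract_feature(featurizer_ckpt, "CCO")
        after = extract_feature(loaded, "CCO")
        assert (before == after).all()


class TestTraining:
    def test_generator_loss_decreases(self, generator_ckpt):
        history = generator_ckpt.meta["fixture_loss_history"]
        assert history[-1] < history[0]

    def test_bidirectional_loss_decreases(self, featurizer_ckpt):
        history = featurizer_ckpt.meta["loss_history"]
        assert history[-1] < history[0]

    def test_deterministic_loss_curve(self):
        corpus = ["CCO", "CCN", "CCC", "CCOC", "c1ccccc1", "c1ccncc1"] * 5
        vocab = build_vocabulary(corpus)
        seqs = preprocess_corpus(corpus, vocab, max_content_len=10)
        cfg = TransformerConfig(vocab_size=len(vocab), block_len=12, n_blocks=1,
                                n_heads=2, embed_dim=16, conditioned=False)
        st = TransformerTrainSettings(epochs=3, batch_size=8, lr=1e-3, seed=11)
        _, h1 = train_bidirectional(seqs, vocab, cfg, st)
        _, h2 = train_bidirectional(seqs, vocab, cfg, st)
        assert h1 == h2

    def test_memorization_of_single_molecule(self):
        corpus = ["CCOc1ccccc1"] * 40
        vocab = build_vocabulary(corpus)
        cfg = TransformerConfig(vocab_size=len(vocab), block_len=16, n_blocks=1,
                                n_heads=2, embed_dim=32, dropout=0.0, conditioned=True)
        st = TransformerTrainSettings(epochs=60, batch_size=16, lr=3e-3, seed=0)
        ckpt, history = train_generator(corpus, vocab, cfg, st, max_content_len=14)
        assert history[-1] < 0.05  # near-zero per-token loss on the memorized molecule

    def test_masking_degenerate_guard(self, toy_vocab, toy_sequences):
        cfg = TransformerConfig(vocab_size=len(toy_vocab), block_len=62, n_blocks=1,
                                n_heads=2, embed_dim=16, conditioned=False)
        with pytest.raises(ValueError, match="select_prob"):
            train_bidirectional(toy_sequences[:8], toy_vocab, cfg,
                                TransformerTrainSettings(epochs=1, batch_size=4),
                                plan=MaskingPlan(select_prob=0.0))

    def test_empty_corpus_is_error(self, toy_vocab):
        cfg = TransformerConfig(vocab_size=len(toy_vocab), block_len=62, conditioned=False)
        with pytest.raises(ValueError, match="empty"):
            train_bidirectional([], toy_vocab, cfg)


class TestSampling:
    def test_argmax_limit_is_deterministic(self):
        corpus = ["CCOc1ccccc1"] * 40
        vocab = build_vocabulary(corpus)
        cfg = TransformerConfig(vocab_size=len(vocab), block_len=16, n_blocks=1,
                                n_heads=2, embed_dim=32, dropout=0.0, conditioned=True)
        ckpt, _ = train_generator(corpus, vocab, cfg,
                                  TransformerTrainSettings(epochs=60, batch_size=16,
                                                           lr=3e-3, seed=0),
                                  max_content_len=14)
        props = features.physchem_properties("CCOc1ccccc1")
        out = sample(ckpt, features.murcko_scaffold("CCOc1ccccc1"), props, 5,
                     np.random.default_rng(0), temperature=0.0)
        assert set(out) == {features.canonicalize("CCOc1ccccc1")}

    def test_all_outputs_parse(self, generator_ckpt, corpus_properties):
        med = np.median(corpus_properties, axis=0)
        out = sample(generator_ckpt, "c1ccccc1", med, 50, np.random.default_rng(1))
        for smi in out:
            assert features.canonicalize(smi) == smi


def _sample_until(ckpt, scaffold, props, want, rng, cap=600):
    got = []
    drawn = 0
    while len(got) < want and drawn < cap:
        got.extend(sample(ckpt, scaffold, props, 100, rng))
        drawn += 100
    return got[:want]


class TestConditioningShift:
    def test_each_property_shifts_generated_distribution(self, generator_ckpt,
                                                         corpus_properties):
        """Fixing one property low vs high (10th/90th corpus percentile,
        others at the median) must shift the generated property distribution
        in the conditioned direction (one-sided rank test, alpha=0.01)."""
        med = np.median(corpus_properties, axis=0)
        rng = np.random.default_rng(42)
        failures = []
        for j, name in enumerate(features.PROPERTY_NAMES):
            lo = np.quantile(corpus_properties[:, j], 0.1)
            hi = np.quantile(corpus_properties[:, j], 0.9)
            if lo == hi:
                lo = corpus_properties[:, j].min()
                hi = corpus_properties[:, j].max()
            p_lo, p_hi = med.copy(), med.copy()
            p_lo[j], p_hi[j] = lo, hi
            gen_lo = _sample_until(generator_ckpt, "c1ccccc1", p_lo, 30, rng)
            gen_hi = _sample_until(generator_ckpt, "c1ccccc1", p_hi, 30, rng)
            v_lo = [features.physchem_properties(s).as_array()[j] for s in gen_lo]
            v_hi = [features.physchem_properties(s).as_array()[j] for s in gen_hi]
            assert len(v_lo) >= 10 and len(v_hi) >= 10, f"too few valid samples for {name}"
            _, p_value = mannwhitneyu(v_hi, v_lo, alternative="greater")
            if p_value >= 0.01:
                failures.append((name, p_value))
        assert not failures, f"conditioning not directionally significant for: {failures}"
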