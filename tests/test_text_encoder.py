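"""Label-aware attention operations against independent loop-level oracles."""

import numpy as np
import pytest

from icufusion.text_encoder import (attend_np, attention_weights_np,
                                    compatibility_np, conv_features_np,
                                    encode_text, init_text_params,
                                    word_label_similarity_np)

RNG = np.random.default_rng(10)


# -- compatibility (cosine grid) -------------------------------------------

def test_identical_word_and_label_vector_give_cosine_one():
    v = np.array([[1.0, 2.0, -1.0]])
    G = compatibility_np(v, v)
    assert abs(G[0, 0] - 1.0) < 1e-9


def test_orthogonal_vectors_give_zero():
    w = np.array([[1.0, 0.0]])
    l = np.array([[0.0, 3.0], [0.0, -2.0]])
    G = compatibility_np(w, l)
    np.testing.assert_allclose(G, 0.0, atol=1e-12)


def test_zero_norm_vector_has_similarity_zero():
    w = np.zeros((1, 3))
    l = np.array([[1.0, 0.0, 0.0]])
    assert compatibility_np(w, l)[0, 0] == 0.0


def test_compatibility_matches_cosine_oracle():
    w = RNG.normal(size=(5, 3))
    l = RNG.normal(size=(2, 3))
    G = compatibility_np(w, l)
    for i in range(5):
        for k in range(2):
            ref = w[i] @ l[k] / (np.linalg.norm(w[i]) * np.linalg.norm(l[k]))
            assert abs(G[i, k] - ref) < 1e-6


def test_pad_rows_are_zeroed():
    w = RNG.normal(size=(6, 3))
    G = compatibility_np(w, RNG.normal(size=(2, 3)), content_length=4)
    np.testing.assert_array_equal(G[4:], 0.0)


# -- windowed word-label similarity ----------------------------------------

def test_negative_grid_with_zero_bias_relus_to_zero():
    G = -np.abs(RNG.normal(size=(6, 2)))
    W = np.zeros((2, 3, 2))
    W[:, 1, :] = np.eye(2)  # identity center tap
    u = word_label_similarity_np(G, 3, W, np.zeros(2))
    np.testing.assert_array_equal(u, 0.0)


def test_identity_window_one_is_passthrough():
    G = np.array([[1.0, 2.0]])
    W = np.eye(2)[:, None, :]  # (O=2, window=1, O=2)
    u = word_label_similarity_np(G, 1, W, np.zeros(2))
    np.testing.assert_allclose(u, [[1.0, 2.0]])


def test_window_similarity_matches_sliding_loop_oracle():
    G = RNG.normal(size=(7, 2))
    W = RNG.normal(size=(2, 3, 2))
    b = RNG.normal(size=2)
    u = word_label_similarity_np(G, 3, W, b)
    Gp = np.vstack([np.zeros(2), G, np.zeros(2)])
    for i in range(7):
        for o in range(2):
            ref = max(0.0, (Gp[i: i + 3] * W[o]).sum() + b[o])
            assert abs(u[i, o] - ref) < 1e-6


def test_even_window_rejected():
    with pytest.raises(ValueError):
        word_label_similarity_np(np.zeros((3, 2)), 2, np.zeros((2, 2, 2)), np.zeros(2))


# -- attention --------------------------------------------------------------

def test_uniform_scores_give_uniform_attention():
    u = np.ones((4, 2))
    alpha, _ = attention_weights_np(u, 4)
    np.testing.assert_allclose(alpha, 0.25)


def test_softmax_of_zero_and_log_two():
    u = np.array([[0.0, 0.0], [np.log(2.0), 0.0]])
    alpha, _ = attention_weights_np(u, 2)
    np.testing.assert_allclose(alpha, [1 / 3, 2 / 3], atol=1e-12)


def test_attention_sums_to_one_and_is_shift_invariant():
    u = RNG.normal(size=(8, 2)) ** 2
    a1, _ = attention_weights_np(u, 8)
    a2, _ = attention_weights_np(u + 7.3, 8)
    assert abs(a1.sum() - 1.0) < 1e-9
    np.testing.assert_allclose(a1, a2, atol=1e-9)


def test_pads_get_zero_attention_and_no_denominator_mass():
    u = np.ones((6, 2))
    alpha, _ = attention_weights_np(u, 3)
    np.testing.assert_array_equal(alpha[3:], 0.0)
    np.testing.assert_allclose(alpha[:3], 1 / 3)


def test_per_label_pool_is_max_over_content():
    u = np.array([[0.1, 5.0], [2.0, 0.3], [9.0, 9.0]])
    _, mk = attention_weights_np(u, 2)  # third row is padding
    np.testing.assert_allclose(mk, [2.0, 5.0])


def test_empty_content_returns_all_zero_alpha():
    alpha, mk = attention_weights_np(np.ones((4, 2)), 0)
    np.testing.assert_array_equal(alpha, 0.0)
    np.testing.assert_array_equal(mk, 0.0)


# -- attend + conv -----------------------------------------------------------

def test_uniform_attention_rescales_vectors():
    wv = RNG.normal(size=(4, 3))
    q = attend_np(wv, np.full(4, 0.25))
    np.testing.assert_allclose(q, wv / 4)


def test_one_hot_attention_keeps_single_row():
    wv = RNG.normal(size=(5, 3))
    alpha = np.zeros(5)
    alpha[2] = 1.0
    q = attend_np(wv, alpha)
    np.testing.assert_allclose(q[2], wv[2])
    assert np.abs(np.delete(q, 2, axis=0)).max() == 0.0


def test_attend_matches_elementwise_product_oracle():
    wv = RNG.normal(size=(6, 4))
    alpha = RNG.random(6)
    np.testing.assert_allclose(attend_np(wv, alpha), alpha[:, None] * wv, atol=1e-12)


def test_zero_conv_weights_give_zero_feature():
    q = RNG.normal(size=(10, 3))
    c = conv_features_np(q, np.zeros((4, 5, 3)), np.zeros(4))
    np.testing.assert_array_equal(c, 0.0)


def test_matched_filter_peaks_at_planted_pattern():
    """A filter equal to a planted subsequence pools its autocorrelation peak."""
    P, s, L = 3, 5, 40
    pattern = RNG.normal(size=(s, P))
    q = RNG.normal(size=(L, P)) * 0.1
    q[17:22] = pattern
    c = conv_features_np(q, pattern[None, :, :], np.zeros(1))
    # oracle: max cross-correlation over all alignments is at the plant
    lpad = (s - 1) // 2
    qp = np.pad(q, ((lpad, s // 2), (0, 0)))
    corr = np.array([(qp[i: i + s] * pattern).sum() for i in range(L)])
    assert np.argmax(corr) == 19  # pattern center
    assert abs(c[0] - max(corr.max(), 0.0)) < 1e-9


def test_feature_dimension_is_filter_count():
    q = RNG.normal(size=(1000, 8))
    c = conv_features_np(q, RNG.normal(size=(100, 5, 8)), np.zeros(100))
    assert c.shape == (100,)


def test_short_content_uses_zero_padded_convolution():
    q = RNG.normal(size=(2, 3))  # shorter than the filter
    c = conv_features_np(np.vstack([q, np.zeros((8, 3))]),
                         RNG.normal(size=(4, 5, 3)), np.zeros(4),
                         content_length=2)
    assert np.isfinite(c).all()


# -- end-to-end padding invariance -------------------------------------------

def test_padding_length_never_changes_outputs():
    params = init_text_params(vocab_size=30, embed_dim=6, joint_dim=4,
                              n_filters=5, filter_size=3, sim_window=3,
                              rng=np.random.default_rng(0))
    content = RNG.integers(2, 30, size=12)
    for L in (20, 50):
        ids = np.zeros((1, L), dtype=np.int64)
        ids[0, :12] = content
        mask = np.arange(L) < 12
        c, alpha, mk = encode_text(ids, mask[None], params, attention=True)
        if L == 20:
            ref_c, ref_a, ref_m = c.data.copy(), alpha.data[0, :12].copy(), mk.data.copy()
        else:
            np.testing.assert_allclose(c.data, ref_c, atol=1e-12)
            np.testing.assert_allclose(alpha.data[0, :12], ref_a, atol=1e-12)
            np.testing.assert_allclose(mk.data, ref_m, atol=1e-12)
            np.testing.assert_array_equal(alpha.data[0, 12:], 0.0)
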