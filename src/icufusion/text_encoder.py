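"""Label-aware attention CNN over clinical-note token sequences.

Word embeddings and the two one-hot label embeddings (survival / death) are
projected into a shared joint space.  Word-label compatibility is the cosine
similarity G between projected words and projected labels; a small
ReLU-activated convolution over each word's neighborhood turns G into
word-label similarity scores u; the per-word max over labels is softmaxed
over content positions (pads excluded) into attention weights alpha; words
are rescaled by alpha and fed to a 1-D convolutional filter bank whose
global max-pool is the text feature c.  The per-label max-pooled scores m_k
double as the auxiliary logits of the joint-embedding loss regularizer.

All functions build autodiff graphs over batches; ``*_np`` wrappers give the
single-instance numpy views the oracle tests exercise.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv1d, take

N_LABELS = 2  # O: survival vs in-hospital death
_EPS = 1e-12


def init_text_params(
    vocab_size: int,
    embed_dim: int,
    joint_dim: int,
    n_filters: int,
    filter_size: int,
    sim_window: int,
    rng: np.random.Generator,
    attention: bool = True,
    pretrained_embeddings: np.ndarray | None = None,
) -> dict[str, Tensor]:
    def glorot(fan_in, fan_out, shape):
        lim = math.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    if pretrained_embeddings is not None:
        emb = np.asarray(pretrained_embeddings, dtype=np.float64)
        if emb.shape != (vocab_size, embed_dim):
            raise ValueError(
                f"pretrained embeddings shape {emb.shape} != ({vocab_size}, {embed_dim})")
        emb = emb.copy()
    else:
        emb = rng.normal(0.0, 0.1, size=(vocab_size, embed_dim))
    emb[0] = 0.0  # pad row stays zero at init
    params = {
        "emb": Tensor(emb, requires_grad=True),
        "Wv1": glorot(embed_dim, joint_dim, (embed_dim, joint_dim)),
        "conv_W": glorot(filter_size * joint_dim, n_filters,
                         (n_filters, filter_size, joint_dim)),
        "conv_b": Tensor(np.zeros(n_filters), requires_grad=True),
    }
    if attention:
        params["Wv2"] = glorot(N_LABELS, joint_dim, (N_LABELS, joint_dim))
        # identity-centered init: the center tap passes each label's own
        # compatibility through, so u starts as ReLU(G) and attention reflects
        # word-label similarity from the first step instead of a squashed mix
        sim_W = np.zeros((N_LABELS, sim_window, N_LABELS))
        sim_W[:, sim_window // 2, :] = np.eye(N_LABELS)
        sim_W += rng.normal(0.0, 0.01, size=sim_W.shape)
        params["sim_W"] = Tensor(sim_W, requires_grad=True)
        params["sim_b"] = Tensor(np.zeros(N_LABELS), requires_grad=True)
    return params


def project_words(ids: np.ndarray, params: dict[str, Tensor]) -> Tensor:
    """(B, L) token ids -> (B, L, P) joint-space word vectors."""
    return take(params["emb"], ids) @ params["Wv1"]


def label_vectors(params: dict[str, Tensor]) -> Tensor:
    """Joint-space projections of the one-hot label embeddings: (O, P)."""
    one_hot = Tensor(np.eye(N_LABELS))
    return one_hot @ params["Wv2"]


def _l2_normalize(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + _EPS).sqrt()
    return x / norm


def compatibility(word_vecs: Tensor, label_vecs: Tensor,
                  content_mask: np.ndarray) -> Tensor:
    """Cosine word-label compatibility G: (B, L, O); pad rows zeroed.

    A zero-norm vector has cosine similarity defined as 0 (the epsilon in the
    normalizer makes 0/eps = 0 exactly).
    """
    wn = _l2_normalize(word_vecs)
    ln = _l2_normalize(label_vecs)
    G = wn @ ln.transpose(1, 0)
    return G * content_mask[..., None].astype(np.float64)


def word_label_similarity(G: Tensor, params: dict[str, Tensor],
                          content_mask: np.ndarray) -> Tensor:
    """u = ReLU(conv(G) + b) over each word's neighborhood: (B, L, O), >= 0.

    The similarity window slides over positions with zero border padding;
    pad positions are zeroed afterwards so the bias cannot leak into them.
    """
    u = conv1d(G, params["sim_W"], params["sim_b"]).relu()
    return u * content_mask[..., None].astype(np.float64)


def attention_weights(u: Tensor, content_mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Per-word attention alpha and per-label pooled scores m_k.

    m_i = max over labels of u[i, :]; alpha = softmax of m over content
    positions only (pads get alpha = 0 and never enter the denominator);
    m_k = max over content positions of u[:, k].  A sample with no content
    gets all-zero alpha.
    """
    mask = content_mask.astype(np.float64)            # (B, L)
    m_word = u.max(axis=2)                            # (B, L)
    # constant shift for numerical stability (detached from the graph)
    shifted = np.where(content_mask, m_word.data, -np.inf)
    shift = shifted.max(axis=1, keepdims=True)
    has_content = content_mask.any(axis=1, keepdims=True)
    shift = np.where(has_content, shift, 0.0)
    e = (m_word - Tensor(shift)).exp() * mask
    denom = e.sum(axis=1, keepdims=True) + Tensor((~has_content).astype(np.float64))
    alpha = e / denom
    m_label = (u * mask[..., None]).max(axis=1)       # (B, O)
    return alpha, m_label


def attend(word_vecs: Tensor, alpha: Tensor) -> Tensor:
    """q_i = alpha_i * v_i: per-position rescaling, sequence shape kept."""
    B, L = alpha.shape
    return word_vecs * alpha.reshape(B, L, 1)


def conv_features(q: Tensor, params: dict[str, Tensor],
                  content_mask: np.ndarray) -> Tensor:
    """Filter-bank convolution + ReLU + global max-pool -> c: (B, n_filters).

    The pool runs over content positions only (pad activations are zeroed
    first), so c never depends on how much padding a sequence carries.
    """
    a = conv1d(q, params["conv_W"], params["conv_b"]).relu()
    a = a * content_mask[..., None].astype(np.float64)
    return a.max(axis=1)


def encode_text(
    ids: np.ndarray,
    content_mask: np.ndarray,
    params: dict[str, Tensor],
    attention: bool = True,
) -> tuple[Tensor, Tensor | None, Tensor | None]:
    """Full text branch: (c, alpha, m_label); alpha/m_label are None for the
    plain (label-agnostic) CNN used by the cn_only / multi_cn variants."""
    wv = project_words(ids, params)
    if not attention:
        return conv_features(wv, params, content_mask), None, None
    G = compatibility(wv, label_vectors(params), content_mask)
    u = word_label_similarity(G, params, content_mask)
    alpha, m_label = attention_weights(u, content_mask)
    c = conv_features(attend(wv, alpha), params, content_mask)
    return c, alpha, m_label


# ---------------------------------------------------------------------------
# single-instance numpy views (the operation contracts the oracle tests hit)
# ---------------------------------------------------------------------------

def compatibility_np(word_vectors: np.ndarray, label_vectors_: np.ndarray,
                     content_length: int | None = None) -> np.ndarray:
    """(L, P) x (O, P) -> cosine grid (L, O), rows >= content_length zeroed."""
    L = word_vectors.shape[0]
    n = L if content_length is None else content_length
    mask = np.arange(L) < n
    out = compatibility(Tensor(word_vectors[None]), Tensor(label_vectors_),
                        mask[None]).data[0]
    return out


def word_label_similarity_np(G: np.ndarray, window_w: int,
                             weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """u = ReLU of the width-``window_w`` windowed map of G: (L, O)."""
    if window_w % 2 != 1:
        raise ValueError("window_w must be odd")
    O = G.shape[1]
    params = {"sim_W": Tensor(np.asarray(weights, dtype=np.float64)),
              "sim_b": Tensor(np.asarray(bias, dtype=np.float64))}
    mask = np.ones(G.shape[0], dtype=bool)
    return word_label_similarity(Tensor(G[None]), params, mask[None]).data[0]


def attention_weights_np(u: np.ndarray, content_length: int) -> tuple[np.ndarray, np.ndarray]:
    """alpha (L,) and per-label pooled m_k (O,) for one sequence."""
    L = u.shape[0]
    mask = np.arange(L) < content_length
    alpha, m_label = attention_weights(Tensor(u[None]), mask[None])
    return alpha.data[0], m_label.data[0]


def attend_np(word_vectors: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    return attend(Tensor(word_vectors[None]), Tensor(alpha[None])).data[0]


def conv_features_np(q: np.ndarray, conv_W: np.ndarray, conv_b: np.ndarray,
                     content_length: int | None = None) -> np.ndarray:
    L = q.shape[0]
    n = L if content_length is None else content_length
    mask = np.arange(L) < n
    params = {"conv_W": Tensor(np.asarray(conv_W, dtype=np.float64)),
              "conv_b": Tensor(np.asarray(conv_b, dtype=np.float64))}
    return conv_features(Tensor(q[None]), params, mask[None]).data[0]
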