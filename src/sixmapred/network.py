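"""The 6mA-Pred network: embedding -> BiLSTM -> dot-product attention -> softmax head.

The model classifies a token stream (overlapping k-mers of a 41-bp window) as
6mA-positive or negative.  Tokens are embedded into dense vectors, a single
bidirectional LSTM layer processes the stream, and a Luong-style dot-product
attention pools the per-timestep outputs into one context vector which a fully
connected layer maps to two class probabilities.

The LSTM cell follows the standard gate equations

    i_t = sigmoid(W_ii x_t + b_ii + W_hi h_{t-1} + b_hi)
    f_t = sigmoid(W_if x_t + b_if + W_hf h_{t-1} + b_hf)
    g_t = tanh   (W_ig x_t + b_ig + W_hg h_{t-1} + b_hg)
    o_t = sigmoid(W_io x_t + b_io + W_ho h_{t-1} + b_ho)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

with h_0 = c_0 = 0 in both directions.  Attention uses the final concatenated
output as the query: score_t = <query, output_t>, weights = softmax(scores),
context = sum_t weight_t * output_t.

Everything is plain NumPy.  Gradients for training are derived by hand in
:func:`backward_batch` and verified against finite differences in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import expit

from .kmer import KmerVocabulary, TokenStream, build_vocabulary

CHECKPOINT_FORMAT = "6mapred-checkpoint-v1"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the published configuration: hidden_dim 100, dropout 0.3,
    k = 3 (vocabulary 64).  The embedding width is not pinned down anywhere,
    so it defaults to the hidden width.
    """

    k: int = 3
    embedding_dim: int = 100
    hidden_dim: int = 100
    dropout_rate: float = 0.3
    num_classes: int = 2
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.embedding_dim < 1 or self.hidden_dim < 1:
            raise ValueError("embedding_dim and hidden_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.num_classes != 2:
            raise ValueError("this model is a two-class classifier")

    @property
    def vocab_size(self) -> int:
        return 4**self.k

    @property
    def output_dim(self) -> int:
        """Width of one BiLSTM output row (both directions concatenated)."""
        return self.hidden_dim * (2 if self.bidirectional else 1)


@dataclass
class LSTMWeights:
    """One direction's gate weights, stacked in gate order (i, f, g, o).

    ``w_ih`` is (4H, E): rows [0:H) drive the input gate, [H:2H) the forget
    gate, [2H:3H) the candidate, [3H:4H) the output gate; likewise ``w_hh``
    (4H, H) for the recurrent path and the bias vectors.
    """

    w_ih: np.ndarray
    w_hh: np.ndarray
    b_ih: np.ndarray
    b_hh: np.ndarray


@dataclass
class ModelParameters:
    """All trainable tensors of one model instance."""

    embedding: np.ndarray  # (vocab_size, embedding_dim)
    fwd: LSTMWeights
    bwd: LSTMWeights | None
    w_out: np.ndarray  # (2, output_dim)
    b_out: np.ndarray  # (2,)

    def named_arrays(self) -> dict[str, np.ndarray]:
        out = {"embedding": self.embedding, "w_out": self.w_out, "b_out": self.b_out}
        for prefix, w in (("fwd", self.fwd), ("bwd", self.bwd)):
            if w is None:
                continue
            out[f"{prefix}.w_ih"] = w.w_ih
            out[f"{prefix}.w_hh"] = w.w_hh
            out[f"{prefix}.b_ih"] = w.b_ih
            out[f"{prefix}.b_hh"] = w.b_hh
        return out

    def copy(self) -> "ModelParameters":
        def cw(w: LSTMWeights | None) -> LSTMWeights | None:
            if w is None:
                return None
            return LSTMWeights(w.w_ih.copy(), w.w_hh.copy(), w.b_ih.copy(), w.b_hh.copy())

        return ModelParameters(
            embedding=self.embedding.copy(),
            fwd=cw(self.fwd),
            bwd=cw(self.bwd),
            w_out=self.w_out.copy(),
            b_out=self.b_out.copy(),
        )

    def check_finite(self) -> None:
        for name, arr in self.named_arrays().items():
            if not np.isfinite(arr).all():
                raise FloatingPointError(f"non-finite values in parameter {name}")


@dataclass(frozen=True)
class AttentionResult:
    """Per-timestep scores and softmax weights plus the pooled context."""

    scores: np.ndarray  # (T,)
    weights: np.ndarray  # (T,), nonnegative, sums to 1
    context: np.ndarray  # (output_dim,)


def init_parameters(config: ModelConfig, rng: np.random.Generator) -> ModelParameters:
    """Seeded random initialization.

    The embedding table is drawn uniformly from [-0.1, 0.1] (randomly
    initialized, no pretraining); LSTM and head weights uniformly from
    [-1/sqrt(hidden_dim), +1/sqrt(hidden_dim)].
    """
    H, E = config.hidden_dim, config.embedding_dim
    bound = 1.0 / np.sqrt(H)

    def u(*shape) -> np.ndarray:
        return rng.uniform(-bound, bound, size=shape)

    def direction() -> LSTMWeights:
        return LSTMWeights(w_ih=u(4 * H, E), w_hh=u(4 * H, H), b_ih=u(4 * H), b_hh=u(4 * H))

    return ModelParameters(
        embedding=rng.uniform(-0.1, 0.1, size=(config.vocab_size, E)),
        fwd=direction(),
        bwd=direction() if config.bidirectional else None,
        w_out=u(2, config.output_dim),
        b_out=u(2),
    )


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction)."""
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _step(x, h_prev, c_prev, w: LSTMWeights, H: int):
    """One LSTM step returning the gate internals needed for backprop."""
    z = x @ w.w_ih.T + h_prev @ w.w_hh.T + w.b_ih + w.b_hh
    i = expit(z[..., :H])
    f = expit(z[..., H : 2 * H])
    g = np.tanh(z[..., 2 * H : 3 * H])
    o = expit(z[..., 3 * H :])
    c = f * c_prev + i * g
    tanh_c = np.tanh(c)
    h = o * tanh_c
    return h, c, (x, h_prev, c_prev, i, f, g, o, tanh_c)


def lstm_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    weights: LSTMWeights,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the six gate equations once; returns (h_t, c_t).

    Accepts single vectors or leading batch dimensions.
    """
    H = weights.w_hh.shape[1]
    if x.shape[-1] != weights.w_ih.shape[1]:
        raise ValueError(
            f"input width {x.shape[-1]} != expected {weights.w_ih.shape[1]}"
        )
    if h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise ValueError(f"state width must be {H}")
    h, c, _ = _step(x, h_prev, c_prev, weights, H)
    return h, c


def _tokens_to_matrix(tokens) -> np.ndarray:
    if isinstance(tokens, TokenStream):
        ids = tokens.as_array()
    else:
        ids = np.asarray(tokens, dtype=np.int64)
    if ids.ndim == 1:
        ids = ids[None, :]
    return ids


def _run_direction(inputs: np.ndarray, w: LSTMWeights, H: int):
    """Unroll one direction over time-ordered inputs (B, T, E)."""
    B, T, _ = inputs.shape
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    caches = []
    for t in range(T):
        h, c, cache = _step(inputs[:, t], h, c, w, H)
        hs[:, t] = h
        caches.append(cache)
    return hs, caches


def forward_batch(
    tokens: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Batched forward pass; returns a cache dict holding ``probs`` (B, 2).

    In training mode, inverted dropout is applied to the embedded inputs and
    to the context vector, with masks drawn from ``rng``.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.ndim != 2 or tokens.shape[1] < 1:
        raise ValueError("tokens must be a (batch, T>=1) integer matrix")
    if tokens.min() < 0 or tokens.max() >= config.vocab_size:
        raise ValueError(
            f"token ids must lie in [0, {config.vocab_size}); got range "
            f"[{tokens.min()}, {tokens.max()}]"
        )
    if training and config.dropout_rate > 0 and rng is None:
        raise ValueError("training-mode forward with dropout needs an rng")

    H = config.hidden_dim
    p_drop = config.dropout_rate if training else 0.0

    xe = params.embedding[tokens]  # (B, T, E)
    if p_drop > 0:
        mask_e = (rng.random(xe.shape) >= p_drop) / (1.0 - p_drop)
        xe = xe * mask_e
    else:
        mask_e = None

    hs_f, cache_f = _run_direction(xe, params.fwd, H)
    if config.bidirectional:
        hs_b_proc, cache_b = _run_direction(xe[:, ::-1], params.bwd, H)
        hs_b = hs_b_proc[:, ::-1]
        outputs = np.concatenate([hs_f, hs_b], axis=2)  # (B, T, 2H)
    else:
        cache_b = None
        outputs = hs_f

    query = outputs[:, -1, :]  # (B, D)
    scores = np.einsum("btd,bd->bt", outputs, query)
    weights = softmax(scores, axis=1)
    context = np.einsum("bt,btd->bd", weights, outputs)

    if p_drop > 0:
        mask_c = (rng.random(context.shape) >= p_drop) / (1.0 - p_drop)
        context_d = context * mask_c
    else:
        mask_c = None
        context_d = context

    logits = context_d @ params.w_out.T + params.b_out
    probs = softmax(logits, axis=1)

    return {
        "tokens": tokens,
        "mask_e": mask_e,
        "mask_c": mask_c,
        "cache_f": cache_f,
        "cache_b": cache_b,
        "outputs": outputs,
        "query": query,
        "scores": scores,
        "weights": weights,
        "context": context,
        "context_d": context_d,
        "probs": probs,
    }


def _direction_backward(w: LSTMWeights, caches, d_hidden: np.ndarray):
    """Backpropagation through time for one direction.

    ``d_hidden`` is (B, T, H) in the direction's own processing order.
    Returns (grads dict, d_inputs (B, T, E) in processing order).
    """
    B, T, H = d_hidden.shape
    g_w_ih = np.zeros_like(w.w_ih)
    g_w_hh = np.zeros_like(w.w_hh)
    g_b = np.zeros_like(w.b_ih)
    d_inputs = np.empty((B, T, w.w_ih.shape[1]))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
        dh = d_hidden[:, t] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        g_w_ih += dz.T @ x
        g_w_hh += dz.T @ h_prev
        g_b += dz.sum(axis=0)
        d_inputs[:, t] = dz @ w.w_ih
        dh_next = dz @ w.w_hh
        dc_next = dc * f
    return {"w_ih": g_w_ih, "w_hh": g_w_hh, "b": g_b}, d_inputs


def backward_batch(
    cache: dict,
    labels: np.ndarray,
    params: ModelParameters,
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Gradients of the mean cross-entropy loss w.r.t. every parameter.

    Returns a dict keyed like :meth:`ModelParameters.named_arrays`.
    """
    labels = np.asarray(labels, dtype=np.int64)
    probs = cache["probs"]
    B, T, D = cache["outputs"].shape
    H = config.hidden_dim

    d_logits = probs.copy()
    d_logits[np.arange(B), labels] -= 1.0
    d_logits /= B

    grads: dict[str, np.ndarray] = {
        "w_out": d_logits.T @ cache["context_d"],
        "b_out": d_logits.sum(axis=0),
    }
    d_context = d_logits @ params.w_out
    if cache["mask_c"] is not None:
        d_context = d_context * cache["mask_c"]

    outputs = cache["outputs"]
    weights = cache["weights"]
    query = cache["query"]

    d_weights = np.einsum("bd,btd->bt", d_context, outputs)
    d_outputs = weights[:, :, None] * d_context[:, None, :]
    # softmax backward: ds = w * (dw - <dw, w>)
    d_scores = weights * (d_weights - np.sum(d_weights * weights, axis=1, keepdims=True))
    d_outputs += d_scores[:, :, None] * query[:, None, :]
    d_query = np.einsum("bt,btd->bd", d_scores, outputs)
    d_outputs[:, -1, :] += d_query

    if config.bidirectional:
        d_hf = d_outputs[:, :, :H]
        d_hb = d_outputs[:, :, H:]
        g_f, d_in_f = _direction_backward(params.fwd, cache["cache_f"], d_hf)
        g_b, d_in_b_proc = _direction_backward(
            params.bwd, cache["cache_b"], d_hb[:, ::-1]
        )
        d_xe = d_in_f + d_in_b_proc[:, ::-1]
        grads.update(
            {
                "fwd.w_ih": g_f["w_ih"],
                "fwd.w_hh": g_f["w_hh"],
                "fwd.b_ih": g_f["b"],
                "fwd.b_hh": g_f["b"].copy(),
                "bwd.w_ih": g_b["w_ih"],
                "bwd.w_hh": g_b["w_hh"],
                "bwd.b_ih": g_b["b"],
                "bwd.b_hh": g_b["b"].copy(),
            }
        )
    else:
        g_f, d_xe = _direction_backward(params.fwd, cache["cache_f"], d_outputs)
        grads.update(
            {
                "fwd.w_ih": g_f["w_ih"],
                "fwd.w_hh": g_f["w_hh"],
                "fwd.b_ih": g_f["b"],
                "fwd.b_hh": g_f["b"].copy(),
            }
        )

    if cache["mask_e"] is not None:
        d_xe = d_xe * cache["mask_e"]
    g_emb = np.zeros_like(params.embedding)
    np.add.at(g_emb, cache["tokens"].reshape(-1), d_xe.reshape(-1, d_xe.shape[-1]))
    grads["embedding"] = g_emb
    return grads


def bilstm_forward(tokens, params: ModelParameters, config: ModelConfig) -> np.ndarray:
    """Per-timestep outputs for one token stream: a (T, output_dim) matrix.

    Row t concatenates the forward hidden state h_t and the backward hidden
    state for position t (the backward pass runs over the reversed stream);
    both directions start from zero states.
    """
    ids = _tokens_to_matrix(tokens)
    if ids.shape[1] < 1:
        raise ValueError("empty token stream")
    xe = params.embedding[ids]
    hs_f, _ = _run_direction(xe, params.fwd, config.hidden_dim)
    if not config.bidirectional:
        return hs_f[0]
    hs_b_proc, _ = _run_direction(xe[:, ::-1], params.bwd, config.hidden_dim)
    return np.concatenate([hs_f, hs_b_proc[:, ::-1]], axis=2)[0]


def attend(outputs: np.ndarray) -> AttentionResult:
    """Dot-product attention pooling of a (T, D) output matrix.

    The query is the final output row; scores are inner products of the query
    with every row; weights are their softmax; the context is the
    weight-averaged output.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 2 or outputs.shape[0] < 1:
        raise ValueError("outputs must be a (T>=1, D) matrix")
    query = outputs[-1]
    scores = outputs @ query
    weights = softmax(scores)
    context = weights @ outputs
    return AttentionResult(scores=scores, weights=weights, context=context)


def forward(
    tokens,
    params: ModelParameters,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, AttentionResult]:
    """Full forward pass for one token stream.

    Returns the two-class probability vector (negative, positive) and the
    attention result.  Inference (``training=False``) is deterministic:
    dropout is disabled.
    """
    ids = _tokens_to_matrix(tokens)
    cache = forward_batch(ids, params, config, training=training, rng=rng)
    attention = AttentionResult(
        scores=cache["scores"][0],
        weights=cache["weights"][0],
        context=cache["context"][0],
    )
    return cache["probs"][0], attention


def save_checkpoint(
    path, config: ModelConfig, params: ModelParameters, vocab: KmerVocabulary
) -> None:
    """Single-file archive: config (JSON), all tensors, and the vocabulary."""
    meta = {"format": CHECKPOINT_FORMAT, "config": asdict(config), "vocab_k": vocab.k}
    arrays = {k.replace(".", "__"): v for k, v in params.named_arrays().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[ModelConfig, ModelParameters, KmerVocabulary]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(
                f"unrecognized checkpoint format {meta.get('format')!r} in {path}"
            )
        config = ModelConfig(**meta["config"])
        arr = {k.replace("__", "."): data[k] for k in data.files if k != "__meta__"}
    params = ModelParameters(
        embedding=arr["embedding"],
        fwd=LSTMWeights(
            arr["fwd.w_ih"], arr["fwd.w_hh"], arr["fwd.b_ih"], arr["fwd.b_hh"]
        ),
        bwd=(
            LSTMWeights(arr["bwd.w_ih"], arr["bwd.w_hh"], arr["bwd.b_ih"], arr["bwd.b_hh"])
            if config.bidirectional
            else None
        ),
        w_out=arr["w_out"],
        b_out=arr["b_out"],
    )
    return config, params, build_vocabulary(meta["vocab_k"])
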