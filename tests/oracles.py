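"""Independent straight-line oracles used to check the vectorized model.

Everything here is written with explicit Python loops and ``math`` scalar
functions, transcribing the gate equations, attention and softmax head
directly, with no shared code with the package's NumPy implementation.
"""

import math


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _matvec(m, v):
    return [sum(m[r][c] * v[c] for c in range(len(v))) for r in range(len(m))]


def oracle_lstm_step(x, h_prev, c_prev, w_ih, w_hh, b_ih, b_hh):
    """One cell update from the six equations; all arguments plain lists.

    Gate rows of the stacked matrices follow the package convention:
    [0:H) input gate, [H:2H) forget, [2H:3H) candidate, [3H:4H) output.
    """
    H = len(h_prev)
    zx = _matvec(w_ih, x)
    zh = _matvec(w_hh, h_prev)
    z = [zx[r] + zh[r] + b_ih[r] + b_hh[r] for r in range(4 * H)]
    i = [_sigmoid(z[r]) for r in range(0, H)]
    f = [_sigmoid(z[r]) for r in range(H, 2 * H)]
    g = [math.tanh(z[r]) for r in range(2 * H, 3 * H)]
    o = [_sigmoid(z[r]) for r in range(3 * H, 4 * H)]
    c = [f[j] * c_prev[j] + i[j] * g[j] for j in range(H)]
    h = [o[j] * math.tanh(c[j]) for j in range(H)]
    return h, c


def _run_direction(inputs, w_ih, w_hh, b_ih, b_hh, H):
    h = [0.0] * H
    c = [0.0] * H
    states = []
    for x in inputs:
        h, c = oracle_lstm_step(x, h, c, w_ih, w_hh, b_ih, b_hh)
        states.append(h)
    return states


def oracle_softmax(values):
    m = max(values)
    exps = [math.exp(v - m) for v in values]
    s = sum(exps)
    return [e / s for e in exps]


def oracle_forward(token_ids, params, config):
    """Full forward pass: embed -> BiLSTM -> dot attention -> FC -> softmax.

    ``params`` is a ModelParameters instance; all tensors are converted to
    plain lists up front so the computation below touches no NumPy.
    """
    emb = params.embedding.tolist()
    fw = [params.fwd.w_ih.tolist(), params.fwd.w_hh.tolist(),
          params.fwd.b_ih.tolist(), params.fwd.b_hh.tolist()]
    w_out = params.w_out.tolist()
    b_out = params.b_out.tolist()
    H = config.hidden_dim

    inputs = [emb[t] for t in token_ids]
    states_f = _run_direction(inputs, *fw, H)
    if config.bidirectional:
        bw = [params.bwd.w_ih.tolist(), params.bwd.w_hh.tolist(),
              params.bwd.b_ih.tolist(), params.bwd.b_hh.tolist()]
        states_b_rev = _run_direction(list(reversed(inputs)), *bw, H)
        states_b = list(reversed(states_b_rev))
        outputs = [states_f[t] + states_b[t] for t in range(len(inputs))]
    else:
        outputs = states_f

    query = outputs[-1]
    scores = [sum(o_j * q_j for o_j, q_j in zip(row, query)) for row in outputs]
    weights = oracle_softmax(scores)
    D = len(outputs[0])
    context = [sum(weights[t] * outputs[t][d] for t in range(len(outputs)))
               for d in range(D)]
    logits = [sum(w_out[r][d] * context[d] for d in range(D)) + b_out[r]
              for r in range(2)]
    probs = oracle_softmax(logits)
    return probs, weights, context


def oracle_pairwise_auc(labels, scores):
    """Brute-force all-pairs AUC with ties counted one half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
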