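"""Independent straight-line reference implementations used by the tests.

Everything here is deliberately written as plain loops directly from the
mathematical definitions, sharing no code with the package, so it can
serve as an oracle for the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

BN_EPS = 1e-5


def elu_scalar(v: float) -> float:
    return v if v > 0 else math.exp(v) - 1.0


def conv1d_same_loop(x, W, b, stride: int = 1):
    """Same-padded 1-D cross-correlation with plain loops.

    x: (B, Cin, L); W: (Cout, Cin, K) with odd K; output (B, Cout, ceil(L/stride)).
    """
    B, Cin, L = x.shape
    Cout, _, K = W.shape
    half = K // 2
    Lout = (L - 1) // stride + 1
    out = np.zeros((B, Cout, Lout))
    for bi in range(B):
        for o in range(Cout):
            for l in range(Lout):
                acc = b[o]
                center = l * stride
                for c in range(Cin):
                    for k in range(K):
                        pos = center + k - half
                        if 0 <= pos < L:
                            acc += x[bi, c, pos] * W[o, c, k]
                out[bi, o, l] = acc
    return out


def batchnorm_eval_loop(x, gamma, beta, mean, var):
    B, C, L = x.shape
    out = np.zeros_like(x)
    for bi in range(B):
        for c in range(C):
            for l in range(L):
                xn = (x[bi, c, l] - mean[c]) / math.sqrt(var[c] + BN_EPS)
                out[bi, c, l] = xn * gamma[c] + beta[c]
    return out


def elu_loop(x):
    out = np.zeros_like(x)
    for idx in np.ndindex(*x.shape):
        out[idx] = elu_scalar(x[idx])
    return out


def avgpool_loop(x, p: int):
    B, C, L = x.shape
    out = np.zeros((B, C, L // p))
    for bi in range(B):
        for c in range(C):
            for l in range(L // p):
                out[bi, c, l] = sum(x[bi, c, l * p + j] for j in range(p)) / p
    return out


def fusion_loop(x, params, state, p: int):
    """The multi-scale fusion stage, Eq. by Eq., in eval mode.

    x1 = AvgPool(ELU(BN(Conv(X))));  x2 = AvgPool(ELU(BN(Conv(x1))));
    x3 = ELU(BN(Conv(x2)));  r1 = AvgPool(ELU(BN(Conv_stride-p(X))));
    r2 = AvgPool(x1);  fused = concat(r1, r2, x2, x3) on channels.
    """
    fp = params["fusion"]

    def block(inp, conv, bn, st, stride=1):
        y = conv1d_same_loop(inp, conv["W"], conv["b"], stride=stride)
        y = batchnorm_eval_loop(y, bn["gamma"], bn["beta"], st["mean"], st["var"])
        return elu_loop(y)

    x1 = avgpool_loop(block(x, fp["conv1"], fp["bn1"], state["bn1"]), p)
    x2 = avgpool_loop(block(x1, fp["conv2"], fp["bn2"], state["bn2"]), p)
    x3 = block(x2, fp["conv3"], fp["bn3"], state["bn3"])
    r1 = avgpool_loop(block(x, fp["convr1"], fp["bnr1"], state["bnr1"], stride=p), p)
    r2 = avgpool_loop(x1, p)
    return np.concatenate([r1, r2, x2, x3], axis=1)


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------


def entropy_from_counts(counts) -> float:
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            h -= (c / n) * math.log(c / n)
    return h


def homogeneity_completeness_bruteforce(y_true, clusters):
    """h and c straight from the conditional-entropy definitions."""
    y_true = list(y_true)
    clusters = list(clusters)
    n = len(y_true)
    classes = sorted(set(y_true))
    clusts = sorted(set(clusters))
    joint = {(a, k): 0 for a in classes for k in clusts}
    for a, k in zip(y_true, clusters):
        joint[(a, k)] += 1
    h_class = entropy_from_counts([sum(joint[(a, k)] for k in clusts) for a in classes])
    h_clust = entropy_from_counts([sum(joint[(a, k)] for a in classes) for k in clusts])
    # H(class | cluster) = sum_k p(k) H(class in cluster k)
    h_class_given = 0.0
    h_clust_given = 0.0
    for k in clusts:
        nk = sum(joint[(a, k)] for a in classes)
        h_class_given += (nk / n) * entropy_from_counts([joint[(a, k)] for a in classes])
    for a in classes:
        na = sum(joint[(a, k)] for k in clusts)
        h_clust_given += (na / n) * entropy_from_counts([joint[(a, k)] for k in clusts])
    h = 1.0 if h_class == 0 else 1.0 - h_class_given / h_class
    c = 1.0 if h_clust == 0 else 1.0 - h_clust_given / h_clust
    return h, c


def auc_pair_count(pos_scores, neg_scores) -> float:
    """AUC by exhaustive pair enumeration: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))
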