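"""Independent slow reference implementations used only as test oracles.

Everything here is written with explicit Python loops and scalar arithmetic,
deliberately sharing no code with the package's vectorized implementations.
"""

import math

import numpy as np


def conv2d_loops(x, w, b=None, stride=1, padding=0, groups=1):
    """Direct-convolution oracle. x: (N,C,H,W), w: (Co, C/g, kh, kw)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    n, c, h, wd = x.shape
    co, cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((n, co, ho, wo))
    cpg_out = co // groups
    for ni in range(n):
        for oc in range(co):
            g = oc // cpg_out
            for oi in range(ho):
                for oj in range(wo):
                    acc = 0.0
                    for ic in range(cg):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += (w[oc, ic, ki, kj]
                                        * xp[ni, g * cg + ic,
                                             oi * stride + ki, oj * stride + kj])
                    if b is not None:
                        acc += b[oc]
                    out[ni, oc, oi, oj] = acc
    return out


def pool2d_loops(x, kernel, stride, padding=0, mode="avg"):
    """Pooling oracle; avg divides by the full window (zeros in the pad)."""
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    out = np.zeros((n, c, ho, wo))
    for ni in range(n):
        for ci in range(c):
            for oi in range(ho):
                for oj in range(wo):
                    vals = []
                    for ki in range(kernel):
                        for kj in range(kernel):
                            ii = oi * stride + ki - padding
                            jj = oj * stride + kj - padding
                            if 0 <= ii < h and 0 <= jj < w:
                                vals.append(x[ni, ci, ii, jj])
                            elif mode == "avg":
                                vals.append(0.0)
                    out[ni, ci, oi, oj] = (sum(vals) / (kernel * kernel)
                                           if mode == "avg" else max(vals))
    return out


def gelu_scalar(v):
    return 0.5 * v * (1.0 + math.erf(v / math.sqrt(2.0)))


def gelu_loops(x):
    return np.vectorize(gelu_scalar)(np.asarray(x, dtype=np.float64))


def sigmoid_scalar(v):
    return 1.0 / (1.0 + math.exp(-v))


def bn_eval_loops(x, gamma, beta, mean, var, eps=1e-5):
    """Inference-mode batch norm with given per-channel statistics."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    for ci in range(x.shape[1]):
        out[:, ci] = (gamma[ci] * (x[:, ci] - mean[ci])
                      / math.sqrt(var[ci] + eps) + beta[ci])
    return out


def softmax_loops(z):
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    for i in range(z.shape[0]):
        m = max(z[i])
        e = [math.exp(v - m) for v in z[i]]
        s = sum(e)
        out[i] = [v / s for v in e]
    return out


def metrics_loops(counts):
    """Second, loop-based implementation of the confusion-matrix statistics.

    Returns fractions (not percent): per-class precision/recall/F1, macro
    averages, accuracy, balanced accuracy, and for binary matrices the
    sensitivity/specificity (support class 0) and G-mean.
    """
    counts = np.asarray(counts, dtype=np.float64)
    k = counts.shape[0]
    precision, recall, f1 = [], [], []
    for i in range(k):
        tp = counts[i][i]
        col = sum(counts[j][i] for j in range(k))
        row = sum(counts[i][j] for j in range(k))
        p = tp / col if col else 0.0
        r = tp / row if row else 0.0
        precision.append(p)
        recall.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
    total = counts.sum()
    result = {
        "precision": precision, "recall": recall, "f1": f1,
        "macro_precision": sum(precision) / k,
        "macro_recall": sum(recall) / k,
        "macro_f1": sum(f1) / k,
        "accuracy": sum(counts[i][i] for i in range(k)) / total,
        "balanced_accuracy": sum(recall) / k,
    }
    if k == 2:
        result["sensitivity"] = recall[0]
        result["specificity"] = recall[1]
        result["g_mean"] = math.sqrt(recall[0] * recall[1])
    return result


def binomial_tail_loops(correct, n, p):
    """P(X >= correct) by direct pmf summation (log-space terms)."""
    total = 0.0
    for x in range(correct, n + 1):
        logpmf = (math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
                  + x * math.log(p) + (n - x) * math.log1p(-p))
        total += math.exp(logpmf)
    return total


def pr_points_loops(scores, positives, thresholds):
    """(precision, recall) at each threshold t with the rule score >= t."""
    out = []
    n_pos = sum(positives)
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, positives) if s >= t and y)
        fp = sum(1 for s, y in zip(scores, positives) if s >= t and not y)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / n_pos if n_pos else 0.0
        out.append((precision, recall))
    return out


def wilson_interval_loops(correct, n, z=1.959963984540054):
    """Closed-form 95% Wilson score interval."""
    phat = correct / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half
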