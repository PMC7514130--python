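"""Independent brute-force oracles used only by the tests.

Each oracle is a literal transcription of the defining formula or a
direct enumeration, kept structurally separate from the package
implementation it checks.
"""

import math

import numpy as np


def sampen_oracle(x, m, r, T=1):
    """Literal template-counting Sample Entropy.

    Builds every delay-embedded template over the common index range
    i <= N - m*T, counts for each i the directed matches B_i (dimension
    m) and A_i (dimension m+1) with Chebyshev distance <= r, j != i, and
    returns -ln(sum A_i / sum B_i).
    """
    x = np.asarray(x, float)
    N = len(x)
    n = N - m * T

    def directed_matches(dim):
        templates = np.array([[x[i + k * T] for k in range(dim)] for i in range(n)])
        total = 0
        for i in range(n):
            d = np.max(np.abs(templates - templates[i]), axis=1)
            total += int(np.count_nonzero(d <= r)) - 1  # exclude j == i
        return total

    b = directed_matches(m)
    a = directed_matches(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def coarse_grain_oracle(x, tau):
    """Direct 1-based index arithmetic: y_j = (1/tau) * sum_{i=(j-1)tau+1}^{j tau} x_i."""
    x = np.asarray(x, float)
    n_blocks = len(x) // tau
    y = []
    for j in range(1, n_blocks + 1):
        total = 0.0
        for i in range((j - 1) * tau + 1, j * tau + 1):
            total += x[i - 1]
        y.append(total / tau)
    return np.array(y)


def bh_oracle(p, q):
    """Benjamini-Hochberg by explicit maximization over k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    if k_star > 0:
        reject = p <= p[order[k_star - 1]]
    return reject


def pooled_ttest_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def auc_oracle(scores, labels):
    """Pairwise-concordance AUC with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
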