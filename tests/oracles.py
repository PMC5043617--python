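"""Independent brute-force oracles used by the test suite only.

These are deliberately literal transcriptions — loops and explicit set
arithmetic — kept separate from the package implementations they check.
"""

import numpy as np


def tanimoto_brute(a, b) -> float:
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return inter / union if union else 0.0


def knn_score_brute(tanimotos, labels):
    """Literal transcription of the three branch formulas.

    score1 = (Σ T_n)/k                          all neighbours active
    score2 = 1 − score1                         all neighbours inactive
    score3 = (Σ T_n)/k_a + (1 − (Σ T_m)/k_in)   mixed
    Returns (raw, normalized).
    """
    k = len(labels)
    act = [t for t, l in zip(tanimotos, labels) if l == 1]
    ina = [t for t, l in zip(tanimotos, labels) if l == 0]
    if len(act) == k:
        raw = sum(act) / k
        return raw, raw
    if len(ina) == k:
        raw = 1.0 - sum(ina) / k
        return raw, raw
    raw = sum(act) / len(act) + (1.0 - sum(ina) / len(ina))
    return raw, raw / 2.0


def knn_predict_brute(Q, X, y, k):
    """Full pairwise Tanimoto + top-k (ties by row index) + score formulas."""
    out = []
    for q in Q:
        sims = [tanimoto_brute(q, x) for x in X]
        order = sorted(range(len(X)), key=lambda i: (-sims[i], i))[:k]
        _, norm = knn_score_brute([sims[i] for i in order], [y[i] for i in order])
        out.append(norm)
    return np.array(out)


def nb_posterior_brute(X, y, query, alpha=1.0) -> float:
    """Literal naïve-Bayes product for all-binary features, Laplace alpha.

    P(c) * Π_j P(x_j | c) with P(x_j=1|c) = (count + alpha) / (n_c + 2 alpha),
    normalized over the two classes.  Returns P(active | query).
    """
    n = len(y)
    joint = {}
    for c in (0, 1):
        rows = [X[i] for i in range(n) if y[i] == c]
        n_c = len(rows)
        prob = n_c / n
        for j, xq in enumerate(query):
            p1 = (sum(r[j] for r in rows) + alpha) / (n_c + 2 * alpha)
            prob *= p1 if xq == 1 else (1.0 - p1)
        joint[c] = prob
    return joint[1] / (joint[0] + joint[1])


def auc_brute(scores, labels) -> float:
    """Pairwise concordance over all positive × negative pairs, ties ½."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
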