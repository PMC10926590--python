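"""Independent brute-force oracles shared across test modules."""

import math

import numpy as np


def pair_counting_auc(scores, labels):
    """O(n^2) AUC: pairwise wins with half credit for score ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by direct enumeration over heterozygote counts."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)

    def weight(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        return (math.factorial(n) // (math.factorial(hr) * math.factorial(h)
                                      * math.factorial(hc))) * 2**h

    weights = {h: weight(h) for h in range(rare % 2, rare + 1, 2)}
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total
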