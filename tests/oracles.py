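"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: plain loops,
textbook formulas, exhaustive enumeration.
"""

import itertools
from math import factorial

import numpy as np

from phenorec import soft_membership


def exhaustive_l1_kmeans(X, k, w=None):
    """Optimal weighted within-cluster L1 objective over all label
    assignments with median centroids. Exponential — tiny n only."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    w = np.ones(X.shape[1]) if w is None else np.asarray(w, dtype=float)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        if len(np.unique(labels)) < k:
            continue
        obj = 0.0
        for c in range(k):
            members = X[labels == c]
            center = np.median(members, axis=0)
            obj += np.sum(np.abs(members - center) @ w)
        best = min(best, obj)
    return best


def oracle_shapley(x, cluster, model, background_point, groups):
    """Textbook Shapley sum over all coalitions, one plain membership
    evaluation per coalition."""
    names = list(groups)
    p = len(names)

    def value(coalition):
        z = background_point.copy()
        for g in coalition:
            z[groups[names[g]]] = x[groups[names[g]]]
        return soft_membership(z, model.cluster_centers_, model.weights_used_)[cluster]

    phi = np.zeros(p)
    for g in range(p):
        others = [j for j in range(p) if j != g]
        for r in range(p):
            for S in itertools.combinations(others, r):
                wgt = factorial(len(S)) * factorial(p - len(S) - 1) / factorial(p)
                phi[g] += wgt * (value(S + (g,)) - value(S))
    return phi


# Per-profile generator signatures: the raw features a profile's members
# deviate on (Likert shifts plus the occupation/age drivers).
PROFILE_SIGNATURE_FEATURES = {
    1: {"online_notifications", "texting", "insomnia", "bad_mood", "neighborhood"},
    2: {"online_notifications", "social_media", "attention_problems",
        "energetic_charge", "age"},
    3: {"occupation", "age"},
    4: {"obsession", "pain", "attention_problems", "energetic_charge", "occupation"},
}
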