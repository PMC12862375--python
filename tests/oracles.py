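"""Independent reference implementations used as oracles in the tests.

These deliberately use brute force or textbook formulas, never the package's
own code paths.
"""

import math

import numpy as np
from scipy.stats import distributions


def pearson_r_oracle(x, y) -> float:
    """Textbook product-moment correlation from the sum formula."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def hypergeom_tail_oracle(overlap: int, universe: int, regulon: int, members: int) -> float:
    """P(X >= overlap) by exhaustive enumeration of the hypergeometric pmf."""
    total = 0.0
    for k in range(overlap, min(regulon, members) + 1):
        total += (
            math.comb(regulon, k)
            * math.comb(universe - regulon, members - k)
            / math.comb(universe, members)
        )
    return min(total, 1.0)


def bh_oracle(pvals):
    """Naive O(m^2) Benjamini-Hochberg step-up adjustment."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def dagostino_k2_oracle(sample):
    """Textbook D'Agostino K2: squared z-transforms of sample skewness and kurtosis.

    Skewness transform after D'Agostino (1970); kurtosis transform after
    Anscombe & Glynn (1983); K2 ~ chi2(2) under normality.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    d = x - x.mean()
    m2 = (d**2).mean()
    m3 = (d**3).mean()
    m4 = (d**4).mean()
    b1 = m3 / m2**1.5
    b2 = m4 / m2**2

    # skewness z
    Y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    W2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(W2))
    alpha = math.sqrt(2.0 / (W2 - 1.0))
    Z1 = delta * math.asinh(Y / alpha)

    # kurtosis z
    Eb2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - Eb2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n * n - 5 * n + 2) / ((n + 7) * (n + 9))
    ) * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    A = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1**2))
    num = 1.0 - 2.0 / A
    denom = 1.0 + xk * math.sqrt(2.0 / (A - 4.0))
    Z2 = ((1.0 - 2.0 / (9.0 * A)) - np.sign(denom) * abs(num / denom) ** (1.0 / 3.0)) / math.sqrt(
        2.0 / (9.0 * A)
    )
    K2 = Z1 * Z1 + Z2 * Z2
    return K2, distributions.chi2.sf(K2, 2)


def explained_variance_oracle(X, M, A) -> float:
    """Direct Frobenius-norm computation, no projection refit."""
    X = np.asarray(X, float)
    resid = X - np.asarray(M, float) @ np.asarray(A, float)
    return 1.0 - (resid**2).sum() / (X**2).sum()
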