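"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: posterior enumeration
sums over every single-SNP causal configuration directly, and the Bayes
factor oracle integrates the marginal likelihood numerically.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.stats import norm


def enumerate_posteriors(bf1: np.ndarray, bf2: np.ndarray, p1: float, p2: float, p12: float) -> np.ndarray:
    """Posterior PP0..PP4 by brute-force enumeration of causal configurations.

    Configurations: the null (weight 1 relative to the null likelihood);
    disease causal at i (weight p1 * BF1_i); eQTL causal at j (p2 * BF2_j);
    distinct pair i != j (p1 p2 BF1_i BF2_j); shared SNP i (p12 BF1_i BF2_i).
    """
    bf1 = np.asarray(bf1, dtype=float)
    bf2 = np.asarray(bf2, dtype=float)
    Q = len(bf1)
    w = np.zeros(5)
    w[0] = 1.0
    for i in range(Q):
        w[1] += p1 * bf1[i]
        w[2] += p2 * bf2[i]
        w[4] += p12 * bf1[i] * bf2[i]
        for j in range(Q):
            if j != i:
                w[3] += p1 * p2 * bf1[i] * bf2[j]
    return w / w.sum()


def log_abf_by_integration(beta: float, varbeta: float, w: float) -> float:
    """Log marginal-likelihood ratio by numerical integration over the effect."""
    sd = math.sqrt(varbeta)

    def integrand(b: float) -> float:
        return norm.pdf(beta, loc=b, scale=sd) * norm.pdf(b, loc=0.0, scale=math.sqrt(w))

    lim = 12.0 * max(math.sqrt(w), sd, abs(beta))
    peak = w / (w + varbeta) * beta  # posterior mode of the effect
    num, _ = integrate.quad(
        integrand, -lim, lim, points=[peak], limit=200, epsabs=1e-300, epsrel=1e-12
    )
    return math.log(num) - norm.logpdf(beta, loc=0.0, scale=sd)


def log_abf_closed_form(beta: float, varbeta: float, w: float) -> float:
    """Density-ratio form: Normal(beta; 0, V+W) / Normal(beta; 0, V)."""
    return float(
        norm.logpdf(beta, scale=math.sqrt(varbeta + w)) - norm.logpdf(beta, scale=math.sqrt(varbeta))
    )
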