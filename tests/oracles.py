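"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed forms under test: the posterior oracle
integrates the joint density on a dense 2-D grid, and the log-uniform
moment oracle uses the closed-form antiderivatives of ln and ln^2.
"""

import math

import numpy as np
from scipy.stats import norm


def grid_posterior(
    phi,
    h,
    sigma_phi,
    sigma_h,
    mu_s,
    sigma_s,
    mu_d,
    sigma_d,
    step=0.002,
    span=6.0,
):
    """Posterior mean/variance of log-distance by brute-force 2-D grid integration.

    Integrates p(d | phi[, h]) over the (d, s) grid:
    p ~ N(phi; s-d, v_phi) * [N(h; s, v_h)] * N(s; mu_s, v_s) * N(d; mu_d, v_d),
    then marginalizes over s numerically. Pass ``h=None`` for the
    vision-only posterior.
    """
    d = np.arange(mu_d - span * sigma_d, mu_d + span * sigma_d + step, step)
    s = np.arange(mu_s - span * sigma_s, mu_s + span * sigma_s + step, step)
    D, S = np.meshgrid(d, s, indexing="ij")
    logp = (
        norm.logpdf(phi, S - D, sigma_phi)
        + norm.logpdf(S, mu_s, sigma_s)
        + norm.logpdf(D, mu_d, sigma_d)
    )
    if h is not None:
        logp = logp + norm.logpdf(h, S, sigma_h)
    p = np.exp(logp - logp.max())
    pd = p.sum(axis=1)
    pd /= pd.sum()
    mean = float((d * pd).sum())
    var = float(((d - mean) ** 2 * pd).sum())
    return mean, var


def log_uniform_mean(a, b):
    """E[ln X], X ~ U(a, b), via the antiderivative x ln x - x."""
    if a == b:
        return math.log(a)
    return (b * math.log(b) - b - (a * math.log(a) - a)) / (b - a)


def log_uniform_sd(a, b):
    """SD[ln X], X ~ U(a, b), via the antiderivative of ln^2."""
    if a == b:
        return 0.0

    def anti(x):
        lx = math.log(x)
        return x * (lx * lx - 2 * lx + 2)

    second = (anti(b) - anti(a)) / (b - a)
    return math.sqrt(second - log_uniform_mean(a, b) ** 2)


def ks_critical_value(n, alpha=0.01):
    """Asymptotic one-sample Kolmogorov-Smirnov critical value."""
    return math.sqrt(-0.5 * math.log(alpha / 2.0)) / math.sqrt(n)
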