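"""Shared fixtures: published gene-level count quadruples and helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import optimize

from proxecat import GeneCounts

# Gene-level rare-allele quadruples (x1f, x1p, x0f, x0p) and reported
# ProxECAT p-values for the four obesity candidate genes, in the
# high-coverage-cases vs. low-coverage-cohort analysis and the
# cases-vs-ExAC analysis.
COHORT_GENES = {
    "CD22": ((15, 0, 13, 18), 1.1e-05),
    "MIB2": ((0, 8, 62, 16), 1.9e-06),
    "NDEL1": ((13, 0, 18, 25), 1.7e-05),
    "PRDM13": ((9, 0, 13, 33), 1.1e-05),
}
EXAC_GENES = {
    "CD22": ((16, 1, 380, 247), 1.5e-03),
    "MIB2": ((0, 4, 600, 361), 5.2e-03),
    "NDEL1": ((11, 1, 357, 268), 8.1e-03),
    "PRDM13": ((7, 0, 173, 116), 7.8e-03),
}

# Case-control comparator results: (xf_case, xf_ctrl, n_case, n_ctrl) -> p
CASE_CONTROL = {
    ("MIB2", "exac"): ((0, 600, 927, 33370), 9.8e-09),
    ("MIB2", "cohort"): ((0, 62, 926, 3621), 1.1e-07),
    ("CD22", "cohort"): ((15, 13, 926, 3621), 1.1e-04),
}


def agrees_at_2sf(value: float, printed: float) -> bool:
    """True when value rounds to the printed number at 2 significant figures.

    Equivalent to |value - printed| being at most half a unit in the second
    significant digit of the printed value.
    """
    unit = 10.0 ** math.floor(math.log10(abs(printed)))
    return abs(value - printed) <= 0.055 * unit


@pytest.fixture
def cohort_counts():
    return {g: GeneCounts(*q, gene_id=g) for g, (q, _) in COHORT_GENES.items()}


def poisson_constrained_oracle(q: tuple[float, ...]) -> tuple[float, float]:
    """Numerically maximize the equal-ratio-constrained Poisson log-likelihood.

    Independent of the closed form: optimizes (log rho, log lam1p, log lam0p)
    by Nelder-Mead and returns (max log-likelihood, deviance statistic).
    """
    x1f, x1p, x0f, x0p = (float(v) for v in q)

    def loglik(lam):
        return sum(x * math.log(l) - l if x > 0 else -l
                   for x, l in zip((x1f, x1p, x0f, x0p), lam))

    def neg(t):
        rho, l1p, l0p = np.exp(t)
        return -loglik((rho * l1p, l1p, rho * l0p, l0p))

    t0 = np.log([
        (x1f + x0f + 0.5) / (x1p + x0p + 0.5),
        max(x1p, 0.5),
        max(x0p, 0.5),
    ])
    res = optimize.minimize(neg, t0, method="Nelder-Mead",
                            options=dict(xatol=1e-10, fatol=1e-12, maxiter=10_000))
    ll_unconstrained = sum(
        x * math.log(x) - x if x > 0 else 0.0 for x in (x1f, x1p, x0f, x0p)
    )
    return -res.fun, 2.0 * (ll_unconstrained - (-res.fun))
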