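"""Diagnostics for the Poisson count approximation and for test calibration.

Per-gene rare-allele totals arise from summing, over the variants in a
gene, binomial minor-allele counts across 2n sampled chromosomes.  This
module simulates that generative process under Hardy-Weinberg equilibrium
to check how well a Poisson law with matched mean approximates the
per-gene totals (moments and total-variation distance), and provides
QQ-plot machinery with the genomic inflation factor for genome-wide
p-value sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import lambda_gc

__all__ = [
    "BinomialGeneModel",
    "PoissonFit",
    "simulate_binomial_totals",
    "compare_to_poisson",
    "qq_points",
]


@dataclass(frozen=True)
class BinomialGeneModel:
    """Per-variant binomial sampling model for one gene region.

    ``k_variants`` independent variants, each with minor allele frequency
    ``maf``, genotyped in ``n`` diploid individuals; the per-gene total is
    the sum of minor-allele counts over variants.
    """

    maf: float
    n: int
    k_variants: int
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf < 0.5):
            raise ValueError("maf must be in (0, 0.5)")
        if self.n < 1 or self.k_variants < 1 or self.replicates < 1:
            raise ValueError("n, k_variants and replicates must be >= 1")

    @property
    def expected_total(self) -> float:
        return 2.0 * self.n * self.maf * self.k_variants


def simulate_binomial_totals(
    model: BinomialGeneModel,
    rng: np.random.Generator | None = None,
    *,
    genotype_level: bool = False,
) -> np.ndarray:
    """Sample per-gene minor-allele totals under the binomial model.

    By default each variant's count is drawn directly as Binomial(2n, maf)
    at the allele level; under HWE and independence this is exactly the
    distribution of 2 x (minor homozygotes) + heterozygotes, so the
    genotype-level path (``genotype_level=True``, multinomial over the
    three genotype classes) is retained only as a fidelity check.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if genotype_level:
        p, q = model.maf, 1.0 - model.maf
        probs = [p * p, 2 * p * q, q * q]
        g = rng.multinomial(model.n, probs, size=(model.replicates, model.k_variants))
        per_variant = 2 * g[..., 0] + g[..., 1]
    else:
        per_variant = rng.binomial(2 * model.n, model.maf, size=(model.replicates, model.k_variants))
    return per_variant.sum(axis=1)


@dataclass(frozen=True)
class PoissonFit:
    """Moment comparison and total-variation distance to a Poisson reference."""

    sample_mean: float
    sample_var: float
    lam: float
    tv_distance: float

    @property
    def dispersion_ratio(self) -> float:
        """Sample variance over sample mean; 1 for a Poisson-like sample."""
        return self.sample_var / self.sample_mean


def compare_to_poisson(samples: np.ndarray, lam: float) -> PoissonFit:
    """Compare an integer sample with Poisson(lam).

    Total variation distance is computed between the empirical mass
    function and the Poisson mass function over the support where either
    has mass above 1e-12 (Poisson tail mass beyond the truncation point is
    included in the distance).
    """
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("empty sample")
    if not lam > 0:
        raise ValueError("lam must be positive")
    hi = int(max(samples.max(), stats.poisson.isf(1e-12, lam))) + 1
    support = np.arange(hi + 1)
    emp = np.bincount(samples.astype(int), minlength=hi + 1) / samples.size
    pois = stats.poisson.pmf(support, lam)
    tv = 0.5 * (np.abs(emp - pois).sum() + float(stats.poisson.sf(hi, lam)))
    return PoissonFit(
        sample_mean=float(samples.mean()),
        sample_var=float(samples.var(ddof=1)),
        lam=float(lam),
        tv_distance=float(tv),
    )


def qq_points(p_values: np.ndarray) -> tuple[pd.DataFrame, float]:
    """QQ-plot coordinates on the -log10 scale, with a 95% band and lambda.

    Expected quantiles are i/(n+1) for the i-th order statistic; the
    pointwise band comes from the Beta(i, n+1-i) distribution of uniform
    order statistics.  Returns ``(table, lambda_gc)`` where the table has
    columns ``expected, observed, band_low, band_high`` sorted from most
    to least significant, invariant to the input order.
    """
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    n = p.size
    order = np.sort(p)
    i = np.arange(1, n + 1)
    expected = i / (n + 1.0)
    band_low = stats.beta.ppf(0.025, i, n + 1 - i)
    band_high = stats.beta.ppf(0.975, i, n + 1 - i)
    table = pd.DataFrame({
        "expected": -np.log10(expected),
        "observed": -np.log10(np.maximum(order, np.finfo(float).tiny)),
        "band_low": -np.log10(band_high),   # beta quantiles flip under -log10
        "band_high": -np.log10(band_low),
    })
    return table, lambda_gc(p_values=p)
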