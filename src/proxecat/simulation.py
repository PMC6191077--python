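"""Genome-scale count simulation for type-I-error and power studies.

Each gene contributes four independent Poisson (or negative-binomial)
counts — case functional, case proxy, control functional, control proxy —
with means built from a baseline per-subject per-kb minor-allele rate,
the gene length and the group sample sizes, times scenario multipliers:

* ``effect_mult`` — the disease association; multiplies the case
  *functional* rate only, and only for associated genes;
* ``cc_conf_mult`` — case-control confounding: a genome-wide technology or
  pipeline difference that inflates *both* variant classes in cases;
* ``gene_conf_mult`` — gene confounding: a gene-specific deviation
  (mutation rate, callability, annotation quality) that inflates both
  classes, either in cases and controls or, with
  ``gene_conf_cases_only``, in cases alone.

Confounding multiplies both functional and proxy rates because it models
sequencing and processing artifacts, which are agnostic to predicted
function; association touches the functional class only.  That asymmetry
is exactly what the proxy-ratio null exploits.

Genes are allocated across the four association x gene-confounding states;
type-I error is estimated on non-associated genes and power on associated
ones, with exact (Clopper-Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import core

__all__ = [
    "SimScenario",
    "GeneState",
    "STATE_ORDER",
    "simulate_gene",
    "simulate_genes",
    "type1_experiment",
    "power_experiment",
    "power_vs_controls",
    "clopper_pearson",
]


@dataclass(frozen=True)
class GeneState:
    """One of the four association x gene-confounding states."""

    assoc: bool
    gene_conf: bool


#: Canonical state order: (1) associated, no gene confounding;
#: (2) associated + confounded; (3) confounded only; (4) plain null.
STATE_ORDER: tuple[GeneState, ...] = (
    GeneState(True, False),
    GeneState(True, True),
    GeneState(False, True),
    GeneState(False, False),
)


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulation scenario.

    Defaults are the baseline study conditions: 0.001 minor alleles per
    subject per kb, 20 kb genes, 1000 cases and 1000 controls, 20,000
    genes, Poisson counts, nominal alpha 0.05.  ``state_proportions``
    (ordered as :data:`STATE_ORDER`) defaults to splitting genes equally
    over the states that the scenario's multipliers actually activate.
    """

    baseline_rate: float = 0.001
    gene_length_kb: float = 20.0
    n_cases: int = 1000
    n_controls: int = 1000
    effect_mult: float = 1.0
    gene_conf_mult: float = 1.0
    gene_conf_cases_only: bool = False
    cc_conf_mult: float = 1.0
    n_genes: int = 20_000
    state_proportions: tuple[float, float, float, float] | None = None
    eta: float | None = None
    seed: int = 0
    alpha: float = 0.05
    adjust: bool = True

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "gene_length_kb", "effect_mult",
                     "gene_conf_mult", "cc_conf_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_genes < 1:
            raise ValueError("sample sizes and n_genes must be positive")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive when set")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.state_proportions is not None:
            props = self.state_proportions
            if len(props) != 4 or any(p < 0 for p in props) or not math.isclose(sum(props), 1.0):
                raise ValueError("state_proportions must be 4 non-negative values summing to 1")

    def resolved_proportions(self) -> tuple[float, float, float, float]:
        """Explicit proportions, or an equal split over the active states."""
        if self.state_proportions is not None:
            return self.state_proportions
        has_assoc = self.effect_mult != 1.0
        has_conf = self.gene_conf_mult != 1.0
        if has_assoc and has_conf:
            return (0.25, 0.25, 0.25, 0.25)
        if has_assoc:
            return (0.5, 0.0, 0.0, 0.5)
        if has_conf:
            return (0.0, 0.0, 0.5, 0.5)
        return (0.0, 0.0, 0.0, 1.0)

    def alpha_used(self) -> float:
        return core.adjust_alpha(self.alpha) if self.adjust else self.alpha


def _cell_means(scenario: SimScenario, assoc: np.ndarray, conf: np.ndarray):
    """Per-gene Poisson/NB means for the four cells (arrays over genes)."""
    s = scenario
    base_case = s.baseline_rate * s.gene_length_kb * s.n_cases
    base_ctrl = s.baseline_rate * s.gene_length_kb * s.n_controls
    gconf_case = np.where(conf, s.gene_conf_mult, 1.0)
    gconf_ctrl = np.where(conf & (not s.gene_conf_cases_only), s.gene_conf_mult, 1.0)
    eff = np.where(assoc, s.effect_mult, 1.0)
    mu1f = base_case * s.cc_conf_mult * gconf_case * eff
    mu1p = base_case * s.cc_conf_mult * gconf_case
    mu0f = base_ctrl * gconf_ctrl
    mu0p = base_ctrl * gconf_ctrl
    return mu1f, mu1p, mu0f, mu0p


def _draw(rng: np.random.Generator, mu: np.ndarray, eta: float | None) -> np.ndarray:
    if eta is None:
        return rng.poisson(mu).astype(float)
    # NB with mean mu and size eta: variance mu * (1 + mu/eta)
    return rng.negative_binomial(eta, eta / (eta + mu)).astype(float)


def simulate_gene(scenario: SimScenario, state: GeneState, rng: np.random.Generator) -> core.GeneCounts:
    """Draw one gene's count quadruple under the given state."""
    assoc = np.array([state.assoc])
    conf = np.array([state.gene_conf])
    mus = _cell_means(scenario, assoc, conf)
    draws = [float(_draw(rng, mu, scenario.eta)[0]) for mu in mus]
    return core.GeneCounts(*draws)


def simulate_genes(scenario: SimScenario, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the full genome for a scenario.

    Returns a DataFrame with columns ``x1f, x1p, x0f, x0p, assoc, gene_conf``
    of length ``scenario.n_genes``; gene-state labels allow the caller to
    split null from associated genes.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    props = scenario.resolved_proportions()
    counts_per_state = np.floor(np.asarray(props) * scenario.n_genes).astype(int)
    # distribute the remainder to the largest-proportion states
    for i in np.argsort(props)[::-1]:
        if counts_per_state.sum() >= scenario.n_genes:
            break
        counts_per_state[i] += scenario.n_genes - counts_per_state.sum()
    assoc = np.concatenate([
        np.full(n, st.assoc) for st, n in zip(STATE_ORDER, counts_per_state)
    ])
    conf = np.concatenate([
        np.full(n, st.gene_conf) for st, n in zip(STATE_ORDER, counts_per_state)
    ])
    mu1f, mu1p, mu0f, mu0p = _cell_means(scenario, assoc, conf)
    return pd.DataFrame({
        "x1f": _draw(rng, mu1f, scenario.eta),
        "x1p": _draw(rng, mu1p, scenario.eta),
        "x0f": _draw(rng, mu0f, scenario.eta),
        "x0p": _draw(rng, mu0p, scenario.eta),
        "assoc": assoc,
        "gene_conf": conf,
    })


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    a = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return lo, hi


_DEFAULT_TESTS = ("proxecat", "case_control", "case_only")


def _test_pvalues(genes: pd.DataFrame, scenario: SimScenario, tests: Sequence[str]) -> dict[str, np.ndarray]:
    """All requested tests on a simulated genome; keyed by method label."""
    x1f = genes["x1f"].to_numpy()
    x1p = genes["x1p"].to_numpy()
    x0f = genes["x0f"].to_numpy()
    x0p = genes["x0p"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for t in tests:
        if t == "proxecat":
            out[t] = core.proxecat_pvalues(x1f, x1p, x0f, x0p)
        elif t == "proxecat_weighted":
            w = core.weight_medians(genes)
            out[t] = core.proxecat_pvalues(x1f / w.m1, x1p, x0f / w.m0, x0p)
        elif t == "proxecat_over":
            if scenario.eta is None:
                raise ValueError("proxecat_over requires scenario.eta")
            out[t] = core.proxecat_over_pvalues(x1f, x1p, x0f, x0p, scenario.eta)
        elif t == "case_control":
            out[t] = core.case_control_pvalues(x1f, x0f, scenario.n_cases, scenario.n_controls)
        elif t == "case_only":
            # genome-wide length-adjusted average rate, estimated from the data
            rate_hat = x1f.sum() / (scenario.gene_length_kb * len(x1f) * scenario.n_cases)
            expected = rate_hat * scenario.gene_length_kb * scenario.n_cases
            out[t] = core.case_only_pvalues(x1f, expected)
        else:
            raise ValueError(f"unknown test {t!r}")
    return out


def _rejection_table(pvals: dict[str, np.ndarray], mask: np.ndarray, alpha_used: float) -> pd.DataFrame:
    rows = []
    for name, p in pvals.items():
        p_sel = p[mask]
        ok = np.isfinite(p_sel)
        n = int(ok.sum())
        k = int((p_sel[ok] < alpha_used).sum())
        lo, hi = clopper_pearson(k, n)
        rows.append({
            "test": name, "n_genes": n, "n_reject": k,
            "rate": k / n if n else math.nan,
            "ci_low": lo, "ci_high": hi, "alpha_used": alpha_used,
        })
    return pd.DataFrame(rows)


def type1_experiment(scenario: SimScenario, tests: Sequence[str] = _DEFAULT_TESTS) -> pd.DataFrame:
    """Empirical type-I error per test over the scenario's null genes.

    Rejection fractions are computed on non-associated genes only, at the
    scenario's (optionally 0.9-adjusted) alpha, with exact binomial 95%
    intervals.  Degenerate genes (flagged NaN p-values) are excluded from
    the denominator.
    """
    genes = simulate_genes(scenario)
    null_mask = ~genes["assoc"].to_numpy()
    if not null_mask.any():
        raise ValueError("scenario allocates no null genes")
    pvals = _test_pvalues(genes, scenario, tests)
    return _rejection_table(pvals, null_mask, scenario.alpha_used())


def power_experiment(scenario: SimScenario, tests: Sequence[str] = _DEFAULT_TESTS) -> pd.DataFrame:
    """Empirical power per test over the scenario's associated genes."""
    if scenario.effect_mult <= 1.0:
        raise ValueError("power requires effect_mult > 1")
    genes = simulate_genes(scenario)
    assoc_mask = genes["assoc"].to_numpy()
    if not assoc_mask.any():
        raise ValueError("scenario allocates no associated genes")
    pvals = _test_pvalues(genes, scenario, tests)
    return _rejection_table(pvals, assoc_mask, scenario.alpha_used())


def power_vs_controls(
    scenario: SimScenario,
    n_controls_grid: Sequence[int],
    tests: Sequence[str] = ("proxecat",),
) -> pd.DataFrame:
    """Sweep the external-control sample size, holding everything else fixed.

    Each grid point re-runs :func:`power_experiment` with the same seed
    discipline (seed offset by the grid index) and stacks the results with
    an ``n_controls`` column.
    """
    frames = []
    for i, n_ctrl in enumerate(n_controls_grid):
        sc = replace(scenario, n_controls=int(n_ctrl), seed=scenario.seed + i)
        df = power_experiment(sc, tests)
        df.insert(0, "n_controls", int(n_ctrl))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
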