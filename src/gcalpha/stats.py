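"""Region-level rare-variant test statistics.

The centrepiece is the Gaussian (generalised) C-alpha test: given per-variant
effect estimates ``beta_k`` with standard errors ``se_k``, it accumulates the
overdispersion of the estimates around the null mean,

    S = sum_k [(beta_k - mu0)^2 - se_k^2],        c = 2 sum_k se_k^4,
    Z = S / sqrt(c),

and rejects for large Z in a one-tailed standard-normal test.  Under the null
every estimate is drawn from N(mu0, se_k^2), so each summand of S has mean
zero and variance 2 se_k^4; a mixture of non-null effect directions inflates
the observed variance and drives S positive regardless of sign balance --
this is what distinguishes the test from a burden (mean-shift) test.

Also provided: the Binomial C-alpha comparator for case/control allele
counts, and a carrier-proportion burden test fitted by generalised linear
regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

if TYPE_CHECKING:  # pragma: no cover
    from .effects import GenotypeRegion

__all__ = [
    "EffectEstimate",
    "CalphaResult",
    "BinomialSite",
    "gaussian_calpha",
    "gaussian_calpha_from_summary",
    "binomial_calpha",
    "binomial_variance_term",
    "burden_scores",
    "burden_test",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Per-variant effect of the minor allele and its standard error.

    ``beta`` is on the trait scale (log-odds for a binary trait, trait units
    per allele for a quantitative trait) and is oriented to the minor allele.
    ``se = 0`` marks a degenerate fit and is never silently used downstream.
    """

    variant_id: str
    beta: float
    se: float
    mac: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError(f"negative se for variant {self.variant_id}")


@dataclass
class CalphaResult:
    """Result of a region-level C-alpha test.

    ``z = S / sqrt(c)`` whenever ``c > 0``; ``p_asymptotic`` is the one-tailed
    upper standard-normal tail of ``z``.  ``p_permutation`` is attached only
    when a permutation run was performed; ``uncalibrated`` flags results (e.g.
    from summary statistics) for which permutation calibration was impossible.
    """

    S: float
    c: float
    z: float
    p_asymptotic: float
    n_variants: int
    p_permutation: float | None = None
    n_permutations: int = 0
    uncalibrated: bool = False
    permuted_stats: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class BinomialSite:
    """Minor-allele counts at one variant: ``y`` of ``n`` observed in cases."""

    y: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.y <= self.n) or self.n < 1:
            raise ValueError(f"require 0 <= y <= n, n >= 1; got y={self.y}, n={self.n}")


def _upper_tail(z: float) -> float:
    return float(sps.norm.sf(z))


def gaussian_calpha(
    effects: Sequence[EffectEstimate], mu0: float = 0.0
) -> CalphaResult:
    """Gaussian C-alpha test from per-variant effect estimates.

    Parameters
    ----------
    effects
        Converged per-variant estimates with strictly positive standard
        errors.  Ordering is irrelevant.
    mu0
        Null mean of the effect distribution.  For genetic association the
        expected effect of a minor allele is zero, so ``mu0 = 0`` (default).

    Raises
    ------
    ValueError
        On an empty list, any non-converged or zero-``se`` estimate, or a
        degenerate normalizer ``c = 0``.
    """
    if len(effects) == 0:
        raise ValueError("no variants")
    for e in effects:
        if not e.converged:
            raise ValueError(f"non-converged estimate at variant {e.variant_id}")
        if e.se == 0:
            raise ValueError(f"degenerate (se=0) estimate at variant {e.variant_id}")
    beta = np.array([e.beta for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    S = float(np.sum((beta - mu0) ** 2 - se**2))
    c = float(2.0 * np.sum(se**4))
    if c == 0:
        raise ValueError("degenerate normalizer")
    z = S / np.sqrt(c)
    return CalphaResult(
        S=S, c=c, z=z, p_asymptotic=_upper_tail(z), n_variants=len(effects)
    )


def inverse_variance_mu0(effects: Sequence[EffectEstimate]) -> float:
    """Inverse-variance-weighted mean of betas (null mean for non-genetic use)."""
    beta = np.array([e.beta for e in effects], dtype=float)
    w = np.array([1.0 / e.se**2 for e in effects], dtype=float)
    return float(np.sum(w * beta) / np.sum(w))


def gaussian_calpha_from_summary(
    table: pd.DataFrame, mu0: float = 0.0
) -> CalphaResult:
    """Gaussian C-alpha from a summary-statistics table.

    ``table`` needs columns ``variant_id``, ``beta``, ``se``.  The result is
    flagged ``uncalibrated``: without individual-level data no permutation
    calibration is possible and the asymptotic p-value may be anticonservative
    (correlated variants, sparse counts), so summary-mode results are for
    discovery only.
    """
    required = {"variant_id", "beta", "se"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    beta = pd.to_numeric(table["beta"], errors="coerce")
    se = pd.to_numeric(table["se"], errors="coerce")
    bad = table.index[~np.isfinite(beta) | ~np.isfinite(se) | (se <= 0)].tolist()
    if bad:
        raise ValueError(f"non-finite or invalid beta/se in rows {bad}")
    effects = [
        EffectEstimate(variant_id=str(v), beta=float(b), se=float(s))
        for v, b, s in zip(table["variant_id"], beta, se)
    ]
    res = gaussian_calpha(effects, mu0=mu0)
    res.uncalibrated = True
    return res


def binomial_variance_term(n: int, p0: float) -> float:
    """Null variance of one site's Binomial C-alpha summand, by enumeration.

    Returns ``Var_0[(y - n p0)^2 - n p0 (1-p0)]`` for ``y ~ Binomial(n, p0)``,
    computed exactly as ``sum_u [(u - n p0)^2 - n p0 (1-p0)]^2 Binom(u; n, p0)``.
    Equals the central-moment form ``mu4 - mu2^2``.  Zero for singletons
    (``n = 1``): a single observation carries no overdispersion information.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    u = np.arange(n + 1)
    m = n * p0
    v = m * (1.0 - p0)
    summand = ((u - m) ** 2 - v) ** 2
    return float(np.sum(summand * sps.binom.pmf(u, n, p0)))


def binomial_calpha(sites: Sequence[BinomialSite], p0: float) -> CalphaResult:
    """Binomial C-alpha test for a binary trait (Neale-style comparator).

    Models the number of minor alleles observed in cases, ``y_k``, out of the
    ``n_k`` total copies at variant k as Binomial(``n_k``, ``p_k``); under the
    null ``p_k = p0``, the case fraction.  The statistic

        T = sum_k [(y_k - n_k p0)^2 - n_k p0 (1 - p0)]

    is standardised by the exact null variance of each summand (enumeration
    over ``y``).  Cannot adjust for covariates or use dosages.
    """
    if len(sites) == 0:
        raise ValueError("no variants")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    y = np.array([s.y for s in sites], dtype=float)
    n = np.array([s.n for s in sites], dtype=float)
    m = n * p0
    T = float(np.sum((y - m) ** 2 - m * (1.0 - p0)))
    c = float(sum(binomial_variance_term(s.n, p0) for s in sites))
    if c == 0:
        raise ValueError("degenerate normalizer")
    z = T / np.sqrt(c)
    return CalphaResult(
        S=T, c=c, z=z, p_asymptotic=_upper_tail(z), n_variants=len(sites)
    )


def burden_scores(region: "GenotypeRegion", carrier_threshold: float = 0.5) -> np.ndarray:
    """Carrier-proportion burden score per sample.

    For each sample: the fraction of non-missing variants at which it carries
    at least one minor allele.  Hard genotypes carry at dosage >= 1; for
    imputed dosages the carrier call uses ``carrier_threshold`` (default 0.5,
    midpoint rounding of the expected genotype).  Samples with all genotypes
    missing get NaN with a warning.
    """
    dose = np.asarray(region.dosage, dtype=float)
    observed = ~np.isnan(dose)
    n_obs = observed.sum(axis=1)
    # hard calls (0/1/2) make any het a carrier at the default threshold
    carrier = (dose >= carrier_threshold) & observed
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = carrier.sum(axis=1) / n_obs
    if np.any(n_obs == 0):
        warnings.warn(
            f"{int(np.sum(n_obs == 0))} sample(s) with all genotypes missing; "
            "burden score undefined (NaN)",
            stacklevel=2,
        )
        scores = np.where(n_obs == 0, np.nan, scores)
    return scores


def burden_test(
    scores: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    trait_type: str = "quantitative",
) -> tuple[float, float, float]:
    """Regress the trait on the burden score (plus covariates).

    Linear regression for a quantitative trait, logistic for binary; returns
    ``(beta, se, p)`` with a two-sided Wald p-value for the score term.
    """
    scores = np.asarray(scores, dtype=float)
    trait = np.asarray(trait, dtype=float)
    keep = np.isfinite(scores) & np.isfinite(trait)
    scores, trait = scores[keep], trait[keep]
    if np.ptp(scores) == 0:
        raise ValueError("no burden variation")
    X = scores[:, None]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([X, cov[keep]])
    X = sm.add_constant(X, prepend=True)
    if trait_type == "quantitative":
        fit = sm.OLS(trait, X).fit()
    elif trait_type == "binary":
        fit = sm.GLM(trait, X, family=sm.families.Binomial()).fit()
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
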