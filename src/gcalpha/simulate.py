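"""Synthetic rare-variant regions and trait architectures.

Emulates the study design used to calibrate the tests: diploid samples
genotyped across a 30-200 kb gene-sized region whose polymorphic sites carry
a rare-allele frequency spectrum, and a quantitative trait driven by a random
mixture of trait-increasing and trait-decreasing causal variants of fixed
total MAF and fixed variance explained, optionally dichotomised at the
median into cases and controls.

The generator draws the number of sites as Poisson(theta * length_kb), each
site's population frequency from the neutral spectrum (density proportional
to 1/f on [1/(2n), 0.02]) and genotypes as independent Binomial(2, f) across
samples and sites.  The spectrum extends one octave above the 1% rare-variant
analysis ceiling so that realized-MAF windows bounded at 1% see symmetric
binomial smearing across that edge, as they would in a region that also
carries commoner variants removed by the MAF filter.  Sites are independent — there is no linkage
disequilibrium by construction; ``sample_region`` accepts a pluggable
``site_sampler`` hook so a coalescent simulator can be substituted when LD
matters.  The mutation intensity ``theta`` (expected polymorphic sites per
kb) is not a free dial: :func:`calibrate_theta` pins it to a target mean
variant count in a MAF window, reproducing the observed-variant density of
the study this emulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .effects import GenotypeRegion, orient_and_maf

logger = logging.getLogger(__name__)

__all__ = [
    "SimRegionConfig",
    "TraitModel",
    "sample_region",
    "calibrate_theta",
    "build_trait_model",
    "simulate_quantitative_trait",
    "dichotomize",
]

#: upper bound of the rare-allele spectrum (population MAF); one octave above
#: the 1% analysis ceiling so MAF windows ending at 1% see symmetric smearing
SPECTRUM_FMAX = 0.02


@dataclass(frozen=True)
class SimRegionConfig:
    """Region-simulation parameters.

    theta is the expected number of polymorphic rare sites per kb;
    length_kb defaults inside the 30-200 kb gene-sized range.
    """

    n_samples: int
    length_kb: float = 50.0
    theta: float = 1.5
    sfs_shape: str = "neutral_1f"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.sfs_shape != "neutral_1f":
            raise ValueError(f"unknown sfs_shape {self.sfs_shape!r}")


@dataclass
class TraitModel:
    """A simulated trait architecture on a region.

    ``effect`` is the common absolute per-allele effect a (trait units, total
    trait variance normalised to 1); ``signs`` are +1 for increaser and -1
    for decreaser causal variants, with round(prop_risk * n_causal) positive.
    """

    causal_ids: list[str]
    causal_idx: np.ndarray
    signs: np.ndarray
    effect: float
    residual_sd: float
    max_causal_maf: float = 0.01
    total_causal_maf: float = 0.05
    prop_risk: float = 0.5
    variance_explained: float = 0.006
    achieved_causal_maf: float = field(default=0.0)


def _sample_spectrum(rng: np.random.Generator, m: int, f_lo: float, f_hi: float) -> np.ndarray:
    """Draw m population MAFs from density 1/f on [f_lo, f_hi] (inverse CDF)."""
    u = rng.random(m)
    return f_lo * (f_hi / f_lo) ** u


def sample_region(config: SimRegionConfig, rng: np.random.Generator | None = None,
                  site_sampler=None) -> GenotypeRegion:
    """Simulate one diploid genotype region.

    Site count ~ Poisson(theta * length_kb); population MAF per site from the
    1/f spectrum on [1/(2 n), 0.02]; genotypes Binomial(2, f) independently
    per sample and site.  Returns an oriented region with realized MAFs.
    ``site_sampler(rng, m, n_samples) -> (n, m) dosage matrix`` overrides the
    independent-sites model when provided.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    m = int(rng.poisson(config.theta * config.length_kb))
    positions = np.sort(rng.integers(1, int(config.length_kb * 1000) + 1, size=m))
    if site_sampler is not None:
        dose = np.asarray(site_sampler(rng, m, n), dtype=float)
    else:
        f = _sample_spectrum(rng, m, 1.0 / (2 * n), SPECTRUM_FMAX)
        # Binomial(2, f) per sample as two independent allele draws; the
        # uniform-compare form is much faster than rng.binomial with a
        # per-site p vector
        u = rng.random((2, n, m), dtype=np.float32)
        dose = (u < f.astype(np.float32)).sum(axis=0).astype(float)
    region = GenotypeRegion(
        samples=[f"S{i:05d}" for i in range(n)],
        variant_ids=[f"var{j:04d}" for j in range(m)],
        positions=positions,
        dosage=dose,
    )
    return orient_and_maf(region)


def _mac_window_counts(
    rng: np.random.Generator,
    theta: float,
    length_kb: float,
    n_samples: int,
    maf_min: float,
    maf_max: float,
    reps: int,
) -> np.ndarray:
    """Mean-variant-count evaluation without materialising genotype matrices.

    A site with population MAF f has realized minor-allele count distributed
    Binomial(2n, f) (sum of 2n independent allele draws), so the count of
    variants inside a realized-MAF window per region only needs site-level
    draws.
    """
    two_n = 2 * n_samples
    counts = np.empty(reps)
    f_lo = 1.0 / two_n
    for r in range(reps):
        m = rng.poisson(theta * length_kb)
        f = _sample_spectrum(rng, m, f_lo, SPECTRUM_FMAX)
        mac = rng.binomial(two_n, f)
        maf = np.minimum(mac, two_n - mac) / two_n
        counts[r] = np.sum((maf > maf_min) & (maf < maf_max))
    return counts


def calibrate_theta(
    target_mean_variants: float,
    maf_window: tuple[float, float],
    length_kb: float,
    n_samples: int,
    reps: int = 2000,
    seed: int | None = None,
    rel_tol: float = 0.02,
) -> float:
    """Find theta so the mean variant count in a realized-MAF window hits a target.

    Bisection on theta with Monte-Carlo evaluation (common random numbers per
    evaluation so the objective is monotone).  Converges to within
    ``rel_tol`` of the target or raises with diagnostics.
    """
    if target_mean_variants <= 0:
        raise ValueError("target must be > 0")
    maf_min, maf_max = maf_window
    seed_seq = np.random.SeedSequence(seed)

    def mean_count(theta: float) -> float:
        rng = np.random.default_rng(seed_seq)  # common random numbers
        return float(
            _mac_window_counts(
                rng, theta, length_kb, n_samples, maf_min, maf_max, reps
            ).mean()
        )

    # the mean is linear in theta, so bracket from a pilot slope
    pilot = mean_count(1.0)
    if pilot == 0:
        raise ValueError(
            "no variants fall in the MAF window under the spectrum; "
            f"window=({maf_min}, {maf_max}), n={n_samples}, length={length_kb} kb"
        )
    lo, hi = 0.0, 2.0 * target_mean_variants / pilot
    while mean_count(hi) < target_mean_variants:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target mean variant count unattainable under the spectrum")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        got = mean_count(mid)
        if abs(got - target_mean_variants) <= rel_tol * target_mean_variants:
            logger.debug("calibrated theta=%.4f (mean count %.2f)", mid, got)
            return mid
        if got < target_mean_variants:
            lo = mid
        else:
            hi = mid
    raise ValueError("theta bisection failed to converge")


def build_trait_model(
    region: GenotypeRegion,
    rng: np.random.Generator,
    max_causal_maf: float = 0.01,
    total_causal_maf: float = 0.05,
    prop_risk: float = 0.5,
    variance_explained: float = 0.006,
) -> TraitModel:
    """Choose causal variants and solve the effect size from variance explained.

    Variants with MAF below ``max_causal_maf`` are accumulated in random
    order until their summed MAF first reaches ``total_causal_maf``;
    ``round(prop_risk * n_causal)`` of them get sign +1 (trait-increasing).
    With independent sites in Hardy-Weinberg proportions the genetic variance
    is ``a^2 * sum_k 2 f_k (1 - f_k)``, so the common absolute effect solves
    ``a = sqrt(h2 / sum_k 2 f_k (1-f_k))`` and ``residual_sd = sqrt(1 - h2)``
    (total trait variance 1).  ``variance_explained = 0`` gives the pure-null
    generator.
    """
    if region.maf is None:
        region = orient_and_maf(region)
    h2 = variance_explained
    if not (0.0 <= h2 < 1.0):
        raise ValueError("variance_explained must be in [0, 1)")
    if h2 == 0.0:
        return TraitModel(
            causal_ids=[], causal_idx=np.array([], dtype=int),
            signs=np.array([], dtype=float), effect=0.0, residual_sd=1.0,
            max_causal_maf=max_causal_maf, total_causal_maf=total_causal_maf,
            prop_risk=prop_risk, variance_explained=0.0,
        )
    eligible = np.flatnonzero((region.maf > 0) & (region.maf < max_causal_maf))
    order = rng.permutation(eligible)
    cum = np.cumsum(region.maf[order])
    if cum.size == 0 or cum[-1] < total_causal_maf:
        raise ValueError(
            f"cannot reach total causal MAF {total_causal_maf:.3f}: "
            f"available {0.0 if cum.size == 0 else cum[-1]:.3f}"
        )
    n_causal = int(np.searchsorted(cum, total_causal_maf) + 1)
    causal_idx = np.sort(order[:n_causal])
    f = region.maf[causal_idx]
    n_risk = int(round(prop_risk * n_causal))
    signs = np.full(n_causal, -1.0)
    signs[rng.choice(n_causal, size=n_risk, replace=False)] = 1.0
    var_per_a2 = float(np.sum(2.0 * f * (1.0 - f)))
    a = float(np.sqrt(h2 / var_per_a2))
    return TraitModel(
        causal_ids=[region.variant_ids[i] for i in causal_idx],
        causal_idx=causal_idx,
        signs=signs,
        effect=a,
        residual_sd=float(np.sqrt(1.0 - h2)),
        max_causal_maf=max_causal_maf,
        total_causal_maf=total_causal_maf,
        prop_risk=prop_risk,
        variance_explained=h2,
        achieved_causal_maf=float(np.sum(f)),
    )


def simulate_quantitative_trait(
    region: GenotypeRegion, model: TraitModel, rng: np.random.Generator
) -> np.ndarray:
    """Trait values y_i = sum_k sign_k a g_ik + e_i, e ~ N(0, residual_sd^2)."""
    n = region.n_samples
    eps = rng.normal(0.0, model.residual_sd, size=n)
    if model.causal_idx.size == 0 or model.effect == 0.0:
        return eps
    G = region.dosage[:, model.causal_idx]
    return G @ (model.signs * model.effect) + eps


def dichotomize(trait: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Cases (1) are the upper half of the trait distribution.

    Values strictly above the median are cases; ties at the median are broken
    in random order until the case count reaches floor(n/2), so the case and
    control counts differ by at most one.
    """
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(trait) == 0:
        raise ValueError("constant trait cannot be dichotomized")
    if rng is None:
        rng = np.random.default_rng()
    # random tiebreak: jitter ranks by a random permutation before argsort
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, trait))  # ascending trait, random within ties
    y = np.zeros(n)
    y[order[n - n // 2:]] = 1.0
    return y
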