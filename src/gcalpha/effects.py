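"""Per-variant effect estimation from individual-level genotypes.

Produces the :class:`~gcalpha.stats.EffectEstimate` inputs of the Gaussian
C-alpha test: one additive regression coefficient (and standard error) per
variant, with the dosage oriented to the minor allele, covariate adjustment,
and per-variant complete-case handling of missing genotypes.

Very rare variants make single-variant maximum-likelihood estimates fragile
(separation in logistic fits, monomorphic-in-subsample columns), so degenerate
or non-converged fits are excluded from the region test entirely rather than
patched, and a minimum minor-allele-count guard (``mac >= 2`` by default)
drops variants whose estimates could not be stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .stats import EffectEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeRegion",
    "PhenotypeTable",
    "orient_and_maf",
    "filter_by_maf",
    "fit_linear",
    "fit_logistic",
    "estimate_effects",
]

#: iteration cap and deviance tolerance for logistic IRLS
IRLS_MAXITER = 25
IRLS_TOL = 1e-8

#: above this |log-odds| a logistic fit is treated as separated
_SEPARATION_BETA = 15.0


@dataclass
class GenotypeRegion:
    """Sample-by-variant dosage matrix with variant metadata.

    ``dosage`` holds expected minor-allele counts in [0, 2] (NaN = missing).
    After :func:`orient_and_maf`, every column counts the *minor* allele:
    ``mean(dosage)/2 <= 0.5`` per variant, with ``flipped`` recording which
    columns were reoriented.
    """

    samples: list[str]
    variant_ids: list[str]
    positions: np.ndarray
    dosage: np.ndarray
    maf: np.ndarray | None = None
    mac: np.ndarray | None = None
    flipped: np.ndarray | None = None
    oriented: bool = False

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset_variants(self, keep: np.ndarray) -> "GenotypeRegion":
        keep = np.asarray(keep)
        return GenotypeRegion(
            samples=self.samples,
            variant_ids=[self.variant_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.variant_ids[i] for i in keep],
            positions=self.positions[keep],
            dosage=self.dosage[:, keep],
            maf=None if self.maf is None else self.maf[keep],
            mac=None if self.mac is None else self.mac[keep],
            flipped=None if self.flipped is None else self.flipped[keep],
            oriented=self.oriented,
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeRegion":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        out = GenotypeRegion(
            samples=[self.samples[i] for i in idx],
            variant_ids=self.variant_ids,
            positions=self.positions,
            dosage=self.dosage[idx, :],
            oriented=False,
        )
        # allele frequencies change under subsetting; re-derive
        return orient_and_maf(out) if self.oriented else out


@dataclass
class PhenotypeTable:
    """Trait and covariates for the analysed samples.

    ``trait_type`` is ``"quantitative"`` or ``"binary"`` (binary coded {0,1}
    with both classes present).  ``covariates`` is an n-by-C float matrix or
    None.
    """

    samples: list[str]
    trait: np.ndarray
    trait_type: str
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        if np.any(~np.isfinite(self.trait)):
            raise ValueError("missing or non-finite trait values for analysed samples")
        if self.trait_type == "binary":
            classes = np.unique(self.trait)
            if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size != 2:
                raise ValueError("binary trait must be coded {0,1} with both classes present")
        elif self.trait_type != "quantitative":
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.trait.shape[0]:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.trait.shape[0]:
                raise ValueError("covariate rows do not match samples")


def orient_and_maf(region: GenotypeRegion) -> GenotypeRegion:
    """Orient every variant to its minor allele and record MAF/MAC.

    The allele frequency is ``f = mean(dosage)/2`` over non-missing samples;
    columns with ``f > 0.5`` are flipped (``dosage -> 2 - dosage``) so that
    downstream betas always refer to the minor allele.  MAC is the rounded
    minor-allele dosage total.
    """
    dose = np.asarray(region.dosage, dtype=float)
    if np.any(dose < 0.0) or np.any(dose > 2.0):  # NaN compares False: missing ok
        raise ValueError("dosage outside [0, 2]")
    has_missing = bool(np.isnan(dose).any())
    if has_missing:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            f = np.nanmean(dose, axis=0) / 2.0
        f = np.where(np.isfinite(f), f, 0.0)
    else:
        f = dose.mean(axis=0) / 2.0
    flip = f > 0.5
    if flip.any():
        dose = dose.copy()
        dose[:, flip] = 2.0 - dose[:, flip]
    maf = np.where(flip, 1.0 - f, f)
    total = np.nansum(dose, axis=0) if has_missing else dose.sum(axis=0)
    mac = np.rint(total).astype(int)
    return GenotypeRegion(
        samples=region.samples,
        variant_ids=region.variant_ids,
        positions=region.positions,
        dosage=dose,
        maf=maf,
        mac=mac,
        flipped=flip,
        oriented=True,
    )


def filter_by_maf(
    region: GenotypeRegion, maf_min: float, maf_max: float, min_mac: int = 2
) -> GenotypeRegion:
    """Keep variants with ``maf_min < MAF < maf_max`` (strict) and MAC >= ``min_mac``.

    The strict inequalities mirror the usual printed windows (e.g.
    0.1%<MAF<0.5%).  The MAC guard drops variants whose handful of carriers
    cannot support a stable single-variant estimate; set ``min_mac=0`` to
    disable.
    """
    if not region.oriented or region.maf is None:
        region = orient_and_maf(region)
    keep = (region.maf > maf_min) & (region.maf < maf_max) & (region.mac >= min_mac)
    n_before, n_after = region.n_variants, int(keep.sum())
    if n_after == 0:
        raise ValueError("empty region after MAF filter")
    logger.debug("MAF filter (%g, %g): %d -> %d variants", maf_min, maf_max, n_before, n_after)
    return region.subset_variants(keep)


def _design(g: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != g.shape[0]:
            cov = cov.T
        cols.append(cov)
    return np.column_stack(cols)


def fit_linear(
    g: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
) -> EffectEstimate:
    """OLS per-allele effect of dosage on a quantitative trait.

    Intercept and covariates included; samples with missing dosage excluded
    for this variant only.  Zero dosage variance or collinearity with the
    covariates yields a non-converged estimate (excluded upstream), as does a
    perfect fit (``se = 0``).
    """
    g = np.asarray(g, dtype=float)
    obs = np.isfinite(g)
    g_o, y_o = g[obs], np.asarray(trait, dtype=float)[obs]
    cov_o = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        cov_o = (cov if cov.shape[0] == g.shape[0] else cov.T)[obs]
    mac = int(np.rint(g_o.sum()))
    n_cov = 0 if cov_o is None else cov_o.shape[1]
    if g_o.size < n_cov + 2 or np.ptp(g_o) == 0:
        return EffectEstimate(variant_id, 0.0, 0.0, mac=mac, converged=False)
    X = _design(g_o, cov_o)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return EffectEstimate(variant_id, 0.0, 0.0, mac=mac, converged=False)
    fit = sm.OLS(y_o, X).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if se <= 1e-10 * max(abs(beta), 1.0):
        # a perfect fit has no sampling variance to report: degenerate, flagged
        return EffectEstimate(variant_id, beta, 0.0, mac=mac, converged=False)
    return EffectEstimate(variant_id, beta, se, mac=mac, converged=True)


def fit_logistic(
    g: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
    one_step: bool = False,
) -> EffectEstimate:
    """Additive log-odds effect of dosage on a binary trait.

    Maximum likelihood via iteratively reweighted least squares (cap
    ``IRLS_MAXITER`` iterations, deviance tolerance ``IRLS_TOL``).
    Separation — expected for very rare variants — is flagged as
    ``converged=False``, not raised.  ``one_step=True`` instead takes a single
    Newton step from beta = 0 (the score/information estimator), which is what
    the batched permutation engine uses for binary traits.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(trait, dtype=float)
    obs = np.isfinite(g)
    g_o, y_o = g[obs], y[obs]
    cov_o = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        cov_o = (cov if cov.shape[0] == g.shape[0] else cov.T)[obs]
    mac = int(np.rint(g_o.sum()))
    if np.unique(y_o).size < 2:
        raise ValueError("all-case or all-control input")
    if np.ptp(g_o) == 0:
        return EffectEstimate(variant_id, 0.0, 0.0, mac=mac, converged=False)
    if one_step:
        beta, se = onestep_logistic(g_o, y_o, cov_o)
        return EffectEstimate(variant_id, beta, se, mac=mac, converged=se > 0)
    X = _design(g_o, cov_o)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return EffectEstimate(variant_id, 0.0, 0.0, mac=mac, converged=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.GLM(y_o, X, family=sm.families.Binomial()).fit(
                maxiter=IRLS_MAXITER, tol=IRLS_TOL
            )
    except (PerfectSeparationError, PerfectSeparationWarning):
        return EffectEstimate(variant_id, 0.0, 0.0, mac=mac, converged=False)
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > _SEPARATION_BETA:
        return EffectEstimate(variant_id, beta, 0.0, mac=mac, converged=False)
    return EffectEstimate(variant_id, beta, se, mac=mac, converged=True)


def onestep_logistic(
    g: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """One Newton step from beta=0 for the logistic dosage coefficient.

    With no covariates the null fit is the case fraction ``p``; the step is

        beta = sum_i gc_i (y_i - p) / (w * sum_i gc_i^2),   w = p (1 - p),

    with ``gc`` the centred dosage and ``se = 1/sqrt(w * sum gc^2)``.  With
    covariates, ``g`` and ``y - p_hat`` are residualised on the null
    (covariates-only) logistic fit in the working metric.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        p = y.mean()
        w = p * (1.0 - p)
        gc = g - g.mean()
        info = w * float(gc @ gc)
        if info <= 0:
            return 0.0, 0.0
        return float(gc @ (y - p)) / info, 1.0 / np.sqrt(info)
    X0 = sm.add_constant(np.atleast_2d(covariates), prepend=True)
    null = sm.GLM(y, X0, family=sm.families.Binomial()).fit()
    p = np.asarray(null.fittedvalues)
    w = p * (1.0 - p)
    # weighted projection of g off the null design
    WX = X0 * w[:, None]
    coef, *_ = np.linalg.lstsq(X0.T @ WX, X0.T @ (w * g), rcond=None)
    g_res = g - X0 @ coef
    info = float((w * g_res) @ g_res)
    if info <= 0:
        return 0.0, 0.0
    return float(g_res @ (y - p)) / info, 1.0 / np.sqrt(info)


def estimate_effects(
    region: GenotypeRegion,
    phenotypes: PhenotypeTable,
    one_step: bool = False,
) -> tuple[list[EffectEstimate], np.ndarray]:
    """One effect estimate per variant of an oriented, MAF-filtered region.

    Returns ``(estimates, kept)`` where ``kept`` is the boolean mask of
    variants whose fits converged with a positive standard error.  Degenerate
    and non-converged fits are excluded and logged; permutation replicates
    must reuse exactly this surviving variant set (consistency contract
    enforced by :mod:`gcalpha.permutation`).
    """
    if region.n_samples != len(phenotypes.trait):
        raise ValueError("region and phenotype samples are not aligned")
    fit = fit_linear if phenotypes.trait_type == "quantitative" else fit_logistic
    kwargs = {} if phenotypes.trait_type == "quantitative" else {"one_step": one_step}
    estimates: list[EffectEstimate] = []
    kept = np.zeros(region.n_variants, dtype=bool)
    for j in range(region.n_variants):
        est = fit(
            region.dosage[:, j],
            phenotypes.trait,
            phenotypes.covariates,
            variant_id=region.variant_ids[j],
            **kwargs,
        )
        if est.converged and est.se > 0:
            estimates.append(est)
            kept[j] = True
        else:
            logger.info("excluding variant %s: degenerate or non-converged fit", est.variant_id)
    if not estimates:
        raise ValueError("no variants with stable effect estimates")
    return estimates, kept
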