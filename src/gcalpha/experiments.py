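"""Simulation experiments: type I error calibration and power surfaces.

Reproduces the calibration study design at configurable scale: repeated
synthetic regions (2,000 samples, 50 kb for the null study), a null or
mixture-architecture trait, region tests with permutation significance, and
tabulated rejection rates with binomial confidence intervals.

The desk-scale defaults (10,000 replicates, B = 1,000 permutations) resolve
nominal levels down to 1e-2 comfortably; the 1e-4/1e-5 cells of a
100,000-replicate study are cluster-scale and are deliberately out of the
default profile.

Permutation replay is fully vectorized (one BLAS product per replicate per
MAF window), which is what makes 10^7 test statistics per experiment
practical on one core.  Power experiments default to the asymptotic
one-tailed threshold — at the sample sizes where power is interesting the
permutation and asymptotic scales agree — with permutation power available
via ``power_permutations``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .effects import filter_by_maf
from .permutation import (
    batched_binomial_calpha,
    batched_linear_calpha,
    batched_onestep_calpha,
    permutation_pvalue,
    _permutation_matrix,
)
from .simulate import (
    SimRegionConfig,
    build_trait_model,
    calibrate_theta,
    dichotomize,
    sample_region,
    simulate_quantitative_trait,
)
from .stats import burden_scores, burden_test

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "type1_experiment",
    "power_experiment",
    "region_size_experiment",
]

#: Table-style calibration anchors: mean variant count targets per MAF window
NULL_COUNT_TARGET = {"window": (0.002, 0.01), "mean_variants": 34.0}


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one simulation experiment.

    ``theta=None`` triggers calibration of the mutation intensity so the mean
    variant count in ``calibration_window`` matches ``calibration_target``.
    ``trait_kind`` is ``"quantitative"``, ``"dichotomized"`` or ``"both"``.
    """

    scenario: str = "null"
    n_samples: int = 2000
    length_kb: float = 50.0
    maf_windows: tuple[tuple[float, float], ...] = ((0.002, 0.01), (0.005, 0.01))
    prop_risk_grid: tuple[float, ...] = (0.5,)
    h2: float = 0.0
    n_replicates: int = 10_000
    n_permutations: int = 1000
    levels: tuple[float, ...] = (0.01,)
    seed: int = 0
    trait_kind: str = "quantitative"
    tests: tuple[str, ...] = ("gcalpha",)
    theta: float | None = None
    calibration_window: tuple[float, float] = (0.002, 0.01)
    calibration_target: float = 34.0
    power_permutations: int = 0  # 0 = asymptotic power
    min_mac: int = 2

    def __post_init__(self) -> None:
        if self.n_replicates < 100:
            raise ValueError("need at least 100 replicates")
        if self.n_permutations >= 1:
            floor = 1.0 / (self.n_permutations + 1)
            if any(lv < floor for lv in self.levels):
                raise ValueError(
                    f"significance level below permutation granularity {floor:.2e}"
                )
        if self.trait_kind not in ("quantitative", "dichotomized", "both"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        unknown = set(self.tests) - {"gcalpha", "burden", "binomial"}
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")

    def resolved_theta(self) -> float:
        if self.theta is not None:
            return self.theta
        return calibrate_theta(
            self.calibration_target,
            self.calibration_window,
            self.length_kb,
            self.n_samples,
            seed=self.seed + 7_919,
        )


@dataclass
class ExperimentResult:
    """Tabulated estimates with binomial 95% CIs plus raw per-replicate p-values."""

    table: pd.DataFrame
    config: ExperimentConfig
    theta: float
    runtime_s: float
    pvalues: dict = field(default_factory=dict, repr=False)
    mean_variants: dict = field(default_factory=dict)


def _wilson_ci(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _trait_kinds(config: ExperimentConfig) -> list[str]:
    if config.trait_kind == "both":
        return ["quantitative", "dichotomized"]
    return [config.trait_kind]


def type1_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Null calibration: fraction of replicates with permutation p <= level.

    Per replicate: a fresh region, a trait with no genetic component
    (standard normal; optionally dichotomized at the median), and the
    Gaussian C-alpha permutation test in each MAF window.  The same region
    and the same permutation assignments are shared across windows and trait
    kinds of a replicate, mirroring a single pass over one simulated dataset.
    """
    if config.h2 != 0.0:
        raise ValueError("type I error experiment requires h2 = 0")
    t0 = time.perf_counter()
    theta = config.resolved_theta()
    kinds = _trait_kinds(config)
    B = config.n_permutations
    ss = np.random.SeedSequence(config.seed)
    pvals: dict[tuple[str, tuple[float, float]], np.ndarray] = {
        (k, w): np.full(config.n_replicates, np.nan)
        for k in kinds
        for w in config.maf_windows
    }
    nvar: dict[tuple[float, float], list[int]] = {w: [] for w in config.maf_windows}
    region_cfg = SimRegionConfig(
        n_samples=config.n_samples, length_kb=config.length_kb, theta=theta
    )
    for r, child in enumerate(ss.spawn(config.n_replicates)):
        rng = np.random.default_rng(child)
        region = sample_region(region_cfg, rng=rng)
        y = rng.standard_normal(config.n_samples)
        perms = _permutation_matrix(rng, config.n_samples, B).astype(np.intp)
        traits = {"quantitative": y.astype(np.float32)}
        if "dichotomized" in kinds:
            traits["dichotomized"] = dichotomize(y, rng).astype(np.float32)
        # one gather per trait kind, shared across MAF windows; engines take
        # the (n, B) transposed view without copying
        permuted = {k: t[perms].T for k, t in traits.items()}
        for window in config.maf_windows:
            try:
                sub = filter_by_maf(region, *window, min_mac=config.min_mac)
            except ValueError:
                nvar[window].append(0)
                continue
            nvar[window].append(sub.n_variants)
            G = np.asarray(sub.dosage, dtype=np.float32)
            for kind in kinds:
                engine = (
                    batched_linear_calpha
                    if kind == "quantitative"
                    else batched_onestep_calpha
                )
                z_obs, _ = engine(G, traits[kind])
                z_perm, _ = engine(G, permuted[kind])
                pvals[(kind, window)][r] = permutation_pvalue(
                    float(z_obs[0]), z_perm
                )

    rows = []
    for kind in kinds:
        for window in config.maf_windows:
            p = pvals[(kind, window)]
            ok = np.isfinite(p)
            for level in config.levels:
                k = int(np.sum(p[ok] <= level))
                n = int(ok.sum())
                lo, hi = _wilson_ci(k, n)
                rows.append(
                    {
                        "trait_kind": kind,
                        "maf_min": window[0],
                        "maf_max": window[1],
                        "level": level,
                        "estimate": k / n,
                        "ci_low": lo,
                        "ci_high": hi,
                        "mean_variants": float(np.mean(nvar[window])),
                        "n_replicates": n,
                        "n_permutations": B,
                    }
                )
    return ExperimentResult(
        table=pd.DataFrame(rows),
        config=config,
        theta=theta,
        runtime_s=time.perf_counter() - t0,
        pvalues={f"{k}:{w[0]:g}-{w[1]:g}": v for (k, w), v in pvals.items()},
        mean_variants={w: float(np.mean(nvar[w])) for w in config.maf_windows},
    )


def _power_replicate(
    rng: np.random.Generator,
    region_cfg: SimRegionConfig,
    config: ExperimentConfig,
    prop_risk: float,
) -> dict[tuple[str, str, tuple[float, float]], float]:
    """One power replicate: p-value per (test, trait kind, MAF window)."""
    region = sample_region(region_cfg, rng=rng)
    model = build_trait_model(
        region, rng, prop_risk=prop_risk, variance_explained=config.h2
    )
    y = simulate_quantitative_trait(region, model, rng)
    kinds = _trait_kinds(config)
    yb = dichotomize(y, rng) if "dichotomized" in kinds else None
    B = config.power_permutations
    perms = (
        _permutation_matrix(rng, region.n_samples, B) if B >= 1 else None
    )
    out: dict[tuple[str, str, tuple[float, float]], float] = {}
    for window in config.maf_windows:
        try:
            sub = filter_by_maf(region, *window, min_mac=config.min_mac)
        except ValueError:
            continue
        G = np.asarray(sub.dosage, dtype=np.float32)
        for kind in kinds:
            t = y if kind == "quantitative" else yb
            for test in config.tests:
                if test == "gcalpha":
                    engine = (
                        batched_linear_calpha
                        if kind == "quantitative"
                        else batched_onestep_calpha
                    )
                elif test == "binomial":
                    if kind != "dichotomized":
                        continue
                    engine = batched_binomial_calpha
                elif test == "burden":
                    if kind != "quantitative":
                        continue  # carrier burden reported on the trait scale
                    scores = burden_scores(sub)
                    try:
                        _, _, p = burden_test(scores, y, trait_type="quantitative")
                    except ValueError:
                        p = np.nan
                    out[(test, kind, window)] = p
                    continue
                cols = (
                    np.column_stack([t, t[perms.T]]).astype(np.float32)
                    if perms is not None
                    else np.asarray(t, dtype=np.float32)[:, None]
                )
                z, _ = engine(G, cols)
                if perms is not None:
                    out[(test, kind, window)] = permutation_pvalue(float(z[0]), z[1:])
                else:
                    out[(test, kind, window)] = float(sps.norm.sf(z[0]))
    return out


def power_experiment(config: ExperimentConfig, level: float = 0.05) -> ExperimentResult:
    """Power across the risk/protective mixture grid.

    For each ``prop_risk`` cell: fresh regions with a causal architecture of
    total MAF 5% (max 1% each) explaining ``h2`` of the trait variance, and
    the rejection rate of each enabled test at ``level``.  One-tailed
    asymptotic rejection for the C-alpha tests unless ``power_permutations``
    requests permutation p-values; two-sided Wald for the burden regression.
    """
    if config.h2 <= 0:
        raise ValueError("power experiment requires h2 > 0 (use type1_experiment for null)")
    t0 = time.perf_counter()
    theta = config.resolved_theta()
    region_cfg = SimRegionConfig(
        n_samples=config.n_samples, length_kb=config.length_kb, theta=theta
    )
    ss = np.random.SeedSequence(config.seed)
    rows = []
    pvalues: dict[str, np.ndarray] = {}
    for prop_risk in config.prop_risk_grid:
        cells: dict[tuple[str, str, tuple[float, float]], list[float]] = {}
        for child in ss.spawn(config.n_replicates):
            rng = np.random.default_rng(child)
            rep = _power_replicate(rng, region_cfg, config, prop_risk)
            for key, p in rep.items():
                cells.setdefault(key, []).append(p)
        for (test, kind, window), plist in sorted(cells.items()):
            p = np.asarray(plist)
            ok = np.isfinite(p)
            k, n = int(np.sum(p[ok] <= level)), int(ok.sum())
            lo, hi = _wilson_ci(k, n)
            rows.append(
                {
                    "test": test,
                    "trait_kind": kind,
                    "prop_risk": prop_risk,
                    "maf_min": window[0],
                    "maf_max": window[1],
                    "level": level,
                    "power": k / n,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_replicates": n,
                }
            )
            pvalues[f"{test}:{kind}:{window[0]:g}-{window[1]:g}:risk={prop_risk:g}"] = p
    return ExperimentResult(
        table=pd.DataFrame(rows),
        config=config,
        theta=theta,
        runtime_s=time.perf_counter() - t0,
        pvalues=pvalues,
    )


def region_size_experiment(
    config: ExperimentConfig, lengths_kb: tuple[float, ...] = (50.0, 100.0, 200.0),
    level: float = 0.05,
) -> ExperimentResult:
    """Power as a function of region size at a fixed causal architecture.

    Longer regions add non-causal variants (site count is linear in length),
    diluting every test; the table carries one power row per length so the
    monotone trend can be read off directly.
    """
    t0 = time.perf_counter()
    frames = []
    pvalues: dict[str, np.ndarray] = {}
    theta = config.resolved_theta()
    for length in lengths_kb:
        sub = replace(config, length_kb=length, theta=theta)
        res = power_experiment(sub, level=level)
        tab = res.table.copy()
        tab.insert(0, "length_kb", length)
        frames.append(tab)
        pvalues.update({f"len={length:g}:{k}": v for k, v in res.pvalues.items()})
    return ExperimentResult(
        table=pd.concat(frames, ignore_index=True),
        config=config,
        theta=theta,
        runtime_s=time.perf_counter() - t0,
        pvalues=pvalues,
    )
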