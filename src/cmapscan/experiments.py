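"""Simulation experiments shared by the test suite and the acceptance script.

These wrap the pipeline end to end under fixed study conditions: parameter
recovery of the MUNE estimator across pool sizes, and the two-group contrast
pattern (MUNE and CMAP strongly separated, D50 not) on simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort_stats import compare_groups
from .d50 import max_cmap
from .mscanfit import FitConfig, FitNonConvergenceError, estimate_mune
from .scan_model import (
    HEALTHY_GROUP,
    SCI_GROUP,
    DistributionSpec,
    PoolSpec,
    ScanProtocol,
    generate_cohort,
    generate_pool,
    simulate_scan,
)

__all__ = ["recovery_pool_spec", "mune_recovery", "group_contrast",
           "paired_reinnervation_contrast"]

#: per-unit MUAP amplitude of the healthy preset (16.75 mV over 108 units)
MEAN_UNIT_AMPLITUDE_MV = HEALTHY_GROUP.cmap_mean / HEALTHY_GROUP.n_units_mean


def recovery_pool_spec(n_units: int) -> PoolSpec:
    """Healthy-like pool of ``n_units`` units used for parameter recovery:
    lognormal MUAP amplitudes (mean 0.155 mV), thresholds uniform over the
    healthy recruitment range, 2.5% relative spread, 0.03 mV noise."""
    return PoolSpec(
        n_units=n_units,
        amplitude=DistributionSpec(
            "lognormal",
            {"mean": MEAN_UNIT_AMPLITUDE_MV, "sigma": HEALTHY_GROUP.amplitude_sigma},
        ),
        threshold=DistributionSpec(
            "uniform",
            {"low": HEALTHY_GROUP.threshold_low, "high": HEALTHY_GROUP.threshold_high},
        ),
        relative_spread=HEALTHY_GROUP.relative_spread,
        noise_sd=HEALTHY_GROUP.noise_sd,
    )


@dataclass(frozen=True)
class RecoveryResult:
    true_n: np.ndarray
    estimated: np.ndarray
    errors: np.ndarray
    spearman_r: float
    n_fits: int

    @property
    def max_error(self) -> float:
        return float(self.errors.max())


def mune_recovery(
    pool_sizes=(10, 20, 40, 80),
    n_scans_per_size: int = 50,
    seed: int = 0,
    n_stimuli: int = 500,
    fit_config: FitConfig | None = None,
) -> RecoveryResult:
    """Fit the MUNE estimator to simulated scans from pools of known size and
    report the Spearman correlation between true and estimated counts.

    Fits that exhaust the batch cap (none expected under these conditions)
    contribute their best-effort estimate.
    """
    true_n, est, errs = [], [], []
    counter = 0
    for n_units in pool_sizes:
        spec = recovery_pool_spec(n_units)
        for _ in range(n_scans_per_size):
            sub = seed + 1000 * counter
            counter += 1
            pool = generate_pool(spec, seed=sub)
            protocol = ScanProtocol.from_prescan(pool, n_stimuli=n_stimuli)
            scan = simulate_scan(pool, protocol, seed=sub + 1)
            cfg = replace(fit_config or FitConfig(), seed=sub + 2)
            try:
                fit = estimate_mune(scan, cfg)
            except FitNonConvergenceError as exc:
                fit = exc.best_result
            true_n.append(n_units)
            est.append(fit.mune)
            errs.append(fit.percentage_error)
    true_n = np.asarray(true_n)
    est = np.asarray(est)
    rho = float(stats.spearmanr(true_n, est).statistic)
    return RecoveryResult(true_n, est, np.asarray(errs), rho, counter)


def paired_reinnervation_contrast(
    n_pairs: int = 50,
    seed: int = 0,
    sci_n_units: int = 59,
    control_n_units: int = 108,
    sci_cmap: float = 11.5,
    control_cmap: float = 11.7,
    fit_config: FitConfig | None = None,
) -> tuple[int, list]:
    """Paired MUNE comparison of an SCI-like pool (fewer, reinnervation-
    enlarged units) against a control-like pool at near-identical maximum
    CMAP — the situation where CMAP amplitude alone cannot reveal motor unit
    loss.  Returns (number of pairs with SCI estimate < control estimate,
    per-pair estimates)."""
    sci_spec = PoolSpec(
        sci_n_units,
        DistributionSpec("lognormal", {"mean": MEAN_UNIT_AMPLITUDE_MV,
                                       "sigma": SCI_GROUP.amplitude_sigma}),
        DistributionSpec("uniform", {"low": SCI_GROUP.threshold_low,
                                     "high": SCI_GROUP.threshold_high}),
        reinnervation_factor=control_n_units / sci_n_units,
        target_max_cmap=sci_cmap,
    )
    ctl_spec = PoolSpec(
        control_n_units,
        DistributionSpec("lognormal", {"mean": MEAN_UNIT_AMPLITUDE_MV,
                                       "sigma": HEALTHY_GROUP.amplitude_sigma}),
        DistributionSpec("uniform", {"low": HEALTHY_GROUP.threshold_low,
                                     "high": HEALTHY_GROUP.threshold_high}),
        target_max_cmap=control_cmap,
    )
    wins = 0
    pairs = []
    for k in range(n_pairs):
        estimates = []
        for spec, sub in ((sci_spec, seed + 2 * k * 101), (ctl_spec, seed + (2 * k + 1) * 101)):
            pool = generate_pool(spec, seed=sub)
            protocol = ScanProtocol.from_prescan(pool)
            scan = simulate_scan(pool, protocol, seed=sub + 1)
            cfg = replace(fit_config or FitConfig(), seed=sub + 2)
            try:
                fit = estimate_mune(scan, cfg)
            except FitNonConvergenceError as exc:
                fit = exc.best_result
            estimates.append(fit.mune)
        pairs.append(tuple(estimates))
        wins += estimates[0] < estimates[1]
    return wins, pairs


@dataclass(frozen=True)
class ContrastResult:
    mune_p: np.ndarray
    cmap_p: np.ndarray
    d50_p: np.ndarray
    n_replicates: int

    def fraction(self, which: str, threshold: float) -> float:
        p = getattr(self, f"{which}_p")
        return float(np.mean(p < threshold))


def group_contrast(
    n_replicates: int = 100,
    n_per_group: int = 13,
    seed: int = 0,
    n_stimuli: int = 500,
) -> ContrastResult:
    """Replicate the two-group comparison on simulated cohorts drawn from the
    SCI-like and healthy-like presets; returns the per-replicate p-values for
    motor unit count, maximum CMAP and D50."""
    mune_p, cmap_p, d50_p = [], [], []
    for rep in range(n_replicates):
        table, _ = generate_cohort(
            HEALTHY_GROUP, SCI_GROUP, n_per_group=n_per_group,
            seed=seed + rep, n_stimuli=n_stimuli,
        )
        g1, g2 = table.groups[0], table.groups[1]
        for var, store in (("mune", mune_p), ("cmap_mV", cmap_p), ("d50", d50_p)):
            cmp_ = compare_groups(table.column(var, g1), table.column(var, g2),
                                  variable=var)
            store.append(cmp_.p_value)
    return ContrastResult(np.asarray(mune_p), np.asarray(cmap_p),
                          np.asarray(d50_p), n_replicates)
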