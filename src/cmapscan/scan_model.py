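"""Generative model of motor-unit pools and the CMAP scan protocol.

A muscle's compound response to nerve stimulation is modelled as a pool of
motor units.  Each unit is all-or-none: at stimulus intensity I (mA) it fires
with probability Phi((I - mu) / (rs * mu)), where mu is its mean activation
threshold and rs the relative spread (threshold SD as a fraction of the mean)
— the standard threshold-tracking excitability convention.  The recorded
amplitude at each stimulus is the sum of the firing units' MUAP amplitudes
plus additive Gaussian baseline noise, floored at 0 mV.

The scan protocol mirrors clinical practice: a pre-scan search locates S0
(intensity first activating the lowest-threshold unit) and S100 (intensity at
which every unit is recruited), then 500 stimuli are delivered with intensity
declining linearly across the recruitment range.

Two study conditions are built in as group presets: a healthy-like pool
(~108 units, ~16.75 mV maximum CMAP, thresholds 4.5-16 mA) and an SCI-like
pool (~59 units, ~8 mV, thresholds 8.5-19.4 mA) in which surviving units may
be enlarged by collateral reinnervation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .cohort_stats import CohortTable
from .d50 import CMAPScan, compute_d50, max_cmap

__all__ = [
    "MotorUnit",
    "MotorUnitPool",
    "ScanProtocol",
    "DistributionSpec",
    "PoolSpec",
    "GroupSpec",
    "HEALTHY_GROUP",
    "SCI_GROUP",
    "generate_pool",
    "activation_probability",
    "simulate_scan",
    "prescan_search",
    "generate_cohort",
]


@dataclass(frozen=True)
class MotorUnit:
    """One motor unit: MUAP amplitude (mV), mean threshold (mA), relative spread."""

    muap_amplitude: float
    threshold_mean: float
    relative_spread: float = 0.025

    def __post_init__(self) -> None:
        if not self.muap_amplitude > 0:
            raise ValueError("muap_amplitude must be > 0 mV")
        if not self.threshold_mean > 0:
            raise ValueError("threshold_mean must be > 0 mA")
        if not 0 < self.relative_spread < 0.2:
            raise ValueError("relative_spread must lie in (0, 0.2)")

    @property
    def threshold_sd(self) -> float:
        """Threshold standard deviation in mA."""
        return self.relative_spread * self.threshold_mean


@dataclass(frozen=True)
class MotorUnitPool:
    """An ordered collection of motor units plus per-stimulus noise SD (mV)."""

    units: tuple
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        units = tuple(self.units)
        if len(units) < 1:
            raise ValueError("a pool needs at least one motor unit")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "units", units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([u.muap_amplitude for u in self.units])

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([u.threshold_mean for u in self.units])

    @property
    def threshold_sds(self) -> np.ndarray:
        return np.array([u.threshold_sd for u in self.units])

    @property
    def max_expected_cmap(self) -> float:
        """Sum of all MUAP amplitudes: the noise-free maximum CMAP (mV)."""
        return float(self.amplitudes.sum())


@dataclass(frozen=True)
class ScanProtocol:
    """CMAP scan stimulation protocol.

    500 stimuli with intensity declining linearly from ``start_intensity`` to
    ``end_intensity``; pulse duration (0.1 ms) and rate (2 Hz) are carried as
    metadata only (the amplitude model has no time axis).
    """

    start_intensity: float
    end_intensity: float
    n_stimuli: int = 500
    pulse_duration_ms: float = 0.1
    stimulus_rate_hz: float = 2.0

    def __post_init__(self) -> None:
        if self.n_stimuli < 2:
            raise ValueError("n_stimuli must be >= 2")
        if not self.start_intensity > self.end_intensity:
            raise ValueError("intensity must decline: start_intensity > end_intensity")

    @property
    def intensities(self) -> np.ndarray:
        """Descending linear ramp of stimulus intensities (mA)."""
        return np.linspace(self.start_intensity, self.end_intensity, self.n_stimuli)

    @classmethod
    def from_prescan(
        cls,
        pool: MotorUnitPool,
        n_stimuli: int = 500,
        margin: float = 0.05,
        tolerance: float = 0.1,
    ) -> "ScanProtocol":
        """Protocol covering the pool's recruitment range [S0, S100] expanded
        by ``margin`` (fraction of the range) on each side."""
        s0, s100 = prescan_search(pool, tolerance=tolerance)
        pad = max((s100 - s0) * margin, tolerance)
        return cls(start_intensity=s100 + pad, end_intensity=max(s0 - pad, 0.0),
                   n_stimuli=n_stimuli)


@dataclass(frozen=True)
class DistributionSpec:
    """Named scalar distribution used for sampling unit parameters.

    Supported: ``point(value)``, ``uniform(low, high)``,
    ``normal(mean, sd)`` (truncated at > 0 by resampling),
    ``lognormal(mean, sigma)`` where ``mean`` is the distribution mean on the
    natural scale and ``sigma`` the log-scale SD.
    """

    name: str
    params: dict

    _REQUIRED = {
        "point": ("value",),
        "uniform": ("low", "high"),
        "normal": ("mean", "sd"),
        "lognormal": ("mean", "sigma"),
    }

    def __post_init__(self) -> None:
        if self.name not in self._REQUIRED:
            raise ValueError(f"unknown distribution {self.name!r}")
        missing = [k for k in self._REQUIRED[self.name] if k not in self.params]
        if missing:
            raise ValueError(f"{self.name} distribution missing parameters: {missing}")
        p = self.params
        if self.name == "point" and not p["value"] > 0:
            raise ValueError("point distribution: 'value' must be > 0")
        if self.name == "uniform" and not 0 < p["low"] <= p["high"]:
            raise ValueError("uniform distribution: need 0 < low <= high")
        if self.name == "normal" and not (p["mean"] > 0 and p["sd"] >= 0):
            raise ValueError("normal distribution: need mean > 0 and sd >= 0")
        if self.name == "lognormal" and not (p["mean"] > 0 and p["sigma"] >= 0):
            raise ValueError("lognormal distribution: need mean > 0 and sigma >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.name == "point":
            return np.full(n, float(p["value"]))
        if self.name == "uniform":
            return rng.uniform(p["low"], p["high"], n)
        if self.name == "normal":
            out = rng.normal(p["mean"], p["sd"], n)
            while (out <= 0).any():  # amplitude/threshold draws must stay positive
                bad = out <= 0
                out[bad] = rng.normal(p["mean"], p["sd"], int(bad.sum()))
            return out
        # lognormal parameterised by its natural-scale mean
        sigma = float(p["sigma"])
        mu = math.log(p["mean"]) - 0.5 * sigma**2
        return rng.lognormal(mu, sigma, n)


@dataclass(frozen=True)
class PoolSpec:
    """Recipe for sampling a motor-unit pool.

    ``reinnervation_factor`` (>= 1) multiplies all MUAP amplitudes, emulating
    collateral reinnervation after motor neuron loss.  If ``target_max_cmap``
    is set, amplitudes are finally rescaled so the pool's noise-free maximum
    CMAP equals it exactly.
    """

    n_units: int
    amplitude: DistributionSpec
    threshold: DistributionSpec
    relative_spread: float = 0.025
    reinnervation_factor: float = 1.0
    noise_sd: float = 0.03
    target_max_cmap: float | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.reinnervation_factor < 1:
            raise ValueError("reinnervation_factor must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.relative_spread < 0.2:
            raise ValueError("relative_spread must lie in (0, 0.2)")


def generate_pool(spec: PoolSpec, seed: int) -> MotorUnitPool:
    """Sample a motor-unit pool from ``spec``; identical (spec, seed) pairs
    produce identical pools."""
    rng = np.random.default_rng(seed)
    amps = spec.amplitude.sample(spec.n_units, rng) * spec.reinnervation_factor
    thrs = spec.threshold.sample(spec.n_units, rng)
    if spec.target_max_cmap is not None:
        amps *= spec.target_max_cmap / amps.sum()
    units = tuple(
        MotorUnit(float(a), float(t), spec.relative_spread)
        for a, t in zip(amps, thrs)
    )
    return MotorUnitPool(units=units, noise_sd=spec.noise_sd)


def activation_probability(unit: MotorUnit, intensity) -> np.ndarray | float:
    """Probability that ``unit`` fires at ``intensity`` (mA): the Gaussian CDF
    of (I - mu) / (rs * mu).  Equals 0.5 at the mean threshold and is
    nondecreasing in intensity."""
    intensity = np.asarray(intensity, dtype=float)
    if (intensity < 0).any():
        raise ValueError("intensity must be >= 0 mA")
    z = (intensity - unit.threshold_mean) / unit.threshold_sd
    out = ndtr(z)
    return float(out) if out.ndim == 0 else out


def _firing_probabilities(pool: MotorUnitPool, intensities: np.ndarray) -> np.ndarray:
    """(n_stimuli, n_units) matrix of activation probabilities."""
    z = (intensities[:, None] - pool.thresholds[None, :]) / pool.threshold_sds[None, :]
    return ndtr(z)


def expected_scan_amplitude(pool: MotorUnitPool, intensities) -> np.ndarray:
    """Noise-free expected amplitude at each intensity (mV)."""
    intensities = np.atleast_1d(np.asarray(intensities, dtype=float))
    return _firing_probabilities(pool, intensities) @ pool.amplitudes


def simulate_scan(pool: MotorUnitPool, protocol: ScanProtocol, seed: int) -> CMAPScan:
    """Simulate one CMAP scan.

    Per stimulus each unit fires independently with its activation
    probability; the amplitude is the summed MUAP contribution of the firing
    units plus Gaussian noise, floored at 0 mV.  Deterministic under
    (pool, protocol, seed).
    """
    intensities = protocol.intensities
    # recruitment range at the pre-scan probability cutoffs (5% / 95%)
    z = 1.6449  # Phi^-1(0.95)
    lo = float((pool.thresholds - z * pool.threshold_sds).min())
    hi = float((pool.thresholds + z * pool.threshold_sds).max())
    if intensities.max() < hi or intensities.min() > lo:
        warnings.warn(
            "scan protocol does not span the pool's recruitment range "
            f"[{lo:.2f}, {hi:.2f}] mA",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    p = _firing_probabilities(pool, intensities)
    firing = rng.random(p.shape) < p
    amplitude = firing @ pool.amplitudes
    if pool.noise_sd > 0:
        amplitude = amplitude + rng.normal(0.0, pool.noise_sd, amplitude.shape)
    return CMAPScan(
        stimulus_index=np.arange(1, protocol.n_stimuli + 1),
        intensity=intensities,
        amplitude=np.maximum(amplitude, 0.0),
    )


def prescan_search(
    pool: MotorUnitPool,
    tolerance: float = 0.1,
    p_low: float = 0.05,
    p_high: float = 0.95,
) -> tuple[float, float]:
    """Automatic pre-scan search for S0 and S100 (mA).

    S0 is the intensity at which the most excitable unit reaches activation
    probability ``p_low``; S100 the intensity at which every unit reaches
    ``p_high``.  Both are monotone in intensity and located by bisection to
    within ``tolerance``.
    """
    mus, sds = pool.thresholds, pool.threshold_sds

    def first_unit_prob(i: float) -> float:
        return float(ndtr((i - mus) / sds).max())

    def all_units_prob(i: float) -> float:
        return float(ndtr((i - mus) / sds).min())

    hi = float((mus + 10 * sds).max())

    def bisect(f, target):
        lo_i, hi_i = 0.0, hi
        while hi_i - lo_i > tolerance:
            mid = 0.5 * (lo_i + hi_i)
            if f(mid) < target:
                lo_i = mid
            else:
                hi_i = mid
        return 0.5 * (lo_i + hi_i)

    s0 = bisect(first_unit_prob, p_low)
    s100 = bisect(all_units_prob, p_high)
    return s0, max(s100, s0 + tolerance)


def s50_intensity(pool: MotorUnitPool, tolerance: float = 0.01) -> float:
    """Intensity at which the noise-free expected amplitude reaches 50% of
    the maximum CMAP (bisection)."""
    half = 0.5 * pool.max_expected_cmap
    lo, hi = 0.0, float((pool.thresholds + 10 * pool.threshold_sds).max())
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if expected_scan_amplitude(pool, mid)[0] < half:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class GroupSpec:
    """Population-level recipe for one study group.

    Per subject, a unit count and a target maximum CMAP are drawn from
    truncated normal distributions, thresholds from a uniform range, and MUAP
    amplitudes from a lognormal rescaled to the target CMAP — so a subject
    with few units but a normal CMAP has reinnervation-enlarged units.
    """

    label: str
    n_units_mean: float
    n_units_sd: float
    cmap_mean: float
    cmap_sd: float
    threshold_low: float
    threshold_high: float
    amplitude_sigma: float = 0.5
    relative_spread: float = 0.025
    noise_sd: float = 0.03
    min_units: int = 2
    min_cmap: float = 0.3

    def sample_pool_spec(self, rng: np.random.Generator) -> PoolSpec:
        n = max(self.min_units, int(round(rng.normal(self.n_units_mean, self.n_units_sd))))
        target = max(self.min_cmap, float(rng.normal(self.cmap_mean, self.cmap_sd)))
        return PoolSpec(
            n_units=n,
            amplitude=DistributionSpec("lognormal", {"mean": target / n, "sigma": self.amplitude_sigma}),
            threshold=DistributionSpec("uniform", {"low": self.threshold_low, "high": self.threshold_high}),
            relative_spread=self.relative_spread,
            noise_sd=self.noise_sd,
            target_max_cmap=target,
        )


# Group presets anchored to the published cohort summaries: unit counts
# 59 +/- 37 (SCI) vs 108 +/- 21 (control), maximum CMAP 8.01 +/- 3.97 vs
# 16.75 +/- 3.55 mV, recruitment ranges 8.5-19.4 vs 4.5-16.0 mA.
SCI_GROUP = GroupSpec(
    label="SCI", n_units_mean=59, n_units_sd=37, cmap_mean=8.01, cmap_sd=3.97,
    threshold_low=8.5, threshold_high=19.4,
)
HEALTHY_GROUP = GroupSpec(
    label="control", n_units_mean=108, n_units_sd=21, cmap_mean=16.75, cmap_sd=3.55,
    threshold_low=4.5, threshold_high=16.0,
)


def _sample_clinical(rng: np.random.Generator) -> dict:
    """Plausible clinical covariates for an SCI-like subject (means/SDs from
    the published cohort; durations are right-skewed so drawn lognormally)."""
    sigma = 0.85
    duration = rng.lognormal(math.log(9.5) - 0.5 * sigma**2, sigma)
    return {
        "gender": rng.choice(["M", "F"], p=[0.77, 0.23]),
        "hand": rng.choice(["R", "L"], p=[0.92, 0.08]),
        "level": rng.choice(["C1", "C3", "C4", "C5", "C6", "C7"]),
        "ais": rng.choice(["A", "B", "C", "D"]),
        "age": float(np.clip(rng.normal(43.4, 15.0), 18, 80)),
        "years_injury": float(duration),
        "grassp": float(np.clip(rng.normal(57.2, 36.2), 0, 116)),
        "grip_kg": float(max(rng.normal(8.3, 12.7), 0.0)),
        "pinch_kg": float(max(rng.normal(2.7, 3.5), 0.0)),
    }


def generate_cohort(
    healthy_spec: GroupSpec = HEALTHY_GROUP,
    sci_spec: GroupSpec = SCI_GROUP,
    n_per_group: int = 13,
    seed: int = 0,
    n_stimuli: int = 500,
) -> tuple[CohortTable, dict[str, CMAPScan]]:
    """Simulate a two-group study: per subject, sample a pool, run a scan,
    and tabulate group label, covariates, true unit count (``mune`` column),
    measured maximum CMAP and D50.  Deterministic under ``seed``."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    rows, scans = [], {}
    for gspec, prefix in ((sci_spec, "SCI"), (healthy_spec, "CTL")):
        for i in range(n_per_group):
            pool_spec = gspec.sample_pool_spec(rng)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            pool = generate_pool(pool_spec, seed=sub_seed)
            protocol = ScanProtocol.from_prescan(pool, n_stimuli=n_stimuli)
            scan = simulate_scan(pool, protocol, seed=sub_seed + 1)
            subject_id = f"{prefix}{i + 1:02d}"
            row = {
                "subject_id": subject_id,
                "group": gspec.label,
                "mune": pool.n_units,  # ground-truth count for synthetic subjects
                "cmap_mV": max_cmap(scan),
                "d50": compute_d50(scan),
            }
            if prefix == "SCI":
                row.update(_sample_clinical(rng))
            rows.append(row)
            scans[subject_id] = scan
    df = pd.DataFrame(rows)
    return CohortTable(df), scans
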