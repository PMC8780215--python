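"""Stimulus-response curve features of a CMAP scan.

A CMAP scan delivers ~500 electrical stimuli to a motor nerve with the
intensity declining linearly across the motor-unit recruitment range, and
records the compound muscle action potential (CMAP) amplitude evoked by each
stimulus.  This module holds the scan container and the curve features that
are read directly off it: the maximum CMAP amplitude, negative-peak amplitude
extraction from a raw waveform, and the D50 discontinuity index.

D50 is computed from the size-ranked amplitudes A (expressed as % of the
maximum CMAP), their consecutive differences dA, and the cumulative sums M of
the differences re-ranked largest first: D50 is the smallest n at which M_n
exceeds 50%.  Few, large discontinuities (few, enlarged motor units) give a
small D50; a smooth recruitment curve gives a large one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CMAPScan",
    "RankedDifferences",
    "D50UndefinedError",
    "negative_peak_amplitude",
    "max_cmap",
    "compute_d50",
]


class D50UndefinedError(ValueError):
    """Raised when D50 is undefined (e.g. a scan with zero maximum CMAP)."""


@dataclass(frozen=True)
class CMAPScan:
    """One CMAP scan: per-stimulus index, intensity (mA) and amplitude (mV).

    Records are kept in delivery order.  Negative amplitudes (measurement
    noise dipping below baseline) are floored at 0 mV on construction, since
    amplitudes are baseline-to-negative-peak magnitudes.
    """

    stimulus_index: np.ndarray
    intensity: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.stimulus_index, dtype=int)
        inten = np.asarray(self.intensity, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if not (idx.shape == inten.shape == amp.shape) or idx.ndim != 1:
            raise ValueError("stimulus_index, intensity and amplitude must be 1-D and equal length")
        if idx.size < 2:
            raise ValueError("a CMAP scan needs at least 2 records")
        if np.unique(idx).size != idx.size:
            raise ValueError("stimulus_index values must be unique")
        if not (np.isfinite(inten).all() and np.isfinite(amp).all()):
            raise ValueError("intensities and amplitudes must be finite")
        object.__setattr__(self, "stimulus_index", idx)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "amplitude", np.maximum(amp, 0.0))

    @property
    def n_stimuli(self) -> int:
        return self.stimulus_index.size

    @classmethod
    def from_amplitudes(cls, amplitude, intensity=None) -> "CMAPScan":
        """Build a scan from amplitudes alone (unit ramp of intensities)."""
        amplitude = np.asarray(amplitude, dtype=float)
        n = amplitude.size
        if intensity is None:
            intensity = np.linspace(float(n), 1.0, n)
        return cls(np.arange(1, n + 1), intensity, amplitude)


@dataclass(frozen=True)
class RankedDifferences:
    """The ranked-amplitude decomposition of a scan, on a % of max-CMAP scale.

    ranked_amplitudes
        A, the amplitudes sorted ascending, as percent of the maximum CMAP.
    consecutive_differences
        dA, the N-1 consecutive differences of A (all >= 0).
    cumulative_ranked_sums
        M, the cumulative sums of dA after re-ranking the differences from
        largest to smallest; M[-1] is 100% up to floating error whenever the
        smallest amplitude is 0.
    """

    ranked_amplitudes: np.ndarray
    consecutive_differences: np.ndarray
    cumulative_ranked_sums: np.ndarray

    @classmethod
    def from_scan(cls, scan: CMAPScan) -> "RankedDifferences":
        peak = float(scan.amplitude.max())
        if peak <= 0.0:
            raise D50UndefinedError("all amplitudes are zero; ranked differences undefined")
        a = np.sort(scan.amplitude) * (100.0 / peak)
        da = np.diff(a)
        # stable descending sort; ties are order-invariant in the cumsum
        m = np.cumsum(np.sort(da)[::-1])
        return cls(a, da, m)


def negative_peak_amplitude(waveform, baseline_window=slice(0, 10)) -> float:
    """Baseline-to-negative-peak amplitude of a sampled waveform.

    The amplitude is the mean of the baseline window minus the minimum sample
    (the negative peak, plotted negative-up in clinical convention), floored
    at 0 when the trace never dips below baseline.
    """
    trace = np.asarray(waveform, dtype=float)
    if trace.size == 0:
        raise ValueError("empty waveform")
    baseline = trace[baseline_window]
    if baseline.size == 0:
        raise ValueError("baseline window is outside the trace")
    return max(float(baseline.mean() - trace.min()), 0.0)


def max_cmap(scan: CMAPScan) -> float:
    """Maximum CMAP amplitude (mV) over all stimuli of the scan."""
    return float(scan.amplitude.max())


def compute_d50(scan: CMAPScan, threshold: float = 50.0, strict: bool = True) -> int:
    """D50 of a CMAP scan: how many of the largest consecutive differences
    among the size-ranked amplitudes are needed to accumulate 50% of the
    maximum CMAP.

    Parameters
    ----------
    scan
        The scan; its maximum amplitude must be positive.
    threshold
        Build-up threshold in percent of the maximum CMAP (default 50).
    strict
        If True (default), D50 is the smallest n with M_n strictly above the
        threshold; if False, reaching the threshold exactly counts.

    Returns
    -------
    int in [1, N-1].
    """
    ranked = RankedDifferences.from_scan(scan)
    m = ranked.cumulative_ranked_sums
    hit = m > threshold if strict else m >= threshold
    if not hit.any():
        # only possible when the smallest amplitude exceeds threshold% of max
        raise D50UndefinedError(
            f"cumulative ranked differences never exceed {threshold}% of the maximum CMAP"
        )
    return int(np.argmax(hit)) + 1
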