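"""Micro-movement spikes (MMS).

The MMS series standardizes a kinematic signal into unitless spike
amplitudes: each local peak V is normalized by the mean of its two flanking
local minima,

    Npeak = peakV / (peakV + mean(min_before, min_after)),

which lies in (0, 1] and cancels any uniform amplitude scale — the same
walk recorded on anatomically different bodies maps onto a common range.
The fluctuations of these amplitudes, and of the inter-peak interval
timings, feed every downstream analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: below this many peaks a gamma fit is reported missing, not attempted
MIN_PEAKS_FOR_GAMMA = 20


@dataclass
class PeakSet:
    """Peak indices with their flanking local-minima indices."""

    peak_indices: np.ndarray          # int, strictly increasing
    minima_before: np.ndarray         # int, same length
    minima_after: np.ndarray          # int, same length

    def __len__(self) -> int:
        return len(self.peak_indices)


@dataclass
class MMSSeries:
    """Normalized spike amplitudes with their timing.

    ``values`` holds one normalized amplitude per detected peak; uncentered
    values lie in (0, 1]. After :func:`gamma_center`, the MLE-fitted gamma
    mean (shape*scale) has been subtracted and the fit parameters retained.
    """

    values: np.ndarray
    peak_times_s: np.ndarray
    centered: bool = False
    source_unit: str = "unitless"
    gamma_shape: float | None = None
    gamma_scale: float | None = None
    node_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if len(self.values) != len(self.peak_times_s):
            raise ValueError("values and peak_times_s lengths differ")
        if len(self.peak_times_s) > 1 and np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if not self.centered and len(self.values):
            if np.any(self.values <= 0) or np.any(self.values > 1):
                raise ValueError("uncentered MMS values must lie in (0, 1]")

    @property
    def inter_peak_intervals_s(self) -> np.ndarray:
        return np.diff(self.peak_times_s)

    def __len__(self) -> int:
        return len(self.values)


def detect_peaks(signal: np.ndarray, rate_hz: float) -> PeakSet:
    """Find strict local maxima and their flanking local minima.

    A peak is a transition of the first difference from positive to
    negative. Plateaus take their first sample as the peak. Boundary
    samples are never peaks; a flanking minimum falling off the series
    uses the boundary sample itself.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < 3:
        raise ValueError("signal must have at least 3 samples")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")

    d = np.diff(x)
    # sign changes over nonzero steps: a rise-plateau-fall counts one peak,
    # placed at the first sample of the plateau
    nz = np.flatnonzero(d)
    if len(nz) < 2:
        return PeakSet(np.array([], int), np.array([], int), np.array([], int))
    s = np.sign(d[nz])
    peaks = nz[:-1][(s[:-1] > 0) & (s[1:] < 0)] + 1
    mins = nz[:-1][(s[:-1] < 0) & (s[1:] > 0)] + 1

    before = np.empty(len(peaks), dtype=int)
    after = np.empty(len(peaks), dtype=int)
    for k, p in enumerate(peaks):
        prev = mins[mins < p]
        nxt = mins[mins > p]
        before[k] = prev[-1] if len(prev) else 0
        after[k] = nxt[0] if len(nxt) else len(x) - 1
    return PeakSet(peak_indices=peaks, minima_before=before, minima_after=after)


def normalize_peaks(
    signal: np.ndarray,
    peaks: PeakSet,
    rate_hz: float,
    *,
    source_unit: str = "unitless",
    node_name: str = "",
) -> MMSSeries:
    """Normalize peak amplitudes into an uncentered :class:`MMSSeries`.

    Non-positive peaks are skipped with a warning. The normalization is
    scale invariant: multiplying the signal by any c > 0 leaves every
    output value unchanged. Values are reported at a fixed 1e-9 resolution
    (they live in (1/2, 1], so nine decimals keep full practical
    precision) so that the cancellation of the amplitude scale is exact
    rather than exact-up-to-rounding.
    """
    x = np.asarray(signal, dtype=float)
    values, times = [], []
    skipped = 0
    for p, mb, ma in zip(peaks.peak_indices, peaks.minima_before,
                         peaks.minima_after):
        peak_v = x[p]
        if peak_v <= 0:
            skipped += 1
            continue
        local_avg = 0.5 * (x[mb] + x[ma])
        values.append(round(peak_v / (peak_v + local_avg), 9))
        times.append(p / rate_hz)
    if skipped:
        logger.warning("skipped %d non-positive peak(s)", skipped)
    return MMSSeries(
        values=np.array(values),
        peak_times_s=np.array(times),
        source_unit=source_unit,
        node_name=node_name,
    )


def extract_mms(
    signal: np.ndarray,
    rate_hz: float,
    *,
    source_unit: str = "unitless",
    node_name: str = "",
) -> MMSSeries:
    """Convenience wrapper: detect peaks then normalize them."""
    peaks = detect_peaks(signal, rate_hz)
    return normalize_peaks(signal, peaks, rate_hz, source_unit=source_unit,
                           node_name=node_name)


def gamma_center(series: MMSSeries, *, min_peaks: int = MIN_PEAKS_FOR_GAMMA) -> MMSSeries:
    """Subtract the MLE gamma-fitted mean from an uncentered MMS series.

    The gamma family is fitted by maximum likelihood with location pinned
    at zero (MMS amplitudes are positive by construction); the subtracted
    mean is shape*scale and both parameters are retained on the result.
    """
    if series.centered:
        raise ValueError("series is already centered")
    n = len(series)
    if n < min_peaks:
        raise ValueError(
            f"need at least {min_peaks} peaks for a gamma fit, got {n}")
    vals = series.values
    if np.ptp(vals) == 0:
        raise ValueError(
            f"constant MMS series {series.node_name!r}: gamma fit undefined")
    try:
        shape, _, scale = stats.gamma.fit(vals, floc=0)
    except Exception as exc:  # pragma: no cover - scipy failure paths
        raise ValueError(
            f"gamma MLE failed for series {series.node_name!r}: {exc}") from exc
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise ValueError(
            f"gamma MLE did not converge for series {series.node_name!r}")
    return MMSSeries(
        values=vals - shape * scale,
        peak_times_s=series.peak_times_s,
        centered=True,
        source_unit=series.source_unit,
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        node_name=series.node_name,
    )


def inter_peak_intervals(series: MMSSeries) -> tuple[np.ndarray, dict[str, float]]:
    """Successive peak-time differences with mean/std summary."""
    if len(series) < 2:
        raise ValueError("need at least 2 peaks for intervals")
    iv = series.inter_peak_intervals_s
    return iv, {"mean_s": float(iv.mean()), "std_s": float(iv.std(ddof=1)) if len(iv) > 1 else 0.0}


def write_mms(series: MMSSeries, path: str | Path) -> None:
    """MMS as CSV plus a JSON sidecar holding the gamma fit parameters."""
    path = Path(path)
    iv = np.concatenate([[np.nan], series.inter_peak_intervals_s]) if len(series) else np.array([])
    df = pd.DataFrame({
        "peak_time_s": series.peak_times_s,
        "value": series.values,
        "interval_prev_s": iv,
    })
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "centered": series.centered,
        "source_unit": series.source_unit,
        "gamma_shape": series.gamma_shape,
        "gamma_scale": series.gamma_scale,
        "node_name": series.node_name,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
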