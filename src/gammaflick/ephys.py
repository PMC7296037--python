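"""Quantification of evoked fEPSP sweeps.

Covers the slice-electrophysiology readouts of CA3-CA1 synaptic
function: per-sweep slope/amplitude features, input-output (I/O) curves
with half-maximal stimulus intensity, the paired-pulse ratio (PPR, the
second response's slope over the first's, in percent), and long-term
potentiation (LTP) magnitude from baseline-normalized time courses.

Conventions
-----------
* The fEPSP slope is a least-squares line fit over the 20-80% span of
  the rising phase (configurable), signed by the deflection direction;
  amplitude is the baseline-to-peak magnitude.
* A 1 ms post-stimulus blanking interval excludes the stimulus artifact.
* At short inter-stimulus intervals the second response rides on the
  decay of the first; a single-exponential extrapolation of the first
  response's tail is subtracted before measuring the second.
* LTP time courses are normalized so the pre-tetanus baseline mean is
  100%; magnitude defaults to the mean over 45-60 min post-tetanus
  (the 0-60 min window is supported via ``measure_window``).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from typing import Sequence

import numpy as np

from .errors import FeatureNotFoundError, InvalidParameterError, ShapeError
from .spectral import Signal

__all__ = [
    "SweepRecord",
    "FEPSPFeatures",
    "IOCurve",
    "PPRMeasurement",
    "PPRResult",
    "LTPResult",
    "fepsp_features",
    "io_curve",
    "io_curve_from_means",
    "paired_pulse_ratio",
    "paired_pulse_curve",
    "ltp_timecourse",
]

DEFAULT_ISIS_MS = (20.0, 40.0, 60.0, 80.0, 100.0, 200.0)


@dataclasses.dataclass(frozen=True)
class SweepRecord:
    """One evoked sweep: trace, stimulus times, optional intensity."""

    trace: Signal
    stim_times: tuple[float, ...]
    intensity: float | None = None
    label: str = ""

    def __post_init__(self):
        st = tuple(float(t) for t in self.stim_times)
        if len(st) == 0:
            raise InvalidParameterError("sweep needs at least one stimulus time")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise InvalidParameterError("stim_times must be strictly increasing")
        t_end = self.trace.t0 + self.trace.duration_s
        if st[0] < self.trace.t0 or st[-1] >= t_end:
            raise InvalidParameterError("stim_times must lie inside the trace")
        object.__setattr__(self, "stim_times", st)


@dataclasses.dataclass(frozen=True)
class FEPSPFeatures:
    """Slope (units/ms, signed), amplitude (units) and latency (ms)."""

    slope: float
    amplitude: float
    latency_to_peak_ms: float


@dataclasses.dataclass(frozen=True)
class IOCurve:
    intensities: np.ndarray
    slopes: np.ndarray
    amplitudes: np.ndarray
    half_max_intensity: float
    flagged_nonmonotone: bool = False


@dataclasses.dataclass(frozen=True)
class PPRMeasurement:
    """Paired-pulse ratio from a single two-stimulus sweep."""

    isi_ms: float
    ppr_percent: float
    first: FEPSPFeatures
    second: FEPSPFeatures


@dataclasses.dataclass(frozen=True)
class PPRResult:
    """Mean PPR per inter-stimulus interval."""

    isis_ms: np.ndarray
    ppr_percent: np.ndarray
    n_sweeps: np.ndarray


@dataclasses.dataclass(frozen=True)
class LTPResult:
    times_min: np.ndarray
    timecourse_percent: np.ndarray
    baseline_window_min: tuple[float, float]
    measure_window_min: tuple[float, float]
    magnitude_percent: float


def _measure(
    sweep: SweepRecord,
    stim_index: int,
    slope_window: tuple[float, float],
    blank_ms: float,
    baseline_ms: float,
    response_ms: float,
    noise_mult: float,
):
    """Internal feature measurement returning indices for reuse."""
    lo_frac, hi_frac = slope_window
    if not (0 <= lo_frac < hi_frac <= 1):
        raise InvalidParameterError("slope_window fractions must satisfy 0<=lo<hi<=1")
    x = sweep.trace.samples
    fs = sweep.trace.fs
    t0 = sweep.trace.t0
    if stim_index < 0 or stim_index >= len(sweep.stim_times):
        raise InvalidParameterError(f"stim_index {stim_index} out of range")
    i_stim = int(round((sweep.stim_times[stim_index] - t0) * fs))
    i_blank = i_stim + max(1, int(round(blank_ms * 1e-3 * fs)))
    i_base0 = max(0, i_stim - int(round(baseline_ms * 1e-3 * fs)))
    if i_stim - i_base0 < 2:
        raise InvalidParameterError("no pre-stimulus baseline window available")
    baseline = float(np.mean(x[i_base0:i_stim]))
    noise_sd = float(np.std(x[i_base0:i_stim]))
    if stim_index + 1 < len(sweep.stim_times):
        i_end = int(round((sweep.stim_times[stim_index + 1] - t0) * fs))
    else:
        i_end = min(x.size, i_stim + int(round(response_ms * 1e-3 * fs)))
    if i_end - i_blank < 3:
        raise InvalidParameterError("response window too short")
    d = x[i_blank:i_end] - baseline
    ipk = int(np.argmax(np.abs(d)))
    amp = float(np.abs(d[ipk]))
    if amp == 0 or amp <= noise_mult * noise_sd:
        raise FeatureNotFoundError(
            f"no deflection above {noise_mult}x baseline noise "
            f"(noise sd {noise_sd:.3g}) after stimulus {stim_index}"
        )
    sign = 1.0 if d[ipk] >= 0 else -1.0
    r = sign * d  # positive-deflection view
    lo_thr = lo_frac * amp
    hi_thr = hi_frac * amp
    below = np.flatnonzero(r[: ipk + 1] <= lo_thr)
    i20 = int(below[-1]) if below.size else 0
    above = np.flatnonzero(r[i20 : ipk + 1] >= hi_thr)
    i80 = i20 + int(above[0]) if above.size else ipk
    if i80 - i20 < 2:  # too few samples for a fit; widen minimally
        i20 = max(0, i20 - 1)
        i80 = min(ipk, i80 + 1)
    seg = slice(i_blank + i20, i_blank + i80 + 1)
    t_ms = np.arange(seg.start, seg.stop) / fs * 1e3
    slope = float(np.polyfit(t_ms, x[seg], 1)[0])
    feats = FEPSPFeatures(
        slope=slope,
        amplitude=amp,
        latency_to_peak_ms=(i_blank + ipk - i_stim) / fs * 1e3,
    )
    return feats, dict(
        i_stim=i_stim, i_blank=i_blank, i_peak=i_blank + ipk,
        baseline=baseline, sign=sign, amp=amp,
    )


def fepsp_features(
    sweep: SweepRecord,
    stim_index: int = 0,
    slope_window: tuple[float, float] = (0.2, 0.8),
    *,
    blank_ms: float = 1.0,
    baseline_ms: float = 5.0,
    response_ms: float = 50.0,
    noise_mult: float = 5.0,
) -> FEPSPFeatures:
    """Measure slope, amplitude and latency of one evoked response.

    Amplitude is ``|peak - pre-stimulus baseline|``; the slope is the
    least-squares line over the ``slope_window`` fractional span of the
    rising phase, signed by the deflection direction.  Raises
    :class:`FeatureNotFoundError` when no deflection exceeds
    ``noise_mult`` times the baseline noise SD.
    """
    feats, _ = _measure(
        sweep, stim_index, slope_window, blank_ms, baseline_ms,
        response_ms, noise_mult,
    )
    return feats


def paired_pulse_ratio(
    sweep: SweepRecord,
    slope_window: tuple[float, float] = (0.2, 0.8),
    **feature_kwargs,
) -> PPRMeasurement:
    """Paired-pulse ratio of a two-stimulus sweep, in percent.

    ``ppr = 100 * slope_2 / slope_1``, where the second response is
    measured after subtracting a single-exponential extrapolation of
    the first response's decaying tail.
    """
    if len(sweep.stim_times) != 2:
        raise InvalidParameterError(
            f"paired-pulse sweep needs exactly 2 stimuli, got "
            f"{len(sweep.stim_times)}"
        )
    isi_ms = (sweep.stim_times[1] - sweep.stim_times[0]) * 1e3
    f1, info = _measure(
        sweep, 0, slope_window,
        feature_kwargs.get("blank_ms", 1.0),
        feature_kwargs.get("baseline_ms", 5.0),
        feature_kwargs.get("response_ms", 50.0),
        feature_kwargs.get("noise_mult", 5.0),
    )
    x = sweep.trace.samples
    fs = sweep.trace.fs
    i_stim2 = int(round((sweep.stim_times[1] - sweep.trace.t0) * fs))
    sign = info["sign"]
    base = info["baseline"]
    ipk = info["i_peak"]
    # fit exp decay on the tail between first peak and second stimulus
    corrected = x.copy()
    tail = slice(ipk + 2, i_stim2 - 1)
    y = sign * (x[tail] - base)
    good = y > 0.02 * info["amp"]
    if good.sum() >= 4:
        t = np.arange(tail.start, tail.stop)[good] / fs
        coef = np.polyfit(t, np.log(y[good]), 1)
        t2 = np.arange(i_stim2, x.size) / fs
        extrap = np.exp(coef[1] + coef[0] * t2)
        corrected[i_stim2:] -= sign * extrap
    sweep2 = SweepRecord(
        trace=Signal(corrected, fs, sweep.trace.t0),
        stim_times=sweep.stim_times,
        intensity=sweep.intensity,
        label=sweep.label,
    )
    f2 = fepsp_features(sweep2, 1, slope_window, **feature_kwargs)
    if abs(f1.slope) < 1e-300:
        raise ZeroDivisionError("first-pulse slope is zero; PPR undefined")
    return PPRMeasurement(
        isi_ms=isi_ms,
        ppr_percent=100.0 * f2.slope / f1.slope,
        first=f1,
        second=f2,
    )


def paired_pulse_curve(
    sweeps: Sequence[SweepRecord], **kwargs
) -> PPRResult:
    """Aggregate single-sweep PPR measurements by inter-stimulus interval."""
    by_isi: dict[float, list[float]] = defaultdict(list)
    for sw in sweeps:
        m = paired_pulse_ratio(sw, **kwargs)
        by_isi[round(m.isi_ms, 3)].append(m.ppr_percent)
    isis = np.array(sorted(by_isi))
    return PPRResult(
        isis_ms=isis,
        ppr_percent=np.array([np.mean(by_isi[i]) for i in isis]),
        n_sweeps=np.array([len(by_isi[i]) for i in isis]),
    )


def io_curve_from_means(
    intensities: Sequence[float],
    slopes: Sequence[float],
    amplitudes: Sequence[float] | None = None,
) -> IOCurve:
    """Build an I/O curve from per-intensity mean slopes.

    The half-maximal intensity is found by linear interpolation at the
    first crossing of 50% of the maximal mean ``|slope|``.  A curve
    that dips non-monotonically (beyond 5% of the maximum) is still
    interpolated at the first crossing but flagged.
    """
    i = np.asarray(intensities, float)
    s = np.asarray(slopes, float)
    if i.size < 3:
        raise InvalidParameterError("need at least 3 distinct intensities")
    if i.size != s.size:
        raise ShapeError("intensities and slopes must have equal length")
    order = np.argsort(i)
    i, s = i[order], s[order]
    if np.any(np.diff(i) <= 0):
        raise InvalidParameterError("intensities must be distinct")
    a = (
        np.asarray(amplitudes, float)[order]
        if amplitudes is not None
        else np.full_like(s, np.nan)
    )
    m = np.abs(s)
    target = 0.5 * m.max()
    flagged = bool(np.any(np.diff(m) < -0.05 * m.max()))
    if flagged:
        warnings.warn(
            "I/O curve is non-monotone beyond noise; interpolating at the "
            "first half-max crossing",
            stacklevel=2,
        )
    above = np.flatnonzero(m >= target)
    j = int(above[0])
    if j == 0:
        half = float(i[0])
    else:
        frac = (target - m[j - 1]) / (m[j] - m[j - 1])
        half = float(i[j - 1] + frac * (i[j] - i[j - 1]))
    return IOCurve(
        intensities=i, slopes=s, amplitudes=a,
        half_max_intensity=half, flagged_nonmonotone=flagged,
    )


def io_curve(sweeps: Sequence[SweepRecord], **feature_kwargs) -> IOCurve:
    """Input-output curve from sweeps grouped by stimulus intensity.

    Sweeps with no detectable response (sub-threshold intensities)
    contribute slope and amplitude 0.
    """
    by_int: dict[float, list[FEPSPFeatures]] = defaultdict(list)
    for sw in sweeps:
        if sw.intensity is None:
            raise InvalidParameterError("every sweep needs an intensity for an I/O curve")
        try:
            f = fepsp_features(sw, 0, **feature_kwargs)
        except FeatureNotFoundError:
            f = FEPSPFeatures(slope=0.0, amplitude=0.0, latency_to_peak_ms=np.nan)
        by_int[float(sw.intensity)].append(f)
    ints = sorted(by_int)
    slopes = [float(np.mean([f.slope for f in by_int[i]])) for i in ints]
    amps = [float(np.mean([f.amplitude for f in by_int[i]])) for i in ints]
    return io_curve_from_means(ints, slopes, amps)


def ltp_timecourse(
    sweeps: Sequence[SweepRecord],
    tetanus_time_min: float,
    baseline_window_min: tuple[float, float] | None = None,
    measure_window_min: tuple[float, float] = (45.0, 60.0),
    times_min: Sequence[float] | None = None,
    **feature_kwargs,
) -> LTPResult:
    """Baseline-normalized LTP time course and magnitude.

    Each sweep's slope is divided by the mean slope over the baseline
    window (default: the 30 min preceding the tetanus) and expressed in
    percent, so the baseline mean is 100% by construction.  The LTP
    magnitude is the mean normalized response over ``measure_window_min``
    (expressed relative to the tetanus; default 45-60 min post-tetanus,
    with (0, 60) supported as an alternative convention).
    """
    if not sweeps:
        raise InvalidParameterError("no sweeps supplied")
    if times_min is None:
        # one evoked response per 30 s
        times = np.arange(len(sweeps)) * 0.5
    else:
        times = np.asarray(times_min, float)
        if times.size != len(sweeps):
            raise ShapeError("times_min must match the number of sweeps")
    if baseline_window_min is None:
        baseline_window_min = (tetanus_time_min - 30.0, tetanus_time_min)
    b0, b1 = baseline_window_min
    if b1 > tetanus_time_min + 1e-9:
        raise InvalidParameterError("baseline window must precede the tetanus")
    m0, m1 = (
        tetanus_time_min + measure_window_min[0],
        tetanus_time_min + measure_window_min[1],
    )
    slopes = np.array(
        [fepsp_features(sw, 0, **feature_kwargs).slope for sw in sweeps]
    )
    base_mask = (times >= b0) & (times < b1)
    if not base_mask.any():
        raise InvalidParameterError("baseline window contains no sweeps")
    base_mean = slopes[base_mask].mean()
    if base_mean == 0:
        raise ZeroDivisionError("baseline mean slope is zero")
    norm = slopes / base_mean * 100.0
    meas_mask = (times >= m0) & (times <= m1)
    if not meas_mask.any():
        raise InvalidParameterError("measure window contains no sweeps")
    return LTPResult(
        times_min=times,
        timecourse_percent=norm,
        baseline_window_min=(b0, b1),
        measure_window_min=measure_window_min,
        magnitude_percent=float(norm[meas_mask].mean()),
    )
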