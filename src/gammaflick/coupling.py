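"""Theta-gamma phase-amplitude coupling (PAC).

The coupling strength between a slow oscillation's phase and a fast
oscillation's amplitude is quantified with the entropy-normalized
(Kullback-Leibler) modulation index: the instantaneous amplitude of the
fast band is binned by the instantaneous phase of the slow band, the
per-bin mean amplitudes are normalized to a distribution ``P``, and

    MI = KL(P || uniform) / log(n_bins)
       = (log(n_bins) + sum_j P_j log P_j) / log(n_bins)

which is 0 for a phase-independent amplitude and 1 when all amplitude
concentrates in a single phase bin.  Scanning MI over a grid of (phase
frequency, amplitude frequency) pairs yields the comodulogram.

Phase and amplitude series come from a zero-phase Butterworth band-pass
followed by the Hilbert transform (analytic signal); one second is
trimmed from each end before binning to discard filter edge effects.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .errors import BandRangeError, InvalidParameterError, ShapeError
from .spectral import THETA, FrequencyBand, Signal, filter_band

__all__ = [
    "AnalyticSignal",
    "PhaseAmplitudeDistribution",
    "ModulationIndexResult",
    "Comodulogram",
    "analytic_signal",
    "phase_amplitude_distribution",
    "modulation_index",
    "comodulogram",
    "surrogate_null",
]

#: Default edge trim (s) discarded from each end before phase binning.
DEFAULT_TRIM_S = 1.0
#: Default number of phase bins for the modulation index.
DEFAULT_N_BINS = 18


@dataclasses.dataclass(frozen=True)
class AnalyticSignal:
    """Instantaneous phase and amplitude of a band-limited signal."""

    phase: np.ndarray
    amplitude: np.ndarray
    band: FrequencyBand
    fs: float

    def __post_init__(self):
        if self.phase.shape != self.amplitude.shape:
            raise ShapeError("phase and amplitude must have equal length")

    @property
    def n_samples(self) -> int:
        return self.phase.size


@dataclasses.dataclass(frozen=True)
class PhaseAmplitudeDistribution:
    """Phase-binned mean-amplitude profile and its normalized form."""

    bin_edges: np.ndarray
    mean_amplitude: np.ndarray
    normalized: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.mean_amplitude.size


@dataclasses.dataclass(frozen=True)
class ModulationIndexResult:
    """Entropy-normalized modulation index for one frequency pair."""

    mi: float
    n_bins: int
    phase_band: FrequencyBand
    amp_band: FrequencyBand
    n_samples: int
    distribution: PhaseAmplitudeDistribution | None = None


@dataclasses.dataclass(frozen=True)
class Comodulogram:
    """MI over a grid of (phase frequency, amplitude frequency) pairs."""

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray
    phase_bandwidth: float
    amp_bandwidth: float

    def argmax(self) -> tuple[float, float]:
        """(phase center, amplitude center) of the strongest coupling."""
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


def analytic_signal(signal: Signal, band: FrequencyBand = THETA) -> AnalyticSignal:
    """Band-pass a signal and extract its analytic phase and amplitude.

    Zero-phase 4th-order Butterworth band-pass followed by the Hilbert
    transform; phase is the argument and amplitude the modulus of the
    analytic extension.  The theta default is the 4-12 Hz band.
    """
    nyq = signal.fs / 2
    if band.f_hi >= nyq:
        raise BandRangeError(
            f"band {band.name!r} upper edge {band.f_hi} Hz is at or above "
            f"Nyquist ({nyq} Hz)"
        )
    min_len = 10.0 / band.f_lo if band.f_lo > 0 else 0.0
    if signal.duration_s < min_len:
        raise InvalidParameterError(
            f"signal of {signal.duration_s:.3g} s is shorter than 10 cycles "
            f"of {band.f_lo} Hz ({min_len:.3g} s)"
        )
    filtered = filter_band(signal, band.f_lo, band.f_hi)
    analytic = hilbert(filtered.samples)
    return AnalyticSignal(
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        band=band,
        fs=signal.fs,
    )


def _trim(arr: np.ndarray, fs: float, trim_s: float) -> np.ndarray:
    n_trim = int(round(trim_s * fs))
    if n_trim > 0 and arr.size > 2 * n_trim + 10:
        return arr[n_trim:-n_trim]
    return arr


def phase_amplitude_distribution(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int, strict: bool = False
) -> PhaseAmplitudeDistribution:
    """Bin amplitude by phase and normalize the per-bin means.

    In lenient mode (default) empty phase bins are dropped with a
    warning and the distribution is renormalized over the occupied
    bins; in strict mode an empty bin raises.
    """
    if n_bins < 4:
        raise InvalidParameterError(f"n_bins must be >= 4, got {n_bins}")
    if phase.shape != amplitude.shape:
        raise ShapeError("phase and amplitude must have equal length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # map phase in (-pi, pi] to bin 0..n_bins-1
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    if not occupied.all():
        if strict:
            raise InvalidParameterError(
                f"{int((~occupied).sum())} empty phase bin(s) with n_bins={n_bins}"
            )
        warnings.warn(
            f"dropping {int((~occupied).sum())} empty phase bin(s); "
            f"distribution renormalized over {int(occupied.sum())} bins",
            stacklevel=2,
        )
    means = np.zeros(n_bins)
    means[occupied] = sums[occupied] / counts[occupied]
    total = means.sum()
    if total <= 0:
        raise InvalidParameterError("amplitude sums to zero; cannot normalize")
    return PhaseAmplitudeDistribution(
        bin_edges=edges,
        mean_amplitude=means,
        normalized=means / total,
    )


def modulation_index(
    phase: AnalyticSignal,
    amplitude: AnalyticSignal,
    n_bins: int = DEFAULT_N_BINS,
    *,
    trim_s: float = DEFAULT_TRIM_S,
    strict: bool = False,
) -> ModulationIndexResult:
    """Entropy-normalized modulation index between two analytic signals.

    ``phase`` contributes its instantaneous phase, ``amplitude`` its
    envelope.  The result is deterministic and bounded in [0, 1].
    """
    if phase.n_samples != amplitude.n_samples:
        raise ShapeError("phase and amplitude series must have equal length")
    ph = _trim(phase.phase, phase.fs, trim_s)
    am = _trim(amplitude.amplitude, amplitude.fs, trim_s)
    dist = phase_amplitude_distribution(ph, am, n_bins, strict=strict)
    p = dist.normalized[dist.normalized > 0]
    n_eff = int((dist.mean_amplitude > 0).sum()) or n_bins
    # KL(P || uniform over occupied bins) / log(n_eff)
    if n_eff <= 1:
        mi = 0.0
    else:
        mi = float((np.log(n_eff) + np.sum(p * np.log(p))) / np.log(n_eff))
        mi = min(max(mi, 0.0), 1.0)
    return ModulationIndexResult(
        mi=mi,
        n_bins=n_bins,
        phase_band=phase.band,
        amp_band=amplitude.band,
        n_samples=ph.size,
        distribution=dist,
    )


def _default_phase_freqs() -> np.ndarray:
    return np.arange(2.0, 12.0 + 1e-9, 1.0)


def _default_amp_freqs() -> np.ndarray:
    return np.arange(20.0, 120.0 + 1e-9, 5.0)


def comodulogram(
    signal: Signal,
    phase_freqs: Sequence[float] | None = None,
    amp_freqs: Sequence[float] | None = None,
    phase_bw: float = 2.0,
    amp_bw: float = 20.0,
    n_bins: int = DEFAULT_N_BINS,
    *,
    trim_s: float = DEFAULT_TRIM_S,
) -> Comodulogram:
    """Scan MI over a grid of (phase, amplitude) center frequencies.

    Each center frequency is analyzed in a band of the stated width
    around it.  Default grids: phase 2-12 Hz in 1 Hz steps with 2 Hz
    bandwidth (covering the 4-12 Hz theta band), amplitude 20-120 Hz in
    5 Hz steps with 20 Hz bandwidth.
    """
    pf = np.asarray(
        _default_phase_freqs() if phase_freqs is None else phase_freqs, float
    )
    af = np.asarray(_default_amp_freqs() if amp_freqs is None else amp_freqs, float)
    if pf.size == 0 or af.size == 0:
        raise InvalidParameterError("frequency grids must be nonempty")
    phases = []
    for fc in pf:
        band = FrequencyBand(f"phase_{fc:g}", max(fc - phase_bw / 2, 0.1), fc + phase_bw / 2)
        phases.append(analytic_signal(signal, band))
    amps = []
    for fc in af:
        band = FrequencyBand(f"amp_{fc:g}", max(fc - amp_bw / 2, 0.1), fc + amp_bw / 2)
        amps.append(analytic_signal(signal, band))
    mi = np.zeros((pf.size, af.size))
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            mi[i, j] = modulation_index(ph, am, n_bins, trim_s=trim_s).mi
    return Comodulogram(
        phase_freqs=pf, amp_freqs=af, mi=mi,
        phase_bandwidth=phase_bw, amp_bandwidth=amp_bw,
    )


def surrogate_null(
    phase: AnalyticSignal,
    amplitude: AnalyticSignal,
    n_surrogates: int = 200,
    seed: int = 0,
    *,
    min_shift_s: float = 1.0,
    n_bins: int = DEFAULT_N_BINS,
    trim_s: float = DEFAULT_TRIM_S,
) -> np.ndarray:
    """Null MI distribution from circular time-shifts of the amplitude.

    Each surrogate circularly shifts the amplitude series by a uniform
    random offset of at least ``min_shift_s`` seconds before recomputing
    MI, destroying phase-amplitude alignment while preserving both
    marginals.  The edge trim is applied *before* shifting so filter
    startup transients never rotate into the interior of a surrogate
    (which would bias the null upward).  Seeded and reproducible.
    """
    if n_surrogates < 1:
        raise InvalidParameterError("n_surrogates must be >= 1")
    if phase.n_samples != amplitude.n_samples:
        raise ShapeError("phase and amplitude series must have equal length")
    ph = _trim(phase.phase, phase.fs, trim_s)
    am = _trim(amplitude.amplitude, amplitude.fs, trim_s)
    n = am.size
    min_shift = int(round(min_shift_s * amplitude.fs))
    if n <= 2 * min_shift:
        raise InvalidParameterError(
            f"signal of {n} usable samples is too short for circular shifts "
            f"of >= {min_shift} samples"
        )
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    out = np.empty(n_surrogates)
    for i, s in enumerate(shifts):
        dist = phase_amplitude_distribution(ph, np.roll(am, int(s)), n_bins)
        p = dist.normalized[dist.normalized > 0]
        n_eff = int((dist.mean_amplitude > 0).sum()) or n_bins
        out[i] = (
            0.0
            if n_eff <= 1
            else float((np.log(n_eff) + np.sum(p * np.log(p))) / np.log(n_eff))
        )
    return out
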