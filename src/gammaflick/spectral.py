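"""Multitaper spectral estimation for local field potentials.

This module implements the spectral half of the LFP analysis chain:
discrete prolate spheroidal (Slepian) tapers, the multitaper power
spectral density, band-limited power, artifact-aware epoch selection,
short-time (Hann) spectrograms and perievent spectrograms, and the
band-power ratio statistic used to compare behavioral states.

The multitaper estimator averages ``K`` direct spectral estimates, each
computed with one member of an orthonormal Slepian taper family with
time-half-bandwidth product ``NW``.  With ``K = 2*NW - 1`` tapers the
estimate trades a controlled amount of spectral smoothing (half-width
``W = NW / N`` cycles/sample) for a ``1/K`` reduction in variance
relative to the raw periodogram.

Two output conventions are provided:

``mode="density"``
    One-sided power spectral density in units**2/Hz.  Each taper ``u``
    has unit energy, so ``|FFT(u * x)|**2 / fs`` integrates (over the
    one-sided grid, with interior bins doubled) to the signal variance;
    this is the convention under which Parseval's identity holds and is
    the default.
``mode="raw"``
    The bare taper-averaged quantity ``mean_k |(1/N) sum_n
    exp(2*pi*i*f*n) * u_n^k * x_n|**2`` with no one-sided doubling,
    matching the arbitrary-unit spectra produced by common
    electrophysiology packages.

Both conventions differ only by the constant factor ``2 * N**2 / fs``
on interior bins, so peak locations, band ratios and any normalized
statistic are identical between them.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

from .errors import (
    BandRangeError,
    InsufficientEpochsError,
    InvalidParameterError,
    ShapeError,
)

__all__ = [
    "Signal",
    "TaperSet",
    "FrequencyBand",
    "PSDEstimate",
    "Spectrogram",
    "EpochSet",
    "THETA",
    "LOW_GAMMA",
    "HIGH_GAMMA",
    "BANDS",
    "make_slepian_tapers",
    "multitaper_psd",
    "epoch_average_psd",
    "band_power",
    "select_epochs",
    "spectrogram",
    "perievent_spectrogram",
    "psd_band_ratio",
    "filter_band",
]


@dataclasses.dataclass(frozen=True)
class Signal:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage series (arbitrary units; microvolts nominal for LFP).
    fs : float
        Sampling rate in Hz.  LFP recordings default to 1000 Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ShapeError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 2:
            raise InvalidParameterError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("signal contains non-finite values")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclasses.dataclass(frozen=True)
class TaperSet:
    """An orthonormal family of Slepian (DPSS) tapers.

    ``tapers`` has shape ``(K, n_samples)``; rows are ordered by
    decreasing in-band spectral concentration and each has unit
    Euclidean norm.
    """

    n_samples: int
    time_half_bandwidth: float
    tapers: np.ndarray

    @property
    def k(self) -> int:
        return self.tapers.shape[0]

    @property
    def half_bandwidth_cycles(self) -> float:
        """Concentration half-width ``W = NW / N`` in cycles per sample."""
        return self.time_half_bandwidth / self.n_samples


@dataclasses.dataclass(frozen=True)
class FrequencyBand:
    """A named frequency interval ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 <= self.f_lo < self.f_hi):
            raise InvalidParameterError(
                f"band {self.name!r} requires 0 <= f_lo < f_hi, "
                f"got ({self.f_lo}, {self.f_hi})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


#: Hippocampal theta band.
THETA = FrequencyBand("theta", 4.0, 12.0)
#: Hippocampal low (slow) gamma band.
LOW_GAMMA = FrequencyBand("low_gamma", 30.0, 50.0)
#: Hippocampal high (fast) gamma band.
HIGH_GAMMA = FrequencyBand("high_gamma", 80.0, 120.0)

BANDS = {b.name: b for b in (THETA, LOW_GAMMA, HIGH_GAMMA)}


@dataclasses.dataclass(frozen=True)
class PSDEstimate:
    """Power spectral density on a one-sided frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    n_tapers: int
    n_samples: int
    fs: float
    mode: str = "density"


@dataclasses.dataclass(frozen=True)
class Spectrogram:
    """Short-time power estimates on a time-frequency grid.

    ``power`` is a (time, frequency) matrix; ``times`` are window
    centers and advance by ``shift_s``.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    shift_s: float
    window_fn: str = "hann"
    n_events: int | None = None
    n_skipped: int | None = None


@dataclasses.dataclass(frozen=True)
class EpochSet:
    """A seeded random sample of fixed-length artifact-free signal windows."""

    epochs: list[Signal]
    epoch_s: float
    indices: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.epochs)


def make_slepian_tapers(
    n_samples: int, time_half_bandwidth: float, k: int | None = None
) -> TaperSet:
    """Construct ``k`` discrete prolate spheroidal sequences.

    Parameters
    ----------
    n_samples : int
        Taper length; must be at least 8.
    time_half_bandwidth : float
        The product ``NW``; the concentration half-width is
        ``W = NW / n_samples`` cycles per sample.
    k : int, optional
        Number of tapers.  Defaults to ``2 * NW - 1``, the number of
        sequences with near-unity concentration.

    Returns
    -------
    TaperSet
        Unit-norm, mutually orthogonal tapers ordered by decreasing
        spectral concentration.
    """
    if n_samples < 8:
        raise InvalidParameterError(f"n_samples must be >= 8, got {n_samples}")
    if time_half_bandwidth < 1:
        raise InvalidParameterError(
            f"time_half_bandwidth must be >= 1, got {time_half_bandwidth}"
        )
    k_max = int(round(2 * time_half_bandwidth - 1))
    if k is None:
        k = k_max
    if not (1 <= k <= k_max):
        raise InvalidParameterError(
            f"k must lie in [1, 2*NW-1] = [1, {k_max}], got {k}"
        )
    # sym=True keeps the sequences exactly orthogonal (the asymmetric
    # variant truncates an (N+1)-point solution and loses orthogonality)
    tapers = sps.windows.dpss(
        n_samples, time_half_bandwidth, Kmax=k, sym=True, norm=2
    )
    tapers = np.atleast_2d(tapers)
    # dpss already returns unit-energy rows; renormalize to be exact.
    tapers = tapers / np.linalg.norm(tapers, axis=1, keepdims=True)
    return TaperSet(
        n_samples=int(n_samples),
        time_half_bandwidth=float(time_half_bandwidth),
        tapers=tapers,
    )


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def multitaper_psd(
    signal: Signal,
    taper_set: TaperSet | None = None,
    *,
    nw: float = 3.0,
    k: int | None = None,
    nfft: int | None = None,
    mode: str = "density",
    detrend: str | None = "constant",
    allow_segmented: bool = False,
) -> PSDEstimate:
    """Multitaper power spectral density of a signal.

    Each taper's direct spectral estimate is computed by FFT of the
    taper-weighted signal on a zero-padded grid (next power of two by
    default, giving <= 0.5 Hz resolution on 2-s, 1 kHz epochs) and the
    ``K`` estimates are averaged.  See the module docstring for the two
    output conventions (``mode``).

    If ``taper_set`` is shorter than the signal and ``allow_segmented``
    is true, the signal is cut into consecutive non-overlapping segments
    of the taper length and the per-segment estimates are averaged;
    otherwise a length mismatch raises :class:`ShapeError`.
    """
    if mode not in ("density", "raw"):
        raise InvalidParameterError(f"mode must be 'density' or 'raw', got {mode!r}")
    if taper_set is None:
        taper_set = make_slepian_tapers(signal.n_samples, nw, k)
    n = taper_set.n_samples
    if signal.n_samples != n:
        if allow_segmented and signal.n_samples > n:
            n_seg = signal.n_samples // n
            parts = []
            for i in range(n_seg):
                seg = Signal(
                    signal.samples[i * n : (i + 1) * n], signal.fs,
                    signal.t0 + i * n / signal.fs,
                )
                parts.append(
                    multitaper_psd(
                        seg, taper_set, nfft=nfft, mode=mode, detrend=detrend
                    )
                )
            power = np.mean([p.power for p in parts], axis=0)
            ref = parts[0]
            return PSDEstimate(
                freqs=ref.freqs, power=power, n_tapers=taper_set.k,
                n_samples=signal.n_samples, fs=signal.fs, mode=mode,
            )
        raise ShapeError(
            f"taper length {n} does not match signal length "
            f"{signal.n_samples}; pass allow_segmented=True to average "
            "over consecutive segments"
        )
    x = signal.samples
    if detrend == "constant":
        x = x - x.mean()
    elif detrend is not None:
        raise InvalidParameterError(f"unknown detrend {detrend!r}")
    if nfft is None:
        nfft = _next_pow2(n)
    if nfft < n:
        raise InvalidParameterError(f"nfft={nfft} is smaller than n_samples={n}")
    spec = rfft(taper_set.tapers * x[np.newaxis, :], n=nfft, axis=-1)
    p = (spec.real**2 + spec.imag**2)
    if mode == "density":
        p = p / signal.fs
        # one-sided: double interior bins (not DC; not Nyquist when nfft even)
        hi = p.shape[-1] - 1 if nfft % 2 == 0 else p.shape[-1]
        p[..., 1:hi] *= 2.0
    else:  # raw: |(1/N) sum exp(2 pi i f n) u_n x_n|^2 averaged over tapers
        p = p / float(n) ** 2
    freqs = rfftfreq(nfft, 1.0 / signal.fs)
    return PSDEstimate(
        freqs=freqs, power=p.mean(axis=0), n_tapers=taper_set.k,
        n_samples=n, fs=signal.fs, mode=mode,
    )


def epoch_average_psd(
    epochs: EpochSet | Sequence[Signal],
    *,
    nw: float = 3.0,
    k: int | None = None,
    nfft: int | None = None,
    mode: str = "density",
) -> PSDEstimate:
    """Average the multitaper PSD over equal-length epochs."""
    sigs = epochs.epochs if isinstance(epochs, EpochSet) else list(epochs)
    if not sigs:
        raise InvalidParameterError("no epochs to average")
    n = sigs[0].n_samples
    if any(s.n_samples != n for s in sigs):
        raise ShapeError("epochs must all have the same length")
    tapers = make_slepian_tapers(n, nw, k)
    ests = [multitaper_psd(s, tapers, nfft=nfft, mode=mode) for s in sigs]
    return PSDEstimate(
        freqs=ests[0].freqs,
        power=np.mean([e.power for e in ests], axis=0),
        n_tapers=tapers.k,
        n_samples=n,
        fs=sigs[0].fs,
        mode=mode,
    )


def band_power(psd: PSDEstimate, band: FrequencyBand) -> float:
    """Integrate spectral density over a band by the trapezoid rule.

    The integrand is evaluated on the PSD grid points strictly inside
    ``[f_lo, f_hi]`` plus linearly interpolated values at the exact band
    edges, so a flat density ``c`` yields exactly ``c * band.width``.
    """
    f = psd.freqs
    if band.f_lo < f[0] - 1e-9 or band.f_hi > f[-1] + 1e-9:
        raise BandRangeError(
            f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) lies outside "
            f"the PSD grid [{f[0]}, {f[-1]}] Hz"
        )
    inside = (f > band.f_lo) & (f < band.f_hi)
    grid = np.concatenate(([band.f_lo], f[inside], [band.f_hi]))
    vals = np.interp(grid, f, psd.power)
    return float(np.trapezoid(vals, grid))


def select_epochs(
    signal: Signal,
    n_epochs: int = 10,
    epoch_s: float = 2.0,
    artifact_z: float = 6.0,
    seed: int = 0,
    candidate_step: int | None = None,
) -> EpochSet:
    """Randomly select non-overlapping artifact-free epochs.

    A window qualifies when the peak absolute robust z-score of its
    samples (median / 1.4826*MAD of the whole recording) stays below
    ``artifact_z``.  Candidate window starts are drawn without
    replacement in a seeded random order and accepted greedily subject
    to non-overlap, so the selection is deterministic for a fixed seed.

    Raises
    ------
    InsufficientEpochsError
        When fewer than ``n_epochs`` clean non-overlapping windows can
        be placed; the count actually available is attached.
    """
    if n_epochs < 1:
        raise InvalidParameterError("n_epochs must be >= 1")
    x = signal.samples
    n_len = int(round(epoch_s * signal.fs))
    if n_len < 2:
        raise InvalidParameterError("epoch_s too short for this sampling rate")
    if n_len > x.size:
        raise InvalidParameterError("epoch_s exceeds the recording duration")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = x.std() or 1.0
    bad = (np.abs(x - med) / scale) >= artifact_z
    bad_csum = np.concatenate(([0], np.cumsum(bad)))

    step = candidate_step if candidate_step is not None else max(1, n_len // 4)
    starts = np.arange(0, x.size - n_len + 1, step)
    clean = (bad_csum[starts + n_len] - bad_csum[starts]) == 0

    rng = np.random.default_rng(seed)
    order = rng.permutation(starts.size)
    chosen: list[int] = []
    for idx in order:
        if not clean[idx]:
            continue
        s = int(starts[idx])
        if any(s < c + n_len and c < s + n_len for c in chosen):
            continue
        chosen.append(s)
        if len(chosen) == n_epochs:
            break
    if len(chosen) < n_epochs:
        raise InsufficientEpochsError(requested=n_epochs, available=len(chosen))
    chosen.sort()
    epochs = [
        Signal(x[s : s + n_len], signal.fs, signal.t0 + s / signal.fs)
        for s in chosen
    ]
    return EpochSet(
        epochs=epochs, epoch_s=epoch_s, indices=np.asarray(chosen), seed=seed
    )


def spectrogram(
    signal: Signal,
    window_s: float = 1.0,
    shift_s: float = 0.1,
    f_max: float = 120.0,
) -> Spectrogram:
    """Single-taper Hann-windowed short-time power spectrogram.

    Overlapping windows of ``window_s`` seconds advance by ``shift_s``
    seconds; frequencies are clipped to ``[0, f_max]`` (120 Hz default,
    matching the 0-120 Hz digital filtering convention of the LFP
    workflow).  Times are window centers.
    """
    if not (window_s >= shift_s > 0):
        raise InvalidParameterError("need window_s >= shift_s > 0")
    nperseg = int(round(window_s * signal.fs))
    nshift = int(round(shift_s * signal.fs))
    if nshift < 1:
        raise InvalidParameterError("shift_s too small for this sampling rate")
    if nperseg > signal.n_samples:
        raise ShapeError(
            f"window of {nperseg} samples exceeds signal length "
            f"{signal.n_samples}"
        )
    freqs, times, sxx = sps.spectrogram(
        signal.samples,
        fs=signal.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - nshift,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    keep = freqs <= f_max + 1e-9
    return Spectrogram(
        times=times + signal.t0,
        freqs=freqs[keep],
        power=sxx[keep].T.copy(),
        window_s=window_s,
        shift_s=shift_s,
        window_fn="hann",
    )


def perievent_spectrogram(
    signal: Signal,
    event_times: Sequence[float],
    pre_s: float,
    post_s: float,
    window_s: float = 0.5,
    shift_s: float = 0.1,
    f_max: float = 120.0,
) -> Spectrogram:
    """Event-aligned average spectrogram.

    A spectrogram is computed on the slice ``[event - pre_s, event +
    post_s]`` around each event, the time axis is re-referenced to the
    event (negative = pre-event), and the power matrices are averaged.
    Events whose slice extends beyond the recording are skipped with a
    warning; the counts are recorded on the result.
    """
    if pre_s < 0 or post_s <= 0:
        raise InvalidParameterError("need pre_s >= 0 and post_s > 0")
    n = signal.n_samples
    acc = None
    used = 0
    skipped = 0
    template: Spectrogram | None = None
    for ev in event_times:
        i0 = int(round((ev - pre_s - signal.t0) * signal.fs))
        i1 = int(round((ev + post_s - signal.t0) * signal.fs))
        if i0 < 0 or i1 > n:
            skipped += 1
            continue
        sub = Signal(signal.samples[i0:i1], signal.fs, t0=-pre_s)
        sg = spectrogram(sub, window_s=window_s, shift_s=shift_s, f_max=f_max)
        if acc is None:
            acc = sg.power.copy()
            template = sg
        else:
            acc += sg.power
        used += 1
    if used == 0:
        raise InvalidParameterError(
            "no event has full perievent support inside the recording"
        )
    if skipped:
        warnings.warn(
            f"perievent_spectrogram skipped {skipped} event(s) too close to "
            "a recording edge",
            stacklevel=2,
        )
    assert template is not None
    return Spectrogram(
        times=template.times,
        freqs=template.freqs,
        power=acc / used,
        window_s=window_s,
        shift_s=shift_s,
        window_fn="hann",
        n_events=used,
        n_skipped=skipped,
    )


def psd_band_ratio(
    psd_num: PSDEstimate, psd_den: PSDEstimate, band: FrequencyBand
) -> float:
    """Ratio of band power between two PSDs on identical grids.

    This is the exploration/approach statistic: the band power of the
    numerator state divided by that of the denominator state.
    """
    if psd_num.freqs.shape != psd_den.freqs.shape or not np.allclose(
        psd_num.freqs, psd_den.freqs
    ):
        raise ShapeError("PSD frequency grids differ; recompute on a common grid")
    num = band_power(psd_num, band)
    den = band_power(psd_den, band)
    if den == 0:
        raise ZeroDivisionError(
            f"denominator band power is zero in band {band.name!r} "
            f"({band.f_lo}-{band.f_hi} Hz)"
        )
    return num / den


def filter_band(
    signal: Signal, f_lo: float | None, f_hi: float | None, order: int = 4
) -> Signal:
    """Zero-phase Butterworth band-pass (forward-backward) of a signal.

    Emulates acquisition-side analog band-limiting (e.g. 0.5-300 Hz) and
    digital low-pass conventions (0-120 Hz).  Pass ``None`` for an open
    edge to get a pure low-pass or high-pass.
    """
    nyq = signal.fs / 2
    if f_hi is not None and f_hi >= nyq:
        raise BandRangeError(f"f_hi={f_hi} must be below Nyquist ({nyq} Hz)")
    if f_lo is not None and f_lo <= 0:
        f_lo = None
    if f_lo is None and f_hi is None:
        return signal
    if f_lo is None:
        sos = sps.butter(order, f_hi, btype="lowpass", fs=signal.fs, output="sos")
    elif f_hi is None:
        sos = sps.butter(order, f_lo, btype="highpass", fs=signal.fs, output="sos")
    else:
        sos = sps.butter(
            order, [f_lo, f_hi], btype="bandpass", fs=signal.fs, output="sos"
        )
    return Signal(sps.sosfiltfilt(sos, signal.samples), signal.fs, signal.t0)
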