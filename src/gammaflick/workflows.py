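"""Composite analyses used by the pipeline, tests and reproduction script.

Thin glue that chains the single-purpose operations of the other
modules into the session-level quantities of interest: per-band power
from randomly selected epochs, theta-gamma modulation indices, and the
exploration/approach band-power ratio.
"""

from __future__ import annotations

import numpy as np

from .coupling import analytic_signal, modulation_index
from .spectral import (
    BANDS,
    FrequencyBand,
    HIGH_GAMMA,
    LOW_GAMMA,
    PSDEstimate,
    Signal,
    THETA,
    epoch_average_psd,
    psd_band_ratio,
    select_epochs,
)
from .simulate import SessionSim

__all__ = [
    "session_band_powers",
    "session_modulation_indices",
    "labeled_epoch_psd",
    "session_psd_ratios",
    "analyze_session",
    "peak_prominence",
    "max_offband_prominence",
]


def session_band_powers(
    lfp: Signal,
    *,
    n_epochs: int = 10,
    epoch_s: float = 2.0,
    nw: float = 3.0,
    seed: int = 0,
) -> dict[str, float]:
    """Theta / low-gamma / high-gamma power from random clean epochs."""
    epochs = select_epochs(lfp, n_epochs=n_epochs, epoch_s=epoch_s, seed=seed)
    psd = epoch_average_psd(epochs, nw=nw)
    from .spectral import band_power

    return {name: band_power(psd, band) for name, band in BANDS.items()}


def session_modulation_indices(
    lfp: Signal, *, n_bins: int = 18
) -> dict[str, float]:
    """Theta-phase modulation index of the low- and high-gamma envelopes."""
    ph = analytic_signal(lfp, THETA)
    out = {}
    for name, band in (("low_gamma", LOW_GAMMA), ("high_gamma", HIGH_GAMMA)):
        am = analytic_signal(lfp, band)
        out[f"theta_{name}_mi"] = modulation_index(ph, am, n_bins).mi
    return out


def labeled_epoch_psd(
    session: SessionSim, label: str, *, nw: float = 3.0
) -> PSDEstimate:
    """Average multitaper PSD over all epochs carrying a behavioral label."""
    lfp = session.lfp
    sigs = []
    for tag, onset, dur in session.labels:
        if tag != label:
            continue
        i0 = int(round((onset - lfp.t0) * lfp.fs))
        i1 = i0 + int(round(dur * lfp.fs))
        if 0 <= i0 < i1 <= lfp.n_samples:
            sigs.append(Signal(lfp.samples[i0:i1], lfp.fs, onset))
    if not sigs:
        raise ValueError(f"session has no epochs labeled {label!r}")
    return epoch_average_psd(sigs, nw=nw)


def session_psd_ratios(session: SessionSim, *, nw: float = 3.0) -> dict[str, float]:
    """Exploration/approach band-power ratio per band (plus the 40 Hz sub-band)."""
    psd_exp = labeled_epoch_psd(session, "explore", nw=nw)
    psd_app = labeled_epoch_psd(session, "approach", nw=nw)
    bands = dict(BANDS)
    bands["gamma_40hz"] = FrequencyBand("gamma_40hz", 35.0, 45.0)
    return {
        f"{name}_ratio": psd_band_ratio(psd_exp, psd_app, band)
        for name, band in bands.items()
    }


def peak_prominence(
    psd: PSDEstimate, f0: float, *, half_hz: float = 10.0, notch_hz: float = 2.0
) -> float:
    """Spectral line prominence: density at ``f0`` over the local floor.

    The floor is the median density within ``f0 +- half_hz``, excluding
    the ``+- notch_hz`` neighborhood of the peak itself.  An entrained
    oscillation produces a prominence orders of magnitude above 1; a
    featureless spectrum stays near 1.
    """
    f, p = psd.freqs, psd.power
    pk = p[int(np.argmin(np.abs(f - f0)))]
    ring = (np.abs(f - f0) <= half_hz) & (np.abs(f - f0) > notch_hz)
    floor = np.median(p[ring])
    return float(pk / floor) if floor > 0 else np.inf


def max_offband_prominence(
    psd: PSDEstimate,
    lo_hz: float = 15.0,
    hi_hz: float = 100.0,
    exclude: tuple[tuple[float, float], ...] = ((28.0, 52.0), (88.0, 112.0)),
) -> float:
    """Largest line prominence outside the intrinsic oscillation bands.

    Used to ask whether a stimulus adds any dominant spectral line the
    ongoing rhythms do not already account for: the default exclusion
    zones blank the low-gamma carrier (and its theta sidebands) and the
    high-gamma component.
    """
    best = 0.0
    for f0 in np.arange(lo_hz, hi_hz + 0.5, 1.0):
        if any(a <= f0 <= b for a, b in exclude):
            continue
        best = max(best, peak_prominence(psd, f0))
    return best


def analyze_session(session: SessionSim, *, seed: int = 0) -> dict[str, float]:
    """All session-level readouts: band powers, MIs and (if labeled) ratios."""
    out: dict[str, float] = {}
    out.update(session_band_powers(session.lfp, seed=seed))
    out.update(session_modulation_indices(session.lfp))
    if session.labels:
        out.update(session_psd_ratios(session))
    return out
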