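"""Seeded synthetic-data generators for every analysis stage.

These generators stand in for in-vivo CA1 recordings, slice
electrophysiology and two-photon FM1-43 imaging.  Each one is a pure
function of its config plus seed (bit-reproducible) and returns, next
to the data, a ``truth`` dictionary holding the realized parameters so
that every downstream analysis output has a computable expectation —
the basis for the package's parameter-recovery tests.

Signal model for the LFP
------------------------
``x(t) = theta + low_gamma + high_gamma + pink noise [+ entrainment]``

* theta: sinusoid at ``theta_hz`` (default 8 Hz, inside the 4-12 Hz band);
* low gamma: carrier at ``low_gamma_hz`` (default 40 Hz) whose envelope
  follows the theta phase,
  ``env = gamma_amp * (1 - d + d * (1 + cos(theta_phase)) / 2)``
  with coupling depth ``d`` in [0, 1] — ``d = 0`` gives a constant
  envelope (no PAC), ``d = 1`` full-depth modulation;
* high gamma: constant-amplitude sinusoid at ``high_gamma_hz`` (100 Hz);
* noise: 1/f^a background of unit variance scaled by ``noise_amp``;
* entrainment: a sinusoid at the flicker frequency, or for the
  "arrhythmic" stimulus a jittered pulse train with matched mean rate.

The "2VO" condition preset multiplies the low-gamma amplitude and the
coupling depth by an attenuation factor (default 0.6 each), leaving
theta and high gamma untouched — the ischemia phenotype is a selective
low-gamma/PAC deficit.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from .errors import InvalidParameterError
from .ephys import DEFAULT_ISIS_MS, SweepRecord
from .fm143 import PunctumTrace
from .spectral import Signal

__all__ = [
    "LFPSimConfig",
    "SessionSim",
    "EphysSimConfig",
    "FMSimConfig",
    "simulate_lfp",
    "simulate_session",
    "simulate_fepsp_experiment",
    "simulate_fm143",
    "fepsp_kernel",
    "expected_ppr_percent",
]

#: Attenuation applied by the "2VO" preset to low-gamma amplitude.
TWO_VO_GAMMA_FACTOR = 0.6
#: Attenuation applied by the "2VO" preset to theta->low-gamma coupling depth.
TWO_VO_COUPLING_FACTOR = 0.6
#: Exploration-epoch low-gamma amplitude boost, by condition.
EXPLORE_BOOST = {"sham": 2.0, "2VO": 1.2}


@dataclasses.dataclass(frozen=True)
class LFPSimConfig:
    """Configuration of the synthetic CA1 LFP."""

    fs: float = 1000.0
    duration_s: float = 120.0
    theta_hz: float = 8.0
    low_gamma_hz: float = 40.0
    high_gamma_hz: float = 100.0
    theta_amp: float = 1.0
    gamma_amp: float = 0.5
    high_gamma_amp: float = 0.25
    coupling_depth: float = 0.8
    entrain_hz: float | str | None = None
    entrain_amp: float = 2.0
    arrhythmic_rate_hz: float = 40.0
    noise_exponent: float = 1.0
    noise_amp: float = 0.5
    condition: str = "sham"
    seed: int = 0

    def __post_init__(self):
        for name in ("theta_amp", "gamma_amp", "high_gamma_amp", "entrain_amp",
                     "noise_amp"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not (0 <= self.coupling_depth <= 1):
            raise InvalidParameterError("coupling_depth must lie in [0, 1]")
        if self.condition not in ("sham", "2VO"):
            raise InvalidParameterError(
                f"condition must be 'sham' or '2VO', got {self.condition!r}"
            )
        fmax = max(self.theta_hz, self.low_gamma_hz, self.high_gamma_hz)
        if isinstance(self.entrain_hz, (int, float)):
            fmax = max(fmax, float(self.entrain_hz))
        elif self.entrain_hz not in (None, "arrhythmic"):
            raise InvalidParameterError(
                "entrain_hz must be a frequency, 'arrhythmic', or None"
            )
        if self.fs <= 2 * fmax:
            raise InvalidParameterError(
                f"fs={self.fs} violates Nyquist for max component {fmax} Hz"
            )


@dataclasses.dataclass(frozen=True)
class SessionSim:
    """A simulated recording session plus its ground truth."""

    lfp: Signal
    event_times: dict[str, list[float]]
    labels: list[tuple[str, float, float]]
    truth: dict


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    y = irfft(spec * scale, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _arrhythmic_pulses(
    rng: np.random.Generator, n: int, fs: float, rate_hz: float, amp: float
) -> np.ndarray:
    """Jittered pulse train with mean rate ``rate_hz``.

    Inter-pulse intervals are uniform on [0.5, 1.5] / rate, so the mean
    rate matches the rhythmic stimulus but no spectral line forms.
    Each pulse is a raised-cosine bump of half a mean period.
    """
    duration = n / fs
    n_max = int(np.ceil(duration * rate_hz * 1.6)) + 2
    intervals = rng.uniform(0.5, 1.5, size=n_max) / rate_hz
    times = np.cumsum(intervals)
    times = times[times < duration - 1.0 / rate_hz]
    width = max(2, int(round(fs / (2 * rate_hz))))
    kernel = amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    out = np.zeros(n)
    for t in times:
        i = int(round(t * fs))
        j = min(n, i + width)
        out[i:j] += kernel[: j - i]
    return out


def _components(
    cfg: LFPSimConfig,
    rng: np.random.Generator,
    n: int,
) -> tuple[dict[str, np.ndarray], dict]:
    t = np.arange(n) / cfg.fs
    phases = rng.uniform(0, 2 * np.pi, size=4)
    if cfg.condition == "2VO":
        gamma_amp = cfg.gamma_amp * TWO_VO_GAMMA_FACTOR
        depth = cfg.coupling_depth * TWO_VO_COUPLING_FACTOR
    else:
        gamma_amp = cfg.gamma_amp
        depth = cfg.coupling_depth
    theta_phase = 2 * np.pi * cfg.theta_hz * t + phases[0]
    comps = {
        "theta": cfg.theta_amp * np.cos(theta_phase),
        "high_gamma": cfg.high_gamma_amp
        * np.cos(2 * np.pi * cfg.high_gamma_hz * t + phases[2]),
        "noise": cfg.noise_amp * _pink_noise(rng, n, cfg.fs, cfg.noise_exponent),
    }
    env = gamma_amp * (1.0 - depth + depth * (1.0 + np.cos(theta_phase)) / 2.0)
    comps["low_gamma_env"] = env
    comps["low_gamma_carrier"] = np.cos(
        2 * np.pi * cfg.low_gamma_hz * t + phases[1]
    )
    if cfg.entrain_hz is None:
        comps["entrain"] = np.zeros(n)
    elif cfg.entrain_hz == "arrhythmic":
        comps["entrain"] = _arrhythmic_pulses(
            rng, n, cfg.fs, cfg.arrhythmic_rate_hz, cfg.entrain_amp
        )
    else:
        comps["entrain"] = cfg.entrain_amp * np.sin(
            2 * np.pi * float(cfg.entrain_hz) * t + phases[3]
        )
    truth = {
        "theta_amp": cfg.theta_amp,
        "low_gamma_amp": gamma_amp,
        "high_gamma_amp": cfg.high_gamma_amp,
        "coupling_depth": depth,
        "noise_amp": cfg.noise_amp,
        "entrain_hz": cfg.entrain_hz,
        "entrain_amp": cfg.entrain_amp if cfg.entrain_hz is not None else 0.0,
        "condition": cfg.condition,
        "seed": cfg.seed,
    }
    return comps, truth


def simulate_lfp(config: LFPSimConfig) -> SessionSim:
    """Generate a synthetic CA1 LFP trace (see the module docstring)."""
    n = int(round(config.duration_s * config.fs))
    rng = np.random.default_rng(config.seed)
    comps, truth = _components(config, rng, n)
    x = (
        comps["theta"]
        + comps["low_gamma_env"] * comps["low_gamma_carrier"]
        + comps["high_gamma"]
        + comps["noise"]
        + comps["entrain"]
    )
    return SessionSim(
        lfp=Signal(x, config.fs), event_times={}, labels=[], truth=truth
    )


def simulate_session(
    config: LFPSimConfig,
    n_events: int = 8,
    approach_s: float = 2.0,
    explore_s: float = 2.0,
    gap_s: float = 2.0,
    explore_gamma_boost: float | None = None,
) -> SessionSim:
    """Simulate a novel-object session with approach/exploration epochs.

    Each of the ``n_events`` trials consists of a gap, an approach epoch
    and an exploration epoch.  During exploration the low-gamma
    amplitude is multiplied by ``explore_gamma_boost`` (condition
    defaults: sham 2.0, 2VO 1.2 — an amplitude factor, so the expected
    band-power ratio is its square before noise dilution).  Onset times
    of both epoch types are recorded in ``event_times``.
    """
    if n_events < 1:
        raise InvalidParameterError("n_events must be >= 1")
    trial_s = gap_s + approach_s + explore_s
    needed = n_events * trial_s + gap_s
    if config.duration_s < needed:
        raise InvalidParameterError(
            f"duration {config.duration_s} s cannot hold {n_events} events "
            f"({needed:.1f} s needed)"
        )
    boost = (
        EXPLORE_BOOST[config.condition]
        if explore_gamma_boost is None
        else float(explore_gamma_boost)
    )
    n = int(round(config.duration_s * config.fs))
    rng = np.random.default_rng(config.seed)
    comps, truth = _components(config, rng, n)

    mask = np.ones(n)
    approach_on: list[float] = []
    explore_on: list[float] = []
    labels: list[tuple[str, float, float]] = []
    for ev in range(n_events):
        a0 = gap_s + ev * trial_s
        e0 = a0 + approach_s
        approach_on.append(a0)
        explore_on.append(e0)
        labels.append(("approach", a0, approach_s))
        labels.append(("explore", e0, explore_s))
        i0 = int(round(e0 * config.fs))
        i1 = min(n, int(round((e0 + explore_s) * config.fs)))
        mask[i0:i1] = boost
    x = (
        comps["theta"]
        + mask * comps["low_gamma_env"] * comps["low_gamma_carrier"]
        + comps["high_gamma"]
        + comps["noise"]
        + comps["entrain"]
    )
    truth = dict(truth)
    truth["explore_gamma_boost"] = boost
    truth["expected_low_gamma_power_ratio"] = boost**2
    return SessionSim(
        lfp=Signal(x, config.fs),
        event_times={"approach": approach_on, "explore": explore_on},
        labels=labels,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Evoked fEPSP experiments
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class EphysSimConfig:
    """Configuration of a simulated fEPSP experiment.

    ``protocol`` is one of ``io``, ``ppr``, ``ltp_nmdar`` (100 Hz, 1 s
    tetanus) or ``ltp_lvgcc`` (4 x 200 Hz, 0.5 s trains with D-APV) —
    the tetanus descriptions are metadata only; pharmacological
    isolation is represented as a label, not analysis logic.
    """

    protocol: str = "ppr"
    release_p: float = 0.3
    facilitation_tau_ms: float = 60.0
    facilitation_gain: float = 0.5
    ltp_step_percent: float = 150.0
    noise_cv: float = 0.0
    isis_ms: tuple[float, ...] = DEFAULT_ISIS_MS
    intensities_mA: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    io_midpoint_mA: float = 0.28
    io_slope_mA: float = 0.08
    io_max_amp: float = 1.0
    fs: float = 10000.0
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 8.0
    amp_per_release: float = 2.0
    n_sweeps: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.release_p < 1):
            raise InvalidParameterError("release_p must lie in (0, 1)")
        if self.protocol not in ("io", "ppr", "ltp_nmdar", "ltp_lvgcc"):
            raise InvalidParameterError(f"unknown protocol {self.protocol!r}")
        if not self.isis_ms or not self.intensities_mA:
            raise InvalidParameterError("isis_ms and intensities_mA must be nonempty")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")


def fepsp_kernel(
    t_s: np.ndarray, tau_rise_ms: float = 1.0, tau_decay_ms: float = 8.0
) -> np.ndarray:
    """Unit-peak double-exponential fEPSP waveform (positive-going)."""
    tr = tau_rise_ms * 1e-3
    td = tau_decay_ms * 1e-3
    g = np.where(t_s >= 0, np.exp(-np.maximum(t_s, 0) / td) - np.exp(-np.maximum(t_s, 0) / tr), 0.0)
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return g / peak


def expected_ppr_percent(
    release_p: float, isi_ms: float, facilitation_gain: float, facilitation_tau_ms: float
) -> float:
    """Closed-form expected PPR of the release model, in percent.

    The second pulse releases with probability
    ``p + gain * (1 - p) * exp(-ISI / tau)`` — residual facilitation
    recruits part of the non-released pool — so PPR is inversely
    related to the initial release probability ``p``.
    """
    p2 = release_p + facilitation_gain * (1.0 - release_p) * np.exp(
        -isi_ms / facilitation_tau_ms
    )
    return 100.0 * max(p2, 0.0) / release_p


def _make_sweep(
    cfg: EphysSimConfig,
    rng: np.random.Generator,
    amps: Sequence[float],
    stim_times_s: Sequence[float],
    duration_s: float,
    intensity: float | None,
    label: str,
) -> SweepRecord:
    n = int(round(duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    for amp, ts in zip(amps, stim_times_s):
        a = amp
        if cfg.noise_cv > 0:
            a = amp * (1.0 + cfg.noise_cv * rng.standard_normal())
        x -= a * fepsp_kernel(t - ts, cfg.tau_rise_ms, cfg.tau_decay_ms)
    if cfg.noise_cv > 0:
        x += cfg.noise_cv * 0.02 * rng.standard_normal(n)
    return SweepRecord(
        trace=Signal(x, cfg.fs), stim_times=tuple(stim_times_s),
        intensity=intensity, label=label,
    )


def simulate_fepsp_experiment(
    config: EphysSimConfig,
) -> tuple[list[SweepRecord], dict]:
    """Simulate an fEPSP protocol; returns sweeps and closed-form truth.

    * ``ppr``: one two-stimulus sweep per ISI; the first-pulse amplitude
      is proportional to the release probability and the second follows
      the facilitation model of :func:`expected_ppr_percent`.
    * ``io``: single-stimulus sweeps across the intensity grid with a
      sigmoidal amplitude law of known midpoint.
    * ``ltp_nmdar`` / ``ltp_lvgcc``: one sweep per 30 s, 30 min baseline
      then 60 min in which the mean response is stepped to
      ``ltp_step_percent`` of baseline.
    """
    rng = np.random.default_rng(config.seed)
    sweeps: list[SweepRecord] = []
    truth: dict = {"protocol": config.protocol, "seed": config.seed}
    a1 = config.amp_per_release * config.release_p
    if config.protocol == "ppr":
        expected = {}
        for isi in config.isis_ms:
            r = expected_ppr_percent(
                config.release_p, isi,
                config.facilitation_gain, config.facilitation_tau_ms,
            )
            expected[float(isi)] = r
            a2 = a1 * r / 100.0
            t1 = 0.05
            t2 = t1 + isi * 1e-3
            dur = t2 + 0.25
            for _ in range(config.n_sweeps):
                sweeps.append(
                    _make_sweep(
                        config, rng, (a1, a2), (t1, t2), dur, None,
                        f"ppr_isi{isi:g}",
                    )
                )
        truth["ppr_expected_percent"] = expected
        truth["release_p"] = config.release_p
    elif config.protocol == "io":
        for inten in config.intensities_mA:
            amp = config.io_max_amp / (
                1.0 + np.exp(-(inten - config.io_midpoint_mA) / config.io_slope_mA)
            )
            for _ in range(max(config.n_sweeps, 3)):
                sweeps.append(
                    _make_sweep(
                        config, rng, (amp,), (0.05,), 0.2, float(inten),
                        f"io_{inten:g}mA",
                    )
                )
        truth["io_midpoint_mA"] = config.io_midpoint_mA
        truth["io_max_amp"] = config.io_max_amp
    else:  # ltp protocols
        baseline_min, post_min = 30.0, 60.0
        n_base = int(baseline_min * 2)  # one sweep per 30 s
        n_post = int(post_min * 2)
        tetanus = {
            "ltp_nmdar": "100Hz_1s",
            "ltp_lvgcc": "4x200Hz_0.5s_D-APV50uM",
        }[config.protocol]
        for i in range(n_base + n_post):
            amp = a1 if i < n_base else a1 * config.ltp_step_percent / 100.0
            sweeps.append(
                _make_sweep(
                    config, rng, (amp,), (0.05,), 0.15, None,
                    f"{config.protocol}_sweep{i}",
                )
            )
        truth["ltp_step_percent"] = config.ltp_step_percent
        truth["tetanus_time_min"] = baseline_min
        truth["tetanus_protocol"] = tetanus
    return sweeps, truth


# ---------------------------------------------------------------------------
# FM1-43 destaining
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FMSimConfig:
    """Configuration of simulated FM1-43 punctum traces.

    ``snr`` is the ratio of the releasable fluorescence amplitude to
    the additive Gaussian noise SD; ``snr=None`` means noiseless.  The
    "2VO" condition multiplies the decay rate by ``condition_k_factor``
    (slower unloading after ischemia).  ``include_qc_failures`` plants
    one oversized punctum and one punctum sitting exactly at the
    +2 SD intensity boundary, for exercising the QC stage.
    """

    n_puncta: int = 15
    k_per_s: float = 0.05
    residual_frac: float = 0.08
    frame_interval_s: float = 26.5
    n_frames: int = 12
    snr: float | None = 20.0
    amplitude: float = 1.0
    background_mean: float = 0.2
    background_sd: float = 0.02
    condition: str = "sham"
    condition_k_factor: float = 0.6
    include_qc_failures: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.k_per_s <= 0:
            raise InvalidParameterError("k_per_s must be > 0")
        if not (0 < self.residual_frac < 1):
            raise InvalidParameterError("residual_frac must lie in (0, 1)")
        if self.condition not in ("sham", "2VO"):
            raise InvalidParameterError("condition must be 'sham' or '2VO'")
        if self.n_frames < 5:
            raise InvalidParameterError("need at least 5 frames")


def simulate_fm143(config: FMSimConfig) -> tuple[list[PunctumTrace], dict]:
    """Simulate destaining traces ``I(t) = bg + A*(r + (1-r) e^{-kt}) + noise``."""
    rng = np.random.default_rng(config.seed)
    k_true = config.k_per_s * (
        config.condition_k_factor if config.condition == "2VO" else 1.0
    )
    times = np.arange(config.n_frames) * config.frame_interval_s
    noise_sd = 0.0 if config.snr is None else config.amplitude / config.snr
    puncta: list[PunctumTrace] = []
    for i in range(config.n_puncta):
        decay = config.residual_frac + (1 - config.residual_frac) * np.exp(
            -k_true * times
        )
        y = config.background_mean + config.amplitude * decay
        if noise_sd > 0:
            y = y + noise_sd * rng.standard_normal(times.size)
        y = np.maximum(y, 0.0)
        puncta.append(
            PunctumTrace(
                times=times,
                intensity=y,
                diameter_um=float(rng.uniform(0.5, 1.5)),
                circularity=float(rng.uniform(0.75, 0.95)),
                background_mean=config.background_mean,
                background_sd=config.background_sd,
                punctum_id=f"{config.condition}_p{i}",
            )
        )
    if config.include_qc_failures:
        decay = config.residual_frac + (1 - config.residual_frac) * np.exp(
            -k_true * times
        )
        big = PunctumTrace(
            times=times,
            intensity=config.background_mean + config.amplitude * decay,
            diameter_um=2.5,
            circularity=0.9,
            background_mean=config.background_mean,
            background_sd=config.background_sd,
            punctum_id="qc_fail_diameter",
        )
        # initial intensity exactly at the +2 SD boundary (noiseless so
        # the strict ">" criterion is exercised exactly)
        dim_amp = 2.0 * config.background_sd
        dim = PunctumTrace(
            times=times,
            intensity=config.background_mean + dim_amp * decay / decay[0],
            diameter_um=1.0,
            circularity=0.9,
            background_mean=config.background_mean,
            background_sd=config.background_sd,
            punctum_id="qc_fail_intensity",
        )
        puncta.extend([big, dim])
    truth = {
        "k_true": k_true,
        "inv_t_half_true": k_true / float(np.log(2.0)),
        "residual_frac": config.residual_frac,
        "condition": config.condition,
        "n_puncta": config.n_puncta,
        "seed": config.seed,
    }
    return puncta, truth
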