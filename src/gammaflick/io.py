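"""Trace tables, run manifests and the reproducible pipeline driver.

Traces travel as plain CSV (one channel per file, ``time_s,value``
header) with a JSON sidecar carrying metadata (sampling rate, stimulus
times, QC attributes...).  All writes are atomic — data is written to a
temporary file in the destination directory and renamed into place — so
partial outputs never masquerade as complete, and every numeric CSV's
sidecar records the hash of the manifest that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PipelineUsageError, TraceValidationError
from .spectral import Signal

__all__ = [
    "TraceTable",
    "RunManifest",
    "read_trace",
    "write_trace",
    "atomic_write_text",
    "write_csv",
    "run_pipeline",
]

PIPELINE_STAGES = ("simulate", "psd", "pac", "spectrogram", "ppr", "ltp", "fm143")


@dataclasses.dataclass
class TraceTable:
    """A time-indexed table of one or more value columns plus metadata."""

    data: pd.DataFrame
    metadata: dict

    @property
    def fs(self) -> float:
        """Sampling rate: from metadata if present, else median time step."""
        if "fs" in self.metadata:
            return float(self.metadata["fs"])
        dt = np.median(np.diff(self.data["time_s"].to_numpy()))
        return 1.0 / dt

    def to_signal(self, column: str = "value") -> Signal:
        t = self.data["time_s"].to_numpy()
        return Signal(self.data[column].to_numpy(), self.fs, t0=float(t[0]))

    @classmethod
    def from_signal(cls, signal: Signal, metadata: dict | None = None) -> "TraceTable":
        df = pd.DataFrame({"time_s": signal.times, "value": signal.samples})
        meta = {"fs": signal.fs}
        if metadata:
            meta.update(metadata)
        return cls(data=df, metadata=meta)


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Provenance record for one pipeline run.

    The hash covers command, configuration, seed and input digests —
    everything that determines the outputs of a deterministic stage —
    but not the timestamp, so reruns of identical work share a hash.
    """

    command: str
    config: dict
    seed: int
    input_digests: dict[str, str]
    package_version: str
    timestamp: str

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {
                "command": self.command,
                "config": self.config,
                "seed": self.seed,
                "inputs": self.input_digests,
                "version": self.package_version,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hash"] = self.hash
        return d


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def atomic_write_text(path: Path, text: str) -> None:
    """Write text via a temp file + rename in the destination directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trace(table: TraceTable, path: str | Path) -> None:
    """Write a trace CSV and its JSON metadata sidecar atomically."""
    path = Path(path)
    atomic_write_text(path, table.data.to_csv(index=False, lineterminator="\n"))
    atomic_write_text(
        _sidecar_path(path), json.dumps(table.metadata, indent=2, sort_keys=True)
    )


def read_trace(path: str | Path) -> TraceTable:
    """Read a trace CSV plus sidecar, validating the time axis.

    Raises :class:`TraceValidationError` for a missing time column,
    non-monotone time, or an unreadable sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise TraceValidationError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise TraceValidationError(
            f"{path}: missing required 'time_s' column (found {list(df.columns)})"
        )
    bad = np.flatnonzero(np.diff(df["time_s"].to_numpy()) <= 0)
    if bad.size:
        raise TraceValidationError(
            f"{path}: time_s is not strictly increasing at data row(s) "
            f"{(bad + 2).tolist()[:5]}"
        )
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        try:
            meta = json.loads(sc.read_text())
        except json.JSONDecodeError as e:
            raise TraceValidationError(f"{sc}: unreadable sidecar: {e}") from e
    return TraceTable(data=df, metadata=meta)


def write_csv(
    df: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Atomically write a result CSV with a JSON metadata sidecar."""
    path = Path(path)
    atomic_write_text(path, df.to_csv(index=False, lineterminator="\n"))
    if metadata is not None:
        atomic_write_text(
            _sidecar_path(path), json.dumps(metadata, indent=2, sort_keys=True)
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: dict, out_dir: str | Path, seed: int = 0
) -> RunManifest:
    """Execute a sequence of analysis stages and write one manifest.

    ``config["stages"]`` names the stages to run, in order, among
    ``simulate, psd, pac, spectrogram, ppr, ltp, fm143``.  Stage
    options live under the stage's key.  Unknown stages or an empty
    stage list raise :class:`PipelineUsageError` before any work is
    done.  All randomness derives from ``seed``, so repeated runs write
    byte-identical result CSVs.
    """
    from . import __version__
    from .ephys import ltp_timecourse, paired_pulse_curve
    from .fm143 import normalize_unloading, qc_puncta, unloading_rate
    from .simulate import (
        EphysSimConfig,
        FMSimConfig,
        LFPSimConfig,
        simulate_fepsp_experiment,
        simulate_fm143,
        simulate_session,
    )
    from .spectral import spectrogram as make_spectrogram
    from .workflows import analyze_session

    stages = config.get("stages")
    if not stages:
        raise PipelineUsageError("pipeline config names no stages")
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise PipelineUsageError(
            f"unknown stage(s) {unknown}; valid stages: {list(PIPELINE_STAGES)}"
        )
    needs_sessions = {"psd", "pac", "spectrogram"} & set(stages)
    if needs_sessions and "simulate" not in stages and "input" not in config:
        raise PipelineUsageError(
            "psd/pac/spectrogram stages need a 'simulate' stage or an 'input'"
        )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command="pipeline",
        config=config,
        seed=seed,
        input_digests={},
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    meta = {"manifest_hash": manifest.hash, "seed": seed}

    sessions: dict[str, object] = {}
    summary_rows: list[dict] = []

    for stage in stages:
        if stage == "simulate":
            opts = config.get("simulate", {})
            conditions = opts.get("conditions", ["sham", "2VO"])
            base = {
                k: v for k, v in opts.items() if k not in ("conditions", "n_events")
            }
            for cond in conditions:
                cfg = LFPSimConfig(condition=cond, seed=seed, **base)
                sess = simulate_session(cfg, n_events=opts.get("n_events", 8))
                sessions[cond] = sess
                write_trace(
                    TraceTable.from_signal(sess.lfp, {**meta, "condition": cond}),
                    out / f"lfp_{cond}.csv",
                )
        elif stage == "psd" or stage == "pac":
            for cond, sess in sessions.items():
                res = analyze_session(sess, seed=seed)
                for key, val in res.items():
                    summary_rows.append(
                        {"condition": cond, "metric": key, "value": val}
                    )
            # analysis of both kinds is produced in one pass; drop dupes later
        elif stage == "spectrogram":
            for cond, sess in sessions.items():
                sg = make_spectrogram(sess.lfp)
                df = pd.DataFrame(
                    sg.power, index=sg.times, columns=np.round(sg.freqs, 3)
                )
                df.index.name = "time_s"
                write_csv(
                    df.reset_index(), out / f"spectrogram_{cond}.csv",
                    {**meta, "window_s": sg.window_s, "shift_s": sg.shift_s,
                     "window_fn": sg.window_fn, "condition": cond},
                )
        elif stage == "ppr":
            opts = config.get("ppr", {})
            cfg = EphysSimConfig(protocol="ppr", seed=seed, **opts)
            sweeps, truth = simulate_fepsp_experiment(cfg)
            res = paired_pulse_curve(sweeps)
            write_csv(
                pd.DataFrame(
                    {"isi_ms": res.isis_ms, "ppr_percent": res.ppr_percent,
                     "n_sweeps": res.n_sweeps}
                ),
                out / "ppr.csv",
                {**meta, "release_p": truth["release_p"]},
            )
        elif stage == "ltp":
            opts = config.get("ltp", {})
            cfg = EphysSimConfig(protocol="ltp_nmdar", seed=seed, **opts)
            sweeps, truth = simulate_fepsp_experiment(cfg)
            res = ltp_timecourse(sweeps, truth["tetanus_time_min"])
            write_csv(
                pd.DataFrame(
                    {"time_min": res.times_min,
                     "normalized_percent": res.timecourse_percent}
                ),
                out / "ltp_timecourse.csv",
                {**meta, "magnitude_percent": res.magnitude_percent,
                 "tetanus_protocol": truth["tetanus_protocol"]},
            )
        elif stage == "fm143":
            opts = config.get("fm143", {})
            cfg = FMSimConfig(seed=seed, **opts)
            puncta, truth = simulate_fm143(cfg)
            report = qc_puncta(puncta)
            rows = []
            for p in report.accepted:
                kin = unloading_rate(normalize_unloading(p))
                rows.append(
                    {"punctum_id": p.punctum_id, "k_per_s": kin.k,
                     "t_half_s": kin.t_half, "inv_t_half_per_s": kin.inv_t_half}
                )
            write_csv(
                pd.DataFrame(rows), out / "fm143_rates.csv",
                {**meta, "k_true": truth["k_true"],
                 "n_rejected": len(report.rejected)},
            )

    if summary_rows:
        df = pd.DataFrame(summary_rows).drop_duplicates(
            subset=["condition", "metric"]
        )
        write_csv(df, out / "summary.csv", meta)
    atomic_write_text(
        out / "manifest.json", json.dumps(manifest.to_dict(), indent=2)
    )
    return manifest
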