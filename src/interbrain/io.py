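"""Readers, writers and analysis configuration.

Two input routes are supported: European Data Format (EDF) files, read
through MNE and epoched around annotated or explicitly supplied event
onsets, and a plain-text delimited layout (one file per channel, one row per
trial) that round-trips exactly and doubles as the simulation fixture
format.  Results are written as tidy long-format CSV plus a JSON summary,
both stamped with the configuration hash and seed so any result file can be
regenerated from its provenance record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concurrent import EntrainmentMap
from .signal_model import DyadEpochs, Recording


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(
    path,
    epoch_s: float,
    pre_s: float = 0.0,
    event_times_s=None,
    person_id: str | None = None,
) -> Recording:
    """Read an EDF recording and cut it into epochs.

    Event onsets are taken from ``event_times_s`` (seconds from recording
    start) when given, otherwise from the file's annotations.  Each epoch
    spans ``[-pre_s, epoch_s - pre_s)`` around its onset; with no events at
    all the whole recording becomes a single trial.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    srate = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    if event_times_s is None and len(raw.annotations) > 0:
        event_times_s = np.asarray(raw.annotations.onset, dtype=float)
    n_epoch = int(round(epoch_s * srate))
    t0_index = int(round(pre_s * srate))
    if event_times_s is None:
        trials = data[:, np.newaxis, :]
        t0_index = 0
    else:
        event_times_s = np.atleast_1d(np.asarray(event_times_s, dtype=float))
        starts = np.round(event_times_s * srate).astype(int) - t0_index
        segs = []
        for s in starts:
            if s < 0 or s + n_epoch > data.shape[1]:
                raise ValueError(
                    f"epoch at {s / srate:.3f}s does not fit inside the recording"
                )
            segs.append(data[:, s : s + n_epoch])
        trials = np.stack(segs, axis=1)
    return Recording(
        person_id=person_id or Path(path).stem,
        channel_labels=list(raw.ch_names),
        data=trials,
        srate=srate,
        t0_index=t0_index,
    )


# ---------------------------------------------------------------------------
# Delimited text epochs
# ---------------------------------------------------------------------------

def write_delimited_epochs(rec: Recording, out_dir) -> list:
    """One CSV per channel: a ``#``-prefixed metadata header, then one row of
    samples per trial.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ci, label in enumerate(rec.channel_labels):
        p = out_dir / f"{rec.person_id}_{label}.csv"
        with open(p, "w") as fh:
            fh.write(
                f"# person={rec.person_id} channel={label} srate={rec.srate!r} "
                f"t0_index={rec.t0_index} n_trials={rec.n_trials} "
                f"n_samples={rec.n_samples}\n"
            )
            np.savetxt(fh, rec.data[ci], delimiter=",", fmt="%.17g")
        paths.append(p)
    return paths


def _parse_header(line: str, path) -> dict:
    if not line.startswith("#"):
        raise ValueError(f"{path}: missing metadata header line")
    meta = {}
    for token in line.lstrip("#").split():
        key, _, val = token.partition("=")
        meta[key] = val
    for req in ("srate", "t0_index"):
        if req not in meta:
            raise ValueError(f"{path}: header lacks required field {req!r}")
    return meta


def read_delimited_epochs(paths, person_id: str | None = None) -> Recording:
    """Read one or more per-channel delimited files into a Recording.

    Every file must carry the metadata header written by
    :func:`write_delimited_epochs`; ragged rows are reported with their row
    number.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    channels, labels = [], []
    meta = None
    for path in paths:
        with open(path) as fh:
            header = _parse_header(fh.readline(), path)
            rows = []
            width = None
            for ri, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                vals = line.strip().split(",")
                if width is None:
                    width = len(vals)
                elif len(vals) != width:
                    raise ValueError(
                        f"{path}: row {ri} has {len(vals)} values, expected {width}"
                    )
                rows.append([float(v) for v in vals])
        if meta is None:
            meta = header
        elif float(header["srate"]) != float(meta["srate"]):
            raise ValueError("channel files disagree on srate")
        channels.append(np.asarray(rows))
        labels.append(header.get("channel", Path(path).stem))
    data = np.stack(channels, axis=0)
    return Recording(
        person_id=person_id or meta.get("person", "unknown"),
        channel_labels=labels,
        data=data,
        srate=float(meta["srate"]),
        t0_index=int(meta["t0_index"]),
    )


def write_dyad(dyad: DyadEpochs, out_dir) -> dict:
    """Write both persons of a dyad under ``out_dir/a`` and ``out_dir/b``."""
    out_dir = Path(out_dir)
    return {
        "a": [str(p) for p in write_delimited_epochs(dyad.a, out_dir / "a")],
        "b": [str(p) for p in write_delimited_epochs(dyad.b, out_dir / "b")],
    }


def read_dyad(dir_path) -> DyadEpochs:
    dir_path = Path(dir_path)
    a_files = sorted((dir_path / "a").glob("*.csv"))
    b_files = sorted((dir_path / "b").glob("*.csv"))
    if not a_files or not b_files:
        raise ValueError(f"{dir_path}: expected a/ and b/ subdirectories with CSVs")
    return DyadEpochs(a=read_delimited_epochs(a_files), b=read_delimited_epochs(b_files))


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def _provenance(meta: dict) -> str:
    digest = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return digest


def write_entrainment_csv(emap: EntrainmentMap, path, p_map=None, sig=None,
                          seed=None) -> None:
    """Tidy long-format CSV: metric, direction, frequency_hz, time_s, value
    (+ p and significant when inference was run), preceded by commented
    provenance lines (config hash, seed, package version)."""
    vals = emap.values if emap.directions is not None else emap.values[np.newaxis]
    dirs = emap.directions if emap.directions is not None else ["none"]
    rows = []
    for di, dname in enumerate(dirs):
        for fi, f in enumerate(emap.freqs_hz):
            for ti, t in enumerate(emap.time_stamps):
                row = {
                    "metric": emap.metric, "direction": dname,
                    "frequency_hz": f, "time_s": t, "value": vals[di, fi, ti],
                }
                if p_map is not None:
                    row["p"] = np.asarray(p_map)[fi, ti] if np.ndim(p_map) == 2 \
                        else np.asarray(p_map)[di, fi, ti]
                if sig is not None:
                    row["significant"] = bool(np.asarray(sig)[fi, ti]) if np.ndim(sig) == 2 \
                        else bool(np.asarray(sig)[di, fi, ti])
                rows.append(row)
    df = pd.DataFrame(rows)
    meta = {k: v for k, v in emap.meta.items()
            if isinstance(v, (str, int, float, bool, type(None)))}
    with open(path, "w") as fh:
        fh.write(f"# interbrain v{__version__} metric={emap.metric} "
                 f"config_hash={_provenance(meta)} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_entrainment_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_summary_json(results: dict, path) -> None:
    """JSON mirror of the result set (maps reduced to summaries plus
    provenance)."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return str(obj)

    payload = dict(results)
    payload["package_version"] = __version__
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

KNOWN_METRICS = (
    "power_correlation", "itc", "plv_trials", "plv_time", "gc", "gc_spectral",
    "pdc", "pte",
)


@dataclass
class AnalysisConfig:
    """Flat, typed analysis configuration.

    Unknown keys in the config file are errors, not warnings — silent
    misconfiguration is the main failure mode of analysis toolkits.
    """

    dyad_dir: str
    out_dir: str
    metrics: list
    channel: int = 0
    freq_start_hz: float = 2.0
    freq_stop_hz: float = 30.0
    freq_step_hz: float = 1.0
    cycles: float | None = None
    window_length_s: float = 0.5
    window_step_s: float = 0.25
    gc_order: str | int = "bic"
    gc_p_max: int = 30
    pte_delta: int | None = None
    pte_bins: int | None = None
    perm_scheme: str | None = None
    n_perm: int = 1000
    seed: int | None = None
    applied_defaults: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for m in self.metrics:
            if m not in KNOWN_METRICS:
                raise ValueError(
                    f"unknown metric {m!r}; choose from {KNOWN_METRICS}"
                )
        if self.perm_scheme is not None and self.seed is None:
            raise ValueError("a seed is mandatory when permutations are requested")

    @property
    def freqs_hz(self) -> np.ndarray:
        return np.arange(self.freq_start_hz, self.freq_stop_hz + 1e-9, self.freq_step_hz)


def load_config(path) -> AnalysisConfig:
    """Load a flat YAML key-value config; unknown keys are errors."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in fields(AnalysisConfig)} - {"applied_defaults"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = {"dyad_dir", "out_dir", "metrics"} - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required keys {sorted(missing)}")
    if isinstance(raw.get("metrics"), str):
        raw["metrics"] = [m.strip() for m in raw["metrics"].split(",")]
    cfg = AnalysisConfig(**raw)
    cfg.applied_defaults = {
        f.name: getattr(cfg, f.name)
        for f in fields(AnalysisConfig)
        if f.name not in raw and f.name not in ("applied_defaults",)
    }
    return cfg
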