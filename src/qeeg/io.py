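"""Signal I/O, pipeline orchestration and run reports.

Supported on-disk formats
-------------------------
* Delimited text (comma or tab): one header row of channel labels, one
  row per sample.  The sampling rate comes from a JSON sidecar
  (``<file>.json`` with at least ``{"fs": ...}``) or the ``fs``
  argument.  Lossless at full float precision.
* EDF (European Data Format, 16-bit): read through :mod:`mne`
  (optional dependency); written by a built-in minimal writer
  (plain EDF, one data record per second, microvolt physical units).

``run_pipeline`` ties the stages together: read -> detect events ->
intervals -> empirical distribution -> q-exponential vs BG model
comparison, and emits a JSON-serializable :class:`RunReport` embedding
the full configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .distributions import HistogramSpec, build_distribution
from .events import Signal, ThresholdSpec, detect_events, intervals_from_events
from .fitting import FitConfig, compare_models

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunReport",
    "read_signal",
    "write_signal_delimited",
    "write_signal_edf",
    "run_pipeline",
    "MissingSamplingRateError",
    "UnparseableFileError",
]


class MissingSamplingRateError(ValueError):
    """No sampling rate in header, sidecar or arguments."""


class UnparseableFileError(ValueError):
    """The input file could not be parsed as a signal."""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_signal(path, fmt: str | None = None, fs: float | None = None) -> Signal:
    """Read a multichannel signal from EDF or delimited text.

    ``fmt`` is inferred from the extension when omitted ("edf" for
    ``.edf``, "delimited" otherwise).  Channel order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "delimited":
        return _read_delimited(path, fs=fs)
    raise ValueError(f"unknown format {fmt!r}")


def _read_delimited(path: Path, fs: float | None = None) -> Signal:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise UnparseableFileError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0 or frame.shape[0] < 2:
        raise UnparseableFileError(f"{path} holds no signal (shape {frame.shape})")
    metadata = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        fs = fs if fs is not None else metadata.get("fs")
    if fs is None:
        raise MissingSamplingRateError(
            f"no sampling rate for {path}: pass fs= or provide sidecar {sidecar.name}"
        )
    return Signal(
        samples=frame.to_numpy(dtype=float).T,
        fs=float(fs),
        channel_labels=[str(c) for c in frame.columns],
        metadata=metadata,
    )


def _read_edf(path: Path) -> Signal:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires the optional dependency mne "
            "(pip install qeeg[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne rescales EEG channels to volts; the writer declares uV
    data = raw.get_data() * 1e6
    return Signal(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        metadata={"source": str(path)},
    )


def write_signal_delimited(signal: Signal, path, sep: str = ",") -> None:
    """Write channels as columns with a header row, plus a JSON sidecar.

    The sidecar carries ``fs``, the channel labels and any signal
    metadata (including surrogate ground truth), keeping the pair fully
    round-trippable at float precision.
    """
    path = Path(path)
    frame = pd.DataFrame(signal.samples.T, columns=signal.channel_labels)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    sidecar = {
        "fs": signal.fs,
        "channel_labels": list(signal.channel_labels),
        **signal.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def _edf_field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        text = text[:width]
    return text.ljust(width).encode("ascii")


def _edf_number(value: float, width: int) -> bytes:
    for fmt in (f"%.{width - 2}g", "%.3g", "%.1f", "%d"):
        text = fmt % value
        if len(text) <= width:
            return text.ljust(width).encode("ascii")
    raise ValueError(f"cannot encode {value} in {width} EDF chars")


def write_signal_edf(signal: Signal, path) -> None:
    """Write a plain 16-bit EDF file (one 1-second data record per second).

    The sampling rate must be a positive integer (EDF stores integer
    samples-per-record here).  Physical units are microvolts; amplitudes
    are linearly mapped onto the full 16-bit digital range per channel,
    so the round-trip error is bounded by half a digital step.
    """
    fs = signal.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate (got {fs})")
    fs = int(round(fs))
    path = Path(path)
    n_ch, n_samp = signal.samples.shape
    n_records = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = signal.samples

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = bytearray()
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_ch, 4)
    for label in signal.channel_labels:
        header += _edf_field(label, 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_number(v, 8) for v in phys_min)
    header += b"".join(_edf_number(v, 8) for v in phys_max)
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(fs, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            chunk = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(chunk.tobytes())


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one analysis run."""

    inputs: tuple
    fmt: str | None = None
    fs: float | None = None
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    # pipeline histograms always carry counts, so the statistically
    # efficient deviance (binned maximum-likelihood) loss is the default
    fit: FitConfig = field(default_factory=lambda: FitConfig(loss="deviance"))
    output: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(str(p) for p in self.inputs))
        if not self.inputs:
            raise ValueError("at least one input path is required")


@dataclass
class RunReport:
    """Outcome of :func:`run_pipeline`, JSON-serializable."""

    config: RunConfig
    comparisons: list
    event_counts: dict
    interval_counts: dict
    n_discarded: int
    skipped_channels: list
    warnings: list
    seed: int

    @property
    def pooled_q(self) -> float:
        """Entropic index of the pooled q-exponential fit."""
        return self.comparisons[0]["comparison"].qexp.params.q

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        return {
            "software_version": _version,
            "seed": self.seed,
            "config": cfg,
            "comparisons": [
                {"scope": c["scope"], **c["comparison"].to_dict()}
                for c in self.comparisons
            ],
            "event_counts": self.event_counts,
            "interval_counts": self.interval_counts,
            "n_discarded": self.n_discarded,
            "skipped_channels": self.skipped_channels,
            "warnings": self.warnings,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(config: RunConfig, signal: Signal | None = None) -> RunReport:
    """Execute the full analysis and return a :class:`RunReport`.

    ``signal`` may be passed directly (bypassing file I/O); otherwise
    every path in ``config.inputs`` is read and analyzed jointly
    (channels concatenated across files).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    warnings_: list[str] = []
    if signal is None:
        signals = [read_signal(p, fmt=config.fmt, fs=config.fs) for p in config.inputs]
        if len(signals) == 1:
            signal = signals[0]
        else:
            if len({s.fs for s in signals}) != 1:
                raise ValueError("all inputs must share one sampling rate")
            n = min(s.n_samples for s in signals)
            signal = Signal(
                samples=np.vstack([s.samples[:, :n] for s in signals]),
                fs=signals[0].fs,
                channel_labels=[
                    f"{Path(p).stem}:{lb}"
                    for p, s in zip(config.inputs, signals)
                    for lb in s.channel_labels
                ],
            )

    fit_config = FitConfig(
        bounds=config.fit.bounds,
        n_starts=config.fit.n_starts,
        seed=config.seed,
        loss=config.fit.loss,
        tol=config.fit.tol,
        include_zero_bins=config.fit.include_zero_bins,
    )

    trains = detect_events(signal, config.threshold)
    detected = {t.channel for t in trains}
    skipped = [c for c in signal.channel_labels if c not in detected]
    for ch in skipped:
        warnings_.append(f"channel {ch} unusable (no negative part); skipped")

    series = [intervals_from_events(t) for t in trains]
    event_counts = {t.channel: int(t.event_times.size) for t in trains}
    interval_counts = {s.channel: int(s.intervals.size) for s in series}
    logger.info("events per channel: %s", event_counts)

    quantum = 1000.0 / signal.fs
    comparisons = []
    if config.histogram.pooling == "per_channel":
        dists = build_distribution(series, config.histogram, quantum=quantum)
    else:
        dists = [build_distribution(series, config.histogram, quantum=quantum)]
    n_discarded = 0
    for dist in dists:
        n_discarded += dist.n_discarded
        comparison = compare_models(dist, fit_config)
        scope = dist.channel if dist.channel is not None else "pooled"
        logger.info(
            "%s: q = %.4f (preferred model: %s)",
            scope,
            comparison.qexp.params.q,
            comparison.preferred,
        )
        comparisons.append({"scope": scope, "comparison": comparison})

    report = RunReport(
        config=config,
        comparisons=comparisons,
        event_counts=event_counts,
        interval_counts=interval_counts,
        n_discarded=n_discarded,
        skipped_channels=skipped,
        warnings=warnings_,
        seed=config.seed,
    )
    if config.output:
        report.to_json(config.output)
    return report
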