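"""Synthetic inputs with known ground truth.

Three generators:

* :func:`logistic_map` — the canonical route-to-chaos recurrence
  ``x(t+1) = r x(t) (1 - x(t))``, used as a deterministic-chaos test
  signal (fixed point for r < 3, period doubling, fully developed chaos
  at r = 4 with exponential sensitivity to initial conditions).
* :func:`sample_qexp_intervals` — i.i.d. inter-event intervals drawn
  from the q-exponential law by its exact analytic inverse CDF.
* :func:`synthesize_signal` — an EEG-like surrogate: Gaussian noise on
  a negative baseline with a single-sample negative pulse planted at
  each event time, event times being the cumulative sums of sampled
  intervals.  The planted ground truth rides along in
  ``Signal.metadata`` so the full pipeline (detect -> bin -> fit) can
  be scored against it.

The surrogate emulates only the statistical structure the method
consumes — sub-threshold events and their interval law — not
biophysically realistic EEG (no oscillatory bands, no 1/f spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .events import Signal
from .qstats import QExpParams, qexp_ppf

__all__ = [
    "LogisticMapConfig",
    "SurrogateSpec",
    "logistic_map",
    "sample_qexp_intervals",
    "synthesize_signal",
]


@dataclass(frozen=True)
class LogisticMapConfig:
    """Logistic-map recurrence configuration: 1 < r <= 4, 0 < x0 < 1."""

    r: float
    x0: float
    n: int

    def __post_init__(self):
        if not (1.0 < self.r <= 4.0):
            raise ValueError(f"control parameter r must be in (1, 4] (got {self.r})")
        if not (0.0 < self.x0 < 1.0):
            raise ValueError(f"initial value must be in (0, 1) (got {self.x0})")
        if self.n < 1:
            raise ValueError("need n >= 1")


def logistic_map(config: LogisticMapConfig) -> np.ndarray:
    """Iterate ``x(t+1) = r x(t) (1 - x(t))`` exactly for n steps."""
    out = np.empty(config.n)
    x = config.x0
    for i in range(config.n):
        out[i] = x
        x = config.r * x * (1.0 - x)
    return out


def sample_qexp_intervals(params: QExpParams, n: int, seed=None) -> np.ndarray:
    """Draw n i.i.d. intervals (ms) by the exact inverse CDF.

    ``seed`` may be an int or a :class:`numpy.random.Generator`;
    identical seeds give identical samples.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.asarray(qexp_ppf(rng.random(n), params))


@dataclass(frozen=True)
class SurrogateSpec:
    """Ground-truth specification of an EEG-like surrogate signal.

    ``n_events`` events per channel; negative single-sample pulses of
    ``pulse_amplitude`` on Gaussian noise (sd ``noise_sd``) around a
    negative baseline.  The planting guarantee ``|pulse_amplitude| >
    5 noise_sd`` keeps pulses separable from noise by the -1 SD
    threshold rule.  ``baseline_offset`` defaults to ``-noise_sd``
    (or to ``-0.05 |pulse_amplitude|`` in the noiseless case) so the
    negative part of the signal is always populated.
    """

    interval_params: QExpParams
    n_events: int = 10_000
    fs: float = 1000.0
    pulse_amplitude: float = -50.0
    noise_sd: float = 1.0
    seed: int = 0
    n_channels: int = 1
    baseline_offset: Optional[float] = None
    start_ms: float = 50.0
    max_duration_ms: Optional[float] = None

    def __post_init__(self):
        if self.n_events < 2:
            raise ValueError("need n_events >= 2")
        if not self.pulse_amplitude < 0:
            raise ValueError("pulse amplitude must be negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.pulse_amplitude) > 5.0 * self.noise_sd:
            raise ValueError(
                "planting guarantee |pulse_amplitude| > 5 noise_sd violated"
            )
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if self.n_channels < 1:
            raise ValueError("need n_channels >= 1")

    @property
    def effective_baseline(self) -> float:
        if self.baseline_offset is not None:
            return self.baseline_offset
        if self.noise_sd > 0:
            return -self.noise_sd
        return -0.05 * abs(self.pulse_amplitude)


def synthesize_signal(spec: SurrogateSpec) -> Signal:
    """Build a surrogate :class:`~qeeg.events.Signal` with planted events.

    Event times per channel are ``start_ms`` plus the cumulative sums of
    intervals drawn from ``spec.interval_params``; each event is one
    sample of ``pulse_amplitude`` added to the noisy baseline.  The
    realized (sample-grid) event times in ms are stored in
    ``metadata["event_times_ms"]`` per channel.

    Raises
    ------
    ValueError
        If the required duration exceeds ``max_duration_ms``.
    """
    root = np.random.default_rng(spec.seed)
    streams = root.spawn(spec.n_channels)
    events_per_channel = []
    last = 0.0
    for rng in streams:
        iv = sample_qexp_intervals(spec.interval_params, spec.n_events - 1, rng)
        times = spec.start_ms + np.concatenate(([0.0], np.cumsum(iv)))
        events_per_channel.append(times)
        last = max(last, times[-1])
    duration_ms = last + 100.0
    if spec.max_duration_ms is not None and duration_ms > spec.max_duration_ms:
        raise ValueError(
            f"surrogate would span {duration_ms:.0f} ms > "
            f"max_duration_ms = {spec.max_duration_ms:.0f}"
        )
    n_samples = int(np.ceil(duration_ms * spec.fs / 1000.0))
    samples = np.empty((spec.n_channels, n_samples))
    realized = []
    for ch, (rng, times) in enumerate(zip(streams, events_per_channel)):
        x = rng.normal(0.0, spec.noise_sd, n_samples) if spec.noise_sd > 0 else np.zeros(n_samples)
        x += spec.effective_baseline
        idx = np.unique(np.round(times * spec.fs / 1000.0).astype(int))
        idx = idx[idx < n_samples]
        x[idx] += spec.pulse_amplitude
        samples[ch] = x
        realized.append(idx * 1000.0 / spec.fs)
    labels = [f"ch{i:02d}" for i in range(spec.n_channels)]
    meta = {
        "event_times_ms": [t.tolist() for t in realized],
        "ground_truth": {
            "b": spec.interval_params.b,
            "c": spec.interval_params.c,
            "h": spec.interval_params.h,
            "q": spec.interval_params.q,
        },
        "seed": spec.seed,
        "n_events": spec.n_events,
        "pulse_amplitude": spec.pulse_amplitude,
        "noise_sd": spec.noise_sd,
    }
    return Signal(samples=samples, fs=spec.fs, channel_labels=labels, metadata=meta)
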