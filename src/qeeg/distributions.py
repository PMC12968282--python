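"""Empirical inter-event interval distributions.

Intervals from one or many channels are pooled (or kept per channel)
and counted into equal-width, left-closed right-open bins on
``[t_min, t_max)``.  Intervals outside the range are discarded — never
clipped, which would distort the fitted tail — and the per-bin
probabilities are relative frequencies among the in-range intervals.

The canonical configurations use 100, 500 or 1000 interval classes on
0–1000 ms; the fitted entropic index is inherently relative to this
configuration, so both the bin count and the range are explicit here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .events import IntervalSeries
from .qstats import QExpParams, BGExpParams, qexp_pdf, bg_pdf

logger = logging.getLogger(__name__)

__all__ = ["HistogramSpec", "IntervalDistribution", "build_distribution"]


@dataclass(frozen=True)
class HistogramSpec:
    """Binning configuration for interval histograms."""

    n_bins: int = 500
    t_min: float = 0.0
    t_max: float = 1000.0
    pooling: str = "pooled"

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError(f"need at least 2 bins (got {self.n_bins})")
        if not (self.t_max > self.t_min >= 0):
            raise ValueError(f"need t_max > t_min >= 0 (got [{self.t_min}, {self.t_max}))")
        if self.pooling not in ("pooled", "per_channel"):
            raise ValueError("pooling must be 'pooled' or 'per_channel'")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.t_min, self.t_max, self.n_bins + 1)


@dataclass
class IntervalDistribution:
    """Empirical probability distribution of inter-event intervals.

    Attributes
    ----------
    bin_edges : ndarray, shape (n_bins + 1,)
        Equal-width edges in ms; bins are ``[e_i, e_{i+1})``.
    probabilities : ndarray, shape (n_bins,)
        Relative frequencies; sum to 1 whenever any interval was counted.
    n_total : int
        Number of in-range intervals counted.
    n_discarded : int
        Intervals outside ``[t_min, t_max)``.
    channel : str or None
        Channel label for per-channel distributions; None when pooled.
    quantum : float
        Sampling quantum of the interval values in ms (``1000/fs``) when
        the intervals live on a sample grid, else 0.  Model fits use it
        for a discretization (continuity) correction.
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_total: int
    n_discarded: int = 0
    channel: str | None = None
    quantum: float = 0.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size != self.bin_edges.size - 1:
            raise ValueError("probabilities must have one entry per bin")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=0):
            raise ValueError("bins must be equal-width")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if self.n_total > 0 and abs(self.probabilities.sum() - 1.0) > 1e-12 * self.n_total:
            raise ValueError("probabilities must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.probabilities.size

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def counts(self) -> np.ndarray:
        """Integer bin counts (reconstructed from relative frequencies)."""
        return np.rint(self.probabilities * self.n_total).astype(int)

    # -- construction -------------------------------------------------

    @classmethod
    def from_model(cls, params, spec: HistogramSpec | None = None) -> "IntervalDistribution":
        """Noiseless distribution implied by a fitted/ground-truth model.

        Per-bin probabilities are bin-width x pdf(bin center),
        renormalized over the histogram window.
        """
        spec = spec or HistogramSpec()
        edges = spec.edges
        centers = (edges[:-1] + edges[1:]) / 2.0
        pdf = qexp_pdf if isinstance(params, QExpParams) else bg_pdf
        p = np.diff(edges) * np.asarray(pdf(centers, params))
        return cls(bin_edges=edges, probabilities=p / p.sum(), n_total=0)

    # -- serialization -------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "bin_edges": self.bin_edges.tolist(),
            "probabilities": self.probabilities.tolist(),
            "n_total": int(self.n_total),
            "n_discarded": int(self.n_discarded),
            "channel": self.channel,
            "quantum": self.quantum,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "IntervalDistribution":
        source = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(source)
        return cls(
            bin_edges=np.array(d["bin_edges"]),
            probabilities=np.array(d["probabilities"]),
            n_total=d["n_total"],
            n_discarded=d.get("n_discarded", 0),
            channel=d.get("channel"),
            quantum=d.get("quantum", 0.0),
        )

    def to_text(self, path, sep: str = "\t") -> None:
        """Two-column (bin_center, probability) delimited dump."""
        arr = np.column_stack([self.bin_centers, self.probabilities])
        np.savetxt(path, arr, delimiter=sep, header=f"bin_center{sep}probability")


def build_distribution(
    series: Sequence[IntervalSeries] | IntervalSeries,
    spec: HistogramSpec | None = None,
    quantum: float = 0.0,
):
    """Bin interval series into an empirical probability distribution.

    In pooled mode (default) the intervals of every channel are
    concatenated before binning and a single
    :class:`IntervalDistribution` is returned; in ``per_channel`` mode a
    list with one distribution per non-empty series is returned.

    Raises
    ------
    ValueError
        If no interval falls inside ``[t_min, t_max)``.
    """
    spec = spec or HistogramSpec()
    if isinstance(series, IntervalSeries):
        series = [series]
    if spec.pooling == "per_channel":
        pooled_spec = HistogramSpec(spec.n_bins, spec.t_min, spec.t_max, "pooled")
        return [
            _bin_one(s.intervals, pooled_spec, channel=s.channel, quantum=quantum)
            for s in series
            if s.intervals.size
        ]
    intervals = (
        np.concatenate([s.intervals for s in series]) if series else np.empty(0)
    )
    return _bin_one(intervals, spec, channel=None, quantum=quantum)


def _bin_one(intervals, spec, channel, quantum) -> IntervalDistribution:
    intervals = np.asarray(intervals, dtype=float)
    in_range = (intervals >= spec.t_min) & (intervals < spec.t_max)
    n_total = int(in_range.sum())
    n_discarded = intervals.size - n_total
    if n_total == 0:
        raise ValueError(
            f"no intervals inside [{spec.t_min}, {spec.t_max}) "
            f"({n_discarded} discarded)"
        )
    if n_discarded:
        logger.info(
            "discarded %d of %d intervals outside [%g, %g)",
            n_discarded, intervals.size, spec.t_min, spec.t_max,
        )
    counts, _ = np.histogram(intervals[in_range], bins=spec.edges)
    return IntervalDistribution(
        bin_edges=spec.edges,
        probabilities=counts / n_total,
        n_total=n_total,
        n_discarded=n_discarded,
        channel=channel,
        quantum=quantum,
    )
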