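"""Peri-event time histograms and their z-score normalization.

Two dialects are implemented, matching how prefrontal (IL) and basal-amygdala
(Ba) units are conventionally analysed:

* tone dialect — spikes binned at 100 ms around each tone onset, trials
  averaged, and each bin z-scored against the mean and sample SD of the four
  pre-tone baseline bins of the trial-averaged histogram;
* pip dialect — spikes binned at 20 ms around every pip onset of the trial
  set (5 CSs x 27 pips = 135 events by default), averaged, and z-scored
  against baseline statistics from the 500 ms preceding each tone onset
  (25 pre-tone 20-ms bins of the trial-averaged baseline histogram).

Averaging happens before z-scoring in both dialects.  A baseline SD of zero
makes z undefined: the histogram is flagged degenerate and its z bins masked
(no epsilon inflation, so null behaviour stays honest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ZPETH",
    "avg_event_counts",
    "zscore_from_counts",
    "zscore_tone_peth",
    "zscore_pip_peth",
    "window_response",
]


@dataclass(frozen=True)
class ZPETH:
    """Z-scored peri-event histogram with baseline provenance."""

    unit_id: str
    session: str
    bin_edges_ms: np.ndarray        # length n_bins + 1, relative to event onset
    z: np.ndarray                   # NaN-masked when degenerate
    counts: np.ndarray              # trial-averaged counts per bin
    baseline_window_ms: tuple
    baseline_mean_hz: float
    baseline_sd_hz: float
    n_events: int
    degenerate: bool = False

    @property
    def bin_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])


def avg_event_counts(spikes_s: np.ndarray, event_times_s: np.ndarray,
                     edges_ms: np.ndarray) -> np.ndarray:
    """Trial-averaged spike counts in half-open bins [left, right) around events."""
    spikes = np.sort(np.asarray(spikes_s, dtype=float))
    events = np.asarray(event_times_s, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event")
    edges_s = np.asarray(edges_ms, dtype=float) / 1000.0
    counts = np.zeros(edges_s.size - 1)
    for t0 in events:
        rel = spikes[np.searchsorted(spikes, t0 + edges_s[0], side="left"):
                     np.searchsorted(spikes, t0 + edges_s[-1], side="left")] - t0
        # half-open [left, right): searchsorted-based binning
        idx = np.searchsorted(edges_s, rel, side="right") - 1
        idx = idx[(idx >= 0) & (idx < counts.size)]
        np.add.at(counts, idx, 1.0)
    return counts / events.size


def zscore_from_counts(avg_counts: np.ndarray, n_baseline_bins: int,
                       baseline_counts: np.ndarray | None = None
                       ) -> tuple[np.ndarray, float, float, bool]:
    """Z-score averaged bins against baseline bins.

    Baseline bins are the first ``n_baseline_bins`` of ``avg_counts`` unless a
    separate ``baseline_counts`` vector is supplied.  Returns
    (z, mu, sd, degenerate); z is all-NaN when the baseline SD is zero.
    """
    counts = np.asarray(avg_counts, dtype=float)
    base = counts[:n_baseline_bins] if baseline_counts is None else np.asarray(
        baseline_counts, dtype=float)
    if base.size < 2:
        raise ValueError("need >= 2 baseline bins")
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    if sd == 0.0:
        return np.full_like(counts, np.nan), mu, sd, True
    return (counts - mu) / sd, mu, sd, False


def zscore_tone_peth(spikes_s: np.ndarray, tone_onsets_s: np.ndarray,
                     bin_ms: float = 100.0, n_baseline_bins: int = 4,
                     post_ms: float = 1000.0, unit_id: str = "",
                     session: str = "") -> ZPETH:
    """Tone-aligned z-scored PETH (100-ms bins, 4 pre-tone baseline bins)."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    tone_onsets_s = np.asarray(tone_onsets_s, dtype=float)
    if tone_onsets_s.size == 0:
        raise ValueError("need at least one tone onset")
    pre_ms = n_baseline_bins * bin_ms
    n_post = int(np.ceil(post_ms / bin_ms))
    edges = np.arange(-n_baseline_bins, n_post + 1) * bin_ms
    counts = avg_event_counts(spikes_s, tone_onsets_s, edges)
    z, mu, sd, degenerate = zscore_from_counts(counts, n_baseline_bins)
    to_hz = 1000.0 / bin_ms
    return ZPETH(unit_id, session, edges, z, counts, (-pre_ms, 0.0),
                 mu * to_hz, sd * to_hz, int(tone_onsets_s.size), degenerate)


def zscore_pip_peth(spikes_s: np.ndarray, tone_onsets_s: np.ndarray,
                    pip_onsets_s: np.ndarray, bin_ms: float = 20.0,
                    baseline_ms: float = 500.0, post_ms: float = 600.0,
                    unit_id: str = "", session: str = "") -> ZPETH:
    """Pip-aligned z-scored PETH (20-ms bins, 500-ms pre-tone baseline).

    Counts are averaged over every pip of the trial set; baseline mean and SD
    come from the trial-averaged 20-ms bins of the 500 ms preceding each tone
    onset.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    pip_onsets_s = np.asarray(pip_onsets_s, dtype=float)
    tone_onsets_s = np.asarray(tone_onsets_s, dtype=float)
    if pip_onsets_s.size == 0:
        raise ValueError("pip-aligned histogram requested without pip events")
    if tone_onsets_s.size == 0:
        raise ValueError("need tone onsets for the pre-tone baseline")
    n_base = int(round(baseline_ms / bin_ms))
    base_edges = np.arange(-n_base, 1) * bin_ms
    base_counts = avg_event_counts(spikes_s, tone_onsets_s, base_edges)

    n_post = int(np.ceil(post_ms / bin_ms))
    edges = np.arange(0, n_post + 1) * bin_ms
    counts = avg_event_counts(spikes_s, pip_onsets_s, edges)
    z, mu, sd, degenerate = zscore_from_counts(counts, n_base,
                                               baseline_counts=base_counts)
    to_hz = 1000.0 / bin_ms
    return ZPETH(unit_id, session, edges, z, counts, (-baseline_ms, 0.0),
                 mu * to_hz, sd * to_hz, int(pip_onsets_s.size), degenerate)


def window_response(zpeth: ZPETH, window_ms: tuple[float, float] = (0.0, 400.0),
                    stat: str = "mean") -> float:
    """Mean or max z over bins fully contained in ``[start, end)``.

    Returns NaN when the histogram is degenerate (baseline SD = 0).
    """
    start, end = window_ms
    left = zpeth.bin_edges_ms[:-1]
    right = zpeth.bin_edges_ms[1:]
    inside = (left >= start) & (right <= end)
    if not inside.any():
        raise ValueError("no bins fully inside the requested window")
    if zpeth.degenerate:
        return float("nan")
    vals = zpeth.z[inside]
    if stat == "mean":
        return float(vals.mean())
    if stat == "max":
        return float(vals.max())
    raise ValueError(f"unknown stat {stat!r}")
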