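"""CS-responsiveness testing and fear / extinction neuron typing.

A unit is CS-responsive in a recall epoch when its per-event spike counts in
the 100 ms following event onset differ significantly from per-event counts in
an equal-duration window immediately before onset (two-sided unpaired t test,
p < alpha); the sign of the mean difference gives the response direction.

Typing across epochs follows the field's definitions: *fear neurons* respond
excitatorily when conditioned fear is recalled (post-Cond) but not during
habituation nor after extinction; *extinction neurons* respond excitatorily
when extinction is recalled (post-Ext1) but not during habituation nor fear
recall; a unit responding in exactly one other epoch is *session-selective*;
everything else is non-responsive.  Because the published exemplars show
*strong* excitatory responses, typing additionally requires the epoch's peak
windowed |z| (the largest-z cell-based statistic) to reach ``min_abs_z``
(default 3, the same scale used for latency detection); pass
``min_abs_z=None`` for the ungated p-value-only behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peth import ZPETH, window_response, zscore_pip_peth, zscore_tone_peth

__all__ = [
    "EpochResponse",
    "ResponsivenessProfile",
    "NeuronType",
    "RECALL_EPOCHS",
    "cs_responsive_test",
    "per_event_counts",
    "build_profile",
    "classify_neuron",
    "response_latency",
    "percentage",
    "cohort_summary",
]

RECALL_EPOCHS = ("Hab", "post-Cond", "post-Ext1", "post-Ext2", "post-Ext3")


@dataclass(frozen=True)
class EpochResponse:
    responsive: bool
    sign: str                 # "excitatory" | "inhibitory" | "none"
    p_value: float
    mean_window_z: float
    peak_window_z: float = float("nan")   # z of the largest-|z| bin in window
    code: str | None = None   # e.g. "exact_tie"

    def __post_init__(self):
        if (self.sign == "none") != (not self.responsive):
            raise ValueError("sign must be 'none' exactly when not responsive")


@dataclass(frozen=True)
class ResponsivenessProfile:
    unit_id: str
    epochs: Mapping[str, EpochResponse]


@dataclass(frozen=True)
class NeuronType:
    unit_id: str
    label: str                      # fear | extinction | session_selective | non_responsive
    target: str | None = None       # epoch, for session_selective
    latency_ms: float | None = None


def cs_responsive_test(response_counts: Sequence[float],
                       baseline_counts: Sequence[float],
                       alpha: float = 0.05) -> EpochResponse:
    """Two-sided unpaired t test of per-event response vs baseline counts."""
    x = np.asarray(response_counts, dtype=float)
    y = np.asarray(baseline_counts, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 events per side")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return EpochResponse(False, "none", 1.0, np.nan, code="exact_tie")
        # degenerate separation: no within-group variability, means differ
        sign = "excitatory" if x.mean() > y.mean() else "inhibitory"
        return EpochResponse(True, sign, 0.0, np.nan, code="zero_variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    responsive = bool(p < alpha)
    sign = "none"
    if responsive:
        sign = "excitatory" if x.mean() > y.mean() else "inhibitory"
    return EpochResponse(responsive, sign, float(p), np.nan)


def per_event_counts(spikes_s: np.ndarray, onsets_s: np.ndarray,
                     window_ms: tuple[float, float]) -> np.ndarray:
    """Spike count in ``[onset + start, onset + end)`` for every event."""
    spikes = np.sort(np.asarray(spikes_s, dtype=float))
    onsets = np.asarray(onsets_s, dtype=float)
    lo = onsets + window_ms[0] / 1000.0
    hi = onsets + window_ms[1] / 1000.0
    return (np.searchsorted(spikes, hi, side="left")
            - np.searchsorted(spikes, lo, side="left")).astype(float)


def build_profile(unit_id: str, spikes_s: np.ndarray,
                  epoch_events: Mapping[str, Mapping[str, np.ndarray]],
                  mode: str = "tone", alpha: float = 0.05,
                  response_window_ms: float = 100.0) -> tuple[
                      ResponsivenessProfile, dict[str, ZPETH]]:
    """Responsiveness profile plus per-epoch z-PETHs for one unit.

    ``epoch_events`` maps epoch label -> {"tones": onsets, "pips": onsets}
    (``pips`` required in pip mode).  The t test compares per-event counts in
    [0, response_window_ms) against an equal, rate-matched window immediately
    pre-onset; events are pips in pip mode and tones in tone mode.
    """
    if mode not in ("tone", "pip"):
        raise ValueError(f"unknown mode {mode!r}")
    epochs: dict[str, EpochResponse] = {}
    zpeths: dict[str, ZPETH] = {}
    for epoch, ev in epoch_events.items():
        tones = np.asarray(ev["tones"], dtype=float)
        if mode == "pip":
            if "pips" not in ev or len(ev["pips"]) == 0:
                raise ValueError(f"pip mode requires pip events (epoch {epoch})")
            aligned = np.asarray(ev["pips"], dtype=float)
            zp = zscore_pip_peth(spikes_s, tones, aligned,
                                 unit_id=unit_id, session=epoch)
            zwin = (0.0, 100.0)
        else:
            aligned = tones
            zp = zscore_tone_peth(spikes_s, tones, unit_id=unit_id, session=epoch)
            zwin = (0.0, 400.0)
        resp = per_event_counts(spikes_s, aligned, (0.0, response_window_ms))
        base = per_event_counts(spikes_s, aligned, (-response_window_ms, 0.0))
        res = cs_responsive_test(resp, base, alpha=alpha)
        try:
            mean_z = window_response(zp, zwin, stat="mean")
            peak_z = _peak_window_z(zp, zwin)
        except ValueError:
            mean_z = peak_z = float("nan")
        epochs[epoch] = EpochResponse(res.responsive, res.sign, res.p_value,
                                      mean_z, peak_z, res.code)
        zpeths[epoch] = zp
    return ResponsivenessProfile(unit_id, epochs), zpeths


def _peak_window_z(zpeth: ZPETH, window_ms: tuple[float, float]) -> float:
    """Z of the largest-magnitude bin fully inside the window."""
    if zpeth.degenerate:
        return float("nan")
    left = zpeth.bin_edges_ms[:-1]
    right = zpeth.bin_edges_ms[1:]
    inside = (left >= window_ms[0]) & (right <= window_ms[1])
    if not inside.any():
        raise ValueError("no bins fully inside the requested window")
    vals = zpeth.z[inside]
    return float(vals[np.argmax(np.abs(vals))])


def _active(resp: EpochResponse, min_abs_z: float | None) -> bool:
    if not resp.responsive:
        return False
    if min_abs_z is None:
        return True
    return np.isfinite(resp.peak_window_z) and abs(resp.peak_window_z) >= min_abs_z


def classify_neuron(profile: ResponsivenessProfile,
                    min_abs_z: float | None = 3.0,
                    required: Sequence[str] = RECALL_EPOCHS) -> NeuronType:
    """Type a unit from its per-epoch responsiveness profile."""
    missing = [e for e in required if e not in profile.epochs]
    if missing:
        raise ValueError(f"profile missing required epochs: {missing}")
    ep = profile.epochs

    def active(name: str) -> bool:
        return _active(ep[name], min_abs_z)

    def exc(name: str) -> bool:
        return active(name) and ep[name].sign == "excitatory"

    post_ext = ("post-Ext1", "post-Ext2", "post-Ext3")
    if exc("post-Cond") and not active("Hab") and not any(active(e) for e in post_ext):
        return NeuronType(profile.unit_id, "fear")
    if exc("post-Ext1") and not active("Hab") and not active("post-Cond"):
        return NeuronType(profile.unit_id, "extinction")
    active_epochs = [e for e in required if active(e)]
    if len(active_epochs) == 1:
        return NeuronType(profile.unit_id, "session_selective",
                          target=active_epochs[0])
    return NeuronType(profile.unit_id, "non_responsive")


def response_latency(zpeth: ZPETH, criterion_z: float = 3.0,
                     window_ms: tuple[float, float] = (0.0, 400.0)) -> float | None:
    """Left edge of the first bin in the window with z >= criterion, or None."""
    if zpeth.degenerate:
        raise ValueError("latency undefined for a degenerate histogram")
    left = zpeth.bin_edges_ms[:-1]
    right = zpeth.bin_edges_ms[1:]
    inside = (left >= window_ms[0]) & (right <= window_ms[1])
    if not inside.any():
        raise ValueError("no bins fully inside the requested window")
    hits = np.flatnonzero(inside & (zpeth.z >= criterion_z))
    if hits.size == 0:
        return None
    return float(left[hits[0]])


def percentage(count: int, denominator: int, decimals: int = 2) -> float:
    """100 * count / denominator rounded to ``decimals`` places."""
    if denominator <= 0:
        raise ZeroDivisionError("zero denominator")
    return round(100.0 * count / denominator, decimals)


def cohort_summary(types: Sequence[NeuronType], n_recorded: int,
                   n_cs_responsive: int | None = None) -> pd.DataFrame:
    """Population composition: counts and percentages per label.

    ``n_cs_responsive`` defaults to the number of units typed with any label
    other than non_responsive.  Percentages are reported to 2 decimals; a zero
    denominator yields 0.00 with the ``flag`` column set.
    """
    labels = [t.label for t in types]
    if n_recorded < len(labels):
        raise ValueError("n_recorded smaller than the number of typed units")
    if n_cs_responsive is None:
        n_cs_responsive = sum(1 for l in labels if l != "non_responsive")
    rows = []
    for label in ("fear", "extinction", "session_selective", "non_responsive"):
        count = labels.count(label)
        flag = None
        if n_recorded > 0:
            pct_rec = percentage(count, n_recorded)
        else:
            pct_rec, flag = 0.0, "zero_denominator"
        if label != "non_responsive" and n_cs_responsive > 0:
            pct_resp = percentage(count, n_cs_responsive)
        elif label == "non_responsive":
            pct_resp = float("nan")
        else:
            pct_resp, flag = 0.0, "zero_denominator"
        rows.append((label, count, pct_rec, pct_resp, flag))
    return pd.DataFrame(rows, columns=["label", "count", "pct_recorded",
                                       "pct_cs_responsive", "flag"])
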