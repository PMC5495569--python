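"""Whole-cell slice electrophysiology metrics.

Implements the standard synaptic-efficacy readouts from voltage-clamp sweep
data: paired-pulse ratio of evoked EPSCs (second / first peak of the averaged,
baseline-subtracted trace), AMPA/NMDA current ratio (|peak| of the averaged
trace at -70 mV over the averaged current exactly 50 ms after the stimulus at
+50 mV, where the fast AMPA component has decayed), miniature-event detection
on continuous traces (threshold crossings with a refractory minimum interval),
input-output slope (OLS line of mean |EPSC| amplitude vs stimulus intensity,
pA/uA), and the series-resistance stability gate (discard a cell if Rs changes
by more than 20% from its initial value).

All amplitudes are reported as magnitudes; the raw signed traces are kept in
the sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Sweep",
    "SweepSet",
    "MiniEventTable",
    "IOCurve",
    "average_sweeps",
    "paired_pulse_ratio",
    "ampa_nmda_ratio",
    "detect_minis",
    "io_slope",
    "sweep_qc",
    "sweeps_to_frame",
    "sweeps_from_frame",
]


@dataclass(frozen=True)
class Sweep:
    t_ms: np.ndarray
    i_pA: np.ndarray
    holding_mV: float | None = None
    stim_times_ms: tuple = ()
    intensity_uA: float | None = None
    series_resistance_Mohm: float | None = None

    def __post_init__(self):
        t = np.asarray(self.t_ms, dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0]):
                raise ValueError("sweep sampling must be uniform")
        if len(self.stim_times_ms) >= 2 and not all(
                a < b for a, b in zip(self.stim_times_ms, self.stim_times_ms[1:])):
            raise ValueError("stimulus times must be strictly increasing")


@dataclass(frozen=True)
class SweepSet:
    kind: str   # paired_pulse | dual_holding | io_series | continuous
    sweeps: tuple


@dataclass(frozen=True)
class MiniEventTable:
    times_ms: np.ndarray
    amplitudes_pA: np.ndarray     # magnitudes, > 0
    duration_s: float

    @property
    def frequency_hz(self) -> float:
        return self.times_ms.size / self.duration_s

    @property
    def mean_amplitude_pA(self) -> float:
        return float(self.amplitudes_pA.mean()) if self.amplitudes_pA.size else float("nan")

    def cumulative_amplitudes(self) -> np.ndarray:
        """Sorted amplitudes, ready for KS comparison of cumulative histograms."""
        return np.sort(self.amplitudes_pA)

    def inter_event_intervals_ms(self) -> np.ndarray:
        return np.diff(np.sort(self.times_ms))


@dataclass(frozen=True)
class IOCurve:
    points: pd.DataFrame          # intensity_uA, amplitude_pA
    slope_pA_per_uA: float
    intercept_pA: float


def average_sweeps(sweeps: Sequence[Sweep]) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise average of sweeps sharing a time base."""
    if not sweeps:
        raise ValueError("need at least one sweep")
    t0 = np.asarray(sweeps[0].t_ms, dtype=float)
    traces = []
    for sw in sweeps:
        t = np.asarray(sw.t_ms, dtype=float)
        if t.size != t0.size or not np.allclose(t, t0):
            raise ValueError("sweeps must share an identical time base")
        traces.append(np.asarray(sw.i_pA, dtype=float))
    return t0, np.mean(traces, axis=0)


def _baseline(t: np.ndarray, i: np.ndarray, before_ms: float) -> tuple[float, float]:
    """Mean and SD of the trace before ``before_ms``."""
    pre = i[t < before_ms]
    if pre.size == 0:
        return 0.0, 0.0
    return float(pre.mean()), float(pre.std())


def _peak_magnitude(t: np.ndarray, i: np.ndarray, lo_ms: float, hi_ms: float) -> float:
    seg = i[(t >= lo_ms) & (t < hi_ms)]
    if seg.size == 0:
        raise ValueError("empty peak-search window")
    return float(np.abs(seg).max())


def paired_pulse_ratio(sweepset: SweepSet, noise_floor_pA: float | None = None
                       ) -> tuple[float | None, dict]:
    """Second / first peak amplitude of the averaged paired-pulse trace.

    Sweeps are averaged, the pre-stimulus mean subtracted, and each peak
    searched from its pulse up to the next pulse (or trace end).  If the first
    peak does not clear the noise floor (default: 3x pre-stimulus SD of the
    averaged trace) the ratio is undefined and a reason is returned.
    """
    sweeps = sweepset.sweeps
    if not sweeps:
        raise ValueError("need at least one sweep")
    stims = sweeps[0].stim_times_ms
    if len(stims) != 2:
        raise ValueError("paired-pulse sweeps need exactly two stimulus times")
    t, avg = average_sweeps(sweeps)
    b_mean, b_sd = _baseline(t, avg, stims[0])
    sig = avg - b_mean
    floor = 3.0 * b_sd if noise_floor_pA is None else noise_floor_pA
    p1 = _peak_magnitude(t, sig, stims[0], stims[1])
    p2 = _peak_magnitude(t, sig, stims[1], t[-1] + (t[1] - t[0]))
    if p1 <= floor:
        return None, {"reason": "first_peak_below_noise", "p1": p1, "p2": p2,
                      "noise_floor_pA": floor}
    return p2 / p1, {"p1": p1, "p2": p2, "noise_floor_pA": floor}


def ampa_nmda_ratio(neg70: SweepSet | Sequence[Sweep],
                    pos50: SweepSet | Sequence[Sweep],
                    stim_time_ms: float, lag_ms: float = 50.0,
                    noise_floor_pA: float | None = None) -> tuple[float | None, dict]:
    """|peak| of the averaged -70 mV trace over the +50 mV current at stim+lag."""
    neg_sweeps = neg70.sweeps if isinstance(neg70, SweepSet) else tuple(neg70)
    pos_sweeps = pos50.sweeps if isinstance(pos50, SweepSet) else tuple(pos50)
    if not neg_sweeps or not pos_sweeps:
        raise ValueError("both holding potentials must be present")
    tn, avg_n = average_sweeps(neg_sweeps)
    tp, avg_p = average_sweeps(pos_sweeps)
    bn, _ = _baseline(tn, avg_n, stim_time_ms)
    bp, bp_sd = _baseline(tp, avg_p, stim_time_ms)
    numerator = _peak_magnitude(tn, avg_n - bn, stim_time_ms, tn[-1] + (tn[1] - tn[0]))
    target = stim_time_ms + lag_ms
    idx = int(np.argmin(np.abs(tp - target)))
    if abs(tp[idx] - target) > (tp[1] - tp[0]) / 2 + 1e-9:
        raise ValueError("sampling grid does not cover stim + lag")
    denominator = abs(float(avg_p[idx] - bp))
    floor = 3.0 * bp_sd if noise_floor_pA is None else noise_floor_pA
    if denominator <= floor:
        return None, {"reason": "nmda_component_below_noise",
                      "numerator_pA": numerator, "denominator_pA": denominator}
    return numerator / denominator, {"numerator_pA": numerator,
                                     "denominator_pA": denominator}


def detect_minis(t_ms: np.ndarray, i_pA: np.ndarray, threshold_pA: float,
                 min_interval_ms: float, polarity: int = -1) -> MiniEventTable:
    """Threshold-crossing miniature-event detection with a refractory interval.

    The trace median serves as baseline; events are peaks of the
    baseline-corrected, polarity-rectified trace exceeding ``threshold_pA``
    and separated by at least ``min_interval_ms``.  Amplitude is the peak
    excursion from baseline (magnitude).
    """
    if threshold_pA <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(t_ms, dtype=float)
    i = np.asarray(i_pA, dtype=float)
    duration_s = (t[-1] - t[0] + (t[1] - t[0])) / 1000.0
    if duration_s * 1000.0 <= min_interval_ms:
        raise ValueError("trace shorter than the minimum inter-event interval")
    dt = t[1] - t[0]
    signal = polarity * (i - np.median(i))
    distance = max(1, int(round(min_interval_ms / dt)))
    peaks, props = find_peaks(signal, height=threshold_pA, distance=distance)
    return MiniEventTable(t[peaks], props["peak_heights"].astype(float), duration_s)


def io_slope(data: SweepSet | pd.DataFrame, stim_time_ms: float | None = None
             ) -> IOCurve:
    """OLS input-output line: mean |EPSC| amplitude vs stimulus intensity.

    ``data`` is either an io_series SweepSet (peaks measured per sweep after
    baseline subtraction, then averaged per intensity) or a precomputed
    DataFrame with columns intensity_uA and amplitude_pA.
    """
    if isinstance(data, SweepSet):
        if stim_time_ms is None:
            stims = data.sweeps[0].stim_times_ms
            stim_time_ms = stims[0] if stims else 0.0
        rows = []
        for sw in data.sweeps:
            t = np.asarray(sw.t_ms, dtype=float)
            i = np.asarray(sw.i_pA, dtype=float)
            b, _ = _baseline(t, i, stim_time_ms)
            amp = _peak_magnitude(t, i - b, stim_time_ms, t[-1] + (t[1] - t[0]))
            rows.append((sw.intensity_uA, amp))
        points = (pd.DataFrame(rows, columns=["intensity_uA", "amplitude_pA"])
                  .groupby("intensity_uA", as_index=False).mean())
    else:
        points = data[["intensity_uA", "amplitude_pA"]].copy()
    if points["intensity_uA"].nunique() < 2:
        raise ValueError("need >= 2 distinct intensities for a slope")
    slope, intercept = np.polyfit(points["intensity_uA"], points["amplitude_pA"], 1)
    return IOCurve(points, float(slope), float(intercept))


def sweeps_to_frame(sweepsets: dict[str, SweepSet]) -> pd.DataFrame:
    """Long-format sweep table: sweep_id, kind, holding_mV, intensity_uA,
    stim_times_ms (semicolon-joined), series_resistance_Mohm, t_ms, i_pA."""
    frames = []
    for name, ss in sweepsets.items():
        for j, sw in enumerate(ss.sweeps):
            frames.append(pd.DataFrame({
                "sweep_id": f"{name}:{j:03d}", "kind": ss.kind,
                "holding_mV": sw.holding_mV if sw.holding_mV is not None else np.nan,
                "intensity_uA": sw.intensity_uA if sw.intensity_uA is not None else np.nan,
                "stim_times_ms": ";".join(f"{s:g}" for s in sw.stim_times_ms),
                "series_resistance_Mohm": (sw.series_resistance_Mohm
                                           if sw.series_resistance_Mohm is not None
                                           else np.nan),
                "t_ms": np.asarray(sw.t_ms, dtype=float),
                "i_pA": np.asarray(sw.i_pA, dtype=float)}))
    return pd.concat(frames, ignore_index=True)


def sweeps_from_frame(df: pd.DataFrame) -> dict[str, SweepSet]:
    """Inverse of :func:`sweeps_to_frame`, grouping by sweep-set prefix."""
    sets: dict[str, list[Sweep]] = {}
    kinds: dict[str, str] = {}
    for sid, grp in df.groupby("sweep_id", sort=False):
        grp = grp.sort_values("t_ms")
        name = str(sid).rsplit(":", 1)[0]
        first = grp.iloc[0]
        stims = tuple(float(s) for s in str(first["stim_times_ms"]).split(";")
                      if s not in ("", "nan"))
        sweep = Sweep(
            grp["t_ms"].to_numpy(), grp["i_pA"].to_numpy(),
            holding_mV=None if pd.isna(first["holding_mV"]) else float(first["holding_mV"]),
            stim_times_ms=stims,
            intensity_uA=(None if pd.isna(first["intensity_uA"])
                          else float(first["intensity_uA"])),
            series_resistance_Mohm=(None if pd.isna(first["series_resistance_Mohm"])
                                    else float(first["series_resistance_Mohm"])))
        sets.setdefault(name, []).append(sweep)
        kinds[name] = str(first["kind"])
    return {name: SweepSet(kinds[name], tuple(sw)) for name, sw in sets.items()}


def sweep_qc(series_resistances: Sequence[float], max_change: float = 0.20
             ) -> tuple[bool, float]:
    """Keep a cell iff |Rs_t - Rs_0| / Rs_0 never exceeds ``max_change``.

    Returns (keep, max_fractional_change); strictly greater than the limit
    discards, so exactly 20% is kept.
    """
    rs = np.asarray(series_resistances, dtype=float)
    if rs.size < 2:
        raise ValueError("need >= 2 series-resistance readings")
    if (rs <= 0).any():
        raise ValueError("series resistance must be positive")
    frac = np.abs(rs - rs[0]) / rs[0]
    worst = float(frac.max())
    return worst <= max_change, worst
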