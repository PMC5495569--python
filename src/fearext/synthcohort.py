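"""Synthetic fear-conditioning / extinction cohorts with planted ground truth.

Generates everything the downstream analysis chain consumes, without any
external data: multi-session protocols (habituation, conditioning, extinction
1-3, retention test), inhomogeneous-Poisson spike trains whose CS-evoked rate
modulation follows planted neuron phenotypes, per-session waveform templates
with controllable inter-session drift, binary immobility traces whose scored
freezing matches planted per-session targets, and voltage-clamp sweep sets
encoding planted paired-pulse ratios, AMPA/NMDA ratios, input-output slopes
and miniature-event statistics.

Protocol presets mirror the three experimental variants: ``recording``
(0.5 mA / 0.5 s footshock, 5 CS/US pairings, 20-CS first extinction),
``slice`` (1 mA / 1 s, 3 pairings, extinction 2 and 3 with 15 CSs) and
``lesion`` (0.4 mA / 1 s, 4 pairings).

Determinism: a single global seed fans out to per-unit / per-rat / per-stage
substreams through stable CRC-32 tag hashing, so identical (config, seed)
yields byte-identical tables and adding a unit does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .slice_ephys import Sweep, SweepSet

__all__ = [
    "PipSpec",
    "SessionSpec",
    "SessionPlan",
    "NeuronSpec",
    "UnitData",
    "SlicePlant",
    "SliceData",
    "make_session_plan",
    "recall_epochs",
    "make_events",
    "epoch_event_times",
    "make_neuron_spec",
    "simulate_unit",
    "sample_snippets",
    "default_freezing_targets",
    "simulate_freezing",
    "simulate_slice_data",
    "substream",
]

SESSION_LABELS = ("Hab", "Cond", "Ext1", "Ext2", "Ext3", "Test")


def substream(seed: int, *tags) -> np.random.Generator:
    """Independent generator for (seed, tags), stable under cohort changes."""
    keys = [int(seed) & 0x7FFFFFFF]
    keys += [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(keys))


# ---------------------------------------------------------------------------
# Session plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipSpec:
    n_pips: int = 27
    pip_duration_ms: float = 200.0
    pip_rate_hz: float = 0.9


@dataclass(frozen=True)
class SessionSpec:
    label: str
    n_cs: int
    cs_duration_s: float = 30.0
    iti_s: tuple = (80.0, 120.0)
    us: tuple | None = None      # (amplitude_mA, duration_s)


@dataclass(frozen=True)
class SessionPlan:
    sessions: tuple
    alignment: str = "tone"          # "tone" | "pip"
    pip_spec: PipSpec | None = None
    retention_window: int = 5

    def __post_init__(self):
        labels = [s.label for s in self.sessions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate session labels")
        for s in self.sessions:
            # only sessions probed as recall epochs need the leading-CS window;
            # Hab is its own epoch and Cond CSs are conditioning trials
            if s.label not in ("Hab", "Cond") and s.n_cs < self.retention_window:
                raise ValueError(
                    f"session {s.label}: n_cs < retention_window")
            if s.us is not None and s.label != "Cond":
                raise ValueError("US allowed only in Cond")
        if (self.alignment == "pip") != (self.pip_spec is not None):
            raise ValueError("pip_spec must be present iff alignment is 'pip'")

    def session(self, label: str) -> SessionSpec:
        for s in self.sessions:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.sessions)


_PRESETS = {
    "recording": dict(
        sessions=[("Hab", 5, None), ("Cond", 5, (0.5, 0.5)), ("Ext1", 20, None),
                  ("Ext2", 20, None), ("Ext3", 20, None), ("Test", 5, None)],
        iti=(80.0, 120.0)),
    "slice": dict(
        sessions=[("Cond", 3, (1.0, 1.0)), ("Ext1", 20, None),
                  ("Ext2", 15, None), ("Ext3", 15, None)],
        iti=(100.0, 100.0)),
    "lesion": dict(
        sessions=[("Cond", 4, (0.4, 1.0)), ("Ext1", 20, None),
                  ("Ext2", 20, None), ("Ext3", 20, None), ("Test", 5, None)],
        iti=(100.0, 100.0)),
}

_OVERRIDE_KEYS = {"alignment", "pip_spec", "retention_window", "cs_duration_s",
                  "iti_s", "n_cs", "us"}


def make_session_plan(preset: str, overrides: Mapping | None = None) -> SessionPlan:
    """Build a protocol plan from a preset, with field-level overrides.

    Override keys: ``alignment`` ('tone'/'pip'; switching to 'pip' installs the
    default 27-pip spec), ``pip_spec``, ``retention_window``, ``cs_duration_s``,
    ``iti_s``, ``n_cs`` ({session: count}), ``us`` ({session: (mA, s) or None}).
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    cfg = _PRESETS[preset]
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise KeyError(f"unknown override keys: {sorted(unknown)}")

    cs_dur = float(overrides.get("cs_duration_s", 30.0))
    iti = tuple(overrides.get("iti_s", cfg["iti"]))
    n_cs_over = dict(overrides.get("n_cs", {}))
    us_over = dict(overrides.get("us", {}))

    sessions = []
    for label, n_cs, us in cfg["sessions"]:
        n = int(n_cs_over.pop(label, n_cs))
        u = us_over.pop(label, us)
        sessions.append(SessionSpec(label, n, cs_dur, iti, u))
    if n_cs_over:
        raise KeyError(f"n_cs override for unknown sessions: {sorted(n_cs_over)}")
    if us_over:
        raise KeyError(f"us override for unknown sessions: {sorted(us_over)}")

    alignment = overrides.get("alignment", "tone")
    pip_spec = overrides.get("pip_spec")
    if alignment == "pip" and pip_spec is None:
        pip_spec = PipSpec()
    if alignment == "tone":
        pip_spec = None
    return SessionPlan(tuple(sessions), alignment, pip_spec,
                       int(overrides.get("retention_window", 5)))


def recall_epochs(plan: SessionPlan) -> list[tuple[str, str, np.ndarray]]:
    """(epoch label, session label, CS indices) for every recall epoch.

    The leading ``retention_window`` CSs of each post-conditioning session act
    as the retention test of the previous session's learning (post-Cond,
    post-Ext1, ...); the habituation session is its own epoch.
    """
    out = []
    labels = plan.labels
    for i, s in enumerate(plan.sessions):
        if s.label == "Hab":
            out.append(("Hab", "Hab", np.arange(min(plan.retention_window, s.n_cs))))
        elif s.label == "Cond":
            continue
        else:
            prev = labels[i - 1]
            out.append((f"post-{prev}", s.label, np.arange(plan.retention_window)))
    return out


# ---------------------------------------------------------------------------
# Event schedules
# ---------------------------------------------------------------------------

def make_events(plan: SessionPlan, seed: int) -> pd.DataFrame:
    """CS / pip / US onset schedule, session-local clock (seconds).

    Columns: session, cs_index, onset_s, kind in {tone, pip, us}.
    """
    rows = []
    for s in plan.sessions:
        rng = substream(seed, "events", s.label)
        t = 60.0  # settling time before the first CS
        for k in range(s.n_cs):
            rows.append((s.label, k, t, "tone"))
            if plan.alignment == "pip":
                period = 1.0 / plan.pip_spec.pip_rate_hz
                for j in range(plan.pip_spec.n_pips):
                    rows.append((s.label, k, t + j * period, "pip"))
            if s.us is not None:
                rows.append((s.label, k, t + s.cs_duration_s - s.us[1], "us"))
            t += s.cs_duration_s + rng.uniform(*s.iti_s)
    return pd.DataFrame(rows, columns=["session", "cs_index", "onset_s", "kind"])


def epoch_event_times(events: pd.DataFrame, plan: SessionPlan
                      ) -> dict[str, dict[str, np.ndarray]]:
    """Per-epoch tone (and pip) onset times, for profiling and PETHs."""
    out = {}
    for epoch, session, cs_idx in recall_epochs(plan):
        sel = events[(events["session"] == session)
                     & (events["cs_index"].isin(cs_idx))]
        entry = {"tones": sel[sel["kind"] == "tone"]["onset_s"].to_numpy()}
        if plan.alignment == "pip":
            entry["pips"] = sel[sel["kind"] == "pip"]["onset_s"].to_numpy()
        out[epoch] = entry
    return out


# ---------------------------------------------------------------------------
# Units: spikes and waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronSpec:
    unit_id: str
    phenotype: str                     # fear | extinction | session_selective | non_responsive
    baseline_rate_hz: float
    evoked_rate_hz: Mapping[str, float]   # one entry per session in the plan
    response_latency_ms: float = 10.0
    response_duration_ms: float = 50.0
    target_epoch: str | None = None    # for session_selective

    def validate(self, plan: SessionPlan) -> None:
        if self.baseline_rate_hz < 0 or any(v < 0 for v in self.evoked_rate_hz.values()):
            raise ValueError("rates must be non-negative")
        missing = set(plan.labels) - set(self.evoked_rate_hz)
        if missing:
            raise ValueError(f"evoked_rate_hz missing sessions: {sorted(missing)}")


@dataclass(frozen=True)
class UnitData:
    spec: NeuronSpec
    spikes: pd.DataFrame        # unit_id, session, t_s
    templates: Mapping[str, np.ndarray]
    events: pd.DataFrame


# epoch in which each phenotype is CS-active -> the session housing that epoch
def _active_session(phenotype: str, plan: SessionPlan, target_epoch: str | None) -> str | None:
    epochs = {e: s for e, s, _ in recall_epochs(plan)}
    if phenotype == "fear":
        return epochs.get("post-Cond")
    if phenotype == "extinction":
        return epochs.get("post-Ext1")
    if phenotype == "session_selective":
        if target_epoch not in epochs:
            raise ValueError(f"unknown target epoch {target_epoch!r}")
        return epochs[target_epoch]
    if phenotype == "non_responsive":
        return None
    raise ValueError(f"unknown phenotype {phenotype!r}")


def make_neuron_spec(unit_id: str, phenotype: str, plan: SessionPlan,
                     baseline_rate_hz: float = 8.0, modulation: float = 10.0,
                     response_latency_ms: float = 10.0,
                     response_duration_ms: float = 50.0,
                     target_epoch: str | None = None) -> NeuronSpec:
    """NeuronSpec whose evoked-rate map mirrors a planted phenotype.

    The active session carries ``modulation`` x baseline evoked rate; all
    other sessions stay at baseline.
    """
    active = _active_session(phenotype, plan, target_epoch)
    evoked = {lab: baseline_rate_hz for lab in plan.labels}
    if active is not None:
        evoked[active] = modulation * baseline_rate_hz
    return NeuronSpec(unit_id, phenotype, baseline_rate_hz, evoked,
                      response_latency_ms, response_duration_ms, target_epoch)


def _session_spikes(rng: np.random.Generator, total_s: float, base_hz: float,
                    window_starts: np.ndarray, window_s: float,
                    evoked_hz: float) -> np.ndarray:
    """Piecewise-constant-rate Poisson process via superposition / thinning."""
    spikes = []
    if base_hz > 0:
        n = rng.poisson(base_hz * total_s)
        t = rng.uniform(0.0, total_s, n)
        if evoked_hz < base_hz and window_starts.size:
            idx = np.searchsorted(window_starts, t, side="right") - 1
            in_win = (idx >= 0) & (t < window_starts[np.clip(idx, 0, None)] + window_s)
            keep = ~in_win | (rng.uniform(size=t.size) < evoked_hz / base_hz)
            t = t[keep]
        spikes.append(t)
    if evoked_hz > base_hz and window_starts.size:
        extra = rng.poisson((evoked_hz - base_hz) * window_s * window_starts.size)
        w = rng.integers(0, window_starts.size, extra)
        spikes.append(window_starts[w] + rng.uniform(0.0, window_s, extra))
    if not spikes:
        return np.empty(0)
    return np.sort(np.concatenate(spikes))


def _base_template(rng: np.random.Generator, n_samples: int = 32) -> np.ndarray:
    """Extracellular-like biphasic waveform, microvolts."""
    amp = rng.uniform(80.0, 200.0)
    t = np.arange(n_samples, dtype=float)
    shape = -np.exp(-((t - 10.0) / 2.2) ** 2) + 0.45 * np.exp(-((t - 18.0) / 4.5) ** 2)
    return amp * shape / np.abs(shape).max()


def _drift_templates(base: np.ndarray, n_sessions: int, r: float,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Session templates with exact consecutive Pearson correlation ``r``."""
    mu, scale = base.mean(), np.linalg.norm(base - base.mean())
    cur = (base - mu) / scale
    out = [base.copy()]
    for _ in range(n_sessions - 1):
        if r >= 1.0:
            out.append(out[-1].copy())
            continue
        g = rng.standard_normal(base.size)
        g -= g.mean()
        g -= (g @ cur) * cur
        g /= np.linalg.norm(g)
        cur = r * cur + np.sqrt(1.0 - r * r) * g
        cur /= np.linalg.norm(cur)   # guard drift of norm
        out.append(mu + scale * cur)
    return out


def simulate_unit(spec: NeuronSpec, plan: SessionPlan, seed: int,
                  events: pd.DataFrame | None = None,
                  template_r: float = 1.0) -> UnitData:
    """Spike trains and per-session waveform templates for one unit.

    Spikes follow an inhomogeneous Poisson process: baseline rate everywhere,
    elevated (or suppressed) to the session's evoked rate inside
    ``[latency, latency + duration]`` after every aligned event (tone onsets
    in tone mode, pip onsets in pip mode).  ``template_r`` plants the exact
    Pearson correlation between consecutive-session templates.
    """
    if not plan.sessions:
        raise ValueError("empty plan")
    spec.validate(plan)
    if events is None:
        events = make_events(plan, seed)
    align_kind = "pip" if plan.alignment == "pip" else "tone"
    window_s = spec.response_duration_ms / 1000.0
    lat_s = spec.response_latency_ms / 1000.0

    frames = []
    for s in plan.sessions:
        ev = events[events["session"] == s.label]
        onsets = np.sort(ev[ev["kind"] == align_kind]["onset_s"].to_numpy())
        tones = ev[ev["kind"] == "tone"]["onset_s"].to_numpy()
        total = float(tones.max() + s.cs_duration_s + 60.0) if tones.size else 120.0
        rng = substream(seed, "spikes", spec.unit_id, s.label)
        t = _session_spikes(rng, total, spec.baseline_rate_hz, onsets + lat_s,
                            window_s, spec.evoked_rate_hz[s.label])
        frames.append(pd.DataFrame({"unit_id": spec.unit_id,
                                    "session": s.label, "t_s": t}))
    spikes = pd.concat(frames, ignore_index=True)

    wf_rng = substream(seed, "waveform", spec.unit_id)
    base = _base_template(wf_rng)
    templates = dict(zip(plan.labels,
                         _drift_templates(base, len(plan.sessions), template_r, wf_rng)))
    return UnitData(spec, spikes, templates, events)


def sample_snippets(template: np.ndarray, n_spikes: int, noise_sd_uv: float,
                    seed: int, tag: str = "") -> np.ndarray:
    """Noisy spike snippets around a template (n_spikes x n_samples)."""
    rng = substream(seed, "snippets", tag)
    return template[None, :] + rng.normal(0.0, noise_sd_uv,
                                          (n_spikes, template.size))


# ---------------------------------------------------------------------------
# Freezing traces
# ---------------------------------------------------------------------------

def default_freezing_targets(plan: SessionPlan, recall: str = "successful"
                             ) -> dict[str, tuple[float, float]]:
    """Per-session (mean, SD) freezing targets emulating extinction dynamics.

    Conditioned freezing rises with conditioning and progressively decreases
    over the extinction sessions; ``poor`` recall rats stay high after the
    first extinction session.
    """
    if recall == "successful":
        tbl = {"Hab": (5.0, 3.0), "Cond": (40.0, 10.0), "Ext1": (65.0, 10.0),
               "Ext2": (25.0, 8.0), "Ext3": (15.0, 6.0), "Test": (10.0, 5.0)}
    elif recall == "poor":
        tbl = {"Hab": (5.0, 3.0), "Cond": (45.0, 10.0), "Ext1": (70.0, 10.0),
               "Ext2": (65.0, 8.0), "Ext3": (55.0, 8.0), "Test": (50.0, 8.0)}
    else:
        raise ValueError(f"unknown recall class {recall!r}")
    return {lab: tbl[lab] for lab in plan.labels}


def simulate_freezing(rat_id: str, targets: Mapping[str, tuple[float, float]],
                      plan: SessionPlan, seed: int, dt_s: float = 0.1,
                      min_bout_s: float = 2.0) -> pd.DataFrame:
    """Binary immobility traces per CS whose scored freezing hits the target.

    For each CS a freezing percentage is drawn from the session's
    (mean, SD) target, converted to a frozen duration on the ``dt_s`` grid,
    and realized as immobility bouts each at least ``min_bout_s`` long, so the
    2-s scoring rule recovers the drawn value exactly.  Drawn durations below
    one bout score zero.
    """
    for lab, (m, sd) in targets.items():
        if not (0.0 <= m <= 100.0) or sd < 0:
            raise ValueError(f"target for {lab} outside [0, 100]")
    rows = []
    min_steps = int(round(min_bout_s / dt_s))
    for s in plan.sessions:
        mean, sd = targets[s.label]
        n = int(round(s.cs_duration_s / dt_s))
        rng = substream(seed, "freezing", rat_id, s.label)
        for k in range(s.n_cs):
            target = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
            d = int(round(target / 100.0 * n))
            trace = np.zeros(n, dtype=int)
            if d >= n:
                trace[:] = 1
            elif d >= min_steps:
                nb = int(rng.integers(1, max(1, d // (2 * min_steps)) + 1))
                bouts = min_steps + rng.multinomial(d - nb * min_steps,
                                                    np.full(nb, 1.0 / nb))
                gaps = rng.multinomial(n - d, np.full(nb + 1, 1.0 / (nb + 1)))
                pos = 0
                for b, g in zip(bouts, gaps):
                    pos += g
                    trace[pos:pos + b] = 1
                    pos += b
            rows.append(pd.DataFrame({
                "rat_id": rat_id, "session": s.label, "cs_index": k,
                "t_s": np.round(np.arange(n) * dt_s, 6), "immobile": trace}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Slice sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceData:
    """Generated sweep sets plus the planted ground truth they encode."""

    sweepsets: Mapping[str, SweepSet]
    planted: "SlicePlant"
    planted_mini_times_ms: np.ndarray

    def __getitem__(self, kind: str) -> SweepSet:
        return self.sweepsets[kind]


@dataclass(frozen=True)
class SlicePlant:
    """Planted ground-truth synaptic metrics."""

    ppr: float = 0.8
    ampa_nmda: float = 2.0
    io_slope_pA_per_uA: float = 5.28
    io_intercept_pA: float = 0.0
    mini_rate_hz: float = 5.0
    mini_amp_pA: float = 30.0
    mini_amp_sd_pA: float = 5.0
    epsc1_pA: float = 150.0

    def __post_init__(self):
        if self.ppr <= 0 or self.ampa_nmda <= 0:
            raise ValueError("planted ratios must be positive")


def _epsc(t_ms: np.ndarray, onset_ms: float, amp_pA: float,
          width_ms: float = 20.0) -> np.ndarray:
    """Finite-support EPSC transient (sin^2 pulse), peak exactly amp at mid-width."""
    x = (t_ms - onset_ms) / width_ms
    inside = (x >= 0.0) & (x <= 1.0)
    out = np.zeros_like(t_ms)
    out[inside] = amp_pA * np.sin(np.pi * x[inside]) ** 2
    return out


def _nmda(t_ms: np.ndarray, onset_ms: float, value_at_lag_pA: float,
          lag_ms: float = 50.0, tau_rise: float = 5.0, tau_decay: float = 80.0
          ) -> np.ndarray:
    s = t_ms - onset_ms
    kern = np.where(s >= 0, np.exp(-s / tau_decay) - np.exp(-s / tau_rise), 0.0)
    norm = np.exp(-lag_ms / tau_decay) - np.exp(-lag_ms / tau_rise)
    return value_at_lag_pA / norm * kern


def simulate_slice_data(planted: SlicePlant | None = None,
                        noise_sd_pA: float = 2.0, seed: int = 0,
                        n_sweeps: int = 20,
                        intensities_uA: Sequence[float] | None = None,
                        io_noise_sd_pA: float = 5.0,
                        continuous_duration_s: float = 120.0,
                        rs_base_Mohm: float = 10.0,
                        rs_drift_frac: float = 0.0) -> SliceData:
    """Sweep sets for every recording kind, encoding the planted metrics.

    With ``noise_sd_pA = 0`` the paired-pulse and AMPA/NMDA round trips are
    exact (finite-support EPSC kernels, grid-aligned peaks).  Inward currents
    are negative; the analysis reports magnitudes.
    """
    planted = planted or SlicePlant()
    if intensities_uA is None:
        intensities_uA = np.arange(10.0, 101.0, 10.0)
    rng = substream(seed, "slice")
    dt = 0.1
    t = np.round(np.arange(0.0, 250.0, dt), 6)

    def rs(i, total):
        return rs_base_Mohm * (1.0 + rs_drift_frac * i / max(total - 1, 1))

    # paired pulses, 50-ms inter-pulse interval
    pp = []
    stims = (100.0, 150.0)
    for i in range(n_sweeps):
        trace = (-_epsc(t, stims[0], planted.epsc1_pA)
                 - _epsc(t, stims[1], planted.epsc1_pA * planted.ppr))
        trace = trace + rng.normal(0.0, noise_sd_pA, t.size) if noise_sd_pA > 0 else trace
        pp.append(Sweep(t, trace, holding_mV=-70.0, stim_times_ms=stims,
                        series_resistance_Mohm=rs(i, n_sweeps)))

    # dual holding potential
    neg, pos = [], []
    nmda_at_lag = planted.epsc1_pA / planted.ampa_nmda
    for i in range(n_sweeps):
        tr_n = -_epsc(t, 100.0, planted.epsc1_pA)
        tr_p = _epsc(t, 100.0, 0.5 * planted.epsc1_pA) + _nmda(t, 100.0, nmda_at_lag)
        if noise_sd_pA > 0:
            tr_n = tr_n + rng.normal(0.0, noise_sd_pA, t.size)
            tr_p = tr_p + rng.normal(0.0, noise_sd_pA, t.size)
        neg.append(Sweep(t, tr_n, holding_mV=-70.0, stim_times_ms=(100.0,),
                         series_resistance_Mohm=rs(i, n_sweeps)))
        pos.append(Sweep(t, tr_p, holding_mV=50.0, stim_times_ms=(100.0,),
                         series_resistance_Mohm=rs(i, n_sweeps)))

    # input-output series
    io = []
    n_io_sweeps = 5
    for inten in intensities_uA:
        for i in range(n_io_sweeps):
            amp = (planted.io_slope_pA_per_uA * inten + planted.io_intercept_pA
                   + (rng.normal(0.0, io_noise_sd_pA) if io_noise_sd_pA > 0 else 0.0))
            trace = -_epsc(t, 100.0, max(amp, 0.0))
            if noise_sd_pA > 0:
                trace = trace + rng.normal(0.0, noise_sd_pA, t.size)
            io.append(Sweep(t, trace, holding_mV=-70.0, stim_times_ms=(100.0,),
                            intensity_uA=float(inten)))

    # continuous trace with miniature events
    dt_c = 1.0
    tc = np.arange(0.0, continuous_duration_s * 1000.0, dt_c)
    n_events = rng.poisson(planted.mini_rate_hz * continuous_duration_s)
    times = np.sort(rng.uniform(0.0, continuous_duration_s * 1000.0 - 20.0, n_events))
    amps = np.clip(rng.normal(planted.mini_amp_pA, planted.mini_amp_sd_pA, n_events),
                   a_min=planted.mini_amp_pA / 3.0, a_max=None)
    trace = np.zeros_like(tc)
    for t0, a in zip(times, amps):
        i0 = int(t0 / dt_c)
        seg = _epsc(tc[i0:i0 + 12], tc[i0], a, width_ms=10.0)
        trace[i0:i0 + seg.size] -= seg
    if noise_sd_pA > 0:
        trace = trace + rng.normal(0.0, noise_sd_pA, tc.size)
    cont = Sweep(tc, trace, holding_mV=-70.0)

    sweepsets = {
        "paired_pulse": SweepSet("paired_pulse", tuple(pp)),
        "dual_holding_neg70": SweepSet("dual_holding", tuple(neg)),
        "dual_holding_pos50": SweepSet("dual_holding", tuple(pos)),
        "io_series": SweepSet("io_series", tuple(io)),
        "continuous": SweepSet("continuous", (cont,)),
    }
    return SliceData(sweepsets, planted, times)
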