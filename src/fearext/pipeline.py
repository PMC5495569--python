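"""End-to-end orchestration: simulate -> QC -> PETH -> classify -> stats -> report.

``run_experiment`` generates a synthetic cohort from a :class:`RunConfig`,
scores freezing and assigns recall groups, applies the waveform-stability
gate, builds per-epoch z-PETHs and responsiveness profiles for the surviving
units, types the neurons, summarizes the population composition, runs the
statistics battery on the figure-level summaries, and writes a plain
TSV/JSON report bundle.  Every stage is a pure function of (config, seed):
rerunning with the same config yields byte-identical files.  Records dropped
by a filter are logged with a reason code and the per-stage counts always
satisfy input = output + dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, classify, stats, synthcohort, unitqc

__all__ = ["RunConfig", "run_experiment"]

log = logging.getLogger("fearext.pipeline")

_EPOCH_ORDER = classify.RECALL_EPOCHS


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one synthetic experiment."""

    preset: str = "recording"
    alignment: str = "pip"
    n_rats_successful: int = 14
    n_rats_poor: int = 5
    n_units: int = 130
    n_fear: int = 8
    n_extinction: int = 6
    n_session_selective: int = 21
    n_unstable: int = 0
    unstable_template_r: float = 0.90
    baseline_rate_hz: float = 8.0
    modulation: float = 10.0
    alpha: float = 0.05
    latency_z: float = 3.0
    min_abs_z: float | None = 3.0
    r_threshold: float = 0.97
    recall_level: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if self.alignment not in ("tone", "pip"):
            raise ValueError("alignment must be 'tone' or 'pip'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")
        if not 0 < self.recall_level < 1:
            raise ValueError("recall_level outside (0, 1)")
        planted = self.n_fear + self.n_extinction + self.n_session_selective
        if planted + self.n_unstable > self.n_units:
            raise ValueError("phenotype mix exceeds the number of units")
        if self.baseline_rate_hz < 0 or self.modulation < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold outside (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _unit_specs(cfg: RunConfig, plan) -> list:
    """Planted phenotype mix; session-selective targets avoid the fear and
    extinction signature epochs so the planted label round-trips."""
    specs = []
    selective_targets = [e for e in _EPOCH_ORDER if e not in ("post-Cond", "post-Ext1")]
    idx = 0

    def add(phenotype, count, target=None):
        nonlocal idx
        for _ in range(count):
            specs.append(synthcohort.make_neuron_spec(
                f"u{idx:03d}", phenotype, plan,
                baseline_rate_hz=cfg.baseline_rate_hz, modulation=cfg.modulation,
                target_epoch=target))
            idx += 1

    add("fear", cfg.n_fear)
    add("extinction", cfg.n_extinction)
    for i in range(cfg.n_session_selective):
        add("session_selective", 1, target=selective_targets[i % len(selective_targets)])
    add("non_responsive",
        cfg.n_units - cfg.n_fear - cfg.n_extinction - cfg.n_session_selective)
    return specs


def _latency_epoch(label: str, target: str | None) -> str | None:
    if label == "fear":
        return "post-Cond"
    if label == "extinction":
        return "post-Ext1"
    if label == "session_selective":
        return target
    return None


def run_experiment(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full chain; returns the in-memory bundle, optionally writes it."""
    cfg = config
    plan = synthcohort.make_session_plan(
        cfg.preset, {"alignment": cfg.alignment} if cfg.alignment == "pip" else None)
    events = synthcohort.make_events(plan, cfg.seed)
    epoch_events = synthcohort.epoch_event_times(events, plan)
    mode = plan.alignment
    zwin = (0.0, 100.0) if mode == "pip" else (0.0, 400.0)
    provenance: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    # ---- behaviour -------------------------------------------------------
    log.info("stage freezing: %d rats", cfg.n_rats_successful + cfg.n_rats_poor)
    frames = []
    for i in range(cfg.n_rats_successful + cfg.n_rats_poor):
        recall = "successful" if i < cfg.n_rats_successful else "poor"
        rat = f"rat{i:02d}"
        targets = synthcohort.default_freezing_targets(plan, recall)
        movement = synthcohort.simulate_freezing(rat, targets, plan, cfg.seed)
        frames.append(behavior.score_movement_table(
            movement, cs_duration_s=plan.sessions[0].cs_duration_s))
    freezing = pd.concat(frames, ignore_index=True)

    ext2_like = next(s for e, s, _ in synthcohort.recall_epochs(plan)
                     if e == "post-Ext1")
    post_ext1 = behavior.recall_epoch_freezing(freezing, ext2_like,
                                               plan.retention_window)
    groups, threshold = behavior.assign_recall_groups(post_ext1, cfg.recall_level)
    groups_df = pd.DataFrame(
        [(g.rat_id, g.group, round(g.threshold_pct, 4)) for g in groups],
        columns=["rat_id", "group", "threshold_pct"])
    provenance["stages"]["behavior"] = {
        "n_rats": len(groups), "threshold_pct": round(threshold, 4),
        "n_successful": sum(g.group == "successful" for g in groups)}

    # ---- units: simulate, stability gate, profile, classify -------------
    specs = _unit_specs(cfg, plan)
    qc_rows, profile_rows, type_rows = [], [], []
    zmatrix: dict[str, dict[str, float]] = {}
    n_dropped = 0
    for i, spec in enumerate(specs):
        planted_unstable = i >= len(specs) - cfg.n_unstable
        template_r = cfg.unstable_template_r if planted_unstable else 1.0
        unit = synthcohort.simulate_unit(spec, plan, cfg.seed, events=events,
                                         template_r=template_r)
        stab = unitqc.template_stability(unit.templates, spec.unit_id,
                                         threshold=cfg.r_threshold)
        qc_rows.append((spec.unit_id, spec.phenotype,
                        round(min(stab.template_r), 6) if stab.template_r else 1.0,
                        stab.stable, stab.reason or ""))
        if not stab.stable:
            n_dropped += 1
            log.info("unit %s dropped: %s", spec.unit_id, stab.reason)
            continue
        # session clocks are local, so each epoch is profiled against the
        # spikes of the session it lives in
        spikes_by_session = {s: g["t_s"].to_numpy()
                             for s, g in unit.spikes.groupby("session", sort=False)}
        profile, zpeths = _profile_unit(spec.unit_id, spikes_by_session, plan,
                                        epoch_events, mode, cfg.alpha)
        ntype = classify.classify_neuron(profile, min_abs_z=cfg.min_abs_z)
        lat_epoch = _latency_epoch(ntype.label, ntype.target)
        latency = None
        if lat_epoch is not None and not zpeths[lat_epoch].degenerate:
            latency = classify.response_latency(zpeths[lat_epoch],
                                                criterion_z=cfg.latency_z,
                                                window_ms=zwin)
        type_rows.append((spec.unit_id, spec.phenotype, ntype.label,
                          ntype.target or "", "" if latency is None else latency))
        zmatrix[spec.unit_id] = {}
        for epoch in profile.epochs:
            r = profile.epochs[epoch]
            profile_rows.append((
                spec.unit_id, epoch, r.responsive, r.sign, round(r.p_value, 8),
                round(r.mean_window_z, 6) if np.isfinite(r.mean_window_z) else "",
                round(r.peak_window_z, 6) if np.isfinite(r.peak_window_z) else ""))
            zmatrix[spec.unit_id][epoch] = r.mean_window_z

    qc_df = pd.DataFrame(qc_rows, columns=["unit_id", "phenotype", "min_template_r",
                                           "stable", "reason"])
    profiles_df = pd.DataFrame(profile_rows, columns=[
        "unit_id", "epoch", "responsive", "sign", "p_value", "mean_window_z",
        "peak_window_z"])
    types_df = pd.DataFrame(type_rows, columns=[
        "unit_id", "planted", "label", "target", "latency_ms"])
    n_stable = len(specs) - n_dropped
    provenance["stages"]["unitqc"] = {
        "n_in": len(specs), "n_out": n_stable, "n_dropped": n_dropped,
        "drop_reason_counts": qc_df[~qc_df["stable"]]["reason"]
        .value_counts().to_dict()}

    composition = classify.cohort_summary(
        [classify.NeuronType(r[0], r[2], r[3] or None) for r in type_rows],
        n_recorded=n_stable)
    provenance["stages"]["classify"] = {
        "n_recorded": n_stable,
        "n_cs_responsive": int((types_df["label"] != "non_responsive").sum())}

    # ---- statistics battery ---------------------------------------------
    stat_results = {}
    epoch_freezing = {}
    for epoch, sess, _ in synthcohort.recall_epochs(plan):
        epoch_freezing[epoch] = behavior.recall_epoch_freezing(
            freezing, sess, plan.retention_window)
    fz = pd.DataFrame(epoch_freezing).dropna()
    if fz.shape[1] >= 3 and fz.shape[0] >= 2:
        res = stats.friedman(fz.to_numpy())
        stat_results["freezing_friedman"] = _result_dict(res)
        post = stats.dunn_bky(fz.to_numpy(), design="repeated",
                              labels=list(fz.columns))
        stat_results["freezing_dunn_bky"] = _posthoc_dict(post)

    for label in ("fear", "extinction"):
        cells = types_df[types_df["label"] == label]["unit_id"]
        mat = _z_matrix(zmatrix, cells)
        if mat is not None and mat.shape[0] >= 2:
            res = stats.friedman(mat)
            stat_results[f"{label}_z_friedman"] = _result_dict(res)

    all_mat = _z_matrix(zmatrix, types_df["unit_id"])
    if all_mat is not None and all_mat.shape[0] >= 2:
        res = stats.rm_anova1(all_mat)
        stat_results["population_z_rm_anova"] = _result_dict(res)

    bundle = {"plan": plan, "freezing": freezing, "groups": groups_df,
              "unit_qc": qc_df, "profiles": profiles_df, "types": types_df,
              "composition": composition, "stats": stat_results,
              "provenance": provenance}
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _profile_unit(unit_id, spikes_by_session, plan, epoch_events, mode, alpha):
    """Profile each epoch against the spikes of the session it belongs to."""
    profile_epochs = {}
    zpeths = {}
    for epoch, sess, _ in synthcohort.recall_epochs(plan):
        spikes = spikes_by_session.get(sess, np.empty(0))
        prof, zp = classify.build_profile(
            unit_id, spikes, {epoch: epoch_events[epoch]}, mode=mode, alpha=alpha)
        profile_epochs[epoch] = prof.epochs[epoch]
        zpeths[epoch] = zp[epoch]
    return classify.ResponsivenessProfile(unit_id, profile_epochs), zpeths


def _z_matrix(zmatrix, unit_ids):
    rows = []
    for uid in unit_ids:
        vals = [zmatrix[uid].get(e, np.nan) for e in _EPOCH_ORDER]
        if all(np.isfinite(v) for v in vals):
            rows.append(vals)
    return np.array(rows) if rows else None


def _result_dict(res: stats.TestResult) -> dict:
    return {"test": res.name, "statistic": round(res.statistic, 4),
            "df": res.df, "p_value": round(res.p_value, 6), "n": list(res.n)}


def _posthoc_dict(table: stats.PosthocTable) -> dict:
    return {"method": table.method, "level": table.level,
            "comparisons": [{"pair": list(c.pair), "statistic": round(c.statistic, 4),
                             "p_raw": round(c.p_raw, 6), "significant": c.significant}
                            for c in table.comparisons]}


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    kwargs = dict(sep="\t", index=False, float_format="%.10g")
    bundle["freezing"].to_csv(outdir / "freezing.tsv", **kwargs)
    bundle["groups"].to_csv(outdir / "groups.tsv", **kwargs)
    bundle["unit_qc"].to_csv(outdir / "unit_qc.tsv", **kwargs)
    bundle["profiles"].to_csv(outdir / "profiles.tsv", **kwargs)
    bundle["types"].to_csv(outdir / "types.tsv", **kwargs)
    bundle["composition"].to_csv(outdir / "composition.tsv", **kwargs)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(bundle["stats"], fh, indent=2, sort_keys=True)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(bundle["provenance"], fh, indent=2, sort_keys=True)
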