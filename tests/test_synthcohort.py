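"""Synthetic cohort generator: protocols, determinism, planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from fearext import behavior
from fearext import synthcohort as sc


class TestSessionPlans:
    def test_recording_preset_protocol(self):
        plan = sc.make_session_plan("recording")
        cond = plan.session("Cond")
        assert cond.n_cs == 5 and cond.us == (0.5, 0.5)
        assert plan.session("Ext1").n_cs == 20
        assert plan.session("Hab").n_cs == 5
        assert cond.iti_s == (80.0, 120.0)

    def test_slice_preset_protocol(self):
        plan = sc.make_session_plan("slice")
        assert plan.session("Cond").n_cs == 3
        assert plan.session("Cond").us == (1.0, 1.0)
        assert plan.session("Ext2").n_cs == 15
        assert plan.session("Ext3").n_cs == 15

    def test_lesion_preset_protocol(self):
        plan = sc.make_session_plan("lesion")
        assert plan.session("Cond").n_cs == 4
        assert plan.session("Cond").us == (0.4, 1.0)

    def test_override_replaces_only_matching_field(self):
        base = sc.make_session_plan("recording")
        over = sc.make_session_plan("recording", {"n_cs": {"Ext1": 1},
                                                  "retention_window": 1})
        assert over.session("Ext1").n_cs == 1
        for lab in base.labels:
            if lab != "Ext1":
                assert over.session(lab) == base.session(lab)

    def test_unknown_preset_and_override_rejected(self):
        with pytest.raises(ValueError):
            sc.make_session_plan("chronic")
        with pytest.raises(KeyError):
            sc.make_session_plan("recording", {"n_trials": 3})
        with pytest.raises(KeyError):
            sc.make_session_plan("recording", {"n_cs": {"Ext9": 3}})

    def test_plan_invariants_enforced(self):
        with pytest.raises(ValueError):  # US outside Cond
            sc.SessionPlan((sc.SessionSpec("Ext1", 20, us=(0.5, 0.5)),))
        with pytest.raises(ValueError):  # pip_spec without pip alignment
            sc.SessionPlan((sc.SessionSpec("Cond", 5),), alignment="tone",
                           pip_spec=sc.PipSpec())
        with pytest.raises(ValueError):  # retention window exceeds n_cs
            sc.SessionPlan((sc.SessionSpec("Test", 3),), retention_window=5)

    def test_pip_alignment_installs_pip_spec(self):
        plan = sc.make_session_plan("recording", {"alignment": "pip"})
        assert plan.pip_spec == sc.PipSpec(27, 200.0, 0.9)


class TestEvents:
    def test_pip_trains_per_cs(self, pip_plan, pip_events):
        hab = pip_events[(pip_events["session"] == "Hab")
                         & (pip_events["cs_index"] == 0)]
        pips = hab[hab["kind"] == "pip"]["onset_s"].to_numpy()
        assert pips.size == 27
        np.testing.assert_allclose(np.diff(pips), 1.0 / 0.9)

    def test_us_coterminates_with_cs(self, pip_events):
        cond = pip_events[(pip_events["session"] == "Cond")
                          & (pip_events["cs_index"] == 0)]
        tone = cond[cond["kind"] == "tone"]["onset_s"].iloc[0]
        us = cond[cond["kind"] == "us"]["onset_s"].iloc[0]
        assert us == pytest.approx(tone + 30.0 - 0.5)

    def test_iti_within_bounds(self, pip_plan, pip_events):
        ext1 = pip_events[(pip_events["session"] == "Ext1")
                          & (pip_events["kind"] == "tone")]["onset_s"].to_numpy()
        gaps = np.diff(ext1) - 30.0
        assert (gaps >= 80.0).all() and (gaps <= 120.0).all()


class TestSimulateUnit:
    def test_determinism_byte_identical(self, tone_plan):
        spec = sc.make_neuron_spec("u0", "fear", tone_plan, 6.0)
        a = sc.simulate_unit(spec, tone_plan, seed=9)
        b = sc.simulate_unit(spec, tone_plan, seed=9)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        for s in tone_plan.labels:
            np.testing.assert_array_equal(a.templates[s], b.templates[s])

    def test_adding_a_unit_does_not_perturb_others(self, tone_plan):
        """Substreams are keyed by unit id, not by simulation order."""
        spec0 = sc.make_neuron_spec("u0", "fear", tone_plan, 6.0)
        alone = sc.simulate_unit(spec0, tone_plan, seed=9)
        sc.simulate_unit(sc.make_neuron_spec("u1", "extinction", tone_plan, 6.0),
                         tone_plan, seed=9)
        again = sc.simulate_unit(spec0, tone_plan, seed=9)
        pd.testing.assert_frame_equal(alone.spikes, again.spikes)

    def test_zero_rates_give_empty_table(self, tone_plan):
        spec = sc.NeuronSpec("u0", "non_responsive", 0.0,
                             {lab: 0.0 for lab in tone_plan.labels})
        unit = sc.simulate_unit(spec, tone_plan, seed=1)
        assert unit.spikes.empty

    def test_negative_rates_rejected(self, tone_plan):
        spec = sc.NeuronSpec("u0", "fear", -1.0,
                             {lab: 1.0 for lab in tone_plan.labels})
        with pytest.raises(ValueError):
            sc.simulate_unit(spec, tone_plan, seed=1)

    def test_evoked_rate_elevated_only_in_active_session(self, tone_plan):
        spec = sc.make_neuron_spec("u0", "fear", tone_plan, 5.0, modulation=10.0)
        assert spec.evoked_rate_hz["Ext1"] == 50.0
        assert all(v == 5.0 for k, v in spec.evoked_rate_hz.items() if k != "Ext1")
        unit = sc.simulate_unit(spec, tone_plan, seed=2)
        ev = unit.events
        tones = ev[(ev["session"] == "Ext1") & (ev["kind"] == "tone")]["onset_s"]
        spikes = unit.spikes[unit.spikes["session"] == "Ext1"]["t_s"].to_numpy()
        in_win = sum(((spikes >= t + 0.01) & (spikes < t + 0.06)).sum() for t in tones)
        # expectation 0.05 s x 50 Hz x 20 CS = 50 evoked-window spikes vs 5 at rest
        assert in_win > 25

    def test_inhibitory_modulation_thins_baseline(self, tone_plan):
        spec = sc.NeuronSpec("u0", "session_selective", 20.0,
                             {lab: (2.0 if lab == "Ext1" else 20.0)
                              for lab in tone_plan.labels},
                             response_latency_ms=0.0, response_duration_ms=1000.0)
        unit = sc.simulate_unit(spec, tone_plan, seed=5)
        ev = unit.events
        tones = ev[(ev["session"] == "Ext1") & (ev["kind"] == "tone")]["onset_s"]
        spikes = unit.spikes[unit.spikes["session"] == "Ext1"]["t_s"].to_numpy()
        in_win = sum(((spikes >= t) & (spikes < t + 1.0)).sum() for t in tones)
        assert in_win < 0.5 * 20.0 * 20  # far below the 20 Hz baseline expectation


class TestSimulateFreezing:
    def test_target_100_fully_immobile(self, tone_plan):
        mv = sc.simulate_freezing("r", {lab: (100.0, 0.0) for lab in tone_plan.labels},
                                  tone_plan, seed=1)
        assert (mv["immobile"] == 1).all()

    def test_target_0_scores_zero(self, tone_plan):
        mv = sc.simulate_freezing("r", {lab: (0.0, 0.0) for lab in tone_plan.labels},
                                  tone_plan, seed=1)
        fz = behavior.score_movement_table(mv)
        assert (fz["freezing_pct"] == 0.0).all()

    def test_mean_scored_freezing_matches_target(self):
        """Across many rats the 2-s-rule score averages to the planted mean."""
        plan = sc.SessionPlan((sc.SessionSpec("Test", 5),), retention_window=5)
        vals = []
        for i in range(500):
            mv = sc.simulate_freezing(f"r{i}", {"Test": (50.0, 10.0)}, plan, seed=i)
            vals.extend(behavior.score_movement_table(mv)["freezing_pct"])
        assert abs(np.mean(vals) - 50.0) <= 2.0

    def test_bouts_respect_minimum_length(self, tone_plan):
        mv = sc.simulate_freezing("r", {lab: (30.0, 10.0) for lab in tone_plan.labels},
                                  tone_plan, seed=3)
        one_cs = mv[(mv["session"] == "Ext1") & (mv["cs_index"] == 0)]
        trace = one_cs.sort_values("t_s")["immobile"].to_numpy()
        padded = np.concatenate([[0], trace, [0]])
        runs = np.flatnonzero(np.diff(padded) == -1) - np.flatnonzero(np.diff(padded) == 1)
        assert (runs >= 20).all()

    def test_out_of_range_target_rejected(self, tone_plan):
        with pytest.raises(ValueError):
            sc.simulate_freezing("r", {lab: (120.0, 5.0) for lab in tone_plan.labels},
                                 tone_plan, seed=1)

    def test_determinism(self, tone_plan):
        targets = sc.default_freezing_targets(tone_plan)
        a = sc.simulate_freezing("r", targets, tone_plan, seed=4)
        b = sc.simulate_freezing("r", targets, tone_plan, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestSliceGenerator:
    def test_noiseless_round_trip_is_exact(self):
        from fearext import slice_ephys
        data = sc.simulate_slice_data(sc.SlicePlant(ppr=0.6, ampa_nmda=3.0),
                                      noise_sd_pA=0.0, io_noise_sd_pA=0.0, seed=2)
        ppr, _ = slice_ephys.paired_pulse_ratio(data["paired_pulse"])
        assert ppr == pytest.approx(0.6, abs=1e-12)
        an, _ = slice_ephys.ampa_nmda_ratio(data["dual_holding_neg70"],
                                            data["dual_holding_pos50"], 100.0)
        assert an == pytest.approx(3.0, rel=1e-9)
        io = slice_ephys.io_slope(data["io_series"])
        assert io.slope_pA_per_uA == pytest.approx(5.28, rel=1e-9)

    def test_planted_ratio_validation(self):
        with pytest.raises(ValueError):
            sc.SlicePlant(ppr=-0.5)

    def test_mini_count_in_poisson_band(self):
        """1-Hz planted rate over 120 s: detected count inside the 95% band."""
        from fearext import slice_ephys
        data = sc.simulate_slice_data(sc.SlicePlant(mini_rate_hz=1.0),
                                      noise_sd_pA=0.0, seed=3)
        sw = data["continuous"].sweeps[0]
        table = slice_ephys.detect_minis(sw.t_ms, sw.i_pA, threshold_pA=5.0,
                                         min_interval_ms=5.0)
        mean = 120.0
        lo, hi = mean - 1.96 * np.sqrt(mean), mean + 1.96 * np.sqrt(mean)
        assert lo <= table.times_ms.size <= hi
        # and the detector finds essentially every planted event
        planted = data.planted_mini_times_ms.size
        assert abs(table.times_ms.size - planted) <= 0.03 * planted

    def test_determinism(self):
        a = sc.simulate_slice_data(seed=11)
        b = sc.simulate_slice_data(seed=11)
        np.testing.assert_array_equal(a["continuous"].sweeps[0].i_pA,
                                      b["continuous"].sweeps[0].i_pA)
        np.testing.assert_array_equal(a["paired_pulse"].sweeps[0].i_pA,
                                      b["paired_pulse"].sweeps[0].i_pA)


def test_substream_stability_and_independence():
    a = sc.substream(1, "x").uniform(size=3)
    b = sc.substream(1, "x").uniform(size=3)
    c = sc.substream(1, "y").uniform(size=3)
    np.testing.assert_array_equal(a, b)
    assert not np.allclose(a, c)
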