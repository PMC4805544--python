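import numpy as np
import pandas as pd
import pytest

import vtapipe as vp
from vtapipe import signals
from vtapipe.errors import (
    BehaviorDesignError,
    MissingRewardError,
    SampleSizeError,
    ZeroVarianceError,
)

from _oracles import paired_t_oracle, pearson_oracle


@pytest.fixture(scope="module")
def probe_phasic(task_spec):
    pop = vp.PopulationSpec(n_phasic=20, n_sustained_excited=0,
                            n_sustained_inhibited=0, seed=31)
    return vp.simulate_population(pop, task_spec, phases=("probe",))


@pytest.fixture(scope="module")
def cond_phasic(task_spec):
    pop = vp.PopulationSpec(n_phasic=10, n_sustained_excited=0,
                            n_sustained_inhibited=0, seed=32)
    return vp.simulate_population(pop, task_spec, phases=("conditioning",))


class TestOnsetRewardDifference:
    def test_flat_neurons_center_on_zero(self, task_spec, config):
        pop = vp.PopulationSpec(
            n_phasic=6, n_sustained_excited=0, n_sustained_inhibited=0, seed=33,
            archetype_overrides={"phasic": dict(phasic_gain=0.0, a_sustained_gain=0.0)})
        sim = vp.simulate_population(pop, task_spec, phases=("conditioning",))
        d = signals.onset_reward_difference(sim.spikes, sim.events, config)
        assert abs(d["diff"].mean()) < 0.05

    def test_sign_flips_from_first_to_last_session(self, cond_phasic, config):
        d = signals.onset_reward_difference(cond_phasic.spikes, cond_phasic.events, config)
        by_session = d.groupby("session_index")["diff"].mean()
        assert by_session.iloc[0] < 0 < by_session.iloc[-1]

    def test_unrewarded_sessions_rejected(self, task_spec, config, small_sim):
        with pytest.raises(MissingRewardError):
            signals.onset_reward_difference(small_sim.spikes, small_sim.events, config,
                                            sessions=[1])


class TestMigrationCorrelation:
    def test_positive_trajectory_detected(self, cond_phasic, config):
        d = signals.onset_reward_difference(cond_phasic.spikes, cond_phasic.events, config)
        res = signals.migration_correlation(d)
        assert res.r > 0 and res.p < 0.05
        assert res.df == res.n - 2

    def test_matches_textbook_formula(self, cond_phasic, config):
        d = signals.onset_reward_difference(cond_phasic.spikes, cond_phasic.events, config)
        res = signals.migration_correlation(d)
        assert res.r == pytest.approx(
            pearson_oracle(d.session_index, d["diff"]), abs=1e-10)

    def test_zero_variance_rejected(self):
        d = pd.DataFrame({"session_index": [1, 2, 3], "diff": [0.1, 0.1, 0.1]})
        with pytest.raises(ZeroVarianceError):
            signals.migration_correlation(d)


class TestContrasts:
    def test_cached_and_inferred_contrasts_positive(self, probe_phasic, config):
        bd = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "B", "D")
        ac = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "A", "C")
        assert bd.mean_diff > 0 and ac.mean_diff > 0
        assert bd.df == len(bd.per_neuron) - 1

    def test_antisymmetry(self, probe_phasic, config):
        bd = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "B", "D")
        db = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "D", "B")
        assert np.allclose(bd.per_neuron["diff"], -db.per_neuron["diff"])
        assert bd.t == pytest.approx(-db.t, abs=1e-12)

    def test_t_matches_textbook_formula(self, probe_phasic, config):
        bd = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "B", "D")
        assert bd.t == pytest.approx(paired_t_oracle(bd.per_neuron["diff"]), abs=1e-10)

    def test_identical_responses_give_zero_t(self, config):
        events = pd.DataFrame([
            dict(session_id=9, phase="probe", trial=t, cue_id=c, cue_on=2.0,
                 cue_off=12.0, reward_times=[], trial_duration=15.0)
            for t, c in [(1, "A"), (2, "C")]])
        spikes = pd.concat([
            pd.DataFrame({"neuron_id": nid, "session_id": 9, "phase": "probe",
                          "trial": t, "spike_time": [2.2, 2.4, 5.0]})
            for nid in (0, 1) for t in (1, 2)], ignore_index=True)
        res = signals.cue_contrast(spikes, events, config, "A", "C", sessions=[9])
        assert res.t == 0.0 and res.p == 1.0

    def test_sustained_window_detects_a_specific_component(self, probe_phasic, config):
        ac = signals.sustained_contrast(probe_phasic.spikes, probe_phasic.events,
                                        config, "A", "C")
        assert ac.window == tuple(config.sustained_window)
        assert ac.mean_diff > 0

    def test_sustained_ablation_centers_on_zero(self, task_spec, config):
        pop = vp.PopulationSpec(
            n_phasic=20, n_sustained_excited=0, n_sustained_inhibited=0, seed=34,
            archetype_overrides={"phasic": dict(a_sustained_gain=0.0)})
        sim = vp.simulate_population(pop, task_spec, phases=("probe",))
        ac = signals.sustained_contrast(sim.spikes, sim.events, config, "A", "C")
        assert abs(ac.mean_diff) < 0.5  # Hz; no systematic component remains

    def test_auroc_measure_variant(self, probe_phasic, config):
        ac = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "A", "C", measure="auroc")
        assert ac.measure == "auroc"
        assert ac.mean_diff > 0

    def test_single_neuron_rejected(self, probe_phasic, config):
        with pytest.raises(SampleSizeError):
            signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                    config, "B", "D", neurons=[0])


class TestInferredVsCached:
    def test_duplicated_contrast_has_unit_correlation(self, probe_phasic, config):
        bd = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "B", "D")
        res = signals.inferred_vs_cached_correlation(bd, bd)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.df == res.n - 2

    def test_matches_textbook_formula(self, probe_phasic, config):
        bd = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "B", "D")
        ac = signals.phasic_contrast(probe_phasic.spikes, probe_phasic.events,
                                     config, "A", "C")
        res = signals.inferred_vs_cached_correlation(bd, ac)
        assert res.r == pytest.approx(
            pearson_oracle(bd.per_neuron["diff"], ac.per_neuron["diff"]), abs=1e-10)


class TestBehaviorStats:
    def test_all_zero_occupancy_flagged_degenerate(self, task_spec):
        params = vp.BehaviorParams(base_occupancy=0.0, max_b_occupancy=0.0,
                                   probe_a_occupancy=0.0, transfer=0.0)
        beh = vp.simulate_behavior(task_spec, params, seed=1)
        st = signals.behavior_stats(beh, "conditioning")
        assert st.degenerate
        assert (st.means.occupancy_fraction == 0).all()

    def test_conditioning_cue_effect_detected(self, task_spec):
        cohort = vp.simulate_cohort(task_spec, vp.BehaviorParams(), seed=6, n_rats=6)
        st = signals.behavior_stats(cohort, "conditioning")
        cue = st.anova.set_index("effect").loc["cue_id"]
        assert cue.p < 0.05
        assert not st.degenerate

    def test_probe_transfer_effect_detected(self, task_spec):
        cohort = vp.simulate_cohort(task_spec, vp.BehaviorParams(), seed=7, n_rats=6)
        st = signals.behavior_stats(cohort, "probe")
        cue = st.anova.set_index("effect").loc["cue_id"]
        assert cue.p < 0.05

    def test_preconditioning_uses_all_four_cues(self, task_spec):
        beh = vp.simulate_behavior(task_spec, vp.BehaviorParams(), seed=8)
        st = signals.behavior_stats(beh, "preconditioning")
        assert set(st.means.cue_id) == set(vp.CUES)

    def test_empty_cells_listed(self, task_spec):
        beh = vp.simulate_behavior(task_spec, vp.BehaviorParams(), seed=9)
        trimmed = beh[~((beh.phase == "conditioning") & (beh.cue_id == "D")
                        & (beh.session_id == 4))]
        with pytest.raises(BehaviorDesignError) as exc:
            signals.behavior_stats(trimmed, "conditioning")
        assert exc.value.cells
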