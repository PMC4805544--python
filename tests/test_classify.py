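import numpy as np
import pandas as pd
import pytest

import vtapipe as vp
from vtapipe.classify import ARCHETYPE_ORDER
from vtapipe.errors import AmbiguousArchetypeError, ConfigError, SampleSizeError, WaveformError

from _oracles import complete_linkage_oracle, partition_of


def _matrix(values, bin_width=0.1):
    values = np.asarray(values, float)
    centers = (np.arange(values.shape[1]) + 0.5) * bin_width
    return vp.AUROCMatrix(values=values, neuron_ids=np.arange(len(values)),
                          bin_centers=centers, cue_id="B")


def _template_matrix(n_per=5, noise=0.0, seed=0):
    """Hand-built auROC traces for the three archetypes over 100 bins."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for arch in ARCHETYPE_ORDER:
        for _ in range(n_per):
            trace = np.full(100, 0.5)
            if arch == "phasic":
                trace[:5] = 0.95
                trace[10:15] = 0.9   # reward transient
                trace[5:] += 0.05
            elif arch == "sustained_excited":
                trace[:] = 0.8
            else:
                trace[:] = 0.3
            rows.append(trace + noise * rng.normal(size=100))
            truth.append(arch)
    return _matrix(np.clip(rows, 0, 1)), truth


class TestResponsePCA:
    def test_identical_rows_give_equal_scores(self):
        m = np.tile(np.linspace(0.3, 0.8, 40), (6, 1))
        res = vp.response_pca(m, n_components=3)
        assert np.allclose(res.scores, res.scores[0])

    def test_rank_one_structure_dominates(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=30)[:, None]
        v = rng.normal(size=50)[None, :]
        m = u @ v + 1e-4 * rng.normal(size=(30, 50))
        res = vp.response_pca(m, n_components=3)
        assert res.explained_variance_ratio[0] > 0.99

    def test_rank3_reconstruction_beats_rank2(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(25, 40))
        centered = m - m.mean(axis=0)

        def recon_err(k):
            res = vp.response_pca(m, n_components=k)
            approx = res.scores @ res.components
            return np.linalg.norm(centered - approx)

        assert recon_err(3) <= recon_err(2) + 1e-9

    def test_sign_convention_fixed(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(20, 30))
        res = vp.response_pca(m)
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ConfigError):
            vp.response_pca(np.zeros((2, 40)), n_components=3)


class TestClusterNeurons:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(c, 0.05, size=(10, 3)) for c in (0.0, 5.0, 10.0)])
        labels = vp.cluster_neurons(pts, k=3)
        expect = np.repeat([0, 1, 2], 10)
        assert partition_of(labels) == partition_of(expect)

    def test_k_equals_n_gives_singletons(self):
        pts = np.random.default_rng(5).normal(size=(7, 2))
        assert len(set(vp.cluster_neurons(pts, k=7))) == 7

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(SampleSizeError):
            vp.cluster_neurons(np.zeros((2, 3)), k=3)

    @pytest.mark.parametrize("seed,n,k", [(0, 8, 2), (1, 15, 3), (2, 30, 3), (3, 12, 4)])
    def test_matches_naive_complete_linkage(self, seed, n, k):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=4, size=(k, 3))
        pts = np.vstack([rng.normal(c, 1.0, size=(n // k + 1, 3)) for c in centers])[:n]
        got = partition_of(vp.cluster_neurons(pts, k=k))
        assert got == set(complete_linkage_oracle(pts, k))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(c, 0.5, size=(8, 3)) for c in (0.0, 4.0, 9.0)])
        perm = rng.permutation(len(pts))
        base = partition_of(vp.cluster_neurons(pts, k=3))
        shuffled = vp.cluster_neurons(pts[perm], k=3)
        unshuffled = np.empty(len(pts), int)
        unshuffled[perm] = shuffled
        assert partition_of(unshuffled) == base


class TestLabelArchetypes:
    def test_template_population_labeled_correctly(self, config):
        m, truth = _template_matrix(noise=0.02)
        clusters = np.repeat([0, 1, 2], 5)
        labels = vp.label_archetypes(clusters, m, config)
        assert [labels[c] for c in (0, 1, 2)] == list(ARCHETYPE_ORDER)

    def test_inverting_a_trace_flips_excited_to_inhibited(self, config):
        m, _ = _template_matrix(noise=0.02)
        clusters = np.repeat([0, 1, 2], 5)
        flipped = m.values.copy()
        flipped[5:10] = 1.0 - flipped[5:10]   # invert the sustained-excited block
        labels = vp.label_archetypes(clusters, _matrix(flipped), config)
        assert labels[1] == "sustained_inhibited"

    def test_all_flat_population_is_ambiguous(self, config):
        m = _matrix(np.full((9, 100), 0.5))
        with pytest.raises(AmbiguousArchetypeError):
            vp.label_archetypes(np.repeat([0, 1, 2], 3), m, config)

    def test_wrong_cluster_count_rejected(self, config):
        m, _ = _template_matrix()
        with pytest.raises(ConfigError):
            vp.label_archetypes(np.zeros(15, int), m, config)


class TestWaveform:
    def _features(self, hw, pos, neg=-1.0):
        return pd.DataFrame({"negative_half_width": [hw],
                             "max_positive_deflection": [pos],
                             "min_negative_deflection": [neg]})

    def test_wide_with_positive_peak_passes(self):
        assert vp.classify_waveform(self._features(500.0, 0.4)).iloc[0]

    def test_narrow_fails_regardless_of_ratio(self):
        assert not vp.classify_waveform(self._features(300.0, 0.9)).iloc[0]

    def test_wide_without_positive_deflection_fails(self):
        assert not vp.classify_waveform(self._features(500.0, -0.1)).iloc[0]
        assert not vp.classify_waveform(self._features(500.0, 0.0)).iloc[0]

    def test_zero_or_positive_trough_rejected(self):
        with pytest.raises(WaveformError):
            vp.classify_waveform(self._features(500.0, 0.4, neg=0.0))
        with pytest.raises(WaveformError):
            vp.classify_waveform(self._features(500.0, 0.4, neg=0.5))

    def test_generated_population_flags_match_ground_truth(self, small_sim):
        wide = vp.classify_waveform(small_sim.waveforms.set_index("neuron_id"))
        truth = small_sim.truth.set_index("neuron_id").wide_waveform
        assert (wide.sort_index() == truth.sort_index()).all()


class TestEndToEnd:
    def test_recovery_on_simulated_population(self, small_sim, config, task_spec):
        m = vp.auroc_matrix(small_sim.spikes, small_sim.events, "B", config,
                            sessions=list(task_spec.conditioning_sessions))
        labels = vp.classify_population(m, config)
        merged = labels.merge(small_sim.truth, on="neuron_id",
                              suffixes=("_hat", "_true"))
        acc = (merged.archetype_hat == merged.archetype_true).mean()
        assert acc >= 0.9
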