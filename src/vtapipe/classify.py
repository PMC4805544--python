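"""Response-type classification of VTA units.

Two independent routes:

1. **Response dynamics** — PCA on the neuron × time auROC matrix for the
   reward-predictive cue (first 3 components), then agglomerative
   complete-linkage clustering (Euclidean distance in component space)
   cut to exactly 3 clusters.  Clusters are then mapped to archetypes
   from their mean auROC traces: the cluster with the lowest full-window
   mean is *sustained_inhibited*; of the remaining two, the one with the
   larger transient index (onset-window mean minus sustained-window
   mean) is *phasic* and the other *sustained_excited*.
2. **Waveform** — a unit is flagged wide-waveform (putative dopaminergic
   by the classic criterion) when its negative half-width exceeds
   450 µs and its mean waveform has a genuinely positive maximal
   deflection (the positive/negative deflection ratio, with the trough
   stored as a signed negative value, is positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .auroc import AnalysisConfig, AUROCMatrix
from .errors import AmbiguousArchetypeError, ConfigError, SampleSizeError, WaveformError

ARCHETYPE_ORDER = ("phasic", "sustained_excited", "sustained_inhibited")


@dataclass(frozen=True)
class WaveformCriteria:
    """Thresholds for the classic wide-waveform screen."""

    min_negative_half_width: float = 450.0  # microseconds
    deflection_ratio_threshold: float = 0.0

    def __post_init__(self):
        if self.min_negative_half_width <= 0:
            raise ConfigError("min_negative_half_width must be positive")


@dataclass
class PCAResult:
    scores: np.ndarray                 # (n_neurons, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray             # (n_components, n_bins)


def response_pca(matrix: AUROCMatrix | np.ndarray, n_components: int = 3) -> PCAResult:
    """First principal components of the neuron × time response matrix.

    Columns (time bins) are mean-centered but not variance-scaled, since
    auROC values already share the [0, 1] scale.  Component signs are
    fixed so each component's largest-magnitude loading is positive,
    making scores deterministic across platforms.
    """
    x = matrix.values if isinstance(matrix, AUROCMatrix) else np.asarray(matrix, float)
    if n_components > min(x.shape):
        raise ConfigError(
            f"n_components={n_components} exceeds matrix rank bound {min(x.shape)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    comps = pca.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAResult(scores=scores, explained_variance_ratio=pca.explained_variance_ratio_,
                     components=comps)


def cluster_neurons(scores: np.ndarray, k: int = 3) -> np.ndarray:
    """Complete-linkage agglomerative clustering cut to exactly ``k`` clusters.

    Returns 0-based cluster indices, relabeled by first appearance so the
    labeling is deterministic in the input order.
    """
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if n < k:
        raise SampleSizeError(f"need at least k={k} neurons, got {n}")
    if k < 1:
        raise ConfigError("k must be positive")
    if k == n:
        return np.arange(n)
    z = linkage(scores, method="complete", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    # Relabel in order of first appearance.
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=np.int64)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap)
        out[i] = remap[c]
    return out


def label_archetypes(cluster_indices: np.ndarray, matrix: AUROCMatrix,
                     config: AnalysisConfig | None = None,
                     atol: float = 1e-9) -> dict[int, str]:
    """Map 3 cluster indices to response archetypes from mean auROC traces.

    Raises :class:`AmbiguousArchetypeError` when two clusters tie (within
    ``atol``) on the statistic that would decide their labels, rather
    than choosing arbitrarily.
    """
    config = config or AnalysisConfig()
    cluster_indices = np.asarray(cluster_indices)
    clusters = sorted(set(int(c) for c in cluster_indices))
    if len(clusters) != 3:
        raise ConfigError(f"expected exactly 3 clusters, got {len(clusters)}")

    centers = matrix.bin_centers
    onset = centers < config.onset_window
    sustained = (centers >= config.sustained_window[0]) & (centers < config.sustained_window[1])
    if not onset.any() or not sustained.any():
        raise ConfigError("matrix window does not cover onset and sustained windows")

    means, transients = {}, {}
    for c in clusters:
        trace = matrix.values[cluster_indices == c].mean(axis=0)
        means[c] = float(trace.mean())
        transients[c] = float(trace[onset].mean() - trace[sustained].mean())

    ordered = sorted(clusters, key=lambda c: means[c])
    if abs(means[ordered[0]] - means[ordered[1]]) <= atol:
        raise AmbiguousArchetypeError(
            "two clusters tie on the full-cue mean that identifies sustained inhibition")
    labels = {ordered[0]: "sustained_inhibited"}
    a, b = ordered[1], ordered[2]
    if abs(transients[a] - transients[b]) <= atol:
        raise AmbiguousArchetypeError(
            "two clusters tie on the transient index separating phasic from sustained excitation")
    if transients[a] > transients[b]:
        labels[a], labels[b] = "phasic", "sustained_excited"
    else:
        labels[a], labels[b] = "sustained_excited", "phasic"
    return labels


def classify_waveform(features: pd.DataFrame,
                      criteria: WaveformCriteria | None = None) -> pd.Series:
    """Boolean wide-waveform flag per unit.

    ``min_negative_deflection`` must be stored signed (negative); a zero
    or positive trough makes the deflection ratio ill-defined and is
    rejected.  The ratio compares the positive peak to the trough
    magnitude, so the screen passes only units with a genuinely positive
    maximal deflection.
    """
    criteria = criteria or WaveformCriteria()
    neg = features["min_negative_deflection"].to_numpy(float)
    if np.any(neg == 0):
        raise WaveformError("zero negative deflection: ratio undefined")
    if np.any(neg > 0):
        raise WaveformError("min_negative_deflection must be stored as a signed negative value")
    ratio = features["max_positive_deflection"].to_numpy(float) / np.abs(neg)
    wide = (features["negative_half_width"].to_numpy(float) > criteria.min_negative_half_width) \
        & (ratio > criteria.deflection_ratio_threshold)
    return pd.Series(wide, index=features.index, name="wide_waveform")


def classify_population(matrix: AUROCMatrix, config: AnalysisConfig | None = None,
                        k: int = 3, n_components: int = 3) -> pd.DataFrame:
    """auROC matrix -> PCA -> clustering -> archetype labels.

    Returns a DataFrame with neuron_id, cluster, archetype.
    """
    config = config or AnalysisConfig()
    pca = response_pca(matrix, n_components=n_components)
    clusters = cluster_neurons(pca.scores, k=k)
    labels = label_archetypes(clusters, matrix, config)
    return pd.DataFrame({
        "neuron_id": matrix.neuron_ids,
        "cluster": clusters,
        "archetype": [labels[int(c)] for c in clusters],
    })
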