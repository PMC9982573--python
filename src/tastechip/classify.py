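"""Electrode specificity, PCA projection, condition clustering and taste
detection-threshold resolution.

The recognition logic of the chip: electrodes that respond to exactly one
tastant are retained; 8-feature vectors from those electrodes are
standardised and projected onto three principal components; condition
signals are grouped by Ward agglomerative clustering with the number of
clusters chosen by mean silhouette; the taste detection threshold is the
lowest tested concentration whose signals do not share the control's
cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .features import FEATURE_COLUMNS
from .recording import StimulusLabel
from .spectral import BandPowerSet

__all__ = [
    "SpecificityMask",
    "select_specific_electrodes",
    "PCAResult",
    "pca_project",
    "ClusterAssignment",
    "cluster_conditions",
    "resolve_detection_threshold",
]


@dataclass
class SpecificityMask:
    """Per-channel responsive tastant sets; specific = exactly one."""

    responsive: dict[str, frozenset[str]]
    undefined_baseline: frozenset[str] = frozenset()

    def is_specific(self, channel: str) -> bool:
        return (
            channel not in self.undefined_baseline
            and len(self.responsive.get(channel, ())) == 1
        )

    def specific_channels(self, tastant: str | None = None) -> list[str]:
        out = []
        for ch in self.responsive:
            if not self.is_specific(ch):
                continue
            (t,) = self.responsive[ch]
            if tastant is None or t == tastant:
                out.append(ch)
        return out


def _total_psd(value) -> float:
    if isinstance(value, BandPowerSet):
        return value.total
    if isinstance(value, Mapping):
        return float(sum(value.values()))
    return float(value)


def select_specific_electrodes(
    responses: Mapping[str, Mapping[str, object]],
    baselines: Mapping[str, object],
    fold_threshold: float = 2.0,
) -> SpecificityMask:
    """Mark channels that respond to exactly one tastant.

    ``responses[channel][tastant]`` and ``baselines[channel]`` are
    :class:`BandPowerSet` objects (or band->PSD mappings, or precomputed
    totals). A channel *responds* to a tastant when its total five-band PSD
    under that stimulus is at least ``fold_threshold`` times its baseline
    total. Channels with a zero baseline total are flagged and excluded.
    """
    responsive: dict[str, frozenset[str]] = {}
    undefined: set[str] = set()
    for ch, per_tastant in responses.items():
        if ch not in baselines:
            raise KeyError(f"no baseline for channel {ch!r}")
        base = _total_psd(baselines[ch])
        if base <= 0:
            warnings.warn(f"channel {ch}: undefined baseline (zero total PSD)")
            undefined.add(ch)
            responsive[ch] = frozenset()
            continue
        hits = {
            t for t, v in per_tastant.items() if _total_psd(v) >= fold_threshold * base
        }
        responsive[ch] = frozenset(hits)
    return SpecificityMask(responsive=responsive, undefined_baseline=frozenset(undefined))


@dataclass
class PCAResult:
    scores: np.ndarray  # n x 3
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # n_features x 3
    feature_means: np.ndarray
    feature_scales: np.ndarray
    feature_names: tuple[str, ...]


def pca_project(fm, n_components: int = 3, log_psd: bool = False) -> PCAResult:
    """Standardise the 8 features and project onto the top principal
    components.

    Accepts the feature-matrix DataFrame (uses the 8 canonical feature
    columns) or a plain array. Columns are centred and scaled to unit
    variance (``log_psd=True`` additionally log10-transforms the five PSD
    columns first, for data whose band densities span decades);
    zero-variance columns are centred only, with a warning. The sign of
    each component is fixed so that its largest-magnitude loading is
    positive.
    """
    if isinstance(fm, pd.DataFrame):
        names = tuple(c for c in FEATURE_COLUMNS if c in fm.columns)
        x = fm[list(names)].to_numpy(dtype=np.float64)
        if log_psd:
            x = x.copy()
            for i, name in enumerate(names):
                if name.startswith("psd_"):
                    x[:, i] = np.log10(np.maximum(x[:, i], 1e-12))
    else:
        x = np.asarray(fm, dtype=np.float64)
        names = tuple(f"f{i}" for i in range(x.shape[1]))
    if x.ndim != 2 or x.shape[0] <= n_components:
        raise ValueError(
            f"insufficient samples: need more than {n_components} rows, got {x.shape}"
        )
    means = x.mean(axis=0)
    scales = x.std(axis=0)
    dead = scales <= 1e-12 * np.maximum(np.abs(means), 1.0)
    if dead.any():
        warnings.warn(
            f"zero-variance feature(s) dropped from standardization: "
            f"{[names[i] for i in np.flatnonzero(dead)]}"
        )
        scales = np.where(dead, 1.0, scales)
    z = (x - means) / scales
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        feature_means=means,
        feature_scales=scales,
        feature_names=names,
    )


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..k per sample
    k: int
    condition_to_cluster: dict[Hashable, int]
    silhouette: float | None
    degenerate: bool = False


def cluster_conditions(
    scores: np.ndarray | PCAResult,
    condition_labels: Sequence[Hashable],
    method: str = "ward",
    k_range: Sequence[int] | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Group condition signals in principal-component space.

    The clustering operates on the *condition centroids* in score space
    (Ward linkage by default; ``method="kmeans"`` with a fixed seed is the
    alternative): for each candidate k the centroids are grouped, every
    sample inherits the cluster of its condition, and the k with the
    highest mean silhouette over the samples wins (ties favour fewer
    clusters). Replicate spread therefore informs k — two conditions merge
    when their centroids sit closer together than their replicate scatter
    warrants separating. If all points coincide the assignment is flagged
    degenerate with k=1.
    """
    pts = scores.scores if isinstance(scores, PCAResult) else np.asarray(scores, float)
    condition_labels = list(condition_labels)
    if len(condition_labels) != len(pts):
        raise ValueError("one condition label per sample required")
    conditions = sorted(set(condition_labels), key=str)
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    if np.allclose(pts, pts[0]):
        labels = np.ones(len(pts), dtype=int)
        return ClusterAssignment(
            labels=labels,
            k=1,
            condition_to_cluster={c: 1 for c in conditions},
            silhouette=None,
            degenerate=True,
        )
    centroids = np.vstack(
        [
            pts[[i for i, lab in enumerate(condition_labels) if lab == c]].mean(axis=0)
            for c in conditions
        ]
    )
    cond_index = {c: i for i, c in enumerate(conditions)}
    sample_cond = np.array([cond_index[lab] for lab in condition_labels])
    if k_range is None:
        k_range = range(2, min(len(conditions), len(pts) - 1) + 1)
    best: tuple[float, int, np.ndarray] | None = None
    for k in k_range:
        if k > len(conditions):
            continue
        if method == "ward":
            cent_fit = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(
                centroids
            )
        elif method == "kmeans":
            cent_fit = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(
                centroids
            )
        else:
            raise ValueError(f"unknown clustering method: {method!r}")
        fit = cent_fit[sample_cond]
        if len(np.unique(fit)) < 2:
            continue
        score = silhouette_score(pts, fit)
        if best is None or score > best[0] + 1e-12:
            best = (score, k, cent_fit)
    assert best is not None
    score, k, cent_fit = best
    labels = cent_fit[sample_cond] + 1
    cond_map = {c: int(cent_fit[cond_index[c]]) + 1 for c in conditions}
    return ClusterAssignment(
        labels=labels, k=k, condition_to_cluster=cond_map, silhouette=float(score)
    )


def resolve_detection_threshold(
    ca: ClusterAssignment,
    conditions: Sequence[StimulusLabel],
) -> float | None:
    """Lowest tested concentration whose cluster differs from the control's.

    ``conditions`` must include the control; its cluster defines "not
    detected". Returns ``None`` when every concentration shares the
    control's cluster.
    """
    controls = [c for c in conditions if c.is_control]
    if not controls:
        raise ValueError("no control condition")
    control_cluster = ca.condition_to_cluster[controls[0].key()]
    tested = sorted(
        (c for c in conditions if not c.is_control), key=lambda c: c.concentration
    )
    for cond in tested:
        if ca.condition_to_cluster[cond.key()] != control_cluster:
            return float(cond.concentration)
    return None
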