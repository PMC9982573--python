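"""Canned dose-response experiments at desk scale.

The reference acquisition geometry is a 64-electrode chip recorded for
3 minutes per stimulus. For routine verification this module runs the same
end-to-end pipeline on a desk-scale geometry — 48 electrodes, 60-second
stimuli — which preserves every pipeline stage and the per-condition
feature structure while keeping a full four-tastant recovery study within
minutes on one core. The generative model itself is always the default
3-minute-calibrated model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import PipelineConfig, PipelineReport, run_full_pipeline
from .recording import Tastant

__all__ = [
    "DESK_N_ELECTRODES",
    "DESK_DURATION_S",
    "EXPECTED_CLUSTERS",
    "EXPECTED_MERGES",
    "ClusterRecovery",
    "desk_config",
    "run_cluster_recovery",
]

DESK_N_ELECTRODES = 48
DESK_DURATION_S = 60.0

#: Cluster count each dose-response experiment should resolve, and the
#: conditions expected to share one cluster (condition keys are
#: (tastant value, concentration); ("none", 0.0) is the control).
EXPECTED_CLUSTERS: dict[Tastant, int] = {
    Tastant.SOUR_ACETIC: 5,
    Tastant.SWEET_SUCROSE: 5,
    Tastant.BITTER_PTC: 5,
    Tastant.SALTY_NACL: 4,
}
EXPECTED_MERGES: dict[Tastant, tuple[tuple[str, float], ...]] = {
    Tastant.SOUR_ACETIC: (("sour_acetic", 1.5625), ("sour_acetic", 3.125)),
    Tastant.SWEET_SUCROSE: (("none", 0.0), ("sweet_sucrose", 0.125)),
    Tastant.BITTER_PTC: (("none", 0.0), ("bitter_PTC", 0.001)),
    Tastant.SALTY_NACL: (("none", 0.0), ("salty_NaCl", 0.75), ("salty_NaCl", 1.5)),
}


@dataclass(frozen=True)
class ClusterRecovery:
    k: int
    merge_ok: bool
    threshold: float | None
    silhouette: float | None

    @property
    def success(self) -> bool:
        return self.merge_ok


def desk_config(seed: int, **overrides) -> PipelineConfig:
    kwargs = dict(
        seed=seed,
        duration_s=DESK_DURATION_S,
        n_electrodes=DESK_N_ELECTRODES,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def run_cluster_recovery(
    tastant: Tastant, seed: int, **overrides
) -> tuple[ClusterRecovery, PipelineReport]:
    """Run one desk-scale dose-response experiment and score its clustering.

    ``merge_ok`` requires the expected condition subset to share exactly one
    cluster that contains no other condition, together with the expected
    total cluster count.
    """
    report = run_full_pipeline(desk_config(seed, **overrides), tastant)
    merged = EXPECTED_MERGES[tastant]
    cl = report.clusters.condition_to_cluster
    one_cluster = len({cl[m] for m in merged}) == 1
    exclusive = all(
        cl[c] != cl[merged[0]] for c in cl if c not in merged
    )
    k_ok = report.clusters.k == EXPECTED_CLUSTERS[tastant]
    rec = ClusterRecovery(
        k=report.clusters.k,
        merge_ok=one_cluster and exclusive and k_ok,
        threshold=report.threshold,
        silhouette=report.clusters.silhouette,
    )
    return rec, report
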