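"""End-to-end workbench: simulate a dose-response experiment, run the
feature/classification pipeline and emit a reproducibility report.

``run_full_pipeline`` chains every stage: default model -> electrode map ->
specificity screen -> per-condition recordings -> 8-feature matrix on the
tastant-specific electrodes -> replicate aggregation -> summary stats with
ANOVA + Fisher's LSD -> radar-normalised table -> 3-component PCA ->
silhouette-selected clustering -> detection threshold. All outputs are
plain CSV/JSON with fixed float formatting and no timestamps, so a given
(config, seed) reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ClusterAssignment,
    PCAResult,
    SpecificityMask,
    cluster_conditions,
    pca_project,
    resolve_detection_threshold,
    select_specific_electrodes,
)
from .features import (
    FEATURE_COLUMNS,
    aggregate_by_replicate,
    extract_feature_matrix,
    fisher_lsd,
    normalize_for_radar,
    one_way_anova,
    summarize_conditions,
)
from .recording import Recording, StimulusLabel, Tastant, write_recording
from .simulate import (
    DEFAULT_DURATION_S,
    DEFAULT_FS,
    DEFAULT_N_ELECTRODES,
    COGNATE_TASTANT,
    ElectrodeMap,
    GroundTruth,
    TasteResponseModel,
    assign_electrodes,
    build_default_model,
    default_conditions,
    simulate_experiment,
)
from .spectral import get_bands
from .spikes import SpikeDetectionConfig

__all__ = ["PipelineConfig", "PipelineReport", "screen_specificity",
           "run_full_pipeline", "make_figures"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full pipeline; every field has a reproducible default."""

    seed: int
    fs: float = DEFAULT_FS
    duration_s: float = DEFAULT_DURATION_S
    n_electrodes: int = DEFAULT_N_ELECTRODES
    n_replicates: int = 3
    band_edges: str = "methods"
    window_len_s: float = 1.0
    overlap_fraction: float = 0.5
    k_sigma: float = 3.0
    dead_time_s: float = 0.003
    p2p_window_s: float = 0.004
    fold_threshold: float = 2.0
    chip_cv: float = 0.10
    chip_cv_gain: float = 0.04
    clustering: str = "ward"
    write_recordings: bool = False
    outdir: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for a simulated run")
        if self.fs < 200 or self.duration_s <= 0 or self.n_electrodes < 1:
            raise ValueError("invalid acquisition geometry")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        get_bands(self.band_edges)
        if self.clustering not in ("ward", "kmeans"):
            raise ValueError(f"unknown clustering method {self.clustering!r}")
        SpikeDetectionConfig(self.k_sigma, self.dead_time_s, self.p2p_window_s)

    @property
    def spike_cfg(self) -> SpikeDetectionConfig:
        return SpikeDetectionConfig(self.k_sigma, self.dead_time_s, self.p2p_window_s)


@dataclass
class PipelineReport:
    config: PipelineConfig
    tastant: Tastant
    conditions: list[StimulusLabel]
    model: TasteResponseModel
    electrode_map: ElectrodeMap
    mask: SpecificityMask
    recordings: list[Recording]
    ground_truths: list[GroundTruth]
    feature_matrix: pd.DataFrame
    replicate_matrix: pd.DataFrame
    summary: pd.DataFrame
    radar: pd.DataFrame
    stats: pd.DataFrame
    pca: PCAResult
    clusters: ClusterAssignment
    threshold: float | None
    manifest: dict


def screen_specificity(
    model: TasteResponseModel,
    emap: ElectrodeMap,
    cfg: PipelineConfig,
    seed: int,
) -> SpecificityMask:
    """Tastant-specificity screen mirroring the sequential-exposure session:
    every channel is recorded under control medium and under a strong dose
    of each tastant, and a channel is kept when its total band PSD rises at
    least ``fold_threshold``-fold over baseline for exactly one tastant.

    The screen is run without chip-level variability so the fold change
    compares like with like on the same (simulated) chip.
    """
    from .spectral import compute_band_psds

    strong = {
        Tastant.SOUR_ACETIC: 25.0,
        Tastant.SWEET_SUCROSE: 0.75,
        Tastant.BITTER_PTC: 1.0,
        Tastant.SALTY_NACL: 6.0,
    }
    conditions = [StimulusLabel()] + [
        StimulusLabel(t, c, _units(t)) for t, c in strong.items()
    ]
    sims = simulate_experiment(
        model, emap, conditions, cfg.duration_s, cfg.fs,
        n_replicates=1, seed=seed, chip_cv=0.0,
    )
    bands = get_bands(cfg.band_edges)
    baselines: dict[str, object] = {}
    responses: dict[str, dict[str, object]] = {ch: {} for ch in emap.channel_ids}
    for rec, _ in sims:
        for ch in rec.channel_ids:
            bps = compute_band_psds(rec, ch, cfg.window_len_s, cfg.overlap_fraction, bands)
            if rec.stimulus.is_control:
                baselines[ch] = bps
            else:
                responses[ch][rec.stimulus.tastant.value] = bps
    return select_specific_electrodes(responses, baselines, cfg.fold_threshold)


def _units(t: Tastant):
    from .recording import TASTANT_UNITS

    return TASTANT_UNITS[t]


def run_full_pipeline(
    cfg: PipelineConfig,
    tastant: Tastant,
    concentrations: list[float] | None = None,
) -> PipelineReport:
    """Simulate and analyse one dose-response experiment end to end."""
    cfg.validate()
    if tastant == Tastant.NONE:
        raise ValueError("pick one of the four tastants")
    model = build_default_model()
    emap = assign_electrodes(cfg.n_electrodes, seed=cfg.seed)

    if concentrations is None:
        conditions = default_conditions(tastant)
    else:
        conditions = [StimulusLabel()] + [
            StimulusLabel(tastant, c, _units(tastant)) for c in sorted(concentrations)
        ]
    if not any(c.is_control for c in conditions):
        raise ValueError("concentrations must include the 0/control condition")

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        screen_seed = int(np.random.SeedSequence([cfg.seed, 101]).generate_state(1)[0])
        mask = screen_specificity(model, emap, cfg, seed=screen_seed)
        channels = mask.specific_channels(tastant.value)
        if not channels:
            raise RuntimeError("specificity screen kept no electrode for this tastant")

        sims = simulate_experiment(
            model, emap, conditions, cfg.duration_s, cfg.fs,
            n_replicates=cfg.n_replicates, seed=cfg.seed, chip_cv=cfg.chip_cv,
            chip_cv_gain=cfg.chip_cv_gain,
        )
        recordings = [rec for rec, _ in sims]
        truths = [gt for _, gt in sims]

        fm = extract_feature_matrix(
            recordings,
            channels=channels,
            window_len_s=cfg.window_len_s,
            overlap_fraction=cfg.overlap_fraction,
            bands=get_bands(cfg.band_edges),
            spike_cfg=cfg.spike_cfg,
        )
        agg = aggregate_by_replicate(fm)
        summary = summarize_conditions(agg)
        radar = normalize_for_radar(summary)
        stats = _group_statistics(agg)
        pca = pca_project(agg)
        cond_keys = [
            (t, c) for t, c in zip(agg["tastant"], agg["concentration"])
        ]
        clusters = cluster_conditions(
            pca, cond_keys, method=cfg.clustering, seed=cfg.seed
        )
        threshold = resolve_detection_threshold(clusters, conditions)
        collected = [str(w.message) for w in caught]

    manifest = {
        "software": "tastechip",
        "version": __version__,
        "seed": cfg.seed,
        "tastant": tastant.value,
        "config": dataclasses.asdict(cfg),
        "conditions": [c.key() for c in conditions],
        "n_recordings": len(recordings),
        "n_specific_channels": len(channels),
        "n_feature_rows": int(len(fm)),
        "n_replicate_rows": int(len(agg)),
        "cluster_k": int(clusters.k),
        "silhouette": clusters.silhouette,
        "detection_threshold": threshold,
        "warnings": collected,
    }
    report = PipelineReport(
        config=cfg,
        tastant=tastant,
        conditions=conditions,
        model=model,
        electrode_map=emap,
        mask=mask,
        recordings=recordings,
        ground_truths=truths,
        feature_matrix=fm,
        replicate_matrix=agg,
        summary=summary,
        radar=radar,
        stats=stats,
        pca=pca,
        clusters=clusters,
        threshold=threshold,
        manifest=manifest,
    )
    if cfg.outdir is not None:
        write_report(report, Path(cfg.outdir))
    return report


def _group_statistics(agg: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA across conditions plus Fisher's LSD, per feature."""
    keys = sorted(
        set(zip(agg["tastant"], agg["concentration"])), key=lambda k: (k[0], k[1])
    )
    rows = []
    for feat in FEATURE_COLUMNS:
        groups = [
            agg.loc[
                (agg["tastant"] == t) & (agg["concentration"] == c), feat
            ].to_numpy()
            for t, c in keys
        ]
        f, p = one_way_anova(groups)
        lsd = fisher_lsd(groups)
        row = {"feature": feat, "anova_F": f, "anova_p": p}
        for (ki, kj) in [(i, j) for i in range(len(keys)) for j in range(i + 1, len(keys))]:
            row[f"lsd_p[{keys[ki][0]}:{keys[ki][1]:g} vs {keys[kj][0]}:{keys[kj][1]:g}]"] = lsd[ki, kj]
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: PipelineReport, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.feature_matrix.to_csv(
        outdir / "features.csv", index=False, float_format=_FLOAT_FMT
    )
    report.replicate_matrix.to_csv(
        outdir / "features_by_replicate.csv", index=False, float_format=_FLOAT_FMT
    )
    report.summary.to_csv(outdir / "summary.csv", index=False, float_format=_FLOAT_FMT)
    report.radar.to_csv(outdir / "radar.csv", float_format=_FLOAT_FMT)
    report.stats.to_csv(outdir / "stats.csv", index=False, float_format=_FLOAT_FMT)
    scores = pd.DataFrame(report.pca.scores, columns=["PC1", "PC2", "PC3"])
    scores["tastant"] = report.replicate_matrix["tastant"].to_numpy()
    scores["concentration"] = report.replicate_matrix["concentration"].to_numpy()
    scores["chip_id"] = report.replicate_matrix["chip_id"].to_numpy()
    scores["cluster"] = report.clusters.labels
    scores.to_csv(outdir / "pca_scores.csv", index=False, float_format=_FLOAT_FMT)
    mask_rows = [
        {
            "channel": ch,
            "responsive_to": ";".join(sorted(report.mask.responsive[ch])),
            "is_specific": report.mask.is_specific(ch),
        }
        for ch in report.mask.responsive
    ]
    pd.DataFrame(mask_rows).to_csv(outdir / "specificity_mask.csv", index=False)
    report.model.to_table(outdir / "model_table.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=1, sort_keys=True, default=str)
    )
    if report.config.write_recordings:
        rec_dir = outdir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(report.recordings):
            stem = f"{rec.stimulus.tastant.value}_{rec.stimulus.concentration:g}_{rec.chip_id}"
            write_recording(rec, rec_dir / f"{stem}.csv")


_REQUIRED_TABLES = (
    "feature_matrix", "replicate_matrix", "summary", "radar", "pca", "clusters",
)


def make_figures(report: PipelineReport, outdir: str | Path) -> list[Path]:
    """Static per-experiment figures: representative traces, a spectrogram
    heat map, the radar chart of the 8 normalised parameters and the 3-D
    PCA scatter. Deterministic output (no embedded timestamps)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name in _REQUIRED_TABLES:
        if getattr(report, name, None) is None:
            raise ValueError(f"incomplete bundle: missing {name}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    made: list[Path] = []
    channels = report.mask.specific_channels(report.tastant.value)
    ch = channels[0] if channels else report.recordings[0].channel_ids[0]
    conds = report.conditions

    fig, axes = plt.subplots(len(conds), 1, figsize=(8, 1.6 * len(conds)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, cond in zip(axes, conds):
        rec = next(r for r in report.recordings if r.stimulus == cond)
        t = np.arange(rec.n_samples) / rec.fs
        ax.plot(t, rec.channel(ch), lw=0.3, color="k")
        ax.set_ylabel(str(cond), fontsize=7)
    axes[-1].set_xlabel("time (s)")
    fig.suptitle(f"representative traces, channel {ch}")
    path = outdir / "traces.png"
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    made.append(path)

    from .spectral import compute_spectrogram

    rec = next(r for r in report.recordings if not r.stimulus.is_control)
    spec = compute_spectrogram(
        rec.channel(ch), rec.fs, report.config.window_len_s, report.config.overlap_fraction
    )
    keep = spec.freqs_hz <= 40
    fig, ax = plt.subplots(figsize=(8, 3))
    pcm = ax.pcolormesh(
        spec.times_s, spec.freqs_hz[keep],
        10 * np.log10(spec.power[:, keep].T + 1e-12), shading="auto",
    )
    fig.colorbar(pcm, ax=ax, label="PSD (dB µV²/Hz)")
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)", title=str(rec.stimulus))
    path = outdir / "spectrogram.png"
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    made.append(path)

    angles = np.linspace(0, 2 * np.pi, len(FEATURE_COLUMNS), endpoint=False)
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    for key, row in report.radar.iterrows():
        vals = row[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=str(key))
    ax.set_xticks(angles)
    ax.set_xticklabels(FEATURE_COLUMNS, fontsize=7)
    ax.legend(fontsize=6, loc="upper right", bbox_to_anchor=(1.3, 1.1))
    path = outdir / "radar.png"
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    made.append(path)

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    concs = report.replicate_matrix["concentration"].to_numpy()
    sc = ax.scatter(
        report.pca.scores[:, 0], report.pca.scores[:, 1], report.pca.scores[:, 2],
        c=report.clusters.labels, cmap="tab10", s=40,
    )
    for i, c in enumerate(concs):
        ax.text(*report.pca.scores[i, :3], f"{c:g}", fontsize=6)
    ax.set(xlabel="PC1", ylabel="PC2", zlabel="PC3")
    path = outdir / "pca_scatter.png"
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    made.append(path)
    return made
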