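"""Assembly of the 8-parameter feature vectors and group statistics.

Each analysed channel of each recording yields an ordered 8-vector: the
five band PSDs (δ, θ, α, β, γ; µV²/Hz) followed by the three spike-train
features (fire rate in spikes/s, maximum and average peak-to-peak amplitude
in µV). Feature matrices are plain pandas DataFrames carrying the stimulus
label, chip/replicate id and channel id as metadata columns.

The statistical unit for the n=3 group comparisons is the replicate
recording (chip): channel values are averaged within a recording before
ANOVA / Fisher's LSD (``aggregate_by_replicate``); per-channel testing
remains available by passing the unaggregated matrix.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recording import Recording
from .spectral import FrequencyBand, METHODS_BANDS, compute_band_psds
from .spikes import SpikeDetectionConfig, compute_spike_features, detect_spikes

__all__ = [
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "extract_feature_matrix",
    "aggregate_by_replicate",
    "summarize_conditions",
    "normalize_for_radar",
    "one_way_anova",
    "fisher_lsd",
]

FEATURE_COLUMNS = (
    "psd_delta",
    "psd_theta",
    "psd_alpha",
    "psd_beta",
    "psd_gamma",
    "fire_rate",
    "max_amplitude",
    "mean_amplitude",
)
META_COLUMNS = ("tastant", "concentration", "concentration_units", "chip_id", "channel")


def extract_feature_matrix(
    recordings: Iterable[Recording],
    channels: Sequence[str] | None = None,
    window_len_s: float = 1.0,
    overlap_fraction: float = 0.5,
    bands: tuple[FrequencyBand, ...] = METHODS_BANDS,
    spike_cfg: SpikeDetectionConfig | None = None,
) -> pd.DataFrame:
    """One labelled 8-feature row per (recording, channel)."""
    spike_cfg = spike_cfg or SpikeDetectionConfig()
    rows = []
    for rec in recordings:
        use = channels if channels is not None else rec.channel_ids
        for ch in use:
            bps = compute_band_psds(rec, ch, window_len_s, overlap_fraction, bands)
            events = detect_spikes(rec.channel(ch), rec.fs, spike_cfg)
            spk = compute_spike_features(events, rec.duration_s)
            rows.append(
                {
                    "tastant": rec.stimulus.tastant.value,
                    "concentration": rec.stimulus.concentration,
                    "concentration_units": rec.stimulus.concentration_units.value,
                    "chip_id": rec.chip_id,
                    "channel": ch,
                    "psd_delta": bps.psd["delta"],
                    "psd_theta": bps.psd["theta"],
                    "psd_alpha": bps.psd["alpha"],
                    "psd_beta": bps.psd["beta"],
                    "psd_gamma": bps.psd["gamma"],
                    "fire_rate": spk.fire_rate_hz,
                    "max_amplitude": spk.max_amplitude_uv,
                    "mean_amplitude": spk.mean_amplitude_uv,
                }
            )
    if not rows:
        raise ValueError("no data: no (recording, channel) pairs to featurise")
    return pd.DataFrame(rows)


def aggregate_by_replicate(fm: pd.DataFrame) -> pd.DataFrame:
    """Average channels within each (condition, chip) replicate recording."""
    keys = ["tastant", "concentration", "concentration_units", "chip_id"]
    out = fm.groupby(keys, as_index=False, sort=True)[list(FEATURE_COLUMNS)].mean()
    return out


def summarize_conditions(fm: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, feature) mean, sample SD (n-1) and n.

    Rows of the input are the statistical units (aggregate first if the
    unit is the replicate recording).
    """
    if fm.empty:
        raise ValueError("no data: empty feature matrix")
    long = fm.melt(
        id_vars=["tastant", "concentration"],
        value_vars=list(FEATURE_COLUMNS),
        var_name="feature",
    )
    grouped = long.groupby(["tastant", "concentration", "feature"], sort=True)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] == 1, "sd"] = 0.0
    return out


def normalize_for_radar(summary: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalise condition means per feature to [0, 1].

    Input is the output of :func:`summarize_conditions`. A feature whose
    condition means are all equal maps to 0 everywhere.
    """
    pivot = summary.pivot_table(
        index=["tastant", "concentration"], columns="feature", values="mean", sort=True
    )
    if len(pivot) < 2:
        raise ValueError("need >= 2 conditions for radar normalization")
    lo, hi = pivot.min(axis=0), pivot.max(axis=0)
    span = hi - lo
    normed = (pivot - lo).divide(span.where(span > 0, np.inf), axis=1)
    return normed[[c for c in FEATURE_COLUMNS if c in normed.columns]]


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("insufficient data: need >= 2 groups with n >= 2 each")
    n_total = sum(a.size for a in arrs)
    if n_total <= len(arrs):
        raise ValueError("insufficient data: no within-group degrees of freedom")
    return arrs


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Ordinary one-way ANOVA: (F, p) over k groups."""
    arrs = _check_groups(groups)
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def fisher_lsd(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Uncorrected Fisher's LSD pairwise p-values.

    Pairwise t statistics use the pooled within-group mean square (MSW)
    with N - k degrees of freedom; two-sided p, no multiplicity
    correction. Returns a symmetric k x k matrix with unit diagonal.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    n = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df = int(n.sum() - k)
    msw = ssw / df
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw * (1 / n[i] + 1 / n[j]))
            if se == 0:
                p = 1.0 if means[i] == means[j] else 0.0
            else:
                t = (means[i] - means[j]) / se
                p = 2 * float(stats.t.sf(abs(t), df))
            pmat[i, j] = pmat[j, i] = p
    return pmat
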