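"""Short-time Fourier spectrogram and five-band power spectral density.

The frequency-domain half of the 8-parameter feature set: the signal is
tiled with Hamming-tapered windows, each window yields a one-sided power
spectral density (µV²/Hz, density normalisation), and the five canonical
field-potential bands δ/θ/α/β/γ spanning 0–40 Hz are summarised by the mean
density over (time slices x in-band bins).

Two band-edge conventions are provided. ``"methods"`` (the default, and the
operational definition used everywhere in this package) puts α at 8–12 Hz
and β at 12–30 Hz; ``"results"`` uses α 8–13 / β 13–30 Hz. Bands are
half-open ``[lo, hi)`` so no frequency bin is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import Recording, StimulusLabel

__all__ = [
    "FrequencyBand",
    "METHODS_BANDS",
    "RESULTS_BANDS",
    "get_bands",
    "BAND_NAMES",
    "Spectrogram",
    "BandPowerSet",
    "compute_spectrogram",
    "band_power",
    "compute_band_psds",
]


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValueError("band edges must satisfy 0 <= lo < hi")


BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

METHODS_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 0.0, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("alpha", 8.0, 12.0),
    FrequencyBand("beta", 12.0, 30.0),
    FrequencyBand("gamma", 30.0, 40.0),
)

RESULTS_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 0.0, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("alpha", 8.0, 13.0),
    FrequencyBand("beta", 13.0, 30.0),
    FrequencyBand("gamma", 30.0, 40.0),
)


def get_bands(edges: str = "methods") -> tuple[FrequencyBand, ...]:
    """Return the canonical five-band set for an edge convention."""
    try:
        return {"methods": METHODS_BANDS, "results": RESULTS_BANDS}[edges]
    except KeyError:
        raise ValueError(f"unknown band edge set: {edges!r}") from None


@dataclass
class Spectrogram:
    """Time x frequency one-sided power density (µV²/Hz)."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # shape (n_times, n_freqs)
    window_len_s: float
    overlap_fraction: float


@dataclass
class BandPowerSet:
    """Mean band PSD (µV²/Hz) for the five canonical bands of one channel."""

    psd: dict[str, float]
    channel_id: str = ""
    stimulus: StimulusLabel = field(default_factory=StimulusLabel)

    @property
    def total(self) -> float:
        return float(sum(self.psd.values()))


def compute_spectrogram(
    x: np.ndarray,
    fs: float,
    window_len_s: float = 1.0,
    overlap_fraction: float = 0.5,
) -> Spectrogram:
    """Hamming-windowed short-time PSD with one-sided density scaling.

    Each window is mean-subtracted before tapering so a DC electrode offset
    does not leak into the δ band. The number of time slices equals
    ``floor((N - W) / (W - O)) + 1`` for window W and overlap O samples.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D signal")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    nperseg = int(round(window_len_s * fs))
    if nperseg < 2:
        raise ValueError("window too short")
    if x.size < nperseg:
        raise ValueError(
            f"signal too short: {x.size} samples < one {nperseg}-sample window"
        )
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, times, sxx = sps.spectrogram(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    return Spectrogram(
        times_s=times,
        freqs_hz=freqs,
        power=sxx.T,
        window_len_s=window_len_s,
        overlap_fraction=overlap_fraction,
    )


def band_power(spec: Spectrogram, band: FrequencyBand) -> float:
    """Mean power density over time slices and bins with ``lo <= f < hi``."""
    mask = (spec.freqs_hz >= band.lo_hz) & (spec.freqs_hz < band.hi_hz)
    if not mask.any():
        raise ValueError(
            f"empty band: no frequency bins in [{band.lo_hz}, {band.hi_hz}) Hz"
        )
    return float(spec.power[:, mask].mean())


def compute_band_psds(
    rec: Recording,
    channel: str,
    window_len_s: float = 1.0,
    overlap_fraction: float = 0.5,
    bands: tuple[FrequencyBand, ...] = METHODS_BANDS,
) -> BandPowerSet:
    """Five-band PSD summary of one channel of a recording."""
    spec = compute_spectrogram(
        rec.channel(channel), rec.fs, window_len_s, overlap_fraction
    )
    psd = {b.name: band_power(spec, b) for b in bands}
    return BandPowerSet(psd=psd, channel_id=channel, stimulus=rec.stimulus)
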