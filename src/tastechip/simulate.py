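"""Ground-truthed synthetic taste-organoid MEA recordings.

The simulator stands in for the biological chip: each electrode sees one
taste-receptor cell type, and a :class:`TasteResponseModel` maps
(cell type, tastant, concentration) to the generative parameters of the
extracellular trace recorded at that electrode:

* a Poisson spike train (rate ``spike_rate_hz``) of biphasic template
  spikes whose peak-to-peak amplitudes are lognormal draws,
* five band-limited Gaussian components confined to the canonical
  δ/θ/α/β/γ bands, each with SD ``band_gain[i]`` µV (δ-dominant at
  baseline, as in slow field-potential activity),
* a small white instrument-noise floor (``noise_sd_uv``).

A cell type responds only to its cognate tastant; under any other stimulus
(or control medium) it falls back to its baseline profile. The default
model is calibrated so that the 3-sigma detection pipeline recovers the
reported concentration-response values: planted rates and mean amplitudes
equal the reported per-condition numbers, and the lognormal spread is
solved numerically so the *expected maximum* of the expected number of
draws in a 3-minute recording equals the reported maximum amplitude.

Every stochastic operation takes an explicit integer seed. Sub-streams are
derived with ``numpy.random.SeedSequence([seed, condition_index,
replicate_index, slot])`` where slot 0 carries the chip-level variability
draws and slot ``1 + channel_index`` the per-channel trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .recording import (
    TASTANT_UNITS,
    ConcentrationUnits,
    Recording,
    StimulusLabel,
    Tastant,
)
from .spectral import METHODS_BANDS

__all__ = [
    "CellType",
    "COGNATE_TASTANT",
    "CellTypeProfile",
    "TasteResponseModel",
    "ElectrodeMap",
    "ChannelGroundTruth",
    "GroundTruth",
    "DEFAULT_CONCENTRATIONS",
    "build_default_model",
    "assign_electrodes",
    "simulate_channel",
    "simulate_experiment",
    "spike_template",
    "render_spike_train",
    "expected_lognormal_max",
    "solve_amplitude_sigma",
]

#: Default acquisition geometry: 64 electrodes, 3-minute stimuli, 1 kHz.
#: 1 kHz renders the millisecond spike template while keeping a 3-minute
#: 64-channel experiment tractable; the analysed bands stop at 40 Hz.
DEFAULT_FS = 1000.0
DEFAULT_DURATION_S = 180.0
DEFAULT_N_ELECTRODES = 64

_TEMPLATE_RISE_S = 0.0015
_TEMPLATE_TOTAL_S = 0.0045
_TEMPLATE_PEAK_FRACTION = 0.8  # share of p2p carried by the positive phase


class CellType(str, Enum):
    TYPE_III_SOUR = "typeIII_sour"
    TYPE_II_SWEET = "typeII_sweet"
    TYPE_II_BITTER = "typeII_bitter"
    SALT_SENSOR = "salt_sensor"
    NONRESPONSIVE = "nonresponsive"


COGNATE_TASTANT: dict[CellType, Tastant | None] = {
    CellType.TYPE_III_SOUR: Tastant.SOUR_ACETIC,
    CellType.TYPE_II_SWEET: Tastant.SWEET_SUCROSE,
    CellType.TYPE_II_BITTER: Tastant.BITTER_PTC,
    CellType.SALT_SENSOR: Tastant.SALTY_NACL,
    CellType.NONRESPONSIVE: None,
}


@dataclass(frozen=True)
class CellTypeProfile:
    """Generative parameters of one electrode's trace under one condition."""

    spike_rate_hz: float
    amp_logmean: float
    amp_logsd: float
    band_gain: tuple[float, float, float, float, float]
    noise_sd_uv: float

    def __post_init__(self) -> None:
        if self.spike_rate_hz < 0 or self.noise_sd_uv < 0 or self.amp_logsd < 0:
            raise ValueError("rates, gains and SDs must be non-negative")
        if any(g < 0 for g in self.band_gain):
            raise ValueError("band gains must be non-negative")

    @property
    def mean_amplitude_uv(self) -> float:
        """Expected peak-to-peak spike amplitude, exp(µ + σ²/2)."""
        return float(np.exp(self.amp_logmean + self.amp_logsd**2 / 2))


@dataclass
class TasteResponseModel:
    """Map from (cell type, tastant, concentration) to a profile.

    ``resolve`` implements tastant specificity: a non-cognate stimulus (or
    control) resolves to the cell type's baseline profile.
    """

    baseline: dict[CellType, CellTypeProfile]
    table: dict[tuple[CellType, Tastant, float], CellTypeProfile]

    @staticmethod
    def _key(cell_type: CellType, tastant: Tastant, conc: float):
        return (cell_type, tastant, round(float(conc), 9))

    def resolve(self, cell_type: CellType, stimulus: StimulusLabel) -> CellTypeProfile:
        if stimulus.is_control:
            return self.baseline[cell_type]
        if COGNATE_TASTANT[cell_type] != stimulus.tastant:
            return self.baseline[cell_type]
        key = self._key(cell_type, stimulus.tastant, stimulus.concentration)
        if key not in self.table:
            raise KeyError(
                f"condition not in model: {stimulus.tastant.value} "
                f"{stimulus.concentration} for {cell_type.value}"
            )
        return self.table[key]

    def concentrations(self, tastant: Tastant) -> list[float]:
        return sorted(c for (ct, t, c) in self.table if t == tastant)

    # -- human-readable serialization -------------------------------------

    def to_table(self, path: str | Path) -> None:
        rows = []
        for ct, prof in self.baseline.items():
            rows.append(self._row(ct, Tastant.NONE, 0.0, prof))
        for (ct, t, c), prof in sorted(
            self.table.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2])
        ):
            rows.append(self._row(ct, t, c, prof))
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")

    @staticmethod
    def _row(ct: CellType, t: Tastant, c: float, p: CellTypeProfile) -> dict:
        row = {
            "cell_type": ct.value,
            "tastant": t.value,
            "concentration": c,
            "spike_rate_hz": p.spike_rate_hz,
            "amp_logmean": p.amp_logmean,
            "amp_logsd": p.amp_logsd,
            "noise_sd_uv": p.noise_sd_uv,
        }
        for band, g in zip(("delta", "theta", "alpha", "beta", "gamma"), p.band_gain):
            row[f"gain_{band}"] = g
        return row

    @classmethod
    def from_table(cls, path: str | Path) -> "TasteResponseModel":
        frame = pd.read_csv(path)
        baseline: dict[CellType, CellTypeProfile] = {}
        table: dict[tuple[CellType, Tastant, float], CellTypeProfile] = {}
        for _, row in frame.iterrows():
            prof = CellTypeProfile(
                spike_rate_hz=float(row["spike_rate_hz"]),
                amp_logmean=float(row["amp_logmean"]),
                amp_logsd=float(row["amp_logsd"]),
                band_gain=tuple(
                    float(row[f"gain_{b}"])
                    for b in ("delta", "theta", "alpha", "beta", "gamma")
                ),
                noise_sd_uv=float(row["noise_sd_uv"]),
            )
            ct = CellType(row["cell_type"])
            t = Tastant(row["tastant"])
            if t == Tastant.NONE:
                baseline[ct] = prof
            else:
                table[cls._key(ct, t, float(row["concentration"]))] = prof
        return cls(baseline=baseline, table=table)


@dataclass
class ElectrodeMap:
    assignment: dict[str, CellType]
    n_electrodes: int

    def __post_init__(self) -> None:
        if len(self.assignment) != self.n_electrodes:
            raise ValueError("every electrode must be assigned exactly one cell type")

    def channels_of(self, cell_type: CellType) -> list[str]:
        return [ch for ch, ct in self.assignment.items() if ct == cell_type]

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(self.assignment)


@dataclass
class ChannelGroundTruth:
    """Planted spikes and the profile actually used for one channel."""

    spike_times_s: np.ndarray
    spike_amplitudes_uv: np.ndarray
    profile: CellTypeProfile

    def __post_init__(self) -> None:
        if len(self.spike_times_s) != len(self.spike_amplitudes_uv):
            raise ValueError("times and amplitudes must pair up")


GroundTruth = dict[str, ChannelGroundTruth]


# ---------------------------------------------------------------------------
# amplitude-law calibration
# ---------------------------------------------------------------------------

def expected_lognormal_max(mu: float, sigma: float, n: int) -> float:
    """E[max of n i.i.d. lognormal(mu, sigma) draws], by direct quadrature
    over the order statistic of the underlying normal."""
    if n <= 1:
        return float(np.exp(mu + sigma**2 / 2))
    z = np.linspace(-12, 12, 4001)
    pdf = n * stats.norm.pdf(z) * stats.norm.cdf(z) ** (n - 1)
    return float(np.trapezoid(pdf * np.exp(mu + sigma * z), z))


def solve_amplitude_sigma(
    mean_uv: float, max_uv: float, n_spikes: int, default_sigma: float = 0.25
) -> tuple[float, float]:
    """Solve (amp_logmean, amp_logsd) so E[amplitude] = ``mean_uv`` and the
    expected maximum of ``n_spikes`` draws = ``max_uv``.

    With fewer than two expected spikes the maximum carries no information
    and ``default_sigma`` is used.
    """
    if mean_uv <= 0:
        raise ValueError("mean amplitude must be positive")
    if n_spikes < 2 or max_uv <= mean_uv * 1.02:
        sigma = default_sigma
        return float(np.log(mean_uv) - sigma**2 / 2), sigma

    def gap(sigma: float) -> float:
        mu = np.log(mean_uv) - sigma**2 / 2
        return expected_lognormal_max(mu, sigma, n_spikes) - max_uv

    sigma = float(optimize.brentq(gap, 1e-4, 3.0, xtol=1e-8))
    return float(np.log(mean_uv) - sigma**2 / 2), sigma


# ---------------------------------------------------------------------------
# default model
# ---------------------------------------------------------------------------

#: Baseline (control-medium) generative parameters shared by all cell types:
#: essentially silent spiking and a δ-dominated 0-40 Hz background.
_BASELINE_RATE = 0.001
_BASELINE_AMP_MEAN = 20.0
_BASELINE_GAINS = (0.42, 0.07, 0.03, 0.015, 0.010)
_NOISE_SD = 0.01

#: Per-condition anchors: concentration -> (rate Hz, mean amp µV, max amp µV,
#: band gains µV). Acetic-acid time-domain values are the reported
#: concentration-response numbers; the other tastants' time-domain values and
#: all band-gain ladders are model constants chosen to satisfy the reported
#: ordinal patterns (see docs/methods.md). A ``None`` entry means the
#: condition is generatively identical to baseline (below the chip's taste
#: threshold).
_ANCHORS: dict[Tastant, dict[float, tuple | None]] = {
    Tastant.SOUR_ACETIC: {
        25.0: (0.25, 64.16, 293.40, (1.230, 0.410, 0.305, 0.125, 0.0110)),
        12.5: (0.09, 61.47, 182.90, (1.225, 0.400, 0.300, 0.118, 0.0108)),
        6.25: (0.06, 54.45, 122.50, (1.215, 0.390, 0.038, 0.016, 0.0106)),
        3.125: (0.05, 32.63, 74.91, (1.205, 0.101, 0.0376, 0.0158, 0.0104)),
        1.5625: (0.001, 5.40, 5.40, (1.200, 0.0995, 0.037, 0.0156, 0.0102)),
    },
    Tastant.SWEET_SUCROSE: {
        1.0: (0.15, 45.0, 110.0, (1.26, 0.42, 0.248, 0.055, 0.0110)),
        0.75: (0.22, 58.0, 135.0, (1.25, 0.41, 0.240, 0.105, 0.0425)),
        0.5: (0.18, 56.0, 140.0, (1.23, 0.40, 0.037, 0.100, 0.0420)),
        0.25: (0.08, 30.0, 68.0, (1.20, 0.10, 0.036, 0.016, 0.0102)),
        0.125: None,
    },
    Tastant.BITTER_PTC: {
        10.0: (0.12, 50.0, 110.0, (1.24, 0.40, 0.180, 0.105, 0.040)),
        1.0: (0.16, 52.0, 118.0, (1.22, 0.39, 0.175, 0.100, 0.038)),
        0.1: (0.11, 38.0, 85.0, (1.20, 0.38, 0.170, 0.095, 0.036)),
        0.01: (0.008, 18.0, 22.0, (0.44, 0.072, 0.031, 0.0158, 0.0103)),
        0.001: None,
    },
    Tastant.SALTY_NACL: {
        6.0: (0.12, 55.0, 150.0, (1.25, 0.42, 0.032, 0.0158, 0.0104)),
        4.5: (0.11, 48.0, 85.0, (1.15, 0.36, 0.031, 0.0157, 0.0103)),
        3.0: (0.06, 47.0, 95.0, (0.46, 0.084, 0.030, 0.0156, 0.0102)),
        1.5: None,
        0.75: None,
    },
}

_TASTANT_CELL: dict[Tastant, CellType] = {
    t: ct for ct, t in COGNATE_TASTANT.items() if t is not None
}

#: Concentration series of the four dose-response experiments (descending).
DEFAULT_CONCENTRATIONS: dict[Tastant, list[float]] = {
    t: sorted(anchors, reverse=True) for t, anchors in _ANCHORS.items()
}


def default_conditions(tastant: Tastant, include_control: bool = True) -> list[StimulusLabel]:
    """The tastant's concentration series as stimulus labels, control first."""
    units = TASTANT_UNITS[tastant]
    labels = [StimulusLabel()] if include_control else []
    labels += [
        StimulusLabel(tastant, c, units)
        for c in sorted(DEFAULT_CONCENTRATIONS[tastant])
    ]
    return labels


def build_default_model(
    duration_s: float = DEFAULT_DURATION_S,
    noise_sd_uv: float = _NOISE_SD,
) -> TasteResponseModel:
    """Default taste-response model calibrated to the reported
    concentration-response anchors.

    ``duration_s`` is the recording length assumed when converting a
    reported maximum amplitude into a lognormal spread (the expected number
    of draws is ``rate * duration``); the reference protocol is 3 minutes.
    """
    mu0 = float(np.log(_BASELINE_AMP_MEAN) - 0.3**2 / 2)
    baseline = {
        ct: CellTypeProfile(
            spike_rate_hz=_BASELINE_RATE,
            amp_logmean=mu0,
            amp_logsd=0.3,
            band_gain=_BASELINE_GAINS,
            noise_sd_uv=noise_sd_uv,
        )
        for ct in CellType
    }
    table: dict[tuple[CellType, Tastant, float], CellTypeProfile] = {}
    for tastant, anchors in _ANCHORS.items():
        ct = _TASTANT_CELL[tastant]
        for conc, anchor in anchors.items():
            if anchor is None:
                prof = baseline[ct]
            else:
                rate, mean_amp, max_amp, gains = anchor
                n_expected = int(round(rate * duration_s))
                mu, sigma = solve_amplitude_sigma(mean_amp, max_amp, n_expected)
                prof = CellTypeProfile(
                    spike_rate_hz=rate,
                    amp_logmean=mu,
                    amp_logsd=sigma,
                    band_gain=tuple(gains),
                    noise_sd_uv=noise_sd_uv,
                )
            table[TasteResponseModel._key(ct, tastant, conc)] = prof
    return TasteResponseModel(baseline=baseline, table=table)


# ---------------------------------------------------------------------------
# electrode assignment
# ---------------------------------------------------------------------------

def assign_electrodes(
    n_electrodes: int = DEFAULT_N_ELECTRODES,
    proportions: Mapping[CellType, float] | None = None,
    seed: int = 0,
) -> ElectrodeMap:
    """Assign each electrode one cell type.

    Counts follow largest-remainder rounding of ``n * fraction`` (ties are
    broken in ``CellType`` declaration order), and the spatial arrangement
    is shuffled deterministically by ``seed``. The default mixture is an
    equal split of the four responsive types plus nonresponsive tissue.
    """
    if proportions is None:
        proportions = {ct: 1 / 5 for ct in CellType}
    fracs = {ct: float(f) for ct, f in proportions.items()}
    if any(f < 0 for f in fracs.values()) or abs(sum(fracs.values()) - 1) > 1e-9:
        raise ValueError("invalid proportions: fractions must be >= 0 and sum to 1")
    order = [ct for ct in CellType if ct in fracs]
    exact = {ct: n_electrodes * fracs[ct] for ct in order}
    counts = {ct: int(np.floor(exact[ct])) for ct in order}
    short = n_electrodes - sum(counts.values())
    for ct in sorted(order, key=lambda c: exact[c] - counts[c], reverse=True)[:short]:
        counts[ct] += 1
    types: list[CellType] = []
    for ct in order:
        types += [ct] * counts[ct]
    rng = np.random.default_rng(seed)
    types = [types[i] for i in rng.permutation(n_electrodes)]
    width = len(str(n_electrodes))
    ids = [f"E{i + 1:0{width}d}" for i in range(n_electrodes)]
    return ElectrodeMap(assignment=dict(zip(ids, types)), n_electrodes=n_electrodes)


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def spike_template(fs: float) -> np.ndarray:
    """Biphasic extracellular spike template with unit peak-to-peak span.

    1.5 ms rise to the positive peak, 3 ms decay through a shallow
    undershoot back to zero. The sampled template is renormalised so its
    max - min is exactly 1, making planted peak-to-peak amplitudes exact at
    any sampling rate that resolves the template.
    """
    n = int(np.floor(_TEMPLATE_TOTAL_S * fs)) + 1
    if n < 2:
        raise ValueError("fs too low to render the spike template")
    t = np.arange(n) / fs
    g = np.zeros(n)
    peak, trough_t = _TEMPLATE_PEAK_FRACTION, _TEMPLATE_RISE_S + 0.001
    rise = t < _TEMPLATE_RISE_S
    g[rise] = peak * np.sin(np.pi * t[rise] / (2 * _TEMPLATE_RISE_S))
    # fast downstroke: peak to trough 1 ms after the peak
    mid = (t >= _TEMPLATE_RISE_S) & (t < trough_t)
    g[mid] = (peak - 0.5) + 0.5 * np.cos(np.pi * (t[mid] - _TEMPLATE_RISE_S) / 0.001)
    # slow repolarisation back to baseline
    tail = t >= trough_t
    g[tail] = -(1 - peak) * np.cos(
        np.pi * (t[tail] - trough_t) / (2 * (_TEMPLATE_TOTAL_S - trough_t))
    )
    span = g.max() - g.min()
    if span == 0:
        raise ValueError("fs too low to render the spike template")
    return g / span


def render_spike_train(
    times_s: np.ndarray,
    amplitudes_uv: np.ndarray,
    duration_s: float,
    fs: float,
) -> np.ndarray:
    """Render spikes onto a zero trace; overlapping templates sum."""
    n = int(round(duration_s * fs))
    template = spike_template(fs) if len(times_s) else np.zeros(1)
    out = np.zeros(n)
    for t, a in zip(times_s, amplitudes_uv):
        start = int(round(t * fs))
        stop = min(start + len(template), n)
        if start >= n:
            continue
        out[start:stop] += a * template[: stop - start]
    return out


def _band_background(
    rng: np.random.Generator, n: int, fs: float, gains: Sequence[float]
) -> np.ndarray:
    """Sum of five band-limited Gaussian components, one per canonical band,
    each normalised to SD = gain (µV) within this realisation."""
    if not any(g > 0 for g in gains):
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaped = np.zeros_like(spectrum)
    for band, gain in zip(METHODS_BANDS, gains):
        if gain <= 0:
            continue
        # guard margins inside the band edges: keep the component's energy
        # inside its nominal band even after short-time-window smearing
        # (the upper guard is wider because smearing rides on the steep
        # low-frequency rolloff)
        lo = band.lo_hz + 0.5
        hi = band.hi_hz - 1.25
        mask = (freqs >= lo) & (freqs < hi) & (freqs > 0) & (freqs < fs / 2)
        if not mask.any():
            continue
        # Parseval: variance of the band component from its rfft bins
        var = 2.0 * np.sum(np.abs(spectrum[mask]) ** 2) / n**2
        if var <= 0:
            continue
        shaped[mask] = spectrum[mask] * (gain / np.sqrt(var))
    return np.fft.irfft(shaped, n)


def simulate_channel(
    profile: CellTypeProfile,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> tuple[np.ndarray, ChannelGroundTruth]:
    """Simulate one electrode trace plus its ground truth.

    Signal = band-limited Gaussian background + white noise + Poisson
    spike train of biphasic templates with lognormal peak-to-peak
    amplitudes. Deterministic given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    spike_template(fs)  # raises "fs too low" before any drawing
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    signal = _band_background(rng, n, fs, profile.band_gain)
    if profile.noise_sd_uv > 0:
        signal = signal + profile.noise_sd_uv * rng.standard_normal(n)
    count = rng.poisson(profile.spike_rate_hz * duration_s)
    times = np.sort(rng.uniform(0, duration_s, count))
    amps = rng.lognormal(profile.amp_logmean, profile.amp_logsd, count)
    if count:
        signal = signal + render_spike_train(times, amps, duration_s, fs)
    truth = ChannelGroundTruth(
        spike_times_s=times, spike_amplitudes_uv=amps, profile=profile
    )
    return signal, truth


def _chip_effects(
    rng: np.random.Generator, cv: float, cv_gain: float
) -> tuple[float, float, float]:
    """Multiplicative chip-level variability: lognormal factors of mean 1
    for the spike rate and the amplitude scale (coefficient of variation
    ``cv``, cellular excitability differs between organoid batches) and a
    single shared electrode-coupling factor for all five band gains
    (``cv_gain``; band powers of one chip co-vary and couple more stably)."""

    def draw(c: float) -> float:
        if c <= 0:
            return 1.0
        s = float(np.sqrt(np.log1p(c**2)))
        return float(rng.lognormal(-s**2 / 2, s))

    return draw(cv), draw(cv), draw(cv_gain)


def _perturbed(profile: CellTypeProfile, fx: tuple[float, float, float]) -> CellTypeProfile:
    eta_rate, eta_amp, eta_gain = fx
    return replace(
        profile,
        spike_rate_hz=profile.spike_rate_hz * eta_rate,
        amp_logmean=profile.amp_logmean + float(np.log(eta_amp)),
        band_gain=tuple(g * eta_gain for g in profile.band_gain),
    )


def simulate_experiment(
    model: TasteResponseModel,
    emap: ElectrodeMap,
    conditions: Sequence[StimulusLabel],
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    n_replicates: int = 3,
    seed: int = 0,
    chip_cv: float = 0.10,
    chip_cv_gain: float = 0.04,
) -> list[tuple[Recording, GroundTruth]]:
    """Simulate one recording per (condition, replicate).

    Each replicate emulates an independent chip/session: a shared
    multiplicative lognormal factor (CV ``chip_cv``) perturbs the rate,
    amplitude scale and band gains of every channel of that recording,
    reproducing the chip-to-chip spread of replicate experiments. The
    20-minute recovery between stimuli is modelled as full statistical
    independence between recordings.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    # fail fast if any condition is unresolvable
    for cond in conditions:
        for ct in set(emap.assignment.values()):
            model.resolve(ct, cond)
    out: list[tuple[Recording, GroundTruth]] = []
    channel_ids = emap.channel_ids
    for ci, cond in enumerate(conditions):
        for r in range(n_replicates):
            fx_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), ci, r, 0])
            )
            fx = _chip_effects(fx_rng, chip_cv, chip_cv_gain)
            samples = np.empty((len(channel_ids), int(round(duration_s * fs))))
            truth: GroundTruth = {}
            for k, ch in enumerate(channel_ids):
                profile = _perturbed(model.resolve(emap.assignment[ch], cond), fx)
                child = np.random.SeedSequence([int(seed), ci, r, 1 + k])
                sig, ch_truth = simulate_channel(
                    profile, duration_s, fs, seed=child.generate_state(1)[0]
                )
                samples[k] = sig
                truth[ch] = ch_truth
            rec = Recording(
                samples=samples,
                fs=fs,
                channel_ids=channel_ids,
                stimulus=cond,
                chip_id=f"chip{r + 1}",
            )
            out.append((rec, truth))
    return out
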