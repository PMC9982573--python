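"""Multichannel extracellular-potential recording container.

A :class:`Recording` holds a channels x samples matrix of potentials in µV
together with the sampling rate and the taste stimulus applied during the
recording. On disk a recording is a plain numeric CSV (rows = samples,
columns = channels, header row = channel ids) plus a JSON sidecar
``<stem>.meta.json`` with keys ``fs_hz``, ``units``, ``tastant``,
``concentration``, ``concentration_units`` and ``chip_id``. The format is
deliberately language-neutral and inspectable with a text editor.

Units are fixed to µV and Hz inside the data model; any conversion belongs
at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tastant",
    "ConcentrationUnits",
    "StimulusLabel",
    "Recording",
    "read_recording",
    "write_recording",
    "subset_recording",
]


class Tastant(str, Enum):
    """Taste stimulus identity used throughout the pipeline."""

    NONE = "none"
    SOUR_ACETIC = "sour_acetic"
    SWEET_SUCROSE = "sweet_sucrose"
    BITTER_PTC = "bitter_PTC"
    SALTY_NACL = "salty_NaCl"


class ConcentrationUnits(str, Enum):
    MG_PER_ML = "mg_per_mL"
    G_PER_ML = "g_per_mL"
    MM = "mM"
    M = "M"


#: Units each tastant is dosed in (acetic acid mg/mL, sucrose g/mL, PTC mM,
#: NaCl mol/L), following the concentration series of the source experiments.
TASTANT_UNITS: dict[Tastant, ConcentrationUnits] = {
    Tastant.SOUR_ACETIC: ConcentrationUnits.MG_PER_ML,
    Tastant.SWEET_SUCROSE: ConcentrationUnits.G_PER_ML,
    Tastant.BITTER_PTC: ConcentrationUnits.MM,
    Tastant.SALTY_NACL: ConcentrationUnits.M,
}


@dataclass(frozen=True)
class StimulusLabel:
    """Tastant identity plus dose. ``tastant=NONE`` means control medium."""

    tastant: Tastant = Tastant.NONE
    concentration: float = 0.0
    concentration_units: ConcentrationUnits = ConcentrationUnits.MG_PER_ML

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.tastant == Tastant.NONE:
            if self.concentration != 0:
                raise ValueError("tastant=none implies concentration=0")
        else:
            expected = TASTANT_UNITS[self.tastant]
            if self.concentration_units != expected:
                raise ValueError(
                    f"{self.tastant.value} is dosed in {expected.value}, "
                    f"got {self.concentration_units.value}"
                )

    @property
    def is_control(self) -> bool:
        return self.tastant == Tastant.NONE

    def key(self) -> tuple[str, float]:
        """Hashable (tastant, concentration) pair used as a condition key."""
        return (self.tastant.value, float(self.concentration))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_control:
            return "control"
        return f"{self.tastant.value} {self.concentration:g} {self.concentration_units.value}"


CONTROL = StimulusLabel()


@dataclass
class Recording:
    """Channels x samples extracellular potential trace in µV."""

    samples: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]
    stimulus: StimulusLabel = field(default_factory=StimulusLabel)
    chip_id: str = "chip1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        self.channel_ids = tuple(str(c) for c in self.channel_ids)
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"shape mismatch: {len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.samples.shape[0] < 1:
            raise ValueError("need at least one channel")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite sample in recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        try:
            i = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel: {channel_id!r}") from None
        return self.samples[i]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_name(path.with_suffix("").name + ".meta.json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` to ``path`` (CSV) plus its JSON metadata sidecar.

    Values are written with 12 significant digits so that a read/write round
    trip reproduces samples to well below 1e-9 µV.
    """
    path = Path(path)
    if not np.all(np.isfinite(rec.samples)):  # defensive; ctor also checks
        raise ValueError("non-finite sample; refusing to write")
    frame = pd.DataFrame(rec.samples.T, columns=list(rec.channel_ids))
    frame.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "fs_hz": rec.fs,
        "units": "uV",
        "n_channels": rec.n_channels,
        "tastant": rec.stimulus.tastant.value,
        "concentration": rec.stimulus.concentration,
        "concentration_units": rec.stimulus.concentration_units.value,
        "chip_id": rec.chip_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata missing: expected sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        frame = pd.read_csv(path, dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"parse error: non-numeric sample in {path}: {exc}") from exc
    declared = int(meta.get("n_channels", frame.shape[1]))
    if frame.shape[1] != declared:
        raise ValueError(
            f"shape mismatch: CSV has {frame.shape[1]} columns, sidecar "
            f"declares {declared} channels"
        )
    stimulus = StimulusLabel(
        tastant=Tastant(meta["tastant"]),
        concentration=float(meta["concentration"]),
        concentration_units=ConcentrationUnits(meta["concentration_units"]),
    )
    return Recording(
        samples=frame.to_numpy().T,
        fs=float(meta["fs_hz"]),
        channel_ids=tuple(frame.columns),
        stimulus=stimulus,
        chip_id=str(meta.get("chip_id", "chip1")),
    )


def subset_recording(
    rec: Recording,
    channels: Sequence[str] | None = None,
    t0_s: float = 0.0,
    t1_s: float | None = None,
) -> Recording:
    """Return the sub-recording with ``channels`` (in the requested order)
    restricted to the half-open time window ``[t0_s, t1_s)``.

    Sample indices are ``floor(t * fs)`` so adjacent windows concatenate
    without duplicating samples.
    """
    if channels is None:
        channels = rec.channel_ids
    if t1_s is None:
        t1_s = rec.duration_s
    unknown = [c for c in channels if c not in rec.channel_ids]
    if unknown:
        raise KeyError(f"unknown channel: {unknown}")
    if not (0 <= t0_s < t1_s <= rec.duration_s + 1e-12):
        raise ValueError(f"empty window: [{t0_s}, {t1_s}) out of [0, {rec.duration_s}]")
    i0 = int(np.floor(t0_s * rec.fs))
    i1 = int(np.floor(t1_s * rec.fs))
    if i1 <= i0:
        raise ValueError("empty window: no samples in range")
    rows = [rec.channel_ids.index(c) for c in channels]
    return replace(
        rec,
        samples=rec.samples[rows, i0:i1].copy(),
        channel_ids=tuple(channels),
    )
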