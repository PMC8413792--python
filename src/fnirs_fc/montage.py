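"""Measurement geometry and block protocol for the 48-channel frontal fNIRS montage.

The montage covers the prefrontal and motor cortices with 16 dual-wavelength
(760/850 nm) sources and 16 photodetectors placed on international 10-10
scalp positions, defining 48 source-detector channels at a nominal 3 cm
separation.  The recording protocol is a one-minute eyes-open rest followed
by six 10-s finger-tapping stimuli (alternating left/right index finger)
with 10-s inter-stimulus intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

SOURCE_LABELS: tuple[str, ...] = (
    "F3", "AF7", "AF3", "Fz", "Fpz", "AF4", "F4", "AF8",
    "FC6", "C4", "FC2", "CP2", "FC1", "CP1", "C3", "FC5",
)
DETECTOR_LABELS: tuple[str, ...] = (
    "F5", "F1", "Fp1", "AFz", "F2", "Fp2", "F6", "AFF6h",
    "C6", "CC4", "CP4", "C2", "C1", "FC3", "CP3", "C5",
)

WAVELENGTHS_NM: tuple[float, float] = (760.0, 850.0)
DEFAULT_FS_HZ = 3.9

# Flat 2-D scalp-grid coordinates (units of one 10-10 step, approx. 3 cm).
# Rows front to back: Fp, AF, AFF (10-5 intermediate), F, FC, C, CC
# (10-5 intermediate), CP.  Columns: odd = left, even = right, z = midline.
_ROW_Y = {"Fp": 5.0, "AF": 4.0, "AFF": 3.5, "F": 3.0, "FC": 2.0,
          "C": 1.0, "CC": 0.5, "CP": 0.0}
_GRID_STEP_CM = 3.0


def _label_xy(label: str) -> tuple[float, float]:
    """Coordinates of a 10-10 (or intermediate 10-5) label on the flat grid."""
    stem = label[:-1] if label.endswith("h") else label
    if stem.endswith("z"):
        row, col = stem[:-1], "z"
    else:
        i = 0
        while i < len(stem) and not stem[i].isdigit():
            i += 1
        row, col = stem[:i], stem[i:]
    y = _ROW_Y[row]
    if col == "z":
        x = 0.0
    else:
        n = int(col)
        x = math.ceil(n / 2) * (1.0 if n % 2 == 0 else -1.0)
    return x, y


@dataclass(frozen=True)
class Montage:
    """Optode layout: labelled sources/detectors and their channel pairing."""

    source_labels: tuple[str, ...]
    detector_labels: tuple[str, ...]
    channels: tuple[tuple[str, str], ...]
    source_detector_distance_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.source_detector_distance_cm <= 0:
            raise ValueError("source-detector distance must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels in montage")
        for src, det in self.channels:
            if src not in self.source_labels:
                raise ValueError(f"channel references unknown source {src!r}")
            if det not in self.detector_labels:
                raise ValueError(f"channel references unknown detector {det!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_names(self) -> list[str]:
        return [f"{s}-{d}" for s, d in self.channels]

    def channel_positions(self) -> np.ndarray:
        """Channel midpoints on the flat scalp grid, in cm, shape (n, 2)."""
        out = np.empty((self.n_channels, 2))
        for k, (s, d) in enumerate(self.channels):
            sx, sy = _label_xy(s)
            dx, dy = _label_xy(d)
            out[k] = ((sx + dx) / 2 * _GRID_STEP_CM, (sy + dy) / 2 * _GRID_STEP_CM)
        return out

    def right_hemisphere_channels(self) -> list[int]:
        """Indices of channels whose midpoint lies right of the midline."""
        return [k for k, (x, _) in enumerate(self.channel_positions()) if x > 0]

    def left_hemisphere_channels(self) -> list[int]:
        return [k for k, (x, _) in enumerate(self.channel_positions()) if x < 0]

    def motor_channels(self, hemisphere: str) -> list[int]:
        """Channels over the motor strip (FC/C/CP rows) of one hemisphere.

        Used for planting lateralised finger-tapping responses: a left-hand
        stimulus drives the contralateral (right) motor channels.
        """
        pos = self.channel_positions()
        sign = 1.0 if hemisphere == "right" else -1.0
        # motor strip: grid rows FC..CP, i.e. y midpoints <= 2 grid steps
        return [
            k for k in range(self.n_channels)
            if sign * pos[k, 0] > 0 and pos[k, 1] <= 2.0 * _GRID_STEP_CM
        ]


def build_default_montage() -> Montage:
    """The packaged 16-source / 16-detector frontal montage with 48 channels.

    The published optode lists do not include the source-detector pairing, so
    the packaged montage pairs every source with its three spatially nearest
    detectors on the flat 10-10 grid (ties broken by detector list order),
    which yields exactly 48 channels.  Channels are ordered lexicographically
    by (source index, detector index); readers accept any montage carried in
    the input file, so the pairing is data, not an algorithmic assumption.
    """
    channels: list[tuple[str, str]] = []
    det_xy = [_label_xy(d) for d in DETECTOR_LABELS]
    for src in SOURCE_LABELS:
        sx, sy = _label_xy(src)
        d2 = [(sx - x) ** 2 + (sy - y) ** 2 for x, y in det_xy]
        nearest = sorted(range(len(DETECTOR_LABELS)), key=lambda j: (d2[j], j))[:3]
        for j in sorted(nearest):
            channels.append((src, DETECTOR_LABELS[j]))
    return Montage(SOURCE_LABELS, DETECTOR_LABELS, tuple(channels))


@dataclass(frozen=True)
class EventSchedule:
    """Ordered, non-overlapping labelled epochs (label, onset_s, duration_s)."""

    entries: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        t = -math.inf
        for label, onset, dur in self.entries:
            if dur <= 0:
                raise ValueError(f"non-positive duration for {label}")
            if onset < t:
                raise ValueError("events overlap or are out of order")
            t = onset + dur

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def end_s(self) -> float:
        """End time of the last labelled epoch."""
        last = self.entries[-1]
        return last[1] + last[2]

    def get(self, label: str) -> tuple[float, float]:
        for lab, onset, dur in self.entries:
            if lab == label:
                return onset, dur
        raise KeyError(f"no event labelled {label!r}")

    def stimulus_hand(self, label: str) -> str:
        """Hand performing a stimulus: odd stimuli are left, even are right."""
        if not label.startswith("Stim"):
            raise ValueError(f"{label!r} is not a stimulus")
        return "left" if int(label[4:]) % 2 == 1 else "right"


TASK_STATES: tuple[str, ...] = ("Rest", "Stim1", "Stim2", "Stim3",
                                "Stim4", "Stim5", "Stim6")
SLEEP_STATES: tuple[str, str] = ("before_SD", "after_SD")


def build_default_schedule(
    rest_s: float = 60.0, stim_s: float = 10.0, isi_s: float = 10.0
) -> EventSchedule:
    """One-minute rest, then six 10-s finger-tapping stimuli with 10-s ISIs.

    Stimuli alternate left (Stim1, 3, 5) and right (Stim2, 4, 6) index
    finger; the last stimulus ends at 170 s with the default timings.
    """
    entries: list[tuple[str, float, float]] = [("Rest", 0.0, rest_s)]
    t = rest_s
    for k in range(1, 7):
        entries.append((f"Stim{k}", t, stim_s))
        t += stim_s + isi_s
    return EventSchedule(tuple(entries))


@dataclass
class Recording:
    """One fNIRS session: dual-wavelength optical-density change per channel.

    ``od`` has shape (time, channel, wavelength) and holds optical-density
    change relative to the per-channel temporal mean intensity,
    OD(t) = -log10(I(t) / mean(I)).  ``raw_intensity`` (same shape, optional)
    retains the detected light intensities for quality control.
    """

    montage: Montage
    fs_hz: float
    od: np.ndarray
    events: EventSchedule
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM
    subject_id: str = "S01"
    sleep_state: str = "before_SD"
    raw_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.od.ndim != 3:
            raise ValueError("od must have shape (time, channel, wavelength)")
        if self.od.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"od has {self.od.shape[1]} channels, montage defines "
                f"{self.montage.n_channels}"
            )
        if self.od.shape[2] != len(self.wavelengths_nm):
            raise ValueError("od must have one slice per wavelength")
        if self.sleep_state not in SLEEP_STATES:
            raise ValueError(f"unknown sleep state {self.sleep_state!r}")
        if self.n_samples < int(self.events.end_s * self.fs_hz):
            raise ValueError("recording does not span the event schedule")

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical-density change relative to the temporal mean intensity.

    OD(t) = -log10(I(t) / mean_t I); a constant channel maps to identically
    zero.  Intensities must be positive.
    """
    intensity = np.asarray(intensity, dtype=float)
    mean = intensity.mean(axis=0, keepdims=True)
    if np.any(intensity <= 0) or np.any(mean <= 0):
        raise ValueError("intensities must be positive to form optical density")
    return -np.log10(intensity / mean)
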