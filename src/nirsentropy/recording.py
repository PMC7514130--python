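"""Core data containers for channelized fNIRS recordings.

A recording is a set of optical channels (one source-detector pair each)
measured at two wavelengths (690 and 830 nm) at a fixed sampling rate,
with event annotations that partition the session into rest and task
phases (clock drawing, digit span, Corsi block tapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Decadic extinction coefficients, OD / (uM * cm), rows = wavelength.
#: Columns: (O2Hb, HHb).  Values from the standard compiled hemoglobin
#: spectra used by continuous-wave NIRS packages.
EXTINCTION_UM_CM = {
    690.0: (0.000350, 0.002051),
    830.0: (0.000974, 0.000693),
}

#: Differential pathlength factor defaults per wavelength (dimensionless).
DPF_DEFAULT = {690.0: 6.0, 830.0: 5.2}

WAVELENGTHS_NM = (690.0, 830.0)

#: Canonical phase labels, in session order.
PHASE_LABELS = ("rest1", "CDT", "rest2", "DST", "rest3", "CBTT")
TASK_LABELS = ("CDT", "DST", "CBTT")


def extinction_matrix(wavelengths=WAVELENGTHS_NM) -> np.ndarray:
    """2x2 extinction matrix: rows = wavelengths, columns = (O2Hb, HHb)."""
    return np.array([EXTINCTION_UM_CM[float(w)] for w in wavelengths])


def dpf_vector(wavelengths=WAVELENGTHS_NM, dpf=None) -> np.ndarray:
    if dpf is None:
        dpf = DPF_DEFAULT
    if isinstance(dpf, dict):
        return np.array([dpf[float(w)] for w in wavelengths], float)
    return np.asarray(dpf, float)


@dataclass(frozen=True)
class PhaseWindows:
    """Ordered, disjoint half-open sample intervals labelling each phase.

    Each window is ``(label, start_sample, end_sample)`` with
    ``start <= t < end``.
    """

    windows: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        prev_end = 0
        for label, start, end in self.windows:
            if not (0 <= start < end):
                raise ValueError(f"invalid window for {label!r}: [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"window {label!r} overlaps or is out of order")
            prev_end = end

    @classmethod
    def from_durations(cls, plan, sampling_rate: float) -> "PhaseWindows":
        """Build contiguous windows from ``[(label, duration_s), ...]``."""
        windows, cursor = [], 0
        for label, dur_s in plan:
            n = int(round(dur_s * sampling_rate))
            windows.append((label, cursor, cursor + n))
            cursor += n
        return cls(tuple(windows))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w[0] for w in self.windows)

    @property
    def n_samples(self) -> int:
        return self.windows[-1][2]

    def get(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.windows:
            if lab == label:
                return start, end
        raise KeyError(f"no phase labelled {label!r}")

    def length(self, label: str) -> int:
        start, end = self.get(label)
        return end - start

    def truncate(self, label: str, new_length: int) -> "PhaseWindows":
        """Shorten one phase from the end to ``new_length`` samples."""
        start, end = self.get(label)
        if new_length > end - start:
            raise ValueError(
                f"cannot extend phase {label!r} from {end - start} to {new_length}"
            )
        new = tuple(
            (lab, s, s + new_length) if lab == label else (lab, s, e)
            for lab, s, e in self.windows
        )
        return PhaseWindows(new)


@dataclass
class RawIntensityRecording:
    """Two-wavelength light-intensity recording for one subject.

    ``intensities`` has shape (n_channels, n_wavelengths, n_samples) in
    arbitrary units; values must be strictly positive because optical
    density takes their logarithm.
    """

    intensities: np.ndarray
    wavelengths: tuple[float, ...]
    sampling_rate: float
    source_detector_distance_cm: np.ndarray
    events: PhaseWindows
    subject_id: str
    group_label: int  # 1 = patient, 0 = control

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, float)
        self.source_detector_distance_cm = np.asarray(
            self.source_detector_distance_cm, float
        )
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (channels, wavelengths, time)")
        if self.intensities.shape[1] != len(self.wavelengths):
            raise ValueError("wavelength axis does not match wavelengths")
        if self.source_detector_distance_cm.shape != (self.intensities.shape[0],):
            raise ValueError("need one source-detector distance per channel")
        bad = self.intensities <= 0
        if bad.any():
            ch, wl, t = (int(a[0]) for a in np.nonzero(bad))
            raise ValueError(
                f"non-positive intensity at channel {ch}, wavelength index {wl}, "
                f"sample {t}"
            )
        if self.events.n_samples > self.intensities.shape[2]:
            raise ValueError("events extend beyond the recording")
        if self.group_label not in (0, 1):
            raise ValueError("group_label must be 0 (control) or 1 (patient)")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]


@dataclass
class OpticalDensitySeries:
    """Optical-density change series, carrying channel geometry and events."""

    od: np.ndarray  # (channels, wavelengths, time), dimensionless
    wavelengths: tuple[float, ...]
    sampling_rate: float
    source_detector_distance_cm: np.ndarray
    events: PhaseWindows
    subject_id: str
    group_label: int
    history: tuple[str, ...] = ()

    def __post_init__(self):
        self.od = np.asarray(self.od, float)
        if not np.isfinite(self.od).all():
            raise ValueError("optical density contains non-finite values")

    def with_od(self, od: np.ndarray, step: str) -> "OpticalDensitySeries":
        return replace(self, od=od, history=self.history + (step,))


@dataclass
class HemoglobinRecording:
    """O2Hb / HHb concentration-change series (uM) per channel."""

    o2hb: np.ndarray  # (channels, time)
    hhb: np.ndarray  # (channels, time)
    sampling_rate: float
    events: PhaseWindows
    subject_id: str
    group_label: int
    cbsi_applied: bool = False
    history: tuple[str, ...] = ()

    def __post_init__(self):
        self.o2hb = np.asarray(self.o2hb, float)
        self.hhb = np.asarray(self.hhb, float)
        if self.o2hb.shape != self.hhb.shape:
            raise ValueError("o2hb and hhb must have the same shape")

    @property
    def n_channels(self) -> int:
        return self.o2hb.shape[0]

    @property
    def n_samples(self) -> int:
        return self.o2hb.shape[1]
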