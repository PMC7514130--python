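"""Synthetic two-group fNIRS cohorts with a controllable complexity effect.

The clinical recordings this pipeline was designed for are not publicly
deposited, so every downstream stage is exercised on simulated cohorts.
Each subject's latent oxygenated-hemoglobin signal per channel is a
variance-preserving blend of a white (irregular, high Sample Entropy)
process and a strongly autocorrelated second-order autoregressive
(smooth, low Sample Entropy) process.  The blend weight ``noise_mix`` is
the single complexity knob: patients are shifted by ``complexity_effect``
on the affected channels.  Deoxygenated hemoglobin is a negatively scaled
copy of O2Hb plus independent noise, honoring the activation-induced
anticorrelation that the CBSI correction assumes.  Physiological
oscillations (cardiac ~1.1 Hz, respiratory ~0.25 Hz, Mayer waves
~0.1 Hz), a linear drift and motion artifacts are superimposed, and the
result is pushed through the forward modified Beer-Lambert law to obtain
two-wavelength light intensities.

This is deliberately a signal-statistics emulation, not a biophysical
model of Alzheimer hemodynamics: it gives a monotone, verifiable entropy
response to one parameter without claiming disease realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import (
    DPF_DEFAULT,
    PHASE_LABELS,
    TASK_LABELS,
    WAVELENGTHS_NM,
    PhaseWindows,
    RawIntensityRecording,
    dpf_vector,
    extinction_matrix,
)

#: AR(2) coefficients of the smooth (low-complexity) latent process:
#: double pole at 0.9, i.e. x_t = 1.8 x_{t-1} - 0.81 x_{t-2} + e_t.
AR2_COEFFS = (1.8, -0.81)

#: Default phase plan: 1-min rests interleaved with the three tasks.
#: Task durations (before per-subject jitter) sit just above the
#: homogenized lengths used downstream (370 / 380 / 530 samples at 10 Hz).
DEFAULT_PHASE_PLAN = (
    ("rest1", 60.0),
    ("CDT", 37.0),
    ("rest2", 60.0),
    ("DST", 38.0),
    ("rest3", 60.0),
    ("CBTT", 53.0),
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Conditions for one simulated two-group cohort.

    The defaults mirror the acquisition being emulated: 11 patients vs 11
    controls, 21 channels at 10 Hz, tasks separated by 1-min rests, with
    source-detector distances alternating between 3 and 4 cm.
    """

    n_per_group: int = 11
    n_channels: int = 21
    sampling_rate: float = 10.0
    phase_plan: tuple[tuple[str, float], ...] = DEFAULT_PHASE_PLAN
    #: added to the patient group's noise_mix on affected channels
    complexity_effect: float = 0.0
    affected_channels: tuple[int, ...] = (4, 10, 17)
    #: baseline white-vs-AR(2) blend weight (0 = smooth, 1 = white)
    noise_mix: float = 0.5
    #: between-subject SD of the blend weight
    noise_mix_sd: float = 0.08
    #: (cardiac, respiratory, Mayer) amplitudes, uM
    physio_amplitudes: tuple[float, float, float] = (0.2, 0.1, 0.15)
    #: expected motion artifacts per minute
    artifact_rate: float = 0.5
    #: latent functional-oscillation SD, uM
    latent_sd_um: float = 0.5
    #: uniform jitter added to task-phase durations per subject, s
    task_jitter_s: float = 5.0
    #: linear drift magnitude, uM per minute (sign randomized)
    drift_um_per_min: float = 0.3
    #: reference intensity per wavelength, arbitrary units
    i0: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ValueError("noise_mix must be in [0, 1]")
        if any(d <= 0 for _, d in self.phase_plan):
            raise ValueError("phase durations must be positive")
        for lab in TASK_LABELS:
            dur = dict(self.phase_plan).get(lab, 0.0)
            if dur * self.sampling_rate < 300:
                raise ValueError(
                    f"task phase {lab!r} shorter than 300 samples after truncation"
                )
        if any(a < 0 for a in self.physio_amplitudes):
            raise ValueError("physiological amplitudes must be non-negative")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")
        if self.i0 <= 0:
            raise ValueError("reference intensity must be positive")
        if not all(0 <= c < self.n_channels for c in self.affected_channels):
            raise ValueError("affected_channels out of range")


@dataclass
class CohortGroundTruth:
    """What the generator actually did, for validation downstream."""

    affected_channels: tuple[int, ...]
    complexity_effect: float
    #: subject_id -> per-channel blend weight actually used
    noise_mix: dict[str, np.ndarray]
    #: subject_id -> list of artifact event dicts per channel
    artifacts: dict[str, list]
    #: subject_id -> latent O2Hb (channels x time), before physio/drift
    latent_o2hb: dict[str, np.ndarray] = field(default_factory=dict)


def forward_mbll(
    o2hb,
    hhb,
    distance_cm: float,
    dpf=None,
    extinction: np.ndarray | None = None,
    i0: float = 1.0,
    wavelengths=WAVELENGTHS_NM,
):
    """Forward modified Beer-Lambert law: concentrations -> OD -> intensity.

    ``dOD(lambda) = [eps_O2Hb(lambda) * dO2Hb + eps_HHb(lambda) * dHHb]
    * distance * DPF(lambda)`` and ``I(lambda, t) = I0 * 10**(-dOD)``.

    Returns ``(od, intensities)``, each (n_wavelengths, n_samples).
    """
    o2hb = np.asarray(o2hb, float)
    hhb = np.asarray(hhb, float)
    if o2hb.shape != hhb.shape or o2hb.ndim != 1:
        raise ValueError("o2hb and hhb must be 1-D series of equal length")
    if i0 <= 0:
        raise ValueError("reference intensity i0 must be positive")
    ext = extinction_matrix(wavelengths) if extinction is None else np.asarray(extinction, float)
    if ext.shape != (2, 2) or abs(np.linalg.det(ext)) < 1e-15:
        raise ValueError("extinction matrix must be invertible 2x2")
    dpf_v = dpf_vector(wavelengths, dpf)
    conc = np.vstack([o2hb, hhb])  # (2, T)
    od = (ext @ conc) * (distance_cm * dpf_v[:, None])
    return od, i0 * 10.0 ** (-od)


def inject_artifacts(series, artifact_rate: float, sampling_rate: float, rng):
    """Add motion artifacts (spikes and step shifts) at random positions.

    Spikes have amplitude 5-20 x signal SD and width 1-5 samples; step
    shifts are baseline jumps of 1-5 x SD.  Returns the contaminated
    series and the ground-truth event list.
    """
    if artifact_rate < 0:
        raise ValueError("artifact_rate must be non-negative")
    x = np.array(series, float)
    events = []
    if artifact_rate == 0:
        return x, events
    duration_min = len(x) / sampling_rate / 60.0
    n_events = int(rng.poisson(artifact_rate * duration_min))
    sd = x.std() or 1.0
    for _ in range(n_events):
        pos = int(rng.integers(0, len(x)))
        sign = float(rng.choice((-1.0, 1.0)))
        if rng.random() < 0.6:
            amp = sign * float(rng.uniform(5.0, 20.0)) * sd
            width = int(rng.integers(1, 6))
            end = min(len(x), pos + width)
            bump = np.hanning(2 * width + 3)[1 : 1 + (end - pos)] if width > 1 else np.ones(end - pos)
            x[pos:end] += amp * bump
            events.append({"kind": "spike", "index": pos, "amplitude": amp, "width": width})
        else:
            amp = sign * float(rng.uniform(1.0, 5.0)) * sd
            x[pos:] += amp
            events.append({"kind": "shift", "index": pos, "amplitude": amp, "width": len(x) - pos})
    return x, events


def _ar2_process(rng, n: int) -> np.ndarray:
    """Unit-variance strongly autocorrelated AR(2) sample path."""
    a1, a2 = AR2_COEFFS
    burn = 500
    e = rng.standard_normal(n + burn)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], e)[burn:]
    return x / x.std()


def latent_o2hb_signal(rng, n: int, noise_mix: float, sd_um: float) -> np.ndarray:
    """Variance-preserving blend of white and AR(2) processes, scaled to sd_um."""
    w = float(np.clip(noise_mix, 0.0, 1.0))
    white = rng.standard_normal(n)
    smooth = _ar2_process(rng, n)
    x = np.sqrt(w) * white + np.sqrt(1.0 - w) * smooth
    return sd_um * x / x.std()


def _subject_phase_windows(cfg: SyntheticCohortConfig, rng) -> PhaseWindows:
    plan = []
    for label, dur in cfg.phase_plan:
        if label in TASK_LABELS and cfg.task_jitter_s > 0:
            dur = dur + float(rng.uniform(0.0, cfg.task_jitter_s))
        plan.append((label, dur))
    return PhaseWindows.from_durations(plan, cfg.sampling_rate)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[RawIntensityRecording], CohortGroundTruth]:
    """Simulate a patient and a control group of raw intensity recordings.

    Deterministic given ``config.seed``: all randomness flows from one
    seed sequence with one spawned substream per subject.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    subject_streams = ss.spawn(2 * cfg.n_per_group)
    cardiac_amp, resp_amp, mayer_amp = cfg.physio_amplitudes
    ext = extinction_matrix()
    distances = np.where(np.arange(cfg.n_channels) % 2 == 0, 3.0, 4.0)

    recordings: list[RawIntensityRecording] = []
    truth = CohortGroundTruth(
        affected_channels=tuple(cfg.affected_channels),
        complexity_effect=cfg.complexity_effect,
        noise_mix={},
        artifacts={},
    )
    for s in range(2 * cfg.n_per_group):
        group = 1 if s < cfg.n_per_group else 0
        sid = f"{'AD' if group else 'HC'}{(s % cfg.n_per_group) + 1:02d}"
        rng = np.random.default_rng(subject_streams[s])
        events = _subject_phase_windows(cfg, rng)
        n = events.n_samples
        t = np.arange(n) / cfg.sampling_rate

        w_subj = float(np.clip(rng.normal(cfg.noise_mix, cfg.noise_mix_sd), 0.0, 1.0))
        w_channels = np.full(cfg.n_channels, w_subj)
        if group == 1:
            for ch in cfg.affected_channels:
                w_channels[ch] = float(np.clip(w_subj + cfg.complexity_effect, 0.0, 1.0))

        # subject-level physiological rhythms, shared phase across channels
        f_card = rng.uniform(1.0, 1.2)
        f_resp = rng.uniform(0.22, 0.28)
        f_mayer = rng.uniform(0.09, 0.11)
        physio = (
            cardiac_amp * np.sin(2 * np.pi * f_card * t + rng.uniform(0, 2 * np.pi))
            + resp_amp * np.sin(2 * np.pi * f_resp * t + rng.uniform(0, 2 * np.pi))
            + mayer_amp * np.sin(2 * np.pi * f_mayer * t + rng.uniform(0, 2 * np.pi))
        )

        latent = np.empty((cfg.n_channels, n))
        o2hb = np.empty((cfg.n_channels, n))
        hhb = np.empty((cfg.n_channels, n))
        subj_artifacts = []
        for ch in range(cfg.n_channels):
            lat = latent_o2hb_signal(rng, n, w_channels[ch], cfg.latent_sd_um)
            latent[ch] = lat
            drift = (
                float(rng.choice((-1.0, 1.0)))
                * cfg.drift_um_per_min
                * (t / 60.0)
            )
            x = lat + physio + drift
            y = -0.4 * lat + 0.2 * physio + 0.1 * cfg.latent_sd_um * rng.standard_normal(n)
            x, ev = inject_artifacts(x, cfg.artifact_rate, cfg.sampling_rate, rng)
            for e in ev:  # motion moves both chromophores together
                if e["kind"] == "shift":
                    y[e["index"] :] += 0.5 * e["amplitude"]
            o2hb[ch], hhb[ch] = x, y
            subj_artifacts.append(ev)

        intensities = np.empty((cfg.n_channels, 2, n))
        for ch in range(cfg.n_channels):
            _, intensities[ch] = forward_mbll(
                o2hb[ch], hhb[ch], distances[ch], extinction=ext, i0=cfg.i0
            )
        recordings.append(
            RawIntensityRecording(
                intensities=intensities,
                wavelengths=WAVELENGTHS_NM,
                sampling_rate=cfg.sampling_rate,
                source_detector_distance_cm=distances,
                events=events,
                subject_id=sid,
                group_label=group,
            )
        )
        truth.noise_mix[sid] = w_channels
        truth.artifacts[sid] = subj_artifacts
        truth.latent_o2hb[sid] = latent
    return recordings, truth
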