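"""Synthetic oddball ECoG generator.

Emulates epidural multichannel recordings from an auditory oddball session:
event-related components (P1, N1, P2, N2, P3) modelled as polarity-signed
Gaussian bumps of a few µV riding on a mixture of white and 1/f noise, with
per-animal gain/latency variability, treatment effects expressed as
per-component amplitude gains and latency shifts, and occasional
high-amplitude artifact transients. The defaults reproduce the study design
this package analyses: sessions of 1,200 standard and 180 deviant tones
(13% deviants, never two deviants in a row) at 1 s inter-stimulus interval,
sampled at 3 kHz on a 3x3 grid of nine channels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    CHANNELS,
    DEVIANT,
    STANDARD,
    ConstraintError,
    ContinuousRecording,
    EpochSet,
    StimulusSequence,
)

COMPONENT_POLARITY = {"P1": +1, "N1": -1, "P2": +1, "N2": -1, "P3": +1}

#: Relative evoked-response gain per channel. Auditory ERP components peak
#: frontocentrally; the gradient falls off toward posterior sites.
CHANNEL_GAINS = {
    "FC": 1.0, "FL": 0.95, "FR": 0.95,
    "MC": 0.9, "ML": 0.85, "MR": 0.85,
    "PC": 0.8, "PL": 0.75, "PR": 0.75,
}

ARTIFACT_AMPLITUDE_UV = 600.0
ARTIFACT_DURATION_MS = 50.0


@dataclass(frozen=True)
class ComponentTemplate:
    """One ERP component: a Gaussian bump of fixed polarity.

    ``amplitude_uV`` is the (nonnegative) peak magnitude; the rendered
    contribution is ``polarity * amplitude``.
    """

    name: str
    peak_latency_ms: float
    width_ms: float
    amplitude_uV: float

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_POLARITY:
            raise ValueError(f"unknown component {self.name!r}")
        if self.amplitude_uV < 0:
            raise ValueError("amplitude_uV must be >= 0")
        if not 0 < self.peak_latency_ms < 700:
            raise ValueError("peak_latency_ms must lie in (0, 700) ms")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")

    @property
    def polarity(self) -> int:
        return COMPONENT_POLARITY[self.name]


@dataclass(frozen=True)
class ERPTemplate:
    stimulus_class: str
    components: tuple[ComponentTemplate, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique within a template")

    def component(self, name: str) -> ComponentTemplate:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative amplitude gains and additive latency shifts per component.

    The sham (untreated) condition is the identity effect.
    """

    label: str
    gain: dict[str, float] = field(default_factory=dict)
    latency_shift_ms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, g in self.gain.items():
            if name not in COMPONENT_POLARITY:
                raise ValueError(f"gain for unknown component {name!r}")
            if not np.isfinite(g) or g < 0:
                raise ValueError("gains must be finite and >= 0")
        for name in self.latency_shift_ms:
            if name not in COMPONENT_POLARITY:
                raise ValueError(f"latency shift for unknown component {name!r}")

    def gain_for(self, name: str) -> float:
        return self.gain.get(name, 1.0)

    def shift_for(self, name: str) -> float:
        return self.latency_shift_ms.get(name, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study-level simulation parameters.

    Session shape defaults are the oddball protocol this package targets:
    1,200 standards + 180 deviants at 1 s ISI, 3 kHz sampling. Noise defaults
    put a single trial at roughly -10 dB SNR against the deviant template
    (template RMS ~1.5 µV over the epoch, noise SD 5 µV).
    """

    n_animals: int = 10
    animal_gain_sd: float = 0.2
    animal_latency_jitter_sd_ms: float = 4.0
    trial_latency_jitter_sd_ms: float = 6.0
    noise_sd_uV: float = 5.0
    pink_fraction: float = 0.5
    artifact_rate: float = 0.02
    seed: int = 0
    n_standard: int = 1200
    n_deviant: int = 180
    isi_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("animal_gain_sd", "animal_latency_jitter_sd_ms",
                     "trial_latency_jitter_sd_ms", "noise_sd_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.pink_fraction <= 1:
            raise ValueError("pink_fraction must lie in [0, 1]")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


def default_templates() -> dict[str, ERPTemplate]:
    """Standard and deviant templates.

    Amplitudes are a few µV with the deviant carrying clearly larger N1 and
    P3 (change detection / conscious evaluation), matching the morphology the
    analysis expects; latencies sit inside the canonical measurement windows.
    """
    standard = ERPTemplate(STANDARD, (
        ComponentTemplate("P1", 50.0, 8.0, 2.0),
        ComponentTemplate("N1", 93.0, 10.0, 2.0),
        ComponentTemplate("P2", 118.0, 8.0, 1.5),
        ComponentTemplate("N2", 150.0, 12.0, 1.0),
        ComponentTemplate("P3", 300.0, 35.0, 1.0),
    ))
    deviant = ERPTemplate(DEVIANT, (
        ComponentTemplate("P1", 50.0, 8.0, 2.5),
        ComponentTemplate("N1", 93.0, 10.0, 6.0),
        ComponentTemplate("P2", 118.0, 8.0, 2.0),
        ComponentTemplate("N2", 150.0, 12.0, 1.5),
        ComponentTemplate("P3", 300.0, 35.0, 4.0),
    ))
    return {STANDARD: standard, DEVIANT: deviant}


def default_treatments() -> dict[str, TreatmentEffect]:
    """Qualitative treatment effect models (directions only are constrained
    by the study; magnitudes are simulator parameters)."""
    return {
        "sham": TreatmentEffect("sham"),
        "alcohol_low": TreatmentEffect(
            "alcohol_low", latency_shift_ms={"N2": 15.0}),
        "alcohol_high": TreatmentEffect(
            "alcohol_high",
            gain={"P1": 0.6, "N1": 0.25, "P2": 0.3, "N2": 0.3, "P3": 0.4}),
        "el_stim": TreatmentEffect(
            "el_stim", gain={"P1": 1.5, "N1": 1.5, "N2": 1.4}),
        "ntx3": TreatmentEffect(
            "ntx3", gain={"N1": 1.4, "P2": 1.3},
            latency_shift_ms={"P1": -8.0, "N1": -8.0}),
        "ntx6": TreatmentEffect(
            "ntx6", gain={"N1": 1.2, "N2": 1.3, "P3": 1.2}),
        "ntx30": TreatmentEffect(
            "ntx30", gain={"N1": 1.5, "P2": 1.4, "P3": 1.3},
            latency_shift_ms={"P1": -8.0, "N1": -8.0}),
    }


# ---------------------------------------------------------------------------
# stimulus sequences
# ---------------------------------------------------------------------------

def generate_oddball_sequence(n_standard: int, n_deviant: int, isi_s: float,
                              seed: int) -> StimulusSequence:
    """Random oddball train with no two successive deviants.

    Constructive placement: the ``n_standard`` standards define
    ``n_standard + 1`` gaps (before, between, after); each deviant occupies a
    distinct gap, drawn uniformly without replacement, which is a bijection
    onto the valid arrangements. Satisfiable iff
    ``n_deviant <= n_standard + 1``.
    """
    if n_standard < 0 or n_deviant < 0:
        raise ConstraintError("stimulus counts must be nonnegative")
    if n_deviant > n_standard + 1:
        raise ConstraintError(
            f"{n_deviant} deviants cannot be placed between {n_standard} "
            "standards without two deviants occurring successively")
    if isi_s <= 0:
        raise ConstraintError("isi_s must be positive")
    rng = np.random.default_rng(seed)
    gaps = np.sort(rng.choice(n_standard + 1, size=n_deviant, replace=False))
    labels: list[str] = []
    g = 0
    for gap in range(n_standard + 1):
        if g < n_deviant and gaps[g] == gap:
            labels.append(DEVIANT)
            g += 1
        if gap < n_standard:
            labels.append(STANDARD)
    onsets = np.arange(len(labels), dtype=float) * isi_s
    return StimulusSequence(tuple(labels), onsets, isi_s)


# ---------------------------------------------------------------------------
# noise and waveform rendering
# ---------------------------------------------------------------------------

def _pink_unit(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise along the last axis.

    White Gaussian noise is shaped in the rFFT domain by 1/sqrt(k) (DC
    zeroed) and rescaled by the analytically expected time-domain variance,
    keeping the output Gaussian and the generator linear/deterministic.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    k = np.arange(spec.shape[-1], dtype=float)
    w = np.zeros_like(k)
    w[1:] = 1.0 / np.sqrt(k[1:])
    shaped = np.fft.irfft(spec * w, n=n, axis=-1)
    # E[var] of irfft(rfft(white)*w): (w0^2 + 2*sum(mid w^2) + c*w_nyq^2)/n
    w2 = w**2
    if n % 2 == 0:
        evar = (w2[0] + 2.0 * w2[1:-1].sum() + w2[-1]) / n
    else:
        evar = (w2[0] + 2.0 * w2[1:].sum()) / n
    return shaped / np.sqrt(evar)


def make_noise(rng: np.random.Generator, shape: tuple[int, ...],
               noise_sd_uV: float, pink_fraction: float) -> np.ndarray:
    """Zero-mean additive noise: white/pink Gaussian mixture with total SD
    ``noise_sd_uV`` and fraction ``pink_fraction`` of variance from 1/f."""
    if noise_sd_uV < 0:
        raise ValueError("noise SD must be >= 0")
    if not 0 <= pink_fraction <= 1:
        raise ValueError("pink_fraction must lie in [0, 1]")
    if noise_sd_uV == 0:
        return np.zeros(shape)
    out = np.zeros(shape)
    if pink_fraction < 1:
        out += np.sqrt(1 - pink_fraction) * rng.standard_normal(shape)
    if pink_fraction > 0:
        out += np.sqrt(pink_fraction) * _pink_unit(rng, shape)
    return noise_sd_uV * out


def epoch_time_grid(window_ms: tuple[float, float], fs_hz: float) -> np.ndarray:
    """Half-open [start, end) sample grid in ms, with a sample exactly at 0.

    First index is round(start*fs/1000); count is round((end-start)*fs/1000).
    """
    start, end = window_ms
    first = round(start * fs_hz / 1000.0)
    n = round((end - start) * fs_hz / 1000.0)
    return (first + np.arange(n)) / fs_hz * 1000.0


def render_waveforms(template: ERPTemplate, effect: TreatmentEffect,
                     time_ms: np.ndarray, animal_gain: float,
                     animal_latency_offset_ms: float,
                     trial_latency_jitter_ms: np.ndarray | None = None,
                     n_trials: int = 1) -> np.ndarray:
    """Noiseless evoked waveforms, (n_trials, n_samples).

    Each component contributes polarity * amplitude * effect-gain *
    animal-gain * Gaussian(t; latency + effect-shift + animal offset +
    per-trial jitter, width).
    """
    t = np.asarray(time_ms, dtype=float)
    if trial_latency_jitter_ms is None:
        jitter = np.zeros(n_trials)
    else:
        jitter = np.asarray(trial_latency_jitter_ms, dtype=float)
        n_trials = jitter.size
    out = np.zeros((n_trials, t.size))
    for c in template.components:
        amp = c.polarity * c.amplitude_uV * effect.gain_for(c.name) * animal_gain
        if amp == 0:
            continue
        mu = (c.peak_latency_ms + effect.shift_for(c.name)
              + animal_latency_offset_ms + jitter)  # (n_trials,)
        out += amp * np.exp(-((t[None, :] - mu[:, None]) ** 2)
                            / (2.0 * c.width_ms ** 2))
    return out


def render_epoch(template: ERPTemplate, effect: TreatmentEffect, fs_hz: float,
                 window_ms: tuple[float, float], animal_gain: float = 1.0,
                 latency_offsets_ms: dict[str, float] | None = None,
                 noise_sd_uV: float = 0.0, pink_fraction: float = 0.0,
                 seed: int = 0) -> np.ndarray:
    """Render one single-trial waveform (µV per sample) over ``window_ms``."""
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if noise_sd_uV < 0:
        raise ValueError("noise SD must be >= 0")
    t = epoch_time_grid(window_ms, fs_hz)
    offsets = latency_offsets_ms or {}
    wave = np.zeros(t.size)
    for c in template.components:
        mu = c.peak_latency_ms + effect.shift_for(c.name) + offsets.get(c.name, 0.0)
        if not window_ms[0] <= mu < window_ms[1]:
            raise ValueError(
                f"shifted latency of {c.name} ({mu} ms) falls outside the "
                f"window {window_ms}")
        amp = c.polarity * c.amplitude_uV * effect.gain_for(c.name) * animal_gain
        wave += amp * np.exp(-((t - mu) ** 2) / (2.0 * c.width_ms ** 2))
    rng = np.random.default_rng(seed)
    return wave + make_noise(rng, (t.size,), noise_sd_uV, pink_fraction)


def _artifact_bump(fs_hz: float) -> np.ndarray:
    """Square-cosine (Hann) transient, 600 µV peak, ~50 ms duration —
    comfortably beyond the 400 µV rejection criterion."""
    n = max(3, round(ARTIFACT_DURATION_MS / 1000.0 * fs_hz))
    phase = np.linspace(0.0, np.pi, n)
    return ARTIFACT_AMPLITUDE_UV * np.sin(phase) ** 2


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


def session_seed(cohort_seed: int, animal_index: int, label: str) -> int:
    """Stable per-(animal, treatment) session seed below 2**31."""
    ss = np.random.SeedSequence(cohort_seed,
                                spawn_key=(animal_index, _label_key(label)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def animal_parameters(cohort: CohortSpec, animal_index: int) -> tuple[float, float]:
    """Per-animal (global gain, latency offset in ms).

    Drawn from the cohort seed and animal index only, so the same animal
    keeps its gain and latency idiosyncrasy across all of its treatment
    sessions (within-subjects design).
    """
    ss = np.random.SeedSequence(cohort.seed, spawn_key=(0xA11, animal_index))
    rng = np.random.default_rng(ss)
    gain = float(np.exp(rng.normal(0.0, cohort.animal_gain_sd)))
    offset = float(rng.normal(0.0, cohort.animal_latency_jitter_sd_ms))
    return gain, offset


# ---------------------------------------------------------------------------
# session-level simulation
# ---------------------------------------------------------------------------

def simulate_epochs(cohort: CohortSpec, animal_index: int,
                    effect: TreatmentEffect,
                    sequence: StimulusSequence | None = None,
                    fs_hz: float = 3000.0,
                    window_ms: tuple[float, float] = (-100.0, 700.0),
                    templates: dict[str, ERPTemplate] | None = None,
                    channel: str = "FC") -> EpochSet:
    """Render one session directly as stimulus-locked single-channel epochs.

    Equivalent to simulating the continuous record and segmenting it, minus
    inter-trial overlap and drift; used where only epoch-level content
    matters (classification experiments) because it is much cheaper.
    """
    if animal_index >= cohort.n_animals:
        raise ValueError("animal_index out of range")
    templates = templates or default_templates()
    seed = session_seed(cohort.seed, animal_index, effect.label)
    if sequence is None:
        sequence = generate_oddball_sequence(
            cohort.n_standard, cohort.n_deviant, cohort.isi_s, seed=seed)
    # noise/jitter stream forked per channel; the sequence stays shared
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_label_key(channel),)))
    gain, latency_offset = animal_parameters(cohort, animal_index)
    gain *= CHANNEL_GAINS.get(channel, 1.0)
    t = epoch_time_grid(window_ms, fs_hz)
    labels = np.asarray(sequence.labels)
    n_trials = labels.size
    jitter = rng.normal(0.0, cohort.trial_latency_jitter_sd_ms, size=n_trials)
    data = np.zeros((n_trials, t.size))
    for cls in (STANDARD, DEVIANT):
        mask = labels == cls
        if mask.any():
            data[mask] = render_waveforms(
                templates[cls], effect, t, gain, latency_offset,
                trial_latency_jitter_ms=jitter[mask])
    data += make_noise(rng, data.shape, cohort.noise_sd_uV, cohort.pink_fraction)
    artifact_trials = np.flatnonzero(
        rng.random(n_trials) < cohort.artifact_rate)
    bump = _artifact_bump(fs_hz)
    for tr in artifact_trials:
        pos = int(rng.integers(0, t.size - bump.size))
        data[tr, pos:pos + bump.size] += bump
    return EpochSet(
        data=data[:, None, :], time_ms=t, fs_hz=fs_hz, trial_class=labels,
        channels=(channel,),
        meta={"animal": animal_index, "treatment": effect.label,
              "seed": seed, "artifact_trials": artifact_trials.tolist()})


def simulate_session(cohort: CohortSpec, animal_index: int,
                     effect: TreatmentEffect,
                     sequence: StimulusSequence | None = None,
                     fs_hz: float = 3000.0,
                     templates: dict[str, ERPTemplate] | None = None,
                     ) -> ContinuousRecording:
    """Simulate one continuous 9-channel recording of a full oddball session.

    Evoked responses (standard or deviant template, treatment effect applied)
    are inserted at each stimulus onset on all channels, scaled by the
    frontocentral-to-posterior channel gain gradient; noise is independent
    per channel; artifact transients hit all channels simultaneously (they
    emulate movement) on randomly chosen trials.
    """
    if animal_index >= cohort.n_animals:
        raise ValueError("animal_index out of range")
    templates = templates or default_templates()
    seed = session_seed(cohort.seed, animal_index, effect.label)
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = generate_oddball_sequence(
            cohort.n_standard, cohort.n_deviant, cohort.isi_s,
            seed=int(rng.integers(2**31)))
    # one-ISI lead-in so the first stimulus has a full pre-stimulus window
    lead_s = sequence.isi_s
    if sequence.onsets_s[0] < 0.2:
        sequence = StimulusSequence(
            sequence.labels, sequence.onsets_s + lead_s, sequence.isi_s)
    n_samples = int(np.ceil((sequence.onsets_s[-1] + 0.9) * fs_hz))
    gain, latency_offset = animal_parameters(cohort, animal_index)

    # evoked content over a (-100, 700) ms support around each onset
    win = (-100.0, 700.0)
    t = epoch_time_grid(win, fs_hz)
    labels = np.asarray(sequence.labels)
    n_trials = labels.size
    jitter = rng.normal(0.0, cohort.trial_latency_jitter_sd_ms, size=n_trials)
    evoked = np.zeros((n_trials, t.size))
    for cls in (STANDARD, DEVIANT):
        mask = labels == cls
        if mask.any():
            evoked[mask] = render_waveforms(
                templates[cls], effect, t, gain, latency_offset,
                trial_latency_jitter_ms=jitter[mask])
    artifact_trials = np.flatnonzero(rng.random(n_trials) < cohort.artifact_rate)
    bump = _artifact_bump(fs_hz)
    art_wave = np.zeros((artifact_trials.size, t.size))
    for i in range(artifact_trials.size):
        pos = int(rng.integers(0, t.size - bump.size))
        art_wave[i, pos:pos + bump.size] = bump

    onset_samples = np.round(sequence.onsets_s * fs_hz).astype(int)
    first = round(win[0] * fs_hz / 1000.0)
    data = np.empty((len(CHANNELS), n_samples))
    for ci, ch in enumerate(CHANNELS):
        row = make_noise(rng, (n_samples,), cohort.noise_sd_uV,
                         cohort.pink_fraction)
        cg = CHANNEL_GAINS[ch]
        for tr in range(n_trials):
            lo = onset_samples[tr] + first
            row[lo:lo + t.size] += cg * evoked[tr]
        for i, tr in enumerate(artifact_trials):
            lo = onset_samples[tr] + first
            row[lo:lo + t.size] += art_wave[i]
        data[ci] = row
    return ContinuousRecording(
        channels=CHANNELS, fs_hz=fs_hz, data=data, events=sequence,
        meta={"animal": animal_index, "treatment": effect.label, "seed": seed,
              "artifact_trials": artifact_trials.tolist(), "unit": "uV"})


def simulate_cohort(cohort: CohortSpec, treatments: list[TreatmentEffect],
                    out_dir, fs_hz: float = 3000.0,
                    templates: dict[str, ERPTemplate] | None = None):
    """Simulate and write one session per (animal, treatment).

    Returns the manifest DataFrame (animal, treatment, path, seed); also
    written as ``manifest.tsv`` in ``out_dir``. Regeneration from the same
    CohortSpec is byte-identical.
    """
    import pandas as pd

    from . import io as _io

    labels = [t.label for t in treatments]
    if len(set(labels)) != len(labels):
        raise ConstraintError("duplicate treatment labels in cohort manifest")
    if cohort.n_animals < 2:
        raise ConstraintError(
            "leave-one-animal-out needs at least 2 animals")
    out_dir = _io.ensure_dir(out_dir)
    rows = []
    for animal in range(cohort.n_animals):
        for eff in treatments:
            rec = simulate_session(cohort, animal, eff, fs_hz=fs_hz,
                                   templates=templates)
            stem = f"animal{animal:02d}_{eff.label}"
            path = _io.write_recording(rec, out_dir / stem)
            rows.append({"animal": animal, "treatment": eff.label,
                         "path": str(path.name),
                         "seed": rec.meta["seed"]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def scaled_cohort(cohort: CohortSpec, **overrides) -> CohortSpec:
    """Return a copy of ``cohort`` with fields replaced (convenience)."""
    return replace(cohort, **overrides)
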