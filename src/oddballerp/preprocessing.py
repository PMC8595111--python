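"""Preprocessing: FIR filtering, epoching, baseline correction, artifact
rejection and the classification-path anti-alias downsampling.

The ERP path band-passes the continuous record at 0.1-45 Hz with a
Kaiser-window FIR, segments -100..700 ms epochs around each stimulus,
baseline-corrects on the -100..0 ms interval and rejects any (trial,
channel) whose peak-to-peak range exceeds a delta criterion (400 µV).
The classification path additionally low-passes at 32 Hz with a
least-squares linear-phase FIR and downsamples epochs to 64 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .types import ContinuousRecording, EpochSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """A designed linear-phase FIR filter.

    ``order`` is even; ``coefficients`` has ``order + 1`` symmetric taps
    (type-I), so the group delay is exactly ``order / 2`` samples.
    """

    kind: str  # 'bandpass_kaiser' | 'lowpass_leastsquares'
    band_hz: tuple
    fs_hz: float
    order: int
    coefficients: np.ndarray
    kaiser_beta: float | None = None
    attenuation_db: float | None = None
    transition_hz: float | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", h)
        if self.order % 2 != 0:
            raise ValueError("filter order must be even")
        if h.size != self.order + 1:
            raise ValueError("coefficient length must equal order + 1")
        if not np.allclose(h, h[::-1], atol=1e-12):
            raise ValueError("coefficients must be symmetric (linear phase)")

    @property
    def length(self) -> int:
        return self.coefficients.size

    def response_at(self, freq_hz) -> np.ndarray:
        """Magnitude response at the given frequencies."""
        w = 2 * np.pi * np.atleast_1d(np.asarray(freq_hz, float)) / self.fs_hz
        _, h = signal.freqz(self.coefficients, worN=w)
        return np.abs(h)


def design_bandpass_kaiser(low_hz: float, high_hz: float, fs_hz: float,
                           ripple: float = 0.001) -> FilterSpec:
    """Kaiser-window band-pass FIR (ERP path, default 0.1-45 Hz).

    The attenuation target is A = -20 log10(ripple) dB; beta follows the
    standard Kaiser formula (0.1102 (A - 8.7) for A > 50). The transition
    width is tied to the low edge, Δf = min(max(0.25 f_low, 2 Hz), 2 f_low),
    and the order is ceil((A - 8) / (2.285 · 2π Δf / fs)) rounded up to
    even. At 0.1-45 Hz / 3 kHz / 60 dB this yields order 54,330.
    """
    if not 0 < low_hz < high_hz < fs_hz / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    if not 0 < ripple < 1:
        raise ValueError("ripple must lie in (0, 1)")
    atten_db = -20.0 * np.log10(ripple)
    if atten_db > 50:
        beta = 0.1102 * (atten_db - 8.7)
    elif atten_db >= 21:
        beta = 0.5842 * (atten_db - 21) ** 0.4 + 0.07886 * (atten_db - 21)
    else:
        beta = 0.0
    transition = min(max(0.25 * low_hz, 2.0), 2.0 * low_hz)
    dw = 2 * np.pi * transition / fs_hz
    order = int(np.ceil((atten_db - 8.0) / (2.285 * dw)))
    if order % 2:
        order += 1
    h = signal.firwin(order + 1, [low_hz, high_hz], window=("kaiser", beta),
                      pass_zero=False, fs=fs_hz)
    # 0 Hz sits exactly at the lower stop-band edge; null the DC response
    # outright (symmetric tap-mean subtraction, perturbing the rest of the
    # response by < ripple) so a constant offset cannot leak through.
    h = h - h.sum() / h.size
    return FilterSpec(kind="bandpass_kaiser", band_hz=(low_hz, high_hz),
                      fs_hz=fs_hz, order=order, coefficients=h,
                      kaiser_beta=beta, attenuation_db=atten_db,
                      transition_hz=transition)


def design_antialias_ls(fs_hz: float, cutoff_hz: float = 32.0,
                        order: int = 1000,
                        target_fs_hz: float = 64.0) -> FilterSpec:
    """Least-squares linear-phase low-pass FIR for anti-alias filtering
    before downsampling (classification path, 32 Hz cut-off for 64 Hz).

    The design band transitions symmetrically around ``cutoff_hz`` (±12.5%).
    """
    if cutoff_hz > target_fs_hz / 2 or target_fs_hz / 2 > fs_hz / 2:
        raise ValueError(
            "cutoff must satisfy cutoff <= target_fs/2 <= fs/2 to prevent "
            "aliasing")
    if order % 2:
        order += 1
    edge_lo = 0.875 * cutoff_hz
    edge_hi = 1.125 * cutoff_hz
    h = signal.firls(order + 1, [0, edge_lo, edge_hi, fs_hz / 2],
                     [1, 1, 0, 0], fs=fs_hz)
    return FilterSpec(kind="lowpass_leastsquares", band_hz=(cutoff_hz,),
                      fs_hz=fs_hz, order=order, coefficients=h,
                      transition_hz=edge_hi - edge_lo)


def _filter_compensated(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Linear-phase FIR along the last axis with the group delay (order/2)
    removed, so features stay time-locked; output length equals input."""
    delay = (h.size - 1) // 2
    y = signal.fftconvolve(x, h[(np.newaxis,) * (x.ndim - 1) + (slice(None),)],
                           axes=-1)
    return y[..., delay:delay + x.shape[-1]]


def apply_fir(obj, spec: FilterSpec):
    """Filter a ContinuousRecording or EpochSet with a designed FIR.

    Continuous data must be longer than the filter; epochs shorter than the
    filter raise with the instruction to filter before epoching. Edge
    samples within order/2 of the record ends are contaminated by the
    convolution boundary; their count is recorded in metadata.
    """
    h = spec.coefficients
    if isinstance(obj, ContinuousRecording):
        if obj.data.shape[-1] <= h.size:
            raise ValueError("signal shorter than the filter")
        if abs(obj.fs_hz - spec.fs_hz) > 1e-9:
            raise ValueError("filter was designed for a different rate")
        data = _filter_compensated(obj.data, h)
        meta = dict(obj.meta)
        meta["edge_invalid_samples"] = spec.order // 2
        meta.setdefault("filters", []).append(spec.kind)
        return ContinuousRecording(obj.channels, obj.fs_hz, data, obj.events,
                                   meta)
    if isinstance(obj, EpochSet):
        if obj.data.shape[-1] <= h.size:
            raise ValueError(
                "epochs are shorter than the filter; apply this filter to "
                "the continuous recording before epoching")
        if abs(obj.fs_hz - spec.fs_hz) > 1e-9:
            raise ValueError("filter was designed for a different rate")
        # reflect-pad so epoch edges see signal, not zeros
        pad = min((h.size - 1) // 2, obj.data.shape[-1] - 1)
        padded = np.concatenate(
            [obj.data[..., pad:0:-1], obj.data, obj.data[..., -2:-pad - 2:-1]],
            axis=-1)
        data = _filter_compensated(padded, h)[..., pad:pad + obj.data.shape[-1]]
        meta = dict(obj.meta)
        meta.setdefault("filters", []).append(spec.kind)
        return obj.copy_with(data=data, meta=meta)
    raise TypeError(f"cannot filter object of type {type(obj).__name__}")


def extract_epochs(recording: ContinuousRecording,
                   window_ms: tuple[float, float] = (-100.0, 700.0)
                   ) -> EpochSet:
    """Segment stimulus-locked epochs on a half-open [start, end) ms grid.

    Stimulus onset maps exactly onto a sample (time 0). Events whose window
    would cross a record edge are dropped with a warning and counted in
    ``meta['n_dropped_edge']``.
    """
    fs = recording.fs_hz
    start, end = window_ms
    first = round(start * fs / 1000.0)
    n_samp = round((end - start) * fs / 1000.0)
    time_ms = (first + np.arange(n_samp)) / fs * 1000.0
    onset_samples = np.round(recording.events.onsets_s * fs).astype(int)
    lo = onset_samples + first
    ok = (lo >= 0) & (lo + n_samp <= recording.data.shape[1])
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("dropping %d epochs crossing the record edge", n_dropped)
    idx = lo[ok][:, None] + np.arange(n_samp)[None, :]
    data = recording.data[:, idx]          # (ch, trials, samples)
    data = np.transpose(data, (1, 0, 2))   # (trials, ch, samples)
    labels = np.asarray(recording.events.labels)[ok]
    meta = {k: recording.meta.get(k) for k in ("animal", "treatment", "seed")
            if k in recording.meta}
    meta["n_dropped_edge"] = n_dropped
    meta["window_ms"] = (float(start), float(end))
    if "artifact_trials" in recording.meta:
        kept = np.flatnonzero(ok)
        remap = {orig: new for new, orig in enumerate(kept)}
        meta["artifact_trials"] = [
            remap[t] for t in recording.meta["artifact_trials"] if t in remap]
    return EpochSet(data=data, time_ms=time_ms, fs_hz=fs, trial_class=labels,
                    channels=recording.channels, meta=meta)


def baseline_correct(epochs: EpochSet,
                     baseline_ms: tuple[float, float] = (-100.0, 0.0)
                     ) -> EpochSet:
    """Subtract the per-(trial, channel) mean over the pre-stimulus interval
    [-100, 0) ms; idempotent."""
    mask = (epochs.time_ms >= baseline_ms[0]) & (epochs.time_ms < baseline_ms[1])
    if not mask.any():
        raise ValueError(
            "no pre-stimulus samples in the epoch window; cannot baseline")
    means = epochs.data[..., mask].mean(axis=-1, keepdims=True)
    meta = dict(epochs.meta)
    meta["baseline_ms"] = tuple(map(float, baseline_ms))
    return epochs.copy_with(data=epochs.data - means, meta=meta)


def reject_artifacts(epochs: EpochSet, delta_uV: float = 400.0) -> EpochSet:
    """Flag (trial, channel) entries whose peak-to-peak range exceeds the
    delta criterion; per-channel rejection counts go to metadata."""
    if delta_uV <= 0:
        raise ValueError("delta_uV must be positive")
    ptp = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)
    keep = ptp <= delta_uV
    retained = epochs.retained & keep
    counts = {ch: int((~retained[:, ci]).sum())
              for ci, ch in enumerate(epochs.channels)}
    if not retained.any():
        log.warning("artifact rejection removed every trial")
    meta = dict(epochs.meta)
    meta["delta_uV"] = float(delta_uV)
    meta["rejected_per_channel"] = counts
    log.info("artifact rejection at %g µV: %s", delta_uV, counts)
    return epochs.copy_with(retained=retained, meta=meta)


def resample(epochs: EpochSet, target_fs_hz: float = 64.0,
             antialias: FilterSpec | None = None) -> EpochSet:
    """Anti-alias filter and downsample epochs to ``target_fs_hz``.

    The output grid is anchored at stimulus onset: samples sit at
    t = k / target_fs within the original window, so a sample lies at or
    immediately after each window boundary and time 0 is always on the
    grid (51 samples for -100..700 ms at 64 Hz). The signal is 32 Hz
    band-limited and ~47x oversampled at 3 kHz, so cubic-spline evaluation
    onto the new grid is accurate band-limited interpolation.
    """
    if target_fs_hz >= epochs.fs_hz:
        raise ValueError("upsampling is not supported")
    if antialias is None:
        antialias = design_antialias_ls(epochs.fs_hz,
                                        target_fs_hz=target_fs_hz)
    filtered = apply_fir(epochs, antialias)
    step_ms = 1000.0 / target_fs_hz
    t0, t1 = epochs.time_ms[0], epochs.time_ms[-1]
    k_min = int(np.ceil(t0 / step_ms - 1e-9))
    k_max = int(np.floor((t1 + (epochs.time_ms[1] - epochs.time_ms[0]))
                         / step_ms - 1e-9))
    new_t = np.arange(k_min, k_max + 1) * step_ms
    new_t = new_t[(new_t >= t0) & (new_t <= t1)]
    spline = interpolate.CubicSpline(filtered.time_ms, filtered.data, axis=-1)
    data = spline(new_t)
    meta = dict(filtered.meta)
    meta["source_fs_hz"] = epochs.fs_hz
    return EpochSet(data=data, time_ms=new_t, fs_hz=target_fs_hz,
                    trial_class=epochs.trial_class, channels=epochs.channels,
                    retained=epochs.retained.copy(), meta=meta)
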